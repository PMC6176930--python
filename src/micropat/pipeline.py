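"""Run orchestration: configuration, stage sequencing, outputs, manifest.

A run takes a :class:`RunConfig` (usually parsed from a YAML file),
executes the enabled stages in order —

    simulate → [render → segment] → gate → register → bdm → stats

— and writes the canonical per-cell table, per-colony results, BDM
matrices and a JSON manifest (config echo, seed, library versions, row
counts) into the output directory.  Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import PatternShape, default_shape
from .image_quant import extract_cell_features, render_image, segment_nuclei
from .io import read_cells, write_bdm, write_cells
from .registration import compute_bdm, register_colony
from .spatial_stats import classify_colony, gate_t, patterning_score
from .synthetic import Colony, GeneratorConfig, colonies_to_table, simulate_experiment

__all__ = ["RunConfig", "ConfigurationError", "run", "colonies_from_table"]


class ConfigurationError(ValueError):
    """Invalid stage combination or missing inputs, with an explicit message."""


_DEFAULT_STAGES = {
    "simulate": True,
    "render": False,
    "segment": False,
    "gate": True,
    "register": True,
    "bdm": True,
    "stats": True,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``generator`` (keyword arguments for
    :class:`~micropat.synthetic.GeneratorConfig`) with the simulate stage
    on, or ``input_table`` (path to a canonical per-cell TSV) plus
    ``shape`` naming the pattern preset the cells were grown on.
    """

    out_dir: str = "micropat_run"
    seed: int = 0
    generator: dict = field(default_factory=dict)
    input_table: str | None = None
    shape: str | None = None
    stages: dict = field(default_factory=dict)
    gate: dict = field(default_factory=lambda: {"method": "gmm2_log", "channel": "tbra"})
    bdm: dict = field(default_factory=lambda: {"bin_size_um": 10.0,
                                               "classes": ["T_pos", "T_neg"]})
    classify: dict = field(default_factory=lambda: {"method": "sign",
                                                    "score_threshold": 0.0,
                                                    "side_min_fraction": 0.25})

    def resolved_stages(self) -> dict:
        stages = dict(_DEFAULT_STAGES)
        stages.update(self.stages)
        return stages

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def colonies_from_table(table: pd.DataFrame, shape: PatternShape) -> list[Colony]:
    """Group a canonical per-cell table into Colony objects with one shape."""
    colonies = []
    for cid, group in table.groupby("colony_id", sort=True):
        colonies.append(
            Colony(colony_id=str(cid), shape=shape, cells=group.reset_index(drop=True))
        )
    return colonies


def _segment_colonies(colonies: list[Colony], seed: int) -> list[Colony]:
    """Replace each colony's cell table by the render→segment→extract output."""
    root = np.random.SeedSequence(seed)
    out = []
    for colony, child in zip(colonies, root.spawn(len(colonies))):
        image = render_image(colony, seed=np.random.default_rng(child))
        seg = segment_nuclei(image)
        features = extract_cell_features(seg, image)
        cells = pd.DataFrame(
            {
                "colony_id": colony.colony_id,
                "cell_id": features["label"].to_numpy(dtype=int) - 1
                if len(features)
                else np.array([], dtype=int),
                "x_um": features["x_um"].to_numpy(dtype=float),
                "y_um": features["y_um"].to_numpy(dtype=float),
                "z_um": 0.0,
            }
        )
        for ch in image.channels:
            cells[ch] = features[ch].to_numpy(dtype=float) if len(features) else []
        out.append(
            Colony(colony.colony_id, colony.shape, cells,
                   metadata=dict(colony.metadata), seed=colony.seed)
        )
    return out


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    stages = config.resolved_stages()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    if stages["simulate"]:
        gen = GeneratorConfig(**{"seed": config.seed, **config.generator})
        colonies = simulate_experiment(gen)
        shape = gen.resolve_shape()
    else:
        if config.input_table is None:
            raise ConfigurationError("simulate disabled but no input_table given")
        if config.shape is None:
            raise ConfigurationError("input_table runs must name the pattern `shape`")
        table = read_cells(config.input_table)
        shape = default_shape(config.shape)
        colonies = colonies_from_table(table, shape)

    if stages["render"] or stages["segment"]:
        colonies = _segment_colonies(colonies, config.seed)

    if stages["gate"]:
        pooled = pd.concat([c.cells for c in colonies], ignore_index=True)
        labels = gate_t(pooled, seed=config.seed, **config.gate)
        offset = 0
        for colony in colonies:
            n = colony.n_cells
            colony.cells["t_label"] = labels[offset : offset + n]
            offset += n
    elif stages["stats"] or stages["bdm"]:
        have_labels = all("t_label" in c.cells.columns for c in colonies)
        have_truth = all("t_label_true" in c.cells.columns for c in colonies)
        if have_truth and not have_labels:
            for colony in colonies:
                colony.cells["t_label"] = colony.cells["t_label_true"]
        elif not have_labels:
            raise ConfigurationError(
                "stats/bdm stages need a t_label column: enable the gate stage "
                "or provide gated input"
            )

    if stages["register"]:
        colonies = [register_colony(c) for c in colonies]

    cells_path = out_dir / "cells.tsv"
    table = colonies_to_table(colonies)
    table["run_seed"] = config.seed
    write_cells(cells_path, table)
    outputs["cells"] = str(cells_path)
    counts["cells"] = len(table)

    if stages["bdm"]:
        if not stages["register"]:
            raise ConfigurationError("bdm stage requires the register stage")
        for cls in config.bdm.get("classes", ["T_pos", "T_neg"]):
            bdm = compute_bdm(
                colonies, cell_class=cls,
                bin_size_um=config.bdm.get("bin_size_um", 10.0),
            )
            path = out_dir / f"bdm_{cls}.tsv"
            write_bdm(path, bdm)
            outputs[f"bdm_{cls}"] = str(path)
            counts[f"bdm_{cls}_cells"] = bdm.n_cells

    if stages["stats"]:
        if not stages["register"]:
            raise ConfigurationError("stats stage requires the register stage")
        rows = []
        perm_root = np.random.SeedSequence(config.seed + 1)
        children = perm_root.spawn(len(colonies))
        for colony, child in zip(colonies, children):
            result = patterning_score(colony)
            category = classify_colony(
                result, colony, seed=np.random.default_rng(child), **config.classify
            )
            rows.append(
                {
                    "colony_id": colony.colony_id,
                    "n_cells": result.n_cells,
                    "n_t_pos": result.n_t_pos,
                    "pct_t_pos": 100.0 * result.n_t_pos / result.n_cells,
                    "mean_travel_t_pos": result.mean_travel_t_pos,
                    "mean_travel_all": result.mean_travel_all,
                    "score": result.score,
                    "category": category,
                    "run_seed": config.seed,
                }
            )
        results = pd.DataFrame(rows)
        results_path = out_dir / "colony_results.tsv"
        results.to_csv(results_path, sep="\t", index=False)
        outputs["colony_results"] = str(results_path)
        counts["colony_results"] = len(results)

    manifest = {
        "micropat_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": outputs,
        "row_counts": counts,
        "n_colonies": len(colonies),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
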