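"""Canonical per-cell feature tables and BDM serialisation.

The exchange format is a UTF-8 tab-separated table with '.' decimal
separator, mirroring the per-cell feature-vector export of the original
quantification software: one row per cell with colony id, position in µm,
channel intensities and (once gated) the T label.  Unknown extra columns
are preserved verbatim on round trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .registration import BinnedDensityMap

__all__ = [
    "MANDATORY_COLUMNS",
    "SchemaError",
    "read_cells",
    "write_cells",
    "write_bdm",
    "read_bdm",
    "render_bdm",
]

#: Required columns of the canonical per-cell table, in canonical order.
MANDATORY_COLUMNS = ("colony_id", "cell_id", "x_um", "y_um", "z_um")


class SchemaError(ValueError):
    """A table is missing mandatory columns (named in the message)."""


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")


def write_cells(path: str | Path, table: pd.DataFrame) -> None:
    """Write the canonical per-cell TSV (full float precision, lossless)."""
    _check_schema(table)
    ordered = list(MANDATORY_COLUMNS) + [
        c for c in table.columns if c not in MANDATORY_COLUMNS
    ]
    table[ordered].to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a canonical per-cell TSV, validating the mandatory columns."""
    df = pd.read_csv(path, sep="\t")
    _check_schema(df)
    return df


def write_bdm(path: str | Path, bdm: BinnedDensityMap) -> None:
    """Write a BDM as a TSV count matrix preceded by a '#' metadata block."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# bin_size_um\t{bdm.bin_size!r}\n")
        fh.write(f"# cell_class\t{bdm.cell_class}\n")
        fh.write(f"# shape_kind\t{bdm.shape.kind}\n")
        fh.write(f"# n_cells\t{bdm.n_cells}\n")
        fh.write(f"# n_colonies\t{bdm.n_colonies}\n")
        fh.write("# x_edges\t" + "\t".join(repr(float(v)) for v in bdm.x_edges) + "\n")
        fh.write("# y_edges\t" + "\t".join(repr(float(v)) for v in bdm.y_edges) + "\n")
        np.savetxt(fh, bdm.counts, fmt="%d", delimiter="\t")


def render_bdm(path: str | Path, bdm: BinnedDensityMap, cmap: str = "magma") -> None:
    """Render a BDM as a heat-map image file (format from the extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent = (bdm.x_edges[0], bdm.x_edges[-1], bdm.y_edges[0], bdm.y_edges[-1])
    im = ax.imshow(bdm.fractions, origin="lower", extent=extent, cmap=cmap)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(
        f"{bdm.cell_class} — {bdm.n_cells} cells, {bdm.n_colonies} colonies"
    )
    fig.colorbar(im, ax=ax, label="fraction of pooled cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_bdm(path: str | Path, shape=None) -> BinnedDensityMap:
    """Read a BDM matrix written by :func:`write_bdm`.

    The pattern shape is not serialised beyond its kind; pass ``shape`` to
    restore interior-mask queries.
    """
    meta: dict[str, str] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value
            elif line.strip():
                rows.append([int(v) for v in line.split("\t")])
    counts = np.array(rows, dtype=np.int64)
    return BinnedDensityMap(
        bin_size=float(meta["bin_size_um"]),
        x_edges=np.array([float(v) for v in meta["x_edges"].split("\t")]),
        y_edges=np.array([float(v) for v in meta["y_edges"].split("\t")]),
        counts=counts,
        cell_class=meta["cell_class"],
        shape=shape,
        n_cells=int(meta["n_cells"]),
        n_colonies=int(meta["n_colonies"]),
    )
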