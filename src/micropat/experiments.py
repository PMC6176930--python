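"""Reference experiments: the standard recovery analyses, packaged as functions.

These functions wire the generator, gating, registration and statistics
into the standard parameter-recovery experiments the package is validated
against: geometric worked examples on the printed distance pairs, the
null calibration of the patterning score, recovery of the configured
per-colony T⁺ fraction through the full gating pipeline, and recovery of
the patterned / two-sided / one-sided proportions from a generator
parameterised with the reported mixture.  Both the test suite and
``scripts/acceptance.py`` run them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .geometry import Point, default_shape, distance_to_boundary, distance_to_nearest_tip
from .registration import register_colony
from .spatial_stats import classify_colony, gate_t, patterning_score
from .synthetic import DEFAULT_SIDED_MIXTURE, GeneratorConfig, simulate_experiment

__all__ = [
    "disc_boundary_distance_example",
    "ellipse_tip_distance_example",
    "score_null_calibration",
    "fraction_recovery",
    "classification_recovery",
    "DISC_T_FRACTION",
    "ELLIPSE_T_FRACTION",
    "SIDED_MIXTURE",
]

#: Reported per-colony T⁺ percentages (mean, SD): 12.6 ± 5.2 on discs,
#: 17.1 ± 7.5 on ellipses.
DISC_T_FRACTION = (12.6, 5.2)
ELLIPSE_T_FRACTION = (17.1, 7.5)

#: Reported patterning mixture on ellipses: 35% two-sided and 40%
#: one-sided of all colonies, with 85% of T⁺-containing colonies
#: patterned; those three printed figures jointly imply 13.2% randomly
#: positioned ("undefined") and 11.8% zero-T⁺ ("none") colonies.
SIDED_MIXTURE = dict(DEFAULT_SIDED_MIXTURE)


def disc_boundary_distance_example(n_cells: int = 360) -> float:
    """Mean boundary distance (µm) of cells 62.7 µm from a disc-M centre.

    Cells ringed at the reported mean distance from the centre of the
    97.5 µm disc; the expected mean distance to the boundary is 34.8 µm.
    """
    disc = default_shape("disc_m")
    angles = np.linspace(0.0, 2.0 * math.pi, n_cells, endpoint=False)
    d = [
        distance_to_boundary(disc, Point(62.7 * math.cos(t), 62.7 * math.sin(t)))
        for t in angles
    ]
    return float(np.mean(d))


def ellipse_tip_distance_example(n_cells: int = 100) -> float:
    """Mean tip distance (µm) of on-axis cells 109 µm from an ellipse-M centre.

    Cells alternate between the two major-axis sides at ±109 µm; the
    expected mean distance to the nearest tip is 11 µm.
    """
    ellipse = default_shape("ellipse_m")
    d = [
        distance_to_nearest_tip(ellipse, Point(109.0 if i % 2 == 0 else -109.0, 0.0))
        for i in range(n_cells)
    ]
    return float(np.mean(d))


def _null_config(n_colonies: int, seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        shape="ellipse_m",
        n_colonies=n_colonies,
        seed=seed,
        t_fraction_mean=15.0,
        t_fraction_sd=0.0,
        bias_strength=0.0,
        sided_mixture={"two_sided": 0.0, "one_sided": 0.0, "undefined": 1.0, "none": 0.0},
    )


def score_null_calibration(n_colonies: int = 300, seed: int = 0) -> float:
    """Mean patterning score of bias-0 colonies (expected 0).

    Ellipse-M colonies of ~200 cells with dome density and a 15% T⁺
    fraction assigned independently of position.
    """
    colonies = simulate_experiment(_null_config(n_colonies, seed))
    scores = []
    for colony in colonies:
        colony.cells["t_label"] = colony.cells["t_label_true"]
        scores.append(patterning_score(register_colony(colony)).score)
    return float(np.nanmean(scores))


def fraction_recovery(
    shape: str,
    t_fraction: tuple[float, float],
    n_colonies: int = 500,
    seed: int = 0,
) -> float:
    """Mean per-colony %T⁺ recovered end-to-end through intensity gating.

    Per-colony T⁺ fractions are drawn from a truncated normal with the
    given (mean, SD); intensities are simulated and cells re-gated with
    the two-component mixture model before measuring the mean fraction.
    The zero-T⁺ mixture class is disabled so the configured mean is the
    estimand.
    """
    mean, sd = t_fraction
    config = GeneratorConfig(
        shape=shape,
        n_colonies=n_colonies,
        seed=seed,
        t_fraction_mean=mean,
        t_fraction_sd=sd,
        sided_mixture={"two_sided": 0.39, "one_sided": 0.44, "undefined": 0.17, "none": 0.0},
    )
    colonies = simulate_experiment(config)
    pooled = pd.concat([c.cells for c in colonies], ignore_index=True)
    pooled["t_label"] = gate_t(pooled, seed=seed)
    pct = pooled.groupby("colony_id")["t_label"].apply(
        lambda s: 100.0 * (s == "T_pos").mean()
    )
    return float(pct.mean())


def classification_recovery(n_colonies: int = 500, seed: int = 0) -> dict:
    """Recover the patterned / two-sided / one-sided proportions.

    Ellipse-M colonies generated with the reported sidedness mixture
    (patterned colonies at full tips bias, the rest unbiased), gated from
    simulated intensities, and classified with the permutation-test rule
    ("undefined" = indistinguishable from random positioning at α=0.05).
    Returns percentages: patterned among T⁺-containing colonies,
    two-sided and one-sided over all colonies.
    """
    config = GeneratorConfig(
        shape="ellipse_m",
        n_colonies=n_colonies,
        seed=seed,
        t_fraction_mean=ELLIPSE_T_FRACTION[0],
        t_fraction_sd=ELLIPSE_T_FRACTION[1],
        bias_strength=1.0,
        sided_mixture=dict(SIDED_MIXTURE),
    )
    colonies = simulate_experiment(config)
    pooled = pd.concat([c.cells for c in colonies], ignore_index=True)
    labels = gate_t(pooled, seed=seed)
    offset = 0
    categories = []
    perm_root = np.random.SeedSequence(seed + 1)
    for colony, child in zip(colonies, perm_root.spawn(len(colonies))):
        n = colony.n_cells
        colony.cells["t_label"] = labels[offset : offset + n]
        offset += n
        registered = register_colony(colony)
        result = patterning_score(registered)
        categories.append(
            classify_colony(
                result,
                registered,
                method="permutation",
                seed=np.random.default_rng(child),
            )
        )
    categories = pd.Series(categories)
    n_total = len(categories)
    n_with_t = int((categories != "none").sum())
    n_patterned = int(categories.isin(["two_sided", "one_sided"]).sum())
    return {
        "patterned_pct": 100.0 * n_patterned / n_with_t if n_with_t else math.nan,
        "two_sided_pct": 100.0 * (categories == "two_sided").mean(),
        "one_sided_pct": 100.0 * (categories == "one_sided").mean(),
        "n_colonies": n_total,
    }
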