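"""Per-colony patterning statistics.

Implements the quantitative read-outs used to characterise spatial
organisation of T⁺ (brachyury-positive) cells in confined colonies:

* **patterning score** — log₂ of the mean *travel distance* (distance from
  the pattern centre as % of the longest half-axis) of T⁺ cells over the
  mean travel distance of every cell.  0 means random positioning, positive
  means peripheral/tip enrichment, negative means central enrichment.
* **colony classification** — none / undefined / one-sided / two-sided,
  with an optional permutation test against the random-positioning null.
* **neighbourhood-density statistics** — per-cell neighbour counts within a
  radius (NR, default 75 µm) and sweeps over radii, split by T label.
* **concentration-proxy maps** — top-hat neighbourhood counts on a grid,
  used as a stand-in for putative secreted-inhibitor profiles.
* **flower statistics** — inner/outer-tip T⁺ ratios and mean absolute
  deviations of per-petal %T⁺ within versus across four-petal flowers.
* plus intensity gating, surface-coverage accounting, the %T⁺-vs-density
  regression and the Pfaffl relative-expression ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

from .geometry import InvalidKindError, PatternShape
from .synthetic import T_NEG, T_POS, Colony

__all__ = [
    "PatterningResult",
    "NeighbourSpec",
    "FlowerStats",
    "EmptyColonyError",
    "UngateableError",
    "travel_distances",
    "patterning_score",
    "score_permutation_pvalue",
    "classify_colony",
    "neighbour_counts",
    "neighbour_sweep",
    "concentration_proxy_map",
    "flower_stats",
    "gate_t",
    "surface_coverage",
    "density_response_fit",
    "pfaffl_ratio",
]


class EmptyColonyError(ValueError):
    """Statistic requested on a colony with no cells."""


class UngateableError(RuntimeError):
    """Intensity mixture fit degenerate and no fallback threshold given."""


@dataclass
class PatterningResult:
    """Per-colony travel-distance summary and patterning score."""

    colony_id: str
    mean_travel_t_pos: float
    mean_travel_all: float
    score: float  # NaN when undefined (no T+ cells)
    n_t_pos: int
    n_cells: int
    category: str | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class NeighbourSpec:
    """Neighbourhood-radius specification for local-density counts."""

    radius: float = 75.0
    metric: str = "planar_2d"  # or 'euclidean_3d'
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.metric not in ("planar_2d", "euclidean_3d"):
            raise ValueError(f"unknown metric {self.metric!r}")


def travel_distances(colony: Colony) -> np.ndarray:
    """Per-cell travel distance (%) for a colony, vectorised.

    The distance from the shape centre in the shape plane, as a percentage
    of the disc radius / outer semi-major axis.
    """
    shape = colony.shape
    c = shape.to_canonical(colony.positions())
    return 100.0 * np.hypot(c[:, 0], c[:, 1]) / shape.semi_major


def patterning_score(colony: Colony, label_column: str = "t_label") -> PatterningResult:
    """Compute the colony's patterning score.

    ``score = log2(mean travel% of T+ cells / mean travel% of all cells)``
    where "all" includes the T⁺ cells.  With no T⁺ cells the score is
    undefined (NaN) and the category is "none".
    """
    if colony.n_cells == 0:
        raise EmptyColonyError(f"colony {colony.colony_id} has no cells")
    travel = travel_distances(colony)
    labels = colony.labels(label_column)
    is_pos = labels == T_POS
    n_pos = int(is_pos.sum())
    mean_all = float(travel.mean())
    if n_pos == 0 or mean_all <= 0:
        return PatterningResult(
            colony.colony_id, math.nan, mean_all, math.nan, n_pos, colony.n_cells,
            category="none",
        )
    mean_pos = float(travel[is_pos].mean())
    score = math.log2(mean_pos / mean_all)
    return PatterningResult(
        colony.colony_id, mean_pos, mean_all, score, n_pos, colony.n_cells
    )


def score_permutation_pvalue(
    colony: Colony,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    label_column: str = "t_label",
) -> float:
    """One-sided permutation p-value for peripheral enrichment of T⁺ cells.

    Null: the T⁺ label is assigned independently of position.  The observed
    mean travel distance of the T⁺ subset is compared against means of
    random subsets of the same size; p = P(random subset mean ≥ observed).
    """
    travel = travel_distances(colony)
    is_pos = colony.labels(label_column) == T_POS
    k, n = int(is_pos.sum()), len(travel)
    if k == 0 or k == n:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = travel[is_pos].mean()
    r = rng.random((n_permutations, n))
    idx = np.argpartition(r, k - 1, axis=1)[:, :k]
    perm_means = travel[idx].mean(axis=1)
    return float((1 + np.sum(perm_means >= obs)) / (n_permutations + 1))


def _side_fractions(colony: Colony, label_column: str) -> tuple[float, float]:
    c = colony.shape.to_canonical(colony.positions())
    is_pos = colony.labels(label_column) == T_POS
    x = c[is_pos, 0]
    n = len(x)
    if n == 0:
        return 0.0, 0.0
    return float((x > 0).sum() / n), float((x < 0).sum() / n)


def classify_colony(
    result: PatterningResult,
    colony: Colony,
    score_threshold: float = 0.0,
    side_min_fraction: float = 0.25,
    method: str = "sign",
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    label_column: str = "t_label",
) -> str:
    """Assign a patterning category to a colony.

    * ``none`` — no T⁺ cells.
    * ``undefined`` — T⁺ cells randomly positioned or closer to the centre
      than average.  With ``method='sign'`` this is ``score <= threshold``;
      with ``method='permutation'`` a colony is additionally undefined when
      the one-sided permutation test cannot reject random positioning at
      ``alpha`` (recommended: a random colony exceeds a zero threshold half
      the time by chance alone).
    * ``two_sided`` / ``one_sided`` — on ellipse-family shapes, patterned
      colonies split by whether both major-axis sides hold at least
      ``side_min_fraction`` of the T⁺ cells.  On discs patterned colonies
      are reported as ``patterned`` (sidedness undefined).
    """
    if result.n_t_pos == 0:
        result.category = "none"
        return "none"
    if method not in ("sign", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    patterned = result.score > score_threshold
    if patterned and method == "permutation":
        p = score_permutation_pvalue(
            colony, n_permutations=n_permutations, seed=seed, label_column=label_column
        )
        result.p_value = p
        patterned = p <= alpha
    if not patterned:
        result.category = "undefined"
        return "undefined"
    if colony.shape.kind == "disc":
        result.category = "patterned"
        return "patterned"
    fa, fb = _side_fractions(colony, label_column)
    category = (
        "two_sided" if (fa >= side_min_fraction and fb >= side_min_fraction) else "one_sided"
    )
    result.category = category
    return category


# ---------------------------------------------------------------------------
# neighbourhood density


def _coords(positions: np.ndarray, spec: NeighbourSpec) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if spec.metric == "planar_2d":
        return positions[:, :2]
    if positions.shape[1] < 3:
        z = np.zeros((len(positions), 1))
        return np.hstack([positions[:, :2], z])
    return positions[:, :3]


def neighbour_counts(positions: np.ndarray, spec: NeighbourSpec | None = None) -> np.ndarray:
    """Number of neighbours within ``spec.radius`` µm of each cell.

    Distances at exactly the radius count as neighbours; self excluded
    unless ``spec.include_self``.
    """
    spec = spec or NeighbourSpec()
    pts = _coords(positions, spec)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, spec.radius, return_length=True)
    if not spec.include_self:
        counts = counts - 1
    return counts.astype(int)


def neighbour_sweep(
    units: Sequence[Colony] | Sequence[tuple[np.ndarray, np.ndarray]],
    radii: Sequence[float],
    label_column: str = "t_label",
    metric: str = "planar_2d",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Neighbour-count distributions over a range of radii, split by T label.

    ``units`` are the pooling units (colonies, or (positions, labels)
    pairs for unconfined fields); counts are computed within each unit and
    pooled.  Returns ``(per_cell, summary)``: the long per-cell table
    (unit, radius, t_label, count) and medians per (radius, label).
    """
    radii = list(radii)
    if any(r <= 0 for r in radii) or sorted(radii) != radii:
        raise ValueError("radii must be positive and sorted ascending")
    rows = []
    for u, unit in enumerate(units):
        if isinstance(unit, Colony):
            pos, labels = unit.positions(), unit.labels(label_column)
            unit_id = unit.colony_id
        else:
            pos, labels = unit
            unit_id = f"u{u}"
        for r in radii:
            counts = neighbour_counts(pos, NeighbourSpec(radius=r, metric=metric))
            rows.append(
                pd.DataFrame(
                    {"unit": unit_id, "radius_um": r, "t_label": labels, "count": counts}
                )
            )
    per_cell = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit", "radius_um", "t_label", "count"]
    )
    summary = (
        per_cell.groupby(["radius_um", "t_label"], observed=True)["count"]
        .agg(median="median", mean="mean", n="size")
        .reset_index()
    )
    return per_cell, summary


def concentration_proxy_map(
    positions: np.ndarray,
    kernel_radius_um: float,
    grid_step_um: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-hat neighbourhood map: cells within the kernel radius of each node.

    A proxy for the concentration profile a uniformly secreted, locally
    acting molecule would reach — the kernel radius plays the role of the
    diffusion length.  Returns ``(x_nodes, y_nodes, field)`` with ``field``
    indexed ``[iy, ix]``.
    """
    if kernel_radius_um <= 0 or grid_step_um <= 0:
        raise ValueError("kernel radius and grid step must be positive")
    positions = np.asarray(positions, dtype=float)[:, :2] if len(positions) else (
        np.empty((0, 2))
    )
    if bounds is None:
        if len(positions) == 0:
            bounds = (-1.0, 1.0, -1.0, 1.0)
        else:
            m = kernel_radius_um
            bounds = (
                positions[:, 0].min() - m,
                positions[:, 0].max() + m,
                positions[:, 1].min() - m,
                positions[:, 1].max() + m,
            )
    x0, x1, y0, y1 = bounds
    xs = np.arange(x0, x1 + 0.5 * grid_step_um, grid_step_um)
    ys = np.arange(y0, y1 + 0.5 * grid_step_um, grid_step_um)
    field_shape = (len(ys), len(xs))
    if len(positions) == 0:
        return xs, ys, np.zeros(field_shape)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(positions)
    counts = tree.query_ball_point(nodes, kernel_radius_um, return_length=True)
    return xs, ys, counts.reshape(field_shape).astype(float)


# ---------------------------------------------------------------------------
# flower statistics


@dataclass
class FlowerStats:
    """Inner/outer tip enrichment and petal-to-petal variability of %T⁺.

    ``petals`` has one row per petal (flower_id, petal_index, pct_t_pos,
    inner_pct, outer_pct, log2_inner_outer); ``within_flower_mad`` one value
    per flower; ``across_flower_mad`` the MAD of per-flower mean %T⁺.
    """

    petals: pd.DataFrame
    within_flower_mad: pd.Series
    across_flower_mad: float
    tip_window: float = 0.25


class IncompleteFlowerError(ValueError):
    """A flower with fewer than 4 petals was supplied."""


def _mad(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.mean(np.abs(values - values.mean())))


def flower_stats(
    flowers: Sequence[Sequence[Colony]],
    tip_window: float = 0.25,
    label_column: str = "t_label",
) -> FlowerStats:
    """Tip-ratio and MAD statistics over four-petal flowers.

    Petal colonies must be registered with the inner tip (nearest the
    flower centre) at −x.  ``tip_window`` is the fraction of the major axis
    taken as each tip region (0.25 → the outer quarter of [−a, a] on each
    end, i.e. |x| ≥ a/2).  The inner/outer log₂ ratio uses a pseudo-count
    of one cell's worth of percentage to stay finite; petals with zero T⁺
    cells at both tips get ratio 0.
    """
    if not 0 < tip_window < 0.5:
        raise ValueError("tip_window must lie in (0, 0.5)")
    rows = []
    flower_means = []
    within = {}
    for f, petals in enumerate(flowers):
        if len(petals) < 4:
            raise IncompleteFlowerError(f"flower {f} has {len(petals)} petals; need 4")
        pcts = []
        for j, petal in enumerate(petals):
            labels = petal.labels(label_column)
            is_pos = labels == T_POS
            n = petal.n_cells
            pct = 100.0 * is_pos.sum() / n if n else 0.0
            pcts.append(pct)
            a = petal.shape.semi_major
            x = petal.shape.to_canonical(petal.positions())[:, 0]
            cut = a * (1.0 - 2.0 * tip_window)
            inner_mask, outer_mask = x <= -cut, x >= cut
            inner_pct = (
                100.0 * (is_pos & inner_mask).sum() / inner_mask.sum()
                if inner_mask.any()
                else 0.0
            )
            outer_pct = (
                100.0 * (is_pos & outer_mask).sum() / outer_mask.sum()
                if outer_mask.any()
                else 0.0
            )
            if inner_pct == 0.0 and outer_pct == 0.0:
                ratio = 0.0
            else:
                eps = 100.0 / n if n else 1.0
                ratio = math.log2((inner_pct + eps) / (outer_pct + eps))
            rows.append(
                {
                    "flower_id": f,
                    "petal_index": j,
                    "pct_t_pos": pct,
                    "inner_pct": inner_pct,
                    "outer_pct": outer_pct,
                    "log2_inner_outer": ratio,
                }
            )
        within[f] = _mad(np.array(pcts))
        flower_means.append(float(np.mean(pcts)))
    petals_df = pd.DataFrame(rows)
    return FlowerStats(
        petals=petals_df,
        within_flower_mad=pd.Series(within, name="within_flower_mad"),
        across_flower_mad=_mad(np.array(flower_means)),
        tip_window=tip_window,
    )


# ---------------------------------------------------------------------------
# gating, coverage, regression, qPCR


def gate_t(
    table: pd.DataFrame,
    method: str = "gmm2_log",
    channel: str = "tbra",
    threshold: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Label each cell T_pos/T_neg from its brachyury-channel intensity.

    ``gmm2_log`` fits a two-component Gaussian mixture to log10 intensities
    and assigns T_pos at posterior > 0.5 for the high component.  If the
    fitted components are closer than 0.1 log10 units the fit is considered
    degenerate and the method falls back to ``threshold`` (if given) or
    raises :class:`UngateableError`.  ``fixed_threshold`` labels T_pos at
    intensity strictly above the threshold.
    """
    values = table[channel].to_numpy(dtype=float)
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold gating needs a threshold")
        return np.where(values > threshold, T_POS, T_NEG).astype(object)
    if method != "gmm2_log":
        raise ValueError(f"unknown gating method {method!r}")
    if np.any(values <= 0):
        raise ValueError("log-scale gating requires strictly positive intensities")
    logv = np.log10(values).reshape(-1, 1)
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gmm.fit(logv)
    means = gmm.means_.ravel()
    if abs(means[0] - means[1]) < 0.1:
        if threshold is not None:
            return np.where(values > threshold, T_POS, T_NEG).astype(object)
        raise UngateableError(
            "mixture components closer than 0.1 log10 units and no fallback threshold"
        )
    high = int(np.argmax(means))
    post = gmm.predict_proba(logv)[:, high]
    return np.where(post > 0.5, T_POS, T_NEG).astype(object)


def surface_coverage(
    mode: str,
    n_cells: int | None = None,
    area_um2: float | None = None,
    colonies_per_cm2: float | None = None,
    mean_cells_per_colony: float | None = None,
) -> float:
    """Cells per cm² for unconfined or micropatterned cultures.

    Unconfined: segmented nuclei divided by imaged area.  Micropatterned:
    colonies per cm² (visual count) times mean cells per colony.
    """
    if mode == "unconfined":
        if n_cells is None or area_um2 is None:
            raise ValueError("unconfined mode needs n_cells and area_um2")
        if area_um2 <= 0:
            raise ValueError("area must be positive")
        return n_cells / area_um2 * 1e8  # µm² per cm²
    if mode == "micropatterned":
        if colonies_per_cm2 is None or mean_cells_per_colony is None:
            raise ValueError(
                "micropatterned mode needs colonies_per_cm2 and mean_cells_per_colony"
            )
        return colonies_per_cm2 * mean_cells_per_colony
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DensityFit:
    """OLS fit of %T⁺ against (log) global density with a 95% CI band."""

    slope: float
    intercept: float
    log_x: bool
    _results: object = field(repr=False, default=None)

    def predict(self, x: np.ndarray) -> pd.DataFrame:
        """Fitted %T⁺ and pointwise 95% CI at densities ``x`` (cells/cm²)."""
        x = np.asarray(x, dtype=float)
        xt = np.log10(x) if self.log_x else x
        exog = sm.add_constant(xt, has_constant="add")
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=0.05)
        return pd.DataFrame(
            {
                "x": x,
                "fit": frame["mean"].to_numpy(),
                "ci_low": frame["mean_ci_lower"].to_numpy(),
                "ci_high": frame["mean_ci_upper"].to_numpy(),
            }
        )

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self._results.conf_int(alpha=alpha)[1]
        return float(lo), float(hi)


def density_response_fit(
    x: np.ndarray, y: np.ndarray, log_x: bool = True
) -> DensityFit:
    """Fit %T⁺ per field against global cell density by OLS.

    The covariate defaults to log₁₀ density because tested densities span
    more than an order of magnitude.  Requires ≥3 points and non-constant
    x; a negative slope is the expected direction (lower global density →
    more T⁺ cells).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant covariate: singular fit")
    xt = np.log10(x) if log_x else x
    exog = sm.add_constant(xt)
    results = sm.OLS(y, exog).fit()
    return DensityFit(
        slope=float(results.params[1]),
        intercept=float(results.params[0]),
        log_x=log_x,
        _results=results,
    )


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected relative expression ratio for qPCR.

    ``ratio = E_target^ΔCt_target / E_ref^ΔCt_ref`` with
    ΔCt = Ct(control) − Ct(sample) and amplification efficiencies in
    (1, 2] (2 = perfect doubling per cycle).
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if e <= 1.0:
            raise ValueError(f"{name} efficiency must exceed 1, got {e}")
    return float(e_target**dct_target / e_ref**dct_ref)
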