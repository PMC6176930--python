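"""Desk-scale image quantification: render, segment, extract.

The original quantification software segmented nuclei in 3D confocal
stacks and exported
per-cell centroids and channel intensities.  This module re-implements
that front end in 2D at the reference lateral sampling (0.38 µm/px): it
renders two-channel synthetic colony images from a generated
:class:`~micropat.synthetic.Colony` (nuclear stain + brachyury channel),
segments nuclei with a standard smooth → Otsu → distance-transform
watershed chain, and extracts per-cell centroids and mean intensities —
so the whole statistics pipeline can be exercised end-to-end from pixels
against generator ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .synthetic import Colony

__all__ = [
    "ColonyImage",
    "SegmentationResult",
    "CanvasError",
    "render_image",
    "segment_nuclei",
    "extract_cell_features",
    "write_image",
    "read_image",
]

#: Lateral pixel size matching the reference confocal sampling.
DEFAULT_PIXEL_SIZE_UM = 0.38


class CanvasError(ValueError):
    """Colony extent exceeds the configured maximum canvas."""


@dataclass
class ColonyImage:
    """Two-channel 2D image of one colony.

    ``channels`` maps name → float array (AFU), all sharing one shape;
    ``origin_um`` is the µm coordinate of the outer corner of pixel
    (0, 0), so pixel centre (row, col) sits at
    ``origin + (col + 0.5, row + 0.5) * pixel_size``.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    origin_um: tuple[float, float]
    colony_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share dimensions")

    def px_to_um(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_um[0] + (np.asarray(cols) + 0.5) * self.pixel_size_um
        y = self.origin_um[1] + (np.asarray(rows) + 0.5) * self.pixel_size_um
        return x, y


@dataclass
class SegmentationResult:
    """Nuclei label map plus per-object measurements.

    ``label_map`` assigns 0 to background and 1..K to objects;
    ``features`` has one row per object (label, x_um, y_um, area_um2 and a
    mean-intensity column per channel).
    """

    label_map: np.ndarray
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_objects(self) -> int:
        return int(self.label_map.max())


def render_image(
    colony: Colony,
    nucleus_radius_um: float = 3.0,
    psf_sigma_um: float = 0.5,
    noise_model: dict | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    margin_um: float = 12.0,
    nuclear_channel: str = "dapi",
    t_channel: str = "tbra",
    max_canvas_px: int = 6000,
) -> ColonyImage:
    """Render a colony as a two-channel image.

    Each cell contributes a disc of radius ``nucleus_radius_um`` carrying
    its nuclear-channel AFU (nuclear channel) and its brachyury AFU
    (T channel) within the same footprint; both channels are blurred with
    a Gaussian PSF and given additive Gaussian background noise
    (``noise_model = {'background': 10, 'sd': 2}`` by default).
    Deterministic given the seed.
    """
    if nucleus_radius_um <= 0 or pixel_size_um <= 0 or psf_sigma_um < 0:
        raise ValueError("radii and pixel size must be positive")
    noise = {"background": 10.0, "sd": 2.0, **(noise_model or {})}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pos = colony.positions()
    if len(pos):
        x0 = pos[:, 0].min() - margin_um
        x1 = pos[:, 0].max() + margin_um
        y0 = pos[:, 1].min() - margin_um
        y1 = pos[:, 1].max() + margin_um
    else:
        x0, x1, y0, y1 = -margin_um, margin_um, -margin_um, margin_um
    ncols = int(math.ceil((x1 - x0) / pixel_size_um))
    nrows = int(math.ceil((y1 - y0) / pixel_size_um))
    if ncols > max_canvas_px or nrows > max_canvas_px:
        raise CanvasError(
            f"canvas {nrows}x{ncols} px exceeds maximum {max_canvas_px}"
        )
    nuclear = np.zeros((nrows, ncols))
    t_chan = np.zeros((nrows, ncols))

    r_px = nucleus_radius_um / pixel_size_um
    patch = int(math.ceil(r_px)) + 1
    amp_nuc = (
        colony.cells[nuclear_channel].to_numpy(dtype=float)
        if nuclear_channel in colony.cells.columns
        else np.full(len(pos), 500.0)
    )
    amp_t = (
        colony.cells[t_channel].to_numpy(dtype=float)
        if t_channel in colony.cells.columns
        else np.full(len(pos), 100.0)
    )
    for (cx, cy), an, at in zip(pos, amp_nuc, amp_t):
        col_c = (cx - x0) / pixel_size_um - 0.5
        row_c = (cy - y0) / pixel_size_um - 0.5
        rlo = max(0, int(row_c) - patch)
        rhi = min(nrows, int(row_c) + patch + 2)
        clo = max(0, int(col_c) - patch)
        chi = min(ncols, int(col_c) + patch + 2)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        mask = (rr - row_c) ** 2 + (cc - col_c) ** 2 <= r_px**2
        nuclear[rlo:rhi, clo:chi] += an * mask
        t_chan[rlo:rhi, clo:chi] += at * mask

    sigma_px = psf_sigma_um / pixel_size_um
    if sigma_px > 0:
        nuclear = gaussian(nuclear, sigma=sigma_px, preserve_range=True)
        t_chan = gaussian(t_chan, sigma=sigma_px, preserve_range=True)
    for img in (nuclear, t_chan):
        img += rng.normal(noise["background"], noise["sd"], size=img.shape)
        np.clip(img, 0.0, None, out=img)
    return ColonyImage(
        channels={nuclear_channel: nuclear, t_channel: t_chan},
        pixel_size_um=pixel_size_um,
        origin_um=(x0, y0),
        colony_id=colony.colony_id,
        seed=colony.seed,
    )


def segment_nuclei(
    image: ColonyImage,
    smoothing_sigma_um: float = 1.0,
    threshold_method: str = "otsu",
    min_area_um2: float = 9.0,
    min_peak_separation_um: float = 3.0,
    nuclear_channel: str = "dapi",
    fixed_threshold: float | None = None,
) -> SegmentationResult:
    """Segment nuclei in the nuclear channel.

    Gaussian smoothing → global threshold (Otsu by default) → watershed on
    the distance transform seeded at local maxima at least
    ``min_peak_separation_um`` apart → removal of objects below
    ``min_area_um2``.  A background-only image yields an empty result.
    """
    if nuclear_channel not in image.channels:
        raise KeyError(f"image has no channel {nuclear_channel!r}")
    img = image.channels[nuclear_channel].astype(float)
    px = image.pixel_size_um
    smoothed = gaussian(img, sigma=smoothing_sigma_um / px, preserve_range=True)

    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold_method needs fixed_threshold")
        thr = fixed_threshold
    elif threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
        # reject an Otsu split of pure background noise
        med = float(np.median(smoothed))
        mad = float(np.median(np.abs(smoothed - med)))
        if thr <= med + 6.0 * 1.4826 * mad:
            return SegmentationResult(
                np.zeros_like(img, dtype=np.int32), _empty_features(image)
            )
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")

    binary = smoothed > thr
    if not binary.any():
        return SegmentationResult(np.zeros_like(img, dtype=np.int32), _empty_features(image))
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=max(1, int(round(min_peak_separation_um / px))),
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros_like(img, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=binary)

    min_area_px = min_area_um2 / px**2
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region in regionprops(labels):
        if region.area >= min_area_px:
            out[labels == region.label] = next_label
            next_label += 1
    return SegmentationResult(out, _empty_features(image))


def _empty_features(image: ColonyImage) -> pd.DataFrame:
    cols = ["label", "x_um", "y_um", "area_um2"] + [f"{c}" for c in image.channels]
    return pd.DataFrame(columns=cols)


def extract_cell_features(seg: SegmentationResult, image: ColonyImage) -> pd.DataFrame:
    """Per-object feature table: sub-pixel centroid (µm) and mean AFU per channel.

    Centroids are intensity-weighted by the nuclear channel if present
    (sub-pixel accuracy on isolated nuclei), otherwise geometric.
    """
    labels = seg.label_map
    if labels.max() == 0:
        seg.features = _empty_features(image)
        return seg.features
    channel_names = list(image.channels)
    weight_name = "dapi" if "dapi" in image.channels else channel_names[0]
    px = image.pixel_size_um
    rows = []
    props = regionprops(labels, intensity_image=image.channels[weight_name])
    means = {
        name: ndi.labeled_comprehension(
            image.channels[name], labels, np.arange(1, labels.max() + 1), np.mean, float, 0.0
        )
        for name in channel_names
    }
    for region in props:
        wrow, wcol = region.centroid_weighted
        x, y = image.px_to_um(np.array(wrow), np.array(wcol))
        row = {
            "label": region.label,
            "x_um": float(x),
            "y_um": float(y),
            "area_um2": float(region.area) * px**2,
        }
        for name in channel_names:
            row[name] = float(means[name][region.label - 1])
        rows.append(row)
    seg.features = pd.DataFrame(rows)
    return seg.features


# ---------------------------------------------------------------------------
# TIFF IO


def write_image(path, image: ColonyImage) -> None:
    """Write a multi-page TIFF (one page per channel) with µm metadata."""
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "origin_um": list(image.origin_um),
        "channels": list(image.channels),
        "colony_id": image.colony_id,
        "seed": image.seed,
    }
    stack = np.stack([image.channels[c] for c in image.channels]).astype(np.float32)
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_image(path) -> ColonyImage:
    """Read a multi-page TIFF written by :func:`write_image`."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    return ColonyImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        origin_um=tuple(meta["origin_um"]),
        colony_id=meta.get("colony_id", ""),
        seed=meta.get("seed"),
    )
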