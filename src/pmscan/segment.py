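"""Cell centroid detection, PM/nuclear masking and territory assignment.

Segmentation works from the designated channel roles: centroids come
from one of three strategies (the nuclear hole left by a
nucleus-excluded reporter, the void inside a membrane-only reporter, or
an explicit nuclear marker); the PM mask is the thinned ridge of the
membrane channel; territories partition the field so every downstream
statistic is per-cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .core import (
    ROLE_MEMBRANE,
    ROLE_NUCLEAR,
    ROLE_REPORTER,
    ChannelMissingError,
    FieldImage,
)

log = logging.getLogger(__name__)

STRATEGY_NUCLEAR_HOLE = "nuclear-hole"
STRATEGY_MEMBRANE_VOID = "membrane-void"
STRATEGY_NUCLEAR_MARKER = "nuclear-marker"
STRATEGIES = (STRATEGY_NUCLEAR_HOLE, STRATEGY_MEMBRANE_VOID,
              STRATEGY_NUCLEAR_MARKER)


class NoMembraneStructureError(RuntimeError):
    """Membrane channel has no ridge (e.g. uniformly saturated)."""


@dataclass
class SegmentationParams:
    """Tunables shared by all segmentation steps.

    ``expected_cell_radius`` (px) scales the background-subtraction
    structuring element (4x the radius); ``smooth_sigma`` is the Gaussian
    pre-smoothing applied before thresholding; ``min_blob_area`` (px^2)
    drops spurious detections.
    """

    expected_cell_radius: float = 16.0
    smooth_sigma: float = 1.0
    min_blob_area: float = 30.0
    exclude_border_blobs: bool = True


@dataclass
class SegmentationResult:
    """Centroids, masks and per-pixel cell territories for one field.

    ``territories`` labels every pixel with the cell it belongs to
    (1-based, matching centroid order; 0 never occurs — background is
    split among the nearest cells so cytoplasm statistics stay per-cell).
    ``border_cell[i]`` flags cells whose territory touches the image edge.
    """

    centroids: np.ndarray            # (n, 2) float, (row, col)
    pm_mask: np.ndarray              # bool
    territories: np.ndarray          # int labels, 1-based
    nuclear_mask: np.ndarray | None  # int labels matching centroid indices
    strategy_used: str
    border_cell: np.ndarray = field(default=None)  # bool per cell

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------

def subtract_background(channel: np.ndarray,
                        radius: float | None = None,
                        expected_cell_radius: float = 16.0) -> np.ndarray:
    """Morphological background estimate (grey opening) subtracted, clipped at 0.

    The structuring element spans 4x the expected cell radius so whole
    cells are treated as foreground while smooth illumination gradients
    and constant offsets are removed.
    """
    if radius is None:
        radius = 4.0 * expected_cell_radius
    size = 2 * int(radius) + 1
    bg = ndi.grey_opening(channel, size=(size, size))
    return np.clip(channel - bg, 0.0, None)


def _smoothed(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    ch = subtract_background(channel,
                             expected_cell_radius=params.expected_cell_radius)
    if params.smooth_sigma > 0:
        ch = ndi.gaussian_filter(ch, params.smooth_sigma)
    return ch


def _weighted_centroids(weight: np.ndarray, labels: np.ndarray,
                        index: Sequence[int]) -> np.ndarray:
    w = np.clip(weight, 1e-12, None)
    coms = ndi.center_of_mass(w, labels=labels, index=list(index))
    return np.asarray(coms, dtype=float).reshape(-1, 2)


def _filter_blobs(mask: np.ndarray, params: SegmentationParams
                  ) -> tuple[np.ndarray, list[int]]:
    """Label a binary mask, dropping small and (optionally) border blobs."""
    labels, n = ndi.label(mask)
    if n == 0:
        return labels, []
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = set(np.flatnonzero(areas >= params.min_blob_area) + 1)
    if params.exclude_border_blobs:
        edge = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        keep -= set(int(e) for e in edge if e)
    return labels, sorted(keep)


# --------------------------------------------------------------------------
# centroid strategies
# --------------------------------------------------------------------------

def detect_centroids(fieldimg: FieldImage, strategy: str,
                     params: SegmentationParams | None = None) -> np.ndarray:
    """Locate one centroid per cell using the requested strategy.

    * ``nuclear-hole``: dark nuclear holes inside the bright reporter
      signal of cells whose reporter is excluded from the nucleus;
    * ``membrane-void``: the dark interior enclosed by each membrane ring;
    * ``nuclear-marker``: bright blobs of an explicit nuclear channel.

    Centroids are intensity-weighted centers of the detected blobs (the
    weights are inverted for hole/void strategies).  Blobs below the
    minimum area or touching the image border are dropped.  Returns an
    (n, 2) array of (row, col); an empty field yields an empty array.
    """
    params = params or SegmentationParams()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")

    if strategy == STRATEGY_NUCLEAR_MARKER:
        ch = _smoothed(fieldimg.channel(ROLE_NUCLEAR), params)
        mask = _threshold(ch)
        labels, keep = _filter_blobs(mask, params)
        weight = ch
    elif strategy == STRATEGY_NUCLEAR_HOLE:
        ch = _smoothed(fieldimg.channel(ROLE_REPORTER), params)
        mask = _threshold(ch)
        holes = ndi.binary_fill_holes(mask) & ~mask
        labels, keep = _filter_blobs(holes, params)
        weight = np.clip(ch.max() - ch, 0.0, None)
    else:  # membrane-void
        ch = _smoothed(fieldimg.channel(ROLE_MEMBRANE), params)
        mask = _threshold(ch)
        voids = ndi.binary_fill_holes(mask) & ~mask
        labels, keep = _filter_blobs(voids, params)
        weight = np.clip(ch.max() - ch, 0.0, None)

    if not keep:
        log.info("detect_centroids(%s): zero detections", strategy)
        return np.empty((0, 2), dtype=float)
    return _weighted_centroids(weight, labels, keep)


def _threshold(smoothed: np.ndarray) -> np.ndarray:
    """Otsu threshold gated against pure noise.

    On a background-only field Otsu happily splits the noise in two; the
    gate requires the threshold to clear 6x the robust noise scale
    (MAD-based, valid because background dominates the pixel population)
    before any pixel counts as foreground.
    """
    if np.ptp(smoothed) < 1e-9:
        return np.zeros(smoothed.shape, dtype=bool)
    thr = threshold_otsu(smoothed)
    med = np.median(smoothed)
    noise_scale = 1.4826 * np.median(np.abs(smoothed - med))
    if thr < med + 6.0 * noise_scale:
        return np.zeros(smoothed.shape, dtype=bool)
    return smoothed > thr


# --------------------------------------------------------------------------
# masks
# --------------------------------------------------------------------------

def build_pm_mask(fieldimg: FieldImage,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Thinned (<=2 px) ridge of the membrane channel.

    Background-subtract, smooth, Otsu-threshold, then skeletonize the
    binary membrane band down to its centerline.  Raises
    :class:`NoMembraneStructureError` when the channel carries no ridge
    (flat or uniformly saturated).
    """
    params = params or SegmentationParams()
    raw = fieldimg.channel(ROLE_MEMBRANE)
    ch = _smoothed(raw, params)
    mask = _threshold(ch)
    frac = mask.mean()
    if frac < 1e-5 or frac > 0.9:
        raise NoMembraneStructureError("no membrane structure")
    return skeletonize(mask)


def build_nuclear_mask(fieldimg: FieldImage,
                       centroids: np.ndarray | None = None,
                       params: SegmentationParams | None = None,
                       allow_hole_fallback: bool = False) -> np.ndarray:
    """Labeled nuclear mask, one label per cell.

    Uses the nuclear channel when present; with ``allow_hole_fallback``
    the nuclear holes of a nucleus-excluded reporter stand in for it.
    When ``centroids`` are given, labels correspond to centroid indices
    (label ``i+1`` = centroid ``i``) and touching nuclei are split by
    marker-based watershed from the centroids.
    """
    params = params or SegmentationParams()
    if ROLE_NUCLEAR in fieldimg.channels:
        ch = _smoothed(fieldimg.channel(ROLE_NUCLEAR), params)
        binary = _threshold(ch)
    elif allow_hole_fallback:
        ch = _smoothed(fieldimg.channel(ROLE_REPORTER), params)
        mask = _threshold(ch)
        binary = ndi.binary_fill_holes(mask) & ~mask
    else:
        raise ChannelMissingError(
            "field has no 'nuclear' channel and hole fallback not requested")

    # drop specks
    lab0, n0 = ndi.label(binary)
    if n0:
        areas = ndi.sum_labels(binary, lab0, index=np.arange(1, n0 + 1))
        bad = np.flatnonzero(areas < params.min_blob_area) + 1
        binary &= ~np.isin(lab0, bad)

    if centroids is None or len(centroids) == 0:
        labels, _ = ndi.label(binary)
        return labels

    markers = np.zeros(binary.shape, dtype=np.int32)
    idx = np.clip(np.round(np.asarray(centroids)).astype(int), 0,
                  np.array(binary.shape) - 1)
    markers[idx[:, 0], idx[:, 1]] = np.arange(1, len(centroids) + 1)
    dist = ndi.distance_transform_edt(binary)
    labels = watershed(-dist, markers=markers, mask=binary)
    return labels


def assign_territories(centroids: np.ndarray, pm_mask: np.ndarray,
                       shape: tuple[int, int]) -> np.ndarray:
    """Assign every pixel to its cell (1-based labels matching centroids).

    Nearest-centroid flooding with the PM mask acting as a barrier:
    water must rise over the membrane ridge to cross it, so territories
    respect closed rings (geodesic preference) and meet at the
    equidistance line in open background.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) < 1:
        raise ValueError("assign_territories requires at least one centroid")
    markers = np.zeros(shape, dtype=np.int32)
    idx = np.clip(np.round(centroids).astype(int), 0, np.array(shape) - 1)
    markers[idx[:, 0], idx[:, 1]] = np.arange(1, len(centroids) + 1)
    dist = ndi.distance_transform_edt(markers == 0)
    barrier = float(dist.max()) + 1.0
    elevation = dist + barrier * pm_mask
    return watershed(elevation, markers=markers)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def segment(fieldimg: FieldImage, strategy: str = "auto",
            params: SegmentationParams | None = None,
            build_nuclei: bool | None = None) -> SegmentationResult:
    """Full segmentation: centroids, PM mask, territories, nuclei, QC flags.

    ``strategy='auto'`` picks nuclear-marker when a nuclear channel is
    present, else nuclear-hole when a reporter is present, else
    membrane-void.
    """
    params = params or SegmentationParams()
    if strategy == "auto":
        if ROLE_NUCLEAR in fieldimg.channels:
            strategy = STRATEGY_NUCLEAR_MARKER
        elif ROLE_REPORTER in fieldimg.channels:
            strategy = STRATEGY_NUCLEAR_HOLE
        else:
            strategy = STRATEGY_MEMBRANE_VOID

    centroids = detect_centroids(fieldimg, strategy, params)
    if len(centroids) == 0:
        try:
            pm_mask = build_pm_mask(fieldimg, params)
        except NoMembraneStructureError:
            pm_mask = np.zeros(fieldimg.shape, dtype=bool)
        return SegmentationResult(
            centroids=centroids, pm_mask=pm_mask,
            territories=np.zeros(fieldimg.shape, dtype=np.int32),
            nuclear_mask=None, strategy_used=strategy,
            border_cell=np.zeros(0, dtype=bool))
    pm_mask = build_pm_mask(fieldimg, params)
    territories = assign_territories(centroids, pm_mask, fieldimg.shape)

    if build_nuclei is None:
        build_nuclei = ROLE_NUCLEAR in fieldimg.channels
    nuclear_mask = None
    if build_nuclei:
        nuclear_mask = build_nuclear_mask(
            fieldimg, centroids, params,
            allow_hole_fallback=ROLE_NUCLEAR not in fieldimg.channels)

    # a cell is a border cell when its PM ring is interrupted by the image
    # edge: an intact ring encloses the centroid, so hole-filling the ridge
    # covers it, while a cut ring does not fill
    filled = ndi.binary_fill_holes(pm_mask)
    idx = np.clip(np.round(centroids).astype(int), 0,
                  np.array(fieldimg.shape) - 1)
    border = ~filled[idx[:, 0], idx[:, 1]]
    return SegmentationResult(
        centroids=centroids, pm_mask=pm_mask, territories=territories,
        nuclear_mask=nuclear_mask, strategy_used=strategy, border_cell=border)
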