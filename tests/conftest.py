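"""Shared fixtures and oracles for the test suite.

The dense-polar oracle recomputes a cell's PM/cytoplasm ratio directly
from the analytic cell geometry (no segmentation, no masks): crossings
are placed on the exact PM-band centerline and intensities are sampled
densely along each radius.  It is the independent reference the radial
scan is checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from pmscan.quantify import RayScanParams
from pmscan.segment import subtract_background
from pmscan.synth import CellSpec, FieldSpec, NoiseModel, render_field


@pytest.fixture(scope="session")
def single_cell_factory():
    """Render one cell on a small noiseless field; returns (image, cell)."""

    def make(pm_enrichment=2.0, outer_radius=16.0, eccentricity=0.0,
             orientation=0.0, nuclear_void=True, nuc_cyto_ratio=1.0,
             centroid=(64.0, 64.0), shape=(128, 128), noise=None,
             background=100.0, seed=1):
        cell = CellSpec(centroid=centroid, outer_radius=outer_radius,
                        nuclear_radius=0.42 * outer_radius,
                        eccentricity=eccentricity, orientation=orientation,
                        pm_enrichment=pm_enrichment,
                        nuc_cyto_ratio=nuc_cyto_ratio,
                        nuclear_void=nuclear_void)
        spec = FieldSpec(image_shape=shape, n_cells=1,
                         noise=noise or NoiseModel.none(),
                         background=background, seed=seed)
        img, gt = render_field(spec, [cell])
        return img, cell

    return make


def polar_oracle_ratio(channel: np.ndarray, cell: CellSpec,
                       params: RayScanParams | None = None,
                       n_angles: int = 720, fine_step: float = 0.1,
                       subtract_bg: bool = True) -> float:
    """Brute-force PM/cytoplasm ratio from dense polar resampling.

    Uses the analytic band centerline as the crossing (the elliptic
    radius is linear along a ray, so the crossing distance is exact),
    a dense max over the +/-w_pm membrane window, and a dense mean over
    the cytoplasm window with the (2 px padded) nucleus excluded.
    """
    params = params or RayScanParams()
    if subtract_bg:
        channel = subtract_background(channel)
    a, b = cell.semi_axes
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    dr, dc = np.sin(theta), np.cos(theta)
    co, si = np.cos(cell.orientation), np.sin(cell.orientation)
    u = dc * co + dr * si
    v = -dc * si + dr * co
    rho_unit = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # rho per px along ray
    rho_cross = 1.0 - (cell.pm_band_width / 2.0) / cell.outer_radius
    s_cross = rho_cross / rho_unit

    ratios = []
    for k in range(n_angles):
        s_hi = np.arange(s_cross[k] - params.w_pm,
                         s_cross[k] + params.w_pm + 1e-9, fine_step)
        s_lo = np.arange(s_cross[k] - params.gap - params.w_cyto,
                         s_cross[k] - params.gap + 1e-9, fine_step)
        s_lo = s_lo[s_lo > cell.nuclear_radius + 2.0]
        if len(s_lo) == 0:
            continue
        rows_hi = cell.centroid[0] + dr[k] * s_hi
        cols_hi = cell.centroid[1] + dc[k] * s_hi
        rows_lo = cell.centroid[0] + dr[k] * s_lo
        cols_lo = cell.centroid[1] + dc[k] * s_lo
        i_pm = ndi.map_coordinates(channel, np.stack([rows_hi, cols_hi]),
                                   order=1, mode="nearest").max()
        i_cy = ndi.map_coordinates(channel, np.stack([rows_lo, cols_lo]),
                                   order=1, mode="nearest").mean()
        if i_cy > 0:
            ratios.append(i_pm / i_cy)
    return float(np.mean(ratios))


def match_records_to_truth(records, gt, max_dist: float = 3.0):
    """Pair measured cell records with ground-truth cells by centroid.

    Returns (record, cell) pairs for records whose centroid lies within
    ``max_dist`` px of a unique ground-truth centroid.
    """
    tree = cKDTree(gt.centroids)
    pairs = []
    for rec in records:
        d, i = tree.query(rec.centroid)
        if d <= max_dist:
            pairs.append((rec, gt.cells[int(i)]))
    return pairs
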