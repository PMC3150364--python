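"""Radial-scan measurement properties: identity, invariances, oracle
agreement, nuclear/cytoplasmic conventions, QC."""

import numpy as np
import pytest

from conftest import match_records_to_truth, polar_oracle_ratio
from pmscan.core import FieldImage
from pmscan.pipeline import segmentation_from_truth
from pmscan.quantify import (
    CellRecord,
    QCCriteria,
    RayReason,
    RayScanParams,
    RaySet,
    aggregate_cells,
    bulk_nuc_cyto_intensity,
    nuc_cyto_ratio,
    qc_filter,
    radial_scan,
)
from pmscan.segment import segment
from pmscan.synth import CellSpec, FieldSpec, NoiseModel, render_field


@pytest.fixture(scope="module")
def noiseless_cell_scan(single_cell_factory):
    img, cell = single_cell_factory(pm_enrichment=2.0)
    seg = segment(img)
    records = radial_scan(img, seg)
    return img, cell, seg, records


def test_uniform_reporter_gives_unit_ratio(single_cell_factory):
    """A constant reporter channel yields ray ratios of exactly 1."""
    img, cell = single_cell_factory()
    flat = img.with_channels({"reporter": np.full(img.shape, 500.0)})
    seg = segment(flat)
    params = RayScanParams(subtract_bg=False)
    rec = radial_scan(flat, seg, params=params)[0]
    ratios = rec.rays.valid_ratios
    assert np.allclose(ratios, 1.0, atol=0.01)
    assert rec.pm_cyto_ratio == pytest.approx(1.0, abs=0.005)


def test_noiseless_enrichment_recovered_and_oracle_agrees(noiseless_cell_scan):
    img, cell, seg, records = noiseless_cell_scan
    rec = records[0]
    assert rec.pm_cyto_ratio == pytest.approx(2.0, abs=0.05)
    oracle = polar_oracle_ratio(img.channels["reporter"], cell)
    assert abs(rec.pm_cyto_ratio - oracle) <= 0.02


def test_exactly_360_ray_measurements_at_defaults(noiseless_cell_scan):
    _, _, _, records = noiseless_cell_scan
    assert records[0].n_rays == 360
    assert len(records[0].rays.ratio) == 360
    assert set(records[0].rays.angles_deg) == set(float(a) for a in range(360))


def test_border_cell_rays_invalid_and_fails_qc():
    """Rays leaving the image find no crossing; a cut cell fails QC."""
    cell = CellSpec(centroid=(64.0, 4.0), outer_radius=14, nuclear_radius=5)
    spec = FieldSpec(image_shape=(128, 128), n_cells=1,
                     placement="allow-border", noise=NoiseModel.none(), seed=0)
    img, gt = render_field(spec, [cell])
    seg = segmentation_from_truth(gt, img.shape)
    rec = radial_scan(img, seg)[0]
    assert (rec.rays.reason == RayReason.NO_CROSSING).sum() > 0
    if rec.n_valid / rec.n_rays < 0.5:
        assert not rec.qc_pass


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def _fake_record(cell_id, ratios, n_invalid=0, border=False, area=500.0):
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios) + n_invalid
    full = np.concatenate([ratios, np.full(n_invalid, np.nan)])
    reason = np.concatenate([
        np.zeros(len(ratios), dtype=np.int8),
        np.full(n_invalid, int(RayReason.NO_CROSSING), dtype=np.int8)])
    rays = RaySet(angles_deg=np.arange(n, dtype=float),
                  crossing=np.full((n, 2), np.nan),
                  i_pm=np.abs(full), i_cyto=np.ones(n), ratio=full,
                  reason=reason)
    return CellRecord(cell_id=cell_id, centroid=(0.0, 0.0), rays=rays,
                      pm_cyto_ratio=float(np.nanmean(full)),
                      n_valid=len(ratios), area=area, border=border,
                      qc_pass=True)


def test_field_mean_and_sem_hand_values():
    recs = [_fake_record(i, [r]) for i, r in enumerate([1.0, 1.0, 1.0])]
    s = aggregate_cells(recs)
    assert (s.mean_ratio, s.sem_ratio) == (1.0, 0.0)
    recs = [_fake_record(0, [1.0]), _fake_record(1, [1.2])]
    s = aggregate_cells(recs)
    assert s.mean_ratio == pytest.approx(1.1)
    assert s.sem_ratio == pytest.approx(0.1)
    assert s.n_cells_pass == 2


def test_median_policy_differs_on_skewed_rays():
    recs = [_fake_record(0, [1.0, 1.0, 4.0])]
    assert aggregate_cells(recs, policy="mean").mean_ratio == pytest.approx(2.0)
    assert aggregate_cells(recs, policy="median").mean_ratio == pytest.approx(1.0)
    with pytest.raises(ValueError):
        aggregate_cells(recs, policy="mode")


def test_empty_summary_flagged():
    s = aggregate_cells([])
    assert s.empty and s.n_cells_pass == 0


# --------------------------------------------------------------------------
# QC filter
# --------------------------------------------------------------------------

def test_qc_filter_reason_codes():
    all_good = [_fake_record(0, [1.1] * 300)]
    kept, dropped = qc_filter(all_good)
    assert len(kept) == 1 and not dropped

    bad_rays = _fake_record(1, [1.1] * 160, n_invalid=200)
    border = _fake_record(2, [1.1] * 300, border=True)
    tiny = _fake_record(3, [1.1] * 300, area=10.0)
    crazy = _fake_record(4, [50.0] * 300)
    kept, dropped = qc_filter([all_good[0], bad_rays, border, tiny, crazy])
    reasons = {rec.cell_id: why for rec, why in dropped}
    assert len(kept) == 1
    assert reasons == {1: "ray-validity", 2: "border", 3: "area",
                       4: "ratio-bounds"}


def test_border_cells_dropped_against_truth_placement():
    """In a field with border-crossing cells, exactly those are dropped."""
    interior = [(60.0, 60.0), (60.0, 128.0), (60.0, 196.0),
                (128.0, 60.0), (128.0, 128.0), (128.0, 196.0),
                (196.0, 96.0), (196.0, 170.0)]
    border_pos = [(100.0, 3.0), (180.0, 253.0), (3.0, 150.0), (253.0, 90.0)]
    cells = [CellSpec(centroid=c, outer_radius=13.0, nuclear_radius=5.0)
             for c in interior + border_pos]
    spec = FieldSpec(image_shape=(256, 256), n_cells=12,
                     placement="allow-border", noise=NoiseModel.none(), seed=0)
    img, gt = render_field(spec, cells)
    seg = segment(img, strategy="nuclear-marker")
    records = radial_scan(img, seg)
    kept, dropped = qc_filter(records)
    from scipy.spatial import cKDTree
    tree = cKDTree([c.centroid for c in cells])
    kept_truth = {int(tree.query(r.centroid)[1]) for r in kept}
    assert kept_truth == set(range(8))


# --------------------------------------------------------------------------
# invariances
# --------------------------------------------------------------------------

def test_gain_invariance_of_ray_ratios(noiseless_cell_scan):
    img, cell, seg, records = noiseless_cell_scan
    for c in (2.0, 0.3, 17.0):
        gained = img.with_channels({"reporter": c * img.channels["reporter"]})
        rec = radial_scan(gained, seg)[0]
        np.testing.assert_allclose(rec.rays.valid_ratios,
                                   records[0].rays.valid_ratios,
                                   rtol=0, atol=1e-9)


def test_offset_invariance_after_background_subtraction(noiseless_cell_scan):
    img, cell, seg, records = noiseless_cell_scan
    shifted = img.with_channels({"reporter": img.channels["reporter"] + 250.0})
    rec = radial_scan(shifted, seg)[0]
    assert abs(rec.pm_cyto_ratio - records[0].pm_cyto_ratio) < 0.01


def test_rotation_invariance_of_cell_ratio():
    spec = FieldSpec(image_shape=(384, 384), n_cells=12, seed=13)
    img, gt = render_field(spec)
    seg = segment(img)
    recs = radial_scan(img, seg)
    rot = FieldImage(channels={r: np.rot90(a).copy()
                               for r, a in img.channels.items()})
    seg_r = segment(rot)
    recs_r = radial_scan(rot, seg_r)
    n = img.shape[1]
    by_pos = {(round(r.centroid[0]), round(r.centroid[1])): r for r in recs}
    matched = 0
    for r in recs_r:
        orig = (round(r.centroid[1]), round(n - 1 - r.centroid[0]))
        cand = [by_pos.get((orig[0] + dr, orig[1] + dc))
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        cand = [c for c in cand if c is not None]
        if cand:
            assert abs(r.pm_cyto_ratio - cand[0].pm_cyto_ratio) <= 0.02
            matched += 1
    assert matched >= 10


def test_measured_ratio_monotone_in_true_enrichment(single_cell_factory):
    measured = []
    for enr in (0.5, 1.0, 1.5, 2.0, 3.0):
        img, cell = single_cell_factory(pm_enrichment=enr)
        rec = radial_scan(img, segment(img))[0]
        measured.append(rec.pm_cyto_ratio)
    assert np.all(np.diff(measured) > 0)


def test_oracle_agreement_on_random_noiseless_cells(single_cell_factory):
    """>=20 random cells: |radial scan - dense polar oracle| <= 0.02."""
    rng = np.random.default_rng(77)
    diffs = []
    for _ in range(22):
        img, cell = single_cell_factory(
            pm_enrichment=float(rng.uniform(0.8, 2.5)),
            outer_radius=float(rng.uniform(12, 19)),
            eccentricity=float(rng.uniform(0, 0.2)),
            orientation=float(rng.uniform(0, np.pi)),
            centroid=(float(rng.uniform(58, 70)), float(rng.uniform(58, 70))),
            seed=int(rng.integers(2 ** 31)))
        rec = radial_scan(img, segment(img))[0]
        oracle = polar_oracle_ratio(img.channels["reporter"], cell)
        diffs.append(abs(rec.pm_cyto_ratio - oracle))
    assert max(diffs) <= 0.02


# --------------------------------------------------------------------------
# nuclear / cytoplasmic readouts
# --------------------------------------------------------------------------

def _nc_field(ratios, radii=None, noiseless=True):
    radii = radii or [16.0] * len(ratios)
    cells = []
    for i, (nc, r) in enumerate(zip(ratios, radii)):
        cells.append(CellSpec(centroid=(60.0 + 110.0 * (i // 3),
                                        60.0 + 110.0 * (i % 3)),
                              outer_radius=r, nuclear_radius=0.42 * r,
                              nuc_cyto_ratio=nc, nuclear_void=False))
    n = int(np.ceil(len(ratios) / 3))
    shape = (max(340, 110 * n + 60), 340)
    spec = FieldSpec(image_shape=shape, n_cells=len(cells),
                     noise=NoiseModel.none() if noiseless else NoiseModel(),
                     seed=0)
    img, gt = render_field(spec, cells)
    return img, gt, cells


def test_uniform_reporter_nuclear_ratio_unity():
    img, gt, cells = _nc_field([1.0])
    seg = segment(img)
    res = nuc_cyto_ratio(img, seg)
    assert res.per_cell[0] == pytest.approx(1.0, abs=0.02)


def test_true_nuclear_ratio_recovered():
    img, gt, cells = _nc_field([2.0])
    seg = segment(img)
    res = nuc_cyto_ratio(img, seg)
    assert res.per_cell[0] == pytest.approx(2.0, abs=0.05)


def test_per_cell_first_averaging_convention():
    """Half the cells at ratio 1, half at 3: field mean is 2 per-cell-first."""
    img, gt, cells = _nc_field([1.0, 3.0, 1.0, 3.0, 1.0, 3.0])
    seg = segment(img)
    res = nuc_cyto_ratio(img, seg)
    assert res.field_mean == pytest.approx(2.0, abs=0.05)


def test_bulk_readout_uniform_image_and_ratio():
    img, gt, cells = _nc_field([2.0, 2.0])
    seg = segment(img)
    nuc, cyto = bulk_nuc_cyto_intensity(img, seg)
    assert nuc / cyto == pytest.approx(2.0, abs=0.05)


def test_pooled_vs_per_cell_convention_differ_on_unequal_areas():
    """A big ratio-1 cell and a small ratio-3 cell: the pooled-pixel ratio
    is pulled toward the big cell, the per-cell mean is not."""
    img, gt, cells = _nc_field([1.0, 3.0], radii=[19.0, 12.0])
    seg = segment(img)
    per_cell = nuc_cyto_ratio(img, seg).field_mean
    nuc, cyto = bulk_nuc_cyto_intensity(img, seg)
    pooled = nuc / cyto
    assert per_cell == pytest.approx(2.0, abs=0.05)
    assert pooled < per_cell - 0.1


def test_nuc_cyto_requires_nuclear_mask(single_cell_factory):
    img, _ = single_cell_factory()
    seg = segment(img, build_nuclei=False)
    with pytest.raises(ValueError, match="nuclear"):
        nuc_cyto_ratio(img, seg)
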