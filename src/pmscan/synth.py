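"""Synthetic confocal-section generator with exact ground truth.

Renders multi-channel 2D fields that emulate equatorial confocal
cross-sections of adherent cells: a bright plasma-membrane (PM) ring,
a cytoplasmic pool, and a dark or labeled nucleus.  Every rendered cell
carries its true PM enrichment (PM-band intensity divided by cytoplasmic
intensity in the translocation-reporter channel) and its true
nuclear/cytoplasmic ratio, so every downstream measurement stage can be
validated against known truth without microscope data.

Dose series and time-lapse series drive the per-dose / per-frame true
enrichment through closed-form response curves (four-parameter logistic,
delayed single exponential), which makes parameter-recovery tests exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    KNOWN_ROLES,
    ROLE_MEMBRANE,
    ROLE_NUCLEAR,
    ROLE_REPORTER,
    FieldImage,
)


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement cannot be satisfied."""


# --------------------------------------------------------------------------
# closed-form response curves (forward direction; the fitting module keeps
# its own, independently written, model functions)
# --------------------------------------------------------------------------

def logistic_response(dose: float | np.ndarray, bottom: float, top: float,
                      ec50: float, hill: float) -> float | np.ndarray:
    """Inhibitor-style four-parameter logistic on linear dose.

    Returns ``top`` at zero dose and decays to ``bottom`` at saturating
    dose, with midpoint at ``ec50`` (response = (top+bottom)/2) and
    steepness ``hill``.
    """
    dose = np.asarray(dose, dtype=float)
    out = bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)
    return float(out) if out.ndim == 0 else out


def delayed_exponential(t: float | np.ndarray, y0: float, amplitude: float,
                        rate: float, t_lag: float) -> float | np.ndarray:
    """Single exponential with an onset delay.

    ``y(t) = y0`` for ``t < t_lag`` and
    ``y0 + A (1 - exp(-k (t - t_lag)))`` after onset.
    """
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t_lag, 0.0, None)
    out = y0 + amplitude * -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Camera noise: signal-dependent shot component plus read noise.

    ``shot_coeff`` sets the variance of the shot term to
    ``shot_coeff * intensity`` (AU^2 per AU), i.e. an effective photon
    gain; ``read_sd`` is the SD of the additive zero-mean read component
    in AU.  Defaults correspond to roughly 1% shot and 2% read noise at
    the default cytoplasmic amplitude of 1000 AU.
    """

    shot_coeff: float = 0.1
    read_sd: float = 20.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(shot_coeff=0.0, read_sd=0.0)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.shot_coeff == 0.0 and self.read_sd == 0.0:
            return clean
        noisy = clean + rng.standard_normal(clean.shape) * np.sqrt(
            self.shot_coeff * np.clip(clean, 0.0, None)
        )
        if self.read_sd > 0:
            noisy = noisy + rng.normal(0.0, self.read_sd, clean.shape)
        return np.clip(noisy, 0.0, None)


DEFAULT_AMPLITUDES = {
    ROLE_MEMBRANE: 1500.0,
    ROLE_REPORTER: 1000.0,
    ROLE_NUCLEAR: 800.0,
}


@dataclass
class CellSpec:
    """Geometry and photometry of one synthetic cell.

    The cell is an ellipse (mild eccentricity) whose outermost
    ``pm_band_width`` pixels form the PM band.  ``pm_enrichment`` is the
    true PM-band / cytoplasm intensity ratio in the translocation-reporter
    channel; ``nuc_cyto_ratio`` the true nuclear / cytoplasmic ratio for
    nucleocytoplasmic reporters.  ``nuclear_void`` excludes the reporter
    from the nucleus entirely (the usual case for PM-translocation
    reporters, and what makes nuclear-hole centroid detection possible).
    """

    centroid: tuple[float, float]
    outer_radius: float
    nuclear_radius: float
    pm_band_width: float = 3.0
    eccentricity: float = 0.0
    orientation: float = 0.0
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    pm_enrichment: float = 1.0
    nuc_cyto_ratio: float = 1.0
    nuclear_void: bool = True

    def validate(self) -> None:
        if not self.outer_radius > self.nuclear_radius + self.pm_band_width:
            raise ValueError(
                "outer_radius must exceed nuclear_radius + pm_band_width "
                f"({self.outer_radius} vs {self.nuclear_radius} + {self.pm_band_width})"
            )
        if self.pm_enrichment <= 0:
            raise ValueError("pm_enrichment must be > 0")
        if any(a < 0 for a in self.channel_amplitudes.values()):
            raise ValueError("channel amplitudes must be >= 0")
        if not 0 <= self.eccentricity <= 0.3:
            raise ValueError("eccentricity outside [0, 0.3]")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes; geometric mean equals outer_radius."""
        s = 1.0 + self.eccentricity / 2.0
        return self.outer_radius * s, self.outer_radius / s


@dataclass
class CellPopulation:
    """Sampling distributions for auto-generated cells.

    Radii in pixels; the defaults emulate adherent cells of ~16 px
    equatorial radius with a nucleus at ~40% of the cell radius and a
    3 px PM band.  ``pm_enrichment`` and ``nuc_cyto_ratio`` are drawn
    per cell from normal laws, truncated at a small positive floor.
    """

    radius_mean: float = 16.0
    radius_sd: float = 1.5
    radius_range: tuple[float, float] = (12.0, 20.0)
    nuclear_fraction: float = 0.42
    pm_band_width: float = 3.0
    eccentricity_max: float = 0.2
    amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    pm_enrichment_mean: float = 1.0
    pm_enrichment_sd: float = 0.0
    nuc_cyto_mean: float = 1.0
    nuc_cyto_sd: float = 0.0
    nuclear_void: bool = True

    def sample(self, centroid: tuple[float, float],
               rng: np.random.Generator) -> CellSpec:
        r = float(np.clip(rng.normal(self.radius_mean, self.radius_sd),
                          *self.radius_range))
        enr = max(0.05, float(rng.normal(self.pm_enrichment_mean,
                                         self.pm_enrichment_sd)))
        ncr = max(0.0, float(rng.normal(self.nuc_cyto_mean, self.nuc_cyto_sd)))
        return CellSpec(
            centroid=centroid,
            outer_radius=r,
            nuclear_radius=self.nuclear_fraction * r,
            pm_band_width=self.pm_band_width,
            eccentricity=float(rng.uniform(0.0, self.eccentricity_max)),
            orientation=float(rng.uniform(0.0, np.pi)),
            channel_amplitudes=dict(self.amplitudes),
            pm_enrichment=enr,
            nuc_cyto_ratio=ncr,
            nuclear_void=self.nuclear_void,
        )


@dataclass
class FieldSpec:
    """One synthetic field: geometry, channels, noise, seed."""

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 20
    placement: str = "non-overlapping"  # or "allow-border"
    channel_roles: tuple[str, ...] = (ROLE_MEMBRANE, ROLE_REPORTER, ROLE_NUCLEAR)
    noise: NoiseModel = field(default_factory=NoiseModel)
    background: float = 100.0
    seed: int = 0
    edge_sigma: float = 0.5  # px, soft optical edge
    population: CellPopulation = field(default_factory=CellPopulation)

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.placement not in ("non-overlapping", "allow-border"):
            raise ValueError(f"unknown placement {self.placement!r}")
        unknown = set(self.channel_roles) - set(KNOWN_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles {sorted(unknown)}")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-cell and field-level truth for one rendered field."""

    cells: list[CellSpec]
    seed: int
    preset: str | None = None
    #: closed-form target driving the field (dose/time series), if any
    target_pm_enrichment: float | None = None
    condition: dict = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells], dtype=float)

    @property
    def pm_enrichments(self) -> np.ndarray:
        return np.array([c.pm_enrichment for c in self.cells], dtype=float)

    @property
    def nuc_cyto_ratios(self) -> np.ndarray:
        return np.array([c.nuc_cyto_ratio for c in self.cells], dtype=float)

    def summary(self) -> dict:
        enr = self.pm_enrichments
        ncr = self.nuc_cyto_ratios
        return {
            "n_cells": len(self.cells),
            "mean_pm_enrichment": float(enr.mean()) if len(enr) else float("nan"),
            "sd_pm_enrichment": float(enr.std(ddof=1)) if len(enr) > 1 else 0.0,
            "mean_nuc_cyto_ratio": float(ncr.mean()) if len(ncr) else float("nan"),
        }

    # ---- lossless JSON round-trip -------------------------------------
    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "preset": self.preset,
            "target_pm_enrichment": self.target_pm_enrichment,
            "condition": self.condition,
            "summary": self.summary(),
            "cells": [asdict(c) for c in self.cells],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        cells = []
        for c in payload["cells"]:
            c = dict(c)
            c["centroid"] = tuple(c["centroid"])
            cells.append(CellSpec(**c))
        return cls(
            cells=cells,
            seed=payload["seed"],
            preset=payload.get("preset"),
            target_pm_enrichment=payload.get("target_pm_enrichment"),
            condition=payload.get("condition", {}),
        )


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _elliptic_rho(cell: CellSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Normalized elliptic radius: rho = 1 on the cell's outer boundary."""
    a, b = cell.semi_axes
    dr = rows - cell.centroid[0]
    dc = cols - cell.centroid[1]
    co, si = np.cos(cell.orientation), np.sin(cell.orientation)
    u = dc * co + dr * si
    v = -dc * si + dr * co
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _cell_patch(cell: CellSpec, shape: tuple[int, int]):
    """Slices and coordinate grids of the cell's bounding box inside shape."""
    a, _ = cell.semi_axes
    pad = int(np.ceil(a + 3))
    r0 = max(0, int(np.floor(cell.centroid[0])) - pad)
    r1 = min(shape[0], int(np.ceil(cell.centroid[0])) + pad + 1)
    c0 = max(0, int(np.floor(cell.centroid[1])) - pad)
    c1 = min(shape[1], int(np.ceil(cell.centroid[1])) + pad + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1].astype(float)
    return (slice(r0, r1), slice(c0, c1)), rows, cols


def analytic_masks(cell: CellSpec, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Exact boolean masks of the cell's compartments on the full grid.

    Returns ``interior`` (whole cell), ``band`` (PM annulus), ``band_center``
    (±0.5 px around the annulus centerline), ``nucleus`` and ``cytoplasm``
    (interior minus band minus nucleus).  Used by measurement oracles and
    by the segmentation-bypass pipeline mode.
    """
    sl, rows, cols = _cell_patch(cell, shape)
    rho = _elliptic_rho(cell, rows, cols)
    r_geo = cell.outer_radius
    depth = (1.0 - rho) * r_geo  # ~px inward from the outer boundary
    interior_p = rho <= 1.0
    band_p = interior_p & (depth <= cell.pm_band_width)
    center_p = np.abs(depth - cell.pm_band_width / 2.0) <= 0.5
    nuc_p = ((rows - cell.centroid[0]) ** 2 + (cols - cell.centroid[1]) ** 2
             <= cell.nuclear_radius ** 2)
    out = {}
    for name, patch in [
        ("interior", interior_p),
        ("band", band_p),
        ("band_center", center_p & interior_p),
        ("nucleus", nuc_p & interior_p),
        ("cytoplasm", interior_p & ~band_p & ~(nuc_p & interior_p)),
    ]:
        full = np.zeros(shape, dtype=bool)
        full[sl] = patch
        out[name] = full
    return out


def measure_true_enrichment(channel: np.ndarray, cell: CellSpec,
                            background: float = 0.0) -> float:
    """Exact-mask PM enrichment: band-centerline mean over deep-cytoplasm mean.

    The cytoplasm mean keeps a margin from both the PM band and the
    nucleus so the soft optical edge does not contaminate it; the margin
    (up to 2 px) adapts to the cytoplasmic shell thickness of small cells.
    """
    shape = channel.shape
    sl, rows, cols = _cell_patch(cell, shape)
    rho = _elliptic_rho(cell, rows, cols)
    depth = (1.0 - rho) * cell.outer_radius
    ring = (np.abs(depth - cell.pm_band_width / 2.0) <= 0.5) & (rho <= 1.0)
    nuc_d2 = (rows - cell.centroid[0]) ** 2 + (cols - cell.centroid[1]) ** 2
    shell = cell.outer_radius - cell.nuclear_radius - cell.pm_band_width
    margin = float(np.clip(shell / 2.0 - 0.1, 0.5, 2.0))
    cyto = ((depth >= cell.pm_band_width + margin)
            & (nuc_d2 >= (cell.nuclear_radius + margin) ** 2))
    patch = channel[sl] - background
    return float(patch[ring].mean() / patch[cyto].mean())


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _place_cells(spec: FieldSpec, rng: np.random.Generator) -> list[CellSpec]:
    cells: list[CellSpec] = []
    max_tries = max(1000, 300 * spec.n_cells)
    tries = 0
    h, w = spec.image_shape
    while len(cells) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(cells)}/{spec.n_cells} cells after "
                f"{max_tries} attempts; field too crowded for "
                f"{spec.placement!r} placement"
            )
        tries += 1
        # sample geometry first so the border margin is known
        probe = spec.population.sample((0.0, 0.0), rng)
        a, _ = probe.semi_axes
        if spec.placement == "non-overlapping":
            m = a + 2.0
            if 2 * m >= min(h, w):
                raise PlacementError("image too small for a single cell")
            cen = (float(rng.uniform(m, h - m)), float(rng.uniform(m, w - m)))
            ok = all(
                np.hypot(cen[0] - c.centroid[0], cen[1] - c.centroid[1])
                > a + c.semi_axes[0] + 2.0
                for c in cells
            )
            if not ok:
                continue
        else:  # allow-border
            cen = (float(rng.uniform(0, h)), float(rng.uniform(0, w)))
        cell = replace(probe, centroid=cen)
        cell.validate()
        cells.append(cell)
    return cells


def _render_clean(spec: FieldSpec, cells: Sequence[CellSpec]) -> dict[str, np.ndarray]:
    imgs = {role: np.zeros(spec.image_shape) for role in spec.channel_roles}
    for cell in cells:
        sl, rows, cols = _cell_patch(cell, spec.image_shape)
        if rows.size == 0:
            continue
        rho = _elliptic_rho(cell, rows, cols)
        depth = (1.0 - rho) * cell.outer_radius
        interior = rho <= 1.0
        band = interior & (depth <= cell.pm_band_width)
        nuc = (((rows - cell.centroid[0]) ** 2 + (cols - cell.centroid[1]) ** 2)
               <= cell.nuclear_radius ** 2) & interior
        cyto = interior & ~band & ~nuc
        amp = cell.channel_amplitudes
        for role in spec.channel_roles:
            if role == ROLE_MEMBRANE:
                patch = band * amp.get(role, 0.0)
            elif role == ROLE_NUCLEAR:
                patch = nuc * amp.get(role, 0.0)
            else:  # translocation reporter(s)
                a0 = amp.get(role, 0.0)
                nuc_amp = 0.0 if cell.nuclear_void else a0 * cell.nuc_cyto_ratio
                patch = (cyto * a0
                         + band * a0 * cell.pm_enrichment
                         + nuc * nuc_amp)
            np.maximum(imgs[role][sl], patch, out=imgs[role][sl])
    return imgs


def render_field(spec: FieldSpec,
                 cells: Sequence[CellSpec] | None = None,
                 *,
                 preset: str | None = None,
                 condition: dict | None = None,
                 target_pm_enrichment: float | None = None,
                 ) -> tuple[FieldImage, GroundTruth]:
    """Render one multi-channel field and its ground truth.

    When ``cells`` is None, per-cell parameters are drawn from
    ``spec.population`` using ``spec.seed``; otherwise the provided specs
    are rendered verbatim.  Rendering order: analytic compartment masks,
    soft Gaussian optical edge (``spec.edge_sigma``), background offset,
    then camera noise from ``spec.noise``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if cells is None:
        cells = _place_cells(spec, rng)
    else:
        cells = list(cells)
        for c in cells:
            c.validate()
    clean = _render_clean(spec, cells)
    channels = {}
    for role, img in clean.items():
        if spec.edge_sigma > 0:
            img = gaussian_filter(img, spec.edge_sigma)
        img = img + spec.background
        channels[role] = spec.noise.apply(img, rng)
    meta = {"seed": spec.seed, "background": spec.background}
    if preset:
        meta["preset"] = preset
    if condition:
        meta.update(condition)
    gt = GroundTruth(cells=cells, seed=spec.seed, preset=preset,
                     target_pm_enrichment=target_pm_enrichment,
                     condition=dict(condition or {}))
    return FieldImage(channels=channels, metadata=meta), gt


# --------------------------------------------------------------------------
# dose series
# --------------------------------------------------------------------------

@dataclass
class DoseSeriesSpec:
    """Serial-dilution dose series driving true enrichment through a 4PL.

    ``doses`` may be given explicitly (strictly decreasing, molar) or is
    derived from ``top_dose`` / ``dilution_factor`` / ``n_points``.  The
    response curve ``(bottom, top, ec50, hill)`` sets the closed-form
    target enrichment at each dose (``top`` at zero dose for an
    inhibitor); per-cell enrichments scatter around the target with SD
    ``cell_sd``.
    """

    n_points: int = 10
    top_dose: float = 1e-4          # molar
    dilution_factor: float = 2.52
    doses: tuple[float, ...] | None = None
    bottom: float = 1.05
    top: float = 1.45
    ec50: float = 5.1e-6            # molar
    hill: float = 1.0
    cell_sd: float = 0.05
    fields_per_dose: int = 1
    field: FieldSpec = None  # template; seed is re-derived per rendered field
    seed: int = 0

    def __post_init__(self):
        if self.field is None:
            self.field = FieldSpec()

    def dose_vector(self) -> np.ndarray:
        if self.doses is not None:
            d = np.asarray(self.doses, dtype=float)
        else:
            d = self.top_dose / self.dilution_factor ** np.arange(self.n_points)
        if np.any(np.diff(d) >= 0):
            raise ValueError("doses must be strictly decreasing")
        return d

    def validate(self) -> None:
        if self.bottom <= 0 or self.top <= 0:
            raise ValueError("bottom and top must be > 0")
        self.dose_vector()
        self.field.validate()


def render_dose_series(spec: DoseSeriesSpec
                       ) -> list[tuple[float, FieldImage, GroundTruth]]:
    """Render every (dose, field) of a dose series; one GroundTruth per field."""
    spec.validate()
    doses = spec.dose_vector()
    master = np.random.default_rng(spec.seed)
    out = []
    for dose in doses:
        target = float(logistic_response(dose, spec.bottom, spec.top,
                                         spec.ec50, spec.hill))
        for rep in range(spec.fields_per_dose):
            fseed = int(master.integers(2 ** 31))
            pop = replace(spec.field.population,
                          pm_enrichment_mean=target,
                          pm_enrichment_sd=spec.cell_sd)
            fspec = replace(spec.field, seed=fseed, population=pop)
            img, gt = render_field(
                fspec,
                condition={"dose_m": float(dose), "replicate": rep},
                target_pm_enrichment=target,
            )
            out.append((float(dose), img, gt))
    return out


# --------------------------------------------------------------------------
# time-lapse series
# --------------------------------------------------------------------------

@dataclass
class SecondEvent:
    """Sequential compound addition: at ``gap_min`` after the first addition
    the trajectory switches to an exponential approach toward ``target``."""

    gap_min: float
    target: float
    rate: float  # per minute


@dataclass
class KineticsSpec:
    """Time-lapse series driven by a delayed single exponential.

    Frames run from ``-n_baseline_frames * frame_interval`` (pre-addition
    baseline) to ``duration`` minutes.  True enrichment follows
    ``y0 + A (1 - exp(-k (t - t_lag)))`` after onset; an optional second
    event replaces the trajectory target ``gap_min`` minutes after the
    first addition.
    """

    frame_interval: float = 3.0     # minutes
    duration: float = 120.0         # minutes
    y0: float = 1.1
    amplitude: float = 0.4
    rate: float = 0.1               # per minute
    t_lag: float = 0.0              # minutes
    second_event: SecondEvent | None = None
    n_baseline_frames: int = 3
    cell_sd: float = 0.05
    field: FieldSpec = None
    seed: int = 0

    def __post_init__(self):
        if self.field is None:
            self.field = FieldSpec()

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.rate <= 0:
            raise ValueError("rate k must be > 0")
        if self.t_lag < 0:
            raise ValueError("t_lag must be >= 0")
        if self.duration <= self.t_lag:
            raise ValueError("duration must exceed t_lag")
        self.field.validate()

    def frame_times(self) -> np.ndarray:
        n_post = int(np.floor(self.duration / self.frame_interval)) + 1
        post = np.arange(n_post) * self.frame_interval
        pre = -np.arange(self.n_baseline_frames, 0, -1) * self.frame_interval
        return np.concatenate([pre, post])

    def target(self, t: float) -> float:
        """Closed-form true enrichment at time t (minutes after addition)."""
        if t < 0:
            return self.y0
        if self.second_event is not None and t >= self.second_event.gap_min:
            ev = self.second_event
            y_gap = delayed_exponential(ev.gap_min, self.y0, self.amplitude,
                                        self.rate, self.t_lag)
            return float(ev.target + (y_gap - ev.target)
                         * np.exp(-ev.rate * (t - ev.gap_min)))
        return float(delayed_exponential(t, self.y0, self.amplitude,
                                         self.rate, self.t_lag))


def render_time_series(spec: KineticsSpec
                       ) -> list[tuple[float, FieldImage, GroundTruth]]:
    """Render every frame of a time-lapse series (frame-independent fields).

    Each frame is rendered as an independent field whose population mean
    enrichment equals the closed-form trajectory target at that frame time;
    this emulates population-level (untracked) kinetic readouts.
    """
    spec.validate()
    master = np.random.default_rng(spec.seed)
    out = []
    for t in spec.frame_times():
        target = spec.target(float(t))
        fseed = int(master.integers(2 ** 31))
        pop = replace(spec.field.population,
                      pm_enrichment_mean=target,
                      pm_enrichment_sd=spec.cell_sd)
        fspec = replace(spec.field, seed=fseed, population=pop)
        img, gt = render_field(fspec,
                               condition={"time_min": float(t)},
                               target_pm_enrichment=target)
        out.append((float(t), img, gt))
    return out


# --------------------------------------------------------------------------
# fast population fixture (bypasses rendering)
# --------------------------------------------------------------------------

def sample_ratio_population(mu: float, sigma: float, n: int,
                            seed: int) -> np.ndarray:
    """Draw a per-cell ratio population from a normal law.

    Fast fixture for assay-quality statistics (e.g. Z-factor) that does
    not require rendering and measuring a field.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return rng.normal(mu, sigma, size=n)
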