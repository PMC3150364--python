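"""Named, versioned fixture presets for the synthetic generator.

Each preset captures the study conditions of one benchmark scenario:
single fields with a known mean PM enrichment, an inhibitor serial
dilution, stable/transient expression Z-factor populations, and the
kinetic trajectories of membrane recruitment/displacement.  Anchor
values (means, EC50, onset delays, gaps) define the scenarios; field
geometry and noise are generator choices shared across presets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .synth import (
    CellPopulation,
    DoseSeriesSpec,
    FieldSpec,
    KineticsSpec,
    SecondEvent,
)

PRESET_VERSION = "1"

#: default geometry of a full-scale endpoint field (~400 cells)
_ENDPOINT_SHAPE = (1448, 1448)
#: default geometry of a dose-series field (~200 cells)
_DOSE_SHAPE = (1024, 1024)
#: default geometry of a time-lapse frame (smaller fields, many frames)
_KINETIC_SHAPE = (600, 600)
_KINETIC_CELLS = 70


@dataclass(frozen=True)
class MomentPreset:
    """Normal-population moments for screening-window (Z-factor) fixtures."""

    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float


def _akt_field(mu: float, seed: int) -> FieldSpec:
    pop = CellPopulation(pm_enrichment_mean=mu, pm_enrichment_sd=0.05)
    return FieldSpec(image_shape=_ENDPOINT_SHAPE, n_cells=400,
                     population=pop, seed=seed)


def _kinetic_field() -> FieldSpec:
    return FieldSpec(image_shape=_KINETIC_SHAPE, n_cells=_KINETIC_CELLS)


_FIELD_PRESETS: dict[str, Callable[[int], FieldSpec]] = {
    # subtle serum-dependent PM targeting of an Akt reporter:
    # stimulated vs starved population means 1.11 / 1.08, between-cell SD 0.05
    "akt-serum": lambda seed: _akt_field(1.11, seed),
    "akt-starved": lambda seed: _akt_field(1.08, seed),
}

_DOSE_PRESETS: dict[str, Callable[[int], DoseSeriesSpec]] = {
    # 10-point serial dilution of a Ras/Raf disruptor from 100 uM
    # (2.52x steps -> lowest dose ~24 nM); 4PL bottom 1.05, top 1.45,
    # EC50 5.1 uM, unit Hill slope
    "mcp110": lambda seed: DoseSeriesSpec(
        n_points=10, top_dose=1e-4, dilution_factor=2.52,
        bottom=1.05, top=1.45, ec50=5.1e-6, hill=1.0,
        cell_sd=0.05, fields_per_dose=1, seed=seed,
        field=FieldSpec(image_shape=_DOSE_SHAPE, n_cells=200),
    ),
}

_KINETIC_PRESETS: dict[str, Callable[[int], KineticsSpec]] = {
    # immediate PM recruitment after Raf-inhibitor addition
    "kin-gdc": lambda seed: KineticsSpec(
        frame_interval=3.0, duration=60.0, y0=1.1, amplitude=0.4,
        rate=0.2, t_lag=0.0, seed=seed, field=_kinetic_field()),
    # Mek-inhibitor-induced recruitment with a 36 min onset delay
    "kin-meki": lambda seed: KineticsSpec(
        frame_interval=3.0, duration=120.0, y0=1.1, amplitude=0.4,
        rate=0.1, t_lag=36.0, seed=seed, field=_kinetic_field()),
    # RasGTP-sensor recruitment within 1.5 min of Mek inhibition
    "kin-rbd-meki": lambda seed: KineticsSpec(
        frame_interval=1.5, duration=45.0, y0=1.5, amplitude=0.4,
        rate=0.4, t_lag=1.0, seed=seed, field=_kinetic_field()),
    # sensor displacement beginning 7.5 min after Raf-inhibitor addition
    "kin-rbd-gdc": lambda seed: KineticsSpec(
        frame_interval=1.5, duration=60.0, y0=1.5, amplitude=-0.4,
        rate=0.15, t_lag=7.5, seed=seed, field=_kinetic_field()),
    # sequential addition: displacement, then full recovery when the second
    # compound is added 28.5 min after the first
    "kin-sequential": lambda seed: KineticsSpec(
        frame_interval=1.5, duration=75.0, y0=1.5, amplitude=-0.4,
        rate=0.15, t_lag=7.5,
        second_event=SecondEvent(gap_min=28.5, target=1.5, rate=0.3),
        seed=seed, field=_kinetic_field()),
}

_MOMENT_PRESETS: dict[str, MomentPreset] = {
    # stable, balanced expression: narrow per-cell ratio distributions
    "zfactor-stable": MomentPreset(mu_neg=1.00, sigma_neg=0.01167,
                                   mu_pos=1.50, sigma_pos=0.04),
    # transient transfection: broad distributions, marginal window
    "zfactor-transient": MomentPreset(mu_neg=1.00, sigma_neg=0.05167,
                                      mu_pos=1.50, sigma_pos=0.10),
}


def preset_names() -> list[str]:
    return sorted([*_FIELD_PRESETS, *_DOSE_PRESETS, *_KINETIC_PRESETS,
                   *_MOMENT_PRESETS])


def preset_kind(name: str) -> str:
    """One of 'field', 'dose', 'kinetics', 'moments'."""
    if name in _FIELD_PRESETS:
        return "field"
    if name in _DOSE_PRESETS:
        return "dose"
    if name in _KINETIC_PRESETS:
        return "kinetics"
    if name in _MOMENT_PRESETS:
        return "moments"
    raise KeyError(
        f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
    )


def get_preset(name: str, seed: int = 0):
    """Instantiate a preset spec (or moment set) with the given seed."""
    kind = preset_kind(name)
    if kind == "field":
        return _FIELD_PRESETS[name](seed)
    if kind == "dose":
        return _DOSE_PRESETS[name](seed)
    if kind == "kinetics":
        return _KINETIC_PRESETS[name](seed)
    return _MOMENT_PRESETS[name]
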