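"""Dose-response, kinetics and assay-quality statistics.

Implements the downstream statistical layer of the translocation
platform: four-parameter logistic (variable-slope sigmoid) dose-response
fits on log10 dose, delayed single-exponential kinetics fits with a
profiled onset lag, the screening-window Z-factor, Welch two-sample
t-tests and the standard error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit: y = bottom + (top-bottom) /
    (1 + 10^((log10_ec50 - log10 x) * hill))."""

    bottom: float
    top: float
    log10_ec50: float
    hill: float
    r_squared: float
    stderr: dict = field(default_factory=dict)
    n_points: int = 0
    converged: bool = True
    flat_curve: bool = False
    ec50_extrapolated: bool = False

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log10_ec50

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom, "top": self.top, "ec50": self.ec50,
            "log10_ec50": self.log10_ec50, "hill": self.hill,
            "r_squared": self.r_squared, "stderr": self.stderr,
            "n_points": self.n_points, "converged": self.converged,
            "flat_curve": self.flat_curve,
            "ec50_extrapolated": self.ec50_extrapolated,
        }


@dataclass
class KineticsFit:
    """Delayed single exponential: y = y0 + A (1 - exp(-k (t - t_lag)))
    for t >= t_lag, y0 before onset."""

    y0: float
    amplitude: float
    rate: float
    t_lag: float
    r_squared: float
    stderr: dict = field(default_factory=dict)
    n_points: int = 0
    converged: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _delayed_exp_model(np.asarray(t, float), self.y0,
                                  self.amplitude, self.rate, self.t_lag)

    def to_dict(self) -> dict:
        return {
            "y0": self.y0, "amplitude": self.amplitude, "rate": self.rate,
            "t_lag": self.t_lag, "r_squared": self.r_squared,
            "stderr": self.stderr, "n_points": self.n_points,
            "converged": self.converged,
        }


@dataclass
class AssayQuality:
    """Screening-window statistic for a positive/negative control pair.

    z = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|, from sample
    moments.  ``z_factor`` is None (undefined) when the means coincide.
    """

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_factor: float | None


# --------------------------------------------------------------------------
# sigmoid dose-response
# --------------------------------------------------------------------------

def _logistic4(logx: np.ndarray, bottom: float, top: float,
               log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logx) * hill))


def fit_sigmoid(doses, responses, weights=None) -> DoseResponseFit:
    """Least-squares variable-slope sigmoid fit on log10 dose.

    Requires >=5 distinct positive doses.  Multi-start initialization
    over Hill-slope sign and a grid of candidate midpoints; returns
    parameter standard errors from the Jacobian and
    ``r_squared = 1 - SS_res/SS_tot``.  Flat responses are flagged
    (non-converged, EC50 undefined) rather than fitted.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if len(np.unique(doses)) < 5:
        raise ValueError("sigmoid fit requires at least 5 distinct doses")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (molar)")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    w = np.ones_like(responses) if weights is None else np.asarray(weights, float)

    logx = np.log10(doses)
    ss_tot = float(((responses - responses.mean()) ** 2).sum())
    span = float(np.ptp(responses))
    if ss_tot < 1e-12 or span < 1e-9 * max(1.0, abs(responses.mean())):
        return DoseResponseFit(
            bottom=float(responses.mean()), top=float(responses.mean()),
            log10_ec50=float("nan"), hill=float("nan"), r_squared=0.0,
            n_points=len(doses), converged=False, flat_curve=True)

    lo, hi = float(responses.min()), float(responses.max())
    mid_grid = np.quantile(logx, [0.25, 0.5, 0.75])
    best = None
    for h0 in (1.0, -1.0, 2.0, -2.0):
        for m0 in mid_grid:
            p0 = (lo, hi, m0, h0)
            try:
                popt, pcov = optimize.curve_fit(
                    _logistic4, logx, responses, p0=p0, sigma=1.0 / w,
                    absolute_sigma=False, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = responses - _logistic4(logx, *popt)
            ssr = float((resid ** 2).sum())
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
    if best is None:
        return DoseResponseFit(bottom=lo, top=hi, log10_ec50=float("nan"),
                               hill=float("nan"), r_squared=0.0,
                               n_points=len(doses), converged=False)
    ssr, popt, pcov = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    names = ("bottom", "top", "log10_ec50", "hill")
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]),
        log10_ec50=float(popt[2]), hill=float(popt[3]),
        r_squared=1.0 - ssr / ss_tot,
        stderr={k: float(e) for k, e in zip(names, perr)},
        n_points=len(doses), converged=True,
        ec50_extrapolated=not (logx.min() <= popt[2] <= logx.max()))


# --------------------------------------------------------------------------
# delayed exponential kinetics
# --------------------------------------------------------------------------

def _delayed_exp_model(t: np.ndarray, y0: float, amplitude: float,
                       rate: float, t_lag: float) -> np.ndarray:
    dt = np.clip(t - t_lag, 0.0, None)
    return y0 + amplitude * (1.0 - np.exp(-rate * dt))


def _fit_fixed_lag(t, y, t_lag):
    y_pre = y[t <= t_lag]
    y0_0 = float(y_pre.mean()) if len(y_pre) else float(y[0])
    a0 = float(y[-1] - y0_0) or 1e-3
    span = max(float(t.max() - t_lag), 1e-6)
    k0 = 3.0 / span

    def model(tt, y0, a, k):
        return _delayed_exp_model(tt, y0, a, k, t_lag)

    popt, pcov = optimize.curve_fit(
        model, t, y, p0=(y0_0, a0, k0),
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000)
    ssr = float(((y - model(t, *popt)) ** 2).sum())
    return popt, pcov, ssr


def fit_exponential(times_min, responses, allow_delay: bool = True
                    ) -> KineticsFit:
    """Fit a (possibly delayed) single exponential to a trajectory.

    With ``allow_delay`` the onset lag is profiled over the observed
    frame grid and then refined continuously between the bracketing
    frames (the joint least-squares problem is non-smooth in ``t_lag``,
    so a grid-then-refine profile is used).  With ``allow_delay=False``
    the lag is fixed at 0.  Requires >=6 frames at strictly increasing
    times.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(responses, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and responses must have equal length")
    if len(t) < 6:
        raise ValueError("kinetics fit requires at least 6 frames")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    ss_tot = float(((y - y.mean()) ** 2).sum())

    def profile(lag):
        try:
            return _fit_fixed_lag(t, y, lag)[2]
        except RuntimeError:
            return np.inf

    if allow_delay:
        grid = np.unique(np.clip(t, 0.0, None))
        grid = grid[grid < t.max()]
        ssrs = np.array([profile(g) for g in grid])
        if not np.isfinite(ssrs).any():
            return KineticsFit(y0=float(y[0]), amplitude=0.0, rate=0.0,
                               t_lag=0.0, r_squared=0.0, n_points=len(t),
                               converged=False)
        j = int(np.argmin(ssrs))
        lo = grid[max(0, j - 1)]
        hi = grid[min(len(grid) - 1, j + 1)]
        if hi > lo:
            res = optimize.minimize_scalar(profile, bounds=(lo, hi),
                                           method="bounded",
                                           options={"xatol": 1e-3})
            t_lag = float(res.x) if res.fun <= ssrs[j] else float(grid[j])
        else:
            t_lag = float(grid[j])
    else:
        t_lag = 0.0

    try:
        popt, pcov, ssr = _fit_fixed_lag(t, y, t_lag)
    except RuntimeError:
        return KineticsFit(y0=float(y[0]), amplitude=0.0, rate=0.0,
                           t_lag=t_lag, r_squared=0.0, n_points=len(t),
                           converged=False)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    names = ("y0", "amplitude", "rate")
    return KineticsFit(
        y0=float(popt[0]), amplitude=float(popt[1]), rate=float(popt[2]),
        t_lag=t_lag,
        r_squared=1.0 - ssr / ss_tot if ss_tot > 0 else 0.0,
        stderr={k: float(e) for k, e in zip(names, perr)},
        n_points=len(t), converged=True)


# --------------------------------------------------------------------------
# assay quality and group comparison
# --------------------------------------------------------------------------

def z_factor(pos, neg) -> AssayQuality:
    """Plug-in screening-window statistic from sample moments.

    z = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|.  Always <= 1;
    undefined (None) when the group means coincide.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("z_factor requires >=2 values per group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        z = None
    else:
        z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return AssayQuality(mu_pos=mu_p, sigma_pos=sd_p, mu_neg=mu_n,
                        sigma_neg=sd_n, z_factor=z)


def compare_groups(a, b) -> tuple[float | None, float | None, float | None]:
    """Welch (unequal-variance) two-sided two-sample t-test.

    Returns ``(t, df, p)``; all three are None for the degenerate case
    where every pooled value is identical (p undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups requires >=2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return None, None, None
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("sem requires n >= 2")
    return float(values.std(ddof=1) / np.sqrt(len(values)))
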