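"""Biophysical measurement models and nonlinear least-squares fitters.

Four curve families cover the wet-lab readouts around a dimeric lectin:

* pulsed-field-gradient NMR diffusion decay
  ``I(g) = I(0) exp[-D (γ g δ)^2 (Δ - δ/3 - τ/2)]`` with δ the total
  bipolar-pair gradient duration, Δ the diffusion delay and τ the gradient
  stabilization delay;
* four-parameter logistic (4PL) dose-response with EC50, fitted on
  log10(concentration), compared across datasets with the extra
  sum-of-squares F-test;
* two-state thermal melting monitored by ellipticity, with the melting
  midpoint T_m located from the Savitzky-Golay-smoothed first derivative;
* monomer-dimer exchange titration: the signal tracks the fraction of a
  trace-labeled protomer residing in a dimer under mass-action equilibrium
  2M <-> D with K_D = [M]^2/[D] (equal homo-/heterodimer affinity), scaled
  between free and bound plateaus.

All fitters report parameter estimates, standard errors from the Jacobian,
and 95% confidence intervals (t-based; profile-likelihood/F-based for the
EC50, whose sampling distribution is strongly asymmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "GAMMA_H",
    "CurveSeries",
    "DecayExperiment",
    "FitResult",
    "decay_model",
    "logistic4",
    "melt_model",
    "exchange_model",
    "dimer_fraction",
    "fit_diffusion",
    "fit_ec50_4pl",
    "compare_curves_ftest",
    "ftest_from_rss",
    "melt_tm",
    "fit_dimer_kd",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8

GAUSS_PER_CM_TO_T_PER_M = 0.01


@dataclass
class CurveSeries:
    """A generic (x, y) measurement series with instrument metadata."""

    x: np.ndarray
    y: np.ndarray
    xlabel: str = "x"
    ylabel: str = "y"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")


@dataclass
class FitResult:
    params: dict[str, float]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_points: int
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("residual sum of squares cannot be negative")
        for name, (lo, hi) in self.ci95.items():
            est = self.params.get(name)
            if est is not None and not (lo <= est <= hi):
                raise ValueError(f"CI95 for {name} does not bracket the estimate")


@dataclass
class DecayExperiment:
    """Gradient-strength/intensity series with the pulse-sequence constants.

    ``g`` in T/m (use :meth:`from_gauss_per_cm` for G/cm input); ``delta``
    is the *total* bipolar-pair gradient duration (a stated half-duration
    δ/2 of 4.3 ms means delta = 8.6e-3 s).
    """

    g: np.ndarray            # T/m, strictly increasing
    I: np.ndarray            # arbitrary units, > 0
    delta: float             # s
    Delta: float             # s
    tau: float               # s
    gamma: float = GAMMA_H   # rad s^-1 T^-1

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, float)
        self.I = np.asarray(self.I, float)
        if self.g.shape != self.I.shape or self.g.ndim != 1:
            raise ValueError("g and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.g) <= 0):
            raise ValueError("gradient strengths must be strictly increasing")
        if np.any(self.I <= 0):
            raise ValueError("intensities must be positive")
        if min(self.delta, self.Delta, self.tau) <= 0:
            raise ValueError("delta, Delta and tau must be positive")
        if self.Delta <= self.delta / 3.0 + self.tau / 2.0:
            raise ValueError("diffusion delay too short: Delta must exceed delta/3 + tau/2")

    @classmethod
    def from_gauss_per_cm(cls, g_gauss_per_cm, I, **kwargs) -> "DecayExperiment":
        return cls(g=np.asarray(g_gauss_per_cm, float) * GAUSS_PER_CM_TO_T_PER_M, I=I, **kwargs)

    @property
    def b_values(self) -> np.ndarray:
        """(γ g δ)^2 (Δ - δ/3 - τ/2), s/m²; I = I0 exp(-D b)."""
        return (self.gamma * self.g * self.delta) ** 2 * (
            self.Delta - self.delta / 3.0 - self.tau / 2.0
        )


def decay_model(b: np.ndarray, i0: float, d: float) -> np.ndarray:
    return i0 * np.exp(-d * b)


def logistic4(conc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    """4PL response on concentration; EC50 = 10**log_ec50 in the same units."""
    logc = np.log10(conc)
    expo = np.clip(hill * (log_ec50 - logc), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def melt_model(T: np.ndarray, tm: float, width: float, folded: float, unfolded: float) -> np.ndarray:
    """Two-state melting sigmoid with flat baselines."""
    frac_u = 1.0 / (1.0 + np.exp((tm - T) / width))
    return folded + (unfolded - folded) * frac_u


def dimer_fraction(total: np.ndarray, kd: float) -> np.ndarray:
    """Fraction of protomer residing in dimers at total protomer conc ``total``.

    Mass action 2M <-> D with K_D = [M]^2/[D]:
    [M] = (-K_D + sqrt(K_D^2 + 8 K_D P)) / 4, fraction = 1 - [M]/P.
    """
    P = np.asarray(total, float)
    if kd == 0:
        return np.ones_like(P)
    m = (-kd + np.sqrt(kd * kd + 8.0 * kd * P)) / 4.0
    return 1.0 - m / P


def exchange_model(total: np.ndarray, kd: float, free: float, bound: float) -> np.ndarray:
    return free + (bound - free) * dimer_fraction(total, kd)


def _t_ci(est: float, se: float, dof: int) -> tuple[float, float]:
    t = stats.t.ppf(0.975, max(dof, 1))
    return (est - t * se, est + t * se)


def _curve_fit(f, x, y, p0, bounds=(-np.inf, np.inf), maxfev=20000):
    popt, pcov = optimize.curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=maxfev)
    resid = y - f(x, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return popt, se, rss


def fit_diffusion(exp: DecayExperiment) -> FitResult:
    """Two-parameter fit of the diffusion decay; D in m²/s.

    The initial D comes from the log-linear slope of I against b; the warn
    threshold flags series whose total attenuation is under 20%, where D is
    poorly determined.
    """
    if exp.g.size < 3:
        raise ValueError("need at least 3 gradient points")
    if exp.I[-1] / exp.I[0] > 0.8:
        warnings.warn("decay spans less than 20% attenuation; D will be poorly determined")
    b = exp.b_values
    slope, intercept = np.polyfit(b, np.log(exp.I), 1)
    p0 = (float(np.exp(intercept)), max(-slope, 0.0))
    popt, se, rss = _curve_fit(lambda bb, i0, d: decay_model(bb, i0, d), b, exp.I, p0)
    i0, d = popt
    if d < -1e-18:
        raise RuntimeError(f"fitted diffusion coefficient is negative ({d:.3e} m²/s)")
    dof = exp.g.size - 2
    return FitResult(
        params={"I0": float(i0), "D": float(d)},
        stderr={"I0": float(se[0]), "D": float(se[1])},
        ci95={"I0": _t_ci(i0, se[0], dof), "D": _t_ci(d, se[1], dof)},
        rss=rss,
        n_points=exp.g.size,
    )


def _fit_4pl_raw(conc, resp, p0=None):
    conc = np.asarray(conc, float)
    resp = np.asarray(resp, float)
    if p0 is None:
        lo, hi = float(resp.min()), float(resp.max())
        half = lo + 0.5 * (hi - lo)
        k = int(np.argmin(np.abs(resp - half)))
        p0 = (lo, hi, float(np.log10(conc[k])), 1.0)
    return _curve_fit(logistic4, conc, resp, p0)


def _profile_ci_ec50(conc, resp, popt, rss_min, alpha=0.05):
    """Profile-likelihood (F-based) CI for log EC50."""
    n, p = len(conc), 4
    dof = n - p
    if dof <= 0:
        return (-np.inf, np.inf)
    fcrit = stats.f.ppf(1 - alpha, 1, dof)
    rss_star = rss_min * (1.0 + fcrit / dof)

    def prof(le):  # RSS with log_ec50 fixed
        f = lambda c, bottom, top, hill: logistic4(c, bottom, top, le, hill)
        try:
            _popt, _se, rss = _curve_fit(f, conc, resp, (popt[0], popt[1], popt[3]))
            return rss
        except RuntimeError:
            return np.inf

    le_hat = popt[2]
    bounds = []
    for direction in (-1.0, +1.0):
        step = 0.05
        lo_le, hi_le = le_hat, le_hat
        for _ in range(60):
            cand = le_hat + direction * step
            if prof(cand) > rss_star:
                hi_le = cand
                break
            lo_le = cand
            step *= 1.6
        else:
            bounds.append(direction * np.inf)
            continue
        a, bnd = sorted((lo_le, hi_le))
        root = optimize.brentq(lambda le: prof(le) - rss_star, a, bnd, xtol=1e-6)
        bounds.append(root)
    return tuple(bounds)


def fit_ec50_4pl(conc: np.ndarray, response: np.ndarray) -> FitResult:
    """Four-parameter logistic fit on log-concentration.

    EC50's CI95 is profile-likelihood based; an EC50 outside the tested
    concentration range is flagged in ``extra['ec50_in_range']``.
    """
    conc = np.asarray(conc, float)
    response = np.asarray(response, float)
    if conc.size < 5:
        warnings.warn("fewer than 5 concentrations: EC50 may be poorly constrained")
    popt, se, rss = _fit_4pl_raw(conc, response)
    bottom, top, log_ec50, hill = popt
    ec50 = 10.0 ** log_ec50
    dof = conc.size - 4
    ci_le = _profile_ci_ec50(conc, response, popt, rss)
    # delta-method standard error on the linear scale
    se_ec50 = float(ec50 * np.log(10.0) * se[2])
    in_range = bool(conc.min() <= ec50 <= conc.max())
    if not in_range:
        warnings.warn(f"fitted EC50 {ec50:.3g} lies outside the tested range")
    return FitResult(
        params={"EC50": float(ec50), "hill": float(hill), "top": float(top), "bottom": float(bottom)},
        stderr={"EC50": se_ec50, "hill": float(se[3]), "top": float(se[1]), "bottom": float(se[0])},
        ci95={
            "EC50": (10.0 ** ci_le[0], 10.0 ** ci_le[1]),
            "hill": _t_ci(hill, se[3], dof),
            "top": _t_ci(top, se[1], dof),
            "bottom": _t_ci(bottom, se[0], dof),
        },
        rss=rss,
        n_points=conc.size,
        extra={"log_ec50": float(log_ec50), "ec50_in_range": in_range},
    )


def ftest_from_rss(rss_shared: float, df_shared: int, rss_separate: float, df_separate: int):
    """Extra sum-of-squares F-test between nested least-squares models."""
    if df_shared <= df_separate or df_separate <= 0:
        raise ValueError("models are not properly nested")
    if rss_shared < rss_separate - 1e-9 * max(rss_separate, 1.0):
        raise ValueError("shared-model RSS is smaller than separate-model RSS: not nested fits")
    num = (rss_shared - rss_separate) / (df_shared - df_separate)
    den = rss_separate / df_separate
    F = num / den if den > 0 else np.inf
    p = float(stats.f.sf(F, df_shared - df_separate, df_separate))
    return float(F), p


def compare_curves_ftest(datasets: list[tuple[np.ndarray, np.ndarray]], alpha: float = 0.05) -> dict:
    """Do several dose-response datasets share one 4PL curve?

    Fits each dataset separately and all data pooled under one curve, then
    applies the extra sum-of-squares F-test.  ``preferred`` is "separate"
    when the pooled fit is rejected at ``alpha``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to compare")
    rss_sep = 0.0
    n_tot = 0
    for conc, resp in datasets:
        _p, _s, rss = _fit_4pl_raw(conc, resp)
        rss_sep += rss
        n_tot += len(conc)
    df_sep = n_tot - 4 * len(datasets)
    all_c = np.concatenate([np.asarray(c, float) for c, _ in datasets])
    all_r = np.concatenate([np.asarray(r, float) for _, r in datasets])
    _p, _s, rss_shared = _fit_4pl_raw(all_c, all_r)
    df_shared = n_tot - 4
    F, p = ftest_from_rss(rss_shared, df_shared, rss_sep, df_sep)
    return {"F": F, "p": p, "preferred": "separate" if p <= alpha else "shared",
            "rss_shared": rss_shared, "rss_separate": rss_sep,
            "df_shared": df_shared, "df_separate": df_sep}


def melt_tm(T: np.ndarray, signal_y: np.ndarray, window: int = 11, polyorder: int = 3) -> FitResult:
    """Melting midpoint from the Savitzky-Golay first derivative.

    The ellipticity series is smoothed and differentiated with a
    Savitzky-Golay filter (11-point window, cubic, configurable); T_m is
    the interior extremum of |d signal / dT| refined by local quadratic
    interpolation, so the estimate is not quantized to the grid.
    """
    T = np.asarray(T, float)
    y = np.asarray(signal_y, float)
    if T.ndim != 1 or T.shape != y.shape:
        raise ValueError("T and signal must be 1-D arrays of equal length")
    order = np.argsort(T)
    T, y = T[order], y[order]
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly monotone")
    steps = np.diff(T)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("temperature grid must be uniform")
    if window >= T.size:
        raise ValueError("smoothing window exceeds series length")
    dy = signal.savgol_filter(y, window_length=window, polyorder=polyorder,
                              deriv=1, delta=steps[0])
    mag = np.abs(dy)
    k = int(np.argmax(mag[1:-1])) + 1
    # the interior extremum must stand out against the baselines
    prominence = mag[k] - max(mag[0], mag[-1])
    if prominence <= 1e-9 * max(1.0, mag[k]):
        raise ValueError("no interior derivative extremum: transition not in range")
    # quadratic through the three points around the extremum
    a = (mag[k - 1] - 2 * mag[k] + mag[k + 1]) / 2.0
    b = (mag[k + 1] - mag[k - 1]) / 2.0
    if a >= 0:
        raise ValueError("no interior derivative extremum: transition not in range")
    offset = -b / (2 * a)
    tm = T[k] + offset * steps[0]
    if not T[0] < tm < T[-1]:
        raise ValueError("no interior derivative extremum: transition not in range")
    # half the grid step is an honest resolution statement for this estimator
    half_step = steps[0] / 2.0
    return FitResult(
        params={"Tm": float(tm)},
        stderr={"Tm": float(half_step / 1.96)},
        ci95={"Tm": (float(tm - half_step), float(tm + half_step))},
        rss=0.0,
        n_points=T.size,
        extra={"derivative": dy, "grid_step": float(steps[0])},
    )


def fit_dimer_kd(total_conc: np.ndarray, signal_y: np.ndarray) -> FitResult:
    """Monomer-dimer exchange fit; K_D in the concentration units of the input."""
    c = np.asarray(total_conc, float)
    y = np.asarray(signal_y, float)
    if c.size < 8:
        raise ValueError("need at least 8 titration points")
    p0 = (float(np.median(c)), float(y[np.argmin(c)]), float(y[np.argmax(c)]))
    popt, se, rss = _curve_fit(
        lambda cc, kd, free, bound: exchange_model(cc, kd, free, bound),
        c, y, p0, bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
    )
    kd, free, bound = popt
    dof = c.size - 3
    return FitResult(
        params={"KD": float(kd), "free": float(free), "bound": float(bound)},
        stderr={"KD": float(se[0]), "free": float(se[1]), "bound": float(se[2])},
        ci95={"KD": _t_ci(kd, se[0], dof), "free": _t_ci(free, se[1], dof),
              "bound": _t_ci(bound, se[2], dof)},
        rss=rss,
        n_points=c.size,
    )
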