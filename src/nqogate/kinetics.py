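"""Steady-state and transient kinetics fitting.

The steady-state layer fits the ping-pong bi-bi rate law

    v0/e = A*B*kcat / (A*Kb + B*Ka + A*B)

and its NADH-substrate-inhibition extension (the Kb*A term scaled by
1 + A/Kis) jointly over all (A, B) = ([NADH], [CoQ0]) points of an
initial-rate table.  The transient layer fits stopped-flow absorbance
traces to a double exponential and the resulting fast-phase rates to a
zero-intercept hyperbola kobs = kred*S/(Kd + S).

All fits are unweighted nonlinear least squares.  Strictly positive
parameters are handled on a log scale internally (so no bound is ever
active) and reported on the natural scale with delta-method standard
errors; multistart initialization guards against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synthetic import (RateDataset, StoppedFlowTrace, biexponential,
                        pingpong_rate, saturation_kobs)

__all__ = [
    "SteadyStateFit",
    "BiexpFit",
    "SaturationFit",
    "ModelSelection",
    "FoldChange",
    "FitError",
    "absorbance_to_rate",
    "fit_pingpong",
    "fit_pingpong_substrate_inhibition",
    "select_model",
    "fit_biexponential",
    "fit_saturation",
    "efficiency",
    "fold_change",
    "EPSILON_340_NADH",
]

#: molar extinction coefficient of NADH at 340 nm (M^-1 cm^-1)
EPSILON_340_NADH = 6220.0


class FitError(RuntimeError):
    """Raised when a fit fails to converge or the design is degenerate."""


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyStateFit:
    kcat: float                     # s^-1
    Ka: float                       # K_NADH, uM
    Kb: float                       # K_CoQ0, uM
    Kis: float | None               # uM, None for the plain ping-pong model
    se: dict                        # parameter -> standard error
    r_squared: float
    model: str                      # "pingpong" | "pingpong_si"
    rss: float
    n_points: int

    @property
    def n_parameters(self) -> int:
        return 3 if self.Kis is None else 4

    def predict(self, A, B):
        return pingpong_rate(A, B, self.kcat, self.Ka, self.Kb, self.Kis)

    def aicc(self) -> float:
        return _aicc(self.rss, self.n_points, self.n_parameters)


@dataclass(frozen=True)
class BiexpFit:
    B1: float                       # fast-phase amplitude, AU
    B2: float                       # slow-phase amplitude, AU
    kobs1: float                    # s^-1, fast (kobs1 >= kobs2 by convention)
    kobs2: float                    # s^-1, slow
    C: float                        # offset, AU
    se: dict
    r_squared: float
    rates_distinguishable: bool     # False when kobs1/kobs2 < 1.5

    @property
    def amplitude_fraction_fast(self) -> float:
        return self.B1 / (self.B1 + self.B2)

    def predict(self, t):
        return biexponential(t, self.B1, self.B2, self.kobs1, self.kobs2,
                             self.C)


@dataclass(frozen=True)
class SaturationFit:
    kred: float                     # s^-1
    Kd: float                       # uM
    se: dict
    r_squared: float
    kd_unconstrained: bool          # True when Kd > 10x the largest S

    def predict(self, S):
        return saturation_kobs(S, self.kred, self.Kd)


@dataclass(frozen=True)
class ModelSelection:
    choice: str                     # model id of the preferred fit
    aicc: dict                      # model id -> AICc
    f_statistic: float
    p_value: float                  # extra-sum-of-squares F-test


@dataclass(frozen=True)
class FoldChange:
    numerator_label: str
    denominator_label: str
    ratio: float                    # >= 1
    direction: str                  # "increase" | "decrease"


# ---------------------------------------------------------------------------
# shared least-squares machinery (log-parameterized, multistart)
# ---------------------------------------------------------------------------

def _aicc(rss: float, n: int, p: int) -> float:
    k = p + 1   # +1 for the residual variance
    if n - k - 1 <= 0:
        raise FitError(f"too few points (n={n}) for AICc with {p} parameters")
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_log_ls(predict, y, starts, max_nfev=2000):
    """Least squares over log-parameters with multistart.

    ``predict`` maps a natural-scale parameter vector to predictions;
    ``starts`` is an iterable of natural-scale start vectors.  Returns
    (params, se, rss) with delta-method natural-scale standard errors.
    """
    y = np.asarray(y, float)

    def resid(theta):
        return predict(np.exp(theta)) - y

    best = None
    for p0 in starts:
        theta0 = np.log(np.asarray(p0, float))
        try:
            sol = optimize.least_squares(resid, theta0, method="lm",
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                         max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-14 * max(best.cost, 1):
            best = sol
    if best is None:
        raise FitError("nonlinear least squares failed from every start")
    params = np.exp(best.x)
    rss = float(2 * best.cost)
    n, p = len(y), len(params)
    # covariance of log-params at the optimum; natural-scale SE by delta method
    J = best.jac
    dof = max(n - p, 1)
    s2 = rss / dof
    # pseudo-inverse: flat (unidentifiable) parameter directions yield huge
    # or infinite uncertainty rather than a numerical failure
    JTJ = J.T @ J
    cov_log = s2 * np.linalg.pinv(JTJ, rcond=1e-12, hermitian=True)
    var_log = np.maximum(np.diag(cov_log), 0.0)
    flat = np.diag(JTJ) <= 1e-12 * max(np.diag(JTJ).max(), 1e-300)
    se = params * np.sqrt(var_log)
    se[flat] = np.inf
    return params, se, rss


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, float)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssr / sst if sst > 0 else 1.0


def _steady_state_starts(data: RateDataset, with_kis: bool,
                         n_starts: int, seed: int = 7):
    """Heuristic multistart grid: kcat near the rate ceiling, K's near the
    concentration medians, log-jittered."""
    vmax = float(np.max(data.v))
    medA = float(np.median(data.A))
    medB = float(np.median(data.B))
    base = [vmax * 1.5, medA, medB] + ([medA] if with_kis else [])
    rng = np.random.default_rng(seed)
    starts = [np.array(base)]
    while len(starts) < n_starts:
        starts.append(np.array(base) * np.exp(rng.normal(0, 1.0, len(base))))
    return starts


def _fit_steady_state(data: RateDataset, with_kis: bool, n_starts: int,
                      weighting: str = "none") -> SteadyStateFit:
    if len(np.unique(np.stack([data.A, data.B], axis=1), axis=0)) < 3:
        raise FitError("need at least 3 distinct (NADH, CoQ0) combinations")
    if weighting not in ("none", "relative"):
        raise ValueError("weighting must be 'none' or 'relative'")
    A, B, v = data.A, data.B, data.v
    # 'relative' divides residuals by the observed rate — the consistent
    # choice when rate errors scale with the signal (constant CV)
    w = v if weighting == "relative" else np.ones_like(v)

    if with_kis:
        def predict(p):
            return pingpong_rate(A, B, p[0], p[1], p[2], p[3]) / w
    else:
        def predict(p):
            return pingpong_rate(A, B, p[0], p[1], p[2], None) / w

    starts = _steady_state_starts(data, with_kis, n_starts)
    params, se, rss = _fit_log_ls(predict, v / w, starts)
    names = ["kcat", "Ka", "Kb"] + (["Kis"] if with_kis else [])
    se_map = dict(zip(names, (float(s) for s in se)))
    return SteadyStateFit(
        kcat=float(params[0]), Ka=float(params[1]), Kb=float(params[2]),
        Kis=float(params[3]) if with_kis else None,
        se=se_map, r_squared=_r_squared(v, predict(params) * w),
        model="pingpong_si" if with_kis else "pingpong",
        rss=rss, n_points=len(v))


def fit_pingpong(data: RateDataset, n_starts: int = 8,
                 weighting: str = "none") -> SteadyStateFit:
    """Fit the plain ping-pong bi-bi law to an initial-rate table."""
    return _fit_steady_state(data, with_kis=False, n_starts=n_starts,
                             weighting=weighting)


def fit_pingpong_substrate_inhibition(data: RateDataset, n_starts: int = 8,
                                      weighting: str = "none",
                                      ) -> SteadyStateFit:
    """Fit the ping-pong law with NADH substrate inhibition (finite Kis)."""
    return _fit_steady_state(data, with_kis=True, n_starts=n_starts,
                             weighting=weighting)


def select_model(fit1: SteadyStateFit, fit2: SteadyStateFit,
                 data: RateDataset) -> ModelSelection:
    """Choose between nested steady-state models.

    The richer model is preferred only when BOTH the corrected AIC favors
    it AND the extra-sum-of-squares F-test rejects the simpler model at
    alpha = 0.05.  AICc alone admits a boundary-constrained extra parameter
    a few percent of the time by chance; requiring F-test support as well
    keeps that false-positive rate low without hurting power when the
    extra parameter is real.  Ties go to the model with fewer parameters.
    Both fits must have been run with the same weighting so their residual
    sums are comparable.
    """
    simple, rich = sorted([fit1, fit2], key=lambda f: f.n_parameters)
    n = simple.n_points
    if n != rich.n_points:
        raise ValueError("fits must be on the same dataset")
    a_simple, a_rich = simple.aicc(), rich.aicc()
    dp = rich.n_parameters - simple.n_parameters
    dof = n - rich.n_parameters
    if dp > 0 and dof > 0 and rich.rss > 0:
        f_stat = ((simple.rss - rich.rss) / dp) / (rich.rss / dof)
        p_val = float(stats.f.sf(max(f_stat, 0.0), dp, dof))
    else:
        f_stat, p_val = float("nan"), float("nan")
    rich_supported = (a_rich < a_simple
                      and np.isfinite(p_val) and p_val < 0.05)
    choice = rich.model if rich_supported else simple.model
    return ModelSelection(choice=choice,
                          aicc={simple.model: a_simple, rich.model: a_rich},
                          f_statistic=float(f_stat), p_value=p_val)


# ---------------------------------------------------------------------------
# transient kinetics
# ---------------------------------------------------------------------------

def _biexp_initial_guess(t, a):
    """Data-driven initial guess: offset from the tail, half-life for the
    fast rate, log-linear tail slope for the slow rate."""
    C0 = float(np.min(a))
    amp = max(float(a[0] - C0), 1e-6)
    half = a[0] - 0.5 * amp
    below = np.nonzero(a <= half)[0]
    t_half = float(t[below[0]]) if len(below) else float(t[len(t) // 2])
    k1 = math.log(2.0) / max(t_half, 1e-9)
    # slow rate from the log-linear tail of the residual decay
    tail = slice(int(0.7 * len(t)), None)
    resid = np.maximum(a[tail] - C0, 1e-9)
    slope = np.polyfit(t[tail], np.log(resid), 1)[0]
    k2 = max(-float(slope), k1 / 100.0)
    return amp * 0.9, amp * 0.1, k1, max(k2, 1e-6), C0


def fit_biexponential(trace: StoppedFlowTrace, n_starts: int = 4) -> BiexpFit:
    """Fit A(t) = B1 e^(-kobs1 t) + B2 e^(-kobs2 t) + C to one transient.

    Amplitudes and rates are kept positive (log scale); the offset C is
    free.  The two phases are relabeled after fitting so kobs1 >= kobs2;
    a rate ratio below 1.5 is flagged as indistinguishable.
    """
    t, a = trace.times, trace.absorbance
    if len(t) < 10:
        raise FitError("need at least 10 time points for a biexponential fit")
    head, tail = np.mean(a[:5]), np.mean(a[-5:])
    if head <= tail:
        raise FitError("trace is not an overall decay")
    B1g, B2g, k1g, k2g, Cg = _biexp_initial_guess(t, a)
    a_shift = a - Cg + 1.0   # keep the free offset positive for log-params

    def predict(p):
        return biexponential(t, p[0], p[1], p[2], p[3], p[4])

    rng = np.random.default_rng(11)
    base = np.array([B1g, B2g, k1g, k2g, 1.0])
    starts = [base]
    # deterministic spread over rate separations plus seeded jitter
    starts.append(base * np.array([1, 1, 2.0, 0.25, 1]))
    while len(starts) < n_starts:
        starts.append(base * np.exp(rng.normal(0, 0.7, 5)))
    params, se, rss = _fit_log_ls(predict, a_shift, starts)
    B1, B2, k1, k2, Cpos = params
    C = float(Cpos - 1.0 + Cg)
    seB1, seB2, sek1, sek2, seC = se
    if k1 < k2:   # relabel: phase 1 is the fast phase
        B1, B2, k1, k2 = B2, B1, k2, k1
        seB1, seB2, sek1, sek2 = seB2, seB1, sek2, sek1
    yhat = biexponential(t, B1, B2, k1, k2, C)
    return BiexpFit(
        B1=float(B1), B2=float(B2), kobs1=float(k1), kobs2=float(k2), C=C,
        se={"B1": float(seB1), "B2": float(seB2), "kobs1": float(sek1),
            "kobs2": float(sek2), "C": float(seC)},
        r_squared=_r_squared(a, yhat),
        rates_distinguishable=bool(k1 / max(k2, 1e-300) >= 1.5))


def fit_saturation(points, n_starts: int = 4) -> SaturationFit:
    """Fit kobs = kred*S/(Kd + S) (zero intercept) to (S, kobs) pairs.

    The fitted Kd is flagged as unconstrained when it falls outside the
    sampled concentration range by more than a decade on either side: far
    above max(S) the data are linear in S (only kred/Kd identified), far
    below min(S) the enzyme is saturated everywhere (only kred identified
    and the data merely bound Kd from above).
    """
    pts = np.asarray(list(points), float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError("need at least 3 (S, kobs) points")
    S, kobs = pts[:, 0], pts[:, 1]
    if np.any(S <= 0):
        raise FitError("substrate concentrations must be > 0")

    def predict(p):
        return saturation_kobs(S, p[0], p[1])

    base = np.array([float(np.max(kobs)) * 1.2, float(np.median(S))])
    rng = np.random.default_rng(13)
    starts = [base, base * np.array([1.0, 0.1])]
    while len(starts) < n_starts:
        starts.append(base * np.exp(rng.normal(0, 1.0, 2)))
    params, se, rss = _fit_log_ls(predict, kobs, starts)
    return SaturationFit(
        kred=float(params[0]), Kd=float(params[1]),
        se={"kred": float(se[0]), "Kd": float(se[1])},
        r_squared=_r_squared(kobs, predict(params)),
        kd_unconstrained=bool(params[1] > 10.0 * float(np.max(S))
                              or params[1] < 0.1 * float(np.min(S))))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def absorbance_to_rate(slope: float, extinction: float = EPSILON_340_NADH,
                       path_length: float = 1.0,
                       enzyme_concentration: float = 1.0) -> float:
    """Convert an absorbance slope (AU/s) to turnover v0/e (s^-1).

    Beer-Lambert: v0 [M/s] = |slope| / (extinction [M^-1 cm^-1] * path [cm]);
    dividing by the enzyme concentration (uM, converted to M) gives s^-1.
    """
    if extinction <= 0 or path_length <= 0 or enzyme_concentration <= 0:
        raise ValueError("extinction, path length and enzyme concentration "
                         "must be > 0")
    v0_molar = abs(slope) / (extinction * path_length)
    return v0_molar / (enzyme_concentration * 1e-6)


def efficiency(kcat: float, K_uM: float, se_kcat: float = 0.0,
               se_K: float = 0.0) -> tuple[float, float]:
    """Catalytic efficiency kcat/K in M^-1 s^-1 with propagated SE.

    First-order propagation for a ratio:
    se(r)/r = sqrt((se_kcat/kcat)^2 + (se_K/K)^2).
    """
    if kcat <= 0 or K_uM <= 0:
        raise ValueError("kcat and K must be > 0")
    value = kcat / (K_uM * 1e-6)
    rel = math.sqrt((se_kcat / kcat) ** 2 + (se_K / K_uM) ** 2)
    return value, value * rel


def fold_change(value_a: float, value_b: float, label_a: str = "a",
                label_b: str = "b") -> FoldChange:
    """Fold change from ``value_a`` to ``value_b`` (ratio always >= 1).

    ``direction`` describes the a -> b change; equal values report a
    1.0-fold increase by convention.
    """
    if value_a <= 0 or value_b <= 0:
        raise ValueError("fold change requires positive values")
    ratio = max(value_a, value_b) / min(value_a, value_b)
    direction = "decrease" if value_b < value_a else "increase"
    return FoldChange(numerator_label=label_b, denominator_label=label_a,
                      ratio=ratio, direction=direction)
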