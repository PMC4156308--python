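"""Sequential-stage model of single-nucleus marker acquisition.

After nuclear transfer, transplanted nuclei acquire four markers in a fixed
order — oocyte linker histone B4, hypophosphorylated Pol IIA, Ser5-phosphorylated
Pol II, then Ser2-phosphorylated Pol II.  We model this as an irreversible
sequential chain with independent exponential sojourn times (rates k1..k4 per
hour); a marker is observed iff its stage has been reached by the observation
time.  Stage-occupancy probabilities are hypoexponential CDFs, and rates are
estimated by maximum likelihood from cross-sectional binomial counts of
positive nuclei per time point.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

MARKERS = ("B4", "PolIIA", "Ser5P", "Ser2P")

#: marker patterns consistent with strictly sequential acquisition
VALID_PATTERNS = ((0, 0, 0, 0), (1, 0, 0, 0), (1, 1, 0, 0), (1, 1, 1, 0), (1, 1, 1, 1))

# relative gap below which the distinct-rate closed form is numerically unsafe
_TIE_RTOL = 1e-6


@dataclass
class TimeCourse:
    """Cross-sectional marker counts: per time, nuclei scored and positives per marker."""

    times: np.ndarray
    n_scored: np.ndarray
    positives: pd.DataFrame  # times x MARKERS
    per_nucleus: dict[float, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_scored = np.asarray(self.n_scored, dtype=int)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.n_scored = self.n_scored[order]
        self.positives = self.positives.iloc[order].reset_index(drop=True)
        pos = self.positives.to_numpy()
        if np.any(pos < 0) or np.any(pos > self.n_scored[:, None]):
            raise ValueError("positives must satisfy 0 <= positives <= n_scored")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        pos = df[[f"pos_{m}" for m in MARKERS]].copy()
        pos.columns = list(MARKERS)
        return cls(df["time_h"].to_numpy(), df["n_scored"].to_numpy(), pos)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.times, "n_scored": self.n_scored})
        for m in MARKERS:
            out[f"pos_{m}"] = self.positives[m].to_numpy()
        return out


@dataclass
class RateEstimate:
    """Maximum-likelihood stage rates with profile-likelihood 95% CIs."""

    rates: np.ndarray
    log_likelihood: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------
# stage-occupancy probabilities
# ---------------------------------------------------------------------------

def _hypoexp_cdf_closed(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Distinct-rate closed form: P(sum Exp(k_i) <= t) = 1 - sum_i w_i e^{-k_i t}."""
    j = len(rates)
    w = np.ones(j)
    for i in range(j):
        for m in range(j):
            if m != i:
                w[i] *= rates[m] / (rates[m] - rates[i])
    return 1.0 - np.exp(-np.outer(t, rates)) @ w


def _hypoexp_cdf_expm(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Matrix-exponential branch, exact for tied or near-tied rates."""
    j = len(rates)
    q = np.zeros((j + 1, j + 1))
    for i, k in enumerate(rates):
        q[i, i] = -k
        q[i, i + 1] = k
    return np.array([linalg.expm(q * ti)[0, j] for ti in t])


def _hypoexp_cdf(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if len(rates) == 1:
        return 1.0 - np.exp(-rates[0] * t)
    gaps = np.abs(rates[:, None] - rates[None, :]) / np.maximum(rates[:, None], rates[None, :])
    np.fill_diagonal(gaps, np.inf)
    if gaps.min() < _TIE_RTOL:
        return _hypoexp_cdf_expm(rates, t)
    return np.clip(_hypoexp_cdf_closed(rates, t), 0.0, 1.0)


def stage_probabilities(rates: Sequence[float], t: float | Sequence[float]) -> np.ndarray:
    """P_j(t) that a nucleus has reached stage j (j = 1..J) by time t.

    Returns an array of shape (J,) for scalar t, else (len(t), J).  P_j is the
    hypoexponential CDF of the first j sojourn times, so P_1 >= P_2 >= ... for
    every t (the containment property of the sequential model).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be positive and finite")
    scalar = np.isscalar(t)
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tv < 0):
        raise ValueError("t must be non-negative")
    out = np.column_stack([_hypoexp_cdf(rates[: j + 1], tv) for j in range(len(rates))])
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# maximum-likelihood rate fitting
# ---------------------------------------------------------------------------

def _nll(log_rates: np.ndarray, tc: TimeCourse) -> float:
    p = stage_probabilities(np.exp(log_rates), tc.times)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    pos = tc.positives.to_numpy(dtype=float)
    n = tc.n_scored[:, None].astype(float)
    return -float(np.sum(pos * np.log(p) + (n - pos) * np.log1p(-p)))


def _identifiable(tc: TimeCourse) -> bool:
    pos = tc.positives.to_numpy()
    n = tc.n_scored[:, None]
    return bool(np.any((pos > 0) & (pos < n)))


def fit_rates(tc: TimeCourse, seed: int = 0, n_starts: int = 8) -> RateEstimate:
    """Fit stage rates by maximum likelihood with multi-start quasi-Newton.

    The likelihood is a product of binomials — positives_j(t) ~ Bin(n_t, P_j(t))
    — reflecting that each time point scores an independent cross-section of
    nuclei.  95% CIs are profile-likelihood intervals (chi-square(1) cutoff).
    Saturated or all-negative data are non-identifiable: flagged, infinite CIs.
    """
    j = len(MARKERS)
    if not _identifiable(tc):
        return RateEstimate(
            rates=np.full(j, np.nan),
            log_likelihood=np.nan,
            ci_lower=np.zeros(j),
            ci_upper=np.full(j, np.inf),
            converged=False,
        )
    rng = np.random.default_rng(seed)
    t_ref = max(np.median(tc.times[tc.times > 0]), 1.0)
    base = np.log(np.full(j, np.log(2.0) / t_ref))
    best = None
    for i in range(n_starts):
        x0 = base if i == 0 else base + rng.normal(0.0, 1.0, size=j)
        res = optimize.minimize(_nll, x0, args=(tc,), method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    ll = -best.fun
    lo = np.empty(j)
    hi = np.empty(j)
    for idx in range(j):
        lo[idx], hi[idx] = _profile_ci(tc, best.x, idx, best.fun)
    return RateEstimate(rates, ll, lo, hi, converged=bool(best.success))


def _profile_nll(tc: TimeCourse, fixed_idx: int, fixed_logk: float, x_init: np.ndarray) -> float:
    free = [i for i in range(len(x_init)) if i != fixed_idx]

    def f(xfree: np.ndarray) -> float:
        x = np.empty(len(x_init))
        x[fixed_idx] = fixed_logk
        x[free] = xfree
        return _nll(x, tc)

    res = optimize.minimize(f, x_init[free], method="L-BFGS-B")
    return res.fun


def _profile_ci(
    tc: TimeCourse, x_hat: np.ndarray, idx: int, nll_min: float, level: float = 0.95
) -> tuple[float, float]:
    cutoff = nll_min + stats.chi2.ppf(level, df=1) / 2.0
    k_hat = x_hat[idx]

    def excess(logk: float) -> float:
        return _profile_nll(tc, idx, logk, x_hat) - cutoff

    bounds = []
    for direction in (-1.0, +1.0):
        step, probe = 0.25, k_hat
        bracket = None
        for _ in range(60):
            probe = probe + direction * step
            if excess(probe) > 0:
                bracket = (min(probe, probe - direction * step), max(probe, probe - direction * step))
                break
            step *= 1.6
        if bracket is None:
            bounds.append(-np.inf if direction < 0 else np.inf)
        else:
            root = optimize.brentq(excess, bracket[0], bracket[1], xtol=1e-4)
            bounds.append(root)
    return float(np.exp(bounds[0])), float(np.exp(bounds[1]))


# ---------------------------------------------------------------------------
# containment and hierarchy diagnostics
# ---------------------------------------------------------------------------

def containment_matrix(per_nucleus: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """C[x, y] = fraction of x-positive nuclei that are also y-positive.

    Returns the matrix and the per-marker denominators (number of x-positive
    nuclei).  Cells with a zero denominator are NaN.
    """
    if per_nucleus.shape[0] == 0:
        raise ValueError("empty marker matrix")
    m = per_nucleus[list(MARKERS)].to_numpy()
    if not np.isin(m, (0, 1)).all():
        raise ValueError("marker matrix must be binary")
    denom = m.sum(axis=0)
    c = np.full((len(MARKERS), len(MARKERS)), np.nan)
    for x in range(len(MARKERS)):
        if denom[x] > 0:
            c[x] = m[m[:, x] == 1].mean(axis=0)
    cdf = pd.DataFrame(c, index=MARKERS, columns=MARKERS)
    return cdf, pd.Series(denom, index=MARKERS, name="n_positive")


def hierarchy_violation_score(per_nucleus: pd.DataFrame) -> tuple[float, dict[tuple[int, ...], int]]:
    """Fraction of nuclei whose marker pattern is not a prefix of the stage order.

    Valid patterns are 0000, 1000, 1100, 1110, 1111.  Also returns the tally of
    every observed pattern.
    """
    m = per_nucleus[list(MARKERS)].to_numpy()
    if not np.isin(m, (0, 1)).all():
        raise ValueError("marker matrix must be binary")
    tally: dict[tuple[int, ...], int] = {}
    for row in m:
        key = tuple(int(v) for v in row)
        tally[key] = tally.get(key, 0) + 1
    valid = sum(tally.get(p, 0) for p in VALID_PATTERNS)
    score = 1.0 - valid / m.shape[0] if m.shape[0] else 0.0
    return score, tally
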