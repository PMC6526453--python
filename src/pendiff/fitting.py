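"""Per-participant diffusion-model estimation by KS-distance minimization.

Correct and error responses of one condition are pooled into a *signed*
RT sample (word/upper-boundary responses positive, nonword/lower-boundary
responses negated), whose population distribution function is the signed
predicted CDF of the model. The fit criterion per condition is the
Kolmogorov-Smirnov p-value of the sample against that CDF; the combined
objective maximized over parameters is the sum of the two conditions' log
p-values (equivalently their product), so conditions with different trial
counts are weighted comparably. Optimization uses the Nelder-Mead SIMPLEX
with box constraints enforced by penalty, multiple jittered restarts, and a
final polish from the best restart.

Constraint structure: drift rate and relative starting point are estimated
separately per stimulus condition; boundary separation, nondecision time
and the across-trial variabilities are shared. A control model with a
single shared starting point is available via ``share_zr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._exceptions import DataError, EstimationError
from .params import DiffusionParams
from .wfpt import SignedCDFGrid, predicted_signed_cdf

__all__ = [
    "FitConfig",
    "FitResult",
    "signed_sample",
    "ks_distance",
    "ks_pvalue",
    "ks_log_pvalue",
    "initial_values",
    "fit_participant",
    "fit_results_to_frame",
]

_CONDITIONS = ("word", "nonword")


@dataclass
class FitConfig:
    """Settings of the SIMPLEX/KS estimation procedure."""

    share_zr: bool = False  # single relative starting point for both conditions
    fix_variabilities_at_zero: bool = False
    n_restarts: int = 5
    max_iterations: int = 500  # objective evaluations per SIMPLEX run
    convergence_tolerance: float = 1e-3  # fatol on the combined objective
    seed: Optional[int] = None
    include_practice: bool = True
    # RT window the trials were trimmed to; the model CDF is conditioned on
    # (renormalized within) this window so that trimming introduces no
    # truncation bias. Set to None when fitting untrimmed data. If a sample
    # contains RTs outside the window, conditioning is skipped.
    window: Optional[tuple] = (0.250, 3.500)
    # quadrature nodes for drift / starting point / nondecision mixtures
    n_v: int = 20
    n_zr: int = 10
    n_t0: int = 10
    # restarts explore with a coarser quadrature; the final polish uses the
    # full node counts
    coarse_factor: float = 0.4

    def __post_init__(self):
        if self.n_restarts < 1:
            raise EstimationError("n_restarts must be at least 1")


@dataclass
class FitResult:
    """Estimates and fit statistics for one participant."""

    estimate: DiffusionParams
    ks_D_word: float
    ks_D_nonword: float
    ks_p_word: float
    ks_p_nonword: float
    objective: float  # sum of log KS p-values at the estimate
    n_word: int
    n_nonword: int
    converged: bool
    restarts_used: int


def signed_sample(trials: pd.DataFrame, condition: str) -> np.ndarray:
    """Sorted signed RTs of one condition (word responses +, nonword -).

    Expects trimmed, non-reference trials with responses present.
    """
    sel = trials[
        (trials["condition"] == condition)
        & ~trials["is_reference"].astype(bool)
        & trials["response"].notna()
        & trials["rt_s"].notna()
    ]
    if sel.empty:
        raise DataError(f"no usable trials in condition {condition!r}")
    signed = np.where(sel["response"] == "word", sel["rt_s"], -sel["rt_s"])
    return np.sort(signed.astype(float))


def ks_distance(sample: np.ndarray, G) -> float:
    """Supremum distance between a sample's ECDF and a distribution ``G``.

    ``G`` may be a callable or precomputed values of the CDF at the sorted
    sample points. Both one-sided gaps of the ECDF step function are
    examined at every sample point.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 1:
        raise DataError("empty sample")
    g = np.asarray(G(x) if callable(G) else G, dtype=float)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(hi - g), np.abs(lo - g))))


def _ks_lambda(D: float, n: int) -> float:
    sq = math.sqrt(n)
    return D * (sq + 0.12 + 0.11 / sq)


def ks_log_pvalue(D: float, n: int) -> float:
    """Natural log of the KS tail probability (asymptotic, finite-n scaled).

    Uses ``lambda = D (sqrt(n) + 0.12 + 0.11/sqrt(n))`` and the Kolmogorov
    series ``Q(lambda) = 2 sum_k (-1)^(k-1) exp(-2 k^2 lambda^2)``, evaluated
    in log space so the objective stays smooth for arbitrarily poor fits.
    """
    lam = _ks_lambda(D, n)
    if lam < 0.3:  # Q(0.3) > 1 - 1e-7
        return 0.0
    l2 = lam * lam
    # factor out the leading term: Q = 2 e^{-2 l2} (1 - e^{-6 l2} + e^{-16 l2} - ...)
    k = np.arange(1, 12)
    series = np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * (k * k - 1.0) * l2))
    series = max(series, 1e-12)
    return min(0.0, math.log(2.0) - 2.0 * l2 + math.log(series))


def ks_pvalue(D: float, n: int) -> float:
    """KS p-value, clipped to [0, 1]; decreasing in ``D`` at fixed ``n``."""
    if not (0.0 <= D <= 1.0):
        raise DataError(f"KS distance must lie in [0, 1], got {D}")
    if n < 1:
        raise DataError("sample size must be at least 1")
    return float(np.clip(math.exp(ks_log_pvalue(D, n)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# moment-based starting values
# ---------------------------------------------------------------------------

def _ez_va(pc: float, vrt: float, n: int):
    """EZ-style drift magnitude and boundary from accuracy and RT variance."""
    pc = float(np.clip(pc, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    if abs(pc - 0.5) < 1.0 / (2 * n) or vrt <= 0:
        return 0.0, 1.5
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    a = L / v if v != 0 else 1.5
    return float(np.clip(v, -9.0, 9.0)), float(np.clip(a, 0.15, 8.0))


def initial_values(trials: pd.DataFrame, min_trials: int = 20) -> DiffusionParams:
    """Deterministic moment-based starting point for the SIMPLEX search.

    Boundary separation and per-condition drift come from EZ-type moment
    equations (edge-corrected accuracy, correct-RT variance); nondecision
    time starts at 90% of the smallest RT; the starting points are offset
    from 0.5 by the response-proportion asymmetry between conditions.
    Variabilities start at fixed small values inside their feasible region.
    """
    usable = trials[
        ~trials["is_reference"].astype(bool)
        & trials["response"].notna()
        & trials["rt_s"].notna()
    ]
    stats = {}
    for cond in _CONDITIONS:
        sub = usable[usable["condition"] == cond]
        n = len(sub)
        if n < min_trials:
            raise EstimationError(
                f"need at least {min_trials} trials per condition, "
                f"got {n} for {cond!r}"
            )
        correct = sub["response"] == cond
        rt_c = sub.loc[correct, "rt_s"].to_numpy()
        vrt = float(np.var(rt_c, ddof=1)) if rt_c.size > 1 else 0.0
        stats[cond] = (float(correct.mean()), vrt, n)

    v_w, a_w = _ez_va(*stats["word"])
    v_nw, a_nw = _ez_va(*stats["nonword"])
    a = max(0.3, (a_w + a_nw) / 2.0)
    t0 = max(0.06, 0.9 * float(usable["rt_s"].min()))
    zr = float(np.clip(0.5 + 0.5 * (stats["word"][0] - stats["nonword"][0]), 0.15, 0.85))
    s_zr = min(0.1, 1.6 * min(zr, 1.0 - zr))
    s_t0 = min(0.1, 1.8 * (t0 - 0.051)) if t0 > 0.051 else 0.0
    return DiffusionParams(
        v_word=max(v_w, 0.05) if v_w >= 0 else v_w,
        v_nonword=min(-v_nw, -0.05) if v_nw >= 0 else -v_nw,
        a=a,
        zr_word=zr,
        zr_nonword=zr,
        t0=t0,
        s_v=0.3,
        s_zr=max(s_zr, 0.0),
        s_t0=max(s_t0, 0.0),
    ).validate()


# ---------------------------------------------------------------------------
# the SIMPLEX fit
# ---------------------------------------------------------------------------

class _Problem:
    """Free-parameter vector <-> DiffusionParams plus the penalized objective."""

    _EDGE = 0.015  # hard inner margin for starting-point ranges

    def __init__(self, samples, config: FitConfig, min_rt: float):
        self.samples = samples  # {condition: sorted signed sample}
        self.config = config
        self.min_rt = min_rt
        self.window = config.window
        if self.window is not None:
            lo, hi = self.window
            if any(
                (np.abs(s) < lo - 1e-12).any() or (np.abs(s) > hi + 1e-12).any()
                for s in samples.values()
            ):
                self.window = None  # data were not trimmed to this window
        names = ["v_word", "v_nonword", "a", "zr_word", "t0"]
        if not config.share_zr:
            names.insert(4, "zr_nonword")
        if not config.fix_variabilities_at_zero:
            names += ["s_v", "s_zr", "s_t0"]
        self.names = names

    def to_params(self, x: np.ndarray) -> DiffusionParams:
        d = dict(zip(self.names, map(float, x)))
        if self.config.share_zr:
            d["zr_nonword"] = d["zr_word"]
        for key in ("s_v", "s_zr", "s_t0"):
            d.setdefault(key, 0.0)
        return DiffusionParams(**d)

    def to_vector(self, p: DiffusionParams) -> np.ndarray:
        return np.array([getattr(p, n) for n in self.names], dtype=float)

    def violation(self, p: DiffusionParams) -> float:
        """Scaled distance outside the admissible box (0 when feasible)."""
        v = 0.0
        v += max(0.0, 0.1 - p.a) + max(0.0, p.a - 10.0)
        for drift in (p.v_word, p.v_nonword):
            v += max(0.0, abs(drift) - 10.0)
        # the *earliest possible* nondecision time (t0 - s_t0/2) must stay
        # between a physiological floor and the fastest observed response
        t0_lo = p.t0 - p.s_t0 / 2
        v += max(0.0, 0.03 - t0_lo) + max(0.0, t0_lo - self.min_rt)
        v += max(0.0, p.t0 - 3.5)
        v += max(0.0, -p.s_v) + max(0.0, p.s_v - 2.5)
        v += max(0.0, -p.s_zr) + max(0.0, -p.s_t0)
        for zr in (p.zr_word, p.zr_nonword):
            v += max(0.0, (0.02 + self._EDGE) - zr) + max(0.0, zr - (0.98 - self._EDGE))
            v += max(0.0, self._EDGE - (zr - p.s_zr / 2))
            v += max(0.0, (zr + p.s_zr / 2) - (1.0 - self._EDGE))
        v += max(0.0, p.s_t0 / 2 - p.t0)
        return v

    def _model_values(self, sample: np.ndarray, G) -> np.ndarray:
        """Model CDF at the sample points, window-conditioned if applicable.

        With a trimming window ``[lo, hi]`` the kept signed RTs live on
        ``[-hi, -lo] U [lo, hi]``; the comparison distribution is the model
        CDF restricted to that region and renormalized by its mass.
        """
        if self.window is None:
            return np.asarray(G(sample), dtype=float)
        lo, hi = self.window
        pts = np.concatenate([sample, [-hi, -lo, lo, hi]])
        vals = np.asarray(G(pts), dtype=float)
        Gx, (G_mhi, G_mlo, G_lo, G_hi) = vals[:-4], vals[-4:]
        mass = max((G_mlo - G_mhi) + (G_hi - G_lo), 1e-12)
        kept_below = np.where(
            sample < 0, Gx - G_mhi, (G_mlo - G_mhi) + (Gx - G_lo)
        )
        return np.clip(kept_below / mass, 0.0, 1.0)

    def neg_log_p(self, x: np.ndarray, n_v: int, n_zr: int, n_t0: int) -> float:
        p = self.to_params(x)
        viol = self.violation(p)
        if viol > 0:
            return 1e4 * (1.0 + viol)
        total = 0.0
        for cond, sample in self.samples.items():
            G = SignedCDFGrid(p, cond, n_v=n_v, n_zr=n_zr, n_t0=n_t0)
            D = ks_distance(sample, self._model_values(sample, G))
            total += ks_log_pvalue(D, sample.size)
        return -total

    def exact_stats(self, p: DiffusionParams):
        """KS statistics at the estimate via the exact quadrature CDF."""
        out = {}
        for cond, sample in self.samples.items():
            def G(pts, _c=cond):
                return predicted_signed_cdf(
                    p, _c, pts,
                    n_v=self.config.n_v, n_zr=self.config.n_zr,
                    n_t0=self.config.n_t0,
                )
            D = ks_distance(sample, self._model_values(sample, G))
            out[cond] = (D, ks_pvalue(D, sample.size), ks_log_pvalue(D, sample.size))
        return out


def fit_participant(
    trials: pd.DataFrame,
    config: Optional[FitConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> FitResult:
    """Estimate the diffusion model for one participant's trimmed trials.

    The trial table must contain both stimulus conditions. Starting from
    moment-based initial values, ``n_restarts`` SIMPLEX runs (the first from
    the initial values, the rest from multiplicatively jittered copies,
    +-20%) maximize the combined KS criterion; the best solution is polished
    with a final full-resolution run. Degenerate data (e.g. all responses at
    one boundary) never raise from the optimizer: the result is returned
    with ``converged=False`` if no run succeeded.
    """
    config = config or FitConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if trials["participant_id"].nunique() > 1:
        raise DataError("fit_participant expects a single participant's trials")
    if not config.include_practice:
        trials = trials[~trials["is_practice"].astype(bool)]

    samples = {c: signed_sample(trials, c) for c in _CONDITIONS}
    min_rt = float(min(np.abs(s).min() for s in samples.values()))
    problem = _Problem(samples, config, min_rt)
    x0 = problem.to_vector(initial_values(trials))

    cf = max(min(config.coarse_factor, 1.0), 0.2)
    coarse = (
        max(6, int(config.n_v * cf)),
        max(4, int(config.n_zr * cf)),
        max(4, int(config.n_t0 * cf)),
    )
    full = (config.n_v, config.n_zr, config.n_t0)
    opts = dict(
        maxfev=config.max_iterations,
        fatol=config.convergence_tolerance,
        xatol=5e-4,
        adaptive=True,
    )

    # The KS surface has separate local basins for different response-bias
    # structures (starting points biased toward vs. away from the correct
    # boundary) and a long shallow valley in boundary separation, which
    # plain jitter around one start cannot bridge. The restarts therefore
    # combine the moment-based start with bias-structured starts, one of
    # them approaching the valley from the large-boundary side (and
    # jittered copies of these).
    p0 = problem.to_params(x0)
    s_t0_b = min(0.16, 1.8 * max(min_rt - 0.05, 0.0))
    t0_b = float(np.clip(min_rt + s_t0_b / 2 - 0.02, 0.06, 3.0))
    biased = []
    for zw, znw, a_scale in ((0.66, 0.36, 1.0), (0.36, 0.66, 1.0), (0.66, 0.36, 1.45)):
        biased.append(
            p0.replace(
                zr_word=zw, zr_nonword=znw, s_zr=0.2, s_v=0.6,
                s_t0=s_t0_b, t0=t0_b, a=min(p0.a * a_scale, 9.0),
            )
        )
    starts = [x0] + [problem.to_vector(b) for b in biased]
    starts = starts[: config.n_restarts]
    k = 0
    while len(starts) < config.n_restarts:
        base = starts[k % 4]
        starts.append(base * (1.0 + 0.2 * rng.uniform(-1, 1, size=x0.size)))
        k += 1

    best_x, best_f, any_success = None, np.inf, False
    for r in range(config.n_restarts):
        xs = starts[r]
        if problem.violation(problem.to_params(xs)) > 0:
            xs = x0
        res = minimize(
            problem.neg_log_p, xs, args=coarse, method="Nelder-Mead", options=opts
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
            any_success = any_success or bool(res.success)

    polish_opts = dict(opts, maxfev=int(1.5 * config.max_iterations))
    polish = minimize(
        problem.neg_log_p, best_x, args=full, method="Nelder-Mead", options=polish_opts
    )
    if polish.fun < problem.neg_log_p(best_x, *full):
        best_x = polish.x
    converged = bool(polish.success) or any_success

    estimate = problem.to_params(best_x)
    stats = problem.exact_stats(estimate)
    (D_w, p_w, lp_w) = stats["word"]
    (D_nw, p_nw, lp_nw) = stats["nonword"]
    return FitResult(
        estimate=estimate,
        ks_D_word=D_w,
        ks_D_nonword=D_nw,
        ks_p_word=p_w,
        ks_p_nonword=p_nw,
        objective=lp_w + lp_nw,
        n_word=int(samples["word"].size),
        n_nonword=int(samples["nonword"].size),
        converged=converged,
        restarts_used=config.n_restarts,
    )


def fit_results_to_frame(results: dict) -> pd.DataFrame:
    """``{participant_id: FitResult}`` -> one-row-per-participant table."""
    rows = []
    for pid, fr in results.items():
        row = {"participant_id": pid}
        row.update(fr.estimate.as_dict())
        row.update(
            ks_D_word=fr.ks_D_word, ks_D_nonword=fr.ks_D_nonword,
            ks_p_word=fr.ks_p_word, ks_p_nonword=fr.ks_p_nonword,
            objective=fr.objective, n_word=fr.n_word, n_nonword=fr.n_nonword,
            converged=fr.converged, restarts_used=fr.restarts_used,
        )
        rows.append(row)
    return pd.DataFrame(rows)
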