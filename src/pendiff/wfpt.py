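"""Wiener first-passage-time mathematics for the two-boundary diffusion model.

This module contains the analytic core of the package: choice probabilities,
defective first-passage densities and CDFs of the Wiener process between two
absorbing boundaries, the signed predicted CDF with across-trial parameter
variabilities marginalized by deterministic quadrature, and an Euler-type
trial simulator.

Conventions
-----------
* The within-trial diffusion coefficient is fixed at ``s = 1``.
* The "word" response is absorption at the *upper* boundary ``a``; the
  "nonword" response is absorption at the *lower* boundary 0. The process
  starts at ``z = zr * a``.
* Signed response times put upper-boundary responses on the positive
  half-axis and negate lower-boundary response times, so the joint
  distribution of (choice, RT) becomes a single distribution function on
  the real line.

Two exact series representations are used for the defective density/CDF and
the evaluation switches between them: a large-time trigonometric series
(fast for ``t / a**2`` not small) and a small-time method-of-images series
evaluated in log space (stable for short times and for extreme drifts).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import log_ndtr

from ._exceptions import ParameterError, SimulationError
from .params import DiffusionParams

__all__ = [
    "choice_probability",
    "fpt_density",
    "fpt_cdf",
    "predicted_signed_cdf",
    "SignedCDFGrid",
    "simulate_trial",
    "simulate_trials",
]

# Boundary of the switching region between the two series representations,
# in normalized time t / a**2.
_T_SWITCH_REL = 0.04
# Largest tolerated log-prefactor of the large-time series; beyond this the
# alternating sum cancels catastrophically in double precision and the
# images representation is used instead.
_MAX_LARGE_LOG_PREF = 25.0


def _check_domain(v: float, a: float, zr: float) -> None:
    if not a > 0:
        raise ParameterError(f"boundary separation must be positive, got {a}")
    if not 0.0 < zr < 1.0:
        raise ParameterError(f"relative starting point must lie in (0, 1), got {zr}")
    if not np.isfinite(v):
        raise ParameterError(f"drift rate must be finite, got {v}")


def _p_lower(v, a, zr):
    """Probability of absorption at the lower boundary (vectorized, stable).

    For ``v != 0`` the closed form is
    ``(exp(-2 v a) - exp(-2 v z)) / (exp(-2 v a) - 1)`` with ``z = zr * a``;
    the zero-drift limit is ``1 - zr``. Evaluated through ``expm1`` on the
    side of the reflection symmetry where all exponents are non-positive.
    """
    v = np.asarray(v, dtype=float)
    zr = np.asarray(zr, dtype=float)
    v_b, zr_b = np.broadcast_arrays(v, zr)
    out = np.empty(v_b.shape, dtype=float)

    tiny = np.abs(v_b) * a < 1e-10
    out[tiny] = 1.0 - zr_b[tiny]

    def lower_pos(vv, zz):
        # all exponents <= 0 for vv > 0
        z = zz * a
        return np.exp(-2.0 * vv * z) * np.expm1(-2.0 * vv * (a - z)) / np.expm1(-2.0 * vv * a)

    pos = (v_b > 0) & ~tiny
    neg = (v_b < 0) & ~tiny
    out[pos] = lower_pos(v_b[pos], zr_b[pos])
    # reflection: P_lower(v, zr) = 1 - P_lower(-v, 1 - zr)
    out[neg] = 1.0 - lower_pos(-v_b[neg], 1.0 - zr_b[neg])
    return out if out.ndim else float(out)


def choice_probability(v: float, a: float, zr: float) -> float:
    """Probability of an upper-boundary ("word") response.

    Parameters
    ----------
    v : drift rate
    a : boundary separation (> 0)
    zr : relative starting point in (0, 1)
    """
    _check_domain(v, a, zr)
    return float(1.0 - _p_lower(v, a, zr))


# ---------------------------------------------------------------------------
# series representations (lower boundary; upper boundary via reflection)
# ---------------------------------------------------------------------------

def _large_time_K(tmin: float, v: float, a: float, z: float) -> int:
    """Number of large-time series terms for truncation error < ~1e-10."""
    log_pref = max(0.0, -v * z - 0.5 * v * v * tmin)
    k = int(math.ceil((a / math.pi) * math.sqrt(2.0 * (32.0 + log_pref) / tmin))) + 1
    return min(max(k, 8), 512)


def _images_K(tmax: float, v: float, a: float) -> int:
    """Number of image pairs for the small-time series, error < ~1e-10."""
    av = abs(v)
    # solve (2Ka)^2 / (2 t) - 2 av K a >= 45
    k = (av * tmax + math.sqrt(av * av * tmax * tmax + 90.0 * tmax)) / (4.0 * a)
    return min(max(int(math.ceil(k)) + 2, 3), 64)


def _cdf_lower_large(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    z = zr * a
    K = _large_time_K(float(t.min()), v, a, z)
    k = np.arange(1, K + 1, dtype=float)
    lam = 0.5 * (v * v + (k * math.pi / a) ** 2)
    coef = k * np.sin(k * math.pi * zr) / lam
    expo = -v * z - np.multiply.outer(t, lam)
    F = _p_lower(v, a, zr) - (math.pi / a**2) * (np.exp(expo) @ coef)
    return np.clip(F, 0.0, 1.0)


def _cdf_lower_images(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    z = zr * a
    K = _images_K(float(t.max()), v, a)
    ks = np.arange(-K, K + 1, dtype=float)
    c = z + 2.0 * a * ks
    sgn = np.sign(c)
    cab = np.abs(c)
    mu = -sgn * v
    sqt = np.sqrt(t)[:, None]
    tt = t[:, None]
    base = v * (c - z)
    term1 = np.exp(base + log_ndtr((mu * tt - cab) / sqt))
    term2 = np.exp(base + 2.0 * mu * cab + log_ndtr((-mu * tt - cab) / sqt))
    F = ((term1 + term2) * sgn).sum(axis=1)
    return np.clip(F, 0.0, 1.0)


def _cdf_lower(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    """Defective lower-boundary CDF at decision times ``t`` (t <= 0 gives 0)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    if not pos.any():
        return out
    z = zr * a
    t_lo = _T_SWITCH_REL * a * a
    if -v * z > _MAX_LARGE_LOG_PREF:
        # strong drift away from the lower boundary: the large-time series
        # cancels badly until exp(-v z - v^2 t / 2) has decayed
        t_lo = max(t_lo, 2.0 * (-v * z - _MAX_LARGE_LOG_PREF) / (v * v))
    small = pos & (t < t_lo)
    large = pos & ~small
    if small.any():
        out[small] = _cdf_lower_images(t[small], v, a, zr)
    if large.any():
        out[large] = _cdf_lower_large(t[large], v, a, zr)
    return out


def _pdf_lower_large(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    z = zr * a
    K = _large_time_K(float(t.min()), v, a, z)
    k = np.arange(1, K + 1, dtype=float)
    lam = 0.5 * (v * v + (k * math.pi / a) ** 2)
    coef = k * np.sin(k * math.pi * zr)
    expo = -v * z - np.multiply.outer(t, lam)
    g = (math.pi / a**2) * (np.exp(expo) @ coef)
    return np.maximum(g, 0.0)


def _pdf_lower_images(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    z = zr * a
    K = _images_K(float(t.max()), v, a)
    ks = np.arange(-K, K + 1, dtype=float)
    c = z + 2.0 * a * ks
    tt = t[:, None]
    # every term's exponent is <= 0, so this is unconditionally stable
    expo = -v * z - 0.5 * v * v * tt - c**2 / (2.0 * tt)
    g = (c * np.exp(expo)).sum(axis=1) / np.sqrt(2.0 * math.pi * t**3)
    return np.maximum(g, 0.0)


def _pdf_lower(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    if not pos.any():
        return out
    z = zr * a
    t_lo = _T_SWITCH_REL * a * a
    if -v * z > _MAX_LARGE_LOG_PREF:
        t_lo = max(t_lo, 2.0 * (-v * z - _MAX_LARGE_LOG_PREF) / (v * v))
    small = pos & (t < t_lo)
    large = pos & ~small
    if small.any():
        out[small] = _pdf_lower_images(t[small], v, a, zr)
    if large.any():
        out[large] = _pdf_lower_large(t[large], v, a, zr)
    return out


def fpt_density(t, v: float, a: float, zr: float, boundary: str = "lower"):
    """Defective first-passage-time density at decision time ``t``.

    The density integrates (over ``t`` and both boundaries) to 1; the
    integral over a single boundary equals that boundary's choice
    probability. ``t`` must be positive.
    """
    _check_domain(v, a, zr)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr <= 0).any():
        raise ParameterError("decision time must be positive")
    if boundary == "lower":
        out = _pdf_lower(t_arr, v, a, zr)
    elif boundary == "upper":
        out = _pdf_lower(t_arr, -v, a, 1.0 - zr)
    else:
        raise ParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return out if np.ndim(t) else float(out[0])


def fpt_cdf(t, v: float, a: float, zr: float, boundary: str = "lower"):
    """Defective first-passage-time CDF at decision time ``t``.

    Nondecreasing in ``t``; its limit for ``t -> inf`` is the boundary's
    choice probability (a *defective* distribution).
    """
    _check_domain(v, a, zr)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr <= 0).any():
        raise ParameterError("decision time must be positive")
    if boundary == "lower":
        out = _cdf_lower(t_arr, v, a, zr)
    elif boundary == "upper":
        out = _cdf_lower(t_arr, -v, a, 1.0 - zr)
    else:
        raise ParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# quadrature over across-trial variabilities
# ---------------------------------------------------------------------------

def _drift_nodes(mean: float, sd: float, n: int):
    """Gauss-Hermite nodes/weights for a Normal(mean, sd) drift mixture."""
    if sd <= 0 or n <= 1:
        return np.array([mean]), np.array([1.0])
    x, w = np.polynomial.hermite.hermgauss(n)
    return mean + math.sqrt(2.0) * sd * x, w / math.sqrt(math.pi)


def _uniform_nodes(center: float, width: float, n: int):
    """Gauss-Legendre nodes/weights for a Uniform(center +- width/2) mixture."""
    if width <= 0 or n <= 1:
        return np.array([center]), np.array([1.0])
    x, w = np.polynomial.legendre.leggauss(n)
    return center + 0.5 * width * x, w / 2.0


def _condition_nodes(params: DiffusionParams, condition: str, n_v: int, n_zr: int):
    v_nodes, v_w = _drift_nodes(params.v(condition), params.s_v, n_v)
    zr_nodes, zr_w = _uniform_nodes(params.zr(condition), params.s_zr, n_zr)
    return v_nodes, v_w, zr_nodes, zr_w


def predicted_signed_cdf(
    params: DiffusionParams,
    condition: str,
    x,
    n_v: int = 20,
    n_zr: int = 10,
    n_t0: int = 10,
) -> np.ndarray:
    """Predicted CDF of the signed response time for one stimulus condition.

    ``G(x)`` is the probability of (lower-boundary response with RT < -x)
    for x < 0 and (lower-boundary response, any RT) plus (upper-boundary
    response with RT < x) for x > 0, with drift marginalized over
    ``Normal(v, s_v)`` (Gauss-Hermite), starting point over
    ``Uniform(zr +- s_zr/2)`` and nondecision time over
    ``Uniform(t0 +- s_t0/2)`` (Gauss-Legendre each). ``G`` is nondecreasing
    with limits 0 and 1. When all variabilities are zero the quadrature
    collapses to single nodes and the result is the plain defective-CDF
    construction.
    """
    params.validate()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    v_nodes, v_w, zr_nodes, zr_w = _condition_nodes(params, condition, n_v, n_zr)
    t0_nodes, t0_w = _uniform_nodes(params.t0, params.s_t0, n_t0)

    vv, zz = np.meshgrid(v_nodes, zr_nodes, indexing="ij")
    ww = np.outer(v_w, zr_w)
    p_lower_mix = float((ww * _p_lower(vv, params.a, zz)).sum())

    G = np.full(x.shape, p_lower_mix, dtype=float)
    neg = x < 0
    pos = x > 0
    finite = np.isfinite(x)
    for sel, sign_is_neg in ((neg & finite, True), (pos & finite, False)):
        if not sel.any():
            continue
        base = -x[sel] if sign_is_neg else x[sel]
        td = base[:, None] - t0_nodes[None, :]  # decision times per t0 node
        td_flat = td.ravel()
        acc = np.zeros(td_flat.shape, dtype=float)
        for vi, wvi in zip(v_nodes, v_w):
            for zj, wzj in zip(zr_nodes, zr_w):
                if sign_is_neg:
                    acc += wvi * wzj * _cdf_lower(td_flat, vi, params.a, zj)
                else:
                    acc += wvi * wzj * _cdf_lower(td_flat, -vi, params.a, 1.0 - zj)
        F = (acc.reshape(td.shape) * t0_w).sum(axis=1)
        if sign_is_neg:
            G[sel] = p_lower_mix - F
        else:
            G[sel] = p_lower_mix + F
    # signed +-inf map to the distribution limits
    G[np.isneginf(x)] = 0.0
    G[np.isposinf(x)] = 1.0
    return G


class SignedCDFGrid:
    """Fast signed-CDF evaluator used inside the fit objective.

    The defective decision-time CDFs for both boundaries are computed once
    per parameter vector on a fixed time grid, marginalized over the drift
    and starting-point quadrature nodes, and then evaluated at arbitrary
    signed RTs by linear interpolation with the nondecision-time mixture
    applied as a shift. Quadrature nodes match
    :func:`predicted_signed_cdf`; the only additional approximation is the
    grid interpolation (grid resolution keeps it below ~1e-3, negligible
    against the sampling error of empirical CDFs at realistic trial
    numbers).
    """

    def __init__(
        self,
        params: DiffusionParams,
        condition: str,
        n_v: int = 20,
        n_zr: int = 10,
        n_t0: int = 10,
        t_max: float = 3.8,
    ):
        self.params = params
        self.condition = condition
        a = params.a
        v_nodes, v_w, zr_nodes, zr_w = _condition_nodes(params, condition, n_v, n_zr)
        t0_nodes, t0_w = _uniform_nodes(params.t0, params.s_t0, n_t0)
        self._t0_nodes, self._t0_w = t0_nodes, t0_w

        vv, zz = np.meshgrid(v_nodes, zr_nodes, indexing="ij")
        ww = np.outer(v_w, zr_w)
        self.p_lower = float((ww * _p_lower(vv, a, zz)).sum())

        grid = np.concatenate(
            [[0.0], np.geomspace(8e-4, 0.12, 28), np.linspace(0.128, t_max, 236)]
        )
        self._grid = grid
        self._F_lower = self._mixture_cdf_grid(v_nodes, v_w, zr_nodes, zr_w, a)
        self._F_upper = self._mixture_cdf_grid(
            -v_nodes, v_w, 1.0 - zr_nodes, zr_w, a
        )

    def _mixture_cdf_grid(self, v_nodes, v_w, zr_nodes, zr_w, a):
        """Quadrature-weighted defective CDF on the time grid (one boundary)."""
        grid = self._grid
        t = grid[1:]  # grid[0] == 0 -> F = 0
        F = np.zeros(t.shape, dtype=float)

        # nodes with extreme drift-boundary products go through the (slower
        # but unconditionally stable) images representation in full
        v_abs_max = float(np.max(np.abs(v_nodes)))
        safe = np.abs(v_nodes) * a <= 30.0

        t_lo = _T_SWITCH_REL * a * a
        if v_abs_max > 0:
            t_lo = min(t_lo, a / (2.0 * v_abs_max))
        i_sw = int(np.searchsorted(t, t_lo))
        t_small, t_large = t[:i_sw], t[i_sw:]

        # --- small times: method of images, vectorized over all nodes ---
        if t_small.size:
            z = a * zr_nodes[None, :] * np.ones((v_nodes.size, 1))  # (nv, nzr)
            v = v_nodes[:, None] * np.ones((1, zr_nodes.size))
            K = _images_K(float(t_small.max()), v_abs_max, a)
            ks = np.arange(-K, K + 1, dtype=float)
            c = z[..., None] + 2.0 * a * ks  # (nv, nzr, nk)
            sgn = np.sign(c)
            cab = np.abs(c)
            mu = -sgn * v[..., None]
            base = v[..., None] * (c - z[..., None])
            tt = t_small[:, None, None, None]
            sqt = np.sqrt(t_small)[:, None, None, None]
            term1 = np.exp(base + log_ndtr((mu * tt - cab) / sqt))
            term2 = np.exp(base + 2.0 * mu * cab + log_ndtr((-mu * tt - cab) / sqt))
            Fn = ((term1 + term2) * sgn).sum(axis=3)  # (nt, nv, nzr)
            w = np.outer(v_w, zr_w)
            F[:i_sw] = np.einsum("tij,ij->t", Fn, w)

        # --- large times: trigonometric series, factorized over zr ---
        if t_large.size:
            vs = v_nodes[safe]
            ws = v_w[safe]
            if vs.size:
                tmin = float(t_large.min())
                Kl = max(
                    _large_time_K(tmin, float(vs.min()), a, a * float(zr_nodes.max())),
                    _large_time_K(tmin, float(vs.max()), a, a * float(zr_nodes.max())),
                )
                k = np.arange(1, Kl + 1, dtype=float)
                lam = 0.5 * (vs[:, None] ** 2 + (k[None, :] * math.pi / a) ** 2)
                # sum over zr nodes first: C[i, k]
                E = np.exp(-np.outer(vs, a * zr_nodes)) * zr_w[None, :]
                S = k[:, None] * np.sin(np.outer(k, math.pi * zr_nodes))
                C = E @ S.T  # (nv_safe, K)
                coef = (ws[:, None] * C / lam).ravel()
                T = np.exp(-np.multiply.outer(t_large, lam.ravel()))
                vvs, zzs = np.meshgrid(vs, zr_nodes, indexing="ij")
                wws = np.outer(ws, zr_w)
                p_low_safe = float((wws * _p_lower(vvs, a, zzs)).sum())
                F[i_sw:] += p_low_safe - (math.pi / a**2) * (T @ coef)
            # rare extreme-drift nodes: exact per-node images evaluation
            if (~safe).any():
                for vi, wvi in zip(v_nodes[~safe], v_w[~safe]):
                    for zj, wzj in zip(zr_nodes, zr_w):
                        F[i_sw:] += wvi * wzj * _cdf_lower_images(
                            t_large, vi, a, zj
                        )

        out = np.empty(grid.shape, dtype=float)
        out[0] = 0.0
        out[1:] = np.clip(F, 0.0, 1.0)
        return np.maximum.accumulate(out)

    def __call__(self, x) -> np.ndarray:
        """Evaluate the signed CDF at signed response times ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        G = np.full(x.shape, self.p_lower, dtype=float)
        neg = x < 0
        pos = x > 0
        for sel, F, sign_is_neg in (
            (neg, self._F_lower, True),
            (pos, self._F_upper, False),
        ):
            if not sel.any():
                continue
            base = -x[sel] if sign_is_neg else x[sel]
            acc = np.zeros(base.shape, dtype=float)
            for t0k, wk in zip(self._t0_nodes, self._t0_w):
                acc += wk * np.interp(base - t0k, self._grid, F)
            if sign_is_neg:
                G[sel] = self.p_lower - acc
            else:
                G[sel] = self.p_lower + acc
        return G


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

#: Boundary-shift constant for the Euler scheme (Broadie-Glasserman-type
#: continuity correction, -zeta(1/2)/sqrt(2 pi)); shifting both boundaries
#: inwards by ``0.5826 * sqrt(dt)`` removes the O(sqrt(dt)) crossing bias.
_BGK = 0.5826


def simulate_trials(
    params: DiffusionParams,
    condition: str,
    n: int,
    rng: np.random.Generator,
    dt: float = 5e-5,
    t_max: float = 60.0,
):
    """Simulate ``n`` diffusion trials of one condition (vectorized).

    Per-trial parameters are drawn from the across-trial distributions
    (drift normal, starting point and nondecision time uniform), then a
    Euler-Maruyama walk with step ``dt`` runs until a boundary is crossed.
    The boundaries are shifted inwards by ``0.5826 * sqrt(dt)`` and half a
    step is subtracted from the crossing time, which corrects the leading
    discretization bias of the scheme.

    Returns
    -------
    upper : bool array
        True where the upper ("word") boundary was reached.
    rt : float array
        Response times in seconds (nondecision time included).
    """
    params.validate()
    if dt <= 0:
        raise ParameterError("Euler step dt must be positive")
    a = params.a
    v = rng.normal(params.v(condition), params.s_v, size=n) if params.s_v > 0 else np.full(n, params.v(condition))
    zr = (
        rng.uniform(params.zr(condition) - params.s_zr / 2, params.zr(condition) + params.s_zr / 2, size=n)
        if params.s_zr > 0
        else np.full(n, params.zr(condition))
    )
    t0 = (
        rng.uniform(params.t0 - params.s_t0 / 2, params.t0 + params.s_t0 / 2, size=n)
        if params.s_t0 > 0
        else np.full(n, params.t0)
    )

    shift = _BGK * math.sqrt(dt)
    shift = min(shift, 0.25 * a)  # keep the effective corridor open
    lo, hi = shift, a - shift
    x = np.clip(zr * a, lo + 1e-12, hi - 1e-12)

    sq = math.sqrt(dt)
    max_steps = int(math.ceil(t_max / dt))
    idx = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    steps = np.zeros(n, dtype=np.int64)

    step = 0
    while idx.size:
        step += 1
        if step > max_steps:
            raise SimulationError(
                f"{idx.size} walks did not terminate within t_max={t_max}s"
            )
        x = x + v[idx] * dt + sq * rng.standard_normal(idx.size)
        hit_up = x >= hi
        hit_lo = x <= lo
        done = hit_up | hit_lo
        if done.any():
            fin = idx[done]
            upper[fin] = hit_up[done]
            steps[fin] = step
            keep = ~done
            idx = idx[keep]
            x = x[keep]
    rt = t0 + steps * dt - dt / 2.0
    return upper, rt


def simulate_trial(
    params: DiffusionParams,
    condition: str,
    rng: np.random.Generator,
    dt: float = 5e-5,
):
    """Simulate a single trial; returns ``("upper"|"lower", rt_seconds)``."""
    up, rt = simulate_trials(params, condition, 1, rng, dt=dt)
    return ("upper" if up[0] else "lower"), float(rt[0])
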