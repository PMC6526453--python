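"""Goodness-of-fit assessment and bootstrap calibration of the KS criterion.

A participant's model fit is summarized by a single p-value (the smaller of
the two condition-wise KS p-values). Because the KS test's power grows with
the number of trials, judging misfit against the nominal level flags too
many models in large experiments; the calibrated criterion replaces the
nominal cutoff with the alpha-quantile of model p-values obtained from
refitting datasets simulated under the fitted model itself (parametric
bootstrap over the cohort's estimated parameter distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError
from .params import DiffusionParams, PARAM_NAMES
from .fitting import FitConfig, FitResult, fit_participant, signed_sample
from .wfpt import predicted_signed_cdf, simulate_trials

__all__ = [
    "CalibrationResult",
    "model_p",
    "bootstrap_critical_p",
    "flag_misfit",
    "cdf_overlay_table",
]


@dataclass
class CalibrationResult:
    """Outcome of the parametric-bootstrap calibration."""

    critical_p: float
    simulated_p: List[float]
    alpha: float = 0.01
    n_sims: int = 1000


def model_p(fit: FitResult) -> float:
    """One fit statistic per participant: min of the condition p-values."""
    return float(min(fit.ks_p_word, fit.ks_p_nonword))


def _draw_valid_params(
    mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator, max_tries: int = 200
) -> DiffusionParams:
    for _ in range(max_tries):
        x = rng.multivariate_normal(mean, cov, method="svd")
        p = DiffusionParams.from_array(x)
        if p.is_valid():
            return p
    # fall back to a clipped draw at the mean (degenerate but valid)
    x = np.asarray(mean, dtype=float).copy()
    d = dict(zip(PARAM_NAMES, x))
    d["a"] = max(d["a"], 0.2)
    for c in ("word", "nonword"):
        d[f"zr_{c}"] = float(np.clip(d[f"zr_{c}"], 0.1, 0.9))
    d["s_zr"] = min(
        d["s_zr"],
        1.8 * min(min(d["zr_word"], 1 - d["zr_word"]),
                  min(d["zr_nonword"], 1 - d["zr_nonword"])),
    )
    d["s_v"] = max(d["s_v"], 0.0)
    d["t0"] = max(d["t0"], 0.1)
    d["s_t0"] = min(max(d["s_t0"], 0.0), 2 * d["t0"])
    return DiffusionParams(**d).validate()


def _simulate_fit_dataset(
    params: DiffusionParams,
    n_word: int,
    n_nonword: int,
    config: FitConfig,
    rng: np.random.Generator,
    dt: float,
) -> FitResult:
    rows = []
    for cond, n in (("word", n_word), ("nonword", n_nonword)):
        up, rt = simulate_trials(params, cond, n, rng, dt=dt)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": "sim",
                    "session": 1, "page": 1, "slot": 2,
                    "condition": cond,
                    "is_reference": False,
                    "is_practice": False,
                    "response": np.where(up, "word", "nonword"),
                    "rt_s": rt,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)
    if config.window is not None:
        lo, hi = config.window
        trials = trials[(trials["rt_s"] >= lo) & (trials["rt_s"] <= hi)]
    return fit_participant(trials, config, rng)


def bootstrap_critical_p(
    fits: Dict[str, FitResult],
    n_sims: int = 1000,
    alpha: float = 0.01,
    config: Optional[FitConfig] = None,
    rng: Optional[np.random.Generator] = None,
    dt: float = 5e-5,
) -> CalibrationResult:
    """Calibrate the critical fit value by parametric bootstrap.

    The fitted parameter vectors of all participants define a multivariate
    normal (their mean and covariance). ``n_sims`` parameter vectors are
    drawn from it (redrawn until valid), each simulates a dataset whose
    per-condition trial counts are resampled from the participants'
    empirical counts, each dataset is refit with the same configuration,
    and the critical value is the empirical ``alpha``-quantile of the
    resulting model p-values.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be at least 1")
    if len(fits) < 2:
        raise DataError("bootstrap calibration needs at least 2 fitted participants")
    config = config or FitConfig()
    rng = rng or np.random.default_rng()

    X = np.array([fr.estimate.to_array() for fr in fits.values()])
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    # a singular covariance (e.g. a parameter fixed across participants)
    # falls back to its diagonal
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular parameter covariance; falling back to diagonal covariance"
        )
        cov = np.diag(np.diag(cov))

    counts = [(fr.n_word, fr.n_nonword) for fr in fits.values()]
    sim_p = []
    for _ in range(n_sims):
        params = _draw_valid_params(mean, cov, rng)
        n_w, n_nw = counts[rng.integers(len(counts))]
        fr = _simulate_fit_dataset(params, n_w, n_nw, config, rng, dt)
        sim_p.append(model_p(fr))
    critical = float(np.quantile(sim_p, alpha))
    return CalibrationResult(
        critical_p=critical, simulated_p=sim_p, alpha=alpha, n_sims=n_sims
    )


def flag_misfit(fits: Dict[str, FitResult], critical_p: float) -> pd.DataFrame:
    """Flag participants whose model p-value falls below the critical value."""
    if not 0.0 <= critical_p <= 1.0:
        raise ConfigurationError("critical_p must lie in [0, 1]")
    rows = [
        {
            "participant_id": pid,
            "model_p": model_p(fr),
            "flagged": model_p(fr) < critical_p,
        }
        for pid, fr in fits.items()
    ]
    return pd.DataFrame(rows)


def cdf_overlay_table(
    fit: FitResult,
    trials: pd.DataFrame,
    condition: str,
    grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Empirical vs. predicted signed CDF on a grid (plot-ready table).

    The empirical column is the step function of the participant's signed
    sample; the predicted column evaluates the signed model CDF at the
    estimate. The maximum gap between the two columns approaches the
    condition's KS statistic as the grid is refined.
    """
    sample = signed_sample(trials, condition)
    if grid is None:
        pad = 0.1
        grid = np.linspace(sample.min() - pad, sample.max() + pad, 512)
    grid = np.asarray(grid, dtype=float)
    emp = np.searchsorted(sample, grid, side="right") / sample.size
    pred = predicted_signed_cdf(fit.estimate, condition, grid)
    return pd.DataFrame({"x_signed_s": grid, "empirical": emp, "predicted": pred})
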