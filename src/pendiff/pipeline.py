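"""End-to-end orchestration: simulate -> preprocess -> fit -> assess -> stats.

Every stage reads and writes plain CSV/JSON artifacts in the output
directory, so stages can be rerun individually and mixed with user-supplied
inputs (any stage's input files may come from elsewhere, as long as they
follow the table dialects). Per-stage random seeds are derived
deterministically from the master seed, and a fixed seed makes the whole
run reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError, PendiffError
from .cohort import GroupProfile, generate_cohort, older_profile, younger_profile
from .design import ExperimentDesign
from .diagnostics import bootstrap_critical_p, flag_misfit, model_p, cdf_overlay_table
from .fitting import FitConfig, FitResult, fit_participant, fit_results_to_frame
from .groupstats import (
    correlations, drift_sign_convert, mixed_anova, pairwise_bonferroni,
    table2_summary, ttest_between,
)
from .params import DiffusionParams, PARAM_NAMES
from .strokes import TRIM_HI, TRIM_LO, trim_rts
from . import tables

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "fit", "assess", "stats")


class PipelineError(PendiffError):
    """A stage failed; the message names the stage."""


@dataclass
class DiagnosticsConfig:
    n_sims: int = 1000
    alpha: float = 0.01
    n_overlays: int = 10


@dataclass
class PipelineConfig:
    out_dir: str = "pendiff_out"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    profiles: List[GroupProfile] = field(
        default_factory=lambda: [younger_profile(), older_profile()]
    )
    fit: FitConfig = field(default_factory=FitConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    trim_lo: float = TRIM_LO
    trim_hi: float = TRIM_HI
    exclude_practice: bool = False

    def validate(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if not self.trim_lo < self.trim_hi:
            raise ConfigurationError("trim_lo must be below trim_hi")
        self.design.validate()
        for p in self.profiles:
            p.validate()
        return self

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        pl = raw.get("pipeline", {})
        cfg.out_dir = pl.get("out_dir", cfg.out_dir)
        cfg.seed = int(pl.get("seed", cfg.seed))
        cfg.stages = list(pl.get("stages", cfg.stages))
        cfg.trim_lo = float(pl.get("trim_lo", cfg.trim_lo))
        cfg.trim_hi = float(pl.get("trim_hi", cfg.trim_hi))
        cfg.exclude_practice = bool(pl.get("exclude_practice", cfg.exclude_practice))
        if "design" in raw:
            cfg.design = ExperimentDesign(**raw["design"])
        if "fit" in raw:
            fit_kw = dict(raw["fit"])
            if "window" in fit_kw and fit_kw["window"] == "none":
                fit_kw["window"] = None
            cfg.fit = FitConfig(**fit_kw)
        if "diagnostics" in raw:
            cfg.diagnostics = DiagnosticsConfig(**raw["diagnostics"])
        if "groups" in raw:
            profiles = []
            for label, spec in raw["groups"].items():
                base = younger_profile if label == "younger" else older_profile
                kw = dict(spec)
                means = kw.pop("param_means", None)
                prof = base(**kw) if label in ("younger", "older") else GroupProfile(
                    label=label, **kw
                )
                if means:
                    prof.param_means = DiffusionParams(**means)
                profiles.append(prof.validate())
            cfg.profiles = profiles
        return cfg.validate()


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return np.random.default_rng(ss)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(fh, msg: str):
    line = f"{msg}"
    print(line, file=sys.stderr)
    fh.write(line + "\n")
    fh.flush()


def _fits_from_frame(df: pd.DataFrame) -> Dict[str, FitResult]:
    out = {}
    for _, row in df.iterrows():
        est = DiffusionParams(**{n: float(row[n]) for n in PARAM_NAMES})
        out[str(row["participant_id"])] = FitResult(
            estimate=est,
            ks_D_word=float(row["ks_D_word"]),
            ks_D_nonword=float(row["ks_D_nonword"]),
            ks_p_word=float(row["ks_p_word"]),
            ks_p_nonword=float(row["ks_p_nonword"]),
            objective=float(row["objective"]),
            n_word=int(row["n_word"]),
            n_nonword=int(row["n_nonword"]),
            converged=bool(row["converged"]),
            restarts_used=int(row["restarts_used"]),
        )
    return out


def _stats_tables(trials, fits_df, truth, alpha=0.05):
    """All group-level effects on one cohort; returns (results, summary)."""
    groups = dict(zip(truth["participant_id"], truth["group"]))
    summary = table2_summary(trials, groups)

    results = []

    def subject_table(col_by_cond: pd.DataFrame, name):
        rows = []
        for _, r in col_by_cond.iterrows():
            for cond in ("word", "nonword"):
                rows.append(
                    {
                        "subject": r["participant_id"],
                        "group": groups[r["participant_id"]],
                        "condition": cond,
                        "value": r[f"{name}_{cond}"],
                    }
                )
        return pd.DataFrame(rows)

    # trial-level outcomes: correct RT and accuracy per subject x condition
    t = trials[~trials["is_reference"].astype(bool)]
    t = t[t["response"].notna() & t["rt_s"].notna()].copy()
    t["correct"] = (t["response"] == t["condition"]).astype(float)
    per = t.groupby(["participant_id", "condition"]).agg(
        accuracy=("correct", "mean")
    )
    rt_corr = (
        t[t["correct"] == 1]
        .groupby(["participant_id", "condition"])["rt_s"]
        .mean()
        .rename("rt_correct")
    )
    per = per.join(rt_corr).reset_index()
    behav = per.pivot(index="participant_id", columns="condition")
    behav.columns = [f"{a}_{b}" for a, b in behav.columns]
    behav = behav.reset_index()

    fits_c = drift_sign_convert(fits_df)
    fits_c = fits_c.rename(columns={"zr_word": "zr_word", "zr_nonword": "zr_nonword"})

    anova_specs = [
        ("correct RT", behav.rename(columns={"rt_correct_word": "m_word",
                                             "rt_correct_nonword": "m_nonword"}), "m"),
        ("accuracy", behav.rename(columns={"accuracy_word": "m_word",
                                           "accuracy_nonword": "m_nonword"}), "m"),
        ("drift rate", fits_c.rename(columns={"v_word": "m_word",
                                              "v_nonword": "m_nonword"}), "m"),
        ("starting point", fits_c.rename(columns={"zr_word": "m_word",
                                                  "zr_nonword": "m_nonword"}), "m"),
    ]
    for label, table, stem in anova_specs:
        vals = subject_table(table, stem)
        effects = mixed_anova(vals)
        for e in effects:
            e.effect = f"{label}: {e.effect}"
            results.append(e)
        inter_p = effects[2].p_raw
        if inter_p < alpha:
            family = [
                {"kind": "between", "condition": "word"},
                {"kind": "between", "condition": "nonword"},
            ] + [{"kind": "within", "group": g} for g in sorted(set(groups.values()))]
            for e in pairwise_bonferroni(vals, family):
                e.effect = f"{label}: {e.effect}"
                results.append(e)

    glabels = fits_df["participant_id"].map(groups)
    for col, label in [
        ("a", "boundary separation"), ("t0", "nondecision time"),
        ("s_v", "drift variability"), ("s_t0", "nondecision variability"),
        ("s_zr", "starting-point variability"),
    ]:
        try:
            e = ttest_between(fits_df[col].to_numpy(), glabels.to_numpy(), effect=label)
            results.append(e)
        except DataError:
            pass

    if "vocabulary" in truth.columns:
        merged = fits_df.merge(
            truth[["participant_id", "group", "vocabulary"]], on="participant_id"
        )
        cr = correlations(
            merged["v_word"], merged["vocabulary"], merged["group"]
        )
        from .groupstats import GroupTestResult

        results.append(GroupTestResult(
            effect="v_word ~ vocabulary", statistic_type="r",
            value=cr.r_bivariate, df=(float(cr.n - 2),), eta_squared=None,
            p_raw=cr.p_bivariate, n=cr.n,
        ))
        results.append(GroupTestResult(
            effect="v_word ~ vocabulary | group", statistic_type="r",
            value=cr.r_partial, df=(float(cr.n - 3),), eta_squared=None,
            p_raw=cr.p_partial, n=cr.n,
        ))

    res_df = pd.DataFrame([r.as_dict() for r in results])
    return res_df, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    manifest = {"seed": config.seed, "stages": [], "artifacts": {}}
    t_start = time.time()

    def register(name: str):
        p = out / name
        manifest["artifacts"][name] = _sha256(p)

    with open(log_path, "a") as logf:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            rng = _stage_rng(config.seed, stage)
            t0 = time.time()
            _log(logf, f"[{stage}] start (seed={config.seed}, stage_key={STAGES.index(stage)})")
            try:
                if stage == "simulate":
                    strokes, trials, truth = generate_cohort(
                        config.profiles, config.design, rng
                    )
                    tables.write_strokes(strokes, out / "strokes.csv")
                    tables.write_trials(trials, out / "trials.csv")
                    tables.write_truth(truth, out / "truth.csv")
                    for n in ("strokes.csv", "trials.csv", "truth.csv"):
                        register(n)

                elif stage == "preprocess":
                    src = out / "trials.csv"
                    if not src.exists():
                        raise DataError("preprocess requires trials.csv (run simulate "
                                        "or provide one)")
                    trials = tables.read_trials(src)
                    if config.exclude_practice:
                        trials = trials[~trials["is_practice"].astype(bool)]
                    kept, n_elim, frac = trim_rts(trials, config.trim_lo, config.trim_hi)
                    tables.write_trials(kept, out / "trials_trimmed.csv")
                    (out / "trim.json").write_text(json.dumps({
                        "lo_s": config.trim_lo, "hi_s": config.trim_hi,
                        "n_eliminated": n_elim, "fraction_eliminated": frac,
                    }, indent=2))
                    register("trials_trimmed.csv")
                    register("trim.json")
                    _log(logf, f"[preprocess] eliminated {n_elim} trials ({frac:.2%})")

                elif stage == "fit":
                    src = out / "trials_trimmed.csv"
                    if not src.exists():
                        raise DataError("fit requires trials_trimmed.csv (run "
                                        "preprocess first)")
                    trials = tables.read_trials(src)
                    fits = {}
                    pids = list(trials["participant_id"].unique())
                    for i, pid in enumerate(pids, 1):
                        sub = trials[trials["participant_id"] == pid]
                        child = np.random.default_rng(rng.integers(2**31))
                        fits[pid] = fit_participant(sub, config.fit, child)
                        _log(logf, f"[fit] {pid} ({i}/{len(pids)}): "
                                   f"model_p={model_p(fits[pid]):.4f}")
                    tables.write_fits(fit_results_to_frame(fits), out / "fits.csv")
                    register("fits.csv")

                elif stage == "assess":
                    for req in ("fits.csv", "trials_trimmed.csv"):
                        if not (out / req).exists():
                            raise DataError(f"assess requires {req}")
                    fits = _fits_from_frame(tables.read_fits(out / "fits.csv"))
                    trials = tables.read_trials(out / "trials_trimmed.csv")
                    cal = bootstrap_critical_p(
                        fits, n_sims=config.diagnostics.n_sims,
                        alpha=config.diagnostics.alpha, config=config.fit, rng=rng,
                    )
                    (out / "calibration.json").write_text(json.dumps({
                        "alpha": cal.alpha, "critical_p": cal.critical_p,
                        "n_sims": cal.n_sims,
                        "simulated_p_quantiles": {
                            q: float(np.quantile(cal.simulated_p, float(q)))
                            for q in ("0.01", "0.05", "0.25", "0.5", "0.75", "0.95")
                        },
                    }, indent=2))
                    flags = flag_misfit(fits, cal.critical_p)
                    flags.to_csv(out / "flags.csv", index=False)
                    register("calibration.json")
                    register("flags.csv")
                    _log(logf, f"[assess] critical_p={cal.critical_p:.4f}, "
                               f"{int(flags['flagged'].sum())} flagged")
                    # CDF overlays for a subset of participants
                    n_ov = min(config.diagnostics.n_overlays, len(fits))
                    chosen = list(rng.choice(list(fits), size=n_ov, replace=False))
                    for pid in chosen:
                        sub = trials[trials["participant_id"] == pid]
                        for cond in ("word", "nonword"):
                            tab = cdf_overlay_table(fits[pid], sub, cond)
                            name = f"overlay_{pid}_{cond}.csv"
                            tab.to_csv(out / name, index=False)
                            register(name)

                elif stage == "stats":
                    for req in ("fits.csv", "trials_trimmed.csv", "truth.csv"):
                        if not (out / req).exists():
                            raise DataError(f"stats requires {req}")
                    fits_df = tables.read_fits(out / "fits.csv")
                    trials = tables.read_trials(out / "trials_trimmed.csv")
                    truth = tables.read_truth(out / "truth.csv")
                    res, summary = _stats_tables(trials, fits_df, truth)
                    res.to_csv(out / "results.csv", index=False)
                    summary.to_csv(out / "summary.csv", index=False)
                    register("results.csv")
                    register("summary.csv")
                    flags_path = out / "flags.csv"
                    if flags_path.exists():
                        flags = pd.read_csv(flags_path)
                        keep = set(flags.loc[~flags["flagged"], "participant_id"])
                        if 2 <= len(keep) < len(fits_df):
                            res2, _ = _stats_tables(
                                trials[trials["participant_id"].isin(keep)],
                                fits_df[fits_df["participant_id"].isin(keep)],
                                truth[truth["participant_id"].isin(keep)],
                            )
                            res2.to_csv(out / "results_excluding_flagged.csv",
                                        index=False)
                            register("results_excluding_flagged.csv")

            except Exception as exc:
                (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
                _log(logf, f"[{stage}] FAILED: {exc}")
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

            manifest["stages"].append(
                {"stage": stage, "seed_key": STAGES.index(stage)}
            )
            _log(logf, f"[{stage}] done in {time.time() - t0:.1f}s")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log_total = time.time() - t_start
    return manifest
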