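"""Synthetic cohorts for the paper-based lexical decision experiment.

A cohort consists of groups (younger / older adults) of simulated
participants. Each participant gets true diffusion parameters drawn around
the group's population means, a vocabulary covariate correlated with the
word-condition drift rate (better vocabulary, more efficient lexical
evidence accumulation), a full stimulus schedule, diffusion-simulated
choices and response times, an optional fraction of contaminant trials, and
a digital-pen stroke log constructed so that stroke-to-trial extraction
inverts the simulation exactly.

The default group profiles use the empirical group-level parameter means
and standard deviations estimated in the digital-pen lexical-decision aging
experiment that this package models, so a default cohort reproduces that
study's qualitative structure: older adults respond more conservatively
(larger boundary separation), with a longer nondecision time, and are more
accurate on words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .design import ExperimentDesign, build_design
from .params import DiffusionParams, PARAM_NAMES
from .strokes import TRIM_HI, TRIM_LO
from .wfpt import simulate_trials

__all__ = [
    "GroupProfile",
    "younger_profile",
    "older_profile",
    "draw_participant_truth",
    "generate_cohort",
]

#: Group-mean diffusion parameters of the two age groups (younger adults:
#: word drift 1.472, nonword drift -1.944, boundary 2.106, t0 345 ms, ...).
YOUNGER_MEANS = DiffusionParams(
    v_word=1.472, v_nonword=-1.944, a=2.106, zr_word=0.724, zr_nonword=0.359,
    t0=0.345, s_v=0.662, s_zr=0.256, s_t0=0.183,
)
OLDER_MEANS = DiffusionParams(
    v_word=2.033, v_nonword=-2.069, a=2.679, zr_word=0.771, zr_nonword=0.305,
    t0=0.399, s_v=0.758, s_zr=0.215, s_t0=0.172,
)
#: Between-person standard deviations of the parameter estimates.
YOUNGER_SDS = {
    "v_word": 0.675, "v_nonword": 0.645, "a": 0.489, "zr_word": 0.089,
    "zr_nonword": 0.123, "t0": 0.073, "s_v": 0.191, "s_zr": 0.088, "s_t0": 0.052,
}
OLDER_SDS = {
    "v_word": 0.602, "v_nonword": 0.545, "a": 0.540, "zr_word": 0.107,
    "zr_nonword": 0.125, "t0": 0.071, "s_v": 0.153, "s_zr": 0.062, "s_t0": 0.062,
}
#: Vocabulary-score distributions (younger 72.06 +- 12.23, older 85.37 +- 13.41).
VOCAB = {"younger": (72.06, 12.23), "older": (85.37, 13.41)}


@dataclass
class GroupProfile:
    """Population distribution of one age group's parameters and covariates."""

    label: str  # "younger" | "older"
    n_participants: int = 20
    param_means: DiffusionParams = field(default_factory=lambda: YOUNGER_MEANS)
    param_sds: Dict[str, float] = field(default_factory=lambda: dict(YOUNGER_SDS))
    vocab_mean: float = 72.06
    vocab_sd: float = 12.23
    vocab_drift_corr: float = 0.5
    contamination_rate: float = 0.02

    def validate(self) -> "GroupProfile":
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be at least 1")
        if any(sd < 0 for sd in self.param_sds.values()) or self.vocab_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not abs(self.vocab_drift_corr) < 1:
            raise ConfigurationError("|vocab_drift_corr| must be below 1")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ConfigurationError("contamination_rate must lie in [0, 1)")
        self.param_means.validate()
        return self


def younger_profile(**overrides) -> GroupProfile:
    """Default younger-adult group profile."""
    base = dict(
        label="younger", param_means=YOUNGER_MEANS, param_sds=dict(YOUNGER_SDS),
        vocab_mean=VOCAB["younger"][0], vocab_sd=VOCAB["younger"][1],
    )
    base.update(overrides)
    return GroupProfile(**base).validate()


def older_profile(**overrides) -> GroupProfile:
    """Default older-adult group profile."""
    base = dict(
        label="older", param_means=OLDER_MEANS, param_sds=dict(OLDER_SDS),
        vocab_mean=VOCAB["older"][0], vocab_sd=VOCAB["older"][1],
    )
    base.update(overrides)
    return GroupProfile(**base).validate()


def draw_participant_truth(
    profile: GroupProfile, rng: np.random.Generator, max_tries: int = 1000
) -> Tuple[DiffusionParams, float]:
    """Draw one participant's true parameters and vocabulary score.

    Parameters are drawn independently Normal(mean, sd) and redrawn until
    the joint parameter invariants hold. The word-condition drift is coupled
    to the vocabulary z-score so that the population correlation between
    vocabulary and ``v_word`` equals ``vocab_drift_corr``.
    """
    profile.validate()
    means = profile.param_means
    sds = profile.param_sds
    rho = profile.vocab_drift_corr
    z_vocab = rng.standard_normal()
    vocab = profile.vocab_mean + profile.vocab_sd * z_vocab
    for _ in range(max_tries):
        draws = {}
        for name in PARAM_NAMES:
            sd = sds.get(name, 0.0)
            if name == "v_word":
                z = rho * z_vocab + np.sqrt(1 - rho * rho) * rng.standard_normal()
                draws[name] = getattr(means, name) + sd * z
            else:
                draws[name] = rng.normal(getattr(means, name), sd) if sd > 0 else getattr(means, name)
        candidate = DiffusionParams(**draws)
        if candidate.is_valid():
            return candidate, float(vocab)
    raise ConfigurationError(
        f"could not draw valid parameters for group {profile.label!r}; "
        "the profile's invariant region may be infeasible"
    )


def _synthesize_strokes(
    trials: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Pen strokes whose stroke-to-trial extraction reproduces ``trials``.

    The reference mark on each page starts at a small random offset; each
    following pen-down is the previous pen-up plus that trial's RT, and
    marking a checkbox takes a random few hundred milliseconds.
    """
    df = trials.sort_values(["participant_id", "session", "page", "slot"])
    n = len(df)
    mark = rng.uniform(0.25, 0.6, size=n)  # checkbox marking duration
    first = (~df.duplicated(["participant_id", "session", "page"])).to_numpy()
    rt = df["rt_s"].to_numpy()
    # pen_down advances by (previous mark duration + this item's RT) within a
    # page; expressed as a per-page cumulative sum of increments
    inc = rt + np.concatenate([[0.0], mark[:-1]])
    inc[first] = rng.uniform(1.0, 3.0, size=int(first.sum()))  # page offsets
    page_id = first.cumsum()
    pen_down = (
        pd.Series(inc).groupby(page_id).cumsum().to_numpy()
    )
    pen_up = pen_down + mark
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "session": df["session"].to_numpy(),
            "page": df["page"].to_numpy(),
            "slot": df["slot"].to_numpy(),
            "checkbox": np.where(df["response"].to_numpy() == "word", "yes", "no"),
            "pen_down_s": pen_down,
            "pen_up_s": pen_up,
        }
    )


def generate_cohort(
    profiles: List[GroupProfile],
    design: Optional[ExperimentDesign] = None,
    rng: Optional[np.random.Generator] = None,
    dt: float = 5e-5,
):
    """Simulate a full cohort: strokes, trials, and the truth table.

    Every participant receives a randomized stimulus schedule; each
    non-reference item is simulated from the participant's true parameters
    (references get simulated responses too, but no RT enters the analysis).
    With probability ``contamination_rate`` a trial's RT is replaced by a
    uniform draw inside the trimming window and its response by a fair coin
    — contaminants that RT trimming alone cannot remove.

    Returns
    -------
    (strokes, trials, truth) : three DataFrames. ``truth`` holds one row per
    participant: group label, true parameters, vocabulary score, and trial
    counts per condition.
    """
    if not profiles:
        raise ConfigurationError("at least one group profile is required")
    design = (design or ExperimentDesign()).validate()
    rng = rng or np.random.default_rng()

    all_trials = []
    truth_rows = []
    counter = 0
    for profile in profiles:
        profile.validate()
        for _ in range(profile.n_participants):
            counter += 1
            pid = f"{profile.label[0].upper()}{counter:03d}"
            params, vocab = draw_participant_truth(profile, rng)
            schedule = build_design(design, rng)
            sched = pd.DataFrame([s.__dict__ for s in schedule])

            rts = np.empty(len(sched))
            resp_word = np.empty(len(sched), dtype=bool)
            for cond in ("word", "nonword"):
                m = (sched["condition"] == cond).to_numpy()
                up, rt = simulate_trials(params, cond, int(m.sum()), rng, dt=dt)
                resp_word[m] = up
                rts[m] = rt
            if profile.contamination_rate > 0:
                contam = rng.random(len(sched)) < profile.contamination_rate
                ncon = int(contam.sum())
                rts[contam] = rng.uniform(TRIM_LO, TRIM_HI, size=ncon)
                resp_word[contam] = rng.random(ncon) < 0.5

            trials = pd.DataFrame(
                {
                    "participant_id": pid,
                    "session": sched["session"],
                    "page": sched["page"],
                    "slot": sched["slot"],
                    "condition": sched["condition"],
                    "is_reference": sched["is_reference"].astype(bool),
                    "is_practice": sched["session"] <= design.n_practice_sessions,
                    "response": np.where(resp_word, "word", "nonword"),
                    "rt_s": rts,
                }
            )
            # references anchor the timing but never carry an RT themselves
            trials.loc[trials["is_reference"], "rt_s"] = np.nan
            trials["correct"] = np.where(
                trials["response"].notna(),
                trials["response"] == trials["condition"], np.nan,
            )
            all_trials.append(trials)

            counts = trials[~trials["is_reference"]]["condition"].value_counts()
            row = {"participant_id": pid, "group": profile.label,
                   "vocabulary": vocab,
                   "n_word": int(counts.get("word", 0)),
                   "n_nonword": int(counts.get("nonword", 0))}
            row.update({k: v for k, v in params.as_dict().items() if k != "s"})
            truth_rows.append(row)

    trials = pd.concat(all_trials, ignore_index=True)
    # strokes are synthesized from the trial timeline (pen-down of an item
    # minus pen-up of its predecessor equals the trial RT by construction);
    # reference marks get a nominal spacing
    strokes_src = trials.copy()
    ref_fill = rng.uniform(0.8, 2.0, size=int(strokes_src["rt_s"].isna().sum()))
    strokes_src.loc[strokes_src["rt_s"].isna(), "rt_s"] = ref_fill
    strokes = _synthesize_strokes(strokes_src, rng)
    truth = pd.DataFrame(truth_rows)
    return strokes, trials, truth
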