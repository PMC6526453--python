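"""Synthetic cohort generation: truths, coupling, stroke-log inversion."""

import numpy as np
import pytest

from pendiff import (
    ExperimentDesign, draw_participant_truth, generate_cohort, strokes_to_trials,
)
from pendiff.cohort import younger_profile, older_profile, YOUNGER_MEANS

ALL_PARAMS = ["v_word", "v_nonword", "a", "zr_word", "zr_nonword", "t0",
              "s_v", "s_zr", "s_t0"]


def _zero_sd_profile(**kw):
    return younger_profile(param_sds={k: 0.0 for k in ALL_PARAMS}, **kw)


class TestTruthDraws:
    def test_zero_sds_give_the_means(self, rng):
        prof = _zero_sd_profile()
        params, _ = draw_participant_truth(prof, rng)
        for name in ALL_PARAMS:
            assert getattr(params, name) == getattr(YOUNGER_MEANS, name)

    def test_vocabulary_drift_correlation(self):
        rng = np.random.default_rng(99)
        prof = younger_profile()
        vs, vocabs = [], []
        for _ in range(10_000):
            p, vocab = draw_participant_truth(prof, rng)
            vs.append(p.v_word)
            vocabs.append(vocab)
        r = np.corrcoef(vs, vocabs)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_drawn_parameters_satisfy_invariants(self):
        rng = np.random.default_rng(3)
        prof = older_profile()
        for _ in range(300):
            p, _ = draw_participant_truth(prof, rng)
            for zr in (p.zr_word, p.zr_nonword):
                assert 0.0 < zr - p.s_zr / 2 and zr + p.s_zr / 2 < 1.0
            assert p.t0 - p.s_t0 / 2 >= 0


@pytest.fixture(scope="module")
def small_cohort():
    design = ExperimentDesign(n_sessions=4, n_practice_sessions=1)
    profiles = [
        _zero_sd_profile(n_participants=2, contamination_rate=0.0),
        older_profile(n_participants=2),
    ]
    rng = np.random.default_rng(11)
    return design, generate_cohort(profiles, design, rng)


class TestCohortGeneration:

    def test_schedule_volume(self, small_cohort):
        design, (strokes, trials, truth) = small_cohort
        assert len(truth) == 4
        per = trials.groupby("participant_id").size()
        assert (per == design.n_stimuli).all()

    def test_truth_trials_relational_consistency(self, small_cohort):
        _, (strokes, trials, truth) = small_cohort
        assert set(trials["participant_id"]) == set(truth["participant_id"])
        counts = (
            trials[~trials["is_reference"]]
            .groupby(["participant_id", "condition"])
            .size()
            .unstack()
        )
        for _, row in truth.iterrows():
            assert counts.loc[row["participant_id"], "word"] == row["n_word"]
            assert counts.loc[row["participant_id"], "nonword"] == row["n_nonword"]

    def test_stroke_log_inverts_to_trials(self, small_cohort):
        design, (strokes, trials, truth) = small_cohort
        pid = trials["participant_id"].iloc[0]
        sub_strokes = strokes[strokes["participant_id"] == pid]
        # reconstruct the schedule of this participant from their trials
        sched = trials[trials["participant_id"] == pid][
            ["session", "page", "slot", "condition", "is_reference"]
        ]
        back = strokes_to_trials(sub_strokes, sched, design.n_practice_sessions)
        orig = (
            trials[trials["participant_id"] == pid]
            .sort_values(["session", "page", "slot"])
            .reset_index(drop=True)
        )
        back = back.sort_values(["session", "page", "slot"]).reset_index(drop=True)
        assert (back["response"] == orig["response"]).all()
        m = orig["rt_s"].notna()
        assert np.allclose(back.loc[m, "rt_s"], orig.loc[m, "rt_s"], atol=1e-9)
        assert back.loc[~m, "rt_s"].isna().all()

    def test_contamination_rate_zero_is_pure_simulation(self, small_cohort):
        _, (_, trials, truth) = small_cohort
        # the zero-SD zero-contamination participants' RTs respect the
        # nondecision floor of the generating parameters; contaminants would
        # violate it with high probability
        pure = truth[truth["group"] == "younger"]["participant_id"]
        sub = trials[trials["participant_id"].isin(pure) & trials["rt_s"].notna()]
        floor = YOUNGER_MEANS.t0 - YOUNGER_MEANS.s_t0 / 2
        assert sub["rt_s"].min() >= floor - 1e-9


class TestQualitativeAgePattern:
    def test_older_slower_on_nonwords_and_more_accurate_on_words(self, make_trials_fn):
        # scaled-down version of the cohort-level pattern check: group means
        # of accuracy and correct RT reproduce the expected ordering in at
        # least 2 of 3 seeded runs
        make_trials = make_trials_fn
        hits_rt, hits_acc = 0, 0
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            stats = {}
            for label, prof in (("younger", younger_profile()),
                                ("older", older_profile())):
                acc_w, rt_nw = [], []
                for _ in range(6):
                    params, _ = draw_participant_truth(prof, rng)
                    t = make_trials(params, 800, 800, rng)
                    w = t[t["condition"] == "word"]
                    nw = t[t["condition"] == "nonword"]
                    acc_w.append((w["response"] == "word").mean())
                    corr_nw = nw[nw["response"] == "nonword"]
                    rt_nw.append(corr_nw["rt_s"].mean())
                stats[label] = (np.mean(acc_w), np.mean(rt_nw))
            if stats["older"][1] > stats["younger"][1]:
                hits_rt += 1
            if stats["older"][0] > stats["younger"][0]:
                hits_acc += 1
        assert hits_rt >= 2
        assert hits_acc >= 2
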