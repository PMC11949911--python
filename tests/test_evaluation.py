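"""Evaluation statistics against brute-force oracles and constructed cases."""

import numpy as np
import pandas as pd
import pytest

import soundease as se
from soundease.evaluation import (
    clip_rms,
    compare_task_ratings,
    evaluate_predictions,
    group_profile_comparison,
    reproducibility_value,
    reproducibility_from_trials,
    rms_comparability,
    significance_stars,
    usage_counts,
)
from soundease.specs import RATING_ITEMS, param_keys


def _brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def _brute_spearman(x, y):
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            m = v == val
            r[m] = r[m].mean()
        return r

    return _brute_pearson(ranks(np.asarray(x, float)), ranks(np.asarray(y, float)))


def _unit_table(task, pairs):
    """Build (true, pred) unit matrices with one varying column."""
    n = len(pairs)
    k = len(param_keys(task)) + 5
    true = np.full((n, k), 0.5)
    pred = np.full((n, k), 0.5)
    true[:, 0] = [a for a, _ in pairs]
    pred[:, 0] = [b for _, b in pairs]
    true[:, -1] = [a for a, _ in pairs]
    pred[:, -1] = [b for _, b in pairs]
    return true, pred


def test_metrics_match_brute_force_on_hand_table():
    """Pearson, Spearman and native-unit MAE agree with direct formulas on a
    six-row hand-made table."""
    pairs = [(0.1, 0.2), (0.3, 0.25), (0.5, 0.6), (0.7, 0.55), (0.9, 0.8), (0.2, 0.35)]
    true, pred = _unit_table("recollection", pairs)
    report = evaluate_predictions("recollection", true, pred).table
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    # column 0 is amplify_all.gain with range 1-5 (span 4)
    row0 = report.iloc[0]
    assert row0["output"] == "amplify_all.gain"
    assert row0["r"] == pytest.approx(_brute_pearson(a, b), abs=1e-12)
    assert row0["mae"] == pytest.approx(np.mean(np.abs(a - b)) * 4.0, abs=1e-12)
    # last column is a rating (Spearman, span 6)
    rowr = report.iloc[-1]
    assert rowr["kind"] == "rating"
    assert rowr["r"] == pytest.approx(_brute_spearman(a, b), abs=1e-12)
    assert rowr["mae"] == pytest.approx(np.mean(np.abs(a - b)) * 6.0, abs=1e-12)


def test_perfect_and_constant_predictors():
    rng = np.random.default_rng(0)
    k = len(param_keys("recollection")) + 5
    true = rng.uniform(0, 1, (8, k))
    report = evaluate_predictions("recollection", true, true.copy()).table
    assert np.allclose(report["r"], 1.0) and np.allclose(report["mae"], 0.0)
    const = np.full_like(true, 0.5)
    report2 = evaluate_predictions("recollection", true, const).table
    assert report2["r"].isna().all()  # zero-variance predictions -> NA
    assert (report2["stars"] == "NA").all()


def test_significance_star_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.004) == "***"
    assert significance_stars(0.2) == ""


# ---------------------------------------------------------------------------
# Reproducibility value
# ---------------------------------------------------------------------------

def test_reproducibility_set_enumeration():
    # first changes {A, B}, second {A, C}: both=1, one=2 -> 0.5
    value, c_both, c_one = reproducibility_value([({"A", "B"}, {"A", "C"})])
    assert (value, c_both, c_one) == (0.5, 1, 2)
    # identical singleton change in both -> zero denominator, flagged NaN
    value, c_both, c_one = reproducibility_value([({"A"}, {"A"})])
    assert np.isnan(value) and c_both == 1 and c_one == 0
    # nothing changed anywhere -> NaN as well
    value, *_ = reproducibility_value([(set(), set())])
    assert np.isnan(value)
    # union reading
    value, *_ = reproducibility_value([({"A", "B"}, {"A", "C"})], mode="ratio_to_union")
    assert value == pytest.approx(1 / 3)


def test_reproducibility_from_trials_flags_undefined(default_trials):
    res = reproducibility_from_trials(default_trials, "recollection")
    assert set(res.per_participant.columns) >= {"value", "c_both", "c_one", "defined"}
    assert len(res.per_participant) == 57
    assert np.isfinite(res.mean) and res.mean >= 0.0
    # mean excludes undefined rows but keeps them in the table
    defined = res.per_participant[res.per_participant["defined"]]
    assert res.mean == pytest.approx(defined["value"].mean())


# ---------------------------------------------------------------------------
# Usage counts
# ---------------------------------------------------------------------------

def test_usage_counts_all_default_and_single_touch(full_stimuli, full_participants, full_design):
    trials = se.generate_trials(
        full_stimuli, full_participants, se.ResponseModel(noise_sd=0.0), 11, full_design
    )
    # hand-build an all-default table from two rows
    sub = trials[trials["task"] == "recollection"].head(2).copy()
    from soundease.specs import default_settings, task_bounds

    lo, hi = task_bounds("recollection")
    defaults = default_settings("recollection")
    for k, l, h in zip(param_keys("recollection"), lo, hi):
        sub[f"u_{k}"] = (defaults.values[k] - l) / (h - l)
    counts = usage_counts(sub, "recollection")
    assert (counts[["train_all", "test_all"]].to_numpy() == 0).all()
    sub.iloc[0, sub.columns.get_loc("u_noise.amplitude")] = 0.2  # touch Noise once
    counts = usage_counts(sub, "recollection")
    assert counts.set_index("filter").loc["noise", "train_all"] == 1


def test_usage_counts_match_planted_probabilities(default_trials):
    """Observed usage fractions stay inside wide binomial bounds around the
    generator's anchor probabilities."""
    counts = usage_counts(default_trials, "recollection").set_index("filter")
    rec = default_trials[(default_trials["task"] == "recollection") & (~default_trials["is_repeat"])]
    n_train = int(rec["stimulus_category"].isin(("training", "training_reserve")).sum())
    from soundease.synthetic import _USAGE_RECOLLECTION

    for fname, p in _USAGE_RECOLLECTION.items():
        frac = counts.loc[fname, "train_all"] / n_train
        # generous band: anchors hold at mean latent ~1, the population latent
        # spreads around it, so allow +/- 0.2 around the anchor
        assert abs(frac - p) < 0.2, (fname, frac, p)


# ---------------------------------------------------------------------------
# Task rating comparison
# ---------------------------------------------------------------------------

def _paired_frame(rec_vals, eas_vals):
    rows = []
    for i, (a, b) in enumerate(zip(rec_vals, eas_vals)):
        for task, v in (("recollection", a), ("easing", b)):
            row = {
                "participant_id": f"P{i%4}",
                "stimulus_id": f"S{i}",
                "presentation": 1,
                "task": task,
                "is_repeat": False,
            }
            for item in RATING_ITEMS:
                row[f"rating_{item}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def test_compare_ratings_constructed_shift():
    rng = np.random.default_rng(0)
    rec = rng.integers(2, 8, 40)
    df = _paired_frame(rec, rec - 1)  # easing exactly one point lower
    out = compare_task_ratings(df)
    assert (out["mean_difference"] == -1.0).all()
    assert (out["direction"] == "lower").all()
    assert (out["p_ttest"] < 1e-6).all()
    same = compare_task_ratings(_paired_frame(rec, rec))
    assert (same["mean_difference"] == 0.0).all()


# ---------------------------------------------------------------------------
# RMS comparability and group profiles
# ---------------------------------------------------------------------------

def test_ks_trivial_cases():
    same = np.linspace(0.1, 0.5, 30)
    stat, p = rms_comparability(same, same)
    assert stat == 0.0 and p == pytest.approx(1.0)
    stat, _ = rms_comparability(np.full(30, 0.01) + np.arange(30) * 1e-5, np.full(12, 0.9))
    assert stat == 1.0
    with pytest.raises(ValueError):
        rms_comparability([0.1], [0.2, 0.3])


def test_clip_rms_of_constant_signal():
    audio = se.AudioBuffer(np.full(44_100, 0.25), 44_100)
    assert clip_rms(audio) == pytest.approx(0.25, rel=1e-6)


def test_group_comparison_planted_shifts(full_participants):
    out = group_profile_comparison(full_participants).set_index("measure")
    for m in ("aq", "aasp_sensory_sensitivity", "aasp_auditory_total",
              "aasp_low_registration", "aasp_sensation_avoiding"):
        assert out.loc[m, "p"] < 0.05 and out.loc[m, "direction"] == "DD higher"
    assert out.loc["aasp_sensation_seeking", "p"] > 0.05  # null by construction


def test_group_comparison_identical_groups():
    base = se.generate_participants(se.ExperimentDesign(n_dd=5, n_td=5), seed=0)
    clone = base.copy()
    clone.loc[clone["group"] == "TD", list(se.synthetic.TRAIT_PARAMS)] = (
        clone.loc[clone["group"] == "DD", list(se.synthetic.TRAIT_PARAMS)].to_numpy()
    )
    out = group_profile_comparison(clone).set_index("measure")
    assert (out["direction"] == "none").all()
    with pytest.raises(ValueError):
        group_profile_comparison(base.iloc[:4])  # a group below 3 members
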