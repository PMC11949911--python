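"""Evaluation metrics and study statistics.

Covers: per-output test-set performance (Pearson r for filter parameters,
Spearman rho for the ordinal ratings, MAE in native units), filter usage
counts, the paired Recollection-vs-Easing rating comparison, the per-listener
reproducibility value for repeated stimuli, stimulus-RMS comparability between
the training and test sets (two-sample Kolmogorov-Smirnov), and the DD-vs-TD
trait comparison (Mann-Whitney U after Shapiro-Wilk).

Significance stars follow the convention * p<0.05, ** p<0.01, *** p<0.005.
Outputs with zero variance on either side are reported as NA rather than
dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioBuffer
from .specs import RATING_ITEMS, default_settings, param_keys, task_bounds

__all__ = [
    "EvaluationReport",
    "evaluate_predictions",
    "usage_counts",
    "ReproducibilityResult",
    "reproducibility_value",
    "reproducibility_from_trials",
    "compare_task_ratings",
    "rms_comparability",
    "group_profile_comparison",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class EvaluationReport:
    """Per-output performance table for one task and regime."""

    task: str
    regime: str  # All | DD | TD
    table: pd.DataFrame  # columns: output, kind, r, p, stars, mae, n

    def __str__(self) -> str:
        lines = [f"[{self.task} / {self.regime}]"]
        for _, row in self.table.iterrows():
            r = "NA" if pd.isna(row["r"]) else f"{row['r']:.3f} ({row['stars']})"
            lines.append(f"  {row['output']:<36s} r={r:<16s} MAE={row['mae']:.4g}")
        return "\n".join(lines)


def _corr(kind: str, y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float]:
    if np.ptp(y_true) == 0.0 or np.ptp(y_pred) == 0.0:
        return np.nan, np.nan
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # near-constant inputs: report NaN, not noise
        if kind == "rating":
            rho, p = stats.spearmanr(y_true, y_pred)
        else:
            rho, p = stats.pearsonr(y_true, y_pred)
    return float(rho), float(p)


def evaluate_predictions(
    task: str,
    true_unit: np.ndarray,
    pred_unit: np.ndarray,
    regime: str = "All",
) -> EvaluationReport:
    """Score unit-scale predictions against unit-scale truths.

    Filter parameters are compared with Pearson correlation, rating items with
    Spearman (they are ordinal); both with two-sided p-values.  MAE is
    computed after inverse min-max scaling, i.e. in each parameter's native
    units (Hz for frequencies, rating points for ratings).
    """
    keys = param_keys(task)
    n_params = len(keys)
    if true_unit.shape != pred_unit.shape or true_unit.shape[1] != n_params + len(RATING_ITEMS):
        raise ValueError("prediction/truth shape mismatch")
    if len(true_unit) == 0:
        raise ValueError("empty evaluation subset")
    lo, hi = task_bounds(task)
    span = np.concatenate([hi - lo, np.full(len(RATING_ITEMS), 6.0)])
    rows = []
    names = keys + [f"rating_{r}" for r in RATING_ITEMS]
    for j, name in enumerate(names):
        kind = "rating" if j >= n_params else "filter"
        r, p = _corr(kind, true_unit[:, j], pred_unit[:, j])
        mae = float(np.mean(np.abs(true_unit[:, j] - pred_unit[:, j])) * span[j])
        rows.append(
            {
                "output": name,
                "kind": kind,
                "r": r,
                "p": p,
                "stars": significance_stars(p) if np.isfinite(p) else "NA",
                "mae": mae,
                "n": len(true_unit),
            }
        )
    return EvaluationReport(task=task, regime=regime, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Usage counts
# ---------------------------------------------------------------------------

def usage_counts(trials: pd.DataFrame, task: str, atol: float = 1e-12) -> pd.DataFrame:
    """Count trials in which each filter was touched (differs from default).

    A filter counts as used when any of its parameters differs from the
    registry default.  Counts are reported per split (train/test) and per
    group, over non-repeat trials.
    """
    sub = trials[(trials["task"] == task) & (~trials["is_repeat"])]
    defaults = default_settings(task)
    lo, hi = task_bounds(task)
    keys = param_keys(task)
    unit_defaults = {
        k: (defaults.values[k] - l) / (h - l) for k, l, h in zip(keys, lo, hi)
    }
    filters: Dict[str, List[str]] = {}
    for k in keys:
        filters.setdefault(k.split(".")[0], []).append(k)
    is_test = sub["stimulus_category"].isin(("test", "test_reserve"))
    rows = []
    for fname, fkeys in filters.items():
        used = np.zeros(len(sub), dtype=bool)
        for k in fkeys:
            used |= (sub[f"u_{k}"] - unit_defaults[k]).abs().to_numpy() > atol
        rows.append(
            {
                "filter": fname,
                "train_all": int((used & ~is_test).sum()),
                "test_all": int((used & is_test).sum()),
                "train_dd": int((used & ~is_test & (sub["group"] == "DD")).sum()),
                "test_dd": int((used & is_test & (sub["group"] == "DD")).sum()),
                "train_td": int((used & ~is_test & (sub["group"] == "TD")).sum()),
                "test_td": int((used & is_test & (sub["group"] == "TD")).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reproducibility of repeated stimuli
# ---------------------------------------------------------------------------

@dataclass
class ReproducibilityResult:
    per_participant: pd.DataFrame  # participant_id, value, c_both, c_one, defined
    mean: float
    sem: float
    mode: str

    def __str__(self):
        return f"reproducibility ({self.mode}): {self.mean:.3f} +/- {self.sem:.3f} (SE)"


def _changed_set(unit_values: Dict[str, float], task: str, atol: float = 1e-12) -> set:
    defaults = default_settings(task)
    lo, hi = task_bounds(task)
    keys = param_keys(task)
    ud = {k: (defaults.values[k] - l) / (h - l) for k, l, h in zip(keys, lo, hi)}
    changed = set()
    for k in keys:
        if abs(unit_values[k] - ud[k]) > atol:
            changed.add(k.split(".")[0])
    return changed


def reproducibility_value(
    pairs: Sequence[Tuple[set, set]], mode: str = "ratio_to_one"
) -> Tuple[float, int, int]:
    """Reproducibility value for one participant.

    ``pairs`` holds, per repeated stimulus, the sets of filters changed from
    default on the first and second presentations.  ``C_both`` counts
    (stimulus, filter) pairs changed in both presentations, ``C_one`` those
    changed in exactly one.  Two readings of the ratio are supported:
    ``"ratio_to_one"`` (the literal reading, ``C_both / C_one``) and
    ``"ratio_to_union"`` (``C_both / (C_both + C_one)``).  Returns
    ``(value, c_both, c_one)`` with NaN when the denominator is zero.
    """
    c_both = sum(len(a & b) for a, b in pairs)
    c_one = sum(len(a ^ b) for a, b in pairs)
    if mode == "ratio_to_one":
        denom = c_one
    elif mode == "ratio_to_union":
        denom = c_both + c_one
    else:
        raise ValueError(f"unknown mode {mode!r}")
    value = c_both / denom if denom > 0 else np.nan
    return value, c_both, c_one


def reproducibility_from_trials(
    trials: pd.DataFrame, task: str, mode: str = "ratio_to_one"
) -> ReproducibilityResult:
    """Per-participant reproducibility over the repeated stimuli.

    Undefined participants (zero denominator) are flagged and excluded from
    the mean/SE, never silently dropped from the table.
    """
    sub = trials[trials["task"] == task]
    repeats = sub[sub["is_repeat"]]
    if repeats.empty:
        raise ValueError("no repeated presentations in the trial table")
    keys = param_keys(task)
    rows = []
    for pid, grp in repeats.groupby("participant_id"):
        pairs = []
        for _, second in grp.iterrows():
            first = sub[
                (sub["participant_id"] == pid)
                & (sub["stimulus_id"] == second["stimulus_id"])
                & (~sub["is_repeat"])
            ]
            if first.empty:
                continue
            first = first.iloc[0]
            set1 = _changed_set({k: first[f"u_{k}"] for k in keys}, task)
            set2 = _changed_set({k: second[f"u_{k}"] for k in keys}, task)
            pairs.append((set1, set2))
        value, c_both, c_one = reproducibility_value(pairs, mode)
        rows.append(
            {
                "participant_id": pid,
                "value": value,
                "c_both": c_both,
                "c_one": c_one,
                "defined": np.isfinite(value),
            }
        )
    table = pd.DataFrame(rows)
    defined = table.loc[table["defined"], "value"]
    mean = float(defined.mean()) if len(defined) else np.nan
    sem = float(defined.sem()) if len(defined) > 1 else np.nan
    return ReproducibilityResult(per_participant=table, mean=mean, sem=sem, mode=mode)


# ---------------------------------------------------------------------------
# Recollection vs Easing ratings
# ---------------------------------------------------------------------------

def compare_task_ratings(trials: pd.DataFrame) -> pd.DataFrame:
    """Paired per-item comparison of Recollection vs Easing stress ratings.

    Rows are paired by (participant, stimulus, presentation); for each rating
    item a Shapiro-Wilk normality check is run on the paired differences,
    then a paired t-test (primary, mirroring the stated procedure) and a
    Wilcoxon signed-rank test (non-normal branch) are both reported, with the
    mean difference (Easing - Recollection) and its direction.
    """
    keys = ["participant_id", "stimulus_id", "presentation"]
    rec = trials[(trials["task"] == "recollection") & (~trials["is_repeat"])]
    eas = trials[(trials["task"] == "easing") & (~trials["is_repeat"])]
    merged = rec.merge(eas, on=keys, suffixes=("_rec", "_eas"))
    if merged.empty:
        raise ValueError("no paired (participant, stimulus) rows between the tasks")
    rows = []
    for item in RATING_ITEMS:
        a = merged[f"rating_{item}_rec"].to_numpy(dtype=float)
        b = merged[f"rating_{item}_eas"].to_numpy(dtype=float)
        diff = b - a
        sw_p = float(stats.shapiro(diff[:5000]).pvalue) if np.std(diff) > 0 else np.nan
        t_stat, t_p = stats.ttest_rel(b, a)
        if np.all(diff == 0):
            w_p = 1.0
        else:
            w_p = float(stats.wilcoxon(diff[diff != 0]).pvalue) if np.any(diff != 0) else 1.0
        md = float(np.mean(diff))
        rows.append(
            {
                "item": item,
                "n_pairs": len(diff),
                "mean_difference": md,
                "direction": "lower" if md < 0 else ("higher" if md > 0 else "none"),
                "t": float(t_stat),
                "p_ttest": float(t_p),
                "p_wilcoxon": w_p,
                "shapiro_p": sw_p,
                "stars": significance_stars(float(t_p)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stimulus RMS comparability
# ---------------------------------------------------------------------------

_RMS_FRAME = 2048
_RMS_HOP = 512


def clip_rms(audio: AudioBuffer) -> float:
    """Frame-wise RMS (frame 2,048 / hop 512) aggregated by the mean."""
    x = audio.mono()
    if len(x) < _RMS_FRAME:
        return float(np.sqrt(np.mean(x**2)))
    starts = np.arange(0, len(x) - _RMS_FRAME + 1, _RMS_HOP)
    idx = starts[:, None] + np.arange(_RMS_FRAME)[None, :]
    return float(np.mean(np.sqrt((x[idx] ** 2).mean(axis=1))))


def rms_comparability(
    train_rms: Sequence[float], test_rms: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample KS test between the per-clip RMS samples of the two sets.

    Returns (statistic, p) for the standard KS null of equal distributions;
    interpretation is left to the caller.
    """
    a, b = np.asarray(train_rms, float), np.asarray(test_rms, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two stimuli per side")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# DD vs TD trait comparison
# ---------------------------------------------------------------------------

_TRAIT_MEASURES = (
    "aq",
    "aasp_low_registration",
    "aasp_sensation_seeking",
    "aasp_sensory_sensitivity",
    "aasp_sensation_avoiding",
    "aasp_auditory_total",
)


def group_profile_comparison(participants: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney U per trait measure between the DD and TD groups.

    Shapiro-Wilk is reported per group alongside; the non-parametric test is
    the inferential one throughout.
    """
    dd = participants[participants["group"] == "DD"]
    td = participants[participants["group"] == "TD"]
    if len(dd) < 3 or len(td) < 3:
        raise ValueError("each group needs at least 3 members")
    rows = []
    for m in _TRAIT_MEASURES:
        a, b = dd[m].to_numpy(float), td[m].to_numpy(float)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        sw_dd = float(stats.shapiro(a).pvalue) if np.std(a) > 0 else np.nan
        sw_td = float(stats.shapiro(b).pvalue) if np.std(b) > 0 else np.nan
        delta = float(np.mean(a) - np.mean(b))
        if p >= 0.05:
            direction = "none"
        else:
            direction = "DD higher" if np.median(a) > np.median(b) else "TD higher"
        rows.append(
            {
                "measure": m,
                "U": float(u),
                "p": float(p),
                "stars": significance_stars(float(p)),
                "dd_mean": float(np.mean(a)),
                "td_mean": float(np.mean(b)),
                "mean_difference": delta,
                "direction": direction,
                "shapiro_p_dd": sw_dd,
                "shapiro_p_td": sw_td,
            }
        )
    return pd.DataFrame(rows)
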