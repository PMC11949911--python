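"""End-to-end plumbing: embeddings for a stimulus set, model-ready datasets,
and a train-plus-evaluate convenience wrapper.

The assembly contract: trials reference stimuli by id; embeddings are
computed once per unique stimulus; covariates come from the participant table
(plus, for the Easing task, the same trial's Recollection settings and
ratings); targets are the task's unit-scale filter parameters followed by the
five unit-scaled ratings.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import features
from .engine import volume_correction_db
from .model import (
    ModelBundle,
    ModelConfig,
    TaskDataset,
    build_model,
    predict_unit,
    split_by_stimulus,
    train,
)
from .evaluation import EvaluationReport, evaluate_predictions
from .specs import RATING_ITEMS, normalize_ratings, param_keys
from .synthetic import Stimulus

__all__ = [
    "embed_stimuli",
    "covariates_for",
    "build_task_dataset",
    "train_and_evaluate",
]


def embed_stimuli(stimuli: Sequence[Stimulus], frontend: str = "fallback") -> Dict[str, np.ndarray]:
    """Embed every stimulus once; returns ``stimulus_id -> (41, 1024)``."""
    out = {}
    for s in stimuli:
        if s.audio is None:
            raise ValueError(f"stimulus {s.stimulus_id} carries no audio")
        out[s.stimulus_id] = features.embed_audio(s.audio, frontend=frontend).astype(np.float32)
    return out


def covariates_for(participants: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Base covariate vector per participant id (task-independent part)."""
    out = {}
    for _, row in participants.iterrows():
        profile = features.ParticipantProfile(
            group=row["group"],
            age=float(row["age"]),
            sex=row["sex"],
            aq=float(row["aq"]),
            aasp_low_registration=float(row["aasp_low_registration"]),
            aasp_sensation_seeking=float(row["aasp_sensation_seeking"]),
            aasp_sensory_sensitivity=float(row["aasp_sensory_sensitivity"]),
            aasp_sensation_avoiding=float(row["aasp_sensation_avoiding"]),
            aasp_auditory_total=float(row["aasp_auditory_total"]),
        )
        state = features.SessionState(
            sleep_minutes=float(row["sleep_minutes"]),
            fatigue_physical=float(row["fatigue_physical"]),
            fatigue_mental=float(row["fatigue_mental"]),
            volume_o=float(row["volume_o"]),
            bluetooth_profile=row["bluetooth_profile"],
        )
        a_db = volume_correction_db(state.volume_o)
        out[row["participant_id"]] = features.build_covariates(profile, state, a_db)
    return out


def _regime_mask(df: pd.DataFrame, regime: str) -> pd.Series:
    regime = regime.lower()
    if regime == "all":
        return pd.Series(True, index=df.index)
    if regime in ("dd", "td"):
        return df["group"] == regime.upper()
    raise ValueError(f"unknown regime {regime!r}; expected All, DD or TD")


def build_task_dataset(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    embeddings: Dict[str, np.ndarray],
    task: str,
    regime: str = "All",
) -> TaskDataset:
    """Assemble model arrays for one task from a (subset of a) trial table.

    ``trials`` should already be one side of :func:`split_by_stimulus`.
    For the Easing task the covariates are extended with the trial's
    Recollection settings and ratings, which must be present in the table.
    """
    task = task.lower()
    sub = trials[(trials["task"] == task) & _regime_mask(trials, regime)]
    if sub.empty:
        raise ValueError(f"no {task!r} trials in regime {regime!r}")
    base_cov = covariates_for(participants)
    keys = param_keys(task)

    rec_lookup = None
    if task == "easing":
        rec_keys = param_keys("recollection")
        rec = trials[trials["task"] == "recollection"]
        rec_lookup = rec.set_index(["participant_id", "stimulus_id", "presentation"])

    stim_ids = sorted(sub["stimulus_id"].unique())
    stim_row = {sid: i for i, sid in enumerate(stim_ids)}
    emb = np.stack([embeddings[sid] for sid in stim_ids])

    covs: List[np.ndarray] = []
    targets: List[np.ndarray] = []
    stim_index = np.empty(len(sub), dtype=np.intp)
    for i, (_, row) in enumerate(sub.iterrows()):
        stim_index[i] = stim_row[row["stimulus_id"]]
        c = base_cov[row["participant_id"]]
        if task == "easing":
            try:
                rec_row = rec_lookup.loc[
                    (row["participant_id"], row["stimulus_id"], row["presentation"])
                ]
            except KeyError:
                raise ValueError(
                    f"no Recollection counterpart for trial "
                    f"({row['participant_id']}, {row['stimulus_id']})"
                ) from None
            rec_settings = np.array([rec_row[f"u_{k}"] for k in rec_keys])
            rec_ratings = normalize_ratings(
                [rec_row[f"rating_{it}"] for it in RATING_ITEMS]
            )
            c = np.concatenate([c, rec_settings, rec_ratings])
        covs.append(c)
        y = np.array(
            [row[f"u_{k}"] for k in keys]
            + list(normalize_ratings([row[f"rating_{it}"] for it in RATING_ITEMS]))
        )
        targets.append(y)
    return TaskDataset(
        embeddings=emb,
        stim_index=stim_index,
        covariates=np.stack(covs),
        targets=np.stack(targets),
        stimulus_ids=np.array([row for row in sub["stimulus_id"]]),
        meta=sub.reset_index(drop=True),
    )


def train_and_evaluate(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    embeddings: Dict[str, np.ndarray],
    config: ModelConfig,
    regime: str = "All",
    epochs: Optional[int] = None,
) -> Tuple[ModelBundle, EvaluationReport, TaskDataset, TaskDataset]:
    """Split by stimulus, train on the regime's training side, score the test
    side; returns (bundle, report, train_data, test_data)."""
    train_df, test_df = split_by_stimulus(trials)
    train_data = build_task_dataset(train_df, participants, embeddings, config.task, regime)
    test_data = build_task_dataset(test_df, participants, embeddings, config.task, regime)
    bundle = build_model(config, cov_dim=train_data.covariates.shape[1])
    train(bundle, train_data, epochs=epochs)
    pred = predict_unit(bundle, test_data)
    report = evaluate_predictions(config.task, test_data.targets, pred, regime=regime)
    return bundle, report, train_data, test_data
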