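"""Task predictors: Bi-LSTM regressors of filter settings and stress ratings.

One joint model per task maps a stimulus embedding (41 feature frames x 1,024
features) plus the unit-scaled covariate vector onto all outputs at once:
the task's filter parameters (13 for Recollection, 17 for Easing) and the five
stress ratings, every output on the unit scale.  Training minimizes MSE with
Adam (default 300 epochs, batch size 24); the dataset is always split by
stimulus, never by listener, so evaluation measures generalization to novel
sounds.  Predictions are mapped back to native units by inverse min-max
scaling, which together with the sigmoid head makes them range-respecting by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nn import Adam, BiLSTMRegressor
from .specs import RATING_ITEMS, denormalize_ratings, param_keys, task_bounds

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "TaskDataset",
    "build_model",
    "split_by_stimulus",
    "train",
    "predict_unit",
    "predict",
    "save_bundle",
    "load_bundle",
]

TRAIN_CATEGORIES = ("training", "training_reserve")
TEST_CATEGORIES = ("test", "test_reserve")


@dataclass
class ModelConfig:
    task: str = "recollection"
    lstm_hidden: int = 128
    dense_widths: Tuple[int, ...] = (256, 128)
    dropout_rate: float = 0.2
    epochs: int = 300
    batch_size: int = 24
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        self.task = self.task.lower()
        if self.task not in ("recollection", "easing"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.epochs <= 0 or self.batch_size <= 0 or any(w <= 0 for w in self.dense_widths):
            raise ValueError("epochs, batch_size and dense widths must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TaskDataset:
    """Model-ready arrays for one task and one trial subset.

    ``embeddings`` holds one row per *unique* stimulus; ``stim_index`` maps
    each trial to its stimulus row, so the LSTM work is shared across trials
    of the same sound.
    """

    embeddings: np.ndarray  # (S, 41, 1024)
    stim_index: np.ndarray  # (N,)
    covariates: np.ndarray  # (N, C)
    targets: np.ndarray  # (N, K) unit scale
    stimulus_ids: Optional[np.ndarray] = None
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self):
        n = len(self.stim_index)
        if self.covariates.shape[0] != n or self.targets.shape[0] != n:
            raise ValueError("inconsistent trial counts in dataset arrays")

    @property
    def n_trials(self) -> int:
        return len(self.stim_index)


def output_schema(task: str) -> List[str]:
    """Ordered output names: filter parameters, then the five rating items."""
    return param_keys(task) + [f"rating_{r}" for r in RATING_ITEMS]


@dataclass
class ModelBundle:
    """A (possibly trained) predictor plus everything needed to use it."""

    config: ModelConfig
    net: BiLSTMRegressor
    output_schema: List[str] = field(default_factory=list)
    loss_trace: List[float] = field(default_factory=list)
    trained: bool = False

    @property
    def n_params_out(self) -> int:
        return len(param_keys(self.config.task))


def build_model(config: ModelConfig, cov_dim: int, seq_features: int = 1024) -> ModelBundle:
    """Construct an untrained predictor for the configured task."""
    schema = output_schema(config.task)
    net = BiLSTMRegressor(
        seq_features=seq_features,
        cov_dim=cov_dim,
        n_outputs=len(schema),
        lstm_hidden=config.lstm_hidden,
        dense_widths=tuple(config.dense_widths),
        dropout=config.dropout_rate,
        seed=config.seed,
    )
    return ModelBundle(config=config, net=net, output_schema=schema)


def split_by_stimulus(trials: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition trials by stimulus category (never by participant).

    Training + Training-reserve stimuli form the training set; Test +
    Test-reserve the test set.  Repeated presentations (reproducibility
    checks) are excluded from both sides.
    """
    if "stimulus_category" not in trials.columns:
        raise KeyError("trials need a 'stimulus_category' column")
    cats = set(trials["stimulus_category"].unique())
    unknown = cats - set(TRAIN_CATEGORIES) - set(TEST_CATEGORIES)
    if unknown:
        raise ValueError(f"unlabeled stimulus categories: {sorted(unknown)}")
    base = trials[~trials.get("is_repeat", False)] if "is_repeat" in trials.columns else trials
    train = base[base["stimulus_category"].isin(TRAIN_CATEGORIES)]
    test = base[base["stimulus_category"].isin(TEST_CATEGORIES)]
    overlap = set(train["stimulus_id"]) & set(test["stimulus_id"])
    if overlap:
        raise ValueError(f"stimuli appear on both sides of the split: {sorted(overlap)[:5]}")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train(
    bundle: ModelBundle,
    data: TaskDataset,
    epochs: Optional[int] = None,
    verbose: bool = False,
) -> List[float]:
    """Minibatch MSE training with Adam; returns the per-epoch loss trace.

    Deterministic under the bundle's seed on a single thread.  Raises on an
    empty training set or a non-finite loss.
    """
    if data.n_trials == 0:
        raise ValueError("training set is empty")
    cfg = bundle.config
    n_epochs = epochs if epochs is not None else cfg.epochs
    net = bundle.net
    opt = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 7)
    emb = data.embeddings.astype(net.dtype, copy=False)
    cov = data.covariates.astype(net.dtype, copy=False)
    tgt = data.targets.astype(net.dtype, copy=False)
    n = data.n_trials
    bs = cfg.batch_size
    trace: List[float] = []
    for epoch in range(n_epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            u, inv = np.unique(data.stim_index[idx], return_inverse=True)
            net.zero_grad()
            y = net.forward(emb[u], inv, cov[idx], training=True)
            err = y - tgt[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // bs}: {loss}"
                )
            net.backward((2.0 / err.size) * err)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if verbose and (epoch % 25 == 0 or epoch == n_epochs - 1):
            print(f"epoch {epoch + 1}/{n_epochs}  mse={trace[-1]:.5f}")
    bundle.loss_trace.extend(trace)
    bundle.trained = True
    return trace


def predict_unit(bundle: ModelBundle, data: TaskDataset, batch_size: int = 256) -> np.ndarray:
    """Unit-scale predictions (N, K) in evaluation mode (no dropout, running
    batch-norm statistics)."""
    net = bundle.net
    outs = []
    emb = data.embeddings.astype(net.dtype, copy=False)
    cov = data.covariates.astype(net.dtype, copy=False)
    for start in range(0, data.n_trials, batch_size):
        idx = np.arange(start, min(start + batch_size, data.n_trials))
        u, inv = np.unique(data.stim_index[idx], return_inverse=True)
        outs.append(net.forward(emb[u], inv, cov[idx], training=False))
    return np.concatenate(outs, axis=0).astype(np.float64)


def predict(bundle: ModelBundle, data: TaskDataset) -> Tuple[np.ndarray, np.ndarray]:
    """Predictions in native units.

    Returns ``(settings, ratings)``: filter parameters inverse-scaled to
    their declared ranges (N x 13 or N x 17, in ``param_keys`` order) and
    ratings on the continuous 1-7 scale (N x 5).
    """
    y = predict_unit(bundle, data)
    k = bundle.n_params_out
    lo, hi = task_bounds(bundle.config.task)
    settings = lo + y[:, :k] * (hi - lo)
    ratings = denormalize_ratings(y[:, k:])
    return settings, ratings


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist weights + config + schema as one ``.npz`` archive."""
    meta = {
        "config": asdict(bundle.config),
        "output_schema": bundle.output_schema,
        "trained": bundle.trained,
        "cov_dim": bundle.net.cov_dim,
        "loss_trace": bundle.loss_trace,
        "format_version": 1,
    }
    arrays = bundle.net.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["dense_widths"] = tuple(cfg_dict["dense_widths"])
    config = ModelConfig(**cfg_dict)
    bundle = build_model(config, cov_dim=meta["cov_dim"])
    bundle.net.load_state_arrays(arrays)
    bundle.trained = meta["trained"]
    bundle.loss_trace = list(meta.get("loss_trace", []))
    return bundle
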