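"""Training and nested cross-validation.

The loss is amino-acid-level cross entropy: for one protein with one-hot
target ``y`` (96x3) and predicted probabilities ``h`` (96x3),

    Loss(y, h) = - sum_{i=1..96} sum_{j=1..3} y_ij * ln(h_ij)

with probabilities clipped to ``[1e-7, 1]`` before the logarithm.  Padded
positions carry class N and are included by default (the sum runs over all
96 positions); an optional mask excludes them.

Model evaluation uses nested cross-validation with k outer folds: for each
outer test partition, hyper-parameters are selected by a (k-1)-fold inner
cross-validation over the k-1 training partitions, the k-1 inner models of
the winning candidate are applied to the test partition, and their
probability matrices are arithmetically averaged before the sequence-level
decision rule.  The outer test partition never informs any selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import EncodedSample
from .metrics import ConfusionCounts, evaluate_counts, mcc, metric_report
from .network import Model, NetworkConfig, build_network, count_parameters
from .predict import DecisionConfig, call_signal_peptide

CLIP_LO = 1e-7


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (Adam on the mean per-protein loss)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    mask_padding: bool = False

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")


def loss(
    y: np.ndarray,
    h: np.ndarray,
    mask_padding: bool = False,
    n_real: int | None = None,
) -> float:
    """Cross entropy over all 96 positions of one protein.

    ``mask_padding`` with ``n_real`` restricts the sum to the first
    ``n_real`` (non-padding) positions.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    if y.shape != h.shape or y.ndim != 2 or y.shape[1] != 3:
        raise ValueError(f"expected matching (L, 3) matrices, got {y.shape} and {h.shape}")
    terms = -(y * np.log(np.clip(h, CLIP_LO, 1.0))).sum(axis=1)
    if mask_padding and n_real is not None:
        terms = terms[:n_real]
    return float(terms.sum())


def _stack(samples: Sequence[EncodedSample]):
    x = np.stack([s.x for s in samples])
    y = np.stack([s.y for s in samples])
    return x, y


def _pad_mask(samples: Sequence[EncodedSample], length: int) -> np.ndarray:
    """(n, length, 1) mask: 1 on real positions, 0 on padding."""
    mask = np.zeros((len(samples), length, 1))
    for i, s in enumerate(samples):
        mask[i, : s.n_real, 0] = 1.0
    return mask


def _batch_loss(y: np.ndarray, h: np.ndarray, mask: np.ndarray | None) -> float:
    """Mean over proteins of the 96-term cross-entropy sum."""
    terms = -(y * np.log(np.clip(h, CLIP_LO, 1.0))).sum(axis=2, keepdims=True)
    if mask is not None:
        terms = terms * mask
    return float(terms.sum() / y.shape[0])


def train_model(
    train: Sequence[EncodedSample],
    val: Sequence[EncodedSample],
    net_config: NetworkConfig,
    train_config: TrainConfig,
) -> tuple[Model, dict]:
    """Train a freshly initialised model, early-stopping on validation loss.

    Returns the model with the best-validation-epoch weights restored, and a
    history dict with per-epoch ``train_loss`` / ``val_loss``.  Fully
    reproducible for a fixed seed and thread count.
    """
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    if any(s.y is None for s in train) or any(s.y is None for s in val):
        raise ValueError("all samples must carry labels")

    from .nn import Adam  # local import to keep module load light

    rng = np.random.default_rng(train_config.seed)
    model = build_network(net_config, seed=int(rng.integers(2**31)))
    opt = Adam(model.parameters(), lr=train_config.learning_rate)

    xt, yt = _stack(train)
    xv, yv = _stack(val)
    mask_t = _pad_mask(train, xt.shape[1]) if train_config.mask_padding else None
    mask_v = _pad_mask(val, xv.shape[1]) if train_config.mask_padding else None

    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0
    B = train_config.batch_size

    for _epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(train), B):
            idx = order[start : start + B]
            xb, yb = xt[idx], yt[idx]
            probs = model.forward(xb)
            mb = mask_t[idx] if mask_t is not None else None
            epoch_loss += _batch_loss(yb, probs, mb) * len(idx)
            # gradient of mean-over-batch summed cross entropy w.r.t. logits
            dlogits = (probs - yb) / len(idx)
            if mb is not None:
                dlogits = dlogits * mb
            model.backward(dlogits)
            opt.step(model.gradients())
        history["train_loss"].append(epoch_loss / len(train))

        val_loss = _batch_loss(yv, model.forward(xv), mask_v)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_config.patience:
                break

    model.set_weights(best_weights)
    history["best_val_loss"] = best_val
    return model, history


@dataclass
class CVPlan:
    """Nested cross-validation plan: outer folds and the hyper-parameter grid."""

    k: int = 5
    hyper_grid: list[tuple[NetworkConfig, float]] = field(default_factory=list)
    selection_metric: str = "mcc"
    seed: int = 0
    window: int = 4

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.selection_metric != "mcc":
            raise ValueError("only 'mcc' selection is supported")


@dataclass
class FoldResult:
    fold: int
    test_ids: list[str]
    selected_config: NetworkConfig
    selected_threshold: float
    inner_scores: dict
    avg_probs: np.ndarray  # (n_test, 96, 3) ensemble-averaged
    calls: list[bool]
    scores: list[float]


@dataclass
class CVResult:
    folds: list[FoldResult]
    counts: ConfusionCounts
    report: dict


def _class_of(sample: EncodedSample) -> str:
    if sample.true_is_sp:
        return "sp"
    if sample.true_is_tm:
        return "tm"
    return "other"


def stratified_folds(
    samples: Sequence[EncodedSample], k: int, seed: int
) -> list[list[int]]:
    """Disjoint covering index partitions, stratified by protein-level class."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(_class_of(s), []).append(i)
    offset = 0
    for cls in sorted(by_class):
        idx = np.array(by_class[cls])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx)  # rotate so small classes spread over folds
    return folds


def _protein_mcc(
    probs: np.ndarray,
    samples: Sequence[EncodedSample],
    threshold: float,
    window: int,
) -> float:
    cfg = DecisionConfig(threshold=threshold, window=window)
    calls = [call_signal_peptide(p, cfg)[0] for p in probs]
    counts = evaluate_counts(
        [bool(s.true_is_sp) for s in samples],
        [bool(s.true_is_tm) for s in samples],
        calls,
    )
    return mcc(counts)


TrainFn = Callable[[Sequence[EncodedSample], Sequence[EncodedSample], NetworkConfig, TrainConfig], Model]


def _default_train_fn(train, val, net_config, train_config) -> Model:
    model, _ = train_model(train, val, net_config, train_config)
    return model


def nested_cv(
    samples: Sequence[EncodedSample],
    plan: CVPlan,
    train_config: TrainConfig,
    train_fn: TrainFn | None = None,
) -> CVResult:
    """Run the full nested cross-validation protocol.

    For each outer fold, the k-1 training partitions serve as the inner
    folds: every hyper-parameter candidate is scored by the mean
    inner-validation MCC over the k-1 inner splits (models are shared among
    candidates that differ only in threshold), and the k-1 models trained
    for the winning architecture are ensembled (probability matrices
    averaged) on the outer test partition.

    ``train_fn`` may replace the real trainer (e.g. with a stub) and must
    return an object with a ``predict(x_batch) -> (n, 96, 3)`` method.
    """
    if not plan.hyper_grid:
        raise ValueError("hyper_grid must not be empty")
    if len(samples) < plan.k:
        raise ValueError("need at least k samples")
    if train_fn is None:
        train_fn = _default_train_fn

    folds = stratified_folds(samples, plan.k, plan.seed)
    fold_results: list[FoldResult] = []

    for f in range(plan.k):
        test_idx = folds[f]
        train_parts = [folds[j] for j in range(plan.k) if j != f]
        test_ids = {samples[i].source_id for i in test_idx}

        # one model per (architecture, inner split); thresholds reuse them
        configs = []
        for cfg, _thr in plan.hyper_grid:
            if cfg not in configs:
                configs.append(cfg)
        models: dict[int, list[Model]] = {}
        val_probs: dict[int, list[np.ndarray]] = {}
        inner_vals: list[list[EncodedSample]] = []
        for j in range(len(train_parts)):
            val_idx = train_parts[j]
            tr_idx = [i for p, part in enumerate(train_parts) if p != j for i in part]
            train_ids = {samples[i].source_id for i in tr_idx}
            val_ids = {samples[i].source_id for i in val_idx}
            assert not (test_ids & train_ids) and not (test_ids & val_ids), (
                "outer test partition leaked into the inner loop"
            )
            tr = [samples[i] for i in tr_idx]
            va = [samples[i] for i in val_idx]
            inner_vals.append(va)
            xv = np.stack([s.x for s in va])
            for ci, cfg in enumerate(configs):
                mdl = train_fn(tr, va, cfg, train_config)
                models.setdefault(ci, []).append(mdl)
                val_probs.setdefault(ci, []).append(mdl.predict(xv))

        # candidate selection by mean inner-validation MCC
        inner_scores: dict = {}
        best = None  # (score, params, threshold, candidate)
        for cfg, thr in plan.hyper_grid:
            ci = configs.index(cfg)
            scores = [
                _protein_mcc(val_probs[ci][j], inner_vals[j], thr, plan.window)
                for j in range(len(train_parts))
            ]
            mean_score = float(np.mean(scores))
            inner_scores[(ci, thr)] = mean_score
            key = (-mean_score, count_parameters(cfg), thr)
            if best is None or key < best[0]:
                best = (key, cfg, thr, ci)
        _, sel_cfg, sel_thr, sel_ci = best

        x_test = np.stack([samples[i].x for i in test_idx])
        avg = np.mean([m.predict(x_test) for m in models[sel_ci]], axis=0)
        cfg_dec = DecisionConfig(threshold=sel_thr, window=plan.window)
        calls, scores = [], []
        for p in avg:
            is_sp, score = call_signal_peptide(p, cfg_dec)
            calls.append(is_sp)
            scores.append(score)
        fold_results.append(
            FoldResult(
                fold=f,
                test_ids=[samples[i].source_id for i in test_idx],
                selected_config=sel_cfg,
                selected_threshold=sel_thr,
                inner_scores=inner_scores,
                avg_probs=avg,
                calls=calls,
                scores=scores,
            )
        )

    all_sp, all_tm, all_calls = [], [], []
    for fr, f in zip(fold_results, range(plan.k)):
        for i, call in zip(folds[f], fr.calls):
            all_sp.append(bool(samples[i].true_is_sp))
            all_tm.append(bool(samples[i].true_is_tm))
            all_calls.append(call)
    counts = evaluate_counts(all_sp, all_tm, all_calls)
    return CVResult(folds=fold_results, counts=counts, report=metric_report(counts))
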