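"""From per-residue probabilities to calls.

The sequence-level rule: a protein is called a signal peptide when the
S-channel probability of four consecutive residues all exceed a threshold.
The reported score is therefore the max over all length-``window`` windows
of the within-window minimum S-probability, and the call is
``score > threshold`` (strict).  The threshold is a hyper-parameter tuned
by nested cross-validation; the window defaults to 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CLASSES, INPUT_LENGTH


@dataclass(frozen=True)
class DecisionConfig:
    threshold: float = 0.5
    window: int = 4
    statistic: str = "min"  # min | mean over the window

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if not 1 <= self.window <= INPUT_LENGTH:
            raise ValueError(f"window must lie in [1, {INPUT_LENGTH}]")
        if self.statistic not in ("min", "mean"):
            raise ValueError(f"unknown window statistic {self.statistic!r}")


@dataclass
class PredictionResult:
    probs: np.ndarray
    is_sp: bool
    score: float
    residue_labels: str
    sp_end: int | None
    source_id: str = ""


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError(f"expected an (L, 3) matrix, got {probs.shape}")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    return probs


def window_score(probs: np.ndarray, cfg: DecisionConfig) -> float:
    """Max over consecutive windows of the within-window min (or mean) S-probability."""
    s = probs[:, CLASSES.index("S")]
    w = cfg.window
    if w > len(s):
        raise ValueError("window longer than the sequence")
    windows = np.lib.stride_tricks.sliding_window_view(s, w)
    stat = windows.min(axis=1) if cfg.statistic == "min" else windows.mean(axis=1)
    return float(stat.max())


def call_signal_peptide(
    probs: np.ndarray, cfg: DecisionConfig
) -> tuple[bool, float]:
    """Sequence-level signal-peptide call: (is_sp, score)."""
    probs = _check_probs(probs)
    score = window_score(probs, cfg)
    return score > cfg.threshold, score


def segment(probs: np.ndarray) -> tuple[str, int | None]:
    """Per-residue argmax labels and the 1-based end of the leading S-run.

    Ties are broken by channel priority S > T > N (the channel order), so a
    perfectly uniform row is labelled S.  ``sp_end`` is None when the first
    position is not S.
    """
    probs = _check_probs(probs)
    idx = np.argmax(probs, axis=1)  # first max wins: S > T > N priority
    labels = "".join(CLASSES[i] for i in idx)
    if not labels.startswith("S"):
        return labels, None
    run = len(labels) - len(labels.lstrip("S"))
    return labels, run


def predict_result(
    probs: np.ndarray, cfg: DecisionConfig, source_id: str = ""
) -> PredictionResult:
    is_sp, score = call_signal_peptide(probs, cfg)
    labels, sp_end = segment(probs)
    return PredictionResult(
        probs=probs,
        is_sp=is_sp,
        score=score,
        residue_labels=labels,
        sp_end=sp_end,
        source_id=source_id,
    )
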