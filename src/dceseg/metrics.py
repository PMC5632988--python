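"""Segmentation evaluation: area overlap measure, corresponding ratio,
percent match, and aggregation over repeated experiments.

Given a predicted tumor mask A_R and a ground-truth mask A_G on the same
grid:

* AOM = |A_R ∩ A_G| / |A_R ∪ A_G|  (the Jaccard index);
* PM  = 100 * TP / GT              (voxel-level sensitivity);
* CR  = 100 * (TP - 0.5 * FP) / GT (overlap penalized by false positives),

with TP = |A_R ∩ A_G|, FP = |A_R \\ A_G|, GT = |A_G|.  CR may be negative and
is reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalResult", "aom", "cr_pm", "aggregate"]


@dataclass(frozen=True)
class EvalResult:
    """Voxel counts and derived scores for one segmentation vs ground truth."""

    tp: int
    fp: int
    gt: int
    aom: float
    cr: float
    pm: float


def _as_bool(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        arr = arr.astype(bool)
    return arr


def _check_pair(result: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r, t = _as_bool(result), _as_bool(truth)
    if r.shape != t.shape:
        raise ValueError(f"mask grids differ: {r.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("ground-truth mask is empty")
    return r, t


def aom(result: np.ndarray, truth: np.ndarray) -> float:
    """Area overlap measure (Jaccard index) of two binary masks."""
    r, t = _check_pair(result, truth)
    inter = np.count_nonzero(r & t)
    union = np.count_nonzero(r | t)
    return inter / union


def cr_pm(result: np.ndarray, truth: np.ndarray) -> EvalResult:
    """TP/FP/GT counts with AOM, CR and PM for one mask pair."""
    r, t = _check_pair(result, truth)
    tp = int(np.count_nonzero(r & t))
    fp = int(np.count_nonzero(r & ~t))
    gt = int(np.count_nonzero(t))
    union = np.count_nonzero(r | t)
    return EvalResult(
        tp=tp,
        fp=fp,
        gt=gt,
        aom=tp / union,
        cr=100.0 * (tp - 0.5 * fp) / gt,
        pm=100.0 * tp / gt,
    )


def aggregate(repeats) -> dict:
    """Summarize AOM/CR/PM over repeated train/test runs.

    Parameters
    ----------
    repeats
        List of repeats, each a list of per-sample :class:`EvalResult`.

    Returns
    -------
    dict
        For each of ``aom``, ``cr``, ``pm``: per-repeat means, the mean and
        SD (ddof=1 across repeats; 0 with a single repeat) and a 2-decimal
        ``"mean ± sd"`` string.
    """
    repeats = [list(r) for r in repeats]
    if not repeats or any(len(r) == 0 for r in repeats):
        raise ValueError("aggregate requires nonempty repeats")
    out: dict = {"n_repeats": len(repeats)}
    for key in ("aom", "cr", "pm"):
        per_repeat = [float(np.mean([getattr(e, key) for e in rep])) for rep in repeats]
        mean = float(np.mean(per_repeat))
        sd = float(np.std(per_repeat, ddof=1)) if len(per_repeat) > 1 else 0.0
        out[key] = {
            "per_repeat": per_repeat,
            "mean": mean,
            "sd": sd,
            "formatted": f"{mean:.2f} ± {sd:.2f}",
        }
    return out
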