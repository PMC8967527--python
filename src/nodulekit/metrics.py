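"""Segmentation and recognition evaluation metrics.

Segmentation quality between a reference mask Eg (expert outline) and an
algorithm mask Es is summarised by four percentages:

    Md = |Eg ∩ Es| / |Eg ∪ Es| · 100        (Jaccard overlap)
    Vd = |Es ⊕ Eg| / |Es| · 100             (mismatch relative to Es)
    Ud = |Eg ⊕ Es| / |Eg| · 100             (mismatch relative to Eg)
    CM = (Md + (100 − Vd) + (100 − Ud)) / 3 (combined measure)

⊕ is voxelwise XOR. Md and CM increase with quality, Vd and Ud decrease;
Vd/Ud can exceed 100 for gross mismatches and are deliberately not
clamped. Recognition quality uses sensitivity, specificity and the
misclassified fraction FPF = (FP + FN) / total, all in percent, plus ROC
curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SegScores:
    md: float
    vd: float
    ud: float
    cm: float

    def as_dict(self) -> dict[str, float]:
        return {"Md": self.md, "Vd": self.vd, "Ud": self.ud, "CM": self.cm}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def seg_scores(eg: np.ndarray, es: np.ndarray) -> SegScores:
    """Md/Vd/Ud/CM between reference mask ``eg`` and predicted ``es``."""
    eg = np.asarray(eg, bool)
    es = np.asarray(es, bool)
    if eg.shape != es.shape:
        raise ValueError(f"mask shapes differ: {eg.shape} vs {es.shape}")
    n_eg = int(eg.sum())
    n_es = int(es.sum())
    if n_eg == 0:
        raise ValueError("reference mask Eg is empty; Md and Ud are undefined")
    if n_es == 0:
        raise ValueError("predicted mask Es is empty; Vd is undefined")
    inter = int((eg & es).sum())
    union = n_eg + n_es - inter
    xor = union - inter
    md = 100.0 * inter / union
    vd = 100.0 * xor / n_es
    ud = 100.0 * xor / n_eg
    cm = (md + (100.0 - vd) + (100.0 - ud)) / 3.0
    return SegScores(md, vd, ud, cm)


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1.0) -> float:
    """Dice loss 1 − 2Σpg/(Σp² + Σg² + ε) for probabilities p, binary g."""
    p = np.asarray(p, np.float64)
    g = np.asarray(g, np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(1.0 - 2.0 * (p * g).sum() / ((p**2).sum() + (g**2).sum() + eps))


def recognition_scores(c: ConfusionCounts) -> tuple[float, float, float]:
    """(SEN, SPE, FPF) in percent from a confusion table.

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), FPF = (FP+FN)/total — the last
    is a misclassification rate and equals 100 − accuracy.
    """
    if c.tp + c.fn == 0:
        raise ValueError("SEN undefined: no positive samples (TP+FN=0)")
    if c.tn + c.fp == 0:
        raise ValueError("SPE undefined: no negative samples (TN+FP=0)")
    sen = 100.0 * c.tp / (c.tp + c.fn)
    spe = 100.0 * c.tn / (c.tn + c.fp)
    fpf = 100.0 * (c.fp + c.fn) / c.total
    return sen, spe, fpf


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    """ROC points (monotone from (0,0) to (1,1)) and trapezoidal area."""
    from sklearn import metrics as skm

    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("ROC requires both classes present in labels")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    return RocCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


def plot_roc(curve: RocCurve, path: str) -> None:  # pragma: no cover - viz
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
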