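"""Partner-prediction performance against a gold standard of native pairs.

Instances are protein pairs scored by NII; positives are the native
(benchmark) pairs, negatives all other unmasked pairs.  The default
convention evaluates unordered pairs with the symmetrised score
max(NII[i, j], NII[j, i]); ordered evaluation treats each direction as
its own instance.  ROC AUC uses the rank statistic (ties counted half);
threshold metrics are sensitivity, specificity, precision, balanced
F-score and Matthews correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass
class GoldStandard:
    """Native pairs of a benchmark plus the protein universe."""

    native_pairs: set[frozenset]
    universe: set[str]
    excluded: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.native_pairs = {frozenset(p) for p in self.native_pairs}
        self.excluded = {frozenset(p) for p in self.excluded}
        for p in self.native_pairs:
            if not p <= self.universe:
                raise ValueError(f"native pair {set(p)} outside universe")

    def is_native(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.native_pairs


def _pair_instances(nii: pd.DataFrame, gold: GoldStandard,
                    ordered: bool) -> tuple[np.ndarray, np.ndarray]:
    proteins = [p for p in nii.index if p in gold.universe]
    pos = {p: i for i, p in enumerate(proteins)}
    m = nii.loc[proteins, proteins].to_numpy(dtype=float)
    n = len(proteins)
    native = np.zeros((n, n), dtype=bool)
    for pair in gold.native_pairs:
        a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
        if a in pos and b in pos:
            native[pos[a], pos[b]] = native[pos[b], pos[a]] = True
    excl = np.zeros((n, n), dtype=bool)
    for pair in gold.excluded:
        ab = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
        if ab[0] in pos and ab[-1] in pos:
            excl[pos[ab[0]], pos[ab[-1]]] = excl[pos[ab[-1]], pos[ab[0]]] = True
    if ordered:
        keep = ~np.eye(n, dtype=bool) & ~excl & ~np.isnan(m)
        return m[keep], native[keep]
    sym = np.fmax(m, m.T)
    iu = np.triu_indices(n, k=1)
    scores, labels = sym[iu], native[iu]
    keep = ~excl[iu] & ~np.isnan(scores)
    return scores[keep], labels[keep]


def roc_auc(nii: pd.DataFrame, gold: GoldStandard,
            ordered: bool = False) -> float:
    """Area under the ROC curve of NII-ranked partner prediction."""
    scores, labels = _pair_instances(nii, gold, ordered)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one positive and one negative pair")
    return float(roc_auc_score(labels, scores))


def metrics_at(nii: pd.DataFrame, gold: GoldStandard, threshold: float,
               ordered: bool = False) -> dict[str, float]:
    """Confusion-matrix metrics at a NII operating point.

    Predicted-positive means NII >= threshold.  MCC is reported as 0 when
    a denominator factor vanishes.
    """
    scores, labels = _pair_instances(nii, gold, ordered)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sen, "specificity": spe, "ppv": ppv,
            "f_score": f, "mcc": float(mcc)}


def metrics_report(metrics: dict[str, float]) -> str:
    """Formatted text block with the five standard performance measures."""
    lines = ["metric\tvalue"]
    for k in ("sensitivity", "specificity", "ppv", "f_score", "mcc"):
        lines.append(f"{k}\t{metrics[k]:.3f}")
    return "\n".join(lines)
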