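"""Evaluation metrics and statistical summaries of transfer results.

Accuracy and macro-F1 score the classifier; Cohen's kappa quantifies
chance-corrected inter-annotator agreement; the standardized correlation
relates structural (Tanimoto) similarity to cross-drug transfer F1; and
pair categorization buckets ordered (train drug, test drug) pairs by
therapeutic grouping and similarity band for downstream plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, f1_score

from .chem import DrugRecord, SimilarityMatrix
from .corpus import LABELS

#: similarity-band thresholds: pairs above HIGH count as structurally
#: similar, pairs below LOW as structurally dissimilar
HIGH_SIMILARITY = 0.15
LOW_SIMILARITY = 0.03

#: therapeutic classes pooled into the psychoactive pair type
_PSYCHO_CLASSES = {"hypnotic_anxiolytic", "antipsychotic"}


def accuracy(true: Sequence[str], pred: Sequence[str]) -> float:
    """Fraction of exact label matches."""
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} vs {len(pred)}")
    if len(true) == 0:
        raise ValueError("empty label sequences")
    return float(np.mean([t == p for t, p in zip(true, pred)]))


def macro_f1(
    true: Sequence[str], pred: Sequence[str], label_set: Sequence[str] = LABELS
) -> float:
    """Unweighted mean of per-class F1 over ``label_set``.

    A class of ``label_set`` absent from both ``true`` and ``pred`` is
    excluded from the mean; a class that occurs but has no true or predicted
    positives on the other side contributes F1 = 0.
    """
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} vs {len(pred)}")
    if len(true) == 0:
        raise ValueError("empty label sequences")
    present = set(true) | set(pred)
    labels = [l for l in label_set if l in present]
    if not labels:
        raise ValueError("no label of label_set occurs in true or pred")
    return float(
        f1_score(list(true), list(pred), labels=labels, average="macro", zero_division=0)
    )


def cohen_kappa(ann1: Sequence[str], ann2: Sequence[str]) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) between two annotators."""
    if len(ann1) != len(ann2):
        raise ValueError(f"length mismatch: {len(ann1)} vs {len(ann2)}")
    if len(ann1) == 0:
        raise ValueError("empty annotation sequences")
    # degenerate case p_e = 1: both annotators constant with the same value;
    # perfect observed agreement is scored 1.0
    if len(set(ann1)) == 1 and len(set(ann2)) == 1:
        return 1.0 if ann1[0] == ann2[0] else 0.0
    return float(cohen_kappa_score(list(ann1), list(ann2)))


def standardized_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p after z-scoring both vectors.

    Both axes are standardized to mean 0 and (population) variance 1, as for
    a standardized scatter; Pearson r is invariant to this affine rescaling,
    which is asserted.  The p-value comes from the exact t/beta reference
    distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sx, sy = x.std(), y.std()  # population (ddof=0) standard deviations
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    r, p = sps.pearsonr(zx, zy)
    r_raw, _ = sps.pearsonr(x, y)
    assert abs(r - r_raw) < 1e-12, "standardization must not change r"
    return float(r), float(p)


@dataclass(frozen=True)
class PairRecord:
    """One ordered (train drug, test drug) pair with its similarity and F1."""

    drug_a: str
    drug_b: str
    tanimoto: float
    f1: float
    pair_type: str  # OTC_rel | antipsycho | other
    similarity_band: str  # high (> HIGH_SIMILARITY) | low (< LOW_SIMILARITY) | mid

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError("pair must join two distinct drugs")
        if not (0.0 <= self.tanimoto <= 1.0 and 0.0 <= self.f1 <= 1.0):
            raise ValueError("tanimoto and f1 must lie in [0, 1]")


def _pair_type(a: DrugRecord, b: DrugRecord) -> str:
    if a.otc_flag or b.otc_flag:
        return "OTC_rel"
    if a.therapeutic_class in _PSYCHO_CLASSES and b.therapeutic_class in _PSYCHO_CLASSES:
        return "antipsycho"
    return "other"


def _band(t: float) -> str:
    if t > HIGH_SIMILARITY:
        return "high"
    if t < LOW_SIMILARITY:
        return "low"
    return "mid"


def categorize_pairs(
    transfer_matrix, simmat: SimilarityMatrix, panel: Sequence[DrugRecord]
) -> list[PairRecord]:
    """One PairRecord per ordered (train, test) pair of distinct drugs."""
    names = tuple(r.query_name for r in panel)
    if tuple(transfer_matrix.drug_order) != names or simmat.drug_order != names:
        raise ValueError("transfer matrix, similarity matrix and panel must share drug order")
    by_name = {r.query_name: r for r in panel}
    out = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            t = float(simmat.values[i, j])
            out.append(
                PairRecord(
                    drug_a=a,
                    drug_b=b,
                    tanimoto=t,
                    f1=float(transfer_matrix.f1[i, j]),
                    pair_type=_pair_type(by_name[a], by_name[b]),
                    similarity_band=_band(t),
                )
            )
    return out


def pairs_to_csv(pairs: Sequence[PairRecord], path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_a", "drug_b", "tanimoto", "f1", "pair_type", "similarity_band"])
        for p in pairs:
            w.writerow([p.drug_a, p.drug_b, p.tanimoto, p.f1, p.pair_type, p.similarity_band])
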