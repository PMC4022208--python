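"""Scoring of detection results against a synthetic panel's ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import TyElement
from .synthetic import TruthRecord

HYBRID_CATEGORIES = ("full_hybrid", "short_hybrid")


def effective_category(element: TyElement) -> str:
    """Detected category with hybrid status folded in (a full element flagged
    full_hybrid is compared against a planted full_hybrid truth record)."""
    if element.category == "full" and element.hybrid_status in HYBRID_CATEGORIES:
        return element.hybrid_status
    return element.category


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class RecoveryScore:
    per_category: pd.DataFrame  # tp / fn / fp / precision / recall / f1
    matches: pd.DataFrame  # one row per truth record
    family_accuracy: float  # Ty1-vs-Ty2 assignment among matched coding elements

    @property
    def precision(self) -> float:
        tp = self.per_category["tp"].sum()
        fp = self.per_category["fp"].sum()
        return tp / (tp + fp) if tp + fp else 0.0

    @property
    def recall(self) -> float:
        tp = self.per_category["tp"].sum()
        fn = self.per_category["fn"].sum()
        return tp / (tp + fn) if tp + fn else 0.0

    @property
    def mean_f1(self) -> float:
        f1 = self.per_category["f1"]
        return float(f1.mean()) if len(f1) else 0.0


def score_recovery(
    truth: list[TruthRecord],
    elements: list[TyElement],
    min_overlap: float = 0.5,
) -> RecoveryScore:
    """One-to-one matching of truth records to detected elements.

    A truth record is recovered when a detected element on the same contig
    overlaps at least ``min_overlap`` of the truth interval, carries the
    same effective category, and (for non-hybrid categories) the same
    family.  Hybrids are matched on hybrid status alone because best-score
    family assignment of a recombinant is family-ambiguous by construction.
    """
    unmatched = list(range(len(elements)))
    rows = []
    family_ok = 0
    family_total = 0
    for t in truth:
        best_idx = None
        best_ov = 0
        for idx in unmatched:
            el = elements[idx]
            if el.strain != t.strain or el.contig != t.contig:
                continue
            ov = _overlap(t.interval, el.interval)
            if ov < min_overlap * (t.end - t.start):
                continue
            if ov > best_ov:
                best_ov = ov
                best_idx = idx
        matched = False
        det_cat = det_fam = ""
        if best_idx is not None:
            el = elements[best_idx]
            det_cat = effective_category(el)
            det_fam = el.family
            cat_ok = det_cat == t.category
            fam_ok = t.category in HYBRID_CATEGORIES or el.family == t.family
            if cat_ok and fam_ok:
                matched = True
                unmatched.remove(best_idx)
                if t.category == "full" and t.family in ("Ty1", "Ty2"):
                    family_total += 1
                    if el.family == t.family:
                        family_ok += 1
        rows.append(
            dict(
                locus_id=t.locus_id, strain=t.strain, category=t.category,
                family=t.family, matched=matched, detected_category=det_cat,
                detected_family=det_fam,
            )
        )
    matches = pd.DataFrame(rows)
    categories = sorted({t.category for t in truth} | {effective_category(elements[i]) for i in unmatched})
    per_cat = []
    for cat in categories:
        tp = int(((matches["category"] == cat) & matches["matched"]).sum())
        fn = int(((matches["category"] == cat) & ~matches["matched"]).sum())
        fp = sum(1 for i in unmatched if effective_category(elements[i]) == cat)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_cat.append(dict(category=cat, tp=tp, fn=fn, fp=fp, precision=prec, recall=rec, f1=f1))
    per_category = pd.DataFrame(per_cat).set_index("category")
    fam_acc = family_ok / family_total if family_total else 1.0
    return RecoveryScore(per_category=per_category, matches=matches, family_accuracy=fam_acc)


def locus_truth_labels(mapped, loci_table: pd.DataFrame, tol: int = 60) -> list[str]:
    """Truth locus_id for each mapped insertion, by nearest planted junction.

    ``loci_table`` is the generator's locus table (reference coordinates).
    Insertions farther than ``tol`` from every planted junction get a
    sentinel label of their own.
    """
    positions = loci_table["position"].to_numpy()
    ids = loci_table["locus_id"].to_numpy()
    labels = []
    for k, m in enumerate(mapped):
        deltas = abs(positions - m.position)
        best = int(deltas.argmin())
        labels.append(str(ids[best]) if deltas[best] <= tol else f"__orphan{k}__")
    return labels


def rand_index(labels_a: list, labels_b: list) -> float:
    """Plain Rand index between two partitions given as parallel label lists."""
    if len(labels_a) != len(labels_b):
        raise ValueError("partitions must label the same items")
    n = len(labels_a)
    if n < 2:
        return 1.0
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            agree += same_a == same_b
            total += 1
    return agree / total
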