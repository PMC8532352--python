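"""Benchmark evaluation under the gene-hit counting rule.

A truth variant counts as detected when any call's gene set intersects the
variant's gene set — either partner suffices for fusions, and the call's
class label is ignored for recall. Classification consistency is computed
separately, over calls located inside simulated variant genes, as the
fraction whose class belongs to the truth record's plausible class set.
False positives are split into calls hitting background (unaltered) genes
and calls outside every simulated gene; contigs that hit a truth gene do
not contribute false positives via their remaining calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Set

from .annotate import VariantCall
from .genome import AnnotationIndex
from .simulate import VariantTruth


@dataclass
class EvaluationReport:
    per_type_recall: Dict[str, float]
    per_type_detected: Dict[str, int]
    per_type_total: Dict[str, int]
    overall_recall: float
    category_recall: Dict[str, float]
    n_detected: int
    n_truth: int
    fp_background: int
    fp_outside: int
    classification_consistency: float
    n_consistent_calls: int
    n_in_gene_calls: int


def evaluate(
    calls: Sequence[VariantCall],
    truth: Sequence[VariantTruth],
    index: AnnotationIndex,
    background_genes: Sequence[str] = (),
) -> EvaluationReport:
    known_genes = set(index.gene_extents)
    gene_to_truth: Dict[str, VariantTruth] = {}
    for t in truth:
        for g in t.genes:
            gene_to_truth[g] = t
    unknown = sorted(
        {g for t in truth for g in t.genes if g not in known_genes}
    )
    for c in calls:
        unknown.extend(g for g in c.genes if g not in known_genes and g != "intergenic")
    if unknown:
        raise ValueError(f"gene ids absent from annotation: {sorted(set(unknown))}")

    background = set(background_genes)
    detected: Set[str] = set()
    consistent = 0
    in_gene_calls = 0
    fp_background = 0
    fp_outside = 0
    # a contig hitting any truth gene is a true-positive contig; its other
    # calls are not counted as false positives
    tp_contigs = {
        c.contig_id
        for c in calls
        if any(g in gene_to_truth for g in c.genes)
    }
    for c in calls:
        hit = [g for g in c.genes if g in gene_to_truth]
        if hit:
            t = gene_to_truth[hit[0]]
            detected.add(t.variant_id)
            in_gene_calls += 1
            if c.vclass.value in t.expected_classes:
                consistent += 1
        elif c.contig_id not in tp_contigs:
            if any(g in background for g in c.genes):
                fp_background += 1
            else:
                fp_outside += 1

    per_type_total: Dict[str, int] = {}
    per_type_detected: Dict[str, int] = {}
    cat_total: Dict[str, int] = {}
    cat_detected: Dict[str, int] = {}
    for t in truth:
        key = t.vtype.value
        per_type_total[key] = per_type_total.get(key, 0) + 1
        ck = t.vtype.category.value
        cat_total[ck] = cat_total.get(ck, 0) + 1
        if t.variant_id in detected:
            per_type_detected[key] = per_type_detected.get(key, 0) + 1
            cat_detected[ck] = cat_detected.get(ck, 0) + 1

    per_type_recall = {
        k: per_type_detected.get(k, 0) / n for k, n in per_type_total.items()
    }
    category_recall = {
        k: cat_detected.get(k, 0) / n for k, n in cat_total.items()
    }
    n_truth = len(truth)
    return EvaluationReport(
        per_type_recall=per_type_recall,
        per_type_detected={k: per_type_detected.get(k, 0) for k in per_type_total},
        per_type_total=per_type_total,
        overall_recall=(len(detected) / n_truth) if n_truth else 0.0,
        category_recall=category_recall,
        n_detected=len(detected),
        n_truth=n_truth,
        fp_background=fp_background,
        fp_outside=fp_outside,
        classification_consistency=(consistent / in_gene_calls) if in_gene_calls else 0.0,
        n_consistent_calls=consistent,
        n_in_gene_calls=in_gene_calls,
    )
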