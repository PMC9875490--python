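"""End-to-end convenience wrappers over the module-level API.

`analyze_pair` drives the full two-condition analysis on simulated (or
externally loaded) bundles: merged-peak differential tests, compartment
calls and switch classification, candidate-element construction, ABC
predictions per condition, and the link-level comparison that the
counterfactual decomposition consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import abc_model, annotation, compartments, decomposition, differential
from .genome_model import ContactMatrix, Gene, GenomicInterval, Peak
from .synthetic import ConditionBundle

__all__ = [
    "merge_replicates",
    "peak_count_table",
    "merge_peak_counts",
    "analyze_pair",
    "PairAnalysis",
    "match_elements_to_truth",
    "planted_link_sets",
    "link_recovery",
]


def merge_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Sum replicate contact matrices into one per-condition matrix."""
    total = matrices[0].matrix.copy()
    for m in matrices[1:]:
        total = total + m.matrix
    return ContactMatrix(
        matrices[0].chrom, matrices[0].resolution, matrices[0].n_bins, total
    )


def peak_count_table(
    peaks_c1: list[Peak], peaks_c2: list[Peak]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Feature x sample count table over the shared (merged) peak universe.

    Both conditions must carry peaks with identical ids (the merged list);
    sample columns are prefixed with the condition.
    """
    ids1 = [p.peak_id for p in peaks_c1]
    ids2 = [p.peak_id for p in peaks_c2]
    if ids1 != ids2:
        raise ValueError("peak universes differ between conditions; merge first")
    data: dict[str, list[float]] = {}
    cond_of: dict[str, str] = {}
    for cond, peaks in (("c1", peaks_c1), ("c2", peaks_c2)):
        sample_names = sorted({s for p in peaks for s in p.counts})
        for s in sample_names:
            col = f"{cond}_{s}"
            data[col] = [p.counts.get(s, 0.0) for p in peaks]
            cond_of[col] = cond
    return pd.DataFrame(data, index=ids1), cond_of


# backwards-friendly alias
merge_peak_counts = peak_count_table


def match_elements_to_truth(elements, element_truth: pd.DataFrame) -> dict[str, str]:
    """Map planted element ids to candidate element ids by best overlap.

    Candidate regions can shift by a few bp when neighbouring peaks merge,
    so matching is by largest interval overlap rather than exact
    coordinates. Planted elements with no overlapping candidate are absent
    from the map.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end, el.element_id
        )
    out: dict[str, str] = {}
    for r in element_truth.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        best, best_ov = None, 0
        for h in tree.overlap(r.start, r.end):
            ov = min(h.end, r.end) - max(h.begin, r.start)
            if ov > best_ov:
                best, best_ov = h.data, ov
        if best is not None:
            out[r.element_id] = best
    return out


def planted_link_sets(
    truth, elements
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Planted active (element_id, gene_id) links per condition.

    Planted element ids are translated to candidate element ids via
    ``match_elements_to_truth``.
    """
    mapping = match_elements_to_truth(elements, truth.element_truth)
    out = []
    for cond in (0, 1):
        links = set()
        for eid, gid in truth.planted_links(cond):
            if eid in mapping:
                links.add((mapping[eid], gid))
        out.append(links)
    return out[0], out[1]


def link_recovery(
    predictions: pd.DataFrame, planted: set[tuple[str, str]]
) -> dict[str, float]:
    """Precision/recall/F1 of predicted element-gene links vs planted truth."""
    pred = set(zip(
        predictions.element_id[predictions.predicted],
        predictions.gene_id[predictions.predicted],
    ))
    tp = len(pred & planted)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0 else 0.0
    )
    return dict(precision=precision, recall=recall, f1=f1,
                n_predicted=len(pred), n_planted=len(planted))


@dataclass
class PairAnalysis:
    """All intermediate and final tables of one two-condition analysis."""

    genes: list[Gene]
    gene_de: pd.DataFrame
    de_labels: dict[str, str]
    de_labels_fdr_only: dict[str, str]
    compartment_calls: pd.DataFrame
    elements: list
    fits: dict[str, abc_model.PowerlawFit]
    matrices: dict[str, ContactMatrix]
    predictions: dict[str, pd.DataFrame]
    links: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_pair(
    bundle1: ConditionBundle,
    bundle2: ConditionBundle,
    threshold: float = abc_model.DEFAULT_THRESHOLD,
    max_distance: float = abc_model.DEFAULT_MAX_DISTANCE,
    de_only_links: bool = True,
) -> PairAnalysis:
    """Run the full two-condition analysis on a pair of bundles."""
    genes = bundle1.genes

    # --- expression differential -----------------------------------------
    counts = pd.concat(
        [bundle1.gene_counts.add_prefix("c1_"), bundle2.gene_counts.add_prefix("c2_")],
        axis=1,
    )
    cond_of = {c: c.split("_")[0] for c in counts.columns}
    gene_de = differential.nb_differential(counts.round().astype(int), cond_of)
    strict = differential.classify_de(gene_de)
    de_labels = dict(zip(gene_de.feature_id, strict))
    # DE with FDR only (no fold-change cutoff), the link-level convention
    fdr_only = differential.classify_de(gene_de, lfc=0.0)
    de_labels_fdr_only = dict(zip(gene_de.feature_id, fdr_only))

    # --- compartments ------------------------------------------------------
    res = bundle1.contacts_compartment[0].resolution
    n_bins = bundle1.contacts_compartment[0].n_bins
    track = compartments.orientation_from_peaks(
        bundle1.atac_peaks + bundle2.atac_peaks, n_bins, res
    )
    pc1_c1 = compartments.call_compartments(bundle1.contacts_compartment, track)
    pc1_c2 = compartments.call_compartments(bundle2.contacts_compartment, track)
    calls = compartments.classify_switching(
        pc1_c1, pc1_c2, chrom=bundle1.contacts_compartment[0].chrom, resolution=res
    )

    # --- candidate elements and ABC ---------------------------------------
    elements = abc_model.make_candidate_regions(
        bundle1.atac_peaks, genes, n_strongest=150_000
    )
    abc_model.quantify_elements(
        elements,
        atac_by_condition={"c1": bundle1.atac_peaks, "c2": bundle2.atac_peaks},
        k27_by_condition={"c1": bundle1.k27_peaks, "c2": bundle2.k27_peaks},
    )
    matrices = {
        "c1": merge_replicates(bundle1.contacts_abc),
        "c2": merge_replicates(bundle2.contacts_abc),
    }
    fits = {c: abc_model.fit_powerlaw(m) for c, m in matrices.items()}
    predictions = {
        c: abc_model.predict_enhancers(
            elements, c, genes, fits[c], matrices[c],
            threshold=threshold, max_distance=max_distance,
        )
        for c in ("c1", "c2")
    }

    element_classes = annotation.assign_compartment(
        [e.interval for e in elements], calls,
        [e.element_id for e in elements],
    )
    switch_of_element = dict(zip(element_classes.feature_id,
                                 element_classes.switch_class))
    links = decomposition.classify_links(
        predictions["c1"], predictions["c2"],
        de_labels=de_labels_fdr_only, de_only=de_only_links,
        element_switch_class=switch_of_element,
    )

    return PairAnalysis(
        genes=genes,
        gene_de=gene_de,
        de_labels=de_labels,
        de_labels_fdr_only=de_labels_fdr_only,
        compartment_calls=calls,
        elements=elements,
        fits=fits,
        matrices=matrices,
        predictions=predictions,
        links=links,
    )
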