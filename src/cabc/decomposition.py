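"""Counterfactual Activity/Contact decomposition of enhancer rewiring.

Enhancer-promoter links are compared between two conditions and classified
as gained (predicted only in condition 2), lost (only in condition 1) or
shared. To attribute rewiring to its drivers, predictions are recomputed
with Activity taken wholly from one condition and Contact (the Hi-C matrix
together with its power-law fit) wholly from the other:

* constant Activity: condition-1 Activity with condition-2 Contact. Links
  still gained or lost under this assumption are contact-driven.
* constant Contact: condition-2 Activity with condition-1 Contact. Links
  still gained or lost are activity-driven.

The retained fraction (counterfactual differential links over baseline
differential links) quantifies each driver's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abc_model import (
    DEFAULT_MAX_DISTANCE,
    DEFAULT_THRESHOLD,
    CandidateElement,
    ContactMatrix,
    PowerlawFit,
    predict_enhancers,
)
from .genome_model import Gene

__all__ = [
    "counterfactual_predictions",
    "classify_links",
    "run_decomposition",
    "net_enhancer_change",
    "zero_activity_fraction",
    "activity_contact_scatter_data",
    "CounterfactualResult",
]


@dataclass(frozen=True)
class CounterfactualResult:
    """Gained/lost/shared link counts under one counterfactual assumption."""

    assumption: str
    n_gained: int
    n_lost: int
    n_shared: int
    baseline_gained: int
    baseline_lost: int

    @property
    def retained_fraction(self) -> float:
        base = self.baseline_gained + self.baseline_lost
        if base == 0:
            return float("nan")
        return (self.n_gained + self.n_lost) / base


def counterfactual_predictions(
    elements: Sequence[CandidateElement],
    genes: Sequence[Gene],
    activity_condition: str,
    contact_matrix: ContactMatrix,
    contact_fit: PowerlawFit,
    threshold: float = DEFAULT_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    gene_mask: Sequence[str] | None = None,
    qnorm_reference: np.ndarray | None = None,
) -> pd.DataFrame:
    """ABC predictions mixing one condition's Activity with another's Contact.

    With the activity and contact sources from the same condition this is
    exactly the baseline run for that condition.
    """
    return predict_enhancers(
        elements, activity_condition, genes, contact_fit, contact_matrix,
        threshold=threshold, max_distance=max_distance,
        gene_mask=gene_mask, qnorm_reference=qnorm_reference,
    )


def _link_set(predictions: pd.DataFrame) -> set[tuple[str, str]]:
    pred = predictions[predictions.predicted]
    return set(zip(pred.element_id, pred.gene_id))


def classify_links(
    pred_c1: pd.DataFrame,
    pred_c2: pd.DataFrame,
    de_labels: Mapping[str, str] | None = None,
    de_only: bool = True,
    element_switch_class: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Gained/lost/shared status of every predicted element-gene link.

    The statuses partition the union of the two predicted link sets. With
    ``de_only`` the table is restricted to links whose gene is in the
    up/down DE set (FDR-based, no fold-change cutoff by convention).
    Activities and contacts from both runs are carried along for the
    scatter and zero-Activity summaries.
    """
    l1 = _link_set(pred_c1)
    l2 = _link_set(pred_c2)
    union = l1 | l2

    def lookup(pred: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
        return {
            (r.element_id, r.gene_id): (r.activity, r.contact)
            for r in pred.itertuples()
        }

    d1, d2 = lookup(pred_c1), lookup(pred_c2)
    rows = []
    for key in sorted(union):
        eid, gid = key
        in1, in2 = key in l1, key in l2
        status = "shared" if (in1 and in2) else ("lost" if in1 else "gained")
        if de_only and de_labels is not None:
            if de_labels.get(gid, "NDE") not in {"up", "down"}:
                continue
        a1, c1 = d1.get(key, (0.0, float("nan")))
        a2, c2 = d2.get(key, (0.0, float("nan")))
        rows.append(dict(
            element_id=eid, gene_id=gid, status=status,
            activity_c1=a1, activity_c2=a2,
            contact_c1=c1, contact_c2=c2,
            switch_class=(element_switch_class or {}).get(eid, "unassigned"),
            gene_de_label=(de_labels or {}).get(gid, "NDE"),
        ))
    return pd.DataFrame(rows, columns=[
        "element_id", "gene_id", "status", "activity_c1", "activity_c2",
        "contact_c1", "contact_c2", "switch_class", "gene_de_label",
    ])


def _count_changes(links: pd.DataFrame) -> tuple[int, int, int]:
    vc = links.status.value_counts()
    return int(vc.get("gained", 0)), int(vc.get("lost", 0)), int(vc.get("shared", 0))


def run_decomposition(
    baseline_c1: pd.DataFrame,
    baseline_c2: pd.DataFrame,
    elements: Sequence[CandidateElement],
    genes: Sequence[Gene],
    matrices: Mapping[str, ContactMatrix],
    fits: Mapping[str, PowerlawFit],
    de_labels: Mapping[str, str] | None = None,
    de_only: bool = True,
    conditions: tuple[str, str] = ("c1", "c2"),
    threshold: float = DEFAULT_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    qnorm_reference: np.ndarray | None = None,
) -> dict[str, CounterfactualResult]:
    """Both counterfactuals against the baseline condition-1 predictions.

    constant_activity: condition-1 Activity + condition-2 Contact (what
    contact changes alone would rewire); constant_contact: condition-2
    Activity + condition-1 Contact (what activity changes alone would
    rewire). Each is compared with baseline condition 1, and its
    gained+lost count is reported relative to the baseline c1-vs-c2
    differential.
    """
    c1, c2 = conditions
    base_links = classify_links(baseline_c1, baseline_c2, de_labels, de_only)
    bg, bl, _ = _count_changes(base_links)

    results = {}
    specs = {
        "constant_activity": (c1, c2),  # activity fixed at c1, contact from c2
        "constant_contact": (c2, c1),   # contact fixed at c1, activity from c2
    }
    for name, (act_cond, contact_cond) in specs.items():
        cf = counterfactual_predictions(
            elements, genes, act_cond,
            matrices[contact_cond], fits[contact_cond],
            threshold=threshold, max_distance=max_distance,
            qnorm_reference=qnorm_reference,
        )
        links = classify_links(baseline_c1, cf, de_labels, de_only)
        g, l, s = _count_changes(links)
        results[name] = CounterfactualResult(
            assumption=name, n_gained=g, n_lost=l, n_shared=s,
            baseline_gained=bg, baseline_lost=bl,
        )
    return results


def net_enhancer_change(
    pred_c1: pd.DataFrame,
    pred_c2: pd.DataFrame,
    genes: Sequence[Gene],
    switch_class_of_gene: Mapping[str, str] | None = None,
    de_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene change in predicted enhancer count, with strata.

    Delta = predicted (non-promoter) count in condition 2 minus condition 1;
    genes absent from both prediction runs have delta 0.
    """
    def counts(pred: pd.DataFrame) -> pd.Series:
        p = pred[pred.predicted & ~pred.is_promoter]
        return p.groupby("gene_id").size()

    c1 = counts(pred_c1)
    c2 = counts(pred_c2)
    rows = []
    for g in genes:
        gid = g.gene_id
        delta = int(c2.get(gid, 0)) - int(c1.get(gid, 0))
        rows.append(dict(
            gene_id=gid,
            n_enhancers_c1=int(c1.get(gid, 0)),
            n_enhancers_c2=int(c2.get(gid, 0)),
            delta=delta,
            switch_class=(switch_class_of_gene or {}).get(gid, "unassigned"),
            de_label=(de_labels or {}).get(gid, "NDE"),
        ))
    return pd.DataFrame(rows)


def stratum_medians(changes: pd.DataFrame) -> pd.DataFrame:
    """Median per-gene enhancer change per (switch_class, de_label) stratum."""
    return (
        changes.groupby(["switch_class", "de_label"])
        .delta.agg(["median", "mean", "count"])
        .reset_index()
    )


def zero_activity_fraction(link_changes: pd.DataFrame) -> pd.DataFrame:
    """Fraction of rewired links whose element had exactly zero Activity.

    For gained links the relevant side is the pre-switch condition
    (activity_c1); for lost links the post-switch condition (activity_c2).
    Reported per compartment switch class; empty strata are flagged.
    """
    rows = []
    for cls, grp in link_changes.groupby("switch_class", sort=True):
        for status, col in (("gained", "activity_c1"), ("lost", "activity_c2")):
            sub = grp[grp.status == status]
            if len(sub) == 0:
                rows.append(dict(switch_class=cls, status=status,
                                 n=0, zero_fraction=float("nan"), defined=False))
            else:
                frac = float((sub[col] == 0.0).mean())
                rows.append(dict(switch_class=cls, status=status,
                                 n=len(sub), zero_fraction=frac, defined=True))
    return pd.DataFrame(rows)


def activity_contact_scatter_data(
    link_changes: pd.DataFrame, pseudocount: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 Activity and Contact changes for rewired-link scatter plots.

    Returns (activity table, contact table). Activity has one row per
    unique element; Contact one row per element-gene pair (an element can
    contact several promoters). Zeros are floored at ``pseudocount``
    (default: the smallest positive value observed in the relevant pair of
    columns).
    """
    def log2_change(v1: np.ndarray, v2: np.ndarray, eps: float | None) -> np.ndarray:
        both = np.concatenate([v1, v2])
        pos = both[both > 0]
        e = eps if eps is not None else (pos.min() if pos.size else 1.0)
        return np.log2(np.maximum(v2, e) / np.maximum(v1, e))

    act = (
        link_changes.groupby("element_id", sort=True)
        .agg(activity_c1=("activity_c1", "first"),
             activity_c2=("activity_c2", "first"),
             switch_class=("switch_class", "first"),
             status=("status", "first"))
        .reset_index()
    )
    act["log2_activity_change"] = log2_change(
        act.activity_c1.to_numpy(), act.activity_c2.to_numpy(), pseudocount
    )

    con = link_changes[[
        "element_id", "gene_id", "contact_c1", "contact_c2", "switch_class", "status"
    ]].copy()
    c1 = np.nan_to_num(con.contact_c1.to_numpy(), nan=0.0)
    c2 = np.nan_to_num(con.contact_c2.to_numpy(), nan=0.0)
    con["log2_contact_change"] = log2_change(c1, c2, pseudocount)
    return act, con
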