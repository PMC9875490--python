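"""Activity-by-Contact enhancer prediction.

Each candidate element e is scored against each gene g within a distance
cap as

    ABC(e, g) = A_e * C_eg / sum_{e'} A_e' * C_e'g

where Activity A is the geometric mean of depth-normalized ATAC and
H3K27ac read counts at the element and Contact C is the normalized Hi-C
contact frequency between the element and the gene promoter, floored by a
power-law distance expectation fitted to the same matrix. The promoter
element always participates in the denominator but is never reported as an
enhancer. An element is a predicted enhancer for a gene when its score
reaches the threshold (0.02 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_model import ContactMatrix, Gene, GenomicInterval, Peak

__all__ = [
    "CandidateElement",
    "PowerlawFit",
    "make_candidate_regions",
    "element_activity",
    "quantify_elements",
    "quantile_normalize",
    "synthetic_qnorm_reference",
    "fit_powerlaw",
    "contact_estimate",
    "abc_scores",
    "predict_enhancers",
    "enhancers_per_gene",
    "compare_enhancer_sets",
]

DEFAULT_THRESHOLD = 0.02
DEFAULT_MAX_DISTANCE = 5_000_000
DISTANCE_BINS = ("<10kb", "10-100kb", "100kb-1Mb", ">1Mb")


@dataclass
class CandidateElement:
    """A 500 bp candidate regulatory element."""

    interval: GenomicInterval
    element_id: str
    is_promoter: bool = False
    promoter_gene_id: str | None = None
    atac: dict[str, float] = field(default_factory=dict)      # condition -> RPM
    h3k27ac: dict[str, float] = field(default_factory=dict)   # condition -> RPM

    def activity(self, condition: str) -> float:
        return element_activity(
            self.atac.get(condition, 0.0), self.h3k27ac.get(condition, 0.0)
        )


@dataclass(frozen=True)
class PowerlawFit:
    """Power-law distance decay of contact frequency: exp(log_scale) * d^-gamma."""

    gamma: float
    log_scale: float
    fit_range: tuple[float, float]

    def expected(self, distance: float) -> float:
        return math.exp(self.log_scale) * distance ** (-self.gamma)


def make_candidate_regions(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    n_strongest: int = 150_000,
    extend: int = 250,
    resize: int = 500,
) -> list[CandidateElement]:
    """Candidate elements from peak summits plus gene promoters.

    The ``n_strongest`` peaks by score contribute a summit +/- ``extend``
    region each; overlapping regions are merged and each merged region is
    resized to ``resize`` bp centered on its midpoint. A TSS-centered
    promoter element is appended per gene; peak-derived elements that
    overlap a promoter window are dropped so each promoter enters the
    score denominator exactly once. The list is deduplicated and sorted on
    (chrom, start, end, id).
    """
    for p in peaks:
        if p.summit is None:
            raise ValueError(f"peak {p.peak_id} has no summit")
    strongest = sorted(peaks, key=lambda p: -p.score)[:n_strongest]
    regions: dict[str, list[tuple[int, int]]] = {}
    for p in strongest:
        s = p.summit_pos
        regions.setdefault(p.interval.chrom, []).append((max(0, s - extend), s + extend))

    promoter_windows: dict[str, list[tuple[int, int]]] = {}
    half = resize // 2
    for g in genes:
        s = max(0, g.tss - half)
        promoter_windows.setdefault(g.interval.chrom, []).append((s, s + resize))

    elements: list[CandidateElement] = []
    seen: set[tuple[str, int, int]] = set()
    for chrom, spans in regions.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        proms = promoter_windows.get(chrom, [])
        for s, e in merged:
            mid = (s + e) // 2
            rs = max(0, mid - resize // 2)
            key = (chrom, rs, rs + resize)
            if key in seen:
                continue
            if any(rs < pe and ps < rs + resize for ps, pe in proms):
                continue
            seen.add(key)
            elements.append(CandidateElement(
                GenomicInterval(chrom, rs, rs + resize),
                element_id=f"elem_{chrom}_{rs}",
            ))
    for g in genes:
        s = max(0, g.tss - half)
        key = (g.interval.chrom, s, s + resize)
        elements.append(CandidateElement(
            GenomicInterval(g.interval.chrom, s, s + resize),
            element_id=f"prom_{g.gene_id}",
            is_promoter=True,
            promoter_gene_id=g.gene_id,
        ))
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start,
                                 e.interval.end, e.element_id))
    return elements


def element_activity(atac_count: float, h3k27ac_count: float) -> float:
    """Geometric mean of ATAC and H3K27ac read counts."""
    if atac_count < 0 or h3k27ac_count < 0:
        raise ValueError("read counts must be nonnegative")
    return math.sqrt(atac_count * h3k27ac_count)


def _rpm_of_peaks(peaks: Sequence[Peak]) -> dict[str, float]:
    """Mean across replicates of reads-per-million per peak."""
    samples = sorted({s for p in peaks for s in p.counts})
    totals = {s: sum(p.counts.get(s, 0.0) for p in peaks) for s in samples}
    out = {}
    for p in peaks:
        rpms = [
            p.counts[s] / (totals[s] / 1e6) if totals[s] > 0 else 0.0
            for s in samples
            if s in p.counts
        ]
        out[p.peak_id] = float(np.mean(rpms)) if rpms else 0.0
    return out


def quantify_elements(
    elements: Sequence[CandidateElement],
    atac_by_condition: Mapping[str, Sequence[Peak]],
    k27_by_condition: Mapping[str, Sequence[Peak]],
) -> None:
    """Fill per-condition depth-normalized counts on the elements in place.

    For each assay and condition, per-peak counts are converted to
    reads-per-million (per replicate, then averaged), and an element's
    count is the RPM sum of all peaks overlapping it.
    """
    for assay, by_cond in (("atac", atac_by_condition), ("h3k27ac", k27_by_condition)):
        for cond, peaks in by_cond.items():
            rpm = _rpm_of_peaks(peaks)
            trees: dict[str, IntervalTree] = {}
            for p in peaks:
                trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                    p.interval.start, p.interval.end, rpm[p.peak_id]
                )
            for el in elements:
                tree = trees.get(el.interval.chrom)
                hits = tree.overlap(el.interval.start, el.interval.end) if tree else ()
                getattr(el, assay)[cond] = float(sum(h.data for h in hits))


def quantile_normalize(
    activities: np.ndarray, reference_distribution: np.ndarray
) -> np.ndarray:
    """Map values onto a reference distribution by fractional rank.

    The value at rank r maps to the reference quantile at the same
    fractional rank (linear interpolation); tied inputs share the mean of
    their mapped values, so the output is a monotone function of the input.
    """
    x = np.asarray(activities, dtype=float)
    ref = np.sort(np.asarray(reference_distribution, dtype=float))
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    n = x.size
    if n == 0:
        return x.copy()
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n)
    frac = ranks / max(n - 1, 1)
    ref_frac = np.linspace(0.0, 1.0, ref.size) if ref.size > 1 else np.array([0.0])
    mapped = np.interp(frac, ref_frac, ref)
    # ties share the mean of their mapped values
    return pd.Series(mapped).groupby(pd.Series(x)).transform("mean").to_numpy()


def synthetic_qnorm_reference(n: int = 1000, seed: int = 0) -> np.ndarray:
    """A synthetic reference Activity distribution for quantile normalization.

    A sorted lognormal sample standing in for an empirical enhancer-activity
    reference; real analyses should supply their own measured distribution.
    """
    rng = np.random.default_rng(seed)
    return np.sort(rng.lognormal(mean=1.0, sigma=1.0, size=n))


def fit_powerlaw(
    matrix: ContactMatrix, fit_range: tuple[float, float] = (10_000, 1_000_000)
) -> PowerlawFit:
    """Least-squares power-law fit of mean contact vs genomic distance.

    Fits ln(mean contact at distance d) against ln d over distances inside
    ``fit_range`` with positive mean contact; gamma is minus the slope.
    """
    obs = matrix.matrix
    n = matrix.n_bins
    res = matrix.resolution
    ds, means = [], []
    arr = obs.toarray() if n <= 2000 else None
    for k in range(1, n):
        d = k * res
        if not fit_range[0] <= d <= fit_range[1]:
            continue
        if arr is not None:
            diag = np.diagonal(arr, offset=k)
            m = diag.mean()
        else:
            m = obs.diagonal(k).mean()
        if m > 0:
            ds.append(d)
            means.append(m)
    if len(ds) < 5:
        raise ValueError("fewer than 5 usable distance points for power-law fit")
    slope, intercept = np.polyfit(np.log(ds), np.log(means), 1)
    return PowerlawFit(gamma=-float(slope), log_scale=float(intercept),
                       fit_range=(float(fit_range[0]), float(fit_range[1])))


def contact_estimate(
    matrix: ContactMatrix, fit: PowerlawFit, element_pos: int, promoter_tss: int
) -> float:
    """Normalized contact between an element and a promoter.

    Observed contact between the two bins, scaled to contacts per million,
    plus a power-law pseudocount (the fitted expectation at the pair
    distance, same scaling). Pairs closer than one bin carry no usable
    observed signal (self-ligation dominates the diagonal) and use the fit
    evaluated at d = resolution alone. Symmetric in its two loci.
    """
    bi = matrix.bin_of(element_pos)
    bj = matrix.bin_of(promoter_tss)
    depth_scale = matrix.total / 1e6
    if depth_scale <= 0:
        raise ValueError("empty contact matrix")
    d = abs(element_pos - promoter_tss)
    if d < matrix.resolution:
        return fit.expected(matrix.resolution) / depth_scale
    observed = matrix.entry(bi, bj) / depth_scale
    pseudo = fit.expected(d) / depth_scale
    return observed + pseudo


def abc_scores(
    elements: Sequence[CandidateElement],
    activities: np.ndarray,
    gene: Gene,
    fit: PowerlawFit,
    matrix: ContactMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """ABC scores of every candidate element near one gene.

    ``activities`` aligns with ``elements``. All elements whose midpoint is
    within ``max_distance`` of the TSS enter the denominator (including the
    gene's promoter element, which must exist); an element is ``predicted``
    when its score reaches ``threshold`` and it is not a promoter.
    """
    if not any(e.is_promoter and e.promoter_gene_id == gene.gene_id for e in elements):
        raise ValueError(f"no promoter element for gene {gene.gene_id}")
    tss = gene.tss
    rows = []
    for el, act in zip(elements, activities):
        if el.interval.chrom != gene.interval.chrom:
            continue
        dist = abs(el.interval.midpoint - tss)
        if dist > max_distance:
            continue
        contact = contact_estimate(matrix, fit, el.interval.midpoint, tss)
        rows.append(dict(
            element_id=el.element_id,
            gene_id=gene.gene_id,
            chrom=el.interval.chrom,
            start=el.interval.start,
            end=el.interval.end,
            is_promoter=el.is_promoter,
            activity=float(act),
            contact=float(contact),
            abc_numerator=float(act) * float(contact),
            distance=dist,
        ))
    df = pd.DataFrame(rows)
    total = df.abc_numerator.sum()
    df["abc_score"] = df.abc_numerator / total if total > 0 else 0.0
    df["predicted"] = (df.abc_score >= threshold) & ~df.is_promoter
    return df


def predict_enhancers(
    elements: Sequence[CandidateElement],
    condition: str,
    genes: Sequence[Gene],
    fit: PowerlawFit,
    matrix: ContactMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    gene_mask: Sequence[str] | None = None,
    qnorm_reference: np.ndarray | None = None,
) -> pd.DataFrame:
    """All putative element-gene pairs with ABC scores for one condition.

    Activities are taken from the elements' stored counts for ``condition``.
    With ``qnorm_reference``, positive activities are quantile normalized
    onto the reference while exact zeros stay zero (an element silent in
    one condition must keep zero Activity). ``gene_mask`` restricts scoring
    to a subset of genes (e.g. the expressed-gene filter).
    """
    activities = np.array([e.activity(condition) for e in elements])
    if qnorm_reference is not None:
        pos = activities > 0
        if pos.any():
            activities = activities.copy()
            activities[pos] = quantile_normalize(activities[pos], qnorm_reference)
    mask = set(gene_mask) if gene_mask is not None else None
    parts = []
    for g in genes:
        if mask is not None and g.gene_id not in mask:
            continue
        parts.append(abc_scores(
            elements, activities, g, fit, matrix,
            threshold=threshold, max_distance=max_distance,
        ))
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def enhancers_per_gene(predictions: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Predicted (non-promoter) enhancer count per gene plus a summary."""
    pred = predictions[predictions.predicted & ~predictions.is_promoter]
    counts = pred.groupby("gene_id").size()
    counts = counts.reindex(sorted(predictions.gene_id.unique()), fill_value=0)
    hist = counts.value_counts().sort_index().to_dict()
    summary = dict(
        mean=float(counts.mean()) if len(counts) else float("nan"),
        median=float(counts.median()) if len(counts) else float("nan"),
        histogram=hist,
        total_links=int(len(pred)),
    )
    return counts, summary


def distance_histogram(distances: np.ndarray) -> dict[str, int]:
    edges = [0, 10_000, 100_000, 1_000_000, np.inf]
    counts, _ = np.histogram(distances, bins=edges)
    return dict(zip(DISTANCE_BINS, counts.astype(int)))


def compare_enhancer_sets(
    predictions_c1: pd.DataFrame, predictions_c2: pd.DataFrame
) -> dict:
    """Element-level sharing between two prediction runs plus distances.

    Both runs must come from the same merged element universe. An element
    is shared when it is predicted for at least one gene in both
    conditions. The distance histogram covers the union of predicted
    element-gene links.
    """
    u1 = set(predictions_c1.element_id)
    u2 = set(predictions_c2.element_id)
    if u1 != u2:
        raise ValueError("prediction runs use different element universes")
    e1 = set(predictions_c1.loc[predictions_c1.predicted, "element_id"])
    e2 = set(predictions_c2.loc[predictions_c2.predicted, "element_id"])
    links = pd.concat([
        predictions_c1[predictions_c1.predicted],
        predictions_c2[predictions_c2.predicted],
    ]).drop_duplicates(subset=["element_id", "gene_id"])
    return dict(
        shared=len(e1 & e2),
        unique_c1=len(e1 - e2),
        unique_c2=len(e2 - e1),
        shared_fraction=(len(e1 & e2) / len(e1 | e2)) if (e1 | e2) else float("nan"),
        distance_histogram=distance_histogram(links.distance.to_numpy()),
    )
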