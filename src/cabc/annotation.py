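"""Peak annotation, gene-peak class association, and compartment assignment.

Peaks are categorized with priority promoter > genic > intergenic. The
promoter window is TSS-centered (+/- 250 bp by default), the same promoter
concept the enhancer-prediction module uses. Intergenic peaks are assigned
the gene with the nearest TSS; ties break deterministically on
(chrom, start, gene_id).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Gene, GenomicInterval, Peak

__all__ = ["annotate_peaks", "gene_peak_classes", "assign_compartment"]


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    promoter_halfwidth: int = 250,
    max_distance: float = float("inf"),
) -> pd.DataFrame:
    """Assign each peak a category and a target gene.

    * promoter: overlaps a TSS-centered window of 2 x halfwidth;
    * genic: overlaps a gene body (outside all promoter windows);
    * intergenic: neither; target is the gene with the nearest TSS, up to
      ``max_distance`` (unbounded by default).

    Distance to TSS is 0 for promoter and genic peaks and the unsigned
    midpoint-to-TSS distance for intergenic ones. Peaks on chromosomes with
    no gene are flagged ``unassigned``.
    """
    gene_order = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    by_chrom: dict[str, list[Gene]] = {}
    for g in gene_order:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    rows = []
    for p in peaks:
        ps, pe = p.interval.start, p.interval.end
        mid = p.interval.midpoint
        chrom_genes = by_chrom.get(p.interval.chrom, [])
        if not chrom_genes:
            rows.append(dict(peak_id=p.peak_id, category="unassigned",
                             target_gene_id="", distance_to_tss=np.nan))
            continue
        promoter_hits = [
            g for g in chrom_genes
            if ps < g.tss + promoter_halfwidth and g.tss - promoter_halfwidth < pe
        ]
        genic_hits = [
            g for g in chrom_genes
            if ps < g.interval.end and g.interval.start < pe
        ]
        if promoter_hits:
            target = min(promoter_hits, key=lambda g: abs(mid - g.tss))
            rows.append(dict(peak_id=p.peak_id, category="promoter",
                             target_gene_id=target.gene_id, distance_to_tss=0))
        elif genic_hits:
            target = min(genic_hits, key=lambda g: abs(mid - g.tss))
            rows.append(dict(peak_id=p.peak_id, category="genic",
                             target_gene_id=target.gene_id, distance_to_tss=0))
        else:
            # nearest TSS; ties resolved by (chrom, start, id) ordering,
            # which is the iteration order of chrom_genes
            dists = [abs(mid - g.tss) for g in chrom_genes]
            k = int(np.argmin(dists))
            if dists[k] > max_distance:
                rows.append(dict(peak_id=p.peak_id, category="intergenic",
                                 target_gene_id="", distance_to_tss=dists[k]))
            else:
                rows.append(dict(peak_id=p.peak_id, category="intergenic",
                                 target_gene_id=chrom_genes[k].gene_id,
                                 distance_to_tss=dists[k]))
    return pd.DataFrame(rows)


def gene_peak_classes(
    diff_peak_labels: Mapping[str, str], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene peak class from the labels of its associated peaks.

    Association is by ``target_gene_id``; a gene is ``up``/``down`` when all
    its differential peaks go one way, ``both`` when it has at least one of
    each, and ``none`` when every associated peak is non-differential.
    """
    ann = annotations[annotations.target_gene_id != ""]
    rows = []
    for gene_id, grp in ann.groupby("target_gene_id", sort=True):
        labels = {diff_peak_labels.get(pid, "NDE") for pid in grp.peak_id}
        has_up = "up" in labels
        has_down = "down" in labels
        if has_up and has_down:
            cls = "both"
        elif has_up:
            cls = "up"
        elif has_down:
            cls = "down"
        else:
            cls = "none"
        rows.append(dict(gene_id=gene_id, peak_class=cls, n_peaks=len(grp)))
    return pd.DataFrame(rows)


def assign_compartment(
    features: Sequence[GenomicInterval],
    compartment_calls: pd.DataFrame,
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Attach a compartment switch class to each interval feature.

    A feature overlapping at least one switching bin takes that switch
    class (switch precedence over stable); one overlapping both A2B and B2A
    bins is ``mixed`` (excluded from per-class summaries); otherwise it
    takes the stable class of the bin with the largest overlap. Features
    outside the binned region are ``unassigned``.
    """
    calls = compartment_calls
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(len(features))]
    rows = []
    for fid, iv in zip(feature_ids, features):
        sub = calls[
            (calls.chrom == iv.chrom)
            & (calls.start < iv.end)
            & (iv.start < calls.end)
        ]
        sub = sub[~sub.switch_class.isin(["unassigned", "ambiguous"])]
        if len(sub) == 0:
            rows.append(dict(feature_id=fid, switch_class="unassigned"))
            continue
        classes = set(sub.switch_class)
        if "A2B" in classes and "B2A" in classes:
            cls = "mixed"
        elif "A2B" in classes:
            cls = "A2B"
        elif "B2A" in classes:
            cls = "B2A"
        else:
            overlap = (
                np.minimum(sub.end, iv.end) - np.maximum(sub.start, iv.start)
            )
            cls = sub.switch_class.iloc[int(np.argmax(overlap.to_numpy()))]
        rows.append(dict(feature_id=fid, switch_class=cls))
    return pd.DataFrame(rows)
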