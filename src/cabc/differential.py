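"""Differential testing of count tables and downstream classification rules.

``nb_differential`` is a lightweight negative-binomial Wald test in the
DESeq style: median-of-ratios size factors, a method-of-moments dispersion
estimate (floored, and moderated toward the across-feature median when
replication is thin), and a normal-approximation Wald p-value on the log
fold-change of normalized means. It deliberately omits shrinkage, Cook's
filtering and independent filtering: downstream analysis consumes only the
(log2fc, padj) decisions.

Classification thresholds follow the study conventions: differentially
expressed genes at |log2FC| > 2 and padj <= 0.05 (strict comparisons),
differential peaks at |log2FC| >= threshold with padj <= 0.05 (inclusive
comparisons), and gene-level accessibility as the unweighted mean log2FC of
peaks overlapping the gene body or its 750 bp upstream promoter window,
called differential beyond +/- 0.05.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import Gene, Peak

__all__ = [
    "nb_differential",
    "classify_de",
    "classify_diff_peak",
    "gene_accessibility",
    "enrichment_residuals",
]

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 0.01


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference)."""
    logc = np.log(counts.where(counts > 0))
    log_ref = logc.mean(axis=1)
    usable = np.isfinite(log_ref)
    if usable.sum() == 0:
        return pd.Series(1.0, index=counts.columns)
    ratios = logc.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def nb_differential(
    counts: pd.DataFrame,
    condition_of_sample: Mapping[str, str],
    size_factors_override: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald differential test of condition 2 over condition 1.

    ``counts`` is a feature x sample table of raw integer counts;
    ``condition_of_sample`` maps sample id to one of exactly two condition
    labels (sorted order defines condition 1 vs 2). Features with zero
    counts in every sample are excluded. Returns feature_id, base_mean,
    log2fc, pvalue, padj.
    """
    conds = sorted(set(condition_of_sample.values()))
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    samples = [s for s in counts.columns if s in condition_of_sample]
    groups = {c: [s for s in samples if condition_of_sample[s] == c] for c in conds}
    for c, ss in groups.items():
        if len(ss) < 2:
            raise ValueError(f"condition {c!r} has {len(ss)} samples; need >= 2")
    mat = counts[samples]
    arr = mat.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("counts must be nonnegative integers")

    expressed = arr.sum(axis=1) > 0
    mat = mat.loc[expressed]

    sf = size_factors_override if size_factors_override is not None else size_factors(mat)
    norm = mat / sf

    g1, g2 = groups[conds[0]], groups[conds[1]]
    n1, n2 = len(g1), len(g2)
    m1 = norm[g1].mean(axis=1).to_numpy()
    m2 = norm[g2].mean(axis=1).to_numpy()
    v1 = norm[g1].var(axis=1, ddof=1).to_numpy()
    v2 = norm[g2].var(axis=1, ddof=1).to_numpy()

    log2fc = np.log2((m2 + PSEUDOCOUNT) / (m1 + PSEUDOCOUNT))

    # method-of-moments NB dispersion from within-condition moments.
    # Per-feature moments carry very few degrees of freedom, so the raw
    # estimate is shrunk toward the across-feature mean with a prior
    # weight (empirical-Bayes moderation), then floored.
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1) / m1**2
        a2 = (v2 - m2) / m2**2
    alpha_raw = np.nanmean(np.vstack([a1, a2]), axis=0)
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, DISPERSION_FLOOR)
    alpha_global = float(np.mean(alpha_raw))
    df_res = (n1 - 1) + (n2 - 1)
    prior_df = 10.0
    alpha = (df_res * alpha_raw + prior_df * alpha_global) / (df_res + prior_df)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # delta-method variance of log2 ratio of means under NB sampling
    mu1 = np.maximum(m1, PSEUDOCOUNT)
    mu2 = np.maximum(m2, PSEUDOCOUNT)
    var_log = (1.0 / mu1 + alpha) / n1 + (1.0 / mu2 + alpha) / n2
    se = np.sqrt(var_log) / np.log(2.0)
    z = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(dict(
        feature_id=mat.index,
        base_mean=(m1 * n1 + m2 * n2) / (n1 + n2),
        log2fc=log2fc,
        pvalue=pvals,
        padj=padj,
    )).reset_index(drop=True)


def classify_de(results: pd.DataFrame, lfc: float = 2.0, alpha: float = 0.05) -> pd.Series:
    """DEG labels with strict fold-change comparisons: up/down/NDE.

    up: log2fc > lfc and padj <= alpha; down: log2fc < -lfc and padj <= alpha.
    """
    up = (results.log2fc > lfc) & (results.padj <= alpha)
    down = (results.log2fc < -lfc) & (results.padj <= alpha)
    return pd.Series(
        np.select([up, down], ["up", "down"], default="NDE"),
        index=results.index, name="class_label",
    )


def classify_diff_peak(results: pd.DataFrame, lfc: float, alpha: float = 0.05) -> pd.Series:
    """Differential-peak labels with inclusive fold-change comparisons.

    up: log2fc >= lfc and padj <= alpha; down: log2fc <= -lfc and padj <= alpha.
    Use lfc=2.0 for H3K27ac peaks and lfc=0.5 for the ATAC DP analysis.
    """
    up = (results.log2fc >= lfc) & (results.padj <= alpha)
    down = (results.log2fc <= -lfc) & (results.padj <= alpha)
    return pd.Series(
        np.select([up, down], ["up", "down"], default="NDE"),
        index=results.index, name="class_label",
    )


def gene_accessibility(
    peak_results: pd.DataFrame,
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    promoter_upstream: int = 750,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-level accessibility: mean log2FC of peaks on the gene.

    A peak counts toward a gene when it overlaps the gene body or the
    strand-aware window of ``promoter_upstream`` bp upstream of the TSS. A
    peak spanning two genes contributes to both. Direction is ``up`` when
    avg_log2fc > threshold, ``down`` when < -threshold; genes with no
    overlapping peak have a missing average and are not differential.
    """
    lfc_of = dict(zip(peak_results.feature_id, peak_results.log2fc))
    rows = []
    for g in genes:
        iv = g.interval
        if iv.strand == "-":
            prom = (iv.end, iv.end + promoter_upstream)
        else:
            prom = (max(0, iv.start - promoter_upstream), iv.start)
        fcs = []
        for p in peaks:
            if p.peak_id not in lfc_of or p.interval.chrom != iv.chrom:
                continue
            ps, pe = p.interval.start, p.interval.end
            body = ps < iv.end and iv.start < pe
            promoter = ps < prom[1] and prom[0] < pe
            if body or promoter:
                fcs.append(lfc_of[p.peak_id])
        avg = float(np.mean(fcs)) if fcs else float("nan")
        direction = "none"
        if fcs and avg > threshold:
            direction = "up"
        elif fcs and avg < -threshold:
            direction = "down"
        rows.append(dict(
            gene_id=g.gene_id, n_peaks=len(fcs), avg_log2fc=avg,
            direction=direction, differential=direction != "none",
        ))
    return pd.DataFrame(rows)


def enrichment_residuals(table: np.ndarray) -> tuple[np.ndarray, float]:
    """Pearson residuals and Yates-corrected chi-squared p for a 2x2 table.

    residual(i,j) = (O - E)/sqrt(E) with E from the independence model; the
    p-value uses the continuity-corrected statistic with df=1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = stats.contingency.expected_freq(table)
    residuals = (table - expected) / np.sqrt(expected)
    # Yates statistic; in a 2x2 |O - E| is identical in all four cells, and
    # the correction clips at zero so an exactly independent table gives p=1
    d = max(abs(table[0, 0] - expected[0, 0]) - 0.5, 0.0)
    chi2 = d**2 * (1.0 / expected).sum()
    p = float(stats.chi2.sf(chi2, df=1))
    return residuals, p
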