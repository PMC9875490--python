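"""A/B compartment calling and TAD insulation scoring.

Compartments are called with the standard eigenvector method: the contact
map is normalized to observed/expected ratios per genomic distance, a
Pearson correlation matrix of O/E columns is formed, and the first
principal component (leading eigenvector of the correlation matrix) gives
the per-bin compartment signal. The PC1 sign is arbitrary, so it is
oriented against a user-supplied per-bin track of gene activity or open
chromatin (A compartments correlate positively with activity).

Switching between conditions is decided per bin by a moderated two-sample
t test on replicate PC1 values (variance shrunk toward the chromosome-wide
pooled estimate) with Benjamini-Hochberg correction; a bin is switching
when its mean PC1 changes sign with FDR below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import ContactMatrix, GenomicInterval, Peak

__all__ = [
    "observed_expected",
    "compartment_pc1",
    "classify_switching",
    "insulation_scores",
    "differential_insulation",
    "orientation_from_peaks",
]

MIN_BIN_CONTACTS = 10  # bins below this marginal total are masked from PCA
AMBIGUOUS_PC1 = 1e-4   # |mean PC1| below this in either condition -> ambiguous


def observed_expected(matrix: ContactMatrix) -> np.ndarray:
    """O/E normalization: each entry divided by the mean at its distance.

    Diagonals whose mean is zero map to zero.
    """
    obs = matrix.toarray()
    n = matrix.n_bins
    if n < 3:
        raise ValueError("need at least 3 bins for O/E normalization")
    if obs.sum() == 0:
        raise ValueError("no contacts")
    oe = np.zeros_like(obs)
    for d in range(n):
        diag = np.diagonal(obs, offset=d)
        m = diag.mean()
        if m > 0:
            vals = diag / m
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def compartment_pc1(
    oe: np.ndarray,
    orientation_track: np.ndarray,
    bin_totals: np.ndarray | None = None,
    min_contacts: float = MIN_BIN_CONTACTS,
) -> np.ndarray:
    """First principal component of the O/E correlation matrix.

    Bins with fewer than ``min_contacts`` total contacts are masked and
    return NaN. The sign is chosen so the correlation of PC1 with
    ``orientation_track`` is >= 0; if that correlation is exactly zero the
    first nonzero loading is made positive.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if oe.shape != (n, n):
        raise ValueError("O/E matrix must be square")
    orientation_track = np.asarray(orientation_track, dtype=float)
    if orientation_track.shape != (n,):
        raise ValueError("orientation track length must match bin count")

    keep = np.ones(n, dtype=bool)
    if bin_totals is not None:
        keep &= np.asarray(bin_totals) >= min_contacts
    keep &= oe.sum(axis=1) > 0
    sub = oe[np.ix_(keep, keep)]
    if sub.shape[0] < 3:
        raise ValueError("no compartment signal: too few usable bins")
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("no compartment signal: constant O/E columns")
    corr = np.corrcoef(sub, rowvar=False)
    w, v = np.linalg.eigh(corr)
    pc1 = v[:, -1]

    full = np.full(n, np.nan)
    full[keep] = pc1
    track = orientation_track[keep]
    r = 0.0
    if track.std() > 0 and pc1.std() > 0:
        r = float(np.corrcoef(pc1, track)[0, 1])
    if r < 0:
        full = -full
    elif r == 0:
        nz = pc1[pc1 != 0]
        if nz.size and nz[0] < 0:
            full = -full
    return full


def orientation_from_peaks(
    peaks: Sequence[Peak], n_bins: int, resolution: int
) -> np.ndarray:
    """Per-bin open-chromatin signal for orienting the PC1 sign.

    Sums log-scale peak read counts per bin: the log compresses focal
    high-signal peaks so the track reflects broad accessibility, which is
    what distinguishes A from B compartments.
    """
    track = np.zeros(n_bins)
    for p in peaks:
        b = p.interval.midpoint // resolution
        if 0 <= b < n_bins:
            counts = list(p.counts.values())
            val = float(np.mean(counts)) if counts else p.score
            track[b] += np.log1p(val)
    return track


PRIOR_DF = 8.0  # prior degrees of freedom for variance moderation


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t-test p-value; NaN-safe for flat inputs."""
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        # identical, zero-variance groups: no evidence of change
        return 1.0
    return p


def _moderated_t_pvalues(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Per-column moderated two-sample t p-values.

    ``g1``/``g2`` are (replicates, features). Replicate noise is close to
    homoscedastic along a chromosome, and with two replicates the per-bin
    variance has too few degrees of freedom to power a per-bin test, so the
    pooled per-bin variance is shrunk toward the across-bin mean residual
    variance with ``PRIOR_DF`` prior degrees of freedom (empirical-Bayes
    moderation in the limma style). Columns containing NaN give NaN.
    """
    n1, n2 = g1.shape[0], g2.shape[0]
    df_res = n1 + n2 - 2
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_res
    s2_prior = np.nanmean(s2)
    if not np.isfinite(s2_prior) or s2_prior == 0:
        s2_prior = np.nanmax(s2) if np.isfinite(np.nanmax(s2)) else 1.0
    s2_mod = (PRIOR_DF * s2_prior + df_res * s2) / (PRIOR_DF + df_res)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (g2.mean(axis=0) - g1.mean(axis=0)) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=PRIOR_DF + df_res)
    p = np.where(se == 0, 1.0, p)
    return p


def classify_switching(
    pc1_c1: np.ndarray,
    pc1_c2: np.ndarray,
    chrom: str = "chr1",
    resolution: int = 50_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin compartment calls and switch classes between two conditions.

    ``pc1_c1``/``pc1_c2`` are (n_replicates, n_bins) arrays of replicate PC1
    tracks. The between-condition test is a variance-moderated two-sample t
    per bin. A bin is ``A2B``/``B2A`` when its mean PC1 changes sign with
    BH-adjusted p < alpha; a sign flip without FDR support, or no flip, is
    ``stable_{A,B}`` by the condition-1 label; near-zero mean PC1 in either
    condition is ``ambiguous``. Masked (NaN) bins are excluded.
    """
    pc1_c1 = np.atleast_2d(np.asarray(pc1_c1, dtype=float))
    pc1_c2 = np.atleast_2d(np.asarray(pc1_c2, dtype=float))
    if pc1_c1.shape[0] < 2 or pc1_c2.shape[0] < 2:
        raise ValueError("need >= 2 replicates per condition to estimate variance")
    n = pc1_c1.shape[1]
    mean1 = pc1_c1.mean(axis=0)
    mean2 = pc1_c2.mean(axis=0)
    usable = ~(np.isnan(mean1) | np.isnan(mean2))

    pvals = np.full(n, np.nan)
    pvals[usable] = _moderated_t_pvalues(pc1_c1[:, usable], pc1_c2[:, usable])
    fdr = np.full(n, np.nan)
    if usable.any():
        fdr[usable] = multipletests(pvals[usable], method="fdr_bh")[1]

    classes = []
    for i in range(n):
        if not usable[i]:
            classes.append("unassigned")
            continue
        if min(abs(mean1[i]), abs(mean2[i])) < AMBIGUOUS_PC1:
            classes.append("ambiguous")
            continue
        l1 = "A" if mean1[i] > 0 else "B"
        l2 = "A" if mean2[i] > 0 else "B"
        if l1 != l2 and fdr[i] < alpha:
            classes.append("A2B" if l1 == "A" else "B2A")
        else:
            classes.append(f"stable_{l1}")

    return pd.DataFrame(dict(
        chrom=chrom,
        start=np.arange(n) * resolution,
        end=(np.arange(n) + 1) * resolution,
        bin=np.arange(n),
        mean_pc1_c1=mean1,
        mean_pc1_c2=mean2,
        label_c1=np.where(mean1 > 0, "A", "B"),
        label_c2=np.where(mean2 > 0, "A", "B"),
        pvalue=pvals,
        fdr=fdr,
        switch_class=classes,
    ))


def call_compartments(
    matrices: Sequence[ContactMatrix], orientation_track: np.ndarray
) -> np.ndarray:
    """Replicate PC1 tracks, stacked (n_replicates, n_bins)."""
    return np.vstack([
        compartment_pc1(observed_expected(m), orientation_track, m.bin_totals())
        for m in matrices
    ])


def switching_fraction(calls: pd.DataFrame) -> float:
    """Fraction of classified bins in A2B or B2A."""
    classified = calls[~calls.switch_class.isin(["unassigned", "ambiguous"])]
    if len(classified) == 0:
        return float("nan")
    return float(classified.switch_class.isin(["A2B", "B2A"]).mean())


EPS_INSULATION = 1e-6


def insulation_scores(
    matrix: ContactMatrix, domains: Sequence[GenomicInterval]
) -> list[float]:
    """log2 ratio of within-domain to domain-vs-flank mean O/E.

    Flanks are windows of equal bin length on each side, truncated at the
    chromosome ends; domains shorter than two bins are skipped (NaN) with a
    warning. Scores are invariant to global scaling of the contact map.
    """
    oe = observed_expected(matrix)
    n = matrix.n_bins
    res = matrix.resolution
    scores: list[float] = []
    for dom in domains:
        b0 = dom.start // res
        b1 = (dom.end + res - 1) // res
        w = b1 - b0
        if w < 2:
            warnings.warn(f"domain {dom.chrom}:{dom.start}-{dom.end} shorter than 2 bins; skipped")
            scores.append(float("nan"))
            continue
        intra = oe[b0:b1, b0:b1]
        iu = np.triu_indices(w, k=1)
        mean_intra = intra[iu].mean()
        left = oe[max(0, b0 - w) : b0, b0:b1]
        right = oe[b1 : min(n, b1 + w), b0:b1]
        inter_vals = np.concatenate([left.ravel(), right.ravel()])
        mean_inter = inter_vals.mean() if inter_vals.size else 0.0
        scores.append(float(np.log2(
            (mean_intra + EPS_INSULATION) / (mean_inter + EPS_INSULATION)
        )))
    return scores


def differential_insulation(
    scores_c1: np.ndarray,
    scores_c2: np.ndarray,
    domains: Sequence[GenomicInterval],
    delta_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential domain insulation between conditions.

    ``scores_c*`` are (n_replicates, n_domains). A domain is differential
    when |mean difference| > ``delta_threshold`` and BH-adjusted p < alpha.
    """
    s1 = np.atleast_2d(np.asarray(scores_c1, dtype=float))
    s2 = np.atleast_2d(np.asarray(scores_c2, dtype=float))
    if s1.shape[0] < 2 or s2.shape[0] < 2:
        raise ValueError("need >= 2 replicates per condition")
    n = s1.shape[1]
    delta = s2.mean(axis=0) - s1.mean(axis=0)
    pvals = np.array([_two_sample_t(s1[:, i], s2[:, i]) for i in range(n)])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(dict(
        chrom=[d.chrom for d in domains],
        start=[d.start for d in domains],
        end=[d.end for d in domains],
        mean_c1=s1.mean(axis=0),
        mean_c2=s2.mean(axis=0),
        delta=delta,
        pvalue=pvals,
        padj=padj,
        differential=(np.abs(delta) > delta_threshold) & (padj < alpha),
    ))
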