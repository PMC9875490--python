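"""Two-condition multi-omics simulator with planted ground truth.

Generates, for each of two conditions, replicate cis contact matrices at a
compartment resolution (50 kb) and a finer contact resolution (5 kb), ATAC
and H3K27ac peak sets with negative-binomial replicate counts, gene models,
and gene-level expression counts. The planted structure mirrors what the
downstream analysis assumes:

* a checkerboard compartment organization with power-law distance decay and
  within-compartment contact enrichment, with a configurable fraction of
  bins switching compartment between conditions;
* peak signal that tracks compartment state (background open-chromatin
  sites in A-state bins are stronger by ``background_compartment_contrast``);
* per-gene enhancer elements, a fraction of which are gained or lost
  between conditions (rewired elements may drop to exactly zero signal in
  their inactive condition);
* gene expression whose log2 fold-change follows the net number of
  enhancers gained, with per-gene jitter so the relationship is a
  correlation rather than an identity.

Everything is drawn from a single seeded generator, so identical configs
produce identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_model import (
    ContactMatrix,
    Gene,
    GenomicInterval,
    Peak,
    contact_matrix_from_triplets,
    write_bed_like,
    write_contact_matrix,
    write_table,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConditionBundle",
    "simulate_dataset",
    "downsample_contacts",
    "expected_contact_matrix",
    "write_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-condition experiment.

    Defaults describe a 20 Mb chromosome (400 bins at 50 kb) sequenced to
    5x10^5 cis contacts per replicate, with 10% of bins switching
    compartment, about two enhancers per gene, and a quarter of enhancers
    gained or lost between conditions.
    """

    n_bins: int = 400
    resolution_compartment: int = 50_000
    resolution_contact: int = 5_000
    gamma: float = 1.0
    checkerboard_boost: float = 0.6
    switch_fraction: float = 0.1
    n_genes: int = 40
    enhancers_per_gene_mean: float = 2.0
    frac_enhancer_gain: float = 0.25
    frac_enhancer_loss: float = 0.25
    activity_effect: float = 8.0
    zero_activity_fraction: float = 0.6
    expression_effect_per_enhancer: float = 1.0
    expression_jitter_sd: float = 0.3
    nb_dispersion: float = 0.05
    depth: float = 2e6
    n_replicates: int = 2
    seed: int = 0
    chrom: str = "chr1"
    mean_block_bins: float = 10.0
    enhancer_max_distance: int = 100_000
    enhancer_distance_scale: int = 30_000
    enhancer_min_distance: int = 2_000
    gene_min_spacing: int = 400_000
    activity_lognorm_sd: float = 0.25
    # signal scales (expected read counts per peak in the active state)
    enhancer_signal: float = 50.0
    promoter_signal: float = 80.0
    background_signal: float = 2.0
    background_compartment_contrast: float = 4.0
    background_tss_exclusion: int = 20_000
    expression_baseline: float = 100.0
    # planted single-driver scenarios: share one data layer between conditions
    shared_contacts: bool = False
    shared_activity: bool = False

    def __post_init__(self) -> None:
        for name in ("switch_fraction", "frac_enhancer_gain", "frac_enhancer_loss",
                     "zero_activity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_enhancer_gain + self.frac_enhancer_loss > 1.0:
            raise ValueError("gain + loss fractions exceed 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.checkerboard_boost < 0:
            raise ValueError("checkerboard_boost must be >= 0")
        if self.resolution_compartment % self.resolution_contact != 0:
            raise ValueError("compartment resolution must be a multiple of contact resolution")

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.resolution_compartment


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset.

    ``is_a`` has shape (2, n_bins): compartment state per condition (True=A).
    ``element_truth`` carries one row per element (enhancer, promoter or
    background peak) with its planted status and expected activity per
    condition; ``gene_truth`` one row per gene with enhancer bookkeeping and
    the planted expression log2 fold-change.
    """

    is_a: np.ndarray
    switch_set: np.ndarray
    gene_truth: pd.DataFrame
    element_truth: pd.DataFrame

    def state_label(self, condition: int, bin_id: int) -> str:
        return "A" if self.is_a[condition, bin_id] else "B"

    def switch_class(self, bin_id: int) -> str:
        a1, a2 = self.is_a[0, bin_id], self.is_a[1, bin_id]
        if a1 and not a2:
            return "A2B"
        if not a1 and a2:
            return "B2A"
        return "stable_A" if a1 else "stable_B"

    def planted_links(self, condition: int) -> set[tuple[str, str]]:
        """(element_id, gene_id) pairs of enhancers active in a condition."""
        et = self.element_truth
        col = f"active_c{condition + 1}"
        enh = et[(et.status.isin(["gained", "lost", "stable"])) & et[col]]
        return set(zip(enh.element_id, enh.gene_id))


@dataclass
class ConditionBundle:
    """All simulated data layers for one condition."""

    condition: str
    contacts_compartment: list[ContactMatrix]
    contacts_abc: list[ContactMatrix]
    atac_peaks: list[Peak]
    k27_peaks: list[Peak]
    genes: list[Gene]
    gene_counts: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.gene_counts.columns)


def _block_states(rng: np.random.Generator, n_bins: int, mean_block: float) -> np.ndarray:
    """Contiguous A/B runs with geometric lengths (mean ``mean_block``)."""
    states = np.empty(n_bins, dtype=bool)
    pos = 0
    current = bool(rng.integers(2))
    p = 1.0 / mean_block
    while pos < n_bins:
        run = int(rng.geometric(p))
        states[pos : pos + run] = current
        pos += run
        current = not current
    return states


def _pair_weight_normalizer(is_a: np.ndarray, gamma: float, boost: float) -> float:
    """Sum of unnormalized expected contacts over i <= j."""
    n = len(is_a)
    total = 0.0
    for d in range(n):
        d_eff = max(d, 1)
        same = is_a[: n - d] == is_a[d:]
        total += (d_eff ** -gamma) * (len(same) + boost * same.sum())
    return total


def expected_contact_matrix(
    is_a: np.ndarray, gamma: float, boost: float, depth: float
) -> np.ndarray:
    """Dense matrix of expected contact counts for one condition/replicate.

    E[i, j] = scale * max(|i-j|, 1)^(-gamma) * (1 + boost * 1[same state]),
    with scale chosen so the sum over i <= j equals ``depth``.
    """
    is_a = np.asarray(is_a, dtype=bool)
    n = len(is_a)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    d_eff = np.maximum(d, 1).astype(float)
    same = np.equal.outer(is_a, is_a)
    w = d_eff ** -gamma * (1.0 + boost * same)
    scale = depth / _pair_weight_normalizer(is_a, gamma, boost)
    return scale * w


def _sample_contact_matrix(
    rng: np.random.Generator,
    chrom: str,
    resolution: int,
    is_a: np.ndarray,
    gamma: float,
    boost: float,
    depth: float,
) -> ContactMatrix:
    """Per-diagonal Poisson sampling; memory stays O(n_bins)."""
    n = len(is_a)
    scale = depth / _pair_weight_normalizer(is_a, gamma, boost)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)
    for d in range(n):
        d_eff = max(d, 1)
        same = is_a[: n - d] == is_a[d:]
        mu = scale * (d_eff ** -gamma) * (1.0 + boost * same)
        counts = rng.poisson(mu)
        nz = counts.nonzero()[0]
        if nz.size:
            rows.append(idx[nz])
            cols.append(idx[nz] + d)
            vals.append(counts[nz])
    if not rows:
        return ContactMatrix(chrom, resolution, n, sp.csr_matrix((n, n)))
    return contact_matrix_from_triplets(
        chrom, resolution,
        np.concatenate(rows), np.concatenate(cols),
        np.concatenate(vals).astype(float), n_bins=n,
    )


def downsample_contacts(matrix: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomial thinning of every contact pair; symmetry is preserved."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return matrix
    rng = np.random.default_rng(seed)
    upper = sp.triu(sp.coo_matrix(matrix.matrix))
    thinned = rng.binomial(upper.data.astype(np.int64), fraction).astype(float)
    return contact_matrix_from_triplets(
        matrix.chrom, matrix.resolution, upper.row, upper.col, thinned,
        n_bins=matrix.n_bins,
    )


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + alpha*mu^2)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _place_genes(rng: np.random.Generator, cfg: SimConfig) -> list[Gene]:
    """Genes on a jittered grid with a minimum TSS spacing.

    Keeping regulatory neighbourhoods spatially disjoint is what makes the
    planted element-target assignment unambiguous ground truth.
    """
    margin = cfg.enhancer_max_distance + 25_000
    usable = cfg.chrom_length - 2 * margin
    slot = usable / cfg.n_genes
    if slot < cfg.gene_min_spacing:
        raise ValueError(
            f"cannot space {cfg.n_genes} genes >= {cfg.gene_min_spacing} bp apart "
            f"on a {cfg.chrom_length} bp chromosome"
        )
    jitter = slot - cfg.gene_min_spacing
    genes: list[Gene] = []
    for g in range(cfg.n_genes):
        tss = int(margin + g * slot + rng.uniform(0, jitter))
        length = int(rng.integers(5_000, 20_000))
        strand = "+" if rng.integers(2) else "-"
        if strand == "+":
            iv = GenomicInterval(cfg.chrom, tss, tss + length, strand)
        else:
            iv = GenomicInterval(cfg.chrom, tss - length + 1, tss + 1, strand)
        genes.append(Gene(iv, f"gene_{g:04d}"))
    return sorted(genes, key=lambda g: (g.interval.start, g.gene_id))


def _place_enhancer(
    rng: np.random.Generator, cfg: SimConfig, tss: int, gene_spans: np.ndarray
) -> tuple[int, int]:
    """An intergenic 500 bp window near a TSS.

    Enhancer-promoter distances decay roughly exponentially in real data
    (most links within tens of kb), so |offset| is drawn exponential with
    scale ``enhancer_distance_scale``, floored at ``enhancer_min_distance``
    and capped at ``enhancer_max_distance``.
    """
    for _ in range(300):
        dist = cfg.enhancer_min_distance + rng.exponential(cfg.enhancer_distance_scale)
        if dist > cfg.enhancer_max_distance:
            continue
        offset = int(dist) * (1 if rng.integers(2) else -1)
        start = tss + offset - 250
        end = start + 500
        if start < 0 or end > cfg.chrom_length:
            continue
        hits = (gene_spans[:, 0] < end) & (start < gene_spans[:, 1])
        if not hits.any():
            return start, end
    raise RuntimeError("could not place an intergenic enhancer near the target TSS")


def simulate_dataset(config: SimConfig) -> tuple[ConditionBundle, ConditionBundle, SimTruth]:
    """Simulate both condition bundles and the planted truth.

    Raises if no A-state bin exists to host active elements, and warns
    (planting zero switches) when ``switch_fraction * n_bins < 1``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- compartment states and switches ---------------------------------
    state1 = _block_states(rng, cfg.n_bins, cfg.mean_block_bins)
    n_switch = int(round(cfg.switch_fraction * cfg.n_bins))
    if cfg.switch_fraction > 0 and n_switch < 1:
        warnings.warn("switch_fraction * n_bins < 1; planting zero switches")
    switch_set = np.sort(rng.choice(cfg.n_bins, size=n_switch, replace=False))
    state2 = state1.copy()
    state2[switch_set] = ~state2[switch_set]
    is_a = np.vstack([state1, state2])
    if not is_a.any():
        raise ValueError("too few A-compartment bins to place active elements")

    # --- contact matrices -------------------------------------------------
    factor = cfg.resolution_compartment // cfg.resolution_contact
    bundles_contacts: list[tuple[list[ContactMatrix], list[ContactMatrix]]] = []
    for cond in range(2):
        if cfg.shared_contacts and cond == 1:
            bundles_contacts.append(bundles_contacts[0])
            continue
        st = is_a[cond]
        st_fine = np.repeat(st, factor)
        comp = [
            _sample_contact_matrix(
                rng, cfg.chrom, cfg.resolution_compartment, st,
                cfg.gamma, cfg.checkerboard_boost, cfg.depth,
            )
            for _ in range(cfg.n_replicates)
        ]
        fine = [
            _sample_contact_matrix(
                rng, cfg.chrom, cfg.resolution_contact, st_fine,
                cfg.gamma, cfg.checkerboard_boost, cfg.depth,
            )
            for _ in range(cfg.n_replicates)
        ]
        bundles_contacts.append((comp, fine))

    # --- genes and regulatory elements ------------------------------------
    genes = _place_genes(rng, cfg)
    gene_spans = np.array([[g.interval.start, g.interval.end] for g in genes])

    elem_rows: list[dict] = []
    gene_rows: list[dict] = []
    p_stable = 1.0 - cfg.frac_enhancer_gain - cfg.frac_enhancer_loss
    for g in genes:
        n_enh = int(rng.poisson(cfg.enhancers_per_gene_mean))
        statuses = rng.choice(
            ["gained", "lost", "stable"], size=n_enh,
            p=[cfg.frac_enhancer_gain, cfg.frac_enhancer_loss, p_stable],
        )
        n_gain = int((statuses == "gained").sum())
        n_loss = int((statuses == "lost").sum())
        for k, status in enumerate(statuses):
            start, end = _place_enhancer(rng, cfg, g.tss, gene_spans)
            base = cfg.enhancer_signal * float(rng.lognormal(0.0, cfg.activity_lognorm_sd))
            if status == "stable":
                sig1 = sig2 = base
            else:
                silent = rng.random() < cfg.zero_activity_fraction
                weak = 0.0 if silent else base / cfg.activity_effect
                sig1, sig2 = (weak, base) if status == "gained" else (base, weak)
            elem_rows.append(dict(
                element_id=f"{g.gene_id}_enh{k}", chrom=cfg.chrom,
                start=start, end=end, gene_id=g.gene_id, status=status,
                signal_c1=sig1, signal_c2=sig2,
                active_c1=sig1 > 0 and status != "gained",
                active_c2=sig2 > 0 and status != "lost",
            ))
        net = n_gain - n_loss
        true_lfc = cfg.expression_effect_per_enhancer * net
        realized_lfc = true_lfc + float(rng.normal(0.0, cfg.expression_jitter_sd))
        gene_rows.append(dict(
            gene_id=g.gene_id, tss=g.tss, n_enhancers=n_enh,
            n_gained=n_gain, n_lost=n_loss, net_change=net,
            true_log2fc=true_lfc, realized_log2fc=realized_lfc,
        ))

    # promoter elements: constitutively open/acetylated
    for g in genes:
        start = max(0, g.tss - 250)
        elem_rows.append(dict(
            element_id=f"{g.gene_id}_prom", chrom=cfg.chrom,
            start=start, end=start + 500, gene_id=g.gene_id, status="promoter",
            signal_c1=cfg.promoter_signal, signal_c2=cfg.promoter_signal,
            active_c1=False, active_c2=False,
        ))

    # background peaks: one per compartment bin, signal tracks the bin
    # state; kept clear of promoters, where open chromatin would be
    # regulatory rather than background
    tss_arr = np.array([g.tss for g in genes])
    for b in range(cfg.n_bins):
        start = None
        for _ in range(50):
            cand = int(b * cfg.resolution_compartment
                       + rng.integers(0, cfg.resolution_compartment - 500))
            if np.abs(tss_arr - (cand + 250)).min() > cfg.background_tss_exclusion:
                start = cand
                break
        if start is None:
            continue
        sigs = [
            cfg.background_signal
            * (cfg.background_compartment_contrast if is_a[c, b] else 1.0)
            for c in range(2)
        ]
        elem_rows.append(dict(
            element_id=f"bg_{b:05d}", chrom=cfg.chrom,
            start=start, end=start + 500, gene_id="", status="background",
            signal_c1=sigs[0], signal_c2=sigs[1],
            active_c1=False, active_c2=False,
        ))

    element_truth = pd.DataFrame(elem_rows)
    gene_truth = pd.DataFrame(gene_rows)

    # --- peak tracks with replicate counts ---------------------------------
    def make_peaks(cond: int, assay: str) -> list[Peak]:
        col = f"signal_c{cond + 1}"
        peaks = []
        for row in element_truth.itertuples():
            mu = getattr(row, col)
            counts = {
                f"rep{r + 1}": int(_nb_counts(rng, mu, cfg.nb_dispersion, 1)[0])
                for r in range(cfg.n_replicates)
            }
            iv = GenomicInterval(row.chrom, row.start, row.end)
            peaks.append(Peak(
                iv, f"{assay}_{row.element_id}", summit=iv.length // 2,
                score=float(max(mu, 1.0)), counts=counts,
            ))
        return peaks

    peaks_by_cond = []
    for cond in range(2):
        if cfg.shared_activity and cond == 1:
            peaks_by_cond.append(peaks_by_cond[0])
            continue
        peaks_by_cond.append((make_peaks(cond, "atac"), make_peaks(cond, "k27ac")))

    # --- expression counts --------------------------------------------------
    base_mean = cfg.expression_baseline * rng.lognormal(0.0, 0.8, size=len(genes))
    counts_by_cond = []
    for cond in range(2):
        shift = np.where(
            np.full(len(genes), cond == 1),
            2.0 ** gene_truth.realized_log2fc.to_numpy(), 1.0,
        )
        mat = np.column_stack([
            _nb_counts_vec(rng, base_mean * shift, cfg.nb_dispersion)
            for _ in range(cfg.n_replicates)
        ])
        counts_by_cond.append(pd.DataFrame(
            mat, index=gene_truth.gene_id,
            columns=[f"rep{r + 1}" for r in range(cfg.n_replicates)],
        ))

    bundles = []
    for cond, name in enumerate(["c1", "c2"]):
        comp, fine = bundles_contacts[cond]
        atac, k27 = peaks_by_cond[cond]
        bundles.append(ConditionBundle(
            condition=name,
            contacts_compartment=comp,
            contacts_abc=fine,
            atac_peaks=atac,
            k27_peaks=k27,
            genes=genes,
            gene_counts=counts_by_cond[cond],
        ))

    truth = SimTruth(
        is_a=is_a, switch_set=switch_set,
        gene_truth=gene_truth, element_truth=element_truth,
    )
    return bundles[0], bundles[1], truth


def _nb_counts_vec(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    out = np.zeros(means.shape, dtype=np.int64)
    pos = means > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(means[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + means[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def write_bundle(bundle: ConditionBundle, truth: SimTruth, outdir) -> None:
    """Write one condition bundle (and the shared truth tables) to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for r, cm in enumerate(bundle.contacts_compartment):
        write_contact_matrix(cm, out / f"contacts_{cm.resolution}bp_rep{r + 1}.txt")
    for r, cm in enumerate(bundle.contacts_abc):
        write_contact_matrix(cm, out / f"contacts_{cm.resolution}bp_rep{r + 1}.txt")
    write_bed_like(bundle.atac_peaks, out / "atac_peaks.bed")
    write_bed_like(bundle.k27_peaks, out / "k27ac_peaks.bed")
    write_bed_like(bundle.genes, out / "genes.bed")
    bundle.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    write_table(truth.gene_truth, out / "truth_genes.tsv")
    write_table(truth.element_truth, out / "truth_elements.tsv")
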