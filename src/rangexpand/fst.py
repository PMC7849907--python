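"""Weir-Cockerham F_ST and a permutation outlier scan.

The estimator decomposes allele-frequency variance into components
a (among populations), b (among individuals within populations) and
c (within individuals), computed from diploid genotype counts with the
observed-heterozygosity term.  Per-SNP theta is a / (a + b + c); the
overall theta is the ratio of summed components (not the mean of
per-SNP ratios), the standard multi-locus combination.

The outlier scan replaces a Bayesian model-based scan with a desk-scale
label-permutation null on the same theta statistic: population labels
are permuted, all permuted per-SNP thetas are pooled into one null
distribution, empirical p-values use the add-one rule, and candidates
are selected by Benjamini-Hochberg at the requested FDR (1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from rangexpand.genotypes import MISSING, GenotypeMatrix
from rangexpand.filtering import allele_frequencies

__all__ = ["FstResult", "OutlierScanResult", "remove_rare", "weir_cockerham", "outlier_scan"]


def remove_rare(G: GenotypeMatrix, threshold: float = 0.10) -> GenotypeMatrix:
    """Drop SNPs whose folded minor-allele frequency over the pooled
    samples falls below ``threshold`` (default 10%)."""
    freq = allele_frequencies(G)
    folded = np.minimum(freq, 1.0 - freq)
    keep = folded >= threshold
    keep &= ~np.isnan(freq)
    return G.take_snps(keep)


@dataclass
class FstResult:
    """Per-SNP Weir-Cockerham variance components and theta.

    SNPs flagged undefined (zero total variance, or any population with
    fewer than two called diploids) carry NaN theta and are excluded from
    the overall ratio-of-sums.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    overall_theta: float
    defined: np.ndarray  # bool per SNP
    pop_sizes: dict[str, int]


def _components(dosage: np.ndarray, pop_masks: list[np.ndarray]):
    """Vectorized W&C components over all SNPs for given population masks."""
    r = len(pop_masks)
    called = dosage != MISSING
    het = dosage == 1
    n_i = np.stack([(called[m]).sum(axis=0) for m in pop_masks]).astype(float)  # r x m
    alt_i = np.stack([np.where(called[m], dosage[m], 0).sum(axis=0) for m in pop_masks])
    het_i = np.stack([(het[m] & called[m]).sum(axis=0) for m in pop_masks]).astype(float)

    defined = (n_i >= 2).all(axis=0)
    n_i_safe = np.where(n_i > 0, n_i, np.nan)
    p_i = alt_i / (2.0 * n_i_safe)
    h_i = het_i / n_i_safe

    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / sum_n
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / sum_n

    with np.errstate(invalid="ignore", divide="ignore"):
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    tot = a + b + c
    defined &= np.isfinite(tot) & (tot != 0)
    return a, b, c, defined


def weir_cockerham(G: GenotypeMatrix, pop_labels: dict[str, str] | pd.Series) -> FstResult:
    """Weir-Cockerham theta between the labeled populations.

    ``pop_labels`` maps sample id -> population name; only mapped samples
    enter the estimate.  At least two populations are required.
    """
    labels = pd.Series(pop_labels)
    labels = labels[labels.index.isin(G.sample_ids)]
    pops = sorted(labels.unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    sample_pos = {s: i for i, s in enumerate(G.sample_ids)}
    pop_masks = []
    for p in pops:
        mask = np.zeros(G.n_samples, dtype=bool)
        mask[[sample_pos[s] for s in labels.index[labels == p]]] = True
        pop_masks.append(mask)

    a, b, c, defined = _components(G.dosage, pop_masks)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(defined, a / (a + b + c), np.nan)
    if defined.any():
        overall = a[defined].sum() / (a + b + c)[defined].sum()
    else:
        overall = np.nan
    return FstResult(
        a=a, b=b, c=c, theta=theta, overall_theta=float(overall), defined=defined,
        pop_sizes={p: int(m.sum()) for p, m in zip(pops, pop_masks)},
    )


@dataclass
class OutlierScanResult:
    """Permutation outlier-scan output."""

    theta: np.ndarray
    p_value: np.ndarray  # NaN for undefined SNPs
    q_value: np.ndarray
    candidates: np.ndarray  # indices of SNPs with q <= fdr
    fdr: float
    n_permutations: int
    seed: int


def outlier_scan(
    G: GenotypeMatrix,
    pop_labels: dict[str, str] | pd.Series,
    n_perm: int = 999,
    fdr: float = 0.01,
    seed: int = 0,
) -> OutlierScanResult:
    """Scan for divergence outliers against a pooled permutation null.

    The panel should already be rare-SNP-filtered (folded MAF >= 10%).
    Undefined-theta SNPs are reported with NaN p and excluded from
    candidate testing.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = pd.Series(pop_labels)
    labels = labels[labels.index.isin(G.sample_ids)]
    res = weir_cockerham(G, labels)
    if not res.defined.any():
        raise ValueError("all SNPs have undefined theta")

    sample_pos = {s: i for i, s in enumerate(G.sample_ids)}
    idx = np.array([sample_pos[s] for s in labels.index])
    lab = labels.to_numpy().copy()
    rng = np.random.default_rng(seed)

    null: list[np.ndarray] = []
    for _ in range(n_perm):
        rng.shuffle(lab)
        perm_labels = pd.Series(lab, index=labels.index)
        pr = weir_cockerham(G, perm_labels)
        null.append(pr.theta[pr.defined])
    null_pool = np.sort(np.concatenate(null))

    m = G.n_snps
    p = np.full(m, np.nan)
    obs = res.theta
    di = np.flatnonzero(res.defined)
    # number of null thetas >= observed, via sorted search
    ge = len(null_pool) - np.searchsorted(null_pool, obs[di], side="left")
    p[di] = (ge + 1) / (len(null_pool) + 1)

    q = np.full(m, np.nan)
    if len(di):
        _, q_def, _, _ = multipletests(p[di], method="fdr_bh")
        q[di] = q_def
    candidates = di[q[di] <= fdr] if len(di) else np.array([], dtype=int)
    return OutlierScanResult(
        theta=obs, p_value=p, q_value=q, candidates=candidates,
        fdr=fdr, n_permutations=n_perm, seed=seed,
    )


def scan_table(G: GenotypeMatrix, scan: OutlierScanResult) -> pd.DataFrame:
    """Per-SNP TSV-ready table (chrom, pos, theta, p, q, candidate)."""
    cand = np.zeros(G.n_snps, dtype=bool)
    cand[scan.candidates] = True
    return pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "pos": G.snps["pos"],
            "theta": scan.theta,
            "p_value": scan.p_value,
            "q_value": scan.q_value,
            "candidate": cand,
        }
    )
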