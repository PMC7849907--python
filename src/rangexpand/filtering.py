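"""SNP-panel filters: MAF bounds, missingness, distance thinning,
Hardy-Weinberg exact test, and windowed LD pruning.

The filters mirror the vcftools/PLINK stages used to prepare diploid SNP
panels for structure inference and PCA: ``--maf 0.02 --max-maf 0.98
--max-missing-count 0 --thin 50`` followed by ``--indep-pairwise 50 5 0.9``
and ``--hwe 1e-10`` (strict panel), or a missing-rate 0.9 / LD 0.5 variant
(PCA panel).  All filters return order-preserving SNP subsets and are
idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from rangexpand.genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "allele_frequencies",
    "filter_maf",
    "filter_missing",
    "thin_by_distance",
    "hwe_exact_p",
    "hwe_filter",
    "ld_prune",
    "apply_preset",
    "PRESETS",
]


@dataclass
class FilterConfig:
    """Thresholds for the SNP filter stages.

    ``max_missing_count`` and ``max_missing_rate`` are alternatives; the
    one that is set selects the missingness mode.
    """

    maf_min: float = 0.02
    maf_max: float = 0.98
    max_missing_count: int | None = 0
    max_missing_rate: float | None = None
    thin_bp: int = 50
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.9
    hwe_p: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < self.maf_max <= 1.0):
            raise ValueError("need 0 <= maf_min < maf_max <= 1")
        for name in ("thin_bp", "ld_window", "ld_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per SNP over non-missing calls.

    SNPs with zero called samples get NaN (undefined, flagged by the
    caller's downstream filters).
    """
    called = G.dosage != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, G.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    return freq


def _log_stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d -> %d SNPs", name, n_in, n_out)


def filter_maf(G: GenotypeMatrix, maf_min: float = 0.02, maf_max: float = 0.98) -> GenotypeMatrix:
    """Keep SNPs with alt-allele frequency in [maf_min, maf_max]
    (vcftools ``--maf/--max-maf`` semantics: unfolded frequency)."""
    freq = allele_frequencies(G)
    keep = (freq >= maf_min) & (freq <= maf_max)
    keep &= ~np.isnan(freq)
    out = G.take_snps(keep)
    _log_stage("maf", G.n_snps, out.n_snps)
    return out


def filter_missing(
    G: GenotypeMatrix,
    max_missing_count: int | None = None,
    max_missing_rate: float | None = None,
) -> GenotypeMatrix:
    """Keep SNPs by missing-call count (absolute) or missing rate.

    Exactly one of the two thresholds must be given.
    """
    if (max_missing_count is None) == (max_missing_rate is None):
        raise ValueError("set exactly one of max_missing_count / max_missing_rate")
    n_missing = (G.dosage == MISSING).sum(axis=0)
    if max_missing_count is not None:
        keep = n_missing <= max_missing_count
    else:
        keep = n_missing / G.n_samples <= max_missing_rate
    out = G.take_snps(keep)
    _log_stage("missing", G.n_snps, out.n_snps)
    return out


def thin_by_distance(G: GenotypeMatrix, thin_bp: int = 50) -> GenotypeMatrix:
    """Greedy left-to-right thinning per chromosome: keep a SNP iff it lies
    more than ``thin_bp`` bp from the last kept SNP (vcftools ``--thin``)."""
    keep = np.zeros(G.n_snps, dtype=bool)
    chroms = G.snps["chrom"].to_numpy()
    pos = G.snps["pos"].to_numpy()
    last_kept: dict[str, int] = {}
    for j in range(G.n_snps):
        c = chroms[j]
        if c not in last_kept or pos[j] - last_kept[c] > thin_bp:
            keep[j] = True
            last_kept[c] = pos[j]
    out = G.take_snps(keep)
    _log_stage("thin", G.n_snps, out.n_snps)
    return out


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP's genotype counts.

    Conditional on the allele counts, the probability of each possible
    heterozygote count is P(n_het) = n! / (n_AA! n_Aa! n_aa!) * 2^{n_Aa}
    * n_A! n_a! / (2n)!; the p-value sums the probabilities of all
    configurations no more likely than the observed one (no mid-p).
    Monomorphic SNPs have a single configuration and p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_r = 2 * n - n_a
    rare = min(n_a, n_r)
    if rare == 0:
        return 1.0
    lg = math.lgamma

    def log_prob(nh: int) -> float:
        # genotype counts implied by heterozygote count nh
        n_alt_hom = (n_a - nh) // 2
        n_ref_hom = n - nh - n_alt_hom
        return (
            lg(n + 1) - lg(n_ref_hom + 1) - lg(nh + 1) - lg(n_alt_hom + 1)
            + nh * math.log(2.0)
            + lg(n_a + 1) + lg(n_r + 1) - lg(2 * n + 1)
        )

    parity = n_a % 2
    hets = range(parity, rare + 1, 2)
    logs = {nh: log_prob(nh) for nh in hets}
    obs = logs[n_het]
    # sum probabilities <= P(observed), with a tolerance for ties
    total = sum(math.exp(lp) for lp in logs.values())
    p = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12) / total
    return min(p, 1.0)


def hwe_filter(G: GenotypeMatrix, p_threshold: float = 1e-10) -> GenotypeMatrix:
    """Remove SNPs whose exact Hardy-Weinberg p-value falls below the
    threshold (PLINK ``--hwe`` semantics: remove if p < threshold)."""
    keep = np.ones(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        col = G.dosage[:, j]
        called = col[col != MISSING]
        p = hwe_exact_p(
            int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
        )
        keep[j] = p >= p_threshold
    out = G.take_snps(keep)
    _log_stage("hwe", G.n_snps, out.n_snps)
    return out


def _imputed_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Float dosage with missing entries replaced by the SNP mean
    (used only inside the LD correlation; the matrix itself is untouched)."""
    X = G.dosage.astype(float)
    miss = G.dosage == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)
    idx = np.where(miss)
    X[idx] = col_mean[idx[1]]
    return X


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2: float = 0.9
) -> GenotypeMatrix:
    """PLINK-style ``--indep-pairwise`` pruning on dosage correlations.

    A window of ``window`` SNPs slides by ``step`` along each chromosome;
    within a window, every retained pair with squared Pearson correlation
    of (mean-imputed) dosages above ``r2`` loses its later-positioned
    member.  Zero-variance SNPs correlate with nothing and are retained.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = _imputed_dosage(G)
    keep = np.ones(G.n_snps, dtype=bool)
    chroms = G.snps["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        n = len(cidx)
        for w0 in range(0, max(n - 1, 1), step):
            widx = cidx[w0 : w0 + window]
            if len(widx) < 2:
                continue
            sub = X[:, widx]
            sd = sub.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(sub, rowvar=False)
            for a in range(len(widx)):
                if not keep[widx[a]] or sd[a] == 0:
                    continue
                for b in range(a + 1, len(widx)):
                    if not keep[widx[b]] or sd[b] == 0:
                        continue
                    if corr[a, b] ** 2 > r2:
                        keep[widx[b]] = False
            if w0 + window >= n:
                break
    out = G.take_snps(keep)
    _log_stage("ld_prune", G.n_snps, out.n_snps)
    return out


def apply_preset(G: GenotypeMatrix, preset: str, cfg: FilterConfig | None = None):
    """Run a named filter pipeline; returns (filtered panel, stage log).

    Presets: ``structure`` (MAF 0.02-0.98, zero missing calls, 50-bp thin,
    HWE 1e-10, LD prune 50/5/0.9), ``pca`` (missing rate <= 0.9, LD prune
    at r2 0.5) and ``bayescan`` (folded MAF >= 0.10 prefilter for the
    outlier scan).  The stage log is a list of (stage, SNPs in, SNPs out).
    """
    from rangexpand.fst import remove_rare

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = cfg or FilterConfig()
    log: list[tuple[str, int, int]] = []

    def run(name, fn):
        nonlocal G
        n_in = G.n_snps
        G = fn(G)
        log.append((name, n_in, G.n_snps))

    if preset == "structure":
        run("maf", lambda g: filter_maf(g, cfg.maf_min, cfg.maf_max))
        run("missing", lambda g: filter_missing(g, max_missing_count=cfg.max_missing_count or 0))
        run("thin", lambda g: thin_by_distance(g, cfg.thin_bp))
        run("hwe", lambda g: hwe_filter(g, cfg.hwe_p))
        run("ld", lambda g: ld_prune(g, cfg.ld_window, cfg.ld_step, cfg.ld_r2))
    elif preset == "pca":
        rate = cfg.max_missing_rate if cfg.max_missing_rate is not None else 0.9
        run("missing", lambda g: filter_missing(g, max_missing_rate=rate))
        run("ld", lambda g: ld_prune(g, cfg.ld_window, cfg.ld_step, 0.5))
    elif preset == "bayescan":
        run("rare", lambda g: remove_rare(g, 0.10))
    return G, log


PRESETS = ("structure", "pca", "bayescan")
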