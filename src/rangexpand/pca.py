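"""Genotype PCA with sample projection, plus structure post-processing.

PCA follows the EIGENSTRAT/SNPRelate convention: dosages are standardized
per SNP as (g - 2p) / sqrt(2 p (1 - p)) with p the training alt-allele
frequency and missing entries set to 0 after centering; the genetic
relationship matrix X X^T / m is eigendecomposed.  SNP loadings allow new
samples (standardized with the *training* frequencies) to be projected
onto the fitted components.

The module also covers the admixture post-processing steps: ancestry-
threshold population assignment, the ancestry-vs-location R^2 permutation
statistic, Evanno delta-K, and identity-by-state hierarchical clustering
with newick export.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from rangexpand.genotypes import MISSING, GenotypeMatrix
from rangexpand.filtering import allele_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "fit_pca",
    "project_samples",
    "assign_populations",
    "AncestryLocationResult",
    "ancestry_location_r2",
    "evanno_delta_k",
    "ibs_distance",
    "hierarchical_tree",
    "read_q_matrix",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Fitted genotype PCA.

    ``eigenvalues`` are those of the GRM X X^T / m; ``scores`` are the
    principal-component scores (eigenvector * sqrt(m * eigenvalue), i.e.
    X @ loadings); ``loadings`` columns are orthonormal SNP loadings.
    Component signs are fixed so each loading column's largest-magnitude
    entry is positive.
    """

    sample_ids: list[str]
    snps: pd.DataFrame  # SNPs retained by the fit (zero-variance dropped)
    freqs: np.ndarray  # training alt-allele frequency per retained SNP
    eigenvalues: np.ndarray
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # SNPs x components
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _standardize(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    denom = np.sqrt(2.0 * p * (1.0 - p))
    X = (dosage.astype(float) - 2.0 * p) / denom
    X[dosage == MISSING] = 0.0
    return X


def fit_pca(G: GenotypeMatrix, n_components: int = 10) -> PCAModel:
    """Fit a standardized-genotype PCA (GRM eigendecomposition via SVD)."""
    if G.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    p = allele_frequencies(G)
    ok = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance/monomorphic SNPs before PCA", n_dropped)
    Gk = G.take_snps(ok)
    p = p[ok]
    m = Gk.n_snps
    if n_components > min(G.n_samples, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples={G.n_samples}, SNPs={m})"
        )
    X = _standardize(Gk.dosage, p)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = S**2 / m
    total_var = eigenvalues.sum()  # trace of the GRM
    k = n_components
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # deterministic sign: largest-|loading| entry of each column positive
    signs = np.empty(k)
    for c in range(k):
        signs[c] = np.sign(loadings[np.argmax(np.abs(loadings[:, c])), c]) or 1.0
    loadings *= signs
    scores *= signs
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = eigenvalues[:k] / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(
        sample_ids=list(G.sample_ids),
        snps=Gk.snps,
        freqs=p,
        eigenvalues=eigenvalues[:k],
        scores=scores,
        loadings=loadings,
        variance_explained=ve,
    )


def project_samples(model: PCAModel, G_new: GenotypeMatrix) -> np.ndarray:
    """Project new samples onto a fitted PCA using the training frequencies.

    ``G_new`` must carry the model's SNP set (matched by chrom, pos, ref,
    alt; any order); missing model SNPs raise with the offenders listed.
    Projecting the training panel reproduces its scores.
    """
    if G_new.n_samples == 0:
        raise ValueError("no samples to project")
    model_keys = list(
        zip(model.snps["chrom"], model.snps["pos"], model.snps["ref"], model.snps["alt"])
    )
    new_index = {key: j for j, key in enumerate(G_new.snp_keys())}
    missing = [key for key in model_keys if key not in new_index]
    if missing:
        shown = ", ".join(map(str, missing[:5]))
        raise ValueError(
            f"{len(missing)} model SNPs absent from the new panel (first: {shown})"
        )
    order = np.array([new_index[key] for key in model_keys])
    Z = _standardize(G_new.dosage[:, order], model.freqs)
    return Z @ model.loadings


# ---------------------------------------------------------------------------
# Ancestry post-processing
# ---------------------------------------------------------------------------


def read_q_matrix(path: str) -> pd.DataFrame:
    """Read a TSV Q-matrix with header ``sample, q1..qK``.

    (Raw Structure output files carry the Q block inside a larger report;
    export that block to this TSV layout first — parsing the report format
    itself is out of scope.)
    """
    q = pd.read_csv(path, sep="\t")
    q = q.set_index(q.columns[0])
    _validate_q(q)
    return q


def _validate_q(Q: pd.DataFrame) -> None:
    arr = Q.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("ancestry proportions must lie in [0, 1]")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ancestry rows must sum to 1")


def assign_populations(Q: pd.DataFrame, threshold: float = 0.8) -> pd.Series:
    """Assign each sample to the population whose inferred ancestry
    strictly exceeds ``threshold``; otherwise ``admixed``.

    With threshold >= 0.5 at most one population can exceed it, so the
    assignment is always unique; a row of exactly (threshold, ...) is
    admixed by the strict inequality.
    """
    _validate_q(Q)
    arr = Q.to_numpy(dtype=float)
    best = arr.argmax(axis=1)
    labels = [
        f"pop_{best[i] + 1}" if arr[i, best[i]] > threshold else "admixed"
        for i in range(len(Q))
    ]
    return pd.Series(labels, index=Q.index, name="population")


@dataclass
class AncestryLocationResult:
    """ANOVA-style R^2 of ancestry profiles against a grouping, with a
    label-permutation p-value (add-one rule, never exactly 0)."""

    r_squared: float
    p_value: float
    n_permutations: int


def _r2_stat(q: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = q.mean(axis=0)
    sst = float(((q - grand) ** 2).sum())
    if sst == 0.0:
        return 0.0
    ssw = 0.0
    for g in range(n_groups):
        rows = q[codes == g]
        if len(rows):
            ssw += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return 1.0 - ssw / sst


def ancestry_location_r2(
    Q: pd.DataFrame,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
) -> AncestryLocationResult:
    """R^2 = 1 - SSW/SST of ancestry rows across label groups, with a
    permutation p-value from shuffling the group labels."""
    _validate_q(Q)
    codes, uniques = pd.factorize(np.asarray(labels))
    if len(uniques) < 2:
        raise ValueError("need at least 2 label groups")
    q = Q.to_numpy(dtype=float)
    obs = _r2_stat(q, codes, len(uniques))
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _r2_stat(q, perm, len(uniques)) >= obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return AncestryLocationResult(r_squared=obs, p_value=p, n_permutations=n_perm)


def evanno_delta_k(loglik: pd.DataFrame) -> pd.Series:
    """Evanno delta-K per interior K from a replicate ln P(K) table.

    Expects columns ``K, rep, ln_prob`` with the same replicate count per
    K.  delta-K(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)| /
    sd(L(K)); endpoints are undefined and omitted.  A zero replicate sd
    yields inf with a warning.
    """
    wide = loglik.pivot(index="rep", columns="K", values="ln_prob").sort_index(axis=1)
    ks = wide.columns.to_numpy()
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if wide.shape[0] < 2:
        raise ValueError("need >= 2 replicates per K")
    if wide.isna().any().any():
        raise ValueError("unbalanced replicate table")
    vals = wide.to_numpy()
    out = {}
    for i in range(1, len(ks) - 1):
        second = np.abs(vals[:, i + 1] - 2 * vals[:, i] + vals[:, i - 1]).mean()
        sd = vals[:, i].std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"zero replicate sd at K={ks[i]}; delta-K is infinite")
            out[int(ks[i])] = np.inf if second > 0 else np.nan
        else:
            out[int(ks[i])] = second / sd
    return pd.Series(out, name="delta_k")


# ---------------------------------------------------------------------------
# Distance and trees
# ---------------------------------------------------------------------------


def ibs_distance(G: GenotypeMatrix) -> pd.DataFrame:
    """1 - identity-by-state similarity between samples.

    d(a, b) averages |g_a - g_b| / 2 over SNPs called in both samples;
    identical samples get 0, opposite homozygotes at every SNP get 1.
    """
    if G.n_samples < 2:
        raise ValueError("need >= 2 samples")
    D = G.dosage.astype(float)
    D[G.dosage == MISSING] = np.nan
    n = G.n_samples
    out = np.zeros((n, n))
    for a in range(n):
        diff = np.abs(D[a] - D[a:]) / 2.0
        out[a, a:] = np.nanmean(diff, axis=1)
    out = np.triu(out) + np.triu(out, 1).T
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=G.sample_ids, columns=G.sample_ids)


def hierarchical_tree(
    dist: pd.DataFrame, method: str = "average", canonical: bool = True
) -> str:
    """Agglomerative clustering (UPGMA by default) to a newick string.

    Branch lengths are ultrametric (merge height / 2 minus child height).
    ``canonical=True`` sorts children by their smallest leaf id so the
    output is invariant to the input sample order (up to leaf rotation).
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    ids = list(dist.index)
    # deterministic tie-break: feed samples to scipy in sorted-id order
    order = sorted(range(len(ids)), key=lambda i: str(ids[i]))
    arr = arr[np.ix_(order, order)]
    ids = [ids[i] for i in order]
    Z = linkage(squareform(arr, checks=False), method=method)
    root = to_tree(Z)

    def render(node) -> tuple[str, str, float]:
        """returns (newick fragment sans branch length, min leaf id, height)"""
        if node.is_leaf():
            return str(ids[node.id]), str(ids[node.id]), 0.0
        kids = [render(node.left), render(node.right)]
        if canonical:
            kids.sort(key=lambda t: t[1])
        height = node.dist / 2.0
        parts = [f"{frag}:{height - h:.10g}" for frag, _, h in kids]
        return "(" + ",".join(parts) + ")", min(k[1] for k in kids), height

    frag, _, _ = render(root)
    return frag + ";"
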