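"""Ground-truth synthetic data generators.

Every pipeline stage can be exercised without real sequencing data:

* :func:`simulate_genotype_panel` — Balding-Nichols diploid SNP panels with
  controllable per-population differentiation F and Dirichlet admixture;
* :func:`plant_outlier_snps` — spike divergent SNPs with a known frequency
  differential for outlier-scan power testing;
* :func:`simulate_depth_table` — negative-binomial per-ORF median depth
  tables with known copy-number truth;
* :func:`simulate_strain_contigs` — contigs carrying planted LTR insertions
  with genuine 5-bp target-site duplications, including edge / N-flank /
  truncation / full-element / shared cases;
* :func:`simulate_q_matrix` and :func:`simulate_structure_loglik` — ancestry
  matrices and admixture log-likelihood tables for the structure
  post-processing steps.

All generators are pure functions of their configuration plus a seed: a
single :class:`numpy.random.Generator` is created per call and no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rangexpand.genotypes import GenotypeMatrix
from rangexpand.ltr import RepeatHit

__all__ = [
    "SimPanelConfig",
    "PanelTruth",
    "DepthSimConfig",
    "InsertionCase",
    "InsertionTruth",
    "simulate_genotype_panel",
    "plant_outlier_snps",
    "simulate_depth_table",
    "simulate_strain_contigs",
    "standard_six_cases",
    "simulate_q_matrix",
    "simulate_structure_loglik",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Genotype panels (Balding-Nichols)
# ---------------------------------------------------------------------------


@dataclass
class SimPanelConfig:
    """Balding-Nichols two-or-more-population diploid panel configuration.

    ``fst`` gives the differentiation parameter F for each population:
    population allele frequencies are drawn Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral frequency p, so the expected Weir-Cockerham theta
    between two populations sharing F is approximately F.  F = 0 is the
    degenerate case where population frequencies equal the ancestral ones
    exactly.  ``admixture_alpha`` = 0 gives one-hot ancestry (no admixture);
    positive values draw per-sample ancestry from a symmetric Dirichlet.
    """

    n_pops: int = 2
    pop_sizes: Sequence[int] = (50, 50)
    fst: Sequence[float] = (0.05, 0.05)
    n_snps: int = 2000
    admixture_alpha: float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or len(self.pop_sizes) != self.n_pops:
            raise ConfigError("pop_sizes must list one size per population")
        if any(n < 1 for n in self.pop_sizes):
            raise ConfigError("pop_sizes must all be >= 1")
        if len(self.fst) != self.n_pops:
            raise ConfigError("fst must list one F per population")
        if any(not (0.0 <= f < 1.0) for f in self.fst):
            raise ConfigError("F must lie in [0, 1)")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.admixture_alpha < 0:
            raise ConfigError("admixture_alpha must be >= 0")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("ancestral_freq_range must lie inside (0, 1)")


@dataclass
class PanelTruth:
    """Generative ground truth for a simulated panel."""

    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray  # n_pops x n_snps
    q_true: np.ndarray  # n_samples x n_pops
    pop_labels: list[str]  # nominal population of each sample
    outlier_snps: set[int] = field(default_factory=set)
    outlier_delta: float | None = None


def _pop_name(k: int) -> str:
    return f"pop{k + 1}"


def simulate_genotype_panel(cfg: SimPanelConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Draw a diploid SNP panel under the Balding-Nichols model."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, cfg.n_snps)

    pop_freqs = np.empty((cfg.n_pops, cfg.n_snps))
    for k, F in enumerate(cfg.fst):
        if F == 0.0:
            pop_freqs[k] = p_anc
        else:
            ratio = (1.0 - F) / F
            pop_freqs[k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)

    n_total = int(sum(cfg.pop_sizes))
    membership = np.repeat(np.arange(cfg.n_pops), cfg.pop_sizes)
    if cfg.admixture_alpha == 0.0:
        q = np.zeros((n_total, cfg.n_pops))
        q[np.arange(n_total), membership] = 1.0
    else:
        q = rng.dirichlet([cfg.admixture_alpha] * cfg.n_pops, size=n_total)

    expected = q @ pop_freqs  # per-sample per-SNP alt frequency
    dosage = rng.binomial(2, expected).astype(np.int8)

    pos = np.arange(1, cfg.n_snps + 1) * 100
    ref_idx = rng.integers(0, 4, cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, cfg.n_snps)) % 4
    bases = np.array(list("ACGT"))
    snps = pd.DataFrame(
        {"chrom": "chrI", "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx]}
    )

    counts = {k: 0 for k in range(cfg.n_pops)}
    sample_ids, pop_labels = [], []
    for k in membership:
        counts[k] += 1
        sample_ids.append(f"{_pop_name(k)}_s{counts[k]:03d}")
        pop_labels.append(_pop_name(k))

    G = GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)
    truth = PanelTruth(
        ancestral_freqs=p_anc, pop_freqs=pop_freqs, q_true=q, pop_labels=pop_labels
    )
    return G, truth


def plant_outlier_snps(
    G: GenotypeMatrix,
    truth: PanelTruth,
    n_outliers: int,
    delta: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PanelTruth]:
    """Redraw ``n_outliers`` SNPs with a planted between-population frequency
    differential ``delta`` (pop1 freq p, pop2 freq p + delta, both clipped to
    [0.02, 0.98]); planted indices are recorded in the returned truth.

    Only defined for two-population panels.
    """
    if not (-1.0 < delta < 1.0):
        raise ConfigError("delta must lie in (-1, 1)")
    if n_outliers > G.n_snps:
        raise ConfigError("n_outliers exceeds panel size")
    if truth.pop_freqs.shape[0] != 2:
        raise ConfigError("outlier planting requires a two-population panel")
    if n_outliers == 0:
        return G, truth

    rng = np.random.default_rng(seed)
    idx = rng.choice(G.n_snps, size=n_outliers, replace=False)
    lo = max(0.02, 0.02 - delta)
    hi = min(0.98, 0.98 - delta)
    p1 = rng.uniform(lo, hi, n_outliers)
    p2 = np.clip(p1 + delta, 0.02, 0.98)
    p1 = np.clip(p1, 0.02, 0.98)

    pop_freqs = truth.pop_freqs.copy()
    pop_freqs[0, idx] = p1
    pop_freqs[1, idx] = p2
    expected = truth.q_true @ pop_freqs[:, idx]
    dosage = G.dosage.copy()
    dosage[:, idx] = rng.binomial(2, expected).astype(np.int8)

    new_truth = PanelTruth(
        ancestral_freqs=truth.ancestral_freqs,
        pop_freqs=pop_freqs,
        q_true=truth.q_true,
        pop_labels=list(truth.pop_labels),
        outlier_snps=set(int(i) for i in idx),
        outlier_delta=delta,
    )
    return GenotypeMatrix(G.sample_ids, G.snps, dosage), new_truth


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------


@dataclass
class DepthSimConfig:
    """Negative-binomial per-ORF *median* depth simulation.

    The emulated table entry is the median read depth across an ORF: each
    of ``orf_length`` base positions draws NegBin(mean = mean_depth[s] *
    cn_truth[s, o], size = dispersion) and the entry is their median,
    which is what an ORF-level depth table derived from a pileup reports.
    ``orf_length = 1`` degenerates to one NB draw per entry.  Entries are
    exactly 0 whenever the true copy number is 0 (no mismapping noise —
    the downstream CN statistic uses medians, which are insensitive to a
    noise tail).  The defaults mirror a ~50x short-read survey (observed
    strain medians in real surveys of this kind run roughly 20-75x).
    """

    cn_truth: pd.DataFrame  # samples x ORFs true copy number
    mean_depth: float | Sequence[float] = 50.0
    dispersion: float = 10.0
    orf_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cn_truth.to_numpy() < 0).any():
            raise ConfigError("cn_truth must be nonnegative")
        md = np.atleast_1d(np.asarray(self.mean_depth, dtype=float))
        if (md <= 0).any():
            raise ConfigError("mean_depth must be > 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.orf_length < 1:
            raise ConfigError("orf_length must be >= 1")


def simulate_depth_table(cfg: DepthSimConfig) -> pd.DataFrame:
    """Simulate a median-depth table (rows = ORFs, columns = samples)."""
    rng = np.random.default_rng(cfg.seed)
    cn = cfg.cn_truth.to_numpy(dtype=float)  # samples x orfs
    mean_depth = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.mean_depth, dtype=float)), (cn.shape[0],)
    )
    mu = cn * mean_depth[:, None]
    size = cfg.dispersion
    depth = np.zeros_like(mu)
    pos = mu > 0
    # numpy parameterization: n = size, p = size / (size + mean)
    if cfg.orf_length == 1:
        depth[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
    else:
        draws = rng.negative_binomial(
            size, size / (size + mu[pos, None]), size=(int(pos.sum()), cfg.orf_length)
        )
        depth[pos] = np.median(draws, axis=1)
    return pd.DataFrame(
        depth.T, index=list(cfg.cn_truth.columns), columns=list(cfg.cn_truth.index)
    )


# ---------------------------------------------------------------------------
# LTR-bearing contigs
# ---------------------------------------------------------------------------

# Approximate solo-LTR consensus lengths (bp) per Ty family, and the internal
# coding region length used for full elements.
_LTR_LENGTHS = {"Ty1": 334, "Ty2": 332, "Ty1/2": 333, "Ty3": 340, "Ty4": 371, "Ty5": 251}
_INTERNAL_LENGTH = 4500

_CASE_TAGS = ("normal", "edge", "n_flank", "truncated", "full_element", "shared")


@dataclass
class InsertionCase:
    """Requested planted insertion: one case tag on one (or more) strains."""

    case: str
    strains: Sequence[str]
    family: str = "Ty1"

    def __post_init__(self) -> None:
        if self.case not in _CASE_TAGS:
            raise ConfigError(f"unknown case tag {self.case!r}")
        if self.case == "shared" and len(self.strains) < 2:
            raise ConfigError("shared case needs >= 2 strains")
        if self.case != "shared" and len(self.strains) != 1:
            raise ConfigError("non-shared cases take exactly one strain")


@dataclass
class InsertionTruth:
    """Ground truth for one planted LTR hit and its expected census outcome."""

    strain: str
    contig: str
    start: int  # 1-based inclusive on the contig
    end: int
    family: str
    tsd_5mer: str
    case: str
    catalogued: bool
    discard_reason: str | None  # edge | n_flank | partial | None
    context: str | None  # solo | element_associated
    sharing_group: int | None  # planted byte-identical group id


def standard_six_cases() -> list[InsertionCase]:
    """The standard six-case toy genome: normal solo, full element,
    contig-edge, N-flank, truncated, and shared-in-2-strains."""
    return [
        InsertionCase("normal", ["S1"], "Ty1"),
        InsertionCase("full_element", ["S1"], "Ty2"),
        InsertionCase("edge", ["S1"], "Ty3"),
        InsertionCase("n_flank", ["S2"], "Ty1"),
        InsertionCase("truncated", ["S2"], "Ty4"),
        InsertionCase("shared", ["S1", "S2"], "Ty5"),
    ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_tsd(rng: np.random.Generator) -> str:
    # exclude homopolymers so a planted TSD cannot be mimicked by a slipped
    # mononucleotide run in the random background
    while True:
        t = _random_seq(rng, 5)
        if len(set(t)) > 1:
            return t


def simulate_strain_contigs(
    cases: Sequence[InsertionCase] | None = None,
    seed: int = 0,
    flank_len: int = 400,
) -> tuple[dict[str, dict[str, str]], list[RepeatHit], list[InsertionTruth]]:
    """Build contigs with planted LTR insertions and genuine 5-bp TSDs.

    Returns ``(contigs, hits, truth)`` where ``contigs`` maps strain ->
    contig id -> sequence, ``hits`` is the RepeatMasker-style coordinate
    table a census would consume, and ``truth`` records the expected census
    outcome of every planted LTR hit.  Each case is placed on its own
    contig.  Truncated plants keep only the first 100 bp of the consensus.
    """
    if cases is None:
        cases = standard_six_cases()
    rng = np.random.default_rng(seed)
    if flank_len < 10:
        raise ConfigError("contig flanks too short to host an insertion")

    # one consensus per family per call, shared by all plants of that family
    ltr_seqs = {fam: _random_seq(rng, n) for fam, n in _LTR_LENGTHS.items()}
    internal_seqs = {fam: _random_seq(rng, _INTERNAL_LENGTH) for fam in _LTR_LENGTHS}

    contigs: dict[str, dict[str, str]] = {}
    hits: list[RepeatHit] = []
    truth: list[InsertionTruth] = []
    ctg_counter: dict[str, int] = {}

    def new_contig_id(strain: str) -> str:
        ctg_counter[strain] = ctg_counter.get(strain, 0) + 1
        return f"{strain}_ctg{ctg_counter[strain]}"

    def add_ltr_hit(strain, ctg, start, ltr_len, family, cons_end=None):
        cons_len = _LTR_LENGTHS[family]
        hit = RepeatHit(
            strain=strain,
            contig=ctg,
            start=start,
            end=start + ltr_len - 1,
            strand="+",
            family=family,
            kind="ltr",
            consensus_begin=1,
            consensus_end=cons_end if cons_end is not None else cons_len,
            consensus_length=cons_len,
        )
        hits.append(hit)
        return hit

    group_counter = 0
    for case in cases:
        fam = case.family
        ltr = ltr_seqs[fam]
        if case.case == "shared":
            group_counter += 1
            group: int | None = group_counter
            tsd = _random_tsd(rng)
            insert = tsd + ltr + tsd
            for strain in case.strains:
                ctg = new_contig_id(strain)
                left = _random_seq(rng, flank_len)
                right = _random_seq(rng, flank_len)
                contigs.setdefault(strain, {})[ctg] = left + insert + right
                start = flank_len + 5 + 1
                hit = add_ltr_hit(strain, ctg, start, len(ltr), fam)
                truth.append(
                    InsertionTruth(strain, ctg, hit.start, hit.end, fam, tsd,
                                   "shared", True, None, "solo", group)
                )
            continue

        strain = case.strains[0]
        ctg = new_contig_id(strain)
        left = _random_seq(rng, flank_len)
        right = _random_seq(rng, flank_len)
        tsd = _random_tsd(rng)

        if case.case == "normal":
            contigs.setdefault(strain, {})[ctg] = left + tsd + ltr + tsd + right
            start = flank_len + 5 + 1
            hit = add_ltr_hit(strain, ctg, start, len(ltr), fam)
            truth.append(InsertionTruth(strain, ctg, hit.start, hit.end, fam, tsd,
                                        "normal", True, None, "solo", None))
        elif case.case == "full_element":
            internal = internal_seqs[fam]
            contigs.setdefault(strain, {})[ctg] = (
                left + tsd + ltr + internal + ltr + tsd + right
            )
            s1 = flank_len + 5 + 1
            h1 = add_ltr_hit(strain, ctg, s1, len(ltr), fam)
            s_int = h1.end + 1
            hits.append(
                RepeatHit(strain, ctg, s_int, s_int + len(internal) - 1, "+",
                          fam, "internal", 1, len(internal), len(internal))
            )
            s2 = s_int + len(internal)
            h2 = add_ltr_hit(strain, ctg, s2, len(ltr), fam)
            for h in (h1, h2):
                truth.append(InsertionTruth(strain, ctg, h.start, h.end, fam, tsd,
                                            "full_element", True, None,
                                            "element_associated", None))
        elif case.case == "edge":
            # LTR begins 2 bp into the contig: upstream flank unobtainable
            contigs.setdefault(strain, {})[ctg] = left[:2] + ltr + tsd + right
            hit = add_ltr_hit(strain, ctg, 3, len(ltr), fam)
            truth.append(InsertionTruth(strain, ctg, hit.start, hit.end, fam, tsd,
                                        "edge", False, "edge", None, None))
        elif case.case == "n_flank":
            tsd_n = tsd[:2] + "N" + tsd[3:]
            contigs.setdefault(strain, {})[ctg] = left + tsd_n + ltr + tsd + right
            start = flank_len + 5 + 1
            hit = add_ltr_hit(strain, ctg, start, len(ltr), fam)
            truth.append(InsertionTruth(strain, ctg, hit.start, hit.end, fam, tsd,
                                        "n_flank", False, "n_flank", None, None))
        elif case.case == "truncated":
            part = ltr[:100]
            contigs.setdefault(strain, {})[ctg] = left + tsd + part + tsd + right
            start = flank_len + 5 + 1
            hit = add_ltr_hit(strain, ctg, start, len(part), fam, cons_end=100)
            truth.append(InsertionTruth(strain, ctg, hit.start, hit.end, fam, tsd,
                                        "truncated", False, "partial", None, None))
    return contigs, hits, truth


# ---------------------------------------------------------------------------
# Ancestry matrices and admixture log-likelihood tables
# ---------------------------------------------------------------------------


def simulate_q_matrix(
    n_samples: int,
    K: int,
    alpha: float,
    location_labels: Sequence[str] | None = None,
    location_means: dict[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a samples x K ancestry (Q) matrix of Dirichlet draws.

    With ``location_labels`` given, each location gets a mean ancestry
    vector (either supplied via ``location_means`` or assigned cyclically:
    location i leans toward cluster i mod K) and rows are drawn from a
    Dirichlet re-centred on that mean with total concentration
    ``alpha * K``.  ``alpha = 0`` returns the means exactly (one-hot rows
    when the means are one-hot).  Without labels, rows are symmetric
    Dirichlet(alpha) draws.
    """
    if K < 1:
        raise ConfigError("K must be >= 1")
    if alpha < 0:
        raise ConfigError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    idx = [f"s{i + 1:03d}" for i in range(n_samples)]

    if location_labels is None:
        if alpha == 0:
            raise ConfigError("alpha = 0 requires location means")
        q = rng.dirichlet([alpha] * K, size=n_samples)
    else:
        if len(location_labels) != n_samples:
            raise ConfigError("one location label per sample required")
        locs = list(dict.fromkeys(location_labels))
        if location_means is None:
            means = {}
            for i, loc in enumerate(locs):
                m = np.full(K, 0.1 / max(K - 1, 1)) if K > 1 else np.array([1.0])
                if K > 1:
                    m[i % K] = 0.9
                means[loc] = m
        else:
            means = {loc: np.asarray(m, dtype=float) for loc, m in location_means.items()}
        q = np.empty((n_samples, K))
        for i, loc in enumerate(location_labels):
            m = means[loc]
            if not np.isclose(m.sum(), 1.0):
                raise ConfigError(f"location mean for {loc!r} must sum to 1")
            if alpha == 0:
                q[i] = m
            else:
                conc = np.maximum(m * alpha * K, 1e-12)
                q[i] = rng.dirichlet(conc)
    q = q / q.sum(axis=1, keepdims=True)
    return pd.DataFrame(q, index=idx, columns=[f"q{k + 1}" for k in range(K)])


def simulate_structure_loglik(
    k_range: Sequence[int],
    true_k: int,
    n_reps: int = 5,
    noise_sd: float = 50.0,
    seed: int = 0,
    slope_before: float = 800.0,
    slope_after: float = 40.0,
    base: float = -20000.0,
) -> pd.DataFrame:
    """Simulate replicate admixture log-likelihoods ln P(K) over a K range.

    The replicate mean is piecewise linear in K with a slope break at
    ``true_k`` (steep improvement up to the true cluster number, marginal
    gains after), plus Gaussian replicate noise — the shape the Evanno
    second-difference statistic is designed to detect.
    """
    ks = sorted(int(k) for k in k_range)
    if true_k not in ks:
        raise ConfigError("true_k must lie inside k_range")
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2 (delta-K needs a replicate sd)")
    rng = np.random.default_rng(seed)
    rows = []
    for K in ks:
        if K <= true_k:
            mean = base + slope_before * (K - ks[0])
        else:
            mean = base + slope_before * (true_k - ks[0]) + slope_after * (K - true_k)
        for rep in range(n_reps):
            rows.append((K, rep, mean + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["K", "rep", "ln_prob"])
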