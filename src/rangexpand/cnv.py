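"""Read-depth-ratio ORF copy-number profiling.

Copy number of an ORF in a sample is its median read depth divided by the
sample's overall median depth; here the sample normalizer is the median of
that sample's per-ORF median depths (the table's column median), which a
``normalizer`` override or an ORF exclusion list can replace.  Downstream
steps compare per-population median copy numbers, keep ORFs present in
either population at a median CN of at least 0.5, flag ORFs enriched in
one population by a factor of 2 or more (inclusive), and call the
2-micron plasmid per sample from the median CN of its ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_copy_number",
    "population_median_cn",
    "presence_filter",
    "enrichment_scan",
    "EnrichmentReport",
    "plasmid_status",
]


def compute_copy_number(
    depth: pd.DataFrame,
    normalizer: pd.Series | None = None,
    exclude_orfs: list[str] | None = None,
) -> pd.DataFrame:
    """Convert a depth table (rows = ORFs, columns = samples) to copy numbers.

    ``normalizer`` supplies pre-computed per-sample depths (e.g. per-base
    genome medians) instead of the table's own column medians;
    ``exclude_orfs`` removes rows (e.g. plasmid or mitochondrial ORFs) from
    the median computation only.  A sample whose normalizer is 0 is
    rejected by name.
    """
    if (depth.to_numpy() < 0).any():
        raise ValueError("depth table contains negative values")
    if normalizer is None:
        base = depth.drop(index=exclude_orfs) if exclude_orfs else depth
        normalizer = base.median(axis=0)
    normalizer = normalizer.reindex(depth.columns)
    bad = normalizer[(normalizer <= 0) | normalizer.isna()]
    if len(bad):
        raise ValueError(f"zero/undefined median depth for sample(s): {list(bad.index)}")
    return depth.div(normalizer, axis=1)


def population_median_cn(cn: pd.DataFrame, pop_map: pd.Series | dict) -> pd.DataFrame:
    """Per-ORF median copy number within each population.

    Every sample column must be mapped; even-count medians are midpoints.
    """
    pop_map = pd.Series(pop_map)
    unmapped = [s for s in cn.columns if s not in pop_map.index]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    out = {}
    for pop in sorted(pop_map.unique()):
        samples = [s for s in cn.columns if pop_map[s] == pop]
        out[pop] = cn[samples].median(axis=1)
    return pd.DataFrame(out)


def presence_filter(medians: pd.DataFrame, threshold: float = 0.5) -> pd.Index:
    """ORFs whose median CN reaches ``threshold`` (inclusive) in at least
    one population."""
    return medians.index[(medians >= threshold).any(axis=1)]


@dataclass
class EnrichmentReport:
    """Presence-filtered ORFs enriched toward the focal population."""

    focal: str
    other: str
    present: pd.Index
    enriched: pd.DataFrame  # index = orf; columns focal_median, other_median, factor
    presence_threshold: float
    factor: float


def enrichment_scan(
    medians: pd.DataFrame,
    focal: str,
    other: str,
    factor: float = 2.0,
    presence_threshold: float = 0.5,
    resolution: float | None = None,
) -> EnrichmentReport:
    """ORFs enriched in ``focal`` relative to ``other`` by ``factor`` or more.

    Only ORFs passing the presence filter are tested.  When the other
    population's median is 0 and the focal median passes presence, the ORF
    is enriched with an infinite factor.

    ``resolution`` rounds the population medians to that granularity before
    the presence and ratio tests (0.5 is the natural choice when true copy
    numbers are integers: depth-ratio medians scatter tightly around
    integer values, and a ratio whose true value sits exactly on the
    inclusive ``factor`` boundary would otherwise be decided by estimator
    noise rather than by the underlying copy number).
    """
    if resolution is not None:
        medians = (medians / resolution).round() * resolution
    present = presence_filter(medians, presence_threshold)
    mf = medians.loc[present, focal]
    mo = medians.loc[present, other]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mo > 0, mf / mo, np.where(mf >= presence_threshold, np.inf, 0.0))
    mask = ratio >= factor
    enriched = pd.DataFrame(
        {"focal_median": mf[mask], "other_median": mo[mask], "factor": ratio[mask]}
    )
    return EnrichmentReport(
        focal=focal, other=other, present=present, enriched=enriched,
        presence_threshold=presence_threshold, factor=factor,
    )


def plasmid_status(
    cn: pd.DataFrame, plasmid_orf_ids: list[str], presence_cn: float = 0.5
) -> pd.DataFrame:
    """Per-sample 2-micron plasmid presence and relative copy number.

    The plasmid CN is the median of the plasmid ORFs' copy numbers;
    presence requires that median to reach ``presence_cn``.
    """
    ids = [o for o in plasmid_orf_ids if o in cn.index]
    if not ids:
        raise ValueError("none of the plasmid ORF ids occur in the table")
    plasmid_cn = cn.loc[ids].median(axis=0)
    return pd.DataFrame(
        {"plasmid_cn": plasmid_cn, "present": plasmid_cn >= presence_cn}
    )
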