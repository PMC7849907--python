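"""TSD-anchored LTR retrotransposon insertion census.

From repeat-hit coordinates (RepeatMasker ``.out`` or BED) and strain
contigs, extract LTR sequences with 5-bp flanks, validate target-site
duplications (TSDs), classify solo vs element-associated and full vs
partial hits, deduplicate insertions shared between strains by TSD, flag
population-unique vs ancestral-shared insertions, and export
alignment-ready FASTA.

Coordinates are 1-based inclusive internally; BED I/O converts explicitly.
A TSD is *valid* when both 5-mers are obtainable and N-free — the two
flanks are not required to be byte-identical (post-insertion mutation can
break identity); identity is recorded separately.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatHit",
    "TSD",
    "InsertionRecord",
    "CensusResult",
    "parse_repeat_hits",
    "write_bed",
    "extract_with_flanks",
    "classify_completeness",
    "classify_context",
    "build_catalogue",
    "classify_population_unique",
    "run_census",
    "export_fasta",
    "read_contigs_fasta",
    "write_contigs_fasta",
]

KNOWN_FAMILIES = ("Ty1", "Ty2", "Ty1/2", "Ty3", "Ty4", "Ty5")

# Ty1, Ty2 and Ty1/2 LTRs recombine within the copia-like superfamily; the
# gypsy-like Ty3 and the outliers Ty4/Ty5 each stand alone.
_SUPERFAMILY = {
    "Ty1": "Ty1/2",
    "Ty2": "Ty1/2",
    "Ty1/2": "Ty1/2",
    "Ty3": "Ty3",
    "Ty4": "Ty4",
    "Ty5": "Ty5",
}


class RepeatHitParseError(ValueError):
    """Malformed repeat-hit file."""


@dataclass(frozen=True)
class RepeatHit:
    """One repeat hit on a strain contig (1-based inclusive coordinates)."""

    strain: str
    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    family: str  # one of KNOWN_FAMILIES
    kind: str = "ltr"  # "ltr" or "internal"
    consensus_begin: int | None = None
    consensus_end: int | None = None
    consensus_length: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.family not in KNOWN_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def superfamily(self) -> str:
        return _SUPERFAMILY[self.family]


@dataclass(frozen=True)
class TSD:
    """The 5-bp flanks of an LTR hit, in element orientation."""

    upstream: str | None
    downstream: str | None
    status: str  # valid | contains_N | edge_undeterminable

    @property
    def identical(self) -> bool:
        return (
            self.status == "valid"
            and self.upstream is not None
            and self.upstream == self.downstream
        )


@dataclass(frozen=True)
class InsertionRecord:
    """One catalogued (or discarded) LTR insertion."""

    hit: RepeatHit
    sequence: str
    tsd: TSD
    completeness: str  # full | partial
    context: str | None = None  # solo | element_associated
    provenance: str = "focal"  # focal | reference_panel
    population_status: str | None = None  # unique | shared_ancestral
    shared_strains: tuple[str, ...] = ()

    def sharing_key(self, tsd_only: bool = False) -> tuple:
        key = (self.hit.family, self.tsd.upstream, self.tsd.downstream)
        return key if tsd_only else key + (self.sequence,)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _normalize_family(name: str) -> tuple[str, str] | None:
    """Map a repeat-library name onto (family, kind); None when unknown."""
    raw = name.strip()
    kind = "ltr"
    up = raw.upper().replace("-", "_")
    for suffix in ("_I", "_INT", "_INTERNAL"):
        if up.endswith(suffix):
            kind = "internal"
            up = up[: -len(suffix)]
            break
    if up.endswith("_LTR"):
        up = up[:-4]
    up = up.replace("TY1/TY2", "TY1/2")
    mapping = {"TY1": "Ty1", "TY2": "Ty2", "TY1/2": "Ty1/2", "TY3": "Ty3",
               "TY4": "Ty4", "TY5": "Ty5"}
    fam = mapping.get(up)
    return None if fam is None else (fam, kind)


def parse_repeat_hits(path: str, fmt: str = "rm_out", strain: str | None = None):
    """Parse repeat hits from RepeatMasker ``.out`` or BED.

    ``rm_out`` skips the fixed three-line header; BED intervals (0-based,
    half-open) are converted to 1-based inclusive.  BED columns are
    ``contig start end name score strand`` with three optional extra
    columns ``consensus_begin consensus_end consensus_length`` (written by
    :func:`write_bed` so that a round trip preserves the hit list).
    Hits with a repeat name outside the Ty1-Ty5 LTR/internal set are
    skipped with a warning; structurally malformed lines raise with the
    line number.
    """
    if fmt not in ("rm_out", "bed"):
        raise ValueError(f"unknown format {fmt!r}")
    if strain is None:
        stem = str(path).rsplit("/", 1)[-1]
        strain = stem.split(".")[0]
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if fmt == "rm_out":
                f = line.split()
                if f[0] in ("SW", "score") or f[0].startswith("There"):
                    continue  # header / no-hits banner
                try:
                    int(f[0])
                except ValueError:
                    continue  # second header line
                if len(f) < 14:
                    raise RepeatHitParseError(f"{path}:{lineno}: truncated .out line")
                try:
                    contig, start, end = f[4], int(f[5]), int(f[6])
                    strand = "+" if f[8] == "+" else "-"
                    name = f[9]
                    if strand == "+":
                        cb, ce = int(f[11]), int(f[12])
                        left = int(f[13].strip("()"))
                    else:  # complement hits swap the repeat-coordinate columns
                        left = int(f[11].strip("()"))
                        ce, cb = int(f[12]), int(f[13])
                    clen = ce + left
                except (ValueError, IndexError) as exc:
                    raise RepeatHitParseError(
                        f"{path}:{lineno}: malformed .out line"
                    ) from exc
            else:
                f = line.split("\t") if "\t" in line else line.split()
                if len(f) < 4:
                    raise RepeatHitParseError(f"{path}:{lineno}: need >=4 BED columns")
                try:
                    contig = f[0]
                    start = int(f[1]) + 1  # 0-based half-open -> 1-based inclusive
                    end = int(f[2])
                    name = f[3]
                    strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
                    cb = int(f[6]) if len(f) > 8 and f[6] != "." else None
                    ce = int(f[7]) if len(f) > 8 and f[7] != "." else None
                    clen = int(f[8]) if len(f) > 8 and f[8] != "." else None
                except ValueError as exc:
                    raise RepeatHitParseError(
                        f"{path}:{lineno}: malformed BED line"
                    ) from exc
            norm = _normalize_family(name)
            if norm is None:
                logger.warning("%s:%d: skipping unknown repeat %r", path, lineno, name)
                continue
            fam, kind = norm
            hits.append(
                RepeatHit(strain, contig, start, end, strand, fam, kind, cb, ce, clen)
            )
    return hits


def write_bed(hits: Iterable[RepeatHit], path: str) -> None:
    """Write hits as 9-column BED (0-based half-open + consensus span)."""
    with open(path, "w") as fh:
        for h in hits:
            name = h.family + ("_I" if h.kind == "internal" else "_LTR")
            cb = "." if h.consensus_begin is None else h.consensus_begin
            ce = "." if h.consensus_end is None else h.consensus_end
            cl = "." if h.consensus_length is None else h.consensus_length
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{name}\t0\t{h.strand}"
                f"\t{cb}\t{ce}\t{cl}\n"
            )


def read_contigs_fasta(path: str) -> dict[str, str]:
    """Read a multi-FASTA of contigs into {contig id: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_contigs_fasta(contigs: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Extraction and classification
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_with_flanks(
    contigs: Mapping[str, str], hit: RepeatHit, flank: int = 5
) -> tuple[str, TSD]:
    """Extract the LTR sequence plus its two flanking 5-mers.

    Reverse-strand hits are reverse-complemented, with the flanks swapped
    and complemented so the TSD is reported in element orientation.  The
    TSD status is ``edge_undeterminable`` when either flank window leaves
    the contig and ``contains_N`` when either flank contains an N.
    """
    if hit.contig not in contigs:
        raise KeyError(f"contig {hit.contig!r} not found for strain {hit.strain!r}")
    seq = contigs[hit.contig].upper()
    if hit.end > len(seq):
        raise ValueError(f"hit {hit.start}..{hit.end} exceeds contig length {len(seq)}")
    ltr = seq[hit.start - 1 : hit.end]

    up = seq[hit.start - 1 - flank : hit.start - 1] if hit.start - flank >= 1 else None
    down = seq[hit.end : hit.end + flank] if hit.end + flank <= len(seq) else None

    if hit.strand == "-":
        ltr = _revcomp(ltr)
        up, down = (
            _revcomp(down) if down is not None else None,
            _revcomp(up) if up is not None else None,
        )

    if up is None or down is None:
        status = "edge_undeterminable"
    elif "N" in up or "N" in down:
        status = "contains_N"
    else:
        status = "valid"
    return ltr, TSD(up, down, status)


def classify_completeness(hit: RepeatHit, min_consensus_frac: float = 0.9) -> str:
    """``full`` iff the matched consensus span covers at least
    ``min_consensus_frac`` of the consensus length (inclusive boundary)."""
    if hit.consensus_length is None or hit.consensus_begin is None or hit.consensus_end is None:
        logger.warning(
            "hit %s:%d-%d lacks a consensus span; classified partial",
            hit.contig, hit.start, hit.end,
        )
        return "partial"
    span = hit.consensus_end - hit.consensus_begin + 1
    return "full" if span >= min_consensus_frac * hit.consensus_length else "partial"


def classify_context(
    hits: Sequence[RepeatHit],
    max_gap: int = 50,
    max_element_span: int = 7000,
) -> dict[RepeatHit, str]:
    """Classify each LTR hit as ``solo`` or ``element_associated``.

    An LTR is element-associated when a same-superfamily internal-region
    hit on the same contig begins within ``max_gap`` bp of the LTR's inner
    boundary, or when a second same-superfamily LTR lies within
    ``max_element_span`` bp with an internal hit between the two.
    """
    by_contig: dict[tuple[str, str], list[RepeatHit]] = defaultdict(list)
    for h in hits:
        by_contig[(h.strain, h.contig)].append(h)
    out: dict[RepeatHit, str] = {}
    for group in by_contig.values():
        group = sorted(group, key=lambda h: (h.start, h.end))
        ltrs = [h for h in group if h.kind == "ltr"]
        internals = [h for h in group if h.kind == "internal"]
        for ltr in ltrs:
            assoc = False
            for intl in internals:
                if intl.superfamily != ltr.superfamily:
                    continue
                gap_right = intl.start - ltr.end - 1
                gap_left = ltr.start - intl.end - 1
                if 0 <= gap_right <= max_gap or 0 <= gap_left <= max_gap:
                    assoc = True
                    break
            if not assoc:
                for other in ltrs:
                    if other is ltr or other.superfamily != ltr.superfamily:
                        continue
                    lo, hi = min(ltr.start, other.start), max(ltr.end, other.end)
                    if hi - lo + 1 > max_element_span:
                        continue
                    if any(
                        i.superfamily == ltr.superfamily and lo < i.start and i.end < hi
                        for i in internals
                    ):
                        assoc = True
                        break
            out[ltr] = "element_associated" if assoc else "solo"
    return out


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------


def build_catalogue(
    records: Sequence[InsertionRecord],
    reference_panel_ids: Sequence[str] = (),
    tsd_only: bool = False,
) -> list[InsertionRecord]:
    """Deduplicate insertions shared between strains.

    The sharing key is (family, upstream 5-mer, downstream 5-mer, LTR
    sequence); ``tsd_only=True`` drops the sequence from the key.  Records
    with equal keys collapse to one representative, preferring
    reference-panel provenance, then the lexicographically smallest strain
    id.  Records must already be TSD-valid and full-length.
    """
    panel = set(reference_panel_ids)
    for r in records:
        if r.tsd.status != "valid" or r.completeness != "full":
            raise ValueError(
                "catalogue input must be pre-filtered to valid-TSD, full-length records"
            )
    groups: dict[tuple, list[InsertionRecord]] = defaultdict(list)
    for r in records:
        groups[r.sharing_key(tsd_only)].append(r)
    reps: list[InsertionRecord] = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        members.sort(
            key=lambda r: (r.hit.strain not in panel, r.hit.strain, r.hit.contig, r.hit.start)
        )
        rep = members[0]
        shared = tuple(sorted({m.hit.strain for m in members}))
        prov = "reference_panel" if rep.hit.strain in panel else "focal"
        reps.append(replace(rep, provenance=prov, shared_strains=shared))
    reps.sort(key=lambda r: (r.hit.strain, r.hit.contig, r.hit.start))
    return reps


def classify_population_unique(
    catalogue: Sequence[InsertionRecord], reference_panel_ids: Sequence[str] = ()
) -> list[InsertionRecord]:
    """Mark each representative ``unique`` (focal-population only) or
    ``shared_ancestral`` (the same insertion occurs in a reference-panel
    strain, i.e. it predates the focal population's isolation)."""
    panel = set(reference_panel_ids)
    out = []
    for r in catalogue:
        in_panel = bool(panel.intersection(r.shared_strains)) or r.hit.strain in panel
        out.append(replace(r, population_status="shared_ancestral" if in_panel else "unique"))
    return out


@dataclass
class CensusResult:
    """End-to-end census output: catalogue plus discard log and counts."""

    catalogue: list[InsertionRecord]
    discarded: list[tuple[RepeatHit, str]]  # (hit, reason in {edge, n_flank, partial})
    summary: dict


def run_census(
    contigs_by_strain: Mapping[str, Mapping[str, str]],
    hits: Sequence[RepeatHit],
    reference_panel_ids: Sequence[str] = (),
    min_consensus_frac: float = 0.9,
    max_gap: int = 50,
    max_element_span: int = 7000,
    tsd_only: bool = False,
) -> CensusResult:
    """Full census: extract, validate, classify, deduplicate, annotate."""
    context = classify_context(hits, max_gap=max_gap, max_element_span=max_element_span)
    records: list[InsertionRecord] = []
    discarded: list[tuple[RepeatHit, str]] = []
    for hit in hits:
        if hit.kind != "ltr":
            continue
        seq, tsd = extract_with_flanks(contigs_by_strain[hit.strain], hit)
        completeness = classify_completeness(hit, min_consensus_frac)
        if tsd.status == "edge_undeterminable":
            discarded.append((hit, "edge"))
            continue
        if tsd.status == "contains_N":
            discarded.append((hit, "n_flank"))
            continue
        if completeness == "partial":
            discarded.append((hit, "partial"))
            continue
        records.append(
            InsertionRecord(
                hit=hit,
                sequence=seq,
                tsd=tsd,
                completeness=completeness,
                context=context[hit],
                provenance=(
                    "reference_panel" if hit.strain in set(reference_panel_ids) else "focal"
                ),
            )
        )
    catalogue = build_catalogue(records, reference_panel_ids, tsd_only=tsd_only)
    catalogue = classify_population_unique(catalogue, reference_panel_ids)

    summary: dict = {"families": {}, "discarded": defaultdict(int)}
    for _, reason in discarded:
        summary["discarded"][reason] += 1
    summary["discarded"] = dict(summary["discarded"])
    summary["n_hits"] = sum(1 for h in hits if h.kind == "ltr")
    summary["n_catalogued_records"] = len(records)
    summary["n_representatives"] = len(catalogue)
    for fam in KNOWN_FAMILIES:
        fam_reps = [r for r in catalogue if r.hit.family == fam]
        if not fam_reps:
            continue
        summary["families"][fam] = {
            "total": len(fam_reps),
            "solo": sum(1 for r in fam_reps if r.context == "solo"),
            "element_associated": sum(
                1 for r in fam_reps if r.context == "element_associated"
            ),
            "unique": sum(1 for r in fam_reps if r.population_status == "unique"),
            "shared_ancestral": sum(
                1 for r in fam_reps if r.population_status == "shared_ancestral"
            ),
        }
    return CensusResult(catalogue=catalogue, discarded=discarded, summary=summary)


def export_fasta(
    catalogue: Sequence[InsertionRecord], path: str, family: str | None = None
) -> int:
    """Write alignment-ready FASTA of catalogue representatives.

    Record ids are ``strain|contig|start-end|family|status``; sequences are
    upper-case and strand-normalized.  Returns the number of records
    written; an empty selection writes an empty file with a warning.
    """
    recs = [r for r in catalogue if family is None or r.hit.family == family]
    if not recs:
        logger.warning("no catalogue records for family %r; writing empty FASTA", family)
    out = []
    for r in recs:
        status = r.population_status or "unclassified"
        fam = r.hit.family.replace("/", "-")
        rid = f"{r.hit.strain}|{r.hit.contig}|{r.hit.start}-{r.hit.end}|{fam}|{status}"
        out.append(SeqRecord(Seq(r.sequence.upper()), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")
    return len(out)
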