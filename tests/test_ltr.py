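"""LTR census: parsing, flank extraction, classification, dedup, export."""

import random

import pytest
from Bio import SeqIO

from rangexpand import synthetic
from rangexpand.ltr import (
    InsertionRecord,
    RepeatHit,
    RepeatHitParseError,
    TSD,
    build_catalogue,
    classify_completeness,
    classify_context,
    classify_population_unique,
    export_fasta,
    extract_with_flanks,
    parse_repeat_hits,
    run_census,
    write_bed,
)

RM_OUT = """\
   SW   perc perc perc  query      position in query           matching       repeat              position in repeat
score   div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

  2013   9.4  0.0  0.0  ctg1          101     434  (5000) +   TY1_LTR        LTR/Copia                1  334    (0)     1
  1500  10.1  0.2  0.0  ctg1         5001    5332  (100)  C   TY2_LTR        LTR/Copia              (0)  332      1     2
   900  12.0  0.5  0.1  ctg2          201     300  (9000) +   TY4_LTR        LTR/Ty4                  1  100  (271)     3
   400  15.0  0.0  0.0  ctg2         1000    1100  (8000) +   WEIRD_REPEAT   Unknown                  1  101    (0)     4
"""


class TestParsing:
    def test_handcrafted_out_file(self, tmp_path):
        path = tmp_path / "strainX.out"
        path.write_text(RM_OUT)
        hits = parse_repeat_hits(str(path), fmt="rm_out")
        assert len(hits) == 3  # unknown repeat skipped with warning
        h1, h2, h3 = hits
        assert (h1.strain, h1.contig, h1.start, h1.end) == ("strainX", "ctg1", 101, 434)
        assert h1.family == "Ty1" and h1.strand == "+" and h1.consensus_length == 334
        assert h2.strand == "-" and h2.family == "Ty2"
        assert (h2.consensus_begin, h2.consensus_end, h2.consensus_length) == (1, 332, 332)
        assert h3.consensus_length == 371  # 100 matched + 271 left

    def test_bed_coordinate_convention(self, tmp_path):
        path = tmp_path / "hits.bed"
        path.write_text("ctg1\t99\t199\tTY3_LTR\t0\t+\n")
        (hit,) = parse_repeat_hits(str(path), fmt="bed", strain="S")
        assert (hit.start, hit.end) == (100, 199)
        assert hit.family == "Ty3"

    def test_round_trip_out_to_bed(self, tmp_path):
        out_path = tmp_path / "strainX.out"
        out_path.write_text(RM_OUT)
        hits = parse_repeat_hits(str(out_path), fmt="rm_out")
        bed_path = tmp_path / "strainX.bed"
        write_bed(hits, str(bed_path))
        again = parse_repeat_hits(str(bed_path), fmt="bed", strain="strainX")
        assert again == hits

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("ctg1\t99\t199\tTY3_LTR\n" "ctg1\tnot_an_int\t5\tTY1_LTR\n")
        with pytest.raises(RepeatHitParseError, match=":2"):
            parse_repeat_hits(str(path), fmt="bed")


class TestExtraction:
    def _hit(self, start, end, strand="+", contig="c", family="Ty1"):
        return RepeatHit("S", contig, start, end, strand, family, "ltr", 1, 334, 334)

    def test_planted_normal_flanks_match(self):
        contigs, hits, truth = synthetic.simulate_strain_contigs(seed=0)
        by_loc = {(t.strain, t.contig, t.start): t for t in truth}
        for hit in hits:
            t = by_loc.get((hit.strain, hit.contig, hit.start))
            if t is None or t.case != "normal":
                continue
            _, tsd = extract_with_flanks(contigs[hit.strain], hit)
            assert tsd.status == "valid"
            assert tsd.upstream == tsd.downstream == t.tsd_5mer
            assert tsd.identical

    def test_hit_near_contig_start_is_edge(self):
        contigs = {"c": "AA" + "G" * 50 + "T" * 20}
        hit = self._hit(3, 52)
        _, tsd = extract_with_flanks(contigs, hit)
        assert tsd.status == "edge_undeterminable" and tsd.upstream is None

    def test_n_in_flank(self):
        contigs = {"c": "ACNGT" + "G" * 40 + "CCCCC" + "A" * 10}
        hit = self._hit(6, 45)
        _, tsd = extract_with_flanks(contigs, hit)
        assert tsd.status == "contains_N"

    def test_reverse_strand_orientation(self):
        up, ltr, down = "ACGTA", "GGGTTTCCC", "TGCAT"
        contigs = {"c": "AAAA" + up + ltr + down + "AAAA"}
        hit = self._hit(10, 18, strand="-")
        seq, tsd = extract_with_flanks(contigs, hit)
        assert seq == "GGGAAACCC"  # revcomp of the planted LTR
        assert tsd.upstream == "ATGCA"  # revcomp of the downstream flank
        assert tsd.downstream == "TACGT"
        assert tsd.status == "valid"

    def test_missing_contig_rejected(self):
        with pytest.raises(KeyError):
            extract_with_flanks({}, self._hit(10, 20))


class TestCompleteness:
    @pytest.mark.parametrize(
        "span,expected",
        [((1, 330), "full"), ((1, 100), "partial"), ((21, 310), "partial"),
         ((1, 300), "full")],  # 300/333 < 0.9? no: 0.9009 -> inclusive full
    )
    def test_consensus_fraction(self, span, expected):
        hit = RepeatHit("S", "c", 1, span[1] - span[0] + 1, "+", "Ty1", "ltr",
                        span[0], span[1], 333)
        assert classify_completeness(hit, 0.9) == expected

    def test_exact_boundary_inclusive(self):
        hit = RepeatHit("S", "c", 1, 270, "+", "Ty1", "ltr", 1, 270, 300)
        assert classify_completeness(hit, 0.9) == "full"  # exactly 0.9

    def test_missing_consensus_warns_partial(self):
        hit = RepeatHit("S", "c", 1, 300, "+", "Ty1", "ltr")
        assert classify_completeness(hit) == "partial"


class TestContext:
    def _ltr(self, start, end, family="Ty1", contig="c"):
        return RepeatHit("S", contig, start, end, "+", family, "ltr", 1, 334, 334)

    def _internal(self, start, end, family="Ty1", contig="c"):
        return RepeatHit("S", contig, start, end, "+", family, "internal",
                         1, 4500, 4500)

    def test_full_element_both_ltrs_associated(self):
        hits = [self._ltr(100, 433), self._internal(434, 4933),
                self._ltr(4934, 5267)]
        ctx = classify_context(hits)
        assert ctx[hits[0]] == ctx[hits[2]] == "element_associated"

    def test_isolated_ltr_is_solo(self):
        hits = [self._ltr(100, 433)]
        assert classify_context(hits)[hits[0]] == "solo"

    def test_distant_ltr_pair_without_internal_is_solo(self):
        hits = [self._ltr(100, 433), self._ltr(20100, 20433)]
        ctx = classify_context(hits)
        assert all(v == "solo" for v in ctx.values())

    def test_superfamily_mismatch_stays_solo(self):
        hits = [self._ltr(100, 433, family="Ty3"), self._internal(440, 4940)]
        assert classify_context(hits)[hits[0]] == "solo"

    def test_ty1_ltr_pairs_with_ty2_internal(self):
        # Ty1 and Ty2 share the copia-like superfamily
        hits = [self._ltr(100, 433, family="Ty1"),
                self._internal(440, 4940, family="Ty2")]
        assert classify_context(hits)[hits[0]] == "element_associated"


def _record(strain, seq="ACGT" * 90, up="ACGTA", down="ACGTA", family="Ty1",
            contig="c1", start=100):
    hit = RepeatHit(strain, contig, start, start + len(seq) - 1, "+", family,
                    "ltr", 1, len(seq), len(seq))
    return InsertionRecord(hit=hit, sequence=seq, tsd=TSD(up, down, "valid"),
                           completeness="full")


class TestCatalogue:
    def test_same_insertion_two_strains_one_representative(self):
        recs = [_record("S1"), _record("S2")]
        cat = build_catalogue(recs)
        assert len(cat) == 1
        assert cat[0].hit.strain == "S1"  # lexicographically smallest
        assert cat[0].shared_strains == ("S1", "S2")

    def test_same_site_different_tsd_kept_separate(self):
        recs = [_record("S1", up="ACGTA"), _record("S2", up="TTTCA")]
        assert len(build_catalogue(recs)) == 2

    def test_hand_walked_mixed_panel(self):
        """10 crafted records with 3 shared pairs -> 7 representatives,
        panel strains preferred as representatives."""
        recs = [
            _record("S1", seq="A" * 100),             # pair 1 (with SGRP1)
            _record("SGRP1", seq="A" * 100),
            _record("S2", seq="C" * 100),             # pair 2 (focal only)
            _record("S3", seq="C" * 100),
            _record("S4", seq="G" * 100),             # pair 3 (focal only)
            _record("S5", seq="G" * 100),
            _record("S6", seq="T" * 100),
            _record("S7", seq="AC" * 50),
            _record("SGRP2", seq="GT" * 50),
            _record("S8", seq="TG" * 50),
        ]
        cat = build_catalogue(recs, reference_panel_ids=["SGRP1", "SGRP2"])
        assert len(cat) == 7
        pair1 = [r for r in cat if r.sequence == "A" * 100]
        assert pair1[0].hit.strain == "SGRP1"
        assert pair1[0].provenance == "reference_panel"

    def test_dedup_order_independent(self):
        recs = [_record(f"S{i}", seq="AC" * 50 if i % 2 else "GT" * 50)
                for i in range(8)]
        cat1 = build_catalogue(recs)
        shuffled = recs[:]
        random.Random(0).shuffle(shuffled)
        cat2 = build_catalogue(shuffled)
        assert cat1 == cat2

    def test_prefiltered_input_enforced(self):
        bad = InsertionRecord(
            hit=RepeatHit("S", "c", 1, 10, "+", "Ty1", "ltr", 1, 334, 334),
            sequence="ACGTACGTAC", tsd=TSD(None, "ACGTA", "edge_undeterminable"),
            completeness="full",
        )
        with pytest.raises(ValueError):
            build_catalogue([bad])

    def test_population_unique_vs_ancestral(self):
        cat = build_catalogue(
            [_record("S1", seq="A" * 60), _record("SGRP1", seq="C" * 60)],
            reference_panel_ids=["SGRP1"],
        )
        cat = classify_population_unique(cat, ["SGRP1"])
        by_seq = {r.sequence[0]: r.population_status for r in cat}
        assert by_seq == {"A": "unique", "C": "shared_ancestral"}


class TestEndToEndCensus:
    @pytest.mark.parametrize("seed", range(5))
    def test_six_case_census_matches_truth(self, seed):
        """The standard six-case genome reproduces the generator truth table
        exactly: discard reasons, solo/element calls, dedup, uniqueness."""
        contigs, hits, truth = synthetic.simulate_strain_contigs(seed=seed)
        res = run_census(contigs, hits)

        expected_discards = sorted(
            (t.strain, t.contig, t.discard_reason)
            for t in truth if not t.catalogued
        )
        got_discards = sorted((h.strain, h.contig, r) for h, r in res.discarded)
        assert got_discards == expected_discards

        truth_by_loc = {(t.strain, t.contig, t.start): t for t in truth}
        # every catalogued truth hit appears via its dedup representative
        kept_truth = [t for t in truth if t.catalogued]
        shared = [t for t in kept_truth if t.case == "shared"]
        n_expected_reps = len(kept_truth) - (len(shared) - 1)
        assert len(res.catalogue) == n_expected_reps

        for rep in res.catalogue:
            t = truth_by_loc[(rep.hit.strain, rep.hit.contig, rep.hit.start)]
            assert rep.context == t.context
            assert rep.population_status == "unique"  # no panel strains here
            if t.case == "shared":
                assert set(rep.shared_strains) == {"S1", "S2"}

    def test_shared_with_panel_strain_is_ancestral(self):
        cases = [
            synthetic.InsertionCase("normal", ["NZ1"], "Ty1"),
            synthetic.InsertionCase("shared", ["NZ1", "SGRP1"], "Ty3"),
        ]
        contigs, hits, truth = synthetic.simulate_strain_contigs(cases, seed=4)
        res = run_census(contigs, hits, reference_panel_ids=["SGRP1"])
        status = {r.hit.family: r.population_status for r in res.catalogue}
        assert status == {"Ty1": "unique", "Ty3": "shared_ancestral"}
        ty3 = [r for r in res.catalogue if r.hit.family == "Ty3"]
        assert ty3[0].hit.strain == "SGRP1"  # panel preferred representative


class TestExport:
    def test_fasta_round_trip_and_unique_ids(self, tmp_path):
        contigs, hits, _ = synthetic.simulate_strain_contigs(seed=1)
        res = run_census(contigs, hits)
        path = tmp_path / "ltrs.fasta"
        n = export_fasta(res.catalogue, str(path))
        records = list(SeqIO.parse(str(path), "fasta"))
        assert len(records) == n == len(res.catalogue)
        ids = [r.id for r in records]
        assert len(set(ids)) == len(ids)
        by_seq = {str(r.seq) for r in records}
        assert by_seq == {r.sequence.upper() for r in res.catalogue}
        for rid in ids:
            strain, contig, span, fam, status = rid.split("|")
            assert status in ("unique", "shared_ancestral")

    def test_empty_family_warns(self, tmp_path):
        contigs, hits, _ = synthetic.simulate_strain_contigs(seed=1)
        res = run_census(contigs, hits)
        path = tmp_path / "empty.fasta"
        assert export_fasta(res.catalogue, str(path), family="Ty3") == 0
        assert path.read_text() == ""
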