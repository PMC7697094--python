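"""Microexon classification, expression filter, placement, motifs, cognates."""

import numpy as np
import pytest

import mecirc as mc
from mecirc._seq import revcomp
from mecirc.microexon import cognate_summary, classify_position

from conftest import build_gene, rand_seq
from oracles import naive_placements


def _circ(chrom="chr1", start=1000, end=2000, strand="+", gene="g", kind="canonical",
          exons=(1, 2, 3), insert="", count=5):
    return mc.CircRNACall(chrom, start, end, strand, gene, tuple(exons), kind, insert, count)


class TestClassifyPosition:
    @pytest.mark.parametrize("strand", "+-")
    def test_terminal_and_body_rules(self, strand):
        circ = _circ(start=1000, end=2000, strand=strand)
        five = "junction_5p" if strand == "+" else "junction_3p"
        three = "junction_3p" if strand == "+" else "junction_5p"
        assert classify_position(1000, 1010, circ) == five
        assert classify_position(1990, 2000, circ) == three
        assert classify_position(1500, 1510, circ) == "body"
        assert classify_position(900, 950, circ) is None
        assert classify_position(990, 1005, circ) is None  # straddles the edge

    def test_exhaustive_trichotomy_over_all_offsets(self):
        """Sliding a 10-nt ME across a span labels every placement exactly
        once as 5'/3'/body/no-call, matching direct interval arithmetic."""
        circ = _circ(start=100, end=200, strand="+")
        for s in range(60, 240):
            e = s + 10
            got = classify_position(s, e, circ)
            if e <= 100 or s >= 200 or s < 100 or e > 200:
                expected = None
            elif s == 100:
                expected = "junction_5p"
            elif e == 200:
                expected = "junction_3p"
            else:
                expected = "body"
            assert got == expected, (s, e)


def _three_exon_gene(strand="+", seed=2):
    rng = np.random.default_rng(seed)
    exons = [rand_seq(rng, 30), rand_seq(rng, 9), rand_seq(rng, 30)]
    introns = ["GT" + rand_seq(rng, 40) + "AG"] * 2
    return build_gene("g", "chrM", strand, exons, introns)


class TestExpressionFilter:
    def test_covered_me_kept_uncovered_dropped(self):
        genome, model = _three_exon_gene()
        models = {"g": model}
        me_exon = model.exon(2)
        me = mc.KnownME(me_exon.chrom, me_exon.start, me_exon.end, "+", "me1", "g")
        other = mc.KnownME(me_exon.chrom, me_exon.start, me_exon.end, "-", "wrongstrand", "")
        read = model.exon(1).sequence[-12:] + me_exon.sequence + model.exon(3).sequence[:12]
        kept = mc.filter_expressed_known_mes([("r1", read)], [me], models, genome)
        assert kept == [me]
        assert mc.filter_expressed_known_mes([("r1", "ACGT" * 30)], [me], models, genome) == []
        # opposite-strand ME has no host gene -> orphan, excluded
        assert mc.filter_expressed_known_mes([("r1", read)], [other], models, genome) == []

    def test_me_only_read_without_exon_anchor_dropped(self):
        """A read containing the ME but not reaching a flanking exon fails
        the oracle substring (ME + >=anchor nt of exon) and is dropped."""
        genome, model = _three_exon_gene()
        models = {"g": model}
        me_exon = model.exon(2)
        me = mc.KnownME(me_exon.chrom, me_exon.start, me_exon.end, "+", "me1", "g")
        bare = "A" * 20 + me_exon.sequence + "C" * 20
        assert mc.filter_expressed_known_mes([("r1", bare)], [me], models, genome) == []
        short_anchor = me_exon.sequence + model.exon(3).sequence[:5]
        assert (
            mc.filter_expressed_known_mes([("r1", short_anchor)], [me], models, genome)
            == []
        )

    def test_require_both_needs_full_crossing_read(self):
        genome, model = _three_exon_gene()
        models = {"g": model}
        me_exon = model.exon(2)
        me = mc.KnownME(me_exon.chrom, me_exon.start, me_exon.end, "+", "me1", "g")
        one_side = me_exon.sequence + model.exon(3).sequence[:12]
        both = model.exon(1).sequence[-10:] + me_exon.sequence + model.exon(3).sequence[:10]
        assert mc.filter_expressed_known_mes(
            [("r", one_side)], [me], models, genome, require_both=True) == []
        assert mc.filter_expressed_known_mes(
            [("r", both)], [me], models, genome, require_both=True) == [me]


class TestOverlapKnownMes:
    def test_positions_and_strand_rule(self):
        genome, model = _three_exon_gene()
        me_exon = model.exon(2)
        circ = _circ(chrom="chrM", start=model.exon(1).start, end=model.exon(3).end,
                     strand="+", gene="g")
        body_me = mc.KnownME("chrM", me_exon.start, me_exon.end, "+", "b", "g")
        term_me = mc.KnownME("chrM", circ.start, circ.start + 8, "+", "t", "g")
        anti_me = mc.KnownME("chrM", me_exon.start, me_exon.end, "-", "x", "g")
        calls = mc.overlap_known_mes([circ], [body_me, term_me, anti_me], genome)
        by_id = {c.me_id: c for c in calls}
        assert by_id["b"].position == "body"
        assert by_id["t"].position == "junction_5p"
        assert "x" not in by_id


class TestLocateMe:
    def test_planted_insert_found_exactly(self, sim_bundle):
        for circ_truth in sim_bundle.truth.circs:
            if len(circ_truth.insert_seq) < 6:
                continue
            call = _circ(
                chrom=circ_truth.chrom,
                strand=circ_truth.strand,
                gene=circ_truth.gene_id,
                kind="me_junction",
                exons=tuple(range(circ_truth.acceptor_exon, circ_truth.donor_exon + 1)),
                insert=circ_truth.insert_seq,
            )
            loc, reason = mc.locate_me(
                circ_truth.insert_seq, call, sim_bundle.models, sim_bundle.genome
            )
            assert reason == "" and loc is not None
            assert (loc.start, loc.end) == (circ_truth.me_start, circ_truth.me_end)

    def test_matches_naive_substring_oracle(self, sim_bundle):
        """The chosen interval is an intronic occurrence at minimal distance."""
        for circ_truth in sim_bundle.truth.circs:
            ins = circ_truth.insert_seq
            if len(ins) < 6:
                continue
            model = sim_bundle.models[circ_truth.gene_id]
            call = _circ(
                chrom=circ_truth.chrom, strand=circ_truth.strand,
                gene=circ_truth.gene_id, kind="me_junction",
                exons=tuple(range(circ_truth.acceptor_exon, circ_truth.donor_exon + 1)),
                insert=ins,
            )
            loc, _ = mc.locate_me(ins, call, sim_bundle.models, sim_bundle.genome)
            occurrences = naive_placements(ins, model, sim_bundle.genome)
            assert (loc.start, loc.end) in occurrences

    def test_absent_insert_unplaced(self, toy_gene):
        call = _circ(chrom="chrT", gene="G", kind="me_junction", exons=(1, 3),
                     insert="ACGTACGTAC")
        loc, reason = mc.locate_me("CCCCCCGGGGGG", call, toy_gene.models, toy_gene.genome)
        assert loc is None and reason == "no_intronic_match"

    def test_short_insert_unplaced_with_reason(self, toy_gene):
        call = _circ(chrom="chrT", gene="G", kind="me_junction", exons=(1, 3), insert="ACGTA")
        loc, reason = mc.locate_me("ACGTA", call, toy_gene.models, toy_gene.genome)
        assert loc is None and reason == "too_short_to_place"

    def test_nearest_of_two_occurrences_wins(self):
        """Two intronic hits at different distances: the closer one is chosen."""
        rng = np.random.default_rng(8)
        ins = rand_seq(rng, 12)
        exons = [rand_seq(rng, 30), rand_seq(rng, 30)]
        # occurrence near the intron start (close to exon1 = donor side) and a
        # second one much deeper into the intron
        intron = "GT" + rand_seq(rng, 5) + ins + rand_seq(rng, 200) + ins + rand_seq(rng, 50) + "AG"
        genome, model = build_gene("g", "chrL", "+", exons, [intron])
        call = _circ(chrom="chrL", gene="g", kind="me_junction", exons=(1, 2), insert=ins)
        loc, _ = mc.locate_me(ins, call, {"g": model}, genome)
        expected_start = model.introns[0][0] + 7
        assert loc.start == expected_start and loc.tie is False


class TestSpliceDinucs:
    def test_plus_strand_canonical_context(self):
        genome = {"c": "T" * 50 + "CCCAG" + "ACGTACGTAT" + "GTCCC" + "T" * 50}
        loc = mc.LocatedME("c", 55, 65, "+", 0)
        acc, don, gtag, fa, fd = mc.splice_dinucs(loc, genome)
        assert (acc, don, gtag) == ("AG", "GT", True)
        assert fa == "CCCAG" + "ACGTA" and fd == "CGTAT" + "GTCCC"

    def test_minus_strand_symmetry(self):
        plus = "T" * 50 + "CCCAG" + "ACGTACGTAT" + "GTCCC" + "T" * 50
        genome = {"c": revcomp(plus)}
        T = len(plus)
        loc = mc.LocatedME("c", T - 65, T - 55, "-", 0)
        acc, don, gtag, fa, fd = mc.splice_dinucs(loc, genome)
        assert (acc, don, gtag) == ("AG", "GT", True)
        assert fa == "CCCAG" + "ACGTA" and fd == "CGTAT" + "GTCCC"

    def test_noncanonical_flanks_flag_false(self):
        genome = {"c": "T" * 50 + "CCCTT" + "ACGTACGTAT" + "AACCC" + "T" * 50}
        acc, don, gtag, *_ = mc.splice_dinucs(mc.LocatedME("c", 55, 65, "+", 0), genome)
        assert (acc, don, gtag) == ("TT", "AA", False)

    def test_simulator_planted_flanks_are_all_canonical(self, sim_bundle):
        n = 0
        for c in sim_bundle.truth.circs:
            if c.me_start is None:
                continue
            loc = mc.LocatedME(c.chrom, c.me_start, c.me_end, c.strand, 0)
            acc, don, gtag, *_ = mc.splice_dinucs(loc, sim_bundle.genome)
            assert gtag, c.circ_id
            n += 1
        assert n >= 2


class TestMotifMatrix:
    def _call(self, fa, fd):
        return mc.MicroexonCall(
            source="de_novo", me_id="m", insert_seq="ACGTACG",
            circ_key=("g", 1, 2, "ACGTACG"), position="junction_5p",
            located=mc.LocatedME("c", 0, 7, "+", 0),
            flank_acceptor=fa, flank_donor=fd,
        )

    def test_single_call_unit_columns(self):
        m = mc.motif_matrix([self._call("CCCAGACGTA", "TACGTGTCCC")])
        assert m.n_sequences == 1
        assert (m.acceptor.sum(axis=0) == 1).all()
        assert m.acceptor.loc["A", "-2"] == 1 and m.acceptor.loc["G", "-1"] == 1
        assert m.donor.loc["G", "+1"] == 1 and m.donor.loc["T", "+2"] == 1

    def test_identical_contexts_accumulate(self):
        calls = [self._call("CCCAGACGTA", "TACGTGTCCC") for _ in range(7)]
        m = mc.motif_matrix(calls)
        assert m.n_sequences == 7
        assert (m.acceptor.sum(axis=0) == 7).all() and (m.donor.sum(axis=0) == 7).all()
        norm = m.normalized()
        assert norm.acceptor.loc["G", "-1"] == 1.0

    def test_zero_placed_calls_is_error(self):
        unplaced = mc.MicroexonCall(
            "de_novo", "m", "ACG", ("g", 1, 2, "ACG"), "junction_5p", None
        )
        with pytest.raises(ValueError):
            mc.motif_matrix([unplaced])


class TestCognates:
    def test_pairing_and_orphans(self):
        calls = [
            _circ(gene="g1", exons=(1, 3), kind="canonical"),
            _circ(gene="g1", exons=(1, 3), kind="me_junction", insert="ACGTAA"),
            _circ(gene="g2", exons=(2, 5), kind="me_junction", insert="TTTCCCAA"),
            _circ(gene="g3", exons=(1, 2), kind="me_junction", insert="ACGTACGT"),
            _circ(gene="g4", exons=(1, 4), kind="me_junction", insert="GGGTTTAC"),
        ]
        df = mc.pair_cognates(calls)
        assert len(df) == 4
        assert df.set_index("gene_id")["has_cognate"].to_dict() == {
            "g1": True, "g2": False, "g3": False, "g4": False,
        }
        summary = cognate_summary(df)
        assert summary["n_with_cognate"] == 1 and summary["n_orphan"] == 3
        assert summary["fraction_with_cognate"] == pytest.approx(0.25)

    def test_empty_me_set(self):
        df = mc.pair_cognates([_circ(kind="canonical")])
        assert len(df) == 0
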