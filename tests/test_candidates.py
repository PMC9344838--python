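import numpy as np
import pytest

import splicewarp as sw
from splicewarp.candidates import CandidateOptions
from splicewarp.reference import revcomp


def make_jwr(junction):
    return sw.JWR(
        read_id="r",
        junction=junction,
        junction_qpos=50,
        read_span=(24, 76),
        cigar=((0, 50), (3, junction.intron_length), (0, 50)),
        ref_start=junction.donor_end - 50,
        read_length=100,
    )


def scan_oracle(seq, mapped, window=10, pairs=(("GT", "AG"),)):
    """Exhaustive dinucleotide scan: cross-pair every donor and acceptor
    dinucleotide within the window, keep valid introns, mapped always in."""
    found = {(mapped.donor_end, mapped.acceptor_end)}
    for first2, last2 in pairs:
        donors = [
            d
            for d in range(mapped.donor_end - window, mapped.donor_end + window + 1)
            if seq[d : d + 2] == first2
        ]
        acceptors = [
            a
            for a in range(
                mapped.acceptor_end - window, mapped.acceptor_end + window + 1
            )
            if seq[a - 2 : a] == last2
        ]
        for d in donors:
            for a in acceptors:
                if a - d >= 4:
                    found.add((d, a))
    return found


def test_unique_motif_single_candidate():
    seq = "C" * 150 + "GT" + "C" * 96 + "AG" + "C" * 150
    ref = sw.ReferenceSource.from_dict({"c": seq})
    j = sw.SpliceJunction("c", 150, 250, "+")
    junctions, sources = sw.enumerate_candidates(make_jwr(j), ref)
    assert junctions == [j]
    assert sources == ["mapped"]


def test_two_acceptors_five_apart(two_candidate_locus):
    """The near-miss situation: one donor, two AG acceptors 5 nt apart."""
    loc = two_candidate_locus
    junctions, _ = sw.enumerate_candidates(make_jwr(loc["true"]), loc["ref"])
    accs = sorted(j.acceptor_end for j in junctions)
    assert loc["true"].acceptor_end in accs
    assert loc["alt"].acceptor_end in accs
    pair = [a for a in accs if a in (loc["true"].acceptor_end, loc["alt"].acceptor_end)]
    assert pair[1] - pair[0] == 5


def test_enumeration_matches_exhaustive_scan():
    rng = np.random.default_rng(21)
    for trial in range(10):
        seq = "".join(rng.choice(list("ACGT"), 400))
        j = sw.SpliceJunction("c", 150, 250, "+")
        ref = sw.ReferenceSource.from_dict({"c": seq})
        junctions, _ = sw.enumerate_candidates(
            make_jwr(j), ref, options=CandidateOptions(max_candidates=10_000)
        )
        got = {(x.donor_end, x.acceptor_end) for x in junctions}
        assert got == scan_oracle(seq, j)
        assert junctions[0] == j  # mapped junction first


def test_noncanonical_pairings():
    seq = "C" * 148 + "CAGTC" * 0 + "C" * 0
    # background without GT/AG; plant GC..AG and AT..AC introns only
    s = list("C" * 400)
    s[150:152] = "GC"
    s[248:250] = "AG"
    s[155:157] = "AT"
    s[243:245] = "AC"
    seq = "".join(s)
    ref = sw.ReferenceSource.from_dict({"c": seq})
    mapped = sw.SpliceJunction("c", 150, 250, "+")
    base, _ = sw.enumerate_candidates(make_jwr(mapped), ref)
    assert {(j.donor_end, j.acceptor_end) for j in base} == {(150, 250)}
    more, sources = sw.enumerate_candidates(
        make_jwr(mapped), ref, options=CandidateOptions(noncanonical=True)
    )
    got = {(j.donor_end, j.acceptor_end) for j in more}
    assert (150, 250) in got  # GC-AG
    assert (155, 245) in got  # AT-AC
    assert "AT_AC" in sources


def test_strand_symmetric_counts_and_revcomp_motifs():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 400))
    plus_ref = sw.ReferenceSource.from_dict({"c": seq})
    minus_ref = sw.ReferenceSource.from_dict({"c": revcomp(seq)})
    jp = sw.SpliceJunction("c", 150, 250, "+")
    L = len(seq)
    jm = sw.SpliceJunction("c", L - 250, L - 150, "-")
    cp, _ = sw.enumerate_candidates(make_jwr(jp), plus_ref)
    cm, _ = sw.enumerate_candidates(make_jwr(jm), minus_ref)
    assert len(cp) == len(cm)
    mp = sw.build_junction_motifs(cp, plus_ref)
    mm = sw.build_junction_motifs(cm, minus_ref)
    assert sorted(mp.motifs) == sorted(mm.motifs)  # minus motifs already revcomped


def test_user_and_annotation_candidates():
    seq = "C" * 150 + "GT" + "C" * 96 + "AG" + "C" * 150
    ref = sw.ReferenceSource.from_dict({"c": seq})
    mapped = sw.SpliceJunction("c", 150, 250, "+")
    extra = sw.SpliceJunction("c", 153, 247, "+")
    far = sw.SpliceJunction("c", 300, 380, "+")
    junctions, sources = sw.enumerate_candidates(
        make_jwr(mapped),
        ref,
        options=CandidateOptions(user_junctions=(extra, far)),
    )
    got = {(j.donor_end, j.acceptor_end) for j in junctions}
    assert (153, 247) in got  # within window
    assert (300, 380) not in got  # outside window
    assert "user" in sources


def test_annotation_only_restricts_to_mapped_plus_annotation():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), 400))
    ref = sw.ReferenceSource.from_dict({"c": seq})
    mapped = sw.SpliceJunction("c", 150, 250, "+")
    ann = sw.SpliceJunction("c", 148, 252, "+")
    junctions, sources = sw.enumerate_candidates(
        make_jwr(mapped),
        ref,
        options=CandidateOptions(annotation=(ann,), annotation_only=True),
    )
    assert {(j.donor_end, j.acceptor_end) for j in junctions} == {
        (150, 250),
        (148, 252),
    }


def test_candidate_cap_keeps_mapped_and_nearest():
    seq = ("GT" + "AG") * 100  # motif soup
    ref = sw.ReferenceSource.from_dict({"c": seq})
    mapped = sw.SpliceJunction("c", 150, 250, "+")
    junctions, sources = sw.enumerate_candidates(
        make_jwr(mapped), ref, options=CandidateOptions(max_candidates=5)
    )
    assert len(junctions) == 5
    assert junctions[0] == mapped


class TestBuildMotifs:
    def test_shared_prefix_lengths_differ_by_offset(self, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        a, b = cs.motifs
        assert len(a) - len(b) == 5  # shorter intron keeps 5 more exon bases
        shared = cs.buffer_head + 16 + (loc["true"].donor_end - min(
            j.donor_end for j in cs.junctions
        ))
        assert a[:shared] == b[:shared]

    def test_single_candidate_motif_length(self):
        seq = "C" * 150 + "GT" + "C" * 96 + "AG" + "C" * 150
        ref = sw.ReferenceSource.from_dict({"c": seq})
        j = sw.SpliceJunction("c", 150, 250, "+")
        cs = sw.build_junction_motifs([j], ref, flank=16, buffer=10)
        assert len(cs.motifs[0]) == 2 * (16 + 10)

    def test_common_flank_ends_identical_across_candidates(self, model6):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ref = sw.ReferenceSource.from_dict({"c": seq})
        juncs = [
            sw.SpliceJunction("c", 200, 300, "+"),
            sw.SpliceJunction("c", 197, 300, "+"),
            sw.SpliceJunction("c", 200, 305, "+"),
        ]
        cs = sw.build_junction_motifs(juncs, ref, flank=16, buffer=10)
        k = model6.k
        head = cs.buffer_head + k - 1
        tail = cs.buffer_tail + k - 1
        for m in cs.motifs[1:]:
            assert m[:head] == cs.motifs[0][:head]
            assert m[-tail:] == cs.motifs[0][-tail:]
        # hence candidate squiggles share leading and trailing states
        sq = cs.squiggles(model6)
        lead = cs.buffer_head
        for s in sq[1:]:
            np.testing.assert_array_equal(s.means[:lead], sq[0].means[:lead])
            np.testing.assert_array_equal(s.means[-lead:], sq[0].means[-lead:])

    def test_motif_equals_independent_splice_concat(self):
        """Oracle: splice-and-concatenate done directly on the sequence."""
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ref = sw.ReferenceSource.from_dict({"c": seq})
        j = sw.SpliceJunction("c", 200, 300, "+")
        cs = sw.build_junction_motifs([j], ref, flank=16, buffer=10)
        lo = 200 - 16 - 10
        hi = 300 + 16 + 10
        assert cs.motifs[0] == seq[lo:200] + seq[300:hi]

    def test_uniform_priors(self, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs([loc["true"], loc["alt"]], loc["ref"])
        np.testing.assert_array_equal(cs.prior_weights, [0.5, 0.5])

    def test_source_weight_multipliers(self, two_candidate_locus):
        loc = two_candidate_locus
        cs = sw.build_junction_motifs(
            [loc["true"], loc["alt"]],
            loc["ref"],
            sources=("mapped", "annotation"),
            source_weights={"annotation": 9.0},
        )
        np.testing.assert_allclose(cs.prior_weights, [0.1, 0.9])

    def test_mixed_strand_rejected(self):
        seq = "A" * 400
        ref = sw.ReferenceSource.from_dict({"c": seq})
        with pytest.raises(ValueError):
            sw.build_junction_motifs(
                [
                    sw.SpliceJunction("c", 150, 250, "+"),
                    sw.SpliceJunction("c", 150, 250, "-"),
                ],
                ref,
            )

    def test_flank_must_be_positive(self):
        ref = sw.ReferenceSource.from_dict({"c": "A" * 400})
        with pytest.raises(ValueError):
            sw.build_junction_motifs(
                [sw.SpliceJunction("c", 150, 250, "+")], ref, flank=0
            )


def test_gtf_intron_extraction(tmp_path):
    gtf = tmp_path / "ann.gtf"
    lines = [
        # two-exon transcript: intron = [200, 300) 0-based
        'c\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'c\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        # three-exon transcript adds [450, 500) and duplicates [200, 300)
        'c\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
        'c\tsrc\texon\t301\t450\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
        'c\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
    ]
    gtf.write_text("\n".join(lines) + "\n")
    juncs = sw.read_annotation_junctions(gtf)
    assert {(j.donor_end, j.acceptor_end) for j in juncs} == {(200, 300), (450, 500)}


def test_junction_bed_reading(tmp_path):
    bed = tmp_path / "cands.bed"
    bed.write_text("c\t150\t250\tj1\t7\t+\nc\t300\t400\tj2\t3\t-\n")
    juncs = sw.read_junction_bed(bed)
    assert juncs[0] == sw.SpliceJunction("c", 150, 250, "+")
    juncs2, weights = sw.read_junction_bed(bed, score_as_weight=True)
    assert weights == [7.0, 3.0]
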