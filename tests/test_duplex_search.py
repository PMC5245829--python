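import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinomir.collapse_filter import CollapsedSet
from dinomir.duplex_search import (
    DuplexPair,
    abundance_asymmetry,
    candidate_mirnas,
    find_duplexes,
    pair_duplex,
)
from dinomir.sequence_io import CollapsedRead, revcomp

from .oracles import oracle_all_pairs, oracle_pair

PROBE = "ACAGATTGCGGCAACCGTGCAG"  # 22-nt abundant Symbiodinium-type miRNA


def perfect_partner(a, overhang="TT"):
    return revcomp(a[:-2]) + overhang


def cset(seq_counts):
    reads = [CollapsedRead(seq=s, count=c, id=f"s{i}") for i, (s, c) in enumerate(seq_counts)]
    return CollapsedSet(reads=reads, total_input=sum(c for _, c in seq_counts))


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate_pairing_region(rng, partner, k):
    """Substitute k pairing-region bases so they no longer pair."""
    pos = rng.choice(len(partner) - 2, size=k, replace=False)
    s = list(partner)
    for p in pos:
        s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
    return "".join(s)


class TestPairDuplex:
    def test_perfect_partner_of_probe(self):
        b = perfect_partner(PROBE)
        assert b == "GCACGGTTGCCGCAATCTGTTT"
        aln = pair_duplex(PROBE, b)
        assert aln.mismatches == 0 and aln.n_bulges == 0

    def test_all_mismatch_cases(self):
        # pairing regions A*20 vs revcomp(G*20)=C*20: A:C never pairs
        assert pair_duplex("A" * 22, "G" * 22) is None
        assert oracle_pair("A" * 22, "G" * 22) is None
        # poly(A) against poly(T) is a perfect A:T duplex, by contrast
        assert pair_duplex("A" * 22, "T" * 22).mismatches == 0
        assert oracle_pair("A" * 22, "T" * 22) == 0

    def test_mismatch_budget_boundary(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = random_seq(rng, 22)
            b3 = mutate_pairing_region(rng, perfect_partner(a), 3)
            aln = pair_duplex(a, b3)
            assert aln is not None and aln.mismatches == 3
            assert oracle_pair(a, b3) == 3
            b4 = mutate_pairing_region(rng, perfect_partner(a), 4)
            assert pair_duplex(a, b4) is None
            assert oracle_pair(a, b4) is None

    def test_length_difference_two_is_geometric_rejection(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert pair_duplex(random_seq(rng, 22), random_seq(rng, 24)) is None

    def test_single_bulge_alignment(self):
        a = "ACAGATTGCGGCAACCGTGCAG"
        # partner one base longer: insert an extra base in its pairing region
        partner = perfect_partner(a)
        bulged = partner[:10] + "G" + partner[10:]
        aln = pair_duplex(a, bulged)
        assert aln is not None and aln.n_bulges == 1
        assert aln.bulges[0][0] == "B"
        assert aln.mismatches == oracle_pair(a, bulged)

    def test_bulge_never_at_pairing_region_terminus(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = random_seq(rng, 22)
            partner = perfect_partner(a)
            # extra base prepended to the pairing region start: a terminal
            # gap would be needed, so geometry must reject unless an internal
            # alignment happens to fit
            bulged = "G" + partner
            assert (pair_duplex(a, bulged) is not None) == (oracle_pair(a, bulged) is not None)

    def test_rejects_foreign_alphabet(self):
        with pytest.raises(ValueError):
            pair_duplex("ACGU" * 5 + "AC", "ACGT" * 5 + "AC")

    def test_n_never_pairs(self):
        a = PROBE
        b = perfect_partner(a)
        b_n = "N" + b[1:]
        aln = pair_duplex(a, b_n)
        assert aln is not None and aln.mismatches == 1

    @given(st.text("ACGT", min_size=18, max_size=26), st.text("ACGT", min_size=2, max_size=2))
    @settings(max_examples=150, deadline=None)
    def test_perfect_partner_completeness(self, a, xy):
        aln = pair_duplex(a, revcomp(a[:-2]) + xy)
        assert aln is not None and aln.mismatches == 0

    @given(st.text("ACGT", min_size=18, max_size=26), st.text("ACGT", min_size=18, max_size=26))
    @settings(max_examples=300, deadline=None)
    def test_symmetry(self, a, b):
        x, y = pair_duplex(a, b), pair_duplex(b, a)
        assert (x is None) == (y is None)
        if x is not None:
            assert x.mismatches == y.mismatches and x.n_bulges == y.n_bulges


class TestFindDuplexes:
    def test_planted_pair_among_random_decoys(self):
        rng = np.random.default_rng(8)
        a = random_seq(rng, 22)
        b = perfect_partner(a)
        decoys = []
        while len(decoys) < 50:
            d = random_seq(rng, 22)
            if d not in (a, b):
                decoys.append(d)
        cs = cset([(a, 100), (b, 5)] + [(d, 1) for d in set(decoys)])
        pairs = find_duplexes(cs)
        expected = oracle_all_pairs([(cr.seq, cr.count) for cr in cs.reads])
        got = {tuple(sorted((p.read_a.seq, p.read_b.seq))): p.alignment.mismatches
               for p in pairs}
        assert got == expected
        assert tuple(sorted((a, b))) in got

    def test_empty_set(self):
        assert find_duplexes(cset([])) == []

    def test_oracle_equivalence_on_random_sets(self):
        rng = np.random.default_rng(13)
        seqs = {random_seq(rng, int(rng.integers(18, 27))) for _ in range(120)}
        # add related pairs so the oracle has hits to agree on
        for _ in range(10):
            a = random_seq(rng, 22)
            seqs.add(a)
            seqs.add(mutate_pairing_region(rng, perfect_partner(a), int(rng.integers(0, 4))))
        cs = cset([(s, 1) for s in sorted(seqs)])
        got = {tuple(sorted((p.read_a.seq, p.read_b.seq))): p.alignment.mismatches
               for p in find_duplexes(cs)}
        assert got == oracle_all_pairs([(s, 1) for s in sorted(seqs)])

    def test_accepted_pairs_satisfy_length_geometry(self, default_pipeline):
        for p in default_pipeline.duplex_pairs:
            assert abs(len(p.read_a.seq) - len(p.read_b.seq)) <= 1


class TestCandidateMirnas:
    def test_one_pair_two_uniques(self):
        a = PROBE
        b = perfect_partner(a)
        pairs = find_duplexes(cset([(a, 3), (b, 1)]))
        uniq, hist = candidate_mirnas(pairs)
        assert uniq == {a, b} and hist == {22: 2}

    def test_shared_sequence_counted_once(self):
        rng = np.random.default_rng(21)
        a = random_seq(rng, 22)
        b = perfect_partner(a, "TT")
        c = perfect_partner(a, "GG")
        pairs = find_duplexes(cset([(a, 5), (b, 2), (c, 2)]))
        uniq, hist = candidate_mirnas(pairs)
        assert a in uniq and len(uniq) >= 3
        assert sum(hist.values()) == len(uniq)

    def test_planted_loci_yield_two_uniques_each(self, default_bundle, default_pipeline):
        uniq, _ = candidate_mirnas(default_pipeline.duplex_pairs)
        planted = {loc.guide for loc in default_bundle.manifest.loci} | {
            loc.star for loc in default_bundle.manifest.loci
        }
        assert planted <= uniq


class TestAbundanceAsymmetry:
    def make_pair(self, ca, cb):
        rng = np.random.default_rng(4)
        a = random_seq(rng, 22)
        b = perfect_partner(a)
        (pair,) = find_duplexes(cset([(a, ca), (b, cb)]))
        return pair

    def test_ratio_and_guide_call(self):
        call = abundance_asymmetry(self.make_pair(100, 5))
        assert call.ratio == 20.0 and call.guide.count == 100 and not call.tie

    def test_tie_flagged(self):
        call = abundance_asymmetry(self.make_pair(7, 7))
        assert call.ratio == 1.0 and call.tie

    def test_planted_fifty_to_one_recovered(self, default_bundle, default_pipeline):
        by_seq = {cr.seq: cr.count for cr in default_pipeline.candidates.reads}
        for loc in default_bundle.manifest.loci:
            assert by_seq[loc.guide] / by_seq[loc.star] == pytest.approx(50.0)
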