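import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeaudit.distance import (
    DistanceMatrix,
    collapse_haplotypes,
    k2p_distance,
    pairwise_matrix,
    species_nn,
)
from barcodeaudit.records import AlignedSequence, SpecimenCollection
from barcodeaudit.simulate import mutate_sequence
from conftest import make_record


def seq_pair_with(ts, tv, overlap=658):
    """Construct two sequences with exact transition/transversion counts."""
    a = list("A" * overlap)
    b = list("A" * overlap)
    for i in range(ts):
        b[i] = "G"  # A->G transition
    for i in range(ts, ts + tv):
        b[i] = "C"  # A->C transversion
    return AlignedSequence("".join(a)), AlignedSequence("".join(b))


class TestK2P:
    def test_identical_sequences(self, template):
        a = AlignedSequence(template)
        c = k2p_distance(a, a)
        assert c.distance == 0.0 and c.transitions_p == 0.0 and c.transversions_q == 0.0
        assert c.defined

    def test_closed_form_example(self):
        # P=0.10, Q=0.05: independently evaluated closed form = 0.1701815...
        a, b = seq_pair_with(ts=2, tv=1, overlap=20)
        c = k2p_distance(a, b, min_overlap=1)
        assert c.overlap == 20
        assert c.transitions_p == pytest.approx(0.10)
        assert c.transversions_q == pytest.approx(0.05)
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert c.distance == pytest.approx(expected, abs=1e-12)
        assert round(c.distance, 5) == 0.17018

    def test_min_overlap_undefined(self):
        a, b = seq_pair_with(ts=1, tv=0, overlap=120)
        c = k2p_distance(a, b, min_overlap=200)
        assert not c.defined and c.distance is None

    def test_pairwise_deletion(self):
        a = AlignedSequence("ACGT" * 10 + "N" * 10)
        b = AlignedSequence("ACGT" * 10 + "A" * 10)
        c = k2p_distance(a, b, min_overlap=1)
        assert c.overlap == 40 and c.distance == 0.0

    def test_unequal_frames_error(self):
        # sequences longer than the frame are rejected at construction
        with pytest.raises(ValueError):
            AlignedSequence("A" * 700)

    def test_saturated_pair_undefined(self):
        # P + Q large enough that 1-2P-Q <= 0
        a, b = seq_pair_with(ts=350, tv=0, overlap=658)
        c = k2p_distance(a, b, min_overlap=1)
        assert not c.defined

    def test_q_zero_reduces_to_transition_form(self):
        for ts in (1, 5, 20, 80):
            a, b = seq_pair_with(ts=ts, tv=0)
            c = k2p_distance(a, b)
            p = ts / 658
            assert c.distance == pytest.approx(
                -0.5 * math.log(1 - 2 * p) - 0.25 * math.log(1.0), abs=1e-12
            )

    @given(st.integers(0, 120), st.integers(0, 120))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_jensen(self, ts, tv):
        a, b = seq_pair_with(ts, tv)
        c1 = k2p_distance(a, b)
        c2 = k2p_distance(b, a)
        assert c1 == c2
        if c1.defined:
            # the log correction never shrinks the raw p-distance
            assert c1.distance >= c1.transitions_p + c1.transversions_q - 1e-12
            assert (c1.distance == 0.0) == (ts == 0 and tv == 0)


class TestPairwiseMatrix:
    def test_identical_sequences_all_zero(self, template):
        seqs = {f"s{i}": AlignedSequence(template) for i in range(3)}
        m = pairwise_matrix(seqs)
        assert np.allclose(m.distance, 0.0)
        assert m.defined.all()

    def test_single_specimen_errors(self, template):
        with pytest.raises(ValueError):
            pairwise_matrix({"s1": AlignedSequence(template)})

    def test_matches_brute_force_oracle(self, template):
        rng = np.random.default_rng(42)
        seqs = {}
        for i in range(12):
            n = int(rng.integers(0, 40))
            s = mutate_sequence(template, n, 3.0, rng)
            if i % 4 == 0:  # some fragments
                s = "-" * 100 + s[100:550] + "-" * 108
            seqs[f"s{i}"] = AlignedSequence(s)
        m = pairwise_matrix(seqs, min_overlap=300)
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i == j:
                    continue
                ref = k2p_distance(seqs[a], seqs[b], min_overlap=300)
                got = m.get(a, b)
                assert got.overlap == ref.overlap
                assert got.defined == ref.defined
                if ref.defined:
                    assert m.distance[i, j] == pytest.approx(ref.distance, abs=1e-12)

    def test_subset_is_consistent(self, template):
        rng = np.random.default_rng(1)
        seqs = {f"s{i}": AlignedSequence(mutate_sequence(template, 5 * i, 3.0, rng))
                for i in range(6)}
        m = pairwise_matrix(seqs)
        sub = m.subset(["s1", "s4"])
        assert sub.distance[0, 1] == m.distance[m.index["s1"], m.index["s4"]]

    def test_exports(self, template, tmp_path):
        rng = np.random.default_rng(2)
        seqs = {f"s{i}": AlignedSequence(mutate_sequence(template, 4, 3.0, rng))
                for i in range(3)}
        m = pairwise_matrix(seqs)
        m.write_phylip(tmp_path / "m.phy")
        m.write_tsv(tmp_path / "m.tsv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["id1", "id2", "overlap", "P", "Q", "distance"]
        assert len(lines) == 1 + 3


class TestHaplotypes:
    def test_identical_full_length_one_group(self, template):
        seqs = {"a": AlignedSequence(template), "b": AlignedSequence(template)}
        groups = collapse_haplotypes(pairwise_matrix(seqs))
        assert groups.n_groups == 1

    def test_subfragment_zero_mismatch_same_group(self, template):
        frag = template[:550] + "-" * 108
        seqs = {"a": AlignedSequence(template), "b": AlignedSequence(frag)}
        groups = collapse_haplotypes(pairwise_matrix(seqs))
        assert groups.n_groups == 1

    def test_one_mismatch_different_groups(self, template):
        rng = np.random.default_rng(0)
        seqs = {
            "a": AlignedSequence(template),
            "b": AlignedSequence(mutate_sequence(template, 1, 3.0, rng)),
        }
        groups = collapse_haplotypes(pairwise_matrix(seqs))
        assert groups.n_groups == 2

    def test_short_overlap_not_shared(self, template):
        frag = template[:400] + "-" * 258
        seqs = {"a": AlignedSequence(template), "b": AlignedSequence(frag)}
        groups = collapse_haplotypes(pairwise_matrix(seqs), min_overlap=500)
        assert groups.n_groups == 2

    def test_component_closure_via_bridge(self, template):
        # two long fragments overlap a full-length bridge but not each other
        left = template[:350] + "-" * 308
        right = "-" * 308 + template[308:]
        seqs = {
            "bridge": AlignedSequence(template),
            "l": AlignedSequence(left),
            "r": AlignedSequence(right),
        }
        groups = collapse_haplotypes(pairwise_matrix(seqs, min_overlap=1), min_overlap=300)
        assert groups.n_groups == 1


class TestSpeciesNN:
    def test_two_singletons(self, template):
        rng = np.random.default_rng(3)
        other = mutate_sequence(template, 20, 3.0, rng)
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template),
            make_record("s2", "Cc dd", other),
        ])
        m = pairwise_matrix(coll)
        records = {r.species: r for r in species_nn(m, coll.species_of())}
        d = k2p_distance(AlignedSequence(template), AlignedSequence(other)).distance * 100
        for sp in ("Aa bb", "Cc dd"):
            assert records[sp].nn_distance == pytest.approx(d)
            assert records[sp].intra_mean is None

    def test_matches_brute_force_oracle(self, four_species_collection):
        coll = four_species_collection
        m = pairwise_matrix(coll)
        got = {r.species: r for r in species_nn(m, coll.species_of())}

        # brute-force enumeration over all specimen pairs
        recs = coll.sequenced()
        for sp in coll.species():
            inter, intra = [], []
            for i in range(len(recs)):
                for j in range(len(recs)):
                    if i >= j:
                        continue
                    c = k2p_distance(recs[i].sequence, recs[j].sequence)
                    if not c.defined:
                        continue
                    pair = {recs[i].species, recs[j].species}
                    if pair == {sp}:
                        intra.append(c.distance)
                    elif sp in pair:
                        inter.append(c.distance)
            assert got[sp].nn_distance == pytest.approx(min(inter) * 100, abs=1e-9)
            assert got[sp].intra_mean == pytest.approx(
                100 * sum(intra) / len(intra), abs=1e-9
            )
            assert got[sp].intra_max == pytest.approx(100 * max(intra), abs=1e-9)

    def test_sharing_species_has_zero_nn(self, template):
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template),
            make_record("s2", "Cc dd", template),
        ])
        m = pairwise_matrix(coll)
        for r in species_nn(m, coll.species_of()):
            assert r.nn_distance == 0.0

    def test_from_square_constructor(self):
        d = np.array([[0.0, 0.01], [0.01, 0.0]])
        m = DistanceMatrix.from_square(["a", "b"], d)
        assert m.get("a", "b").distance == pytest.approx(0.01)
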