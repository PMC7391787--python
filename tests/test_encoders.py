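from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aovote as av
from aovote.encoders import PAIR_ORDER, encode_record

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementation)


def brute_ggap(seq: str, g: int) -> dict[str, float]:
    L = len(seq)
    counts: dict[str, int] = {}
    for p in range(L - g - 1):
        pair = seq[p] + seq[p + g + 1]
        counts[pair] = counts.get(pair, 0) + 1
    return {pair: c / (L - g - 1) for pair, c in counts.items()}


def brute_raac(seq: str, profile: av.ClusterProfile, n: int) -> dict[str, float]:
    mapping = profile.mapping
    reduced = "".join(mapping[c] for c in seq)
    L = len(reduced)
    counts: dict[str, int] = {}
    for p in range(L - n + 1):
        mer = reduced[p : p + n]
        counts[mer] = counts.get(mer, 0) + 1
    return {mer: c / (L - n + 1) for mer, c in counts.items()}


aa_seq = st.text(alphabet=av.AMINO_ACIDS, min_size=12, max_size=50)


# ---------------------------------------------------------------------------


class TestGGap:
    def test_adjacent_dipeptides_hand_enumeration(self):
        vec = av.ggap_composition(av.ProteinRecord("x", "ACDE"), av.GGapSpec(0))
        nz = {n: v for n, v in zip(vec.names, vec.values) if v}
        third = pytest.approx(1 / 3)
        assert nz == {"A.C|g=0": third, "C.D|g=0": third, "D.E|g=0": third}

    def test_single_dipeptide_type(self):
        vec = av.ggap_composition(av.ProteinRecord("x", "AAAA"), av.GGapSpec(1))
        nz = {n: v for n, v in zip(vec.names, vec.values) if v}
        assert nz == {"A.A|g=1": 1.0}

    def test_minimum_length_single_pair(self):
        vec = av.ggap_composition(av.ProteinRecord("x", "ACDE"), av.GGapSpec(2))
        nz = {n: v for n, v in zip(vec.names, vec.values) if v}
        assert nz == {"A.E|g=2": 1.0}

    @pytest.mark.parametrize("g", range(10))
    def test_dimension_is_400_for_all_gaps(self, g):
        vec = av.ggap_composition(
            av.ProteinRecord("x", av.AMINO_ACIDS), av.GGapSpec(g)
        )
        assert len(vec.values) == 400

    def test_too_short_sequence_names_record_and_gap(self):
        with pytest.raises(ValueError, match="shorty.*g=3|shorty.*3"):
            av.ggap_composition(av.ProteinRecord("shorty", "ACD"), av.GGapSpec(3))

    def test_counts_total_is_length_law(self, rng):
        seq = "".join(rng.choice(list(av.AMINO_ACIDS), size=37))
        for g in range(10):
            vec = av.ggap_composition(av.ProteinRecord("x", seq), av.GGapSpec(g))
            assert vec.counts.sum() == 37 - g - 1

    def test_gap_range_guard(self):
        with pytest.raises(ValueError):
            av.GGapSpec(10)
        assert av.GGapSpec(10, allow_extended=True).g == 10
        with pytest.raises(ValueError):
            av.GGapSpec(-1)

    @given(seq=aa_seq, g=st.integers(0, 9))
    def test_matches_brute_force(self, seq, g):
        vec = av.ggap_composition(av.ProteinRecord("h", seq), av.GGapSpec(g))
        expected = brute_ggap(seq, g)
        got = {n.split("|")[0].replace(".", ""): v for n, v in zip(vec.names, vec.values) if v}
        assert got.keys() == expected.keys()
        for pair, freq in expected.items():
            assert got[pair] == pytest.approx(freq, abs=1e-12)


class TestProfiles:
    def test_partitions_cover_alphabet(self):
        for profile in av.PROFILES.values():
            letters = sorted("".join(profile.groups))
            assert letters == sorted(av.AMINO_ACIDS)
            assert profile.size == int(profile.name[2:])

    @pytest.mark.parametrize(
        "name,k,n,dim",
        [("Op5", 5, 3, 125), ("Op8", 8, 2, 64), ("Op9", 9, 2, 81),
         ("Op11", 11, 2, 121), ("Op13", 13, 2, 169)],
    )
    def test_group_counts_and_default_dimensions(self, name, k, n, dim):
        profile = av.PROFILES[name]
        assert profile.size == k
        assert profile.optimal_n == n
        assert profile.dimension() == dim

    def test_reduction_examples(self):
        assert av.reduce_sequence("GIVA", av.PROFILES["Op5"]) == "GIIA"
        assert av.reduce_sequence("TC", av.PROFILES["Op9"]) == "TT"
        for profile in av.PROFILES.values():
            assert av.reduce_sequence("PPPP", profile) == "PPPP"

    def test_reduction_preserves_length_and_is_idempotent(self, rng):
        seq = "".join(rng.choice(list(av.AMINO_ACIDS), size=60))
        for profile in av.PROFILES.values():
            reduced = av.reduce_sequence(seq, profile)
            assert len(reduced) == len(seq)
            assert av.reduce_sequence(reduced, profile) == reduced

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            av.ClusterProfile(name="bad", groups=("ACDE",), optimal_n=2)
        with pytest.raises(ValueError):  # duplicate letter
            av.ClusterProfile(
                name="dup", groups=("AACDEFGHIK", "LMNPQRSTVWY"), optimal_n=2
            )

    def test_load_profile_file(self, tmp_path):
        path = tmp_path / "custom.txt"
        path.write_text("G\nIVFYW\nALMEQRK\nP\nNDHSTC\n")
        profile = av.encoders.load_profile(path, optimal_n=3)
        assert profile.size == 5
        assert profile.dimension() == 125


class TestRAAC:
    def test_op5_tripeptide_dimension(self):
        vec = av.raac_composition(av.ProteinRecord("x", av.AMINO_ACIDS), av.PROFILES["Op5"], 3)
        assert len(vec.values) == 125

    def test_op5_dipeptide_is_25(self):
        vec = av.raac_composition(av.ProteinRecord("x", "AAAA"), av.PROFILES["Op5"], 2)
        assert len(vec.values) == 25
        nz = {n: v for n, v in zip(vec.names, vec.values) if v}
        assert nz == {"AA|Op5": 1.0}

    def test_giva_op8_hand_enumeration(self):
        vec = av.raac_composition(av.ProteinRecord("x", "GIVA"), av.PROFILES["Op8"], 2)
        assert len(vec.values) == 64
        nz = {n: v for n, v in zip(vec.names, vec.values) if v}
        third = pytest.approx(1 / 3)
        assert nz == {"GI|Op8": third, "II|Op8": third, "IA|Op8": third}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            av.raac_composition(av.ProteinRecord("tiny", "AC"), av.PROFILES["Op5"], 3)

    @given(seq=aa_seq, name=st.sampled_from(sorted(av.PROFILES)))
    def test_matches_brute_force(self, seq, name):
        profile = av.PROFILES[name]
        n = profile.optimal_n
        vec = av.raac_composition(av.ProteinRecord("h", seq), profile, n)
        expected = brute_raac(seq, profile, n)
        got = {nm.split("|")[0]: v for nm, v in zip(vec.names, vec.values) if v}
        assert got.keys() == expected.keys()
        for mer, freq in expected.items():
            assert got[mer] == pytest.approx(freq, abs=1e-12)

    @given(seq=aa_seq)
    def test_normalization_sums_to_one(self, seq):
        record = av.ProteinRecord("h", seq)
        for g in (0, 5, 9):
            assert av.ggap_composition(record, av.GGapSpec(g)).values.sum() == pytest.approx(1.0, abs=1e-9)
        for profile in av.PROFILES.values():
            assert av.raac_composition(record, profile).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestEncodeDataset:
    def test_matrix_shape_and_row_normalization(self, small_dataset):
        fm = av.encode_dataset(small_dataset, av.GGapSpec(0))
        assert fm.X.shape == (len(small_dataset), 400)
        assert np.allclose(fm.X.sum(axis=1), 1.0, atol=1e-9)
        assert fm.ids == small_dataset.ids

    def test_short_record_error_lists_offenders(self, small_dataset):
        bad = av.LabeledDataset(
            records=small_dataset.records + [av.ProteinRecord("runt", "ACD")],
            labels=small_dataset.labels + [+1],
        )
        with pytest.raises(ValueError, match="runt"):
            av.encode_dataset(bad, av.GGapSpec(3))

    def test_deterministic(self, small_dataset):
        a = av.encode_dataset(small_dataset, (av.PROFILES["Op9"], 2))
        b = av.encode_dataset(small_dataset, (av.PROFILES["Op9"], 2))
        assert np.array_equal(a.X, b.X)

    def test_tsv_roundtrip(self, small_dataset, tmp_path):
        fm = av.encode_dataset(small_dataset, (av.PROFILES["Op5"], 2))
        path = tmp_path / "fm.tsv"
        fm.to_tsv(path)
        back = av.FeatureMatrix.from_tsv(path)
        assert back.feature_names == fm.feature_names
        assert np.allclose(back.X, fm.X)
        assert np.array_equal(back.labels, fm.labels)

    def test_feature_name_order_is_lexicographic_pairs(self):
        assert PAIR_ORDER[0] == "AA"
        assert PAIR_ORDER[-1] == "YY"
        assert list(PAIR_ORDER) == ["".join(p) for p in product(av.AMINO_ACIDS, repeat=2)]
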