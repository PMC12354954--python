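import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pseucnn.feature_extraction import (
    FREE_ENERGY,
    HYDROPHILICITY,
    PROPERTY_TABLE,
    amplitude_spectrum,
    dft,
    encode_property,
    extract_features,
    feature_arrays,
    feature_names,
    pad_profile,
    read_features,
    sequence_features,
    validate_property_table,
    write_features,
)
from pseucnn.sequence_io import LabeledSequenceSet, RnaSequence


def naive_dft(profile):
    """Independent O(L^2) double-loop oracle for the transform."""
    L = len(profile)
    out = np.empty(L, dtype=complex)
    for k in range(L):
        acc = 0j
        for n in range(L):
            acc += profile[n] * np.exp(-1j * 2 * np.pi * k * n / L)
        out[k] = acc
    return out


def make_set(residues_list):
    seqs = [RnaSequence(f"s{i}", r) for i, r in enumerate(residues_list)]
    return LabeledSequenceSet(seqs, np.arange(len(seqs)) % 2)


class TestPropertyTable:
    def test_sixteen_dinucleotides_per_property(self):
        validate_property_table(PROPERTY_TABLE)
        assert len(FREE_ENERGY) == len(HYDROPHILICITY) == 16

    @pytest.mark.parametrize(
        "prop,dinuc,value",
        [
            ("free_energy", "GG", -3.260),
            ("free_energy", "AA", -0.930),
            ("hydrophilicity", "CU", 0.520),
            ("hydrophilicity", "AA", 0.040),
            ("free_energy", "GA", -2.350),
        ],
    )
    def test_shipped_values(self, prop, dinuc, value):
        assert PROPERTY_TABLE[prop][dinuc] == pytest.approx(value)

    def test_incomplete_table_rejected(self):
        broken = {"free_energy": {k: v for k, v in FREE_ENERGY.items() if k != "AU"}}
        with pytest.raises(ValueError, match="AU"):
            validate_property_table(broken)


class TestEncodeProperty:
    @pytest.mark.parametrize(
        "residues,prop,expected",
        [
            ("GG", "free_energy", [-3.260]),
            ("GGA", "free_energy", [-3.260, -2.350]),
            ("AA", "hydrophilicity", [0.040]),
        ],
    )
    def test_tabulated_values(self, residues, prop, expected):
        np.testing.assert_allclose(encode_property(residues, prop), expected)

    def test_profile_length_is_n_minus_one(self):
        seq = "ACUGA" * 4 + "U"  # 21 nt
        assert encode_property(seq, "free_energy").size == 20

    def test_unknown_property_rejected(self):
        with pytest.raises(KeyError, match="stacking"):
            encode_property("ACGU", "stacking")


class TestPadProfile:
    def test_zeros_appended_on_right(self):
        np.testing.assert_array_equal(
            pad_profile([1.0, 2.0], 4), [1.0, 2.0, 0.0, 0.0]
        )

    def test_identity_when_already_at_target(self):
        np.testing.assert_array_equal(pad_profile([1.0], 1), [1.0])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            pad_profile([], 2)

    def test_shrinking_rejected(self):
        with pytest.raises(ValueError):
            pad_profile([1.0, 2.0, 3.0], 2)


class TestDft:
    def test_constant_profile_is_dc_only(self):
        spec = dft(np.full(8, 3.5))
        assert spec[0] == pytest.approx(28.0)
        np.testing.assert_allclose(np.abs(spec[1:]), 0.0, atol=1e-9)

    def test_two_point_transform(self):
        spec = dft([1.0, -1.0])
        np.testing.assert_allclose(spec, [0.0, 2.0], atol=1e-12)

    def test_matches_naive_oracle_across_lengths(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            L = int(rng.integers(1, 65))
            profile = rng.normal(0, 2, size=L)
            np.testing.assert_allclose(
                dft(profile), naive_dft(profile), atol=1e-9
            )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            dft([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=1,
            max_size=64,
        )
    )
    def test_parseval_and_conjugate_symmetry(self, values):
        profile = np.array(values)
        L = profile.size
        amps = amplitude_spectrum(dft(profile))
        # Parseval: sum Z^2 = L * sum h^2
        assert np.sum(amps**2) == pytest.approx(
            L * np.sum(profile**2), rel=1e-9, abs=1e-9
        )
        # real input: Z_k = Z_{L-k}
        for k in range(1, L):
            assert amps[k] == pytest.approx(amps[L - k], rel=1e-9, abs=1e-9)


class TestAmplitudeSpectrum:
    def test_three_four_five(self):
        assert amplitude_spectrum(np.array([3 + 4j]))[0] == pytest.approx(5.0)

    def test_zero_maps_to_zero(self):
        assert amplitude_spectrum(np.array([0j]))[0] == 0.0

    def test_dc_amplitude_equals_absolute_profile_sum(self):
        profile = encode_property("GGAA", "free_energy")
        np.testing.assert_allclose(profile, [-3.260, -2.350, -0.930])
        amps = amplitude_spectrum(dft(profile))
        assert amps[0] == pytest.approx(6.540)
        np.testing.assert_allclose(amps, np.abs(naive_dft(profile)), atol=1e-9)


class TestExtractFeatures:
    def test_21bp_set_yields_40_columns(self):
        sset = make_set(["ACUGA" * 4 + "U"] * 4)
        feats = extract_features(sset)
        assert feats.shape[1] - 2 == 40

    def test_31bp_set_yields_60_columns(self):
        sset = make_set(["ACUGA" * 6 + "U"] * 4)
        assert extract_features(sset).shape[1] - 2 == 60

    def test_mixed_lengths_padded_to_longest(self):
        short = "ACUGA" * 3 + "ACUG"  # 19 nt
        long = "ACUGA" * 4 + "U"  # 21 nt
        feats = extract_features(make_set([short, long]))
        assert feats.shape[1] - 2 == 40
        # padding the 18-value profile with zeros must not change its energy
        profile = encode_property(short, "free_energy")
        amps = feats.iloc[0, 2:22].to_numpy(dtype=float)
        assert np.sum(amps**2) == pytest.approx(20 * np.sum(profile**2), rel=1e-9)

    def test_block_order_free_energy_then_hydrophilicity(self):
        names = feature_names(3)
        assert names == [
            "FreeEnergy_Amp_1", "FreeEnergy_Amp_2", "FreeEnergy_Amp_3",
            "Hydrophilicity_Amp_1", "Hydrophilicity_Amp_2", "Hydrophilicity_Amp_3",
        ]
        seq = "GGAA"
        vec = sequence_features(seq, 3)
        np.testing.assert_allclose(
            vec[:3], np.abs(naive_dft(encode_property(seq, "free_energy"))), atol=1e-9
        )
        np.testing.assert_allclose(
            vec[3:], np.abs(naive_dft(encode_property(seq, "hydrophilicity"))), atol=1e-9
        )

    def test_permutation_equivariance(self):
        residues = ["AAUAA", "CGUGC", "UUUUU", "GGUGG", "ACUCA"]
        sset = make_set(residues)
        perm = [3, 0, 4, 1, 2]
        permuted = make_set([residues[i] for i in perm])
        direct = extract_features(sset).iloc[perm, 2:].to_numpy(dtype=float)
        other = extract_features(permuted).iloc[:, 2:].to_numpy(dtype=float)
        np.testing.assert_array_equal(direct, other)

    def test_features_finite_and_nonnegative(self, strong_signal_features):
        X, _, _ = strong_signal_features
        assert np.all(np.isfinite(X)) and np.all(X >= 0)

    def test_standardize_switch_defaults_off(self):
        sset = make_set(["AAUAA", "CGUGC", "UUUUU", "GGUGG"])
        raw = extract_features(sset)
        z = extract_features(sset, standardize=True)
        assert not np.allclose(
            raw.iloc[:, 2:].to_numpy(dtype=float), z.iloc[:, 2:].to_numpy(dtype=float)
        )
        np.testing.assert_allclose(
            z.iloc[:, 2:].to_numpy(dtype=float).mean(axis=0), 0.0, atol=1e-12
        )

    def test_tsv_round_trip_bit_exact(self, tmp_path):
        sset = make_set(["AAUAA", "CGUGC", "UUUUU", "GGUGG"])
        feats = extract_features(sset)
        path = tmp_path / "features.tsv"
        write_features(feats, path)
        again = read_features(path)
        assert list(again.columns) == list(feats.columns)
        X1, y1, ids1 = feature_arrays(feats)
        X2, y2, ids2 = feature_arrays(again)
        np.testing.assert_array_equal(X1, X2)
        assert y1.tolist() == y2.tolist() and ids1 == ids2
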