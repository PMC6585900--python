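"""Tripeptide/PseAAC encoding against closed-form cases and a naive oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prtup import (
    AMINO_ACIDS,
    EncodingConfig,
    PropertyTable,
    correlation_factors,
    dipeptide_frequencies,
    encode,
    feature_names,
    standardize_properties,
    tripeptide_frequencies,
)
from prtup.encoding import TRIPEPTIDE_INDEX, EncodingError

peptide_seqs = st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=10)


def naive_encode(seq, raw_table, lam, w):
    """Direct transcription of the encoding definition, kept independent
    of the library implementation: explicit loops, dict-based counting."""
    n_props = raw_table.shape[0]
    std = np.empty_like(raw_table, dtype=float)
    for k in range(n_props):
        row = raw_table[k]
        mean = sum(row) / 20
        norm = sum((x - mean) ** 2 for x in row) ** 0.5
        std[k] = [(x - mean) / norm for x in row]
    h = {aa: std[:, i] for i, aa in enumerate(AMINO_ACIDS)}
    L = len(seq)
    counts = {}
    for i in range(L - 2):
        counts[seq[i:i + 3]] = counts.get(seq[i:i + 3], 0) + 1
    f = np.zeros(8000)
    for t, c in counts.items():
        f[TRIPEPTIDE_INDEX[t]] = c / (L - 2)
    taus = []
    for g in range(1, lam + 1):
        for k in range(n_props):
            taus.append(
                sum(h[seq[i]][k] * h[seq[i + g]][k] for i in range(L - g)) / (L - g)
            )
    taus = np.array(taus)
    denom = f.sum() + w * taus.sum()
    return np.concatenate([f, w * taus]) / denom


class TestStandardize:
    def test_fixed_point_of_already_standardized_values(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=20)
        raw = raw - raw.mean()
        raw /= np.sqrt(np.sum(raw**2))
        t = standardize_properties(raw[None, :], names=["x"])
        assert np.allclose(t.standardized[0], raw, atol=1e-12)

    def test_arithmetic_sequence_closed_form(self):
        raw = np.arange(1, 21, dtype=float)
        t = standardize_properties(raw[None, :], names=["x"])
        norm = np.sqrt(np.sum((raw - 10.5) ** 2))
        assert abs(t.standardized[0].mean()) < 1e-12
        assert t.standardized[0][-1] == pytest.approx((20 - 10.5) / norm)

    def test_constant_property_rejected(self):
        with pytest.raises(EncodingError):
            standardize_properties(np.full((1, 20), 3.0), names=["x"])

    def test_default_table_mean_zero_unit_norm(self, table):
        assert np.abs(table.standardized.mean(axis=1)).max() < 1e-12
        assert np.allclose(np.sum(table.standardized**2, axis=1), 1.0)

    def test_normalizer_positive_across_whole_w_grid(self, table):
        """With the printed standardization the encoding denominator stays
        positive for every (lambda, w) in the canonical tuning grid."""
        from prtup import default_lambda_w_grid
        worst = "RRRRKKK"  # strongly charged, large negative correlations
        for lam, w in default_lambda_w_grid():
            v = encode(worst, EncodingConfig(lam=lam, w=w), table)
            assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_affine_transform_of_raw_scale_is_absorbed(self, table):
        shifted = standardize_properties(
            3.0 * table.raw + 7.0, names=table.names
        )
        assert np.allclose(shifted.standardized, table.standardized)


class TestTripeptideFrequencies:
    def test_homopolymer_single_tripeptide(self):
        f = tripeptide_frequencies("AAAAAAA")
        assert f[TRIPEPTIDE_INDEX["AAA"]] == 1.0
        assert f.sum() == 1.0 and np.count_nonzero(f) == 1

    def test_alternating_sequence_window_counts(self):
        f = tripeptide_frequencies("ACACACA")  # windows ACA,CAC,ACA,CAC,ACA
        assert f[TRIPEPTIDE_INDEX["ACA"]] == pytest.approx(3 / 5)
        assert f[TRIPEPTIDE_INDEX["CAC"]] == pytest.approx(2 / 5)
        assert np.count_nonzero(f) == 2

    @given(st.text(alphabet=AMINO_ACIDS, min_size=7, max_size=7))
    def test_seven_mer_has_at_most_five_nonzeros_summing_to_one(self, seq):
        f = tripeptide_frequencies(seq)
        assert np.count_nonzero(f) <= 5
        assert f.sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(EncodingError):
            tripeptide_frequencies("AC")


class TestCorrelationFactors:
    def test_homopolymer_gives_squared_property_value(self, table):
        tau = correlation_factors("AAAAAAA", table, lam=2)
        hA = table.standardized[:, 0]
        assert np.allclose(tau, np.tile(hA**2, 2))

    def test_lambda3_nine_properties_gives_27_values(self, table):
        assert correlation_factors("ACDEFGH", table, lam=3).shape == (27,)

    def test_two_residue_single_property_product(self):
        # single property with standardized h(A)=1, h(C)=-1: the lone pair
        # term gives tau_1 = 1 * (-1) / (2 - 1) = -1
        std = np.zeros((1, 20))
        std[0, 0], std[0, 1] = 1.0, -1.0  # A, C
        t = PropertyTable(names=("x",), raw=std.copy(), standardized=std)
        tau = correlation_factors("AC", t, lam=1)
        assert tau.shape == (1,)
        assert tau[0] == pytest.approx(-1.0)

    def test_two_level_scale_matches_standardized_product(self):
        raw = np.array([1.0 if aa == "A" else -1.0 for aa in AMINO_ACIDS])
        t = standardize_properties(raw[None, :], names=["x"])
        tau = correlation_factors("AC", t, lam=1)
        assert tau[0] == pytest.approx(t.standardized[0][0] * t.standardized[0][1])

    def test_lambda_exceeding_length_rejected(self, table):
        with pytest.raises(EncodingError, match="lambda"):
            correlation_factors("ACDE", table, lam=4)

    def test_tier_major_ordering(self, table):
        """tau is ordered all properties at gap 1, then gap 2, ..."""
        seq = "ACDEFGH"
        tau = correlation_factors(seq, table, lam=3)
        for g in range(1, 4):
            single = np.array([
                correlation_factors(seq, PropertyTable.from_raw([n], table.raw[[k]]), lam=g)[-1]
                for k, n in enumerate(table.names)
            ])
            assert np.allclose(tau[(g - 1) * 9: g * 9], single)


class TestEncode:
    def test_dimension_8027_for_lambda3_nine_properties(self, table):
        v = encode("ACDEFGH", EncodingConfig(lam=3, w=0.15), table)
        assert v.shape == (8027,)
        assert len(feature_names(EncodingConfig(lam=3), table)) == 8027

    def test_zero_weight_reduces_to_tripeptide_frequencies(self, table):
        v = encode("ACDEFGH", EncodingConfig(lam=3, w=0.0), table)
        assert np.allclose(v[8000:], 0.0)
        assert np.allclose(v[:8000], tripeptide_frequencies("ACDEFGH"))

    @settings(deadline=None, max_examples=60)
    @given(peptide_seqs, st.integers(1, 3), st.floats(0.05, 0.7))
    def test_components_sum_to_one(self, table, seq, lam, w):
        try:
            v = encode(seq, EncodingConfig(lam=lam, w=w), table)
        except EncodingError:
            # non-positive normalizer (strongly anti-correlated short
            # peptide): rejected by contract, nothing to check
            return
        assert v.shape == (8000 + 9 * lam,)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=7, max_size=7),
           st.integers(1, 4), st.floats(0.05, 0.7))
    def test_agrees_with_naive_transcription(self, table, seq, lam, w):
        try:
            got = encode(seq, EncodingConfig(lam=lam, w=w), table)
        except EncodingError:
            return
        want = naive_encode(seq, table.raw, lam, w)
        assert np.allclose(got, want, atol=1e-12)

    def test_dimension_formula_across_lambda(self, table):
        for lam in range(1, 7):
            v = encode("ACDEFGHIK", EncodingConfig(lam=lam, w=0.1), table)
            assert v.shape == (8000 + 9 * lam,)


class TestDipeptide:
    def test_homopolymer(self):
        f = dipeptide_frequencies("AAAAAAA")
        assert f[0] == 1.0 and f.sum() == 1.0  # AA is index 0

    def test_alternating(self):
        f = dipeptide_frequencies("ACACACA")  # 6 windows: 3x AC, 3x CA
        ac = list(itertools.product(AMINO_ACIDS, repeat=2)).index(("A", "C"))
        ca = list(itertools.product(AMINO_ACIDS, repeat=2)).index(("C", "A"))
        assert f[ac] == pytest.approx(0.5) and f[ca] == pytest.approx(0.5)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=7, max_size=7))
    def test_sums_to_one(self, seq):
        assert dipeptide_frequencies(seq).sum() == pytest.approx(1.0)

    def test_dipeptide_mode_dimension(self, table):
        v = encode("ACDEFGH", EncodingConfig(mode="dipeptide"), table)
        assert v.shape == (400,)
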