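"""Descriptor-block correctness: hand-enumerated oracles, normalization
invariants, dimensionality identities and purity."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phagehydro as ph
from phagehydro.encoders import (
    load_ctd_groupings,
    load_gtpc_classes,
    load_property_scales,
)
from phagehydro.exceptions import ConfigError, EncodingError, LengthError

valid_sequences = st.text(alphabet=ph.ALPHABET, min_size=17, max_size=80)


def as_dict(fv):
    return dict(zip(fv.names, fv.values))


class TestBundledTables:
    def test_ten_scales_normalized_to_zero_mean_unit_variance(self):
        scales = load_property_scales()
        assert len(scales) == 10
        assert {s.name for s in scales} >= {"hydrophobicity", "hydrophilicity", "polarity"}
        for s in scales:
            vals = np.array([s.normalized_values[a] for a in ph.ALPHABET])
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1.0) < 1e-12

    def test_gtpc_partition_covers_alphabet(self):
        table = load_gtpc_classes()
        assert len(table.classes) == 5
        assert sorted("".join(table.classes.values())) == sorted(ph.ALPHABET)

    def test_ctd_has_13_groupings_of_3_classes(self):
        tables = load_ctd_groupings()
        assert len(tables) == 13
        for t in tables:
            assert len(t.classes) == 3
            assert sorted("".join(t.classes.values())) == sorted(ph.ALPHABET)


class TestGGDC:
    def test_hand_enumerated_acdac(self):
        # two 2-gap pairs: (A..A) at 1->4 and (C..C) at 2->5; denominator L-g-1=2
        d = as_dict(ph.encode_ggdc("ACDAC", g=2))
        assert d["ggdc|AA"] == pytest.approx(0.5)
        assert d["ggdc|CC"] == pytest.approx(0.5)
        assert sum(v != 0 for v in d.values()) == 2

    def test_homopolymer(self):
        d = as_dict(ph.encode_ggdc("AAAAAA", g=2))
        assert d["ggdc|AA"] == pytest.approx(1.0)

    def test_too_short_names_the_record(self):
        with pytest.raises(LengthError, match="rec9"):
            ph.encode_ggdc("ACD", g=2, seq_id="rec9")

    def test_negative_g_rejected(self):
        with pytest.raises(ConfigError):
            ph.encode_ggdc("ACDEF", g=-1)

    @given(valid_sequences)
    def test_400_entries_summing_to_one(self, seq):
        fv = ph.encode_ggdc(seq, g=2)
        assert len(fv) == 400
        assert fv.values.sum() == pytest.approx(1.0)
        assert (fv.values >= 0).all()

    def test_g_zero_is_adjacent_dipeptide_composition(self):
        d = as_dict(ph.encode_ggdc("ACAC", g=0))
        assert d["ggdc|AC"] == pytest.approx(2 / 3)
        assert d["ggdc|CA"] == pytest.approx(1 / 3)


class TestPseAAC:
    def test_homopolymer_correlation_is_squared_scale_value(self):
        # with H(x, y) = h(x) h(y) every summand equals h(G)^2, for all lags
        fv = ph.encode_pseaac("G" * 20, lam=15)
        assert len(fv) == 150
        by_prop = {}
        for name, value in zip(fv.names, fv.values):
            by_prop.setdefault(name.split("|")[2], set()).add(round(value, 12))
        for scale in load_property_scales():
            expected = scale.normalized_values["G"] ** 2
            assert by_prop[scale.name] == {round(expected, 12)}

    def test_length_equal_to_lambda_errors(self):
        with pytest.raises(LengthError):
            ph.encode_pseaac("A" * 15, lam=15)

    def test_lag_major_feature_order(self):
        fv = ph.encode_pseaac("ACDEFGHIKLMNPQRSTVWY", lam=2)
        assert fv.names[0].startswith("pseaac|lag01|")
        assert fv.names[10].startswith("pseaac|lag02|")
        assert len(fv) == 20

    def test_squared_diff_variant_differs_and_is_nonnegative(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        prod = ph.encode_pseaac(seq, lam=5)
        sq = ph.encode_pseaac(seq, lam=5, correlation="squared-diff")
        assert (sq.values >= 0).all()
        assert not np.allclose(prod.values, sq.values)

    def test_matches_bruteforce_lag_correlation(self):
        # independent oracle: explicit double loop over lags and positions
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(ph.ALPHABET), size=37))
        lam = 4
        fv = ph.encode_pseaac(seq, lam=lam)
        got = as_dict(fv)
        for scale in load_property_scales():
            h = scale.normalized_values
            for j in range(1, lam + 1):
                expected = np.mean(
                    [h[seq[k]] * h[seq[k + j]] for k in range(len(seq) - j)]
                )
                assert got[f"pseaac|lag{j:02d}|{scale.name}"] == pytest.approx(expected)


class TestGTPC:
    def test_single_tripeptide(self):
        d = as_dict(ph.encode_gtpc("AAA"))
        assert d["gtpc|g1.g1.g1"] == pytest.approx(1.0)

    def test_hand_enumerated_aafd(self):
        # AAF -> (g1,g1,g2), AFD -> (g1,g2,g4); 2 tripeptides
        d = as_dict(ph.encode_gtpc("AAFD"))
        assert d["gtpc|g1.g1.g2"] == pytest.approx(0.5)
        assert d["gtpc|g1.g2.g4"] == pytest.approx(0.5)

    def test_too_short(self):
        with pytest.raises(LengthError):
            ph.encode_gtpc("AA")

    def test_alternative_denominator_scales_by_ratio(self):
        seq = "ACDEFGHIKL"
        default = ph.encode_gtpc(seq).values
        alt = ph.encode_gtpc(seq, denominator="n-1").values
        np.testing.assert_allclose(alt * (len(seq) - 1), default * (len(seq) - 2))

    @given(valid_sequences)
    def test_125_entries_summing_to_one(self, seq):
        fv = ph.encode_gtpc(seq)
        assert len(fv) == 125
        assert fv.values.sum() == pytest.approx(1.0)


class TestCTDC:
    def test_charge_homopolymer(self):
        d = as_dict(ph.encode_ctdc("KKKK"))
        assert d["ctd|charge|positive"] == pytest.approx(1.0)
        assert d["ctd|charge|neutral"] == 0.0
        assert d["ctd|charge|negative"] == 0.0

    def test_charge_on_ad(self):
        d = as_dict(ph.encode_ctdc("AD"))
        assert d["ctd|charge|neutral"] == pytest.approx(0.5)
        assert d["ctd|charge|negative"] == pytest.approx(0.5)

    @given(valid_sequences)
    def test_39_entries_summing_to_13(self, seq):
        fv = ph.encode_ctdc(seq)
        assert len(fv) == 39
        assert fv.values.sum() == pytest.approx(13.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(ph.ALPHABET), size=60))
        shuffled = "".join(rng.permutation(list(seq)))
        np.testing.assert_allclose(
            ph.encode_ctdc(seq).values, ph.encode_ctdc(shuffled).values
        )
        # order-sensitive blocks generally change under permutation
        assert not np.allclose(
            ph.encode_ggdc(seq).values, ph.encode_ggdc(shuffled).values
        )
        assert not np.allclose(
            ph.encode_gtpc(seq).values, ph.encode_gtpc(shuffled).values
        )


class TestCombined:
    @pytest.mark.parametrize(
        "scheme,dim",
        [("ggdc+pseaac", 550), ("gtpc+ctd", 164), ("all", 714)],
    )
    def test_scheme_dimensions(self, small_dataset, scheme, dim):
        m = ph.encode_combined(small_dataset, scheme=scheme)
        assert m.n_features == dim
        assert ph.scheme_dimension(scheme) == dim

    def test_block_order_is_fixed(self, small_dataset):
        m = ph.encode_combined(small_dataset, scheme="all")
        assert m.block_prefixes() == ["ggdc", "pseaac", "gtpc", "ctd"]

    def test_encoding_is_pure(self, small_dataset):
        a = ph.encode_combined(small_dataset, scheme="all")
        b = ph.encode_combined(small_dataset, scheme="all")
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)

    def test_short_sequences_reported_in_aggregate(self):
        ds = ph.Dataset(
            [
                ph.ProteinRecord("ok", "A" * 30, 1),
                ph.ProteinRecord("short1", "ACDE", 0),
                ph.ProteinRecord("short2", "ACD", 0),
            ]
        )
        with pytest.raises(EncodingError) as exc:
            ph.encode_combined(ds, scheme="all")
        assert set(exc.value.failed_ids) == {"short1", "short2"}

    def test_unknown_scheme_rejected(self, small_dataset):
        with pytest.raises(ConfigError):
            ph.encode_combined(small_dataset, scheme="ggdc+ctd")
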