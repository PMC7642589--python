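import math

import numpy as np
import pytest

from oracles import (
    oracle_aac,
    oracle_cksaagp,
    oracle_ctdc,
    oracle_ctdt,
    oracle_ctriad,
    oracle_dde,
    oracle_grouped_kmer,
    oracle_kmer,
)
from thermoprot.encoders import (
    FeatureMatrix,
    ProteinFeatureEncoder,
    encode_aac,
    encode_cksaagp,
    encode_ctdc,
    encode_ctdt,
    encode_ctriad,
    encode_dataset,
    encode_dde,
    encode_dpc,
    encode_gdpc,
    encode_gtpc,
    encode_tpc,
)
from thermoprot.sequence_io import ProteinSequence
from thermoprot.tables import AA_GROUPS_5, CTD_PROPERTIES, CTRIAD_CLASSES


def seq(residues: str, sid: str = "s") -> ProteinSequence:
    return ProteinSequence(sid, residues)


class TestTrivialExamples:
    def test_aac_homopolymer(self):
        v = encode_aac(seq("AAAA")).as_dict()
        assert v["A"] == 1.0 and sum(v.values()) == 1.0

    def test_aac_mkkd(self):
        v = encode_aac(seq("MKKD")).as_dict()
        assert v["K"] == 0.5 and v["M"] == 0.25 and v["D"] == 0.25

    def test_dpc_overlapping_windows(self):
        assert encode_dpc(seq("AAA")).as_dict()["AA"] == 1.0
        v = encode_dpc(seq("MKKD")).as_dict()
        assert v["MK"] == v["KK"] == v["KD"] == pytest.approx(1 / 3)

    def test_tpc_overlapping_windows(self):
        assert encode_tpc(seq("AAAA")).as_dict()["AAA"] == 1.0
        v = encode_tpc(seq("MKKDE")).as_dict()
        assert v["MKK"] == v["KKD"] == v["KDE"] == pytest.approx(1 / 3)

    def test_dde_two_residue_closed_form(self):
        tm = (4 / 61) * (2 / 61)
        expected = (1 - tm) / math.sqrt(tm * (1 - tm))
        assert encode_dde(seq("AC")).as_dict()["AC"] == pytest.approx(expected, abs=1e-12)

    def test_dde_sign_tracks_observed_minus_expected(self, random_sequences):
        from thermoprot.tables import CODON_COUNTS

        s = random_sequences[0]
        dde = encode_dde(s).as_dict()
        dpc = encode_dpc(s).as_dict()
        for name, value in dde.items():
            tm = (CODON_COUNTS[name[0]] / 61) * (CODON_COUNTS[name[1]] / 61)
            assert np.sign(value) == np.sign(dpc[name] - tm)
        # A-homopolymer: observed AA frequency 1 far exceeds (4/61)^2
        assert encode_dde(seq("A" * 400)).as_dict()["AA"] > 0

    def test_gdpc_single_group(self):
        v = encode_gdpc(seq("GAVL")).as_dict()  # all aliphatic (g1)
        assert v["g1g1"] == 1.0

    def test_gtpc_single_group(self):
        v = encode_gtpc(seq("GAVLMI")).as_dict()
        assert v["g1g1g1"] == 1.0

    def test_cksaagp_gap0_equals_gdpc(self, random_sequences):
        s = next(x for x in random_sequences if len(x) >= 7)
        ck = encode_cksaagp(s).as_dict()
        gd = encode_gdpc(s).as_dict()
        for pair, value in gd.items():
            assert ck[f"{pair}.k0"] == pytest.approx(value, abs=1e-15)

    def test_ctdc_all_group1(self):
        # RKEDQN is group 1 of the PRAM900101 hydrophobicity attribute
        v = encode_ctdc(seq("RKEDQN")).as_dict()
        assert v["hydrophobicity_PRAM900101.G1"] == 1.0

    def test_ctdt_homogeneous_no_transitions(self):
        v = encode_ctdt(seq("RRRR")).as_dict()
        assert all(value == 0.0 for value in v.values())

    def test_ctdt_alternating(self):
        # charge attribute: K in group 1, D in group 3 -> alternating 1313..
        v = encode_ctdt(seq("KDKDKD")).as_dict()
        assert v["charge.Tr31"] == 1.0

    def test_ctriad_single_class(self):
        v = encode_ctriad(seq("AGVAGV")).as_dict()
        assert v["111"] == 1.0


class TestOracleEquivalence:
    """Vectorized encoders vs naive window-enumeration on random sequences."""

    def test_aac_dpc_tpc_dde(self, random_sequences):
        for s in random_sequences[:50]:
            assert encode_aac(s).as_dict() == pytest.approx(oracle_aac(s.residues), abs=1e-12)
            assert encode_dpc(s).as_dict() == pytest.approx(
                oracle_kmer(s.residues, 2), abs=1e-12
            )
            assert encode_tpc(s).as_dict() == pytest.approx(
                oracle_kmer(s.residues, 3), abs=1e-12
            )
            assert encode_dde(s).as_dict() == pytest.approx(
                oracle_dde(s.residues), abs=1e-12
            )

    def test_grouped_encoders(self, random_sequences):
        for s in random_sequences[:50]:
            assert encode_gdpc(s).as_dict() == pytest.approx(
                oracle_grouped_kmer(s.residues, 2, AA_GROUPS_5), abs=1e-12
            )
            assert encode_gtpc(s).as_dict() == pytest.approx(
                oracle_grouped_kmer(s.residues, 3, AA_GROUPS_5), abs=1e-12
            )
            if len(s) >= 7:
                assert encode_cksaagp(s).as_dict() == pytest.approx(
                    oracle_cksaagp(s.residues, AA_GROUPS_5), abs=1e-12
                )

    def test_ctd_and_ctriad(self, random_sequences):
        for s in random_sequences[:50]:
            assert encode_ctdc(s).as_dict() == pytest.approx(
                oracle_ctdc(s.residues, CTD_PROPERTIES), abs=1e-12
            )
            assert encode_ctdt(s).as_dict() == pytest.approx(
                oracle_ctdt(s.residues, CTD_PROPERTIES), abs=1e-12
            )
            assert encode_ctriad(s).as_dict() == pytest.approx(
                oracle_ctriad(s.residues, CTRIAD_CLASSES), abs=1e-12
            )


class TestInvariants:
    def test_permutation_invariance_aac_ctdc(self, random_sequences):
        rng = np.random.default_rng(3)
        s = random_sequences[10]
        shuffled = seq("".join(rng.permutation(list(s.residues))), "shuf")
        np.testing.assert_allclose(
            encode_aac(s).values, encode_aac(shuffled).values, atol=1e-15
        )
        np.testing.assert_allclose(
            encode_ctdc(s).values, encode_ctdc(shuffled).values, atol=1e-15
        )

    def test_order_sensitivity_witness(self):
        """DPC/TPC/CTDT change when the sequence order changes."""
        a, b = seq("KDKDKDKD"), seq("KKKKDDDD")
        assert not np.allclose(encode_dpc(a).values, encode_dpc(b).values)
        assert not np.allclose(encode_tpc(a).values, encode_tpc(b).values)
        assert not np.allclose(encode_ctdt(a).values, encode_ctdt(b).values)

    def test_determinism_bit_identical(self, random_sequences):
        s = random_sequences[0]
        for fn in (encode_aac, encode_dpc, encode_dde, encode_ctdt):
            first, second = fn(s), fn(s)
            assert np.array_equal(first.values, second.values)
            assert first.names == second.names

    @pytest.mark.parametrize(
        "fn,n_min",
        [(encode_dpc, 2), (encode_tpc, 3), (encode_dde, 2), (encode_gtpc, 3),
         (encode_ctriad, 3), (encode_cksaagp, 7)],
    )
    def test_too_short_raises(self, fn, n_min):
        with pytest.raises(ValueError, match="requires length"):
            fn(seq("A" * (n_min - 1)))


class TestDatasetAssembly:
    def test_single_encoder_shape(self, small_dataset):
        m = encode_dataset(small_dataset, ["AAC"])
        assert m.shape == (80, 20)
        assert m.feature_names[8] == "AAC:K"

    def test_concatenation_order_and_width(self, small_dataset):
        m = encode_dataset(small_dataset, ["AAC", "DPC"])
        assert m.shape[1] == 420
        assert m.feature_names[:20] == [f"AAC:{a}" for a in "ACDEFGHIKLMNPQRSTVWY"]
        assert m.feature_names[20] == "DPC:AA"

    def test_named_column_matches_encoder(self, small_dataset):
        m = encode_dataset(small_dataset, ["AAC", "DPC"])
        s = small_dataset.sequences[5]
        assert m.X.loc[s.id, "DPC:LK"] == pytest.approx(
            oracle_kmer(s.residues, 2)["LK"], abs=1e-12
        )

    def test_labels_carried(self, small_dataset):
        m = encode_dataset(small_dataset, ["AAC"])
        assert m.y.sum() == 40 and len(m.y) == 80

    def test_too_short_sequence_names_offender(self):
        data = [ProteinSequence("ok", "MKLD", 1), ProteinSequence("tiny", "MK", 0)]
        with pytest.raises(ValueError, match="tiny.*TPC"):
            encode_dataset(data, ["TPC"])

    def test_unknown_encoder(self, small_dataset):
        with pytest.raises(ValueError, match="unknown encoder"):
            encode_dataset(small_dataset, ["nope"])

    def test_csv_roundtrip(self, tmp_path, small_dataset):
        m = encode_dataset(small_dataset, ["AAC"])
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.feature_names == m.feature_names
        np.testing.assert_allclose(back.X.to_numpy(), m.X.to_numpy(), atol=1e-12)
        assert (back.y == m.y).all()

    def test_libsvm_format(self, tmp_path, small_dataset):
        m = encode_dataset(small_dataset, ["AAC"])
        path = tmp_path / "m.libsvm"
        m.to_libsvm(path)
        first = path.read_text().splitlines()[0].split()
        assert first[0] in {"0", "1"}
        idx, val = first[1].split(":")
        assert int(idx) >= 1 and float(val) > 0


class TestSklearnTransformer:
    def test_transform_matches_encode_dataset(self, small_dataset):
        enc = ProteinFeatureEncoder(encoders=["AAC", "CTDC"]).fit(small_dataset.sequences)
        out = enc.transform(small_dataset.sequences)
        ref = encode_dataset(small_dataset, ["AAC", "CTDC"])
        assert list(out.columns) == ref.feature_names
        np.testing.assert_allclose(out.to_numpy(), ref.X.to_numpy(), atol=1e-15)

    def test_accepts_raw_strings(self):
        out = ProteinFeatureEncoder(encoders=["AAC"]).fit_transform(["MKKD", "MLLD"])
        assert out.shape == (2, 20)

    def test_feature_names_out(self, small_dataset):
        enc = ProteinFeatureEncoder(encoders=["GDPC"]).fit(small_dataset.sequences)
        assert list(enc.get_feature_names_out())[:2] == ["GDPC:g1g1", "GDPC:g1g2"]
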