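import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcvote import (
    EncoderConfig,
    EncodingError,
    LabeledDataset,
    ProteinSequence,
    encode_188d,
    encode_apaac,
    encode_cksaagp,
    encode_cksaap,
    encode_dataset,
    encode_ksctriad,
    encode_mixed,
    encode_paac,
)
from mhcvote.seqio import ALPHABET

from .oracles import (
    oracle_188d,
    oracle_apaac,
    oracle_cksaagp,
    oracle_cksaap,
    oracle_ksctriad,
    oracle_paac,
)

residues = st.text(alphabet=ALPHABET, min_size=12, max_size=60)


class TestPropertyTables:
    def test_partitions_cover_alphabet(self, tables):
        for name, classes in tables.ctd_partitions.items():
            assert sorted(classes) == sorted(ALPHABET), name
            assert set(classes.values()) == {1, 2, 3}, name
        assert len(tables.ctd_partitions) == 8
        assert sorted("".join("".join(g) for g in tables.sidechain_groups.values())) \
            == sorted(ALPHABET)
        assert sorted(tables.triad_classes) == sorted(ALPHABET)
        assert set(tables.triad_classes.values()) == set(range(1, 8))

    def test_scales_standardized(self, tables):
        for name, scale in tables.scales.items():
            vals = np.array([scale[a] for a in ALPHABET])
            assert abs(vals.mean()) < 1e-9, name
            assert abs(vals.std() - 1) < 1e-9, name


class TestDimensions:
    def test_188d_is_188(self, random_seq):
        assert len(encode_188d(random_seq(40))) == 188

    def test_ctd_block_is_21_per_property(self, random_seq):
        fv = encode_188d(random_seq(40))
        per_prop = {}
        for lab in fv.labels[20:]:
            per_prop.setdefault(lab.split(".")[1], []).append(lab)
        assert len(per_prop) == 8
        assert all(len(v) == 21 for v in per_prop.values())

    @pytest.mark.parametrize(
        "enc,args,expect",
        [
            (encode_apaac, {"lam": 1}, 22),
            (encode_paac, {"lam": 3}, 23),
            (encode_ksctriad, {"kmax": 0}, 343),
            (encode_ksctriad, {"kmax": 2}, 1029),
            (encode_cksaagp, {"kmax": 4}, 125),
            (encode_cksaap, {"kmax": 0}, 400),
        ],
    )
    def test_closed_forms(self, random_seq, enc, args, expect):
        assert len(enc(random_seq(50), **args)) == expect

    @pytest.mark.parametrize("seed", range(20))
    def test_mixed_dimension_law_random_configs(self, random_seq, seed):
        r = np.random.default_rng(seed)
        cfg = EncoderConfig(
            lambda_apaac=int(r.integers(1, 8)),
            lambda_paac=int(r.integers(1, 8)),
            kmax_ksctriad=int(r.integers(0, 3)),
            kmax_cksaagp=int(r.integers(0, 5)),
            enabled=tuple(
                b for b in ("d188", "apaac", "ksctriad", "cksaagp", "paac")
                if r.random() < 0.7
            ) or ("d188",),
        )
        fv = encode_mixed(random_seq(60, seed=seed), cfg)
        assert len(fv) == cfg.dimension == len(fv.labels)

    def test_mixed_example_599(self, random_seq):
        cfg = EncoderConfig(
            lambda_apaac=1, lambda_paac=1, kmax_ksctriad=0, kmax_cksaagp=0
        )
        assert cfg.dimension == 188 + 22 + 343 + 25 + 21 == 599
        assert len(encode_mixed(random_seq(50), cfg)) == 599


class TestAACAnd188D:
    def test_homopolymer_aac(self):
        fv = encode_188d(ProteinSequence(id="h", residues="AAAA"))
        assert fv.values[0] == 1.0
        assert np.allclose(fv.values[1:20], 0)
        assert abs(fv.values[:20].sum() - 1) < 1e-12

    def test_aac_sums_to_one(self, random_seq):
        for seed in range(5):
            fv = encode_188d(random_seq(33, seed=seed))
            assert abs(fv.values[:20].sum() - 1) < 1e-9

    def test_single_crossing_transition(self, tables):
        # A (neutral) and C (hydrophobic) sit in different hydrophobicity
        # classes: the single adjacent pair crosses class pair 2-3 with
        # frequency 1/(L-1) = 1.
        fv = encode_188d(ProteinSequence(id="ac", residues="AC"))
        lab2val = dict(zip(fv.labels, fv.values))
        assert tables.ctd_partitions["hydrophobicity"]["A"] == 2
        assert tables.ctd_partitions["hydrophobicity"]["C"] == 3
        assert lab2val["d188.hydrophobicity.T23"] == 1.0
        assert lab2val["d188.hydrophobicity.T12"] == 0.0

    def test_absent_class_distribution_zero(self):
        # "AAAA" has no charged residues: both charge classes 1 and 3 absent.
        fv = encode_188d(ProteinSequence(id="h", residues="AAAA"))
        lab2val = dict(zip(fv.labels, fv.values))
        for c in (1, 3):
            for q in ("first", "p25", "p50", "p75", "p100"):
                assert lab2val[f"d188.charge.D{c}.{q}"] == 0.0

    def test_shuffle_leaves_composition_blocks(self, random_seq, rng):
        seq = random_seq(60)
        shuffled = ProteinSequence(
            id="sh", residues="".join(rng.permutation(list(seq.residues)))
        )
        a, b = encode_188d(seq), encode_188d(shuffled)
        comp_idx = [i for i, lab in enumerate(a.labels)
                    if "AAC" in lab or lab.split(".")[2].startswith("C")]
        assert np.allclose(a.values[comp_idx], b.values[comp_idx])


class TestPseudoComposition:
    def test_apaac_sums_to_one(self, random_seq):
        for seed in range(5):
            fv = encode_apaac(random_seq(50, seed=seed), lam=5)
            assert abs(fv.values.sum() - 1) < 1e-9

    def test_paac_sums_to_one(self, random_seq):
        for seed in range(5):
            fv = encode_paac(random_seq(50, seed=seed), lam=5)
            assert abs(fv.values.sum() - 1) < 1e-9

    def test_apaac_homopolymer_closed_form(self, tables):
        # For a constant sequence every tau collapses to H(A)^2.
        seq = ProteinSequence(id="h", residues="AAAAAA")
        fv = encode_apaac(seq, lam=2, w=0.05)
        h1a = tables.scales["hydrophobicity"]["A"]
        h2a = tables.scales["hydrophilicity"]["A"]
        denom = 1 + 0.05 * (2 * h1a**2 + 2 * h2a**2)
        lab2val = dict(zip(fv.labels, fv.values))
        assert lab2val["apaac.tau.1"] == pytest.approx(0.05 * h1a**2 / denom)
        assert lab2val["apaac.tau.3"] == pytest.approx(0.05 * h1a**2 / denom)
        assert lab2val["apaac.tau.2"] == pytest.approx(0.05 * h2a**2 / denom)
        assert lab2val["apaac.tau.4"] == pytest.approx(0.05 * h2a**2 / denom)

    def test_paac_homopolymer_equals_aac(self):
        # Zero property differences: theta = 0, vector reduces to plain AAC.
        seq = ProteinSequence(id="h", residues="CCCCCCCC")
        fv = encode_paac(seq, lam=3)
        assert np.allclose(fv.values[20:], 0)
        assert fv.values[1] == pytest.approx(1.0)  # C frequency

    def test_too_short_rejected(self, random_seq):
        with pytest.raises(EncodingError, match="minimum"):
            encode_apaac(random_seq(5), lam=10)
        with pytest.raises(EncodingError, match="minimum"):
            encode_paac(random_seq(5), lam=5)


class TestTriadsAndPairs:
    def test_single_triad_window(self):
        # A maps to conjoint-triad class 1: one window, count at (1,1,1).
        fv = encode_ksctriad(ProteinSequence(id="t", residues="AAA"), kmax=0)
        assert fv.values[0] == 1.0  # (count 1 - min 0) / max 1
        assert fv.values[1:].sum() == 0

    def test_cksaagp_single_pair(self):
        fv = encode_cksaagp(ProteinSequence(id="gf", residues="GF"), kmax=0)
        lab2val = dict(zip(fv.labels, fv.values))
        assert lab2val["cksaagp.k0.aliphatic|aromatic"] == 1.0
        assert fv.values.sum() == 1.0

    def test_cksaagp_blocks_sum_to_one(self, random_seq):
        fv = encode_cksaagp(random_seq(40), kmax=3)
        for k in range(4):
            assert abs(fv.values[25 * k : 25 * (k + 1)].sum() - 1) < 1e-9

    def test_cksaap_two_windows(self):
        fv = encode_cksaap(ProteinSequence(id="aca", residues="ACA"), kmax=0)
        lab2val = dict(zip(fv.labels, fv.values))
        assert lab2val["cksaap.k0.AC"] == 0.5
        assert lab2val["cksaap.k0.CA"] == 0.5

    def test_cksaap_blocks_sum_to_one(self, random_seq):
        fv = encode_cksaap(random_seq(30), kmax=2)
        for k in range(3):
            assert abs(fv.values[400 * k : 400 * (k + 1)].sum() - 1) < 1e-9

    def test_short_sequence_rejected(self):
        with pytest.raises(EncodingError):
            encode_ksctriad(ProteinSequence(id="x", residues="ACDE"), kmax=1)
        with pytest.raises(EncodingError):
            encode_cksaagp(ProteinSequence(id="x", residues="AC"), kmax=1)


class TestOracleEquivalence:
    """Every encoder against an independent naive enumeration."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_encoders_match_brute_force(self, tables, random_seq, seed):
        r = np.random.default_rng(100 + seed)
        seq = random_seq(int(r.integers(15, 31)), seed=200 + seed)
        s = seq.residues
        checks = [
            (encode_188d(seq, tables).values, oracle_188d(s, tables)),
            (encode_apaac(seq, 3, 0.05, tables).values,
             oracle_apaac(s, 3, 0.05, tables)),
            (encode_paac(seq, 4, 0.05, tables).values,
             oracle_paac(s, 4, 0.05, tables)),
            (encode_ksctriad(seq, 1, tables).values, oracle_ksctriad(s, 1, tables)),
            (encode_cksaagp(seq, 2, tables).values, oracle_cksaagp(s, 2, tables)),
            (encode_cksaap(seq, 2).values, oracle_cksaap(s, 2)),
        ]
        for got, expected in checks:
            np.testing.assert_allclose(got, np.array(expected), atol=1e-9)


class TestMixed:
    def test_single_block_identity(self, random_seq):
        seq = random_seq(50)
        cfg = EncoderConfig(enabled=("d188",))
        assert np.array_equal(encode_mixed(seq, cfg).values, encode_188d(seq).values)

    def test_block_independence(self, random_seq):
        seq = random_seq(50)
        full = EncoderConfig(lambda_apaac=2, lambda_paac=2, kmax_ksctriad=0,
                             kmax_cksaagp=1)
        partial = EncoderConfig(lambda_apaac=2, lambda_paac=2, kmax_ksctriad=0,
                                kmax_cksaagp=1,
                                enabled=("d188", "ksctriad", "paac"))
        fv_full = encode_mixed(seq, full)
        fv_part = encode_mixed(seq, partial)
        full_map = dict(zip(fv_full.labels, fv_full.values))
        for lab, val in zip(fv_part.labels, fv_part.values):
            assert full_map[lab] == val

    def test_error_names_failing_block(self, random_seq):
        cfg = EncoderConfig(lambda_apaac=40)
        with pytest.raises(EncodingError, match="apaac"):
            encode_mixed(random_seq(20), cfg)

    def test_canonical_block_order(self, random_seq):
        cfg = EncoderConfig(enabled=("paac", "d188"))  # order is canonicalized
        fv = encode_mixed(random_seq(40), cfg)
        assert fv.labels[0].startswith("d188.")
        assert fv.labels[-1].startswith("paac.")


@given(residues)
@settings(max_examples=30, deadline=None)
def test_dimension_law_property(s):
    cfg = EncoderConfig(lambda_apaac=2, lambda_paac=2, kmax_ksctriad=1,
                        kmax_cksaagp=2)
    if len(s) < cfg.min_length:
        with pytest.raises(EncodingError):
            encode_mixed(ProteinSequence(id="h", residues=s), cfg)
    else:
        fv = encode_mixed(ProteinSequence(id="h", residues=s), cfg)
        assert len(fv) == cfg.dimension
        assert np.all(np.isfinite(fv.values))


class TestEncodeDataset:
    @staticmethod
    def _dataset(random_seq, n=5, length=50):
        seqs = [random_seq(length, seed=i, sid=f"q{i}") for i in range(n)]
        return LabeledDataset(sequences=seqs, labels=[1, 1, 1, 0, 0][:n])

    def test_matrix_shape_and_consistency(self, random_seq):
        cfg = EncoderConfig(lambda_apaac=1, lambda_paac=1, kmax_ksctriad=0,
                            kmax_cksaagp=0)
        ds = self._dataset(random_seq)
        X, y, ids, labels = encode_dataset(ds, cfg)
        assert X.shape == (5, 599)
        assert list(y) == ds.labels and ids == ds.ids
        row = encode_mixed(ds.sequences[2], cfg)
        np.testing.assert_array_equal(X[2], row.values)
        assert labels == row.labels

    def test_empty_dataset_rejected(self):
        from mhcvote import DataError

        with pytest.raises(DataError):
            encode_dataset(LabeledDataset(sequences=[], labels=[]))

    def test_unencodable_ids_listed(self, random_seq):
        cfg = EncoderConfig(lambda_apaac=30, lambda_paac=30)
        short = ProteinSequence(id="shorty", residues="ACDEFGHIKL")
        ds = LabeledDataset(
            sequences=[random_seq(80, sid="ok"), short], labels=[1, 0]
        )
        with pytest.raises(EncodingError, match="shorty"):
            encode_dataset(ds, cfg)
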