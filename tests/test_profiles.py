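import math

import numpy as np
import pytest

from idrpred.errors import DataError
from idrpred.profiles import (
    FEATURE_ROW_NAMES,
    assemble_feature_matrix,
    pseudo_pssm,
    read_feature_tsv,
    shannon_entropy_track,
    topological_entropy_track,
    windowed_average_track,
    write_feature_tsv,
)
from idrpred.scales import default_scales, load_scales_json, save_scales_json
from idrpred.seq_io import ProteinRecord

AA = "ARNDCQEGHILKMFPSTWYV"


class TestWindowedAverage:
    def test_constant_interior(self):
        out = windowed_average_track(np.full(11, 5.0), 3)
        np.testing.assert_allclose(out[1:-1], 5.0)

    def test_zero_padded_terminal(self):
        out = windowed_average_track(np.full(11, 3.0), 3)
        assert out[0] == pytest.approx(2.0)  # (0 + 3 + 3)/3
        assert out[-1] == pytest.approx(2.0)

    def test_all_zero(self):
        np.testing.assert_array_equal(windowed_average_track(np.zeros(9), 5), np.zeros(9))

    def test_window_validation(self):
        with pytest.raises(DataError):
            windowed_average_track(np.zeros(9), 4)
        with pytest.raises(DataError):
            windowed_average_track(np.zeros(9), 9)


class TestShannonEntropy:
    def test_homopolymer_zero(self):
        track = shannon_entropy_track(ProteinRecord("h", "A" * 20), 5)
        np.testing.assert_array_equal(track, 0.0)

    def test_hand_worked_two_to_one(self):
        # interior window "AAR": -(2/3)log2(2/3) - (1/3)log2(1/3)
        track = shannon_entropy_track(ProteinRecord("x", "AARAA"), 3)
        assert track[1] == pytest.approx(0.918296, abs=1e-6)

    def test_uniform_window_hits_log2_of_alphabet(self):
        rec = ProteinRecord("u", AA + AA)
        track = shannon_entropy_track(rec, 21)
        # a window holding 21 of 40 cyclic residues covers 20 distinct ones
        # once plus one duplicate; max possible entropy is log2(20)
        assert track.max() <= math.log2(20) + 1e-12
        assert track.max() > 4.2


class TestTopologicalEntropy:
    def test_homopolymer_zero(self):
        track = topological_entropy_track(ProteinRecord("h", "A" * 40), 21)
        np.testing.assert_array_equal(track, 0.0)

    def test_ten_distinct_prefix_value(self):
        # first 20 characters of each window contain 10 distinct residues
        seq = "ARNDCQEGHI" * 6
        track = topological_entropy_track(ProteinRecord("x", seq), 33)
        assert track[30] == pytest.approx(math.log(10, 20), abs=1e-9)

    def test_bounded_by_one(self, rng):
        seq = "".join(rng.choice(list(AA), size=80))
        track = topological_entropy_track(ProteinRecord("r", seq), 21)
        assert np.all(track <= 1.0 + 1e-12)
        assert np.all(track >= 0.0)

    def test_window_below_20_errors(self):
        with pytest.raises(DataError, match="topological entropy"):
            topological_entropy_track(ProteinRecord("x", "A" * 30), 15)


class TestScales:
    def test_ten_scales_complete(self):
        scales = default_scales()
        assert len(scales) == 10
        for s in scales:
            assert len(s.values) == 20

    def test_json_roundtrip(self, tmp_path):
        scales = default_scales()
        path = tmp_path / "scales.json"
        save_scales_json(path, scales)
        back = load_scales_json(path)
        assert [s.name for s in back] == [s.name for s in scales]
        assert back[0].values == scales[0].values

    def test_propensity_standins_flag_their_provenance(self):
        for s in default_scales()[7:]:
            assert "synthetic" in s.provenance


class TestAssembly:
    @pytest.fixture()
    def matrix(self, tiny_corpus, tiny_tables):
        records, pssms = tiny_corpus
        t2, t3 = tiny_tables
        rec = records[0]
        F = assemble_feature_matrix(rec, pssms[rec.id], t2, t3, window=33)
        return rec, F

    def test_shape_and_finiteness(self, matrix):
        rec, F = matrix
        assert F.shape == (35, len(rec))
        assert np.isfinite(F).all()

    def test_row_semantics_documented_order(self, matrix, tiny_corpus, tiny_tables):
        records, pssms = tiny_corpus
        t2, t3 = tiny_tables
        rec, F = matrix
        assert len(FEATURE_ROW_NAMES) == 35
        assert FEATURE_ROW_NAMES[0] == "pssm_A"
        assert FEATURE_ROW_NAMES[33] == "pcaa2"
        # rows 1-20 are the window-averaged PSSM channels
        np.testing.assert_allclose(
            F[0], windowed_average_track(pssms[rec.id][:, 0], 33)
        )
        # rows 34-35 are the raw PCAA tracks
        from idrpred.kmers import pcaa_track

        np.testing.assert_allclose(F[33], pcaa_track(rec, t2))
        np.testing.assert_allclose(F[34], pcaa_track(rec, t3))
        assert np.all((F[33:] >= 0) & (F[33:] <= 1))

    def test_entropy_rows_nonnegative(self, matrix):
        _, F = matrix
        assert np.all(F[30:33] >= 0)

    def test_homopolymer_constant_interior(self, tiny_tables):
        t2, t3 = tiny_tables
        rec = ProteinRecord("h", "A" * 80)
        pssm = np.tile(np.arange(20, dtype=float), (80, 1))
        F = assemble_feature_matrix(rec, pssm, t2, t3, window=21)
        interior = F[:, 25:55]
        np.testing.assert_allclose(interior, interior[:, :1] * np.ones((1, 30)), atol=1e-9)

    def test_locality_of_point_mutation(self, tiny_corpus, tiny_tables):
        records, pssms = tiny_corpus
        t2, t3 = tiny_tables
        rec = records[1]
        N = 21
        p = len(rec) // 2
        mutated_seq = rec.sequence[:p] + ("A" if rec.sequence[p] != "A" else "R") + rec.sequence[p + 1 :]
        mut = ProteinRecord(rec.id + "_mut", mutated_seq)
        F0 = assemble_feature_matrix(rec, pssms[rec.id], t2, t3, window=N)
        F1 = assemble_feature_matrix(mut, pssms[rec.id], t2, t3, window=N)
        diff_cols = np.where(np.abs(F0 - F1).max(axis=0) > 1e-12)[0]
        assert diff_cols.size > 0
        assert diff_cols.min() >= p - N + 1
        assert diff_cols.max() <= p + N - 1

    def test_missing_pssm_requires_fallback_flag(self, tiny_tables):
        t2, t3 = tiny_tables
        rec = ProteinRecord("x", "MKVLAEDTSGRPQNWYHCIF" * 3)
        with pytest.raises(DataError, match="PSSM"):
            assemble_feature_matrix(rec, None, t2, t3, window=21)
        F = assemble_feature_matrix(rec, None, t2, t3, window=21, pssm_fallback=True)
        assert F.shape == (35, 60)

    def test_pssm_shape_mismatch(self, tiny_tables):
        t2, t3 = tiny_tables
        rec = ProteinRecord("x", "MKVLAEDTSGRPQNWYHCIF" * 3)
        with pytest.raises(DataError):
            assemble_feature_matrix(rec, np.zeros((10, 20)), t2, t3, window=21)

    def test_deterministic(self, tiny_corpus, tiny_tables):
        records, pssms = tiny_corpus
        t2, t3 = tiny_tables
        rec = records[2]
        F1 = assemble_feature_matrix(rec, pssms[rec.id], t2, t3, window=21)
        F2 = assemble_feature_matrix(rec, pssms[rec.id], t2, t3, window=21)
        np.testing.assert_array_equal(F1, F2)

    def test_tsv_roundtrip(self, tmp_path, matrix):
        rec, F = matrix
        path = tmp_path / "f.tsv"
        write_feature_tsv(path, rec, F)
        back = read_feature_tsv(path)
        assert back.shape == F.shape
        np.testing.assert_allclose(back, F, rtol=1e-4, atol=1e-5)


class TestPseudoPssm:
    def test_blosum_rows(self):
        rec = ProteinRecord("x", "AR")
        mat = pseudo_pssm(rec)
        assert mat.shape == (2, 20)
        assert mat[0, 0] == 4.0  # BLOSUM62 A->A
        assert mat[1, 1] == 5.0  # BLOSUM62 R->R
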