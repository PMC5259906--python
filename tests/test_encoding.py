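import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gtpsite import encoding
from gtpsite.encoding import (
    WindowFragment,
    encode_pssm_window,
    encode_substitution_window,
    extract_windows,
    logistic_scale,
    substitution_encoding,
)
from gtpsite.io_formats import (
    ConsistencyError,
    ParameterError,
    ProteinRecord,
    PSSMProfile,
    PSSM_COLUMNS,
)


class TestLogisticScale:
    def test_midpoint(self):
        assert logistic_scale(0) == 0.5

    def test_direct_value(self):
        assert logistic_scale(7) == pytest.approx(1 / (1 + math.exp(-7)), abs=1e-12)
        assert logistic_scale(7) == pytest.approx(0.999088, abs=1e-6)

    @given(st.floats(min_value=-30, max_value=30))
    def test_symmetry_sums_to_one(self, x):
        assert logistic_scale(x) + logistic_scale(-x) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=-20, max_value=20), st.floats(min_value=0.01, max_value=5))
    def test_strictly_increasing(self, x, dx):
        assert logistic_scale(x + dx) > logistic_scale(x)


class TestExtractWindows:
    def test_exhaustive_small_case(self):
        rec = ProteinRecord("P1", "GKS")
        frags = extract_windows(rec, 3)
        assert [f.residues for f in frags] == ["-GK", "GKS", "KS-"]
        assert [f.label for f in frags] == [0, 0, 0]
        assert [f.center for f in frags] == [0, 1, 2]

    def test_center_label_from_annotation(self):
        rec = ProteinRecord("P1", "GKS", binding_positions={2})
        assert [f.label for f in extract_windows(rec, 3)] == [0, 1, 0]

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            extract_windows(ProteinRecord("P1", "GKS"), 4)

    @given(st.integers(min_value=1, max_value=30), st.sampled_from([1, 3, 19]))
    def test_one_window_per_residue(self, n, w):
        rec = ProteinRecord("P1", "A" * n)
        frags = extract_windows(rec, w)
        assert len(frags) == n
        half = (w - 1) // 2
        for f in frags:
            assert len(f.residues) == w
            assert f.residues[half] == rec.sequence[f.center]

    def test_total_fragments_and_positives_over_dataset(self, signal_dataset):
        records, _, _ = signal_dataset
        frags = [f for r in records for f in extract_windows(r, 19)]
        assert len(frags) == sum(len(r.sequence) for r in records)
        assert sum(f.label for f in frags) == sum(r.n_positive for r in records)


class TestEncodePSSMWindow:
    def make(self, n=25, seed=0):
        rng = np.random.default_rng(seed)
        rec = ProteinRecord("P1", "".join(rng.choice(list(PSSM_COLUMNS), n)))
        prof = PSSMProfile("P1", rng.integers(-8, 10, size=(n, 20)))
        return rec, prof

    def test_length_380_for_window_19(self):
        rec, prof = self.make()
        frag = extract_windows(rec, 19)[12]
        assert encode_pssm_window(prof, frag).shape == (380,)

    def test_zero_scores_map_to_half(self):
        rec = ProteinRecord("P1", "ACD")
        prof = PSSMProfile("P1", np.zeros((3, 20), dtype=int))
        frag = extract_windows(rec, 3)[1]  # no padding
        assert np.all(encode_pssm_window(prof, frag) == 0.5)

    def test_left_padding_contributes_exact_zeros(self):
        rec, prof = self.make()
        frag = extract_windows(rec, 19)[0]
        vec = encode_pssm_window(prof, frag)
        assert np.all(vec[: 9 * 20] == 0.0)
        assert np.all(vec[9 * 20 :] > 0.0)

    def test_real_positions_strictly_inside_unit_interval(self):
        rec, prof = self.make()
        for frag in extract_windows(rec, 19):
            vec = encode_pssm_window(prof, frag).reshape(19, 20)
            pad = np.array([c == "-" for c in frag.residues])
            assert np.all(vec[pad] == 0.0)
            assert np.all((vec[~pad] > 0.0) & (vec[~pad] < 1.0))

    def test_monotone_in_single_score(self):
        rec, prof = self.make()
        frag = extract_windows(rec, 19)[12]
        base = encode_pssm_window(prof, frag)
        bumped = PSSMProfile("P1", prof.scores.copy())
        bumped.scores[12, 7] += 1
        vec = encode_pssm_window(bumped, frag)
        changed = np.flatnonzero(vec != base)
        assert changed.tolist() == [9 * 20 + 7]
        assert vec[changed[0]] > base[changed[0]]

    def test_id_mismatch_rejected(self):
        rec, prof = self.make()
        frag = extract_windows(rec, 19)[0]
        frag.protein_id = "OTHER"
        with pytest.raises(ConsistencyError):
            encode_pssm_window(prof, frag)


class TestSubstitutionEncoding:
    def test_binary_one_hot_blocks(self):
        enc = substitution_encoding("BINARY")
        rec = ProteinRecord("P1", "AAA")
        frag = extract_windows(rec, 3)[1]
        vec = encode_substitution_window(rec, frag, enc)
        assert vec.sum() == 3
        blocks = vec.reshape(3, 20)
        assert np.array_equal(blocks[0], blocks[1])

    def test_binary_sum_equals_window_without_padding(self):
        enc = substitution_encoding("BINARY")
        rec = ProteinRecord("P1", "ACDEFGHIK")
        frag = extract_windows(rec, 5)[4]
        assert encode_substitution_window(rec, frag, enc).sum() == 5

    def test_blosum62_self_score_scaled(self):
        enc = substitution_encoding("BLOSUM62")
        rec = ProteinRecord("P1", "WWW")
        frag = extract_windows(rec, 3)[1]
        vec = encode_substitution_window(rec, frag, enc).reshape(3, 20)
        w_col = PSSM_COLUMNS.index("W")
        assert vec[1, w_col] == pytest.approx(float(logistic_scale(11)), abs=1e-12)

    def test_padding_and_ambiguity_are_zero_blocks(self):
        enc = substitution_encoding("PAM250")
        rec = ProteinRecord("P1", "AXC")
        frags = extract_windows(rec, 3)
        vec = encode_substitution_window(rec, frags[0], enc).reshape(3, 20)
        assert np.all(vec[0] == 0.0)  # padding
        mid = encode_substitution_window(rec, frags[1], enc).reshape(3, 20)
        assert np.all(mid[1] == 0.0)  # X at centre

    def test_unknown_name_rejected(self):
        with pytest.raises(ParameterError):
            substitution_encoding("BLOSUM80")
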