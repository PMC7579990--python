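import numpy as np
import pytest
from hypothesis import given, strategies as st

from tnfpred import (
    EmbeddingModel,
    FeatureVector,
    TrainingConfig,
    Vocabulary,
    aac,
    combine_grams,
    dpc,
    embed_sequence,
    pssm_features,
    read_pssm,
)
from tnfpred.seqdata import AMINO_ACIDS

PSSM_COLS = "A R N D C Q E G H I K L M F P S T W Y V"


def toy_model(scalars: dict[str, float], n: int) -> tuple[Vocabulary, EmbeddingModel]:
    vocab = Vocabulary(tuple(scalars), n)
    model = EmbeddingModel(TrainingConfig(), [(w, 1) for w in scalars], dict(scalars))
    return vocab, model


class TestEmbedSequence:
    def setup_method(self):
        self.vocab, self.model = toy_model({"AA": 0.5, "AC": -0.2, "CA": 0.1}, 2)

    def test_each_word_once(self):
        fv = embed_sequence("AACA", 2, self.vocab, self.model)
        assert fv.coords == (0.5, -0.2, 0.1)

    def test_repeated_word_scales_by_occurrences(self):
        fv = embed_sequence("AAAA", 2, self.vocab, self.model)  # AA x3
        assert fv.coords == (1.5, 0.0, 0.0)

    def test_sequence_shorter_than_gram_gives_zero_vector(self):
        fv = embed_sequence("A", 2, self.vocab, self.model)
        assert fv.coords == (0.0, 0.0, 0.0)

    def test_gram_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gram size"):
            embed_sequence("AACA", 3, self.vocab, self.model)

    def test_out_of_vocabulary_words_contribute_nothing(self):
        fv = embed_sequence("GGGG", 2, self.vocab, self.model)
        assert fv.coords == (0.0, 0.0, 0.0)

    def test_matches_bruteforce_count_times_scalar_oracle(self, rng):
        # 200 random small instances against an independent substring scan.
        for _ in range(200):
            n = int(rng.integers(1, 4))
            words = sorted({"".join(rng.choice(list(AMINO_ACIDS[:6]), n)) for _ in range(6)})
            scalars = {w: float(rng.normal()) for w in words}
            vocab, model = toy_model(scalars, n)
            seq = "".join(rng.choice(list(AMINO_ACIDS[:6]), int(rng.integers(0, 25))))
            fv = embed_sequence(seq, n, vocab, model)
            for j, w in enumerate(vocab.words):
                count = sum(1 for i in range(len(seq) - n + 1) if seq[i : i + n] == w)
                assert fv.coords[j] == pytest.approx(count * scalars[w])


class TestCombineGrams:
    @staticmethod
    def fv(length: int, gram: int) -> FeatureVector:
        return FeatureVector(tuple(float(i) for i in range(length)), (gram,))

    @pytest.mark.parametrize("lengths, grams, total", [
        ((20, 398), (1, 2), 418),     # 1-g + 2-g hybrid
        ((395, 1736), (2, 3), 2131),  # 2-g + 3-g hybrid
    ])
    def test_concatenated_length_is_sum_of_parts(self, lengths, grams, total):
        combined = combine_grams([self.fv(l, g) for l, g in zip(lengths, grams)])
        assert len(combined) == total
        assert combined.gram_sizes == grams

    def test_ascending_gram_order_regardless_of_input_order(self):
        combined = combine_grams([self.fv(3, 3), self.fv(2, 1)])
        assert combined.gram_sizes == (1, 3)
        assert combined.coords == (0.0, 1.0, 0.0, 1.0, 2.0)

    def test_single_vector_is_identity(self):
        v = self.fv(4, 2)
        assert combine_grams([v]) == v

    def test_duplicate_gram_sizes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_grams([self.fv(2, 2), self.fv(3, 2)])


class TestCompositions:
    def test_aac_single_residue_sequence(self):
        v = aac("AAAA")
        assert v[0] == 1.0 and v.sum() == pytest.approx(1.0) and (v[1:] == 0).all()

    def test_aac_even_mixture(self):
        v = aac("ACAC")
        assert v[AMINO_ACIDS.index("A")] == 0.5
        assert v[AMINO_ACIDS.index("C")] == 0.5

    def test_dpc_known_fractions(self):
        v = dpc("ACAC")  # dipeptides AC, CA, AC
        idx = {d: i for i, d in enumerate(
            a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)}
        assert v[idx["AC"]] == pytest.approx(2 / 3)
        assert v[idx["CA"]] == pytest.approx(1 / 3)
        assert v.shape == (400,)

    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=50))
    def test_compositions_are_probability_vectors(self, seq):
        for v in (aac(seq), dpc(seq)):
            assert (v >= 0).all() and v.sum() == pytest.approx(1.0)

    def test_empty_and_too_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            aac("")
        with pytest.raises(ValueError):
            dpc("A")


def write_synthetic_pssm(path, sequence: str, scores: np.ndarray) -> None:
    """Emit text in the PSI-BLAST ASCII profile layout (synthetic stand-in)."""
    lines = ["", "Last position-specific scoring matrix computed", ""]
    lines.append("            " + PSSM_COLS + "   " + PSSM_COLS)
    for i, (res, row) in enumerate(zip(sequence, scores), start=1):
        ints = " ".join(f"{int(x):3d}" for x in row)
        freqs = " ".join("0" for _ in range(20))
        lines.append(f"{i:5d} {res}  {ints}  {freqs}  0.20 0.10")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.13     0.31"]
    path.write_text("\n".join(lines) + "\n")


class TestPssm:
    def test_shape_and_reread_determinism(self, tmp_path, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), 120))
        scores = rng.integers(-8, 9, size=(120, 20))
        path = tmp_path / "p.pssm"
        write_synthetic_pssm(path, seq, scores)
        prof = read_pssm(path)
        assert prof.matrix.shape == (120, 20)
        assert prof.sequence == seq
        assert np.array_equal(prof.matrix, read_pssm(path).matrix)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "t.pssm"
        write_synthetic_pssm(path, "ACD", np.zeros((3, 20)))
        text = path.read_text().splitlines()
        text[5] = "    3 D  broken row"
        path.write_text("\n".join(text))
        with pytest.raises(ValueError, match=r":\d+"):
            read_pssm(path)

    def test_headerless_file_rejected(self, tmp_path):
        path = tmp_path / "x.pssm"
        path.write_text("not a pssm\n")
        with pytest.raises(ValueError):
            read_pssm(path)

    def test_zero_scores_give_half_on_present_residue_rows(self, tmp_path):
        path = tmp_path / "z.pssm"
        write_synthetic_pssm(path, "ACDA", np.zeros((4, 20)))
        feats = pssm_features(read_pssm(path)).reshape(20, 20)
        for res in "ACD":
            assert np.allclose(feats[AMINO_ACIDS.index(res)], 0.5)
        assert np.allclose(feats[AMINO_ACIDS.index("W")], 0.0)

    def test_doubling_the_profile_leaves_features_unchanged(self, tmp_path, rng):
        seq = "ACDEF"
        scores = rng.integers(-5, 6, size=(5, 20))
        p1, p2 = tmp_path / "a.pssm", tmp_path / "b.pssm"
        write_synthetic_pssm(p1, seq, scores)
        write_synthetic_pssm(p2, seq * 2, np.vstack([scores, scores]))
        assert np.allclose(pssm_features(read_pssm(p1)), pssm_features(read_pssm(p2)))
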