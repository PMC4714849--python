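"""Fickett TESTCODE, hexamer bias, and the logistic coding classifier."""

import numpy as np
import pytest

from lncforge.coding_potential import (
    CodingModel,
    build_hexamer_table,
    coding_probability,
    fickett_score,
    fit_coding_model,
    hexamer_llr,
    sequence_features,
)
from lncforge.orf import find_max_orf
from lncforge.synthetic_data import default_coding_corpora, random_coding_orf, random_noncoding

# ---------------------------------------------------------------------------
# independent straight-from-the-tables TESTCODE oracle (separate code path)
# ---------------------------------------------------------------------------

_ORACLE_POS = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_ORACLE_CONT = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}


def oracle_fickett(seq: str) -> float:
    seq = seq.upper()
    pos_weight = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
    cont_weight = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
    pos_para = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
    cont_para = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
    total = sum(seq.count(b) for b in "ACGT")
    score = 0.0
    for b in "ACGT":
        c0 = sum(1 for i in range(0, len(seq), 3) if seq[i] == b)
        c1 = sum(1 for i in range(1, len(seq), 3) if seq[i] == b)
        c2 = sum(1 for i in range(2, len(seq), 3) if seq[i] == b)
        val = max(c0, c1, c2) / (min(c0, c1, c2) + 1)
        idx = next(i for i, thr in enumerate(pos_para) if val >= thr)
        score += _ORACLE_POS[b][idx] * pos_weight[b]
        frac = seq.count(b) / total
        idx = next(i for i, thr in enumerate(cont_para) if frac >= thr)
        score += _ORACLE_CONT[b][idx] * cont_weight[b]
    return score


class TestFickett:
    def test_case_invariance(self):
        assert fickett_score("ACGT" * 100) == fickett_score("acgt" * 100)

    def test_short_sequence_rejected(self, rng):
        with pytest.raises(ValueError, match="200"):
            fickett_score("".join(rng.choice(list("ACGT"), size=150)))

    def test_matches_table_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            n = int(rng.integers(200, 1500))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fickett_score(seq) == pytest.approx(oracle_fickett(seq), abs=1e-12)

    def test_coding_scores_above_random(self, rng):
        np_rng = np.random.default_rng(7)
        coding = [random_coding_orf(np_rng, 150) for _ in range(20)]
        noncoding = [random_noncoding(np_rng, 453, max_orf_aa=None) for _ in range(20)]
        assert np.mean([fickett_score(s) for s in coding]) > \
            np.mean([fickett_score(s) for s in noncoding])


class TestHexamer:
    def test_uniform_table_gives_zero_llr(self):
        flat = np.full(4096, 1 / 4096)
        from lncforge.coding_potential import HexamerTable

        table = HexamerTable(flat.copy(), flat.copy(), 1.0, 10, 10)
        assert hexamer_llr("ACGTACGTACGTACG", table) == 0.0

    def test_single_hexamer_dominates_coding_class(self):
        coding = ["ATGATG" * 30] * 10
        noncoding = ["ACGTTGCAGTTACGGA" * 10] * 10
        table = build_hexamer_table(coding, noncoding)
        top = int(np.argmax(table.coding_freq))
        import itertools

        hexamers = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
        assert hexamers[top] == "ATGATG"
        assert table.coding_freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert table.noncoding_freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetric_under_table_swap(self, rng):
        np_rng = np.random.default_rng(3)
        coding = [random_coding_orf(np_rng, 100) for _ in range(15)]
        noncoding = [random_noncoding(np_rng, 300, max_orf_aa=None) for _ in range(15)]
        table = build_hexamer_table(coding, noncoding)
        seq = random_noncoding(np_rng, 500, max_orf_aa=None)
        assert hexamer_llr(seq, table) == pytest.approx(
            -hexamer_llr(seq, table.swapped()), abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        np_rng = np.random.default_rng(4)
        coding = [random_coding_orf(np_rng, 120) for _ in range(15)]
        noncoding = [random_noncoding(np_rng, 400, max_orf_aa=None) for _ in range(15)]
        table = build_hexamer_table(coding, noncoding)
        import itertools

        index = {"".join(p): i for i, p in enumerate(itertools.product("ACGT", repeat=6))}
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 600))))
            aa, start, _ = find_max_orf(seq)
            region = seq[start:start + 3 * aa] if aa else seq
            vals = [np.log(table.coding_freq[index[region[i:i + 6]]]
                           / table.noncoding_freq[index[region[i:i + 6]]])
                    for i in range(0, len(region) - 5, 3)]
            expected = float(np.mean(vals)) if vals else 0.0
            assert hexamer_llr(seq, table) == pytest.approx(expected, abs=1e-12)

    def test_determinism_of_table_build(self):
        c, o, n = default_coding_corpora(20, seed=9)
        t1 = build_hexamer_table(o, n)
        t2 = build_hexamer_table(o, n)
        assert t1.checksum() == t2.checksum()

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            build_hexamer_table([], ["ACGTAC"] * 10)


@pytest.fixture(scope="module")
def corpora_features():
    coding, orfs, noncoding = default_coding_corpora(100, seed=5)
    table = build_hexamer_table(orfs, noncoding)
    feats = np.array([sequence_features(s, table) for s in coding + noncoding])
    labels = np.array([1] * len(coding) + [0] * len(noncoding))
    return table, feats, labels


class TestCodingModel:
    def test_refit_same_seed_identical(self, corpora_features):
        table, feats, labels = corpora_features
        m1 = fit_coding_model(feats, labels, seed=2, table=table)
        m2 = fit_coding_model(feats, labels, seed=2, table=table)
        assert np.array_equal(m1.coef, m2.coef) and m1.intercept == m2.intercept

    def test_separable_case_has_perfect_auc(self, rng):
        n = 120
        orf = np.concatenate([rng.uniform(400, 900, n), rng.uniform(0, 200, n)])
        feats = np.column_stack([orf, orf / 1000, rng.uniform(0.7, 1.3, 2 * n),
                                 rng.normal(0, 1, 2 * n)])
        labels = np.array([1] * n + [0] * n)
        model = fit_coding_model(feats, labels, seed=1)
        assert model.holdout_auc == 1.0

    def test_single_class_rejected(self, rng):
        feats = rng.normal(size=(100, 4))
        with pytest.raises(ValueError):
            fit_coding_model(feats, np.ones(100, dtype=int), seed=1)

    def test_probability_bounds_and_serialization(self, corpora_features, tmp_path):
        table, feats, labels = corpora_features
        model = fit_coding_model(feats, labels, seed=1, table=table)
        probs = model.predict_proba(feats)
        assert np.all((probs >= 0) & (probs <= 1))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CodingModel.from_json(path)
        assert np.allclose(back.predict_proba(feats), probs)
        assert back.table_checksum == table.checksum()

    def test_score_separates_planted_classes(self, scorer):
        np_rng = np.random.default_rng(11)
        noncoding = [random_noncoding(np_rng, 600, max_orf_aa=100) for _ in range(40)]
        mrna = ["".join(["ATTCGC" * 5, random_coding_orf(np_rng, 300), "TTGCAC" * 5])
                for _ in range(40)]
        nc_calls = [coding_probability(s, scorer.model, scorer.table).coding_probability
                    for s in noncoding]
        c_calls = [coding_probability(s, scorer.model, scorer.table).coding_probability
                   for s in mrna]
        assert np.mean(np.array(nc_calls) < 0.345) >= 0.95
        assert np.mean(np.array(c_calls) > 0.345) >= 0.95

    def test_recalibrate_moves_threshold(self, corpora_features):
        table, feats, labels = corpora_features
        model = fit_coding_model(feats, labels, seed=1, recalibrate=True, table=table)
        assert model.threshold != 0.345 or model.holdout_auc == 1.0
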