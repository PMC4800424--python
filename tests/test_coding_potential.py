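import math

import numpy as np
import pytest

from lncstage.coding_potential import (
    FEATURE_NAMES,
    HEXAMERS,
    CodingModel,
    FeatureVector,
    HexamerTable,
    classify_transcript,
    coding_probability,
    extract_features,
    fickett_parameters,
    fickett_score,
    fit_coding_model,
    hexamer_bias,
    hexamer_index,
    read_hexamer_table,
    read_model,
    train_hexamer_table,
    write_hexamer_table,
    write_model,
)
from lncstage.io_formats import TranscriptRecord
from lncstage.orf_finder import find_orfs, revcomp

# ---------------------------------------------------------------------------
# Fickett TESTCODE: independent table-lookup oracle
# ---------------------------------------------------------------------------
# The printed TESTCODE lookup tables, restated here so the oracle does not
# share code with the implementation.

ORACLE_POS_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
ORACLE_POS_W = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
ORACLE_POS_BREAKS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
ORACLE_CONT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
ORACLE_CONT_W = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
ORACLE_CONT_BREAKS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.15, 0.0]


def oracle_fickett(seq: str) -> float:
    from collections import Counter

    score = 0.0
    counts = {b: Counter() for b in "ACGT"}
    total = 0
    for i, ch in enumerate(seq):
        if ch in "ACGT":
            counts[ch][i % 3] += 1
            total += 1
    for b in "ACGT":
        per_pos = [counts[b][p] for p in range(3)]
        posval = max(per_pos) / (min(per_pos) + 1)
        content = sum(per_pos) / total
        for brk, prob in zip(ORACLE_POS_BREAKS, ORACLE_POS_PROB[b]):
            if posval >= brk:
                score += prob * ORACLE_POS_W[b]
                break
        for brk, prob in zip(ORACLE_CONT_BREAKS, ORACLE_CONT_PROB[b]):
            if content >= brk:
                score += prob * ORACLE_CONT_W[b]
                break
    return score


class TestFickett:
    def test_homopolymer_parameters(self):
        params = fickett_parameters("A" * 120)
        assert params["A_content"] == 1.0
        assert params["C_content"] == params["G_content"] == params["T_content"] == 0.0
        assert params["A_position"] == pytest.approx(40 / 41)
        assert fickett_score("A" * 120) == pytest.approx(oracle_fickett("A" * 120))

    def test_score_within_table_bounds(self, rng):
        lo = sum(min(ORACLE_POS_PROB[b]) * ORACLE_POS_W[b] for b in "ACGT") + sum(
            min(ORACLE_CONT_PROB[b]) * ORACLE_CONT_W[b] for b in "ACGT"
        )
        hi = sum(max(ORACLE_POS_PROB[b]) * ORACLE_POS_W[b] for b in "ACGT") + sum(
            max(ORACLE_CONT_PROB[b]) * ORACLE_CONT_W[b] for b in "ACGT"
        )
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            assert lo <= fickett_score(seq) <= hi

    def test_matches_independent_lookup_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            assert fickett_score(seq) == pytest.approx(oracle_fickett(seq), abs=1e-12)

    def test_all_n_sequence_is_error(self):
        with pytest.raises(ValueError):
            fickett_score("NNNNNN")

    def test_homopolymer_reversal_invariance(self):
        assert fickett_score("A" * 90) == pytest.approx(fickett_score(("A" * 90)[::-1]))


# ---------------------------------------------------------------------------
# hexamer usage bias
# ---------------------------------------------------------------------------

def make_record(rid, seq):
    return TranscriptRecord(rid, seq)


def symmetric_table():
    f = np.full(4096, 1 / 4096)
    return HexamerTable(f, f.copy(), 1.0)


class TestHexamer:
    def test_identical_training_sets_give_symmetric_table(self, rng):
        # ORF-free sequences (alphabet ACG: no ATG, no stop) so both classes
        # are tallied in frame 0 and identical inputs mean identical counts
        seqs = [
            make_record(f"t{i}", "".join(np.array(list("ACG"))[rng.integers(0, 3, 120)]))
            for i in range(5)
        ]
        table = train_hexamer_table(seqs, seqs, pseudocount=1.0)
        np.testing.assert_allclose(table.f_coding, table.f_noncoding)
        assert table.f_coding.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_hexamer_dominates_with_pseudocount(self):
        rec = make_record("x", "ATGGCA")
        with pytest.raises(ValueError):
            train_hexamer_table([rec], [rec], pseudocount=0)
        table = train_hexamer_table([rec], [rec], pseudocount=0.5)
        idx = hexamer_index("ATGGCA")
        assert table.f_noncoding[idx] > table.f_noncoding.max(initial=0) / 2
        assert all(
            table.f_noncoding[idx] > table.f_noncoding[j] for j in range(4096) if j != idx
        )

    def test_counts_match_sliding_window_oracle(self, rng):
        # noncoding records are counted frame 0; oracle tallies by hand
        seqs = [
            make_record(f"t{i}", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 99)]))
            for i in range(10)
        ]
        table = train_hexamer_table([make_record("c", "ATG" + "GCA" * 40 + "TAA")], seqs,
                                    pseudocount=1.0)
        counts = np.zeros(4096)
        for rec in seqs:
            s = rec.sequence
            for i in range(0, len(s) - 5, 3):
                counts[hexamer_index(s[i : i + 6])] += 1
        expected = (counts + 1.0) / (counts + 1.0).sum()
        np.testing.assert_allclose(table.f_noncoding, expected)

    def test_coding_records_counted_in_orf_frame(self):
        # ORF is offset by 1 nt: hexamers must align to the ORF, not frame 0
        orf = "ATG" + "GCA" * 30 + "TAA"
        rec = make_record("c", "C" + orf + "GG")
        table = train_hexamer_table([rec], [make_record("n", "ACGT" * 30)], pseudocount=1.0)
        idx = hexamer_index("GCAGCA")
        assert table.f_coding[idx] == table.f_coding.max()

    def test_symmetric_table_gives_zero_bias(self, rng):
        table = symmetric_table()
        for _ in range(5):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            assert hexamer_bias(seq, 0, table) == pytest.approx(0.0)

    def test_constant_ratio_gives_log_of_ratio(self):
        # build a table where f_coding = 2 * f_noncoding exactly on every
        # hexamer of the probe, rebalancing the complement so both sum to 1
        probe = "ATGGCAATGGCA"
        used = sorted({hexamer_index(probe[i : i + 6]) for i in range(0, len(probe) - 5, 3)})
        f_n = np.full(4096, 1 / 4096)
        f_c = f_n.copy()
        mass = len(used) / 4096
        f_c[used] *= 2.0
        others = np.setdiff1d(np.arange(4096), used)
        f_c[others] *= (1 - 2 * mass) / (1 - mass)
        table = HexamerTable(f_c, f_n, 1.0)
        assert hexamer_bias(probe, 0, table) == pytest.approx(math.log(2.0))

    def test_matches_direct_summation_oracle(self, rng):
        raw_c = rng.uniform(0.1, 1.0, 4096)
        raw_n = rng.uniform(0.1, 1.0, 4096)
        table = HexamerTable(raw_c / raw_c.sum(), raw_n / raw_n.sum(), 1.0)
        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
            terms = [
                math.log(
                    table.f_coding[hexamer_index(seq[i : i + 6])]
                    / table.f_noncoding[hexamer_index(seq[i : i + 6])]
                )
                for i in range(0, len(seq) - 5, 3)
            ]
            assert hexamer_bias(seq, 0, table) == pytest.approx(sum(terms) / len(terms))

    def test_zero_countable_hexamers_is_error(self):
        with pytest.raises(ValueError):
            hexamer_bias("ACGTN", 0, symmetric_table())


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_full_length_orf_has_unit_coverage(self):
        seq = "ATG" + "GCA" * 98 + "TAA"  # 300 nt, ORF spans everything
        fv = extract_features(make_record("t", seq), symmetric_table())
        assert fv.orf_size == 300
        assert fv.orf_coverage == pytest.approx(1.0)

    def test_no_atg_gives_zero_orf_features(self):
        seq = "CCCACCCCACCCACCACCCACCACCCACCC"
        fv = extract_features(make_record("t", seq), symmetric_table())
        assert fv.orf_size == 0
        assert fv.orf_coverage == 0.0

    def test_composition_of_component_operations(self, rng):
        table = symmetric_table()
        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 240)])
            rec = make_record("t", seq)
            fv = extract_features(rec, table)
            hits = find_orfs(rec, strand_mode="both")
            if hits:
                h = hits[0]
                assert fv.orf_size == h.nt_length
                s = seq if h.strand == "+" else revcomp(seq)
                sub = s[h.nt_start : h.nt_start + 3 * h.aa_length]  # residues only
                if len(sub) >= 6:
                    assert fv.hexamer == pytest.approx(hexamer_bias(sub, 0, table))
            else:
                assert fv.orf_size == 0
            assert fv.fickett == pytest.approx(fickett_score(seq))
            assert fv.orf_coverage == pytest.approx(fv.orf_size / len(seq))


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------

class TestCodingModel:
    def test_null_model_probability_half(self):
        model = CodingModel(0.0, np.zeros(4))
        fv = FeatureVector(100, 0.5, 1.0, -0.2)
        assert coding_probability(fv, model) == 0.5

    def test_closed_form_intercept_only(self):
        model = CodingModel(math.log(3), np.zeros(4))
        assert coding_probability(FeatureVector(1, 0.1, 0.2, 0.3), model) == pytest.approx(0.75)

    def test_monotone_in_positive_coefficient(self):
        model = CodingModel(0.0, np.array([0.01, 0.0, 0.0, 0.0]))
        p1 = coding_probability(FeatureVector(100, 0.5, 0.5, 0.0), model)
        p2 = coding_probability(FeatureVector(200, 0.5, 0.5, 0.0), model)
        assert p2 > p1

    def test_separable_feature_with_ridge_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(3)
        feats, labels = [], []
        for i in range(200):
            coding = i % 2 == 0
            orf = rng.integers(400, 900) if coding else rng.integers(30, 250)
            feats.append(FeatureVector(int(orf), 0.5, 1.0, 0.0))
            labels.append("coding" if coding else "noncoding")
        model = fit_coding_model(feats, labels, cutoff=0.5, ridge=1e-6)
        preds = [
            classify_transcript(coding_probability(f, model), 0.5) for f in feats
        ]
        assert preds == labels

    def test_permuted_labels_give_near_zero_coefficients(self):
        rng = np.random.default_rng(9)
        n = 5000
        X = rng.normal(0, 1, (n, 4))
        y = rng.integers(0, 2, n)  # labels independent of features
        feats = [FeatureVector(float(a), min(abs(b) / 4, 1.0), float(c), float(d))
                 for a, b, c, d in X]
        labels = ["coding" if v else "noncoding" for v in y]
        model = fit_coding_model(feats, labels, ridge=1e-6)
        probs = [coding_probability(f, model) for f in feats]
        prior = y.mean()
        assert np.mean(probs) == pytest.approx(prior, abs=0.05)
        # per-sd effect sizes shrink as 1/sqrt(n)
        X_used = np.array([f.as_array() for f in feats])
        effects = model.coefficients * X_used.std(axis=0)
        assert np.all(np.abs(effects) < 0.1)

    def test_parameter_recovery_within_three_standard_errors(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 2000
        beta = np.array([0.8, -0.5, 0.3, 1.2])
        intercept = -0.2
        X = rng.normal(0, 1, (n, 4))
        p = 1 / (1 + np.exp(-(intercept + X @ beta)))
        y = rng.uniform(size=n) < p
        feats = [FeatureVector(float(a), min(abs(b) / 5, 1.0), float(c), float(d))
                 for a, b, c, d in X]
        # feature vector coerces column 1; rebuild the design used for truth
        X_used = np.array([f.as_array() for f in feats])
        p2 = 1 / (1 + np.exp(-(intercept + X_used @ beta)))
        y = rng.uniform(size=n) < p2
        labels = ["coding" if v else "noncoding" for v in y]
        model = fit_coding_model(feats, labels, ridge=1e-6)
        sm_fit = sm.Logit(y.astype(int), sm.add_constant(X_used)).fit(disp=0)
        se = sm_fit.bse
        assert abs(model.intercept - intercept) < 3 * se[0] + 1e-6
        for j in range(4):
            assert abs(model.coefficients[j] - beta[j]) < 3 * se[j + 1] + 1e-6

    def test_collinear_without_ridge_raises(self):
        feats = [FeatureVector(i, 0.5, float(i), 0.0) for i in range(10)]
        labels = ["coding"] * 5 + ["noncoding"] * 5
        with pytest.raises(ValueError, match="ridge"):
            fit_coding_model(feats, labels, ridge=0.0)

    def test_single_class_rejected(self):
        feats = [FeatureVector(10, 0.5, 0.5, 0.0)] * 4
        with pytest.raises(ValueError, match="both classes"):
            fit_coding_model(feats, ["coding"] * 4)


class TestClassifyTranscript:
    def test_cutoff_is_strict_lower_bound_for_noncoding(self):
        assert classify_transcript(0.38, 0.39) == "noncoding"
        assert classify_transcript(0.39, 0.39) == "coding"
        assert classify_transcript(1.0, 0.39) == "coding"


class TestSerialization:
    def test_model_and_table_round_trip(self, tmp_path, trained_model):
        model, table = trained_model
        write_hexamer_table(table, tmp_path / "hex.tsv")
        write_model(model, table, tmp_path / "model.txt")
        table2 = read_hexamer_table(tmp_path / "hex.tsv")
        model2 = read_model(tmp_path / "model.txt", table2)
        np.testing.assert_allclose(table2.f_coding, table.f_coding, rtol=1e-10)
        np.testing.assert_allclose(model2.coefficients, model.coefficients, rtol=1e-10)
        assert model2.cutoff == model.cutoff

    def test_checksum_mismatch_detected(self, tmp_path, trained_model):
        model, table = trained_model
        write_model(model, table, tmp_path / "model.txt")
        other = symmetric_table()
        with pytest.raises(ValueError, match="checksum"):
            read_model(tmp_path / "model.txt", other)
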