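import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glocerna.core import (
    GloceRNAConfig,
    baseline_identify,
    ce_lncrnas,
    classify_pair,
    dec_sample,
    dec_score,
    global_correlation,
    relative_expression,
    run_glocerna,
)
from glocerna.exceptions import (
    CohortSizeError,
    DomainError,
    GeneLookupError,
    UndefinedCorrelationError,
    ValidationError,
)
from glocerna.pairing import CandidatePair, build_candidate_pairs
from glocerna.synthetic import SyntheticConfig, generate_cohort
from glocerna.types import MatchedExpressionMatrix

finite = st.floats(
    min_value=-50, max_value=50, allow_nan=False, allow_infinity=False
)


def make_matrix(normal, tumor, classes):
    genes = list(classes)
    n = len(next(iter(normal.values())))
    patients = [f"P{i}" for i in range(n)]
    return MatchedExpressionMatrix(
        normal=pd.DataFrame(normal, index=patients).T.loc[genes],
        tumor=pd.DataFrame(tumor, index=patients).T.loc[genes],
        gene_class=pd.Series(classes),
    )



def rel_from_rows(e_l, e_g):
    mat = make_matrix(
        normal={"L1": np.ones(len(e_l)), "G1": np.ones(len(e_l))},
        tumor={"L1": 2.0 ** np.asarray(e_l), "G1": 2.0 ** np.asarray(e_g)},
        classes={"L1": "lncRNA", "G1": "PCG"},
    )
    return relative_expression(mat)

class TestRelativeExpression:
    def test_log2_fold_change(self, tiny_matrix):
        rel = relative_expression(tiny_matrix)
        assert rel.e.loc["L1", "P1"] == pytest.approx(2.0)  # log2(8)-log2(2)
        assert rel.e.loc["L1", "P2"] == pytest.approx(0.0)
        assert rel.e.loc["G1", "P3"] == pytest.approx(-2.0)

    def test_equal_matrices_give_zero(self, tiny_matrix):
        mat = MatchedExpressionMatrix(
            normal=tiny_matrix.normal,
            tumor=tiny_matrix.normal.copy(),
            gene_class=tiny_matrix.gene_class,
        )
        assert (relative_expression(mat).e == 0).all().all()

    def test_zero_without_pseudocount_is_domain_error(self, tiny_matrix):
        tumor = tiny_matrix.tumor.copy()
        tumor.loc["L1", "P1"] = 0.0
        mat = MatchedExpressionMatrix(
            normal=tiny_matrix.normal, tumor=tumor, gene_class=tiny_matrix.gene_class
        )
        with pytest.raises(DomainError, match="pseudocount"):
            relative_expression(mat)
        rel = relative_expression(mat, pseudocount=0.01)
        assert np.isfinite(rel.e.to_numpy()).all()


class TestDecSample:
    def test_worked_example(self):
        assert dec_sample(3.1, 2.2, fc_threshold=1) == 1

    def test_concordant_down(self):
        assert dec_sample(-2.0, -3.0) == -1

    def test_threshold_is_strict(self):
        assert dec_sample(1.0, 2.0) == 0
        assert dec_sample(-1.0, -2.0) == 0

    def test_discordant_is_zero(self):
        assert dec_sample(3.0, -3.0) == 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            dec_sample(float("nan"), 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(finite, finite)
    def test_sign_symmetry(self, a, b):
        assert dec_sample(-a, -b) == -dec_sample(a, b)

    @settings(derandomize=True, max_examples=200)
    @given(finite, finite, st.floats(min_value=0.1, max_value=5), st.floats(min_value=0, max_value=5))
    def test_raising_threshold_never_increases_consistency(self, a, b, t, dt):
        assert abs(dec_sample(a, b, t + dt)) <= abs(dec_sample(a, b, t))


class TestDecScore:
    def test_counts_nonzero_samples(self):
        rel = rel_from_rows(
            [3.1, -2.0, 0.5, 2.0, 0.0], [2.2, -3.0, 0.5, 4.0, 0.0]
        )
        # per-sample scores (+1, -1, 0, +1, 0) -> 3
        assert dec_score(rel, "L1", "G1") == 3

    def test_zero_on_flat_profile(self):
        rel = rel_from_rows([0.0] * 4, [0.0] * 4)
        assert dec_score(rel, "L1", "G1") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_sample_loop(self, seed):
        rng = np.random.default_rng(seed)
        e_l, e_g = rng.normal(0, 2, 8), rng.normal(0, 2, 8)
        rel = rel_from_rows(e_l, e_g)
        expected = sum(
            abs(dec_sample(a, b)) for a, b in zip(rel.e.loc["L1"], rel.e.loc["G1"])
        )
        assert dec_score(rel, "L1", "G1") == expected

    def test_symmetric_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        e_l, e_g = rng.normal(0, 2, 10), rng.normal(0, 2, 10)
        rel = rel_from_rows(e_l, e_g)
        perm = rng.permutation(10)
        rel_perm = rel_from_rows(e_l[perm], e_g[perm])
        assert dec_score(rel, "L1", "G1") == dec_score(rel_perm, "L1", "G1")
        rel_swap = rel_from_rows(e_g, e_l)
        assert dec_score(rel, "L1", "G1") == dec_score(rel_swap, "L1", "G1")

    def test_unknown_gene_raises(self):
        rel = rel_from_rows([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(GeneLookupError):
            dec_score(rel, "L1", "NOPE")


class TestGlobalCorrelation:
    def test_affine_relation_gives_one(self):
        e_l = np.array([0.1, 0.5, 1.0, 2.0, 3.0])
        rel = rel_from_rows(e_l, 2 * e_l + 1)
        cor, p = global_correlation(rel, "L1", "G1")
        assert cor == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        rel = rel_from_rows([1, 2, 3, 4], [4, 3, 2, 1])
        cor, _ = global_correlation(rel, "L1", "G1")
        assert cor == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        e_l, e_g = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        rel = rel_from_rows(e_l, e_g)
        cor, p = global_correlation(rel, "L1", "G1")
        ref = stats.pearsonr(rel.e.loc["L1"], rel.e.loc["G1"])
        assert cor == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        e_l, e_g = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        rel = rel_from_rows(e_l, e_g)
        cor_ab, p_ab = global_correlation(rel, "L1", "G1")
        cor_ba, p_ba = global_correlation(rel, "G1", "L1")
        assert cor_ab == pytest.approx(cor_ba)
        assert p_ab == pytest.approx(p_ba)
        assert -1 <= cor_ab <= 1 and 0 < p_ab <= 1

    def test_zero_variance_is_signalled(self):
        rel = rel_from_rows([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        with pytest.raises(UndefinedCorrelationError):
            global_correlation(rel, "L1", "G1")

    def test_too_few_samples(self):
        rel = rel_from_rows([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(CohortSizeError):
            global_correlation(rel, "L1", "G1")


class TestClassifyPair:
    def test_all_criteria_met(self):
        assert classify_pair(6, 0.5, 0.01) is True

    def test_dec_cutoff_is_strict(self):
        assert classify_pair(5, 0.9, 0.001) is False

    def test_negative_correlation_fails(self):
        assert classify_pair(6, -0.2, 0.001) is False

    def test_p_cutoff_is_strict(self):
        assert classify_pair(6, 0.5, 0.05) is False


class TestRunGlocerna:
    def test_planted_pair_called_null_pair_not(self):
        config = SyntheticConfig(
            n_patients=20, n_lncrnas=4, n_pcgs=8, n_true_pairs=1,
            n_decoy_pairs=1, seed=11,
        )
        matrix, interactions, truth = generate_cohort(config)
        pairs = build_candidate_pairs(interactions)
        res = run_glocerna(matrix, pairs)
        res = res.set_index(["lncrna_id", "pcg_id"])
        (true_key,) = truth.true_pair_set
        decoy = truth.decoy_pairs.iloc[0]
        assert bool(res.loc[true_key, "functional"]) is True
        assert bool(res.loc[(decoy["lncrna_id"], decoy["pcg_id"]), "functional"]) is False
        assert ce_lncrnas(res.reset_index()) == [true_key[0]]

    def test_equals_per_pair_composition(self, small_cohort):
        """Vectorized scorer equals dec_score + global_correlation +
        classify_pair applied pair by pair."""
        _, matrix, interactions, _ = small_cohort
        pairs = build_candidate_pairs(interactions)[:20]
        config = GloceRNAConfig()
        res = run_glocerna(matrix, pairs, config)
        rel = relative_expression(matrix)
        assert len(res) == len(pairs)
        for _, row in res.iterrows():
            d = dec_score(rel, row["lncrna_id"], row["pcg_id"], config.fc_threshold)
            cor, p = global_correlation(rel, row["lncrna_id"], row["pcg_id"])
            assert row["dec_score"] == d
            assert row["cor"] == pytest.approx(cor, abs=1e-10)
            assert row["p_value"] == pytest.approx(p, abs=1e-10)
            assert row["functional"] == classify_pair(d, cor, p, config)

    def test_vacuous_cutoff_removes_everything(self, small_cohort):
        _, matrix, interactions, _ = small_cohort
        pairs = build_candidate_pairs(interactions)
        res = run_glocerna(
            matrix, pairs, GloceRNAConfig(dec_cutoff=matrix.n_patients)
        )
        assert not res["functional"].any()

    def test_patient_permutation_invariance(self, small_cohort):
        _, matrix, interactions, _ = small_cohort
        pairs = build_candidate_pairs(interactions)
        res = run_glocerna(matrix, pairs)
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(list(matrix.patient_ids)))
        matrix_perm = MatchedExpressionMatrix(
            normal=matrix.normal[perm],
            tumor=matrix.tumor[perm],
            gene_class=matrix.gene_class,
        )
        res_perm = run_glocerna(matrix_perm, pairs)
        pd.testing.assert_frame_equal(res, res_perm, check_exact=False, atol=1e-12)

    def test_absent_genes_skipped_and_counted(self, small_cohort):
        _, matrix, interactions, _ = small_cohort
        pairs = build_candidate_pairs(interactions)
        ghost = CandidatePair("LNC9999", "PCG9999", frozenset({"miR-x"}))
        res = run_glocerna(matrix, pairs + [ghost])
        assert res.attrs["n_skipped_absent"] == 1
        assert res.attrs["n_tested"] == len(pairs)


class TestBaseline:
    def test_recovers_planted_pairs_with_fixed_signs(self):
        """The SAM(0.05)-analogue+Cor combination finds planted pairs when
        the deregulation direction is shared by all patients (a mean
        shift paired DE can see)."""
        config = SyntheticConfig(
            n_patients=40, n_lncrnas=20, n_pcgs=60, n_true_pairs=10,
            n_decoy_pairs=30, per_sample_signs=False, seed=7,
        )
        matrix, interactions, truth = generate_cohort(config)
        pairs = build_candidate_pairs(interactions)
        res = baseline_identify(matrix, pairs, de_fdr=0.05)
        res = res.set_index(["lncrna_id", "pcg_id"])
        recovered = [bool(res.loc[k, "functional"]) for k in truth.true_pair_set]
        assert np.mean(recovered) > 0.5

    def test_no_de_means_empty_result(self, tiny_matrix):
        mat = MatchedExpressionMatrix(
            normal=tiny_matrix.normal,
            tumor=tiny_matrix.normal.copy(),
            gene_class=tiny_matrix.gene_class,
        )
        pairs = [CandidatePair("L1", "G1", frozenset({"m"}))]
        res = baseline_identify(mat, pairs)
        assert not len(res) or not res["functional"].any()

    def test_hyper_criterion_only_removes_pairs(self, small_cohort):
        _, matrix, interactions, _ = small_cohort
        pairs = build_candidate_pairs(interactions)
        loose = baseline_identify(matrix, pairs, use_hyper=False)
        strict = baseline_identify(matrix, pairs, interactions, use_hyper=True)
        f_loose = set(map(tuple, loose.loc[loose.functional, ["lncrna_id", "pcg_id"]].to_numpy()))
        f_strict = set(map(tuple, strict.loc[strict.functional, ["lncrna_id", "pcg_id"]].to_numpy()))
        assert f_strict <= f_loose
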