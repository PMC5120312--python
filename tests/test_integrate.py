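"""Spearman machinery, interaction calling, permutation null, exact CI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import small_config
from valvemir.diffexpr import differential_expression
from valvemir.integrate import (
    PermutationResult,
    call_interactions,
    clopper_pearson_ci,
    permutation_null,
    spearman_rho,
)
from valvemir.io import ExpressionMatrix, ValidationError
from valvemir.synth import simulate_expression, simulate_target_scores


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        rho, _ = spearman_rho(x, x)
        assert rho == pytest.approx(1.0)
        rho_neg, _ = spearman_rho(x, [-v for v in x])
        assert rho_neg == pytest.approx(-1.0)

    def test_hand_ranked_oracle_with_ties(self):
        x = [1, 2, 3, 4, 5]
        y = [5, 6, 7, 8, 7]
        rho, p = spearman_rho(x, y)
        # midranks of y: (1, 2, 3.5, 5, 3.5); Pearson on ranks by hand
        rho_hand = 8 / np.sqrt(10 * 9.5)
        assert rho == pytest.approx(rho_hand)
        t = rho_hand * np.sqrt(3 / (1 - rho_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho1, p1 = spearman_rho(x, y)
        rho2, p2 = spearman_rho(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestClopperPearson:
    def test_zero_successes_matches_closed_form(self):
        low, high = clopper_pearson_ci(0, 100)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 100))
        assert round(high, 3) == 0.036

    def test_all_successes_upper_is_one(self):
        low, high = clopper_pearson_ci(100, 100)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 100))

    def test_half_matches_beta_quantiles(self):
        low, high = clopper_pearson_ci(50, 100)
        assert low < 0.5 < high
        assert low == pytest.approx(stats.beta.ppf(0.025, 50, 51))
        assert high == pytest.approx(stats.beta.ppf(0.975, 51, 50))

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            clopper_pearson_ci(5, 3)
        with pytest.raises(ValidationError):
            clopper_pearson_ci(0, 0)


@pytest.fixture(scope="module")
def planted():
    """Paired-sample study with planted repression (integration design)."""
    cfg = small_config(
        n_case=15, n_control=16, n_mirna=80, n_mrna=200, n_de_mirna=30,
        n_de_mrna=40, n_clusters=3, n_repressive_pairs=20, n_hub_targets=2,
        hub_parents=2, n_decoy_pairs=120, repression_strength=0.8, seed=21,
    )
    mirna, mrna, meta, truth = simulate_expression(cfg)
    scores = simulate_target_scores(cfg, truth)
    de_m = differential_expression(mirna, meta)
    de_g = differential_expression(mrna, meta)
    subset = (
        meta.loc[meta.group == "case", "sample_id"].tolist()[:10]
        + meta.loc[meta.group == "control", "sample_id"].tolist()[:10]
    )
    return dict(
        cfg=cfg, truth=truth, scores=scores, de_m=de_m, de_g=de_g,
        mirna=mirna.subset_samples(subset), mrna=mrna.subset_samples(subset),
    )


class TestCallInteractions:
    def test_recovers_planted_pairs(self, planted):
        inter = call_interactions(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"],
        )
        truth_pairs = set(planted["truth"].repressive_pairs)
        called = set(
            zip(inter.loc[inter.significant, "mirna_id"],
                inter.loc[inter.significant, "gene_id"])
        )
        recall = len(called & truth_pairs) / len(truth_pairs)
        assert recall >= 0.8
        decoys = set(zip(inter.mirna_id, inter.gene_id)) - truth_pairs
        fpr = len(called - truth_pairs) / max(1, len(decoys))
        assert fpr < 0.1
        assert (inter.score >= 0.8).all()
        assert (inter.loc[inter.significant, "p_adj"] < 0.05).all()

    def test_empty_candidate_set(self, planted):
        inter = call_interactions(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], score_threshold=1.01,
        )
        assert len(inter) == 0
        assert inter.attrs["n_significant"] == 0

    def test_sample_mismatch_rejected(self, planted):
        shuffled = ExpressionMatrix(
            planted["mrna"].values.iloc[:, ::-1], "mRNA"
        )
        with pytest.raises(ValidationError):
            call_interactions(
                planted["de_m"], planted["de_g"], planted["mirna"], shuffled,
                planted["scores"],
            )

    def test_invariant_to_joint_sample_relabeling(self, planted):
        rng = np.random.default_rng(0)
        order = list(rng.permutation(planted["mirna"].sample_ids))
        inter1 = call_interactions(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"],
        )
        inter2 = call_interactions(
            planted["de_m"], planted["de_g"],
            planted["mirna"].subset_samples(order),
            planted["mrna"].subset_samples(order),
            planted["scores"],
        )
        pd.testing.assert_frame_equal(inter1, inter2)

    def test_two_sided_mode_p_is_larger(self, planted):
        one = call_interactions(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], sidedness="one",
        )
        two = call_interactions(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], sidedness="two",
        )
        neg = one.rho < 0
        assert np.all(two.loc[neg, "p"].to_numpy() >= one.loc[neg, "p"].to_numpy() - 1e-12)


class TestPermutationNull:
    def test_planted_signal_beats_every_permutation(self, planted):
        res = permutation_null(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], n_permutations=100, seed=5,
        )
        assert res.b == 0
        assert res.p_perm == pytest.approx(1 / 101)
        assert res.p_perm < 0.01
        assert (res.ci_low, round(res.ci_high, 3)) == (0.0, 0.036)
        assert res.observed_count > max(res.perm_counts)

    def test_zero_observed_count_gives_p_one(self, planted):
        res = permutation_null(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], score_threshold=1.01, n_permutations=10, seed=0,
        )
        assert res.observed_count == 0
        assert res.b == 10
        assert res.p_perm == 1.0

    def test_single_permutation_below_observed(self, planted):
        res = permutation_null(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], n_permutations=1, seed=3,
        )
        assert res.b == 0
        assert res.p_perm == pytest.approx(0.5)

    def test_reproducible_with_fixed_seed(self, planted):
        kwargs = dict(n_permutations=20, seed=17)
        r1 = permutation_null(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], **kwargs,
        )
        r2 = permutation_null(
            planted["de_m"], planted["de_g"], planted["mirna"], planted["mrna"],
            planted["scores"], **kwargs,
        )
        assert r1 == r2
        assert r1.p_perm >= 1 / 21  # observed data counts as a permutation
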