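"""Cohort statistics: correlations, BH, Mann-Whitney, Hedges g, meta, AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import gammaln

import tissuemod as tm
from tissuemod.network import Eigengenes


class TestPearsonWithP:
    def test_null_case(self):
        # orthogonal contrasts give r = 0 exactly
        res = tm.pearson_with_p([1, -1, 1, -1], [1, 1, -1, -1])
        assert res.r == pytest.approx(0.0)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_frozen_example_r_half_n_ten(self):
        """r = 0.5, n = 10 gives t = 1.633, p = 0.1411 (independent t-CDF)."""
        # construct vectors with r exactly 0.5 via x and a rotated residual
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=10)
        e = e - e.mean()
        e = e - x * (x @ e) / (x @ x)  # orthogonal to x
        y = 0.5 * x + np.sqrt(1 - 0.25) * e / e.std()
        res = tm.pearson_with_p(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.t_statistic == pytest.approx(0.5 * np.sqrt(8 / 0.75), abs=1e-9)
        assert res.p == pytest.approx(2 * sps.t.sf(1.6329932, df=8), abs=1e-6)
        assert res.p == pytest.approx(0.1411, abs=2e-4)

    def test_identity_gives_r_one_p_zero(self):
        res = tm.pearson_with_p([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.r == 1.0 and res.p == 0.0

    def test_constant_vector_rejected(self):
        with pytest.raises(tm.DataError):
            tm.pearson_with_p([1, 1, 1], [1, 2, 3])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert tm.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            tm.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_output_at_least_input_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = tm.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=31)
        perm = rng.permutation(31)
        np.testing.assert_allclose(tm.bh_adjust(p)[perm], tm.bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(tm.ParameterError):
            tm.bh_adjust([0.1, 1.5])


def _eig(scores: np.ndarray, samples=None, names=None) -> Eigengenes:
    scores = np.asarray(scores, dtype=float)
    scores = scores / np.linalg.norm(scores, axis=0, keepdims=True)
    samples = samples or [f"s{i}" for i in range(scores.shape[0])]
    names = names or [f"M{j + 1}" for j in range(scores.shape[1])]
    return Eigengenes(scores=pd.DataFrame(scores, index=samples, columns=names))


class TestPairedTest:
    def _fixture(self, diffs):
        n = len(diffs)
        base = np.linspace(-1, 1, n)
        col = np.concatenate([base + np.asarray(diffs), base])
        samples = [f"i{k}" for k in range(n)] + [f"u{k}" for k in range(n)]
        eig = _eig(col[:, None], samples=samples)
        pairing = pd.Series([f"p{k}" for k in range(n)] * 2, index=samples)
        condition = pd.Series(["inflamed"] * n + ["uninflamed"] * n, index=samples)
        return eig, pairing, condition

    def test_zero_differences(self):
        eig, pairing, condition = self._fixture([0.0, 0.0, 0.0])
        table, _ = tm.paired_eigengene_test(eig, pairing, condition)
        assert table["t"].iloc[0] == pytest.approx(0.0)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_frozen_example_diffs_123(self):
        """Differences (1,2,3): t = 2/(1/sqrt(3)) = 3.464, p = 0.0742 (df 2)."""
        eig, pairing, condition = self._fixture([1.0, 2.0, 3.0])
        table, diffs = tm.paired_eigengene_test(eig, pairing, condition)
        # eigengene columns are renormalized, so compare t and p only
        assert table["t"].iloc[0] == pytest.approx(2 * math.sqrt(3), abs=1e-9)
        assert table["p"].iloc[0] == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), df=2),
                                                   abs=1e-12)
        assert table["p"].iloc[0] == pytest.approx(0.0742, abs=2e-4)

    def test_condition_swap_negates_difference(self):
        eig, pairing, condition = self._fixture([1.0, 2.0, 3.0])
        # rename levels so the other member of each pair sorts first
        swapped = condition.map({"inflamed": "z_state", "uninflamed": "a_state"})
        t1, _ = tm.paired_eigengene_test(eig, pairing, condition)
        t2, _ = tm.paired_eigengene_test(eig, pairing, swapped)
        assert t1["mean_difference"].iloc[0] == pytest.approx(
            -t2["mean_difference"].iloc[0]
        )
        assert t1["p"].iloc[0] == pytest.approx(t2["p"].iloc[0])

    def test_single_pair_rejected(self):
        eig, pairing, condition = self._fixture([1.0, 2.0])
        keep = pairing.isin(["p0"])
        with pytest.raises(tm.DataError):
            tm.paired_eigengene_test(eig, pairing[keep], condition[keep])


def mann_whitney_enumeration(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mid = len(a) * len(b) / 2
    dev_obs = abs(u_obs - mid)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        count += abs(u - mid) >= dev_obs - 1e-9
        total += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = tm.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_p_one(self):
        _, p = tm.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a, b = [0.3, 1.7, 2.2, 5.0], [0.9, 1.1, 4.4]
        u1, p1 = tm.mann_whitney(a, b)
        u2, p2 = tm.mann_whitney(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n_a", [2, 3, 4])
    def test_exact_branch_matches_enumeration_oracle(self, n_a):
        """Exact branch equals full enumeration for all splits of 8 values."""
        values = np.array([0.5, 1.2, 2.9, 3.1, 4.8, 5.5, 7.0, 8.3])
        for idx in itertools.combinations(range(8), n_a):
            a = values[list(idx)]
            b = np.delete(values, list(idx))
            _, p = tm.mann_whitney(a, b)
            assert p == pytest.approx(mann_whitney_enumeration(a, b), abs=1e-12)

    def test_large_sample_matches_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1, size=35)
        _, p = tm.mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=True).pvalue
        assert p == pytest.approx(ref)


class TestResponseDifference:
    def _dataset(self, shift, n=40, seed=0):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=(2 * n, 2))
        scores[n:, 0] += shift
        eig = _eig(scores)
        response = pd.Series(["responder"] * n + ["nonresponder"] * n,
                             index=eig.scores.index)
        return eig, response

    def test_direction_matches_planted_shift(self):
        eig, response = self._dataset(shift=1.5)
        table = tm.test_response_difference(eig, response)
        m1 = table[table["module"] == "M1"].iloc[0]
        assert m1["direction"] == 1
        assert m1["fdr"] < 0.05

    def test_per_regimen_blocks(self):
        eig, response = self._dataset(shift=0.0, n=30)
        regimen = pd.Series(["4wk"] * 30 + ["8wk"] * 30, index=eig.scores.index)
        # interleave responders/nonresponders within regimens
        response.iloc[:15] = "nonresponder"
        response.iloc[30:45] = "responder"
        table = tm.test_response_difference(eig, response, regimen=regimen)
        assert set(table["regimen"]) == {"4wk", "8wk"}
        assert len(table) == 4  # 2 modules x 2 regimens

    def test_single_class_rejected(self):
        eig, response = self._dataset(shift=0.0)
        response[:] = "responder"
        with pytest.raises(tm.DataError):
            tm.test_response_difference(eig, response)


class TestHedgesG:
    def test_null_effect_variance_lower_bound(self):
        e = tm.hedges_g([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 1.0, 4.0])
        assert e.g == pytest.approx(0.0)
        assert e.v == pytest.approx(8 / 16)

    def test_exact_correction_n10(self):
        """d = 1 at n=10/10: g = J(18) d with J(18) = Gamma(9)/(3 Gamma(8.5))."""
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        a = (a - a.mean()) / a.std(ddof=1)
        b = rng.normal(size=10)
        b = (b - b.mean()) / b.std(ddof=1)  # means 0, sds 1 -> d = mean diff
        e = tm.hedges_g(a + 1.0, b)
        j18 = math.exp(gammaln(9) - gammaln(8.5)) / 3.0
        assert j18 == pytest.approx(0.9577, abs=2e-4)
        assert e.g == pytest.approx(j18 * 1.0, abs=1e-9)

    def test_correction_vanishes_asymptotically(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=1000)
        a = (a - a.mean()) / a.std(ddof=1)
        b = rng.normal(size=1000)
        b = (b - b.mean()) / b.std(ddof=1)
        e = tm.hedges_g(a + 1.0, b)
        assert abs(e.g - 1.0) < 1e-3

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(tm.DataError):
            tm.hedges_g([1.0, 1.0], [1.0, 1.0])


class TestMetaAnalyze:
    def test_single_study_closed_form(self):
        e = tm.EffectSize(g=0.5, v=0.04, n1=50, n2=50)
        res = tm.meta_analyze([e])
        assert res.pooled_smd == pytest.approx(0.5)
        assert res.tau2 == 0.0
        assert res.ci_low == pytest.approx(0.5 - 1.96 * 0.2)
        assert res.ci_high == pytest.approx(0.5 + 1.96 * 0.2)

    def test_identical_effects_no_heterogeneity(self):
        effects = [tm.EffectSize(g=0.7, v=0.05, n1=40, n2=40) for _ in range(3)]
        res = tm.meta_analyze(effects)
        assert res.pooled_smd == pytest.approx(0.7)
        assert res.Q == pytest.approx(0.0)
        assert res.tau2 == 0.0

    def test_tau2_zero_reduces_to_inverse_variance_mean(self):
        effects = [
            tm.EffectSize(g=g, v=v, n1=30, n2=30)
            for g, v in [(0.4, 0.07), (0.45, 0.08), (0.5, 0.07)]
        ]
        res = tm.meta_analyze(effects)
        w = np.array([1 / 0.07, 1 / 0.08, 1 / 0.07])
        g = np.array([0.4, 0.45, 0.5])
        assert res.tau2 == pytest.approx(0.0)  # Q < k-1 here
        assert res.pooled_smd == pytest.approx(float((w * g).sum() / w.sum()))

    def test_matches_statsmodels_dersimonian_laird(self):
        from statsmodels.stats.meta_analysis import combine_effects

        g = np.array([0.9, 0.4, 1.3, 0.2])
        v = np.array([0.05, 0.09, 0.12, 0.07])
        effects = [tm.EffectSize(g=gi, v=vi, n1=60, n2=60) for gi, vi in zip(g, v)]
        res = tm.meta_analyze(effects)
        ref = combine_effects(g, v, method_re="dl")
        frame = ref.summary_frame()
        assert res.pooled_smd == pytest.approx(frame.loc["random effect", "eff"], abs=1e-8)
        assert res.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(tm.ParameterError):
            tm.meta_analyze([])


def _make_dataset(values: np.ndarray, labels, gene_ids=None):
    n = values.shape[1]
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    expr = tm.ExpressionMatrix(values, gene_ids, [f"s{j}" for j in range(n)], "tpm")
    response = pd.Series(labels, index=expr.sample_ids)
    return tm.ResponseDataset(expr=expr, response=response, study_id="toy",
                              treatment="anti-TNF")


class TestAUCRanking:
    def test_printed_toy_example(self):
        """Cases (3,4,5) vs controls (1,2,3): AUC = (8 + 0.5)/9 = 0.944."""
        ds = _make_dataset(
            np.array([[3.0, 4.0, 5.0, 1.0, 2.0, 3.0]]),
            ["nonresponder"] * 3 + ["responder"] * 3,
        )
        table = tm.rank_genes_by_auc(ds)
        assert table["auc"].iloc[0] == pytest.approx(8.5 / 9)

    def test_perfect_separator_rank_one(self):
        values = np.array([[10.0, 11.0, 12.0, 1.0, 2.0, 3.0],
                           [5.0, 1.0, 4.0, 2.0, 6.0, 3.0]])
        ds = _make_dataset(values, ["nonresponder"] * 3 + ["responder"] * 3)
        table = tm.rank_genes_by_auc(ds)
        assert table["auc"].iloc[0] == 1.0
        assert table["rank"].iloc[0] == 1

    def test_constant_gene_auc_half(self):
        values = np.array([[2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
                           [5.0, 1.0, 4.0, 2.0, 6.0, 3.0]])
        ds = _make_dataset(values, ["nonresponder"] * 3 + ["responder"] * 3)
        assert tm.rank_genes_by_auc(ds)["auc"].iloc[0] == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_rank_formula_equals_logistic_prediction_auc(self, seed):
        """The rank-formula AUC equals the AUC of fitted univariate logistic
        predictions (monotone-link equivalence), checked against sklearn."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(4, 12, size=2)
        x = np.concatenate([rng.normal(0.8, 1, n1), rng.normal(0, 1, n0)])
        y = np.array([1] * n1 + [0] * n0)
        ds = _make_dataset(x[None, :],
                           ["nonresponder"] * n1 + ["responder"] * n0)
        auc_rank = tm.rank_genes_by_auc(ds)["auc"].iloc[0]
        model = LogisticRegression(C=np.inf, tol=1e-12, max_iter=20000).fit(x[:, None], y)
        preds = model.predict_proba(x[:, None])[:, 1]
        assert auc_rank == pytest.approx(roc_auc_score(y, preds), abs=1e-9)


class TestCombineRanks:
    def _tables(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(30)]
        tables = []
        for study in ("s1", "s2"):
            auc = rng.uniform(0.3, 0.7, size=30)
            auc[:5] = rng.uniform(0.85, 0.99, size=5)  # module genes predictive
            t = pd.DataFrame({"gene": genes, "auc": auc, "study_id": study})
            t["rank"] = t["auc"].rank(ascending=False).astype(int)
            tables.append(t)
        return genes, tables

    def test_best_gene_combined_rank_two(self):
        genes, tables = self._tables()
        for t in tables:
            t.loc[0, "auc"] = 1.0
        combined, _ = tm.combine_ranks(tables)
        assert combined.loc["G0", "combined_rank"] == 2
        assert combined["combined_rank"].min() == 2

    def test_module_with_planted_effect_ranks_better(self):
        genes, tables = self._tables()
        sets = {"M1": genes[:5], "Mbg": genes[5:]}
        combined, comparisons = tm.combine_ranks(tables, module_sets=sets)
        assert (
            combined.loc[combined["module"] == "M1", "combined_rank"].median()
            < combined.loc[combined["module"] == "Mbg", "combined_rank"].median()
        )
        row = comparisons.iloc[0]
        assert row["p"] < 0.05

    def test_label_reversal_reverses_order(self):
        genes, tables = self._tables()
        combined, _ = tm.combine_ranks(tables)
        flipped = []
        for t in tables:
            f = t.copy()
            f["auc"] = 1.0 - f["auc"]
            flipped.append(f)
        combined_f, _ = tm.combine_ranks(flipped)
        n = len(genes)
        # per-study ranks reverse: rank -> n + 1 - rank
        np.testing.assert_array_equal(
            combined_f["combined_rank"].to_numpy(),
            2 * (n + 1) - combined["combined_rank"].to_numpy(),
        )

    def test_empty_intersection_rejected(self):
        _, tables = self._tables()
        tables[1]["gene"] = [f"X{i}" for i in range(30)]
        with pytest.raises(tm.DataError):
            tm.combine_ranks(tables)


class TestClusterPatients:
    def _archetype_eigengenes(self, sizes=(5, 6, 6, 6), seed=0):
        """Patients drawn from 4 archetypes in (M4, M5, M6) eigengene space."""
        rng = np.random.default_rng(seed)
        centers = {
            "M4/M5-high": (2.0, 2.0, -1.0),
            "M6-high": (-1.0, -1.0, 2.0),
            "M5-only": (-1.0, 2.0, -1.0),
            "all-low": (-1.0, -1.0, -1.0),
        }
        rows, truth = [], []
        for (name, c), n in zip(centers.items(), sizes):
            rows.append(np.asarray(c) + rng.normal(0, 0.2, size=(n, 3)))
            truth += [name] * n
        scores = np.vstack(rows)
        return _eig(scores, names=["M4", "M5", "M6"]), np.array(truth)

    def test_recovers_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        eig, truth = self._archetype_eigengenes(sizes=(12, 12, 12, 12))
        summary = tm.cluster_patients(eig, ["M4", "M5", "M6"], k=4)
        groups = summary.attrs["groups"]
        assert adjusted_rand_score(truth, groups.to_numpy()) >= 0.9

    def test_group_percentages_printed_values(self):
        """Sizes (5, 6, 6, 6) report 21.7% and 26.1% shares."""
        assert tm.group_percentages([5, 6, 6, 6]) == [21.7, 26.1, 26.1, 26.1]

    def test_archetype_sizes_recover_percentages(self):
        eig, truth = self._archetype_eigengenes(sizes=(5, 6, 6, 6))
        summary = tm.cluster_patients(eig, ["M4", "M5", "M6"], k=4)
        assert sorted(summary["percent"]) == [21.7, 26.1, 26.1, 26.1]
        high = summary[summary["n"] == 5].iloc[0]
        assert "M4-high" in high["label"] and "M5-high" in high["label"]

    def test_k_one_single_group(self):
        eig, _ = self._archetype_eigengenes()
        summary = tm.cluster_patients(eig, ["M4", "M5"], k=1)
        assert len(summary) == 1 and summary["percent"].iloc[0] == 100.0

    def test_unknown_module_rejected(self):
        eig, _ = self._archetype_eigengenes()
        with pytest.raises(tm.ParameterError):
            tm.cluster_patients(eig, ["M99"], k=2)


class TestProjectModules:
    def test_projection_onto_defining_data_is_idempotent(self, small_log_cohort):
        _, logged, _, truth, _ = small_log_cohort
        eig = tm.compute_eigengenes(logged, truth)
        sets = truth.to_gene_sets()
        proj, coverage = tm.project_modules(sets, logged)
        np.testing.assert_allclose(
            proj.scores.to_numpy(), eig.scores.to_numpy(), atol=1e-10
        )
        assert (coverage["fraction_mapped"] == 1.0).all()

    def test_coverage_fraction_reported(self, small_log_cohort):
        _, logged, _, truth, _ = small_log_cohort
        sets = truth.to_gene_sets()
        # drop 21% of module-1 genes from the replication matrix
        m1 = sets["M1"]
        keep = [g for g in logged.gene_ids if g not in m1[: int(0.21 * len(m1))]]
        sub = logged.subset_genes(keep)
        _, coverage = tm.project_modules(sets, sub)
        frac = coverage.set_index("module").loc["M1", "fraction_mapped"]
        assert frac == pytest.approx(1 - int(0.21 * len(m1)) / len(m1))

    def test_half_gene_loss_still_tracks_latent(self):
        params = tm.BulkSimParams(n_samples=120, n_genes=80, module_sizes=(40,),
                                  seed=21)
        expr, _, truth, latent = tm.simulate_bulk_cohort(params)
        logged = tm.filter_and_log(expr)
        rng = np.random.default_rng(0)
        m1 = truth.to_gene_sets()["M1"]
        lost = set(rng.choice(m1, size=20, replace=False))
        sub = logged.subset_genes([g for g in logged.gene_ids if g not in lost])
        proj, coverage = tm.project_modules(truth.to_gene_sets(), sub)
        r = np.corrcoef(proj.scores["M1"], latent[:, 0])[0, 1]
        assert abs(r) >= 0.9
        assert coverage["fraction_mapped"].iloc[0] == pytest.approx(0.5)

    def test_module_with_too_few_mapped_genes_skipped(self, small_log_cohort):
        _, logged, *_ = small_log_cohort
        sets = {"Mghost": ["NOPE1", "NOPE2", "NOPE3"], "Mok": logged.gene_ids[:10]}
        proj, coverage = tm.project_modules(sets, logged)
        assert proj.module_names == ["Mok"]
        assert coverage.set_index("module").loc["Mghost", "n_mapped"] == 0


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene_r_one(self, small_log_cohort):
        _, logged, traits, truth, _ = small_log_cohort
        eig = tm.compute_eigengenes(logged, truth)
        t = traits.copy()
        t["self"] = eig.scores["M1"]
        table = tm.correlate_eigengenes_with_traits(eig, t)
        row = table[(table["module"] == "M1") & (table["trait"] == "self")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_planted_trait_effect_strongest_for_its_module(self, small_log_cohort):
        _, logged, traits, truth, _ = small_log_cohort
        eig = tm.compute_eigengenes(logged, truth)
        table = tm.correlate_eigengenes_with_traits(eig, traits)
        best = table.loc[table["r"].abs().idxmax()]
        assert best["module"] == "M1"  # trait_effects = {1: 1.0}
        assert best["significant"]

    def test_shuffled_trait_rarely_significant(self, small_log_cohort):
        _, logged, traits, truth, _ = small_log_cohort
        eig = tm.compute_eigengenes(logged, truth)
        rng = np.random.default_rng(9)
        hits = []
        for _ in range(50):
            t = traits.copy()
            t["inflammation"] = rng.permutation(t["inflammation"].to_numpy())
            table = tm.correlate_eigengenes_with_traits(eig, t)
            hits.append(table["significant"].mean())
        assert np.mean(hits) <= 0.05

    def test_no_overlap_rejected(self, small_log_cohort):
        _, logged, traits, truth, _ = small_log_cohort
        eig = tm.compute_eigengenes(logged, truth)
        t = traits.copy()
        t.index = [f"other_{i}" for i in range(len(t))]
        with pytest.raises(tm.DataError):
            tm.correlate_eigengenes_with_traits(eig, t)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as hst  # noqa: E402

finite_p = hst.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@settings(derandomize=True, max_examples=50)
@given(hst.lists(finite_p, min_size=1, max_size=40))
def test_bh_adjust_dominates_input_and_caps(pvals):
    adj = tm.bh_adjust(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()


@settings(derandomize=True, max_examples=50)
@given(
    hst.lists(hst.floats(-50, 50), min_size=2, max_size=12),
    hst.lists(hst.floats(-50, 50), min_size=2, max_size=12),
)
def test_hedges_correction_shrinks_toward_zero(a, b):
    """|g| <= |d|: the small-sample correction factor J(m) is below 1."""
    a, b = np.asarray(a), np.asarray(b)
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled_var == 0:
        return
    e = tm.hedges_g(a, b)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var / (len(a) + len(b) - 2))
    assert abs(e.g) <= abs(d) + 1e-12
    assert e.v >= (e.n1 + e.n2) / (e.n1 * e.n2) - 1e-12


@settings(derandomize=True, max_examples=50)
@given(hst.lists(hst.integers(1, 1000), min_size=1, max_size=20))
def test_group_percentages_sum_near_100(sizes):
    pcts = tm.group_percentages(sizes)
    assert abs(sum(pcts) - 100.0) <= 0.1 * len(sizes)
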