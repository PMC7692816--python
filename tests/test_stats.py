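import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tmedeconv import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    compare_groups,
    correlate,
    disease_score_correlation,
    ffm_activity,
    ffm_immune_heatmap,
    generate_mixture,
    generate_signatures,
    inject_coupled_genes,
    overlap_sets,
    simple_de,
)
from tmedeconv.stats import mannwhitney_exact_p


def _series(vals, name="x"):
    return pd.Series(np.asarray(vals, dtype=float), name=name)


class TestCorrelate:
    def test_perfect_linearity(self):
        x = _series([1, 2, 3, 4, 5])
        (rec,) = correlate(x, _series(2 * x + 1, name="y"), method="pearson")
        assert rec.r == pytest.approx(1.0)
        assert rec.significant

    def test_spearman_textbook_example(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum 2 -> 0.8
        (rec,) = correlate(
            _series([1, 2, 3, 4]), _series([1, 3, 2, 4], name="y"),
            method="spearman",
        )
        assert rec.r == pytest.approx(0.8)

    def test_pearson_matches_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            (rec,) = correlate(_series(x), _series(y, name="y"))
            expected = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
            assert rec.r == pytest.approx(expected, abs=1e-12)

    def test_p_value_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        (rec,) = correlate(_series(x), _series(y, name="y"))
        assert rec.p_value == pytest.approx(sps.pearsonr(x, y).pvalue, rel=1e-9)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            (rec,) = correlate(_series(x), _series(y, name="y"), alpha=0.05)
            hits += rec.significant
        assert 0.03 <= hits / reps <= 0.07

    def test_zero_variance_flagged_undefined(self):
        (rec,) = correlate(_series([1, 1, 1, 1]), _series([1, 2, 3, 4], name="y"))
        assert not rec.defined and not rec.significant

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            correlate(_series([1, 2]), _series([1, 2], name="y"))


class TestMannWhitney:
    def test_textbook_separation(self, two_group_metadata):
        meta = SampleMetadata(list("abcdef"), ["g1"] * 3 + ["g2"] * 3)
        rec = compare_groups(np.array([1, 2, 3, 4, 5, 6.0]), meta, "g1", "g2")
        assert rec.statistic == 0.0
        assert rec.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme
        assert rec.direction == "up_in_b"

    def test_identical_groups(self):
        meta = SampleMetadata(list("abcd"), ["g1", "g1", "g2", "g2"])
        rec = compare_groups(np.array([5.0, 7.0, 5.0, 7.0]), meta, "g1", "g2")
        assert rec.p_value == 1.0
        assert rec.direction == "none"

    def test_full_separation_large_n(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        meta = SampleMetadata([str(i) for i in range(40)],
                              ["g1"] * 20 + ["g2"] * 20)
        rec = compare_groups(np.concatenate([a, a + 100]), meta, "g1", "g2")
        assert rec.p_value < 1e-6
        assert rec.test == "mann-whitney-asymptotic"

    def test_paired_uses_signed_rank(self):
        meta = SampleMetadata([str(i) for i in range(10)],
                              ["g1"] * 5 + ["g2"] * 5)
        vals = np.array([1, 2, 3, 4, 5, 2, 3, 4, 5, 6.0])
        rec = compare_groups(vals, meta, "g1", "g2", paired=True)
        assert rec.test == "wilcoxon-signed-rank"

    def test_missing_group_errors(self):
        meta = SampleMetadata(["a", "b"], ["g1", "g1"])
        with pytest.raises(ValidationError):
            compare_groups(np.array([1.0, 2.0]), meta, "g1", "g2")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 12), min_size=2, max_size=7),
        b=st.lists(st.integers(0, 12), min_size=2, max_size=7),
    )
    def test_exact_path_equals_pairwise_enumeration(self, a, b):
        """The rank-sum enumeration must equal an independent oracle that
        counts pairwise wins (plus half-ties) for every labeling."""
        a = np.array(a, float)
        b = np.array(b, float)
        u_obs, p = mannwhitney_exact_p(a, b)

        pooled = np.concatenate([a, b])
        n_a, n = len(a), len(pooled)

        def u_of(subset):
            av = pooled[list(subset)]
            bv = pooled[[i for i in range(n) if i not in subset]]
            return sum(
                (x > y) + 0.5 * (x == y) for x in av for y in bv
            )

        mu = n_a * (n - n_a) / 2.0
        obs = u_of(range(n_a))
        assert obs == pytest.approx(u_obs)
        devs = [abs(u_of(c) - mu) for c in itertools.combinations(range(n), n_a)]
        expected_p = np.mean([d >= abs(obs - mu) - 1e-9 for d in devs])
        assert p == pytest.approx(expected_p)


@pytest.fixture(scope="module")
def scored_mixture():
    names = [f"FFM{k}" for k in range(1, 5)] + [f"imm{k}" for k in range(4)]
    S, sets = generate_signatures(200, names, 5, 10.0, seed=6)
    X, truth = generate_mixture(S, 80, [1.0] * 8, noise_sd=0.1, seed=6,
                                marker_sets=sets)
    act = ffm_activity(X, sets[:4])
    return X, truth, act


class TestDiseaseScore:

    def test_score_built_from_ffm2_truth(self, scored_mixture):
        X, truth, act = scored_mixture
        score = truth.P_true[1] * 100  # FFM2 row scaled to [0, 100]
        meta = SampleMetadata(list(act.index), ["m"] * len(act), score)
        recs = disease_score_correlation(act, meta, method="spearman")
        by = {r.x_name: r for r in recs}
        assert by["FFM2"].r > 0.9 and by["FFM2"].significant
        assert all(abs(by[f"FFM{k}"].r) < 0.6 for k in (1, 3, 4))

    def test_negative_construction(self, scored_mixture):
        X, truth, act = scored_mixture
        p3 = truth.P_true[2]
        score = (1 - (p3 - p3.min()) / (p3.max() - p3.min())) * 100
        meta = SampleMetadata(list(act.index), ["m"] * len(act), score)
        recs = disease_score_correlation(act, meta, method="spearman")
        by = {r.x_name: r for r in recs}
        assert by["FFM3"].r < -0.9

    def test_constant_score_undefined(self, scored_mixture):
        X, truth, act = scored_mixture
        meta = SampleMetadata(list(act.index), ["m"] * len(act),
                              np.full(len(act), 50.0))
        recs = disease_score_correlation(act, meta)
        assert all(not r.defined for r in recs)

    def test_missing_score_errors(self, scored_mixture):
        X, truth, act = scored_mixture
        meta = SampleMetadata(list(act.index), ["m"] * len(act))
        with pytest.raises(ValidationError):
            disease_score_correlation(act, meta)


class TestHeatmap:
    def _coupled_dataset(self, seed, beta_by_class=(2.0, -2.0)):
        names = [f"FFM{k}" for k in range(1, 5)]
        S, sets = generate_signatures(150, names, 5, 10.0, seed=seed)
        X, truth = generate_mixture(S, 60, [1.0] * 4, noise_sd=0.2, seed=seed,
                                    marker_sets=sets)
        sup, act = beta_by_class
        couplings = [(f"SUP{j}", "FFM2", sup) for j in range(4)]
        couplings += [(f"ACT{j}", "FFM2", act) for j in range(4)]
        X2, truth = inject_coupled_genes(X, truth, couplings, noise_sd=0.2,
                                        seed=seed)
        ann = {f"SUP{j}": "suppressing" for j in range(4)}
        ann.update({f"ACT{j}": "activating" for j in range(4)})
        activities = ffm_activity(X2, sets)
        return X2, activities, ann

    def test_sign_pattern_matches_coupling(self):
        X, activities, ann = self._coupled_dataset(seed=0)
        r, mask, classes = ffm_immune_heatmap(activities, X, ann)
        assert set(r.index) == set(ann)
        for g in r.index:
            if classes[g] == "suppressing":
                assert r.loc[g, "FFM2"] > 0 and mask.loc[g, "FFM2"]
            else:
                assert r.loc[g, "FFM2"] < 0 and mask.loc[g, "FFM2"]

    def test_opposite_couplings_opposite_signs(self):
        names = [f"FFM{k}" for k in range(1, 5)]
        S, sets = generate_signatures(150, names, 5, 10.0, seed=3)
        X, truth = generate_mixture(S, 100, [1.0] * 4, noise_sd=0.1, seed=3,
                                    marker_sets=sets)
        X2, truth = inject_coupled_genes(
            X, truth, [("DUAL", "FFM2", 2.0)], noise_sd=0.05, seed=3
        )
        act = ffm_activity(X2, sets)
        r, mask, _ = ffm_immune_heatmap(act, X2, {"DUAL": "suppressing"})
        # FFM2 and FFM4 proportions are anticorrelated on the simplex,
        # so one coupled gene shows opposite signs in the two columns
        assert r.loc["DUAL", "FFM2"] > 0

    def test_null_gene_usually_filtered(self):
        kept = 0
        for rep in range(20):
            names = [f"FFM{k}" for k in range(1, 5)]
            S, sets = generate_signatures(100, names, 5, 10.0, seed=rep)
            X, truth = generate_mixture(S, 100, [1.0] * 4, noise_sd=0.1,
                                        seed=rep, marker_sets=sets)
            X2, truth = inject_coupled_genes(X, truth, [("NULL", "FFM2", 0.0)],
                                            noise_sd=0.2, seed=rep)
            act = ffm_activity(X2, sets)
            r, _, _ = ffm_immune_heatmap(act, X2, {"NULL": "activating"})
            kept += "NULL" in r.index
        assert kept <= 4  # filtered out in the vast majority of runs

    def test_no_survivors_gives_empty_tables(self):
        X = ExpressionMatrix(
            ["FFMG", "g2"], ["a", "b", "c", "d", "e"],
            np.array([[1, 2, 3, 4, 5.0], [7, 7, 7, 7, 7.0]]),
        )
        act = pd.DataFrame({"FFM1": [1, 2, 3, 4, 5.0]},
                           index=["a", "b", "c", "d", "e"])
        r, mask, classes = ffm_immune_heatmap(act, X, {"g2": "activating"})
        assert r.empty and mask.empty and classes.empty


class TestOverlap:
    def test_small_example(self):
        rep = overlap_sets(["g1", "g2"], ["g2", "g3"], ["g2"])
        assert rep.region_counts["abc"] == 1
        assert rep.region_members["abc"] == ["g2"]
        assert rep.region_counts["a_only"] == 1

    def test_disjoint_lists(self):
        rep = overlap_sets(["a"], ["b", "c"], ["d"])
        assert rep.region_counts["abc"] == 0
        assert rep.region_counts["a_only"] == 1
        assert rep.region_counts["b_only"] == 2
        assert rep.region_counts["c_only"] == 1

    def test_identical_twelve_gene_lists(self):
        core = [f"g{i}" for i in range(12)]
        rep = overlap_sets(core, list(core), list(core))
        assert rep.region_counts["abc"] == 12
        assert sum(v for k, v in rep.region_counts.items() if k != "abc") == 0

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            overlap_sets(["a", "a"], ["b"], ["c"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_inclusion_exclusion_identities(self, a, b, c):
        A, B, C = (sorted(map(str, s)) for s in (a, b, c))
        rep = overlap_sets(A, B, C)
        rc = rep.region_counts
        assert sum(rc.values()) == len(set(A) | set(B) | set(C))
        assert rc["a_only"] + rc["ab"] + rc["ac"] + rc["abc"] == len(A)
        assert rc["b_only"] + rc["ab"] + rc["bc"] + rc["abc"] == len(B)
        assert rc["c_only"] + rc["ac"] + rc["bc"] + rc["abc"] == len(C)
        assert rc["ab"] + rc["abc"] == len(set(A) & set(B))
        members = list(itertools.chain.from_iterable(rep.region_members.values()))
        assert len(members) == len(set(members))  # regions are disjoint


class TestSimpleDE:
    def _two_group_matrix(self, seed, n_shifted=10, n_null=90, fold=8.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(10, 100, size=(n_shifted + n_null, 40))
        vals = base * np.exp(rng.normal(0, 0.3, base.shape))
        vals[:n_shifted, 20:] *= fold
        genes = [f"DE{i}" if i < n_shifted else f"NULL{i}"
                 for i in range(n_shifted + n_null)]
        X = ExpressionMatrix(genes, [f"s{j}" for j in range(40)], vals)
        meta = SampleMetadata(X.sample_ids, ["a"] * 20 + ["b"] * 20)
        return X, meta

    def test_power_and_false_positives(self):
        good = 0
        for rep in range(10):
            X, meta = self._two_group_matrix(seed=rep)
            hits = simple_de(X, meta, "a", "b")
            true_pos = sum(g.startswith("DE") for g in hits["gene"])
            false_pos = sum(g.startswith("NULL") for g in hits["gene"])
            good += (true_pos >= 9) and (false_pos <= 2)
        assert good >= 9  # >= 90% of seeded repetitions

    def test_null_matrix_controls_fdr(self):
        false = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            vals = rng.uniform(10, 100, (50, 30)) * np.exp(
                rng.normal(0, 0.3, (50, 30))
            )
            X = ExpressionMatrix([f"g{i}" for i in range(50)],
                                 [f"s{j}" for j in range(30)], vals)
            meta = SampleMetadata(X.sample_ids, ["a"] * 15 + ["b"] * 15)
            false.append(len(simple_de(X, meta, "a", "b")))
        assert np.mean(np.array(false) > 0) <= 0.05 + 0.08  # BH null behavior

    def test_identical_groups_empty(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(1, 50, (20, 10))
        vals = np.hstack([half, half])
        X = ExpressionMatrix([f"g{i}" for i in range(20)],
                             [f"s{j}" for j in range(20)], vals)
        meta = SampleMetadata(X.sample_ids, ["a"] * 10 + ["b"] * 10)
        assert len(simple_de(X, meta, "a", "b")) == 0
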