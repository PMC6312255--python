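import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domix.dose_response import (
    DunnettResult,
    classify_shape,
    dose_response_table,
    dunnett_vs_control,
    kruskal_wallis,
    storey_qvalues,
    summarize_dose_sets,
)
from domix.io import RunConfig, ValidationError
from domix.simulate import simulate_cohort, simulate_proteome
from domix.transcript_de import bh_adjust


class TestKruskalWallis:
    def test_hand_evaluated_rank_sum_example(self):
        vals = np.arange(1, 13, dtype=float)
        labels = np.repeat(list("abcd"), 3)
        h, _ = kruskal_wallis(vals, labels)
        assert h == pytest.approx(10.3846, abs=1e-4)

    def test_equal_mean_ranks_give_zero(self):
        h, p = kruskal_wallis([1, 4, 2, 3], ["a", "a", "b", "b"], exact_max_n=0)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_values(self):
        h, p = kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_exact_p_equals_brute_force_enumeration(self, rng):
        """n=8, two groups of 4: compare with exhaustive label permutation."""
        vals = rng.normal(size=8)
        labels = np.repeat(["a", "b"], 4)
        h_obs, p_exact = kruskal_wallis(vals, labels)

        def kw_h(assign):
            ranks = stats.rankdata(vals)
            n = len(vals)
            h = 0.0
            for g in (0, 1):
                r = ranks[np.array(assign) == g]
                h += r.sum() ** 2 / len(r)
            return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            assign = np.ones(8, int)
            assign[list(combo)] = 0
            total += 1
            if kw_h(assign) >= h_obs - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / total, abs=1e-12)

    def test_tie_correction_matches_scipy(self, rng):
        vals = rng.integers(0, 5, size=24).astype(float)
        labels = np.repeat(list("abcd"), 6)
        h, p = kruskal_wallis(vals, labels)
        ref = stats.kruskal(*[vals[labels == g] for g in "abcd"])
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestStorey:
    def test_capped_pi0_reduces_to_bh(self):
        p = np.array([0.001, 0.01, 0.6, 0.8, 0.9])
        q, pi0 = storey_qvalues(p)
        assert pi0 == 1.0  # 3 / (5 * 0.5) caps at 1
        np.testing.assert_allclose(q, bh_adjust(p), atol=1e-15)

    def test_all_ones(self):
        q, pi0 = storey_qvalues(np.ones(20))
        assert (q == 1.0).all()

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_pi0_estimate_tracks_null_fraction(self, rng):
        p = np.concatenate([rng.uniform(size=900), rng.uniform(0, 0.001, size=100)])
        _, pi0 = storey_qvalues(p)
        assert 0.8 <= pi0 <= 1.0

    def test_rejects_invalid(self):
        with pytest.raises(ValidationError):
            storey_qvalues([])
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, 1.2])


class TestDunnett:
    def test_single_comparison_equals_pooled_t(self, rng):
        a = rng.normal(size=6)
        c = rng.normal(size=5)
        res = dunnett_vs_control(c, {"t": a}, seed=0)
        t_ref = stats.ttest_ind(a, c, equal_var=True)
        assert res.pvalue[0] == pytest.approx(t_ref.pvalue, abs=1e-3)

    def test_multiplicity_bounds(self, rng):
        c = rng.normal(size=4)
        groups = {f"g{i}": rng.normal(size=5) for i in range(3)}
        res = dunnett_vs_control(c, groups, seed=0)
        for i, g in enumerate(res.groups):
            # compare against the per-comparison raw p computed from the
            # Dunnett statistic with the pooled degrees of freedom
            raw = 2 * stats.t.sf(abs(res.statistic[i]), df=len(c) - 1 + sum(len(v) - 1 for v in groups.values()))
            assert res.pvalue[i] >= raw - 1e-6
            assert res.pvalue[i] <= min(1.0, 3 * raw) + 1e-6

    def test_direction_is_mean_difference_sign(self):
        res = dunnett_vs_control(
            [0.0, 0.1, -0.1], {"up": [2.0, 2.1, 1.9], "down": [-2.0, -2.1, -1.9]}, seed=0
        )
        assert res.direction.tolist() == [1.0, -1.0]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            dunnett_vs_control([1.0, 1.0], {"t": [1.0, 1.0]}, seed=0)

    def test_adjusted_p_matches_monte_carlo_max_t_oracle(self, rng):
        """Dunnett adjusted p agrees with brute-force simulation of the
        max-|t| null on random small instances."""
        n_rep = 200_000
        for _ in range(5):
            sizes = rng.integers(3, 8, size=4)  # control + 3 groups
            data = [rng.normal(size=s) for s in sizes]
            res = dunnett_vs_control(
                data[0], {f"g{i}": d for i, d in enumerate(data[1:])}, seed=1
            )
            # simulate null max-|t| with the same group sizes
            sim_t = np.empty((n_rep, 3))
            df = sum(sizes) - 4
            draws = [rng.standard_normal((n_rep, s)) for s in sizes]
            means = [d.mean(axis=1) for d in draws]
            ss = sum(((d - m[:, None]) ** 2).sum(axis=1) for d, m in zip(draws, means))
            sp = np.sqrt(ss / df)
            for i in range(3):
                se = sp * np.sqrt(1 / sizes[i + 1] + 1 / sizes[0])
                sim_t[:, i] = (means[i + 1] - means[0]) / se
            max_abs = np.abs(sim_t).max(axis=1)
            for i in range(3):
                mc_p = (max_abs >= abs(res.statistic[i])).mean()
                assert res.pvalue[i] == pytest.approx(mc_p, abs=0.005)


class TestShape:
    def _dunnett(self, pvals, dirs):
        return DunnettResult(("low", "medium", "high"), np.zeros(3), np.array(pvals), np.array(dirs))

    def test_flat_when_not_fdr_significant(self):
        dn = self._dunnett([0.01, 0.01, 0.01], [1, 1, 1])
        assert classify_shape(0.2, dn, {}, 0.05, 0.05) == "flat"

    def test_down_when_all_significant_directions_negative(self):
        dn = self._dunnett([0.5, 0.01, 0.001], [1, -1, -1])
        assert classify_shape(0.01, dn, {}, 0.05, 0.05) == "down"

    def test_cap_when_directions_mixed_with_negative_curvature(self):
        dn = self._dunnett([0.01, 0.3, 0.01], [1, 1, -1])
        means = {"control": 0.0, "low": 1.0, "medium": 0.6, "high": -1.0}
        assert classify_shape(0.01, dn, means, 0.05, 0.05) == "cap_shape"

    def test_u_when_positive_curvature(self):
        dn = self._dunnett([0.01, 0.3, 0.01], [-1, -1, 1])
        means = {"control": 0.0, "low": -1.0, "medium": -0.6, "high": 1.0}
        assert classify_shape(0.01, dn, means, 0.05, 0.05) == "u_shape"

    def test_significant_without_posthoc_goes_to_shape(self):
        dn = self._dunnett([0.5, 0.5, 0.5], [1, -1, 1])
        means = {"control": 0.0, "low": -0.5, "medium": -0.2, "high": 0.4}
        assert classify_shape(0.01, dn, means, 0.05, 0.05) in ("u_shape", "cap_shape")


class TestTableAndSummary:
    def test_significant_features_partition_into_shapes(self, cohort, small_proteome, config):
        ab, _ = small_proteome
        table = dose_response_table(ab, cohort, config)
        sig = table[table["q_value"] <= config.fdr_level]
        assert set(sig["shape"]) <= {"up", "down", "u_shape", "cap_shape"}
        flat = table[table["q_value"] > config.fdr_level]
        assert (flat["shape"] == "flat").all()
        # internal identity: q-significant count == non-flat count
        assert len(sig) == (table["shape"] != "flat").sum()

    def test_summary_counts_consistent(self, cohort, small_proteome, config):
        ab, _ = small_proteome
        table = dose_response_table(ab, cohort, config)
        summary = summarize_dose_sets(table, config.posthoc_alpha, config.fdr_level)
        for d in ("up", "down"):
            for g, n in summary["per_group"][d].items():
                cells = sum(
                    v for k, v in summary["venn"][d].items() if g in k.split("&")
                )
                assert cells == n
        assert sum(summary["shape_counts"].values()) == len(table)

    def test_empty_significant_set_all_zero(self, cohort, rng):
        from domix.io import AbundanceMatrix

        vals = pd.DataFrame(
            rng.normal(size=(15, len(cohort))),
            index=[f"P{i}" for i in range(15)],
            columns=cohort.sample_ids,
        )
        table = dose_response_table(AbundanceMatrix(vals), cohort, RunConfig(fdr_level=1e-6))
        summary = summarize_dose_sets(table, 1e-6, 1e-6)
        assert all(n == 0 for d in ("up", "down") for n in summary["per_group"][d].values())

    def test_high_dose_down_effects_dominate_low_dose(self):
        """Planted monotone-down dose effects hit the high group far more
        often than the low group (dose scaling makes low-dose shifts tiny)."""
        md = simulate_cohort(seed=5)
        ab, truth = simulate_proteome(
            md,
            n_features=80,
            category_proportions={"dose_only": 1.0},
            effect_size=3.0,
            seed=5,
        )
        down_ids = set(truth.loc[truth["true_direction"] == "down", "feature_id"])
        table = dose_response_table(ab, md, RunConfig(seed=5))
        table = table[table["feature_id"].isin(down_ids)]
        summary = summarize_dose_sets(table)
        assert summary["per_group"]["down"]["high"] > summary["per_group"]["down"]["low"]

    def test_fully_null_proteome_controls_fdr(self):
        """Fraction of q <= 0.05 calls on a null proteome stays at/below
        the nominal level across seeds (rank tests are transform-invariant,
        so the raw scale is used directly)."""
        flagged = total = 0
        for s in range(30):
            md = simulate_cohort(seed=s)
            ab, _ = simulate_proteome(
                md, n_features=150, category_proportions={"none": 1.0}, seed=s
            )
            groups = md.dose_group.to_numpy()
            pvals = np.array(
                [kruskal_wallis(row, groups)[1] for row in ab.values.to_numpy()]
            )
            q, _ = storey_qvalues(pvals)
            flagged += (q <= 0.05).sum()
            total += len(q)
        assert flagged / total <= 0.05
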