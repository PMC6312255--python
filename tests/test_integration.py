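import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from domix.integration import (
    coherence_report,
    fisher_combine,
    integrate,
    map_features,
    protein_high_vs_control_p,
    restrictive_intersection,
)
from domix.io import AbundanceMatrix, FeatureMap, ValidationError
from domix.simulate import simulate_proteome


class TestProteinTwoGroup:
    def test_identical_groups_p_one(self, cohort):
        vals = pd.DataFrame(
            np.ones((3, len(cohort))), index=list("abc"), columns=cohort.sample_ids
        )
        table = protein_high_vs_control_p(AbundanceMatrix(vals), cohort)
        assert (table["protein_p"] == 1.0).all()
        assert (table["protein_direction"] == 0).all()

    def test_complete_separation_matches_enumeration(self, cohort):
        """3 controls vs 10 high with full separation: exact two-sided p is
        2 / C(13,3)."""
        ctrl = cohort.group_samples("control")
        high = cohort.group_samples("high")
        row = pd.Series(0.0, index=cohort.sample_ids)
        row[ctrl] = [1.0, 2.0, 3.0]
        row[high] = np.arange(10) + 100.0
        vals = pd.DataFrame([row], index=["p1"])
        table = protein_high_vs_control_p(AbundanceMatrix(vals), cohort)
        from math import comb

        assert table["protein_p"].iloc[0] == pytest.approx(2 / comb(13, 3), rel=1e-12)
        assert table["protein_direction"].iloc[0] == 1

    def test_direction_flips_with_group_swap(self, cohort, rng):
        vals = rng.normal(size=(1, len(cohort)))
        frame = pd.DataFrame(vals, index=["p1"], columns=cohort.sample_ids)
        high = cohort.group_samples("high")
        frame.loc["p1", high] += 5.0
        up = protein_high_vs_control_p(AbundanceMatrix(frame), cohort)
        frame.loc["p1", high] -= 10.0
        down = protein_high_vs_control_p(AbundanceMatrix(frame), cohort)
        assert up["protein_direction"].iloc[0] == 1
        assert down["protein_direction"].iloc[0] == -1


class TestFisherCombine:
    def test_unit_inputs(self):
        stat, p = fisher_combine(1.0, 1.0)
        assert stat == 0.0 and p == 1.0

    def test_frozen_closed_form_values(self):
        assert fisher_combine(0.05, 0.05)[1] == pytest.approx(0.017479, abs=1e-6)
        assert fisher_combine(0.01, 0.5)[1] == pytest.approx(0.031492, abs=1e-6)

    def test_closed_form_equals_chi2_survival(self):
        for p1, p2 in [(0.5, 0.5), (0.01, 0.9), (1e-8, 0.3), (0.2, 0.04)]:
            stat, p = fisher_combine(p1, p2)
            assert p == pytest.approx(stats.chi2.sf(stat, df=4), abs=1e-10)

    @given(
        st.floats(min_value=1e-10, max_value=1.0),
        st.floats(min_value=1e-10, max_value=1.0),
        st.floats(min_value=1e-10, max_value=1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_monotone(self, a, b, c):
        assert fisher_combine(a, b)[1] == pytest.approx(fisher_combine(b, a)[1], rel=1e-12)
        lo, hi = sorted([b, c])
        assert fisher_combine(a, lo)[1] <= fisher_combine(a, hi)[1] + 1e-12

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            stat, p = fisher_combine(0.0, 0.5)
        assert 0 < p < 1e-100

    def test_invalid_rejected(self):
        with pytest.raises(ValidationError):
            fisher_combine(1.5, 0.5)


class TestMapping:
    def _tables(self, gene_rows):
        prot = pd.DataFrame(
            {"protein_id": ["P1"], "protein_p": [0.03], "protein_direction": [1]}
        )
        genes = pd.DataFrame(gene_rows)
        fmap = FeatureMap(
            pd.DataFrame(
                {"gene_id": [r["gene_id"] for r in gene_rows], "protein_id": "P1"}
            )
        )
        return prot, genes, fmap

    def test_minimum_p_gene_chosen(self):
        prot, genes, fmap = self._tables(
            [
                {"gene_id": "g1", "wald_p": 0.01, "log2_fold_change": 1.0},
                {"gene_id": "g2", "wald_p": 0.2, "log2_fold_change": -1.0},
            ]
        )
        matched, unmapped = map_features(prot, genes, fmap)
        assert matched["chosen_gene_id"].iloc[0] == "g1"
        assert unmapped == []

    def test_tie_broken_lexicographically(self):
        prot, genes, fmap = self._tables(
            [
                {"gene_id": "gB", "wald_p": 0.05, "log2_fold_change": 1.0},
                {"gene_id": "gA", "wald_p": 0.05, "log2_fold_change": 1.0},
            ]
        )
        matched, _ = map_features(prot, genes, fmap)
        assert matched["chosen_gene_id"].iloc[0] == "gA"

    def test_protein_without_tested_gene_reported(self):
        prot = pd.DataFrame(
            {"protein_id": ["P1", "P2"], "protein_p": [0.5, 0.5], "protein_direction": [1, 1]}
        )
        genes = pd.DataFrame(
            [{"gene_id": "g1", "wald_p": 0.1, "log2_fold_change": 0.5}]
        )
        fmap = FeatureMap(pd.DataFrame({"gene_id": ["g1"], "protein_id": ["P1"]}))
        matched, unmapped = map_features(prot, genes, fmap)
        assert list(matched["protein_id"]) == ["P1"]
        assert unmapped == ["P2"]


class TestRestrictiveAndCoherence:
    def _matched(self):
        return pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3", "P4"],
                "chosen_gene_id": ["g1", "g2", "g3", "g4"],
                "protein_p": [0.01, 0.01, 0.5, 0.01],
                "gene_p": [0.02, 0.03, 0.01, 0.04],
                "protein_direction": [-1, 1, 1, 1],
                "gene_direction": [-1, 1, 1, -1],
            }
        )

    def test_partition_by_direction(self):
        buckets = restrictive_intersection(self._matched(), 0.05)
        assert list(buckets["down"]["protein_id"]) == ["P1"]
        assert list(buckets["up"]["protein_id"]) == ["P2"]
        assert list(buckets["discordant"]["protein_id"]) == ["P4"]

    def test_disjoint_significant_sets_empty(self):
        m = self._matched()
        m["gene_p"] = [0.9, 0.9, 0.9, 0.9]
        buckets = restrictive_intersection(m, 0.05)
        assert all(len(v) == 0 for v in buckets.values())

    def test_coherence_fraction(self):
        records = integrate(self._matched())
        frac = coherence_report(records, alpha=0.5)
        sig = records[records["bh_adjusted_combined_p"] <= 0.5]
        assert frac == pytest.approx(sig["coherent"].mean())

    def test_no_significant_pairs_gives_nan(self):
        records = integrate(self._matched())
        assert np.isnan(coherence_report(records, alpha=1e-12))


def test_integrative_detects_at_least_restrictive_pairs(cohort):
    """On concordant planted effects the Fisher route recovers at least as
    many true pairs as the double-0.05 restrictive rule."""
    from domix.simulate import simulate_feature_map, simulate_transcriptome
    from domix.transcript_de import run_de

    wins = ties = losses = 0
    for s in range(10):
        ab, truth = simulate_proteome(
            cohort,
            n_features=80,
            category_proportions={"dose_only": 0.5, "none": 0.5},
            effect_size=3.0,
            seed=s,
        )
        fm = simulate_feature_map(truth, 400, seed=s)
        counts, truth2 = simulate_transcriptome(
            cohort, fm, truth, n_genes=400, fold=4.0, seed=s
        )
        de, _ = run_de(counts, np.array(["control"] * 2 + ["high"] * 2), reference="control")
        prot = protein_high_vs_control_p(ab, cohort)
        matched, _ = map_features(prot, de, fm)
        records = integrate(matched)
        true_pairs = set(truth2.loc[truth2["paired_gene"] != "", "feature_id"])
        integ = set(
            records.loc[records["bh_adjusted_combined_p"] <= 0.05, "protein_id"]
        ) & true_pairs
        buckets = restrictive_intersection(matched, 0.05)
        restr = (
            set(buckets["up"]["protein_id"]) | set(buckets["down"]["protein_id"])
        ) & true_pairs
        if len(integ) > len(restr):
            wins += 1
        elif len(integ) == len(restr):
            ties += 1
        else:
            losses += 1
    assert losses == 0
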