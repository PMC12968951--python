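import itertools

import numpy as np
import pandas as pd
import pytest

from trapsurv import effort
from trapsurv.data_model import IncidenceMatrix, Landscape
from trapsurv.diversity import expected_rarefied_richness, incidence_frequencies

from conftest import make_traps, random_incidence_matrix


class TestRemovalOrder:
    def test_most_urbanized_first_sorts_descending(self):
        traps = make_traps({"a": 10, "b": 50, "c": 30})
        assert effort.removal_order(traps, "most_urbanized_first") == ["b", "c", "a"]

    def test_least_urbanized_first_is_reverse_when_distinct(self):
        traps = make_traps({"a": 10, "b": 50, "c": 30})
        most = effort.removal_order(traps, "most_urbanized_first")
        least = effort.removal_order(traps, "least_urbanized_first")
        assert least == most[::-1]

    def test_ties_break_by_trap_id(self):
        traps = make_traps({"z": 20, "a": 20, "m": 20})
        assert effort.removal_order(traps, "most_urbanized_first") == ["a", "m", "z"]

    def test_missing_index_is_error(self):
        import dataclasses

        traps = make_traps({"a": 10})
        traps[0] = dataclasses.replace(traps[0], urbanization_index=None)
        with pytest.raises(ValueError, match="missing"):
            effort.removal_order(traps, "most_urbanized_first")


class TestSpeciesLossGivenOrder:
    def test_m1_retain_two_traps(self, m1):
        # removal sequence t4,t3,t2,t1: retaining k=2 keeps {t1,t2} -> 4 species
        curve = effort.species_loss_given_order(m1, ["t4", "t3", "t2", "t1"])
        assert curve.at(2) == pytest.approx(20.0)

    def test_m1_retain_worst_single_trap(self, m1):
        # retaining only t4 = {sp1} loses 4 of 5 species
        curve = effort.species_loss_given_order(m1, ["t1", "t2", "t3", "t4"])
        assert curve.at(1) == pytest.approx(80.0)

    def test_full_retention_loses_nothing(self, m1):
        curve = effort.species_loss_given_order(m1, ["t2", "t1", "t4", "t3"])
        assert curve.at(4) == 0.0

    def test_non_permutation_rejected(self, m1):
        with pytest.raises(ValueError):
            effort.species_loss_given_order(m1, ["t1", "t1", "t2", "t3"])

    def test_loss_monotone_in_removal(self, m1):
        for perm in itertools.permutations(m1.trap_ids):
            loss = effort.species_loss_given_order(m1, list(perm)).mean_loss_pct
            assert (np.diff(loss) <= 1e-12).all()  # more traps retained, less loss


class TestRandomMeanLoss:
    def test_deterministic_under_seed(self, m1):
        a = effort.random_mean_loss(m1, 10, seed=42).mean_loss_pct
        b = effort.random_mean_loss(m1, 10, seed=42).mean_loss_pct
        assert np.array_equal(a, b)

    def test_matches_analytic_identity_at_n1000(self, m1):
        """Mean loss over random permutations converges to the rarefaction
        identity 100*(1 - S(k)/S_obs)."""
        f = incidence_frequencies(m1)
        curve = effort.random_mean_loss(m1, 1000, seed=7)
        for k in range(1, 5):
            expected = 100.0 * (1 - expected_rarefied_richness(f, k) / f.S_obs)
            assert curve.at(k) == pytest.approx(expected, abs=1.5)

    def test_exact_permutation_average_equals_identity(self):
        """Averaging over all T! permutations reproduces the analytic curve
        exactly (subset mean = permutation mean)."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = random_incidence_matrix(rng, n_traps=int(rng.integers(2, 6)))
            f = incidence_frequencies(m)
            exact = effort.exact_mean_loss(m)
            for k in range(1, f.T + 1):
                expected = 100.0 * (1 - expected_rarefied_richness(f, k) / f.S_obs)
                assert exact.at(k) == pytest.approx(expected, abs=1e-9)


def _ordered_fixture():
    """4 traps whose richness strictly decreases with urbanization index:
    the least urbanized trap holds a superset of every other trap."""
    values = np.array(
        [
            [1, 1, 1, 1],
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
            [1, 0, 0, 0],
        ]
    )
    m = IncidenceMatrix(
        species_ids=[f"sp{i}" for i in range(5)],
        trap_ids=["t1", "t2", "t3", "t4"],
        values=values,
    )
    traps = make_traps({"t1": 5, "t2": 30, "t3": 60, "t4": 90})
    return m, traps


def test_ordered_policies_bracket_random():
    """With richness strictly decreasing in urbanization, removing the most
    urbanized traps first loses the fewest species at every k."""
    m, traps = _ordered_fixture()
    most = effort.species_loss_given_order(m, effort.removal_order(traps, "most_urbanized_first"))
    least = effort.species_loss_given_order(m, effort.removal_order(traps, "least_urbanized_first"))
    rand = effort.exact_mean_loss(m)
    for k in range(1, 5):
        assert most.at(k) <= rand.at(k) + 1e-9
        assert rand.at(k) <= least.at(k) + 1e-9


class TestScenarioTable:
    def _items(self, n_landscapes=3, seed=0):
        rng = np.random.default_rng(seed)
        items = []
        for i in range(n_landscapes):
            m = random_incidence_matrix(rng, n_species=12, n_traps=8)
            idx = {tid: float(rng.uniform(0, 100)) for tid in m.trap_ids}
            traps = make_traps(idx, landscape_id=f"L{i}")
            items.append((Landscape(f"L{i}", 50.0, tuple(traps)), m))
        return items

    def _scenarios(self):
        return [
            effort.RemovalScenario("random", n_randomizations=50, seed=1),
            effort.RemovalScenario("most_urbanized_first"),
            effort.RemovalScenario("least_urbanized_first"),
        ]

    def test_cardinality(self):
        table = effort.scenario_table(self._items(), self._scenarios(), k_values=(4, 2))
        assert len(table) == 3 * 3 * 2  # landscapes x policies x k

    def test_equal_indices_make_policies_agree_in_expectation(self):
        """When every trap shares one index value the ordered policies pick
        an arbitrary (id-sorted) permutation that carries no information
        about the community, so averaged over landscapes all three policies
        lose the same fraction of species (exchangeability)."""
        rng = np.random.default_rng(1)
        items = []
        for i in range(40):
            m = random_incidence_matrix(rng, n_species=10, n_traps=6)
            traps = make_traps({tid: 50.0 for tid in m.trap_ids}, f"L{i}")
            items.append((Landscape(f"L{i}", 50.0, tuple(traps)), m))
        scenarios = [
            effort.RemovalScenario("random", n_randomizations=200, seed=3),
            effort.RemovalScenario("most_urbanized_first"),
            effort.RemovalScenario("least_urbanized_first"),
        ]
        table = effort.scenario_table(items, scenarios, k_values=(3,))
        means = table.groupby("policy")["mean_loss_pct"].mean()
        assert means.max() - means.min() < 3.0  # Monte-Carlo error only

    def test_k_exceeding_T_flagged_not_dropped(self):
        table = effort.scenario_table(self._items(), self._scenarios(), k_values=(10,))
        assert table["k_exceeds_T"].all()
        assert len(table) == 9


class TestCompareScenarios:
    def _table(self, loss_by_policy: dict, n_landscapes=5, k=4, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_landscapes):
            for pol, base in loss_by_policy.items():
                rows.append(
                    {
                        "landscape_id": f"L{i}",
                        "policy": pol,
                        "k": k,
                        "mean_loss_pct": base + i + jitter * rng.normal(),
                        "k_exceeds_T": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_policies_give_null_result(self):
        table = self._table({"random": 20.0, "most_urbanized_first": 20.0})
        res = effort.compare_scenarios(table, 4)
        assert res["overall"]["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res["pairwise"][0]["mean_difference"] == 0.0
        assert res["pairwise"][0]["p"] == 1.0

    def test_detects_policy_separation(self):
        table = self._table(
            {"most_urbanized_first": 15.0, "least_urbanized_first": 30.0}, jitter=0.5
        )
        res = effort.compare_scenarios(table, 4)
        assert res["overall"]["p"] < 0.01
        contrast = res["pairwise"][0]
        assert contrast["p"] < 0.01
        assert abs(contrast["mean_difference"]) == pytest.approx(15.0, abs=2.0)
        assert (
            res["policy_means"]["most_urbanized_first"]
            < res["policy_means"]["least_urbanized_first"]
        )

    def test_invariant_to_landscape_relabeling(self):
        table = self._table(
            {"random": 20.0, "least_urbanized_first": 26.0}, jitter=1.0
        )
        res1 = effort.compare_scenarios(table, 4)
        relabeled = table.copy()
        relabeled["landscape_id"] = relabeled["landscape_id"].map(
            lambda s: f"site_{hash(s) % 97}"
        )
        res2 = effort.compare_scenarios(relabeled, 4)
        assert res1["overall"]["chi2"] == pytest.approx(res2["overall"]["chi2"])
        assert res1["pairwise"][0]["p"] == pytest.approx(res2["pairwise"][0]["p"])

    def test_needs_two_landscapes(self):
        table = self._table({"random": 20.0, "most_urbanized_first": 18.0}, n_landscapes=1)
        with pytest.raises(ValueError):
            effort.compare_scenarios(table, 4)


class TestLandscapeRegressions:
    def test_perfect_line(self):
        fit = effort.loss_covariate_regression([(0, 0), (1, 1), (2, 2)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = effort.coverage_covariate_regression([(10, 0.9), (40, 0.9), (70, 0.9)])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            effort.loss_covariate_regression([(5, 1), (5, 2), (5, 3)])

    def test_null_rejection_rate_is_nominal(self):
        """Under a flat true slope, the F-test rejects at ~ alpha = 0.05."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            x = rng.uniform(10, 80, 13)
            y = 20 + rng.normal(0, 5, 13)
            fit = effort.landscape_ols(x, y)
            rejections += fit.p_value < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.015)

    def test_coverage_slope_saturates_with_effort(self):
        """Coverage rises with landscape tree cover at low trap numbers, but
        the regression slope shrinks toward zero at t=32 where every
        landscape's coverage approaches saturation."""
        from trapsurv import data_model
        from trapsurv.diversity import coverage_at, incidence_frequencies
        from trapsurv.synthetic import SyntheticStudyConfig, generate_study

        s4, s32 = [], []
        for seed in range(30):
            study = generate_study(SyntheticStudyConfig(seed=seed))
            x, c4, c32 = [], [], []
            for land in study.landscapes:
                _, inc = data_model.build_matrices(
                    study.traps, study.records, land.landscape_id
                )
                f = incidence_frequencies(inc)
                x.append(land.tree_cover_2km)
                c4.append(coverage_at(f, 4))
                c32.append(coverage_at(f, 32))
            s4.append(effort.coverage_covariate_regression(zip(x, c4)).slope)
            s32.append(effort.coverage_covariate_regression(zip(x, c32)).slope)
        assert abs(np.mean(s32)) < abs(np.mean(s4))
        assert np.mean(s4) > 0  # sparser, more urban landscapes covered worse

    def test_recovers_negative_loss_tree_cover_slope(self):
        """With the generator's default negative urbanization effect, species
        loss at half effort declines with landscape tree cover: the fitted
        slope is negative in the large majority of replicates and strongly
        negative on average.  (The expected loss is computed analytically via
        the rarefaction identity, removing Monte-Carlo noise from the check.)
        """
        from trapsurv import data_model
        from trapsurv.diversity import expected_rarefied_richness, incidence_frequencies
        from trapsurv.synthetic import SyntheticStudyConfig, generate_study

        slopes = []
        n_reps = 60
        for seed in range(n_reps):
            study = generate_study(SyntheticStudyConfig(seed=seed))
            pairs = []
            for land in study.landscapes:
                _, inc = data_model.build_matrices(
                    study.traps, study.records, land.landscape_id
                )
                f = incidence_frequencies(inc)
                loss = 100.0 * (1 - expected_rarefied_richness(f, 8) / f.S_obs)
                pairs.append((land.tree_cover_2km, loss))
            slopes.append(effort.loss_covariate_regression(pairs).slope)
        slopes = np.asarray(slopes)
        assert (slopes < 0).mean() >= 0.80
        # pooled evidence: mean slope well below zero
        assert slopes.mean() / (slopes.std(ddof=1) / np.sqrt(n_reps)) < -4.0
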