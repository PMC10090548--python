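import numpy as np
import pytest

from ccmen import (
    CBETable,
    Configuration,
    class_probabilities,
    configuration_bst,
    count_combinations,
    count_configurations,
    distribution_over_k,
    enumerate_configurations,
    zero_channel,
)
from ccmen.errors import DegenerateModelError

from _oracle import oracle_bst


class TestCounting:
    @pytest.mark.parametrize("n,k,expected", [(11, 2, 55), (11, 11, 1), (4, 2, 6)])
    def test_binomial(self, n, k, expected):
        assert count_combinations(n, k) == expected

    @pytest.mark.parametrize("n,k", [(4, 0), (4, 5), (4, -1)])
    def test_domain_errors(self, n, k):
        with pytest.raises(ValueError):
            count_combinations(n, k)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_configuration_count_matches_closed_form(self, n):
        configs = list(enumerate_configurations(n))
        assert len(configs) == len(set(configs))  # each exactly once
        assert len(configs) == count_configurations(n)
        # brute-force count oracle: sum over k of C(n,k) * (2k+1)
        brute = sum(
            count_combinations(n, k) * (2 * k + 1) for k in range(1, n + 1)
        )
        assert len(configs) == brute


class TestEnumerateConfigurations:
    def test_n2_exhaustive_hand_enumeration(self):
        configs = {(c.codes, c.k_f, c.branch) for c in enumerate_configurations(2)}
        expected = {
            ((1,), 0, "GCC"), ((1,), 0, "NHC"), ((1,), 1, "F_only"),
            ((2,), 0, "GCC"), ((2,), 0, "NHC"), ((2,), 1, "F_only"),
            ((1, 2), 0, "GCC"), ((1, 2), 0, "NHC"),
            ((1, 2), 1, "GCC"), ((1, 2), 1, "NHC"),
            ((1, 2), 2, "F_only"),
        }
        assert configs == expected

    def test_n1_has_three_configurations(self):
        assert len(list(enumerate_configurations(1))) == 3

    def test_f_only_requires_full_factor_degree(self):
        with pytest.raises(ValueError):
            Configuration(codes=(1, 2), k_f=1, branch="F_only")
        with pytest.raises(ValueError):
            Configuration(codes=(1, 2), k_f=2, branch="GCC")


class TestConfigurationBst:
    def test_two_assignment_average(self):
        cbe = CBETable(gcc={1: 2.0, 2: 4.0}, nhc={1: 0.0, 2: 0.0}, f={1: 1.0, 2: 3.0})
        config = Configuration(codes=(1, 2), k_f=1, branch="GCC")
        bst = configuration_bst(config, cbe)
        # assignments: {1 factor-bound} -> cell 4, factor 1; {2} -> cell 2, factor 3
        assert bst.gcc == pytest.approx(3.0)
        assert bst.f == pytest.approx(2.0)

    def test_no_factor_bound_members(self, toy_cbe):
        config = Configuration(codes=(1, 2), k_f=0, branch="GCC")
        bst = configuration_bst(config, toy_cbe)
        assert bst.f == 0.0
        assert bst.gcc == pytest.approx(toy_cbe.gcc[1] + toy_cbe.gcc[2])

    def test_full_factor_interaction(self, toy_cbe):
        config = Configuration(codes=(1, 2), k_f=2, branch="F_only")
        bst = configuration_bst(config, toy_cbe)
        assert bst.gcc == 0.0 and bst.nhc == 0.0
        assert bst.f == pytest.approx(toy_cbe.f[1] + toy_cbe.f[2])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_assignment_enumeration(self, make_cbe, seed):
        cbe = make_cbe(n=5, seed=seed)
        for config in enumerate_configurations(5):
            bst = configuration_bst(config, cbe)
            expected = oracle_bst(config.codes, config.k_f, cbe.gcc, cbe.nhc, cbe.f)
            assert bst.as_array() == pytest.approx(np.array(expected))


class TestClassProbabilities:
    def test_normalization(self, make_cbe):
        cbe = make_cbe(n=4, seed=7)
        ptable = class_probabilities(enumerate_configurations(4), cbe)
        assert ptable.frame["p_abs"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_nhc_channel_kills_nhc_mass(self, make_cbe):
        cbe = zero_channel(make_cbe(n=4, seed=7), "NHC")
        ptable = class_probabilities(enumerate_configurations(4), cbe)
        nhc = ptable.frame[ptable.frame["channel"] == "NHC"]
        assert (nhc["p_abs"] == 0).all()

    def test_all_zero_cbe_is_degenerate(self):
        cbe = CBETable(gcc={1: 0.0}, nhc={1: 0.0}, f={1: 0.0})
        with pytest.raises(DegenerateModelError):
            class_probabilities(enumerate_configurations(1), cbe)

    def test_scale_invariance_of_probabilities(self, make_cbe):
        cbe = make_cbe(n=4, seed=2)
        base = class_probabilities(enumerate_configurations(4), cbe)
        scaled = class_probabilities(enumerate_configurations(4), cbe.scaled(17.0))
        assert scaled.frame["p_abs"].to_numpy() == pytest.approx(
            base.frame["p_abs"].to_numpy()
        )
        assert scaled.frame["cp_within_k"].to_numpy() == pytest.approx(
            base.frame["cp_within_k"].to_numpy()
        )

    def test_no_simultaneous_gcc_and_nhc_mass(self, make_cbe):
        # assumption: the cell branch is exclusive per configuration
        cbe = make_cbe(n=4, seed=5)
        ptable = class_probabilities(enumerate_configurations(4), cbe)
        per_branch = ptable.frame.groupby(["codes", "kf", "branch"])["channel"].apply(set)
        for channels in per_branch:
            assert not {"GCC", "NHC"} <= channels


class TestDistributionOverK:
    def test_per_k_channel_sums_to_one(self, make_cbe):
        cbe = make_cbe(n=5, seed=11)
        ptable = class_probabilities(enumerate_configurations(5), cbe)
        dist = distribution_over_k(ptable)
        sums = dist[["GCC", "NHC", "F"]].sum(axis=1)
        assert sums.to_numpy() == pytest.approx(np.ones(5))
        assert dist["mass"].sum() == pytest.approx(1.0)

    def test_single_receptor_all_mass_at_k1(self):
        cbe = CBETable(gcc={1: 1.0}, nhc={1: 1.0}, f={1: 1.0})
        ptable = class_probabilities(enumerate_configurations(1), cbe)
        dist = distribution_over_k(ptable)
        assert dist.loc[1, "mass"] == pytest.approx(1.0)

    def test_uniform_cbe_mass_matches_hand_totals(self):
        # with every CBE = 1 a degree-k combination carries k(k+1)/2 weight on
        # each cell channel and k^2 on F, i.e. k(2k+1) in total, so the
        # per-degree mass is proportional to C(n,k) * k * (2k+1)
        n = 4
        cbe = CBETable(
            gcc={c: 1.0 for c in range(1, n + 1)},
            nhc={c: 1.0 for c in range(1, n + 1)},
            f={c: 1.0 for c in range(1, n + 1)},
        )
        ptable = class_probabilities(enumerate_configurations(n), cbe)
        dist = distribution_over_k(ptable)
        raw = np.array(
            [count_combinations(n, k) * k * (2 * k + 1) for k in range(1, n + 1)],
            dtype=float,
        )
        assert dist["mass"].to_numpy() == pytest.approx(raw / raw.sum())
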