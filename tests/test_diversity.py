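import warnings

import numpy as np
import pytest

from gdassess.diversity import (
    TajimaConstants,
    folded_sfs,
    harmonic_a1,
    individual_heterozygosity,
    nucleotide_diversity,
    pairwise_diversity_abs,
    population_summary,
    tajimas_d,
    watterson_theta,
    window_stats,
)
from gdassess.genomic_io import HET, HOM_ALT, HOM_REF, MISSING, Window
from gdassess.synthetic import pairwise_differences, simulate_coalescent, pair_diploids

from conftest import make_table
from oracles import brute_force_pi, tajimas_d_exact


class TestFoldedSFS:
    def test_hand_counted_example(self):
        # 4 haplotypes = 2 diploids; derived counts {1, 2, 2}
        table = make_table(
            [10, 20, 30],
            [[HET, HOM_REF],      # x=1
             [HOM_ALT, HOM_REF],  # x=2
             [HET, HET]],         # x=2
        )
        sfs = folded_sfs(table)
        assert sfs.n_chromosomes == 4
        assert list(sfs.counts[1:]) == [1, 2]
        assert sfs.n_segregating == 3

    def test_monomorphic_sites_contribute_nothing(self):
        table = make_table([10, 20], [[HOM_REF, HOM_REF], [HOM_ALT, HOM_ALT]])
        assert folded_sfs(table).n_segregating == 0

    def test_folding_symmetry(self):
        # derived count 3 of 4 folds into the same bin as count 1
        high = make_table([10], [[HOM_ALT, HET]])
        low = make_table([10], [[HET, HOM_REF]])
        assert list(folded_sfs(high).counts) == list(folded_sfs(low).counts)


class TestWatterson:
    def test_worked_example_to_six_decimals(self):
        assert watterson_theta(3, 4, 100) == pytest.approx(3 / (11 / 6) / 100, abs=1e-6)

    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 4, 100) == 0.0

    def test_doubling_length_halves_theta(self):
        assert watterson_theta(5, 8, 200) == pytest.approx(
            watterson_theta(5, 8, 100) / 2
        )

    def test_undefined_without_denominator(self):
        assert watterson_theta(3, 4, 0) is None


class TestPi:
    def test_single_site_example(self):
        # x=2, n=4 -> 2*2*2/(4*3) = 2/3 per site over L=100
        table = make_table([10], [[HET, HET]])
        assert nucleotide_diversity(table, L_eff=100) == pytest.approx(2 / 300, abs=1e-7)

    def test_monomorphic_region_is_zero(self):
        table = make_table([10], [[HOM_REF, HOM_REF]])
        assert nucleotide_diversity(table, L_eff=100) == 0.0

    @pytest.mark.parametrize("n_hap,theta,seed", [(4, 3.0, 0), (6, 4.0, 1), (8, 6.0, 2)])
    def test_counting_formula_equals_all_pairs_oracle(self, n_hap, theta, seed):
        """π by 2x(n−x)/(n(n−1)) counting equals brute-force pairwise distances."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            hap = simulate_coalescent(n_hap, theta, rng, window_length=1000)
            if len(hap.positions) > 20:
                continue
            counts = np.array([len(c) for c in hap.carriers])
            ns = np.full(len(counts), n_hap)
            assert pairwise_diversity_abs(counts, ns) == pytest.approx(
                brute_force_pi(hap), abs=1e-9
            )


class TestTajimasD:
    def test_matches_exact_rational_constants(self):
        assert tajimas_d(3, 2.0, 4) == pytest.approx(tajimas_d_exact(3, 2.0, 4), abs=1e-12)
        assert tajimas_d(3, 2.0, 4) == pytest.approx(2.01, abs=0.005)

    def test_zero_when_pi_equals_watterson(self):
        a1 = harmonic_a1(6)
        assert tajimas_d(4, 4 / a1, 6) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_at_no_segregating_sites(self):
        assert tajimas_d(0, 0.0, 10) is None

    def test_constants_table(self):
        k = TajimaConstants.from_n(4)
        assert k.a1 == pytest.approx(11 / 6, abs=1e-12)
        assert k.a2 == pytest.approx(49 / 36, abs=1e-12)

    def test_neutral_numerator_is_mean_zero(self):
        """π − S/a1 has expectation 0 under neutrality (both estimate θ)."""
        rng = np.random.default_rng(11)
        a1 = harmonic_a1(10)
        vals = []
        for _ in range(2000):
            hap = simulate_coalescent(10, 5.0, rng)
            vals.append(pairwise_differences(hap) - len(hap.positions) / a1)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestWindowStats:
    def test_composition_of_worked_examples(self):
        table = make_table(
            [10, 20, 30],
            [[HET, HOM_REF], [HOM_ALT, HOM_REF], [HET, HET]],
        )
        w = Window("s1", 0, 100, effective_sites=100)
        st = window_stats(table, w)
        assert st.S == 3
        assert st.theta_w == pytest.approx(0.0163636, abs=1e-6)
        assert st.pi == pytest.approx((0.5 + 2 / 3 + 2 / 3) / 100)
        assert st.tajimas_d == pytest.approx(
            tajimas_d_exact(3, 0.5 + 2 / 3 + 2 / 3, 4), abs=1e-12
        )

    def test_no_sites_but_callable(self):
        table = make_table([], np.empty((0, 2)))
        st = window_stats(table, Window("s1", 0, 100, effective_sites=100))
        assert (st.S, st.theta_w, st.pi, st.tajimas_d) == (0, 0.0, 0.0, None)

    def test_zero_effective_sites_flags_undefined(self):
        table = make_table([10], [[HET, HOM_REF]])
        st = window_stats(table, Window("s1", 0, 100, effective_sites=0))
        assert st.theta_w is None and st.pi is None

    def test_window_split_conserves_segregating_sites(self):
        table = make_table(
            [10, 60, 110, 160],
            [[HET, HOM_REF]] * 4,
        )
        whole = window_stats(table, Window("s1", 0, 200, 200))
        left = window_stats(table, Window("s1", 0, 100, 100))
        right = window_stats(table, Window("s1", 100, 200, 100))
        assert left.S + right.S == whole.S == 4

    def test_low_call_rate_sites_dropped(self):
        table = make_table(
            [10, 20],
            [[HET, MISSING, MISSING, MISSING], [HET, HOM_REF, HOM_REF, HOM_REF]],
        )
        st = window_stats(table, Window("s1", 0, 100, 100), call_rate=0.8)
        assert st.S == 1  # first site has call rate 0.25


class TestHeterozygosity:
    def test_count_over_callable(self):
        table = make_table([10, 20, 30], [[HET, HOM_REF]] * 3)
        est = individual_heterozygosity(table, "ind0", 1000)
        assert est.H == pytest.approx(0.003)

    def test_bounds(self):
        table = make_table([10, 20], [[HOM_REF, HET], [HOM_ALT, HET]])
        assert individual_heterozygosity(table, "ind0", 2).H == 0.0
        assert individual_heterozygosity(table, "ind1", 2).H == 1.0

    def test_undefined_denominator(self):
        table = make_table([10], [[HET, HET]])
        assert individual_heterozygosity(table, "ind0", 0) is None

    def test_unknown_sample(self):
        table = make_table([10], [[HET, HET]])
        with pytest.raises(ValueError, match="ghost"):
            individual_heterozygosity(table, "ghost", 10)


class TestPopulationSummary:
    def test_window_means(self):
        table = make_table([10], [[HET, HOM_REF]])
        s1 = window_stats(table, Window("s1", 0, 100, 100))
        table2 = make_table([110, 120, 130], [[HET, HOM_REF]] * 3)
        s2 = window_stats(table2, Window("s1", 100, 200, 100))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = population_summary([s1, s2], [], label="toy")
        assert summary.mean_theta_w == pytest.approx((s1.theta_w + s2.theta_w) / 2)
        assert summary.n_windows == 2

    def test_single_individual_warns(self):
        table = make_table([10], [[HET, HOM_REF]])
        st = window_stats(table, Window("s1", 0, 100, 100))
        h = individual_heterozygosity(table, "ind0", 100)
        with pytest.warns(UserWarning, match="fewer than 2"):
            summary = population_summary([st], [h])
        assert summary.mean_H == h.H

    def test_no_defined_windows_errors(self):
        table = make_table([10], [[HET, HOM_REF]])
        st = window_stats(table, Window("s1", 0, 100, 0))
        with pytest.raises(ValueError):
            population_summary([st], [])

    def test_mean_invariant_to_window_order(self):
        rng = np.random.default_rng(3)
        stats = []
        for i in range(5):
            hap = simulate_coalescent(8, 4.0, rng, window_length=1000)
            table = pair_diploids(hap, "s1", offset=i * 1000)
            stats.append(window_stats(table, Window("s1", i * 1000, (i + 1) * 1000, 1000)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = population_summary(stats, [])
            rev = population_summary(stats[::-1], [])
        assert fwd.mean_theta_w == pytest.approx(rev.mean_theta_w)
        assert fwd.mean_pi == pytest.approx(rev.mean_pi)
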