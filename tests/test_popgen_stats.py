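"""Window grid, π, Watterson's θ, F_ST estimators and the π-ratio."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.genotypes import MISSING
from sweepscan import popgen_stats as ps
from sweepscan.synthetic_data import SimulationConfig, simulate_cohort
from conftest import make_matrix
from oracles import explicit_window_pi, wc_theta_literal


class TestMakeWindows:
    @pytest.mark.parametrize("length,n_full", [
        (1_000_000, 91), (100_000, 1), (120_000, 3)])
    def test_full_window_counts(self, length, n_full):
        grid = ps.make_windows({"chr1": length})
        full = grid[~grid["partial"]]
        assert len(full) == n_full
        starts = full["start"].to_numpy()
        assert np.all(np.diff(starts) == 10_000)
        assert (full["end"] <= length).all()

    def test_short_chromosome_single_partial(self, caplog):
        with caplog.at_level("WARNING"):
            grid = ps.make_windows({"chr1": 60_000})
        assert len(grid) == 1
        assert grid.iloc[0]["partial"]
        assert grid.iloc[0]["end"] == 60_000

    def test_trailing_partial_needs_half_window(self):
        # 1,000,000 leaves a 90-kb tail at 910,000 -> partial included
        grid = ps.make_windows({"chr1": 1_000_000})
        tail = grid[grid["partial"]]
        assert len(tail) == 1
        assert (tail.iloc[0]["start"], tail.iloc[0]["end"]) == (910_000, 1_000_000)
        # non-overlapping 100-bp windows: a 30-bp tail is below half a
        # window and dropped, a 60-bp tail is kept
        grid = ps.make_windows({"chr1": 230}, 100, 100)
        assert not grid["partial"].any()
        grid = ps.make_windows({"chr1": 260}, 100, 100)
        assert grid["partial"].sum() == 1

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            ps.make_windows({"chr1": 1_000_000}, 10_000, 20_000)


class TestSitePi:
    def test_two_homozygotes(self):
        # alleles {A,A,T,T}: 4 of 6 pairs differ -> 2/3
        assert ps.site_pi([0, 2]) == pytest.approx(2 / 3)

    def test_two_heterozygotes_same_value(self):
        assert ps.site_pi([1, 1]) == pytest.approx(2 / 3)

    def test_monomorphic_is_zero(self):
        assert ps.site_pi([0, 0, 0]) == 0.0

    def test_single_called_sample_excluded(self):
        # one called heterozygote still has 2 alleles: the single pair differs
        assert ps.site_pi([1, MISSING]) == pytest.approx(1.0)
        assert ps.site_pi([MISSING, MISSING]) == 0.0


class TestWindowPi:
    def test_single_site_over_span(self):
        g = make_matrix(np.array([[0], [2], [0], [0]], dtype=np.int8),
                        positions=[500],
                        populations=["p1", "p1", "p2", "p2"])
        grid = ps.make_windows({"chr1": 100_000})
        pi = ps.window_pi(g, "p1", grid)
        assert pi[0] == pytest.approx(2 / 3 / 100_000)

    def test_empty_window_invalid(self):
        g = make_matrix(np.zeros((4, 1), dtype=np.int8), positions=[500])
        grid = ps.make_windows({"chr1": 200_000}, 100_000, 100_000)
        stats = ps.window_statistics(g, grid, "pop1", "pop2", min_snvs=1)
        assert stats["pi_pop1"][1] == 0.0
        assert not stats["valid"][1]

    def test_matches_explicit_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(-1, 3, size=(6, 20)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 300_000), 20, replace=False))
        g = make_matrix(d, positions=pos,
                        populations=["p1"] * 3 + ["p2"] * 3)
        grid = ps.make_windows({"chr1": 300_000})
        for pop in ("p1", "p2"):
            fast = ps.window_pi(g, pop, grid)
            brute = explicit_window_pi(g, pop, grid)
            np.testing.assert_allclose(fast, brute, rtol=0, atol=1e-15)

    def test_linearity_over_disjoint_windows(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(8, 200)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 400_000), 200, replace=False))
        g = make_matrix(d, positions=pos)
        grid = ps.make_windows({"chr1": 400_000}, 100_000, 100_000)
        assert not grid["partial"].any()
        total = ps.window_pi(g, "pop1", grid) @ (
            grid["end"] - grid["start"]).to_numpy()
        assert total == pytest.approx(ps.per_site_pi(g, "pop1").sum())


class TestWattersonTheta:
    def test_harmonic_number_arithmetic(self):
        # S=1 with 4 called alleles over a 100-kb window
        d = np.array([[0], [1], [0], [0]], dtype=np.int8)
        g = make_matrix(d, positions=[500],
                        populations=["p1", "p1", "p2", "p2"])
        grid = ps.make_windows({"chr1": 100_000})
        theta = ps.watterson_theta(g, "p1", grid)
        assert theta[0] == pytest.approx(1 / ((1 + 1 / 2 + 1 / 3) * 1e5))

    def test_no_segregating_sites(self):
        g = make_matrix(np.zeros((4, 3), dtype=np.int8))
        grid = ps.make_windows({"chr1": 100_000})
        assert ps.watterson_theta(g, "pop1", grid)[0] == 0.0

    def test_textbook_form_constant_sample(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        g = make_matrix(d, positions=pos, populations=["p1"] * 10)
        grid = ps.make_windows({"chr1": 100_000})
        alt, tot = g.allele_counts("p1")
        S = int(((alt > 0) & (alt < tot)).sum())
        a_n = sum(1 / i for i in range(1, 20))
        assert ps.watterson_theta(g, "p1", grid)[0] == pytest.approx(
            S / (a_n * 100_000))


class TestWcComponents:
    def test_no_differentiation(self):
        # equal frequencies, HWE-balanced genotypes, equal sizes
        pop = [0] * 4 + [1] * 8 + [2] * 4  # p = 0.5, h = 0.5 over n=16
        a, b, c = ps.wc_fst_components(pop, pop)
        assert a == pytest.approx(0.0, abs=0.01)
        assert a / (a + b + c) <= 0.0 + 1e-12

    def test_fixed_difference(self):
        a, b, c = ps.wc_fst_components([0] * 10, [2] * 10)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_against_literal_transcription(self):
        """HWE-rounded genotype counts at p1=0.2 (n=20), p2=0.8 (n=13)."""
        # 20 diploids at p(alt)=0.2: HWE counts ~ (12.8,6.4,0.8) -> 13,6,1
        # 13 diploids at p(alt)=0.8: HWE counts ~ (0.52,4.16,8.32) -> 1,4,8
        counts1, counts2 = (13, 6, 1), (1, 4, 8)
        dos1 = [0] * 13 + [1] * 6 + [2] * 1
        dos2 = [0] * 1 + [1] * 4 + [2] * 8
        a, b, c = ps.wc_fst_components(dos1, dos2)
        a_o, b_o, c_o = wc_theta_literal(counts1, counts2)
        assert a == pytest.approx(a_o, rel=1e-12)
        assert b == pytest.approx(b_o, rel=1e-12)
        assert c == pytest.approx(c_o, rel=1e-12)

    def test_population_without_calls_rejected(self):
        with pytest.raises(ValueError):
            ps.wc_fst_components([MISSING, MISSING], [0, 1])


class TestWindowFst:
    def test_fixed_differences_give_one(self):
        d = np.vstack([np.zeros((5, 30)), np.full((5, 30), 2)]).astype(np.int8)
        g = make_matrix(d)
        grid = ps.make_windows({"chr1": 100_000})
        for estimator in ("wc", "hudson"):
            fst, _ = ps.window_fst(g, grid, "pop1", "pop2", estimator)
            assert fst[0] == pytest.approx(1.0)

    def test_estimators_agree_on_balanced_hwe(self):
        cfg = SimulationConfig(chrom_lengths={"chr1": 10_000_000},
                               n_sites=10_000, sweep_intervals=[],
                               background_F=0.1, missing_rate=0.0,
                               n_pop1=16, n_pop2=16, seed=21)
        g, _ = simulate_cohort(cfg)
        grid = ps.make_windows({"chr1": 10_000_000})
        wc, _ = ps.window_fst(g, grid, "domestic", "wild", "wc")
        hu, _ = ps.window_fst(g, grid, "domestic", "wild", "hudson")
        ok = ~np.isnan(wc) & ~np.isnan(hu)
        assert np.nanmax(np.abs(wc[ok] - hu[ok])) < 0.02

    def test_monomorphic_window_is_nan(self):
        g = make_matrix(np.zeros((6, 5), dtype=np.int8))
        grid = ps.make_windows({"chr1": 100_000})
        fst, _ = ps.window_fst(g, grid, "pop1", "pop2")
        assert np.isnan(fst[0])


class TestPiRatio:
    def test_identity(self):
        assert ps.pi_ratio([1e-4], [1e-4])[0] == pytest.approx(1.0)

    def test_zero_domestic_diversity_is_inf(self):
        assert ps.pi_ratio([0.0], [1e-4])[0] == np.inf

    def test_zero_over_zero_invalid(self):
        assert np.isnan(ps.pi_ratio([0.0], [0.0])[0])

    def test_sweep_windows_have_elevated_ratio(self, small_cohort,
                                               small_config):
        g, truth = small_cohort
        grid = ps.make_windows(small_config.chrom_lengths)
        stats = ps.window_statistics(g, grid)
        chrom, s, e = truth.sweep_intervals[0]
        inside = (stats["start"] >= s) & (stats["end"] <= e) & stats["valid"]
        outside = stats["valid"] & ~inside
        assert (np.median(stats.loc[inside, "pi_ratio"])
                > np.median(stats.loc[outside, "pi_ratio"]))


class TestInvariances:
    @pytest.fixture()
    def random_matrix(self):
        rng = np.random.default_rng(9)
        d = rng.integers(-1, 3, size=(12, 100)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 200_000), 100, replace=False))
        return make_matrix(d, positions=pos)

    def test_sample_permutation(self, random_matrix):
        g = random_matrix
        grid = ps.make_windows({"chr1": 200_000})
        base = ps.window_statistics(g, grid, "pop1", "pop2", min_snvs=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_samples)
        shuffled = g.take_samples(perm)
        out = ps.window_statistics(shuffled, grid, "pop1", "pop2", min_snvs=1)
        for col in ("pi_pop1", "pi_pop2", "fst"):
            np.testing.assert_allclose(out[col], base[col], atol=1e-12)

    def test_ref_alt_relabel(self, random_matrix):
        g = random_matrix
        flipped_d = g.dosages.copy()
        called = flipped_d != MISSING
        flipped_d[called] = 2 - flipped_d[called]
        flipped = make_matrix(flipped_d, positions=g.sites["pos"],
                              populations=list(g.populations),
                              ref=list(g.sites["alt"]),
                              alt=list(g.sites["ref"]))
        grid = ps.make_windows({"chr1": 200_000})
        base = ps.window_statistics(g, grid, "pop1", "pop2", min_snvs=1)
        out = ps.window_statistics(flipped, grid, "pop1", "pop2", min_snvs=1)
        for col in ("pi_pop1", "pi_pop2", "fst"):
            np.testing.assert_allclose(out[col], base[col], atol=1e-12)
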