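"""Spearman correlation, LOESS, and the two sampling-effect analyses."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from barcodegap.gap_analysis import SpeciesGapSummary
from barcodegap.sampling_stats import (
    ResamplingDesign,
    divergence_vs_sample_size,
    loess_fit,
    spearman_correlation,
    species_resampling_experiment,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1)
        assert spearman_correlation([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1)

    def test_ties_use_average_ranks(self):
        # ranks x = (1, 2.5, 2.5, 4), y = (1, 3, 2, 4): Pearson = 0.948683
        r = spearman_correlation([1, 2, 2, 4], [1, 3, 2, 4])
        assert r.rho == pytest.approx(0.9486832980505138)
        assert r.rho == pytest.approx(
            sps.spearmanr([1, 2, 2, 4], [1, 3, 2, 4]).statistic
        )

    def test_exact_permutation_p_small_n(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        r = spearman_correlation(x, y)
        # brute-force oracle over all 5! permutations
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        assert r.p_value == pytest.approx(hits / total)

    def test_large_n_matches_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r = spearman_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_flagged_undefined(self):
        r = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert r.undefined and math.isnan(r.rho)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [1, 2])


class TestLoess:
    def test_linear_data_fit_exactly(self):
        x = np.arange(12.0)
        y = 3.0 * x - 2.0
        for span in (0.4, 0.75, 1.0):
            fit = loess_fit(x, y, span=span, degree=1)
            assert np.allclose(fit.fitted, 3.0 * fit.x - 2.0, atol=1e-9)
            assert np.allclose(fit.ci_halfwidth, 0.0, atol=1e-7)

    def test_constant_y_zero_ci(self):
        fit = loess_fit(np.arange(10.0), np.full(10, 5.0), degree=2)
        assert np.allclose(fit.fitted, 5.0)
        assert np.allclose(fit.ci_halfwidth, 0.0, atol=1e-12)

    def test_span_one_degree_one_matches_global_weighted_ls(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 10))
        y = np.sin(x) + rng.normal(0, 0.2, 10)
        fit = loess_fit(x, y, span=1.0, degree=1, eval_x=x)
        for x0, got in zip(x, fit.fitted):
            d = np.abs(x - x0)
            w = (1 - (d / d.max()) ** 3) ** 3
            X = np.vstack([np.ones_like(x), x - x0]).T
            beta = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                   y * np.sqrt(w), rcond=None)[0]
            assert got == pytest.approx(beta[0], abs=1e-9)

    def test_degree_one_matches_statsmodels_lowess(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 30))
        y = np.sin(x) + rng.normal(0, 0.1, 30)
        fit = loess_fit(x, y, span=0.6, degree=1, eval_x=x)
        ref = lowess(y, x, frac=0.6, it=0, delta=0.0, return_sorted=False)
        assert np.allclose(fit.fitted, ref, atol=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            loess_fit([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            loess_fit([1.0, 2.0], [1.0, 2.0], degree=2)


def _summary(species, n, max_intra, nn=0.1):
    return SpeciesGapSummary(
        species=species, n_specimens=n, n_haplotypes=min(n, 2),
        max_intra=max_intra if n > 1 else None,
        mean_intra=max_intra if n > 1 else None,
        nn_distance=nn, nn_species="other",
    )


class TestDivergenceVsSampleSize:
    def test_drops_singletons_and_exclusions(self):
        summaries = [
            _summary("A", 5, 0.004), _summary("B", 3, 0.002),
            _summary("C", 2, 0.001), _summary("D", 1, None),
            _summary("E", 1, None), _summary("F", 4, 0.003),
        ]
        df, corr, fit = divergence_vs_sample_size(summaries)
        assert len(df) == 4
        df2, *_ = divergence_vs_sample_size(summaries, exclusions=["F"])
        assert "F" not in set(df2["species"])

    def test_constant_divergence_flags_rho_undefined(self):
        summaries = [_summary(s, n, 0.005) for s, n in
                     zip("ABCD", (2, 3, 4, 5))]
        _, corr, _ = divergence_vs_sample_size(summaries)
        assert corr.undefined

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError, match="species"):
            divergence_vs_sample_size([_summary("A", 2, 0.1)])


@pytest.fixture(scope="module")
def resampling_library():
    from barcodegap.distances import build_distance_matrix
    from barcodegap.synthetic_data import SimulationConfig, simulate_library

    library, _ = simulate_library(SimulationConfig(n_species=60, seed=5))
    return library, build_distance_matrix(library)


class TestResamplingExperiment:
    def test_row_count_is_sizes_times_replicates(self, resampling_library):
        library, matrix = resampling_library
        design = ResamplingDesign(subset_sizes=(10, 20, 30), replicates=4, seed=9)
        result, corr, fit = species_resampling_experiment(
            library, design, matrix=matrix)
        assert len(result) == 12
        assert (result["min_nn"] <= result["mean_nn"] + 1e-15).all()

    def test_deterministic_for_fixed_seed(self, resampling_library):
        library, matrix = resampling_library
        design = ResamplingDesign(subset_sizes=(10, 25), replicates=3, seed=4)
        a, *_ = species_resampling_experiment(library, design, matrix=matrix)
        b, *_ = species_resampling_experiment(library, design, matrix=matrix)
        assert a.to_csv() == b.to_csv()

    def test_nested_min_nn_monotone_nonincreasing(self, resampling_library):
        library, matrix = resampling_library
        design = ResamplingDesign(subset_sizes=(10, 20, 30, 40, 50),
                                  replicates=3, seed=2, nested=True)
        result, *_ = species_resampling_experiment(library, design, matrix=matrix)
        for _, grp in result.sort_values("subset_size").groupby("replicate"):
            assert (grp["min_nn"].diff().dropna() <= 1e-15).all()

    def test_full_coverage_equals_full_library_mean(self, resampling_library):
        from barcodegap.gap_analysis import species_gap_summary

        library, matrix = resampling_library
        n_species = len(library.species_names)
        design = ResamplingDesign(subset_sizes=(n_species,), replicates=3, seed=1)
        result, *_ = species_resampling_experiment(library, design, matrix=matrix)
        full = np.mean([s.nn_distance
                        for s in species_gap_summary(matrix, library)])
        assert np.allclose(result["mean_nn"], full)
        # replicates collapse: identical species set every draw
        assert result["mean_nn"].max() - result["mean_nn"].min() < 1e-12

    def test_insufficient_species_raises(self, resampling_library):
        library, matrix = resampling_library
        with pytest.raises(ValueError, match="found"):
            species_resampling_experiment(
                library, ResamplingDesign(subset_sizes=(1000,)), matrix=matrix)
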