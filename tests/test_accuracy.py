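import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pooledseq.accuracy import (
    AccuracyReport,
    ResampleDesign,
    accuracy_experiment,
    bin_index,
    binned_resample,
    binomial_expectation,
    lin_ccc,
    relative_error,
    write_accuracy_report,
)
from pooledseq.pool_freq import FrequencyTable
from pooledseq.synthetic_data import PoissonDepth, sample_depths


def brute_force_ccc(x, y):
    """Independent oracle: Pearson r scaled by the location/scale penalty."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r, _ = stats.pearsonr(x, y)
    sx = x.std()  # population (1/n)
    sy = y.std()
    cb = 2 * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2)
    return r * cb


finite_vectors = st.integers(2, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n),
    )
)


class TestLinCcc:
    def test_perfect_agreement(self):
        assert lin_ccc([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 1.0

    def test_shifted_example(self):
        # oracle: 2*0.106667/(0.106667+0.106667+0.01)
        got = lin_ccc([0.1, 0.5, 0.9], [0.2, 0.6, 1.0])
        expected = 2 * (0.32 / 3) / (2 * 0.32 / 3 + 0.01)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.9552238805970149, abs=1e-9)

    def test_perfect_reversal(self):
        assert lin_ccc([0.0, 1.0], [1.0, 0.0]) == -1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lin_ccc([1, 2], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0], [1.0])

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lin_ccc([2.0, 2.0], [2.0, 2.0])

    def test_one_constant_is_zero(self):
        assert lin_ccc([1.0, 1.0, 1.0], [0.0, 0.5, 1.0]) == 0.0

    def test_matches_brute_force_on_1000_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(2, 50)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            assert lin_ccc(x, y) == pytest.approx(brute_force_ccc(x, y), abs=1e-12)

    def test_never_exceeds_abs_pearson(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x = rng.uniform(size=n)
            y = rng.uniform(size=n)
            r, _ = stats.pearsonr(x, y)
            assert lin_ccc(x, y) <= abs(r) + 1e-12

    @given(finite_vectors)
    @settings(max_examples=200, deadline=None)
    def test_property_bounded_and_below_pearson(self, xy):
        x, y = np.array(xy[0]), np.array(xy[1])
        if x.std() == 0 and y.std() == 0:
            return
        c = lin_ccc(x, y)
        assert -1.0 <= c <= 1.0
        if x.std() > 1e-9 and y.std() > 1e-9:
            r, _ = stats.pearsonr(x, y)
            if not math.isnan(r):
                assert c <= abs(r) + 1e-9


class TestRelativeError:
    def test_perfect_estimate(self):
        per, mean = relative_error([0.1, 0.4], [0.1, 0.4])
        assert (per == 0).all() and mean == 0

    def test_printed_formula(self):
        per, mean = relative_error([0.25], [0.20])
        assert per[0] == pytest.approx(0.0625)
        assert mean == pytest.approx(0.0625)

    def test_zero_truth_names_site(self):
        with pytest.raises(ValueError, match="siteB"):
            relative_error([0.1, 0.2], [0.5, 0.0], site_ids=["siteA", "siteB"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            relative_error([0.1], [0.1, 0.2])


class TestResampleDesign:
    def test_default_covers_unit_interval(self):
        d = ResampleDesign()
        assert d.n_bins * d.bin_width == pytest.approx(1.0, abs=1e-12)
        assert d.sites_per_rep == 1000

    def test_inconsistent_design_rejected(self):
        with pytest.raises(ValueError):
            ResampleDesign(n_bins=20, bin_width=0.04)

    def test_bin_index_last_bin_closed(self):
        d = ResampleDesign()
        assert bin_index([1.0], d)[0] == 19
        assert bin_index([0.0], d)[0] == 0
        assert bin_index([0.05], d)[0] == 1  # half-open [low, high)


class TestBinnedResample:
    def test_default_design_yields_1000(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(size=100_000)
        idx = binned_resample(truth, seed=1)
        assert idx.shape[0] == 1000
        assert np.unique(idx).shape[0] == 1000  # without replacement
        counts = np.bincount(bin_index(truth[idx], ResampleDesign()), minlength=20)
        assert (counts == 50).all()

    def test_all_in_one_bin_errors(self):
        truth = np.full(5000, 0.42)
        with pytest.raises(ValueError, match="bins"):
            binned_resample(truth, seed=0)

    def test_forced_full_sample(self):
        truth = np.arange(20) * 0.05 + 0.025
        idx = binned_resample(truth, ResampleDesign(per_bin=1), seed=0)
        assert sorted(idx) == list(range(20))

    def test_short_bins_error_by_default(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(size=300)  # ~15 per bin < 50
        with pytest.raises(ValueError, match="allow_short_bins"):
            binned_resample(truth, seed=0)

    def test_short_bins_downscale_when_allowed(self, caplog):
        rng = np.random.default_rng(3)
        truth = rng.uniform(size=400)
        import logging

        with caplog.at_level(logging.WARNING, logger="pooledseq.accuracy"):
            idx = binned_resample(truth, seed=0, allow_short_bins=True)
        assert "downscaling" in caplog.text
        occ = np.bincount(bin_index(truth, ResampleDesign()), minlength=20)
        assert idx.shape[0] == 20 * occ.min()


class TestBinomialExpectation:
    def test_boundaries_exact(self):
        truth = np.array([0.0, 1.0])
        depths = np.array([17, 23])
        sim = binomial_expectation(truth, depths, seed=0)
        np.testing.assert_array_equal(sim, [0.0, 1.0])

    def test_variance_matches_binomial(self):
        # oracle: Var = p(1-p)/d
        n = 100_000
        sim = binomial_expectation(np.full(n, 0.5), np.full(n, 20), seed=1)
        assert abs(sim.var() - 0.0125) < 0.05 * 0.0125

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            binomial_expectation([0.5], [0], seed=0)


def _uniform_table(n_sites, depth_mean, seed, noisy=True):
    rng = np.random.default_rng(seed)
    truth = rng.uniform(size=n_sites)
    depth = sample_depths(PoissonDepth(depth_mean), n_sites, min_depth=10, seed=rng)
    est = rng.binomial(depth, truth) / depth if noisy else truth.copy()
    return FrequencyTable(
        site_ids=np.arange(n_sites).astype(str),
        est_freq=est,
        depth=depth,
        truth_freq=truth,
        library_id=f"u{depth_mean}",
    )


class TestAccuracyExperiment:
    def test_perfect_estimator(self):
        table = _uniform_table(30_000, 20, seed=5, noisy=False)
        rep = accuracy_experiment(table, n_reps=5, seed=1)
        np.testing.assert_array_equal(rep.observed_ccc, np.ones(5))
        np.testing.assert_array_equal(rep.observed_relerr, np.zeros(5))

    def test_observed_overlaps_expected_for_binomial_estimates(self):
        # the estimates ARE binomial draws, so observed and expected ranges overlap
        table = _uniform_table(50_000, 40, seed=6)
        rep = accuracy_experiment(table, n_reps=20, seed=2)
        olo, ohi = rep.range("observed_ccc")
        elo, ehi = rep.range("expected_ccc")
        assert olo <= ehi and elo <= ohi

    def test_replicate_mode_lower_than_vs_truth(self):
        # two-noisy concordance 2V/(2V+2c) < one-noisy 2V/(2V+c)
        t1 = _uniform_table(50_000, 20, seed=7)
        rng = np.random.default_rng(8)
        est2 = rng.binomial(t1.depth, t1.truth_freq) / t1.depth
        t2 = FrequencyTable(
            site_ids=t1.site_ids, est_freq=est2, depth=t1.depth,
            truth_freq=t1.truth_freq, library_id="u20b",
        )
        vs = accuracy_experiment(t1, mode="vs_truth", n_reps=20, seed=3)
        rep = accuracy_experiment(t1, mode="replicate", est_table_2=t2, n_reps=20, seed=3)
        assert rep.expected_ccc.mean() < vs.expected_ccc.mean()
        assert rep.observed_ccc.mean() < vs.observed_ccc.mean()

    def test_expected_ccc_monotone_in_depth(self):
        means = {}
        for depth in (10, 20, 40):
            table = _uniform_table(10_000, depth, seed=11)
            rep = accuracy_experiment(table, n_reps=20, seed=4)
            means[depth] = rep.expected_ccc.mean()
        assert means[40] > means[20] > means[10]

    @pytest.mark.parametrize("d", [20, 40])
    def test_constant_depth_closed_form(self, d):
        # analytic oracle: CCC -> 2 Var(p) / (2 Var(p) + E[p(1-p)]/d)
        # with p ~ Uniform(0,1): Var(p)=1/12, E[p(1-p)]=1/6
        rng = np.random.default_rng(d)
        n = 50_000
        truth = rng.uniform(size=n)
        depth = np.full(n, d)
        est = rng.binomial(depth, truth) / depth
        table = FrequencyTable(
            site_ids=np.arange(n).astype(str), est_freq=est, depth=depth, truth_freq=truth
        )
        rep = accuracy_experiment(table, n_reps=20, seed=5)
        analytic = 2 * (1 / 12) / (2 * (1 / 12) + (1 / 6) / d)
        assert abs(rep.expected_ccc.mean() - analytic) < 0.005

    def test_missing_truth_rejected(self):
        t = FrequencyTable(
            site_ids=np.array(["a", "b"]), est_freq=np.array([0.1, 0.2]),
            depth=np.array([20, 20]),
        )
        with pytest.raises(ValueError, match="truth"):
            accuracy_experiment(t)

    def test_replicate_needs_matching_sites(self):
        t1 = _uniform_table(2000, 20, seed=1)
        t2 = _uniform_table(1000, 20, seed=2)
        with pytest.raises(ValueError, match="site set"):
            accuracy_experiment(t1, mode="replicate", est_table_2=t2, n_reps=2, seed=0)

    def test_deterministic_for_seed(self):
        table = _uniform_table(30_000, 20, seed=9)
        a = accuracy_experiment(table, n_reps=5, seed=77)
        b = accuracy_experiment(table, n_reps=5, seed=77)
        np.testing.assert_array_equal(a.observed_ccc, b.observed_ccc)
        np.testing.assert_array_equal(a.expected_ccc, b.expected_ccc)


class TestAccuracyReport:
    def test_range_over_exactly_n_reps(self):
        table = _uniform_table(30_000, 20, seed=10)
        rep = accuracy_experiment(table, n_reps=7, seed=6)
        assert rep.observed_ccc.shape[0] == 7
        lo, hi = rep.range("observed_ccc")
        assert lo == rep.observed_ccc.min() and hi == rep.observed_ccc.max()
        assert ((rep.observed_ccc >= -1) & (rep.observed_ccc <= 1)).all()
        assert (rep.observed_relerr >= 0).all()

    def test_writer_roundtrip_shape(self, tmp_path):
        table = _uniform_table(30_000, 20, seed=10)
        rep = accuracy_experiment(table, n_reps=4, seed=6)
        path = tmp_path / "acc.tsv"
        write_accuracy_report(rep, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 + 4 + 1  # header, reps, range row
        assert lines[0].split("\t")[1] == "observed_ccc"
        assert lines[-1].startswith("range")

    def test_invalid_ccc_rejected(self):
        with pytest.raises(ValueError):
            AccuracyReport(
                mode="vs_truth", n_reps=1, design=ResampleDesign(),
                observed_ccc=np.array([1.5]), expected_ccc=np.array([0.5]),
                observed_relerr=np.array([0.0]), expected_relerr=np.array([0.0]),
            )
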