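"""Coalescent engine: calibration, demography, reproducibility and the
null-distribution / percentile machinery."""

import math

import numpy as np
import pytest

from standscan import stats as st
from standscan.coalescent import (
    DemographicModel,
    NullDistribution,
    SimParams,
    child_seed,
    neutrality_test,
    null_distribution,
    null_table,
    percentile,
    simulate_sample,
    write_ms,
)

CONSTANT = DemographicModel("constant")


def simulate_many(params, model, reps, seed=0):
    out = []
    for i in range(reps):
        rng = np.random.default_rng(child_seed(seed, i))
        out.append(simulate_sample(params, model, rng))
    return out


class TestModelValidation:
    def test_unknown_model(self):
        with pytest.raises(ValueError):
            DemographicModel("weird")

    def test_bottleneck_requires_parameters(self):
        with pytest.raises(ValueError):
            DemographicModel("bottleneck", t0=1600)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            SimParams(n=10, L=100, theta_per_bp=-1, rho_per_bp=0)
        with pytest.raises(ValueError):
            SimParams(n=10, L=100, theta_per_bp=math.inf, rho_per_bp=0)


class TestCalibration:
    """Moments of S and pi under the constant-size model (closed forms)."""

    def test_mean_s_and_pi(self):
        params = SimParams(n=20, L=5000, theta_per_bp=2e-3, rho_per_bp=1e-3, seed=11)
        theta = params.theta_per_bp * params.L
        a1 = st.tajima_constants(params.n).a1
        Ss, pis = [], []
        for h in simulate_many(params, CONSTANT, 1500, seed=11):
            Ss.append(st.segregating_sites(h))
            pis.append(st.pairwise_diversity_total(h))
        se_s = np.std(Ss, ddof=1) / math.sqrt(len(Ss))
        se_pi = np.std(pis, ddof=1) / math.sqrt(len(pis))
        assert np.mean(Ss) == pytest.approx(theta * a1, abs=3 * se_s)
        assert np.mean(pis) == pytest.approx(theta, abs=3 * se_pi)

    def test_variance_of_s_without_recombination(self):
        # Watterson: Var(S) = a1*theta + a2*theta^2
        params = SimParams(n=10, L=2000, theta_per_bp=2.5e-3, rho_per_bp=0, seed=13)
        theta = params.theta_per_bp * params.L
        k = st.tajima_constants(params.n)
        Ss = [st.segregating_sites(h) for h in simulate_many(params, CONSTANT, 4000, 13)]
        expected = k.a1 * theta + k.a2 * theta**2
        var = np.var(Ss, ddof=1)
        # SE of a variance estimate ~ var * sqrt(2/(n-1)) for normal-ish data;
        # S is overdispersed, so allow a generous 10% band
        assert var == pytest.approx(expected, rel=0.10)

    def test_site_frequency_spectrum_shape(self):
        # E[# derived-count-i sites] proportional to 1/i under neutrality
        params = SimParams(n=12, L=5000, theta_per_bp=2e-3, rho_per_bp=1e-3, seed=17)
        counts = np.zeros(params.n)
        for h in simulate_many(params, CONSTANT, 800, 17):
            c = h.derived_counts()
            for v in c[(c > 0) & (c < params.n)]:
                counts[v] += 1
        observed = counts[1 : params.n]
        expected = 1.0 / np.arange(1, params.n)
        expected = expected / expected.sum() * observed.sum()
        # chi-square goodness of fit, crude 99.9% bound
        chi2 = ((observed - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist.ppf(0.999, df=params.n - 2)

    def test_recombination_reduces_pi_variance(self):
        variances = []
        for rho in (0.0, 5e-4, 5e-3):
            params = SimParams(n=12, L=4000, theta_per_bp=2e-3, rho_per_bp=rho, seed=19)
            pis = [
                st.pairwise_diversity_total(h)
                for h in simulate_many(params, CONSTANT, 1500, seed=19)
            ]
            variances.append(np.var(pis, ddof=1))
        assert variances[0] > variances[1] > variances[2]


class TestFixedS:
    def test_exact_site_count(self, rng):
        params = SimParams(
            n=10, L=2000, theta_per_bp=1e-3, rho_per_bp=1e-3, seed=3, fixed_s=25
        )
        h = simulate_sample(params, CONSTANT, rng)
        assert h.n_site == 25
        assert st.segregating_sites(h) == 25

    def test_conditional_mean_pi(self):
        # E[pi | S] = S/a1 under constant size
        S = 30
        params = SimParams(
            n=16, L=3000, theta_per_bp=1e-3, rho_per_bp=1e-3, seed=5, fixed_s=S
        )
        pis = [
            st.pairwise_diversity_total(h)
            for h in simulate_many(params, CONSTANT, 1200, seed=5)
        ]
        a1 = st.tajima_constants(16).a1
        se = np.std(pis, ddof=1) / math.sqrt(len(pis))
        assert np.mean(pis) == pytest.approx(S / a1, abs=3.5 * se)


class TestDemography:
    def test_expansion_shifts_spectrum_to_rare_variants(self):
        # a strong recent expansion makes genealogies star-like: pi | S drops
        S = 30
        base = dict(n=20, L=3000, theta_per_bp=1e-3, rho_per_bp=0.0, fixed_s=S)
        pis = {}
        for name, model in (
            ("constant", CONSTANT),
            ("expansion", DemographicModel("recent_expansion", N0=1e4, N1=1e7, t=1000)),
        ):
            params = SimParams(seed=23, **base)
            pis[name] = np.mean(
                [
                    st.pairwise_diversity_total(h)
                    for h in simulate_many(params, model, 500, seed=23)
                ]
            )
        assert pis["expansion"] < pis["constant"]

    def test_bottleneck_and_structure_run(self, rng):
        for model in (
            DemographicModel("bottleneck", N0=1e4, t0=1600, t1=1200, b=0.1),
            DemographicModel("structure", N0=1e4, npop=2, m=1.0),
            DemographicModel("twofold_growth", N0=1e4, t=1000),
        ):
            params = SimParams(n=8, L=2000, theta_per_bp=1e-3, rho_per_bp=1e-3, seed=2)
            h = simulate_sample(params, model, rng)
            assert h.n_hap == 8

    def test_structure_inflates_intermediate_frequencies(self):
        # two weakly connected demes push Tajima's D upward
        base = dict(n=20, L=3000, theta_per_bp=1e-3, rho_per_bp=0.0, fixed_s=30)
        means = {}
        for name, model in (
            ("constant", CONSTANT),
            ("structure", DemographicModel("structure", N0=1e4, npop=2, m=0.5)),
        ):
            params = SimParams(seed=29, **base)
            ds = []
            for h in simulate_many(params, model, 400, seed=29):
                s = st.summarize(h, params.L)
                if not math.isnan(s.tajima_d):
                    ds.append(s.tajima_d)
            means[name] = np.mean(ds)
        assert means["structure"] > means["constant"]


class TestReproducibility:
    def test_identical_seeds_identical_distributions(self):
        params = SimParams(n=10, L=2000, theta_per_bp=1e-3, rho_per_bp=1e-3,
                           reps=120, seed=42)
        nd1 = null_distribution(params, CONSTANT, "S")
        nd2 = null_distribution(params, CONSTANT, "S")
        assert np.array_equal(nd1.values, nd2.values)

    def test_different_seeds_differ(self):
        base = dict(n=10, L=2000, theta_per_bp=1e-3, rho_per_bp=1e-3, reps=120)
        nd1 = null_distribution(SimParams(seed=1, **base), CONSTANT, "S")
        nd2 = null_distribution(SimParams(seed=2, **base), CONSTANT, "S")
        assert not np.array_equal(nd1.values, nd2.values)


class TestPercentile:
    def test_linear_interpolation_convention(self):
        nd = NullDistribution("S", np.arange(1.0, 101.0), 100, "x")
        assert percentile(nd, 97.5) == pytest.approx(97.525)

    def test_median_of_symmetric_set(self):
        nd = NullDistribution("S", np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 5, "x")
        assert percentile(nd, 50) == 3.0

    def test_matches_sort_and_index_oracle(self, rng):
        v = rng.normal(size=501)
        nd = NullDistribution("S", v, 501, "x")
        q = 97.5
        # brute force: sorted values, fractional index h = (n-1)*q/100
        sv = np.sort(v)
        hidx = (len(sv) - 1) * q / 100
        lo = int(math.floor(hidx))
        expected = sv[lo] + (hidx - lo) * (sv[lo + 1] - sv[lo])
        assert percentile(nd, q) == pytest.approx(expected)

    def test_bounds(self):
        nd = NullDistribution("S", np.array([1.0]), 1, "x")
        with pytest.raises(ValueError):
            percentile(nd, 0)
        with pytest.raises(ValueError):
            percentile(nd, 100)


class TestNeutralityTest:
    def test_observed_above_all(self):
        nd = NullDistribution("pi_per_bp", np.arange(100.0), 100, "x")
        p, flag = neutrality_test(1000.0, nd, "pi_per_bp")
        assert p == pytest.approx(1 / 101)
        assert flag

    def test_observed_at_median(self):
        nd = NullDistribution("pi_per_bp", np.arange(101.0), 101, "x")
        p, flag = neutrality_test(50.0, nd, "pi_per_bp")
        assert p == pytest.approx(0.5, abs=0.02)
        assert not flag

    def test_statistic_mismatch(self):
        nd = NullDistribution("pi_per_bp", np.arange(100.0), 100, "x")
        with pytest.raises(ValueError, match="mismatch"):
            neutrality_test(1.0, nd, "tajima_d")

    def test_flag_consistent_with_percentile(self, rng):
        v = rng.normal(size=400)
        nd = NullDistribution("tajima_d", v, 400, "x")
        cut = percentile(nd, 97.5)
        for obs in (cut - 0.01, cut + 0.01):
            _, flag = neutrality_test(obs, nd, "tajima_d")
            assert flag == (obs > cut)


class TestNullDistribution:
    def test_excluded_replicates_accounted(self):
        # tiny theta: many replicates have S=0 and drop from the D null
        params = SimParams(n=6, L=100, theta_per_bp=2e-3, rho_per_bp=0,
                           reps=150, seed=7)
        nd = null_distribution(params, CONSTANT, "tajima_d")
        assert len(nd.values) + nd.n_excluded == params.reps
        assert nd.n_excluded > 0

    def test_null_table_matches_null_distribution(self):
        params = SimParams(n=8, L=1000, theta_per_bp=1e-3, rho_per_bp=0,
                           reps=120, seed=31)
        tab = null_table(params, CONSTANT)
        nd = null_distribution(params, CONSTANT, "S")
        assert np.array_equal(np.sort(tab["S"].to_numpy(float)), nd.values)


def test_ms_output_format(tmp_path, rng):
    params = SimParams(n=4, L=1000, theta_per_bp=1e-3, rho_per_bp=0, seed=3)
    samples = [simulate_sample(params, CONSTANT, rng) for _ in range(2)]
    out = tmp_path / "out.ms"
    with open(out, "w") as fh:
        write_ms(samples, params.L, fh)
    text = out.read_text()
    assert text.count("//") == 2
    assert "segsites:" in text


def test_cross_validation_against_msprime():
    """S distribution indistinguishable from msprime at matched parameters."""
    msprime = pytest.importorskip("msprime")
    from scipy.stats import ks_2samp

    n, L, theta_bp, rho_bp = 20, 10_000, 1e-3, 5e-4
    N0 = 1e4
    params = SimParams(n=n, L=L, theta_per_bp=theta_bp, rho_per_bp=rho_bp, seed=101)
    ours = [
        st.segregating_sites(h)
        for h in simulate_many(params, CONSTANT, 600, seed=101)
    ]
    mu = theta_bp / (4 * N0)
    r = rho_bp / (4 * N0)
    theirs = []
    reps = msprime.sim_ancestry(
        samples=n // 2, ploidy=2, sequence_length=L, population_size=N0,
        recombination_rate=r, gene_conversion_rate=2 * r,
        gene_conversion_tract_length=500, num_replicates=600, random_seed=55,
    )
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=mu, discrete_genome=False,
                                    random_seed=1000 + i)
        theirs.append(mts.num_sites)
    assert ks_2samp(ours, theirs).pvalue > 0.01
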