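"""Bootstrap, likelihood, permutation, heterogeneity and pooling inference."""

import math

import numpy as np
import pytest
from scipy import stats

from rcpmeth.core import DyadFrequencies, rcp
from rcpmeth.errors import ConversionRates
from rcpmeth.inference import (
    PoolingError,
    bootstrap_distribution,
    bootstrap_rcp,
    heterogeneity_test,
    likelihood_ci,
    mlct,
    permutation_test,
    pool_replicates,
)
from rcpmeth.inference import test_rcp_vs_null as rcp_vs_null
from rcpmeth.patterns import DyadCounts
from rcpmeth.simulate import SimulationConfig, simulate_reads

from conftest import make_read

NO_ERR = ConversionRates()


def single_dyad_reads(n_full, n_hemi, n_unmeth):
    reads = []
    for state, n in (("F", n_full), ("T", n_hemi), ("U", n_unmeth)):
        for i in range(n):
            reads.append(
                make_read(state, read_id=f"{state}{i}", barcode=f"{state}{i}")
            )
    return reads


def naive_bca_oracle(theta_boot, theta_hat, theta_jack, level):
    """Straight-from-the-textbook BCa interval over a given resample stream."""
    tb = np.sort(theta_boot[~np.isnan(theta_boot)])
    B = len(tb)
    frac = np.sum(tb < theta_hat) / B
    frac = min(max(frac, 0.5 / B), 1 - 0.5 / B)
    z0 = stats.norm.ppf(frac)
    jack = theta_jack[np.isfinite(theta_jack)]
    d = jack.mean() - jack
    a = np.sum(d**3) / (6.0 * np.sum(d**2) ** 1.5)

    def endpoint(alpha):
        z = stats.norm.ppf(alpha)
        q = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        return tb[min(max(math.ceil(q * B) - 1, 0), B - 1)]

    al = 0.5 * (1 - level)
    return endpoint(al), endpoint(1 - al)


class TestBootstrap:
    def test_deterministic_given_seed(self, mixed_reads):
        e1 = bootstrap_rcp(mixed_reads, NO_ERR, n_boot=500, seed=7)
        e2 = bootstrap_rcp(mixed_reads, NO_ERR, n_boot=500, seed=7)
        assert e1 == e2

    def test_identical_reads_zero_width_ci(self):
        reads = [make_read("FHU".replace("H", "T"), read_id=str(i), barcode=str(i))
                 for i in range(20)]
        est = bootstrap_rcp(reads, NO_ERR, n_boot=200, seed=1)
        assert est.ci_low == est.ci_high == est.point_bc

    def test_single_dyad_reads_match_bca_oracle(self):
        reads = single_dyad_reads(200, 100, 200)
        est = bootstrap_rcp(reads, NO_ERR, n_boot=2000, level=0.95, seed=11)
        assert est.point == pytest.approx(4.0, abs=1e-12)
        assert est.ci_low < 4.0 < est.ci_high
        theta_hat, theta_boot, theta_jack = bootstrap_distribution(
            reads, NO_ERR, 2000, 11
        )
        lo, hi = naive_bca_oracle(theta_boot, theta_hat, theta_jack, 0.95)
        assert est.ci_low == pytest.approx(lo, abs=1e-3)
        assert est.ci_high == pytest.approx(hi, abs=1e-3)

    def test_point_bc_inside_ci(self):
        cfg = SimulationConfig(n_reads=200, dyads_per_read=4, m=0.4, r=5.0, seed=3)
        reads, _ = simulate_reads(cfg)
        est = bootstrap_rcp(reads, NO_ERR, n_boot=1000, seed=5)
        assert est.ci_low <= est.point_bc <= est.ci_high

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_rcp([make_read("F")], NO_ERR, n_boot=10, seed=0)


class TestNullTest:
    def test_strong_concordance_highly_significant(self):
        reads = single_dyad_reads(200, 100, 200)
        res = rcp_vs_null(reads, NO_ERR, r0=1.0, tails="one", n_boot=2000, seed=2)
        assert res.p_value < 1e-3
        assert res.statistic > 0

    def test_centered_null_gives_p_near_one(self):
        reads = single_dyad_reads(200, 100, 200)
        est = bootstrap_rcp(reads, NO_ERR, n_boot=2000, seed=2)
        res = rcp_vs_null(
            reads, NO_ERR, r0=est.point_bc, tails="two", n_boot=2000, seed=2
        )
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_null_calibration(self):
        # data simulated at RCP=1: p should exceed 0.05 in most runs
        hits = 0
        n_runs = 40
        for i in range(n_runs):
            cfg = SimulationConfig(
                n_reads=250, dyads_per_read=4, m=0.4, r=1.0, seed=900 + i
            )
            reads, _ = simulate_reads(cfg)
            res = rcp_vs_null(reads, NO_ERR, r0=1.0, tails="one",
                                   n_boot=400, seed=i)
            hits += res.p_value > 0.05
        assert hits >= 0.85 * n_runs


class TestLikelihoodCI:
    def test_binomial_counts(self):
        est = likelihood_ci(DyadCounts("s", "L", 25, 50, 25))
        assert est.point == pytest.approx(1.0, abs=1e-12)
        assert est.ci_low < 1.0 < est.ci_high

    def test_concordant_counts_exclude_one(self):
        est = likelihood_ci(DyadCounts("s", "L", 40, 20, 40))
        assert est.point == pytest.approx(4.0, abs=1e-12)
        assert est.ci_low > 1.0

    def test_matches_grid_search_oracle(self):
        counts = DyadCounts("s", "L", 40, 20, 40)
        est = likelihood_ci(counts, level=0.95)
        lo, hi = grid_oracle_ci(np.array([40.0, 20.0, 40.0]), 0.95)
        assert est.ci_low == pytest.approx(lo, abs=0.01)
        assert est.ci_high == pytest.approx(hi, abs=0.01)

    def test_zero_cell_one_sided(self):
        est = likelihood_ci(DyadCounts("s", "L", 0, 10, 10))
        assert est.point == 0.0
        assert est.ci_low == 0.0
        assert est.one_sided
        assert 0 < est.ci_high < math.inf

    def test_agrees_with_bootstrap_on_iid_dyads(self):
        cfg = SimulationConfig(n_reads=500, dyads_per_read=4, m=0.4, r=5.0,
                               rho=0.0, seed=21)
        reads, _ = simulate_reads(cfg)
        from rcpmeth.patterns import count_dyads

        counts = count_dyads(reads)
        lik = likelihood_ci(counts)
        boot = bootstrap_rcp(reads, NO_ERR, n_boot=4000, seed=8)
        assert boot.ci_low == pytest.approx(lik.ci_low, rel=0.10)
        assert boot.ci_high == pytest.approx(lik.ci_high, rel=0.10)


def grid_oracle_ci(counts, level):
    """Dense grid evaluation of the profile multinomial likelihood."""
    rs = np.linspace(1.2, 12.0, 8001)
    ms = np.linspace(0.25, 0.75, 2001)
    r2 = (rs**2)[:, None]
    mm = ms[None, :]
    a = r2 - 1.0
    b = -(2 * (1 - mm) * r2 + 2 * mm - 1)
    c = r2 * (1 - mm) ** 2
    disc = np.maximum(b * b - 4 * a * c, 0.0)
    U = (-b - np.sqrt(disc)) / (2 * a)  # smaller root is the feasible one for r>1
    M = U + 2 * mm - 1
    H = 2 * (1 - U - mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            counts[0] * np.log(M)
            + counts[1] * np.log(H)
            + counts[2] * np.log(U)
        )
    ll[~np.isfinite(ll)] = -np.inf
    profile = ll.max(axis=1)
    n = counts.sum()
    ll_max = np.sum(counts * np.log(counts / n))
    dev = 2 * (ll_max - profile)
    inside = rs[dev <= stats.chi2.ppf(level, 1)]
    return inside.min(), inside.max()


class TestMlct:
    def test_sample_against_itself(self):
        c = DyadCounts("s", "L", 40, 20, 40)
        res = mlct(c, c)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-3)

    def test_binomial_counts_fit_null_exactly(self):
        res = mlct(DyadCounts("s", "L", 25, 50, 25), r0=1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_null_mle_statistic(self):
        # H0 r=1: binomial likelihood in m, so m_hat0 = (2M + H) / (2n) = 0.5
        counts = np.array([40.0, 20.0, 40.0])
        n = counts.sum()
        m0 = (2 * counts[0] + counts[1]) / (2 * n)
        p0 = np.array([m0**2, 2 * m0 * (1 - m0), (1 - m0) ** 2])
        ll0 = np.sum(counts * np.log(p0))
        ll1 = np.sum(counts * np.log(counts / n))
        expected = 2 * (ll1 - ll0)
        res = mlct(DyadCounts("s", "L", 40, 20, 40), r0=1.0)
        assert res.statistic == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(38.55, abs=0.01)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-6)
        assert res.df == 1

    def test_two_sample_detects_difference(self):
        res = mlct(DyadCounts("a", "L", 40, 20, 40), DyadCounts("b", "L", 25, 50, 25))
        assert res.p_value < 1e-4
        assert res.df == 1

    def test_zero_cell_uses_parametric_bootstrap(self):
        res = mlct(DyadCounts("s", "L", 0, 30, 30), r0=1.0,
                   fallback_n_boot=200, seed=4)
        assert "bootstrap" in res.notes
        assert 0.0 < res.p_value <= 1.0


class TestPermutation:
    def test_identical_groups_p_one(self, mixed_reads):
        res = permutation_test(mixed_reads, list(mixed_reads), NO_ERR,
                               n_perm=200, seed=9)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        a, _ = simulate_reads(
            SimulationConfig(n_reads=50, dyads_per_read=4, m=0.4, r=2.0, seed=1)
        )
        b, _ = simulate_reads(
            SimulationConfig(n_reads=50, dyads_per_read=4, m=0.4, r=6.0, seed=2,
                             sample_id="b")
        )
        r1 = permutation_test(a, b, NO_ERR, n_perm=500, seed=13)
        r2 = permutation_test(a, b, NO_ERR, n_perm=500, seed=13)
        assert r1 == r2

    def test_detects_large_rcp_difference(self):
        a, _ = simulate_reads(
            SimulationConfig(n_reads=300, dyads_per_read=4, m=0.4, r=1.0, seed=5)
        )
        b, _ = simulate_reads(
            SimulationConfig(n_reads=300, dyads_per_read=4, m=0.4, r=8.0, seed=6,
                             sample_id="b")
        )
        res = permutation_test(a, b, NO_ERR, n_perm=1000, seed=3)
        assert res.p_value < 0.01

    def test_null_p_values_super_uniform(self):
        # permutation p-values under the null should not be anti-conservative
        ps = []
        for i in range(60):
            a, _ = simulate_reads(
                SimulationConfig(n_reads=40, dyads_per_read=4, m=0.4, r=2.0,
                                 seed=3000 + i)
            )
            b, _ = simulate_reads(
                SimulationConfig(n_reads=40, dyads_per_read=4, m=0.4, r=2.0,
                                 seed=4000 + i, sample_id="b")
            )
            ps.append(permutation_test(a, b, NO_ERR, n_perm=200, seed=i).p_value)
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.10


class TestHeterogeneityAndPooling:
    def test_identical_replicates(self):
        reps = [DyadCounts(f"s{i}", "L", 40, 20, 40) for i in range(3)]
        res = heterogeneity_test(reps)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 4

    def test_matches_scipy_g_test(self):
        reps = [DyadCounts("a", "L", 40, 20, 40), DyadCounts("b", "L", 25, 50, 25)]
        res = heterogeneity_test(reps)
        g, p, df, _ = stats.chi2_contingency(
            np.array([[40, 20, 40], [25, 50, 25]]), correction=False,
            lambda_="log-likelihood",
        )
        assert res.statistic == pytest.approx(g, abs=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        assert res.df == df == 2

    def test_pool_proportional_replicates(self):
        pooled = pool_replicates(
            [DyadCounts("a", "L", 10, 5, 10), DyadCounts("b", "L", 20, 10, 20)]
        )
        assert pooled.as_tuple() == (30, 15, 30)
        assert rcp(DyadFrequencies.from_counts(*pooled.as_tuple())) == pytest.approx(
            rcp(DyadFrequencies.from_counts(10, 5, 10))
        )

    def test_heterogeneous_pool_refused_then_forced(self):
        reps = [DyadCounts("a", "L", 40, 20, 40), DyadCounts("b", "L", 25, 50, 25)]
        with pytest.raises(PoolingError):
            pool_replicates(reps)
        pooled = pool_replicates(reps, force=True)
        assert pooled.as_tuple() == (65, 70, 65)
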