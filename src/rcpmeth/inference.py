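"""Confidence intervals and hypothesis tests for RCP.

Two inferential routes are provided, differing in what they assume about
the sampling of dyads:

* **Read-level bootstrap with BCa correction** — resamples whole reads
  (molecules), never individual dyads, so within-molecule correlation of
  dyad states is respected.  Conversion-error correction is applied inside
  every resample.  Confidence intervals and bias-corrected point estimates
  use the bias-corrected-and-accelerated (BCa) construction with the bias
  constant taken from the bootstrap distribution and the acceleration from
  a leave-one-read-out jackknife.
* **Multinomial likelihood** — treats the dyad-state tallies (M, H, U) as
  a multinomial sample of independent dyads, reparameterized to
  ``(m, RCP)``.  Profile-likelihood confidence intervals invert the
  likelihood-ratio statistic against the chi-square(1) quantile, and the
  maximum-likelihood comparison test (MLCT) compares RCP against a null
  value or between two samples.

A permutation test compares two read sets without distributional
assumptions, and a multinomial likelihood-ratio heterogeneity test gates
the pooling of replicate count tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import (
    DyadFrequencies,
    RcpUndefinedError,
    rcp,
    u_from_m_rcp,
)
from .errors import ConversionRates, apply_errors, correct_freq_array
from .patterns import DoubleStrandRead, DyadCounts

__all__ = [
    "RcpEstimate",
    "TestResult",
    "PoolingError",
    "bootstrap_rcp",
    "bootstrap_distribution",
    "test_rcp_vs_null",
    "likelihood_ci",
    "mlct",
    "permutation_test",
    "heterogeneity_test",
    "pool_replicates",
]

_EPS_M = 1e-9  # interior bound for m during profile optimization


@dataclass(frozen=True)
class RcpEstimate:
    """An RCP point estimate with a method-tagged confidence interval."""

    point: float
    point_bc: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "bootstrap_bca"
    n_boot: int = 0
    seed: int | None = None
    n_dropped: int = 0
    one_sided: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"confidence level {self.level} outside (0, 1)")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test on RCP or dyad distributions."""

    statistic: float
    p_value: float
    tails: str
    method: str
    df: int | None = None
    n_dropped: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError(f"df={self.df} must be >= 1")


class PoolingError(RuntimeError):
    """Replicates are significantly heterogeneous; pooling refused."""

    def __init__(self, test: TestResult):
        self.test = test
        super().__init__(
            f"replicates heterogeneous (G={test.statistic:.3f}, df={test.df}, "
            f"p={test.p_value:.3g}); pass force=True to pool anyway"
        )


# ---------------------------------------------------------------------------
# vectorized helpers
# ---------------------------------------------------------------------------

def _read_count_matrix(reads: Sequence[DoubleStrandRead]) -> np.ndarray:
    """(n_reads, 3) matrix of per-read (n_full, n_hemi, n_unmeth)."""
    return np.array([r.state_counts() for r in reads], dtype=float)


def _rcp_array(freqs: np.ndarray) -> np.ndarray:
    """RCP of each row of an (n, 3) frequency array; NaN where undefined."""
    freqs = np.atleast_2d(freqs)
    M, H, U = freqs[:, 0], freqs[:, 1], freqs[:, 2]
    m = M + 0.5 * H
    out = np.full(len(freqs), np.nan)
    defined = (m > 0.0) & (m < 1.0)
    inf_mask = defined & (H == 0.0)
    out[inf_mask] = np.inf
    fin = defined & (H > 0.0)
    out[fin] = 2.0 * np.sqrt(M[fin] * U[fin]) / H[fin]
    return out


def _counts_to_corrected_freqs(
    counts: np.ndarray, rates: ConversionRates
) -> np.ndarray:
    """Normalize (n, 3) count rows and apply conversion-error correction."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    freqs = counts / safe
    freqs[totals[:, 0] == 0] = np.nan
    corrected = correct_freq_array(freqs, rates)
    return corrected


def _quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Order-statistic quantile (ceil convention), safe with infinities."""
    n = len(sorted_vals)
    idx = min(max(int(math.ceil(q * n)) - 1, 0), n - 1)
    return float(sorted_vals[idx])


# ---------------------------------------------------------------------------
# read-level bootstrap
# ---------------------------------------------------------------------------

def bootstrap_distribution(
    reads: Sequence[DoubleStrandRead],
    rates: ConversionRates,
    n_boot: int,
    seed: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Plug-in RCP, bootstrap replicate RCPs, and jackknife RCPs.

    Resampling is at the read level: each bootstrap replicate draws
    ``n_reads`` reads with replacement, tallies their dyads, corrects the
    frequencies for conversion error and evaluates RCP.  Replicates with
    undefined RCP (m of 0 or 1) are returned as NaN for the caller to drop
    and count.  Jackknife values come from leave-one-read-out tallies.

    Returns ``(theta_hat, theta_boot, theta_jack)``.
    """
    if len(reads) < 2:
        raise ValueError("bootstrap requires at least 2 reads")
    R = _read_count_matrix(reads)
    total = R.sum(axis=0)
    theta_hat_arr = _rcp_array(_counts_to_corrected_freqs(total[None, :], rates))
    theta_hat = float(theta_hat_arr[0])
    if math.isnan(theta_hat):
        raise RcpUndefinedError(
            "plug-in RCP undefined: sample is completely methylated or unmethylated"
        )
    rng = np.random.default_rng(seed)
    n = len(reads)
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    boot_counts = weights @ R
    theta_boot = _rcp_array(_counts_to_corrected_freqs(boot_counts, rates))
    jack_counts = total[None, :] - R
    theta_jack = _rcp_array(_counts_to_corrected_freqs(jack_counts, rates))
    return theta_hat, theta_boot, theta_jack


def _bca_quantile_positions(
    theta_boot_valid: np.ndarray,
    theta_hat: float,
    theta_jack: np.ndarray,
    alphas: Sequence[float],
) -> list[float]:
    """BCa-adjusted quantile positions for the requested nominal alphas."""
    b = len(theta_boot_valid)
    frac_less = np.sum(theta_boot_valid < theta_hat) / b
    frac_less = min(max(frac_less, 0.5 / b), 1.0 - 0.5 / b)
    z0 = stats.norm.ppf(frac_less)
    jack = theta_jack[np.isfinite(theta_jack)]
    if len(jack) >= 2:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2)) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    positions = []
    for alpha in alphas:
        z = stats.norm.ppf(alpha)
        denom = 1.0 - a * (z0 + z)
        if denom <= 0:  # acceleration pathologically large; fall back
            adj = z0 + z
        else:
            adj = z0 + (z0 + z) / denom
        positions.append(float(stats.norm.cdf(adj)))
    return positions


def bootstrap_rcp(
    reads: Sequence[DoubleStrandRead],
    rates: ConversionRates = ConversionRates(),
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> RcpEstimate:
    """BCa bootstrap confidence interval for RCP, resampling reads.

    ``point`` is the plug-in, conversion-corrected RCP of the full sample;
    ``point_bc`` is the BCa median-adjusted estimate; the interval is the
    BCa interval at ``level``.  Fully reproducible given ``seed``.
    """
    theta_hat, theta_boot, theta_jack = bootstrap_distribution(
        reads, rates, n_boot, seed
    )
    valid = ~np.isnan(theta_boot)
    n_dropped = int(n_boot - valid.sum())
    if n_dropped == n_boot:
        raise RuntimeError("every bootstrap replicate had undefined RCP")
    if n_dropped > 0.1 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates had undefined RCP",
            RuntimeWarning,
            stacklevel=2,
        )
    tb = np.sort(theta_boot[valid])
    if tb[0] == tb[-1]:
        # degenerate resampling (e.g. all reads identical)
        val = float(tb[0])
        return RcpEstimate(
            point=theta_hat, point_bc=val, ci_low=val, ci_high=val,
            level=level, method="bootstrap_bca", n_boot=n_boot, seed=seed,
            n_dropped=n_dropped,
        )
    alpha = 0.5 * (1.0 - level)
    q_lo, q_mid, q_hi = _bca_quantile_positions(
        tb, theta_hat, theta_jack, (alpha, 0.5, 1.0 - alpha)
    )
    ci_low = _quantile(tb, q_lo)
    ci_high = _quantile(tb, q_hi)
    point_bc = min(max(_quantile(tb, q_mid), ci_low), ci_high)
    return RcpEstimate(
        point=theta_hat, point_bc=point_bc, ci_low=ci_low, ci_high=ci_high,
        level=level, method="bootstrap_bca", n_boot=n_boot, seed=seed,
        n_dropped=n_dropped,
    )


def test_rcp_vs_null(
    reads: Sequence[DoubleStrandRead],
    rates: ConversionRates = ConversionRates(),
    r0: float = 1.0,
    tails: str = "one",
    n_boot: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Bootstrap test of the observed RCP against a null value ``r0``.

    The statistic is ``log(point_bc / r0)`` divided by the bootstrap
    standard error of log-RCP; the p-value comes from the normal
    approximation on the log scale, so p-values far below the resampling
    resolution (e.g. 1e-16) remain representable.  ``tails="one"`` reports
    the tail in the direction of the observed deviation.
    """
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    if r0 <= 0:
        raise ValueError(f"null RCP r0={r0} must be positive")
    est = bootstrap_rcp(reads, rates, n_boot=n_boot, level=0.95, seed=seed)
    theta_hat, theta_boot, _ = bootstrap_distribution(reads, rates, n_boot, seed)
    lt = np.log(theta_boot[np.isfinite(theta_boot) & (theta_boot > 0)])
    if len(lt) < 2 or lt.std(ddof=1) == 0.0:
        z = math.inf if est.point_bc != r0 else 0.0
    else:
        se = float(lt.std(ddof=1))
        if est.point_bc == 0.0 or math.isinf(est.point_bc):
            z = -math.inf if est.point_bc == 0.0 else math.inf
        else:
            z = (math.log(est.point_bc) - math.log(r0)) / se
    if math.isinf(z):
        p = 0.0
    else:
        p = float(stats.norm.sf(abs(z)))
        if tails == "two":
            p = min(1.0, 2.0 * p)
    return TestResult(
        statistic=z, p_value=p, tails=tails, method="bootstrap",
    )


# ---------------------------------------------------------------------------
# multinomial likelihood (independent-dyad) inference
# ---------------------------------------------------------------------------

def _model_probs(m: float, r: float, rates: ConversionRates) -> np.ndarray:
    """Observed-space dyad-state probabilities under (m, RCP=r)."""
    U = u_from_m_rcp(m, r)
    true = DyadFrequencies(max(U + 2.0 * m - 1.0, 0.0),
                           max(2.0 * (1.0 - U - m), 0.0), U)
    obs = apply_errors(true, rates)
    return np.asarray(obs.as_tuple())


def _loglik(counts: np.ndarray, m: float, r: float, rates: ConversionRates) -> float:
    p = _model_probs(m, r, rates)
    ll = 0.0
    for n_i, p_i in zip(counts, p):
        if n_i > 0:
            if p_i <= 0.0:
                return -math.inf
            ll += n_i * math.log(p_i)
    return ll


def _profile_loglik(counts: np.ndarray, r: float, rates: ConversionRates) -> float:
    """Max over m of the multinomial log-likelihood at fixed RCP = r."""
    res = optimize.minimize_scalar(
        lambda m: -_loglik(counts, m, r, rates),
        bounds=(_EPS_M, 1.0 - _EPS_M),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return -float(res.fun)


def _saturated_fit(
    counts: np.ndarray, rates: ConversionRates
) -> tuple[float, float, float]:
    """(m_hat, r_hat, loglik_max) of the unrestricted (m, r) model."""
    phat = _counts_to_corrected_freqs(counts[None, :], rates)[0]
    freqs = DyadFrequencies(*phat)
    m_hat = freqs.m
    if m_hat <= 0.0 or m_hat >= 1.0:
        raise RcpUndefinedError(
            "RCP undefined after correction: completely methylated or "
            "unmethylated counts"
        )
    r_hat = rcp(freqs)
    ll = _loglik(counts, m_hat, r_hat if math.isfinite(r_hat) else math.inf, rates)
    if not rates.is_zero and math.isfinite(r_hat) and r_hat > 0.0:
        # clipping during correction can leave the plug-in off the optimum
        res = optimize.minimize(
            lambda t: -_loglik(
                counts,
                1.0 / (1.0 + math.exp(-t[0])),
                math.exp(t[1]),
                rates,
            ),
            x0=[math.log(m_hat / (1.0 - m_hat)), math.log(r_hat)],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        if -res.fun > ll:
            ll = -float(res.fun)
            m_hat = 1.0 / (1.0 + math.exp(-res.x[0]))
            r_hat = math.exp(res.x[1])
    return m_hat, r_hat, ll


def likelihood_ci(
    counts: DyadCounts,
    rates: ConversionRates = ConversionRates(),
    level: float = 0.95,
) -> RcpEstimate:
    """Profile-likelihood confidence interval for RCP from dyad counts.

    Assumes independent sampling of dyads: the tallies are multinomial with
    probabilities parameterized by ``(m, r)`` pushed through the
    conversion-error matrix.  The interval is
    ``{r : 2[l_max - l_profile(r)] <= chi2_1(level)}``.  A zero cell puts
    the MLE on the boundary (r of 0 or infinity) and yields a one-sided
    interval, flagged via ``one_sided``.
    """
    if counts.total < 3:
        raise ValueError("likelihood CI requires at least 3 counted dyads")
    arr = np.asarray(counts.as_tuple(), dtype=float)
    m_hat, r_hat, ll_max = _saturated_fit(arr, rates)
    threshold = float(stats.chi2.ppf(level, df=1))

    def deviance(r: float) -> float:
        return 2.0 * (ll_max - _profile_loglik(arr, r, rates))

    one_sided = r_hat == 0.0 or math.isinf(r_hat)
    # lower endpoint
    if r_hat == 0.0:
        ci_low = 0.0
    else:
        r_anchor = r_hat if math.isfinite(r_hat) else 1e6
        ci_low = 0.0
        r_lo = r_anchor
        for _ in range(60):
            r_lo /= 4.0
            if r_lo < 1e-12 or deviance(r_lo) > threshold:
                break
        if r_lo >= 1e-12 and deviance(r_lo) > threshold:
            ci_low = float(
                optimize.brentq(
                    lambda s: deviance(math.exp(s)) - threshold,
                    math.log(r_lo),
                    math.log(r_anchor),
                    xtol=1e-10,
                )
            )
            ci_low = math.exp(ci_low)
    # upper endpoint
    if math.isinf(r_hat):
        ci_high = math.inf
    else:
        r_anchor = r_hat if r_hat > 0.0 else 1e-6
        ci_high = math.inf
        r_hi = r_anchor
        for _ in range(60):
            r_hi *= 4.0
            if r_hi > 1e12 or deviance(r_hi) > threshold:
                break
        if r_hi <= 1e12 and deviance(r_hi) > threshold:
            ci_high = float(
                optimize.brentq(
                    lambda s: deviance(math.exp(s)) - threshold,
                    math.log(r_anchor),
                    math.log(r_hi),
                    xtol=1e-10,
                )
            )
            ci_high = math.exp(ci_high)
    return RcpEstimate(
        point=r_hat, point_bc=r_hat, ci_low=ci_low, ci_high=ci_high,
        level=level, method="likelihood", n_boot=0, seed=None,
        one_sided=one_sided,
        notes="one-sided: MLE on boundary" if one_sided else "",
    )


def _fit_null_one_sample(
    counts: np.ndarray, r0: float, rates: ConversionRates
) -> tuple[float, float]:
    """(m_hat0, loglik0) under H0: r = r0 with m free."""
    res = optimize.minimize_scalar(
        lambda m: -_loglik(counts, m, r0, rates),
        bounds=(_EPS_M, 1.0 - _EPS_M),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x), -float(res.fun)


def mlct(
    counts_a: DyadCounts,
    counts_b: DyadCounts | None = None,
    *,
    r0: float | None = None,
    rates_a: ConversionRates = ConversionRates(),
    rates_b: ConversionRates | None = None,
    fallback_n_boot: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Maximum-likelihood comparison test (multinomial LRT) on RCP.

    One-sample form (``r0`` given): H0 fixes ``r = r0`` with ``m`` free
    against the unrestricted ``(m, r)`` model, df = 1.  Two-sample form
    (``counts_b`` given): H0 shares one ``r`` across samples with separate
    ``m`` per sample, df = 1.  P-values come from chi-square(1); when a
    zero cell puts an MLE on the boundary the chi-square calibration is
    replaced by a parametric bootstrap (``fallback_n_boot`` simulations),
    noted in the result.
    """
    if (counts_b is None) == (r0 is None):
        raise ValueError("provide exactly one of counts_b (two-sample) or r0")
    arr_a = np.asarray(counts_a.as_tuple(), dtype=float)
    if r0 is not None:
        if r0 < 0:
            raise ValueError(f"null RCP r0={r0} must be non-negative")
        _, _, ll1 = _saturated_fit(arr_a, rates_a)
        m0, ll0 = _fit_null_one_sample(arr_a, r0, rates_a)
        statistic = max(2.0 * (ll1 - ll0), 0.0)
        boundary = 0 in counts_a.as_tuple()
        if not boundary:
            p = float(stats.chi2.sf(statistic, df=1))
            return TestResult(statistic, p, "two", "mlct", df=1)
        # parametric bootstrap under the H0 fit
        rng = np.random.default_rng(seed)
        p0 = _model_probs(m0, r0, rates_a)
        n = int(arr_a.sum())
        sims = rng.multinomial(n, p0, size=fallback_n_boot)
        exceed = 0
        for sim in sims:
            simf = sim.astype(float)
            try:
                _, _, l1 = _saturated_fit(simf, rates_a)
            except RcpUndefinedError:
                continue
            _, l0 = _fit_null_one_sample(simf, r0, rates_a)
            if max(2.0 * (l1 - l0), 0.0) >= statistic:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + fallback_n_boot)
        return TestResult(
            statistic, p, "two", "mlct", df=1,
            notes="boundary zero cell: parametric-bootstrap p-value",
        )
    # two-sample form
    assert counts_b is not None
    rates_b = rates_b if rates_b is not None else rates_a
    arr_b = np.asarray(counts_b.as_tuple(), dtype=float)
    m_a, r_a, ll_a = _saturated_fit(arr_a, rates_a)
    m_b, r_b, ll_b = _saturated_fit(arr_b, rates_b)
    ll1 = ll_a + ll_b

    def neg_shared(s: float) -> float:
        r = math.exp(s)
        return -(_profile_loglik(arr_a, r, rates_a) + _profile_loglik(arr_b, r, rates_b))

    res = optimize.minimize_scalar(
        neg_shared, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-10},
    )
    ll0 = -float(res.fun)
    statistic = max(2.0 * (ll1 - ll0), 0.0)
    boundary = 0 in counts_a.as_tuple() or 0 in counts_b.as_tuple()
    if not boundary:
        p = float(stats.chi2.sf(statistic, df=1))
        return TestResult(statistic, p, "two", "mlct", df=1)
    rng = np.random.default_rng(seed)
    r_shared = math.exp(float(res.x))
    ma0, _ = _fit_null_one_sample(arr_a, r_shared, rates_a)
    mb0, _ = _fit_null_one_sample(arr_b, r_shared, rates_b)
    pa = _model_probs(ma0, r_shared, rates_a)
    pb = _model_probs(mb0, r_shared, rates_b)
    na, nb = int(arr_a.sum()), int(arr_b.sum())
    sims_a = rng.multinomial(na, pa, size=fallback_n_boot)
    sims_b = rng.multinomial(nb, pb, size=fallback_n_boot)
    exceed = 0
    for sa, sb in zip(sims_a, sims_b):
        sa_f, sb_f = sa.astype(float), sb.astype(float)
        try:
            _, _, la = _saturated_fit(sa_f, rates_a)
            _, _, lb = _saturated_fit(sb_f, rates_b)
        except RcpUndefinedError:
            continue
        res0 = optimize.minimize_scalar(
            lambda s: -(
                _profile_loglik(sa_f, math.exp(s), rates_a)
                + _profile_loglik(sb_f, math.exp(s), rates_b)
            ),
            bounds=(-25.0, 25.0), method="bounded", options={"xatol": 1e-8},
        )
        if max(2.0 * (la + lb + float(res0.fun)), 0.0) >= statistic:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + fallback_n_boot)
    return TestResult(
        statistic, p, "two", "mlct", df=1,
        notes="boundary zero cell: parametric-bootstrap p-value",
    )


# ---------------------------------------------------------------------------
# permutation comparison of two read sets
# ---------------------------------------------------------------------------

def permutation_test(
    reads_a: Sequence[DoubleStrandRead],
    reads_b: Sequence[DoubleStrandRead],
    rates: ConversionRates = ConversionRates(),
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Two-tailed permutation test of equal RCP between two read sets.

    The statistic is ``|log rcp_a - log rcp_b|`` on conversion-corrected
    frequencies; the null distribution reshuffles read-to-group labels
    preserving group sizes.  Permutations yielding an undefined RCP in
    either group are dropped and counted.
    """
    if len(reads_a) < 2 or len(reads_b) < 2:
        raise ValueError("permutation test requires >= 2 reads per group")
    Ra = _read_count_matrix(reads_a)
    Rb = _read_count_matrix(reads_b)
    R = np.vstack([Ra, Rb])
    na, n = len(Ra), len(R)
    total = R.sum(axis=0)

    def stat_from_counts(ca: np.ndarray) -> np.ndarray:
        cb = total[None, :] - ca
        ra = _rcp_array(_counts_to_corrected_freqs(ca, rates))
        rb = _rcp_array(_counts_to_corrected_freqs(cb, rates))
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.abs(np.log(ra) - np.log(rb))
        # a zero/inf RCP on one side only is a maximal, well-defined statistic
        s[np.isnan(ra) | np.isnan(rb)] = np.nan
        both_extreme = ((ra == 0) & (rb == 0)) | (np.isinf(ra) & np.isinf(rb))
        s[both_extreme] = 0.0
        return s

    obs = float(stat_from_counts(Ra.sum(axis=0)[None, :])[0])
    if math.isnan(obs):
        raise RcpUndefinedError("observed RCP undefined in one of the groups")
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_perm)
    chunk = 512
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        idx_a = order[:, :na]
        ca = R[idx_a].sum(axis=1)
        null_stats[done : done + k] = stat_from_counts(ca)
        done += k
    valid = ~np.isnan(null_stats)
    n_dropped = int(n_perm - valid.sum())
    ns = null_stats[valid]
    if len(ns) == 0:
        raise RuntimeError("all permutations yielded undefined RCP")
    p = (1.0 + float(np.sum(ns >= obs))) / (1.0 + len(ns))
    return TestResult(
        statistic=obs, p_value=p, tails="two", method="permutation",
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# heterogeneity and pooling of replicates
# ---------------------------------------------------------------------------

def heterogeneity_test(replicates: Sequence[DyadCounts]) -> TestResult:
    """Multinomial LRT (G-test) of a shared dyad distribution across replicates.

    H0: every replicate shares one (M, H, U); H1: each replicate free.
    The statistic is ``2 * sum O * ln(O / E)`` over the k x 3 table with
    expectations from the pooled distribution, df = 2(k - 1).  Replicates
    with zero total are excluded with a warning.
    """
    reps = []
    for rep in replicates:
        if rep.total == 0:
            warnings.warn(
                f"replicate {rep.sample_id!r}/{rep.locus!r} has zero dyads; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            reps.append(rep)
    k = len(reps)
    if k < 2:
        raise ValueError("heterogeneity test requires >= 2 non-empty replicates")
    table = np.array([rep.as_tuple() for rep in reps], dtype=float)
    row_tot = table.sum(axis=1, keepdims=True)
    col_tot = table.sum(axis=0, keepdims=True)
    expected = row_tot * col_tot / table.sum()
    mask = table > 0
    g = 2.0 * float(np.sum(table[mask] * np.log(table[mask] / expected[mask])))
    g = max(g, 0.0)
    df = 2 * (k - 1)
    p = float(stats.chi2.sf(g, df=df))
    return TestResult(statistic=g, p_value=p, tails="two", method="heterogeneity", df=df)


def pool_replicates(
    replicates: Sequence[DyadCounts], force: bool = False
) -> DyadCounts:
    """Element-wise sum of replicate dyad counts, gated on homogeneity.

    If the heterogeneity test rejects at 0.05 and ``force`` is not set,
    pooling is refused with the test attached (:class:`PoolingError`).
    """
    if len(replicates) < 2:
        raise ValueError("pooling requires >= 2 replicates")
    het = heterogeneity_test(replicates)
    if het.p_value < 0.05 and not force:
        raise PoolingError(het)
    pooled = DyadCounts(
        sample_id=replicates[0].sample_id,
        locus=replicates[0].locus,
        n_full=sum(r.n_full for r in replicates),
        n_hemi=sum(r.n_hemi for r in replicates),
        n_unmeth=sum(r.n_unmeth for r in replicates),
        n_reads=sum(r.n_reads for r in replicates),
    )
    rcps = []
    try:
        for rep in replicates:
            rcps.append(rcp(DyadFrequencies.from_counts(*rep.as_tuple())))
        pooled_rcp = rcp(DyadFrequencies.from_counts(*pooled.as_tuple()))
        assert min(rcps) - 1e-9 <= pooled_rcp <= max(rcps) + 1e-9
    except RcpUndefinedError:
        pass
    return pooled
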