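"""The Ratio of Concordance Preference statistic and its configuration space.

A CpG dyad — the symmetric CpG/CpG unit on complementary DNA strands — is
fully methylated (frequency ``M``), hemimethylated (``H``) or unmethylated
(``U``).  The Ratio of Concordance Preference,

.. math::

    \\mathrm{RCP} = \\frac{2\\sqrt{MU}}{H}
                  = \\frac{\\sqrt{U(U + 2m - 1)}}{1 - U - m},

with overall methylation frequency :math:`m = M + H/2`, quantifies the
preference of the methylation system for concordant (both-or-neither) over
discordant (one-strand) dyads.  RCP equals 1 under random placement of
methyl groups (the Hardy–Weinberg configuration :math:`M=m^2`,
:math:`H=2m(1-m)`, :math:`U=(1-m)^2`), exceeds 1 for conservative
(maintenance-dominated) systems, approaches infinity under complete
concordance preference, and falls below 1 — down to 0 — for dispersive
systems that favour hemimethylation.

Because :math:`M` and :math:`H` are determined by :math:`(m, U)`, the pair
``(m, U)`` carries the full information of the dyad-frequency simplex.  In
that plane the feasible region is bounded above by the fully conservative
line ``U = 1 - m``, below by the fully dispersive boundary
``U = max(1 - 2m, 0)``, and crossed by the random (binomial) curve
``U = (1 - m)^2``; RCP is constant along contours between the boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SIMPLEX_TOL",
    "DyadFrequencies",
    "MethylationSummary",
    "MixtureComponent",
    "RcpUndefinedError",
    "rcp",
    "rcp_from_counts",
    "summary_from_freqs",
    "freqs_from_summary",
    "region_boundaries",
    "u_from_m_rcp",
    "rcp_contour",
    "mixture_freqs",
    "min_fraction_for_rcp",
]

#: Tolerance used everywhere for simplex / feasibility checks.
SIMPLEX_TOL = 1e-9


class RcpUndefinedError(ValueError):
    """RCP is undefined: the region is completely methylated or unmethylated."""


@dataclass(frozen=True)
class DyadFrequencies:
    """Frequencies of the three dyad states (a point on the 2-simplex).

    Parameters
    ----------
    M, H, U
        Frequencies of fully methylated, hemimethylated and unmethylated
        dyads.  They must be non-negative and sum to 1 within
        :data:`SIMPLEX_TOL`; frequencies within tolerance are renormalized
        on construction.
    """

    M: float
    H: float
    U: float

    def __post_init__(self) -> None:
        m, h, u = float(self.M), float(self.H), float(self.U)
        if min(m, h, u) < -SIMPLEX_TOL:
            raise ValueError(f"negative dyad frequency in ({m}, {h}, {u})")
        total = m + h + u
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"dyad frequencies sum to {total}, not 1")
        m, h, u = (max(x, 0.0) / total for x in (m, h, u))
        object.__setattr__(self, "M", m)
        object.__setattr__(self, "H", h)
        object.__setattr__(self, "U", u)

    @property
    def m(self) -> float:
        """Overall methylation frequency of CpG cytosines, ``M + H/2``."""
        return self.M + 0.5 * self.H

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.M, self.H, self.U)

    @classmethod
    def from_counts(cls, n_full: int, n_hemi: int, n_unmeth: int) -> "DyadFrequencies":
        total = n_full + n_hemi + n_unmeth
        if total < 1:
            raise ValueError("at least one counted dyad is required")
        return cls(n_full / total, n_hemi / total, n_unmeth / total)


@dataclass(frozen=True)
class MethylationSummary:
    """The ``(m, U)`` reparameterization of a dyad-frequency point.

    ``m`` is the overall frequency of methylated cytosines and ``U`` the
    frequency of unmethylated dyads; feasibility requires
    ``max(1 - 2m, 0) <= U <= 1 - m``.
    """

    m: float
    U: float


@dataclass(frozen=True)
class MixtureComponent:
    """One subpopulation in a cell-population mixture."""

    weight: float
    freqs: DyadFrequencies

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0 + SIMPLEX_TOL:
            raise ValueError(f"mixture weight {self.weight} outside [0, 1]")


def rcp(freqs: DyadFrequencies) -> float:
    """Ratio of Concordance Preference of a dyad-frequency point.

    Returns ``2*sqrt(M*U)/H``; ``+inf`` when ``H == 0`` with both
    concordant classes present, and ``0.0`` when a concordant class is
    absent but hemimethylation is not.

    Raises
    ------
    RcpUndefinedError
        If ``m`` is 0 or 1 (completely unmethylated or methylated region):
        no information about concordance preference exists there.
    """
    M, H, U = freqs.M, freqs.H, freqs.U
    m = freqs.m
    if m <= 0.0 or m >= 1.0:
        raise RcpUndefinedError(
            f"RCP is undefined at m={m:g}: completely "
            f"{'methylated' if m >= 1 else 'unmethylated'} region"
        )
    if H == 0.0:
        return math.inf
    return 2.0 * math.sqrt(M * U) / H


def rcp_from_counts(n_full: int, n_hemi: int, n_unmeth: int) -> float:
    """Plug-in RCP of raw dyad counts."""
    return rcp(DyadFrequencies.from_counts(n_full, n_hemi, n_unmeth))


def summary_from_freqs(freqs: DyadFrequencies) -> MethylationSummary:
    """Project dyad frequencies to the ``(m, U)`` plane."""
    return MethylationSummary(m=freqs.m, U=freqs.U)


def freqs_from_summary(s: MethylationSummary) -> DyadFrequencies:
    """Invert :func:`summary_from_freqs`: ``M = U + 2m - 1``, ``H = 2(1 - U - m)``.

    Points within :data:`SIMPLEX_TOL` of a boundary are clipped onto it;
    infeasible ``(m, U)`` raises a :class:`ValueError` naming the violated
    boundary.
    """
    m, U = float(s.m), float(s.U)
    lo, hi = max(1.0 - 2.0 * m, 0.0), 1.0 - m
    if U < lo - SIMPLEX_TOL:
        raise ValueError(
            f"(m={m:g}, U={U:g}) below the dispersive boundary U = max(1-2m, 0) = {lo:g}"
        )
    if U > hi + SIMPLEX_TOL:
        raise ValueError(
            f"(m={m:g}, U={U:g}) above the conservative boundary U = 1-m = {hi:g}"
        )
    U = min(max(U, lo), hi)
    M = U + 2.0 * m - 1.0
    H = 2.0 * (1.0 - U - m)
    return DyadFrequencies(max(M, 0.0), max(H, 0.0), U)


def region_boundaries(m: float) -> tuple[float, float, float]:
    """Boundary and random-curve ``U`` values at methylation frequency ``m``.

    Returns ``(U_dispersive, U_random, U_conservative)`` =
    ``(max(1-2m, 0), (1-m)^2, 1-m)``.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m={m} outside [0, 1]")
    return (max(1.0 - 2.0 * m, 0.0), (1.0 - m) ** 2, 1.0 - m)


def u_from_m_rcp(m: float, r: float) -> float:
    """The unique ``U`` on the RCP contour ``r`` at methylation frequency ``m``.

    Solves ``(r^2-1)U^2 - (2(1-m)r^2 + 2m - 1)U + r^2(1-m)^2 = 0`` for the
    root inside the feasible band ``[max(1-2m,0), 1-m]``; the equation is
    linear at ``r = 1`` (the binomial curve ``U = (1-m)^2``).
    """
    if not 0.0 < m < 1.0:
        raise ValueError(f"m={m} must lie strictly inside (0, 1)")
    if r < 0.0:
        raise ValueError(f"RCP value {r} is negative")
    lo, hi = max(1.0 - 2.0 * m, 0.0), 1.0 - m
    if math.isinf(r):
        return hi
    if r == 1.0:
        return (1.0 - m) ** 2
    r2 = r * r
    a = r2 - 1.0
    b = -(2.0 * (1.0 - m) * r2 + 2.0 * m - 1.0)
    c = r2 * (1.0 - m) ** 2
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        if disc < -1e-12:  # impossible for feasible input
            raise ArithmeticError(f"no real contour root at (m={m}, r={r})")
        disc = 0.0
    # numerically stable quadratic roots
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    roots = sorted({q / a, c / q} if q != 0.0 else {0.0, -b / a})
    feasible = [u for u in roots if lo - 1e-9 <= u <= hi + 1e-9]
    if not feasible:
        raise ArithmeticError(f"no feasible contour root at (m={m}, r={r}): {roots}")
    return min(max(feasible[0], lo), hi)


def rcp_contour(r: float, m_grid: Sequence[float]) -> list[tuple[float, float]]:
    """``(m, U)`` points of the RCP contour ``r`` over a grid of ``m``."""
    return [(float(m), u_from_m_rcp(float(m), r)) for m in m_grid]


def mixture_freqs(components: Iterable[MixtureComponent]) -> DyadFrequencies:
    """Pooled dyad frequencies of a population mixture (weights sum to 1)."""
    comps = list(components)
    if not comps:
        raise ValueError("empty mixture")
    wsum = sum(c.weight for c in comps)
    if abs(wsum - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"mixture weights sum to {wsum}, not 1")
    M = sum(c.weight * c.freqs.M for c in comps)
    H = sum(c.weight * c.freqs.H for c in comps)
    U = sum(c.weight * c.freqs.U for c in comps)
    return DyadFrequencies(M, H, U)


def min_fraction_for_rcp(
    target_r: float,
    high: DyadFrequencies,
    low: DyadFrequencies,
    tol: float = 1e-6,
) -> float:
    """Smallest fraction of the high-RCP subpopulation explaining ``target_r``.

    Answers the subpopulation-contamination question: what proportion ``w``
    of cells with dyad frequencies ``high`` must be mixed into a background
    ``low`` for the pooled RCP to reach ``target_r``?  Found by bisection to
    ``tol``; the pooled RCP must be monotone in ``w`` on the instance (it is
    for conservative-vs-random mixtures), which is verified on a coarse grid.
    """
    r_hi, r_lo = rcp(high), rcp(low)
    if not (r_hi > target_r > r_lo):
        if target_r == r_lo:
            return 0.0
        if target_r == r_hi:
            return 1.0
        raise ValueError(
            f"target RCP {target_r} not bracketed by components ({r_lo}, {r_hi})"
        )

    def pooled(w: float) -> float:
        return rcp(
            mixture_freqs(
                [MixtureComponent(w, high), MixtureComponent(1.0 - w, low)]
            )
        )

    grid = [pooled(w) for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("pooled RCP is not monotone in the mixing fraction")

    a, b = 0.0, 1.0
    while b - a > tol:
        mid = 0.5 * (a + b)
        if pooled(mid) >= target_r:
            b = mid
        else:
            a = mid
    return b
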