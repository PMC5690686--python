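"""Bisulfite conversion-error model for double-stranded methylation data.

Bisulfite sequencing reads the methylation state of each cytosine with two
error modes: *failed conversion* (an unmethylated cytosine escapes
conversion and is read as methylated, rate ``f``) and *inappropriate
conversion* (a methylated cytosine is converted and read as unmethylated,
rate ``c``).  Applied independently to the two strands of a CpG dyad, the
per-strand misread kernel induces a 3x3 stochastic matrix between true and
observed dyad states.  Because both error modes break strand concordance
more often than they create it, conversion error biases observed RCP toward
1; correcting for it is a linear inversion on the dyad-frequency simplex.

Rates are supplied by the user (typically estimated from M.SssI-treated or
unmethylated control sequences) and are assumed strand-symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DyadFrequencies

__all__ = ["ConversionRates", "error_matrix", "apply_errors", "correct_freqs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConversionRates:
    """Per-cytosine bisulfite conversion-error probabilities.

    Attributes
    ----------
    failed
        Probability that a truly unmethylated cytosine is read as methylated.
    inappropriate
        Probability that a truly methylated cytosine is read as unmethylated.
    """

    failed: float = 0.0
    inappropriate: float = 0.0

    def __post_init__(self) -> None:
        f, c = self.failed, self.inappropriate
        if not (0.0 <= f < 1.0 and 0.0 <= c < 1.0):
            raise ValueError(f"conversion rates ({f}, {c}) must lie in [0, 1)")
        if f + c >= 1.0:
            raise ValueError(
                f"failed + inappropriate = {f + c} >= 1: error model degenerate"
            )

    @property
    def is_zero(self) -> bool:
        return self.failed == 0.0 and self.inappropriate == 0.0


def error_matrix(rates: ConversionRates) -> np.ndarray:
    """3x3 row-stochastic matrix from true to observed dyad state.

    Rows and columns are indexed (FULL, HEMI, UNMETH).  Entry ``(i, j)`` is
    the probability that a dyad truly in state ``i`` is observed in state
    ``j``, obtained by applying the per-strand kernel — methylated read as
    methylated with probability ``1 - c``, unmethylated read as methylated
    with probability ``f`` — independently to both strands and collapsing
    the two hemimethylation orientations.
    """
    f, c = rates.failed, rates.inappropriate
    # per-strand P(read methylated | true state)
    pm_meth = 1.0 - c
    pm_unmeth = f
    return np.array(
        [
            [pm_meth**2, 2.0 * pm_meth * (1.0 - pm_meth), (1.0 - pm_meth) ** 2],
            [
                pm_meth * pm_unmeth,
                pm_meth * (1.0 - pm_unmeth) + (1.0 - pm_meth) * pm_unmeth,
                (1.0 - pm_meth) * (1.0 - pm_unmeth),
            ],
            [pm_unmeth**2, 2.0 * pm_unmeth * (1.0 - pm_unmeth), (1.0 - pm_unmeth) ** 2],
        ]
    )


def apply_errors(freqs: DyadFrequencies, rates: ConversionRates) -> DyadFrequencies:
    """Expected observed dyad frequencies given true frequencies and rates."""
    if rates.is_zero:
        return freqs
    obs = np.asarray(freqs.as_tuple()) @ error_matrix(rates)
    return DyadFrequencies(*obs)


def correct_freqs(observed: DyadFrequencies, rates: ConversionRates) -> DyadFrequencies:
    """Invert :func:`apply_errors`: infer true frequencies from observed ones.

    Solves the linear system exactly; solutions pushed off the simplex by
    sampling noise are clipped at 0 and renormalized (logged as a warning).
    """
    if rates.is_zero:
        return observed
    E = error_matrix(rates)
    true = np.linalg.solve(E.T, np.asarray(observed.as_tuple()))
    if np.any(true < -1e-12):
        logger.warning(
            "conversion-error correction left the simplex at %s; clipping", true
        )
        true = np.clip(true, 0.0, None)
        true = true / true.sum()
    else:
        true = np.clip(true, 0.0, None)
        true = true / true.sum()
    return DyadFrequencies(*true)


def correct_freq_array(observed: np.ndarray, rates: ConversionRates) -> np.ndarray:
    """Vectorized correction of an ``(n, 3)`` array of observed frequencies.

    Used by the resampling machinery, where thousands of bootstrap or
    permutation replicates are corrected at once.  Rows are clipped to the
    simplex and renormalized exactly as :func:`correct_freqs`.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if rates.is_zero:
        return observed
    E = error_matrix(rates)
    true = np.linalg.solve(E.T, observed.T).T
    true = np.clip(true, 0.0, None)
    sums = true.sum(axis=1, keepdims=True)
    sums[sums == 0.0] = 1.0
    return true / sums
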