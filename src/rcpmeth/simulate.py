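"""Synthetic double-stranded methylation reads with known (m, RCP).

The generator draws dyad states for each simulated hairpin molecule from a
stationary first-order Markov chain over {FULL, HEMI, UNMETH} whose
stationary distribution is the target dyad-frequency point.  The one-step
kernel is the sticky mixture ``(1 - rho) * stationary + rho * identity``:
``rho = 0`` gives independent dyads, larger ``rho`` makes neighbouring
dyads within a read agree more often, creating exactly the within-molecule
correlation that read-level (rather than dyad-level) resampling exists to
handle.  Hemimethylated dyads are assigned a top- or bottom-strand methyl
group with probability 1/2 each, and bisulfite conversion errors are then
injected per strand at the configured failed/inappropriate rates.

Reads carry unique molecule barcodes over the non-cytosine alphabet
{A, G, T} and a batchstamp equal to the sample id, so simulated files
exercise the same deduplication path as real pattern files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DyadFrequencies, freqs_from_summary, MethylationSummary, u_from_m_rcp
from .errors import ConversionRates
from .patterns import DoubleStrandRead, DyadState

__all__ = ["SimulationConfig", "target_freqs", "simulate_reads", "trajectory"]

_BARCODE_ALPHABET = np.array(list("AGT"))
_BARCODE_LEN = 10


def target_freqs(m: float, r: float) -> DyadFrequencies:
    """Dyad frequencies at methylation frequency ``m`` on the RCP contour ``r``."""
    U = u_from_m_rcp(m, r)
    return freqs_from_summary(MethylationSummary(m=m, U=U))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sample.

    Either ``freqs`` or the pair ``(m, r)`` fixes the target dyad-state
    distribution; ``rho`` is the within-read stickiness of the dyad chain,
    and ``rates`` the conversion-error probabilities injected after the
    true states are drawn.
    """

    n_reads: int
    dyads_per_read: int
    seed: int
    m: float | None = None
    r: float | None = None
    freqs: DyadFrequencies | None = None
    rho: float = 0.0
    rates: ConversionRates = field(default_factory=ConversionRates)
    locus: str = "locusA"
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.dyads_per_read < 1:
            raise ValueError("need n_reads >= 0 and dyads_per_read >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho={self.rho} outside [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.freqs is None:
            if self.m is None or self.r is None:
                raise ValueError("provide freqs or both m and r")
            target_freqs(self.m, self.r)  # raises if infeasible

    def resolve_freqs(self) -> DyadFrequencies:
        if self.freqs is not None:
            return self.freqs
        assert self.m is not None and self.r is not None
        return target_freqs(self.m, self.r)


def _unique_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    # length chosen so the 3-letter space exceeds n ~100-fold: collisions stay rare
    length = max(_BARCODE_LEN, math.ceil(math.log(max(n, 1) * 100) / math.log(3)))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        chars = rng.choice(_BARCODE_ALPHABET, size=(n - len(out), length))
        for row in chars:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_reads(
    config: SimulationConfig,
) -> tuple[list[DoubleStrandRead], DyadFrequencies]:
    """Generate reads under ``config``; returns them with the true frequencies.

    Identical configs (including seed) produce bit-identical reads.
    """
    pi = np.asarray(config.resolve_freqs().as_tuple())
    rng = np.random.default_rng(config.seed)
    n, L = config.n_reads, config.dyads_per_read
    if n == 0:
        return [], config.resolve_freqs()

    states = np.empty((n, L), dtype=np.int8)
    states[:, 0] = rng.choice(3, size=n, p=pi)
    for j in range(1, L):
        fresh = rng.choice(3, size=n, p=pi)
        stick = rng.random(n) < config.rho
        states[:, j] = np.where(stick, states[:, j - 1], fresh)

    # strand-level methylation: top/bottom booleans per dyad
    top = states == 0  # FULL
    bottom = states == 0
    hemi = states == 1
    orient_top = rng.random((n, L)) < 0.5
    top |= hemi & orient_top
    bottom |= hemi & ~orient_top

    f, c = config.rates.failed, config.rates.inappropriate
    if f > 0.0 or c > 0.0:
        for strand in (top, bottom):
            u = rng.random((n, L))
            flip_meth = strand & (u < c)  # inappropriate conversion
            flip_unmeth = ~strand & (u < f)  # failed conversion
            strand ^= flip_meth | flip_unmeth

    char_lut = {
        (True, True): DyadState.FULL,
        (True, False): DyadState.HEMI_TOP,
        (False, True): DyadState.HEMI_BOTTOM,
        (False, False): DyadState.UNMETH,
    }
    barcodes = _unique_barcodes(n, rng)
    reads = []
    for i in range(n):
        dyads = tuple(char_lut[(bool(top[i, j]), bool(bottom[i, j]))] for j in range(L))
        reads.append(
            DoubleStrandRead(
                read_id=f"{config.sample_id}_r{i:06d}",
                sample_id=config.sample_id,
                locus=config.locus,
                batchstamp=config.sample_id,
                barcode=barcodes[i],
                dyad_states=dyads,
            )
        )
    return reads, config.resolve_freqs()


def trajectory(
    configs: Sequence[SimulationConfig],
) -> tuple[list[DoubleStrandRead], dict[str, DyadFrequencies]]:
    """Concatenate simulated samples into one multi-sample read list.

    Emulates a developmental time course in which RCP shifts between
    stages; sample ids must be distinct so downstream comparisons can
    split the stages again.
    """
    if not configs:
        raise ValueError("trajectory requires at least one config")
    ids = [c.sample_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_ids in trajectory: {ids}")
    all_reads: list[DoubleStrandRead] = []
    truths: dict[str, DyadFrequencies] = {}
    for cfg in configs:
        reads, truth = simulate_reads(cfg)
        all_reads.extend(reads)
        truths[cfg.sample_id] = truth
    return all_reads, truths
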