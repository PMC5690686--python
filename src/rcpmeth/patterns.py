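"""Reading, validating and tabulating double-stranded methylation patterns.

One record corresponds to one sequenced hairpin-bisulfite molecule: the
hairpin linker covalently joins the two strands of a single DNA molecule,
so each read reports the methylation state of both cytosines of every CpG
dyad it covers.  The linker also encodes an experiment-level *batchstamp*
(contamination monitoring) and a molecule-level *barcode* (redundancy
removal).

Pattern files are TSV with header
``read_id  sample_id  locus  batchstamp  barcode  dyads`` where ``dyads``
is a string over ``F`` (fully methylated), ``T``/``B`` (hemimethylated,
methyl group on the top/bottom strand), ``U`` (unmethylated) and ``.``
(dyad not called).  Dyad-count tables are TSV with header
``sample_id  locus  n_full  n_hemi  n_unmeth  n_reads  failed_rate
inapprop_rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

from .errors import ConversionRates

__all__ = [
    "DyadState",
    "DoubleStrandRead",
    "DyadCounts",
    "PatternParseError",
    "parse_pattern_file",
    "write_pattern_file",
    "deduplicate_reads",
    "count_dyads",
    "read_count_table",
    "write_count_table",
]

logger = logging.getLogger(__name__)

PATTERN_HEADER = ["read_id", "sample_id", "locus", "batchstamp", "barcode", "dyads"]
COUNT_HEADER = [
    "sample_id",
    "locus",
    "n_full",
    "n_hemi",
    "n_unmeth",
    "n_reads",
    "failed_rate",
    "inapprop_rate",
]


class DyadState(str, Enum):
    """Methylation state of one CpG dyad as called from a hairpin read."""

    FULL = "F"
    HEMI_TOP = "T"
    HEMI_BOTTOM = "B"
    UNMETH = "U"
    MISSING = "."

    @property
    def is_hemi(self) -> bool:
        return self in (DyadState.HEMI_TOP, DyadState.HEMI_BOTTOM)


_CHAR_TO_STATE = {s.value: s for s in DyadState}


class PatternParseError(ValueError):
    """A pattern or count file violated the format contract."""


@dataclass(frozen=True)
class DoubleStrandRead:
    """One sequenced hairpin molecule with its ordered dyad-state calls."""

    read_id: str
    sample_id: str
    locus: str
    batchstamp: str
    barcode: str
    dyad_states: tuple[DyadState, ...]

    def __post_init__(self) -> None:
        if not self.dyad_states:
            raise ValueError(f"read {self.read_id!r} has no dyad states")

    @property
    def dyad_string(self) -> str:
        return "".join(s.value for s in self.dyad_states)

    def state_counts(self) -> tuple[int, int, int]:
        """(n_full, n_hemi, n_unmeth) of this read; MISSING dyads skipped."""
        n_full = n_hemi = n_unmeth = 0
        for s in self.dyad_states:
            if s is DyadState.FULL:
                n_full += 1
            elif s.is_hemi:
                n_hemi += 1
            elif s is DyadState.UNMETH:
                n_unmeth += 1
        return (n_full, n_hemi, n_unmeth)


@dataclass(frozen=True)
class DyadCounts:
    """Tallies of dyad states for one sample/locus: the sufficient statistics."""

    sample_id: str
    locus: str
    n_full: int
    n_hemi: int
    n_unmeth: int
    n_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("n_full", "n_hemi", "n_unmeth", "n_reads"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.n_full + self.n_hemi + self.n_unmeth

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_full, self.n_hemi, self.n_unmeth)


def _parse_dyad_string(dyads: str, lineno: int) -> tuple[DyadState, ...]:
    states = []
    for ch in dyads:
        try:
            states.append(_CHAR_TO_STATE[ch])
        except KeyError:
            raise PatternParseError(
                f"line {lineno}: illegal dyad-state character {ch!r} "
                f"(expected one of F, T, B, U, .)"
            ) from None
    if not states:
        raise PatternParseError(f"line {lineno}: empty dyad string")
    return tuple(states)


def parse_pattern_file(stream: IO[str] | Iterable[str]) -> list[DoubleStrandRead]:
    """Parse a pattern TSV into reads, in file order.

    Raises :class:`PatternParseError` naming the offending line for a wrong
    column count or an illegal dyad-state character.  Logs the fraction of
    MISSING dyads seen.
    """
    reads: list[DoubleStrandRead] = []
    n_missing = n_dyads = 0
    it = iter(stream)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise PatternParseError("empty file: missing header") from None
    if header != PATTERN_HEADER:
        raise PatternParseError(
            f"bad header {header!r}; expected {PATTERN_HEADER!r}"
        )
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise PatternParseError(
                f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
            )
        read_id, sample_id, locus, batchstamp, barcode, dyads = fields
        states = _parse_dyad_string(dyads, lineno)
        n_missing += sum(1 for s in states if s is DyadState.MISSING)
        n_dyads += len(states)
        reads.append(
            DoubleStrandRead(read_id, sample_id, locus, batchstamp, barcode, states)
        )
    if n_dyads:
        logger.info(
            "parsed %d reads; %.2f%% of dyad positions missing",
            len(reads),
            100.0 * n_missing / n_dyads,
        )
    return reads


def write_pattern_file(reads: Iterable[DoubleStrandRead], stream: IO[str]) -> None:
    """Write reads as a pattern TSV (inverse of :func:`parse_pattern_file`)."""
    stream.write("\t".join(PATTERN_HEADER) + "\n")
    for r in reads:
        stream.write(
            "\t".join(
                (r.read_id, r.sample_id, r.locus, r.batchstamp, r.barcode, r.dyad_string)
            )
            + "\n"
        )


def deduplicate_reads(
    reads: Sequence[DoubleStrandRead],
) -> tuple[list[DoubleStrandRead], int]:
    """Drop reads repeating a (batchstamp, barcode, locus) key; keep the first.

    Molecule barcodes identify redundant sequences arising from PCR
    amplification of the same template; the first occurrence in input order
    is kept, so the operation is deterministic and idempotent.
    """
    seen: set[tuple[str, str, str]] = set()
    kept: list[DoubleStrandRead] = []
    for r in reads:
        key = (r.batchstamp, r.barcode, r.locus)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept, len(reads) - len(kept)


def count_dyads(
    reads: Sequence[DoubleStrandRead],
    sample_id: str = "",
    locus: str = "",
) -> DyadCounts:
    """Tally dyad states over reads; hemimethylation orientation is collapsed.

    MISSING dyads contribute to no count.  ``sample_id``/``locus`` default
    to the first read's values when not given.
    """
    n_full = n_hemi = n_unmeth = 0
    for r in reads:
        f, h, u = r.state_counts()
        n_full += f
        n_hemi += h
        n_unmeth += u
    if reads:
        sample_id = sample_id or reads[0].sample_id
        locus = locus or reads[0].locus
    return DyadCounts(
        sample_id=sample_id,
        locus=locus,
        n_full=n_full,
        n_hemi=n_hemi,
        n_unmeth=n_unmeth,
        n_reads=len(reads),
    )


def read_count_table(
    stream: IO[str] | Iterable[str],
) -> list[tuple[DyadCounts, ConversionRates]]:
    """Parse a dyad-count TSV into (counts, conversion-rates) records."""
    records: list[tuple[DyadCounts, ConversionRates]] = []
    it = iter(stream)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise PatternParseError("empty file: missing header") from None
    if header != COUNT_HEADER:
        raise PatternParseError(f"bad header {header!r}; expected {COUNT_HEADER!r}")
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise PatternParseError(
                f"line {lineno}: expected 8 tab-separated fields, got {len(fields)}"
            )
        sample_id, locus = fields[0], fields[1]
        try:
            n_full, n_hemi, n_unmeth, n_reads = (int(x) for x in fields[2:6])
            failed, inapprop = float(fields[6]), float(fields[7])
        except ValueError as exc:
            raise PatternParseError(f"line {lineno}: {exc}") from None
        try:
            counts = DyadCounts(sample_id, locus, n_full, n_hemi, n_unmeth, n_reads)
            rates = ConversionRates(failed=failed, inappropriate=inapprop)
        except ValueError as exc:
            raise PatternParseError(f"line {lineno}: {exc}") from None
        records.append((counts, rates))
    return records


def write_count_table(
    records: Iterable[tuple[DyadCounts, ConversionRates]], stream: IO[str]
) -> None:
    """Write (counts, rates) records as a dyad-count TSV (round-trip exact)."""
    stream.write("\t".join(COUNT_HEADER) + "\n")
    for counts, rates in records:
        stream.write(
            "\t".join(
                (
                    counts.sample_id,
                    counts.locus,
                    str(counts.n_full),
                    str(counts.n_hemi),
                    str(counts.n_unmeth),
                    str(counts.n_reads),
                    repr(rates.failed),
                    repr(rates.inappropriate),
                )
            )
            + "\n"
        )
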