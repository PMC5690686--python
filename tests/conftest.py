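import hypothesis
import pytest

from rcpmeth.patterns import DoubleStrandRead, DyadState

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")

_CHAR = {s.value: s for s in DyadState}


def make_read(
    dyads: str,
    read_id: str = "r1",
    sample_id: str = "s1",
    locus: str = "L1",
    batchstamp: str = "BS1",
    barcode: str = "GATTACA",
) -> DoubleStrandRead:
    """Build a read from its dyad-state string, e.g. ``"FTU."``."""
    return DoubleStrandRead(
        read_id=read_id,
        sample_id=sample_id,
        locus=locus,
        batchstamp=batchstamp,
        barcode=barcode,
        dyad_states=tuple(_CHAR[c] for c in dyads),
    )


@pytest.fixture
def mixed_reads():
    """A small heterogeneous read set with every dyad state represented."""
    return [
        make_read("FTU.", read_id="r1", barcode="AAA"),
        make_read("FFUU", read_id="r2", barcode="AAG"),
        make_read("FBUF", read_id="r3", barcode="AAT"),
        make_read("UUTF", read_id="r4", barcode="AGA"),
        make_read("F.UB", read_id="r5", barcode="AGG"),
    ]
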