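import numpy as np
import pytest

from ovismt.seqio import AlignedSeq, CoordinateMap, SeqRecord
from ovismt.synthetic import (
    REF_START,
    default_panel_specs,
    gen_haplogroup_panel,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def syn_ref() -> SeqRecord:
    return synthetic_reference()


@pytest.fixture(scope="session")
def syn_ref_aligned(syn_ref) -> AlignedSeq:
    return AlignedSeq(syn_ref, CoordinateMap.identity(REF_START, len(syn_ref)))


@pytest.fixture(scope="session")
def panel():
    """60 synthetic CR sequences over haplogroups A, B, C, E and wild X."""
    return gen_haplogroup_panel(
        default_panel_specs(include_wild_x=True), n=60, private_mut_rate=1.0, seed=11
    )


def anchor_panel_record(rec: SeqRecord) -> AlignedSeq:
    """Panel sequences share the reference's prefix layout: identity anchor."""
    return AlignedSeq(rec, CoordinateMap.identity(REF_START, len(rec)))


@pytest.fixture(scope="session")
def toy_alignment() -> list[str]:
    """Fixed 10-sequence, 20-site alignment with S=6 segregating sites."""
    return [
        "ACGTACGTACGTACGTACGT",
        "ACGTACGTACGTACGTACGT",
        "ACGTACGAACGTACGTACGT",
        "ACGTACGAACGTACGTACGT",
        "ACGTACGTACGTACGAACGT",
        "ACGTACGTACGTACGAACGA",
        "ACGTACGTACGTACGTACGA",
        "TCGTACGTACGTACGTACGT",
        "TCGTACGTACCTACGTACGT",
        "ACGTACGTACGTACTTACGT",
    ]
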