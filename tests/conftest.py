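"""Shared fixtures: the simulator mini-reference and a plain-text SAM builder.

All alignment fixtures are generated at test time; SAM text inputs exercise
the index-less full-scan path of the pileup, simulated BAMs the indexed path.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from sma_caller.locus_config import LocusConfig
from sma_caller.simulator import (
    CONTIG_LENGTH,
    KEY_POS_1BASED,
    SMN1_CONTIG,
    SMN2_CONTIG,
    build_mini_reference,
    mini_reference_config,
)

SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    f"@SQ\tSN:{SMN1_CONTIG}\tLN:{CONTIG_LENGTH}\n"
    f"@SQ\tSN:{SMN2_CONTIG}\tLN:{CONTIG_LENGTH}\n"
)


def sam_record(
    qname: str,
    base: str,
    *,
    rname: str = SMN1_CONTIG,
    key_pos: int = KEY_POS_1BASED,
    flag: int = 0,
    mapq: int = 0,
    qual: int = 30,
    read_length: int = 9,
    cigar: str | None = None,
    offset: int = 4,
) -> str:
    """One SAM line for a read whose base at ``key_pos`` is ``base``.

    The read starts ``offset`` bases before the key position; with the
    default 9 bp / offset 4 the key base sits mid-read.  A custom CIGAR
    (e.g. one deleting the key base) overrides the default full match.
    """
    pos = key_pos - offset
    seq = "A" * offset + base + "A" * (read_length - offset - 1)
    if cigar is None:
        cigar = f"{read_length}M"
    qual_str = chr(qual + 33) * read_length
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
        f"{seq}\t{qual_str}\n"
    )


def write_sam(path: Path, records: list[str]) -> Path:
    path.write_text(SAM_HEADER + "".join(records))
    return path


@pytest.fixture(scope="session")
def mini_ref(tmp_path_factory) -> tuple[Path, LocusConfig]:
    out = tmp_path_factory.mktemp("mini_ref")
    return build_mini_reference(out)


@pytest.fixture()
def mini_config() -> LocusConfig:
    return mini_reference_config()
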