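"""Count base observations at the c.840 position of both SMN paralogs.

The two statistics everything else consumes are N (total qualifying base
observations over the *SMN1* + *SMN2* c.840 positions) and r (the subset
showing 'C', the functional *SMN1* base).  Reads at this locus routinely
carry MAPQ 0 because the paralogs are near-identical, so mapping quality
is deliberately NOT a filter; duplicate / secondary / supplementary /
QC-fail / unmapped records are excluded, a base quality floor applies at
the pileup position, and overlapping mates of one fragment contribute a
single observation (the mate with the higher base quality wins, ties to
the first encountered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .errors import ContigError, ContractError, ReferenceRequiredError
from .locus_config import LocusConfig, resolve_contig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadFilters:
    """Which records and base calls qualify for the pileup."""

    min_base_quality: int = 13
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        return True


@dataclass(frozen=True)
class LocusCounts:
    """Base breakdown at one paralog's c.840 position."""

    n_c: int = 0
    n_t: int = 0
    n_other: int = 0

    @property
    def n_total(self) -> int:
        return self.n_c + self.n_t + self.n_other

    def __add__(self, other: "LocusCounts") -> "LocusCounts":
        return LocusCounts(
            self.n_c + other.n_c,
            self.n_t + other.n_t,
            self.n_other + other.n_other,
        )


@dataclass(frozen=True)
class PileupCounts:
    """Combined and per-locus counts for one sample.

    ``n_c`` is the method's r and ``n_total`` its N.
    """

    sample_id: str
    smn1: LocusCounts = field(default_factory=LocusCounts)
    smn2: LocusCounts = field(default_factory=LocusCounts)

    @property
    def combined(self) -> LocusCounts:
        return self.smn1 + self.smn2

    @property
    def n_c(self) -> int:
        return self.combined.n_c

    @property
    def n_t(self) -> int:
        return self.combined.n_t

    @property
    def n_other(self) -> int:
        return self.combined.n_other

    @property
    def n_total(self) -> int:
        return self.combined.n_total

    def validate(self) -> None:
        for locus in (self.smn1, self.smn2):
            if min(locus.n_c, locus.n_t, locus.n_other) < 0:
                raise ContractError(f"negative counter in {locus}")


def _open_alignment(
    path: str | Path, reference_fasta: str | Path | None
) -> pysam.AlignmentFile:
    path = Path(path)
    if path.suffix.lower() == ".cram" and reference_fasta is None:
        raise ReferenceRequiredError(
            f"{path.name}: CRAM input requires --fasta with the alignment reference"
        )
    kwargs = {}
    if reference_fasta is not None:
        kwargs["reference_filename"] = str(reference_fasta)
    return pysam.AlignmentFile(str(path), **kwargs)


def _reads_by_locus(
    af: pysam.AlignmentFile, targets: dict[str, tuple[str, int]]
) -> dict[str, list[pysam.AlignedSegment]]:
    """Reads overlapping each target's [pos0, pos0+1), keyed like ``targets``
    (gene -> (contig, pos0)).

    Indexed BAM/CRAM uses region fetches (an index-less file surfaces
    pysam's index error); plain SAM has no index and is single-pass, so all
    targets are collected in one full scan."""
    if af.format != "SAM":
        return {
            gene: list(af.fetch(contig, pos0, pos0 + 1))
            for gene, (contig, pos0) in targets.items()
        }
    hits: dict[str, list[pysam.AlignedSegment]] = {gene: [] for gene in targets}
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.reference_start is None or read.reference_end is None:
            continue
        for gene, (contig, pos0) in targets.items():
            if (
                read.reference_name == contig
                and read.reference_start <= pos0 < read.reference_end
            ):
                hits[gene].append(read)
    return hits


def _base_at(read: pysam.AlignedSegment, pos0: int) -> tuple[str, int] | None:
    """(base, quality) the read reports at reference position pos0, or None
    if the position falls in a deletion / reference skip."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos == pos0:
            if qpos is None:
                return None
            qual = read.query_qualities[qpos] if read.query_qualities is not None else 0
            return read.query_sequence[qpos].upper(), qual
    return None


def _count_one_locus(
    reads: list[pysam.AlignedSegment], pos0: int, filters: ReadFilters
) -> LocusCounts:
    # fragment name -> (base, qual); overlapping mates collapse to one entry
    observations: dict[str, tuple[str, int]] = {}
    for read in reads:
        if not filters.passes(read):
            continue
        hit = _base_at(read, pos0)
        if hit is None:
            continue
        base, qual = hit
        if qual < filters.min_base_quality:
            continue
        prev = observations.get(read.query_name)
        if prev is None or qual > prev[1]:
            observations[read.query_name] = (base, qual)
    n_c = sum(1 for base, _ in observations.values() if base == "C")
    n_t = sum(1 for base, _ in observations.values() if base == "T")
    n_other = len(observations) - n_c - n_t
    return LocusCounts(n_c=n_c, n_t=n_t, n_other=n_other)


def _warn_on_alt_contigs(af: pysam.AlignmentFile, resolved_chrom: str) -> None:
    alts = [
        name
        for name in af.references
        if name.lower().endswith("_alt") and name.startswith(f"{resolved_chrom}_")
    ]
    if alts:
        logger.warning(
            "header contains SMN-region ALT contigs (%s); only primary-assembly "
            "positions are counted — verify the aligner was ALT-aware",
            ", ".join(alts[:5]),
        )


def sample_id_from_alignment(af: pysam.AlignmentFile, path: str | Path) -> str:
    """Sample name from the read-group SM tags, else the file stem."""
    try:
        names = {
            rg["SM"] for rg in af.header.to_dict().get("RG", []) if "SM" in rg
        }
    except (AttributeError, KeyError):
        names = set()
    if len(names) == 1:
        return names.pop()
    return Path(path).name.removesuffix(".bam").removesuffix(".cram").removesuffix(".sam")


def count_c840_reads(
    alignments: str | Path,
    config: LocusConfig,
    filters: ReadFilters | None = None,
    reference_fasta: str | Path | None = None,
) -> PileupCounts:
    """Produce r and N (plus the full base breakdown) for one alignment file.

    The file must be indexed for BAM/CRAM region access; plain SAM inputs
    are scanned in full.  Contig naming dialects are auto-resolved against
    the header.
    """
    filters = filters or ReadFilters()
    with _open_alignment(alignments, reference_fasta) as af:
        if not af.references:
            raise ContigError(f"{alignments}: header declares no reference sequences")
        targets: dict[str, tuple[str, int]] = {}
        for gene, chrom, pos, _ in config.loci:
            contig = resolve_contig(chrom, af.references)
            _warn_on_alt_contigs(af, contig)
            targets[gene] = (contig, pos - 1)
        reads = _reads_by_locus(af, targets)
        per_gene = {
            gene: _count_one_locus(reads[gene], targets[gene][1], filters)
            for gene in targets
        }
        counts = PileupCounts(
            sample_id=sample_id_from_alignment(af, alignments),
            smn1=per_gene["SMN1"],
            smn2=per_gene["SMN2"],
        )
    counts.validate()
    return counts
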