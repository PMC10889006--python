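"""Per-build coordinates of the c.840 position in *SMN1* and *SMN2*.

*SMN1* and *SMN2* are near-identical paralogs on chromosome 5q13 that
differ at the c.840 position: 'C' in *SMN1* (full-length transcript) and
'T' in *SMN2* (exon-7 skipping).  Everything downstream keys off these two
genomic coordinates, so this module defines them per reference build,
loads user overrides from a flat config file, and validates the expected
bases against an indexed FASTA.

Coordinates are stored 1-based (VCF/HGVS convention); conversion to the
0-based pysam coordinate system happens explicitly at each API boundary.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import ConfigError, ContigError, ValidationError

HUMAN_BUILDS = ("GRCh37", "GRCh38", "T2T-CHM13")


@dataclass(frozen=True)
class LocusConfig:
    """Coordinates and expected reference bases of c.840 in both paralogs.

    For the human builds both positions live on the same chromosome; a
    user-defined build (e.g. the simulator's mini-reference) may place
    each paralog on its own contig.
    """

    build_name: str
    smn1_chrom: str
    smn1_c840_pos: int
    smn2_chrom: str
    smn2_c840_pos: int
    smn1_base: str = "C"
    smn2_base: str = "T"

    def __post_init__(self) -> None:
        if self.smn1_c840_pos <= 0 or self.smn2_c840_pos <= 0:
            raise ConfigError(
                f"{self.build_name}: c.840 coordinates must be positive integers"
            )
        if self.smn1_base.upper() != "C" or self.smn2_base.upper() != "T":
            raise ConfigError(
                f"{self.build_name}: expected bases must be C (SMN1) and T (SMN2), "
                f"got {self.smn1_base!r}/{self.smn2_base!r}"
            )
        if self.build_name in HUMAN_BUILDS:
            if self.smn1_chrom != self.smn2_chrom:
                raise ConfigError(
                    f"{self.build_name}: both positions must be on one chromosome"
                )
            if self.smn1_c840_pos == self.smn2_c840_pos:
                raise ConfigError(
                    f"{self.build_name}: SMN1 and SMN2 positions must differ"
                )

    @property
    def chromosome(self) -> str:
        """Shared chromosome name; defined only when both loci agree."""
        if self.smn1_chrom != self.smn2_chrom:
            raise ValueError(
                "config places the paralogs on different contigs; "
                "use smn1_chrom / smn2_chrom"
            )
        return self.smn1_chrom

    @property
    def loci(self) -> tuple[tuple[str, str, int, str], ...]:
        """(gene, contig, 1-based position, expected base) for both paralogs."""
        return (
            ("SMN1", self.smn1_chrom, self.smn1_c840_pos, self.smn1_base.upper()),
            ("SMN2", self.smn2_chrom, self.smn2_c840_pos, self.smn2_base.upper()),
        )


@dataclass(frozen=True)
class LocusValidation:
    """One validated position: what was expected vs. what the FASTA holds."""

    gene: str
    contig_used: str
    position: int
    expected_base: str
    observed_base: str

    @property
    def passed(self) -> bool:
        return self.observed_base.upper() == self.expected_base.upper()


@dataclass(frozen=True)
class ValidationReport:
    entries: tuple[LocusValidation, ...]

    @property
    def passed(self) -> bool:
        return all(e.passed for e in self.entries)

    def raise_on_failure(self) -> None:
        for e in self.entries:
            if not e.passed:
                raise ValidationError(
                    f"{e.gene} expected {e.expected_base!r} at "
                    f"{e.contig_used}:{e.position} but reference has "
                    f"{e.observed_base!r}"
                )


def _contig_dialects(name: str) -> tuple[str, ...]:
    """Candidate spellings of a contig under the chr-prefix dialects."""
    bare = name[3:] if name.lower().startswith("chr") else name
    return tuple(dict.fromkeys([name, bare, f"chr{bare}"]))


def resolve_contig(name: str, available: Iterable[str]) -> str:
    """Map a configured contig name onto the naming dialect a file uses."""
    avail = set(available)
    for candidate in _contig_dialects(name):
        if candidate in avail:
            return candidate
    raise ContigError(
        f"contig {name!r} (or a chr-prefixed/stripped variant) not found; "
        f"file has: {', '.join(sorted(avail)[:10])}"
    )


def _parse_build_section(build_name: str, section: configparser.SectionProxy) -> LocusConfig:
    try:
        chrom = section.get("chromosome")
        smn1_chrom = section.get("smn1_chromosome", chrom)
        smn2_chrom = section.get("smn2_chromosome", chrom)
        if smn1_chrom is None or smn2_chrom is None:
            raise ConfigError(
                f"[{build_name}]: need 'chromosome' or per-gene "
                "'smn1_chromosome'/'smn2_chromosome'"
            )
        return LocusConfig(
            build_name=build_name,
            smn1_chrom=smn1_chrom,
            smn1_c840_pos=section.getint("smn1_c840_pos"),
            smn2_chrom=smn2_chrom,
            smn2_c840_pos=section.getint("smn2_c840_pos"),
            smn1_base=section.get("smn1_base", "C"),
            smn2_base=section.get("smn2_base", "T"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[{build_name}]: malformed entry: {exc}") from exc


def _read_config_file(text: str, origin: str) -> dict[str, LocusConfig]:
    parser = configparser.ConfigParser()
    try:
        parser.read_string(text, source=origin)
    except configparser.Error as exc:
        # configparser errors carry the offending line number in their message
        raise ConfigError(f"cannot parse {origin}: {exc}") from exc
    return {
        name: _parse_build_section(name, parser[name]) for name in parser.sections()
    }


def builtin_builds() -> dict[str, LocusConfig]:
    """The bundled registry (GRCh37, GRCh38, T2T-CHM13)."""
    text = resources.files("sma_caller.data").joinpath("builds.cfg").read_text()
    return _read_config_file(text, "builds.cfg (bundled)")


def load_locus_config(
    build_name: str, source: str | Path | None = None
) -> LocusConfig:
    """Look up a build in a user config file or the bundled registry.

    A user-supplied ``source`` file is consulted first and may override a
    bundled build of the same name.
    """
    registry = builtin_builds()
    if source is not None:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"locus config file not found: {path}")
        registry.update(_read_config_file(path.read_text(), str(path)))
    try:
        return registry[build_name]
    except KeyError:
        raise ConfigError(
            f"unknown build {build_name!r}; available: "
            + ", ".join(sorted(registry))
        ) from None


def validate_reference_bases(
    config: LocusConfig, reference: str | Path
) -> ValidationReport:
    """Check that the FASTA holds 'C' at the SMN1 position and 'T' at SMN2.

    Chromosome-name dialects ("5" vs "chr5") are resolved symmetrically.
    Raises ContigError / coordinate errors for structural problems; base
    mismatches are reported, not raised (see ValidationReport.raise_on_failure).
    """
    entries = []
    with pysam.FastaFile(str(reference)) as fasta:
        for gene, chrom, pos, expected in config.loci:
            contig = resolve_contig(chrom, fasta.references)
            length = fasta.get_reference_length(contig)
            if pos > length:
                raise ContigError(
                    f"{gene} position {pos} exceeds {contig} length {length}"
                )
            observed = fasta.fetch(contig, pos - 1, pos)
            entries.append(
                LocusValidation(gene, contig, pos, expected, observed.upper())
            )
    return ValidationReport(tuple(entries))


def derive_positions_by_flank_match(
    source_config: LocusConfig,
    source_fasta: str | Path,
    target_fasta: str | Path,
    target_build_name: str,
    flank: int = 30,
) -> LocusConfig:
    """Lift the two c.840 positions onto another assembly by exact flank match.

    Extracts ±``flank`` bp around each configured position from the source
    FASTA and requires a unique exact occurrence of that window in the
    target contig (same chromosome, either naming dialect).  The resulting
    config is validated against the target FASTA before being returned, so
    an off-by-one can never slip through the C/T base check.
    """
    positions: dict[str, tuple[str, int]] = {}
    with pysam.FastaFile(str(source_fasta)) as src, pysam.FastaFile(
        str(target_fasta)
    ) as tgt:
        for gene, chrom, pos, _ in source_config.loci:
            src_contig = resolve_contig(chrom, src.references)
            window = src.fetch(src_contig, pos - 1 - flank, pos + flank).upper()
            if len(window) != 2 * flank + 1:
                raise ContigError(
                    f"{gene}: flank window truncated at {src_contig}:{pos}"
                )
            tgt_contig = resolve_contig(chrom, tgt.references)
            target_seq = tgt.fetch(tgt_contig).upper()
            first = target_seq.find(window)
            if first < 0:
                raise ValidationError(
                    f"{gene}: flank sequence not found in target {tgt_contig}"
                )
            if target_seq.find(window, first + 1) >= 0:
                raise ValidationError(
                    f"{gene}: flank sequence is not unique in target {tgt_contig}"
                )
            positions[gene] = (tgt_contig, first + flank + 1)  # back to 1-based

    derived = replace(
        source_config,
        build_name=target_build_name,
        smn1_chrom=positions["SMN1"][0],
        smn1_c840_pos=positions["SMN1"][1],
        smn2_chrom=positions["SMN2"][0],
        smn2_c840_pos=positions["SMN2"][1],
    )
    validate_reference_bases(derived, target_fasta).raise_on_failure()
    return derived
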