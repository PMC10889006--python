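"""Seeded synthetic-read simulator for the SMN c.840 locus.

Real data at this locus is short paired-end reads over two ~99.9%-identical
paralogs, with copy numbers between 0 and 5 per paralog across genomes.
The simulator reproduces the features the caller actually sees:

* a mini-reference of two ~2 kb contigs, identical except at one aligned
  key site ('C' in the SMN1-like contig, 'T' in the SMN2-like contig) plus
  a handful of paralog-distinguishing bases far from the key site;
* per-sample paralog copy numbers, with the number of fragments covering
  the key site Poisson(mean_depth_per_copy * total copies) and each
  fragment's paralog of origin categorical in the copy numbers;
* independent per-base miscalls at a configurable rate;
* ambiguous mapping: a pair whose key-covering read window contains no
  distinguishing base besides the key site gets MAPQ 0, as BWA-like
  aligners produce here.

Alignments are written directly (no external aligner): each pair is placed
on the contig best matching the key-covering mate's sequence.  Everything
is deterministic given the SimSpec seed; BAM headers carry no timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .caller import CallStatus
from .errors import ManifestError
from .locus_config import LocusConfig, validate_reference_bases

SMN1_CONTIG = "SMN1_region"
SMN2_CONTIG = "SMN2_region"
CONTIG_LENGTH = 2000
KEY_POS_1BASED = 1000
# paralog-distinguishing sites outside any 150 bp read window over the key site
EXTRA_DIFF_POSITIONS_1BASED = (300, 600, 1700)
_REFERENCE_SEED = 715517  # fixed: the mini-reference is a constant artifact

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def mini_reference_config() -> LocusConfig:
    return LocusConfig(
        build_name="mini",
        smn1_chrom=SMN1_CONTIG,
        smn1_c840_pos=KEY_POS_1BASED,
        smn2_chrom=SMN2_CONTIG,
        smn2_c840_pos=KEY_POS_1BASED,
    )


def _mini_reference_sequences() -> tuple[str, str]:
    rng = np.random.default_rng(_REFERENCE_SEED)
    seq1 = rng.choice(_BASES, size=CONTIG_LENGTH)
    seq1[KEY_POS_1BASED - 1] = b"C"
    seq2 = seq1.copy()
    seq2[KEY_POS_1BASED - 1] = b"T"
    for pos in EXTRA_DIFF_POSITIONS_1BASED:
        current = seq2[pos - 1]
        alternatives = [b for b in _BASES if b != current]
        seq2[pos - 1] = alternatives[rng.integers(len(alternatives))]
    return (
        seq1.tobytes().decode("ascii"),
        seq2.tobytes().decode("ascii"),
    )


def build_mini_reference(output_dir: str | Path) -> tuple[Path, LocusConfig]:
    """Write the two-contig mini-reference FASTA (+ .fai) and its LocusConfig."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = output_dir / "smn_mini_reference.fa"
    seq1, seq2 = _mini_reference_sequences()
    with open(fasta_path, "w") as fh:
        for name, seq in ((SMN1_CONTIG, seq1), (SMN2_CONTIG, seq2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(fasta_path))
    config = mini_reference_config()
    validate_reference_bases(config, fasta_path).raise_on_failure()
    return fasta_path, config


@dataclass(frozen=True)
class SimSpec:
    """Parameters for one simulated sample."""

    sample_id: str = "sim"
    smn1_copies: int = 2
    smn2_copies: int = 2
    mean_depth_per_copy: float = 15.0
    read_length: int = 150
    base_error_rate: float = 0.005
    fragment_size_mean: float = 350.0
    fragment_size_sd: float = 50.0
    base_quality: int = 30
    force_mate_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.smn1_copies <= 5 and 0 <= self.smn2_copies <= 5):
            raise ValueError("copy numbers must be in 0..5")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if not 0 <= self.base_error_rate < 0.1:
            raise ValueError("base_error_rate must be in [0, 0.1)")

    @property
    def total_copies(self) -> int:
        return self.smn1_copies + self.smn2_copies


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label implied by a SimSpec: positive iff no SMN1 copies."""

    sample_id: str
    smn1_copies: int
    smn2_copies: int

    @property
    def expected_status(self) -> CallStatus:
        return (
            CallStatus.POSITIVE if self.smn1_copies == 0 else CallStatus.NEGATIVE
        )


@dataclass
class _Record:
    name: str
    contig: str
    start0: int
    seq: str
    mapq: int
    is_read1: bool
    mate_start0: int
    base_quality: int


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        seq = seq.copy()
        for i in hits:
            # substitute uniformly among the three other bases
            others = [b for b in _BASES if b != seq[i]]
            seq[i] = others[rng.integers(3)]
    return seq


def _window_has_extra_diff(start0: int, length: int) -> bool:
    end0 = start0 + length  # exclusive
    return any(start0 <= p - 1 < end0 for p in EXTRA_DIFF_POSITIONS_1BASED)


def _best_contig(
    seq: np.ndarray, start0: int, refs: dict[str, np.ndarray]
) -> tuple[str, bool]:
    """Contig with fewest mismatches for this placement; True if tied."""
    scores = {
        name: int(np.count_nonzero(seq != ref[start0 : start0 + seq.size]))
        for name, ref in refs.items()
    }
    best = min(scores, key=lambda k: (scores[k], k))
    tied = len({v for v in scores.values()}) == 1
    return best, tied


def simulate_sample(
    spec: SimSpec,
    reference_fasta: str | Path,
    output_bam: str | Path,
) -> tuple[Path, TruthRecord]:
    """Write a coordinate-sorted, indexed BAM for one simulated sample.

    A total-copy-number of zero with positive requested depth yields a
    valid, empty BAM (whole-locus deletion), not an error.
    """
    rng = np.random.default_rng(spec.seed)
    with pysam.FastaFile(str(reference_fasta)) as fa:
        refs = {
            name: np.frombuffer(
                fa.fetch(name).upper().encode("ascii"), dtype="S1"
            )
            for name in (SMN1_CONTIG, SMN2_CONTIG)
        }

    L = spec.read_length
    key0 = KEY_POS_1BASED - 1
    n_fragments = (
        rng.poisson(spec.mean_depth_per_copy * spec.total_copies)
        if spec.total_copies > 0
        else 0
    )
    copy_p = (
        np.array([spec.smn1_copies, spec.smn2_copies], dtype=float)
        / spec.total_copies
        if spec.total_copies
        else None
    )

    records: list[_Record] = []
    for i in range(n_fragments):
        origin = (SMN1_CONTIG, SMN2_CONTIG)[rng.choice(2, p=copy_p)]
        ref = refs[origin]
        # read 1 covers the key site
        lo = max(0, key0 - L + 1)
        hi = min(key0, CONTIG_LENGTH - L)
        r1_start = int(rng.integers(lo, hi + 1))
        if spec.force_mate_overlap:
            r2_start = int(rng.integers(lo, hi + 1))
        else:
            frag = max(L + 10, int(round(rng.normal(spec.fragment_size_mean, spec.fragment_size_sd))))
            r2_start = min(max(key0 + 1, r1_start + frag - L), CONTIG_LENGTH - L)
        seqs = {}
        for start in {r1_start, r2_start}:
            raw = ref[start : start + L]
            seqs[start] = _apply_errors(raw, spec.base_error_rate, rng)
        # the pair is placed on the contig best matching the key-covering read
        pair_contig, tied_r1 = _best_contig(seqs[r1_start], r1_start, refs)
        ambiguous = not _window_has_extra_diff(r1_start, L)
        mapq = 0 if (ambiguous or tied_r1) else 60
        name = f"{spec.sample_id}_frag{i:06d}"
        for is_read1, start, mate_start in (
            (True, r1_start, r2_start),
            (False, r2_start, r1_start),
        ):
            records.append(
                _Record(
                    name=name,
                    contig=pair_contig,
                    start0=start,
                    seq=seqs[start].tobytes().decode("ascii"),
                    mapq=mapq,
                    is_read1=is_read1,
                    mate_start0=mate_start,
                    base_quality=spec.base_quality,
                )
            )

    output_bam = Path(output_bam)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": SMN1_CONTIG, "LN": CONTIG_LENGTH},
            {"SN": SMN2_CONTIG, "LN": CONTIG_LENGTH},
        ],
        "RG": [{"ID": spec.sample_id, "SM": spec.sample_id}],
    }
    tid = {SMN1_CONTIG: 0, SMN2_CONTIG: 1}
    records.sort(key=lambda rec: (tid[rec.contig], rec.start0, rec.name, not rec.is_read1))
    with pysam.AlignmentFile(str(output_bam), "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rec.name
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(
                chr(rec.base_quality + 33) * len(rec.seq)
            )
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.start0
            a.mapping_quality = rec.mapq
            a.cigarstring = f"{len(rec.seq)}M"
            a.next_reference_id = tid[rec.contig]
            a.next_reference_start = rec.mate_start0
            a.template_length = 0
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = rec.is_read1
            a.is_read2 = not rec.is_read1
            a.is_reverse = not rec.is_read1
            a.mate_is_reverse = rec.is_read1
            a.set_tag("RG", spec.sample_id)
            bam.write(a)
    pysam.index(str(output_bam))
    truth = TruthRecord(spec.sample_id, spec.smn1_copies, spec.smn2_copies)
    return output_bam, truth


@dataclass(frozen=True)
class CohortManifest:
    """Paths and truth labels for a simulated cohort."""

    bam_paths: tuple[Path, ...]
    truth: tuple[TruthRecord, ...]
    truth_table_path: Path
    fasta_path: Path
    locus_config_path: Path


def _write_locus_config_file(config: LocusConfig, path: Path) -> None:
    path.write_text(
        f"[{config.build_name}]\n"
        f"smn1_chromosome = {config.smn1_chrom}\n"
        f"smn2_chromosome = {config.smn2_chrom}\n"
        f"smn1_c840_pos = {config.smn1_c840_pos}\n"
        f"smn2_c840_pos = {config.smn2_c840_pos}\n"
        f"smn1_base = {config.smn1_base}\n"
        f"smn2_base = {config.smn2_base}\n"
    )


def simulate_cohort(
    specs: Sequence[SimSpec], output_dir: str | Path
) -> CohortManifest:
    """One indexed BAM per spec plus a tab-separated truth table."""
    if not specs:
        raise ManifestError("no simulation specs given")
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ManifestError(f"duplicate sample ids: {', '.join(dupes)}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    fasta_path, config = build_mini_reference(output_dir)
    config_path = output_dir / "locus_config.cfg"
    _write_locus_config_file(config, config_path)

    paths: list[Path] = []
    truths: list[TruthRecord] = []
    for spec in specs:
        bam, truth = simulate_sample(
            spec, fasta_path, output_dir / f"{spec.sample_id}.bam"
        )
        paths.append(bam)
        truths.append(truth)

    truth_path = output_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tsmn1_copies\tsmn2_copies\texpected_status\n")
        for t in truths:
            fh.write(
                f"{t.sample_id}\t{t.smn1_copies}\t{t.smn2_copies}\t"
                f"{t.expected_status.value}\n"
            )
    return CohortManifest(
        tuple(paths), tuple(truths), truth_path, fasta_path, config_path
    )
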