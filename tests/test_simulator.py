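"""Simulator: mini-reference construction, seeded determinism, depth and
base-fraction calibration, mate-overlap option, cohort manifests."""

import numpy as np
import pysam
import pytest

from sma_caller.caller import CallStatus, call_sample
from sma_caller.errors import ManifestError
from sma_caller.locus_config import validate_reference_bases
from sma_caller.pileup import count_c840_reads
from sma_caller.simulator import (
    CONTIG_LENGTH,
    EXTRA_DIFF_POSITIONS_1BASED,
    KEY_POS_1BASED,
    SMN1_CONTIG,
    SMN2_CONTIG,
    SimSpec,
    TruthRecord,
    build_mini_reference,
    simulate_cohort,
    simulate_sample,
)


class TestMiniReference:
    def test_two_equal_length_contigs_with_few_diffs(self, mini_ref):
        fasta, _ = mini_ref
        with pysam.FastaFile(str(fasta)) as fa:
            assert set(fa.references) == {SMN1_CONTIG, SMN2_CONTIG}
            s1, s2 = fa.fetch(SMN1_CONTIG), fa.fetch(SMN2_CONTIG)
        assert len(s1) == len(s2) == CONTIG_LENGTH
        diffs = [i + 1 for i, (a, b) in enumerate(zip(s1, s2)) if a != b]
        assert len(diffs) <= 4
        near_key = [p for p in diffs if abs(p - KEY_POS_1BASED) <= 150]
        assert near_key == [KEY_POS_1BASED]
        assert s1[KEY_POS_1BASED - 1] == "C" and s2[KEY_POS_1BASED - 1] == "T"

    def test_validation_passes_by_construction(self, mini_ref):
        fasta, config = mini_ref
        assert validate_reference_bases(config, fasta).passed

    def test_rebuild_is_byte_identical(self, tmp_path, mini_ref):
        fasta, _ = mini_ref
        again, _ = build_mini_reference(tmp_path)
        assert again.read_bytes() == fasta.read_bytes()


class TestSimulateSample:
    def test_seeded_runs_are_byte_identical(self, mini_ref, tmp_path):
        fasta, _ = mini_ref
        spec = SimSpec(sample_id="det", smn1_copies=1, smn2_copies=2, seed=11)
        bam1, _ = simulate_sample(spec, fasta, tmp_path / "a.bam")
        bam2, _ = simulate_sample(spec, fasta, tmp_path / "b.bam")
        assert bam1.read_bytes() == bam2.read_bytes()

    def test_zero_copies_yields_valid_empty_bam(self, mini_ref, tmp_path):
        fasta, config = mini_ref
        bam, truth = simulate_sample(
            SimSpec(sample_id="del0", smn1_copies=0, smn2_copies=0, seed=1),
            fasta, tmp_path / "del0.bam",
        )
        counts = count_c840_reads(bam, config)
        assert counts.n_total == 0
        assert truth.expected_status is CallStatus.POSITIVE

    def test_depth_is_poisson_in_total_copies(self, mini_ref, tmp_path):
        fasta, config = mini_ref
        totals = []
        for seed in range(60):
            bam, _ = simulate_sample(
                SimSpec(sample_id="d", smn1_copies=2, smn2_copies=2,
                        mean_depth_per_copy=15.0, seed=seed),
                fasta, tmp_path / "d.bam",
            )
            totals.append(count_c840_reads(bam, config).n_total)
        mean = np.mean(totals)
        # Poisson(60): SE of the mean over 60 reps is 1; allow 4 SE
        assert abs(mean - 60.0) < 4.0

    def test_c_fraction_matches_copy_ratio(self, mini_ref, tmp_path):
        """smn1=smn2=2 at depth-per-copy 15: mean C fraction over 200
        replicate seeds sits within 0.5 +/- 0.03."""
        fasta, config = mini_ref
        fractions = []
        for seed in range(200):
            bam, _ = simulate_sample(
                SimSpec(sample_id="f", smn1_copies=2, smn2_copies=2, seed=seed),
                fasta, tmp_path / "f.bam",
            )
            c = count_c840_reads(bam, config)
            fractions.append(c.n_c / c.n_total)
        assert abs(np.mean(fractions) - 0.5) < 0.03

    def test_c_observations_without_smn1_come_from_errors(self, mini_ref, tmp_path):
        fasta, config = mini_ref
        n_c = n_tot = 0
        for seed in range(200):
            bam, _ = simulate_sample(
                SimSpec(sample_id="e", smn1_copies=0, smn2_copies=2, seed=seed),
                fasta, tmp_path / "e.bam",
            )
            c = count_c840_reads(bam, config)
            n_c += c.n_c
            n_tot += c.n_total
        # errors hit the key site at rate eps=0.005, of which 1/3 become 'C'
        assert 0.0 < n_c / n_tot < 0.01

    def test_mate_overlap_mode_still_counts_fragments_once(self, mini_ref, tmp_path):
        fasta, config = mini_ref
        bam, _ = simulate_sample(
            SimSpec(sample_id="ov", smn1_copies=2, smn2_copies=2,
                    force_mate_overlap=True, seed=5),
            fasta, tmp_path / "ov.bam",
        )
        frags, key_cover = set(), []
        with pysam.AlignmentFile(str(bam)) as af:
            for read in af.fetch(until_eof=True):
                frags.add(read.query_name)
                if read.reference_start <= KEY_POS_1BASED - 1 < read.reference_end:
                    key_cover.append(read)
        # both mates cover the key site, yet each fragment counts once
        assert len(key_cover) == 2 * len(frags)
        assert count_c840_reads(bam, config).n_total == len(frags)

    def test_no_duplicate_or_secondary_records_emitted(self, mini_ref, tmp_path):
        fasta, _ = mini_ref
        bam, _ = simulate_sample(
            SimSpec(sample_id="flags", smn1_copies=2, smn2_copies=1, seed=9),
            fasta, tmp_path / "flags.bam",
        )
        with pysam.AlignmentFile(str(bam)) as af:
            for read in af.fetch(until_eof=True):
                assert not read.is_duplicate and not read.is_secondary
                assert not read.is_supplementary and not read.is_qcfail

    def test_ambiguous_windows_get_mapq_zero(self, mini_ref, tmp_path):
        fasta, _ = mini_ref
        bam, _ = simulate_sample(
            SimSpec(sample_id="mq", smn1_copies=2, smn2_copies=2, seed=13),
            fasta, tmp_path / "mq.bam",
        )
        extra0 = {p - 1 for p in EXTRA_DIFF_POSITIONS_1BASED}
        with pysam.AlignmentFile(str(bam)) as af:
            pairs = {}
            for read in af.fetch(until_eof=True):
                if read.is_read1:
                    pairs[read.query_name] = read
            assert pairs
            for read in pairs.values():
                window = set(range(read.reference_start, read.reference_end))
                if not window & extra0:
                    assert read.mapping_quality == 0

    def test_copy_number_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimSpec(smn1_copies=6)
        with pytest.raises(ValueError):
            SimSpec(base_error_rate=0.2)


class TestParameterRecovery:
    def test_c_fraction_across_copy_grid(self, mini_ref, tmp_path):
        """Across the (smn1, smn2) grid, the mean key-site C fraction over
        replicate seeds lands within 3 standard errors of the error-adjusted
        copy ratio."""
        fasta, config = mini_ref
        eps = 0.005
        for smn1 in range(0, 4):
            for smn2 in range(0, 4):
                if smn1 == smn2 == 0:
                    continue
                f = smn1 / (smn1 + smn2)
                # a true-C base survives with prob 1-eps; other bases err to C
                # uniformly over the 3 alternatives
                expected = f * (1 - eps) + (1 - f) * (eps / 3)
                fracs = []
                for rep in range(200):
                    bam, _ = simulate_sample(
                        SimSpec(sample_id="g", smn1_copies=smn1, smn2_copies=smn2,
                                seed=100_000 + 1000 * smn1 + 100 * smn2 + rep),
                        fasta, tmp_path / "g.bam",
                    )
                    c = count_c840_reads(bam, config)
                    if c.n_total:
                        fracs.append(c.n_c / c.n_total)
                se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
                assert abs(np.mean(fracs) - expected) < 3 * max(se, 1e-4), (smn1, smn2)


class TestCohort:
    def test_manifest_and_truth_table(self, tmp_path):
        specs = [
            SimSpec(sample_id="s_pos", smn1_copies=0, smn2_copies=2, seed=1),
            SimSpec(sample_id="s_neg", smn1_copies=2, smn2_copies=2, seed=2),
            SimSpec(sample_id="s_thin", smn1_copies=1, smn2_copies=1,
                    mean_depth_per_copy=2.0, seed=3),
        ]
        manifest = simulate_cohort(specs, tmp_path / "cohort")
        assert len(manifest.bam_paths) == 3
        for bam in manifest.bam_paths:
            assert bam.exists()
            assert bam.with_suffix(".bam.bai").exists()
        lines = manifest.truth_table_path.read_text().strip().split("\n")
        assert lines[0] == "sample_id\tsmn1_copies\tsmn2_copies\texpected_status"
        assert len(lines) == 4
        assert manifest.fasta_path.exists()
        assert manifest.locus_config_path.exists()

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        specs = [SimSpec(sample_id="dup", seed=1), SimSpec(sample_id="dup", seed=2)]
        with pytest.raises(ManifestError, match="dup"):
            simulate_cohort(specs, tmp_path / "x")
        with pytest.raises(ManifestError):
            simulate_cohort([], tmp_path / "y")

    def test_end_to_end_truth_recovery(self, tmp_path, mini_config):
        specs = [
            SimSpec(sample_id=f"s{i}_{s1}_{s2}", smn1_copies=s1, smn2_copies=s2,
                    seed=40 + i)
            for i, (s1, s2) in enumerate(
                [(0, 2), (0, 3), (1, 1), (2, 2), (1, 3), (3, 2)]
            )
        ]
        manifest = simulate_cohort(specs, tmp_path / "e2e")
        for bam, truth in zip(manifest.bam_paths, manifest.truth):
            call = call_sample(bam, mini_config)
            if call.status is not CallStatus.NOT_ENOUGH_READS:
                assert call.status is truth.expected_status, truth


def test_truth_record_label_follows_smn1():
    assert TruthRecord("a", 0, 3).expected_status is CallStatus.POSITIVE
    assert TruthRecord("b", 1, 0).expected_status is CallStatus.NEGATIVE
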