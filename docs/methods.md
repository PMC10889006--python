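# Methods

## The statistic and its assumptions

The caller reduces each sample to two numbers: N, the count of qualifying
base observations overlapping the c.840 position of *SMN1* plus *SMN2*,
and r, the subset reading 'C'. Pooling both paralog positions is what makes
the method robust to the segmental duplication: it does not matter which
paralog a read was assigned to (or that its MAPQ is 0), only which base it
carries at the discriminating site. The assumptions are:

* reads are Illumina-style short reads from a BWA-like aligner, so every
  read derived from either paralog lands on one of the two configured
  positions;
* base calls at the site are independent across fragments;
* an individual with ≥ 1 functional *SMN1* copy carries at least 1 'C'
  haplotype among ≥ 2 total SMN copies, and total SMN copy number is
  bounded (0–5 per paralog is what is observed in populations).

The decision rule is a two-point likelihood-ratio test on r | N:
P('C') = ε under zero *SMN1* copies versus P('C') = θ under the least
favourable *SMN1*-present configuration. Working with the least favourable
θ (one 'C' copy of four, θ = 0.25) makes the test conservative against
every easier configuration (1/2, 2/4, …), whose likelihoods dominate H₁'s.
The llr10 = 0 contour is linear in (r, N):

r = c·N with c = log10((1−ε)/(1−θ)) / [log10((1−ε)/(1−θ)) − log10(ε/θ)],

c ≈ 0.0674 at the defaults. Ties (llr10 = 0) are called negative: a
positive SMA report requires positive evidence.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_coverage` | 14 | smallest callable N, inclusive (N = 13 is a no-call). Below this the test has little power and coverage itself signals assay failure at the locus. |
| `base_error_rate` ε | 0.005 | per-observation probability of reading 'C' with no *SMN1* present; post-quality-filter Illumina substitution scale. |
| `carrier_c_fraction` θ | 0.25 | expected 'C' fraction under the minimal *SMN1*-present genome (1 of 4 SMN copies). |
| `max_confidence` | 1000 phred | cosmetic cap keeping output finite at very high N. |
| `min_base_quality` | 13 | pileup base-quality floor (~5% error ceiling), the conventional default. |

Read-filter policy (the paper-gap decisions, recorded here as this
package's contract): duplicate, secondary, supplementary, unmapped and
QC-fail records never count; no MAPQ filter (it would discard nearly all
reads at this locus); overlapping mates of a fragment are one observation,
taking the higher-quality base (ties → first encountered) because the two
mates are not independent evidence; deletions/reference skips spanning the
site contribute no observation; 'N' and other non-C/T bases count toward N
(they are reads overlapping the position and keeping them is conservative
for the coverage gate) but support neither hypothesis asymmetrically.
On GRCh38, only the primary-assembly chromosome 5 positions are counted;
a header advertising SMN-region ALT contigs triggers a warning since a
non-ALT-aware alignment can divert reads there.

## Locus configuration

Coordinates are 1-based (HGVS/VCF convention) and stored per build;
chromosome-name dialects ("5" vs "chr5") are resolved against each file's
header at run time. GRCh37 (5:70247773 / 5:69372353) and GRCh38
(5:70951946 / 5:70076526) are bundled. T2T-CHM13 coordinates are bundled
as best-available values for the original locus and should be confirmed
once against a local CHM13 FASTA with `validate-reference`; the package
also provides `derive_positions_by_flank_match`, which lifts the positions
onto any assembly by requiring a unique exact match of the ±30 bp GRCh38
flank and then re-validating the C/T bases, so an off-by-one cannot
survive the check. The base check against the FASTA is always the source
of truth; `validate-reference` should be run once per new reference.

## What the simulator emulates — and what it does not

The simulator writes alignments directly rather than invoking an external
aligner. It reproduces the features the caller is sensitive to: two
near-identical ~2 kb paralog contigs differing at the key site (plus ≤ 3
distinguishing bases placed outside any 150 bp read window over the key
site), fragment counts Poisson(depth-per-copy × total copies), paralog of
origin categorical in the copy numbers, uniform base miscalls, and MAPQ 0
for pairs whose key-covering window contains no distinguishing base
besides the key site. Pairs are placed on the single contig best matching
the key-covering mate, since real aligners keep mates together. By default
only one mate covers the key site; `force_mate_overlap` exercises the
mate-deduplication path.

It does **not** model indels, sequencing-error profiles beyond uniform
substitution, gene-conversion breakpoints, exome/panel capture bias, or
reference bias in alignment. Passing the simulated-recovery tests
therefore demonstrates that the counting and decision machinery is
correct under the stated sampling model — not that the fixed ε and θ are
optimal for any particular real instrument or capture chemistry.
Everything is deterministic given the spec's seed, including file bytes
(headers carry no timestamps).

## Numerical and reporting choices

* Fisher's exact test (two-sided) uses the point-probability convention —
  sum over the hypergeometric support of all tables at most as probable as
  the observed one (relative tolerance 1e-7, as in the standard stacks) —
  computed from the hypergeometric log-pmf, so margins near 200,000 are
  handled without overflow; the support, bounded by the smallest margin,
  stays tiny.
* Percent renderings: PPV rounds to whole percent. No-call rates at or
  above 0.1% round to one decimal; below that they are truncated (floored)
  at three decimals so a rare-event rate is never rounded up — this
  reproduces the published renderings exactly (85/198,868 → "0.042%").
* Concordance between two call sets is computed over samples with a
  definitive call in both; no-calls and errors are excluded from the
  denominator and listed separately.
* Batch runs never abort on a bad sample: the row gets status `error`
  with the reason, and the process exit code signals the failure.

## Problem sizes

The published cohort analyses (tens of thousands to ~200k samples) enter
only through their printed count tables, on which the evaluation
arithmetic is exact. The simulated accuracy study uses 1000 end-to-end
samples per copy-number configuration at depth-per-copy 15 — configurations
(0,2), (0,3), (0,4) for positives and (1,1), (1,2), (1,3), (2,2) for
negatives, with (1,3) the design stress point where the true 'C' fraction
equals θ. Calibration checks in the test suite use 200 replicate seeds per
configuration.

## Known limitations

* Only the zero-vs-nonzero *SMN1* question is answered; carrier status and
  *SMN2* copy number are out of scope, and pathogenic variants that do not
  disrupt c.840 are missed (false negatives by design).
* Exact numeric agreement with any other implementation's confidence
  score is not claimed — the boundary slope and score scale are this
  package's own definition; agreement is asserted in call status against
  simulated truth.
* The bundled T2T-CHM13 coordinates require one-time validation against a
  local FASTA (see above).
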