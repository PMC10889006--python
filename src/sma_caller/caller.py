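"""Likelihood-ratio classification of SMA status from c.840 counts.

Given N base observations at c.840 (both paralogs pooled) of which r show
'C', compare two binomial hypotheses:

* H0 — zero functional *SMN1* copies: a 'C' arises only through a base-call
  error, with probability ``base_error_rate`` (epsilon).
* H1 — at least one *SMN1* copy: the smallest plausible 'C' fraction is one
  *SMN1* copy out of four total SMN copies, ``carrier_c_fraction`` (theta)
  = 0.25.

The base-10 log-likelihood ratio is

    llr10(r, N) = r * log10(eps/theta) + (N - r) * log10((1-eps)/(1-theta))

A sample is called positive (has SMA) iff llr10 > 0, so the decision
boundary llr10 = 0 is the straight line r = slope * N.  Confidence is the
phred-scaled magnitude 10*|llr10|, capped.  Samples with N below the
coverage gate (default 14, inclusive) are no-calls regardless of r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .errors import ContractError
from .locus_config import LocusConfig
from .pileup import PileupCounts, ReadFilters, count_c840_reads


class CallStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_ENOUGH_READS = "not_enough_reads"


@dataclass(frozen=True)
class CallerParams:
    """Decision-rule parameters.

    min_coverage: smallest callable N (inclusive).
    base_error_rate: P('C' observation | zero SMN1 copies), epsilon.
    carrier_c_fraction: expected 'C' fraction under the minimal
        SMN1-present configuration (1 of 4 SMN copies), theta.
    max_confidence: cap on the reported phred score.
    """

    min_coverage: int = 14
    base_error_rate: float = 0.005
    carrier_c_fraction: float = 0.25
    max_confidence: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_error_rate < self.carrier_c_fraction < 1.0):
            raise ContractError(
                "need 0 < base_error_rate < carrier_c_fraction < 1, got "
                f"{self.base_error_rate} / {self.carrier_c_fraction}"
            )
        if self.min_coverage < 1 or self.max_confidence <= 0:
            raise ContractError("min_coverage >= 1 and max_confidence > 0 required")

    @property
    def boundary_slope(self) -> float:
        """c such that the llr10 = 0 contour is r = c * N."""
        up = math.log10((1 - self.base_error_rate) / (1 - self.carrier_c_fraction))
        down = math.log10(self.base_error_rate / self.carrier_c_fraction)
        return up / (up - down)


@dataclass(frozen=True)
class SmaCall:
    """Classification for one sample: status, phred confidence, and the
    r / N counts it was based on."""

    sample_id: str
    status: CallStatus
    confidence: float
    r: int
    n: int


def log_likelihood_ratio10(r: int, n: int, params: CallerParams) -> float:
    """Base-10 log LR of H0 (no SMN1) over H1 (SMN1 present)."""
    eps = params.base_error_rate
    theta = params.carrier_c_fraction
    return r * math.log10(eps / theta) + (n - r) * math.log10(
        (1 - eps) / (1 - theta)
    )


def classify(counts: PileupCounts, params: CallerParams | None = None) -> SmaCall:
    """Apply the coverage gate and the likelihood-ratio rule to one sample.

    Ties (llr10 exactly 0) are called negative: a positive SMA report
    requires positive evidence.
    """
    params = params or CallerParams()
    counts.validate()
    r, n = counts.n_c, counts.n_total
    if not 0 <= r <= n:
        raise ContractError(f"invalid counts r={r}, N={n}")
    if n < params.min_coverage:
        return SmaCall(counts.sample_id, CallStatus.NOT_ENOUGH_READS, 0.0, r, n)
    llr10 = log_likelihood_ratio10(r, n, params)
    status = CallStatus.POSITIVE if llr10 > 0 else CallStatus.NEGATIVE
    confidence = min(10.0 * abs(llr10), params.max_confidence)
    return SmaCall(counts.sample_id, status, confidence, r, n)


def call_sample(
    alignments: str | Path,
    config: LocusConfig,
    params: CallerParams | None = None,
    filters: ReadFilters | None = None,
    reference_fasta: str | Path | None = None,
) -> SmaCall:
    """End-to-end call for one alignment file: pileup then classify."""
    counts = count_c840_reads(
        alignments, config, filters=filters, reference_fasta=reference_fasta
    )
    return classify(counts, params)
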