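"""Validation arithmetic: PPV, no-call rates, Fisher's exact test,
call-set concordance, and the r-vs-N diagnostic scatter plot."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .caller import CallerParams
from .errors import ContractError, SmaCallerError, UndefinedMetricError

CALLED_STATUSES = {"has_sma", "does_not_have_sma", "positive", "negative"}
_POSITIVE_STATUSES = {"has_sma", "positive"}


def compute_ppv(tp: int, fp: int) -> float:
    """Positive predictive value tp/(tp+fp)."""
    if tp < 0 or fp < 0:
        raise ContractError("counts must be non-negative")
    if tp + fp == 0:
        raise UndefinedMetricError("PPV undefined with no positive calls")
    return tp / (tp + fp)


def render_ppv_percent(ppv: float) -> str:
    """Whole-percent rendering for reporting, e.g. 0.9655 -> '97%'."""
    return f"{round(ppv * 100):.0f}%"


def nocall_rate(n_nocall: int, n_total: int) -> float:
    if n_total <= 0:
        raise UndefinedMetricError("no-call rate undefined for empty cohort")
    if not 0 <= n_nocall <= n_total:
        raise ContractError("need 0 <= n_nocall <= n_total")
    return n_nocall / n_total


def render_rate_percent(fraction: float) -> str:
    """Percent rendering: one rounded decimal at or above 0.1%, otherwise
    three decimals truncated toward zero (a rare-event rate is never
    rounded up into visibility)."""
    pct = fraction * 100.0
    if pct == 0.0:
        return "0.0%"
    if pct >= 0.1:
        return f"{pct:.1f}%"
    truncated = math.floor(pct * 1000 + 1e-9) / 1000
    return f"{truncated:.3f}%"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = assay type and columns = no-call vs called."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ContractError("contingency table is all zero")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Point-probability method: with margins fixed, sum the hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed one (within a small relative tolerance, as is standard).
    Probabilities come from the hypergeometric log-pmf, so margins in the
    hundreds of thousands are exact to double precision — the support,
    bounded by the smallest margin, stays tiny.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    logp = hypergeom.logpmf(support, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    keep = logp <= log_obs + 1e-7
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class CohortEval:
    """Confusion counts of a call set against a truth table."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_nocall: int
    n_error: int = 0

    @property
    def ppv(self) -> float:
        return compute_ppv(self.tp, self.fp)

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("no truth positives")
        return self.tp / (self.tp + self.fn)


def _status_series(calls: pd.DataFrame) -> pd.Series:
    col = "sma_status" if "sma_status" in calls.columns else "status"
    if col not in calls.columns:
        raise SmaCallerError("call set needs an 'sma_status' or 'status' column")
    return calls.set_index("sample_id")[col].astype(str)


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> CohortEval:
    """Confusion matrix of a results table against a truth table.

    ``truth`` needs sample_id and expected_status (or truth_status)
    columns; no-calls and errors are tallied separately, not as false
    negatives.
    """
    status = _status_series(calls)
    tcol = "expected_status" if "expected_status" in truth.columns else "truth_status"
    expected = truth.set_index("sample_id")[tcol].astype(str)
    shared = status.index.intersection(expected.index)
    if shared.empty:
        raise SmaCallerError("no shared sample ids between calls and truth")
    tp = fp = tn = fn = nocall = nerror = 0
    for sid in shared:
        s, t = status[sid], expected[sid]
        truth_pos = t in _POSITIVE_STATUSES
        if s == "error":
            nerror += 1
        elif s not in CALLED_STATUSES:
            nocall += 1
        elif s in _POSITIVE_STATUSES:
            tp, fp = (tp + 1, fp) if truth_pos else (tp, fp + 1)
        else:
            tn, fn = (tn + 1, fn) if not truth_pos else (tn, fn + 1)
    return CohortEval(tp, fp, tn, fn, nocall, nerror)


@dataclass(frozen=True)
class ConcordanceResult:
    concordance: float
    n_compared: int
    discordant: tuple[tuple[str, str, str], ...]  # (sample_id, status_a, status_b)
    excluded: tuple[str, ...]  # shared ids not called in both sets


def compare_call_sets(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> ConcordanceResult:
    """Status concordance over samples callable in both sets.

    The denominator excludes samples that are no-call or error in either
    set; those are listed in ``excluded`` so coverage failures remain
    visible without diluting the concordance estimate.
    """
    sa, sb = _status_series(calls_a), _status_series(calls_b)
    shared = sa.index.intersection(sb.index)
    if shared.empty:
        raise SmaCallerError("call sets share no sample ids")
    discordant = []
    excluded = []
    n_compared = 0
    n_same = 0
    for sid in shared:
        a, b = sa[sid], sb[sid]
        if a not in CALLED_STATUSES or b not in CALLED_STATUSES:
            excluded.append(sid)
            continue
        n_compared += 1
        if (a in _POSITIVE_STATUSES) == (b in _POSITIVE_STATUSES):
            n_same += 1
        else:
            discordant.append((sid, a, b))
    if n_compared == 0:
        raise SmaCallerError("no samples callable in both sets")
    return ConcordanceResult(
        n_same / n_compared, n_compared, tuple(discordant), tuple(excluded)
    )


def plot_r_vs_n(
    rows: pd.DataFrame,
    params: CallerParams | None = None,
    output: str | Path = "r_vs_n.png",
) -> Path:
    """Diagnostic scatter of r (x) against N (y) with the decision boundary.

    Both axes are symlog — linear up to the coverage gate (14), then
    logarithmic — so the whole cohort and the near-origin positives are
    visible at once; the llr10 = 0 boundary line therefore appears curved
    although it is straight in Cartesian coordinates.  The gray band marks
    the no-call region N < min_coverage.  Marginal histograms show the
    distributions of r and N.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rows.empty:
        raise SmaCallerError("nothing to plot")
    params = params or CallerParams()
    rcol = "c840_reads_with_smn1_base_C" if "c840_reads_with_smn1_base_C" in rows else "r"
    ncol = "c840_total_reads" if "c840_total_reads" in rows else "n"
    scol = "sma_status" if "sma_status" in rows.columns else "status"
    r = pd.to_numeric(rows[rcol], errors="coerce")
    n = pd.to_numeric(rows[ncol], errors="coerce")
    status = rows[scol].astype(str)
    ok = (r.notna() & n.notna()).values
    r, n, status = r.values[ok], n.values[ok], status.values[ok]

    fig = plt.figure(figsize=(7, 7))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 5), hspace=0.05, wspace=0.05
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)

    palette = {
        "has_sma": ("tab:red", "positive"),
        "does_not_have_sma": ("tab:gray", "negative"),
        "not_enough_reads": ("tab:blue", "no-call"),
        "error": ("black", "error"),
    }
    for key, (color, label) in palette.items():
        mask = status == key
        if mask.any():
            ax.scatter(
                r[mask], n[mask], s=14, c=color, label=label, alpha=0.7, zorder=3
            )

    nmax = max(float(n.max()), params.min_coverage * 4)
    grid = np.linspace(0, nmax * 1.1, 200)
    ax.plot(
        params.boundary_slope * grid, grid, color="red", lw=1.2,
        label="decision boundary", zorder=2,
    )
    ax.axhspan(0, params.min_coverage, color="0.85", zorder=1)
    linthresh = max(params.min_coverage, 1)
    for a in (ax,):
        a.set_xscale("symlog", linthresh=linthresh)
        a.set_yscale("symlog", linthresh=linthresh)
    ax.set_xlim(left=-0.5)
    ax.set_ylim(bottom=-0.5)
    ax.set_xlabel("reads with 'C' at c.840 (r)")
    ax.set_ylabel("total reads over c.840 in SMN1 + SMN2 (N)")
    ax.legend(loc="upper left", fontsize=8)

    bins = np.linspace(0, max(float(r.max()), 1) + 1, 30)
    ax_top.hist(r, bins=bins, color="0.6")
    ax_right.hist(n, bins=np.linspace(0, nmax + 1, 30), color="0.6",
                  orientation="horizontal")
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)

    output = Path(output)
    fig.savefig(output, dpi=120)
    plt.close(fig)
    return output
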