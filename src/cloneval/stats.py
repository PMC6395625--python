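"""Estimators on top of verdicts: PCR fidelity, quality-filter loss, and the
barcoding-vs-validation read budget."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .select import Read, VariantCall
from .validation import TRUE_VARIANT, Verdict


def doublings_from_copies(initial_copies: float, final_copies: float) -> float:
    """Effective PCR doubling events, d = log2(final / initial), from qPCR
    quantification of the library before and after amplification."""
    if initial_copies <= 0 or final_copies <= 0:
        raise ValueError("copy numbers must be positive")
    return math.log2(final_copies / initial_copies)


@dataclass(frozen=True)
class ErrorRateEstimate:
    """PCR-induced error rate per base per doubling.

    rate = true_variant_bases / assayed_bases / doublings, with an exact
    (Garwood) Poisson confidence interval on the validated mutation count
    propagated to the rate.  ``assayed_bases`` excludes primer-masked bases.
    """

    true_variant_bases: int
    assayed_bases: int
    doublings: float
    rate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def pcr_error_rate(
    true_variant_bases: int,
    assayed_bases: int,
    doublings: float,
    confidence: float = 0.95,
) -> ErrorRateEstimate:
    if assayed_bases <= 0:
        raise ValueError("assayed_bases must be positive")
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    k = int(true_variant_bases)
    alpha = 1 - confidence
    lo = 0.0 if k == 0 else 0.5 * _st.chi2.ppf(alpha / 2, 2 * k)
    hi = 0.5 * _st.chi2.ppf(1 - alpha / 2, 2 * k + 2)
    denom = assayed_bases * doublings
    return ErrorRateEstimate(
        k, int(assayed_bases), float(doublings),
        rate=k / denom, ci_low=lo / denom, ci_high=hi / denom,
        confidence=confidence,
    )


def count_true_variant_bases(
    verdicts: Iterable[Verdict], include_primer: bool = False
) -> int:
    """Validated true-variant bases (primer-region calls excluded by default,
    since those can be oligo synthesis errors rather than PCR errors)."""
    return sum(
        v.variant.n_bases
        for v in verdicts
        if v.category == TRUE_VARIANT and (include_primer or not v.variant.in_primer)
    )


# ---------------------------------------------------------------------------
# quality filtering

MEAN_Q = "mean_q"
FRACTION_ABOVE = "fraction_above"


def quality_filter(
    reads: Sequence[Read],
    q_threshold: float,
    mode: str = MEAN_Q,
    p_fraction: float = 0.5,
) -> list[Read]:
    """Reads surviving a Phred-quality filter.

    ``mean_q`` keeps reads whose mean Phred score is >= the threshold (the
    common average-quality trimming convention); ``fraction_above`` keeps
    reads where at least ``p_fraction`` of bases have Q >= threshold (the
    ``-q N -p P`` convention, inclusive comparisons on both counts).
    """
    if mode not in (MEAN_Q, FRACTION_ABOVE):
        raise ValueError(f"unknown quality filter mode {mode!r}")
    if mode == FRACTION_ABOVE and not 0 < p_fraction <= 1:
        raise ValueError("p_fraction must lie in (0, 1]")
    kept = []
    for r in reads:
        if mode == MEAN_Q:
            ok = r.quals.mean() >= q_threshold
        else:
            ok = (r.quals >= q_threshold).mean() >= p_fraction
        if ok:
            kept.append(r)
    return kept


@dataclass
class QcLossCurve:
    """Reads, variant calls and validated true variants surviving each
    quality threshold; all three are non-increasing in the threshold."""

    table: pd.DataFrame  # threshold, reads, calls, true_variants, true_loss_vs_first

    def knee(self) -> float | None:
        """Threshold with the steepest drop in retained true variants."""
        t = self.table
        if len(t) < 2:
            return None
        drops = -np.diff(t["true_variants"].to_numpy())
        return float(t["threshold"].iloc[int(np.argmax(drops)) + 1])


def qc_loss_analysis(
    reads: Sequence[Read],
    calls: Sequence[VariantCall],
    verdicts: Sequence[Verdict],
    thresholds: Sequence[float],
    mode: str = MEAN_Q,
    p_fraction: float = 0.5,
) -> QcLossCurve:
    """How much quality control costs in validated true variants.

    For each threshold: reads retained, variant calls on retained reads, and
    true-variant verdicts on retained reads, plus the fraction of the first
    (loosest) threshold's true variants lost.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    true_ids: dict[str, int] = {}
    for v in verdicts:
        if v.category == TRUE_VARIANT:
            true_ids[v.variant.read_id] = true_ids.get(v.variant.read_id, 0) + 1
    calls_per_read: dict[str, int] = {}
    for c in calls:
        calls_per_read[c.read_id] = calls_per_read.get(c.read_id, 0) + 1

    rows = []
    for t in thresholds:
        kept = quality_filter(reads, t, mode, p_fraction)
        kept_ids = {r.read_id for r in kept}
        rows.append(
            {
                "threshold": t,
                "reads": len(kept),
                "calls": sum(calls_per_read.get(i, 0) for i in kept_ids),
                "true_variants": sum(true_ids.get(i, 0) for i in kept_ids),
            }
        )
    df = pd.DataFrame(rows)
    first = df["true_variants"].iloc[0]
    df["true_loss_vs_first"] = np.where(
        first > 0, (first - df["true_variants"]) / max(first, 1), 0.0
    )
    return QcLossCurve(df)


# ---------------------------------------------------------------------------
# read-budget model


@dataclass
class BudgetModel:
    """Read budgets of barcoded consensus sequencing vs post-hoc clone
    validation, for a panel of ``n_sites`` rare-variant sites.

    The model (deliberately simple, and echoed in the output so alternates can
    be swapped in): one sequencing run of at least ``run_reads`` reads covers
    the panel at ``per_site_depth``; a read spans ``sites_per_read`` candidate
    sites.  Barcoding must replicate the *entire* run ``barcode_depth`` times
    - including every non-target read, which is what makes it expensive.
    Validation re-sequences only flagged clones: ``ngs_error_rate x
    per_site_depth x n_sites`` false calls plus ``true_calls`` real ones, each
    costing ``validation_reads_per_call`` reads.
    """

    n_sites: int = 1000
    ngs_error_rate: float = 1e-3  # per base, the modern-instrument figure
    barcode_depth: int = 10  # replicate reads per molecule for consensus
    per_site_depth: int = 100
    validation_reads_per_call: float = 1000.0
    run_reads: float = 1e5  # minimum economical run size
    sites_per_read: float = 200.0
    true_calls: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "n_sites", "ngs_error_rate", "barcode_depth", "per_site_depth",
            "run_reads", "sites_per_read",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def _run(self, n_sites: float) -> float:
        return max(self.run_reads, self.per_site_depth * n_sites / self.sites_per_read)

    def reads_barcoding(self, n_sites: float | None = None) -> float:
        n = self.n_sites if n_sites is None else n_sites
        return self.barcode_depth * self._run(n)

    def reads_validation(self, n_sites: float | None = None) -> float:
        n = self.n_sites if n_sites is None else n_sites
        flagged = self.ngs_error_rate * self.per_site_depth * n + self.true_calls
        return self._run(n) + self.validation_reads_per_call * flagged

    def equations(self) -> str:
        return (
            "run(n) = max(run_reads, per_site_depth * n / sites_per_read); "
            "reads_barcoding(n) = barcode_depth * run(n); "
            "reads_validation(n) = run(n) + validation_reads_per_call * "
            "(ngs_error_rate * per_site_depth * n + true_calls)"
        )


@dataclass
class BudgetResult:
    reads_barcoding: float
    reads_validation: float
    crossover_sites: float  # inf when validation never catches up
    model: BudgetModel
    equations: str = ""


def budget_crossover(model: BudgetModel) -> BudgetResult:
    """Budgets at ``model.n_sites`` and the panel size where they cross.

    Below the crossover, selective clone validation spends fewer reads than
    barcoding the whole run; with the defaults (0.1% error rate, barcode
    depth 10) the crossover sits on the order of 10^4 sites, shrinking in
    inverse proportion to the error rate.
    """
    f = lambda n: model.reads_barcoding(n) - model.reads_validation(n)
    crossover = math.inf
    lo, hi = 1.0, 1.0e12
    if f(lo) > 0 and f(hi) < 0:
        from scipy.optimize import brentq

        crossover = float(brentq(f, lo, hi, xtol=1e-6, rtol=1e-12))
    elif f(lo) <= 0:
        crossover = lo  # validation never cheaper
    return BudgetResult(
        model.reads_barcoding(),
        model.reads_validation(),
        crossover,
        model,
        model.equations(),
    )
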