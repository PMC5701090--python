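"""Case/control locus screening for informative microsatellite markers.

For every locus, the *modal* genotype is the most frequent genotype among
control samples and the *predominant cancer* genotype is the most frequent
among cases; either is additionally flagged "predominant" when it covers
strictly more than half of the called samples in its cohort.  Two screening
modes are supported:

discovery
    A 2x2 Fisher exact test on modal vs non-modal genotype counts in
    cases and controls, with Benjamini-Hochberg FDR control across loci;
    a locus is informative when its adjusted p-value clears the cutoff.

validation
    A locus is informative when the control modal genotype and the case
    predominant genotype are each predominant (>50% of called samples)
    and differ from each other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotyper import Genotype, GenotypeMatrix

__all__ = [
    "LocusStats",
    "modal_genotype",
    "predominant_genotype",
    "fisher_modal_test",
    "bh_fdr",
    "locus_odds_ratio",
    "select_informative_loci",
    "stats_to_dataframe",
]


class UnscreenableLocus(ValueError):
    """Raised when a cohort has no called genotypes at a locus."""


@dataclass
class LocusStats:
    """Per-locus screening result."""

    locus_id: str
    modal_genotype: Genotype
    modal_freq_controls: float
    modal_predominant: bool
    predominant_cancer_genotype: Optional[Genotype]
    predominant_freq_cases: float
    cancer_predominant: bool
    counts2x2: tuple[int, int, int, int]  # case-modal, case-nonmodal, control-modal, control-nonmodal
    fisher_p: float
    bh_q: float
    informative: bool
    odds_ratio: float
    call_rate: float

    @property
    def risk_genotype(self) -> Optional[Genotype]:
        """Risk genotype used by a validation-mode classifier."""
        return self.predominant_cancer_genotype


def _most_frequent(calls: Sequence[Optional[Genotype]]) -> tuple[Genotype, float, bool]:
    called = [c for c in calls if c is not None]
    if not called:
        raise UnscreenableLocus("no called genotypes in cohort")
    counts = Counter((c.a1, c.a2) for c in called)
    top_count = max(counts.values())
    # ties broken to the lexicographically smallest (a1, a2) pair
    top = min(pair for pair, n in counts.items() if n == top_count)
    freq = top_count / len(called)
    return Genotype(*top), freq, freq > 0.5


def modal_genotype(control_calls: Sequence[Optional[Genotype]]) -> tuple[Genotype, float, bool]:
    """Most frequent control genotype, its frequency, and predominance.

    Frequency denominator is the number of *called* controls; missing
    calls never count.  Predominance is strict (>0.5), so an exact tie
    is never predominant.
    """
    return _most_frequent(control_calls)


def predominant_genotype(case_calls: Sequence[Optional[Genotype]]) -> tuple[Genotype, float, bool]:
    """Most frequent case genotype, its frequency, and predominance."""
    return _most_frequent(case_calls)


def fisher_modal_test(
    case_modal: int, case_nonmodal: int, control_modal: int, control_nonmodal: int
) -> float:
    """Two-sided Fisher exact p for a modal/non-modal 2x2 table.

    Uses the conventional two-sided definition: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more likely than the
    observed one.  A degenerate margin gives p = 1.
    """
    table = np.array([[case_modal, case_nonmodal], [control_modal, control_nonmodal]])
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if table.sum(axis=1).min() < 1:
        raise ValueError("both cohorts need at least one called sample")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(
    pvalues: Sequence[float], q_cutoff: float = 0.0001
) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up adjusted p-values and significance calls.

    Adjusted values are p(i)*m/rank with running-minimum monotonization;
    a test is significant when its adjusted value is strictly below
    ``q_cutoff``.  Input order is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return [], []
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return adjusted.tolist(), (adjusted < q_cutoff).tolist()


def locus_odds_ratio(counts2x2: Sequence[int]) -> float:
    """Odds ratio (case-risk/case-nonrisk)/(control-risk/control-nonrisk).

    The Haldane-Anscombe continuity correction (+0.5 to every cell) is
    applied whenever any cell is zero, keeping the ratio finite.
    """
    a, b, c, d = (float(x) for x in counts2x2)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def select_informative_loci(
    matrix: GenotypeMatrix,
    mode: str = "validation",
    q_cutoff: float = 0.0001,
    min_call_rate: float = 0.5,
) -> list[LocusStats]:
    """Screen every adequately called locus and flag the informative ones.

    Loci with a call rate below ``min_call_rate`` (over all samples) or
    with an entirely missing cohort are excluded before testing.  In
    discovery mode the Fisher test compares modal vs non-modal genotype
    counts between cohorts with BH FDR across the screened loci; in
    validation mode informativeness is the two-sided predominance rule.
    The per-locus odds ratio orients the risk category (non-modal in
    discovery, the case-predominant genotype in validation) toward cases.
    """
    if mode not in ("discovery", "validation"):
        raise ValueError(f"unknown mode {mode!r}")
    cases = matrix.samples_by_label("case")
    controls = matrix.samples_by_label("control")
    if not cases or not controls:
        raise ValueError("matrix must contain both case and control samples")

    screened: list[LocusStats] = []
    for locus_id in matrix.loci:
        rate = matrix.call_rate(locus_id)
        if rate < min_call_rate:
            continue
        case_calls = [c for c in matrix.locus_calls(locus_id, "case") if c is not None]
        control_calls = [c for c in matrix.locus_calls(locus_id, "control") if c is not None]
        if not case_calls or not control_calls:
            continue
        modal, modal_freq, modal_pred = modal_genotype(control_calls)
        cancer, cancer_freq, cancer_pred = predominant_genotype(case_calls)

        case_modal = sum(1 for c in case_calls if c == modal)
        control_modal = sum(1 for c in control_calls if c == modal)
        counts = (
            case_modal,
            len(case_calls) - case_modal,
            control_modal,
            len(control_calls) - control_modal,
        )
        p = fisher_modal_test(*counts)

        if mode == "discovery":
            # risk category = non-modal
            or_counts = (counts[1], counts[0], counts[3], counts[2])
        else:
            case_risk = sum(1 for c in case_calls if c == cancer)
            control_risk = sum(1 for c in control_calls if c == cancer)
            or_counts = (
                case_risk,
                len(case_calls) - case_risk,
                control_risk,
                len(control_calls) - control_risk,
            )

        screened.append(
            LocusStats(
                locus_id=locus_id,
                modal_genotype=modal,
                modal_freq_controls=modal_freq,
                modal_predominant=modal_pred,
                predominant_cancer_genotype=cancer,
                predominant_freq_cases=cancer_freq,
                cancer_predominant=cancer_pred,
                counts2x2=counts,
                fisher_p=p,
                bh_q=np.nan,
                informative=False,
                odds_ratio=locus_odds_ratio(or_counts),
                call_rate=rate,
            )
        )

    if mode == "discovery":
        adjusted, significant = bh_fdr([s.fisher_p for s in screened], q_cutoff)
        for s, q, sig in zip(screened, adjusted, significant):
            s.bh_q = q
            s.informative = sig
    else:
        for s in screened:
            s.informative = (
                s.modal_predominant
                and s.cancer_predominant
                and s.predominant_cancer_genotype != s.modal_genotype
            )
    return screened


def stats_to_dataframe(screened: Sequence[LocusStats]) -> pd.DataFrame:
    """Flatten LocusStats records to a tidy per-locus table."""
    rows = []
    for s in screened:
        rows.append(
            {
                "locus_id": s.locus_id,
                "modal_genotype": f"{s.modal_genotype.a1}/{s.modal_genotype.a2}",
                "modal_freq_controls": s.modal_freq_controls,
                "modal_predominant": s.modal_predominant,
                "predominant_cancer_genotype": (
                    f"{s.predominant_cancer_genotype.a1}/{s.predominant_cancer_genotype.a2}"
                    if s.predominant_cancer_genotype
                    else MISSING_STR
                ),
                "predominant_freq_cases": s.predominant_freq_cases,
                "cancer_predominant": s.cancer_predominant,
                "case_modal": s.counts2x2[0],
                "case_nonmodal": s.counts2x2[1],
                "control_modal": s.counts2x2[2],
                "control_nonmodal": s.counts2x2[3],
                "fisher_p": s.fisher_p,
                "bh_q": s.bh_q,
                "informative": s.informative,
                "odds_ratio": s.odds_ratio,
                "call_rate": s.call_rate,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


MISSING_STR = "."
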