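"""Validation arithmetic: confusion-matrix construction with VUS-exclusion
semantics and the standard classifier performance ratios.

The five-tier classes are collapsed for validation: classes 4 and 5 count
as a positive (pathogenic) test, classes 1 and 2 as a negative (benign)
test, class 3 (VUS) is tallied separately per truth stratum and excluded
from sensitivity/specificity/PPV/NPV.  PIEV calls are outside the binary
contrast and are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Dict, List, Optional, Sequence, Union

from .core import ConfusionCounts, FinalClass, InputError, PIEV_CLASS


class Truth(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"


class Collapsed(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    VUS = "VUS"
    PIEV = "PIEV"


def collapse_class(c: FinalClass) -> Collapsed:
    """Merge likely classes with their definite neighbours: {4,5} positive,
    {1,2} negative, 3 VUS; PIEV stays apart."""
    if c == PIEV_CLASS:
        return Collapsed.PIEV
    if c in (4, 5):
        return Collapsed.POSITIVE
    if c in (1, 2):
        return Collapsed.NEGATIVE
    if c == 3:
        return Collapsed.VUS
    raise InputError(f"not a final class: {c!r}")


def confusion(
    truth: Sequence[Union[Truth, str]], predicted: Sequence[FinalClass]
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with per-stratum VUS counts.

    TP: truth-pathogenic predicted 4/5.  FN: truth-pathogenic predicted
    1/2.  FP and TN mirror on the benign stratum.  VUS predictions land in
    the stratum's VUS counter; PIEV predictions are excluded from all
    tallies.
    """
    if len(truth) != len(predicted):
        raise InputError(
            f"truth and prediction lengths differ: {len(truth)} vs {len(predicted)}"
        )
    tp = fp = fn = tn = vp = vb = 0
    for t, p in zip(truth, predicted):
        t = Truth(t)
        c = collapse_class(p)
        if c is Collapsed.PIEV:
            continue
        if t is Truth.PATHOGENIC:
            if c is Collapsed.POSITIVE:
                tp += 1
            elif c is Collapsed.NEGATIVE:
                fn += 1
            else:
                vp += 1
        else:
            if c is Collapsed.NEGATIVE:
                tn += 1
            elif c is Collapsed.POSITIVE:
                fp += 1
            else:
                vb += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           vus_pathogenic=vp, vus_benign=vb)


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """Performance ratios with their display renderings.

    Ratios are full precision; ``*_pct`` displays round half-up to one
    decimal for the four metrics and to the nearest integer for the VUS
    rates.  A zero denominator makes a metric absent (None), never an
    error.
    """

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    vus_rate_pathogenic: Optional[float]
    vus_rate_benign: Optional[float]

    def display(self) -> Dict[str, Optional[float]]:
        def pct1(x: Optional[float]) -> Optional[float]:
            return None if x is None else _round_half_up(100.0 * x, 1)

        def pct0(x: Optional[float]) -> Optional[float]:
            return None if x is None else _round_half_up(100.0 * x, 0)

        return {
            "sensitivity_pct": pct1(self.sensitivity),
            "specificity_pct": pct1(self.specificity),
            "ppv_pct": pct1(self.ppv),
            "npv_pct": pct1(self.npv),
            "vus_rate_pathogenic_pct": pct0(self.vus_rate_pathogenic),
            "vus_rate_benign_pct": pct0(self.vus_rate_benign),
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and the two VUS rates."""
    return MetricsReport(
        counts=c,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        vus_rate_pathogenic=_ratio(c.vus_pathogenic, c.total_pathogenic),
        vus_rate_benign=_ratio(c.vus_benign, c.total_benign),
    )


def format_report(report: MetricsReport, name: str = "classifier") -> str:
    """Plain-text rendering of one validation row."""
    d = report.display()
    c = report.counts
    lines = [
        f"{name}: TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn} "
        f"VUS(path)={c.vus_pathogenic} VUS(benign)={c.vus_benign}",
    ]
    for key in ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct",
                "vus_rate_pathogenic_pct", "vus_rate_benign_pct"):
        val = d[key]
        lines.append(f"  {key}: {'n/a' if val is None else val}")
    return "\n".join(lines)
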