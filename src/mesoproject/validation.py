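"""Expected/observed (E/O) validation and model selection.

A projection model is validated on a holdout window by the ratio of its
expected case count E to the observed count O.  The 95% confidence interval
uses the normal approximation to the Poisson distribution of O:

    (E/O) * exp(+/- z * sqrt(1/O)),    z = 1.96 at alpha = 0.05,

which is symmetric on the log scale.  Among candidate models, the one whose
E/O ratio is closest to 1 is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import norm

__all__ = [
    "EOResult",
    "SelectionOutcome",
    "eo_ratio",
    "eo_ci",
    "evaluate_eo",
    "select_model",
    "sum_periods",
    "round_half_away",
    "eo_table",
]


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (table-reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def eo_ratio(expected: float, observed: float) -> float:
    """E/O ratio; observed must be a positive count."""
    if observed <= 0:
        raise ValueError(f"observed count must be > 0, got {observed}")
    if expected < 0:
        raise ValueError(f"expected count must be >= 0, got {expected}")
    return expected / observed


def eo_ci(ratio: float, observed_ci: float, alpha: float = 0.05
          ) -> tuple[float, float]:
    """Poisson normal-approximation CI for an E/O ratio.

    ``observed_ci`` is the count inside sqrt(1/O); it may differ from the
    stratum's own O in legacy-pooled mode (see :func:`evaluate_eo`).
    """
    if observed_ci <= 0:
        raise ValueError(f"observed count for the CI must be > 0, got {observed_ci}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z = norm.ppf(1 - alpha / 2)
    half = z * (1.0 / observed_ci) ** 0.5
    from math import exp
    return ratio * exp(-half), ratio * exp(half)


@dataclass
class EOResult:
    """One validation atom: expected vs observed with its CI."""

    expected: float
    observed: int
    ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    label: str = ""
    observed_ci: int | None = None   # count used inside the CI formula

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValueError("ratio must lie inside its own confidence interval")


def evaluate_eo(expected: float, observed: int, label: str = "",
                alpha: float = 0.05, observed_ci: int | None = None) -> EOResult:
    """Compute ratio + CI for one stratum.

    ``observed_ci`` defaults to the stratum's own observed count; passing a
    pooled count reproduces published tables whose stratum CIs were all
    computed with the pooled O (legacy-pooled mode).
    """
    o_ci = observed if observed_ci is None else observed_ci
    ratio = eo_ratio(expected, observed)
    lo, hi = eo_ci(ratio, o_ci, alpha)
    return EOResult(expected=float(expected), observed=int(observed), ratio=ratio,
                    ci_low=lo, ci_high=hi, alpha=alpha, label=label,
                    observed_ci=int(o_ci))


@dataclass
class SelectionOutcome:
    """Which candidate's E/O ratio is closest to 1."""

    labels: tuple[str, ...]
    distances: tuple[float, ...]
    chosen: str
    tie: bool = False
    degenerate: bool = False   # single candidate


def select_model(results: Mapping[str, "EOResult | float"],
                 scale: str = "natural", tol: float = 1e-9) -> SelectionOutcome:
    """Pick the candidate whose E/O ratio is closest to 1.

    ``scale="natural"`` measures |ratio - 1|; ``scale="log"`` uses
    |log(ratio)|.  Equal distances (within ``tol``) set the tie flag rather
    than silently choosing.
    """
    if not results:
        raise ValueError("no candidates to select among")
    from math import log
    labels, dists = [], []
    for label, r in results.items():
        ratio = r.ratio if isinstance(r, EOResult) else float(r)
        if scale == "natural":
            d = abs(ratio - 1.0)
        elif scale == "log":
            d = abs(log(ratio))
        else:
            raise ValueError(f"unknown scale {scale!r}")
        labels.append(label)
        dists.append(d)
    best = min(range(len(dists)), key=lambda i: dists[i])
    tie = sum(1 for d in dists if abs(d - dists[best]) <= tol) > 1
    return SelectionOutcome(tuple(labels), tuple(dists), labels[best],
                            tie=tie, degenerate=len(labels) == 1)


def sum_periods(counts: Sequence[float]) -> float:
    """Grand total over period totals (non-negative entries)."""
    total = 0.0
    for c in counts:
        if c < 0:
            raise ValueError(f"period totals must be non-negative, got {c}")
        total += c
    return total


def eo_table(results: Sequence[EOResult]) -> pd.DataFrame:
    """Tabular E/O report: one row per stratum, 3-decimal rounded ratios."""
    rows = [{"stratum": r.label, "E": r.expected, "O": r.observed,
             "ratio": round_half_away(r.ratio, 3),
             "ci_low": round_half_away(r.ci_low, 3),
             "ci_high": round_half_away(r.ci_high, 3)} for r in results]
    return pd.DataFrame(rows, columns=["stratum", "E", "O", "ratio",
                                       "ci_low", "ci_high"])
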