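"""Approach-decision rule and cohort statistics.

The orbitozygomatic decision rule encodes the observed surgical pattern:
when point C sits close (< 3 cm) to both the zygomatic arch and the
lateral canthus, the steep upward corridor of an orbitozygomatic
approach (OZA) is needed; when C is comfortably far (> 4 cm) from both,
a standard pterional craniotomy suffices. The band in between is
genuinely indeterminate — a pterional attempt there can fail to deliver
an adequate operative field — so it is reported as its own label rather
than forced into either class.

Correlation analysis follows the source protocol: Pearson r with
two-sided t-distribution p-values (df = n - 2) for each of the three
anatomical predictors (height of A, height of B, width of B) against
each distance outcome (C-Z, C-L), with Bonferroni correction over the
m = 3 predictors per outcome family (0.05 / 3 -> 0.017 at 3 d.p.).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, UndefinedCorrelationError

OZA_LOW_MM = 30.0
OZA_HIGH_MM = 40.0

OUTCOME_COLUMNS = {"cz": "cz_mm", "cl": "cl_mm"}
PREDICTOR_COLUMNS = {
    "height_A": "height_A_mm",
    "height_B": "height_B_mm",
    "width_B": "width_B_mm",
}


class Decision(str, enum.Enum):
    OZA_RECOMMENDED = "oza_recommended"
    PTERIONAL_SUFFICIENT = "pterional_sufficient"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DecisionOutcome:
    label: Decision
    cz_mm: float
    cl_mm: float
    low_mm: float
    high_mm: float


def classify_oza(
    cz_mm: float,
    cl_mm: float,
    low_mm: float = OZA_LOW_MM,
    high_mm: float = OZA_HIGH_MM,
) -> DecisionOutcome:
    """Classify one subject-side by its C-Z and C-L distances.

    Both distances below ``low_mm`` recommend the OZA; both above
    ``high_mm`` indicate a plain pterional approach suffices; anything
    else — including exact boundary values — is indeterminate.
    """
    if cz_mm < 0 or cl_mm < 0:
        raise ParameterError(
            f"distances must be non-negative, got cz={cz_mm}, cl={cl_mm}"
        )
    if not low_mm < high_mm:
        raise ParameterError(f"low threshold must be < high, got ({low_mm}, {high_mm})")
    if cz_mm < low_mm and cl_mm < low_mm:
        label = Decision.OZA_RECOMMENDED
    elif cz_mm > high_mm and cl_mm > high_mm:
        label = Decision.PTERIONAL_SUFFICIENT
    else:
        label = Decision.INDETERMINATE
    return DecisionOutcome(label=label, cz_mm=cz_mm, cl_mm=cl_mm, low_mm=low_mm, high_mm=high_mm)


@dataclass(frozen=True)
class CorrelationEntry:
    outcome: str
    predictor: str
    r: float
    p: float
    significant: bool


@dataclass(frozen=True)
class CorrelationReport:
    entries: list[CorrelationEntry]
    corrected_alpha: float
    family_alpha: float
    m: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([e.__dict__ for e in self.entries])
        df["corrected_alpha"] = self.corrected_alpha
        df["n"] = self.n
        return df

    def get(self, outcome: str, predictor: str) -> CorrelationEntry:
        for e in self.entries:
            if e.outcome == outcome and e.predictor == predictor:
                return e
        raise KeyError((outcome, predictor))

    def to_text(self) -> str:
        lines = [
            f"Pearson correlations (n = {self.n}); "
            f"significance at p < {self.corrected_alpha:.3f} "
            f"(Bonferroni, alpha = {self.family_alpha} / m = {self.m})",
        ]
        for e in self.entries:
            p_str = "n/a" if np.isnan(e.p) else f"{e.p:.4g}"
            flag = "*" if e.significant else " "
            lines.append(
                f"  {e.outcome:>3} ~ {e.predictor:<9} r = {e.r:+.3f}  p = {p_str} {flag}"
            )
        return "\n".join(lines)


def pearson_with_bonferroni(
    cohort: pd.DataFrame, family_alpha: float = 0.05, m: int = 3
) -> CorrelationReport:
    """Pearson r / two-sided p for every (distance, predictor) pair.

    ``cohort`` must carry the standard cohort columns. With fewer than
    three rows the correlation has no residual degrees of freedom, so a
    warning is emitted and p-values are reported as NaN (never
    significant) while r is still computed where defined.
    """
    n = len(cohort)
    if n < 2:
        raise ParameterError(f"need at least 2 rows for correlation, got {n}")
    missing = [
        c
        for c in list(OUTCOME_COLUMNS.values()) + list(PREDICTOR_COLUMNS.values())
        if c not in cohort.columns
    ]
    if missing:
        raise ParameterError(f"cohort table missing columns: {missing}")
    if cohort[list(OUTCOME_COLUMNS.values()) + list(PREDICTOR_COLUMNS.values())].isna().any().any():
        raise ParameterError("cohort table contains missing values")

    corrected_alpha = family_alpha / m
    small_n = n < 3
    if small_n:
        warnings.warn(
            f"n = {n} leaves df = {n - 2} for the correlation t-test; "
            "p-values are undefined and reported as NaN",
            stacklevel=2,
        )

    entries = []
    for outcome, ocol in OUTCOME_COLUMNS.items():
        for predictor, pcol in PREDICTOR_COLUMNS.items():
            x = cohort[pcol].to_numpy(dtype=float)
            y = cohort[ocol].to_numpy(dtype=float)
            degenerate = [name for name, v in ((pcol, x), (ocol, y)) if np.ptp(v) == 0]
            if degenerate and not small_n:
                raise UndefinedCorrelationError(
                    f"column {degenerate[0]!r} has zero variance; correlation undefined"
                )
            if small_n:
                # df <= 0: r where defined, NaN otherwise; p never computed
                r = float("nan") if degenerate else float(np.corrcoef(x, y)[0, 1])
                p = float("nan")
            else:
                res = sps.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            entries.append(
                CorrelationEntry(
                    outcome=outcome,
                    predictor=predictor,
                    r=r,
                    p=p,
                    significant=bool(p < corrected_alpha) if not np.isnan(p) else False,
                )
            )
    return CorrelationReport(
        entries=entries,
        corrected_alpha=corrected_alpha,
        family_alpha=family_alpha,
        m=m,
        n=n,
    )


@dataclass(frozen=True)
class SummaryStats:
    """Per-quantity mean / SD / range summaries of a cohort table."""

    table: pd.DataFrame  # index: quantity; columns: mean, sd, min, max, n

    def format(self, quantity: str, digits: int = 1) -> str:
        row = self.table.loc[quantity]
        return (
            f"{row['mean']:.{digits}f} ± {row['sd']:.{digits}f} "
            f"({row['min']:.{digits}f}–{row['max']:.{digits}f})"
        )


def summarize(cohort: pd.DataFrame, columns: list[str] | None = None) -> SummaryStats:
    """Mean, sample SD (n-1), min, max per measured quantity."""
    if len(cohort) < 1:
        raise ParameterError("cannot summarize an empty cohort")
    if columns is None:
        columns = [
            c for c in cohort.columns if c.endswith("_mm") and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = {}
    for c in columns:
        v = cohort[c].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows[c] = {
            "mean": float(np.mean(v)),
            "sd": sd,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": len(v),
        }
    return SummaryStats(table=pd.DataFrame(rows).T)
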