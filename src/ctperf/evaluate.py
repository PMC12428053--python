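"""Four-category diagnostic evaluation of lesion-prediction volumes.

Every examination contributes, per algorithm and compartment, one of four
categories determined by whether a volume was predicted (> 0 mL) and whether
an infarct developed on follow-up (> 0 mL):

* no abnormality — no prediction, no infarct;
* underestimated progressive infarct — no prediction, infarct;
* reversible perfusion deficit — prediction, no infarct;
* progressive infarct — prediction, infarct.

Treating "infarct developed" as the condition and "volume predicted" as the
test, the contingency counts give

    sensitivity = progressive / (progressive + underestimated)
    specificity = no_abnormality / (no_abnormality + reversible)
    PPV         = progressive / (progressive + reversible)
    NPV         = no_abnormality / (no_abnormality + underestimated)

A zero denominator yields an explicit undefined marker (``None``), printed
as "/" — never coerced to 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from .simulate import ALGORITHMS, COMPARTMENTS, CohortRecord
from .stats import GamesHowellResult, WelchResult, games_howell, welch_anova


class PredictionCategory(str, Enum):
    NO_ABNORMALITY = "no_abnormality"
    UNDERESTIMATED = "underestimated_progressive_infarct"
    REVERSIBLE = "reversible_perfusion_deficit"
    PROGRESSIVE = "progressive_infarct"


def classify_prediction(
    predicted_ml: float,
    infarct_ml: float,
    epsilon: float = 0.0,
) -> PredictionCategory:
    """Four-way category from predicted and final-infarct volumes.

    A volume counts as positive when strictly greater than ``epsilon``
    (default 0, i.e. the 0-mL-vs-greater grouping; raise epsilon to ignore
    sub-threshold volumes from noisy segmentations).
    """
    if predicted_ml < 0 or infarct_ml < 0:
        raise ValueError("volumes must be >= 0")
    pred = predicted_ml > epsilon
    inf = infarct_ml > epsilon
    if pred and inf:
        return PredictionCategory.PROGRESSIVE
    if pred:
        return PredictionCategory.REVERSIBLE
    if inf:
        return PredictionCategory.UNDERESTIMATED
    return PredictionCategory.NO_ABNORMALITY


@dataclass(frozen=True)
class ContingencyTable:
    """Four-category counts for one algorithm x compartment."""

    algorithm: str
    compartment: str
    n_no_abnormality: int
    n_underestimated: int
    n_reversible: int
    n_progressive: int

    def __post_init__(self) -> None:
        if min(self.counts) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.n_no_abnormality,
            self.n_underestimated,
            self.n_reversible,
            self.n_progressive,
        )

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def n_predicted_positive(self) -> int:
        """Examinations with a nonzero predicted volume."""
        return self.n_reversible + self.n_progressive


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Fractions in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percent_strings(self) -> dict[str, str]:
        """One-decimal percent display, '/' for undefined."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = "/" if value is None else f"{100 * value:.1f}"
        return out


def build_contingency(
    records: Sequence[CohortRecord],
    algorithm: str,
    compartment: str,
    epsilon: float = 0.0,
) -> ContingencyTable:
    """Tally the four categories over a cohort for one algorithm/compartment."""
    if not records:
        raise ValueError("record list is empty")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    counts = {cat: 0 for cat in PredictionCategory}
    for rec in records:
        counts[classify_prediction(rec.volume(algorithm, compartment), rec.infarct_ml, epsilon)] += 1
    return ContingencyTable(
        algorithm=algorithm,
        compartment=compartment,
        n_no_abnormality=counts[PredictionCategory.NO_ABNORMALITY],
        n_underestimated=counts[PredictionCategory.UNDERESTIMATED],
        n_reversible=counts[PredictionCategory.REVERSIBLE],
        n_progressive=counts[PredictionCategory.PROGRESSIVE],
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV from a four-category table."""
    if table.total == 0:
        raise ValueError("empty contingency table")
    no, under, rev, prog = table.counts
    return DiagnosticMetrics(
        sensitivity=_ratio(prog, prog + under),
        specificity=_ratio(no, no + rev),
        ppv=_ratio(prog, prog + rev),
        npv=_ratio(no, no + under),
    )


# --------------------------------------------------------------------------
# packaged reference counts
# --------------------------------------------------------------------------


def load_reference_counts() -> tuple[dict[tuple[str, str], ContingencyTable], int]:
    """Packaged four-category counts of the published comparison cohort.

    Returns the tables keyed by (algorithm, compartment) and the cohort size.
    """
    text = resources.files("ctperf.data").joinpath("reference_counts.json").read_text()
    payload = json.loads(text)
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for algorithm, comps in payload["counts"].items():
        for compartment, counts in comps.items():
            tables[(algorithm, compartment)] = ContingencyTable(
                algorithm=algorithm,
                compartment=compartment,
                n_no_abnormality=counts["no_abnormality"],
                n_underestimated=counts["underestimated_progressive_infarct"],
                n_reversible=counts["reversible_perfusion_deficit"],
                n_progressive=counts["progressive_infarct"],
            )
    return tables, int(payload["n"])


def reference_metrics_report() -> dict:
    """Recompute all diagnostic metrics from the packaged reference counts."""
    tables, n = load_reference_counts()
    report: dict = {"n": n, "algorithms": {}}
    for (algorithm, compartment), table in tables.items():
        metrics = diagnostic_metrics(table)
        entry = report["algorithms"].setdefault(algorithm, {})
        entry[compartment] = {
            "counts": dict(zip(
                ("no_abnormality", "underestimated_progressive_infarct",
                 "reversible_perfusion_deficit", "progressive_infarct"),
                table.counts,
            )),
            "predicted_positive_datasets": table.n_predicted_positive,
            "metrics_percent": metrics.as_percent_strings(),
        }
    return report


# --------------------------------------------------------------------------
# cohort-level evaluation
# --------------------------------------------------------------------------

Stratification = Literal["overall", "treated", "untreated"]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    n_positive: int
    mean_ml: float
    min_ml: float
    max_ml: float


@dataclass
class CohortReport:
    """Full evaluation of one stratum of a cohort."""

    stratification: Stratification
    n: int
    tables: dict[tuple[str, str], ContingencyTable]
    metrics: dict[tuple[str, str], DiagnosticMetrics]
    volume_summaries: dict[str, GroupSummary]        # per volume group incl. infarct
    welch: dict[str, WelchResult | None]             # per compartment
    games_howell: dict[str, list[GamesHowellResult]]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "stratification": self.stratification,
            "n": self.n,
            "flags": list(self.flags),
            "cells": {},
            "volumes": {
                name: {
                    "n": s.n, "n_positive": s.n_positive,
                    "mean_ml": s.mean_ml, "min_ml": s.min_ml, "max_ml": s.max_ml,
                }
                for name, s in self.volume_summaries.items()
            },
            "welch": {
                comp: None if res is None else
                {"f": res.f, "df1": res.df1, "df2": res.df2, "p": res.p}
                for comp, res in self.welch.items()
            },
            "games_howell": {
                comp: [
                    {"pair": f"{r.group_a} vs {r.group_b}", "mean_diff_ml": r.mean_diff,
                     "t": r.t, "df": r.df, "p": r.p}
                    for r in rows
                ]
                for comp, rows in self.games_howell.items()
            },
        }
        for (algorithm, compartment), table in self.tables.items():
            cell = out["cells"].setdefault(algorithm, {})
            cell[compartment] = {
                "counts": list(table.counts),
                "metrics_percent": self.metrics[(algorithm, compartment)].as_percent_strings(),
            }
        return out


def evaluate_cohort(
    records: Sequence[CohortRecord],
    stratification: Stratification = "overall",
    epsilon: float = 0.0,
) -> CohortReport:
    """Contingency tables, diagnostic metrics and Welch/Games–Howell statistics.

    ``overall`` uses every record; ``treated``/``untreated`` keep only records
    with the matching flag (records flagged ``excluded`` — e.g. prior
    intra-arterial treatment — never enter a stratum).
    """
    records = list(records)
    if stratification == "overall":
        stratum = records
    elif stratification in ("treated", "untreated"):
        stratum = [r for r in records if r.treatment == stratification]
    else:
        raise ValueError(f"unknown stratification {stratification!r}")
    if not stratum:
        raise ValueError(f"empty stratum {stratification!r}")

    tables: dict[tuple[str, str], ContingencyTable] = {}
    metrics: dict[tuple[str, str], DiagnosticMetrics] = {}
    for algorithm in ALGORITHMS:
        for compartment in COMPARTMENTS:
            table = build_contingency(stratum, algorithm, compartment, epsilon)
            tables[(algorithm, compartment)] = table
            metrics[(algorithm, compartment)] = diagnostic_metrics(table)

    def summarise(values: np.ndarray) -> GroupSummary:
        return GroupSummary(
            n=values.size,
            n_positive=int(np.count_nonzero(values > epsilon)),
            mean_ml=float(values.mean()),
            min_ml=float(values.min()),
            max_ml=float(values.max()),
        )

    infarct = np.array([r.infarct_ml for r in stratum])
    summaries: dict[str, GroupSummary] = {"infarct": summarise(infarct)}
    flags: list[str] = []
    welch: dict[str, WelchResult | None] = {}
    gh: dict[str, list[GamesHowellResult]] = {}
    for compartment in COMPARTMENTS:
        groups: dict[str, np.ndarray] = {}
        for algorithm in ALGORITHMS:
            values = np.array([r.volume(algorithm, compartment) for r in stratum])
            summaries[f"{algorithm}_{compartment}"] = summarise(values)
            groups[algorithm] = values
        groups["infarct"] = infarct
        try:
            welch[compartment] = welch_anova(groups)
            gh[compartment] = games_howell(groups)
        except ValueError as err:
            welch[compartment] = None
            gh[compartment] = []
            flags.append(f"statistics skipped for {compartment}: {err}")

    return CohortReport(
        stratification=stratification,
        n=len(stratum),
        tables=tables,
        metrics=metrics,
        volume_summaries=summaries,
        welch=welch,
        games_howell=gh,
        flags=flags,
    )
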