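"""Welch's ANOVA and the Games–Howell post hoc test.

Both procedures are valid under variance heterogeneity, which cohort volume
distributions exhibit strongly (log-normal-like, with means differing by an
order of magnitude between algorithms).

Welch's ANOVA: with group weights ``w_i = n_i / s_i^2``, ``W = sum w_i``,
weighted grand mean ``m = sum w_i x_i / W`` and
``A = sum (1 - w_i/W)^2 / (n_i - 1)``,

    F = [ sum w_i (x_i - m)^2 / (k - 1) ] / [ 1 + 2 (k - 2) A / (k^2 - 1) ]

with ``df1 = k - 1`` and Welch–Satterthwaite ``df2 = (k^2 - 1) / (3 A)``;
the p value comes from the F distribution.

Games–Howell: for each pair, ``t = |x_i - x_j| / sqrt(s_i^2/n_i + s_j^2/n_j)``
with pairwise Welch–Satterthwaite df; the adjusted p value is the survival
function of the studentized range distribution at ``q = t * sqrt(2)`` with
``k`` groups.  At k = 2 this reduces exactly to the two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WelchResult:
    f: float
    df1: float
    df2: float
    p: float

    @property
    def significant(self) -> bool:
        """Two-tailed significance at alpha = 0.05."""
        return self.p < 0.05


@dataclass(frozen=True)
class GamesHowellResult:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b, mL when applied to volumes
    t: float
    df: float
    p: float


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {str(name): np.asarray(g, dtype=float).ravel() for name, g in items}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in out.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {name!r} has zero variance")
    return out


def welch_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA."""
    data = _as_groups(groups)
    k = len(data)
    n = np.array([g.size for g in data.values()], dtype=float)
    m = np.array([g.mean() for g in data.values()])
    v = np.array([g.var(ddof=1) for g in data.values()])
    w = n / v
    big_w = w.sum()
    grand = float((w * m).sum() / big_w)
    a = float((((1.0 - w / big_w) ** 2) / (n - 1.0)).sum())
    num = float((w * (m - grand) ** 2).sum() / (k - 1))
    den = 1.0 + 2.0 * (k - 2) * a / (k**2 - 1.0)
    f = num / den
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * a)
    p = float(sps.f.sf(f, df1, df2))
    return WelchResult(f=float(f), df1=df1, df2=df2, p=p)


def games_howell(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> list[GamesHowellResult]:
    """All pairwise Games–Howell comparisons."""
    data = _as_groups(groups)
    k = len(data)
    names = list(data)
    results: list[GamesHowellResult] = []
    for a, b in combinations(names, 2):
        ga, gb = data[a], data[b]
        na, nb = ga.size, gb.size
        va, vb = ga.var(ddof=1), gb.var(ddof=1)
        se2 = va / na + vb / nb
        diff = float(ga.mean() - gb.mean())
        t = abs(diff) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        results.append(
            GamesHowellResult(group_a=a, group_b=b, mean_diff=diff, t=float(t), df=float(df), p=p)
        )
    return results
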