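"""Three-group statistical comparison of per-subject NCA parameters.

Implements the study's statistical layer: group means ± SD, classical
one-way ANOVA, post-hoc pairwise Student's t tests (pooled variance) with
Bonferroni correction, and a Spearman rank correlation between clearance and
the ordered extent of hepatectomy.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gdnca.simulate import GROUPS, ValidationError

#: Parameters compared between groups by default (per-subject table columns).
DEFAULT_PARAMETERS = (
    "auc_last",
    "auc_inf",
    "auc_extrapolated_pct",
    "auc_inf_per_dose",
    "cmax",
    "cmax_per_dose",
    "cl",
    "v_ss",
    "v_z",
    "t_half_beta",
    "t_half_eff",
)

ALPHA = 0.050  # two-sided significance threshold


def summarize_groups(
    table: pd.DataFrame,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    group_col: str = "group",
) -> pd.DataFrame:
    """Sample mean and SD (n−1 denominator) per group per parameter.

    Groups of a single subject report the mean with a missing SD.
    """
    parameters = [p for p in parameters if p in table.columns]
    if not parameters:
        raise ValidationError("no requested parameter columns present")
    out = []
    for group, sub in table.groupby(group_col, sort=False):
        for p in parameters:
            values = sub[p].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValidationError(f"missing values in tested column {p!r}")
            out.append(
                {
                    "group": group,
                    "parameter": p,
                    "n": len(values),
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(out)


def one_way_anova(values_by_group: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: returns (F, p).

    Zero within-group variance with equal group means is reported as
    F = 0, p = 1; with unequal means as F = inf, p = 0.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs at least two groups of at least two subjects")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def pairwise_t_bonferroni(
    values_by_group: Mapping[str, np.ndarray]
) -> dict[tuple[str, str], float]:
    """Two-sided pooled-variance Student's t per group pair, Bonferroni-adjusted.

    Adjusted p = min(1, m × raw p) with m = number of pairs.  Degenerate
    pairs (zero variance in both groups) report p = 1 when the means agree
    and p = 0 otherwise.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        x = np.asarray(values_by_group[a], dtype=float)
        y = np.asarray(values_by_group[b], dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("each compared group needs at least two subjects")
        if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
            raw = 1.0 if x.mean() == y.mean() else 0.0
        else:
            raw = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        out[(a, b)] = min(1.0, m * raw)
    return out


def spearman_group_trend(
    cl_values: Sequence[float], group_codes: Sequence[int]
) -> tuple[float, float]:
    """Spearman rank correlation between clearance and ordinal group code.

    Midranks handle the heavy ties produced by the 0/1/2 group coding; the
    p-value comes from the t approximation.
    """
    cl = np.asarray(cl_values, dtype=float)
    codes = np.asarray(group_codes, dtype=float)
    if len(cl) != len(codes) or len(cl) < 5:
        raise ValidationError("need at least five paired observations")
    if np.all(cl == cl[0]) or np.all(codes == codes[0]):
        raise ValidationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(cl, codes)
    return float(rho), float(p)


@dataclass
class GroupComparisonReport:
    """Per-parameter ANOVA + pairwise Bonferroni p-values + group summaries."""

    summaries: pd.DataFrame
    anova: dict[str, tuple[float, float]]  # parameter -> (F, p)
    pairwise: dict[str, dict[tuple[str, str], float]]
    spearman_cl: tuple[float, float] | None  # (rho, p) for CL vs group order
    group_order: tuple[str, ...]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group_order": list(self.group_order),
            "summaries": self.summaries.to_dict(orient="records"),
            "anova": {p: {"F": f, "p": pv} for p, (f, pv) in self.anova.items()},
            "pairwise_bonferroni_p": {
                p: {f"{a}_vs_{b}": pv for (a, b), pv in pairs.items()}
                for p, pairs in self.pairwise.items()
            },
            "spearman_cl_vs_group": (
                None
                if self.spearman_cl is None
                else {"rho": self.spearman_cl[0], "p": self.spearman_cl[1]}
            ),
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Human-readable report, rounded to one decimal like a journal table."""
        lines = ["Group summaries (mean ± SD):"]
        for (group, param), sub in self.summaries.groupby(["group", "parameter"], sort=False):
            row = sub.iloc[0]
            sd = "NA" if math.isnan(row["sd"]) else f"{row['sd']:.1f}"
            lines.append(f"  {param:>22s}  {group:<8s} {row['mean']:.1f} ± {sd} (n={row['n']})")
        lines.append("")
        lines.append("Parameter comparisons (ANOVA p; pairwise Bonferroni p):")
        for param, (f, p) in self.anova.items():
            pairs = "  ".join(
                f"{a} vs {b}: {_fmt_p(pv)}" for (a, b), pv in self.pairwise[param].items()
            )
            lines.append(f"  {param:>22s}  overall {_fmt_p(p)};  {pairs}")
        if self.spearman_cl is not None:
            rho, p = self.spearman_cl
            lines.append("")
            lines.append(f"Spearman CL vs group order: rho = {rho:.3f}, p {_fmt_p(p)}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"= {p:.3f}"


def compare_groups(
    table: pd.DataFrame,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    group_order: Sequence[str] = GROUPS,
    group_col: str = "group",
) -> GroupComparisonReport:
    """Full statistical comparison of a per-subject parameter table.

    ``group_order`` defines the ordinal coding used for the Spearman trend
    (increasing extent of hepatectomy).  Groups absent from the table are
    skipped; with fewer than two groups only the summaries are produced.
    """
    present = [g for g in group_order if g in set(table[group_col])]
    parameters = [p for p in parameters if p in table.columns]
    summaries = summarize_groups(table, parameters, group_col=group_col)
    warnings = []
    anova: dict[str, tuple[float, float]] = {}
    pairwise: dict[str, dict[tuple[str, str], float]] = {}
    spearman: tuple[float, float] | None = None

    comparable = [
        g for g in present if (table[group_col] == g).sum() >= 2
    ]
    if len(comparable) < 2:
        warnings.append("fewer than two groups with n >= 2; comparisons skipped")
    else:
        by_group = {
            g: table.loc[table[group_col] == g] for g in comparable
        }
        for p in parameters:
            values = {g: sub[p].to_numpy(dtype=float) for g, sub in by_group.items()}
            anova[p] = one_way_anova(values)
            pairwise[p] = pairwise_t_bonferroni(values)
        if "cl" in parameters:
            sub = table[table[group_col].isin(comparable)]
            codes = sub[group_col].map({g: i for i, g in enumerate(group_order)})
            try:
                spearman = spearman_group_trend(
                    sub["cl"].to_numpy(dtype=float), codes.to_numpy(dtype=int)
                )
            except ValidationError as err:
                warnings.append(f"Spearman trend unavailable: {err}")
    return GroupComparisonReport(
        summaries=summaries,
        anova=anova,
        pairwise=pairwise,
        spearman_cl=spearman,
        group_order=tuple(present),
        warnings=warnings,
    )
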