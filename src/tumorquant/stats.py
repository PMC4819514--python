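"""Group statistics: mean ± SE summaries, one-way ANOVA, Newman–Keuls.

The cohort design is per-tumor metric values keyed by tumor line, treatment
arm and day. Within each (metric, line, day) stratum, arms are compared by
one-way ANOVA followed by the Student–Newman–Keuls (SNK) stepwise multiple
comparison. SNK orders the group means and tests pairs against the
studentized-range quantile q(alpha, r, df) for the number of means r the
pair spans, with the containment rule: every pair nested inside a
non-significant span is itself declared non-significant without testing.

Studentized-range probabilities come from ``scipy.stats.studentized_range``
(numerical integration of the range distribution, not table lookup); unequal
group sizes use the harmonic mean of the two compared groups, the standard
SNK compromise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "GROUP_COLUMNS",
    "PosthocResult",
    "validate_group_table",
    "summarize",
    "one_way_anova",
    "newman_keuls",
    "run_cohort_report",
]

GROUP_COLUMNS = ["tumor_id", "line", "arm", "day", "metric", "value"]


@dataclass(frozen=True)
class PosthocResult:
    """One SNK pairwise decision."""

    pair: tuple[str, str]
    p_value: float
    significant: bool
    step_range: int  # number of ordered means the pair spans
    q_statistic: float


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table schema and value finiteness."""
    missing = [c for c in GROUP_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"group table missing columns: {missing}")
    if not np.isfinite(table["value"]).all():
        raise InvalidInputError("group table contains non-finite values")
    return table


def summarize(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean, standard error (SD/sqrt(n)) and n.

    Groups with a single observation get SE = NaN (undefined), not zero.
    """
    validate_group_table(table)
    by = by or ["metric", "line", "arm", "day"]
    g = table.groupby(by, sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "se"] = np.nan
    return out.drop(columns="sd")


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Standard one-way fixed-effects ANOVA.

    Returns (F, df_between, df_within, p). Computed from the between/within
    sums of squares directly; cross-checked in the test suite against
    independent reference implementations.
    """
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("every group needs n >= 2")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            raise DegenerateDataError("zero variance everywhere: F undefined")
        return np.inf, df_b, df_w, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def newman_keuls(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Student–Newman–Keuls stepwise all-pairs comparison.

    Group means are sorted; a pair spanning r ordered means is tested with
    the studentized range q = |mean_i - mean_j| / sqrt(MSE / n_h) against
    the range distribution with parameters (r, df_within), n_h the harmonic
    mean of the two group sizes. Pairs are processed from the widest span
    inward; any pair nested inside a non-significant span is reported
    non-significant with its nominal p but never flagged (containment rule).
    """
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    if any(np.asarray(v).size < 2 for v in groups.values()):
        raise InvalidInputError("SNK requires n >= 2 per group")

    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    _, _, df_w, _ = one_way_anova(arrays)
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_w

    order = np.argsort([g.mean() for g in arrays])
    ordered = [names[i] for i in order]
    means = {n: float(np.mean(groups[n])) for n in names}
    sizes = {n: int(np.asarray(groups[n]).size) for n in names}

    k = len(ordered)
    blocked: set[tuple[int, int]] = set()
    results: list[PosthocResult] = []
    # widest spans first so the containment rule can block nested pairs
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            a, b = ordered[i], ordered[j]
            n_h = 2.0 / (1.0 / sizes[a] + 1.0 / sizes[b])
            diff = abs(means[b] - means[a])
            if mse > 0:
                q = diff / np.sqrt(mse / n_h)
                p = float(sps.studentized_range.sf(q, r, df_w))
            else:
                q = np.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            contained = (i, j) in blocked
            significant = (p < alpha) and not contained
            if not significant:
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked.add((ii, jj))
            results.append(
                PosthocResult(
                    pair=(a, b),
                    p_value=p,
                    significant=significant,
                    step_range=r,
                    q_statistic=float(q),
                )
            )
    return results


def run_cohort_report(
    table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    control_arm: str = "Veh-ctrl",
) -> pd.DataFrame:
    """Per-stratum summary + ANOVA + SNK over treatment arms.

    For every (metric, line, day) stratum with at least two arms of n >= 2,
    runs the one-way ANOVA across arms followed by Newman–Keuls, and emits
    one row per arm pair with the ANOVA p, the SNK p and significance flag.
    Strata that cannot be tested (single arm, tiny groups) are skipped with
    their summaries still present (pair columns NaN).
    """
    validate_group_table(table)
    rows = []
    for (metric, line, day), sub in table.groupby(["metric", "line", "day"], sort=True):
        arms = {str(a): g["value"].to_numpy() for a, g in sub.groupby("arm", sort=True)}
        testable = {a: v for a, v in arms.items() if v.size >= 2}
        base = {"metric": metric, "line": line, "day": day}
        if len(testable) < 2:
            rows.append({**base, "arm_a": None, "arm_b": None, "anova_p": np.nan,
                         "snk_p": np.nan, "significant": np.nan})
            continue
        try:
            _, _, _, anova_p = one_way_anova(list(testable.values()))
        except DegenerateDataError:
            anova_p = np.nan
        try:
            posthoc = newman_keuls(testable, alpha=alpha)
        except (InvalidInputError, DegenerateDataError):
            posthoc = []
        by_pair = {frozenset(r.pair): r for r in posthoc}
        for a, b in combinations(sorted(testable), 2):
            r = by_pair.get(frozenset((a, b)))
            rows.append(
                {
                    **base,
                    "arm_a": a,
                    "arm_b": b,
                    "anova_p": anova_p,
                    "snk_p": r.p_value if r else np.nan,
                    "significant": bool(r.significant) if r else np.nan,
                }
            )
    report = pd.DataFrame(rows)
    report.attrs["alpha"] = alpha
    report.attrs["control_arm"] = control_arm
    return report


def format_report_text(report: pd.DataFrame, summary: pd.DataFrame) -> str:
    """Human-readable cohort report."""
    lines = ["Cohort report", "=" * 60, "", "Group summaries (mean +/- SE, n):"]
    for _, row in summary.iterrows():
        se = "undef" if np.isnan(row["se"]) else f"{row['se']:.4g}"
        lines.append(
            f"  {row['metric']} | {row['line']} day {row['day']} {row['arm']}: "
            f"{row['mean']:.4g} +/- {se} (n={row['n']})"
        )
    lines += ["", f"Pairwise comparisons (alpha={report.attrs.get('alpha', 0.05)}):"]
    for _, row in report.iterrows():
        if row["arm_a"] is None:
            lines.append(
                f"  {row['metric']} | {row['line']} day {row['day']}: not testable"
            )
            continue
        star = "*" if row["significant"] is True or row["significant"] == 1.0 else " "
        lines.append(
            f"  {row['metric']} | {row['line']} day {row['day']} "
            f"{row['arm_a']} vs {row['arm_b']}: SNK p={row['snk_p']:.4g} {star}"
        )
    return "\n".join(lines) + "\n"
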