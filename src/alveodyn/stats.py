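"""Statistical layer: one-sample t-tests, Welch pairwise comparisons,
one-way ANOVA, five-number summaries and experiment reports.

The headline questions of the shape-change analysis are one-sample
questions — is q different from 1, is Δθ different from 0 — tested with
a one-sample Student's t-test that accepts either raw values or printed
summary statistics (mean, SEM, n), since published figures often report
only the latter.  Between-condition (PEEP-group) differences use one-way
ANOVA with Welch's unequal-variance t-test for pairwise post-hocs.  All
tests are two-sided; no multiplicity adjustment is applied by default
(Holm adjustment is available by flag).  SEM is the n−1 sample SD over
√n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    DomainError,
    InsufficientGroupsError,
    SchemaError,
)

__all__ = [
    "StatResult",
    "FiveNumberSummary",
    "one_sample_t",
    "welch_pairwise",
    "anova_oneway",
    "five_number",
    "summarize_experiment",
    "ExperimentReport",
]


@dataclass(frozen=True)
class StatResult:
    """One test result: group label, sample summary, t, df and p."""

    group: str
    n: int
    mean: float
    sem: float
    t: float
    df: float
    p: float
    null_value: float = 0.0


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


def one_sample_t(
    values=None,
    *,
    mean: float | None = None,
    sem: float | None = None,
    n: int | None = None,
    null_value: float = 0.0,
    group: str = "",
) -> StatResult:
    """Two-sided one-sample Student's t-test against ``null_value``.

    Give either raw ``values`` or the printed summary triple
    ``(mean, sem, n)``; the two routes agree to machine precision since
    t = (mean − null)/SEM with df = n − 1 either way.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise DomainError("need at least two values")
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(v.size))
        n = int(v.size)
    if mean is None or sem is None or n is None:
        raise DomainError("give values, or all of mean, sem and n")
    if n < 2:
        raise DomainError("n must be >= 2")
    if sem < 0:
        raise DomainError("sem must be >= 0")
    if sem == 0:
        if mean != null_value:
            raise DegenerateVarianceError(
                "zero SEM with mean != null: t undefined"
            )
        t = 0.0
    else:
        t = (mean - null_value) / sem
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df)) if t != 0 else 1.0
    return StatResult(group, n, float(mean), float(sem), float(t), df,
                      min(p, 1.0), null_value)


def welch_pairwise(
    groups: dict[str, np.ndarray],
    *,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch's unequal-variance t-test for every pair of groups.

    Returns a table with one row per pair: t, Welch–Satterthwaite df and
    the two-sided p (optionally Holm-adjusted in ``p_adj``).
    """
    if len(groups) < 2:
        raise InsufficientGroupsError("need at least two groups")
    names = list(groups)
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if v.size < 2:
            raise DomainError(f"group {k!r} needs n >= 2")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = arrs[a], arrs[b]
            vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            se = np.sqrt(vx + vy)
            if se == 0:
                t, df, p = 0.0, float(x.size + y.size - 2), 1.0
            else:
                t = (x.mean() - y.mean()) / se
                df = (vx + vy) ** 2 / (
                    vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
                )
                p = float(2.0 * sps.t.sf(abs(t), df))
            rows.append(
                {"group_a": a, "group_b": b, "t": float(t),
                 "df": float(df), "p": p}
            )
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adj"] = adj
    return out


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test across groups.

    Degenerate inputs are resolved explicitly: zero between- and
    within-group variance gives (F=0, p=1); zero within-group variance
    with distinct means gives (F=inf, p=0).
    """
    if len(groups) < 2:
        raise InsufficientGroupsError("need at least two groups")
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    for v in arrs:
        if v.size < 2:
            raise DomainError("each group needs n >= 2")
    grand = np.concatenate(arrs)
    ssb = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in arrs)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrs)
    if ssw == 0:
        return (0.0, 1.0) if ssb <= 1e-300 else (np.inf, 0.0)
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def five_number(values) -> FiveNumberSummary:
    """Minimum, quartiles and maximum (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("empty sample")
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumberSummary(*map(float, q))


# ---------------------------------------------------------------------------
# experiment-level reporting

_SUMMARY_COLS = (
    "q", "dtheta_deg", "eps_A", "eps_ER", "dS",
    "D_A_exp_um", "D_A_insp_um", "T_A_um",
)


@dataclass
class ExperimentReport:
    """Aggregated per-condition summary of a paired-dynamics study."""

    summary: pd.DataFrame  # condition x metric mean/sem/n
    tests: pd.DataFrame  # one-sample tests of q vs 1 and dtheta vs 0
    anova: pd.DataFrame  # per-metric ANOVA across conditions (may be empty)
    posthoc: pd.DataFrame  # Welch pairwise post-hocs (may be empty)

    def to_text(self) -> str:
        lines = ["Alveolar micro-dynamics report", "=" * 31, ""]
        lines.append("Per-condition summaries (mean ± SEM [n]):")
        for _, r in self.summary.iterrows():
            lines.append(
                f"  {r['condition']:>12}  {r['metric']:<12} "
                f"{r['mean']:+.4g} ± {r['sem']:.3g}  [n={int(r['n'])}]"
            )
        lines.append("")
        lines.append("One-sample tests:")
        for _, r in self.tests.iterrows():
            lines.append(
                f"  {r['condition']:>12}  {r['metric']} vs "
                f"{r['null_value']:g}: t({int(r['df'])}) = {r['t']:.3f}, "
                f"p = {r['p']:.3g}"
            )
        if not self.anova.empty:
            lines.append("")
            lines.append("One-way ANOVA across conditions:")
            for _, r in self.anova.iterrows():
                lines.append(
                    f"  {r['metric']}: F = {r['F']:.3f}, p = {r['p']:.3g}"
                )
        if not self.posthoc.empty:
            lines.append("")
            lines.append("Welch pairwise post-hocs (unadjusted):")
            for _, r in self.posthoc.iterrows():
                lines.append(
                    f"  {r['metric']}: {r['group_a']} vs {r['group_b']}: "
                    f"t({r['df']:.1f}) = {r['t']:.3f}, p = {r['p']:.3g}"
                )
        return "\n".join(lines) + "\n"


def summarize_experiment(
    tables: dict[str, pd.DataFrame],
    *,
    unit_role: str = "unit_AAD",
) -> ExperimentReport:
    """Summarize paired-dynamics tables, one per experimental condition.

    Each table is a `compute_dynamics`-style frame, optionally with a
    ``dtheta_deg`` column (angle pairs).  Per condition, every available
    metric gets mean ± SEM; q (unit rows) is tested against 1 and Δθ
    against 0 with one-sample t-tests; with two or more conditions each
    metric additionally gets a one-way ANOVA and Welch post-hocs.
    Ordering is deterministic (input order of ``tables``).
    """
    if not tables:
        raise SchemaError("no condition tables given")
    summary_rows, test_rows, metric_values = [], [], {}
    for cond, df in tables.items():
        if df.empty:
            raise SchemaError(f"condition {cond!r} has an empty table")
        has_role = "role" in df.columns
        for metric in _SUMMARY_COLS:
            if metric not in df.columns:
                continue
            if metric == "q" and has_role:
                vals = df.loc[df["role"] == unit_role, metric]
            elif metric in ("eps_A", "eps_ER", "dS") and has_role:
                vals = df.loc[df["role"] == "alveolus", metric]
            else:
                vals = df[metric]
            vals = vals.dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sem = (
                vals.std(ddof=1) / np.sqrt(vals.size)
                if vals.size > 1
                else 0.0
            )
            summary_rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sem": float(sem),
                    "n": vals.size,
                }
            )
            metric_values.setdefault(metric, {})[cond] = vals
            null = {"q": 1.0, "dtheta_deg": 0.0}.get(metric)
            if null is not None and vals.size >= 2 and vals.std(ddof=1) > 0:
                res = one_sample_t(vals, null_value=null, group=cond)
                test_rows.append(
                    {
                        "condition": cond,
                        "metric": metric,
                        "null_value": null,
                        "n": res.n,
                        "mean": res.mean,
                        "sem": res.sem,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
    anova_rows, posthoc_rows = [], []
    if len(tables) >= 2:
        for metric, by_cond in metric_values.items():
            usable = {
                c: v for c, v in by_cond.items() if v.size >= 2
            }
            if len(usable) < 2:
                continue
            F, p = anova_oneway(usable)
            anova_rows.append({"metric": metric, "F": F, "p": p})
            ph = welch_pairwise(usable)
            ph.insert(0, "metric", metric)
            posthoc_rows.append(ph)
    return ExperimentReport(
        summary=pd.DataFrame(summary_rows),
        tests=pd.DataFrame(
            test_rows,
            columns=[
                "condition", "metric", "null_value", "n", "mean", "sem",
                "t", "df", "p",
            ],
        ),
        anova=pd.DataFrame(anova_rows, columns=["metric", "F", "p"]),
        posthoc=(
            pd.concat(posthoc_rows, ignore_index=True)
            if posthoc_rows
            else pd.DataFrame()
        ),
    )
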