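"""Group-level nonparametric statistics and incidence arithmetic.

The battery mirrors a standard Prism workflow on small slice groups:
Mann-Whitney U for two groups (exact permutation distribution at small n,
tie-corrected normal approximation otherwise), Kruskal-Wallis with Dunn's
post hoc (Bonferroni-adjusted) for three or more, and Pearson's 2x2
chi-square without continuity correction for incidence comparisons.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, floor

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IncidenceResult",
    "incidence",
    "compare_two_groups",
    "compare_k_groups",
    "compare_incidence",
    "experiment_report",
    "report_text",
]

#: Combined sample size up to which the exact Mann-Whitney distribution is
#: enumerated (C(12, 6) = 924 assignments at worst).
EXACT_MWU_MAX_N = 12


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceResult:
    n_events: int
    n_total: int
    percent: int  # round(100 * n_events / n_total)
    chi2_p: float | None = None


def incidence(flags) -> IncidenceResult:
    """Count positive flags; percent rounded to the nearest integer."""
    flags = list(flags)
    if not flags:
        raise ValueError("incidence of an empty group is undefined")
    k = int(sum(bool(f) for f in flags))
    n = len(flags)
    return IncidenceResult(k, n, int(floor(100.0 * k / n + 0.5)))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    exact: bool


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def compare_two_groups(x, y, exact: bool | None = None) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact mode enumerates every assignment of the pooled values to the two
    group sizes and counts assignments at least as extreme as observed
    (|U - E[U]| criterion, valid with ties); used by default when the
    combined sample size is at most ``EXACT_MWU_MAX_N``. Otherwise the
    tie-corrected normal approximation (with continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_x], n_x)

    if exact is None:
        exact = n_x + n_y <= EXACT_MWU_MAX_N

    if exact:
        mu = n_x * n_y / 2.0
        n_total = n_x + n_y
        d_obs = abs(u_obs - mu)
        hits = 0
        for idx in combinations(range(n_total), n_x):
            u = _u_statistic(ranks[list(idx)], n_x)
            if abs(u - mu) >= d_obs - 1e-9:
                hits += 1
        return MannWhitneyResult(u_obs, hits / comb(n_total, n_x), True)

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u_obs, 1.0, False)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), False)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # columns: i, j, z, p_unadjusted, p_adjusted


def compare_k_groups(groups, p_adjust: str = "bonferroni") -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H followed by Dunn's pairwise z tests.

    Dunn's z uses the pooled mean-rank difference with the tie-corrected
    variance; adjusted p-values are Bonferroni over the tested pairs by
    default (``p_adjust=None`` disables adjustment).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k == 2:
        raise ValueError("two groups: use compare_two_groups (Mann-Whitney) instead")
    if k < 3:
        raise ValueError("need at least three groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)

    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos : pos + g.size].mean())
        pos += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_un = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_un * len(pairs)) if p_adjust == "bonferroni" else p_un
        rows.append({"i": i, "j": j, "z": z, "p_unadjusted": p_un, "p_adjusted": p_adj})
    return KruskalDunnResult(float(h), float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Chi-square on incidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    p: float


def compare_incidence(
    a: tuple[int, int], b: tuple[int, int], yates: bool = False
) -> ChiSquareResult:
    """Pearson 2x2 chi-square on (events, total) pairs, df = 1.

    No continuity correction by default; a degenerate table (an all-zero or
    all-one margin) gives chi2 = 0, p = 1.
    """
    (k1, n1), (k2, n2) = a, b
    if n1 < 1 or n2 < 1:
        raise ValueError("group totals must be at least 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("event counts must lie within totals")
    a11, a12 = k1, n1 - k1
    a21, a22 = k2, n2 - k2
    n = n1 + n2
    margins = [(a11 + a12), (a21 + a22), (a11 + a21), (a12 + a22)]
    if 0 in margins:
        return ChiSquareResult(0.0, 1.0)
    diff = abs(a11 * a22 - a12 * a21)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return ChiSquareResult(float(chi2), float(sps.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Experiment report
# ---------------------------------------------------------------------------

GROUP_TABLE_COLUMNS = (
    "slice_id",
    "condition",
    "window",
    "fp_freq",
    "amplitude",
    "burst_duration",
    "first_fp_latency",
    "has_ictal",
    "has_se",
)

_METRICS = ("fp_freq", "amplitude", "burst_duration", "first_fp_latency")


def _sem(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _descriptives(sub: pd.DataFrame) -> dict:
    out: dict = {}
    for window, wsub in sub.groupby("window"):
        block = {}
        for metric in _METRICS:
            vals = wsub[metric].to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            block[metric] = {
                "n": int(finite.size),
                "mean": float(finite.mean()) if finite.size else float("nan"),
                "sem": _sem(vals),
                "values": [float(v) for v in vals],
            }
        out[str(window)] = block
    return out


def _slice_flags(sub: pd.DataFrame) -> pd.DataFrame:
    """Per-slice incidence flags: a slice is positive if any window row is."""
    g = sub.groupby("slice_id").agg(has_ictal=("has_ictal", "any"), has_se=("has_se", "any"))
    g["has_ictal_or_se"] = g["has_ictal"] | g["has_se"]
    return g


def experiment_report(table: pd.DataFrame, contrasts: list[dict] | None = None) -> dict:
    """Descriptives, designated tests and incidence tables per contrast.

    ``table`` follows the group-table layout (one row per slice x window);
    each contrast is a mapping with keys ``name``, ``a``, ``b`` (condition
    labels) and optionally ``metrics``. Unknown labels raise ``KeyError``.
    """
    missing = set(GROUP_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    conditions = list(dict.fromkeys(table["condition"]))
    report: dict = {"conditions": {}, "contrasts": {}}
    for cond in conditions:
        sub = table[table["condition"] == cond]
        flags = _slice_flags(sub)
        inc_se = incidence(flags["has_se"])
        inc_any = incidence(flags["has_ictal_or_se"])
        report["conditions"][cond] = {
            "n_slices": int(flags.shape[0]),
            "descriptives": _descriptives(sub),
            "incidence": {
                "se": {"n_events": inc_se.n_events, "n_total": inc_se.n_total, "percent": inc_se.percent},
                "ictal_or_se": {
                    "n_events": inc_any.n_events,
                    "n_total": inc_any.n_total,
                    "percent": inc_any.percent,
                },
            },
        }

    for contrast in contrasts or []:
        name = contrast.get("name") or f"{contrast['a']}_vs_{contrast['b']}"
        a, b = contrast["a"], contrast["b"]
        for label in (a, b):
            if label not in conditions:
                raise KeyError(f"contrast {name!r} references unknown condition {label!r}")
        metrics = contrast.get("metrics", list(_METRICS))
        sub_a = table[table["condition"] == a]
        sub_b = table[table["condition"] == b]
        block: dict = {"a": a, "b": b, "tests": {}, "incidence": {}}
        for window in sorted(set(table["window"])):
            wa = sub_a[sub_a["window"] == window]
            wb = sub_b[sub_b["window"] == window]
            for metric in metrics:
                va = wa[metric].to_numpy(dtype=float)
                vb = wb[metric].to_numpy(dtype=float)
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                if va.size == 0 or vb.size == 0:
                    continue
                res = compare_two_groups(va, vb)
                block["tests"][f"{metric}@{window}"] = {
                    "test": "mann_whitney",
                    "u": res.u,
                    "p": res.p,
                    "exact": res.exact,
                }
        fa, fb = _slice_flags(sub_a), _slice_flags(sub_b)
        for flag in ("has_se", "has_ictal_or_se"):
            ia, ib = incidence(fa[flag]), incidence(fb[flag])
            chi = compare_incidence((ia.n_events, ia.n_total), (ib.n_events, ib.n_total))
            block["incidence"][flag] = {
                "a": {"n_events": ia.n_events, "n_total": ia.n_total, "percent": ia.percent},
                "b": {"n_events": ib.n_events, "n_total": ib.n_total, "percent": ib.percent},
                "chi2": chi.chi2,
                "p": chi.p,
            }
        report["contrasts"][name] = block
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering of an experiment report."""
    lines: list[str] = []
    for cond, block in report["conditions"].items():
        lines.append(f"condition {cond} (n={block['n_slices']} slices)")
        for window, metrics in block["descriptives"].items():
            for metric, d in metrics.items():
                lines.append(
                    f"  {window} {metric}: mean={d['mean']:.4g} sem={d['sem']:.3g} n={d['n']}"
                )
        inc = block["incidence"]
        lines.append(
            f"  incidence SE {inc['se']['percent']}% "
            f"({inc['se']['n_events']}/{inc['se']['n_total']}), "
            f"ictal+SE {inc['ictal_or_se']['percent']}% "
            f"({inc['ictal_or_se']['n_events']}/{inc['ictal_or_se']['n_total']})"
        )
    for name, block in report.get("contrasts", {}).items():
        lines.append(f"contrast {name}: {block['a']} vs {block['b']}")
        for key, t in block["tests"].items():
            mode = "exact" if t["exact"] else "asymptotic"
            lines.append(f"  {key}: U={t['u']:.4g} p={t['p']:.4g} ({mode} Mann-Whitney)")
        for flag, inc in block["incidence"].items():
            lines.append(
                f"  {flag}: {inc['a']['percent']}% vs {inc['b']['percent']}% "
                f"chi2={inc['chi2']:.4g} p={inc['p']:.4g}"
            )
    return "\n".join(lines)
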