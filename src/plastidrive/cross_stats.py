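"""Transmission-genetics and enzyme-assay statistics.

Percent-biparental inheritance from seedling variegation counts, with
Fisher's exact tests of each line against a reference line on
season-pooled counts; Kruskal–Wallis one-way ANOVA on ranks for
paternal-plastome fractions (with pairwise Mann–Whitney + BH post hoc);
and the arithmetic of the radiolabel ACCase assay: dpm-per-minute fixation
rates, chloroplast-count normalisation, relative activities versus a
reference line with paired t tests and BH adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import bh_adjust

__all__ = [
    "biparental_percent",
    "fisher_vs_reference",
    "cross_table_tests",
    "kruskal_wallis",
    "pairwise_mannwhitney",
    "chloroplast_concentration",
    "accase_activity",
    "relative_activity_tests",
]


def _validate_counts(variegated, total) -> None:
    v = np.asarray(variegated)
    t = np.asarray(total)
    if np.any(v < 0) or np.any(t <= 0):
        raise ValueError("need variegated >= 0 and total > 0")
    if np.any(v > t):
        raise ValueError("variegated exceeds total")
    if np.any(v != np.floor(v)) or np.any(t != np.floor(t)):
        raise ValueError("counts must be integral")


def biparental_percent(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent variegated (biparental) progeny per line, per season and
    season-pooled.

    ``counts`` needs columns ``line``, ``season``, ``variegated``,
    ``total``; extra columns (e.g. ``direction``) pass through grouping.
    The pooled value is 100 * sum(variegated) / sum(total), i.e. the
    total-count-weighted mean of per-season percentages.
    """
    required = {"line", "season", "variegated", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    _validate_counts(counts["variegated"], counts["total"])
    per_season = (
        counts.groupby(["line", "season"], as_index=False)[["variegated", "total"]]
        .sum()
        .assign(percent=lambda d: 100.0 * d["variegated"] / d["total"])
    )
    pooled = (
        counts.groupby("line", as_index=False)[["variegated", "total"]]
        .sum()
        .assign(season="pooled", percent=lambda d: 100.0 * d["variegated"] / d["total"])
    )
    return pd.concat([per_season, pooled], ignore_index=True)[
        ["line", "season", "variegated", "total", "percent"]
    ]


def fisher_vs_reference(
    line_counts: tuple[int, int], reference_counts: tuple[int, int]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of a line's season-pooled variegation
    against the reference line.

    Arguments are ``(variegated, total)`` pairs.  Returns the sample odds
    ratio (ad/bc; inf when the reference has no variegated progeny and the
    line has some) and the two-sided p-value.
    """
    v1, t1 = line_counts
    v2, t2 = reference_counts
    _validate_counts([v1, v2], [t1, t2])
    table = np.array([[v1, t1 - v1], [v2, t2 - v2]], dtype=np.int64)
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("degenerate all-zero margin in 2x2 table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def cross_table_tests(counts: pd.DataFrame, reference_line: str) -> pd.DataFrame:
    """Season-pooled percent biparental per line plus Fisher's exact test
    (and BH-adjusted p) of each line versus ``reference_line``."""
    pooled = biparental_percent(counts).query("season == 'pooled'").set_index("line")
    if reference_line not in pooled.index:
        raise ValueError(f"reference line {reference_line!r} absent from counts")
    ref = (int(pooled.loc[reference_line, "variegated"]), int(pooled.loc[reference_line, "total"]))
    rows = []
    for line, rec in pooled.iterrows():
        if line == reference_line:
            rows.append((line, rec["percent"], np.nan, np.nan))
            continue
        odds, p = fisher_vs_reference((int(rec["variegated"]), int(rec["total"])), ref)
        rows.append((line, rec["percent"], odds, p))
    out = pd.DataFrame(rows, columns=["line", "percent_biparental", "odds_ratio", "p"])
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H across >= 2 groups with a
    chi-square p on k - 1 df.  All-identical data give H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_mannwhitney(
    groups: dict[str, list], reference: str
) -> pd.DataFrame:
    """Post-hoc pairwise two-sided Mann–Whitney U of every group against
    the reference, BH-adjusted across comparisons."""
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    ref = np.asarray(groups[reference], dtype=float)
    rows = []
    for name, values in groups.items():
        if name == reference:
            continue
        u, p = stats.mannwhitneyu(np.asarray(values, dtype=float), ref,
                                  alternative="two-sided")
        rows.append((name, float(u), float(p)))
    out = pd.DataFrame(rows, columns=["group", "U", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def chloroplast_concentration(avg_count_per_b_square: float) -> float:
    """Chloroplasts per millilitre from the counting-chamber average:
    10 * average count per B square / 4e-6."""
    c = float(avg_count_per_b_square)
    if c < 0:
        raise ValueError("counting-chamber average must be >= 0")
    return 10.0 * c / (4.0 * 1e-6)


def accase_activity(
    total_dpm,
    control_dpm,
    chloroplasts_per_ml: float,
    incubation_minutes: float = 20.0,
) -> float:
    """ACCase activity as net dpm/min per chloroplast.

    Technical replicate dpm totals are converted to rates (dpm divided
    by the incubation time), averaged, the mean minus-acetyl-CoA control
    rate subtracted, and the net rate divided by the chloroplast count.
    """
    if incubation_minutes <= 0:
        raise ValueError("incubation time must be positive")
    if chloroplasts_per_ml <= 0:
        raise ValueError("chloroplast count must be positive")
    total = np.atleast_1d(np.asarray(total_dpm, dtype=float))
    if control_dpm is None:
        raise ValueError("control (minus acetyl-CoA) measurement required")
    control = np.atleast_1d(np.asarray(control_dpm, dtype=float))
    if np.any(total < 0) or np.any(control < 0):
        raise ValueError("dpm values must be >= 0")
    rate = float(np.mean(total / incubation_minutes))
    control_rate = float(np.mean(control / incubation_minutes))
    return (rate - control_rate) / chloroplasts_per_ml


def relative_activity_tests(
    rates: pd.DataFrame, reference_line: str
) -> pd.DataFrame:
    """Per-line activity relative to the reference line, combined over
    independent experiments with a paired two-tailed t test against 1,
    BH-adjusted over lines.

    ``rates`` needs columns ``line``, ``experiment``, ``rate``.  Lines
    with zero within-pair variance (ratios all identical) are flagged
    with NaN p rather than p = 0.
    """
    required = {"line", "experiment", "rate"}
    if required - set(rates.columns):
        raise ValueError(f"missing columns: {sorted(required - set(rates.columns))}")
    wide = rates.pivot_table(index="experiment", columns="line", values="rate")
    if reference_line not in wide.columns:
        raise ValueError(f"reference line {reference_line!r} absent")
    if wide[reference_line].isna().any():
        raise ValueError("reference line missing from some experiments")
    rel = wide.div(wide[reference_line], axis=0)
    rows = []
    for line in wide.columns:
        if line == reference_line:
            continue
        ratios = rel[line].dropna().to_numpy()
        mean_rel = float(np.mean(ratios)) if len(ratios) else np.nan
        if len(ratios) < 2:
            rows.append((line, mean_rel, len(ratios), np.nan))
            continue
        if np.allclose(ratios, ratios[0]):
            rows.append((line, mean_rel, len(ratios), np.nan))
            continue
        _, p = stats.ttest_1samp(ratios, popmean=1.0)
        rows.append((line, mean_rel, len(ratios), float(p)))
    out = pd.DataFrame(rows, columns=["line", "relative_activity", "n_experiments", "p"])
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out
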