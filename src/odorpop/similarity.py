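"""Chemical-similarity coding analyses.

For every unit the strongest odour response (trial-averaged firing rate in
the odour window) defines a normalizer; responses to the remaining odours
are expressed relative to it.  Two views of the resulting table quantify
response selectivity:

* the *ranked curve*: mean relative strength as a function of within-unit
  response rank (1..6), and
* the *chain-distance curve*: mean relative strength as a function of
  |Δ carbon chain length| between each odour and the unit's best odour
  (the axis of chemical similarity for a homologous aldehyde series).

Genotype contrasts use an ordinary two-way ANOVA (genotype × chain distance)
for the chain-distance curve and a mixed (repeated-measures) two-way ANOVA
(genotype × rank, matched within unit) for the ranked curve, each followed
by Šídák-adjusted pairwise post-hocs within genotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclass
class SimilarityAnova:
    effects: dict  # name -> {"F", "df1", "df2", "p"}
    posthoc: pd.DataFrame | None = None
    kind: str = "two_way"


def relative_responses(strength_table: pd.DataFrame) -> pd.DataFrame:
    """Per-unit relative response strengths, ranks, and chain distances.

    ``strength_table`` needs columns unit_id, odour_carbon,
    response_strength (optionally genotype/region, carried through).
    Ties for the best odour break toward the lower carbon number.  Units
    whose strengths are all zero are excluded (normalization undefined).
    """
    required = {"unit_id", "odour_carbon", "response_strength"}
    if not required <= set(strength_table.columns):
        raise ValueError(f"strength table needs columns {sorted(required)}")
    out = []
    for unit_id, grp in strength_table.groupby("unit_id", sort=False):
        grp = grp.sort_values("odour_carbon").reset_index(drop=True)
        s = grp["response_strength"].to_numpy(dtype=float)
        if np.all(s == 0):
            continue
        best_idx = int(np.argmax(s))  # argmax -> first (lowest carbon) on ties
        best_carbon = int(grp.loc[best_idx, "odour_carbon"])
        rel = s / s[best_idx]
        # rank 1 = strongest; ties broken by carbon order (stable sort)
        order = np.argsort(-s, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(s) + 1)
        g = grp.copy()
        g["relative_strength"] = rel
        g["best_odour_flag"] = np.arange(len(s)) == best_idx
        g["rank"] = rank
        g["chain_distance"] = (g["odour_carbon"] - best_carbon).abs()
        out.append(g)
    if not out:
        raise ValueError("no unit with a non-zero response strength")
    return pd.concat(out, ignore_index=True)


def ranked_curve(table: pd.DataFrame, exclude_rank_1: bool = False) -> pd.DataFrame:
    """Mean relative strength per rank (per genotype when present)."""
    t = table[table["rank"] > 1] if exclude_rank_1 else table
    keys = ["genotype", "rank"] if "genotype" in t.columns else ["rank"]
    return (
        t.groupby(keys)["relative_strength"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )


def chain_distance_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Mean relative strength per |Δ chain| 1..5 (per genotype when present).

    The best odour (|Δ| = 0, relative 1 by construction) is excluded.  Cell
    counts are unequal across |Δ| because they depend on each unit's best
    odour; means are over whatever entries exist.
    """
    t = table[table["chain_distance"] > 0]
    keys = ["genotype", "chain_distance"] if "genotype" in t.columns else ["chain_distance"]
    return (
        t.groupby(keys)["relative_strength"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )


def sidak_adjust(p_values, m: int | None = None):
    """Šídák multiple-comparison adjustment: p_adj = 1 − (1 − p)^m."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < p.size:
        raise ValueError("m must be >= the number of tests")
    adj = 1.0 - (1.0 - p) ** m
    adj = np.clip(adj, 0.0, 1.0)
    return float(adj[0]) if np.isscalar(p_values) or adj.size == 1 else adj


def _sidak_posthoc(table: pd.DataFrame, value: str, factor: str, paired_on: str | None):
    """Pairwise comparisons across ``factor`` levels within each genotype."""
    rows = []
    genotypes = table["genotype"].unique() if "genotype" in table.columns else [None]
    for g in genotypes:
        t = table if g is None else table[table["genotype"] == g]
        levels = sorted(t[factor].unique())
        m = len(levels) * (len(levels) - 1) // 2
        for a, b in itertools.combinations(levels, 2):
            va = t.loc[t[factor] == a, [value] + ([paired_on] if paired_on else [])]
            vb = t.loc[t[factor] == b, [value] + ([paired_on] if paired_on else [])]
            if paired_on:
                merged = va.merge(vb, on=paired_on, suffixes=("_a", "_b"))
                res = _stats.ttest_rel(merged[f"{value}_a"], merged[f"{value}_b"])
            else:
                res = _stats.ttest_ind(va[value], vb[value])
            rows.append(
                dict(genotype=g, level_a=a, level_b=b,
                     statistic=float(res.statistic), p_raw=float(res.pvalue),
                     p_adj=sidak_adjust(float(res.pvalue), m))
            )
    return pd.DataFrame(rows)


def two_way_anova(
    table: pd.DataFrame,
    value: str = "relative_strength",
    factor_a: str = "genotype",
    factor_b: str = "chain_distance",
    repeated_on: str | None = None,
) -> SimilarityAnova:
    """Two-way ANOVA with factors ``factor_a`` (between) and ``factor_b``.

    Without ``repeated_on``: ordinary fixed-effects two-way ANOVA (Type II
    sums of squares, appropriate for the unbalanced chain-distance cells).
    With ``repeated_on`` (a subject/unit column): mixed ANOVA with
    ``factor_b`` as the within factor matched on that column.  Both are
    computed by pingouin.  Šídák-adjusted pairwise post-hocs across
    ``factor_b`` within each level of ``factor_a`` are attached.
    """
    import pingouin as pg

    df = table[[c for c in {value, factor_a, factor_b, repeated_on} if c]].dropna().copy()
    for f in (factor_a, factor_b):
        levels = df[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = (
        df.groupby([factor_a, factor_b], observed=True)[value]
        .count()
        .unstack(fill_value=0)
    )
    if (counts.to_numpy() < 1).any():
        empty = [
            (a, b)
            for a in counts.index
            for b in counts.columns
            if counts.loc[a, b] < 1
        ]
        raise ValueError(f"empty cell(s) {empty}")
    if float(np.var(df[value])) == 0.0:
        raise ValueError("all values identical: F undefined")

    if repeated_on is None:
        aov = pg.anova(data=df, dv=value, between=[factor_a, factor_b], ss_type=2)
        kind = "two_way"
    else:
        aov = pg.mixed_anova(data=df, dv=value, within=factor_b,
                             subject=repeated_on, between=factor_a)
        kind = "mixed"
    resid_df = np.nan
    if "DF" in aov.columns and (aov["Source"].str.lower() == "residual").any():
        resid_df = float(aov.loc[aov["Source"].str.lower() == "residual", "DF"].iloc[0])
    effects = {}
    for _, row in aov.iterrows():
        name = str(row["Source"])
        if name.lower() == "residual":
            continue
        p = row["p_unc"] if "p_unc" in aov.columns else row.get("p-unc", np.nan)
        effects[name] = {
            "F": float(row["F"]),
            "df1": float(row["DF1"] if "DF1" in aov.columns else row.get("DF", np.nan)),
            "df2": float(row["DF2"]) if "DF2" in aov.columns else resid_df,
            "p": float(p),
        }
    posthoc = _sidak_posthoc(
        df, value, factor_b, paired_on=repeated_on
    ) if "genotype" in df.columns or factor_a in df.columns else None
    return SimilarityAnova(effects=effects, posthoc=posthoc, kind=kind)


def chain_distance_effect(table: pd.DataFrame, value: str = "relative_strength") -> dict:
    """One-way ANOVA of relative strength across |Δ chain| levels.

    Used within a single genotype (where the two-way main effect is not
    defined); returns F, dfs and p of the classical one-way ANOVA.
    """
    t = table[table["chain_distance"] > 0]
    groups = [g[value].to_numpy() for _, g in t.groupby("chain_distance")]
    if len(groups) < 2:
        raise ValueError("need >= 2 chain-distance levels")
    F, p = _stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}
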