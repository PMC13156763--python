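"""Stratified group comparison of step micro-parameters.

A locomotion experiment yields hundreds of steps per fish, nested within
fish, nested within treatment groups.  Comparing groups step-wise therefore
uses a linear mixed model -- a fixed group effect plus a per-fish random
intercept -- which respects the repeated-measures structure (fitting fish
means with a t-test would discard the step-level information; pooling steps
with an ordinary regression would pseudo-replicate).

Because swimming context matters (a high speed change demands large, fast
bends; slow swimming exercises fine control), steps are additionally
stratified *within each fish* into the lowest 25% / middle 50% / highest
25% of a stratifying parameter (speed change, typically), cut at that
fish's own first and third quartiles, and each stratum is compared
separately.  Left-right gait asymmetry of any lateralized parameter is
quantified as (R - L) / (R + L) on per-side magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonResult",
    "stratify_steps",
    "asymmetry_index",
    "asymmetry_by_fish",
    "mixed_model_compare",
    "batch_compare",
    "STRATA",
]

STRATA = ("low", "mid", "high")


@dataclass
class ComparisonResult:
    """Outcome of one group comparison for one parameter and stratum."""

    parameter: str
    stratum: str
    estimate: float
    se: float
    pvalue: float
    n_steps: int
    n_fish: int
    method: str = "mixedlm"

    def as_row(self) -> dict:
        return dict(
            parameter=self.parameter,
            stratum=self.stratum,
            estimate=self.estimate,
            se=self.se,
            pvalue=self.pvalue,
            n_steps=self.n_steps,
            n_fish=self.n_fish,
            method=self.method,
        )


def stratify_steps(
    table: pd.DataFrame,
    parameter: str,
    fish_col: str = "fish",
    min_steps: int = 4,
) -> pd.DataFrame:
    """Label each step low / mid / high within its own fish.

    Cutoffs are the per-fish first and third quartiles of ``parameter``
    (linear-interpolation quantiles); values <= Q1 are ``low``, >= Q3 are
    ``high``, the rest ``mid``.  A fish with fewer than ``min_steps`` steps
    is labeled all-mid with a warning.  Returns a copy of the table with a
    ``{parameter}_stratum`` column.
    """
    if parameter not in table.columns:
        raise KeyError(f"no column {parameter!r}")
    out = table.copy()
    col = f"{parameter}_stratum"
    out[col] = "mid"
    for fish, grp in table.groupby(fish_col):
        vals = grp[parameter].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() < min_steps:
            warnings.warn(
                f"fish {fish!r} has < {min_steps} usable steps; all labeled mid",
                stacklevel=2,
            )
            continue
        q1, q3 = np.quantile(vals[finite], [0.25, 0.75])
        if q3 <= q1:  # degenerate spread: no outer quartiles to isolate
            continue
        labels = np.where(vals <= q1, "low", np.where(vals >= q3, "high", "mid"))
        labels[~finite] = "mid"
        out.loc[grp.index, col] = labels
    return out


def asymmetry_index(right_total: float, left_total: float) -> float:
    """(R - L) / (R + L) on magnitudes; +1 fully right-biased, -1 fully
    left-biased, NaN when both sides are zero."""
    r, l = abs(right_total), abs(left_total)
    total = r + l
    if total == 0:
        return float("nan")
    return (r - l) / total


def asymmetry_by_fish(
    table: pd.DataFrame,
    parameter: str,
    direction_col: str = "direction",
    fish_col: str = "fish",
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-fish left/right asymmetry of a lateralized parameter.

    ``mode="mean"`` compares per-side means of |parameter| (per-episode
    aggregate); ``mode="total"`` compares per-side sums (macro totals).
    """
    if mode not in ("mean", "total"):
        raise ValueError("mode must be 'mean' or 'total'")
    rows = []
    for fish, grp in table.groupby(fish_col):
        sides = {}
        for side in ("left", "right"):
            vals = grp.loc[grp[direction_col] == side, parameter].abs()
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                sides[side] = 0.0
            else:
                sides[side] = float(vals.sum() if mode == "total" else vals.mean())
        rows.append(
            dict(
                fish=fish,
                parameter=parameter,
                left=sides["left"],
                right=sides["right"],
                asymmetry=asymmetry_index(sides["right"], sides["left"]),
            )
        )
    return pd.DataFrame(rows)


def _fallback_compare(values, groups, fish, parameter, stratum, reason):
    """Fish-mean two-sample comparison used when the mixed model cannot be
    fit; clearly labeled in the result."""
    from scipy import stats as sps

    df = pd.DataFrame({"value": values, "group": groups, "fish": fish})
    means = df.groupby(["group", "fish"])["value"].mean()
    levels = sorted(df["group"].unique())
    a = means.loc[levels[0]].to_numpy()
    b = means.loc[levels[1]].to_numpy() if len(levels) > 1 else np.array([])
    if len(a) < 1 or len(b) < 1:
        est, se, p = np.nan, np.nan, np.nan
    elif len(a) < 2 or len(b) < 2:
        est, se, p = float(np.mean(b) - np.mean(a)) if len(b) else np.nan, np.nan, np.nan
    else:
        tt = sps.ttest_ind(b, a, equal_var=False)
        est = float(np.mean(b) - np.mean(a))
        se = est / tt.statistic if tt.statistic != 0 else np.nan
        p = float(tt.pvalue)
    warnings.warn(
        f"mixed model unavailable for {parameter}/{stratum} ({reason}); "
        "fell back to a fish-mean two-sample comparison",
        stacklevel=3,
    )
    return ComparisonResult(
        parameter=parameter,
        stratum=stratum,
        estimate=est,
        se=se,
        pvalue=p,
        n_steps=len(df),
        n_fish=df["fish"].nunique(),
        method="fish-mean t-test",
    )


def mixed_model_compare(
    values,
    groups,
    fish,
    parameter: str = "value",
    stratum: str = "all",
) -> ComparisonResult:
    """Linear mixed model: value ~ group (fixed) + fish random intercept.

    Fit by REML; the p-value refers the Wald statistic of the group
    coefficient to a t distribution with ``n_fish - 2`` degrees of freedom.
    The group contrast is a between-fish comparison, so its effective
    degrees of freedom are set by the number of fish, not the number of
    steps; the asymptotic normal reference is anticonservative at typical
    cohort sizes (~13 fish) and the between-cluster t reference restores
    the nominal error rate.  Requires two group levels with at least two
    fish each -- otherwise, or on a singular/failed fit, falls back to
    comparing fish means with a prominent warning.
    """
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    df = pd.DataFrame({"value": values, "group": groups, "fish": fish}).dropna()
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("exactly two group levels are required")
    fish_per_group = df.groupby("group")["fish"].nunique()
    if (fish_per_group < 2).any():
        return _fallback_compare(
            df["value"], df["group"], df["fish"], parameter, stratum,
            "fewer than 2 fish in a group",
        )
    if df["value"].nunique() < 2:
        return _fallback_compare(
            df["value"], df["group"], df["fish"], parameter, stratum, "constant values"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ C(group)", df, groups=df["fish"])
            fit = model.fit(reml=True)
        coef_name = [c for c in fit.params.index if c.startswith("C(group)")][0]
        est = float(fit.params[coef_name])
        se = float(fit.bse[coef_name])
        dof = df["fish"].nunique() - 2
        p = float(2.0 * sps.t.sf(abs(est / se), dof)) if se > 0 else np.nan
        if not np.isfinite(p):
            raise ValueError("non-finite p-value (singular fit)")
    except Exception as exc:  # singular fits, convergence failures
        return _fallback_compare(
            df["value"], df["group"], df["fish"], parameter, stratum, str(exc)
        )
    return ComparisonResult(
        parameter=parameter,
        stratum=stratum,
        estimate=est,
        se=se,
        pvalue=p,
        n_steps=len(df),
        n_fish=df["fish"].nunique(),
    )


def batch_compare(
    table: pd.DataFrame,
    parameters: list[str],
    stratifier: str = "speed_change",
    group_col: str = "group",
    fish_col: str = "fish",
    adjust: str | None = None,
) -> pd.DataFrame:
    """One comparison per parameter x {unstratified, low, mid, high}.

    Steps are stratified per fish by ``stratifier``; every parameter is
    compared group-wise in the full table and within each stratum.  Rows
    are deterministic in (parameter, stratum) order.  ``adjust="bh"``
    optionally appends Benjamini-Hochberg adjusted p-values (off by
    default: raw per-comparison p-values are reported).
    """
    table = stratify_steps(table, stratifier, fish_col=fish_col)
    strat_col = f"{stratifier}_stratum"
    rows = []
    for parameter in parameters:
        for stratum in ("all",) + STRATA:
            sub = table if stratum == "all" else table[table[strat_col] == stratum]
            ok = sub.dropna(subset=[parameter])
            groups_present = ok.groupby(group_col)[fish_col].nunique()
            if len(groups_present) < 2 or (groups_present < 1).any() or len(ok) == 0:
                warnings.warn(
                    f"empty stratum {stratum!r} for {parameter!r} in a group; "
                    "p undefined",
                    stacklevel=2,
                )
                rows.append(
                    ComparisonResult(
                        parameter=parameter,
                        stratum=stratum,
                        estimate=np.nan,
                        se=np.nan,
                        pvalue=np.nan,
                        n_steps=len(ok),
                        n_fish=ok[fish_col].nunique(),
                        method="undefined",
                    ).as_row()
                )
                continue
            res = mixed_model_compare(
                ok[parameter], ok[group_col], ok[fish_col],
                parameter=parameter, stratum=stratum,
            )
            rows.append(res.as_row())
    out = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = np.isfinite(out["pvalue"])
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask] = multipletests(out.loc[mask, "pvalue"], method="fdr_bh")[1]
        out["pvalue_bh"] = adj
    return out
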