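"""Population comparisons: Welch t-tests, one-way ANOVA with Tukey HSD.

The Welch (unequal-variance) two-sample t-test is the default because
population comparisons here are built from small groups (n = 5) whose
variances routinely differ severalfold; the Welch–Satterthwaite
degrees of freedom are what reproduce published two-decimal p-values
from printed mean ± SD summaries where a pooled test does not.

``welch_from_summary`` works directly from printed summary statistics
(mean, SD, n per group), its raw-data twin ``welch_from_raw`` from
value vectors.  ``anova_tukey`` wraps the classical one-way fixed
effects ANOVA with Tukey's honestly-significant-difference post hoc.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("thermadapt")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test result with the summary statistics that produced it."""

    label: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    method: str = "welch"
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "mean1": self.mean1, "sd1": self.sd1, "n1": self.n1,
            "mean2": self.mean2, "sd2": self.sd2, "n2": self.n2,
            "t": self.t, "df": self.df, "p": self.p,
            "method": self.method,
        }


def format_p(p: float) -> str:
    """Report rounding for p-values: 2 decimals, 3 when p < 0.005."""
    if math.isnan(p):
        return "nan"
    return f"{p:.3f}" if p < 0.005 else f"{p:.2f}"


def welch_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    label: str = "",
) -> GroupComparison:
    """Welch's t-test from per-group mean, SD and n.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2), with Welch–Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.
    Both SDs zero is degenerate: p = 1 when the means agree, p → 0
    otherwise (flagged, not raised).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return GroupComparison(label, mean1, sd1, n1, mean2, sd2, n2,
                                   t=0.0, df=float(n1 + n2 - 2), p=1.0,
                                   degenerate=True)
        return GroupComparison(label, mean1, sd1, n1, mean2, sd2, n2,
                               t=math.copysign(math.inf, mean1 - mean2),
                               df=float(n1 + n2 - 2), p=0.0, degenerate=True)
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(label, mean1, sd1, n1, mean2, sd2, n2,
                           t=t, df=df, p=p)


def welch_from_raw(
    values1: Sequence[float], values2: Sequence[float], label: str = ""
) -> GroupComparison:
    """Welch's t-test from raw value vectors (sample SD, n − 1 denominator)."""
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need >=2 values per group")
    return welch_from_summary(
        float(x1.mean()), float(x1.std(ddof=1)), int(x1.size),
        float(x2.mean()), float(x2.std(ddof=1)), int(x2.size),
        label=label,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg FDR-adjusted p-values (off by default in reports)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA followed by Tukey's HSD.

    All groups being one identical constant is degenerate (F = 0,
    p = 1: no variance to partition); otherwise F and p come from
    the F distribution and the post hoc from the studentized range.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has <2 values")
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate(
        [np.repeat(name, arr.size) for name, arr in arrays.items()]
    )
    df_between = len(arrays) - 1
    df_within = values.size - len(arrays)

    grand = values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    if ss_within == 0.0 and ss_between == 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat, p = stats.f_oneway(*arrays.values())
        f_stat, p = float(f_stat), float(p)

    hsd = pairwise_tukeyhsd(values, labels)
    pairs = [
        (hsd.groupsunique[i], hsd.groupsunique[j])
        for i, j in zip(*np.triu_indices(len(hsd.groupsunique), 1))
    ]
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": hsd.meandiffs,
            "p_adj": hsd.pvalues,
            "lower": hsd.confint[:, 0],
            "upper": hsd.confint[:, 1],
            "reject": hsd.reject,
        }
    )
    return AnovaResult(f=f_stat, df_between=df_between, df_within=df_within,
                       p=p, tukey=tukey)


def population_report(
    arrhenius: pd.DataFrame,
    profiles: pd.DataFrame,
    populations: tuple[str, str] | None = None,
    temperatures: Sequence[float] = (5.0, 10.0),
    digits: int = 3,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per tissue × enzyme comparison table between two populations.

    For each requested temperature: mean ± SD per population and the
    Welch p built from those summaries; likewise for the per-replicate
    activation energies.  With a single population the p columns are
    omitted.  Tissue × enzyme cells present for only one population
    are skipped with a warning.  ``adjust="bh"`` applies a
    Benjamini–Hochberg correction jointly over all p-values in the
    report; the default reports raw p per cell.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    pops = sorted(profiles["population"].unique()) if populations is None \
        else list(populations)
    if len(pops) > 2:
        raise ValueError("population_report compares at most two populations")
    single = len(pops) == 1

    rows = []
    combos = profiles[["tissue", "enzyme"]].drop_duplicates()
    for tissue, enzyme in combos.itertuples(index=False):
        prof = profiles[(profiles["tissue"] == tissue)
                        & (profiles["enzyme"] == enzyme)]
        ea = arrhenius[(arrhenius["tissue"] == tissue)
                       & (arrhenius["enzyme"] == enzyme)]
        present = set(prof["population"])
        if not single and not set(pops) <= present:
            logger.warning("%s/%s: unmatched population pair, row skipped",
                           tissue, enzyme)
            continue
        row: dict = {"tissue": tissue, "enzyme": enzyme}
        for temp in temperatures:
            cell = prof[prof["temperature_C"] == temp]
            stats_by_pop = {}
            for pop in pops:
                sub = cell[cell["population"] == pop]
                if len(sub) != 1:
                    continue
                rec = sub.iloc[0]
                stats_by_pop[pop] = (rec["mean"], rec["sd"], int(rec["n"]))
                row[f"{pop}_mean_{temp:g}C"] = round(rec["mean"], digits)
                row[f"{pop}_sd_{temp:g}C"] = round(rec["sd"], digits)
            if not single and len(stats_by_pop) == 2:
                (m1, s1, k1), (m2, s2, k2) = (stats_by_pop[p] for p in pops)
                cmp_ = welch_from_summary(m1, s1, k1, m2, s2, k2)
                row[f"p_{temp:g}C"] = cmp_.p
        ea_by_pop = {}
        for pop in pops:
            vals = ea[ea["population"] == pop]["ea_kj_mol"].to_numpy()
            if vals.size:
                ea_by_pop[pop] = vals
                row[f"{pop}_ea_mean"] = round(float(vals.mean()), digits)
                row[f"{pop}_ea_sd"] = round(float(vals.std(ddof=1)), digits) \
                    if vals.size > 1 else 0.0
        if not single and len(ea_by_pop) == 2:
            cmp_ = welch_from_raw(*(ea_by_pop[p] for p in pops))
            row["p_ea"] = cmp_.p
        rows.append(row)
    df = pd.DataFrame(rows)
    p_cols = [c for c in df.columns if c.startswith("p_")]
    if p_cols:
        if adjust == "bh":
            flat = df[p_cols].to_numpy(dtype=float).ravel()
            ok = ~np.isnan(flat)
            flat[ok] = benjamini_hochberg(flat[ok])
            df[p_cols] = flat.reshape((len(df), len(p_cols)))
        for c in p_cols:
            df[c] = df[c].map(
                lambda v: format_p(v) if pd.notna(v) else v)
    return df
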