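"""Group comparisons, percent-change reporting and cohort report assembly.

The comparison conventions mirror standard muscle-physiology reporting:
classic (equal-variance) Student's t-tests, paired t-tests for
within-heart contrasts, one- and two-way ANOVA with Bonferroni-adjusted
pairwise follow-ups, significance stars at p < 0.05 / 0.01 / 0.001, and
percent changes rounded half away from zero for text reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

TESTS = ("t_unpaired", "t_paired", "anova1_bonferroni", "anova2_bonferroni")


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if p is None or not math.isfinite(p):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def percent_change(reference: float, test: float, rounded: bool = False):
    """100 (test - reference) / reference; optionally rounded to the
    nearest integer percent, half away from zero."""
    if reference == 0:
        raise ValueError("zero reference value")
    pct = 100.0 * (test - reference) / reference
    if rounded:
        return int(math.copysign(math.floor(abs(pct) + 0.5), pct))
    return pct


@dataclass
class GroupComparison:
    """One statistical contrast with per-group estimates."""

    group_labels: tuple
    estimates: dict          # label -> {"mean": ..., "sem"/"sd": ..., "n": ...}
    test: str
    statistic: float | None
    p_value: float | None
    p_adjusted: float | None = None
    flag: str | None = None

    @property
    def stars(self) -> str:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return significance_stars(p) if p is not None else ""


def _estimates(df: pd.DataFrame, value: str, group: str,
               dispersion: str = "sem") -> dict:
    out = {}
    for label, sub in df.groupby(group, sort=True):
        v = sub[value].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        disp = sd / math.sqrt(v.size) if dispersion == "sem" else sd
        out[label] = {"mean": float(np.mean(v)), dispersion: disp, "n": int(v.size)}
    return out


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment p*m, capped at 1."""
    return min(1.0, p * m)


def compare_groups(df: pd.DataFrame, design: dict) -> list[GroupComparison]:
    """Run the comparison described by ``design`` on a tidy table.

    ``design`` keys: ``test`` (one of t_unpaired, t_paired,
    anova1_bonferroni, anova2_bonferroni), ``value`` (response column),
    ``group`` (factor column), plus ``pair_by`` (subject column, paired
    t), ``group2`` (second factor, two-way ANOVA), ``dispersion``
    ("sem" or "sd") and ``m_comparisons`` (Bonferroni m; default = number
    of pairwise contrasts).
    """
    test = design["test"]
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    value, group = design["value"], design["group"]
    dispersion = design.get("dispersion", "sem")
    labels = sorted(df[group].unique())
    est = _estimates(df, value, group, dispersion)
    for lab in labels:
        if est[lab]["n"] < 2:
            raise ValueError(f"group {lab!r}: need >= 2 observations")

    if test == "t_unpaired":
        if len(labels) != 2:
            raise ValueError("t_unpaired needs exactly 2 groups")
        a = df.loc[df[group] == labels[0], value].to_numpy(dtype=float)
        b = df.loc[df[group] == labels[1], value].to_numpy(dtype=float)
        flag = None
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            return [GroupComparison(tuple(labels), est, test, None, None,
                                    flag="zero_variance")]
        res = sps.ttest_ind(a, b, equal_var=True)
        return [GroupComparison(tuple(labels), est, test,
                                float(res.statistic), float(res.pvalue), flag=flag)]

    if test == "t_paired":
        pair_by = design["pair_by"]
        if len(labels) != 2:
            raise ValueError("t_paired needs exactly 2 groups")
        wide = df.pivot(index=pair_by, columns=group, values=value).dropna()
        d = wide[labels[1]].to_numpy(dtype=float) - wide[labels[0]].to_numpy(dtype=float)
        if np.var(d, ddof=1) == 0:
            return [GroupComparison(tuple(labels), est, test, None, None,
                                    flag="zero_variance")]
        res = sps.ttest_rel(wide[labels[1]], wide[labels[0]])
        return [GroupComparison(tuple(labels), est, test,
                                float(res.statistic), float(res.pvalue))]

    if test == "anova1_bonferroni":
        groups = [df.loc[df[group] == lab, value].to_numpy(dtype=float)
                  for lab in labels]
        f_res = sps.f_oneway(*groups)
        out = [GroupComparison(tuple(labels), est, "anova1",
                               float(f_res.statistic), float(f_res.pvalue))]
        pairs = list(combinations(range(len(labels)), 2))
        m = design.get("m_comparisons", len(pairs))
        for i, j in pairs:
            t_res = sps.ttest_ind(groups[i], groups[j], equal_var=True)
            out.append(GroupComparison(
                (labels[i], labels[j]),
                {labels[i]: est[labels[i]], labels[j]: est[labels[j]]},
                "t_bonferroni", float(t_res.statistic), float(t_res.pvalue),
                p_adjusted=bonferroni(float(t_res.pvalue), m)))
        return out

    # two-way ANOVA (between-subjects) with Bonferroni pairwise contrasts
    # on the primary factor within each level of the second factor
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    group2 = design["group2"]
    data = df.rename(columns={value: "_y", group: "_g1", group2: "_g2"})
    model = smf.ols("_y ~ C(_g1) * C(_g2)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for effect in table.index:
        if effect == "Residual":
            continue
        out.append(GroupComparison(
            tuple(labels), est, "anova2",
            float(table.loc[effect, "F"]), float(table.loc[effect, "PR(>F)"]),
            flag=effect.replace("C(_g1)", group).replace("C(_g2)", group2)))
    levels2 = sorted(df[group2].unique())
    pairs = [(lv, a, b) for lv in levels2
             for a, b in combinations(labels, 2)]
    m = design.get("m_comparisons", len(pairs))
    for lv, a, b in pairs:
        sub = df[df[group2] == lv]
        xa = sub.loc[sub[group] == a, value].to_numpy(dtype=float)
        xb = sub.loc[sub[group] == b, value].to_numpy(dtype=float)
        if xa.size < 2 or xb.size < 2:
            continue
        t_res = sps.ttest_ind(xa, xb, equal_var=True)
        out.append(GroupComparison(
            (f"{a}@{lv}", f"{b}@{lv}"), {}, "t_bonferroni",
            float(t_res.statistic), float(t_res.pvalue),
            p_adjusted=bonferroni(float(t_res.pvalue), m)))
    return out


# --------------------------------------------------------------------------
# cohort report assembly

def build_report(tables: dict[str, pd.DataFrame],
                 sources: dict[str, dict[str, str]],
                 config: dict | None = None) -> dict:
    """Merge module outputs into one machine-readable cohort report.

    ``tables`` maps table name -> tidy DataFrame; ``sources`` maps table
    name -> {column -> operation id}, so that every cell in the report
    carries the identifier of the operation that produced it.  Columns
    without a source entry are rejected, which keeps the report fully
    traceable.  The output is a plain nested dict; ``report_to_json``
    serializes it deterministically.
    """
    if not tables:
        raise ValueError("at least one module output required")
    report: dict = {"config": dict(config or {}), "tables": {}}
    for name, df in tables.items():
        src = sources.get(name, {})
        missing = [c for c in df.columns if c not in src]
        if missing:
            raise ValueError(f"table {name!r}: no source recorded for {missing}")
        rows = []
        for _, row in df.iterrows():
            rows.append({col: {"value": _jsonable(row[col]), "source": src[col]}
                         for col in df.columns})
        report["tables"][name] = rows
    return report


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2, separators=(",", ": "))
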