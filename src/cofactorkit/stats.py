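"""Longitudinal statistics for plasma metabolite and protein panels.

All operations work on a long-format panel ``DataFrame`` with columns
``subject_id, arm, analyte, time_h, value`` (NaN value = missing).  The
pipeline is: normalize each subject/analyte trajectory to its t=0
baseline, then per analyte and time point run a two-group one-way ANOVA
(vs baseline, or supplementation vs control), adjust with
Benjamini-Hochberg FDR, and summarize analytes significant at >= k time
points.  Spearman correlations relate every analyte to the supplemented
cofactors.  Missing values are removed pairwise throughout.

A one-way ANOVA with two groups is the square of the pooled two-sample t
test; it is applied literally (unpaired) with a paired option for the
baseline comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PANEL_COLUMNS",
    "normalize_to_baseline",
    "anova_vs_baseline",
    "between_study_anova",
    "count_significant",
    "spearman_vs_cofactors",
    "detection_filter",
    "panel_intersection",
]

PANEL_COLUMNS = ["subject_id", "arm", "analyte", "time_h", "value"]


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    return panel


def normalize_to_baseline(panel: pd.DataFrame) -> pd.DataFrame:
    """Fold change of every record to its subject/analyte t=0 value.

    Subject-analyte pairs with a missing or zero baseline are dropped
    with a warning.  Idempotent: re-normalizing divides by the new
    baseline of exactly 1.
    """
    _check_panel(panel)
    df = panel.copy()
    base = (
        df[df["time_h"] == 0]
        .set_index(["subject_id", "analyte"])["value"]
        .rename("baseline")
    )
    df = df.join(base, on=["subject_id", "analyte"])
    bad = df["baseline"].isna() | (df["baseline"] == 0)
    if bad.any():
        dropped = df.loc[bad, ["subject_id", "analyte"]].drop_duplicates()
        warnings.warn(
            f"dropping {len(dropped)} subject-analyte pairs with missing/zero baseline"
        )
        df = df[~bad]
    df["value"] = df["value"] / df["baseline"]
    return df.drop(columns="baseline").reset_index(drop=True)


def _two_group_anova(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups (equals the pooled t squared)."""
    res = sps.f_oneway(a, b)
    return float(res.statistic), float(res.pvalue)


def _fdr(table: pd.DataFrame, scope: str) -> pd.DataFrame:
    table = table.copy()
    table["q"] = np.nan
    testable = table["p"].notna()
    if scope == "per_timepoint":
        for _, idx in table[testable].groupby("time_h").groups.items():
            table.loc[idx, "q"] = multipletests(
                table.loc[idx, "p"], method="fdr_bh"
            )[1]
    elif scope == "global":
        idx = table.index[testable]
        if len(idx):
            table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    else:
        raise ValueError("fdr_scope must be 'per_timepoint' or 'global'")
    return table


def anova_vs_baseline(
    fc_panel: pd.DataFrame,
    fdr_scope: str = "per_timepoint",
    paired: bool = False,
) -> pd.DataFrame:
    """Per analyte and time point, test fold changes against baseline.

    Unpaired (default): two-group one-way ANOVA of the time-t fold
    changes against the baseline fold changes (all 1 by construction).
    Paired: one-sample t test of per-subject (FC - 1), reported as F=t^2.
    Cells with n<2 or zero variance in both groups are marked untestable
    (NaN p) and excluded from the FDR adjustment.
    """
    _check_panel(fc_panel)
    base_groups = {
        analyte: grp.set_index("subject_id")["value"]
        for analyte, grp in fc_panel[fc_panel["time_h"] == 0].groupby("analyte")
    }
    rows = []
    for (analyte, time_h), grp in fc_panel[fc_panel["time_h"] != 0].groupby(
        ["analyte", "time_h"], sort=True
    ):
        base_s = base_groups.get(analyte, pd.Series(dtype=float))
        vals = grp["value"].dropna().to_numpy()
        base = base_s.dropna().to_numpy()
        f = p = np.nan
        n = vals.size
        if paired:
            diff = (
                grp.set_index("subject_id")["value"] - base_s
            ).dropna().to_numpy()
            n = diff.size
            if n >= 2 and diff.std(ddof=1) > 0:
                t, p = sps.ttest_1samp(diff, 0.0)
                f = float(t) ** 2
        elif vals.size >= 2 and base.size >= 2 and (
            vals.std(ddof=0) > 0 or base.std(ddof=0) > 0
        ):
            f, p = _two_group_anova(vals, base)
        if n:
            ref_mean = np.mean(base) if (not paired and base.size) else 1.0
            direction = "up" if np.mean(vals) > ref_mean else "down"
        else:
            direction = "flat"
        rows.append(
            {"analyte": analyte, "time_h": time_h, "F": f, "p": p,
             "direction": direction, "n": int(n)}
        )
    return _fdr(pd.DataFrame(rows), fdr_scope)


def between_study_anova(
    panel_suppl: pd.DataFrame,
    panel_control: pd.DataFrame,
    fdr_scope: str = "per_timepoint",
) -> pd.DataFrame:
    """Supplementation vs control one-way ANOVA per analyte and time point.

    Operates on fold-change panels; only analytes and time points present
    in both arms are tested.
    """
    _check_panel(panel_suppl)
    _check_panel(panel_control)
    combined = pd.concat(
        [panel_suppl.assign(_arm="a"), panel_control.assign(_arm="b")],
        ignore_index=True,
    )
    rows = []
    for (analyte, time_h), grp in combined[combined["time_h"] != 0].groupby(
        ["analyte", "time_h"], sort=True
    ):
        a = grp.loc[grp["_arm"] == "a", "value"].dropna().to_numpy()
        b = grp.loc[grp["_arm"] == "b", "value"].dropna().to_numpy()
        f = p = np.nan
        if a.size >= 2 and b.size >= 2 and (a.std(ddof=0) > 0 or b.std(ddof=0) > 0):
            f, p = _two_group_anova(a, b)
        if a.size and b.size:
            direction = "up" if a.mean() > b.mean() else "down"
        else:
            direction = "flat"
        rows.append(
            {"analyte": analyte, "time_h": time_h, "F": f, "p": p,
             "direction": direction, "n": int(a.size + b.size)}
        )
    return _fdr(pd.DataFrame(rows), fdr_scope)


def count_significant(
    test_table: pd.DataFrame, min_timepoints: int = 3, alpha: float = 0.05
) -> pd.DataFrame:
    """Analytes with q < alpha at >= ``min_timepoints`` time points."""
    if test_table.empty:
        return pd.DataFrame(columns=["analyte", "n_significant_timepoints"])
    sig = test_table[test_table["q"] < alpha]
    counts = (
        sig.groupby("analyte")
        .size()
        .rename("n_significant_timepoints")
        .reset_index()
    )
    return counts[counts["n_significant_timepoints"] >= min_timepoints].reset_index(
        drop=True
    )


def spearman_vs_cofactors(
    fc_panel: pd.DataFrame,
    cofactor_analytes: list[str],
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman rho of every analyte against each supplemented cofactor.

    Observations are paired on (subject, time) across all records;
    missing values are removed pairwise.  Pairs with fewer than
    ``min_pairs`` complete observations are recorded untested (NaN);
    BH-FDR is applied across all tested pairs.
    """
    _check_panel(fc_panel)
    wide = fc_panel.pivot_table(
        index=["subject_id", "time_h"], columns="analyte", values="value"
    )
    rows = []
    for cof in cofactor_analytes:
        if cof not in wide.columns:
            raise ValueError(f"cofactor analyte '{cof}' not in panel")
        y_all = wide[cof].to_numpy(dtype=float)
        for analyte in wide.columns:
            x_all = wide[analyte].to_numpy(dtype=float)
            mask = np.isfinite(x_all) & np.isfinite(y_all)
            pair = np.column_stack([x_all[mask], y_all[mask]])
            rho = p = np.nan
            if len(pair) >= min_pairs:
                rho, p = sps.spearmanr(pair[:, 0], pair[:, 1])
            rows.append(
                {"analyte": analyte, "cofactor": cof, "rho": rho, "p": p,
                 "n": int(len(pair))}
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table


def detection_filter(
    raw_panel: pd.DataFrame, min_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep analytes detected in more than ``min_fraction`` of samples.

    The inequality is strict (an analyte at exactly the threshold is
    dropped).  Returns the filtered panel and a per-analyte report with
    detection fractions and the kept/dropped status.
    """
    _check_panel(raw_panel)
    frac = raw_panel.groupby("analyte")["value"].apply(
        lambda v: float(v.notna().mean())
    )
    report = frac.rename("detected_fraction").reset_index()
    report["kept"] = report["detected_fraction"] > min_fraction
    kept = set(report.loc[report["kept"], "analyte"])
    return raw_panel[raw_panel["analyte"].isin(kept)].reset_index(drop=True), report


def _normalize_name(name: str) -> str:
    return "".join(ch for ch in str(name).casefold() if ch.isalnum())


def panel_intersection(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    name_map: dict[str, str] | None = None,
) -> list[str]:
    """Analytes present in both panels after name normalization.

    Names are case-folded and stripped of punctuation before matching;
    ``name_map`` overrides individual normalizations.  Returns the
    (sorted) analyte names as spelled in ``panel_a``.
    """
    name_map = name_map or {}

    def norm(n: str) -> str:
        return name_map.get(n, _normalize_name(n))

    a_names = {norm(n): n for n in panel_a["analyte"].unique()}
    b_keys = {norm(n) for n in panel_b["analyte"].unique()}
    return sorted(a_names[k] for k in set(a_names) & b_keys)
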