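"""Descriptive and inferential cohort statistics for plate-fit results.

Reproduces the study's statistical toolkit: Mann–Whitney U for two
independent samples (continuous measures), Pearson chi-square (without
continuity correction) for criterion pass rates, and Spearman rank
correlation for associations; all tests two-sided with alpha = 0.05 and
no multiple-testing correction.  Descriptive tables report the
``median ± SD (range)`` convention of the source tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError

ALPHA = 0.05
EXACT_N_MAX = 8  # exact Mann-Whitney enumeration up to this group size


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when both groups have at most
    :data:`EXACT_N_MAX` observations and there are no ties; otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateTestError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise DegenerateTestError("pooled data are constant")
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(a), len(b)) <= EXACT_N_MAX
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      test=f"mann-whitney-u ({method})",
                      n_a=len(a), n_b=len(b))


def chi_square_fit_rates(pass_counts, group_sizes) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2
    pass/fail-by-group table."""
    pass_counts = np.asarray(pass_counts, dtype=float)
    group_sizes = np.asarray(group_sizes, dtype=float)
    if pass_counts.shape != (2,) or group_sizes.shape != (2,):
        raise DegenerateTestError("expect two groups")
    if np.any(pass_counts > group_sizes) or np.any(group_sizes <= 0):
        raise DegenerateTestError("invalid pass counts / group sizes")
    table = np.array([pass_counts, group_sizes - pass_counts]).T  # 2x2
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected == 0):
        raise DegenerateTestError("zero expected cell count")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p),
                      test="chi-square (pearson, no correction)",
                      n_a=int(group_sizes[0]), n_b=int(group_sizes[1]))


def spearman_rho(x, y) -> TestResult:
    """Two-sided Spearman rank correlation with average-rank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateTestError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      test="spearman", n_a=len(x), n_b=len(x))


# ---------------------------------------------------------------------------
# Strata and tables
# ---------------------------------------------------------------------------

def age_group_of(age: float) -> str:
    """Young (< 65 years) vs old (>= 65 years)."""
    return "young" if age < 65 else "old"


def _stratum_rows(df: pd.DataFrame):
    """(label tuple, sub-frame) iterator over the standard table strata:
    ethnicity x {both, young, old} x {all, male, female}."""
    for eth in sorted(df["ethnicity"].unique()):
        de = df[df["ethnicity"] == eth]
        for grp_label, dg in (("both", de),
                              ("young", de[de["age_group"] == "young"]),
                              ("old", de[de["age_group"] == "old"])):
            for sex_label, ds in (("all", dg),
                                  ("male", dg[dg["sex"] == "male"]),
                                  ("female", dg[dg["sex"] == "female"])):
                yield (eth, grp_label, sex_label), ds


def _desc(values: np.ndarray) -> dict:
    """median ± SD (range) block; SD blank for n < 2."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return {"median": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return {"median": float(np.median(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
            "min": float(values.min()), "max": float(values.max())}


def descriptive_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptives per stratum (age / height / bow radius)."""
    rows = []
    for (eth, grp, sex), ds in _stratum_rows(summary):
        row = {"ethnicity": eth, "age_group": grp, "sex": sex, "n": len(ds)}
        for col, label in (("age", "age"), ("height_cm", "height"),
                           ("true_R_bow_mm", "roc")):
            d = _desc(ds[col].to_numpy()) if len(ds) else _desc([])
            row.update({f"{label}_{k}": v for k, v in d.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def fit_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum criterion distances and satisfaction rates."""
    rows = []
    for (eth, grp, sex), ds in _stratum_rows(summary):
        row = {"ethnicity": eth, "age_group": grp, "sex": sex, "n": len(ds)}
        for crit in ("c1", "c2", "c3"):
            d = _desc(ds[f"{crit}_mean_mm"].to_numpy()) if len(ds) else _desc([])
            row.update({f"{crit}_{k}": v for k, v in d.items()})
            n_pass = int(ds[f"{crit}_pass"].sum()) if len(ds) else 0
            row[f"{crit}_satisfied_n"] = n_pass
            row[f"{crit}_satisfied_pct"] = (100.0 * n_pass / len(ds)
                                            if len(ds) else np.nan)
        n_all = int(ds["overall_pass"].sum()) if len(ds) else 0
        row["all_satisfied_n"] = n_all
        row["all_satisfied_pct"] = 100.0 * n_all / len(ds) if len(ds) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _comparisons(df: pd.DataFrame):
    """The pairwise group comparisons of the published test grids."""
    out = []
    eths = sorted(df["ethnicity"].unique())
    for eth in eths:
        de = df[df["ethnicity"] == eth]
        out.append((f"{eth} males vs females", de[de["sex"] == "male"],
                    de[de["sex"] == "female"]))
        out.append((f"{eth} young vs old", de[de["age_group"] == "young"],
                    de[de["age_group"] == "old"]))
    if len(eths) == 2:
        a, b = eths
        da, db = df[df["ethnicity"] == a], df[df["ethnicity"] == b]
        out.append((f"{a} vs {b} (all)", da, db))
        for sex in ("male", "female"):
            out.append((f"{a} vs {b} ({sex}s)", da[da["sex"] == sex],
                        db[db["sex"] == sex]))
    return out


def _safe_mwu_p(a, b):
    try:
        return mann_whitney_u(a, b).p_value
    except DegenerateTestError:
        return np.nan


def comparison_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Mann–Whitney p-values for age/height/ROC between group pairs."""
    rows = []
    for label, da, db in _comparisons(summary):
        row = {"comparison": label, "n_a": len(da), "n_b": len(db)}
        for col, name in (("age", "age_p"), ("height_cm", "height_p"),
                          ("true_R_bow_mm", "roc_p")):
            row[name] = (_safe_mwu_p(da[col], db[col])
                         if len(da) and len(db) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_comparison_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Mann–Whitney p-values on criterion distances and chi-square
    p-values on criterion pass rates between group pairs."""
    rows = []
    for label, da, db in _comparisons(summary):
        row = {"comparison": label, "n_a": len(da), "n_b": len(db)}
        for crit in ("c1", "c2", "c3"):
            if len(da) and len(db):
                row[f"{crit}_distance_p"] = _safe_mwu_p(
                    da[f"{crit}_mean_mm"], db[f"{crit}_mean_mm"])
                try:
                    row[f"{crit}_satisfied_p"] = chi_square_fit_rates(
                        [da[f"{crit}_pass"].sum(), db[f"{crit}_pass"].sum()],
                        [len(da), len(db)]).p_value
                except DegenerateTestError:
                    row[f"{crit}_satisfied_p"] = np.nan
            else:
                row[f"{crit}_distance_p"] = np.nan
                row[f"{crit}_satisfied_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Spearman associations between height/ROC/age and fit measures."""
    pairs = [("height_cm", "true_R_bow_mm"),
             ("height_cm", "proximal_tip_mm"),
             ("true_R_bow_mm", "proximal_tip_mm"),
             ("height_cm", "distal_tip_mm"),
             ("true_R_bow_mm", "distal_tip_mm"),
             ("age", "true_R_bow_mm"),
             ("height_cm", "c3_mean_mm"),
             ("true_R_bow_mm", "c3_mean_mm")]
    rows = []
    for x, y in pairs:
        if x not in summary or y not in summary or len(summary) < 3:
            continue
        try:
            r = spearman_rho(summary[x], summary[y])
            rows.append({"x": x, "y": y, "rho": r.statistic,
                         "p": r.p_value, "n": r.n_a})
        except DegenerateTestError:
            rows.append({"x": x, "y": y, "rho": np.nan, "p": np.nan,
                         "n": len(summary)})
    return pd.DataFrame(rows)


def make_tables(summary: pd.DataFrame) -> dict:
    """All cohort output tables from a per-bone fit summary frame."""
    return {
        "descriptives": descriptive_table(summary),
        "group_comparisons": comparison_table(summary),
        "fit": fit_table(summary),
        "fit_comparisons": fit_comparison_table(summary),
        "correlations": correlation_table(summary),
    }
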