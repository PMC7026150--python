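"""Published group-summary fixtures and their recomputation.

Ships the three printed descriptive tables (validation boys vs girls,
male siblings vs male controls, female siblings vs female controls) and
the proband masculinity-score summaries as package data, and recomputes
every test statistic from the printed (n, M, SD) values so deviations
from the printed statistics can be inspected.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from . import stats
from .stats import GroupSummary

__all__ = [
    "FEATURES",
    "load_table",
    "load_probands",
    "row_summaries",
    "feature_moments",
    "cohort_moments",
    "score_moments",
    "recompute_printed_tables",
    "facial_area_moments",
    "PRINTED_ANOVA",
]

#: Canonical ordering of the 11 distance features (3 linear, 8 geodesic).
FEATURES: tuple[str, ...] = (
    "linear_alar_base_width",
    "linear_nose_height",
    "linear_upper_lip_height",
    "geodesic_outer_canthal_width",
    "geodesic_forehead_height",
    "geodesic_forehead_width",
    "geodesic_right_upper_cheek_height",
    "geodesic_nasal_tip_protrusion",
    "geodesic_nose_height",
    "geodesic_upper_lip_height",
    "geodesic_nasal_bridge_length",
)

#: Printed one-way ANOVA results for the proband/sibling/control comparison.
PRINTED_ANOVA = {
    "male": {"F": 16.8, "df_between": 2, "df_within": 150},
    "female": {"F": 14.0, "df_between": 2, "df_within": 102},
}

_GROUP_LABELS = {
    "table1": ("boys", "girls"),
    "table2": ("male_siblings", "male_controls"),
    "table3": ("female_siblings", "female_controls"),
}


@lru_cache(maxsize=None)
def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("facedim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def _load_table_cached(name: str) -> pd.DataFrame:
    df = _read_csv(f"{name}.csv").copy()
    df["flags"] = df["flags"].fillna("").map(lambda s: tuple(f for f in s.split(";") if f))
    return df


def load_table(name: str) -> pd.DataFrame:
    """Load a printed table fixture: 'table1', 'table2' or 'table3'."""
    if name not in _GROUP_LABELS:
        raise KeyError(f"unknown table {name!r}; expected one of {sorted(_GROUP_LABELS)}")
    return _load_table_cached(name).copy()


def load_probands() -> pd.DataFrame:
    """Masculinity-score summaries of the autistic proband groups."""
    return _read_csv("probands.csv")


def row_summaries(row: pd.Series, labels: tuple[str, str]) -> tuple[GroupSummary, GroupSummary]:
    s1 = GroupSummary(n=int(row.n1), location=float(row.loc1), spread=float(row.spread1),
                      kind=row.kind, label=labels[0])
    s2 = GroupSummary(n=int(row.n2), location=float(row.loc2), spread=float(row.spread2),
                      kind=row.kind, label=labels[1])
    return s1, s2


def feature_moments(table: str, side: int) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, SD) of one group column of a table.

    ``side`` is 1 for the first printed group (boys / siblings) and 2 for
    the second (girls / controls). median/IQR rows are converted to
    mean/SD under normality.
    """
    if side not in (1, 2):
        raise ValueError("side must be 1 or 2")
    df = load_table(table)
    out: dict[str, tuple[float, float]] = {}
    for row in df.itertuples():
        loc = float(getattr(row, f"loc{side}"))
        spread = float(getattr(row, f"spread{side}"))
        if row.kind == "median_iqr":
            spread = stats.iqr_to_sd(spread)
        out[row.feature_key] = (loc, spread)
    return out


def cohort_moments(group: str) -> tuple[np.ndarray, np.ndarray, int]:
    """11-feature (means, SDs, n) for a study group.

    Groups: validation_male / validation_female use the validation table;
    sibling_* / control_* use the sibling-comparison tables for the eight
    dimorphic distances and fall back to the same-sex validation column
    for the three distances those tables do not report.
    """
    t1_male = feature_moments("table1", 1)
    t1_female = feature_moments("table1", 2)
    if group == "validation_male":
        base, n = t1_male, 40
    elif group == "validation_female":
        base, n = t1_female, 40
    elif group in ("sibling_male", "control_male", "sibling_female", "control_female"):
        sex = group.split("_")[1]
        table = "table2" if sex == "male" else "table3"
        side = 1 if group.startswith("sibling") else 2
        reported = feature_moments(table, side)
        base = dict(t1_male if sex == "male" else t1_female)
        base.update({k: v for k, v in reported.items() if k in FEATURES})
        df = load_table(table)
        n = int(df.iloc[0][f"n{side}"])
    else:
        raise KeyError(f"unknown group {group!r}")
    means = np.array([base[f][0] for f in FEATURES])
    sds = np.array([base[f][1] for f in FEATURES])
    return means, sds, n


def score_moments(group: str) -> tuple[float, float, int]:
    """(mean, SD, n) of the masculinity score for one study group."""
    if group in ("proband_male", "proband_female"):
        df = load_probands()
        row = df[df.sex == group.split("_")[1]].iloc[0]
        return float(row["mean"]), float(row["sd"]), int(row["n"])
    sex = group.split("_")[1]
    table = "table2" if sex == "male" else "table3"
    side = 1 if group.startswith("sibling") else 2
    df = load_table(table)
    row = df[df.variable == "masculinity_score"].iloc[0]
    loc = float(row[f"loc{side}"])
    spread = float(row[f"spread{side}"])
    if row.kind == "median_iqr":
        spread = stats.iqr_to_sd(spread)
    return loc, spread, int(row[f"n{side}"])


def facial_area_moments(group: str) -> tuple[float, float, int]:
    """(mean, SD, n) of facial area for one study group, converting the
    median/IQR validation row under normality."""
    if group.startswith("validation"):
        table, side = "table1", (1 if group.endswith("male") else 2)
    else:
        sex = group.split("_")[1]
        table = "table2" if sex == "male" else "table3"
        side = 1 if group.startswith("sibling") else 2
    df = load_table(table)
    row = df[df.variable == "facial_area"].iloc[0]
    loc = float(row[f"loc{side}"])
    spread = float(row[f"spread{side}"])
    if row.kind == "median_iqr":
        spread = stats.iqr_to_sd(spread)
    return loc, spread, int(row[f"n{side}"])


def recompute_printed_tables(
    alpha: float = 0.05,
    tables: Iterable[str] = ("table1", "table2", "table3"),
) -> tuple[pd.DataFrame, dict]:
    """Recompute t, df, p, d and the d CI from every printed summary row.

    Returns a tidy frame with printed values, recomputed values and
    absolute deviations, plus a per-table summary with the count of
    distance features significant at ``alpha``. A Holm-adjusted p column
    is included for transparency but does not feed the headline counts.
    """
    records = []
    for table in tables:
        df = load_table(table)
        labels = _GROUP_LABELS[table]
        for _, row in df.iterrows():
            s1, s2 = row_summaries(row, labels)
            res = stats.welch_from_summaries(s1, s2, median_approx=True)
            records.append({
                "table": table,
                "variable": row.variable,
                "feature_key": row.feature_key,
                "kind": row.kind,
                "printed_stat_name": row.stat_name,
                "printed_stat": row.stat,
                "printed_df": row.df,
                "printed_p": row.p,
                "printed_d": row.d,
                "printed_d_lo": row.d_lo,
                "printed_d_hi": row.d_hi,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "d": res.d,
                "d_lo": res.d_ci[0],
                "d_hi": res.d_ci[1],
                "significant": res.p < alpha,
                "median_iqr_approx": res.approximated_from_median_iqr,
                "abs_dev_stat": (abs(res.statistic - abs(float(row.stat)))
                                 if row.stat_name == "t" else np.nan),
                "abs_dev_df": (abs(res.df - float(row.df))
                               if pd.notna(row.df) else np.nan),
                "abs_dev_d": abs(abs(res.d) - abs(float(row.d))),
            })
    report = pd.DataFrame.from_records(records)
    report["holm_p"] = np.nan
    summary: dict = {"alpha": alpha, "tables": {}}
    for table in tables:
        mask = report.table == table
        feat = mask & report.feature_key.isin(FEATURES)
        report.loc[feat, "holm_p"] = stats.holm_adjust(report.loc[feat, "p"].to_numpy())
        summary["tables"][table] = {
            "n_feature_rows": int(feat.sum()),
            "n_significant_features": int(report.loc[feat, "significant"].sum()),
            "max_abs_dev_df": float(np.nanmax(report.loc[mask, "abs_dev_df"].to_numpy())),
        }
    return report, summary
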