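"""The study's three analyses as reproducible, serializable steps.

* validation: sex-classification accuracy plus per-feature dimorphism
  tests on a labelled boy/girl cohort (or on the printed summary table).
* sibling comparison: sibling vs same-sex control on facial area, the
  masculinity score and the eight dimorphic distances.
* three-group: proband / sibling / control ANOVA with Tukey HSD and
  score-density curves per group.

Every comparison row records which test was chosen (parametric or
nonparametric, via Shapiro–Wilk) and whether the observed shift points in
the masculinised direction for that feature.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import stats, tables
from .gender_model import GenderModel, fit_lda, normalize_sex
from .stats import GroupSummary
from .tables import FEATURES

__all__ = [
    "StudyConfig",
    "MASCULINE_DIRECTION",
    "run_validation",
    "run_sibling_comparison",
    "run_three_group",
    "density_curve",
    "validate_report",
    "loo_accuracy",
]

#: Sign of the masculinised shift per variable (+1: males larger, -1:
#: females larger, from the validation-table dimorphism).
MASCULINE_DIRECTION: dict[str, int] = {f: 1 for f in FEATURES}
MASCULINE_DIRECTION["geodesic_forehead_height"] = -1
MASCULINE_DIRECTION["masculinity_score"] = 1
MASCULINE_DIRECTION["facial_area"] = 1

DENSITY_GRID = np.linspace(0.0, 20.0, 201)


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Run-time options shared by the pipeline commands."""

    alpha: float = 0.05
    alpha_norm: float = 0.05
    seed: int = 0
    fixtures: bool = False
    model_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _compare(x: np.ndarray, y: np.ndarray, variable: str, alpha_norm: float) -> dict:
    """One two-group comparison row with automatic test selection."""
    decision = stats.choose_test(x, y, alpha_norm=alpha_norm)
    if decision["choice"] == "parametric":
        res = stats.welch_t(x, y)
    else:
        res = stats.rank_sum_test(x, y)
    sign = MASCULINE_DIRECTION.get(variable, 1)
    return {
        "variable": variable,
        "test": decision["choice"],
        "shapiro_p1": decision["shapiro_p"][0],
        "shapiro_p2": decision["shapiro_p"][1],
        "statistic_name": res.statistic_name,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p,
        "d": res.d,
        "d_lo": res.d_ci[0],
        "d_hi": res.d_ci[1],
        "masculinised": bool(np.sign(res.d) == sign and res.d != 0),
    }


def loo_accuracy(df: pd.DataFrame, feature_names: Sequence[str] = FEATURES) -> dict[str, float]:
    """Leave-one-out per-class classification accuracy of the LDA."""
    labels = [normalize_sex(s) for s in df["sex"]]
    correct = {"male": 0, "female": 0}
    totals = {"male": 0, "female": 0}
    for i in range(len(df)):
        train = df.drop(df.index[i])
        model = fit_lda(train, feature_names=feature_names)
        pred = model.classify(df.iloc[i][list(feature_names)].to_numpy(dtype=float))
        totals[labels[i]] += 1
        correct[labels[i]] += int(pred == labels[i])
    return {cls: correct[cls] / totals[cls] for cls in totals if totals[cls]}


def run_validation(features: pd.DataFrame | None = None,
                   config: StudyConfig = StudyConfig()) -> dict:
    """Classification-accuracy check plus per-feature dimorphism tests."""
    if config.fixtures:
        report, summary = tables.recompute_printed_tables(alpha=config.alpha,
                                                          tables=("table1",))
        return {
            "analysis": "validation",
            "mode": "fixtures",
            "rows": report.to_dict(orient="records"),
            "n_significant_features": summary["tables"]["table1"]["n_significant_features"],
            "accuracy": None,
        }
    if features is None:
        raise ConfigError("feature table required when fixtures=False")
    if "sex" not in features.columns:
        raise ConfigError("feature table must carry a 'sex' column")
    sexes = {normalize_sex(s) for s in features["sex"]}
    if sexes != {"male", "female"}:
        raise ConfigError(f"validation needs both sexes, got {sorted(sexes)}")
    males = features[[normalize_sex(s) == "male" for s in features["sex"]]]
    females = features[[normalize_sex(s) == "female" for s in features["sex"]]]
    rows = []
    for variable in list(FEATURES) + (["facial_area"] if "facial_area" in features else []):
        if variable not in features.columns:
            continue
        rows.append(_compare(males[variable].to_numpy(), females[variable].to_numpy(),
                             variable, config.alpha_norm))
    feature_rows = [r for r in rows if r["variable"] in FEATURES]
    return {
        "analysis": "validation",
        "mode": "data",
        "accuracy": loo_accuracy(features),
        "rows": rows,
        "n_significant_features": int(sum(r["p"] < config.alpha for r in feature_rows)),
        "input_hash": _hash_frame(features),
    }


def _dimorphic_features(sex: str) -> list[str]:
    table = "table2" if sex == "male" else "table3"
    df = tables.load_table(table)
    return [k for k in df.feature_key if k in FEATURES]


def run_sibling_comparison(comparison: pd.DataFrame | None = None, sex: str = "male",
                           config: StudyConfig = StudyConfig()) -> dict:
    """Sibling vs control rows: facial area, masculinity score, 8 distances."""
    sex = normalize_sex(sex)
    table = "table2" if sex == "male" else "table3"
    if config.fixtures:
        report, _ = tables.recompute_printed_tables(alpha=config.alpha, tables=(table,))
        return {"analysis": "sibling_comparison", "sex": sex, "mode": "fixtures",
                "rows": report.to_dict(orient="records")}
    if comparison is None:
        raise ConfigError("comparison table required when fixtures=False")
    sub = comparison[[normalize_sex(s) == sex for s in comparison["sex"]]]
    sib = sub[sub.group.str.startswith("sibling")]
    ctl = sub[sub.group.str.startswith("control")]
    if len(sib) < 2 or len(ctl) < 2:
        raise ConfigError(f"need n >= 2 sibling and control subjects for sex={sex}")
    variables = ["facial_area", "masculinity_score"] + _dimorphic_features(sex)
    rows = []
    for variable in variables:
        if variable not in sub.columns or sub[variable].isna().all():
            continue
        rows.append(_compare(sib[variable].to_numpy(dtype=float),
                             ctl[variable].to_numpy(dtype=float),
                             variable, config.alpha_norm))
    return {
        "analysis": "sibling_comparison", "sex": sex, "mode": "data",
        "n_sibling": int(len(sib)), "n_control": int(len(ctl)),
        "rows": rows, "input_hash": _hash_frame(sub),
    }


def density_curve(scores: np.ndarray, grid: np.ndarray = DENSITY_GRID) -> dict:
    """Gaussian-kernel density (Silverman bandwidth) on the score grid,
    renormalized so it integrates to 1 over the grid."""
    scores = np.asarray(scores, dtype=float)
    kde = gaussian_kde(scores, bw_method="silverman")
    dens = kde(grid)
    mass = np.trapezoid(dens, grid)
    if mass <= 0:
        raise ValueError("degenerate density")
    dens = dens / mass
    return {"grid": grid.tolist(), "density": dens.tolist()}


def run_three_group(scores: pd.DataFrame | None = None, sex: str = "male",
                    config: StudyConfig = StudyConfig()) -> dict:
    """Proband/sibling/control one-way ANOVA + Tukey HSD on masculinity scores."""
    sex = normalize_sex(sex)
    if config.fixtures:
        summaries = []
        for grp in (f"proband_{sex}", f"sibling_{sex}", f"control_{sex}"):
            m, s, n = tables.score_moments(grp)
            summaries.append(GroupSummary(n=n, location=m, spread=s, label=grp))
        res = stats.anova_from_summaries(summaries)
        return {
            "analysis": "three_group", "sex": sex, "mode": "fixtures",
            "F": res.F, "df_between": res.df_between, "df_within": res.df_within,
            "p": res.p, "tukey": None, "densities": None,
            "printed": tables.PRINTED_ANOVA[sex],
        }
    if scores is None:
        raise ConfigError("score table required when fixtures=False")
    sub = scores[[normalize_sex(s) == sex for s in scores["sex"]]]
    groups, labels = [], []
    for prefix in ("proband", "sibling", "control"):
        vals = sub[sub.group.str.startswith(prefix)]["masculinity_score"].dropna()
        if len(vals):
            groups.append(vals.to_numpy(dtype=float))
            labels.append(prefix)
    if len(groups) < 3:
        raise ConfigError(
            f"three-group analysis needs proband, sibling and control groups for sex={sex}; "
            f"got {labels}; use run_sibling_comparison for two groups"
        )
    res = stats.tukey_hsd(groups, labels=labels)
    densities = {lab: density_curve(np.clip(g, 0.0, 20.0)) for lab, g in zip(labels, groups)}
    return {
        "analysis": "three_group", "sex": sex, "mode": "data",
        "F": res.F, "df_between": res.df_between, "df_within": res.df_within, "p": res.p,
        "tukey": [{"pair": list(pair), "mean_diff": diff, "p_adj": p}
                  for pair, diff, p in res.tukey_pairs],
        "densities": densities,
        "group_sizes": {lab: int(len(g)) for lab, g in zip(labels, groups)},
        "input_hash": _hash_frame(sub),
    }


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

def _schema() -> dict:
    from importlib import resources

    with resources.files("facedim.data").joinpath("report.schema.json").open("r") as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Check a report section against the shipped structural schema.

    Minimal validator (required keys + type names) — kept dependency-free.
    """
    schema = _schema()
    analysis = report.get("analysis")
    if analysis not in schema["sections"]:
        raise ValueError(f"unknown analysis section {analysis!r}")
    spec = schema["sections"][analysis]
    for key in spec["required"]:
        if key not in report:
            raise ValueError(f"report section {analysis!r} missing key {key!r}")
    if report.get("mode") == "data" and "rows" in report:
        for row in report["rows"]:
            for key in schema["row_required"]:
                if key not in row:
                    raise ValueError(f"comparison row missing key {key!r}")
    if report.get("densities"):
        for lab, curve in report["densities"].items():
            mass = np.trapezoid(np.asarray(curve["density"]), np.asarray(curve["grid"]))
            if abs(mass - 1.0) > 0.01:
                raise ValueError(f"density for {lab!r} integrates to {mass:.4f}, not 1")
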