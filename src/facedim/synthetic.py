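"""Synthetic cohorts and faces with the structure the analyses assume.

Two generators live here:

* :func:`generate_cohort` draws multivariate-normal feature tables whose
  per-group moments match a :class:`CohortSpec` (typically built from the
  published summary tables), with configurable inter-feature correlation.
* :func:`generate_face` builds a smooth dome-plus-nose-ridge heightfield
  mesh with the 13 canonical landmarks placed on-surface, good enough to
  exercise every geometry invariant; it is a surrogate, not anatomy.

:func:`generate_study` bundles a full synthetic replication of the study
design (validation 40+40, sibling/control 30/69 and 25/60, proband score
groups 54/20), deterministic under a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from . import tables
from .geometry import LANDMARK_NAMES, FaceMesh, LandmarkSet
from .tables import FEATURES

__all__ = [
    "CohortSpec",
    "FaceParams",
    "StudyBundle",
    "correlation_matrix",
    "generate_cohort",
    "generate_face",
    "generate_study",
    "cohort_spec_for_group",
    "DEFAULT_RHO",
]

DEFAULT_RHO = 0.3  # plausible craniofacial inter-feature correlation


class SpecError(ValueError):
    pass


def correlation_matrix(rho: float | np.ndarray, p: int) -> np.ndarray:
    """Exchangeable correlation (1-rho) I + rho J, or a full matrix passed through."""
    R = np.asarray(rho, dtype=float)
    if R.ndim == 0:
        R = (1.0 - float(rho)) * np.eye(p) + float(rho) * np.ones((p, p))
    if R.shape != (p, p):
        raise SpecError(f"correlation must be scalar or ({p}, {p})")
    if not np.allclose(R, R.T):
        raise SpecError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(R).min() <= 1e-12:
        raise SpecError("correlation matrix must be positive-definite")
    return R


@dataclass(frozen=True)
class CohortSpec:
    """Target moments for one group of synthetic subjects."""

    label: str
    n: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    rho: float = DEFAULT_RHO
    sex: str | None = None
    feature_names: tuple[str, ...] = FEATURES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SpecError("n must be >= 2")
        if len(self.means) != len(self.sds) or len(self.means) != len(self.feature_names):
            raise SpecError("means/sds/feature_names length mismatch")
        if any(s <= 0 for s in self.sds):
            raise SpecError("all SDs must be > 0")


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``spec.n`` multivariate-normal subjects with the spec's moments."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = len(spec.feature_names)
    R = correlation_matrix(spec.rho, p)
    D = np.diag(spec.sds)
    cov = D @ R @ D
    X = rng.multivariate_normal(np.asarray(spec.means), cov, size=spec.n,
                                method="cholesky")
    df = pd.DataFrame(X, columns=list(spec.feature_names))
    df.insert(0, "subject_id", [f"{spec.label}_{i:03d}" for i in range(spec.n)])
    df.insert(1, "sex", spec.sex)
    df.insert(2, "group", spec.label)
    return df


def cohort_spec_for_group(group: str, rho: float = DEFAULT_RHO,
                          label: str | None = None) -> CohortSpec:
    """CohortSpec with moments taken from the published summary tables."""
    means, sds, n = tables.cohort_moments(group)
    return CohortSpec(
        label=label or group, n=n, means=tuple(means), sds=tuple(sds), rho=rho,
        sex=group.split("_")[1],
    )


# ---------------------------------------------------------------------------
# Parametric face surrogate
# ---------------------------------------------------------------------------

# 2D landmark anchors (x lateral, y vertical, mm) per dimorphism preset,
# tuned so the measured feature vector lands inside the same-sex +-3 SD
# envelope of the published validation summaries.
_ANCHORS = {
    "male": {
        "trichion": (0.0, 81.0),
        "nasion": (0.0, 31.0),
        "pronasale": (0.0, 1.0),
        "subnasale": (0.0, -7.0),
        "labiale_superius": (0.0, -19.0),
        "stomion": (0.0, -30.5),
        "exocanthion_left": (-47.0, 30.0),
        "exocanthion_right": (47.0, 30.0),
        "alare_left": (-7.5, -4.0),
        "alare_right": (7.5, -4.0),
        "frontotemporale_left": (-66.0, 55.0),
        "frontotemporale_right": (66.0, 55.0),
        "zygion_right": (62.0, -30.0),
    },
    "female": {
        "trichion": (0.0, 86.0),
        "nasion": (0.0, 29.0),
        "pronasale": (0.0, 1.0),
        "subnasale": (0.0, -7.0),
        "labiale_superius": (0.0, -16.5),
        "stomion": (0.0, -27.0),
        "exocanthion_left": (-44.5, 30.0),
        "exocanthion_right": (44.5, 30.0),
        "alare_left": (-7.0, -4.0),
        "alare_right": (7.0, -4.0),
        "frontotemporale_left": (-63.5, 55.0),
        "frontotemporale_right": (63.5, 55.0),
        "zygion_right": (60.0, -29.0),
    },
}

_DOME = {"a": 110.0, "b": 140.0, "c": 60.0}
_NOSE = {"amp": 13.5, "sx": 8.5, "sy_up": 13.0, "sy_down": 5.0, "yc": 1.0}


@dataclass(frozen=True)
class FaceParams:
    """Knobs of the synthetic face generator."""

    preset: str = "male"
    size_scale: float = 1.0
    resolution: int = 56
    jitter_mm: float = 0.5
    nose_amp: float = _NOSE["amp"]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.preset not in _ANCHORS:
            raise SpecError(f"unknown preset {self.preset!r}")
        if self.resolution < 8:
            raise SpecError("resolution must be >= 8")
        if self.size_scale <= 0:
            raise SpecError("size_scale must be > 0")
        if self.jitter_mm > 2.0:
            raise SpecError("jitter above 2 mm can push landmarks off-surface")


def _surface_height(x: np.ndarray, y: np.ndarray, nose_amp: float) -> np.ndarray:
    """Dome (ellipsoid cap) plus an asymmetric Gaussian nose ridge."""
    r2 = (x / _DOME["a"]) ** 2 + (y / _DOME["b"]) ** 2
    z = _DOME["c"] * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    sy = np.where(y >= _NOSE["yc"], _NOSE["sy_up"], _NOSE["sy_down"])
    bump = nose_amp * np.exp(
        -(x**2) / (2 * _NOSE["sx"] ** 2) - ((y - _NOSE["yc"]) ** 2) / (2 * sy**2)
    )
    return z + bump


def generate_face(params: FaceParams = FaceParams()) -> tuple[FaceMesh, LandmarkSet]:
    """Build a synthetic face mesh and its 13 on-surface landmarks."""
    rng = np.random.default_rng(params.seed)
    n = params.resolution
    xs = np.linspace(-88.0, 88.0, n)
    ys = np.linspace(-60.0, 100.0, n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = _surface_height(gx, gy, params.nose_amp)
    verts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # grid triangulation; diagonal orientation alternated for isotropy
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v01 = i * n + j, i * n + j + 1
            v10, v11 = (i + 1) * n + j, (i + 1) * n + j + 1
            if (i + j) % 2 == 0:
                faces.append((v00, v10, v11))
                faces.append((v00, v11, v01))
            else:
                faces.append((v00, v10, v01))
                faces.append((v10, v11, v01))
    mesh = FaceMesh(verts, np.array(faces), subject_id=f"synthetic_{params.preset}")

    points: dict[str, np.ndarray] = {}
    for name in LANDMARK_NAMES:
        ax, ay = _ANCHORS[params.preset][name]
        jx, jy = rng.normal(0.0, params.jitter_mm, size=2) if params.jitter_mm > 0 else (0.0, 0.0)
        # mirror-symmetric jitter keeps paired landmarks symmetric
        if name.endswith("_left"):
            twin = name.replace("_left", "_right")
            if twin in points:
                t = points[twin]
                points[name] = np.array([-t[0], t[1], t[2]])
                continue
        target = np.array([ax + jx, ay + jy])
        idx = int(np.argmin(np.sum((verts[:, :2] - target) ** 2, axis=1)))
        points[name] = verts[idx].copy()
    landmarks = LandmarkSet(points, subject_id=mesh.subject_id)

    if params.size_scale != 1.0:
        mesh = FaceMesh(mesh.vertices * params.size_scale, mesh.faces, mesh.subject_id)
        landmarks = landmarks.transformed(scale=params.size_scale)
    return mesh, landmarks


# ---------------------------------------------------------------------------
# Full-study bundle
# ---------------------------------------------------------------------------

_STUDY_GROUPS = (
    ("validation_male", "validation"),
    ("validation_female", "validation"),
    ("sibling_male", "comparison"),
    ("control_male", "comparison"),
    ("sibling_female", "comparison"),
    ("control_female", "comparison"),
)


@dataclass
class StudyBundle:
    """Synthetic replication of the study's cohorts."""

    validation: pd.DataFrame
    comparison: pd.DataFrame
    probands: pd.DataFrame
    manifest: dict

    def group_sizes(self) -> tuple[int, ...]:
        """Sizes of the six current-study groups, in design order."""
        counts = pd.concat([self.validation, self.comparison]).groupby("group").size()
        return tuple(int(counts[g]) for g, _ in _STUDY_GROUPS)

    def write(self, outdir: str | Path) -> list[Path]:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("validation", "comparison", "probands"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            written.append(p)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        written.append(p)
        return written


def generate_study(seed: int, rho: float = DEFAULT_RHO) -> StudyBundle:
    """Generate every cohort of the study design from the published moments."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STUDY_GROUPS) + 2)

    frames: dict[str, list[pd.DataFrame]] = {"validation": [], "comparison": []}
    for (group, section), child in zip(_STUDY_GROUPS, children):
        spec = cohort_spec_for_group(group, rho=rho)
        df = generate_cohort(spec, rng=np.random.default_rng(child))
        score_stream, area_stream = child.spawn(2)
        m, s, _ = tables.facial_area_moments(group)
        df["facial_area"] = np.random.default_rng(area_stream).normal(m, s, size=len(df))
        if section == "comparison":
            m, s, _ = tables.score_moments(group)
            df["masculinity_score"] = np.random.default_rng(score_stream).normal(
                m, s, size=len(df)
            )
        frames[section].append(df)

    proband_rows = []
    for group, child in zip(("proband_male", "proband_female"), children[-2:]):
        m, s, n = tables.score_moments(group)
        scores = np.random.default_rng(child).normal(m, s, size=n)
        proband_rows.append(pd.DataFrame({
            "subject_id": [f"{group}_{i:03d}" for i in range(n)],
            "sex": group.split("_")[1],
            "group": group,
            "masculinity_score": scores,
        }))

    manifest = {
        "seed": int(seed),
        "rho": float(rho),
        "groups": {g: int(cohort_spec_for_group(g).n) for g, _ in _STUDY_GROUPS},
        "proband_groups": {"proband_male": 54, "proband_female": 20},
        "moment_source": "published summary tables (median/IQR rows converted under normality)",
    }
    return StudyBundle(
        validation=pd.concat(frames["validation"], ignore_index=True),
        comparison=pd.concat(frames["comparison"], ignore_index=True),
        probands=pd.concat(proband_rows, ignore_index=True),
        manifest=manifest,
    )
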