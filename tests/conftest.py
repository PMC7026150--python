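import math

import numpy as np
import pytest

from facedim.geometry import FaceMesh, extract_features
from facedim.synthetic import FaceParams, generate_face


def build_icosphere(subdivisions: int) -> FaceMesh:
    """Unit icosphere, built independently of the package geometry code."""
    t = (1 + 5**0.5) / 2
    verts = [np.array(v, dtype=float) for v in [
        (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
        (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
        (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1),
    ]]
    verts = [v / np.linalg.norm(v) for v in verts]
    faces = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
             (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
             (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
             (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return FaceMesh(np.array(verts), np.array(faces), subject_id=f"icosphere{subdivisions}")


def build_flat_grid(n: int = 11, spacing: float = 1.0) -> FaceMesh:
    """Planar square grid in the z=0 plane, diagonals along (1, 1)."""
    xs = np.arange(n) * spacing
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v01 = i * n + j, i * n + j + 1
            v10, v11 = (i + 1) * n + j, (i + 1) * n + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return FaceMesh(verts, np.array(faces), subject_id="flatgrid")


@pytest.fixture(scope="session")
def icosphere3() -> FaceMesh:
    return build_icosphere(3)


@pytest.fixture(scope="session")
def flat_grid() -> FaceMesh:
    return build_flat_grid()


@pytest.fixture(scope="session")
def male_face():
    return generate_face(FaceParams(preset="male", seed=1))


@pytest.fixture(scope="session")
def female_face():
    return generate_face(FaceParams(preset="female", seed=1))


@pytest.fixture(scope="session")
def male_features(male_face):
    mesh, landmarks = male_face
    return extract_features(mesh, landmarks)
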