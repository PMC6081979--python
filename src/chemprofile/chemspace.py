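"""Satellite-based chemical-space projection.

Instead of embedding an n x n similarity matrix, each molecule is described
by its Tanimoto similarity to a small set of k reference molecules — the
"chemical satellites" — and the n x k similarity matrix is reduced to 2 or 3
principal components.  Because the model stores the satellites, the column
means and the component loadings, new libraries can be projected into an
existing map, which is what makes side-by-side database comparisons cheap.
With k = n (every molecule a satellite) the construction reduces exactly to
classical principal-component scores of the full centered similarity matrix.

Satellites are chosen either uniformly at random or by greedy farthest-point
(MaxMin) selection under 1 - Tanimoto, which spreads them over the occupied
space; fingerprints are the same MACCS dialect used by the diversity module
so the two views of a library are consistent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .curation import CuratedLibrary, MoleculeRecord
from .diversity import FINGERPRINT_DIALECT, _fingerprint_matrix, _pair_sample

DEFAULT_K = 200


@dataclass
class ProjectionModel:
    satellites: list[MoleculeRecord]
    column_means: np.ndarray          # length k
    loadings: np.ndarray              # k x d, orthonormal columns
    explained_variance_fractions: np.ndarray  # length d, non-increasing
    method: str = "maxmin"
    dialect: str = FINGERPRINT_DIALECT

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str) -> None:
        payload = {
            "satellites": [vars(s) for s in self.satellites],
            "column_means": self.column_means.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fractions": self.explained_variance_fractions.tolist(),
            "method": self.method,
            "dialect": self.dialect,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ProjectionModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            satellites=[MoleculeRecord(**s) for s in p["satellites"]],
            column_means=np.asarray(p["column_means"]),
            loadings=np.asarray(p["loadings"]),
            explained_variance_fractions=np.asarray(p["explained_variance_fractions"]),
            method=p["method"],
            dialect=p["dialect"],
        )


@dataclass(frozen=True)
class EmbeddedPoint:
    id: str
    source: str
    coords: tuple


def _similarity_to_satellites(fps: np.ndarray, sat_fps: np.ndarray) -> np.ndarray:
    """n x k Tanimoto matrix of library fingerprints vs satellite fingerprints."""
    f = fps.astype(np.float64)
    s = sat_fps.astype(np.float64)
    inter = f @ s.T
    union = f.sum(axis=1)[:, None] + s.sum(axis=1)[None, :] - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)


def select_satellites(
    lib: CuratedLibrary | list[MoleculeRecord],
    k: int,
    method: str = "maxmin",
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Pick k satellite molecules from a library.

    ``maxmin`` starts from a seeded random molecule and greedily adds the
    molecule farthest (1 - Tanimoto) from the current set; ``random`` is a
    seeded uniform sample.  Exact duplicates are never both picked while
    distinct molecules remain.
    """
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    n = len(records)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    if k == n:
        return list(records)
    if method == "random":
        idx = sorted(rng.choice(n, size=k, replace=False).tolist())
        return [records[i] for i in idx]
    if method != "maxmin":
        raise ValueError(f"unknown satellite selection method {method!r}")
    fps = _fingerprint_matrix(records)
    sim = _similarity_to_satellites(fps, fps)
    chosen = [int(rng.integers(n))]
    min_dist = 1.0 - sim[chosen[0]]
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))  # ties -> lowest index, deterministic
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, 1.0 - sim[nxt])
    return [records[i] for i in chosen]


def fit_projection(
    lib: CuratedLibrary | list[MoleculeRecord],
    satellites: list[MoleculeRecord],
    d: int = 2,
) -> ProjectionModel:
    """Fit a d-dimensional satellite map to a library.

    Builds the library-vs-satellite Tanimoto matrix, centers its columns and
    extracts the top-d principal directions by SVD.  Axis signs are fixed by
    forcing the largest-magnitude loading of each component to be positive.
    If fewer than d directions carry variance, the model keeps the available
    ones and warns.
    """
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    fps = _fingerprint_matrix(records)
    sat_fps = _fingerprint_matrix(satellites)
    sim = _similarity_to_satellites(fps, sat_fps)
    means = sim.mean(axis=0)
    centered = sim - means
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    var = svals**2
    nonzero = int(np.sum(var > var[0] * 1e-12)) if var.size and var[0] > 0 else 0
    d_eff = min(d, nonzero) if nonzero else 0
    if d_eff < d:
        warnings.warn(
            f"similarity matrix supports only {d_eff} nonzero-variance directions "
            f"(requested {d}); returning the available ones"
        )
    if d_eff == 0:
        # degenerate: all molecules identical; keep d zero-loading axes
        loadings = np.zeros((sat_fps.shape[0], d))
        evf = np.zeros(d)
        return ProjectionModel(list(satellites), means, loadings, evf)
    loadings = vt[:d_eff].T
    # sign convention: largest-|loading| entry of each component positive
    for c in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1
    total_var = var.sum()
    evf = var[:d_eff] / total_var if total_var > 0 else np.zeros(d_eff)
    return ProjectionModel(list(satellites), means, loadings, evf)


def project(
    model: ProjectionModel, libs: list[CuratedLibrary]
) -> list[EmbeddedPoint]:
    """Embed libraries into a fitted map via their satellite-similarity rows."""
    if not libs:
        raise ValueError("project requires at least one library")
    sat_fps = _fingerprint_matrix(model.satellites)
    points: list[EmbeddedPoint] = []
    for lib in libs:
        fps = _fingerprint_matrix(lib.records)
        sim = _similarity_to_satellites(fps, sat_fps)
        coords = (sim - model.column_means) @ model.loadings
        points.extend(
            EmbeddedPoint(id=r.id, source=lib.tag, coords=tuple(map(float, xy)))
            for r, xy in zip(lib.records, coords)
        )
    return points


def points_frame(points: list[EmbeddedPoint]) -> pd.DataFrame:
    d = len(points[0].coords)
    cols = ["x", "y", "z"][:d]
    rows = [{"id": p.id, "source": p.source, **dict(zip(cols, p.coords))} for p in points]
    return pd.DataFrame(rows)


def distance_preservation(
    model: ProjectionModel,
    lib: CuratedLibrary | list[MoleculeRecord],
    n_pairs: int = 10_000,
    seed: int = 0,
) -> float:
    """Spearman correlation of embedded vs full-fingerprint-space distances.

    Full-space distance is 1 - Tanimoto on the complete fingerprints;
    embedded distance is Euclidean in the map.  Returns NaN when the
    embedding has zero variance (correlation undefined).
    """
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    if len(records) < 10:
        raise ValueError("distance_preservation requires >= 10 molecules")
    fps = _fingerprint_matrix(records)
    sat_fps = _fingerprint_matrix(model.satellites)
    sim = _similarity_to_satellites(fps, sat_fps)
    coords = (sim - model.column_means) @ model.loadings
    i, j = _pair_sample(len(records), n_pairs, seed)
    emb_d = np.linalg.norm(coords[i] - coords[j], axis=1)
    full_sim = _similarity_to_satellites(fps, fps)
    full_d = 1.0 - full_sim[i, j]
    if np.allclose(emb_d, emb_d[0]) or np.allclose(full_d, full_d[0]):
        return float("nan")
    rho, _ = spearmanr(emb_d, full_d)
    return float(rho)


def plot_embedding(points: list[EmbeddedPoint], path: str) -> None:
    """Scatter the embedded points with one color per source library."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = points_frame(points)
    fig, ax = plt.subplots(figsize=(6, 5))
    for tag, grp in df.groupby("source"):
        ax.scatter(grp["x"], grp["y"], s=8, alpha=0.6, label=tag)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(markerscale=2, fontsize=8)
    ax.set_title("Chemical space (satellite projection)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
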