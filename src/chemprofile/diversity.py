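"""Global diversity statistics and the Consensus Diversity Plot (CDP).

Three statistics summarize each library: the median pairwise Tanimoto
similarity of 166-bit MACCS structural-key fingerprints (structural
diversity; lower = more diverse), the scaffold recovery-curve AUC (scaffold
diversity; lower = more diverse), and the mean intra-library Euclidean
distance of the six auto-scaled physicochemical properties (property
diversity; higher = more diverse).  The CDP draws one point per library:
median Tanimoto on x, scaffold AUC on y, property diversity as a continuous
color, library size as point area — so the most diverse libraries fall in
the lower-left quadrant.

Auto-scaling pools all libraries under comparison (z-scores with pooled
mean/sd), which makes property diversity invariant under any affine
transform applied uniformly to a raw property.  Pairwise statistics above
``max_pairs`` pairs are estimated on a seeded uniform pair sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .curation import CuratedLibrary, MoleculeRecord
from .profiling import PROPERTY_NAMES, compute_properties
from .scaffolds import recovery_curve, scaffold_frequencies

FINGERPRINT_DIALECT = "MACCS-166 (RDKit public keys)"
DEFAULT_MAX_PAIRS = 1_000_000


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary structural-key fingerprint."""

    bits: np.ndarray  # bool vector

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return self.bits.size


def maccs_fingerprint(mol: MoleculeRecord | Chem.Mol | str) -> BitFingerprint:
    """166-bit MACCS keys fingerprint (RDKit dialect; bit 0 is unused and dropped)."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.canonical_structure
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"invalid structure: {mol!r}")
    else:
        m = mol
    bv = MACCSkeys.GenMACCSKeys(m)
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return BitFingerprint(bits=arr[1:])


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |a&b|/|a|b|; two all-zero fingerprints compare as 1.0."""
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a.bits & b.bits)) / union


def _fingerprint_matrix(records: list[MoleculeRecord]) -> np.ndarray:
    return np.stack([maccs_fingerprint(r).bits for r in records])


def _pair_sample(n: int, max_pairs: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """All C(n,2) pairs, or a seeded uniform sample of max_pairs of them."""
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        return np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    # sample flat pair indices without replacement, decode to (i, j)
    flat = rng.choice(n_pairs, size=max_pairs, replace=False)
    # row i covers pairs [offset_i, offset_i + n-1-i); invert the offsets
    offsets = np.cumsum(np.concatenate([[0], np.arange(n - 1, 0, -1)]))
    i = np.searchsorted(offsets, flat, side="right") - 1
    j = flat - offsets[i] + i + 1
    return i, j


def pairwise_tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    """Dense n x n Tanimoto matrix from a boolean fingerprint matrix."""
    f = fps.astype(np.float64)
    inter = f @ f.T
    on = f.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return sim


def median_pairwise_tanimoto(
    lib: CuratedLibrary | list[MoleculeRecord],
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> float:
    """Median MACCS Tanimoto over all molecule pairs (sampled above max_pairs)."""
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    if len(records) < 2:
        raise ValueError("median_pairwise_tanimoto requires >= 2 molecules")
    fps = _fingerprint_matrix(records)
    i, j = _pair_sample(len(records), max_pairs, seed)
    fi, fj = fps[i].astype(np.float64), fps[j].astype(np.float64)
    inter = (fi * fj).sum(axis=1)
    union = fi.sum(axis=1) + fj.sum(axis=1) - inter
    sims = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return float(np.median(sims))


def pooled_scaling_stats(
    all_vectors: list[pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Pooled per-property mean/sd over the union of the compared libraries."""
    pooled = (
        pd.concat(all_vectors, ignore_index=True)
        if isinstance(all_vectors, list)
        else all_vectors
    )
    stats = pd.DataFrame({
        "mean": pooled[list(PROPERTY_NAMES)].mean(),
        "sd": pooled[list(PROPERTY_NAMES)].std(ddof=1),
    })
    return stats


def pcp_diversity(
    lib_vectors: pd.DataFrame,
    scaling_stats: pd.DataFrame,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> float:
    """Mean intra-library pairwise Euclidean distance of auto-scaled properties.

    ``scaling_stats`` must come from :func:`pooled_scaling_stats` over every
    library under comparison.  Properties constant across the pool (sd = 0)
    are dropped with a warning rather than dividing by zero.
    """
    if len(lib_vectors) < 2:
        raise ValueError("pcp_diversity requires >= 2 molecules")
    cols = [c for c in PROPERTY_NAMES if scaling_stats.loc[c, "sd"] > 0]
    if len(cols) < len(PROPERTY_NAMES):
        import warnings

        dropped = sorted(set(PROPERTY_NAMES) - set(cols))
        warnings.warn(f"constant properties dropped from auto-scaling: {dropped}")
    z = (
        lib_vectors[cols] - scaling_stats.loc[cols, "mean"]
    ) / scaling_stats.loc[cols, "sd"]
    z = z.to_numpy(dtype=float)
    i, j = _pair_sample(len(z), max_pairs, seed)
    d = np.linalg.norm(z[i] - z[j], axis=1)
    return float(d.mean())


def property_vectors(records: list[MoleculeRecord]) -> pd.DataFrame:
    """Six-property DataFrame for a record list (column order fixed)."""
    rows = [compute_properties(r).as_tuple() for r in records]
    return pd.DataFrame(rows, columns=list(PROPERTY_NAMES))


@dataclass
class DiversityProfile:
    """Per-library CDP coordinates: fingerprint, scaffold, property diversity, size."""

    library: str
    median_tanimoto: float
    scaffold_auc: float
    pcp_distance: float
    size: int


def consensus_profiles(
    libs: list[CuratedLibrary],
    *,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
    include_acyclic: bool = True,
) -> list[DiversityProfile]:
    """One DiversityProfile per library, with a single pooled property scaling."""
    if len(libs) < 2:
        raise ValueError("consensus_profiles requires >= 2 libraries")
    vectors = [property_vectors(lib.records) for lib in libs]
    stats = pooled_scaling_stats(vectors)
    profiles = []
    for lib, vecs in zip(libs, vectors):
        table = scaffold_frequencies(lib, include_acyclic=include_acyclic)
        profiles.append(
            DiversityProfile(
                library=lib.tag,
                median_tanimoto=median_pairwise_tanimoto(lib, max_pairs, seed),
                scaffold_auc=recovery_curve(table).auc,
                pcp_distance=pcp_diversity(vecs, stats, max_pairs, seed),
                size=len(lib),
            )
        )
    return profiles


def profiles_frame(profiles: list[DiversityProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles]).set_index("library")


AUTO = "auto"

# Quadrant labels.  Lower-left is diverse on both axes; a point exactly on a
# threshold is assigned to the lower/left (more diverse) side.
_QUADRANTS = {
    (True, True): "lower-left (diverse by fingerprints and scaffolds)",
    (True, False): "upper-left (fingerprint-diverse only)",
    (False, True): "lower-right (scaffold-diverse only)",
    (False, False): "upper-right (diverse by neither)",
}


def cdp_assign(
    profiles: list[DiversityProfile],
    x_threshold: float | str = AUTO,
    y_threshold: float | str = AUTO,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Assign CDP quadrants and optionally draw the plot.

    AUTO thresholds are the medians of each axis across the profiles (which
    needs >= 2 profiles to be meaningful).  Returns the profile table with a
    ``quadrant`` column; if ``plot_path`` is given, writes the CDP there
    (color = property diversity, area proportional to library size).
    """
    if len(profiles) < 2 and (x_threshold == AUTO or y_threshold == AUTO):
        raise ValueError("AUTO thresholds require >= 2 profiles")
    df = profiles_frame(profiles)
    xt = float(df["median_tanimoto"].median()) if x_threshold == AUTO else float(x_threshold)
    yt = float(df["scaffold_auc"].median()) if y_threshold == AUTO else float(y_threshold)
    df["quadrant"] = [
        _QUADRANTS[(mt <= xt, auc <= yt)]
        for mt, auc in zip(df["median_tanimoto"], df["scaffold_auc"])
    ]
    df.attrs["x_threshold"] = xt
    df.attrs["y_threshold"] = yt
    if plot_path is not None:
        _plot_cdp(df, xt, yt, plot_path)
    return df


def _plot_cdp(df: pd.DataFrame, xt: float, yt: float, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    area = 2000.0 * df["size"] / df["size"].max()
    sc = ax.scatter(
        df["median_tanimoto"], df["scaffold_auc"], s=area, c=df["pcp_distance"],
        cmap="viridis", alpha=0.8, edgecolors="k",
    )
    for name, row in df.iterrows():
        ax.annotate(name, (row["median_tanimoto"], row["scaffold_auc"]),
                    textcoords="offset points", xytext=(6, 6), fontsize=8)
    ax.axvline(xt, ls="--", c="gray", lw=0.8)
    ax.axhline(yt, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("median MACCS Tanimoto (lower = more diverse)")
    ax.set_ylabel("scaffold recovery AUC (lower = more diverse)")
    fig.colorbar(sc, ax=ax, label="PCP diversity (mean auto-scaled distance)")
    ax.set_title("Consensus Diversity Plot")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
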