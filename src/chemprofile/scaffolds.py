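"""Bemis-Murcko scaffold analysis.

A molecule's scaffold is the union of its ring systems and the linkers
connecting them, with all side chains removed (exocyclic atoms double-bonded
to the ring/linker stay attached, the standard behavior).  Ring-free
molecules map to the reserved pseudo-scaffold ``ACYCLIC``, which is a
first-class frequency category by default and can be excluded for
sensitivity analysis.  Scaffold diversity of a library is quantified by the
area under its scaffold recovery curve: scaffolds are ranked by descending
frequency and the curve plots the cumulative fraction of molecules covered
(y) against the cumulative fraction of distinct scaffolds used (x).  A
library where a few scaffolds dominate has AUC near 1; a library with every
scaffold equally populated lies on the diagonal (AUC 0.5).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import CuratedLibrary, MoleculeRecord

logger = logging.getLogger(__name__)

ACYCLIC = "ACYCLIC"


def extract_scaffold(mol: MoleculeRecord | Chem.Mol | str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES, or ``ACYCLIC`` for ring-free input."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.canonical_structure
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"invalid structure: {mol!r}")
    else:
        m = mol
    if m.GetRingInfo().NumRings() == 0:
        return ACYCLIC
    core = MurckoScaffold.GetScaffoldForMol(m)
    return Chem.MolToSmiles(core)


@dataclass
class ScaffoldTable:
    """Scaffold -> count mapping for one library (ACYCLIC included)."""

    entries: dict[str, int]
    total: int = 0

    def __post_init__(self):
        if not self.total:
            self.total = sum(self.entries.values())
        assert self.total == sum(self.entries.values())

    def without_acyclic(self) -> "ScaffoldTable":
        entries = {k: v for k, v in self.entries.items() if k != ACYCLIC}
        return ScaffoldTable(entries=entries)

    def top_k(self, k: int = 10) -> pd.DataFrame:
        """Top-k scaffolds with count and percentage of the library."""
        items = sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        return pd.DataFrame(
            [{"scaffold": s, "count": c, "percent": 100.0 * c / self.total}
             for s, c in items]
        )

    def to_frame(self) -> pd.DataFrame:
        return self.top_k(len(self.entries))


def scaffold_frequencies(
    lib: CuratedLibrary | list[MoleculeRecord], *, include_acyclic: bool = True
) -> ScaffoldTable:
    """Frequency table of canonical scaffolds in a curated library."""
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    if not records:
        raise ValueError("scaffold_frequencies requires a nonempty library")
    counts = Counter(extract_scaffold(r) for r in records)
    table = ScaffoldTable(entries=dict(counts))
    return table if include_acyclic else table.without_acyclic()


@dataclass
class RecoveryCurve:
    """Scaffold recovery curve: points from (0,0) to (1,1) and trapezoid AUC."""

    x: np.ndarray
    y: np.ndarray
    auc: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.points:
            self.points = list(zip(self.x.tolist(), self.y.tolist()))


def recovery_curve(table: ScaffoldTable) -> RecoveryCurve:
    """Recovery curve and AUC from a scaffold frequency table.

    Scaffolds are ordered by descending count, ties broken lexicographically
    by canonical SMILES so the curve is deterministic; point i is
    (i/S, cumulative_count_i/N) with (0,0) prepended; AUC is the trapezoidal
    integral, always in [0.5, 1].
    """
    if not table.entries:
        raise ValueError("recovery_curve requires a table with at least one scaffold")
    counts = np.array(
        [c for _, c in sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))],
        dtype=float,
    )
    s = counts.size
    x = np.concatenate([[0.0], np.arange(1, s + 1) / s])
    y = np.concatenate([[0.0], np.cumsum(counts) / counts.sum()])
    return RecoveryCurve(x=x, y=y, auc=float(np.trapezoid(y, x)))


def match_reference_scaffolds(
    table: ScaffoldTable, reference: list[tuple[str, float]]
) -> tuple[pd.DataFrame, dict]:
    """Match a library's scaffolds against an annotated reference scaffold list.

    Reference structures are re-canonicalized with the same scaffold
    canonicalization before matching (so decorated reference entries still
    match on their core).  Returns the matched rows and the mean/sd of the
    numeric annotation over matches; unparseable reference rows are skipped
    and counted.
    """
    keys = set(table.entries) - {ACYCLIC}
    matches, n_skipped = [], 0
    for smi, annotation in reference:
        try:
            canon = extract_scaffold(smi)
        except ValueError:
            n_skipped += 1
            continue
        if canon in keys:
            matches.append({"scaffold": canon, "annotation": float(annotation),
                            "count": table.entries[canon]})
    if n_skipped:
        logger.warning("match_reference_scaffolds: skipped %d unparseable rows", n_skipped)
    df = pd.DataFrame(matches, columns=["scaffold", "annotation", "count"])
    ann = df["annotation"].to_numpy()
    summary = {
        "n_matches": len(df),
        "n_skipped": n_skipped,
        "annotation_mean": float(ann.mean()) if len(df) else float("nan"),
        "annotation_sd": float(ann.std(ddof=1)) if len(df) > 1 else float("nan"),
    }
    return df, summary
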