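"""Physicochemical-property and molecular-complexity profiling.

Six standard properties per molecule — SlogP (Crippen log partition
coefficient), TPSA (Ertl topological polar surface area, A^2), AMW
(average molecular weight, g/mol), RB (rotatable bonds), HBD and HBA
(Lipinski NH/OH donor and N+O acceptor counts) — plus two complexity
metrics: Fsp3 (fraction of sp3 carbons) and the tetrahedral stereocenter
count including unassigned potential centers.  Library summaries follow a
boxplot convention where whiskers sit at median +/- 1.5*IQR (the literal
rule; the conventional Tukey quartile-based rule is available behind a
flag) and points outside the whiskers are counted as omitted outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .curation import MoleculeRecord

PROPERTY_NAMES = ("SlogP", "TPSA", "AMW", "RB", "HBD", "HBA")
COMPLEXITY_NAMES = ("fsp3", "n_stereo")


@dataclass(frozen=True)
class PropertyVector:
    SlogP: float
    TPSA: float
    AMW: float
    RB: int
    HBD: int
    HBA: int

    def as_tuple(self) -> tuple:
        return (self.SlogP, self.TPSA, self.AMW, self.RB, self.HBD, self.HBA)


@dataclass(frozen=True)
class ComplexityVector:
    fsp3: float  # NaN for carbon-free molecules
    n_stereo: int


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        mol = mol.canonical_structure
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"invalid structure: {mol!r}")
        return m
    return mol


def compute_properties(mol: MoleculeRecord | Chem.Mol | str) -> PropertyVector:
    """The six physicochemical properties of one curated molecule."""
    m = _as_mol(mol)
    return PropertyVector(
        SlogP=Crippen.MolLogP(m),
        TPSA=Descriptors.TPSA(m),
        AMW=Descriptors.MolWt(m),
        RB=int(Descriptors.NumRotatableBonds(m)),
        HBD=int(Lipinski.NHOHCount(m)),
        HBA=int(Lipinski.NOCount(m)),
    )


def compute_complexity(mol: MoleculeRecord | Chem.Mol | str) -> ComplexityVector:
    """Fsp3 and stereocenter count (assigned + unassigned tetrahedral centers).

    Fsp3 is reported as NaN (missing) for molecules without carbon rather
    than 0, which would wrongly read as "fully unsaturated".
    """
    m = _as_mol(mol)
    n_carbon = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6)
    fsp3 = Descriptors.FractionCSP3(m) if n_carbon else math.nan
    centers = Chem.FindMolChiralCenters(
        m, includeUnassigned=True, useLegacyImplementation=False
    )
    return ComplexityVector(fsp3=fsp3, n_stereo=len(centers))


def property_table(records: list[MoleculeRecord]) -> pd.DataFrame:
    """Per-molecule table of the six properties and two complexity metrics."""
    rows = []
    for rec in records:
        pv = compute_properties(rec)
        cv = compute_complexity(rec)
        rows.append({"id": rec.id, **{f.name: getattr(pv, f.name) for f in fields(pv)},
                     "fsp3": cv.fsp3, "n_stereo": cv.n_stereo})
    return pd.DataFrame(rows).set_index("id")


@dataclass
class PropertySummary:
    """Boxplot statistics for one property across a library."""

    property: str
    n: int
    mean: float
    sd: float  # sample sd (ddof=1); NaN for n=1
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_omitted_outliers: int


def summarize_values(
    values, name: str = "", *, outlier_rule: str = "median_iqr"
) -> PropertySummary:
    """Summary statistics for one property.

    ``outlier_rule`` selects the whisker convention: ``"median_iqr"`` places
    whiskers at median +/- 1.5*IQR; ``"tukey"`` at q1 - 1.5*IQR and
    q3 + 1.5*IQR.  Values outside the whiskers are counted, not dropped from
    the moments.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("summarize_values requires at least one finite value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    if outlier_rule == "median_iqr":
        lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
    elif outlier_rule == "tukey":
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown outlier_rule {outlier_rule!r}")
    return PropertySummary(
        property=name,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else math.nan,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(lo),
        whisker_high=float(hi),
        n_omitted_outliers=int(np.sum((x < lo) | (x > hi))),
    )


def summarize_library(
    table: pd.DataFrame, *, outlier_rule: str = "median_iqr"
) -> pd.DataFrame:
    """Per-property summary of a property/complexity table (one row each)."""
    if table.empty:
        raise ValueError("summarize_library requires a nonempty table")
    rows = [
        vars(summarize_values(table[col].to_numpy(), col, outlier_rule=outlier_rule))
        for col in table.columns
        if col in PROPERTY_NAMES + COMPLEXITY_NAMES
    ]
    return pd.DataFrame(rows).set_index("property")
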