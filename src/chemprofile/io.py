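"""Readers and writers for molecule files (SMILES line files and SDF)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .curation import MoleculeRecord

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def _infer_format(path: str) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        return "smi"
    if suffix == ".sdf":
        return "sdf"
    raise FormatError(f"cannot infer format from {path!r}; pass format explicitly")


def read_molecules(
    path: str, fmt: str | None = None
) -> tuple[list[tuple[str, str]], list[str]]:
    """Read raw ``(id, structure)`` records from a SMILES or SDF file.

    Malformed entries are collected (ids returned in the second element) and
    logged rather than fatal, but a file where more than half the entries
    fail to parse is rejected as probably being in the wrong format.
    """
    fmt = fmt or _infer_format(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    malformed: list[str] = []
    if fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smi = parts[0]
                rec_id = parts[1] if len(parts) > 1 else f"R{i + 1}"
                if Chem.MolFromSmiles(smi) is None:
                    malformed.append(rec_id)
                else:
                    records.append((rec_id, smi))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                malformed.append(f"R{i + 1}")
                continue
            rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"R{i + 1}"
            records.append((rec_id, Chem.MolToSmiles(mol)))
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    total = len(records) + len(malformed)
    if total == 0:
        raise FormatError(f"no entries found in {path!r}")
    if malformed:
        logger.warning("%s: %d of %d entries malformed", path, len(malformed), total)
    if len(malformed) > total / 2:
        raise FormatError(
            f"{path!r}: {len(malformed)}/{total} entries malformed — wrong format?"
        )
    return records, malformed


def write_curated_smiles(records: list[MoleculeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.canonical_structure}\t{r.id}\n")


def write_records_sdf(records: list[MoleculeRecord], path: str) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            m = r.to_mol()
            m.SetProp("_Name", r.id)
            m.SetProp("source", r.source)
            writer.write(m)
    finally:
        writer.close()


def read_reference_scaffolds(
    path: str, fmt: str | None = None, annotation_field: str = "annotation"
) -> list[tuple[str, float]]:
    """Annotated reference scaffold list from CSV (scaffold,annotation) or SDF."""
    fmt = fmt or ("sdf" if Path(path).suffix.lower() == ".sdf" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
        cols = list(df.columns)
        return list(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))
    out = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(annotation_field):
            continue
        out.append((Chem.MolToSmiles(mol), float(mol.GetProp(annotation_field))))
    return out
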