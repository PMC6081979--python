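"""Rule-based polyphenol classification.

A molecule is polyphenolic when it carries at least two phenolic hydroxyl
groups (an -OH bonded directly to an aromatic carbon; ethers and esters do
not count) or one biphenol motif (two directly bonded aromatic rings, each
bearing at least one hydroxyl).  The two-hydroxyl rule is read literally:
both hydroxyls may sit on the same ring, so catechol qualifies; a stricter
mode requiring hydroxyls on two distinct aromatic rings is available for
sensitivity analysis.  Heteroaromatic rings bearing OH on an aromatic
carbon count as phenolic.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .curation import CuratedLibrary, MoleculeRecord

# hydroxyl oxygen (2-connected O with exactly one H) on an aromatic carbon
_PHENOLIC_OH = Chem.MolFromSmarts("[OX2H1][c]")


@dataclass(frozen=True)
class PolyphenolVerdict:
    is_polyphenol: bool
    n_phenolic_oh: int
    has_biphenol_motif: bool


def _as_mol(mol: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        mol = mol.canonical_structure
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"invalid structure: {mol!r}")
        return m
    return mol


def count_phenolic_hydroxyls(mol: MoleculeRecord | Chem.Mol | str) -> int:
    """Number of hydroxyl groups bonded directly to an aromatic carbon."""
    return len(_as_mol(mol).GetSubstructMatches(_PHENOLIC_OH))


def _rings_with_phenolic_oh(m: Chem.Mol) -> list[frozenset[int]]:
    """Aromatic SSSR rings that carry >= 1 phenolic hydroxyl."""
    oh_carbons = {match[1] for match in m.GetSubstructMatches(_PHENOLIC_OH)}
    rings = []
    for ring in m.GetRingInfo().AtomRings():
        if all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring) and oh_carbons & set(ring):
            rings.append(frozenset(ring))
    return rings


def _has_biphenol_motif(m: Chem.Mol) -> bool:
    """Two directly bonded aromatic rings, each bearing a phenolic hydroxyl."""
    hydroxylated = _rings_with_phenolic_oh(m)
    for i, ring_a in enumerate(hydroxylated):
        for ring_b in hydroxylated[i + 1:]:
            if ring_a & ring_b:
                continue  # fused rings are one system, not a biaryl
            for a in ring_a:
                for b in ring_b:
                    if m.GetBondBetweenAtoms(a, b) is not None:
                        return True
    return False


def is_polyphenol(
    mol: MoleculeRecord | Chem.Mol | str, *, distinct_rings: bool = False
) -> PolyphenolVerdict:
    """Classify one molecule under the polyphenol rule.

    ``distinct_rings=True`` switches to the strict reading in which the two
    phenolic hydroxyls must sit on two different aromatic rings (catechol
    then no longer qualifies on the hydroxyl-count branch; the biphenol
    branch is unchanged).
    """
    m = _as_mol(mol)
    n_oh = count_phenolic_hydroxyls(m)
    biphenol = _has_biphenol_motif(m)
    if distinct_rings:
        enough_oh = len(_rings_with_phenolic_oh(m)) >= 2
    else:
        enough_oh = n_oh >= 2
    return PolyphenolVerdict(
        is_polyphenol=enough_oh or biphenol,
        n_phenolic_oh=n_oh,
        has_biphenol_motif=biphenol,
    )


def polyphenol_fraction(
    lib: CuratedLibrary | list[MoleculeRecord], *, distinct_rings: bool = False
) -> tuple[int, float, list[MoleculeRecord]]:
    """Count, fraction and subset of polyphenolic molecules in a library."""
    records = lib.records if isinstance(lib, CuratedLibrary) else lib
    if not records:
        raise ValueError("polyphenol_fraction requires a nonempty library")
    subset = [r for r in records if is_polyphenol(r, distinct_rings=distinct_rings).is_polyphenol]
    return len(subset), len(subset) / len(records), subset
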