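"""Structure standardization and library curation.

Implements an open, fully documented equivalent of the salt-stripping /
charge-neutralization preprocessing used for compound-database comparisons:
keep the largest fragment, neutralize charges where a neutral form exists,
canonicalize, and collapse duplicates within a library.  The exact rule set
(tie-breaks included) is part of the contract so that curated counts are
reproducible.
"""

from __future__ import annotations

import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# Settings fingerprint carried by every curated library; libraries curated
# under different settings must not be intersected.
DEFAULT_SETTINGS = {
    "largest_fragment": "heavy_atoms,mw,lex",
    "neutralize": "uncharger",
    "stereo_distinct": True,
}


class ParseError(ValueError):
    """Raised when a structure string cannot be parsed; carries the record id."""

    def __init__(self, record_id: str, raw: str):
        self.record_id = record_id
        self.raw = raw
        super().__init__(f"unparseable structure for record {record_id!r}: {raw!r}")


class ConfigurationError(ValueError):
    """Raised when two curated libraries have incompatible curation settings."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated structure: identifier, canonical SMILES, source-library tag."""

    id: str
    canonical_structure: str
    source: str = ""

    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_structure)


@dataclass
class CurationLog:
    n_input: int = 0
    n_fragment_stripped: int = 0
    n_neutralized: int = 0
    n_duplicates_removed: int = 0
    n_unparseable: int = 0
    n_output: int = 0

    def check(self) -> None:
        assert self.n_output == self.n_input - self.n_duplicates_removed - self.n_unparseable


@dataclass
class CuratedLibrary:
    """A curated library: unique standardized records plus provenance."""

    tag: str
    records: list[MoleculeRecord]
    log: CurationLog
    settings: dict = field(default_factory=lambda: dict(DEFAULT_SETTINGS))

    def __len__(self) -> int:
        return len(self.records)

    def smiles_set(self) -> set[str]:
        return {r.canonical_structure for r in self.records}


_uncharger = rdMolStandardize.Uncharger()


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Keep the organic (carbon-containing) fragment with the most heavy atoms.

    Organic fragments always beat counterions regardless of size (so methane
    survives a sodium salt); ties break by heavy-atom count, then molecular
    weight, then lexicographically smallest canonical SMILES.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0], False

    def key(f: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        return (not has_c, -f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f))

    return sorted(frags, key=key)[0], True


def standardize(raw: str, record_id: str = "?") -> str:
    """Standardize one structure string to its canonical curated form.

    Keeps the largest fragment, neutralizes protonation states where a
    neutral form exists (permanently charged species such as quaternary
    ammonium stay charged), and returns the canonical isomeric SMILES.
    Idempotent: standardizing the output returns it unchanged.
    """
    smiles, _, _ = _standardize_with_flags(raw, record_id)
    return smiles


def _standardize_with_flags(raw: str, record_id: str = "?") -> tuple[str, bool, bool]:
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise ParseError(record_id, raw)
    mol, stripped = _largest_fragment(mol)
    Chem.SanitizeMol(mol)
    before = Chem.GetFormalCharge(mol)
    mol = _uncharger.uncharge(mol)
    neutralized = Chem.GetFormalCharge(mol) != before
    return Chem.MolToSmiles(mol), stripped, neutralized


def curate_library(
    records: list[tuple[str, str]],
    source: str,
    *,
    stereo_distinct: bool = True,
) -> tuple[list[MoleculeRecord], CurationLog]:
    """Standardize and deduplicate raw ``(id, structure)`` records.

    Duplicates (identical canonical structure) collapse to the first
    occurrence, whose id is kept.  With ``stereo_distinct=False``,
    stereoisomers with identical constitution are also treated as duplicates.
    Returns the unique records and a count-consistent :class:`CurationLog`.
    """
    if not records:
        raise ValueError("curate_library requires a nonempty record list")
    log = CurationLog(n_input=len(records))
    seen: OrderedDict[str, MoleculeRecord] = OrderedDict()
    for rec_id, raw in records:
        try:
            smiles, stripped, neutralized = _standardize_with_flags(raw, rec_id)
        except ParseError:
            log.n_unparseable += 1
            logger.warning("dropping unparseable record %s: %r", rec_id, raw)
            continue
        log.n_fragment_stripped += stripped
        log.n_neutralized += neutralized
        key = smiles
        if not stereo_distinct:
            key = Chem.MolToSmiles(Chem.MolFromSmiles(smiles), isomericSmiles=False)
        if key in seen:
            log.n_duplicates_removed += 1
        else:
            seen[key] = MoleculeRecord(id=rec_id, canonical_structure=smiles, source=source)
    out = list(seen.values())
    log.n_output = len(out)
    log.check()
    if not out:
        warnings.warn(f"library {source!r}: all {log.n_input} records unparseable")
    return out, log


def curate(
    records: list[tuple[str, str]], source: str, *, stereo_distinct: bool = True
) -> CuratedLibrary:
    """Convenience wrapper returning a :class:`CuratedLibrary`."""
    recs, log = curate_library(records, source, stereo_distinct=stereo_distinct)
    settings = dict(DEFAULT_SETTINGS)
    settings["stereo_distinct"] = stereo_distinct
    return CuratedLibrary(tag=source, records=recs, log=log, settings=settings)


def library_overlap(a: CuratedLibrary, b: CuratedLibrary) -> tuple[int, float]:
    """Structural overlap of two curated libraries.

    Returns the number of canonical structures present in both libraries and
    that count as a fraction of ``b``'s size.  Refuses libraries curated under
    different standardization settings, since their canonical strings are not
    comparable.
    """
    if a.settings != b.settings:
        raise ConfigurationError(
            f"libraries {a.tag!r} and {b.tag!r} were curated with different settings"
        )
    count = len(a.smiles_set() & b.smiles_set())
    return count, count / len(b)
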