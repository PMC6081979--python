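"""Reproducible synthetic molecule libraries for end-to-end testing.

Real food/drug compound collections cannot be redistributed, so this module
generates libraries with the statistical structure the downstream analysis
assumes: a fixed ring-template vocabulary combined into a scaffold pool,
molecules assigned to scaffolds by a normalized power law over scaffold
ranks (exponent = ``scaffold_skew``; 0 = uniform quota), a tunable fraction
of polyphenolic structures (>= 2 aromatic hydroxyls), ring-free decoys,
and curation noise (counterions / ionized acids, and duplicate records
re-emitted with permuted atom order).  A sidecar truth table records each
molecule's intended scaffold, polyphenol flag and duplicate group, which
downstream modules use as an oracle.

Everything is driven by one integer seed; the same spec and seed produce
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

# Ring templates, written so that both the first and the last atom are
# carbons with a free valence (fragments concatenate by SMILES juxtaposition).
RING_TEMPLATES = {
    "benzene": "c1ccccc1",
    "cyclohexane": "C1CCCCC1",
    "tetrahydropyran": "C1CCOCC1",
    "cyclohexene": "C1=CCCCC1",
    "pyridine": "c1ccncc1",
    "furan": "c1ccoc1",
}
LINKERS = ("", "C", "CC", "CCC")

# Decoration vocabulary: small drug-like substituents (fragment SMILES whose
# first atom is the attachment point).
SUBSTITUENTS = {
    "methyl": "C",
    "ethyl": "CC",
    "propyl": "CCC",
    "hydroxyl": "O",
    "methoxy": "OC",
    "chloro": "Cl",
    "fluoro": "F",
    "carboxyl": "C(=O)O",
}


class CapacityError(ValueError):
    """Requested more scaffolds than the template vocabulary can construct."""


class InfeasibleSpecError(ValueError):
    """Library spec whose fractions/counts cannot be satisfied simultaneously."""


@dataclass(frozen=True)
class LibrarySpec:
    """Conditions for one synthetic library.

    Defaults emulate a large food-chemical collection: ~32% acyclic
    molecules, ~13.5% polyphenols, a skewed scaffold frequency distribution
    and a few percent of salt/duplicate curation noise.
    """

    n_molecules: int
    n_scaffolds: int = 50
    scaffold_skew: float = 1.0
    polyphenol_fraction: float = 0.135
    acyclic_fraction: float = 0.32
    salt_noise_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    seed: int = 0
    ring_count_range: tuple[int, int] = (1, 3)

    def validate(self) -> None:
        if self.n_molecules < 1 or self.n_scaffolds < 1:
            raise InfeasibleSpecError("n_molecules and n_scaffolds must be >= 1")
        for name in ("polyphenol_fraction", "acyclic_fraction",
                     "salt_noise_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpecError(f"{name}={v} outside [0, 1]")
        if self.polyphenol_fraction + self.acyclic_fraction > 1.0:
            raise InfeasibleSpecError(
                "polyphenol_fraction + acyclic_fraction must be <= 1"
            )
        n = self.n_molecules
        n_dup = int(self.duplicate_fraction * n)
        n_plain = (n - n_dup) - int(self.polyphenol_fraction * n) - int(self.acyclic_fraction * n)
        if n_plain < 0 or (n_dup > 0 and n_plain < 1):
            raise InfeasibleSpecError(
                "fractions leave no room for plain molecules "
                "(duplicates restate plain cyclic records)"
            )


@dataclass
class SyntheticLibrary:
    """Raw records plus the generation truth table."""

    spec: LibrarySpec
    records: list[tuple[str, str]]  # (id, raw structure string)
    truth: pd.DataFrame = field(repr=False)  # id, scaffold_id, is_polyphenol, duplicate_group

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# scaffold pool

def _is_own_scaffold(smiles: str) -> str | None:
    """Canonical SMILES if the structure is its own Murcko scaffold, else None."""
    m = Chem.MolFromSmiles(smiles)
    if m is None or m.GetRingInfo().NumRings() == 0:
        return None
    canon = Chem.MolToSmiles(m)
    core = Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(m))
    return canon if canon == core else None


def _enumerate_combos(ring_count_range: tuple[int, int]) -> list[str]:
    """All template/linker concatenations with ring counts in the range."""
    lo, hi = ring_count_range
    if not 1 <= lo <= hi <= 4:
        raise ValueError("ring_count_range must lie within [1, 4]")
    templates = list(RING_TEMPLATES.values())
    combos: list[str] = []
    level = [""] if lo > 1 else None
    current = templates[:]
    if lo == 1:
        combos.extend(current)
    for r in range(2, hi + 1):
        current = [c + link + t for c in current for link in LINKERS for t in templates]
        if r >= lo:
            combos.extend(current)
    return combos


def make_scaffold_pool(
    n_scaffolds: int,
    ring_count_range: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> list[str]:
    """Distinct, chemically valid ring systems in scaffold-canonical form.

    Candidates are enumerated from the template vocabulary, shuffled with the
    seed, canonicalized and kept only if they equal their own extracted
    scaffold.  Raises :class:`CapacityError` when the vocabulary cannot
    supply ``n_scaffolds`` distinct structures.
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    combos = _enumerate_combos(ring_count_range)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    pool: list[str] = []
    seen: set[str] = set()
    for idx in order:
        canon = _is_own_scaffold(combos[idx])
        if canon is None or canon in seen:
            continue
        seen.add(canon)
        pool.append(canon)
        if len(pool) == n_scaffolds:
            return pool
    raise CapacityError(
        f"vocabulary supports only {len(pool)} distinct scaffolds in "
        f"ring range {ring_count_range}; {n_scaffolds} requested"
    )


# ---------------------------------------------------------------------------
# molecule construction

def _free_carbon_sites(m: Chem.Mol, aromatic: bool | None = None) -> list[int]:
    sites = []
    for a in m.GetAtoms():
        if a.GetAtomicNum() != 6 or a.GetTotalNumHs() < 1:
            continue
        if aromatic is None or a.GetIsAromatic() == aromatic:
            sites.append(a.GetIdx())
    return sites


def _attach(m: Chem.Mol, atom_idx: int, frag_smiles: str) -> Chem.Mol:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(m, frag))
    combo.AddBond(atom_idx, m.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _aromatic_capable(scaffold_smiles: str) -> bool:
    m = Chem.MolFromSmiles(scaffold_smiles)
    return len(_free_carbon_sites(m, aromatic=True)) >= 2


def _decorate(
    scaffold: str,
    rng: np.random.Generator,
    polyphenol: bool,
    max_subs: int = 3,
) -> str:
    """One decorated molecule on a scaffold.

    Polyphenolic molecules get >= 2 hydroxyls on aromatic carbons; all other
    molecules never receive an aromatic hydroxyl, so the generation flag and
    the structural classifier agree by construction.
    """
    m = Chem.MolFromSmiles(scaffold)
    if polyphenol:
        n_oh = 2 + int(rng.random() < 0.3)
        for _ in range(n_oh):
            sites = _free_carbon_sites(m, aromatic=True)
            if not sites:
                break
            m = _attach(m, int(rng.choice(sites)), "O")
    names = list(SUBSTITUENTS)
    for _ in range(int(rng.integers(0, max_subs + 1))):
        sites = _free_carbon_sites(m)
        if not sites:
            break
        site = int(rng.choice(sites))
        sub = SUBSTITUENTS[names[int(rng.integers(len(names)))]]
        if sub == "O" and not polyphenol and m.GetAtomWithIdx(site).GetIsAromatic():
            sub = "C"  # never place a phenolic OH on a non-polyphenol
        m = _attach(m, site, sub)
    return Chem.MolToSmiles(m)


def _random_acyclic(rng: np.random.Generator) -> str:
    """Random ring-free molecule (branched alkane/ether/alcohol tree)."""
    n_heavy = int(rng.integers(3, 10))
    m = Chem.RWMol()
    m.AddAtom(Chem.Atom(6))
    for _ in range(n_heavy - 1):
        z = 8 if rng.random() < 0.18 else 6
        # candidate parents with free valence; O never bonds to O
        parents = [
            a.GetIdx()
            for a in m.GetAtoms()
            if a.GetDegree() < (2 if a.GetAtomicNum() == 8 else 4)
            and not (z == 8 and a.GetAtomicNum() == 8)
        ]
        if not parents:
            break
        idx = m.AddAtom(Chem.Atom(z))
        m.AddBond(int(rng.choice(parents)), idx, Chem.BondType.SINGLE)
    out = m.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer quotas summing to total, proportional to weights."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = total * w
    base = np.floor(raw).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def _zipf_weights(s: int, skew: float) -> np.ndarray:
    return np.arange(1, s + 1, dtype=float) ** (-skew)


def _permuted_smiles(smiles: str, rng: np.random.Generator) -> str:
    """The same structure written with a permuted atom order."""
    m = Chem.MolFromSmiles(smiles)
    perm = rng.permutation(m.GetNumAtoms()).tolist()
    return Chem.MolToSmiles(Chem.RenumberAtoms(m, perm), canonical=False)


_ACID = Chem.MolFromSmarts("C(=O)[OX2H1]")


def _salted(smiles: str, rng: np.random.Generator) -> str:
    """A salt/charge-noise variant: deprotonated acid + Na+, or a NaCl contaminant."""
    m = Chem.MolFromSmiles(smiles)
    if m.HasSubstructMatch(_ACID) and rng.random() < 0.7:
        match = m.GetSubstructMatches(_ACID)[0]
        em = Chem.RWMol(m)
        o = em.GetAtomWithIdx(match[2])
        o.SetFormalCharge(-1)
        o.SetNoImplicit(True)
        o.SetNumExplicitHs(0)
        ion = em.GetMol()
        Chem.SanitizeMol(ion)
        return Chem.MolToSmiles(ion) + ".[Na+]"
    return smiles + ".[Na+].[Cl-]"


ACYCLIC_ID = "ACYCLIC"


def generate_library(spec: LibrarySpec) -> SyntheticLibrary:
    """Generate one synthetic library per the spec, with its truth table.

    Exactly ``n_molecules`` records: ``floor(polyphenol_fraction*n)``
    polyphenols, ``floor(acyclic_fraction*n)`` ring-free molecules,
    ``floor(duplicate_fraction*n)`` atom-order restatements of earlier plain
    records and ``floor(salt_noise_fraction*n)`` records emitted in salted /
    ionized form.  Scaffold quotas follow the power law deterministically
    (largest-remainder rounding), so identical specs give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    n_dup = int(spec.duplicate_fraction * n)
    n_poly = int(spec.polyphenol_fraction * n)
    n_acyclic = int(spec.acyclic_fraction * n)
    n_plain = n - n_dup - n_poly - n_acyclic
    n_salt = int(spec.salt_noise_fraction * n)

    pool = make_scaffold_pool(spec.n_scaffolds, spec.ring_count_range, spec.seed)
    weights = _zipf_weights(len(pool), spec.scaffold_skew)
    plain_counts = _largest_remainder(n_plain, weights)
    aromatic_idx = [i for i, s in enumerate(pool) if _aromatic_capable(s)]
    if n_poly > 0 and not aromatic_idx:
        raise InfeasibleSpecError(
            "polyphenol_fraction > 0 but the scaffold pool has no scaffold "
            "with two free aromatic carbons"
        )
    poly_counts = (
        _largest_remainder(n_poly, weights[aromatic_idx]) if n_poly else np.array([], dtype=int)
    )

    # build distinct base molecules: (smiles, scaffold_id, is_polyphenol)
    base: list[tuple[str, str, bool]] = []
    seen: set[str] = set()

    def _add_unique(make, scaffold_id: str, poly: bool) -> None:
        for attempt in range(80):
            smi = make(max_subs=3 + attempt // 10) if attempt else make()
            canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            if canon not in seen:
                seen.add(canon)
                base.append((smi, scaffold_id, poly))
                return
        raise InfeasibleSpecError(
            f"could not generate enough distinct molecules on scaffold {scaffold_id}"
        )

    for i, count in enumerate(plain_counts):
        scaffold = pool[i]
        for _ in range(int(count)):
            _add_unique(
                lambda max_subs=3: _decorate(scaffold, rng, polyphenol=False, max_subs=max_subs),
                scaffold, False,
            )
    for j, count in enumerate(poly_counts):
        scaffold = pool[aromatic_idx[j]]
        for _ in range(int(count)):
            _add_unique(
                lambda max_subs=3: _decorate(scaffold, rng, polyphenol=True, max_subs=max_subs),
                scaffold, True,
            )
    for _ in range(n_acyclic):
        _add_unique(lambda max_subs=None: _random_acyclic(rng), ACYCLIC_ID, False)

    # shuffle base order, then append duplicates (restatements of earlier records)
    order = rng.permutation(len(base))
    base = [base[i] for i in order]

    width = len(str(n))
    ids = [f"M{i + 1:0{width}d}" for i in range(n)]
    records: list[tuple[str, str]] = []
    rows: list[dict] = []
    for rec_id, (smi, scaffold_id, poly) in zip(ids, base):
        records.append((rec_id, smi))
        rows.append({"id": rec_id, "scaffold_id": scaffold_id,
                     "is_polyphenol": poly, "duplicate_group": rec_id})

    plain_positions = [k for k, (_, sid, poly) in enumerate(base)
                       if sid != ACYCLIC_ID and not poly]
    dup_sources = (
        rng.choice(plain_positions, size=n_dup, replace=n_dup > len(plain_positions))
        if n_dup
        else np.array([], dtype=int)
    )
    for d, src in enumerate(dup_sources):
        src = int(src)
        rec_id = ids[len(base) + d]
        smi, scaffold_id, poly = base[src]
        records.append((rec_id, _permuted_smiles(smi, rng)))
        rows.append({"id": rec_id, "scaffold_id": scaffold_id,
                     "is_polyphenol": poly, "duplicate_group": ids[src]})

    # salt/charge noise on base records (duplicates stay exact restatements)
    salt_targets = rng.choice(len(base), size=min(n_salt, len(base)), replace=False)
    for t in sorted(int(x) for x in salt_targets):
        records[t] = (records[t][0], _salted(records[t][1], rng))

    truth = pd.DataFrame(rows)
    return SyntheticLibrary(spec=spec, records=records, truth=truth)


# ---------------------------------------------------------------------------
# file output

def write_smiles(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rec_id, smi in records:
            fh.write(f"{smi}\t{rec_id}\n")


def write_sdf(records: list[tuple[str, str]], path: str) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for rec_id, smi in records:
            m = Chem.MolFromSmiles(smi)
            if m is None:
                logger.warning("skipping unparseable record %s in SDF export", rec_id)
                continue
            m.SetProp("_Name", rec_id)
            writer.write(m)
    finally:
        writer.close()


def write_truth(lib: SyntheticLibrary, path: str) -> None:
    lib.truth.to_csv(path, index=False)
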