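"""Molecular fingerprints and Tanimoto similarity over a drug panel.

SMILES strings are parsed with RDKit (including aromaticity perception and
salt stripping) into a light-weight :class:`Molecule` graph.  Circular
ECFP-style fingerprints are then computed natively: each atom receives an
initial invariant from its element, charge, degree, hydrogen count, ring
membership and aromaticity; ``radius`` rounds of neighborhood hashing follow,
and every identifier from every round is folded into a fixed-width bit vector
by modulo.  The hash is a fixed, seedless 32-bit FNV-1a mix, so fingerprints
are reproducible across runs and platforms.

Bit patterns are deliberately *not* required to match RDKit's Morgan
implementation (hash functions differ); what the downstream analysis relies
on is the similarity *ordering*, which is validated against RDKit by rank
agreement.  :func:`rdkit_reference_matrix` exposes that independent
reference route.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

THERAPEUTIC_CLASSES = (
    "analgesic",
    "hypnotic_anxiolytic",
    "antipsychotic",
    "antiallergic",
    "antitussive",
    "antibiotic",
    "antidiabetic",
    "diuretic",
)

#: bond orders as stored on :class:`Bond`
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_BOND_CODE = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}

_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class DrugRecord:
    """One drug of the panel: tweet-query name, structure and grouping."""

    query_name: str
    generic_name: str
    smiles: str
    therapeutic_class: str
    otc_flag: bool

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"drug {self.query_name!r}: empty SMILES")
        if self.therapeutic_class not in THERAPEUTIC_CLASSES:
            raise ValueError(
                f"drug {self.query_name!r}: unknown therapeutic class "
                f"{self.therapeutic_class!r}"
            )


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int
    n_hs: int
    in_ring: bool
    aromatic: bool


@dataclass(frozen=True)
class Bond:
    """Undirected bond; ``i < j`` by construction, order in BOND_ORDERS."""

    i: int
    j: int
    order: str


@dataclass(frozen=True)
class Molecule:
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) outside atom range 0..{n - 1}")
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if b.order not in _BOND_CODE:
                raise ValueError(f"unknown bond order {b.order!r}")

    def neighbors(self) -> list[list[tuple[int, str]]]:
        """Adjacency as, per atom, a list of (neighbor index, bond order)."""
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append((b.j, b.order))
            adj[b.j].append((b.i, b.order))
        return adj


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary fingerprint: a set of on-bit positions in [0, width)."""

    width: int
    on_bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("fingerprint width must be >= 1")
        if any(not (0 <= b < self.width) for b in self.on_bits):
            raise ValueError("on-bit outside [0, width)")


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` graph.

    RDKit performs the parse and aromaticity perception.  Stereochemistry is
    discarded and only the largest covalent fragment is kept (salts and
    counter-ions are stripped), since the similarity analysis is purely
    2D/topological.  Implicit hydrogens are recorded as per-atom counts, not
    materialised as atoms.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            n_hs=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = _RDKIT_BOND.get(b.GetBondType())
        if order is None:
            # exotic bond types (dative etc.) degrade to single
            order = "single"
        bonds.append(Bond(min(i, j), max(i, j), order))
    return Molecule(atoms=atoms, bonds=tuple(bonds))


# ---------------------------------------------------------------------------
# native circular fingerprint

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


def _mix32(values: Iterable[int]) -> int:
    """Seedless FNV-1a over a sequence of ints, 4 bytes each, little-endian."""
    h = _FNV_OFFSET
    for v in values:
        v &= _MASK32
        for _ in range(4):
            h = ((h ^ (v & 0xFF)) * _FNV_PRIME) & _MASK32
            v >>= 8
    return h


def _hash_str(s: str) -> int:
    h = _FNV_OFFSET
    for byte in s.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & _MASK32
    return h


def _initial_invariants(mol: Molecule) -> list[int]:
    """ECFP-style connectivity invariants.

    Components per atom: element, formal charge, heavy-atom degree,
    attached-H count and ring membership.  Aromaticity enters through the
    aromatic bond type during the neighborhood iterations, not the atom
    invariant.
    """
    adj = mol.neighbors()
    return [
        _mix32(
            (
                _hash_str(a.element),
                a.charge & _MASK32,
                len(adj[idx]),
                a.n_hs,
                int(a.in_ring),
            )
        )
        for idx, a in enumerate(mol.atoms)
    ]


def morgan_fingerprint(mol: Molecule, radius: int = 2, width: int = 1024) -> Fingerprint:
    """Fold an ECFP-style circular fingerprint of ``mol`` to ``width`` bits.

    Each retained atom-environment identifier of iterations 0..radius is
    folded to ``id % width`` and recorded as an on-bit (binary occupancy,
    no counts).  As in canonical ECFP generation, duplicate environments
    are removed: an environment covering a bond set already emitted at a
    smaller radius — or emitted at the same radius by another atom, where
    the smaller identifier wins — contributes no new identifier.
    Deterministic: a given molecule graph always yields the same bits.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if width < 1:
        raise ValueError("width must be >= 1")
    if not mol.atoms:
        raise ValueError("cannot fingerprint a molecule with no atoms")
    adj = mol.neighbors()
    bond_index: dict[tuple[int, int], int] = {}
    for k, b in enumerate(mol.bonds):
        bond_index[(b.i, b.j)] = k
        bond_index[(b.j, b.i)] = k
    ids = _initial_invariants(mol)
    envs: list[frozenset[int]] = [frozenset() for _ in mol.atoms]
    kept_ids = list(ids)  # radius-0 identifiers are always kept
    # the empty bond set is the radius-0 environment: an environment that
    # stops growing (isolated atom, or whole molecule covered) emits nothing new
    seen_envs: set[frozenset[int]] = {frozenset()}
    for r in range(1, radius + 1):
        new_ids = []
        new_envs = []
        for idx in range(len(mol.atoms)):
            env_atoms = sorted((_BOND_CODE[order], ids[nb]) for nb, order in adj[idx])
            parts = [r, ids[idx]]
            for code, nb_id in env_atoms:
                parts.extend((code, nb_id))
            new_ids.append(_mix32(parts))
            bonds = set(envs[idx])
            for nb, _ in adj[idx]:
                bonds.add(bond_index[(idx, nb)])
                bonds.update(envs[nb])
            new_envs.append(frozenset(bonds))
        # duplicate-environment removal: one identifier per distinct bond set
        this_round: dict[frozenset[int], int] = {}
        for ident, env in zip(new_ids, new_envs):
            if env in seen_envs:
                continue
            if env not in this_round or ident < this_round[env]:
                this_round[env] = ident
        kept_ids.extend(this_round.values())
        seen_envs.update(this_round)
        ids, envs = new_ids, new_envs
    return Fingerprint(width=width, on_bits=frozenset(i % width for i in kept_ids))


def fingerprint_smiles(smiles: str, radius: int = 2, width: int = 1024) -> Fingerprint:
    """Convenience: parse and fingerprint in one call."""
    return morgan_fingerprint(parse_smiles(smiles), radius=radius, width=width)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two fingerprints."""
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return len(a.on_bits & b.on_bits) / union


# ---------------------------------------------------------------------------
# similarity matrices


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric drug-by-drug Tanimoto matrix with diagonal exactly 1.0."""

    drug_order: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.drug_order)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} drugs")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("similarity matrix diagonal must be exactly 1.0")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def index(self, drug: str) -> int:
        try:
            return self.drug_order.index(drug)
        except ValueError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["drug", *self.drug_order])
            for name, row in zip(self.drug_order, self.values):
                w.writerow([name, *(f"{x:.6f}" for x in row)])

    def to_long_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["drug_a", "drug_b", "tanimoto"])
            for i, a in enumerate(self.drug_order):
                for j, b in enumerate(self.drug_order):
                    if i < j:
                        w.writerow([a, b, f"{self.values[i, j]:.6f}"])

    def max_offdiagonal_pair(self) -> tuple[str, str, float]:
        """The unordered off-diagonal pair with the highest similarity."""
        masked = self.values - 2.0 * np.eye(len(self.drug_order))
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        return self.drug_order[i], self.drug_order[j], float(self.values[i, j])


def similarity_matrix_from_fingerprints(
    names: Sequence[str], fingerprints: Sequence[Fingerprint]
) -> SimilarityMatrix:
    if len(names) != len(fingerprints):
        raise ValueError("names and fingerprints length mismatch")
    if len(names) < 2:
        raise ValueError("need at least 2 drugs")
    if len(set(names)) != len(names):
        raise ValueError("drug names must be unique")
    n = len(names)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    return SimilarityMatrix(drug_order=tuple(names), values=values)


def build_similarity_matrix(
    panel: Sequence[DrugRecord], radius: int = 2, width: int = 1024
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over a drug panel, in panel order."""
    if len(panel) < 2:
        raise ValueError("need at least 2 drugs to build a similarity matrix")
    fps = []
    for rec in panel:
        try:
            fps.append(fingerprint_smiles(rec.smiles, radius=radius, width=width))
        except SmilesParseError as exc:
            raise SmilesParseError(f"drug {rec.query_name!r}: {exc}") from exc
    return similarity_matrix_from_fingerprints([r.query_name for r in panel], fps)


def rdkit_reference_matrix(
    panel: Sequence[DrugRecord], radius: int = 2, width: int | None = None
) -> SimilarityMatrix:
    """Independent reference: RDKit's own Morgan fingerprints and Tanimoto.

    With ``width=None`` (default) the similarity is computed on the full,
    unfolded environment identifiers — the toolkit's exact Morgan
    similarity, free of bit-folding collision noise.  With an integer
    ``width`` the identifiers are folded as in a production fingerprint.
    Used as a cross-check of the native implementation's similarity
    *ranking*; never used by the analysis pipeline itself.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=width if width is not None else 2048
    )
    sets = []
    for rec in panel:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise SmilesParseError(f"drug {rec.query_name!r}: could not parse SMILES")
        if width is None:
            ids = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
            sets.append(frozenset(int(i) % (1 << 62) for i in ids))
        else:
            sets.append(frozenset(gen.GetFingerprint(mol).GetOnBits()))
    eff_width = width if width is not None else (1 << 62)
    fps = [Fingerprint(width=eff_width, on_bits=s) for s in sets]
    return similarity_matrix_from_fingerprints([r.query_name for r in panel], fps)


# ---------------------------------------------------------------------------
# panel I/O

_PANEL_FIELDS = ["query_name", "generic_name", "smiles", "therapeutic_class", "otc_flag"]


def read_panel(path: str | Path) -> list[DrugRecord]:
    """Read a drug panel CSV with header query_name,generic_name,smiles,therapeutic_class,otc_flag."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _PANEL_FIELDS:
            raise ValueError(
                f"panel header must be {','.join(_PANEL_FIELDS)}, got {reader.fieldnames}"
            )
        records = [
            DrugRecord(
                query_name=row["query_name"],
                generic_name=row["generic_name"],
                smiles=row["smiles"],
                therapeutic_class=row["therapeutic_class"],
                otc_flag=row["otc_flag"].strip().lower() in {"true", "1", "yes"},
            )
            for row in reader
        ]
    names = [r.query_name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("panel query_names must be unique")
    return records


def write_panel(panel: Sequence[DrugRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PANEL_FIELDS)
        for r in panel:
            w.writerow(
                [r.query_name, r.generic_name, r.smiles, r.therapeutic_class, r.otc_flag]
            )
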