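"""SMILES parsing, canonicalization, and structural descriptors.

A :class:`Molecule` is a validated, canonicalized structure keyed by its
canonical SMILES.  Two structural descriptors are computed at parse time:

``n_aromatic_rings``
    Number of rings in the smallest ring basis (SSSR) whose every bond is
    aromatic.

``conjugate_length``
    The extent of the longest chain of alternating single/double bonds,
    measured in double-bond units.  Aromatic systems are kekulized first
    (one kekulé structure, chosen deterministically by the canonicalization
    routine), so benzene has conjugate length 3 and a lone C=C has length 1.
    Triple bonds do not participate.

Only the heavy-atom graph is considered; hydrogens are implicit throughout.
By default molecules are restricted to the {H, C, N, O} alphabet of the
training corpus; the constraint can be switched off per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger

from .errors import ElementConstraintError, InputError, InvalidSmilesError, StructureError

RDLogger.DisableLog("rdApp.error")

#: Element alphabet of the training corpus.
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O"})


@dataclass(frozen=True)
class Molecule:
    """A parsed, validated, canonicalized chemical structure.

    ``smiles_canonical`` is the deduplication key: any two SMILES spellings
    of the same structure map to the same canonical string.
    """

    smiles_input: str
    smiles_canonical: str
    atoms: tuple[tuple[str, bool], ...]  # (element symbol, aromatic flag)
    bonds: tuple[tuple[int, int, str], ...]  # (i, j, order)
    n_aromatic_rings: int
    conjugate_length: int
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    def element_count(self, symbol: str) -> int:
        return sum(1 for s, _ in self.atoms if s == symbol)


_BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def parse_smiles(text: str, enforce_elements: bool = True) -> Molecule:
    """Parse and validate a SMILES string into a :class:`Molecule`.

    Chemically invalid strings (unbalanced rings/branches, valence
    violations) raise :class:`InvalidSmilesError`; they are never silently
    repaired.  With ``enforce_elements`` (the default), any element outside
    {H, C, N, O} raises :class:`ElementConstraintError`.
    """
    if not text:
        raise InputError("empty SMILES string")
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise InvalidSmilesError(f"invalid SMILES: {text!r}")
    if enforce_elements:
        for atom in rdmol.GetAtoms():
            if atom.GetSymbol() not in ALLOWED_ELEMENTS:
                raise ElementConstraintError(
                    f"element {atom.GetSymbol()!r} in {text!r} outside allowed set "
                    f"{sorted(ALLOWED_ELEMENTS)}"
                )
    canonical = Chem.MolToSmiles(rdmol)
    atoms = tuple((a.GetSymbol(), a.GetIsAromatic()) for a in rdmol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER_NAMES[b.GetBondType()])
        for b in rdmol.GetBonds()
    )
    return Molecule(
        smiles_input=text,
        smiles_canonical=canonical,
        atoms=atoms,
        bonds=bonds,
        n_aromatic_rings=_count_aromatic_rings(rdmol),
        conjugate_length=_count_conjugate_length(rdmol),
        _rdmol=rdmol,
    )


def count_aromatic_rings(mol: Molecule) -> int:
    """Number of SSSR rings whose every bond is aromatic."""
    return mol.n_aromatic_rings


def count_conjugate_length(mol: Molecule) -> int:
    """Longest alternating single/double bond path, in double-bond units."""
    return mol.conjugate_length


def _count_aromatic_rings(rdmol: Chem.Mol) -> int:
    ring_info = rdmol.GetRingInfo()
    n = 0
    for bond_ring in ring_info.BondRings():
        if all(rdmol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            n += 1
    return n


def _count_conjugate_length(rdmol: Chem.Mol) -> int:
    """Exhaustive DFS over simple paths with strictly alternating bond orders.

    Molecules in this search are small (tens of heavy atoms), so exhaustive
    enumeration is affordable and leaves no heuristic gap.
    """
    try:
        kek = Chem.Mol(rdmol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rare on sanitized mols
        raise StructureError(f"kekulization failed: {exc}") from exc

    # adjacency restricted to single/double bonds; triples break conjugation
    neighbors: dict[int, list[tuple[int, int]]] = {
        a.GetIdx(): [] for a in kek.GetAtoms()
    }
    for bond in kek.GetBonds():
        order = bond.GetBondType()
        if order == Chem.BondType.SINGLE:
            o = 1
        elif order == Chem.BondType.DOUBLE:
            o = 2
        else:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[i].append((j, o))
        neighbors[j].append((i, o))

    best = 0

    def dfs(atom: int, prev_order: int, visited: set[int], n_double: int) -> None:
        nonlocal best
        best = max(best, n_double)
        for nxt, order in neighbors[atom]:
            if nxt in visited or order == prev_order:
                continue
            visited.add(nxt)
            dfs(nxt, order, visited, n_double + (order == 2))
            visited.remove(nxt)

    for start in neighbors:
        dfs(start, 0, {start}, 0)
    return best


def load_corpus(path: str | Path) -> list[str]:
    """Read a SMILES corpus: one SMILES per line, '#' comments and blank
    lines ignored, UTF-8."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    corpus = [ln.strip() for ln in lines]
    return [ln for ln in corpus if ln and not ln.startswith("#")]
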