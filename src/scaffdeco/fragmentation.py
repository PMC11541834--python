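"""Matched-molecular-pair style slicing of molecules into scaffold and
decoration fragments, and the inverse reattachment.

A molecule is cut at every acyclic single bond between heavy atoms.  The
ring-containing side becomes the scaffold, the other side the decoration; when
both sides carry a ring, both orientations are emitted.  Each fragment gets a
single attachment-point dummy atom, written ``[*]``, so that
``attach(scaffold, decoration)`` reproduces the source molecule exactly
(canonical-SMILES equality).

Decorations entering a pair library must satisfy community drug-likeness
bounds on the fragment itself (hydrogen-bond donors, Crippen ClogP and
rotatable-bond count, each ≤ 5 by default), and scaffolds must retain at
least one ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Lipinski, rdMolDescriptors


class FragmentationError(ValueError):
    pass


@dataclass(frozen=True)
class ScaffoldDecorationPair:
    """A ring-containing scaffold and its detached decoration.

    Both SMILES carry exactly one ``[*]`` attachment token.  ``cut_bond``
    records the (begin, end) atom indices of the severed bond in the source
    molecule, begin on the scaffold side.
    """

    scaffold_smiles: str
    decoration_smiles: str
    source_id: str = ""
    cut_bond: tuple[int, int] = (-1, -1)


@dataclass(frozen=True)
class DecorationConstraints:
    """Bounds a decoration fragment must satisfy to enter a pair library."""

    max_hbd: int = 5
    max_clogp: float = 5.0
    max_rotbonds: int = 5

    def __post_init__(self):
        if self.max_hbd < 0 or self.max_clogp < 0 or self.max_rotbonds < 0:
            raise ValueError("constraint bounds must be >= 0")


@dataclass
class PairLibrary:
    """Deduplicated scaffold–decoration pairs with an 8:1:1 split.

    ``train``/``validation``/``test`` are disjoint, exhaustive index lists
    into ``pairs``; the remainder after integer division goes to train.
    """

    pairs: list[ScaffoldDecorationPair]
    train: list[int] = field(default_factory=list)
    validation: list[int] = field(default_factory=list)
    test: list[int] = field(default_factory=list)

    def split(self, name: str) -> list[ScaffoldDecorationPair]:
        idx = {"train": self.train, "validation": self.validation, "test": self.test}[name]
        return [self.pairs[i] for i in idx]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"unparseable SMILES: {smiles!r}")
    return mol


def _has_ring(mol: Chem.Mol) -> bool:
    return mol.GetRingInfo().NumRings() > 0


def _fragment_smiles(mol: Chem.Mol, bond_idx: int) -> tuple[str, str, tuple[int, int]] | None:
    """Cut one bond, returning the two fragment SMILES (each with one [*])
    ordered (begin-side, end-side), or None if fragmentation fails."""
    bond = mol.GetBondWithIdx(bond_idx)
    begin, end = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:
        return None
    frags_with_atoms = Chem.GetMolFrags(frag)
    # map source atom index -> piece holding it
    side_of = {}
    for piece_i, atoms in enumerate(frags_with_atoms):
        for a in atoms:
            if a < mol.GetNumAtoms():
                side_of[a] = piece_i
    s_begin = Chem.MolToSmiles(pieces[side_of[begin]])
    s_end = Chem.MolToSmiles(pieces[side_of[end]])
    return s_begin, s_end, (begin, end)


def enumerate_cuts(smiles: str, source_id: str = "") -> list[ScaffoldDecorationPair]:
    """Enumerate all single-cut scaffold–decoration pairs of a molecule.

    One pair per acyclic single non-ring bond between heavy atoms whose
    ring-containing side becomes the scaffold; when both sides contain rings,
    both orientations are emitted.  An acyclic molecule yields no pairs.
    """
    mol = _mol_from_smiles(smiles)
    pairs: list[ScaffoldDecorationPair] = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.GetBeginAtom().GetAtomicNum() == 1 or bond.GetEndAtom().GetAtomicNum() == 1:
            continue
        cut = _fragment_smiles(mol, bond.GetIdx())
        if cut is None:
            continue
        s_begin, s_end, (begin, end) = cut
        ring_begin = _has_ring(_mol_from_smiles(s_begin))
        ring_end = _has_ring(_mol_from_smiles(s_end))
        if ring_begin:
            pairs.append(ScaffoldDecorationPair(s_begin, s_end, source_id, (begin, end)))
        if ring_end:
            pairs.append(ScaffoldDecorationPair(s_end, s_begin, source_id, (end, begin)))
    return pairs


def _decoration_mol(decoration_smiles: str) -> Chem.Mol:
    """Decoration with the attachment dummy replaced by hydrogen, for
    descriptor evaluation on the fragment as a standalone molecule."""
    mol = Chem.RWMol(_mol_from_smiles(decoration_smiles))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
    out = Chem.RemoveHs(mol.GetMol())
    Chem.SanitizeMol(out)
    return out


def decoration_descriptors(decoration_smiles: str) -> tuple[int, float, int]:
    """(HBD, ClogP, rotatable bonds) of a decoration fragment."""
    mol = _decoration_mol(decoration_smiles)
    return (
        Lipinski.NumHDonors(mol),
        Crippen.MolLogP(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
    )


def filter_pairs(
    pairs: list[ScaffoldDecorationPair],
    constraints: DecorationConstraints = DecorationConstraints(),
) -> list[ScaffoldDecorationPair]:
    """Keep pairs whose scaffold has a ring and whose decoration satisfies
    the HBD / ClogP / rotatable-bond bounds."""
    kept = []
    for p in pairs:
        if not _has_ring(_mol_from_smiles(p.scaffold_smiles)):
            continue
        hbd, clogp, rotb = decoration_descriptors(p.decoration_smiles)
        if hbd <= constraints.max_hbd and clogp <= constraints.max_clogp and rotb <= constraints.max_rotbonds:
            kept.append(p)
    return kept


def _single_attachment_index(mol: Chem.Mol, what: str) -> int:
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise FragmentationError(f"{what} must carry exactly one attachment token, found {len(dummies)}")
    return dummies[0]


def attach(scaffold_smiles: str, decoration_smiles: str) -> str:
    """Join a scaffold and a decoration at their attachment points.

    Forms a single bond between the two attachment neighbours, removes the
    dummy atoms and returns the canonical SMILES of the product.
    """
    scaffold = _mol_from_smiles(scaffold_smiles)
    decoration = _mol_from_smiles(decoration_smiles)
    i_s = _single_attachment_index(scaffold, "scaffold")
    i_d = _single_attachment_index(decoration, "decoration")
    combo = Chem.RWMol(Chem.CombineMols(scaffold, decoration))
    offset = scaffold.GetNumAtoms()
    dummy_s, dummy_d = i_s, offset + i_d
    nbrs_s = combo.GetAtomWithIdx(dummy_s).GetNeighbors()
    nbrs_d = combo.GetAtomWithIdx(dummy_d).GetNeighbors()
    if not nbrs_s or not nbrs_d:
        raise FragmentationError("attachment token has no neighbour to bond from")
    combo.AddBond(nbrs_s[0].GetIdx(), nbrs_d[0].GetIdx(), Chem.BondType.SINGLE)
    for idx in sorted((dummy_s, dummy_d), reverse=True):
        combo.RemoveAtom(idx)
    try:
        product = combo.GetMol()
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise FragmentationError(f"attachment produced an invalid molecule: {exc}")
    return Chem.MolToSmiles(product)


def build_pair_library(
    library,
    constraints: DecorationConstraints = DecorationConstraints(),
    split_seed: int = 0,
) -> PairLibrary:
    """Slice every molecule, filter, deduplicate and split 8:1:1.

    ``library`` is an iterable of objects with ``smiles`` and ``mol_id``
    attributes (e.g. :class:`scaffdeco.synthetic.MoleculeRecord`) or plain
    SMILES strings.  Deduplication is on the ordered tuple of canonical
    scaffold and decoration SMILES.  Raises on an empty result.
    """
    seen: set[tuple[str, str]] = set()
    pairs: list[ScaffoldDecorationPair] = []
    for entry in library:
        smiles = getattr(entry, "smiles", entry)
        mol_id = getattr(entry, "mol_id", "")
        for p in filter_pairs(enumerate_cuts(smiles, mol_id), constraints):
            key = (p.scaffold_smiles, p.decoration_smiles)
            if key not in seen:
                seen.add(key)
                pairs.append(p)
    if not pairs:
        raise FragmentationError("no scaffold-decoration pairs survived slicing and filtering")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_val, n_test = n // 10, n // 10
    n_train = n - n_val - n_test
    return PairLibrary(
        pairs=pairs,
        train=sorted(int(i) for i in order[:n_train]),
        validation=sorted(int(i) for i in order[n_train : n_train + n_val]),
        test=sorted(int(i) for i in order[n_train + n_val :]),
    )


def write_pair_library(lib: PairLibrary, path) -> None:
    """TSV with columns scaffold, decoration, source_id, split."""
    split_of = {}
    for name in ("train", "validation", "test"):
        for i in getattr(lib, name):
            split_of[i] = name
    with open(path, "w") as fh:
        fh.write("scaffold\tdecoration\tsource_id\tsplit\n")
        for i, p in enumerate(lib.pairs):
            fh.write(f"{p.scaffold_smiles}\t{p.decoration_smiles}\t{p.source_id}\t{split_of[i]}\n")
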