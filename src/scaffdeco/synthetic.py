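"""Synthetic inputs with known ground truth for every stage of the pipeline.

Four generators emulate the data classes the pipeline consumes:

* drug-like, ring-containing molecule libraries built by an attachment
  grammar (ring core + up to ``max_substituents`` substituents at ring
  positions), valid by construction;
* injectively scored candidate tables for the screening funnel;
* trajectories with per-residue Gaussian fluctuation of controllable
  amplitude and planted inter-residue correlation (closed-form RMSF and
  DCCM ground truth: RMSF = σ√3, block correlation = ρ);
* per-frame MM-PBSA energy components with specified means and SDs.

All randomness flows through a single seeded :class:`numpy.random.Generator`
per call; identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .energetics import COMPONENT_COLUMNS, EnergyFrameTable
from .funnel import ScoredRecord
from .trajectory import Trajectory

import pandas as pd


class ConfigurationError(ValueError):
    pass


# ------------------------------------------------------------- molecules

@dataclass(frozen=True)
class MoleculeRecord:
    mol_id: str
    smiles: str


DEFAULT_RING_SYSTEMS = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1cc[nH]n1",          # pyrazole
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2c(c1)cc[nH]2",  # indole
    "c1ccc2c(c1)cccn2",    # quinoline
    "C1CCNCC1",            # piperidine
    "C1COCCN1",            # morpholine
    "c1ccc(-c2ccncc2)cc1", # phenylpyridine biaryl
)

DEFAULT_SUBSTITUENTS = (
    "[*]C", "[*]CC", "[*]C(C)C", "[*]O", "[*]OC", "[*]N", "[*]NC",
    "[*]F", "[*]Cl", "[*]Br", "[*]C#N", "[*]C(F)(F)F",
    "[*]C(=O)N", "[*]C(=O)OC", "[*]S(=O)(=O)C", "[*]CCO",
    "[*]c1ccccc1", "[*]C(=O)c1ccccc1", "[*]N1CCOCC1", "[*]CN1CCCC1",
)


@dataclass(frozen=True)
class MoleculeLibrarySpec:
    """Attachment-grammar molecule library: ring cores decorated with up to
    ``max_substituents`` substituents at ring positions, aiming for molecular
    weights inside ``target_mw_range`` (best effort, never at the cost of
    validity)."""

    n_molecules: int = 100
    seed: int = 0
    ring_systems: tuple[str, ...] = DEFAULT_RING_SYSTEMS
    substituent_alphabet: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    max_substituents: int = 4
    target_mw_range: tuple[float, float] = (150.0, 550.0)

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if not self.ring_systems or not self.substituent_alphabet:
            raise ConfigurationError("ring_systems and substituent_alphabet must be non-empty")


def _attach_substituent(mol: Chem.Mol, sub_smiles: str, position: int) -> Chem.Mol | None:
    """Bond a [*]-carrying substituent to atom ``position`` of ``mol``."""
    sub = Chem.MolFromSmiles(sub_smiles)
    if sub is None:
        return None
    dummies = [a.GetIdx() for a in sub.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        return None
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    dummy = mol.GetNumAtoms() + dummies[0]
    nbr = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combo.AddBond(position, nbr, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy)
    try:
        product = combo.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return product


def _open_ring_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.IsInRing() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]


def gen_molecule_library(spec: MoleculeLibrarySpec) -> list[MoleculeRecord]:
    """Generate ``spec.n_molecules`` valid, ring-containing molecules.

    Deterministic for a fixed spec (seed included); every SMILES parses and
    contains at least one ring by construction.
    """
    for s in spec.ring_systems:
        if Chem.MolFromSmiles(s) is None:
            raise ConfigurationError(f"invalid ring system {s!r}")
    rng = np.random.default_rng(spec.seed)
    low, high = spec.target_mw_range
    records: list[MoleculeRecord] = []
    for i in range(spec.n_molecules):
        core = spec.ring_systems[rng.integers(len(spec.ring_systems))]
        mol = Chem.MolFromSmiles(core)
        n_sub = int(rng.integers(0, spec.max_substituents + 1))
        for _ in range(n_sub):
            mw = Descriptors.MolWt(mol)
            if mw >= high - 100:
                break
            positions = _open_ring_positions(mol)
            if not positions:
                break
            pos = positions[rng.integers(len(positions))]
            sub = spec.substituent_alphabet[rng.integers(len(spec.substituent_alphabet))]
            grown = _attach_substituent(mol, sub, int(pos))
            if grown is not None:
                mol = grown
        # below the target range: keep decorating deterministically
        extra = 0
        while Descriptors.MolWt(mol) < low and extra < 8:
            positions = _open_ring_positions(mol)
            if not positions:
                break
            pos = positions[rng.integers(len(positions))]
            sub = spec.substituent_alphabet[rng.integers(len(spec.substituent_alphabet))]
            grown = _attach_substituent(mol, sub, int(pos))
            if grown is not None:
                mol = grown
            extra += 1
        records.append(MoleculeRecord(f"SYN{i:05d}", Chem.MolToSmiles(mol)))
    return records


def write_smi(records, path) -> None:
    """One `SMILES<TAB>id` per line."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.mol_id}\n")


def read_smi(path) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"MOL{i:05d}"
            records.append(MoleculeRecord(mol_id, smiles))
    return records


# ---------------------------------------------------------- scored tables

def _injective(rng: np.random.Generator, base: np.ndarray, jitter: float) -> np.ndarray:
    """Base plus noise, redrawing duplicates until strictly distinct."""
    values = base + rng.normal(0.0, jitter, base.size)
    while True:
        _, first = np.unique(values, return_index=True)
        if first.size == values.size:
            return values
        dup = np.setdiff1d(np.arange(values.size), first)
        values[dup] = base[dup] + rng.normal(0.0, jitter, dup.size)


def gen_scored_table(n: int, seed: int = 0) -> list[ScoredRecord]:
    """``n`` candidates with strictly distinct scores per docking tier.

    Tier scores share a latent 'true quality' so the funnel behaves like a
    real screen (stages agree but not perfectly); the affinity column tracks
    the same latent on the MM-GBSA scale (~−40..−70 kcal/mol).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    quality = rng.normal(-9.0, 1.2, n)
    table = {
        "htvs": _injective(rng, quality, 0.6),
        "sp": _injective(rng, quality, 0.4),
        "xp": _injective(rng, quality, 0.3),
    }
    affinity = _injective(rng, 6.0 * quality, 3.0)
    return [
        ScoredRecord(
            id=f"C{i:05d}",
            scores={stage: float(col[i]) for stage, col in table.items()},
            affinity=float(affinity[i]),
        )
        for i in range(n)
    ]


# ------------------------------------------------------------ trajectories

@dataclass(frozen=True)
class CorrelatedBlock:
    """Two residue ranges [start, stop) sharing a latent displacement that
    yields pairwise displacement correlation ``rho``."""

    block_a: tuple[int, int]
    block_b: tuple[int, int]
    rho: float

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must be in [-1, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    n_residues: int = 50
    atoms_per_residue: int = 1
    n_frames: int = 1000
    frame_interval: float = 2.0  # ps
    sigma_profile: tuple[float, ...] | float = 1.0  # Å
    correlated_blocks: tuple[CorrelatedBlock, ...] = ()
    seed: int = 0

    def sigmas(self) -> np.ndarray:
        if np.isscalar(self.sigma_profile):
            return np.full(self.n_residues, float(self.sigma_profile))
        sig = np.asarray(self.sigma_profile, float)
        if sig.size != self.n_residues:
            raise ConfigurationError("sigma_profile length must equal n_residues")
        return sig


_ATOM_NAMES = ("CA", "N", "C", "O", "CB", "CG")
_ATOM_MASSES = {"CA": 12.011, "N": 14.007, "C": 12.011, "O": 15.999, "CB": 12.011, "CG": 12.011}


def reference_structure(spec: TrajectorySpec) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Extended-chain reference: residues 3.8 Å apart along x, extra atoms
    offset in y.  Returns (coords, residue map, atom names, masses)."""
    coords, residues, names = [], [], []
    for r in range(spec.n_residues):
        for a in range(spec.atoms_per_residue):
            name = _ATOM_NAMES[a % len(_ATOM_NAMES)]
            coords.append([3.8 * r, 1.3 * a, 0.0])
            residues.append(r)
            names.append(name)
    masses = np.array([_ATOM_MASSES[n] for n in names])
    return np.array(coords, float), np.array(residues, int), names, masses


def gen_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Reference coordinates plus zero-mean Gaussian displacement with
    per-coordinate SD ``sigma_profile[r]`` for residue r.

    Atoms in a correlated block pair mix a shared per-frame latent vector
    with their private noise so that displacement correlation between (and
    within) the paired blocks equals ρ, while per-atom variance stays σ_r².
    """
    ref, residues, names, masses = reference_structure(spec)
    rng = np.random.default_rng(spec.seed)
    n_atoms = ref.shape[0]
    eps = rng.standard_normal((spec.n_frames, n_atoms, 3))
    disp = eps.copy()
    for block in spec.correlated_blocks:
        in_a = (residues >= block.block_a[0]) & (residues < block.block_a[1])
        in_b = (residues >= block.block_b[0]) & (residues < block.block_b[1])
        rho = block.rho
        z = rng.standard_normal((spec.n_frames, 1, 3))
        root, rem = np.sqrt(abs(rho)), np.sqrt(1.0 - abs(rho))
        disp[:, in_a, :] = root * z + rem * eps[:, in_a, :]
        sign = 1.0 if rho >= 0 else -1.0
        disp[:, in_b, :] = sign * root * z + rem * eps[:, in_b, :]
    sigma_atom = spec.sigmas()[residues]
    coords = ref[None, :, :] + disp * sigma_atom[None, :, None]
    times = spec.frame_interval * np.arange(spec.n_frames, dtype=float)
    return Trajectory(coords, masses, residues, names, frame_times=times)


# ------------------------------------------------------------ energy frames

#: Component means/SDs emulating a converged end-point run on a tight binder
#: (the M1 system of the reference table).
DEFAULT_ENERGY_MEANS = {
    "e_pbcom": -3316.136, "e_pbpro": -3322.892, "e_pblig": -24.415,
    "e_sacom": 143.705, "e_sapro": 145.861, "e_salig": 5.155,
    "e_cou": -10.494, "e_vdw": -46.0,
}
DEFAULT_ENERGY_SDS = {
    "e_pbcom": 102.502, "e_pbpro": 103.359, "e_pblig": 0.605,
    "e_sacom": 1.253, "e_sapro": 1.33, "e_salig": 0.099,
    "e_cou": 1.214, "e_vdw": 1.013,
}


@dataclass(frozen=True)
class EnergyFrameSpec:
    n_frames: int = 5000
    means: dict = field(default_factory=lambda: dict(DEFAULT_ENERGY_MEANS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_ENERGY_SDS))
    minus_tds: float = 1.9161  # kcal/mol
    interval_ps: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        for c in COMPONENT_COLUMNS:
            if c not in self.means or c not in self.sds:
                raise ConfigurationError(f"missing mean/sd for component {c}")
            if self.sds[c] < 0:
                raise ConfigurationError("SDs must be >= 0")


def gen_energy_frames(spec: EnergyFrameSpec) -> EnergyFrameTable:
    """Independent Gaussian draws per component and frame; sample means
    converge to the spec means by the CLT."""
    rng = np.random.default_rng(spec.seed)
    data = {"time_ps": spec.interval_ps * np.arange(1, spec.n_frames + 1)}
    for c in COMPONENT_COLUMNS:
        data[c] = rng.normal(spec.means[c], spec.sds[c], spec.n_frames)
    return EnergyFrameTable(pd.DataFrame(data))
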