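"""Per-molecule and per-library property profiling: physicochemical
descriptors, QED drug-likeness, synthetic-accessibility (SA) score, extended
rule-of-five flags, chiral-center and Bemis–Murcko scaffold statistics, PCA
chemical-space projection and rank-based distribution comparison.

The SA scorer (fragment contributions + complexity penalty, 1 = easy to
10 = hard) is loaded from the RDKit distribution's contributed implementation
so that no network fetch is involved.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

_sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
if _sa_dir not in sys.path:
    sys.path.append(_sa_dir)
import sascorer  # noqa: E402


@dataclass(frozen=True)
class PropertyProfile:
    """Physicochemical profile of one molecule."""

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rotbonds: int
    chiral_centers: int
    qed: float
    sa_score: float


def _mol(smiles_or_mol) -> Chem.Mol:
    if isinstance(smiles_or_mol, Chem.Mol):
        return smiles_or_mol
    mol = Chem.MolFromSmiles(smiles_or_mol)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles_or_mol!r}")
    return mol


def profile(smiles_or_mol) -> PropertyProfile:
    """Full property profile; QED is the desirability-function aggregate in
    [0, 1], SA the fragment-contribution score in [1, 10].  Chiral-center
    counting includes unassigned potential stereocenters."""
    mol = _mol(smiles_or_mol)
    return PropertyProfile(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        rotbonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        chiral_centers=len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)),
        qed=QED.qed(mol),
        sa_score=sascorer.calculateScore(mol),
    )


@dataclass(frozen=True)
class ERo5Flags:
    """Extended rule-of-five: MW ≤ 500, HBD ≤ 5, HBA ≤ 10, LogP ≤ 5,
    PSA ≤ 200 Å²; boundary values pass."""

    mw_ok: bool
    hbd_ok: bool
    hba_ok: bool
    logp_ok: bool
    psa_ok: bool

    @property
    def overall(self) -> bool:
        return self.mw_ok and self.hbd_ok and self.hba_ok and self.logp_ok and self.psa_ok


def ero5_flags(p: PropertyProfile) -> ERo5Flags:
    return ERo5Flags(
        mw_ok=p.mw <= 500,
        hbd_ok=p.hbd <= 5,
        hba_ok=p.hba <= 10,
        logp_ok=p.logp <= 5,
        psa_ok=p.tpsa <= 200,
    )


def murcko_scaffold(smiles_or_mol) -> str:
    """Bemis–Murcko scaffold (rings + linkers, side chains removed) as
    canonical SMILES; acyclic molecules give the empty string."""
    mol = _mol(smiles_or_mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def count_unique_scaffolds(library) -> int:
    """Distinct Bemis–Murcko scaffolds in a library of SMILES / records;
    all acyclic molecules count once (the empty scaffold)."""
    scaffolds = set()
    for entry in library:
        smiles = getattr(entry, "smiles", entry)
        scaffolds.add(murcko_scaffold(smiles))
    return len(scaffolds)


def profile_table(library) -> pd.DataFrame:
    """Per-molecule profiles as a DataFrame (index: molecule id if present)."""
    rows = []
    for i, entry in enumerate(library):
        smiles = getattr(entry, "smiles", entry)
        mol_id = getattr(entry, "mol_id", f"MOL{i:05d}")
        p = profile(smiles)
        rows.append({"id": mol_id, "smiles": smiles, **p.__dict__})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ chemical space

@dataclass
class ChemSpaceProjection:
    """Low-dimensional chemical-space coordinates per molecule with the
    explained-variance ratios of the retained principal components."""

    coordinates: pd.DataFrame  # columns PC1..PCk plus 'library'
    explained_variance_ratio: np.ndarray
    descriptor_names: list[str]
    dropped_descriptors: list[str]


def descriptor_matrix(smiles_list) -> pd.DataFrame:
    """The toolkit's full 2D descriptor catalogue (~200 descriptors) per
    molecule."""
    rows = []
    for s in smiles_list:
        mol = _mol(s)
        rows.append({name: fn(mol) for name, fn in Descriptors.descList})
    return pd.DataFrame(rows)


def pca_chemspace(libraries: dict, n_components: int = 2) -> ChemSpaceProjection:
    """Project labelled libraries into a shared PCA chemical space.

    Descriptors are computed on the pooled set, z-score standardized;
    constant or non-finite descriptors are dropped (recorded in the result).
    Principal axes come from the pooled molecules, so identical libraries get
    identical point clouds.
    """
    labels, smiles = [], []
    for name, lib in libraries.items():
        for entry in lib:
            labels.append(name)
            smiles.append(getattr(entry, "smiles", entry))
    if len(smiles) < 2:
        raise ValueError("need at least 2 molecules")
    if len(smiles) < n_components:
        raise ValueError("fewer molecules than requested components")
    desc = descriptor_matrix(smiles)
    finite = desc.replace([np.inf, -np.inf], np.nan)
    keep = finite.columns[(finite.notna().all()) & (finite.nunique() > 1)]
    dropped = [c for c in desc.columns if c not in set(keep)]
    X = StandardScaler().fit_transform(finite[keep].to_numpy(float))
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(X)
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(n_components)])
    df["library"] = labels
    return ChemSpaceProjection(df, pca.explained_variance_ratio_, list(keep), dropped)


# ------------------------------------------------------ distribution tests

@dataclass(frozen=True)
class DistributionComparison:
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def compare_property_distributions(a, b) -> DistributionComparison:
    """Two-sided Mann–Whitney U test between two samples of a property
    (e.g. docking scores of two generated libraries).  Identical constant
    samples give p = 1 by convention."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return DistributionComparison(a.size * b.size / 2.0, 1.0, float(np.median(a)), float(np.median(b)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return DistributionComparison(float(res.statistic), float(res.pvalue), float(np.median(a)), float(np.median(b)))


def plot_property_distributions(libraries: dict, prop: str, path, bins: int = 40) -> None:
    """Overlayed histogram of one profile property (e.g. 'qed', 'sa_score')
    across labelled libraries, written to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, lib in libraries.items():
        values = [getattr(profile(getattr(e, "smiles", e)), prop) for e in lib]
        ax.hist(values, bins=bins, alpha=0.5, label=name, density=True)
    ax.set_xlabel(prop)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_chemspace(projection: ChemSpaceProjection, path) -> None:
    """2D or 3D scatter of a PCA chemical-space projection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = projection.coordinates
    three_d = "PC3" in coords.columns
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    for name, group in coords.groupby("library"):
        if three_d:
            ax.scatter(group["PC1"], group["PC2"], group["PC3"], s=8, alpha=0.6, label=name)
        else:
            ax.scatter(group["PC1"], group["PC2"], s=8, alpha=0.6, label=name)
    ax.set_xlabel(f"PC1 ({projection.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({projection.explained_variance_ratio[1]:.0%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def density_mode(values, grid_points: int = 512) -> float:
    """Location of the highest point of a Gaussian-kernel density estimate
    (Silverman bandwidth) — the 'distribution peak' summary reported for
    SA/QED histograms.  Descriptive only."""
    values = np.asarray(values, float)
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])
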