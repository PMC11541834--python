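"""Trajectory analytics: superposition RMSD, per-residue RMSF, radius of
gyration, hydrogen-bond counts, Shrake–Rupley SASA, dynamic cross-correlation
maps and RMSD–Rg free-energy landscapes.

Coordinates are stored in Å internally; Rg is reported in nm and SASA in nm²
(the conventions of MD practice).  Superposition uses the Kabsch algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import R_KCAL, DEFAULT_TEMPERATURE


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with residue mapping.

    ``atom_residues`` maps each atom to a residue index; ``atom_names`` are
    PDB-style names used for the backbone/Cα selections; masses are amu.
    """

    coords: np.ndarray  # (F, A, 3) Å
    masses: np.ndarray  # (A,)
    atom_residues: np.ndarray  # (A,) int
    atom_names: list[str] = field(default_factory=list)
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        self.masses = np.asarray(self.masses, float)
        self.atom_residues = np.asarray(self.atom_residues, int)
        if self.masses.shape[0] != self.coords.shape[1]:
            raise ValueError("masses length must equal atom count")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.atom_residues.shape[0] != self.coords.shape[1]:
            raise ValueError("atom_residues length must equal atom count")
        if not self.atom_names:
            self.atom_names = ["CA"] * self.coords.shape[1]
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.atom_residues.max()) + 1 if self.n_atoms else 0

    def selection(self, which: str = "all") -> np.ndarray:
        """Boolean atom mask: 'all', 'backbone' (N/CA/C/O) or 'calpha'."""
        names = np.array(self.atom_names)
        if which == "all":
            return np.ones(self.n_atoms, bool)
        if which == "backbone":
            return np.isin(names, ("N", "CA", "C", "O"))
        if which == "calpha":
            return names == "CA"
        raise ValueError(f"unknown selection {which!r}")


# ---------------------------------------------------------------- PDB I/O

def write_pdb(traj: Trajectory, path) -> None:
    """Write frames as MODEL/ENDMDL blocks of ATOM records (element C/N by
    atom name; residues named GLY for simplicity)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                name = traj.atom_names[a]
                element = name[0]
                fh.write(
                    f"ATOM  {a + 1:5d} {name:^4s}GLY A{traj.atom_residues[a] + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


_MASS_BY_ELEMENT = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def read_pdb(path) -> Trajectory:
    """Read a multi-model PDB written by :func:`write_pdb` (or compatible)."""
    frames: list[list[list[float]]] = []
    names: list[str] = []
    residues: list[int] = []
    elements: list[str] = []
    current: list[list[float]] | None = None
    first = True
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                if current is not None:
                    frames.append(current)
                    first = False
                current = None
            elif line.startswith(("ATOM", "HETATM")):
                if current is None:  # single-model file without MODEL records
                    current = []
                x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
                current.append([x, y, z])
                if first:
                    names.append(line[12:16].strip())
                    residues.append(int(line[22:26]) - 1)
                    elements.append((line[76:78].strip() or line[12:16].strip()[0]).upper())
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no coordinates found in {path}")
    masses = np.array([_MASS_BY_ELEMENT.get(e[0], 12.011) for e in elements])
    return Trajectory(np.array(frames, float), masses, np.array(residues), names)


# ------------------------------------------------------------ superposition

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ‖(mobile·R + t) − reference‖²."""
    mc, rc = mobile.mean(0), reference.mean(0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, rc - mc @ R


def superpose(traj: Trajectory, reference: np.ndarray, selection: np.ndarray) -> np.ndarray:
    """Least-squares fit every frame onto ``reference`` using the selected
    atoms; returns transformed coordinates for all atoms."""
    out = np.empty_like(traj.coords)
    ref_sel = reference[selection]
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f][selection], ref_sel)
        out[f] = traj.coords[f] @ R + t
    return out


def superpose_rmsd(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: str | np.ndarray = "backbone",
) -> np.ndarray:
    """Per-frame RMSD (Å) over the selection after Kabsch superposition.

    ``reference`` defaults to the first frame; it must match the trajectory's
    atom count.
    """
    sel = traj.selection(selection) if isinstance(selection, str) else np.asarray(selection, bool)
    if not sel.any():
        raise ValueError("empty selection")
    if reference is None:
        reference = traj.coords[0]
    reference = np.asarray(reference, float)
    if reference.shape != traj.coords.shape[1:]:
        raise ValueError("reference atom count does not match trajectory")
    fitted = superpose(traj, reference, sel)
    diff = fitted[:, sel, :] - reference[sel]
    return np.sqrt((diff ** 2).sum(-1).mean(-1))


def rmsf(
    traj: Trajectory,
    selection: str | np.ndarray = "calpha",
    fit: bool = True,
) -> np.ndarray:
    """Per-residue RMSF (Å): after superposing each frame onto the mean
    structure, RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩), averaged over each residue's
    selected atoms."""
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames")
    sel = traj.selection(selection) if isinstance(selection, str) else np.asarray(selection, bool)
    coords = traj.coords
    if fit:
        mean = coords.mean(0)
        coords = superpose(traj, mean, sel)
        mean = coords.mean(0)
    else:
        mean = coords.mean(0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(-1).mean(0))
    residues = np.unique(traj.atom_residues[sel])
    return np.array([
        per_atom[sel & (traj.atom_residues == r)].mean() for r in residues
    ])


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Per-frame mass-weighted radius of gyration in nm."""
    m = traj.masses / traj.masses.sum()
    com = np.einsum("a,fax->fx", m, traj.coords)
    d2 = ((traj.coords - com[:, None, :]) ** 2).sum(-1)
    return np.sqrt(np.einsum("a,fa->f", m, d2)) * 0.1  # Å -> nm


# --------------------------------------------------------------- H-bonds

def hbond_count(
    traj: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> np.ndarray:
    """Per-frame hydrogen-bond counts.

    ``donors`` are (donor-heavy-atom, attached-hydrogen) index pairs;
    ``acceptors`` are heavy-atom indices.  A bond is counted when the
    donor–acceptor distance is ≤ ``distance_cutoff`` Å and the
    hydrogen–donor–acceptor angle is ≤ ``angle_cutoff`` degrees.
    """
    for d, h in donors:
        if not (0 <= h < traj.n_atoms):
            raise ValueError(f"donor {d} has no attached hydrogen index {h}")
    counts = np.zeros(traj.n_frames, int)
    cos_max = 1.0
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        n = 0
        for d, h in donors:
            for a in acceptors:
                if a == d:
                    continue
                da = xyz[a] - xyz[d]
                dist = np.linalg.norm(da)
                if dist > distance_cutoff or dist == 0:
                    continue
                dh = xyz[h] - xyz[d]
                nh = np.linalg.norm(dh)
                if nh == 0:
                    continue
                cosang = np.clip(np.dot(dh, da) / (nh * dist), -1.0, cos_max)
                if np.degrees(np.arccos(cosang)) <= angle_cutoff:
                    n += 1
        counts[f] = n
    return counts


# ----------------------------------------------------------------- SASA

def _sphere_points(n: int) -> np.ndarray:
    """Approximately uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def sasa(
    traj: Trajectory,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-frame Shrake–Rupley solvent-accessible surface area in nm².

    ``radii`` are per-atom van der Waals radii (Å); each atom's expanded
    sphere (radius + probe) is sampled with ``n_points`` test points and the
    exposed fraction converted to area.
    """
    radii = np.asarray(radii, float)
    if radii.shape[0] != traj.n_atoms:
        raise ValueError("radii length must equal atom count")
    if np.any(~np.isfinite(radii)):
        raise ValueError("missing (non-finite) radius")
    sphere = _sphere_points(n_points)
    expanded = radii + probe
    out = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        total = 0.0
        for i in range(traj.n_atoms):
            pts = xyz[i] + expanded[i] * sphere
            accessible = np.ones(n_points, bool)
            for j in range(traj.n_atoms):
                if j == i:
                    continue
                d2 = ((pts - xyz[j]) ** 2).sum(1)
                r2 = expanded[j] ** 2
                buried = d2 < r2 - 1e-9
                if j < i:
                    # boundary tie-break: a point exactly on a neighbouring
                    # sphere belongs to the lower-index atom
                    buried |= np.abs(d2 - r2) <= 1e-9
                accessible &= ~buried
            total += 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
        out[f] = total * 0.01  # Å² -> nm²
    return out


# ----------------------------------------------------------------- DCCM

@dataclass
class CorrelationMatrix:
    """Normalized covariance of Cα displacements; entries in [−1, 1] with a
    unit diagonal.  ``mask`` flags atoms with zero variance (undefined rows)."""

    values: np.ndarray
    mask: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dccm(traj: Trajectory, selection: str | np.ndarray = "calpha", fit: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation map over the selected atoms:
    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), Δr the deviation from the
    time mean after superposition."""
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames")
    sel = traj.selection(selection) if isinstance(selection, str) else np.asarray(selection, bool)
    coords = superpose(traj, traj.coords.mean(0), sel) if fit else traj.coords
    x = coords[:, sel, :]
    dx = x - x.mean(0)
    cov = np.einsum("fix,fjx->ij", dx, dx) / traj.n_frames
    var = np.diag(cov).copy()
    immobile = var <= 0
    var[immobile] = 1.0
    denom = np.sqrt(np.outer(var, var))
    values = cov / denom
    values[immobile, :] = np.nan
    values[:, immobile] = np.nan
    np.fill_diagonal(values, 1.0)
    for i in np.where(immobile)[0]:
        values[i, i] = np.nan
    return CorrelationMatrix(values, immobile)


# ------------------------------------------------------------------ FEL

@dataclass
class FreeEnergySurface:
    """2D free-energy surface over (RMSD Å, Rg nm); empty bins are NaN and
    the most-populated bin sits at exactly G = 0 kcal/mol."""

    G: np.ndarray
    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    counts: np.ndarray


def plot_fel(surface: "FreeEnergySurface", path) -> None:
    """Filled-contour rendering of a free-energy surface to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = 0.5 * (surface.rmsd_edges[:-1] + surface.rmsd_edges[1:])
    y = 0.5 * (surface.rg_edges[:-1] + surface.rg_edges[1:])
    mesh = ax.pcolormesh(x, y, surface.G.T, shading="auto", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="G (kcal/mol)")
    ax.set_xlabel("RMSD (Å)")
    ax.set_ylabel("Rg (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fel(
    rmsd_series: np.ndarray,
    rg_series: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bins: int | tuple[int, int] = 50,
) -> FreeEnergySurface:
    """Free-energy landscape G(bin) = −RT·ln(N_bin/N_max) from joint
    populations of the two collective coordinates."""
    rmsd_series = np.asarray(rmsd_series, float)
    rg_series = np.asarray(rg_series, float)
    if rmsd_series.size == 0 or rmsd_series.shape != rg_series.shape:
        raise ValueError("series must be equal-length and non-empty")
    counts, xe, ye = np.histogram2d(rmsd_series, rg_series, bins=bins)
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        G = -R_KCAL * temperature * np.log(counts / nmax)
    G[counts == 0] = np.nan
    return FreeEnergySurface(G, xe, ye, counts)
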