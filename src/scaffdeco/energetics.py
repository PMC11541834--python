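"""MM-PBSA end-point binding free energy aggregation.

Works on per-frame energy-component tables (kcal/mol) with columns

``e_pbcom, e_pbpro, e_pblig`` — polar-solvation energy of complex/protein/ligand
``e_sacom, e_sapro, e_salig`` — nonpolar (surface-area) solvation terms
``e_cou, e_vdw``              — gas-phase Coulomb and van der Waals interaction

and applies the end-point identities

    ΔE_MM  = ΔE_COU + ΔE_VDW
    ΔE_PB  = ΔE_PBcom − (ΔE_PBpro + ΔE_PBlig)
    ΔE_SA  = ΔE_SAcom − (ΔE_SApro + ΔE_SAlig)
    ΔH     = ΔE_MM + ΔE_PB + ΔE_SA
    ΔG_bind = ΔH + (−TΔS)

with the entropy term −TΔS supplied per system (an interaction-entropy
estimator from the fluctuations of ΔE_MM is available but off by default).
The inhibition constant follows from ΔG_bind = RT·ln Ki with
R = 1.9872041e−3 kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K; Ki is reported
in nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_KCAL = 1.9872041e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K

COMPONENT_COLUMNS = (
    "e_pbcom", "e_pbpro", "e_pblig",
    "e_sacom", "e_sapro", "e_salig",
    "e_cou", "e_vdw",
)


class EnergyTableError(ValueError):
    pass


@dataclass
class EnergyFrameTable:
    """Per-frame energy components with frame times in ps."""

    frames: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COMPONENT_COLUMNS if c not in self.frames.columns]
        if missing:
            raise EnergyTableError(f"missing component columns: {missing}")
        values = self.frames[list(COMPONENT_COLUMNS)].to_numpy(float)
        if not np.all(np.isfinite(values)):
            raise EnergyTableError("non-finite energy values")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_csv(cls, path) -> "EnergyFrameTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)


@dataclass
class BindingEnergySummary:
    """Component means ± SD plus the derived end-point quantities."""

    component_means: dict[str, float]
    component_sds: dict[str, float]
    de_mm: float
    de_pb: float
    de_sa: float
    dh: float
    minus_tds: float
    dg_bind: float
    ki_nm: float
    temperature: float = DEFAULT_TEMPERATURE
    n_frames: int = 0

    def as_series(self) -> pd.Series:
        out = {}
        for name in COMPONENT_COLUMNS:
            out[name] = self.component_means[name]
            out[name + "_sd"] = self.component_sds[name]
        out.update(
            de_mm=self.de_mm, de_pb=self.de_pb, de_sa=self.de_sa, dh=self.dh,
            minus_tds=self.minus_tds, dg_bind=self.dg_bind, ki_nm=self.ki_nm,
            temperature=self.temperature, n_frames=self.n_frames,
        )
        return pd.Series(out)


def derived_from_means(means: dict[str, float], minus_tds: float) -> dict[str, float]:
    """Apply the end-point identities to component means."""
    de_mm = means["e_cou"] + means["e_vdw"]
    de_pb = means["e_pbcom"] - (means["e_pbpro"] + means["e_pblig"])
    de_sa = means["e_sacom"] - (means["e_sapro"] + means["e_salig"])
    dh = de_mm + de_pb + de_sa
    dg = dh + minus_tds
    return {"de_mm": de_mm, "de_pb": de_pb, "de_sa": de_sa, "dh": dh, "dg_bind": dg}


def ki_from_dg(dg_kcal_mol: float, temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """Inhibition constant in nM from a binding free energy in kcal/mol."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return 1e9 * math.exp(dg_kcal_mol / (R_KCAL * temperature_K))


def dg_from_ki(ki_nm: float, temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy in kcal/mol from an inhibition constant in nM."""
    if ki_nm <= 0:
        raise ValueError("Ki must be positive")
    return R_KCAL * temperature_K * math.log(ki_nm * 1e-9)


def ki_consistent(
    dg_kcal_mol: float,
    reported_ki_nm: float,
    temperature_K: float = DEFAULT_TEMPERATURE,
    rtol: float = 5e-3,
) -> bool:
    """Whether a reported Ki agrees with ΔG_bind under Ki = exp(ΔG/RT)
    to about three significant figures.  Useful for flagging transcription
    errors in published tables."""
    implied = ki_from_dg(dg_kcal_mol, temperature_K)
    return abs(implied - reported_ki_nm) <= rtol * reported_ki_nm


def interaction_entropy(frames: EnergyFrameTable, temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """−TΔS estimate from the fluctuation of the gas-phase interaction energy:
    −TΔS = RT·ln⟨exp(ΔE_MM − ⟨ΔE_MM⟩)/RT⟩ (interaction-entropy formula)."""
    e_mm = (frames.frames["e_cou"] + frames.frames["e_vdw"]).to_numpy(float)
    beta = 1.0 / (R_KCAL * temperature_K)
    dev = e_mm - e_mm.mean()
    # log-sum-exp for numerical stability
    m = (beta * dev).max()
    return (m + np.log(np.mean(np.exp(beta * dev - m)))) / beta


def aggregate(
    frames: EnergyFrameTable,
    minus_tds: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BindingEnergySummary:
    """Summarize a per-frame component table into a binding-energy row.

    Means and sample SDs (n−1) per component; derived quantities via the
    end-point identities applied to the means; Ki from ΔG_bind.
    Requires at least two frames for the SDs.
    """
    if len(frames) < 2:
        raise EnergyTableError("need >= 2 frames for standard deviations")
    data = frames.frames
    means = {c: float(data[c].mean()) for c in COMPONENT_COLUMNS}
    sds = {c: float(data[c].std(ddof=1)) for c in COMPONENT_COLUMNS}
    d = derived_from_means(means, minus_tds)
    return BindingEnergySummary(
        component_means=means,
        component_sds=sds,
        de_mm=d["de_mm"], de_pb=d["de_pb"], de_sa=d["de_sa"], dh=d["dh"],
        minus_tds=minus_tds, dg_bind=d["dg_bind"],
        ki_nm=ki_from_dg(d["dg_bind"], temperature),
        temperature=temperature, n_frames=len(frames),
    )


def select_snapshots(total_ns: float, window_ns: float, interval_ps: float) -> np.ndarray:
    """Frame times (ps) for end-point analysis: the last ``window_ns`` of a
    ``total_ns`` trajectory sampled every ``interval_ps``.

    Times lie in (total−window, total]; the count is window·1000/interval.
    The interval must divide the window exactly.
    """
    if window_ns > total_ns:
        raise ValueError("window longer than trajectory")
    if interval_ps <= 0:
        raise ValueError("interval must be positive")
    window_ps = window_ns * 1000.0
    n = window_ps / interval_ps
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"interval {interval_ps} ps does not divide window {window_ns} ns")
    n = int(round(n))
    if n < 2:
        raise ValueError("snapshot selection must yield at least 2 frames")
    end_ps = total_ns * 1000.0
    return end_ps - window_ps + interval_ps * np.arange(1, n + 1)


@dataclass
class ResidueEnergyTable:
    """Per-residue decomposition: Coulomb, polar solvation, nonpolar
    solvation and van der Waals contributions (kcal/mol)."""

    table: pd.DataFrame  # columns: residue, e_cou, e_pb, e_sa, e_vdw

    COMPONENTS = ("e_cou", "e_pb", "e_sa", "e_vdw")

    def __post_init__(self):
        missing = [c for c in ("residue",) + self.COMPONENTS if c not in self.table.columns]
        if missing:
            raise EnergyTableError(f"missing residue-table columns: {missing}")


@dataclass
class KeyResidue:
    residue: str
    total: float
    dominant: str
    components: dict[str, float] = field(default_factory=dict)


def key_residues(table: ResidueEnergyTable, threshold: float = 1.0) -> list[KeyResidue]:
    """Residues whose total interaction energy exceeds ``threshold`` in
    magnitude, sorted by |total| descending, each labelled with the
    largest-magnitude component."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: list[KeyResidue] = []
    for _, row in table.table.iterrows():
        comps = {c: float(row[c]) for c in ResidueEnergyTable.COMPONENTS}
        total = sum(comps.values())
        if abs(total) > threshold:
            dominant = max(comps, key=lambda c: abs(comps[c]))
            out.append(KeyResidue(str(row["residue"]), total, dominant, comps))
    out.sort(key=lambda r: abs(r.total), reverse=True)
    return out


def summary_table(summaries: dict[str, BindingEnergySummary]) -> pd.DataFrame:
    """Assemble per-system summaries into a publication-shaped table
    (systems as columns, energy terms as rows)."""
    return pd.DataFrame({name: s.as_series() for name, s in summaries.items()})
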