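"""Published benchmark tables for the mIDH1 inhibitor candidate set.

Two small tables accompany the pipeline as reference inputs:

* ``TOP10_DOCKING`` — molecular weight, Glide SP/XP docking scores and Prime
  MM-GBSA affinities (kcal/mol) for the reference inhibitor IDH305 and the ten
  screened candidates M1..M10.
* ``MMPBSA_COMPONENTS`` — per-system MM-PBSA component means and standard
  deviations (kcal/mol) plus the entropy term −TΔS and the reported inhibition
  constant Ki (nM) for IDH305 and the six simulated candidates M1..M6.

These are inputs to the aggregation and funnel algebra, not outputs of this
package; the derived quantities (ΔE_MM, ΔE_PB, ΔE_SA, ΔH, ΔG_bind, Ki) are
recomputed from the components by :mod:`scaffdeco.energetics`.
"""

from __future__ import annotations

import pandas as pd

# id -> (MW, SP score, XP score, MM-GBSA affinity), all energies kcal/mol
TOP10_DOCKING: dict[str, tuple[float, float, float, float]] = {
    "IDH305": (490.459, -10.658, -11.097, -55.65),
    "M1": (406.483, -11.659, -13.931, -70.93),
    "M2": (417.909, -11.412, -12.295, -69.02),
    "M3": (429.477, -11.163, -12.167, -66.21),
    "M4": (413.493, -11.117, -11.691, -64.19),
    "M5": (401.424, -10.939, -11.375, -58.72),
    "M6": (400.821, -10.736, -11.314, -57.95),
    "M7": (401.461, -10.586, -10.929, -54.49),
    "M8": (415.488, -10.533, -10.844, -53.34),
    "M9": (324.397, -10.370, -10.838, -52.76),
    "M10": (274.091, -10.025, -10.438, -50.51),
}

# Component rows: mean and SD per system.  Sign conventions follow the
# MM-PBSA end-point scheme: E_PB* are polar-solvation energies of complex /
# protein / ligand, E_SA* the nonpolar (surface-area) terms, E_COU / E_VDW the
# gas-phase Coulomb and van der Waals interaction energies.
_MMPBSA_ROWS = {
    #            IDH305            M1               M2               M3                M4               M5               M6
    "dg_bind": [(-19.817, 3.874), (-30.718, 1.672), (-28.241, 1.373), (-22.717, 2.962), (-22.399, 2.491), (-22.369, 2.96), (-21.86, 1.448)],
    "dh":      [(-21.204, 3.874), (-32.634, 1.672), (-30.997, 1.373), (-24.732, 2.962), (-25.469, 2.491), (-24.843, 2.96), (-25.465, 1.448)],
    "ki_nm":   [(2.98e-06, None), (3.045e-14, None), (1.99e-12, None), (2.23e-08, None), (3.81e-11, None), (4.01e-08, None), (9.48e-08, None)],
    "minus_tds": [(1.387, None), (1.9161, None), (2.755, None), (2.015, None), (3.070, None), (2.474, None), (3.605, None)],
    "e_vdw":   [(-43.768, 2.855), (-46.0, 1.013), (-42.583, 2.178), (-44.93, 1.54), (-37.799, 2.253), (-44.847, 3.383), (-46.047, 1.624)],
    "e_cou":   [(-18.055, 2.552), (-10.494, 1.214), (-11.782, 2.206), (-6.52, 0.87), (-5.923, 1.461), (-3.264, 2.379), (-7.005, 1.084)],
    "de_mm":   [(-61.823, 1.626), (-56.494, 1.794), (-54.365, 2.619), (-51.45, 2.346), (-43.722, 2.805), (-48.111, 3.625), (-53.052, 2.569)],
    "de_pb":   [(47.133, 2.976), (31.171, 1.493), (29.766, 2.084), (33.681, 1.623), (24.357, 2.328), (29.808, 2.179), (34.64, 2.002)],
    "de_sa":   [(-6.514, 0.198), (-7.311, 0.141), (-6.398, 0.167), (-6.963, 0.144), (-6.104, 0.426), (-6.54, 0.071), (-7.052, 0.192)],
    "e_pbcom": [(-3135.426, 43.007), (-3316.136, 102.502), (-3310.787, 80.483), (-3253.908, 117.952), (-3274.957, 88.882), (-3426.912, 31.894), (-3348.73, 82.995)],
    "e_pbpro": [(-3145.018, 43.997), (-3322.892, 103.359), (-3307.11, 80.62), (-3251.864, 117.302), (-3268.931, 89.265), (-3433.222, 31.742), (-3350.214, 80.941)],
    "e_pblig": [(-37.541, 1.023), (-24.415, 0.605), (-33.444, 0.94), (-35.725, 1.483), (-30.383, 1.392), (-23.498, 1.603), (-33.156, 1.514)],
    "e_sacom": [(144.111, 1.624), (143.705, 1.253), (147.166, 1.21), (146.995, 1.322), (145.804, 2.951), (148.143, 1.47), (145.449, 1.09)],
    "e_sapro": [(146.028, 1.636), (145.861, 1.33), (148.884, 1.142), (149.159, 1.345), (147.234, 2.684), (150.291, 1.395), (147.689, 1.031)],
    "e_salig": [(4.597, 0.054), (5.155, 0.099), (4.68, 0.085), (4.798, 0.075), (4.674, 0.091), (4.391, 0.064), (4.812, 0.1)],
}

MMPBSA_SYSTEMS = ["IDH305", "M1", "M2", "M3", "M4", "M5", "M6"]


def mmpbsa_components() -> pd.DataFrame:
    """Reference MM-PBSA table as a tidy frame: one row per (system, term).

    Columns: ``system``, ``term``, ``mean``, ``sd`` (sd is NaN where the
    source table prints none, e.g. Ki and −TΔS).
    """
    rows = []
    for term, values in _MMPBSA_ROWS.items():
        for system, (mean, sd) in zip(MMPBSA_SYSTEMS, values):
            rows.append({"system": system, "term": term, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def mmpbsa_means() -> pd.DataFrame:
    """Reference component means pivoted to one row per system."""
    df = mmpbsa_components().pivot(index="system", columns="term", values="mean")
    return df.loc[MMPBSA_SYSTEMS]


def top10_docking() -> pd.DataFrame:
    """The screened top-10 candidate table (plus the IDH305 reference row)."""
    df = pd.DataFrame.from_dict(
        TOP10_DOCKING, orient="index", columns=["mw", "score_sp", "score_xp", "mmgbsa"]
    )
    df.index.name = "id"
    return df.reset_index()
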