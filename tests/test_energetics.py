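import numpy as np
import pandas as pd
import pytest

from scaffdeco.energetics import (
    COMPONENT_COLUMNS,
    EnergyFrameTable,
    EnergyTableError,
    ResidueEnergyTable,
    aggregate,
    derived_from_means,
    dg_from_ki,
    interaction_entropy,
    key_residues,
    ki_consistent,
    ki_from_dg,
    select_snapshots,
)
from scaffdeco.reference_data import MMPBSA_SYSTEMS, mmpbsa_means
from scaffdeco.synthetic import EnergyFrameSpec, gen_energy_frames

DERIVED = ("de_mm", "de_pb", "de_sa", "dh", "dg_bind")


class TestEndpointIdentities:
    @pytest.mark.parametrize("system", MMPBSA_SYSTEMS)
    def test_reference_table_closure(self, system):
        """Applying the identities to printed component means reproduces the
        printed derived rows to printed precision (±0.002 for rounding)."""
        row = mmpbsa_means().loc[system]
        means = {c: row[c] for c in COMPONENT_COLUMNS}
        derived = derived_from_means(means, row["minus_tds"])
        for key in DERIVED:
            assert derived[key] == pytest.approx(row[key], abs=2e-3)

    def test_m1_worked_example(self):
        means = {
            "e_cou": -10.494, "e_vdw": -46.0,
            "e_pbcom": -3316.136, "e_pbpro": -3322.892, "e_pblig": -24.415,
            "e_sacom": 143.705, "e_sapro": 145.861, "e_salig": 5.155,
        }
        d = derived_from_means(means, 1.9161)
        assert d["de_mm"] == pytest.approx(-56.494, abs=1e-3)
        assert d["de_pb"] == pytest.approx(31.171, abs=1e-3)
        assert d["de_sa"] == pytest.approx(-7.311, abs=1e-3)
        assert d["dh"] == pytest.approx(-32.634, abs=1e-3)
        assert d["dg_bind"] == pytest.approx(-30.718, abs=1e-3)


class TestKiConversion:
    @pytest.mark.parametrize(
        "dg, expected",
        [(-30.718, 3.045e-14), (-19.817, 2.98e-06)],
    )
    def test_printed_values_to_three_significant_figures(self, dg, expected):
        ki = ki_from_dg(dg)
        assert ki == pytest.approx(expected, rel=5e-3)

    def test_zero_dg_is_one_molar(self):
        assert ki_from_dg(0.0) == pytest.approx(1e9)

    def test_round_trip(self):
        for dg in (-30.0, -5.5, 0.0, 3.2):
            assert dg_from_ki(ki_from_dg(dg)) == pytest.approx(dg, rel=1e-9, abs=1e-12)

    def test_reference_table_consistency_flags(self):
        """Every system's printed Ki follows from its ΔG_bind at 298.15 K —
        except M4, whose printed Ki is off by three orders of magnitude."""
        means = mmpbsa_means()
        for system in MMPBSA_SYSTEMS:
            row = means.loc[system]
            consistent = ki_consistent(row["dg_bind"], row["ki_nm"])
            assert consistent == (system != "M4")

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ki_from_dg(-10.0, temperature_K=0.0)


class TestAggregate:
    def _table(self, means, n=100, sds=None, seed=0):
        spec = EnergyFrameSpec(
            n_frames=n, means=means,
            sds=sds or {c: 0.0 for c in COMPONENT_COLUMNS}, seed=seed)
        return gen_energy_frames(spec)

    def test_zero_components_give_zero_dg_and_molar_ki(self):
        table = self._table({c: 0.0 for c in COMPONENT_COLUMNS})
        s = aggregate(table, minus_tds=0.0)
        assert s.dg_bind == 0.0
        assert s.ki_nm == pytest.approx(1e9)

    def test_stochastic_frames_recover_reference_dg(self):
        from scaffdeco.synthetic import DEFAULT_ENERGY_MEANS, DEFAULT_ENERGY_SDS

        table = gen_energy_frames(EnergyFrameSpec(n_frames=5000, seed=3))
        s = aggregate(table, minus_tds=1.9161)
        # SE of dG: dominated by the PB terms
        var = sum((DEFAULT_ENERGY_SDS[c] ** 2) / 5000 for c in COMPONENT_COLUMNS)
        assert abs(s.dg_bind - (-30.718)) < 3 * np.sqrt(var)

    def test_linearity_under_scaling(self):
        means = {c: float(v) for c, v in zip(COMPONENT_COLUMNS, range(1, 9))}
        t1 = self._table(means)
        t2 = EnergyFrameTable(t1.frames.assign(**{c: 2 * t1.frames[c] for c in COMPONENT_COLUMNS}))
        s1 = aggregate(t1, 0.0)
        s2 = aggregate(t2, 0.0)
        for attr in DERIVED[:4]:
            assert getattr(s2, attr) == pytest.approx(2 * getattr(s1, attr))

    def test_single_frame_rejected(self):
        frame = pd.DataFrame({c: [1.0] for c in COMPONENT_COLUMNS})
        with pytest.raises(EnergyTableError):
            aggregate(EnergyFrameTable(frame), 0.0)

    def test_sample_sd_uses_n_minus_one(self):
        data = pd.DataFrame({c: [0.0, 2.0] for c in COMPONENT_COLUMNS})
        s = aggregate(EnergyFrameTable(data), 0.0)
        assert s.component_sds["e_cou"] == pytest.approx(np.sqrt(2.0))

    def test_interaction_entropy_zero_for_constant_frames(self):
        table = self._table({c: -5.0 for c in COMPONENT_COLUMNS})
        assert interaction_entropy(table) == pytest.approx(0.0, abs=1e-9)


class TestSnapshotSelection:
    def test_production_window(self):
        times = select_snapshots(400, 10, 2)
        assert len(times) == 5000
        assert times[0] == pytest.approx(390002.0)
        assert times[-1] == pytest.approx(400000.0)

    def test_whole_trajectory_window(self):
        times = select_snapshots(10, 10, 2)
        assert len(times) == 5000
        assert times[0] == pytest.approx(2.0) and times[0] > 0

    def test_non_dividing_interval_rejected(self):
        with pytest.raises(ValueError):
            select_snapshots(400, 10, 10000)

    def test_window_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError):
            select_snapshots(5, 10, 2)


class TestKeyResidues:
    def _table(self, rows):
        return ResidueEnergyTable(pd.DataFrame(rows, columns=["residue", "e_cou", "e_pb", "e_sa", "e_vdw"]))

    def test_vdw_dominant_residue_selected(self):
        table = self._table([("ALA111", 0.0, 0.0, 0.0, -2.0)])
        [res] = key_residues(table, 1.0)
        assert res.residue == "ALA111" and res.dominant == "e_vdw"

    def test_subthreshold_residues_excluded(self):
        table = self._table([(f"R{i}", 0.5, 0.0, 0.0, 0.0) for i in range(10)])
        assert key_residues(table, 1.0) == []

    def test_planted_hotspots_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        hotspots = {17, 40, 111, 120, 128, 278, 285}
        for i in range(300):
            if i in hotspots:
                vdw = -2.5 - rng.uniform(0, 1)
            else:
                vdw = rng.uniform(-0.2, 0.2)
            rows.append((f"R{i}", rng.uniform(-0.05, 0.05), 0.0, 0.0, vdw))
        found = {r.residue for r in key_residues(self._table(rows), 1.0)}
        assert found == {f"R{i}" for i in hotspots}

    def test_sorted_by_magnitude(self):
        table = self._table([("A", 0, 0, 0, -2.0), ("B", 0, 0, 0, -4.0), ("C", 3.0, 0, 0, 0)])
        assert [r.residue for r in key_residues(table, 1.0)] == ["B", "C", "A"]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            key_residues(self._table([("A", 0, 0, 0, -2.0)]), 0.0)
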