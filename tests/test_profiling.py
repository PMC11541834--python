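import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from scaffdeco.profiling import (
    ChemSpaceProjection,
    compare_property_distributions,
    count_unique_scaffolds,
    density_mode,
    ero5_flags,
    murcko_scaffold,
    pca_chemspace,
    profile,
    profile_table,
)
from scaffdeco.profiling import PropertyProfile
from scaffdeco.synthetic import MoleculeLibrarySpec, gen_molecule_library


class TestProfile:
    def test_benzene_has_no_donors_acceptors_or_stereocenters(self):
        p = profile("c1ccccc1")
        assert (p.hbd, p.hba, p.chiral_centers) == (0, 0, 0)

    def test_ethanol_donor_acceptor_counts(self):
        p = profile("CCO")
        assert (p.hbd, p.hba) == (1, 1)

    def test_unassigned_stereocenter_counted(self):
        assert profile("CC(N)O").chiral_centers == 1

    def test_qed_and_sa_ranges_on_500_synthetic_molecules(self):
        lib = gen_molecule_library(MoleculeLibrarySpec(n_molecules=500, seed=21))
        for rec in lib:
            p = profile(rec.smiles)
            assert 0.0 <= p.qed <= 1.0
            assert 1.0 <= p.sa_score <= 10.0

    def test_invariant_to_smiles_representation(self, molecule_library):
        for rec in molecule_library:
            mol = Chem.MolFromSmiles(rec.smiles)
            scrambled = Chem.MolToSmiles(mol, doRandom=True, canonical=False)
            a, b = profile(scrambled), profile(rec.smiles)
            for name in a.__dataclass_fields__:
                assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9), name

    def test_parse_failure_raises(self):
        with pytest.raises(ValueError):
            profile("xx((")


class TestERo5:
    def _profile(self, **kw):
        base = dict(mw=300.0, logp=2.0, hbd=1, hba=3, tpsa=60.0,
                    rotbonds=3, chiral_centers=0, qed=0.7, sa_score=2.5)
        base.update(kw)
        return PropertyProfile(**base)

    @pytest.mark.parametrize("field, boundary", [
        ("mw", 500.0), ("hbd", 5), ("hba", 10), ("logp", 5.0), ("tpsa", 200.0)])
    def test_boundary_values_pass(self, field, boundary):
        assert ero5_flags(self._profile(**{field: boundary})).overall

    def test_just_over_mw_boundary_fails(self):
        flags = ero5_flags(self._profile(mw=500.1))
        assert not flags.mw_ok and not flags.overall

    def test_benzene_passes_overall(self):
        assert ero5_flags(profile("c1ccccc1")).overall


class TestMurcko:
    def test_toluene_reduces_to_benzene(self):
        assert murcko_scaffold("Cc1ccccc1") == Chem.CanonSmiles("c1ccccc1")

    def test_biphenyl_is_its_own_scaffold(self):
        smiles = "c1ccc(-c2ccccc2)cc1"
        assert murcko_scaffold(smiles) == Chem.CanonSmiles(smiles)

    def test_side_chain_homologs_collapse_to_one_scaffold(self):
        assert count_unique_scaffolds(["Cc1ccccc1", "CCc1ccccc1", "c1ccccc1"]) == 1

    def test_acyclic_molecules_count_once(self):
        assert count_unique_scaffolds(["CCO", "CCC", "CCN"]) == 1

    def test_count_bounded_by_library_size_and_order_invariant(self, molecule_library):
        smiles = [r.smiles for r in molecule_library]
        n = count_unique_scaffolds(smiles)
        assert n <= len(smiles)
        assert n == count_unique_scaffolds(list(reversed(smiles)))


class TestChemSpace:
    def test_duplicated_library_gives_identical_point_clouds(self, molecule_library):
        lib = [r.smiles for r in molecule_library[:20]]
        proj = pca_chemspace({"a": lib, "b": lib}, n_components=2)
        a = proj.coordinates[proj.coordinates.library == "a"][["PC1", "PC2"]].to_numpy()
        b = proj.coordinates[proj.coordinates.library == "b"][["PC1", "PC2"]].to_numpy()
        assert np.allclose(a, b)

    def test_explained_variance_properties(self, molecule_library):
        proj = pca_chemspace({"lib": [r.smiles for r in molecule_library[:30]]}, n_components=3)
        evr = proj.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9
        assert np.isfinite(proj.coordinates[["PC1", "PC2", "PC3"]].to_numpy()).all()

    def test_rank_two_descriptor_matrix_fully_captured_in_two_components(self):
        """PCA of an exactly rank-2 standardized matrix explains 100% of
        variance with 2 components (checked on the numeric path the chemical
        descriptors feed)."""
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(0)
        u = rng.normal(size=(60, 2))
        v = rng.normal(size=(2, 25))
        X = StandardScaler().fit_transform(u @ v)
        evr = PCA(n_components=2).fit(X).explained_variance_ratio_
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            pca_chemspace({"a": ["CCO"]}, n_components=2)


class TestDistributionComparison:
    def test_identical_samples_give_high_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        res = compare_property_distributions(a, a)
        assert res.p_value > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)
        res = compare_property_distributions(a, b)
        assert res.p_value < 1e-10

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        assert compare_property_distributions(a, b).p_value == pytest.approx(
            compare_property_distributions(b, a).p_value)

    def test_constant_identical_samples_p_one(self):
        res = compare_property_distributions([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_property_distributions([1.0], [2.0, 3.0])


class TestDescriptiveSummaries:
    def test_density_mode_finds_dominant_peak(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(2.9, 0.15, 2000), rng.normal(6.0, 0.3, 300)])
        assert density_mode(values) == pytest.approx(2.9, abs=0.15)

    def test_profile_table_shape(self, molecule_library):
        df = profile_table(molecule_library[:10])
        assert len(df) == 10
        assert {"mw", "qed", "sa_score", "chiral_centers"} <= set(df.columns)

    def test_plot_helpers_write_image_files(self, tmp_path, molecule_library):
        from scaffdeco.profiling import plot_chemspace, plot_property_distributions
        from scaffdeco.trajectory import fel, plot_fel

        lib = [r.smiles for r in molecule_library[:10]]
        plot_property_distributions({"lib": lib}, "qed", tmp_path / "qed.png")
        plot_chemspace(pca_chemspace({"lib": lib}, 2), tmp_path / "pca.png")
        rng = np.random.default_rng(0)
        plot_fel(fel(rng.normal(2, 0.3, 300), rng.normal(1.8, 0.05, 300)), tmp_path / "fel.png")
        for name in ("qed.png", "pca.png", "fel.png"):
            assert (tmp_path / name).stat().st_size > 0
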