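import pytest

from scaffdeco.decorator import DecoratorConfig, ScaffoldDecorator
from scaffdeco.fragmentation import build_pair_library
from scaffdeco.synthetic import MoleculeLibrarySpec, gen_molecule_library


@pytest.fixture(scope="session")
def molecule_library():
    """100 synthetic drug-like molecules (fixed seed)."""
    return gen_molecule_library(MoleculeLibrarySpec(n_molecules=100, seed=11))


@pytest.fixture(scope="session")
def toy_pairs():
    """20 scaffold-decoration pairs with distinct scaffolds — a separable
    corpus a small model can memorize."""
    lib = gen_molecule_library(MoleculeLibrarySpec(n_molecules=12, seed=5))
    pair_lib = build_pair_library(lib, split_seed=0)
    seen, toy = set(), []
    for p in pair_lib.pairs:
        if p.scaffold_smiles not in seen:
            seen.add(p.scaffold_smiles)
            toy.append(p)
        if len(toy) == 20:
            break
    assert len(toy) == 20
    return toy


@pytest.fixture(scope="session")
def trained_toy_model(toy_pairs):
    """Desk-scale decorator trained to memorization on the toy corpus.

    Trained once per session; several tests (and the acceptance checks)
    read from it.
    """
    model = ScaffoldDecorator(toy_pairs, DecoratorConfig(epochs=300, seed=0))
    log = model.fit()
    return model, log
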