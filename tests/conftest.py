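import warnings

import numpy as np
import pytest

from resmutscan import fixtures, respred
from resmutscan.structmut import load_complex


@pytest.fixture(scope="session")
def sig_bundle(tmp_path_factory):
    return fixtures.make_toy_signature_catalog(
        4, seed=101, out_dir=tmp_path_factory.mktemp("sig"))


@pytest.fixture(scope="session")
def complex_bundle(tmp_path_factory):
    return fixtures.make_toy_complex(
        12, 5, seed=202, out_dir=tmp_path_factory.mktemp("cx"))


@pytest.fixture(scope="session")
def toy_complex(complex_bundle):
    return load_complex(complex_bundle.complex_pdb, "LIG")


@pytest.fixture(scope="session")
def small_training_set(tmp_path_factory):
    """12-per-class planted table with strong signal, features extracted."""
    bundle = fixtures.make_toy_training_table(
        12, signal_strength=1.0, seed=303,
        out_dir=tmp_path_factory.mktemp("train"), n_decoys=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return respred.build_training_set(
            bundle.training_table, schema="aa-v1", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_toy_complex(rng, n_res=6, n_lig=4):
    """Random self-avoiding-ish complex for brute-force geometry oracles."""
    from resmutscan._aa_data import AA1
    from resmutscan.fixtures import build_toy_chain
    from resmutscan.structmut import Atom, ComplexModel, Residue

    seq = "".join(rng.choice(list(AA1.replace("P", "")))
                  for _ in range(n_res))
    residues = build_toy_chain(seq)
    center = residues[n_res // 2].atom("CA").pos
    atoms = [
        Atom(f"C{i+1}", "C", center + rng.uniform(-12, 12, size=3))
        for i in range(n_lig)
    ]
    return ComplexModel(residues, Residue("A", 900, "LIG", atoms, het=True))
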