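from __future__ import annotations

import pytest

from qmmmprep import FixtureSpec, assign_charges, make_polypeptide_complex
from qmmmprep.fixtures import build_fixture_model


@pytest.fixture(scope="session")
def std_spec() -> FixtureSpec:
    """Canonical 5-residue capped complex: ligand 4 A from residue 3."""
    return FixtureSpec(n_residues=5, ligand_distance=4.0, seed=11)


@pytest.fixture()
def std_model(std_spec):
    """Freshly built (mutable) model + charge table for the canonical spec."""
    return build_fixture_model(std_spec)


@pytest.fixture()
def charged_model(std_model):
    model, charges = std_model
    assign_charges(model, overrides=charges)
    return model


@pytest.fixture(scope="session")
def std_files(std_spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    return make_polypeptide_complex(std_spec, d / "complex.pdb",
                                    d / "complex.charges")


def build_charged(spec: FixtureSpec):
    model, charges = build_fixture_model(spec)
    assign_charges(model, overrides=charges)
    return model
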