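"""Shared fixtures: small seeded ensembles and constructed frames.

Everything is generated programmatically; session scope keeps the more
expensive ensembles to one construction per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from preorg import synthetic as syn
from preorg.model import Ensemble, Frame


@pytest.fixture(scope="session")
def solute():
    return syn.solute_template()


@pytest.fixture(scope="session")
def bulk_small() -> Ensemble:
    """40 frames x 20 pairs = 800 bulk dimers, 30% coplanar."""
    spec = syn.EnsembleSpec(n_frames=40, n_solutes=40, coplanar_fraction_bulk=0.3, seed=42)
    return syn.make_bulk_ensemble(spec)


@pytest.fixture(scope="session")
def templated_small() -> Ensemble:
    """60-frame templated ensemble, large modifier, strong templating."""
    spec = syn.EnsembleSpec(n_frames=60, n_solutes=12, templating_strength=5.0, seed=42)
    return syn.make_templated_ensemble(spec, syn.modifier_template(3))


@pytest.fixture(scope="session")
def lattice() -> Frame:
    return syn.make_crystal_lattice((2, 2, 2))


def place_solute(rotation: np.ndarray, translation, molecule_id: int):
    return syn.solute_template().instantiate(
        np.asarray(rotation, dtype=float), np.asarray(translation, dtype=float), molecule_id
    )


@pytest.fixture
def make_solute():
    return place_solute
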