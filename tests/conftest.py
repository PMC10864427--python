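"""Shared fixtures: a small planted cohort and an AtomArray builder."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from neoprior import synthetic

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort of 5 planted passers plus one decoy per criterion (seed 42)."""
    proteome = synthetic.simulate_proteome(40, seed=42)
    return synthetic.simulate_cohort(
        proteome, n_pass=5, n_fail_per_criterion=1, seed=42
    )


def build_frame(records):
    """AtomArray from (chain_id, res_id, atom_name, element, x, y, z) rows."""
    from biotite.structure import AtomArray

    atoms = AtomArray(len(records))
    atoms.coord = np.array([r[4:7] for r in records], dtype=float)
    atoms.chain_id = np.array([r[0] for r in records])
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array(["ALA"] * len(records))
    atoms.atom_name = np.array([r[2] for r in records])
    atoms.element = np.array([r[3] for r in records])
    return atoms
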