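"""Shared fixtures: synthetic curves, filaments and fibril files.

All fixtures are generated programmatically and deterministically; nothing is
downloaded.
"""

from __future__ import annotations

import numpy as np
import pytest

from tautopo.curves import FilamentModel, PolygonalCurve, annotate_repeats
from tautopo.synthetic import (default_fold_curve, make_synthetic_fibril,
                               random_open_curve, sidechain_turns_rule)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240330)


@pytest.fixture()
def random_curve_pair():
    c1 = random_open_curve(15, seed=101)
    c2 = random_open_curve(15, seed=202).transformed(shift=[0.4, 0.3, 0.2])
    return c1, c2


@pytest.fixture()
def tau_like_filament():
    """An annotated filament spanning residues 272..342 (R1 tail through R3)
    with a random but reproducible 3-D fold."""
    curve = random_open_curve(71, seed=7, scale=3.8)
    f = FilamentModel(backbone=curve,
                      residue_numbers=np.arange(272, 343),
                      accession="synthetic", chain_id="A")
    return annotate_repeats(f)


@pytest.fixture(scope="session")
def fibril_pdb(tmp_path_factory):
    """Three-rung twisted fibril with 3 right-handed side-chain turns."""
    path = tmp_path_factory.mktemp("fibril") / "fibril3.pdb"
    make_synthetic_fibril(path, n_rungs=3, twist_deg=-1.0,
                          fold_curve=default_fold_curve(71),
                          sidechain_rule=sidechain_turns_rule(3),
                          first_residue=1, seed=0)
    return path


@pytest.fixture(scope="session")
def flat_stack_pdb(tmp_path_factory):
    """Two untwisted, purely translated planar rungs."""
    path = tmp_path_factory.mktemp("flat") / "flat2.pdb"
    make_synthetic_fibril(path, n_rungs=2, twist_deg=0.0, seed=0)
    return path
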