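"""Shared fixtures: toy structures and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from pocketec.annotation import default_scheme
from pocketec.descriptor import BindingSite
from pocketec.structure_io import Atom, Structure


def _ca_atom(resname: str, seq: int, x: float, y: float = 0.0, z: float = 0.0,
             chain: str = "A") -> Atom:
    return Atom(
        atom_name="CA", element="C", residue_name=resname, residue_seq=seq,
        insertion_code="", chain_id=chain, coord=np.array([x, y, z], dtype=float),
    )


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def toy_t5():
    """Five Cα-only residues on a line at x = 0, 3.8, ..., 15.2 Å."""
    atoms = [
        _ca_atom(name, i + 1, 3.8 * i)
        for i, name in enumerate(["GLY", "ALA", "SER", "LEU", "PHE"])
    ]
    s = Structure(atoms=atoms, source_id="T5")
    site = BindingSite(center=np.zeros(3), source="experimental")
    return s, site


@pytest.fixture(scope="session")
def small_dataset():
    from pocketec.synthetic import make_dataset

    return make_dataset(n_per_class=6, seed=0)


@pytest.fixture(scope="session")
def small_graphs(small_dataset, scheme):
    from pocketec.graph_build import build_pocket_graph

    return [
        build_pocket_graph(s, site, scheme, cut_mode="count", cut_param=12, label=cls)
        for s, site, cls in small_dataset.items
    ]
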