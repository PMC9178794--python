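"""Shared fixtures and small trajectory builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerkit.core import (
    AtomRecord,
    Frame,
    ResidueClass,
    Topology,
    Trajectory,
    UnitCell,
)


def point_topology(n: int, name: str = "OW", resname: str = "SOL",
                   mass: float = 15.999,
                   rclass: ResidueClass = ResidueClass.SOLVENT) -> Topology:
    """Topology of n identical single-atom residues."""
    return Topology([
        AtomRecord(i + 1, name, resname, i + 1, mass, residue_class=rclass)
        for i in range(n)
    ])


def point_trajectory(coords_per_frame, cell: UnitCell, dt: float = 1.0,
                     topology: Topology | None = None) -> Trajectory:
    """Trajectory over ad-hoc coordinate arrays (frames, atoms, 3)."""
    coords_per_frame = [np.atleast_2d(c) for c in coords_per_frame]
    topo = topology or point_topology(coords_per_frame[0].shape[0])
    frames = [Frame(time=i * dt, coordinates=c, cell=cell)
              for i, c in enumerate(coords_per_frame)]
    return Trajectory(topo, frames)


@pytest.fixture
def cell() -> UnitCell:
    return UnitCell(6.72, 6.72, 9.0)


@pytest.fixture
def flat_bilayer():
    """Noise-free flat bilayer: exact P-to-P of 3.1 nm, no pore."""
    from bilayerkit.synthetic import BilayerSpec, generate

    spec = BilayerSpec(seed=7)
    return spec, generate(spec)
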