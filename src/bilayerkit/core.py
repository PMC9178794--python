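"""Domain types for membrane structures and trajectories.

Internal unit conventions, used everywhere in this package:

* lengths in nanometres (PDB angstroms are converted at the file boundary),
* times in picoseconds,
* masses in atomic mass units.

Atom and residue indices are 1-based at the file interface (GRO/PDB
convention) and 0-based in every in-memory array.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ResidueClass",
    "AtomRecord",
    "Topology",
    "UnitCell",
    "Frame",
    "Trajectory",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_coordinates",
]


class ResidueClass(str, enum.Enum):
    """Coarse chemical classification of an atom's parent residue."""

    CATIONIC = "cationic"
    ANIONIC = "anionic"
    POLAR = "polar"
    HYDROPHOBIC = "hydrophobic"
    SOLVENT = "solvent"
    LIPID = "lipid"
    OTHER = "other"


# mass lookup (amu) for element guessing from atom names
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
}


def guess_mass(atom_name: str) -> float:
    """Guess an atomic mass (amu) from an atom name, GROMACS-style.

    Two-letter ion names (NA, CL, MG, K) are matched first, then the first
    alphabetic character is taken as the element symbol.  Unrecognised names
    fall back to carbon.
    """
    name = atom_name.strip().upper()
    if name in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[name]
    for ch in name:
        if ch.isalpha():
            return _ELEMENT_MASSES.get(ch, 12.011)
    return 12.011


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``atom_index`` is 1-based, matching the numbering written to GRO/PDB
    files.  ``residue_class`` carries the coarse chemical role used by the
    interaction analyses (e.g. selecting all cationic side chains).
    """

    atom_index: int
    atom_name: str
    residue_name: str
    residue_index: int
    mass: float
    protomer_id: str | None = None
    residue_class: ResidueClass = ResidueClass.OTHER

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_index}: mass must be > 0, got {self.mass}")


class Topology:
    """Ordered collection of :class:`AtomRecord` plus named selection groups."""

    def __init__(self, atoms: Sequence[AtomRecord], groups: dict[str, Sequence[int]] | None = None):
        self.atoms = list(atoms)
        seen: set[int] = set()
        for a in self.atoms:
            if a.atom_index in seen:
                raise ValueError(f"duplicate atom_index {a.atom_index} in topology")
            seen.add(a.atom_index)
        self.groups: dict[str, np.ndarray] = {}
        for name, idx in (groups or {}).items():
            self.set_group(name, idx)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def set_group(self, name: str, indices: Iterable[int]) -> None:
        """Register a named selection group of 0-based atom indices."""
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=np.intp)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise IndexError(f"group {name!r} references atoms outside the topology")
        self.groups[name] = idx

    # cached per-atom arrays ------------------------------------------------
    def _cache(self, key: str, build) -> np.ndarray:
        store = self.__dict__.setdefault("_arrays", {})
        if key not in store:
            store[key] = build()
        return store[key]

    @property
    def masses(self) -> np.ndarray:
        return self._cache("masses", lambda: np.array([a.mass for a in self.atoms]))

    @property
    def names(self) -> np.ndarray:
        return self._cache("names", lambda: np.array([a.atom_name for a in self.atoms]))

    @property
    def residue_names(self) -> np.ndarray:
        return self._cache("resnames", lambda: np.array([a.residue_name for a in self.atoms]))

    @property
    def residue_indices(self) -> np.ndarray:
        return self._cache("resids", lambda: np.array([a.residue_index for a in self.atoms]))

    @property
    def protomer_ids(self) -> np.ndarray:
        return self._cache(
            "segids", lambda: np.array([a.protomer_id or "" for a in self.atoms])
        )

    @property
    def residue_classes(self) -> np.ndarray:
        return self._cache(
            "classes", lambda: np.array([a.residue_class.value for a in self.atoms])
        )


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic simulation cell with edges in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError(f"cell edges must be > 0, got {(self.lx, self.ly, self.lz)}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def lateral_area(self) -> float:
        """Projected xy area, nm^2."""
        return self.lx * self.ly

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz


@dataclass
class Frame:
    """Per-frame coordinates (N x 3, nm) with a time stamp (ps) and a cell."""

    time: float
    coordinates: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if self.time < 0:
            raise ValueError(f"frame time must be non-negative, got {self.time}")


class Trajectory:
    """A topology plus an ordered sequence of frames with increasing times."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        self.topology = topology
        self.frames = list(frames)
        n = len(topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i}: {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Displacement a - b mapped into the minimum-image convention.

    Broadcasts over leading dimensions; the last axis must be xyz.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    box = cell.lengths
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, cell: UnitCell) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention (orthorhombic)."""
    d = minimum_image_displacement(a, b, cell)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coordinates(coords: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, L) along each axis.

    Wrapping is never applied implicitly by the readers; analyses that need
    wrapped coordinates (the water census) call this explicitly, while
    displacement-based analyses (MSD) require the unwrapped originals.
    """
    box = cell.lengths
    return np.mod(coords, box)
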