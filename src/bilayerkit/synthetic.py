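"""Synthetic bilayer trajectories with known ground truth.

The generator builds minimal pseudo-molecules rather than full lipids: each
lipid is a phosphorus atom, two carbonyl/glycerol oxygen acceptors and two
tail beads; water is a single oxygen site (optional hydrogens for H-bond
geometry tests). That is exactly the atom inventory the analyses touch —
P atoms for surface fitting and thickness, tails for contacts, O acceptors
for H-bonds, water oxygens for the census — at a tiny fraction of the cost
of a real membrane. No energetics or dynamics are implied; every frame is
an independent draw around the configured geometry.

Leaflet phosphorus heights follow

    z(x, y) = z0 +/- p2p_mean / 2 + A sin(2 pi n_x x / Lx) sin(2 pi n_y y / Ly)
              [- dimple(x, y) on the upper leaflet] + Gaussian noise,

so surface fitting, thickness and order maps all have analytic truth. An
optional cylindrical trans-bilayer water pore carries an exactly known
number of molecules inside the bilayer-center census slab, and a per-frame
lateral dilation schedule emulates the area widening produced by an applied
surface tension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AtomRecord,
    Frame,
    ResidueClass,
    Topology,
    Trajectory,
    UnitCell,
)

__all__ = [
    "DimpleSpec",
    "PoreSpec",
    "PeptideSpec",
    "BilayerSpec",
    "generate",
    "apply_dilation",
    "WATER_MOLAR_MASS",
    "AVOGADRO",
    "bulk_water_number_density",
]

WATER_MOLAR_MASS = 18.015  # g/mol
AVOGADRO = 6.02214076e23  # 1/mol


def bulk_water_number_density(rho_g_cm3: float = 1.0) -> float:
    """Number density of water molecules (nm^-3) at mass density rho."""
    return rho_g_cm3 / WATER_MOLAR_MASS * AVOGADRO * 1e-21


@dataclass(frozen=True)
class DimpleSpec:
    """Local Gaussian depression pressed into the upper leaflet.

    Emulates the footprint of a bound peptide: the upper phosphorus surface
    is lowered by ``depth * exp(-r^2 / (2 radius^2))`` around ``center``.
    """

    center: tuple[float, float]
    depth: float
    radius: float


@dataclass(frozen=True)
class PoreSpec:
    """Cylindrical trans-bilayer water column.

    ``occupancy_in_center_slab`` fixes the exact number of water molecules
    placed with z inside the 0.5 nm census slab about the bilayer midplane;
    it may be a single integer or one integer per frame (a census schedule).
    When None, the occupancy is derived from ``fill_density`` and the slab
    cylinder volume, i.e. the pore is filled at bulk water density.
    """

    diameter: float
    axis: tuple[float, float] | None = None
    occupancy_in_center_slab: int | Sequence[int] | None = None
    fill_density: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"pore diameter must be > 0, got {self.diameter}")
        occ = self.occupancy_in_center_slab
        if occ is not None:
            vals = [occ] if np.isscalar(occ) else list(occ)
            if any(int(v) < 0 for v in vals):
                raise ValueError("pore occupancy must be >= 0")

    def occupancy_for_frame(self, frame_index: int, slab_height: float) -> int:
        occ = self.occupancy_in_center_slab
        if occ is None:
            volume = np.pi * (self.diameter / 2.0) ** 2 * slab_height  # nm^3
            return int(round(volume * bulk_water_number_density(self.fill_density)))
        if np.isscalar(occ):
            return int(occ)
        return int(list(occ)[frame_index])


@dataclass(frozen=True)
class PeptideSpec:
    """A bound pseudo-peptide: rings of labelled residue beads per protomer."""

    n_protomers: int = 2
    residues: Sequence[tuple[str, ResidueClass]] = (
        ("LYS", ResidueClass.CATIONIC),
        ("TRP", ResidueClass.HYDROPHOBIC),
        ("GLU", ResidueClass.ANIONIC),
        ("SER", ResidueClass.POLAR),
        ("LEU", ResidueClass.HYDROPHOBIC),
        ("ARG", ResidueClass.CATIONIC),
    )
    placement: str = "surface_bound"  # solution | surface_bound | inserted
    com_depth: float = 0.0  # nm below the upper P surface (surface_bound)

    def __post_init__(self) -> None:
        if self.placement not in ("solution", "surface_bound", "inserted"):
            raise ValueError(f"unknown peptide placement {self.placement!r}")
        if self.n_protomers < 1:
            raise ValueError("n_protomers must be >= 1")


@dataclass(frozen=True)
class BilayerSpec:
    """Full recipe for one synthetic trajectory.

    Defaults describe the reference system of the analyses: a 128-lipid
    (64 per leaflet) anionic bilayer in a 6.72 x 6.72 nm cell (0.7056 nm^2
    per lipid), mean P-to-P separation 3.1 nm, bounded by bulk water slabs
    at 1 g/cm^3.
    """

    cell: UnitCell = UnitCell(6.72, 6.72, 9.0)
    lipids_per_leaflet: int = 64
    p2p_mean: float = 3.1
    undulation_amplitude: float = 0.0
    undulation_wavelengths: tuple[int, int] = (1, 1)
    dimple: DimpleSpec | None = None
    positional_noise_sd: float = 0.0
    water_slab_thickness: float = 1.5
    bulk_water_density: float = 1.0  # g/cm^3
    midplane_z: float | None = None
    slab_height: float = 0.5  # census slab height about the midplane, nm
    pore: PoreSpec | None = None
    peptide: PeptideSpec | None = None
    dilation_schedule: Sequence[float] | None = None
    conserve_volume: bool = True
    water_hydrogens: bool = False
    n_frames: int = 1
    dt: float = 100.0  # ps between frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p2p_mean <= 0:
            raise ValueError("p2p_mean must be > 0")
        if self.undulation_amplitude < 0 or self.positional_noise_sd < 0:
            raise ValueError("amplitude and noise sd must be >= 0")
        if self.lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")
        if self.dilation_schedule is not None:
            if len(self.dilation_schedule) != self.n_frames:
                raise ValueError("dilation_schedule length must equal n_frames")
            if any(f <= 0 for f in self.dilation_schedule):
                raise ValueError("dilation factors must be > 0")
        if self.pore is not None and self.pore.diameter >= min(self.cell.lx, self.cell.ly):
            raise ValueError("pore diameter exceeds the cell")
        if self.dimple is not None and self.dimple.depth >= self.p2p_mean:
            raise ValueError("dimple depth would produce non-positive thickness")

    @property
    def z0(self) -> float:
        """Bilayer midplane height (nm)."""
        return self.cell.lz / 2.0 if self.midplane_z is None else self.midplane_z

    @property
    def census_slab(self) -> tuple[float, float]:
        """The bilayer-center slab [z0 - h/2, z0 + h/2) used for the water census."""
        return (self.z0 - self.slab_height / 2.0, self.z0 + self.slab_height / 2.0)


# lipid pseudo-molecule: name, offset from P toward the midplane (nm), mass
_LIPID_SITES = [
    ("P", 0.00, 30.974),
    ("OC", 0.35, 15.999),
    ("OG", 0.45, 15.999),
    ("C1", 0.80, 12.011),
    ("C2", 1.30, 12.011),
]
_TAIL_NAMES = ("C1", "C2")
_ACCEPTOR_NAMES = ("OC", "OG")


def _lateral_sites(n: int, lx: float, ly: float) -> np.ndarray:
    """n lattice sites covering the cell; first n cells of the smallest grid."""
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack([(ix.ravel() + 0.5) / nx * lx, (iy.ravel() + 0.5) / ny * ly])
    return xy[:n]


def _undulation(xy: np.ndarray, spec: BilayerSpec) -> np.ndarray:
    nx, ny = spec.undulation_wavelengths
    return (
        spec.undulation_amplitude
        * np.sin(2 * np.pi * nx * xy[:, 0] / spec.cell.lx)
        * np.sin(2 * np.pi * ny * xy[:, 1] / spec.cell.ly)
    )


def _dimple_depth(xy: np.ndarray, spec: BilayerSpec) -> np.ndarray:
    if spec.dimple is None:
        return np.zeros(len(xy))
    d = spec.dimple
    dx = xy[:, 0] - d.center[0]
    dy = xy[:, 1] - d.center[1]
    # minimum-image so the footprint respects lateral periodicity
    dx -= spec.cell.lx * np.round(dx / spec.cell.lx)
    dy -= spec.cell.ly * np.round(dy / spec.cell.ly)
    return d.depth * np.exp(-(dx**2 + dy**2) / (2 * d.radius**2))


def _build_topology(spec: BilayerSpec, n_bulk_water: int, n_pore_water: int) -> Topology:
    records: list[AtomRecord] = []
    groups: dict[str, list[int]] = {
        "P": [], "upper_P": [], "lower_P": [], "tails": [], "acceptors": [],
        "water_O": [], "pore_water_O": [], "peptide": [],
    }
    serial = 0
    resid = 0

    def add(name, resname, mass, rclass, segid=None):
        nonlocal serial
        serial += 1
        records.append(AtomRecord(serial, name, resname, resid, mass, segid, rclass))
        return serial - 1  # 0-based index

    for leaflet in ("upper", "lower"):
        for _ in range(spec.lipids_per_leaflet):
            resid += 1
            for name, _, mass in _LIPID_SITES:
                i = add(name, "LIP", mass, ResidueClass.LIPID)
                if name == "P":
                    groups["P"].append(i)
                    groups[f"{leaflet}_P"].append(i)
                elif name in _TAIL_NAMES:
                    groups["tails"].append(i)
                elif name in _ACCEPTOR_NAMES:
                    groups["acceptors"].append(i)

    if spec.peptide is not None:
        pep = spec.peptide
        for p in range(pep.n_protomers):
            segid = chr(ord("A") + p)
            for resname, rclass in pep.residues:
                resid += 1
                groups["peptide"].append(add("BB", resname, 56.0, rclass, segid))
                groups["peptide"].append(add("SC", resname, 60.0, rclass, segid))
                key = f"peptide_{rclass.value}"
                groups.setdefault(key, []).extend([serial - 2, serial - 1])

    for kind, count in (("water_O", n_bulk_water), ("pore_water_O", n_pore_water)):
        for _ in range(count):
            resid += 1
            i = add("OW", "SOL", 15.999, ResidueClass.SOLVENT)
            groups["water_O"].append(i)
            if kind == "pore_water_O":
                groups["pore_water_O"].append(i)
            if spec.water_hydrogens:
                add("HW1", "SOL", 1.008, ResidueClass.SOLVENT)
                add("HW2", "SOL", 1.008, ResidueClass.SOLVENT)

    topo = Topology(records, groups)
    return topo


def _water_positions(rng, spec: BilayerSpec, frame_index: int):
    """Bulk-slab and pore water oxygen positions for one frame."""
    c = spec.cell
    z0 = spec.z0
    pad = 0.25
    half = spec.p2p_mean / 2.0
    rho_n = bulk_water_number_density(spec.bulk_water_density)
    slab_vol = c.lx * c.ly * spec.water_slab_thickness
    n_side = int(round(rho_n * slab_vol))

    bulk = []
    for sign in (+1, -1):
        lo = z0 + sign * (half + pad) + (0 if sign > 0 else -spec.water_slab_thickness)
        xyz = np.column_stack([
            rng.uniform(0, c.lx, n_side),
            rng.uniform(0, c.ly, n_side),
            rng.uniform(lo, lo + spec.water_slab_thickness, n_side),
        ])
        bulk.append(xyz)
    bulk = np.vstack(bulk) if bulk else np.empty((0, 3))

    pore = np.empty((0, 3))
    if spec.pore is not None:
        p = spec.pore
        ax = p.axis if p.axis is not None else (c.lx / 2.0, c.ly / 2.0)
        r_max = p.diameter / 2.0

        def disk(n):
            r = r_max * np.sqrt(rng.uniform(0, 1, n))
            th = rng.uniform(0, 2 * np.pi, n)
            return ax[0] + r * np.cos(th), ax[1] + r * np.sin(th)

        n_slab = spec.pore.occupancy_for_frame(frame_index, spec.slab_height)
        zlo, zhi = spec.census_slab
        x, y = disk(n_slab)
        z = rng.uniform(zlo, zhi, n_slab)
        z = np.minimum(z, np.nextafter(zhi, -np.inf))  # keep the half-open contract
        parts = [np.column_stack([x, y, z])]
        # fill the rest of the cylinder (outside the slab) at fill_density
        stub = half - spec.slab_height / 2.0
        if stub > 0:
            n_stub = int(round(np.pi * r_max**2 * stub
                               * bulk_water_number_density(p.fill_density)))
            for sign in (+1, -1):
                x, y = disk(n_stub)
                lo = z0 + sign * spec.slab_height / 2.0 + (0 if sign > 0 else -stub)
                parts.append(np.column_stack([x, y, rng.uniform(lo, lo + stub, n_stub)]))
        pore = np.vstack(parts)
    return bulk, pore


def _peptide_positions(rng, spec: BilayerSpec) -> np.ndarray:
    pep = spec.peptide
    c = spec.cell
    z0 = spec.z0
    half = spec.p2p_mean / 2.0
    if pep.placement == "solution":
        com_z = z0 + half + 0.25 + spec.water_slab_thickness / 2.0
    elif pep.placement == "surface_bound":
        com_z = z0 + half + 0.5 - pep.com_depth
    else:  # inserted
        com_z = z0
    coords = []
    n_res = len(pep.residues)
    for p in range(pep.n_protomers):
        cx = c.lx / 2.0 + (p - (pep.n_protomers - 1) / 2.0) * 1.6
        cy = c.ly / 2.0
        for k in range(n_res):
            th = 2 * np.pi * k / n_res
            bx = cx + 0.7 * np.cos(th)
            by = cy + 0.7 * np.sin(th)
            coords.append([bx, by, com_z])                       # BB bead
            coords.append([bx + 0.25 * np.cos(th), by + 0.25 * np.sin(th),
                           com_z - 0.15])                        # SC bead
    out = np.asarray(coords)
    if spec.positional_noise_sd > 0:
        out = out + rng.normal(0, spec.positional_noise_sd, out.shape)
    return out


def generate(spec: BilayerSpec) -> Trajectory:
    """Generate a synthetic trajectory from a :class:`BilayerSpec`.

    All randomness derives from ``spec.seed``; identical specs produce
    bit-identical trajectories. Frames are independent draws (fresh
    positional noise and water placement each frame) around the same
    geometry, optionally rescaled by the per-frame dilation schedule.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.cell
    z0 = spec.z0
    half = spec.p2p_mean / 2.0

    xy = _lateral_sites(spec.lipids_per_leaflet, c.lx, c.ly)
    und = _undulation(xy, spec)
    dimple = _dimple_depth(xy, spec)

    # peek atom counts with a throwaway stream so topology and coordinates agree
    n_bulk, n_pore = (len(a) for a in _water_positions(
        np.random.default_rng(spec.seed), spec, 0))
    max_pore = n_pore
    if spec.pore is not None and not np.isscalar(spec.pore.occupancy_in_center_slab) \
            and spec.pore.occupancy_in_center_slab is not None:
        # census schedules vary per frame; pad the molecule count to the max
        base = n_pore - spec.pore.occupancy_for_frame(0, spec.slab_height)
        max_pore = base + max(int(v) for v in spec.pore.occupancy_in_center_slab)
    topo = _build_topology(spec, n_bulk, max_pore)

    frames = []
    for t in range(spec.n_frames):
        upper_z = z0 + half + und - dimple
        lower_z = z0 - half + und
        coords = []
        for leaflet_z, sign in ((upper_z, +1), (lower_z, -1)):
            for j in range(spec.lipids_per_leaflet):
                for _, offset, _ in _LIPID_SITES:
                    coords.append([xy[j, 0], xy[j, 1], leaflet_z[j] - sign * offset])
        coords = np.asarray(coords, dtype=float)
        if spec.positional_noise_sd > 0:
            coords = coords + rng.normal(0, spec.positional_noise_sd, coords.shape)

        if spec.peptide is not None:
            coords = np.vstack([coords, _peptide_positions(rng, spec)])

        bulk, pore = _water_positions(rng, spec, t)
        if len(pore) < max_pore:  # park unused pore slots far outside the slab
            spare = np.column_stack([
                rng.uniform(0, c.lx, max_pore - len(pore)),
                rng.uniform(0, c.ly, max_pore - len(pore)),
                np.full(max_pore - len(pore), min(z0 + half + 0.35, c.lz - 0.05)),
            ])
            pore = np.vstack([pore, spare]) if len(pore) else spare
        waters = np.vstack([bulk, pore]) if len(bulk) + len(pore) else np.empty((0, 3))
        if spec.water_hydrogens and len(waters):
            with_h = np.empty((len(waters) * 3, 3))
            with_h[0::3] = waters
            with_h[1::3] = waters + np.array([0.0957, 0.0, 0.0])
            with_h[2::3] = waters + np.array([-0.024, 0.0926, 0.0])
            waters = with_h
        coords = np.vstack([coords, waters]) if len(waters) else coords

        cell_t = c
        if spec.dilation_schedule is not None:
            f = float(spec.dilation_schedule[t])
            coords = coords.copy()
            coords[:, :2] *= f
            lz = c.lz
            if spec.conserve_volume:
                coords[:, 2] /= f * f
                lz = c.lz / (f * f)
            cell_t = UnitCell(c.lx * f, c.ly * f, lz)
        frames.append(Frame(time=t * spec.dt, coordinates=coords, cell=cell_t))

    return Trajectory(topo, frames)


def apply_dilation(traj: Trajectory, factors: Sequence[float],
                   conserve_volume: bool = True) -> Trajectory:
    """Rescale each frame laterally by its dilation factor.

    x, y and the lateral cell edges are multiplied by the frame's factor;
    with ``conserve_volume`` the z coordinates and Lz are divided by
    factor^2, the incompressible-membrane response (thickness thins as the
    area widens, volume fixed).
    """
    if len(factors) != len(traj):
        raise ValueError(f"{len(factors)} factors for {len(traj)} frames")
    if any(f <= 0 for f in factors):
        raise ValueError("dilation factors must be > 0")
    frames = []
    for fr, f in zip(traj, factors):
        f = float(f)
        coords = fr.coordinates.copy()
        coords[:, :2] *= f
        lz = fr.cell.lz
        if conserve_volume:
            coords[:, 2] /= f * f
            lz = fr.cell.lz / (f * f)
        frames.append(Frame(time=fr.time, coordinates=coords,
                            cell=UnitCell(fr.cell.lx * f, fr.cell.ly * f, lz)))
    return Trajectory(traj.topology, frames)
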