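"""Peptide-lipid and peptide-solvent interaction statistics.

Contacts, hydrogen bonds, residue-residue distance maps, centre-of-mass
tracks, diffusion coefficients from mean-squared displacements, and the
charge/counterion bookkeeping of peptide-membrane systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Trajectory, UnitCell, minimum_image_distance

__all__ = [
    "ContactSeries",
    "HBond",
    "HBondExistenceMap",
    "ResiduePairDistanceMap",
    "ComTrack",
    "DiffusionEstimate",
    "ChargeBook",
    "count_contacts",
    "min_distance_map",
    "find_hbonds",
    "com_track",
    "msd_diffusion",
    "net_charge",
    "counterions_needed",
]

NM2_PER_PS_TO_CM2_PER_S = 1e-2  # 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s


@dataclass
class ContactSeries:
    """Per-frame number of inter-group atom pairs within the cutoff."""

    times: np.ndarray
    counts: np.ndarray
    group_a: str
    group_b: str
    cutoff: float  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be >= 0")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int


@dataclass
class HBondExistenceMap:
    """Boolean bond-by-frame existence matrix with its geometric criteria."""

    bonds: list[HBond]
    present: np.ndarray  # (n_bonds, n_frames) bool
    d_max: float  # donor-acceptor distance criterion, nm
    angle_max: float  # hydrogen-donor-acceptor angle criterion, degrees

    def occupancy(self) -> np.ndarray:
        """Fraction of frames each bond exists."""
        return self.present.mean(axis=1)


@dataclass
class ResiduePairDistanceMap:
    """Frame-averaged minimum inter-residue atom distances (nm)."""

    matrix: np.ndarray
    residue_labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.allclose(m, m.T):
            raise ValueError("distance map must be symmetric")
        self.matrix = m


@dataclass
class ComTrack:
    """Mass-weighted centre-of-mass track: z(t) or COM-COM distance(t)."""

    times: np.ndarray
    values: np.ndarray
    mode: str  # "z_of_com" | "com_distance"


@dataclass
class DiffusionEstimate:
    """Einstein-relation diffusion coefficient from an MSD curve."""

    d: float  # cm^2/s
    dimensionality: int
    fit_window: tuple[float, float]  # ps
    lags: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    exponent: float  # log-log slope of the MSD over the fit window
    diffusive: bool  # False when the MSD grows markedly non-linearly

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass(frozen=True)
class ChargeBook:
    """Residue-composition charge bookkeeping for one peptide monomer.

    With a circular (head-to-tail) backbone the termini carry no charge;
    protonated GLU contributes zero instead of -1.
    """

    n_lys: int = 0
    n_arg: int = 0
    n_glu: int = 0
    glu_protonated: bool = False
    circular: bool = True

    def __post_init__(self) -> None:
        if min(self.n_lys, self.n_arg, self.n_glu) < 0:
            raise ValueError("residue counts must be >= 0")


# ---------------------------------------------------------------------------
# contacts and distances
# ---------------------------------------------------------------------------

def _wrapped(coords: np.ndarray, cell: UnitCell) -> np.ndarray:
    box = cell.lengths
    # cKDTree requires points strictly inside [0, L)
    w = np.mod(coords, box)
    return np.where(w >= box, 0.0, w)


def count_contacts(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 0.6,
    labels: tuple[str, str] = ("A", "B"),
) -> ContactSeries:
    """Count atom pairs (a in A, b in B) closer than ``cutoff`` per frame.

    Each pair is counted individually (atoms in several contacts contribute
    several counts). Distances use the minimum-image convention; a periodic
    k-d tree provides the cell-list acceleration, with results identical to
    the all-pairs definition. Overlapping groups count unordered pairs once
    and never pair an atom with itself.
    """
    a_idx = np.asarray(group_a, dtype=np.intp)
    b_idx = np.asarray(group_b, dtype=np.intp)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("contact groups must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    shared = np.intersect1d(a_idx, b_idx)
    counts = np.empty(len(traj), dtype=int)
    for i, frame in enumerate(traj):
        box = frame.cell.lengths
        pa = _wrapped(frame.coordinates[a_idx], frame.cell)
        pb = _wrapped(frame.coordinates[b_idx], frame.cell)
        tree_a = cKDTree(pa, boxsize=box)
        tree_b = cKDTree(pb, boxsize=box)
        # count_neighbors uses d <= r; shrink to emulate the strict inequality
        r = np.nextafter(cutoff, 0.0)
        n = int(tree_a.count_neighbors(tree_b, r))
        if shared.size:
            # remove self pairs, then halve the double-counted shared pairs
            n_self = shared.size
            pos_a = {int(v): k for k, v in enumerate(a_idx)}
            both = np.array([pos_a[int(v)] for v in shared])
            tree_s = cKDTree(pa[both], boxsize=box)
            n_ss = int(tree_s.count_neighbors(tree_s, r)) - n_self  # ordered pairs
            n = n - n_self - n_ss // 2
        counts[i] = n
    return ContactSeries(traj.times, counts, labels[0], labels[1], cutoff)


def min_distance_map(
    traj: Trajectory,
    residues: dict[str, np.ndarray],
) -> ResiduePairDistanceMap:
    """Frame-averaged minimum atom-atom distance between every residue pair.

    ``residues`` maps residue labels to their atom index arrays (a
    partitioning of the peptide atoms).
    """
    labels = list(residues)
    for lab in labels:
        if len(residues[lab]) == 0:
            raise ValueError(f"residue {lab!r} has no atoms")
    n = len(labels)
    acc = np.zeros((n, n))
    for frame in traj:
        for i in range(n):
            ci = frame.coordinates[np.asarray(residues[labels[i]], dtype=np.intp)]
            for j in range(i + 1, n):
                cj = frame.coordinates[np.asarray(residues[labels[j]], dtype=np.intp)]
                d = minimum_image_distance(ci[:, None, :], cj[None, :, :], frame.cell)
                acc[i, j] += d.min()
    acc = (acc + acc.T) / len(traj)
    return ResiduePairDistanceMap(acc, labels)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _attached_hydrogens(traj: Trajectory, donors: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens bonded to each donor, by naming convention + first-frame
    proximity (H-named atom of the same residue within 0.12 nm)."""
    topo = traj.topology
    frame0 = traj[0]
    names = topo.names
    resids = topo.residue_indices
    h_idx = np.flatnonzero(np.char.startswith(names.astype(str), "H"))
    out: dict[int, list[int]] = {}
    for d in donors:
        same_res = h_idx[resids[h_idx] == resids[d]]
        if same_res.size == 0:
            continue
        dist = minimum_image_distance(
            frame0.coordinates[same_res], frame0.coordinates[d], frame0.cell
        )
        close = same_res[np.atleast_1d(dist) < 0.12]
        if close.size:
            out[int(d)] = [int(h) for h in close]
    return out


def find_hbonds(
    traj: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float = 0.35,
    angle_max: float = 30.0,
    donor_hydrogens: dict[int, list[int]] | None = None,
) -> HBondExistenceMap:
    """Geometric hydrogen-bond detection with an existence map over frames.

    A bond (D, H, A) exists in a frame iff the donor-acceptor distance is
    <= ``d_max`` and the H-D-A angle is <= ``angle_max`` degrees — the
    conventional geometric criterion (0.35 nm / 30 deg by default).
    Hydrogens attached to each donor are found by naming convention unless
    supplied explicitly. Map rows are ordered by first occurrence.
    """
    donors = np.asarray(donors, dtype=np.intp)
    acceptors = np.asarray(acceptors, dtype=np.intp)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    hyd = donor_hydrogens if donor_hydrogens is not None else _attached_hydrogens(traj, donors)
    missing = [int(d) for d in donors if int(d) not in hyd or not hyd[int(d)]]
    if missing:
        shown = ", ".join(str(m) for m in missing[:8])
        more = f" (+{len(missing) - 8} more)" if len(missing) > 8 else ""
        warnings.warn(f"skipping donors without attached hydrogens: {shown}{more}")
    pairs = [(d, h) for d in donors if int(d) in hyd for h in hyd[int(d)]]

    cos_max = np.cos(np.deg2rad(angle_max))
    found: dict[HBond, list[int]] = {}
    order: list[HBond] = []
    for fi, frame in enumerate(traj):
        c = frame.coordinates
        cell = frame.cell
        for d, h in pairs:
            da = np.asarray(minimum_image_distance(c[acceptors], c[d], cell))
            near = acceptors[np.atleast_1d(da) <= d_max]
            for a in near:
                if int(a) == int(d) or int(a) == int(h):
                    continue
                v_h = c[h] - c[d]
                v_a = c[int(a)] - c[d]
                v_h -= cell.lengths * np.round(v_h / cell.lengths)
                v_a -= cell.lengths * np.round(v_a / cell.lengths)
                cos = float(v_h @ v_a / (np.linalg.norm(v_h) * np.linalg.norm(v_a)))
                if cos >= cos_max:
                    bond = HBond(int(d), int(h), int(a))
                    if bond not in found:
                        found[bond] = []
                        order.append(bond)
                    found[bond].append(fi)
    present = np.zeros((len(order), len(traj)), dtype=bool)
    for row, bond in enumerate(order):
        present[row, found[bond]] = True
    return HBondExistenceMap(order, present, d_max, angle_max)


# ---------------------------------------------------------------------------
# COM tracks and diffusion
# ---------------------------------------------------------------------------

def _com(frame_coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    total = masses.sum()
    if total <= 0:
        raise ValueError("selection has zero total mass")
    return masses @ frame_coords / total


def com_track(
    traj: Trajectory,
    selection: np.ndarray,
    mode: str = "z_of_com",
    selection2: np.ndarray | None = None,
) -> ComTrack:
    """Mass-weighted COM per frame: its z, or its distance to a second COM."""
    idx = np.asarray(selection, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("selection is empty")
    masses = traj.topology.masses[idx]
    if mode == "z_of_com":
        values = np.array([_com(fr.coordinates[idx], masses)[2] for fr in traj])
    elif mode == "com_distance":
        if selection2 is None or len(selection2) == 0:
            raise ValueError("com_distance mode needs a non-empty second selection")
        idx2 = np.asarray(selection2, dtype=np.intp)
        masses2 = traj.topology.masses[idx2]
        values = np.array([
            float(minimum_image_distance(
                _com(fr.coordinates[idx], masses),
                _com(fr.coordinates[idx2], masses2),
                fr.cell,
            ))
            for fr in traj
        ])
    else:
        raise ValueError(f"unknown COM track mode {mode!r}")
    return ComTrack(traj.times, values, mode)


def msd_diffusion(
    traj: Trajectory,
    selection: np.ndarray,
    dimensionality: int = 3,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> DiffusionEstimate:
    """Diffusion coefficient via the Einstein relation, D = slope / (2 n).

    The MSD uses every time origin; the slope is a least-squares fit over
    the ``fit_window`` fraction of the lag range (default the 10-50%
    middle band, avoiding ballistic short lags and noisy long ones).
    Requires unwrapped coordinates — per-frame jumps beyond half the box
    are rejected. A log-log exponent far from 1 over the fit window flags
    the motion as non-diffusive (e.g. coherent drift, which grows
    quadratically).
    """
    idx = np.asarray(selection, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("selection is empty")
    if dimensionality not in (2, 3):
        raise ValueError("dimensionality must be 2 or 3")
    if len(traj) < 50:
        raise ValueError(f"need >= 50 frames for an MSD fit, got {len(traj)}")
    pos = np.stack([fr.coordinates[idx] for fr in traj])  # (T, N, 3)
    box = traj[0].cell.lengths
    jumps = np.abs(np.diff(pos, axis=0))
    if np.any(jumps > box / 2):
        raise ValueError(
            "coordinates appear wrapped (jump > half box); unwrap before MSD analysis"
        )
    ndim = dimensionality
    pos = pos[..., :ndim]
    times = traj.times
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt):
        raise ValueError("MSD needs a uniform time step")
    n_t = len(traj)
    max_lag = n_t - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.sum(disp**2, axis=-1))
    lag_times = lags * dt

    lo = max(1, int(np.floor(fit_window[0] * max_lag)))
    hi = max(lo + 2, int(np.ceil(fit_window[1] * max_lag)))
    sel = slice(lo - 1, hi)
    slope, _ = np.polyfit(lag_times[sel], msd[sel], 1)
    slope = max(slope, 0.0)
    d = slope / (2.0 * ndim) * NM2_PER_PS_TO_CM2_PER_S

    with np.errstate(divide="ignore"):
        log_l = np.log(lag_times[sel])
        log_m = np.log(np.maximum(msd[sel], 1e-300))
    exponent = float(np.polyfit(log_l, log_m, 1)[0]) if np.ptp(log_m) > 0 else 0.0
    diffusive = bool(0.5 <= exponent <= 1.5) and slope > 0
    return DiffusionEstimate(
        d=d,
        dimensionality=ndim,
        fit_window=(float(lag_times[sel][0]), float(lag_times[sel][-1])),
        lags=lag_times,
        msd=msd,
        exponent=exponent,
        diffusive=diffusive,
    )


# ---------------------------------------------------------------------------
# charge bookkeeping
# ---------------------------------------------------------------------------

def net_charge(book: ChargeBook) -> int:
    """Net charge of one peptide monomer.

    Basic residues contribute +1 each; GLU contributes -1 unless
    protonated; a circular backbone has no charged termini (a linear one
    would add the zwitterionic pair, net 0, so the sum is unchanged — the
    flag is kept for bookkeeping clarity).
    """
    glu = 0 if book.glu_protonated else book.n_glu
    return book.n_lys + book.n_arg - glu


def counterions_needed(n_anionic_lipids: int, n_monomers: int, book: ChargeBook) -> int:
    """Monovalent cations needed to neutralise lipids + peptides.

    Each anionic lipid carries -1; ``n_monomers`` peptide monomers carry
    ``net_charge(book)`` each. The returned count satisfies
    counterions + total peptide charge - n_anionic_lipids = 0.
    """
    if n_anionic_lipids < 0 or n_monomers < 0:
        raise ValueError("counts must be >= 0")
    return n_anionic_lipids - n_monomers * net_charge(book)
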