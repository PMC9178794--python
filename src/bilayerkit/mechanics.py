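"""Bilayer mechanics: tension elasticity, water census and pore sizing.

Two small closed-form models anchor this module.

**Tension elasticity.** For a bilayer with area compressibility modulus
``K_A``, the lateral tension and relative area increment are linked by

    Gamma = K_A * (dA / A),

and for an (approximately) volume-incompressible hydrocarbon core the
relative thinning mirrors the area increment, ``dh/h ~= -dA/A``. The
hydrocarbon core thickness is obtained from the P-to-P distance by
subtracting 1.0 nm (0.5 nm phosphate-to-hydrocarbon offset per leaflet).

**Cylindrical pore sizing.** A trans-bilayer water column of ``NW``
molecules, assumed at bulk density ``rho`` inside a cylinder of height
``h``, has volume ``V = NW * M_w / (rho * N_A)`` and therefore diameter

    d = sqrt(4 V / (pi h)).

The census that feeds NW counts water oxygens inside a 0.5 nm-high slab
about the bilayer center — a bottleneck cross-section of the (generally
irregular) pore, so the diameter is a limiting estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Trajectory, wrap_coordinates

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ElasticState",
    "PoreCylinder",
    "CensusSeries",
    "hydrocarbon_thickness",
    "fractional_thinning",
    "tension_from_area",
    "area_from_tension",
    "estimate_KA",
    "water_census",
    "plateau_stats",
    "pore_diameter",
    "detect_disruption",
]

BOLTZMANN_J_PER_K = 1.380649e-23
WATER_MOLAR_MASS = 18.015  # g/mol
AVOGADRO = 6.02214076e23  # 1/mol

HUANG_P_TO_HYDROCARBON_OFFSET = 1.0  # nm, 0.5 per leaflet


@dataclass
class ElasticState:
    """Bundle of the tension-elasticity quantities for one system state."""

    gamma: float  # surface tension, mN/m
    k_a: float  # area compressibility modulus, mN/m
    rel_area_change: float  # dA/A, dimensionless
    rel_thickness_change: float  # dh/h, dimensionless (thinning negative)
    p2p: float  # P-to-P distance, nm
    h_hydrocarbon: float  # hydrocarbon core thickness, nm
    delta_h: float  # thickness decrement, nm

    def __post_init__(self) -> None:
        if self.k_a <= 0:
            raise ValueError("K_A must be > 0")
        if self.h_hydrocarbon <= 0:
            raise ValueError("hydrocarbon thickness must be > 0")


@dataclass
class PoreCylinder:
    """Cylindrical pore model: water count -> volume -> diameter."""

    nw: float  # number of water molecules
    h_cyl: float = 0.5  # cylinder height, nm
    rho: float = 1.0  # water density, g/cm^3
    m_w: float = WATER_MOLAR_MASS
    n_a: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.nw < 0:
            raise ValueError("water count must be >= 0")
        if self.h_cyl <= 0 or self.rho <= 0:
            raise ValueError("cylinder height and density must be > 0")

    @property
    def mass_g(self) -> float:
        """Total water mass M in grams."""
        return self.nw * self.m_w / self.n_a

    @property
    def volume_cm3(self) -> float:
        """Cylinder volume V in cm^3 (mass over density)."""
        return self.mass_g / self.rho

    @property
    def volume_nm3(self) -> float:
        return self.volume_cm3 * 1e21

    @property
    def diameter(self) -> float:
        """Pore diameter d = sqrt(4 V / (pi h)), nm, unrounded."""
        return float(np.sqrt(4.0 * self.volume_nm3 / (np.pi * self.h_cyl)))

    @property
    def diameter_reported(self) -> float:
        """Diameter rounded to one decimal, the reporting precision."""
        return round(self.diameter, 1)


@dataclass
class CensusSeries:
    """Per-frame count of water molecules inside the bilayer-center slab."""

    times: np.ndarray  # ps
    counts: np.ndarray  # integer counts
    slab: tuple[float, float]  # [z_min, z_max), nm
    plateau_mean: float | None = None
    plateau_sd: float | None = None
    plateau_onset: float | None = None  # ps
    disruption_time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("census counts must be >= 0")
        if self.slab[0] >= self.slab[1]:
            raise ValueError("slab z_min must be < z_max")

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# tension elasticity
# ---------------------------------------------------------------------------

def hydrocarbon_thickness(p2p: float) -> float:
    """Hydrocarbon core thickness from the P-to-P distance (minus 1.0 nm)."""
    if p2p <= HUANG_P_TO_HYDROCARBON_OFFSET:
        raise ValueError(
            f"P-to-P distance {p2p} nm <= {HUANG_P_TO_HYDROCARBON_OFFSET} nm "
            "leaves no hydrocarbon core"
        )
    return p2p - HUANG_P_TO_HYDROCARBON_OFFSET


def fractional_thinning(delta_h: float, h: float) -> float:
    """Signed relative thickness change -dh/h (a decrement gives < 0)."""
    if h <= 0:
        raise ValueError("thickness must be > 0")
    return -delta_h / h


def tension_from_area(rel_area_change: float, k_a: float) -> float:
    """Surface tension Gamma = K_A * dA/A, in the units of K_A (mN/m)."""
    if k_a <= 0:
        raise ValueError("K_A must be > 0")
    return k_a * rel_area_change


def area_from_tension(gamma: float, k_a: float) -> float:
    """Relative area increment dA/A = Gamma / K_A."""
    if k_a <= 0:
        raise ValueError("K_A must be > 0")
    return gamma / k_a


def estimate_KA(
    area_series: np.ndarray,
    temperature: float,
    n_bootstrap: int = 200,
    block_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Area compressibility modulus from equilibrium area fluctuations.

    The standard fluctuation estimator ``K_A = k_B T <A> / var(A)`` (area
    in nm^2, result in mN/m), with a block-bootstrap standard error to
    respect serial correlation. Requires a reasonably long, stationary
    series (>= 100 frames).
    """
    a = np.asarray(area_series, dtype=float)
    if len(a) < 100:
        raise ValueError(f"need >= 100 frames for the fluctuation estimator, got {len(a)}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    var = a.var()
    if var == 0:
        raise ValueError("fluctuation estimator undefined: zero area variance")

    def ka_of(x: np.ndarray) -> float:
        # A [nm^2] = 1e-18 m^2; var [nm^4] = 1e-36 m^4; result N/m -> mN/m
        return BOLTZMANN_J_PER_K * temperature * x.mean() * 1e18 / x.var() * 1e3

    rng = rng if rng is not None else np.random.default_rng(0)
    block = max(1, int(len(a) * block_fraction))
    n_blocks = int(np.ceil(len(a) / block))
    reps = np.empty(n_bootstrap)
    for r in range(n_bootstrap):
        starts = rng.integers(0, len(a) - block + 1, n_blocks)
        sample = np.concatenate([a[s:s + block] for s in starts])[: len(a)]
        reps[r] = ka_of(sample)
    return ka_of(a), float(reps.std())


# ---------------------------------------------------------------------------
# water census and pore sizing
# ---------------------------------------------------------------------------

def water_census(
    traj: Trajectory,
    slab: tuple[float, float],
    water_selection: np.ndarray,
    window: int = 10,
) -> CensusSeries:
    """Count selected water oxygens with wrapped z in [z_min, z_max) per frame.

    Coordinates are wrapped into the primary cell before the slab test, so
    the census is insensitive to how the trajectory was imaged. Plateau
    statistics and disruption annotation are filled in via
    :func:`plateau_stats` and :func:`detect_disruption`.
    """
    idx = np.asarray(water_selection, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("water selection is empty")
    z_min, z_max = slab
    counts = np.empty(len(traj), dtype=int)
    for i, frame in enumerate(traj):
        if not (0 <= z_min and z_max <= frame.cell.lz):
            raise ValueError(
                f"frame {i}: slab [{z_min}, {z_max}) outside cell of height {frame.cell.lz}"
            )
        z = wrap_coordinates(frame.coordinates[idx], frame.cell)[:, 2]
        counts[i] = int(np.count_nonzero((z >= z_min) & (z < z_max)))
    series = CensusSeries(traj.times, counts, slab)
    if len(series) > window:
        window = max(2, min(window, len(series) // 2))
        onset, mean, sd = plateau_stats(series, window)
        series.plateau_onset = onset
        series.plateau_mean = mean
        series.plateau_sd = sd
        series.disruption_time = detect_disruption(series)
        if series.disruption_time is not None:
            # re-evaluate the plateau over the pre-disruption segment only
            stop = int(np.searchsorted(series.times, series.disruption_time))
            if onset is not None:
                start = int(np.searchsorted(series.times, onset))
                if stop - start >= 2:
                    seg = series.counts[start:stop]
                    series.plateau_mean = float(seg.mean())
                    series.plateau_sd = float(seg.std())
    return series


def plateau_stats(
    series: CensusSeries, window: int = 10, rel_tol: float = 0.10
) -> tuple[float | None, float, float]:
    """Locate the census plateau: (onset time, mean, sd).

    The plateau level is taken as the median of the rolling means (width
    ``window``), which is robust both to an initial filling ramp and to a
    late blow-up tail. The onset is the first frame whose rolling mean is
    within ``max(rel_tol * level, 1)`` of that level and still is one
    window later (a persistent entry into the plateau band). The mean and
    sd are robust location/scale (median and scaled MAD) over
    [onset, end); :func:`water_census` later tightens them to the
    pre-disruption segment. A series that never stabilises gets
    ``onset=None`` and whole-series statistics with a warning.
    """
    counts = np.asarray(series.counts, dtype=float)
    n = len(counts)
    if n < 2 * window:
        raise ValueError(f"series of {n} frames is too short for window {window}")
    kernel = np.ones(window) / window
    rolling = np.convolve(counts, kernel, mode="valid")  # rolling[t] = mean(t .. t+w-1)
    level = float(np.median(rolling))
    band = max(rel_tol * abs(level), 1.0)
    onset_idx = None
    for t in range(len(rolling) - window):
        if abs(rolling[t] - level) <= band and abs(rolling[t + window] - level) <= band:
            onset_idx = t
            break
    if onset_idx is None:
        warnings.warn("census series never stabilises; using whole-series statistics")
        seg = counts
        onset_time = None
    else:
        seg = counts[onset_idx:]
        onset_time = float(series.times[onset_idx])
    med = float(np.median(seg))
    mad = float(np.median(np.abs(seg - med)))
    return onset_time, med, 1.4826 * mad


def pore_diameter(pore: PoreCylinder) -> float:
    """Unrounded cylinder diameter (nm); see :class:`PoreCylinder`."""
    return pore.diameter


def detect_disruption(
    series: CensusSeries, k_sd: float = 5.0, persistence: int = 5
) -> float | None:
    """First time the census blows up past the plateau, or None.

    Disruption is called at the first frame whose count exceeds
    ``plateau_mean + k_sd * max(plateau_sd, 1)`` and stays above it for
    ``persistence`` consecutive frames — an operationalisation of the
    abrupt pre-collapse increase in trans-bilayer water.
    """
    if series.plateau_mean is None or series.plateau_sd is None:
        onset, mean, sd = plateau_stats(series, window=min(10, max(2, len(series) // 4)))
        series.plateau_onset, series.plateau_mean, series.plateau_sd = onset, mean, sd
    threshold = series.plateau_mean + k_sd * max(series.plateau_sd, 1.0)
    above = np.asarray(series.counts) > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            return float(series.times[i - persistence + 1])
    return None
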