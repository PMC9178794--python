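"""Contacts, H-bonds, distance maps, COM tracks, diffusion, charges."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerkit.core import (
    AtomRecord,
    ResidueClass,
    Topology,
    UnitCell,
    minimum_image_distance,
)
from bilayerkit.interactions import (
    ChargeBook,
    com_track,
    count_contacts,
    counterions_needed,
    find_hbonds,
    min_distance_map,
    msd_diffusion,
    net_charge,
)

from conftest import point_topology, point_trajectory

CELL = UnitCell(5.0, 5.0, 5.0)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _two_atom_traj(separation):
    coords = np.array([[1.0, 1.0, 1.0], [1.0 + separation, 1.0, 1.0]])
    return point_trajectory([coords], CELL)


@pytest.mark.parametrize("sep,expected", [(0.59, 1), (0.61, 0)])
def test_contact_cutoff_boundary(sep, expected):
    traj = _two_atom_traj(sep)
    series = count_contacts(traj, np.array([0]), np.array([1]), cutoff=0.6)
    assert series.counts[0] == expected


def test_contact_through_periodic_image():
    coords = np.array([[0.1, 1.0, 1.0], [4.8, 1.0, 1.0]])  # 0.3 nm via wrap
    traj = point_trajectory([coords], CELL)
    assert count_contacts(traj, np.array([0]), np.array([1]), 0.6).counts[0] == 1
    # same separation without wrapping would be far
    assert minimum_image_distance(coords[0], coords[1], CELL) == pytest.approx(0.3)


def _brute_contacts(coords, a_idx, b_idx, cell, cutoff):
    n = 0
    seen = set()
    for a in a_idx:
        for b in b_idx:
            if a == b:
                continue
            key = (min(a, b), max(a, b)) if a in b_idx and b in a_idx else (a, b)
            if key in seen:
                continue
            seen.add(key)
            if minimum_image_distance(coords[a], coords[b], cell) < cutoff:
                n += 1
    return n


@pytest.mark.parametrize("overlap", [False, True])
def test_contacts_match_brute_force_over_seeds(overlap):
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        coords = rng.uniform(0, 5, (200, 3))
        traj = point_trajectory([coords], CELL)
        if overlap:
            a_idx = np.arange(0, 150)
            b_idx = np.arange(100, 200)
        else:
            a_idx = np.arange(0, 100)
            b_idx = np.arange(100, 200)
        fast = count_contacts(traj, a_idx, b_idx, 0.6).counts[0]
        brute = _brute_contacts(coords, a_idx, b_idx, CELL, 0.6)
        assert fast == brute


def test_contacts_symmetric_in_groups():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 5, (60, 3))
    traj = point_trajectory([coords], CELL)
    a, b = np.arange(30), np.arange(30, 60)
    assert (count_contacts(traj, a, b, 0.6).counts
            == count_contacts(traj, b, a, 0.6).counts).all()


def test_contacts_empty_group_rejected():
    traj = _two_atom_traj(0.5)
    with pytest.raises(ValueError, match="non-empty"):
        count_contacts(traj, np.array([], dtype=int), np.array([1]))


# ---------------------------------------------------------------------------
# residue distance maps
# ---------------------------------------------------------------------------

def test_distance_map_fixed_pair():
    r = 1.25
    coords = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    traj = point_trajectory([coords, coords + 0.1], CELL)
    dmap = min_distance_map(traj, {"A": np.array([0]), "B": np.array([1])})
    assert dmap.matrix[0, 1] == pytest.approx(r, abs=1e-12)
    assert dmap.matrix[0, 0] == 0.0
    np.testing.assert_allclose(dmap.matrix, dmap.matrix.T)


def test_distance_map_matches_brute_force():
    rng = np.random.default_rng(2)
    coords = [rng.uniform(0, 5, (12, 3)) for _ in range(3)]
    residues = {f"R{k}": np.arange(4 * k, 4 * k + 4) for k in range(3)}
    traj = point_trajectory(coords, CELL)
    dmap = min_distance_map(traj, residues)
    labels = list(residues)
    for i in range(3):
        for j in range(i + 1, 3):
            acc = 0.0
            for c in coords:
                best = min(
                    minimum_image_distance(c[a], c[b], CELL)
                    for a in residues[labels[i]] for b in residues[labels[j]]
                )
                acc += best
            assert dmap.matrix[i, j] == pytest.approx(acc / 3, abs=1e-9)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_topology():
    return Topology([
        AtomRecord(1, "OD", "SER", 1, 15.999, residue_class=ResidueClass.POLAR),
        AtomRecord(2, "HD", "SER", 1, 1.008, residue_class=ResidueClass.POLAR),
        AtomRecord(3, "OA", "LIP", 2, 15.999, residue_class=ResidueClass.LIPID),
    ])


def _hbond_coords(da=0.28, angle_deg=0.0):
    d = np.array([1.0, 1.0, 1.0])
    t = np.deg2rad(angle_deg)
    h = d + 0.1 * np.array([np.cos(t), np.sin(t), 0.0])
    a = d + np.array([da, 0.0, 0.0])
    return np.vstack([d, h, a])


def test_ideal_hbond_detected():
    traj = point_trajectory([_hbond_coords()], CELL, topology=_hbond_topology())
    hmap = find_hbonds(traj, np.array([0]), np.array([2]))
    assert len(hmap.bonds) == 1
    assert hmap.present[0, 0]


@pytest.mark.parametrize("da,angle", [(0.40, 0.0), (0.28, 45.0)])
def test_hbond_criteria_boundaries(da, angle):
    traj = point_trajectory([_hbond_coords(da, angle)], CELL,
                            topology=_hbond_topology())
    hmap = find_hbonds(traj, np.array([0]), np.array([2]))
    assert len(hmap.bonds) == 0


def test_hbond_existence_row_equals_even_frame_mask():
    frames = [_hbond_coords() if i % 2 == 0 else _hbond_coords(da=0.45)
              for i in range(8)]
    traj = point_trajectory(frames, CELL, topology=_hbond_topology())
    hmap = find_hbonds(traj, np.array([0]), np.array([2]))
    assert len(hmap.bonds) == 1
    np.testing.assert_array_equal(hmap.present[0], [True, False] * 4)
    assert hmap.occupancy()[0] == pytest.approx(0.5)


def test_hbond_invariant_under_rigid_motion():
    base = _hbond_coords()
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1]])
    moved = base @ rot.T + np.array([0.8, 0.4, 1.1])
    for coords in (base, moved):
        traj = point_trajectory([coords], CELL, topology=_hbond_topology())
        assert len(find_hbonds(traj, np.array([0]), np.array([2])).bonds) == 1


def test_generator_water_hydrogens_found_by_convention():
    from bilayerkit.interactions import _attached_hydrogens
    from bilayerkit.synthetic import BilayerSpec, PoreSpec, generate

    spec = BilayerSpec(water_hydrogens=True, water_slab_thickness=0.3,
                       pore=PoreSpec(diameter=0.8, occupancy_in_center_slab=3),
                       seed=1)
    traj = generate(spec)
    donors = traj.topology.groups["pore_water_O"]
    hyd = _attached_hydrogens(traj, donors)
    assert set(hyd) == {int(d) for d in donors}
    assert all(len(h) == 2 for h in hyd.values())


def test_donor_without_hydrogen_skipped_with_warning():
    topo = Topology([
        AtomRecord(1, "OD", "SER", 1, 15.999),
        AtomRecord(2, "OA", "LIP", 2, 15.999),
    ])
    coords = np.array([[1.0, 1.0, 1.0], [1.28, 1.0, 1.0]])
    traj = point_trajectory([coords], CELL, topology=topo)
    with pytest.warns(UserWarning, match="without attached hydrogens"):
        hmap = find_hbonds(traj, np.array([0]), np.array([1]))
    assert len(hmap.bonds) == 0


# ---------------------------------------------------------------------------
# COM tracks
# ---------------------------------------------------------------------------

def test_single_atom_com_is_its_coordinate():
    coords = [np.array([[1.0, 2.0, 3.0]]), np.array([[1.0, 2.0, 3.5]])]
    traj = point_trajectory(coords, CELL)
    track = com_track(traj, np.array([0]), "z_of_com")
    np.testing.assert_allclose(track.values, [3.0, 3.5])


def test_equal_mass_com_is_midpoint_and_weighting_works():
    topo = Topology([
        AtomRecord(1, "A", "X", 1, 10.0),
        AtomRecord(2, "B", "X", 1, 30.0),
    ])
    coords = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 3.0]])
    traj = point_trajectory([coords], CELL, topology=topo)
    track = com_track(traj, np.array([0, 1]), "z_of_com")
    assert track.values[0] == pytest.approx((10 * 1 + 30 * 3) / 40)


def test_com_track_shifts_with_rigid_translation():
    rng = np.random.default_rng(3)
    base = rng.uniform(1, 4, (5, 3))
    delta = np.array([0.0, 0.0, 0.7])
    traj = point_trajectory([base, base + delta], CELL)
    track = com_track(traj, np.arange(5), "z_of_com")
    assert track.values[1] - track.values[0] == pytest.approx(0.7, abs=1e-12)


def test_com_distance_mode_uses_minimum_image():
    coords = np.array([[0.2, 2.5, 2.5], [4.8, 2.5, 2.5]])
    traj = point_trajectory([coords], CELL)
    track = com_track(traj, np.array([0]), "com_distance", np.array([1]))
    assert track.values[0] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def _random_walk_traj(d_cm2_s, n_frames=200, n_atoms=60, dt=10.0, seed=0, drift=0.0):
    d_nm2_ps = d_cm2_s * 100.0  # 1 cm^2/s = 100 nm^2/ps
    sd = np.sqrt(2 * d_nm2_ps * dt)
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, sd, (n_frames - 1, n_atoms, 3))
    pos = np.concatenate([np.zeros((1, n_atoms, 3)), np.cumsum(steps, axis=0)])
    pos += drift * np.arange(n_frames)[:, None, None] * dt
    big = UnitCell(1e6, 1e6, 1e6)  # effectively unbounded, unwrapped
    return point_trajectory(list(pos + 5e5), big, dt=dt,
                            topology=point_topology(n_atoms))


def test_stationary_particle_has_zero_d():
    traj = point_trajectory([np.array([[1.0, 1.0, 1.0]])] * 60, CELL, dt=1.0)
    est = msd_diffusion(traj, np.array([0]))
    assert est.d == 0.0


def test_brownian_walk_d_recovered_within_15_percent():
    target = 6.0e-7  # cm^2/s
    estimates = [
        msd_diffusion(_random_walk_traj(target, seed=s), np.arange(60)).d
        for s in range(5)
    ]
    assert np.mean(estimates) == pytest.approx(target, rel=0.15)


def test_mobility_ratio_recovered_within_20_percent():
    fast = np.mean([
        msd_diffusion(_random_walk_traj(6.0e-7, seed=10 + s), np.arange(60)).d
        for s in range(3)
    ])
    slow = np.mean([
        msd_diffusion(_random_walk_traj(1.0e-8, seed=20 + s), np.arange(60)).d
        for s in range(3)
    ])
    assert fast / slow == pytest.approx(60.0, rel=0.20)


def test_linear_drift_flagged_non_diffusive():
    traj = _random_walk_traj(0.0, drift=1e-3, seed=1)
    est = msd_diffusion(traj, np.arange(60))
    assert est.exponent > 1.5 or not est.diffusive
    assert not est.diffusive


def test_wrapped_coordinates_rejected():
    rng = np.random.default_rng(4)
    coords = [rng.uniform(0, 5, (3, 3)) for _ in range(60)]
    traj = point_trajectory(coords, CELL)
    with pytest.raises(ValueError, match="unwrap"):
        msd_diffusion(traj, np.arange(3))


def test_dimensionality_2d_uses_lateral_only():
    traj = _random_walk_traj(6.0e-7, seed=5)
    est2 = msd_diffusion(traj, np.arange(60), dimensionality=2)
    assert est2.dimensionality == 2
    assert est2.d == pytest.approx(6.0e-7, rel=0.2)


# ---------------------------------------------------------------------------
# charge bookkeeping
# ---------------------------------------------------------------------------

def test_monomer_charges_for_both_protonation_states():
    book = ChargeBook(n_lys=8, n_arg=2, n_glu=4, glu_protonated=False)
    assert net_charge(book) == 6
    assert net_charge(ChargeBook(n_lys=8, n_arg=2, n_glu=4, glu_protonated=True)) == 10


def test_counterion_counts_for_reference_system():
    unprot = ChargeBook(n_lys=8, n_arg=2, n_glu=4, glu_protonated=False)
    prot = ChargeBook(n_lys=8, n_arg=2, n_glu=4, glu_protonated=True)
    assert counterions_needed(128, 2, unprot) == 116
    assert counterions_needed(128, 2, prot) == 108


def test_system_electroneutrality_invariant():
    for n_lip in (64, 128):
        for n_mono in (0, 2, 4):
            for prot in (False, True):
                book = ChargeBook(n_lys=8, n_arg=2, n_glu=4, glu_protonated=prot)
                ions = counterions_needed(n_lip, n_mono, book)
                assert ions + n_mono * net_charge(book) - n_lip == 0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ChargeBook(n_lys=-1)
    with pytest.raises(ValueError):
        counterions_needed(-5, 2, ChargeBook())
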