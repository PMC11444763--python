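"""Hydrogen-bond/contact geometry, contact probabilities, RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from achescreen.structure_contacts import (
    ContactCriteria,
    contact_probability,
    detect_hbonds,
    detect_sc_contacts,
    load_trajectory,
    rmsd,
    write_multimodel_pdb,
)
from achescreen.synthetic_data import TrajectorySpec, make_binding_trajectory
from conftest import make_frame


# ---------------------------------------------------------------------------
# Hydrogen bonds

def test_collinear_geometry_is_a_bond(hb_frame):
    hbs = detect_hbonds(hb_frame)
    assert hbs == [(0, 1, 2)]


def test_distance_gate_rejects(hb_frame):
    far = make_frame(
        [[0, 0, 0], [1, 0, 0], [4.0, 0, 0]], ["N", "H", "O"], [False, False, True]
    )
    assert detect_hbonds(far) == []


def test_angle_gate_rejects():
    # acceptor placed so the A-H-D angle is 120 deg with d(D,A) = 3.0
    h = np.array([1.0, 0.0, 0.0])
    d = np.zeros(3)
    # a = h + r*u with u at 120 deg from (d-h); |a-d|^2 = 1 + r^2 + r = 9
    # gives r = (-1 + sqrt(33))/2 exactly
    r = (-1.0 + np.sqrt(33.0)) / 2.0
    a = h + r * np.array([0.5, np.sqrt(3) / 2, 0.0])
    assert np.linalg.norm(a - d) == pytest.approx(3.0)
    frame = make_frame([d, h, a], ["N", "H", "O"], [False, False, True])
    assert detect_hbonds(frame) == []


def test_ligand_can_donate_to_receptor():
    frame = make_frame(
        [[0, 0, 0], [1, 0, 0], [2.9, 0, 0]],
        ["O", "H", "N"],
        [True, True, False],
    )
    assert detect_hbonds(frame) == [(0, 1, 2)]


def test_frame_without_hydrogens_warns_empty():
    frame = make_frame([[0, 0, 0], [3.0, 0, 0]], ["N", "O"], [False, True])
    with pytest.warns(UserWarning, match="no hydrogens"):
        assert detect_hbonds(frame) == []


def test_hb_set_shrinks_with_stricter_criteria(hb_frame):
    base = detect_hbonds(hb_frame, ContactCriteria())
    tighter_angle = detect_hbonds(hb_frame, ContactCriteria(hb_angle_min=179.5))
    shorter = detect_hbonds(hb_frame, ContactCriteria(hb_da_max=2.0))
    assert set(tighter_angle) <= set(base)
    assert set(shorter) <= set(base)


# ---------------------------------------------------------------------------
# Side-chain contacts

@pytest.mark.parametrize("dist, expected", [(4.4, {1}), (4.6, set())])
def test_sc_distance_gate(dist, expected):
    frame = make_frame([[0, 0, 0], [dist, 0, 0]], ["C", "C"], [False, True])
    assert detect_sc_contacts(frame) == expected


def test_hydrogen_pairs_never_count():
    frame = make_frame([[0, 0, 0], [1.0, 0, 0]], ["H", "H"], [False, True])
    assert detect_sc_contacts(frame) == set()


def test_sc_set_shrinks_with_smaller_cutoff():
    frame = make_frame(
        [[0, 0, 0], [0, 3.0, 0], [2.0, 0, 0]],
        ["C", "C", "C"],
        [False, False, True],
        resids=[1, 2, 999],
    )
    wide = detect_sc_contacts(frame, ContactCriteria(sc_max=4.5))
    narrow = detect_sc_contacts(frame, ContactCriteria(sc_max=2.5))
    assert narrow <= wide


# ---------------------------------------------------------------------------
# Contact probabilities

def test_planted_fractions_recovered_exactly():
    plan = ((101, 0.3, 0.6), (102, 0.0, 1.0), (103, 1.0, 1.0), (104, 0.0, 0.0))
    frames, truth = make_binding_trajectory(
        TrajectorySpec(n_frames=100, residue_plan=plan, seed=8)
    )
    profile = contact_probability(frames)
    for rid, (hb, sc) in truth.items():
        assert profile.probability(rid, "hb") == hb
        assert profile.probability(rid, "sc") == sc
    assert profile.probability(103, "sc") == 1.0
    assert profile.probability(104, "sc") == 0.0


def test_profile_invariant_under_rigid_motion():
    frames, _ = make_binding_trajectory(
        TrajectorySpec(n_frames=20, residue_plan=((1, 0.25, 0.5),), seed=3)
    )
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
    moved = []
    for fr in frames:
        fr2 = make_frame(
            rot.apply(fr.coordinates) + np.array([11.0, -5.0, 2.5]),
            fr.elements,
            fr.ligand_mask,
            names=fr.atom_names,
            resids=fr.residue_ids,
            resnames=fr.residue_names,
        )
        moved.append(fr2)
    a = contact_probability(frames).table
    b = contact_probability(moved).table
    assert a.equals(b)


def test_inconsistent_atom_counts_rejected():
    frames, _ = make_binding_trajectory(
        TrajectorySpec(n_frames=3, residue_plan=((1, 0.0, 1.0),), seed=0)
    )
    other, _ = make_binding_trajectory(
        TrajectorySpec(n_frames=3, residue_plan=((1, 0.0, 1.0), (2, 0.0, 0.0)), seed=0)
    )
    with pytest.raises(ValueError, match="atom count"):
        contact_probability([frames[0], other[0]])


def test_pdb_roundtrip_preserves_contact_profile(tmp_path):
    frames, truth = make_binding_trajectory(
        TrajectorySpec(n_frames=10, residue_plan=((1, 0.3, 0.5), (2, 0.0, 0.8)), seed=4)
    )
    path = tmp_path / "traj.pdb"
    write_multimodel_pdb(frames, path)
    loaded = load_trajectory(path, ligand_resname="LIG")
    assert len(loaded) == 10
    profile = contact_probability(loaded)
    for rid, (hb, sc) in truth.items():
        assert profile.probability(rid, "hb") == pytest.approx(hb)
        assert profile.probability(rid, "sc") == pytest.approx(sc)


# ---------------------------------------------------------------------------
# RMSD

def grid_rmsd_oracle(mobile, target, levels=6, n=24):
    """Brute-force minimum RMSD over rotations: zooming Euler-angle grid.

    Exhaustive n^3 grid over zyz Euler angles, re-centered and shrunk by 3x
    per level; final angular spacing ~1e-3 rad.  Independent of the SVD
    superposition it cross-checks.
    """
    A = mobile - mobile.mean(axis=0)
    B = target - target.mean(axis=0)
    center = np.zeros(3)
    widths = np.array([2 * np.pi, np.pi, 2 * np.pi])
    best_val = np.inf
    for _ in range(levels):
        axes = [np.linspace(c - w / 2, c + w / 2, n) for c, w in zip(center, widths)]
        angles = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        rotated = np.einsum("nij,aj->nai", mats, A)
        vals = np.sqrt(((rotated - B) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val = float(vals[k])
            center = angles[k]
        widths = widths / 3.0
    return best_val


def toy(coords):
    n = len(coords)
    return make_frame(
        coords, ["C"] * n, [False] * (n - 1) + [True], resids=[1] * (n - 1) + [999]
    )


def test_rmsd_zero_on_identity_and_translation():
    rng = np.random.default_rng(0)
    ref = toy(rng.normal(0, 2, (4, 3)))
    assert rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)
    shifted = toy(ref.coordinates + np.array([5.0, 0.0, 0.0]))
    assert rmsd(shifted, ref, do_fit=True) == pytest.approx(0.0, abs=1e-9)
    assert rmsd(shifted, ref, do_fit=False) == pytest.approx(5.0)


def test_fitted_rmsd_matches_grid_oracle_on_toys():
    rng = np.random.default_rng(42)
    for _ in range(3):
        ref = toy(rng.normal(0, 2, (3, 3)))
        mob = toy(ref.coordinates + rng.normal(0, 0.5, (3, 3)))
        fitted = rmsd(mob, ref, do_fit=True)
        oracle = grid_rmsd_oracle(mob.coordinates, ref.coordinates)
        assert abs(fitted - oracle) < 1e-3


def test_fit_never_worse_than_no_fit():
    rng = np.random.default_rng(9)
    for _ in range(5):
        ref = toy(rng.normal(0, 2, (6, 3)))
        mob = toy(
            Rotation.random(random_state=rng.integers(1 << 16)).apply(ref.coordinates)
            + rng.normal(0, 1, 3)
        )
        assert rmsd(mob, ref, do_fit=True) <= rmsd(mob, ref, do_fit=False) + 1e-12


def test_rmsd_selection_and_mismatch():
    rng = np.random.default_rng(2)
    ref = toy(rng.normal(0, 2, (5, 3)))
    mob = toy(ref.coordinates + rng.normal(0, 0.1, (5, 3)))
    sel = np.array([True, True, True, False, False])
    assert rmsd(mob, ref, fit_selection=sel) >= 0
    small = toy(rng.normal(0, 2, (4, 3)))
    with pytest.raises(ValueError, match="atom count"):
        rmsd(small, ref)
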