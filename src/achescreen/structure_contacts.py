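"""Geometric receptor–ligand contact analysis on multi-model PDB frames.

Three detections, all purely geometric:

* hydrogen bonds — donor–H···acceptor triples across the receptor/ligand
  interface passing an angle-at-hydrogen test (acceptor–hydrogen–donor
  >= 135 deg) and a donor–acceptor distance test (<= 3.5 A);
* side-chain (heavy-atom) contacts — a receptor residue counts as in
  contact when any of its non-hydrogen atoms is within 4.5 A of any ligand
  non-hydrogen atom;
* RMSD — optionally after least-squares rigid-body superposition.

Per-residue contact probabilities over a trajectory are reported as the
fraction of frames in which the residue forms at least one qualifying
contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Frame",
    "ContactCriteria",
    "ContactProfile",
    "load_trajectory",
    "write_multimodel_pdb",
    "detect_hbonds",
    "detect_sc_contacts",
    "contact_probability",
    "rmsd",
]

# Covalent radii (A) for bond inference; sparse on purpose — the elements a
# receptor/ligand interface analysis actually meets.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 0.9
_BOND_TOLERANCE = 1.2  # bonded if d < 1.2 * (r_i + r_j)

_DONOR_ELEMENTS = frozenset({"N", "O", "S"})
_ACCEPTOR_ELEMENTS = frozenset({"N", "O"})


@dataclass
class Frame:
    """One set of coordinates with atom/residue labels and a ligand mask."""

    coordinates: np.ndarray  # (n_atoms, 3) in A
    elements: np.ndarray  # str per atom, upper-case symbol
    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray  # int per atom
    chains: np.ndarray
    ligand_mask: np.ndarray  # bool per atom

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        n = self.coordinates.shape[0]
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        for attr in ("elements", "atom_names", "residue_names", "residue_ids",
                     "chains", "ligand_mask"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length != n_atoms")
        n_lig = int(self.ligand_mask.sum())
        if n_lig == 0 or n_lig == n:
            raise ValueError("ligand_mask must select at least one atom and not all")

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])

    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) == "H"


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric gates for hydrogen bonds and heavy-atom contacts."""

    hb_angle_min: float = 135.0  # deg, at the hydrogen (acceptor-H-donor)
    hb_da_max: float = 3.5  # A, donor-acceptor
    sc_max: float = 4.5  # A, non-hydrogen pair
    accept_sulfur: bool = False  # treat S as HB acceptor
    side_chain_only: bool = False  # restrict SC contacts to side-chain atoms

    def __post_init__(self) -> None:
        if min(self.hb_angle_min, self.hb_da_max, self.sc_max) <= 0:
            raise ValueError("contact criteria must be positive")


@dataclass
class ContactProfile:
    """Per-residue HB/SC contact probabilities over a trajectory."""

    table: pd.DataFrame  # residue_id, residue_name, hb_probability, sc_probability
    n_frames: int

    def probability(self, residue_id: int, kind: str = "sc") -> float:
        row = self.table.loc[self.table.residue_id == residue_id]
        if row.empty:
            return 0.0
        return float(row.iloc[0][f"{kind}_probability"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["n_frames"] = self.n_frames
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PDB I/O

def load_trajectory(
    path: str | Path,
    ligand_resname: str | None = None,
    ligand_chain: str | None = None,
) -> list[Frame]:
    """Read a (multi-MODEL) PDB file into a list of :class:`Frame`.

    Model order defines frame order.  The ligand is selected by residue name
    and/or chain identifier; at least one selector is required.
    """
    import MDAnalysis as mda

    if ligand_resname is None and ligand_chain is None:
        raise ValueError("select the ligand by residue name or chain")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses/elements noisily
        u = mda.Universe(str(path))
    atoms = u.atoms
    try:
        elements = np.array([e.upper() for e in atoms.elements], dtype=object)
    except (AttributeError, mda.exceptions.NoDataError):
        elements = np.array(
            [_element_from_name(n) for n in atoms.names], dtype=object
        )
    # Fill blanks left by a sparse element column
    blank = np.array([not str(e).strip() for e in elements])
    if blank.any():
        names = np.asarray(atoms.names, dtype=object)
        elements[blank] = [_element_from_name(n) for n in names[blank]]
    try:
        chains = np.asarray(atoms.chainIDs, dtype=object)
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([""] * len(atoms), dtype=object)

    mask = np.ones(len(atoms), dtype=bool)
    if ligand_resname is not None:
        mask &= np.asarray(atoms.resnames, dtype=object) == ligand_resname
    if ligand_chain is not None:
        mask &= chains == ligand_chain

    frames = []
    for _ in u.trajectory:
        frames.append(
            Frame(
                coordinates=atoms.positions.astype(float).copy(),
                elements=elements.copy(),
                atom_names=np.asarray(atoms.names, dtype=object),
                residue_names=np.asarray(atoms.resnames, dtype=object),
                residue_ids=np.asarray(atoms.resids, dtype=int),
                chains=chains,
                ligand_mask=mask.copy(),
            )
        )
    return frames


def _element_from_name(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_multimodel_pdb(frames: list[Frame], path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL records with element columns filled."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, fr in enumerate(frames, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for j in range(fr.n_atoms):
                x, y, z = fr.coordinates[j]
                record = "HETATM" if fr.ligand_mask[j] else "ATOM  "
                name = str(fr.atom_names[j])[:4]
                fh.write(
                    f"{record}{j + 1:5d} {name:<4s} {str(fr.residue_names[j])[:3]:>3s} "
                    f"{str(fr.chains[j])[:1] or 'A':1s}{int(fr.residue_ids[j]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{str(fr.elements[j])[:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Detections

def _covalent_pairs(frame: Frame, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Boolean (len(idx_a), len(idx_b)) matrix of distance-inferred bonds."""
    coords = frame.coordinates
    d = cdist(coords[idx_a], coords[idx_b])
    ra = np.array(
        [_COVALENT_RADII.get(str(frame.elements[i]).upper(), _DEFAULT_RADIUS)
         for i in idx_a]
    )
    rb = np.array(
        [_COVALENT_RADII.get(str(frame.elements[i]).upper(), _DEFAULT_RADIUS)
         for i in idx_b]
    )
    return d < _BOND_TOLERANCE * (ra[:, None] + rb[None, :])


def _donor_hydrogen_pairs(frame: Frame, subset: np.ndarray) -> list[tuple[int, int]]:
    """(donor_idx, hydrogen_idx) pairs within ``subset`` (atom indices)."""
    elems = np.char.upper(frame.elements.astype(str))
    hyd = subset[elems[subset] == "H"]
    heavy = subset[np.isin(elems[subset], sorted(_DONOR_ELEMENTS))]
    if hyd.size == 0 or heavy.size == 0:
        return []
    bonded = _covalent_pairs(frame, heavy, hyd)
    pairs = []
    for hj, h in enumerate(hyd):
        partners = heavy[bonded[:, hj]]
        if partners.size == 0:
            continue
        # closest donor-capable heavy atom owns the hydrogen
        dists = np.linalg.norm(
            frame.coordinates[partners] - frame.coordinates[h], axis=1
        )
        pairs.append((int(partners[np.argmin(dists)]), int(h)))
    return pairs


def detect_hbonds(
    frame: Frame, criteria: ContactCriteria = ContactCriteria()
) -> list[tuple[int, int, int]]:
    """Receptor–ligand hydrogen bonds as (donor, hydrogen, acceptor) indices.

    Donors are N/O/S atoms with a covalently bound hydrogen (bonds inferred
    by distance against covalent radii); acceptors are N/O (S with the
    ``accept_sulfur`` flag).  A triple qualifies when the donor–acceptor
    distance is <= ``hb_da_max`` and the acceptor–hydrogen–donor angle at
    the hydrogen is >= ``hb_angle_min``.  Both interface directions are
    scanned.  A frame with no hydrogens yields an empty list with a warning.
    """
    if not frame.is_hydrogen().any():
        warnings.warn("frame contains no hydrogens; no HBs detectable", stacklevel=2)
        return []
    acceptor_elems = _ACCEPTOR_ELEMENTS | ({"S"} if criteria.accept_sulfur else set())
    elems = np.char.upper(frame.elements.astype(str))
    lig = np.flatnonzero(frame.ligand_mask)
    rec = np.flatnonzero(~frame.ligand_mask)

    out: list[tuple[int, int, int]] = []
    for donor_side, acceptor_side in ((rec, lig), (lig, rec)):
        acceptors = acceptor_side[np.isin(elems[acceptor_side], sorted(acceptor_elems))]
        if acceptors.size == 0:
            continue
        for donor, hyd in _donor_hydrogen_pairs(frame, donor_side):
            d_da = np.linalg.norm(
                frame.coordinates[acceptors] - frame.coordinates[donor], axis=1
            )
            for acc, dist in zip(acceptors[d_da <= criteria.hb_da_max],
                                 d_da[d_da <= criteria.hb_da_max]):
                v1 = frame.coordinates[acc] - frame.coordinates[hyd]
                v2 = frame.coordinates[donor] - frame.coordinates[hyd]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= criteria.hb_angle_min:
                    out.append((int(donor), int(hyd), int(acc)))
    return out


_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


def detect_sc_contacts(
    frame: Frame, criteria: ContactCriteria = ContactCriteria()
) -> set[int]:
    """Receptor residue ids with a heavy atom within ``sc_max`` of the ligand.

    Hydrogens never count.  With ``criteria.side_chain_only`` backbone atoms
    (N/CA/C/O) are excluded from the receptor side.
    """
    heavy = ~frame.is_hydrogen()
    lig = frame.ligand_mask & heavy
    rec = ~frame.ligand_mask & heavy
    if criteria.side_chain_only:
        backbone = np.isin(
            np.char.upper(frame.atom_names.astype(str)), sorted(_BACKBONE_NAMES)
        )
        rec &= ~backbone
    lig_idx = np.flatnonzero(lig)
    rec_idx = np.flatnonzero(rec)
    if lig_idx.size == 0 or rec_idx.size == 0:
        return set()
    d = cdist(frame.coordinates[rec_idx], frame.coordinates[lig_idx])
    close = (d <= criteria.sc_max).any(axis=1)
    return {int(r) for r in frame.residue_ids[rec_idx[close]]}


def contact_probability(
    frames: list[Frame], criteria: ContactCriteria = ContactCriteria()
) -> ContactProfile:
    """Fraction of frames in which each receptor residue forms HB/SC contacts.

    A residue scores a frame when it participates in at least one qualifying
    hydrogen bond (on either side of the bond) or heavy-atom contact.
    """
    if not frames:
        raise ValueError("need at least one frame")
    n_atoms = frames[0].n_atoms
    for fr in frames[1:]:
        if fr.n_atoms != n_atoms:
            raise ValueError("inconsistent atom count across frames")
    rec_mask = ~frames[0].ligand_mask
    resids = frames[0].residue_ids[rec_mask]
    resnames = frames[0].residue_names[rec_mask]
    order = []
    names = {}
    for rid, rname in zip(resids, resnames):
        if int(rid) not in names:
            order.append(int(rid))
            names[int(rid)] = str(rname)

    hb_counts = {rid: 0 for rid in order}
    sc_counts = {rid: 0 for rid in order}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hydrogen-free frames warn per frame
        for fr in frames:
            hb_res = set()
            for donor, _h, acc in detect_hbonds(fr, criteria):
                for idx in (donor, acc):
                    if not fr.ligand_mask[idx]:
                        hb_res.add(int(fr.residue_ids[idx]))
            for rid in hb_res:
                if rid in hb_counts:
                    hb_counts[rid] += 1
            for rid in detect_sc_contacts(fr, criteria):
                if rid in sc_counts:
                    sc_counts[rid] += 1

    n = len(frames)
    table = pd.DataFrame(
        {
            "residue_id": order,
            "residue_name": [names[r] for r in order],
            "hb_probability": [hb_counts[r] / n for r in order],
            "sc_probability": [sc_counts[r] / n for r in order],
        }
    )
    return ContactProfile(table=table, n_frames=n)


# ---------------------------------------------------------------------------
# RMSD

def rmsd(
    frame: Frame,
    reference: Frame,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    do_fit: bool = True,
) -> float:
    """RMSD (A) between a frame and a reference, optionally after fitting.

    With ``do_fit`` the frame is superposed onto the reference by the
    optimal least-squares rigid-body transform (Kabsch) computed on
    ``fit_selection`` (boolean mask or index array; default all atoms),
    then the RMSD is measured over ``measure_selection`` (default: the fit
    selection).
    """
    if frame.n_atoms != reference.n_atoms:
        raise ValueError("atom count mismatch with reference")
    fit_idx = _as_index(fit_selection, frame.n_atoms)
    meas_idx = (
        fit_idx if measure_selection is None
        else _as_index(measure_selection, frame.n_atoms)
    )
    if fit_idx.size == 0 or meas_idx.size == 0:
        raise ValueError("empty atom selection")

    mobile = frame.coordinates
    target = reference.coordinates
    if do_fit:
        mob_c = mobile[fit_idx].mean(axis=0)
        tgt_c = target[fit_idx].mean(axis=0)
        rot, _ = Rotation.align_vectors(
            target[fit_idx] - tgt_c, mobile[fit_idx] - mob_c
        )
        mobile = rot.apply(mobile - mob_c) + tgt_c
    diff = mobile[meas_idx] - target[meas_idx]
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def _as_index(selection: np.ndarray | None, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.size != n_atoms:
            raise ValueError("boolean selection length mismatch")
        return np.flatnonzero(sel)
    return sel.astype(int)
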