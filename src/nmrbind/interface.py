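"""Geometric detection of hydrogen bonds and stacking at interfaces.

Hydrogen bonds are called on distance and, when an explicit hydrogen is
present, the donor-H-acceptor angle:

    d(D, A) <= d_max   (default 3.5 A)
    angle(D-H...A) >= theta_min   (default 120 deg, only if H present)

Donor/acceptor typing comes from residue templates for the 20 amino acids
and the 4 ribonucleotides, shipped as TSV package data.  Stacking contacts
between aromatic rings (and ring vs phosphate / aliphatic C-H) are measured
by centroid distance, interplanar angle, and lateral offset; centroids are
unweighted centers of geometry.  Classification thresholds follow common
MD-analysis conventions and are configurable — the field has no single
standard, so every measured value is reported alongside its label.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import AtomSet, Trajectory, buried_surface_area

RNA_RESIDUES = {"A", "C", "G", "U"}

# Aromatic ring definitions: residue -> tuple of ring-atom names.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),  # 6-ring of the indole
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    # nucleotide bases: the 6-membered ring (shared by purines/pyrimidines)
    "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O1P", "O2P")
RIBOSE_CARBONS = ("C1'", "C2'", "C3'", "C4'", "C5'")


def _load_templates(name: str) -> set[tuple[str, str]]:
    text = (
        importlib.resources.files("nmrbind.data").joinpath(name).read_text()
    )
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            res, atom = line.split("\t")
            out.add((res, atom))
    return out


DONOR_TEMPLATES = _load_templates("hbond_donors.tsv")
ACCEPTOR_TEMPLATES = _load_templates("hbond_acceptors.tsv")


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5          # A, donor-acceptor heavy-atom distance
    theta_min: float = 120.0    # deg, D-H...A angle when H present
    h_bond_length: float = 1.25  # A, max covalent D-H distance for pairing H


@dataclass(frozen=True)
class StackCriteria:
    d_pipi: float = 5.5      # A, ring-ring centroid cutoff
    d_chpi: float = 4.5      # A, aliphatic C to ring centroid
    d_anpi: float = 5.0      # A, phosphate centroid to ring centroid
    parallel_max_angle: float = 30.0   # deg
    tshaped_min_angle: float = 60.0    # deg
    displaced_min_offset: float = 1.0  # A


@dataclass
class HBond:
    donor: int          # atom index in the AtomSet
    acceptor: int
    hydrogen: int | None
    distance_DA: float  # A
    angle_DHA: float | None  # deg

    def key(self) -> tuple[int, int]:
        return (self.donor, self.acceptor)


@dataclass
class StackContact:
    group_a: str
    group_b: str
    kind: str  # pi_pi_parallel | pi_pi_displaced | pi_pi_tshaped | ch_pi | anion_pi
    centroid_distance: float
    interplanar_angle: float | None
    lateral_offset: float | None


def _atom_label(atoms: pd.DataFrame, i: int) -> str:
    r = atoms.iloc[i]
    return f"{r['chain']}/{r['residue_name']}{r['residue_number']}/{r['atom_name']}"


# ---------------------------------------------------------------------------
# Hydrogen bonds

def _typed_atoms(model: AtomSet, templates: set[tuple[str, str]]) -> np.ndarray:
    keys = list(zip(model.atoms["residue_name"], model.atoms["atom_name"]))
    return np.array([k in templates for k in keys])


def _attached_hydrogens(model: AtomSet, donor_idx: int, max_dist: float) -> list[int]:
    atoms = model.atoms
    same_res = (
        (atoms["chain"] == atoms.at[donor_idx, "chain"])
        & (atoms["residue_number"] == atoms.at[donor_idx, "residue_number"])
        & (atoms["element"] == "H")
    ).to_numpy()
    cand = np.flatnonzero(same_res)
    if len(cand) == 0:
        return []
    d = np.linalg.norm(model.coords[cand] - model.coords[donor_idx], axis=1)
    return cand[d <= max_dist].tolist()


def detect_hbonds(
    model: AtomSet,
    group_a: np.ndarray,
    group_b: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Cross-partition hydrogen bonds under distance/angle criteria.

    Donors in one group are paired with acceptors in the other (both
    directions).  When the donor carries at least one explicit hydrogen,
    the best (largest) D-H...A angle must clear ``theta_min``; with no
    hydrogens the call is distance-only.  Atoms of residues without a
    template are skipped.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    donors = _typed_atoms(model, DONOR_TEMPLATES)
    acceptors = _typed_atoms(model, ACCEPTOR_TEMPLATES)
    bonds: list[HBond] = []
    for d_group, a_group in ((group_a, group_b), (group_b, group_a)):
        d_idx = np.flatnonzero(donors & d_group)
        a_idx = np.flatnonzero(acceptors & a_group)
        if len(d_idx) == 0 or len(a_idx) == 0:
            continue
        dist = np.linalg.norm(
            model.coords[d_idx][:, None, :] - model.coords[a_idx][None, :, :],
            axis=2,
        )
        for di, ai in zip(*np.nonzero(dist <= criteria.d_max)):
            donor, acceptor = int(d_idx[di]), int(a_idx[ai])
            hydrogens = _attached_hydrogens(model, donor, criteria.h_bond_length)
            best_h, best_angle = None, None
            for h in hydrogens:
                ang = _angle(
                    model.coords[donor], model.coords[h], model.coords[acceptor]
                )
                if best_angle is None or ang > best_angle:
                    best_h, best_angle = h, ang
            if best_angle is not None and best_angle < criteria.theta_min:
                continue
            bonds.append(
                HBond(
                    donor=donor, acceptor=acceptor, hydrogen=best_h,
                    distance_DA=float(dist[di, ai]), angle_DHA=best_angle,
                )
            )
    return bonds


def _angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - vertex, c - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_occupancy(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    interval_ns: float | None = None,
) -> dict:
    """Per-bond occupancy fractions and per-interval mean bond counts.

    A bond's identity is its (donor atom, acceptor atom) pair; occupancy is
    the exact fraction of frames in which the pair satisfies the criteria.
    ``interval_ns`` (default: one frame) sets the width of the time bins
    used for the stacked-bar-style count summary.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    per_frame: list[set[tuple[int, int]]] = []
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.model(f), group_a, group_b, criteria)
        per_frame.append({b.key() for b in bonds})
    all_keys = sorted(set().union(*per_frame))
    occupancy = {
        key: sum(key in frame for frame in per_frame) / traj.n_frames
        for key in all_keys
    }
    counts = np.array([len(frame) for frame in per_frame])
    interval = interval_ns if interval_ns is not None else traj.frame_spacing
    frames_per_bin = max(1, int(round(interval / traj.frame_spacing)))
    bins = [
        counts[i: i + frames_per_bin].mean()
        for i in range(0, traj.n_frames, frames_per_bin)
    ]
    labels = {
        key: (
            _atom_label(traj.atoms, key[0]),
            _atom_label(traj.atoms, key[1]),
        )
        for key in all_keys
    }
    return {
        "occupancy": occupancy,
        "labels": labels,
        "per_frame_counts": counts,
        "interval_counts": np.array(bins),
        "interval_ns": frames_per_bin * traj.frame_spacing,
    }


def occupancy_to_tsv(result: dict, path) -> None:
    rows = [
        (
            result["labels"][k][0], result["labels"][k][1],
            result["occupancy"][k],
        )
        for k in sorted(result["occupancy"])
    ]
    pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


# ---------------------------------------------------------------------------
# Stacking

def _residue_groups(model: AtomSet, mask: np.ndarray):
    """Yield (label, kind, indices) for rings, phosphates, ribose carbons and
    aliphatic carbons within a partition."""
    atoms = model.atoms
    sub = atoms[mask]
    for (chain, resnum, resname), g in sub.groupby(
        ["chain", "residue_number", "residue_name"], sort=True
    ):
        label = f"{chain}/{resname}{resnum}"
        names = set(g["atom_name"])
        if resname in RING_ATOMS and set(RING_ATOMS[resname]) <= names:
            idx = [
                g.index[g["atom_name"] == a][0] for a in RING_ATOMS[resname]
            ]
            yield label + "/ring", "ring", np.array(idx)
        if resname in RNA_RESIDUES:
            phos = g.index[g["atom_name"].isin(PHOSPHATE_ATOMS)].to_numpy()
            if len(phos) >= 2:
                yield label + "/phosphate", "anion", phos
            rib = g.index[g["atom_name"].isin(RIBOSE_CARBONS)].to_numpy()
            for i in rib:
                yield f"{label}/{atoms.at[i, 'atom_name']}", "ch", np.array([i])
        elif resname not in RING_ATOMS:
            # aliphatic carbons of non-aromatic amino acids (CH-pi donors)
            ali = g.index[
                (g["element"] == "C") & (~g["atom_name"].isin(("C", "O")))
            ].to_numpy()
            for i in ali:
                yield f"{label}/{atoms.at[i, 'atom_name']}", "ch", np.array([i])


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def detect_stacking(
    model: AtomSet,
    group_a: np.ndarray,
    group_b: np.ndarray,
    criteria: StackCriteria = StackCriteria(),
) -> list[StackContact]:
    """Cross-partition stacking contacts with measured geometry.

    pi-pi: two rings with centroid distance <= d_pipi; interplanar angle
    <= 30 deg is the parallel family (lateral offset > 1 A makes it
    displaced), >= 60 deg is T-shaped; intermediate angles meet no class
    and are not reported.  CH-pi: aliphatic/ribose carbon within d_chpi of
    a ring centroid.  Anion-pi: phosphate-group centroid within d_anpi.
    """
    ga = list(_residue_groups(model, np.asarray(group_a, bool)))
    gb = list(_residue_groups(model, np.asarray(group_b, bool)))
    contacts: list[StackContact] = []
    for la, ka, ia in ga:
        ca = model.coords[ia].mean(axis=0)
        for lb, kb, ib in gb:
            cb = model.coords[ib].mean(axis=0)
            d = float(np.linalg.norm(cb - ca))
            if ka == "ring" and kb == "ring":
                if d > criteria.d_pipi:
                    continue
                na = _plane_normal(model.coords[ia])
                nb = _plane_normal(model.coords[ib])
                angle = float(np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0, 1))))
                offset = _lateral_offset(ca, cb, na, nb)
                kind = None
                if angle <= criteria.parallel_max_angle:
                    kind = (
                        "pi_pi_displaced"
                        if offset > criteria.displaced_min_offset
                        else "pi_pi_parallel"
                    )
                elif angle >= criteria.tshaped_min_angle:
                    kind = "pi_pi_tshaped"
                if kind:
                    contacts.append(
                        StackContact(la, lb, kind, d, angle, offset)
                    )
            elif ("ring" in (ka, kb)) and ("anion" in (ka, kb)):
                if d <= criteria.d_anpi:
                    contacts.append(StackContact(la, lb, "anion_pi", d, None, None))
            elif ("ring" in (ka, kb)) and ("ch" in (ka, kb)):
                if d <= criteria.d_chpi:
                    contacts.append(StackContact(la, lb, "ch_pi", d, None, None))
    return contacts


def _lateral_offset(
    ca: np.ndarray, cb: np.ndarray, na: np.ndarray, nb: np.ndarray
) -> float:
    """Offset of the centroid-centroid vector projected onto the mean ring
    plane (normals aligned before averaging)."""
    if np.dot(na, nb) < 0:
        nb = -nb
    n_mean = na + nb
    n_mean /= np.linalg.norm(n_mean)
    v = cb - ca
    return float(np.linalg.norm(v - np.dot(v, n_mean) * n_mean))


# ---------------------------------------------------------------------------
# Interface residues by buried surface area

def interface_residues(
    complex_model: AtomSet,
    group_a: np.ndarray,
    group_b: np.ndarray,
    bsa_threshold: float = 0.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Residues with buried surface area above a threshold, largest first."""
    result = buried_surface_area(complex_model, group_a, group_b, probe, n_points)
    per_res = result["per_residue"]
    out = per_res[per_res["bsa"] > bsa_threshold].sort_values(
        "bsa", ascending=False
    )
    return out.reset_index(drop=True)
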