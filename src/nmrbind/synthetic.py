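"""Synthetic data generators with known ground truth.

Every generator is bit-reproducible from its seed and returns its ground
truth alongside the data, so downstream tests never infer truth from the
data itself.  The defaults emulate the study conditions this package is
built around: a ~97-residue RRM domain (numbered from 231) with two CSP
hotspot clusters on the RNA-binding face, a 20-model NMR ensemble with an
ordered core and disordered termini, short MD-like trajectories with
hydrogen bonds of prescribed occupancy, and idealized stacking geometries.

Geometry fixtures use idealized regular hexagons (1.39 A bond length)
rather than residue templates, so centroids and plane normals have exact
closed forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csp import ResonanceEntry, ShiftTable
from .structure import AtomSet, Ensemble, Trajectory

RING_RADIUS = 1.39  # A, regular hexagon bond length == circumradius


@dataclass
class GeneratorSpec:
    """Sizes, effects and noise levels for the synthetic generators."""

    seed: int = 0
    # sizes
    n_residues: int = 97
    first_residue: int = 231
    n_models: int = 20
    n_frames: int = 20
    frame_spacing: float = 0.5  # ns (10 ns trajectory over 20 frames)
    # CSP effects (ppm)
    hotspots: tuple[tuple[int, int], ...] = ((262, 267), (270, 275))
    hotspot_dd_h: float = 0.20
    hotspot_dd_n: float = 1.00
    noise_h: float = 0.01
    noise_n: float = 0.05
    unobserved: tuple[int, ...] = ()  # e.g. proline positions
    # ensemble geometry (A)
    core_range: tuple[int, int] = (20, 80)
    sigma_core: float = 0.2
    sigma_tail: float = 2.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Chemical shift tables

def make_shift_pair(
    spec: GeneratorSpec,
) -> tuple[ShiftTable, ShiftTable, set[int]]:
    """Free/bound amide shift tables with planted perturbation hotspots.

    Free shifts are drawn uniformly from plausible amide ranges (H 7.5-9.5,
    N 105-130 ppm; placeholders, not predictions).  Bound shifts add the
    hotspot effect on hotspot residues and Gaussian noise everywhere else.
    Returns (free, bound, hotspot residue set).
    """
    rng = spec.rng()
    residues = list(
        range(spec.first_residue, spec.first_residue + spec.n_residues)
    )
    hot: set[int] = set()
    for lo, hi in spec.hotspots:
        if lo < spec.first_residue or hi >= spec.first_residue + spec.n_residues:
            raise ValueError(f"hotspot range ({lo}, {hi}) outside residue span")
        span = set(range(lo, hi + 1))
        if hot & span:
            warnings.warn("overlapping hotspot ranges merged")
        hot |= span

    free_entries, bound_entries = [], []
    for r in residues:
        if r in spec.unobserved:
            continue
        h = rng.uniform(7.5, 9.5)
        n = rng.uniform(105.0, 130.0)
        free_entries += [
            ResonanceEntry(r, "X", "H", h),
            ResonanceEntry(r, "X", "N", n),
        ]
        if r in hot:
            bh, bn = h + spec.hotspot_dd_h, n + spec.hotspot_dd_n
        else:
            bh = h + rng.normal(0.0, spec.noise_h)
            bn = n + rng.normal(0.0, spec.noise_n)
        bound_entries += [
            ResonanceEntry(r, "X", "H", bh),
            ResonanceEntry(r, "X", "N", bn),
        ]
    free = ShiftTable(free_entries, state_label="free")
    bound = ShiftTable(bound_entries, state_label="bound")
    return free, bound, hot


# ---------------------------------------------------------------------------
# Coordinate ensembles

def _ideal_backbone(n_residues: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Extended backbone trace: N, CA, C per residue along a gentle helix,
    so the chain is never collinear."""
    rows, xyz = [], []
    for i in range(n_residues):
        t = 0.35 * i
        ca = np.array([3.0 * i, 4.0 * np.cos(t), 4.0 * np.sin(t)])
        offsets = {"N": np.array([-1.2, 0.8, 0.0]), "CA": np.zeros(3),
                   "C": np.array([1.2, 0.8, 0.0])}
        for name in ("N", "CA", "C"):
            rows.append(("A", i + 1, "ALA", name, name[0]))
            xyz.append(ca + offsets[name])
    atoms = pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name",
                       "atom_name", "element"],
    )
    return atoms, np.array(xyz)


def make_ensemble(spec: GeneratorSpec) -> tuple[Ensemble, dict]:
    """Multi-model ensemble with a rigid core and noisy tails.

    Per-residue, per-coordinate Gaussian jitter with SD ``sigma_core``
    inside ``core_range`` and ``sigma_tail`` outside.  Returns the ensemble
    and truth: the planted per-residue sigma profile and the core range.
    """
    if spec.n_models < 2:
        raise ValueError("n_models must be >= 2")
    rng = spec.rng()
    atoms, ideal = _ideal_backbone(spec.n_residues)
    resnum = atoms["residue_number"].to_numpy()
    lo, hi = spec.core_range
    sigma_res = {
        r: spec.sigma_core if lo <= r <= hi else spec.sigma_tail
        for r in range(1, spec.n_residues + 1)
    }
    sigma_atom = np.array([sigma_res[r] for r in resnum])
    models = np.stack([
        ideal + rng.normal(0.0, 1.0, ideal.shape) * sigma_atom[:, None]
        for _ in range(spec.n_models)
    ])
    ens = Ensemble(atoms=atoms, coords=models, source_label="synthetic")
    return ens, {"sigma_profile": sigma_res, "core_range": spec.core_range}


def make_trajectory(spec: GeneratorSpec) -> tuple[Trajectory, dict]:
    """Like :func:`make_ensemble` but frames encode time."""
    ens, truth = make_ensemble(
        GeneratorSpec(**{**spec.__dict__, "n_models": spec.n_frames})
    )
    traj = Trajectory(
        atoms=ens.atoms, coords=ens.coords,
        source_label="synthetic", frame_spacing=spec.frame_spacing,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Hydrogen-bond trajectories

def make_hbond_trajectory(
    schedules: list[list[bool]] | list[float],
    n_frames: int | None = None,
    frame_spacing: float = 0.5,
) -> tuple[Trajectory, np.ndarray, np.ndarray, list[list[bool]]]:
    """Trajectory of donor-acceptor pairs toggled bonded/broken per frame.

    Each schedule is either an explicit per-frame bonded flag list or an
    occupancy fraction (converted to exactly round(occ*n_frames) leading
    bonded frames).  Bonded geometry is a linear N-H...O arrangement at
    2.9 A donor-acceptor distance (angle 170 deg by construction margin);
    broken geometry moves the acceptor to 6 A.  Pairs are spaced 25 A
    apart so they never cross-detect.

    Returns (trajectory, group_a mask, group_b mask, resolved schedules).
    """
    resolved: list[list[bool]] = []
    for s in schedules:
        if isinstance(s, (int, float)):
            if not 0.0 <= s <= 1.0:
                raise ValueError("occupancy must be in [0, 1]")
            if n_frames is None:
                raise ValueError("n_frames required with fractional schedules")
            k = round(float(s) * n_frames)
            resolved.append([i < k for i in range(n_frames)])
        else:
            resolved.append(list(s))
    n = len(resolved[0])
    if any(len(s) != n for s in resolved):
        raise ValueError("all schedules must have equal frame counts")

    rows, donor_pos = [], []
    for b in range(len(resolved)):
        origin = np.array([25.0 * b, 0.0, 0.0])
        # donor: lysine side-chain amine with one explicit hydrogen
        rows.append(("A", b + 1, "LYS", "NZ", "N"))
        rows.append(("A", b + 1, "LYS", "HZ1", "H"))
        # acceptor: RNA backbone O3'
        rows.append(("B", 100 + b, "A", "O3'", "O"))
        donor_pos.append(origin)

    frames = []
    for f in range(n):
        xyz = []
        for b, origin in enumerate(donor_pos):
            xyz.append(origin)                          # NZ
            xyz.append(origin + np.array([1.0, 0.0, 0.0]))  # HZ1
            d_da = 2.9 if resolved[b][f] else 6.0
            xyz.append(origin + np.array([d_da, 0.0, 0.0]))  # O3'
        frames.append(np.array(xyz))

    atoms = pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name",
                       "atom_name", "element"],
    )
    traj = Trajectory(
        atoms=atoms, coords=np.stack(frames),
        source_label="synthetic-hbond", frame_spacing=frame_spacing,
    )
    group_a = (atoms["chain"] == "A").to_numpy()
    group_b = (atoms["chain"] == "B").to_numpy()
    return traj, group_a, group_b, resolved


# ---------------------------------------------------------------------------
# Stacking fixtures

def _hexagon(names: tuple[str, ...], resname: str) -> np.ndarray:
    angles = np.radians(60.0 * np.arange(len(names)))
    return np.column_stack([
        RING_RADIUS * np.cos(angles),
        RING_RADIUS * np.sin(angles),
        np.zeros(len(names)),
    ])


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(a), -np.sin(a)],
        [0.0, np.sin(a), np.cos(a)],
    ])


def make_stack_fixture(
    kind: str,
    distance: float,
    angle_deg: float = 0.0,
    offset: float = 0.0,
) -> tuple[AtomSet, np.ndarray, np.ndarray, dict]:
    """Two groups at exact centroid distance, interplanar angle and offset.

    ``pi_pi``: an idealized Phe ring (chain A) and a pyrimidine 6-ring
    (chain B); ring B is tilted by ``angle_deg`` about the offset axis and
    its centroid placed so that the centroid distance, interplanar angle
    and mean-plane lateral offset all equal the requested values exactly.
    ``anion_pi``: Phe ring vs an RNA phosphate group whose centroid sits at
    ``distance`` along the ring normal.  ``ch_pi``: Phe ring vs a ribose
    carbon at ``distance``.

    Returns (atoms, group_a mask, group_b mask, truth geometry dict).
    """
    if min(distance, RING_RADIUS) <= 0:
        raise ValueError("geometry parameters must be positive")
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    rows = [("A", 1, "PHE", n, "C") for n in ring_names]
    xyz = list(_hexagon(ring_names, "PHE"))

    if kind == "pi_pi":
        if offset > distance:
            raise ValueError("offset cannot exceed centroid distance")
        base_names = ("N1", "C2", "N3", "C4", "C5", "C6")
        ringb = _hexagon(base_names, "C") @ _rotation_about_x(angle_deg).T
        # mean-plane normal of {z-hat, tilted normal} bisects the tilt; the
        # x axis lies in the mean plane, so an x offset is the lateral offset
        n_mean = _rotation_about_x(angle_deg / 2.0) @ np.array([0.0, 0.0, 1.0])
        h = np.sqrt(distance**2 - offset**2)
        centroid_b = offset * np.array([1.0, 0.0, 0.0]) + h * n_mean
        for name, pos in zip(base_names, ringb + centroid_b):
            rows.append(("B", 10, "C", name, name[0]))
            xyz.append(pos)
        truth = {"kind_family": "pi_pi", "centroid_distance": distance,
                 "interplanar_angle": angle_deg, "lateral_offset": offset}
    elif kind == "anion_pi":
        t = np.array([0.0, 0.0, distance])
        group = {
            "P": t + np.array([0.0, 0.0, 0.4]),
            "OP1": t + np.array([0.35, 0.0, -0.2]),
            "OP2": t + np.array([-0.35, 0.0, -0.2]),
        }
        for name, pos in group.items():
            rows.append(("B", 10, "C", name, name[0]))
            xyz.append(pos)
        truth = {"kind_family": "anion_pi", "centroid_distance": distance}
    elif kind == "ch_pi":
        rows.append(("B", 10, "C", "C1'", "C"))
        xyz.append(np.array([0.0, 0.0, distance]))
        truth = {"kind_family": "ch_pi", "centroid_distance": distance}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    atoms = pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name",
                       "atom_name", "element"],
    )
    model = AtomSet(atoms=atoms, coords=np.array(xyz))
    group_a = (atoms["chain"] == "A").to_numpy()
    group_b = (atoms["chain"] == "B").to_numpy()
    return model, group_a, group_b, truth
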