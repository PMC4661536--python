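"""Multi-model coordinate handling and ensemble statistics.

Coordinates live in an :class:`AtomSet` (atom metadata DataFrame + an
(n_atoms, 3) array, Angstrom) or an :class:`Ensemble` (shared roster +
(n_models, n_atoms, 3)).  On top of these: Kabsch superposition, ensemble
RMSD in two conventions, iterative detection of the ordered core, per-residue
RMSF over trajectories, Shrake-Rupley solvent-accessible surface areas with
a deterministic Fibonacci-lattice point set, buried surface areas, and
relative (fractional) SASA.

Backbone selection is atoms named N, CA, C (carbonyl O excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# Fixed van der Waals radii (Angstrom); hydrogens are included when present.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "H": 1.20}

BACKBONE_ATOMS = ("N", "CA", "C")

# Theoretical maximum per-residue accessibilities (Tien et al. 2013,
# PLoS ONE 8:e80635, "theoretical" column), Angstrom^2.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

ATOM_COLUMNS = ["chain", "residue_number", "residue_name", "atom_name", "element"]


@dataclass
class AtomSet:
    """One coordinate set: per-atom metadata plus an (n, 3) position array."""

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.atoms) != len(self.coords):
            raise ValueError("metadata and coordinate lengths differ")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        # positional indexing into coords relies on a clean RangeIndex
        self.atoms = self.atoms.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.atoms)

    def radii(self) -> np.ndarray:
        """Per-atom vdW radii; unknown elements are a hard error."""
        els = self.atoms["element"].to_numpy()
        missing = sorted({e for e in els if e not in VDW_RADII})
        if missing:
            names = self.atoms.loc[
                ~self.atoms["element"].isin(VDW_RADII), "atom_name"
            ].tolist()
            raise ValueError(f"no vdW radius for elements {missing} (atoms {names})")
        return np.array([VDW_RADII[e] for e in els])

    def subset(self, mask: np.ndarray) -> "AtomSet":
        mask = np.asarray(mask, dtype=bool)
        return AtomSet(self.atoms[mask].reset_index(drop=True), self.coords[mask])

    def select(self, expr: str) -> np.ndarray:
        return select(self.atoms, expr)


@dataclass
class Ensemble:
    """Ordered models sharing one atom roster (identical atoms, same order)."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_models, n_atoms, 3)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("roster and coordinate widths differ")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def model(self, i: int) -> AtomSet:
        return AtomSet(self.atoms, self.coords[i])

    def select(self, expr: str) -> np.ndarray:
        return select(self.atoms, expr)


@dataclass
class Trajectory(Ensemble):
    """An ensemble whose model order encodes time."""

    frame_spacing: float = 0.5  # ns

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.n_models


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def read_models(path: str | Path) -> Ensemble:
    """Read a single- or multi-model PDB file into an Ensemble.

    Keeps altloc A (and blank), keeps hydrogens when present, and enforces
    an identical atom roster across models — the first mismatching atom is
    named in the error.
    """
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")

    rosters = []
    coords = []
    for model in st:
        rows = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append((
                        chain.name, res.seqid.num, res.name.strip(),
                        atom.name.strip(), atom.element.name.upper() or "C",
                    ))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        rosters.append(rows)
        coords.append(np.array(xyz))

    ref = rosters[0]
    for mi, roster in enumerate(rosters[1:], start=2):
        if len(roster) != len(ref):
            raise ValueError(
                f"model {mi} has {len(roster)} atoms, model 1 has {len(ref)}"
            )
        for ai, (a, b) in enumerate(zip(ref, roster)):
            if a != b:
                raise ValueError(
                    f"atom roster mismatch at model {mi}, atom {ai + 1}: "
                    f"{b} vs {a}"
                )
    atoms = pd.DataFrame(ref, columns=ATOM_COLUMNS)
    return Ensemble(atoms=atoms, coords=np.stack(coords),
                    source_label=str(path))


def write_models(ensemble: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = ensemble.source_label or "nmrbind"
    rows = list(ensemble.atoms.itertuples(index=False))
    for mi in range(ensemble.n_models):
        model = gemmi.Model(mi + 1)
        # gemmi add_* methods copy, so build each container fully first
        chain_order: list[str] = []
        chains: dict[str, list[gemmi.Residue]] = {}
        res = None
        prev_key = None
        for ai, row in enumerate(rows):
            key = (row.chain, row.residue_number, row.residue_name)
            if key != prev_key:
                res = gemmi.Residue()
                res.name = row.residue_name
                res.seqid = gemmi.SeqId(row.residue_number, " ")
                if row.chain not in chains:
                    chains[row.chain] = []
                    chain_order.append(row.chain)
                chains[row.chain].append(res)
                prev_key = key
            atom = gemmi.Atom()
            atom.name = row.atom_name
            atom.element = gemmi.Element(row.element)
            x, y, z = ensemble.coords[mi, ai]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
        for cname in chain_order:
            chain = gemmi.Chain(cname)
            for res in chains[cname]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selections

def select(atoms: pd.DataFrame, expr: str) -> np.ndarray:
    """Boolean mask from a mini selection expression.

    Clauses joined by ``and``: ``chain A``, ``resi 231-276,280-323``,
    ``name N CA C`` (or comma-separated), ``backbone``, ``all``.
    """
    mask = np.ones(len(atoms), dtype=bool)
    for clause in expr.split(" and "):
        parts = clause.split()
        if not parts:
            continue
        kw = parts[0].lower()
        if kw == "all":
            continue
        if kw == "backbone":
            mask &= atoms["atom_name"].isin(BACKBONE_ATOMS).to_numpy()
        elif kw == "chain":
            mask &= atoms["chain"].isin(parts[1:]).to_numpy()
        elif kw == "name":
            names = [n for p in parts[1:] for n in p.split(",") if n]
            mask &= atoms["atom_name"].isin(names).to_numpy()
        elif kw == "resi":
            ok = np.zeros(len(atoms), dtype=bool)
            for rng in " ".join(parts[1:]).split(","):
                rng = rng.strip()
                if "-" in rng[1:]:
                    lo, hi = rng.rsplit("-", 1) if not rng.startswith("-") else (rng, rng)
                    lo_i, hi_i = int(lo), int(hi)
                else:
                    lo_i = hi_i = int(rng)
                ok |= (
                    (atoms["residue_number"] >= lo_i)
                    & (atoms["residue_number"] <= hi_i)
                ).to_numpy()
            mask &= ok
        else:
            raise ValueError(f"unknown selection keyword {kw!r} in {expr!r}")
    return mask


# ---------------------------------------------------------------------------
# Superposition and RMSD

def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns (rotation R, translation t, rmsd) such that
    ``mobile @ R.T + t`` best fits ``reference``; the returned RMSD is the
    global minimum over rigid transforms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("mobile and reference must be equal (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def ensemble_rmsd(
    ensemble: Ensemble,
    selection: str | np.ndarray = "backbone",
    mode: str = "pairwise_mean",
) -> dict:
    """Ensemble coordinate spread, in one of two conventions.

    ``pairwise_mean``: mean over all model pairs of the superposed RMSD.
    ``to_mean_structure``: mean RMSD to iteratively refined mean coordinates.
    Both are reported with their SD over pairs/models; the mode is recorded
    in the returned dict because the two conventions differ numerically.
    """
    mask = ensemble.select(selection) if isinstance(selection, str) else np.asarray(selection, bool)
    if not mask.any():
        raise ValueError(f"empty selection {selection!r}")
    if ensemble.n_models < 2:
        raise ValueError("need at least 2 models")
    X = ensemble.coords[:, mask, :]
    if mode == "pairwise_mean":
        vals = [
            superpose(X[j], X[i])[2]
            for i in range(len(X)) for j in range(i + 1, len(X))
        ]
    elif mode == "to_mean_structure":
        fitted, mean = _iterative_mean(X)
        vals = [
            float(np.sqrt(np.mean(np.sum((f - mean) ** 2, axis=1))))
            for f in fitted
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.asarray(vals)
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
        "mode": mode,
        "n_atoms": int(mask.sum()),
    }


def _iterative_mean(
    X: np.ndarray, max_iter: int = 20, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all models onto their evolving mean until it stabilizes."""
    fitted = X.copy()
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for i in range(len(fitted)):
            R, t, _ = superpose(fitted[i], mean)
            fitted[i] = apply_transform(fitted[i], R, t)
        new_mean = fitted.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return fitted, mean


def find_ordered_range(
    ensemble: Ensemble,
    cutoff: float = 1.5,
    selection: str = "backbone",
    max_iter: int = 20,
) -> list[tuple[int, int]]:
    """Residue ranges forming the converged (ordered) core of an ensemble.

    Iterates: superpose all models on the retained backbone atoms, compute
    each residue's mean positional spread (RMSF about the ensemble mean),
    drop residues above ``cutoff``, refit on the remainder — until the
    retained set is stable or ``max_iter`` rounds.  Returns maximal
    contiguous residue ranges.
    """
    mask = ensemble.select(selection)
    if not mask.any():
        raise ValueError("selection matches no atoms")
    atoms = ensemble.atoms[mask].reset_index(drop=True)
    X = ensemble.coords[:, mask, :]
    residues = atoms["residue_number"].to_numpy()
    unique_res = np.unique(residues)
    retained = set(unique_res.tolist())

    for _ in range(max_iter):
        fit_mask = np.isin(residues, sorted(retained))
        if fit_mask.sum() < 3:
            raise ValueError(
                f"all residues excluded at cutoff {cutoff} A; try a larger cutoff"
            )
        fitted = X.copy()
        mean = fitted[0, fit_mask].copy()
        for _ in range(5):
            for i in range(len(fitted)):
                R, t, _ = superpose(fitted[i, fit_mask], mean)
                fitted[i] = apply_transform(fitted[i], R, t)
            mean = fitted[:, fit_mask].mean(axis=0)
        mean_all = fitted.mean(axis=0)
        dev = np.sqrt(np.mean(np.sum((fitted - mean_all) ** 2, axis=2), axis=0))
        spread = {r: float(dev[residues == r].mean()) for r in unique_res}
        new_retained = {r for r in unique_res if spread[r] <= cutoff}
        if not new_retained:
            raise ValueError(
                f"all residues excluded at cutoff {cutoff} A; try a larger cutoff"
            )
        if new_retained == retained:
            break
        retained = new_retained

    return _contiguous_ranges(sorted(retained))


def _contiguous_ranges(residues: list[int]) -> list[tuple[int, int]]:
    ranges = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r != prev + 1:
            ranges.append((start, prev))
            start = r
        prev = r
    ranges.append((start, prev))
    return ranges


def per_residue_rmsf(
    traj: Trajectory, selection: str | np.ndarray = "backbone"
) -> pd.DataFrame:
    """Per-residue RMSF about the time-mean position.

    Frames are assumed pre-superposed on the caller's chosen reference
    selection; RMSF_r averages atomic RMSFs over the selected atoms of
    residue r.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    mask = traj.select(selection) if isinstance(selection, str) else np.asarray(selection, bool)
    if not mask.any():
        raise ValueError("empty selection")
    X = traj.coords[:, mask, :]
    residues = traj.atoms.loc[mask, "residue_number"].to_numpy()
    mean = X.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    out = (
        pd.DataFrame({"residue_number": residues, "rmsf": atom_rmsf})
        .groupby("residue_number", as_index=False)["rmsf"].mean()
    )
    return out


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    model: AtomSet, probe: float = 1.4, n_points: int = 960
) -> tuple[np.ndarray, pd.DataFrame]:
    """Shrake-Rupley SASA, per atom and per residue (Angstrom^2).

    Each atom's sphere of radius r + probe is sampled with a deterministic
    Fibonacci lattice; the exposed fraction of the lattice scales the
    sphere's analytic area.  Deterministic for a given n_points.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    radii = model.radii() + probe
    coords = model.coords
    n = len(model)
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    per_res = (
        model.atoms.assign(sasa=areas)
        .groupby(["chain", "residue_number", "residue_name"], as_index=False)["sasa"]
        .sum()
    )
    return areas, per_res


def buried_surface_area(
    complex_model: AtomSet,
    group_a: np.ndarray,
    group_b: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict:
    """Per-residue buried surface area and total interface area.

    BSA_r = SASA_r(component alone) - SASA_r(in complex); the interface
    area is half the summed BSA over both components.  The two groups must
    be disjoint and nonempty.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if (group_a & group_b).any():
        raise ValueError("partition groups overlap")
    if not group_a.any() or not group_b.any():
        raise ValueError("both partition groups must be nonempty")

    _, res_complex = sasa(complex_model, probe, n_points)
    parts = []
    for mask in (group_a, group_b):
        _, res_alone = sasa(complex_model.subset(mask), probe, n_points)
        merged = res_alone.merge(
            res_complex, on=["chain", "residue_number", "residue_name"],
            suffixes=("_alone", "_complex"),
        )
        merged["bsa"] = merged["sasa_alone"] - merged["sasa_complex"]
        parts.append(merged[["chain", "residue_number", "residue_name", "bsa"]])
    per_residue = pd.concat(parts, ignore_index=True)
    total = float(per_residue["bsa"].sum()) / 2.0
    return {"per_residue": per_residue, "interface_area": total}


def relative_sasa(
    model: AtomSet, probe: float = 1.4, n_points: int = 960
) -> pd.DataFrame:
    """Per-residue SASA as a fraction of the residue's theoretical maximum.

    Normalizes against the Tien et al. (2013) theoretical maxima.  Values
    may exceed 1 for distorted termini and are not clipped; residues absent
    from the reference table are excluded with a warning.
    """
    _, per_res = sasa(model, probe, n_points)
    known = per_res["residue_name"].isin(MAX_SASA)
    if not known.all():
        unknown = sorted(per_res.loc[~known, "residue_name"].unique())
        warnings.warn(f"no reference max SASA for residues {unknown}; excluded")
    out = per_res[known].copy()
    out["rel_sasa"] = out.apply(
        lambda r: r["sasa"] / MAX_SASA[r["residue_name"]], axis=1
    )
    return out
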