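"""Chemical-shift-perturbation (CSP) mapping of binding interfaces.

A 1H-15N correlation spectrum gives one backbone-amide peak per non-proline
residue.  Titrating a ligand shifts peaks of residues at or near the binding
site; the combined perturbation

    dd_combined = sqrt(dd_H**2 + (alpha * dd_N)**2)

collapses the proton and nitrogen shift changes onto one ppm scale.  The
nitrogen scaling ``alpha`` compensates for the ~5x wider 15N dispersion;
0.14 is the conventional backbone-amide value and the default here (it is a
convention, not a measured constant — always configurable).

Residues are tiered against the profile's own statistics: *significant*
above mean + 1 SD, *strong* above mean + 2 SD, both with strict inequality
so a flat profile flags nothing.  Statistics run only over residues observed
in both states; prolines and unassigned residues are *unobserved*.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_N_WEIGHT = 0.14

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class CSPClass(str, enum.Enum):
    NONE = "none"
    SIGNIFICANT = "significant"
    STRONG = "strong"
    UNOBSERVED = "unobserved"


@dataclass(frozen=True)
class ResonanceEntry:
    """One assigned chemical shift: residue, atom, ppm value."""

    residue_number: int
    residue_type: str
    atom_name: str
    shift: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError(
                f"non-finite shift for residue {self.residue_number} "
                f"atom {self.atom_name}"
            )


@dataclass
class ShiftTable:
    """Assigned shifts for one state (free or bound) of one construct."""

    entries: list[ResonanceEntry]
    state_label: str = ""
    construct_label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            key = (e.residue_number, e.atom_name)
            if key in seen:
                raise ValueError(f"duplicate (residue, atom) key {key}")
            seen.add(key)

    def shift_of(self, residue_number: int, atom_name: str) -> float | None:
        for e in self.entries:
            if e.residue_number == residue_number and e.atom_name == atom_name:
                return e.shift
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.residue_number, e.residue_type, e.atom_name, e.shift) for e in self.entries],
            columns=["residue_number", "residue_type", "atom_name", "shift"],
        )


@dataclass
class CSPProfile:
    """Per-residue combined perturbations with significance classes.

    ``records`` columns: residue_number, dd_H, dd_N, dd_combined, cls.
    Mean and SD (population, ddof=0) are taken over observed residues only.
    """

    records: pd.DataFrame
    mean_csp: float = float("nan")
    sd_csp: float = float("nan")
    n_weight: float = DEFAULT_N_WEIGHT

    def observed(self) -> pd.DataFrame:
        return self.records[self.records["cls"] != CSPClass.UNOBSERVED.value]

    def residues_with_class(self, *classes: CSPClass) -> list[int]:
        wanted = {c.value for c in classes}
        sel = self.records[self.records["cls"].isin(wanted)]
        return sorted(sel["residue_number"].tolist())

    def to_tsv(self, path: str | Path) -> None:
        out = self.records.rename(
            columns={"dd_H": "dd_H_ppm", "dd_N": "dd_N_ppm",
                     "dd_combined": "dd_combined_ppm", "cls": "class"}
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.5f")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 n_weight: float = DEFAULT_N_WEIGHT) -> "CSPProfile":
        """Rebuild a profile (with recomputed mean/SD) from its TSV export."""
        df = pd.read_csv(path, sep="\t")
        records = df.rename(
            columns={"dd_H_ppm": "dd_H", "dd_N_ppm": "dd_N",
                     "dd_combined_ppm": "dd_combined", "class": "cls"}
        )
        observed = records[records["cls"] != CSPClass.UNOBSERVED.value]
        vals = observed["dd_combined"].to_numpy()
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0
        return cls(records=records, mean_csp=mean, sd_csp=sd, n_weight=n_weight)


# ---------------------------------------------------------------------------
# Readers

def read_shift_table(
    path: str | Path,
    format: str = "tsv",
    state_label: str = "",
    construct_label: str = "",
) -> ShiftTable:
    """Read a shift list from TSV or from a minimal NMR-STAR v3 subset.

    TSV dialect: header line required with columns residue_number,
    residue_type, atom_name, shift; '#' starts a comment.  The NMR-STAR
    reader covers only the ``Atom_chem_shift`` loop (Comp_index_ID, Comp_ID,
    Atom_ID, Val) — enough to ingest a deposited backbone shift list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        entries = _read_tsv(path)
    elif format == "nmrstar_subset":
        entries = _read_nmrstar_subset(path)
    else:
        raise ValueError(f"unknown shift-table format: {format!r}")
    if not entries:
        raise ValueError(f"empty shift table: {path}")
    return ShiftTable(entries=entries, state_label=state_label,
                      construct_label=construct_label)


def _read_tsv(path: Path) -> list[ResonanceEntry]:
    entries: list[ResonanceEntry] = []
    bad_lines: list[int] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"residue_number", "residue_type", "atom_name", "shift"}
                if not required.issubset(header):
                    raise ValueError(
                        f"{path}:{lineno}: header must contain {sorted(required)}"
                    )
                continue
            try:
                row = dict(zip(header, fields, strict=True))
                entries.append(
                    ResonanceEntry(
                        residue_number=int(row["residue_number"]),
                        residue_type=row["residue_type"],
                        atom_name=row["atom_name"],
                        shift=float(row["shift"]),
                    )
                )
            except (ValueError, KeyError):
                bad_lines.append(lineno)
    if bad_lines:
        raise ValueError(f"{path}: unparseable lines {bad_lines}")
    return entries


def _read_nmrstar_subset(path: Path) -> list[ResonanceEntry]:
    """Parse the Atom_chem_shift loop of an NMR-STAR v3 file.

    Only the loop structure is interpreted: a ``loop_`` keyword, a block of
    ``_Atom_chem_shift.<tag>`` names, whitespace-separated data rows, and a
    ``stop_`` terminator.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    reading_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower() == "loop_":
                in_loop, reading_data, tags = True, False, []
                continue
            if in_loop and line.startswith("_"):
                tags.append(line.split(".")[-1] if "." in line else line.lstrip("_"))
                continue
            if in_loop and line.lower() == "stop_":
                if rows:
                    break
                in_loop = False
                continue
            if in_loop and tags:
                if not tags[0] or not _is_shift_loop(tags):
                    in_loop = False
                    continue
                reading_data = True
                rows.append(line.split())
    if not reading_data or not rows:
        raise ValueError(f"{path}: no Atom_chem_shift loop found")
    idx = {t: i for i, t in enumerate(tags)}
    entries = []
    for r in rows:
        entries.append(
            ResonanceEntry(
                residue_number=int(r[idx["Comp_index_ID"]]),
                residue_type=r[idx["Comp_ID"]],
                atom_name=r[idx["Atom_ID"]],
                shift=float(r[idx["Val"]]),
            )
        )
    return entries


def _is_shift_loop(tags: list[str]) -> bool:
    return {"Comp_index_ID", "Comp_ID", "Atom_ID", "Val"}.issubset(tags)


# ---------------------------------------------------------------------------
# CSP computation

def combined_csp(dd_h: float, dd_n: float, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Combined amide perturbation sqrt(dd_H^2 + (alpha*dd_N)^2), in ppm."""
    return math.hypot(dd_h, n_weight * dd_n)


def compute_csp(
    free: ShiftTable,
    bound: ShiftTable,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> CSPProfile:
    """Per-residue combined amide CSP between free and bound states.

    A residue is observed when both its amide H and N shifts are present in
    both tables; residues seen in only one state (or missing an atom, e.g.
    prolines) are classed unobserved and excluded from the mean/SD.
    """
    if n_weight <= 0:
        raise ValueError("n_weight must be positive")

    def amides(table: ShiftTable) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for e in table.entries:
            if e.atom_name in ("H", "HN", "N"):
                atom = "N" if e.atom_name == "N" else "H"
                out.setdefault(e.residue_number, {})[atom] = e.shift
        return out

    fa, ba = amides(free), amides(bound)
    residues = sorted(set(fa) | set(ba))
    rows = []
    for r in residues:
        f, b = fa.get(r, {}), ba.get(r, {})
        if {"H", "N"} <= set(f) and {"H", "N"} <= set(b):
            dd_h = b["H"] - f["H"]
            dd_n = b["N"] - f["N"]
            rows.append((r, dd_h, dd_n, combined_csp(dd_h, dd_n, n_weight),
                         CSPClass.NONE.value))
        else:
            rows.append((r, np.nan, np.nan, np.nan, CSPClass.UNOBSERVED.value))
    records = pd.DataFrame(
        rows, columns=["residue_number", "dd_H", "dd_N", "dd_combined", "cls"]
    )
    observed = records[records["cls"] != CSPClass.UNOBSERVED.value]
    if observed.empty:
        raise ValueError("no residues with amide H and N observed in both states")
    vals = observed["dd_combined"].to_numpy()
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0
    profile = CSPProfile(records=records, mean_csp=mean, sd_csp=sd, n_weight=n_weight)
    return classify_csp(profile)


def classify_csp(profile: CSPProfile) -> CSPProfile:
    """Fill significance classes from the profile's own mean and SD.

    significant iff dd > mean + 1*SD; strong iff dd > mean + 2*SD (strict),
    so strong residues are always a subset of significant ones and a
    zero-variance profile flags nothing.  Idempotent.
    """
    if not math.isfinite(profile.mean_csp):
        raise ValueError("mean/SD not computed; run compute_csp first")
    sd = profile.sd_csp if math.isfinite(profile.sd_csp) else 0.0
    t1 = profile.mean_csp + sd
    t2 = profile.mean_csp + 2 * sd

    def tier(row: pd.Series) -> str:
        if row["cls"] == CSPClass.UNOBSERVED.value:
            return CSPClass.UNOBSERVED.value
        dd = row["dd_combined"]
        if dd > t2:
            return CSPClass.STRONG.value
        if dd > t1:
            return CSPClass.SIGNIFICANT.value
        return CSPClass.NONE.value

    profile.records["cls"] = profile.records.apply(tier, axis=1)
    return profile


def hotspot_clusters(profile: CSPProfile, min_run: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of consecutive significant/strong residues.

    A single unobserved residue (typically a proline gap) inside a run does
    not break it; a sub-threshold observed residue does.  Runs shorter than
    ``min_run`` (counting only significant/strong members) are dropped.
    """
    rec = profile.records.sort_values("residue_number")
    status: dict[int, str] = dict(zip(rec["residue_number"], rec["cls"]))
    residues = sorted(status)
    hits = {r for r in residues
            if status[r] in (CSPClass.SIGNIFICANT.value, CSPClass.STRONG.value)}
    clusters: list[tuple[int, int]] = []
    start: int | None = None
    prev_hit: int | None = None
    n_members = 0

    def flush() -> None:
        nonlocal start, prev_hit, n_members
        if start is not None and n_members >= min_run:
            clusters.append((start, prev_hit))
        start, prev_hit, n_members = None, None, 0

    for r in residues:
        if r in hits:
            if start is None:
                start = r
            elif not _gap_ok(prev_hit, r, status):
                flush()
                start = r
            prev_hit = r
            n_members += 1
        elif start is not None and status.get(r) != CSPClass.UNOBSERVED.value:
            flush()
    flush()
    return clusters


def _gap_ok(prev_hit: int | None, r: int, status: dict[int, str]) -> bool:
    """Gap between consecutive hits may contain at most one residue, and only
    if that residue is unobserved (not merely sub-threshold)."""
    if prev_hit is None or r - prev_hit == 1:
        return True
    if r - prev_hit == 2:
        between = status.get(prev_hit + 1)
        return between == CSPClass.UNOBSERVED.value or between is None
    return False
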