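"""NOE restraint statistics and CSP-derived docking restraints.

``classify_restraints`` buckets NOE upper-distance restraints by residue
separation |i-j| into the conventional classes (intraresidual 0, sequential
1, medium-range 1<|i-j|<5, long-range >4) and reports counts, percentages
and restraints per residue — the bookkeeping behind structure-statistics
tables.

``generate_airs`` turns a classified CSP profile plus a structure into
ambiguous interaction restraints (AIRs) for data-driven docking: *active*
residues are those with significant perturbations (above mean + 1 SD);
*passive* residues are solvent-exposed neighbors of active ones.  The
emitted text follows the ``assign (...) (...) d dminus dplus`` ambiguous
distance-restraint dialect with the conventional 2.0 A effective distance.
The explicit passive rule (relative SASA > 50% within 6.5 A of an active
residue) approximates what docking servers compute automatically when
passives are "left as default".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import CSPClass, CSPProfile
from .structure import AtomSet, relative_sasa


@dataclass(frozen=True)
class NOERestraint:
    residue_i: int
    residue_j: int
    atom_i: str
    atom_j: str
    upper_bound: float  # A

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")


CLASS_ORDER = ("intraresidual", "sequential", "medium", "long")


@dataclass
class RestraintStats:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    per_residue: float


def restraint_class(sep: int) -> str:
    """Class from residue separation |i-j|: 0 intraresidual, 1 sequential,
    1<|i-j|<5 medium-range, >4 long-range."""
    if sep == 0:
        return "intraresidual"
    if sep == 1:
        return "sequential"
    if sep < 5:
        return "medium"
    return "long"


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (matches printed-table formatting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_restraints(
    restraints: list[NOERestraint], n_residues: int
) -> RestraintStats:
    """Partition NOE restraints by |i-j| class; every restraint lands in
    exactly one class."""
    if not restraints:
        raise ValueError("empty restraint list")
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    counts = {c: 0 for c in CLASS_ORDER}
    for r in restraints:
        counts[restraint_class(abs(r.residue_i - r.residue_j))] += 1
    total = len(restraints)
    percentages = {c: _round2(100.0 * counts[c] / total) for c in CLASS_ORDER}
    return RestraintStats(
        total=total,
        counts=counts,
        percentages=percentages,
        per_residue=_round2(total / n_residues),
    )


def read_restraints_tsv(path: str | Path) -> list[NOERestraint]:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return [
        NOERestraint(
            residue_i=int(r["i"]), atom_i=str(r["atom_i"]),
            residue_j=int(r["j"]), atom_j=str(r["atom_j"]),
            upper_bound=float(r["upper"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Ambiguous interaction restraints

@dataclass
class AIRSpec:
    active: list[int]
    passive: list[int]
    partner_active: list[int]
    distance_bound: float = 2.0  # A effective distance

    def __post_init__(self) -> None:
        if set(self.active) & set(self.passive):
            raise ValueError("active and passive residue sets overlap")


def generate_airs(
    profile: CSPProfile,
    model: AtomSet,
    ligand_active: list[int],
    sasa_cut: float = 0.5,
    vicinity: float = 6.5,
    distance_bound: float = 2.0,
    receptor_segid: str = "A",
    ligand_segid: str = "B",
) -> tuple[AIRSpec, str]:
    """Derive active/passive residues from a CSP profile and emit AIR text.

    Active: residues classed significant or strong.  Passive: residues with
    relative SASA above ``sasa_cut`` whose nearest heavy atom lies within
    ``vicinity`` A of any active residue's heavy atom, excluding actives.
    The ligand side's active residues (e.g. the RNA loop bases contacted)
    are supplied by the caller.
    """
    active = profile.residues_with_class(CSPClass.SIGNIFICANT, CSPClass.STRONG)
    if not active:
        raise ValueError("no significant CSPs: cannot define active residues")

    rel = relative_sasa(model)
    exposed = set(
        rel.loc[rel["rel_sasa"] > sasa_cut, "residue_number"].astype(int)
    )

    heavy = (model.atoms["element"] != "H").to_numpy()
    resnums = model.atoms["residue_number"].to_numpy()
    active_mask = heavy & np.isin(resnums, active)
    passive: list[int] = []
    if active_mask.any():
        active_xyz = model.coords[active_mask]
        for r in sorted(exposed - set(active)):
            r_mask = heavy & (resnums == r)
            if not r_mask.any():
                continue
            d = np.linalg.norm(
                model.coords[r_mask][:, None, :] - active_xyz[None, :, :], axis=2
            )
            if d.min() <= vicinity:
                passive.append(r)

    spec = AIRSpec(
        active=active, passive=passive,
        partner_active=sorted(ligand_active), distance_bound=distance_bound,
    )
    return spec, format_air_table(spec, receptor_segid, ligand_segid)


def format_air_table(
    spec: AIRSpec, receptor_segid: str = "A", ligand_segid: str = "B"
) -> str:
    """Ambiguous distance restraints in the .tbl dialect.

    One ``assign`` per receptor active residue, OR-ed over the ligand's
    active residues, and the symmetric block for the ligand side targeting
    receptor active+passive; effective distance d with bounds (d-d, d+0),
    i.e. 2.0 (0.0, 2.0) by default.
    """
    d = spec.distance_bound
    lines = [
        "! Ambiguous interaction restraints derived from CSP mapping",
        f"! receptor active: {' '.join(map(str, spec.active))}",
        f"! receptor passive: {' '.join(map(str, spec.passive))}",
        f"! ligand active: {' '.join(map(str, spec.partner_active))}",
    ]
    for r in spec.active:
        targets = " or ".join(
            f"(resid {p} and segid {ligand_segid})" for p in spec.partner_active
        )
        lines.append(
            f"assign (resid {r} and segid {receptor_segid}) ({targets}) "
            f"{d:.1f} {d:.1f} 0.0"
        )
    receptor_targets = " or ".join(
        f"(resid {p} and segid {receptor_segid})"
        for p in spec.active + spec.passive
    )
    for r in spec.partner_active:
        lines.append(
            f"assign (resid {r} and segid {ligand_segid}) ({receptor_targets}) "
            f"{d:.1f} {d:.1f} 0.0"
        )
    return "\n".join(lines) + "\n"
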