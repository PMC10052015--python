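"""In-silico point substitutions and geometric hydrogen-bond assessment.

The reference crystal structure carries no hydrogens, so hydrogen bonds are
called from heavy-atom geometry alone: a polar side-chain atom (N/O/S with
donor or acceptor capability) paired with a polar ligand atom counts as a
*strong* H-bond when the heavy-atom distance lies in ``[d_min, d_strong]``
and a *weak* one in ``(d_strong, d_weak]``.  No angular term is applied.

Substitutions are modelled as single-conformer replacements: the backbone is
kept exactly, the new side chain is grafted from an idealized residue
template (CCD geometry via biotite), and chi1/chi2 torsions are copied from
the wild-type residue where the atom tree allows.  No rotamer search and no
clash relief are performed — determinism is prioritised over refinement, and
verdicts for substitutions that would require chi rearrangement can differ
from what an interactive modelling session would show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import PROTEIN, LigandGroup, StructureModel

__all__ = [
    "HBond",
    "HBondCriteria",
    "SubstitutionImpact",
    "POLAR_SIDECHAIN_ATOMS",
    "detect_hbonds",
    "substitute_residue",
    "assess_substitution",
    "classify_verdict",
    "impact_report",
    "AA_THREE",
]

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}

#: Side-chain heavy atoms with hydrogen-bonding capability per residue type.
#: Values: "d" donor, "a" acceptor, "da" both.  Ligand atoms (N/O/S) are
#: treated as both-capable since protonation states are unknown.
POLAR_SIDECHAIN_ATOMS: dict[str, dict[str, str]] = {
    "SER": {"OG": "da"},
    "THR": {"OG1": "da"},
    "TYR": {"OH": "da"},
    "CYS": {"SG": "da"},
    "ASN": {"OD1": "a", "ND2": "d"},
    "GLN": {"OE1": "a", "NE2": "d"},
    "ASP": {"OD1": "a", "OD2": "a"},
    "GLU": {"OE1": "a", "OE2": "a"},
    "LYS": {"NZ": "d"},
    "ARG": {"NE": "d", "NH1": "d", "NH2": "d"},
    "HIS": {"ND1": "da", "NE2": "da"},
    "TRP": {"NE1": "d"},
    "MET": {"SD": "a"},
}

_CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class HBondCriteria:
    """Distance windows (Å) for heavy-atom H-bond calling."""

    d_min: float = 2.4
    d_strong: float = 3.3
    d_weak: float = 3.6


@dataclass(frozen=True)
class HBond:
    residue_atom: str
    partner_atom: str
    partner: str  # ligand group label
    partner_residue: str  # e.g. "DT 6" within the group
    distance: float
    strength: str  # strong | weak


@dataclass
class SubstitutionImpact:
    notation: str
    strain: str
    before: list[HBond]
    after: list[HBond]
    per_partner: dict[str, str]
    verdict: str  # gain | loss | weakened | strengthened | unchanged | mixed


def _residue_rows(s: StructureModel, position: int, chain: str | None, numbering_offset: int) -> pd.DataFrame:
    resnum = position + numbering_offset
    prot = s.df[s.df.entity == PROTEIN]
    if chain is None:
        chains = prot.chain.unique()
        if len(chains) == 0:
            raise ValueError("no protein residues in structure")
        chain = chains[0]
    rows = prot[(prot.chain == chain) & (prot.resnum == resnum)]
    if not len(rows):
        raise KeyError(f"no protein residue at position {position} (resnum {resnum}, chain {chain})")
    return rows


def detect_hbonds(
    s: StructureModel,
    position: int,
    partners: Sequence[LigandGroup],
    criteria: HBondCriteria | None = None,
    chain: str | None = None,
    numbering_offset: int = 0,
) -> list[HBond]:
    """Geometric H-bonds between a residue's polar side chain and partner groups."""
    criteria = criteria or HBondCriteria()
    if not partners:
        raise ValueError("no partner groups")
    rows = _residue_rows(s, position, chain, numbering_offset)
    resname = rows.resname.iloc[0]
    polar = POLAR_SIDECHAIN_ATOMS.get(resname, {})
    sel = rows[rows.atom.isin(polar)]
    if not len(sel):
        warnings.warn(f"residue {resname} {position} has no polar side-chain atoms")
        return []
    bonds: list[HBond] = []
    rxyz = sel[["x", "y", "z"]].to_numpy(float)
    for g in partners:
        gat = g.atoms[g.atoms.element.isin(["N", "O", "S"])]
        if not len(gat):
            continue
        gxyz = gat[["x", "y", "z"]].to_numpy(float)
        d = np.linalg.norm(rxyz[:, None, :] - gxyz[None, :, :], axis=-1)
        for i, j in zip(*np.nonzero((d >= criteria.d_min) & (d <= criteria.d_weak))):
            dist = float(d[i, j])
            bonds.append(
                HBond(
                    residue_atom=str(sel.atom.iloc[i]),
                    partner_atom=str(gat.atom.iloc[j]),
                    partner=g.label,
                    partner_residue=f"{gat.resname.iloc[j]} {gat.resnum.iloc[j]}",
                    distance=dist,
                    strength="strong" if dist <= criteria.d_strong else "weak",
                )
            )
    bonds.sort(key=lambda b: (b.partner, b.distance))
    return bonds


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of `mobile` onto `target` (N x 3)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    return rot, mc, tc


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = axis
    p = points - origin
    cos, sin = np.cos(angle), np.sin(angle)
    rot = p * cos + np.cross(k, p) * sin + np.outer(p @ k, k) * (1 - cos)
    return rot + origin


def _template(aa3: str):
    import biotite.structure.info as info

    t = info.residue(aa3)
    heavy = t[(t.element != "H") & (t.atom_name != "OXT")]
    return heavy


def _distal_atoms(template, from_atom: str, through_atom: str) -> set[str]:
    """Atom names reachable from `through_atom` without crossing `from_atom`."""
    names = list(template.atom_name)
    adj: dict[str, set[str]] = {n: set() for n in names}
    bonds, _ = template.bonds.get_all_bonds()
    for i, nbrs in enumerate(bonds):
        for j in nbrs:
            if j >= 0 and j < len(names):
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    seen = {from_atom, through_atom}
    stack = [through_atom]
    out = set()
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):  # walk away from the rotation bond
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                stack.append(nxt)
    return out


def substitute_residue(
    s: StructureModel,
    position: int,
    new_aa: str,
    chain: str | None = None,
    numbering_offset: int = 0,
) -> StructureModel:
    """Replace one residue's side chain with an idealized one of ``new_aa``.

    Backbone atoms (N, CA, C, O, OXT) are preserved exactly.  An identity
    substitution returns an unmodified copy.  The grafted side chain keeps
    the template's internal geometry; chi1 and chi2 are copied from the
    wild-type side chain when both residue types define them.
    """
    new_aa = new_aa.upper()
    if new_aa not in AA_THREE:
        raise ValueError(f"not a standard amino acid: {new_aa!r}")
    rows = _residue_rows(s, position, chain, numbering_offset)
    old3 = rows.resname.iloc[0]
    new3 = AA_THREE[new_aa]
    if old3 == new3:
        return s.copy()

    bb = rows[rows.atom.isin(["N", "CA", "C"])]
    if set(bb.atom) != {"N", "CA", "C"}:
        raise ValueError(f"residue at {position} lacks backbone atoms needed for placement")
    target_bb = {a: bb[bb.atom == a][["x", "y", "z"]].to_numpy(float)[0] for a in ("N", "CA", "C")}

    t = _template(new3)
    tnames = list(t.atom_name)
    for a in ("N", "CA", "C"):
        if a not in tnames:
            raise ValueError(f"template {new3} missing backbone atom {a}")
    tcoord = t.coord.astype(float)
    mobile = np.array([tcoord[tnames.index(a)] for a in ("N", "CA", "C")])
    target = np.array([target_bb[a] for a in ("N", "CA", "C")])
    rot, mc, tc = _kabsch(mobile, target)
    placed = (tcoord - mc) @ rot.T + tc
    pos_of = {n: placed[i] for i, n in enumerate(tnames)}

    # Copy chi angles from the wild type where both residue types define them.
    old_xyz = {r.atom: np.array([r.x, r.y, r.z]) for r in rows.itertuples(index=False)}
    old_chis = _CHI_ATOMS.get(old3, [])
    new_chis = _CHI_ATOMS.get(new3, [])
    for k in range(min(len(old_chis), len(new_chis))):
        oa = old_chis[k]
        na = new_chis[k]
        if not all(a in old_xyz for a in oa) or not all(a in pos_of for a in na):
            break
        chi_old = _dihedral(*(old_xyz[a] for a in oa))
        chi_new = _dihedral(*(pos_of[a] for a in na))
        moving = _distal_atoms(t, na[1], na[2])  # atoms beyond the rotation bond
        moving.discard(na[2])
        axis = pos_of[na[2]] - pos_of[na[1]]
        if np.linalg.norm(axis) < 1e-9 or not moving:
            break
        names = [n for n in tnames if n in moving or n == na[3]]
        names = sorted(set(names) | {na[3]})
        pts = np.array([pos_of[n] for n in names])
        newpts = _rotate_about_axis(pts, pos_of[na[1]], axis, chi_old - chi_new)
        for n, p in zip(names, newpts):
            pos_of[n] = p

    # Assemble: original backbone rows + grafted side-chain rows, in place.
    keep = rows[rows.atom.isin(_BACKBONE)].copy()
    keep["resname"] = new3
    side_names = [n for n in tnames if n not in _BACKBONE]
    elem = {n: t.element[tnames.index(n)] for n in side_names}
    proto = keep.iloc[0]
    side_rows = pd.DataFrame(
        {
            "chain": proto.chain,
            "resnum": proto.resnum,
            "icode": proto.icode,
            "resname": new3,
            "atom": side_names,
            "element": [elem[n] for n in side_names],
            "x": [pos_of[n][0] for n in side_names],
            "y": [pos_of[n][1] for n in side_names],
            "z": [pos_of[n][2] for n in side_names],
            "occ": 1.0,
            "altloc": "",
            "entity": PROTEIN,
        }
    )
    first = rows.index.min()
    before = s.df[(s.df.index < first) & ~s.df.index.isin(rows.index)]
    after = s.df[(s.df.index > first) & ~s.df.index.isin(rows.index)]
    out = pd.concat([before, keep, side_rows, after], ignore_index=True)
    return StructureModel(out, source=s.source)


_STRENGTH_RANK = {"none": 0, "weak": 1, "strong": 2}


def _best_strength(bonds: Sequence[HBond], partner: str) -> str:
    best = "none"
    for b in bonds:
        if b.partner == partner and _STRENGTH_RANK[b.strength] > _STRENGTH_RANK[best]:
            best = b.strength
    return best


def classify_verdict(before: Sequence[HBond], after: Sequence[HBond]) -> tuple[dict[str, str], str]:
    """Verdict per partner group and overall, from the bond sets alone.

    Per partner, the best bond strength (none < weak < strong) before vs
    after decides: none→bonded = gain; bonded→none = loss; strong→weak =
    weakened; weak→strong = strengthened; otherwise unchanged.  The overall
    verdict is the single non-unchanged per-partner verdict, ``mixed`` when
    partners disagree, else ``unchanged``.
    """
    partners = sorted({b.partner for b in before} | {b.partner for b in after})
    per: dict[str, str] = {}
    for p in partners:
        a, b = _best_strength(before, p), _best_strength(after, p)
        if a == "none" and b != "none":
            per[p] = "gain"
        elif a != "none" and b == "none":
            per[p] = "loss"
        elif a == "strong" and b == "weak":
            per[p] = "weakened"
        elif a == "weak" and b == "strong":
            per[p] = "strengthened"
        else:
            per[p] = "unchanged"
    nontrivial = sorted({v for v in per.values() if v != "unchanged"})
    if not nontrivial:
        overall = "unchanged"
    elif len(nontrivial) == 1:
        overall = nontrivial[0]
    else:
        overall = "mixed"
    return per, overall


def assess_substitution(
    s: StructureModel,
    position: int,
    from_aa: str,
    to_aa: str,
    partners: Sequence[LigandGroup],
    criteria: HBondCriteria | None = None,
    chain: str | None = None,
    numbering_offset: int = 0,
    strain: str = "",
) -> SubstitutionImpact:
    """Detect H-bonds, model the substitution, re-detect, classify the change."""
    rows = _residue_rows(s, position, chain, numbering_offset)
    current = AA_ONE.get(rows.resname.iloc[0], "X")
    if current != from_aa.upper():
        raise ValueError(
            f"structure has {current} at position {position}, substitution says {from_aa} "
            "(numbering mismatch?)"
        )
    before = detect_hbonds(s, position, partners, criteria, chain, numbering_offset)
    s2 = substitute_residue(s, position, to_aa, chain, numbering_offset)
    after = detect_hbonds(s2, position, partners, criteria, chain, numbering_offset)
    per, overall = classify_verdict(before, after)
    return SubstitutionImpact(
        notation=f"{from_aa.upper()}{position}{to_aa.upper()}",
        strain=strain,
        before=before,
        after=after,
        per_partner=per,
        verdict=overall,
    )


def impact_report(impacts: Sequence[SubstitutionImpact]) -> pd.DataFrame:
    """One row per (substitution, partner) with verdict and best distances."""
    rows = []
    for imp in impacts:
        partners = sorted(imp.per_partner) or ["-"]
        for p in partners:
            db = min((b.distance for b in imp.before if b.partner == p), default=np.nan)
            da = min((b.distance for b in imp.after if b.partner == p), default=np.nan)
            rows.append(
                {
                    "strain": imp.strain,
                    "substitution": imp.notation,
                    "partner": p,
                    "verdict": imp.per_partner.get(p, "unchanged"),
                    "overall": imp.verdict,
                    "min_dist_before_A": db,
                    "min_dist_after_A": da,
                }
            )
    return pd.DataFrame(rows, columns=["strain", "substitution", "partner", "verdict", "overall", "min_dist_before_A", "min_dist_after_A"])
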