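"""Cross-strain variant tables at ligand-proximal positions.

The central object is the :class:`VariantTable`: rows are contact-shell
positions in reference (SEL) numbering, each carrying the ligand class it is
proximal to, and columns are strains, each cell the residue the strain holds
at that position.  Two comparison frames coexist and are always explicit:

* variant *flagging* is against the structural reference (SEL) — a row is a
  variant row iff at least one strain differs from SEL;
* phenotype work (substitution calls, integrity scores) is against the
  functional benchmark strain NRC-1, whose photolyase supports efficient
  photoreactivation.

The packaged table of 15 variant positions across the study strains ships
with the package and can be loaded with :func:`load_reference_table`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .seqmap import GAP, PositionMap, map_position
from .structure import ContactShell

__all__ = [
    "VariantTable",
    "SubstitutionCall",
    "IntegrityWeights",
    "KEY_POSITIONS",
    "DEFAULT_PARTITION",
    "load_reference_table",
    "load_strain_metadata",
    "build_variant_table",
    "diff_counts",
    "classify_substitution",
    "is_charge_change",
    "integrity_score",
]

#: Ligand-proximal positions singled out as functionally key in the
#: reference photolyase (HDF anchor R50; DNA-flipping loop G149; FAD-shell
#: E282 and N385; DNA-proximal D398 and K413).
KEY_POSITIONS = (50, 149, 282, 385, 398, 413)

#: Physicochemical classes used for the default conservativeness call:
#: aliphatic/small, aromatic, hydroxyl, amide(+Cys), acidic, basic.
DEFAULT_PARTITION = ("AGVLIPM", "FWY", "ST", "CNQ", "DE", "KRH")

_ACIDIC, _BASIC = set("DE"), set("KRH")


@dataclass(frozen=True)
class SubstitutionCall:
    position: int
    from_aa: str
    to_aa: str
    strain: str
    interaction: str
    conservativeness: str  # identical | conservative | non-conservative

    @property
    def notation(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass
class VariantTable:
    """Positions x strains residue matrix with per-position ligand labels."""

    table: pd.DataFrame  # index: position (int, ascending); columns: strains (+ structural ref)
    interaction: dict[int, str]
    structural_ref: str = "SEL"

    def __post_init__(self) -> None:
        if not self.table.index.is_monotonic_increasing:
            self.table = self.table.sort_index()
        missing = set(self.table.index) - set(self.interaction)
        if missing:
            raise ValueError(f"positions without interaction label: {sorted(missing)}")

    @property
    def positions(self) -> list[int]:
        return list(self.table.index)

    @property
    def strains(self) -> list[str]:
        return [c for c in self.table.columns]

    def residue(self, position: int, strain: str) -> str:
        return str(self.table.at[position, strain])

    def variant_rows(self, vs: str | None = None) -> "VariantTable":
        """Rows where at least one strain differs from the comparison column."""
        ref = vs or self.structural_ref
        others = [c for c in self.table.columns if c != ref]
        mask = self.table[others].ne(self.table[ref], axis=0).any(axis=1)
        sub = self.table[mask]
        return VariantTable(sub, {p: self.interaction[p] for p in sub.index}, self.structural_ref)


def load_reference_table() -> VariantTable:
    """The packaged 15-position variant table of the study strains."""
    with resources.files("phrscan.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df = df.set_index("position")
    interaction = df["interaction"].to_dict()
    return VariantTable(df.drop(columns=["interaction"]), interaction, structural_ref="SEL")


def load_strain_metadata() -> dict[str, dict]:
    """Habitat class and phr2 gene presence for the study strains."""
    with resources.files("phrscan.data").joinpath("strains.json").open() as fh:
        return json.load(fh)["strains"]


def build_variant_table(
    shell: ContactShell,
    ref_sequence_at: Mapping[int, str],
    maps: Sequence[PositionMap],
    interaction_override: Mapping[int, str] | None = None,
    variants_only: bool = False,
) -> VariantTable:
    """Assemble the variant table from a contact shell and position maps.

    ``ref_sequence_at`` gives the reference residue per reference-numbered
    position.  The interaction label per position is the ligand of minimum
    distance in the shell (ties: all labels joined with '/'), unless
    overridden.
    """
    ids = [m.query_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate strain ids in maps: {ids}")
    ref_ids = {m.ref_id for m in maps}
    if len(ref_ids) > 1:
        raise ValueError(f"maps disagree on reference: {sorted(ref_ids)}")
    positions = shell.positions
    interaction: dict[int, str] = {}
    for p in positions:
        if interaction_override and p in interaction_override:
            interaction[p] = interaction_override[p]
            continue
        entries = [e for e in shell.entries if e.position == p]
        dmin = min(e.min_distance for e in entries)
        labels = sorted(e.ligand for e in entries if abs(e.min_distance - dmin) < 1e-9)
        interaction[p] = "/".join(labels)

    ref_label = next(iter(ref_ids)) if ref_ids else "SEL"
    data: dict[str, list[str]] = {ref_label: []}
    for p in positions:
        if p not in ref_sequence_at:
            raise ValueError(f"shell position {p} outside reference sequence range")
        data[ref_label].append(ref_sequence_at[p])
    for m in maps:
        col = []
        for p in positions:
            try:
                aa, _ = map_position(m, p)
            except KeyError:
                aa = GAP
            col.append(aa)
        data[m.query_id] = col
    vt = VariantTable(pd.DataFrame(data, index=positions), interaction, structural_ref=ref_label)
    return vt.variant_rows() if variants_only else vt


def classify_substitution(from_aa: str, to_aa: str, partition: Sequence[str] = DEFAULT_PARTITION) -> str:
    """identical / conservative / non-conservative under a class partition."""
    a, b = from_aa.upper(), to_aa.upper()
    for x in (a, b):
        if len(x) != 1 or (x not in set("".join(partition)) and x not in "ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"invalid amino acid {x!r}")
    if a == b:
        return "identical"
    for cls in partition:
        if a in cls and b in cls:
            return "conservative"
    return "non-conservative"


def is_charge_change(from_aa: str, to_aa: str) -> bool:
    """True when the substitution flips or removes/introduces a side-chain charge."""
    a, b = from_aa.upper(), to_aa.upper()
    charge = lambda x: 1 if x in _BASIC else (-1 if x in _ACIDIC else 0)
    return charge(a) != charge(b)


@dataclass
class DiffResult:
    strain: str
    vs: str
    total: int
    per_interaction: dict[str, int]
    calls: list[SubstitutionCall]


def diff_counts(vt: VariantTable, strain: str, vs: str = "NRC-1", partition: Sequence[str] = DEFAULT_PARTITION) -> DiffResult:
    """Residue differences of ``strain`` relative to ``vs`` over the table."""
    for s in (strain, vs):
        if s not in vt.table.columns:
            raise KeyError(f"unknown strain {s!r}; table has {list(vt.table.columns)}")
    calls: list[SubstitutionCall] = []
    per: dict[str, int] = {}
    for p in vt.positions:
        a, b = vt.residue(p, vs), vt.residue(p, strain)
        if a != b:
            cons = "non-conservative" if GAP in (a, b) else classify_substitution(a, b, partition)
            calls.append(SubstitutionCall(p, a, b, strain, vt.interaction[p], cons))
            per[vt.interaction[p]] = per.get(vt.interaction[p], 0) + 1
    return DiffResult(strain=strain, vs=vs, total=len(calls), per_interaction=per, calls=calls)


@dataclass(frozen=True)
class IntegrityWeights:
    """Penalty weights for the photolyase integrity score (all <= 0).

    Gene absence is itself a weight, chosen to sit strictly below any
    attainable substitution-penalty total so an absent gene always ranks
    last, while keeping the score linear in the weights.
    """

    hbond_loss: float = -2.0
    hbond_weakened: float = -1.0
    hbond_gain: float = -1.0  # a new bond perturbs the tuned interface
    non_conservative: float = -1.0
    conservative: float = 0.0
    gene_absent: float = -100.0

    def scaled(self, factor: float) -> "IntegrityWeights":
        return IntegrityWeights(
            *(factor * w for w in (self.hbond_loss, self.hbond_weakened, self.hbond_gain, self.non_conservative, self.conservative, self.gene_absent))
        )


def integrity_score(
    vt: VariantTable,
    impacts: Mapping[str, str] | None = None,
    gene_present: Mapping[str, bool] | None = None,
    weights: IntegrityWeights | None = None,
    vs: str = "NRC-1",
    key_positions_only: bool = False,
) -> dict[str, float]:
    """Photolyase-integrity score per strain; reference scores 0 = most intact.

    ``impacts`` optionally maps substitution notation (e.g. ``"R50V"``) to an
    H-bond verdict (loss/weakened/gain/strengthened/unchanged/mixed) from the
    structural assessment; substitutions without a verdict fall back to their
    conservativeness class.  Higher scores mean a more intact enzyme; a
    strain whose gene is absent receives the gene-absent weight outright.
    """
    weights = weights or IntegrityWeights()
    gene_present = gene_present or {}
    verdict_w = {
        "loss": weights.hbond_loss,
        "weakened": weights.hbond_weakened,
        "gain": weights.hbond_gain,
        "mixed": weights.hbond_weakened,
        "strengthened": 0.0,
        "unchanged": None,  # fall back to conservativeness
    }
    scores: dict[str, float] = {}
    strains = [c for c in vt.table.columns if c != vt.structural_ref]
    # strains known only through gene presence (e.g. gene lost entirely)
    strains += [s for s in gene_present if s not in strains and s != vt.structural_ref]
    for strain in strains:
        if not gene_present.get(strain, True):
            scores[strain] = weights.gene_absent
            continue
        d = diff_counts(vt, strain, vs=vs)
        total = 0.0
        for call in d.calls:
            if key_positions_only and call.position not in KEY_POSITIONS:
                continue
            w = None
            if impacts is not None and call.notation in impacts:
                w = verdict_w.get(impacts[call.notation])
            if w is None:
                if impacts is not None and call.notation not in impacts and call.conservativeness == "non-conservative":
                    warnings.warn(f"no structural impact for {call.notation}; using conservativeness")
                w = weights.non_conservative if call.conservativeness == "non-conservative" else weights.conservative
            total += w
        scores[strain] = total
    return scores
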