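"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is seed-deterministic and emits a machine-readable truth
record (serialized as a ``<output>.truth.json`` side-car when an output
directory is given) that tests consume directly — truth is never re-derived
from the generated files.

What is emulated, and what is not: the mini structures have exact planted
protein–ligand distances and H-bond geometries but no secondary structure
or crystallographic noise; homolog families carry planted substitutions
only (no indels); survival counts follow single-hit exponential kill with
lognormal count noise; 16S-like sequences evolve by Jukes–Cantor on a known
tree (substitutions only); gene neighborhoods carry planted label orders,
an anchor-less strain and planted indels with exact bp lengths.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import gemmi
import numpy as np
import pandas as pd

from .seqmap import ProteinRecord
from .variants import load_reference_table, load_strain_metadata

__all__ = [
    "StructureSpec",
    "gen_structure",
    "gen_sequences",
    "gen_survival",
    "gen_tree_sequences",
    "gen_neighborhoods",
    "PAPER_DOSES",
    "paper_shaped_kill_rates",
    "CLADE_TREE_NEWICK",
]

#: UV-C doses (J/m²) of the survival assay protocol.
PAPER_DOSES = (0.0, 24.0, 48.0, 96.0, 144.0)

_RES_SPACING = 8.0  # Å between successive CA atoms; keeps residues independent


def _write_truth(outdir: str | Path | None, name: str, truth: dict) -> None:
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{name}.truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_LIGAND_RESNAMES = {"DNA": "DT", "FAD": "FAD", "HDF": "HDF"}


@dataclass
class StructureSpec:
    """Mini protein plus pseudo-ligand clusters with exact planted distances.

    ``contacts``: (resnum, ligand label, distance Å) — a carbon atom of the
    ligand group is placed exactly that far from the residue's CB.
    ``hbonds``: (resnum, ligand label, distance Å) — the residue becomes a
    serine and a nitrogen partner atom is placed that far from its OG.
    """

    n_residues: int = 10
    contacts: Sequence[tuple[int, str, float]] = ()
    hbonds: Sequence[tuple[int, str, float]] = ()
    residue_aa: Mapping[int, str] = field(default_factory=dict)
    ligand_labels: Sequence[str] = ("DNA", "FAD", "HDF")

_AA3 = {
    "A": "ALA", "S": "SER", "G": "GLY", "V": "VAL", "D": "ASP", "N": "ASN",
    "R": "ARG", "K": "LYS", "T": "THR", "E": "GLU", "Q": "GLN", "L": "LEU",
    "I": "ILE", "M": "MET", "F": "PHE", "W": "TRP", "Y": "TYR", "H": "HIS",
    "C": "CYS", "P": "PRO",
}


def _place_ideal_residue(aa3: str, x_offset: float, anchor: str) -> list[tuple[str, str, np.ndarray]]:
    """Ideal-geometry heavy atoms of one residue, CA at (x_offset, 0, 0).

    Oriented so the CA->anchor direction is -y and the CA->N direction lies
    in the +x half of the xz-plane after projection — fully deterministic.
    """
    import biotite.structure.info as info

    t = info.residue(aa3)
    t = t[(t.element != "H") & (t.atom_name != "OXT")]
    names = list(t.atom_name)
    coord = t.coord.astype(float)
    ca = coord[names.index("CA")]
    rel = coord - ca
    a = rel[names.index(anchor)]
    a = a / np.linalg.norm(a)
    b = np.array([0.0, -1.0, 0.0])
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        r1 = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        r1 = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    rel = rel @ r1.T
    n = rel[names.index("N")]
    ang = np.arctan2(n[2], n[0])
    cos, sin = np.cos(-ang), np.sin(-ang)
    r2 = np.array([[cos, 0, sin], [0, 1, 0], [-sin, 0, cos]])
    rel = rel @ r2.T
    rel[:, 0] += x_offset
    return [(names[k], str(t.element[k]), rel[k]) for k in range(len(names))]


def gen_structure(spec: StructureSpec, seed: int = 0, outdir: str | Path | None = None, name: str = "mini"):
    """Build the mini structure; returns (pdb_path_or_None, truth dict).

    The protein backbone runs along x with residues spaced far enough apart
    that a planted ligand atom below one residue's CB cannot come closer to
    any other residue — the planted distance IS the minimum distance.
    """
    for resnum, _, _ in list(spec.contacts) + list(spec.hbonds):
        if not 1 <= resnum <= spec.n_residues:
            raise ValueError(f"planted residue {resnum} out of range")
    seen: dict[tuple[int, str], float] = {}
    for resnum, label, dist in list(spec.contacts) + [(r, l, d) for r, l, d in spec.hbonds]:
        key = (resnum, label)
        if key in seen and not math.isclose(seen[key], dist):
            raise ValueError(f"conflicting distance constraints for residue {resnum} / {label}")
        seen[key] = dist

    hbond_res = {r for r, _, _ in spec.hbonds}
    aa_of = {}
    for i in range(1, spec.n_residues + 1):
        aa = spec.residue_aa.get(i, "S" if i in hbond_res else "A")
        if i in hbond_res and aa != "S":
            raise ValueError(f"H-bond planting requires serine at residue {i}")
        aa_of[i] = aa

    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    def add_atom(res, aname, element, pos):
        at = gemmi.Atom()
        at.name = aname
        at.element = gemmi.Element(element)
        at.pos = gemmi.Position(*pos)
        at.occ = 1.0
        res.add_atom(at)

    coords: dict[tuple[int, str], np.ndarray] = {}
    for i in range(1, spec.n_residues + 1):
        x = _RES_SPACING * (i - 1)
        res = gemmi.Residue()
        res.name = _AA3[aa_of[i]]
        res.seqid = gemmi.SeqId(i, " ")
        # Residues are ideal-geometry templates, deterministically oriented so
        # the planted-interaction atom (OG for H-bond serines, else CB, else N)
        # points straight down (-y): a partner atom planted below it at
        # distance d is then exactly d from the residue's nearest atom.
        placed = _place_ideal_residue(_AA3[aa_of[i]], x, anchor="OG" if aa_of[i] == "S" else ("CB" if aa_of[i] != "G" else "N"))
        for aname, element, p in placed:
            add_atom(res, aname, element, tuple(p))
            coords[(i, aname)] = np.asarray(p)
        chain.add_residue(res)
    model.add_chain(chain)

    lig_chain = gemmi.Chain("L")
    truth_contacts, truth_hbonds = [], []
    for gi, label in enumerate(spec.ligand_labels):
        res = gemmi.Residue()
        res.name = _LIGAND_RESNAMES.get(label, label[:3].upper())
        res.seqid = gemmi.SeqId(1000 + gi, " ")
        res.het_flag = "H"
        # body atoms far below the protein, group-specific offset
        add_atom(res, "C1", "C", (-20.0 - 10.0 * gi, -40.0, 0.0))
        add_atom(res, "C2", "C", (-20.0 - 10.0 * gi, -41.5, 0.0))
        k = 0
        for resnum, lab, dist in spec.contacts:
            if lab != label:
                continue
            anchor_name = "OG" if aa_of[resnum] == "S" else ("CB" if aa_of[resnum] != "G" else "N")
            p = coords[(resnum, anchor_name)] + np.array([0.0, -dist, 0.0])
            k += 1
            add_atom(res, f"C{2 + k}", "C", tuple(p))
            truth_contacts.append({"resnum": resnum, "ligand": label, "distance": dist})
        for resnum, lab, dist in spec.hbonds:
            if lab != label:
                continue
            og = coords[(resnum, "OG")]
            p = og + np.array([0.0, -dist, 0.0])
            k += 1
            add_atom(res, f"N{k}", "N", tuple(p))
            truth_hbonds.append({"resnum": resnum, "ligand": label, "distance": dist})
        lig_chain.add_residue(res)
    model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()

    truth = {
        "seed": seed,
        "n_residues": spec.n_residues,
        "sequence": "".join(aa_of[i] for i in range(1, spec.n_residues + 1)),
        "contacts": sorted(truth_contacts, key=lambda r: (r["resnum"], r["ligand"])),
        "hbonds": sorted(truth_hbonds, key=lambda r: (r["resnum"], r["ligand"])),
        "ligand_labels": list(spec.ligand_labels),
    }
    path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{name}.pdb"
        st.write_pdb(str(path))
        _write_truth(outdir, f"{name}.pdb", truth)
    return st, path, truth


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def gen_sequences(
    seed: int = 0,
    length: int = 480,
    ref_id: str = "SEL",
    substitutions: Mapping[str, Mapping[int, str]] | None = None,
    absent_strains: Sequence[str] = (),
    background_rate: float = 0.0,
    add_initiator_met: bool = True,
    preset: str | None = None,
    outdir: str | Path | None = None,
    name: str = "family",
):
    """Reference sequence plus homologs with planted substitutions.

    ``substitutions`` maps strain -> {reference position: residue}.  The
    ``"table2"`` preset emulates the study's Phr2 family: the 15 tabulated
    positions carry exactly the tabulated residues per strain, and the
    gene-less strain is omitted from the FASTA but flagged in the truth.
    Positions are reference numbering (initiator Met excluded); when
    ``add_initiator_met`` is set every emitted sequence gains a leading M
    and records numbering_offset 1.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    if preset == "table2":
        vt = load_reference_table()
        meta = load_strain_metadata()
        substitutions = {}
        for strain in vt.strains:
            if strain == "SEL":
                continue
            substitutions[strain] = {p: vt.residue(p, strain) for p in vt.positions}
        absent_strains = tuple(s for s, m in meta.items() if not m["phr2_present"])
        ref_cells = {p: vt.residue(p, "SEL") for p in vt.positions}
        length = max(length, max(vt.positions) + 10)
    else:
        substitutions = dict(substitutions or {})
        ref_cells = {}

    ref_seq = rng.choice(alphabet, size=length)
    for p, aa in ref_cells.items():
        ref_seq[p - 1] = aa
    ref_seq = "".join(ref_seq)

    offset = 1 if add_initiator_met else 0
    records = [ProteinRecord(ref_id, ("M" if add_initiator_met else "") + ref_seq, offset)]
    truth_subs: dict[str, dict[str, str]] = {}
    for strain, subs in substitutions.items():
        seq = list(ref_seq)
        applied = {}
        for p, aa in subs.items():
            if not 1 <= p <= length:
                raise ValueError(f"substitution position {p} out of range 1..{length}")
            if seq[p - 1] != aa:
                applied[str(p)] = f"{seq[p-1]}{p}{aa}"
            seq[p - 1] = aa
        if background_rate > 0:
            n_bg = rng.binomial(length, background_rate)
            protected = set(subs)
            sites = [s for s in rng.permutation(length) + 1 if s not in protected][:n_bg]
            for s in sites:
                choices = [c for c in alphabet if c != seq[s - 1]]
                seq[s - 1] = str(rng.choice(choices))
        records.append(ProteinRecord(strain, ("M" if add_initiator_met else "") + "".join(seq), offset))
        truth_subs[strain] = applied

    truth = {
        "seed": seed,
        "ref_id": ref_id,
        "length": length,
        "numbering_offset": offset,
        "substitutions_vs_ref": truth_subs,
        "absent_strains": list(absent_strains),
        "background_rate": background_rate,
    }
    path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{name}.faa"
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        _write_truth(outdir, f"{name}.faa", truth)
    return records, path, truth


# ---------------------------------------------------------------------------
# survival counts
# ---------------------------------------------------------------------------

def paper_shaped_kill_rates() -> dict[str, dict[str, float]]:
    """Exponential kill rates (per J/m²) encoding the qualitative phenotypes.

    Surface-brine/salt-crust strains photoreactivate to near-complete light
    survival; the sediment isolate is intermediate; subsurface-halite
    strains show little light/dark difference and heavy killing (roughly
    three to four logs at the 144 J/m² top dose).
    """
    return {
        "NRC-1": {"light": 0.004, "dark": 0.008},
        "BOL4-2": {"light": 0.005, "dark": 0.056},
        "GSL-19": {"light": 0.006, "dark": 0.056},
        "JOR-1": {"light": 0.007, "dark": 0.056},
        "BOL3-1": {"light": 0.008, "dark": 0.056},
        "Hla": {"light": 0.024, "dark": 0.056},
        "BOL6-1": {"light": 0.050, "dark": 0.060},
        "BOL5-1": {"light": 0.056, "dark": 0.060},
        "BOL5-4": {"light": 0.065, "dark": 0.065},
    }


def gen_survival(
    seed: int = 0,
    kill_rates: Mapping[str, Mapping[str, float]] | None = None,
    doses: Sequence[float] = PAPER_DOSES,
    n0: float = 1.0e6,
    cv: float = 0.2,
    replicates: int = 2,
    dilution: float = 1.0,
    preset: str | None = None,
    outdir: str | Path | None = None,
    name: str = "counts",
):
    """CFU counts from noisy exponential kill; truth carries the rates.

    Counts at dose d are ``round(n0 * exp(-k d) * eps)`` with lognormal
    ``eps`` of mean 1 and coefficient of variation ``cv``.
    """
    if preset == "paper-shaped":
        kill_rates = paper_shaped_kill_rates()
    if kill_rates is None:
        raise ValueError("kill_rates required unless a preset is chosen")
    for strain, ks in kill_rates.items():
        for cond, k in ks.items():
            if k < 0:
                raise ValueError(f"negative kill rate for {strain}/{cond}")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    rows = []
    for strain in sorted(kill_rates):
        for cond in ("light", "dark"):
            k = kill_rates[strain][cond]
            for d in doses:
                mean = n0 * math.exp(-k * d)
                for rep in range(1, replicates + 1):
                    eps = rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma > 0 else 1.0
                    rows.append(
                        {
                            "strain": strain,
                            "condition": cond,
                            "dose_J_per_m2": d,
                            "replicate": rep,
                            "dilution": dilution,
                            "cfu": int(round(mean * eps)),
                        }
                    )
    df = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "kill_rates": {s: dict(v) for s, v in kill_rates.items()},
        "expected_log10_slope": {
            s: {c: -k / math.log(10.0) for c, k in v.items()} for s, v in kill_rates.items()
        },
        "doses": list(doses),
        "n0": n0,
        "cv": cv,
        "light_order_best_to_worst": sorted(kill_rates, key=lambda s: (kill_rates[s]["light"], s)),
    }
    path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        _write_truth(outdir, f"{name}.csv", truth)
    return df, path, truth


# ---------------------------------------------------------------------------
# trees and 16S-like sequences
# ---------------------------------------------------------------------------

#: Three well-separated clades plus a distant outgroup, mirroring the
#: three haloarchaeal orders in a 16S tree.
CLADE_TREE_NEWICK = (
    "((A1:0.02,A2:0.02,A3:0.02):0.15,"
    "(B1:0.02,B2:0.02,B3:0.02):0.15,"
    "(C1:0.02,C2:0.02,C3:0.02):0.15,OUT:0.6);"
)


def gen_tree_sequences(
    seed: int = 0,
    newick: str = CLADE_TREE_NEWICK,
    seq_length: int = 1200,
    outdir: str | Path | None = None,
    name: str = "sixteenS",
):
    """Evolve gapless nucleotide sequences along a tree under Jukes–Cantor.

    Branch lengths are expected substitutions per site; a site changes along
    an edge of length t with probability (3/4)(1 - exp(-4t/3)).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, size=seq_length)

    seqs: dict[str, str] = {}

    def evolve(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
            child_seq = seq.copy()
            flips = rng.random(seq_length) < p_change
            if flips.any():
                shifts = rng.integers(1, 4, size=int(flips.sum()))
                child_seq[flips] = (child_seq[flips] + shifts) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(bases[child_seq])
            else:
                evolve(child, child_seq)

    evolve(tree.seed_node, root_seq)
    truth = {
        "seed": seed,
        "newick": newick.strip(),
        "seq_length": seq_length,
        "taxa": sorted(seqs),
    }
    path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{name}.aln.fasta"
        with open(path, "w") as fh:
            for label in sorted(seqs):
                fh.write(f">{label}\n{seqs[label]}\n")
        (outdir / f"{name}.true.nwk").write_text(newick.strip() + "\n")
        _write_truth(outdir, f"{name}.aln.fasta", truth)
    return seqs, path, truth


# ---------------------------------------------------------------------------
# gene neighborhoods
# ---------------------------------------------------------------------------

def _layout(strain: str, labels_strands: Sequence[tuple[str, str]], gene_len: int = 900, gap: int = 100, start: int = 1001):
    from .synteny import Gene, GeneNeighborhood

    genes = []
    pos = start
    for idx, (label, strand) in enumerate(labels_strands):
        genes.append(Gene(f"{strain}_{idx + 1:02d}", label, pos, pos + gene_len - 1, strand))
        pos += gene_len + gap
    return GeneNeighborhood(strain, genes)


def gen_neighborhoods(
    seed: int = 0,
    preset: str = "paper-shaped",
    deletion_bp: int = 1727,
    insertion_bp: int = 237,
    outdir: str | Path | None = None,
):
    """Gene neighborhoods around phr2 with planted synteny and indels.

    The paper-shaped preset plants: identical neighborhoods for the three
    closely related surface strains; a variant with two hypothetical genes
    between phr2 and sod2; a distinct shared layout for the two Halorubrum
    analogs (no sod2); related layouts for the subsurface strains; and one
    strain lacking phr2 entirely, whose region differs from its closest
    relative by a deletion and a short ORF insertion of exact planted sizes.
    """
    from .synteny import Gene, GeneNeighborhood

    if preset != "paper-shaped":
        raise ValueError(f"unknown preset {preset!r}")
    plus = "+"
    nb: dict[str, GeneNeighborhood] = {}
    halobact = [("coa_ligase", plus), ("sulfatase", plus), ("thioesterase", plus), ("phr2", plus), ("sod2", plus), ("mbl_hydrolase", plus)]
    for s in ("NRC-1", "BOL4-2", "GSL-19"):
        nb[s] = _layout(s, halobact)
    nb["JOR-1"] = _layout(
        "JOR-1",
        [("coa_ligase", plus), ("thioesterase", plus), ("phr2", plus), ("hypothetical", plus), ("hypothetical", plus), ("sod2", plus), ("mbl_hydrolase", plus)],
    )
    halorubrum = [("cupin", plus), ("thy_synthase", plus), ("phr2", plus), ("helicase", plus), ("ghmp_kinase", plus)]
    nb["Hla"] = _layout("Hla", halorubrum)
    nb["BOL3-1"] = _layout("BOL3-1", halorubrum)
    nb["BOL5-1"] = _layout("BOL5-1", [("duf115", plus), ("phr2", plus), ("cell_division", plus), ("oxidoreductase", plus)])
    bol61 = [("duf115", plus), ("fgf_hyp", plus), ("phr2", plus), ("cell_division", plus), ("sugar_isomerase", plus)]
    # phr2-sized genes and roomy intergenic gaps so the planted deletion fits
    nb["BOL6-1"] = _layout("BOL6-1", bol61, gene_len=1200, gap=400)

    # BOL5-4: same flanks as BOL6-1 but phr2 replaced by a short ORF; the
    # inter-flank span shrinks by deletion_bp while gaining insertion_bp.
    b61 = nb["BOL6-1"]
    left, right = b61.find("fgf_hyp"), b61.find("cell_division")
    span_a = right.start - left.end - 1
    span_b = span_a - deletion_bp + insertion_bp
    if span_b < insertion_bp + 2:
        raise ValueError("planted deletion too large for the layout")
    genes54 = [
        Gene("BOL5-4_01", "duf115", b61.find("duf115").start, b61.find("duf115").end, plus),
        Gene("BOL5-4_02", "fgf_hyp", left.start, left.end, plus),
        Gene("BOL5-4_03", "orf_unknown", left.end + 1 + (span_b - insertion_bp) // 2, left.end + (span_b - insertion_bp) // 2 + insertion_bp, plus),
        Gene("BOL5-4_04", "cell_division", left.end + span_b + 1, left.end + span_b + right.length, plus),
        Gene("BOL5-4_05", "sugar_isomerase", left.end + span_b + right.length + 101, left.end + span_b + right.length + 100 + 900, plus),
    ]
    nb["BOL5-4"] = GeneNeighborhood("BOL5-4", genes54)

    truth = {
        "seed": seed,
        "anchor": "phr2",
        "anchor_absent": ["BOL5-4"],
        "identical_groups": [["NRC-1", "BOL4-2", "GSL-19"], ["Hla", "BOL3-1"]],
        "jor1_intervening_between_phr2_sod2": 2,
        "planted_indels_BOL6-1_vs_BOL5-4": {"deletion": deletion_bp, "insertion": insertion_bp},
        "indel_flanks": ["fgf_hyp", "cell_division"],
    }
    paths = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s, hood in nb.items():
            p = outdir / f"{s}.region.gff3"
            with open(p, "w") as fh:
                fh.write("##gff-version 3\n")
                for g in hood.genes:
                    fh.write(
                        f"contig1\tphrscan_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                        f"ID={g.id};label={g.label}\n"
                    )
            paths[s] = p
        _write_truth(outdir, "neighborhoods", truth)
    return nb, paths, truth
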