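"""Gene-neighborhood comparison around an anchor gene (phr2).

Neighborhoods are ordered lists of genes with functional labels drawn from a
controlled vocabulary (mirroring how genome maps are color-coded by
function).  Homology between genes is label-based: two genes are treated as
orthologous iff their functional labels match — the comparison operates at
annotation level, not sequence level.

Order conservation is scored as a strand-aware longest common subsequence
of the label sequences, normalised by the longer neighborhood; a
neighborhood and its reverse complement are equivalent.  Coordinate-level
indel detection compares the spans between declared homologous flanking
genes and reports insertion/deletion lengths in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Gene",
    "GeneNeighborhood",
    "SyntenyReport",
    "AnchorContext",
    "read_gff3",
    "read_tsv",
    "synteny_score",
    "anchor_context",
    "indel_detect",
]

ANCHOR_DEFAULT = "phr2"


@dataclass(frozen=True)
class Gene:
    id: str
    label: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneNeighborhood:
    strain: str
    genes: list[Gene]
    anchor: str = ANCHOR_DEFAULT

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.start)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.genes]

    @property
    def anchor_present(self) -> bool:
        return any(g.label == self.anchor for g in self.genes)

    def find(self, label: str) -> Gene:
        hits = [g for g in self.genes if g.label == label]
        if not hits:
            raise KeyError(f"label {label!r} not in neighborhood of {self.strain}")
        return hits[0]

    def reverse_complement(self) -> "GeneNeighborhood":
        span_end = max(g.end for g in self.genes)
        flipped = [
            Gene(g.id, g.label, span_end - g.end + 1, span_end - g.start + 1, "+" if g.strand == "-" else "-")
            for g in self.genes
        ]
        return GeneNeighborhood(self.strain, flipped, self.anchor)


def read_gff3(path: str | Path, strain: str, label_attr: str = "label", anchor: str = ANCHOR_DEFAULT) -> GeneNeighborhood:
    """Read gene features from a GFF3 file (subset: ``gene`` features with a label attribute)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        label = feat.attributes.get(label_attr, feat.attributes.get("Name", [feat.id]))[0]
        genes.append(Gene(feat.id, label, feat.start, feat.end, feat.strand))
    if not genes:
        raise ValueError(f"no gene features in {path}")
    return GeneNeighborhood(strain, genes, anchor)


def read_tsv(path: str | Path, strain: str, anchor: str = ANCHOR_DEFAULT) -> GeneNeighborhood:
    """Read a 6-column TSV: gene_id, label, start, end, strand, contig."""
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = [Gene(str(r.gene_id), str(r.label), int(r.start), int(r.end), str(r.strand)) for r in df.itertuples(index=False)]
    return GeneNeighborhood(strain, genes, anchor)


@dataclass
class SyntenyReport:
    strain_a: str
    strain_b: str
    shared_labels: int
    lcs_length: int
    score: float  # normalised LCS in [0, 1]
    orientation: str  # "forward" or "reverse-complement" (of b, achieving the LCS)
    anchor_in_a: bool
    anchor_in_b: bool


def _lcs(a: Sequence[tuple[str, str]], b: Sequence[tuple[str, str]]) -> int:
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def synteny_score(a: GeneNeighborhood, b: GeneNeighborhood) -> SyntenyReport:
    """Strand-aware normalised LCS of the two label sequences.

    The better of b-as-given and b reverse-complemented is used, so an
    inverted but otherwise identical neighborhood still scores 1.
    """
    if not a.genes or not b.genes:
        raise ValueError("empty neighborhood")
    sa = list(zip(a.labels, (g.strand for g in a.genes)))
    fwd = _lcs(sa, list(zip(b.labels, (g.strand for g in b.genes))))
    brc = b.reverse_complement()
    rev = _lcs(sa, list(zip(brc.labels, (g.strand for g in brc.genes))))
    lcs = max(fwd, rev)
    return SyntenyReport(
        strain_a=a.strain,
        strain_b=b.strain,
        shared_labels=len(set(a.labels) & set(b.labels)),
        lcs_length=lcs,
        score=lcs / max(len(sa), len(b.genes)),
        orientation="forward" if fwd >= rev else "reverse-complement",
        anchor_in_a=a.anchor_present,
        anchor_in_b=b.anchor_present,
    )


@dataclass
class AnchorContext:
    """Genes between the anchor and another labelled gene; explicit ABSENT flag."""

    strain: str
    anchor: str
    other: str
    anchor_absent: bool
    intervening: list[Gene] = field(default_factory=list)


def anchor_context(n: GeneNeighborhood, anchor: str | None = None, other: str = "sod2") -> AnchorContext:
    """Ordered genes strictly between the anchor gene and another label.

    A missing anchor yields an ``anchor_absent`` result rather than an
    exception, so a strain that has lost the gene is reported, not crashed
    on.  A missing ``other`` label is an error.
    """
    anchor = anchor or n.anchor
    if not any(g.label == anchor for g in n.genes):
        return AnchorContext(n.strain, anchor, other, anchor_absent=True)
    ga = n.find(anchor)
    gb = n.find(other)
    lo, hi = min(ga.end, gb.end), max(ga.start, gb.start)
    between = [g for g in n.genes if g.start > lo and g.end < hi and g.id not in (ga.id, gb.id)]
    return AnchorContext(n.strain, anchor, other, anchor_absent=False, intervening=between)


def indel_detect(
    a: GeneNeighborhood,
    b: GeneNeighborhood,
    flanks: Sequence[str],
) -> list[tuple[str, int]]:
    """Insertion/deletion lengths (bp) between shared homologous flanks.

    ``flanks`` is an ordered list of labels present in both neighborhoods.
    Within each interval between consecutive flanks: genes of ``b`` whose
    labels do not occur in the corresponding interval of ``a`` are reported
    as insertions (their annotated lengths); the remaining span difference,
    when positive, is a deletion in ``b`` relative to ``a`` — unmatched
    genes of ``a`` (lost in ``b``) fall inside that deleted span.
    """
    if len(flanks) < 2:
        raise ValueError("need at least two flank labels")
    try:
        fa = [a.find(f) for f in flanks]
        fb = [b.find(f) for f in flanks]
    except KeyError as exc:
        raise ValueError(f"flanks not shared: {exc}") from exc

    events: list[tuple[str, int]] = []
    for (a1, a2), (b1, b2) in zip(zip(fa, fa[1:]), zip(fb, fb[1:])):
        span_a = a2.start - a1.end - 1
        span_b = b2.start - b1.end - 1
        in_a = [g for g in a.genes if g.start > a1.end and g.end < a2.start]
        in_b = [g for g in b.genes if g.start > b1.end and g.end < b2.start]
        labels_a = {g.label for g in in_a}
        inserted = [g for g in in_b if g.label not in labels_a]
        ins_total = 0
        for g in inserted:
            events.append(("insertion", g.length))
            ins_total += g.length
        net = span_a - (span_b - ins_total)
        if net > 0:
            events.append(("deletion", net))
        elif net < 0:
            events.append(("insertion", -net))
    return events
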