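# Methods

This note documents the models, parameter choices and limitations behind
`phrscan`. It covers what each stage computes, why the defaults are what
they are, and what the synthetic generators do and do not emulate.

## Reference frame and numbering

All cross-strain positions are reported in the numbering of the reference
photolyase of *Synechococcus elongatus* PCC 6301 (SEL), **excluding the
initiator methionine**. A sequence record that still carries the leading M
declares `numbering_offset = 1`; position *p* then denotes sequence index
*p* − 1 + offset. Internally everything is 0-based half-open and converted
at I/O boundaries. Two reference roles are deliberately separate and always
explicit: the *structural* reference (SEL, the frame in which positions are
defined and substitutions are modelled) and the *functional* reference
(*Halobacterium* sp. NRC-1, the strain with demonstrated efficient
photoreactivation, against which substitution loads and integrity scores
are counted).

## Contact shells

A protein residue belongs to the shell of a ligand group (the DNA duplex
including the CPD analog, the catalytic FAD, or the antenna chromophore
HDF) at threshold *t* iff the minimum heavy-atom Euclidean distance between
the residue and the group is ≤ *t*. Hydrogens are absent from the relevant
crystal structures, so all criteria in this package are heavy-atom and
distance-only. Defaults: threshold 2.8 Å (the conventional close-contact
cutoff for this analysis, known to be approximate), all-heavy atom scope
(a side-chain-only scope is available, since it is ambiguous which was used
historically), waters and ions excluded on both sides, alternate locations
resolved to the highest-occupancy conformer (ties: alphabetically first),
model 1 of multi-model files. Because the cutoff is approximate, the
calibration is itself an operation: `sweep_thresholds` /
`phrscan contacts-sweep` reports the union shell size on a grid (default
2.6–4.0 Å in 0.1 Å steps) so a target shell size can be matched openly
rather than baked in. Nonstandard residue names of the CPD-analog strand
are declared in configuration (`nucleic_names`), never hard-coded.

The implementation uses a KD-tree per ligand group; tests assert equality
with a brute-force all-pairs scan on small structures, threshold
monotonicity, and rigid-motion invariance to 10⁻⁶ Å.

## Sequence mapping

Homologs are aligned to the reference pairwise with Needleman–Wunsch global
alignment (Biopython's `PairwiseAligner`), BLOSUM62, gap open 10 / extend 1.
Pairwise-to-one-reference is sufficient because the only alignment product
consumed downstream is the per-position residue map; a multiple alignment
adds nothing to that contract. Percent identity is defined as identical
columns divided by aligned columns (columns gapped in both excluded) — the
published identity figures for this family were produced by an unspecified
aligner/parameterisation and are therefore treated as indicative, not as
exact targets. Alignment scores are verified against an exhaustive
enumeration of all global alignments on short sequences; the position map
is tested for round-trip identity, strict monotonicity, and invariance of
reference-numbered answers to a leading Met.

## Variant table and conservativeness

The variant table crosses contact-shell positions with strains. A row is a
*variant row* iff at least one strain differs from SEL; substitution calls
and counts are taken against NRC-1. The per-position interaction label
comes from the packaged table when using fixture mode, or from the ligand
of minimum distance when computed from a structure — provenance is kept
explicit because printed labels and surrounding text disagree for position
282 (DNA vs FAD); the packaged fixture carries the printed label.
Similarly, the packaged table yields exactly one BOL3-1 difference vs NRC-1
(position 385), which contradicts a prose statement that BOL3-1 shows no
key-residue substitutions; the package reports the literal table content.

Conservativeness uses the side-chain class partition
{AGVLIPM} {FWY} {ST} {CNQ} {DE} {KRH}: identical / conservative (same
class) / non-conservative (different class), with a charge-change flag for
acidic↔basic or charged↔uncharged swaps. The partition is configurable; the
default reproduces the classifications asserted in the source analysis
(T149S conservative; R50V, K413E, D398N non-conservative).

## Substitution modelling and H-bonds

`substitute_residue` keeps the backbone (N, CA, C, O, OXT) exactly, grafts
the new side chain from the idealized residue geometry of the chemical
component dictionary (via biotite), and copies χ1/χ2 from the wild-type
conformer where both residue types define them (rotation subtrees are
derived from the template bond graph). No rotamer search, no clash relief,
no refinement: determinism and auditability are prioritised, and verdicts
for substitutions that would require χ3+/backbone rearrangement can differ
from what interactive modelling would show. Identity substitutions return
the input unchanged by construction.

H-bonds are called between donor/acceptor-capable side-chain N/O/S atoms
(per-residue capability table) and partner N/O/S atoms (ligand atoms are
treated as both-capable since protonation states are unknown): *strong* at
2.4–3.3 Å, *weak* at 3.3–3.6 Å, no angular term (no hydrogens). The exact
strong/weak cutoffs used to draw the original figures are unpublished, so
these windows are configuration with documented defaults, and
reproduction of published verdicts is threshold-calibrated and reported as
such. A substitution's verdict is a pure function of the per-partner best
strength before and after (none→bonded gain; bonded→none loss; strong→weak
weakened; weak→strong strengthened; several differing partners → mixed),
unit-tested exhaustively. Mg²⁺ is carried as an ion entity but excluded
from partner sets by default.

## Integrity score

Per strain: 0 for the functional reference; each substitution contributes
its penalty — H-bond loss −2, weakening −1, unexpected gain −1 (a new bond
perturbs a tuned interface; the D398N-type case), otherwise conservativeness
fallback (non-conservative −1, conservative 0). All contact-shell positions
count: every tabulated position is ligand-proximal, so "key" is the shell
itself; the six historically highlighted positions (50, 149, 282, 385, 398,
413) are available as a named filter. A strain whose phr2 gene is absent
receives a dedicated weight (−100 by default), chosen to sit strictly below
any attainable substitution total while keeping the score linear in the
weights (doubling all weights doubles every distance from the reference).
A true "gene absent = 0 on a positive scale" convention was rejected
because it collides with "reference = 0 = best" on a penalty scale.

Limitation worth stating: conservativeness-only scoring ties the sediment
isolate Hla (three conservative changes) with the intact surface strains
and places JOR-1 (non-conservative R413D, phenotypically harmless) slightly
below it. The genotype–phenotype association is therefore asserted as a
rank correlation plus the subsurface-strains-last property, not as an exact
ordering of the intermediate strains.

## Survival statistics

Counts are dilution-corrected (titer = CFU × dilution), replicates averaged
on the linear scale (log-scale averaging is available), and survival is
S(d) = 100·titer(d)/titer(0). Zero-colony observations are floored at half
a colony at the deepest plated dilution and flagged censored, keeping log
survival finite. The summary per strain/condition is the least-squares
slope of log₁₀ S vs dose (S(0) = 100 included), the extrapolation-flagged
dose to 10% survival, and the top-dose log-kill. Photoreactivation benefit
is log₁₀ S_light − log₁₀ S_dark per dose, with the mean over positive doses
as the scalar summary. Rankings default to light-condition survival at the
highest common dose, ties broken by mean benefit then strain id,
deterministically.

The source survival data exist only as plotted curves — no CFU values are
printed — so all quantitative testing of this module is synthetic and
property-based, with the qualitative habitat ordering (surface > sediment >
subsurface) encoded as a rank assertion. This is stated here precisely to
avoid implying a numerical reproduction that the inputs cannot support.

The genotype–phenotype correlation is Spearman's ρ with a two-sided
permutation p-value: exhaustive over all n! relabelings for n ≤ 8, seeded
Monte-Carlo with add-one correction above.

## Phylogeny

p-distance and Jukes–Cantor d = −(3/4)ln(1 − 4p/3) with pairwise gap
deletion; p ≥ 0.75 under JC raises a saturation error rather than returning
infinity. Neighbor joining is implemented in-house (Saitou–Nei Q-criterion,
deterministic lowest-index tie-break, standard branch-length formulas,
negative estimates clamped to 0 with a warning) because NJ is the named
method of the original tree and is exactly testable: on additive matrices
it provably recovers the generating tree, which the tests exercise on
random 4–8-taxon trees (topology and path distances to 10⁻⁹), with
scikit-bio's independent NJ as a cross-check. Monophyly reports root the
tree at a designated outgroup and compare each group's MRCA leaf set to its
membership.

## Synteny

Gene neighborhoods are ordered label sequences (controlled functional
vocabulary mirroring how such maps are color-coded); homology is
label-based by design — sequence-level orthology is out of scope. The order
score is LCS over (label, strand) pairs, normalised by the longer
neighborhood, computed for the partner as given and reverse-complemented
(the better orientation wins), so inversion-equivalent neighborhoods score
1. Indel detection compares spans between consecutive shared flanking
genes: unmatched annotated genes in the second neighborhood are insertions
(their annotated lengths); the residual span difference is a deletion
(unmatched genes of the first neighborhood fall inside it). Coordinates are
1-based inclusive (GFF3 convention) externally.

## Synthetic data: what it emulates, what it does not

All generators are seed-deterministic and write `<output>.truth.json`
side-cars consumed directly by tests. Defaults encode the study conditions:
UV-C doses 0/24/48/96/144 J/m²; duplicate spots; lognormal count noise with
CV 20%; kill rates per strain/condition chosen so that surface strains
photoreactivate to high light survival, the sediment isolate is
intermediate, and subsurface strains show three-to-four logs of killing at
the top dose with little light/dark difference (the NRC-1 analog also
retains strong dark repair). The neighborhood preset plants the observed
relations: identical layouts for the three closely related surface strains,
two hypothetical genes between phr2 and sod2 in the JOR-1 analog, a shared
sod2-less layout for the two *Halorubrum* analogs, and a phr2-less strain
whose region differs from its closest relative by a 1727 bp deletion plus a
237 bp ORF insertion, planted at exactly those sizes.

Mini structures are built from ideal residue templates on a linear backbone
with residues spaced 8 Å apart; planted ligand atoms sit exactly at the
requested minimum distances (the geometry guarantees the planted pair is
the minimum). They have no secondary structure, no crystallographic noise
and no packing, so passing structural tests demonstrates correctness of the
geometry pipeline, not robustness to real crystal artifacts. Protein
families carry substitutions only (no indels); 16S-like sequences evolve
gaplessly under Jukes–Cantor on a known tree.

The end-to-end synthetic preset uses a 30-residue structure with five
shell positions (H-bond donors at 5 and 12, contacts at 8, 20, 25), six
strains of graded damage plus one gene-less strain, and kill rates ordered
with the planted damage; problem sizes throughout (30 residues, ≤ 10 taxa,
100 simulated strains for slope recovery) are chosen so the full suite and
the acceptance script run in well under a minute each while keeping the
statistics stable.

## Reference-structure analyses

The contact-shell count calibration (59 residues) and the published H-bond
verdicts (R50V loss vs HDF; D398N gain vs DNA; K413T loss vs DNA) are
properties of the real reference structure, PDB 1TEZ, which is not
redistributed with the package. `fetch_reference_structure` uses a local
copy (`data/1tez.pdb`) when present and downloads from RCSB otherwise; the
corresponding acceptance tests fail with an explicit message when the
structure is unavailable. The auth-numbering offset of the deposited file
relative to SEL numbering is detected at run time by checking the expected
residue identities rather than assumed.

## Known limitations

* Single-conformer substitution modelling: no repacking, no energetics;
  verdicts are qualitative and threshold-sensitive by design.
* Label-based synteny cannot distinguish paralogs with identical functional
  labels.
* Integrity weights are heuristic; the score is a rank statistic, not a
  calibrated functional prediction.
* The log-linear survival model ignores shoulders and multi-hit kinetics;
  it is a summary statistic, not a mechanistic repair model.
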