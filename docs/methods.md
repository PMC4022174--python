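# Methods

## The classification problem

Major intrinsic proteins (MIPs, or aquaporins) are membrane channels that
passively transport water and other small uncharged molecules. Two short
structural signatures carry most of the information used to classify them
from sequence alone:

* the two **NPA boxes** — Asn-Pro-Ala tripeptides on loops B and E, whose
  third (rarely second) letter varies in characteristic ways between
  subfamilies (NPM, NPG, NGA, NPT, ...);
* the **ar/R selectivity filter** — one residue each from transmembrane
  helices H2 and H5 plus two from the loop-E region (roles LE1 and LE2),
  which forms the pore constriction and largely determines whether the
  channel passes water (aquaporin-like composition F-H-[A/C]-R) or glycerol
  (glyceroporin-like composition W-V-[A/G]-R).

`mipclass` detects the boxes, extracts the filter by alignment to annotated
references, places queries on a neighbour-joining tree built from pairwise
JTT maximum-likelihood distances with bootstrap supports, and combines the
evidence into a subfamily call (PIP, GIP, MIPE, LIP, or unclassified). The
LIP ("large intrinsic protein") group of nine heterokont algal MIPs is
delineated primarily by its filter signature: proline at LE1 together with
leucine or isoleucine at LE2, usually accompanied by an NPM second box, a
C-terminal lysine, and W/Y at H2.

## Motif scanning

Candidates are all N-[PG]-X tripeptides over the standard 20-letter
alphabet. The reported pair (i, j) must satisfy: i starts in the N-terminal
60% of the sequence, j in the C-terminal 60% (the windows overlap so short
~225-residue sequences are handled), and j − i ≥ `min_separation`
(default 40 residues, from the three transmembrane helices between loops B
and E). Among admissible pairs, the summed preference score (exact NPA = 2,
any other N-[PG]-X = 1) is maximized; ties break to the smallest i, then
smallest j. When no admissible pair exists the best lone candidate is
reported on its side and the other box is absent — boxes are never
fabricated. This windowed-regex scheme is a deliberately self-contained
substitute for profile-HMM localisation; it needs no external profile and
is exact on the generator's outputs (see below).

## Filter extraction

Annotated reference positions (packaged: an HsAQP1-like annotation with
F56/H180/C189/R195 and an EcGlpF-like annotation with W48/G191/F200/R205)
are mapped onto the query through an optimal global Needleman–Wunsch
alignment under BLOSUM62 with affine gaps (open 10, extend 1 — conventional
protein defaults, exposed in config). The reference used is the one with
the higher alignment score to the query, ties going to packaged order. A
reference position landing on a gap column yields a '-' in that filter role
and the call is flagged low-confidence; specificity for any incomplete
filter is "unknown" rather than a guess, because partial filters have no
defined selectivity rule.

Specificity rules, in fixed precedence (they are mutually exclusive — the
H2 letters W and F are disjoint):

| rule | pattern | call |
|------|---------------|---------------------|
| G | W-V-[A/G]-R | glycerol permease |
| W | F-H-[A/C]-R | water |
| — | anything else | unknown |

## Distances, trees, bootstrap

Pairwise distances are maximum-likelihood estimates under the JTT model:
Q_ij = s_ij·π_j with the published Jones et al. (1992) exchangeabilities
and frequencies (shipped in `data/jtt_jones1992.dat`, sha256-checked at
load), normalised to one expected substitution per site per unit time.
For each pair, only columns ungapped in both rows contribute (pairwise
deletion, the common default of distance methods; complete deletion is the
configurable alternative), and the log-likelihood
Σ log(π_a P(a→b | d)) is maximised over d ∈ [0, 10] by bounded Brent search
to 1e-6. A fit reaching the bound is capped at d_max = 10 and the pair is
flagged saturated. Transition matrices come from the eigendecomposition of
the symmetrised generator, which is stable for all d. The estimator was
validated against an independent `scipy.linalg.expm` grid-search likelihood
and recovers the true distance on long simulated alignments (e.g. 0.400 at
truth 0.4 on 200k sites).

Trees are built by Saitou–Nei neighbour joining with the Studier–Keppler
Q-criterion; ties in Q break to the lexicographically smallest pair of
cluster representative ids, so runs are reproducible. Negative intermediate
branch lengths are clamped to zero with the difference transferred to the
sibling edge, preserving the joined pair's distance. NJ is exact on
additive matrices, and the tests exercise that guarantee on random additive
matrices of 4–12 taxa.

Bootstrap supports resample alignment columns with replacement (same column
count), rebuild distances and the NJ tree, and report for each internal
edge the percentage of replicates containing the same leaf bipartition.
Replicates with a degenerate distance matrix (a pair left without shared
columns) are skipped; more than 10% skips aborts the run. All resampling is
driven by a single seed.

## Subfamily assignment

Rule precedence:

1. **LIP filter signature** (LE1 = P and LE2 ∈ {L, I}): always wins and is
   tree-independent, so withholding the tree never changes a LIP call. A
   conflicting tree placement is recorded in the evidence trail.
2. **Tree placement**: the smallest bipartition side containing the query
   and every reference leaf of exactly one labeled group, provided it
   contains no other group's references and its edge support meets the
   threshold (default 50%; nested low-support clades are skipped in favour
   of the next enclosing supported clade, and ties between groups are
   treated as ambiguous).
3. **Rule G** (glyceroporin filter) → GIP.
4. **Rule W** (aquaporin filter) → PIP or MIPE, which the filter alone
   cannot separate; without decisive tree evidence the call stays
   unclassified with both candidates recorded.
5. Otherwise unclassified.

Every call carries a non-empty evidence list (filter, boxes, C-terminal
residue, fired rules, tree placement, conflicts), so a reviewer can trace
any label to its inputs.

## The synthetic-data generator

All generated sequences descend from one fixed master scaffold laid out as
a 356-column alignment: background columns, the two box sites, the four
filter sites, and a C-terminal site. Panel sequences, subfamily templates
and the packaged references occupy known column subsets of this scaffold,
so the true alignment of any pair is known by construction and every
downstream stage can be scored against planted truth.

Design choices that matter:

* **Backgrounds** are drawn from the JTT equilibrium frequencies;
  divergence between related sequences is introduced by JTT-conditional
  resampling (master-level relationships) or, for `generate_family`, by a
  per-site Poisson(d) process with uniform replacement over the 19
  alternatives (expected differing-site fraction (19/20)(1 − e^(−20d/19)),
  the closed form the tests check) or an optional JTT-conditional mode.
* **Anchor columns**: the five columns either side of each filter site (and
  a loop-B flank) are conserved in every sequence and take a fixed cycle of
  distinct letters that excludes N/P/G and the common box/filter letters.
  The panel geometry has only two residues between LE1 and LE2 while the
  reference geometries have four or five (their annotated positions are
  fixed by the published numbering), so an alignment gap adjacent to those
  sites is unavoidable; distinct conserved anchors pin the gap between the
  anchors instead of letting it slide onto a filter column. This mirrors
  the biological fact that the NPA boxes and filter sit in the most
  conserved parts of real MIPs.
* **Motif uniqueness**: outside planted boxes, every N-[PG] bigram in any
  background is scrubbed (redrawing the mutable partner), so planted boxes
  are the only motif candidates and recovery statistics are exact rather
  than approximate.
* **Protected sites**: planted boxes, filter residues and the C-terminal
  residue never mutate; indels (per-site probability, default 0.005;
  geometric lengths, mean 2) are re-drawn if a deletion would cover, or an
  insertion would land inside, a protected window (box start−1..start+3,
  filter ±1, terminus).
* **The heterokont panel** encodes the published description of the 20
  algal MIPs: per-protein filter strings, the eight NPM second boxes, the
  NGA and NPG first-box variants, C-terminal lysines, and lengths
  (225/230 for the two short LIPs, 280–317 for the rest of the LIP group).
  Member backgrounds derive from per-subfamily templates (0.35 expected
  substitutions per site from the scaffold) with 0.1 member-specific
  divergence, so tree stages see subfamily-structured signal; the six
  labeled reference leaves (two each for GIP/PIP/MIPE) join the panel's
  true alignment for tree-based assignment. Scaffold, templates and
  packaged references use fixed internal seeds — planted truth is identical
  across user seeds, while member backgrounds vary with the seed.
* **Related template families**: `make_template_family` derives several
  templates from a common root (~0.45 substitutions/site each, so ~0.9
  between siblings). Templates with unrelated random backgrounds would sit
  at saturation (capped distances under pairwise deletion), where
  neighbour-joining placement of long branches is genuinely unstable — an
  early run showed a planted family clade at 99% rather than 100% support
  for exactly this reason. Keeping inter-family divergence far above the
  intra-family level but below saturation makes the bootstrap property
  well-posed.

What the generator does **not** emulate: real transmembrane hydrophobicity
patterns, compositional biases of membrane proteins, rate heterogeneity
across sites, genuine insertion/deletion evolution (indels are placed
uniformly, not loop-biased), and real MIP sequence diversity. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
calibrated on sequences with known truth — not that it would reach the same
accuracy on arbitrary real proteomes.

## Problem sizes and numerical choices

The shipped checks run the panel pipeline with 100 bootstrap replicates on
the 26-row × 356-column alignment, filter recovery on 520 simulated
sequences at divergence 0.3, NJ exactness on 100 random additive matrices
(4–12 taxa), distance calibration on nine 10,000-site simulated pairs
(true d 0.05–0.8), and family bootstrap on 20 sequences from five related
templates — sizes chosen so the whole suite completes in well under a
minute while leaving each statistical check comfortably powered. Optimizer
tolerance is 1e-6 on d; distances are written to six decimals; supports are
integer percentages in Newick output. Degenerate inputs (empty sequences,
ragged alignments, duplicate ids, all-gap trims, matrices with NaNs) are
rejected with messages naming the offending item.

## Known limitations

* The full 212-sequence analysis of real MIPs (and its printed supports,
  e.g. 98% for the LIP clade) requires the deposited dataset and is outside
  desk scale; the statistical property checks above stand in for it.
* PIP vs MIPE separation relies entirely on tree evidence, as the filter
  compositions coincide.
* The packaged references are synthetic stand-ins; for real data a user
  should supply genuine annotated references via the reference-table TSV.
* SIP/MIPC/NIP/TIP labels are recognised in generator truth but are not
  assignable to queries.
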