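# Methods

## The statistic and the decision framework

The toolkit operationalizes a genome-based genus delimitation framework for
bacteria. Its central statistic is the core-proteome average amino acid
identity (cpAAI): the percentage of identical residues between two strains
over the compared columns of a concatenated alignment of a fixed panel of
single-copy marker proteins. Comparison uses *pairwise deletion*: a column
is compared for a pair only if neither row carries missing data there, so
each pair is scored on its own informative sites rather than on a
complete-deletion core. Genera are delimited by combining a cpAAI threshold
with the requirement that a genus be monophyletic in a rooted phylogeny;
species-level questions (synonymy of names) are decided from whole-genome
ANI and dDDH with explicit thresholds.

## Marker extraction

Each genome is translated in all six reading frames; frames are split at
stop codons into open segments. Candidate segments for a marker are those
sharing at least one exact amino-acid 4-mer with the reference and at least
80% of `min_coverage × reference length` residues (a prefilter that removes
essentially all of the short random segments produced by spacer DNA). Each
candidate is aligned locally to the reference (BLOSUM62 with X scoring 0
against everything; affine gaps, open 11 / extend 1). A hit is reported if
its score is ≥ `min_score` (default 50 matrix units) and it covers ≥
`min_coverage` (default 0.5) of the reference; the best hit per marker is
kept, with ties broken by contig id, start coordinate, then '+' strand.
These acceptance thresholds are this toolkit's own: in simulation they
reject i.i.d. random sequence (whose best local scores sit well below 50)
while retaining markers diverged by ~30% at the amino-acid level. Because
alignments are local and never cross stop codons, a mismatched terminal
residue may be shaved off, so reported nucleotide coordinates can sit a few
codons inside the true gene extent; a marker interrupted by an internal
stop contributes its best single segment. Markers with no qualifying hit
are replaced by all-X "gap proteins" of reference length, so a strain's row
is always complete.

An external translated-search tool can replace the built-in stage as a
configured command; its output is mapped onto the same hit contract.

## Alignment, trimming, concatenation

The built-in aligner is a deterministic center-star progressive alignment:
the center is the sequence maximizing the summed pairwise global alignment
score (ties to the earlier strain), every other sequence is aligned to the
center, and gap patterns are merged ("once a gap, always a gap"). This is a
transparent, dependency-free surrogate for a production aligner; MAFFT or
any other tool can be plugged in as a `{in}`/`{out}` command template, and
the pipeline contract is aligner-agnostic (switching aligners is known to
shift cpAAI values slightly, which is why thresholds are guidelines rather
than hard limits).

Trimming removes columns whose gap fraction exceeds `max_gap_fraction`
(default 0.9). Only `-` counts as a gap; X counts as a residue for trimming
but as missing for cpAAI. This asymmetry is deliberate: placeholder columns
must survive trimming so that pairwise deletion — not the trimmer — decides
which sites a pair is compared on. The named heuristics of dedicated
trimming tools are not re-implemented. Trimmed marker alignments are
concatenated in panel order; the partition map records each marker's column
range, and slicing the supermatrix by the map reproduces the inputs
exactly.

## cpAAI

For rows *a*, *b* of the supermatrix, cpAAI = 100·m/c with c the number of
columns where neither row is in the missing set {`-`, `X`} and m the
identical ones among them. Treating X as missing (exposed as
`--missing-chars`) is what gives the gap proteins their intended semantics;
the implementation guarantees exactly that padding a marker with X for a
strain equals deleting that marker's columns for that strain's comparisons.
A pair with zero comparable sites is an error, not a number. Values are
kept at full precision internally and reported to 2 decimals.

## Tree building, rooting, monophyly

The built-in tree is neighbor joining on the percent-difference matrix
100 − cpAAI, with ties in the Q criterion broken by the smallest index pair
and negative branch lengths clamped to zero (deficit logged). NJ exactly
inverts additive matrices, which is the property the tests enforce. The
likelihood machinery of production phylogenomics (model selection, ML
search, support values) is deliberately out of scope: an externally
inferred tree can be supplied as Newick and used by every downstream stage,
and support annotations are carried but never drive delimitation decisions.
Rooting is strictly by outgroup (root at the midpoint of the edge
separating the outgroup, which must be a clan); the pipeline falls back to
midpoint rooting when no outgroup is configured. A leaf set is monophyletic
iff the leaves under its MRCA are exactly that set.

## Genus delimitation

Clustering is single linkage: connected components of the graph with an
edge wherever cpAAI ≥ τ. Single linkage was chosen because the framework's
notion of a boundary is "clean separation" — no chain of above-threshold
pairs across genera — and because it is order-independent. τ defaults to
86.5%. Clusters that are not monophyletic are re-clustered *locally* (among
their own members only) at τ′ = τ + k·step (step 0.1) up to τ_max = 89%,
accepting the smallest τ′ at which all sub-clusters are monophyletic; this
mirrors the practice of raising the threshold within a recalcitrant clade
(boundaries around 88.0–88.5% in the hardest cases) while the cap guards
against over-splitting. Irreconcilable clusters are reported whole as
`manual_review` with their cpAAI evidence printed — expert judgment calls
(e.g. keeping a borderline monophyletic group together) are deliberately
not automated.

Actions are derived from type species: a cluster with exactly one genus
type species keeps that name and differently-labelled members become
transfers; several type species raise merge flags; none yields a
novel-genus placeholder (naming is a human act); a genus scattered over
clusters is flagged paraphyletic. Every action cites the minimum
within-cluster cpAAI, the maximum cpAAI to other clusters, and the
cluster's monophyly status.

## ANI and synonymy

The fragment ANI estimator cuts the query into non-overlapping 1,020 bp
windows and aligns each to the subject (edit distance, infix mode, both
strands); fragment identity is 1 − edits/alignment length, fragments are
kept at ≥ 30% identity over ≥ 70% of their length, ANI is the mean kept
identity, and symmetric mode averages both directions. These are classical
fragment-ANI conventions; the estimator is exact on identical and
reverse-complemented genomes and tracks planted divergence d as
100·(1 − d) within a percentage point. Published ANI values can always be
supplied by table instead, and the packaged *Rhizobiaceae* table is the
reference input for the synonymy screen. dDDH is never computed — values
(with confidence intervals and formula provenance) are ingested only.

The synonymy rule, in order: ANI < 95% → distinct; dDDH missing → flagged
`needs_dddh`; dDDH ≥ 70% and ANI > 96% → synonym; dDDH < 70% → distinct;
dDDH ≥ 70% with ANI ≤ 96% → `conflict` (a combination the framework has
not encountered; flagged, not resolved). The 96% species cut-off follows
the proposal for the *Rhizobium* species complex; all three thresholds are
configuration.

## Synthetic data

The generator builds an ultrametric tree in which each genus is a clade:
within-genus coalescences below `within_depth` (crown exactly at it) and
genus-level joins confined to the deepest 5% of `between_depth`, so
between-genus paths are all close to 2·between_depth. Marker proteins
evolve by uniform replacement: on a branch of length l each site is
resampled uniformly over the 20 amino acids with probability 1 − e^(−r·l),
giving the closed form id(ℓ) = e^(−rℓ) + (1 − e^(−rℓ))/20 for two leaves
at path length ℓ. The defaults (r = 1.0, within_depth = 0.044,
between_depth = 0.118) were solved from that closed form to put
within-genus cpAAI at ≈ 92–100% and between-genus cpAAI at ≈ 80%, the
regime in which a mid-80s threshold separates genera. Genomes pack
reverse-translated markers (uniform synonymous codons) in random order and
strand with random 50–150 bp spacers; per-marker dropout simulates
incomplete assemblies. All randomness flows from one seeded generator per
call; outputs are byte-identical across reruns.

What the simulations do *not* emulate: indels within markers (substitutions
only), empirical amino-acid exchangeabilities, codon bias, paralogy,
horizontal transfer, contamination, and realistic genome architecture.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's logic, not robustness to every artefact of real assemblies; on
real data the external aligner/search hooks and the manual-review pathway
carry that load.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale datasets chosen as the package's
own validation conditions: 5 genera × 4 strains × 170 markers (~60–140 aa)
for end-to-end recovery over five seeds, 200 kb genomes for ANI
calibration, trees of up to 12 leaves for NJ inversion and 8 leaves for
exhaustive monophyly enumeration. Floating-point behaviour is kept
deterministic: fixed tie-breaks in search, alignment and NJ; threshold
grids generated by integer steps and rounded; cpAAI compared exactly
against a brute-force oracle in the tests. Degenerate inputs fail loudly
(empty alignments after trimming, pairs with no comparable sites,
outgroups that are not clans, unrooted trees passed to monophyly-dependent
stages).
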