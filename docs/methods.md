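# Methods

This note documents the models and algorithmic choices behind
`repskim`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design
was genuinely open.

## Synthetic data model (`synthgen`)

The generator emulates a multi-species genome-skimming experiment on a
small plant clade.

**Species tree.** `make_species_tree` draws a rooted, ultrametric
binary tree with user-defined clades. Within-clade joins happen in a
shallow height band and clade joins in a deep band (defaults 8–30%
and 70–100% of the root-to-tip depth; the bundled four-clade scenario
tightens these to 3–10% and 90–100%), giving the pattern of recent
radiations separated by deep cladogenesis. Depth is in expected
substitutions per site. Clades are monophyletic by construction and
all branch lengths are positive.

**Repeat family evolution.** Each family has a single consensus that
evolves down the tree by a per-edge Jukes–Cantor kernel
(P(change) = ¾(1 − e^(−4d/3)), uniform over alternatives), which
composes exactly along paths. Two divergence modes exist: a flat
per-branch expected divergence (every edge contributes the same), and
a clock-like rate multiplying branch lengths. Evolution is
substitution-only — no indels — so identity expectations between any
two species' copies are closed-form, and alignment-based oracles stay
exact. Within a species all copies of a family are identical; real
repeat families carry within-genome variation that this model omits,
so tests exercising cross-species contrasts are conservative about
within-species noise.

**Genomes and reads.** Tandem families are emitted as one contiguous
head-to-tail array (copy number = fraction × genome / monomer length;
dropped with a warning below 2 copies); TE families as dispersed
identical copies; the remainder is i.i.d. uniform background.
Realized fractions match requests to within one monomer/element.
Reads (default 151 bp) are drawn uniformly with uniform strand,
i.i.d. substitution errors (default 0.1%) and constant phred
qualities implied by the error rate; mates are emulated as
independent reads. Read counts follow round(coverage × G / L)
exactly; a fixed seed makes all outputs byte-identical.

**What passing tests show.** The generator has no indels, no nested
insertions, no quality drift, no organelle genome beyond a random
decoy contig, and no within-species repeat heterogeneity. Tests
passing on it demonstrate the pipeline's contracts and statistical
behavior under those idealizations, not performance on real library
artifacts.

## The four-clade benchmark scenario

`four_clade_scenario` fixes the study design used by the end-to-end
validation: 15 species in clades of 6/2/6/1 with 1-Mb genomes,
151-bp reads at 0.15× simulated coverage, comparative subsampling to
0.1× (≈ 714 reads/species, ~10⁴ pooled), 2% organelle contamination.
Families: five 1.2-kb TE families shared by all species (lineage
labels from the controlled vocabulary) evolving clock-like at rate
0.58 per unit branch length; three clade-specific satellites per
multi-species clade (monomers 171/180/184 bp); one species-specific
satellite per species (177 bp); and one 158-bp "relic" satellite
shared across two clades. Per-species repeat content lands around
38–44%, dominated by the TE families, matching what skims of small
crucifer genomes report.

The TE rate is the load-bearing calibration: at tree depth 0.1,
cross-clade copy identity sits just above the 90% edge threshold
(sparse inter-clade edges) while within-clade identity is 97–99%
(near-complete edge density). That contrast is what the
observed/expected edge statistic converts into tree signal. Satellite
monomers (≈180 sites) were deliberately *not* used as the all-species
signal carriers: per-family realized divergence on so few sites has
large Poisson spread, which pushes individual species pairs off the
identity threshold entirely and produces incomplete similarity
matrices. Long elements average that noise over 1,200 sites.

## Preprocessing (`readprep`)

The preprocessing contract: a read survives iff ≥ 90% of its bases
are ≥ Q20 and it is ≥ 140 bp; survivors keep their 5′-most 140 bases
(a deterministic rule chosen over sliding-window trimming because
only the output-length contract matters downstream). Organelle reads
are removed when ≥ 50% of a read's canonical 31-mers occur in the
chloroplast/mitochondrial reference index — a deterministic,
alignment-free filter; the threshold and k are declared defaults, not
inferred from any published setting. Coverage normalization draws
round(c · G / L) reads without replacement under a fixed seed,
counting single reads (not pairs).

## Read clustering (`graphclust`)

Edges require identity ≥ 0.90 over ≥ 0.55 · L columns of the best
local alignment (+1/−1/−2, both strands); both thresholds are
inclusive. Three-stage screening keeps all-vs-all feasible: (1)
shared canonical 17-mers nominate candidate pairs (≥ 3 shared; any
pair with a ⌈0.55 L⌉ exact stretch shares ≥ 61, so the guarantee
holds with margin); (2) the offsets implied by shared k-mers are
evaluated ungapped — a pair already passing both thresholds ungapped
is an edge, one > 0.04 identity below threshold at its best offset is
dropped (gapped alignment cannot close that gap under this scoring);
(3) the inconclusive band goes to the dynamic-programming kernel.

Clusters are connected components, ordered by size with smallest-id
tie-break; singletons pool as unclustered. Components with edge
density < 0.01 are additionally split by greedy modularity refinement
when it yields modularity > 0.3. The threshold is deliberately low:
reads tiling a long element form a legitimate low-density positional
chain (density ~0.05–0.1), and a higher threshold was observed
cutting such families into positional fragments. Genome proportion is
100 · size / total reads, with detailed annotation only *strictly
above* 0.01%. Cluster annotation takes the majority lineage among
reads hitting a reference at ≥ 90% identity over ≥ 50 columns;
"unclassified" below 20% hitting reads; a confident tandem call
overrides.

Known limitation: connected components are single-linkage, so
families below ~20% mutual divergence can chain through occasional
77-bp windows that exceed 90% identity, merging clusters; conversely
low coverage can fragment a family positionally when read-start gaps
exceed L(1 − 0.55). Purity claims therefore hold for clearly
divergent families at adequate coverage.

## Tandem monomer calling (`tandemcall`)

The de Bruijn graph uses canonical (strand-minimal) 21-mers with
counts. The monomer detector walks greedily from the heaviest k-mer
along heaviest successors until a cycle closes; the cycle spells the
monomer, reduced to its primitive root and canonical rotation
(lexicographic minimum over rotations × strands). Confidence is the
cycle's share of graph weight computed over "solid" k-mers — count
≥ max(2, 0.2 × the heaviest count). The adaptive floor matters: at a
5% per-base error rate only 0.95²¹ ≈ 34% of k-mer instances are
error-free, so confidence over the raw graph could never reach the
0.45 acceptance threshold even for a perfect satellite; anchoring the
floor to the heaviest (always-genuine) k-mer strips the error cloud
across any coverage. Monomers longer than twice the read length are
flagged low-confidence: no read spans them, so their length is an
estimate from the cycle walk. The autocorrelation periodicity check
scans lags from 10 to half the sequence length and then reduces the
best lag to its smallest divisor scoring within 0.05 — without the
reduction, any multiple of a short period would be reported when the
true period lies below the scanned range; 0.05 covers the score
fluctuation a 5% substitution load induces.

## Shared repeats (`sharedrep`)

Monomers are circular, so identity is the maximum over all rotations
of the shorter sequence and both strands of global-alignment identity
(end gaps penalized like internal ones). Families form by single
linkage at ≥ 80% identity with a 2-fold length gate; the default sits
just below the 82.5% floor observed for genuinely homologous shared
satellites in published inventories, and is a configuration knob
since no detection cutoff is standard. Classification counts
per-species repeat records (not families): species-specific /
within-clade / cross-clade percentages are rounded half-up to one
decimal so the three classes reproduce printed partitions exactly.

## Repeat-similarity phylogeny (`repeatphylo`)

The expected inter-species edge count places the cluster's M edges
uniformly over read pairs: E_ij = M · 2 n_i n_j / (N(N−1)). This is a
declared surrogate — the upstream literature does not print its
formula — and reduces to S = 1 for a perfectly mixed cluster.
Distances are plain inverses; clusters with a missing species or a
zero observed pair are excluded as incomplete. Neighbor joining is
the standard Q-criterion agglomeration with smallest-index
tie-breaking and no branch-length clamping by default (negative NJ
lengths are information, not errors). The majority-rule consensus
keeps splits in strictly more than half the trees, greedily skipping
incompatibilities in frequency order; branch lengths average over
supporting trees and supports are written as internal node labels.
Per-cluster distances are not normalized before consensus. The
abundance dendrogram uses Euclidean distances between species'
cluster-abundance profiles (clusters filtered at > 0.01% genome
proportion) under complete linkage.

## Ks estimation and WGD dating (`ksdate`)

Sites and differences follow NG86: per-codon synonymous site
fractions from the nine single-nucleotide neighbors (stop-codon
mutations excluded from denominators), multi-hit codons averaged over
all minimal stop-free pathways, site totals averaged over the two
sequences. Ks applies the Jukes–Cantor correction and is undefined at
ps ≥ 0.75 (flagged saturated, excluded from peaks). The estimator is
recorded in output metadata since different pipelines default to
different corrections. Peak detection evaluates a Gaussian KDE on
[0, 2] and reports local maxima with prominence ≥ 10% of the maximum.
The bandwidth defaults to Scott's rule (scipy's `gaussian_kde`
default) and is overridable; a Sheather–Jones selector was considered
and not adopted because no dependency in the supported stack provides
one and re-deriving it here would be its own project. Dating uses
T = Ks/(2μ): both lineages accumulate synonymous substitutions, so
the pairwise distance grows at 2μ per year. The four-fold-degenerate
codon-pair simulator exists because it makes the JC-corrected
estimator exactly unbiased (every codon carries one clean four-state
site), which is what a calibration test needs.

## Summary statistics (`repstats`)

Percentages round half-up at printed precision so published-style
table arithmetic reproduces digit-for-digit; totals and their
low/single-copy complements always close to 100. A column is
parsimony-informative iff at least two residues each occur in at
least two sequences, with gaps and ambiguity codes ignored as states
(the standard convention; gap handling is otherwise unspecified in
the sources this mirrors). The repeat-content/genome-size regression
is ordinary least squares with the two-sided slope t-test; abundance
may be supplied in Mb or percent.

## Problem sizes

The default test suite and the acceptance script run at desk scale:
1-Mb genomes, ≈ 714 comparative reads per species (≈ 10,700 pooled),
five complete-matrix clusters feeding the consensus, 400 simulated
gene pairs of 300 codons for the Ks peak, and monomers from 27 to
500 bp for length recovery. These sizes were chosen so a full run
completes in minutes on one CPU while every statistical claim keeps a
comfortable margin; the same code runs unchanged on larger designs.
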