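# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Homolog collection

Collection is the least fixed point of an iterative similarity search:
starting from seeds, every database subject whose hit from *any* current
member has `E ≤ ε` joins, and rounds repeat until nothing is added. Union
("any member") semantics makes the result independent of seed processing
order; a visited set guarantees termination; the result equals plain
reachability in the directed passing-hit graph (checked against an
independent breadth-first oracle).

A printed E-value of exactly 0.0 is representation-dependent, so the
stringency is expressed as a configurable epsilon, default `ε = 1e-180`
(roughly where ~700-residue near-identical protein pairs saturate the
Karlin–Altschul formula). The simulated study uses `ε = 1e-50`: at 300
residues and family-level divergence that cutoff plays the same
"essentially exact match" role, since the formula scales with sequence
length. The built-in backend is exact Smith–Waterman (Biopython's
`PairwiseAligner`, BLOSUM62, affine −11/−1 by default) with
`E = K·m·n·exp(−λS)`, `K = 0.041`, `λ = 0.267` (ungapped BLOSUM62
constants; absolute calibration matters less here than monotonicity, and
both are configurable). Deduplication keeps the longest record per
(taxon, gene label), ties broken to the smallest id; records labelled
`other` group by taxon alone with a logged warning.

## Parsimony, MPRs, and unambiguous synapomorphies

**Scoring.** `fitch_score` implements Hartigan's state-count algorithm:
at each node the children's state sets vote, the states with the maximal
count are kept, and `(#children − max count)` changes are charged. On
binary trees this is exactly Fitch; on polytomies it remains exact
(verified against exhaustive labeling enumeration). Gaps and `X` are
treated as missing data — the full state set, contributing no forced
change — not as a 21st state.

**MPR space.** For unordered characters with unit costs, some optimal
labeling uses only observed states (replacing any maximal connected set
of unobserved-state nodes with its most frequent boundary state strictly
reduces cost), so MPR enumeration and all derived quantities restrict the
internal state space to the states observed in the column.

**Unambiguous synapomorphies.** The definition: (node, column) is an
unambiguous synapomorphy iff every MPR places a change on the branch
entering the node and the derived state is identical across MPRs.
Rather than materialising MPR sets (worst-case exponential), the
implementation uses an equivalent characterisation in terms of Sankoff
inside/outside minimum costs: letting `possible(v)` be the states `v`
takes in at least one MPR (`inside(v,s) + outside(v,s) = optimum`), the
condition holds exactly when `possible(v) = {s}` and
`s ∉ possible(parent)`. Equivalence with the literal all-MPRs definition
is exercised on random instances in the acceptance suite. Entries are
recorded once per (node, column); the ancestral state is reported as the
`/`-join of `possible(parent)`. Only internal nodes enter the table;
changes on terminal branches are counted separately as autapomorphies.
Detection requires a rooted tree (polarity is undefined otherwise), and
a clade whose stem coincides with the root edge cannot yield stem
synapomorphies — the reason the simulator plants a basal outgroup.

**Search.** Multi-start: each start builds a random-addition tree (greedy
stepwise insertion in a shuffled order) and hill-climbs with
subtree-prune-regraft moves, first-improvement sweeps, until a local
optimum; all distinct topologies at the best score across starts are
retained (cap 64). Scoring is vectorised over columns with bitmask state
sets. Defaults: 4–8 starts, fixed seed; deterministic for a fixed seed.
This is a documented standard substitute for specialised ratchet/drift
heuristics and decay indices, so support values are comparable in kind,
not in number, with such tools. Consensus trees (strict and >cutoff
majority rule, default 0.5) delegate split bookkeeping to dendropy.
Bootstrap supports are standard nonparametric column resampling (default
100 replicates, 2 starts per replicate), reported as 0–100 clade
frequencies on the majority consensus of replicate trees.

## Frequency profiles and domain tables

Per-column synapomorphy counts are scaled to percentages of the total
(zero totals yield a flagged all-zero profile); histograms use bins
anchored at column 0 (default width 5, final bin partial), and binning
conserves mass exactly. Domain membership is by alignment column: each
domain's reference-residue interval is projected through the reference
row to a column window (insertions relative to the reference inside the
interval are included). Columns outside every domain fall in an implicit
`inter-domain` row so totals reconcile; overlapping domains (βA4 within
E3) are kept explicitly and each counts its columns, so only disjoint
domains are additive. Two denominator conventions are provided:
`scope="whole"` divides by the whole tree's synapomorphy total,
`scope="branch"` by each branch's own total. Branch stratification keeps
entries on nodes inside a named monophyletic clade, stem node included by
default (stem changes are what diagnose the clade).

## β-pairing energies and the consensus predictor

A pairing is an equal-length ungapped window pair (length ≥
`min_strand_len`, default 4), parallel or antiparallel, scored as the sum
of tabulated residue-pair energies; identical self-windows are excluded
but register-shifted self-pairings are allowed. Each residue's profile
value is the minimum energy among pairings covering it (the total energy
of the best covering pairing, not a per-residue average); residues no
admissible pairing covers carry an infinite sentinel. The implementation
works diagonal-by-diagonal with cumulative sums and sliding-window
minima, and is exact: it matches an exhaustive `O(L⁴)` window-pair oracle
on random sequences.

**The energy table is a synthetic surrogate**, not a published potential:
`E(a,b) = −γ(p_a·p_b − θ)` per paired position with a β-aggregation
propensity scale `p ∈ [0,1]` (I/V/F/L high, D/E/K/P near zero),
`γ = 1.1`, `θ = 0.25`, antiparallel scaled ×1.05. The constants were
calibrated once against three anchors — the C-terminal half of human
Aβ42 scores below −4, a poly-serine control stays above −2, and planted
hydrophobic 8-mers yield qualifying segments — and are not revisited.
Absolute energies from the surrogate are therefore not comparable to any
published server's values; the −4/−3/−2 thresholds retain their roles
(fibril-competent / marginal / non-amyloidogenic) relative to this
calibration.

The consensus predictor is k-of-n (default k=2) over three built-in
per-residue scorers: centred 5-residue Kyte–Doolittle hydrophobicity mean
≥ 1.5; centred 5-residue Chou–Fasman β-sheet propensity mean ≥ 1.2; and a
hexapeptide stretch detector flagging 6-windows drawn entirely from
{I,V,L,F,M,W,Y,C,A,T}. Consensus is antitone in k and in every scorer
threshold (property-tested). Segments are maximal runs where energy band
and consensus agree — high: `E < −4`; low: `−4 ≤ E ≤ −3` (the boundary
−4 belongs to the low band) — with runs shorter than `min_run = 3`
dropped to suppress single-residue threshold noise. The truncation scan
re-evaluates the global minimum energy after each C-terminal deletion and
stops at the first value above −2 (entry included); a prefix too short
for any pairing reports the sentinel, which also stops the scan.

**Region extraction.** The βA4-homologous region runs from the β-site to
the γ-site and is split at the α-site column into N- and C-terminal
windows. Boundary columns come from the taxon's own cleavage annotation
if present, else from the nearest annotated taxon by topological tree
distance (ties to the lexicographically smallest id), else from the
reference projection; the provenance (`own` / `neighbor:<id>` /
`fallback-reference`) is recorded per taxon. Energies are profiled over
the whole region (the two strands stabilise each other), then segments
are classified within each window separately, so one boundary-spanning
run cannot satisfy the two-region rule by itself. The per-taxon call:
`none` if either window lacks a qualifying segment, otherwise the class
of the best N-terminal segment (`high` beats `low`). The packaged human
APP770 domain map and cleavage annotation are worked examples of the
input formats, with approximate domain boundaries; real analyses should
supply curated coordinates.

## The simulator

`simulate_family` draws a Yule backbone over the clades with one Yule
subtree per clade (clades are monophyletic by construction), optionally
attaches a basal outgroup tip, and normalises total tree length to 1 so
the global rate reads as expected substitutions per site across the whole
tree. Sequences evolve site-independently under uniform exchange (a
mutated site moves to one of the other 19 residues uniformly); per-domain
rate multipliers scale the per-branch substitution probability
`p = 1 − exp(−rate·mult·t)`. Planted clade-diagnostic substitutions are
applied on the designated clade's stem and their columns are frozen
everywhere else, so the truth is assertable; planted aggregation motifs
are drawn once per plant from a hydrophobic alphabet and written verbatim
into every targeted tip (a conserved amyloidogenic region). Every event
is logged (mutation log, planted coordinates, true tree) and emission is
byte-reproducible for a fixed config and seed.

The standard simulated study (defaults in
`appfam.pipeline.default_study_config`) uses five clades × four species
plus the outgroup, 300 residues, 0.25 substitutions/site over the tree,
domain analogs NTS/E1/E2/βA4/E3 with rate multipliers
1.2/0.8/1.6/0.5/0.3 (E2 most variable, E3 most conserved), three planted
synapomorphies per clade placed in the E2 analog, one conserved
C-terminal βA4 motif family-wide and one N-terminal motif confined to the
APP clade, over a polar-biased background. Validation batches use
4 clades × 4 species (16 family taxa) for speed. These sizes keep the
whole validation battery and acceptance run within a couple of minutes on
one CPU.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: indels and alignment error (simulated rows are
indel-free, so the alignment step is trivial and the center-star fallback
aligner is exercised only on toy insertions); rate variation beyond
per-domain multipliers (no among-site gamma, no heterotachy); realistic
residue exchangeabilities (uniform exchange, not an empirical matrix);
database noise (no partial sequences, no isoform redundancy beyond what
dedup tests construct); and the true βA4 sequence composition (plants are
random hydrophobic stretches). Recovery rates measured on simulations are
upper bounds on what curated real data would give.

## Numerical and interface conventions

Coordinates are 0-based half-open in memory, 1-based inclusive in every
on-disk table and printed report. Gaps are `-` (`.` normalised on read);
`*` stops are stripped; rare ambiguity codes (B, Z, J, U, O) fold to `X`.
FASTA headers carry `id|taxon|gene_label`; Newick annotations use
`[&support=..,class=..]` comments (parsed via dendropy, written by the
package so the dialect round-trips). Unrooted tree comparisons use
Robinson–Foulds symmetric difference on canonical splits. All stochastic
procedures take explicit integer seeds; the pipeline writes a sha256
manifest per run and identical configs reproduce identical manifests.

## Limitations

Bayesian inference, decay indices and nucleotide-level analyses are out
of scope. The heuristic search can return multiple tied optima on weak
backbone signal; consensus polytomies then raise the RF distance to the
true tree even when every clade of interest is recovered (the planted
synapomorphy recovery metric is the meaningful one). The surrogate
energy table is qualitative; conclusions that depend on absolute pairing
energies of real proteins require transcribing a published potential into
the `PairingEnergyTable` TSV format and re-running with
`--energy-table`. The nearest-annotated-neighbour rule for cleavage
boundaries is a reconstruction heuristic; where boundaries matter,
annotate taxa explicitly.
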