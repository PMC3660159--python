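# appfam

Phylogenetic conservation and amyloid-aggregation analysis of the amyloid
precursor protein (APP) gene family.

## The problem

The APP family — APP, APLP1 and APLP2 in vertebrates, APL-1/APPL-1 in
invertebrates — is ancient and highly conserved, yet only some species
deposit amyloid-β, the aggregation product of the βA4 region of APP.
Asking *where* in the protein evolutionary change concentrates, and *when*
an aggregation-competent βA4 could first have existed, requires three
linked analyses:

1. **Homolog collection.** Starting from seed sequences, an iteratively
   repeated stringent similarity search is run to its transitive fixed
   point: every subject whose best hit from any current member passes the
   E-value threshold joins, until a round adds nothing. One longest
   representative per (taxon, gene) is kept. The built-in backend is exact
   Smith–Waterman with Karlin–Altschul E-values
   (`E = K·m·n·exp(−λS)`); an external search tool can be plugged in.
2. **Maximum-parsimony phylogeny and synapomorphy profiling.** Trees are
   scored by Fitch parsimony (Hartigan's exact generalisation on
   polytomies), searched with random-addition + SPR hill climbing, and
   summarised by majority-rule consensus with bootstrap supports. An
   *unambiguous synapomorphy* at a node is a column for which **every**
   most-parsimonious reconstruction places a change on the branch entering
   that node, always to the same derived state. Synapomorphy counts are
   profiled per column (5-residue binned histograms) and per named domain
   (signal peptide, E1, E2, E3, βA4), both as a share of the whole tree's
   synapomorphies and as a share within each major clade — low frequency
   marks conserved domains, high frequency marks variable ones.
3. **Amyloid-potential modelling.** For each taxon's βA4-homologous region
   (delimited by secretase cleavage annotations, a nearest annotated
   neighbour on the tree, or projection from the reference), a β-pairing
   energy profile assigns every residue the minimum energy over all
   window-pair alignments covering it (both strand orientations). Residues
   with energy < −4 and agreement of ≥ 2 of 3 sliding-window scorers form
   *high* segments; the −4…−3 band forms *low* segments; a C-terminal
   truncation scan records the minimum energy until it rises above −2.
   A taxon is called **high**/**low**/**none** by the two-region rule: a
   stable cross-β fold needs qualifying segments in *both* the N- and
   C-terminal windows, with the N-terminal segment setting the class.

Because real accession harvests are database-version dependent, the
package ships a first-class simulator: families evolved along a known tree
with domain-structured rates, planted clade-diagnostic substitutions
(known synapomorphies) and planted hydrophobic motifs (known
aggregation-prone regions), so every stage is validated against ground
truth. The packaged β-pairing energy table is a calibrated synthetic
surrogate (see `docs/methods.md`).

## Worked example

The numbered scripts under `analysis/` run the standard simulated study
(five clades of four species plus an outgroup, 300 residues) and write
their tables under `results/study/`:

```bash
python analysis/01_simulate_family.py --seed 1
python analysis/02_collect_homologs.py
python analysis/03_build_tree.py
python analysis/04_synapomorphy_profile.py
python analysis/05_amyloid_potential.py
```

which prints, among other things:

```
collection closure over 21 database records
  retained after closure + longest-per-taxon: 21
parsimony search kept 4 optimal tree(s)
  bootstrap supports: median 100 over 12 clades
52 unambiguous synapomorphies on the consensus tree
  NTS            3.85% of whole-tree synapomorphies
  E1            17.31% of whole-tree synapomorphies
  E2            46.15% of whole-tree synapomorphies
  bA4           21.15% of whole-tree synapomorphies
  E3             3.85% of whole-tree synapomorphies
planted synapomorphies recovered at the correct node: 15/15
per-taxon amyloid-formation potential (n=21): high=4, low=0, none=17
  high-potential taxa: ['APP_01', 'APP_02', 'APP_03', 'APP_04']
```

Read: the closure recovered the whole family from five seeds; the fast
E2 analog concentrates change (46%) while the E3 analog is conserved
(3.9%); every planted clade-diagnostic substitution was re-identified at
its clade's node; and only the APP clade — the one carrying planted
aggregation motifs in **both** βA4 windows — is called high-potential,
while the family-wide conserved C-terminal motif alone leaves every other
taxon at "none".

The same machinery is scriptable (`appfam run -c config.json`) and usable
as a library; see `appfam.pipeline.PipelineConfig` for every knob.

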