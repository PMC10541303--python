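# Methods

## Mass arithmetic

Monoisotopic masses are sums of most-abundant-isotope exact masses from a
bundled CODATA/IUPAC table (C = 12 exactly, H = 1.00782503207,
O = 15.9949146196, N = 14.0030740048, …). Protonation uses the proton mass
1.00727646 Da — i.e. the electron mass is accounted for — which is standard
ESI-MS practice. Adduct m/z is (M − Σ neutral losses + n·m_H⁺)/z; the only
neutral loss the adduct grammar currently accepts is a formula in square
brackets, e.g. `(M+H)+[-H2O]`. ppm error is signed,
(measured − theoretical)/theoretical × 10⁶.

Formula parsing strips underscore/caret markup first so strings copied out
of typeset tables parse verbatim. Reported table output rounds half-even to
4 decimals; full precision is kept internally.

Two caveats observed while validating against published marker-compound
tables: printed "calculated" ion values are sometimes given at 3 decimals
or are internally inconsistent with the formula by ~0.6–0.9 mDa, and
printed ppm-error columns are not always reproducible from the printed
measured/calculated pairs under any standard sign convention. The package
implements the standard definitions and asserts agreement only within one
unit of the last printed decimal, only for rows that are internally
consistent.

## QED drug-likeness

Each descriptor x is mapped through an asymmetric double sigmoid

d(x) = [a + b·σ((x − c + d/2)/e)·(1 − σ((x − c − d/2)/f))] / d_max,

with the published coefficient table (one set per descriptor) shipped as a
constant. The logistic is evaluated in an overflow-safe form and d is
floored at 10⁻¹² so the log-space geometric mean is total; the floor is far
below the ADS asymptote a/d_max and never binds in practice. QED is
exp(Σ wᵢ ln dᵢ / Σ wᵢ). The default is the unweighted variant (wᵢ = 1); the
published maximum-information-content weights are available as
`weights="max_info"`. The choice matters little for a 0.4 cutoff but is
left explicit because screening reports rarely state which variant was used.

Descriptors are consumed from the input table rather than computed from
structure, keeping the core free of a chemistry toolkit dependency; the
test suite cross-checks the ADS/QED implementation against rdkit's
independent reference to 10⁻⁶ on random descriptor vectors.

The OB flag is an input column. The synthetic generator derives it as a
Bernoulli(0.9/0.1) conditioned on a Lipinski + Veber pass, which mimics a
rule-based oral-absorbability call with some disagreement noise.

## Target mapping

Gene symbols are canonicalized by strip + upper-case; the intersection key
is the symbol (UniProt accessions are carried as annotation only).
Relevance scores come from the disease-gene input; the cutoff (default 9)
is inclusive. Conflicting duplicate scores are an error rather than a
silent first-wins.

## PPI topology

Edges with STRING-style combined score ≥ 700 ("high confidence") are kept;
self-loops dropped; duplicate orientations collapsed (keeping the larger
score). Shortest paths are unweighted — confidence gates edge inclusion but
does not weight distances, matching common practice for topological
screens. Centralities:

* degree — incident edge count;
* betweenness — shortest-path betweenness normalized by (n−1)(n−2)/2, so
  published thresholds like 0.001 are meaningful on small subnetworks;
* closeness — (n_c − 1)/Σd within a component, scaled by (n_c − 1)/(n − 1)
  (Wasserman–Faust), because potential-target subgraphs are often
  disconnected. Isolated nodes get 0 for both.

These equal explicit enumeration of every shortest path on all random
graphs up to 10 nodes (1,000 cases in the suite).

The triple threshold (degree ≥ 10, betweenness ≥ 0.001, closeness ≥ 0.6 by
default) is entirely configurable: published screens sometimes state a
degree cutoff inconsistent with the degrees of the targets they report,
which suggests degrees computed on a different (larger) neighborhood. The
pipeline computes subgraph degree and leaves the thresholds to the
configuration; the synthetic fixtures use thresholds consistent with their
own construction (below).

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k), evaluated via the
survival function (log-space internally); exact agreement with rational
arithmetic enumeration is asserted for every configuration with N ≤ 12.
The universe defaults to the union of the annotation collection (enrichment
backgrounds are rarely stated in screening reports, so the default is the
most reproducible one) and can be overridden. Raw P < 0.05 is the default
filter; BH adjustment at the same level is the optional stricter mode.
Terms with zero overlap are never reported. Top pathways for the C-T-P
network are the first 20 by ascending p with term-id tie-break.

Because the hypergeometric is discrete, the attainable level just below
0.05 is slightly conservative; with the calibration design used in the
suite (universe 2,000, query 300, term sizes 150–400) the null rejection
fraction is ≈ 0.042, inside the 0.05 ± 0.02 band asserted over 2,000
replicates.

## C-T-P network

Node ids are layer-prefixed (`cpd:`, `tgt:`, `pwy:`) so compound names
cannot collide with gene symbols; only compound–target and target–pathway
edges are representable. Compound degree equals the number of correlating
key targets. Key compounds are selected either by top-k or by a degree
threshold (degree ≥ 3 reproduces the seven-marker example bundled in
`phytonet.datasets`). Exports are two sorted TSVs (nodes, edges) that
round-trip and import into Cytoscape-class viewers.

## Synthetic study generator

What it emulates — and the defaults, which mirror the scale of the
ten-herb screen the pipeline is patterned on:

* **Library**: 2,419 rows over 10 herbs; duplicate rate 0.91 (so ~220
  unique compounds, matching the heavy inter-herb redundancy real formulas
  show); MW lognormal around 350 g/mol (σ = 0.35), ALOGP ~ N(2.5, 1.5),
  Poisson counts for HBA/HBD/ROTB/AROM/ALERTS, lognormal PSA around 70 Å².
* **Predictions**: per-compound Poisson(8) target lists over a 3,000-gene
  universe with 1/√rank popularity weights.
* **Disease genes**: 196 genes; relevance scores Pareto(α = 1) with the
  scale solved so that ~40% clear the score-9 cut — matching the observed
  ratio of potential to common targets.
* **PPI**: planted hubs are wired to every node of the potential-target
  subnetwork (degree n−1, closeness 1), background edges are Erdős–Rényi at
  density 0.1 with per-node degree capped below the hub degree. The
  generator returns recommended thresholds (the midpoint between the
  guaranteed hub degree and the background cap, plus 0.001/0.6 for
  betweenness/closeness), under which exactly the planted hubs pass — by
  construction, not by chance. Combined scores are uniform on [700, 999].
* **Pathways**: 120 terms of size 5–40; 5 planted terms contain all hub
  genes plus random fillers, so they dominate the hypergeometric ranking.
* Hub genes are force-linked to a small pool of screened compounds and
  force-listed as high-relevance disease genes, anchoring the planted truth
  to the screen the pipeline actually runs.

Everything is derived from `numpy` SeedSequences of a single seed; the same
seed yields byte-identical output files.

What the generator does **not** emulate: real chemistry (formulas and the
absent SMILES are placeholders), correlated descriptors, database version
drift, literature-biased target prediction, or scale-free PPI topology
beyond the planted hubs. Passing the planted-recovery tests therefore
demonstrates that the pipeline's filters select what its thresholds say
they select — not that the thresholds are biologically optimal.

## Determinism and problem sizes

All orderings are total (score descending, then lexicographic id);
re-running a pipeline with the same inputs yields byte-identical outputs
(the funnel report's wall-clock timings excepted). The suite's statistical
checks use 1,000 random graphs for the centrality oracle, all N ≤ 12
configurations for the hypergeometric oracle, 2,000 replicates for type-I
calibration, 100 seeded studies for planted recovery, and 100 random
vectors for the QED reference comparison — sizes at which each check's
sampling error is far below its assertion tolerance while the whole suite
runs in about a minute.

## Known limitations

* The funnel's absolute counts on real data depend on live database
  versions; they are reported, never asserted.
* Closeness/betweenness definitions vary across tools; ours are stated
  above and may differ from GUI defaults elsewhere.
* The enrichment module implements the plain hypergeometric test, not
  EASE-style corrections some web tools apply.
* The adduct grammar covers positive-mode protonation with neutral losses
  only — no sodiation, dimers, or negative mode.
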