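# Methods

## Scaffold encoding and the reaction grammar

An oxidized iridoid scaffold is represented by one complex number per
skeleton carbon (C1, C3–C11; the pyran oxygen occupies position 2, so there
is no C2). The real part is the ordinal oxidation state — 0 saturated,
1 alcohol, 2 aldehyde/ketone, 3 carboxylic acid, 4 decarboxylated — except
at C11, which is oxidized directly to the aldehyde by iridoid oxidase and
therefore uses the shifted scale 0/1/2/3 (saturated/aldehyde/acid/
decarboxylated). The imaginary part encodes shared unsaturation: `i/4` on
both carbons of a double bond, `3i/4` on both carbons of an epoxide. Flags
must tile into adjacent pairs along the fixed cyclopentanopyran bond list
(C1–C9, C9–C5, C5–C4, C4–C3, C5–C6, C6–C7, C7–C8, C8–C9, C8–C10, C4–C11).
Because the skeleton's only cycle (the cyclopentane ring) is odd, a valid
flag assignment has exactly one pairing, so the per-carbon vector is a
complete, unambiguous description.

The registered reactions are single oxidation steps (+1 on one carbon,
within that carbon's valence cap), desaturation (adds `i/4` to both carbons
of an eligible bond), and epoxidation (either promoting an existing double
bond, `i/4 → 3i/4`, or closing an epoxide on a saturated eligible pair).
The literal complex Manhattan distance assigns 0.5 to a desaturation, 1.0
to a double-bond→epoxide step and 1.5 to direct epoxidation; calibration
weights (2, 1, 2/3 on imaginary quarter-steps of size 1, 2, 3 quarters)
normalize every registered move to generalized distance exactly 1, which
the test suite verifies move by move. The grammar — per-carbon maximum
states, flag-eligible bonds, flagged-carbon caps and the calibration — is a
single configurable object, so alternative valence tables enumerate
alternative spaces.

The default (published) grammar uses maximum states C1:2, C3:1, C4:1,
C5:1, C6:1, C7:2, C8:2, C9:1, C10:3, C11:3; double bonds on C4–C3, C6–C7,
C8–C9 and C8–C10; epoxides on C9–C5 and C7–C8; double-bond carbons must be
saturated while epoxide carbons may carry one hydroxyl; epoxides may form
directly from a saturated pair. Under these constants the space enumerates
to 62,400 scaffolds joined by 411,080 undirected unit-distance links —
822,160 when each adjacency is counted in both directions, the convention
of a sparse adjacency matrix and the one used for the reported reaction
count. Direct epoxidation is required for reachability here, since the
epoxide-eligible bonds are not double-bond-eligible.

## Chemical space

`enumerate_space` iterates labeled flag tilings and the admissible
oxidation states per tiling, then generates edges by applying every
registered move to every node; enumeration order is deterministic, and the
whole space builds in a few seconds. Geodesics are breadth-first searches
on the integer-id adjacency. The catalpol, aucubin and bartsioside codes
validate in this grammar, bartsioside→aucubin is a single hydroxylation
edge, and bartsioside→catalpol has geodesic length 2.

## Phylogenetic weighting

Two schemes score genus × item report matrices (items are scaffolds or
reactions; a genus carries a reaction when both endpoint scaffolds carry
the corresponding status):

* **Phylogenetic correlation** — the Brownian-motion tip correlation
  `corr(i,j) = t_shared / sqrt(depth_i · depth_j)`. Scores are the
  correlation matrix times the presence matrix, so an item reported in
  close relatives of the focal genus scores almost as highly as one
  reported in the genus itself.
* **Felsenstein root weights** — the posterior probability of "present" at
  the root under a symmetric two-state model (rate 1 per unit branch
  length, flat root prior) computed by the pruning recursion. Unreported
  genera enter as missing data (partial likelihood 1 for both states), so
  absence of a report is never evidence of absence. A vectorized
  implementation carries a 2×n_items likelihood block per node; it agrees
  with the scalar recursion to 1e-12 and with brute-force state-sum
  enumeration to 1e-10 on trees of ≤5 tips.

## Pathway reconstruction

The *naïve prediction* places every scaffold reported anywhere in the
family into the space, extends the set by `n_reactions` breadth-first
steps, and links all unit-distance pairs. A genus's naïve network is the
union of connected components containing at least one of its own reports;
its nodes carry status `reported` (this genus), `predicted` (reported
elsewhere in the family) or `theoretical` (reported nowhere). This
family-wide construction is what lets a genus hypothesis pass through —
and thus predict — scaffolds never reported in that genus.

Pruning enumerates candidate pathways per component: inclusion-minimal
connected subgraphs joining the genus's reported scaffolds. Components up
to 15 nodes are enumerated exhaustively; larger components use seeded
randomized shortest-path assembly — each sample visits the reported nodes
in random order and joins them along shortest paths under jittered,
score-discounted node weights, and the assembled subgraph is peeled to a
minimal connector. Candidates are scored as the sum of the phylogenetic
scores of their vertices, edges or both; all candidates within `tolerance`
percent of the maximum are retained and their union (nodes, and the edges
each candidate induces) is the pathway hypothesis. Tolerance 100% is the
no-pruning limit and returns the full component. Ties share union
semantics, so results are order-independent, and hypotheses grow
monotonically with tolerance.

The natural-data protocol runs the benchmark-selected 0-extension model
first and applies the 1-extension model only to reported scaffolds left
unconnected, merging in just the components that rescue them; scaffolds
still unconnected stay isolated.

The ancestral pathway applies Felsenstein root weights to every node and
edge occurring in any genus hypothesis (presence = membership of the
hypothesis) and keeps items with weight above 0.9.

## Pathway evolution model

Evolution is neutral exploration of the reaction space along the
phylogeny: each branch executes `round(rounds_per_unit × length)`
exploration rounds (a Poisson mode is available); a round draws one space
edge uniformly at random and fixes it as an enzyme only if at least one
endpoint is already producible from the pathway source (the fully
saturated scaffold by default); beyond `max_enzymes`, a uniformly chosen
enzyme is evicted and producibility is recomputed from scratch. Children
inherit independent copies of the parent state; tips become genus
pathways. Defaults — ancestral pathway of 10 reactions, enzyme cap 30,
5×10⁴ exploration rounds per unit branch length on unit-depth trees —
were chosen so that simulated genus pathways hold roughly 18–27
metabolites with a shared core and substantial between-genus divergence
(mean Jaccard ≈ 0.5), the scale implied by the curated family data
(64 scaffolds, ~6 reports per genus, each scaffold reported in ~2 genera).
With ~4×10⁵ unit-distance links, a uniform draw fixes with probability
~10⁻³, which is why the round counts are large.

Report sampling draws `ceil(fraction × n)` metabolites per genus uniformly
without replacement; the benchmark preset uses fractions 0.1–0.6 in 0.1
steps, retaining the ground truth alongside.

## Surrogate selection

Each pathway set reduces to 16 classical topology descriptors per genus
(node/edge counts, density, degree moments, component structure,
diameter/radius and mean shortest path of the largest component,
clustering, articulation points, leaves, assortativity, cycle rank, degree
entropy — a documented registry, replaceable as a unit), concatenated in
fixed genus order (336 columns for 21 genera), deduplicated,
`log10(x+1)`-transformed (extended as `sign(x)·log10(1+|x|)` for the one
signed descriptor) and column-z-scaled. A 2-D UMAP is fitted on the
surrogate rows together with the natural row — projecting a strictly
out-of-sample row carries a placement offset unrelated to topology
similarity — and the natural row is then projected repeatedly with varying
transform seeds. Surrogates whose squared Mahalanobis distance to the
projection cloud falls below the 0.99 quantile of χ²(2) are selected.
Because the library's transform jitter can be arbitrarily tight relative
to the embedding's own resolution, the cloud covariance is floored at the
embedding's median nearest-neighbor spacing whenever it is smaller; the
gate then reads "within a few spacings of the natural location" at any
embedding scale.

## Parameter benchmark

The grid crosses extensions {0,1,2} × tolerance {0,…,100}% × scheme
{correlation, Felsenstein} × target {vertices, edges, both} × basis
{reported, predicted} — 396 combinations. Each surrogate is resampled at
its own fraction, reconstructed, and compared with its ground-truth
pathway per genus on nodes (metabolites) and edges (enzymes): TPR, FPR,
false omission rate, PPV and the Matthews correlation coefficient, with
undefined MCC mapped to 0 (flagged) and perfect agreement mapped to 1.
The true-negative universe is the genus's naïve prediction — the solution
space actually searched — and, in the benchmark, the truth is restricted
to that universe as well: a scaffold that no report ever placed in the
space cannot be counted as a miss of the pruning step. (The
`confusion_metrics` API default keeps the full truth, under which the
universe choice provably never changes TP or FN.)

The scaled replication runs 50 replicate evolutions × 6 sampling
fractions as surrogate candidates, selects with 100 projections, and
evaluates the three benchmark-selected parameter rows on the 20
nature-closest surrogates × 3 resamples (the χ²-selected sets enter
first; when the gate passes fewer than 20, the next nature-closest
candidates top the pool up deterministically).  Connector sampling uses
200 draws for the tolerance-10% row and 24 for the tolerance-0 rows,
whose retained set is only the argmax candidates.  These problem sizes
are the package's desk-scale defaults; the pipeline completes in roughly
a quarter hour on one core.

## Coexpression candidate ranking

Expression (FPKM-like) is transformed `log2(x+1)` and z-scored per
transcript (constant transcripts are zeroed and flagged). A batch
self-organizing map on a 20×20 hexagonal toroidal grid (Gaussian
neighborhood, linearly decaying radius, seeded) assigns transcripts to 400
neurons; the codebook vectors are clustered by Ward's criterion on
Manhattan distances and cut into ten clusters; transcripts inherit their
neuron's cluster. Bait enrichment per cluster is the exact hypergeometric
upper tail; members of clusters with p < 0.05 are the candidates, ranked
by cluster p-value. The SOM is implemented in-package as a compact batch
algorithm; its training schedule (20 epochs by default) is configurable.

## Synthetic fixtures

Fixtures generate everything a pipeline run needs from one seed: a
birth-death genus tree scaled to unit depth (optionally jittered to
non-ultrametric), a pathway evolution with sampled reports, and an
expression matrix with one genuinely coexpressed module around designated
bait transcripts (shared tissue profile + Gaussian log-scale noise,
lognormal background). What the fixtures do **not** emulate: literature
reporting bias (real reports favor abundant or novel compounds, ours are
uniform), decorations and stereochemistry (out of scope of the scaffold
representation), tissue-correlation structure of real transcriptomes, and
any model misspecification of the neutral-evolution premise itself — so
green tests certify the algorithms, not the biology.

## Numerical and degenerate-input conventions

Distances are exact rationals in floating point (quarters and unit steps);
the tolerance cut uses a 1e-12 slack. Empty graphs yield all-zero
descriptor vectors. Zero-variance feature columns z-scale to 0. Degenerate
projection-cloud covariance is ridged as described. MCC denominators of
zero map to 0 with an explicit flag. The pruning recursion returns the
prior (0.5) when every tip is missing. Trees must be rooted with ≥2 root
children and nonnegative branch lengths; zero-depth tips are rejected for
the correlation scheme.

## Known limitations

The grammar constants are a calibrated stand-in reproducing the published
space size; the original per-carbon constants have not been released, so
per-scaffold identity of all 62,400 nodes is not guaranteed — only the
counts, and the encodings of the named reference scaffolds (catalpol,
aucubin, bartsioside and relatives), are pinned. The
candidate-pathway enumeration is likewise a documented stand-in (the
published algorithm's candidate set is not specified in the main text);
its recall is bounded by the fact that a minimal connector can never
recover unsampled dead-end scaffolds, which depresses enzyme-level scores
in particular. Simulated truth pathways are tree-like (edges ≈ nodes)
under every parameter regime we probed, so reconstruction is evaluated in
a slightly sparser-mesh regime than the published description of the
simulation outputs suggests.
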