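# Methods

## Problem and approach

`pocketec` predicts the Enzyme Commission (EC) class of a protein from its 3D
structure, using only the region around a binding-site center — a *localized
3D descriptor*.  The premise is that the chemistry of the catalytic site, not
the global fold, determines the reaction an enzyme catalyzes.  Working from a
local descriptor has two consequences: the classifier cannot lean on
fold–function correlations (which leak through ordinary random splits and
break down for fold families like TIM barrels that host many functions), and
graphs stay small enough for atom-resolution message passing.

The pipeline is: parse a PDB structure (protein ATOM records only, all chains
together, first model, highest-occupancy altlocs) → pick a binding-site
center (experimental annotation, a pocket-prediction table, homolog-ligand
transfer, or a random-center control) → cut the descriptor (the *n* nearest
residues/atoms or everything within radius *r*, inclusive) → build a typed
3D graph → classify with a message-passing network → optionally explain the
prediction with a per-node soft mask.

## Graphs

At **residue resolution** each kept residue becomes one node at its Cα
position, typed by amino-acid identity (21 classes: 20 standard + other).
At **atom resolution** every kept heavy atom is a node, typed by *chemical
environment* rather than element (31 classes in the spirit of force-field
atom typing: backbone Cα / carbonyl C / amide N / carbonyl O, methyl vs
methylene vs branched sp3 carbons, aromatic CH vs ring junctions, carboxylate
vs hydroxyl vs phenol oxygens, thiol vs thioether sulfur, guanidinium,
imidazole, indole nitrogens, a catch-all).  The mapping is a documented
reconstruction from standard force-field groupings — not a copy of any
published table — and alternative tab-separated mappings can be loaded.  A
20-class hydrogen vocabulary is implemented but unused by the default models
(hydrogen nodes multiply graph size for little signal).

Directed edges j→i connect nodes within a neighbor radius (default 15 Å for
residue graphs, ~6 Å for atom graphs; the cap of 32 nearest senders per
receiver bounds the in-degree).  Distances are quantized to 1e-9 Å before
ordering or thresholding so that geometrically exact ties break by node index
— this makes descriptor cuts and edge lists exactly invariant under rigid
motions of the input.  Graphs carry no edge features; all geometry is
recomputed from node positions inside the networks, which makes jitter
augmentation essentially free.

## Networks

Both architectures embed the node-type integers and pass messages; geometry
enters only through distances and angles, so predictions are invariant to
global rotation/translation by construction and to node permutation via sum
pooling (mean pooling is available).

**distances** — continuous-filter convolutions.  Interaction block *l*
updates node features by x_i ← x_i + f(Σ_j x_j ∘ W^l(d_ij)) where the filter
W^l is a two-layer MLP (shifted softplus, ssp(x) = ln(½eˣ + ½)) on a Gaussian
radial basis expansion e_k(d) = exp(−γ(d−μ_k)²).  Defaults: 6 interaction
blocks, 128-dimensional embeddings and filters, 50 Gaussian centers evenly
spaced on [0, cutoff] with γ = 10 Å⁻² (a dense 0–30 Å/0.1 Å grid mode is
available as configuration), readout = per-node dense → ssp → dropout 0.25 →
dense → sum pool.

**distances_angles** — directional message passing over per-edge messages
m_ji.  Triplets (k→j, j→i) contribute Σ_k m_kj ∘ MLP(e_RBF) ∘ MLP(a_SBF),
where a_SBF is a spherical Fourier–Bessel basis on the pair (d_kj, α_(kj,ji)):
products of spherical Bessel functions j_l(z_{ln}·d/c) (roots found
numerically at configuration time) and Legendre polynomials of cos α, with 7
spherical × 6 radial components.  Basis representations are combined with
messages by Hadamard products after small linear embeddings (basis embedding
8, interaction embedding 64), per the directional-message-passing
"++" construction.  Four building blocks (embedding + 3 interaction); each
block feeds an output block (output embedding 256) whose per-node
contributions are summed across blocks and pooled per graph.

No deep-learning framework is required: the package carries a compact
reverse-mode automatic-differentiation engine over NumPy float64 arrays
(`pocketec.autodiff`) covering dense linear algebra, elementwise
nonlinearities, gather/segment-sum, and log-softmax, plus an Adam
implementation.  Since positions enter the networks only through precomputed
basis expansions, gradients flow solely to parameters and to the explainer
mask, which keeps the engine small and the tape shallow.

## Training

Weighted cross-entropy l_n = −Σ_c ω_c y_{n,c} log softmax_c(x_n), with
inverse-frequency weights normalized to mean 1 (rarer EC classes weigh
more; the exact form is configurable).  Adam with lr = 0.001, β₁ = 0.9,
β₂ = 0.999.  Optional class-balanced oversampling with replacement.
Training-time augmentation jitters node positions by up to 0.05 Å (uniform
direction, uniform radius; edges kept).  Early stopping monitors validation
accuracy with patience 10 by default; checkpoint selection tie-breaks equal
validation scores by training accuracy.  Training is bit-reproducible for a
fixed seed.

The public surface is a scikit-learn-style estimator
(`GraphNetClassifier.fit/predict/predict_proba/score`), so the classifier
composes with sklearn model selection; `X` is a list of pocket graphs.

## Evaluation

Protein-centric F-score in two conventions: **F-max** (sweep a confidence
threshold; a protein predicts its label only above threshold; precision over
covered proteins, recall over all; report the maximum harmonic mean) and the
plain single-label F1, which for singleton truths equals accuracy.  Per-class
AUPR uses step interpolation (Σ ΔR·P, verified in tests against an
independent average-precision implementation).  Hierarchy levels (main, sub,
sub-subclass) are scored by truncating the predicted designation — one flat
softmax, no per-level heads.

## Explanation

A per-node soft mask F ∈ [0,1]^N multiplies the node-type embeddings (the
only differentiable attachment point for categorical nodes) and is optimized
by gradient descent with backtracking (accepted steps never increase the
objective) on

  l(y, ŷ_masked) + β₁·mean(F) + β₂·mean(H(F)),
  H = −F log(F+c) − (1−F) log(1−F+c),

with defaults β₁ = 0.05, β₂ = 0.1, c = 1e-15, 100 steps of size 0.01 from
F = 0.5.  Edge masks are deliberately not used: edges here encode proximity,
not chemical bonds, so an edge mask would have no chemical reading.  The
converged mask is min-max normalized per structure to [0,1] (single node →
1.0; constant vector → 0.5, both flagged); atom-level values aggregate to
residues by maximum.

## Data splitting

The **fold split** removes fold bias.  Items carry a sequence-cluster id
(ingested from an external clustering tool's TSV; clusters holding several
EC classes are first separated by class).  Per class: with ≥3 clusters, whole
clusters are distributed (smallest to test, then val, remainder by largest
relative deficit — so no cluster spans partitions); with 2 clusters the
smaller one goes to test and the other is divided over train/val; with 1
cluster, items are divided 80/10/10 directly.  `verify_split` reports any
cluster of a multi-cluster class spanning partitions; single-cluster classes
are exempt by construction.  The **temporal split** orders by deposition
date, oldest 80% to train, ties broken by id.  `clustering_jaccard` compares
two clusterings as |co-clustered pairs in both| / |in either|.

## Binding-site acquisition

Pocket-prediction CSVs (rank + center, P2Rank-style dialects) are ingested
and only the rank-1 site is consumed by default.  For structures modeled from
homologs, ligand positions transfer: hits with alignment score > 0.5
contribute the heavy-atom centroids of their ligands (common crystallization
additives excluded via an editable list), mapped into the target frame by the
externally-computed rigid transforms; centroids within 4 Å merge (center =
member mean) and candidate locations are ranked by supporting-ligand count.
A least-squares rigid superposition utility is included for fixtures only —
structure alignment itself is out of scope.

## Synthetic data

The generator builds idealized helical chains: Cα positions on a helix with
rise 1.5 Å and 100° twist, radius chosen so consecutive Cα–Cα distances are
exactly 3.8 Å; backbone N/C/O and pseudo side-chain atoms sit at canonical
per-residue offsets (correct atom names, non-physical geometry — sufficient
for typing and distance logic, and documented as such).  Each class is a
`MotifSpec`: a residue multiset planted near the chain middle; the site
center is the motif's Cα centroid.  An optional pairwise-distance matrix
selects motif positions matching a target geometry (validated for 3D
embeddability via the classical-MDS Gram criterion).  Decoy structures plant
a *wrong*-class motif at the chain end, > 2× the placement radius from the
center — only a site-local model classifies them correctly.

Dataset structure: classes are balanced; each class has five lineages with
uneven sizes (50/20/10/10/10%), and a structure re-draws 80% of background
positions from its lineage's base sequence.  The lineage id is the emitted
cluster assignment.  The uneven sizes let whole-cluster fold assignment reach
80/10/10 (four equal clusters cannot do better than 50/25/25); the high
mutation rate ensures lineage background cannot be memorized, so
cross-lineage generalization must come from the planted motif.

The default four-class fixture is separable from node-type composition alone
(disjoint motifs: Ser/His/Asp, Cys/Cys/Glu, Lys/Arg/Tyr, Trp/Met/Asn), which
a nearest-centroid histogram baseline verifies.  The *benchmark* fixture
replaces the fourth class with a stretched Ser/His/Asp triad (pairwise Cα
distances ≈ 6.2/6.2/12.3 Å vs the compact consecutive triad): two classes
share a residue multiset and differ only in local shape, so the task requires
distance information, mirroring the interplay of chemistry and local shape
that motivates 3D-aware message passing.  Without such a pair, a sum-pooled
type-aware network is a composition classifier and coordinate noise cannot
degrade it.

What passing tests on this data do and do not show: they demonstrate that the
pipeline learns exactly the signal it is promised (site-local chemistry and
geometry), generalizes across sequence clusters when that signal is present,
collapses when it is removed (alanine mutation) or corrupted (translation),
and that the explainer points at the planted signal.  They do not show
real-enzyme performance: real binding sites are conformationally
heterogeneous, side chains have rotameric freedom, EC labels are noisy, and
class counts are heavily imbalanced — none of which the generator emulates.

## The standard benchmark

`pocketec.benchmark` fixes one desk-scale experiment shared by the test suite
and `scripts/acceptance.py`: 4 classes × 40 structures of 60 residues,
residue resolution, 12-residue count-cut pockets, lineage fold split, and a
reduced distance-architecture instance (embedding/filter width 32, two
interaction blocks, 24 radial basis functions, batch 32, 150 epochs at a
fixed budget).  The reduction is a size choice for a four-class local task;
every component of the full configuration is exercised.  On one CPU a
training run takes roughly half a minute.

## Numerical choices and degenerate inputs

- Double precision throughout; rigid-motion invariance holds to machine
  precision (measured ~1e-15 relative).
- Distance quantization 1e-9 Å for all ordering/thresholding (tie rule above).
- Radius cuts are boundary-inclusive (d ≤ r).
- Empty descriptor, empty structure, malformed PDB records (with line
  number), hydrogen names in the heavy-atom vocabulary, non-finite logits,
  zero-count classes, and coincident points in angle computation all raise
  typed errors.
- Nodes without in-edges receive exact zero convolution sums; edges without
  triplets receive only the self/radial path.
- Softmax confidence ties resolve to the lowest class index, with a warning.

## Known limitations

- The NumPy engine is single-threaded per operation and tape-based;
  full-scale training (hundreds of classes, 10⁵ structures) is out of its
  intended range — the package targets method correctness and desk-scale
  experiments.
- The heavy-atom typing table is a reconstruction; users with a canonical
  force-field table should load it via `load_scheme`.
- Homolog-transfer takes superposition transforms as input; no aligner is
  bundled.
- The atom-resolution directional (distance + angle) configuration is
  implemented and tested for correctness but not benchmarked here; triplet
  counts grow quickly with atom-graph density.
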