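# Methods

`subcellmap` implements the downstream analysis chain of correlation-profiling
spatial proteomics: proteins are quantified across subcellular fractions (TMT
reporter channels), proteins co-residing in an organelle share a fraction
profile, and everything downstream — classification, resolution metrics,
dataset integration, enrichment of the unclassified set — operates on that
profile matrix. This note records the models, the defaults and the open design
choices.

## Data model and preprocessing

A `ProfileDataset` is a proteins x channels matrix of non-negative relative
abundances with channel metadata (replicate, fraction) and feature metadata
(accession, curated marker class or `unknown`, optional ground-truth class and
abundance). Missing quantitation is NaN, never zero.

The preprocessing chain mirrors standard practice for isobaric-tag profiling:

1. **Sum-normalisation** — each PSM (or protein) row is divided by its row sum,
   so profiles are unitless distributions over channels. Idempotent; all-zero
   rows are an error.
2. **Median aggregation** — PSM rows are collapsed to protein groups by the
   channel-wise median. *No renormalisation is applied afterwards*: the median
   of simplex vectors is not itself a simplex vector, and silently rescaling
   would change relative channel weights. An explicit re-normalise call is
   available to callers who want it.
3. **Complete-profile filter** — rows with any missing channel are dropped
   (the "full reporter ion series" rule). No imputation anywhere: profile
   shape is the signal, and imputed channels would manufacture shape.
4. **Channel exclusion and contaminant removal** are by explicit user lists;
   there is no automatic low-intensity channel detector (no principled
   threshold generalises across instruments) and no bundled contaminant
   database (version-dependent).
5. **Replicate concatenation** joins on exact accession strings (isoforms are
   distinct features) over the intersection of accessions, stacking channels;
   conflicting marker labels are an error, not a vote.

PCA is plain mean-centred SVD — no unit-variance scaling, since all channels
are already on a common ratio scale. Component signs are fixed so the
largest-magnitude channel loading of each component is positive, which makes
score plots reproducible across runs and libraries.

## Synthetic organelle maps

The generator emulates the cluster structure of a differential-pelleting
experiment, not the mass spectrometry itself. Each class gets a template: a
discretised Gaussian bump over the fraction axis, peaking at a class-specific
position, normalised to the simplex; pairwise cosine similarity between
templates is bounded (default 0.85) unless a pair is deliberately overlapped.
A protein's profile is its class template (or, for multilocalising proteins, a
convex mixture `alpha*t1 + (1-alpha)*t2` with `alpha ~ U(0.25, 0.75)`) plus
additive Gaussian noise per channel, clipped at zero and renormalised per
replicate block. "Unrelated" proteins draw flat Dirichlet profiles. Protein
abundance is log-normal (`mu = 15`, `sigma = 2` on the natural-log scale,
roughly the dynamic range of deep proteome surveys).

Defaults: 10 classes, 10 channels x 3 replicates, 30 markers and 200
unannotated proteins per class, 300 multilocalising, 200 unrelated,
`noise_sd = 0.05`. At that noise a peaked template is visibly perturbed but
classes remain largely separable — the regime in which a well-executed
experiment operates.

**Overlapping pairs.** For paired primary/auxiliary maps, a designated class
pair can be made unresolvable in one map only. Overlap is defined in the space
where it matters — relative to the noise: the second template is placed half
the typical within-cluster point displacement (`0.5 * noise_sd * sqrt(n_channels)`)
from the first, so the two marker clouds genuinely intermingle (cosine
similarity ≳ 0.99; a cosine-only criterion leaves the pair separable to k-NN
in 30 dimensions and would not emulate an unresolved pair). At zero noise the
placement falls back to a cosine floor so templates stay distinct.

What the generator does *not* emulate: peptide sampling stochasticity, TMT
ratio compression/interference, correlated noise across channels, missing
values not at random, or class-size imbalance. Passing tests therefore show
the algorithms are correct and recover known structure under idealised noise —
not that any particular biological dataset will resolve.

## SVM classification and FDR control

Curated markers train a radial-basis SVM; kernel convention
`K(x, y) = exp(-sigma * ||x - y||^2)` (i.e. sigma is the kernel's gamma —
conventions differ across libraries, so printed optima like `sigma = 0.01`
refer to this form). Hyperparameters are tuned by nested cross-validation:
each round holds out a stratified 1/folds of the markers, an inner folds-fold
CV on the remainder grid-searches (sigma, cost) by macro F1, and the winner is
refit and scored on the held-out part. Defaults: 100 rounds, 5 folds, grids
`sigma ∈ {1e-3 … 1e2}`, `C ∈ {2^-4 … 2^4}`. Round r uses seed + r, and markers
are sorted by accession first, so results are invariant to row order.

The per-class SVM "score" is a calibrated class probability from pairwise
coupling (sigmoid calibration over a seeded CV). A probability was chosen
because it makes the score-ordered FDR walk well-defined; a raw decision value
would rank but not normalise across classes.

**FDR thresholding.** Per class, non-marker proteins assigned to the class and
carrying a reference label are ranked by descending score; the threshold is
the lowest score whose accepted prefix keeps the disagreement fraction ≤ q
(default 0.05), maximising the accepted set; score ties at the boundary share
the boundary's fate; everything assigned to the class below the threshold
becomes `unknown`. FDR is estimated per class, not globally, since each
compartment's score distribution differs. In synthetic runs the reference is
ground truth on a random half of the single-class unannotated proteins, so the
empirical FDR measured on all of them is an out-of-sample check, not true by
construction.

## QSep

Resolution is summarised by average Euclidean distances over marker clusters:
entry (i, j) is the mean over all cross pairs, the diagonal the mean over
unordered distinct within-cluster pairs (self-distances excluded — including
them would deflate the compactness reference). Normalisation divides each
entry by the *row* class's within-distance (the reference convention is not
canonical; a column orientation is exposed via a flag, and since the raw
matrix is symmetric the two are transposes). The normalised diagonal is
exactly 1; values say how many within-cluster spreads separate two
compartments. Degenerate clusters (zero within-distance) raise rather than
produce infinities.

## Transfer learning

For a query protein, each dataset contributes a per-class k-NN affinity (the
fraction of the k nearest markers, Euclidean distance on the full concatenated
profile, carrying that label; neighbour ties at rank k break by ascending
accession). Affinities are blended per class:
`combined_c = theta_c * primary_c + (1 - theta_c) * auxiliary_c`, prediction
by argmax with lexicographic tie-break. Note the blended vector sums to one
only when all classes share one theta.

Theta is selected by repeated cross-validation on the markers shared by both
datasets (default candidates {0, 0.5, 1}, 100 iterations, 5 folds, k tuned
separately per dataset). The search is exhaustive when
`|candidates|^n_classes` fits a budget (default 10,000) and coordinate ascent
otherwise (random class order, max 5 sweeps, started from all-ones); both
agree on easy fixtures. Equal-F1 ties resolve toward larger weights — prefer
the primary, higher-resolution map. The reported profile is the per-class
interpolating median of per-iteration winners, so medians like 0.75 arise
from {0.5, 1} draws.

A structural consequence of the tie-break worth knowing: when a class pair
overlaps in the primary map only, down-weighting *either* member fixes both
confusion directions, so the selected weight vectors typically drive one
member of the pair to 0 while the other keeps 1 — the pair-minimum weight is
the informative statistic for an unresolved pair.

## Bias-corrected enrichment

Detection and classification favour abundant proteins, so testing the
unclassified set against categories with a plain hypergeometric test
confounds abundance with biology. The correction estimates a probability
weight function P(selected | abundance) by isotonic regression on log
abundance (direction from the Spearman sign; the pool-adjacent-violators fit
preserves the overall selection rate). The null distribution of a category's
overlap is approximated by drawing selected-set-sized null sets with
inclusion probability proportional to the weights, using Pareto
probability-proportional-to-size sampling — chosen over sequential weighted
sampling because at large selected fractions the latter distorts inclusion
probabilities and makes the test markedly conservative. One null ensemble
(default 10,000 draws) is shared across categories. The empirical p is
`(1 + #{null >= observed}) / (1 + draws)` — never zero, and conservative for
small categories because overlap counts are discrete. Benjamini–Hochberg
adjustment and the significance filter (adjusted p < 0.01, category size ≥ 5)
follow.

## Problem sizes used in checks

The automated checks run at desk scale: QSep against an exhaustive
double-loop oracle on 50 random datasets (≤ 8 classes x ≤ 10 markers);
classifier recovery on the default generator (2,800 proteins, 20 tuning
rounds, FDR pooled over 10 seeds); transfer recovery on 6-class paired maps
(25 markers/class, noise 0.1, exhaustive 3^6 grid, 20 iterations) — noise set
so marker CV macro F1 sits near 0.9, the band real maps occupy, keeping F1
ties rare enough for weight selection to be informative; enrichment
calibration on a 10,000-protein universe with 500 size-200 null categories
pooled over 5 independent simulated experiments (category size chosen because
the discrete empirical p is conservative for small categories, and pooling
independent experiments averages over the shared realised selection within
each).

## Known limitations

- The FDR walk needs reference labels per class; classes with assignments but
  no referenced members are left unthresholded (with a warning).
- Theta optimisation requires markers present in both datasets; proteins in
  one dataset only are classified from that dataset and flagged.
- The enrichment module tests flat category memberships; ontology structure
  (term graph, propagation) is out of scope.
- Isotonic PWF fits are step functions; with few distinct abundance values
  the weights are coarse.
- The generator's Gaussian profile noise is independent across channels;
  real reporter noise is not.
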