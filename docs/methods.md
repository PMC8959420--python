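# Methods

This note documents the models and procedures implemented in `msgcn`, the
design choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
details a user would need to reproduce or audit a run.

## 1. Brain graph and spectral operators

The cortical surface is a closed triangle mesh shared by all subjects (all
data are assumed registered to one template). Vertices outside the cortex
mask (medial wall) are **removed** from the graph, with a stored index map
back to the original mesh order, rather than kept as isolated nodes —
isolated vertices would make the normalized Laplacian undefined and carry
no signal. Two vertices are adjacent iff they co-occur in at least one
triangle; the adjacency is binary and symmetric, giving vertex degrees of
roughly 4–6 on triangulated surfaces.

The symmetric normalized Laplacian `L = I − D^{−1/2} A D^{−1/2}` has
spectrum in [0, 2]. The Chebyshev rescaling `L̃ = 2L/λ_max − I` needs the
largest eigenvalue; by default it is estimated by power iteration
(relative tolerance 1e−6, cap 10,000 iterations, seeded start vector).
Power iteration converges here because L is positive semidefinite, so its
largest eigenvalue is also largest in magnitude. The spectral upper bound
λ_max = 2 may be passed explicitly instead; with the exact value the
spectrum of L̃ lies in [−1, 1], with the bound it lies strictly inside.
Disconnected graphs are allowed with a warning (the operators remain well
defined); isolated single vertices are an error the caller must resolve.

## 2. Connectivity fingerprints and initial parcellation

Standard rs-fMRI post-processing is provided as two operations applied
before connectivity: least-squares residualization against an intercept
plus confound regressors (white-matter/CSF signals), and a zero-phase
4th-order Butterworth band-pass at 0.01–0.1 Hz (`sosfiltfilt`, so no phase
distortion; the output is mean-free).

A vertex's fingerprint is its Pearson correlation with each atlas ROI's
mean series — raw correlations, not probabilities: correlation is the
conventional fingerprint and preserves sign. Vertices with zero-variance
series get an all-zero fingerprint row, are flagged, and get label 0
everywhere downstream; they are never silently imputed.

The initial parcellation assigns each vertex to the parcel whose centroid
fingerprint is most correlated with the vertex's own fingerprint, where
the centroid is the mean fingerprint over the parcel's *atlas* vertices of
the *same session* (the construct is per-subject, per-session). Similarity
is profile-to-profile correlation, not the single own-parcel fingerprint
entry. Exact ties break to the lowest parcel index.

## 3. The masked network

Architecture: two Chebyshev layers of order K = 3 (higher orders
over-smooth, pushing all subjects toward identical maps), F → 64 hidden →
K_parcels + 1 output channels, rectifier between layers, inverted dropout
(rate 0.5) on the hidden features during training only, per-layer bias
terms (toggleable), row-wise softmax output. Class 0 is the background /
unassigned class, so a K-parcel atlas yields K + 1 classes. Parameters are
initialized from a seeded normal with standard deviation
`1/sqrt(n_in · (K+1))` (fan-in scaling over all polynomial orders).

The confidence mask keeps a vertex iff its initial label is nonzero,
equals the group-atlas label, and does so in every session of the subject;
one mask per subject is shared by all of that subject's sessions, which
are presented as separate training samples. Training targets are the
group-atlas labels (inside the mask these coincide with the session
initial labels by construction).

The loss is the masked negative log-likelihood
`−Σ_v w_v log p_{v,y_v}` — the KL divergence from the one-hot atlas prior
restricted to masked vertices. The public `masked_kl_loss` returns this
masked **sum** (so M masked vertices under uniform 201-class probabilities
give exactly M·ln 201); the training loop minimizes the **mean** over
masked vertices so that the learning rate does not scale with mask
coverage. Probabilities are floored at 1e−12 before the log.

Optimization: Adam (learning rate 1e−3, β = 0.9/0.999), one
subject-session per step in a seeded shuffled order, l2 weight decay
5e−4 added to the kernel gradients (not biases), 100 epochs, early
stopping when the mean masked validation loss has not improved for 10
epochs, parameters of the best validation epoch returned. The forward and
backward passes are plain NumPy over SciPy sparse products; because
T_k(L̃) is symmetric, the adjoint of each convolution reuses the same
Chebyshev recurrence, and gradients are exact. Training is bit-reproducible
from the config seed.

Inference is dropout-free and deterministic: label(v) = argmax_k p_{v,k},
with class 0 mapping to label 0 and ties breaking to the lower class.

## 4. Evaluation battery

* **Dice**: per parcel 2|A∩B|/(|A|+|B|) over the vertex sets labelled k in
  two maps, label 0 excluded; the map-level value is the unweighted mean
  over parcels present in either map.
* **Cohen's d**: (μ_inter − μ_intra)/√(σ²_inter + σ²_intra) with
  population (denominator-n) variances, since the defining expression is
  written with plain σ²; sample variance is available by flag. Per-parcel
  topographic variability uses 1 − Dice (a dissimilarity), so larger d
  means more intersubject variability; connectivity variability uses 1 −
  correlation of parcel-mean fingerprint profiles between runs.
* **Functional homogeneity**: mean pairwise Pearson correlation among a
  parcel's vertex series; "adjusted for parcel size" is implemented as
  vertex-count weighting of the global average (parcels with fewer than
  two vertices are skipped).
* **Task alignment**: within-parcel population standard deviation
  (variability) and mean (homogeneity) of a per-vertex activation map;
  whole-brain task variability is the size-weighted mean of per-parcel
  standard deviations.
* Comparisons between paired conditions (intra vs inter, individualized
  vs atlas) use routine two-sided paired t-tests.

## 5. Behavior prediction

The working assumption is that similar parcellation topography implies
similar behavior: y ≈ Σ_i Dice(l, l_i) y_i. An unnormalized weighted sum
is scale-inconsistent, so the implementation is kernel ridge regression in
dual form with the mean-Dice matrix as Gram matrix: scores are
mean-centered, α = (K + λI)^{−1} y, and λ is picked from a logarithmic
grid (1e−4 … 1e3, 15 points) by seeded subject-level 5-fold
cross-validation. The Dice similarity is an empirical kernel, not a Mercer
kernel, so up to 1e−6 of diagonal jitter is added if the regularized
system is unsolvable. A normalized Dice-weighted-average baseline is
provided for comparison.

The permutation null is evaluated by correlating the fitted model's
predictions with seeded permutations of the observed scores (100
permutations; the mean |r| is reported). With any single permutation at a
few dozen subjects the null correlation has a sampling standard deviation
above 0.1, so the averaged magnitude is the stable summary.

## 6. Synthetic cohorts: what they emulate, and what they do not

The generator produces a closed icosphere "cortex" (100 mm radius;
subdivision 4 → 2,562 vertices at the default desk scale), an optional
polar cap standing in for the medial wall, and a K = 50 parcel atlas grown
by multi-source breadth-first search from farthest-point seeds — every
parcel is connected by construction. A spatially contiguous half of the
parcels (those farthest along a random direction) is tagged
`association`, the rest `primary`.

Subject ground truths warp the atlas borders stochastically: in each of R
rounds a boundary vertex adopts a random neighboring label with
probability warp/R, where warp is 0.15 for primary and 0.45 for
association parcels. These intensities were chosen so the cohort sits in
the similarity regime reported for real individualized parcellations
(mean Dice between subject truth and atlas ≈ 0.85, intrasubject ≈ 0.87 vs
intersubject ≈ 0.83 for the predicted maps). Each subject additionally
draws a global warp multiplier from U[0.5, 1.5]: real cohorts contain
subjects whose topography deviates little or much from the template, and
this across-subject variance is what makes topography-linked behavior
identifiable at the cohort level. Interior vertices never move, so
deviations concentrate at borders, and a flip never empties a parcel.

Sessions draw one band-limited (0.01–0.1 Hz at TR = 0.72 s) unit-variance
latent series per parcel; each vertex observes its parcel's latent plus
independent Gaussian noise of standard deviation 1/SNR (default SNR 3, at
which the similarity-based initial parcellation recovers >90% of
ground-truth labels). Sessions of one subject share the truth but draw
independent latents and noise. Parcel latents are mutually independent by
default, which makes fingerprints maximally parcel-informative; real
functional connectivity has rich between-ROI correlation structure that
this deliberately omits.

Behavioral scores are `effect · Σ_k c_k · dice_k(subject, atlas) + noise`
with fixed seeded contrasts. The default contrasts are **positive**
(U[0.5, 1.5]): a whole-cortex mean-Dice kernel is structurally sensitive
to a subject's overall topographic deviation but nearly blind to
region-specific signed contrasts (a limitation inherent to a global
similarity kernel), so the recoverable-score condition requires scores
that load on overall deviation. Signed contrasts (`contrast_sign=
"signed"`) are available precisely to demonstrate that limitation.

What passing on these cohorts shows: the pipeline recovers individual
topography better than the atlas, separates subject identity from session
noise, concentrates variability where the generator put it, and recovers
topography-linked scores. What it does not show: robustness to head
motion, physiological noise, registration error, hemispheric topology,
distance-dependent connectivity structure, or any property of real BOLD
beyond parcel-shared band-limited dynamics.

All generators are bit-reproducible from (config, seed); cohort-level
randomness flows from one seed through named SeedSequence substreams
(atlas / subjects / sessions / behavior / λ_max start vector).

## 7. Problem sizes

Default study sizes, chosen to keep a full run on one CPU in minutes:
individualization uses 30 subjects (16 train, 4 validation, 10 held out) ×
2 sessions × 400 timepoints on 2,562 vertices with 50 parcels; behavior
uses 60 subjects (40 train, 20 held out) on subject ground truths.
The training protocol itself (100 epochs, batch of one subject-session,
patience 10, weight decay 5e−4, dropout 0.5) follows the standard recipe
for this model family.

## 8. Known limitations

* The graph is built once from a template mesh; subject-specific meshes
  with differing vertex counts are out of scope.
* The CLI's `train` subcommand currently consumes cohorts written by
  `simulate` (it regenerates them bit-identically from the manifest);
  arbitrary external datasets go through the library API.
* No GPU path; the NumPy implementation is sized for template-resolution
  graphs (tens of thousands of vertices) with a few hundred features.
* The Dice kernel for behavior is a global similarity; region-specific
  behavioral effects need other kernels (connectivity, morphometry),
  which are not implemented.
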