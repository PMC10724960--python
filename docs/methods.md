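# Methods

## Data model and preprocessing

The canonical object is a samples × genes matrix with one integer class code
per sample; loaders transpose genes-as-rows files and reject non-finite
cells (no imputation by default). Normalization is per-gene min–max to
[0, 1], computed once on the full dataset before any split. Min–max matches
the optimizer's [0,1] position space and common microarray practice, but the
choice is the package's own; z-scoring and no normalization are selectable.
Because scaling is computed before cross-validation splits, LOOCV estimates
carry a small optimistic leakage bias — acceptable for comparing selectors
on the same footing, not for reporting unbiased generalization error.

## mRMR prefilter

Mutual information is the plug-in estimator on discretized data: each gene
is independently cut into `n_bins = 3` quantile bins (closed-right
intervals; a bin edge separates only if it lies in `[min, max)`, so constant
genes map to a single code). Labels are used as-is. Greedy forward selection
starts at the maximum-relevance gene and then maximizes the difference form
MID = MI(g, y) − mean MI(g, s) over already-selected s (MIQ divides instead,
denominator floored at 1e-12). Every argmax tie breaks to the lowest gene
index. Redundancy sums are accumulated incrementally (one new MI column per
step), so selecting k genes from p candidates costs O(k·p) MI evaluations.
The default pool size min(200, p) is a logged configuration value; the
bundled benchmark uses 50.

## Position encoding and fitness

Swarm members are continuous points in [0,1]^d over the pool; a gene is
selected iff its coordinate strictly exceeds 0.5. An empty decode is
repaired deterministically to the pool's top-ranked gene. Fitness is
leave-one-out cross-validated accuracy on the 0–100 scale of the decoded
subset, maximized with no parsimony term; the reported best breaks exact
fitness ties toward the smaller subset, then the lexicographically smaller
mask. Distinct positions decoding to the same mask share one classifier
evaluation through a mask-keyed cache, which is also the evaluation counter.

The search-time classifier is 1-NN with Euclidean distance and fixed tie
rules (equal distances → lowest sample index; equal votes → lowest class
code), evaluated by one all-pairs distance matrix per mask with the diagonal
excluded. This keeps a full run of tens of thousands of subset evaluations
in seconds; running the CNN inside every fitness call would require millions
of trainings per experiment. The CNN is the final-evaluation classifier.

## The hybrid optimizer

Control parameters and their defaults: population 50 (the cuckoo "nests"
and the spider-monkey swarm are one population), 10 cuckoo rounds per local
search, 200 generations, discovery probability ramped linearly from 0.3 to
0.5 across generations, Lévy step scale α = 1 with Mantegna β = 1.5, at most
MG = 5 groups, GlobalLeaderLimit 50, LocalLeaderLimit 1500, per-dimension
perturbation rate pr = 0.3, 100 runs for summary statistics. pr and the pa
schedule shape are package choices (only the endpoints of pa are fixed by
the operating point); both are configurable.

Per generation: local leader phase (each member perturbs each dimension
with probability pr toward its group's local leader plus a random
group-mate term, greedy accept), selection probabilities, global leader
phase (selected members update one uniformly chosen dimension toward the
global leader, greedy accept), greedy leader learning (exact ties count as
stagnation so the counters keep advancing), then the two decisions. The
hybrid's defining move is the local-leader decision: a stagnant group
forages with cuckoo search — per round one Lévy-flight egg per member guided
by the current local leader, greedy replacement of a uniformly chosen nest,
then abandonment of a pa-fraction of non-best nests. The global-leader
decision splits the swarm into one more contiguous, near-equal group, or
merges back to a single group once MG is reached; local leaders are then
re-learned from scratch. The swarm starts as one group. Runs stop at the
generation cap or as soon as the leader reaches accuracy 100.

Baselines: pure CSA (Lévy walks toward the global best plus abandonment,
same population size and schedules) and classic SMO (same six phases, but
the local-leader decision re-diversifies members dimension-wise — uniform
re-initialization with probability pr, else a move toward the global leader
and away from the local leader).

All randomness flows through one seeded generator per run, consumed in a
fixed documented order (initialization, then phases in sequence), so runs
are bit-reproducible; multi-run experiments use sequential seed offsets.

## CNN classifier

The gene vector fills the smallest square grid row-major (zero padded,
minimum 2×2) and passes through six blocks of 8, 16, 32, 64, 128, 256
filters of 2×2 at stride 1, each conv → batch-norm → ReLU → 2×2/stride-2
max-pool, the pool omitted on the last block and whenever a spatial side is
below 2. Three numerical choices are the package's own, made because the
published configuration specifies kernels and counts but not the
surrounding details:

- convolutions pad one pixel on the bottom/right so the spatial size is
  preserved — with shrinking convolutions the deeper blocks would have
  nothing left to convolve on the small grids gene subsets produce;
- max-pooling is ceil-mode (odd sides padded with −inf) so no grid cell is
  silently dropped — on a 7×7 grid floor-mode pooling discards a full row
  and column, which can contain planted genes;
- batch-norm running statistics are recalibrated over the full training set
  after each epoch; with mini-batches of 16 the momentum-averaged statistics
  are noisy enough to visibly distort held-out predictions.

The head is flatten → dense → softmax (the final layer of the published
stack is not described; this is the minimal standard head). Training is
mini-batch Adam (learning rate 1e-3, batch min(16, N_train)) on
cross-entropy with decoupled weight decay 1e-4 — with tens of training
samples and ~10^5 parameters the unregularized network memorizes the
training set. Default evaluation uses a stratified 80/20 split with at least
one sample per class on each side; per-epoch train/test accuracy and loss
curves are returned for plotting. ReLU is max(0, x); forward and backward
passes are plain NumPy (einsum convolutions), which is ample at these
problem sizes and keeps the package free of deep-learning frameworks.

## Synthetic benchmark

The generator emulates the structure the method assumes: `n_genes ≫
n_samples`, a few informative genes whose class-c mean is `c · effect ·
noise_sd` (a monotone ladder, so any class count works), redundant copies
`parent + N(0, τ²)` with `τ² = σ²(1−ρ²)/ρ²` targeting correlation ρ on the
parent's residual scale, and independent N(0, σ²) noise genes. Labels get
exact class counts (largest-remainder rounding of the proportions, then a
seeded permutation), so every class is always present. Gene roles are
scattered by a seeded permutation of the columns.

The bundled benchmark — the default `SyntheticSpec` — is 60 samples × 500
genes, 2 balanced classes, 5 informative genes at effect 2.0σ with 4
redundant copies each at ρ = 0.8, reduced to an mRMR pool of 50 and searched
with a reduced configuration (swarm 20, 30 generations, 1-NN fitness) over
10 seeds; these sizes keep a full three-algorithm comparison under a minute
on one CPU. What the generator does *not* model: probe-level noise,
batch/platform effects, heavy-tailed or count-valued expression, correlated
noise blocks. Passing recovery tests therefore shows the pipeline finds
planted mean-shift signal through redundancy and noise — not that it
handles real-array artifacts.

Recovery scoring counts an informative gene as found if it *or any of its
redundant copies* is selected (the copies carry the same signal), and also
reports the selected-subset size and its noise fraction.

## Degenerate inputs and edge rules

Constant genes: min–max and z-score map them to 0, discretization to a
single code, MI to exactly 0. Single-gene pools collapse the search space to
one subset. Groups of size one skip the group-mate term in position
updates. `k = 1` LOOCV with a sample whose nearest neighbor is equidistant
to several points resolves by lowest index. An accuracy of 100 stops the
run early — no better subset can exist under this fitness.

## Known limitations

- LOOCV fitness on tens of samples is a high-variance, optimistically
  biased selection criterion; with strong planted signal many subsets reach
  100 and the optimizer stops at the first, so selected subsets typically
  still contain noise genes (the early stop trades pruning for speed).
- The CNN is data-hungry relative to microarray sample sizes; on the
  60-sample benchmark its held-out split has 12 samples and its accuracy is
  correspondingly coarse and seed-sensitive.
- Normalization before splitting leaks scale information (see above).
- The mRMR estimator is the 3-bin plug-in; continuous estimators (e.g.,
  KSG) are out of scope.
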