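# Methods

This note describes the statistical methodology implemented by `walkmmd`:
what is computed, why, and which design choices matter. Symbols follow the
code; all defaults quoted here are the package defaults.

## 1. Problem setting

The data are sets of short 2D single-particle trajectories: ordered
localizations (in µm) at a uniform time lapse `dt` (default 0.0154 s).
Typical tracks have 7–25 points, far too short to classify individual
trajectories reliably. The unit of inference is therefore the *set*: we ask
whether two sets of trajectories were drawn from the same underlying
distribution of motion behaviours, and if not, which behaviours account for
the difference.

Two deliberate constraints shape everything downstream:

- **Model-free testing.** No motion model is fitted to the experimental
  data. Trajectories are mapped to feature vectors by a *frozen* function,
  and distributions of feature vectors are compared non-parametrically.
- **Amortized simulation-based inference.** The feature map is learnt once
  from simulations spanning a broad family of motion models, then reused
  unchanged for any dataset. Nothing is ever refit on data being tested.

## 2. Simulation models and priors

Five canonical random-walk models cover qualitatively distinct physics —
Gaussian and non-Gaussian increments, stationary and ageing dynamics,
ergodic and weakly non-ergodic behaviour, continuous and jump paths:

| Model | Mechanism | anomalous exponent α prior |
| --- | --- | --- |
| fBM | fractional Brownian motion, correlated Gaussian increments (Hurst H = α/2), exact Cholesky fGn | U[0.2, 1.8] |
| sBM | scaled Brownian motion, independent increments with per-step variance 2 K_α Δ(tᵅ), K_α = D·dt^(1−α) | U[0.2, 1.8] |
| OU | Ornstein–Uhlenbeck confinement, exact discretization, stationary start, per-dim stationary variance D·dt/θ | — (not anomalous) |
| CTRW | continuous-time random walk, Pareto waiting times ψ(τ) ∝ τ^−(1+α) (τ₀ = dt/10), Gaussian jumps | U[0.2, 1.0] |
| LW | Lévy walk, constant-speed ballistic flights with Pareto durations of exponent γ = 3 − α | U[1.0, 2.0] |

Shared priors: trajectory length N log-uniform on [7, 25] (mean ≈ 14);
effective diffusivity D log-normal with ⟨log₁₀ D⟩ = −0.5 and sd 0.5 (µm²/s);
OU relaxation rate θ log-uniform on [0.01, 1] per time lapse; localization
noise i.i.d. Gaussian with sd uniform on [0.015, 0.040] µm, added to every
coordinate.

A practical subtlety for validation: CTRW and sBM are weakly non-ergodic,
so their time-averaged MSD does not reproduce the ensemble exponent. Scaling
checks in the test suite therefore use the *ensemble* MSD from the origin,
⟨r²(t)⟩ over many independent trajectories; and Lévy-walk scaling is checked
at mid-range α where the finite-time crossover to the asymptotic regime is
fast.

## 3. Trajectory graphs

Each trajectory becomes a directed graph whose nodes are localizations.
Node i receives edges from its predecessors at offsets
{1, 2, 3, 5, 7, 9, 13, 19, …} (capped at in-degree 10); nodes with fewer
than that many predecessors connect to all of them. This wiring mixes local
and long-range temporal context at O(N) edges.

Features are built to be invariant to translation and rotation, and — apart
from one explicit global channel — to spatial scale. Positions are first
normalized by the trajectory's standard-deviation scale `s`; the log₁₀ of
`s` is kept as a global graph attribute. Six node features encode normalized
time and cumulative path statistics (power sums of step lengths, distances
from the start and maximal excursion); six edge features encode the time
offset, normalized end-to-end distance of the hop, cumulative step sums
between the endpoints, and the cosine between the arriving displacements at
the two endpoints. Zero-variance (stuck) trajectories are rejected as
degenerate.

## 4. The encoder

A graph neural network maps each trajectory graph to a 16-dimensional
latent summary vector. Architecture: node (6→10) and edge (6→16) embedding
perceptrons; three edge-conditioned GIN-style message-passing layers with
32 channels where messages are `relu(h_src + W·e)`; attention pooling over
nodes; concatenation of the global log-scale channel; a perceptron to the
16D latent; and two task heads — the anomalous exponent α (masked for OU)
and the generating model (5-way). Training minimizes masked-α MSE plus
cross-entropy with Adam (lr 10⁻³, batch 256) on 100k trajectories streamed
fresh from the prior, so the network never sees an example twice.

Because the tasks are only a scaffold, what matters is that the latent
becomes an informative, well-conditioned summary. Three conditioning choices
are load-bearing on these short, heavy-tailed inputs:

1. **log1p compression** of the nonnegative cumulative-sum features before
   z-scoring — their power-law tails otherwise leave outliers tens of
   standard deviations out;
2. **degree-normalized (mean) aggregation** of messages — plain sums grow
   with fan-in and saturate the attention softmax before training starts;
3. **layer normalization** after each message-passing perceptron.

Input standardization statistics are frozen at first exposure and stored
with the model; the whole encoder is deterministic at evaluation time and
serializes to a single `.npz` archive (bit-exact round trip, versioned
format).

At the defaults the encoder reaches ≈ 0.48 held-out 5-way model
classification accuracy (chance 0.2) and α mean absolute error ≈ 0.27
against ≈ 0.43 for the constant-prediction baseline — the expected regime
for 7–25-point tracks, where single-trajectory classification is
intrinsically ambiguous.

For visualization and low-dimensional testing, a 2D projection of the
latents is learnt once on simulations: a seeded UMAP embedding of ≥ 10⁴
simulated latents distilled into a small MLP regressor. The distilled map
is parametric, deterministic and frozen — applying it to new data never
refits anything.

## 5. The kernel two-sample test

Feature sets X = {x₁…x_m}, Y = {y₁…y_n} are compared with the unbiased
squared maximum mean discrepancy under a Gaussian kernel
k(x, y) = exp(−‖x−y‖²/2σ²):

MMD²_u = Σ_{i≠j} k(x_i,x_j)/(m(m−1)) + Σ_{i≠j} k(y_i,y_j)/(n(n−1)) − 2 Σ_{ij} k(x_i,y_j)/(mn)

The bandwidth σ is the median pairwise distance of the pooled sample (the
median heuristic). The null distribution is obtained by permutation: the
pooled sample is randomly re-split B times (default 500–1000) and the
statistic recomputed; the p-value is (1 + #{null ≥ observed})/(B + 1), and
H₀ is rejected at level β when the observed statistic exceeds the (1−β)
empirical null quantile. The permutation null is exact by construction, so
the test is calibrated for *any* feature map — including a learnt encoder —
which is what licenses testing on learnt summaries. A sensitivity check in
the test suite confirms the median-heuristic bandwidth is within Monte
Carlo error of the best fixed bandwidth over a 1/8×–8× sweep.

Two nuisance controls precede the test. *Length marginalization*: the two
sets are subsampled so their trajectory-length histograms match (per-length
minimum counts), preventing a difference in track length alone from driving
a rejection. *Size equalization*: the larger set is subsampled to the
smaller's size.

A Hotelling T² two-sample test on feature means is provided as the
classical parametric baseline; it is blind to any difference that preserves
the mean, which the MMD test is not.

### Calibration and power

Measured on the fBM/sBM mixture benchmark (contrast ν: set X has fBM
fraction 0.5 + ν, set Y 0.5 − ν), classical features, B = 500, β = 0.05,
100 repetitions per cell:

- type-I error at ν = 0: ≈ 0.06 (binomial 95% band around 0.05);
- power at ν = 0.2: 0.00 / 0.13 / 0.55 for set sizes 50 / 200 / 1000;
- power at N = 200: 0.06 / 0.13 / 0.50 for ν = 0 / 0.2 / 0.5;
- power at ν = 0.5, N = 1000: 1.00.

Power grows with both the contrast and the set size, as it must for a
consistent test.

## 6. Interpreting a rejection

The witness function f(z) = mean_i k(x_i, z) − mean_j k(y_j, z) is the
empirical maximizer of the MMD: its sign says which set is over-represented
near z, its magnitude how strongly. On a grid over a 2D feature plane the
package computes S(z) = mean(f(z))²/var(f(z)), with mean and variance over
bootstrap resamples of each set, regularized additively by 10⁻³ of the
maximal grid variance so S vanishes in data-free space instead of
amplifying noise.

The *critical region* of a condition is the connected component of
{S ≥ ¾ max S}, intersected with that condition's witness sign, containing
that side's S maximum. Trajectories whose features fall inside a region are
the concrete examples of the detected difference; the 16 nearest
trajectories to a chosen point (e.g. the region peak) serve as canonical
exemplars.

## 7. Comparing many groups

For G groups, all pairwise squared MMDs form a G×G matrix. Each entry gets
an uncertainty from repeated random subsampling of the two groups (variance
of the subsampled statistics, halved because subsampling varies both sets);
groups below a minimum size (default 150) are excluded. The matrix is
embedded in 2–3 dimensions by weighted metric MDS minimizing the stress
Σ w_ij (d_ij − δ_ij)², with weights w_ij the inverse variances, multiple
seeded restarts, and negative squared-MMD entries (possible for the
unbiased estimator under near-identical groups) clamped at zero distance.
Uncertain pairwise estimates therefore pull on the embedding weakly, and
well-measured ones strongly.

## 8. Spatial regions

For spatially resolved experiments, a kernel-density threshold on the
pooled localizations extracts polygonal dense-region masks; trajectories
are split by region membership into per-region groups, which then enter the
group-level pipeline above.
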