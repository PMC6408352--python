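# Methods

`recticluster` clusters complete multi-indexed response data under an
algebraic interpretability constraint — every cluster must be a Cartesian
product of a row subset and a column subset of the experiment grid — and
then searches a combinatorial space of small ODE models for mechanisms that
explain each cluster's mean response. This note records the model, the
conventions, the numerical choices, and what the synthetic benchmark does
and does not establish.

## Data model and similarity

A complete dataset is an order-`h` tensor `Z` with named, labelled axes
(canonically cell line x ligand x dose x time x protein). Experiments are
indexed by the leading `d` axes (default `d = 2`). Flattening reshapes `Z`
into an `N1 x N2` matrix `Z~` with `N1 = n1...nd` rows, one per experiment,
using row-major (last-axis-fastest) enumeration throughout; this fixed
convention makes the similarity-matrix/similarity-tensor correspondence
bit-stable. Rows are normalized (default: unit Euclidean norm, so cosine
similarity reduces to a dot product; `max1` and `none` are options) and the
cosine similarity matrix `S~` is reverse-flattened into the order-`2d`
similarity tensor `S`. Incomplete tensors are a hard error — the method
requires a measurement for every label combination — and no imputation is
attempted.

Within-group heterogeneity is summarized as the mean of `1 - s_ij` over
unordered distinct experiment pairs in the group: 0 means all pairwise
similarities are 1 (complete homogeneity), 1 means all are 0. Self-pairs
are excluded because self-similarity is identically 1 and would only dilute
the statistic. The score requires non-negative similarities, hence
non-negative measurements.

## Rectangular clustering as integer programming

A hard partition is encoded two ways:

* `X`, Boolean pairwise indicators with `x_ij = 0` iff experiments `i, j`
  share a cluster, constrained by the equivalence-relation inequalities
  (reflexivity, symmetry, transitivity `0 <= -x_ik + x_ij + x_jk <= 2`)
  plus three rectangularity families: the diagonal-swap equality
  `x_{i1 i2, j1 j2} = x_{i1 j2, j1 i2}` and two side inequalities tying the
  diagonal pair to its same-row and same-column pairs.
* `Y` (or a seed `W`), one-hot cell-to-cluster assignments with the
  rectangle-closure condition `-1 <= y_ikr + y_jlr - y_ilr <= 1`.

They are linked entrywise by `1 - x_ij = sum_k y_ik y_jk` (a tested
invariant). Rectangles may be disconnected: no ordering of rows or columns
is assumed or exploited.

**Direct pathway.** `max <S, 1-X> + lambda <1, X>` over feasible `X`. One
Boolean variable is created per unordered pair of distinct grid cells;
reflexivity and symmetry are enforced structurally rather than as rows,
which halves the variable count. Row counts are reported both under the
as-written convention (reflexivity `N1`, symmetry `N1^2`, transitivity
`N1^3`, three rectangularity families of `n1^2 n2^2` rows each — about
1.3e8 rows for the 36 x 14 study grid) and as built (deduplicated:
`3 C(N,3)` transitivity rows plus `5 C(n1,2) C(n2,2)` rectangularity rows).
The diagonal terms of `S` are included in the objective; they are constant
across partitions and immaterial to the argmax.

**Refinement pathway.** Given any hard seed clustering `W` (from
agglomerative, spectral, k-means, or an external tool via CSV), maximize
the number of unchanged assignments `<W, Y>` subject to unique assignment
and rectangle closure. The slice count `m` is exactly `W`'s cluster count;
slices may empty out but never split or merge. A rectangular seed is a
fixed point with agreement `n1 n2`. The seed method is user-facing
configuration, not a mere initialization: the refinement finds the nearest
rectangular partition to whatever structure the seed encodes.

**Solving.** Both programs are solved by branch and cut to a certified
global optimum (relative MIP gap 0) with the HiGHS solver bundled in SciPy;
the backend contract (Boolean variables, two-sided sparse rows) is solver
agnostic and programs can be exported in LP format for any external tool.
Solutions are decoded back to partitions and re-validated; a constraint
violating assignment is reported as an internal error, never returned.
For grids above 60 cells, transitivity rows are generated lazily: solve,
locate violated triples in the incumbent, append those rows, repeat. The
final optimum is identical to the full build (tested), while avoiding the
O(N^3) row materialization that is intractable at `N = 504`.

**Choosing lambda.** The pair penalty trades within-cluster similarity
against the number of between-cluster pairs; larger values yield finer
partitions, and the count of between-cluster pairs at the optimum is
non-decreasing in lambda (tested). No single default suits all data, so
two mechanisms are provided: an explicit scan (`--lam-scan`), and a
data-driven default that segments the off-diagonal similarity distribution
into three classes by maximizing between-class variance (histogram
multi-Otsu, 256 bins) and places lambda at the midpoint of the two upper
class means. The three-class form matters: cross-cluster similarities are
often themselves multi-modal, and a two-class split can land between two
cross modes rather than between cross and within. The heuristic assumes a
clearly separated, low-noise similarity structure; on noisy data prefer the
scan or the refinement pathway, which needs no lambda.

**Ties and determinism.** Decoded partitions are canonicalized (clusters
ordered by lexicographically smallest member cell). Where the optimum is
non-unique (e.g. symmetric instances at the crossover lambda), tests and
reports compare objective values, not partitions. The brute-force oracles
(exhaustive enumeration of rectangular partitions, guarded at 12 grid
cells) break ties by enumeration order.

## The crosstalk model space

Candidate mechanisms couple a ligand-bound receptor `R` to the two observed
readouts, phosphorylated ERK (`E`) and phosphorylated AKT (`A`). Each of
the six ordered pairs R->E, R->A, E->A, A->E, E->R, A->R carries one of
{activation, inhibition, none}; enumerating all sign patterns gives the
default pool of 3^6 = 729 models. The kinetic regime (mass action vs
Michaelis-Menten) and the inhibition mechanism (blocking/sequestration vs
removal/degradation) are uniform, config-switchable conventions, and the
enumeration is config-driven so an externally derived model list can be
supplied verbatim. This combinatorial scheme is a documented
reconstruction; the package makes no claim that it reproduces any
externally published model list.

Dynamics conventions (all concentrations normalized, capacities
`E_tot = A_tot = 1`, `R_tot = dose`):

* `dR/dt = -delta_R R` with `R(0) = dose scale`, plus any activation influx;
* activation of `T` by `U`: `k U (T_tot - T)` (mass action) or
  `V U (T_tot - T) / (K + T_tot - T)` (Michaelis-Menten, 2 parameters);
* blocking inhibition of `T` by `I`: all activation influx into `T` is
  multiplied by `1 / (1 + I/K_I)`;
* removal inhibition: an extra term `-k_rem I T`;
* first-order decay `-delta_T T` for every species with an incoming edge
  (always for `R`).

Parameter counting is deterministic from the model structure: `delta_R`, plus
`delta_E`/`delta_A` when the species has an incoming edge, plus one or two
parameters per active edge as above. A blocking edge whose target has no
activation influx is structurally void — it contributes no term and no
parameter — so observationally identical model pairs are explicit rather
than hidden behind phantom parameters.

Initial conditions default to `E(0) = A(0) = 0`: the readouts are
baseline-normalized phosphorylation levels and stimulation starts at t = 0.
An alternative convention that seeds the ODE with the first measured value
is available (`FitOptions(initial="first-observation")`) but is not the
default, because with time grids that exclude t = 0 it displaces the model
family away from its own simulated output: fitting a model to noise-free
data generated by that very model then stalls at a residual floor (~5e-3
observed) with badly biased rates. With three time points there is no room
to fit initial conditions as free parameters.

Integration uses LSODA (stiff-capable, adaptive) with rtol 1e-8 / atol
1e-10 for simulation and a relaxed rtol 1e-6 inside fitting loops.
Integration failures and blow-ups are mapped to infinite loss upstream;
genuinely negative trajectories raise rather than being clipped (only
tolerance-level jitter, above -1e-6, is floored at zero).

## Fitting and ranking

Each cluster's experiments are averaged pointwise into a single
dose x time x observable response (n = 12 by default). A practical
identifiability screen replaces symbolic analysis: models must satisfy
`n - k - 1 >= 1` so the small-sample AIC is defined (k <= 10 at n = 12),
optionally pass a finite-difference sensitivity-rank test at a reference
parameter point, or match a user-supplied whitelist exactly.

Parameters are estimated by squeeze-and-breathe Monte-Carlo search:
iterated rounds of log-uniform sampling within a box (default bounds
[1e-3, 1e3], rates being positive and scale-free after normalization),
elite selection (top 10%), box contraction around the elites (factor 0.5
per round), one mid-schedule re-expansion to the full box, and a final
local refinement. Defaults are 10 rounds of 200 samples. The refinement is
trust-region least squares in log-parameter space started from (i) the top
distinct elites, (ii) each round's best sample — pre-contraction rounds
explore different basins — and (iii) decay-permuted copies of the best
elite. The last matters because linear compartment cascades are nearly
symmetric under exchange of decay rates (`e^{-at} - e^{-bt}` is symmetric
in a and b; only saturation breaks the tie), so the contracted search can
settle in a mirror basin whose residual is orders of magnitude above the
true one; permuting the `delta_*` values probes those basins directly and
deterministically. The whole search is reproducible bit-for-bit given its
seed. Global optimality is not claimed.

Models are scored with the small-sample-corrected Akaike criterion in its
Gaussian residual form with the error variance profiled out,
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`, with RSS floored at 1e-12 to
guard `ln 0`. Rankings are ascending with ties broken by smaller `k`, then
canonical model serialization. A known limitation at n = 12: against a
nested competitor with one extra parameter, AICc requires roughly a 32%
residual reduction to switch, which pure noise achieves in about 9% of
replicates — model selection against one-parameter supersets is therefore
intrinsically unreliable at this sample size, and the identification
benchmark uses structurally distinct candidates.

## Synthetic benchmark

The generator plants a random rectangular partition (repeated random
splitting of a cluster's row- or column-set into two non-empty parts,
producing possibly disconnected rectangles; exactly m non-empty clusters),
assigns each cluster a mechanism from a library of distinct single- and
two-edge models, simulates every grid cell's dose/time/protein curves from
its cluster's mechanism, and adds Gaussian noise truncated at zero
(additive rather than multiplicative, keeping non-negativity and making
the cosine-similarity degradation predictable). Problem sizes used in the
shipped experiments — grids up to 5 x 4, m <= 3, 2 doses x 3 times x
2 proteins, 20-25 replicates — were chosen so every ILP remains within the
brute-force oracle's reach and the full battery runs in minutes.

The default library leads with receptor-to-pERK-only and
receptor-to-pAKT-only mechanisms (orthogonal response signatures) and a
balanced dual-activation mechanism; cross-cluster cosine similarities then
sit near 0 and 0.7 against a within-cluster mode at 1. With only two
observed proteins, at most two mechanisms can be exactly orthogonal, so
separation degrades beyond three planted clusters — a ceiling of the
2-observable design, not of the method. Per-cell dose jitter (log-normal
sensitivity factors) is available but defaults to off, so that at zero
noise within-cluster responses are identical and recovery claims are
exact.

What passing the benchmark shows: the encodings, programs, solver layer,
decoders and fitting machinery are mutually consistent and certified
optimal where an oracle exists, and the pipeline recovers planted
structure under modest noise. What it does not show: performance on real
phosphoproteomic data, whose noise is multiplicative and structured, whose
clusters are not exactly rectangular, and whose mechanisms are not drawn
from the candidate pool.

## Known limitations

* The direct ILP is exact but exponential in the worst case; it is
  intended for small grids or as a refinement target. Large instances
  should use the refinement pathway (its program has `O(n1^2 n2^2 m)` rows
  and solves quickly at study scale).
* The lambda heuristic assumes separated similarity modes; use the scan on
  ambiguous data.
* AICc at n = 12 cannot reliably reject one-extra-parameter supersets
  (see above).
* Michaelis-Menten constants are weakly identified when responses stay far
  from saturation; the recovery guarantees shipped with the package are
  stated for the mass-action family.
* The heterogeneity score and the cosine kernel require non-negative data;
  alternative kernels are hookable but untested.
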