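# recticluster

Constrained tensor clustering of multi-indexed biological response data,
with a downstream systematic search for ODE signalling mechanisms.

## The problem

High-throughput perturbation studies measure the response of many cell
lines to many ligands, each response itself multi-dimensional (doses, time
points, readouts such as phosphorylated ERK and AKT). A complete dataset of
this kind is naturally an order-5 tensor **Z** — for the motivating
breast-cancer study design, 36 cell lines x 14 ligands x 2 doses x 3 time
points x 2 proteins. Ordinary clustering of the 504 cell-line/ligand
experiments happily groups any two experiments that look alike, but such
clusters need not admit a *mechanistic* reading. If (cell *c_h*, ligand
*l_i*) and (cell *c_k*, ligand *l_j*) respond alike because they share a
signalling mechanism, then the swapped combinations (*c_k*, *l_i*) and
(*c_h*, *l_j*) should respond alike too. `recticluster` enforces exactly
this: every cluster must be **rectangular** — a Cartesian product of a
cell-line subset and a ligand subset, possibly non-contiguous — so clusters
can be interpreted as "these cell lines share a mechanism that these
ligands engage".

## The method

1. **Similarity tensor.** Flatten **Z** (row-major) into the experiment
   matrix `Z~ ∈ R^(N1 x N2)`, `N1 = n1 n2`; normalize rows; take the cosine
   similarity matrix `S~ ∈ R^(N1 x N1)`; reverse-flatten into the order-4
   similarity tensor **S**.
2. **Clustering as exact integer programming.** Encode a partition by
   Boolean pairwise indicators `x_ij` (0 = same cluster) constrained by the
   equivalence-relation inequalities (reflexivity, symmetry, transitivity
   `0 ≤ −x_ik + x_ij + x_jk ≤ 2`) plus algebraic rectangularity constraints,
   and solve

       max ⟨S, 1−X⟩ + λ⟨1, X⟩   s.t.   b_l ≤ V·vec(X) ≤ b_u

   by branch and cut to a **certified global optimum** (λ regularizes the
   number of clusters). Alternatively, start from *any* pre-existing
   clustering **W** (agglomerative, spectral, k-means, or an external tool)
   and solve `max ⟨W, Y⟩` over rectangular one-hot assignments **Y** — the
   nearest interpretable partition, measured in unchanged assignments.
3. **Mechanism search.** For each cluster's mean response, enumerate a pool
   of 729 three-species ODE models (receptor R, pERK E, pAKT A; each of the
   6 ordered pairs carries activation, inhibition or nothing; mass-action or
   Michaelis–Menten kinetics; blocking or removal inhibition), filter for
   practical identifiability, fit by squeeze-and-breathe Monte-Carlo search,
   and rank by the small-sample Akaike criterion
   `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`.

A synthetic-data generator plants rectangular partitions with
mechanism-driven responses, so the whole pipeline is testable end to end
without any external dataset. See `docs/methods.md` for conventions,
numerical choices and limitations.

## Worked example

Generate a 6 x 5 grid with 3 planted rectangular clusters at noise
σ = 0.05, then run the refinement pathway (seed clustering + exact
rectangular refinement):

```bash
recticluster synth --n1 6 --n2 5 --m 3 --sigma 0.05 --seed 0 \
    --out data.csv --truth truth.json
recticluster run --data data.csv --out-dir run --pathway refine --m 3 --seed 0
```

which prints

```
wrote data.csv (360 values, 3 planted clusters)
{
  "objective": 30.0,
  "certified": true,
  "n_clusters": 3
}
```

`objective: 30.0` means all 30 grid cells kept their seed assignment — the
seed clustering was already rectangular, and the branch-and-cut proof
(`certified: true`, optimality gap 0) guarantees no better rectangular
partition exists for this seed. `run/partition.json` contains the three
clusters; for this instance they match the planted truth exactly, e.g.
cluster 1 is `{C01, C04} x {L03}` — a *disconnected* rectangle, allowed by
design since row/column order carries no meaning. The manifest also reports
per-cluster heterogeneity scores (mean of 1 − cosine similarity over
experiment pairs; 0 = homogeneous, 1 = heterogeneous):

```
heterogeneity: {"0": 0.0079, "1": 0.0040, "2": 0.0096}
```

small, as expected for within-cluster variation generated by σ = 0.05 noise
alone. Adding `--fit-models` appends an AICc-ranked table of candidate
mechanisms per cluster (`run/model_ranking.json`).

The same machinery is available as a library:

```python
from recticluster import tensor_core, ilp_engine

Z = tensor_core.load_long_table("data.csv",
        ("cell_line", "ligand", "dose", "time", "protein"))
S_mat, S = tensor_core.similarity_from_tensor(Z, d=2)
program = ilp_engine.build_direct_program(S, lam=0.85)
result = ilp_engine.solve(program)          # certified optimum
partition = ilp_engine.decode_direct(result, Z.shape[:2])
```

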