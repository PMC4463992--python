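# Methods

## The similarity model

`shellsim` treats a protein structure as an unordered atom cloud and asks
how similar two clouds are in their radial mass distribution and gross
composition. The representation is intentionally alignment-free: no
superposition, no residue correspondence, no sequence. That makes the score
cheap (linear in atom count) and applicable to structures with no usable
homology, at the cost of ignoring all angular information — two structures
with identical radial profiles but different folds are indistinguishable to
the density term.

### Layering

Radial distances are taken from the unweighted geometric center (every atom
weighs the same, regardless of element). The default scheme has ten shells
with boundaries at 10, 20, 30, 40, 50, 60, 70, 80, 100 in the coordinate
file's native length unit, the last shell open-ended. Shells are half-open
`[lo, hi)`, so every radius maps to exactly one shell and a radius exactly
on a boundary belongs to the outer shell. The boundary values follow the
published layering; the source text labels them "nm", but PDB coordinates
are in Å and an 80 nm protein radius is physically implausible, so the
numbers are read in the file's own unit.

### Per-parameter scores

The shell-density similarity divides by the *query's* shell count, so the
score is asymmetric; the query must always be the first argument. A shell
empty in the query makes the published formula undefined; we score such a
shell 1 when it is also empty in the target and 0 otherwise, which is the
unique choice that keeps self-similarity exactly 1 while staying bounded
above by 1. No similarity is clamped: published reference values go as low
as −1.78, so negativity is part of the model, and the scalar form
1 − |n1 − n2|/n1 goes negative once the target exceeds twice the query.

The P/S positional rule (same shell 1.0, adjacent 0.8, else 0) is defined
in the source only for single atoms. With several P or S atoms we take the
best cross-pair score (optimistic matching), which reduces to the plain
rule in the single-atom case. An element absent from both structures scores
1.0 — the published table scores the phosphorus column 1.0 although the
query protein has no P — and absent from exactly one scores 0.0.

Residue counts use distinct `(chain, residue_id)` pairs; residue *types*
count distinct names among the 20 standard amino acids, so modified or
non-standard residues do not inflate the type count.

### Combination weights

The overall score is the plain dot product with nine weights. The packaged
default is the published back-propagation fit
(0.3183, 0.0343, 0.0204, 0.0603, 0.0653, 0.1062, 0.1002, 0.1477, 0.1480);
the weights sum to 1.0007, confirming that no sum-to-one constraint was
imposed, and none is imposed here. The published per-protein table is
shipped verbatim as a fixture. Its printed overall column is mutually
inconsistent with its printed rows under the printed formula (top row:
recomputed 0.8328 vs printed 0.8102); the package reproduces the formula
and documents the discrepancy rather than silently correcting either
number. The recomputed ranking keeps the same rank-1 protein.

## Weight training

The published combination rule is an intercept-free linear form, so the
default "network" is a single linear output unit without bias, trained
full-batch by gradient descent on mean squared error. The problem is convex;
on noiseless linear data the fit converges to the generating weights and
agrees with a normal-equations solution to better than 1e−3 (asserted
against `numpy.linalg.lstsq` as an independent oracle). Defaults: learning
rate 0.2, at most 50 000 epochs, early stop when the per-epoch loss
decrease falls inside [0, 1e−13) — the lower bound matters, since a plain
"small change" test would also stop on divergence; a non-finite loss raises
instead, naming the epoch. A one-hidden-layer variant (default 6 hidden
units, linear activations, backprop through both matrices) exists for
fidelity to the "neural network" description; because the activations are
linear its two matrices collapse to an exact equivalent nine-weight map,
which is what is returned. It is not the default: the composite problem is
non-convex and buys nothing for a linear target.

No non-negativity constraint is applied to fitted weights (the published
fit has none).

## Pathway propagation

The regulatory network is a signed DAG; conditional probability tables are
never published for such curated networks, so a sign-gated combination rule
stands in for them: a node activates when at least one activating parent
fires and no inhibiting parent fires, parents independent (noisy-OR with
inhibitor gating). On trees this equals exact enumeration over Bernoulli
source states (asserted to 1e−12); on DAGs with shared ancestors the
parent-independence assumption makes it an approximation, which is the
standard trade-off of layer-wise propagation.

The published child-probability formula is a sum of products of
complemented inhibitors with each activator and with the joint activator
term; taken literally that sum over-counts the union and can exceed 1. Both
semantics are implemented: `union` (default, coherent) and `literal`
(faithful to the printed formula, clamped at 1 with a logged diagnostic).
The published top-path probability (0.9781) depends on an unprinted network
topology and prior assignment and is therefore not reproducible; the
packaged example network is an explicitly labelled reconstruction on which
the published winning chain ranks first with probability equal to its
clamped prior, 0.8102.

A pathway's probability is computed on the path in isolation: the source's
prior carried along the chain, inhibiting edges replacing it by its
complement. Source attribution at a node is Bayes-style: each source's
contribution is the node probability with all other priors zeroed,
normalized over sources. Ties anywhere break lexicographically so all
rankings are deterministic.

## Synthetic data

The generator exists because the original inputs are not recoverable: the
training pairs were labelled through an external homology service and the
network figure's edge set is unprinted. It emulates:

* **Structures** — point clouds with a planned per-shell count vector
  (largest-remainder apportionment of the atom total), radii uniform within
  each shell, directions arranged so the arithmetic mean is *exactly* the
  origin: antipodal pairs and 120° zero-sum triples within shells, residual
  odd-shell singletons balanced by tilting donor pairs. Exactness matters:
  it makes the planned shell counts ground truth that is independent of the
  binning code under test. Degenerate plans that cannot be balanced (e.g.
  nothing but single-atom shells) raise rather than silently drifting.
  Default composition C/N/O/S = 0.62/0.17/0.20/0.01 (typical heavy-atom
  protein composition; no P, like the motivating query protein); default
  radial profile puts most mass in the inner shells with a small tail
  beyond 80, mirroring the described distance distribution. The open tenth
  shell is sampled within 20 % past the last boundary.
* **Training tables** — features uniform on [−0.5, 1] (the observed range
  of the reference table, negative values included), labels from a known
  weight vector plus Gaussian noise; n = 100 matches the original
  training-set size, noise sd 0.05 where noise is wanted.
* **Networks** — layered signed DAGs with one planted source given an
  all-activating chain to the sink and a prior exceeding every competitor
  by a margin (default 0.5). Competitor priors live in [0.1, 0.45], so any
  competitor path scores at most max(0.45, 1 − 0.1) = 0.9 < 0.95 and the
  planted path provably dominates at the default margin.

What the generator does **not** emulate: bond geometry, secondary
structure, anything angular, or correlated features in training tables.
Passing tests therefore demonstrate correctness of the arithmetic and the
propagation semantics on controlled inputs, not biological validity of the
metric on real structures.

## Numerical choices and limitations

* Shell binning via `searchsorted(side="right")` implements the half-open
  convention exactly; oracle comparisons use explicit interval loops.
* Layer weights always sum to 1 up to float rounding; tests assert 1e−12.
* PDB coordinates carry three decimals, so structure round-trips are exact
  to 5e−4 per coordinate.
* Similarity scores seed priors only after clamping to [0, 1]; clamps are
  logged, not silent.
* Multi-model PDB files use the first model; alternate locations keep the
  first altloc; waters and HETATM are excluded by default and hydrogens
  kept — all toggleable, since the original atom-filtering conventions are
  unstated.
* Problem sizes in the test and acceptance battery (structures up to 2 000
  atoms, 100 random pairs, 50 network seeds, trees of 8 nodes) keep the
  full suite in the seconds-to-a-minute range while still exercising every
  code path at realistic scale.
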