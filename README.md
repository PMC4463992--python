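# shellsim

Alignment-free protein structural similarity scoring and signed-network
pathway ranking.

`shellsim` is for researchers who want to compare a query protein against a
panel of reference structures **without** sequence alignment or structural
superposition, and then use those similarities to rank candidate regulatory
pathways. The motivating use case is a poorly characterised protein (such as
the gastric-carcinoma-associated p42.3, which shares an EF-hand and a
coiled-coil domain with the S100 family): reference proteins with known
pathways are scored against the query, the scores seed a curated signed
regulatory network, and the maximum-probability source-to-sink chain is
reported as the most plausible acting pathway.

## The model

Each structure is reduced to its atom cloud. With the geometric center as
origin, atoms are binned into ten concentric shells (boundaries at 10, 20,
..., 80, 100 in the file's length unit; the tenth shell is open-ended). An
ordered pair (query *1*, target *2*) is scored on nine parameters
S<sub>1</sub>..S<sub>9</sub>:

* **S1 — shell density.** Per shell *i*, sim<sub>i</sub> = 1 − |l<sub>1i</sub> −
  l<sub>2i</sub>| / l<sub>1i</sub>; shells are weighted by
  w<sub>i</sub> = (l<sub>1i</sub>/n<sub>1</sub> + l<sub>2i</sub>/n<sub>2</sub>)/2
  (the weights sum to 1) and S1 = Σ w<sub>i</sub> sim<sub>i</sub>.
* **S2–S4 — atom count, residue count, residue-type count**, each scored
  1 − |n<sub>1</sub> − n<sub>2</sub>| / n<sub>1</sub>.
* **S5–S7 — C, N, O proportions**, same relative-difference form on the
  element fractions.
* **S8, S9 — P and S shell position**: same shell → 1.0, adjacent shells →
  0.8, otherwise → 0; an element absent from both structures scores 1.0.

Scores are deliberately **unclamped** (dissimilar pairs go negative) and
**asymmetric** (the query's value is the denominator). The overall score is

S = Σ Q<sub>i</sub> S<sub>i</sub>,  with packaged weights
Q = (0.3183, 0.0343, 0.0204, 0.0603, 0.0653, 0.1062, 0.1002, 0.1477, 0.1480)

fitted by back-propagation on labelled protein pairs; `shellsim train`
re-fits them from any 10-column table by full-batch gradient descent.

For the pathway stage, overall similarities (clamped to [0, 1]) become the
prior activation probabilities of the source nodes of a signed DAG.
Probabilities propagate in topological order under a noisy-OR rule with
inhibitor gating,

P(v) = ∏<sub>u inhibiting</sub>(1 − P(u)) · (1 − ∏<sub>u activating</sub>(1 − P(u))),

and every simple source-to-sink path is scored by the probability it alone
delivers to the sink (activating edges carry the probability forward,
inhibiting edges take the complement). The top-ranked path is the reported
pathway.

## Worked example

```
$ shellsim simulate --outdir demo --seed 5        # synthetic fixtures
$ shellsim compare demo/structure_00.pdb demo/structure_00.pdb demo/structure_01.pdb
# shellsim: 0.1.0
# mode: union
# seed: 0
# query: structure_00
# weights: packaged
protein	atoms	residues	residue_types	C	N	O	S_position	P_position	density	overall
structure_00	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0007
structure_01	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	1.0000	-0.4518	0.5386
```

A structure against itself scores 1 on every parameter, so the overall score
equals the sum of the nine packaged weights, 1.0007. The second target has
the same size and composition but a different radial profile, so only the
density term (here −0.4518) drags the overall score down to 0.5386.

```
$ shellsim pathway --example
rank	probability	pathway
1	0.8102	S100A11 -> RAGE -> P38 -> MAPK -> Microtubule-associated protein -> Spindle protein -> Centromere protein -> Cell proliferation
2	0.8068	RASEF -> MAPK -> Microtubule-associated protein -> ...
```

`--example` loads the packaged reconstruction of the p42.3 reference
network with the published overall similarities as priors: the
S100A11-rooted all-activating chain wins with probability equal to its
prior, 0.8102. The packaged edge list is an illustrative reconstruction
(the original figure's exact topology is not published) and is a plain TSV
you can edit.

A note on the packaged reference table: the published overall-similarity
column does not equal the dot product of its own printed per-parameter rows
with the published weights (the top row recomputes to ≈0.8328 against the
printed 0.8102). `shellsim` ships the table verbatim, recomputes scores from
the formula, and documents the discrepancy; the recomputed ranking preserves
the published rank-1 protein.

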