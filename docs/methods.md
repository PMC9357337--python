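# Methods

## Model and assumptions

`pathko` treats a curated pathway as a typed directed multigraph over
three entity classes — genes (leaves carrying experimental expression
status), complexes and abstracts — and four interaction kinds. The Boolean
semantics (AND over components, OR over members, a signed
activator/inhibitor balance gating complexes and abstracts) are encoded
exactly as linear constraints over binary activity variables, so the
minimum number of lowly expressed genes needed to sustain a forced-active
entity is obtained by exact integer programming rather than by
enumerating Boolean states, whose cost grows exponentially with pathway
size.

Key modelling assumptions, inherited from the constraint-based framing:

- Every complex and abstract is treated as equally indispensable: each
  one in turn is forced active and screened. No weighting between actives
  is attempted.
- The balance constraint is one-sided: an inhibitory balance
  (`F_i < w`) forces a node off, while an activating balance merely
  *permits* activation. A node with active activators may still rest at 0
  if nothing else requires it; since the objective only counts lowly
  expressed genes, optimal solutions switch entities off wherever the
  constraints allow.
- Balance constraints apply only to complexes and abstracts. Genes are
  network entries; their global regulation is not captured by individual
  pathways, so activation/inhibition edges onto gene-class children impose
  no constraint.
- Genes appearing in a pathway but missing from the expression profile
  count as expressed: they cost nothing in the objective and remain
  knockout candidates. Lowly expressed genes are never knocked out
  (essential genes are sought among the expressed).
- Pathways are screened independently; a gene present in several
  pathways is knocked out separately in each.
- Cycles are admissible. The encoding is declarative, so a positive
  feedback loop can self-sustain; the problem builder logs detected
  cycles at debug level. The synthetic generator produces layered acyclic
  networks by default so that planted ground truth stays unambiguous, with
  an opt-in flag adding feedback edges for solver stress tests.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `big_m` | 1000 | big-M constant of the balance switch; validated at build time to exceed the maximum parent count + 1, so it never binds spuriously (unitless) |
| `w` | 0.51 | activation weight; any value in (0.5, 1] is semantically identical because the balance is integer-valued — activation needs strictly more active activators than inhibitors; exposed for sensitivity checks |
| `brute_force_cap` | 20 entities | upper size bound for the enumeration oracle (2^n states) |
| ECS `denominator` | `predicted` | divide by Σ\|Ā_p\| (actives with ≥ 1 essentiality prediction). The literal form Σ\|A_p\| (all screened actives) is available as `"literal"`; the default is the one under which "essential in 100 % of predictions" yields exactly ECS = 1 even when some actives produced no predictions |
| ECS `actives_mode` | `all_genes` | an active counts as predicted if *any* gene's knockout was essential for it; `per_gene` restricts to the scored gene's own calls |
| score threshold | −0.5 | ground-truth rule for external dependency scores (lower = more essential) |
| location test | Welch | two-sample test behind the benchmark p-value; a rank-sum alternative is exposed (`test="ranksum"`) since the choice is conventional |
| multiplicity adjustment | Benjamini–Hochberg | for the per-gene enrichment p-values; the standard field default |

## Numerical choices and degenerate inputs

- **Solver.** `scipy.optimize.milp` (HiGHS branch-and-cut) solves each
  instance exactly; only the objective value is contract-stable, the
  reported assignment is one optimum among possibly many. The balance
  variables `F_i` are explicit integer variables defined by equality
  constraints, bounded by `[−|I_i|, |J_i|]`.
- **Infeasibility is first-class.** Knocking out the only component of a
  forced-active complex makes the instance infeasible; this is mapped to
  an infinite knockout objective (the active cannot be sustained at any
  cost), which strictly exceeds every finite wild type and yields an
  essential call. Conversely, an active whose *wild-type* instance is
  infeasible (e.g. only inhibitor parents) is skipped without emitting
  calls: no knockout can be blamed for an entity unreachable even
  unconstrained. Infinite objectives serialise as the token `Inf`.
- **Single-parent degeneracies.** With one component parent the AND pair
  collapses to `E_child = E_parent`; with one member parent likewise.
  These fall out of the general constraints and are covered by tests.
- **Ties.** Alternative optima are irrelevant downstream (only objective
  values are compared); no tie-breaking is imposed.
- **Canonical serialisation.** Written pathway files sort entity lines
  then interaction lines lexicographically, so topologically identical
  networks serialise byte-identically and pipeline outputs are
  reproducible byte-for-byte.
- **Undefined metrics.** When a benchmark prediction group is empty the
  delta-score and p-value are reported as NaN; precision is NaN when
  nothing was predicted essential; MCC of a degenerate confusion matrix
  follows scikit-learn's convention (0).

## Synthetic data: what it emulates and what it does not

The generator emits layered networks (genes → complexes → abstracts;
complexes drawing 2–4 component parents, abstracts drawing
member/activation/inhibition parents with configurable probabilities),
binary profiles with each gene expressed independently (default expressed
fraction 0.7, typical of binarised bulk expression over pathway genes),
and pseudo dependency score tables in which essential (gene, sample)
pairs are centred at −1.0 and non-essential at 0.0 with configurable
noise, so the conventional −0.5 cutoff separates the groups exactly at
zero noise. Generation is a pure function of the spec (integer-state RNG).

`plant_essential(k)` constructs ground truth analytically: a planted
expressed gene is the sole component of one activation route to an
abstract whose only alternative route requires exactly *k* lowly
expressed genes (plus an expressed decoy whose knockout is provably
harmless), so the knockout delta for the planted gene is exactly *k*.
Every planted delta is re-verified with the enumeration oracle before
use.

These fixtures exercise the mathematics, not the biology: they do not
mimic curated-pathway degree distributions, co-expression structure, or
the error modes of real discretisation. Passing tests therefore
demonstrate correctness of the encoding, the screen and the scores —
not predictive performance on real expression data, which additionally
depends on the quality of the pathway collection and the binarisation
strategy.

## Problem sizes used in the test and acceptance suites

The oracle-equivalence suite compares the ILP against exhaustive
enumeration on 200 seeded networks of ≤ 12 entities (every active ×
knockout instance, several thousand solves); screening suites use 5–10
gene networks with 2–3 complexes and 2 abstracts over a handful of
samples. These sizes make every expected value independently computable
by brute force while exercising all constraint families; the ILP itself
scales to far larger pathways.

## Known limitations

- Single knockouts only; no synthetic-lethal pairs.
- The binary expression input pushes all discretisation uncertainty
  upstream; continuous matrices are rejected rather than auto-thresholded
  (a plain cutoff utility is provided but never applied implicitly).
- All actives are weighted equally; biological prioritisation of
  processes is out of scope.
- The balance constraint ignores edge multiplicities and regulator
  strength: activators and inhibitors vote with unit weight.
- `member`/`component` semantics follow the pathway-tab reading used
  here; formats with richer edge types (BioPAX, SBML) are not parsed.
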