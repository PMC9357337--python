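# pathko

Context-specific **gene essentiality prediction** on multisystem pathway
networks by integer linear programming.

Given (i) a collection of curated pathways — genes, protein complexes and
biological abstracts connected by `component`, `member`, `activation` and
`inhibition` edges, in UCSC Pathway Tab Format — and (ii) a **binarized**
gene-expression profile for a sample (1 = expressed, 0 = lowly expressed),
`pathko` asks: *how many lowly expressed genes would the cell have to
switch on to keep each indispensable entity running, and which single-gene
knockouts force that number up?* Genes whose in-silico knockout strictly
increases the minimum are predicted **essential for that sample**. It is
aimed at computational biologists studying condition-specific
vulnerabilities (e.g. candidate drug targets essential in tumour samples
but not in matched healthy tissue).

## The model

Each entity *i* carries a binary activity variable `E_i`. Writing `B^i`
for the parents of *i* under one edge kind and `N^i = |B^i|`:

- **component (AND)** — `E_i ≥ Σ_b E_b − (N^i − 1)` and
  `N^i·E_i ≤ Σ_b E_b`: a complex is active iff *all* components are.
- **member (OR)** — `N^i·E_i ≥ Σ_b E_b` and `E_i ≤ Σ_b E_b`: a family is
  active iff *any* member is.
- **activation/inhibition balance** — with activators `J_i`, inhibitors
  `I_i`, an integer `F_i = Σ_{J_i} E_b − Σ_{I_i} E_b` and the big-M switch
  `M·(E_i − 1) ≤ F_i − w` (`M = 1000`, `w = 0.51`): activation requires a
  strict majority of active activators; it is necessary, not sufficient.
  Imposed only on complexes and abstracts.

For every **active** `a` (each complex and abstract, a proxy for a process
the cell must sustain) one instance fixes `E_a = 1` and solves

```
S_a^wild = min Σ_{i ∈ L} E_i
```

where `L` is the sample's lowly expressed gene set. Re-solving with
`E_g = 0` for each expressed gene `g` gives `S_a^g`; the gene is called
essential for `(p, a)` when `S_a^g > S_a^wild` (`C_{g,p,a} = 1`). Calls
aggregate by maximum over actives and pathways (`C_{g,p}`, `C_g`), and the
continuous **Essentiality Congruity Score**

```
ECS_g = Σ_p Σ_{a ∈ Ā_p} C_{g,p,a}  /  Σ_p |Ā_p|   ∈ [0, 1]
```

(`Ā_p` = actives of pathway *p* with at least one essentiality
prediction) expresses what fraction of a gene's predictions were
essential, taming the false-positive sensitivity of the plain maximum.
Solving is exact (HiGHS branch-and-cut via `scipy.optimize.milp`); an
exhaustive Boolean enumeration oracle cross-checks every small instance.

## Worked example

```bash
python examples/toy_knockout.py
```

```
scenario C: expressed=['FZD1', 'FZD7', 'WNT5A'] lowly=['WNT3A']
  wild-type minimum S_wild = 0
  knockout FZD1: S = 0  -> not essential
  knockout FZD7: S = 1  -> ESSENTIAL
  knockout WNT5A: S = 1  -> ESSENTIAL
```

In the Wnt toy pathway two receptor complexes (WNT5A/FZD7, WNT3A/FZD1)
each suffice to activate the signalling abstract. In scenario C the
expressed route runs through WNT5A/FZD7; the wild type needs no lowly
expressed gene (`S_wild = 0`), but knocking out FZD7 forces the cell onto
the other route, which needs the lowly expressed WNT3A (`S = 1`) — so
FZD7 is essential. In scenario A (both WNT ligands lowly expressed)
`S_wild = 1` already and no single knockout raises it further.

Further examples: `examples/ecs_pipeline.py` (multi-pathway screen + ECS
table) and `examples/benchmark_scores.py` (delta-score/MCC/precision
benchmark against pseudo dependency scores, ECS threshold sweep,
case-control enrichment). A thin CLI wraps the same pipeline:

```bash
pathko simulate -o fixture --seed 1 --n-genes 10 --n-complexes 2
pathko run -p fixture/pathways -e fixture/expression.tsv -o out
pathko validate -p fixture/pathways -e fixture/expression.tsv \
    -s fixture/scores.csv -o val --grid 0,0.25,0.5
```

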