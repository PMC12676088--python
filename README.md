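# bipnull

Maximum-entropy null-model analysis of bipartite ecological association
networks — built for plant × arbuscular-mycorrhizal-fungus (AMF) incidence
matrices, applicable to any binary bipartite network.

## The problem

Given a binary incidence matrix **A** (rows: plant species, populations or
samples; columns: fungal taxa — species, OTUs or virtual taxa; `a_ij = 1`
when an association was observed), ecologists ask whether the network is
**nested** (specialists interact with subsets of the partners of
generalists) or **modular** (groups of plants and fungi associate mostly
within their group), *beyond what the degree sequence alone explains*.
Classic null models answer this by rewiring the observed links under hard
marginal constraints. `bipnull` instead uses the **bipartite binary
configuration model (BiCM)**: the maximum-entropy probability distribution
over matrices whose *expected* degree sequence equals the observed one — a
soft constraint that lets every node's degree fluctuate across the
ensemble, as real ecological data do.

The BiCM factorizes over entries, with connection probabilities

```
p_ij = x_i y_j / (1 + x_i y_j)
```

where `x_i` and `y_j` are one positive Lagrange multiplier per plant row
and fungal column, fitted so that row/column sums of `p` reproduce the
observed degrees `k_i` and `d_j` (equivalently, maximizing the Bernoulli
log-likelihood of **A**). Sampling each entry independently as
Bernoulli(`p_ij`) yields the null ensemble (999 matrices by default).
Structure is then scored by

* **NODF** nestedness (nested overlap and decreasing fill, 0–100), and
* **Barber bipartite modularity** `Q = (1/E) Σ_ij (a_ij − k_i d_j/E) δ(g_i, h_j)`,
  maximized over partitions by a seeded label-propagation + module-merge
  search,

and each observed metric is compared with its null distribution via
`z = (observed − null mean) / null SD` and add-one empirical tail
p-values. Negative NODF z with small lower-tail p ⇒ **anti-nested**;
positive Q z with small upper-tail p ⇒ **modular**.

## Worked example

```sh
bipnull simulate --generator modular --rows 20 --cols 32 --modules 4 \
    --p-in 0.6 --p-out 0.05 --seed 7 --out demo.csv
bipnull analyze --input demo.csv --nulls 999 --seed 42 --out demo_report.json
```

prints

```
wrote 20x32 matrix (121 links) to demo.csv
demo: NODF z=-1.99 (anti-nested), Q z=+5.68 (modular); fit residual 4.90e-09
```

The simulated matrix has four planted plant–fungus modules. The analysis
fits the BiCM (the residual is the largest gap between expected and
observed degrees — here ~5e-9, i.e. the soft constraint holds to solver
tolerance), draws 999 null matrices, and finds the observed modularity
(Q = 0.498) far above the null ensemble (0.359 ± 0.024, z = +5.68,
p = 0.001): the network is called **modular**. Observed nestedness
(NODF = 18.5) falls below the null mean (24.0 ± 2.7, z = −1.99,
p_lower = 0.018): **anti-nested**. Planted modular structure showing up as
joint modularity + anti-nestedness is exactly the signature this pipeline
is designed to detect.

The same analysis is available as a library call:

```python
import bipnull as bp

inc = bp.read_incidence("demo.csv", binarize=True)
inc, removed = bp.drop_empty_nodes(inc)
report = bp.analyze_network(inc, n_null=999, seed=42)
print(report.verdicts)           # {'nestedness': 'anti-nested', 'modularity': 'modular'}
```

Other CLI subcommands: `fit` (probability matrix + fit report), `metrics`
(NODF and Q for one matrix), `batch` (a manifest of datasets → per-dataset
JSON reports and a summary CSV).

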