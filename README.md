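# contrastnet

Contrast-subgraph mining for comparing weighted biological networks.

Biological comparisons often come down to two networks over the same
genes or proteins: coexpression networks of two cancer subtypes, mRNA-
vs protein-level coexpression, or protein–protein interaction maps from
different cell lines. `contrastnet` finds the node sets that are
densely connected in one network and sparse in the other — the modules
whose wiring, not just expression, differs between conditions — and
supplies the surrounding workflow: WGCNA-style coexpression network
construction, degree/overlap statistics, and gene-set enrichment.

## The method in brief

For networks A and B over shared nodes, with induced edge-weight sums
e_A(S) and e_B(S), the contrast subgraph maximises the density of the
signed difference graph:

    f(S) = (e_A(S) − e_B(S)) / |S|

Because difference weights can be negative this densest-subgraph
variant is NP-hard, so mining uses generalised greedy peeling: remove
the node minimising C·deg⁺(v) + deg⁻(v), keep every intermediate set as
a candidate, return the densest candidate, and sweep a small grid of C
values. At C = 1 the result is guaranteed to reach at least
ρ*/2 − Δ/2, with ρ* the exact optimum and Δ the largest absolute
negative degree. Top-k mining repeats the sweep after zeroing each
result's within-set edges. Coexpression networks are built as
complete weighted graphs with w = (0.5·(1 + ρ))^12 from Spearman
correlation or ρ-proportionality (clr-based, for compositional data).
See `docs/methods.md` for the full account.

## Worked example

Plant a 20-node module that is densely wired (p = 0.9) in condition A
and background-sparse (p = 0.05) in condition B, on 200 nodes, then
mine and test it:

```python
from contrastnet import (
    PeelParams, PlantedGraphSpec, degree_distribution_test,
    planted_contrast_pair, recovery_score, top_k_contrast,
)

spec = PlantedGraphSpec(n_nodes=200, module=20, p_in_a=0.9,
                        p_in_b=0.05, p_background=0.05, seed=7)
net_a, net_b, module = planted_contrast_pair(spec)

results = top_k_contrast(net_a, net_b, PeelParams(k=2))
for r in results:
    print(r.rank, r.c_value, round(r.objective, 3), r.size)
print("recovery", recovery_score(results[0], module))

da, db, u, p = degree_distribution_test(results[0].node_set, net_a, net_b)
print(f"U={u:.1f} p={p:.3g}  mean degree A {da.mean():.2f}  B {db.mean():.2f}")
```

Output:

```
1 0.25 8.05 20
2 1.0 2.518 56
recovery 1.0
U=400.0 p=4.89e-08  mean degree A 17.20  B 1.10
```

The rank-1 subgraph is exactly the planted module (Jaccard recovery
1.0) with contrast density 8.05 — on average each of its 20 nodes gains
~16 units of within-set edge weight in A relative to B (its members
average 17.2 within-set neighbours in A versus 1.1 in B, a difference
the Mann–Whitney test resolves at p ≈ 5·10⁻⁸). The rank-2 set is
residual background noise with a much weaker objective (2.5), the usual
signature of an exhausted signal.

The same workflow runs from the shell: `contrastnet build-net`,
`contrast`, `compare`, `enrich`, `simulate`, and `pipeline`
(YAML-configured end-to-end run); see `contrastnet --help`.

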