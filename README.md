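# netattack

Simulation framework for studying how **imperfect network observation degrades
targeted attack and immunization strategies**.

Network attack strategies pick a small set of nodes whose removal fragments a
network — the same computation that, run constructively, tells an
epidemiologist whom to vaccinate first. Nearly all such strategies assume the
attacker knows the full graph. In practice the observed network `G′` differs
from the true network `G`: inferred gene or contact networks carry **link
errors** (a fraction δ of true links missing, a fraction α of spurious links
added), and very large networks are known only through **node sampling** (a
crawl covering a fraction p_s of nodes, with only the links among sampled
nodes visible). This package measures what those observation errors cost: the
attacker ranks nodes on `G′`, but the damage is always evaluated on `G`.

## What is implemented

**Generators** — Barabási–Albert growth (default n = 10,000, m = 2; shifted
linear preferential attachment, attachment probability ∝ degree + 1) and
geometric random graphs (n = 10,000 points uniform on the unit square,
connection radius 0.015), plus readers for GML and SNAP-style edge lists to
analyse real networks.

**Observation models** — link errors: delete `round(|E|·δ)` links uniformly,
then add `round(|E|·α)` false links among non-adjacent pairs; node sampling:
BFS, DFS, SEC (sample edge count: greedily add the frontier node with the
most edges into the current sample) and uniform random (RAND), each followed
by the induced subgraph.

**Attack strategies** —

* `Degree`: static ranking by observed degree;
* `HDA`: high-degree adaptive — recompute degrees after every removal;
* `CI(ℓ)`: collective influence, `CI_ℓ(i) = (k_i − 1) · Σ_{j ∈ ∂Ball(i,ℓ)} (k_j − 1)`
  over the ring of nodes at hop distance exactly ℓ, used adaptively with
  localized rescoring (provably identical to full recomputation).

**Evaluation** — giant-component (GC) fragmentation curves on the true
network versus removal fraction p; Spearman rank correlation between true and
observed node rankings (unobserved nodes tied at the lowest rank); and a
discrete-time SIR epidemic (β = 0.1, γ = 0.01 per step) with an immunized
compartment, scored by the final fraction of never-infected nodes.

**Experiment runner** — seeded factorial grids over (δ, α) or (method, p_s) ×
strategies × replicates, returning tidy long-format tables, with a `netattack`
command-line interface wrapping every stage.

## Worked example

```python
import numpy as np
import netattack as na

g = na.generate_ba(na.BAParams(n=2000, m=2, seed=7))
h = na.apply_link_errors(g, na.ErrorParams(delta=0.3, alpha=0.3, seed=8))

grid = na.default_p_grid()                      # p = 0.00 ... 0.50
for name, make in [("Degree", na.rank_degree),
                   ("CI(l=2)", lambda x, seed: na.attack_order_ci(x, l=2, seed=seed))]:
    a_true = na.curve_area(grid, na.gc_curve(g, make(g, seed=9), grid))
    a_obs = na.curve_area(grid, na.gc_curve(g, make(h, seed=9), grid))
    print(f"GC-curve area, {name} attack: complete info {a_true:.3f}, noisy info {a_obs:.3f}")

sir = na.immunization_curve(g, na.rank_degree(h, seed=9), [0.0, 0.1, 0.2],
                            na.SIRParams(beta=0.1, gamma=0.01),
                            n_runs=200, rng=np.random.default_rng(10))
print("mean non-infected fraction at p=0, 0.1, 0.2:", np.round(sir, 3))
```

prints

```
GC-curve area, Degree attack: complete info 0.128, noisy info 0.183
GC-curve area, CI(l=2) attack: complete info 0.115, noisy info 0.180
mean non-infected fraction at p=0, 0.1, 0.2: [0.038 0.402 0.845]
```

The area under the GC curve summarises attack quality (smaller = the network
fragments sooner). With complete information CI(ℓ=2) beats Degree
(0.115 < 0.128); with 30% link noise both collapse to roughly the same
effectiveness (0.180 vs 0.183) — the state-of-the-art strategy loses its edge
exactly because its ranking is more sensitive to link errors. The SIR numbers
show immunizing the top 10% / 20% of degree-ranked nodes (chosen from the
*noisy* network) raises the protected fraction from 4% to 40% and 85%.

The same pipeline is available from the shell:

```bash
netattack generate --network ba --n 2000 --seed 7 --out g.txt
netattack perturb --delta 0.3 --alpha 0.3 --seed 8 --in g.txt --out gobs.txt
netattack attack --strategy ci --l 2 --seed 9 --in gobs.txt --out order.csv
netattack gc-curve --true g.txt --order order.csv --out curve.csv
```

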