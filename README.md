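# synclust

Stochastic spatial modelling of nuclear clustering in the human placental
syncytiotrophoblast, together with the morphometric rules used to quantify
syncytial nuclear aggregates (SNAs) and syncytial nuclear clusters (SNCs)
in tissue and culture.

The syncytiotrophoblast is the multinucleated epithelium covering placental
villi; its nuclei aggregate into SNAs whose prominence is associated with
pregnancy disorders. `synclust` is aimed at quantitative placental biologists
who want to (a) simulate hypotheses about what drives nuclear aggregation
(nuclear adhesiveness, nuclear movement, preferential cytotrophoblast fusion
sites, syncytium thickness variation) and (b) apply consistent, scripted
definitions of SNAs/SNCs and related morphometrics to nuclear centroid data.

## The model

Nuclei are unit-diameter discs performing overdamped interacting Brownian
motion in a 2D strip of length *L* = 250 and mean thickness *T* = 1.5
nuclear diameters (140 nuclei, matching a 29.4% areal nuclear density).
Each nucleus obeys the Euler–Maruyama update

    dx_i = F_i dt + sqrt(2 D dt) xi_i,     xi_i ~ N(0, I)

where *F_i* sums pairwise forces from a contact potential *V(x)* and
harmonic wall repulsion. With centre separation *x* in diameters:

    V(x) = k_rep (1 - x)^2 - S          x < 1         (overlap: strong repulsion)
    V(x) = -S (1 - (x-1)/R)^2           1 <= x <= 1+R  (adhesive shell, depth S)
    V(x) = 0                            x > 1+R        (no interaction)

with shell width *R* = 0.05. The upper membrane is corrugated: a stationary
Ornstein–Uhlenbeck process (sd 0.25 diameters, confining the variation to
±0.75 diameters with 99.7% confidence) sampled at regular knots,
cubic-spline interpolated, and scaled by an amplitude *A*. Entry positions
of nuclei can be uniform or drawn from Normal(*L*/2, σ²) — preferential
fusion sites. At the end of a run, nuclei within distance 1+*R* are
"connected"; clusters are connected components of that graph, and the
headline statistic is the mass-weighted mean cluster size Σ size²/N — the
expected size of the cluster containing a randomly chosen nucleus.

Four replicated scenario sweeps probe the drivers of clustering: stickiness
*S*; diffusion *D* (with *S/D* held constant); fusion-site spread σ; and
boundary amplitude *A*.

Morphometry (micron units) implements the measurement rules: edge-to-edge
nearest-neighbour internuclear distance; SNC = ≥6 nuclei with gaps ≤3 μm;
SNA = ≥10 nuclei; large syncytium = ≥6 nuclei with cytoplasmic area per
nucleus from the cell-boundary polygon; shed-particle census at the
80 μm² threshold.

## Worked example

```python
import numpy as np
from synclust import SimParams, run_simulation
from synclust.clustering import cluster_census, mean_cluster_size_per_nucleus

result = run_simulation(SimParams(seed=1))
for t, snap in zip(result.snapshot_times, result.snapshots):
    print(f"t={t:5.1f}  mean cluster size/nucleus={mean_cluster_size_per_nucleus(snap):5.2f}"
          f"  clusters(>=2)={cluster_census(snap, 2)}")
```

prints

```
t=  0.0  mean cluster size/nucleus= 1.07  clusters(>=2)=5
t= 10.0  mean cluster size/nucleus= 2.20  clusters(>=2)=35
t= 20.0  mean cluster size/nucleus= 2.14  clusters(>=2)=34
t= 30.0  mean cluster size/nucleus= 1.93  clusters(>=2)=34
t= 40.0  mean cluster size/nucleus= 2.03  clusters(>=2)=37
t= 50.0  mean cluster size/nucleus= 2.13  clusters(>=2)=36
```

i.e. from a non-overlapping random start, adhesion (S = 1, D = 0.2) builds
the nuclei into ~35 multi-nucleus clusters within ten time units, after
which cluster mass fluctuates around its steady level: a randomly chosen
nucleus then sits in a cluster of about two.

The same workflow is available from the shell:

```bash
synclust simulate run.yaml --out trajectory.csv
synclust sweep run.yaml --out sweep.csv --plot fig5a.png
synclust generate run.yaml --out-dir synthetic/
synclust analyze run.yaml --out morphometry.csv
synclust render run.yaml --out snapshot.png
```

where `run.yaml` is a validated configuration (see `synclust.config`; an
empty file gives the default parameters above).

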