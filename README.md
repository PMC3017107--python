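# wormdev

Spatio-temporal analysis of a developing neuronal network, built around the
*C. elegans* hermaphrodite nervous system: 279 neurons with known 3D soma
positions, birth times from the cell lineage, and adult connectivity
(gap junctions and chemical synapses).

The package is for computational neuroscientists and systems biologists who
want to ask *when* the wiring of a connectome could have been established:
which connected neuron pairs are born close together in time, whether hubs
are early-born, whether long-distance connections are laid down before the
body grows, and whether each observation survives comparison with proper
null models.

## What it computes

Given a neuron table (id, 2D position, left/right/midline side, birth time,
type, region, circuits) and an edge table (pre, post, synapse kind), the
pipeline:

1. lifts 2D soma positions onto a cylindrical body model of radius
   *r* = 50 µm: *x* = AP position, *y* = DV position,
   *|z|* = √(*r*² − *y*²), left positive / right negative / midline zero;
2. builds **staged networks**: at time *t* the network contains the neurons
   with birth time ≤ *t*, and a *connection-pair* is present once both
   neurons of an adult link are born (no claim about synaptogenesis);
3. quantifies **temporal features** — birth-time differences of connected
   neurons, within-phase wiring fractions for the embryonic and
   post-embryonic bursts, the Pearson correlation of degree with birth
   time, hub reports at degree thresholds 20/30/60, late-forming
   neighbours, bilateral-pair timing, and per-type growth curves;
4. quantifies **spatial features** — soma-to-soma Euclidean connection
   lengths split into ten 0.12 mm bins (short < 0.36 mm, long ≥ 0.84 mm),
   appearance curves per length class and per functional circuit,
   synapse-kind × length × early/late contingency tables, and region
   connectivity;
5. computes **small-world indices** per stage — clustering coefficient *C*
   and characteristic path length *L* on the symmetrized graph, with
   *C*/*C*<sub>rand</sub> and *L*/*L*<sub>rand</sub> against Erdős–Rényi
   G(*n*, *m*) baselines;
6. compares every comparable scalar with an **identity-shuffle null**: the
   graph stays fixed while the bundles of (position, birth time,
   annotations) are permuted across nodes — degree sequence exactly
   preserved — over an ensemble of twenty shuffles, summarized by a
   one-sample t-test *t* = (obs − mean)/(sd/√*n*), df = *n* − 1.

A seeded synthetic generator produces connectomes with the same gross
structure (two birth bursts, axial head/body/tail clustering, mirrored
bilateral pairs, distance-decaying connectivity) plus *planted* effects —
an early-birth hub bias and an early long-range bias — so the whole
pipeline is validated by parameter recovery.

## Worked example

```python
from wormdev import (GeneratorConfig, generate_connectome,
                     degree_birth_correlation, ensemble, one_sample_ttest)
from wormdev.metrics import prehatch_pct_long

connectome, truth = generate_connectome(GeneratorConfig(seed=1))
print(connectome.n_neurons, connectome.n_connections)
# 279 2990

print(round(degree_birth_correlation(connectome), 3))
# -0.685        <- early-born neurons are the highly connected ones

obs = prehatch_pct_long(connectome)
ens = ensemble("prehatch_pct_long", connectome, n_trials=20, seed=2)
t, p = one_sample_ttest(obs, ens)
print(round(obs, 1), round(ens.mean, 1), round(ens.sd, 1), round(t, 1))
# 90.8 52.5 2.2 76.4
```

Reading: 90.8% of long-range connection-pairs have both neurons born before
hatching (840 min), while identity-shuffled networks average 52.5% ± 2.2 —
the planted early-long-range effect is recovered far outside the null
(t = 76.4, p ≪ 0.001). The negative degree–birth correlation recovers the
planted hub effect.

The same run from the shell:

```sh
wormdev synth --out data/ --seed 1
wormdev run --config cfg.yaml        # full report: CSV tables + report.json
wormdev null --neurons data/neurons.csv --edges data/edges.csv \
             --metric prehatch_pct_long
```

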