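# Methods

## Scope and data model

The package analyses a developing neuronal network reconstructed from three
ingredients: adult connectivity (typed links between named neurons), birth
times from the cell lineage, and 2D soma positions lifted onto a simple body
model. Everything downstream — staged networks, timing statistics, wiring
length classes, null ensembles — consumes one validated `Connectome` object:
a neuron table keyed by id plus a link list with no self-loops and no
duplicate pairs.

Links are stored once each. A gap junction or combination junction is
inherently bidirectional; chemical synapses may be uni- or bidirectional.
Degree counts incoming plus outgoing arcs, so a bidirectional link
contributes 2 to each endpoint and a unidirectional link contributes 1 to
each (out to the presynaptic, in to the postsynaptic neuron). The handshake
identity (sum of degrees = 2 × arcs) is enforced by tests.

Reference scale throughout is the *C. elegans* hermaphrodite assembly this
kind of analysis is performed on: 279 neurons and 2,990 links (1,584
unidirectional + 1,406 bidirectional; 672 gap junctions, 1,962 chemical
synapses, 376 combination junctions), after excluding the neuro-muscular-only
neuron VC6 and three self-loops.

## Coordinate lifting

The body is a cylinder of radius r = 0.05 mm (50 µm), constant along the
anterior-posterior axis; all lengths are stored in millimetres because the
length-class thresholds are most naturally stated in mm. Given a 2D soma
position (AP, DV), the lateral coordinate is the circular cross-section

    x = AP,  y = DV,  |z| = sqrt(r^2 - DV^2)

which is the unique form with the right boundary behaviour: z = 0 on the
dorsal and ventral midlines (|DV| = r) and |z| = r at the equator. Side
breaks the sign symmetry: left positive, right negative (an arbitrary but
fixed convention), midline forced to z = 0. Digitized positions may
overshoot the idealized cylinder, so |DV| exceeding r is clamped to the
surface; an excess beyond 1e-6 mm logs a warning, smaller excess is clamped
silently.

## Staging and connection-pairs

The network at developmental time t contains the neurons with
birth_time <= t (inclusive cutoff, so the pre-hatching stage holds every
embryonically born neuron) and a link iff both endpoints are present. This
is the *connection-pair* reading: a pair connected in the adult counts as
"present" once both neurons are born, which says nothing about when the
synapse actually forms. Default stage times are 350, 400, 500, 800, 2000
and 2700 minutes post-fertilization; hatching is at ~840 minutes and
divides births into embryonic and post-embryonic phases. Staging is
monotone by construction (tested as a property).

## Temporal statistics

- **Birth-time differences**: one value |birth(pre) − birth(post)| per
  link. Histograms use equal-width bins over [0, max] with per-bin means;
  empty bins report a missing mean, never 0.
- **Phase fractions**: with phases split at hatching, the embryonic
  fraction is endpoint-weighted — over all link endpoints belonging to
  embryonic neurons, the share whose partner is also embryonic (each
  within-phase link contributes two endpoints, each crossing link one).
  This matches the reading "embryonic neurons make X% of *their*
  connections within the phase". A simpler link-level variant
  (within-links / links touching the phase) is available behind
  `endpoint_weighted=False`. Region connectivity uses the same
  endpoint-weighted convention for internal consistency.
- **Hubs**: reports at a degree threshold take an explicit comparator
  (>= or >) rather than a hidden convention, because prose thresholds mix
  "20 or more" with "more than 30". "Late-forming neighbour" means a
  connected neuron with birth_time >= hatch time.
- **Type growth curves**: cumulative birth percentage per type relative to
  the adult count of that type; polymodal neurons count in every type they
  carry, and an additional exclusive-motor curve covers neurons that are
  motor and nothing else.

## Spatial statistics

Connection length is the Euclidean soma-to-soma distance in 3D — not the
axon path, not the synapse position. Lengths fall into ten 0.12 mm bins:
the first three short (< 0.36 mm), the last three long, the middle four
medium. Bins are half-open [lo, hi), so exactly 0.84 mm is long (the prose
"longer than 0.84" leaves the boundary ambiguous; this choice is fixed and
tested). Lengths beyond the last bin are still long — the classifier is
total, which matters for synthetic data.

Appearance curves give, per length class (and per functional circuit), the
percentage of that class's adult pairs present at each stage; lengths are
always computed from adult positions. A connection-pair spanning two
circuits belongs to both. The synapse breakdown is a full contingency table
over kind × length class × early/late, where "early" means both endpoints
born before hatching; "electrically coupled" aggregates gap plus
combination junctions.

## Null models

- **Identity shuffle**: the graph (and hence the degree sequence, synapse
  kinds, directedness) stays fixed; the identity bundles — 3D and 2D
  position, side, birth time, region, type, circuits — are permuted across
  nodes as wholes, preserving the coupling between a neuron's position and
  its birth time. Bilateral-partner references are remapped through the
  same permutation so the annotation stays symmetric. Ensembles default to
  twenty trials; trial seeds derive from the master seed via
  `numpy.random.SeedSequence(master, spawn_key=(trial,))`, giving
  reproducible, well-separated streams.
- **Erdős–Rényi G(n, m)**: exactly m distinct unordered pairs chosen
  uniformly; used only as the baseline for topology metrics, matched on
  node and link counts.
- **t-test**: observed scalars are compared to an ensemble by a one-sample
  t-test of the trials against the observed value,
  t = (obs − mean)/(sd/√n) with df = n − 1, sd with the n−1 denominator.
  Exact p values are returned (two- or one-sided); thresholding is left to
  the caller. A zero-sd ensemble raises instead of returning p = 0. The
  alternative orientation (testing the observed value as the sample) is
  algebraically identical in |t|.

## Topology metrics

Clustering coefficient C and characteristic path length L follow the
Watts–Strogatz formulation on the symmetrized simple graph (an undirected
edge wherever any arc exists); a directed variant is out of scope. Nodes of
degree < 2 contribute 0 to C and stay in the average — one of the two
common conventions, fixed here because it changes C. Early-stage networks
can be disconnected, so L is computed within the largest connected
component and the component coverage is reported alongside. Both metrics
are verified against brute-force oracles (O(n³) triple enumeration;
Floyd–Warshall) on exhaustive small graphs.

## Synthetic generator

The generator emulates the gross structure the analyses assume, with known
planted effects for recovery testing. Defaults, chosen once to match the
reference scale: 279 neurons, 2,990 links; embryonic birth window
(350, 750) min and post-embryonic (840, 2700) min with 70% of neurons
embryonic (≈ the real pre-hatching share); head/body/tail axial clusters
weighted 0.55/0.25/0.20 on a 1.2 mm body (head = anterior 20%, tail =
posterior 15%); 60% of neurons in mirrored left/right pairs born ≤ 10 min
apart; synapse kinds at the real proportions (gap 672/2990, combination
376/2990, remainder chemical).

Connection sampling: pair (i, j) gets weight

    w_ij = exp(-d_ij / λ) · exp(β_hub · e_i · e_j)  [+ β_long · w̄ if long & both embryonic]

with λ = 0.25 mm distance decay, earliness e = (latest − birth)/(latest −
earliest) in [0, 1], w̄ the mean baseline weight, and "long" the
classifier's ≥ 0.84 mm threshold. Exactly `n_connections` links are drawn
without replacement with probability proportional to w, so the edge count
is exact. Defaults β_hub = 2.0 and β_long = 1.0 plant effects strong
enough for robust sign recovery; setting either to 0 removes that effect
cleanly (tested). The drawn coefficients, per-neuron earliness and per-pair
length class at generation are recorded as ground truth and never touched
by analyses.

What the generator does **not** emulate: the real degree distribution's
exact shape (hub counts are larger than real at the default bias), lineage
structure, neuron-class anatomy, synapse multiplicity, pruning, or any
growth mechanism. Passing recovery tests therefore shows the *pipeline*
measures what it claims; it does not validate biological conclusions about
real data.

## Problem sizes and numerical choices

Recovery tests run at 200 neurons / 2,000 links over 20 seeds with
20-trial ensembles; oracle equivalence runs on 100 random graphs of up to
15 nodes; t-test calibration uses 1,000 replicates of 20-trial ensembles.
These sizes give stable statistics while keeping the full suite fast.
Floating-point conventions: the cylinder round-trip y² + z² = r² is checked
to 1e-9 mm; classifier boundaries are exact comparisons on the derived
thresholds; report JSON is written with sorted keys so identical
configurations produce byte-identical reports.

## Known limitations

- Connection lengths are soma-to-soma; real wiring length along axon
  trajectories can differ substantially, especially for midline-crossing
  and fasciculated processes.
- Staging assumes adult connectivity projected backwards ("earliest
  possible" networks); pruning and transient connectivity are ignored.
- The identity shuffle preserves degree sequence but not spatial
  autocorrelation of attributes; the Erdős–Rényi baseline preserves even
  less. Neither is a degree-preserving rewiring null (Maslov–Sneppen),
  which is deliberately out of scope.
- The report-schema validator covers required keys and primitive types (the
  subset of JSON-schema the shipped document uses), not the full draft
  2020-12 feature set.
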