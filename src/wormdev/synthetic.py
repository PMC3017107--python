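"""Synthetic connectome generator with planted developmental effects.

Emulates the statistical structure of the adult hermaphrodite nervous
system as seen through a developmental lens: 279 neurons born in two
bursts (a brief embryonic burst and a longer post-embryonic one), somata
clustered into head/body/tail along a ~1.2 mm cylindrical body of radius
50 µm, bilateral left/right pairs born within minutes of each other, a
heavy-tailed degree distribution whose hubs are early-born, and an excess
of long-distance connection pairs in which both neurons are embryonic.

The generator makes no claim of biophysical fidelity: its contract is to
plant *recoverable* versions of these effects with known coefficients, so
that the analysis pipeline can be validated by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .config import LengthClassifier, SpatialConfig
from .connectome import Connection, Connectome, Neuron, lift_to_3d


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic connectome.

    Defaults emulate the real network's scale: 279 neurons and 2,990 links,
    embryonic births in (350, 750) minutes and post-embryonic births in
    (840, 2700), about 70% of neurons embryonic, 60% of neurons in
    left/right bilateral pairs born within 10 minutes of each other, and
    synapse kinds split roughly 22% gap / 13% combination / 65% chemical.

    ``hub_early_bias`` multiplies pair connection weights by
    ``exp(bias * earliness_i * earliness_j)`` so early-born neurons become
    hubs; ``long_range_early_bias`` adds weight to pairs beyond the
    long-range threshold when both neurons are embryonic. Both are zero-
    disables-effect coefficients.
    """

    n_neurons: int = 279
    region_weights: tuple[float, float, float] = (0.55, 0.25, 0.20)  # head/body/tail
    body_length: float = 1.2  # mm
    body_radius: float = 0.05  # mm
    embryonic_window: tuple[float, float] = (350.0, 750.0)
    postembryonic_window: tuple[float, float] = (840.0, 2700.0)
    embryonic_fraction: float = 0.7
    bilateral_fraction: float = 0.6
    bilateral_time_jitter: float = 10.0  # minutes
    n_connections: int = 2990
    hub_early_bias: float = 2.0
    long_range_early_bias: float = 1.0
    distance_decay_mm: float = 0.25  # lambda of the exponential baseline
    gap_fraction: float = 672 / 2990
    combination_fraction: float = 376 / 2990
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        for p in (
            self.embryonic_fraction,
            self.bilateral_fraction,
            self.gap_fraction,
            self.combination_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.embryonic_window[1] >= self.postembryonic_window[0]:
            raise ValueError("embryonic window must end before the post-embryonic one")
        max_links = self.n_neurons * (self.n_neurons - 1) // 2
        if not 0 <= self.n_connections <= max_links:
            raise ValueError(
                f"n_connections must be in [0, {max_links}] for {self.n_neurons} neurons"
            )
        if self.hub_early_bias < 0 or self.long_range_early_bias < 0:
            raise ValueError("bias coefficients must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time; never mutated by analyses."""

    hub_early_bias: float
    long_range_early_bias: float
    earliness: dict[str, float]  # per neuron, in [0, 1]
    intended_hubs: list[str]  # top-decile earliness when hub bias is active
    pair_length_class: dict[tuple[str, str], str]  # sampled pairs, at generation

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "hub_early_bias": self.hub_early_bias,
            "long_range_early_bias": self.long_range_early_bias,
            "earliness": self.earliness,
            "intended_hubs": self.intended_hubs,
            "pair_length_class": {
                f"{a}|{b}": c for (a, b), c in self.pair_length_class.items()
            },
        }


def _region_bounds(body_length: float) -> dict[str, tuple[float, float]]:
    # head: anterior 20% of the body axis; tail: posterior 15%; body between
    return {
        "head": (0.0, 0.20 * body_length),
        "body": (0.20 * body_length, 0.85 * body_length),
        "tail": (0.85 * body_length, body_length),
    }


def generate_connectome(config: GeneratorConfig | None = None) -> tuple[Connectome, PlantedTruth]:
    """Draw a synthetic connectome; deterministic given ``config.seed``.

    Positions are drawn in three axial clusters and lifted onto the
    cylinder cross-section; birth times come from the two bursts; bilateral
    pairs are mirrored in z with birth offsets bounded by the jitter.
    Exactly ``n_connections`` distinct links are sampled without
    replacement with probability proportional to
    ``exp(-d/lambda) * exp(hub_bias * e_i * e_j) + long_bias * w0`` (the
    additive term applying to long-range embryonic-embryonic pairs only,
    with ``w0`` the mean baseline weight).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    spatial = SpatialConfig(body_radius=cfg.body_radius)
    classifier = LengthClassifier()
    bounds = _region_bounds(cfg.body_length)

    n = cfg.n_neurons
    n_pairs_bilateral = int(cfg.bilateral_fraction * n / 2)
    n_singletons = n - 2 * n_pairs_bilateral

    regions = rng.choice(
        ["head", "body", "tail"],
        size=n_pairs_bilateral + n_singletons,
        p=np.asarray(cfg.region_weights, dtype=float),
    )
    n_units = n_pairs_bilateral + n_singletons
    n_embryonic_units = int(round(cfg.embryonic_fraction * n_units))
    embryonic = np.zeros(n_units, dtype=bool)
    embryonic[rng.choice(n_units, size=n_embryonic_units, replace=False)] = True

    neurons: list[Neuron] = []
    for u in range(n_units):
        lo, hi = bounds[regions[u]]
        ap = rng.uniform(lo, hi)
        dv = rng.uniform(-cfg.body_radius, cfg.body_radius)
        window = cfg.embryonic_window if embryonic[u] else cfg.postembryonic_window
        birth = rng.uniform(*window)
        if u < n_pairs_bilateral:
            # mirror-image left/right pair, nearly simultaneous births
            offset = rng.uniform(0.0, cfg.bilateral_time_jitter)
            birth2 = min(birth + offset, window[1])  # |delta| <= jitter, in-window
            left_id, right_id = f"SN{u:03d}L", f"SN{u:03d}R"
            for nid, side, bt, partner in (
                (left_id, "left", birth, right_id),
                (right_id, "right", birth2, left_id),
            ):
                neurons.append(
                    Neuron(
                        id=nid,
                        position2d=(ap, dv),
                        side=side,
                        birth_time=bt,
                        position3d=lift_to_3d((ap, dv), side, spatial),
                        neuron_class=f"SN{u:03d}",
                        neuron_type=frozenset([rng.choice(["sensory", "inter", "motor"])]),
                        region=regions[u],
                        circuits=frozenset([f"circuit_{regions[u]}"]),
                        bilateral_partner=partner,
                    )
                )
        else:
            nid = f"SN{u:03d}M"
            neurons.append(
                Neuron(
                    id=nid,
                    position2d=(ap, dv),
                    side="midline",
                    birth_time=birth,
                    position3d=lift_to_3d((ap, dv), "midline", spatial),
                    neuron_class=f"SN{u:03d}",
                    neuron_type=frozenset([rng.choice(["sensory", "inter", "motor"])]),
                    region=regions[u],
                    circuits=frozenset([f"circuit_{regions[u]}"]),
                )
            )

    ids = [nrn.id for nrn in neurons]
    pos = np.array([nrn.position3d for nrn in neurons])
    births = np.array([nrn.birth_time for nrn in neurons])
    latest = max(
        cfg.postembryonic_window[1], cfg.embryonic_window[1], births.max()
    )
    earliest = min(cfg.embryonic_window[0], births.min())
    earliness = (latest - births) / (latest - earliest)
    is_embryonic = births < (cfg.embryonic_window[1] + cfg.postembryonic_window[0]) / 2

    iu, ju = np.triu_indices(n, k=1)
    dist = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    base = np.exp(-dist / cfg.distance_decay_mm)
    w = base * np.exp(cfg.hub_early_bias * earliness[iu] * earliness[ju])
    long_mask = (dist >= classifier.long_min) & is_embryonic[iu] & is_embryonic[ju]
    w = w + cfg.long_range_early_bias * base.mean() * long_mask
    total = w.sum()
    if not np.isfinite(total) or total <= 0 or np.count_nonzero(w) < cfg.n_connections:
        raise ValueError(
            "infeasible edge count for the realized pair weights; lower "
            "n_connections or soften the bias/decay parameters"
        )
    chosen = rng.choice(len(w), size=cfg.n_connections, replace=False, p=w / total)

    kinds = rng.choice(
        ["gap", "combination", "chemical"],
        size=cfg.n_connections,
        p=[
            cfg.gap_fraction,
            cfg.combination_fraction,
            1.0 - cfg.gap_fraction - cfg.combination_fraction,
        ],
    )
    connections: list[Connection] = []
    pair_class: dict[tuple[str, str], str] = {}
    for k, kind in zip(chosen, kinds):
        a, b = ids[iu[k]], ids[ju[k]]
        if kind == "chemical":
            directed = rng.choice(["uni", "bi"], p=[0.75, 0.25])
            if directed == "uni" and rng.random() < 0.5:
                a, b = b, a
        else:
            directed = "bi"
        connections.append(Connection(a, b, str(kind), str(directed)))
        d = dist[k]
        cls = (
            "short"
            if d < classifier.short_max
            else ("long" if d >= classifier.long_min else "medium")
        )
        pair_class[(min(a, b), max(a, b))] = cls

    cut = np.quantile(earliness, 0.9)
    truth = PlantedTruth(
        hub_early_bias=cfg.hub_early_bias,
        long_range_early_bias=cfg.long_range_early_bias,
        earliness={nid: float(e) for nid, e in zip(ids, earliness)},
        intended_hubs=(
            [nid for nid, e in zip(ids, earliness) if e >= cut]
            if cfg.hub_early_bias > 0
            else []
        ),
        pair_length_class=pair_class,
    )
    connectome = Connectome(
        neurons,
        connections,
        config=spatial,
        provenance=f"synthetic (seed={cfg.seed}, n={n}, links={cfg.n_connections})",
    )
    return connectome, truth


def write_fixture(
    connectome: Connectome,
    directory,
    truth: PlantedTruth | None = None,
) -> dict[str, Any]:
    """Write the CSV pair (plus optional ground-truth JSON) for a connectome."""
    import json
    from pathlib import Path

    from .io import write_connectome

    paths = write_connectome(connectome, directory)
    if truth is not None:
        truth_path = Path(directory) / "planted_truth.json"
        truth_path.write_text(json.dumps(truth.to_jsonable(), indent=2), encoding="utf-8")
        paths["truth"] = truth_path
    return paths
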