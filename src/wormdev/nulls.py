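"""Null models and ensemble statistics.

Two baselines: the identity shuffle, which keeps the graph fixed and
permutes whole neuron identity bundles (position + birth time + annotations)
across nodes, so the degree sequence is exactly preserved while every
spatial/temporal quantity randomizes; and Erdős–Rényi G(n, m) graphs, which
preserve only node and link counts (used for small-world baselines).

Observed statistics are compared to a shuffle ensemble (default twenty
trials) with a one-sample t-test of the trials against the observed value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats as sps

from .config import SpatialConfig
from .connectome import Connection, Connectome, Neuron

__all__ = [
    "EnsembleResult",
    "shuffle_identities",
    "ensemble",
    "one_sample_ttest",
    "erdos_renyi",
    "METRICS",
    "register_metric",
]

#: metric registry: name -> callable(Connectome) -> float
METRICS: dict[str, Callable[[Connectome], float]] = {}


def register_metric(name: str):
    """Decorator registering a named scalar metric for ensemble runs."""

    def deco(fn: Callable[[Connectome], float]):
        METRICS[name] = fn
        return fn

    return deco


@dataclass(frozen=True)
class EnsembleResult:
    """Per-trial metric values over a null ensemble with summary statistics.

    ``sd`` uses the sample (n-1) denominator. Trials on which the metric
    failed are recorded as NaN and the ensemble is flagged.
    """

    metric_name: str
    trial_values: tuple[float, ...]
    seed: int
    flagged: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trial_values)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.trial_values))

    @property
    def sd(self) -> float:
        vals = [v for v in self.trial_values if not math.isnan(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def _trial_seed(master_seed: int, trial: int) -> int:
    """Deterministic, well-mixed per-trial seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(trial,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def shuffle_identities(connectome: Connectome, seed: int) -> Connectome:
    """Identity-shuffle null: permute identity bundles over a fixed graph.

    The edge structure (and so the degree sequence), synapse kinds and
    directedness are untouched; the bundles of spatial position, side,
    birth time, region, neuron type and circuit membership are reassigned
    to nodes by a uniform random permutation. Bilateral-partner references
    are remapped through the same permutation, so partnered bundles stay
    partnered (and the annotation stays symmetric). Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = list(connectome.neurons)
    index = {nid: i for i, nid in enumerate(ids)}
    perm = rng.permutation(len(ids))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(ids))
    shuffled = []
    for i, nid in enumerate(ids):
        donor = connectome.neurons[ids[perm[i]]]
        partner = (
            ids[int(inv[index[donor.bilateral_partner]])]
            if donor.bilateral_partner is not None
            else None
        )
        shuffled.append(
            Neuron(
                id=nid,
                position2d=donor.position2d,
                side=donor.side,
                birth_time=donor.birth_time,
                position3d=donor.position3d,
                neuron_class=donor.neuron_class,
                neuron_type=donor.neuron_type,
                region=donor.region,
                circuits=donor.circuits,
                bilateral_partner=partner,
            )
        )
    return Connectome(
        shuffled,
        connectome.connections,
        config=connectome.config,
        provenance=f"{connectome.provenance} | identity shuffle seed={seed}".strip(" |"),
    )


def ensemble(
    metric: Callable[[Connectome], float] | str,
    connectome: Connectome,
    n_trials: int = 20,
    seed: int = 0,
) -> EnsembleResult:
    """Evaluate a metric over ``n_trials`` independent identity shuffles.

    Trial seeds derive deterministically from the master seed. A metric
    failure on a trial is recorded as NaN and flags the ensemble rather
    than aborting it.
    """
    if isinstance(metric, str):
        name, fn = metric, METRICS[metric]
    else:
        name, fn = getattr(metric, "__name__", "metric"), metric
    values: list[float] = []
    flagged = False
    for i in range(n_trials):
        shuffled = shuffle_identities(connectome, _trial_seed(seed, i))
        try:
            values.append(float(fn(shuffled)))
        except Exception:
            values.append(float("nan"))
            flagged = True
    return EnsembleResult(
        metric_name=name, trial_values=tuple(values), seed=seed, flagged=flagged
    )


def one_sample_ttest(
    observed: float, ens: EnsembleResult, sides: str = "two"
) -> tuple[float, float]:
    """One-sample t-test of the ensemble trials against the observed value.

    ``t = (observed - mean) / (sd / sqrt(n))`` with ``n - 1`` degrees of
    freedom. The two-sided p is ``2 * P(T >= |t|)``; the one-sided p is the
    tail beyond t in its own direction. A degenerate ensemble (sd = 0)
    raises rather than returning p = 0.
    """
    if ens.n_trials < 2:
        raise ValueError("need at least 2 trials")
    sd = ens.sd
    if not (sd > 0):
        raise ValueError("degenerate ensemble: sd is zero (or undefined)")
    n = ens.n_trials
    t = (observed - ens.mean) / (sd / math.sqrt(n))
    df = n - 1
    if sides == "two":
        p = 2.0 * float(sps.t.sf(abs(t), df))
    elif sides == "one":
        p = float(sps.t.sf(t, df)) if t >= 0 else float(sps.t.cdf(t, df))
    else:
        raise ValueError("sides must be 'two' or 'one'")
    return t, min(p, 1.0)


def erdos_renyi(n_nodes: int, n_links: int, seed: int) -> Connectome:
    """Topology-only Erdős–Rényi G(n, m) connectome.

    Exactly ``n_links`` distinct unordered node pairs are chosen uniformly
    without replacement; no self-loops. Node attributes are placeholders
    (the graph feeds only topology baselines). Deterministic given seed.
    """
    max_links = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_links <= max_links:
        raise ValueError(f"n_links must be in [0, {max_links}] for n={n_nodes}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_links, size=n_links, replace=False)
    iu, ju = np.triu_indices(n_nodes, k=1)
    ids = [f"N{i}" for i in range(n_nodes)]
    neurons = [
        Neuron(id=ids[i], position2d=(0.0, 0.0), side="midline", birth_time=0.0)
        for i in range(n_nodes)
    ]
    connections = [
        Connection(ids[int(iu[k])], ids[int(ju[k])], "chemical", "bi") for k in chosen
    ]
    return Connectome(
        neurons,
        connections,
        config=SpatialConfig(),
        provenance=f"erdos-renyi n={n_nodes} m={n_links} seed={seed}",
    )
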