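"""Named scalar metrics usable against null ensembles.

Each metric maps a connectome to one number and is registered by name so
the pipeline and the CLI can pair any observed value with its
identity-shuffle ensemble.
"""
from __future__ import annotations

import numpy as np

from .config import LengthClassifier
from .connectome import Connectome
from .nulls import register_metric
from .spatial import classify_length, connection_lengths
from .temporal import (
    birth_time_differences,
    degree_birth_correlation,
    hub_report,
    phase_fractions,
)


@register_metric("n_connections")
def n_connections(c: Connectome) -> float:
    """Link count (topology-invariant: constant under identity shuffles)."""
    return float(c.n_connections)


@register_metric("mean_birth_time_difference")
def mean_birth_time_difference(c: Connectome) -> float:
    """Mean |birth(pre) - birth(post)| over links, minutes."""
    return float(birth_time_differences(c).mean())


@register_metric("frac_pairs_within_200min")
def frac_pairs_within_200min(c: Connectome) -> float:
    """Fraction of links whose endpoints are born less than 200 minutes apart."""
    d = birth_time_differences(c)
    return float((d < 200.0).mean())


@register_metric("embryonic_within_fraction")
def embryonic_within_fraction(c: Connectome) -> float:
    """Endpoint-weighted within-phase fraction for embryonic neurons."""
    emb, _ = phase_fractions(c)
    if emb is None:
        raise ValueError("no embryonic neurons")
    return emb


@register_metric("postembryonic_within_fraction")
def postembryonic_within_fraction(c: Connectome) -> float:
    """Endpoint-weighted within-phase fraction for post-embryonic neurons."""
    _, post = phase_fractions(c)
    if post is None:
        raise ValueError("no post-embryonic neurons")
    return post


@register_metric("degree_birth_correlation")
def degree_birth_metric(c: Connectome) -> float:
    """Pearson r of degree versus birth time."""
    return degree_birth_correlation(c)


@register_metric("hub30_prehatch_fraction")
def hub30_prehatch_fraction(c: Connectome) -> float:
    """Fraction of neurons with degree > 30 born before hatching."""
    rep = hub_report(c, 30, comparator="gt")
    if rep.fraction_born_before is None:
        raise ValueError("no neurons above the degree threshold")
    return rep.fraction_born_before


@register_metric("hub60_multi_late_neighbor_fraction")
def hub60_multi_late_neighbor_fraction(c: Connectome) -> float:
    """Fraction of degree > 60 neurons with more than one late-forming neighbour."""
    rep = hub_report(c, 60, comparator="gt")
    if not rep.members:
        raise ValueError("no neurons above the degree threshold")
    return sum(1 for *_rest, n_late in rep.members if n_late > 1) / len(rep.members)


def _prehatch_pct(c: Connectome, length_class: str) -> float:
    classifier = LengthClassifier()
    hatch = c.config.hatch_time
    births = {nid: n.birth_time for nid, n in c.neurons.items()}
    lengths = connection_lengths(c)
    in_class = early = 0
    for conn, d in zip(c.connections, lengths):
        if classify_length(float(d), classifier) != length_class:
            continue
        in_class += 1
        if births[conn.pre] < hatch and births[conn.post] < hatch:
            early += 1
    if in_class == 0:
        raise ValueError(f"no {length_class}-class connection-pairs")
    return 100.0 * early / in_class


@register_metric("prehatch_pct_short")
def prehatch_pct_short(c: Connectome) -> float:
    """Percent of short-class adult pairs with both neurons born pre-hatching."""
    return _prehatch_pct(c, "short")


@register_metric("prehatch_pct_medium")
def prehatch_pct_medium(c: Connectome) -> float:
    """Percent of medium-class adult pairs with both neurons born pre-hatching."""
    return _prehatch_pct(c, "medium")


@register_metric("prehatch_pct_long")
def prehatch_pct_long(c: Connectome) -> float:
    """Percent of long-class adult pairs with both neurons born pre-hatching."""
    return _prehatch_pct(c, "long")
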