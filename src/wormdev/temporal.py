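"""Birth-time statistics of the developing network.

Covers the timing of connected-neuron births, the tendency of embryonic
neurons to wire within their own phase, the early birth of hub neurons,
late-forming neighbours of hubs, bilateral-pair timing symmetry, and the
growth curves of the sensory / inter / motor neuron classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import Connectome

__all__ = [
    "Histogram",
    "HubReport",
    "birth_time_differences",
    "binned_histogram",
    "phase_fractions",
    "degree_birth_correlation",
    "hub_report",
    "bilateral_timing",
    "type_growth_curves",
]


@dataclass(frozen=True)
class Histogram:
    """Equal-width histogram with per-bin means of the binned values.

    ``bin_means[i]`` is ``None`` for empty bins (never 0, which would
    corrupt downstream plots).
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    bin_means: tuple[float | None, ...]


@dataclass(frozen=True)
class HubReport:
    """Neurons at or above a degree threshold and their birth timing.

    ``members`` rows are (id, degree, birth_time, n_late_neighbors) where a
    late neighbour is a connected neuron born at or after hatching.
    """

    degree_threshold: int
    comparator: str  # "ge" or "gt"
    n_at_or_above: int
    fraction_born_before: float | None
    members: tuple[tuple[str, int, float, int], ...]


def birth_time_differences(connectome: Connectome) -> np.ndarray:
    """Absolute birth-time difference (minutes) for every link, counted once."""
    births = {nid: n.birth_time for nid, n in connectome.neurons.items()}
    return np.array(
        [abs(births[c.pre] - births[c.post]) for c in connectome.connections],
        dtype=float,
    )


def binned_histogram(values, n_bins: int = 10) -> Histogram:
    """Split values into ``n_bins`` equal-width bins over [0, max] with per-bin means.

    The last bin is right-closed; the others are half-open [lo, hi). If
    every value is zero the histogram degenerates to a single bin holding
    everything.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("binned_histogram requires at least one value")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    top = float(values.max())
    if top <= 0.0:
        return Histogram(
            bin_edges=(0.0, 0.0),
            counts=(int(values.size),),
            bin_means=(0.0,),
        )
    edges = np.linspace(0.0, top, n_bins + 1)
    idx = np.minimum(np.searchsorted(edges, values, side="right") - 1, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    means: list[float | None] = []
    for b in range(n_bins):
        in_bin = values[idx == b]
        means.append(float(in_bin.mean()) if in_bin.size else None)
    return Histogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        bin_means=tuple(means),
    )


def phase_fractions(
    connectome: Connectome,
    hatch_time: float | None = None,
    endpoint_weighted: bool = True,
) -> tuple[float | None, float | None]:
    """Within-phase connection fractions for the embryonic and post-embryonic bursts.

    A neuron is embryonic if ``birth_time < hatch_time``. With the default
    endpoint weighting, the embryonic fraction asks: over all connection
    endpoints belonging to embryonic neurons, how often is the partner also
    embryonic? (Each within-phase link contributes two such endpoints, each
    crossing link one.) The link-level variant (``endpoint_weighted=False``)
    instead divides within-phase links by links touching the phase at all.

    A phase with no neurons yields ``None`` for its fraction.
    """
    hatch = connectome.config.hatch_time if hatch_time is None else hatch_time
    emb = {nid for nid, n in connectome.neurons.items() if n.birth_time < hatch}
    post = set(connectome.neurons) - emb

    def fraction(phase: set[str]) -> float | None:
        if not phase:
            return None
        within = crossing = 0
        for c in connectome.connections:
            a, b = c.pre in phase, c.post in phase
            if a and b:
                within += 1
            elif a or b:
                crossing += 1
        if endpoint_weighted:
            num, den = 2 * within, 2 * within + crossing
        else:
            num, den = within, within + crossing
        return num / den if den else None

    return fraction(emb), fraction(post)


def degree_birth_correlation(connectome: Connectome) -> float:
    """Pearson correlation of total degree against birth time over all neurons."""
    if connectome.n_neurons < 3:
        raise ValueError("need at least 3 neurons")
    deg = connectome.degrees()
    x = np.array([deg[nid] for nid in connectome.neurons], dtype=float)
    y = np.array([n.birth_time for n in connectome.neurons.values()], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in degree or birth time")
    return float(stats.pearsonr(x, y).statistic)


def hub_report(
    connectome: Connectome,
    degree_threshold: int,
    hatch_time: float | None = None,
    comparator: str = "ge",
) -> HubReport:
    """High-degree neurons, their pre-hatching fraction and late neighbours.

    ``comparator`` selects degree >= threshold ("ge") or > threshold
    ("gt"). A "late forming neighbour" of a hub is a connected neuron with
    ``birth_time >= hatch_time``.
    """
    if degree_threshold < 0:
        raise ValueError("degree_threshold must be >= 0")
    if comparator not in ("ge", "gt"):
        raise ValueError("comparator must be 'ge' or 'gt'")
    hatch = connectome.config.hatch_time if hatch_time is None else hatch_time
    deg = connectome.degrees()
    members = []
    n_before = 0
    for nid, n in connectome.neurons.items():
        d = deg[nid]
        if (d >= degree_threshold) if comparator == "ge" else (d > degree_threshold):
            n_late = sum(
                1
                for other in connectome.neighbors(nid)
                if connectome.neurons[other].birth_time >= hatch
            )
            members.append((nid, d, n.birth_time, n_late))
            if n.birth_time < hatch:
                n_before += 1
    members.sort(key=lambda row: (-row[1], row[0]))
    return HubReport(
        degree_threshold=degree_threshold,
        comparator=comparator,
        n_at_or_above=len(members),
        fraction_born_before=(n_before / len(members)) if members else None,
        members=tuple(members),
    )


def bilateral_timing(connectome: Connectome) -> list[tuple[tuple[str, str], float]]:
    """Birth-time differences of annotated bilateral pairs, each pair once."""
    seen: set[tuple[str, str]] = set()
    out: list[tuple[tuple[str, str], float]] = []
    for nid, n in connectome.neurons.items():
        p = n.bilateral_partner
        if p is None:
            continue
        partner = connectome.neurons.get(p)
        if partner is None or partner.bilateral_partner != nid:
            raise ValueError(f"asymmetric bilateral annotation between {nid!r} and {p!r}")
        key = (min(nid, p), max(nid, p))
        if key in seen:
            continue
        seen.add(key)
        out.append((key, abs(n.birth_time - partner.birth_time)))
    return out


def type_growth_curves(
    connectome: Connectome,
    stage_times=None,
) -> dict[str, list[float]]:
    """Cumulative birth percentage per neuron type at each stage time.

    Curves are produced for sensory, inter and motor neurons plus
    "exclusive_motor" (motor and nothing else). A polymodal neuron counts
    in every type it carries. Percentages are relative to the adult count
    of that type; a type with no adult members is omitted with a warning.
    """
    import logging

    stage_times = (
        connectome.config.stage_times if stage_times is None else tuple(stage_times)
    )
    groups = {
        "sensory": [],
        "inter": [],
        "motor": [],
        "exclusive_motor": [],
    }
    for n in connectome.neurons.values():
        for t in n.neuron_type:
            groups[t].append(n.birth_time)
        if n.neuron_type == frozenset({"motor"}):
            groups["exclusive_motor"].append(n.birth_time)
    curves: dict[str, list[float]] = {}
    for name, births in groups.items():
        if not births:
            logging.getLogger(__name__).warning("no adult neurons of type %s", name)
            continue
        arr = np.asarray(births)
        curves[name] = [100.0 * float((arr <= t).mean()) for t in stage_times]
    return curves
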