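"""Spatial wiring statistics: connection lengths, length classes, curves.

Connection length is the Euclidean distance between the two somata in 3D
(not the axonal path, and not the synapse position). Lengths fall into ten
0.12 mm bins: the first three are short range (< 0.36 mm), the last three
long range (>= 0.84 mm), the middle four medium range.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import LengthClassifier
from .connectome import Connection, Connectome

logger = logging.getLogger(__name__)

LENGTH_CLASSES = ("short", "medium", "long")

__all__ = [
    "AppearanceCurve",
    "connection_length",
    "connection_lengths",
    "classify_length",
    "class_counts",
    "appearance_curves",
    "synapse_breakdown",
    "region_connectivity",
    "circuit_curves",
    "degree_length_correlations",
]


@dataclass(frozen=True)
class AppearanceCurve:
    """Percentage of a class of adult connection-pairs present per stage."""

    name: str
    stage_times: tuple[float, ...]
    percentages: tuple[float, ...]
    adult_count: int


def connection_length(connectome: Connectome, connection: Connection) -> float:
    """Euclidean soma-to-soma distance (mm) of a link; symmetric in endpoints."""
    for nid in (connection.pre, connection.post):
        if nid not in connectome.neurons:
            raise KeyError(f"connection endpoint {nid!r} has no position")
    a = np.asarray(connectome.neurons[connection.pre].position3d)
    b = np.asarray(connectome.neurons[connection.post].position3d)
    return float(np.linalg.norm(a - b))


def connection_lengths(connectome: Connectome) -> np.ndarray:
    """Length of every link, in connection order."""
    pos = {nid: np.asarray(n.position3d) for nid, n in connectome.neurons.items()}
    return np.array(
        [float(np.linalg.norm(pos[c.pre] - pos[c.post])) for c in connectome.connections]
    )


def classify_length(d: float, classifier: LengthClassifier | None = None) -> str:
    """Assign a length (mm) to short / medium / long.

    Short iff ``d < short_max``; long iff ``d >= long_min`` (lengths beyond
    the last bin are still long); medium otherwise.
    """
    classifier = classifier or LengthClassifier()
    if d < 0:
        raise ValueError(f"negative connection length {d}")
    if d < classifier.short_max:
        return "short"
    if d >= classifier.long_min:
        return "long"
    return "medium"


def class_counts(
    connectome: Connectome, classifier: LengthClassifier | None = None
) -> dict[str, int]:
    """Number of links per length class; the three counts sum to the total."""
    classifier = classifier or LengthClassifier()
    counts = dict.fromkeys(LENGTH_CLASSES, 0)
    for d in connection_lengths(connectome):
        counts[classify_length(float(d), classifier)] += 1
    return counts


def appearance_curves(
    connectome: Connectome,
    stage_times=None,
    classifier: LengthClassifier | None = None,
) -> dict[str, AppearanceCurve]:
    """Per length class, the percentage of adult connection-pairs present per stage.

    A pair is present once both neurons are born; lengths are always taken
    from adult positions. Percentages are relative to the adult pair count
    of that class; a class with no adult pairs is omitted with a warning.
    """
    classifier = classifier or LengthClassifier()
    stage_times = (
        connectome.config.stage_times if stage_times is None else tuple(stage_times)
    )
    births = {nid: n.birth_time for nid, n in connectome.neurons.items()}
    lengths = connection_lengths(connectome)
    classes = [classify_length(float(d), classifier) for d in lengths]
    pair_birth = [
        max(births[c.pre], births[c.post]) for c in connectome.connections
    ]
    curves: dict[str, AppearanceCurve] = {}
    for cls in LENGTH_CLASSES:
        times = [t for t, c in zip(pair_birth, classes) if c == cls]
        if not times:
            logger.warning("no adult connection-pairs in class %s; curve omitted", cls)
            continue
        arr = np.asarray(times)
        curves[cls] = AppearanceCurve(
            name=cls,
            stage_times=tuple(stage_times),
            percentages=tuple(
                100.0 * float((arr <= t).mean()) for t in stage_times
            ),
            adult_count=len(times),
        )
    return curves


def synapse_breakdown(
    connectome: Connectome,
    classifier: LengthClassifier | None = None,
    hatch_time: float | None = None,
) -> dict[tuple[str, str, str], int]:
    """Contingency counts over (synapse kind, length class, early/late).

    "Early" means both endpoints were born before hatching. The electrically
    coupled aggregate (gap plus combination junctions) is derivable by
    summing the gap and combination rows.
    """
    classifier = classifier or LengthClassifier()
    hatch = connectome.config.hatch_time if hatch_time is None else hatch_time
    births = {nid: n.birth_time for nid, n in connectome.neurons.items()}
    counts: dict[tuple[str, str, str], int] = {
        (kind, cls, phase): 0
        for kind in ("gap", "chemical", "combination")
        for cls in LENGTH_CLASSES
        for phase in ("early", "late")
    }
    lengths = connection_lengths(connectome)
    for c, d in zip(connectome.connections, lengths):
        cls = classify_length(float(d), classifier)
        early = births[c.pre] < hatch and births[c.post] < hatch
        counts[(c.synapse_kind, cls, "early" if early else "late")] += 1
    return counts


def electrically_coupled_fraction(
    breakdown: dict[tuple[str, str, str], int], length_class: str
) -> float | None:
    """Fraction of links of a length class that are gap or combination junctions."""
    total = sum(v for (k, c, p), v in breakdown.items() if c == length_class)
    if total == 0:
        return None
    coupled = sum(
        v
        for (k, c, p), v in breakdown.items()
        if c == length_class and k in ("gap", "combination")
    )
    return coupled / total


def region_connectivity(
    connectome: Connectome, endpoint_weighted: bool = True
) -> dict[str, float | None]:
    """Within-region connection fraction per body region (head / body / tail).

    Endpoint-weighted like the phase fractions: over connection endpoints
    lying in region R, the fraction whose partner also lies in R. Regions
    with no neurons are omitted.
    """
    regions = sorted(
        {n.region for n in connectome.neurons.values() if n.region is not None}
    )
    member = {nid: n.region for nid, n in connectome.neurons.items()}
    out: dict[str, float | None] = {}
    for reg in regions:
        within = crossing = 0
        for c in connectome.connections:
            a, b = member[c.pre] == reg, member[c.post] == reg
            if a and b:
                within += 1
            elif a or b:
                crossing += 1
        if endpoint_weighted:
            num, den = 2 * within, 2 * within + crossing
        else:
            num, den = within, within + crossing
        out[reg] = num / den if den else None
    return out


def circuit_curves(
    connectome: Connectome, stage_times=None
) -> dict[str, AppearanceCurve]:
    """Per functional circuit, percentage of its connection-pairs present per stage.

    A connection-pair belongs to every circuit either endpoint belongs to
    (a pair spanning two circuits counts in both). Neurons with no circuit
    membership contribute to no curve.
    """
    stage_times = (
        connectome.config.stage_times if stage_times is None else tuple(stage_times)
    )
    births = {nid: n.birth_time for nid, n in connectome.neurons.items()}
    circuits = {nid: n.circuits for nid, n in connectome.neurons.items()}
    if any(not c for c in circuits.values()):
        logger.warning("some neurons have no circuit membership; they join no curve")
    per_circuit: dict[str, list[float]] = {}
    for c in connectome.connections:
        t = max(births[c.pre], births[c.post])
        for circuit in circuits[c.pre] | circuits[c.post]:
            per_circuit.setdefault(circuit, []).append(t)
    out: dict[str, AppearanceCurve] = {}
    for circuit, times in sorted(per_circuit.items()):
        arr = np.asarray(times)
        out[circuit] = AppearanceCurve(
            name=circuit,
            stage_times=tuple(stage_times),
            percentages=tuple(100.0 * float((arr <= t).mean()) for t in stage_times),
            adult_count=len(times),
        )
    return out


def degree_length_correlations(
    connectome: Connectome, classifier: LengthClassifier | None = None
) -> tuple[float, float]:
    """Pearson correlation of degree with per-neuron short- and long-class proportions.

    For each neuron with at least one link, the proportion of its links in
    the short (resp. long) class is correlated against its total degree.
    """
    classifier = classifier or LengthClassifier()
    lengths = connection_lengths(connectome)
    classes = [classify_length(float(d), classifier) for d in lengths]
    totals: dict[str, int] = {}
    short: dict[str, int] = {}
    long_: dict[str, int] = {}
    for c, cls in zip(connectome.connections, classes):
        for nid in (c.pre, c.post):
            totals[nid] = totals.get(nid, 0) + 1
            if cls == "short":
                short[nid] = short.get(nid, 0) + 1
            elif cls == "long":
                long_[nid] = long_.get(nid, 0) + 1
    ids = sorted(totals)
    if len(ids) < 3:
        raise ValueError("need at least 3 connected neurons")
    deg = connectome.degrees()
    x = np.array([deg[nid] for nid in ids], dtype=float)
    p_short = np.array([short.get(nid, 0) / totals[nid] for nid in ids])
    p_long = np.array([long_.get(nid, 0) / totals[nid] for nid in ids])
    if np.ptp(x) == 0 or np.ptp(p_short) == 0 or np.ptp(p_long) == 0:
        raise ValueError("zero variance in degree or class proportions")
    r_short = float(stats.pearsonr(x, p_short).statistic)
    r_long = float(stats.pearsonr(x, p_long).statistic)
    return r_short, r_long
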