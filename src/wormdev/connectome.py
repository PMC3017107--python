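"""Core data model: neurons, connections and staged connectomes.

The connectome is a set of annotated neurons (3D soma position, birth time,
type, body region, circuit memberships) plus typed links between them.
Links are stored once each; a bidirectional link (gap junction, combination
junction, or reciprocal chemical synapses recorded as one row) expands to
two arcs only inside degree and topology computations.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .config import SpatialConfig

logger = logging.getLogger(__name__)

SIDES = ("left", "right", "midline")
REGIONS = ("head", "body", "tail")
SYNAPSE_KINDS = ("gap", "chemical", "combination")
NEURON_TYPES = ("sensory", "inter", "motor")

#: |dv| may exceed the body radius by this much (mm) and be clamped silently;
#: larger excess is clamped with a logged warning.
DV_CLAMP_TOLERANCE = 1e-6


def lift_to_3d(
    position2d: tuple[float, float],
    side: str,
    config: SpatialConfig,
) -> tuple[float, float, float]:
    """Lift a 2D soma position onto the cylindrical body model.

    The worm body is modelled as a cylinder of radius ``config.body_radius``
    along the anterior-posterior axis. Given the AP coordinate and the
    dorsoventral coordinate ``dv``, the lateral coordinate follows the
    circular cross-section, ``|z| = sqrt(r^2 - dv^2)``: zero on the dorsal
    and ventral midlines (|dv| = r) and maximal (|z| = r) at the equator.
    Left-side neurons get positive z, right-side negative, and midline
    neurons have z forced to zero.

    Values of |dv| exceeding the radius are clamped to the radius (z = 0);
    an excess beyond ``DV_CLAMP_TOLERANCE`` additionally logs a warning,
    since digitized 2D positions may overshoot the idealized cylinder.
    """
    ap, dv = float(position2d[0]), float(position2d[1])
    if not (math.isfinite(ap) and math.isfinite(dv)):
        raise ValueError(f"non-finite 2D position ({ap}, {dv})")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    r = config.body_radius
    if abs(dv) > r:
        if abs(dv) - r > DV_CLAMP_TOLERANCE:
            logger.warning(
                "dorsoventral coordinate %.6g mm exceeds body radius %.6g mm; "
                "clamping to the body surface (z = 0)",
                dv,
                r,
            )
        dv = math.copysign(r, dv)
    if side == "midline":
        z = 0.0
    else:
        z = math.sqrt(max(r * r - dv * dv, 0.0))
        if side == "right":
            z = -z
    return (ap, dv, z)


@dataclass(frozen=True)
class Neuron:
    """An annotated node of the connectome.

    ``position2d`` is (anterior-posterior, dorsoventral) in mm;
    ``position3d`` is derived via :func:`lift_to_3d`. ``birth_time`` is
    minutes post-fertilization. ``neuron_type`` is a subset of
    {sensory, inter, motor} (polymodal neurons carry more than one).
    """

    id: str
    position2d: tuple[float, float]
    side: str
    birth_time: float
    position3d: tuple[float, float, float] = (0.0, 0.0, 0.0)
    neuron_class: str = ""
    neuron_type: frozenset[str] = frozenset()
    region: str | None = None
    circuits: frozenset[str] = frozenset()
    bilateral_partner: str | None = None

    def __post_init__(self) -> None:
        if self.birth_time < 0:
            raise ValueError(f"neuron {self.id}: birth_time must be >= 0")
        if self.side not in SIDES:
            raise ValueError(f"neuron {self.id}: bad side {self.side!r}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"neuron {self.id}: bad region {self.region!r}")
        bad = set(self.neuron_type) - set(NEURON_TYPES)
        if bad:
            raise ValueError(f"neuron {self.id}: unknown neuron types {sorted(bad)}")


@dataclass(frozen=True)
class Connection:
    """A typed link between two neurons.

    Gap junctions and combination junctions are inherently bidirectional;
    chemical synapses may be uni- or bidirectional.
    """

    pre: str
    post: str
    synapse_kind: str = "chemical"
    directedness: str = "uni"

    def __post_init__(self) -> None:
        if self.synapse_kind not in SYNAPSE_KINDS:
            raise ValueError(f"bad synapse_kind {self.synapse_kind!r}")
        if self.directedness not in ("uni", "bi"):
            raise ValueError(f"bad directedness {self.directedness!r}")
        if self.synapse_kind in ("gap", "combination") and self.directedness != "bi":
            raise ValueError(
                f"{self.synapse_kind} junction {self.pre}->{self.post} must be "
                "bidirectional"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.pre == self.post

    def key(self) -> tuple[str, str]:
        """Canonical link key: unordered for bidirectional links."""
        if self.directedness == "bi":
            return (min(self.pre, self.post), max(self.pre, self.post))
        return (self.pre, self.post)


class Connectome:
    """A validated neuron set plus link set; the unit every analysis consumes.

    Construction checks that every link endpoint exists, that there are no
    duplicate link keys and (unless ``allow_self_loops``) no self-loops.
    """

    def __init__(
        self,
        neurons: Iterable[Neuron],
        connections: Iterable[Connection],
        config: SpatialConfig | None = None,
        provenance: str = "",
        allow_self_loops: bool = False,
    ) -> None:
        self.config = config or SpatialConfig()
        self.provenance = provenance
        self.neurons: dict[str, Neuron] = {}
        for n in neurons:
            if n.id in self.neurons:
                raise ValueError(f"duplicate neuron id {n.id!r}")
            self.neurons[n.id] = n
        self.connections: list[Connection] = []
        seen: set[tuple[str, str]] = set()
        for c in connections:
            for endpoint in (c.pre, c.post):
                if endpoint not in self.neurons:
                    raise ValueError(
                        f"connection {c.pre}->{c.post}: unknown neuron {endpoint!r}"
                    )
            if c.is_self_loop and not allow_self_loops:
                raise ValueError(f"self-loop connection on {c.pre!r}")
            k = c.key()
            if k in seen:
                raise ValueError(f"duplicate connection {c.pre}->{c.post}")
            seen.add(k)
            self.connections.append(c)
        self._validate_bilateral_symmetry()

    def _validate_bilateral_symmetry(self) -> None:
        for n in self.neurons.values():
            p = n.bilateral_partner
            if p is None:
                continue
            partner = self.neurons.get(p)
            if partner is None or partner.bilateral_partner != n.id:
                raise ValueError(
                    f"asymmetric bilateral annotation between {n.id!r} and {p!r}"
                )

    # -- basic properties -------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self.neurons

    def __iter__(self) -> Iterator[Neuron]:
        return iter(self.neurons.values())

    def degree(self, neuron_id: str) -> int:
        """Total degree of a neuron: incoming plus outgoing arcs.

        A unidirectional link contributes 1 to each endpoint (out to the
        presynaptic, in to the postsynaptic neuron); a bidirectional link
        contributes 2 (one in plus one out) to each endpoint.
        """
        if neuron_id not in self.neurons:
            raise KeyError(f"unknown neuron id {neuron_id!r}")
        return self.degrees()[neuron_id]

    def degrees(self) -> dict[str, int]:
        """Total degree of every neuron (see :meth:`degree`)."""
        deg = {nid: 0 for nid in self.neurons}
        for c in self.connections:
            w = 2 if c.directedness == "bi" else 1
            deg[c.pre] += w
            deg[c.post] += w
        return deg

    def neighbors(self, neuron_id: str) -> set[str]:
        """Ids of neurons sharing at least one link, ignoring direction."""
        if neuron_id not in self.neurons:
            raise KeyError(f"unknown neuron id {neuron_id!r}")
        out: set[str] = set()
        for c in self.connections:
            if c.pre == neuron_id:
                out.add(c.post)
            elif c.post == neuron_id:
                out.add(c.pre)
        return out

    # -- transformations ---------------------------------------------------

    def stage_network(self, t: float) -> "Connectome":
        """Induced sub-connectome at developmental time ``t`` (minutes).

        Contains the neurons with ``birth_time <= t`` (inclusive cutoff) and
        a link iff both endpoints are present — the connection-pair reading:
        a pair connected in the adult counts as present once both neurons
        have been born, without implying synaptogenesis.
        """
        if t < 0:
            raise ValueError("stage time must be >= 0")
        present = {nid for nid, n in self.neurons.items() if n.birth_time <= t}
        conns = [c for c in self.connections if c.pre in present and c.post in present]
        staged_neurons = []
        for nid in present:
            n = self.neurons[nid]
            if n.bilateral_partner is not None and n.bilateral_partner not in present:
                n = replace(n, bilateral_partner=None)  # partner not yet born
            staged_neurons.append(n)
        return Connectome(
            staged_neurons,
            conns,
            config=self.config,
            provenance=f"{self.provenance} | stage t={t:g} min".strip(" |"),
        )

    def apply_exclusions(self, excluded_ids: Iterable[str] = ()) -> "Connectome":
        """Remove listed neurons (with incident links) and all self-loops.

        Idempotent; an excluded id that is absent only logs a warning. Also
        drops dangling bilateral-partner references to removed neurons.
        """
        excluded = set(excluded_ids)
        missing = excluded - set(self.neurons)
        if missing:
            logger.warning("excluded ids not present: %s", sorted(missing))
        kept_ids = set(self.neurons) - excluded
        kept_conns = []
        n_loops = n_incident = 0
        for c in self.connections:
            if c.is_self_loop:
                n_loops += 1
            elif c.pre in kept_ids and c.post in kept_ids:
                kept_conns.append(c)
            else:
                n_incident += 1
        kept_neurons = []
        for nid in kept_ids:
            n = self.neurons[nid]
            if n.bilateral_partner is not None and n.bilateral_partner not in kept_ids:
                n = replace(n, bilateral_partner=None)
            kept_neurons.append(n)
        logger.info(
            "exclusions: removed %d neurons, %d incident links, %d self-loops",
            len(excluded & set(self.neurons)),
            n_incident,
            n_loops,
        )
        return Connectome(
            kept_neurons,
            kept_conns,
            config=self.config,
            provenance=self.provenance,
        )

    # -- graph views -------------------------------------------------------

    def to_directed_graph(self) -> nx.DiGraph:
        """Directed view: one arc per unidirectional link, two per bidirectional."""
        g = nx.DiGraph()
        g.add_nodes_from(self.neurons)
        for c in self.connections:
            g.add_edge(c.pre, c.post, synapse_kind=c.synapse_kind)
            if c.directedness == "bi":
                g.add_edge(c.post, c.pre, synapse_kind=c.synapse_kind)
        return g

    def to_undirected_graph(self) -> nx.Graph:
        """Symmetrized simple graph: an edge iff any arc links the pair."""
        g = nx.Graph()
        g.add_nodes_from(self.neurons)
        for c in self.connections:
            g.add_edge(c.pre, c.post)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.neurons == other.neurons
            and sorted(self.connections, key=lambda c: (c.pre, c.post)) ==
            sorted(other.connections, key=lambda c: (c.pre, c.post))
            and self.config == other.config
        )
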