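"""CSV / GraphML / config file input and output.

CSV dialect: comma-separated, UTF-8, header row required, "." decimal
separator. Set-valued fields (neuron_type, circuits) are semicolon-separated
within a cell.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from .config import LengthClassifier, SpatialConfig
from .connectome import Connection, Connectome, Neuron, lift_to_3d

logger = logging.getLogger(__name__)

NEURON_REQUIRED_COLUMNS = ("id", "ap_mm", "dv_mm", "side", "birth_time_min")
NEURON_OPTIONAL_COLUMNS = (
    "neuron_class",
    "neuron_type",
    "region",
    "circuits",
    "bilateral_partner",
)
EDGE_COLUMNS = ("pre", "post", "synapse_kind", "directedness")


class LoadError(ValueError):
    """Raised for malformed input tables."""


def _split_set(cell: Any) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(part.strip() for part in str(cell).split(";") if part.strip())


def load_neuron_table(path: str | Path, config: SpatialConfig | None = None) -> list[Neuron]:
    """Read a neuron CSV into :class:`Neuron` records with 3D positions.

    Required columns: id, ap_mm, dv_mm, side, birth_time_min. Optional:
    neuron_class, neuron_type, region, circuits, bilateral_partner; missing
    optional columns default to empty/none. The lateral (z) coordinate is
    derived from the cylindrical body model.
    """
    config = config or SpatialConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in NEURON_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")
    neurons: list[Neuron] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        nid = str(row.id).strip()
        if nid in seen:
            raise LoadError(f"{path}: duplicate neuron id {nid!r}")
        seen.add(nid)
        try:
            ap = float(row.ap_mm)
            dv = float(row.dv_mm)
            birth = float(row.birth_time_min)
        except ValueError as exc:
            raise LoadError(f"{path} line {i}: non-numeric value ({exc})") from exc
        side = str(row.side).strip()
        pos3d = lift_to_3d((ap, dv), side, config)
        get = lambda col: getattr(row, col, "") if col in df.columns else ""
        partner = str(get("bilateral_partner")).strip() or None
        region = str(get("region")).strip() or None
        neurons.append(
            Neuron(
                id=nid,
                position2d=(ap, dv),
                side=side,
                birth_time=birth,
                position3d=pos3d,
                neuron_class=str(get("neuron_class")).strip(),
                neuron_type=_split_set(get("neuron_type")),
                region=region,
                circuits=_split_set(get("circuits")),
                bilateral_partner=partner,
            )
        )
    return neurons


def load_edge_table(path: str | Path) -> list[Connection]:
    """Read an edge CSV into :class:`Connection` records.

    Duplicate rows for the same link are collapsed; if both a gap junction
    and a chemical synapse appear between a pair, the link is upgraded to a
    combination junction (bidirectional).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("pre", "post") if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")
    # accumulate per unordered pair: which kinds were seen, which arc directions
    pairs: dict[tuple[str, str], dict[str, Any]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pre, post = str(row.pre).strip(), str(row.post).strip()
        kind = str(getattr(row, "synapse_kind", "chemical")).strip() or "chemical"
        directed = str(getattr(row, "directedness", "")).strip()
        if not directed:
            directed = "bi" if kind in ("gap", "combination") else "uni"
        if kind not in ("gap", "chemical", "combination"):
            raise LoadError(f"{path} line {i}: bad synapse_kind {kind!r}")
        if directed not in ("uni", "bi"):
            raise LoadError(f"{path} line {i}: bad directedness {directed!r}")
        key = (min(pre, post), max(pre, post)) if pre != post else (pre, post)
        entry = pairs.setdefault(key, {"kinds": set(), "arcs": set(), "first": (pre, post)})
        entry["kinds"].add(kind)
        if directed == "bi":
            entry["arcs"].update({(pre, post), (post, pre)})
        else:
            entry["arcs"].add((pre, post))
    out: list[Connection] = []
    for key, entry in pairs.items():
        kinds, arcs = entry["kinds"], entry["arcs"]
        pre, post = entry["first"]
        if "combination" in kinds or {"gap", "chemical"} <= kinds:
            kind = "combination"
        else:
            (kind,) = kinds
        bi = kind in ("gap", "combination") or len(arcs) == 2 or pre == post
        out.append(Connection(pre, post, kind, "bi" if bi else "uni"))
    return out


def load_connectome(
    neuron_csv: str | Path,
    edge_csv: str | Path,
    config: SpatialConfig | None = None,
    provenance: str = "",
) -> Connectome:
    """Load a full connectome from a neuron CSV plus an edge CSV."""
    config = config or SpatialConfig()
    neurons = load_neuron_table(neuron_csv, config)
    connections = load_edge_table(edge_csv)
    return Connectome(
        neurons,
        connections,
        config=config,
        provenance=provenance or f"loaded from {neuron_csv} + {edge_csv}",
        allow_self_loops=True,
    )


def write_connectome(connectome: Connectome, directory: str | Path) -> dict[str, Path]:
    """Write neuron and edge CSVs in the dialect :func:`load_connectome` reads.

    Returns the paths written; a write-then-load round trip reproduces the
    connectome field-by-field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    neuron_path = directory / "neurons.csv"
    edge_path = directory / "edges.csv"
    nrows = []
    for n in connectome.neurons.values():
        nrows.append(
            {
                "id": n.id,
                "ap_mm": repr(n.position2d[0]),
                "dv_mm": repr(n.position2d[1]),
                "side": n.side,
                "birth_time_min": repr(n.birth_time),
                "neuron_class": n.neuron_class,
                "neuron_type": ";".join(sorted(n.neuron_type)),
                "region": n.region or "",
                "circuits": ";".join(sorted(n.circuits)),
                "bilateral_partner": n.bilateral_partner or "",
            }
        )
    pd.DataFrame(
        nrows, columns=list(NEURON_REQUIRED_COLUMNS) + list(NEURON_OPTIONAL_COLUMNS)
    ).to_csv(neuron_path, index=False)
    erows = [
        {
            "pre": c.pre,
            "post": c.post,
            "synapse_kind": c.synapse_kind,
            "directedness": c.directedness,
        }
        for c in connectome.connections
    ]
    pd.DataFrame(erows, columns=list(EDGE_COLUMNS)).to_csv(edge_path, index=False)
    return {"neurons": neuron_path, "edges": edge_path}


def export_graphml(connectome: Connectome, path: str | Path) -> None:
    """Export the directed graph with all neuron fields as node attributes."""
    g = connectome.to_directed_graph()
    for nid, n in connectome.neurons.items():
        g.nodes[nid].update(
            ap_mm=n.position2d[0],
            dv_mm=n.position2d[1],
            x_mm=n.position3d[0],
            y_mm=n.position3d[1],
            z_mm=n.position3d[2],
            side=n.side,
            birth_time_min=n.birth_time,
            neuron_class=n.neuron_class,
            neuron_type=";".join(sorted(n.neuron_type)),
            region=n.region or "",
            circuits=";".join(sorted(n.circuits)),
            bilateral_partner=n.bilateral_partner or "",
        )
    nx.write_graphml(g, str(path))


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise LoadError(f"{path}: expected a mapping at top level")
    return dict(data)


def spatial_config_from_mapping(data: Mapping[str, Any]) -> SpatialConfig:
    kwargs = {
        k: data[k] for k in ("body_radius", "hatch_time", "stage_times") if k in data
    }
    if "stage_times" in kwargs:
        kwargs["stage_times"] = tuple(float(t) for t in kwargs["stage_times"])
    return SpatialConfig(**kwargs)


def length_classifier_from_mapping(data: Mapping[str, Any]) -> LengthClassifier:
    kwargs = {
        k: data[k]
        for k in ("n_bins", "bin_width", "short_bins", "long_bins")
        if k in data
    }
    return LengthClassifier(**kwargs)
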