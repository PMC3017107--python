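"""End-to-end orchestration: load or generate, analyze, compare to nulls.

``run_pipeline`` executes the four-fold analysis — temporal statistics,
spatial wiring statistics, functional-circuit curves and per-stage
topology — on a loaded or synthetic connectome, pairs every comparable
scalar with its identity-shuffle ensemble, and writes CSV tables plus one
machine-readable JSON report. Fully deterministic given the master seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import metrics as _metrics  # noqa: F401  (populates the registry)
from .config import LengthClassifier, SpatialConfig
from .connectome import Connectome
from .io import load_connectome, write_connectome
from .nulls import METRICS, EnsembleResult, ensemble, one_sample_ttest
from .spatial import (
    appearance_curves,
    circuit_curves,
    class_counts,
    classify_length,
    connection_lengths,
    degree_length_correlations,
    region_connectivity,
    synapse_breakdown,
)
from .synthetic import GeneratorConfig, generate_connectome
from .temporal import (
    bilateral_timing,
    binned_histogram,
    birth_time_differences,
    degree_birth_correlation,
    hub_report,
    phase_fractions,
    type_growth_curves,
)
from .topology import small_world_series

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("temporal", "spatial", "circuits", "topology")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """Raised when an analysis stage fails; names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``neuron_csv`` + ``edge_csv``) or ``synth`` must be
    set. ``excluded_ids`` are removed (with self-loops) before analysis.
    ``n_trials = 0`` disables null ensembles; comparisons are then marked
    unavailable.
    """

    neuron_csv: str | None = None
    edge_csv: str | None = None
    synth: GeneratorConfig | None = None
    spatial_config: SpatialConfig = field(default_factory=SpatialConfig)
    classifier: LengthClassifier = field(default_factory=LengthClassifier)
    excluded_ids: tuple[str, ...] = ()
    n_trials: int = 20
    seed: int = 0
    output_dir: str | None = None
    analyses: tuple[str, ...] = ALL_ANALYSES

    def __post_init__(self) -> None:
        has_files = self.neuron_csv is not None and self.edge_csv is not None
        if has_files == (self.synth is not None):
            raise ValueError("set exactly one of (neuron_csv, edge_csv) or synth")
        bad = set(self.analyses) - set(ALL_ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}")


def _comparison(
    name: str, observed: float, connectome: Connectome, n_trials: int, seed: int
) -> dict[str, Any]:
    """Observed scalar paired with its shuffle-ensemble statistics."""
    out: dict[str, Any] = {"observed": observed}
    if n_trials <= 1:
        out["ensemble"] = None
        return out
    ens = ensemble(name, connectome, n_trials=n_trials, seed=seed)
    entry = {
        "mean": ens.mean,
        "sd": ens.sd,
        "n_trials": ens.n_trials,
        "trial_values": list(ens.trial_values),
        "flagged": ens.flagged,
    }
    try:
        t, p = one_sample_ttest(observed, ens)
        entry["t"] = t
        entry["p"] = p
    except ValueError:
        entry["t"] = entry["p"] = None
    out["ensemble"] = entry
    return out


def validate_inputs(config: RunConfig) -> list[dict[str, str]]:
    """Schema and consistency checks; returns findings instead of raising.

    Each finding is ``{"level": "error"|"warning", "message": ...}``.
    Checks CSV schemas, unknown edge endpoints, bilateral symmetry and
    dorsoventral coordinates beyond the body radius (which would be
    clamped).
    """
    findings: list[dict[str, str]] = []
    if config.synth is not None:
        return findings
    from .io import NEURON_REQUIRED_COLUMNS

    try:
        ndf = pd.read_csv(config.neuron_csv, dtype=str, keep_default_na=False)
    except Exception as exc:
        return [{"level": "error", "message": f"cannot read neuron CSV: {exc}"}]
    for col in NEURON_REQUIRED_COLUMNS:
        if col not in ndf.columns:
            findings.append(
                {"level": "error", "message": f"neuron CSV missing column {col!r}"}
            )
    if findings:
        return findings
    ids = set()
    r = config.spatial_config.body_radius
    partner_of: dict[str, str] = {}
    for i, row in enumerate(ndf.itertuples(index=False), start=2):
        nid = str(row.id).strip()
        if nid in ids:
            findings.append(
                {"level": "error", "message": f"duplicate neuron id {nid!r} (line {i})"}
            )
        ids.add(nid)
        try:
            dv = float(row.dv_mm)
            float(row.ap_mm)
            float(row.birth_time_min)
        except ValueError:
            findings.append(
                {"level": "error", "message": f"non-numeric value on line {i}"}
            )
            continue
        if abs(dv) > r:
            findings.append(
                {
                    "level": "warning",
                    "message": (
                        f"neuron {nid}: |dv| = {abs(dv):g} mm exceeds body radius "
                        f"{r:g} mm and will be clamped"
                    ),
                }
            )
        partner = str(getattr(row, "bilateral_partner", "")).strip()
        if partner:
            partner_of[nid] = partner
    for nid, p in partner_of.items():
        if partner_of.get(p) != nid:
            findings.append(
                {
                    "level": "error",
                    "message": f"asymmetric bilateral annotation between {nid!r} and {p!r}",
                }
            )
    try:
        edf = pd.read_csv(config.edge_csv, dtype=str, keep_default_na=False)
    except Exception as exc:
        findings.append({"level": "error", "message": f"cannot read edge CSV: {exc}"})
        return findings
    for i, row in enumerate(edf.itertuples(index=False), start=2):
        for endpoint in (str(row.pre).strip(), str(row.post).strip()):
            if endpoint not in ids:
                findings.append(
                    {
                        "level": "error",
                        "message": (
                            f"edge {row.pre}->{row.post} (line {i}) references "
                            f"unknown neuron {endpoint!r}"
                        ),
                    }
                )
    return findings


def _obtain_connectome(config: RunConfig) -> Connectome:
    if config.synth is not None:
        connectome, _truth = generate_connectome(config.synth)
    else:
        connectome = load_connectome(
            config.neuron_csv, config.edge_csv, config=config.spatial_config
        )
    return connectome.apply_exclusions(config.excluded_ids)


def _temporal_block(c: Connectome, cfg: RunConfig) -> dict[str, Any]:
    diffs = birth_time_differences(c)
    hist = binned_histogram(diffs, n_bins=10)
    emb, post = phase_fractions(c)
    hubs = {
        str(thr): dataclasses.asdict(hub_report(c, thr, comparator=cmp))
        for thr, cmp in ((20, "ge"), (30, "gt"), (60, "gt"))
    }
    block: dict[str, Any] = {
        "birth_time_difference_histogram": dataclasses.asdict(hist),
        "phase_fractions": {
            "embryonic_within": _comparison(
                "embryonic_within_fraction", emb, c, cfg.n_trials, cfg.seed + 1
            )
            if emb is not None
            else None,
            "postembryonic_within": _comparison(
                "postembryonic_within_fraction", post, c, cfg.n_trials, cfg.seed + 2
            )
            if post is not None
            else None,
        },
        "frac_pairs_within_200min": _comparison(
            "frac_pairs_within_200min",
            METRICS["frac_pairs_within_200min"](c),
            c,
            cfg.n_trials,
            cfg.seed + 3,
        ),
        "degree_birth_correlation": _comparison(
            "degree_birth_correlation",
            degree_birth_correlation(c),
            c,
            cfg.n_trials,
            cfg.seed + 4,
        ),
        "hub_reports": hubs,
        "bilateral_timing": {
            "n_pairs": len(bilateral_timing(c)),
            "max_delta_min": max((d for _, d in bilateral_timing(c)), default=None),
        },
        "type_growth_curves": type_growth_curves(c),
    }
    try:
        block["hub30_prehatch_fraction"] = _comparison(
            "hub30_prehatch_fraction",
            METRICS["hub30_prehatch_fraction"](c),
            c,
            cfg.n_trials,
            cfg.seed + 5,
        )
    except ValueError:
        block["hub30_prehatch_fraction"] = None
    return block


def _spatial_block(c: Connectome, cfg: RunConfig) -> dict[str, Any]:
    curves = appearance_curves(c, classifier=cfg.classifier)
    block: dict[str, Any] = {
        "class_counts": class_counts(c, cfg.classifier),
        "appearance_curves": {
            name: dataclasses.asdict(curve) for name, curve in curves.items()
        },
        "synapse_breakdown": [
            {"synapse_kind": k, "length_class": cls, "phase": ph, "count": v}
            for (k, cls, ph), v in sorted(
                synapse_breakdown(c, cfg.classifier).items()
            )
        ],
        "region_connectivity": region_connectivity(c),
        "prehatch_pct": {},
    }
    for cls in ("short", "medium", "long"):
        name = f"prehatch_pct_{cls}"
        try:
            block["prehatch_pct"][cls] = _comparison(
                name, METRICS[name](c), c, cfg.n_trials, cfg.seed + 6
            )
        except ValueError:
            block["prehatch_pct"][cls] = None
    try:
        r_short, r_long = degree_length_correlations(c, cfg.classifier)
        block["degree_length_correlations"] = {"short": r_short, "long": r_long}
    except ValueError as exc:
        block["degree_length_correlations"] = {"error": str(exc)}
    return block


def _circuits_block(c: Connectome, cfg: RunConfig) -> dict[str, Any]:
    return {
        "curves": {
            name: dataclasses.asdict(curve)
            for name, curve in circuit_curves(c).items()
        }
    }


def _topology_block(c: Connectome, cfg: RunConfig) -> dict[str, Any]:
    reports = small_world_series(
        c, n_random=max(cfg.n_trials, 2), seed=cfg.seed + 7
    )
    return {"stages": [dataclasses.asdict(r) for r in reports]}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the enabled analyses and return (and optionally write) the report."""
    t0 = time.perf_counter()
    connectome = _obtain_connectome(config)
    logger.info(
        "connectome ready: %d neurons, %d links (%.2fs)",
        connectome.n_neurons,
        connectome.n_connections,
        time.perf_counter() - t0,
    )
    report: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "n_trials": config.n_trials,
            "source": (
                "synthetic" if config.synth is not None else str(config.neuron_csv)
            ),
            "n_neurons": connectome.n_neurons,
            "n_connections": connectome.n_connections,
            "stage_times": list(connectome.config.stage_times),
            "hatch_time": connectome.config.hatch_time,
        },
        "analyses": {},
    }
    runners = {
        "temporal": _temporal_block,
        "spatial": _spatial_block,
        "circuits": _circuits_block,
        "topology": _topology_block,
    }
    for name in config.analyses:
        t1 = time.perf_counter()
        try:
            report["analyses"][name] = runners[name](connectome, config)
        except Exception as exc:
            raise PipelineError(f"analysis stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t1)
    validate_report(report)
    if config.output_dir is not None:
        _write_outputs(connectome, report, config)
    return report


def _write_outputs(c: Connectome, report: Mapping[str, Any], cfg: RunConfig) -> None:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    # per-connection table
    births = {nid: n.birth_time for nid, n in c.neurons.items()}
    rows = []
    for conn, d in zip(c.connections, connection_lengths(c)):
        early = (
            births[conn.pre] < c.config.hatch_time
            and births[conn.post] < c.config.hatch_time
        )
        rows.append(
            {
                "pre": conn.pre,
                "post": conn.post,
                "length_mm": float(d),
                "length_class": classify_length(float(d), cfg.classifier),
                "synapse_kind": conn.synapse_kind,
                "directedness": conn.directedness,
                "phase": "early" if early else "late",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "connections.csv", index=False)
    analyses = report["analyses"]
    if "topology" in analyses:
        pd.DataFrame(analyses["topology"]["stages"]).to_csv(
            outdir / "topology.csv", index=False
        )
    if "spatial" in analyses:
        pd.DataFrame(analyses["spatial"]["synapse_breakdown"]).to_csv(
            outdir / "synapse_breakdown.csv", index=False
        )
        curve_rows = [
            {"class": name, "stage_time": t, "percent": p}
            for name, curve in analyses["spatial"]["appearance_curves"].items()
            for t, p in zip(curve["stage_times"], curve["percentages"])
        ]
        pd.DataFrame(curve_rows).to_csv(outdir / "appearance_curves.csv", index=False)
    if "circuits" in analyses:
        curve_rows = [
            {"circuit": name, "stage_time": t, "percent": p}
            for name, curve in analyses["circuits"]["curves"].items()
            for t, p in zip(curve["stage_times"], curve["percentages"])
        ]
        pd.DataFrame(curve_rows).to_csv(outdir / "circuit_curves.csv", index=False)
    if "temporal" in analyses:
        hub_rows = [
            {
                "threshold": thr,
                "comparator": rep["comparator"],
                "id": m[0],
                "degree": m[1],
                "birth_time": m[2],
                "n_late_neighbors": m[3],
            }
            for thr, rep in analyses["temporal"]["hub_reports"].items()
            for m in rep["members"]
        ]
        pd.DataFrame(hub_rows).to_csv(outdir / "hubs.csv", index=False)


# -- report schema -----------------------------------------------------------


def load_report_schema() -> dict[str, Any]:
    """The shipped JSON-schema document for the run report."""
    text = resources.files("wormdev").joinpath("report_schema.json").read_text("utf-8")
    return json.loads(text)


def validate_report(report: Mapping[str, Any]) -> None:
    """Structural validation of a run report against the shipped schema.

    Covers the subset of JSON-schema used by the document: required keys
    and primitive types at the top two levels.
    """
    schema = load_report_schema()
    _check(report, schema, path="report")


def _check(obj: Any, schema: Mapping[str, Any], path: str) -> None:
    typ = schema.get("type")
    if typ == "object":
        if not isinstance(obj, Mapping):
            raise ValueError(f"{path}: expected object")
        for key in schema.get("required", []):
            if key not in obj:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj and obj[key] is not None:
                _check(obj[key], sub, f"{path}.{key}")
    elif typ == "array":
        if not isinstance(obj, Sequence) or isinstance(obj, (str, bytes)):
            raise ValueError(f"{path}: expected array")
    elif typ == "number":
        if not isinstance(obj, (int, float)):
            raise ValueError(f"{path}: expected number")
    elif typ == "string":
        if not isinstance(obj, str):
            raise ValueError(f"{path}: expected string")
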