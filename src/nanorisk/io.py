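"""File formats and the end-to-end pipeline runner.

Canonical on-disk network format is JSON (variables, states, bin edges,
edges, CPTs, tags, experience counts), written with sorted keys so equal
networks serialize to identical bytes. XMLBIF export/import is provided
for interoperability with standard BN software; it preserves structure and
CPTs but not bin edges, tags or experience (XMLBIF has no slots for them),
so round-tripping through XMLBIF yields a categorical-only network with
identical posteriors.

Case tables are CSV: header row of variable names, empty field = missing.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .learning import ExperienceTable, em_fit, update_with_cases
from .materials import MATERIALS, build_material_network
from .network import CPT, NetworkSpec, VariableSpec, validate_network
from .risk import (
    DiscreteDistribution,
    DoseResponseConfig,
    concentration_distribution,
    derive_oel,
    hazard_quotient,
    heatmap_point,
    oel_distribution,
    render_heatmap,
)

log = logging.getLogger("nanorisk")


# ---------------------------------------------------------------------------
# network JSON


def network_to_dict(net: NetworkSpec) -> dict:
    return {
        "name": net.name,
        "variables": [
            {
                "name": v.name,
                "kind": v.kind,
                "states": list(v.states),
                "tag": v.tag,
                **({"bin_edges": list(v.bin_edges)} if v.bin_edges else {}),
            }
            for v in net.variables
        ],
        "edges": [[p, c] for p, c in net.edges],
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "table": [[float(x) for x in row] for row in cpt.table],
            }
            for name, cpt in net.cpts.items()
        },
        "experience": {
            name: [float(x) for x in counts]
            for name, counts in net.experience.items()
        },
    }


def _require(cond: bool, where: str, msg: str) -> None:
    if not cond:
        raise DataError(f"network file, {where}: {msg}")


def network_from_dict(doc: dict) -> NetworkSpec:
    """Parse and validate a network document, with field-level diagnostics."""
    _require(isinstance(doc, dict), "top level", "expected a JSON object")
    for key in ("variables", "edges"):
        _require(key in doc, "top level", f"missing required field {key!r}")
    _require(isinstance(doc["variables"], list), "variables", "expected a list")

    variables = []
    for i, v in enumerate(doc["variables"]):
        where = f"variables[{i}]"
        _require(isinstance(v, dict), where, "expected an object")
        for key in ("name", "states"):
            _require(key in v, where, f"missing required field {key!r}")
        variables.append(
            VariableSpec(
                name=v["name"],
                states=tuple(v["states"]),
                kind=v.get("kind", "categorical"),
                bin_edges=tuple(v["bin_edges"]) if v.get("bin_edges") else None,
                tag=v.get("tag", "physicochemical"),
            )
        )
    edges = []
    for i, e in enumerate(doc["edges"]):
        _require(
            isinstance(e, (list, tuple)) and len(e) == 2,
            f"edges[{i}]",
            "expected a [parent, child] pair",
        )
        edges.append((e[0], e[1]))
    cpts = {}
    for name, c in doc.get("cpts", {}).items():
        where = f"cpts[{name!r}]"
        _require(isinstance(c, dict) and "table" in c, where, "missing 'table'")
        cpts[name] = CPT(name, tuple(c.get("parents", ())), np.asarray(c["table"], float))
    experience = {
        name: np.asarray(vals, float)
        for name, vals in doc.get("experience", {}).items()
    }
    spec = NetworkSpec(
        name=doc.get("name", "network"),
        variables=variables,
        edges=edges,
        cpts=cpts,
        experience=experience,
    )
    return validate_network(spec)


def write_network(net: NetworkSpec, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(net), indent=2, sort_keys=True) + "\n"
    )


def read_network(path: str | Path) -> NetworkSpec:
    try:
        doc = json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise ConfigError(f"network file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise DataError(f"network file {path}: invalid JSON ({exc})") from None
    return network_from_dict(doc)


# ---------------------------------------------------------------------------
# XMLBIF


def write_xmlbif(net: NetworkSpec, path: str | Path) -> None:
    """Export structure and CPTs in XMLBIF 0.3.

    Table entries are row-major over parent configurations in declared
    parent order, child state varying fastest.
    """
    bif = ET.Element("BIF", VERSION="0.3")
    network = ET.SubElement(bif, "NETWORK")
    ET.SubElement(network, "NAME").text = net.name
    for v in net.variables:
        var = ET.SubElement(network, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = v.name
        for s in v.states:
            ET.SubElement(var, "OUTCOME").text = s
    for name in net.names:
        cpt = net.cpts[name]
        definition = ET.SubElement(network, "DEFINITION")
        ET.SubElement(definition, "FOR").text = name
        for p in cpt.parents:
            ET.SubElement(definition, "GIVEN").text = p
        ET.SubElement(definition, "TABLE").text = " ".join(
            repr(float(x)) for x in cpt.table.ravel()
        )
    ET.indent(bif)
    ET.ElementTree(bif).write(path, encoding="unicode", xml_declaration=True)


def read_xmlbif(path: str | Path) -> NetworkSpec:
    """Import an XMLBIF 0.3 file as a categorical network."""
    try:
        root = ET.parse(path).getroot()
    except (FileNotFoundError, ET.ParseError) as exc:
        raise DataError(f"XMLBIF file {path}: {exc}") from None
    network = root.find("NETWORK")
    _require(network is not None, "XMLBIF", "no NETWORK element")
    name_el = network.find("NAME")
    variables = []
    for var in network.findall("VARIABLE"):
        vname = var.findtext("NAME")
        states = tuple(o.text for o in var.findall("OUTCOME"))
        variables.append(VariableSpec(vname, states))
    cpts = {}
    edges = []
    for definition in network.findall("DEFINITION"):
        child = definition.findtext("FOR")
        parents = tuple(g.text for g in definition.findall("GIVEN"))
        values = np.array(definition.findtext("TABLE").split(), dtype=float)
        cards = {v.name: len(v.states) for v in variables}
        n_cfg = int(np.prod([cards[p] for p in parents], dtype=int)) if parents else 1
        cpts[child] = CPT(child, parents, values.reshape(n_cfg, cards[child]))
        edges.extend((p, child) for p in parents)
    spec = NetworkSpec(
        name=name_el.text if name_el is not None else "network",
        variables=variables,
        edges=edges,
        cpts=cpts,
    )
    return validate_network(spec)


# ---------------------------------------------------------------------------
# case CSV


def read_cases(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise ConfigError(f"case file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise DataError(f"case file {path}: {exc}") from None
    return df.replace("", np.nan)


def write_cases(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# run configuration and the 4-step pipeline


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a JSON file."""

    network: str | None = None
    material: str | None = "CNT"
    cases: list[str] = field(default_factory=list)
    learn: str | None = None  # None | "em" | "update"
    evidence: dict[str, str] = field(default_factory=dict)
    dose_response: dict | None = None
    oel_source: str = "auto"  # auto | config | network
    prior_strength: float = 1.0
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    output: str | None = None
    heatmap: str | None = None
    fitted_network_out: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            doc = json.loads(Path(path).read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file {path}: invalid JSON ({exc})") from None
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.network is None and self.material is None:
            raise ConfigError("config needs a network path or a material")
        if self.material is not None and self.network is None and self.material not in MATERIALS:
            raise ConfigError(f"unknown material {self.material!r}")
        if self.learn not in (None, "em", "update"):
            raise ConfigError(f"learn must be null, 'em' or 'update', got {self.learn!r}")
        if self.oel_source not in ("auto", "config", "network"):
            raise ConfigError(f"bad oel_source {self.oel_source!r}")
        if not (self.prior_strength >= 0 and self.tol > 0 and self.max_iter >= 1):
            raise ConfigError("EM settings out of range")
        if self.learn and not self.cases:
            raise ConfigError("learning requested but no case tables given")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full 4-step risk characterization and return the report.

    Stages: validate → (optional) EM fit or experience update → exposure
    posterior → OEL derivation → hazard-quotient forecast → control band →
    heat-map coordinates. Deterministic given the config (including seed);
    every stage is logged with its parameters.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stages: list[str] = []
    report: dict = {"config_seed": cfg.seed, "stages": stages}

    # 1. hazard identification: the network of physicochemical characteristics
    if cfg.network:
        net = read_network(cfg.network)
    else:
        net = build_material_network(cfg.material)
    log.info("stage=validate network=%r variables=%d", net.name, len(net.variables))
    stages.append("validate")
    report["network"] = net.name

    # optional learning
    if cfg.learn:
        tables = [read_cases(p) for p in cfg.cases]
        cases = pd.concat(tables, ignore_index=True) if len(tables) > 1 else tables[0]
        if cfg.learn == "em":
            log.info(
                "stage=em_fit rows=%d prior_strength=%g tol=%g max_iter=%d seed=%d",
                len(cases), cfg.prior_strength, cfg.tol, cfg.max_iter, cfg.seed,
            )
            fit = em_fit(
                net, cases,
                prior_strength=cfg.prior_strength,
                tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed,
            )
            net = fit.network
            report["fit"] = {
                "n_iter": fit.n_iter,
                "converged": fit.converged,
                "final_objective": fit.loglik_trace[-1],
            }
            stages.append("em_fit")
        else:
            exp = ExperienceTable(
                {k: np.asarray(v) for k, v in net.experience.items()}
            ) if net.experience else None
            log.info("stage=update rows=%d", len(cases))
            net, new_exp = update_with_cases(net, exp, cases)
            report["update"] = {
                "total_experience": {n: new_exp.total(n) for n in net.names}
            }
            stages.append("update")
        if cfg.fitted_network_out:
            write_network(net, cfg.fitted_network_out)

    # 2. exposure assessment
    log.info("stage=exposure evidence=%r", cfg.evidence)
    exposure = concentration_distribution(net, cfg.evidence or None)
    stages.append("exposure")

    # 3. dose-response assessment
    oel_source = cfg.oel_source
    if oel_source == "auto":
        oel_source = "config" if cfg.dose_response else "network"
    if oel_source == "config":
        if not cfg.dose_response:
            raise ConfigError("oel_source='config' but no dose_response settings")
        dr = DoseResponseConfig(**cfg.dose_response)
        oel_value = derive_oel(dr)
        oel_dist = DiscreteDistribution.point(oel_value)
        report["oel"] = {
            "source": "dose_response_config",
            "mode": dr.effective_mode,
            "pod_kind": dr.pod_kind,
            "point_of_departure_ugm3": dr.point_of_departure,
            "uncertainty_factor": dr.uncertainty_factor,
            "oel_ugm3": oel_value,
        }
        log.info("stage=dose_response mode=%s oel=%g ug/m3", dr.effective_mode, oel_value)
    else:
        oel_dist = oel_distribution(net, cfg.evidence or None)
        report["oel"] = {"source": "network_posterior", "mean_oel_ugm3": oel_dist.mean}
        log.info("stage=dose_response source=network mean_oel=%g", oel_dist.mean)
    stages.append("dose_response")

    # 4. risk characterization
    forecast = hazard_quotient(exposure, oel_dist)
    point = heatmap_point(forecast, label=report["network"])
    # HQ and margin of exposure are used synonymously here (exposure / OEL)
    report["forecast"] = forecast.to_dict()
    report["forecast"]["margin_of_exposure_percent"] = forecast.mean_hq
    report["heatmap"] = point.to_dict()
    stages.append("risk")
    log.info(
        "stage=risk mean_hq=%.2f%% interval_90=(%.2f, %.2f) band=%s",
        forecast.mean_hq, *forecast.interval_90, forecast.band,
    )

    if cfg.heatmap:
        render_heatmap([point], cfg.heatmap)
        report["heatmap_png"] = cfg.heatmap
    if cfg.output:
        Path(cfg.output).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
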