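"""End-to-end pipeline orchestration.

A single :class:`RunConfig` describes a run — where the data come from
(a trait CSV or a synthetic configuration), the significance level,
the bootstrap, rarefaction and group-comparison settings — and
:func:`run_pipeline` executes the stages into a deterministic output
directory:

``networks/``   edge list + GraphML and correlation matrices
``metrics/``    per-trait degree/module CSV and scalar JSON
``summaries/``  bootstrap and rarefaction summary tables
``tests/``      Duncan letter tables and between-group t-tests
``figures/``    plots, each with a CSV twin of the plotted numbers

The run's configuration is copied into the directory for provenance,
and rerunning with the same config and seed reproduces every CSV
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _plots
from .compare import compare_group_ptns, duncan_mrt
from .metrics import compute_metrics, hub_traits, importance
from .network import build_network, write_correlations, write_edge_list, write_graphml
from .resampling import bootstrap_ptn, rarefaction, summaries_frame
from .synthetic import SyntheticConfig, generate, write_ground_truth
from .trait_data import log_transform, read_trait_table, write_trait_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML/JSON."""

    input: str | None = None                  # trait CSV path, or None to simulate
    schema: dict | None = None                # column-role mapping for the CSV
    synthetic: SyntheticConfig | None = None  # used when input is None
    alpha: float = 0.05
    bootstrap_B: int = 1000
    fraction_min: float = 0.75
    rarefaction_counts: list[int] | None = None
    rarefaction_R: int = 500
    with_replacement: bool = True
    community_method: str = "greedy"
    group_by: str | None = None               # "life_form" | "aridity" | None
    aridity_boundary: float = 0.2
    seed: int = 0
    outdir: str = "ptn_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    t0 = time.perf_counter()
    out = Path(config.outdir)
    for sub in ("networks", "metrics", "summaries", "tests", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "config.yaml")
    log: dict = {"seed": config.seed, "stages": {}}

    # -- input ------------------------------------------------------------
    if config.input is not None:
        m_raw = read_trait_table(config.input, schema=config.schema)
        logger.info("read %d records x %d traits from %s",
                    m_raw.n_records, m_raw.n_traits, config.input)
    elif config.synthetic is not None:
        m_raw = generate(config.synthetic)
        write_trait_table(m_raw, out / "simulated_traits.csv")
        write_ground_truth(config.synthetic, out / "ground_truth.json")
    else:
        raise ValueError("config needs either an input path or a synthetic config")
    m = log_transform(m_raw)
    log["n_records"], log["n_traits"] = m.n_records, m.n_traits

    # -- network + metrics ------------------------------------------------
    net = build_network(m, alpha=config.alpha)
    met = compute_metrics(net, method=config.community_method, seed=config.seed)
    write_edge_list(net, out / "networks" / "edges.csv")
    write_graphml(net, out / "networks" / "network.graphml")
    write_correlations(net.source, out / "networks" / "correlation_r.csv",
                       out / "networks" / "correlation_p.csv")
    met.to_frame().to_csv(out / "metrics" / "trait_metrics.csv", index=False)
    scal = met.scalars()
    scal["hub_trait"] = hub_traits(met, k=1)[0][0]
    (out / "metrics" / "network_scalars.json").write_text(
        json.dumps(scal, indent=2, sort_keys=True)
    )
    imp = None
    if m.categories:
        imp = importance(met, m.categories)
        imp.to_frame().to_csv(out / "metrics" / "importance.csv", index=False)

    # -- bootstrap ---------------------------------------------------------
    boot = bootstrap_ptn(
        m, B=config.bootstrap_B, fraction_min=config.fraction_min,
        alpha=config.alpha, seed=config.seed, method=config.community_method,
    )
    summaries_frame(boot).to_csv(out / "summaries" / "bootstrap.csv", index=False)
    deg_letters = duncan_mrt(
        {t: boot[f"degree[{t}]"].replicates for t in m.trait_names},
        alpha=config.alpha,
    )
    deg_letters.to_frame().to_csv(out / "tests" / "degree_letters.csv", index=False)
    log["stages"]["bootstrap"] = {"B": config.bootstrap_B}

    # -- rarefaction -------------------------------------------------------
    curve = None
    if config.rarefaction_counts:
        curve = rarefaction(
            m, counts=config.rarefaction_counts, R=config.rarefaction_R,
            alpha=config.alpha, seed=config.seed,
            with_replacement=config.with_replacement,
            method=config.community_method,
        )
        curve.to_frame().to_csv(out / "summaries" / "rarefaction.csv", index=False)
        log["stages"]["rarefaction"] = {
            "counts": curve.species_counts, "R": config.rarefaction_R,
        }

    # -- group comparison --------------------------------------------------
    report = None
    if config.group_by:
        report = compare_group_ptns(
            m, variable=config.group_by, aridity_boundary=config.aridity_boundary,
            B=config.bootstrap_B, fraction_min=config.fraction_min,
            alpha=config.alpha, seed=config.seed, method=config.community_method,
        )
        for lab, g in report.groups.items():
            gdir = out / "groups" / lab
            gdir.mkdir(parents=True, exist_ok=True)
            write_edge_list(g.network, gdir / "edges.csv")
            write_graphml(g.network, gdir / "network.graphml")
            g.metrics.to_frame().to_csv(gdir / "trait_metrics.csv", index=False)
            summaries_frame(g.bootstrap).to_csv(gdir / "bootstrap.csv", index=False)
            if g.importance is not None:
                g.importance.to_frame().to_csv(gdir / "importance.csv", index=False)
            if g.duncan_degree is not None:
                g.duncan_degree.to_frame().to_csv(gdir / "degree_letters.csv",
                                                  index=False)
            if g.duncan_importance is not None:
                g.duncan_importance.to_frame().to_csv(
                    gdir / "importance_letters.csv", index=False)
        if report.tests:
            report.tests_frame().to_csv(out / "tests" / "group_tests.csv",
                                        index=False)
        log["stages"]["compare"] = {"groups": sorted(report.groups)}

    # -- figures -----------------------------------------------------------
    _plots.plot_network(net, met, out / "figures" / "network.png",
                        seed=config.seed)
    _plots.plot_degree_bars(boot, m.trait_names,
                            out / "figures" / "degree_bars.png",
                            letters=deg_letters)
    if imp is not None:
        _plots.plot_importance_bars(imp.to_frame(),
                                    out / "figures" / "importance.png")
    if curve is not None:
        _plots.plot_rarefaction(curve, out / "figures" / "rarefaction.png")

    # -- manifest + log ----------------------------------------------------
    manifest = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name not in ("manifest.json", "run_log.json")
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log["elapsed_s"] = round(time.perf_counter() - t0, 3)
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
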