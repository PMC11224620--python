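"""Config-driven pipeline: simulate/load -> score -> validate -> report.

A run is described by a single YAML/JSON mapping (see
:class:`RunConfig`), validated before any computation.  Each data role
(network, module, DEG tables) comes either from input files or from
the built-in simulator — exactly one source per role.  All artifacts
are written under one output directory:

``ranking.tsv``
    Genome-wide hub ranking (gene, xbar, mu, sigma, n, z, rank, flag).
``curve.tsv``
    Rank-enrichment curve (cutoff, hits, fold).
``report.json`` / ``report.md``
    Machine- and human-readable run report.  The JSON report contains
    the resolved config (every default materialized), the seed and a
    file manifest with checksums, so a run can be reproduced exactly
    from the report alone.
``truth.json``
    Generator ground truth (simulated runs only).
``run.log``
    One line per stage with input/output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import pair_connectivity_rank, rank_module_hubs
from .net_io import (
    DEGTable,
    FunctionalNetwork,
    GeneModule,
    read_deg_table,
    read_gmt,
    read_network,
    write_deg_table,
    write_gmt,
    write_network,
)
from .synthetic import GeneratorParams, generate_network, generate_paired_degs, generate_perturbation_degs
from .validation import (
    deg_connectivity_test,
    fisher_overlap,
    rank_enrichment_curve,
    signed_overlap,
)

__all__ = ["RunConfig", "run", "report_render", "load_config"]

log = logging.getLogger("modhub")

_KNOWN_KEYS = {
    "network",
    "network_format",
    "modules",
    "module_name",
    "deg",
    "deg2",
    "simulate",
    "hub",
    "min_module_size",
    "z_denominator",
    "threshold",
    "cutoff",
    "include_module_members",
    "top_k",
    "out_dir",
    "overwrite",
    "seed",
    "log_level",
    "pair_rank",
}


@dataclass
class RunConfig:
    """Validated run configuration with every default materialized."""

    out_dir: str
    network: str | None = None
    network_format: str = "edge_list"
    modules: str | None = None
    module_name: str | None = None
    deg: str | None = None
    deg2: str | None = None
    simulate: dict | None = None
    hub: str | None = None
    min_module_size: int = 3
    z_denominator: str = "se"
    threshold: str = "padj"
    cutoff: float = 0.05
    include_module_members: bool = True
    top_k: int = 25
    overwrite: bool = False
    seed: int = 0
    log_level: str = "INFO"
    pair_rank: list = field(default_factory=list)  # list of [query, target]

    def validate(self) -> None:
        simulated = self.simulate is not None
        if simulated and (self.network or self.modules or self.deg):
            raise ValueError(
                "config must use either 'simulate' or input paths, not both"
            )
        if not simulated:
            if not (self.network and self.modules and self.deg):
                raise ValueError(
                    "file-based run requires 'network', 'modules' and 'deg' paths"
                )
            for p in filter(None, (self.network, self.modules, self.deg, self.deg2)):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        if self.z_denominator not in ("se", "sd_over_n"):
            raise ValueError("z_denominator must be 'se' or 'sd_over_n'")
        if self.threshold not in ("padj", "pvalue"):
            raise ValueError("threshold must be 'padj' or 'pvalue'")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, out: Path):
    """Return (net, module, deg table, optional second table, truth)."""
    if cfg.simulate is not None:
        params = GeneratorParams(**{**cfg.simulate, "seed": cfg.seed})
        net, truth = generate_network(params)
        if cfg.deg2 == "paired":
            degs, degs2 = generate_paired_degs(
                net, truth, params, seed2=cfg.seed + 1
            )
        else:
            degs, truth = generate_perturbation_degs(net, truth, params)
            degs2 = None
        module = truth.module
        write_network(net, out / "network.tsv")
        write_gmt([module], out / "modules.gmt")
        write_deg_table(degs, out / "degs.tsv")
        if degs2 is not None:
            write_deg_table(degs2, out / "degs2.tsv")
        (out / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1, sort_keys=True)
        )
        return net, module, degs, degs2, truth

    net = read_network(cfg.network, cfg.network_format)
    modules = {m.name: m for m in read_gmt(cfg.modules)}
    name = cfg.module_name or next(iter(modules))
    if name not in modules:
        raise ValueError(f"module {name!r} not found in {cfg.modules}")
    degs = read_deg_table(cfg.deg)
    degs2 = read_deg_table(cfg.deg2) if cfg.deg2 and cfg.deg2 != "paired" else None
    return net, modules[name], degs, degs2, None


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline and return the report dict (also written)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty (set overwrite: true)"
        )
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(cfg.log_level)

    try:
        net, module, degs, degs2, truth = _load_inputs(cfg, out)
        log.info(
            "stage=load n_genes=%d module=%s module_size=%d degs=%d",
            net.n_genes,
            module.name,
            len(module),
            len(degs),
        )

        ranking = rank_module_hubs(
            net,
            module,
            include_module_members=cfg.include_module_members,
            min_module_size=cfg.min_module_size,
            z_denominator=cfg.z_denominator,
        )
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.10g")
        log.info("stage=score checksum=%s", _sha256(out / "ranking.tsv"))

        scored = ranking[ranking["flag"] == ""]
        hub = cfg.hub
        if hub is None:
            non_module = scored[~scored["in_module"]]
            hub = str(non_module.iloc[0]["gene"]) if len(non_module) else str(
                scored.iloc[0]["gene"]
            )
        hub_row = ranking[ranking["gene"] == hub]
        if hub_row.empty:
            raise ValueError(f"hub {hub!r} not present in ranking")

        validation: dict = {"hub": hub, "threshold": cfg.threshold, "cutoff": cfg.cutoff}
        try:
            rs = deg_connectivity_test(
                net, hub, degs, threshold=cfg.threshold, cutoff=cfg.cutoff
            )
            validation["deg_connectivity"] = asdict(rs)
        except ValueError as exc:
            validation["deg_connectivity"] = {"error": str(exc)}
        try:
            universe = frozenset(net.genes) & degs.tested(cfg.threshold) - {hub}
            fo = fisher_overlap(
                module.members & universe,
                degs.significant(cfg.threshold, cfg.cutoff) & universe,
                universe,
            )
            validation["module_deg_overlap"] = asdict(fo)
        except ValueError as exc:
            validation["module_deg_overlap"] = {"error": str(exc)}
        try:
            curve = rank_enrichment_curve(
                net, hub, degs, threshold=cfg.threshold, cutoff=cfg.cutoff
            )
            pd.DataFrame(
                {"cutoff": curve.cutoffs, "hits": curve.hits, "fold": curve.fold}
            ).to_csv(out / "curve.tsv", sep="\t", index=False, float_format="%.10g")
            validation["enrichment_curve"] = {
                "n_deg": curve.n_deg,
                "universe_size": curve.universe_size,
                "fold_top_decile": float(
                    curve.fold[
                        np.searchsorted(
                            curve.cutoffs, max(1, curve.universe_size // 10)
                        )
                    ]
                ),
                "rug": [int(r) for r in curve.rug[:200]],
            }
            log.info("stage=curve checksum=%s", _sha256(out / "curve.tsv"))
        except ValueError as exc:
            validation["enrichment_curve"] = {"error": str(exc)}
        if degs2 is not None:
            so = signed_overlap(
                degs, degs2, threshold=cfg.threshold, cutoff=cfg.cutoff
            )
            validation["signed_overlap"] = {
                "up": asdict(so.up),
                "down": asdict(so.down),
                "concordant": asdict(so.concordant),
                "n_discordant": so.n_discordant,
            }

        pair_queries = []
        for query, target in cfg.pair_rank:
            wgt, rnk, total = pair_connectivity_rank(net, query, target)
            pair_queries.append(
                {"query": query, "target": target, "weight": wgt, "rank": rnk, "total": total}
            )

        top = ranking.head(cfg.top_k)
        report = {
            "version": __version__,
            "config": asdict(cfg),
            "hub": hub,
            "hub_rank": None
            if pd.isna(hub_row.iloc[0]["rank"])
            else int(hub_row.iloc[0]["rank"]),
            "hub_z": None
            if pd.isna(hub_row.iloc[0]["z"])
            else float(hub_row.iloc[0]["z"]),
            "top_hubs": top.to_dict(orient="records"),
            "pair_rank": pair_queries,
            "validation": validation,
            "n_genes": net.n_genes,
            "module": module.name,
            "module_size": len(module),
            "note": (
                "p-values are reported raw, each with its own settings; no "
                "multiple-testing correction is applied across the report's tests"
            ),
        }
        if truth is not None:
            report["truth_hub"] = truth.hub
            report["hub_matches_truth"] = truth.hub == hub

        manifest = {}
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name not in ("report.json", "report.md", "run.log"):
                manifest[f.name] = _sha256(f)
        report["manifest"] = manifest

        payload = dict(report)
        payload["timestamp"] = datetime.now(timezone.utc).isoformat()
        (out / "report.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
        )
        (out / "report.md").write_text(report_render(report))
        log.info("stage=report checksum=%s", _sha256(out / "report.json"))
        return report
    finally:
        log.removeHandler(fh)
        fh.close()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "NA"
    return f"{p:.3g}"


def report_render(report: dict) -> str:
    """Deterministic human-readable (markdown) rendering of a report."""
    lines = [
        "# modhub run report",
        "",
        f"- version: {report['version']}",
        f"- seed: {report['config']['seed']}",
        f"- z denominator: **{report['config']['z_denominator']}** "
        "(standard error sigma/sqrt(n) when 'se'; sigma/n otherwise)",
        f"- DEG threshold: **{report['config']['threshold']} < "
        f"{report['config']['cutoff']}**",
        "",
        "## Hub",
        "",
        f"- module: {report['module']} ({report['module_size']} genes)",
        f"- hub gene: **{report['hub']}** (z = "
        f"{_fmt_p(report['hub_z'])}, rank {report['hub_rank']})",
    ]
    if "truth_hub" in report:
        match = "matches" if report["hub_matches_truth"] else "does NOT match"
        lines.append(f"- planted hub: {report['truth_hub']} ({match} the top hub)")
    v = report["validation"]
    lines += ["", "## Validation", ""]
    dc = v.get("deg_connectivity", {})
    if "error" in dc:
        lines.append(f"- DEG-connectivity rank-sum: error — {dc['error']}")
    else:
        signif = "significant" if dc["pvalue"] < 0.05 else "non-significant"
        lines.append(
            f"- DEG-connectivity rank-sum ({dc['method']}): one-sided p = "
            f"{_fmt_p(dc['pvalue'])} ({signif}); {dc['n_deg']} DEGs vs "
            f"{dc['n_nondeg']} non-DEGs; median connectivity "
            f"{dc['median_deg']:.3g} vs {dc['median_nondeg']:.3g}"
        )
    mo = v.get("module_deg_overlap", {})
    if "error" in mo:
        lines.append(f"- module-DEG Fisher overlap: error — {mo['error']}")
    else:
        signif = "significant" if mo["pvalue"] < 0.05 else "non-significant"
        lines.append(
            f"- module-DEG Fisher overlap: p = {_fmt_p(mo['pvalue'])} ({signif}), "
            f"odds ratio {mo['odds_ratio']:.3g}, overlap {mo['in_both']} of "
            f"universe {mo['universe_size']}"
        )
    ec = v.get("enrichment_curve", {})
    if ec and "error" not in ec:
        lines.append(
            f"- enrichment curve: fold {ec['fold_top_decile']:.3g} at the top "
            f"decile; {ec['n_deg']} DEGs in a universe of {ec['universe_size']}"
        )
    so = v.get("signed_overlap")
    if so:
        lines.append(
            f"- signed overlap: concordant p = {_fmt_p(so['concordant']['pvalue'])}, "
            f"up p = {_fmt_p(so['up']['pvalue'])}, down p = "
            f"{_fmt_p(so['down']['pvalue'])}, {so['n_discordant']} discordant"
        )
    for q in report["pair_rank"]:
        lines.append(
            f"- pair rank: {q['query']} -> {q['target']}: weight "
            f"{q['weight']:.3g}, rank {q['rank']} of {q['total']}"
        )
    flagged = [h for h in report["top_hubs"] if h.get("flag")]
    if flagged:
        lines += ["", "## Flagged genes", ""]
        for h in flagged:
            lines.append(f"- {h['gene']}: {h['flag']}")
    lines.append("")
    lines.append(report["note"])
    lines.append("")
    return "\n".join(lines)
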