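"""End-to-end analysis pipeline: rarefy -> diversity -> null models ->
NST / neutral fit -> niche breadth -> correlogram -> network.

A run is described by a :class:`RunConfig` (YAML-serialisable).  Every
stage derives its seed from the global seed and the stage name, so a
run is bit-reproducible and upstream results do not depend on
downstream parameters.  Optional stages that cannot run on the data at
hand (e.g. the network on too few taxa) are logged and skipped.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_data as cd
from . import diversity, networks, null_models, simulate, stochasticity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either the three input paths (``table``, ``tree``, ``metadata``) or
    ``simulate: true`` (generate the default simulated study) must be
    given.  ``group_column`` names the metadata column defining sample
    groups for the process classification, NST and per-group summaries.
    """

    output_dir: str = "assemblyscope_run"
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    simulate: bool = False
    simulate_args: dict = field(default_factory=dict)
    rarefy_depth: int | None = None
    group_column: str = "treatment"
    env_columns: list[str] = field(default_factory=lambda: ["pH", "NO3"])
    n_null: int = 999
    nst_metric: str = "bray_curtis"
    network_scan: tuple[float, float, float] = (0.5, 0.95, 0.01)
    n_random: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.network_scan = tuple(cfg.network_scan)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.validate_dict(), fh, sort_keys=True)

    def validate_dict(self) -> dict:
        d = asdict(self)
        d["network_scan"] = list(self.network_scan)
        return d

    def validate(self) -> None:
        if not self.simulate:
            for name in ("table", "tree", "metadata"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config needs either simulate: true or a {name} path")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        if self.rarefy_depth is not None and self.rarefy_depth <= 0:
            raise ValueError("rarefy_depth must be positive")
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99 for process classification")


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, status: str, seconds: float, **info) -> None:
        self.stages[stage] = {"status": status, "seconds": round(seconds, 3), **info}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "warnings": self.warnings,
                },
                fh, indent=2, default=str,
            )


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: CRC32 of the stage name mixed with the seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path, report: RunReport, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    report.outputs.append(str(path))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in fixed order; returns the run report.

    Hard failures of optional stages (network construction) are logged
    and skipped; failures of core stages propagate after being recorded.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.validate_dict())
    config.to_yaml(out / "config_used.yaml")
    report.outputs.append(str(out / "config_used.yaml"))

    # -- inputs --------------------------------------------------------
    t0 = time.time()
    if config.simulate:
        table, tree, meta = simulate.simulate_study(
            seed=stage_seed(config.seed, "simulate"), **config.simulate_args
        )
        cd.write_count_table(table, out / "table.tsv")
        cd.write_tree(tree, str(out / "tree.nwk"))
        meta.to_csv(out / "metadata.tsv", sep="\t")
        report.outputs += [str(out / p) for p in ("table.tsv", "tree.nwk", "metadata.tsv")]
    else:
        table = cd.read_count_table(config.table)
        tree = cd.read_tree(config.tree)
        meta = cd.read_metadata(config.metadata, sample_ids=table.sample_ids)
    report.record("load", "ok", time.time() - t0,
                  n_samples=table.n_samples, n_taxa=table.n_taxa)

    if config.group_column not in meta.columns:
        raise ValueError(f"group column {config.group_column!r} not in metadata")

    # -- rarefaction ---------------------------------------------------
    t0 = time.time()
    if config.rarefy_depth is not None:
        totals = table.data.sum(axis=1)
        if config.rarefy_depth > totals.max():
            raise ValueError(
                f"rarefy_depth {config.rarefy_depth} exceeds the largest sample "
                f"total ({int(totals.max())})"
            )
        table = cd.rarefy(table, config.rarefy_depth,
                          seed=stage_seed(config.seed, "rarefy"))
        meta = meta.loc[table.sample_ids]
        report.record("rarefy", "ok", time.time() - t0, depth=config.rarefy_depth,
                      n_samples=table.n_samples)
    else:
        report.record("rarefy", "skipped", 0.0)

    table, tree, match_log = cd.match_tree_table(table, tree)
    if match_log["dropped_taxa"] or match_log["dropped_tips"]:
        report.warnings.append(f"match_tree_table: {match_log}")

    groups = meta[config.group_column]
    group_map = {str(g): list(idx) for g, idx in groups.groupby(groups).groups.items()}

    # -- diversity -----------------------------------------------------
    t0 = time.time()
    alpha = diversity.alpha_diversity(table, tree)
    _write(alpha, out / "alpha_diversity.tsv", report, index_label="sample")
    bc = diversity.bray_curtis(table)
    bc.to_tsv(out / "bray_curtis.tsv")
    report.outputs.append(str(out / "bray_curtis.tsv"))
    bmntd = diversity.beta_mntd(table, tree)
    bmntd.to_tsv(out / "beta_mntd.tsv")
    report.outputs.append(str(out / "beta_mntd.tsv"))
    report.record("diversity", "ok", time.time() - t0)

    # -- null models & classification ---------------------------------
    t0 = time.time()
    nspec = null_models.NullEnsembleSpec(
        n_null=config.n_null, seed=stage_seed(config.seed, "null_models")
    )
    bnti = null_models.beta_nti(table, tree, nspec)
    bnti.to_tsv(out / "beta_nti.tsv")
    rc = null_models.raup_crick_bray(table, nspec)
    rc.to_tsv(out / "rc_bray.tsv")
    report.outputs += [str(out / "beta_nti.tsv"), str(out / "rc_bray.tsv")]

    processes = {}
    for gname, members in sorted(group_map.items()):
        pairs = [
            (members[i], members[j])
            for i in range(len(members)) for j in range(i + 1, len(members))
        ]
        summ = null_models.classify_processes(bnti, rc, pairs)
        processes[gname] = {
            "fractions": summ.fractions,
            "counts": summ.counts,
            "n_pairs": summ.n_pairs,
            "n_excluded": summ.n_excluded,
            "stochastic_fraction": summ.stochastic_fraction,
        }
    overall = null_models.classify_processes(bnti, rc)
    processes["__all__"] = {
        "fractions": overall.fractions,
        "counts": overall.counts,
        "n_pairs": overall.n_pairs,
        "n_excluded": overall.n_excluded,
        "stochastic_fraction": overall.stochastic_fraction,
    }
    with open(out / "processes.json", "w") as fh:
        json.dump({"seed": nspec.seed, "n_null": nspec.n_null,
                   "groups": processes}, fh, indent=2)
    report.outputs.append(str(out / "processes.json"))
    report.record("null_models", "ok", time.time() - t0, n_null=config.n_null)

    # -- NST -----------------------------------------------------------
    t0 = time.time()
    nst_spec = null_models.NullEnsembleSpec(
        n_null=min(config.n_null, 199), seed=stage_seed(config.seed, "nst")
    )
    nst_res = stochasticity.nst(table, group_map, metric=config.nst_metric,
                                spec=nst_spec)
    _write(nst_res.pairs, out / "nst_pairs.tsv", report, index=False)
    with open(out / "nst.json", "w") as fh:
        json.dump({"group_nst_percent": nst_res.group_nst,
                   "metric": nst_res.metric, "n_null": nst_res.n_null,
                   "seed": nst_res.seed}, fh, indent=2)
    report.outputs.append(str(out / "nst.json"))
    report.record("nst", "ok", time.time() - t0)

    # -- Sloan neutral fit --------------------------------------------
    t0 = time.time()
    try:
        fit = stochasticity.sloan_fit(table)
        _write(fit.taxa, out / "sloan_taxa.tsv", report, index_label="taxon")
        with open(out / "sloan_fit.json", "w") as fh:
            json.dump({"nm": fit.nm, "m": fit.m, "r2": fit.r2,
                       "fraction_inside": fit.fraction_inside,
                       "community_size": fit.community_size,
                       "detection_limit": fit.detection_limit}, fh, indent=2)
        report.outputs.append(str(out / "sloan_fit.json"))
        report.record("sloan", "ok", time.time() - t0, r2=round(fit.r2, 4))
    except (ValueError, RuntimeError) as exc:
        report.record("sloan", "failed", time.time() - t0, error=str(exc))
        report.warnings.append(f"sloan: {exc}")

    # -- niche breadth -------------------------------------------------
    t0 = time.time()
    nb = stochasticity.levins_breadth(table)
    _write(nb.per_taxon.to_frame(), out / "niche_breadth.tsv", report,
           index_label="taxon")
    report.record("niche_breadth", "ok", time.time() - t0, bcom=round(nb.bcom, 3))

    # -- phylogenetic-signal correlogram (one per group) --------------
    t0 = time.time()
    env_cols = [c for c in config.env_columns if c in meta.columns]
    if env_cols:
        corr_frames = []
        for gname, members in sorted(group_map.items()):
            sub = table.subset_samples(members).drop_empty_taxa()
            sub_matched, sub_tree, _ = cd.match_tree_table(sub, tree)
            corr = stochasticity.phylo_signal_correlogram(
                sub_matched, sub_tree, meta.loc[members, env_cols], n_perm=199,
                seed=stage_seed(config.seed, f"correlogram:{gname}"),
            )
            if corr.defined:
                frame = corr.classes.copy()
                frame.insert(0, "group", gname)
                corr_frames.append(frame)
            else:
                report.warnings.append(f"correlogram[{gname}]: undefined")
        if corr_frames:
            _write(pd.concat(corr_frames, ignore_index=True),
                   out / "correlogram.tsv", report, index=False)
            report.record("correlogram", "ok", time.time() - t0,
                          groups=len(corr_frames))
        else:
            report.record("correlogram", "undefined", time.time() - t0)
    else:
        report.record("correlogram", "skipped", 0.0,
                      reason="no env columns present")

    # -- co-association networks, one per group (optional stage) ------
    # each group is a sub-community with its own network, compared
    # against degree-preserving randomizations; groups too small for a
    # correlation network fall back to the whole table
    t0 = time.time()
    network_groups = {g: m for g, m in group_map.items() if len(m) >= 6}
    if not network_groups:
        network_groups = {"__all__": table.sample_ids}
    topo_frames, built = [], {}
    for gname, members in sorted(network_groups.items()):
        try:
            sub = table.subset_samples(members).drop_empty_taxa()
            prepared = networks.prepare_nodes(sub)
            corr_m = networks.correlation_matrix(prepared)
            st, trace = networks.rmt_threshold(corr_m, scan=config.network_scan)
            net = networks.build_network(corr_m, st)
            topo = networks.topology(net)
            try:
                topo.random_reference = networks.random_ensemble(
                    net, n=config.n_random,
                    seed=stage_seed(config.seed, f"network:{gname}"),
                )
            except ValueError as exc:
                report.warnings.append(f"network[{gname}] random ensemble: {exc}")
            frame = topo.to_table()
            frame.insert(0, "group", gname)
            topo_frames.append(frame)
            zp = networks.zi_pi(net)
            zp.insert(0, "group", gname)
            built[gname] = (net, zp)
        except ValueError as exc:
            report.warnings.append(f"network[{gname}]: {exc}")
    if built:
        _write(pd.concat(topo_frames, ignore_index=True),
               out / "network_topology.tsv", report, index=False)
        _write(pd.concat([zp for _, zp in built.values()]),
               out / "zi_pi.tsv", report)
        edges = pd.concat([
            pd.DataFrame(
                [(g, u, v, d["weight"], d["sign"])
                 for u, v, d in net.graph.edges(data=True)],
                columns=["group", "source", "target", "weight", "sign"],
            )
            for g, (net, _) in built.items()
        ], ignore_index=True)
        _write(edges, out / "network_edges.tsv", report, index=False)
        report.record("network", "ok", time.time() - t0,
                      groups=sorted(built))
    else:
        report.record("network", "skipped", time.time() - t0,
                      reason="no group yielded a network")

    report.save(out / "report.json")
    report.outputs.append(str(out / "report.json"))
    return report


def summarize(report: RunReport) -> dict[str, pd.DataFrame]:
    """Collect figure-analog summary tables from a completed run.

    Returns tidy frames: per-group process fractions, per-group NST,
    and the network topology record, omitting blocks whose stage did
    not complete.
    """
    out = Path(report.config["output_dir"])
    tables: dict[str, pd.DataFrame] = {}

    if report.stages.get("null_models", {}).get("status") == "ok":
        with open(out / "processes.json") as fh:
            proc = json.load(fh)["groups"]
        rows = []
        for g, rec in proc.items():
            if g == "__all__":
                continue
            rows.append({"group": g, **rec["fractions"],
                         "stochastic_fraction": rec["stochastic_fraction"]})
        tables["process_fractions"] = pd.DataFrame(rows)

    if report.stages.get("nst", {}).get("status") == "ok":
        with open(out / "nst.json") as fh:
            nst = json.load(fh)
        tables["nst"] = pd.DataFrame(
            [{"group": g, "nst_percent": v} for g, v in nst["group_nst_percent"].items()]
        )

    if report.stages.get("network", {}).get("status") == "ok":
        tables["network_topology"] = pd.read_csv(out / "network_topology.tsv", sep="\t")

    for name, df in tables.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    return tables
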