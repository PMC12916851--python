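"""End-to-end pipeline: filter -> diversity -> networks -> comparison ->
robustness -> knockouts, from a single validated configuration, with a
checksummed output manifest for reproducibility.

All per-stage seeds are derived from one base seed by fixed offsets, so an
identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import diversity as dv
from . import netbuild, netcompare, robustness, synthdata
from .knockout import knockout_experiment
from .sparcc import SparCC, threshold_edges
from .tables_io import TaxaTable, find_contaminants, read_taxa_table

log = logging.getLogger(__name__)

_SEED_OFFSETS = {
    "synth": 11, "sparcc": 23, "topology": 31, "attack_random": 41,
    "addition": 53, "bootstrap": 61, "permanova": 71,
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    # inputs: either file paths or a synthetic-data spec
    table_path: str | None = None
    metadata_path: str | None = None
    synth: dict | None = None
    # stage parameters
    contaminant_threshold: float = 0.5
    remove_contaminants: bool = True
    pseudocount: float = 1.0
    n_iter: int = 10
    exclusion_threshold: float = 0.1
    n_resamples: int = 20
    edge_cutoff: float = 0.5
    centrality_percentile: float = 75.0
    attack_strategies: tuple = tuple(robustness.STRATEGIES)
    addition_grid: tuple = (100, 300, 500, 700, 1000)
    addition_reps: int = 3
    addition_record_every: int = 10
    n_permutations: int = 999
    knockout_taxa: tuple = ("Pantoea", "Stenotrophomonas", "Delftia",
                            "Alcaligenes")
    seed: int = 0
    out_dir: str = "mosqnet_out"

    def __post_init__(self) -> None:
        if not (0.0 < self.edge_cutoff <= 1.0):
            raise ValueError("edge_cutoff must be in (0, 1]")
        if not (0.0 < self.contaminant_threshold <= 1.0):
            raise ValueError("contaminant_threshold must be in (0, 1]")
        if not (0.0 < self.centrality_percentile < 100.0):
            raise ValueError("centrality_percentile must be in (0, 100)")
        for s in self.attack_strategies:
            if s not in robustness.STRATEGIES:
                raise ValueError(f"unknown attack strategy {s!r}")
        if self.table_path is None and self.synth is None:
            self.synth = {}  # default synthetic design

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("attack_strategies", "addition_grid", "knockout_taxa"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 101 + _SEED_OFFSETS[stage]) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Executes the stages and records every written file in a manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []

    # -- helpers -----------------------------------------------------------
    def _write_df(self, df: pd.DataFrame, rel: str, index: bool = True):
        path = self.out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        self.files.append(path)
        return path

    def _write_text(self, text: str, rel: str):
        path = self.out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        self.files.append(path)
        return path

    def _sparcc_config(self) -> dict:
        c = self.config
        return dict(pseudocount=c.pseudocount, n_iter=c.n_iter,
                    exclusion_threshold=c.exclusion_threshold,
                    n_resamples=c.n_resamples, cutoff=c.edge_cutoff,
                    seed=c.stage_seed("sparcc"),
                    topology_seed=c.stage_seed("topology"),
                    attack_seed=c.stage_seed("attack_random"))

    # -- stages ------------------------------------------------------------
    def load_table(self) -> TaxaTable:
        c = self.config
        if c.table_path is not None:
            log.info("reading taxa table from %s", c.table_path)
            return read_taxa_table(c.table_path, c.metadata_path)
        params = dict(c.synth or {})
        params.setdefault("seed", c.stage_seed("synth"))
        spec = synthdata.SynthSpec(**params)
        if not spec.planted_graph:
            spec.planted_graph = synthdata.default_planted_graph(spec)
            spec.__post_init__()
        log.info("generating synthetic table (seed %d)", spec.seed)
        table = synthdata.generate_table(spec)
        table.write(self.out / "table.tsv", self.out / "metadata.tsv")
        self.files += [self.out / "table.tsv", self.out / "metadata.tsv"]
        return table

    def run_filter(self, table: TaxaTable) -> TaxaTable:
        c = self.config
        report = find_contaminants(table, threshold=c.contaminant_threshold,
                                   remove=c.remove_contaminants)
        self._write_df(report.scores, "filter/contaminant_report.tsv")
        log.info("flagged %d contaminant taxa", len(report.contaminants))
        return report.filtered.biological()

    def run_diversity(self, table: TaxaTable) -> dict:
        c = self.config
        alpha = dv.alpha_diversity(table)
        self._write_df(alpha.per_sample, "diversity/alpha.tsv")
        self._write_df(alpha.tests, "diversity/alpha_tests.tsv")
        bc = dv.beta_distance(table, "bray_curtis")
        jc = dv.beta_distance(table, "jaccard")
        self._write_df(bc.data, "diversity/bray_curtis.tsv")
        self._write_df(jc.data, "diversity/jaccard.tsv")
        ord_res = dv.pcoa(bc)
        self._write_df(ord_res.coordinates.iloc[:, :4], "diversity/pcoa.tsv")
        groups = list(table.group)
        perm = dv.permanova(bc, groups, n_perm=c.n_permutations,
                            seed=c.stage_seed("permanova"))
        disp = dv.betadisper(bc, groups)
        stats_df = pd.DataFrame(
            [("permanova", perm.f, perm.p),
             ("betadisper", disp.f, disp.p)],
            columns=["test", "statistic", "p"])
        self._write_df(stats_df, "diversity/beta_tests.tsv", index=False)
        tree = dv.hclust_tree(jc)
        self._write_text(tree.newick() + "\n", "diversity/dendrogram.nwk")
        labels = sorted(set(groups))
        venn = dv.venn_partition(
            table.subset_group(labels[0]).present_taxa(),
            table.subset_group(labels[1]).present_taxa())
        venn_df = pd.DataFrame(
            [(labels[0], venn["counts"][0]), ("shared", venn["counts"][1]),
             (labels[1], venn["counts"][2])], columns=["partition", "count"])
        self._write_df(venn_df, "diversity/venn.tsv", index=False)
        return {"alpha": alpha, "permanova": perm, "betadisper": disp,
                "venn": venn, "venn_labels": labels}

    def run_networks(self, table: TaxaTable) -> dict[str, nx.Graph]:
        c = self.config
        networks = {}
        for label in sorted(set(table.group)):
            sub = table.subset_group(label)
            model = SparCC(sub, pseudocount=c.pseudocount, n_iter=c.n_iter,
                           exclusion_threshold=c.exclusion_threshold,
                           n_resamples=c.n_resamples)
            res = model.fit(seed=c.stage_seed("sparcc"))
            self._write_df(res.correlations,
                           f"network/{label}/correlations.tsv")
            edges = threshold_edges(res, c.edge_cutoff)
            self._write_df(edges, f"network/{label}/edges.tsv", index=False)
            net = netbuild.build_network(edges)
            netbuild.annotate_network(net, seed=c.stage_seed("topology"))
            summ = netbuild.topology_summary(net,
                                             seed=c.stage_seed("topology"))
            self._write_df(pd.DataFrame([summ.as_row()], index=[label]),
                           f"network/{label}/topology.tsv")
            path = self.out / f"network/{label}/network.graphml"
            netbuild.export_graphml(net, path)
            self.files.append(path)
            networks[label] = net
            log.info("network %s: %d nodes, %d edges", label,
                     net.number_of_nodes(), net.number_of_edges())
        return networks

    def run_compare(self, networks: dict[str, nx.Graph]) -> pd.DataFrame:
        c = self.config
        labels = sorted(networks)
        report = netcompare.compare_networks(
            networks[labels[0]], networks[labels[1]],
            percentile=c.centrality_percentile)
        self._write_df(report, "compare/jaccard_comparison.tsv", index=False)
        diff = netcompare.differential_edges(networks[labels[0]],
                                             networks[labels[1]])
        rows = [(cat, a, b) for cat, pairs in diff.items()
                for a, b in pairs]
        self._write_df(pd.DataFrame(rows, columns=["category", "taxon_a",
                                                   "taxon_b"]),
                       "compare/differential_edges.tsv", index=False)
        return report

    def run_robustness(self, networks: dict[str, nx.Graph]) -> dict:
        c = self.config
        results = {"attack": {}, "addition": {}}
        for label, net in sorted(networks.items()):
            frames = []
            for strat in c.attack_strategies:
                curve = robustness.attack(
                    net, strat, seed=c.stage_seed("attack_random"))
                frames.append(curve.as_frame())
                results["attack"].setdefault(label, {})[strat] = curve
            self._write_df(pd.concat(frames, ignore_index=True),
                           f"robustness/{label}/attack_curves.tsv",
                           index=False)
            grid_df = robustness.addition_grid(
                net, grid=c.addition_grid, reps=c.addition_reps,
                seed=c.stage_seed("addition"),
                record_every=c.addition_record_every)
            self._write_df(grid_df, f"robustness/{label}/addition_curves.tsv",
                           index=False)
            results["addition"][label] = grid_df
        labels = sorted(networks)
        if len(labels) == 2:
            comp = self._compare_addition_grids(results["addition"][labels[0]],
                                                results["addition"][labels[1]])
            self._write_df(comp, "robustness/addition_comparison.tsv",
                           index=False)
            results["addition_comparison"] = comp
        return results

    def _compare_addition_grids(self, grid_a: pd.DataFrame,
                                grid_b: pd.DataFrame) -> pd.DataFrame:
        c = self.config
        frames = []
        for n_add in sorted(grid_a["grid"].unique()):
            curves_a = _frame_to_curves(grid_a[grid_a["grid"] == n_add])
            curves_b = _frame_to_curves(grid_b[grid_b["grid"] == n_add])
            comp = robustness.compare_addition(
                curves_a, curves_b, seed=c.stage_seed("bootstrap"))
            comp.insert(0, "grid", n_add)
            frames.append(comp)
        out = pd.concat(frames, ignore_index=True)
        # BH across the whole family (grid x metric)
        out["p_adj"] = robustness.benjamini_hochberg(out["p"].to_numpy())
        return out

    def run_knockouts(self, table: TaxaTable,
                      networks: dict[str, nx.Graph]) -> list:
        c = self.config
        labels = sorted(set(table.group))
        reports = knockout_experiment(
            table.subset_group(labels[0]), table.subset_group(labels[1]),
            list(c.knockout_taxa), config=self._sparcc_config(),
            baselines=networks)
        for rep in reports:
            base = f"knockout/{rep.taxon}"
            self._write_df(rep.topology_frame(), f"{base}/topology.tsv")
            rows = []
            for label, em in rep.emergent.items():
                for a, b in em["edges_positive"]:
                    rows.append((label, "edge_positive", a, b))
                for a, b in em["edges_negative"]:
                    rows.append((label, "edge_negative", a, b))
                for node in em["nodes"]:
                    rows.append((label, "node", node, ""))
            self._write_df(pd.DataFrame(
                rows, columns=["group", "kind", "a", "b"]),
                f"{base}/emergent.tsv", index=False)
            for label, phases in rep.attack_curves.items():
                frames = [curve.as_frame().assign(phase=phase)
                          for phase, by_strat in sorted(phases.items())
                          for curve in [by_strat[s] for s in sorted(by_strat)]]
                if frames:
                    self._write_df(pd.concat(frames, ignore_index=True),
                                   f"{base}/attack_{label}.tsv", index=False)
            for label, nets in rep.networks.items():
                path = self.out / f"{base}/{label}_post.graphml"
                netbuild.export_graphml(nets["post"], path)
                self.files.append(path)
        return reports

    # -- driver ------------------------------------------------------------
    def run_all(self) -> dict:
        table = self.load_table()
        filtered = self.run_filter(table)
        diversity_res = self.run_diversity(filtered)
        networks = self.run_networks(filtered)
        compare = self.run_compare(networks)
        robust = self.run_robustness(networks)
        knockouts = self.run_knockouts(filtered, networks)
        manifest = {
            "config": _jsonable(asdict(self.config)),
            "files": {str(p.relative_to(self.out)): _sha256(p)
                      for p in sorted(set(self.files))},
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        self.results = {"table": table, "filtered": filtered,
                        "diversity": diversity_res, "networks": networks,
                        "compare": compare, "robustness": robust,
                        "knockouts": knockouts, "manifest": manifest}
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _frame_to_curves(frame: pd.DataFrame) -> list:
    curves = []
    for rep, sub in frame.groupby("replicate"):
        curves.append(robustness.AdditionCurve(
            replicate=int(rep),
            n_added=sub["n_added"].to_numpy(),
            lcc=sub["lcc"].to_numpy(float),
            apl=sub["apl"].to_numpy(float)))
    return curves


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (paths + checksums)."""
    return PipelineRun(config).run_all()
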