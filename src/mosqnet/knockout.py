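"""In-silico taxon knockout: zero a taxon's reads, re-infer the networks,
compare topology and robustness, and list emergent interactions.

Knockouts are single-taxon (not cumulative) and independent of each other.
The knocked-out column is retained as zeros in the table; the basis-
correlation stage drops zero-variance columns, so the taxon vanishes from the
re-inferred network.  Baseline and depleted runs share the same resampling
seed so topology differences are attributable to the knockout rather than
resampling noise.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .netbuild import build_network, topology_summary, TopologySummary
from .robustness import STRATEGIES, AttackCurve, attack
from .sparcc import sparcc_infer, threshold_edges
from .tables_io import TaxaTable


def remove_taxon(table: TaxaTable, taxon: str) -> TaxaTable:
    """Copy of the table with the taxon's column set to zero everywhere."""
    if taxon not in table.counts.columns:
        close = difflib.get_close_matches(taxon, map(str, table.counts.columns))
        hint = f"; did you mean {close}?" if close else ""
        raise KeyError(f"taxon {taxon!r} not in table{hint}")
    counts = table.counts.copy()
    counts[taxon] = 0
    return TaxaTable(counts, table.group, table.is_control)


def emergent_interactions(pre: nx.Graph, post: nx.Graph) -> dict:
    """Edges and nodes present only after the knockout, tagged by sign."""
    pre_edges = {frozenset((u, v)) for u, v in pre.edges}
    emergent = []
    for u, v, d in post.edges(data=True):
        if frozenset((u, v)) not in pre_edges:
            emergent.append((*sorted((u, v)), d.get("sign", 1)))
    return {
        "edges_positive": sorted((a, b) for a, b, s in emergent if s > 0),
        "edges_negative": sorted((a, b) for a, b, s in emergent if s < 0),
        "nodes": sorted(set(post.nodes) - set(pre.nodes)),
    }


@dataclass
class KnockoutReport:
    """Before/after comparison for one taxon knockout across both groups."""

    taxon: str
    summaries: dict[str, dict[str, TopologySummary]]  # group -> {pre,post}
    networks: dict[str, dict[str, nx.Graph]] = field(repr=False,
                                                     default_factory=dict)
    emergent: dict[str, dict] = field(default_factory=dict)  # per group
    attack_curves: dict[str, dict[str, dict[str, AttackCurve]]] = field(
        repr=False, default_factory=dict)  # group -> {pre,post} -> strategy

    def topology_frame(self) -> pd.DataFrame:
        rows = {}
        for group, phases in self.summaries.items():
            for phase, summ in phases.items():
                rows[f"{group}_{phase}"] = summ.as_row()
        return pd.DataFrame.from_dict(rows, orient="index")


def _infer_network(table: TaxaTable, config: dict) -> nx.Graph:
    res = sparcc_infer(
        table,
        n_iter=config.get("n_iter", 10),
        exclusion_threshold=config.get("exclusion_threshold", 0.1),
        n_resamples=config.get("n_resamples", 20),
        pseudocount=config.get("pseudocount", 1.0),
        seed=config.get("seed", 0),
    )
    return build_network(threshold_edges(res, config.get("cutoff", 0.5)))


def knockout_experiment(table_a: TaxaTable, table_b: TaxaTable,
                        taxa, config: dict | None = None,
                        baselines: dict[str, nx.Graph] | None = None,
                        run_attacks: bool = True) -> list[KnockoutReport]:
    """Knock out each taxon independently and rebuild both groups' networks.

    ``config`` carries the inference settings (seed, n_resamples, cutoff,
    ...) shared by baseline and depleted runs.  ``baselines`` may supply
    precomputed baseline networks keyed by group label to avoid re-inference.
    """
    config = dict(config or {})
    groups = {}
    for tab in (table_a, table_b):
        label = str(tab.group.iloc[0])
        groups[label] = tab
    for taxon in taxa:
        for label, tab in groups.items():
            if taxon not in tab.counts.columns:
                raise KeyError(f"taxon {taxon!r} missing from group {label}")
    if baselines is None:
        baselines = {label: _infer_network(tab, config)
                     for label, tab in groups.items()}
    topo_seed = config.get("topology_seed", 0)
    reports = []
    for taxon in taxa:
        summaries, networks, emergent, curves = {}, {}, {}, {}
        for label, tab in groups.items():
            pre = baselines[label]
            post = _infer_network(remove_taxon(tab, taxon), config)
            summaries[label] = {
                "pre": topology_summary(pre, seed=topo_seed),
                "post": topology_summary(post, seed=topo_seed),
            }
            networks[label] = {"pre": pre, "post": post}
            emergent[label] = emergent_interactions(pre, post)
            if run_attacks:
                curves[label] = {
                    phase: {s: attack(g, s, seed=config.get("attack_seed", 0))
                            for s in STRATEGIES if g.number_of_edges() > 0}
                    for phase, g in networks[label].items()
                }
        reports.append(KnockoutReport(taxon=taxon, summaries=summaries,
                                      networks=networks, emergent=emergent,
                                      attack_curves=curves))
    return reports
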