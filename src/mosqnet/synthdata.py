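"""Synthetic genus-level taxa tables with a planted log-scale interaction graph.

The generator emulates the sampling design of a two-site mosquito microbiome
survey: two groups of individually sequenced adults, a single dominant
endosymbiont (*Wolbachia*-like) with very low cross-sample variance, a small
shared core of genera, larger group-specific accessory floras, and a handful
of sterile-water negative controls carrying reagent contaminants.

Counts are produced by a log-normal / multinomial compositional model:
log-abundances are drawn from a multivariate normal whose covariance encodes
the planted interaction graph, the vector is closed to proportions with the
dominant taxon pinned near its target fraction, and reads are drawn
multinomially at a fixed sequencing depth.  This is the generative regime in
which basis-correlation inference from log-ratio variances is consistent, so
planted edges are recoverable by the network stage and the dominant taxon —
having essentially no covariance signal — stays out of inferred networks by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import TaxaTable


class SynthSpecError(ValueError):
    """Raised for inconsistent generator specifications."""


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-group taxa table.

    Defaults mirror the study design the generator emulates: 10 samples per
    group, a ~15-genus shared core containing a dominant *Wolbachia*-like
    taxon, 100 vs 61 group-specific accessory genera, 4 negative controls,
    and 20,000 reads per sample.
    """

    n_samples_per_group: int = 10
    n_core_taxa: int = 15
    n_accessory_taxa_per_group: tuple[int, int] = (100, 61)
    dominant_fraction: float = 0.7
    planted_graph: list[tuple[str, str, int]] = field(default_factory=list)
    log_effect_size: float = 0.8
    sequencing_depth: int = 20_000
    n_controls: int = 4
    contaminant_taxa: list[str] = field(
        default_factory=lambda: ["Contaminant_1", "Contaminant_2"])
    group_labels: tuple[str, str] = ("Pecs", "Barcs")
    base_log_sigma: float = 1.0
    stable_core_log_sigma: float = 0.2
    dominant_log_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_core_taxa < 1:
            raise SynthSpecError("sample and core taxa counts must be >= 1")
        if not (0.0 < self.dominant_fraction < 1.0):
            raise SynthSpecError("dominant_fraction must be in (0, 1)")
        if self.log_effect_size <= 0:
            raise SynthSpecError("log_effect_size must be positive")
        if self.sequencing_depth < 1:
            raise SynthSpecError("sequencing_depth must be positive")
        if self.n_controls < 0:
            raise SynthSpecError("n_controls must be non-negative")
        declared = set(self.all_taxa())
        for i, j, s in self.planted_graph:
            if i == j:
                raise SynthSpecError(f"self-pair in planted graph: {i}")
            if s not in (-1, 1):
                raise SynthSpecError(f"edge sign must be +-1, got {s!r}")
            for t in (i, j):
                if t not in declared:
                    raise SynthSpecError(
                        f"planted graph references undeclared taxon {t!r}")

    # -- taxon naming ------------------------------------------------------
    def core_taxa(self) -> list[str]:
        # dominant endosymbiont first; the named genera are the conserved
        # shared core typically reported for Ae. albopictus
        named = ["Wolbachia", "Acinetobacter", "Pantoea", "Stenotrophomonas",
                 "Delftia", "Leuconostoc", "Alcaligenes"]
        named = named[:self.n_core_taxa]
        extra = [f"Core_{k:03d}" for k in range(len(named) + 1,
                                                self.n_core_taxa + 1)]
        return named + extra

    def accessory_taxa(self, group_index: int) -> list[str]:
        label = self.group_labels[group_index]
        n = self.n_accessory_taxa_per_group[group_index]
        return [f"{label}_acc_{k:03d}" for k in range(1, n + 1)]

    def all_taxa(self) -> list[str]:
        return (self.core_taxa() + self.accessory_taxa(0)
                + self.accessory_taxa(1) + list(self.contaminant_taxa))

    def group_taxa(self, group_index: int) -> list[str]:
        return self.core_taxa() + self.accessory_taxa(group_index)


def _covariance(spec: SynthSpec, taxa: list[str]) -> np.ndarray:
    """Log-scale covariance with planted +-log_effect_size*sigma^2 entries.

    Core genera that take part in no planted interaction are modelled as a
    stable conserved core (low cross-sample variance, like the dominant
    endosymbiont but less extreme) — which is why most shared genera, albeit
    consistently detected, do not surface in inferred networks.
    """
    d = len(taxa)
    interacting = {t for i, j, _ in spec.planted_graph for t in (i, j)}
    core = set(spec.core_taxa())
    sig = np.full(d, spec.base_log_sigma ** 2)
    for k, t in enumerate(taxa):
        if t in core and t not in interacting:
            sig[k] = spec.stable_core_log_sigma ** 2
    sig[0] = spec.dominant_log_sigma ** 2  # dominant taxon: near-zero variance
    cov = np.diag(sig)
    index = {t: k for k, t in enumerate(taxa)}
    for i, j, s in spec.planted_graph:
        if i in index and j in index:
            a, b = index[i], index[j]
            cov[a, b] = cov[b, a] = (
                s * spec.log_effect_size * np.sqrt(sig[a] * sig[b]))
    # planted blocks with |rho| < 1 keep this PD; guard anyway
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise SynthSpecError(
            "planted graph yields a non-positive-definite covariance; "
            "reduce log_effect_size or edge overlap")
    return cov


def _mean_log_abundance(spec: SynthSpec, group_index: int) -> np.ndarray:
    """Bimodal rank-abundance profile, as seen in real amplicon tables.

    Core genera and accessory taxa that take part in planted interactions are
    moderately abundant (tens to hundreds of reads, so their covariance is
    observable); the remaining accessory flora forms a rare tail (expected
    counts near or below one read per sample), mirroring the long tail of
    sporadically detected genera in real data.
    """
    interacting = {t for i, j, _ in spec.planted_graph for t in (i, j)}
    core = spec.core_taxa()
    acc = spec.accessory_taxa(group_index)
    mean = np.empty(len(core) + len(acc))
    mean[:len(core)] = np.linspace(3.0, 1.0, len(core))
    hot = [k for k, t in enumerate(acc) if t in interacting]
    cold = [k for k, t in enumerate(acc) if t not in interacting]
    if hot:
        mean[len(core) + np.array(hot)] = np.linspace(-1.0, -2.0, len(hot))
    if cold:
        mean[len(core) + np.array(cold)] = np.linspace(-3.5, -5.5, len(cold))
    return mean


def _group_counts(spec: SynthSpec, group_index: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    taxa = spec.group_taxa(group_index)
    n = spec.n_samples_per_group
    cov = _covariance(spec, taxa)
    mean = _mean_log_abundance(spec, group_index)
    logab = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    ab = np.exp(logab)
    # pin the dominant taxon near dominant_fraction of the composition
    others = ab[:, 1:].sum(axis=1)
    ab[:, 0] = (spec.dominant_fraction / (1.0 - spec.dominant_fraction)
                * others * np.exp(rng.normal(0.0, spec.dominant_log_sigma, n)))
    props = ab / ab.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(spec.sequencing_depth, p) for p in props])
    label = spec.group_labels[group_index]
    sample_ids = [f"{label}_{k:02d}" for k in range(1, n + 1)]
    return pd.DataFrame(counts, index=sample_ids, columns=taxa)


def _control_counts(spec: SynthSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Negative controls: contaminants at high prevalence, biology near zero."""
    sample_ids = [f"NC_{k:02d}" for k in range(1, spec.n_controls + 1)]
    cols = spec.contaminant_taxa
    if not cols:
        return pd.DataFrame(0, index=sample_ids, columns=[], dtype=np.int64)
    depth = max(200, spec.sequencing_depth // 100)  # low-biomass wells
    p = np.full(len(cols), 1.0 / len(cols))
    counts = np.vstack([rng.multinomial(depth, p) for _ in sample_ids])
    counts = np.maximum(counts, 1)  # present in every control
    return pd.DataFrame(counts, index=sample_ids, columns=cols)


def generate_table(spec: SynthSpec) -> TaxaTable:
    """Generate the full synthetic table: both groups plus negative controls.

    Deterministic given ``spec.seed``.  Biological sample rows sum exactly to
    ``sequencing_depth``; contaminant taxa additionally appear at low counts
    in a few biological samples so the prevalence filter has work to do.
    """
    rng = np.random.default_rng(spec.seed)
    g0 = _group_counts(spec, 0, rng)
    g1 = _group_counts(spec, 1, rng)
    all_taxa = spec.all_taxa()
    frames = [g0, g1]
    if spec.n_controls:
        frames.append(_control_counts(spec, rng))
    counts = (pd.concat(frames).reindex(columns=all_taxa).fillna(0)
              .astype(np.int64))
    # sprinkle contaminants into ~20% of biological samples (cross-talk),
    # taken out of the dominant taxon so row sums stay at sequencing_depth
    n_bio = 2 * spec.n_samples_per_group
    for taxon in spec.contaminant_taxa:
        hit = rng.choice(n_bio, size=max(1, n_bio // 5), replace=False)
        for s in hit:
            spill = int(rng.integers(1, 6))
            spill = min(spill, int(counts.iloc[s, 0]))
            counts.iloc[s, counts.columns.get_loc(taxon)] += spill
            counts.iloc[s, 0] -= spill
    labels = ([spec.group_labels[0]] * spec.n_samples_per_group
              + [spec.group_labels[1]] * spec.n_samples_per_group
              + ["control"] * spec.n_controls)
    flags = [False] * n_bio + [True] * spec.n_controls
    group = pd.Series(labels, index=counts.index)
    is_control = pd.Series(flags, index=counts.index)
    return TaxaTable(counts, group, is_control)


def generate_controls(spec: SynthSpec) -> TaxaTable:
    """Only the negative-control rows of :func:`generate_table`."""
    if spec.n_controls < 1:
        raise SynthSpecError("n_controls must be >= 1 for generate_controls")
    return generate_table(spec).controls()


def default_planted_graph(spec: SynthSpec) -> list[tuple[str, str, int]]:
    """A realistic planted interaction structure for the default design.

    Positive equicorrelated blocks (cliques in log-abundance space) are
    planted per group: each of the four knockout-candidate shared genera
    anchors a block of group-specific accessory taxa, plus a few
    accessory-only blocks.  The first group's blocks are larger, giving the
    denser, more clustered network the design emulates; all planted
    interactions are positive, matching the all-positive baseline networks.
    Blocks are disjoint within a group, so the covariance stays positive
    definite for any block correlation < 1.
    """
    import itertools

    anchors = ["Pantoea", "Stenotrophomonas", "Delftia", "Alcaligenes"]
    anchors = [a for a in anchors if a in spec.core_taxa()]
    edges: list[tuple[str, str, int]] = []
    plans = [
        # (group_index, block sizes for anchor blocks, accessory-only blocks)
        (0, [8, 6, 5, 4], [5, 5, 4, 3]),
        (1, [4, 3, 2, 2], [4, 3]),
    ]
    for gi, anchor_sizes, free_sizes in plans:
        acc = spec.accessory_taxa(gi)
        cursor = 0
        blocks = []
        for a, size in zip(anchors, anchor_sizes):
            members = [a] + acc[cursor:cursor + size]
            cursor += size
            blocks.append(members)
        for size in free_sizes:
            blocks.append(acc[cursor:cursor + size])
            cursor += size
        for members in blocks:
            for u, v in itertools.combinations(members, 2):
                edges.append((u, v, 1))
    return edges
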