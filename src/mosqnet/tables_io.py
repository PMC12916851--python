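"""Taxa count tables: I/O, rarefaction and prevalence-based contaminant filtering.

The central container is :class:`TaxaTable`, a samples x taxa matrix of
non-negative integer read counts together with per-sample metadata (group
label and a negative-control flag).  On disk the table uses the common
taxa-as-rows orientation (first column ``taxon_id``, one column per sample)
and is transposed to samples x taxa on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class TaxaTableError(ValueError):
    """Raised for malformed tables or metadata."""


@dataclass
class TaxaTable:
    """Samples x taxa matrix of read counts with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = sample ids, columns = taxon ids.
    group : pandas.Series
        Group label per sample (index aligned with ``counts``).
    is_control : pandas.Series
        Boolean negative-control flag per sample.
    """

    counts: pd.DataFrame
    group: pd.Series
    is_control: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise TaxaTableError("duplicate sample ids: "
                                 f"{sorted(c.index[c.index.duplicated()])}")
        if c.columns.duplicated().any():
            raise TaxaTableError("duplicate taxon ids: "
                                 f"{sorted(c.columns[c.columns.duplicated()])}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise TaxaTableError("counts must be integers")
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            bad = c.columns[(arr < 0).any(axis=0)]
            raise TaxaTableError(f"negative counts in taxa {list(bad)}")
        for name, s in (("group", self.group), ("is_control", self.is_control)):
            missing = c.index.difference(s.index)
            if len(missing):
                raise TaxaTableError(
                    f"metadata '{name}' missing samples: {sorted(missing)}")
        self.group = self.group.reindex(c.index)
        self.is_control = self.is_control.reindex(c.index).astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    # -- views -------------------------------------------------------------
    def biological(self) -> "TaxaTable":
        """Subset to non-control samples."""
        keep = ~self.is_control
        return TaxaTable(self.counts.loc[keep],
                         self.group.loc[keep], self.is_control.loc[keep])

    def controls(self) -> "TaxaTable":
        keep = self.is_control.astype(bool)
        return TaxaTable(self.counts.loc[keep],
                         self.group.loc[keep], self.is_control.loc[keep])

    def subset_group(self, label: str) -> "TaxaTable":
        keep = (self.group == label) & (~self.is_control)
        if not keep.any():
            raise TaxaTableError(f"no biological samples in group {label!r}")
        return TaxaTable(self.counts.loc[keep],
                         self.group.loc[keep], self.is_control.loc[keep])

    def drop_taxa(self, taxa) -> "TaxaTable":
        cols = [t for t in self.counts.columns if t not in set(taxa)]
        return TaxaTable(self.counts[cols], self.group, self.is_control)

    def present_taxa(self) -> set[str]:
        """Taxa with count > 0 in at least one sample."""
        return set(self.counts.columns[(self.counts > 0).any(axis=0)])

    # -- I/O ---------------------------------------------------------------
    def write(self, table_path, metadata_path) -> None:
        out = self.counts.T.copy()
        out.index.name = "taxon_id"
        out.to_csv(table_path, sep="\t")
        meta = pd.DataFrame({
            "sample_id": self.counts.index,
            "group": self.group.values,
            "is_control": ["true" if v else "false" for v in self.is_control],
        })
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(cls, table_path, metadata_path) -> "TaxaTable":
        return read_taxa_table(table_path, metadata_path)


def read_taxa_table(path, metadata_path) -> TaxaTable:
    """Read a taxa TSV (taxa rows, sample columns) plus a metadata TSV.

    The metadata file must have columns ``sample_id``, ``group``,
    ``is_control`` and cover every sample column of the table.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    counts = raw.T  # samples x taxa
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    counts.columns.name = None
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "is_control"):
        if col not in meta.columns:
            raise TaxaTableError(f"metadata file lacks column {col!r}")
    meta = meta.set_index("sample_id")
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise TaxaTableError(f"metadata missing samples: {sorted(missing)}")
    truthy = {"true": True, "1": True, "yes": True,
              "false": False, "0": False, "no": False}
    try:
        flags = meta["is_control"].str.lower().map(truthy)
    except AttributeError:  # already bool
        flags = meta["is_control"].astype(bool)
    if flags.isna().any():
        raise TaxaTableError("is_control must be true/false")
    return TaxaTable(counts, meta["group"].reindex(counts.index),
                     flags.reindex(counts.index).astype(bool))


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(table: TaxaTable, depths, reps: int = 10, seed=None,
                      method: str = "exact") -> pd.DataFrame:
    """Expected number of observed taxa per sample at each subsampling depth.

    With ``method='exact'`` the hypergeometric closed form is used:
    E[richness at depth d] = sum_t 1 - C(N - n_t, d) / C(N, d),
    where N is the sample total and n_t the taxon's count.  With
    ``method='montecarlo'`` the mean over ``reps`` without-replacement
    subsamples is returned.  Depths above a sample's total yield NaN.

    Returns a DataFrame indexed by sample id with one column per depth.
    """
    depths = [int(d) for d in depths]
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=table.counts.index, columns=depths, dtype=float)
    for sid, row in table.counts.iterrows():
        n = row.to_numpy()
        n = n[n > 0]
        total = int(n.sum())
        for d in depths:
            if d > total:
                out.loc[sid, d] = np.nan
            elif method == "exact":
                # P(taxon absent from subsample) = C(N-n_t, d)/C(N, d)
                p_absent = np.exp(_log_comb(total - n, d) - _log_comb(total, d))
                out.loc[sid, d] = float(np.sum(1.0 - p_absent))
            elif method == "montecarlo":
                pool = np.repeat(np.arange(len(n)), n)
                vals = [len(np.unique(rng.choice(pool, size=d, replace=False)))
                        for _ in range(reps)]
                out.loc[sid, d] = float(np.mean(vals))
            else:
                raise ValueError(f"unknown method {method!r}")
    return out


def _log_comb(n, k):
    """log C(n, k) elementwise; -inf where k > n."""
    from scipy.special import gammaln
    n = np.atleast_1d(np.asarray(n, dtype=float))
    return np.where(k <= n,
                    gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1)
                    - gammaln(k + 1), -np.inf)


# ---------------------------------------------------------------------------
# Contaminant identification (prevalence method)
# ---------------------------------------------------------------------------

@dataclass
class ContaminantReport:
    """Per-taxon prevalence contrast against negative controls.

    ``scores`` holds, per taxon: prevalence_in_samples, prevalence_in_controls,
    score (one-sided Fisher exact probability of control enrichment at least
    as extreme) and is_contaminant (score < threshold).  ``filtered`` is a
    copy of the input table with contaminant taxa removed.
    """

    scores: pd.DataFrame
    threshold: float
    filtered: TaxaTable = field(repr=False)

    @property
    def contaminants(self) -> list[str]:
        return list(self.scores.index[self.scores["is_contaminant"]])


def find_contaminants(table: TaxaTable, threshold: float = 0.5,
                      remove: bool = True) -> ContaminantReport:
    """Classify taxa as contaminants by presence enrichment in controls.

    For each taxon the 2x2 presence/absence x control/biological table is
    scored with a one-sided Fisher exact test (alternative: presence enriched
    in controls); a taxon is a contaminant when that probability is below
    ``threshold``.  Presence means count >= 1.
    """
    if not table.is_control.any():
        raise TaxaTableError(
            "table has no negative controls; skip contaminant filtering")
    if table.is_control.all():
        raise TaxaTableError("table has no biological samples")
    present = table.counts > 0
    ctrl = table.is_control.to_numpy(bool)
    n_ctrl, n_bio = int(ctrl.sum()), int((~ctrl).sum())
    rows = {}
    for taxon in table.counts.columns:
        in_ctrl = int(present.loc[ctrl, taxon].sum())
        in_bio = int(present.loc[~ctrl, taxon].sum())
        tab = [[in_ctrl, n_ctrl - in_ctrl], [in_bio, n_bio - in_bio]]
        score = stats.fisher_exact(tab, alternative="greater")[1]
        rows[taxon] = (in_bio / n_bio, in_ctrl / n_ctrl, score,
                       score < threshold)
    scores = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["prevalence_in_samples", "prevalence_in_controls",
                 "score", "is_contaminant"])
    scores.index.name = "taxon_id"
    contaminants = scores.index[scores["is_contaminant"]]
    filtered = table.drop_taxa(contaminants) if remove else table
    return ContaminantReport(scores=scores, threshold=threshold,
                             filtered=filtered)
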