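"""Basis-correlation inference for compositional count data (SparCC).

Read counts only carry relative information, so Pearson correlations on
proportions are biased by closure.  SparCC instead works from the variation
matrix

    t_ij = Var_samples[ log(f_i / f_j) ] = w_i + w_j - 2 r_ij sqrt(w_i w_j),

where f are component fractions, w_i the (unobserved) basis log-variances and
r_ij the basis correlations.  Under a sparsity assumption (correlations
average out), the row sums of t give a linear system for w:

    (D - 2) w_i + sum_j w_j = sum_j t_ij,

i.e. M w = t 1 with M having diagonal D-1 and off-diagonal 1.  Strongly
correlated pairs violate the sparsity assumption, so the estimator iterates:
solve, find the strongest pair with |r| above an exclusion threshold, drop
that pair from the system, re-solve.  Uncertainty in the fractions is handled
by averaging (here: median) over Dirichlet resamples of the posterior
fractions.

The estimator is exposed statsmodels-style: build :class:`SparCC` from a
counts matrix and call :meth:`SparCC.fit` to obtain :class:`SparCCResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import TaxaTable

log = logging.getLogger(__name__)

_OMEGA_FLOOR = 1e-6  # floor for non-positive basis-variance estimates


def variation_matrix(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Variation matrix t_ij = Var[log(f_i/f_j)] from a counts matrix.

    Fractions are posterior means (count + pseudocount) / row total.  The
    result is symmetric with a zero diagonal.  Requires >= 2 samples and
    >= 3 taxa (the basis solve needs D >= 3).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if x.shape[1] < 3:
        raise ValueError("basis correlation inference requires >= 3 taxa")
    f = x + pseudocount
    f /= f.sum(axis=1, keepdims=True)
    return _variation_from_fractions(f)


def _variation_from_fractions(f: np.ndarray) -> np.ndarray:
    logf = np.log(f)
    v = np.var(logf, axis=0, ddof=1)
    c = np.cov(logf, rowvar=False)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations(t: np.ndarray,
                       excluded: set[tuple[int, int]] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Solve for basis variances w and correlations r from a variation matrix.

    ``excluded`` pairs (i < j) are removed from the linear system (their t
    entry leaves the row sums and the corresponding coefficients drop by one),
    mirroring the iterative strongest-pair exclusion.

    Returns ``(w, r)`` with r symmetric, unit diagonal, clipped to [-1, 1].
    """
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 3:
        raise ValueError("need >= 3 components")
    m = np.ones((d, d)) + np.diag(np.full(d, float(d - 2)))
    rhs = t.sum(axis=1)
    if excluded:
        for i, j in excluded:
            rhs[i] -= t[i, j]
            rhs[j] -= t[i, j]
            m[i, j] -= 1.0
            m[j, i] -= 1.0
            m[i, i] -= 1.0
            m[j, j] -= 1.0
    w = np.linalg.solve(m, rhs)
    n_floored = int((w <= 0).sum())
    if n_floored:
        log.debug("floored %d non-positive basis variances", n_floored)
        w = np.maximum(w, _OMEGA_FLOOR)
    sw = np.sqrt(w)
    r = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sw, sw))
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return w, r


def _iterative_sparcc(f: np.ndarray, n_iter: int, exclusion_threshold: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One SparCC pass on a fraction matrix with strongest-pair exclusion."""
    d = f.shape[1]
    t = _variation_from_fractions(f)
    excluded: set[tuple[int, int]] = set()
    w, r = basis_correlations(t)
    counts = np.zeros(d, int)
    for _ in range(n_iter):
        mask = np.abs(r.copy())
        np.fill_diagonal(mask, 0.0)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = 0.0
        # taxa saturated with exclusions would make the system singular
        saturated = counts >= d - 3
        mask[saturated, :] = 0.0
        mask[:, saturated] = 0.0
        i, j = np.unravel_index(int(np.argmax(mask)), mask.shape)
        if mask[i, j] <= exclusion_threshold:
            break
        pair = (min(i, j), max(i, j))
        excluded.add(pair)
        counts[i] += 1
        counts[j] += 1
        if d - int((counts >= d - 3).sum()) < 4:
            log.debug("stopping exclusion: fewer than 4 active taxa left")
            break
        try:
            w, r = basis_correlations(t, excluded)
        except np.linalg.LinAlgError:
            log.debug("singular exclusion system; keeping previous solution")
            excluded.discard(pair)
            break
    return w, r


@dataclass
class SparCCResults:
    """Fitted basis correlations.

    Attributes
    ----------
    correlations : pandas.DataFrame
        Symmetric taxa x taxa correlation estimates in [-1, 1], unit diagonal
        (median over Dirichlet resamples).
    basis_variances : pandas.Series
        Basis log-variance estimates (median over resamples).
    n_resamples : int
    dropped_taxa : list of str
        Taxa removed before inference (all-zero or zero-variance columns).
    """

    correlations: pd.DataFrame
    basis_variances: pd.Series
    n_resamples: int
    dropped_taxa: list[str] = field(default_factory=list)
    params_used: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.correlations.columns)

    def edges(self, cutoff: float = 0.5) -> pd.DataFrame:
        """Signed edge list of pairs with |r| >= cutoff (inclusive)."""
        return threshold_edges(self, cutoff)

    def summary(self) -> str:
        r = self.correlations.to_numpy()
        iu = np.triu_indices_from(r, k=1)
        off = r[iu]
        lines = [
            "Basis correlation fit (SparCC)",
            "=" * 34,
            f"taxa:               {len(self.taxa)}",
            f"dropped taxa:       {len(self.dropped_taxa)}",
            f"resamples:          {self.n_resamples}",
            f"|r| >= 0.5 pairs:   {int((np.abs(off) >= 0.5).sum())}",
            f"max |r|:            {np.abs(off).max():.3f}" if off.size else
            "max |r|:            n/a",
            f"median basis var:   {float(np.median(self.basis_variances)):.3f}",
        ]
        for k, v in sorted(self.params_used.items()):
            lines.append(f"{k + ':':<20}{v}")
        return "\n".join(lines)


class SparCC:
    """Basis-correlation model for a taxa count matrix.

    Parameters
    ----------
    table : TaxaTable or pandas.DataFrame
        Samples x taxa counts.  All-zero and zero-variance taxa are dropped
        before inference (log-ratios are undefined / uninformative for them),
        as are taxa whose observed log-fraction variance is smaller than
        ``VARIANCE_NOISE_RATIO`` times the variance expected from counting
        noise alone: for such taxa — dominant genera with near-constant
        relative abundance, and very rare tail genera — the basis correlation
        is unidentifiable, and the tiny basis-variance denominator would
        amplify estimation noise into spurious strong correlations.  Dropped
        taxa are recorded on the results object.
    pseudocount : float
        Added to counts when forming point-estimate fractions.
    n_iter : int
        Maximum number of strongest-pair exclusions per resample.
    exclusion_threshold : float
        |r| above which the strongest pair is excluded and the system
        re-solved.
    n_resamples : int
        Number of Dirichlet posterior resamples of the fractions; the final
        estimate is the elementwise median.
    """

    VARIANCE_NOISE_RATIO = 2.0
    MIN_LOG_VARIANCE = 0.25  # log-sd 0.5: below this, r is not estimable here

    def __init__(self, table, pseudocount: float = 1.0, n_iter: int = 10,
                 exclusion_threshold: float = 0.1, n_resamples: int = 20,
                 variance_filter: bool = True,
                 min_log_variance: float | None = None):
        if isinstance(table, TaxaTable):
            counts = table.counts
        else:
            counts = pd.DataFrame(table)
        keep, dropped = [], []
        if min_log_variance is None:
            min_log_variance = self.MIN_LOG_VARIANCE
        if not variance_filter:
            noise_ratio, min_log_variance = 0.0, 0.0
        else:
            noise_ratio = self.VARIANCE_NOISE_RATIO
        f = (counts.to_numpy(float) + pseudocount)
        f /= f.sum(axis=1, keepdims=True)
        logf = np.log(f)
        data_var = logf.var(axis=0, ddof=1)
        # expected log-fraction variance from counting noise alone
        # (Dirichlet posterior: Var[log p_t] ~ psi1(count + pseudocount))
        from scipy.special import polygamma
        noise_var = polygamma(1, counts.to_numpy(float)
                              + pseudocount).mean(axis=0)
        for k, col in enumerate(counts.columns):
            v = counts[col].to_numpy()
            if v.sum() == 0 or np.all(v == v[0]):
                dropped.append(str(col))
            elif data_var[k] < max(noise_ratio * noise_var[k],
                                   min_log_variance):
                dropped.append(str(col))
            else:
                keep.append(col)
        self.counts = counts[keep]
        self.dropped_taxa = dropped
        self.pseudocount = float(pseudocount)
        self.n_iter = int(n_iter)
        self.exclusion_threshold = float(exclusion_threshold)
        self.n_resamples = int(n_resamples)
        if self.counts.shape[1] < 3:
            raise ValueError("fewer than 3 informative taxa")
        if self.counts.shape[0] < 2:
            raise ValueError("need >= 2 samples")

    def fit(self, seed=None) -> SparCCResults:
        """Run the resampled iterative estimator; deterministic given seed."""
        rng = np.random.default_rng(seed)
        x = self.counts.to_numpy(dtype=float)
        rs, ws = [], []
        for _ in range(self.n_resamples):
            f = np.vstack([rng.dirichlet(row + self.pseudocount)
                           for row in x])
            w, r = _iterative_sparcc(f, self.n_iter, self.exclusion_threshold)
            rs.append(r)
            ws.append(w)
        r_med = np.median(np.stack(rs), axis=0)
        r_med = np.clip((r_med + r_med.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r_med, 1.0)
        w_med = np.median(np.stack(ws), axis=0)
        taxa = [str(c) for c in self.counts.columns]
        return SparCCResults(
            correlations=pd.DataFrame(r_med, index=taxa, columns=taxa),
            basis_variances=pd.Series(w_med, index=taxa),
            n_resamples=self.n_resamples,
            dropped_taxa=self.dropped_taxa,
            params_used=dict(pseudocount=self.pseudocount,
                             n_iter=self.n_iter,
                             exclusion_threshold=self.exclusion_threshold,
                             n_resamples=self.n_resamples,
                             seed=seed),
        )


def sparcc_infer(table, n_iter: int = 10, exclusion_threshold: float = 0.1,
                 n_resamples: int = 20, seed=None, pseudocount: float = 1.0,
                 variance_filter: bool = True) -> SparCCResults:
    """Functional wrapper: ``SparCC(table, ...).fit(seed)``."""
    model = SparCC(table, pseudocount=pseudocount, n_iter=n_iter,
                   exclusion_threshold=exclusion_threshold,
                   n_resamples=n_resamples, variance_filter=variance_filter)
    return model.fit(seed=seed)


def threshold_edges(result: SparCCResults | pd.DataFrame,
                    cutoff: float = 0.5) -> pd.DataFrame:
    """Signed edge list of taxon pairs with r >= cutoff or r <= -cutoff.

    The bound is inclusive.  Returns columns ``taxon_a, taxon_b, r, sign``
    with taxon_a < taxon_b in the matrix ordering.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    corr = (result.correlations if isinstance(result, SparCCResults)
            else pd.DataFrame(result))
    taxa = list(corr.columns)
    r = corr.to_numpy()
    rows = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if abs(r[i, j]) >= cutoff:
                rows.append((taxa[i], taxa[j], float(r[i, j]),
                             1 if r[i, j] > 0 else -1))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "sign"])
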