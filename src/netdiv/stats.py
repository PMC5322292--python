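"""Multivariate statistics on distance matrices.

PERMANOVA follows Anderson's (2001) partition: Gower-centre the squared
distance matrix, G = -(1/2) J D^2 J, partition tr(G) sequentially across
model terms via hat matrices (the adonis convention: Type-I sums of squares
in the order the terms are given), and assess each term's pseudo-F against
free permutations of sample labels.  The permutation p-value carries the +1
correction, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so it is never 0.

PCoA is classical scaling of the same Gower matrix (via scikit-bio); negative
eigenvalues are reported but not corrected, and coordinates are returned for
positive axes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import skbio

from .data import DataValidationError, DistanceMatrix

__all__ = [
    "PermanovaResult",
    "PcoaResult",
    "permanova",
    "permanova_formula",
    "pcoa",
    "gradient_correlation",
]


@dataclass
class PermanovaResult:
    """Per-term pseudo-F, R-squared and permutation p-values.

    ``table`` is indexed by term (plus a ``Residual`` row) with columns
    ``df``, ``ss``, ``F``, ``R2`` and ``p``.  For a single-factor model the
    scalar accessors ``f``, ``r2`` and ``p`` read the first term's row.
    """

    table: pd.DataFrame
    n_permutations: int

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]

    @property
    def f(self) -> float:
        return float(self.table.loc[self.terms[0], "F"])

    @property
    def r2(self) -> float:
        return float(self.table.loc[self.terms[0], "R2"])

    @property
    def p(self) -> float:
        return float(self.table.loc[self.terms[0], "p"])


def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy_columns(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype(str), drop_first=False).to_numpy(float)


def _term_matrix(term: str, meta: pd.DataFrame) -> np.ndarray:
    """Model columns for one term; ``a:b`` builds interaction columns."""
    parts = term.split(":")
    if len(set(parts)) != len(parts):
        raise DataValidationError(f"term {term!r} interacts a factor with itself")
    for part in parts:
        if part not in meta.columns:
            raise DataValidationError(f"unknown factor {part!r}")
    cols = _dummy_columns(meta[parts[0]])
    for part in parts[1:]:
        nxt = _dummy_columns(meta[part])
        cols = np.einsum("ni,nj->nij", cols, nxt).reshape(cols.shape[0], -1)
    return cols


def permanova_formula(
    d: DistanceMatrix,
    metadata: pd.DataFrame | Mapping[str, Mapping[str, object]],
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA over an ordered list of terms.

    ``metadata`` maps sample IDs (rows) to factor columns; interaction terms
    are written ``a:b``.  Each term's SS is the increment in explained
    tr(HG) as its columns join the model; F uses the residual mean square of
    the full model.  A term adding no rank raises an aliasing error.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame(metadata)
    missing = [s for s in d.sample_ids if s not in metadata.index]
    if missing:
        raise DataValidationError(f"samples missing from metadata: {missing[:10]}")
    meta = metadata.loc[list(d.sample_ids)]
    if not np.isfinite(d.values).all():
        raise DataValidationError("non-finite distances")
    n = len(d.sample_ids)
    g = _gower(d.values)
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise DataValidationError("degenerate distance matrix (zero total SS)")

    # cumulative hat matrices, intercept first
    x = np.ones((n, 1))
    hats = []
    ranks = [1]
    for term in terms:
        x = np.hstack([x, _term_matrix(term, meta)])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        basis = u[:, s > 1e-9 * s.max()]
        rank = basis.shape[1]
        if rank <= ranks[-1]:
            raise DataValidationError(
                f"term {term!r} is aliased with earlier terms (adds no rank)"
            )
        hats.append(basis @ basis.T)
        ranks.append(rank)
    h_full = hats[-1]
    df_terms = np.diff(ranks)
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise DataValidationError("no residual degrees of freedom")

    def partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        expl = []
        last = 0.0
        for h in hats:
            cur = float(np.einsum("ij,ji->", h, gm))
            expl.append(cur - last)
            last = cur
        ss_res = float(np.trace(gm)) - last
        return np.array(expl), ss_res

    ss_terms, ss_res = partition(g)
    f_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    if n_perm < 1:
        raise DataValidationError("n_perm must be >= 1")
    exceed = np.zeros(len(hats), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_t, ss_r = partition(gp)
        f_p = (ss_t / df_terms) / (ss_r / df_res)
        exceed += f_p >= f_obs
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            dict(term=term, df=int(df_terms[k]), ss=ss_terms[k], F=f_obs[k],
                 R2=ss_terms[k] / ss_total, p=p_vals[k])
        )
    rows.append(
        dict(term="Residual", df=int(df_res), ss=ss_res, F=np.nan,
             R2=ss_res / ss_total, p=np.nan)
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table, n_perm)


def permanova(
    d: DistanceMatrix,
    groups: Mapping[str, object] | Sequence[object],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a grouping of samples.

    F = (SS_between / (a - 1)) / (SS_within / (n - a)) with the sums of
    squares computed from squared distances; requires at least two groups,
    each with at least two samples.
    """
    if isinstance(groups, Mapping):
        labels = [groups[s] for s in d.sample_ids]
    else:
        labels = list(groups)
        if len(labels) != len(d.sample_ids):
            raise DataValidationError("one group label per sample required")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise DataValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise DataValidationError(f"singleton groups not allowed: {small}")
    meta = pd.DataFrame({"group": [str(x) for x in labels]}, index=list(d.sample_ids))
    return permanova_formula(d, meta, ["group"], n_perm=n_perm, seed=seed)


@dataclass
class PcoaResult:
    """Principal-coordinates embedding.

    ``coordinates``: samples x axes (positive-eigenvalue axes only, ordered
    by descending eigenvalue); ``eigenvalues``: all eigenvalues including
    negative ones.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported uncorrected;
    coordinates are returned only for positive axes.  ``n_axes`` beyond the
    positive-eigenvalue count is truncated with a warning.
    """
    dm = skbio.DistanceMatrix(d.values, ids=list(d.sample_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = skbio.stats.ordination.pcoa(dm, method="eigh")
    eigvals = np.asarray(res.eigvals, dtype=float)
    coords = res.samples.to_numpy(dtype=float)
    pos = eigvals > 1e-10 * max(1.0, np.abs(eigvals).max())
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else n_axes
    if k > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            "truncating", stacklevel=2,
        )
        k = n_pos
    cols = [f"PC{i + 1}" for i in range(k)]
    frame = pd.DataFrame(coords[:, :k], index=list(d.sample_ids), columns=cols)
    return PcoaResult(frame, eigvals)


def gradient_correlation(
    d: DistanceMatrix,
    covariate: Mapping[str, float] | Sequence[float],
    transform: str = "absdiff",
) -> float:
    """Spearman correlation between pairwise distances and |Delta covariate|.

    The upper triangle of ``d`` is correlated against the absolute pairwise
    difference of a numeric sample covariate (e.g. latitude).
    """
    if transform != "absdiff":
        raise ValueError(f"unknown transform: {transform!r}")
    if isinstance(covariate, Mapping):
        v = np.array([float(covariate[s]) for s in d.sample_ids])
    else:
        v = np.asarray(covariate, dtype=float)
        if v.shape[0] != len(d.sample_ids):
            raise DataValidationError("one covariate value per sample required")
    if np.ptp(v) == 0:
        raise DataValidationError("constant covariate: correlation undefined")
    iu = np.triu_indices(len(v), k=1)
    delta = np.abs(v[:, None] - v[None, :])[iu]
    rho = sps.spearmanr(d.condensed(), delta).statistic
    return float(rho)
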