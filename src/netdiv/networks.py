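"""Taxa association networks: inference and the canonical [0, 1] transform.

Raw co-occurrence interaction matrices ``I_C`` can be inferred from a count
table by four methods (SparCC, Spearman, taxa-wise Bray–Curtis similarity,
taxa-wise weighted Jaccard similarity), or from a phylogeny as the cophenetic
similarity matrix ``I_phi``.  Because each method lives on its own scale, raw
matrices are brought to a common scale by the canonical transform: correlate
every pair of taxa by their full association *profiles* (their rows of the raw
matrix) and map the Pearson correlation r to C = (1 + r) / 2.  The result
scales from 0 (avoidance) through 0.5 (neutral) to 1 (complete association)
and is positive semi-definite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .data import (
    AssociationMatrix,
    CountTable,
    DataValidationError,
    InteractionMatrix,
    PhyloTree,
)

__all__ = [
    "infer_cooccurrence",
    "sparcc_correlations",
    "transform_association",
    "cophenetic_similarity",
    "phylo_association",
]


def _drop_zero_taxa(table: CountTable) -> CountTable:
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        gone = [t for t, s in zip(table.taxa_ids, totals) if s == 0]
        warnings.warn(
            f"excluding {len(gone)} all-zero taxa from network inference: {gone[:10]}",
            stacklevel=3,
        )
        keep = [t for t, s in zip(table.taxa_ids, totals) if s > 0]
        table = table.select_taxa(keep)
    return table


def infer_cooccurrence(
    table: CountTable, method: str = "sparcc", seed: int | None = None
) -> InteractionMatrix:
    """Infer a raw taxa co-occurrence matrix I_C from a count table.

    ``spearman`` and ``sparcc`` return correlations on [-1, 1]; ``braycurtis``
    and ``wjaccard`` return taxa-wise similarities (1 - dissimilarity across
    samples) on [0, 1].  Diagonal is the method's self-association (1 for all
    four).  Taxa with all-zero counts are excluded with a warning.
    """
    if table.n_samples < 3:
        raise DataValidationError("network inference needs at least 3 samples")
    table = _drop_zero_taxa(table)
    if table.n_taxa < 2:
        raise DataValidationError("network inference needs at least 2 taxa")
    x = table.counts.astype(float)
    if method == "spearman":
        rho = sps.spearmanr(x, axis=1).statistic
        if table.n_taxa == 2:  # scipy returns a scalar for two variables
            rho = np.array([[1.0, rho], [rho, 1.0]])
        rho = np.nan_to_num(np.asarray(rho, dtype=float), nan=0.0)
        vals = np.clip(rho, -1.0, 1.0)
    elif method == "braycurtis":
        s = x.sum(axis=1)
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = s[:, None] + s[None, :]
        vals = 1.0 - num / den
    elif method == "wjaccard":
        mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
        maxs = np.maximum(x[:, None, :], x[None, :, :]).sum(axis=2)
        vals = mins / maxs
    elif method == "sparcc":
        return sparcc_correlations(table, seed=seed)
    else:
        raise ValueError(f"unknown network method: {method!r}")
    np.fill_diagonal(vals, 1.0)
    return InteractionMatrix(list(table.taxa_ids), vals, method)


def _basis_correlations(
    T: np.ndarray, n_exclusion_iters: int, threshold: float
) -> np.ndarray:
    """One SparCC basis-correlation estimate from a log-ratio variation matrix.

    T[i, j] = Var(log(x_i / x_j)).  Basis variances omega solve the sparse
    approximation (diag(d) + W) omega = t, where W marks still-included pairs,
    d its row sums and t the row sums of T over included pairs.  The most
    strongly correlated pair above ``threshold`` is iteratively excluded.
    """
    d = T.shape[0]
    include = ~np.eye(d, dtype=bool)
    rho = np.eye(d)
    for _ in range(n_exclusion_iters + 1):
        W = include.astype(float)
        A = np.diag(W.sum(axis=1)) + W
        t = (T * W).sum(axis=1)
        try:
            omega = np.linalg.solve(A, t)
        except np.linalg.LinAlgError:
            break
        omega = np.maximum(omega, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - T) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        masked = np.where(include, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        include[i, j] = include[j, i] = False
        # never fully disconnect a taxon from the system
        if include[i].sum() < 2 or include[j].sum() < 2:
            include[i, j] = include[j, i] = True
            break
    return rho


def sparcc_correlations(
    table: CountTable,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    n_resamples: int = 20,
    seed: int | None = None,
) -> InteractionMatrix:
    """SparCC basis correlations for compositional count data.

    Per resample, taxon fractions are drawn from Dirichlet(counts + 1) per
    sample, the log-ratio variation matrix T_ij = Var(log x_i - log x_j) is
    computed across samples, and basis correlations are estimated under a
    sparsity assumption with iterative exclusion of the most strongly
    correlated pair (threshold 0.1, up to ``n_exclusion_iters`` exclusions).
    Estimates are averaged over ``n_resamples`` Dirichlet draws and clipped to
    [-1, 1].  Deterministic given ``seed``.
    """
    if table.n_samples < 3:
        raise DataValidationError("SparCC needs at least 3 samples")
    table = _drop_zero_taxa(table)
    if table.n_taxa < 4:
        raise DataValidationError(
            "SparCC basis-variance estimation needs at least 4 taxa"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    d, n = counts.shape
    acc = np.zeros((d, d))
    for _ in range(n_resamples):
        # per-sample Dirichlet(counts + 1) fractions
        gam = rng.standard_gamma(counts.T + 1.0)  # samples x taxa
        frac = gam / gam.sum(axis=1, keepdims=True)
        logf = np.log(frac)
        V = np.cov(logf, rowvar=False)  # taxa x taxa covariance of log fractions
        var = np.diag(V)
        T = var[:, None] + var[None, :] - 2.0 * V
        np.fill_diagonal(T, 0.0)
        acc += _basis_correlations(T, n_exclusion_iters, exclusion_threshold)
    rho = np.clip(acc / n_resamples, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return InteractionMatrix(list(table.taxa_ids), rho, "sparcc")


def transform_association(
    raw: InteractionMatrix, exclude_focal: bool = False
) -> AssociationMatrix:
    """Canonical transform of a raw interaction matrix to the [0, 1] scale.

    C_ij = (1 + pearson(I_i*, I_j*)) / 2, correlating the full association
    profiles (rows) of taxa i and j.  By default the full rows enter the
    correlation, including the diagonal and the focal columns i and j;
    ``exclude_focal=True`` drops columns i and j from the two profiles.
    Zero-variance profiles get neutral associations (C = 0.5) with a warning.
    """
    vals = raw.values
    n = vals.shape[0]
    if n < 3:
        raise DataValidationError("association transform needs at least 3 taxa")
    if not exclude_focal:
        sd = vals.std(axis=1)
        flat = sd <= 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(vals)
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} taxa have constant association profiles; "
                "their associations are set to neutral (0.5)",
                stacklevel=2,
            )
            r[flat, :] = 0.0
            r[:, flat] = 0.0
        r = np.nan_to_num(r, nan=0.0)
    else:
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                xi, xj = vals[i, mask], vals[j, mask]
                if xi.std() <= 1e-12 or xj.std() <= 1e-12:
                    r[i, j] = r[j, i] = 0.0
                else:
                    r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    c = (1.0 + r) / 2.0
    return AssociationMatrix(
        list(raw.taxa_ids),
        c,
        source="phylogeny" if raw.method_tag == "cophenetic" else "cooccurrence",
    )


def cophenetic_similarity(tree: PhyloTree) -> InteractionMatrix:
    """Cophenetic phylogenetic similarity matrix I_phi.

    I_phi[i, j] = 1 - d_coph(i, j) / max d_coph, where d_coph is the total
    branch length of the path between leaves i and j.  Self-similarity is 1;
    the most distant leaf pair has similarity 0.
    """
    names = tree.leaf_names
    if len(names) < 3:
        raise DataValidationError("cophenetic similarity needs at least 3 leaves")
    dm = tree.tree.tip_tip_distances(names)
    d = np.asarray(dm.data, dtype=float)
    if not np.isfinite(d).all():
        raise DataValidationError("non-finite branch lengths in tree")
    dmax = d.max()
    if dmax <= 0:
        raise DataValidationError("all cophenetic distances are zero")
    sim = 1.0 - d / dmax
    np.fill_diagonal(sim, 1.0)
    return InteractionMatrix(list(dm.ids), sim, "cophenetic")


def phylo_association(tree: PhyloTree, exclude_focal: bool = False) -> AssociationMatrix:
    """Phylogenetic association matrix Phi = transform(I_phi)."""
    return transform_association(cophenetic_similarity(tree), exclude_focal)
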