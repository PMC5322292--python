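"""Synthetic community generators: GLV dynamics, interaction matrices,
count shuffling, Dirichlet-multinomial sampling and rarefaction.

These engines emulate habitat-structured OTU count tables with controllable
habitat preference, taxa co-abundance and explicit interaction structure.
:func:`make_benchmark_scenario` composes them into four named setups:

* ``negative_control`` — abundances shuffled across all samples (breaking
  habitat preference and co-abundance) fed to an interaction-neutral GLV; no
  index should separate the habitat groups.
* ``habitat_only`` — abundances shuffled *within* habitat groups (breaking
  co-abundance but keeping preference) with neutral GLV dynamics.
* ``interaction_only`` — Poisson(lambda=5) starting counts, invariant growth
  rates, and a two-group interaction matrix (scale-free within-group
  structure, competitive between groups); habitat labels are assigned
  *post hoc* from summed group abundances.
* ``habitat_plus_interaction`` — within-group shuffled starting counts plus
  the two-group interaction matrix.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import CountTable, DataValidationError, PhyloTree

__all__ = [
    "GlvConfig",
    "ScenarioResult",
    "SCENARIO_NAMES",
    "glv_simulate",
    "make_interaction_matrix",
    "shuffle_counts",
    "poisson_counts",
    "assign_mock_habitats",
    "sample_dirichlet_multinomial",
    "rarefy",
    "random_tree",
    "make_benchmark_scenario",
    "default_base_table",
]

SCENARIO_NAMES = (
    "negative_control",
    "habitat_only",
    "interaction_only",
    "habitat_plus_interaction",
)


@dataclass
class GlvConfig:
    """Parameters of the discrete-time generalized Lotka–Volterra run.

    ``carrying_capacity`` is per sample (scalar broadcast allowed); growth
    rates are per taxon on [0, 1]; ``interaction_matrix[i, j]`` is the effect
    of taxon j on taxon i (diagonal must be <= 0, self-limitation).  Starting
    abundances are scaled so each sample begins at ``initial_fraction`` of
    its carrying capacity.
    """

    n_taxa: int
    n_samples: int
    carrying_capacity: np.ndarray | float
    growth_rates: np.ndarray
    interaction_matrix: np.ndarray | None = None
    initial_fraction: float = 0.1
    n_steps: int = 100
    step_size: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.growth_rates.shape != (self.n_taxa,):
            raise DataValidationError("growth_rates must be one value per taxon")
        k = np.broadcast_to(
            np.asarray(self.carrying_capacity, dtype=float), (self.n_samples,)
        ).copy()
        if (k <= 0).any():
            raise DataValidationError("carrying capacities must be positive")
        self.carrying_capacity = k
        if self.interaction_matrix is None:
            self.interaction_matrix = np.zeros((self.n_taxa, self.n_taxa))
        a = np.asarray(self.interaction_matrix, dtype=float)
        if a.shape != (self.n_taxa, self.n_taxa):
            raise DataValidationError("interaction matrix shape mismatch")
        if (np.diag(a) > 0).any():
            raise DataValidationError(
                "interaction matrix diagonal must be <= 0 (self-limitation)"
            )
        self.interaction_matrix = a
        if not (0 < self.initial_fraction <= 1):
            raise DataValidationError("initial_fraction must be in (0, 1]")


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    floor = np.floor(x)
    frac = x - floor
    return (floor + (rng.random(x.shape) < frac)).astype(np.int64)


def glv_simulate(config: GlvConfig, starting_counts: CountTable) -> CountTable:
    """Run per-sample GLV dynamics from a starting count table.

    Ricker-type update per step:
        x_i <- x_i * exp(dt * (r_i (1 - sum_x / K) + (A x)_i / K))
    which keeps abundances non-negative without an ODE solver.  Starting
    abundances are rescaled to ``initial_fraction * K`` per sample; final
    abundances are stochastically rounded to integer counts (floor plus a
    Bernoulli remainder, driven by the config seed).
    """
    if starting_counts.counts.shape != (config.n_taxa, config.n_samples):
        raise DataValidationError("starting counts do not match config dimensions")
    rng = np.random.default_rng(config.seed)
    k = config.carrying_capacity
    x = starting_counts.counts.astype(float)
    totals = x.sum(axis=0)
    x = x * (config.initial_fraction * k / totals)[np.newaxis, :]
    r = config.growth_rates[:, np.newaxis]
    a = config.interaction_matrix
    dt = config.step_size
    for _ in range(config.n_steps):
        tot = x.sum(axis=0)
        growth = r * (1.0 - tot / k)[np.newaxis, :] + (a @ x) / k[np.newaxis, :]
        x = x * np.exp(dt * growth)
        if not np.isfinite(x).all():
            bad = starting_counts.sample_ids[
                int(np.argwhere(~np.isfinite(x))[0][1])
            ]
            raise DataValidationError(f"non-finite GLV state in sample {bad!r}")
        over = x.sum(axis=0) > 1e6 * k
        if over.any():
            bad = starting_counts.sample_ids[int(np.argmax(over))]
            raise DataValidationError(f"GLV divergence in sample {bad!r}")
    counts = np.clip(_stochastic_round(x, rng), 0, None)
    # guard against fully extinct samples (keeps CountTable invariant)
    dead = counts.sum(axis=0) == 0
    if dead.any():
        top = np.argmax(x, axis=0)
        counts[top[dead], np.where(dead)[0]] = 1
    return CountTable(list(starting_counts.taxa_ids),
                      list(starting_counts.sample_ids), counts)


def make_interaction_matrix(
    n_taxa: int,
    group_split: tuple[list[int], list[int]],
    ba_edges_per_node: int = 2,
    seed: int | None = None,
    within_strength: float = 0.5,
    between_range: tuple[float, float] = (-0.5, -0.1),
    between_noise: float = 0.05,
) -> np.ndarray:
    """Signed GLV interaction matrix with scale-free within-group structure.

    Within each group, interactions sit on the edges of a Barabási–Albert
    graph with magnitudes Uniform(0, ``within_strength``) and random signs;
    all between-group entries are competitive, Uniform(-0.5, -0.1) plus
    Uniform(-0.05, 0.05) noise (strictly negative).  ``group_split`` gives
    the taxon indices of the two groups (a partition of range(n_taxa)).
    """
    g1, g2 = (list(g) for g in group_split)
    if sorted(g1 + g2) != list(range(n_taxa)):
        raise DataValidationError("group_split must partition the taxa")
    for g in (g1, g2):
        if len(g) < ba_edges_per_node + 1:
            raise DataValidationError(
                f"group of size {len(g)} too small for m={ba_edges_per_node}"
            )
    rng = np.random.default_rng(seed)
    a = np.zeros((n_taxa, n_taxa))
    for g in (g1, g2):
        graph = nx.barabasi_albert_graph(
            len(g), ba_edges_per_node, seed=int(rng.integers(2**31))
        )
        for u, v in graph.edges():
            i, j = g[u], g[v]
            a[i, j] = rng.uniform(0, within_strength) * rng.choice([-1.0, 1.0])
            a[j, i] = rng.uniform(0, within_strength) * rng.choice([-1.0, 1.0])
    lo, hi = between_range
    for gi, gj in ((g1, g2), (g2, g1)):
        block = rng.uniform(lo, hi, size=(len(gi), len(gj)))
        block += rng.uniform(-between_noise, between_noise, size=block.shape)
        a[np.ix_(gi, gj)] = np.minimum(block, -1e-6)
    np.fill_diagonal(a, 0.0)
    return a


def shuffle_counts(
    table: CountTable,
    scope: str = "global",
    groups: dict[str, object] | None = None,
    seed: int | None = None,
) -> CountTable:
    """Permute each taxon's counts across samples.

    ``global`` permutes over all samples (breaking habitat preference and
    co-abundance); ``within_group`` permutes separately inside each sample
    group (breaking co-abundance only).  Per-taxon totals within each scope
    are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    if scope == "global":
        blocks = [np.arange(table.n_samples)]
    elif scope == "within_group":
        if groups is None:
            raise DataValidationError("within_group shuffle requires groups")
        unknown = [s for s in table.sample_ids if s not in groups]
        if unknown:
            raise DataValidationError(f"samples without group label: {unknown[:10]}")
        labels = np.array([str(groups[s]) for s in table.sample_ids])
        blocks = [np.where(labels == lab)[0] for lab in np.unique(labels)]
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    for block in blocks:
        if len(block) < 2:
            continue
        for i in range(table.n_taxa):
            counts[i, block] = counts[i, block[rng.permutation(len(block))]]
    # a sample could end up all-zero; re-draw offending taxa order cheaply by
    # moving one count from the richest sample of the block
    totals = counts.sum(axis=0)
    for block in blocks:
        for s in block:
            if totals[s] == 0:
                donor = block[np.argmax(counts.sum(axis=0)[block])]
                i = int(np.argmax(counts[:, donor]))
                counts[i, s] += 1
                counts[i, donor] -= 1
    return CountTable(list(table.taxa_ids), list(table.sample_ids), counts)


def poisson_counts(
    n_taxa: int, n_samples: int, lam: float = 5.0, seed: int | None = None
) -> CountTable:
    """I.i.d. Poisson(lambda) count table."""
    if lam < 0:
        raise DataValidationError("lambda must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    empty = counts.sum(axis=0) == 0
    if empty.any():  # only plausible for tiny lambda; keep samples non-empty
        counts[0, empty] = 1
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n_samples)]
    return CountTable(taxa, samples, counts)


def assign_mock_habitats(
    table: CountTable, group_split: tuple[list[int], list[int]]
) -> dict[str, str]:
    """Label each sample by the taxa group with the larger summed count.

    Ties go to group 1 with a warning.
    """
    g1, g2 = group_split
    s1 = table.counts[list(g1), :].sum(axis=0)
    s2 = table.counts[list(g2), :].sum(axis=0)
    ties = s1 == s2
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} samples tie between habitat groups; "
            "assigned to group 1", stacklevel=2,
        )
    return {
        s: ("group1" if a >= b else "group2")
        for s, a, b in zip(table.sample_ids, s1, s2)
    }


def sample_dirichlet_multinomial(
    component_weights,
    component_alphas,
    depth: int,
    n_samples: int,
    seed: int | None = None,
) -> tuple[CountTable, list[int]]:
    """Sample counts from a Dirichlet-multinomial mixture.

    For each sample: draw a mixture component, draw taxon probabilities from
    Dirichlet(alpha_component), draw counts Multinomial(depth, p).  Returns
    the table plus the component index per sample.
    """
    if depth <= 0:
        raise DataValidationError("depth must be positive")
    w = np.asarray(component_weights, dtype=float)
    if abs(w.sum() - 1) > 1e-8 or (w < 0).any():
        raise DataValidationError("component weights must be a simplex")
    alphas = [np.asarray(a, dtype=float) for a in component_alphas]
    if len(alphas) != len(w) or any((a <= 0).any() for a in alphas):
        raise DataValidationError("component alphas must be positive vectors")
    n_taxa = alphas[0].shape[0]
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    comps: list[int] = []
    for j in range(n_samples):
        c = int(rng.choice(len(w), p=w))
        comps.append(c)
        p = rng.dirichlet(alphas[c])
        counts[:, j] = rng.multinomial(depth, p)
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n_samples)]
    return CountTable(taxa, samples, counts), comps


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning; taxa
    left with all-zero rows are removed.
    """
    if depth < 1:
        raise DataValidationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals >= depth
    if not keep.any():
        raise DataValidationError(f"all samples have fewer than {depth} reads")
    if not keep.all():
        gone = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"rarefy dropped {len(gone)} samples below depth {depth}", stacklevel=2
        )
    cols = []
    sample_ids = []
    for j, s in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col)
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
        sample_ids.append(s)
    counts = np.column_stack(cols)
    nz = counts.sum(axis=1) > 0
    taxa = [t for t, k in zip(table.taxa_ids, nz) if k]
    return CountTable(taxa, sample_ids, counts[nz, :])


def random_tree(taxa_ids, seed: int | None = None) -> PhyloTree:
    """Random bifurcating tree over the given taxa (random joins, exponential
    branch lengths); a lightweight stand-in phylogeny for simulations."""
    from skbio import TreeNode

    rng = np.random.default_rng(seed)
    nodes = []
    for t in taxa_ids:
        n = TreeNode(name=str(t))
        n.length = float(rng.exponential(0.1))
        nodes.append(n)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.exponential(0.1))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.length = None
    root.extend(nodes)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Benchmark scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Everything needed to benchmark indices on one simulated setup."""

    table: CountTable
    labels: dict[str, str]
    true_interactions: np.ndarray | None
    group_split: tuple[list[int], list[int]] | None
    name: str


def default_base_table(
    n_samples: int = 50,
    n_taxa: int = 200,
    depth: int = 2000,
    seed: int | None = None,
) -> tuple[CountTable, dict[str, str], tuple[list[int], list[int]]]:
    """Habitat-structured base table from a two-component Dirichlet-multinomial.

    Half the taxa prefer each habitat: preferred taxa draw lognormal(0, 1)
    Dirichlet weights, non-preferred taxa get 0.02, yielding strong habitat
    preference and within-habitat co-abundance.  Samples split evenly
    between the two habitats.
    """
    rng = np.random.default_rng(seed)
    half = n_taxa // 2
    g1, g2 = list(range(half)), list(range(half, n_taxa))
    a1 = np.full(n_taxa, 0.02)
    a2 = np.full(n_taxa, 0.02)
    a1[g1] = rng.lognormal(0.0, 1.0, size=half)
    a2[g2] = rng.lognormal(0.0, 1.0, size=n_taxa - half)
    n1 = n_samples // 2
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    labels: dict[str, str] = {}
    samples = [f"s{j}" for j in range(n_samples)]
    for j in range(n_samples):
        alpha = a1 if j < n1 else a2
        p = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(depth, p)
        labels[samples[j]] = "habitat1" if j < n1 else "habitat2"
    empty = counts.sum(axis=0) == 0
    counts[0, empty] = 1
    table = CountTable([f"t{i}" for i in range(n_taxa)], samples, counts)
    return table, labels, (g1, g2)


def make_benchmark_scenario(
    name: str,
    base: CountTable | None = None,
    seed: int | None = None,
    base_labels: dict[str, str] | None = None,
    group_split: tuple[list[int], list[int]] | None = None,
) -> ScenarioResult:
    """Compose the generators into one of the four named benchmark setups.

    When ``base`` is omitted, a habitat-structured Dirichlet-multinomial base
    table (50 samples x 200 taxa) is generated.  Returns the simulated count
    table, habitat labels, and — for the interaction scenarios — the known
    ground-truth interaction matrix and taxa group split.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario: {name!r}")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731 - staged seed split

    if base is None:
        base, base_labels, group_split = default_base_table(seed=sub())
    elif base_labels is None and name != "interaction_only":
        raise DataValidationError("habitat scenarios need base labels")
    n_taxa, n_samples = base.n_taxa, base.n_samples
    if group_split is None:
        half = n_taxa // 2
        group_split = (list(range(half)), list(range(half, n_taxa)))

    if name == "negative_control":
        start = shuffle_counts(base, "global", seed=sub())
        cfg = GlvConfig(
            n_taxa, n_samples, base.sample_totals.astype(float),
            growth_rates=rng.uniform(0, 1, n_taxa), seed=sub(),
        )
        table = glv_simulate(cfg, start)
        return ScenarioResult(table, dict(base_labels), None, None, name)

    if name == "habitat_only":
        start = shuffle_counts(base, "within_group", groups=base_labels, seed=sub())
        cfg = GlvConfig(
            n_taxa, n_samples, base.sample_totals.astype(float),
            growth_rates=rng.uniform(0, 1, n_taxa), seed=sub(),
        )
        table = glv_simulate(cfg, start)
        return ScenarioResult(table, dict(base_labels), None, None, name)

    a = make_interaction_matrix(n_taxa, group_split, seed=sub())

    if name == "interaction_only":
        start = poisson_counts(n_taxa, n_samples, 5.0, seed=sub())
        k = start.sample_totals.astype(float) / 0.1  # start at 10% of capacity
        cfg = GlvConfig(
            n_taxa, n_samples, k,
            growth_rates=np.full(n_taxa, 0.5),  # invariant growth rates
            interaction_matrix=a, seed=sub(),
        )
        table = glv_simulate(cfg, start)
        labels = assign_mock_habitats(table, group_split)
        return ScenarioResult(table, labels, a, group_split, name)

    # habitat_plus_interaction
    start = shuffle_counts(base, "within_group", groups=base_labels, seed=sub())
    cfg = GlvConfig(
        n_taxa, n_samples, base.sample_totals.astype(float),
        growth_rates=rng.uniform(0, 1, n_taxa),
        interaction_matrix=a, seed=sub(),
    )
    table = glv_simulate(cfg, start)
    return ScenarioResult(table, dict(base_labels), a, group_split, name)
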