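"""End-to-end benchmarking workflows: network -> transform -> distances ->
PERMANOVA, and repeated downsampling regimes.

Both entry points re-infer the co-occurrence network from exactly the sample
subset under analysis, and split one master seed deterministically across
stages, so a full run is byte-reproducible.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AssociationMatrix, CountTable, DataValidationError, PhyloTree
from .indices import INDEX_CODES, distance_matrix, index_spec
from .networks import infer_cooccurrence, phylo_association, transform_association
from .simulate import rarefy
from .stats import permanova

logger = logging.getLogger(__name__)

__all__ = ["run_benchmark", "run_downsampling"]


def _stage_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def run_benchmark(
    counts: CountTable,
    labels: Mapping[str, object],
    indices: Sequence[str] | None = None,
    tree: PhyloTree | None = None,
    network_method: str = "sparcc",
    n_perm: int = 999,
    seed: int | None = None,
    association: AssociationMatrix | None = None,
) -> pd.DataFrame:
    """PERMANOVA effect sizes (F, R2, p) of a grouping for a set of indices.

    The co-occurrence network behind TU/TW is inferred from ``counts`` itself
    (the same subset under analysis) with ``network_method``, unless a
    precomputed ``association`` matrix is passed (e.g. a known ground-truth
    interaction network); Phi behind PU/PW comes from ``tree``.  Returns one
    row per index with the network method tag.
    """
    if indices is None:
        indices = [c for c in INDEX_CODES
                   if index_spec(c).requires != "tree" or tree is not None]
    seeds = _stage_seeds(seed, 2 + len(indices))
    specs = [index_spec(c) for c in indices]

    assoc_c = association
    if assoc_c is None and any(s.code in ("TU", "TW") for s in specs):
        raw = infer_cooccurrence(counts, network_method, seed=seeds[0])
        assoc_c = transform_association(raw)
        tag = network_method
    else:
        tag = association.source if association is not None else network_method
    assoc_phi = None
    if any(s.code in ("PU", "PW") for s in specs):
        if tree is None:
            raise DataValidationError("PU/PW requested but no tree supplied")
        assoc_phi = phylo_association(tree)

    rows = []
    for k, spec in enumerate(specs):
        if spec.code in ("TU", "TW"):
            aux_assoc, aux_tree = assoc_c, None
        elif spec.code in ("PU", "PW"):
            aux_assoc, aux_tree = assoc_phi, None
        elif spec.requires == "tree":
            if tree is None:
                raise DataValidationError(f"index {spec.code} requires a tree")
            aux_assoc, aux_tree = None, tree
        else:
            aux_assoc, aux_tree = None, None
        d = distance_matrix(counts, spec, tree=aux_tree, assoc=aux_assoc)
        res = permanova(d, {s: labels[s] for s in counts.sample_ids},
                        n_perm=n_perm, seed=seeds[2 + k])
        logger.info("benchmark %s: F=%.3f R2=%.4f p=%.4g", spec.code,
                    res.f, res.r2, res.p)
        rows.append(dict(index=spec.code, network=tag if spec.code in ("TU", "TW")
                         else ("phylogeny" if spec.code in ("PU", "PW") else "counts"),
                         F=res.f, R2=res.r2, p=res.p))
    return pd.DataFrame(rows)


def run_downsampling(
    counts: CountTable,
    labels: Mapping[str, object],
    samples_per_group: Sequence[int] = (),
    reads_per_sample: Sequence[int] = (),
    n_iter: int = 10,
    indices: Sequence[str] | None = None,
    tree: PhyloTree | None = None,
    network_method: str = "sparcc",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeat the benchmark over downsampled datasets.

    Two regime axes: ``samples_per_group`` draws that many samples from each
    group; ``reads_per_sample`` rarefies every sample to that depth.  Each
    (regime, iteration) re-infers the network on the subset.  Returns a
    long-format table with one row per (regime, iteration, index).
    Infeasible regimes are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    lab = {s: str(labels[s]) for s in counts.sample_ids}
    out = []

    def _bench(sub: CountTable, regime: str, value: int, it: int) -> None:
        res = run_benchmark(sub, lab, indices=indices, tree=tree,
                            network_method=network_method, n_perm=n_perm,
                            seed=int(rng.integers(2**31)))
        for _, row in res.iterrows():
            out.append(dict(regime=regime, value=value, iteration=it,
                            n_samples=sub.n_samples,
                            depth=int(sub.sample_totals.min()),
                            index=row["index"], network=row["network"],
                            F=row["F"], R2=row["R2"], p=row["p"]))

    groups: dict[str, list[str]] = {}
    for s, g in lab.items():
        groups.setdefault(g, []).append(s)
    for k in samples_per_group:
        if any(len(m) < k for m in groups.values()):
            warnings.warn(f"regime {k} samples/group infeasible; skipped",
                          stacklevel=2)
            continue
        for it in range(n_iter):
            chosen = []
            for members in groups.values():
                chosen += list(rng.choice(members, size=k, replace=False))
            _bench(counts.select_samples(chosen), "samples_per_group", k, it)
    for depth in reads_per_sample:
        if (counts.sample_totals < depth).all():
            warnings.warn(f"regime depth {depth} infeasible; skipped", stacklevel=2)
            continue
        for it in range(n_iter):
            sub = rarefy(counts, depth, seed=int(rng.integers(2**31)))
            _bench(sub, "reads_per_sample", depth, it)
    return pd.DataFrame(out)
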