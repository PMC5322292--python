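import numpy as np
import pytest

from netdiv.data import AssociationMatrix, CountTable, InteractionMatrix, PhyloTree


@pytest.fixture
def small_table():
    # 3 taxa x 2 samples, n = (8, 6), N = (2, 2)
    return CountTable(["t1", "t2", "t3"], ["A", "B"],
                      np.array([[5, 0], [3, 2], [0, 4]]))


@pytest.fixture
def worked_tree(tmp_path):
    """The 4-leaf worked tree ((A:1,B:1):1,(C:1,D:1):1);"""
    from netdiv.data import read_tree

    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
    return read_tree(p)


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 20, size=(6, 10))
    counts[:, counts.sum(axis=0) == 0] += 1
    return CountTable([f"t{i}" for i in range(6)],
                      [f"s{j}" for j in range(10)], counts)


def canonical_assoc(n_taxa: int, seed: int) -> AssociationMatrix:
    """A random association matrix produced by the canonical transform."""
    from netdiv.networks import transform_association

    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_taxa, n_taxa))
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 1.0)
    return transform_association(
        InteractionMatrix([f"t{i}" for i in range(n_taxa)], raw, "test")
    )
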