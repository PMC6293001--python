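import numpy as np
import pandas as pd
import pytest

from turbicomp import TriangleMesh
from turbicomp.phylo import Phylogeny


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
         [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return TriangleMesh(v, f, "cube")


@pytest.fixture
def tetra_mesh() -> TriangleMesh:
    # regular tetrahedron inscribed in the unit cube's alternating corners
    v = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    return TriangleMesh(v, f, "tetra")


@pytest.fixture
def balanced4() -> Phylogeny:
    return Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def asym4() -> Phylogeny:
    """4-taxon tree with unequal, hand-written branch lengths."""
    return Phylogeny.from_newick("((a:1.0,b:2.0):1.0,(c:1.5,d:0.5):2.0);")


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    return Phylogeny.from_newick(
        "(" + ",".join(f"s{i}:{depth}" for i in range(n)) + ");"
    )


@pytest.fixture
def specimen_table() -> pd.DataFrame:
    rows = []
    for sp, skl in [("sp1", 30.0), ("sp2", 40.0)]:
        for j, f in [(1, 0.95), (2, 1.05)]:
            rows.append({
                "species": sp, "specimen": f"{sp}_{j}",
                "nt": 1.0 * f, "mt": 2.0 * f, "ls": 0.8 * f, "ft1": 1.2 * f,
                "ft2": np.nan, "it": 0.5 * f, "it2": np.nan,
                "etI": 2.0 * f, "etII": 1.5 * f, "etIII": 1.0 * f,
                "SKL": skl * f, "SNL": 12.0 * f, "SNW": 6.0 * f,
                "diet": "omnivorous" if sp == "sp1" else "vermivorous",
                "lifestyle": "terrestrial",
            })
    return pd.DataFrame(rows)
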