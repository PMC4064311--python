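import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pleiomod.diffexpr import CASE, CONTROL, ExpressionStudy


@pytest.fixture
def edge_tsv(tmp_path):
    """Write an edge-list TSV and return its path."""

    def _write(rows, header=None, name="edges.tsv"):
        path = tmp_path / name
        lines = []
        if header:
            lines.append("\t".join(header))
        lines += ["\t".join(str(f) for f in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def triangle_net():
    """Triangle a-b-c plus pendant edge c-d."""
    net = nx.Graph()
    for a, b in [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]:
        net.add_edge(a, b, confidence=0.9)
    return net


def make_study(matrix, n_case, n_control, prefix="s"):
    """ExpressionStudy from a 2-D array with the first n_case columns as cases."""
    matrix = np.asarray(matrix, dtype=float)
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    cols = [f"{prefix}{j}" for j in range(matrix.shape[1])]
    labels = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=cols)
    return ExpressionStudy(pd.DataFrame(matrix, index=genes, columns=cols), labels)


@pytest.fixture
def toy_study():
    rng = np.random.default_rng(0)
    return make_study(rng.standard_normal((20, 12)), 6, 6)
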