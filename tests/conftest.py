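import numpy as np
import pandas as pd
import pytest

from iimat import ExpressionMatrix, GeneRoleCatalog


def make_expression(values, genes=None, n_case=None, labels=None):
    """Build an ExpressionMatrix from a 2D array; first n_case columns are
    cases unless explicit labels are given."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{i}" for i in range(values.shape[1])]
    if labels is None:
        labels = {
            s: ("CASE" if i < n_case else "CONTROL")
            for i, s in enumerate(samples)
        }
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            labels)


@pytest.fixture
def abc_catalog():
    return GeneRoleCatalog({
        "A": {"IMMUNE"},
        "B": {"INFLAMMATION"},
        "C": {"DISEASE"},
        "D": {"IMMUNE", "INFLAMMATION"},
        "E": {"IMMUNE"},
    })


def random_role_catalog(rng, nodes, p_role=0.5):
    """Random catalog: each node independently gains each role w.p. p_role;
    roleless nodes are left out of the catalog."""
    entries = {}
    for n in nodes:
        roles = {r for r in ("IMMUNE", "INFLAMMATION", "DISEASE")
                 if rng.random() < p_role}
        if roles:
            entries[n] = roles
    return GeneRoleCatalog(entries)
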