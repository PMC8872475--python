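import numpy as np
import pytest

from modscreen import PhenotypeTable, StrainExpression
from modscreen.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220221)


@pytest.fixture
def small_phenotypes():
    # values from the published strain table excerpt
    return PhenotypeTable(
        [21, 26, 38, 40, 42],
        np.array([19976.8, 21473.22222, 19981.5, 16992.9, 21481.4]),
    )


@pytest.fixture
def small_expression():
    genes = ["FBgn0000014", "FBgn0000015", "XLOC_000001"]
    columns = [(21, 1), (21, 2), (26, 1), (26, 2)]
    values = np.array([
        [4.244723137096, 4.216353087773, 4.028685457103, 3.965513773625],
        [3.234859699465, 3.199773952148, 3.266073854988, 3.514853683793],
        [8.066864661954, 7.962031504804, 8.016965852717, 8.081375653861],
    ])
    return ExpressionMatrix(genes, columns, values)


def make_strain_expression(values, strain_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return StrainExpression(
        strain_ids or list(range(1, n + 1)),
        gene_ids or [f"FBgn{i:07d}" for i in range(1, g + 1)],
        values,
    )
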