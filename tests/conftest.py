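import numpy as np
import pytest

from codomains.coexpression import build_coexpression_matrix
from codomains.synthetic import (
    SyntheticSpec,
    blocks_with_gaps,
    generate_expression,
)

#: irregular layout for inversion-null scenarios: blocks confined to the 5'
#: quarter so the mirrored set lands on background genes (a palindromic
#: layout would map blocks onto blocks and make the inversion null vacuous)
ASYMMETRIC_BLOCKS = blocks_with_gaps(5, 10, 5, 0.6)  # ranks 5-14 ... 65-74


@pytest.fixture(scope="session")
def default_cohort():
    """Reference scenario: five 10-gene blocks, rho 0.6, 6-gene gaps, 100 samples."""
    spec = SyntheticSpec(seed=11)
    expr, annot, truth = generate_expression(spec)
    cm = build_coexpression_matrix(expr, annot, "1")
    return spec, expr, annot, truth, cm


@pytest.fixture(scope="session")
def coupled_cohort():
    """All five blocks share a common factor: planted intra > inter > rest."""
    spec = SyntheticSpec(seed=7, coupled_groups=[((0, 1, 2, 3, 4), 0.3)])
    expr, annot, truth = generate_expression(spec)
    cm = build_coexpression_matrix(expr, annot, "1")
    return spec, expr, annot, truth, cm


@pytest.fixture(scope="session")
def asymmetric_cohort():
    spec = SyntheticSpec(n_genes=160, blocks=ASYMMETRIC_BLOCKS, seed=23)
    expr, annot, truth = generate_expression(spec)
    cm = build_coexpression_matrix(expr, annot, "1")
    return spec, expr, annot, truth, cm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
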