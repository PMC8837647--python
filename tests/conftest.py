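"""Shared fixtures: one default synthetic bundle reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from spiralst.factorize import run_nnmf
from spiralst.io_core import filter_genes, normalize
from spiralst.synthetic import SpiralSpec, generate

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_spec() -> SpiralSpec:
    return SpiralSpec()


@pytest.fixture(scope="session")
def bundle(default_spec):
    return generate(default_spec)


@pytest.fixture(scope="session")
def norm(bundle):
    return normalize(filter_genes(bundle.dataset))


@pytest.fixture(scope="session")
def model(norm, bundle):
    return run_nnmf(norm, K=len(bundle.truth.factor_names), seed=0)


@pytest.fixture(scope="session")
def matched_factors(bundle, model):
    """Hungarian matching of fitted factors to planted programs.

    Returns list of (program name, fitted index, Pearson r).
    """
    from scipy.optimize import linear_sum_assignment

    tw = bundle.truth.true_W
    K = tw.shape[1]
    corr = np.array(
        [
            [np.corrcoef(tw[:, i], model.W[:, j])[0, 1] for j in range(model.K)]
            for i in range(K)
        ]
    )
    rows, cols = linear_sum_assignment(-corr)
    return [
        (bundle.truth.factor_names[i], int(j), float(corr[i, j]))
        for i, j in zip(rows, cols)
    ]
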