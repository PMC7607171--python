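import numpy as np
import pytest
from hypothesis import settings

from tgmo import assemble_oacd

settings.register_profile("det", derandomize=True, database=None)
settings.load_profile("det")
from tgmo.regression import FittedModel


@pytest.fixture(scope="session")
def design4():
    return assemble_oacd(4)


@pytest.fixture(scope="session")
def design11():
    return assemble_oacd(11)


def make_model(factor_names, terms, coef, pvalues, population=None):
    """Hand-built FittedModel for rule-level tests (no data behind it)."""
    names = ["Intercept"] + [t for t in coef if t != "Intercept"]
    n = len(factor_names)
    return FittedModel(
        factor_names=tuple(factor_names),
        terms=list(terms),
        coef=dict(coef),
        se={k: 1.0 for k in names},
        pvalues=dict(pvalues) | {"Intercept": 0.0},
        r2=0.9,
        nobs=10,
        fitted=np.zeros(10),
        residuals=np.zeros(10),
        row_ids=np.arange(10),
        y=np.zeros(10),
        X=np.ones((10, len(names))),
        population=population,
    )
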