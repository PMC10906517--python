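import numpy as np
import pytest

from gppca import ConceptLexicon, RatingsPanel

# the 2-attribute worked instance used across the core tests:
# eigendecomposition of the symmetrized cross-covariance of (X, 2X) is
# [[2,1],[1,2]] with eigenpairs (3, [1,1]/sqrt2) and (1, [1,-1]/sqrt2)
WORKED_X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])


@pytest.fixture
def worked_panel() -> RatingsPanel:
    return RatingsPanel(
        stimuli=["s1", "s2", "s3"],
        datasets=["d1", "d2"],
        concepts=["c1", "c2"],
        values={"d1": WORKED_X.copy(), "d2": 2.0 * WORKED_X},
    )


@pytest.fixture
def lexicon() -> ConceptLexicon:
    return ConceptLexicon(
        keys=("joy", "fear", "awe"),
        translations={
            "ET": {"joy": "Desta", "fear": "Firhat", "awe": "Megerem"},
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
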