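import numpy as np
import pytest

from hallsim import GenePanel, GeneRecord, HallmarkWeights, normalize_weights
from hallsim.genes import N_HALLMARKS


@pytest.fixture
def panel2() -> GenePanel:
    return GenePanel.from_names(["APC", "KRAS"])


@pytest.fixture
def panel4() -> GenePanel:
    return GenePanel(
        (
            GeneRecord("APC", 8532, "suppressor"),
            GeneRecord("KRAS", 570, "oncogene"),
            GeneRecord("TP53", 1182, "suppressor"),
            GeneRecord("PIK3CA", 3207, "oncogene"),
        )
    )


def random_weights(
    panel: GenePanel, rng: np.random.Generator, density: float = 0.7
) -> HallmarkWeights:
    """Random normalized weight matrix with roughly `density` nonzero entries."""
    raw = rng.random((panel.size, N_HALLMARKS)) * (
        rng.random((panel.size, N_HALLMARKS)) < density
    )
    return HallmarkWeights(panel, normalize_weights(raw), normalize=False)
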