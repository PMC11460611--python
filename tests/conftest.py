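import numpy as np
import pytest

from tinniflow.audiogram import Audiogram


@pytest.fixture
def sloping_loss_audiogram() -> Audiogram:
    """Mild-to-moderate sloping loss whose hearing-loss band is 1-8 kHz."""
    return Audiogram(
        frequencies_hz=(125, 250, 500, 1000, 2000, 4000, 8000),
        thresholds_db_hl=(10, 15, 20, 30, 35, 45, 45),
    )


@pytest.fixture
def toy_mixed_design():
    """4-subject, 2-group, 4-timepoint dataset with a hand-workable
    split-plot decomposition (SS: group 20.25, subjects-within 2.5,
    time 1.25, interaction 11.25, residual 2.5)."""
    Y = np.array(
        [[1, 2, 3, 4], [2, 3, 4, 5], [5, 5, 5, 5], [7, 6, 5, 4]], dtype=float
    )
    groups = np.array(["A", "A", "B", "B"])
    return Y, groups
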