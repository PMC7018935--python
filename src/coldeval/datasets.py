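"""Small bundled example data.

``load_physiological_example`` returns the published six-variety worked
example of the D-value method: three comprehensive-index score columns for
six rice varieties, the contribution rates of the three retained components,
and the subordinate-function values and weights as printed in the original
report (3-decimal precision). Useful for demos and as a regression fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Physiological indicator panel in its conventional x1..x9 order.
PHYSIOLOGICAL_INDICATORS = (
    "SOD", "CAT", "GSH", "MDA", "ATPase", "Pro", "Chl", "ABA", "TPI",
)

#: Contribution rates (%) of the two retained morphological components.
MORPHOLOGICAL_CONTRIBUTION_RATES = (54.545, 32.01)
#: Morphological weights as printed (second weight was truncated, not rounded).
MORPHOLOGICAL_PRINTED_WEIGHTS = (0.630, 0.369)

#: Contribution rates (%) of the three retained physiological components.
PHYSIOLOGICAL_CONTRIBUTION_RATES = (46.789, 28.146, 18.904)
PHYSIOLOGICAL_PRINTED_WEIGHTS = (0.499, 0.300, 0.201)

_VARIETIES = ("WR157", "WR16", "WR164", "WR20", "WR21", "WR155")

_CI = np.array(
    [
        [0.707, 1.073, -1.059],
        [-0.540, 1.252, 1.509],
        [0.910, -0.433, 0.106],
        [-0.127, 0.085, -0.873],
        [0.732, -1.245, 0.783],
        [-1.682, -0.733, -0.466],
    ]
)

_PRINTED_MU = np.array(
    [
        [0.922, 0.928, 0.000],
        [0.440, 1.000, 1.000],
        [1.000, 0.325, 0.454],
        [0.600, 0.532, 0.072],
        [0.931, 0.000, 0.717],
        [0.000, 0.205, 0.231],
    ]
)


def load_physiological_example() -> dict:
    """The six-variety physiological worked example.

    Returns a dict with:

    ``ci_scores``
        6 × 3 DataFrame of comprehensive-index scores (printed at 3 dp).
    ``contribution_rates``
        Percent contribution rates of the three components.
    ``printed_membership``
        The μ values as printed (3 dp) — note two cells differ from exact
        recomputation by one unit in the last digit because the printed CI
        inputs are themselves rounded.
    ``printed_weights``
        The weights as printed.
    """
    cols = ["CI(1)", "CI(2)", "CI(3)"]
    return {
        "ci_scores": pd.DataFrame(_CI, index=list(_VARIETIES), columns=cols),
        "contribution_rates": list(PHYSIOLOGICAL_CONTRIBUTION_RATES),
        "printed_membership": pd.DataFrame(
            _PRINTED_MU, index=list(_VARIETIES), columns=["mu(1)", "mu(2)", "mu(3)"]
        ),
        "printed_weights": list(PHYSIOLOGICAL_PRINTED_WEIGHTS),
    }
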