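"""Published reference estimates for the four-state breast-cancer model.

Point estimates reported by a hospital-based historical cohort study of 573
women with breast cancer (initial treatment / recovery / metastasis / death),
kept here for desk checks and as calibration anchors for the synthetic
cohort generator.  The raw cohort itself is not publicly deposited, so these
printed summaries are the only numeric ground truth available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATE_LABELS = ("initial treatment", "recovery", "metastasis", "death")

# One-year transition probability matrix (point estimates).
_ONE_YEAR = np.array(
    [
        [0.626, 0.326, 0.018, 0.031],
        [0.000, 0.935, 0.025, 0.040],
        [0.000, 0.875, 0.023, 0.102],
        [0.000, 0.000, 0.000, 1.000],
    ]
)

# Five-year transition probability matrix as printed.  The metastasis->
# recovery entry (0.639) makes its row sum 0.900 and is inconsistent with the
# fifth power of the one-year matrix; it is widely treated as a misprint.
_FIVE_YEAR = np.array(
    [
        [0.096, 0.715, 0.020, 0.169],
        [0.000, 0.789, 0.021, 0.190],
        [0.000, 0.639, 0.019, 0.242],
        [0.000, 0.000, 0.000, 1.000],
    ]
)

# Mean sojourn times in years, model without covariates.
_SOJOURN_YEARS = {"initial treatment": 2.135, "recovery": 1.546, "metastasis": 0.041}

# Observed consecutive-pair state table from the cohort (rows: from-state).
_STATE_TABLE = np.array(
    [
        [983, 516, 43, 13],
        [0, 318, 125, 31],
        [0, 5, 7, 146],
        [0, 0, 0, 0],
    ]
)


def reference_one_year_matrix() -> pd.DataFrame:
    """Reported one-year transition probability point estimates."""
    return pd.DataFrame(_ONE_YEAR.copy(), index=STATE_LABELS, columns=STATE_LABELS)


def reference_five_year_matrix() -> pd.DataFrame:
    """Reported five-year transition probability matrix (as printed)."""
    return pd.DataFrame(_FIVE_YEAR.copy(), index=STATE_LABELS, columns=STATE_LABELS)


def reference_sojourn_years() -> dict[str, float]:
    """Reported mean sojourn times (years), no-covariate model."""
    return dict(_SOJOURN_YEARS)


def reference_state_table() -> pd.DataFrame:
    """Reported counts of consecutive observed state pairs."""
    return pd.DataFrame(
        _STATE_TABLE.copy(), index=STATE_LABELS, columns=STATE_LABELS
    )
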