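"""Small bundled example inputs.

Published cross-country indicator correlation matrices used as worked
examples for the composite-index machinery: six governance indicators
and two ICT-access indicators, each rounded to 3 decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GOVERNANCE_INDICATORS = (
    "effectiveness",
    "stability",
    "corruption",
    "regulation",
    "law",
    "accountability",
)

# lower triangle (row, col): Pearson correlation
_GOV_LOWER = {
    ("stability", "effectiveness"): 0.639,
    ("corruption", "effectiveness"): 0.847,
    ("corruption", "stability"): 0.677,
    ("regulation", "effectiveness"): 0.903,
    ("regulation", "stability"): 0.627,
    ("regulation", "corruption"): 0.823,
    ("law", "effectiveness"): 0.904,
    ("law", "stability"): 0.754,
    ("law", "corruption"): 0.886,
    ("law", "regulation"): 0.885,
    ("accountability", "effectiveness"): 0.682,
    ("accountability", "stability"): 0.598,
    ("accountability", "corruption"): 0.709,
    ("accountability", "regulation"): 0.727,
    ("accountability", "law"): 0.787,
}

ICT_INDICATORS = ("internet", "cellular")
ICT_CORRELATION_VALUE = 0.805


def governance_correlation() -> pd.DataFrame:
    """6x6 governance-indicator correlation matrix (example data)."""
    k = len(GOVERNANCE_INDICATORS)
    mat = np.eye(k)
    idx = {name: i for i, name in enumerate(GOVERNANCE_INDICATORS)}
    for (a, b), v in _GOV_LOWER.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = v
    return pd.DataFrame(mat, index=GOVERNANCE_INDICATORS,
                        columns=GOVERNANCE_INDICATORS)


def ict_correlation() -> pd.DataFrame:
    """2x2 ICT-indicator correlation matrix (example data)."""
    mat = np.array([[1.0, ICT_CORRELATION_VALUE],
                    [ICT_CORRELATION_VALUE, 1.0]])
    return pd.DataFrame(mat, index=ICT_INDICATORS, columns=ICT_INDICATORS)
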