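"""Published calibration constants for the LPFS-BF 2.0.

The LPFS-BF 2.0 is a 12-item screening questionnaire for DSM-5 criterion-A
personality-functioning impairment; items are rated 1-4, so total scores span
12-48.  This module ships the published Polish-adult calibration of the
instrument: standardized one-factor loadings and graded-response-model item
parameters (logistic metric, no D = 1.702 scaling), plus the earlier
Danish-sample observed-score cut-offs that reports display for comparison.

These constants serve two roles: default generating parameters for the
synthetic-data module, and inputs for deterministic re-derivations (test
characteristic curve thresholds, reliability from loadings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ITEM_IDS: tuple[str, ...] = tuple(f"LPFS{i}" for i in range(1, 13))

N_ITEMS: int = 12
N_CATEGORIES: int = 4
MIN_TOTAL: int = 12
MAX_TOTAL: int = 48

#: Standardized one-factor loadings of the 12 items (Polish adult calibration).
REFERENCE_LOADINGS: np.ndarray = np.array(
    [0.78, 0.68, 0.79, 0.71, 0.78, 0.70, 0.64, 0.66, 0.68, 0.64, 0.75, 0.70]
)

#: GRM discrimination (a) and ordered difficulty (b1 < b2 < b3) parameters,
#: one row per item, logistic metric.  b_k is the latent value at which the
#: probability of responding in category k+1 or higher equals one half.
REFERENCE_GRM_PARAMS: pd.DataFrame = pd.DataFrame(
    {
        "a": [3.05, 2.00, 3.08, 2.29, 2.96, 2.13, 1.77, 1.91, 1.98, 1.96, 2.62, 2.09],
        "b1": [0.01, -0.56, -0.14, -0.24, -0.26, -0.47, -0.96, -0.50, -0.74, 0.17, -0.08, -0.56],
        "b2": [0.77, 0.62, 0.85, 0.69, 0.66, 0.69, 0.45, 0.81, 0.67, 1.18, 0.84, 0.73],
        "b3": [1.71, 1.98, 1.92, 1.87, 1.97, 2.25, 2.33, 2.53, 2.38, 2.45, 2.20, 2.33],
    },
    index=list(ITEM_IDS),
)

#: Observed-score cut-offs previously derived for the Danish general
#: population at the same latent multipliers; displayed as a comparison
#: column in benchmark reports, never used in computation.
DANISH_COMPARISON_CUTOFFS: tuple[float, ...] = (25.9, 31.0, 36.0, 40.5)

#: Latent-SD multipliers anchoring the severity benchmarks.
DEFAULT_MULTIPLIERS: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)

#: Display labels for the benchmark rows (percentile text is conventional
#: display only, not a computed quantity).
MULTIPLIER_PERCENTILE_LABELS: dict[float, str] = {
    1.0: "84th percentile",
    1.5: "92nd percentile",
    2.0: "97th percentile",
    2.5: "99th percentile",
}
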