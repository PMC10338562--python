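"""Published summary data shipped with the package.

The validation study's per-subject maximal oxygen uptake values — measured
in the maximal test, predicted by the submaximal kinetics pipeline (SMO) and
estimated by the Jurca resting equation — are public summary numbers and are
embedded here so the error analysis can be reproduced without access to the
raw recordings (which were never deposited).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_validation_vo2max"]

# Columns: subject, VO2max experimental (L/min), VO2max SMO (L/min),
# printed SMO error (%), VO2max Jurca (L/min), printed Jurca error (%).
_VALIDATION_ROWS = [
    ("S1", 3.54, 3.47, 1.9, 3.09, 12.7),
    ("S2", 4.57, 4.80, 5.1, 4.20, 8.1),
    ("S3", 4.34, 3.76, 13.4, 4.16, 4.1),
    ("S4", 3.35, 3.55, 6.1, 3.41, 1.9),
    ("S5", 4.58, 4.98, 8.7, 4.02, 12.3),
    ("S6", 3.29, 3.23, 1.9, 2.71, 17.8),
    ("S7", 4.02, 4.20, 4.5, 4.36, 8.5),
    ("S8", 3.68, 3.64, 1.2, 3.00, 18.5),
    ("S9", 3.97, 4.26, 7.4, 3.68, 7.5),
]


def load_validation_vo2max() -> pd.DataFrame:
    """Per-subject VO2max comparison table of the nine-subject validation study.

    Returns a DataFrame with columns ``subject``, ``vo2max_exp_L_min``,
    ``vo2max_smo_L_min``, ``delta_smo_pct``, ``vo2max_jurca_L_min`` and
    ``delta_jurca_pct``.  The two-decimal VO2max columns are the published
    values; the error columns are the published one-decimal relative errors
    (computed from unrounded data, so recomputing them from the two-decimal
    columns can differ by ~0.1 percentage point).
    """
    return pd.DataFrame(
        _VALIDATION_ROWS,
        columns=["subject", "vo2max_exp_L_min", "vo2max_smo_L_min",
                 "delta_smo_pct", "vo2max_jurca_L_min", "delta_jurca_pct"],
    )
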