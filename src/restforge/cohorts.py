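"""Cohort restitution anchors.

Per-cycle-length mean +/- SD of diastolic interval and activation-recovery
interval measured during the clinical decremental pacing protocol
(20 beats per burst, 600 -> 350 ms in 50 ms steps) in the two cohorts:
structurally normal left ventricles (SNLV) and ischemic cardiomyopathy
(ICMP).  These anchors seed the synthetic electrogram generator and, via a
logarithmic fit, define the genetic-algorithm calibration targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COHORT_TABLES", "cohort_table", "log_restitution_coefficients"]

_COLUMNS = ["cl", "di_mean", "di_sd", "ari_mean", "ari_sd"]

# cycle length (ms), DI mean, DI SD, ARI mean, ARI SD (all ms)
_SNLV = [
    (600, 335.2, 29.0, 269.1, 21.8),
    (550, 287.9, 18.1, 262.2, 17.8),
    (500, 245.2, 16.9, 253.0, 15.6),
    (450, 206.7, 13.2, 243.2, 13.7),
    (400, 166.6, 11.6, 233.4, 12.0),
    (350, 127.1, 13.2, 222.3, 13.1),
]

_ICMP = [
    (600, 334.3, 21.1, 266.8, 19.1),
    (550, 293.5, 21.9, 256.2, 22.6),
    (500, 255.3, 22.7, 243.8, 23.3),
    (450, 215.6, 25.5, 234.6, 25.2),
    (400, 180.6, 30.7, 218.8, 31.1),
    (350, 159.3, 41.9, 190.6, 40.4),
]

COHORT_TABLES: dict[str, pd.DataFrame] = {
    "snlv": pd.DataFrame(_SNLV, columns=_COLUMNS),
    "icmp": pd.DataFrame(_ICMP, columns=_COLUMNS),
}


def cohort_table(cohort: str) -> pd.DataFrame:
    """Anchor table for ``cohort`` ('snlv' or 'icmp')."""
    key = cohort.lower()
    if key not in COHORT_TABLES:
        raise KeyError(f"unknown cohort {cohort!r}; expected 'snlv' or 'icmp'")
    return COHORT_TABLES[key].copy()


def log_restitution_coefficients(cohort: str) -> tuple[float, float]:
    """Ordinary least-squares fit of ARI = alpha + beta ln(DI) to the anchors.

    Returns (alpha, beta) in ms.  The anchors are cohort means with no
    outliers, so the OLS fit coincides with the bisquare robust fit.
    """
    tab = cohort_table(cohort)
    x = np.log(tab["di_mean"].to_numpy())
    y = tab["ari_mean"].to_numpy()
    beta, alpha = np.polyfit(x, y, 1)
    return float(alpha), float(beta)
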