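"""Feature stability selection between two control cohorts.

When two sample groups come from different acquisition batches (here:
normal epithelium of two mouse models imaged at very different ages),
features that already differ between the two *control* groups would
confound any comparison of their lesions.  The two-sample
Kolmogorov-Smirnov test screens each feature: those with p >= alpha (no
detectable distribution difference between controls, alpha = 0.05) are
retained.  No multiple-testing correction is applied — the screen is
deliberately conservative in what it keeps, and a correction would only
retain more features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

__all__ = ["KsResult", "ks_two_sample", "select_stable_features"]

ALPHA_DEFAULT = 0.05


@dataclass
class KsResult:
    feature_name: str
    statistic: float  # D = sup |ECDF_x - ECDF_y|
    p_value: float
    retained: bool
    testable: bool = True


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D is evaluated exactly at all pooled breakpoints (correct under
    ties); the p-value uses the asymptotic Kolmogorov distribution with
    effective size n_x n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs >= 2 values")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / nx
    cdf_y = np.searchsorted(y, pooled, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = nx * ny / (nx + ny)
    p = float(kolmogorov(np.sqrt(ne) * d))
    return d, min(1.0, p)


def select_stable_features(
    control_a: pd.DataFrame,
    control_b: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[list[str], pd.DataFrame]:
    """Retain features whose distributions agree between two control groups.

    Inputs are feature matrices (rows = samples, columns = catalogue
    features) sharing their column set.  Missing values are dropped
    pairwise per feature; a feature with fewer than 2 finite values on
    either side is excluded with ``testable=False`` (neither retained nor
    rejected).  Returns the retained names in catalogue (column) order
    and the full audit table.
    """
    if control_a.empty or control_b.empty:
        raise ValueError("empty control matrix")
    common = [c for c in control_a.columns if c in set(control_b.columns)]
    if not common:
        raise ValueError("control matrices share no feature columns")

    rows: list[KsResult] = []
    for name in common:
        xa = control_a[name].to_numpy(dtype=float)
        xb = control_b[name].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if len(xa) < 2 or len(xb) < 2:
            rows.append(KsResult(name, np.nan, np.nan, False, testable=False))
            continue
        d, p = ks_two_sample(xa, xb)
        rows.append(KsResult(name, d, p, retained=bool(p >= alpha)))

    table = pd.DataFrame(
        dict(
            feature=[r.feature_name for r in rows],
            D=[r.statistic for r in rows],
            p=[r.p_value for r in rows],
            retained=[r.retained for r in rows],
            testable=[r.testable for r in rows],
        )
    )
    retained = [r.feature_name for r in rows if r.retained]
    return retained, table
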