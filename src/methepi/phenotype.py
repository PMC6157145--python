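"""Drug-response phenotype construction.

The phenotype is the natural-log ratio of the average post-treatment
triglyceride level (visits 3–4) to the average pre-treatment level
(visits 1–2).  Because within-block visit pairs are highly correlated,
missing visits are singly imputed by ordinary least squares on the
observed partner visit before averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DataError, POST_VISITS, PRE_VISITS, TriglyceridePanel

__all__ = ["impute_missing_visits", "compute_log_tg_ratio"]

_BLOCKS = {"pre": PRE_VISITS, "post": POST_VISITS}


class InsufficientDataError(DataError):
    """Too few complete visit pairs to fit an imputation regression."""


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of simple OLS y ~ x."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise InsufficientDataError("imputation predictor visit is constant")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    return slope, ym - slope * xm


def impute_missing_visits(panel: TriglyceridePanel) -> TriglyceridePanel:
    """Single imputation of missing visits by within-block linear regression.

    For each block (pre: tg1/tg2, post: tg3/tg4) two directed regressions
    are fit on complete-pair subjects (tg2~tg1, tg1~tg2 and likewise for
    the post block); a subject's missing visit is predicted from its
    observed partner.  Observed values are never modified, and applying
    the operation to an already-complete panel is the identity.

    Requires at least 3 complete pairs per block that still has a missing
    value to impute.
    """
    frame = panel.frame.copy()
    for block, (a, b) in _BLOCKS.items():
        miss_a = frame[a].isna()
        miss_b = frame[b].isna()
        if not (miss_a.any() or miss_b.any()):
            continue
        complete = frame[[a, b]].dropna()
        if len(complete) < 3:
            raise InsufficientDataError(
                f"{block} block has only {len(complete)} complete pairs; "
                "need >= 3 to fit imputation regressions"
            )
        xa = complete[a].to_numpy()
        xb = complete[b].to_numpy()
        if miss_b.any():
            slope, intercept = _ols_line(xa, xb)
            frame.loc[miss_b, b] = intercept + slope * frame.loc[miss_b, a]
        if miss_a.any():
            slope, intercept = _ols_line(xb, xa)
            frame.loc[miss_a, a] = intercept + slope * frame.loc[miss_a, b]
    out = TriglyceridePanel(frame)
    if not out.is_complete():
        raise DataError("imputation failed to complete the panel")
    return out


def compute_log_tg_ratio(panel: TriglyceridePanel) -> pd.Series:
    """ln(mean(tg3, tg4) / mean(tg1, tg2)) per subject.

    The panel must be complete (run :func:`impute_missing_visits` first).
    Returns a float Series named ``y`` indexed by sample id; the value is
    unitless and invariant to common rescaling of all four visits.
    """
    if not panel.is_complete():
        raise DataError("panel has missing visits; impute before computing the ratio")
    pre = panel.frame[PRE_VISITS].mean(axis=1)
    post = panel.frame[POST_VISITS].mean(axis=1)
    if (pre <= 0).any() or (post <= 0).any():
        raise DataError("nonpositive block mean; panel values must be positive")
    y = np.log(post / pre)
    y.name = "y"
    return y
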