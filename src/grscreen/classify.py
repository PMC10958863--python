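"""Percentile-based grouping of lines into resistant / intermediate / sensitive.

Lines are ranked by their normalized area over the curve (AOC_n, higher =
stronger drug response) and split at the 33rd and 66th percentiles of the
same AOC vector being classified: strictly below the 33rd percentile is
resistant, strictly above the 66th sensitive, everything else (boundaries
included) intermediate.  Percentiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

GROUPS = ("resistant", "intermediate", "sensitive")
PCT_LOW, PCT_HIGH = 33.0, 66.0


class PercentileResponseClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier over scalar response values.

    ``fit`` learns the percentile boundaries from the training AOC vector;
    ``predict`` assigns group labels.  Fitted attributes: ``p33_``, ``p66_``.
    """

    def __init__(self, pct_low=PCT_LOW, pct_high=PCT_HIGH):
        self.pct_low = pct_low
        self.pct_high = pct_high

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        if values.size < 3:
            raise ValueError("need at least 3 lines to form 3 groups")
        self.p33_ = float(np.percentile(values, self.pct_low))
        self.p66_ = float(np.percentile(values, self.pct_high))
        return self

    def predict(self, X):
        values = np.asarray(X, dtype=float).ravel()
        out = np.full(values.shape, "intermediate", dtype=object)
        out[values < self.p33_] = "resistant"
        out[values > self.p66_] = "sensitive"
        return out


def classify_lines(aoc_by_line: dict) -> pd.DataFrame:
    """Classify lines by AOC; returns a DataFrame with group and boundaries.

    Boundary values are computed from the same AOC vector and repeated on
    every row (``p33``, ``p66``) so the output is self-describing.
    """
    lines = sorted(aoc_by_line)
    values = np.array([aoc_by_line[k] for k in lines], dtype=float)
    clf = PercentileResponseClassifier().fit(values)
    return pd.DataFrame(
        {
            "line_id": lines,
            "aoc": values,
            "group": clf.predict(values),
            "p33": clf.p33_,
            "p66": clf.p66_,
        }
    )
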