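"""Inter-reader reproducibility filtering via Lin's concordance correlation.

Features extracted twice (once per reader) are kept only when the two
readers' per-patient values agree with CCC >= 0.8 ("excellent"); kept
features are merged as the arithmetic mean of the two readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaMismatchError

DEFAULT_CCC_CUTOFF = 0.8


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population denominators).

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2).
    Degenerate conventions: both constant with equal means -> 1; constant
    with unequal means or only one side constant with no covariance -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("CCC needs at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("CCC inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (n)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # identical constants
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)


@dataclass
class CccReport:
    """Per-feature CCC, keep decisions, and the reader-merged table."""

    ccc: pd.Series
    kept: list[str]
    merged: pd.DataFrame
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.ccc.index,
            "ccc": self.ccc.values,
            "kept": [f in set(self.kept) for f in self.ccc.index],
        })


def reliability_filter(table_r1: pd.DataFrame, table_r2: pd.DataFrame,
                       cutoff: float = DEFAULT_CCC_CUTOFF) -> CccReport:
    """Keep features with inter-reader CCC >= cutoff; merge kept by mean."""
    if list(table_r1.columns) != list(table_r2.columns):
        raise SchemaMismatchError("reader tables have different feature sets")
    if not table_r1.index.equals(table_r2.index):
        raise SchemaMismatchError("reader tables have different patients")
    ccc = pd.Series(
        {col: lin_ccc(table_r1[col].to_numpy(), table_r2[col].to_numpy())
         for col in table_r1.columns},
        name="ccc",
    )
    kept = [c for c in table_r1.columns if ccc[c] >= cutoff]
    merged = (table_r1[kept] + table_r2[kept]) / 2.0
    return CccReport(ccc=ccc, kept=kept, merged=merged, cutoff=cutoff)
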