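"""Test–retest reproducibility filtering via Lin's concordance correlation.

A radiomic feature is kept for modeling only if its value agrees between
a test and a retest acquisition of the same subjects. Agreement is
quantified with Lin's concordance correlation coefficient (CCC), which
penalizes both loss of correlation and location/scale shifts::

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

computed with population (1/n) moments. Features pass when CCC strictly
exceeds the modality threshold — 0.75 for CT, 0.65 for PET by default,
the thresholds used by the study this package re-implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RobustnessReport",
    "CCC_THRESHOLDS",
    "lin_ccc",
    "filter_features",
]

#: per-modality CCC thresholds (strict inequality: pass iff CCC > threshold)
CCC_THRESHOLDS: dict[str, float] = {"CT": 0.75, "PET": 0.65}


@dataclass
class RobustnessReport:
    """Per-feature CCC values with pass/fail flags for one modality."""

    modality: str
    threshold: float
    ccc: dict[str, float]
    passed: dict[str, bool]
    degenerate: tuple[str, ...] = ()

    @property
    def retained(self) -> tuple[str, ...]:
        """Names of retained features, in catalog order."""
        return tuple(name for name, ok in self.passed.items() if ok)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_total(self) -> int:
        return len(self.ccc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.ccc),
                "ccc": list(self.ccc.values()),
                "threshold": self.threshold,
                "passed": list(self.passed.values()),
            }
        )

    def summary(self) -> dict:
        return {
            "modality": self.modality,
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "retained": list(self.retained),
        }


def lin_ccc(test, retest) -> float:
    """Lin's concordance correlation coefficient between paired series.

    Uses population (1/n) moments. Degenerate policy: two identical
    constant series have perfect agreement (1); two series that are both
    constant but not identical have none (denominator 0 with a mean gap
    handled by the formula); if variances and the mean gap are all zero
    but the series differ elementwise this cannot occur for constants,
    so the remaining 0/0 case returns 0.

    Raises
    ------
    ValueError
        If lengths differ, n < 3, or values are non-finite.
    """
    x = np.asarray(test, dtype=np.float64)
    y = np.asarray(retest, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be 1D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        # both constant with equal means: identical-constant series agree
        return 1.0 if np.array_equal(x, y) else 0.0
    return float(2.0 * sxy / denom)


def filter_features(
    test_table: pd.DataFrame,
    retest_table: pd.DataFrame,
    modality: str,
    threshold: float | None = None,
) -> RobustnessReport:
    """Compute per-feature CCC across subjects and apply the threshold.

    Both tables are subjects x features with identical index and columns
    (catalog order preserved). A feature is retained iff its CCC strictly
    exceeds the modality threshold. Constant feature pairs that are
    identical count as perfectly reproducible; non-identical degenerate
    pairs get CCC 0 and are flagged.
    """
    modality = modality.upper()
    if threshold is None:
        if modality not in CCC_THRESHOLDS:
            raise ValueError(f"no default CCC threshold for modality {modality!r}")
        threshold = CCC_THRESHOLDS[modality]
    if list(test_table.columns) != list(retest_table.columns):
        raise ValueError("test and retest tables have different feature columns")
    if len(test_table) != len(retest_table) or not (
        test_table.index.equals(retest_table.index)
    ):
        raise ValueError("test and retest tables cover different subjects")

    ccc: dict[str, float] = {}
    passed: dict[str, bool] = {}
    degenerate: list[str] = []
    for name in test_table.columns:
        x = test_table[name].to_numpy()
        y = retest_table[name].to_numpy()
        value = lin_ccc(x, y)
        sx2 = x.var()
        sy2 = y.var()
        if sx2 == 0 and sy2 == 0 and not np.array_equal(x, y):
            degenerate.append(name)
        ccc[name] = value
        passed[name] = bool(value > threshold)
    return RobustnessReport(
        modality=modality,
        threshold=float(threshold),
        ccc=ccc,
        passed=passed,
        degenerate=tuple(degenerate),
    )
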