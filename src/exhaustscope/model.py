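"""The radiomic T-exhaustion score: selection, fitting, and evaluation.

The imaging study this package re-implements screened robust radiomic
features by L1-penalized (LASSO) regression against four immunological
characteristics of CD8+ T-cell exhaustion — early- and terminal-Tex
fractions, the early/terminal (E/T) ratio, and PD-1 MFI — then combined
three PET texture features into an unpenalized binary logistic model for
high vs low exhaustion (cohort-median terminal-Tex split). Its printed
form,

    T exhaustion score = -297.597 * InverseVariance(GLCM)
                         + 178.689 * Homogeneity2(GLCM)
                         + 1.088 * Kurtosis(IntensityHistogram)
                         + 1.485

is interpreted as the logistic model's linear predictor; the probability
of high exhaustion is the logistic transform of the score. This module
ships that model verbatim (immutable, provenance ``"paper"``) alongside
the machinery to refit it on new cohorts, plus the evaluation metrics
used to judge it: the concordance index, the Brier score, and a
calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import LeaveOneOut

__all__ = [
    "CharacteristicTarget",
    "SelectionResult",
    "ScoreModel",
    "PAPER_SCORE_MODEL",
    "SCORE_FEATURES",
    "lasso_select",
    "fit_score_model",
    "t_exhaustion_score",
    "c_index",
    "brier_score",
    "calibration_curve",
]

#: the three PET features of the exhaustion score, in printed order
SCORE_FEATURES: tuple[str, str, str] = (
    "InverseVariance(GLCM)",
    "Homogeneity2(GLCM)",
    "Kurtosis(IntensityHistogram)",
)

#: the four exhaustion characteristics screened by LASSO
CHARACTERISTICS: tuple[str, ...] = (
    "early_tex_frac",
    "terminal_tex_frac",
    "e_t_ratio",
    "pd1_mfi",
)


@dataclass(frozen=True)
class CharacteristicTarget:
    """One exhaustion characteristic used as a selection target."""

    name: str
    kind: str = "continuous"  # "continuous" or "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"kind must be 'continuous' or 'binary', got {self.kind!r}")


@dataclass
class SelectionResult:
    """Nonzero-coefficient features per characteristic at the chosen penalty."""

    entries: dict[str, list[tuple[str, float]]]

    def selected_features(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pairs in self.entries.values():
            for name, _ in pairs:
                seen.setdefault(name)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"characteristic": char, "feature": name, "coefficient": coef}
            for char, pairs in self.entries.items()
            for name, coef in pairs
        ]
        return pd.DataFrame(rows, columns=["characteristic", "feature", "coefficient"])


@dataclass(frozen=True)
class ScoreModel:
    """A three-feature logistic exhaustion model.

    ``score = coefficients . features + intercept`` is the linear
    predictor (log-odds of high exhaustion); ``provenance`` is
    ``"paper"`` for the packaged printed coefficients or ``"refit"`` for
    a model fitted on a new cohort. ``training_median`` records the
    terminal-Tex cutoff used to binarize the training cohort (None for
    the packaged model, whose training data are not public).
    """

    feature_names: tuple[str, str, str]
    coefficients: tuple[float, float, float]
    intercept: float
    provenance: str
    training_median: float | None = None

    def __post_init__(self) -> None:
        if len(self.feature_names) != 3 or len(self.coefficients) != 3:
            raise ValueError("score model uses exactly three features")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "provenance": self.provenance,
            "training_median": self.training_median,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            provenance=str(d["provenance"]),
            training_median=d.get("training_median"),
        )


#: the published model, verbatim and immutable
PAPER_SCORE_MODEL = ScoreModel(
    feature_names=SCORE_FEATURES,
    coefficients=(-297.597, 178.689, 1.088),
    intercept=1.485,
    provenance="paper",
)


def t_exhaustion_score(
    model: ScoreModel, features: Mapping[str, float]
) -> tuple[float, float]:
    """Evaluate the T-exhaustion score and high-exhaustion probability.

    ``features`` is any mapping from feature name to value (a
    :class:`~exhaustscope.features.FeatureVector` works directly). The
    high-exhaustion call is probability > 0.5, equivalently score > 0.

    Raises
    ------
    KeyError
        If a model feature is absent, naming it.
    """
    x = []
    for name in model.feature_names:
        try:
            x.append(float(features[name]))
        except KeyError:
            raise KeyError(f"feature {name!r} missing from input") from None
    score = float(np.dot(model.coefficients, x) + model.intercept)
    # clip the exponent; the probability saturates anyway
    prob = float(1.0 / (1.0 + np.exp(-np.clip(score, -700, 700))))
    return score, prob


# --------------------------------------------------------------------------
# LASSO screening


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, mu, sd, keep


def lasso_select(
    features: pd.DataFrame,
    target: CharacteristicTarget,
    target_values: Sequence[float],
    n_penalties: int = 50,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """L1-penalized screening of one exhaustion characteristic.

    Features are standardized internally; the penalty is chosen by
    leave-one-out cross-validation (smallest mean deviance, no
    one-standard-error rule, fixed fold order) over ``n_penalties``
    grid points. Continuous characteristics use L1-penalized linear
    regression, binary ones L1-penalized logistic regression. Returns
    (feature_name, coefficient) pairs for the nonzero coefficients,
    rescaled to the original feature scale; an empty list (nothing
    selected) is a valid outcome, not an error. All-constant feature
    columns are dropped before fitting.
    """
    y = np.asarray(target_values, dtype=np.float64)
    if len(features) != len(y):
        raise ValueError("feature table and target lengths differ")
    if len(features) < 8:
        raise ValueError(f"need at least 8 subjects for selection, got {len(features)}")
    X = features.to_numpy(dtype=np.float64)
    Z, mu, sd, keep = _standardize(X)
    names = [n for n, k in zip(features.columns, keep) if k]
    if Z.shape[1] == 0:
        return []

    if target.kind == "binary":
        clf = LogisticRegressionCV(
            Cs=n_penalties,
            cv=LeaveOneOut(),
            l1_ratios=[1.0],
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=seed,
            use_legacy_attributes=False,
        )
        clf.fit(Z, y.astype(int))
        coefs = clf.coef_.ravel()
    else:
        reg = LassoCV(alphas=n_penalties, cv=LeaveOneOut(), random_state=seed, max_iter=20000)
        reg.fit(Z, y)
        coefs = reg.coef_

    out = []
    for name, c, s in zip(names, coefs, sd[keep]):
        if c != 0.0:
            out.append((name, float(c / s)))  # back to the original feature scale
    return out


def select_all_characteristics(
    features: pd.DataFrame,
    characteristics: pd.DataFrame,
    binary_label: Sequence[bool] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Run LASSO screening against every exhaustion characteristic.

    ``characteristics`` holds the continuous targets (columns named as in
    :data:`CHARACTERISTICS`); if ``binary_label`` is given, the
    median-split high/low label is screened as an additional binary
    target named ``label_high``.
    """
    entries: dict[str, list[tuple[str, float]]] = {}
    for name in CHARACTERISTICS:
        if name not in characteristics.columns:
            continue
        vals = characteristics[name].to_numpy(dtype=np.float64)
        ok = np.isfinite(vals)
        entries[name] = lasso_select(
            features.loc[ok], CharacteristicTarget(name), vals[ok], seed=seed
        )
    if binary_label is not None:
        entries["label_high"] = lasso_select(
            features,
            CharacteristicTarget("label_high", kind="binary"),
            np.asarray(binary_label, dtype=float),
            seed=seed,
        )
    return SelectionResult(entries=entries)


# --------------------------------------------------------------------------
# The binary logistic exhaustion model


def fit_score_model(
    features: pd.DataFrame,
    terminal_tex_frac: Sequence[float],
    selected: Sequence[str] = SCORE_FEATURES,
    max_iter: int = 1000,
) -> ScoreModel:
    """Refit the three-feature logistic exhaustion model on a cohort.

    The outcome is terminal-Tex fraction strictly above the cohort median
    (ties to the low class); the fit is logistic regression on the three
    named features with a deterministic optimizer. Features are
    standardized internally and a light ridge penalty (C=1000 on the
    standardized scale) stabilizes the fit: it is negligible for
    well-conditioned cohorts but bounds the coefficients when a small
    cohort is perfectly separable, where the unpenalized maximum
    likelihood does not exist. Coefficients are reported on the original
    feature scale.

    Raises
    ------
    ValueError
        If either outcome class has fewer than 2 members, or the
        optimizer fails to produce finite coefficients.
    """
    selected = tuple(selected)
    if len(selected) != 3:
        raise ValueError(f"the exhaustion score uses exactly 3 features, got {len(selected)}")
    missing = [s for s in selected if s not in features.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    t = np.asarray(terminal_tex_frac, dtype=np.float64)
    cutoff = float(np.median(t))
    y = (t > cutoff).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(
            f"median split produced classes of size {int(y.sum())}/{int((1 - y).sum())}; "
            "need at least 2 subjects per class"
        )
    X = features[list(selected)].to_numpy(dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [s for s, v in zip(selected, sd) if v == 0]
        raise ValueError(f"constant feature column(s) in refit: {bad}")
    Z = (X - mu) / sd
    clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=max_iter)
    clf.fit(Z, y)
    coef_std = clf.coef_.ravel()
    if not (np.isfinite(coef_std).all() and np.isfinite(clf.intercept_).all()):
        raise ValueError(
            f"logistic fit diverged: coefficients {coef_std}, intercept {clf.intercept_}"
        )
    coefs = coef_std / sd
    intercept = float(clf.intercept_[0] - np.dot(coef_std, mu / sd))
    return ScoreModel(
        feature_names=selected,
        coefficients=tuple(float(c) for c in coefs),
        intercept=intercept,
        provenance="refit",
        training_median=cutoff,
    )


# --------------------------------------------------------------------------
# Evaluation


def c_index(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance index over all (high, low) label pairs.

    A pair is concordant when the high-label subject receives the larger
    probability; ties count 0.5. For binary outcomes this equals the
    area under the ROC curve. Undefined (error) when only one class is
    present.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1D of equal length")
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("c-index undefined: labels contain a single class")
    diff = pos[:, None] - neg[None, :]
    concordant = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(concordant / (pos.size * neg.size))


def brier_score(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1D of equal length")
    return float(((p - y) ** 2).mean())


def calibration_curve(
    probabilities: Sequence[float], labels: Sequence[int], n_bins: int = 5
) -> pd.DataFrame:
    """Reliability diagram data over equal-width probability bins.

    Returns a frame with one row per non-empty bin: ``mean_predicted``,
    ``observed_frequency`` and ``count``; counts sum to the number of
    subjects.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1D of equal length")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(p[sel].mean()),
                "observed_frequency": float(y[sel].mean()),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["bin", "mean_predicted", "observed_frequency", "count"])
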