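"""Penalized-regression feature ranking and top-k intersection selection.

Features are standardized (zero mean, unit variance) and regressed on a
single numeric response encoding the condition on an arousal-ordered scale
(baseline=0, low=1, high=2, social=3). Lasso (L1) and ridge (L2) fits are
ranked by absolute coefficient; the selected set is the intersection of the
two top-k prefixes (k=20 by default). Regularization strength is chosen by
seeded internal 5-fold cross-validation over a logarithmic grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .bands import CONDITION_CODE
from .exceptions import InconsistencyError, InvalidParameterError

ALPHA_GRID = np.logspace(-4, 2, 25)


@dataclass(frozen=True)
class RankedCoefficients:
    """Features ordered by non-increasing |coefficient| for one penalty."""

    model_kind: str  # "lasso" | "ridge"
    entries: tuple[tuple[str, float], ...]  # (feature_name, |coefficient|)
    regularization_strength: float

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.entries[:k]]


@dataclass(frozen=True)
class SelectionResult:
    lasso_rank: RankedCoefficients
    ridge_rank: RankedCoefficients
    top_k: int
    selected: tuple[str, ...]  # intersection, ordered by ridge rank


def encode_labels(labels) -> np.ndarray:
    """Map condition names to the arousal-ordered numeric scale; pass numerics through."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifu":
        return arr.astype(float)
    try:
        return np.array([CONDITION_CODE[str(v)] for v in arr], dtype=float)
    except KeyError as exc:
        raise InvalidParameterError(f"unknown condition label {exc}") from exc


def _standardize(X: pd.DataFrame) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    constant = std[std == 0].index.tolist()
    if constant:
        raise InvalidParameterError(
            f"constant feature column(s) cannot be standardized: {constant}"
        )
    return ((X - mean) / std).to_numpy()


def fit_ranked_coefficients(
    table: pd.DataFrame,
    labels,
    penalty: str,
    seed: int = 0,
) -> RankedCoefficients:
    """Fit one penalized linear regression and rank features by |coefficient|.

    ``table`` holds only feature columns (callers strip identifier columns).
    Ties are broken by the table's column order, which is canonical for full
    54-feature tables.
    """
    if penalty not in ("lasso", "ridge"):
        raise InvalidParameterError(f"penalty must be lasso|ridge, got {penalty!r}")
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise InvalidParameterError("need >= 2 distinct labels")
    if table.isna().any().any():
        raise InvalidParameterError("feature table contains missing values")
    X = _standardize(table)

    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    if penalty == "lasso":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-n folds may not fully converge
            model = LassoCV(alphas=ALPHA_GRID, cv=cv, max_iter=50_000).fit(X, y)
        alpha = float(model.alpha_)
    else:
        model = RidgeCV(alphas=ALPHA_GRID, cv=cv).fit(X, y)
        alpha = float(model.alpha_)

    names = list(table.columns)
    mags = np.abs(model.coef_)
    order = sorted(range(len(names)), key=lambda i: (-mags[i], i))  # stable tie-break
    entries = tuple((names[i], float(mags[i])) for i in order)
    return RankedCoefficients(penalty, entries, alpha)


def select_common_top_k(
    lasso_rank: RankedCoefficients,
    ridge_rank: RankedCoefficients,
    k: int = 20,
) -> SelectionResult:
    """Intersect the two top-k prefixes; order the result by ridge rank."""
    lasso_names = {n for n, _ in lasso_rank.entries}
    ridge_names = {n for n, _ in ridge_rank.entries}
    if lasso_names != ridge_names:
        raise InconsistencyError("lasso and ridge rankings cover different features")
    if not (1 <= k <= len(ridge_names)):
        raise InvalidParameterError(f"k must be in [1, {len(ridge_names)}], got {k}")
    lasso_top = set(lasso_rank.top(k))
    selected = tuple(n for n in ridge_rank.top(k) if n in lasso_top)
    if not selected:
        warnings.warn(
            f"top-{k} lasso and ridge prefixes are disjoint; nothing selected",
            stacklevel=2,
        )
    return SelectionResult(lasso_rank, ridge_rank, k, selected)


def select_features(
    feature_table: pd.DataFrame, k: int = 20, seed: int = 0
) -> SelectionResult:
    """Convenience wrapper: rank a full feature table under both penalties and intersect.

    ``feature_table`` is the extract_table layout (participant_id, condition,
    54 feature columns).
    """
    X = feature_table.drop(columns=["participant_id", "condition"])
    y = feature_table["condition"]
    lasso = fit_ranked_coefficients(X, y, "lasso", seed=seed)
    ridge = fit_ranked_coefficients(X, y, "ridge", seed=seed)
    return select_common_top_k(lasso, ridge, k=k)


def selection_report(result: SelectionResult) -> pd.DataFrame:
    """Ranked-coefficient table mirroring the report layout: one row per rank
    with ridge and lasso columns side by side plus the selected-common list."""
    k = result.top_k
    ridge = result.ridge_rank.entries[:k]
    lasso = result.lasso_rank.entries[:k]
    selected = list(result.selected) + [""] * (k - len(result.selected))
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "ridge_coefficient": [c for _, c in ridge],
            "ridge_feature": [n for n, _ in ridge],
            "lasso_coefficient": [c for _, c in lasso],
            "lasso_feature": [n for n, _ in lasso],
            "selected_common": selected,
        }
    )
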