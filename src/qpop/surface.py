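"""Patient-specific quadratic response surface and exhaustive ranking.

The platform's central model is a full second-order polynomial in the
normalized doses x_i in {0, 0.5, 1} (coded levels 0/1/2):

    yhat(x) = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

fit by ordinary least squares to the control-normalized viability (NCV)
measured at the composite-design test points.  With k drugs the model has
1 + 2k + k(k-1)/2 coefficients (91 for k = 12), and the fitted surface is
evaluated at every one of the 3^k dose-level assignments (531,441 for
k = 12) to produce a ranked combination list — rank 1 being the lowest
predicted NCV, i.e. the greatest predicted cell kill.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .design import DesignMatrix
from .plate import NormalizedResponse

__all__ = [
    "QuadraticSurfaceRegressor",
    "CombinationRanking",
    "surface_from_coefficients",
    "second_order_terms",
    "all_level_vectors",
    "fit_quadratic_surface",
    "predict_ncv",
    "enumerate_and_rank",
    "top_combinations",
    "pairwise_interaction_matrix",
    "predict_regimen_ncv",
    "model_to_json",
    "model_from_json",
]

#: enumeration refuses beyond 3^13 combinations
MAX_ENUM_K = 13


def second_order_terms(x: np.ndarray) -> np.ndarray:
    """Design matrix of the full quadratic model (without intercept):
    [x_1..x_k, x_1^2..x_k^2, x_i x_j for i<j] for x in normalized doses."""
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    iu, ju = np.triu_indices(k, 1)
    return np.hstack([x, x**2, x[:, iu] * x[:, ju]])


class QuadraticSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Full second-order response surface on coded dose levels.

    ``fit`` takes X as an (n, k) array of coded levels in {0, 1, 2} (or a
    DataFrame whose columns are drug names) and y as NCV values; levels are
    mapped internally to normalized doses {0, 0.5, 1}.  Plain OLS by
    default; ``alpha > 0`` adds a small ridge penalty (on all non-intercept
    terms) for rank-deficient inputs.

    Attributes
    ----------
    intercept_ : float
        Baseline NCV with every drug absent.
    coef_linear_, coef_quadratic_ : ndarray of shape (k,)
    coef_interaction_ : ndarray of shape (k*(k-1)/2,)
        Pairwise terms in ``pair_index_`` order (upper triangle, i < j).
    adj_r2_ : float
        Adjusted R^2 of the fit, the model-robustness diagnostic.
    """

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y) -> "QuadraticSurfaceRegressor":
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.isin(X, (0, 1, 2)).all():
            raise ValueError("coded levels must be in {0, 1, 2}")
        n, k = X.shape
        p = 2 * k + k * (k - 1) // 2
        if n < p + 1:
            raise ValueError(
                f"need at least {p + 1} observations to identify {p + 1} "
                f"coefficients, got {n}"
            )
        terms = second_order_terms(X / 2.0)
        M = np.hstack([np.ones((n, 1)), terms])
        if self.alpha > 0:
            penalty = np.sqrt(self.alpha) * np.eye(p + 1)
            penalty[0, 0] = 0.0  # intercept unpenalized
            Ma = np.vstack([M, penalty])
            ya = np.concatenate([y, np.zeros(p + 1)])
            beta, *_ = np.linalg.lstsq(Ma, ya, rcond=None)
        else:
            rank = np.linalg.matrix_rank(M)
            if rank < p + 1:
                raise ValueError(
                    f"model matrix rank {rank} < {p + 1}: the design does not "
                    "identify the full quadratic model — check the design, or "
                    "set alpha > 0 for a ridge fit"
                )
            beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        if not np.isfinite(beta).all():
            raise ValueError("non-finite coefficients in fit")

        self.n_features_in_ = k
        self.pair_index_ = [tuple(ij) for ij in zip(*np.triu_indices(k, 1))]
        self.intercept_ = float(beta[0])
        self.coef_linear_ = beta[1 : k + 1]
        self.coef_quadratic_ = beta[k + 1 : 2 * k + 1]
        self.coef_interaction_ = beta[2 * k + 1 :]
        self.n_obs_ = n

        resid = y - M @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if n - p - 1 > 0:
            self.adj_r2_ = 1.0 - (1.0 - self.r2_) * (n - 1) / (n - p - 1)
        else:
            self.adj_r2_ = float("nan")
        return self

    # -- prediction -------------------------------------------------------

    def _beta(self) -> np.ndarray:
        return np.concatenate(
            [[self.intercept_], self.coef_linear_, self.coef_quadratic_,
             self.coef_interaction_]
        )

    def predict(self, X) -> np.ndarray:
        """Predicted NCV at coded levels (0/1/2)."""
        check_is_fitted(self, "intercept_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} drugs, got {X.shape[1]}"
            )
        if not np.isin(X, (0, 1, 2)).all():
            raise ValueError("coded levels must be in {0, 1, 2}")
        terms = second_order_terms(X / 2.0)
        return np.hstack([np.ones((len(X), 1)), terms]) @ self._beta()

    # -- introspection ----------------------------------------------------

    @property
    def k(self) -> int:
        check_is_fitted(self, "intercept_")
        return int(self.n_features_in_)

    def drug_names(self) -> list[str]:
        if hasattr(self, "feature_names_in_"):
            return [str(d) for d in self.feature_names_in_]
        return [f"drug_{i}" for i in range(self.k)]

    def interaction(self, i: int, j: int) -> float:
        """Pairwise coefficient b_ij for an unordered drug pair."""
        if i == j:
            raise ValueError("interaction requires two distinct drugs")
        a, b = sorted((i, j))
        return float(self.coef_interaction_[self.pair_index_.index((a, b))])


def surface_from_coefficients(
    intercept: float,
    linear: Sequence[float],
    quadratic: Sequence[float],
    interaction: Sequence[float],
    drug_names: Sequence[str] | None = None,
) -> QuadraticSurfaceRegressor:
    """Build a surface directly from known coefficients (no fitting) —
    used for ground-truth surfaces and for deserialization."""
    k = len(linear)
    if len(quadratic) != k or len(interaction) != k * (k - 1) // 2:
        raise ValueError("coefficient block sizes inconsistent with k")
    m = QuadraticSurfaceRegressor()
    m.n_features_in_ = k
    m.pair_index_ = [tuple(ij) for ij in zip(*np.triu_indices(k, 1))]
    m.intercept_ = float(intercept)
    m.coef_linear_ = np.asarray(linear, dtype=float)
    m.coef_quadratic_ = np.asarray(quadratic, dtype=float)
    m.coef_interaction_ = np.asarray(interaction, dtype=float)
    m.n_obs_ = 0
    m.r2_ = m.adj_r2_ = float("nan")
    if drug_names is not None:
        m.feature_names_in_ = np.asarray(list(drug_names), dtype=object)
    return m


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def fit_quadratic_surface(
    design: DesignMatrix,
    response: NormalizedResponse | np.ndarray,
    drug_names: Sequence[str] | None = None,
    alpha: float = 0.0,
) -> QuadraticSurfaceRegressor:
    """OLS fit of the full quadratic surface to per-design-row NCV."""
    if isinstance(response, NormalizedResponse):
        y = np.full(design.n_rows, np.nan)
        idx = response.ncv.index.to_numpy(int)
        if idx.max() >= design.n_rows:
            raise ValueError("response references design rows beyond the design")
        y[idx] = response.ncv.to_numpy(float)
        if np.isnan(y).any():
            missing = int(np.isnan(y).sum())
            raise ValueError(f"{missing} design rows have no measured response")
    else:
        y = np.asarray(response, dtype=float)
        if len(y) != design.n_rows:
            raise ValueError("response length must equal design row count")
    X = design.codes
    if drug_names is not None:
        X = pd.DataFrame(design.codes, columns=list(drug_names))
    return QuadraticSurfaceRegressor(alpha=alpha).fit(X, y)


def predict_ncv(model: QuadraticSurfaceRegressor, levels: Sequence[int]) -> float:
    """Predicted NCV at a single coded level vector."""
    return float(model.predict(np.asarray(levels).reshape(1, -1))[0])


# ---------------------------------------------------------------------------
# exhaustive enumeration and ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinationRanking:
    """All 3^k dose-level assignments sorted ascending by predicted NCV
    (ties broken lexicographically on the coded vector).  Rank 1 is the
    combination with the greatest predicted cell-killing capability."""

    codes: np.ndarray   # (3^k, k) int8, in rank order
    scores: np.ndarray  # (3^k,) predicted NCV, ascending
    drug_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def k(self) -> int:
        return self.codes.shape[1]

    def order(self) -> np.ndarray:
        """Number of active (non-zero coded) drugs per entry."""
        return (self.codes != 0).sum(axis=1)

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        stop = self.n if top is None else min(top, self.n)
        df = pd.DataFrame(self.codes[:stop], columns=list(self.drug_names))
        df.insert(0, "rank", np.arange(1, stop + 1))
        df["predicted_ncv"] = self.scores[:stop]
        return df


def all_level_vectors(k: int) -> np.ndarray:
    """All 3^k coded vectors in lexicographic order (first drug slowest)."""
    n = 3**k
    idx = np.arange(n)
    powers = 3 ** np.arange(k - 1, -1, -1)
    return ((idx[:, None] // powers) % 3).astype(np.int8)


def enumerate_and_rank(
    model: QuadraticSurfaceRegressor, chunk: int = 1 << 16
) -> CombinationRanking:
    """Score every 3^k combination and sort ascending by predicted NCV.

    Chunked evaluation keeps peak memory modest for k = 12/13; refuses
    k > 13 outright rather than attempt an infeasible enumeration.
    """
    k = model.k
    if k > MAX_ENUM_K:
        raise ValueError(
            f"exhaustive enumeration refused for k={k} (> {MAX_ENUM_K}): "
            f"3^{k} combinations"
        )
    codes = all_level_vectors(k)
    scores = np.empty(len(codes))
    for start in range(0, len(codes), chunk):
        block = codes[start : start + chunk]
        x = block.astype(float) / 2.0
        scores[start : start + chunk] = (
            np.hstack([np.ones((len(block), 1)), second_order_terms(x)])
            @ model._beta()
        )
    # lexicographic tie-break: codes are generated in lexicographic order,
    # so a stable sort on the score alone preserves it
    order = np.argsort(scores, kind="stable")
    return CombinationRanking(
        codes=codes[order],
        scores=scores[order],
        drug_names=tuple(model.drug_names()),
    )


def top_combinations(
    ranking: CombinationRanking, order: int, n: int = 10
) -> pd.DataFrame:
    """First ``n`` entries with exactly ``order`` active drugs, in rank
    order; may return fewer than ``n``."""
    if order < 1:
        raise ValueError("order must be >= 1")
    mask = ranking.order() == order
    idx = np.flatnonzero(mask)[:n]
    df = pd.DataFrame(ranking.codes[idx], columns=list(ranking.drug_names))
    df.insert(0, "rank", idx + 1)
    df["predicted_ncv"] = ranking.scores[idx]
    return df


def pairwise_interaction_matrix(model: QuadraticSurfaceRegressor) -> pd.DataFrame:
    """Polygonogram matrix: best (lowest) predicted NCV for each drug pair
    in isolation.

    Off-diagonal (i, j): min over the four assignments with drugs i and j
    at codes {1, 2} and every other drug absent.  Diagonal: best
    single-drug predicted NCV over codes {1, 2}.  Symmetric by definition.
    """
    k = model.k
    mat = np.zeros((k, k))
    for i in range(k):
        best = np.inf
        for a in (1, 2):
            v = np.zeros(k, dtype=int)
            v[i] = a
            best = min(best, predict_ncv(model, v))
        mat[i, i] = best
    for i in range(k):
        for j in range(i + 1, k):
            best = np.inf
            for a in (1, 2):
                for b in (1, 2):
                    v = np.zeros(k, dtype=int)
                    v[i], v[j] = a, b
                    best = min(best, predict_ncv(model, v))
            mat[i, j] = mat[j, i] = best
    names = model.drug_names()
    return pd.DataFrame(mat, index=names, columns=names)


def predict_regimen_ncv(
    model: QuadraticSurfaceRegressor, regimen: Iterable[str]
) -> float:
    """Predicted NCV of a clinical regimen: each administered drug at its
    highest tested level (code 2), everything else absent — the score
    compared against the response cutoff for concordance."""
    names = model.drug_names()
    regimen = set(regimen)
    if not regimen:
        raise ValueError("regimen must contain at least one drug")
    unknown = regimen - set(names)
    if unknown:
        raise KeyError(f"regimen drugs not in panel: {sorted(unknown)}")
    v = np.zeros(model.k, dtype=int)
    for d in regimen:
        v[names.index(d)] = 2
    return predict_ncv(model, v)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_json(model: QuadraticSurfaceRegressor, path: str | Path | None = None) -> str:
    names = model.drug_names()
    payload = {
        "drugs": names,
        "intercept": model.intercept_,
        "linear": {d: float(c) for d, c in zip(names, model.coef_linear_)},
        "quadratic": {d: float(c) for d, c in zip(names, model.coef_quadratic_)},
        "interaction": {
            f"{names[i]}|{names[j]}": float(c)
            for (i, j), c in zip(model.pair_index_, model.coef_interaction_)
        },
        "adj_r2": None if np.isnan(model.adj_r2_) else model.adj_r2_,
        "n_obs": model.n_obs_,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> QuadraticSurfaceRegressor:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    names = payload["drugs"]
    model = surface_from_coefficients(
        payload["intercept"],
        [payload["linear"][d] for d in names],
        [payload["quadratic"][d] for d in names],
        [
            payload["interaction"][f"{names[i]}|{names[j]}"]
            for i, j in zip(*np.triu_indices(len(names), 1))
        ],
        drug_names=names,
    )
    model.n_obs_ = payload.get("n_obs", 0)
    if payload.get("adj_r2") is not None:
        model.adj_r2_ = payload["adj_r2"]
    return model
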