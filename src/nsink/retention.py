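"""Best-subset regression of retention/loss fractions on site predictors.

Site-level tracer recoveries are regressed on up to nine candidate
predictors (MAT, MAP, mineral-soil C/N, clay, leaf C/N, N deposition,
organic-layer mass, woody biomass, NPP).  Every non-empty predictor
subset is fitted by ordinary least squares, subsets with a variance
inflation factor above a cutoff (default 3) are excluded as collinear,
and the survivor with the smallest small-sample-corrected AIC wins.
The full ranked ledger is retained so the selection is auditable.

The OLS core is written directly on numpy least squares because the
Monte Carlo ensemble evaluates hundreds of thousands of tiny subset
fits; tests cross-check RSS, coefficients and AICc against statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CANDIDATE_PREDICTORS",
    "RegressionFit",
    "SelectionError",
    "SingularFitError",
    "aicc_from_rss",
    "fit_subset",
    "vif",
    "select_best",
    "BestSubsetRegressor",
]

#: The nine candidate predictors considered for every response.
CANDIDATE_PREDICTORS = (
    "mat",
    "map",
    "soil_cn",
    "clay",
    "leaf_cn",
    "n_dep",
    "org_mass",
    "wood_biomass",
    "npp",
)

#: Default multicollinearity cutoff: subsets whose largest VIF exceeds
#: this are dropped from the selection.
VIF_CUTOFF = 3.0

_TIE_TOL = 1e-9


class SingularFitError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


class SelectionError(RuntimeError):
    """No candidate subset survived screening."""


@dataclass(frozen=True)
class RegressionFit:
    """One fitted predictor subset.

    ``coefficients`` maps predictor name -> slope; ``intercept`` is kept
    separately.  ``vif`` maps predictor name -> variance inflation
    factor within this subset (1.0 for a single-predictor model; +inf
    marks perfect collinearity).
    """

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    aicc: float
    r2: float
    vif: dict[str, float]
    n: int
    rss: float
    excluded: bool = False  # True if dropped by the VIF screen

    def predict(self, data: Mapping[str, np.ndarray] | pd.DataFrame):
        """Evaluate the linear model on named columns/layers.

        Works on any mapping of predictor name to array (pandas frame,
        dict of 2-D raster layers, xarray Dataset), broadcasting as the
        arrays do.
        """
        out = self.intercept
        for name, beta in self.coefficients.items():
            out = out + beta * np.asarray(data[name], dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "aicc": self.aicc,
            "r2": self.r2,
            "vif": {k: (None if np.isinf(v) else v) for k, v in self.vif.items()},
            "n": self.n,
            "rss": self.rss,
            "excluded": self.excluded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        vifs = {k: (np.inf if v is None else v) for k, v in d["vif"].items()}
        return cls(
            response=d["response"],
            predictors=tuple(d["predictors"]),
            coefficients=dict(d["coefficients"]),
            intercept=d["intercept"],
            aicc=d["aicc"],
            r2=d["r2"],
            vif=vifs,
            n=d["n"],
            rss=d["rss"],
            excluded=d.get("excluded", False),
        )


def aicc_from_rss(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC from a Gaussian OLS fit.

    ``k`` is the number of predictors; the parameter count entering the
    penalty is k' = k + 2 (slopes + intercept + residual variance):

        AICc = n ln(RSS/n) + 2k' + 2k'(k'+1)/(n − k' − 1)

    using the constant-dropped Gaussian log-likelihood.  RSS of exactly
    zero maps to −inf (a perfect fit always wins).
    """
    kp = k + 2
    if n - kp - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n={n} too small for {k} predictors (need n > k + 3)"
        )
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (beta incl. intercept, rss)."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise SingularFitError(
            f"rank-deficient design: rank {rank} < {A.shape[1]} columns"
        )
    resid = y - A @ beta
    return beta, float(resid @ resid)


def vif(table: pd.DataFrame, predictors: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors within a predictor set.

    VIF_j = 1/(1 − R²_j) from regressing predictor j on the remaining
    ones, computed as the diagonal of the inverse correlation matrix.
    A single predictor has VIF 1.  Perfect collinearity is reported as
    the +inf sentinel, never raised.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        return {p: 1.0 for p in predictors}
    X = table[predictors].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        # a constant column is perfectly predicted by the intercept
        return {p: np.inf for p in predictors}
    R = np.corrcoef(X, rowvar=False)
    try:
        diag = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        return {p: np.inf for p in predictors}
    out = {}
    for p, d in zip(predictors, diag):
        out[p] = np.inf if (d <= 0 or d > 1e12) else float(d)
    return out


def fit_subset(
    table: pd.DataFrame, response: str, predictors: Sequence[str]
) -> RegressionFit:
    """OLS fit of ``response`` on one predictor subset.

    Raises :class:`SingularFitError` for rank-deficient designs and
    ``ValueError`` when the sample is too small for AICc.
    """
    predictors = tuple(predictors)
    cols = [response, *predictors]
    if table[cols].isna().any().any():
        raise ValueError(f"missing values in columns {cols}")
    y = table[response].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float)
    n = len(y)
    beta, rss = _ols(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return RegressionFit(
        response=response,
        predictors=predictors,
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        intercept=float(beta[0]),
        aicc=aicc_from_rss(rss, n, len(predictors)),
        r2=r2,
        vif=vif(table, predictors),
        n=n,
        rss=rss,
    )


def _ranked_key(fit: RegressionFit):
    # ties (ΔAICc below tolerance) break toward fewer predictors, then
    # lexicographic predictor order; quantize AICc to make the tolerance
    # an ordering, not a pairwise relation
    return (round(fit.aicc / _TIE_TOL) * _TIE_TOL, len(fit.predictors), fit.predictors)


def select_best(
    table: pd.DataFrame,
    response: str,
    candidate_predictors: Sequence[str] = CANDIDATE_PREDICTORS,
    vif_cutoff: float = VIF_CUTOFF,
) -> tuple[RegressionFit, list[RegressionFit]]:
    """Exhaustive best-subset selection under an AICc/VIF criterion.

    All 2^p − 1 non-empty subsets of ``candidate_predictors`` are
    evaluated; subsets whose maximum VIF exceeds ``vif_cutoff`` are
    marked excluded and never win, as are subsets too large for the
    sample (AICc undefined) or with rank-deficient designs.  Returns
    ``(best, ledger)`` where the ledger lists every evaluated subset
    ranked by (AICc, parsimony, lexicographic order), excluded fits
    last.

    Raises :class:`SelectionError` when the VIF screen eliminates every
    subset.
    """
    candidates = sorted(candidate_predictors)
    if not candidates:
        raise SelectionError("empty candidate predictor set")

    # hoist the column extraction and the candidate correlation matrix
    # out of the 2^p - 1 loop; subset VIFs are diagonals of inverses of
    # correlation submatrices
    y = table[response].to_numpy(dtype=float)
    X_all = table[candidates].to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(X_all).any():
        raise ValueError(f"missing values in columns {[response, *candidates]}")
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    sd = X_all.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X_all, rowvar=False) if len(candidates) > 1 else None

    def _subset_vif(idx: tuple[int, ...]) -> dict[str, float]:
        names = [candidates[i] for i in idx]
        if len(idx) < 2:
            return {p: 1.0 for p in names}
        if np.any(sd[list(idx)] == 0):
            return {p: np.inf for p in names}
        sub = corr[np.ix_(idx, idx)]
        try:
            diag = np.diag(np.linalg.inv(sub))
        except np.linalg.LinAlgError:
            return {p: np.inf for p in names}
        return {
            p: (np.inf if (d <= 0 or d > 1e12) else float(d))
            for p, d in zip(names, diag)
        }

    ledger: list[RegressionFit] = []

    def _excluded(subset, vifs):
        return RegressionFit(
            response=response,
            predictors=subset,
            coefficients={},
            intercept=np.nan,
            aicc=np.inf,
            r2=np.nan,
            vif=vifs,
            n=n,
            rss=np.nan,
            excluded=True,
        )

    indices = range(len(candidates))
    for k in range(1, len(candidates) + 1):
        for idx in combinations(indices, k):
            subset = tuple(candidates[i] for i in idx)
            vifs = _subset_vif(idx)
            if max(vifs.values()) > vif_cutoff:
                ledger.append(_excluded(subset, vifs))
                continue
            try:
                beta, rss = _ols(X_all[:, idx], y)
                aicc = aicc_from_rss(rss, n, k)
            except (SingularFitError, ValueError):
                # too few samples for AICc at this size, or a degenerate
                # design the VIF screen let through
                ledger.append(_excluded(subset, vifs))
                continue
            ledger.append(
                RegressionFit(
                    response=response,
                    predictors=subset,
                    coefficients={p: float(b) for p, b in zip(subset, beta[1:])},
                    intercept=float(beta[0]),
                    aicc=aicc,
                    r2=1.0 - rss / tss if tss > 0 else 0.0,
                    vif=vifs,
                    n=n,
                    rss=rss,
                )
            )
    survivors = [f for f in ledger if not f.excluded]
    if not survivors:
        raise SelectionError(
            f"every subset for response {response!r} exceeded the VIF "
            f"cutoff of {vif_cutoff}"
        )
    survivors.sort(key=_ranked_key)
    ledger = survivors + [f for f in ledger if f.excluded]
    return survivors[0], ledger


class BestSubsetRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn wrapper around exhaustive AICc/VIF subset selection.

    Parameters
    ----------
    vif_cutoff:
        Subsets whose largest variance inflation factor exceeds this are
        excluded from selection.
    candidates:
        Predictor column names to enumerate; ``None`` uses every column
        of the fitted ``X`` (DataFrame) or all array columns.

    Attributes
    ----------
    best_fit_ : RegressionFit
        The winning subset model.
    ledger_ : list of RegressionFit
        Every evaluated subset, ranked.
    coef_, intercept_ : ndarray, float
        Winning coefficients in fitted-column order (zeros for columns
        outside the selected subset).
    """

    def __init__(self, vif_cutoff: float = VIF_CUTOFF, candidates: Sequence[str] | None = None):
        self.vif_cutoff = vif_cutoff
        self.candidates = candidates

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D")
            frame = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        y = np.asarray(y, dtype=float)
        if len(y) != len(frame):
            raise ValueError("X and y have inconsistent lengths")
        frame = frame.assign(__y__=y)
        cands = list(self.candidates) if self.candidates is not None else list(
            self.feature_names_in_
        )
        self.best_fit_, self.ledger_ = select_best(
            frame, "__y__", cands, vif_cutoff=self.vif_cutoff
        )
        self.intercept_ = self.best_fit_.intercept
        self.coef_ = np.array(
            [self.best_fit_.coefficients.get(c, 0.0) for c in self.feature_names_in_]
        )
        return self

    def predict(self, X):
        if not hasattr(self, "best_fit_"):
            raise RuntimeError("BestSubsetRegressor is not fitted")
        if isinstance(X, pd.DataFrame):
            data = X
        else:
            X = np.asarray(X, dtype=float)
            data = pd.DataFrame(X, columns=list(self.feature_names_in_))
        return np.asarray(self.best_fit_.predict(data), dtype=float)
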