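"""Feature engineering: predictor, six mediators and outcome per focal game type.

For a focal game type *t* the derived analysis variables are:

==  =======================  ====================================================
X   participation            played type *t* at least once last year (0/1)
M1  propensity               demographic problem-gambling propensity score
M2  breadth                  number of game types played (capped, default 7)
M3  frequency within         ordinal frequency (0-5) on type *t*
M4  frequency beyond         maximum frequency over the 14 other types
M5  spending within          winsorized usual spending on type *t*
M6  spending beyond          maximum winsorized spending over the other types
Y   problem-gambling score   severity sum score, upper-capped (default 6)
==  =======================  ====================================================

All derivations operate on the sample of last-year gamblers. Missing depth
responses (frequency, spending) are replaced by 0 in this sample; spending is
winsorized at the 1st/99th percentile pooled across survey years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import percentile
from .config import AnalysisConfig
from .errors import FitError
from .survey import SurveyTable

MEDIATOR_COLUMNS = [
    "M1_propensity",
    "M2_breadth",
    "M3_freq_within",
    "M4_freq_beyond",
    "M5_spend_within",
    "M6_spend_beyond",
]
FEATURE_COLUMNS = ["X"] + MEDIATOR_COLUMNS + ["Y"]

PGSI_GROUP_LABELS = ("no_problem", "low_risk", "moderate_risk", "problem")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def winsorize(values, lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Replace values beyond the empirical percentiles by the percentile values.

    The bounds are the closest-rank order statistics taken *outward* (lower
    bound rounded down, upper bound rounded up), so both bounds are actual
    observations and the operation is exactly idempotent -- an interpolated
    bound would creep on re-application. Missing entries (NaN) are left
    untouched and do not enter the percentile computation. Raises
    ``ValueError`` on an all-missing input or an invalid percentile pair.
    Order-preserving.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    arr = np.asarray(values, dtype=float)
    lo, hi = winsor_bounds(arr, lower_pct, upper_pct)
    out = arr.copy()
    mask = ~np.isnan(arr)
    out[mask] = np.clip(arr[mask], lo, hi)
    return out


def winsor_bounds(values, lower_pct: float, upper_pct: float):
    """Closest-rank-outward winsorization bounds (lower floor, upper ceil)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise ValueError("winsorization of an all-missing input is undefined")
    lo = np.percentile(finite, lower_pct, method="lower")
    hi = np.percentile(finite, upper_pct, method="higher")
    return float(lo), float(hi)


def derive_participation(freq):
    """Dichotomous last-year participation from an ordinal frequency.

    1 when frequency >= 1 (a few times a year or more often); 0 when the
    frequency is 0 (never) or missing. Accepts scalars or arrays.
    """
    arr = np.asarray(freq, dtype=float)
    out = (np.nan_to_num(arr, nan=0.0) >= 1).astype(int)
    return out if arr.ndim else int(out)


def compute_breadth(participation, cap: int = 7):
    """Number of game types played at least once, capped at ``cap``.

    ``participation`` is a (n_types,) vector or (n, n_types) indicator matrix.
    """
    arr = np.asarray(participation, dtype=int)
    total = arr.sum(axis=-1)
    return np.minimum(total, cap)


def beyond_max(values, focal_index: int):
    """Maximum over all game types except the focal one.

    ``values`` is a (n_types,) vector or (n, n_types) matrix with missing
    values already imputed; ``focal_index`` is the column to exclude.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    others = np.delete(arr, focal_index, axis=1)
    out = others.max(axis=1)
    return out if np.asarray(values).ndim == 2 else float(out[0])


def pgsi_group(score):
    """Map a severity sum score to its risk group.

    0 -> ``no_problem``; 1-4 -> ``low_risk``; 5-7 -> ``moderate_risk``;
    8-27 -> ``problem``. Scores outside [0, 27] raise ``ValueError``.
    """
    arr = np.asarray(score)
    if np.any((arr < 0) | (arr > 27)):
        raise ValueError("severity score outside the 0-27 range")
    idx = np.digitize(arr, [1, 5, 8])
    labels = np.array(PGSI_GROUP_LABELS)[idx]
    return labels if arr.ndim else str(labels)


# ---------------------------------------------------------------------------
# demographic propensity model
# ---------------------------------------------------------------------------

PROPENSITY_PREDICTORS = ["male", "education", "single", "age"]


@dataclass
class PropensityModel:
    """Fitted logistic model of being at least at moderate risk, plus scores."""

    coefficients: dict  # name -> log-odds coefficient (incl. "intercept")
    odds_ratios: dict  # name -> exp(coefficient), predictors only
    pvalues: dict
    scores: np.ndarray  # one score per table row (imputed where needed)
    n_missing_imputed: int
    threshold: int
    scale: str  # "probability" | "linear"


def _propensity_design(table: SurveyTable) -> pd.DataFrame:
    df = table.df
    return pd.DataFrame(
        {
            "male": (df["gender"] == "male").astype(float).where(df["gender"].notna()),
            "education": df["education"].astype(float),
            "single": (df["partnered"] == "single").astype(float).where(df["partnered"].notna()),
            "age": df["age"].astype(float),
        }
    )


class PropensityScorer(BaseEstimator):
    """Binary logistic regression of a rare high-risk outcome on demographics.

    scikit-learn style estimator. ``X`` is a DataFrame (or array) with columns
    male (0/1), education (ordered 1-3, entered as one metric term), single
    (0/1) and age (years); ``y`` is the binary outcome. The maximum-likelihood
    fit is computed on complete cases.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray of shape (4,)
        Log-odds coefficients in predictor order.
    intercept_ : float
    odds_ratios_ : dict of predictor -> exp(coefficient)
    pvalues_ : dict
    """

    def __init__(self, scale: str = "probability"):
        self.scale = scale

    def fit(self, X, y):
        X = pd.DataFrame(X, columns=getattr(X, "columns", PROPENSITY_PREDICTORS))
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise FitError("propensity outcome has a single class; cannot fit")
        design = sm.add_constant(X[PROPENSITY_PREDICTORS].astype(float), has_constant="add")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
        except Exception as exc:  # pragma: no cover - perfect separation etc.
            raise FitError(f"propensity logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise FitError("propensity logistic fit did not converge")
        self.result_ = res
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params[PROPENSITY_PREDICTORS].to_numpy()
        self.odds_ratios_ = {
            k: float(np.exp(res.params[k])) for k in PROPENSITY_PREDICTORS
        }
        self.pvalues_ = {k: float(res.pvalues[k]) for k in PROPENSITY_PREDICTORS}
        self.n_features_in_ = 4
        return self

    def decision_function(self, X):
        X = pd.DataFrame(X, columns=getattr(X, "columns", PROPENSITY_PREDICTORS))
        mat = X[PROPENSITY_PREDICTORS].astype(float).to_numpy()
        return self.intercept_ + mat @ self.coef_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def score_values(self, X):
        """Scores on the configured scale (probability or linear predictor)."""
        if self.scale == "linear":
            return self.decision_function(X)
        return self.predict_proba(X)[:, 1]


def fit_propensity(
    table: SurveyTable,
    threshold: int = 5,
    scale: str = "probability",
) -> PropensityModel:
    """Fit the demographic propensity stage on a table of last-year gamblers.

    The outcome is severity score >= ``threshold`` (at least moderate risk).
    Rows with any missing demographic get the mean score of all scored rows;
    the count of such rows is recorded.
    """
    design = _propensity_design(table)
    complete = design.notna().all(axis=1).to_numpy()
    y = (table.df["pgsi_raw"].to_numpy() >= threshold).astype(float)
    scorer = PropensityScorer(scale=scale).fit(design.loc[complete], y[complete])

    scores = np.full(len(table), np.nan)
    scores[complete] = scorer.score_values(design.loc[complete])
    n_imputed = int((~complete).sum())
    if n_imputed:
        scores[~complete] = np.nanmean(scores[complete])
    coeffs = {"intercept": scorer.intercept_}
    coeffs.update(dict(zip(PROPENSITY_PREDICTORS, scorer.coef_)))
    return PropensityModel(
        coefficients=coeffs,
        odds_ratios=scorer.odds_ratios_,
        pvalues=scorer.pvalues_,
        scores=scores,
        n_missing_imputed=n_imputed,
        threshold=threshold,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# featureset assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Complete analysis variables for one focal game type (no missing values)."""

    focal_type: str
    df: pd.DataFrame  # columns FEATURE_COLUMNS
    propensity: PropensityModel | None = None
    winsor_bounds: dict = field(default_factory=dict)  # spend col -> (lo, hi)
    breadth_cap: int = 7
    pgsi_cap: int = 6

    def __len__(self):
        return len(self.df)

    @property
    def mediator_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("X", "Y")]

    @property
    def X(self):
        return self.df["X"].to_numpy(dtype=float)

    @property
    def M(self):
        return self.df[self.mediator_names].to_numpy(dtype=float)

    @property
    def Y(self):
        return self.df["Y"].to_numpy(dtype=float)

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


class FeatureBuilder(BaseEstimator, TransformerMixin):
    """Transformer deriving per-focal-type feature sets from a survey table.

    ``fit`` performs all sample-level work once (depth imputation, pooled
    spending winsorization, breadth, propensity scoring, outcome capping);
    ``featureset(type_id)`` then assembles the variables for any focal type.
    ``transform`` returns the feature sets for every catalog type as a dict.
    """

    def __init__(self, config: AnalysisConfig | None = None):
        self.config = config

    def fit(self, table: SurveyTable, y=None):
        cfg = self.config or AnalysisConfig()
        cat = table.catalog
        freq_raw = table.df[cat.frequency_columns].to_numpy(dtype=float)
        spend_raw = table.df[cat.spending_columns].to_numpy(dtype=float)

        freq = np.nan_to_num(freq_raw, nan=0.0)
        if cfg.impute_before_winsorize:
            spend = np.nan_to_num(spend_raw, nan=0.0)
        else:
            spend = spend_raw
        spend_w = np.empty_like(spend)
        bounds = {}
        for j, col in enumerate(cat.spending_columns):
            spend_w[:, j] = winsorize(spend[:, j], cfg.winsor_lower_pct, cfg.winsor_upper_pct)
            bounds[col] = winsor_bounds(spend[:, j], cfg.winsor_lower_pct, cfg.winsor_upper_pct)
        if not cfg.impute_before_winsorize:
            spend_w = np.nan_to_num(spend_w, nan=0.0)

        participation = (freq >= 1).astype(int)
        if cfg.breadth_cap_mode == "percentile99":
            cap = int(round(percentile(participation.sum(axis=1), 99)))
        else:
            cap = cfg.breadth_cap_value
        breadth = compute_breadth(participation, cap)

        pgsi = table.df["pgsi_raw"].to_numpy(dtype=float)
        if cfg.pgsi_cap_mode == "percentile99":
            pgsi_cap = int(round(percentile(pgsi, 99)))
        else:
            pgsi_cap = cfg.pgsi_cap_value
        y_out = np.minimum(pgsi, pgsi_cap)

        self.config_ = cfg
        self.catalog_ = cat
        self.freq_ = freq
        self.spend_w_ = spend_w
        self.participation_ = participation
        self.breadth_ = breadth
        self.breadth_cap_ = cap
        self.pgsi_cap_ = pgsi_cap
        self.y_ = y_out
        self.winsor_bounds_ = bounds
        self.propensity_ = fit_propensity(
            table, cfg.propensity_threshold, cfg.propensity_score_scale
        )
        return self

    def featureset(self, focal_type: str) -> FeatureSet:
        j = self.catalog_.type_ids.index(focal_type)
        df = pd.DataFrame(
            {
                "X": self.participation_[:, j],
                "M1_propensity": self.propensity_.scores,
                "M2_breadth": self.breadth_,
                "M3_freq_within": self.freq_[:, j],
                "M4_freq_beyond": beyond_max(self.freq_, j),
                "M5_spend_within": self.spend_w_[:, j],
                "M6_spend_beyond": beyond_max(self.spend_w_, j),
                "Y": self.y_,
            }
        )
        return FeatureSet(
            focal_type=focal_type,
            df=df,
            propensity=self.propensity_,
            winsor_bounds=self.winsor_bounds_,
            breadth_cap=self.breadth_cap_,
            pgsi_cap=self.pgsi_cap_,
        )

    def transform(self, table: SurveyTable | None = None) -> dict:
        return {t: self.featureset(t) for t in self.catalog_.type_ids}


def build_featureset(
    table: SurveyTable, focal_type: str, config: AnalysisConfig | None = None
) -> FeatureSet:
    """Derive X, M1-M6 and Y for one focal type (table already filtered)."""
    return FeatureBuilder(config).fit(table).featureset(focal_type)
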