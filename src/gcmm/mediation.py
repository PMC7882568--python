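"""Parallel multiple mediation: OLS paths, effect decomposition, percentile bootstrap.

For a binary exposure X (participation in the focal game type), mediators
M1..Mm and outcome Y (capped problem-gambling score), the model consists of

* a-paths: m simple regressions ``M_j ~ 1 + X``,
* outcome model: ``Y ~ 1 + X + M1 + ... + Mm`` giving b-paths and the direct
  effect c',
* indirect effects ``a_j * b_j`` and the total effect ``c' + sum_j a_j b_j``,
  which by OLS algebra equals the simple-regression slope of Y on X.

Inference is by nonparametric percentile bootstrap: whole rows are resampled
with replacement B times, all paths are refit per resample, and each effect's
confidence interval is the empirical (alpha/2, 1-alpha/2) quantile of its
bootstrap distribution. Resamples with a degenerate design (e.g. the exposure
or a mediator constant in the resample) are redrawn so the distribution keeps
exactly B draws.

The bootstrap is evaluated in batched linear algebra: per resample the
normal equations of the (column-equilibrated, centered) design are solved as
a stacked (m+1)x(m+1) system, which keeps 5000 resamples of a survey-sized
table well under a second of arithmetic per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import percentile, spawn_seed
from .config import AnalysisConfig
from .errors import FitError
from .features import FeatureBuilder, FeatureSet

__all__ = [
    "BootstrapSettings",
    "MediationFit",
    "ParallelMediation",
    "ols_fit",
    "fit_point_estimates",
    "bootstrap",
    "run_all_types",
    "MediationRunResult",
]


@dataclass
class BootstrapSettings:
    """Resampling controls: count, interval level, seed."""

    B: int = 5000
    ci_level: float = 0.95
    seed: int = 20211

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class MediationFit:
    """Point estimates, decomposition and bootstrap intervals for one model.

    ``ci`` and ``relevant`` are keyed by effect name: ``a:<mediator>``,
    ``b:<mediator>``, ``indirect:<mediator>``, ``c_prime`` and ``total``.
    ``decomposition_gap`` records the largest relative discrepancy between
    ``c' + sum a_j b_j`` and the simple-regression slope of Y on X seen across
    the point fit and every bootstrap resample.
    """

    mediators: list[str]
    a: np.ndarray
    b: np.ndarray
    c_prime: float
    indirect: np.ndarray
    total: float
    n: int
    focal_type: str | None = None
    ci: dict = field(default_factory=dict)
    relevant: dict = field(default_factory=dict)
    B: int = 0
    ci_level: float = 0.95
    seed: int | None = None
    n_redraws: int = 0
    decomposition_gap: float = 0.0

    def indirect_effects(self) -> dict:
        return dict(zip(self.mediators, self.indirect))

    def effect_names(self) -> list[str]:
        return (
            [f"a:{m}" for m in self.mediators]
            + [f"b:{m}" for m in self.mediators]
            + [f"indirect:{m}" for m in self.mediators]
            + ["c_prime", "total"]
        )

    def estimates(self) -> dict:
        vals = np.concatenate([self.a, self.b, self.indirect, [self.c_prime, self.total]])
        return dict(zip(self.effect_names(), vals))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per effect with estimate, CI and relevance."""
        rows = []
        for name, est in self.estimates().items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "focal_type": self.focal_type,
                    "effect": name,
                    "estimate": est,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "relevant": self.relevant.get(name, None),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain OLS with rank diagnostics
# ---------------------------------------------------------------------------

def ols_fit(y, design, column_names=None) -> np.ndarray:
    """Least-squares coefficients of ``y`` on ``design`` (caller includes the
    intercept column). A rank-deficient design raises ``FitError`` naming the
    collinear column(s), identified from a pivoted QR of the design."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] < X.shape[1]:
        raise FitError("design must be 2-D with at least as many rows as columns")
    names = list(column_names) if column_names is not None else [
        f"col{i}" for i in range(X.shape[1])
    ]
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise FitError(f"design is rank deficient; collinear column(s): {', '.join(bad)}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# batched path effects
# ---------------------------------------------------------------------------

class _WeightedPaths:
    """All path effects for arbitrarily many bootstrap resamples at once.

    Row resampling with replacement is equivalent to integer *count weights*
    w (summing to n) on the original rows, so every resample's centered
    cross-product matrix is a weighted moment:

        G_w = sum_i w_i d_i d_i' - n * dbar_w dbar_w'

    The per-row outer products are precomputed once into a matrix ``Q`` of
    shape (n, p^2 + 2p + 1); a whole batch of resamples then needs a single
    BLAS product ``W @ Q`` and a batched (p x p) solve -- no per-resample
    gathers. Inputs are expected full-sample centered and SD-scaled
    (equilibrated), which both conditions the solves and makes the mean
    correction term numerically negligible relative to the main moment.
    """

    def __init__(self, xs, Ms, ys):
        self.n, self.m = Ms.shape
        self.p = 1 + self.m
        D = np.column_stack([xs, Ms])  # (n, p)
        outer = D[:, :, None] * D[:, None, :]  # (n, p, p)
        self.Q = np.concatenate(
            [outer.reshape(self.n, self.p**2), D * ys[:, None], D, ys[:, None]],
            axis=1,
        )

    def effects(self, W):
        """Path effects for count-weight matrix ``W`` of shape (C, n).

        Returns (a, b, c_prime, slope_simple, ok) on the scaled metric;
        ``ok`` flags resamples whose outcome design was full rank.
        """
        n, p = self.n, self.p
        C = W.shape[0]
        S = W @ self.Q
        G = S[:, : p**2].reshape(C, p, p).copy()
        r = S[:, p**2 : p**2 + p].copy()
        mean_d = S[:, p**2 + p : p**2 + 2 * p] / n
        mean_y = S[:, -1] / n
        G -= n * mean_d[:, :, None] * mean_d[:, None, :]
        r -= n * mean_d * mean_y[:, None]

        sxx = G[:, 0, 0]
        sxy = r[:, 0]
        sxM = G[:, 0, 1:].copy()

        diag = np.einsum("cii->ci", G)
        ok = (diag > 1e-8 * n).all(axis=1)
        # reject (near-)singular members: on the equilibrated design the Gram
        # matrix is correlation-like, so a tiny relative eigenvalue flags
        # exact or numerically exact collinearity (e.g. a mediator == X)
        if ok.any():
            ev = np.linalg.eigvalsh(G[ok])
            ok[np.flatnonzero(ok)] = ev[:, 0] > 1e-9 * ev[:, -1]
        coef = np.full((C, p), np.nan)
        if ok.any():
            Gok, rok = G[ok], r[ok]
            try:
                sol = np.linalg.solve(Gok, rok[..., None])[..., 0]
            except np.linalg.LinAlgError:  # isolated exactly singular member
                sol = np.full_like(rok, np.nan)
                for i in range(len(Gok)):
                    try:
                        sol[i] = np.linalg.solve(Gok[i], rok[i])
                    except np.linalg.LinAlgError:
                        pass
            coef[ok] = sol
        ok &= np.isfinite(coef).all(axis=1)

        with np.errstate(divide="ignore", invalid="ignore"):
            a = sxM / sxx[:, None]
            slope = sxy / sxx
        return a, coef[:, 1:], coef[:, 0], slope, ok


def _counts_from_indices(idx, n):
    """Row-draw counts (C, n) from a resample index matrix (C, n)."""
    C = idx.shape[0]
    offsets = idx + (np.arange(C) * n)[:, None]
    return (
        np.bincount(offsets.ravel(), minlength=C * n)
        .reshape(C, n)
        .astype(float)
    )


class ParallelMediation(BaseEstimator):
    """scikit-learn style estimator for one parallel multiple mediation model.

    Parameters
    ----------
    n_boot : int
        Number of bootstrap resamples (0 skips interval estimation).
    ci_level : float
        Two-sided confidence level for the percentile intervals.
    random_state : int or None
        Seed of the resampling stream; fits are reproducible given a seed.
    mediator_names : list of str, optional
        Labels for the mediator columns; defaults to DataFrame column names
        or ``M1..Mm``.
    max_redraw_frac : float
        Abort when more than this fraction of resamples had to be redrawn
        because of rank-deficient designs.

    ``fit(X, y)`` expects ``X`` of shape (n, 1+m) whose *first column is the
    binary exposure* and remaining columns the mediators, and ``y`` the
    outcome. Fitted attributes: ``a_``, ``b_``, ``c_prime_``, ``indirect_``,
    ``total_``, ``ci_``, ``relevant_``, ``fit_`` (the full
    :class:`MediationFit`).
    """

    _CHUNK = 1024  # resamples solved per batch; bounds peak memory

    def __init__(
        self,
        n_boot: int = 5000,
        ci_level: float = 0.95,
        random_state: int | None = None,
        mediator_names=None,
        max_redraw_frac: float = 0.1,
    ):
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state
        self.mediator_names = mediator_names
        self.max_redraw_frac = max_redraw_frac

    # -- helpers ------------------------------------------------------------
    def _resolve_names(self, X, m):
        if self.mediator_names is not None:
            names = list(self.mediator_names)
            if len(names) != m:
                raise ValueError("mediator_names length does not match X")
            return names
        if hasattr(X, "columns"):
            return [str(c) for c in list(X.columns)[1:]]
        return [f"M{j + 1}" for j in range(m)]

    def fit(self, X, y):
        cols = self._resolve_names(X, np.asarray(X).shape[1] - 1)
        arr = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("X must be (n, 1+m): exposure column plus mediators")
        if arr.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if np.isnan(arr).any() or np.isnan(y).any():
            raise ValueError("missing values must be resolved before model fitting")
        x, M = arr[:, 0], arr[:, 1:]
        n, m = M.shape

        if np.ptp(x) == 0:
            raise FitError("exposure X is constant; both participation values required")
        sd_M = M.std(axis=0)
        if (sd_M == 0).any():
            bad = [cols[j] for j in np.flatnonzero(sd_M == 0)]
            raise FitError(
                f"constant mediator(s): {', '.join(bad)}; remove them from the model"
            )

        # column equilibration: center and scale every variable by its
        # full-sample SD so the normal equations are solved on a
        # correlation-like, well conditioned system; slopes are mapped back
        # exactly afterwards (slopes are location/scale equivariant).
        sd_x = x.std()
        sd_y = y.std() if y.std() > 0 else 1.0
        xs = (x - x.mean()) / sd_x
        Ms = (M - M.mean(axis=0)) / sd_M
        ys = (y - y.mean()) / sd_y

        paths = _WeightedPaths(xs, Ms, ys)
        a_s, b_s, c_s, slope_s, ok = paths.effects(np.ones((1, n)))
        if not ok[0]:
            raise FitError("outcome design is rank deficient (collinear mediators)")
        fac_a = sd_M / sd_x
        fac_b = sd_y / sd_M
        fac_xy = sd_y / sd_x
        a = a_s[0] * fac_a
        b = b_s[0] * fac_b
        c_prime = float(c_s[0] * fac_xy)
        indirect = a * b
        total = float(c_prime + indirect.sum())
        gap = abs(total - slope_s[0] * fac_xy) / (1.0 + abs(slope_s[0] * fac_xy))

        result = MediationFit(
            mediators=cols,
            a=a,
            b=b,
            c_prime=c_prime,
            indirect=indirect,
            total=total,
            n=n,
            ci_level=self.ci_level,
            seed=self.random_state,
            decomposition_gap=float(gap),
        )

        if self.n_boot >= 1:
            self._bootstrap(result, paths, fac_a, fac_b, fac_xy)

        self.fit_ = result
        self.mediators_ = cols
        self.a_, self.b_ = result.a, result.b
        self.c_prime_, self.total_ = result.c_prime, result.total
        self.indirect_ = result.indirect
        self.ci_, self.relevant_ = result.ci, result.relevant
        self.n_features_in_ = arr.shape[1]
        return self

    def _bootstrap(self, result, paths, fac_a, fac_b, fac_xy):
        B = int(self.n_boot)
        n, m = paths.n, paths.m
        rng = np.random.default_rng(self.random_state)
        stats = np.empty((B, 3 * m + 2))
        gap = result.decomposition_gap
        n_redraws = 0

        pending = np.arange(B)
        idx_all = rng.integers(0, n, size=(B, n))
        while pending.size:
            done = []
            for start in range(0, pending.size, self._CHUNK):
                sel = pending[start : start + self._CHUNK]
                W = _counts_from_indices(idx_all[sel], n)
                a_s, b_s, c_s, slope_s, ok = paths.effects(W)
                a = a_s * fac_a
                b = b_s * fac_b
                ind = a * b
                c_prime = c_s * fac_xy
                total = c_prime + ind.sum(axis=1)
                slope = slope_s * fac_xy
                ok_sel = sel[ok]
                stats[ok_sel, :m] = a[ok]
                stats[ok_sel, m : 2 * m] = b[ok]
                stats[ok_sel, 2 * m : 3 * m] = ind[ok]
                stats[ok_sel, 3 * m] = c_prime[ok]
                stats[ok_sel, 3 * m + 1] = total[ok]
                if ok.any():
                    g = np.abs(total[ok] - slope[ok]) / (1.0 + np.abs(slope[ok]))
                    gap = max(gap, float(g.max()))
                done.extend(sel[ok])
            pending = np.setdiff1d(pending, np.asarray(done, dtype=int))
            if pending.size:
                n_redraws += pending.size
                if n_redraws > self.max_redraw_frac * B:
                    raise FitError(
                        f"more than {self.max_redraw_frac:.0%} of bootstrap resamples "
                        f"({n_redraws}/{B}) were rank deficient; data too degenerate"
                    )
                idx_all[pending] = rng.integers(0, n, size=(pending.size, n))

        alpha = 1.0 - self.ci_level
        lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
        names = result.effect_names()
        for k, name in enumerate(names):
            lo, hi = percentile(stats[:, k], [lo_q, hi_q])
            result.ci[name] = (float(lo), float(hi))
            result.relevant[name] = bool(lo > 0 or hi < 0)
        result.B = B
        result.n_redraws = n_redraws
        result.decomposition_gap = gap
        self.bootstrap_stats_ = stats


# ---------------------------------------------------------------------------
# featureset-level wrappers
# ---------------------------------------------------------------------------

def _fit_featureset(fs: FeatureSet, settings: BootstrapSettings | None) -> MediationFit:
    est = ParallelMediation(
        n_boot=settings.B if settings else 0,
        ci_level=settings.ci_level if settings else 0.95,
        random_state=settings.seed if settings else None,
        mediator_names=fs.mediator_names,
    )
    est.fit(np.column_stack([fs.X, fs.M]), fs.Y)
    est.fit_.focal_type = fs.focal_type
    return est.fit_


def fit_point_estimates(fs: FeatureSet) -> MediationFit:
    """Path point estimates and decomposition only (no intervals)."""
    return _fit_featureset(fs, None)


def bootstrap(fs: FeatureSet, settings: BootstrapSettings | None = None) -> MediationFit:
    """Full fit with percentile-bootstrap intervals and relevance flags."""
    return _fit_featureset(fs, settings or BootstrapSettings())


@dataclass
class MediationRunResult:
    """Fits per game type plus any per-type failures (run never aborts early)."""

    fits: dict  # type_id -> MediationFit
    failures: dict  # type_id -> error message

    def summary(self) -> str:
        lines = [f"fitted {len(self.fits)} game types"]
        for t, msg in self.failures.items():
            lines.append(f"FAILED {t}: {msg}")
        return "\n".join(lines)


def run_all_types(table, catalog=None, config: AnalysisConfig | None = None) -> MediationRunResult:
    """Fit one parallel mediation model per catalog game type.

    ``table`` must already be filtered to last-year gamblers. Each type gets
    its own seed derived from ``config.rng_seed`` so runs are reproducible and
    types are independent streams.
    """
    cfg = config or AnalysisConfig()
    catalog = catalog or table.catalog
    builder = FeatureBuilder(cfg).fit(table)
    fits, failures = {}, {}
    for k, type_id in enumerate(catalog.type_ids):
        try:
            fs = builder.featureset(type_id)
            settings = BootstrapSettings(
                B=cfg.bootstrap_B, ci_level=cfg.ci_level, seed=spawn_seed(cfg.rng_seed, k)
            )
            fits[type_id] = bootstrap(fs, settings)
        except Exception as exc:  # noqa: BLE001 - collected per spec contract
            failures[type_id] = str(exc)
    return MediationRunResult(fits=fits, failures=failures)
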