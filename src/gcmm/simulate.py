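"""Synthetic survey microdata with plantable mediation structure.

The generator emulates the statistical shape of repeated cross-sectional
gambling prevalence surveys:

* 15 game types whose marginal participation spans ~0.2% to ~76% per survey
  year, positively correlated across types through one latent involvement
  factor per respondent (one knob, ``rho``);
* ordinal gambling frequency (0 = never ... 5 = daily) obtained by
  thresholding the latent intensity within participants;
* heavy-tailed usual spending (lognormal body plus a rare inflated-outlier
  component) so that winsorization visibly changes estimates;
* demographics whose link to a rare high-risk outcome follows a logistic
  model with configurable odds ratios;
* a zero-inflated integer problem-gambling score (0-27) driven by a linear
  predictor over the six mediator constructs of the mediation model, with
  configurable true coefficients -- so every downstream stage has a known
  ground truth to recover.

Three generators are exposed: :func:`generate_survey` (the full survey),
:func:`simulate_mediation_dataset` (feature-level data with exactly planted
a/b paths, for calibration and power studies) and
:func:`simulate_demographics_outcome` (demographics plus a binary outcome
drawn from the exact logistic model, for odds-ratio recovery).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, ndtr

from .catalog import default_catalog
from .config import AnalysisConfig
from .errors import ConfigError
from .features import MEDIATOR_COLUMNS, FeatureSet
from .survey import SurveyTable

#: per-year participation rates among last-year gamblers that the default
#: synthetic population mirrors (survey years 2007, 2011, 2017).
_GAMBLER_RATES = {
    "lotto_offline": (0.756, 0.794, 0.680),
    "lotto_online_is": (0.087, 0.105, 0.195),
    "egm_offline": (0.150, 0.129, 0.103),
    "scratch_offline": (0.306, 0.303, 0.327),
    "sportpools_offline": (0.077, 0.078, 0.057),
    "sportpools_online_is": (0.021, 0.037, 0.052),
    "sportbet_offline": (0.035, 0.042, 0.028),
    "sportbet_online_is": (0.015, 0.029, 0.038),
    "livebet_online": (0.008, 0.008, 0.046),
    "sportbet_online_foreign": (0.002, 0.012, 0.053),
    "poker_offline": (0.074, 0.155, 0.096),
    "poker_online_foreign": (0.003, 0.032, 0.020),
    "skillbet_offline": (0.031, 0.032, 0.015),
    "bingo_offline": (0.089, 0.152, 0.211),
    "other_online_foreign": (0.005, 0.013, 0.022),
}

#: fraction of the population that gambled last year (used to convert the
#: gambler-conditional rates above into population marginals).
_GAMBLER_FRACTION = 0.613


def _default_participation() -> dict:
    return {
        t: tuple(round(r * _GAMBLER_FRACTION, 4) for r in rates)
        for t, rates in _GAMBLER_RATES.items()
    }


@dataclass
class OutcomeBetas:
    """True coefficients of the problem-gambling linear predictor.

    Units follow the constructs: propensity is a probability in (0, 1),
    breadth a game-type count, frequencies ordinal 0-5, spending in currency
    units (Krona), hence the small spending coefficients.
    """

    propensity: float = 3.0
    breadth: float = 0.35
    freq_within: float = 0.15
    freq_beyond: float = 0.10
    spend_within: float = 2.0e-5
    spend_beyond: float = 1.0e-5

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.propensity,
                self.breadth,
                self.freq_within,
                self.freq_beyond,
                self.spend_within,
                self.spend_beyond,
            ]
        )


@dataclass
class GeneratorParams:
    """Full configuration of the synthetic survey generator."""

    n_per_year: tuple = (2631, 1887, 2703)
    years: tuple = (2007, 2011, 2017)
    participation: dict = field(default_factory=_default_participation)
    rho: float = 0.45  # cross-type involvement correlation (latent factor loading^2)
    freq_thresholds: tuple = (0.55, 0.85, 0.95, 0.99)
    spend_log_mean: float = 7.0  # ~1100 Krona typical stake
    spend_log_sd: float = 1.0
    spend_freq_corr: float = 0.4  # within-type frequency/spending coupling
    outlier_rate: float = 0.01
    outlier_scale: float = 20.0
    # demographic -> high-risk outcome odds ratios
    or_male: float = 5.026
    or_education: float = 0.527
    or_single: float = 1.671
    or_age: float = 0.951
    demo_intercept: float = -2.6  # gives a ~1.2% mean demographic risk
    # outcome model
    focal_type: str = "egm_offline"
    betas: OutcomeBetas = field(default_factory=OutcomeBetas)
    pgsi_intercept: float = -2.4
    noise_scale: float = 1.0
    noise_tail_prob: float = 0.12
    noise_tail_scale: float = 4.5
    # missingness per block (demographics rate is per row, depth rates per cell)
    missing_rates: dict = field(
        default_factory=lambda: {"frequency": 0.01, "spending": 0.05, "demographics": 0.0294}
    )
    rng_seed: int = 20211

    def __post_init__(self):
        if isinstance(self.betas, dict):
            self.betas = OutcomeBetas(**self.betas)
        if len(self.n_per_year) != len(self.years):
            raise ConfigError("n_per_year and years must have equal length")
        if any(n < 0 for n in self.n_per_year):
            raise ConfigError("n_per_year entries must be >= 0")
        if not (0 <= self.rho <= 1):
            raise ConfigError("rho must lie in [0, 1]")
        th = np.asarray(self.freq_thresholds, dtype=float)
        if th.size != 4 or (np.diff(th) <= 0).any() or th[0] <= 0 or th[-1] > 1:
            raise ConfigError(
                "freq_thresholds must be 4 strictly increasing cut-points in (0, 1]"
            )
        for t, rates in self.participation.items():
            arr = np.atleast_1d(np.asarray(rates, dtype=float))
            if ((arr < 0) | (arr > 1)).any():
                raise ConfigError(f"participation probabilities for {t!r} outside [0, 1]")
        for name in ("or_male", "or_education", "or_single", "or_age"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive odds ratio")
        for k, v in self.missing_rates.items():
            if not (0 <= v <= 1):
                raise ConfigError(f"missing rate {k!r} outside [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Population quantities recorded at generation time for recovery tests."""

    focal_type: str
    a_paths: dict  # mediator construct -> realized mean difference by X
    b_paths: dict  # mediator construct -> true outcome coefficient
    indirect: dict  # mediator construct -> a * b
    demographic_odds_ratios: dict
    n_gamblers: int
    gambler_fraction: float

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# full survey generator
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_survey(params: GeneratorParams | None = None):
    """Generate a synthetic survey and its ground truth.

    Returns ``(SurveyTable, GroundTruth)``. Reproducible for a fixed
    ``params.rng_seed``; per-type marginal participation matches the
    configured probabilities up to Monte-Carlo error by construction
    (latent-threshold sampling).
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    catalog = default_catalog()
    type_ids = catalog.type_ids

    n_total = int(sum(params.n_per_year))
    year = np.repeat(np.asarray(params.years, dtype=int), params.n_per_year)
    year_index = np.repeat(np.arange(len(params.years)), params.n_per_year)

    # demographics
    male = rng.random(n_total) < 0.498
    age = np.round(_truncated_normal(rng, 42.57, 14.39, 18, 70, n_total))
    education = rng.choice([1, 2, 3], size=n_total, p=[0.244, 0.424, 0.332]).astype(int)
    partnered = rng.random(n_total) < 0.632

    # latent involvement and per-type intensity
    load = np.sqrt(params.rho)
    z = rng.normal(size=n_total)
    freq = np.zeros((n_total, len(type_ids)), dtype=float)
    spend = np.full((n_total, len(type_ids)), np.nan)
    th = np.asarray(params.freq_thresholds, dtype=float)
    corr = params.spend_freq_corr
    for j, t in enumerate(type_ids):
        pi = np.atleast_1d(np.asarray(params.participation.get(t, 0.0), dtype=float))
        if pi.size == 1:
            pi = np.repeat(pi, len(params.years))
        pi_row = pi[year_index]
        T = load * z + np.sqrt(1 - params.rho) * rng.normal(size=n_total)
        U = ndtr(T)
        part = (U > 1 - pi_row) & (pi_row > 0)
        # conditional position within the participation tail -> ordinal category
        with np.errstate(divide="ignore", invalid="ignore"):
            V = (U - (1 - pi_row)) / pi_row
        cat = 1 + np.searchsorted(th, V[part], side="left")
        freq[part, j] = np.minimum(cat, 5)
        # usual spending for participants: lognormal coupled to intensity
        n_part = int(part.sum())
        if n_part:
            W = corr * T[part] + np.sqrt(1 - corr**2) * rng.normal(size=n_part)
            amount = np.exp(params.spend_log_mean + params.spend_log_sd * W)
            tail = rng.random(n_part) < params.outlier_rate
            amount[tail] *= params.outlier_scale
            spend[part, j] = np.round(amount, 0)

    participation = (freq >= 1).astype(int)
    breadth = participation.sum(axis=1)
    gambler = breadth >= 1

    # demographic high-risk propensity (exact logistic in the generator)
    eta_demo = (
        params.demo_intercept
        + np.log(params.or_male) * male
        + np.log(params.or_education) * education
        + np.log(params.or_single) * (~partnered)
        + np.log(params.or_age) * age
    )
    p_demo = expit(eta_demo)

    # outcome constructs for the focal type
    jf = type_ids.index(params.focal_type)
    spend0 = np.nan_to_num(spend, nan=0.0)
    constructs = np.column_stack(
        [
            p_demo,
            breadth,
            freq[:, jf],
            np.delete(freq, jf, axis=1).max(axis=1),
            spend0[:, jf],
            np.delete(spend0, jf, axis=1).max(axis=1),
        ]
    )
    beta = params.betas.as_array()
    eta = params.pgsi_intercept + constructs @ beta
    tail = rng.random(n_total) < params.noise_tail_prob
    scale = np.where(tail, params.noise_scale * params.noise_tail_scale, params.noise_scale)
    pgsi = np.clip(np.round(eta + rng.normal(size=n_total) * scale), 0, 27).astype(int)
    pgsi[~gambler] = 0  # non-gamblers score zero by definition

    df = pd.DataFrame(
        {
            "respondent_id": [f"r{i:06d}" for i in range(n_total)],
            "year": year,
            "gender": np.where(male, "male", "female"),
            "age": age.astype(int),
            "education": education,
            "partnered": np.where(partnered, "partnered", "single"),
            "pgsi_raw": pgsi,
        }
    )
    for j, t in enumerate(type_ids):
        df[catalog.get(t).frequency_column] = freq[:, j].astype(int)
    for j, t in enumerate(type_ids):
        df[catalog.get(t).spending_column] = spend[:, j]

    table = SurveyTable(df, catalog, meta={"generator_seed": params.rng_seed})
    if any(v > 0 for v in params.missing_rates.values()):
        table = inject_missing(table, params.missing_rates, seed=params.rng_seed + 1)

    # realized a-paths among last-year gamblers (population quantities from
    # the same latent draws); gambler bookkeeping reflects the *observable*
    # table, i.e. after missingness injection
    x = participation[gambler, jf]
    names = MEDIATOR_COLUMNS
    a_paths = {}
    for k, name in enumerate(names):
        c = constructs[gambler, k]
        if x.size == 0 or x.min() == x.max():
            a_paths[name] = float("nan")
        else:
            a_paths[name] = float(c[x == 1].mean() - c[x == 0].mean())
    b_paths = dict(zip(names, beta))
    observable = (table.participation_matrix().sum(axis=1) >= 1)
    truth = GroundTruth(
        focal_type=params.focal_type,
        a_paths=a_paths,
        b_paths=b_paths,
        indirect={k: a_paths[k] * b_paths[k] for k in names},
        demographic_odds_ratios={
            "male": params.or_male,
            "education": params.or_education,
            "single": params.or_single,
            "age": params.or_age,
        },
        n_gamblers=int(observable.sum()),
        gambler_fraction=float(observable.mean()) if n_total else 0.0,
    )
    return table, truth


def inject_missing(table: SurveyTable, rates: dict, seed: int = 0) -> SurveyTable:
    """Blank cells at the given per-block rates; never removes a row.

    ``rates`` keys: ``frequency`` and ``spending`` (per-cell probabilities
    over the respective columns) and ``demographics`` (per-row probability of
    blanking one randomly chosen demographic field).
    """
    for k, v in rates.items():
        if not (0 <= v <= 1):
            raise ConfigError(f"missing rate {k!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    cat = table.catalog
    n = len(df)

    r = rates.get("frequency", 0.0)
    if r > 0:
        mask = rng.random((n, len(cat))) < r
        block = df[cat.frequency_columns].to_numpy(dtype=float)
        block[mask] = np.nan
        df[cat.frequency_columns] = block
    r = rates.get("spending", 0.0)
    if r > 0:
        mask = rng.random((n, len(cat))) < r
        block = df[cat.spending_columns].to_numpy(dtype=float)
        block[mask] = np.nan
        df[cat.spending_columns] = block
    r = rates.get("demographics", 0.0)
    if r > 0:
        rows = rng.random(n) < r
        cols = rng.integers(0, 4, size=n)
        demo_cols = ["gender", "age", "education", "partnered"]
        for c_idx, col in enumerate(demo_cols):
            hit = rows & (cols == c_idx)
            if hit.any():
                df.loc[hit, col] = np.nan
    return SurveyTable(df, cat, dict(table.meta))


# ---------------------------------------------------------------------------
# planted-path generators
# ---------------------------------------------------------------------------

def simulate_mediation_dataset(
    n: int,
    a,
    b,
    c_prime: float = 0.0,
    p_exposure: float = 0.3,
    noise_sd_m: float = 1.0,
    noise_sd_y: float = 1.0,
    seed: int = 0,
    focal_type: str = "planted",
):
    """Feature-level data with exactly planted paths.

    ``X ~ Bernoulli(p_exposure)``, ``M_j = a_j X + N(0, noise_sd_m)``,
    ``Y = c' X + sum_j b_j M_j + N(0, noise_sd_y)``. Returns a
    :class:`FeatureSet` (mediators named M1..M6 conventionally) plus the dict
    of true indirect effects ``a_j * b_j``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    m = a.size
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_exposure).astype(float)
    M = a[None, :] * x[:, None] + rng.normal(scale=noise_sd_m, size=(n, m))
    y = c_prime * x + M @ b + rng.normal(scale=noise_sd_y, size=n)
    names = MEDIATOR_COLUMNS if m == len(MEDIATOR_COLUMNS) else [f"M{j+1}" for j in range(m)]
    df = pd.DataFrame(M, columns=names)
    df.insert(0, "X", x)
    df["Y"] = y
    fs = FeatureSet(focal_type=focal_type, df=df)
    truth = {name: float(av * bv) for name, av, bv in zip(names, a, b)}
    return fs, truth


def simulate_demographics_outcome(
    n: int,
    or_male: float = 5.026,
    or_education: float = 0.527,
    or_single: float = 1.671,
    or_age: float = 0.951,
    intercept: float = -1.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Demographics plus a binary high-risk outcome from the exact logistic model.

    The default intercept yields a ~5% marginal event rate, chosen for
    identifiability of the odds ratios at moderate sample sizes. Returns a
    DataFrame with columns male, education, single, age, y.
    """
    rng = np.random.default_rng(seed)
    male = (rng.random(n) < 0.498).astype(float)
    education = rng.choice([1.0, 2.0, 3.0], size=n, p=[0.244, 0.424, 0.332])
    single = (rng.random(n) < 0.368).astype(float)
    age = np.round(_truncated_normal(rng, 42.57, 14.39, 18, 70, n))
    eta = (
        intercept
        + np.log(or_male) * male
        + np.log(or_education) * education
        + np.log(or_single) * single
        + np.log(or_age) * age
    )
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {"male": male, "education": education, "single": single, "age": age, "y": y}
    )
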