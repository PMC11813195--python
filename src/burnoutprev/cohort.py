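"""Synthetic physician cohort generator.

Produces, with known ground truth, the three tables the analysis
pipeline consumes:

* survey records — one row per invitation, with 10 item responses when
  the invitation was answered;
* a feature table — per (physician, wave) numeric EHR-use style
  features plus demographics;
* cohort truth — latent burnout score, true response propensity and the
  response draw per invitation, and the cohort-level true prevalence.

The generative model: latent standardized features z follow a
multivariate normal with exchangeable correlation and a physician-level
random intercept shared across waves; observed features are
exponentiated (log-normal, right-skewed like clinical workload counts)
with an optional point mass at zero. Latent burnout is a linear
combination of z plus noise, rescaled to a target mean/SD on the 0-10
scale and clamped to [0, 10]. Response propensity is logistic in z and,
when ``mnar_strength`` is nonzero, in the centered latent burnout score
itself (missingness-not-at-random).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exceptions import ConfigurationError, DomainError
from .scoring import BURNOUT_THRESHOLD, ITEM_COLUMNS, ITEM_MAX, N_ITEMS

RECORDS_CSV = "records.csv"
FEATURES_CSV = "features.csv"
TRUTH_CSV = "truth.csv"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    ``feature_effect_on_response`` is in log-odds per standardized
    feature; ``feature_effect_on_burnout`` is in (pre-rescaling) latent
    units per standardized feature. ``mnar_strength`` is the log-odds of
    response per unit of centered latent burnout; 0 means response is
    missing-at-random given the features.
    """

    n_physicians: int
    n_features: int = 8
    n_waves: int = 2
    frac_invited_one_wave: float = 0.18
    feature_effect_on_response: Sequence[float] = ()
    feature_effect_on_burnout: Sequence[float] = ()
    mnar_strength: float = 0.0
    burnout_mean: float = 3.0
    burnout_sd: float = 1.8
    noise_sd: float = 1.0
    response_intercept: float = 1.4
    feature_corr: float = 0.2
    wave_corr: float = 0.6
    zero_inflation: float = 0.05
    log_mu: float = 3.0
    log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_effect_on_response:
            self.feature_effect_on_response = [0.0] * self.n_features
        if not self.feature_effect_on_burnout:
            self.feature_effect_on_burnout = [0.0] * self.n_features
        self.feature_effect_on_response = np.asarray(
            self.feature_effect_on_response, dtype=float
        )
        self.feature_effect_on_burnout = np.asarray(
            self.feature_effect_on_burnout, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        if self.n_physicians < 1:
            raise ConfigurationError("n_physicians must be >= 1")
        if self.n_waves not in (1, 2):
            raise ConfigurationError("n_waves must be 1 or 2")
        if not 0.0 <= self.frac_invited_one_wave <= 1.0:
            raise ConfigurationError("frac_invited_one_wave must be in [0, 1]")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if len(self.feature_effect_on_response) != self.n_features:
            raise ConfigurationError(
                "feature_effect_on_response length must equal n_features"
            )
        if len(self.feature_effect_on_burnout) != self.n_features:
            raise ConfigurationError(
                "feature_effect_on_burnout length must equal n_features"
            )
        if self.burnout_sd <= 0:
            raise ConfigurationError("burnout_sd must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not -1.0 / max(self.n_features - 1, 1) < self.feature_corr < 1.0:
            raise ConfigurationError("feature_corr outside valid range")
        if not 0.0 <= self.wave_corr <= 1.0:
            raise ConfigurationError("wave_corr must be in [0, 1]")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ConfigurationError("zero_inflation must be in [0, 1)")
        if self.seed is None:
            raise ConfigurationError("seed must be explicit")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["feature_effect_on_response"] = list(
            map(float, d["feature_effect_on_response"])
        )
        d["feature_effect_on_burnout"] = list(
            map(float, d["feature_effect_on_burnout"])
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort.

    ``table`` has one row per invitation with the latent burnout score,
    true response propensity, and the realized response indicator.
    ``true_prevalence`` is the fraction of invitations whose latent
    score is at or above the burnout threshold.
    """

    table: pd.DataFrame
    true_prevalence: float


def example_config(
    n_physicians: int,
    seed: int,
    mnar_strength: float = 0.0,
    **overrides,
) -> GeneratorConfig:
    """A config with strong, negatively aligned feature effects.

    Features that raise burnout lower the odds of response (plus two
    response-only features), so responders systematically under-represent
    burnout — the regime the pipeline is designed to correct.
    """
    burnout_effects = [1.0, 0.8, 0.6, 0.5, -0.4, -0.3, 0.0, 0.0]
    response_effects = [-1.3, -1.0, -0.8, -0.6, 0.5, 0.4, 0.9, -0.7]
    params = dict(
        n_physicians=n_physicians,
        n_features=8,
        feature_effect_on_response=response_effects,
        feature_effect_on_burnout=burnout_effects,
        mnar_strength=mnar_strength,
        burnout_mean=3.0,
        burnout_sd=1.8,
        noise_sd=1.0,
        response_intercept=1.4,
        log_sigma=0.35,
        zero_inflation=0.02,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def invitation_records(
    n_wave1_only: int,
    n_wave2_only: int,
    n_both_waves: int,
    n_responses: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a records table with a given invitation structure.

    Physicians are invited to wave 1 only, wave 2 only, or both waves;
    ``n_responses`` invitations (chosen with the seed) are marked as
    answered (all 10 items filled). Useful for survey-accounting
    fixtures with known counts.
    """
    rows = []
    pid = 0
    for _ in range(n_wave1_only):
        rows.append((f"phys_{pid:05d}", 1))
        pid += 1
    for _ in range(n_wave2_only):
        rows.append((f"phys_{pid:05d}", 2))
        pid += 1
    for _ in range(n_both_waves):
        rows.append((f"phys_{pid:05d}", 1))
        rows.append((f"phys_{pid:05d}", 2))
        pid += 1
    n_inv = len(rows)
    if not 0 <= n_responses <= n_inv:
        raise ConfigurationError("n_responses must be between 0 and the invitation count")
    rng = np.random.default_rng(seed)
    answered = np.zeros(n_inv, dtype=bool)
    answered[rng.choice(n_inv, size=n_responses, replace=False)] = True
    records = pd.DataFrame(rows, columns=["physician_id", "wave"])
    records["invited"] = True
    for col in ITEM_COLUMNS:
        records[col] = np.where(answered, 2.0, np.nan)
    return records


def _exchangeable_chol(k: int, rho: float) -> np.ndarray:
    sigma = np.full((k, k), rho)
    np.fill_diagonal(sigma, 1.0)
    return np.linalg.cholesky(sigma)


def _draw_latent_features(
    rng: np.random.Generator, n: int, n_waves: int, cfg: GeneratorConfig
) -> np.ndarray:
    """Standardized latent features z, shape (n, n_waves, k).

    Marginally each z[i, w] ~ MVN(0, Sigma) with exchangeable
    correlation; corr across waves within physician is wave_corr.
    """
    k = cfg.n_features
    chol = _exchangeable_chol(k, cfg.feature_corr)
    u = rng.standard_normal((n, k)) @ chol.T
    v = rng.standard_normal((n, n_waves, k)) @ chol.T
    a = np.sqrt(cfg.wave_corr)
    b = np.sqrt(1.0 - cfg.wave_corr)
    return a * u[:, None, :] + b * v


def generate_items(latent_score: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw 10 ordinal item values in 0-4 for one latent score.

    Each item is Binomial(4, latent/10), so the expected rescaled mean
    (mean x 2.5) equals the latent score exactly.
    """
    if not 0.0 <= latent_score <= 10.0:
        raise DomainError(f"latent_score {latent_score} outside [0, 10]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.binomial(ITEM_MAX, latent_score / 10.0, size=N_ITEMS)


def generate_cohort(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (records, features, truth) for one synthetic cohort.

    Identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_physicians
    k = config.n_features
    n_waves = config.n_waves

    ids = np.array([f"phys_{i:05d}" for i in range(n)])

    # Invitation structure: a fraction invited to a single wave (split
    # evenly between waves), the rest to every wave.
    n_single = int(round(config.frac_invited_one_wave * n))
    order = rng.permutation(n)
    single = order[:n_single]
    single_wave = np.ones(n, dtype=int)
    if n_waves == 2:
        single_wave[single[1::2]] = 2
    invited = np.ones((n, n_waves), dtype=bool)
    if n_waves == 2:
        for i in single:
            invited[i, 2 - single_wave[i]] = False

    z = _draw_latent_features(rng, n, n_waves, config)

    # Latent burnout: rescale b.z + e so the pre-clamping SD equals
    # burnout_sd while the signal/noise split follows the config.
    b = np.asarray(config.feature_effect_on_burnout, dtype=float)
    sigma = np.full((k, k), config.feature_corr)
    np.fill_diagonal(sigma, 1.0)
    raw_var = float(b @ sigma @ b) + config.noise_sd**2
    noise = config.noise_sd * rng.standard_normal((n, n_waves))
    raw = z @ b + noise
    if raw_var > 0:
        latent = config.burnout_mean + config.burnout_sd * raw / np.sqrt(raw_var)
    else:
        latent = np.full((n, n_waves), config.burnout_mean)
    latent = np.clip(latent, 0.0, 10.0)

    g = np.asarray(config.feature_effect_on_response, dtype=float)
    eta = (
        config.response_intercept
        + z @ g
        + config.mnar_strength * (latent - config.burnout_mean)
    )
    propensity = np.clip(expit(eta), 1e-9, 1.0 - 1e-9)
    responded = rng.uniform(size=(n, n_waves)) < propensity

    # Observed features: log-normal with optional point mass at zero
    # ("no clinical activity" rows).
    obs = np.exp(config.log_mu + config.log_sigma * z)
    if config.zero_inflation > 0:
        zero_mask = rng.uniform(size=obs.shape) < config.zero_inflation
        obs = np.where(zero_mask, 0.0, obs)

    gender = np.where(rng.uniform(size=n) < 0.6, "F", "M")
    age_bin = rng.choice(np.arange(35, 70, 5), size=n)

    rec_rows = []
    feat_rows = []
    truth_rows = []
    feature_names = [f"f_{j:02d}" for j in range(k)]
    for i in range(n):
        for w in range(n_waves):
            if not invited[i, w]:
                continue
            wave = w + 1
            items = (
                generate_items(float(latent[i, w]), rng)
                if responded[i, w]
                else np.full(N_ITEMS, np.nan)
            )
            rec_rows.append((ids[i], wave, True, *items))
            feat_rows.append((ids[i], wave, gender[i], int(age_bin[i]), *obs[i, w]))
            truth_rows.append(
                (
                    ids[i],
                    wave,
                    float(latent[i, w]),
                    float(propensity[i, w]),
                    bool(responded[i, w]),
                )
            )

    records = pd.DataFrame(
        rec_rows, columns=["physician_id", "wave", "invited", *ITEM_COLUMNS]
    )
    features = pd.DataFrame(
        feat_rows,
        columns=["physician_id", "wave", "gender", "age_bin", *feature_names],
    )
    truth_table = pd.DataFrame(
        truth_rows,
        columns=["physician_id", "wave", "latent", "propensity", "responded"],
    )
    truth = CohortTruth(
        table=truth_table,
        true_prevalence=float((truth_table["latent"] >= BURNOUT_THRESHOLD).mean()),
    )
    return records, features, truth


def write_cohort(
    records: pd.DataFrame,
    features: pd.DataFrame,
    truth: Optional[CohortTruth],
    outdir: str | Path,
) -> None:
    """Write cohort tables as CSV (missing items as empty cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / RECORDS_CSV, index=False)
    features.to_csv(outdir / FEATURES_CSV, index=False)
    if truth is not None:
        t = truth.table.copy()
        t["true_prevalence"] = truth.true_prevalence
        t.to_csv(outdir / TRUTH_CSV, index=False)


def read_cohort(
    indir: str | Path,
) -> Tuple[pd.DataFrame, pd.DataFrame, Optional[CohortTruth]]:
    """Read cohort tables written by :func:`write_cohort`."""
    indir = Path(indir)
    records = pd.read_csv(indir / RECORDS_CSV)
    features = pd.read_csv(indir / FEATURES_CSV)
    truth = None
    tpath = indir / TRUTH_CSV
    if tpath.exists():
        t = pd.read_csv(tpath)
        prev = float(t.pop("true_prevalence").iloc[0])
        truth = CohortTruth(table=t, true_prevalence=prev)
    return records, features, truth
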