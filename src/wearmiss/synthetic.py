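"""Synthetic cohorts emulating a multi-night wearable sleep study.

The generator draws a complete 5-night sleep record for every participant,
draws per-participant covariates from configurable marginals, and then
deletes whole nights according to a chosen missingness mechanism:

* ``NONE`` — no deletion;
* ``MCAR`` — every night deleted independently with constant probability;
* ``MAR``  — deletion probability is inverse-logit of an intercept, a
  per-night slope, and an employment effect; the default coefficients are
  the fitted values of the study's final GEE model (intercept −1.8546,
  night slope 0.2554, employment 0.6671), so the defaults generate from the
  mechanism the study inferred;
* ``MNAR`` — the MAR logit plus a term in the night's own (to-be-deleted)
  standardized total sleep, for operating-characteristic studies of what the
  diagnostic pipeline can and cannot detect.

Deletion always removes all five stage durations together, preserving the
whole-night missingness structure of device non-wear.  The heart-rate
presence indicator refers to the day before the night and is keyed to the
*previous* night's observedness: consecutive-night non-wear leaves no
heart-rate trace the next day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import LongitudinalDataset, SLEEP_STAGES, make_dataset

MECHANISMS = ("MCAR", "MAR", "MNAR", "NONE")

#: Default per-stage duration marginals, seconds, (mean, sd) on the natural
#: scale of an independent lognormal per stage.  Calibrated to plausible
#: adult sleep architecture (roughly 7 h total: mostly light sleep, about an
#: hour and a half each of deep and REM, some wake after sleep onset).
DEFAULT_STAGE_PARAMS: dict[str, tuple[float, float]] = {
    "deep_s": (4700.0, 1600.0),
    "light_s": (14000.0, 3500.0),
    "rem_s": (5800.0, 2200.0),
    "awake_s": (1800.0, 1200.0),
    "unmeasurable_s": (600.0, 500.0),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study's shape: 299 participants x 5
    nights, a 32% employment rate, and MAR deletion from the study's fitted
    missingness model.
    """

    n_participants: int = 299
    n_nights: int = 5
    mechanism: str = "MAR"
    mcar_prob: float = 0.30
    #: (intercept, per-night slope, employment effect) on the logit scale.
    mar_coefficients: tuple[float, float, float] = (-1.8546, 0.2554, 0.6671)
    #: Effect of the night's own standardized total sleep on the missingness
    #: logit (only used under MNAR).
    mnar_coefficient: float = 1.0
    employment_rate: float = 0.32
    married_rate: float = 0.40
    #: P(household size = 1 + k), k = 0, 1, ...
    household_size_probs: tuple[float, ...] = (0.15, 0.25, 0.25, 0.18, 0.10, 0.07)
    #: Ordinal education levels 1..len (1 = some primary ... 3 = completed
    #: secondary; 8% completed secondary in the emulated cohort).
    education_probs: tuple[float, ...] = (0.50, 0.42, 0.08)
    #: P(number of children = k); derived from the emulated cohort's
    #: nights-at-risk by children (570/625/275/25 nights over 299 women).
    children_probs: tuple[float, ...] = (0.381, 0.418, 0.184, 0.017)
    sites: tuple[str, ...] = ("Banda", "Bwaise", "Makindye")
    stage_params: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PARAMS))
    #: Log-scale multipliers linking covariates to sleep duration (the
    #: socioeconomic-factors-affect-sleep relationship that motivates the
    #: covariate set): each unit of the covariate multiplies every stage
    #: mean by exp(effect).  Defaults: employment shortens sleep ~8%, each
    #: child ~3%.
    covariate_sleep_effects: dict = field(
        default_factory=lambda: {"employed": -0.08, "n_children": -0.03}
    )
    #: Probability an observed night has any unmeasurable seconds at all
    #: (zeros are common in that category).
    unmeasurable_nonzero_prob: float = 0.30
    #: P(heart-rate present | previous night observed) and | previous night
    #: missing.  Night 1 uses the "observed" probability.
    hr_prob_worn: float = 0.95
    hr_prob_nonwear: float = 0.30
    #: Probability a participant loses all nights independently of
    #: covariates (device-failure emulation; off by default because the MAR
    #: default coefficients already describe the full missingness process).
    complete_case_prob: float = 0.0
    #: Plausible envelope for total sleep duration, seconds (1 h .. 12.5 h).
    total_sleep_bounds: tuple[float, float] = (3600.0, 45000.0)
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        for name in ("mcar_prob", "employment_rate", "married_rate",
                     "unmeasurable_nonzero_prob", "hr_prob_worn",
                     "hr_prob_nonwear", "complete_case_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def true_mechanism(config: GeneratorConfig) -> str:
    """The configured ground-truth mechanism label (for recovery tests)."""
    config.validate()
    return config.mechanism


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    # moment-match a lognormal to the requested natural-scale mean/sd
    var = sd**2
    sigma2 = np.log(1.0 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    hs = np.asarray(cfg.household_size_probs, float)
    edu = np.asarray(cfg.education_probs, float)
    kid = np.asarray(cfg.children_probs, float)
    # sites as equal as the cohort size allows, in order
    base, extra = divmod(n, len(cfg.sites))
    site = np.repeat(cfg.sites, [base + (i < extra) for i in range(len(cfg.sites))])
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "household_size": 1 + rng.choice(len(hs), size=n, p=hs / hs.sum()),
            "education_level": 1 + rng.choice(len(edu), size=n, p=edu / edu.sum()),
            "employed": rng.binomial(1, cfg.employment_rate, size=n),
            "married": rng.binomial(1, cfg.married_rate, size=n),
            "n_children": rng.choice(len(kid), size=n, p=kid / kid.sum()),
            "site": site,
        }
    )


def _sleep_multiplier(cfg: GeneratorConfig, cov: pd.DataFrame) -> np.ndarray:
    """Per-participant multiplier on stage means from covariate effects."""
    log_m = np.zeros(len(cov))
    for name, effect in cfg.covariate_sleep_effects.items():
        log_m += effect * cov[name].to_numpy(dtype=float)
    return np.exp(log_m)


def _draw_sleep(
    cfg: GeneratorConfig, rng: np.random.Generator, multiplier: np.ndarray
) -> pd.DataFrame:
    """Complete stage durations for every participant-night, pre-deletion."""
    n = cfg.n_participants * cfg.n_nights
    lo, hi = cfg.total_sleep_bounds
    mult = np.repeat(multiplier, cfg.n_nights)

    def draw(rows: np.ndarray) -> dict:
        cols = {}
        for stage in SLEEP_STAGES:
            mean, sd = cfg.stage_params[stage]
            base = _lognormal(rng, mean, sd, rows.size)
            cols[stage] = base * mult[rows]
        cols["unmeasurable_s"] = np.where(
            rng.random(rows.size) < cfg.unmeasurable_nonzero_prob,
            cols["unmeasurable_s"],
            0.0,
        )
        return cols

    df = pd.DataFrame(draw(np.arange(n)))
    # resample the rare night whose total falls outside the plausible envelope
    for _ in range(100):
        total = df[["deep_s", "light_s", "rem_s", "unmeasurable_s"]].sum(axis=1)
        bad = np.flatnonzero((total < lo) | (total > hi))
        if bad.size == 0:
            break
        redraw = draw(bad)
        for stage in SLEEP_STAGES:
            df.loc[df.index[bad], stage] = redraw[stage]
    return df.round(0)


def _missingness_probability(
    cfg: GeneratorConfig,
    night_index: np.ndarray,
    employed: np.ndarray,
    std_total_sleep: np.ndarray,
) -> np.ndarray:
    if cfg.mechanism == "NONE":
        return np.zeros_like(std_total_sleep, dtype=float)
    if cfg.mechanism == "MCAR":
        return np.full(std_total_sleep.shape, cfg.mcar_prob, dtype=float)
    b0, b_night, b_emp = cfg.mar_coefficients
    eta = b0 + b_night * night_index + b_emp * employed
    if cfg.mechanism == "MNAR":
        eta = eta + cfg.mnar_coefficient * std_total_sleep
    return expit(eta)


def generate(config: GeneratorConfig) -> LongitudinalDataset:
    """Generate a synthetic longitudinal sleep dataset.

    One seed governs covariates, sleep values, and deletion through
    independent substreams, so changing (say) the deletion mechanism leaves
    the underlying complete data untouched.
    """
    cfg = config.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_cov, rng_sleep, rng_del = (np.random.default_rng(s) for s in ss.spawn(3))

    cov = _draw_covariates(cfg, rng_cov)
    sleep = _draw_sleep(cfg, rng_sleep, _sleep_multiplier(cfg, cov))

    n, t = cfg.n_participants, cfg.n_nights
    night_index = np.tile(np.arange(1, t + 1), n)
    pid = np.repeat(cov["participant_id"].to_numpy(), t)
    employed = np.repeat(cov["employed"].to_numpy(), t)

    total = sleep[["deep_s", "light_s", "rem_s", "unmeasurable_s"]].sum(axis=1)
    std_total = ((total - total.mean()) / total.std(ddof=0)).to_numpy()

    p_miss = _missingness_probability(cfg, night_index, employed, std_total)
    miss = rng_del.random(n * t) < p_miss
    if cfg.complete_case_prob > 0:
        lost = rng_del.random(n) < cfg.complete_case_prob
        miss |= np.repeat(lost, t)

    # heart-rate presence for the *prior* day, keyed to previous-night wear
    miss_mat = miss.reshape(n, t)
    prev_missing = np.concatenate(
        [np.zeros((n, 1), dtype=bool), miss_mat[:, :-1]], axis=1
    ).ravel()
    p_hr = np.where(prev_missing, cfg.hr_prob_nonwear, cfg.hr_prob_worn)
    hr = (rng_del.random(n * t) < p_hr).astype(np.int8)

    nights = sleep.copy()
    nights.loc[miss, SLEEP_STAGES] = np.nan
    nights.insert(0, "participant_id", pid)
    nights.insert(1, "night_index", night_index)
    nights["hr_present_prior_day"] = hr

    ds = make_dataset(nights, cov, n_nights=t)
    ds.meta = {"generator_config": cfg.to_dict(), "mechanism": cfg.mechanism}
    return ds


def from_night_margins(
    night_missing_counts=(67, 79, 81, 88, 140),
    n_participants: int = 299,
    sites: tuple[str, ...] = ("Banda", "Bwaise", "Makindye"),
) -> LongitudinalDataset:
    """Deterministic fixture whose per-night missing counts are exactly as given.

    Night *t* is missing for the first ``night_missing_counts[t-1]``
    participants, so the overall missing count is the sum of the margins
    (455 of 1495 with the defaults, matching the emulated study's night
    rows).  Synthetic: observed nights carry fixed plausible stage values;
    covariates are constant placeholders.
    """
    counts = list(night_missing_counts)
    t = len(counts)
    base, extra = divmod(n_participants, len(sites))
    site = np.repeat(sites, [base + (i < extra) for i in range(len(sites))])
    cov = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n_participants)],
            "household_size": 2,
            "education_level": 1,
            "employed": 0,
            "married": 0,
            "n_children": 0,
            "site": site,
        }
    )
    stage_values = {"deep_s": 4700.0, "light_s": 14000.0, "rem_s": 5800.0,
                    "awake_s": 1800.0, "unmeasurable_s": 0.0}
    rows = []
    for i in range(n_participants):
        for night in range(1, t + 1):
            miss = i < counts[night - 1]
            rec = {"participant_id": f"P{i:04d}", "night_index": night,
                   "hr_present_prior_day": 1}
            for k, v in stage_values.items():
                rec[k] = np.nan if miss else v
            rows.append(rec)
    return make_dataset(pd.DataFrame(rows), cov, n_nights=t)
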