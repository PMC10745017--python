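"""Synthetic infant-bronchiolitis cohorts from a latent-severity model.

No patient-level data accompany the study this pipeline emulates, so every
stage is exercised on cohorts drawn from a single-factor generative model:

1.  Age (months) is log-normal; a standard-normal age deviate ``u`` also
    feeds severity.
2.  Latent severity ``z = (c_age * u + eps) / sqrt(c_age^2 + 1)`` with
    ``eps ~ N(0,1)`` and ``c_age < 0`` (younger infants run sicker);
    ``z`` is standard normal marginally.
3.  Each Wood-Downes-Ferres item is an ordinal cut of ``lambda * z + e_i``
    at per-item cutpoints; the respiratory- and heart-rate items are then
    realised as raw measurements drawn uniformly inside the selected band.
4.  Each lung-ultrasound finding is Bernoulli with logit ``alpha + beta*z``;
    all intercepts are kept <= 0 so that raising any severity slope can
    only raise that finding's prevalence.
5.  A noisy copy of severity, ``o = (z + s*eta)/sqrt(1+s^2)`` (standard
    normal marginally), crosses ordered thresholds to produce the nested
    outcomes: admission, any oxygen therapy, high-flow-or-higher support
    tier, nCPAP/nBiPAP/MV tier.  Thresholds are normal quantiles of the
    target prevalences, so large-cohort marginals match by construction.
6.  Patients on a support tier receive an event time from an exponential
    hazard truncated at follow-up; everyone else is event-free.

Draws happen in the fixed order above, vectorised per step, from one
``numpy.random.default_rng(seed)`` stream, so a given config + seed yields
a byte-identical cohort CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .records import PatientRecord
from .scoring import LUSFindings, ValidationError, WDFItems

__all__ = ["CohortModelConfig", "default_paper_config", "generate_cohort"]

# WDF item order is the draw order.
_WDF_ITEMS = ("wheezing", "retractions", "respiratory_rate", "heart_rate",
              "inspiratory_breath_sounds", "cyanosis")
_LUS_ITEMS = ("blines_gt3", "confluent_blines", "consolidation_small",
              "consolidation_large")
# Raw-measurement ranges per band level (inclusive), sampled uniformly.
_RR_BANDS = [(16, 30), (31, 45), (46, 60), (61, 75)]
_HR_BANDS = [(90, 120), (121, 170)]


@dataclass(frozen=True)
class CohortModelConfig:
    """Parameters of the latent-severity cohort model.

    Defaults (see :func:`default_paper_config`) are calibrated once, as
    packaged constants, to the study cohort's marginals: n = 50, 60% male,
    median age 2.2 months with 22% under 1 month, median WDF 4.5, 66%
    admitted, 42% on any oxygen, 36% on high-flow-or-higher support and
    16% reaching nCPAP/nBiPAP/MV, with LUSCAB stochastically larger in
    higher support tiers.
    """

    n: int = 50
    seed: int = 0
    age_lognormal_mu_sigma: tuple[float, float] = (0.7793, 1.0092)
    p_male: float = 0.60
    severity_age_coefficient: float = -0.7  # on standardized log-age; negative = younger sicker
    wdf_severity_loading: float = 0.45
    wdf_item_cutpoints: dict = field(
        default_factory=lambda: {
            "wheezing": (-0.55, 0.6, 1.8),
            "retractions": (-0.55, 0.6, 1.8),
            "respiratory_rate": (-0.55, 0.6, 1.8),
            "heart_rate": (0.55,),
            "inspiratory_breath_sounds": (-0.55, 0.6, 1.8),
            "cyanosis": (2.1,),
        }
    )
    lus_severity_loadings: dict = field(
        default_factory=lambda: {
            "blines_gt3": (0.0, 0.6),
            "confluent_blines": (-0.8, 0.6),
            "consolidation_small": (-0.8, 0.5),
            "consolidation_large": (-2.0, 1.0),
        }
    )
    outcome_thresholds: dict = field(
        default_factory=lambda: {
            "admission": -0.412463,  # Phi^-1(0.34): 66% admitted
            "oxygen": 0.201893,  # Phi^-1(0.58): 42% any oxygen
            "hfnc_tier": 0.358459,  # Phi^-1(0.64): 36% HFNC or higher
            "ncpap_tier": 0.994458,  # Phi^-1(0.84): 16% nCPAP/nBiPAP/MV
        }
    )
    outcome_noise_sd: float = 0.65
    sao2_mean: float = 95.9
    sao2_sd: float = 2.5
    sao2_severity_slope: float = 0.5  # SaO2 points lost per severity SD
    time_to_support_rate_per_h: float = 0.1
    followup_h: float = 96.0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ValidationError(f"n must be a positive integer, got {self.n!r}")
        if not 0 <= self.p_male <= 1:
            raise ValidationError(f"p_male must be in [0, 1], got {self.p_male}")
        mu, sigma = self.age_lognormal_mu_sigma
        if sigma <= 0:
            raise ValidationError(f"age log-normal sigma must be > 0, got {sigma}")
        t = self.outcome_thresholds
        order = [t["admission"], t["oxygen"], t["hfnc_tier"], t["ncpap_tier"]]
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValidationError(
                "outcome thresholds must be ordered admission <= oxygen <= hfnc <= ncpap"
            )
        for item in _WDF_ITEMS:
            cuts = self.wdf_item_cutpoints[item]
            if any(a >= b for a, b in zip(cuts, cuts[1:])):
                raise ValidationError(f"cutpoints for {item} must be strictly increasing")
        for finding in _LUS_ITEMS:
            alpha, beta = self.lus_severity_loadings[finding]
            if beta < 0:
                raise ValidationError(f"severity slope for {finding} must be >= 0")
        if self.outcome_noise_sd < 0:
            raise ValidationError("outcome_noise_sd must be >= 0")
        if self.time_to_support_rate_per_h <= 0:
            raise ValidationError("time_to_support_rate_per_h must be > 0")
        if self.followup_h <= 0:
            raise ValidationError("followup_h must be > 0")
        if self.sao2_sd < 0:
            raise ValidationError("sao2_sd must be >= 0")

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortModelConfig":
        raw = json.loads(text)
        raw["age_lognormal_mu_sigma"] = tuple(raw["age_lognormal_mu_sigma"])
        raw["wdf_item_cutpoints"] = {k: tuple(v) for k, v in raw["wdf_item_cutpoints"].items()}
        raw["lus_severity_loadings"] = {
            k: tuple(v) for k, v in raw["lus_severity_loadings"].items()
        }
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def default_paper_config(n: int = 50, seed: int = 0) -> CohortModelConfig:
    """The packaged configuration calibrated to the study cohort's marginals."""
    return CohortModelConfig(n=n, seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _band_value(levels: np.ndarray, bands, u: np.ndarray) -> np.ndarray:
    lo = np.array([bands[k][0] for k in levels])
    hi = np.array([bands[k][1] for k in levels])
    return lo + np.floor(u * (hi - lo + 1)).astype(int)


def generate_cohort(config: CohortModelConfig | None = None, seed: int | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic given config + seed.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or default_paper_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    mu, sigma = config.age_lognormal_mu_sigma

    # 1. age
    u_age = rng.standard_normal(n)
    age = np.round(np.exp(mu + sigma * u_age), 2)
    # 2. sex
    male = rng.random(n) < config.p_male
    # 3. latent severity, standard normal marginally
    c = config.severity_age_coefficient
    eps = rng.standard_normal(n)
    z = (c * u_age + eps) / np.hypot(c, 1.0)
    # 4. WDF ordinal items
    lam = config.wdf_severity_loading
    levels = {}
    for item in _WDF_ITEMS:
        e = rng.standard_normal(n)
        latent = lam * z + e
        cuts = np.asarray(config.wdf_item_cutpoints[item])
        levels[item] = (latent[:, None] > cuts[None, :]).sum(axis=1)
    # 5. raw rates inside the selected band
    rr = _band_value(levels["respiratory_rate"], _RR_BANDS, rng.random(n))
    hr = _band_value(levels["heart_rate"], _HR_BANDS, rng.random(n))
    # 6. LUS findings
    findings = {}
    for item in _LUS_ITEMS:
        alpha, beta = config.lus_severity_loadings[item]
        findings[item] = rng.random(n) < _sigmoid(alpha + beta * z)
    # 7. room-air saturation
    sao2 = np.round(
        np.clip(
            config.sao2_mean - config.sao2_severity_slope * z + config.sao2_sd * rng.standard_normal(n),
            80.0,
            100.0,
        ),
        1,
    )
    # 8. outcomes from a noisy severity copy
    s = config.outcome_noise_sd
    eta = rng.standard_normal(n)
    o = (z + s * eta) / np.hypot(s, 1.0)
    t = config.outcome_thresholds
    admitted = o > t["admission"]
    oxygen = o > t["oxygen"]
    ncpap = o > t["ncpap_tier"]
    hfnc_or_higher = o > t["hfnc_tier"]
    tier = np.where(ncpap, "ncpap_bipap_mv", np.where(hfnc_or_higher, "lfnc_hfnc", "none"))
    # 9. time to support, truncated exponential on (0, followup]
    rate, followup = config.time_to_support_rate_per_h, config.followup_h
    u_t = rng.random(n)
    trunc_mass = 1.0 - np.exp(-rate * followup)
    times = np.round(-np.log1p(-u_t * trunc_mass) / rate, 2)

    records = []
    width = len(str(n))
    for i in range(n):
        wdf = WDFItems(
            wheezing=int(levels["wheezing"][i]),
            retractions=int(levels["retractions"][i]),
            respiratory_rate=int(rr[i]),
            heart_rate=int(hr[i]),
            inspiratory_breath_sounds=int(levels["inspiratory_breath_sounds"][i]),
            cyanosis=bool(levels["cyanosis"][i] > 0),
        )
        lus = LUSFindings(
            blines_gt3_bilateral_anterior=bool(findings["blines_gt3"][i]),
            confluent_blines_bilateral_anterior=bool(findings["confluent_blines"][i]),
            posterior_consolidation_small=bool(findings["consolidation_small"][i]),
            posterior_consolidation_large=bool(findings["consolidation_large"][i]),
        )
        on_support = tier[i] != "none"
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                age_months=float(age[i]),
                sex="male" if male[i] else "female",
                sao2_room_air=float(sao2[i]),
                lus=lus,
                admitted=bool(admitted[i]),
                oxygen_therapy=bool(oxygen[i]),
                support_tier=str(tier[i]),
                followup_h=float(followup),
                time_to_support_h=float(times[i]) if on_support else None,
                wdf=wdf,
            )
        )
    return records
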