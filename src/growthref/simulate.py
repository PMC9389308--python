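"""Synthetic growth references and cohorts.

No copyrighted reference tables ship with the package, and the motivating
cohort (children with Down syndrome measured against both a population
chart and a condition-specific chart) is not publicly deposited.  This
module therefore generates:

* a smooth analytic base LMS reference per measure and sex (a logistic-like
  median curve over 0–18 y at 0.1-y knots, L = 1, constant S), standing in
  for a population chart;
* a "specialized" partner chart obtained by shifting the base median by a
  fixed SDS offset delta and scaling S, so that a child at specialized-z 0
  sits at population-z delta exactly when the S ratio is 1;
* cohorts of children whose true scores are drawn from a known latent
  distribution against a chosen truth chart, with covariates matching the
  motivating study's marginals (54% boys, birth weight 2898 +/- 513 g,
  gestation 37.7 +/- 2.17 wk, 78% breastfed, 64% on L-thyroxine).

Because the truth is known, every downstream stage — standardization, band
classification, dual-chart discordance, subgroup contrasts — can be checked
by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import lms
from .references import LMSReference, ReferenceSet

__all__ = [
    "SimulationConfig",
    "make_base_reference",
    "make_base_chart",
    "make_reference_pair",
    "make_chart_pair",
    "simulate_cohort",
]

#: analytic median-curve parameters per (measure, sex):
#: value at birth, adult plateau, logistic midpoint (y), logistic scale (y)
_MEDIAN_SHAPES = {
    ("height", "male"): (50.0, 177.0, 9.5, 4.5),
    ("height", "female"): (50.0, 164.0, 8.5, 4.0),
    ("weight", "male"): (3.5, 70.0, 12.5, 2.8),
    ("weight", "female"): (3.4, 58.0, 11.5, 2.6),
}

#: constant coefficient of variation per measure (height is tightly
#: regulated; weight is the most dispersed)
_S_DEFAULT = {"height": 0.04, "weight": 0.12}


def _median_curve(ages: np.ndarray, v0: float, v_adult: float,
                  midpoint: float, scale: float) -> np.ndarray:
    """Monotone logistic-like growth from v0 at age 0 to v_adult."""
    raw = 1.0 / (1.0 + np.exp(-(ages - midpoint) / scale))
    raw0 = 1.0 / (1.0 + np.exp(midpoint / scale))
    frac = (raw - raw0) / (1.0 - raw0)
    return v0 + (v_adult - v0) * frac


def make_base_reference(measure: str, sex: str, *, rho: float = 0.7,
                        age_step: float = 0.1, label: str = "standard"
                        ) -> LMSReference:
    """Analytic base LMS reference over ages 0–18 y.

    L is identically 1 and S constant per measure.  The BMI reference is
    made consistent with the weight and height curves: its median is
    M_w / (M_h/100)^2 and its S follows the delta-method propagation
    sqrt(S_w^2 + 4 S_h^2 - 4 rho S_w S_h) for latent weight/height scores
    correlated at ``rho``, so that BMI derived from simulated weight and
    height is approximately standard normal against it.
    """
    ages = np.round(np.arange(0.0, 18.0 + age_step / 2, age_step), 10)
    if measure == "bmi":
        m_w = _median_curve(ages, *_MEDIAN_SHAPES[("weight", sex)])
        m_h = _median_curve(ages, *_MEDIAN_SHAPES[("height", sex)])
        M = m_w / (m_h / 100.0) ** 2
        s_w, s_h = _S_DEFAULT["weight"], _S_DEFAULT["height"]
        S = float(np.sqrt(s_w**2 + 4 * s_h**2 - 4 * rho * s_w * s_h))
    else:
        M = _median_curve(ages, *_MEDIAN_SHAPES[(measure, sex)])
        S = _S_DEFAULT[measure]
    return LMSReference(measure=measure, sex=sex, ages=ages,
                        L=np.ones_like(ages), M=M,
                        S=np.full_like(ages, S), label=label)


def make_base_chart(label: str = "standard", rho: float = 0.7) -> ReferenceSet:
    """Base chart: one analytic reference per measure and sex."""
    refs = [make_base_reference(m, s, rho=rho, label=label)
            for m in ("weight", "height", "bmi") for s in ("female", "male")]
    return ReferenceSet(refs, label=label)


def make_reference_pair(base: LMSReference, delta: float,
                        sd_ratio: float = 1.0,
                        specialized_label: str = "specialized"
                        ) -> tuple[LMSReference, LMSReference]:
    """Derive a (standard, specialized) reference pair from a base table.

    The specialized chart's median at every tabulated age is the base
    value lying ``delta`` SDS from the base median
    (``M_spec = lms_value(delta, L, M, S)``) and its S is ``S * sd_ratio``
    (L unchanged).  Requires ``1 + L*S*delta > 0`` at every age.
    """
    arg = 1.0 + base.L * base.S * delta
    bad = np.flatnonzero(arg <= 0)
    if bad.size:
        raise ValueError(
            f"1 + L*S*delta <= 0 at age {base.ages[bad[0]]:g}; "
            f"delta={delta} is outside the Box-Cox domain")
    if sd_ratio <= 0:
        raise ValueError("sd_ratio must be positive")
    m_spec = lms.lms_value(np.full_like(base.ages, float(delta)),
                           base.L, base.M, base.S)
    specialized = LMSReference(measure=base.measure, sex=base.sex,
                               ages=base.ages.copy(), L=base.L.copy(),
                               M=np.atleast_1d(m_spec),
                               S=base.S * sd_ratio, label=specialized_label)
    return base, specialized


def make_chart_pair(delta: dict[str, float], sd_ratio: dict[str, float] | None = None,
                    rho: float = 0.7) -> tuple[ReferenceSet, ReferenceSet]:
    """Build a (standard, specialized) chart pair with per-measure offsets."""
    sd_ratio = sd_ratio or {}
    std_refs, spec_refs = [], []
    for m in ("weight", "height", "bmi"):
        for s in ("female", "male"):
            base = make_base_reference(m, s, rho=rho, label="standard")
            _, spec = make_reference_pair(base, delta.get(m, 0.0),
                                          sd_ratio.get(m, 1.0))
            std_refs.append(base)
            spec_refs.append(spec)
    return (ReferenceSet(std_refs, label="standard"),
            ReferenceSet(spec_refs, label="specialized"))


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the motivating study's reported marginals; the
    specialized-chart offsets ``delta`` are scenario parameters realizing
    the qualitative premise that the condition-specific population is
    shifted down relative to the general one.
    """

    n: int = 400
    seed: int = 0
    male_fraction: float = 0.54
    age_min: float = 0.1          # log-uniform age distribution, years
    age_max: float = 18.0
    truth: str = "specialized"    # chart the latent scores are standard under
    delta: dict = field(default_factory=lambda:
                        {"weight": -1.2, "height": -1.5, "bmi": -0.5})
    sd_ratio: dict = field(default_factory=dict)
    rho: float = 0.7              # latent weight-height z correlation
    birth_weight_mean_g: float = 2898.0
    birth_weight_sd_g: float = 513.0
    gestation_mean_wk: float = 37.7
    gestation_sd_wk: float = 2.17
    breastfed_prob: float = 0.78
    l_thyroxine_prob: float = 0.64
    height_z_sd_treated: float = 0.8
    height_z_sd_untreated: float = 1.2
    couple_l_thyroxine: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("male_fraction", "breastfed_prob", "l_thyroxine_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("birth_weight_sd_g", "gestation_sd_wk",
                     "height_z_sd_treated", "height_z_sd_untreated"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (-1, 1)")
        if not 0 <= self.age_min < self.age_max:
            raise ValueError("need 0 <= age_min < age_max")
        if self.truth not in ("standard", "specialized"):
            raise ValueError("truth must be 'standard' or 'specialized'")

    def to_dict(self) -> dict:
        return asdict(self)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by rejection; bounds are wide so this converges immediately."""
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def simulate_cohort(config: SimulationConfig,
                    chart_standard: ReferenceSet,
                    chart_specialized: ReferenceSet
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort against a truth chart; return (cohort, truth).

    Per child: sex ~ Bernoulli(male_fraction); age log-uniform on
    [age_min, age_max]; latent (z_height, z_weight) bivariate standard
    normal with correlation rho; weight and height realized through the
    inverse LMS transform of the truth chart at the child's (sex, age);
    BMI derived as weight/(height in m)^2.  Covariates are drawn from the
    configured marginals (birth weight truncated positive, gestation
    truncated to [22, 43] weeks).  With ``couple_l_thyroxine`` the latent
    height z of treated/untreated children has SD
    ``height_z_sd_treated``/``height_z_sd_untreated`` instead of 1.

    The truth table carries the latent z's plus the derived BMI z against
    the truth chart's own BMI reference, for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    truth_chart = (chart_specialized if config.truth == "specialized"
                   else chart_standard)
    n = config.n
    male = rng.random(n) < config.male_fraction
    sexes = np.where(male, "male", "female")
    ages = np.exp(rng.uniform(np.log(config.age_min), np.log(config.age_max), n))

    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z_height, z_weight = latent[:, 0].copy(), latent[:, 1].copy()

    l_thyroxine = rng.random(n) < config.l_thyroxine_prob
    if config.couple_l_thyroxine:
        scale = np.where(l_thyroxine, config.height_z_sd_treated,
                         config.height_z_sd_untreated)
        z_height = z_height * scale

    weight = np.empty(n)
    height = np.empty(n)
    for sex in ("female", "male"):
        mask = sexes == sex
        if not mask.any():
            continue
        for measure, z, out in (("weight", z_weight, weight),
                                ("height", z_height, height)):
            ref = truth_chart.get(measure, sex)
            L, M, S = ref.interpolate(ages[mask])
            out[mask] = lms.lms_value(z[mask], L, M, S)

    bmi_values = lms.bmi(weight, height / 100.0)
    z_bmi = np.empty(n)
    for sex in ("female", "male"):
        mask = sexes == sex
        if not mask.any():
            continue
        ref = truth_chart.get("bmi", sex)
        L, M, S = ref.interpolate(ages[mask])
        z_bmi[mask] = lms.lms_z(bmi_values[mask], L, M, S)

    birth_weight = _truncated_normal(rng, config.birth_weight_mean_g,
                                     config.birth_weight_sd_g, 0.0, np.inf, n)
    gestation = _truncated_normal(rng, config.gestation_mean_wk,
                                  config.gestation_sd_wk, 22.0, 43.0, n)
    breastfed = rng.random(n) < config.breastfed_prob
    breastfed_months = np.where(
        breastfed, np.round(np.exp(rng.normal(np.log(9.0), 0.6, n)), 1), np.nan)

    ids = [f"c{i:05d}" for i in range(n)]
    cohort = pd.DataFrame({
        "id": ids,
        "sex": sexes,
        "age_years": ages,
        "weight_kg": weight,
        "height_cm": height,
        "birth_weight_g": np.round(birth_weight, 0),
        "gestational_age_wk": np.round(gestation, 1),
        "breastfed": breastfed,
        "breastfed_months": breastfed_months,
        "l_thyroxine": l_thyroxine,
    })
    cohort["bmi"] = lms.bmi(cohort["weight_kg"].to_numpy(),
                            cohort["height_cm"].to_numpy() / 100.0)
    truth = pd.DataFrame({
        "id": ids,
        "truth_reference": truth_chart.label,
        "z_weight": z_weight,
        "z_height": z_height,
        "z_bmi": z_bmi,
    })
    return cohort, truth


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort in the delimited format the pipeline reads."""
    out = cohort.drop(columns=["bmi"], errors="ignore").copy()
    # measurement precision of the emitted records: 0.01 kg / 0.1 cm
    out["age_years"] = out["age_years"].round(4)
    out["weight_kg"] = out["weight_kg"].round(2)
    out["height_cm"] = out["height_cm"].round(1)
    for col in ("breastfed", "l_thyroxine"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
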