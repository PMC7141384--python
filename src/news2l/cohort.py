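"""Seeded synthetic prehospital syncope cohorts with a two-class structure.

Real prehospital cohorts of this kind are summarised in publications only as
per-class medians and interquartile ranges (survivors vs 48-hour
non-survivors) plus outcome rates; the patient-level data are not deposited.
This module turns those summaries into a generative model so that every
stage of the scoring and accuracy pipeline can be exercised end to end:

* each vital sign, lactate and age is sampled from a class-conditional
  distribution fitted to the published median and quartiles
  (:func:`fit_from_quantiles`);
* the NEWS2 total is never sampled — it is computed from the generated
  vitals through the scoring rubric, so the deterministic score/vital
  relationship is preserved and the published NEWS2 medians act as a
  calibration check, not a sampling target;
* binary outcomes (48-h death, prehospital advanced life support, ICU) are
  drawn from the class mixture with the published conditional rates.

Distribution families
---------------------
``lognormal``
    A three-parameter (shifted) lognormal, automatically reflected for
    left-skewed quantile triples.  The shift is chosen so the three target
    quantiles become exactly log-symmetric, which makes the fit closed-form
    and exact.
``truncated-normal``
    Numeric least-squares quantile matching of a normal truncated to the
    variable's hard physiological bounds.
``split-normal``
    Two half-normals with separate scales below and above the median
    (exact three-quantile match); used for heart and respiratory rate,
    whose published skew flips sign between classes.

Sampling is inverse-transform throughout, so a Gaussian copula can couple
SpO2 and respiratory rate (default rho = -0.4) without disturbing the
fitted marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import SpO2Scale, VitalSigns, compute_news2

__all__ = [
    "QuantileSpec",
    "CohortSpec",
    "PatientRecord",
    "FittingError",
    "fit_from_quantiles",
    "generate_cohort",
    "cohort_to_frame",
    "calibration_report",
    "default_cohort_spec",
    "COHORT_COLUMNS",
]

#: Canonical cohort CSV schema (header names, case-insensitive on input).
COHORT_COLUMNS = [
    "patient_id", "age", "sex", "rr", "spo2", "on_oxygen", "spo2_scale",
    "temp_c", "sbp", "hr", "gcs", "lactate", "death_48h", "pals", "icu",
    "admitted", "ecg_rhythm",
]

_Z75 = float(stats.norm.ppf(0.75))  # 0.6744897...


class FittingError(ValueError):
    """Raised when a quantile triple cannot be represented by the family."""


@dataclass(frozen=True)
class QuantileSpec:
    """A published median/IQR summary plus the family used to emulate it."""

    median: float
    q25: float
    q75: float
    family: str = "lognormal"
    hard_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.q25 <= self.median <= self.q75:
            raise FittingError(
                f"quantiles must be ordered: q25={self.q25}, median={self.median}, q75={self.q75}"
            )


class _Fitted:
    """A fitted marginal exposing an inverse CDF (``ppf``)."""

    def ppf(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=size))


@dataclass
class _ShiftedLogNormal(_Fitted):
    shift: float
    mu: float
    sigma: float
    reflected: bool = False

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if self.reflected:
            return -(self.shift + np.exp(self.mu + self.sigma * stats.norm.ppf(1.0 - u)))
        return self.shift + np.exp(self.mu + self.sigma * stats.norm.ppf(u))


@dataclass
class _TruncNormal(_Fitted):
    mu: float
    sigma: float
    lo: float
    hi: float

    def ppf(self, u):
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        return stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)


@dataclass
class _SplitNormal(_Fitted):
    median: float
    sigma_lo: float
    sigma_hi: float

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        z = stats.norm.ppf(u)
        sigma = np.where(u < 0.5, self.sigma_lo, self.sigma_hi)
        return self.median + sigma * z


def _fit_lognormal(q25: float, m: float, q75: float) -> _ShiftedLogNormal:
    denom = q25 + q75 - 2.0 * m
    if abs(denom) < 1e-9 * (q75 - q25):
        # symmetric triple: the lognormal degenerates; an equal-scale split
        # normal is the exact symmetric limit
        raise FittingError("symmetric quantiles: use split-normal or truncated-normal")
    if denom > 0:  # right skew
        shift = (q25 * q75 - m * m) / denom
        mu = math.log(m - shift)
        sigma = math.log((q75 - shift) / (q25 - shift)) / (2.0 * _Z75)
        return _ShiftedLogNormal(shift=shift, mu=mu, sigma=sigma, reflected=False)
    # left skew: fit the negated triple and reflect
    refl = _fit_lognormal(-q75, -m, -q25)
    return _ShiftedLogNormal(shift=refl.shift, mu=refl.mu, sigma=refl.sigma, reflected=True)


def _fit_truncnorm(q25: float, m: float, q75: float,
                   bounds: Optional[Tuple[float, float]]) -> _TruncNormal:
    lo, hi = bounds if bounds is not None else (-np.inf, np.inf)
    target = np.array([q25, m, q75])
    qs = np.array([0.25, 0.5, 0.75])

    def resid(theta):
        mu, log_s = theta
        s = math.exp(log_s)
        a, b = (lo - mu) / s, (hi - mu) / s
        return stats.truncnorm.ppf(qs, a, b, loc=mu, scale=s) - target

    x0 = np.array([m, math.log((q75 - q25) / (2.0 * _Z75))])
    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    mu, log_s = sol.x
    return _TruncNormal(mu=float(mu), sigma=float(math.exp(log_s)), lo=lo, hi=hi)


def fit_from_quantiles(spec: QuantileSpec) -> _Fitted:
    """Fit the spec's family to its median and quartiles.

    The lognormal and split-normal fits reproduce all three target quantiles
    exactly (closed form); the truncated normal matches them by least
    squares, exactly when the triple is symmetric and the bounds are far.
    Degenerate triples (median = q25 = q75) are rejected.
    """
    if spec.q25 == spec.q75:
        raise FittingError("degenerate quantiles (point mass) cannot be fitted")
    if spec.family == "lognormal":
        return _fit_lognormal(spec.q25, spec.median, spec.q75)
    if spec.family in ("truncated-normal", "truncnorm"):
        return _fit_truncnorm(spec.q25, spec.median, spec.q75, spec.hard_bounds)
    if spec.family == "split-normal":
        return _SplitNormal(
            median=spec.median,
            sigma_lo=(spec.median - spec.q25) / _Z75,
            sigma_hi=(spec.q75 - spec.median) / _Z75,
        )
    raise FittingError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# Cohort specification: defaults are the published per-class summaries.
# ---------------------------------------------------------------------------

_ECG_RHYTHMS = ["sinus", "sinus_bradycardia", "sinus_tachycardia",
                "atrial_fibrillation", "av_block", "pacemaker"]


def _survivor_vitals() -> Dict[str, QuantileSpec]:
    return {
        "rr": QuantileSpec(16, 12, 19, "split-normal", (5, 60)),
        "spo2": QuantileSpec(96, 94, 98, "truncated-normal", (50, 100)),
        "temp_c": QuantileSpec(36.1, 35.8, 36.6, "truncated-normal", (30.0, 42.0)),
        "sbp": QuantileSpec(128, 108, 144, "truncated-normal", (50, 260)),
        "hr": QuantileSpec(70, 57, 87, "split-normal", (20, 220)),
        "lactate": QuantileSpec(2.6, 1.8, 3.6, "lognormal", (0.3, 25.0)),
        "age": QuantileSpec(74, 62, 83, "truncated-normal", (18, 105)),
    }


def _nonsurvivor_vitals() -> Dict[str, QuantileSpec]:
    return {
        "rr": QuantileSpec(20, 16, 32, "lognormal", (5, 60)),
        "spo2": QuantileSpec(89, 76, 94, "truncated-normal", (40, 100)),
        "temp_c": QuantileSpec(35.7, 34.9, 36.2, "truncated-normal", (28.0, 42.0)),
        "sbp": QuantileSpec(105, 84, 139, "truncated-normal", (40, 260)),
        "hr": QuantileSpec(82, 40, 96, "split-normal", (20, 220)),
        "lactate": QuantileSpec(5.2, 4.5, 6.6, "lognormal", (0.3, 25.0)),
        "age": QuantileSpec(81, 73, 87, "truncated-normal", (18, 105)),
    }


#: Discrete GCS distributions per class.  Survivors: median and both
#: quartiles at 15 (alert), a small confused tail.  Non-survivors: median 14,
#: lower quartile 7, upper quartile 15, matching the published triple.
_GCS_SURVIVOR = {15: 0.92, 14: 0.05, 13: 0.01, 12: 0.01, 10: 0.01}
_GCS_NONSURVIVOR = {3: 0.05, 4: 0.05, 5: 0.05, 6: 0.05, 7: 0.08,
                    8: 0.03, 9: 0.03, 10: 0.03, 11: 0.03, 12: 0.03, 13: 0.03,
                    14: 0.24, 15: 0.30}

#: ECG rhythm frequencies per class (descriptive only; feeds nothing
#: downstream).
_ECG_SURVIVOR = [192 / 340, 46 / 340, 33 / 340, 34 / 340, 24 / 340, 11 / 340]
_ECG_NONSURVIVOR = [5 / 21, 1 / 21, 7 / 21, 1 / 21, 6 / 21, 1 / 21]


@dataclass
class CohortSpec:
    """Everything needed to generate a synthetic cohort.

    Defaults reproduce the published study conditions: 5.8% 48-hour
    mortality in 361 patients, conditional advanced-life-support and ICU
    rates per class, 45.4% women, and per-class vital-sign/lactate/age
    quantile summaries.  Supplemental-oxygen rates and the discrete GCS
    distributions are not published; their defaults were calibrated once so
    the class-conditional NEWS2 medians land on the published 3 vs 11.
    """

    n: int = 361
    mortality_rate: float = 0.058
    pals_given_death: float = 16 / 21
    pals_given_survival: float = 35 / 340
    icu_given_death: float = 11 / 21
    icu_given_survival: float = 20 / 340
    admitted_given_survival: float = 116 / 340
    female_fraction: float = 0.454
    oxygen_given_survival: float = 0.05
    oxygen_given_death: float = 0.45
    scale2_fraction: float = 0.03
    spo2_rr_correlation: float = -0.4
    survivor: Dict[str, QuantileSpec] = field(default_factory=_survivor_vitals)
    nonsurvivor: Dict[str, QuantileSpec] = field(default_factory=_nonsurvivor_vitals)
    gcs_survivor: Dict[int, float] = field(default_factory=lambda: dict(_GCS_SURVIVOR))
    gcs_nonsurvivor: Dict[int, float] = field(default_factory=lambda: dict(_GCS_NONSURVIVOR))
    ecg_survivor: Sequence[float] = field(default_factory=lambda: list(_ECG_SURVIVOR))
    ecg_nonsurvivor: Sequence[float] = field(default_factory=lambda: list(_ECG_NONSURVIVOR))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("cohort size must be at least 20")
        rates = [self.mortality_rate, self.pals_given_death, self.pals_given_survival,
                 self.icu_given_death, self.icu_given_survival,
                 self.admitted_given_survival, self.female_fraction,
                 self.oxygen_given_survival, self.oxygen_given_death,
                 self.scale2_fraction]
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")


def default_cohort_spec(**overrides) -> CohortSpec:
    """The published study conditions, optionally overridden field-wise."""
    return replace(CohortSpec(), **overrides) if overrides else CohortSpec()


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: the cohort CSV row in object form."""

    patient_id: str
    age: int
    sex: str
    vitals: VitalSigns
    lactate: float
    death_48h: int
    pals: int
    icu: int
    admitted: int
    ecg_rhythm: str


def _round_half_up(x: np.ndarray, decimals: int = 0) -> np.ndarray:
    f = 10.0**decimals
    return np.floor(x * f + 0.5) / f


def _clip(x: np.ndarray, bounds: Optional[Tuple[float, float]]) -> np.ndarray:
    if bounds is None:
        return x
    return np.clip(x, bounds[0], bounds[1])


def _sample_mixture(u: np.ndarray, death: np.ndarray, name: str,
                    spec: CohortSpec) -> np.ndarray:
    """Inverse-transform one variable from its class-conditional marginal."""
    d_s = fit_from_quantiles(spec.survivor[name])
    d_ns = fit_from_quantiles(spec.nonsurvivor[name])
    out = np.where(death, d_ns.ppf(u), d_s.ppf(u))
    bounds = spec.survivor[name].hard_bounds
    return _clip(out, bounds)


def _sample_categorical(u: np.ndarray, death: np.ndarray,
                        surv: Dict, nonsurv: Dict) -> np.ndarray:
    keys_s, probs_s = zip(*sorted(surv.items()))
    keys_ns, probs_ns = zip(*sorted(nonsurv.items()))
    out = np.empty(len(u), dtype=object)
    for mask, keys, probs in ((~death, keys_s, probs_s), (death, keys_ns, probs_ns)):
        cum = np.cumsum(probs)
        cum = cum / cum[-1]
        idx = np.searchsorted(cum, u[mask], side="left")
        out[mask] = np.asarray(keys, dtype=object)[idx]
    return out


def generate_cohort(spec: Optional[CohortSpec] = None,
                    seed: Optional[int] = None) -> List[PatientRecord]:
    """Draw a synthetic cohort; deterministic for a fixed spec and seed.

    Class labels are Bernoulli(mortality rate); vitals, lactate and age come
    from the class-conditional fitted marginals (SpO2 and respiratory rate
    coupled through a Gaussian copula), rounded to chart resolution and
    clipped to hard physiological bounds; outcomes follow the conditional
    rates.  Every non-survivor is admitted.
    """
    spec = spec if spec is not None else CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    death = rng.uniform(size=n) < spec.mortality_rate

    # correlated uniforms for (rr, spo2) through a Gaussian copula
    rho = spec.spo2_rr_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u_rr, u_spo2 = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    u = {name: rng.uniform(size=n) for name in
         ("temp_c", "sbp", "hr", "lactate", "age", "gcs", "ecg")}

    rr = _round_half_up(_sample_mixture(u_rr, death, "rr", spec)).astype(int)
    spo2 = _round_half_up(_sample_mixture(u_spo2, death, "spo2", spec)).astype(int)
    spo2 = np.minimum(spo2, 100)
    temp = _round_half_up(_sample_mixture(u["temp_c"], death, "temp_c", spec), 1)
    sbp = _round_half_up(_sample_mixture(u["sbp"], death, "sbp", spec)).astype(int)
    hr = _round_half_up(_sample_mixture(u["hr"], death, "hr", spec)).astype(int)
    lactate = _round_half_up(_sample_mixture(u["lactate"], death, "lactate", spec), 1)
    lactate = np.maximum(lactate, 0.1)
    age = _round_half_up(_sample_mixture(u["age"], death, "age", spec)).astype(int)
    gcs = _sample_categorical(u["gcs"], death, spec.gcs_survivor,
                              spec.gcs_nonsurvivor).astype(int)
    ecg = _sample_categorical(
        u["ecg"], death,
        dict(zip(_ECG_RHYTHMS, spec.ecg_survivor)),
        dict(zip(_ECG_RHYTHMS, spec.ecg_nonsurvivor)),
    )

    on_oxygen = rng.uniform(size=n) < np.where(
        death, spec.oxygen_given_death, spec.oxygen_given_survival)
    scale2 = rng.uniform(size=n) < spec.scale2_fraction
    female = rng.uniform(size=n) < spec.female_fraction
    pals = rng.uniform(size=n) < np.where(
        death, spec.pals_given_death, spec.pals_given_survival)
    icu = rng.uniform(size=n) < np.where(
        death, spec.icu_given_death, spec.icu_given_survival)
    admitted = np.where(
        death, True, rng.uniform(size=n) < spec.admitted_given_survival)

    records: List[PatientRecord] = []
    width = len(str(n))
    for i in range(n):
        vitals = VitalSigns(
            respiratory_rate=int(rr[i]),
            spo2=int(spo2[i]),
            on_supplemental_oxygen=bool(on_oxygen[i]),
            temperature=float(temp[i]),
            systolic_bp=int(sbp[i]),
            heart_rate=int(hr[i]),
            gcs=int(gcs[i]),
            spo2_scale=SpO2Scale.SCALE2 if scale2[i] else SpO2Scale.SCALE1,
        )
        records.append(PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            age=int(age[i]),
            sex="F" if female[i] else "M",
            vitals=vitals,
            lactate=float(lactate[i]),
            death_48h=int(death[i]),
            pals=int(pals[i]),
            icu=int(icu[i]),
            admitted=int(admitted[i]),
            ecg_rhythm=str(ecg[i]),
        ))
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into the canonical cohort table."""
    rows = []
    for r in records:
        v = r.vitals
        rows.append({
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "rr": v.respiratory_rate,
            "spo2": v.spo2,
            "on_oxygen": int(v.on_supplemental_oxygen),
            "spo2_scale": v.spo2_scale.value,
            "temp_c": v.temperature,
            "sbp": v.systolic_bp,
            "hr": v.heart_rate,
            "gcs": v.gcs,
            "lactate": r.lactate,
            "death_48h": r.death_48h,
            "pals": r.pals,
            "icu": r.icu,
            "admitted": r.admitted,
            "ecg_rhythm": r.ecg_rhythm,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


#: Published class-conditional score summaries used only as calibration
#: references for the derived rows of :func:`calibration_report`.
SCORE_TARGETS = {
    "survivor": {"news2": (3.0, 1.0, 5.0), "news2_l": (5.9, 3.8, 8.8)},
    "nonsurvivor": {"news2": (11.0, 6.0, 15.0), "news2_l": (16.4, 12.2, 21.0)},
}


def calibration_report(records: Sequence[PatientRecord],
                       spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Compare generated per-class median/IQR against the calibration targets.

    One row per variable per class with generated and target quantiles and
    relative deviations.  Derived rows (NEWS2, NEWS2-L) are marked: they are
    computed through the scoring rubric, not sampled, so they audit the whole
    generative chain.  A missing class is flagged rather than an error.
    """
    spec = spec if spec is not None else CohortSpec()
    df = cohort_to_frame(records)
    news2 = np.array([compute_news2(r.vitals).total for r in records])
    df = df.assign(news2=news2, news2_l=news2 + df["lactate"].to_numpy())

    rows = []
    for cls, mask in (("survivor", df["death_48h"] == 0),
                      ("nonsurvivor", df["death_48h"] == 1)):
        sub = df[mask]
        class_spec = getattr(spec, cls)
        targets = {name: (q.median, q.q25, q.q75) for name, q in class_spec.items()}
        targets.update({name: t for name, t in SCORE_TARGETS[cls].items()})
        for name, (t_med, t_q25, t_q75) in targets.items():
            derived = name in SCORE_TARGETS[cls]
            if sub.empty:
                rows.append({"variable": name, "class": cls, "n": 0,
                             "derived": derived, "note": "class missing"})
                continue
            x = sub[name].to_numpy(dtype=float)
            g_q25, g_med, g_q75 = np.quantile(x, [0.25, 0.5, 0.75])
            rows.append({
                "variable": name, "class": cls, "n": int(mask.sum()),
                "derived": derived,
                "gen_median": g_med, "gen_q25": g_q25, "gen_q75": g_q75,
                "target_median": t_med, "target_q25": t_q25, "target_q75": t_q75,
                "rel_dev_median": abs(g_med - t_med) / abs(t_med),
                "rel_dev_q25": abs(g_q25 - t_q25) / abs(t_q25) if t_q25 else np.nan,
                "rel_dev_q75": abs(g_q75 - t_q75) / abs(t_q75),
                "note": "",
            })
    return pd.DataFrame(rows)
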