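"""Synthetic cohort tables with the structure the statistics battery assumes.

One row per participant: group (SCA patient or race-matched control),
demographic and clinical covariates, a nested lesion-status triple under
the liberal/traditional/restrictive definitions (restrictive implies
traditional implies liberal, enforced by drawing all three from a single
uniform), lesion count and volume given presence, and Wechsler composite
scores (IQ, WMI, PSI).

Default group sizes, prevalences, lesion-metric medians and cognitive
means/SDs follow the source cohort: 106 patients and 48 controls,
prevalences 45/42/25 of 106 and 11/5/2 of 48 across the three
definitions, patient cognition 93.15 (13.28) / 92.04 (14.18) /
89.56 (12.99) and control cognition 97.29 (11.78) / 98.90 (13.34) /
97.10 (13.03) for IQ/WMI/PSI.  Lesion count given presence is
zero-truncated negative binomial and volume log-normal (both metrics are
right-skewed and analysed on a log scale).  An optional per-outcome
``lesion_effect`` adds a linear term in log1p(liberal lesion volume) to
the cognitive scores; it defaults to zero, the no-association null.
Hemoglobin is recorded for patients only; a small fraction of patient
hemoglobin and control SpO2 values are set missing, mirroring the
group-mean imputation step downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort"]

TABLE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "spo2",
    "hemoglobin",
    "education_decile",
    "icv_cm3",
    "sci_liberal",
    "sci_traditional",
    "sci_restrictive",
    "n_liberal",
    "n_traditional",
    "n_restrictive",
    "vol_liberal",
    "vol_traditional",
    "vol_restrictive",
    "iq",
    "wmi",
    "psi",
    "impaired",
]


@dataclass(frozen=True)
class CohortSpec:
    n_sca: int = 106
    n_control: int = 48
    #: per-group P(lesion) under (liberal, traditional, restrictive); must nest
    prevalence_sca: tuple[float, float, float] = (45 / 106, 42 / 106, 25 / 106)
    prevalence_control: tuple[float, float, float] = (11 / 48, 5 / 48, 2 / 48)
    #: lesion count given presence: zero-truncated NB(mean, dispersion k)
    count_mean: dict = field(default_factory=lambda: {"sca": 6.0, "control": 3.0})
    count_dispersion: float = 1.2
    #: liberal volume given presence: log-normal med(mm^3) and log-sd
    volume_median: dict = field(default_factory=lambda: {"sca": 75.0, "control": 22.0})
    volume_log_sd: float = 1.5
    #: cognition means/SDs per group, order (IQ, WMI, PSI)
    cognition_mean_sca: tuple[float, float, float] = (93.15, 92.04, 89.56)
    cognition_sd_sca: tuple[float, float, float] = (13.28, 14.18, 12.99)
    cognition_mean_control: tuple[float, float, float] = (97.29, 98.90, 97.10)
    cognition_sd_control: tuple[float, float, float] = (11.78, 13.34, 13.03)
    #: per-outcome coefficient on log1p(liberal lesion volume)
    lesion_effect: dict = field(
        default_factory=lambda: {"iq": 0.0, "wmi": 0.0, "psi": 0.0}
    )
    #: fraction of male participants per group
    male_fraction: dict = field(
        default_factory=lambda: {"sca": 53 / 106, "control": 20 / 48}
    )
    age_range: tuple[float, float] = (8.0, 30.0)
    missing_hemoglobin_sca: float = 4 / 106
    missing_spo2_control: float = 7 / 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sca < 1 or self.n_control < 1:
            raise ValueError("group sizes must be at least 1")
        for name, p in (("sca", self.prevalence_sca), ("control", self.prevalence_control)):
            if any(not 0 <= x <= 1 for x in p):
                raise ValueError(f"{name} prevalences must lie in [0, 1]")
            if not (p[0] >= p[1] >= p[2]):
                raise ValueError(
                    f"{name} prevalences must nest (liberal >= traditional >= "
                    f"restrictive), got {p}"
                )


def _zt_negative_binomial(
    rng: np.random.Generator, mean: float, k: float, size: int
) -> np.ndarray:
    """Zero-truncated negative binomial via rejection of zeros."""
    p = k / (k + mean)
    out = rng.negative_binomial(k, p, size=size)
    for _ in range(1000):
        zero = out == 0
        if not zero.any():
            break
        out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
    out[out == 0] = 1
    return out


def _group_rows(spec: CohortSpec, rng: np.random.Generator, group: str) -> pd.DataFrame:
    n = spec.n_sca if group == "sca" else spec.n_control
    prev = spec.prevalence_sca if group == "sca" else spec.prevalence_control

    # single uniform per subject makes the status triple monotone by design
    u = rng.uniform(size=n)
    status = np.stack([u < p for p in prev], axis=1)

    n_lib = np.zeros(n, dtype=int)
    pos = status[:, 0]
    n_lib[pos] = _zt_negative_binomial(
        rng, spec.count_mean[group], spec.count_dispersion, int(pos.sum())
    )
    n_trad = np.zeros(n, dtype=int)
    t = status[:, 1]
    n_trad[t] = 1 + rng.binomial(np.maximum(n_lib[t] - 1, 0), 0.7)
    n_rest = np.zeros(n, dtype=int)
    r = status[:, 2]
    n_rest[r] = 1 + rng.binomial(np.maximum(n_trad[r] - 1, 0), 0.5)

    vol_lib = np.zeros(n)
    vol_lib[pos] = rng.lognormal(
        np.log(spec.volume_median[group]), spec.volume_log_sd, int(pos.sum())
    )
    vol_trad = np.zeros(n)
    vol_trad[t] = vol_lib[t] * rng.beta(8.0, 1.4, int(t.sum()))
    vol_rest = np.zeros(n)
    vol_rest[r] = np.maximum(vol_trad[r] * rng.beta(0.8, 8.0, int(r.sum())), 1.0)

    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.uniform(size=n) < spec.male_fraction[group]).astype(int)
    edu = rng.integers(1, 11, size=n).astype(float)
    icv = rng.normal(1450.0, 120.0, size=n)
    if group == "sca":
        spo2 = np.clip(rng.normal(96.5, 2.0, size=n), 89, 100)
        hb = np.clip(rng.normal(87.7, 14.0, size=n), 60, 134)
        hb[rng.uniform(size=n) < spec.missing_hemoglobin_sca] = np.nan
    else:
        spo2 = np.clip(rng.normal(98.5, 1.2, size=n), 93, 100)
        spo2[rng.uniform(size=n) < spec.missing_spo2_control] = np.nan
        hb = np.full(n, np.nan)

    means = spec.cognition_mean_sca if group == "sca" else spec.cognition_mean_control
    sds = spec.cognition_sd_sca if group == "sca" else spec.cognition_sd_control
    metric = np.log1p(vol_lib)
    cog = {}
    for (name, mu, sd) in zip(("iq", "wmi", "psi"), means, sds):
        cog[name] = mu + spec.lesion_effect.get(name, 0.0) * metric + rng.normal(
            0.0, sd, size=n
        )

    return pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "spo2": spo2,
            "hemoglobin": hb,
            "education_decile": edu,
            "icv_cm3": icv,
            "sci_liberal": status[:, 0].astype(int),
            "sci_traditional": status[:, 1].astype(int),
            "sci_restrictive": status[:, 2].astype(int),
            "n_liberal": n_lib,
            "n_traditional": n_trad,
            "n_restrictive": n_rest,
            "vol_liberal": vol_lib,
            "vol_traditional": vol_trad,
            "vol_restrictive": vol_rest,
            "iq": cog["iq"],
            "wmi": cog["wmi"],
            "psi": cog["psi"],
        }
    )


def generate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate one synthetic cohort table; bit-reproducible under a fixed
    seed and spec."""
    rng = np.random.default_rng(spec.seed)
    sca = _group_rows(spec, rng, "sca")
    ctl = _group_rows(spec, rng, "control")
    table = pd.concat([sca, ctl], ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])
    table["impaired"] = (table[["iq", "wmi", "psi"]].min(axis=1) < 70).astype(int)
    return table[TABLE_COLUMNS]
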