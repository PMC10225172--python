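"""Synthetic favorable intermediate-risk (FIR) prostatectomy cohort generator.

No individual-level data from the source registry are available, so every
downstream stage of the pipeline is exercised against synthetic cohorts whose
survival landmarks, censoring structure and demographic marginals emulate the
published summaries: n = 920 men operated 1988-2017 (median surgery year 2011),
followed administratively to end of 2017, with endpoint-specific piecewise-
exponential event times calibrated to the published 5/10/15-year landmarks.

Endpoints are generated independently per subject from their own marginal
hazards; the published summaries are marginal per endpoint and the downstream
analysis consumes nothing but those marginals, so no joint structure is
imposed.  Demographics are cosmetic — estimation never reads them — but are
matched to the published marginals so generated files resemble the real
cohort's descriptive table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import defaults
from .hazard import PiecewiseHazard, calibrate_piecewise_hazard, sample_event_times

__all__ = [
    "DemographicMarginals",
    "CohortSpec",
    "default_study_spec",
    "sample_censoring",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

_STAGES = ("T1", "T2a", "T2b", "T2c")
_HIGH_STAGES = ("T2b", "T2c")


def _sigma_from_quartiles(q1: float, q3: float) -> float:
    # IQR of a normal is 2 * 0.674490 * sigma
    return (q3 - q1) / (2 * 0.6744897501960817)


@dataclass(frozen=True)
class DemographicMarginals:
    """Marginal distributions for the cosmetic subject covariates.

    Age is normal (matched to the published median and quartiles); PSA is
    log-normal (matched on the log scale); race, grade group and clinical
    stage are categorical.  ``gg1_high_psa_fraction`` splits grade-group-1
    subjects — who need a second intermediate-risk feature to be FIR —
    between the PSA 10-20 ng/mL route and the cT2b-c route.
    """

    age_mean: float = defaults.AGE_MEDIAN
    age_sd: float = _sigma_from_quartiles(defaults.AGE_Q1, defaults.AGE_Q3)
    psa_log_mean: float = float(np.log(defaults.PSA_MEDIAN))
    psa_log_sd: float = _sigma_from_quartiles(
        float(np.log(defaults.PSA_Q1)), float(np.log(defaults.PSA_Q3))
    )
    black_fraction: float = defaults.BLACK_FRACTION
    grade_group2_fraction: float = defaults.GRADE_GROUP2_FRACTION
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.STAGE_PROBS)
    )
    gg1_high_psa_fraction: float = defaults.GG1_HIGH_PSA_FRACTION

    def __post_init__(self) -> None:
        for name in ("black_fraction", "grade_group2_fraction", "gg1_high_psa_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        probs = dict(self.stage_probs)
        if set(probs) != set(_STAGES):
            raise ValueError(f"stage_probs must have keys {_STAGES}")
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("stage probabilities must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")
        if self.age_sd <= 0 or self.psa_log_sd <= 0:
            raise ValueError("scale parameters must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``accrual_years`` describes the surgery-year distribution and accepts two
    forms:

    * a 3-tuple ``(first, last, modal)`` — triangular accrual;
    * a 5-tuple ``(first, q1, median, q3, last)`` — piecewise-uniform accrual
      with a quarter of the mass between consecutive knots, which reproduces
      the published surgery-year quartiles exactly (the default).

    ``dropout_rate`` is the per-year rate of non-administrative censoring
    (exponential); administrative censoring truncates follow-up at
    ``study_end_year``.
    """

    n_subjects: int
    endpoint_hazards: Mapping[str, PiecewiseHazard]
    accrual_years: tuple[float, ...] = defaults.ACCRUAL_YEARS
    study_end_year: float = defaults.STUDY_END_YEAR
    dropout_rate: float = defaults.DEFAULT_DROPOUT_RATE
    demographic_marginals: DemographicMarginals = field(
        default_factory=DemographicMarginals
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if not self.endpoint_hazards:
            raise ValueError("need at least one endpoint hazard")
        yrs = tuple(float(y) for y in self.accrual_years)
        if len(yrs) not in (3, 5):
            raise ValueError(
                "accrual_years must be (first, last, modal) or (first, q1, median, q3, last)"
            )
        if len(yrs) == 3:
            first, last, modal = yrs
            if not first <= modal <= last:
                raise ValueError("need first <= modal <= last")
        else:
            first, last = yrs[0], yrs[-1]
            if any(b < a for a, b in zip(yrs, yrs[1:])):
                raise ValueError("accrual quantile years must be non-decreasing")
        if last > self.study_end_year:
            raise ValueError("accrual must end by study_end_year")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")
        object.__setattr__(self, "accrual_years", yrs)
        object.__setattr__(self, "endpoint_hazards", dict(self.endpoint_hazards))


def default_study_spec(
    n_subjects: int = defaults.DEFAULT_N_SUBJECTS, seed: int = 0, **overrides
) -> CohortSpec:
    """The default cohort: published landmarks, accrual and marginals."""
    hazards = {
        ep: calibrate_piecewise_hazard(landmarks)
        for ep, landmarks in defaults.LANDMARK_SURVIVAL.items()
    }
    return CohortSpec(
        n_subjects=n_subjects, endpoint_hazards=hazards, seed=seed, **overrides
    )


def _sample_surgery_years(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    yrs = spec.accrual_years
    if len(yrs) == 3:
        first, last, modal = yrs
        if first == last:
            return np.full(n, first)
        return rng.triangular(first, modal, last, size=n)
    # quartile-matched piecewise uniform: pick a quartile bin, then a uniform
    # point inside it (degenerate bins collapse to their endpoint)
    knots = np.asarray(yrs)
    bins = rng.integers(0, 4, size=n)
    u = rng.random(n)
    return knots[bins] + u * (knots[bins + 1] - knots[bins])


def sample_censoring(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw censoring times (and the surgery years behind them).

    The censoring time is the minimum of the administrative horizon
    ``study_end_year - surgery_year`` and an exponential dropout draw
    (infinite when ``dropout_rate`` is 0).

    Returns
    -------
    (censor_times, surgery_years)
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    surgery = _sample_surgery_years(spec, n, rng)
    admin = spec.study_end_year - surgery
    if spec.dropout_rate > 0:
        dropout = rng.exponential(scale=1.0 / spec.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    return np.minimum(admin, dropout), surgery


def _sample_demographics(
    spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    m = spec.demographic_marginals
    n = spec.n_subjects
    age = np.clip(rng.normal(m.age_mean, m.age_sd, size=n), 40.0, 90.0)
    psa = rng.lognormal(m.psa_log_mean, m.psa_log_sd, size=n)
    race = np.where(rng.random(n) < m.black_fraction, "black", "non-black")
    grade = np.where(rng.random(n) < m.grade_group2_fraction, 2, 1)
    stage_p = np.array([m.stage_probs[s] for s in _STAGES])
    stage = np.asarray(_STAGES)[rng.choice(len(_STAGES), size=n, p=stage_p)]

    # FIR membership: grade-group-1 men need PSA 10-20 or stage cT2b-c.
    gg1 = grade == 1
    via_psa = gg1 & (rng.random(n) < m.gg1_high_psa_fraction)
    via_stage = gg1 & ~via_psa
    # fold the PSA draw into [10, 20) by reflecting the unit quantile
    u = rng.random(int(via_psa.sum()))
    psa[via_psa] = 10.0 + 10.0 * u
    need_fix = via_stage & ~np.isin(stage, _HIGH_STAGES)
    p2b = m.stage_probs["T2b"] / (m.stage_probs["T2b"] + m.stage_probs["T2c"])
    stage[need_fix] = np.where(
        rng.random(int(need_fix.sum())) < p2b, "T2b", "T2c"
    )
    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": age,
            "race": race,
            "psa": psa,
            "grade_group": grade,
            "clinical_stage": stage,
        }
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort as a DataFrame, one row per subject.

    Columns: ``subject_id, age, race, psa, grade_group, clinical_stage,
    surgery_year`` followed by ``<endpoint>_time`` / ``<endpoint>_event`` per
    endpoint.  Observed time is ``min(event time, censor time)`` and the event
    flag is 1 iff the event time came first.  Bit-reproducible for a fixed
    ``spec.seed``: independent sub-streams are spawned per component so adding
    an endpoint never perturbs the others.
    """
    root = np.random.SeedSequence(spec.seed)
    demo_ss, censor_ss, *ep_ss = root.spawn(2 + len(spec.endpoint_hazards))
    df = _sample_demographics(spec, np.random.default_rng(demo_ss))
    censor, surgery = sample_censoring(
        spec, spec.n_subjects, np.random.default_rng(censor_ss)
    )
    df["surgery_year"] = np.floor(surgery + 0.5).astype(int)
    for ss, (ep, hazard) in zip(ep_ss, sorted(spec.endpoint_hazards.items())):
        event_t = sample_event_times(
            hazard, spec.n_subjects, np.random.default_rng(ss)
        )
        observed = np.minimum(event_t, censor)
        df[f"{ep}_time"] = observed
        df[f"{ep}_event"] = (event_t <= censor).astype(int)
    # stable column order regardless of endpoint-map ordering
    base = [
        "subject_id", "age", "race", "psa", "grade_group", "clinical_stage",
        "surgery_year",
    ]
    ep_cols = [
        c for ep in sorted(spec.endpoint_hazards) for c in (f"{ep}_time", f"{ep}_event")
    ]
    return df[base + ep_cols]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort with stable formatting (times to 6 decimals)."""
    out = df.copy()
    for c in out.columns:
        if c.endswith("_time") or c in ("age", "psa"):
            out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
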