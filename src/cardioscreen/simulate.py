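"""Synthetic insurance-claims cohort generator with planted latent structure.

Real pregnancy claims cohorts are proprietary, so every downstream stage of the
screening pipeline is exercised against cohorts generated here.  The generator
emulates the data-generating premise of claims data: a pregnancy's mother (and,
when linked, father) carries a small number of latent clinical factors (e.g. a
latent state of diabetes), and each factor probabilistically *emits* correlated
diagnosis and medication codes.  The pregnancy-level outcome (a cardiac
malformation in any live-born infant) is drawn per fetus from a logistic model
whose log-odds are the sum of planted per-factor effects plus a maternal-age
term, so true odds ratios are known exactly and parameter recovery is testable.

Conventions
-----------
* All event days are integer offsets from the pregnancy's last menstrual
  period (LMP = day 0); exposure windows in the literature are LMP-relative,
  so calendar dates add nothing.
* Outcomes are counted at the pregnancy level: a twin pregnancy receives two
  independent fetal draws and is flagged if either is affected, reproducing
  the mechanical risk inflation of multiple gestation.
* Identical (config, seed) pairs reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration field is invalid."""


# --------------------------------------------------------------------------
# outcome code lists (primary cardiac malformation + 11 subtypes)
# --------------------------------------------------------------------------

#: Default subtype -> [(code, vocabulary), ...] lists used by the generator and
#: by pipeline defaults.  Codes are synthetic stand-ins shaped like ICD-9 /
#: ICD-10 cardiac-malformation codes; real analyses supply validated lists.
DEFAULT_OUTCOME_CODES: dict[str, list[tuple[str, str]]] = {
    "conotruncal": [("745.1", "ICD9"), ("Q20.3", "ICD10")],
    "single_ventricle": [("745.3", "ICD9"), ("Q20.4", "ICD10")],
    "ventricular_septal": [("745.4", "ICD9"), ("Q21.0", "ICD10")],
    "atrial_septal": [("745.5", "ICD9"), ("Q21.1", "ICD10")],
    "atrioventricular_septal": [("745.6", "ICD9"), ("Q21.2", "ICD10")],
    "right_sided": [("746.0", "ICD9"), ("Q22.5", "ICD10")],
    "left_sided": [("746.7", "ICD9"), ("Q23.4", "ICD10")],
    "pda": [("747.0", "ICD9"), ("Q25.0", "ICD10")],
    "pphn": [("747.83", "ICD9"), ("P29.30", "ICD10")],
    "great_veins": [("747.4", "ICD9"), ("Q26.2", "ICD10")],
    "other": [("746.9", "ICD9"), ("Q24.9", "ICD10")],
}

#: Relative frequency of each subtype among affected fetuses (ventricular
#: septal defects dominate in observed cohorts).
DEFAULT_SUBTYPE_WEIGHTS: dict[str, float] = {
    "conotruncal": 0.04,
    "single_ventricle": 0.01,
    "ventricular_septal": 0.55,
    "atrial_septal": 0.10,
    "atrioventricular_septal": 0.02,
    "right_sided": 0.03,
    "left_sided": 0.13,
    "pda": 0.04,
    "pphn": 0.02,
    "great_veins": 0.02,
    "other": 0.04,
}


def primary_outcome_codes() -> list[tuple[str, str]]:
    """Union of all subtype code lists: the primary outcome definition."""
    out: list[tuple[str, str]] = []
    for lst in DEFAULT_OUTCOME_CODES.values():
        out.extend(lst)
    return out


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentFactorSpec:
    """A latent clinical factor that emits correlated codes.

    Parameters
    ----------
    name
        Label for the factor (e.g. ``"diabetes"``).
    emitted_codes
        List of ``(code_id, vocabulary, emission_probability)`` triples with
        vocabulary in ``{"dx-section", "tdc"}``.  A carrier emits each code
        independently with its emission probability.
    carrier_prevalence
        Fraction of pregnancies carrying the factor.
    outcome_log_or
        Log odds-ratio contribution of carrier status to the per-fetus
        outcome model.
    role
        ``"maternal"`` (codes recorded on the mother) or ``"paternal"``.
    multiple_gestation_log_or
        Log odds-ratio contribution of carrier status to the probability of a
        twin pregnancy.  A fertility-treatment proxy uses a positive value
        here with ``outcome_log_or = 0``: its marginal association with the
        outcome is then entirely the pregnancy-level twin-counting artefact.
    outcome_subtype
        If set, affected fetuses of carriers are assigned this cardiac
        subtype, planting a subtype-specific signal.
    """

    name: str
    emitted_codes: Sequence[tuple[str, str, float]]
    carrier_prevalence: float
    outcome_log_or: float
    role: str = "maternal"
    multiple_gestation_log_or: float = 0.0
    outcome_subtype: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.carrier_prevalence < 1.0:
            raise ConfigError(
                f"factor {self.name!r}: carrier_prevalence must be in (0, 1), "
                f"got {self.carrier_prevalence}"
            )
        seen: set[str] = set()
        for code, vocab, p in self.emitted_codes:
            if vocab not in ("dx-section", "tdc"):
                raise ConfigError(
                    f"factor {self.name!r}: emitted code {code!r} has invalid "
                    f"vocabulary {vocab!r}"
                )
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"factor {self.name!r}: emission probability for {code!r} "
                    f"must be in [0, 1], got {p}"
                )
            if code in seen:
                raise ConfigError(
                    f"factor {self.name!r}: duplicate emitted code {code!r}"
                )
            seen.add(code)
        if self.role not in ("maternal", "paternal"):
            raise ConfigError(f"factor {self.name!r}: invalid role {self.role!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the screened pregnancy cohort the pipeline targets:
    pregnancy-level outcome rate ~1.3%, father linkage 70.4%, multiple
    gestation 3.4%, maternal age median 31 (IQR 28-34).
    """

    n_pregnancies: int = 10_000
    n_noise_codes: int = 100
    factors: Sequence[LatentFactorSpec] = ()
    baseline_outcome_rate: float = 0.013
    father_link_rate: float = 0.704
    multiple_gestation_rate: float = 0.034
    age_distribution: tuple[float, tuple[float, float]] = (31.0, (28.0, 34.0))
    age_outcome_slope: float = 0.03  # per-year log-OR on the fetal outcome
    enrollment_gap_rate: float = 0.02  # per-eligibility-rule violation rate
    infant_death_rate: float = 0.002
    noise_max_freq: float = 0.25  # power-law head of noise-code prevalences
    seed: int = 0

    def validate(self) -> None:
        if self.n_pregnancies < 1:
            raise ConfigError(
                f"n_pregnancies must be >= 1, got {self.n_pregnancies}"
            )
        if self.n_noise_codes < 0:
            raise ConfigError(
                f"n_noise_codes must be >= 0, got {self.n_noise_codes}"
            )
        for name in (
            "baseline_outcome_rate",
            "father_link_rate",
            "multiple_gestation_rate",
            "enrollment_gap_rate",
            "infant_death_rate",
            "noise_max_freq",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for f in self.factors:
            f.validate()


# --------------------------------------------------------------------------
# outputs
# --------------------------------------------------------------------------

@dataclass
class ClaimsCohort:
    """Relational bundle of synthetic (or real-shaped) claims tables.

    Tables
    ------
    persons : person_id, sex, birth_year, family_key
    enroll : person_id, start_day, end_day, rx_benefit
    dx : person_id, day, code, vocabulary ("ICD9" | "ICD10")
    rx : person_id, day, code (therapeutic detail code)
    pregnancies : pregnancy_id, mother_id, lmp_day, end_day, delivery_year,
        n_fetuses
    links : pregnancy_id, infant_id, death_day (NaN when alive)
    gem : source, target, flags -- synthetic ICD-10 -> ICD-9 crosswalk rows
    """

    persons: pd.DataFrame
    enroll: pd.DataFrame
    dx: pd.DataFrame
    rx: pd.DataFrame
    pregnancies: pd.DataFrame
    links: pd.DataFrame
    gem: pd.DataFrame

    def validate(self) -> None:
        if (self.enroll["start_day"] > self.enroll["end_day"]).any():
            raise ValueError("enrollment span with start_day > end_day")
        if (self.pregnancies["lmp_day"] >= self.pregnancies["end_day"]).any():
            raise ValueError("pregnancy with LMP day >= end day")
        if (self.pregnancies["n_fetuses"] < 1).any():
            raise ValueError("pregnancy with n_fetuses < 1")
        pid = set(self.persons["person_id"])
        for tbl in (self.dx, self.rx, self.enroll):
            if not set(tbl["person_id"]).issubset(pid):
                raise ValueError("event references unknown person_id")


@dataclass
class GroundTruth:
    """Planted truth for one generated cohort.

    Attributes
    ----------
    codes : DataFrame(code, kind, role, factor, true_log_or)
        ``factor`` is NaN for noise codes; every non-noise code belongs to
        exactly one factor.
    carriers : DataFrame(pregnancy_id + one boolean column per factor)
    violations : DataFrame(pregnancy_id + one boolean column per planted
        eligibility violation)
    implied_outcome_rate : mean pregnancy-level outcome probability under the
        fitted intercept (the target of marginal calibration checks).
    intercept : calibrated per-fetus logistic intercept.
    """

    codes: pd.DataFrame
    carriers: pd.DataFrame
    violations: pd.DataFrame
    implied_outcome_rate: float
    intercept: float


def planted_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """One row per code: (code, true_status, true_or).

    Noise codes have true odds ratio 1.  Codes of a factor whose planted
    log-OR is 0 also report OR 1 but retain their factor-linked status.
    """
    codes = truth.codes
    status = np.where(
        codes["factor"].isna(), "noise", "factor:" + codes["factor"].fillna("")
    )
    return pd.DataFrame(
        {
            "code": codes["code"],
            "true_status": status,
            "true_or": np.exp(codes["true_log_or"].to_numpy()),
        }
    )


# --------------------------------------------------------------------------
# generation internals
# --------------------------------------------------------------------------

# Exposure windows (closed, LMP-relative) the emitted events are placed in.
WINDOWS = {
    ("maternal", "dx"): (-180, 90),
    ("maternal", "rx"): (0, 90),
    ("paternal", "dx"): (-180, 0),
    ("paternal", "rx"): (-90, 0),
}


def _calibrate_intercept(eta0: np.ndarray, n_fetuses: np.ndarray,
                         target: float) -> float:
    """Intercept such that the mean pregnancy-level outcome prob hits target.

    The pregnancy-level probability is 1 - (1 - p)^k for per-fetus risk p and
    k fetuses.
    """
    if target <= 0.0:
        return -np.inf

    def gap(b: float) -> float:
        p = expit(b + eta0)
        return float(np.mean(1.0 - (1.0 - p) ** n_fetuses)) - target

    return brentq(gap, -30.0, 10.0, xtol=1e-12)


def _calibrate_scalar(eta0: np.ndarray, target: float) -> float:
    """Intercept such that mean(expit(b + eta0)) == target."""
    if target <= 0.0:
        return -np.inf

    def gap(b: float) -> float:
        return float(np.mean(expit(b + eta0))) - target

    return brentq(gap, -30.0, 10.0, xtol=1e-12)


def _draw_event_days(rng: np.random.Generator, n: int,
                     window: tuple[int, int]) -> np.ndarray:
    """Event days mostly inside the closed window, ~15% distractors outside."""
    lo, hi = window
    days = rng.integers(lo, hi + 1, size=n)
    out = rng.random(n) < 0.15
    n_out = int(out.sum())
    if n_out:
        before = rng.random(n_out) < 0.5
        lows = rng.integers(lo - 120, lo, size=n_out)       # [lo-120, lo-1]
        highs = rng.integers(hi + 1, hi + 121, size=n_out)  # [hi+1, hi+120]
        days[out] = np.where(before, lows, highs)
    return days


def _emit_code_events(
    rng: np.random.Generator,
    present: np.ndarray,
    person_ids: np.ndarray,
    window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """(person_id, day) arrays: each present row gets 1 + Poisson(0.5) events."""
    idx = np.flatnonzero(present)
    if idx.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    counts = 1 + rng.poisson(0.5, size=idx.size)
    rep = np.repeat(idx, counts)
    days = _draw_event_days(rng, rep.size, window)
    return person_ids[rep], days


def generate_cohort(config: SimConfig) -> tuple[ClaimsCohort, GroundTruth]:
    """Generate a synthetic claims cohort with known planted structure.

    Returns the relational cohort plus the ground truth needed for parameter
    recovery tests: per-code true status, per-pregnancy factor carriage, and
    planted eligibility violations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pregnancies

    # --- pregnancies, mothers, ages -------------------------------------
    preg_id = np.arange(n, dtype=np.int64)
    mother_id = np.arange(n, dtype=np.int64)
    family_key = np.arange(n, dtype=np.int64)
    delivery_year = rng.integers(2011, 2022, size=n)

    med, (q1, q3) = config.age_distribution
    sigma = (q3 - q1) / 1.349 if q3 > q1 else 1.0
    age = np.rint(rng.normal(med, sigma, size=n)).astype(np.int64)
    age = np.clip(age, 12, 55)

    # --- latent factor carriage -----------------------------------------
    factors = list(config.factors)
    carriers = {
        f.name: rng.random(n) < f.carrier_prevalence for f in factors
    }

    # --- multiple gestation (factor-shiftable, marginally calibrated) ----
    mg_eta0 = np.zeros(n)
    for f in factors:
        if f.multiple_gestation_log_or:
            mg_eta0 += f.multiple_gestation_log_or * carriers[f.name]
    if config.multiple_gestation_rate > 0.0:
        mg_b = _calibrate_scalar(mg_eta0, config.multiple_gestation_rate)
        twins = rng.random(n) < expit(mg_b + mg_eta0)
    else:
        twins = np.zeros(n, dtype=bool)
    n_fetuses = np.where(twins, 2, 1).astype(np.int64)

    gest = np.where(twins,
                    np.rint(rng.normal(252.0, 12.0, size=n)),
                    np.rint(rng.normal(273.0, 9.0, size=n)))
    end_day = np.clip(gest, 180, 310).astype(np.int64)

    # --- outcome model ---------------------------------------------------
    eta0 = config.age_outcome_slope * (age - med)
    for f in factors:
        eta0 = eta0 + f.outcome_log_or * carriers[f.name]
    intercept = _calibrate_intercept(eta0, n_fetuses, config.baseline_outcome_rate)
    p_fetus = expit(intercept + eta0) if np.isfinite(intercept) else np.zeros(n)
    implied = float(np.mean(1.0 - (1.0 - p_fetus) ** n_fetuses))
    fetal_draws = rng.random((n, 2)) < p_fetus[:, None]
    fetal_draws[:, 1] &= twins
    affected_any = fetal_draws.any(axis=1)

    # subtype per pregnancy: planted subtype if a carried factor demands one
    subtype_names = list(DEFAULT_OUTCOME_CODES)
    weights = np.array([DEFAULT_SUBTYPE_WEIGHTS[s] for s in subtype_names])
    weights = weights / weights.sum()
    sub_idx = rng.choice(len(subtype_names), size=n, p=weights)
    for f in factors:
        if f.outcome_subtype is not None:
            sub_idx = np.where(carriers[f.name],
                               subtype_names.index(f.outcome_subtype), sub_idx)

    # --- planted eligibility violations ----------------------------------
    r = config.enrollment_gap_rate
    viol_enroll = rng.random(n) < r   # maternal enrollment starts too late
    viol_rx = rng.random(n) < r       # no medication benefits
    viol_infant = rng.random(n) < r   # infant follow-up < 90 days
    viol_age = rng.random(n) < r      # maternal age outside 12-55
    age = np.where(viol_age,
                   np.where(rng.random(n) < 0.5,
                            rng.integers(8, 12, size=n),
                            rng.integers(56, 61, size=n)),
                   age)
    birth_year = delivery_year - age

    # --- maternal enrollment spans ---------------------------------------
    m_start = -180 - rng.integers(0, 200, size=n)
    m_end = end_day + 30 + rng.integers(0, 200, size=n)
    m_start = np.where(viol_enroll, -rng.integers(0, 180, size=n), m_start)
    rx_benefit = ~viol_rx

    enroll_rows = [pd.DataFrame({
        "person_id": mother_id, "start_day": m_start,
        "end_day": m_end, "rx_benefit": rx_benefit,
    })]
    # split ~5% of covering spans into two contiguous pieces (still continuous)
    split = (rng.random(n) < 0.05) & ~viol_enroll & (m_end - m_start > 60)
    if split.any():
        idx = np.flatnonzero(split)
        mid = m_start[idx] + rng.integers(
            20, np.maximum(21, m_end[idx] - m_start[idx] - 20))
        base = enroll_rows[0]
        base.loc[idx, "end_day"] = mid
        enroll_rows.append(pd.DataFrame({
            "person_id": mother_id[idx], "start_day": mid + 1,
            "end_day": m_end[idx], "rx_benefit": rx_benefit[idx],
        }))

    # --- fathers ----------------------------------------------------------
    linked = rng.random(n) < config.father_link_rate
    # half of unlinked families still contain a male who fails the window
    decoy = ~linked & (rng.random(n) < 0.5)
    has_father = linked | decoy
    father_rows = np.flatnonzero(has_father)
    father_id = np.full(n, -1, dtype=np.int64)
    father_id[father_rows] = n + np.arange(father_rows.size)
    f_age = np.clip(np.rint(rng.normal(33.0, 5.2, size=father_rows.size)),
                    18, 70).astype(np.int64)

    f_start = np.where(linked[father_rows],
                       -180 - rng.integers(0, 120, size=father_rows.size),
                       -rng.integers(60, 170, size=father_rows.size))
    f_end = rng.integers(10, 200, size=father_rows.size)
    enroll_rows.append(pd.DataFrame({
        "person_id": father_id[father_rows], "start_day": f_start,
        "end_day": f_end, "rx_benefit": True,
    }))

    # a second, older qualifying male in ~1% of linked families exercises the
    # deterministic oldest-first tie-break without changing the link rate
    extra = linked & (rng.random(n) < 0.01)
    extra_rows = np.flatnonzero(extra)
    next_pid = n + father_rows.size
    extra_id = next_pid + np.arange(extra_rows.size)
    next_pid += extra_rows.size
    enroll_rows.append(pd.DataFrame({
        "person_id": extra_id,
        "start_day": -200 * np.ones(extra_rows.size, dtype=np.int64),
        "end_day": 100 * np.ones(extra_rows.size, dtype=np.int64),
        "rx_benefit": True,
    }))

    # --- infants ----------------------------------------------------------
    inf_rows = np.repeat(preg_id, n_fetuses)
    n_inf = inf_rows.size
    infant_id = next_pid + np.arange(n_inf)
    died = rng.random(n_inf) < config.infant_death_rate
    death_off = rng.integers(0, 90, size=n_inf)
    inf_end_preg = end_day[inf_rows]
    death_day = np.where(died, inf_end_preg + death_off, np.nan)
    short = viol_infant[inf_rows] & ~died
    inf_enroll_end = np.where(
        died, inf_end_preg + death_off,
        np.where(short,
                 inf_end_preg + rng.integers(0, 90, size=n_inf),
                 inf_end_preg + 90 + rng.integers(0, 120, size=n_inf)))
    enroll_rows.append(pd.DataFrame({
        "person_id": infant_id, "start_day": inf_end_preg,
        "end_day": inf_enroll_end.astype(np.int64), "rx_benefit": True,
    }))

    # --- persons table ----------------------------------------------------
    persons = pd.concat([
        pd.DataFrame({"person_id": mother_id, "sex": "F",
                      "birth_year": birth_year, "family_key": family_key}),
        pd.DataFrame({"person_id": father_id[father_rows], "sex": "M",
                      "birth_year": delivery_year[father_rows] - f_age,
                      "family_key": family_key[father_rows]}),
        pd.DataFrame({"person_id": extra_id, "sex": "M",
                      "birth_year": delivery_year[extra_rows] - 60,
                      "family_key": family_key[extra_rows]}),
        pd.DataFrame({"person_id": infant_id,
                      "sex": np.where(rng.random(n_inf) < 0.5, "F", "M"),
                      "birth_year": delivery_year[inf_rows],
                      "family_key": family_key[inf_rows]}),
    ], ignore_index=True)

    # --- code universe ----------------------------------------------------
    code_rows: list[dict] = []   # truth rows
    gem_rows: list[dict] = []
    dx_person: list[np.ndarray] = []
    dx_day: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []
    dx_vocab: list[np.ndarray] = []
    rx_person: list[np.ndarray] = []
    rx_day: list[np.ndarray] = []
    rx_code: list[np.ndarray] = []

    def register_dx_section(section: str) -> tuple[str, str]:
        """Synthetic ICD-9 full code and GEM-mapped ICD-10 code for a section."""
        icd9 = f"{section}.00"
        icd10 = f"Z{section}"
        gem_rows.append({"source": icd10, "target": icd9, "flags": "00000"})
        return icd9, icd10

    def emit_dx(present: np.ndarray, pid: np.ndarray, section: str,
                window: tuple[int, int], icd9: str, icd10: str) -> None:
        ppl, days = _emit_code_events(rng, present, pid, window)
        if ppl.size == 0:
            return
        use10 = rng.random(ppl.size) < 0.4
        dx_person.append(ppl)
        dx_day.append(days)
        dx_code.append(np.where(use10, icd10, icd9))
        dx_vocab.append(np.where(use10, "ICD10", "ICD9"))

    def emit_rx(present: np.ndarray, pid: np.ndarray, code: str,
                window: tuple[int, int]) -> None:
        ppl, days = _emit_code_events(rng, present, pid, window)
        if ppl.size == 0:
            return
        rx_person.append(ppl)
        rx_day.append(days)
        rx_code.append(np.full(ppl.size, code))

    # factor-emitted codes
    for f in factors:
        carr = carriers[f.name]
        if f.role == "paternal":
            pid = father_id
            active = carr & linked
        else:
            pid = mother_id
            active = carr
        for code, vocab, ep in f.emitted_codes:
            kind = "dx" if vocab == "dx-section" else "rx"
            window = WINDOWS[(f.role, kind)]
            present = active & (rng.random(n) < ep)
            if kind == "dx":
                icd9, icd10 = register_dx_section(code)
                emit_dx(present, pid, code, window, icd9, icd10)
            else:
                emit_rx(present, pid, code, window)
            code_rows.append({
                "code": code, "kind": kind, "role": f.role,
                "factor": f.name, "true_log_or": f.outcome_log_or,
            })

    # noise codes: heavy-tailed marginal frequencies, null for the outcome
    n_noise = config.n_noise_codes
    freqs = config.noise_max_freq * (np.arange(1, n_noise + 1) ** -0.8)
    for i in range(n_noise):
        kind = "dx" if i % 2 == 0 else "rx"
        code = f"{100 + i}" if kind == "dx" else f"T{i:04d}"
        fc = freqs[i]
        # maternal emissions
        window = WINDOWS[("maternal", kind)]
        present = rng.random(n) < fc
        if kind == "dx":
            icd9, icd10 = register_dx_section(code)
            emit_dx(present, mother_id, code, window, icd9, icd10)
        else:
            emit_rx(present, mother_id, code, window)
        # paternal emissions (fathers present in data, linked or decoy)
        windowp = WINDOWS[("paternal", kind)]
        presentp = has_father & (rng.random(n) < fc)
        if kind == "dx":
            emit_dx(presentp, father_id, code, windowp, icd9, icd10)
        else:
            emit_rx(presentp, father_id, code, windowp)
        code_rows.append({
            "code": code, "kind": kind, "role": "maternal",
            "factor": np.nan, "true_log_or": 0.0,
        })

    # --- infant outcome codes ---------------------------------------------
    inf_offset = np.zeros(n, dtype=np.int64)  # first-infant row offset
    inf_offset[1:] = np.cumsum(n_fetuses)[:-1]
    for fetus in range(2):
        mask = fetal_draws[:, fetus]
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        iids = infant_id[inf_offset[idx] + fetus]
        days = end_day[idx] + rng.integers(0, 61, size=idx.size)
        subtypes = [subtype_names[s] for s in sub_idx[idx]]
        use10 = rng.random(idx.size) < 0.5
        codes = np.array([
            DEFAULT_OUTCOME_CODES[s][1 if u else 0][0]
            for s, u in zip(subtypes, use10)
        ])
        dx_person.append(iids)
        dx_day.append(days)
        dx_code.append(codes)
        dx_vocab.append(np.where(use10, "ICD10", "ICD9"))

    # --- assemble ----------------------------------------------------------
    def cat(parts: list[np.ndarray], dtype=None) -> np.ndarray:
        if not parts:
            return np.empty(0, dtype=dtype if dtype is not None else np.int64)
        return np.concatenate(parts)

    dx = pd.DataFrame({
        "person_id": cat(dx_person),
        "day": cat(dx_day),
        "code": cat(dx_code, dtype=object),
        "vocabulary": cat(dx_vocab, dtype=object),
    })
    rx = pd.DataFrame({
        "person_id": cat(rx_person),
        "day": cat(rx_day),
        "code": cat(rx_code, dtype=object),
    })
    pregnancies = pd.DataFrame({
        "pregnancy_id": preg_id, "mother_id": mother_id,
        "lmp_day": np.zeros(n, dtype=np.int64), "end_day": end_day,
        "delivery_year": delivery_year, "n_fetuses": n_fetuses,
    })
    links = pd.DataFrame({
        "pregnancy_id": inf_rows, "infant_id": infant_id,
        "death_day": death_day,
    })
    gem = pd.DataFrame(gem_rows, columns=["source", "target", "flags"])
    gem = gem.drop_duplicates(subset="source", keep="first").reset_index(drop=True)
    enroll = pd.concat(enroll_rows, ignore_index=True)
    enroll["start_day"] = enroll["start_day"].astype(np.int64)
    enroll["end_day"] = enroll["end_day"].astype(np.int64)

    cohort = ClaimsCohort(
        persons=persons, enroll=enroll, dx=dx, rx=rx,
        pregnancies=pregnancies, links=links, gem=gem,
    )
    truth = GroundTruth(
        codes=pd.DataFrame(
            code_rows, columns=["code", "kind", "role", "factor", "true_log_or"]
        ),
        carriers=pd.DataFrame(
            {"pregnancy_id": preg_id, **{k: v for k, v in carriers.items()}}
        ),
        violations=pd.DataFrame({
            "pregnancy_id": preg_id,
            "maternal_enrollment": viol_enroll,
            "rx_benefit": viol_rx,
            "infant_followup": viol_infant,
            "maternal_age": viol_age,
        }),
        implied_outcome_rate=implied,
        intercept=float(intercept),
    )
    return cohort, truth


# --------------------------------------------------------------------------
# cohort <-> directory-of-TSVs round trip
# --------------------------------------------------------------------------

_TABLES = {
    "persons": "persons.tsv",
    "enroll": "enroll.tsv",
    "dx": "dx_events.tsv",
    "rx": "rx_events.tsv",
    "pregnancies": "pregnancies.tsv",
    "links": "links.tsv",
    "gem": "gem.tsv",
}


def write_cohort(cohort: ClaimsCohort, outdir: str | Path,
                 truth: GroundTruth | None = None,
                 config: SimConfig | None = None) -> Path:
    """Write the cohort (and optionally truth/config) as delimited tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLES.items():
        getattr(cohort, attr).to_csv(outdir / fname, sep="\t", index=False)
    if truth is not None:
        planted_truth_report(truth).merge(
            truth.codes[["code", "kind", "role"]], on="code"
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if config is not None:
        d = asdict(config)
        d["factors"] = [asdict(f) for f in config.factors]
        (outdir / "config.json").write_text(json.dumps(d, indent=2))
    return outdir


def read_cohort(indir: str | Path) -> ClaimsCohort:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    kw: dict[str, dict] = {
        "persons": {"dtype": {"person_id": np.int64, "sex": str,
                              "birth_year": np.int64, "family_key": np.int64}},
        "enroll": {"dtype": {"person_id": np.int64, "start_day": np.int64,
                             "end_day": np.int64, "rx_benefit": bool}},
        "dx": {"dtype": {"person_id": np.int64, "day": np.int64,
                         "code": str, "vocabulary": str}},
        "rx": {"dtype": {"person_id": np.int64, "day": np.int64, "code": str}},
        "pregnancies": {"dtype": {c: np.int64 for c in (
            "pregnancy_id", "mother_id", "lmp_day", "end_day",
            "delivery_year", "n_fetuses")}},
        "links": {"dtype": {"pregnancy_id": np.int64, "infant_id": np.int64,
                            "death_day": float}},
        "gem": {"dtype": str},
    }
    frames = {
        attr: pd.read_csv(indir / fname, sep="\t", **kw[attr])
        for attr, fname in _TABLES.items()
    }
    return ClaimsCohort(**frames)


# --------------------------------------------------------------------------
# default planted scenario
# --------------------------------------------------------------------------

def default_factors() -> list[LatentFactorSpec]:
    """The default planted scenario: four maternal latent factors.

    Effect sizes echo well-replicated claims findings -- pregestational
    diabetes (OR 2.2 at 1.4% prevalence, emitting diagnosis, insulin, and
    retinopathy codes), chronic hypertension (OR 1.52), supervision of a
    high-risk pregnancy (OR 1.29 at 25% prevalence), and a fertility-treatment
    proxy whose only path to the outcome is multiple gestation.
    """
    return [
        LatentFactorSpec(
            name="diabetes",
            emitted_codes=(("250", "dx-section", 1.0),
                           ("T9001", "tdc", 0.6),     # insulin
                           ("362", "dx-section", 0.15)),  # retinopathy
            carrier_prevalence=0.014,
            outcome_log_or=float(np.log(2.2)),
        ),
        LatentFactorSpec(
            name="hypertension",
            emitted_codes=(("401", "dx-section", 0.9),
                           ("T9002", "tdc", 0.4)),     # ACE inhibitor
            carrier_prevalence=0.028,
            outcome_log_or=float(np.log(1.52)),
        ),
        LatentFactorSpec(
            name="high_risk_supervision",
            emitted_codes=(("V23", "dx-section", 0.9),),
            carrier_prevalence=0.25,
            outcome_log_or=float(np.log(1.29)),
        ),
        LatentFactorSpec(
            name="fertility_treatment",
            emitted_codes=(("T9003", "tdc", 0.8),      # gonadotropin
                           ("628", "dx-section", 0.5)),
            carrier_prevalence=0.02,
            outcome_log_or=0.0,
            multiple_gestation_log_or=2.5,
        ),
    ]


def default_config(n_pregnancies: int = 50_000, seed: int = 0,
                   **overrides) -> SimConfig:
    """Default study conditions with the planted scenario of default_factors."""
    kw = dict(
        n_pregnancies=n_pregnancies,
        n_noise_codes=100,
        factors=tuple(default_factors()),
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)
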