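"""Cohort construction: eligibility, father linkage, code mapping, exposure
panels, outcome flagging, and sensitivity restrictions.

Operates on any :class:`~cardioscreen.simulate.ClaimsCohort`-shaped relational
bundle, synthetic or real.  All exposure windows are closed intervals on
integer day offsets relative to each pregnancy's LMP (day 0).

Eligibility rules applied, in order:

1. at least one linked infant (a pregnancy without one signals upstream
   linkage failure and is excluded with its own tally category);
2. maternal continuous enrollment from 180 days before LMP to pregnancy end
   plus 30 days;
3. maternal medication (rx) benefits from 180 days before LMP to pregnancy
   end;
4. every linked infant enrolled through 90 days after pregnancy end, except
   infants who died earlier and were enrolled to death;
5. maternal age 12-55 at delivery.

Fathers are linked through the shared family key and delivery year and must
hold continuous rx-benefit enrollment over [LMP-180, LMP]; when several males
qualify the oldest is chosen (deterministic, logged).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .simulate import ClaimsCohort, ConfigError, DEFAULT_OUTCOME_CODES

logger = logging.getLogger(__name__)

#: Sentinel returned for ICD-10 codes absent from the GEM crosswalk.
UNMAPPED = "UNMAPPED"

#: Exposure-window presets, closed day offsets relative to LMP.
#: "main" assesses diagnoses over the 180 days before LMP through the first
#: trimester (mothers) or through LMP (fathers) and medications over the first
#: trimester (mothers) or spermatogenesis window (fathers); "acute" narrows
#: diagnosis windows to the same spans as medications.
WINDOW_PRESETS: dict[str, dict[str, tuple[int, int]]] = {
    "main": {
        "maternal-dx": (-180, 90),
        "maternal-rx": (0, 90),
        "paternal-dx": (-180, 0),
        "paternal-rx": (-90, 0),
    },
    "acute": {
        "maternal-dx": (0, 90),
        "maternal-rx": (0, 90),
        "paternal-dx": (-90, 0),
        "paternal-rx": (-90, 0),
    },
}


@dataclass(frozen=True)
class EligibilityConfig:
    pre_lmp_days: int = 180
    post_end_days: int = 30
    infant_followup_days: int = 90
    paternal_pre_lmp_days: int = 180
    age_min: int = 12
    age_max: int = 55

    def validate(self) -> None:
        for name in ("pre_lmp_days", "post_end_days", "infant_followup_days",
                     "paternal_pre_lmp_days"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WindowSpec:
    """An exposure window: role in {maternal,paternal}-{dx,rx}, closed offsets."""

    role: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.role not in ("maternal-dx", "maternal-rx",
                             "paternal-dx", "paternal-rx"):
            raise ConfigError(f"invalid window role {self.role!r}")
        if self.start > self.end:
            raise ConfigError(
                f"window start {self.start} exceeds end {self.end}")

    @property
    def parent(self) -> str:
        return self.role.split("-")[0]

    @property
    def kind(self) -> str:
        return self.role.split("-")[1]


@dataclass
class CovariatePanel:
    """Sparse pregnancy x code exposure matrices for one role and code kind.

    ``indicators[i, j] == 1`` iff ``counts[i, j] >= threshold``; the two
    matrices share shape and index.
    """

    pregnancy_ids: np.ndarray
    codes: pd.DataFrame  # columns: code, kind, role
    counts: sparse.csr_matrix
    indicators: sparse.csr_matrix
    threshold: int
    window: WindowSpec
    n_dropped_no_father: int = 0
    n_unmapped_events: int = 0

    @property
    def prevalence(self) -> np.ndarray:
        """Number of pregnancies with indicator 1 per code."""
        return np.asarray(self.indicators.sum(axis=0)).ravel()


# --------------------------------------------------------------------------
# GEM crosswalk
# --------------------------------------------------------------------------

class GEMap:
    """ICD-10 -> ICD-9 3-digit-section crosswalk.

    When one source code lists several targets, the first-listed target's
    section is used; the code is tallied as ambiguous only if the targets
    disagree at the 3-digit-section level.
    """

    def __init__(self, table: pd.DataFrame):
        self._map: dict[str, str] = {}
        self.ambiguous: set[str] = set()
        self.unmapped_queries = 0
        for source, grp in table.groupby("source", sort=False):
            sections = [icd9_section(t) for t in grp["target"]]
            self._map[source] = sections[0]
            if len(set(sections)) > 1:
                self.ambiguous.add(source)

    def section(self, code: str) -> str:
        sec = self._map.get(code)
        if sec is None:
            self.unmapped_queries += 1
            return UNMAPPED
        return sec

    def __contains__(self, code: str) -> bool:
        return code in self._map


def icd9_section(code: str) -> str:
    """3-digit ICD-9 section: the first three characters of the code."""
    return str(code).strip()[:3]


def load_gem(path) -> GEMap:
    """Load a whitespace-delimited GEM file of (source, target, flags) rows."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: malformed GEM row at line {lineno}: {line!r}")
            rows.append({"source": parts[0], "target": parts[1],
                         "flags": parts[2] if len(parts) > 2 else ""})
    # header row tolerance
    if rows and rows[0]["source"].lower() in ("source", "icd10"):
        rows = rows[1:]
    return GEMap(pd.DataFrame(rows, columns=["source", "target", "flags"]))


def gem_from_frame(table: pd.DataFrame) -> GEMap:
    """Build a GEMap from an in-memory (source, target, flags) DataFrame."""
    return GEMap(table)


def map_icd10_to_icd9_section(code: str, gem: GEMap) -> str:
    """GEM-map one ICD-10 code to its ICD-9 3-digit section (or sentinel)."""
    return gem.section(code)


def _dx_with_sections(dx: pd.DataFrame, gem: GEMap) -> pd.DataFrame:
    """dx events + 'section' column (ICD-9 prefix or GEM-mapped), tallying
    unmapped ICD-10 codes via the GEMap."""
    is9 = dx["vocabulary"].to_numpy() == "ICD9"
    codes = dx["code"].to_numpy()
    section = np.empty(len(dx), dtype=object)
    section[is9] = [icd9_section(c) for c in codes[is9]]
    section[~is9] = [gem.section(c) for c in codes[~is9]]
    out = dx.copy()
    out["section"] = section
    return out


# --------------------------------------------------------------------------
# continuous-enrollment coverage
# --------------------------------------------------------------------------

def _merged_spans(enroll: pd.DataFrame, rx_only: bool = False) -> pd.DataFrame:
    """Merge each person's enrollment spans; spans touching or overlapping
    (gap <= 0 days, i.e. next start <= previous end + 1) are continuous."""
    df = enroll[enroll["rx_benefit"]] if rx_only else enroll
    if df.empty:
        return pd.DataFrame(columns=["person_id", "start_day", "end_day"])
    df = df.sort_values(["person_id", "start_day", "end_day"],
                        kind="mergesort").reset_index(drop=True)
    pid = df["person_id"].to_numpy()
    start = df["start_day"].to_numpy()
    cummax_end = df.groupby("person_id")["end_day"].cummax().to_numpy()
    prev_reach = np.empty(len(df), dtype=np.int64)
    prev_reach[0] = np.iinfo(np.int64).min
    prev_reach[1:] = cummax_end[:-1]
    new_person = np.empty(len(df), dtype=bool)
    new_person[0] = True
    new_person[1:] = pid[1:] != pid[:-1]
    new_group = new_person | (start > prev_reach + 1)
    gid = np.cumsum(new_group)
    merged = df.assign(_gid=gid).groupby("_gid").agg(
        person_id=("person_id", "first"),
        start_day=("start_day", "min"),
        end_day=("end_day", "max"),
    ).reset_index(drop=True)
    return merged


def _covers(merged: pd.DataFrame, person_ids: np.ndarray,
            starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """True where some merged span of person i covers [starts[i], ends[i]]."""
    q = pd.DataFrame({"person_id": person_ids, "_qs": starts, "_qe": ends,
                      "_row": np.arange(len(person_ids))})
    j = q.merge(merged, on="person_id", how="left")
    ok = (j["start_day"] <= j["_qs"]) & (j["end_day"] >= j["_qe"])
    covered = np.zeros(len(q), dtype=bool)
    rows = j.loc[ok.fillna(False), "_row"].to_numpy()
    covered[rows] = True
    return covered


# --------------------------------------------------------------------------
# eligibility
# --------------------------------------------------------------------------

def apply_eligibility(
    cohort: ClaimsCohort, cfg: EligibilityConfig = EligibilityConfig()
) -> tuple[set[int], "OrderedDict[str, int]"]:
    """Apply the eligibility rules; return (eligible ids, per-rule tally).

    Each excluded pregnancy is counted once, under the first rule (in
    application order) it fails; the final eligible *set* is order-invariant.
    """
    cfg.validate()
    preg = cohort.pregnancies
    tally: OrderedDict[str, int] = OrderedDict(
        (k, 0) for k in ("no_linked_infant", "maternal_enrollment",
                         "rx_benefit", "infant_followup", "maternal_age"))
    if preg.empty:
        return set(), tally

    n = len(preg)
    lmp = preg["lmp_day"].to_numpy()
    end = preg["end_day"].to_numpy()
    mother = preg["mother_id"].to_numpy()

    # rule 1: linked infant exists
    has_infant = preg["pregnancy_id"].isin(cohort.links["pregnancy_id"]).to_numpy()

    merged_all = _merged_spans(cohort.enroll)
    merged_rx = _merged_spans(cohort.enroll, rx_only=True)

    # rule 2: maternal enrollment [LMP - pre, end + post]
    enroll_ok = _covers(merged_all, mother,
                        lmp - cfg.pre_lmp_days, end + cfg.post_end_days)

    # rule 3: rx benefits [LMP - pre, end]
    rx_ok = _covers(merged_rx, mother, lmp - cfg.pre_lmp_days, end)

    # rule 4: every linked infant followed to end + fu, or death exception
    links = cohort.links.merge(
        preg[["pregnancy_id", "end_day"]], on="pregnancy_id")
    fu_end = links["end_day"].to_numpy() + cfg.infant_followup_days
    death = links["death_day"].to_numpy(dtype=float)
    died_early = np.isfinite(death) & (death <= fu_end)
    target = np.where(died_early, np.fmax(death, links["end_day"].to_numpy()),
                      fu_end).astype(np.int64)
    inf_ok = _covers(merged_all, links["infant_id"].to_numpy(),
                     links["end_day"].to_numpy(), target)
    inf_ok_by_preg = pd.Series(inf_ok).groupby(
        links["pregnancy_id"].to_numpy()).all()
    infant_ok = preg["pregnancy_id"].map(inf_ok_by_preg).to_numpy()
    infant_ok = np.where(pd.isna(infant_ok), False, infant_ok).astype(bool)

    # rule 5: maternal age at delivery in bounds
    birth_year = preg.merge(
        cohort.persons[["person_id", "birth_year"]],
        left_on="mother_id", right_on="person_id", how="left"
    )["birth_year"].to_numpy()
    age = preg["delivery_year"].to_numpy() - birth_year
    age_ok = (age >= cfg.age_min) & (age <= cfg.age_max)

    rules = [("no_linked_infant", has_infant),
             ("maternal_enrollment", enroll_ok),
             ("rx_benefit", rx_ok),
             ("infant_followup", infant_ok),
             ("maternal_age", age_ok)]
    alive = np.ones(n, dtype=bool)
    for name, ok in rules:
        fail = alive & ~ok
        tally[name] = int(fail.sum())
        alive &= ok
    eligible = set(preg.loc[alive, "pregnancy_id"].tolist())
    return eligible, tally


def link_fathers(
    cohort: ClaimsCohort, eligible: set[int],
    cfg: EligibilityConfig = EligibilityConfig(),
) -> dict[int, int]:
    """Link each eligible pregnancy to a father, where one qualifies.

    The father is the adult male sharing the mother's family key in the
    delivery year, continuously enrolled with rx benefits over
    [LMP - 180, LMP].  Ties (several qualifying males) are broken
    deterministically: oldest first, then smallest person id; ties are logged.
    """
    preg = cohort.pregnancies[
        cohort.pregnancies["pregnancy_id"].isin(eligible)]
    if preg.empty:
        return {}
    persons = cohort.persons
    mothers = preg.merge(persons[["person_id", "family_key"]],
                         left_on="mother_id", right_on="person_id")
    males = persons[persons["sex"] == "M"][
        ["person_id", "birth_year", "family_key"]]
    cand = mothers[["pregnancy_id", "lmp_day", "delivery_year",
                    "family_key"]].merge(males, on="family_key")
    if cand.empty:
        return {}
    # adult at delivery
    cand = cand[cand["delivery_year"] - cand["birth_year"] >= 18]
    if cand.empty:
        return {}
    merged_rx = _merged_spans(cohort.enroll, rx_only=True)
    ok = _covers(merged_rx, cand["person_id"].to_numpy(),
                 cand["lmp_day"].to_numpy() - cfg.paternal_pre_lmp_days,
                 cand["lmp_day"].to_numpy())
    cand = cand[ok]
    if cand.empty:
        return {}
    cand = cand.sort_values(["pregnancy_id", "birth_year", "person_id"],
                            kind="mergesort")
    multi = cand["pregnancy_id"].duplicated(keep=False)
    if multi.any():
        n_tied = cand.loc[multi, "pregnancy_id"].nunique()
        logger.info("father tie-break (oldest first) applied to %d pregnancies",
                    n_tied)
    first = cand.drop_duplicates("pregnancy_id", keep="first")
    return dict(zip(first["pregnancy_id"].astype(int),
                    first["person_id"].astype(int)))


# --------------------------------------------------------------------------
# covariate panels
# --------------------------------------------------------------------------

def derive_panel(
    cohort: ClaimsCohort,
    pregnancy_ids,
    window: WindowSpec,
    gem: GEMap | None = None,
    threshold: int = 1,
    father_map: dict[int, int] | None = None,
) -> CovariatePanel:
    """Count in-window code events per pregnancy and build the sparse panel.

    Diagnosis codes are reduced to ICD-9 3-digit sections first (direct
    prefix for ICD-9, GEM crosswalk for ICD-10; unmappable events are dropped
    and tallied).  Pregnancies without a linked father are dropped from
    paternal panels and tallied.
    """
    if threshold < 1:
        raise ConfigError(f"threshold must be >= 1, got {threshold}")
    preg = cohort.pregnancies[
        cohort.pregnancies["pregnancy_id"].isin(set(pregnancy_ids))]
    preg = preg.sort_values("pregnancy_id").reset_index(drop=True)
    n_dropped = 0
    if window.parent == "maternal":
        pframe = preg[["pregnancy_id", "mother_id", "lmp_day"]].rename(
            columns={"mother_id": "person_id"})
    else:
        if father_map is None:
            raise ConfigError("paternal panel requested without a father map")
        pframe = preg[["pregnancy_id", "lmp_day"]].copy()
        pframe["person_id"] = pframe["pregnancy_id"].map(father_map)
        n_dropped = int(pframe["person_id"].isna().sum())
        pframe = pframe.dropna(subset=["person_id"])
        pframe["person_id"] = pframe["person_id"].astype(np.int64)

    n_unmapped = 0
    if window.kind == "dx":
        if gem is None:
            gem = gem_from_frame(cohort.gem)
        ev = _dx_with_sections(cohort.dx, gem)
        n_unmapped = int((ev["section"] == UNMAPPED).sum())
        ev = ev[ev["section"] != UNMAPPED]
        ev = ev.rename(columns={"section": "panel_code"})[
            ["person_id", "day", "panel_code"]]
    else:
        ev = cohort.rx.rename(columns={"code": "panel_code"})[
            ["person_id", "day", "panel_code"]]

    j = pframe.merge(ev, on="person_id", how="inner")
    day_off = j["day"] - j["lmp_day"]
    j = j[(day_off >= window.start) & (day_off <= window.end)]

    preg_ids = pframe["pregnancy_id"].to_numpy()
    codes_sorted = np.array(sorted(j["panel_code"].unique()), dtype=object)
    code_pos = {c: i for i, c in enumerate(codes_sorted)}
    row = j["pregnancy_id"].map(
        {p: i for i, p in enumerate(preg_ids)}).to_numpy()
    col = j["panel_code"].map(code_pos).to_numpy()
    counts = sparse.coo_matrix(
        (np.ones(len(j), dtype=np.int64), (row, col)),
        shape=(len(preg_ids), len(codes_sorted))).tocsr()
    counts.sum_duplicates()
    ind = counts.copy()
    ind.data = (ind.data >= threshold).astype(np.int8)
    ind.eliminate_zeros()

    codes_df = pd.DataFrame({
        "code": codes_sorted,
        "kind": window.kind,
        "role": window.parent,
    })
    return CovariatePanel(
        pregnancy_ids=preg_ids, codes=codes_df, counts=counts,
        indicators=ind, threshold=threshold, window=window,
        n_dropped_no_father=n_dropped, n_unmapped_events=n_unmapped,
    )


def select_top_codes(panel: CovariatePanel, k: int = 500) -> CovariatePanel:
    """Retain the k most prevalent codes (pregnancies with indicator 1).

    Ties at rank k break by lexicographically smaller code id.  If fewer than
    k codes exist, all are retained.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    prev = panel.prevalence
    order = sorted(range(len(prev)),
                   key=lambda i: (-prev[i], panel.codes["code"].iat[i]))
    keep = sorted(order[:k])
    return CovariatePanel(
        pregnancy_ids=panel.pregnancy_ids,
        codes=panel.codes.iloc[keep].reset_index(drop=True),
        counts=panel.counts[:, keep].tocsr(),
        indicators=panel.indicators[:, keep].tocsr(),
        threshold=panel.threshold,
        window=panel.window,
        n_dropped_no_father=panel.n_dropped_no_father,
        n_unmapped_events=panel.n_unmapped_events,
    )


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def flag_outcomes(
    cohort: ClaimsCohort,
    pregnancy_ids,
    code_lists: dict[str, list[tuple[str, str]]],
    follow_up_days: int = 90,
) -> pd.DataFrame:
    """Pregnancy-level outcome flags from infant code lists.

    A pregnancy is flagged for outcome ``name`` iff any linked infant has a
    qualifying (code, vocabulary) event within [pregnancy end, end +
    follow_up_days] (closed).  Multiple infants' records are unioned: presence
    is counted at the pregnancy level.  Subtype flags are independent and
    non-exclusive.
    """
    for name, lst in code_lists.items():
        if not lst:
            raise ConfigError(f"outcome code list {name!r} is empty")
    ids = sorted(set(pregnancy_ids))
    out = pd.DataFrame(index=pd.Index(ids, name="pregnancy_id"))
    preg = cohort.pregnancies[cohort.pregnancies["pregnancy_id"].isin(ids)]
    links = cohort.links.merge(
        preg[["pregnancy_id", "end_day"]], on="pregnancy_id")
    ev = links.merge(cohort.dx, left_on="infant_id", right_on="person_id")
    if not ev.empty:
        ev = ev[(ev["day"] >= ev["end_day"]) &
                (ev["day"] <= ev["end_day"] + follow_up_days)]
    for name, lst in code_lists.items():
        if ev.empty:
            out[name] = False
            continue
        keys = set((c, v) for c, v in lst)
        hit = [
            (c, v) in keys
            for c, v in zip(ev["code"].to_numpy(), ev["vocabulary"].to_numpy())
        ]
        flagged = set(ev.loc[hit, "pregnancy_id"].tolist())
        out[name] = [p in flagged for p in ids]
    return out


def default_code_lists() -> dict[str, list[tuple[str, str]]]:
    """Primary cardiac-malformation list plus the 11 subtype lists."""
    lists: dict[str, list[tuple[str, str]]] = {
        "primary": [c for lst in DEFAULT_OUTCOME_CODES.values() for c in lst]
    }
    lists.update({k: list(v) for k, v in DEFAULT_OUTCOME_CODES.items()})
    return lists


# --------------------------------------------------------------------------
# sensitivity restrictions
# --------------------------------------------------------------------------

#: Default marker sections for the restriction filters.
DEFAULT_RESTRICTION_MARKERS: dict[str, list[str]] = {
    "no-chromosomal": ["758"],
    "no-diabetes": ["250"],
    "no-parental-malformation": ["745", "746", "747"],
}

RESTRICTIONS = ("no-chromosomal", "singleton", "no-diabetes",
                "no-parental-malformation")


def apply_restriction(
    cohort: ClaimsCohort,
    pregnancy_ids,
    restriction: str,
    markers: dict[str, list[str]] | None = None,
    father_map: dict[int, int] | None = None,
    gem: GEMap | None = None,
) -> set[int]:
    """Set-theoretic sensitivity filter; restrictions compose by chaining.

    ``singleton`` keeps n_fetuses == 1.  Marker-based restrictions drop
    pregnancies whose mother (and, for parental malformation, linked father)
    has a marker dx section recorded: maternal markers are assessed over
    [LMP-180, LMP+90], parental-malformation markers over the 6 months before
    LMP ([LMP-180, LMP]).
    """
    if restriction not in RESTRICTIONS:
        raise ConfigError(f"unknown restriction {restriction!r}")
    ids = set(pregnancy_ids)
    preg = cohort.pregnancies[cohort.pregnancies["pregnancy_id"].isin(ids)]
    if restriction == "singleton":
        return set(preg.loc[preg["n_fetuses"] == 1, "pregnancy_id"].tolist())

    markers = {**DEFAULT_RESTRICTION_MARKERS, **(markers or {})}
    sections = set(markers[restriction])
    if gem is None:
        gem = gem_from_frame(cohort.gem)
    ev = _dx_with_sections(cohort.dx, gem)
    ev = ev[ev["section"].isin(sections)]

    if restriction == "no-parental-malformation":
        lo, hi = -180, 0
        frames = [preg[["pregnancy_id", "mother_id", "lmp_day"]].rename(
            columns={"mother_id": "person_id"})]
        if father_map:
            f = preg[["pregnancy_id", "lmp_day"]].copy()
            f["person_id"] = f["pregnancy_id"].map(father_map)
            frames.append(f.dropna(subset=["person_id"]).astype(
                {"person_id": np.int64}))
        pframe = pd.concat(frames, ignore_index=True)
    else:
        lo, hi = -180, 90
        pframe = preg[["pregnancy_id", "mother_id", "lmp_day"]].rename(
            columns={"mother_id": "person_id"})

    j = pframe.merge(ev[["person_id", "day"]], on="person_id")
    off = j["day"] - j["lmp_day"]
    marked = set(j.loc[(off >= lo) & (off <= hi), "pregnancy_id"].tolist())
    return ids - marked
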