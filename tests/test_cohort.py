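"""Eligibility, linkage, mapping, panel and restriction logic on hand-built
micro-cohorts plus property checks on the synthetic mid cohort."""

import numpy as np
import pandas as pd
import pytest

import cardioscreen as cs
from cardioscreen import cohort as cb
from cardioscreen.simulate import ConfigError

from conftest import base_family, make_cohort


def family_cohort(**kw):
    persons, enroll, pregnancies, links = base_family(**kw)
    return make_cohort(persons=persons, enroll=enroll,
                       pregnancies=pregnancies, links=links)


class TestEligibility:
    def test_fully_eligible_family_retained(self):
        cohort = family_cohort()
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == {0}
        assert all(v == 0 for v in tally.values())

    def test_infant_enrolled_only_60_days_excluded(self):
        cohort = family_cohort()
        cohort.enroll.loc[cohort.enroll["person_id"] == 2, "end_day"] = 273 + 60
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == set()
        assert tally["infant_followup"] == 1

    def test_infant_death_exception_retained(self):
        cohort = family_cohort()
        cohort.links.loc[0, "death_day"] = 273 + 10
        cohort.enroll.loc[cohort.enroll["person_id"] == 2, "end_day"] = 273 + 10
        eligible, _ = cs.apply_eligibility(cohort)
        assert eligible == {0}

    def test_maternal_enrollment_must_start_by_minus_180(self):
        cohort = family_cohort()
        cohort.enroll.loc[cohort.enroll["person_id"] == 0, "start_day"] = -179
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == set() and tally["maternal_enrollment"] == 1
        cohort.enroll.loc[cohort.enroll["person_id"] == 0, "start_day"] = -180
        eligible, _ = cs.apply_eligibility(cohort)
        assert eligible == {0}

    def test_contiguous_spans_count_as_continuous(self):
        cohort = family_cohort()
        m = cohort.enroll["person_id"] == 0
        cohort.enroll.loc[m, "end_day"] = 50
        cohort.enroll = pd.concat([cohort.enroll, pd.DataFrame([
            {"person_id": 0, "start_day": 51, "end_day": 700,
             "rx_benefit": True}])], ignore_index=True)
        eligible, _ = cs.apply_eligibility(cohort)
        assert eligible == {0}
        # a one-day gap breaks continuity
        cohort.enroll.loc[cohort.enroll["start_day"] == 51, "start_day"] = 52
        eligible, _ = cs.apply_eligibility(cohort)
        assert eligible == set()

    def test_rx_benefit_required_through_pregnancy_end(self):
        cohort = family_cohort()
        m = cohort.enroll["person_id"] == 0
        cohort.enroll.loc[m, "rx_benefit"] = False
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == set() and tally["rx_benefit"] == 1

    def test_age_bounds(self):
        for age, ok in ((12, True), (11, False), (55, True), (56, False)):
            cohort = family_cohort(mother_age=age)
            eligible, _ = cs.apply_eligibility(cohort)
            assert (eligible == {0}) is ok

    def test_pregnancy_without_infant_gets_own_tally(self):
        cohort = family_cohort()
        cohort.links = cohort.links.iloc[0:0]
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == set() and tally["no_linked_infant"] == 1

    def test_empty_cohort(self):
        cohort = make_cohort()
        eligible, tally = cs.apply_eligibility(cohort)
        assert eligible == set() and all(v == 0 for v in tally.values())

    def test_final_set_order_invariant(self, mid_prepared):
        # tallies depend on rule order; the surviving set must not
        d = mid_prepared
        eligible2, _ = cs.apply_eligibility(d["cohort"])
        assert eligible2 == d["eligible"]


class TestLinkFathers:
    def test_qualifying_father_linked(self):
        cohort = family_cohort()
        assert cs.link_fathers(cohort, {0}) == {0: 1}

    def test_enrollment_gap_inside_window_blocks_link(self):
        cohort = family_cohort()
        m = cohort.enroll["person_id"] == 1
        cohort.enroll.loc[m, "start_day"] = -170  # gap in [-180, -171]
        assert cs.link_fathers(cohort, {0}) == {}

    def test_tie_break_prefers_oldest(self):
        persons, enroll, pregnancies, links = base_family()
        persons.append({"person_id": 9, "sex": "M", "birth_year": 1970,
                        "family_key": 0})
        enroll.append({"person_id": 9, "start_day": -400, "end_day": 100,
                       "rx_benefit": True})
        cohort = make_cohort(persons=persons, enroll=enroll,
                             pregnancies=pregnancies, links=links)
        assert cs.link_fathers(cohort, {0}) == {0: 9}

    def test_link_rate_close_to_planted(self, mid_prepared):
        d = mid_prepared
        rate = len(d["father_map"]) / len(d["ids"])
        sd = np.sqrt(0.704 * 0.296 / len(d["ids"]))
        assert abs(rate - 0.704) < 3 * sd


class TestGemMapping:
    def test_icd9_section_is_prefix(self):
        assert cb.icd9_section("250.00") == "250"
        assert cb.icd9_section("V23.41") == "V23"

    def test_mapping_and_sentinel(self, tmp_path):
        gem_file = tmp_path / "gem.txt"
        gem_file.write_text(
            "E119 250.00 00000\n"
            "I10X 401.0 00000\n"
        )
        gem = cb.load_gem(gem_file)
        assert cb.map_icd10_to_icd9_section("E119", gem) == "250"
        assert cb.map_icd10_to_icd9_section("ZZZZ", gem) == cb.UNMAPPED
        assert gem.unmapped_queries == 1

    def test_multi_target_same_section_not_ambiguous(self, tmp_path):
        gem_file = tmp_path / "gem.txt"
        gem_file.write_text(
            "I10A 401.0 00000\n"
            "I10A 401.9 00000\n"
            "I10B 402.0 00000\n"
            "I10B 403.0 00000\n"
        )
        gem = cb.load_gem(gem_file)
        assert gem.section("I10A") == "401"
        assert "I10A" not in gem.ambiguous
        # disagreeing sections: first-listed target wins, flagged ambiguous
        assert gem.section("I10B") == "402"
        assert "I10B" in gem.ambiguous

    def test_malformed_row_reports_line_number(self, tmp_path):
        gem_file = tmp_path / "gem.txt"
        gem_file.write_text("E119 250.00 00000\nbadrow\n")
        with pytest.raises(ValueError, match="line 2"):
            cb.load_gem(gem_file)


def panel_cohort(dx=None, rx=None):
    persons, enroll, pregnancies, links = base_family()
    gem = [{"source": "Z250", "target": "250.00", "flags": "00000"}]
    return make_cohort(persons=persons, enroll=enroll, dx=dx, rx=rx,
                       pregnancies=pregnancies, links=links, gem=gem)


class TestDerivePanel:
    def test_window_endpoints_inclusive(self):
        rx = [{"person_id": 0, "day": 90, "code": "T1"}]
        cohort = panel_cohort(rx=rx)
        p = cs.derive_panel(cohort, [0], cb.WindowSpec("maternal-rx", 0, 90))
        assert p.indicators.toarray().tolist() == [[1]]

    def test_event_one_day_outside_window_excluded(self):
        dx = [{"person_id": 0, "day": -181, "code": "250.00",
               "vocabulary": "ICD9"}]
        cohort = panel_cohort(dx=dx)
        p = cs.derive_panel(cohort, [0],
                            cb.WindowSpec("maternal-dx", -180, 90))
        assert p.counts.nnz == 0

    def test_occurrence_threshold(self):
        rx = [{"person_id": 0, "day": 10, "code": "T1"},
              {"person_id": 0, "day": 20, "code": "T1"},
              {"person_id": 0, "day": 30, "code": "T2"}]
        cohort = panel_cohort(rx=rx)
        w = cb.WindowSpec("maternal-rx", 0, 90)
        p1 = cs.derive_panel(cohort, [0], w, threshold=1)
        p2 = cs.derive_panel(cohort, [0], w, threshold=2)
        t1 = dict(zip(p1.codes["code"], p1.indicators.toarray()[0]))
        t2 = dict(zip(p2.codes["code"], p2.indicators.toarray()[0]))
        assert t1 == {"T1": 1, "T2": 1}
        assert t2 == {"T1": 1, "T2": 0}

    def test_icd10_goes_through_gem(self):
        dx = [{"person_id": 0, "day": 5, "code": "Z250",
               "vocabulary": "ICD10"}]
        cohort = panel_cohort(dx=dx)
        p = cs.derive_panel(cohort, [0],
                            cb.WindowSpec("maternal-dx", -180, 90))
        assert list(p.codes["code"]) == ["250"]

    def test_paternal_panel_drops_unlinked(self):
        rx = [{"person_id": 1, "day": -30, "code": "T1"}]
        cohort = panel_cohort(rx=rx)
        p = cs.derive_panel(cohort, [0], cb.WindowSpec("paternal-rx", -90, 0),
                            father_map={})
        assert len(p.pregnancy_ids) == 0 and p.n_dropped_no_father == 1
        p = cs.derive_panel(cohort, [0], cb.WindowSpec("paternal-rx", -90, 0),
                            father_map={0: 1})
        assert p.indicators.toarray().tolist() == [[1]]

    def test_threshold_dominance_and_window_monotonicity(self, mid_prepared):
        d = mid_prepared
        w = cb.WindowSpec("maternal-dx", -180, 90)
        p1 = cs.derive_panel(d["cohort"], d["ids"], w, gem=d["gem"],
                             threshold=1)
        p2 = cs.derive_panel(d["cohort"], d["ids"], w, gem=d["gem"],
                             threshold=2)
        assert (p2.indicators.toarray() <= p1.indicators.toarray()).all()
        # shrinking the window never increases any count
        ws = cb.WindowSpec("maternal-dx", -90, 45)
        ps = cs.derive_panel(d["cohort"], d["ids"], ws, gem=d["gem"])
        common = [c for c in ps.codes["code"] if c in set(p1.codes["code"])]
        a = pd.DataFrame(p1.counts.toarray(), columns=p1.codes["code"])
        b = pd.DataFrame(ps.counts.toarray(), columns=ps.codes["code"])
        assert (b[common].to_numpy() <= a[common].to_numpy()).all()


class TestSelectTopCodes:
    def _panel(self, prevs, codes):
        from scipy import sparse
        n = max(prevs) + 1
        ind = np.zeros((n, len(codes)), dtype=np.int8)
        for j, p in enumerate(prevs):
            ind[:p, j] = 1
        m = sparse.csr_matrix(ind)
        return cb.CovariatePanel(
            pregnancy_ids=np.arange(n), codes=pd.DataFrame(
                {"code": codes, "kind": "rx", "role": "maternal"}),
            counts=m.copy(), indicators=m, threshold=1,
            window=cb.WindowSpec("maternal-rx", 0, 90))

    def test_keeps_most_prevalent(self):
        p = self._panel([10, 5, 1], ["a", "b", "c"])
        out = cs.select_top_codes(p, k=2)
        assert list(out.codes["code"]) == ["a", "b"]

    def test_k_larger_than_codes_is_identity(self):
        p = self._panel([10, 5, 1], ["a", "b", "c"])
        out = cs.select_top_codes(p, k=10)
        assert list(out.codes["code"]) == ["a", "b", "c"]

    def test_tie_at_rank_k_prefers_lexicographic(self):
        p = self._panel([10, 5, 5], ["a", "z", "b"])
        out = cs.select_top_codes(p, k=2)
        assert list(out.codes["code"]) == ["a", "b"]

    def test_retained_prevalences_dominate_dropped(self, mid_prepared):
        d = mid_prepared
        w = cb.WindowSpec("maternal-dx", -180, 90)
        p = cs.derive_panel(d["cohort"], d["ids"], w, gem=d["gem"])
        out = cs.select_top_codes(p, k=10)
        kept = set(out.codes["code"])
        dropped_prev = [v for c, v in zip(p.codes["code"], p.prevalence)
                        if c not in kept]
        assert min(out.prevalence) >= max(dropped_prev)


class TestFlagOutcomes:
    def test_twin_pregnancy_one_affected_infant_flagged(self):
        persons, enroll, pregnancies, links = base_family(n_fetuses=2)
        persons.append({"person_id": 3, "sex": "M", "birth_year": 2015,
                        "family_key": 0})
        enroll.append({"person_id": 3, "start_day": 273, "end_day": 700,
                       "rx_benefit": True})
        links.append({"pregnancy_id": 0, "infant_id": 3, "death_day": np.nan})
        dx = [{"person_id": 3, "day": 280, "code": "745.4",
               "vocabulary": "ICD9"}]
        cohort = make_cohort(persons=persons, enroll=enroll, dx=dx,
                             pregnancies=pregnancies, links=links)
        flags = cs.flag_outcomes(cohort, [0], cs.default_code_lists())
        assert bool(flags.loc[0, "primary"])
        assert bool(flags.loc[0, "ventricular_septal"])
        assert not flags.loc[0, "atrial_septal"]

    def test_no_qualifying_code_unflagged(self):
        cohort = family_cohort()
        flags = cs.flag_outcomes(cohort, [0], cs.default_code_lists())
        assert not flags.loc[0, "primary"]

    def test_follow_up_boundary_day_90_in_91_out(self):
        for day_off, expect in ((90, True), (91, False)):
            persons, enroll, pregnancies, links = base_family()
            dx = [{"person_id": 2, "day": 273 + day_off, "code": "745.4",
                   "vocabulary": "ICD9"}]
            cohort = make_cohort(persons=persons, enroll=enroll, dx=dx,
                                 pregnancies=pregnancies, links=links)
            flags = cs.flag_outcomes(cohort, [0], cs.default_code_lists())
            assert bool(flags.loc[0, "primary"]) is expect

    def test_empty_code_list_rejected(self):
        cohort = family_cohort()
        with pytest.raises(ConfigError, match="empty"):
            cs.flag_outcomes(cohort, [0], {"primary": []})


class TestRestrictions:
    def test_singleton_restriction(self):
        cohort = family_cohort(n_fetuses=2)
        assert cs.apply_restriction(cohort, [0], "singleton") == set()
        cohort2 = family_cohort(n_fetuses=1)
        assert cs.apply_restriction(cohort2, [0], "singleton") == {0}

    def test_marker_restriction_drops_marked_mother(self):
        dx = [{"person_id": 0, "day": 10, "code": "250.00",
               "vocabulary": "ICD9"}]
        cohort = panel_cohort(dx=dx)
        assert cs.apply_restriction(cohort, [0], "no-diabetes") == set()
        assert cs.apply_restriction(cohort, [0], "no-chromosomal") == {0}

    def test_parental_malformation_checks_father_before_lmp(self):
        dx = [{"person_id": 1, "day": -30, "code": "745.4",
               "vocabulary": "ICD9"}]
        cohort = panel_cohort(dx=dx)
        out = cs.apply_restriction(cohort, [0], "no-parental-malformation",
                                   father_map={0: 1})
        assert out == set()
        # same code after LMP is outside the lookback
        cohort.dx.loc[0, "day"] = 30
        out = cs.apply_restriction(cohort, [0], "no-parental-malformation",
                                   father_map={0: 1})
        assert out == {0}

    def test_unknown_restriction_rejected(self):
        cohort = family_cohort()
        with pytest.raises(ConfigError, match="unknown"):
            cs.apply_restriction(cohort, [0], "no-such-rule")

    def test_chained_equals_intersection(self, mid_prepared):
        d = mid_prepared
        s1 = cs.apply_restriction(d["cohort"], d["ids"], "singleton",
                                  gem=d["gem"])
        s2 = cs.apply_restriction(d["cohort"], d["ids"], "no-diabetes",
                                  gem=d["gem"])
        chained = cs.apply_restriction(
            d["cohort"], cs.apply_restriction(d["cohort"], d["ids"],
                                              "singleton", gem=d["gem"]),
            "no-diabetes", gem=d["gem"])
        assert chained == (s1 & s2)
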