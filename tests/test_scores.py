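"""Unit and property tests for the six trauma score calculators."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traumascores import (
    InjuryRecord,
    InvalidInputError,
    MissingValueError,
    NotComputableError,
    ORIENTATION,
    code_rts_components,
    compute_iss,
    compute_kts,
    compute_mgap,
    compute_niss,
    compute_rts,
    compute_triss,
    count_serious_injuries,
    rts_from_codes,
    score_panel,
    to_risk,
    triss_age_index,
)
from traumascores.scores import REGIONS, RTS_MAX
from conftest import make_patient

injury_lists = st.lists(
    st.builds(InjuryRecord,
              region=st.sampled_from(REGIONS),
              ais=st.integers(min_value=1, max_value=6)),
    max_size=8,
)


def iss_bruteforce(injuries, region_once):
    """Exhaustive enumeration over all <=3-subsets of injuries."""
    if any(i.ais == 6 for i in injuries):
        return 75
    best = 0
    for k in range(0, min(3, len(injuries)) + 1):
        for combo in itertools.combinations(injuries, k):
            if region_once and len({i.region for i in combo}) < len(combo):
                continue
            best = max(best, sum(i.ais ** 2 for i in combo))
    return best


class TestRTS:
    @pytest.mark.parametrize("gcs,sbp,rr,codes", [
        (15, 124, 18, (4, 4, 4)),
        (3, 0, 0, (0, 0, 0)),
        (13, 85, 35, (4, 3, 3)),
        (12, 89, 9, (3, 3, 2)),   # boundary bands: GCS 12, SBP 89, RR 9
        (6, 76, 1, (2, 3, 1)),
    ])
    def test_component_coding(self, gcs, sbp, rr, codes):
        assert code_rts_components(gcs, sbp, rr) == codes

    @pytest.mark.parametrize("gcs,sbp,rr,expected", [
        (15, 124, 18, 7.8408),
        (3, 0, 0, 0.0),
        (13, 85, 35, 6.8174),
    ])
    def test_values(self, gcs, sbp, rr, expected):
        assert compute_rts(gcs, sbp, rr) == pytest.approx(expected, abs=1e-10)

    def test_extremes_reached_only_at_extreme_codes(self):
        for codes in itertools.product(range(5), repeat=3):
            val = rts_from_codes(*codes)
            assert (val == pytest.approx(RTS_MAX)) == (codes == (4, 4, 4))
            assert (val == 0.0) == (codes == (0, 0, 0))
            assert 0.0 <= val <= RTS_MAX + 1e-12

    def test_invalid_gcs(self):
        with pytest.raises(InvalidInputError):
            compute_rts(2, 120, 18)
        with pytest.raises(InvalidInputError):
            compute_rts(16, 120, 18)

    def test_missing_component(self):
        with pytest.raises(MissingValueError):
            compute_rts(None, 120, 18)


class TestISSNISS:
    @pytest.mark.parametrize("injuries,expected_iss", [
        ([("head_neck", 5), ("chest", 5), ("abdomen", 5)], 75),
        ([("head_neck", 3)], 9),
        ([("head_neck", 4), ("face", 2), ("chest", 3)], 29),
        ([], 0),
        ([("face", 6)], 75),                     # AIS 6 forces maximum
        ([("chest", 2), ("chest", 5)], 25),      # region maximum only
    ])
    def test_iss(self, injuries, expected_iss):
        inj = [InjuryRecord(r, a) for r, a in injuries]
        assert compute_iss(inj) == expected_iss

    def test_niss_reuses_regions(self):
        inj = [InjuryRecord("head_neck", 4), InjuryRecord("head_neck", 4),
               InjuryRecord("chest", 3)]
        assert compute_niss(inj) == 41
        assert compute_iss(inj) == 25

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            InjuryRecord("skull", 3)
        with pytest.raises(InvalidInputError):
            InjuryRecord("chest", 0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(injury_lists)
    def test_matches_bruteforce_and_dominance(self, injuries):
        iss = compute_iss(injuries)
        niss = compute_niss(injuries)
        assert iss == iss_bruteforce(injuries, region_once=True)
        assert niss == iss_bruteforce(injuries, region_once=False)
        assert niss >= iss
        assert 0 <= iss <= 75 and 0 <= niss <= 75


class TestMGAP:
    @pytest.mark.parametrize("mech,gcs,age,sbp,expected", [
        ("blunt", 15, 30, 130, 29),
        ("penetrating", 3, 70, 50, 3),
        ("blunt", 10, 62, 90, 17),
        ("penetrating", 15, 59, 121, 25),  # age/SBP boundaries
        ("blunt", 15, 60, 60, 22),
    ])
    def test_values(self, mech, gcs, age, sbp, expected):
        assert compute_mgap(mech, gcs, age, sbp) == expected

    def test_range_over_grid(self):
        vals = [compute_mgap(m, g, a, s)
                for m in ("blunt", "penetrating")
                for g in range(3, 16)
                for a in (30, 70)
                for s in (40, 90, 130)]
        assert min(vals) == 3 and max(vals) == 29

    def test_not_computable_for_other_mechanisms(self):
        for mech in ("burn", "mixed", "unknown"):
            with pytest.raises(NotComputableError):
                compute_mgap(mech, 15, 30, 120)


class TestKTS:
    @pytest.mark.parametrize("age,sbp,rr,avpu,nsi,expected", [
        (30, 120, 18, "A", 0, 10),
        (60, 40, 5, "U", 3, 0),
        (30, 70, 18, "V", 1, 7),
        (55, 89, 30, "P", 2, 4),   # boundaries: age 55, SBP 89, RR 30
        (54, 50, 10, "A", 1, 8),
    ])
    def test_values(self, age, sbp, rr, avpu, nsi, expected):
        assert compute_kts(age, sbp, rr, avpu, nsi) == expected

    def test_range_over_grid(self):
        vals = [compute_kts(a, s, r, v, n)
                for a in (30, 70) for s in (40, 70, 120)
                for r in (5, 18, 35) for v in "AVPU" for n in range(4)]
        assert min(vals) == 0 and max(vals) == 10

    def test_invalid_avpu(self):
        with pytest.raises(InvalidInputError):
            compute_kts(30, 120, 18, "X", 0)

    @pytest.mark.parametrize("injuries,expected", [
        ([("head_neck", 5), ("face", 2)], 1),
        ([], 0),
        ([("chest", 3), ("chest", 3), ("extremities", 4)], 3),
    ])
    def test_serious_injury_count(self, injuries, expected):
        inj = [InjuryRecord(r, a) for r, a in injuries]
        assert count_serious_injuries(inj) == expected


class TestTRISS:
    @pytest.mark.parametrize("age,expected", [(54, 0), (55, 1), (18, 0), (90, 1)])
    def test_age_index(self, age, expected):
        assert triss_age_index(age) == expected

    def test_age_index_under_15(self):
        with pytest.raises(InvalidInputError):
            triss_age_index(14)

    def test_closed_form_values(self):
        # direct evaluation of the printed logistic formula
        b = 0.4499 + 0.8085 * 7.8408 - 0.0835 * 1
        assert compute_triss("blunt", 7.8408, 1, 30) == pytest.approx(
            1 / (1 + math.exp(-b)), abs=1e-12)
        b = 2.5355 + 0.9934 * 0 - 0.0651 * 75 - 1.1360
        assert compute_triss("penetrating", 0, 75, 60) == pytest.approx(
            1 / (1 + math.exp(-b)), abs=1e-12)
        assert round(compute_triss("blunt", 7.8408, 1, 30), 4) == 0.9988
        assert round(compute_triss("penetrating", 0, 75, 60), 4) == 0.0298

    def test_monotone_in_iss_and_rts(self):
        for mech in ("blunt", "penetrating"):
            ps_grid = [compute_triss(mech, 5.0, iss, 30) for iss in range(0, 76)]
            assert all(a > b for a, b in zip(ps_grid, ps_grid[1:]))
            rts_grid = np.linspace(0, RTS_MAX, 30)
            ps = [compute_triss(mech, r, 25, 30) for r in rts_grid]
            assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_not_computable_for_burn(self):
        with pytest.raises(NotComputableError):
            compute_triss("burn", 7.8408, 9, 30)


class TestPanel:
    def test_full_panel(self):
        p = make_patient(injuries=[("head_neck", 3), ("chest", 2)])
        panel = score_panel(p)
        d = panel.as_dict()
        assert set(d) == set(ORIENTATION)
        assert all(np.isfinite(v) for v in d.values())
        assert panel.niss >= panel.iss

    def test_no_injury_patient(self):
        panel = score_panel(make_patient(injuries=[]))
        assert panel.iss == 0 and panel.niss == 0
        assert panel.rts == pytest.approx(7.8408)

    def test_missing_fields_named(self):
        p = make_patient(gcs=None)
        with pytest.raises(MissingValueError, match="rts"):
            score_panel(p)

    def test_burn_patient_not_computable(self):
        with pytest.raises(NotComputableError):
            score_panel(make_patient(mechanism="burn"))

    def test_risk_orientation(self):
        assert to_risk(25, "higher_worse") == 25
        assert to_risk(7.84, "lower_worse") == -7.84
        panel = score_panel(make_patient(injuries=[("chest", 4)]))
        risks = panel.risks()
        assert risks["iss"] == panel.iss
        assert risks["kts"] == -panel.kts
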