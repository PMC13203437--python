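"""Sanctuary detection, immunoediting ratio, seeding classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coldsim.model import ReplicateResult, SeedingEvent, Snapshot, TerminationClass
from coldsim.spatial import classify_seeding, detect_sanctuaries, immunoediting_ratio
from coldsim.testing import sanctuary_toy_snapshot


class TestSanctuaryToy:
    def test_minimum_area_filter(self):
        rep = detect_sanctuaries(sanctuary_toy_snapshot())
        # the 4-cell block qualifies; the 3-cell run is rejected by area
        assert rep.count == 1
        assert rep.areas == (4,)
        assert rep.total_area == 4
        assert set(rep.members[0]) == {(15, 15), (15, 16), (16, 15), (16, 16)}

    def test_enrichment_and_membership(self):
        snap = sanctuary_toy_snapshot()
        rep = detect_sanctuaries(snap)
        tum_pos = set(zip(snap.tumour["x"], snap.tumour["y"]))
        for comp in rep.members:
            assert set(comp) <= tum_pos
        assert rep.pdl1_enrichment > 1.0
        assert 0 < rep.tumour_fraction < 1

    def test_unfilled_window_returns_empty_report(self):
        snap = sanctuary_toy_snapshot()
        snap.window_filled = False
        rep = detect_sanctuaries(snap)
        assert rep.count == 0 and not rep.window_filled

    def test_invariant_under_monotone_field_rescaling(self):
        base = sanctuary_toy_snapshot()
        scaled = dataclasses.replace(
            base, tumour=base.tumour.assign(e_total=base.tumour.e_total * 5.0 + 1.0)
        )
        a = detect_sanctuaries(base)
        b = detect_sanctuaries(scaled)
        assert a.count == b.count
        assert a.areas == b.areas
        assert set(a.members) == set(b.members)

    def test_components_are_disjoint_and_area_consistent(self):
        rep = detect_sanctuaries(sanctuary_toy_snapshot())
        cells = [c for comp in rep.members for c in comp]
        assert len(cells) == len(set(cells)) == rep.total_area


class TestImmunoeditingRatio:
    def test_unchanged_population_gives_unity(self):
        assert immunoediting_ratio([1.48, 1.48, 1.48], 1.48) == pytest.approx(1.0)

    def test_printed_adaptive_enrichment_arithmetic(self):
        # survivor median 4.37 over initial 1.48 is the 2.95-fold benchmark
        assert immunoediting_ratio([4.37], 1.48) == pytest.approx(2.95, abs=0.01)

    def test_weak_static_enrichment_arithmetic(self):
        assert immunoediting_ratio([1.63, 1.63, 1.63], 1.48) == pytest.approx(1.10, abs=0.01)

    def test_extinct_population_is_undefined(self):
        with pytest.raises(ValueError):
            immunoediting_ratio([], 1.48)


def _fake_result(events, lineage_counts, n_idx=0):
    return ReplicateResult(
        arm_id="fake",
        replicate_index=n_idx,
        seed=0,
        termination=TerminationClass("max_steps_reached", 500),
        records=pd.DataFrame(),
        survivor_e_basal=np.array([1.0]),
        survivor_e_total=np.array([1.0]),
        n_immune_final=0,
        initial_median=1.48,
        seeding_events=events,
        lineage_final_counts=lineage_counts,
        snapshots=[],
    )


def _event(lineage_id, founder_e=10.0, seed_q=3, primary_q=0):
    return SeedingEvent(
        step=100, x=1, y=1, lineage_id=lineage_id,
        founder_e_total=founder_e, founder_e_basal=founder_e,
        seed_quadrant=seed_q, primary_quadrant=primary_q,
    )


class TestSeedingClassification:
    def test_no_events_no_colonies(self):
        rep = classify_seeding([_fake_result([], {}) for _ in range(10)])
        assert rep.n_colonies == 0
        assert rep.colonised_ci.lower == 0.0
        assert rep.high_pdl1_ci is None

    def test_printed_wilson_benchmark_8_of_50(self):
        results = [
            _fake_result([_event(100 + i)], {100 + i: 10}, n_idx=i) if i < 8
            else _fake_result([], {}, n_idx=i)
            for i in range(50)
        ]
        rep = classify_seeding(results)
        assert rep.n_colonised_replicates == 8
        assert rep.colonised_ci.lower == pytest.approx(0.083, abs=5e-4)
        assert rep.colonised_ci.upper == pytest.approx(0.285, abs=5e-4)

    def test_high_pdl1_split_7_of_8(self):
        results = []
        for i in range(8):
            e = _event(200 + i, founder_e=12.0 if i < 7 else 1.0)
            results.append(_fake_result([e], {200 + i: 6}, n_idx=i))
        rep = classify_seeding(results)
        assert rep.n_high_pdl1_colonies == 7
        assert rep.high_pdl1_ci.lower == pytest.approx(0.529, abs=5e-4)
        assert rep.high_pdl1_ci.upper == pytest.approx(0.978, abs=5e-4)

    def test_same_quadrant_or_small_lineage_not_a_colony(self):
        ev_same_q = _event(1, seed_q=2, primary_q=2)
        ev_small = _event(2)
        r = _fake_result([ev_same_q, ev_small], {1: 50, 2: 3})
        assert classify_seeding([r]).n_colonies == 0
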