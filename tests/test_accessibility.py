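"""Accessibility filter, hot-spot merging and the per-UTR screen."""

import random

import pytest

from oracles import merge_brute
from mirserca.accessibility import (
    accessibility_pass,
    hotspot_summary,
    merge_hotspots,
    multiplicity,
    screen_utr,
)
from mirserca.model_io import DuplexSite, MatureMiRNA, ModelIOError, ScreenConfig, UTRRegion
from mirserca.duplex_thermo import load_default_params
from mirserca.synthetic import PlantSpec, gen_utr, plant_site


def _site(start, end, mirna="m", dg=-22.0, g5=-11.2, g3=-14.9, utr="u"):
    return DuplexSite(
        mirna_name=mirna,
        utr_id=utr,
        start=start,
        end=end,
        dG_bind=dg,
        dG_flank5=g5,
        dG_flank3=g3,
    )


class TestAccessibilityPass:
    def test_printed_one_flank_gap_passes(self):
        # binding -22.0 vs flanks -14.9 / -11.2: the 5' gap is 10.8
        assert accessibility_pass(_site(671, 692), gap=10.0)

    def test_insufficient_gap_fails(self):
        assert not accessibility_pass(_site(671, 692, dg=-15.0), gap=10.0)

    def test_zero_gap_passes_any_bound_site_below_flanks(self):
        assert accessibility_pass(_site(1, 20, dg=-12.0, g5=-11.9, g3=-11.9), gap=0.0)

    def test_monotone_decreasing_in_gap(self):
        site = _site(1, 20, dg=-25.0, g5=-12.0, g3=-18.0)
        passing = [g for g in range(0, 20) if accessibility_pass(site, g)]
        assert passing == list(range(0, max(passing) + 1))

    def test_unset_flanks_rejected(self):
        bare = DuplexSite(mirna_name="m", utr_id="u", start=1, end=20, dG_bind=-20.0)
        with pytest.raises(ModelIOError):
            accessibility_pass(bare, 10.0)

    @pytest.mark.parametrize("isoform_fixture", ["serca2a_sites", "serca2b_sites"])
    def test_every_fixture_row_passes_at_gap_10(self, isoform_fixture, request):
        sites = request.getfixturevalue(isoform_fixture)
        assert all(accessibility_pass(s, 10.0) for s in sites)


class TestMergeHotspots:
    def test_fixture_yields_seven_cooperative_clusters(self, serca2a_sites):
        spots = merge_hotspots(serca2a_sites)
        assert sum(1 for h in spots if h.cooperative) == 7

    def test_disjoint_singletons_stay_singletons(self):
        sites = [_site(i * 100, i * 100 + 10) for i in range(1, 5)]
        spots = merge_hotspots(sites)
        assert len(spots) == 4
        assert not any(h.cooperative for h in spots)

    def test_matches_transitive_closure_oracle_on_random_intervals(self):
        rng = random.Random(987)
        for _ in range(50):
            n = rng.randint(1, 25)
            sites = []
            for k in range(n):
                start = rng.randint(1, 300)
                sites.append(_site(start, start + rng.randint(0, 40), mirna=f"m{k}"))
            spots = merge_hotspots(sites)
            expected = merge_brute([(s.start, s.end) for s in sites])
            got = []
            index_of = {id(s): i for i, s in enumerate(sites)}
            for h in spots:
                got.append(frozenset(index_of[id(s)] for s in h.member_sites))
            assert sorted(got, key=min) == expected

    def test_output_disjoint_and_covering(self, serca2a_sites, serca2b_sites):
        for sites in (serca2a_sites, serca2b_sites):
            spots = merge_hotspots(sites)
            for h1, h2 in zip(spots, spots[1:]):
                assert h1.end < h2.start
            covered = set()
            for h in spots:
                for s in h.member_sites:
                    covered.add((s.start, s.end))
                assert h.start == min(s.start for s in h.member_sites)
                assert h.end == max(s.end for s in h.member_sites)
            assert covered == {(s.start, s.end) for s in sites}

    def test_mixed_utr_ids_rejected(self):
        with pytest.raises(ModelIOError):
            merge_hotspots([_site(1, 10, utr="a"), _site(5, 15, utr="b")])


class TestMultiplicity:
    def test_fixture_counts(self, serca2a_sites, serca2b_sites):
        assert multiplicity(serca2a_sites)["miR-574-5p"] == 5
        assert multiplicity(serca2b_sites)["miR-122"] == 7

    def test_empty_input(self):
        assert multiplicity([]) == {}


@pytest.fixture(scope="module")
def screen_setup():
    params = load_default_params()
    mirna = MatureMiRNA(name="mir-test", sequence="UC" * 11)
    utr = gen_utr(length=900, seed=11, transcript_id="synutr")
    utr, _ = plant_site(
        utr, PlantSpec(mirna=mirna, position=151, accessible=True), params, seed=11
    )
    utr, _ = plant_site(
        utr, PlantSpec(mirna=mirna, position=601, accessible=False), params, seed=11
    )
    return params, mirna, utr


class TestScreenUtr:
    def test_accessible_plant_survives_hairpin_plant_rejected(self, screen_setup):
        params, mirna, utr = screen_setup
        sites = screen_utr([mirna], utr, params)
        spans = [(s.start, s.end) for s in sites]
        assert (151, 172) in spans
        assert not any(s.start == 601 for s in sites)

    def test_empty_mirna_list(self, screen_setup):
        params, _, utr = screen_setup
        assert screen_utr([], utr, params) == []

    def test_deterministic(self, screen_setup):
        params, mirna, utr = screen_setup
        a = screen_utr([mirna], utr, params)
        b = screen_utr([mirna], utr, params)
        assert a == b

    def test_summary_shape(self, serca2a_sites):
        summary = hotspot_summary(serca2a_sites)
        assert summary["n_sites"] == 35
        assert summary["n_cooperative"] == 7
        assert summary["multiplicity"]["miR-199a-3p"] == 5
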