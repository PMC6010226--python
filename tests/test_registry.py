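"""Registry: site/specimen accounting, rarefaction, coverage filtering."""

import itertools

import pytest

from specdelim.registry import (
    CoverageRule,
    RegistryError,
    SiteRecord,
    SpeciesMergeMap,
    concat_eligible,
    cooccurrence_stats,
    depth_profile,
    load_site_table,
    rarefaction_curve,
    regional_summary,
    registry_totals,
    shared_species,
    species_depth_range,
)


def _site(site_id="S1", region="Skagerrak", n=1, clades=("1",), dmin=10, dmax=10):
    return SiteRecord(
        site_id=site_id,
        region=region,
        sample_size=n,
        clades=frozenset(clades),
        latitude=58.0,
        longitude=11.0,
        depth_min=dmin,
        depth_max=dmax,
    )


class TestLoadSiteTable:
    def test_packaged_fixture_row_ka1(self, sites):
        ka1 = next(s for s in sites if s.site_id == "KA1")
        assert ka1.region == "Kattegat"
        assert ka1.sample_size == 11
        assert ka1.clades == {"4"}
        assert (ka1.depth_min, ka1.depth_max) == (18, 20)

    def test_missing_fields_become_none(self, sites):
        ncs3 = next(s for s in sites if s.site_id == "NCS3")
        assert ncs3.habitat is None
        assert ncs3.clades == {"8", "13"}

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("site_id,region,sample_size,clades,latitude,longitude,depth\n")
        with pytest.raises(RegistryError, match="no records"):
            load_site_table(path)

    def test_unknown_region_and_bad_depth_rejected(self, tmp_path):
        head = "site_id,region,sample_size,clades,latitude,longitude,depth\n"
        bad_region = tmp_path / "r.csv"
        bad_region.write_text(head + "X1,Atlantis,1,1,0,0,10\n")
        with pytest.raises(RegistryError, match="row 2.*Atlantis"):
            load_site_table(bad_region)
        bad_depth = tmp_path / "d.csv"
        bad_depth.write_text(head + "X1,Skagerrak,1,1,0,0,deep\n")
        with pytest.raises(RegistryError, match="depth"):
            load_site_table(bad_depth)


class TestTotalsAndRegions:
    def test_survey_totals(self, sites):
        assert registry_totals(sites) == (133, 513, 8.0, 4380.0)

    def test_trivial_totals(self):
        assert registry_totals([_site()]) == (1, 1, 10, 10)
        two = [_site(n=2), _site("S2", n=3)]
        assert registry_totals(two)[1] == 5

    def test_regional_specimens_sum_to_total(self, sites):
        summary = regional_summary(sites)
        assert sum(v["n_specimens"] for v in summary.values()) == 513

    def test_single_clade_region(self):
        summary = regional_summary([_site(n=5), _site("S2", n=3)])
        assert summary["Skagerrak"]["n_species"] == 1

    def test_merge_never_increases_species_counts(self, sites):
        merged = regional_summary(sites, SpeciesMergeMap())
        clade_level = regional_summary(sites, SpeciesMergeMap.identity())
        for region in merged:
            assert merged[region]["n_species"] <= clade_level[region]["n_species"]

    @pytest.mark.parametrize(
        "region,n_specimens,n_species",
        [
            ("Skagerrak", 108, 10),
            ("Barents Sea", 100, 13),
            ("Norwegian coast and shelf", 192, 13),
        ],
    )
    def test_survey_regional_summary(self, sites, region, n_specimens, n_species):
        summary = regional_summary(sites)
        assert summary[region]["n_specimens"] == n_specimens
        assert summary[region]["n_species"] == n_species

    def test_skagerrak_species_identity(self, sites):
        summary = regional_summary(sites)
        assert summary["Skagerrak"]["species"] == {
            "1", "2", "3", "4", "5", "6", "7", "8", "12", "13"
        }


class TestSharedSpecies:
    def test_kattegat_most_similar_to_skagerrak(self, sites):
        summary = regional_summary(sites)
        n_shared, n_in_a, best = shared_species("Kattegat", "Skagerrak", summary)
        assert (n_shared, n_in_a, best) == (4, 4, "Skagerrak")

    def test_greenland_sea_most_similar_to_barents(self, sites):
        summary = regional_summary(sites)
        n_shared, n_in_a, best = shared_species("Greenland Sea", "Barents Sea", summary)
        assert (n_shared, n_in_a, best) == (4, 4, "Barents Sea")

    def test_disjoint_sets_share_nothing(self):
        summary = regional_summary(
            [_site(clades=("1", "2")), _site("S2", region="Kattegat", clades=("3",))]
        )
        assert shared_species("Skagerrak", "Kattegat", summary)[:2] == (0, 2)

    def test_absent_region_rejected(self, sites):
        with pytest.raises(RegistryError):
            shared_species("Skagerrak", "Baltic", regional_summary(sites))


class TestCooccurrence:
    def test_survey_counts(self, sites):
        multi_specimen, multi_species, max_species = cooccurrence_stats(sites)
        assert multi_specimen == 89
        # printed table yields 46 multi-species sites (running text says 49)
        assert multi_species == 46
        assert max_species == 5  # site NCS24

    def test_all_singletons(self):
        stats = cooccurrence_stats([_site(), _site("S2")])
        assert stats == (0, 0, 1)

    def test_multispecies_bounded_by_multispecimen(self, sites):
        multi_specimen, multi_species, _ = cooccurrence_stats(sites)
        assert multi_species <= multi_specimen


def _rarefaction_enumeration(labels, n):
    """Exhaustive-enumeration oracle: mean species count over all C(N, n)
    subsets."""
    subsets = list(itertools.combinations(range(len(labels)), n))
    total = sum(len({labels[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


class TestRarefaction:
    def test_endpoints(self):
        labels = ["A"] * 4 + ["B"] * 3 + ["C"]
        curve = dict(rarefaction_curve(labels))
        assert curve[1] == pytest.approx(1.0)
        assert curve[len(labels)] == pytest.approx(3.0)

    def test_toy_pool_matches_enumeration(self):
        labels = ["A", "A", "B"]
        curve = dict(rarefaction_curve(labels))
        assert curve[2] == pytest.approx(_rarefaction_enumeration(labels, 2), abs=1e-12)

    @pytest.mark.parametrize(
        "labels",
        [
            ["A", "A", "B", "B", "C"],
            ["A"] * 6 + ["B"] * 2,
            ["A", "B", "C", "D", "E", "F", "G", "A"],
            ["A"] * 8,
        ],
    )
    def test_matches_enumeration_small_pools(self, labels):
        curve = dict(rarefaction_curve(labels))
        for n, value in curve.items():
            assert value == pytest.approx(
                _rarefaction_enumeration(labels, n), abs=1e-12
            )

    def test_monotone_nondecreasing(self, specimens):
        labels = [SpeciesMergeMap()(sp.clade) for sp in specimens][:60]
        curve = rarefaction_curve(labels)
        values = [v for _, v in curve]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_oversized_draw_rejected(self):
        with pytest.raises(RegistryError):
            rarefaction_curve(["A", "B"], 3)


class TestDepthProfile:
    def test_abyssal_species_confined_to_arctic(self, sites):
        profile = depth_profile(sites)
        assert set(profile["24"]) == {"Arctic Ocean"}
        assert species_depth_range(profile, "24") == (4038.0, 4380.0)

    def test_deepwater_species_floor(self, sites):
        # Table as printed: one Skagerrak site at 190 m includes clade 8
        profile = depth_profile(sites)
        assert species_depth_range(profile, "8")[0] == 190.0

    def test_single_site_species(self):
        profile = depth_profile([_site(clades=("9",), dmin=40, dmax=60)])
        assert profile["9"]["Skagerrak"] == (40, 60)


# printed per-clade counts of the >=3-marker concatenated data set
CONCAT_BY_CLADE = {
    "1": 5, "2": 4, "3": 5, "4": 4, "5": 4, "6": 4, "7": 5, "8": 3, "9": 2,
    "10": 3, "11": 3, "12": 6, "13": 5, "14": 4, "15": 4, "16": 8, "17": 1,
    "18": 2, "19": 1, "20": 2, "21": 1, "22": 1, "23": 1, "24": 4, "25": 2,
    "26": 2, "27": 1, "28": 4,
}


class TestConcatEligible:
    def test_reproduces_published_concat_counts(self, specimens):
        chosen = concat_eligible(specimens)
        assert len(chosen) == 91
        by_clade = {}
        for sp in specimens:
            if sp.extraction_id in chosen:
                by_clade[sp.clade] = by_clade.get(sp.clade, 0) + 1
        assert by_clade == CONCAT_BY_CLADE

    def test_min_markers_one_selects_any_sequenced(self, specimens):
        chosen = concat_eligible(specimens, CoverageRule(min_markers=1))
        assert len(chosen) == len(
            [sp for sp in specimens if any(sp.marker_flags.values())]
        )

    def test_threshold_boundary(self):
        from specdelim.registry import SpecimenRecord

        three = SpecimenRecord("a", "1", "S1", {"COI": True, "ITS2": True, "16S": True, "28S": False})
        two = SpecimenRecord("b", "1", "S1", {"COI": True, "ITS2": True, "16S": False, "28S": False})
        assert concat_eligible([three, two], CoverageRule(3)) == {"a"}
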