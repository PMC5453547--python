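import numpy as np
import pytest

from barcodeaudit.assemblage import (
    cluster_regions_from_collection,
    collapse_ecoregions,
    latitude_band,
    longitude_band,
    partition_and_summarize,
    presence_absence_matrix,
    region_overlap,
)
from barcodeaudit.audit import Category, build_species_summaries, percentage
from barcodeaudit.clustering import ClusterPartition, single_linkage_clusters
from barcodeaudit.distance import pairwise_matrix
from barcodeaudit.records import SpecimenCollection
from barcodeaudit.simulate import mutate_sequence
from conftest import make_record


class TestEcoregionCollapse:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Arctic Cordillera", "Arctic"),
            ("Tundra", "Arctic"),
            ("Taiga", "Boreal"),
            ("Hudson Plains", "Boreal"),
            ("Northern Forests", "Boreal"),
            ("Great Plains", "Great Plains"),
            ("Boreal", "Boreal"),
        ],
    )
    def test_mapping(self, label, expected):
        assert collapse_ecoregions(label) == expected

    def test_unknown_label_errors_listing_valid(self):
        with pytest.raises(ValueError, match="Tundra"):
            collapse_ecoregions("Atlantis")


class TestBands:
    @pytest.mark.parametrize(
        "lat,band",
        [(52.1, "50-55"), (25.0, "25-30"), (24.9, "<25"), (55.0, ">55"),
         (60.0, ">55"), (40.0, "40-45"), (39.999, "35-40")],
    )
    def test_latitude(self, lat, band):
        assert latitude_band(lat) == band

    @pytest.mark.parametrize(
        "lon,band",
        [(-100.0, "95-105"), (-75.0, "75-85"), (-74.9, "<75"),
         (-135.0, ">135"), (-140.0, ">135")],
    )
    def test_longitude(self, lon, band):
        assert longitude_band(lon) == band

    def test_eastern_longitude_excluded(self):
        assert longitude_band(12.5) is None

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            latitude_band(95.0)


def two_region_library(template, co_occur: bool):
    """Two species sharing a haplotype; co-located or in disjoint regions."""
    rng = np.random.default_rng(17)
    other1 = mutate_sequence(template, 25, 3.0, rng)
    other2 = mutate_sequence(template, 50, 3.0, rng)
    records = [
        make_record("s1", "Aa bb", template, genus="Aa", family="F",
                    ecoregion="Great Plains", zoogeo_region="Nearctic"),
        make_record("s2", "Aa cc", template, genus="Aa", family="F",
                    ecoregion="Great Plains" if co_occur else "Eastern Temperate Forests",
                    zoogeo_region="Nearctic"),
        make_record("s3", "Bb dd", other1, genus="Bb", family="F",
                    ecoregion="Great Plains", zoogeo_region="Nearctic"),
        make_record("s4", "Bb ee", other2, genus="Bb", family="F",
                    ecoregion="Eastern Temperate Forests", zoogeo_region="Nearctic"),
    ]
    return SpecimenCollection(records)


class TestPartitionSummarize:
    def test_one_region_idempotence(self, small_library):
        collection, _ = small_library
        records = []
        for rec in collection:
            rec.ecoregion = "Great Plains"
            records.append(rec)
        coll = SpecimenCollection(records)
        summaries, skipped = partition_and_summarize(coll, "ecoregion")
        assert skipped == 0
        assert len(summaries) == 2  # one region + Total
        region, total = summaries
        continental = build_species_summaries(coll)
        n_sharing = sum(
            1 for s in continental
            if s.assessed and Category.SHARING in s.categories
        )
        assert region.n_sharing == total.n_sharing == n_sharing
        assert region.n_species == len({r.species for r in coll.sequenced()})

    def test_regional_resolution_improvement(self, template):
        # shared haplotype across disjoint regions: continental sharing 2,
        # every per-region sharing 0
        coll = two_region_library(template, co_occur=False)
        continental = build_species_summaries(coll)
        n_cont = sum(1 for s in continental if Category.SHARING in s.categories)
        assert n_cont == 2
        summaries, _ = partition_and_summarize(coll, "ecoregion")
        regional = [s for s in summaries if s.label != "Total"]
        assert len(regional) == 2
        assert all(s.n_sharing == 0 for s in regional)
        # pooled Total row still sees the sharing
        assert summaries[-1].n_sharing == 2

    def test_co_occurring_sharing_persists_regionally(self, template):
        coll = two_region_library(template, co_occur=True)
        summaries, _ = partition_and_summarize(coll, "ecoregion")
        by_label = {s.label: s for s in summaries}
        assert by_label["Great Plains"].n_sharing == 2

    def test_mean_nnd_matches_oracle(self, small_library):
        collection, _ = small_library
        records = []
        for i, rec in enumerate(collection):
            rec.ecoregion = "Boreal" if i % 2 else "Great Plains"
            records.append(rec)
        coll = SpecimenCollection(records)
        summaries, _ = partition_and_summarize(coll, "ecoregion")
        for summ in summaries:
            if summ.label == "Total":
                ids = [r.specimen_id for r in coll.sequenced()]
            else:
                ids = [
                    r.specimen_id for r in coll.sequenced()
                    if r.ecoregion == summ.label
                ]
            sub = coll.subset(ids)
            if len({r.species for r in sub.sequenced()}) < 2:
                continue
            oracle = build_species_summaries(sub)
            nnds = [s.nn_distance for s in oracle if s.nn_distance is not None]
            assert summ.mean_nnd == pytest.approx(sum(nnds) / len(nnds))
            assert summ.max_nnd == pytest.approx(max(nnds))

    def test_missing_key_skipped(self, template):
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template, ecoregion="Great Plains"),
            make_record("s2", "Cc dd", template),
        ])
        _, skipped = partition_and_summarize(coll, "ecoregion")
        assert skipped == 1

    def test_unknown_key_errors(self, template):
        coll = two_region_library(template, co_occur=True)
        with pytest.raises(ValueError, match="unknown partition key"):
            partition_and_summarize(coll, "altitude")

    def test_lat_band_partition(self, template):
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template, latitude=52.0),
            make_record("s2", "Cc dd", template, latitude=33.0),
        ])
        summaries, _ = partition_and_summarize(coll, "lat_band")
        labels = {s.label for s in summaries}
        assert labels == {"50-55", "30-35", "Total"}


class TestPresenceAbsence:
    def test_matrix_shape_and_sums(self, template):
        coll = two_region_library(template, co_occur=False)
        df, skipped = presence_absence_matrix(coll, "ecoregion")
        assert skipped == 0
        assert df.loc["Aa bb"].sum() == 1
        summaries, _ = partition_and_summarize(coll, "ecoregion")
        for s in summaries:
            if s.label == "Total":
                continue
            assert df[s.label].sum() == s.n_species

    def test_species_in_two_regions(self, template):
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template, ecoregion="Great Plains"),
            make_record("s2", "Aa bb", template, ecoregion="Boreal"),
        ])
        df, _ = presence_absence_matrix(coll, "ecoregion")
        assert df.loc["Aa bb"].sum() == 2

    def test_missing_gps_excluded_and_counted(self, template):
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template, latitude=52.0),
            make_record("s2", "Cc dd", template),
        ])
        df, skipped = presence_absence_matrix(coll, "lat_band")
        assert skipped == 1 and "Cc dd" not in df.index


class TestRegionOverlap:
    def test_planted_three_region_design(self):
        cluster_regions = {
            "c1": {"Nearctic"},
            "c2": {"Nearctic", "Neotropical"},
            "c3": {"Nearctic", "Palaearctic"},
            "c4": {"Nearctic"},
        }
        fams = {c: "F1" for c in cluster_regions}
        m = region_overlap(cluster_regions, fams)
        assert m.n_clusters["Total"] == 4
        assert int(m.counts.loc["Total", "Neotropical"]) == 1
        assert m.n_endemic == 2
        assert m.endemic_pct == 50.0
        assert m.region_pct("Neotropical") == 25.0

    def test_every_cluster_in_some_region(self):
        m = region_overlap({"c1": {"Nearctic"}, "c2": set()})
        assert m.n_clusters["Total"] == 1 and m.n_excluded == 1

    def test_unknown_region_errors(self):
        with pytest.raises(ValueError, match="unknown region"):
            region_overlap({"c1": {"Atlantis"}})

    def test_from_collection(self, template):
        rng = np.random.default_rng(4)
        far = mutate_sequence(template, 60, 3.0, rng)
        coll = SpecimenCollection([
            make_record("s1", "Aa bb", template, family="F1", zoogeo_region="Nearctic"),
            make_record("s2", "Aa bb", template, family="F1", zoogeo_region="Neotropical"),
            make_record("s3", "Cc dd", far, family="F2", zoogeo_region="Nearctic"),
        ])
        partition = single_linkage_clusters(pairwise_matrix(coll), 2.2)
        regions, fams = cluster_regions_from_collection(partition, coll)
        m = region_overlap(regions, fams)
        assert m.n_clusters["Total"] == 2
        assert m.n_endemic == 1
        assert int(m.counts.loc["Total", "Neotropical"]) == 1

    def test_regional_sharing_never_exceeds_continental(self, default_library):
        collection, _ = default_library
        summaries, _ = partition_and_summarize(collection, "ecoregion")
        continental = build_species_summaries(collection)
        n_cont = sum(
            1 for s in continental
            if s.assessed and Category.SHARING in s.categories
        )
        for s in summaries:
            if s.label != "Total":
                assert s.n_sharing <= n_cont
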