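import numpy as np
import pytest

from elmcortex import (
    FeatureTable,
    MissingRegionError,
    ParseError,
    SchemaError,
    ValidationError,
    descriptor_for_index,
    normalize_minmax,
    parse_freesurfer_stats,
    read_feature_table,
    standard_schema,
    table_from_records,
    write_feature_table,
)
from elmcortex.schema import MEASURES, REGIONS, generic_descriptors

from conftest import random_table, stats_value, write_stats_file


class TestStandardSchema:
    def test_has_340_features(self):
        assert len(standard_schema()) == 340

    def test_measure_blocks_match_table_layout(self):
        schema = standard_schema()
        blocks = {"thickness": (1, 68), "surface_area": (69, 136),
                  "volume": (137, 204), "folding_index": (205, 272),
                  "curvature": (273, 340)}
        for measure, (lo, hi) in blocks.items():
            assert all(schema[i - 1].measure == measure
                       for i in range(lo, hi + 1))

    def test_known_index_maps_to_right_transversetemporal_folding(self):
        d = descriptor_for_index(271)
        assert (d.measure, d.hemisphere, d.region) == \
            ("folding_index", "right", "transversetemporal")
        assert d.label() == "[271, FI, R-Transversetemporal]"

    def test_bijection_and_identical_block_ordering(self):
        schema = standard_schema()
        triples = {(d.measure, d.hemisphere, d.region) for d in schema}
        assert len(triples) == 340
        assert [d.index for d in schema] == list(range(1, 341))
        first_block = [(d.hemisphere, d.region) for d in schema[:68]]
        for b in range(1, 5):
            block = [(d.hemisphere, d.region)
                     for d in schema[68 * b:68 * (b + 1)]]
            assert block == first_block
        assert len(set(first_block)) == 68


class TestNormalize:
    def test_affine_map_to_unit_interval(self):
        t = FeatureTable(np.array([[2.0], [4.0], [6.0]]),
                         np.array([1, 1, -1]), ["a", "b", "c"],
                         generic_descriptors(["x"]))
        out = normalize_minmax(t)
        assert np.allclose(out.values[:, 0], [0, 0.5, 1])
        assert out.normalized
        assert np.allclose(t.values[:, 0], [2, 4, 6])  # input untouched

    def test_constant_column_maps_to_zeros(self):
        t = FeatureTable(np.full((3, 1), 3.0), np.array([1, 1, -1]),
                         ["a", "b", "c"], generic_descriptors(["x"]))
        assert np.all(normalize_minmax(t).values == 0.0)

    def test_idempotent_and_attains_bounds(self):
        t = random_table(np.random.default_rng(0), n=20, d=7)
        once = normalize_minmax(t)
        assert np.allclose(once.values.min(axis=0), 0)
        assert np.allclose(once.values.max(axis=0), 1)
        twice = normalize_minmax(once)
        assert np.allclose(once.values, twice.values)

    def test_rejects_single_subject(self):
        t = FeatureTable(np.ones((1, 2)), np.array([1]), ["a"],
                         generic_descriptors(["x", "y"]))
        with pytest.raises(ValidationError):
            normalize_minmax(t)


class TestTableIO:
    def test_round_trip_identity(self, tmp_path):
        t = random_table(np.random.default_rng(3), n=9, d=5)
        path = tmp_path / "t.csv"
        write_feature_table(t, path)
        back = read_feature_table(path)
        assert np.array_equal(back.values, t.values)
        assert np.array_equal(back.labels, t.labels)
        assert back.subject_ids == t.subject_ids
        assert not back.normalized

    def test_round_trip_standard_schema_descriptors(self, tmp_path):
        from elmcortex import CohortSpec, generate_cohort
        t = generate_cohort(CohortSpec(n_patients=3, n_controls=3, seed=0))
        path = tmp_path / "t.csv"
        write_feature_table(t, path)
        back = read_feature_table(path)
        assert [d.index for d in back.descriptors] == list(range(1, 341))
        assert back.descriptors[270].region == "transversetemporal"
        assert np.array_equal(back.values, t.values)

    def test_empty_table_round_trips(self, tmp_path):
        t = FeatureTable(np.empty((0, 3)), np.empty(0, dtype=int), [],
                         generic_descriptors(["a", "b", "c"]))
        path = tmp_path / "empty.csv"
        write_feature_table(t, path)
        back = read_feature_table(path)
        assert back.n_subjects == 0 and back.n_features == 3

    def test_string_labels_accepted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,diagnosis,f1\na,ADHD,1.5\nb,control,2.5\n")
        t = read_feature_table(path)
        assert list(t.labels) == [1, -1]

    def test_missing_label_column_is_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,f1\na,1.0\n")
        with pytest.raises(SchemaError, match="diagnosis"):
            read_feature_table(path)

    def test_non_numeric_cell_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,diagnosis,f1,f2\na,1,1.0,NA\nb,-1,2.0,3.0\n")
        with pytest.raises(ParseError, match=r"row 0.*'f2'"):
            read_feature_table(path)

    def test_duplicate_subject_id_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,diagnosis,f1\na,1,1.0\na,-1,2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_feature_table(path)


class TestFreeSurferStats:
    def test_complete_record_in_schema_order(self, stats_pair):
        record = parse_freesurfer_stats(*stats_pair)
        assert len(record) == 340
        descs = list(record.keys())
        assert [d.index for d in descs] == list(range(1, 341))

    def test_values_land_at_the_right_schema_slot(self, stats_pair):
        record = parse_freesurfer_stats(*stats_pair)
        by_key = {(d.measure, d.hemisphere, d.region): v
                  for d, v in record.items()}
        pos = REGIONS.index("cuneus")
        assert by_key[("thickness", "left", "cuneus")] == \
            stats_value(pos, "lh", "ThickAvg")
        assert by_key[("folding_index", "right", "insula")] == \
            stats_value(REGIONS.index("insula"), "rh", "FoldInd")

    def test_missing_region_error_names_it(self, tmp_path):
        lh = write_stats_file(tmp_path / "lh.stats", "lh",
                              skip_regions=("insula",))
        rh = write_stats_file(tmp_path / "rh.stats", "rh")
        with pytest.raises(MissingRegionError, match="insula"):
            parse_freesurfer_stats(lh, rh)

    def test_malformed_header_is_parse_error(self, tmp_path):
        bad = tmp_path / "bad.stats"
        bad.write_text("# no colheaders here\nbankssts 1 2 3\n")
        rh = write_stats_file(tmp_path / "rh.stats", "rh")
        with pytest.raises(ParseError):
            parse_freesurfer_stats(bad, rh)

    def test_cohort_of_records_builds_340_column_table(self, tmp_path):
        records, labels, ids = [], [], []
        for i in range(4):
            lh = write_stats_file(tmp_path / f"lh{i}.stats", "lh")
            rh = write_stats_file(tmp_path / f"rh{i}.stats", "rh")
            records.append(parse_freesurfer_stats(lh, rh))
            labels.append(1 if i % 2 == 0 else -1)
            ids.append(f"sub{i}")
        table = table_from_records(records, labels, ids)
        assert table.n_features == 5 * 68 == 340
        assert table.n_subjects == 4

    def test_subset_of_measures(self, stats_pair):
        record = parse_freesurfer_stats(*stats_pair,
                                        measures=("thickness", "volume"))
        assert len(record) == 136
        assert {d.measure for d in record} == {"thickness", "volume"}


class TestFeatureTableValidation:
    @pytest.mark.parametrize("labels", [[1, 2, -1], [0, 1, -1]])
    def test_rejects_non_pm1_labels(self, labels):
        with pytest.raises(ValidationError):
            FeatureTable(np.ones((3, 1)), np.array(labels), ["a", "b", "c"],
                         generic_descriptors(["x"]))

    def test_rejects_non_finite_values(self):
        with pytest.raises(ValidationError):
            FeatureTable(np.array([[1.0], [np.nan]]), np.array([1, -1]),
                         ["a", "b"], generic_descriptors(["x"]))

    def test_select_features_by_1based_index(self, separable_cohort):
        spec, table = separable_cohort
        sub = table.select_features([271, 72])
        assert sub.descriptors[0].index == 271
        assert sub.n_features == 2
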