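"""I/O, binarization, aggregation and filtering of incidence matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bipnull as bp
from bipnull.incidence import (
    BinaryDomainError,
    CoverageError,
    DegenerateNetworkError,
    FormatError,
    LabelingError,
)

# (plants, fungal nodes) dimensions spanning the range of published
# plant-AMF association surveys, single-plant studies included
SURVEY_DIMS = [
    (1, 14), (10, 48), (1, 49), (3, 24), (6, 12), (4, 8), (5, 23), (11, 40),
    (1, 24), (2, 16), (1, 71), (1, 33), (3, 23), (3, 20), (5, 37), (33, 56),
    (17, 22), (2, 29), (245, 247), (3, 13), (1, 59), (5, 81), (1, 47),
    (5, 38), (3, 92), (218, 277), (3, 52), (1, 148), (1, 21), (12, 18),
    (2, 24), (10, 17), (2, 16), (18, 87), (2, 321), (12, 207),
]


def _write(tmp_path, text, name="m.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadWrite:
    def test_direct_read(self, tmp_path):
        path = _write(tmp_path, ",F1,F2\nP1,1,0\nP2,0,1\n")
        inc = bp.read_incidence(path)
        assert inc.row_labels == ("P1", "P2")
        assert inc.col_labels == ("F1", "F2")
        assert list(inc.row_degrees) == [1, 1]
        assert list(inc.col_degrees) == [1, 1]

    def test_binarize_any_positive_count(self, tmp_path):
        path = _write(tmp_path, ",F1,F2\nP1,5,0\nP2,2,3\n")
        inc = bp.read_incidence(path, binarize=True)
        assert inc.entries.tolist() == [[1, 0], [1, 1]]

    def test_nonbinary_rejected_without_binarize(self, tmp_path):
        path = _write(tmp_path, ",F1,F2\nP1,5,0\nP2,2,3\n")
        with pytest.raises(BinaryDomainError):
            bp.read_incidence(path)

    def test_duplicate_row_labels_rejected(self, tmp_path):
        path = _write(tmp_path, ",F1,F2\nT.zygis,1,0\nT.zygis,0,1\n")
        with pytest.raises(LabelingError):
            bp.read_incidence(path)

    def test_duplicate_column_labels_rejected(self, tmp_path):
        path = _write(tmp_path, ",F1,F1\nP1,1,0\nP2,0,1\n")
        with pytest.raises(LabelingError):
            bp.read_incidence(path)

    @pytest.mark.parametrize("cell", ["-1", "x"])
    def test_bad_cells_rejected(self, tmp_path, cell):
        path = _write(tmp_path, f",F1,F2\nP1,1,{cell}\nP2,0,1\n")
        with pytest.raises(FormatError):
            bp.read_incidence(path, binarize=True)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip(self, tmp_path, seed):
        inc = bp.gen_random(7, 11, 0.4, seed=seed)
        path = tmp_path / "rt.csv"
        bp.write_incidence(inc, path)
        back = bp.read_incidence(path)
        assert back == inc


class TestOccurrences:
    RECORDS = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2"],
            "plant_node": ["A", "A", "A"],
            "amf_node": ["f1", "f2", "f2"],
            "count": [3, 0, 1],
        }
    )

    def test_per_sample_rows(self):
        inc = bp.occurrence_to_incidence(self.RECORDS, plant_key="sample")
        assert inc.row_labels == ("s1", "s2")
        assert inc.entries.tolist() == [[1, 0], [0, 1]]

    def test_pooled_by_plant(self):
        inc = bp.occurrence_to_incidence(self.RECORDS, plant_key="plant")
        assert inc.row_labels == ("A",)
        assert inc.entries.tolist() == [[1, 1]]

    def test_zero_count_fungus_keeps_empty_column(self):
        table = pd.concat(
            [self.RECORDS, pd.DataFrame([{"sample_id": "s1", "plant_node": "A",
                                          "amf_node": "f3", "count": 0}])]
        )
        inc = bp.occurrence_to_incidence(table, plant_key="sample")
        assert "f3" in inc.col_labels
        assert inc.col_degrees[inc.col_labels.index("f3")] == 0

    def test_empty_table_rejected(self):
        with pytest.raises(bp.incidence.IncidenceError):
            bp.occurrence_to_incidence(self.RECORDS.iloc[:0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(perm_seed=st.integers(0, 10_000))
    def test_record_order_invariance(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        shuffled = self.RECORDS.iloc[rng.permutation(len(self.RECORDS))]
        base = bp.occurrence_to_incidence(self.RECORDS, plant_key="sample")
        other = bp.occurrence_to_incidence(shuffled, plant_key="sample")
        # same associations regardless of record order (label order may differ)
        assert base.to_frame().sort_index(axis=0).sort_index(axis=1).equals(
            other.to_frame().sort_index(axis=0).sort_index(axis=1)
        )


class TestAggregation:
    def test_boolean_or_merge(self):
        inc = bp.BipartiteIncidence(("r1", "r2"), ("c1", "c2", "c3"),
                                    [[1, 0, 1], [0, 0, 1]])
        amap = bp.AggregationMap("meta_network", {"r1": "speciesA", "r2": "speciesA"})
        out = bp.aggregate_plants(inc, amap)
        assert out.row_labels == ("speciesA",)
        assert out.entries.tolist() == [[1, 0, 1]]

    def test_identity_map_is_noop(self):
        inc = bp.gen_random(5, 6, 0.5, seed=1)
        out = bp.aggregate_plants(inc, bp.AggregationMap.identity(inc.row_labels))
        assert out == inc

    def test_species_by_site_collapse_matches_groupwise_or(self):
        # 12 sample-rows: 2 species x 3 sites x 2 replicates, aggregated to
        # the species-per-site (population) level
        rng = np.random.default_rng(7)
        entries = (rng.random((12, 5)) < 0.5).astype(int)
        combos = [(sp, site) for sp in "AB" for site in ("s1", "s2", "s3")]
        labels = tuple(
            f"{sp}_{site}_{rep}" for sp, site in combos for rep in (1, 2)
        )
        inc = bp.BipartiteIncidence(labels, tuple("vwxyz"), entries)
        mapping = {lab: lab.rsplit("_", 1)[0] for lab in labels}
        out = bp.aggregate_plants(inc, bp.AggregationMap("population", mapping))
        assert out.n_rows == 6  # one row per species-site population
        for i, lab in enumerate(out.row_labels):
            members = [j for j, l in enumerate(labels) if mapping[l] == lab]
            expected = np.zeros(5, dtype=int)
            for j in members:
                expected |= entries[j]
            assert out.entries[i].tolist() == expected.tolist()

    def test_unmapped_row_is_coverage_error(self):
        inc = bp.gen_random(3, 4, 0.5, seed=2)
        with pytest.raises(CoverageError):
            bp.aggregate_plants(inc, bp.AggregationMap("x", {inc.row_labels[0]: "a"}))

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregation_degree_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        inc = bp.gen_random(8, 6, 0.3, seed=seed)
        targets = rng.integers(0, 3, size=8)
        amap = bp.AggregationMap("region", {l: f"g{t}" for l, t in zip(inc.row_labels, targets)})
        out = bp.aggregate_plants(inc, amap)
        assert (out.col_degrees <= inc.col_degrees).all()
        assert out.n_links <= inc.n_links


class TestFilterAndHygiene:
    def test_too_few_fungi_rejected_with_reason(self):
        inc = bp.gen_random(3, 4, 0.9, seed=0)
        decision = bp.filter_dataset(inc)
        assert not decision
        assert decision.reason == "fungal nodes < 5"

    def test_single_plant_retained(self):
        inc = bp.BipartiteIncidence(("only",), tuple(f"F{i}" for i in range(14)),
                                    np.ones((1, 14), dtype=int))
        assert bp.filter_dataset(inc)

    def test_empty_plant_layer_rejected(self):
        inc = bp.BipartiteIncidence((), tuple(f"F{i}" for i in range(10)),
                                    np.zeros((0, 10), dtype=int))
        assert not bp.filter_dataset(inc)

    def test_all_published_survey_dimensions_pass(self):
        for n_plants, n_fungi in SURVEY_DIMS:
            inc = bp.BipartiteIncidence(
                tuple(f"P{i}" for i in range(n_plants)),
                tuple(f"F{j}" for j in range(n_fungi)),
                np.zeros((n_plants, n_fungi), dtype=int),
            )
            assert bp.filter_dataset(inc), (n_plants, n_fungi)

    def test_drop_empty_nodes(self):
        inc = bp.BipartiteIncidence(("r1", "r2"), ("c1", "c2"), [[1, 0], [0, 0]])
        out, removed = bp.drop_empty_nodes(inc)
        assert out.entries.tolist() == [[1]]
        assert set(removed) == {"r2", "c2"}

    def test_drop_empty_noop(self, two_blocks):
        out, removed = bp.drop_empty_nodes(two_blocks)
        assert removed == []
        assert out == two_blocks

    def test_all_zero_matrix_is_degenerate(self):
        inc = bp.BipartiteIncidence(tuple("abc"), tuple("xyz"), np.zeros((3, 3), dtype=int))
        with pytest.raises(DegenerateNetworkError):
            bp.drop_empty_nodes(inc)
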