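import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.discrimination import (
    DiscriminationReport,
    DistancePartition,
    barcoding_gap,
    build_report,
    fraction_above,
    interspecific_summary,
    intraspecific_summary,
    partition_distances,
    report_row,
    write_report_table,
    REPORT_COLUMNS,
)
from barcodegap.distances import distance_matrix
from barcodegap.haplotypes import GapMode, collapse_haplotypes, count_variable_sites
from barcodegap.io_model import (
    Dataset,
    InputError,
    MetadataTable,
    SampleMetadata,
    build_dataset,
)
from barcodegap.pipeline import evaluate_dataset, representatives_dataset
from conftest import make_alignment
from oracles import naive_mean_sd_max


BASE_SEQ = "ACGTACGTACGT" * 10


def mutate(seq: str, positions: dict[int, str]) -> str:
    out = list(seq)
    for pos, char in positions.items():
        out[pos] = char
    return "".join(out)


def meta_for(rows):
    return MetadataTable(
        SampleMetadata(acc, sp, ("Root",), None, bool(rep)) for acc, sp, rep in rows
    )


def ds_for(seqs: dict[str, str]) -> Dataset:
    labels = tuple(seqs)
    return Dataset("toy", labels, dict(seqs), len(labels), len(next(iter(seqs.values()))))


def part_for(inter, intra_by_species, n_undef=0):
    return DistancePartition(
        interspecific=tuple(inter),
        intraspecific_by_species=dict(intra_by_species),
        n_undefined_excluded=n_undef,
    )


class TestPartitionDistances:
    def test_three_singleton_species(self):
        seqs = {"a1": BASE_SEQ, "b1": mutate(BASE_SEQ, {0: "G"}),
                "c1": mutate(BASE_SEQ, {0: "T", 5: "A"})}
        meta = meta_for([("a1", "A", 1), ("b1", "B", 1), ("c1", "C", 1)])
        dm = distance_matrix(ds_for(seqs), min_overlap=1)
        part = partition_distances(dm, meta)
        assert len(part.interspecific) == 3
        assert part.intraspecific_by_species == {}

    def test_one_species_three_accessions(self):
        seqs = {"a1": BASE_SEQ, "a2": mutate(BASE_SEQ, {3: "A"}),
                "a3": mutate(BASE_SEQ, {7: "C"})}
        meta = meta_for([("a1", "A", 1), ("a2", "A", 0), ("a3", "A", 0)])
        part = partition_distances(distance_matrix(ds_for(seqs), min_overlap=1), meta)
        assert part.interspecific == ()
        assert len(part.intraspecific_by_species["A"]) == 3

    def test_two_by_two_uses_representatives_for_inter(self):
        # enumerate all 6 pairs: 1 representative inter pair, 2 intra pairs,
        # 3 mixed rep/non-rep cross-species pairs are dropped
        seqs = {"a1": BASE_SEQ, "a2": mutate(BASE_SEQ, {1: "T"}),
                "b1": mutate(BASE_SEQ, {0: "G", 4: "C", 9: "A"}),
                "b2": mutate(BASE_SEQ, {0: "G", 4: "C", 9: "A", 13: "G"})}
        meta = meta_for([("a1", "A", 1), ("a2", "A", 0),
                         ("b1", "B", 1), ("b2", "B", 0)])
        part = partition_distances(distance_matrix(ds_for(seqs), min_overlap=1), meta)
        assert len(part.interspecific) == 1
        assert part.interspecific[0][:2] == ("A", "B")
        assert {sp: len(v) for sp, v in part.intraspecific_by_species.items()} \
            == {"A": 1, "B": 1}

    def test_undefined_distances_are_counted_and_excluded(self):
        seqs = {"a1": "ACGT" + "N" * 116, "b1": "NNNN" + "A" * 116 + "",
                "c1": "ACGT" + "A" * 116}
        meta = meta_for([("a1", "A", 1), ("b1", "B", 1), ("c1", "C", 1)])
        part = partition_distances(distance_matrix(ds_for(seqs), min_overlap=100), meta)
        assert part.n_undefined_excluded >= 1
        assert all(not math.isnan(d) for _, _, d in part.interspecific)

    def test_label_without_metadata_raises(self):
        seqs = {"a1": "ACGT" * 30, "zz": "ACGT" * 30}
        meta = meta_for([("a1", "A", 1)])
        with pytest.raises(InputError):
            partition_distances(distance_matrix(ds_for(seqs), min_overlap=1), meta)


class TestSummaries:
    def test_species_averaged_mean(self):
        part = part_for([], {"X": [0.0, 0.0], "Y": [0.01]})
        s = intraspecific_summary(part)
        assert s.mean == pytest.approx(0.005)
        assert s.max == pytest.approx(0.01)
        assert s.n_species == 2

    def test_single_pair_species(self):
        s = intraspecific_summary(part_for([], {"X": [0.003]}))
        assert (s.mean, s.sd, s.max) == (0.003, 0.0, 0.003)
        assert s.n_accessions == 2

    def test_all_zero(self):
        s = intraspecific_summary(part_for([], {"X": [0.0], "Y": [0.0, 0.0, 0.0]}))
        assert (s.mean, s.max) == (0.0, 0.0)

    def test_no_multi_accession_species_gives_none(self):
        assert intraspecific_summary(part_for([("A", "B", 0.01)], {})) is None

    def test_interspecific_trivial(self):
        mean, sd, mx = interspecific_summary(
            part_for([("A", "B", 0.01), ("A", "C", 0.03)], {}))
        assert (mean, mx) == (pytest.approx(0.02), 0.03)

    def test_single_pair_sd_zero(self):
        assert interspecific_summary(part_for([("A", "B", 0.01)], {}))[1] == 0.0

    def test_matches_naive_oracle(self):
        rng = random.Random(9)
        vals = [rng.uniform(0, 0.1) for _ in range(10)]
        part = part_for([("A", f"S{i}", v) for i, v in enumerate(vals)], {})
        assert interspecific_summary(part) == pytest.approx(naive_mean_sd_max(vals))


class TestFractionAbove:
    @pytest.mark.parametrize("threshold, expected", [(0.01, 66.67), (0.02, 33.33)])
    def test_strict_inequality_counting(self, threshold, expected):
        part = part_for([("A", "B", 0.005), ("A", "C", 0.015), ("B", "C", 0.025)], {})
        assert fraction_above(part, threshold) == expected

    def test_threshold_zero_with_positive_distances(self):
        part = part_for([("A", "B", 0.004), ("A", "C", 0.2)], {})
        assert fraction_above(part, 0.0) == 100.00

    @given(st.lists(st.floats(0, 0.2), min_size=1, max_size=30),
           st.floats(0, 0.1), st.floats(0, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_in_threshold(self, dists, t1, t2):
        lo, hi = sorted((t1, t2))
        part = part_for([("A", f"S{i}", d) for i, d in enumerate(dists)], {})
        assert fraction_above(part, lo) >= fraction_above(part, hi)


class TestBarcodingGap:
    def test_gap_exists(self):
        gap = barcoding_gap(part_for([("A", "B", 0.02), ("A", "C", 0.03)],
                                     {"A": [0.001]}))
        assert gap.gap_exists and gap.gap_margin == pytest.approx(0.019)

    def test_overlap_means_no_gap(self):
        gap = barcoding_gap(part_for([("A", "B", 0.005)], {"A": [0.01]}))
        assert not gap.gap_exists and gap.gap_margin == pytest.approx(-0.005)

    def test_zero_margin_is_not_a_gap(self):
        gap = barcoding_gap(part_for([("A", "B", 0.0)], {"A": [0.0]}))
        assert not gap.gap_exists and gap.gap_margin == 0.0

    def test_histograms_cover_pooled_range_and_counts(self):
        part = part_for([("A", "B", 0.012), ("A", "C", 0.024)], {"A": [0.001]})
        gap = barcoding_gap(part, bin_width=0.005)
        assert gap.bin_edges[0] == 0.0
        assert gap.inter_hist.sum() == 2 and gap.intra_hist.sum() == 1
        assert gap.bin_edges[-1] >= 0.024

    def test_empty_intraspecific_raises(self):
        with pytest.raises(InputError):
            barcoding_gap(part_for([("A", "B", 0.01)], {}))


class TestReport:
    def _toy_report(self):
        aln = make_alignment(
            {"L": {"a1": "ACGTACGTAC" * 12, "a2": "ACGTACGTAC" * 12,
                   "b1": "ACGAACGTAC" * 12, "c1": "TCGAACTTAC" * 12}},
            [("a1", "A", ["R"], None, 1), ("a2", "A", ["R"], None, 0),
             ("b1", "B", ["R"], None, 1), ("c1", "C", ["R"], None, 1)],
        )
        ds = build_dataset(aln, ["L"])
        return evaluate_dataset(ds, aln.metadata, min_overlap=10).report

    def test_toy_row_complete_and_consistent(self):
        rep = self._toy_report()
        assert rep.n_species == 3
        assert 0 <= rep.pct_gt_2 <= rep.pct_gt_1 <= 100
        assert rep.inter_mean <= rep.inter_max
        assert rep.intra_mean == 0.0  # a1 == a2

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            DiscriminationReport(
                dataset_name="x", n_species=2, aligned_length=10, n_variable=1,
                n_unique=2, n_unique_fifth=2, max_id_rate_pct=100.0,
                inter_max=0.01, inter_mean=0.005, inter_sd=0.0,
                pct_gt_1=10.0, pct_gt_2=20.0,
            )

    def test_row_formatting_conventions(self):
        rep = DiscriminationReport(
            dataset_name="locX", n_species=108, aligned_length=491, n_variable=103,
            n_unique=54, n_unique_fifth=79, max_id_rate_pct=50.0,
            inter_max=0.0597, inter_mean=0.0184, inter_sd=0.0098,
            pct_gt_1=84.94, pct_gt_2=41.64,
        )
        row = report_row(rep)
        assert row["Unique sequences"] == "54 (79)"
        assert row["% Max ID rate"] == "50.00"
        assert row["Mean (SD)"] == "0.0184 (0.0098)"
        assert row["Max"] == "0.0597"

    def test_table_has_conventional_header(self, tmp_path):
        rep = self._toy_report()
        out = tmp_path / "table.tsv"
        write_report_table([rep], out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == REPORT_COLUMNS
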