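"""Input parsing, validation, interval lookup and challenge output files."""

from __future__ import annotations

import numpy as np
import pytest

from subclonekit.tumor_io import (
    FormatError,
    ValidationError,
    is_sex_chromosome,
    lookup_cna,
    read_cna_segments,
    read_smchet_outputs,
    read_snv_table,
    write_cna_table,
    write_snv_table,
    write_smchet_outputs,
)

from conftest import make_segment, make_snv


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadSnvTable:
    def test_basic_parsing_and_beta(self, tmp_path):
        path = write(
            tmp_path, "snv.tsv",
            "chrom\tpos\tref_count\talt_count\nchr1\t100\t60\t40\nchrX\t5\t10\t0\n",
        )
        records = read_snv_table(path)
        assert records[0].beta == pytest.approx(0.4)
        assert records[0].total_count == 100
        assert records[1].beta == 0.0
        assert not records[1].on_male_sex_chromosome  # female default

    def test_male_sex_chromosome_flag(self, tmp_path):
        path = write(
            tmp_path, "snv.tsv",
            "chrom\tpos\tref_count\talt_count\nchrX\t5\t10\t2\nchr2\t9\t10\t2\n",
        )
        records = read_snv_table(path, sex="male")
        assert records[0].on_male_sex_chromosome
        assert not records[1].on_male_sex_chromosome

    def test_missing_column_names_the_column(self, tmp_path):
        path = write(tmp_path, "snv.tsv", "chrom\tpos\tref_count\nchr1\t1\t5\n")
        with pytest.raises(FormatError, match="alt_count"):
            read_snv_table(path)

    def test_zero_depth_rejected_with_line_number(self, tmp_path):
        path = write(
            tmp_path, "snv.tsv",
            "chrom\tpos\tref_count\talt_count\nchr1\t100\t0\t0\n",
        )
        with pytest.raises(ValidationError, match="line 2"):
            read_snv_table(path)

    def test_negative_count_rejected(self, tmp_path):
        path = write(
            tmp_path, "snv.tsv",
            "chrom\tpos\tref_count\talt_count\nchr1\t100\t-1\t4\n",
        )
        with pytest.raises(ValidationError):
            read_snv_table(path)

    def test_round_trip(self, tmp_path):
        records = [make_snv(4, 30, chrom="chr1", pos=11), make_snv(0, 9, chrom="chr2", pos=5)]
        write_snv_table(records, tmp_path / "out.tsv")
        assert read_snv_table(tmp_path / "out.tsv") == records


@pytest.mark.parametrize(
    "name,expected",
    [("X", True), ("chrY", True), ("chrx", True), ("chr2", False), ("MT", False)],
)
def test_sex_chromosome_detection(name, expected):
    assert is_sex_chromosome(name) is expected


class TestReadCnaSegments:
    def test_identical_intervals_merge_into_multistate(self, tmp_path):
        path = write(
            tmp_path, "cna.tsv",
            "chrom\tstart\tend\tmajor\tminor\nchr2\t0\t1000\t2\t1\nchr2\t0\t1000\t3\t0\n",
        )
        (segment,) = read_cna_segments(path)
        assert segment.multistate
        assert [(s.n_major, s.n_minor) for s in segment.states] == [(2, 1), (3, 0)]

    def test_single_state_segment(self, tmp_path):
        path = write(
            tmp_path, "cna.tsv",
            "chrom\tstart\tend\tmajor\tminor\nchr3\t0\t500\t2\t2\n",
        )
        (segment,) = read_cna_segments(path)
        assert not segment.multistate

    def test_partial_overlap_rejected(self, tmp_path):
        path = write(
            tmp_path, "cna.tsv",
            "chrom\tstart\tend\tmajor\tminor\n"
            "chr2\t0\t1000\t2\t1\nchr2\t500\t1500\t2\t1\n",
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_cna_segments(path)

    def test_major_below_minor_rejected(self, tmp_path):
        path = write(
            tmp_path, "cna.tsv",
            "chrom\tstart\tend\tmajor\tminor\nchr2\t0\t1000\t1\t2\n",
        )
        with pytest.raises(ValidationError):
            read_cna_segments(path)

    def test_fraction_column_round_trip(self, tmp_path):
        segment = make_segment((2, 1), (3, 2))
        states = tuple(
            type(s)(n_major=s.n_major, n_minor=s.n_minor, fraction=0.5)
            for s in segment.states
        )
        segment = type(segment)(
            chromosome=segment.chromosome, start=segment.start,
            end=segment.end, states=states,
        )
        write_cna_table([segment], tmp_path / "cna.tsv")
        assert read_cna_segments(tmp_path / "cna.tsv") == [segment]


class TestLookup:
    def test_coordinate_conversion_and_boundaries(self):
        segment = make_segment((2, 1), chrom="chr2", start=0, end=1000)
        inside = make_snv(1, 10, chrom="chr2", pos=500)
        at_end = make_snv(1, 10, chrom="chr2", pos=1001)  # 0-based 1000: outside
        at_last = make_snv(1, 10, chrom="chr2", pos=1000)  # 0-based 999: inside
        assert lookup_cna(inside, [segment]) is segment
        assert lookup_cna(at_end, [segment]) is None
        assert lookup_cna(at_last, [segment]) is segment

    def test_absent_chromosome(self):
        segment = make_segment((2, 1), chrom="chr2")
        snv = make_snv(1, 10, chrom="chr9", pos=50)
        assert lookup_cna(snv, [segment]) is None

    def test_partition_property(self, rng):
        segments = [
            make_segment((2, 1), chrom="1", start=i * 1000, end=(i + 1) * 1000)
            for i in range(0, 10, 2)
        ]
        for _ in range(100):
            snv = make_snv(1, 10, chrom="1", pos=int(rng.integers(1, 12000)))
            hits = [s for s in segments if s.contains(snv.position - 1)]
            assert len(hits) <= 1
            assert lookup_cna(snv, segments) == (hits[0] if hits else None)


class _FakeResult:
    """Minimal inference-result stand-in for output writing."""

    def __init__(self, peaks, labels, parents):
        peaks = np.asarray(peaks, dtype=float)
        support = np.bincount(labels, minlength=peaks.size)
        self.model = type(
            "M", (), {
                "peaks": peaks,
                "purity": float(peaks[0]),
                "n_subclones": int(peaks.size),
                "snv_support": support,
            },
        )()
        self.assignment = type("A", (), {"hard_label": np.asarray(labels)})()
        self.best_tree = type("T", (), {"parent": tuple(parents)})()


class TestSmchetOutputs:
    def test_single_clone_layout(self, tmp_path):
        result = _FakeResult([0.75], [0] * 10, [-1])
        write_smchet_outputs(result, tmp_path)
        assert (tmp_path / "1A.txt").read_text() == "0.75\n"
        assert (tmp_path / "1B.txt").read_text() == "1\n"
        assert (tmp_path / "1C.txt").read_text() == "1\t10\t0.75\n"
        assert (tmp_path / "2A.txt").read_text().splitlines() == ["1"] * 10

    def test_chain_parent_encoding(self, tmp_path):
        result = _FakeResult([0.8, 0.5], [0, 0, 1], (-1, 0))
        write_smchet_outputs(result, tmp_path)
        assert (tmp_path / "3A.txt").read_text().splitlines() == ["0", "1"]

    def test_2a_line_count_matches_snv_count(self, tmp_path):
        labels = [0, 1, 1, 0, 1, 0, 0]
        result = _FakeResult([0.8, 0.4], labels, (-1, 0))
        write_smchet_outputs(result, tmp_path)
        assert len((tmp_path / "2A.txt").read_text().splitlines()) == len(labels)

    def test_read_back(self, tmp_path):
        result = _FakeResult([0.8, 0.4], [0, 1, 1], (-1, 0))
        write_smchet_outputs(result, tmp_path)
        files = read_smchet_outputs(tmp_path)
        assert files.purity == 0.8
        assert files.n_clones == 2
        assert files.assignments.tolist() == [0, 1, 1]
        assert files.parents.tolist() == [-1, 0]
        assert files.cluster_prevalence.tolist() == [0.8, 0.4]
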