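"""Composition extraction: FASTQ streaming, subsampling, tabulation."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import libtype as lt
from libtype.composition import FastqError

from conftest import write_fastq

TOY = [("r1", "ACGT", "IIII"), ("r2", "acgt", "IIII")]


class TestStreamFastq:
    def test_yields_records_in_order_and_uppercases(self, tmp_path):
        path = write_fastq(tmp_path / "toy.fastq", TOY)
        recs = list(lt.stream_fastq(path))
        assert [r.identifier for r in recs] == ["r1", "r2"]
        assert [r.sequence for r in recs] == ["ACGT", "ACGT"]
        assert recs[0].quality == "IIII"

    def test_gzip_transparency(self, tmp_path):
        plain = write_fastq(tmp_path / "toy.fastq", TOY)
        gz = tmp_path / "toy.fastq.gz"
        with open(plain, "rb") as src, gzip.open(gz, "wb") as dst:
            dst.write(src.read())
        assert list(lt.stream_fastq(gz)) == list(lt.stream_fastq(plain))

    def test_truncated_record_names_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\n")
        with pytest.raises(FastqError, match="record 2"):
            list(lt.stream_fastq(path))

    def test_length_mismatch_names_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(FastqError, match="record 1"):
            list(lt.stream_fastq(path))

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.raises(FastqError, match="empty"):
            list(lt.stream_fastq(path))


class TestReservoirSample:
    def _records(self, n):
        return [lt.FastqRecord(str(i), "ACGT", "IIII") for i in range(n)]

    def test_underfull_reservoir_returns_everything(self):
        sample, total = lt.reservoir_sample(self._records(10), k=100_000, seed=0)
        assert total == 10
        assert [r.identifier for r in sample] == [str(i) for i in range(10)]

    def test_overfull_reservoir_returns_exactly_k(self):
        sample, total = lt.reservoir_sample(self._records(5000), k=1000, seed=3)
        assert (len(sample), total) == (1000, 5000)
        assert len({r.identifier for r in sample}) == 1000  # without replacement

    def test_fixed_seed_is_bit_identical(self):
        a, _ = lt.reservoir_sample(self._records(2000), k=100, seed=5)
        b, _ = lt.reservoir_sample(self._records(2000), k=100, seed=5)
        assert [r.identifier for r in a] == [r.identifier for r in b]

    def test_selection_is_uniform(self):
        # each of 150 records should enter a k=15 sample with frequency 0.1
        n, k, trials = 150, 15, 1500
        recs = self._records(n)
        hits = np.zeros(n)
        for seed in range(trials):
            sample, _ = lt.reservoir_sample(recs, k=k, seed=seed)
            for r in sample:
                hits[int(r.identifier)] += 1
        chi2, p = stats.chisquare(hits)
        assert p > 1e-6, f"selection frequencies not uniform (p={p:.2g})"


class TestTabulate:
    def test_hand_enumerated_two_reads(self):
        reads = [lt.FastqRecord("a", "ACGT", "IIII"), lt.FastqRecord("b", "AAAA", "IIII")]
        prof = lt.tabulate_composition(reads, max_positions=4)
        expected = np.array([
            [2, 0, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 0],
            [1, 0, 0, 1, 0],
        ])
        assert (prof.counts == expected).all()

    def test_all_n_and_unknown_bases(self):
        prof = lt.tabulate_composition([lt.FastqRecord("a", "NX", "II")], max_positions=2)
        assert (prof.counts[:, 4] == [1, 1]).all()
        assert prof.counts[:, :4].sum() == 0

    def test_short_reads_truncate(self):
        prof = lt.tabulate_composition([lt.FastqRecord("a", "ACG", "III")], max_positions=50)
        assert prof.positions == 50
        assert prof.counts[:3].sum() == 3
        assert prof.counts[3:].sum() == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        reads = [
            lt.FastqRecord(str(i), "".join(rng.choice(list("ACGTN"), 30)), "I" * 30)
            for i in range(40)
        ]
        a = lt.tabulate_composition(reads, max_positions=30)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        b = lt.tabulate_composition(perm, max_positions=30)
        assert (a.counts == b.counts).all()

    def test_counts_conserve_covering_reads(self):
        reads = [lt.FastqRecord(str(i), "ACGTACGT"[: 4 + i % 5], "I" * (4 + i % 5))
                 for i in range(20)]
        prof = lt.tabulate_composition(reads, max_positions=8)
        lengths = np.array([len(r.sequence) for r in reads])
        covering = np.array([(lengths > p).sum() for p in range(8)])
        assert (prof.counts.sum(axis=1) == covering).all()

    def test_empty_read_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            lt.tabulate_composition([])


class TestToPercentages:
    def _profile(self, counts):
        counts = np.asarray(counts)
        return lt.CompositionProfile("t", counts, int(counts.sum(1).max()), 10)

    def test_single_base_column(self):
        pct = lt.to_percentages(self._profile([[2, 0, 0, 0, 0]]))
        assert pct.tolist() == [[100.0, 0.0, 0.0, 0.0]]

    def test_even_split(self):
        pct = lt.to_percentages(self._profile([[1, 1, 0, 0, 0]]))
        assert pct.tolist() == [[50.0, 50.0, 0.0, 0.0]]

    def test_n_excluded_from_denominator(self):
        pct = lt.to_percentages(self._profile([[1, 1, 1, 1, 4]]), include_n=False)
        assert np.allclose(pct, 25.0)
        with_n = lt.to_percentages(self._profile([[1, 1, 1, 1, 4]]), include_n=True)
        assert np.allclose(with_n, [12.5, 12.5, 12.5, 12.5, 50.0])

    def test_zero_coverage_warns_then_errors_in_strict(self):
        prof = self._profile([[1, 1, 0, 0, 0], [0, 0, 0, 0, 0]])
        with pytest.warns(UserWarning, match="position\\(s\\) 2"):
            pct = lt.to_percentages(prof)
        assert np.isnan(pct[1]).all()
        with pytest.raises(ValueError, match="position\\(s\\) 2"):
            lt.to_percentages(prof, strict=True)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 1000), min_size=5, max_size=5).filter(
                lambda row: sum(row[:4]) > 0
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_rows_sum_to_100(self, counts):
        pct = lt.to_percentages(self._profile(counts))
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)


class TestProfileRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(50, 5))
        prof = lt.CompositionProfile(
            "sampleX", counts, int(counts.sum(axis=1).max()), 300, seed=7
        )
        path = tmp_path / "p.tsv"
        lt.write_profile(prof, path)
        back = lt.read_profile(path)
        assert back == prof
        assert back.seed == 7

    def test_file_has_one_row_per_position(self, tmp_path):
        prof = lt.CompositionProfile("s", np.ones((50, 5), dtype=int), 5, 5)
        lt.write_profile(prof, tmp_path / "p.tsv")
        rows = [l for l in (tmp_path / "p.tsv").read_text().splitlines()
                if l and not l.startswith("#")]
        assert len(rows) == 51  # header + 50 positions

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("position\tA\tC\tG\tT\n1\t1\t1\t1\t1\n")
        with pytest.raises(ValueError, match="expected columns"):
            lt.read_profile(path)

    def test_non_integer_counts_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("position\tA\tC\tG\tT\tN\n1\t1.5\t1\t1\t1\t0\n")
        with pytest.raises(ValueError, match="integer"):
            lt.read_profile(path)


def test_profile_fastq_end_to_end(tmp_path):
    path = write_fastq(
        tmp_path / "lib.fastq",
        [(f"r{i}", "ACGTACGT", "IIIIIIII") for i in range(30)],
    )
    prof = lt.profile_fastq(path, max_positions=8, sample_reads=20, seed=0)
    assert prof.sample_id == "lib"
    assert (prof.reads_sampled, prof.reads_total) == (20, 30)
    assert (prof.counts.sum(axis=1) == 20).all()
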