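import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodyn.core_io import (
    EmptyProfileError,
    GenomicInterval,
    ParseError,
    PeakSet,
    SignalTrack,
    make_gene,
    meta_profile,
    overlap_any,
    overlaps,
    read_bed,
    read_bedgraph,
    read_gene_table,
    write_bed,
    write_bedgraph,
    write_gene_table,
)


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    @pytest.mark.parametrize("a,b,expected", [
        (("chr1", 100, 200), ("chr1", 150, 250), True),
        (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open touch
        (("chr1", 100, 200), ("chr2", 100, 200), False),
        (("chr1", 100, 200), ("chr1", 199, 500), True),
    ])
    def test_overlaps(self, a, b, expected):
        ia, ib = GenomicInterval(*a), GenomicInterval(*b)
        assert overlaps(ia, ib) is expected
        assert overlaps(ib, ia) is expected  # symmetry

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(s1=st.integers(0, 1000), w1=st.integers(1, 100),
           s2=st.integers(0, 1000), w2=st.integers(1, 100))
    def test_overlaps_symmetric_property(self, s1, w1, s2, w2):
        a = GenomicInterval("chr1", s1, s1 + w1)
        b = GenomicInterval("chr1", s2, s2 + w2)
        assert overlaps(a, b) == overlaps(b, a)
        # half-open definition: shared bp count positive iff overlap
        shared = min(a.end, b.end) - max(a.start, b.start)
        assert overlaps(a, b) == (shared > 0)


class TestBedIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        df = read_bed(p)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row.chrom, row.start, row.end) == ("chr1", 100, 200)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    @pytest.mark.parametrize("content", [
        "chr1\t200\t100\n",          # end <= start
        "chr1\tx\t100\n",            # non-integer
        "chr1\t100\n",               # too few columns
    ])
    def test_malformed_names_line(self, tmp_path, content):
        p = tmp_path / "bad.bed"
        p.write_text(content)
        with pytest.raises(ParseError, match="line 1"):
            read_bed(p)

    def test_signal_column(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t50\tpeak1\t3.5\t+\n")
        df = read_bed(p)
        assert df.iloc[0].signal == 3.5

    def test_round_trip_identity(self, tmp_path, rng):
        starts = np.sort(rng.choice(100_000, size=50, replace=False))
        df = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 100,
            "name": ".", "signal": rng.random(50).round(4), "strand": ".",
        })
        p = tmp_path / "rt.bed"
        write_bed(df, p)
        back = read_bed(p)
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "signal"]],
            df[["chrom", "start", "end", "signal"]])


class TestPeakSet:
    def test_sorted_and_deduplicated(self):
        df = pd.DataFrame({
            "chrom": ["chr2", "chr1", "chr1"],
            "start": [5, 10, 10], "end": [9, 20, 20],
            "name": ".", "signal": np.nan, "strand": ".",
        })
        ps = PeakSet(df, mark="H3K4me3", phase="interphase")
        assert len(ps) == 2
        assert list(ps.df["chrom"]) == ["chr1", "chr2"]

    def test_unknown_mark_rejected(self):
        with pytest.raises(ValueError, match="unknown mark"):
            PeakSet([], mark="H3K9me3")

    def test_clipping_at_chromosome_end(self):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1200],
                           "name": ".", "signal": np.nan, "strand": "."})
        clipped = PeakSet(df).clipped_to({"chr1": 1000})
        assert clipped.df.iloc[0].end == 1000


class TestOverlapAny:
    def test_against_brute_force(self, rng):
        q_starts = rng.integers(0, 10_000, size=200)
        s_starts = rng.integers(0, 10_000, size=150)
        q = pd.DataFrame({"chrom": "chr1", "start": q_starts,
                          "end": q_starts + rng.integers(1, 300, 200)})
        s = pd.DataFrame({"chrom": "chr1", "start": s_starts,
                          "end": s_starts + rng.integers(1, 300, 150)})
        got = overlap_any(q, s)
        want = np.array([
            bool(((s["start"] < qe) & (s["end"] > qs)).any())
            for qs, qe in zip(q["start"], q["end"])
        ])
        assert (got == want).all()


def _constant_track(value=2.5, binsize=100, length=100_000):
    n = -(-length // binsize)
    return SignalTrack(binsize=binsize, chrom_lengths={"chr1": length},
                       values={"chr1": np.full(n, value)})


class TestMetaProfile:
    def test_constant_track_flat(self):
        track = _constant_track(2.5)
        centers = [GenomicInterval("chr1", 40_000, 40_001),
                   GenomicInterval("chr1", 60_000, 60_001)]
        prof, n_used, n_dropped = meta_profile(track, centers, 2000, 100)
        assert n_used == 2 and n_dropped == 0
        assert len(prof) == 40
        np.testing.assert_allclose(prof, 2.5)

    def test_delta_at_center(self):
        track = _constant_track(0.0)
        track.values["chr1"][500] = 7.0  # bin covering 50_000..50_100
        # interval centered at 50_000: the center profile bin samples its
        # midpoint inside track bin 500
        centers = [GenomicInterval("chr1", 49_950, 50_050)]
        prof, _, _ = meta_profile(track, centers, 2000, 100)
        center_bin = len(prof) // 2
        assert prof[center_bin] == 7.0
        assert prof[center_bin - 1] == 0.0 and prof[center_bin + 1] == 0.0

    def test_edge_centers_dropped(self):
        track = _constant_track()
        centers = [GenomicInterval("chr1", 100, 101),      # too close to 0
                   GenomicInterval("chr1", 50_000, 50_001)]
        _, n_used, n_dropped = meta_profile(track, centers, 2000, 100)
        assert (n_used, n_dropped) == (1, 1)

    def test_all_centers_out_of_range(self):
        track = _constant_track()
        with pytest.raises(EmptyProfileError):
            meta_profile(track, [GenomicInterval("chr1", 10, 11)], 2000, 100)

    def test_gaussian_recovery_vs_direct_averaging(self, rng):
        # plant a Gaussian bump (amplitude A, sigma 200 bp) at 100 centers
        binsize, length, A, sigma = 50, 2_000_000, 5.0, 200.0
        n = length // binsize
        vals = np.zeros(n)
        centers_pos = rng.integers(10_000, length - 10_000, size=100)
        x = (np.arange(n) + 0.5) * binsize
        for c in centers_pos:
            vals += A * np.exp(-0.5 * ((x - c) / sigma) ** 2)
        track = SignalTrack(binsize=binsize, chrom_lengths={"chr1": length},
                            values={"chr1": vals})
        centers = [GenomicInterval("chr1", int(c), int(c) + 1)
                   for c in centers_pos]
        prof, _, _ = meta_profile(track, centers, 2000, 50)
        # independent oracle: average the track rows center by center
        oracle = np.zeros(80)
        offs = -2000 + np.arange(80) * 50 + 25
        for c in centers_pos:
            oracle += vals[(c + offs) // binsize]
        oracle /= len(centers_pos)
        np.testing.assert_allclose(prof, oracle, rtol=1e-12)
        # fitted amplitude = peak above the baseline contributed by the
        # other planted bumps (visible at the profile edges)
        baseline = np.r_[prof[:5], prof[-5:]].mean()
        assert abs((prof.max() - baseline) - A) / A < 0.05

    def test_linearity_and_shuffle_invariance(self, rng):
        length = 200_000
        n = length // 100
        v1, v2 = rng.random(n), rng.random(n)
        mk = lambda v: SignalTrack(binsize=100,  # noqa: E731
                                   chrom_lengths={"chr1": length},
                                   values={"chr1": v.copy()})
        centers = [GenomicInterval("chr1", int(p), int(p) + 1)
                   for p in rng.integers(5000, length - 5000, size=30)]
        p1, _, _ = meta_profile(mk(v1), centers, 2000, 100)
        p2, _, _ = meta_profile(mk(v2), centers, 2000, 100)
        psum, _, _ = meta_profile(mk(v1 + v2), centers, 2000, 100)
        np.testing.assert_allclose(psum, p1 + p2, rtol=1e-10)
        shuffled = list(centers)
        rng.shuffle(shuffled)
        ps, _, _ = meta_profile(mk(v1), shuffled, 2000, 100)
        np.testing.assert_allclose(ps, p1, rtol=1e-12)


class TestTracksAndGenes:
    def test_bedgraph_round_trip(self, tmp_path, rng):
        n = 50
        vals = rng.integers(0, 20, size=n).astype(float)
        track = SignalTrack(binsize=100, chrom_lengths={"chr1": 5000},
                            values={"chr1": vals})
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p, 100, {"chr1": 5000})
        np.testing.assert_allclose(back.values["chr1"], vals)

    def test_gene_table_round_trip(self, tmp_path):
        genes = [make_gene("G1", "chr1", "+", 100, 5000, {"bone_specific"}),
                 make_gene("G2", "chr1", "-", 8000, 12_000)]
        p = tmp_path / "genes.tsv"
        write_gene_table(genes, p)
        back = read_gene_table(p)
        assert [g.gene_id for g in back] == ["G1", "G2"]
        assert back[0].tags == frozenset({"bone_specific"})
        assert back[1].tss_pos == 11_999  # minus strand: TSS at body end

    def test_tss_strand_placement(self):
        plus = make_gene("A", "chr1", "+", 100, 600)
        minus = make_gene("B", "chr1", "-", 100, 600)
        assert plus.tss_pos == 100
        assert minus.tss_pos == 599
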