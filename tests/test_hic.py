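import numpy as np
import pandas as pd
import pytest

from mitodyn import synthetic
from mitodyn.core_io import GenomicInterval, PeakSet
from mitodyn.hic import (
    ContactMatrix,
    LoopSet,
    balance,
    bin_contacts,
    boundary_peak_profile,
    compartment_eigenvector,
    insulation,
    loop_apa,
    observed_expected,
    read_bedpe,
    read_coo,
    saddle,
    write_bedpe,
    write_coo,
)


class TestBinContacts:
    def test_single_pair(self):
        rec = pd.DataFrame({"pos1": [100], "pos2": [60_000]})
        cm = bin_contacts(rec, 25_000, "chr1", 100_000)
        assert cm.counts[0, 2] == 1 and cm.counts[2, 0] == 1
        assert cm.counts.sum() == 2

    def test_empty_input(self):
        rec = pd.DataFrame({"pos1": [], "pos2": []})
        cm = bin_contacts(rec, 25_000, "chr1", 100_000)
        assert cm.counts.sum() == 0

    def test_out_of_range_position_names_record(self):
        rec = pd.DataFrame({"pos1": [100, 100], "pos2": [200, 200_000]})
        with pytest.raises(ValueError, match="record 1"):
            bin_contacts(rec, 25_000, "chr1", 100_000)

    def test_matches_brute_force_histogram(self, rng):
        n_pairs, length, binsize = 10_000, 1_000_000, 25_000
        p1 = rng.integers(0, length, n_pairs)
        p2 = rng.integers(0, length, n_pairs)
        cm = bin_contacts(pd.DataFrame({"pos1": p1, "pos2": p2}),
                          binsize, "chr1", length)
        n = length // binsize
        want = np.zeros((n, n))
        for a, b in zip(p1 // binsize, p2 // binsize):
            lo, hi = min(a, b), max(a, b)
            want[lo, hi] += 1
        want = want + np.triu(want, 1).T
        np.testing.assert_array_equal(cm.counts, want)

    def test_pair_order_invariance(self, rng):
        p1 = rng.integers(0, 500_000, 1000)
        p2 = rng.integers(0, 500_000, 1000)
        df = pd.DataFrame({"pos1": p1, "pos2": p2})
        cm1 = bin_contacts(df, 25_000, "chr1", 500_000)
        perm = df.sample(frac=1, random_state=0).reset_index(drop=True)
        cm2 = bin_contacts(perm, 25_000, "chr1", 500_000)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_coo_round_trip(self, tmp_path, rng):
        p1 = rng.integers(0, 500_000, 2000)
        p2 = rng.integers(0, 500_000, 2000)
        cm = bin_contacts(pd.DataFrame({"pos1": p1, "pos2": p2}),
                          25_000, "chr1", 500_000)
        path = tmp_path / "m.coo.tsv"
        write_coo(cm, path)
        back = bin_contacts(read_coo(path), 25_000, "chr1", 500_000)
        np.testing.assert_array_equal(back.counts, cm.counts)


class TestBalance:
    def test_already_balanced_equal_weights(self):
        # symmetric doubly-stochastic-ish matrix: rows sum to 1
        m = np.array([[0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5],
                      [0.0, 0.5, 0.5]])
        cm = ContactMatrix("chr1", 1000, m)
        w = balance(cm)
        np.testing.assert_allclose(w, w[0], rtol=1e-6)

    def test_global_doubling_gives_inverse_sqrt2_weights(self):
        m = np.array([[0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5],
                      [0.0, 0.5, 0.5]])
        cm = ContactMatrix("chr1", 1000, 2 * m)
        w = balance(cm)
        np.testing.assert_allclose(w, 1 / np.sqrt(2), rtol=1e-6)

    def test_random_matrix_row_sums_equalized(self, rng):
        a = rng.random((40, 40)) + 0.1
        m = a + a.T
        cm = ContactMatrix("chr1", 1000, m)
        balance(cm)
        b = cm.balanced()
        good = ~cm.bad_bins
        sums = np.nansum(b[good][:, good], axis=1)
        assert np.std(sums) / np.mean(sums) < 1e-6

    def test_idempotence(self, rng):
        a = rng.random((30, 30)) + 0.1
        cm = ContactMatrix("chr1", 1000, a + a.T)
        balance(cm)
        b = cm.balanced()
        b = np.nan_to_num(b)
        cm2 = ContactMatrix("chr1", 1000, b)
        w2 = balance(cm2)
        good = ~cm2.bad_bins
        np.testing.assert_allclose(w2[good], w2[good][0], rtol=1e-4)


class TestObservedExpected:
    def test_diagonal_means_exactly_one(self, structured_hic):
        cm, oe, _ = structured_hic["chr1"]
        for d in (0, 1, 5, 50, 200):
            diag = np.diagonal(oe, offset=d)
            vals = diag[np.isfinite(diag)]
            assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)

    def test_structureless_map_is_flat(self, mitotic_hic):
        # mixing = 0: per-diagonal O/E mean within 3 sigma of 1
        cm, oe, _ = mitotic_hic["chr1"]
        n = cm.n_bins
        for d in (3, 10, 40):
            diag = np.diagonal(oe, offset=d)
            vals = diag[np.isfinite(diag)]
            sd = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - 1.0) <= max(3 * sd, 1e-9)

    def test_depth_invariance_of_oe(self, truth):
        from mitodyn.hic import balance as bal
        cm1 = synthetic.gen_contacts(truth, mixing=1.0)["chr1"]
        cm2 = synthetic.gen_contacts(truth, mixing=1.0,
                                     depth_scale=2.0)["chr1"]
        assert cm2.counts.sum() > 1.8 * cm1.counts.sum()
        for cm in (cm1, cm2):
            bal(cm)
        oe1, _ = observed_expected(cm1)
        oe2, _ = observed_expected(cm2)
        pairs = truth.loops.anchor_bins("chr1", truth.hic_binsize)
        v1 = np.array([oe1[a, b] for a, b in pairs])
        v2 = np.array([oe2[a, b] for a, b in pairs])
        # same planted structure read back at both depths
        assert np.nanmean(v1) == pytest.approx(np.nanmean(v2), rel=0.15)


class TestCompartments:
    def test_planted_signs_recovered(self, truth, structured_hic):
        for chrom, (cm, oe, _) in structured_hic.items():
            comp = compartment_eigenvector(
                oe, truth.compartment_sign[chrom].astype(float))
            good = np.isfinite(comp.eigenvector)
            agree = (np.sign(comp.eigenvector[good])
                     == truth.compartment_sign[chrom][good]).mean()
            assert agree >= 0.95

    def test_orientation_flip_flips_signs(self, truth, structured_hic):
        cm, oe, _ = structured_hic["chr1"]
        ori = truth.compartment_sign["chr1"].astype(float)
        a = compartment_eigenvector(oe, ori).eigenvector
        b = compartment_eigenvector(oe, -ori).eigenvector
        good = np.isfinite(a)
        np.testing.assert_allclose(a[good], -b[good])

    def test_constant_oe_flagged_no_compartments(self):
        oe = np.ones((60, 60))
        comp = compartment_eigenvector(oe, np.ones(60))
        assert comp.no_compartments
        np.testing.assert_allclose(comp.eigenvector, 0.0)


class TestSaddle:
    def test_uniform_oe_gives_unit_grid(self, rng):
        oe = np.ones((90, 90))
        profile = rng.normal(size=90)
        grid, corners = saddle(oe, profile, n_quantiles=30)
        np.testing.assert_allclose(grid, 1.0)
        assert corners["AA"] == pytest.approx(1.0)

    def test_grid_symmetric_and_corners_ordered(self, truth,
                                                structured_hic):
        cm, oe, _ = structured_hic["chr1"]
        comp = compartment_eigenvector(
            oe, truth.compartment_sign["chr1"].astype(float))
        grid, corners = saddle(oe, comp.eigenvector)
        np.testing.assert_allclose(grid, grid.T, equal_nan=True)
        assert corners["AA"] > 1.0 and corners["BB"] > 1.0
        assert corners["AB"] < 1.0

    def test_permuted_profile_destroys_enrichment(self, truth,
                                                  structured_hic, rng):
        cm, oe, _ = structured_hic["chr1"]
        comp = compartment_eigenvector(
            oe, truth.compartment_sign["chr1"].astype(float))
        prof = comp.eigenvector.copy()
        good = np.isfinite(prof)
        vals = prof[good]
        rng.shuffle(vals)
        prof[good] = vals
        _, corners = saddle(oe, prof)
        for key in ("AA", "BB", "AB"):
            assert corners[key] == pytest.approx(1.0, abs=0.1)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            saddle(np.ones((10, 10)), np.arange(10.0), n_quantiles=30)


class TestInsulation:
    def test_uniform_matrix_flat_no_boundaries(self):
        m = np.ones((120, 120))
        cm = ContactMatrix("chr1", 25_000, m)
        balance(cm)
        prof = insulation(cm, window_bins=10)
        finite = prof.scores[np.isfinite(prof.scores)]
        np.testing.assert_allclose(finite, 0.0, atol=1e-9)
        assert len(prof.boundaries) == 0

    def test_short_chromosome_rejected(self):
        cm = ContactMatrix("chr1", 25_000, np.ones((15, 15)))
        balance(cm)
        with pytest.raises(ValueError):
            insulation(cm, window_bins=10)

    def test_planted_boundaries_recovered(self, truth, structured_hic):
        for chrom, (cm, oe, _) in structured_hic.items():
            prof = insulation(cm)
            true_bins = truth.boundary_positions[chrom] // truth.hic_binsize
            hits = sum(np.abs(prof.boundaries - b).min() <= 1
                       for b in true_bins)
            recall = hits / len(true_bins)
            precision = sum(np.abs(true_bins - c).min() <= 1
                            for c in prof.boundaries) / len(prof.boundaries)
            assert recall >= 0.9 and precision >= 0.9

    def test_strength_increases_with_mixing(self, truth):
        means = []
        for mixing in (0.0, 0.5, 1.0):
            cm = synthetic.gen_contacts(truth, mixing=mixing)["chr1"]
            balance(cm)
            prof = insulation(cm)
            tb = truth.boundary_positions["chr1"] // truth.hic_binsize
            dips = [-prof.scores[b] for b in tb
                    if np.isfinite(prof.scores[b])]
            means.append(np.mean(dips))
        assert means[0] < means[1] < means[2]


class TestLoops:
    def test_bedpe_round_trip(self, tmp_path):
        loops = LoopSet([(GenomicInterval("chr1", 0, 25_000),
                          GenomicInterval("chr1", 500_000, 525_000))])
        p = tmp_path / "l.bedpe"
        write_bedpe(loops, p)
        back = read_bedpe(p)
        assert back.loops == loops.loops

    def test_trans_loops_rejected(self):
        with pytest.raises(ValueError, match="trans"):
            LoopSet([(GenomicInterval("chr1", 0, 100),
                      GenomicInterval("chr2", 500, 600))])

    def test_unit_oe_gives_unit_intensity(self):
        oe = np.ones((200, 200))
        loops = LoopSet([(GenomicInterval("chr1", 30 * 25_000,
                                          31 * 25_000),
                          GenomicInterval("chr1", 90 * 25_000,
                                          91 * 25_000))])
        _, intensity, ratio, n_used, n_dropped = loop_apa(
            oe, loops, "chr1", 25_000, window_bins=10)
        assert intensity == pytest.approx(1.0)
        assert n_used == 1 and n_dropped == 0

    def test_short_range_loops_dropped_and_counted(self):
        oe = np.ones((200, 200))
        loops = LoopSet([
            (GenomicInterval("chr1", 30 * 25_000, 31 * 25_000),
             GenomicInterval("chr1", 35 * 25_000, 36 * 25_000)),  # too close
            (GenomicInterval("chr1", 30 * 25_000, 31 * 25_000),
             GenomicInterval("chr1", 90 * 25_000, 91 * 25_000)),
        ])
        *_, n_used, n_dropped = loop_apa(oe, loops, "chr1", 25_000, 10)
        assert (n_used, n_dropped) == (1, 1)

    def test_planted_enrichment_recovered(self, truth, structured_hic):
        intensities = []
        for chrom, (cm, oe, _) in structured_hic.items():
            _, intensity, *_ = loop_apa(oe, truth.loops, chrom,
                                        truth.hic_binsize)
            intensities.append(intensity)
        e = truth.loop_enrichment
        for val in intensities:
            assert val == pytest.approx(e, rel=0.2)

    def test_displaced_anchors_are_null(self, truth, structured_hic):
        cm, oe, _ = structured_hic["chr1"]
        shifted = LoopSet([
            (GenomicInterval(a1.chrom, a1.start + 10 * truth.hic_binsize,
                             a1.end + 10 * truth.hic_binsize),
             GenomicInterval(a2.chrom, a2.start + 10 * truth.hic_binsize,
                             a2.end + 10 * truth.hic_binsize))
            for a1, a2 in truth.loops.loops if a1.chrom == "chr1"])
        _, intensity, *_ = loop_apa(oe, shifted, "chr1", truth.hic_binsize)
        assert intensity == pytest.approx(1.0, abs=0.35)


class TestBoundaryProfiles:
    def test_peaks_at_boundaries_peak_at_center(self, truth):
        rows = []
        for chrom, ps in truth.boundary_positions.items():
            for p in ps:
                rows.append((chrom, int(p) - 500, int(p) + 500))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"], df["signal"], df["strand"] = ".", np.nan, "."
        prof, n_used, _ = boundary_peak_profile(
            PeakSet(df), truth.boundary_positions, truth.genome,
            flank_bp=250_000, profile_binsize=25_000)
        center = len(prof) // 2
        assert prof[center] == prof.max()
        assert prof[center] > 5 * np.median(prof)

    def test_random_peaks_flat(self, truth, rng):
        rows = []
        for chrom, length in truth.genome.items():
            starts = rng.integers(0, length - 1000, size=2000)
            rows += [(chrom, int(s), int(s) + 1000) for s in starts]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"], df["signal"], df["strand"] = ".", np.nan, "."
        prof, *_ = boundary_peak_profile(
            PeakSet(df), truth.boundary_positions, truth.genome,
            flank_bp=250_000, profile_binsize=25_000)
        assert prof.max() - prof.min() < 6 * np.sqrt(prof.mean())

    def test_ana_telo_specific_k27ac_enriched_at_boundaries(self, truth):
        # the planted boundary-biased acetylation gains are visible as a
        # center enrichment of the ana/telo-specific category
        from mitodyn.spikein import phase_categories
        inter, _ = synthetic.gen_peaks(truth, "H3K27ac", "interphase")
        at, _ = synthetic.gen_peaks(truth, "H3K27ac", "ana_telo")
        cats = phase_categories(inter, at)
        spec = cats[cats["category"] == "ana_telo_specific"].copy()
        spec["name"], spec["signal"], spec["strand"] = ".", np.nan, "."
        prof, *_ = boundary_peak_profile(
            PeakSet(spec), truth.boundary_positions, truth.genome,
            flank_bp=250_000, profile_binsize=25_000)
        center = len(prof) // 2
        flank = np.r_[prof[:3], prof[-3:]].mean()
        assert prof[center - 1:center + 2].max() > 2 * flank
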