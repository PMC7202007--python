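"""Window statistics: Hp, Z-transform, Weir-Cockerham F_ST, the binomial
window LRT, BH correction, candidate calling and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sweeplab import sweepscan
from sweeplab.sweepscan import (benjamini_hochberg, call_candidates,
                                make_windows, pooled_heterozygosity,
                                wc_fst_components, wc_fst_window, window_lrt,
                                z_transform)

from conftest import make_gm


class TestMakeWindows:
    def test_overlapping_grid_arithmetic(self):
        w = make_windows({"c": 100_000}, 40_000, 20_000)
        assert w["start"].tolist() == [0, 20_000, 40_000, 60_000, 80_000]
        assert w["end"].tolist()[-1] == 100_000

    def test_short_contig_truncates(self):
        w = make_windows({"c": 30_000}, 40_000, 20_000)
        assert len(w) == 2 and w.loc[0, "end"] == 30_000

    def test_step_equal_size_tiles_disjointly(self):
        w = make_windows({"c": 120_000}, 40_000, 40_000)
        assert (w["end"] - w["start"]).tolist() == [40_000] * 3


class TestPooledHeterozygosity:
    def test_balanced_counts_reach_maximum(self):
        assert pooled_heterozygosity([5] * 12, [5] * 12) == 0.5

    def test_printed_arithmetic_example(self):
        # sums 90 and 10 -> 2*90*10/100^2
        assert pooled_heterozygosity([45, 45], [5, 5], min_snps=2) == \
            pytest.approx(0.18)

    def test_below_min_snps_is_absent_not_error(self):
        assert np.isnan(pooled_heterozygosity([5], [5]))

    def test_matches_per_snp_hand_count(self, random_gm):
        alt, m = random_gm.allele_counts("GA")
        n_min = np.minimum(alt, m - alt)[:10]
        n_maj = (m - np.minimum(alt, m - alt))[:10]
        hp = pooled_heterozygosity(n_maj, n_min)
        smaj, smin = n_maj.sum(), n_min.sum()
        assert hp == pytest.approx(2 * smaj * smin / (smaj + smin) ** 2)

    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)),
                    min_size=10, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_half(self, counts):
        maj = [max(a, b) for a, b in counts]
        mnr = [min(a, b) for a, b in counts]
        if sum(maj) + sum(mnr) == 0:
            return
        hp = pooled_heterozygosity(maj, mnr)
        assert 0.0 <= hp <= 0.5
        if hp == 0.5:
            assert sum(maj) == sum(mnr)


class TestZTransform:
    def test_unit_spaced_values(self):
        assert z_transform([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_output_standardized(self, rng):
        z = z_transform(rng.normal(5, 3, size=200))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_absences_propagate(self):
        z = z_transform([1.0, np.nan, 2.0, 3.0, np.nan])
        assert np.isnan(z).sum() == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_transform([1.0, np.nan])
        with pytest.raises(ValueError):
            z_transform([2.0, 2.0, 2.0])


def wc84_literal(n, p, h):
    """Independent literal transcription of the 1984 variance components."""
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    r = n.size
    nbar = n.sum() / r
    CV2_num = (n**2).sum() / (r * nbar)
    nc = (r * nbar - CV2_num) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar)
                                              - (r - 1) / r * s2
                                              - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        gt = np.repeat([[0, 0, 0, 0, 0, 2, 2, 2, 2, 2]], 3, axis=0)
        gm = make_gm(gt.astype(np.int8))
        theta = wc_fst_window(gm, ("chr1", 0, 1000), "GA", "GA-R")
        assert theta == pytest.approx(1.0)

    def test_identical_lines_give_non_positive_theta(self):
        gt = np.tile([0, 1, 2, 1, 0, 0, 1, 2, 1, 0], (5, 1)).astype(np.int8)
        gm = make_gm(gt)
        theta = wc_fst_window(gm, ("chr1", 0, 1000), "GA", "GA-R")
        assert theta <= 1e-12

    def test_matches_literal_wc84_transcription(self, random_gm):
        a, b, c, usable = sweepscan._wc_components_sites(random_gm, "GA",
                                                         "GA-R")
        g = random_gm.gt
        ga, gb = g[:, random_gm.line_indices("GA")], \
            g[:, random_gm.line_indices("GA-R")]
        for i in range(random_gm.n_sites):
            if not usable[i]:
                continue
            stats_ab = []
            for grp in (ga[i], gb[i]):
                called = grp[grp != -1]
                stats_ab.append((len(called),
                                 called.sum() / (2 * len(called)),
                                 np.mean(called == 1)))
            (na, pa, ha), (nb, pb, hb) = stats_ab
            ea, eb, ec = wc84_literal([na, nb], [pa, pb], [ha, hb])
            assert a[i] == pytest.approx(ea, abs=1e-12)
            assert b[i] == pytest.approx(eb, abs=1e-12)
            assert c[i] == pytest.approx(ec, abs=1e-12)

    def test_weighted_window_equals_per_snp_theta_for_single_snp(self):
        gt = np.array([[0, 1, 2, 0, 1, 2, 2, 2, 1, 2]], dtype=np.int8)
        gm = make_gm(gt)
        w = wc_fst_window(gm, ("chr1", 0, 1000), "GA", "GA-R", "weighted")
        m = wc_fst_window(gm, ("chr1", 0, 1000), "GA", "GA-R", "mean")
        a, b, c = wc_fst_components(*[np.array(x) for x in
                                      ([5, 5], [0.4, 0.9], [0.4, 0.2])])
        assert w == pytest.approx(m) == pytest.approx(a / (a + b + c))

    def test_empty_window_is_absent(self, random_gm):
        assert np.isnan(wc_fst_window(random_gm, ("chr1", 900_000, 901_000),
                                      "GA", "GA-R"))


class TestWindowLrt:
    def test_identical_counts_give_zero_statistic(self):
        gt = np.tile([0, 1, 2, 1, 0, 0, 1, 2, 1, 0], (4, 1)).astype(np.int8)
        gm = make_gm(gt)
        stat, df, p = window_lrt(gm, ("chr1", 0, 1000), "GA", "GA-R")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 4 and p == pytest.approx(1.0)

    def test_single_fixed_difference_closed_form(self):
        gt = np.array([[2, 2, 2, 2, 2, 0, 0, 0, 0, 0]], dtype=np.int8)
        gm = make_gm(gt)
        stat, df, p = window_lrt(gm, ("chr1", 0, 1000), "GA", "GA-R")
        expected = 2 * (0 - 20 * np.log(0.5))
        assert stat == pytest.approx(expected, abs=1e-9)
        assert stat == pytest.approx(27.7259, abs=1e-3)
        assert p == pytest.approx(sps.chi2.sf(expected, 1))

    def test_type_one_error_calibrated(self, rng):
        # no-difference simulation: windows of 10 SNPs, HWE, shared freqs;
        # 25 diploids per line so the chi-square asymptotics apply
        rejections = 0
        n_windows = 1000
        for _ in range(n_windows):
            p = rng.uniform(0.2, 0.8, size=10)
            hap = rng.random((10, 50, 2)) < p[:, None, None]
            gm = make_gm(hap.sum(axis=2))
            _, _, pval = window_lrt(gm, ("chr1", 0, 2000), "GA", "GA-R")
            rejections += pval < 0.05
        assert 0.03 <= rejections / n_windows <= 0.07


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0] * 3

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]).tolist() == [0.2]

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(size=25)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        manual = np.empty_like(p)
        m = len(p)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            manual[i] = prev
        assert np.allclose(q, manual)


class TestCandidates:
    def frame(self, zhp, zfst, contig="c1", step=20_000):
        n = len(zhp)
        return pd.DataFrame({
            "contig": [contig] * n,
            "start": np.arange(n) * step,
            "end": np.arange(n) * step + 2 * step,
            "zhp": zhp, "zfst": zfst,
        })

    def test_no_window_passes(self):
        win = self.frame([0.0, -1.0], [0.0, 0.5])
        assert call_candidates(win, None).empty

    def test_overlapping_flagged_windows_merge(self):
        win = self.frame([0, -7, -8, 0], [0, 2.0, 2.0, 0])
        out = call_candidates(win, None)
        assert len(out) == 1
        assert out.loc[0, "start"] == 20_000 and out.loc[0, "end"] == 80_000
        assert out.loc[0, "min_zhp"] == -8

    def test_distant_windows_stay_separate(self):
        zhp = [0, -7, 0, 0, 0, 0, -7, 0]
        zfst = [0, 2, 0, 0, 0, 0, 2, 0]
        out = call_candidates(self.frame(zhp, zfst), None)
        assert len(out) == 2

    def test_lrt_significance_required_when_supplied(self):
        win = self.frame([-7.0, 0.0], [2.0, 0.0])
        lrt = pd.DataFrame({"contig": ["c1"], "start": [0], "end": [5000],
                            "q_value": [0.5]})
        assert call_candidates(win, lrt).empty
        lrt["q_value"] = [0.001]
        assert len(call_candidates(win, lrt)) == 1


class TestAnnotation:
    def write_gff(self, path):
        path.write_text(
            "##gff-version 3\n"
            "c1\tx\tgene\t1001\t2000\t.\t+\t.\tID=geneA\n"
            "c1\tx\tgene\t9001\t9500\t.\t-\t.\tID=geneB\n"
            "c2\tx\tgene\t501\t700\t.\t+\t.\tID=geneC\n"
            "c1\tx\texon\t1001\t1200\t.\t+\t.\tID=exon1\n")

    def test_overlap_and_nearest(self, tmp_path):
        gff = tmp_path / "g.gff3"
        self.write_gff(gff)
        cands = pd.DataFrame({"contig": ["c1", "c1"],
                              "start": [1500, 3000],
                              "end": [2500, 6000]})
        out = sweepscan.annotate_candidates(cands, gff)
        assert out.loc[0, "genes"] == "geneA:0"
        # upstream geneA ends at 2000 -> distance 2000-3000 = -1000;
        # downstream geneB starts at 9000 -> +3000
        assert out.loc[1, "genes"] == "geneA:-1000;geneB:+3000"

    def test_contig_absent_from_annotation(self, tmp_path):
        gff = tmp_path / "g.gff3"
        self.write_gff(gff)
        cands = pd.DataFrame({"contig": ["c9"], "start": [0], "end": [100]})
        with pytest.warns(UserWarning):
            out = sweepscan.annotate_candidates(cands, gff)
        assert out.loc[0, "genes"] == "no annotation"

    def test_matches_brute_force_interval_scan(self, tmp_path, rng):
        gff = tmp_path / "g.gff3"
        genes = sorted(rng.integers(0, 50_000, size=(6, 1)).ravel())
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, g in enumerate(genes):
                fh.write(f"c1\tx\tgene\t{g + 1}\t{g + 2000}\t.\t+\t.\tID=g{i}\n")
        cands = pd.DataFrame({"contig": ["c1"] * 3,
                              "start": [0, 20_000, 40_000],
                              "end": [4_000, 24_000, 44_000]})
        out = sweepscan.annotate_candidates(cands, gff)
        for _, row in out.iterrows():
            overlaps = [f"g{i}" for i, g in enumerate(genes)
                        if g < row["end"] and g + 2000 > row["start"]]
            if overlaps:
                listed = [e.split(":")[0] for e in row["genes"].split(";")]
                assert sorted(listed) == sorted(overlaps)
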