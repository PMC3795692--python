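"""Marker QC, heterozygosity, ROH, LD, AMOVA, IBS/MDS, IBD and sex inference."""

import math

import numpy as np
import pandas as pd
import pytest

import rotbreed as rb
from rotbreed.genedrop import GeneticMap, GenotypeMatrix
from rotbreed.pedigree import Pedigree, UNKNOWN

from conftest import make_pedigree


def matrix_from_genotypes(genotypes, bp=None, chrom="chr1"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    bp = np.arange(1, m + 1) * 1_000_000 if bp is None else np.asarray(bp)
    markers = pd.DataFrame({"chrom": chrom, "bp": bp, "cM": bp / 2e6, "is_x": False})
    gmap = GeneticMap(markers=markers, chrom_lengths_bp={chrom: float(bp[-1] + 1)})
    return GenotypeMatrix(ids=[f"a{i}" for i in range(n)], genotypes=genotypes, gmap=gmap)


# ---------------------------------------------------------------------------
# HWE exact test against full enumeration
# ---------------------------------------------------------------------------


def hwe_exact_enumeration(n_het, n_hom1, n_hom2):
    """Levene/Haldane conditional distribution by direct factorial enumeration."""
    n = n_het + n_hom1 + n_hom2
    na = 2 * n_hom1 + n_het
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        a, b = (na - h) // 2, (2 * n - na - h) // 2
        probs[h] = 2.0 ** h / (math.factorial(a) * math.factorial(h) * math.factorial(b))
    tot = sum(probs.values())
    p_obs = probs[n_het] / tot
    return sum(v / tot for v in probs.values() if v / tot <= p_obs * (1 + 1e-12))


class TestMarkerQC:
    @pytest.mark.parametrize("table", [
        (5, 2, 3), (1, 9, 0), (10, 5, 5), (0, 10, 10), (7, 0, 0), (3, 14, 2),
    ])
    def test_hwe_matches_enumeration(self, table):
        assert rb.hwe_exact_pvalue(*table) == pytest.approx(
            hwe_exact_enumeration(*table), abs=1e-10)

    def test_duplicate_marker_flagged_once(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (30, 5)).astype(np.int8)
        g[:, 3] = g[:, 1]  # exact duplicate column
        report = rb.qc_marker_panel(matrix_from_genotypes(g))
        assert report.flags["duplicate"].sum() == 1
        assert report.flags.loc[3, "duplicate"]

    def test_missingness_threshold(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, (100, 3)).astype(np.int8) * 2  # all homozygous: HWE-safe? no
        g = rng.integers(0, 3, (100, 3)).astype(np.int8)
        g[:11, 0] = -1  # 11% missing at a 10% threshold
        report = rb.qc_marker_panel(matrix_from_genotypes(g))
        assert report.flags.loc[0, "missingness"]
        assert 0 not in report.panel1

    def test_stage_bookkeeping(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, (60, 40)).astype(np.int8)
        g[:, 5] = g[:, 2]
        g[:10, 7] = -1
        report = rb.qc_marker_panel(matrix_from_genotypes(g))
        c = report.stage_counts
        assert c["panel1"] == c["input"] - c["duplicate"] - c["missingness"] - c["hwe"]
        assert c["panel2"] == c["panel1"] - c["ld_pruned"] - c["maf"]
        flagged = report.flags.sum(axis=1)
        assert (flagged <= 1).all()  # no marker removed twice

    def test_ld_prune_removes_later_indexed(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, (80, 1)).astype(np.int8)
        noise = rng.integers(0, 3, (80, 4)).astype(np.int8)
        g = np.column_stack([base, noise[:, :2], base, noise[:, 2:]]).astype(np.int8)
        g[0, 3] = (g[0, 3] + 1) % 3  # near-duplicate, r^2 ~ 1 but not identical
        report = rb.qc_marker_panel(matrix_from_genotypes(g))
        assert report.flags.loc[3, "ld_pruned"] and not report.flags.loc[0, "ld_pruned"]

    def test_maf_filter(self):
        g = np.zeros((100, 2), dtype=np.int8)
        g[:2, 0] = 1          # MAF 1% -> removed
        g[:40, 1] = 1         # MAF 20% -> kept
        report = rb.qc_marker_panel(matrix_from_genotypes(g))
        assert report.flags.loc[0, "maf"] and not report.flags.loc[1, "maf"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rb.qc_marker_panel(matrix_from_genotypes(np.zeros((0, 3))))


class TestHeterozygosity:
    def test_all_heterozygous_is_one(self):
        G = matrix_from_genotypes(np.ones((2, 10)))
        assert (rb.observed_heterozygosity(G) == 1.0).all()

    def test_all_homozygous_is_zero(self):
        G = matrix_from_genotypes(np.full((2, 10), 2))
        assert (rb.observed_heterozygosity(G) == 0.0).all()

    def test_missing_excluded(self):
        g = np.array([[1, -1, 0, 1]])
        G = matrix_from_genotypes(g)
        assert rb.observed_heterozygosity(G).iloc[0] == pytest.approx(2 / 3)


class TestROH:
    def roh_matrix(self, genotypes, bp):
        return matrix_from_genotypes(np.asarray([genotypes]), bp=np.asarray(bp))

    def test_three_homozygous_markers_insufficient(self):
        G = self.roh_matrix([0, 0, 0, 1, 1], [1, 2, 3, 4, 5] * np.array(1e5))
        segs, frac = rb.detect_roh(G)
        assert len(segs) == 0 and frac.iloc[0] == 0.0

    def test_five_markers_dense_enough(self):
        """5 homozygous markers spanning 2.0 Mb = 1 per 400 kb -> one segment."""
        bp = [1_000_000, 1_500_000, 2_000_000, 2_500_000, 3_000_000]
        G = self.roh_matrix([2, 2, 0, 2, 2], bp)
        segs, frac = rb.detect_roh(G)
        assert len(segs) == 1
        assert segs.iloc[0]["length_bp"] == pytest.approx(2.0e6)
        assert segs.iloc[0]["n_markers"] == 5
        assert frac.iloc[0] == pytest.approx(2.0e6 / 2.75e9)

    def test_four_markers_too_sparse(self):
        """4 homozygous markers spanning 2.4 Mb = 1 per 600 kb -> rejected."""
        bp = [1_000_000, 1_800_000, 2_600_000, 3_400_000]
        G = self.roh_matrix([0, 0, 0, 0], bp)
        segs, _ = rb.detect_roh(G)
        assert len(segs) == 0

    def test_heterozygote_and_missing_break_runs(self):
        bp = list(range(1_000_000, 1_000_000 + 10 * 200_000, 200_000))
        geno = [2, 2, 2, 2, 1, 2, 2, -1, 2, 2]
        segs, _ = rb.detect_roh(self.roh_matrix(geno, bp))
        assert len(segs) == 1 and segs.iloc[0]["n_markers"] == 4

    def test_matches_hand_enumeration_on_random_panel(self):
        rng = np.random.default_rng(7)
        bp = np.sort(rng.choice(np.arange(1, 3_000), size=40, replace=False)) * 10_000
        geno = rng.choice([0, 1, 2], size=40, p=[0.4, 0.2, 0.4])
        segs, _ = rb.detect_roh(self.roh_matrix(geno, bp))
        # brute-force: enumerate all maximal homozygous runs directly
        expected = []
        i = 0
        hom = (geno == 0) | (geno == 2)
        while i < 40:
            if not hom[i]:
                i += 1
                continue
            j = i
            while j < 40 and hom[j]:
                j += 1
            span = bp[j - 1] - bp[i]
            if j - i >= 4 and span > 0 and (j - i) / span >= 1 / 500_000:
                expected.append((int(bp[i]), int(bp[j - 1]), j - i))
            i = j
        got = [(int(r["start_bp"]), int(r["end_bp"]), int(r["n_markers"]))
               for _, r in segs.iterrows()]
        assert got == expected


class TestLD:
    def test_duplicated_marker_r2_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 80)
        assert rb.ld_r2_em(col, col) == pytest.approx(1.0, abs=1e-6)

    def test_phased_hand_example(self):
        """AB=40, Ab=10, aB=10, ab=40: D = 0.15, p = q = 0.5, r^2 = 0.36."""
        h1 = np.array([1] * 50 + [0] * 50)
        h2 = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        assert rb.ld_r2_phased(h1, h2) == pytest.approx(0.36, abs=1e-12)

    def test_em_equals_phased_counting(self):
        """EM on genotypes from random haplotype pairing recovers phased r^2."""
        rng = np.random.default_rng(2)
        h1 = np.array([1] * 50 + [0] * 50)
        h2 = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        idx = rng.permutation(100)
        g1 = h1[idx[:50]] + h1[idx[50:]]
        g2 = h2[idx[:50]] + h2[idx[50:]]
        em = rb.ld_r2_em(g1, g2)
        direct = rb.ld_r2_phased(h1[idx], h2[idx])
        assert em == pytest.approx(direct, abs=0.02)

    def test_unambiguous_phased_data_exact(self):
        # no double heterozygotes -> EM has a closed solution equal to counting
        g1 = np.array([0, 0, 2, 2, 1, 1, 0, 2] * 5)
        g2 = np.array([0, 0, 2, 2, 0, 2, 0, 2] * 5)
        # no individual is heterozygous at both loci, so phase is determined
        hap1 = np.column_stack([(g1 > 0), (g1 == 2)]).astype(int).ravel()
        hap2 = np.column_stack([(g2 > 0), (g2 == 2)]).astype(int).ravel()
        assert rb.ld_r2_em(g1, g2) == pytest.approx(rb.ld_r2_phased(hap1, hap2), abs=1e-6)

    def test_decay_curve_on_drifted_colony(self):
        gmap = rb.make_genetic_map(n_markers=150, n_autosomes=1, include_x=False,
                                   chrom_lengths_bp={"chr1": 60e6}, seed=4)
        ped = rb.build_random_mating_pedigree(rb.BreederCounts.constant(13, 13, 16), 15, seed=5)
        pool = rb.simulate_founders(gmap, 26, seed=6)
        G = rb.drop_genotypes(ped, pool, seed=7)
        gens = ped.df.set_index("id")["generation"]
        sub = G.subset_animals(list(gens[gens == 15].index))
        curve, crossing = rb.ld_decay(sub, "chr1")
        v = curve["mean_r2"].dropna().to_numpy()
        smooth = np.convolve(v, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(smooth) <= 0.03)  # decays with distance after binning
        assert v[0] > v[-1]


class TestAMOVA:
    def test_fixed_difference_is_one(self):
        g = np.vstack([np.zeros((4, 20)), np.full((4, 20), 2)]).astype(np.int8)
        G = matrix_from_genotypes(g)
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=G.ids)
        assert rb.amova_two_groups(G, labels) == pytest.approx(1.0, abs=1e-9)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for s in range(12):
            g = rng.binomial(2, 0.4, size=(40, 60)).astype(np.int8)
            G = matrix_from_genotypes(g)
            labels = pd.Series(["A"] * 20 + ["B"] * 20, index=G.ids)
            vals.append(rb.amova_two_groups(G, labels))
        vals = np.asarray(vals)
        assert abs(vals.mean()) <= 3 * vals.std(ddof=1) / np.sqrt(len(vals)) + 0.01

    def test_matches_weir_cockerham_oracle(self):
        """Ratio-of-sums AMOVA equals an independently coded per-locus
        Weir-Cockerham theta combination on toy panels."""
        rng = np.random.default_rng(4)
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 15), size=(30, 15)).astype(np.int8)
        g[:15, :5] = np.minimum(g[:15, :5] + 1, 2)  # introduce differentiation
        G = matrix_from_genotypes(g)
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=G.ids)

        num = den = 0.0
        for j in range(15):
            n1 = n2 = 15
            p1 = g[:15, j].sum() / (2 * n1)
            p2 = g[15:, j].sum() / (2 * n2)
            ntot = 2 * n1 + 2 * n2
            pbar = (2 * n1 * p1 + 2 * n2 * p2) / ntot
            if pbar in (0.0, 1.0):
                continue
            msa = (2 * n1 * (p1 - pbar) ** 2 + 2 * n2 * (p2 - pbar) ** 2) / (2 - 1)
            msw = (2 * n1 * p1 * (1 - p1) + 2 * n2 * p2 * (1 - p2)) / (ntot - 2)
            nc = ntot - (4 * n1 ** 2 + 4 * n2 ** 2) / ntot
            num += (msa - msw) / nc
            den += (msa - msw) / nc + msw
        assert rb.amova_two_groups(G, labels) == pytest.approx(num / den, abs=1e-8)

    def test_monomorphic_panel_rejected(self):
        G = matrix_from_genotypes(np.zeros((6, 5)))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=G.ids)
        with pytest.raises(ValueError, match="monomorphic"):
            rb.amova_two_groups(G, labels)


class TestIBSMDS:
    def test_identical_animals(self):
        g = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (3, 1))
        G = matrix_from_genotypes(g)
        ibs = rb.ibs_matrix(G)
        assert np.allclose(ibs.to_numpy(), 1.0)

    def test_mds_reproduces_hand_distances(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [1.5, 1.5]])
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = rb.classical_mds(D, k=2)
        D2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_requires_three_animals(self):
        G = matrix_from_genotypes(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            rb.ibs_mds(G)


class TestIBD:
    def test_duplicate_samples_z2(self):
        rng = np.random.default_rng(5)
        row = rng.binomial(2, 0.5, 400).astype(np.int8)
        G = matrix_from_genotypes(np.vstack([row, row]))
        z = rb.ibd_z_proportions(G).iloc[0]
        assert z["Z2"] > 0.9

    def test_parent_offspring_z1(self):
        gmap = rb.make_genetic_map(n_markers=600, n_autosomes=20, include_x=False, seed=6)
        ped = make_pedigree([
            ("s", UNKNOWN, UNKNOWN, "M", 0),
            ("d", UNKNOWN, UNKNOWN, "F", 0),
            ("c", "s", "d", "F", 1),
        ])
        pool = rb.simulate_founders(gmap, 2, k_strains=8, seed=7)
        G = rb.drop_genotypes(ped, pool, seed=8)
        z = rb.ibd_z_proportions(G)
        po = z[(z["id1"] == "s") & (z["id2"] == "c")].iloc[0]
        assert po["Z1"] == pytest.approx(1.0, abs=0.08)

    def test_full_vs_half_sibs_cluster(self):
        """Full sibs near (Z0, Z1) = (0.25, 0.5); half sibs near (0.5, 0.5)."""
        gmap = rb.make_genetic_map(n_markers=1000, n_autosomes=20, include_x=False, seed=9)
        rows = [("s", UNKNOWN, UNKNOWN, "M", 0), ("d1", UNKNOWN, UNKNOWN, "F", 0),
                ("d2", UNKNOWN, UNKNOWN, "F", 0)]
        for k in range(4):
            rows.append((f"fs{k}", "s", "d1", "M", 1))
            rows.append((f"hs{k}", "s", "d2", "M", 1))
        ped = make_pedigree(rows)
        pool = rb.simulate_founders(gmap, 3, k_strains=8, seed=10)
        G = rb.drop_genotypes(ped, pool, seed=11)
        z = rb.ibd_z_proportions(G).set_index(["id1", "id2"])
        fs = z.loc[("fs0", "fs1")]
        hs = z.loc[("fs0", "hs0")]
        assert fs["Z0"] == pytest.approx(0.25, abs=0.15)
        assert fs["Z1"] == pytest.approx(0.5, abs=0.2)
        assert hs["Z0"] == pytest.approx(0.5, abs=0.15)
        assert hs["Z2"] < 0.1


class TestSexInference:
    def colony(self, seed=0):
        gmap = rb.make_genetic_map(n_markers=500, n_autosomes=6, include_x=True, seed=seed)
        ped = rb.build_random_mating_pedigree(rb.BreederCounts.constant(10, 10, 4), 3, seed=seed)
        pool = rb.simulate_founders(gmap, 20, seed=seed + 1)
        return ped, rb.drop_genotypes(ped, pool, seed=seed + 2)

    def test_matches_recorded_sex(self):
        ped, G = self.colony()
        inferred = rb.infer_sex_chrx(G)
        recorded = ped.df.set_index("id")["sex"]
        agree = (inferred["inferred_sex"] == recorded.reindex(inferred.index)).mean()
        assert agree == 1.0

    def test_males_zero_x_heterozygosity(self):
        ped, G = self.colony(seed=3)
        inferred = rb.infer_sex_chrx(G)
        males = ped.df[ped.df["sex"] == "M"]["id"]
        assert (inferred.loc[males, "x_heterozygosity"] == 0.0).all()

    def test_unimodal_all_ambiguous(self):
        # all-female panel: one tight cluster -> everything flagged
        g = np.ones((12, 40), dtype=np.int8)
        markers = pd.DataFrame({"chrom": "chrX", "bp": np.arange(1, 41) * 1e6,
                                "cM": np.arange(1, 41), "is_x": True})
        gmap = GeneticMap(markers=markers, chrom_lengths_bp={"chrX": 41e6})
        G = GenotypeMatrix(ids=[f"f{i}" for i in range(12)], genotypes=g, gmap=gmap)
        out = rb.infer_sex_chrx(G)
        assert (out["inferred_sex"] == "ambiguous").all()
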