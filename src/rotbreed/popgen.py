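"""SNP-panel statistics: QC, heterozygosity, ROH, LD, AMOVA, IBS/MDS, IBD, sex.

These are the genotype-panel analyses of a two-line selection colony,
re-implemented from first principles so they can run on the gene-drop
module's simulated panels: staged marker QC (duplicates -> missingness -> HWE
exact test -> LD pruning -> MAF), per-animal observed heterozygosity, runs of
homozygosity, LD decay (two-locus EM r^2), two-group AMOVA, IBS/classical
MDS, method-of-moments IBD sharing (Z0/Z1/Z2) and X-heterozygosity sex
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import GeneticMap, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "MarkerQCReport",
    "hwe_exact_pvalue",
    "qc_marker_panel",
    "observed_heterozygosity",
    "heterozygosity_summary",
    "ROHParams",
    "detect_roh",
    "ld_r2_em",
    "ld_r2_phased",
    "ld_decay",
    "amova_two_groups",
    "ibs_matrix",
    "classical_mds",
    "ibs_mds",
    "ibd_z_proportions",
    "infer_sex_chrx",
]


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact (conditional) Hardy-Weinberg test p-value, no mid-p correction.

    Enumerates the distribution of the heterozygote count conditional on the
    observed allele counts (Levene/Haldane distribution) via the standard
    stable recurrence, and sums the probabilities of all tables no more
    probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible heterozygote counts share the parity of the rare-allele count
    h_min = n_rare % 2
    h_max = min(n_rare, 2 * n - n_rare)
    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(len(hs))
    probs[0] = 1.0
    for k in range(1, len(hs)):
        h = hs[k]
        # P(h) / P(h-2) = (rare-h+2)(common-h+2) / (h (h-1))  for allele counts
        rare, common = n_rare, 2 * n - n_rare
        probs[k] = probs[k - 1] * ((rare - h + 2) * (common - h + 2)) / (h * (h - 1))
    probs /= probs.sum()
    p_obs = probs[(n_het - h_min) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass(frozen=True)
class QCThresholds:
    max_missing: float = 0.10
    hwe_alpha: float = 0.001
    ld_r2: float = 0.05
    ld_window: int = 10
    ld_step: int = 2
    min_maf: float = 0.05


@dataclass
class MarkerQCReport:
    """Staged QC bookkeeping.

    ``panel1`` survives duplicates + missingness + HWE; ``panel2``
    additionally survives windowed LD pruning and the MAF filter.  At every
    stage removed + surviving equals the stage input (no double counting).
    """

    flags: pd.DataFrame  # one row per input marker with boolean stage flags
    panel1: np.ndarray
    panel2: np.ndarray
    stage_counts: dict[str, int] = field(default_factory=dict)


def _pairwise_r2_genotypic(g: np.ndarray, i: int, j: int) -> float:
    """Composite (genotype-correlation) r^2 with pairwise-complete missingness."""
    a, b = g[:, i].astype(float), g[:, j].astype(float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def qc_marker_panel(G: GenotypeMatrix, thresholds: QCThresholds | None = None) -> MarkerQCReport:
    """Staged marker QC with the fixed, recorded filter order.

    Stage order: duplicates -> missingness(>max_missing) -> HWE exact test
    (p < hwe_alpha) = Panel-1 -> windowed LD prune (drop the later-indexed
    marker of any surviving pair with r^2 > ld_r2, windows of ``ld_window``
    markers sliding by ``ld_step``) -> MAF(< min_maf) = Panel-2.
    """
    t = thresholds or QCThresholds()
    g = G.genotypes
    if g.size == 0:
        raise ValueError("empty genotype matrix")
    n, m = g.shape
    flags = pd.DataFrame({
        "duplicate": False, "missingness": False, "hwe": False,
        "ld_pruned": False, "maf": False,
    }, index=range(m))

    seen: dict[bytes, int] = {}
    for j in range(m):
        key = g[:, j].tobytes()
        if key in seen:
            flags.loc[j, "duplicate"] = True
        else:
            seen[key] = j
    alive = ~flags["duplicate"].to_numpy()

    miss = np.mean(g == -1, axis=0)
    flags.loc[alive & (miss > t.max_missing), "missingness"] = True
    alive &= ~flags["missingness"].to_numpy()

    for j in np.flatnonzero(alive):
        col = g[:, j]
        col = col[col >= 0]
        p = hwe_exact_pvalue(int(np.sum(col == 1)), int(np.sum(col == 0)), int(np.sum(col == 2)))
        if p < t.hwe_alpha:
            flags.loc[j, "hwe"] = True
    alive &= ~flags["hwe"].to_numpy()
    panel1 = np.flatnonzero(alive)

    surviving = list(panel1)
    removed: set[int] = set()
    start = 0
    while start < len(surviving):
        window = [s for s in surviving[start:start + t.ld_window] if s not in removed]
        for a_ in range(len(window)):
            for b_ in range(a_ + 1, len(window)):
                i, j = window[a_], window[b_]
                if j in removed or i in removed:
                    continue
                if _pairwise_r2_genotypic(g, i, j) > t.ld_r2:
                    removed.add(j)  # later-indexed marker of the pair
        start += t.ld_step
    for j in removed:
        flags.loc[j, "ld_pruned"] = True
    alive = np.zeros(m, dtype=bool)
    alive[[s for s in surviving if s not in removed]] = True

    for j in np.flatnonzero(alive):
        col = g[:, j]
        col = col[col >= 0]
        if len(col) == 0:
            continue
        p = col.mean() / 2.0
        if min(p, 1 - p) < t.min_maf:
            flags.loc[j, "maf"] = True
    alive &= ~flags["maf"].to_numpy()
    panel2 = np.flatnonzero(alive)

    counts = {
        "input": m,
        "duplicate": int(flags["duplicate"].sum()),
        "missingness": int(flags["missingness"].sum()),
        "hwe": int(flags["hwe"].sum()),
        "panel1": len(panel1),
        "ld_pruned": int(flags["ld_pruned"].sum()),
        "maf": int(flags["maf"].sum()),
        "panel2": len(panel2),
    }
    return MarkerQCReport(flags=flags, panel1=panel1, panel2=panel2, stage_counts=counts)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


def observed_heterozygosity(G: GenotypeMatrix, marker_subset=None) -> pd.Series:
    """Per-animal fraction of non-missing genotypes that are heterozygous.

    Animals with no non-missing genotype are excluded (reported by absence).
    """
    g = G.genotypes if marker_subset is None else G.genotypes[:, marker_subset]
    ok = g >= 0
    n_ok = ok.sum(axis=1)
    het = (g == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_ok > 0, het / np.maximum(n_ok, 1), np.nan)
    s = pd.Series(h, index=G.ids, name="H0")
    return s.dropna()


def heterozygosity_summary(h0: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Group mean/SD of per-animal heterozygosity (group labels by animal id)."""
    df = pd.DataFrame({"H0": h0, "group": groups.reindex(h0.index)})
    out = df.groupby("group")["H0"].agg(n="count", mean="mean", sd="std").reset_index()
    return out


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROHParams:
    min_markers: int = 4
    min_density_bp: float = 500_000.0  # >= 1 marker per this many bp
    genome_size_bp: float = 2.75e9


def detect_roh(
    G: GenotypeMatrix,
    params: ROHParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Maximal runs of consecutive homozygous markers meeting both thresholds.

    A run is broken by any heterozygous or missing call (strict reading of
    "homozygous markers"; relax by pre-masking if desired).  A maximal run is
    reported iff it has >= ``min_markers`` markers and density of at least one
    marker per ``min_density_bp``; its length is the bp span from first to
    last marker (1-based inclusive, length = end - start).

    Returns (segments, genome_fraction_per_animal); segments have columns
    animal, chrom, start_bp, end_bp, n_markers, length_bp.
    """
    p = params or ROHParams()
    gmap = G.gmap
    bp = gmap.markers["bp"].to_numpy()
    segments = []
    fractions = {}
    for ai, aid in enumerate(G.ids):
        row = G.genotypes[ai]
        total = 0.0
        for chrom, sl, _ in gmap.chrom_slices():
            hom = (row[sl] == 0) | (row[sl] == 2)
            pos = bp[sl]
            start = None
            for k in range(len(hom) + 1):
                if k < len(hom) and hom[k]:
                    if start is None:
                        start = k
                    continue
                if start is not None:
                    n_run = k - start
                    span = float(pos[k - 1] - pos[start])
                    if n_run >= p.min_markers and span > 0 and n_run / span >= 1.0 / p.min_density_bp:
                        segments.append(dict(
                            animal=aid, chrom=chrom,
                            start_bp=int(pos[start]), end_bp=int(pos[k - 1]),
                            n_markers=n_run, length_bp=span,
                        ))
                        total += span
                    start = None
        fractions[aid] = total / p.genome_size_bp
    seg_df = pd.DataFrame(
        segments,
        columns=["animal", "chrom", "start_bp", "end_bp", "n_markers", "length_bp"],
    )
    return seg_df, pd.Series(fractions, name="roh_fraction")


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2_phased(h1: np.ndarray, h2: np.ndarray) -> float:
    """r^2 by direct haplotype counting from phased alleles at two loci."""
    p_ab = np.mean((h1 == 1) & (h2 == 1))
    p_a = np.mean(h1 == 1)
    p_b = np.mean(h2 == 1)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return np.nan
    d = p_ab - p_a * p_b
    return float(d * d / denom)


def ld_r2_em(g1: np.ndarray, g2: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> float:
    """r^2 from EM-estimated two-locus haplotype frequencies (unphased input).

    Only the double-heterozygote class is phase-ambiguous; the EM iterates its
    expected split between AB/ab and Ab/aB coupling.
    """
    ok = (g1 >= 0) & (g2 >= 0)
    a, b = g1[ok], g2[ok]
    n = len(a)
    if n == 0:
        return np.nan
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return np.nan
    # haplotype counts that are unambiguous from single/double homozygotes
    base = np.zeros(4)  # AB, Ab, aB, ab   (A = allele "1" at locus 1, etc.)
    #  genotype g counts copies of allele 1
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    dh = counts[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        frac = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = base + dh * np.array([frac, 1 - frac, 1 - frac, frac])
        new /= new.sum()
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    p_a_h, p_b_h = f[0] + f[1], f[0] + f[2]
    denom = p_a_h * (1 - p_a_h) * p_b_h * (1 - p_b_h)
    if denom <= 0:
        return np.nan
    d = f[0] - p_a_h * p_b_h
    return float(d * d / denom)


def ld_decay(
    G: GenotypeMatrix,
    chrom: str,
    max_dist_bp: float = 5e6,
    bin_bp: float = 5e5,
    r2_threshold: float = 0.3,
    use_phased: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Binned mean r^2 vs inter-marker distance and the threshold crossing.

    All marker pairs on ``chrom`` within ``max_dist_bp`` contribute; r^2 comes
    from two-locus EM haplotype frequencies (or direct counting when
    ``use_phased`` and phased haplotypes are stored).  The distance at which
    the binned curve crosses ``r2_threshold`` is linearly interpolated between
    bin centers (NaN if never crossed).  Monomorphic pairs are skipped.
    """
    m = G.gmap.markers
    idx = np.flatnonzero((m["chrom"] == chrom).to_numpy())
    if len(idx) < 2:
        raise ValueError(f"need >= 2 markers on {chrom}")
    bp = m["bp"].to_numpy()[idx]
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    cnts = np.zeros(n_bins, dtype=int)
    for a_ in range(len(idx)):
        for b_ in range(a_ + 1, len(idx)):
            dist = bp[b_] - bp[a_]
            if dist > max_dist_bp:
                break
            if use_phased and G.haplotypes is not None:
                h = G.haplotypes
                r2 = ld_r2_phased(h[:, :, idx[a_]].ravel(), h[:, :, idx[b_]].ravel())
            else:
                r2 = ld_r2_em(G.genotypes[:, idx[a_]], G.genotypes[:, idx[b_]])
            if np.isnan(r2):
                continue
            k = min(int(dist // bin_bp), n_bins - 1)
            sums[k] += r2
            cnts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_bp
    curve = pd.DataFrame({"dist_bp": centers, "mean_r2": means, "n_pairs": cnts})
    crossing = np.nan
    valid = curve.dropna(subset=["mean_r2"])
    v = valid["mean_r2"].to_numpy()
    c = valid["dist_bp"].to_numpy()
    for k in range(1, len(v)):
        if v[k - 1] >= r2_threshold > v[k]:
            # linear interpolation between bin centers
            frac = (v[k - 1] - r2_threshold) / (v[k - 1] - v[k])
            crossing = float(c[k - 1] + frac * (c[k] - c[k - 1]))
            break
    return curve, crossing


# ---------------------------------------------------------------------------
# AMOVA (two groups)
# ---------------------------------------------------------------------------


def amova_two_groups(G: GenotypeMatrix, labels: pd.Series | dict) -> float:
    """Among-group proportion of molecular variance over all polymorphic loci.

    Per locus, a one-way ANOVA on allele indicators (2 alleles per non-missing
    genotype) partitions sums of squares among/within the two groups;
    variance components are combined across loci as the ratio of summed
    among-components to summed totals (a weighted average over loci,
    equivalent to a Weir-Cockerham-style FST without the within-individual
    tier).  The value is clipped to [0, 1].
    """
    labels = pd.Series(labels).reindex(G.ids)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    masks = [np.array([labels[a] == grp for a in G.ids]) for grp in groups]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs >= 2 animals")
    g = G.genotypes
    sig_a_sum = 0.0
    sig_tot_sum = 0.0
    any_poly = False
    for j in range(g.shape[1]):
        ns, ps = [], []
        for mask in masks:
            col = g[mask, j]
            col = col[col >= 0]
            if len(col) == 0:
                break
            ns.append(2 * len(col))
            ps.append(col.sum() / (2.0 * len(col)))
        if len(ns) != 2:
            continue
        n_tot = ns[0] + ns[1]
        p_bar = (ns[0] * ps[0] + ns[1] * ps[1]) / n_tot
        if p_bar in (0.0, 1.0):
            continue
        any_poly = True
        ss_among = sum(nk * (pk - p_bar) ** 2 for nk, pk in zip(ns, ps))
        ss_within = sum(nk * pk * (1 - pk) for nk, pk in zip(ns, ps))
        msa = ss_among / 1.0
        msw = ss_within / (n_tot - 2)
        n_c = n_tot - (ns[0] ** 2 + ns[1] ** 2) / n_tot
        sig_a = (msa - msw) / n_c
        sig_a_sum += sig_a
        sig_tot_sum += sig_a + msw
    if not any_poly:
        raise ValueError("panel monomorphic overall; AMOVA undefined")
    return float(np.clip(sig_a_sum / sig_tot_sum, 0.0, 1.0))


# ---------------------------------------------------------------------------
# IBS / MDS
# ---------------------------------------------------------------------------


def ibs_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state: mean over shared non-missing markers of
    (2 - |g_i - g_j|) / 2."""
    g = G.genotypes.astype(np.int16)
    n = g.shape[0]
    out = np.ones((n, n))
    ok = g >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                continue
            s = np.mean((2 - np.abs(g[i, both] - g[j, both])) / 2.0)
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=G.ids, columns=G.ids)


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson scaling of a distance matrix: centered double-centering +
    eigendecomposition; returns n x k' coordinates (k' <= k if fewer positive
    eigenvalues exist, with a warning via fewer columns)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    k_eff = min(k, int(pos.sum()))
    coords = v[:, :k_eff] * np.sqrt(w[:k_eff])
    return coords - coords.mean(axis=0)


def ibs_mds(G: GenotypeMatrix, k: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IBS matrix and classical-MDS coordinates of distance 1 - IBS."""
    if G.n_animals < 3:
        raise ValueError("MDS needs >= 3 animals")
    ibs = ibs_matrix(G)
    coords = classical_mds(1.0 - ibs.to_numpy(), k=k)
    cols = [f"dim{i + 1}" for i in range(coords.shape[1])]
    return ibs, pd.DataFrame(coords, index=G.ids, columns=cols)


# ---------------------------------------------------------------------------
# IBD sharing (method of moments)
# ---------------------------------------------------------------------------


def ibd_z_proportions(G: GenotypeMatrix, allele_freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-pair (Z0, Z1, Z2) probabilities of sharing 0/1/2 alleles IBD.

    Method-of-moments from observed IBS-state counts and per-marker allele
    frequencies (estimated from the sample when not supplied), projected onto
    the probability simplex.  Monomorphic markers carry no information and
    are excluded.  With fewer than ~50 informative markers the estimates are
    noisy (a warning is encoded in the ``n_markers`` column; no exception).
    """
    p = G.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs, float)
    q = 1.0 - p
    informative = (p > 0) & (p < 1) & ~np.isnan(p)
    g = G.genotypes[:, informative]
    p, q = p[informative], q[informative]

    # expected per-locus IBS-state probabilities given IBD state
    e_ibs0_z0 = 2 * p**2 * q**2
    e_ibs1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_z0 = p**4 + q**4 + 4 * p**2 * q**2
    e_ibs1_z1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_z1 = p**3 + q**3 + p**2 * q + p * q**2

    rows = []
    n = g.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            ok = (g[i] >= 0) & (g[j] >= 0)
            if ok.sum() == 0:
                continue
            diff = np.abs(g[i, ok] - g[j, ok])
            c0, c1, c2 = np.sum(diff == 2), np.sum(diff == 1), np.sum(diff == 0)
            s0, s1z0, s2z0 = e_ibs0_z0[ok].sum(), e_ibs1_z0[ok].sum(), e_ibs2_z0[ok].sum()
            s1z1, s2z1 = e_ibs1_z1[ok].sum(), e_ibs2_z1[ok].sum()
            m = int(ok.sum())
            z0 = c0 / s0 if s0 > 0 else 0.0
            z1 = (c1 - z0 * s1z0) / s1z1 if s1z1 > 0 else 0.0
            z2 = (c2 - z0 * s2z0 - z1 * s2z1) / m
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            total = z.sum()
            z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
            rows.append(dict(id1=G.ids[i], id2=G.ids[j],
                             Z0=z[0], Z1=z[1], Z2=z[2], n_markers=m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ChrX sex inference
# ---------------------------------------------------------------------------


def infer_sex_chrx(
    G: GenotypeMatrix,
    x_marker_idx: np.ndarray | None = None,
    min_markers: int = 10,
    ambiguity_band: float = 0.05,
) -> pd.DataFrame:
    """Two-cluster split of X-chromosome heterozygosity.

    Hemizygous males show (near-)zero X heterozygosity, females inherit two X
    copies and show the panel-level heterozygosity.  The threshold sits midway
    across the largest gap in the sorted values (the boundary between the two
    clusters; a midpoint of cluster means would drift toward the larger
    cluster and misclassify low-heterozygosity females).  Animals within
    ``ambiguity_band``/2 of the threshold — or all animals when the
    distribution is unimodal (largest gap below the band) — are flagged
    ambiguous.
    """
    if x_marker_idx is None:
        x_marker_idx = G.gmap.x_marker_indices()
    if len(x_marker_idx) < min_markers:
        raise ValueError(f"need >= {min_markers} X markers, have {len(x_marker_idx)}")
    h = observed_heterozygosity(G, marker_subset=x_marker_idx)
    vals = h.to_numpy()
    order = np.argsort(vals)
    gaps = np.diff(vals[order])
    out = pd.DataFrame({"x_heterozygosity": h, "inferred_sex": "ambiguous"})
    if len(vals) < 2 or gaps.max(initial=0.0) < ambiguity_band:
        return out  # unimodal: all flagged ambiguous
    split = int(np.argmax(gaps))
    threshold = (vals[order][split] + vals[order][split + 1]) / 2.0
    sex = np.where(vals < threshold, "M", "F")
    sex[np.abs(vals - threshold) < ambiguity_band / 2.0] = "ambiguous"
    out["inferred_sex"] = sex
    return out
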