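"""Synthetic genotype engine: maps, mosaic founders, Mendelian gene dropping.

No genotype archive exists for the selection colony, so every genotype-level
analysis in this package runs on simulated data whose structure emulates the
real panel: founders are mosaics of K (default 8) inbred ancestral strains —
the heterogeneous-stock history of the colony's base population — and
genotypes are propagated through an arbitrary pedigree by Mendelian gene
dropping with Haldane (no-interference) recombination on a bp + cM map.

Genotypes are coded 0/1/2 copies of the reference allele, -1 for missing.
X-chromosome transmission is sex-aware: males are hemizygous (stored as a
duplicated maternal haplotype, so their coded X genotypes are homozygous) and
transmit their single X to daughters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GeneticMap",
    "FounderPool",
    "GenotypeMatrix",
    "make_genetic_map",
    "simulate_founders",
    "expected_founder_heterozygosity",
    "drop_genotypes",
]

#: Default genome geometry: total physical size (bp) and bp-per-cM scaling
#: emulating a 2.75 Gb rat-like genome at ~1 cM per 2 Mb.
DEFAULT_GENOME_BP = 2.75e9
DEFAULT_BP_PER_CM = 2.0e6


@dataclass
class GeneticMap:
    """Marker map: per-marker chromosome, bp and cM position, X flag."""

    markers: pd.DataFrame  # columns: chrom, bp, cM, is_x
    chrom_lengths_bp: dict[str, float]

    def __post_init__(self):
        m = self.markers
        for chrom, grp in m.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            cm = grp["cM"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease with bp on {chrom}")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def total_bp(self) -> float:
        return float(sum(self.chrom_lengths_bp.values()))

    def chrom_slices(self) -> list[tuple[str, slice, bool]]:
        """(chrom, marker slice, is_x) in map order; markers are chrom-contiguous."""
        out = []
        chrom = self.markers["chrom"].to_numpy()
        is_x = self.markers["is_x"].to_numpy()
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out.append((chrom[start], slice(start, i), bool(is_x[start])))
                start = i
        return out

    def x_marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.markers["is_x"].to_numpy())

    def autosomal_marker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.markers["is_x"].to_numpy())

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


def _default_chrom_lengths(n_autosomes: int, total_bp: float, x_fraction: float = 0.06):
    """Autosome lengths tapering linearly plus an X chromosome."""
    x_len = total_bp * x_fraction
    weights = np.linspace(2.0, 0.75, n_autosomes)
    weights = weights / weights.sum() * (total_bp - x_len)
    lengths = {f"chr{i + 1}": float(w) for i, w in enumerate(weights)}
    lengths["chrX"] = float(x_len)
    return lengths


def make_genetic_map(
    n_markers: int = 2000,
    n_autosomes: int = 20,
    total_bp: float = DEFAULT_GENOME_BP,
    bp_per_cm: float = DEFAULT_BP_PER_CM,
    spacing: str = "uniform",
    include_x: bool = True,
    chrom_lengths_bp: dict[str, float] | None = None,
    seed: int | None = None,
) -> GeneticMap:
    """Reproducible marker map over a multi-chromosome genome.

    Markers are apportioned to chromosomes proportionally to physical length
    (>= 2 per chromosome) and placed uniformly (``spacing="uniform"``) or
    uniformly at random (``"random"``); cM = bp / ``bp_per_cm``.
    """
    if chrom_lengths_bp is None:
        if include_x:
            chrom_lengths_bp = _default_chrom_lengths(n_autosomes, total_bp)
        else:
            chrom_lengths_bp = {
                k: v for k, v in _default_chrom_lengths(n_autosomes, total_bp).items()
                if k != "chrX"
            }
    if any(v <= 0 for v in chrom_lengths_bp.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths_bp.values())
    chroms = list(chrom_lengths_bp)
    alloc = {c: max(2, int(round(n_markers * chrom_lengths_bp[c] / total))) for c in chroms}
    rows = []
    for chrom in chroms:
        length = chrom_lengths_bp[chrom]
        k = alloc[chrom]
        if spacing == "uniform":
            bp = np.linspace(1, length, k)
        elif spacing == "random":
            bp = np.sort(rng.uniform(1, length, size=k))
            while len(np.unique(np.round(bp))) < k:  # extremely unlikely
                bp = np.sort(rng.uniform(1, length, size=k))
        else:
            raise ValueError("spacing must be 'uniform' or 'random'")
        bp = np.round(bp).astype(np.int64)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "bp": bp,
            "cM": bp / bp_per_cm,
            "is_x": chrom == "chrX",
        }))
    markers = pd.concat(rows, ignore_index=True)
    return GeneticMap(markers=markers, chrom_lengths_bp=dict(chrom_lengths_bp))


@dataclass
class FounderPool:
    """Founder haplotypes as ancestral-strain mosaics.

    ``strain_alleles``: (K, M) 0/1 allele carried by each strain at each
    marker.  ``haplotypes``: (n_founders, 2, M) founder alleles;
    ``strain_of``: matching strain labels per haplotype segment.
    """

    strain_alleles: np.ndarray
    haplotypes: np.ndarray
    strain_of: np.ndarray
    gmap: GeneticMap
    strain_weights: np.ndarray = field(default=None)

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def k_strains(self) -> int:
        return self.strain_alleles.shape[0]


def _mosaic_labels(gmap: GeneticMap, k: int, switch_rate: float, rng, weights) -> np.ndarray:
    """One haplotype's strain label per marker: Markov switches along the cM map."""
    m = gmap.n_markers
    labels = np.empty(m, dtype=np.int32)
    cm = gmap.markers["cM"].to_numpy()
    for _, sl, _ in gmap.chrom_slices():
        c = cm[sl]
        lab = rng.choice(k, p=weights)
        seg = np.empty(len(c), dtype=np.int32)
        seg[0] = lab
        d = np.diff(c)
        switch = rng.random(len(d)) < 1.0 - np.exp(-switch_rate * d)
        for i, sw in enumerate(switch):
            if sw:
                lab = rng.choice(k, p=weights)
            seg[i + 1] = lab
        labels[sl] = seg
    return labels


def simulate_founders(
    gmap: GeneticMap,
    n_founders: int,
    k_strains: int = 8,
    switch_rate_per_cm: float = 0.3,
    allele_freq_range: tuple[float, float] = (0.1, 0.9),
    strain_weights: np.ndarray | None = None,
    seed: int | None = None,
) -> FounderPool:
    """Founders whose haplotypes are mosaics of ``k_strains`` inbred strains.

    Each strain carries a fixed 0/1 allele per marker, drawn Bernoulli with a
    per-marker frequency uniform in ``allele_freq_range``; each founder
    haplotype switches strain ancestry along the map as a Poisson process with
    ``switch_rate_per_cm`` expected switches per cM (the default emulates the
    block structure left by a few tens of generations of stock mixing).

    The expected heterozygosity at a marker is 2 f (1 - f) with f the
    strain-weighted frequency of allele 1 (see
    :func:`expected_founder_heterozygosity`).
    """
    if k_strains < 1:
        raise ValueError("k_strains must be >= 1")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    weights = (np.full(k_strains, 1.0 / k_strains) if strain_weights is None
               else np.asarray(strain_weights, dtype=float) / np.sum(strain_weights))
    lo, hi = allele_freq_range
    p_marker = rng.uniform(lo, hi, size=m)
    strain_alleles = (rng.random((k_strains, m)) < p_marker).astype(np.int8)
    strain_of = np.empty((n_founders, 2, m), dtype=np.int32)
    haplotypes = np.empty((n_founders, 2, m), dtype=np.int8)
    for i in range(n_founders):
        for h in (0, 1):
            lab = _mosaic_labels(gmap, k_strains, switch_rate_per_cm, rng, weights)
            strain_of[i, h] = lab
            haplotypes[i, h] = strain_alleles[lab, np.arange(m)]
    return FounderPool(strain_alleles=strain_alleles, haplotypes=haplotypes,
                       strain_of=strain_of, gmap=gmap, strain_weights=weights)


def expected_founder_heterozygosity(pool: FounderPool) -> float:
    """Closed-form mean founder heterozygosity: mean over markers of 2 f (1-f)."""
    f = pool.strain_weights @ pool.strain_alleles
    return float(np.mean(2.0 * f * (1.0 - f)))


@dataclass
class GenotypeMatrix:
    """Animals x markers dosage matrix with optional phased haplotypes.

    ``genotypes`` holds 0/1/2 reference-allele counts, -1 for missing.
    """

    ids: list[str]
    genotypes: np.ndarray  # (n, M) int8, -1 = missing
    gmap: GeneticMap
    haplotypes: np.ndarray | None = None  # (n, 2, M) int8
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.ids)}
        g = self.genotypes
        if not np.all((g >= -1) & (g <= 2)):
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def row(self, animal_id: str) -> np.ndarray:
        return self.genotypes[self._index[animal_id]]

    def subset_animals(self, ids) -> "GenotypeMatrix":
        idx = [self._index[a] for a in ids]
        return GenotypeMatrix(
            ids=list(ids),
            genotypes=self.genotypes[idx],
            gmap=self.gmap,
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )

    def subset_markers(self, marker_idx) -> "GenotypeMatrix":
        marker_idx = np.asarray(marker_idx)
        sub_map = GeneticMap(
            markers=self.gmap.markers.iloc[marker_idx].reset_index(drop=True),
            chrom_lengths_bp=self.gmap.chrom_lengths_bp,
        )
        return GenotypeMatrix(
            ids=list(self.ids),
            genotypes=self.genotypes[:, marker_idx],
            gmap=sub_map,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, marker_idx],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per marker over non-missing genotypes."""
        g = self.genotypes.astype(float)
        g[self.genotypes < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    # -- text export (PLINK-style .ped/.map column contract) ---------------
    def write_plink_text(self, prefix, sexes: dict[str, str] | None = None) -> None:
        """Write ``<prefix>.ped`` / ``<prefix>.map`` whitespace-text files.

        .map columns: chrom, marker name, cM, bp.  .ped columns: family id
        (always 0), animal id, sire/dam (0), sex code, phenotype (0), then two
        allele columns per marker (A/B alleles, 0 = missing).
        """
        m = self.gmap.markers
        with open(f"{prefix}.map", "w") as fh:
            for i, row in m.iterrows():
                fh.write(f"{row['chrom']}\tm{i}\t{row['cM']:.6f}\t{int(row['bp'])}\n")
        code = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
        with open(f"{prefix}.ped", "w") as fh:
            for i, aid in enumerate(self.ids):
                sex = {"M": "1", "F": "2"}.get((sexes or {}).get(aid, ""), "0")
                geno = " ".join(code[int(g)] for g in self.genotypes[i])
                fh.write(f"0 {aid} 0 0 {sex} 0 {geno}\n")


def _gamete(hap: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """Recombinant gamete from a (2, M) parental haplotype pair.

    Crossover counts per chromosome are Poisson in map length (Haldane, no
    interference), positions uniform in cM; the starting phase is fair.
    X-flagged chromosomes are handled by the caller.
    """
    m = hap.shape[1]
    out = np.empty(m, dtype=np.int8)
    cm = gmap.markers["cM"].to_numpy()
    for _, sl, _ in gmap.chrom_slices():
        c = cm[sl]
        length = c[-1] - c[0]
        k = rng.poisson(length / 100.0)
        phase = int(rng.integers(2))
        if k == 0:
            out[sl] = hap[phase, sl]
            continue
        cuts = np.sort(rng.uniform(c[0], c[-1], size=k))
        which = (phase + np.searchsorted(cuts, c, side="right")) % 2
        seg = np.where(which == 0, hap[0, sl], hap[1, sl])
        out[sl] = seg
    return out


def drop_genotypes(
    ped: Pedigree,
    founders: FounderPool,
    gmap: GeneticMap | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    keep_haplotypes: bool = True,
) -> GenotypeMatrix:
    """Mendelian gene drop of founder haplotypes through a pedigree.

    Pedigree founders are matched to pool founders in row order and must be
    equinumerous.  Each transmitted gamete is produced by :func:`_gamete`;
    on the X chromosome males carry a duplicated maternal haplotype and
    transmit it (unrecombined) to daughters only.  ``missing_rate`` masks
    genotype calls uniformly at random (-1) to exercise QC code.
    Deterministic for a given seed and pedigree.
    """
    gmap = gmap or founders.gmap
    rng = np.random.default_rng(seed)
    n, m = len(ped), gmap.n_markers
    ped_founders = np.flatnonzero(ped.founder_mask)
    if len(ped_founders) != founders.n_founders:
        raise ValueError(
            f"pedigree has {len(ped_founders)} founders but the pool holds "
            f"{founders.n_founders}"
        )
    x_idx = gmap.x_marker_indices()
    sexes = ped.df["sex"].to_numpy()
    haps = np.empty((n, 2, m), dtype=np.int8)
    for j, row_i in enumerate(ped_founders):
        haps[row_i] = founders.haplotypes[j]
        if sexes[row_i] == "M" and len(x_idx):
            haps[row_i, 1, x_idx] = haps[row_i, 0, x_idx]  # hemizygous
    sire, dam = ped.parent_indices()
    order = ped.topological_order()
    for i in order:
        si, di = sire[i], dam[i]
        if si < 0 and di < 0:
            continue
        if si < 0 or di < 0:
            raise ValueError(
                f"animal {ped.ids[i]!r} has exactly one known parent; gene "
                "dropping requires both or neither"
            )
        paternal = _gamete(haps[si], gmap, rng)
        maternal = _gamete(haps[di], gmap, rng)
        if len(x_idx):
            if sexes[i] == "M":
                paternal[x_idx] = maternal[x_idx]  # son: X from dam only
            else:
                paternal[x_idx] = haps[si, 0, x_idx]  # daughter: father's single X
        haps[i, 0] = paternal
        haps[i, 1] = maternal
    genotypes = haps.sum(axis=1, dtype=np.int8)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = -1
    return GenotypeMatrix(
        ids=ped.ids,
        genotypes=genotypes,
        gmap=gmap,
        haplotypes=haps if keep_haplotypes else None,
    )
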