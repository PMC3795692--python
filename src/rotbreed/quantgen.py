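"""Trait simulation, selection-experiment driver, and heritability estimation.

Phenotypes follow a strictly additive polygenic model: y = sum_q x_q a_q + e,
with x_q the 0/1/2 QTL dosage, a_q the allele effect and e ~ N(0, sigma_E^2).
Narrow-sense heritability h^2 = sigma_A^2 / (sigma_A^2 + sigma_E^2) is
estimated two ways — midparent-offspring regression and an individual
("animal") mixed model fitted by REML with the pedigree relationship matrix —
and the effective number of loci behind a line cross is summarized by the
Castle-Wright estimator n_E = (P1 - P2)^2 / (8 (Var_F2 - Var_F1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expectations import BreederCounts
from .genedrop import (
    FounderPool,
    GeneticMap,
    GenotypeMatrix,
    _gamete,
    make_genetic_map,
    simulate_founders,
)
from .pedigree import (
    Pedigree,
    RelationshipMatrix,
    UNKNOWN,
    additive_relationship,
)
from .schemes import RotationScheme, SelectionRule, rotation_sire_family

__all__ = [
    "TraitArchitecture",
    "HeritabilityEstimate",
    "CastleWrightResult",
    "make_random_architecture",
    "simulate_phenotypes",
    "SelectionExperimentConfig",
    "SelectionExperimentResult",
    "run_selection_experiment",
    "heritability_midparent",
    "heritability_animal_model",
    "castle_wright",
    "vertical_work",
    "combined_sex_sd",
    "divergence_statistics",
    "cohort_summary_tables",
    "spearman_distance_weight",
    "load_cohort_phenotypes",
    "load_inbred_strain_distances",
]

GRAVITY = 9.8  # m/s^2
DEFAULT_SLOPE_DEG = 15.0


# ---------------------------------------------------------------------------
# Trait architecture and phenotype simulation
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """Additive QTL architecture: marker indices, allele effects, noise SD."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    env_sd: float
    h2_target: float | None = None

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("QTL effects must be finite")
        if self.env_sd < 0:
            raise ValueError("environmental SD must be >= 0")

    def genetic_values(self, G: GenotypeMatrix) -> np.ndarray:
        x = G.genotypes[:, self.qtl_indices].astype(float)
        x[x < 0] = np.nan  # missing dosage: drop from the sum (rare in sims)
        return np.nansum(x * self.effects, axis=1)


def make_random_architecture(
    founders_G: GenotypeMatrix,
    n_qtl: int,
    h2_target: float,
    effect_scale: float = 1.0,
    equal_effects: bool = True,
    autosomal_only: bool = True,
    seed: int | None = None,
) -> TraitArchitecture:
    """Pick QTL among the map's markers and calibrate the noise variance.

    The environmental variance is set from the *realized* genetic variance in
    the supplied founder panel so that the founder-population heritability
    equals ``h2_target``: sigma_E^2 = Var(g) (1 - h2) / h2.
    """
    if not 0.0 <= h2_target <= 1.0:
        raise ValueError("h2_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    candidates = (founders_G.gmap.autosomal_marker_indices()
                  if autosomal_only else np.arange(founders_G.n_markers))
    # prefer markers segregating in the founders
    freqs = founders_G.allele_frequencies()[candidates]
    seg = candidates[(freqs > 0.05) & (freqs < 0.95)]
    if len(seg) < n_qtl:
        seg = candidates
    qtl = np.sort(rng.choice(seg, size=n_qtl, replace=False))
    if h2_target == 0:
        # a non-heritable trait is pure noise: zero effects, unit noise scale
        return TraitArchitecture(qtl, np.zeros(n_qtl), env_sd=max(effect_scale, 1.0),
                                 h2_target=0.0)
    effects = (np.full(n_qtl, effect_scale) if equal_effects
               else rng.normal(0.0, effect_scale, size=n_qtl))
    arch = TraitArchitecture(qtl, effects, env_sd=0.0, h2_target=h2_target)
    var_g = float(np.var(arch.genetic_values(founders_G), ddof=1))
    if var_g == 0:
        raise ValueError("zero genetic variance in founders with h2_target > 0")
    arch.env_sd = math.sqrt(var_g * (1.0 - h2_target) / h2_target)
    return arch


def simulate_phenotypes(G: GenotypeMatrix, arch: TraitArchitecture, seed: int) -> pd.Series:
    """Additive genetic value plus Gaussian environmental noise, per animal."""
    rng = np.random.default_rng(seed)
    g = arch.genetic_values(G)
    y = g + rng.normal(0.0, arch.env_sd, size=len(g))
    return pd.Series(y, index=G.ids, name="phenotype")


# ---------------------------------------------------------------------------
# Selection experiment driver
# ---------------------------------------------------------------------------


@dataclass
class SelectionExperimentConfig:
    """End-to-end divergent selection run on a shared mosaic founder pool.

    Defaults are a desk-scale rendition of the colony design: 13 families per
    line, one selected breeder pair per family, a rotational mate schedule,
    and litters of ``litter_size`` phenotyped offspring per pair.
    """

    n_generations: int = 26
    n_families: int = 13
    litter_size: int = 8
    founder_pool_size: int = 186
    n_markers: int = 800
    n_autosomes: int = 10
    n_qtl: int = 30
    h2: float = 0.4
    directions: tuple[str, str] = ("highest", "lowest")
    lines: tuple[str, str] = ("HCR", "LCR")
    k_strains: int = 8


@dataclass
class SelectionExperimentResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.Series
    architecture: TraitArchitecture
    summary: pd.DataFrame  # per line x generation phenotype mean/sd/n

    def sample_animals(self, line: str, generation: int, n: int, seed: int = 0) -> list[str]:
        df = self.pedigree.df
        pool = df[(df["line"] == line) & (df["generation"] == generation)]["id"].tolist()
        rng = np.random.default_rng(seed)
        n = min(n, len(pool))
        return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]


def run_selection_experiment(
    config: SelectionExperimentConfig | None = None,
    seed: int = 0,
) -> SelectionExperimentResult:
    """Divergent within-family truncation selection under rotational mating.

    Both lines start from one shared mosaic founder pool: each line's G0 is
    13 founder pairs (disjoint between lines) drawn at random from the pool.
    Every generation, each family's litter is phenotyped, the extreme male
    and female per family are selected (direction per line), and breeders are
    paired under the rotation schedule.  Genotypes are gene-dropped as the
    pedigree grows; phenotypes use one architecture shared by both lines.
    """
    cfg = config or SelectionExperimentConfig()
    rng = np.random.default_rng(seed)
    gmap = make_genetic_map(n_markers=cfg.n_markers, n_autosomes=cfg.n_autosomes,
                            seed=int(rng.integers(2**31)))
    pool = simulate_founders(gmap, cfg.founder_pool_size, k_strains=cfg.k_strains,
                             seed=int(rng.integers(2**31)))
    founder_G = GenotypeMatrix(
        ids=[f"P{i:03d}" for i in range(cfg.founder_pool_size)],
        genotypes=pool.haplotypes.sum(axis=1, dtype=np.int8),
        gmap=gmap, haplotypes=pool.haplotypes,
    )
    arch = make_random_architecture(founder_G, cfg.n_qtl, cfg.h2,
                                    seed=int(rng.integers(2**31)))
    scheme = RotationScheme(cfg.n_families)
    noise_rng = np.random.default_rng(int(rng.integers(2**31)))
    x_idx = gmap.x_marker_indices()

    rows: list[dict] = []
    haps: dict[str, np.ndarray] = {}
    phen: dict[str, float] = {}

    def register(aid, sire, dam, sex, gen, line, family, hap):
        if sex == "M" and len(x_idx):
            hap = hap.copy()
            hap[0, x_idx] = hap[1, x_idx]  # hemizygous X from the dam
        haps[aid] = hap
        g_val = float(np.sum(hap.sum(axis=0)[arch.qtl_indices] * arch.effects))
        y = g_val + noise_rng.normal(0.0, arch.env_sd)
        phen[aid] = y
        rows.append(dict(id=aid, sire=sire, dam=dam, sex=sex, generation=gen,
                         line=line, family=family, best_distance_m=y))

    # founder pool members not drawn into a line stay out of the pedigree
    perm = rng.permutation(cfg.founder_pool_size)
    need = 2 * 2 * cfg.n_families
    if cfg.founder_pool_size < need:
        raise ValueError("founder pool too small for two 13-family lines")
    take = iter(perm[:need])
    breeders: dict[str, dict[int, dict[str, str]]] = {}
    for line in cfg.lines:
        breeders[line] = {}
        for fam in range(1, cfg.n_families + 1):
            pair = {}
            for sex in ("M", "F"):
                k = next(take)
                aid = f"{line}-G00-F{fam:02d}{sex}"
                register(aid, UNKNOWN, UNKNOWN, sex, 0, line, fam, pool.haplotypes[k].copy())
                pair[sex] = aid
            breeders[line][fam] = pair

    for g in range(1, cfg.n_generations + 1):
        rotation = None if g == 1 else g - 1
        for line, direction in zip(cfg.lines, cfg.directions):
            litters: dict[int, list[str]] = {}
            for fam in range(1, cfg.n_families + 1):
                sire_fam = fam if rotation is None else scheme.sire_family(fam, rotation)
                sire = breeders[line][sire_fam]["M"]
                dam = breeders[line][fam]["F"]
                kids = []
                for k in range(cfg.litter_size):
                    sex = "M" if k % 2 == 0 else "F"
                    aid = f"{line}-G{g:02d}-F{fam:02d}K{k}"
                    hap = np.stack([_gamete(haps[sire], gmap, noise_rng),
                                    _gamete(haps[dam], gmap, noise_rng)])
                    if sex == "F" and len(x_idx):
                        hap[0, x_idx] = haps[sire][0, x_idx]  # father's single X
                    register(aid, sire, dam, sex, g, line, fam, hap)
                    kids.append(aid)
                litters[fam] = kids
            # within-family truncation selection for the next breeders
            cand = pd.DataFrame(
                [r for r in rows if r["line"] == line and r["generation"] == g]
            )
            from .schemes import select_breeders_within_family  # local to avoid cycle
            assignment, flagged = select_breeders_within_family(
                cand, SelectionRule(direction=direction)
            )
            if flagged:  # balanced litters -> never expected here
                raise RuntimeError(f"missing breeder slots: {flagged}")
            breeders[line] = assignment

    ped = Pedigree(pd.DataFrame(rows))
    ids = ped.ids
    hap_arr = np.stack([haps[a] for a in ids])
    G = GenotypeMatrix(ids=ids, genotypes=hap_arr.sum(axis=1, dtype=np.int8),
                       gmap=gmap, haplotypes=hap_arr)
    phen_s = pd.Series(phen, name="phenotype").reindex(ids)
    summary = (
        ped.df.assign(y=phen_s.to_numpy())
        .groupby(["line", "generation"])["y"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    return SelectionExperimentResult(pedigree=ped, genotypes=G, phenotypes=phen_s,
                                     architecture=arch, summary=summary)


# ---------------------------------------------------------------------------
# Line-cross (F0 -> F1 -> F2) simulation
# ---------------------------------------------------------------------------


@dataclass
class IntercrossResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.Series
    qtl_indices: np.ndarray
    mean_p1: float
    mean_p2: float
    mean_f1: float
    var_f1: float
    var_f2: float


def simulate_intercross_experiment(
    n_qtl: int = 8,
    qtl_effect: float = 1.0,
    env_sd: float = 2.0,
    design=None,
    n_markers: int = 200,
    n_autosomes: int = 8,
    seed: int = 0,
) -> IntercrossResult:
    """Reciprocal cross of two diverged lines with a known additive trait.

    The parental lines are fixed for alternate alleles at ``n_qtl`` unlinked
    QTL of equal effect (background markers segregate at random), the
    canonical regime for the Castle-Wright estimator: in expectation
    Var(F2) - Var(F1) is the full segregation variance ``n_qtl a^2 / 2`` and
    n_E recovers ``n_qtl``.  Phenotypes carry N(0, env_sd^2) noise.
    """
    from .schemes import CrossBatch, CrossDesign, build_intercross_pedigree
    from .genedrop import FounderPool, drop_genotypes

    if design is None:
        design = CrossDesign(batches=(CrossBatch(8, 100, 100, 400),))
    rng = np.random.default_rng(seed)
    gmap = make_genetic_map(n_markers=n_markers, n_autosomes=n_autosomes,
                            include_x=False, seed=int(rng.integers(2**31)))
    m = gmap.n_markers
    qtl = np.linspace(0, m - 1, n_qtl + 2)[1:-1].astype(int)
    need = max(b.n_f0_pairs for b in design.batches) * len(design.batches)
    f0_high = pd.DataFrame({"id": [f"H{i:02d}" for i in range(2 * need)],
                            "sex": ["M", "F"] * need})
    f0_low = pd.DataFrame({"id": [f"L{i:02d}" for i in range(2 * need)],
                           "sex": ["F", "M"] * need})
    ped = build_intercross_pedigree(design, f0_high, f0_low, seed=int(rng.integers(2**31)))

    founder_rows = ped.df.loc[ped.founder_mask]
    haps = rng.integers(0, 2, (len(founder_rows), 2, m)).astype(np.int8)
    is_high = (founder_rows["line"] == "HCR").to_numpy()
    haps[:, :, qtl] = np.where(is_high[:, None, None], 1, 0)
    pool = FounderPool(strain_alleles=np.zeros((1, m), np.int8), haplotypes=haps,
                       strain_of=np.zeros_like(haps, dtype=np.int32), gmap=gmap,
                       strain_weights=np.array([1.0]))
    G = drop_genotypes(ped, pool, seed=int(rng.integers(2**31)), keep_haplotypes=False)
    arch = TraitArchitecture(qtl, np.full(n_qtl, qtl_effect), env_sd=env_sd)
    y = simulate_phenotypes(G, arch, seed=int(rng.integers(2**31)))
    df = ped.df.assign(_y=y.reindex(ped.ids).to_numpy())
    by = df.groupby("line")["_y"]
    return IntercrossResult(
        pedigree=ped, genotypes=G, phenotypes=y, qtl_indices=qtl,
        mean_p1=float(by.mean()["HCR"]), mean_p2=float(by.mean()["LCR"]),
        mean_f1=float(by.mean()["F1"]),
        var_f1=float(by.var(ddof=1)["F1"]), var_f2=float(by.var(ddof=1)["F2"]),
    )


# ---------------------------------------------------------------------------
# Heritability estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    se: float
    method: str
    covariates: tuple[str, ...] = ()
    n: int = 0


def _design_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        v = df[cov]
        if v.dtype.kind in "OUSb" or cov in ("sex", "line"):
            for level in sorted(v.astype(str).unique())[1:]:
                cols.append((v.astype(str) == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular fixed-effect design; aliased covariates among {names}")
    return X


def heritability_midparent(
    ped: Pedigree,
    trait: str = "best_distance_m",
    covariates: tuple[str, ...] = ("sex",),
) -> HeritabilityEstimate:
    """Midparent-offspring regression after covariate residualization.

    Offspring with both parents phenotyped are grouped by parent pair; the
    slope of family-mean offspring residual on midparent residual estimates
    h^2 (regression SE reported).
    """
    df = ped.df
    y = df[trait].to_numpy(float)
    ok = np.isfinite(y)
    X = _design_matrix(df[ok], covariates)
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    resid = pd.Series(np.nan, index=df["id"])
    resid[df["id"][ok].to_numpy()] = y[ok] - X @ beta

    fam: dict[tuple[str, str], list[float]] = {}
    for _, row in df.iterrows():
        s, d = row["sire"], row["dam"]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        r_off = resid.get(row["id"], np.nan)
        r_s, r_d = resid.get(s, np.nan), resid.get(d, np.nan)
        if np.isfinite(r_off) and np.isfinite(r_s) and np.isfinite(r_d):
            fam.setdefault((s, d), []).append(float(r_off))
    if len(fam) < 2:
        raise ValueError("no (or too few) complete midparent-offspring families")
    mid, off = [], []
    for (s, d), kids in fam.items():
        mid.append((resid[s] + resid[d]) / 2.0)
        off.append(float(np.mean(kids)))
    if len(mid) < 20:
        import warnings
        warnings.warn(f"only {len(mid)} midparent families; estimate will be noisy")
    res = stats.linregress(mid, off)
    return HeritabilityEstimate(
        h2=float(np.clip(res.slope, 0.0, 1.0)), se=float(res.stderr),
        method="midparent", covariates=tuple(covariates), n=len(mid),
    )


def _reml_profile(y, X, eigvals, eigvecs):
    """Profile REML log-likelihood of h2 after rotating by A's eigenvectors."""
    yt = eigvecs.T @ y
    Xt = eigvecs.T @ X
    n, p = X.shape

    def nll(h2):
        lam = h2 * eigvals + (1.0 - h2)
        lam = np.maximum(lam, 1e-12)
        w = 1.0 / lam
        XtW = Xt * w[:, None]
        xtx = Xt.T @ XtW
        beta = np.linalg.solve(xtx, XtW.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        sigma2 = rss / (n - p)
        _, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * ((n - p) * math.log(sigma2) + np.sum(np.log(lam))
                     + logdet_xtx + (n - p))
        return -ll

    return nll


def heritability_animal_model(
    ped: Pedigree,
    trait: str = "best_distance_m",
    covariates: tuple[str, ...] = ("sex",),
    A: RelationshipMatrix | None = None,
    log_transform: bool = False,
) -> HeritabilityEstimate:
    """Animal-model REML: y = X beta + u + e, var(u) = sigma_A^2 A.

    The likelihood is profiled down to the single ratio h^2 via the
    eigendecomposition of the (phenotyped-subset) relationship matrix, then
    maximized by a grid scan plus bounded 1-D search; the SE comes from the
    numerical curvature of the profile at the optimum.  The estimate is
    clipped to [0, 1].
    """
    df = ped.df
    y = df[trait].to_numpy(float)
    if log_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(y > 0, np.log(y), np.nan)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("too few phenotyped animals")
    if np.nanstd(y[ok]) == 0:
        raise ValueError("phenotype is constant")
    A = A or additive_relationship(ped)
    idx = np.flatnonzero(ok)
    A_sub = A.values[np.ix_(idx, idx)]
    X = _design_matrix(df.iloc[idx], covariates)
    eigvals, eigvecs = np.linalg.eigh(A_sub)
    nll = _reml_profile(y[idx], X, eigvals, eigvecs)

    grid = np.linspace(0.0, 0.999, 41)
    vals = [nll(h) for h in grid]
    h0 = grid[int(np.argmin(vals))]
    lo, hi = max(0.0, h0 - 0.05), min(0.999, h0 + 0.05)
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    h2 = float(res.x)
    eps = 1e-3
    a, b = max(0.0, h2 - eps), min(0.999, h2 + eps)
    curv = (nll(a) - 2 * nll(h2) + nll(b)) / ((b - a) / 2) ** 2
    se = float(1.0 / math.sqrt(curv)) if curv > 0 else float("nan")
    return HeritabilityEstimate(
        h2=float(np.clip(h2, 0.0, 1.0)), se=se, method="animal_model_reml",
        covariates=tuple(covariates), n=int(ok.sum()),
    )


def reml_profile_loglik(ped, trait, covariates=("sex",), A=None, h2_values=None):
    """Profile REML log-likelihood evaluated on a grid (diagnostics/tests)."""
    df = ped.df
    y = df[trait].to_numpy(float)
    ok = np.isfinite(y)
    A = A or additive_relationship(ped)
    idx = np.flatnonzero(ok)
    A_sub = A.values[np.ix_(idx, idx)]
    X = _design_matrix(df.iloc[idx], covariates)
    eigvals, eigvecs = np.linalg.eigh(A_sub)
    nll = _reml_profile(y[idx], X, eigvals, eigvecs)
    hs = np.linspace(0.0, 0.999, 21) if h2_values is None else np.asarray(h2_values)
    return pd.DataFrame({"h2": hs, "loglik": [-nll(h) for h in hs]})


# ---------------------------------------------------------------------------
# Castle-Wright, vertical work, cohort summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CastleWrightResult:
    n_e: float
    mean_p1: float
    mean_p2: float
    var_f1: float
    var_f2: float


def castle_wright(mean_p1: float, mean_p2: float, var_f1: float, var_f2: float) -> CastleWrightResult:
    """Effective QTL number n_E = (P1 - P2)^2 / (8 (Var_F2 - Var_F1)).

    Assumes unlinked additive loci of equal effect with no interaction; known
    to be biased downward by linkage and unequal effects.  Raises when the F2
    variance does not exceed the F1 variance (negative segregation variance).
    """
    if var_f2 <= var_f1:
        raise ValueError(
            "negative segregation variance: Var(F2) must exceed Var(F1) for "
            "the Castle-Wright estimator to be defined"
        )
    n_e = (mean_p1 - mean_p2) ** 2 / (8.0 * (var_f2 - var_f1))
    return CastleWrightResult(n_e=float(n_e), mean_p1=mean_p1, mean_p2=mean_p2,
                              var_f1=var_f1, var_f2=var_f2)


def vertical_work(distance_m, body_weight_g, slope_deg: float = DEFAULT_SLOPE_DEG):
    """Treadmill work against gravity in joules.

    work = distance [m] x weight [g] x sin(slope) x 9.8 / 1000; bilinear in
    distance and weight.
    """
    distance_m = np.asarray(distance_m, dtype=float)
    body_weight_g = np.asarray(body_weight_g, dtype=float)
    if np.any(distance_m < 0) or np.any(body_weight_g < 0):
        raise ValueError("distance and body weight must be non-negative")
    w = distance_m * body_weight_g * math.sin(math.radians(slope_deg)) * GRAVITY / 1000.0
    return float(w) if w.ndim == 0 else w


def combined_sex_sd(n_m, mean_m, sd_m, n_f, mean_f, sd_f) -> float:
    """Combined-sex SD from per-sex n/mean/SD via the two-component mixture
    variance (the only convention that reconstructs a pooled SD from a
    published by-sex summary table)."""
    n = n_m + n_f
    mean = (n_m * mean_m + n_f * mean_f) / n
    ex2 = (n_m * (sd_m**2 + mean_m**2) + n_f * (sd_f**2 + mean_f**2)) / n
    return math.sqrt(ex2 - mean**2)


def cohort_summary_tables(ped: Pedigree, traits=("best_distance_m", "body_weight_g")) -> pd.DataFrame:
    """Per line x generation x sex n/mean/SD for each phenotype column."""
    frames = []
    for trait in traits:
        grp = (
            ped.df.dropna(subset=[trait])
            .groupby(["line", "generation", "sex"])[trait]
            .agg(n="count", mean="mean", sd="std")
            .reset_index()
        )
        grp.insert(0, "trait", trait)
        frames.append(grp)
    return pd.concat(frames, ignore_index=True)


def divergence_statistics(summary: pd.DataFrame, generation: int,
                          lines: tuple[str, str] = ("HCR", "LCR"),
                          trait: str | None = None) -> dict[str, float]:
    """Between-line divergence at one generation from a by-sex summary table.

    ``summary`` needs columns line, generation, sex, n, mean, sd (and
    optionally trait).  Returns the fold change of sex-averaged means
    (high / low) and the between-line difference in units of the average
    combined-sex within-line SD.
    """
    t = summary
    if trait is not None and "trait" in t.columns:
        t = t[t["trait"] == trait]
    t = t[t["generation"] == generation]
    stats_by_line = {}
    for line in lines:
        sub = t[t["line"] == line].set_index("sex")
        if not {"M", "F"} <= set(sub.index):
            raise ValueError(f"missing sex stratum for line {line} at G{generation}")
        m, f = sub.loc["M"], sub.loc["F"]
        stats_by_line[line] = dict(
            sex_avg_mean=(m["mean"] + f["mean"]) / 2.0,
            combined_sd=combined_sex_sd(m["n"], m["mean"], m["sd"],
                                        f["n"], f["mean"], f["sd"]),
        )
    hi, lo = stats_by_line[lines[0]], stats_by_line[lines[1]]
    fold = hi["sex_avg_mean"] / lo["sex_avg_mean"]
    avg_sd = (hi["combined_sd"] + lo["combined_sd"]) / 2.0
    sd_units = (hi["sex_avg_mean"] - lo["sex_avg_mean"]) / avg_sd
    return {"fold_change": float(fold), "sd_units": float(sd_units)}


def spearman_distance_weight(
    ped: Pedigree,
    line: str | None = None,
    sex: str | None = None,
    span: tuple[int, int] = (1, 28),
) -> tuple[float, float, pd.Series]:
    """Spearman rho(running distance, body weight) per generation, averaged.

    Ties get average ranks (scipy).  Generations with < 3 complete pairs or a
    constant value are skipped.  Returns (mean, SD across generations,
    per-generation rho series).
    """
    df = ped.df
    if line is not None:
        df = df[df["line"] == line]
    if sex is not None:
        df = df[df["sex"] == sex]
    rhos = {}
    for g in range(span[0], span[1] + 1):
        sub = df[df["generation"] == g].dropna(
            subset=["best_distance_m", "body_weight_g"]
        )
        if len(sub) < 3:
            continue
        x, w = sub["best_distance_m"], sub["body_weight_g"]
        if x.nunique() < 2 or w.nunique() < 2:
            continue
        rho = stats.spearmanr(x, w).statistic
        if np.isfinite(rho):
            rhos[g] = float(rho)
    if not rhos:
        raise ValueError("no generation had enough complete phenotype pairs")
    s = pd.Series(rhos, name="rho")
    return float(s.mean()), float(s.std(ddof=1)), s


# ---------------------------------------------------------------------------
# Embedded study summary tables
# ---------------------------------------------------------------------------


def load_cohort_phenotypes() -> pd.DataFrame:
    """By-sex running-distance and body-weight summaries of the two selection
    lines over 28 generations (columns: line, generation, sex, n,
    distance_mean, distance_sd, weight_mean, weight_sd)."""
    with resources.files("rotbreed.data").joinpath("cohort_phenotypes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_inbred_strain_distances() -> pd.DataFrame:
    """Best treadmill running distance of eleven common inbred rat strains."""
    with resources.files("rotbreed.data").joinpath("inbred_strain_running.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
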