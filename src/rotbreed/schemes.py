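"""Pedigree builders: rotational scheme, random mating, selection, intercross.

The rotational scheme keeps ``n_families`` (default 13) families, one breeding
pair per family per generation.  A female of family *i* is mated, in rotation
*r*, to the male of family ``((i - 1 + r) mod n) + 1``; the rotation index
advances by one each generation and the same-family offset (multiples of *n*)
is skipped, so the effective offsets cycle through 1..n-1.  Offspring belong
to their dam's family.  Because each family contributes one son and one
daughter, the scheme inevitably pairs first cousins whenever consecutive
effective rotations sum to ``n`` — every half cycle (~6 generations for 13
families) — producing the characteristic cyclic spikes in inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectations import BreederCounts
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "RotationScheme",
    "SelectionRule",
    "CrossBatch",
    "CrossDesign",
    "rotation_sire_family",
    "build_idealized_rotational_pedigree",
    "build_random_mating_pedigree",
    "select_breeders_within_family",
    "build_intercross_pedigree",
]


@dataclass(frozen=True)
class RotationScheme:
    """Cyclic between-family mate assignment with same-family offsets skipped."""

    n_families: int = 13

    def effective_rotation(self, rotation: int) -> int:
        """Collapse a raw rotation index onto the 1..n-1 offset cycle."""
        if rotation < 1:
            raise ValueError("rotation index must be >= 1")
        return (rotation - 1) % (self.n_families - 1) + 1

    def sire_family(self, dam_family: int, rotation: int) -> int:
        return rotation_sire_family(dam_family, rotation, self.n_families)


def rotation_sire_family(dam_family: int, rotation: int, n_families: int = 13) -> int:
    """Family of the sire mated to a family-``dam_family`` female in ``rotation``.

    Never returns ``dam_family`` itself: offsets that are multiples of
    ``n_families`` (same-family mating) are skipped, so rotation ``n`` reuses
    the rotation-1 map.
    """
    if n_families < 3:
        raise ValueError("rotational breeding requires at least 3 families")
    if not 1 <= dam_family <= n_families:
        raise ValueError(f"dam_family must lie in 1..{n_families}")
    offset = (rotation - 1) % (n_families - 1) + 1
    return (dam_family - 1 + offset) % n_families + 1


def build_idealized_rotational_pedigree(
    n_generations: int,
    scheme: RotationScheme | None = None,
) -> Pedigree:
    """Deterministic pedigree of a perfectly executed rotational scheme.

    G0 holds one unrelated founder pair per family.  Founder pairs are mated
    within family (harmless: founders are unrelated); generation *g* breeders
    (g >= 1) mate under rotation *g*, so generation g+1 of family *i* has dam
    = the G*g* female of family *i* and sire = the G*g* male of family
    ``sire_family(i, g)``.  Each family contributes exactly one male and one
    female per generation.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    scheme = scheme or RotationScheme()
    n = scheme.n_families

    def ident(g: int, fam: int, sex: str) -> str:
        return f"G{g:02d}F{fam:02d}{sex}"

    rows = []
    for fam in range(1, n + 1):
        for sex in ("M", "F"):
            rows.append(dict(id=ident(0, fam, sex), sire=UNKNOWN, dam=UNKNOWN,
                             sex=sex, generation=0, family=fam))
    for g in range(1, n_generations + 1):
        for fam in range(1, n + 1):
            sire_fam = fam if g == 1 else scheme.sire_family(fam, g - 1)
            sire = ident(g - 1, sire_fam, "M")
            dam = ident(g - 1, fam, "F")
            for sex in ("M", "F"):
                rows.append(dict(id=ident(g, fam, sex), sire=sire, dam=dam,
                                 sex=sex, generation=g, family=fam))
    return Pedigree(pd.DataFrame(rows))


def build_random_mating_pedigree(
    counts: BreederCounts,
    n_generations: int,
    seed: int,
    mating: str = "monogamous",
) -> Pedigree:
    """Random-mating pedigree matched to per-generation breeder counts.

    With ``mating="monogamous"`` (default) the previous generation's breeders
    form ``min(N_m, N_f)`` random couples and each offspring is assigned to a
    uniformly chosen couple (multinomial litter sizes), mirroring a paired
    breeding colony; ``mating="random_union"`` instead draws each offspring's
    sire and dam independently.  The two models are statistically
    indistinguishable for mean inbreeding and both realize Wright's *exact*
    separate-sexes recursion F_{t+1} = c (1 + F_{t-1}) + (1 - 2c) F_t with
    c = (N_f + N_m)/(8 N_f N_m); the lag-free textbook recursion of the
    expectations module matches their asymptotic rate but overstates F at
    finite horizons by about 1.5 generations' worth of drift.
    """
    if mating not in ("random_union", "monogamous"):
        raise ValueError("mating must be 'random_union' or 'monogamous'")
    rng = np.random.default_rng(seed)
    n_m0, n_f0 = counts.at(0)
    rows = []
    males = [f"G00M{i:03d}" for i in range(n_m0)]
    females = [f"G00F{i:03d}" for i in range(n_f0)]
    for a, sex in [(m, "M") for m in males] + [(f, "F") for f in females]:
        rows.append(dict(id=a, sire=UNKNOWN, dam=UNKNOWN, sex=sex, generation=0))
    for g in range(1, n_generations + 1):
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"no breeders of one sex available at generation {g - 1}")
        if mating == "monogamous":
            n_pairs = min(len(males), len(females))
            pm = rng.permutation(len(males))[:n_pairs]
            pf = rng.permutation(len(females))[:n_pairs]
            pairs = [(males[i], females[j]) for i, j in zip(pm, pf)]
        n_m, n_f = counts.at(g)
        new_m = [f"G{g:02d}M{i:03d}" for i in range(n_m)]
        new_f = [f"G{g:02d}F{i:03d}" for i in range(n_f)]
        for ident, sex in [(m, "M") for m in new_m] + [(f, "F") for f in new_f]:
            if mating == "monogamous":
                sire, dam = pairs[rng.integers(len(pairs))]
            else:
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
            rows.append(dict(id=ident, sire=sire, dam=dam, sex=sex, generation=g))
        males, females = new_m, new_f
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Within-family truncation selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionRule:
    """Pick the extreme-trait male and female of each family.

    ``direction`` is ``"highest"`` or ``"lowest"``; ties break deterministically
    to the smallest animal id.
    """

    direction: str = "highest"
    trait: str = "best_distance_m"


def select_breeders_within_family(
    candidates: pd.DataFrame,
    rule: SelectionRule,
) -> tuple[dict[int, dict[str, str]], list[tuple[int, str]]]:
    """Per-family breeder assignment under within-family truncation selection.

    ``candidates`` needs columns id, sex, family and the rule's trait column;
    animals with a missing trait value are not eligible.  Returns
    ``(assignment, flagged)`` where ``assignment[family][sex] -> id`` and
    ``flagged`` lists (family, sex) slots with no eligible candidate — the
    caller may then authorize a substitute (conventionally a male from
    another family).
    """
    if rule.direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    ascending = rule.direction == "lowest"
    eligible = candidates.dropna(subset=[rule.trait])
    assignment: dict[int, dict[str, str]] = {}
    flagged: list[tuple[int, str]] = []
    for fam in sorted(candidates["family"].dropna().unique()):
        fam = int(fam)
        assignment[fam] = {}
        fam_rows = eligible[eligible["family"] == fam]
        for sex in ("M", "F"):
            sub = fam_rows[fam_rows["sex"] == sex]
            if len(sub) == 0:
                flagged.append((fam, sex))
                continue
            sub = sub.sort_values([rule.trait, "id"], ascending=[ascending, True],
                                  kind="stable")
            assignment[fam][sex] = str(sub.iloc[0]["id"])
    return assignment, flagged


# ---------------------------------------------------------------------------
# Line intercross (F0 -> F1 -> F2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossBatch:
    """One intercross batch: F0 pairs -> F1 litter -> F1 pairs -> F2 litter."""

    n_f0_pairs: int
    n_f1: int
    n_f1_breeders: int  # split evenly into males and females -> n/2 pairs
    n_f2: int


@dataclass(frozen=True)
class CrossDesign:
    """Reciprocal two-line intercross in one or more batches.

    Every F0 pair takes one animal from each line; half the pairs put the
    high-line animal as sire and half as dam (reciprocal-parentage balance).
    F1 pairs never unite full sibs.  Defaults mirror the two-batch design of
    the selection-colony study: 8 F0 pairs / 79 F1 / 40 F1 breeders / 154 F2,
    then 18 / 163 / 80 / 491, totalling 645 F2 animals.
    """

    batches: tuple[CrossBatch, ...] = (
        CrossBatch(8, 79, 40, 154),
        CrossBatch(18, 163, 80, 491),
    )


def build_intercross_pedigree(
    design: CrossDesign,
    f0_high: pd.DataFrame,
    f0_low: pd.DataFrame,
    seed: int,
) -> Pedigree:
    """Three-tier F0 -> F1 -> F2 pedigree honoring the design's constraints.

    ``f0_high``/``f0_low`` need columns id and sex and at least as many animals
    of each sex, summed over batches, as the design requires.  Generation
    labels are 0/1/2 with line labels F0 (original line kept), F1, F2.
    Raises if the no-sib-mating constraint is infeasible (fewer than two F0
    pairs in a batch).
    """
    rng = np.random.default_rng(seed)
    rows = []
    used = {"high": {"M": 0, "F": 0}, "low": {"M": 0, "F": 0}}

    def take(frame: pd.DataFrame, which: str, sex: str) -> str:
        pool = frame[frame["sex"] == sex]["id"].tolist()
        k = used[which][sex]
        if k >= len(pool):
            raise ValueError(f"not enough {sex} animals in the {which}-line F0 pool")
        used[which][sex] += 1
        return str(pool[k])

    for b, batch in enumerate(design.batches):
        if batch.n_f0_pairs < 2:
            raise ValueError(
                "a batch needs >= 2 F0 pairs: with a single family every "
                "F1 x F1 pairing would unite full sibs"
            )
        tag = f"B{b + 1}"
        f0_ids = []
        for p in range(batch.n_f0_pairs):
            high_is_sire = p % 2 == 0  # reciprocal balance
            hid = take(f0_high, "high", "M" if high_is_sire else "F")
            lid = take(f0_low, "low", "F" if high_is_sire else "M")
            for aid, line, sex in ((hid, "HCR", "M" if high_is_sire else "F"),
                                   (lid, "LCR", "F" if high_is_sire else "M")):
                rows.append(dict(id=f"{tag}-{aid}", sire=UNKNOWN, dam=UNKNOWN,
                                 sex=sex, generation=0, line=line, family=p + 1))
            f0_ids.append((f"{tag}-{hid if high_is_sire else lid}",
                           f"{tag}-{lid if high_is_sire else hid}"))
        # F1: litters distributed round-robin over F0 pairs, sexes alternating
        f1 = []
        for i in range(batch.n_f1):
            fam = i % batch.n_f0_pairs
            sire, dam = f0_ids[fam]
            sex = "M" if (i // batch.n_f0_pairs + i) % 2 == 0 else "F"
            ident = f"{tag}-F1-{i:03d}"
            rows.append(dict(id=ident, sire=sire, dam=dam, sex=sex,
                             generation=1, line="F1", family=fam + 1))
            f1.append((ident, sex, fam))
        # F1 breeders: equal sexes, families represented as evenly as possible
        males = [(i_, f_) for i_, s_, f_ in f1 if s_ == "M"]
        females = [(i_, f_) for i_, s_, f_ in f1 if s_ == "F"]
        half = batch.n_f1_breeders // 2
        if len(males) < half or len(females) < half:
            raise ValueError("not enough F1 animals of each sex for the breeder quota")
        bm, bf = males[:half], females[:half]
        # pair across families (rotate female list until no pair shares a family)
        for shift in range(half):
            pairs = [(bm[i], bf[(i + shift) % half]) for i in range(half)]
            if all(mf[1] != ff[1] for mf, ff in pairs):
                break
        else:
            raise ValueError("no F1 pairing avoids brother-sister mating")
        # F2
        for i in range(batch.n_f2):
            (sire, _), (dam, _) = pairs[i % half]
            sex = "M" if rng.integers(2) == 0 else "F"
            rows.append(dict(id=f"{tag}-F2-{i:03d}", sire=sire, dam=dam, sex=sex,
                             generation=2, line="F2", family=(i % half) + 1))
    return Pedigree(pd.DataFrame(rows))
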