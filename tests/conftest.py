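"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algebra: inbreeding is
recomputed by explicit common-ancestor path counting (Wright's formula) and,
where noted, by Monte-Carlo single-locus gene dropping, so that the tabular
relationship matrix is checked against genuinely independent routes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rotbreed.pedigree import Pedigree, UNKNOWN


# ---------------------------------------------------------------------------
# Toy pedigree builders
# ---------------------------------------------------------------------------


def make_pedigree(rows):
    """rows: (id, sire, dam, sex, generation[, extra dict])."""
    recs = []
    for row in rows:
        extra = row[5] if len(row) > 5 else {}
        recs.append(dict(id=row[0], sire=row[1], dam=row[2], sex=row[3],
                         generation=row[4], **extra))
    return Pedigree(pd.DataFrame(recs))


@pytest.fixture
def trio():
    return make_pedigree([
        ("s", UNKNOWN, UNKNOWN, "M", 0),
        ("d", UNKNOWN, UNKNOWN, "F", 0),
        ("c", "s", "d", "F", 1),
    ])


@pytest.fixture
def full_sib_family():
    """Unrelated founder pair, two full-sib offspring, and their inbred child."""
    return make_pedigree([
        ("s", UNKNOWN, UNKNOWN, "M", 0),
        ("d", UNKNOWN, UNKNOWN, "F", 0),
        ("b1", "s", "d", "M", 1),
        ("b2", "s", "d", "F", 1),
        ("k", "b1", "b2", "M", 2),
    ])


@pytest.fixture
def first_cousin_family():
    """Two sib pairs from unrelated grandparents; cousins mated."""
    return make_pedigree([
        ("gs", UNKNOWN, UNKNOWN, "M", 0),
        ("gd", UNKNOWN, UNKNOWN, "F", 0),
        ("u1", "gs", "gd", "M", 1),
        ("u2", "gs", "gd", "F", 1),
        ("m1", UNKNOWN, UNKNOWN, "F", 0),
        ("m2", UNKNOWN, UNKNOWN, "M", 0),
        ("c1", "u1", "m1", "M", 2),
        ("c2", "m2", "u2", "F", 2),
        ("kid", "c1", "c2", "F", 3),
    ])


def random_pedigree(n_founders, n_per_gen, n_generations, seed):
    """Random bisexual pedigree for property tests."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        ident = f"g0a{i}"
        rows.append((ident, UNKNOWN, UNKNOWN, sex, 0))
        (males if sex == "M" else females).append(ident)
    for g in range(1, n_generations + 1):
        new_m, new_f = [], []
        for i in range(n_per_gen):
            sex = "M" if i % 2 == 0 else "F"
            ident = f"g{g}a{i}"
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            rows.append((ident, sire, dam, sex, g))
            (new_m if sex == "M" else new_f).append(ident)
        males, females = new_m, new_f
    return make_pedigree(rows)


# ---------------------------------------------------------------------------
# Independent inbreeding oracles
# ---------------------------------------------------------------------------


def wright_path_counting_F(ped: Pedigree, animal_id: str) -> float:
    """F by explicit enumeration of common-ancestor path pairs.

    Wright's formula: F_X = sum over common ancestors A and over pairs of
    parent-to-A paths whose intermediate nodes are disjoint of
    (1/2)^(n1 + n2 + 1) (1 + F_A), with F_A computed recursively the same way.
    Exponential in pedigree depth; only for small pedigrees.
    """
    df = ped.df.set_index("id")

    def parents(a):
        row = df.loc[a]
        return [p for p in (row["sire"], row["dam"]) if p != UNKNOWN]

    def ancestor_paths(a):
        """All paths (a, ..., ancestor) from `a` up; includes path of length 0."""
        paths = [(a,)]
        for p in parents(a):
            for tail in ancestor_paths(p):
                paths.append((a,) + tail)
        return paths

    memo: dict[str, float] = {}

    def F(x):
        key = x
        if key in memo:
            return memo[key]
        par = parents(x)
        if len(par) < 2:
            val = 0.0
        else:
            s, d = par
            val = 0.0
            for p1 in ancestor_paths(s):
                for p2 in ancestor_paths(d):
                    if p1[-1] != p2[-1]:
                        continue
                    # intermediate nodes (everything except the shared ancestor)
                    inter1, inter2 = set(p1[:-1]), set(p2[:-1])
                    if inter1 & inter2:
                        continue
                    n1, n2 = len(p1) - 1, len(p2) - 1
                    val += 0.5 ** (n1 + n2 + 1) * (1.0 + F(p1[-1]))
        memo[key] = val
        return val

    return F(animal_id)


def genedrop_kinship_mc(ped: Pedigree, id1: str, id2: str, n_rep: int, seed: int) -> float:
    """Monte-Carlo kinship: drop one biallelic-unique-allele locus and count IBD.

    Each founder gets two private alleles; kinship(i, j) is estimated as the
    probability that one random allele of i is identical by descent to one
    random allele of j.
    """
    rng = np.random.default_rng(seed)
    sire, dam = ped.parent_indices()
    order = ped.topological_order()
    i1, i2 = ped.index_of(id1), ped.index_of(id2)
    n = len(ped)
    hits = 0
    alleles = np.empty((n, 2), dtype=np.int64)
    for rep in range(n_rep):
        nxt = 0
        for k in order:
            if sire[k] < 0:
                alleles[k] = (nxt, nxt + 1)
                nxt += 2
            else:
                alleles[k, 0] = alleles[sire[k], rng.integers(2)]
                alleles[k, 1] = alleles[dam[k], rng.integers(2)]
        a = alleles[i1, rng.integers(2)]
        b = alleles[i2, rng.integers(2)]
        hits += a == b
    return hits / n_rep
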