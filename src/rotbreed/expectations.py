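"""Closed-form expectations for inbreeding and heterozygosity under random mating.

With N_m male and N_f female breeders per generation, the per-generation
increment of the expected inbreeding coefficient (and the matching relative
loss of expected heterozygosity) under random mating with separate sexes is

    c_n = (N_f + N_m) / (8 N_f N_m)          [= 1 / (2 N_e),  N_e = 4 N_m N_f / (N_m + N_f)]

    F_{n+1} = F_n + (1 - F_n) c_n
    H_{n+1} = H_n (1 - c_n)

These recursions are the yardstick against which a rotational breeding scheme
is judged: the scheme's realized mean-F trajectory rises more slowly than the
recursion run with the same breeder counts, and the slowdown percentage is the
headline effectiveness figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "BreederCounts",
    "ExpectationSeries",
    "per_step_increment",
    "expected_F_random_series",
    "expected_H_random_series",
    "mean_step_increase",
    "mean_relative_decrease",
    "rotational_vs_random_comparison",
    "load_breeder_counts",
]


@dataclass(frozen=True)
class BreederCounts:
    """Per-generation effective breeder counts (N_m, N_f).

    ``generation[i]`` is the generation whose breeders produce generation
    ``generation[i] + 1``; counts must be >= 1 wherever used.
    """

    generation: np.ndarray
    n_m: np.ndarray
    n_f: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "generation", np.asarray(self.generation, dtype=int))
        object.__setattr__(self, "n_m", np.asarray(self.n_m, dtype=int))
        object.__setattr__(self, "n_f", np.asarray(self.n_f, dtype=int))
        if np.any(self.n_m < 1) or np.any(self.n_f < 1):
            raise ValueError("breeder counts must be >= 1 in every generation used")

    @classmethod
    def constant(cls, n_m: int, n_f: int, n_generations: int, start: int = 0) -> "BreederCounts":
        gens = np.arange(start, start + n_generations)
        return cls(gens, np.full_like(gens, n_m), np.full_like(gens, n_f))

    @classmethod
    def from_table(cls, table: pd.DataFrame, line: str | None = None) -> "BreederCounts":
        """Build from a tidy table with columns generation, n_m, n_f (+ line)."""
        t = table
        if line is not None:
            t = t[t["line"] == line]
        t = t.dropna(subset=["n_m", "n_f"]).sort_values("generation")
        return cls(t["generation"].to_numpy(), t["n_m"].to_numpy(), t["n_f"].to_numpy())

    def at(self, generation: int) -> tuple[int, int]:
        idx = np.flatnonzero(self.generation == generation)
        if len(idx) == 0:
            raise KeyError(f"no breeder counts recorded for generation {generation}")
        i = idx[0]
        return int(self.n_m[i]), int(self.n_f[i])


def per_step_increment(n_m: int, n_f: int) -> float:
    """c = (N_f + N_m) / (8 N_f N_m), the per-generation drift increment."""
    return (n_f + n_m) / (8.0 * n_f * n_m)


@dataclass
class ExpectationSeries:
    """Expected F or H by generation with per-step increments."""

    kind: str  # "F" or "H"
    table: pd.DataFrame  # columns: generation, value, increment

    def values_by_generation(self) -> pd.Series:
        return self.table.set_index("generation")["value"]

    def value_at(self, generation: int) -> float:
        return float(self.values_by_generation()[generation])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _iterate(kind, start_value, counts, n_steps, start_generation):
    if not 0.0 <= start_value <= 1.0:
        raise ValueError(f"initial {kind} must lie in [0, 1]")
    gens = [start_generation]
    values = [float(start_value)]
    increments = [np.nan]
    v = float(start_value)
    for step in range(n_steps):
        g = start_generation + step
        n_m, n_f = counts.at(g)
        c = per_step_increment(n_m, n_f)
        if kind == "F":
            nxt = v + (1.0 - v) * c
        else:
            nxt = v * (1.0 - c)
        gens.append(g + 1)
        increments.append(nxt - v)
        values.append(nxt)
        v = nxt
    return ExpectationSeries(
        kind=kind,
        table=pd.DataFrame({"generation": gens, "value": values, "increment": increments}),
    )


def expected_F_random_series(
    counts: BreederCounts,
    F0: float = 0.0,
    n_steps: int = 28,
    start_generation: int = 0,
) -> ExpectationSeries:
    """Iterate F_{n+1} = F_n + (1 - F_n) c_n from ``F0``.

    F = 1 is a fixed point; the series is non-decreasing and bounded by 1.
    """
    return _iterate("F", F0, counts, n_steps, start_generation)


def expected_H_random_series(
    counts: BreederCounts,
    H0: float = 0.5,
    n_steps: int = 28,
    start_generation: int = 0,
) -> ExpectationSeries:
    """Iterate H_{n+1} = H_n (1 - c_n) from ``H0`` (H = 0 is absorbing)."""
    return _iterate("H", H0, counts, n_steps, start_generation)


def mean_step_increase(series: ExpectationSeries, span: tuple[int, int] | None = None) -> float:
    """Average per-step increase in percentage points over ``span``."""
    v = series.values_by_generation()
    a, b = span if span is not None else (v.index.min(), v.index.max())
    return (float(v[b]) - float(v[a])) / (b - a) * 100.0


def mean_relative_decrease(series: ExpectationSeries, span: tuple[int, int] | None = None) -> float:
    """Average per-step *relative* decrease in percent over ``span``.

    For the H recursion the relative per-step decrease is exactly c_n, so this
    equals the mean drift increment over the span regardless of H0.
    """
    v = series.values_by_generation()
    a, b = span if span is not None else (v.index.min(), v.index.max())
    vals = v.loc[a:b].to_numpy()
    rel = (vals[:-1] - vals[1:]) / vals[:-1]
    return float(np.mean(rel)) * 100.0


def rotational_vs_random_comparison(rot_rate: float, rand_rate: float) -> float:
    """Slowdown percentage 100 x (1 - rot_rate / rand_rate).

    Both rates must be expressed in the same convention (e.g. percentage
    points of F per generation over a matched span).
    """
    if rand_rate == 0:
        raise ZeroDivisionError("random-mating rate is zero; slowdown undefined")
    return 100.0 * (1.0 - rot_rate / rand_rate)


def load_breeder_counts() -> pd.DataFrame:
    """Per-generation effective breeder counts of the two selection lines.

    The recorded counts of the 28-generation divergent selection colony
    (columns: generation, line, n_phenotyped, n_breeders, n_m, n_f); the last
    two generations have no breeder counts because the colony's next
    generation was not yet formed when the records were compiled.
    """
    with resources.files("rotbreed.data").joinpath("breeder_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
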