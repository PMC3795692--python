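"""Pedigree data model, I/O, validation and relationship/inbreeding machinery.

A pedigree is a directed acyclic parentage graph over uniquely identified
animals, each carrying sex, a 0-based generation index, an optional line label
(e.g. the high- and low-selected lines of a divergent selection colony), an
optional rotational-family index and an optional set of phenotypes.

The central quantities computed here are Wright's numerator (additive)
relationship matrix A, built by the tabular recursion

    A(i, j) = 1/2 [A(j, s_i) + A(j, d_i)]        (j processed before i)
    A(i, i) = 1 + 1/2 A(s_i, d_i)

and the per-animal inbreeding coefficient F_i = A(i, i) - 1, the probability
that the two alleles an animal carries at a locus are identical by descent
relative to the founder generation.  Founders (both parents unknown) are
treated as unrelated and non-inbred, so every F is the *increase* in
autozygosity accumulated inside the recorded pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "AnimalRecord",
    "Pedigree",
    "PedigreeError",
    "PedigreeIssue",
    "RelationshipMatrix",
    "SeriesSummary",
    "load_pedigree",
    "validate_pedigree",
    "additive_relationship",
    "inbreeding_coefficients",
    "series_summary",
    "rate_per_generation",
]

#: Canonical token for an unknown parent.  In CSV/XLSX input both the literal
#: "0" and an empty cell are normalized to this token.
UNKNOWN = "0"

PHENOTYPE_COLUMNS = ("best_distance_m", "body_weight_g", "work_J")

_STANDARD_COLUMNS = (
    "id",
    "sire",
    "dam",
    "sex",
    "generation",
    "line",
    "family",
) + PHENOTYPE_COLUMNS


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad references...)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One pedigree row.  ``sire``/``dam`` are ids or :data:`UNKNOWN`."""

    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    sex: str = "M"
    generation: int = 0
    line: str = ""
    family: int | None = None
    best_distance_m: float = float("nan")
    body_weight_g: float = float("nan")
    work_J: float = float("nan")


@dataclass(frozen=True)
class PedigreeIssue:
    severity: str  # "error" | "warning"
    rule: str
    animals: tuple[str, ...]
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.rule}: {', '.join(self.animals)} {self.message}"


class Pedigree:
    """Ordered collection of animals with resolved parentage.

    Backed by a :class:`pandas.DataFrame` (one row per animal, input order
    preserved).  Construction normalizes unknown parents and types but does
    not validate; call :func:`validate_pedigree` (or use
    :func:`load_pedigree`, which validates hard rules).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in _STANDARD_COLUMNS:
            if col not in df.columns:
                if col in PHENOTYPE_COLUMNS:
                    df[col] = np.nan
                elif col == "line":
                    df[col] = ""
                elif col == "family":
                    df[col] = pd.NA
                else:
                    raise PedigreeError(f"missing required pedigree column {col!r}")
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            s = df[col].astype(object)
            s = s.where(~pd.isna(s), UNKNOWN).astype(str).str.strip()
            s = s.replace({"": UNKNOWN, "0": UNKNOWN, "0.0": UNKNOWN, "nan": UNKNOWN})
            df[col] = s
        df["sex"] = df["sex"].astype(str).str.upper().str.strip()
        df["generation"] = df["generation"].astype(int)
        df["family"] = df["family"].astype("Int64")
        df["line"] = df["line"].fillna("").astype(str)
        for col in PHENOTYPE_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.df = df[list(_STANDARD_COLUMNS)].reset_index(drop=True)
        self._index = {a: i for i, a in enumerate(self.df["id"])}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[AnimalRecord]) -> "Pedigree":
        rows = [vars(r) if not isinstance(r, dict) else r for r in records]
        df = pd.DataFrame(rows, columns=list(_STANDARD_COLUMNS))
        return cls(df)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def founder_mask(self) -> np.ndarray:
        return ((self.df["sire"] == UNKNOWN) & (self.df["dam"] == UNKNOWN)).to_numpy()

    @property
    def founders(self) -> list[str]:
        return list(self.df.loc[self.founder_mask, "id"])

    def counts(self, by: Sequence[str] = ("line", "generation")) -> pd.DataFrame:
        """Number of animals per grouping (default line x generation)."""
        return self.df.groupby(list(by), dropna=False).size().rename("n").reset_index()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional index of each animal's sire/dam (-1 when unknown)."""

        def resolve(col: str) -> np.ndarray:
            out = np.full(len(self.df), -1, dtype=np.int64)
            for i, p in enumerate(self.df[col]):
                if p != UNKNOWN:
                    try:
                        out[i] = self._index[p]
                    except KeyError:
                        raise PedigreeError(
                            f"row {i}: {col} {p!r} does not resolve to any animal id"
                        ) from None
            return out

        return resolve("sire"), resolve("dam")

    def topological_order(self) -> np.ndarray:
        """Positional order with parents before children.

        Stable sort on generation; raises if any parent does not precede its
        child in that order (generation inversion), instructing a re-sort of
        the recorded generations.
        """
        order = np.argsort(self.df["generation"].to_numpy(), kind="stable")
        pos = np.empty(len(order), dtype=np.int64)
        pos[order] = np.arange(len(order))
        sire, dam = self.parent_indices()
        for i in range(len(order)):
            for p in (sire[i], dam[i]):
                if p >= 0 and pos[p] >= pos[i]:
                    raise PedigreeError(
                        f"pedigree is not topologically orderable by generation: "
                        f"parent {self.df['id'][p]!r} (G{self.df['generation'][p]}) does not "
                        f"precede {self.df['id'][i]!r} (G{self.df['generation'][i]}); "
                        "re-sort or correct the recorded generations"
                    )
        return order

    def subset(self, mask) -> "Pedigree":
        """Row subset (parent links to removed animals become founders)."""
        sub = self.df.loc[mask].copy()
        keep = set(sub["id"])
        for col in ("sire", "dam"):
            sub[col] = [p if p in keep else UNKNOWN for p in sub[col]]
        return Pedigree(sub)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_pedigree(path, dialect: Mapping[str, str] | None = None) -> Pedigree:
    """Read a pedigree table from CSV/TSV/XLSX and validate hard rules.

    Parameters
    ----------
    path:
        File path.  ``.xlsx`` goes through :func:`pandas.read_excel`
        (openpyxl), anything else through :func:`pandas.read_csv` with
        separator sniffing for tabs.
    dialect:
        Optional mapping from standard field names (``id``, ``sire``, ``dam``,
        ``sex``, ``generation``, ``line``, ``family``, ``best_distance_m``,
        ``body_weight_g``, ``work_J``) to the column names used in the file.

    Unknown parents may be recorded as ``0`` or an empty cell.  Unresolvable
    parent references, sex-inconsistent parents and duplicate ids are hard
    errors listing the offending animals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        raw = pd.read_csv(path, sep=sep, dtype={0: str})
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    ped = Pedigree(raw)
    errors = [i for i in validate_pedigree(ped) if i.severity == "error"]
    if errors:
        raise PedigreeError(
            "invalid pedigree:\n" + "\n".join(str(e) for e in errors)
        )
    return ped


def validate_pedigree(ped: Pedigree) -> list[PedigreeIssue]:
    """Report structural problems without raising.

    Rules: duplicate ids, orphan (unresolvable) parent references, parent sex
    mismatches, generation inversions, and parentage cycles.
    """
    issues: list[PedigreeIssue] = []
    df = ped.df

    dup = df["id"][df["id"].duplicated(keep=False)]
    if len(dup):
        issues.append(
            PedigreeIssue("error", "duplicate_id", tuple(sorted(set(dup))))
        )
        return issues  # downstream rules assume unique ids

    known = ped._index
    sex = dict(zip(df["id"], df["sex"]))
    gen = dict(zip(df["id"], df["generation"]))
    orphans, sex_mismatch, gen_inversion = [], [], []
    for _, row in df.iterrows():
        for col, want in (("sire", "M"), ("dam", "F")):
            p = row[col]
            if p == UNKNOWN:
                continue
            if p not in known:
                orphans.append((row["id"], p))
            else:
                if sex.get(p) != want:
                    sex_mismatch.append((row["id"], p))
                if gen[p] >= row["generation"]:
                    gen_inversion.append((row["id"], p))
    if orphans:
        issues.append(
            PedigreeIssue(
                "error", "orphan_parent", tuple(a for a, _ in orphans),
                message=f"unresolved parents: {sorted({p for _, p in orphans})}",
            )
        )
    if sex_mismatch:
        issues.append(
            PedigreeIssue(
                "error", "parent_sex_mismatch",
                tuple(sorted({p for _, p in sex_mismatch})),
            )
        )
    if gen_inversion:
        issues.append(
            PedigreeIssue(
                "warning", "generation_inversion",
                tuple(sorted({a for a, _ in gen_inversion})),
            )
        )

    g = nx.DiGraph()
    g.add_nodes_from(df["id"])
    for _, row in df.iterrows():
        for col in ("sire", "dam"):
            if row[col] != UNKNOWN and row[col] in known:
                g.add_edge(row[col], row["id"])
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        issues.append(
            PedigreeIssue("error", "cycle", tuple(sorted({a for a, _ in cycle})))
        )
    return issues


# ---------------------------------------------------------------------------
# Relationship matrix and inbreeding
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A in the pedigree's input row order."""

    ids: list[str]
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    @property
    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular (Emik-Terrill) construction of the additive relationship matrix.

    Founders get diagonal exactly 1; an unknown parent contributes zero
    relationship.  Works in a topological copy of the pedigree and returns
    entries in the original row order, so the result is invariant to input
    row permutations.
    """
    n = len(ped)
    order = ped.topological_order()
    sire, dam = ped.parent_indices()
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    s = np.array([pos[sire[i]] if sire[i] >= 0 else -1 for i in order])
    d = np.array([pos[dam[i]] if dam[i] >= 0 else -1 for i in order])

    A = np.zeros((n, n))
    for k in range(n):
        si, di = s[k], d[k]
        if si >= 0 and di >= 0:
            row = 0.5 * (A[si, :k] + A[di, :k])
            diag = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            row = 0.5 * A[p, :k]
            diag = 1.0
        else:
            row = 0.0
            diag = 1.0
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = diag

    inv = np.ix_(pos, pos)
    return RelationshipMatrix(ids=ped.ids, values=A[inv])


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Per-animal F = A(i,i) - 1 (founders exactly 0)."""
    return additive_relationship(ped).inbreeding


# ---------------------------------------------------------------------------
# Per-generation summaries and rate conventions
# ---------------------------------------------------------------------------


@dataclass
class SeriesSummary:
    """Per-group summary of a named per-animal statistic.

    ``table`` has the group-key columns followed by
    ``n, mean, sd, median, q25, q75, n_missing``.
    """

    statistic: str
    group_by: tuple[str, ...]
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def generation_means(self) -> pd.Series:
        t = self.table.set_index(list(self.group_by))
        return t["mean"]


def series_summary(
    ped: Pedigree,
    statistic,
    group_by: Sequence[str] = ("generation",),
) -> SeriesSummary:
    """Summarize a per-animal value per generation (optionally x sex/line).

    ``statistic`` is a phenotype column name or any array-like aligned with the
    pedigree rows (e.g. the output of :func:`inbreeding_coefficients` reindexed
    to ``ped.ids``).  Missing values are dropped per group with the dropped
    count reported; empty groups are omitted.
    """
    if isinstance(statistic, str):
        name = statistic
        values = ped.df[statistic].to_numpy(dtype=float)
    else:
        values = np.asarray(pd.Series(statistic).reindex(ped.ids)
                            if isinstance(statistic, pd.Series) else statistic,
                            dtype=float)
        name = getattr(statistic, "name", None) or "value"
    work = ped.df[list(group_by)].copy()
    work["_v"] = values
    rows = []
    for keys, grp in work.groupby(list(group_by), dropna=False, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        v = grp["_v"].dropna()
        if len(v) == 0:
            continue
        rows.append(
            dict(zip(group_by, keys))
            | {
                "n": int(len(v)),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(v.median()),
                "q25": float(v.quantile(0.25)),
                "q75": float(v.quantile(0.75)),
                "n_missing": int(grp["_v"].isna().sum()),
            }
        )
    return SeriesSummary(statistic=name, group_by=tuple(group_by), table=pd.DataFrame(rows))


def rate_per_generation(
    series,
    span: tuple[int, int],
    mode: str = "absolute_points",
) -> float:
    """Average per-generation rate of change of a generation-mean series.

    Two reporting conventions coexist in the selection-colony literature and
    both are provided:

    ``absolute_points``
        (mean_last - mean_first) / n_steps * 100 — percentage *points* per
        generation; the convention used for inbreeding-coefficient series.
    ``relative``
        (mean_first - mean_last) / mean_first / n_steps * 100 — percent of the
        starting value lost per generation; the convention used for
        heterozygosity series.

    ``series`` may be a :class:`SeriesSummary` grouped by generation, a mapping
    / :class:`pandas.Series` of generation -> mean, or an
    :class:`~rotbreed.expectations.ExpectationSeries`.
    """
    if isinstance(series, SeriesSummary):
        means = series.generation_means()
    elif hasattr(series, "values_by_generation"):
        means = series.values_by_generation()
    else:
        means = pd.Series(dict(series)) if isinstance(series, Mapping) else pd.Series(series)
    a, b = span
    if a not in means.index or b not in means.index:
        raise KeyError(f"span endpoints {span} not present in series")
    first, last = float(means[a]), float(means[b])
    steps = b - a
    if steps <= 0:
        raise ValueError("span must be increasing")
    if mode == "absolute_points":
        return (last - first) / steps * 100.0
    if mode == "relative":
        if first == 0:
            raise ZeroDivisionError("relative rate undefined for zero starting mean")
        return (first - last) / first / steps * 100.0
    raise ValueError(f"unknown mode {mode!r}")
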