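"""Genotypic classification of conspecific isolates from pairwise ANI.

A set of isolates of one species is partitioned into genotypic groups at an
average-nucleotide-identity (ANI) cut-off ``t``: two isolates belong to the
same group when they are connected through a chain of pairwise ANI values
>= t (single-linkage / connected components).  Single linkage is the only
standard rule under which "classification at an ANI cut-off" is
well-defined for a non-transitive similarity, and it yields a nested ladder
of partitions as the cut-off is swept from below the minimum pairwise ANI
(one group) up to 100% (every isolate its own group, unless genomes are
identical).

The module also enumerates the distinct classification schemes obtained
over a grid of cut-offs, and computes gene-family union counts for group
combinations on a presence/absence matrix, the quantity used to argue that
combining different genotypic groups increases functional repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANITable",
    "GroupingScheme",
    "roman_label",
    "classify_at_threshold",
    "enumerate_schemes",
    "gene_family_union",
]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]


def roman_label(group_index: int, prefix: str = "ANI_") -> str:
    """Display label for a canonical group index (0 -> 'ANI_I', ...)."""
    if group_index < len(_ROMAN):
        return prefix + _ROMAN[group_index]
    return f"{prefix}{group_index + 1}"


@dataclass(frozen=True)
class ANITable:
    """Symmetric pairwise ANI matrix over isolate identifiers.

    Values are percent identities in (0, 100]; the diagonal is exactly 100.
    """

    isolates: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "isolates", tuple(self.isolates))
        n = len(self.isolates)
        if vals.shape != (n, n):
            raise ValueError(f"ANI matrix shape {vals.shape} does not match {n} isolates")
        if len(set(self.isolates)) != n:
            raise ValueError("duplicate isolate identifiers")

    def validate(self, require_complete: bool = True) -> None:
        v = self.values
        if require_complete and np.isnan(v).any():
            missing = int(np.isnan(v).sum() // 2)
            raise ValueError(f"ANI matrix incomplete: {missing} missing pairs")
        finite = v[~np.isnan(v)]
        if np.any((finite <= 0) | (finite > 100)):
            raise ValueError("ANI values must lie in (0, 100]")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("ANI matrix must be symmetric")
        if not np.all(np.diag(v) == 100.0):
            raise ValueError("ANI diagonal must be exactly 100")

    @property
    def n(self) -> int:
        return len(self.isolates)

    def value(self, a: str, b: str) -> float:
        i, j = self.isolates.index(a), self.isolates.index(b)
        return float(self.values[i, j])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle (i<j) pairwise values, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.isolates), columns=list(self.isolates))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ANITable":
        if list(df.index) != list(df.columns):
            raise ValueError("matrix rows and columns must list the same isolates in order")
        table = cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))
        table.validate(require_complete=False)
        return table


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of isolates induced by one ANI cut-off.

    ``assignment`` maps every isolate to a canonical group index: groups are
    numbered in order of their smallest member index in the ANI table, so
    the labelling is deterministic.  ``interval`` records the closed range
    of cut-offs over which this partition holds when the scheme was
    produced by a threshold sweep.
    """

    threshold: float
    assignment: Mapping[str, int]
    n_groups: int
    interval: tuple[float, float] | None = None

    def members(self, group: int) -> tuple[str, ...]:
        return tuple(i for i, g in self.assignment.items() if g == group)

    def groups(self) -> list[tuple[str, ...]]:
        return [self.members(g) for g in range(self.n_groups)]

    def labels(self) -> dict[str, str]:
        """Isolate -> display label ('ANI_I', 'ANI_II', ...)."""
        return {i: roman_label(g) for i, g in self.assignment.items()}

    def same_partition(self, other: "GroupingScheme") -> bool:
        return dict(self.assignment) == dict(other.assignment)


def _components(values: np.ndarray, threshold: float) -> np.ndarray:
    """Connected-component labels of the >=threshold graph via union-find."""
    n = values.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        row = values[i]
        for j in range(i + 1, n):
            if row[j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    # canonical: number groups by smallest member index
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return labels


def classify_at_threshold(ani: ANITable, threshold: float) -> GroupingScheme:
    """Partition isolates at an ANI cut-off.

    Isolates i, j are grouped together iff they are connected by edges
    ANI >= threshold (inclusive, so at t=100 identical genomes remain
    grouped).  Group labels are canonical (ordered by smallest member
    index).

    Raises
    ------
    ValueError
        If the threshold is outside (0, 100] or the matrix has missing
        pairs.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold {threshold} outside (0, 100]")
    ani.validate(require_complete=True)
    labels = _components(ani.values, threshold)
    assignment = {iso: int(g) for iso, g in zip(ani.isolates, labels)}
    return GroupingScheme(
        threshold=float(threshold),
        assignment=assignment,
        n_groups=int(labels.max()) + 1,
    )


def default_grid(ani: ANITable) -> list[float]:
    """All distinct off-diagonal ANI values plus 100, ascending.

    Classifying at each of these cut-offs realises every partition the
    matrix can produce, without arbitrary spacing.
    """
    vals = sorted(set(float(v) for v in ani.off_diagonal()) | {100.0})
    return vals


def enumerate_schemes(
    ani: ANITable, grid: Sequence[float] | None = None
) -> list[GroupingScheme]:
    """Distinct classification schemes over a cut-off grid.

    One scheme is retained per distinct partition encountered; its
    ``interval`` is the [min, max] of grid cut-offs that produced it.
    Because single-linkage partitions coarsen monotonically as the cut-off
    decreases, the returned schemes form a nesting chain (finest last is
    not guaranteed; they are returned in ascending threshold order,
    i.e. coarsest first).
    """
    if grid is None:
        grid = default_grid(ani)
    grid = sorted(set(float(t) for t in grid))
    if not grid:
        raise ValueError("threshold grid is empty")
    schemes: list[GroupingScheme] = []
    for t in grid:
        s = classify_at_threshold(ani, t)
        if schemes and schemes[-1].same_partition(s):
            prev = schemes[-1]
            lo, hi = prev.interval if prev.interval else (prev.threshold, prev.threshold)
            schemes[-1] = GroupingScheme(
                threshold=prev.threshold,
                assignment=prev.assignment,
                n_groups=prev.n_groups,
                interval=(lo, t),
            )
        else:
            schemes.append(
                GroupingScheme(
                    threshold=t,
                    assignment=s.assignment,
                    n_groups=s.n_groups,
                    interval=(t, t),
                )
            )
    return schemes


def gene_family_union(
    gfm: pd.DataFrame,
    member_sets: Iterable[Sequence[str]],
    scheme: GroupingScheme | None = None,
) -> pd.DataFrame:
    """Gene-family union counts for sets of isolates.

    ``gfm`` is a binary presence/absence matrix, isolates as rows and
    gene-family identifiers as columns.  For each member set the count of
    families present in at least one member is reported.  If a grouping
    scheme is supplied, each set is additionally labelled ``within`` (all
    members in one group) or ``cross`` (members spanning groups), which is
    what the within-vs-cross union-count comparison consumes.
    """
    mat = gfm.to_numpy()
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("gene-family matrix must be binary 0/1")
    index = {iso: k for k, iso in enumerate(gfm.index)}
    rows = []
    for members in member_sets:
        members = tuple(members)
        unknown = [m for m in members if m not in index]
        if unknown:
            raise KeyError(f"unknown isolate(s) in gene-family matrix: {unknown}")
        sel = mat[[index[m] for m in members], :]
        count = int(sel.any(axis=0).sum())
        row = {"members": ",".join(members), "n_members": len(members), "union_count": count}
        if scheme is not None:
            groups = {scheme.assignment[m] for m in members}
            row["combination"] = "within" if len(groups) == 1 else "cross"
        rows.append(row)
    return pd.DataFrame(rows)


def scheme_union_summary(
    gfm: pd.DataFrame, scheme: GroupingScheme, max_set_size: int = 3
) -> pd.DataFrame:
    """Mean union count of within-group vs cross-group isolate combinations.

    Enumerates all isolate subsets of size 2..max_set_size and averages the
    union counts separately for same-group and group-spanning combinations.
    """
    isolates = [i for i in gfm.index if i in scheme.assignment]
    sets = [
        c
        for size in range(2, max_set_size + 1)
        for c in combinations(isolates, size)
    ]
    table = gene_family_union(gfm, sets, scheme=scheme)
    return (
        table.groupby("combination")["union_count"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_union_count", "count": "n_combinations"})
    )
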