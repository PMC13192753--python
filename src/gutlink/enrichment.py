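"""Over-representation analysis of gene lists against GMT gene sets.

For each set the overlap with the query is tested with the one-sided
Fisher's exact test (equivalently the upper hypergeometric tail
P(X >= k) with universe size N, set size K, query size n), followed by
Benjamini-Hochberg adjustment across the tested sets.  The universe is the
set of genes that survived the upstream integration filters; sets are
intersected with it, and sets smaller than ``min_size`` within the universe
are excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import scipy.stats

from .covariates import bh_adjust

__all__ = ["GeneSetCollection", "EnrichmentResult", "read_gmt", "write_gmt", "ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics), with an optional source tag."""

    sets: dict  # name -> frozenset of gene ids
    descriptions: dict | None = None
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}
        if self.descriptions is None:
            self.descriptions = {}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected at "
                                 "least name, description and one member")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"malformed GMT line {lineno}: set {name!r} "
                                 "has no members")
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


@dataclass
class EnrichmentResult:
    """Per-set ORA statistics."""

    table: pd.DataFrame  # set, k, K, n, N, pval, qval, flagged, members
    min_size: int
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["members"] = out["members"].map(lambda m: ",".join(sorted(m)))
        out.to_csv(path, sep="\t", index=False)


def ora(
    query,
    universe,
    sets: GeneSetCollection,
    min_size: int = 10,
    alpha: float = 0.1,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    p = P(X >= k) for overlap k, set size K (within the universe), query
    size n, universe size N; BH adjustment across tested sets; flagged at
    adjusted p < ``alpha``.
    """
    universe = set(universe)
    query = set(query)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes absent from the universe: {stray[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < min_size:
            continue
        overlap = in_universe & query
        k = len(overlap)
        # upper tail: P(X >= k) = sf(k - 1)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, sorted(overlap)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "pval", "members"])
    if len(table):
        table = table.sort_values("pval", kind="stable").reset_index(drop=True)
        table["qval"] = bh_adjust(table["pval"].to_numpy())
    else:
        table["qval"] = pd.Series(dtype=float)
    table["flagged"] = table["qval"] < alpha
    table = table[["set", "k", "K", "n", "N", "pval", "qval", "flagged", "members"]]
    return EnrichmentResult(table=table, min_size=min_size, alpha=alpha)
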