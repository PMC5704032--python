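"""Gene-set over-representation analysis.

Affected-gene lists are tested against a GMT gene-set collection with a
right-tail hypergeometric test: with a universe of N genes, a set of K
members, a query of n genes and an overlap of k, the p-value is
P(X >= k) for X ~ Hypergeom(N, K, n).  Benjamini-Hochberg q-values are
reported alongside but ranking is by raw p, with ties broken by
canonicalized set name so top-k lists are stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

logger = logging.getLogger(__name__)


def canonical_pathway_name(name: str) -> str:
    """Canonical form used for all pathway-name comparisons: lowercase
    with whitespace collapsed."""
    return " ".join(name.lower().split())


@dataclass
class GeneSetCollection:
    """Named gene sets plus the default background universe (the union
    of all member genes)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ConfigError(f"gene set {name!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self):
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name <tab> description <tab> member genes)."""
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigError(f"{path}: GMT line needs name, description, genes")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = (descriptions or {}).get(name, "na")
        genes = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_right_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the chance of drawing at
    least k members of a K-gene set in n draws from an N-gene universe
    without replacement.  Computed in log space via the survival
    function for numerical stability."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ConfigError(f"invalid configuration N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ConfigError(f"overlap k={k} impossible for K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's over-representation result for one query."""

    name: str
    K: int
    n: int
    k: int
    p_value: float
    q_value: float
    overlap: tuple[str, ...]


def enrich(
    query_genes: Sequence[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | None = None,
) -> list[EnrichmentRow]:
    """Test every set in the collection against one gene list.

    Query genes outside the universe are dropped (and counted in the
    log).  An empty effective query yields an explicit empty result with
    a warning rather than an exception, so an individual without
    annotated genes does not abort a multi-sample run.
    """
    background = universe if universe is not None else collection.universe
    query = frozenset(query_genes) & background
    dropped = len(set(query_genes)) - len(query)
    if dropped:
        logger.info("%d query gene(s) outside the universe were dropped", dropped)
    if not query:
        logger.warning("empty effective query; returning no enrichment rows")
        return []
    N = len(background)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        members_bg = members & background
        overlap = tuple(sorted(query & members_bg))
        p = hypergeometric_right_tail(N, len(members_bg), n, len(overlap))
        rows.append((name, len(members_bg), n, len(overlap), p, overlap))
    pvals = [r[4] for r in rows]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentRow(name=name, K=K, n=n, k=k, p_value=p, q_value=float(q),
                      overlap=overlap)
        for (name, K, n, k, p, overlap), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p_value, canonical_pathway_name(r.name)))
    return out


def top_k(rows: Sequence[EnrichmentRow], k: int = 20) -> list[str]:
    """Names of the k most over-represented sets, ascending p with ties
    broken by canonicalized name; min(k, #sets) names are returned."""
    ordered = sorted(rows, key=lambda r: (r.p_value, canonical_pathway_name(r.name)))
    return [r.name for r in ordered[:k]]


def enrichment_to_frame(rows: Sequence[EnrichmentRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set": r.name,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "overlap_genes": ";".join(r.overlap),
            }
            for r in rows
        ],
        columns=["set", "K", "n", "k", "p_value", "q_value", "overlap_genes"],
    )
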