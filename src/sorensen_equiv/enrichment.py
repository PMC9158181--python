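"""Over-representation front-end: raw gene lists -> binary enrichment profiles.

The equivalence machinery consumes a terms-by-lists 0/1 incidence matrix.
This module produces one from raw gene lists by classical ORA: for each
term (gene set) the one-sided hypergeometric tail P(X >= a) is computed
for the overlap a between the list and the term's genes within a fixed
gene universe, p-values are corrected for multiplicity across terms
(Bonferroni by default, Benjamini-Hochberg as an option), and a term is
declared enriched when its adjusted p-value falls at or below the cutoff.

Gene sets are read from GMT files (tab-separated: term id, description,
gene ids...); gene lists from plain text, one identifier per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .contingency import EnrichmentProfile

__all__ = [
    "GeneSetCollection",
    "EnrichmentCall",
    "ora_test",
    "profile_from_lists",
    "read_gene_list",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)

_ADJUST = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (term id -> set of gene ids)."""

    sets: dict
    descriptions: dict | None = None

    def __post_init__(self) -> None:
        empty = [term for term, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")
        self.sets = {term: frozenset(genes) for term, genes in self.sets.items()}

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets, descriptions = {}, {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need term, description and "
                    f"at least one gene"
                )
            term, description, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = frozenset(g for g in genes if g)
            descriptions[term] = description
        return cls(sets=sets, descriptions=descriptions)

    def to_gmt(self, path) -> None:
        lines = []
        for term, genes in self.sets.items():
            desc = (self.descriptions or {}).get(term, "")
            lines.append("\t".join([term, desc, *sorted(genes)]))
        Path(path).write_text("\n".join(lines) + "\n")

    def universe(self) -> frozenset:
        """Union of all annotated genes (convenience universe)."""
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentCall:
    """One term's over-representation result for one gene list."""

    term_id: str
    a: int  # list genes annotated in the term
    K: int  # universe genes annotated in the term
    m: int  # list size (after universe intersection)
    N: int  # universe size
    p_raw: float
    p_adj: float
    enriched: bool


def read_gene_list(path) -> set:
    """Plain-text gene list, one identifier per line; blanks skipped."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def ora_test(
    gene_list: Iterable,
    universe: Iterable,
    sets: GeneSetCollection,
    adjust: str = "bonferroni",
    alpha_cutoff: float = 0.05,
) -> list[EnrichmentCall]:
    """One-sided hypergeometric over-representation test for every term.

    ``p_raw = P(X >= a)`` for ``X ~ Hypergeom(N, K, m)``; adjustment is
    applied across all terms of the collection.  Genes outside the
    universe are dropped (with a logged count).
    """
    if adjust not in _ADJUST:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST)}, got {adjust!r}")
    universe = frozenset(universe)
    gene_list = set(gene_list)
    dropped = gene_list - universe
    if dropped:
        logger.warning(
            "dropping %d gene(s) outside the universe: %s%s",
            len(dropped),
            sorted(dropped)[:5],
            "..." if len(dropped) > 5 else "",
        )
    gene_list &= universe
    if not gene_list:
        raise ValueError("gene list is empty after intersection with the universe")
    N, m = len(universe), len(gene_list)

    terms, a_vals, K_vals, p_raw = [], [], [], []
    for term, genes in sets.sets.items():
        annotated = genes & universe
        K = len(annotated)
        a = len(gene_list & annotated)
        # survival function at a-1 is the upper tail P(X >= a)
        p = float(hypergeom.sf(a - 1, N, K, m)) if K > 0 else 1.0
        terms.append(term)
        a_vals.append(a)
        K_vals.append(K)
        p_raw.append(min(p, 1.0))

    p_adj = multipletests(p_raw, method=_ADJUST[adjust])[1] if terms else []
    return [
        EnrichmentCall(
            term_id=t,
            a=a,
            K=K,
            m=m,
            N=N,
            p_raw=pr,
            p_adj=float(pa),
            enriched=bool(pa <= alpha_cutoff),
        )
        for t, a, K, pr, pa in zip(terms, a_vals, K_vals, p_raw, p_adj)
    ]


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def profile_from_lists(
    lists: Mapping[str, Iterable],
    universe: Iterable,
    sets: GeneSetCollection,
    adjust: str = "bonferroni",
    alpha_cutoff: float = 0.05,
) -> EnrichmentProfile:
    """Binary enrichment profile over the collection's terms, one column
    per gene list, each list tested independently with the same settings."""
    if len(lists) < 2:
        raise ValueError("need at least two gene lists to build a profile")
    universe = frozenset(universe)
    term_ids = list(sets.sets)
    columns = {}
    for name, genes in lists.items():
        calls = {
            c.term_id: int(c.enriched)
            for c in ora_test(genes, universe, sets, adjust, alpha_cutoff)
        }
        columns[name] = [calls[t] for t in term_ids]
    return EnrichmentProfile.from_columns(term_ids, columns)
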