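"""Signed circular gene orders and rearrangement comparison.

The comparison set is the 17 genes shared across Basidiomycota mitogenomes
(15 core protein-coding genes plus the two rRNA genes); tRNAs are excluded.
Orders are signed (strand-aware), circular, and canonicalized to start at
cox1 in forward orientation: records deposited in the opposite overall
orientation reflect onto the same canonical order.

Rearrangement between two species is quantified by the breakpoint count: the
number of signed gene adjacencies of one order absent from the other,
computed on the intersection of the two gene sets. A signed adjacency
(a, b) is equivalent to its mirror (-b, -a), so reading the circle in either
direction gives the same adjacency set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .mito_io import COMPARISON_GENES, MitogenomeAnnotation, normalize_gene_name

__all__ = [
    "GeneOrder",
    "OrderComparison",
    "extract_gene_order",
    "breakpoint_distance",
    "order_group",
    "adjacency_set",
]

_COMPARISON_SET = frozenset(COMPARISON_GENES)


class GeneOrderError(ValueError):
    """Raised when an order cannot be extracted or compared."""


@dataclass(frozen=True)
class GeneOrder:
    """Signed circular order of the comparison genes, cox1-first."""

    species: str
    order: tuple[str, ...]  # e.g. ("+cox1", "-nad4", ...)
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        symbols = [g[1:] for g in self.order]
        if len(set(symbols)) != len(symbols):
            raise GeneOrderError(f"{self.species}: duplicated gene in order")
        if len(self.order) + len(self.missing) != len(COMPARISON_GENES):
            raise GeneOrderError(
                f"{self.species}: order + missing must cover the "
                f"{len(COMPARISON_GENES)}-gene set"
            )
        if self.order and self.order[0] != "+cox1":
            raise GeneOrderError(
                f"{self.species}: canonical order must start at +cox1"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g[1:] for g in self.order)


@dataclass(frozen=True)
class OrderComparison:
    species_a: str
    species_b: str
    shared_adjacencies: int
    breakpoints: int

    @property
    def identical(self) -> bool:
        return self.breakpoints == 0


def _negate(signed: str) -> str:
    return ("-" if signed[0] == "+" else "+") + signed[1:]


def canonicalize(signed_order: list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Rotate (and reflect if cox1 is on '-') so the order starts at +cox1."""
    order = list(signed_order)
    try:
        idx = [g[1:] for g in order].index("cox1")
    except ValueError:
        raise GeneOrderError("cox1 absent: cannot canonicalize")
    if order[idx][0] == "-":
        order = [_negate(g) for g in reversed(order)]
        idx = [g[1:] for g in order].index("cox1")
    return tuple(order[idx:] + order[:idx])


def extract_gene_order(annotation: MitogenomeAnnotation) -> GeneOrder:
    """Signed circular order of the 17-gene set, canonicalized to +cox1.

    Genes are ordered by first-exon start around the circle; absent genes go
    to ``missing``. A record without cox1 cannot be canonicalized and raises.
    """
    found: dict[str, tuple[int, str]] = {}
    for g in annotation.genes:
        name = normalize_gene_name(g.name)
        if name in _COMPARISON_SET and name not in found:
            found[name] = (g.exons[0].start, g.strand)
    if "cox1" not in found:
        raise GeneOrderError(
            f"{annotation.species or annotation.genome.id}: cox1 absent, "
            f"gene order cannot be anchored"
        )
    ordered = sorted(found.items(), key=lambda kv: kv[1][0])
    signed = [f"{strand}{name}" for name, (_, strand) in ordered]
    missing = tuple(sorted(_COMPARISON_SET - set(found)))
    return GeneOrder(
        species=annotation.species or annotation.genome.id,
        order=canonicalize(signed),
        missing=missing,
    )


def adjacency_set(order: tuple[str, ...]) -> frozenset[tuple[str, str]]:
    """Signed circular adjacencies, each in canonical mirror form.

    Adjacency (a, b) and its reverse-reading mirror (-b, -a) are the same
    adjacency; the lexicographically smaller tuple represents both.
    """
    n = len(order)
    out = set()
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        mirror = (_negate(b), _negate(a))
        out.add(min((a, b), mirror))
    return frozenset(out)


def _restrict(order: tuple[str, ...], keep: frozenset[str]) -> tuple[str, ...]:
    sub = tuple(g for g in order if g[1:] in keep)
    return canonicalize(sub) if any(g[1:] == "cox1" for g in sub) else sub


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> OrderComparison:
    """Breakpoints between two canonical orders on their shared gene set."""
    shared = a.genes & b.genes
    if len(shared) < 3:
        raise GeneOrderError(
            f"{a.species} vs {b.species}: fewer than 3 shared genes"
        )
    adj_a = adjacency_set(_restrict(a.order, shared))
    adj_b = adjacency_set(_restrict(b.order, shared))
    shared_adj = len(adj_a & adj_b)
    return OrderComparison(
        species_a=a.species,
        species_b=b.species,
        shared_adjacencies=shared_adj,
        breakpoints=len(adj_a) - shared_adj,
    )


def order_group(orders: list[GeneOrder]) -> list[dict]:
    """Partition species by identical canonical order; singletons are unique."""
    if not orders:
        raise GeneOrderError("no orders supplied")
    groups: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for o in orders:
        groups[o.order].append(o.species)
    out = []
    for order, members in sorted(groups.items(),
                                 key=lambda kv: (-len(kv[1]), kv[1][0])):
        out.append(
            {
                "order": order,
                "species": sorted(members),
                "size": len(members),
                "unique": len(members) == 1,
            }
        )
    return out
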