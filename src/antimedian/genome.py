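"""Signed circular genomes represented as perfect matchings of gene ends.

A genome over genes ``1..n`` is modelled as a set of *adjacencies*: unordered
pairs of gene *ends* (each gene has a tail and a head) such that every one of
the ``2n`` ends occurs in exactly one adjacency.  Together with the implicit
edges joining the two ends of each gene, the adjacencies decompose into
disjoint cycles — the circular chromosomes.  A pair joining the two ends of a
single gene is a legal adjacency and yields a one-gene circular chromosome.

Ends are encoded as integers: tail of gene ``g`` is ``2g - 2``, head is
``2g - 1``.  An adjacency is a sorted 2-tuple of end codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Adjacency",
    "Genome",
    "PartialAssembly",
    "GenomeError",
    "ParseError",
    "tail",
    "head",
    "end_gene",
    "end_label",
    "adjacency",
    "validate_genome",
    "chromosomes",
    "adjacencies_from_gene_order",
    "read_gene_orders",
    "write_gene_orders",
]

Adjacency = tuple[int, int]


class GenomeError(ValueError):
    """A candidate adjacency set violates the genome model."""


class ParseError(ValueError):
    """Malformed gene-order text."""


def tail(gene: int) -> int:
    """End code of the tail (5' extremity) of ``gene``."""
    return 2 * gene - 2


def head(gene: int) -> int:
    """End code of the head (3' extremity) of ``gene``."""
    return 2 * gene - 1


def end_gene(end: int) -> int:
    """Gene to which an end code belongs."""
    return end // 2 + 1


def end_label(end: int) -> str:
    """Human-readable label, e.g. ``'3h'`` for the head of gene 3."""
    return f"{end_gene(end)}{'h' if end % 2 else 't'}"


def adjacency(a: int, b: int) -> Adjacency:
    """Canonical (sorted) adjacency from two end codes."""
    if a == b:
        raise GenomeError(f"adjacency joins end {end_label(a)} to itself")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Genome:
    """A signed circular genome: a perfect matching of the 2n gene ends.

    Instances are produced by :func:`validate_genome`,
    :func:`adjacencies_from_gene_order` or the generators in
    :mod:`antimedian.simulate`; direct construction skips validation.
    """

    n: int
    adjacencies: frozenset[Adjacency]
    name: str = field(default="", compare=False)

    def __contains__(self, adj: Adjacency) -> bool:
        return adj in self.adjacencies

    def __iter__(self) -> Iterator[Adjacency]:
        return iter(self.adjacencies)


def validate_genome(candidate: Iterable[Adjacency], n: int, name: str = "") -> Genome:
    """Validate an adjacency set as a genome on genes ``1..n``.

    Checks that there are exactly ``n`` adjacencies, that all end codes are in
    range, and that every gene end occurs exactly once (the perfect-matching
    property).  Raises :class:`GenomeError` naming the first offending end.
    """
    adjs = frozenset(adjacency(a, b) for a, b in candidate)
    seen: set[int] = set()
    for a, b in sorted(adjs):
        for e in (a, b):
            if not 0 <= e < 2 * n:
                raise GenomeError(
                    f"end {end_label(e)} outside gene universe 1..{n}"
                )
            if e in seen:
                raise GenomeError(
                    f"gene end {end_label(e)} used by more than one adjacency"
                )
            seen.add(e)
    if len(adjs) != n:
        raise GenomeError(f"expected {n} adjacencies, got {len(adjs)}")
    # len(seen) == 2n follows: n disjoint pairs over a 2n universe.
    return Genome(n=n, adjacencies=adjs, name=name)


def _matching_map(adjs: Iterable[Adjacency]) -> dict[int, int]:
    m: dict[int, int] = {}
    for a, b in adjs:
        m[a] = b
        m[b] = a
    return m


def chromosomes(g: Genome) -> list[list[int]]:
    """Decompose a genome into canonical circular chromosomes.

    Each chromosome is a list of signed gene identifiers read around the
    circle.  Canonical form: the cycle starts at its smallest gene id, with
    that gene in positive orientation (traversal leaves through its head).
    """
    partner = _matching_map(g.adjacencies)
    visited: set[int] = set()
    out: list[list[int]] = []
    for start in range(1, g.n + 1):
        if start in visited:
            continue
        cycle: list[int] = []
        gene, sign = start, 1
        while True:
            cycle.append(sign * gene)
            visited.add(gene)
            leave = head(gene) if sign > 0 else tail(gene)
            entry = partner[leave]
            gene = end_gene(entry)
            sign = 1 if entry == tail(gene) else -1
            if gene == start:
                break
        out.append(cycle)
    return out


def adjacencies_from_gene_order(
    orders: Sequence[Sequence[int]], name: str = ""
) -> Genome:
    """Build a genome from circular orders of signed genes.

    Consecutive signed genes ``(x, y)`` contribute the adjacency joining the
    trailing end of ``x`` (head if positive, tail if negative) to the leading
    end of ``y`` (tail if positive, head if negative); the last gene of each
    chromosome wraps around to the first.
    """
    genes = [abs(x) for chrom in orders for x in chrom]
    if 0 in genes:
        raise GenomeError("gene identifier 0 is not allowed")
    n = len(genes)
    if len(set(genes)) != n:
        dup = next(x for x in genes if genes.count(x) > 1)
        raise GenomeError(f"gene {dup} appears more than once")
    if set(genes) != set(range(1, n + 1)):
        missing = min(set(range(1, n + 1)) - set(genes))
        raise GenomeError(f"gene identifiers must be 1..{n}; {missing} missing")
    adjs = []
    for chrom in orders:
        for x, y in zip(chrom, chrom[1:] + [chrom[0]]):
            back = head(abs(x)) if x > 0 else tail(abs(x))
            front = tail(abs(y)) if y > 0 else head(abs(y))
            adjs.append(adjacency(back, front))
    return validate_genome(adjs, n, name=name)


# -- gene-order text I/O ------------------------------------------------------
#
# GRIMM/UniMoG-style dialect, circular chromosomes only:
#   >genome_name
#   1 -2 3 )
#   4 5 )
# Each chromosome line is whitespace-separated signed integers terminated by
# ")".  Linear terminators ("$", "|") are rejected: the model is circular.

def read_gene_orders(text: str) -> list[Genome]:
    """Parse gene-order text into a list of named genomes."""
    genomes: list[Genome] = []
    name: str | None = None
    orders: list[list[int]] = []

    def flush(lineno: int) -> None:
        nonlocal name, orders
        if name is None:
            return
        if not orders:
            raise ParseError(f"line {lineno}: genome '{name}' has no chromosomes")
        genomes.append(adjacencies_from_gene_order(orders, name=name))
        name, orders = None, []

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip() or f"genome{len(genomes) + 1}"
            continue
        if name is None:
            raise ParseError(f"line {lineno}: chromosome data before any '>' header")
        tokens = line.split()
        if tokens[-1] in ("$", "|"):
            raise ParseError(
                f"line {lineno}: linear chromosome terminator '{tokens[-1]}' "
                "rejected; this model is circular-only (use ')')"
            )
        if tokens[-1] != ")":
            raise ParseError(f"line {lineno}: chromosome must end with ')'")
        chrom: list[int] = []
        for tok in tokens[:-1]:
            try:
                chrom.append(int(tok))
            except ValueError:
                raise ParseError(f"line {lineno}: unknown token '{tok}'") from None
        if not chrom:
            raise ParseError(f"line {lineno}: empty chromosome")
        orders.append(chrom)
    flush(lineno=-1 if name is None else lineno + 1)
    return genomes


def write_gene_orders(genomes: Iterable[Genome]) -> str:
    """Serialize genomes in canonical form; inverse of :func:`read_gene_orders`."""
    lines: list[str] = []
    for i, g in enumerate(genomes, start=1):
        lines.append(f">{g.name or f'genome{i}'}")
        for chrom in chromosomes(g):
            lines.append(" ".join(str(x) for x in chrom) + " )")
    return "\n".join(lines) + "\n"


@dataclass
class PartialAssembly:
    """A compatible adjacency set under construction, tracking free ends.

    Invariant: ``len(free_ends) == 2n - 2 * len(adjacencies)`` and no two
    adjacencies share a gene end.
    """

    n: int
    adjacencies: set[Adjacency] = field(default_factory=set)
    free_ends: set[int] = field(default_factory=set)

    @classmethod
    def empty(cls, n: int) -> "PartialAssembly":
        return cls(n=n, free_ends=set(range(2 * n)))

    @classmethod
    def from_adjacencies(cls, adjs: Iterable[Adjacency], n: int) -> "PartialAssembly":
        asm = cls.empty(n)
        for a, b in adjs:
            asm.add(adjacency(a, b))
        return asm

    def add(self, adj: Adjacency) -> None:
        a, b = adj
        for e in (a, b):
            if e not in self.free_ends:
                raise GenomeError(f"gene end {end_label(e)} is not free")
        self.free_ends.discard(a)
        self.free_ends.discard(b)
        self.adjacencies.add(adj)

    def is_free(self, adj: Adjacency) -> bool:
        """True if both ends of ``adj`` are unused by the assembly."""
        return adj[0] in self.free_ends and adj[1] in self.free_ends

    def copy(self) -> "PartialAssembly":
        return PartialAssembly(
            n=self.n,
            adjacencies=set(self.adjacencies),
            free_ends=set(self.free_ends),
        )
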