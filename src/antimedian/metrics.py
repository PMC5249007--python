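"""Breakpoint distance, score, and overlap structure of genome trios.

The breakpoint distance between two genomes on the same ``n`` genes is
``d = n - a`` where ``a`` counts the adjacencies they share.  For a candidate
genome ``x`` and a trio ``g1, g2, g3`` the *score* is the normalized distance
sum ``s(x) = (1/n) * sum_i d(x, g_i)``, ranging from 0 (x identical to all
three) to 3 (no adjacency shared with any).

The overlap structure of a trio is summarized by the proportion ``psi`` of
adjacencies common to all three genomes and proportions ``omega_ij`` common to
exactly the pair ``(i, j)`` — the three-way core is excluded from the pairwise
proportions, so psi and the omegas add without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, GenomeError

__all__ = [
    "OverlapProfile",
    "shared_adjacency_count",
    "breakpoint_distance",
    "distance_sum",
    "score",
    "overlap_profile",
]


@dataclass(frozen=True)
class OverlapProfile:
    """Overlap proportions of a genome trio.

    ``psi`` is the three-way shared proportion; ``omega_ij`` the proportion
    shared by exactly genomes i and j.  ``n`` is the gene count the profile
    was measured at (``None`` for purely analytic profiles).
    """

    psi: float = 0.0
    omega12: float = 0.0
    omega13: float = 0.0
    omega23: float = 0.0
    n: int | None = None

    def __post_init__(self) -> None:
        for nm in ("psi", "omega12", "omega13", "omega23"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")
        for a, b in (("omega12", "omega13"), ("omega12", "omega23"),
                     ("omega13", "omega23")):
            tot = self.psi + getattr(self, a) + getattr(self, b)
            if tot > 1.0 + 1e-12:
                raise ValueError(
                    f"psi + {a} + {b} = {tot} exceeds 1: a genome cannot "
                    "share more than all of its adjacencies"
                )

    @property
    def total(self) -> float:
        """psi plus all pairwise-exclusive proportions."""
        return self.psi + self.omega12 + self.omega13 + self.omega23


def _check_same_n(*genomes: Genome) -> int:
    ns = {g.n for g in genomes}
    if len(ns) != 1:
        raise GenomeError(f"genomes have different gene counts: {sorted(ns)}")
    return ns.pop()


def shared_adjacency_count(g: Genome, h: Genome) -> int:
    """Number of adjacencies the two genomes have in common."""
    _check_same_n(g, h)
    return len(g.adjacencies & h.adjacencies)


def breakpoint_distance(g: Genome, h: Genome) -> int:
    """Breakpoint distance ``d = n - a``."""
    n = _check_same_n(g, h)
    return n - shared_adjacency_count(g, h)


def distance_sum(x: Genome, g1: Genome, g2: Genome, g3: Genome) -> int:
    """Sum of breakpoint distances from ``x`` to the trio."""
    _check_same_n(x, g1, g2, g3)
    return sum(breakpoint_distance(x, g) for g in (g1, g2, g3))


def score(x: Genome, g1: Genome, g2: Genome, g3: Genome) -> float:
    """Normalized distance sum ``s(x)`` in ``[0, 3]``.

    Computed as an exact integer sum divided by ``n``, so values are exact
    multiples of ``1/n``.
    """
    n = _check_same_n(x, g1, g2, g3)
    return distance_sum(x, g1, g2, g3) / n


def overlap_profile(g1: Genome, g2: Genome, g3: Genome) -> OverlapProfile:
    """Measure the overlap structure of a trio.

    ``psi = |g1 ∩ g2 ∩ g3| / n`` and ``omega_ij = |g_i ∩ g_j| / n - psi``.
    """
    n = _check_same_n(g1, g2, g3)
    a12 = g1.adjacencies & g2.adjacencies
    core = len(a12 & g3.adjacencies)
    return OverlapProfile(
        psi=core / n,
        omega12=(len(a12) - core) / n,
        omega13=(len(g1.adjacencies & g3.adjacencies) - core) / n,
        omega23=(len(g2.adjacencies & g3.adjacencies) - core) / n,
        n=n,
    )
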