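"""Seeded random genomes and genome trios with an exact overlap structure.

A random genome is a uniform random perfect matching of the ``2n`` gene ends.
:func:`random_trio` builds three genomes whose measured overlap profile equals
the requested ``(psi, omega12, omega13, omega23)`` proportions *exactly* as
counts: one random partial matching supplies the shared blocks, each genome is
completed independently by a uniform matching of its remaining free ends, and
any accidental coincidence a completion introduces (which would inflate a
shared count) is repaired by redrawing that completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Adjacency, Genome, adjacency, validate_genome

__all__ = ["TrioSpec", "GenerationError", "random_genome", "random_trio"]

# Redraws allowed per completion before giving up; only pathologically small
# n with dense overlap blocks ever approach this.
_MAX_REDRAWS = 1000


class GenerationError(RuntimeError):
    """Trio generation failed (infeasible spec or retry budget exhausted)."""


@dataclass(frozen=True)
class TrioSpec:
    """Requested overlap structure for a generated trio.

    Proportions are relative to ``n``; ``n * psi`` and each ``n * omega_ij``
    are rounded to the nearest integer, and for every genome the rounded
    shared counts must fit inside its ``n`` adjacencies.
    """

    n: int
    psi: float = 0.0
    omega12: float = 0.0
    omega13: float = 0.0
    omega23: float = 0.0
    seed: int = 0

    def counts(self) -> tuple[int, int, int, int]:
        """Rounded block sizes (k_psi, k12, k13, k23)."""
        ks = tuple(
            int(round(self.n * p))
            for p in (self.psi, self.omega12, self.omega13, self.omega23)
        )
        if min(ks) < 0:
            raise GenerationError("negative overlap proportion")
        k_psi, k12, k13, k23 = ks
        per_genome = (k_psi + k12 + k13, k_psi + k12 + k23, k_psi + k13 + k23)
        if max(per_genome) > self.n:
            raise GenerationError(
                f"infeasible spec: a genome would need {max(per_genome)} shared "
                f"adjacencies but only has {self.n}"
            )
        if sum(ks) > self.n:
            raise GenerationError(
                f"infeasible spec: {sum(ks)} overlap-block adjacencies exceed n={self.n}"
            )
        return ks


def _pair_up(ends: np.ndarray) -> set[Adjacency]:
    """Pair a shuffled even-length array of end codes into adjacencies."""
    it = iter(ends.tolist())
    return {adjacency(a, b) for a, b in zip(it, it)}


def random_genome(n: int, rng: np.random.Generator, name: str = "") -> Genome:
    """Uniform random perfect matching of the ``2n`` gene ends.

    The resulting genome typically has several circular chromosomes.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ends = rng.permutation(2 * n)
    return validate_genome(_pair_up(ends), n, name=name)


def _completion(
    free: np.ndarray, avoid: set[Adjacency], rng: np.random.Generator
) -> set[Adjacency]:
    """Uniform matching of ``free`` ends avoiding a set of adjacencies.

    Redraws the whole matching on any collision so the accepted matching is
    uniform over collision-free matchings.
    """
    if free.size == 0:
        return set()
    for _ in range(_MAX_REDRAWS):
        comp = _pair_up(rng.permutation(free))
        if not comp & avoid:
            return comp
    raise GenerationError(
        "could not complete a genome without accidental shared adjacencies "
        f"after {_MAX_REDRAWS} redraws (n too small for the requested overlaps)"
    )


def random_trio(spec: TrioSpec) -> tuple[Genome, Genome, Genome]:
    """Generate a trio whose overlap profile equals the spec exactly.

    The three-way block (size ``n*psi``) goes into all three genomes; each
    pairwise block into its two genomes.  Completions are drawn sequentially,
    each avoiding every adjacency already present in another genome, so the
    measured ``psi`` and ``omega_ij`` counts equal the rounded requests with
    no accidental excess.
    """
    n = spec.n
    k_psi, k12, k13, k23 = spec.counts()
    rng = np.random.default_rng(spec.seed)

    ends = rng.permutation(2 * n)
    pos = 0
    blocks: list[set[Adjacency]] = []
    for k in (k_psi, k12, k13, k23):
        blocks.append(_pair_up(ends[pos:pos + 2 * k]))
        pos += 2 * k
    b_psi, b12, b13, b23 = blocks

    shared = (b_psi | b12 | b13, b_psi | b12 | b23, b_psi | b13 | b23)
    completions: list[set[Adjacency]] = []
    # Adjacencies a completion must not reproduce: blocks it is not part of
    # plus completions already drawn.  Its own blocks occupy its non-free ends
    # and cannot collide.
    other_blocks = (b23, b13, b12)
    for i in range(3):
        used = {e for a, b in shared[i] for e in (a, b)}
        free = np.array([e for e in range(2 * n) if e not in used], dtype=np.int64)
        avoid = set(other_blocks[i]).union(*completions) if completions else set(other_blocks[i])
        completions.append(_completion(free, avoid, rng))

    return tuple(
        validate_genome(shared[i] | completions[i], n, name=f"g{i + 1}")
        for i in range(3)
    )
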