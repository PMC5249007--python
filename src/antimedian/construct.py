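"""The anti-median construction: even compatible sampling, maximal third stage.

Given a trio ``g1, g2, g3``, the construction (i) seeds a partial assembly
with *all* adjacencies in the pairwise and three-way overlaps, (ii) samples a
proportion ``theta_1`` of ``n`` adjacencies uniformly from the candidates of
``g1`` (adjacencies whose two ends are still free), (iii) likewise
``theta_2`` from ``g2``, (iv) takes either an explicit ``theta_3`` or — the
maximal sample — *every* remaining two-free-end candidate of ``g3``, and
(v) completes the assembly to a genome by a uniform random matching of the
leftover free ends.  Greedy inclusion in stage (iv) is exactly maximal: the
candidates are pairwise compatible (they come from a matching) and
compatibility with the assembly is per-adjacency.

Random completion shares no adjacencies with the inputs beyond O(1)
coincidences, so the realized proportions determine the score to O(1/n).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .genome import Adjacency, Genome, PartialAssembly, validate_genome
from .metrics import OverlapProfile, overlap_profile, score

__all__ = [
    "MAXIMAL",
    "SampleRequest",
    "ConstructionResult",
    "ReplicateStats",
    "InfeasibleSampleError",
    "sample_stage",
    "random_completion",
    "construct_antimedian",
    "empirical_max_theta3",
]


class _Maximal:
    def __repr__(self) -> str:  # pragma: no cover
        return "MAXIMAL"


#: Sentinel: take every compatible candidate instead of a fixed proportion.
MAXIMAL = _Maximal()


class InfeasibleSampleError(ValueError):
    """A requested sampling proportion exceeds the available candidates."""

    def __init__(self, requested: int, achievable: int, n: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested {requested} adjacencies but only {achievable} "
            f"candidates have two free ends (achievable proportion "
            f"{achievable / n:.4f})"
        )


@dataclass(frozen=True)
class SampleRequest:
    """Sampling proportions for the three stages, relative to ``n``.

    ``theta3`` may be an explicit proportion or :data:`MAXIMAL`.  Explicit
    triples must leave room for the overlap blocks:
    ``theta1 + theta2 + theta3 < 1 - psi - omega12 - omega13 - omega23``.
    """

    theta1: float
    theta2: float
    theta3: float | _Maximal = MAXIMAL

    def __post_init__(self) -> None:
        thetas = [self.theta1, self.theta2]
        if not isinstance(self.theta3, _Maximal):
            thetas.append(self.theta3)
        for t in thetas:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"sampling proportion {t} outside [0, 1]")


@dataclass(frozen=True)
class ConstructionResult:
    """Outcome of one anti-median construction."""

    genome: Genome
    realized_theta: tuple[float, float, float]
    realized_overlaps: OverlapProfile
    score: float
    n_random_completed: int

    @property
    def n(self) -> int:
        return self.genome.n


def sample_stage(
    assembly: PartialAssembly,
    source: Genome,
    theta: float | _Maximal,
    rng: np.random.Generator,
) -> tuple[PartialAssembly, int]:
    """Add adjacencies sampled from ``source`` to a copy of ``assembly``.

    Candidates are the adjacencies of ``source`` with both ends free.  With an
    explicit ``theta``, a uniform random subset of ``round(n * theta)``
    candidates is added (:class:`InfeasibleSampleError` if fewer exist, the
    message reporting the achievable maximum); with :data:`MAXIMAL`, all
    candidates are added.  Returns the enlarged assembly and the count added.
    """
    if source.n != assembly.n:
        raise ValueError("source genome and assembly have different n")
    candidates = sorted(a for a in source.adjacencies if assembly.is_free(a))
    if isinstance(theta, _Maximal):
        chosen = candidates
    else:
        k = int(round(assembly.n * theta))
        if k > len(candidates):
            raise InfeasibleSampleError(k, len(candidates), assembly.n)
        idx = rng.choice(len(candidates), size=k, replace=False) if k else []
        chosen = [candidates[i] for i in sorted(idx)]
    out = assembly.copy()
    for adj in chosen:
        out.add(adj)
    return out, len(chosen)


def random_completion(
    assembly: PartialAssembly, rng: np.random.Generator
) -> Genome:
    """Pair all free ends by a uniform random matching and return the genome.

    The assembly's adjacencies are preserved verbatim; with zero free ends
    this is the identity.
    """
    free = np.fromiter(assembly.free_ends, dtype=np.int64, count=len(assembly.free_ends))
    adjs: set[Adjacency] = set(assembly.adjacencies)
    if free.size:
        shuffled = rng.permutation(free).tolist()
        it = iter(shuffled)
        for a, b in zip(it, it):
            adjs.add((a, b) if a < b else (b, a))
    return validate_genome(adjs, assembly.n)


def construct_antimedian(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    request: SampleRequest,
    rng: np.random.Generator,
) -> ConstructionResult:
    """Run the full construction pipeline on a trio.

    Overlap adjacencies are always all included; sampling order is fixed
    g1 -> g2 -> g3 (permute the genome arguments for symmetry experiments).
    """
    n = g1.n
    overlaps = (
        (g1.adjacencies & g2.adjacencies)
        | (g1.adjacencies & g3.adjacencies)
        | (g2.adjacencies & g3.adjacencies)
    )
    assembly = PartialAssembly.from_adjacencies(overlaps, n)
    counts: list[int] = []
    for source, theta in ((g1, request.theta1), (g2, request.theta2),
                          (g3, request.theta3)):
        assembly, added = sample_stage(assembly, source, theta, rng)
        counts.append(added)
    n_completed = len(assembly.free_ends) // 2
    x = random_completion(assembly, rng)
    return ConstructionResult(
        genome=x,
        realized_theta=tuple(c / n for c in counts),
        realized_overlaps=overlap_profile(g1, g2, g3),
        score=score(x, g1, g2, g3),
        n_random_completed=n_completed,
    )


@dataclass(frozen=True)
class ReplicateStats:
    """Mean and standard deviation of realized theta3 and score."""

    theta3_mean: float
    theta3_sd: float
    score_mean: float
    score_sd: float
    replicates: int


def empirical_max_theta3(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    theta1: float,
    theta2: float,
    rng: np.random.Generator,
    replicates: int = 3,
) -> ReplicateStats:
    """Realized maximal theta3 statistics over seeded construction replicates.

    Each replicate reruns :func:`construct_antimedian` with ``theta3 =
    MAXIMAL`` and fresh sampling randomness; the realized third proportion is
    the empirical counterpart of the closed-form maximum in
    :mod:`antimedian.analytic`.
    """
    request = SampleRequest(theta1, theta2, MAXIMAL)
    t3s, scores = [], []
    for _ in range(replicates):
        res = construct_antimedian(g1, g2, g3, request, rng)
        t3s.append(res.realized_theta[2])
        scores.append(res.score)
    t3s_a, scores_a = np.asarray(t3s), np.asarray(scores)
    sd = (lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0)
    return ReplicateStats(
        theta3_mean=float(t3s_a.mean()),
        theta3_sd=sd(t3s_a),
        score_mean=float(scores_a.mean()),
        score_sd=sd(scores_a),
        replicates=replicates,
    )
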