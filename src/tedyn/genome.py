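"""Single-genome primitives: fitness, transposition, excision, recombination.

A :class:`Genome` is a haploid individual's TE occupancy over an ordered grid
of ``n_chromosomes x loci_per_chromosome`` insertion sites plus the state of
an unlinked excision-rate modifier allele.  Occupancy is stored sparsely as a
sorted array of occupied site indices; site ``s`` lies on chromosome
``s // loci_per_chromosome`` at within-chromosome position
``s % loci_per_chromosome``.

The population engine (:mod:`tedyn.engine`) reuses the ``_*_sites`` helpers
defined here, so the per-individual semantics of both code paths are
identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimParams

__all__ = ["Genome", "fitness", "transpose", "excise", "recombine"]


def fitness(n, a: float, b: float):
    """Relative fitness of an individual carrying ``n`` TE copies.

    ``w(n) = exp(-a n - b n^2 / 2)`` with ``a`` the per-copy selection
    strength and ``b`` the strength of synergistic epistasis between copies.
    Strictly decreasing in ``n`` whenever ``a > 0`` or ``b > 0``; an empty
    genome has fitness 1.  Accepts scalars or arrays of copy numbers.
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("copy number n must be >= 0")
    if a < 0 or b < 0:
        raise ValueError("selection parameters a and b must be >= 0")
    w = np.exp(-a * n - 0.5 * b * n.astype(float) ** 2)
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class Genome:
    """TE occupancy of one haploid individual.

    ``sites`` is a sorted ``int64`` array of occupied site indices, treated
    as immutable; all operations return new genomes.
    """

    n_chromosomes: int
    loci_per_chromosome: int
    sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    modifier: bool = False

    def __post_init__(self) -> None:
        sites = np.asarray(self.sites, dtype=np.int64)
        if sites.size and (sites.min() < 0 or sites.max() >= self.n_sites):
            raise ValueError("site index out of range")
        if np.unique(sites).size != sites.size:
            raise ValueError("duplicate occupied sites")
        object.__setattr__(self, "sites", np.sort(sites))

    @property
    def n_sites(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def copy_number(self) -> int:
        return int(self.sites.size)

    @property
    def occupancy(self) -> np.ndarray:
        """Dense boolean presence/absence vector over all sites."""
        occ = np.zeros(self.n_sites, dtype=bool)
        occ[self.sites] = True
        return occ

    @classmethod
    def from_occupancy(cls, occ: np.ndarray, n_chromosomes: int,
                       loci_per_chromosome: int, modifier: bool = False) -> "Genome":
        occ = np.asarray(occ, dtype=bool).ravel()
        if occ.size != n_chromosomes * loci_per_chromosome:
            raise ValueError("occupancy length does not match the layout")
        return cls(n_chromosomes, loci_per_chromosome,
                   np.flatnonzero(occ), modifier)

    def same_layout(self, other: "Genome") -> bool:
        return (self.n_chromosomes == other.n_chromosomes
                and self.loci_per_chromosome == other.loci_per_chromosome)


# ---------------------------------------------------------------------------
# sparse per-individual kernels (shared with the population engine)

def _transpose_sites(sites: np.ndarray, n_sites: int, n_new: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Insert ``n_new`` copies, each at a site uniform among current empties.

    Sequential insertion into distinct uniform empty sites is equivalent to
    sampling ``n_new`` empties without replacement.  If fewer empty sites
    remain than pending insertions, the excess insertions are skipped.
    Occupancy is sparse in practice, so empties are rejection-sampled; the
    explicit enumeration path covers near-saturated genomes.
    """
    if n_new <= 0:
        return sites
    n_empty = n_sites - sites.size
    n_new = min(n_new, n_empty)
    if n_new == 0:
        return sites
    if 4 * (sites.size + n_new) < n_sites:
        out = sites
        for _ in range(n_new):
            while True:
                cand = int(rng.integers(n_sites))
                k = np.searchsorted(out, cand)
                if k >= out.size or out[k] != cand:
                    break
            out = np.insert(out, k, cand)
        return out
    mask = np.ones(n_sites, dtype=bool)
    mask[sites] = False
    new = rng.choice(np.flatnonzero(mask), size=n_new, replace=False)
    return np.sort(np.concatenate([sites, new]))


def _excise_sites(sites: np.ndarray, n_lost: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Remove ``n_lost`` copies chosen uniformly without replacement."""
    if n_lost <= 0:
        return sites
    if n_lost == 1:
        return np.delete(sites, int(rng.integers(sites.size)))
    keep = np.ones(sites.size, dtype=bool)
    keep[rng.choice(sites.size, size=n_lost, replace=False)] = False
    return sites[keep]


def _chromosome_origin_masks(n_genomes: int, n_chromosomes: int,
                             loci_per_chromosome: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Parent-of-origin mask for a batch of recombinant offspring.

    Each chromosome receives a Poisson(1) number of crossovers with positions
    uniform over the ``loci_per_chromosome - 1`` inter-locus boundaries.
    Poisson thinning makes the crossover counts at the boundaries independent
    Poisson(1/(L-1)) variables, of which only the parity matters, so each
    boundary switches the active parent independently with probability
    ``(1 - exp(-2/(L-1))) / 2``.  The starting parent of every chromosome is
    chosen fairly.  Returns a boolean array of shape
    ``(n_genomes, n_chromosomes * loci_per_chromosome)``; True marks loci
    copied from the second parent.
    """
    L = loci_per_chromosome
    start = rng.integers(0, 2, size=(n_genomes, n_chromosomes, 1), dtype=np.uint8)
    if L > 1:
        n_cross = rng.poisson(1.0, size=n_genomes * n_chromosomes)
        total = int(n_cross.sum())
        flips = np.zeros((n_genomes * n_chromosomes, L - 1), dtype=np.uint8)
        if total:
            rows = np.repeat(np.arange(n_genomes * n_chromosomes), n_cross)
            cols = rng.integers(0, L - 1, size=total)
            # two crossovers at one boundary cancel: only parity matters
            np.bitwise_xor.at(flips, (rows, cols), 1)
        parity = np.cumsum(flips, axis=1, dtype=np.uint8) & 1
        parity = parity.reshape(n_genomes, n_chromosomes, L - 1)
        origin = np.concatenate([start, (start + parity) & 1], axis=2)
    else:
        origin = start
    return origin.reshape(n_genomes, n_chromosomes * L).astype(bool)


def _recombine_batch(occ1: np.ndarray, occ2: np.ndarray, n_chromosomes: int,
                     loci_per_chromosome: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Recombine paired rows of two dense occupancy matrices."""
    origin = _chromosome_origin_masks(occ1.shape[0], n_chromosomes,
                                      loci_per_chromosome, rng)
    return np.where(origin, occ2, occ1)


# ---------------------------------------------------------------------------
# public single-genome operations

def transpose(genome: Genome, u_eff: float, rng: np.random.Generator) -> Genome:
    """Transposition: each copy spawns a new copy with probability ``u_eff``.

    New copies land at sites drawn uniformly from the currently empty sites;
    existing copies are never removed here.  Insertions that find no empty
    site are skipped.
    """
    if not 0.0 <= u_eff <= 1.0:
        raise ValueError("u_eff must be a probability in [0, 1]")
    gains = int(rng.binomial(genome.copy_number, u_eff))
    sites = _transpose_sites(genome.sites, genome.n_sites, gains, rng)
    return Genome(genome.n_chromosomes, genome.loci_per_chromosome,
                  sites, genome.modifier)


def excise(genome: Genome, params: SimParams, rng: np.random.Generator) -> Genome:
    """Excision: each copy is removed independently with probability v_eff.

    ``v_eff = v + modifier_delta_v`` for modifier carriers, ``v`` otherwise;
    the modifier state itself is untouched.
    """
    v_eff = params.v_modifier if genome.modifier else params.v
    losses = int(rng.binomial(genome.copy_number, v_eff))
    sites = _excise_sites(genome.sites, losses, rng)
    return Genome(genome.n_chromosomes, genome.loci_per_chromosome,
                  sites, genome.modifier)


def recombine(parent1: Genome, parent2: Genome, params: SimParams,
              rng: np.random.Generator) -> Genome:
    """Fuse two haploids and return one recombinant haploid offspring.

    Each chromosome gets on average one crossover (Poisson-distributed, see
    :func:`_chromosome_origin_masks`); the unlinked modifier allele is
    inherited from either parent with probability 1/2, independently of all
    chromosomes.
    """
    if not parent1.same_layout(parent2):
        raise ValueError("parents must share the genome layout")
    occ = _recombine_batch(parent1.occupancy[None, :], parent2.occupancy[None, :],
                           parent1.n_chromosomes, parent1.loci_per_chromosome,
                           rng)[0]
    modifier = bool(parent2.modifier if rng.integers(0, 2) else parent1.modifier)
    return Genome.from_occupancy(occ, parent1.n_chromosomes,
                                 parent1.loci_per_chromosome, modifier)
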