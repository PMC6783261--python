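"""Forward-time Wright–Fisher engine for TE copy-number evolution.

One generation is: fitness-proportional selection of parents, reproduction
(clonal copying, or — in sexual generations — fusion of two distinct parents
followed by recombination) with transposition acting on the newly formed
offspring, then excision on every offspring.  Population size is constant.

The population stores each individual's occupied sites as a sorted index
array (loads are ~50 copies out of 3200 sites, so sparse storage plus
copy-on-write mutation is far cheaper than dense per-generation copies).
Mutating individuals are routed through the same per-genome kernels used by
:mod:`tedyn.genome`, so single-genome and population semantics coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (Genome, _excise_sites, _recombine_batch, _transpose_sites,
                     fitness)
from .params import SimParams

__all__ = ["Population", "Trajectory", "found_population", "select_parents",
           "step_generation", "run_replicate", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class Population:
    """A constant-size deme of haploid genomes.

    ``sites[i]`` is individual *i*'s sorted array of occupied site indices
    (treated as immutable: operations replace entries rather than editing
    them in place, so offspring of a common parent may alias one array),
    ``modifier[i]`` its modifier-allele state.
    """

    params: SimParams
    sites: List[np.ndarray]
    modifier: np.ndarray
    generation: int = 0
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.sites) != self.params.pop_size:
            raise ValueError("population size must equal params.pop_size")
        self.modifier = np.asarray(self.modifier, dtype=bool)
        if self.counts is None:
            self.counts = np.fromiter((s.size for s in self.sites),
                                      count=self.size, dtype=np.int64)

    @property
    def size(self) -> int:
        return len(self.sites)

    @property
    def copy_numbers(self) -> np.ndarray:
        return self.counts

    @property
    def mean_load(self) -> float:
        return float(self.copy_numbers.mean())

    @property
    def var_load(self) -> float:
        return float(self.copy_numbers.var())

    @property
    def modifier_freq(self) -> float:
        return float(self.modifier.mean())

    def occupancy_matrix(self) -> np.ndarray:
        """Dense (N, n_sites) boolean occupancy matrix."""
        occ = np.zeros((self.size, self.params.n_sites), dtype=bool)
        counts = self.copy_numbers
        rows = np.repeat(np.arange(self.size), counts)
        if rows.size:
            occ[rows, np.concatenate(self.sites)] = True
        return occ

    def genome(self, i: int) -> Genome:
        """Individual *i* as a :class:`~tedyn.genome.Genome`."""
        return Genome(self.params.n_chromosomes, self.params.loci_per_chromosome,
                      self.sites[i], bool(self.modifier[i]))


@dataclass(frozen=True)
class Trajectory:
    """Per-replicate time series of TE load and modifier frequency."""

    replicate_id: int
    sampled_generations: np.ndarray
    mean_load: np.ndarray
    var_load: np.ndarray
    modifier_freq: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.sampled_generations), len(self.mean_load),
                   len(self.var_load), len(self.modifier_freq)}
        if len(lengths) != 1:
            raise ValueError("trajectory series must have equal lengths")
        for name in ("sampled_generations", "mean_load", "var_load",
                     "modifier_freq"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.mean_load < 0):
            raise ValueError("mean_load must be >= 0")
        if np.any((self.modifier_freq < 0) | (self.modifier_freq > 1)):
            raise ValueError("modifier_freq must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sampled_generations)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": self.replicate_id,
            "generation": self.sampled_generations,
            "mean_load": self.mean_load,
            "var_load": self.var_load,
            "modifier_freq": self.modifier_freq,
        })


# ---------------------------------------------------------------------------
# vectorised mutation passes (sparse: only individuals with events change)

def _transposition_pass(sites: List[np.ndarray], counts: np.ndarray,
                        u_eff: float, n_sites: int,
                        rng: np.random.Generator) -> None:
    if u_eff <= 0.0:
        return
    gains = rng.binomial(counts, u_eff)
    for i in np.flatnonzero(gains):
        sites[i] = _transpose_sites(sites[i], n_sites, int(gains[i]), rng)
        counts[i] = sites[i].size


def _excision_pass(sites: List[np.ndarray], counts: np.ndarray,
                   modifier: np.ndarray, params: SimParams,
                   rng: np.random.Generator) -> None:
    if params.v <= 0.0 and params.modifier_delta_v <= 0.0:
        return
    v_eff = np.where(modifier, params.v_modifier, params.v)
    losses = rng.binomial(counts, v_eff)
    for i in np.flatnonzero(losses):
        sites[i] = _excise_sites(sites[i], int(losses[i]), rng)
        counts[i] = sites[i].size


def found_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Found a clonal deme from one random genome, then run the burn-in.

    The founder receives ``founder_copies`` TEs placed uniformly without
    replacement among all sites and populates the whole deme clonally.  The
    modifier allele is then assigned to each individual independently with
    probability ``modifier_init_freq``, and ``burn_in_generations`` cycles of
    transposition followed by excision are applied to every individual
    separately, with no selection and no resampling, to build standing
    variation.
    """
    founder = np.sort(rng.choice(params.n_sites, size=params.founder_copies,
                                 replace=False)).astype(np.int64)
    sites = [founder] * params.pop_size
    modifier = rng.random(params.pop_size) < params.modifier_init_freq
    counts = np.full(params.pop_size, params.founder_copies, dtype=np.int64)
    for _ in range(params.burn_in_generations):
        _transposition_pass(sites, counts, params.u, params.n_sites, rng)
        _excision_pass(sites, counts, modifier, params, rng)
    return Population(params, sites, modifier, generation=0, counts=counts)


def select_parents(pop: Population, params: SimParams, count: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` parent indices, probability proportional to fitness."""
    w = fitness(pop.copy_numbers, params.a, params.b)
    return _draw_parents(w, count, rng)


def _draw_parents(w: np.ndarray, count: int,
                  rng: np.random.Generator) -> np.ndarray:
    return rng.choice(w.size, size=count, replace=True, p=w / w.sum())


def step_generation(pop: Population, params: SimParams,
                    rng: np.random.Generator) -> Population:
    """Advance the population by one generation of selection + reproduction.

    The new generation is sexual when its index is a positive multiple of
    ``sex_interval``; then every offspring arises from fusion and
    recombination of two distinct fitness-sampled parents and transposition
    acts on the recombinant at rate ``u_meiotic``.  Otherwise offspring are
    clonal copies mutated at rate ``u``.  Excision concludes the generation.
    """
    N = pop.size
    new_gen = pop.generation + 1
    sexual = params.sex_interval > 0 and new_gen % params.sex_interval == 0
    w = fitness(pop.copy_numbers, params.a, params.b)

    if sexual:
        p1 = _draw_parents(w, N, rng)
        p2 = _draw_parents(w, N, rng)
        clash = p1 == p2
        while clash.any():
            p2[clash] = _draw_parents(w, int(clash.sum()), rng)
            clash = p1 == p2
        occ = pop.occupancy_matrix()
        off = _recombine_batch(occ[p1], occ[p2], params.n_chromosomes,
                               params.loci_per_chromosome, rng)
        counts = off.sum(axis=1).astype(np.int64)
        flat = np.nonzero(off)[1].astype(np.int64)
        sites = list(np.split(flat, np.cumsum(counts)[:-1]))
        from_p2 = rng.integers(0, 2, size=N).astype(bool)
        modifier = np.where(from_p2, pop.modifier[p2], pop.modifier[p1])
        u_eff = params.u_meiotic_effective
    else:
        parents = _draw_parents(w, N, rng)
        sites = [pop.sites[p] for p in parents]
        counts = pop.copy_numbers[parents].copy()
        modifier = pop.modifier[parents].copy()
        u_eff = params.u

    _transposition_pass(sites, counts, u_eff, params.n_sites, rng)
    _excision_pass(sites, counts, modifier, params, rng)
    return Population(params, sites, modifier, generation=new_gen, counts=counts)


def run_replicate(params: SimParams, rng: np.random.Generator,
                  replicate_id: int = 0) -> Trajectory:
    """Found, burn in, and run one replicate for ``total_generations``.

    Mean load, load variance and modifier frequency are recorded at
    generation 0 (right after the burn-in) and every ``sample_every``
    generations thereafter.
    """
    pop = found_population(params, rng)
    gens, mean_load, var_load, mod_freq = [], [], [], []

    def record(p: Population) -> None:
        gens.append(p.generation)
        n = p.copy_numbers
        mean_load.append(float(n.mean()))
        var_load.append(float(n.var()))
        mod_freq.append(p.modifier_freq)

    record(pop)
    for g in range(1, params.total_generations + 1):
        pop = step_generation(pop, params, rng)
        if g % params.sample_every == 0:
            record(pop)
    return Trajectory(replicate_id, np.array(gens), np.array(mean_load),
                      np.array(var_load), np.array(mod_freq))


def run_experiment(params: SimParams,
                   progress: bool = False) -> List[Trajectory]:
    """Run ``n_replicates`` independent replicates.

    Per-replicate RNG streams are spawned from ``SeedSequence(params.seed)``
    in replicate order, so results are reproducible bit-for-bit from the
    master seed alone.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_replicates)
    out = []
    for rep, child in enumerate(children):
        traj = run_replicate(params, np.random.default_rng(child), rep)
        if progress:
            logger.info("replicate %d/%d: final mean load %.2f, "
                        "modifier freq %.3f", rep + 1, params.n_replicates,
                        traj.mean_load[-1], traj.modifier_freq[-1])
        out.append(traj)
    return out
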