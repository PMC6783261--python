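"""Parameterisation of a TE copy-number simulation scenario.

A scenario is a haploid Wright–Fisher population of constant size in which
every individual carries a genome of ``n_chromosomes x loci_per_chromosome``
potential TE insertion sites, an optional schedule of sexual generations
(fusion of two haploids followed by recombination), and an optional unlinked
modifier allele that raises the per-copy excision rate genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

__all__ = ["SimParams", "PRESETS", "yeast_modifier_preset", "no_modifier_preset"]


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of one simulation scenario.

    Parameters
    ----------
    pop_size
        Number of haploid individuals N (constant deme size).
    n_chromosomes, loci_per_chromosome
        Genome layout; every locus is a potential TE insertion target.
    founder_copies
        TE copies placed uniformly at random in the founder genome.
    burn_in_generations
        Transposition/excision cycles applied per individual, without
        selection or resampling, after clonal expansion of the founder.
    total_generations
        Generations of selection + reproduction after the burn-in.
    sex_interval
        Generations between sexual episodes; every generation whose index is
        a positive multiple of ``sex_interval`` is sexual.  0 means a wholly
        asexual run.
    u
        Transposition probability per TE copy per (clonal) reproduction
        event.
    u_meiotic
        Transposition probability per copy applied to recombinant offspring
        in sexual generations; ``None`` means "same as u".
    v
        Baseline excision probability per copy per generation.
    a, b
        Selection strength per copy and pairwise synergistic-epistasis
        strength of the log-fitness function w(n) = exp(-a n - b n^2 / 2).
    modifier_init_freq
        Probability that a founding individual carries the excision-rate
        modifier allele.
    modifier_delta_v
        Additive increase of the per-copy excision rate in modifier
        carriers.  The modifier has no direct fitness effect.
    n_replicates
        Independent replicate runs per experiment.
    sample_every
        Generations between load/modifier-frequency measurements.
    seed
        Master seed; per-replicate streams are spawned from it.
    """

    pop_size: int = 100_000
    n_chromosomes: int = 16
    loci_per_chromosome: int = 200
    founder_copies: int = 50
    burn_in_generations: int = 20
    total_generations: int = 990
    sex_interval: int = 90
    u: float = 1e-5
    u_meiotic: Optional[float] = None
    v: float = 1e-6
    a: float = 1e-3
    b: float = 0.0
    modifier_init_freq: float = 0.0
    modifier_delta_v: float = 0.0
    n_replicates: int = 10
    sample_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.sex_interval > 0 and self.pop_size < 2:
            raise ValueError("sexual reproduction needs pop_size >= 2")
        for name in ("n_chromosomes", "loci_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("founder_copies", "burn_in_generations", "total_generations",
                     "sex_interval", "n_replicates", "sample_every"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.founder_copies > self.n_sites:
            raise ValueError(
                f"founder_copies={self.founder_copies} exceeds the "
                f"{self.n_sites} available insertion sites")
        for name in ("u", "v", "modifier_init_freq", "modifier_delta_v"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must be a probability in [0, 1]")
        if self.u_meiotic is not None and not 0.0 <= self.u_meiotic <= 1.0:
            raise ValueError("u_meiotic must be a probability in [0, 1]")
        if self.v + self.modifier_delta_v > 1.0:
            raise ValueError("v + modifier_delta_v must not exceed 1")
        if self.a < 0 or self.b < 0:
            raise ValueError("selection parameters a and b must be >= 0")

    @property
    def n_sites(self) -> int:
        """Total number of potential insertion sites per genome."""
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def u_meiotic_effective(self) -> float:
        return self.u if self.u_meiotic is None else self.u_meiotic

    @property
    def v_modifier(self) -> float:
        """Per-copy excision rate of a modifier carrier."""
        return self.v + self.modifier_delta_v

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimParams fields: {sorted(unknown)}")
        return cls(**d)


def yeast_modifier_preset(**overrides) -> SimParams:
    """Yeast-like scenario with the excision-rate modifier segregating.

    Baseline transposition/excision rates are of the order measured for Ty
    elements (u ~ 1e-5 per copy per generation, spontaneous excision much
    rarer).  The modifier effect ``modifier_delta_v = 1.5e-4`` together with
    selection ``a = 1e-3`` per copy is calibrated so that asexual
    populations lose ~9 of the 50 ancestral copies by generation 1000
    (direct excision in modifier carriers plus the selection response on the
    excision-generated load variance), while in sexual populations
    recombination keeps the modifier rare and the loss below ~2–3 copies.
    The initial modifier frequency 0.1 represents a standing defense variant
    common enough that its hitchhiking sweep is not drift-dominated at
    desk-scale population sizes; see docs/methods.md for the calibration
    analysis.
    """
    base = dict(
        u=1e-5,
        v=1e-6,
        a=1e-3,
        b=0.0,
        modifier_init_freq=0.1,
        modifier_delta_v=1.5e-4,
    )
    base.update(overrides)
    return SimParams(**base)


def no_modifier_preset(**overrides) -> SimParams:
    """Scenario without the modifier, for the pure sex-vs-asex contrast.

    Selection can only remove TE copies where individuals differ in copy
    number, so this preset uses balanced transposition and excision rates
    (u = v = 3e-4) high enough to maintain segregating insertion/excision
    variants, and per-copy selection a = 5e-3 strong enough that the
    recombination-driven difference in selection efficacy between the two
    reproductive modes dominates replicate-to-replicate drift.
    """
    base = dict(
        u=3e-4,
        v=3e-4,
        a=5e-3,
        b=0.0,
        modifier_init_freq=0.0,
        modifier_delta_v=0.0,
    )
    base.update(overrides)
    return SimParams(**base)


PRESETS = {
    "yeast-modifier": yeast_modifier_preset,
    "no-modifier": no_modifier_preset,
}
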