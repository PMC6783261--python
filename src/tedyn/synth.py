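"""Synthetic inputs mirroring the experimental-evolution study design.

Generates, with a known latent truth, the two table types the analysis
stages consume:

* per-sample TE count tables for 4 sexual + 4 asexual strains sampled at
  generation 0 and every 90 generations up to 990, with coverage-dependent
  detection (each truly present copy is detected with probability
  ``1 - exp(-k * coverage)``), and
* TE insertion-call tables with a programmed full-length / solo-LTR /
  truncated composition reported redundantly by 1–6 detectors with
  breakpoint jitter.

Every generator returns the observable table together with the latent truth
so pipeline estimates can be tested against what was programmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import DEFAULT_FAMILIES, FamilyLengthTable, SOLO_LTR_RANGE, \
    FULL_LENGTH_WINDOW

__all__ = ["GeneratorConfig", "gen_count_table", "gen_insertion_records",
           "gen_read_count_series"]

#: detection probability is 0.5 at exactly one-fold coverage
DEFAULT_DETECTION_K = float(np.log(2.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and effect sizes of the emulated experiment.

    The defaults reproduce the study conditions: four strains per
    reproductive mode, twelve sampling points (generation 0 and every 90
    generations to 990), 50 ancestral full-length TEs of which a fraction
    24/50 is detectable by the insertion callers, and a linear decline of
    -0.009 copies/generation in asexual strains (none in sexual strains) —
    about nine copies lost per 1000 generations.
    """

    n_sexual_strains: int = 4
    n_asexual_strains: int = 4
    time_points: Tuple[int, ...] = tuple(range(0, 991, 90))
    ancestral_full_length: int = 50
    detectable_fraction: float = 24 / 50
    asexual_slope: float = -0.009   # copies per generation
    sexual_slope: float = 0.0
    coverage_range: Tuple[float, float] = (5.0, 50.0)
    detection_k: float = DEFAULT_DETECTION_K
    noise_sd: float = 0.5           # copies, strain-level latent noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sexual_strains < 0 or self.n_asexual_strains < 0:
            raise ValueError("strain counts must be >= 0")
        tp = tuple(self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(t < 0 for t in tp):
            raise ValueError("time points must be non-negative")
        if not 0.0 < self.detectable_fraction <= 1.0:
            raise ValueError("detectable_fraction must be in (0, 1]")
        if self.coverage_range[0] <= 0 or \
                self.coverage_range[1] < self.coverage_range[0]:
            raise ValueError("coverage_range must be 0 < low <= high")
        if self.detection_k <= 0:
            raise ValueError("detection_k must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "time_points", tp)

    def detection_probability(self, coverage) -> np.ndarray:
        """Per-copy detection probability ``1 - exp(-k * coverage)``."""
        return 1.0 - np.exp(-self.detection_k * np.asarray(coverage, float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["time_points"] = list(self.time_points)
        d["coverage_range"] = list(self.coverage_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "time_points" in d:
            d["time_points"] = tuple(d["time_points"])
        if "coverage_range" in d:
            d["coverage_range"] = tuple(d["coverage_range"])
        return cls(**d)


def _strain_names(config: GeneratorConfig) -> List[Tuple[str, str]]:
    sexual = [(f"S{i+1}", "sexual") for i in range(config.n_sexual_strains)]
    asexual = [(f"A{i+1}", "asexual") for i in range(config.n_asexual_strains)]
    return sexual + asexual


def gen_count_table(config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample TE counts with coverage-dependent detection.

    For each strain and time point the latent true copy number is the
    mode-specific linear trend from ``ancestral_full_length`` plus Gaussian
    noise (rounded, floored at 0); the observed count is
    ``Binomial(true, 1 - exp(-k * coverage))`` with the sample's mean
    coverage drawn uniformly from ``coverage_range``.

    Returns ``(table, truth)``: the observable CountTable with columns
    ``strain, mode, generation, coverage, count``, and a truth table that
    additionally carries ``true_count``, ``p_detect`` and the programmed
    slope per row.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for strain, mode in _strain_names(config):
        slope = (config.asexual_slope if mode == "asexual"
                 else config.sexual_slope)
        for gen in config.time_points:
            latent = (config.ancestral_full_length + slope * gen
                      + rng.normal(0.0, config.noise_sd))
            true_count = max(int(round(latent)), 0)
            coverage = rng.uniform(*config.coverage_range)
            p_det = float(config.detection_probability(coverage))
            observed = int(rng.binomial(true_count, p_det))
            rows.append((strain, mode, gen, coverage, observed,
                         true_count, p_det, slope))
    truth = pd.DataFrame(rows, columns=["strain", "mode", "generation",
                                        "coverage", "count", "true_count",
                                        "p_detect", "true_slope"])
    table = truth[["strain", "mode", "generation", "coverage", "count"]].copy()
    return table, truth


def gen_insertion_records(n_full: int, n_solo: int, n_truncated: int,
                          detectors_per_insertion: Optional[Sequence[int]] = None,
                          position_jitter: int = 50,
                          seed: int = 0,
                          families: FamilyLengthTable = DEFAULT_FAMILIES,
                          strain: str = "A1", generation: int = 0,
                          detector_pool: Optional[Sequence[str]] = None,
                          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Insertion-call table with known class composition and redundancy.

    Places ``n_full + n_solo + n_truncated`` distinct insertions on 16
    chromosomes, spaced far enough apart that distinct insertions can never
    be linked by breakpoint clustering, draws each call length inside its
    class window (full: canonical ± 500 bp; solo LTR: 220–420 bp; truncated:
    strictly between), and reports every insertion by 1–6 detectors (or the
    per-insertion counts given) with start-position jitter of at most
    ``position_jitter`` bp.

    Returns ``(records, truth)``: the redundant BED-like call table, and one
    row per unique insertion with its programmed class.
    """
    if min(n_full, n_solo, n_truncated) < 0:
        raise ValueError("class counts must be >= 0")
    if position_jitter < 0:
        raise ValueError("position_jitter must be >= 0")
    rng = np.random.default_rng(seed)
    if detector_pool is None:
        detector_pool = ("ngs_te_mapper", "relocate", "retroseq", "temp",
                         "popoolationte", "te_locate")
    fams = list(families.lengths)
    n_total = n_full + n_solo + n_truncated
    classes = (["full_length"] * n_full + ["solo_LTR"] * n_solo
               + ["truncated"] * n_truncated)
    if detectors_per_insertion is None:
        n_det = rng.integers(1, len(detector_pool) + 1, size=n_total)
    else:
        n_det = np.asarray(detectors_per_insertion, dtype=int)
        if n_det.size != n_total:
            raise ValueError("detectors_per_insertion must have one entry "
                             "per insertion")
        if n_det.size and (n_det.min() < 1 or
                           n_det.max() > len(detector_pool)):
            raise ValueError("detector counts must be between 1 and the "
                             "detector pool size")

    # spacing guarantees that jittered calls of distinct insertions are
    # always farther apart than any sensible clustering tolerance
    spacing = 10_000 + 4 * position_jitter
    truth_rows, call_rows = [], []
    for i in range(n_total):
        cls = classes[i]
        family = fams[int(rng.integers(len(fams)))]
        canonical = families.canonical(family)
        if cls == "full_length":
            length = int(canonical + rng.integers(-FULL_LENGTH_WINDOW,
                                                  FULL_LENGTH_WINDOW + 1))
        elif cls == "solo_LTR":
            length = int(rng.integers(SOLO_LTR_RANGE[0],
                                      SOLO_LTR_RANGE[1] + 1))
        else:
            length = int(rng.integers(SOLO_LTR_RANGE[1] + 1,
                                      canonical - FULL_LENGTH_WINDOW))
        chrom = f"chr{i % 16 + 1:02d}"
        start = 10_000 + (i // 16) * spacing
        truth_rows.append((strain, generation, chrom, start, family, cls))
        detectors = rng.choice(detector_pool, size=int(n_det[i]),
                               replace=False)
        for det in detectors:
            jitter = int(rng.integers(-position_jitter, position_jitter + 1)) \
                if position_jitter else 0
            s = max(start + jitter, 0)
            call_rows.append((strain, generation, chrom, s, s + length,
                              family, det))
    truth = pd.DataFrame(truth_rows, columns=["strain", "generation", "chrom",
                                              "start", "family", "te_class"])
    records = pd.DataFrame(call_rows, columns=["strain", "generation", "chrom",
                                               "start", "end", "family",
                                               "detector"])
    records = records.sample(frac=1.0, random_state=int(rng.integers(2**31))
                             ).reset_index(drop=True)
    return records, truth


def gen_read_count_series(config: GeneratorConfig,
                          initial_fraction: float = 0.03,
                          asexual_total_reduction: float = 0.235,
                          total_reads: int = 3_000_000,
                          rng: Optional[np.random.Generator] = None
                          ) -> pd.DataFrame:
    """TE-mapped/total-mapped read counts with a programmed load decline.

    Emulates the overall-load measurements: the fraction of reads mapping to
    TEs declines linearly in asexual strains by ``asexual_total_reduction``
    (relative, default 23.5%) from the first to the last time point, and is
    constant in sexual strains.  Counts are exact (rounded) so that
    ``te_read_fraction`` recovers the programmed series to within rounding.

    Columns: ``strain, mode, generation, te_reads, total_reads,
    true_fraction`` where ``true_fraction = te_reads / total_reads``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    span = config.time_points[-1] - config.time_points[0]
    rows = []
    for strain, mode in _strain_names(config):
        for gen in config.time_points:
            rel = (gen - config.time_points[0]) / span if span else 0.0
            reduction = asexual_total_reduction if mode == "asexual" else 0.0
            frac = initial_fraction * (1.0 - reduction * rel)
            te_reads = int(round(frac * total_reads))
            rows.append((strain, mode, gen, te_reads, total_reads,
                         te_reads / total_reads))
    return pd.DataFrame(rows, columns=["strain", "mode", "generation",
                                       "te_reads", "total_reads",
                                       "true_fraction"])
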