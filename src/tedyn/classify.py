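"""Post-processing of TE insertion call tables.

Insertion callers report the same physical insertion with slightly different
breakpoints, so calls from multiple detectors are merged into unique
insertions by single-linkage clustering along each chromosome.  Unique
insertions are then classified by length into full-length elements, solo
LTRs, truncated elements, or "other", using per-family canonical lengths of
the yeast Ty1–Ty5 LTR retrotransposons.  The module also provides the
read-fraction TE-load statistic and the low-coverage sample filter.

All coordinates are 0-based half-open; call tables are BED-like DataFrames
with at least the columns ``chrom, start, end, family, detector, strain,
generation`` (``length = end - start``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["FamilyLengthTable", "DEFAULT_FAMILIES", "deduplicate",
           "classify_by_length", "classify_table", "te_read_fraction",
           "coverage_filter", "CLASS_TAGS"]

logger = logging.getLogger(__name__)

CLASS_TAGS = ("full_length", "solo_LTR", "truncated", "other")

#: Solo-LTR length window in bp (a lone LTR left by LTR-LTR recombination).
SOLO_LTR_RANGE = (220, 420)
#: A call within this many bp of the family's canonical length is full-length.
FULL_LENGTH_WINDOW = 500


@dataclass(frozen=True)
class FamilyLengthTable:
    """Canonical full-length and LTR lengths (bp) per TE family.

    Defaults cover the *S. cerevisiae* Ty1–Ty5 families; the table is
    editable, e.g. ``FamilyLengthTable({"Ty1": (5918, 334)})`` or loaded
    from a two-column TSV via :meth:`from_tsv`.
    """

    lengths: Mapping[str, Tuple[int, int]]  # family -> (canonical, ltr)

    def __post_init__(self) -> None:
        for fam, (canonical, ltr) in self.lengths.items():
            if canonical <= 2 * ltr:
                raise ValueError(
                    f"{fam}: canonical length {canonical} must exceed twice "
                    f"the LTR length {ltr}")

    def canonical(self, family: str) -> Optional[int]:
        entry = self.lengths.get(family)
        return None if entry is None else entry[0]

    def __contains__(self, family: str) -> bool:
        return family in self.lengths

    @classmethod
    def from_tsv(cls, path) -> "FamilyLengthTable":
        df = pd.read_csv(path, sep="\t")
        return cls({r.family: (int(r.canonical_bp), int(r.ltr_bp))
                    for r in df.itertuples()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f, c, l) for f, (c, l) in self.lengths.items()],
            columns=["family", "canonical_bp", "ltr_bp"])


DEFAULT_FAMILIES = FamilyLengthTable({
    "Ty1": (5918, 334),
    "Ty2": (5959, 332),
    "Ty3": (5351, 340),
    "Ty4": (6223, 371),
    "Ty5": (5375, 251),
})


def _require_columns(records: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = set(cols) - set(records.columns)
    if missing:
        raise ValueError(f"record table misses columns: {sorted(missing)}")


def deduplicate(records: pd.DataFrame,
                position_tolerance: int = 100) -> pd.DataFrame:
    """Merge calls of the same insertion made by different detectors.

    Within each (strain, generation, chromosome, family) group, calls whose
    start positions differ by at most ``position_tolerance`` bp are chained
    into one cluster (single-linkage along the chromosome) and counted as a
    single insertion.  The merged record keeps the median start position,
    the median length, and the sorted list of contributing detectors; a
    ``dedup_group`` id is assigned per input row order of the first member.

    Idempotent: re-deduplicating an already merged table changes nothing.
    """
    _require_columns(records, ("chrom", "start", "end", "family",
                               "detector", "strain", "generation"))
    if len(records) == 0:
        out = records.copy()
        out["n_detectors"] = pd.Series(dtype=int)
        out["dedup_group"] = pd.Series(dtype=int)
        return out

    df = records.copy().reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    if (df["length"] <= 0).any():
        raise ValueError("all records must have end > start")
    df = df.sort_values(["strain", "generation", "chrom", "family", "start"],
                        kind="stable")
    key = df[["strain", "generation", "chrom", "family"]]
    new_group = (key != key.shift()).any(axis=1)
    gap = df["start"].diff() > position_tolerance
    df["dedup_group"] = (new_group | gap).cumsum() - 1

    def _merge(g: pd.DataFrame) -> pd.Series:
        start = int(np.median(g["start"]))
        length = int(np.median(g["length"]))
        detectors = sorted(set(d for ds in g["detector"]
                               for d in str(ds).split(",")))
        return pd.Series({
            "strain": g["strain"].iloc[0],
            "generation": g["generation"].iloc[0],
            "chrom": g["chrom"].iloc[0],
            "family": g["family"].iloc[0],
            "start": start,
            "end": start + length,
            "detector": ",".join(detectors),
            "n_detectors": len(detectors),
        })

    merged = (df.groupby("dedup_group", sort=True)
                .apply(_merge, include_groups=False)
                .reset_index())
    return merged[["strain", "generation", "chrom", "start", "end", "family",
                   "detector", "n_detectors", "dedup_group"]]


def classify_by_length(length: int, family: str,
                       families: FamilyLengthTable = DEFAULT_FAMILIES) -> str:
    """Length-based class tag of one insertion call.

    ``full_length`` if the length is within ``FULL_LENGTH_WINDOW`` bp of the
    family's canonical length (internal sequence plus both LTRs);
    ``solo_LTR`` for lengths in the 220–420 bp window left by LTR-LTR
    recombination; ``truncated`` for lengths between the solo-LTR ceiling
    and the full-length floor; ``other`` otherwise.  Calls of unknown
    families can never be full-length or truncated; a warning is logged when
    an unknown family's length would only be classifiable against a
    canonical length.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    canonical = families.canonical(family)
    lo, hi = SOLO_LTR_RANGE
    if canonical is not None and abs(length - canonical) <= FULL_LENGTH_WINDOW:
        return "full_length"
    if lo <= length <= hi:
        return "solo_LTR"
    if canonical is not None and hi < length < canonical - FULL_LENGTH_WINDOW:
        return "truncated"
    if canonical is None and length > hi:
        logger.warning("family %r not in the length table; call of length %d "
                       "classified as 'other'", family, length)
    return "other"


def classify_table(records: pd.DataFrame,
                   families: FamilyLengthTable = DEFAULT_FAMILIES
                   ) -> pd.DataFrame:
    """Append a ``te_class`` column classifying every record by length."""
    _require_columns(records, ("start", "end", "family"))
    out = records.copy()
    lengths = out["end"] - out["start"]
    out["te_class"] = [classify_by_length(int(l), f, families)
                       for l, f in zip(lengths, out["family"])]
    return out


def te_read_fraction(te_mapped_reads: int, total_mapped_reads: int) -> float:
    """Fraction of mapped reads that map to TEs (overall TE-load measure)."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if te_mapped_reads < 0 or te_mapped_reads > total_mapped_reads:
        raise ValueError("te_mapped_reads must lie in [0, total_mapped_reads]")
    return te_mapped_reads / total_mapped_reads


def coverage_filter(samples: pd.DataFrame,
                    min_coverage: float = 1.0,
                    coverage_col: str = "coverage") -> pd.DataFrame:
    """Drop samples whose mean per-base coverage is below ``min_coverage``.

    The boundary is strict: exactly one-fold coverage is retained.  Each
    exclusion is logged.
    """
    _require_columns(samples, (coverage_col,))
    if (samples[coverage_col] < 0).any():
        raise ValueError("coverage must be >= 0")
    keep = samples[coverage_col] >= min_coverage
    for _, row in samples[~keep].iterrows():
        ident = row.get("strain", "<sample>")
        gen = row.get("generation", "?")
        logger.info("excluding sample %s (generation %s): coverage %.3f < %g",
                    ident, gen, row[coverage_col], min_coverage)
    return samples[keep].reset_index(drop=True)
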