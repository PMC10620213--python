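"""Proband-specific inheritance classification.

Classifies each QC-passing biallelic (variant, trio) pair into one of
four mutually exclusive categories:

* ``de_novo`` — proband carries an alternate allele absent from both
  parents (autosomes and pseudoautosomal X; also hemizygous male X when
  the mother is homozygous reference).
* ``autosomal_recessive`` — proband homozygous alternate on an
  autosome with both parents heterozygous carriers.
* ``x_linked_male`` — male proband hemizygous alternate outside the
  pseudoautosomal regions with a carrier (heterozygous) mother and a
  reference father.
* ``other`` — any remaining pattern; not proband-specific.

Two pruning steps accompany classification: multiallelic sites are
removed outright, and apparent de novo variants recurring in more than
a configurable number of probands (default 2) are removed as likely
artifacts.  Compound heterozygotes are out of scope, and phase is
ignored throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .models import AnnotatedVariant, InheritanceCall, TrioPedigree, normalize_chrom

log = logging.getLogger(__name__)

__all__ = [
    "ParRegions",
    "GRCH38_PAR",
    "classify_inheritance",
    "prune_recurrent_denovo",
    "drop_multiallelic",
    "DropCounter",
]


@dataclass(frozen=True)
class ParRegions:
    """Pseudoautosomal intervals on X, 1-based inclusive, sorted."""

    intervals: tuple[tuple[int, int], ...]
    build_label: str = "GRCh38"

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if start > end:
                raise ValueError(f"interval ({start}, {end}) has start > end")
            if start <= prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.intervals)

    @classmethod
    def from_bed(cls, path, build_label: str = "custom") -> "ParRegions":
        """Load intervals from a 3-column BED file (0-based half-open on
        disk, converted to 1-based inclusive in memory)."""
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: BED line needs >= 3 columns: {line!r}")
                start0, end0 = int(fields[1]), int(fields[2])
                intervals.append((start0 + 1, end0))
        return cls(intervals=tuple(sorted(intervals)), build_label=build_label)


#: GRCh38 pseudoautosomal regions on X (standard build coordinates).
GRCH38_PAR = ParRegions(
    intervals=((10_001, 2_781_479), (155_701_383, 156_030_895)),
    build_label="GRCh38",
)


def classify_inheritance(
    variant: AnnotatedVariant,
    trio: Optional[TrioPedigree] = None,
    par: ParRegions = GRCH38_PAR,
) -> InheritanceCall:
    """Classify one biallelic (variant, trio) pair.

    The decision table is exhaustive: every genotype/chromosome/sex
    combination maps to exactly one category, with X de novo in males
    (mother non-carrier) taking the ``de_novo`` label so that categories
    stay disjoint from ``x_linked_male`` (carrier mother).  Multiallelic
    input is an error — it must be pruned first.
    """
    if variant.is_multiallelic:
        raise ValueError(
            f"{variant.chrom}:{variant.pos} is multiallelic; run drop_multiallelic first"
        )
    trio = trio or variant.trio
    chrom = normalize_chrom(variant.chrom)
    p = variant.call(trio.proband_id)
    fa = variant.call(trio.father_id)
    mo = variant.call(trio.mother_id)

    def other() -> InheritanceCall:
        return InheritanceCall("other", trio.proband_id, variant.key)

    if p.is_missing or fa.is_missing or mo.is_missing:
        return other()

    x_nonpar = chrom == "X" and not par.contains(variant.pos)
    autosomal_like = chrom not in ("X", "Y", "MT") or (chrom == "X" and not x_nonpar)

    if autosomal_like:
        if p.n_alt >= 1 and fa.is_hom_ref and mo.is_hom_ref:
            return InheritanceCall("de_novo", trio.proband_id, variant.key)
        if chrom != "X" and p.is_hom_alt and fa.is_het and mo.is_het:
            return InheritanceCall("autosomal_recessive", trio.proband_id, variant.key)
        return other()

    if x_nonpar and trio.proband_sex == "male":
        # proband "1" and "1/1" both count as hemizygous alternate;
        # the father must be hemizygous reference ("0" or "0/0").
        if p.is_hemi_alt and fa.is_hemi_ref:
            if mo.is_het:
                return InheritanceCall("x_linked_male", trio.proband_id, variant.key)
            if mo.is_hom_ref:
                return InheritanceCall("de_novo", trio.proband_id, variant.key)
    return other()


def prune_recurrent_denovo(
    calls: list[InheritanceCall], max_probands: int = 2
) -> list[InheritanceCall]:
    """Remove de novo variants recurring in too many probands.

    A variant key called de novo in strictly more than ``max_probands``
    distinct probands is almost certainly a calling artifact; all of its
    de novo occurrences are removed.  Other categories are untouched.
    """
    probands_per_key: dict[tuple, set[str]] = {}
    for c in calls:
        if c.category == "de_novo":
            probands_per_key.setdefault(c.variant_key, set()).add(c.proband_id)
    recurrent = {k for k, ps in probands_per_key.items() if len(ps) > max_probands}
    if recurrent:
        log.info("pruning %d recurrent de novo variant key(s)", len(recurrent))
    return [
        c for c in calls
        if not (c.category == "de_novo" and c.variant_key in recurrent)
    ]


class DropCounter:
    """Mutable drop counter filled while a pruning stream is consumed."""

    def __init__(self) -> None:
        self.n_dropped = 0


def drop_multiallelic(
    variants: Iterable[AnnotatedVariant],
    counter: Optional[DropCounter] = None,
) -> Iterator[AnnotatedVariant]:
    """Drop (and count) variants carrying more than one alternate allele."""
    for v in variants:
        if v.is_multiallelic:
            if counter is not None:
                counter.n_dropped += 1
            continue
        yield v
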