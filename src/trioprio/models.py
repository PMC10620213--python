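"""Core domain types shared across the pipeline.

The unit of analysis throughout the package is a *proband-specific
genotype*: one variant site joined with one parent-offspring trio.  A
site that appears in a joint multi-sample VCF therefore expands into one
record per trio, each carrying exactly the three sample calls of that
trio.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "TrioPedigree",
    "SampleCall",
    "ScorePanel",
    "AnnotatedVariant",
    "InheritanceCall",
    "ClassificationRecord",
    "Detection",
    "DetectionSet",
    "GeneList",
    "VariantKey",
    "normalize_chrom",
    "chrom_sort_key",
]

#: (chrom, pos, ref, alt) — the variant identity used for all joins.
VariantKey = tuple[str, int, str, str]

_SEXES = ("male", "female")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to its prefix-free form (``chr7`` -> ``7``)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c in ("M", "MT") else c


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing 1..22 numerically before X, Y, MT, then others."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25}
    return (special.get(c, 26), c)


@dataclass(frozen=True)
class TrioPedigree:
    """One affected child and its two sequenced parents."""

    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    proband_sex: str  # "male" | "female"
    affected: bool = True

    def __post_init__(self) -> None:
        ids = (self.proband_id, self.father_id, self.mother_id)
        if len(set(ids)) != 3 or not all(ids):
            raise ValueError(f"trio member ids must be distinct and non-empty: {ids}")
        if self.proband_sex not in _SEXES:
            raise ValueError(
                f"proband {self.proband_id!r}: sex must be known "
                f"(male/female), got {self.proband_sex!r}"
            )

    @property
    def member_ids(self) -> tuple[str, str, str]:
        return (self.proband_id, self.father_id, self.mother_id)


@dataclass(frozen=True)
class SampleCall:
    """A single sample's genotype call at one site.

    ``genotype`` is a tuple of allele indices — length 2 for diploid
    calls, length 1 for hemizygous calls (male X outside the PAR) — or
    ``None`` for a missing call.  Missing is distinct from homozygous
    reference.  Phase is ignored: ``0|1`` and ``0/1`` are the same call.
    """

    genotype: Optional[tuple[int, ...]]
    depth: Optional[int] = None
    gq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype is not None:
            if not 1 <= len(self.genotype) <= 2 or any(a < 0 for a in self.genotype):
                raise ValueError(f"bad genotype {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.gq is not None and self.gq < 0:
            raise ValueError("GQ must be non-negative")

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def n_alt(self) -> int:
        """Number of non-reference alleles carried (0 if missing)."""
        return 0 if self.genotype is None else sum(1 for a in self.genotype if a > 0)

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype is not None and all(a == 0 for a in self.genotype)

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and sorted(self.genotype) == [0, 1]

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype is not None and len(self.genotype) == 2 and all(
            a > 0 for a in self.genotype
        )

    @property
    def is_hemi_alt(self) -> bool:
        """Hemizygous (or homozygous — caller dialects differ) altered call."""
        return self.genotype is not None and all(a > 0 for a in self.genotype)

    @property
    def is_hemi_ref(self) -> bool:
        return self.is_hom_ref


_UNIT = ("sift", "polyphen2", "revel", "mcap", "loftool")


@dataclass(frozen=True)
class ScorePanel:
    """In-silico deleteriousness scores for one variant.

    All scores are consumed from upstream annotation, never computed.
    ``None`` means the tool did not score the variant; absent is never
    conflated with zero.  ``loftool`` is a gene-level loss-of-function
    intolerance percentile.
    """

    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    mcap: Optional[float] = None
    mpc: Optional[float] = None
    loftool: Optional[float] = None

    def __post_init__(self) -> None:
        for name in _UNIT:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("cadd_phred", "mpc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be non-negative")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant site joined with one trio.

    ``calls`` holds exactly the three trio members' calls, keyed by
    sample id.  ``pos`` follows the VCF convention (1-based).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    trio: TrioPedigree
    calls: dict[str, SampleCall]
    filter_flags: frozenset[str] = frozenset()
    pop_af: Optional[float] = None
    consequence: Optional[str] = None
    gene: Optional[str] = None
    scores: ScorePanel = field(default_factory=ScorePanel)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")
        if not self.alts:
            raise ValueError("at least one alt allele required")
        if set(self.calls) != set(self.trio.member_ids):
            raise ValueError(
                "calls must cover exactly the three trio members "
                f"({sorted(self.trio.member_ids)}), got {sorted(self.calls)}"
            )
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af={self.pop_af} outside [0, 1]")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, ",".join(self.alts))

    def call(self, sample_id: str) -> SampleCall:
        return self.calls[sample_id]


@dataclass(frozen=True)
class InheritanceCall:
    """Proband-specific genotype category for one (variant, proband) pair."""

    category: str  # de_novo | autosomal_recessive | x_linked_male | other
    proband_id: str
    variant_key: VariantKey

    CATEGORIES = ("de_novo", "autosomal_recessive", "x_linked_male", "other")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown inheritance category {self.category!r}")

    @property
    def is_proband_specific(self) -> bool:
        return self.category != "other"


ACMG_CLASSES = ("P", "LP", "VUS", "LB", "B")


@dataclass(frozen=True)
class ClassificationRecord:
    """One external classifier call (e.g. InterVar or TAPES output row)."""

    variant_key: VariantKey
    proband_id: str
    tool: str
    classification: str  # P | LP | VUS | LB | B
    criteria: frozenset[str] = frozenset()
    classification_after_ps2: Optional[str] = None

    def __post_init__(self) -> None:
        if self.classification not in ACMG_CLASSES:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class Detection:
    """A (variant, proband) detection as used by all evaluation statistics."""

    variant_key: VariantKey
    proband_id: str
    gene: str
    inheritance: str
    consequence_group: str = ""
    detection_class: str = ""

    @property
    def pair_key(self) -> tuple[VariantKey, str]:
        return (self.variant_key, self.proband_id)


@dataclass(frozen=True)
class DetectionSet:
    """A named set of detections produced by one tool or tool combination."""

    tool: str
    members: frozenset[Detection]

    @classmethod
    def from_iterable(cls, tool: str, members) -> "DetectionSet":
        return cls(tool=tool, members=frozenset(members))

    def pair_keys(self) -> set[tuple[VariantKey, str]]:
        return {m.pair_key for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneList:
    """Reference gene list (SFARI-style), optionally with confidence scores 1-3."""

    symbols: frozenset[str]
    scores: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene list must be non-empty")
        extra = set(self.scores) - set(self.symbols)
        if extra:
            raise ValueError(f"scores for non-member symbols: {sorted(extra)[:5]}")
        bad = {g: s for g, s in self.scores.items() if s not in (1, 2, 3)}
        if bad:
            raise ValueError(f"scores must be in {{1,2,3}}: {bad}")

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.symbols

    def subset_with_score(self, score: int) -> "GeneList":
        syms = frozenset(g for g, s in self.scores.items() if s == score)
        return GeneList(symbols=syms, scores={g: score for g in syms})
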