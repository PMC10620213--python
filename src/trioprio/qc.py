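"""Variant-level quality-control cascade.

Each (variant, trio) pair is tested against a fixed-order rule cascade:
missing genotype, low read depth, low genotype quality, caller filter
flags (VQSR tranches / ExcessHet), and common population allele
frequency.  Depth and GQ thresholds are *exclusive*: calls at exactly
the threshold are removed (depth <= 20 reads or GQ <= 50 fails), and all
three trio members must pass.  Rule order affects only which rule is
blamed for a drop, never membership of the kept set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional

from .models import AnnotatedVariant, TrioPedigree

log = logging.getLogger(__name__)

__all__ = ["QcConfig", "QcDecision", "QcReport", "apply_qc", "filter_cohort", "RULE_ORDER"]

#: Fixed evaluation order; ``first_failed_rule`` refers to this order.
RULE_ORDER = ("missing_genotype", "low_depth", "low_gq", "gatk_flag", "common_af")


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC cascade.

    ``min_depth_exclusive`` / ``min_gq_exclusive`` are exclusive lower
    bounds (a call must be strictly greater to pass).  A population AF
    strictly above ``max_pop_af`` fails; an absent AF passes when
    ``treat_missing_af_as_rare`` (the default — ultra-rare variants are
    often unobserved in reference panels).  ``failing_filter_flags``
    are matched as substrings of FILTER entries so that full VQSR
    tranche labels ("VQSRTrancheSNP99.90to100.00") match "VQSR".
    """

    min_depth_exclusive: int = 20
    min_gq_exclusive: int = 50
    max_pop_af: float = 0.01
    failing_filter_flags: tuple[str, ...] = ("VQSR", "ExcessHet")
    treat_missing_af_as_rare: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0 or self.min_gq_exclusive < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 < self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must be in (0, 1]")


@dataclass(frozen=True)
class QcDecision:
    kept: bool
    first_failed_rule: str  # one of RULE_ORDER or "none"

    def __post_init__(self) -> None:
        if self.kept != (self.first_failed_rule == "none"):
            raise ValueError("kept=True iff first_failed_rule='none'")


_KEEP = QcDecision(kept=True, first_failed_rule="none")


def _rule_failures(variant: AnnotatedVariant, cfg: QcConfig) -> dict[str, bool]:
    """Evaluate every rule independently (order-free)."""
    calls = [variant.call(s) for s in variant.trio.member_ids]
    failures = {
        "missing_genotype": any(c.is_missing for c in calls),
        # absent DP/GQ is treated as failing the respective rule
        "low_depth": any(c.depth is None or c.depth <= cfg.min_depth_exclusive for c in calls),
        "low_gq": any(c.gq is None or c.gq <= cfg.min_gq_exclusive for c in calls),
        "gatk_flag": any(
            bad in flag for flag in variant.filter_flags for bad in cfg.failing_filter_flags
        ),
    }
    if variant.pop_af is None:
        failures["common_af"] = not cfg.treat_missing_af_as_rare
    else:
        failures["common_af"] = variant.pop_af > cfg.max_pop_af
    return failures


def apply_qc(variant: AnnotatedVariant, cfg: Optional[QcConfig] = None) -> QcDecision:
    """Pure per-(variant, trio) QC decision.

    All three trio members must carry a called genotype with depth and
    GQ strictly above the exclusive thresholds; the site must carry no
    failing caller flag and must be rare in the population.  Returns the
    first failed rule in cascade order, or a keep decision.
    """
    cfg = cfg or QcConfig()
    failures = _rule_failures(variant, cfg)
    for rule in RULE_ORDER:
        if failures[rule]:
            return QcDecision(kept=False, first_failed_rule=rule)
    return _KEEP


@dataclass
class QcReport:
    """Drop accounting for one cohort pass: input = kept + sum(drops)."""

    n_input: int = 0
    n_kept: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})
    n_fp_filtered: int = 0  # dropped by the pluggable false-positive predicate

    @property
    def n_dropped(self) -> int:
        return sum(self.drops.values()) + self.n_fp_filtered

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(rule, self.drops[rule]) for rule in RULE_ORDER]
        rows.append(("fp_filter", self.n_fp_filtered))
        rows.append(("kept", self.n_kept))
        rows.append(("input", self.n_input))
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tn_dropped\n")
            for rule, n in self.to_rows():
                fh.write(f"{rule}\t{n}\n")


def filter_cohort(
    variants: Iterable[AnnotatedVariant],
    cfg: Optional[QcConfig] = None,
    fp_filter: Optional[Callable[[AnnotatedVariant], bool]] = None,
) -> tuple[Iterator[AnnotatedVariant], QcReport]:
    """Apply the QC cascade to a stream of per-trio variant records.

    ``fp_filter`` is an injectable keep-predicate applied *after* the
    rule cascade — the slot where a trained false-positive classifier
    would plug in; its drops are counted separately in the report.
    Returns a lazy kept-stream plus a report that is complete once the
    stream has been consumed.
    """
    cfg = cfg or QcConfig()
    report = QcReport()

    def gen() -> Iterator[AnnotatedVariant]:
        for v in variants:
            report.n_input += 1
            decision = apply_qc(v, cfg)
            if not decision.kept:
                report.drops[decision.first_failed_rule] += 1
                continue
            if fp_filter is not None and not fp_filter(v):
                report.n_fp_filtered += 1
                continue
            report.n_kept += 1
            yield v
        log.info(
            "QC: %d input, %d kept, drops=%s, fp_filtered=%d",
            report.n_input, report.n_kept, report.drops, report.n_fp_filtered,
        )

    return gen(), report
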