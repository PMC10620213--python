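"""Comparison statistics for detection sets.

Implements every statistic used to compare variant-prioritization
tools against a reference gene list:

* pairwise concordance (Jaccard index, as a percentage);
* 2- and 3-way Venn region counts with union-relative shares;
* positive predictive value (PPV) — the fraction of detected variants
  whose gene is on the reference list;
* odds ratio with a 95% Woolf (log-OR) confidence interval against a
  background variant pool, with Haldane–Anscombe correction on zero
  cells;
* diagnostic yield — the percentage of probands carrying at least one
  detected variant in a listed gene;
* the pooled two-proportion Z test used to flag category enrichment in
  characteristics tables; and
* the vote-threshold sweep trading PPV against yield.

Percentages are rendered half-up at one decimal unless stated
otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import sqrt
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lgd import LgdConfig, classify_consequence_group, detect_lgd
from .models import (
    AnnotatedVariant,
    Detection,
    DetectionSet,
    GeneList,
    InheritanceCall,
    VariantKey,
)

log = logging.getLogger(__name__)

__all__ = [
    "round_half_up",
    "percent",
    "concordance",
    "venn_counts",
    "VennResult",
    "compute_ppv",
    "compute_or_ci",
    "EvalResult",
    "diagnostic_yield",
    "two_proportion_z",
    "ZResult",
    "summary_table",
    "threshold_sweep",
    "SweepPoint",
    "SweepResult",
    "detections_from_calls",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table rendering)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage with half-up rounding, as printed in summary tables."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Set agreement
# ---------------------------------------------------------------------------


def concordance(a: DetectionSet, b: DetectionSet) -> float:
    """Jaccard concordance |a ∩ b| / |a ∪ b| × 100 on (variant, proband) keys."""
    ka, kb = a.pair_keys(), b.pair_keys()
    union = ka | kb
    if not union:
        raise ValueError("concordance undefined for two empty sets")
    return 100.0 * len(ka & kb) / len(union)


@dataclass(frozen=True)
class VennResult:
    """Exclusive region counts plus union-relative percentage shares.

    Region keys are frozensets of tool names; each (variant, proband)
    key is counted in exactly one region, so regions partition the
    union.
    """

    regions: dict[frozenset, int]
    union: int

    def share(self, *tools: str, ndigits: int = 1) -> float:
        """Half-up percentage share of one exclusive region."""
        return percent(self.regions[frozenset(tools)], self.union, ndigits)


def venn_counts(sets: Sequence[DetectionSet]) -> VennResult:
    """Exclusive Venn region counts for 2 or 3 detection sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 sets")
    names = [s.tool for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("detection sets must have distinct tool names")
    keys = {s.tool: s.pair_keys() for s in sets}
    union = set().union(*keys.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(keys[t] for t in combo))
            outside = set().union(*(keys[t] for t in names if t not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    return VennResult(regions=regions, union=len(union))


# ---------------------------------------------------------------------------
# Gene-list enrichment
# ---------------------------------------------------------------------------


def compute_ppv(s: DetectionSet, genes: GeneList) -> float:
    """Fraction of detections whose gene is on the reference list."""
    if not s.members:
        raise ValueError("PPV undefined for an empty detection set")
    hits = sum(1 for m in s.members if m.gene in genes)
    return hits / len(s.members)


@dataclass(frozen=True)
class EvalResult:
    """2×2 enrichment result: detected/not × listed-gene/not."""

    ppv: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    yield_percent: Optional[float]
    counts: tuple[tuple[int, int], tuple[int, int]]  # ((a, b), (c, d)), uncorrected
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


def compute_or_ci(
    s: DetectionSet,
    background: Iterable[tuple[VariantKey, str, str]],
    genes: GeneList,
    yield_n_probands: Optional[int] = None,
) -> EvalResult:
    """Odds ratio of listed-gene membership, detected vs. background.

    ``background`` is the post-QC proband-specific variant pool as
    (variant_key, proband_id, gene) triples and must contain the
    detected variants.  Cells: a = detected ∩ listed, b = detected \\
    listed, c = undetected ∩ listed, d = undetected \\ listed;
    OR = ad/bc with a 95% Woolf CI, exp(log OR ± 1.96·sqrt(Σ 1/cell)).
    Any zero cell gets the Haldane–Anscombe +0.5 on all cells (flagged);
    an empty detected or undetected margin is an error.
    """
    detected_keys = s.pair_keys()
    a = b = c = d = 0
    seen = set()
    for vk, proband, gene in background:
        if (vk, proband) in seen:
            continue
        seen.add((vk, proband))
        det = (vk, proband) in detected_keys
        listed = gene in genes
        if det and listed:
            a += 1
        elif det:
            b += 1
        elif listed:
            c += 1
        else:
            d += 1
    missing = detected_keys - seen
    if missing:
        raise ValueError(
            f"background must contain the detected variants; {len(missing)} missing"
        )
    if a + b == 0 or c + d == 0:
        raise ValueError(f"degenerate 2x2 table: a={a} b={b} c={c} d={d}")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = float(np.log(or_))
    ci_low, ci_high = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    yield_pct = (
        diagnostic_yield(s, genes, yield_n_probands) if yield_n_probands else None
    )
    return EvalResult(
        ppv=a / (a + b),
        odds_ratio=or_,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        yield_percent=yield_pct,
        counts=((a, b), (c, d)),
        continuity_corrected=corrected,
    )


def diagnostic_yield(s: DetectionSet, genes: GeneList, n_probands: int) -> float:
    """Percentage of probands with >= 1 detection in a listed gene.

    A proband with several qualifying detections counts once.
    """
    if n_probands < 1:
        raise ValueError("n_probands must be >= 1")
    qualifying = {m.proband_id for m in s.members if m.gene in genes}
    return 100.0 * len(qualifying) / n_probands


# ---------------------------------------------------------------------------
# Two-proportion Z test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZResult:
    z: float
    p: float
    degenerate: bool = False  # pooled proportion 0 or 1


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ZResult:
    """Two-sided pooled two-proportion Z test.

    z = (p1 − p2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2)) with p̂ the pooled
    proportion.  A pooled proportion of exactly 0 or 1 makes the
    statistic undefined; by convention z = 0, p = 1, flagged.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZResult(z=0.0, p=1.0, degenerate=True)
    se = sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return ZResult(z=z, p=float(2 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Characteristics summary table
# ---------------------------------------------------------------------------


def summary_table(
    sets: Sequence[DetectionSet],
    background_counts: dict[str, int],
    background_total: int,
    categorizer: Callable[[Detection], str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tool, per-category characteristics table.

    For every category in ``background_counts`` and every detection
    set: the member count, its percentage of the tool's total (half-up,
    one decimal), and a significance star when the pooled two-proportion
    Z test of the tool's rate against the background rate is two-sided
    significant at ``alpha``.
    """
    rows = []
    for category, bg_count in background_counts.items():
        for s in sets:
            n_tool = len(s.members)
            count = sum(1 for m in s.members if categorizer(m) == category)
            pct = percent(count, n_tool) if n_tool else 0.0
            star = False
            if n_tool and count:
                star = two_proportion_z(count, n_tool, bg_count, background_total).p < alpha
            rows.append(
                {"category": category, "tool": s.tool, "count": count,
                 "percent": pct, "significant": star}
            )
    return pd.DataFrame(rows, columns=["category", "tool", "count", "percent", "significant"])


# ---------------------------------------------------------------------------
# Vote-threshold sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepPoint:
    min_votes: int
    n_detected: int
    ppv: Optional[float]
    yield_percent: float


@dataclass(frozen=True)
class SweepResult:
    points: tuple[SweepPoint, ...]
    pearson_r: Optional[float]
    pearson_p: Optional[float]


def detections_from_calls(
    pairs: Iterable[tuple[AnnotatedVariant, InheritanceCall]],
    cfg: Optional[LgdConfig] = None,
    tool: str = "lgd",
) -> DetectionSet:
    """Run the LGD detector over (variant, inheritance-call) pairs."""
    cfg = cfg or LgdConfig()
    members = []
    for variant, call in pairs:
        lgd_call = detect_lgd(variant, cfg)
        if lgd_call.detected:
            members.append(
                Detection(
                    variant_key=variant.key,
                    proband_id=call.proband_id,
                    gene=variant.gene or "",
                    inheritance=call.category,
                    consequence_group=classify_consequence_group(
                        variant.consequence, cfg.include_start_stop_lost
                    ),
                    detection_class=lgd_call.detection_class,
                )
            )
    return DetectionSet.from_iterable(tool, members)


def threshold_sweep(
    pairs: Sequence[tuple[AnnotatedVariant, InheritanceCall]],
    genes: GeneList,
    n_probands: int,
    base_cfg: Optional[LgdConfig] = None,
    ks: Sequence[int] = range(1, 7),
) -> SweepResult:
    """Re-run LGD detection across vote thresholds; correlate PPV and yield.

    For each k the detector runs with ``min_votes=k`` (truncating
    detection is unaffected by k, so the sets nest by their missense
    members).  Pearson's r over the (PPV, yield) points is reported with
    its two-sided p-value when at least three points have a defined PPV.
    """
    from dataclasses import replace as _replace

    base_cfg = base_cfg or LgdConfig()
    points = []
    for k in ks:
        cfg = _replace(base_cfg, min_votes=k)
        det = detections_from_calls(pairs, cfg, tool=f"lgd_k{k}")
        ppv = compute_ppv(det, genes) if det.members else None
        points.append(
            SweepPoint(
                min_votes=k,
                n_detected=len(det),
                ppv=ppv,
                yield_percent=diagnostic_yield(det, genes, n_probands),
            )
        )
    valid = [(p.ppv, p.yield_percent) for p in points if p.ppv is not None]
    r = p_val = None
    if len(valid) >= 3:
        xs, ys = zip(*valid)
        if np.std(xs) > 0 and np.std(ys) > 0:
            r_res = stats.pearsonr(xs, ys)
            r, p_val = float(r_res.statistic), float(r_res.pvalue)
        else:
            log.warning("sweep points are constant in PPV or yield; correlation omitted")
    return SweepResult(points=tuple(points), pearson_r=r, pearson_p=p_val)
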