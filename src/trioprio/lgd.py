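"""Likely gene-disrupting (LGD) variant detection by in-silico consensus.

Two detection routes, mirroring the two LGD variant classes:

* **Protein-truncating** variants (frameshift, nonsense, start/stop
  loss, splice acceptor/donor) are called LGD when they hit a gene that
  is loss-of-function intolerant: LoFtool percentile strictly below
  0.25.
* **Missense** substitutions are put to a vote of six deleteriousness
  predictors — SIFT < 0.05, PolyPhen-2 >= 0.15, CADD (phred) > 20,
  REVEL > 0.50, M-CAP > 0.025, MPC >= 2 — and called LGD when at least
  ``min_votes`` (default 5 of 6) vote deleterious.

Inequality strictness follows the dbNSFP-recommended cutoffs exactly:
strict for SIFT/CADD/REVEL/M-CAP (and LoFtool), inclusive for
PolyPhen-2/MPC.  Everything else (synonymous, intronic, in-frame
indels, UTR, splice-region) is never detected — in-frame indels are
deliberately discarded because their relevance to neurodevelopmental
phenotypes is unestablished.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

from .models import AnnotatedVariant, ScorePanel

log = logging.getLogger(__name__)

__all__ = [
    "LgdConfig",
    "LgdCall",
    "classify_consequence_group",
    "count_deleterious_votes",
    "detect_lgd",
    "TRUNCATING_TERMS",
    "VOTING_TOOLS",
]

#: Consequence terms in the protein-truncating group.  ``stop_lost`` /
#: ``start_lost`` are included by default (toggleable via
#: ``LgdConfig.include_start_stop_lost``).
TRUNCATING_TERMS = frozenset({
    "frameshift_variant",
    "stop_gained",
    "splice_acceptor_variant",
    "splice_donor_variant",
})
START_STOP_LOST_TERMS = frozenset({"stop_lost", "start_lost"})
MISSENSE_TERMS = frozenset({"missense_variant"})

#: The six voting predictors, in a fixed reporting order.
VOTING_TOOLS = ("sift", "polyphen2", "cadd_phred", "revel", "mcap", "mpc")


@dataclass(frozen=True)
class LgdConfig:
    """Cutoffs for the LGD consensus detector.

    Vote cutoffs carry their printed inequality direction and
    strictness; no rounding tolerance is applied at the boundaries.
    ``missing_score_policy`` governs absent predictor scores:
    ``count_as_benign`` (default) never votes for an absent score;
    ``drop_from_denominator`` rescales the vote threshold to the tools
    that did score the variant.
    """

    loftool_cutoff_exclusive: float = 0.25
    min_votes: int = 5
    sift_lt: float = 0.05
    polyphen2_ge: float = 0.15
    cadd_gt: float = 20.0
    revel_gt: float = 0.50
    mcap_gt: float = 0.025
    mpc_ge: float = 2.0
    missing_score_policy: str = "count_as_benign"
    include_start_stop_lost: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_votes <= len(VOTING_TOOLS):
            raise ValueError(f"min_votes must be in [0, {len(VOTING_TOOLS)}]")
        if not 0.0 < self.loftool_cutoff_exclusive < 1.0:
            raise ValueError("loftool cutoff must be in (0, 1)")
        if self.missing_score_policy not in ("count_as_benign", "drop_from_denominator"):
            raise ValueError(f"unknown missing_score_policy {self.missing_score_policy!r}")


@dataclass(frozen=True)
class LgdCall:
    """Detection outcome; ``votes`` is meaningful for missense only."""

    detection_class: str  # lgd_truncating | lgd_missense | none
    votes: Optional[int] = None

    @property
    def detected(self) -> bool:
        return self.detection_class != "none"


_WARNED_TERMS: set[str] = set()


def classify_consequence_group(
    consequence: Optional[str], include_start_stop_lost: bool = True
) -> str:
    """Map a Sequence Ontology consequence term to a detection group.

    Returns ``truncating``, ``missense`` or ``other``.  Compound terms
    ("splice_acceptor_variant&intron_variant") match on any component.
    Unknown terms fall to ``other`` with a once-per-term warning.
    """
    if not consequence:
        return "other"
    truncating = TRUNCATING_TERMS | (START_STOP_LOST_TERMS if include_start_stop_lost else frozenset())
    terms = set(consequence.split("&"))
    if terms & truncating:
        return "truncating"
    if terms & MISSENSE_TERMS:
        return "missense"
    from .vcf_io import SO_SEVERITY_ORDER  # known-vocabulary check only

    for t in terms:
        if t not in SO_SEVERITY_ORDER and t not in _WARNED_TERMS:
            _WARNED_TERMS.add(t)
            log.warning("unknown consequence term %r treated as 'other'", t)
    return "other"


def _votes_and_present(scores: ScorePanel, cfg: LgdConfig) -> tuple[int, int]:
    checks = (
        (scores.sift, lambda v: v < cfg.sift_lt),
        (scores.polyphen2, lambda v: v >= cfg.polyphen2_ge),
        (scores.cadd_phred, lambda v: v > cfg.cadd_gt),
        (scores.revel, lambda v: v > cfg.revel_gt),
        (scores.mcap, lambda v: v > cfg.mcap_gt),
        (scores.mpc, lambda v: v >= cfg.mpc_ge),
    )
    votes = present = 0
    for value, passes in checks:
        if value is None:
            continue
        present += 1
        if passes(value):
            votes += 1
    return votes, present


def count_deleterious_votes(scores: ScorePanel, cfg: Optional[LgdConfig] = None) -> int:
    """Count predictors voting deleterious; absent scores never vote."""
    cfg = cfg or LgdConfig()
    return _votes_and_present(scores, cfg)[0]


def detect_lgd(variant: AnnotatedVariant, cfg: Optional[LgdConfig] = None) -> LgdCall:
    """Run the LGD detector on one QC-passed, proband-specific variant.

    Truncating variants require an intolerant LoFtool score (absent
    LoFtool means intolerance cannot be asserted, so no detection);
    missense variants require the vote threshold; all other consequence
    groups are never detected.
    """
    cfg = cfg or LgdConfig()
    group = classify_consequence_group(variant.consequence, cfg.include_start_stop_lost)
    if group == "truncating":
        lof = variant.scores.loftool
        detected = lof is not None and lof < cfg.loftool_cutoff_exclusive
        return LgdCall("lgd_truncating" if detected else "none")
    if group == "missense":
        votes, present = _votes_and_present(variant.scores, cfg)
        if cfg.missing_score_policy == "drop_from_denominator":
            threshold = math.ceil(cfg.min_votes * present / len(VOTING_TOOLS))
            detected = present > 0 and votes >= threshold
        else:
            detected = votes >= cfg.min_votes
        return LgdCall("lgd_missense" if detected else "none", votes=votes)
    return LgdCall("none")
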