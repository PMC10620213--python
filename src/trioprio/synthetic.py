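"""Self-contained synthetic trio cohorts with planted structure.

Generates everything the pipeline consumes — a joint multi-sample VCF,
a PED pedigree, a sidecar annotation TSV, a reference gene list, mock
external-classifier tables — plus a truth table, so that every stage is
testable end to end without access to any real cohort.

What is emulated
----------------
* trio genotype structure: background variation is Mendelian-transmitted
  from parental carriers, then *degraded* wherever a transmission would
  accidentally produce a proband-specific pattern (het x het -> hom-alt
  child; carrier mother -> hemizygous son), so the only proband-specific
  genotypes in a cohort are the planted ones, by construction;
* planted inheritance patterns (de novo, autosomal recessive, X-linked
  in males) at configured per-trio counts;
* QC failure modes injected into background sites at configured rates
  (missing genotypes, low depth, low GQ, caller filter flags, common
  population AF);
* annotation score distributions as a two-component mixture (a
  "damaging" and a "benign" component, each voting per predictor with a
  configured probability and missing at a configured rate);
* gene-list enrichment: damaging plants land in listed genes with a
  configured odds multiplier, giving the cohort a known implied
  detection odds ratio (:func:`implied_detection_odds_ratio`).

Identical seeds give byte-identical output files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .acmg import combine_criteria
from .models import ClassificationRecord, TrioPedigree, chrom_sort_key
from .vcf_io import write_classification_table, write_gene_list
from .models import GeneList

log = logging.getLogger(__name__)

__all__ = [
    "ScoreComponent",
    "SimConfig",
    "SimulatedCohort",
    "TruthRow",
    "simulate_cohort",
    "make_gene_list",
    "mock_classifier_table",
    "implied_detection_odds_ratio",
    "prob_missense_detected",
]

_AUTOSOME_LENGTHS = {str(i): 248_000_000 - 8_000_000 * (i - 1) for i in range(1, 23)}
_X_LENGTH = 156_040_895
_PAR1 = (10_001, 2_781_479)
_NONPAR_START = 3_000_000

_TRUNCATING_CHOICES = (
    "frameshift_variant", "frameshift_variant", "stop_gained",
    "splice_acceptor_variant", "splice_donor_variant", "stop_lost", "start_lost",
)
_BENIGN_CONSEQUENCES = ("synonymous_variant", "intron_variant", "missense_variant")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ScoreComponent:
    """One mixture component of the predictor-score distribution.

    Each of the six missense predictors (and LoFtool, for truncating
    variants) independently produces a score on its cutoff-passing side
    with probability ``p_vote``, is missing with probability
    ``p_missing``, and otherwise produces a clearly failing score.
    """

    p_vote: float
    p_missing: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_vote <= 1.0 or not 0.0 <= self.p_missing <= 1.0:
            raise ValueError("component probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``n_variants_per_trio`` is the total per-trio variant budget;
    planted proband-specific variants are carved out of it and the
    remainder becomes shared background sites, so the plant counts may
    not exceed it.  ``enrichment`` is the odds multiplier for a
    *damaging* planted variant's gene being on the reference list,
    relative to the baseline listing rate ``gene_list_size / n_genes``.
    The defaults mirror a 220-trio exome cohort in which roughly nine
    ultra-rare proband-specific genotypes per trio survive cleaning,
    against a 1031-symbol reference list.
    """

    n_trios: int = 220
    n_variants_per_trio: int = 20
    plant_counts: dict[str, int] = field(
        default_factory=lambda: {"de_novo": 4, "autosomal_recessive": 3, "x_linked_male": 2}
    )
    qc_failure_rates: dict[str, float] = field(
        default_factory=lambda: {
            "missing_genotype": 0.02,
            "low_depth": 0.03,
            "low_gq": 0.03,
            "gatk_flag": 0.02,
            "common_af": 0.01,
        }
    )
    damaging: ScoreComponent = ScoreComponent(p_vote=0.90)
    benign: ScoreComponent = ScoreComponent(p_vote=0.15)
    p_damaging_plant: float = 0.35
    plant_consequence_mix: tuple[float, float, float] = (0.60, 0.25, 0.15)  # missense, truncating, other
    gene_list_size: int = 1031
    n_genes: int = 8000
    enrichment: float = 4.0
    male_fraction: float = 0.8
    x_background_fraction: float = 0.05
    x_par_fraction: float = 0.2  # share of X background placed in PAR1
    fraction_multiallelic: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(n < 0 for n in self.plant_counts.values()):
            raise ValueError("plant counts must be non-negative")
        if any(not 0.0 <= f <= 1.0 for f in self.qc_failure_rates.values()):
            raise ValueError("qc failure rates must be fractions in [0, 1]")
        if sum(self.plant_counts.values()) > self.n_variants_per_trio:
            raise ValueError(
                f"plant counts {self.plant_counts} exceed the per-trio variant "
                f"budget ({self.n_variants_per_trio})"
            )
        if not 1 <= self.gene_list_size <= self.n_genes:
            raise ValueError("need 1 <= gene_list_size <= n_genes")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be a positive odds multiplier")

    @property
    def baseline_listed_rate(self) -> float:
        return self.gene_list_size / self.n_genes

    @property
    def enriched_listed_rate(self) -> float:
        p0 = self.baseline_listed_rate
        odds = self.enrichment * p0 / (1 - p0)
        return odds / (1 + odds)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted proband-specific variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    proband_id: str
    category: str
    gene: str
    consequence: str
    listed_gene: bool
    damaging: bool

    @property
    def variant_key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulatedCohort:
    vcf_path: Path
    ped_path: Path
    annotations_path: Path
    truth_path: Path
    gene_list_path: Path
    trios: list[TrioPedigree]
    truth: list[TruthRow]
    config: SimConfig


# ---------------------------------------------------------------------------
# Detection probabilities implied by the generator's own design
# ---------------------------------------------------------------------------


def prob_missense_detected(component: ScoreComponent, min_votes: int = 5) -> float:
    """P(a missense variant from this component reaches >= min_votes)."""
    p_eff = (1 - component.p_missing) * component.p_vote
    return float(stats.binom.sf(min_votes - 1, 6, p_eff))


def _prob_detected(cfg: SimConfig, component: ScoreComponent, min_votes: int) -> float:
    p_mis, p_trunc, _ = cfg.plant_consequence_mix
    p_lof = (1 - component.p_missing) * component.p_vote
    return p_mis * prob_missense_detected(component, min_votes) + p_trunc * p_lof


def implied_detection_odds_ratio(cfg: SimConfig, min_votes: int = 5) -> float:
    """Closed-form odds ratio implied by the generator's design.

    Over the planted proband-specific pool, a variant is "detected" by
    the LGD detector with probability pi1 (damaging component) or pi0
    (benign component), and its gene is listed with rate p1 or p0
    respectively.  The implied odds ratio of listing, detected versus
    undetected, follows directly from the mixture.
    """
    d = cfg.p_damaging_plant
    pi1 = _prob_detected(cfg, cfg.damaging, min_votes)
    pi0 = _prob_detected(cfg, cfg.benign, min_votes)
    p1, p0 = cfg.enriched_listed_rate, cfg.baseline_listed_rate
    listed_det = d * pi1 * p1 + (1 - d) * pi0 * p0
    unlisted_det = d * pi1 * (1 - p1) + (1 - d) * pi0 * (1 - p0)
    listed_un = d * (1 - pi1) * p1 + (1 - d) * (1 - pi0) * p0
    unlisted_un = d * (1 - pi1) * (1 - p1) + (1 - d) * (1 - pi0) * (1 - p0)
    return (listed_det / unlisted_det) / (listed_un / unlisted_un)


# ---------------------------------------------------------------------------
# Gene list
# ---------------------------------------------------------------------------


def _gene_symbol(i: int) -> str:
    return f"G{i:06d}"


def make_gene_list(cfg: SimConfig, path) -> GeneList:
    """Write the cohort's reference gene list (synthetic symbols).

    Listed symbols are the first ``gene_list_size`` of the gene
    universe, with confidence scores 1/2/3 in 20/40/40 proportions —
    no real gene names appear anywhere.
    """
    n = cfg.gene_list_size
    scores = {}
    for i in range(n):
        g = _gene_symbol(i)
        scores[g] = 1 if i < round(0.2 * n) else (2 if i < round(0.6 * n) else 3)
    genes = GeneList(symbols=frozenset(scores), scores=scores)
    write_gene_list(genes, path)
    return genes


# ---------------------------------------------------------------------------
# Score drawing
# ---------------------------------------------------------------------------

# (damaging-side low, high), (benign-side low, high) per predictor;
# ranges sit strictly inside / outside the detector cutoffs.
_SCORE_RANGES = {
    "sift": ((0.0, 0.049), (0.06, 1.0)),
    "polyphen2": ((0.15, 1.0), (0.0, 0.149)),
    "cadd_phred": ((20.5, 40.0), (0.0, 19.9)),
    "revel": ((0.51, 1.0), (0.0, 0.50)),
    "mcap": ((0.026, 1.0), (0.0, 0.025)),
    "mpc": ((2.0, 5.0), (0.0, 1.99)),
}


def _draw_missense_scores(rng, component: ScoreComponent) -> dict[str, str]:
    cells = {}
    for name, (dmg, ben) in _SCORE_RANGES.items():
        u = rng.random()
        if u < component.p_missing:
            cells[name] = ""
            continue
        side = dmg if rng.random() < component.p_vote else ben
        cells[name] = f"{rng.uniform(*side):.4f}"
    return cells


def _draw_loftool(rng, component: ScoreComponent) -> str:
    if rng.random() < component.p_missing:
        return ""
    if rng.random() < component.p_vote:
        return f"{rng.uniform(0.0, 0.249):.4f}"
    return f"{rng.uniform(0.25, 1.0):.4f}"


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


class _Site:
    __slots__ = (
        "chrom", "x_region", "pos", "ref", "alts", "filter", "pop_af",
        "consequence", "gene", "score_cells", "owner", "category",
        "damaging", "listed", "carrier_events", "qc_events",
    )

    def __init__(self, chrom, x_region=None):
        self.chrom = chrom
        self.x_region = x_region  # None | "par" | "nonpar"
        self.pos = 0
        self.ref = "A"
        self.alts = ("G",)
        self.filter = "PASS"
        self.pop_af = ""
        self.consequence = ""
        self.gene = ""
        self.score_cells = {}
        self.owner = None          # owning trio index for plants
        self.category = None       # planted category
        self.damaging = False
        self.listed = False
        self.carrier_events = []   # (sample_idx, genotype_string) overrides
        self.qc_events = []        # (sample_idx, field, value) or ("site", ...)


def _make_trios(cfg: SimConfig, rng) -> list[TrioPedigree]:
    trios = []
    for i in range(1, cfg.n_trios + 1):
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        trios.append(
            TrioPedigree(
                family_id=f"F{i:04d}",
                proband_id=f"P{i:04d}",
                father_id=f"FA{i:04d}",
                mother_id=f"MO{i:04d}",
                proband_sex=sex,
            )
        )
    return trios


def _write_ped(trios: list[TrioPedigree], path) -> None:
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t1\n")
            sex_code = "1" if t.proband_sex == "male" else "2"
            fh.write(f"{t.family_id}\t{t.proband_id}\t{t.father_id}\t{t.mother_id}\t{sex_code}\t2\n")


def _pick_gene(rng, cfg: SimConfig, listed: bool) -> str:
    if listed:
        return _gene_symbol(int(rng.integers(0, cfg.gene_list_size)))
    return _gene_symbol(int(rng.integers(cfg.gene_list_size, cfg.n_genes)))


def _alleles_for(rng, consequence: str) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    if consequence == "frameshift_variant":
        return ref, ref + _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def simulate_cohort(cfg: SimConfig, outdir) -> SimulatedCohort:
    """Generate one cohort (VCF + PED + annotations + truth + gene list).

    Planted genotypes are consistent with their category (recessive
    plants have two heterozygous parents, X-linked plants a carrier
    mother and hemizygous-reference father); QC failures are injected
    into background sites only, so plants survive cleaning.  Identical
    seeds produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    trios = _make_trios(cfg, rng)

    # sample column order: P, FA, MO per family, families in order
    sample_ids: list[str] = []
    sample_is_male: list[bool] = []
    trio_member_idx: list[tuple[int, int, int]] = []
    for i, t in enumerate(trios):
        base = 3 * i
        sample_ids += [t.proband_id, t.father_id, t.mother_id]
        sample_is_male += [t.proband_sex == "male", True, False]
        trio_member_idx.append((base, base + 1, base + 2))
    n_samples = len(sample_ids)

    sites: list[_Site] = []
    truth: list[TruthRow] = []

    # ---- planted proband-specific sites -------------------------------
    for ti, trio in enumerate(trios):
        ip, ifa, imo = trio_member_idx[ti]
        for category, count in cfg.plant_counts.items():
            if category == "x_linked_male" and trio.proband_sex != "male":
                continue
            for _ in range(count):
                if category == "x_linked_male":
                    site = _Site("X", x_region="nonpar")
                else:
                    site = _Site(str(rng.integers(1, 23)))
                site.owner = ti
                site.category = category
                site.damaging = rng.random() < cfg.p_damaging_plant
                p_listed = cfg.enriched_listed_rate if site.damaging else cfg.baseline_listed_rate
                site.listed = rng.random() < p_listed
                site.gene = _pick_gene(rng, cfg, site.listed)
                u = rng.random()
                p_mis, p_trunc, _ = cfg.plant_consequence_mix
                if u < p_mis:
                    site.consequence = "missense_variant"
                    comp = cfg.damaging if site.damaging else cfg.benign
                    site.score_cells = _draw_missense_scores(rng, comp)
                elif u < p_mis + p_trunc:
                    site.consequence = _TRUNCATING_CHOICES[
                        rng.integers(0, len(_TRUNCATING_CHOICES))
                    ]
                    comp = cfg.damaging if site.damaging else cfg.benign
                    site.score_cells = {"loftool": _draw_loftool(rng, comp)}
                else:
                    site.consequence = "synonymous_variant"
                site.ref, alt = _alleles_for(rng, site.consequence)
                site.alts = (alt,)
                site.pop_af = "" if rng.random() < 0.1 else f"{rng.uniform(0.0, 0.0005):.6f}"
                if category == "de_novo":
                    site.carrier_events = [(ip, "0/1")]
                elif category == "autosomal_recessive":
                    site.carrier_events = [(ip, "1/1"), (ifa, "0/1"), (imo, "0/1")]
                else:  # x_linked_male
                    site.carrier_events = [(ip, "1"), (imo, "0/1")]
                sites.append(site)

    # ---- background sites ---------------------------------------------
    n_bg = cfg.n_trios * (cfg.n_variants_per_trio - sum(cfg.plant_counts.values()))
    n_multi = int(round(cfg.fraction_multiallelic * n_bg))
    parent_cols = np.array(
        [j for triple in trio_member_idx for j in (triple[1], triple[2])], dtype=int
    )

    for b in range(n_bg + n_multi):
        if rng.random() < cfg.x_background_fraction:
            region = "par" if rng.random() < cfg.x_par_fraction else "nonpar"
            site = _Site("X", x_region=region)
        else:
            site = _Site(str(rng.integers(1, 23)))
        site.gene = _gene_symbol(int(rng.integers(0, cfg.n_genes)))
        site.consequence = _BENIGN_CONSEQUENCES[rng.integers(0, len(_BENIGN_CONSEQUENCES))]
        if site.consequence == "missense_variant":
            site.score_cells = _draw_missense_scores(rng, cfg.benign)
        site.ref, alt = _alleles_for(rng, site.consequence)
        if b >= n_bg:  # multiallelic background site
            alt2 = next(x for x in _BASES if x not in (site.ref[0], alt))
            site.alts = (alt, alt2)
        else:
            site.alts = (alt,)

        af = rng.uniform(0.0005, 0.009)
        fails = {
            rule: rng.random() < rate for rule, rate in cfg.qc_failure_rates.items()
        }
        if fails.get("common_af"):
            af = rng.uniform(0.011, 0.05)
        site.pop_af = f"{af:.6f}"
        if fails.get("gatk_flag"):
            site.filter = (
                "VQSRTrancheSNP99.90to100.00" if rng.random() < 0.5 else "ExcessHet"
            )
        for rule, field_name in (
            ("missing_genotype", "gt"), ("low_depth", "dp"), ("low_gq", "gq")
        ):
            if fails.get(rule):
                victim = int(rng.integers(0, n_samples))
                if field_name == "gt":
                    site.qc_events.append((victim, "gt", "./."))
                elif field_name == "dp":
                    site.qc_events.append((victim, "dp", int(rng.integers(0, 21))))
                else:
                    site.qc_events.append((victim, "gq", int(rng.integers(0, 51))))

        # sparse Mendelian background: parents carry the allele rarely;
        # children inherit, then degrade any accidental proband-specific
        # pattern so plants are the only such genotypes in the cohort.
        carrier_draw = rng.random(len(parent_cols)) < 2 * min(af, 0.009)
        events: dict[int, str] = {}
        male_x = site.chrom == "X" and site.x_region == "nonpar"
        for hit in np.nonzero(carrier_draw)[0]:
            col = int(parent_cols[hit])
            if male_x and sample_is_male[col]:
                events[col] = "1"
            else:
                events[col] = "0/1"
        for ti2, (ip2, ifa2, imo2) in enumerate(trio_member_idx):
            fa_carrier = ifa2 in events
            mo_carrier = imo2 in events
            if not (fa_carrier or mo_carrier):
                continue
            proband_male = sample_is_male[ip2]
            if male_x:
                if proband_male:
                    # son inherits X only from the mother; a transmitted
                    # allele would mimic the X-linked pattern -> degrade
                    continue
                alleles = int(fa_carrier) + int(mo_carrier and rng.random() < 0.5)
                if alleles >= 1:
                    events[ip2] = "0/1"
            else:
                a_fa = 1 if fa_carrier and rng.random() < 0.5 else 0
                a_mo = 1 if mo_carrier and rng.random() < 0.5 else 0
                if a_fa + a_mo == 2:
                    events[ip2] = "0/1"  # degraded from hom-alt (would mimic recessive)
                elif a_fa + a_mo == 1:
                    events[ip2] = "0/1"
        site.carrier_events = sorted(events.items())
        sites.append(site)

    # ---- coordinates ---------------------------------------------------
    counters: dict[str, int] = {}
    starts = {**{c: 1_000_000 for c in _AUTOSOME_LENGTHS}, "X_par": 20_000, "X_nonpar": _NONPAR_START}
    for site in sites:
        key = site.chrom if site.chrom != "X" else f"X_{site.x_region}"
        pos = counters.get(key, starts[key]) + int(rng.integers(50, 800))
        counters[key] = pos
        site.pos = pos
    sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos))

    # ---- truth ---------------------------------------------------------
    for site in sites:
        if site.category is not None:
            truth.append(
                TruthRow(
                    chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alts[0],
                    proband_id=trios[site.owner].proband_id, category=site.category,
                    gene=site.gene, consequence=site.consequence,
                    listed_gene=site.listed, damaging=site.damaging,
                )
            )

    # ---- write files ---------------------------------------------------
    vcf_path = outdir / "cohort.vcf"
    ped_path = outdir / "cohort.ped"
    ann_path = outdir / "annotations.tsv"
    truth_path = outdir / "truth.tsv"
    genes_path = outdir / "gene_list.tsv"

    _write_ped(trios, ped_path)
    make_gene_list(cfg, genes_path)
    _write_vcf(cfg, sites, sample_ids, sample_is_male, vcf_path)

    with open(ann_path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tconsequence\tgene\tpop_af\t"
            "sift\tpolyphen2\tcadd_phred\trevel\tmcap\tmpc\tloftool\n"
        )
        for site in sites:
            cells = site.score_cells
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{','.join(site.alts)}\t"
                f"{site.consequence}\t{site.gene}\t{site.pop_af}\t"
                + "\t".join(
                    cells.get(k, "")
                    for k in ("sift", "polyphen2", "cadd_phred", "revel", "mcap", "mpc", "loftool")
                )
                + "\n"
            )

    with open(truth_path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tproband\tcategory\tgene\tconsequence\t"
            "listed_gene\tdamaging_truth\n"
        )
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.proband_id}\t{t.category}\t"
                f"{t.gene}\t{t.consequence}\t{int(t.listed_gene)}\t{int(t.damaging)}\n"
            )

    log.info(
        "simulated cohort: %d trios, %d sites (%d planted), %d samples",
        cfg.n_trios, len(sites), len(truth), n_samples,
    )
    return SimulatedCohort(
        vcf_path=vcf_path, ped_path=ped_path, annotations_path=ann_path,
        truth_path=truth_path, gene_list_path=genes_path,
        trios=trios, truth=truth, config=cfg,
    )


def _write_vcf(cfg, sites, sample_ids, sample_is_male, path) -> None:
    default_dp, default_gq = 50, 99
    dip_ref = f"0/0:{default_dp}:{default_gq}"
    hap_ref = f"0:{default_dp}:{default_gq}"
    n = len(sample_ids)
    autosome_row = [dip_ref] * n
    malex_row = [hap_ref if m else dip_ref for m in sample_is_male]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trioprio-synthetic\n")
        for c, length in _AUTOSOME_LENGTHS.items():
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(f"##contig=<ID=X,length={_X_LENGTH}>\n")
        fh.write('##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="VQSR tranche">\n')
        fh.write('##FILTER=<ID=ExcessHet,Description="Excess heterozygosity">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")

        for site in sites:
            male_x = site.chrom == "X" and site.x_region == "nonpar"
            row = (malex_row if male_x else autosome_row).copy()
            overrides: dict[int, list] = {}

            def cell(idx):
                if idx not in overrides:
                    gt = "0" if (male_x and sample_is_male[idx]) else "0/0"
                    overrides[idx] = [gt, default_dp, default_gq]
                return overrides[idx]

            for idx, gt in site.carrier_events:
                cell(idx)[0] = gt
            for idx, field_name, value in site.qc_events:
                c = cell(idx)
                if field_name == "gt":
                    c[0] = "./." if not (male_x and sample_is_male[idx]) else "."
                elif field_name == "dp":
                    c[1] = value
                else:
                    c[2] = value
            for idx, (gt, dp, gq) in overrides.items():
                row[idx] = f"{gt}:{dp}:{gq}"
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alts)}\t"
                f"100\t{site.filter}\t.\tGT:DP:GQ\t" + "\t".join(row) + "\n"
            )


def simulate_detection_pool(cfg: SimConfig, seed: int):
    """Draw one proband-specific pool and run the LGD detector over it.

    Samples exactly the per-variant quantities that determine the
    enrichment statistics — damaging component, consequence, predictor
    scores, gene listing — using the same score-drawing machinery and
    the real detector, without the VCF/genotype plumbing that does not
    affect the 2x2 table.  Returns ``(detections, background, n_probands)``
    ready for :func:`trioprio.evaluate.compute_or_ci`.
    """
    from .lgd import LgdConfig, detect_lgd
    from .models import AnnotatedVariant, Detection, DetectionSet, SampleCall, ScorePanel, TrioPedigree

    rng = np.random.default_rng(seed)
    n_pool = cfg.n_trios * sum(cfg.plant_counts.values())
    p_mis, p_trunc, _ = cfg.plant_consequence_mix
    lgd_cfg = LgdConfig()
    trio_cache = {}
    members = []
    background = []
    for i in range(n_pool):
        proband = f"P{i % cfg.n_trios:04d}"
        damaging = rng.random() < cfg.p_damaging_plant
        listed = rng.random() < (
            cfg.enriched_listed_rate if damaging else cfg.baseline_listed_rate
        )
        gene = _pick_gene(rng, cfg, listed)
        comp = cfg.damaging if damaging else cfg.benign
        u = rng.random()
        if u < p_mis:
            consequence = "missense_variant"
            cells = _draw_missense_scores(rng, comp)
        elif u < p_mis + p_trunc:
            consequence = _TRUNCATING_CHOICES[rng.integers(0, len(_TRUNCATING_CHOICES))]
            cells = {"loftool": _draw_loftool(rng, comp)}
        else:
            consequence = "synonymous_variant"
            cells = {}
        scores = ScorePanel(**{k: float(v) for k, v in cells.items() if v})
        if proband not in trio_cache:
            trio_cache[proband] = TrioPedigree(
                family_id=proband, proband_id=proband,
                father_id=f"FA{proband}", mother_id=f"MO{proband}",
                proband_sex="male",
            )
        trio = trio_cache[proband]
        variant = AnnotatedVariant(
            chrom="1", pos=1000 + i, ref="A", alts=("G",), trio=trio,
            calls={s: SampleCall(genotype=(0, 1)) for s in trio.member_ids},
            consequence=consequence, gene=gene, scores=scores,
        )
        key = variant.key
        background.append((key, proband, gene))
        call = detect_lgd(variant, lgd_cfg)
        if call.detected:
            members.append(
                Detection(
                    variant_key=key, proband_id=proband, gene=gene,
                    inheritance="de_novo", detection_class=call.detection_class,
                )
            )
    return DetectionSet.from_iterable("lgd", members), background, cfg.n_trios


# ---------------------------------------------------------------------------
# Mock external classifier tables
# ---------------------------------------------------------------------------

_PLP_CRITERIA_CHOICES = (
    frozenset({"PVS1", "PS2"}),          # -> P
    frozenset({"PS2", "PM2"}),           # -> LP
    frozenset({"PS2", "PM2", "PP3"}),    # -> LP
)
_INHERITED_LP = frozenset({"PM1", "PM2", "PM4"})  # -> LP without PS2
_UPGRADEABLE_VUS = frozenset({"PM2", "PP3"})      # -> LP once PS2 is added


def mock_classifier_table(
    truth: Iterable[TruthRow],
    style: str = "denovo_heavy",
    seed: int = 0,
    tool_name: str = "InterVar",
    path=None,
) -> list[ClassificationRecord]:
    """Emit an external-classifier-style table over planted variants.

    ``denovo_heavy`` mimics guideline-based classifiers, whose
    likely-pathogenic calls are almost exclusively de novo (expected
    >= 95%); ``balanced`` emits pathogenic calls at a flat rate so the
    category mix of emitted records tracks the truth proportions.  A
    slice of de novo variants is additionally emitted as VUS with
    moderate/supporting criteria, which the PS2 upgrade can promote.
    Classifications are derived from the assigned criteria via the
    combining rules, so the table is internally consistent.
    """
    if style not in ("denovo_heavy", "balanced"):
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    records: list[ClassificationRecord] = []
    for t in truth:
        u = rng.random()
        criteria: Optional[frozenset] = None
        # pathogenic calls concentrate on truly damaging variants, so the
        # emitted sets inherit the damaging plants' gene-list enrichment
        if style == "denovo_heavy":
            if t.category == "de_novo":
                p_lp = 0.75 if t.damaging else 0.08
                if u < p_lp:
                    criteria = _PLP_CRITERIA_CHOICES[rng.integers(0, len(_PLP_CRITERIA_CHOICES))]
                elif u < p_lp + 0.25:
                    criteria = _UPGRADEABLE_VUS
            else:
                p_lp = 0.008 if t.damaging else 0.002
                if u < p_lp:
                    criteria = _INHERITED_LP
                elif u < p_lp + 0.10:
                    criteria = _UPGRADEABLE_VUS
        else:  # balanced
            p_lp = 0.60 if t.damaging else 0.12
            if u < p_lp:
                criteria = (
                    _PLP_CRITERIA_CHOICES[rng.integers(0, len(_PLP_CRITERIA_CHOICES))]
                    if t.category == "de_novo" else _INHERITED_LP
                )
            elif u < p_lp + 0.15:
                criteria = _UPGRADEABLE_VUS
        if criteria is None:
            continue
        records.append(
            ClassificationRecord(
                variant_key=t.variant_key,
                proband_id=t.proband_id,
                tool=tool_name,
                classification=combine_criteria(criteria),
                criteria=criteria,
            )
        )
    if path is not None:
        write_classification_table(records, path)
    return records


def read_truth_table(path) -> list[TruthRow]:
    """Re-load a truth table written by :func:`simulate_cohort`."""
    import csv

    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                TruthRow(
                    chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                    proband_id=row["proband"], category=row["category"], gene=row["gene"],
                    consequence=row["consequence"],
                    listed_gene=row["listed_gene"] == "1",
                    damaging=row["damaging_truth"] == "1",
                )
            )
    return rows
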