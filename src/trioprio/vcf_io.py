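"""Readers and writers for all external formats.

Handles trio VCFs (annotations either in a VEP-style ``CSQ`` INFO field
or a sidecar TSV keyed by chrom/pos/ref/alt), 6-column PED pedigrees,
gene lists, external ACMG classifier tables, and the package's own
detection / variant-table TSV dialects.  All writers are deterministic
(sorted output) so that identical inputs give byte-identical artifacts.
"""
from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Optional

from cyvcf2 import VCF

from .models import (
    AnnotatedVariant,
    ClassificationRecord,
    Detection,
    DetectionSet,
    GeneList,
    SampleCall,
    ScorePanel,
    TrioPedigree,
    VariantKey,
    chrom_sort_key,
    normalize_chrom,
)

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_ped",
    "read_trio_vcf",
    "read_annotation_table",
    "read_classification_table",
    "write_classification_table",
    "read_gene_list",
    "write_gene_list",
    "write_detections",
    "read_detections",
    "write_variant_table",
    "read_variant_table",
    "write_call_table",
    "read_call_table",
    "CRITERIA_VOCABULARY",
]


class ParseError(ValueError):
    """Malformed content in an input file."""


# ---------------------------------------------------------------------------
# PED pedigrees
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": "male", "2": "female"}


def read_ped(path) -> list[TrioPedigree]:
    """Read a 6-column PED file into trio records.

    Emits one :class:`TrioPedigree` per affected child (phenotype code 2)
    whose father and mother both appear as individuals in the file.
    Children with a missing parent are excluded with a logged warning;
    an affected child with an unknown sex code is an error, because
    X-linked classification requires known proband sex.
    """
    rows: dict[str, tuple[str, str, str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            fam, ind, father, mother, sex, pheno = fields
            rows[ind] = (fam, father, mother, sex, pheno)
            order.append(ind)

    trios: list[TrioPedigree] = []
    for ind in order:
        fam, father, mother, sex, pheno = rows[ind]
        if pheno != "2":
            continue  # only affected children become probands
        if father in ("0", "") or mother in ("0", ""):
            continue  # founder rows are not trios
        if father not in rows or mother not in rows:
            log.warning(
                "pedigree %s: proband %s excluded (parent %s not in file)",
                fam, ind, father if father not in rows else mother,
            )
            continue
        if sex not in _SEX_CODES:
            raise ParseError(
                f"{path}: individual {ind!r}: unknown sex code {sex!r} "
                "(1=male, 2=female required for an affected proband)"
            )
        trios.append(
            TrioPedigree(
                family_id=fam,
                proband_id=ind,
                father_id=father,
                mother_id=mother,
                proband_sex=_SEX_CODES[sex],
            )
        )
    return trios


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

# VEP consequence terms ordered most to least severe; used to pick the
# representative transcript when a CSQ entry annotates several.
SO_SEVERITY_ORDER = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)
_SEVERITY_RANK = {t: i for i, t in enumerate(SO_SEVERITY_ORDER)}

_SCORE_COLUMNS = ("sift", "polyphen2", "cadd_phred", "revel", "mcap", "mpc", "loftool")

# CSQ sub-field name -> ScorePanel field (case-insensitive match)
_CSQ_SCORE_ALIASES = {
    "sift": "sift",
    "polyphen": "polyphen2",
    "polyphen2": "polyphen2",
    "cadd_phred": "cadd_phred",
    "revel": "revel",
    "m-cap": "mcap",
    "m_cap": "mcap",
    "mcap": "mcap",
    "mpc": "mpc",
    "loftool": "loftool",
}

_PAREN_SCORE = re.compile(r"^[A-Za-z_]+\(([-0-9.eE]+)\)$")


def _parse_score(text: str) -> Optional[float]:
    """Parse a CSQ score that may be bare (``0.01``) or VEP-style
    qualitative-with-value (``deleterious(0.01)``)."""
    text = text.strip()
    if not text or text == ".":
        return None
    m = _PAREN_SCORE.match(text)
    if m:
        text = m.group(1)
    return float(text)


def _severity(term: str) -> int:
    return _SEVERITY_RANK.get(term, len(SO_SEVERITY_ORDER))


class Annotation:
    """Per-allele annotation bundle (consequence, gene, AF, scores)."""

    __slots__ = ("consequence", "gene", "pop_af", "scores")

    def __init__(self, consequence=None, gene=None, pop_af=None, scores=None):
        self.consequence = consequence
        self.gene = gene
        self.pop_af = pop_af
        self.scores = scores if scores is not None else ScorePanel()


def read_annotation_table(path) -> dict[VariantKey, Annotation]:
    """Read a sidecar annotation TSV keyed by (chrom, pos, ref, alt).

    Required columns: chrom, pos, ref, alt, consequence, gene, pop_af,
    sift, polyphen2, cadd_phred, revel, mcap, mpc, loftool.  Empty cells
    mean the annotation is absent (never coerced to zero).
    """
    table: dict[VariantKey, Annotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: missing key columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            key = (normalize_chrom(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            scores = {}
            for col in _SCORE_COLUMNS:
                cell = (row.get(col) or "").strip()
                if cell and cell != ".":
                    scores[col] = float(cell)
            af_cell = (row.get("pop_af") or "").strip()
            table[key] = Annotation(
                consequence=(row.get("consequence") or "").strip() or None,
                gene=(row.get("gene") or "").strip() or None,
                pop_af=float(af_cell) if af_cell and af_cell != "." else None,
                scores=ScorePanel(**scores),
            )
    return table


class CsqParser:
    """Parse a VEP-style CSQ INFO field using the header's Format string."""

    def __init__(self, format_description: str):
        # header description ends with "... Format: Allele|Consequence|..."
        m = re.search(r"Format:\s*([\w|.\-]+)", format_description)
        if not m:
            raise ParseError(f"cannot find Format in CSQ description: {format_description!r}")
        self.fields = [f.strip() for f in m.group(1).split("|")]
        lower = [f.lower() for f in self.fields]

        def idx(*names):
            for n in names:
                if n in lower:
                    return lower.index(n)
            return None

        self.i_allele = idx("allele")
        self.i_consequence = idx("consequence")
        self.i_gene = idx("symbol", "gene")
        self.i_af = idx("gnomad_af", "af", "max_af")
        self.score_idx = {
            _CSQ_SCORE_ALIASES[f]: i
            for i, f in enumerate(lower)
            if f in _CSQ_SCORE_ALIASES
        }

    def parse(self, csq_value: str, alt: str) -> Annotation:
        """Pick the most severe-consequence transcript matching ``alt``."""
        best: Optional[list[str]] = None
        best_rank = len(SO_SEVERITY_ORDER) + 1
        for entry in csq_value.split(","):
            parts = entry.split("|")
            if len(parts) != len(self.fields):
                raise ParseError(
                    f"CSQ entry has {len(parts)} fields, header declares {len(self.fields)}"
                )
            if self.i_allele is not None and parts[self.i_allele] not in ("", alt):
                continue
            terms = parts[self.i_consequence].split("&") if self.i_consequence is not None else []
            rank = min((_severity(t) for t in terms), default=best_rank + 1)
            if rank < best_rank:
                best_rank, best = rank, parts
        if best is None:
            return Annotation()
        terms = best[self.i_consequence].split("&") if self.i_consequence is not None else []
        consequence = min(terms, key=_severity) if terms else None
        scores = {}
        for field_name, i in self.score_idx.items():
            val = _parse_score(best[i])
            if val is not None:
                scores[field_name] = val
        af = None
        if self.i_af is not None:
            af = _parse_score(best[self.i_af])
        gene = best[self.i_gene] if self.i_gene is not None and best[self.i_gene] else None
        return Annotation(consequence=consequence, gene=gene, pop_af=af, scores=ScorePanel(**scores))


# ---------------------------------------------------------------------------
# Trio VCF
# ---------------------------------------------------------------------------


def _sample_call(genotypes, depths, quals, i: int) -> SampleCall:
    entry = genotypes[i]
    alleles = tuple(a for a in entry[:-1])  # last element is the phase flag
    gt = None if any(a < 0 for a in alleles) else alleles
    dp = gq = None
    if depths is not None:
        d = int(depths[i, 0])
        dp = d if 0 <= d < 2**31 - 1 else None  # htslib int missing sentinel
    if quals is not None:
        q = float(quals[i, 0])
        gq = int(round(q)) if q >= 0 else None
    return SampleCall(genotype=gt, depth=dp, gq=gq)


def read_trio_vcf(
    path,
    pedigrees: list[TrioPedigree],
    annotations: Optional[dict[VariantKey, Annotation]] = None,
) -> Iterator[AnnotatedVariant]:
    """Stream a joint multi-sample VCF as per-trio annotated records.

    Each VCF site yields one :class:`AnnotatedVariant` per trio, carrying
    exactly that trio's three sample calls, in file order (trios iterate
    in pedigree order within a site).  Annotations come from a sidecar
    table (``annotations``, keyed by chrom/pos/ref/alt) when given,
    otherwise from a VEP-style CSQ INFO field if the header declares one.
    Absent scores stay absent.  A sample named in the pedigree but
    missing from the VCF header is fatal; an unparseable CSQ entry emits
    the variant with absent annotations and a warning.
    """
    vcf = VCF(str(path), gts012=False)
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    for trio in pedigrees:
        missing = [s for s in trio.member_ids if s not in sample_index]
        if missing:
            raise ParseError(f"{path}: pedigree sample(s) {missing} not in VCF header")

    csq_parser: Optional[CsqParser] = None
    if annotations is None:
        try:
            desc = vcf.get_header_type("CSQ").get("Description", "")
            csq_parser = CsqParser(desc.strip('"'))
        except KeyError:
            csq_parser = None

    trio_idx = [
        tuple(sample_index[s] for s in trio.member_ids) for trio in pedigrees
    ]

    for v in vcf:
        chrom = normalize_chrom(v.CHROM)
        alts = tuple(v.ALT)
        if not alts:
            continue
        filt = frozenset() if v.FILTER is None else frozenset(v.FILTER.split(";"))
        ann = Annotation()
        if annotations is not None:
            ann = annotations.get((chrom, v.POS, v.REF, ",".join(alts)), None) or annotations.get(
                (chrom, v.POS, v.REF, alts[0]), Annotation()
            )
        elif csq_parser is not None:
            raw = v.INFO.get("CSQ")
            if raw is not None:
                try:
                    ann = csq_parser.parse(raw, alts[0])
                except (ParseError, ValueError) as exc:
                    log.warning("%s:%s unparseable CSQ (%s); annotations absent", chrom, v.POS, exc)
                    ann = Annotation()
        genotypes = v.genotypes
        depths = v.format("DP")
        quals = v.format("GQ")
        for trio, (ip, ifa, imo) in zip(pedigrees, trio_idx):
            calls = {
                trio.proband_id: _sample_call(genotypes, depths, quals, ip),
                trio.father_id: _sample_call(genotypes, depths, quals, ifa),
                trio.mother_id: _sample_call(genotypes, depths, quals, imo),
            }
            yield AnnotatedVariant(
                chrom=chrom,
                pos=v.POS,
                ref=v.REF,
                alts=alts,
                trio=trio,
                calls=calls,
                filter_flags=filt,
                pop_af=ann.pop_af,
                consequence=ann.consequence,
                gene=ann.gene,
                scores=ann.scores,
            )


# ---------------------------------------------------------------------------
# External classifier tables (InterVar / TAPES style)
# ---------------------------------------------------------------------------

CRITERIA_VOCABULARY = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_CLASS_SYNONYMS = {
    "p": "P", "pathogenic": "P",
    "lp": "LP", "likely pathogenic": "LP", "likely_pathogenic": "LP",
    "vus": "VUS", "uncertain significance": "VUS",
    "uncertain_significance": "VUS", "variant of uncertain significance": "VUS",
    "lb": "LB", "likely benign": "LB", "likely_benign": "LB",
    "b": "B", "benign": "B",
}


def normalize_classification(label: str) -> str:
    norm = _CLASS_SYNONYMS.get(label.strip().lower())
    if norm is None:
        raise ParseError(f"unknown classification label {label!r}")
    return norm


def read_classification_table(path, tool_name: str) -> list[ClassificationRecord]:
    """Read an external ACMG classifier output TSV.

    Columns: chrom, pos, ref, alt, proband, classification, criteria
    (semicolon-separated ACMG tags, possibly empty).  Criteria tags are
    validated against the 28-criterion vocabulary; classification labels
    accept long-form synonyms ("Likely pathogenic" -> LP).
    """
    records: list[ClassificationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "proband", "classification", "criteria"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: classification table needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            raw = (row["criteria"] or "").strip()
            tags = frozenset(t.strip() for t in raw.split(";") if t.strip())
            unknown = tags - CRITERIA_VOCABULARY
            if unknown:
                raise ParseError(
                    f"{path}: row {i}: unknown ACMG criterion tag(s) {sorted(unknown)}"
                )
            try:
                classification = normalize_classification(row["classification"])
            except ParseError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from None
            records.append(
                ClassificationRecord(
                    variant_key=(
                        normalize_chrom(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]
                    ),
                    proband_id=row["proband"],
                    tool=tool_name,
                    classification=classification,
                    criteria=tags,
                )
            )
    return records


def write_classification_table(records: Iterable[ClassificationRecord], path) -> None:
    """Write classifier records; adds ``classification_after_ps2`` when set."""
    records = sorted(
        records, key=lambda r: (chrom_sort_key(r.variant_key[0]), *r.variant_key[1:], r.proband_id)
    )
    has_ps2 = any(r.classification_after_ps2 is not None for r in records)
    cols = ["chrom", "pos", "ref", "alt", "proband", "tool", "classification", "criteria"]
    if has_ps2:
        cols.append("classification_after_ps2")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in records:
            row = [
                r.variant_key[0], r.variant_key[1], r.variant_key[2], r.variant_key[3],
                r.proband_id, r.tool, r.classification, ";".join(sorted(r.criteria)),
            ]
            if has_ps2:
                row.append(r.classification_after_ps2 or "")
            w.writerow(row)


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path) -> GeneList:
    """Read a gene-list TSV with columns ``gene`` and ``score`` (score in
    {1,2,3} or empty)."""
    symbols: set[str] = set()
    scores: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise ParseError(f"{path}: gene list needs a 'gene' column")
        for i, row in enumerate(reader, start=2):
            g = row["gene"].strip()
            if not g:
                raise ParseError(f"{path}: row {i}: empty gene symbol")
            symbols.add(g)
            cell = (row.get("score") or "").strip()
            if cell:
                scores[g] = int(cell)
    return GeneList(symbols=frozenset(symbols), scores=scores)


def write_gene_list(genes: GeneList, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "score"])
        for g in sorted(genes.symbols):
            w.writerow([g, genes.scores.get(g, "")])


# ---------------------------------------------------------------------------
# Detection sets
# ---------------------------------------------------------------------------

_DETECTION_COLS = [
    "chrom", "pos", "ref", "alt", "proband", "gene",
    "inheritance", "consequence_group", "detection_class", "tool",
]


def write_detections(detections: DetectionSet, path) -> None:
    """Write a detection set as a deterministic sorted TSV.

    Sorted by (chrom, pos, ref, alt, proband); re-reading with
    :func:`read_detections` reproduces the set exactly.  An empty set
    yields a header-only file.
    """
    rows = sorted(
        detections.members,
        key=lambda d: (chrom_sort_key(d.variant_key[0]), *d.variant_key[1:], d.proband_id),
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DETECTION_COLS)
        for d in rows:
            w.writerow([
                d.variant_key[0], d.variant_key[1], d.variant_key[2], d.variant_key[3],
                d.proband_id, d.gene, d.inheritance, d.consequence_group,
                d.detection_class, detections.tool,
            ])


def read_detections(path, tool: Optional[str] = None) -> DetectionSet:
    members: set[Detection] = set()
    tools: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            tools.add(row["tool"])
            members.add(
                Detection(
                    variant_key=(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    proband_id=row["proband"],
                    gene=row["gene"],
                    inheritance=row["inheritance"],
                    consequence_group=row["consequence_group"],
                    detection_class=row["detection_class"],
                )
            )
    name = tool if tool is not None else (tools.pop() if len(tools) == 1 else "unknown")
    return DetectionSet(tool=name, members=frozenset(members))


# ---------------------------------------------------------------------------
# Flat per-trio variant table (pipeline stage artifact)
# ---------------------------------------------------------------------------

_VTABLE_COLS = [
    "chrom", "pos", "ref", "alt", "family", "proband", "proband_sex",
    "proband_gt", "father_gt", "mother_gt", "filter", "pop_af",
    "consequence", "gene",
] + list(_SCORE_COLUMNS)


def _fmt_gt(call: SampleCall) -> str:
    if call.genotype is None:
        return "."
    return "/".join(str(a) for a in call.genotype)


def _parse_gt(text: str) -> Optional[tuple[int, ...]]:
    if text in (".", "./.", ""):
        return None
    return tuple(int(a) for a in text.replace("|", "/").split("/"))


def _variant_row(v: AnnotatedVariant) -> list:
    row = [
        v.chrom, v.pos, v.ref, ",".join(v.alts),
        v.trio.family_id, v.trio.proband_id, v.trio.proband_sex,
        _fmt_gt(v.call(v.trio.proband_id)),
        _fmt_gt(v.call(v.trio.father_id)),
        _fmt_gt(v.call(v.trio.mother_id)),
        ";".join(sorted(v.filter_flags)),
        "" if v.pop_af is None else f"{v.pop_af:.6g}",
        v.consequence or "", v.gene or "",
    ]
    for col in _SCORE_COLUMNS:
        val = getattr(v.scores, col)
        row.append("" if val is None else f"{val:.6g}")
    return row


def write_variant_table(records: Iterable[AnnotatedVariant], path) -> int:
    """Serialize per-trio variant records (post-QC stage artifact).

    Depth/GQ are intentionally dropped: QC has already consumed them.
    Returns the number of rows written.
    """
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VTABLE_COLS)
        for v in records:
            w.writerow(_variant_row(v))
            n += 1
    return n


def _read_vtable_rows(path, pedigrees, extra_cols=()):
    by_proband = {t.proband_id: t for t in pedigrees}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            trio = by_proband.get(row["proband"])
            if trio is None:
                raise ParseError(f"{path}: row {i}: proband {row['proband']!r} not in pedigree")
            scores = {}
            for col in _SCORE_COLUMNS:
                cell = (row.get(col) or "").strip()
                if cell:
                    scores[col] = float(cell)
            calls = {
                trio.proband_id: SampleCall(genotype=_parse_gt(row["proband_gt"])),
                trio.father_id: SampleCall(genotype=_parse_gt(row["father_gt"])),
                trio.mother_id: SampleCall(genotype=_parse_gt(row["mother_gt"])),
            }
            v = AnnotatedVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alts=tuple(row["alt"].split(",")),
                trio=trio,
                calls=calls,
                filter_flags=frozenset(f for f in row["filter"].split(";") if f),
                pop_af=float(row["pop_af"]) if row["pop_af"] else None,
                consequence=row["consequence"] or None,
                gene=row["gene"] or None,
                scores=ScorePanel(**scores),
            )
            yield v, {c: row[c] for c in extra_cols}


def write_call_table(pairs, path) -> int:
    """Serialize (variant, inheritance-call) pairs: variant table plus a
    ``category`` column.  Returns the number of rows written."""
    from .models import InheritanceCall  # local: avoid import cycle at module load

    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VTABLE_COLS + ["category"])
        for v, call in pairs:
            row = _variant_row(v) + [call.category]
            w.writerow(row)
            n += 1
    return n


def read_call_table(path, pedigrees: list[TrioPedigree]):
    """Re-hydrate (variant, inheritance-call) pairs from :func:`write_call_table`."""
    from .models import InheritanceCall

    for v, extra in _read_vtable_rows(path, pedigrees, extra_cols=("category",)):
        yield v, InheritanceCall(extra["category"], v.trio.proband_id, v.key)


def read_variant_table(path, pedigrees: list[TrioPedigree]) -> Iterator[AnnotatedVariant]:
    """Re-hydrate per-trio variant records written by :func:`write_variant_table`."""
    for v, _ in _read_vtable_rows(path, pedigrees):
        yield v
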