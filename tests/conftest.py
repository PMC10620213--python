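"""Shared fixtures: variant builders and a small simulated cohort."""
from __future__ import annotations

import pytest

from trioprio.models import AnnotatedVariant, SampleCall, ScorePanel, TrioPedigree
from trioprio.synthetic import SimConfig, simulate_cohort

TRIO = TrioPedigree(
    family_id="F1", proband_id="P1", father_id="FA1", mother_id="MO1",
    proband_sex="male",
)
TRIO_F = TrioPedigree(
    family_id="F2", proband_id="P2", father_id="FA2", mother_id="MO2",
    proband_sex="female",
)


def gt(text: str) -> SampleCall:
    """Build a SampleCall from a compact string like '0/1', '1', '.'."""
    if text == ".":
        return SampleCall(genotype=None, depth=50, gq=99)
    alleles = tuple(int(a) for a in text.replace("|", "/").split("/"))
    return SampleCall(genotype=alleles, depth=50, gq=99)


def mk_variant(
    proband="0/1", father="0/0", mother="0/0", *,
    chrom="7", pos=1000, ref="A", alts=("G",), trio=TRIO,
    consequence="missense_variant", gene="G000001", pop_af=0.0001,
    scores=None, filter_flags=frozenset(), calls=None,
) -> AnnotatedVariant:
    """One-line AnnotatedVariant builder used across the unit tests."""
    if calls is None:
        calls = {
            trio.proband_id: proband if isinstance(proband, SampleCall) else gt(proband),
            trio.father_id: father if isinstance(father, SampleCall) else gt(father),
            trio.mother_id: mother if isinstance(mother, SampleCall) else gt(mother),
        }
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), trio=trio, calls=calls,
        filter_flags=filter_flags, pop_af=pop_af, consequence=consequence,
        gene=gene, scores=scores or ScorePanel(),
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-trio simulated cohort shared by I/O and pipeline tests."""
    outdir = tmp_path_factory.mktemp("cohort12")
    return simulate_cohort(SimConfig(n_trios=12, seed=42), outdir)
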