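"""SNP effect classification against gene models.

Each biallelic SNP is classified per overlapping transcript as noncoding,
synonymous, missense, nonsense or stop_loss by substituting the alternate
base into the reference codon under the universal genetic code.  A SNP may
carry several annotations (one per transcript) — e.g. intronic in one
transcript but exonic in an alternative transcript — and a precedence rule
collapses them to a single class for summary tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from . import codons
from .formats_io import GeneAnnotationSet, GenomicVariant, VariantTable
from .grantham import grantham_score  # noqa: F401  (re-exported module surface)

EFFECT_CLASSES = ("noncoding", "synonymous", "missense", "nonsense", "stop_loss", "unknown")

#: summary precedence: a premature stop outranks everything else
_PRECEDENCE = {
    "nonsense": 5,
    "stop_loss": 4,
    "missense": 3,
    "synonymous": 2,
    "noncoding": 1,
    "unknown": 0,
}


@dataclass
class EffectAnnotation:
    variant_id: str
    transcript_id: str | None
    effect: str
    codon_index: int | None = None  # 0-based within CDS
    codon_position: int | None = None  # 1..3
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_coding(self) -> bool:
        return self.effect in ("synonymous", "missense", "nonsense", "stop_loss")

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect in ("missense", "nonsense", "stop_loss")


def classify_codon_change(ref_codon: str, alt_codon: str) -> str:
    """Effect class of a ref->alt codon substitution under the standard code."""
    ref_aa = codons.translate_codon(ref_codon)
    alt_aa = codons.translate_codon(alt_codon)
    if ref_aa == "*" and alt_aa == "*":
        return "unknown"  # stop-to-stop inside a flagged model
    if ref_aa == "*":
        return "stop_loss"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def classify_variant(
    v: GenomicVariant, genes: GeneAnnotationSet
) -> list[EffectAnnotation]:
    """One annotation per overlapping transcript; noncoding if none overlap.

    Minus-strand variants are complemented before the codon substitution.
    Variants inside flagged (partial / internal-stop) transcripts get class
    ``unknown`` and are excluded from codon-level summaries downstream.
    """
    annotations: list[EffectAnnotation] = []
    for model in genes.overlapping(v.chrom, v.pos):
        if model.flagged:
            annotations.append(
                EffectAnnotation(v.variant_id, model.transcript_id, "unknown")
            )
            continue
        off = model.genome_to_cds(v.pos)
        if off is None:
            # within the transcript footprint but not in CDS: intronic here
            annotations.append(
                EffectAnnotation(v.variant_id, model.transcript_id, "noncoding")
            )
            continue
        codon_idx, pos_in_codon = divmod(off, 3)
        ref_codon = model.cds_seq[3 * codon_idx : 3 * codon_idx + 3]
        if model.strand == "+":
            ref_base, alt_base = v.ref, v.alt
        else:
            ref_base = codons.COMPLEMENT[v.ref]
            alt_base = codons.COMPLEMENT[v.alt]
        if ref_codon[pos_in_codon] != ref_base:
            annotations.append(
                EffectAnnotation(v.variant_id, model.transcript_id, "unknown")
            )
            continue
        alt_codon = (
            ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1 :]
        )
        effect = classify_codon_change(ref_codon, alt_codon)
        annotations.append(
            EffectAnnotation(
                v.variant_id,
                model.transcript_id,
                effect,
                codon_index=codon_idx,
                codon_position=pos_in_codon + 1,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=codons.translate_codon(ref_codon),
                alt_aa=codons.translate_codon(alt_codon),
            )
        )
    if not annotations:
        annotations.append(EffectAnnotation(v.variant_id, None, "noncoding"))
    return annotations


def effect_precedence(annotations: list[EffectAnnotation]) -> str:
    """Single summary class: nonsense > stop_loss > missense > synonymous > noncoding."""
    if not annotations:
        raise ValueError("effect_precedence requires at least one annotation")
    return max(annotations, key=lambda a: _PRECEDENCE[a.effect]).effect


def ts_tv_ratio(variants: VariantTable) -> float:
    """Transition/transversion ratio; inf when there are no transversions."""
    if not variants.records:
        raise ValueError("empty variant table")
    ts = sum(1 for v in variants.records if codons.is_transition(v.ref, v.alt))
    tv = len(variants.records) - ts
    if tv == 0:
        return float("inf")
    return ts / tv


def codon_position_distribution(
    annotations: list[EffectAnnotation],
) -> dict[int, int]:
    """Counts of coding annotations by position within codon (1, 2, 3)."""
    counts = Counter(
        a.codon_position for a in annotations if a.is_coding and a.codon_position
    )
    return {p: counts.get(p, 0) for p in (1, 2, 3)}


def annotations_to_rows(annotations: list[EffectAnnotation]) -> list[dict]:
    """Flatten annotations for TSV output (one row per variant, transcript)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "variant_id": a.variant_id,
                "transcript_id": a.transcript_id or ".",
                "effect": a.effect,
                "codon_index": a.codon_index if a.codon_index is not None else ".",
                "codon_position": a.codon_position if a.codon_position is not None else ".",
                "ref_codon": a.ref_codon or ".",
                "alt_codon": a.alt_codon or ".",
                "ref_aa": a.ref_aa or ".",
                "alt_aa": a.alt_aa or ".",
                "grantham": (
                    grantham_score(a.ref_aa, a.alt_aa)
                    if a.effect == "missense"
                    else "."
                ),
            }
        )
    return rows
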