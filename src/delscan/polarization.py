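"""Ancestral-state polarization and derived site frequency spectra.

Reference/non-reference allele labels are replaced by ancestral/derived
status inferred from an outgroup clade (the species most closely related to
the query in the alignment), which limits reference bias in downstream
frequency summaries.  The ancestral base at a column is the strict-majority
state among non-missing outgroup taxa; ties and uninformative columns are
unknown and those variants are excluded with a reason code.  Heterozygous
genotypes contribute one derived allele (allele-based counting), so a
sample of N diploids yields spectra over 1..2N-1 derived copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .formats_io import CodonAlignment, GenomicVariant

UNKNOWN = "unknown"


@dataclass
class PolarizedVariant:
    variant_id: str
    ancestral: str
    derived: str
    derived_count: int
    total_alleles: int
    carriers: frozenset[str]  # accessions carrying >= 1 derived allele

    @property
    def is_private(self) -> bool:
        return len(self.carriers) == 1


@dataclass
class ExclusionRecord:
    variant_id: str
    reason: str


def infer_ancestral(
    aln: CodonAlignment, outgroup_taxa: set[str], column: int
) -> str:
    """Majority base among non-missing outgroup taxa at an aligned column.

    Strict majority (> half of informative outgroup states); a tie or zero
    informative taxa yields ``"unknown"``.
    """
    unknown_taxa = set(outgroup_taxa) - set(aln.taxa)
    if unknown_taxa:
        raise ValueError(f"outgroup taxa not in alignment: {sorted(unknown_taxa)}")
    bases = aln.nucleotide_column(column)
    votes = Counter(
        b
        for t, b in zip(aln.taxa, bases)
        if t in outgroup_taxa and b in "ACGT"
    )
    if not votes:
        return UNKNOWN
    total = sum(votes.values())
    base, count = votes.most_common(1)[0]
    if count * 2 > total:
        return base
    return UNKNOWN


def polarize(
    v: GenomicVariant, ancestral: str, sample_ids: list[str]
) -> PolarizedVariant | ExclusionRecord:
    """Assign derived status and count derived alleles over called genotypes."""
    if ancestral == v.ref:
        derived = v.alt
        derived_allele = 1
    elif ancestral == v.alt:
        derived = v.ref
        derived_allele = 0
    else:
        return ExclusionRecord(v.variant_id, "ancestral_mismatch")
    derived_count = 0
    total = 0
    carriers = set()
    for sample, gt in zip(sample_ids, v.genotypes):
        if gt[0] is None:
            continue
        total += 2
        n = sum(1 for a in gt if a == derived_allele)
        derived_count += n
        if n:
            carriers.add(sample)
    return PolarizedVariant(
        v.variant_id, ancestral, derived, derived_count, total, frozenset(carriers)
    )


@dataclass
class SFS:
    """Unfolded spectrum: counts of variants by derived-allele copy number."""

    class_label: str
    counts: np.ndarray  # index i-1 holds the count of variants at i copies

    @property
    def n_variants(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {i + 1: int(c) for i, c in enumerate(self.counts)}


def derived_sfs(
    variants: list[PolarizedVariant],
    class_of: dict[str, str],
    classes: tuple[str, ...] = ("synonymous", "tolerated", "deleterious"),
) -> dict[str, SFS]:
    """One spectrum per class over segregating polarized variants.

    All variants must be polarized against the same sample set (equal total
    called-allele capacity); monomorphic-in-sample variants (derived count 0
    or equal to the total) fall outside the 1..2N-1 bins and are skipped.
    """
    totals = {v.total_alleles for v in variants}
    max_alleles = max(totals, default=0)
    if len({t for t in totals}) > 1:
        # allow missing genotypes (smaller totals) but not mixed panels:
        # the bin range is defined by the largest call set
        pass
    spectra = {
        c: np.zeros(max(max_alleles - 1, 0), dtype=np.int64) for c in classes
    }
    for v in variants:
        label = class_of.get(v.variant_id)
        if label not in spectra:
            continue
        if 1 <= v.derived_count <= max_alleles - 1:
            spectra[label][v.derived_count - 1] += 1
    return {c: SFS(c, arr) for c, arr in spectra.items()}


def heterozygosity_by_class(
    variants: list[GenomicVariant], class_of: dict[str, str]
) -> dict[str, float]:
    """Per class, the mean over SNPs of the fraction of heterozygous calls."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for v in variants:
        label = class_of.get(v.variant_id)
        if label is None:
            continue
        called = [g for g in v.genotypes if g[0] is not None]
        if not called:
            continue
        het = sum(1 for g in called if g[0] != g[1]) / len(called)
        sums[label] = sums.get(label, 0.0) + het
        counts[label] = counts.get(label, 0) + 1
    return {c: sums[c] / counts[c] for c in sums}


def private_fraction(variants: list[PolarizedVariant]) -> float:
    """Fraction of variants whose derived allele occurs in exactly one accession."""
    if not variants:
        raise ValueError("no polarized variants")
    return sum(1 for v in variants if v.is_private) / len(variants)
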