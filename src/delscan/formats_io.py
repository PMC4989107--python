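"""Readers and writers for the external formats the toolkit touches.

Coordinate conventions: every external format is 1-based inclusive (VCF and
GFF3 convention); every internal index is 0-based half-open.  Conversion
happens only here, at the I/O boundary.

Formats handled:

* VCF v4.x        -> :class:`VariantTable` (biallelic SNPs only)
* GFF3 + FASTA    -> :class:`GeneAnnotationSet` (spliced, strand-aware CDS)
* aligned FASTA   -> :class:`CodonAlignment` (61 sense-codon states)
* Newick          -> :class:`Phylogeny` (branch lengths required)
* genetic-map TSV -> :class:`GeneticMap` (columns: marker, chrom, bp, cM)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from pyfaidx import Fasta

from . import codons

logger = logging.getLogger("delscan")

Genotype = tuple[int | None, int | None]


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass
class GenomicVariant:
    """One biallelic SNP with unphased diploid genotypes per accession."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: tuple[Genotype, ...]

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")


@dataclass
class VariantTable:
    records: list[GenomicVariant]
    sample_ids: list[str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, GenomicVariant]:
        return {v.variant_id: v for v in self.records}


def _normalize_gt(gt) -> Genotype:
    """Unphased diploid genotype; any half-call or non-diploid call is missing."""
    if gt is None or len(gt) != 2 or None in gt:
        return (None, None)
    return (int(gt[0]), int(gt[1]))


def read_variants(path: str) -> VariantTable:
    """Read a VCF, keeping only biallelic SNP records.

    Multiallelic records and indels/MNPs are dropped (counted in
    ``n_dropped``).  Raises ValueError on a record without a GT call or on a
    position-unsorted file.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    records: list[GenomicVariant] = []
    dropped = 0
    last: dict[str, int] = {}
    for rec in vf:
        if rec.chrom in last and rec.pos < last[rec.chrom]:
            raise ValueError(
                f"VCF not sorted: {rec.chrom}:{rec.pos} after {last[rec.chrom]}"
            )
        last[rec.chrom] = rec.pos
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            dropped += 1
            continue
        if rec.ref.upper() not in "ACGT" or alts[0].upper() not in "ACGT":
            dropped += 1
            continue
        gts = []
        for s in samples:
            sample = rec.samples[s]
            if "GT" not in sample:
                raise ValueError(f"record {rec.chrom}:{rec.pos} has no GT field")
            gts.append(_normalize_gt(sample["GT"]))
        records.append(
            GenomicVariant(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper(), tuple(gts))
        )
    if dropped:
        logger.info("read_variants: dropped %d non-biallelic-SNP records", dropped)
    return VariantTable(records, samples, n_dropped=dropped)


def write_variants(table: VariantTable, path: str) -> None:
    """Write a VariantTable as minimal VCF v4.2 (GT only, round-trip safe)."""
    chroms = []
    for v in table.records:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for v in table.records:
            gt_strs = [
                "./." if g[0] is None else f"{g[0]}/{g[1]}" for g in v.genotypes
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A transcript's CDS: ordered intervals plus the spliced sequence.

    ``intervals`` are 1-based inclusive genome coordinates in *translation*
    order (descending start for minus-strand genes).  ``cds_seq`` is the
    spliced coding sequence after reverse-complementing minus-strand exons
    and trimming ``phase_offset`` leading bases.
    """

    transcript_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    cds_seq: str
    phase_offset: int = 0
    flagged: bool = False
    flag_reason: str = ""

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive genomic footprint of the CDS intervals."""
        starts = [s for s, _ in self.intervals]
        ends = [e for _, e in self.intervals]
        return min(starts), max(ends)

    def genome_to_cds(self, pos: int) -> int | None:
        """0-based offset into the (phase-trimmed) spliced CDS, or None."""
        off = 0
        for start, end in self.intervals:
            if start <= pos <= end:
                if self.strand == "+":
                    off += pos - start
                else:
                    off += end - pos
                off -= self.phase_offset
                return off if off >= 0 else None
            off += end - start + 1
        return None

    def overlaps(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi


@dataclass
class GeneAnnotationSet:
    models: dict[str, GeneModel]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        return [
            m
            for m in self.models.values()
            if m.chrom == chrom and m.overlaps(pos)
        ]


def read_gene_models(gff3_path: str, fasta_path: str) -> GeneAnnotationSet:
    """Build gene models from GFF3 CDS features plus a genome FASTA.

    Minus-strand CDS are reverse-complemented and spliced in translation
    order; the GFF3 phase column of the translation-first CDS segment trims
    partial first codons.  Transcripts whose spliced CDS length is not a
    multiple of 3, or which contain an internal stop, are kept but flagged
    and excluded from codon-level operations downstream.
    """
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome = Fasta(fasta_path)
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        for parent in feat.attributes.get("Parent", []):
            by_parent.setdefault(parent, []).append(feat)

    models: dict[str, GeneModel] = {}
    for tx_id, feats in by_parent.items():
        chrom = feats[0].seqid
        strand = feats[0].strand
        feats = sorted(feats, key=lambda f: f.start, reverse=(strand == "-"))
        intervals = [(f.start, f.end) for f in feats]
        pieces = []
        for f in feats:
            seq = str(genome[chrom][f.start - 1 : f.end]).upper()
            if strand == "-":
                seq = codons.reverse_complement(seq)
            pieces.append(seq)
        spliced = "".join(pieces)
        phase = feats[0].frame
        phase_offset = int(phase) if phase in ("0", "1", "2") else 0
        spliced = spliced[phase_offset:]
        flagged, reason = False, ""
        if len(spliced) % 3 != 0:
            flagged, reason = True, "cds_length_not_multiple_of_3"
            logger.warning("transcript %s flagged: %s", tx_id, reason)
        else:
            protein = "".join(
                codons.translate_codon(spliced[i : i + 3])
                for i in range(0, len(spliced), 3)
            )
            if "*" in protein[:-1]:
                flagged, reason = True, "internal_stop"
                logger.warning("transcript %s flagged: %s", tx_id, reason)
        models[tx_id] = GeneModel(
            tx_id, chrom, strand, intervals, spliced, phase_offset, flagged, reason
        )
    return GeneAnnotationSet(models)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

class CodonAlignment:
    """A species-by-codon-column matrix for one gene.

    States are sense-codon indices (0..60) or ``codons.MISSING``: any gap,
    N, IUPAC ambiguity or stop codon renders the whole codon missing for
    that taxon.  The designated query taxon is the species whose variants
    are being tested; helpers map its ungapped codon/nucleotide coordinates
    into alignment columns.
    """

    def __init__(self, taxa: list[str], seqs: list[str], query_taxon: str):
        if query_taxon not in taxa:
            raise ValueError(f"query taxon {query_taxon!r} not in alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        if len(taxa) != len(set(taxa)):
            raise ValueError("duplicate taxon labels")
        self.taxa = list(taxa)
        self.query_taxon = query_taxon
        self.aligned_seqs = [s.upper() for s in seqs]
        self.n_codons = length // 3
        n_stop = 0
        mat = np.full((len(taxa), self.n_codons), codons.MISSING, dtype=np.int16)
        for t, seq in enumerate(self.aligned_seqs):
            for c in range(self.n_codons):
                codon = seq[3 * c : 3 * c + 3]
                state = codons.encode_codon(codon)
                if state == codons.MISSING and "-" not in codon and codon in codons.STOP_CODONS:
                    n_stop += 1
                mat[t, c] = state
        if n_stop:
            logger.info("alignment: %d stop codons treated as missing", n_stop)
        self.matrix = mat
        self._query_index = self.taxa.index(query_taxon)
        self._build_query_maps()

    def _build_query_maps(self):
        qseq = self.aligned_seqs[self._query_index]
        # ungapped nucleotide position -> alignment column
        self.query_nuc_columns = np.array(
            [i for i, b in enumerate(qseq) if b != "-"], dtype=np.int64
        )
        # ungapped query codon index -> alignment codon column (codon-aware
        # alignments only; partially gapped query codons are unmappable)
        col_map: dict[int, int] = {}
        k = 0
        for c in range(self.n_codons):
            triplet = qseq[3 * c : 3 * c + 3]
            gaps = triplet.count("-")
            if gaps == 0:
                col_map[k] = c
                k += 1
            elif gaps < 3:
                k += sum(1 for b in triplet if b != "-") // 3
        self.query_codon_column = col_map

    @property
    def query_index(self) -> int:
        return self._query_index

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(label)

    def column_states(self, codon_column: int) -> np.ndarray:
        if not 0 <= codon_column < self.n_codons:
            raise IndexError(f"codon column {codon_column} out of range")
        return self.matrix[:, codon_column]

    def nucleotide_column(self, column: int) -> list[str]:
        """Per-taxon base (or gap) at an aligned nucleotide column."""
        if not 0 <= column < 3 * self.n_codons:
            raise IndexError(f"nucleotide column {column} out of range")
        return [s[column] for s in self.aligned_seqs]

    def query_nuc_to_column(self, ungapped_pos: int) -> int:
        """Aligned nucleotide column for a 0-based ungapped query position."""
        if not 0 <= ungapped_pos < len(self.query_nuc_columns):
            raise IndexError(f"query position {ungapped_pos} outside sequence")
        return int(self.query_nuc_columns[ungapped_pos])

    def n_informative(self, codon_column: int, exclude_query: bool = True) -> int:
        states = self.column_states(codon_column)
        mask = states != codons.MISSING
        if exclude_query:
            mask = mask.copy()
            mask[self._query_index] = False
        return int(mask.sum())


def read_alignment(path: str, query_taxon: str) -> CodonAlignment:
    """Read an aligned FASTA of in-frame CDS sequences."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return CodonAlignment(taxa, seqs, query_taxon)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A fixed species tree with branch lengths in substitutions per codon site."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise ValueError("negative branch length")
        self.tree = tree
        self.tip_labels = labels

    @property
    def total_length(self) -> float:
        return sum(
            e.length
            for e in self.tree.preorder_edge_iter()
            if e.length is not None
        )

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)


def read_tree(path: str) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered markers per chromosome: physical (bp) and genetic (cM) position."""

    table: pd.DataFrame  # columns: marker, chrom, bp, cM
    n_duplicates_dropped: int = 0

    def chromosomes(self) -> list[str]:
        return list(self.table["chrom"].unique())

    def markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def read_genetic_map(path: str) -> GeneticMap:
    """Read a marker map TSV with header columns marker, chrom, bp, cM.

    Markers are sorted by bp within each chromosome; duplicate bp positions
    keep the first occurrence (logged).  Non-numeric bp/cM raise ValueError
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "chrom", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"genetic map must have columns {sorted(required)}")
    for col in ("bp", "cM"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"non-numeric {col} at line {line}")
        df[col] = parsed
    df["bp"] = df["bp"].astype(np.int64)
    df = df.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
    before = len(df)
    df = df.drop_duplicates(subset=["chrom", "bp"], keep="first").reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.warning("genetic map: %d duplicate-bp markers dropped", dropped)
    return GeneticMap(df, n_duplicates_dropped=dropped)
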