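"""End-to-end validation on the simulated toy genome.

Runs the full pipeline — effect annotation, per-codon constraint LRT on
simulated homolog alignments, consensus with synthetic SIFT-like and
PolyPhen2-like verdicts, ancestral polarization with frequency spectra, and
the recombination-rate overlay — entirely from generated fixtures, and
returns the bookkeeping needed to check that every stage conserves its
inputs and recovers the planted truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codons
from .formats_io import GeneticMap, read_gene_models, read_variants
from .intersect import combine_predictions
from .lrt import GeneLRT, allele_novelty, bonferroni_threshold, call_deleterious
from .polarization import (
    ExclusionRecord,
    PolarizedVariant,
    derived_sfs,
    infer_ancestral,
    polarize,
)
from .recomb import interval_rates, overlay_deleterious
from .simulate import random_tree, simulate_gene_alignment, simulate_toy_genome
from .variant_effects import classify_variant, effect_precedence

#: genomic positions planted in strongly constrained codons (site omega ~ 0);
#: the pipeline is expected to call exactly these deleterious
INTENDED_DELETERIOUS_POSITIONS = (133, 498)

CONSTRAINED_OMEGA = 1e-3
NONSYN_EFFECTS = ("missense", "nonsense", "stop_loss")


@dataclass
class ToyPipelineResult:
    truth: pd.DataFrame
    predicted_class: dict[str, str]
    class_matches: int
    n_variants: int
    consensus_deleterious: set[str]
    intended_deleterious: set[str]
    n_codons_tested: int
    threshold: float
    lrt_verdicts: dict[str, str]
    # conservation ledgers
    n_polarized: int
    n_excluded_polarization: int
    n_coding_for_polarization: int
    sfs_totals: dict[str, int]
    n_segregating_by_class: dict[str, int]
    n_nonsyn_in_intervals: int
    n_nonsyn_out_of_map: int
    n_nonsyn_total: int

    @property
    def class_recovery(self) -> float:
        return self.class_matches / self.n_variants

    @property
    def consensus_exact(self) -> bool:
        return self.consensus_deleterious == self.intended_deleterious


def run_toy_pipeline(seed: int = 0, n_samples: int = 4) -> ToyPipelineResult:
    rng = np.random.default_rng(seed)
    bundle = simulate_toy_genome(n_samples=n_samples, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        paths = bundle.write(tmp)
        genes = read_gene_models(paths["genes.gff3"], paths["genome.fasta"])
        variants = read_variants(paths["variants.vcf"])

    truth = bundle.truth
    expected = dict(zip(truth["variant_id"], truth["expected_class"]))

    # --- stage 1: effect annotation against the gene models
    annotations = {
        v.variant_id: classify_variant(v, genes) for v in variants.records
    }
    predicted = {vid: effect_precedence(anns) for vid, anns in annotations.items()}
    matches = sum(predicted[vid] == expected[vid] for vid in expected)

    intended = {
        v.variant_id
        for v in variants.records
        if v.pos in INTENDED_DELETERIOUS_POSITIONS
    }
    # variant -> (transcript, annotation) for its first coding annotation
    coding_hits: dict[str, tuple] = {}
    for vid, anns in annotations.items():
        for a in anns:
            if a.is_coding and a.codon_index is not None:
                coding_hits[vid] = (a.transcript_id, a)
                break

    # --- stage 2: constraint LRT on simulated homolog alignments.  The
    # species tree is deep (30 taxa, total length 18 substitutions/site) so
    # constrained codons carry decisive evidence at the Bonferroni threshold.
    tree = random_tree(30, 18.0, seed=int(rng.integers(2**31)))
    query = tree.tip_labels[0]
    transcripts = sorted({tx for tx, _ in coding_hits.values()})
    gene_alns = {}
    gene_results = {}
    n_tested = 0
    for tx in transcripts:
        model = genes.models[tx]
        n_codons = len(model.cds_seq) // 3
        omegas = np.ones(n_codons)
        for vid, (tx2, a) in coding_hits.items():
            if tx2 == tx and vid in intended:
                omegas[a.codon_index] = CONSTRAINED_OMEGA
        aln = simulate_gene_alignment(
            model.cds_seq,
            tree,
            query,
            site_omega=omegas,
            kappa=2.0,
            seed=int(rng.integers(2**31)),
        )
        runner = GeneLRT(aln, tree, seed=int(rng.integers(2**31)))
        results = runner.test_all()
        gene_alns[tx] = aln
        gene_results[tx] = results
        n_tested += sum(1 for r in results if r.verdict != "untested")

    threshold = bonferroni_threshold(0.05, n_tested)
    site_results = {}
    for vid, (tx, a) in coding_hits.items():
        aln = gene_alns[tx]
        col = aln.query_codon_column.get(a.codon_index)
        if col is None:
            continue
        res = gene_results[tx][col]
        nuc_col = 3 * col + a.codon_position - 1
        res.novel = allele_novelty(
            aln,
            nuc_col,
            a.ref_codon[a.codon_position - 1],
            a.alt_codon[a.codon_position - 1],
        )
        site_results[vid] = (tx, a, res, nuc_col)
    lrt_verdicts = {
        vid: call_deleterious(res, threshold)
        for vid, (_, _, res, _) in site_results.items()
    }

    # --- stage 3: consensus with synthetic external prediction tables
    effect_of = predicted
    tables = {"lrt": {}, "sift": {}, "polyphen": {}}
    for vid, eff in effect_of.items():
        if eff not in NONSYN_EFFECTS:
            continue
        verdict = lrt_verdicts.get(vid, "tolerated")
        tables["lrt"][vid] = (
            "deleterious" if verdict == "deleterious" else "tolerated"
        )
        external = "deleterious" if vid in intended else "tolerated"
        tables["sift"][vid] = external
        tables["polyphen"][vid] = external
    consensus = combine_predictions(effect_of, tables)
    consensus_del = {
        vid for vid, c in consensus.items() if c.verdict == "deleterious"
    }

    # --- stage 4: ancestral polarization and class-stratified spectra
    outgroup = set(tree.tip_labels[-3:])
    polarized: list[PolarizedVariant] = []
    excluded: list[ExclusionRecord] = []
    n_coding = 0
    by_id = variants.by_id()
    for vid, (tx, a, res, nuc_col) in site_results.items():
        n_coding += 1
        aln = gene_alns[tx]
        model = genes.models[tx]
        anc_cds = infer_ancestral(aln, outgroup, nuc_col)
        if anc_cds == "unknown":
            excluded.append(ExclusionRecord(vid, "ancestral_unknown"))
            continue
        anc = anc_cds if model.strand == "+" else codons.COMPLEMENT[anc_cds]
        result = polarize(by_id[vid], anc, variants.sample_ids)
        if isinstance(result, PolarizedVariant):
            polarized.append(result)
        else:
            excluded.append(result)

    class_of = {}
    for pol in polarized:
        eff = effect_of[pol.variant_id]
        if eff == "synonymous":
            class_of[pol.variant_id] = "synonymous"
        elif eff in NONSYN_EFFECTS:
            class_of[pol.variant_id] = (
                "deleterious" if pol.variant_id in consensus_del else "tolerated"
            )
    spectra = derived_sfs(polarized, class_of)
    max_alleles = max((p.total_alleles for p in polarized), default=0)
    n_segregating = {c: 0 for c in spectra}
    for pol in polarized:
        label = class_of.get(pol.variant_id)
        if label in n_segregating and 1 <= pol.derived_count <= max_alleles - 1:
            n_segregating[label] += 1

    # --- stage 5: recombination overlay on a synthetic marker map
    gmap = GeneticMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4"],
                "chrom": ["chr1"] * 4,
                "bp": np.array([1, 300, 600, 1000], dtype=np.int64),
                "cM": [0.0, 0.001, 0.003, 0.0035],
            }
        )
    )
    nonsyn_ids = {vid for vid, e in effect_of.items() if e in NONSYN_EFFECTS}
    positions = {
        v.variant_id: (v.chrom, v.pos)
        for v in variants.records
        if v.variant_id in nonsyn_ids
    }
    iset = interval_rates(gmap)
    iset = overlay_deleterious(iset, positions, nonsyn_ids, consensus_del)
    n_in = sum(iv.n_nonsyn for iv in iset.intervals)

    return ToyPipelineResult(
        truth=truth,
        predicted_class=predicted,
        class_matches=matches,
        n_variants=len(expected),
        consensus_deleterious=consensus_del,
        intended_deleterious=intended,
        n_codons_tested=n_tested,
        threshold=threshold,
        lrt_verdicts=lrt_verdicts,
        n_polarized=len(polarized),
        n_excluded_polarization=len(excluded),
        n_coding_for_polarization=n_coding,
        sfs_totals={c: s.n_variants for c, s in spectra.items()},
        n_segregating_by_class=n_segregating,
        n_nonsyn_in_intervals=n_in,
        n_nonsyn_out_of_map=len(iset.out_of_map),
        n_nonsyn_total=len(nonsyn_ids),
    )
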