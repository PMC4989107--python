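"""Simulation harness: codon alignments with known per-site omega, random
trees, and a toy genome bundle (FASTA + GFF3 + VCF + truth table) that
exercises the whole pipeline without any external downloads.

Alignments evolve under exactly the engine's substitution model (root codon
from pi, branch transitions exp(rho t Q(omega_site))), so simulated data are
the calibration oracle for the constraint test.  All randomness flows from
one seed; per-gene streams are split from it so results do not depend on
gene order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codons
from .formats_io import CodonAlignment, Phylogeny
from .lrt import (
    CodonModelParams,
    GeneLRT,
    _eig_transition_factory,
    bonferroni_threshold,
)


def uniform_pi() -> np.ndarray:
    return np.full(codons.N_STATES, 1.0 / codons.N_STATES)


@dataclass
class SimulationSpec:
    """Everything needed to evolve one codon alignment deterministically."""

    tree: Phylogeny
    kappa: float
    site_omega: np.ndarray  # one omega per codon site
    seed: int
    pi: np.ndarray | None = None  # None -> uniform over sense codons
    rho: float = 1.0
    query_taxon: str | None = None  # default: first tip
    root_states: np.ndarray | None = None  # fixed root codons (else drawn from pi)

    def __post_init__(self):
        self.site_omega = np.asarray(self.site_omega, dtype=float)
        if np.any(self.site_omega < 0):
            raise ValueError("site omegas must be nonnegative")

    @property
    def n_codons(self) -> int:
        return len(self.site_omega)


def random_tree(n_taxa: int, total_length: float, seed: int) -> Phylogeny:
    """Random bifurcating tree; branch lengths Exp(1), rescaled to total_length."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = [f"sp{i+1}" for i in range(n_taxa)]
    newicks = list(nodes)
    lengths = []

    def draw() -> float:
        x = float(rng.exponential(1.0))
        lengths.append(x)
        return x

    while len(newicks) > 1:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
        a, b = newicks[i], newicks[j]
        merged = f"({a}:{draw():.10f},{b}:{draw():.10f})"
        newicks = [s for k, s in enumerate(newicks) if k not in (i, j)]
        newicks.append(merged)
    newick = newicks[0] + ";"
    phylo = Phylogeny.from_newick(newick)
    scale = total_length / phylo.total_length
    for edge in phylo.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return phylo


def simulate_alignment(spec: SimulationSpec) -> CodonAlignment:
    """Evolve codons down the tree under the engine's model."""
    pi = spec.pi if spec.pi is not None else uniform_pi()
    params = CodonModelParams(spec.kappa, 1.0, spec.rho, np.asarray(pi))
    params.validate()
    n = spec.n_codons
    if n < 1:
        raise ValueError("need at least one codon site")
    rng = np.random.default_rng(spec.seed)

    unique_omegas = np.unique(spec.site_omega)
    groups = {w: np.nonzero(spec.site_omega == w)[0] for w in unique_omegas}
    factories = {w: _eig_transition_factory(params, w) for w in unique_omegas}

    tree = spec.tree.tree
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    if spec.root_states is not None:
        root_states = np.asarray(spec.root_states, dtype=np.int64)
        if root_states.shape != (n,):
            raise ValueError("root_states length must match site_omega")
        states[id(root)] = root_states
    else:
        states[id(root)] = rng.choice(codons.N_STATES, size=n, p=params.pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_states = states[id(node.parent_node)]
        t = spec.rho * float(node.edge.length)
        child = np.empty(n, dtype=np.int64)
        for w, idx in groups.items():
            p = factories[w](t)
            cum = np.cumsum(p, axis=1)
            u = rng.random(len(idx))
            rows = cum[parent_states[idx]]
            child[idx] = np.minimum(
                (u[:, None] > rows).sum(axis=1), codons.N_STATES - 1
            )
        states[id(node)] = child

    taxa, seqs = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append(
            "".join(codons.SENSE_CODONS[s] for s in states[id(leaf)])
        )
    query = spec.query_taxon or taxa[0]
    return CodonAlignment(taxa, seqs, query)


def simulate_gene_alignment(
    cds: str,
    tree: Phylogeny,
    query_taxon: str,
    site_omega,
    kappa: float = 2.0,
    seed: int = 0,
    rho: float = 1.0,
) -> CodonAlignment:
    """A homolog alignment for one gene, rooted at the gene's own CDS.

    The other species evolve from the CDS codons under the given per-site
    omegas; the query row is then the exact CDS, as a real homolog search
    would return it.  Used to exercise the LRT stage on planted genes.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    states = []
    for i in range(0, len(cds), 3):
        s = codons.encode_codon(cds[i : i + 3])
        if s == codons.MISSING and cds[i : i + 3] not in codons.STOP_CODONS:
            raise ValueError(f"unencodable codon {cds[i:i+3]!r} at {i}")
        states.append(s if s != codons.MISSING else codons.encode_codon("AAA"))
    if query_taxon not in tree.tip_labels:
        raise ValueError(f"{query_taxon!r} not a tree tip")
    spec = SimulationSpec(
        tree=tree,
        kappa=kappa,
        site_omega=site_omega,
        seed=seed,
        rho=rho,
        query_taxon=query_taxon,
        root_states=np.asarray(states),
    )
    sim = simulate_alignment(spec)
    seqs = list(sim.aligned_seqs)
    qi = sim.taxa.index(query_taxon)
    seqs[qi] = cds.upper()
    return CodonAlignment(sim.taxa, seqs, query_taxon)


# ---------------------------------------------------------------------------
# Toy genome bundle
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    """In-memory FASTA/GFF3/VCF plus the planted-SNP truth table."""

    fasta: str
    gff3: str
    vcf: str
    truth: pd.DataFrame  # variant_id, chrom, pos, ref, alt, expected_class

    def write(self, outdir: str) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, content in (
            ("genome.fasta", self.fasta),
            ("genes.gff3", self.gff3),
            ("variants.vcf", self.vcf),
        ):
            path = os.path.join(outdir, name)
            with open(path, "w") as fh:
                fh.write(content)
            paths[name] = path
        truth_path = os.path.join(outdir, "truth.tsv")
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth.tsv"] = truth_path
        return paths


_FILLER_CODONS = [
    c
    for c in codons.SENSE_CODONS
    # avoid codons one substitution away from a stop so random filler cannot
    # collide with planted nonsense changes when edited
    if c not in ("TGG",)
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(_FILLER_CODONS), size=n_codons)
    return [_FILLER_CODONS[i] for i in idx]


def simulate_toy_genome(n_samples: int = 4, seed: int = 0) -> ToyGenome:
    """A small single-chromosome genome with planted SNPs of every class.

    Layout (1-based genomic coordinates on "chr1"):

    * geneA (+): two CDS exons 101-160 / 201-260, with planted synonymous,
      missense, nonsense and stop-loss SNPs plus an intronic SNP.
    * geneB (-): single CDS exon 401-520 with a planted missense SNP
      (complemented genomic alleles).
    * geneC: two transcripts sharing exon 701-760; tx1 adds 801-860.  A SNP
      at 750 is exonic in both; a SNP at 820 is exonic in tx1 but intronic
      in tx2 (whose CDS resumes only via its own second exon 831-860).
    * one intergenic SNP.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)
    genome = list("ACGT"[i] for i in rng.integers(0, 4, size=1000))

    def place(start: int, seq: str):
        genome[start - 1 : start - 1 + len(seq)] = list(seq)

    # --- geneA (+): 20 codons exon1, 20 codons exon2, ends with TAA stop
    a1 = _random_cds(rng, 20)
    a2 = _random_cds(rng, 19) + ["TAA"]
    a1[0] = "ATG"
    a1[5] = "GGT"   # -> GGC synonymous at codon pos 3 (genomic 118)
    a1[10] = "ATG"  # -> ATA missense Met->Ile at pos 3 (genomic 133)
    a2[3] = "TGG"   # -> TAG nonsense Trp->stop at pos 2 (genomic 211)
    place(101, "".join(a1))
    place(201, "".join(a2))
    # stop-loss: last codon TAA -> CAA at pos 1 (genomic 258)

    # --- geneB (-): 40 codons on the minus strand over genomic 401..520.
    b = _random_cds(rng, 40)
    b[0] = "ATG"
    b[7] = "CTT"  # -> CCT missense Leu->Pro at codon pos 2
    place(401, codons.reverse_complement("".join(b)))
    # codon 7 occupies CDS offsets 21..23; pos-in-codon 2 is offset 22 ->
    # genomic position 520 - 22 = 498; CDS base T => genomic base A, alt G.

    # --- geneC: tx1 exons 701-760 + 801-860; tx2 exons 701-760 + 831-860
    c1 = _random_cds(rng, 20)
    c1[0] = "ATG"
    c1[16] = "GAT"  # codon 16, pos 1 at genomic 749: G->A => AAT Asp->Asn missense
    c2 = _random_cds(rng, 20)
    c2[6] = "CAT"  # tx1 codon 26, pos 2 at genomic 820: A->G => CGT His->Arg
    place(701, "".join(c1))
    place(801, "".join(c2))
    fasta = ">chr1\n" + "".join(genome) + "\n"

    gff_rows = [
        "##gff-version 3",
        "chr1\ttoy\tgene\t101\t260\t.\t+\t.\tID=geneA",
        "chr1\ttoy\tmRNA\t101\t260\t.\t+\t.\tID=geneA.t1;Parent=geneA",
        "chr1\ttoy\tCDS\t101\t160\t.\t+\t0\tID=geneA.t1.cds;Parent=geneA.t1",
        "chr1\ttoy\tCDS\t201\t260\t.\t+\t0\tID=geneA.t1.cds;Parent=geneA.t1",
        "chr1\ttoy\tgene\t401\t520\t.\t-\t.\tID=geneB",
        "chr1\ttoy\tmRNA\t401\t520\t.\t-\t.\tID=geneB.t1;Parent=geneB",
        "chr1\ttoy\tCDS\t401\t520\t.\t-\t0\tID=geneB.t1.cds;Parent=geneB.t1",
        "chr1\ttoy\tgene\t701\t860\t.\t+\t.\tID=geneC",
        "chr1\ttoy\tmRNA\t701\t860\t.\t+\t.\tID=geneC.t1;Parent=geneC",
        "chr1\ttoy\tCDS\t701\t760\t.\t+\t0\tID=geneC.t1.cds;Parent=geneC.t1",
        "chr1\ttoy\tCDS\t801\t860\t.\t+\t0\tID=geneC.t1.cds;Parent=geneC.t1",
        "chr1\ttoy\tmRNA\t701\t860\t.\t+\t.\tID=geneC.t2;Parent=geneC",
        "chr1\ttoy\tCDS\t701\t760\t.\t+\t0\tID=geneC.t2.cds;Parent=geneC.t2",
        "chr1\ttoy\tCDS\t831\t860\t.\t+\t0\tID=geneC.t2.cds;Parent=geneC.t2",
    ]
    gff3 = "\n".join(gff_rows) + "\n"

    def gbase(pos: int) -> str:
        return genome[pos - 1]

    planted = [
        # (pos, alt_base, expected per-SNP class under precedence)
        (118, "C", "synonymous"),
        (133, "A", "missense"),
        (211, "A", "nonsense"),
        (258, "C", "stop_loss"),
        (180, None, "noncoding"),   # geneA intron (161..200)
        (498, "G", "missense"),     # geneB minus strand
        (749, "A", "missense"),     # geneC shared exon
        (820, "G", "missense"),     # exonic in tx1, intronic in tx2
        (50, None, "noncoding"),    # intergenic
    ]
    rows = []
    vcf_lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"acc{i+1}" for i in range(n_samples)),
    ]
    for pos, alt, expected in sorted(planted):
        ref = gbase(pos)
        if alt is None:
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        assert alt != ref
        gts = ["1/1"] + [
            rng.choice(["0/0", "0/1", "1/1"]) for _ in range(n_samples - 1)
        ]
        vcf_lines.append(
            f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
        rows.append(
            {
                "variant_id": f"chr1:{pos}:{ref}:{alt}",
                "chrom": "chr1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "expected_class": expected,
            }
        )
    vcf = "\n".join(vcf_lines) + "\n"
    truth = pd.DataFrame(rows)
    return ToyGenome(fasta, gff3, vcf, truth)


# ---------------------------------------------------------------------------
# Calibration experiment
# ---------------------------------------------------------------------------

def calibration_experiment(
    tree: Phylogeny,
    kappa: float,
    omega_grid,
    n_sites: int,
    alpha: float,
    seed: int,
    pi: np.ndarray | None = None,
    min_species: int = 10,
) -> pd.DataFrame:
    """Rejection rates of the site test across a grid of true omegas.

    One alignment per omega with every site at that omega; each site is
    tested with the true generating parameters.  Reports the rejection rate
    at raw alpha and at the Bonferroni threshold (alpha over all sites in
    the grid), with 3-SD binomial intervals.  The grid must include the
    neutral value omega = 1.
    """
    omega_grid = [float(w) for w in omega_grid]
    if 1.0 not in omega_grid:
        raise ValueError("omega grid must include the neutral value 1.0")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    pi_arr = pi if pi is not None else uniform_pi()
    params = CodonModelParams(kappa, 1.0, 1.0, np.asarray(pi_arr))
    n_total_tests = n_sites * len(omega_grid)
    bonf = bonferroni_threshold(alpha, n_total_tests)
    rng = np.random.default_rng(seed)
    rows = []
    for w in omega_grid:
        spec = SimulationSpec(
            tree=tree,
            kappa=kappa,
            site_omega=np.full(n_sites, w),
            seed=int(rng.integers(0, 2**31 - 1)),
            pi=pi_arr,
        )
        aln = simulate_alignment(spec)
        runner = GeneLRT(aln, tree, params=params, min_species=min_species)
        pvals = np.array(
            [r.p_value for r in runner.test_all() if r.verdict != "untested"]
        )
        rate_alpha = float((pvals < alpha).mean()) if pvals.size else float("nan")
        rate_bonf = float((pvals < bonf).mean()) if pvals.size else float("nan")
        sd = np.sqrt(alpha * (1 - alpha) / max(len(pvals), 1))
        rows.append(
            {
                "omega": w,
                "n_tested": len(pvals),
                "rejection_rate_alpha": rate_alpha,
                "rejection_rate_bonferroni": rate_bonf,
                "alpha": alpha,
                "bonferroni_threshold": bonf,
                "ci3sd_low": alpha - 3 * sd,
                "ci3sd_high": alpha + 3 * sd,
                "seed": spec.seed,
            }
        )
    return pd.DataFrame(rows)
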