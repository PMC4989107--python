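"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the likelihood
oracle enumerates joint internal-node states explicitly (no pruning, no
partials) with transition probabilities from scipy's generic ``expm``; the
effect-class oracle is a direct lookup through Biopython's translation.
"""


import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm

from delscan import codons
from delscan.lrt import build_rate_matrix


def enumerate_loglik(aln, phylo, params, omega, col, exclude=frozenset()):
    """Sum the joint likelihood over every internal-node state assignment."""
    q = build_rate_matrix(params, omega)
    tree = phylo.tree
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if n.child_nodes()]
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    pmat = {
        id(n): expm(q * params.rho * float(n.edge.length))
        for n in nodes
        if n.parent_node is not None
    }
    k = len(internals)
    pos_of = {id(n): i for i, n in enumerate(internals)}
    assigns = np.indices((codons.N_STATES,) * k).reshape(k, -1).T
    prob = params.pi[assigns[:, pos_of[id(tree.seed_node)]]].astype(float)
    for n in nodes:
        if n.parent_node is None:
            continue
        parent_states = assigns[:, pos_of[id(n.parent_node)]]
        if n.child_nodes():
            prob *= pmat[id(n)][parent_states, assigns[:, pos_of[id(n)]]]
        else:
            label = n.taxon.label
            if label in row_of and label not in exclude:
                s = aln.matrix[row_of[label], col]
                if s != codons.MISSING:
                    prob *= pmat[id(n)][parent_states, s]
    return float(np.log(prob.sum()))


def effect_class_oracle(ref_codon: str, alt_codon: str) -> str:
    """Classify a single-base codon change by direct translation lookup."""
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == "*" and alt_aa == "*":
        return "unknown"
    if ref_aa == "*":
        return "stop_loss"
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


def all_single_base_changes():
    """All (ref_codon, alt_codon) pairs differing at one position, ref sense."""
    for ref in codons.SENSE_CODONS:
        for pos in range(3):
            for base in "ACGT":
                if base == ref[pos]:
                    continue
                yield ref, ref[:pos] + base + ref[pos + 1 :]
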