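"""Codon-level machinery shared across the toolkit.

Everything here is derived from the universal (standard) nuclear genetic
code, taken from Biopython's codon tables.  The 61 sense codons are the
state space of the codon substitution model; stop codons are never valid
observed states.  Pairwise structure between sense codons (single-nucleotide
neighbours, transition vs transversion, synonymous vs nonsynonymous) is
precomputed once as boolean matrices for the rate-matrix construction.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

# Nucleotides in PAML-style TCAG order; purines A/G, pyrimidines C/T.
BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_CODE = unambiguous_dna_by_id[1]  # the universal code; configurable upstream

ALL_CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS: frozenset[str] = frozenset(_CODE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_STATES = len(SENSE_CODONS)  # 61
CODON_STATE = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) encoded by each sense codon, indexed by state
AMINO_ACID: tuple[str, ...] = tuple(_CODE.forward_table[c] for c in SENSE_CODONS)

MISSING = -1  # state code for an unobservable codon (gap/ambiguity/stop)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def is_transition(b1: str, b2: str) -> bool:
    """True if b1->b2 is a purine<->purine or pyrimidine<->pyrimidine change."""
    if b1 == b2:
        return False
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    return _CODE.forward_table[codon]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def encode_codon(codon: str) -> int:
    """Map a codon string to its sense-codon state, or MISSING.

    Any gap character, N, IUPAC ambiguity, or stop codon yields MISSING: a
    partially observed codon carries no usable information for a model whose
    states are whole codons.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return MISSING
    return CODON_STATE.get(codon, MISSING)


def _pair_structure():
    n = N_STATES
    neighbor = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    diff_pos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            neighbor[i, j] = True
            diff_pos[i, j] = k
            transition[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = AMINO_ACID[i] != AMINO_ACID[j]
    return neighbor, transition, nonsyn, diff_pos


#: single-nucleotide neighbour / transition / nonsynonymous masks, 61x61
NEIGHBOR, IS_TRANSITION, IS_NONSYN, DIFF_POS = _pair_structure()
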