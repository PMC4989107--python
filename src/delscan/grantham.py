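"""Grantham physico-chemical distance between amino acids.

The distance combines three side-chain properties — composition (c, the
atomic weight ratio of non-carbon elements), polarity (p) and molecular
volume (v) — as a weighted Euclidean distance

    d(x, y) = rho * sqrt(alpha (c_x - c_y)^2 + beta (p_x - p_y)^2
                         + gamma (v_x - v_y)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho chosen so the
mean distance over all 190 unordered pairs equals 100.  Rounded to the
nearest integer this reproduces the classical matrix (e.g. Leu-Ile 5,
Cys-Trp 215, the matrix maximum).
"""

from __future__ import annotations

import math

# (composition, polarity, volume) per amino acid, one-letter codes
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399


def _raw(x: str, y: str) -> float:
    cx, px, vx = PROPERTIES[x]
    cy, py, vy = PROPERTIES[y]
    return math.sqrt(
        ALPHA * (cx - cy) ** 2 + BETA * (px - py) ** 2 + GAMMA * (vx - vy) ** 2
    )


def _mean_scale() -> float:
    aas = list(PROPERTIES)
    dists = [_raw(x, y) for i, x in enumerate(aas) for y in aas[i + 1 :]]
    return 100.0 * len(dists) / sum(dists)


RHO = _mean_scale()


def grantham_score(aa_ref: str, aa_alt: str) -> int:
    """Grantham distance between two amino acids (0 iff identical).

    Raises ValueError for stop codons or unknown residues.
    """
    aa_ref, aa_alt = aa_ref.upper(), aa_alt.upper()
    for aa in (aa_ref, aa_alt):
        if aa == "*":
            raise ValueError("Grantham distance is undefined for stop codons")
        if aa not in PROPERTIES:
            raise ValueError(f"unknown amino acid: {aa!r}")
    if aa_ref == aa_alt:
        return 0
    return round(RHO * _raw(aa_ref, aa_alt))
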