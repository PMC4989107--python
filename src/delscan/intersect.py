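"""Consensus of the three deleterious-prediction methods and summary tables.

A nonsynonymous SNP is consensus-deleterious only when all three methods
(a SIFT-like table, a PolyPhen2-like table, and the toolkit's own LRT) are
present and all call it deleterious.  Variants missing any method's verdict
are tabulated separately as "untestable" rather than counted as tolerated;
the number of agreeing methods (0..3) is also reported for spectra
stratified by prediction support.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats_io import GenomicVariant
from .polarization import PolarizedVariant

METHODS = ("sift", "polyphen", "lrt")


@dataclass
class ConsensusCall:
    variant_id: str
    verdict: str  # deleterious | tolerated | untestable
    n_methods_agreeing: int
    per_method: dict[str, str]
    inconsistent_input: bool = False


def consensus_call(
    records: dict[str, str], effect_class: str, variant_id: str = ""
) -> ConsensusCall:
    """Combine per-method verdicts for one variant.

    ``records`` maps method name to verdict ('deleterious'/'tolerated');
    absent methods count as missing.  Only nonsynonymous variants can be
    deleterious; deleterious verdicts on a synonymous/noncoding variant are
    flagged as inconsistent input.
    """
    per_method = {m: records.get(m, "missing") for m in METHODS}
    unknown = set(records) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown prediction methods: {sorted(unknown)}")
    n_del = sum(1 for v in per_method.values() if v == "deleterious")
    nonsyn = effect_class in ("missense", "nonsense", "stop_loss")
    if not nonsyn:
        return ConsensusCall(
            variant_id, "tolerated", n_del, per_method, inconsistent_input=n_del > 0
        )
    if any(v == "missing" for v in per_method.values()):
        return ConsensusCall(variant_id, "untestable", n_del, per_method)
    verdict = "deleterious" if n_del == len(METHODS) else "tolerated"
    return ConsensusCall(variant_id, verdict, n_del, per_method)


def read_prediction_table(path: str, method: str) -> dict[str, str]:
    """TSV with columns variant_id, verdict; variant_id is chrom:pos:ref:alt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "verdict"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns variant_id, verdict")
    if df["variant_id"].duplicated().any():
        dup = df["variant_id"][df["variant_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate {method} record for {dup}")
    return dict(zip(df["variant_id"], df["verdict"]))


def combine_predictions(
    effect_of: dict[str, str], tables: dict[str, dict[str, str]]
) -> dict[str, ConsensusCall]:
    """Consensus call per variant id from per-method verdict tables."""
    calls = {}
    for vid, effect in effect_of.items():
        records = {m: t[vid] for m, t in tables.items() if vid in t}
        calls[vid] = consensus_call(records, effect, vid)
    return calls


def per_sample_counts(
    variants: list[GenomicVariant],
    polarized: dict[str, PolarizedVariant],
    effect_of: dict[str, str],
    consensus: dict[str, ConsensusCall],
    sample_ids: list[str],
) -> pd.DataFrame:
    """Per accession, counts of derived alleles carried in each class.

    A derived allele is "carried" when the accession has at least one copy.
    Classes follow the standard summary-table layout: noncoding, synonymous,
    nonsynonymous (missense + nonsense + stop_loss), nonsense, and
    consensus-deleterious.
    """
    classes = ("noncoding", "synonymous", "nonsynonymous", "nonsense", "deleterious")
    counts = {s: dict.fromkeys(classes, 0) for s in sample_ids}
    for v in variants:
        effect = effect_of.get(v.variant_id)
        if effect is None or effect == "unknown":
            continue
        pol = polarized.get(v.variant_id)
        if pol is None:
            continue
        for sample in pol.carriers:
            if sample not in counts:
                raise KeyError(f"accession {sample} absent from VCF sample set")
            if effect == "noncoding":
                counts[sample]["noncoding"] += 1
            elif effect == "synonymous":
                counts[sample]["synonymous"] += 1
            else:
                counts[sample]["nonsynonymous"] += 1
                if effect == "nonsense":
                    counts[sample]["nonsense"] += 1
            call = consensus.get(v.variant_id)
            if call is not None and call.verdict == "deleterious":
                counts[sample]["deleterious"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")[list(classes)]
    df.index.name = "accession"
    return df


def proportion_deleterious(
    effect_of: dict[str, str], consensus: dict[str, ConsensusCall]
) -> pd.DataFrame:
    """Per-method and consensus proportions of nonsynonymous SNPs deleterious.

    Two denominators are reported: all nonsynonymous variants (shared) and
    the per-method testable subset.
    """
    nonsyn = [
        vid
        for vid, eff in effect_of.items()
        if eff in ("missense", "nonsense", "stop_loss")
    ]
    if not nonsyn:
        raise ValueError("no nonsynonymous variants")
    rows = []
    for method in METHODS:
        n_del = sum(
            1
            for vid in nonsyn
            if consensus[vid].per_method.get(method) == "deleterious"
        )
        testable = [
            vid
            for vid in nonsyn
            if consensus[vid].per_method.get(method, "missing") != "missing"
        ]
        rows.append(
            {
                "method": method,
                "n_deleterious": n_del,
                "proportion_all_nonsyn": n_del / len(nonsyn),
                "proportion_testable": n_del / len(testable) if testable else 0.0,
            }
        )
    n_cons = sum(1 for vid in nonsyn if consensus[vid].verdict == "deleterious")
    testable_all = [
        vid for vid in nonsyn if consensus[vid].verdict != "untestable"
    ]
    rows.append(
        {
            "method": "intersect",
            "n_deleterious": n_cons,
            "proportion_all_nonsyn": n_cons / len(nonsyn),
            "proportion_testable": n_cons / len(testable_all) if testable_all else 0.0,
        }
    )
    return pd.DataFrame(rows)


def causative_panel_report(
    panel: list[str], consensus: dict[str, ConsensusCall]
) -> tuple[float, pd.DataFrame]:
    """Fraction of a known-phenotype SNP panel called consensus-deleterious."""
    if not panel:
        raise ValueError("empty causative panel")
    missing = [vid for vid in panel if vid not in consensus]
    if missing:
        raise KeyError(f"panel variants not found: {missing}")
    rows = []
    n_del = 0
    for vid in panel:
        call = consensus[vid]
        n_del += call.verdict == "deleterious"
        rows.append({"variant_id": vid, "verdict": call.verdict, **call.per_method})
    return n_del / len(panel), pd.DataFrame(rows)
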