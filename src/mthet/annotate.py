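"""Gene, codon and amino-acid-change annotation of heteroplasmic calls.

Each passing call is mapped into every annotation unit covering its
position.  For protein genes the affected codon is read on the coding
strand, the variant base substituted (complemented for minus-strand genes),
and both codons translated with the gene's genetic-code table; the call is
then synonymous, nonsynonymous, nonsense (a stop gained or lost) or unknown
(codon contains N).  Nonsynonymous changes are further classified by which
physicochemical dimensions change: hydropathy (hydrophobic vs hydrophilic),
polarity, and charge.  tRNA calls report whether they hit the third
anticodon base when the annotation supplies anticodon coordinates.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome import (
    COMPLEMENT,
    STOP_AA,
    UNKNOWN_AA,
    AminoAcidProperties,
    GeneAnnotation,
    GeneticCode,
    ReferenceSet,
    genetic_code,
    locate_site,
    translate_codon,
)

ANNOTATION_OUT_COLUMNS = [
    "gene", "gene_class", "codon_number", "codon_position",
    "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect",
    "property_changes", "anticodon_third",
]

PROPERTY_DIMENSIONS = ("hydropathy", "polarity", "charge")


def classify_aa_change(
    ref_aa: str, alt_aa: str, properties: Optional[AminoAcidProperties] = None
) -> set[str]:
    """Physicochemical dimensions that differ between two amino acids.

    Stop codons carry no property classes: any change involving a stop is a
    nonsense change and returns the empty set.
    """
    if STOP_AA in (ref_aa, alt_aa):
        return set()
    props = properties or AminoAcidProperties()
    changed = set()
    if props.hydropathy(ref_aa) != props.hydropathy(alt_aa):
        changed.add("hydropathy")
    if props.polarity(ref_aa) != props.polarity(alt_aa):
        changed.add("polarity")
    if props.charge(ref_aa) != props.charge(alt_aa):
        changed.add("charge")
    return changed


def annotate_call(
    call,
    reference: ReferenceSet,
    annotations: Sequence[GeneAnnotation],
    code: Optional[GeneticCode] = None,
    properties: Optional[AminoAcidProperties] = None,
) -> list[dict]:
    """Annotate one call (anything with chrom/pos/consensus/variant attributes).

    Returns one record per overlapping annotation unit; intergenic calls
    return a single record with gene_class 'intergenic'.
    """
    chrom, pos = call.chrom, int(call.pos)
    variant = call.variant
    contexts = locate_site(chrom, pos, annotations, reference)
    code_cache = {}
    records = []
    for ctx in contexts:
        rec = {
            "gene": ctx.gene,
            "gene_class": ctx.gene_class,
            "codon_number": ctx.codon_number,
            "codon_position": ctx.codon_position,
            "ref_codon": None, "alt_codon": None,
            "ref_aa": None, "alt_aa": None,
            "effect": None, "property_changes": "",
            "anticodon_third": ctx.anticodon_third,
        }
        if ctx.gene_class == "protein" and ctx.codon_position is not None:
            ann = next(a for a in annotations if a.gene == ctx.gene and a.chrom == chrom)
            table_id = ann.transl_table
            if code is not None:
                gene_code = code
            else:
                gene_code = code_cache.setdefault(table_id, genetic_code(table_id))
            ref_codon = ctx.ref_codon
            sub = variant if ann.strand == "+" else COMPLEMENT[variant]
            i = ctx.codon_position - 1
            alt_codon = ref_codon[:i] + sub + ref_codon[i + 1:]
            ref_aa = translate_codon(ref_codon, gene_code)
            alt_aa = translate_codon(alt_codon, gene_code)
            rec.update(ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa)
            if UNKNOWN_AA in (ref_aa, alt_aa):
                rec["effect"] = "unknown"
            elif ref_aa == alt_aa:
                rec["effect"] = "synonymous"
            elif STOP_AA in (ref_aa, alt_aa):
                rec["effect"] = "nonsense"
            else:
                rec["effect"] = "nonsynonymous"
                changed = classify_aa_change(ref_aa, alt_aa, properties)
                rec["property_changes"] = ",".join(sorted(changed))
        records.append(rec)
    return records


def annotate_calls(
    calls: pd.DataFrame,
    reference: ReferenceSet,
    annotations: Sequence[GeneAnnotation],
    code: Optional[GeneticCode] = None,
    properties: Optional[AminoAcidProperties] = None,
) -> pd.DataFrame:
    """Annotate a call table; one output row per (call, overlapping annotation)."""
    rows = []
    for call in calls.itertuples(index=False):
        for rec in annotate_call(call, reference, annotations, code, properties):
            out = call._asdict()
            out.update(rec)
            rows.append(out)
    cols = list(calls.columns) + ANNOTATION_OUT_COLUMNS
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["codon_number"] = df["codon_number"].astype("Int64")
        df["codon_position"] = df["codon_position"].astype("Int64")
    return df
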