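"""Cohort-level aggregation: per-sample summaries, shared-site matrices, t-tests.

Per-sample summaries partition the heteroplasmic sites by gene class
(protein / rRNA / tRNA), effect (synonymous vs nonsynonymous, split by
codon position) and gene, with per-gene rates expressed as sites per kb.
Pairwise sharing between samples is counted as sites matching on
chromosome, position and (by default) variant base.  Group comparisons use
one-sample or two-sample t-tests; the two-sample default is Welch's test
(unequal variances), with the pooled-variance variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation


class CohortError(ValueError):
    pass


@dataclass
class SampleSummary:
    """Category counts for one sample (gene-class, effect, codon-position, per-gene)."""

    sample: str
    group: Optional[str] = None
    total: int = 0
    protein: int = 0
    rrna: int = 0
    trna: int = 0
    intergenic: int = 0
    synonymous: int = 0
    nonsynonymous: int = 0
    unknown_effect: int = 0
    syn_by_codon_pos: dict = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    nonsyn_by_codon_pos: dict = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    anticodon_third: int = 0
    per_gene: dict = field(default_factory=dict)
    per_gene_rate: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "sample": self.sample, "group": self.group, "total": self.total,
            "protein": self.protein, "rRNA": self.rrna, "tRNA": self.trna,
            "synonymous": self.synonymous, "nonsynonymous": self.nonsynonymous,
            "unknown": self.unknown_effect, "anticodon_third": self.anticodon_third,
        }
        for p in (1, 2, 3):
            row[f"syn_codon{p}"] = self.syn_by_codon_pos[p]
            row[f"nonsyn_codon{p}"] = self.nonsyn_by_codon_pos[p]
        return row


def gene_length(ann: GeneAnnotation, chrom_length: Optional[int] = None) -> int:
    return ann.span_length(chrom_length or max(ann.start, ann.end))


def per_gene_rate(count: int, gene_length_bases: int) -> float:
    """Heteroplasmic sites per kb of gene ('A/L')."""
    if gene_length_bases <= 0:
        raise CohortError(f"gene length must be positive, got {gene_length_bases}")
    return count / (gene_length_bases / 1000.0)


def summarize_sample(
    annotated: pd.DataFrame,
    annotations: Optional[Sequence[GeneAnnotation]] = None,
    sample: Optional[str] = None,
    group: Optional[str] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> SampleSummary:
    """Roll one sample's annotated calls into category counts.

    A site overlapping several annotation units counts once in the totals,
    attributed to its first annotation unit.  Duplicate (chrom, pos) rows
    beyond annotation overlap are an error: sites must be unique per sample.
    Intergenic calls are excluded from gene tables but reported separately.
    """
    if sample is None:
        sample = annotated["sample"].iloc[0] if len(annotated) else "sample"
    summary = SampleSummary(sample=sample, group=group)
    if annotations is not None:
        for ann in annotations:
            summary.per_gene.setdefault(ann.gene, 0)
    if len(annotated) == 0:
        _fill_rates(summary, annotations, chrom_lengths)
        return summary

    per_site = annotated.drop_duplicates(subset=["chrom", "pos"], keep="first")
    dup_mask = annotated.duplicated(subset=["chrom", "pos", "gene"], keep=False)
    if dup_mask.any() and annotated.duplicated(
        subset=["chrom", "pos", "gene"]
    ).any():
        bad = annotated.loc[dup_mask, ["chrom", "pos"]].drop_duplicates()
        raise CohortError(
            f"duplicate sites for sample {sample}: {bad.to_records(index=False).tolist()}"
        )

    for row in per_site.itertuples(index=False):
        cls = row.gene_class
        if cls == "intergenic":
            summary.intergenic += 1
            continue
        summary.total += 1
        if cls == "protein":
            summary.protein += 1
            if row.effect == "synonymous":
                summary.synonymous += 1
                summary.syn_by_codon_pos[int(row.codon_position)] += 1
            elif row.effect in ("nonsynonymous", "nonsense"):
                summary.nonsynonymous += 1
                summary.nonsyn_by_codon_pos[int(row.codon_position)] += 1
            else:
                summary.unknown_effect += 1
        elif cls == "rRNA":
            summary.rrna += 1
        elif cls == "tRNA":
            summary.trna += 1
            if getattr(row, "anticodon_third", False):
                summary.anticodon_third += 1
        summary.per_gene[row.gene] = summary.per_gene.get(row.gene, 0) + 1

    _fill_rates(summary, annotations, chrom_lengths)
    return summary


def _fill_rates(summary, annotations, chrom_lengths) -> None:
    if annotations is None:
        return
    for ann in annotations:
        clen = chrom_lengths.get(ann.chrom) if chrom_lengths else None
        summary.per_gene_rate[ann.gene] = per_gene_rate(
            summary.per_gene.get(ann.gene, 0), gene_length(ann, clen)
        )


def summarize_cohort(
    annotated_by_sample: Mapping[str, pd.DataFrame],
    annotations: Optional[Sequence[GeneAnnotation]] = None,
    groups: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """One summary row per sample (the per-cohort table shape)."""
    rows = []
    for sample, annotated in annotated_by_sample.items():
        summ = summarize_sample(
            annotated, annotations, sample=sample,
            group=groups.get(sample) if groups else None,
            chrom_lengths=chrom_lengths,
        )
        rows.append(summ.to_row())
    return pd.DataFrame(rows)


def shared_site_counts(
    calls_by_sample: Mapping[str, pd.DataFrame],
    match: str = "allele",
) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared heteroplasmic sites.

    Two samples share a site when chromosome, position and (with
    ``match='allele'``, the default) the variant base all agree;
    ``match='position'`` ignores the base.  The diagonal holds each
    sample's own site total.
    """
    if match not in ("allele", "position"):
        raise CohortError(f"match must be allele|position, got {match!r}")
    keys = {}
    for sample, calls in calls_by_sample.items():
        cols = ["chrom", "pos"] + (["variant"] if match == "allele" else [])
        dedup = calls.drop_duplicates(subset=["chrom", "pos"])
        keys[sample] = set(map(tuple, dedup[cols].to_numpy()))
    samples = list(calls_by_sample)
    mat = np.zeros((len(samples), len(samples)), dtype=int)
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            mat[i, j] = len(keys[a]) if i == j else len(keys[a] & keys[b])
    return pd.DataFrame(mat, index=samples, columns=samples)


@dataclass
class GroupComparison:
    """Two-group (or one-sample) t-test result with descriptive statistics."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    method: str

    def summary(self) -> str:
        return (
            f"{self.group_a}: mean {self.mean_a:.1f} +/- SD {self.sd_a:.1f} (n={self.n_a})\n"
            f"{self.group_b}: mean {self.mean_b:.1f} +/- SD {self.sd_b:.1f} (n={self.n_b})\n"
            f"{self.method} t = {self.t:.3f}, df = {self.df:.2f}, two-sided p = {self.p:.4g}"
        )


def compare_groups(
    values_a: Sequence[float],
    values_b: Optional[Sequence[float]] = None,
    mu: Optional[float] = None,
    method: str = "welch",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Compare per-sample totals between two groups, or one group against mu.

    ``method`` is ``welch`` (default), ``pooled`` or ``one_sample``.  SDs use
    the n-1 denominator.  Degenerate variance: if both groups have zero
    variance and equal means the test is a tie (t=0, p=1); zero variance
    otherwise is an error (an exact/permutation approach is needed there).
    """
    a = np.asarray(values_a, dtype=float)
    if method == "one_sample" or (values_b is None and mu is not None):
        if a.size < 2:
            raise CohortError("one-sample test needs n >= 2")
        res = stats.ttest_1samp(a, popmean=float(mu))
        sd = float(a.std(ddof=1))
        if sd == 0:
            if a.mean() == mu:
                return GroupComparison(labels[0], f"mu={mu}", a.size, 1, float(a.mean()),
                                       float(mu), 0.0, 0.0, 0.0, 0.0, 0.0, a.size - 1,
                                       1.0, "one_sample")
            raise CohortError("zero variance with unequal mean: use an exact test")
        return GroupComparison(
            labels[0], f"mu={mu}", a.size, 1, float(a.mean()), float(mu),
            sd, 0.0, sd / np.sqrt(a.size), 0.0,
            float(res.statistic), float(a.size - 1), float(res.pvalue), "one_sample",
        )

    if values_b is None:
        raise CohortError("two-sample comparison needs values_b")
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CohortError("two-sample test needs n >= 2 per group")
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    if sd_a == 0 and sd_b == 0:
        if a.mean() == b.mean():
            return GroupComparison(labels[0], labels[1], a.size, b.size,
                                   float(a.mean()), float(b.mean()), 0.0, 0.0, 0.0, 0.0,
                                   0.0, float(a.size + b.size - 2), 1.0, method)
        raise CohortError("zero variance in both groups with unequal means: use an exact test")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise CohortError(f"unknown method {method!r}")
    return GroupComparison(
        labels[0], labels[1], a.size, b.size,
        float(a.mean()), float(b.mean()), sd_a, sd_b,
        sd_a / np.sqrt(a.size), sd_b / np.sqrt(b.size),
        float(res.statistic), float(res.df), float(res.pvalue), method,
    )


def load_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with at least columns sample and group (country etc.)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise CohortError("metadata must have a 'sample' column")
    return df
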