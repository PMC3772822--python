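"""Read QC filtering and reduction of alignments to per-site base counts.

The unit the caller consumes is the *pileup table*: one row per reference
position with A/C/G/T read counts and their sum (depth).  It can be built
from a SAM/BAM alignment via pysam, or read directly from a 7-column
tab-separated dialect (chrom, pos, ref, A, C, G, T) so synthetic pileups can
bypass read emission entirely.  Indel-bearing read positions and N calls are
excluded from counts ("SNPs only"); unmapped/secondary/supplementary records
are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .genome import ReferenceSet

BASES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T"]


class PileupError(ValueError):
    pass


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise PileupError(f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quals")
        if any(q < 0 for q in self.quals):
            raise PileupError(f"read {self.id}: negative Phred score")


@dataclass
class QCReport:
    """Read-filter accounting: kept/dropped counts and the Q20 base rate of kept reads."""

    n_input: int
    n_kept: int
    n_dropped: int
    q20_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def read_fastq(path: Union[str, Path]) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def filter_reads(
    reads: Iterable[ReadRecord], low_q: int = 5, max_fraction: float = 0.5
) -> tuple[list[ReadRecord], QCReport]:
    """Drop reads whose fraction of bases at Phred <= ``low_q`` exceeds ``max_fraction``.

    The boundary is strict: a read with exactly ``max_fraction`` low-quality
    bases is kept.  The Q20 rate reported is the fraction of *kept* bases
    with Phred >= 20.
    """
    kept: list[ReadRecord] = []
    n_input = 0
    q20 = total = 0
    for read in reads:
        n_input += 1
        quals = np.asarray(read.quals)
        if quals.size and (quals <= low_q).mean() > max_fraction:
            continue
        kept.append(read)
        q20 += int((quals >= 20).sum())
        total += quals.size
    report = QCReport(
        n_input=n_input,
        n_kept=len(kept),
        n_dropped=n_input - len(kept),
        q20_rate=q20 / total if total else 0.0,
    )
    return kept, report


def empty_pileup(reference: ReferenceSet) -> pd.DataFrame:
    """All-positions, zero-depth pileup table for a reference set."""
    frames = []
    for seq in reference:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": seq.id,
                    "pos": np.arange(1, seq.length + 1),
                    "ref": list(seq.sequence),
                    "A": 0, "C": 0, "G": 0, "T": 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_site_counts(
    alignments: Union[str, Path, pd.DataFrame],
    reference: ReferenceSet,
    collect_quals: bool = False,
) -> pd.DataFrame:
    """Reduce alignments (SAM/BAM path) or a pileup TSV to the pileup table.

    Every reference position is emitted, zero-coverage ones with depth 0.
    Deletions, reference skips and N basecalls contribute nothing; records
    flagged unmapped/secondary/supplementary are excluded.  With
    ``collect_quals`` the per-base Phred sums are accumulated into extra
    columns ``qA..qT`` (for the quality-weighted consensus mode).
    """
    if isinstance(alignments, pd.DataFrame):
        return _validate_pileup(alignments.copy(), reference)
    path = str(alignments)
    if path.endswith((".tsv", ".txt", ".pileup")):
        return _validate_pileup(pd.read_csv(path, sep="\t", dtype={"chrom": str}), reference)

    counts = {
        seq.id: np.zeros((seq.length, 4), dtype=np.int64) for seq in reference
    }
    qsums = (
        {seq.id: np.zeros((seq.length, 4), dtype=np.int64) for seq in reference}
        if collect_quals
        else None
    )
    base_index = {b: i for i, b in enumerate(BASES)}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        bad = [name for name in af.references if name not in reference]
        if bad:
            raise PileupError(f"alignment references not in reference set: {bad}")
        for name, length in zip(af.references, af.lengths):
            if reference[name].length != length:
                raise PileupError(
                    f"length mismatch for {name}: SAM {length} vs reference {reference[name].length}"
                )
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            arr = counts[rec.reference_name]
            qarr = qsums[rec.reference_name] if collect_quals else None
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                base = seq[qpos]
                bi = base_index.get(base)
                if bi is None:  # N or ambiguity code: excluded
                    continue
                arr[rpos, bi] += 1
                if qarr is not None and quals is not None:
                    qarr[rpos, bi] += quals[qpos]

    frames = []
    for seq in reference:
        frame = pd.DataFrame(
            {
                "chrom": seq.id,
                "pos": np.arange(1, seq.length + 1),
                "ref": list(seq.sequence),
            }
        )
        for i, b in enumerate(BASES):
            frame[b] = counts[seq.id][:, i]
        if collect_quals:
            for i, b in enumerate(BASES):
                frame[f"q{b}"] = qsums[seq.id][:, i]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _validate_pileup(df: pd.DataFrame, reference: Optional[ReferenceSet]) -> pd.DataFrame:
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise PileupError(f"pileup table missing columns: {sorted(missing)}")
    if reference is not None:
        bad = sorted(set(df["chrom"]) - set(reference.ids))
        if bad:
            raise PileupError(f"pileup chroms not in reference set: {bad}")
    if (df[list(BASES)] < 0).any().any():
        raise PileupError("negative counts in pileup table")
    return df


def depth(pileup: pd.DataFrame) -> pd.Series:
    return pileup[list(BASES)].sum(axis=1)


def write_pileup(pileup: pd.DataFrame, path: Union[str, Path]) -> None:
    cols = [c for c in pileup.columns if c in PILEUP_COLUMNS]
    pileup[cols].to_csv(path, sep="\t", index=False)


def read_pileup(path: Union[str, Path], reference: Optional[ReferenceSet] = None) -> pd.DataFrame:
    return _validate_pileup(pd.read_csv(path, sep="\t", dtype={"chrom": str}), reference)


def consensus_base(counts: dict[str, int], ref_base: str = "N") -> str:
    """Majority base of one site; ties prefer the reference base, then alphabetical order.

    Zero depth yields N.
    """
    vec = [counts.get(b, 0) for b in BASES]
    best = max(vec)
    if best == 0:
        return "N"
    tied = [b for b, c in zip(BASES, vec) if c == best]
    return ref_base if ref_base in tied else tied[0]


def consensus_track(pileup: pd.DataFrame, mode: str = "count") -> pd.Series:
    """Per-row consensus base for a pileup table.

    ``mode='count'`` is the default count-majority rule; ``mode='quality'``
    uses summed Phred scores per base (requires the ``qA..qT`` columns from
    ``build_site_counts(..., collect_quals=True)``).
    """
    if mode == "quality":
        qcols = [f"q{b}" for b in BASES]
        if not set(qcols) <= set(pileup.columns):
            raise PileupError("quality consensus requires qA..qT columns")
        mat = pileup[qcols].to_numpy()
    elif mode == "count":
        mat = pileup[list(BASES)].to_numpy()
    else:
        raise PileupError(f"unknown consensus mode {mode!r}")

    best = mat.max(axis=1)
    is_tied = mat == best[:, None]
    ref = pileup["ref"].to_numpy()
    out = np.empty(len(pileup), dtype="U1")
    base_arr = np.array(BASES)
    # alphabetically first tied base, then override with ref where ref is tied
    first_tied = base_arr[is_tied.argmax(axis=1)]
    out[:] = first_tied
    for i, b in enumerate(BASES):
        ref_is_tied = (ref == b) & is_tied[:, i]
        out[ref_is_tied] = b
    out[best == 0] = "N"
    return pd.Series(out, index=pileup.index, name="consensus")
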