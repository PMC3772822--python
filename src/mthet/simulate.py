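"""Synthetic references, pileups and reads with planted heteroplasmy.

The generator emulates the two study architectures end to end so every
pipeline stage can be exercised without sequencing data:

* *louse preset*: 20 circular minichromosomes of 3--4 kb carrying 1--3 genes
  each (37 genes total: 13 protein-coding units including the joint
  atp8-atp6, 2 rRNAs, 22 tRNAs), mean per-site depth 6,000x;
* *tick preset*: one circular chromosome (~14.5 kb of coding sequence plus
  spacers) carrying the same 37-gene repertoire, mean depth 1,700x.

Sequencing noise is a uniform per-base error rate p (default 0.5%), spread
evenly over the three non-template bases.  Planted heteroplasmic sites draw
their minor-allele count from Binomial(n, f(1-p)); error-hotspot artifacts
are placed immediately 3' of injected homopolymer runs (length >= 4) with a
20-fold elevated error rate on one base, putting them above the 1.5%
detection threshold so that only the hotspot filter can remove them.
Planted (non-artifact) sites are chosen away from homopolymer context and
never adjacent, so the truth set is unambiguous.  All randomness flows from
one seeded generator; outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .caller import _homopolymer_context
from .genome import GeneAnnotation, ReferenceSequence, ReferenceSet, write_annotations
from .pileup import BASES, PILEUP_COLUMNS, build_site_counts

PROTEIN_GENES = [
    "atp8-atp6", "cytb", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
]
RRNA_GENES = ["rrnL", "rrnS"]
TRNA_GENES = [
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
]
ALL_GENES = PROTEIN_GENES + RRNA_GENES + TRNA_GENES  # 36 units, 37 genes

STOP_CODONS_TABLE5 = {"TAA", "TAG"}

TRUTH_COLUMNS = ["chrom", "pos", "minor_base", "true_freq", "is_artifact"]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    ``architecture`` is ``minichromosomes`` (louse-like) or ``single``
    (tick-like).  Depth is the mean per-site coverage (Poisson-drawn unless
    ``fixed_depth``); ``error_rate`` is the uniform per-base error
    probability.  ``planted_sites`` may be given explicitly as
    (chrom, pos, minor_base, freq) tuples, or left empty and planted with
    :func:`choose_planted_sites`.
    """

    architecture: str = "minichromosomes"  # minichromosomes | single
    n_chroms: int = 20
    length_range: tuple[int, int] = (3000, 4000)
    single_length: int = 14500
    depth: float = 6000.0
    fixed_depth: bool = False
    error_rate: float = 0.005
    planted_sites: list = field(default_factory=list)
    n_planted: int = 0
    planted_freq: float = 0.05
    hotspot_artifacts: int = 0
    artifact_error_multiplier: float = 20.0
    gc: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("minichromosomes", "single"):
            raise SimulationError(f"bad architecture {self.architecture!r}")
        if not 0 <= self.error_rate <= 1:
            raise SimulationError("error_rate must be in [0,1]")
        for site in self.planted_sites:
            f = site[3]
            if not 0 < f <= 0.5:
                raise SimulationError(f"planted frequency must be in (0, 0.5], got {f}")


def louse_preset(**overrides) -> SimulationConfig:
    """20 circular 3--4 kb minichromosomes, depth 6,000x."""
    cfg = SimulationConfig(architecture="minichromosomes", n_chroms=20,
                           length_range=(3000, 4000), depth=6000.0)
    return dataclasses.replace(cfg, **overrides)


def tick_preset(**overrides) -> SimulationConfig:
    """Single ~14.5 kb chromosome with all 37 genes, depth 1,700x."""
    cfg = SimulationConfig(architecture="single", single_length=14500, depth=1700.0)
    return dataclasses.replace(cfg, **overrides)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _random_coding(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random protein-coding sequence with no in-frame stop codons (table 5)."""
    codons = []
    while len(codons) < n_codons:
        block = _random_bases(rng, 3 * (n_codons - len(codons)), gc)
        for i in range(0, len(block), 3):
            codon = "".join(block[i : i + 3])
            if codon not in STOP_CODONS_TABLE5:
                codons.append(codon)
            if len(codons) == n_codons:
                break
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _gene_lengths(rng: np.random.Generator, name: str, scale: float = 1.0) -> int:
    if name in PROTEIN_GENES:
        return 3 * int(rng.integers(int(150 * scale), int(250 * scale)))  # codons
    if name in RRNA_GENES:
        return int(rng.integers(int(350 * scale), int(600 * scale)))
    return int(rng.integers(62, 72))  # tRNA


def generate_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReferenceSet, list[GeneAnnotation]]:
    """Random reference sequences plus a gene layout in the standard table.

    The 36 annotation units are distributed over the configured chromosomes
    (1--3 per minichromosome, all on one chromosome for ``single``); genes
    get random strands, protein genes are stop-free random codons, tRNAs
    carry an anticodon annotation.  Gene layouts that cannot fit raise an
    error.
    """
    rng = rng or np.random.default_rng(config.seed)
    if config.architecture == "minichromosomes":
        groups = _partition_genes(rng, config.n_chroms)
        chrom_names = [f"mc{idx + 1:02d}_{'_'.join(g)}" for idx, g in enumerate(groups)]
        targets = rng.integers(config.length_range[0], config.length_range[1] + 1,
                               size=config.n_chroms)
        scale = 0.75  # minichromosome genes scaled so up to 3 always fit in 3-4 kb
    else:
        groups = [list(ALL_GENES)]
        chrom_names = ["mt_chromosome"]
        targets = [config.single_length]
        scale = 1.0

    sequences, annotations = [], []
    for name, genes, target in zip(chrom_names, groups, targets):
        # draw gene payloads first, then fit spacers so total == target exactly;
        # genes that no longer fit the chromosome budget are dropped (small
        # test-scale chromosomes carry a gene subset)
        payloads = []
        running = 0
        for gene in genes:
            glen = _gene_lengths(rng, gene, scale)
            strand = "+" if rng.random() < 0.5 else "-"
            if gene in PROTEIN_GENES:
                coding = _random_coding(rng, glen // 3, config.gc)
                insert = coding if strand == "+" else _revcomp(coding)
                gene_class = "protein"
            else:
                insert = "".join(_random_bases(rng, glen, config.gc))
                gene_class = "rRNA" if gene in RRNA_GENES else "tRNA"
            if running + len(insert) + 20 * (len(payloads) + 2) > int(target):
                continue
            payloads.append((gene, gene_class, strand, insert))
            running += len(insert)
        total_gene_len = running
        n_spacers = len(payloads) + 1
        spacer_budget = int(target) - total_gene_len
        spacer_lens = _split_budget(rng, spacer_budget, n_spacers, minimum=20)
        seq_parts: list[str] = []
        cursor = 0
        for (gene, gene_class, strand, insert), spacer in zip(payloads, spacer_lens):
            seq_parts.append("".join(_random_bases(rng, spacer, config.gc)))
            cursor += spacer
            glen = len(insert)
            start, end = cursor + 1, cursor + glen
            anticodon = None
            if gene_class == "tRNA":
                # anticodon loop sits mid-gene on the coding strand
                anticodon = start + glen // 2 if strand == "+" else end - glen // 2
            annotations.append(
                GeneAnnotation(
                    gene=gene, chrom=name, start=start, end=end, strand=strand,
                    gene_class=gene_class, frame_offset=0, transl_table=5,
                    anticodon_start=anticodon,
                )
            )
            seq_parts.append(insert)
            cursor += glen
        seq_parts.append("".join(_random_bases(rng, spacer_lens[-1], config.gc)))
        sequence = "".join(seq_parts)
        assert len(sequence) == int(target)
        sequences.append(ReferenceSequence(name, sequence, topology="circular"))
    return ReferenceSet(sequences), annotations


def _partition_genes(rng: np.random.Generator, n_chroms: int) -> list[list[str]]:
    """Assign the 36 annotation units to chromosomes, 1-3 per chromosome."""
    genes = list(ALL_GENES)
    rng.shuffle(genes)
    if n_chroms > len(genes):
        raise SimulationError(f"more chromosomes ({n_chroms}) than gene units ({len(genes)})")
    genes = genes[: 3 * n_chroms]  # small simulations carry a gene subset
    sizes = np.ones(n_chroms, dtype=int)
    remaining = len(genes) - n_chroms
    while remaining > 0:
        i = int(rng.integers(n_chroms))
        if sizes[i] < 3:
            sizes[i] += 1
            remaining -= 1
    out, cursor = [], 0
    for s in sizes:
        out.append(genes[cursor : cursor + s])
        cursor += s
    return out


def _split_budget(rng, budget: int, parts: int, minimum: int) -> list[int]:
    extra = budget - minimum * parts
    if extra <= 0:
        return [minimum] * parts
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [extra]]))
    return (pieces + minimum).tolist()


def choose_planted_sites(
    reference: ReferenceSet,
    n_sites: int,
    freq: float,
    rng: np.random.Generator,
    annotations: Optional[Sequence[GeneAnnotation]] = None,
    homopolymer_len: int = 4,
    min_spacing: int = 2,
) -> list[tuple[str, int, str, float]]:
    """Pick planted-site coordinates avoiding hotspot context and adjacency.

    Sites land uniformly over the reference (or restricted to annotated
    genes when ``annotations`` is given); positions within homopolymer
    context or within ``min_spacing`` of an already-chosen site are
    rejected so planted truth cannot collide with the hotspot filter.
    """
    candidates: list[tuple[str, int]] = []
    if annotations is not None:
        for ann in annotations:
            ref = reference[ann.chrom]
            if ann.end >= ann.start:
                span = range(ann.start, ann.end + 1)
            else:
                span = list(range(ann.start, ref.length + 1)) + list(range(1, ann.end + 1))
            candidates.extend((ann.chrom, p) for p in span)
    else:
        for ref in reference:
            candidates.extend((ref.id, p) for p in range(1, ref.length + 1))

    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int, str, float]] = []
    used: set[tuple[str, int]] = set()
    for idx in order:
        chrom, pos = candidates[idx]
        ref = reference[chrom]
        if _homopolymer_context(ref, pos, homopolymer_len):
            continue
        if any((chrom, pos + d) in used for d in range(-min_spacing, min_spacing + 1)):
            continue
        ref_base = ref.base_at(pos)
        minor = rng.choice([b for b in BASES if b != ref_base])
        chosen.append((chrom, int(pos), str(minor), float(freq)))
        used.add((chrom, pos))
        if len(chosen) == n_sites:
            return chosen
    raise SimulationError(f"could only place {len(chosen)} of {n_sites} sites")


def inject_homopolymer_artifacts(
    reference: ReferenceSet,
    n_artifacts: int,
    rng: np.random.Generator,
    run_len: int = 4,
) -> tuple[ReferenceSet, list[tuple[str, int, str]]]:
    """Overwrite reference context to create homopolymer-adjacent artifact sites.

    For each artifact a position is chosen, the ``run_len`` bases 5' of it
    are overwritten with one repeated base, and the artifact (elevated
    error) is recorded at the site immediately 3' of the run.  Returns the
    modified reference and (chrom, pos, artifact_base) records.
    """
    seqs = {ref.id: list(ref.sequence) for ref in reference}
    topo = {ref.id: ref.topology for ref in reference}
    records: list[tuple[str, int, str]] = []
    used: set[tuple[str, int]] = set()
    ids = list(seqs)
    attempts = 0
    while len(records) < n_artifacts and attempts < 100 * max(n_artifacts, 1):
        attempts += 1
        chrom = ids[int(rng.integers(len(ids)))]
        length = len(seqs[chrom])
        pos = int(rng.integers(run_len + 2, length))  # keep runs off the origin
        if any((chrom, pos + d) in used for d in range(-(run_len + 2), run_len + 3)):
            continue
        ref_base = seqs[chrom][pos - 1]
        run_base = str(rng.choice([b for b in BASES if b != ref_base]))
        for p in range(pos - run_len, pos):
            seqs[chrom][p - 1] = run_base
        artifact_base = str(rng.choice([b for b in BASES if b != ref_base]))
        records.append((chrom, pos, artifact_base))
        used.add((chrom, pos))
    if len(records) < n_artifacts:
        raise SimulationError("could not place all requested artifacts")
    new_ref = ReferenceSet(
        ReferenceSequence(cid, "".join(s), topo[cid]) for cid, s in seqs.items()
    )
    return new_ref, records


def simulate_pileup(
    reference: ReferenceSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    planted_sites: Optional[Sequence[tuple]] = None,
    artifact_sites: Optional[Sequence[tuple]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an error-contaminated pileup table plus its truth set.

    Per site the depth n is Poisson(mean depth) (or fixed); base counts are
    multinomial with the template base at 1 - p, each non-template base at
    p/3.  A planted site (chrom, pos, minor, f) gives its minor base
    marginal Binomial(n, f(1-p)); an artifact site elevates one base's
    error rate ``artifact_error_multiplier``-fold.
    """
    rng = rng or np.random.default_rng(config.seed)
    planted = list(planted_sites if planted_sites is not None else config.planted_sites)
    artifacts = list(artifact_sites or [])
    p = config.error_rate

    planted_map = {(c, pos): (minor, f) for c, pos, minor, f in planted}
    artifact_map = {(c, pos): b for c, pos, b in artifacts}
    overlap = set(planted_map) & set(artifact_map)
    if overlap:
        raise SimulationError(f"planted and artifact sites overlap: {sorted(overlap)}")

    frames = []
    for ref in reference:
        L = ref.length
        if config.fixed_depth:
            n = np.full(L, int(config.depth), dtype=np.int64)
        else:
            n = rng.poisson(config.depth, size=L).astype(np.int64)
        ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1").astype("U1")
        counts = np.zeros((L, 4), dtype=np.int64)

        special = [
            pos for (c, pos) in list(planted_map) + list(artifact_map) if c == ref.id
        ]
        special_mask = np.zeros(L, dtype=bool)
        for pos in special:
            if not 1 <= pos <= L:
                raise SimulationError(f"site {ref.id}:{pos} outside reference")
            special_mask[pos - 1] = True

        # bulk sites: multinomial grouped by template base
        for bi, base in enumerate(BASES):
            sel = (ref_arr == base) & ~special_mask
            if not sel.any():
                continue
            others = [j for j in range(4) if j != bi]
            pvals = np.empty(4)
            pvals[bi] = 1 - p
            pvals[others] = p / 3
            counts[sel] = rng.multinomial(n[sel], pvals)

        base_idx = {b: i for i, b in enumerate(BASES)}
        for (c, pos), (minor, f) in planted_map.items():
            if c != ref.id:
                continue
            i = pos - 1
            bi, mi = base_idx[ref_arr[i]], base_idx[minor]
            if bi == mi:
                raise SimulationError(f"planted base equals reference at {c}:{pos}")
            pvals = np.full(4, p / 3)
            pvals[mi] = f * (1 - p)
            pvals[bi] = 1 - pvals[[j for j in range(4) if j != bi]].sum()
            counts[i] = rng.multinomial(n[i], pvals)
        for (c, pos), art_base in artifact_map.items():
            if c != ref.id:
                continue
            i = pos - 1
            bi, ai = base_idx[ref_arr[i]], base_idx[art_base]
            pvals = np.full(4, p / 3)
            pvals[ai] = config.artifact_error_multiplier * p / 3
            pvals[bi] = 1 - pvals[[j for j in range(4) if j != bi]].sum()
            counts[i] = rng.multinomial(n[i], pvals)

        frame = pd.DataFrame({"chrom": ref.id, "pos": np.arange(1, L + 1), "ref": ref_arr})
        for j, b in enumerate(BASES):
            frame[b] = counts[:, j]
        frames.append(frame)

    truth_rows = [
        {"chrom": c, "pos": pos, "minor_base": minor, "true_freq": f, "is_artifact": False}
        for (c, pos), (minor, f) in planted_map.items()
    ] + [
        {"chrom": c, "pos": pos, "minor_base": b,
         "true_freq": config.artifact_error_multiplier * p / 3, "is_artifact": True}
        for (c, pos), b in artifact_map.items()
    ]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return pd.concat(frames, ignore_index=True), truth


def emit_reads(
    pileup: pd.DataFrame,
    read_length: int,
    reference: ReferenceSet,
    fastq_path: Union[str, Path],
    sam_path: Union[str, Path],
    n_lowq_reads: int = 0,
    lowq_fraction: float = 0.6,
    lowq_phred: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> tuple[int, int]:
    """Write FASTQ + SAM whose pileup reproduces the input counts exactly.

    Each pileup column is decomposed deterministically into depth layers
    (template base first, then variant bases in A<C<G<T order); layer i
    becomes reads over the maximal runs where depth > i, chopped to
    ``read_length``.  Base qualities are constant Q40.  Optionally
    ``n_lowq_reads`` junk reads with ``lowq_fraction`` of bases at
    ``lowq_phred`` are appended for QC-filter testing; they are flagged
    unmapped in the SAM so counts are unaffected.  Returns
    (n_aligned_reads, n_lowq_reads).
    """
    rng = rng or np.random.default_rng(0)
    if read_length < 1:
        raise SimulationError("read_length must be >= 1")
    for ref in reference:
        if read_length > ref.length:
            raise SimulationError(
                f"read_length {read_length} exceeds chrom {ref.id} length {ref.length}"
            )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.id, "LN": ref.length} for ref in reference],
    }
    n_reads = 0
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(
        str(sam_path), "wh", header=header
    ) as sam:
        for tid, ref in enumerate(reference):
            sub = pileup[pileup["chrom"] == ref.id].sort_values("pos")
            counts = sub[list(BASES)].to_numpy()
            positions = sub["pos"].to_numpy()
            L = len(sub)
            depths = counts.sum(axis=1)
            cons = sub["ref"].to_numpy()
            # per-position ordered base stacks: template first, variants after
            stacks = []
            for i in range(L):
                stack = []
                c = cons[i]
                ci = BASES.index(c) if c in BASES else None
                if ci is not None:
                    stack.extend([c] * counts[i, ci])
                for j, b in enumerate(BASES):
                    if j != ci:
                        stack.extend([b] * counts[i, j])
                stacks.append(stack)
            max_depth = int(depths.max()) if L else 0
            chrom_reads = []
            for layer in range(max_depth):
                i = 0
                while i < L:
                    if depths[i] <= layer:
                        i += 1
                        continue
                    j = i
                    while j < L and depths[j] > layer and j - i < read_length:
                        j += 1
                    bases = "".join(stacks[k][layer] for k in range(i, j))
                    name = f"r{ref.id}_{layer}_{positions[i]}"
                    chrom_reads.append((int(positions[i]), name, bases))
                    i = j
            chrom_reads.sort()  # honour the coordinate-sorted header
            for pos, name, bases in chrom_reads:
                _write_read(fq, sam, name, bases, pos, tid, ref.id)
                n_reads += 1
        for r in range(n_lowq_reads):
            bases = "".join(rng.choice(list("ACGT"), size=read_length))
            n_low = int(round(lowq_fraction * read_length))
            quals = np.full(read_length, 40, dtype=int)
            low_idx = rng.choice(read_length, size=n_low, replace=False)
            quals[low_idx] = lowq_phred
            name = f"lowq_{r}"
            qual_str = "".join(chr(q + 33) for q in quals)
            fq.write(f"@{name}\n{bases}\n+\n{qual_str}\n")
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = bases
            a.flag = 4  # unmapped: never contributes to counts
            a.query_qualities = pysam.qualitystring_to_array(qual_str)
            sam.write(a)
    return n_reads, n_lowq_reads


def _write_read(fq, sam, name: str, bases: str, pos: int, tid: int, chrom: str) -> None:
    qual = "I" * len(bases)  # Q40
    fq.write(f"@{name}\n{bases}\n+\n{qual}\n")
    a = pysam.AlignedSegment()
    a.query_name = name
    a.query_sequence = bases
    a.flag = 0
    a.reference_id = tid
    a.reference_start = pos - 1
    a.mapping_quality = 60
    a.cigarstring = f"{len(bases)}M"
    a.query_qualities = pysam.qualitystring_to_array(qual)
    sam.write(a)


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Precision / recall / frequency error of pass-status calls against truth.

    Recall counts recovered non-artifact planted sites (matching chrom,
    position and minor base); precision is the fraction of pass calls that
    are planted sites.  Frequency error is the mean |observed - true| over
    recovered sites.  With no planted sites recall is NA (None).
    """
    if truth.empty:
        planted = pd.DataFrame(columns=TRUTH_COLUMNS)
    else:
        planted = truth[~truth["is_artifact"]]
    truth_keys = {
        (r.chrom, r.pos, r.minor_base): r.true_freq for r in planted.itertuples()
    }
    call_keys = {
        (r.chrom, r.pos, r.variant): r.freq for r in calls.itertuples()
    }
    recovered = set(truth_keys) & set(call_keys)
    n_true_calls = len(recovered)
    precision = n_true_calls / len(call_keys) if call_keys else float("nan")
    recall = len(recovered) / len(truth_keys) if len(truth_keys) else None
    freq_err = (
        float(np.mean([abs(call_keys[k] - truth_keys[k]) for k in recovered]))
        if recovered
        else float("nan")
    )
    return {
        "n_calls": len(call_keys),
        "n_planted": len(truth_keys),
        "n_recovered": n_true_calls,
        "precision": precision,
        "recall": recall,
        "mean_freq_error": freq_err,
    }


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, sep="\t", index=False)
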