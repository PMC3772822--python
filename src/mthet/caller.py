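"""Heteroplasmy calling: frequency threshold, binomial error model, q-values, hotspots.

A *heteroplasmic site* is a position where a minor allele is seen at a
frequency above a detection threshold (default >1.5%, i.e. three times the
~0.5% per-base error rate of the sequencing platform).  Each candidate is
scored with a binomial false-positive probability

    P_f = C(n, k) * p^k * (1 - p)^(n - k)

where n is the read coverage at the site, k the minor-allele read count and
p the platform error rate.  P_f values are converted to false-discovery
q-values Q_f by the Storey step-up procedure with a configurable pi0, and
calls are accepted at P_f < 1% and Q_f < 0.1%.  Two classes of
sequencing-error hotspots are then excluded: sites immediately following a
homopolymer run of four or more identical bases, and pairs of adjacent
called variants.

The printed P_f is a *point* binomial probability.  The statistically
conventional quantity would be the upper tail P(X >= k); both are available
(``pf_mode='pmf'`` is the default, ``'tail'`` the alternative).

The top-level API is statsmodels-shaped: build a :class:`HeteroplasmyModel`
from a pileup table, call :meth:`~HeteroplasmyModel.fit`, and read the
resulting :class:`HeteroplasmyResults` (calls, attrition, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, AminoAcidProperties, GeneticCode, ReferenceSet
from .pileup import BASES, build_site_counts, consensus_track, depth

CALL_COLUMNS = [
    "sample", "chrom", "pos", "consensus", "variant", "k", "n", "freq",
    "multi_allelic", "p_f", "q_f", "hotspot_homopolymer", "hotspot_adjacent",
    "status",
]

STATUS_ORDER = ["pass", "fail_freq", "fail_pf", "fail_qf", "fail_hotspot"]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds and model constants for heteroplasmy calling.

    min_freq
        Minimum variant frequency; strict inequality (default 0.015).
    error_rate
        Per-base platform error rate p (default 0.005).
    pf_max, qf_max
        Significance thresholds: P_f < pf_max and Q_f < qf_max.
    pi0
        Assumed true-null proportion for the q-value procedure; ``None``
        estimates it with the Storey smoother.
    pf_mode
        ``pmf`` (binomial point probability, the definition used here) or
        ``tail`` (P(X >= k)).
    homopolymer_len
        Minimum run length defining a homopolymer hotspot context.
    """

    min_freq: float = 0.015
    error_rate: float = 0.005
    pf_max: float = 0.01
    qf_max: float = 0.001
    pi0: Optional[float] = 0.05
    pf_mode: str = "pmf"
    homopolymer_len: int = 4
    apply_hotspot_filter: bool = True
    pool_samples: bool = False

    def __post_init__(self) -> None:
        for name in ("min_freq", "error_rate", "pf_max", "qf_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pi0 is not None and not 0 < self.pi0 <= 1:
            raise ValueError(f"pi0 must be in (0,1], got {self.pi0}")
        if self.pf_mode not in ("pmf", "tail"):
            raise ValueError(f"pf_mode must be pmf|tail, got {self.pf_mode!r}")


def binomial_false_positive(
    n, k, p: float = 0.005, mode: str = "pmf"
):
    """False-positive probability of seeing k error reads among n at error rate p.

    ``mode='pmf'`` returns the binomial point mass C(n,k) p^k (1-p)^(n-k),
    evaluated in log space; ``mode='tail'`` returns the upper tail
    P(X >= k).  Accepts scalars or arrays.
    """
    n_arr = np.asarray(n)
    k_arr = np.asarray(k)
    if np.any(k_arr > n_arr) or np.any(k_arr < 0):
        raise ValueError("require 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError(f"error rate must be in [0,1], got {p}")
    if mode == "pmf":
        out = np.exp(stats.binom.logpmf(k_arr, n_arr, p))
    elif mode == "tail":
        out = stats.binom.sf(k_arr - 1, n_arr, p)
    else:
        raise ValueError(f"mode must be pmf|tail, got {mode!r}")
    return float(out) if np.isscalar(n) and np.isscalar(k) else out


def min_coverage_for_significance(
    freq: float, p: float = 0.005, pf_max: float = 0.01,
    mode: str = "pmf", n_max: int = 20000,
) -> int:
    """Coverage beyond which a variant at frequency ``freq`` stays significant.

    At each coverage n the variant count is k = ceil(freq * n); the P_f(n)
    curve oscillates at low coverage as k steps, so the cut-off is the
    smallest n with P_f(n', k(n')) < pf_max for every n' >= n (up to
    ``n_max``).  Raising the frequency threshold lowers this cut-off.
    """
    ns = np.arange(1, n_max + 1)
    ks = np.minimum(np.ceil(freq * ns).astype(int), ns)
    pf = binomial_false_positive(ns, ks, p, mode)
    violations = np.nonzero(pf >= pf_max)[0]
    if violations.size == 0:
        return 1
    cutoff = int(ns[violations[-1]]) + 1
    if cutoff > n_max:
        raise ValueError(f"P_f never stays below {pf_max} for n <= {n_max} at freq {freq}")
    return cutoff


def estimate_pi0(pvalues: np.ndarray, lambdas: Optional[np.ndarray] = None) -> float:
    """Storey smoother estimate of the true-null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid, smoothed
    with a cubic spline and read off at the largest lambda; clipped to (0, 1].
    """
    from scipy.interpolate import UnivariateSpline

    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0s = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if m < 8 or np.allclose(pi0s, pi0s[0]):
        pi0 = pi0s[-1]
    else:
        spline = UnivariateSpline(lambdas, pi0s, k=3)
        pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(
    pvalues: Sequence[float], pi0: Optional[float] = 0.05, m: Optional[int] = None
) -> np.ndarray:
    """Step-up q-values: q(i) = min_{j >= i} pi0 * m * p(j) / j over sorted p.

    ``m`` defaults to the number of p-values; ``pi0=None`` estimates pi0
    with the Storey smoother.  Results are mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    if m is None:
        m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_candidates(
    pileup: pd.DataFrame,
    consensus: Optional[pd.Series] = None,
    config: CallerConfig = CallerConfig(),
    sample: str = "sample",
) -> pd.DataFrame:
    """Candidate heteroplasmic sites: non-consensus bases above the frequency threshold.

    Each qualifying site contributes one candidate for its highest-count
    alternate base (ties broken alphabetically); sites with more than one
    qualifying alternate are flagged multi-allelic.  Zero-depth positions
    are skipped.  Frequencies are relative to total depth, so the minor
    allele is bounded at <= 50% (variants are called against the per-sample
    consensus, not the external reference).
    """
    if consensus is None:
        consensus = consensus_track(pileup)
    counts = pileup[list(BASES)].to_numpy()
    n = counts.sum(axis=1)
    cons = consensus.to_numpy()

    cons_idx = np.full(len(pileup), -1)
    for i, b in enumerate(BASES):
        cons_idx[cons == b] = i
    covered = (n > 0) & (cons_idx >= 0)

    alt = counts.astype(float).copy()
    rows = np.arange(len(pileup))
    alt[rows[covered], cons_idx[covered]] = -1.0  # consensus base never a variant
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = alt / n[:, None]
    qualifies = (freqs > config.min_freq) & covered[:, None]
    n_quals = qualifies.sum(axis=1)
    has_candidate = n_quals > 0

    recs = []
    base_arr = np.array(BASES)
    for i in rows[has_candidate]:
        quald = qualifies[i]
        kvec = np.where(quald, counts[i], -1)
        best = kvec.max()
        variant = base_arr[kvec == best][0]  # alphabetical tie-break
        k = int(counts[i, base_arr.tolist().index(variant)])
        recs.append(
            {
                "sample": sample,
                "chrom": pileup["chrom"].iat[i],
                "pos": int(pileup["pos"].iat[i]),
                "consensus": cons[i],
                "variant": variant,
                "k": k,
                "n": int(n[i]),
                "freq": k / n[i],
                "multi_allelic": bool(n_quals[i] > 1),
            }
        )
    cols = CALL_COLUMNS[:9]
    return pd.DataFrame(recs, columns=cols)


def flag_hotspots(
    calls: pd.DataFrame,
    reference: ReferenceSet,
    homopolymer_len: int = 4,
) -> pd.DataFrame:
    """Set sequencing-error hotspot flags on a call table.

    ``hotspot_homopolymer``: the ``homopolymer_len`` reference bases
    immediately 5' of the site on either strand are one repeated base
    (i.e. pos-L..pos-1 identical, or pos+1..pos+L identical; modular on
    circular chromosomes, truncated sides never flag on linear ones).

    ``hotspot_adjacent``: both members of any pair of called sites at
    consecutive positions on the same chromosome in the same sample.
    """
    calls = calls.copy()
    homo = np.zeros(len(calls), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(calls["chrom"], calls["pos"])):
        ref = reference[chrom]
        homo[i] = _homopolymer_context(ref, int(pos), homopolymer_len)
    calls["hotspot_homopolymer"] = homo

    adj = np.zeros(len(calls), dtype=bool)
    key = calls[["sample", "chrom", "pos"]]
    pos_set = set(map(tuple, key.to_numpy()))
    for i, (s, c, p) in enumerate(key.to_numpy()):
        if (s, c, p + 1) in pos_set or (s, c, p - 1) in pos_set:
            adj[i] = True
    calls["hotspot_adjacent"] = adj
    return calls


def _homopolymer_context(ref, pos: int, run_len: int) -> bool:
    length = ref.length
    circular = ref.topology == "circular"
    for offsets in (range(-run_len, 0), range(1, run_len + 1)):
        positions = [pos + o for o in offsets]
        if not circular and (positions[0] < 1 or positions[-1] > length):
            continue
        bases = {ref.base_at(p) for p in positions}
        if len(bases) == 1 and "N" not in bases:
            return True
    return False


def finalize_calls(
    candidates: pd.DataFrame,
    config: CallerConfig = CallerConfig(),
    reference: Optional[ReferenceSet] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score candidates and assign final status; returns (calls, attrition).

    Status is assigned in filter order: frequency, then P_f, then Q_f
    (computed per sample over that sample's candidate set, or pooled when
    configured), then hotspot exclusion applied to the significance
    survivors.  The attrition dict counts removals per stage.
    """
    calls = candidates.copy()
    if calls.empty:
        for col in CALL_COLUMNS[9:]:
            calls[col] = pd.Series(dtype=float)
        return calls, {"candidates": 0, "fail_freq": 0, "fail_pf": 0,
                       "fail_qf": 0, "fail_hotspot": 0, "pass": 0}

    calls["p_f"] = binomial_false_positive(
        calls["n"].to_numpy(), calls["k"].to_numpy(), config.error_rate, config.pf_mode
    )
    if config.pool_samples:
        calls["q_f"] = storey_qvalues(calls["p_f"].to_numpy(), pi0=config.pi0)
    else:
        calls["q_f"] = (
            calls.groupby("sample", group_keys=False)["p_f"]
            .transform(lambda s: storey_qvalues(s.to_numpy(), pi0=config.pi0))
        )

    if reference is not None:
        calls = flag_hotspots(calls, reference, config.homopolymer_len)
    else:
        calls["hotspot_homopolymer"] = False
        calls["hotspot_adjacent"] = False

    status = np.full(len(calls), "pass", dtype=object)
    fail_freq = ~(calls["freq"].to_numpy() > config.min_freq)
    fail_pf = ~(calls["p_f"].to_numpy() < config.pf_max)
    fail_qf = ~(calls["q_f"].to_numpy() < config.qf_max)
    status[fail_qf] = "fail_qf"
    status[fail_pf] = "fail_pf"
    status[fail_freq] = "fail_freq"
    if config.apply_hotspot_filter:
        # adjacency is re-evaluated among the significance survivors only
        survivors = status == "pass"
        if reference is not None and survivors.any():
            surv = flag_hotspots(
                calls.loc[survivors, CALL_COLUMNS[:9]], reference, config.homopolymer_len
            )
            calls.loc[survivors, "hotspot_adjacent"] = surv["hotspot_adjacent"].to_numpy()
        hot = (
            calls["hotspot_homopolymer"].to_numpy() | calls["hotspot_adjacent"].to_numpy()
        )
        status[survivors & hot] = "fail_hotspot"
    calls["status"] = status

    attrition = {"candidates": len(calls)}
    for s in STATUS_ORDER[1:] + ["pass"]:
        attrition[s] = int((status == s).sum())
    return calls, attrition


# ---------------------------------------------------------------------------
# Model / Results

class HeteroplasmyModel:
    """Binomial sequencing-error model for minor-allele calls in one sample.

    Parameters
    ----------
    pileup : DataFrame | path
        Pileup table (chrom, pos, ref, A, C, G, T) or a path to the TSV /
        SAM / BAM it should be built from.
    reference : ReferenceSet, optional
        Needed for hotspot-context evaluation and annotation.
    sample : str
        Sample identifier carried on every call.
    config : CallerConfig
    annotations, code, properties : optional
        When provided, :meth:`fit` also annotates passing calls with gene,
        codon and amino-acid-change context.
    """

    def __init__(
        self,
        pileup: Union[pd.DataFrame, str, Path],
        reference: Optional[ReferenceSet] = None,
        sample: str = "sample",
        config: Optional[CallerConfig] = None,
        annotations: Optional[Sequence[GeneAnnotation]] = None,
        code: Optional[GeneticCode] = None,
        properties: Optional[AminoAcidProperties] = None,
    ):
        if not isinstance(pileup, pd.DataFrame):
            pileup = build_site_counts(pileup, reference) if reference is not None \
                else pd.read_csv(pileup, sep="\t", dtype={"chrom": str})
        self.pileup = pileup
        self.reference = reference
        self.sample = sample
        self.config = config or CallerConfig()
        self.annotations = annotations
        self.code = code
        self.properties = properties

    def fit(self) -> "HeteroplasmyResults":
        consensus = consensus_track(self.pileup)
        candidates = call_candidates(self.pileup, consensus, self.config, self.sample)
        calls, attrition = finalize_calls(candidates, self.config, self.reference)
        annotated = None
        if self.annotations is not None and self.reference is not None:
            from .annotate import annotate_calls

            annotated = annotate_calls(
                calls[calls["status"] == "pass"],
                self.reference, self.annotations, self.code, self.properties,
            )
        return HeteroplasmyResults(self, calls, attrition, consensus, annotated)


class HeteroplasmyResults:
    """Fitted call set for one sample.

    Attributes
    ----------
    calls : DataFrame
        Every candidate with k, n, freq, P_f, Q_f, hotspot flags and status.
    passed : DataFrame
        The subset with status == 'pass' (the heteroplasmic sites).
    attrition : dict
        Candidates removed per filter stage.
    annotated : DataFrame | None
        Gene/codon/amino-acid annotation of passing calls, when the model
        was given annotations.
    """

    def __init__(self, model, calls, attrition, consensus, annotated=None):
        self.model = model
        self.calls = calls
        self.attrition = attrition
        self.consensus = consensus
        self.annotated = annotated

    @property
    def passed(self) -> pd.DataFrame:
        return self.calls[self.calls["status"] == "pass"]

    @property
    def n_sites(self) -> int:
        return len(self.passed)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Heteroplasmy call summary",
            "=" * 64,
            f"sample:            {self.model.sample}",
            f"positions piled:   {len(self.model.pileup)}",
            f"mean depth:        {depth(self.model.pileup).mean():.1f}",
            f"thresholds:        freq > {cfg.min_freq:g}, P_f < {cfg.pf_max:g}, "
            f"Q_f < {cfg.qf_max:g} (pi0={cfg.pi0}, {cfg.pf_mode})",
            f"error rate p:      {cfg.error_rate:g}",
            "-" * 64,
            f"candidates:        {self.attrition['candidates']}",
            f"  fail frequency:  {self.attrition['fail_freq']}",
            f"  fail P_f:        {self.attrition['fail_pf']}",
            f"  fail Q_f:        {self.attrition['fail_qf']}",
            f"  hotspot-excluded:{self.attrition['fail_hotspot']:>5}",
            f"heteroplasmic sites: {self.attrition['pass']}",
        ]
        if self.annotated is not None and len(self.annotated):
            by_class = (
                self.annotated.drop_duplicates(subset=["chrom", "pos"])
                .groupby("gene_class").size()
            )
            lines.append("-" * 64)
            for cls_name, cnt in by_class.items():
                lines.append(f"  {cls_name:<12} {cnt}")
        return "\n".join(lines)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path: Union[str, Path]) -> None:
        """Minimal VCF: consensus as REF, variant as ALT, FILTER mirrors status."""
        cfg = self.model.config
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=mthet\n')
            if self.model.reference is not None:
                for seq in self.model.reference:
                    fh.write(f"##contig=<ID={seq.id},length={seq.length}>\n")
            fh.write('##INFO=<ID=K,Number=1,Type=Integer,Description="Variant read count">\n')
            fh.write('##INFO=<ID=N,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##INFO=<ID=FREQ,Number=1,Type=Float,Description="Variant frequency">\n')
            fh.write('##INFO=<ID=PF,Number=1,Type=Float,Description="Binomial false-positive probability">\n')
            fh.write('##INFO=<ID=QF,Number=1,Type=Float,Description="Storey q-value">\n')
            fh.write('##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Sequencing-error hotspot context">\n')
            for name in ("fail_freq", "fail_pf", "fail_qf", "fail_hotspot"):
                fh.write(f'##FILTER=<ID={name},Description="Removed at the {name[5:]} stage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for row in self.calls.itertuples(index=False):
                filt = "PASS" if row.status == "pass" else row.status
                info = (
                    f"K={row.k};N={row.n};FREQ={row.freq:.6g};"
                    f"PF={row.p_f:.6g};QF={row.q_f:.6g}"
                )
                if row.hotspot_homopolymer or row.hotspot_adjacent:
                    info += ";HOTSPOT"
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.consensus}\t{row.variant}"
                    f"\t.\t{filt}\t{info}\n"
                )
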