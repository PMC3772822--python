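"""Published cohort summary tables from a deep-sequencing heteroplasmy survey.

These are transcribed per-sample heteroplasmic-site counts for twelve human
lice (six body, six head; Ethiopia, China, France; fragmented 20-mini-
chromosome mt genomes sequenced to ~6,000x) and seven tick species (single
mt chromosome, ~1,700x), called at minimum variant frequency >1.5%,
P_f < 1%, Q_f < 0.1%, hotspot-excluded.  They serve as desk-scale fixtures
for the cohort-statistics layer: the raw sequencing runs they derive from
are multi-gigabyte archive downloads and are not re-processed here.

Loaders return pandas DataFrames; column conventions:

``load_louse_cohort`` / ``load_tick_cohort``
    one row per sample: total, protein (with nonsynonymous subset), rRNA
    and tRNA site counts, plus country metadata.
``load_louse_gene_counts`` / ``load_tick_gene_counts``
    long format: sample, gene, sites, nonsynonymous (blank for rRNA/tRNA
    rows, where the syn/nonsyn split does not apply).
``load_louse_shared_matrix``
    upper-triangular pairwise shared-site counts between the 12 lice,
    returned as a full symmetric matrix with a zero diagonal.

The tables are transcribed verbatim, including one internal inconsistency
in the source: the *Otobius megnini* per-gene row sums to 25 (24 protein +
1 rRNA) while the per-sample summary prints a total of 24 with 23 protein
sites.  Cross-table aggregates derived here use the per-sample summary for
totals and the per-gene table for gene-level sums.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _path(name: str):
    return resources.files(__package__) / name


def load_louse_cohort() -> pd.DataFrame:
    return pd.read_csv(_path("louse_cohort.tsv"), sep="\t")


def load_tick_cohort() -> pd.DataFrame:
    return pd.read_csv(_path("tick_cohort.tsv"), sep="\t")


def load_louse_gene_counts() -> pd.DataFrame:
    return pd.read_csv(_path("louse_gene_counts.tsv"), sep="\t")


def load_tick_gene_counts() -> pd.DataFrame:
    return pd.read_csv(_path("tick_gene_counts.tsv"), sep="\t")


def load_louse_shared_matrix() -> pd.DataFrame:
    """Pairwise shared-site counts, symmetrised (diagonal left at zero)."""
    df = pd.read_csv(_path("louse_shared_sites.tsv"), sep="\t", index_col="sample")
    samples = list(df.index) + [c for c in df.columns if c not in df.index]
    full = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for row in df.index:
        for col in df.columns:
            v = df.loc[row, col]
            if not np.isnan(v):
                full.loc[row, col] = int(v)
                full.loc[col, row] = int(v)
    return full
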