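"""Construction of activity-score training sets from screen phenotype tables.

Hit genes are selected with the discriminant |z * log10(p)| >= threshold in
any screen; each gene's sgRNA phenotypes are then taken from the screen in
which it scored and normalized to the mean of its top-k (default 3) sgRNAs
by absolute value, yielding "activity scores" in which the strongest guides
sit near 1.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, TextIO

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ActivityRecord:
    sgrna_id: str
    gene: str
    tss_id: str
    activity_score: float
    phenotype: float


# gene-level screen statistics: columns gene, screen, z, p
# sgRNA-level phenotypes: columns sgrna_id, gene, screen, phenotype


def discriminant(z: float, p: float) -> float:
    """|z * log10 p|; p == 0 is clamped to the smallest positive float."""
    if p < 0 or p > 1:
        raise ValueError(f"p-value out of range: {p}")
    if p == 0:
        warnings.warn("p == 0 clamped to smallest representable value", stacklevel=2)
        p = sys.float_info.min
    return abs(z * np.log10(p))


def select_hit_genes(
    gene_stats: pd.DataFrame, discriminant_min: float = 20.0
) -> dict[str, str]:
    """Genes meeting the discriminant in any screen -> the screen attaining it.

    When several screens qualify, the screen with the largest discriminant
    wins (the screen "in which the gene was a hit").
    """
    required = {"gene", "screen", "z", "p"}
    if not required.issubset(gene_stats.columns):
        raise ValueError(f"gene_stats must have columns {sorted(required)}")
    hits: dict[str, tuple[float, str]] = {}
    for row in gene_stats.itertuples(index=False):
        d = discriminant(row.z, row.p)
        if d >= discriminant_min:
            best = hits.get(row.gene)
            if best is None or d > best[0]:
                hits[row.gene] = (d, row.screen)
    return {gene: screen for gene, (_, screen) in sorted(hits.items())}


def compute_activity_scores(
    phenotypes: pd.DataFrame,
    hit_screens: Optional[Mapping[str, str]] = None,
    top_k: int = 3,
) -> list[ActivityRecord]:
    """Normalize per-gene sgRNA phenotypes to the top-k |phenotype| mean.

    ``phenotypes`` columns: sgrna_id, gene, phenotype, optionally screen and
    tss_id. With ``hit_screens`` given, only rows from each gene's hit screen
    are used. Genes with fewer than ``top_k`` sgRNAs or a zero normalizer are
    dropped with a warning. Signs are preserved, so a guide as strong as the
    gene's best has score ~= 1 regardless of phenotype direction.
    """
    df = phenotypes.copy()
    if "screen" in df.columns and hit_screens is not None:
        df = df[df.apply(lambda r: hit_screens.get(r["gene"]) == r["screen"], axis=1)]
    elif hit_screens is not None:
        df = df[df["gene"].isin(hit_screens)]
    if "tss_id" not in df.columns:
        df["tss_id"] = df["gene"] + ":P1"

    records: list[ActivityRecord] = []
    for gene, group in df.groupby("gene", sort=True):
        values = group["phenotype"].to_numpy(dtype=float)
        if len(values) < top_k:
            warnings.warn(f"gene {gene}: fewer than {top_k} sgRNAs, dropped", stacklevel=2)
            continue
        # signed mean of the top-k phenotypes ranked by absolute value
        norm = values[np.argsort(np.abs(values))[-top_k:]].mean()
        if norm == 0:
            warnings.warn(f"gene {gene}: top-{top_k} mean is 0, dropped", stacklevel=2)
            continue
        for row in group.itertuples(index=False):
            records.append(
                ActivityRecord(
                    sgrna_id=row.sgrna_id,
                    gene=gene,
                    tss_id=row.tss_id,
                    activity_score=row.phenotype / norm,
                    phenotype=row.phenotype,
                )
            )
    return records


def write_activity_table(records: Iterable[ActivityRecord], handle: TextIO) -> None:
    handle.write("sgrna_id\tgene\ttss_id\tphenotype\tactivity_score\n")
    for r in records:
        handle.write(
            f"{r.sgrna_id}\t{r.gene}\t{r.tss_id}\t{r.phenotype:.6g}\t{r.activity_score:.6g}\n"
        )


def read_activity_table(handle: TextIO) -> list[ActivityRecord]:
    df = pd.read_csv(handle, sep="\t")
    return [
        ActivityRecord(r.sgrna_id, r.gene, r.tss_id, r.activity_score, r.phenotype)
        for r in df.itertuples(index=False)
    ]
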