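"""Pooled-screen quantification: counts -> growth phenotypes -> gene calls.

Per-sgRNA growth phenotypes (gamma) are depth-normalized log2 enrichments
from T0 to endpoint, centered on the median of the non-targeting controls
and divided by the number of cell doublings. Genes are scored by the mean of
their 3 strongest-|gamma| sgRNAs and a two-sided Mann-Whitney test against
the full negative-control sgRNA set; pseudo-genes assembled from randomly
sampled non-targeting guides calibrate the null and the empirical FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

MIN_READS = 50  # sgRNAs under this in BOTH samples are excluded


@dataclass
class CountTable:
    """Read counts per sgRNA at T0/endpoint for one or more replicates."""

    counts: pd.DataFrame  # index sgrna_id; columns (replicate, sample)
    doublings: dict[str, float]  # replicate -> cell doublings

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts must have (replicate, sample) columns")
        for rep, d in self.doublings.items():
            if d <= 0:
                raise ValueError(f"replicate {rep}: doublings must be > 0")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def replicates(self) -> list[str]:
        return sorted({rep for rep, _ in self.counts.columns})


@dataclass
class GrowthPhenotypes:
    """Per-sgRNA gamma values per replicate plus the replicate average."""

    gammas: pd.DataFrame  # index sgrna_id (count-filter survivors); columns: replicates + "mean"
    nontargeting_ids: list[str]

    @property
    def mean(self) -> pd.Series:
        return self.gammas["mean"]


@dataclass(frozen=True)
class GeneScore:
    gene: str
    tss_id: str
    phenotype: float  # mean of top-3 |gamma| sgRNAs
    p_value: float
    n_sgrnas: int
    z: float = math.nan
    hit_score: float = math.nan


@dataclass(frozen=True)
class NcGene:
    pseudo_gene_id: str
    member_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# counting


def count_protospacers(
    reads: Iterable[str],
    expression_seqs: Mapping[str, str],
    offset: int = 0,
) -> tuple[pd.Series, int]:
    """Exact-match counting of expression sequences at a fixed read offset.

    ``reads`` is an iterable of FASTQ lines. Returns (counts per sgRNA id,
    number of unmatched reads).
    """
    lookup: dict[str, str] = {}
    length = None
    for sgrna_id, seq in expression_seqs.items():
        seq = seq.upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError("expression sequences must share one length")
        lookup[seq] = sgrna_id
    counts = {sgrna_id: 0 for sgrna_id in expression_seqs}
    unmatched = 0
    for i, line in enumerate(reads):
        if i % 4 != 1:  # sequence lines of FASTQ records
            continue
        read = line.strip().upper()
        if offset + (length or 0) > len(read):
            raise ValueError(f"offset {offset} beyond read length {len(read)}")
        sgrna_id = lookup.get(read[offset:offset + length])
        if sgrna_id is None:
            unmatched += 1
        else:
            counts[sgrna_id] += 1
    return pd.Series(counts, name="count"), unmatched


def make_count_table(
    t0: Mapping[str, Mapping[str, int]],
    endpoint: Mapping[str, Mapping[str, int]],
    doublings: Mapping[str, float],
) -> CountTable:
    """Build a CountTable from {replicate: {sgrna_id: count}} mappings."""
    frames = {}
    for rep in doublings:
        frames[(rep, "T0")] = pd.Series(t0[rep])
        frames[(rep, "endpoint")] = pd.Series(endpoint[rep])
    df = pd.DataFrame(frames).fillna(0).astype(int)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return CountTable(df, dict(doublings))


# ---------------------------------------------------------------------------
# gamma


def compute_gamma(
    table: CountTable,
    nontargeting_ids: Sequence[str],
    pseudocount: float = 1.0,
    min_reads: int = MIN_READS,
) -> GrowthPhenotypes:
    """Per-sgRNA growth phenotypes.

    sgRNAs with fewer than ``min_reads`` reads in BOTH T0 and endpoint (in
    every replicate) are excluded. Within each replicate, samples are scaled
    to equal total depth, log2 ratios are taken with a pseudocount, the
    median over non-targeting sgRNAs is subtracted (so their median gamma is
    exactly 0), and the result is divided by the replicate's cell doublings.
    """
    nt = set(nontargeting_ids)
    if not nt.issubset(table.counts.index):
        raise ValueError("non-targeting ids missing from count table")
    reps = table.replicates

    keep = pd.Series(False, index=table.counts.index)
    for rep in reps:
        t0 = table.counts[(rep, "T0")]
        end = table.counts[(rep, "endpoint")]
        keep |= (t0 >= min_reads) | (end >= min_reads)
    counts = table.counts.loc[keep]
    nt_kept = [i for i in counts.index if i in nt]
    if not nt_kept:
        raise ValueError("no non-targeting sgRNAs survive the count filter")

    gammas = {}
    for rep in reps:
        t0 = counts[(rep, "T0")].to_numpy(dtype=float)
        end = counts[(rep, "endpoint")].to_numpy(dtype=float)
        if t0.sum() == 0 or end.sum() == 0:
            raise ValueError(f"replicate {rep}: zero total depth")
        scale = t0.sum() / end.sum()
        raw = np.log2((end * scale + pseudocount) / (t0 + pseudocount))
        raw_series = pd.Series(raw, index=counts.index)
        raw_series -= raw_series.loc[nt_kept].median()
        gammas[rep] = raw_series / table.doublings[rep]
    df = pd.DataFrame(gammas)
    df["mean"] = df[reps].mean(axis=1)
    return GrowthPhenotypes(df, nt_kept)


# ---------------------------------------------------------------------------
# gene scoring


def mann_whitney_p(group: np.ndarray, controls: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact for small tie-free inputs, otherwise
    the tie-corrected normal approximation with continuity correction."""
    res = stats.mannwhitneyu(group, controls, alternative="two-sided", method="auto")
    return float(res.pvalue)


def min_achievable_p(n_group: int, n_controls: int) -> float:
    """Floor of the Mann-Whitney p-value for given group sizes."""
    res = stats.mannwhitneyu(
        np.arange(n_group), np.arange(n_group, n_group + n_controls),
        alternative="two-sided", method="exact",
    )
    return float(res.pvalue)


def _top_k_mean_abs(values: np.ndarray, k: int = 3) -> float:
    """Signed mean of the k strongest values by absolute value."""
    idx = np.argsort(np.abs(values))[-k:]
    return float(values[idx].mean())


def score_genes(
    phenotypes: GrowthPhenotypes,
    gene_map: Mapping[str, tuple[str, str]],
    top_k: int = 3,
) -> list[GeneScore]:
    """Score each TSS, then collapse multi-TSS genes to the lowest-p TSS.

    ``gene_map`` maps sgrna_id -> (gene, tss_id). Non-targeting sgRNAs (the
    phenotype object's control set) are the Mann-Whitney reference.
    """
    controls = phenotypes.mean.loc[phenotypes.nontargeting_ids].to_numpy()
    if controls.size == 0:
        raise ValueError("no negative-control sgRNAs available")

    by_tss: dict[tuple[str, str], list[float]] = {}
    for sgrna_id, gamma in phenotypes.mean.items():
        if sgrna_id in gene_map:
            by_tss.setdefault(gene_map[sgrna_id], []).append(float(gamma))

    tss_scores: list[GeneScore] = []
    for (gene, tss_id), values in sorted(by_tss.items()):
        arr = np.asarray(values)
        tss_scores.append(
            GeneScore(
                gene=gene,
                tss_id=tss_id,
                phenotype=_top_k_mean_abs(arr, min(top_k, len(arr))),
                p_value=mann_whitney_p(arr, controls),
                n_sgrnas=len(arr),
            )
        )

    best: dict[str, GeneScore] = {}
    for s in tss_scores:
        cur = best.get(s.gene)
        if cur is None or s.p_value < cur.p_value:
            best[s.gene] = s
    return [best[g] for g in sorted(best)]


def make_nc_genes(
    nontargeting_ids: Sequence[str], n_genes: int, size: int = 10, seed: int = 0
) -> list[NcGene]:
    """Pseudo-genes of non-targeting sgRNAs sampled with replacement."""
    if not nontargeting_ids:
        raise ValueError("need at least one non-targeting sgRNA")
    rng = np.random.default_rng(seed)
    ids = list(nontargeting_ids)
    return [
        NcGene(
            pseudo_gene_id=f"nc_gene_{i:05d}",
            member_ids=tuple(ids[j] for j in rng.integers(0, len(ids), size)),
        )
        for i in range(n_genes)
    ]


def score_nc_genes(
    phenotypes: GrowthPhenotypes, nc_genes: Sequence[NcGene], top_k: int = 3
) -> list[GeneScore]:
    """Score pseudo-genes exactly as true genes."""
    controls = phenotypes.mean.loc[phenotypes.nontargeting_ids].to_numpy()
    out = []
    for nc in nc_genes:
        members = [m for m in nc.member_ids if m in phenotypes.mean.index]
        if not members:
            continue
        arr = phenotypes.mean.loc[members].to_numpy()
        out.append(
            GeneScore(
                gene=nc.pseudo_gene_id,
                tss_id=nc.pseudo_gene_id,
                phenotype=_top_k_mean_abs(arr, min(top_k, len(arr))),
                p_value=mann_whitney_p(arr, controls),
                n_sgrnas=len(arr),
            )
        )
    return out


def standardize_scores(
    gene_scores: Sequence[GeneScore], nc_scores: Sequence[GeneScore]
) -> tuple[list[GeneScore], list[GeneScore]]:
    """Attach z (vs the NC-gene phenotype distribution) and the combined
    hit score z * -log10(p) to every record."""
    nc_phen = np.array([s.phenotype for s in nc_scores])
    if nc_phen.size < 2:
        raise ValueError("need >= 2 negative-control genes for standardization")
    mu, sd = nc_phen.mean(), nc_phen.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate negative-control phenotype distribution")

    def attach(scores: Sequence[GeneScore]) -> list[GeneScore]:
        out = []
        for s in scores:
            z = (s.phenotype - mu) / sd
            out.append(
                GeneScore(
                    gene=s.gene, tss_id=s.tss_id, phenotype=s.phenotype,
                    p_value=s.p_value, n_sgrnas=s.n_sgrnas, z=z,
                    hit_score=z * -math.log10(s.p_value),
                )
            )
        return out

    return attach(gene_scores), attach(nc_scores)


def call_hits(
    gene_scores: Sequence[GeneScore],
    nc_scores: Sequence[GeneScore],
    threshold: Optional[float] = None,
    target_nc_rate: float = 0.0021,
    direction: Optional[str] = None,
) -> dict:
    """Threshold the combined hit score; estimate the empirical FDR.

    ``direction`` of "negative"/"positive" restricts calls to signed hit
    scores <= -threshold / >= +threshold; by default |score| >= threshold.
    Without an explicit threshold, it is calibrated so the NC-gene pass rate
    is at most ``target_nc_rate``.
    """
    if not nc_scores:
        warnings.warn("no NC genes: empirical FDR unavailable", stacklevel=2)

    def passes(score: float, thr: float) -> bool:
        if direction == "negative":
            return score <= -thr
        if direction == "positive":
            return score >= thr
        return abs(score) >= thr

    if threshold is None:
        if not nc_scores:
            raise ValueError("cannot calibrate a threshold without NC genes")
        magnitudes = sorted((abs(s.hit_score) for s in nc_scores), reverse=True)
        k = int(math.floor(target_nc_rate * len(magnitudes)))
        # smallest threshold passing at most k NC genes
        threshold = magnitudes[k] + 1e-12 if k < len(magnitudes) else magnitudes[-1]

    hits = [s.gene for s in gene_scores if passes(s.hit_score, threshold)]
    nc_pass = sum(1 for s in nc_scores if passes(s.hit_score, threshold))
    frac_nc = nc_pass / len(nc_scores) if nc_scores else math.nan
    frac_genes = len(hits) / len(gene_scores) if gene_scores else math.nan
    fdr = frac_nc / frac_genes if (nc_scores and frac_genes > 0) else math.nan
    return {
        "threshold": float(threshold),
        "hits": hits,
        "nc_pass_rate": frac_nc,
        "gene_pass_rate": frac_genes,
        "empirical_fdr": fdr,
    }


# ---------------------------------------------------------------------------
# evaluation against gold standards


def roc_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from .activity_model import roc_curve_points

    return roc_curve_points(labels, scores)


def precision_recall_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) over descending score thresholds."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not labels.any():
        raise ValueError("no positive labels")
    order = np.argsort(-scores, kind="stable")
    l = labels[order]
    s = scores[order]
    tps = np.cumsum(l)
    n_pred = np.arange(1, len(l) + 1)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    recall = tps[distinct] / labels.sum()
    precision = tps[distinct] / n_pred[distinct]
    return recall, precision


def recall_at_precision(
    labels: np.ndarray, scores: np.ndarray, precision_min: float = 0.95
) -> float:
    """Best recall achievable at >= the requested precision."""
    recall, precision = precision_recall_points(labels, scores)
    ok = precision >= precision_min
    return float(recall[ok].max()) if ok.any() else 0.0


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    recall, precision = precision_recall_points(labels, scores)
    r = np.r_[0.0, recall]
    return float(np.sum((r[1:] - r[:-1]) * precision))


def evaluate_screen(
    phenotypes: GrowthPhenotypes,
    gene_scores: Sequence[GeneScore],
    gene_map: Mapping[str, tuple[str, str]],
    essential: set[str],
    nonessential: set[str],
    precision_min: float = 0.95,
) -> dict:
    """sgRNA-level ROC, gene-level precision-recall, active sgRNA fraction.

    sgRNAs are ranked by gamma (negative = depleted = essential-like); genes
    by phenotype. The active fraction is the share of essential-targeting
    sgRNAs with z < -2 relative to the non-essential-targeting distribution.
    """
    if not essential or not nonessential:
        raise ValueError("gold-standard gene sets must be non-empty")
    if essential & nonessential:
        raise ValueError("gold-standard gene sets overlap")

    sg_gamma, sg_label = [], []
    ne_gammas = []
    ess_gammas = []
    for sgrna_id, gamma in phenotypes.mean.items():
        info = gene_map.get(sgrna_id)
        if info is None:
            continue
        gene = info[0]
        if gene in essential:
            sg_gamma.append(gamma)
            sg_label.append(True)
            ess_gammas.append(gamma)
        elif gene in nonessential:
            sg_gamma.append(gamma)
            sg_label.append(False)
            ne_gammas.append(gamma)
    sg_gamma = np.asarray(sg_gamma)
    sg_label = np.asarray(sg_label)
    fpr, tpr = roc_points(sg_label, -sg_gamma)  # more-negative gamma ranks first
    sg_auc = float(np.trapezoid(tpr, fpr))

    ne = np.asarray(ne_gammas)
    z = (np.asarray(ess_gammas) - ne.mean()) / ne.std(ddof=0)
    active_fraction = float((z < -2).mean()) if len(z) else math.nan

    g_label, g_score = [], []
    for s in gene_scores:
        if s.gene in essential:
            g_label.append(True)
        elif s.gene in nonessential:
            g_label.append(False)
        else:
            continue
        g_score.append(-s.phenotype)  # strong depletion ranks first
    g_label = np.asarray(g_label)
    g_score = np.asarray(g_score)
    return {
        "sgrna_roc_auc": sg_auc,
        "sgrna_roc": (fpr, tpr),
        "active_sgrna_fraction": active_fraction,
        "gene_pr": precision_recall_points(g_label, g_score),
        "gene_average_precision": average_precision(g_label, g_score),
        "recall_at_precision": recall_at_precision(g_label, g_score, precision_min),
    }


# ---------------------------------------------------------------------------
# I/O


def write_gene_scores(scores: Iterable[GeneScore], handle: TextIO) -> None:
    handle.write("gene\ttss_id\tphenotype\tp_value\tn_sgrnas\tz\thit_score\n")
    for s in scores:
        handle.write(
            f"{s.gene}\t{s.tss_id}\t{s.phenotype:.6g}\t{s.p_value:.6g}\t"
            f"{s.n_sgrnas}\t{s.z:.6g}\t{s.hit_score:.6g}\n"
        )


def write_phenotypes(phenotypes: GrowthPhenotypes, handle: TextIO) -> None:
    df = phenotypes.gammas.copy()
    df.index.name = "sgrna_id"
    df.to_csv(handle, sep="\t", float_format="%.6g")


def read_gene_list(handle: TextIO) -> set[str]:
    return {line.strip() for line in handle if line.strip()}
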