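"""Candidate sgRNA enumeration and feature engineering.

Candidates are 19-nt protospacers followed by an NGG PAM, enumerated on both
strands within a mode-specific window around each TSS-range edge (measured
at the genomic coordinate of the 3' G of the PAM, strand-aware, positive
downstream of the edge in the gene's transcriptional direction). Feature
computation covers signed TSS distances, per-position sequence one-hots,
dinucleotides, composition and homopolymer descriptors, guide secondary
structure, and chromatin signal averaged over the 22-bp target site.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import rnafold
from .annotations import TssAnnotation
from .intervals import Interval
from .tracks import GenomicTrack

PROTOSPACER_LEN = 19
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN  # 22 bp, PAM included

# default guide scaffold 5' segment used for co-fold metrics
DEFAULT_CONSTANT_REGION = "GTTTAAGAGCTAAGCTGGAA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# enumeration windows relative to TSS-range edges, inclusive
WINDOWS = {"CRISPRi": (-25, 500), "CRISPRa": (-550, -25)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SgrnaCandidate:
    """A genomic sgRNA target site: 19-nt protospacer + NGG PAM."""

    id: str
    gene: str
    tss_id: str  # "<gene>:<P1|P2|P1P2>"
    chrom: str
    strand: str
    pam_3g_coord: int
    protospacer_genomic: str
    expression_seq: str

    def __post_init__(self) -> None:
        if len(self.protospacer_genomic) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 19 nt")
        if len(self.expression_seq) != 20 or self.expression_seq[0] != "G":
            raise ValueError("expression sequence must be 20 nt starting with G")

    @property
    def site_interval(self) -> Interval:
        """Genomic footprint of protospacer + PAM (22 bp)."""
        if self.strand == "+":
            return Interval(self.pam_3g_coord - SITE_LEN + 1, self.pam_3g_coord + 1)
        return Interval(self.pam_3g_coord, self.pam_3g_coord + SITE_LEN)


def _range_edges(strand: str, rng: Interval) -> tuple[int, int]:
    """(upstream_edge, downstream_edge) genomic coordinates of a TSS range."""
    if strand == "+":
        return rng.start, rng.end - 1
    return rng.end - 1, rng.start


def signed_distance(strand: str, edge_coord: int, pam_3g_coord: int) -> int:
    """Signed bp from a TSS edge to the PAM 3'G; positive = downstream."""
    if strand == "+":
        return pam_3g_coord - edge_coord
    return edge_coord - pam_3g_coord


def _scan_plus(seq: str):
    """Yield (pam_3g_coord, protospacer) for + strand NGG sites."""
    for i in range(0, len(seq) - SITE_LEN + 1):
        if seq[i + 20] == "G" and seq[i + 21] == "G":
            proto = seq[i:i + PROTOSPACER_LEN]
            if "N" in proto or seq[i + 19] == "N":
                continue
            yield i + 21, proto


def _scan_minus(seq: str):
    """Yield (pam_3g_coord, protospacer) for - strand NGG sites.

    On the forward genome the site reads CCN + revcomp(protospacer); the 3'G
    of the PAM (read on the minus strand) sits at the leftmost coordinate.
    """
    for j in range(0, len(seq) - SITE_LEN + 1):
        if seq[j] == "C" and seq[j + 1] == "C":
            block = seq[j + 3:j + SITE_LEN]
            if "N" in block or seq[j + 2] == "N":
                continue
            yield j, revcomp(block)


def expression_sequence(protospacer: str) -> str:
    """G-prepended 20-nt sequence expressed from the U6 cassette."""
    return "G" + protospacer


def enumerate_candidates(
    genome: Mapping[str, str],
    tss: TssAnnotation,
    mode: str,
    window: Optional[tuple[int, int]] = None,
) -> list[SgrnaCandidate]:
    """Enumerate every NGG-adjacent candidate inside the TSS windows.

    A site is returned exactly once even if several range edges admit it.
    Windows extending past the contig are truncated with a warning.
    """
    if window is None:
        if mode not in WINDOWS:
            raise ValueError(f"unknown mode {mode!r}")
        window = WINDOWS[mode]
    lo, hi = window
    seq = genome.get(tss.chrom)
    if seq is None:
        raise KeyError(f"contig {tss.chrom!r} not in genome")
    seq = seq.upper()

    edges: list[tuple[str, int]] = []
    for range_name, rng in tss.ranges:
        up, down = _range_edges(tss.strand, rng)
        edges.append((range_name, up))
        edges.append((range_name, down))

    # genomic extent that could contain qualifying PAM 3'G positions
    coords = []
    for _, e in edges:
        if tss.strand == "+":
            coords += [e + lo, e + hi]
        else:
            coords += [e - hi, e - lo]
    gmin, gmax = min(coords), max(coords)
    if gmin < 0 or gmax >= len(seq):
        warnings.warn(
            f"window for {tss.gene} extends past contig {tss.chrom}; truncated",
            stacklevel=2,
        )
    scan_start = max(0, gmin - SITE_LEN)
    scan_end = min(len(seq), gmax + SITE_LEN + 1)
    sub = seq[scan_start:scan_end]

    def in_window(pam_3g: int) -> Optional[str]:
        for range_name, e in edges:
            if lo <= signed_distance(tss.strand, e, pam_3g) <= hi:
                return range_name
        return None

    out: list[SgrnaCandidate] = []
    seen: set[tuple[str, int]] = set()
    for strand, scanner in (("+", _scan_plus), ("-", _scan_minus)):
        for offset, proto in scanner(sub):
            pam_3g = scan_start + offset
            range_name = in_window(pam_3g)
            if range_name is None or (strand, pam_3g) in seen:
                continue
            seen.add((strand, pam_3g))
            tss_id = f"{tss.gene}:{range_name}"
            out.append(
                SgrnaCandidate(
                    id=f"{tss.gene}_{strand}{pam_3g}",
                    gene=tss.gene,
                    tss_id=tss_id,
                    chrom=tss.chrom,
                    strand=strand,
                    pam_3g_coord=pam_3g,
                    protospacer_genomic=proto,
                    expression_seq=expression_sequence(proto),
                )
            )
    out.sort(key=lambda c: (c.pam_3g_coord, c.strand))
    return out


# ---------------------------------------------------------------------------
# features


def position_features(c: SgrnaCandidate, tss: TssAnnotation) -> dict[str, float]:
    """Signed distances from the PAM 3'G to each TSS-range edge.

    Secondary distances are NaN (absent, never zero) when the annotation has
    no separately-targeted secondary range.
    """
    if c.chrom != tss.chrom:
        raise ValueError("candidate and TSS are on different contigs")
    p_up, p_down = _range_edges(tss.strand, tss.primary_range)
    feats = {
        "dist_primary_up": float(signed_distance(tss.strand, p_up, c.pam_3g_coord)),
        "dist_primary_down": float(signed_distance(tss.strand, p_down, c.pam_3g_coord)),
    }
    if tss.secondary_range is not None:
        s_up, s_down = _range_edges(tss.strand, tss.secondary_range)
        feats["dist_secondary_up"] = float(signed_distance(tss.strand, s_up, c.pam_3g_coord))
        feats["dist_secondary_down"] = float(signed_distance(tss.strand, s_down, c.pam_3g_coord))
    else:
        feats["dist_secondary_up"] = math.nan
        feats["dist_secondary_down"] = math.nan
    return feats


@dataclass(frozen=True)
class SequenceFeatureConfig:
    """Extent of flanking sequence included in per-position features."""

    flank5: int = 4  # bases 5' of the protospacer
    flank3: int = 3  # bases 3' of the PAM

    @property
    def context_len(self) -> int:
        return self.flank5 + PROTOSPACER_LEN + PAM_LEN + self.flank3

    def position_labels(self) -> list[str]:
        labels = [f"m{self.flank5 - i}" for i in range(self.flank5)]
        labels += [f"p{i + 1:02d}" for i in range(PROTOSPACER_LEN)]
        labels += ["pamN", "pamG1", "pamG2"]
        labels += [f"f{i + 1}" for i in range(self.flank3)]
        return labels


BASES = "ACGT"


def target_context(
    genome: Mapping[str, str], c: SgrnaCandidate, config: SequenceFeatureConfig
) -> str:
    """Oriented sequence flank5 + protospacer + PAM + flank3 (5'->3')."""
    seq = genome[c.chrom].upper()
    site = c.site_interval
    if c.strand == "+":
        start = site.start - config.flank5
        end = site.end + config.flank3
        ctx = seq[max(0, start):end]
        if start < 0:
            ctx = "N" * (-start) + ctx
    else:
        start = site.start - config.flank3
        end = site.end + config.flank5
        ctx = seq[max(0, start):end]
        if start < 0:
            ctx = "N" * (-start) + ctx
        ctx = revcomp(ctx)
    if len(ctx) < config.context_len:
        ctx = ctx + "N" * (config.context_len - len(ctx))
    return ctx


def sequence_feature_names(config: SequenceFeatureConfig) -> list[str]:
    labels = config.position_labels()
    names: list[str] = []
    for i, lab in enumerate(labels):
        if lab in ("pamG1", "pamG2"):
            continue  # fixed by the PAM; uninformative
        names += [f"base_{lab}_{b}" for b in BASES]
    for i in range(len(labels) - 1):
        names += [f"dinuc_{labels[i]}_{labels[i + 1]}_{x}{y}" for x in BASES for y in BASES]
    names += [f"count_{b}" for b in BASES]
    names += ["gc_fraction"]
    names += [f"homopolymer_{b}" for b in BASES]
    names += ["protospacer_length"]
    return names


def longest_run(seq: str, base: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def sequence_features(
    c: SgrnaCandidate,
    context: str,
    config: SequenceFeatureConfig = SequenceFeatureConfig(),
) -> dict[str, float]:
    """Sequence descriptors over the oriented target context.

    Positions containing N yield NaN for the affected features rather than
    being silently zeroed.
    """
    if len(context) != config.context_len:
        raise ValueError(
            f"context must be {config.context_len} nt, got {len(context)}"
        )
    labels = config.position_labels()
    feats: dict[str, float] = {}
    for i, lab in enumerate(labels):
        if lab in ("pamG1", "pamG2"):
            continue
        ch = context[i]
        for b in BASES:
            feats[f"base_{lab}_{b}"] = math.nan if ch == "N" else float(ch == b)
    for i in range(len(labels) - 1):
        pair = context[i:i + 2]
        missing = "N" in pair
        for x in BASES:
            for y in BASES:
                key = f"dinuc_{labels[i]}_{labels[i + 1]}_{x}{y}"
                feats[key] = math.nan if missing else float(pair == x + y)
    proto = c.protospacer_genomic
    for b in BASES:
        feats[f"count_{b}"] = float(proto.count(b))
    feats["gc_fraction"] = (proto.count("G") + proto.count("C")) / len(proto)
    for b in BASES:
        feats[f"homopolymer_{b}"] = float(longest_run(proto, b))
    feats["protospacer_length"] = float(len(proto))
    return feats


def rna_features(
    expression_seq: str, constant_region: str = DEFAULT_CONSTANT_REGION
) -> dict[str, float]:
    """Folding metrics for the guide alone and guide + constant region."""
    if not expression_seq:
        raise ValueError("empty expression sequence")
    mfe_g, paired_g = rnafold.fold(expression_seq)
    mfe_c, paired_c = rnafold.fold(expression_seq + constant_region)
    return {
        "mfe_guide": mfe_g,
        "paired_guide": float(paired_g),
        "mfe_with_constant": mfe_c,
        "paired_with_constant": float(paired_c),
    }


def chromatin_features(
    c: SgrnaCandidate, tracks: Sequence[GenomicTrack]
) -> dict[str, float]:
    """Per-track mean signal over the 22-bp target site (PAM included)."""
    site = c.site_interval
    return {
        f"chromatin_{t.name}": t.mean_over(c.chrom, site.start, site.end)
        for t in tracks
    }


def feature_names(
    config: SequenceFeatureConfig = SequenceFeatureConfig(),
    track_names: Sequence[str] = (),
) -> list[str]:
    names = [
        "dist_primary_up", "dist_primary_down",
        "dist_secondary_up", "dist_secondary_down",
    ]
    names += sequence_feature_names(config)
    names += ["mfe_guide", "paired_guide", "mfe_with_constant", "paired_with_constant"]
    names += [f"chromatin_{t}" for t in track_names]
    return names


def roster_hash(names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


def compute_feature_matrix(
    candidates: Sequence[SgrnaCandidate],
    genome: Mapping[str, str],
    tss_by_gene: Mapping[str, TssAnnotation],
    tracks: Sequence[GenomicTrack] = (),
    config: SequenceFeatureConfig = SequenceFeatureConfig(),
    constant_region: str = DEFAULT_CONSTANT_REGION,
) -> pd.DataFrame:
    """Full feature matrix (one row per candidate, fixed column roster)."""
    rows = []
    for c in candidates:
        tss = tss_by_gene[c.gene]
        feats = position_features(c, tss)
        feats.update(sequence_features(c, target_context(genome, c, config), config))
        feats.update(rna_features(c.expression_seq, constant_region))
        feats.update(chromatin_features(c, tracks))
        rows.append(feats)
    columns = feature_names(config, [t.name for t in tracks])
    df = pd.DataFrame(rows, index=[c.id for c in candidates])
    return df.reindex(columns=columns)
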