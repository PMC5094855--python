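"""Hybrid TSS annotation from CAGE peaks and transcript models.

A gene's TSS is refined from its transcript-model coordinates using CAGE
peaks via a strict matching hierarchy:

1. same-strand peaks labeled ``p1@GENE``/``p2@GENE`` within 30 kb of any
   transcript TSS for the gene (``cage_matched_peaks``);
2. else any same-strand peak labeled ``p1``/``p2`` within 500 bp
   (``cage_primary_peaks``);
3. else a robust, then permissive, peak within 200 bp
   (``cage_robust_peak`` / ``cage_permissive_peak``);
4. else the transcript-model coordinate itself (``annotation``).

Primary and secondary peaks within 1 kb of each other are merged into a
single spanning "P1P2" range; a secondary TSS is only retained when the p2
peak passes the robust threshold.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO

from .intervals import Interval


class PeakTier(str, enum.Enum):
    ROBUST = "robust"
    PERMISSIVE = "permissive"


class Support(str, enum.Enum):
    CAGE_MATCHED_PEAKS = "cage_matched_peaks"
    CAGE_PRIMARY_PEAKS = "cage_primary_peaks"
    CAGE_ROBUST_PEAK = "cage_robust_peak"
    CAGE_PERMISSIVE_PEAK = "cage_permissive_peak"
    ANNOTATION = "annotation"


_LABEL_RE = re.compile(r"^(p\d+)@(.+)$", re.IGNORECASE)


@dataclass(frozen=True)
class CagePeak:
    chrom: str
    start: int
    end: int
    strand: str
    label: str
    tier: PeakTier = PeakTier.ROBUST
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak has empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)

    @property
    def rank_label(self) -> Optional[str]:
        """'p1', 'p2', ... if the name carries a rank prefix, else None."""
        m = _LABEL_RE.match(self.label)
        if m:
            return m.group(1).lower()
        if re.fullmatch(r"p\d+", self.label, re.IGNORECASE):
            return self.label.lower()
        return None

    @property
    def gene_label(self) -> Optional[str]:
        m = _LABEL_RE.match(self.label)
        return m.group(2) if m else None


@dataclass(frozen=True)
class TranscriptTss:
    gene: str
    transcript_id: str
    chrom: str
    strand: str
    tss_coord: int

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TssAnnotation:
    gene: str
    chrom: str
    strand: str
    primary_range: Interval
    secondary_range: Optional[Interval]
    support: Support
    merged_p1p2: bool = False

    def __post_init__(self) -> None:
        if self.merged_p1p2 and self.secondary_range is not None:
            raise ValueError("merged P1P2 annotation cannot carry a secondary range")

    @property
    def ranges(self) -> list[tuple[str, Interval]]:
        out = [("P1P2" if self.merged_p1p2 else "P1", self.primary_range)]
        if self.secondary_range is not None:
            out.append(("P2", self.secondary_range))
        return out


class AnnotationError(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class MatchDistances:
    """Search radii of the hierarchy, in bp."""

    matched_peak: int = 30_000
    primary_peak: int = 500
    nearby_peak: int = 200
    merge_gap: int = 1_000


def parse_cage_bed(lines: Iterable[str], tier: PeakTier | None = None) -> list[CagePeak]:
    """Parse BED6 lines into :class:`CagePeak` records.

    The name field carries the peak label (e.g. ``p1@GENEA``). When ``tier``
    is None, a trailing tab-separated token equal to ``robust``/``permissive``
    is honored if present (column 7); otherwise peaks default to robust.
    """
    peaks: list[CagePeak] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedParseError(f"line {lineno}: expected >= 6 BED fields, got {len(fields)}")
        chrom, start_s, end_s, label, score_s, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric coordinates") from exc
        try:
            score = float(score_s) if score_s not in (".", "") else 0.0
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric score") from exc
        if strand not in ("+", "-"):
            raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
        peak_tier = tier
        if peak_tier is None:
            if len(fields) >= 7 and fields[6].lower() in ("robust", "permissive"):
                peak_tier = PeakTier(fields[6].lower())
            else:
                peak_tier = PeakTier.ROBUST
        try:
            peaks.append(CagePeak(chrom, start, end, strand, label, peak_tier, score))
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
    return peaks


def _peak_distance(peak: CagePeak, tss_coords: list[int]) -> int:
    return min(peak.interval.distance_to_point(t) for t in tss_coords)


def _closest_peak(peaks: list[CagePeak], tss_coords: list[int]) -> CagePeak:
    # tie on distance broken by genomic coordinate (lower start first)
    return min(peaks, key=lambda p: (_peak_distance(p, tss_coords), p.start, p.end))


def assign_tss(
    gene: str,
    transcript_tsses: list[TranscriptTss],
    peaks: list[CagePeak],
    params: MatchDistances | None = None,
) -> TssAnnotation:
    """Resolve a gene's TSS annotation via the CAGE matching hierarchy."""
    params = params or MatchDistances()
    records = [t for t in transcript_tsses if t.gene == gene]
    if not records:
        raise AnnotationError(f"gene {gene!r} has no transcript TSS records")
    strands = {t.strand for t in records}
    if len(strands) > 1:
        raise AnnotationError(f"gene {gene!r} has transcripts on both strands")
    strand = strands.pop()
    chroms = {t.chrom for t in records}
    if len(chroms) > 1:
        raise AnnotationError(f"gene {gene!r} has transcripts on multiple contigs")
    chrom = chroms.pop()
    tss_coords = [t.tss_coord for t in records]

    local = [p for p in peaks if p.chrom == chrom and p.strand == strand]

    # Rule 1: peaks explicitly labeled for this gene within the wide radius.
    def _matched(rank: str) -> list[CagePeak]:
        return [
            p
            for p in local
            if p.rank_label == rank
            and (p.gene_label or "").lower() == gene.lower()
            and _peak_distance(p, tss_coords) <= params.matched_peak
        ]

    p1_matched = _matched("p1")
    p2_matched = [p for p in _matched("p2") if p.tier is PeakTier.ROBUST]
    if p1_matched or p2_matched:
        primary_pool = p1_matched or p2_matched
        primary = _closest_peak(primary_pool, tss_coords)
        secondary = None
        if p1_matched and p2_matched:
            secondary = _closest_peak(p2_matched, tss_coords)
        return _finalize(gene, chrom, strand, primary, secondary,
                         Support.CAGE_MATCHED_PEAKS, params)

    # Rule 2: any p1/p2-labeled peak within the short radius.
    ranked = [
        p
        for p in local
        if p.rank_label in ("p1", "p2")
        and _peak_distance(p, tss_coords) <= params.primary_peak
    ]
    if ranked:
        p1s = [p for p in ranked if p.rank_label == "p1"]
        p2s = [p for p in ranked if p.rank_label == "p2" and p.tier is PeakTier.ROBUST]
        primary_pool = p1s or ranked
        primary = _closest_peak(primary_pool, tss_coords)
        secondary = None
        if p1s and p2s:
            secondary = _closest_peak(p2s, tss_coords)
        if secondary is not None and secondary == primary:
            secondary = None
        return _finalize(gene, chrom, strand, primary, secondary,
                         Support.CAGE_PRIMARY_PEAKS, params)

    # Rule 3: any robust, then permissive, peak very close by.
    nearby = [p for p in local if _peak_distance(p, tss_coords) <= params.nearby_peak]
    robust = [p for p in nearby if p.tier is PeakTier.ROBUST]
    permissive = [p for p in nearby if p.tier is PeakTier.PERMISSIVE]
    if robust:
        primary = _closest_peak(robust, tss_coords)
        return _finalize(gene, chrom, strand, primary, None,
                         Support.CAGE_ROBUST_PEAK, params)
    if permissive:
        primary = _closest_peak(permissive, tss_coords)
        return _finalize(gene, chrom, strand, primary, None,
                         Support.CAGE_PERMISSIVE_PEAK, params)

    # Rule 4: fall back to the transcript model (5'-most TSS).
    anchor = min(tss_coords) if strand == "+" else max(tss_coords)
    return TssAnnotation(
        gene=gene,
        chrom=chrom,
        strand=strand,
        primary_range=Interval(anchor, anchor + 1),
        secondary_range=None,
        support=Support.ANNOTATION,
    )


def _finalize(
    gene: str,
    chrom: str,
    strand: str,
    primary: CagePeak,
    secondary: Optional[CagePeak],
    support: Support,
    params: MatchDistances,
) -> TssAnnotation:
    if secondary is None:
        return TssAnnotation(gene, chrom, strand, primary.interval, None, support)
    gap = primary.interval.gap_to(secondary.interval)
    if gap <= params.merge_gap:
        return TssAnnotation(
            gene, chrom, strand, primary.interval.span(secondary.interval),
            None, support, merged_p1p2=True,
        )
    return TssAnnotation(gene, chrom, strand, primary.interval,
                         secondary.interval, support)


ANNOTATION_COLUMNS = [
    "gene", "chrom", "strand", "primary_start", "primary_end",
    "secondary_start", "secondary_end", "support", "merged",
]


def write_annotations(annotations: Iterable[TssAnnotation], handle: TextIO) -> None:
    handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
    for ann in annotations:
        sec_start = str(ann.secondary_range.start) if ann.secondary_range else ""
        sec_end = str(ann.secondary_range.end) if ann.secondary_range else ""
        handle.write(
            "\t".join(
                [
                    ann.gene, ann.chrom, ann.strand,
                    str(ann.primary_range.start), str(ann.primary_range.end),
                    sec_start, sec_end, ann.support.value,
                    "1" if ann.merged_p1p2 else "0",
                ]
            )
            + "\n"
        )


def read_annotations(handle: TextIO) -> list[TssAnnotation]:
    header = handle.readline().rstrip("\n").split("\t")
    if header != ANNOTATION_COLUMNS:
        raise AnnotationError(f"unexpected annotation header: {header}")
    out = []
    for line in handle:
        f = line.rstrip("\n").split("\t")
        secondary = Interval(int(f[5]), int(f[6])) if f[5] else None
        out.append(
            TssAnnotation(
                gene=f[0], chrom=f[1], strand=f[2],
                primary_range=Interval(int(f[3]), int(f[4])),
                secondary_range=secondary,
                support=Support(f[7]),
                merged_p1p2=f[8] == "1",
            )
        )
    return out


def read_transcript_table(handle: TextIO) -> list[TranscriptTss]:
    """Read a transcript TSV: gene, transcript_id, chrom, strand, tss."""
    header = handle.readline().rstrip("\n").split("\t")
    expected = ["gene", "transcript_id", "chrom", "strand", "tss"]
    if header != expected:
        raise AnnotationError(f"unexpected transcript header: {header}")
    return [
        TranscriptTss(f[0], f[1], f[2], f[3], int(f[4]))
        for f in (line.rstrip("\n").split("\t") for line in handle if line.strip())
    ]


def write_transcript_table(records: Iterable[TranscriptTss], handle: TextIO) -> None:
    handle.write("gene\ttranscript_id\tchrom\tstrand\ttss\n")
    for t in records:
        handle.write(f"{t.gene}\t{t.transcript_id}\t{t.chrom}\t{t.strand}\t{t.tss_coord}\n")
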