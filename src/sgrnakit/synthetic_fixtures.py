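"""Seeded toy-scale generators with planted ground truth.

Everything the real pipeline consumes — genome FASTA, transcript tables,
CAGE peak BED, chromatin bedGraph, activity tables, screen counts — can be
produced here at desk scale, with the generating parameters (the "planted
truth") serialized alongside so tests can verify recovery. Same seed, same
bytes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import CagePeak, PeakTier, TranscriptTss, write_transcript_table
from .guide_features import SgrnaCandidate, signed_distance, _range_edges
from .annotations import TssAnnotation
from .screen_scoring import CountTable, make_count_table
from .tracks import GenomicTrack
from .training_data import ActivityRecord, compute_activity_scores

BASES = np.array(list("ACGT"))


@dataclass
class PlantedTruth:
    """Generating parameters for synthetic activity and screen data."""

    position_amplitude: float = 0.6
    position_period: float = 190.0
    position_decay: float = 1000.0
    position_offset: float = 0.5
    seq_gc_coef: float = -0.3
    seq_homopolymer_coef: float = -0.05
    noise_sd: float = 0.1
    gene_effects: dict[str, float] = field(default_factory=dict)
    count_dispersion: float = 0.01

    def position_term(self, distance: float) -> float:
        """Decaying nucleosome-phased periodic activity vs TSS distance."""
        return math.exp(-abs(distance) / self.position_decay) * (
            self.position_offset
            + self.position_amplitude
            * math.sin(2 * math.pi * distance / self.position_period)
        )

    def sequence_term(self, protospacer: str) -> float:
        from .guide_features import longest_run

        gc = (protospacer.count("G") + protospacer.count("C")) / len(protospacer)
        longest = max(longest_run(protospacer, b) for b in "ACGT")
        return self.seq_gc_coef * (gc - 0.5) + self.seq_homopolymer_coef * longest

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))


@dataclass
class ToyReference:
    genome: dict[str, str]
    transcripts: list[TranscriptTss]
    peaks: list[CagePeak]
    tracks: list[GenomicTrack]
    tss_positions: dict[str, int]  # gene -> planted TSS coordinate
    strands: dict[str, str]
    chroms: dict[str, str]


# the CAGE-placement scenarios cycled over genes; each maps to the support
# rule it should trigger in the annotation hierarchy
_SCENARIOS = (
    "matched_separate",   # p1@gene + distant robust p2@gene
    "matched_merged",     # p1@gene + nearby robust p2@gene -> P1P2
    "matched_p1_only",
    "primary_unmatched",  # p1-labeled peak for an unknown gene within 500 bp
    "robust_unlabeled",
    "permissive_unlabeled",
    "annotation_only",
)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def make_toy_reference(
    seed: int = 0,
    n_genes: int = 20,
    contig_len: int = 200_000,
    gene_spacing: int = 9_000,
    n_contigs: int = 2,
) -> ToyReference:
    """Random toy genome with genes on both strands and CAGE peaks placed to
    exercise every support rule of the annotation hierarchy."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    per_contig = math.ceil(n_genes / n_contigs)
    if (per_contig + 1) * gene_spacing > contig_len:
        raise ValueError("contig too short for requested genes")

    genome = {f"chr{c + 1}": _random_seq(rng, contig_len) for c in range(n_contigs)}
    transcripts: list[TranscriptTss] = []
    peaks: list[CagePeak] = []
    tss_positions: dict[str, int] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}

    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        chrom = f"chr{g % n_contigs + 1}"
        slot = g // n_contigs
        tss = (slot + 1) * gene_spacing + int(rng.integers(-200, 201))
        strand = "+" if g % 2 == 0 else "-"
        scenario = _SCENARIOS[g % len(_SCENARIOS)]
        tss_positions[gene] = tss
        strands[gene] = strand
        chroms[gene] = chrom

        transcripts.append(TranscriptTss(gene, f"{gene}.t1", chrom, strand, tss))
        if rng.random() < 0.5:
            alt = tss + int(rng.integers(50, 400)) * (1 if strand == "+" else -1)
            transcripts.append(TranscriptTss(gene, f"{gene}.t2", chrom, strand, alt))

        def peak(center: int, width: int, label: str, tier: PeakTier) -> CagePeak:
            start = max(0, center - width // 2)
            return CagePeak(chrom, start, start + width, strand, label, tier,
                            float(rng.integers(5, 100)))

        jitter = int(rng.integers(-40, 41))
        if scenario == "matched_separate":
            peaks.append(peak(tss + jitter, 30, f"p1@{gene}", PeakTier.ROBUST))
            peaks.append(peak(tss + 1600, 25, f"p2@{gene}", PeakTier.ROBUST))
        elif scenario == "matched_merged":
            peaks.append(peak(tss + jitter, 30, f"p1@{gene}", PeakTier.ROBUST))
            peaks.append(peak(tss + 700, 25, f"p2@{gene}", PeakTier.ROBUST))
        elif scenario == "matched_p1_only":
            peaks.append(peak(tss + jitter, 30, f"p1@{gene}", PeakTier.ROBUST))
        elif scenario == "primary_unmatched":
            peaks.append(peak(tss + int(rng.integers(-300, 301)), 30,
                              f"p1@NOVEL{g}", PeakTier.ROBUST))
        elif scenario == "robust_unlabeled":
            peaks.append(peak(tss + int(rng.integers(-150, 151)), 30,
                              f"peak{g}", PeakTier.ROBUST))
        elif scenario == "permissive_unlabeled":
            peaks.append(peak(tss + int(rng.integers(-150, 151)), 30,
                              f"peak{g}", PeakTier.PERMISSIVE))
        # annotation_only: no peak

    tracks = [
        _nucleosome_track("mnase", genome, tss_positions, strands, chroms, phase=0.0),
        _nucleosome_track("dnase", genome, tss_positions, strands, chroms, phase=math.pi),
        GenomicTrack.constant("faire", 1.0, {c: len(s) for c, s in genome.items()}),
    ]
    return ToyReference(genome, transcripts, peaks, tracks, tss_positions, strands, chroms)


def _nucleosome_track(
    name: str,
    genome: Mapping[str, str],
    tss_positions: Mapping[str, int],
    strands: Mapping[str, str],
    chroms: Mapping[str, str],
    phase: float = 0.0,
    period: float = 190.0,
    extent: int = 1000,
) -> GenomicTrack:
    """Phased sinusoid downstream of each TSS over a flat 0.5 baseline."""
    values = {c: np.full(len(s), 0.5) for c, s in genome.items()}
    for gene, pos in tss_positions.items():
        arr = values[chroms[gene]]
        strand = strands[gene]
        for d in range(extent):
            coord = pos + d if strand == "+" else pos - d
            if 0 <= coord < len(arr):
                arr[coord] = 1.0 + math.sin(2 * math.pi * d / period + phase)
    return GenomicTrack(name, values)


# ---------------------------------------------------------------------------
# file emission


def write_fasta(genome: Mapping[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_cage_bed(peaks: Sequence[CagePeak], path: Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.label}\t{p.score:g}\t"
                f"{p.strand}\t{p.tier.value}\n"
            )


def write_toy_reference(ref: ToyReference, outdir: Path) -> dict[str, Path]:
    """Emit the toy reference in the pipeline's input formats."""
    from .tracks import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.tsv",
        "cage": outdir / "cage_peaks.bed",
    }
    write_fasta(ref.genome, paths["genome"])
    with open(paths["transcripts"], "w") as fh:
        write_transcript_table(ref.transcripts, fh)
    write_cage_bed(ref.peaks, paths["cage"])
    for track in ref.tracks:
        p = outdir / f"{track.name}.bedgraph"
        with open(p, "w") as fh:
            write_bedgraph(track, fh)
        paths[track.name] = p
    return paths


# ---------------------------------------------------------------------------
# planted datasets


def simulate_activity_dataset(
    candidates: Sequence[SgrnaCandidate],
    tss_by_gene: Mapping[str, TssAnnotation],
    truth: PlantedTruth,
    seed: int = 0,
) -> list[ActivityRecord]:
    """Activity = planted positional term + sequence term + Gaussian noise,
    normalized per gene to a top-3 |value| mean of 1."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in candidates:
        tss = tss_by_gene[c.gene]
        up_edge, _ = _range_edges(tss.strand, tss.primary_range)
        d = signed_distance(tss.strand, up_edge, c.pam_3g_coord)
        value = (
            truth.position_term(d)
            + truth.sequence_term(c.protospacer_genomic)
            + rng.normal(0.0, truth.noise_sd)
        )
        rows.append(
            {"sgrna_id": c.id, "gene": c.gene, "tss_id": c.tss_id, "phenotype": value}
        )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_activity_scores(df)


def simulate_screen_counts(
    sgrna_genes: Mapping[str, Optional[str]],
    truth: PlantedTruth,
    depth: float = 500.0,
    doublings: float = 10.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> CountTable:
    """Negative-binomial screen counts with planted per-gene growth effects.

    ``sgrna_genes`` maps sgrna_id -> gene (None for non-targeting controls,
    which get a true effect of 0). Endpoint expectation is the T0 abundance
    scaled by 2^(gamma_true * doublings); dispersion 0 gives deterministic
    rounded expectations.
    """
    rng = np.random.default_rng(seed)
    ids = list(sgrna_genes)
    gammas = np.array(
        [truth.gene_effects.get(sgrna_genes[i] or "", 0.0) for i in ids]
    )

    def draw(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        if truth.count_dispersion == 0:
            return np.round(mean).astype(int)
        r = 1.0 / truth.count_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    t0_tables, end_tables = {}, {}
    doubling_map = {}
    for rep_idx in range(n_replicates):
        rep = f"rep{rep_idx + 1}"
        t0_mean = np.full(len(ids), depth)
        t0 = draw(t0_mean)
        growth = 2.0 ** (gammas * doublings)
        end_mean = t0 * growth
        # renormalize endpoint to the same total depth (pool sequencing)
        end_mean = end_mean * (t0_mean.sum() / end_mean.sum())
        end = draw(end_mean)
        t0_tables[rep] = dict(zip(ids, (int(x) for x in t0)))
        end_tables[rep] = dict(zip(ids, (int(x) for x in end)))
        doubling_map[rep] = doublings
    table = make_count_table(t0_tables, end_tables, doubling_map)
    low = (table.counts.to_numpy() < 50).mean()
    if low > 0.5:
        warnings.warn("depth too low: most sgRNAs fall under the count filter",
                      stacklevel=2)
    return table
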