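"""Final library assembly: sgRNA selection, negative controls, oligos.

Selection per TSS is empirical-first (up to 2 validated guides with activity
score >= 0.75 under the strictest filters), then by descending predicted
score with remaining qualified empirical guides given a +0.2 bonus, with
off-target stringency iteratively relaxed T0 -> T4 until 10 guides are
found; a TSS that cannot reach 10 even at T4 is left untargeted. Selected
guides must be tier-passing, free of cloning/sequencing restriction sites in
the assembled oligo, and shifted >= 3 bp from previously selected same-strand
target sites.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import numpy as np

from .guide_features import PROTOSPACER_LEN, SgrnaCandidate, revcomp
from .intervals import Interval
from .offtarget import (
    GENOME_SCORE_CAP,
    PROXIMAL_SCORE_CAP,
    DEFAULT_WEIGHTS,
    OfftargetIndex,
    StringencyTier,
    _in_proximal,
)

BSTXI_ARM = "CCACCTTGTTG"
BLPI_ARM = "GTTTAAGAGCTAAGCTG"
ADAPTER_LEN = 18
OLIGO_LEN = 84

# test/fixture PCR adapters (18 nt each, site-free)
FIXTURE_ADAPTER5 = "ATCTTGTGGAAAGGACGA"
FIXTURE_ADAPTER3 = "CATATGCTTACCGTAACT"

RESTRICTION_SITES = {
    "BstXI": "CCANNNNNNTGG",
    "BlpI": "GCTNAGC",
    "SbfI": "CCTGCAGG",
}

MAX_PER_TSS = 10
EMPIRICAL_MIN_SCORE = 0.75
EMPIRICAL_MAX_TSS_DISTANCE = 5_000
EMPIRICAL_BONUS = 0.2
MIN_SHIFT_BP = 3


class Half(str, enum.Enum):
    TOP5 = "top5"
    SECOND5 = "second5"


class Source(str, enum.Enum):
    EMPIRICAL = "empirical"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class LibraryEntry:
    sgrna_id: str
    gene: str
    tss_id: str
    chrom: str
    strand: str
    pam_3g_coord: int
    protospacer: str
    expression_seq: str
    source: Source
    selection_rank: int
    score: float
    tier: StringencyTier
    half: Half = Half.TOP5
    sublibrary: str = ""

    def __post_init__(self) -> None:
        if self.tier is StringencyTier.FAIL:
            raise ValueError("library entries must pass an off-target tier")
        expected_half = Half.TOP5 if self.selection_rank <= 5 else Half.SECOND5
        if self.half is not expected_half:
            raise ValueError("half must follow selection rank")


@dataclass(frozen=True)
class OligoRecord:
    adapter5: str
    bstxi_arm: str
    insert: str
    blpi_arm: str
    adapter3: str

    @property
    def sequence(self) -> str:
        return self.adapter5 + self.bstxi_arm + self.insert + self.blpi_arm + self.adapter3

    def __post_init__(self) -> None:
        if len(self.sequence) != OLIGO_LEN:
            raise ValueError(f"oligo must be {OLIGO_LEN} bp, got {len(self.sequence)}")


def format_oligo(
    expression_seq: str,
    adapter5: str = FIXTURE_ADAPTER5,
    adapter3: str = FIXTURE_ADAPTER3,
) -> OligoRecord:
    """Assemble adapter5 + BstXI arm + expression_seq + BlpI arm + adapter3."""
    if len(adapter5) != ADAPTER_LEN or len(adapter3) != ADAPTER_LEN:
        raise ValueError(f"adapters must be {ADAPTER_LEN} nt")
    if len(expression_seq) != 20:
        raise ValueError("insert must be the 20-nt expression sequence")
    return OligoRecord(adapter5, BSTXI_ARM, expression_seq, BLPI_ARM, adapter3)


def _site_regex(iupac: str) -> re.Pattern:
    return re.compile(iupac.replace("N", "[ACGT]"))


_SITE_PATTERNS = {name: _site_regex(p) for name, p in RESTRICTION_SITES.items()}


def _find_site_spans(seq: str) -> set[tuple[int, int]]:
    """Spans of restriction-site matches on either strand of ``seq``."""
    spans: set[tuple[int, int]] = set()
    rc = revcomp(seq)
    n = len(seq)
    for pat in _SITE_PATTERNS.values():
        for strand_seq, flip in ((seq, False), (rc, True)):
            pos = 0
            while True:  # overlapping matches included
                m = pat.search(strand_seq, pos)
                if m is None:
                    break
                start, end = m.start(), m.end()
                if flip:
                    start, end = n - end, n - start
                spans.add((start, end))
                pos = m.start() + 1
    return spans


def intended_site_spans(adapter5_len: int = ADAPTER_LEN) -> set[tuple[int, int]]:
    """Spans where the cloning arms intentionally form their sites.

    The BstXI site forms across the arm + the leading G of the insert; the
    BlpI site sits inside the BlpI arm.
    """
    bstxi_start = adapter5_len
    blpi_start = adapter5_len + len(BSTXI_ARM) + 20 + BLPI_ARM.index("GCTAAGC")
    return {
        (bstxi_start, bstxi_start + len(RESTRICTION_SITES["BstXI"])),
        (blpi_start, blpi_start + len(RESTRICTION_SITES["BlpI"])),
    }


def has_forbidden_site(oligo: OligoRecord) -> bool:
    """True iff a BstXI/BlpI/SbfI match exists outside the intended arms."""
    spans = _find_site_spans(oligo.sequence)
    return bool(spans - intended_site_spans(len(oligo.adapter5)))


@dataclass
class SelectionCandidate:
    """A scored, tiered candidate offered to the per-TSS selection loop."""

    candidate: SgrnaCandidate
    predicted_score: float
    tier: StringencyTier
    empirical_score: Optional[float] = None
    tss_distance: Optional[float] = None  # bp from the revised TSS


@dataclass
class SelectionResult:
    entries: list[LibraryEntry]
    targeted: bool
    reason: str = ""


def _shifted_ok(
    cand: SgrnaCandidate, selected: Sequence[LibraryEntry], min_shift: int = MIN_SHIFT_BP
) -> bool:
    """Target site must be >= min_shift bp from any selected same-strand site."""
    for e in selected:
        if e.strand == cand.strand and abs(e.pam_3g_coord - cand.pam_3g_coord) < min_shift:
            return False
    return True


def _clean_oligo(cand: SgrnaCandidate, adapter5: str, adapter3: str) -> bool:
    return not has_forbidden_site(format_oligo(cand.expression_seq, adapter5, adapter3))


def select_sgrnas(
    pool: Sequence[SelectionCandidate],
    tss_id: str,
    max_sgrnas: int = MAX_PER_TSS,
    require_full: bool = True,
    adapter5: str = FIXTURE_ADAPTER5,
    adapter3: str = FIXTURE_ADAPTER3,
) -> SelectionResult:
    """Run the per-TSS selection loop over a candidate pool.

    Ties on score break by lower genomic coordinate, then + strand.
    ``require_full=False`` keeps a partially filled TSS instead of declaring
    it untargeted.
    """
    pool = [sc for sc in pool if sc.candidate.tss_id == tss_id]
    selected: list[LibraryEntry] = []

    def order_key(sc: SelectionCandidate, score: float):
        return (-score, sc.candidate.pam_3g_coord, sc.candidate.strand)

    def passes_common(sc: SelectionCandidate, max_tier: StringencyTier) -> bool:
        return (
            sc.tier is not StringencyTier.FAIL
            and sc.tier <= max_tier
            and _clean_oligo(sc.candidate, adapter5, adapter3)
            and _shifted_ok(sc.candidate, selected)
        )

    def add(sc: SelectionCandidate, source: Source, score: float) -> None:
        rank = len(selected) + 1
        selected.append(
            LibraryEntry(
                sgrna_id=sc.candidate.id,
                gene=sc.candidate.gene,
                tss_id=tss_id,
                chrom=sc.candidate.chrom,
                strand=sc.candidate.strand,
                pam_3g_coord=sc.candidate.pam_3g_coord,
                protospacer=sc.candidate.protospacer_genomic,
                expression_seq=sc.candidate.expression_seq,
                source=source,
                selection_rank=rank,
                score=score,
                tier=sc.tier,
                half=Half.TOP5 if rank <= 5 else Half.SECOND5,
            )
        )

    # Step 1: up to 2 empirical guides under the strictest criteria.
    def empirical_qualifies(sc: SelectionCandidate) -> bool:
        return (
            sc.empirical_score is not None
            and sc.empirical_score >= EMPIRICAL_MIN_SCORE
            and sc.tss_distance is not None
            and abs(sc.tss_distance) < EMPIRICAL_MAX_TSS_DISTANCE
            and sc.tier is StringencyTier.T0
        )

    empirical_pool = sorted(
        (sc for sc in pool if empirical_qualifies(sc)),
        key=lambda sc: order_key(sc, sc.empirical_score),
    )
    taken: set[str] = set()
    for sc in empirical_pool:
        if len([e for e in selected if e.source is Source.EMPIRICAL]) >= 2:
            break
        if passes_common(sc, StringencyTier.T0):
            add(sc, Source.EMPIRICAL, sc.empirical_score)
            taken.add(sc.candidate.id)

    # Step 2/3: predicted-score ranking; leftover qualifying empirical guides
    # keep competing with a +0.2 score bonus.
    def adjusted_score(sc: SelectionCandidate) -> float:
        bonus = EMPIRICAL_BONUS if empirical_qualifies(sc) else 0.0
        return sc.predicted_score + bonus

    remaining = [sc for sc in pool if sc.candidate.id not in taken]
    remaining.sort(key=lambda sc: order_key(sc, adjusted_score(sc)))

    # Step 4: iteratively relax the stringency tier until full.
    for max_tier in (
        StringencyTier.T0,
        StringencyTier.T1,
        StringencyTier.T2,
        StringencyTier.T3,
        StringencyTier.T4,
    ):
        for sc in remaining:
            if len(selected) >= max_sgrnas:
                break
            if sc.candidate.id in taken:
                continue
            if passes_common(sc, max_tier):
                add(sc, Source.PREDICTED, adjusted_score(sc))
                taken.add(sc.candidate.id)
        if len(selected) >= max_sgrnas:
            break

    if len(selected) < max_sgrnas and require_full:
        return SelectionResult(
            entries=[], targeted=False,
            reason=f"only {len(selected)} of {max_sgrnas} sgRNAs at most relaxed tier",
        )
    return SelectionResult(entries=selected, targeted=True)


# ---------------------------------------------------------------------------
# negative controls


class NegativeControlError(RuntimeError):
    pass


def protospacer_base_frequencies(protospacers: Sequence[str]) -> np.ndarray:
    """(length x 4) per-position frequencies over A, C, G, T."""
    if not protospacers:
        raise ValueError("empty library")
    length = len(protospacers[0])
    counts = np.zeros((length, 4))
    index = {b: i for i, b in enumerate("ACGT")}
    for p in protospacers:
        for i, ch in enumerate(p.upper()):
            counts[i, index[ch]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def generate_negative_controls(
    library: Sequence[LibraryEntry],
    n: int,
    genome: Mapping[str, str],
    proximal: Mapping[str, Sequence[Interval]],
    seed: int = 0,
    weights: Sequence[int] = DEFAULT_WEIGHTS,
    max_attempts_factor: int = 1000,
    index: Optional["OfftargetIndex"] = None,
) -> list[str]:
    """Sample composition-matched non-targeting protospacers.

    Per-position base frequencies are estimated from the library; random
    sequences sampled independently at each position are kept only if they
    have zero alignments scoring < 31 TSS-proximally and zero scoring < 21
    genome-wide.
    """
    if index is None:
        index = OfftargetIndex(genome)
    freqs = protospacer_base_frequencies([e.protospacer for e in library])
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    attempts = 0
    max_attempts = max(n * max_attempts_factor, 1000)
    while len(accepted) < n:
        if attempts >= max_attempts:
            raise NegativeControlError(
                f"rejection rate too high: {len(accepted)}/{n} accepted "
                f"after {attempts} attempts"
            )
        attempts += 1
        seq = "".join(
            bases[rng.choice(4, p=freqs[i])] for i in range(freqs.shape[0])
        )
        sites = index.enumerate(seq, weights=weights)
        n_prox = sum(
            1 for s in sites if s.score < PROXIMAL_SCORE_CAP and _in_proximal(s, proximal)
        )
        n_gen = sum(1 for s in sites if s.score < GENOME_SCORE_CAP)
        if n_prox == 0 and n_gen == 0:
            accepted.append(seq)
    return accepted


# ---------------------------------------------------------------------------
# sublibraries and output


def partition_sublibraries(
    entries: Sequence[LibraryEntry], gene_to_group: Mapping[str, str]
) -> list[LibraryEntry]:
    """Label entries with (sublibrary group, top5/second5 half)."""
    out = []
    missing: set[str] = set()
    for e in entries:
        group = gene_to_group.get(e.gene)
        if group is None:
            group = "unassigned"
            missing.add(e.gene)
        out.append(replace(e, sublibrary=group))
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) missing from sublibrary map: "
            + ", ".join(sorted(missing)[:5]),
            stacklevel=2,
        )
    return out


LIBRARY_COLUMNS = [
    "gene", "tss_id", "sgrna_id", "chrom", "strand", "pam_3g_coord",
    "protospacer", "expression_seq", "source", "score", "tier", "rank",
    "half", "sublibrary",
]


def write_library(entries: Iterable[LibraryEntry], handle: TextIO) -> None:
    handle.write("\t".join(LIBRARY_COLUMNS) + "\n")
    for e in entries:
        handle.write(
            "\t".join(
                [
                    e.gene, e.tss_id, e.sgrna_id, e.chrom, e.strand,
                    str(e.pam_3g_coord), e.protospacer, e.expression_seq,
                    e.source.value, f"{e.score:.6g}", e.tier.name,
                    str(e.selection_rank), e.half.value, e.sublibrary,
                ]
            )
            + "\n"
        )


def write_oligos(
    entries: Iterable[LibraryEntry],
    handle: TextIO,
    adapter5: str = FIXTURE_ADAPTER5,
    adapter3: str = FIXTURE_ADAPTER3,
) -> None:
    """Oligo pool as FASTA."""
    for e in entries:
        oligo = format_oligo(e.expression_seq, adapter5, adapter3)
        handle.write(f">{e.sgrna_id}\n{oligo.sequence}\n")
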