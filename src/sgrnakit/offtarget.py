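"""Off-target site enumeration and tiered stringency classification.

Candidate off-target sites are found by an exhaustive scan of both genome
strands for NGG-adjacent 19-mers and scored with a position-weighted
mismatch score (0 = perfect match; PAM-proximal mismatches cost more).
Stringency tiers gate how many sub-threshold alignments an sgRNA may have
TSS-proximally (score < 31) and genome-wide (score < 21), relaxing from T0
(the on-target alignment only) through T4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO

from .guide_features import PROTOSPACER_LEN, SgrnaCandidate, revcomp
from .intervals import Interval, merge_intervals

PROXIMAL_SCORE_CAP = 31
GENOME_SCORE_CAP = 21


def default_mismatch_weights(length: int = PROTOSPACER_LEN) -> list[int]:
    """Per-position penalties rising linearly toward the PAM.

    Position 0 is PAM-distal. Scaled so a perfect match scores 0 and three
    PAM-proximal mismatches exceed the proximal cap (31), preserving the
    "near-perfect duplicates disallowed" semantics of the 31/21 thresholds.
    A published weight vector can be substituted verbatim.
    """
    top3 = (length - 2) + (length - 1) + length
    scale = (PROXIMAL_SCORE_CAP + 4) / top3
    return [round(scale * (i + 1)) for i in range(length)]


DEFAULT_WEIGHTS = tuple(default_mismatch_weights())


def mismatch_score(
    query: str, site: str, weights: Sequence[int] = DEFAULT_WEIGHTS
) -> int:
    """Sum of per-position penalties at mismatched protospacer positions."""
    if len(query) != len(site):
        raise ValueError("query and site lengths differ")
    if len(weights) != len(query):
        raise ValueError("weights length must equal protospacer length")
    return sum(w for q, s, w in zip(query, site, weights) if q != s)


@dataclass(frozen=True)
class OfftargetSite:
    chrom: str
    pam_3g_coord: int
    strand: str
    mismatch_positions: tuple[int, ...]
    score: int

    @property
    def site_interval(self) -> Interval:
        if self.strand == "+":
            return Interval(self.pam_3g_coord - 21, self.pam_3g_coord + 1)
        return Interval(self.pam_3g_coord, self.pam_3g_coord + 22)


class StringencyTier(enum.IntEnum):
    """Off-target stringency; lower value = stricter requirement."""

    T0 = 0
    T1 = 1
    T2 = 2
    T3 = 3
    T4 = 4
    FAIL = 5


def enumerate_offtargets(
    protospacer: str,
    genome: Mapping[str, str],
    score_cap: int = PROXIMAL_SCORE_CAP,
    weights: Sequence[int] = DEFAULT_WEIGHTS,
    masked: Optional[Mapping[str, Sequence[Interval]]] = None,
) -> list[OfftargetSite]:
    """All NGG-adjacent sites on either strand scoring below ``score_cap``.

    The on-target site itself (score 0) is naturally included. ``masked``
    maps contig -> intervals excluded from the scan (e.g. mitochondrial or
    pseudoautosomal sequence).
    """
    query = protospacer.upper()
    if len(query) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 19 nt")
    sites: list[OfftargetSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        mask = list(masked.get(chrom, [])) if masked else []

        def is_masked(iv: Interval) -> bool:
            return any(iv.overlaps(m) for m in mask)

        n = len(seq)
        for i in range(0, n - 21):
            # + strand: protospacer [i, i+19) then NGG at [i+19, i+22)
            if seq[i + 20] == "G" and seq[i + 21] == "G":
                proto = seq[i:i + 19]
                if "N" not in proto:
                    score = mismatch_score(query, proto, weights)
                    if score < score_cap:
                        iv = Interval(i, i + 22)
                        if not is_masked(iv):
                            mm = tuple(
                                k for k in range(19) if proto[k] != query[k]
                            )
                            sites.append(OfftargetSite(chrom, i + 21, "+", mm, score))
            # - strand: CCN at [i, i+3) then revcomp protospacer [i+3, i+22)
            if seq[i] == "C" and seq[i + 1] == "C":
                proto = revcomp(seq[i + 3:i + 22])
                if len(proto) == 19 and "N" not in proto:
                    score = mismatch_score(query, proto, weights)
                    if score < score_cap:
                        iv = Interval(i, i + 22)
                        if not is_masked(iv):
                            mm = tuple(
                                k for k in range(19) if proto[k] != query[k]
                            )
                            sites.append(OfftargetSite(chrom, i, "-", mm, score))
    return sites


class OfftargetIndex:
    """Precomputed NGG-site index for fast repeated scoring.

    Semantically identical to :func:`enumerate_offtargets` (equivalence is
    asserted in the test suite); it simply vectorizes the Hamming comparison
    across all PAM-adjacent sites of the genome.
    """

    _CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

    def __init__(
        self,
        genome: Mapping[str, str],
        masked: Optional[Mapping[str, Sequence[Interval]]] = None,
    ):
        import numpy as np

        protos, chroms, pams, strands = [], [], [], []
        for chrom, seq in genome.items():
            seq = seq.upper()
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            mask_ivs = list(masked.get(chrom, [])) if masked else []
            is_g = arr == ord("G")
            is_c = arr == ord("C")
            n = len(arr)
            codes = np.full(n, 4, dtype=np.int8)
            for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
                codes[arr == ord(base)] = code

            def keep(iv_start: int) -> bool:
                iv = Interval(iv_start, iv_start + 22)
                return not any(iv.overlaps(m) for m in mask_ivs)

            # + strand: GG at i+20, i+21; protospacer [i, i+19)
            plus = np.flatnonzero(is_g[20:n - 1] & is_g[21:n])
            for i in plus:
                block = codes[i:i + 19]
                if 4 in block or codes[i + 19] == 4:
                    continue
                if not keep(int(i)):
                    continue
                protos.append(block)
                chroms.append(chrom)
                pams.append(int(i) + 21)
                strands.append("+")
            # - strand: CC at j, j+1; protospacer revcomp of [j+3, j+22)
            minus = np.flatnonzero(is_c[:n - 21] & is_c[1:n - 20])
            for j in minus:
                block = codes[j + 3:j + 22]
                if 4 in block or codes[j + 2] == 4:
                    continue
                if not keep(int(j)):
                    continue
                protos.append((3 - block)[::-1])  # complement then reverse
                chroms.append(chrom)
                pams.append(int(j))
                strands.append("-")
        self._protos = (
            np.vstack(protos) if protos else np.zeros((0, PROTOSPACER_LEN), np.int8)
        )
        self._chroms = chroms
        self._pams = pams
        self._strands = strands

    def enumerate(
        self,
        protospacer: str,
        score_cap: int = PROXIMAL_SCORE_CAP,
        weights: Sequence[int] = DEFAULT_WEIGHTS,
    ) -> list[OfftargetSite]:
        import numpy as np

        query = np.array([self._CODE[b] for b in protospacer.upper()], dtype=np.int8)
        if len(query) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 19 nt")
        mism = self._protos != query
        scores = mism @ np.asarray(weights, dtype=np.int64)
        hits = np.flatnonzero(scores < score_cap)
        out = []
        for k in hits:
            out.append(
                OfftargetSite(
                    chrom=self._chroms[k],
                    pam_3g_coord=self._pams[k],
                    strand=self._strands[k],
                    mismatch_positions=tuple(np.flatnonzero(mism[k]).tolist()),
                    score=int(scores[k]),
                )
            )
        return out


def build_proximal_reference(
    tss_ranges: Iterable[tuple[str, Interval]],
    transcript_five_prime: Iterable[tuple[str, int]] = (),
    half_window: int = 500,
) -> dict[str, list[Interval]]:
    """TSS-proximal intervals: 1-kb windows around TSS ranges and transcript
    5' ends, merged per contig."""
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, rng in tss_ranges:
        by_chrom.setdefault(chrom, []).append(
            Interval(max(0, rng.start - half_window), rng.end + half_window)
        )
    for chrom, pos in transcript_five_prime:
        by_chrom.setdefault(chrom, []).append(
            Interval(max(0, pos - half_window), pos + half_window)
        )
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}


def _in_proximal(site: OfftargetSite, proximal: Mapping[str, Sequence[Interval]]) -> bool:
    return any(site.site_interval.overlaps(iv) for iv in proximal.get(site.chrom, []))


@dataclass(frozen=True)
class OfftargetReport:
    sgrna_id: str
    n_proximal_lt31: int
    n_genome_lt21: int
    n_sites: int
    tier: StringencyTier


def classify_stringency(
    sites: Sequence[OfftargetSite],
    proximal: Mapping[str, Sequence[Interval]],
    proximal_cap: int = PROXIMAL_SCORE_CAP,
    genome_cap: int = GENOME_SCORE_CAP,
) -> StringencyTier:
    """Assign the strictest tier whose alignment allowances are satisfied.

    T0: <=1 alignment scoring < 31 TSS-proximally AND <=1 scoring < 21
    genome-wide; T1: <=1 proximal < 31 (no genomic bound); T2: <=1 genomic
    < 21; T3: <=2 proximal < 31; T4: <=3 proximal < 31; else FAIL.
    """
    if not any(s.score == 0 for s in sites):
        raise ValueError("on-target site (score 0) missing from site list")
    n_prox = sum(1 for s in sites if s.score < proximal_cap and _in_proximal(s, proximal))
    n_gen = sum(1 for s in sites if s.score < genome_cap)
    if n_prox <= 1 and n_gen <= 1:
        return StringencyTier.T0
    if n_prox <= 1:
        return StringencyTier.T1
    if n_gen <= 1:
        return StringencyTier.T2
    if n_prox <= 2:
        return StringencyTier.T3
    if n_prox <= 3:
        return StringencyTier.T4
    return StringencyTier.FAIL


def score_candidates(
    candidates: Sequence[SgrnaCandidate],
    genome: Mapping[str, str],
    proximal: Mapping[str, Sequence[Interval]],
    weights: Sequence[int] = DEFAULT_WEIGHTS,
    masked: Optional[Mapping[str, Sequence[Interval]]] = None,
    index: Optional[OfftargetIndex] = None,
) -> dict[str, OfftargetReport]:
    """Full off-target report per candidate."""
    if index is None:
        index = OfftargetIndex(genome, masked=masked)
    out: dict[str, OfftargetReport] = {}
    for c in candidates:
        sites = index.enumerate(c.protospacer_genomic, weights=weights)
        tier = classify_stringency(sites, proximal)
        out[c.id] = OfftargetReport(
            sgrna_id=c.id,
            n_proximal_lt31=sum(
                1 for s in sites if s.score < PROXIMAL_SCORE_CAP and _in_proximal(s, proximal)
            ),
            n_genome_lt21=sum(1 for s in sites if s.score < GENOME_SCORE_CAP),
            n_sites=len(sites),
            tier=tier,
        )
    return out


def write_proximal_bed(proximal: Mapping[str, Sequence[Interval]], handle: TextIO) -> None:
    for chrom in sorted(proximal):
        for iv in proximal[chrom]:
            handle.write(f"{chrom}\t{iv.start}\t{iv.end}\tproximal\n")


def write_offtarget_report(reports: Mapping[str, OfftargetReport], handle: TextIO) -> None:
    handle.write("sgrna_id\tn_proximal_lt31\tn_genome_lt21\tn_sites\ttier\n")
    for sgrna_id in sorted(reports):
        r = reports[sgrna_id]
        handle.write(
            f"{r.sgrna_id}\t{r.n_proximal_lt31}\t{r.n_genome_lt21}\t{r.n_sites}\t{r.tier.name}\n"
        )
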