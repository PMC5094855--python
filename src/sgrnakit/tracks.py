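"""Genomic signal tracks backed by bedGraph text.

Continuous chromatin signal (MNase-seq, DNase-seq, FAIRE-seq, ...) is read
from bedGraph into dense per-contig arrays; bases not covered by any record
stay NaN so downstream averaging can distinguish "no data" from zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping, TextIO

import numpy as np


class GenomicTrack:
    """Per-base signal over a set of contigs."""

    def __init__(self, name: str, values: Mapping[str, np.ndarray]):
        self.name = name
        self._values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @classmethod
    def from_bedgraph(
        cls, name: str, handle: Iterable[str], contig_lengths: Mapping[str, int]
    ) -> "GenomicTrack":
        values = {
            c: np.full(length, np.nan) for c, length in contig_lengths.items()
        }
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                continue
            values[chrom][start:end] = value
        return cls(name, values)

    @classmethod
    def constant(
        cls, name: str, value: float, contig_lengths: Mapping[str, int]
    ) -> "GenomicTrack":
        return cls(name, {c: np.full(n, value) for c, n in contig_lengths.items()})

    def has_contig(self, chrom: str) -> bool:
        return chrom in self._values

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); NaN when no data is available."""
        if chrom not in self._values:
            return float("nan")
        arr = self._values[chrom]
        window = arr[max(start, 0):min(end, len(arr))]
        if window.size == 0 or np.all(np.isnan(window)):
            return float("nan")
        return float(np.nanmean(window))


def write_bedgraph(track: GenomicTrack, handle: TextIO) -> None:
    for chrom, arr in track._values.items():
        i = 0
        n = len(arr)
        while i < n:
            if np.isnan(arr[i]):
                i += 1
                continue
            j = i + 1
            while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                j += 1
            handle.write(f"{chrom}\t{i}\t{j}\t{arr[i]:g}\n")
            i = j
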