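"""Minimal RNA secondary-structure folding.

A Zuker-free dynamic program over canonical base pairs (Watson-Crick plus
G:U wobble) with per-pair stacking-independent energies and a minimum
hairpin loop of 3 nt. This is deliberately simple — it captures the
presence and strength of guide secondary structure deterministically
without an external thermodynamics package — and both the minimum free
energy and the paired-base count of the optimal structure are exposed.
"""

from __future__ import annotations

from functools import lru_cache

# kcal/mol per closed pair; more negative = more stable
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

MIN_HAIRPIN_LOOP = 3


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if any(b not in "ACGUN" for b in seq):
        raise ValueError(f"non-nucleotide characters in {seq!r}")
    return seq


def fold(seq: str) -> tuple[float, int]:
    """Return (minimum free energy in kcal/mol, paired bases in that structure).

    An unpairable sequence (e.g. poly-A) folds to 0.0 energy with 0 paired
    bases. Output is a pure function of the input sequence.
    """
    rna = _to_rna(seq)
    n = len(rna)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if j - i <= MIN_HAIRPIN_LOOP:
            return 0.0
        # j unpaired
        e = best(i, j - 1)
        # j paired with k in [i, j - MIN_HAIRPIN_LOOP)
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            pair = PAIR_ENERGY.get((rna[k], rna[j]))
            if pair is None:
                continue
            left = best(i, k - 1) if k > i else 0.0
            e = min(e, left + pair + best(k + 1, j - 1))
        return e

    mfe = best(0, n - 1)

    # traceback for paired-base count
    def count(i: int, j: int) -> int:
        if j - i <= MIN_HAIRPIN_LOOP:
            return 0
        if best(i, j) == best(i, j - 1):
            return count(i, j - 1)
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            pair = PAIR_ENERGY.get((rna[k], rna[j]))
            if pair is None:
                continue
            left = best(i, k - 1) if k > i else 0.0
            if abs(best(i, j) - (left + pair + best(k + 1, j - 1))) < 1e-12:
                return (count(i, k - 1) if k > i else 0) + 2 + count(k + 1, j - 1)
        raise AssertionError("traceback failed")  # pragma: no cover

    paired = count(0, n - 1)
    best.cache_clear()
    return mfe, paired
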