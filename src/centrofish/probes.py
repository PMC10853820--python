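"""smiFISH probe design: length/GC window enumeration, greedy tiling,
overhang chemistry and secondary-oligo mixing arithmetic.

smiFISH uses unlabelled primary probes, each carrying a shared 3' overhang
("FLAP") that is hybridized by a fluorophore-conjugated secondary oligo.
Primary probes tile the target transcript under length (26-32 nt) and GC
(40-60 %) constraints; up to 48 probes are selected per transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Shared overhang appended to every primary probe (bound by the secondary).
FLAP_OVERHANG = "TTACACTCGGACCTCGTCGACATGCATT"

VALID_BASES = set("ACGTUN")
_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

DEFAULT_LENGTH_RANGE = (26, 32)
DEFAULT_GC_RANGE = (0.40, 0.60)
DEFAULT_MAX_PROBES = 48
DEFAULT_MIN_SPACING = 2


@dataclass(frozen=True)
class ProbeCandidate:
    """One admissible probe window on the transcript (0-based, sense strand)."""

    start: int
    length: int
    sequence: str
    gc: float

    @property
    def end(self) -> int:
        """Exclusive end position on the transcript."""
        return self.start + self.length


@dataclass
class ProbeSet:
    """Selected probes plus their overhang-appended oligo sequences."""

    probes: list[ProbeCandidate]
    overhang: str = FLAP_OVERHANG
    max_n: int = DEFAULT_MAX_PROBES
    min_spacing: int = DEFAULT_MIN_SPACING

    @property
    def oligos(self) -> list[str]:
        return [p.sequence + self.overhang for p in self.probes]

    def __len__(self) -> int:
        return len(self.probes)


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length over {A, C, G, T, U, N}; N counts as non-GC."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"illegal character {base!r} at position {i}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def reverse_complement(sequence: str) -> str:
    """Reverse complement (U treated as T); used to emit the hybridizing strand."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def enumerate_candidates(transcript: str,
                         len_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                         gc_range: tuple[float, float] = DEFAULT_GC_RANGE
                         ) -> list[ProbeCandidate]:
    """Every window of every allowed length whose GC lies in ``gc_range``.

    Bounds are inclusive; results are ordered by start, then length.
    Transcripts shorter than the minimum probe length yield an empty list.
    """
    seq = transcript.upper()
    lo, hi = len_range
    gc_lo, gc_hi = gc_range
    n = len(seq)
    out: list[ProbeCandidate] = []
    if n < lo:
        return out
    # Prefix sums make the per-window GC an O(1) lookup.
    gc_prefix = [0] * (n + 1)
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"illegal character {base!r} at position {i}")
        gc_prefix[i + 1] = gc_prefix[i] + (base in "GC")
    for start in range(n - lo + 1):
        for length in range(lo, min(hi, n - start) + 1):
            gc = (gc_prefix[start + length] - gc_prefix[start]) / length
            if gc_lo <= gc <= gc_hi:
                out.append(ProbeCandidate(start=start, length=length,
                                          sequence=seq[start:start + length],
                                          gc=gc))
    return out


def select_probes(candidates: list[ProbeCandidate],
                  max_n: int = DEFAULT_MAX_PROBES,
                  min_spacing: int = DEFAULT_MIN_SPACING,
                  overhang: str = FLAP_OVERHANG) -> ProbeSet:
    """Greedy left-to-right tiling of non-overlapping probes.

    Scanning start positions in ascending order, the first admissible start
    (at or beyond the previous probe's end plus ``min_spacing``) is
    accepted; among windows sharing that start, the one with GC closest to
    0.50 wins (ties: shorter, then the enumeration order).  Stops at
    ``max_n``; duplicate candidates in the input do not affect the result.
    """
    if max_n < 0 or min_spacing < 0:
        raise ValueError("max_n and min_spacing must be >= 0")
    by_start: dict[int, list[ProbeCandidate]] = {}
    for c in dict.fromkeys(candidates):  # dedupe, order-preserving
        by_start.setdefault(c.start, []).append(c)

    chosen: list[ProbeCandidate] = []
    cursor = 0  # minimum admissible start
    for start in sorted(by_start):
        if len(chosen) >= max_n:
            break
        if start < cursor:
            continue
        best = min(by_start[start],
                   key=lambda c: (abs(c.gc - 0.50), c.length))
        chosen.append(best)
        cursor = best.end + min_spacing
    return ProbeSet(probes=chosen, overhang=overhang, max_n=max_n,
                    min_spacing=min_spacing)


def design_probes(transcript: str, max_n: int = DEFAULT_MAX_PROBES,
                  min_spacing: int = DEFAULT_MIN_SPACING,
                  len_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                  gc_range: tuple[float, float] = DEFAULT_GC_RANGE
                  ) -> ProbeSet:
    """enumerate_candidates → select_probes in one call."""
    return select_probes(enumerate_candidates(transcript, len_range, gc_range),
                         max_n=max_n, min_spacing=min_spacing)


def secondary_mix(primary_total_conc: float, excess: float = 0.20) -> float:
    """Secondary-oligo concentration at a molar excess over the primaries.

    The secondary is added in (by default) 20 % molar excess over the total
    primary probe concentration: 20 µM primaries → 24 µM secondary.
    """
    if primary_total_conc <= 0:
        raise ValueError("primary_total_conc must be > 0")
    if excess < 0:
        raise ValueError("excess must be >= 0")
    return primary_total_conc * (1.0 + excess)
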