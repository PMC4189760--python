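"""GC-content accounting for reads, subsets and whole sets.

GC% is computed as 100·(G+C)/(A+C+G+T): ambiguity codes and N are excluded
from both numerator and denominator, and aggregates pool nucleotide counts
rather than averaging per-read percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class GCReport:
    gc_count: int
    acgt_count: int

    @property
    def gc_percent(self) -> float:
        return 100.0 * self.gc_count / self.acgt_count


def gc_content(sequences: Iterable[str] | str) -> GCReport:
    """Pooled GC report over one or more uppercase IUPAC sequences.

    Raises
    ------
    ValueError
        if no unambiguous A/C/G/T nucleotide is present.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = 0
    acgt = 0
    for seq in sequences:
        g = seq.count("G")
        c = seq.count("C")
        gc += g + c
        acgt += seq.count("A") + seq.count("T") + g + c
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous A/C/G/T bases")
    return GCReport(gc_count=gc, acgt_count=acgt)
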