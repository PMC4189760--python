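"""Perfect microsatellite (SSR) detection and motif canonicalization.

Detects maximal perfect tandem repeats with primitive unit lengths 1–6 under
class-specific minimum sizes: mononucleotide runs of at least 10 nt,
dinucleotides of at least 5 repeat units, and tri- through hexanucleotides of
at least 3 units.  Motifs are grouped by cyclic rotation plus reverse
complement; the group representative is the lexicographic minimum over all
2·k candidates.

Only perfect (uninterrupted) repeats are reported.  A locus always spans a
whole number of units; dangling partial units are not included.  Each
nucleotide belongs to at most one reported locus: candidates are ranked
leftmost-first, then longest, then smallest unit, and accepted greedily.
N characters break runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import revcomp

#: minimum total length (nt) for mononucleotide loci
MIN_MONO_NT = 10
#: minimum repeat units per unit length (2..6)
MIN_UNITS = {2: 5, 3: 3, 4: 3, 5: 3, 6: 3}

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem repeat on one read, 0-based half-open coordinates."""

    read_id: str
    start: int
    end: int
    unit: str
    canonical: str
    n_units: int

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def total_len(self) -> int:
        return self.end - self.start

    @property
    def ssr_class(self) -> str:
        return CLASS_NAMES[self.unit_len]


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not itself a repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement orbit.

    All cyclic rotations of the unit and of its reverse complement map to the
    same canonical string (their lexicographic minimum), e.g. GA, TC and CT
    all canonicalize to AG.
    """
    if not 1 <= len(unit) <= 6:
        raise ValueError(f"unit length must be 1-6, got {unit!r}")
    if set(unit) - set("ACGT"):
        raise ValueError(f"unit must contain only A/C/G/T: {unit!r}")
    if not is_primitive(unit):
        raise ValueError(f"unit is not primitive: {unit!r}")
    rc = revcomp(unit)
    k = len(unit)
    candidates = [unit[i:] + unit[:i] for i in range(k)]
    candidates += [rc[i:] + rc[:i] for i in range(k)]
    return min(candidates)


def _threshold_ok(unit_len: int, n_units: int) -> bool:
    if unit_len == 1:
        return n_units >= MIN_MONO_NT
    return n_units >= MIN_UNITS[unit_len]


def _candidate_runs(seq: str) -> list[tuple[int, int, int]]:
    """All threshold-passing maximal-run candidates as (start, end, unit_len).

    For every period k in 1..6, character-maximal period-k runs are located
    with a vectorized self-comparison; a run contributes a candidate spanning
    its left-aligned whole units when the left-edge unit is primitive,
    N-free and meets the class threshold.
    """
    n = len(seq)
    if n < 2:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    out: list[tuple[int, int, int]] = []
    for k in range(1, 7):
        if n < 2 * k:
            continue
        eq = arr[k:] == arr[:-k]
        # N never matches anything, including another N
        eq &= ~is_n[k:]
        eq &= ~is_n[:-k]
        if not eq.any():
            continue
        # boundaries of maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in eq coordinates
        for s, e in zip(starts.tolist(), ends.tolist()):
            run_len = (e - s) + k  # character length of the tandem run
            n_units = run_len // k
            measure = run_len if k == 1 else n_units
            if not _threshold_ok(k, measure):
                continue
            unit = seq[s : s + k]
            if not is_primitive(unit):
                continue  # caught at its true (smaller) period
            out.append((s, s + n_units * k, k))
    return out


def _select_loci(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy non-overlapping selection: leftmost, then longest, then smallest unit."""
    chosen: list[tuple[int, int, int]] = []
    last_end = -1
    for s, e, k in sorted(candidates, key=lambda c: (c[0], c[0] - c[1], c[2])):
        if s >= last_end:
            chosen.append((s, e, k))
            last_end = e
    return chosen


def scan_sequence(seq: str, read_id: str = "") -> list[SSRLocus]:
    """All reported SSR loci of one uppercase ACGTN sequence, left to right."""
    loci = []
    for s, e, k in _select_loci(_candidate_runs(seq)):
        unit = seq[s : s + k]
        loci.append(
            SSRLocus(
                read_id=read_id,
                start=s,
                end=e,
                unit=unit,
                canonical=canonical_motif(unit),
                n_units=(e - s) // k,
            )
        )
    return loci


def find_ssrs(read) -> list[SSRLocus]:
    """SSR loci of a BESRecord (or any object with .name and .sequence)."""
    return scan_sequence(read.sequence, read_id=read.name)


def density_per_100kb(n_loci: int, total_nt: int) -> float:
    """Loci per 100 kb of sequence examined."""
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    return 100_000 * n_loci / total_nt


@dataclass
class SSRSummary:
    n_loci: int
    total_nt: int
    class_counts: dict[str, int]
    motif_counts: Counter = field(default_factory=Counter)

    @property
    def density(self) -> float:
        """Loci per 100 kb examined."""
        return density_per_100kb(self.n_loci, self.total_nt)

    @property
    def mean_spacing_kb(self) -> float | None:
        """Mean distance between loci in kb; None when no locus was found."""
        if self.n_loci == 0:
            return None
        return self.total_nt / self.n_loci / 1000

    @property
    def class_percent(self) -> dict[str, float]:
        if self.n_loci == 0:
            return {name: 0.0 for name in self.class_counts}
        return {
            name: 100.0 * count / self.n_loci
            for name, count in self.class_counts.items()
        }

    def motif_ranking(self) -> list[tuple[str, int]]:
        """Canonical motifs by descending count, alphabetical tie-break."""
        return sorted(self.motif_counts.items(), key=lambda kv: (-kv[1], kv[0]))


def summarize(loci: Iterable[SSRLocus], total_nt: int) -> SSRSummary:
    """Density, spacing, per-class and per-canonical-motif accounting."""
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    loci = list(loci)
    class_counts = {name: 0 for name in CLASS_NAMES.values()}
    motifs: Counter = Counter()
    for locus in loci:
        class_counts[locus.ssr_class] += 1
        motifs[locus.canonical] += 1
    return SSRSummary(
        n_loci=len(loci),
        total_nt=total_nt,
        class_counts=class_counts,
        motif_counts=motifs,
    )


def write_loci(loci: Sequence[SSRLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tunit\tcanonical\tclass\tn_units\n")
        for l in loci:
            fh.write(
                f"{l.read_id}\t{l.start}\t{l.end}\t{l.unit}\t{l.canonical}"
                f"\t{l.ssr_class}\t{l.n_units}\n"
            )
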