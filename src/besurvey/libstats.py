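"""Library-level statistics: genome-equivalent coverage, Poisson recovery
probability, insert-size summaries and contamination rates."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


def coverage(n_clones: int, mean_insert_mb: float, genome_mb: float) -> float:
    """Genome equivalents: n_clones × mean insert (Mb) ÷ genome size (Mb)."""
    if n_clones <= 0 or mean_insert_mb <= 0 or genome_mb <= 0:
        raise ValueError("all coverage inputs must be positive")
    return n_clones * mean_insert_mb / genome_mb


def p_single_copy(cov: float) -> float:
    """Probability a single-copy locus is represented: 1 − e^(−coverage)."""
    if cov < 0:
        raise ValueError("coverage must be non-negative")
    return 1.0 - math.exp(-cov)


@dataclass(frozen=True)
class InsertSummary:
    n: int
    mean_kb: float
    min_kb: float
    max_kb: float
    frac_gt_threshold: float
    threshold_kb: float


def insert_summary(sizes_kb: Sequence[float], threshold_kb: float = 90) -> InsertSummary:
    """Mean/min/max insert size and the fraction strictly above a threshold."""
    if not sizes_kb:
        raise ValueError("at least one insert size required")
    if any(s <= 0 for s in sizes_kb):
        raise ValueError("insert sizes must be positive")
    n = len(sizes_kb)
    return InsertSummary(
        n=n,
        mean_kb=sum(sizes_kb) / n,
        min_kb=min(sizes_kb),
        max_kb=max(sizes_kb),
        frac_gt_threshold=sum(1 for s in sizes_kb if s > threshold_kb) / n,
        threshold_kb=threshold_kb,
    )


def contamination(n_hits: int, n_clones: int) -> float:
    """Contaminating clones as a percentage of all clones."""
    if n_clones == 0:
        raise ValueError("n_clones must be positive")
    if not 0 <= n_hits <= n_clones:
        raise ValueError("n_hits must be within [0, n_clones]")
    return 100.0 * n_hits / n_clones


@dataclass
class LibraryStats:
    n_clones: int
    mean_insert_mb: float
    genome_mb: float
    contamination_pct: dict[str, float]
    inserts: InsertSummary | None = None
    n_organellar: int = 0
    exclude_organellar: bool = True

    @property
    def n_nuclear_clones(self) -> int:
        return self.n_clones - self.n_organellar

    @property
    def coverage(self) -> float:
        n = self.n_nuclear_clones if self.exclude_organellar else self.n_clones
        return coverage(n, self.mean_insert_mb, self.genome_mb)

    @property
    def p_single_copy(self) -> float:
        return p_single_copy(self.coverage)

    @property
    def p_single_copy_rounded_coverage(self) -> float:
        """Recovery probability with coverage first rounded to an integer —
        the rendering some survey reports implicitly use."""
        return p_single_copy(round(self.coverage))

    def rows(self) -> list[tuple[str, str]]:
        out = [
            ("n_clones", str(self.n_clones)),
            ("n_organellar_clones", str(self.n_organellar)),
            ("mean_insert_Mb", f"{self.mean_insert_mb:.4f}"),
            ("genome_Mb", f"{self.genome_mb:.1f}"),
            ("coverage_genome_equivalents", f"{self.coverage:.2f}"),
            ("p_single_copy", f"{self.p_single_copy:.5f}"),
            ("p_single_copy_rounded_coverage", f"{self.p_single_copy_rounded_coverage:.5f}"),
        ]
        for organelle, pct in sorted(self.contamination_pct.items()):
            out.append((f"contamination_{organelle}_pct", f"{pct:.4f}"))
        if self.inserts:
            out += [
                ("insert_mean_kb", f"{self.inserts.mean_kb:.1f}"),
                ("insert_min_kb", f"{self.inserts.min_kb:.1f}"),
                ("insert_max_kb", f"{self.inserts.max_kb:.1f}"),
                (
                    f"insert_frac_gt_{self.inserts.threshold_kb:g}kb",
                    f"{self.inserts.frac_gt_threshold:.3f}",
                ),
            ]
        return out


def write_stats(stats: LibraryStats, path) -> None:
    with open(path, "w") as fh:
        for key, value in stats.rows():
            fh.write(f"{key}\t{value}\n")
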