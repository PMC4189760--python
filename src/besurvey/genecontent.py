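"""Coding-read calls from BLAST tabular hits, species tallies, genome-wide
coding extrapolation and GO-term accounting."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

GO_CATEGORIES = ("molecular_function", "biological_process", "cellular_component")


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular BLAST output."""

    query: str
    subject: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    species: str | None = None
    order: int = 0  # file order, used as the final tie-break

    def __post_init__(self):
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("e-value and bit score must be non-negative")


def read_blast_tab(
    path: str | Path, species_map: dict[str, str] | None = None
) -> list[BlastHit]:
    """Parse 12-column tab-separated BLAST output (outfmt-6 layout).

    Malformed rows are skipped with their line number logged.  ``species_map``
    optionally maps subject ids to species names.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 12:
                    raise ValueError("fewer than 12 columns")
                hits.append(
                    BlastHit(
                        query=parts[0],
                        subject=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        species=(species_map or {}).get(parts[1]),
                        order=lineno,
                    )
                )
            except ValueError as exc:
                logger.warning("skipping malformed hit row %d: %s", lineno, exc)
    return hits


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column subject→species TSV."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            subject, species = line.split("\t")[:2]
            mapping[subject] = species
    return mapping


def call_coding(
    hits: Iterable[BlastHit], evalue_max: float = 1e-6
) -> dict[str, BlastHit]:
    """Per-read coding calls: read → its top hit, for reads with at least one
    hit at e-value strictly below the cutoff.

    Top hit = minimum e-value; ties broken by maximum bit score, then first
    in file order.  Relaxing ``evalue_max`` never shrinks the coding set.
    """
    top: dict[str, BlastHit] = {}
    for hit in hits:
        if hit.evalue >= evalue_max:
            continue
        cur = top.get(hit.query)
        if cur is None or (hit.evalue, -hit.bitscore, hit.order) < (
            cur.evalue,
            -cur.bitscore,
            cur.order,
        ):
            top[hit.query] = hit
    return top


def species_ranking(top_hits: dict[str, BlastHit]) -> list[tuple[str, int, float]]:
    """(species, top-hit count, percent) in descending count order with an
    alphabetical tie-break; unmapped subjects bucket as ``unknown``."""
    counts: dict[str, int] = {}
    for hit in top_hits.values():
        species = hit.species or "unknown"
        counts[species] = counts.get(species, 0) + 1
    total = sum(counts.values())
    return [
        (sp, n, 100.0 * n / total)
        for sp, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def extrapolate(
    n_coding: int, n_total: int, genome_mb: float, avg_gene_kb: float = 3.4
) -> tuple[int, int]:
    """Genome-wide coding Mb and gene-count estimate.

    coding_Mb is the coding-read fraction applied to the genome size,
    truncated to an integer (a presentation choice matching how such survey
    figures are customarily printed); the gene count is coding_Mb divided by
    the average gene length, rounded to the nearest thousand.
    """
    if n_total <= 0 or genome_mb <= 0:
        raise ValueError("n_total and genome_mb must be positive")
    coding_mb = int((n_coding / n_total) * genome_mb)
    gene_count = round(coding_mb * 1000 / avg_gene_kb / 1000) * 1000
    return coding_mb, gene_count


@dataclass
class CodingSummary:
    n_coding: int
    n_total: int
    species_tally: list[tuple[str, int, float]]
    coding_mb: int
    gene_count: int
    avg_gene_kb: float

    @property
    def coding_fraction(self) -> float:
        return self.n_coding / self.n_total


def coding_summary(
    hits: Iterable[BlastHit],
    n_total: int,
    genome_mb: float,
    evalue_max: float = 1e-6,
    avg_gene_kb: float = 3.4,
) -> CodingSummary:
    top = call_coding(hits, evalue_max)
    coding_mb, gene_count = extrapolate(len(top), n_total, genome_mb, avg_gene_kb)
    return CodingSummary(
        n_coding=len(top),
        n_total=n_total,
        species_tally=species_ranking(top),
        coding_mb=coding_mb,
        gene_count=gene_count,
        avg_gene_kb=avg_gene_kb,
    )


# ---------------------------------------------------------------------------
# GO accounting


def terms_per_sequence(n_terms: int, n_annotated: int) -> float:
    """Mean number of assigned terms per annotated sequence."""
    if n_annotated <= 0:
        raise ValueError("no annotated sequences")
    return n_terms / n_annotated


@dataclass
class GOSummary:
    n_terms: int
    n_annotated: int
    category_sequences: dict[str, int]
    term_percent: dict[str, dict[str, float]]  # category -> term -> % of category seqs

    @property
    def mean_terms(self) -> float | None:
        if self.n_annotated == 0:
            return None
        return terms_per_sequence(self.n_terms, self.n_annotated)


def read_go_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Four-column (read id, GO id, category, term name) TSV."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            parts = line.split("\t")
            rows.append((parts[0], parts[1], parts[2], parts[3]))
    return rows


def go_accounting(rows: Iterable[tuple[str, str, str, str]]) -> GOSummary:
    """Totals and per-category accounting over (read, GO id, category, term) rows.

    Duplicate (read, GO id) pairs are collapsed; a sequence may count toward
    several categories.  Term percentages are over sequences holding at least
    one term of that category.  Categories are taken as supplied — there is
    no ontology traversal.
    """
    pairs: set[tuple[str, str]] = set()
    cat_seqs: dict[str, set[str]] = {c: set() for c in GO_CATEGORIES}
    term_seqs: dict[str, dict[str, set[str]]] = {c: {} for c in GO_CATEGORIES}
    annotated: set[str] = set()
    for row in rows:
        read_id, go_id, category, term = row
        if category not in GO_CATEGORIES:
            raise ValueError(f"unknown GO category {category!r} in row {row!r}")
        if (read_id, go_id) in pairs:
            continue
        pairs.add((read_id, go_id))
        annotated.add(read_id)
        cat_seqs[category].add(read_id)
        term_seqs[category].setdefault(term, set()).add(read_id)
    term_percent = {
        cat: {
            term: 100.0 * len(seqs) / len(cat_seqs[cat])
            for term, seqs in terms.items()
        }
        for cat, terms in term_seqs.items()
        if cat_seqs[cat]
    }
    return GOSummary(
        n_terms=len(pairs),
        n_annotated=len(annotated),
        category_sequences={c: len(s) for c, s in cat_seqs.items()},
        term_percent=term_percent,
    )
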