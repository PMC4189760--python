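"""Paired-end microsynteny classification of clone end alignments.

Each clone's forward/reverse end alignments against one reference genome are
classified into exactly one category:

unmapped             neither end mapped
SE                   exactly one end mapped
PE_non_colocalized   ends on different reference sequences
PE_gapped            same reference, outer span outside the accepted window
PE_collinear         span within the window, ends correctly oriented
PE_rearranged        span within the window, ends mis-oriented

The accepted window defaults to 15–350 kb (inclusive bounds).  Correct
orientation means the standard flanking-end configuration: opposite strands
with the plus-strand end leftmost (configurable to strand-opposition only).
Span is measured between the outermost alignment coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam

from .besio import DEFAULT_END_PATTERN, parse_read_name

logger = logging.getLogger(__name__)

CATEGORIES = (
    "unmapped",
    "SE",
    "PE_non_colocalized",
    "PE_gapped",
    "PE_collinear",
    "PE_rearranged",
)


@dataclass(frozen=True)
class EndAlignment:
    """One end's primary alignment, 0-based half-open reference coordinates."""

    read_id: str
    clone_id: str
    end: str  # F or R
    reference: str | None = None
    start: int | None = None
    end_pos: int | None = None
    strand: str | None = None  # "+" or "-"
    mapq: int | None = None
    mapped: bool = False

    def __post_init__(self):
        if self.mapped and self.start >= self.end_pos:
            raise ValueError(
                f"mapped alignment with empty interval for {self.read_id}"
            )


@dataclass(frozen=True)
class PairClass:
    clone_id: str
    category: str
    references: tuple[str, ...] = ()
    span_bp: int | None = None
    strands: tuple[str, ...] = ()
    orientation_ok: bool | None = None


def load_alignments(
    path: str | Path,
    min_mapq: int = 20,
    end_pattern: str = DEFAULT_END_PATTERN,
) -> dict[str, dict[str, EndAlignment]]:
    """Parse primary SAM records into clone_id → {end → EndAlignment}.

    SAM's 1-based positions become 0-based half-open intervals spanning the
    alignment's reference footprint.  Records below ``min_mapq`` are treated
    as unmapped; secondary and supplementary records are ignored; reads whose
    name has no parseable end suffix are skipped with a warning.
    """
    out: dict[str, dict[str, EndAlignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            clone, end = parse_read_name(rec.query_name, end_pattern)
            if end == "unknown":
                logger.warning("skipping read %r: no end suffix", rec.query_name)
                continue
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                aln = EndAlignment(rec.query_name, clone, end, mapped=False)
            else:
                aln = EndAlignment(
                    read_id=rec.query_name,
                    clone_id=clone,
                    end=end,
                    reference=rec.reference_name,
                    start=rec.reference_start,
                    end_pos=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    mapped=True,
                )
            out.setdefault(clone, {})[end] = aln
    return out


def _orientation_ok(a: EndAlignment, b: EndAlignment, mode: str) -> bool:
    if a.strand == b.strand:
        return False
    if mode == "opposite_only":
        return True
    # inward-facing: the plus-strand end must be the left one
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    return plus.start <= minus.start


def classify_pair(
    f: EndAlignment | None,
    r: EndAlignment | None,
    d_min: int = 15_000,
    d_max: int = 350_000,
    orientation: str = "inward",
) -> PairClass:
    """Classify one clone's end pair; rules applied in fixed order.

    The distance window bounds are inclusive.  ``orientation`` is ``inward``
    (opposite strands, plus-strand end leftmost) or ``opposite_only``.
    """
    present = [a for a in (f, r) if a is not None]
    if not present:
        raise ValueError("classify_pair needs at least one end record")
    clone = present[0].clone_id
    mapped = [a for a in present if a.mapped]
    if not mapped:
        return PairClass(clone, "unmapped")
    if len(mapped) == 1:
        a = mapped[0]
        return PairClass(clone, "SE", (a.reference,), strands=(a.strand,))
    a, b = mapped
    if a.reference != b.reference:
        return PairClass(
            clone,
            "PE_non_colocalized",
            (a.reference, b.reference),
            strands=(a.strand, b.strand),
        )
    span = max(a.end_pos, b.end_pos) - min(a.start, b.start)
    ok = _orientation_ok(a, b, orientation)
    if span < d_min or span > d_max:
        category = "PE_gapped"
    elif ok:
        category = "PE_collinear"
    else:
        category = "PE_rearranged"
    return PairClass(
        clone,
        category,
        (a.reference,),
        span_bp=span,
        strands=(a.strand, b.strand),
        orientation_ok=ok,
    )


def classify_all(
    alignments: dict[str, dict[str, EndAlignment]],
    d_min: int = 15_000,
    d_max: int = 350_000,
    orientation: str = "inward",
) -> list[PairClass]:
    """Classify every clone, sorted by clone id for deterministic output."""
    return [
        classify_pair(ends.get("F"), ends.get("R"), d_min, d_max, orientation)
        for _, ends in sorted(alignments.items())
    ]


def span_kb(pos_a: int, pos_b: int) -> float:
    """Distance between two reference positions in kb, one decimal."""
    if pos_a < 0 or pos_b < 0:
        raise ValueError("positions must be non-negative")
    return round(abs(pos_a - pos_b) / 1000, 1)


def summarize_categories(classes) -> dict[str, int]:
    """Per-category counts plus SE/PE totals, in deterministic order."""
    counts = {c: 0 for c in CATEGORIES}
    for pc in classes:
        counts[pc.category] += 1
    counts["total_SE"] = counts["SE"]
    counts["total_PE"] = (
        counts["PE_non_colocalized"]
        + counts["PE_gapped"]
        + counts["PE_collinear"]
        + counts["PE_rearranged"]
    )
    return counts


def write_classes(classes, path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tcategory\treferences\tspan_bp\tstrands\n")
        for pc in classes:
            refs = ",".join(r for r in pc.references if r)
            span = "" if pc.span_bp is None else str(pc.span_bp)
            fh.write(
                f"{pc.clone_id}\t{pc.category}\t{refs}\t{span}\t{','.join(pc.strands)}\n"
            )


def write_summary(counts: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for key in list(CATEGORIES) + ["total_SE", "total_PE"]:
            fh.write(f"{key}\t{counts[key]}\n")
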