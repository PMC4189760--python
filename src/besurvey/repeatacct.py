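"""Repeat-annotation parsing, masking and density accounting.

Features are intervals on reads labelled with a family name and a class path
drawn from a fixed taxonomy mirroring common plant-repeat accounting tables.
Density is the percentage of examined nucleotides covered by at least one
feature: per read, intervals are merged per class and overall, so each
nucleotide counts once.

``naive_mask_search`` is a deliberately simple internal masker (exact k-mer
seeding + ungapped extension against a consensus library) so that the whole
accounting path is testable without an external repeat-masking tool.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._dna import revcomp
from .besio import BESRecord, BESSet

logger = logging.getLogger(__name__)

CLASS_TAXONOMY = (
    "ClassI/LTR/Copia",
    "ClassI/LTR/Gypsy",
    "ClassI/LTR/Unclassified",
    "ClassI/LINE_SINE",
    "ClassII/DNA",
    "Unclassified",
    "SmallRNA",
    "Satellite",
    "SimpleRepeat",
    "LowComplexity",
)

#: glob pattern (matched case-insensitively against "family#class" strings)
#: → class path; first match wins; extensible via config
DEFAULT_CLASS_MAP: tuple[tuple[str, str], ...] = (
    ("*copia*", "ClassI/LTR/Copia"),
    ("*gypsy*", "ClassI/LTR/Gypsy"),
    ("*dirs*", "ClassI/LTR/Gypsy"),
    ("*ltr*", "ClassI/LTR/Unclassified"),
    ("*line*", "ClassI/LINE_SINE"),
    ("*sine*", "ClassI/LINE_SINE"),
    ("*l1*", "ClassI/LINE_SINE"),
    ("*cin4*", "ClassI/LINE_SINE"),
    ("*dna*", "ClassII/DNA"),
    ("*hat*", "ClassII/DNA"),
    ("*activator*", "ClassII/DNA"),
    ("*harbinger*", "ClassII/DNA"),
    ("*tourist*", "ClassII/DNA"),
    ("*mariner*", "ClassII/DNA"),
    ("*mudr*", "ClassII/DNA"),
    ("*helitron*", "ClassII/DNA"),
    ("*transposon*", "ClassII/DNA"),
    ("*rna*", "SmallRNA"),
    ("*satellite*", "Satellite"),
    ("*simple*", "SimpleRepeat"),
    ("*low_complexity*", "LowComplexity"),
    ("*low complexity*", "LowComplexity"),
)


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat interval on a read, 0-based half-open."""

    read_id: str
    start: int
    end: int
    family: str
    class_path: str
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty feature interval [{self.start},{self.end})")


def map_class(label: str, class_map=DEFAULT_CLASS_MAP) -> str:
    """Map an annotation's family/class string to the fixed taxonomy."""
    low = label.lower()
    for pattern, class_path in class_map:
        if fnmatch.fnmatch(low, pattern):
            return class_path
    logger.warning("unmappable repeat class string %r -> Unclassified", label)
    return "Unclassified"


def parse_annotations(
    path: str | Path,
    dialect: str = "rm_out",
    class_map=DEFAULT_CLASS_MAP,
    min_score: float | None = None,
) -> list[RepeatFeature]:
    """Parse repeat features from an annotation file.

    ``rm_out``: the classic whitespace-delimited masker output with three
    header lines and 1-based inclusive query coordinates (converted to
    0-based half-open on read).  ``tsv``: the generic feature table written
    by :func:`write_features`.

    Features with a score below ``min_score`` (when scores are present) are
    dropped and counted in the log.
    """
    features: list[RepeatFeature] = []
    dropped = 0
    if dialect == "rm_out":
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines[3:]:
            parts = line.split()
            if not parts:
                continue
            score = float(parts[0])
            read_id = parts[4]
            qstart = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
            qend = int(parts[6])
            family = parts[9]
            class_label = parts[10] if len(parts) > 10 else family
            if min_score is not None and score < min_score:
                dropped += 1
                continue
            features.append(
                RepeatFeature(
                    read_id=read_id,
                    start=qstart,
                    end=qend,
                    family=family,
                    class_path=map_class(f"{family}#{class_label}", class_map),
                    score=score,
                )
            )
    elif dialect == "tsv":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or (i == 0 and line.startswith("read_id\t")):
                    continue
                read_id, start, end, family, class_path, *rest = line.split("\t")
                score = float(rest[0]) if rest and rest[0] != "" else None
                if min_score is not None and score is not None and score < min_score:
                    dropped += 1
                    continue
                if class_path not in CLASS_TAXONOMY:
                    class_path = map_class(class_path, class_map)
                features.append(
                    RepeatFeature(read_id, int(start), int(end), family, class_path, score)
                )
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    if dropped:
        logger.info("dropped %d features below score cutoff", dropped)
    return features


def write_features(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tfamily\tclass_path\tscore\n")
        for f in features:
            score = "" if f.score is None else repr(f.score)
            fh.write(f"{f.read_id}\t{f.start}\t{f.end}\t{f.family}\t{f.class_path}\t{score}\n")


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mask(beset: BESSet, features, hard: bool = True) -> BESSet:
    """Return a copy of the set with feature positions hard-masked (N) or
    soft-masked (lowercase).  Features out of read bounds are clipped with a
    warning; reads without features are untouched."""
    by_read: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_read.setdefault(f.read_id, []).append((f.start, f.end))
    out = BESSet(n_filtered=beset.n_filtered)
    for rec in beset.records:
        ivs = by_read.get(rec.name)
        if not ivs:
            out.records.append(rec)
            continue
        seq = list(rec.sequence)
        for s, e in merge_intervals(ivs):
            if s < 0 or e > len(seq):
                logger.warning(
                    "feature [%d,%d) out of bounds on %s (%d nt); clipped",
                    s, e, rec.name, len(seq),
                )
                s, e = max(s, 0), min(e, len(seq))
            for i in range(s, e):
                seq[i] = "N" if hard else seq[i].lower()
        out.records.append(BESRecord(rec.name, rec.clone_id, rec.end, "".join(seq)))
    return out


def density_percent(masked_nt: int, total_nt: int) -> float:
    """Percentage of examined nucleotides covered by at least one repeat hit."""
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    return 100.0 * masked_nt / total_nt


@dataclass
class RepeatReport:
    """Per-class element counts, masked nucleotide counts and densities."""

    total_nt: int
    n_elements: int
    masked_nt: int  # overall union across classes
    per_class: dict[str, dict[str, float]]  # class -> {n_elements, masked_nt, percent}

    @property
    def density(self) -> float:
        return density_percent(self.masked_nt, self.total_nt)

    def rows(self) -> list[tuple[str, int, int, float]]:
        out = []
        for cls in CLASS_TAXONOMY:
            if cls in self.per_class:
                d = self.per_class[cls]
                out.append((cls, int(d["n_elements"]), int(d["masked_nt"]), d["percent"]))
        out.append(("Total", self.n_elements, self.masked_nt, self.density))
        return out


def density_report(features, total_nt: int) -> RepeatReport:
    """Class accounting with union semantics.

    Overall density uses the per-read union across all classes; per-class
    figures use per-read per-class unions.  Element count is the number of
    input features.  The result is invariant under feature order and under
    duplication of identical features.
    """
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    features = list(features)
    by_read_all: dict[str, list[tuple[int, int]]] = {}
    by_read_class: dict[tuple[str, str], list[tuple[int, int]]] = {}
    class_elements: dict[str, int] = {}
    for f in features:
        by_read_all.setdefault(f.read_id, []).append((f.start, f.end))
        by_read_class.setdefault((f.read_id, f.class_path), []).append((f.start, f.end))
        class_elements[f.class_path] = class_elements.get(f.class_path, 0) + 1
    masked = sum(
        e - s for ivs in by_read_all.values() for s, e in merge_intervals(ivs)
    )
    per_class: dict[str, dict[str, float]] = {}
    for (read_id, cls), ivs in by_read_class.items():
        nt = sum(e - s for s, e in merge_intervals(ivs))
        entry = per_class.setdefault(cls, {"n_elements": 0, "masked_nt": 0, "percent": 0.0})
        entry["masked_nt"] += nt
    for cls, entry in per_class.items():
        entry["n_elements"] = class_elements[cls]
        entry["percent"] = density_percent(int(entry["masked_nt"]), total_nt)
    return RepeatReport(
        total_nt=total_nt,
        n_elements=len(features),
        masked_nt=masked,
        per_class=per_class,
    )


def write_report(report: RepeatReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tn_elements\tmasked_nt\tpercent_nt\n")
        for cls, n, nt, pct in report.rows():
            fh.write(f"{cls}\t{n}\t{nt}\t{pct:.2f}\n")


# ---------------------------------------------------------------------------
# naive internal masker


def load_library(path: str | Path) -> list[tuple[str, str, str]]:
    """Load a consensus library FASTA as (name, class_path, sequence).

    The class path is taken from the record description (second whitespace
    field of the header); absent descriptions map to Unclassified.
    """
    library = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split()
        class_path = desc[1] if len(desc) > 1 else "Unclassified"
        if class_path not in CLASS_TAXONOMY:
            class_path = map_class(class_path)
        library.append((rec.id, class_path, str(rec.seq).upper()))
    return library


def _extend(read: str, cons: str, r_lo: int, r_hi: int, c_lo: int,
            max_mismatch_frac: float) -> tuple[int, int, int]:
    """Ungapped extension of a matching block in both directions.

    Returns (read_start, read_end, mismatches) with mismatching flanks
    trimmed back to the outermost matching bases.
    """
    diag = c_lo - r_lo  # cons position = read position + diag
    mm = 0
    length = r_hi - r_lo
    # right
    i = r_hi
    best_right, best_mm_r = r_hi, 0
    mm_r = 0
    while i < len(read) and i + diag < len(cons):
        if read[i] == cons[i + diag]:
            if mm + mm_r <= max_mismatch_frac * (i + 1 - r_lo):
                best_right, best_mm_r = i + 1, mm_r
        else:
            mm_r += 1
            if mm + mm_r > max_mismatch_frac * (i + 1 - r_lo) + 1:
                break
        i += 1
    mm += best_mm_r
    # left
    i = r_lo - 1
    best_left, best_mm_l = r_lo, 0
    mm_l = 0
    while i >= 0 and i + diag >= 0:
        if read[i] == cons[i + diag]:
            if mm + mm_l <= max_mismatch_frac * (best_right - i):
                best_left, best_mm_l = i, mm_l
        else:
            mm_l += 1
            if mm + mm_l > max_mismatch_frac * (best_right - i) + 1:
                break
        i -= 1
    return best_left, best_right, mm + best_mm_l


def naive_mask_search(
    beset: BESSet,
    library,
    k: int = 12,
    min_len: int = 50,
    max_mismatch_frac: float = 0.05,
) -> list[RepeatFeature]:
    """Find repeat features by exact k-mer seeding against a consensus library.

    Both strands of every consensus are seeded; seeds sharing a diagonal are
    chained and extended without gaps under the mismatch-fraction tolerance.
    Per read and family, overlapping hits are merged and maximal hits of at
    least ``min_len`` nt are reported.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if isinstance(library, (str, Path)):
        library = load_library(library)
    if not library:
        raise ValueError("empty repeat library")
    # seed index: kmer -> list of (library entry idx, strand, position)
    index: dict[str, list[tuple[int, int, int]]] = {}
    strands: list[list[str]] = []
    for idx, (_name, _cls, seq) in enumerate(library):
        fwd, rev = seq, revcomp(seq)
        strands.append([fwd, rev])
        for strand, s in ((0, fwd), (1, rev)):
            for pos in range(len(s) - k + 1):
                index.setdefault(s[pos : pos + k], []).append((idx, strand, pos))

    features: list[RepeatFeature] = []
    for rec in beset.records:
        read = rec.sequence
        # group seed matches by (library entry, strand, diagonal)
        groups: dict[tuple[int, int, int], list[int]] = {}
        for rpos in range(len(read) - k + 1):
            for idx, strand, cpos in index.get(read[rpos : rpos + k], ()):
                groups.setdefault((idx, strand, cpos - rpos), []).append(rpos)
        hits: dict[str, list[tuple[int, int]]] = {}
        fam_class: dict[str, str] = {}
        for (idx, strand, diag), positions in groups.items():
            cons = strands[idx][strand]
            r_lo, r_hi = min(positions), max(positions) + k
            s, e, _mm = _extend(read, cons, r_lo, r_hi, r_lo + diag, max_mismatch_frac)
            if e - s >= min_len:
                name = library[idx][0]
                fam_class[name] = library[idx][1]
                hits.setdefault(name, []).append((s, e))
        for name, ivs in sorted(hits.items()):
            for s, e in merge_intervals(ivs):
                features.append(
                    RepeatFeature(rec.name, s, e, name, fam_class[name])
                )
    return features
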