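"""Derive a rearranged reference genome and per-clone expected categories.

Edits (inversion, deletion, insertion, translocation) are specified in
source-genome coordinates, must not overlap, and are applied left to right.
The reference may additionally be split into chromosomes at given reference
positions.  For every clone the expected microsynteny category is recomputed
here from first principles (an independent application of the distance-window
and orientation rules), and an alignment file in SAM format is emitted as a
stand-in for an external aligner's output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .._dna import revcomp
from .spec import ConfigError, SurveySpec, stream
from .truth import PairTruth, TruthTable

D_MIN_DEFAULT = 15_000
D_MAX_DEFAULT = 350_000


@dataclass(frozen=True)
class _Piece:
    """A contiguous slice of the reference: a source interval (possibly
    reverse-complemented) or novel inserted sequence."""

    src_start: int | None  # None for insertions
    src_end: int | None
    flipped: bool
    ins_seq: str | None = None

    @property
    def length(self) -> int:
        if self.src_start is None:
            return len(self.ins_seq)
        return self.src_end - self.src_start


def _validate_edits(edits, genome_length: int) -> None:
    segments = []
    for e in edits:
        if e.kind == "insertion":
            if not 0 <= e.position <= genome_length:
                raise ConfigError(f"insertion position {e.position} out of bounds")
            continue
        if e.position + e.length > genome_length:
            raise ConfigError(f"{e.kind} at {e.position} extends past the genome")
        segments.append((e.position, e.position + e.length, e))
    segments.sort()
    for (s1, e1, a), (s2, e2, b) in zip(segments, segments[1:]):
        if s2 < e1:
            raise ConfigError(
                f"overlapping rearrangements: {a.kind}@{a.position} and {b.kind}@{b.position}"
            )
    for e in edits:
        if e.kind == "translocation":
            for s, t, other in segments:
                if other is not e and s < e.dest < t:
                    raise ConfigError("translocation destination inside another edit")


def _build_pieces(edits, genome_length: int, rng, gc: float) -> list[_Piece]:
    segment_edits = sorted(
        (e for e in edits if e.kind in ("inversion", "deletion", "translocation")),
        key=lambda e: e.position,
    )
    pieces: list[_Piece] = []
    cursor = 0
    moved: list = []  # translocations to re-insert
    for e in segment_edits:
        if e.position > cursor:
            pieces.append(_Piece(cursor, e.position, False))
        if e.kind == "inversion":
            pieces.append(_Piece(e.position, e.position + e.length, True))
        elif e.kind == "translocation":
            moved.append(e)
        # deletion: segment simply skipped
        cursor = e.position + e.length
    if cursor < genome_length:
        pieces.append(_Piece(cursor, genome_length, False))

    def insert_at(src_pos: int, new_piece: _Piece) -> None:
        for i, p in enumerate(pieces):
            if p.src_start is None:
                continue
            if p.src_start <= src_pos <= p.src_end:
                left = _Piece(p.src_start, src_pos, p.flipped)
                right = _Piece(src_pos, p.src_end, p.flipped)
                replacement = [x for x in (left, new_piece, right) if x.length > 0]
                pieces[i : i + 1] = replacement
                return
        raise ConfigError(f"no reference piece contains source position {src_pos}")

    for e in moved:
        insert_at(e.dest, _Piece(e.position, e.position + e.length, False))
    for e in (x for x in edits if x.kind == "insertion"):
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=e.length,
                         p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        insert_at(e.position, _Piece(None, None, False, seq.tobytes().decode()))
    return [p for p in pieces if p.length > 0]


class ReferenceMap:
    """The derived reference: its sequence, chromosomes, and a coordinate map
    from source-genome intervals to reference intervals."""

    def __init__(self, genome: str, spec: SurveySpec):
        _validate_edits(spec.rearrangements, len(genome))
        rng = stream(spec.seed, "reference_insertions")
        self.pieces = _build_pieces(
            spec.rearrangements, len(genome), rng, spec.gc_fraction
        )
        self.ref_offsets: list[int] = []
        offset = 0
        chunks = []
        for p in self.pieces:
            self.ref_offsets.append(offset)
            if p.src_start is None:
                chunks.append(p.ins_seq)
            else:
                seg = genome[p.src_start : p.src_end]
                chunks.append(revcomp(seg) if p.flipped else seg)
            offset += p.length
        self.sequence = "".join(chunks)
        breaks = [b for b in spec.reference_breaks if 0 < b < len(self.sequence)]
        bounds = [0] + breaks + [len(self.sequence)]
        self.chromosomes = [
            (f"chr{i + 1}", bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
        ]

    def chromosome_sequences(self) -> list[tuple[str, str]]:
        return [(name, self.sequence[s:e]) for name, s, e in self.chromosomes]

    def _chrom_of(self, ref_pos: int) -> int:
        i = bisect.bisect_right([s for _, s, _ in self.chromosomes], ref_pos) - 1
        return i

    def map_interval(self, start: int, end: int):
        """Map a source interval to (chrom name, chrom-local start, end, flipped).

        Returns None when the interval is deleted, straddles a piece boundary
        or straddles a chromosome split — cases where a real aligner would
        produce no single primary alignment.
        """
        for piece, offset in zip(self.pieces, self.ref_offsets):
            if piece.src_start is None:
                continue
            if piece.src_start <= start and end <= piece.src_end:
                if piece.flipped:
                    ref_start = offset + (piece.src_end - end)
                else:
                    ref_start = offset + (start - piece.src_start)
                ref_end = ref_start + (end - start)
                ci = self._chrom_of(ref_start)
                name, cs, ce = self.chromosomes[ci]
                if ref_end > ce:
                    return None  # straddles a chromosome split
                return name, ref_start - cs, ref_end - cs, piece.flipped
        return None


def _expected_category(
    f_aln, r_aln, d_min: int, d_max: int
) -> tuple[str, tuple[str, ...], int | None]:
    """Independent, rule-by-rule derivation of a pair's expected category.

    Each alignment is (chrom, start, end, strand) or None.
    """
    mapped = [a for a in (f_aln, r_aln) if a is not None]
    if not mapped:
        return "unmapped", (), None
    if len(mapped) == 1:
        return "SE", (mapped[0][0],), None
    (cf, sf, ef, strand_f), (cr, sr, er, strand_r) = f_aln, r_aln
    if cf != cr:
        return "PE_non_colocalized", (cf, cr), None
    span = max(ef, er) - min(sf, sr)
    if span < d_min or span > d_max:
        return "PE_gapped", (cf,), span
    if strand_f != strand_r:
        plus_start = sf if strand_f == "+" else sr
        minus_start = sr if strand_f == "+" else sf
        if plus_start <= minus_start:
            return "PE_collinear", (cf,), span
    return "PE_rearranged", (cf,), span


def derive_reference(
    genome: str,
    spec: SurveySpec,
    truth: TruthTable,
    d_min: int = D_MIN_DEFAULT,
    d_max: int = D_MAX_DEFAULT,
) -> tuple[ReferenceMap, TruthTable]:
    """Build the rearranged reference and record expected pair categories.

    For every clone in the truth table the two end intervals are pushed
    through the coordinate map and the category the classifier must assign is
    derived independently and stored as truth.
    """
    refmap = ReferenceMap(genome, spec)
    reads_by_clone: dict[str, dict[str, int]] = {}
    for r in truth.reads:
        reads_by_clone.setdefault(r.clone_id, {})[r.end] = r.length
    for clone in truth.clones:
        ends = reads_by_clone.get(clone.clone_id, {})
        f_aln = r_aln = None
        if clone.provenance == "nuclear" and clone.start is not None:
            if "F" in ends:
                f_aln = _map_end(refmap, clone.start, ends["F"], "F")
            if "R" in ends:
                start_r = clone.start + clone.insert_len - ends["R"]
                r_aln = _map_end(refmap, start_r, ends["R"], "R")
        if not ends:
            continue
        category, refs, span = _expected_category(f_aln, r_aln, d_min, d_max)
        truth.pairs.append(PairTruth(clone.clone_id, category, refs, span))
    return refmap, truth


def _map_end(refmap: ReferenceMap, start: int, length: int, end_label: str):
    mapped = refmap.map_interval(start, start + length)
    if mapped is None:
        return None
    chrom, s, e, flipped = mapped
    if end_label == "F":
        strand = "-" if flipped else "+"
    else:
        strand = "+" if flipped else "-"
    return chrom, s, e, strand


def write_sam(
    path,
    refmap: ReferenceMap,
    beset,
    truth: TruthTable,
) -> None:
    """Emit the stand-in aligner output: one primary record per read."""
    clone_info = {c.clone_id: c for c in truth.clones}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, s, e in refmap.chromosomes:
            fh.write(f"@SQ\tSN:{name}\tLN:{e - s}\n")
        fh.write("@PG\tID:besurvey-sim\tPN:besurvey-sim\n")
        for rec in beset.records:
            clone = clone_info[rec.clone_id]
            aln = None
            if clone.provenance == "nuclear" and clone.start is not None:
                if rec.end == "F":
                    aln = _map_end(refmap, clone.start, rec.length, "F")
                else:
                    start_r = clone.start + clone.insert_len - rec.length
                    aln = _map_end(refmap, start_r, rec.length, "R")
            if aln is None:
                fh.write(f"{rec.name}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.sequence}\t*\n")
                continue
            chrom, s, e, strand = aln
            flag = 16 if strand == "-" else 0
            seq = revcomp(rec.sequence) if strand == "-" else rec.sequence
            fh.write(
                f"{rec.name}\t{flag}\t{chrom}\t{s + 1}\t60\t{rec.length}M\t*\t0\t0\t{seq}\t*\n"
            )
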