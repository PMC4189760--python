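"""BES FASTA input/output, end pairing, length filtering and set-level QC.

A BES read is one Sanger-style end read of a large-insert clone.  Read names
carry the clone identifier plus a trailing ``F``/``R`` end label
(``c0001F``/``c0001R`` by default, configurable via a regex).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import IUPAC_CODES

logger = logging.getLogger(__name__)

#: default: clone id is everything up to a single trailing F or R
DEFAULT_END_PATTERN = r"^(?P<clone>.*?)(?P<end>[FR])$"

#: default substring→organelle mapping for subject names in hit files
DEFAULT_ORGANELLE_TAGS = {
    "chloroplast": ("chloroplast", "cpdna", "plastid"),
    "mitochondrial": ("mitochond", "mtdna"),
}


class BESError(ValueError):
    """Raised for malformed BES input."""


@dataclass
class BESRecord:
    """One end read: clone identifier, end label and uppercase sequence."""

    name: str
    clone_id: str
    end: str  # "F", "R" or "unknown"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BESSet:
    """An ordered collection of end reads with a clone-pairing index."""

    records: list[BESRecord] = field(default_factory=list)
    n_filtered: int = 0  # reads dropped by the length floor on load

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_reads(self) -> int:
        return len(self.records)

    @property
    def total_nt(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def pairing(self) -> dict[str, dict[str, BESRecord]]:
        """clone_id -> {end label -> record} for records with a parsed end."""
        index: dict[str, dict[str, BESRecord]] = {}
        for rec in self.records:
            if rec.end in ("F", "R"):
                index.setdefault(rec.clone_id, {})[rec.end] = rec
        return index

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def parse_read_name(name: str, end_pattern: str = DEFAULT_END_PATTERN) -> tuple[str, str]:
    """Split a read name into (clone_id, end); end is ``unknown`` if unparseable."""
    m = re.match(end_pattern, name)
    if m:
        return m.group("clone"), m.group("end")
    logger.warning("read name %r has no parseable F/R end suffix", name)
    return name, "unknown"


def load_fasta(
    path: str | Path,
    min_len: int = 100,
    end_pattern: str = DEFAULT_END_PATTERN,
) -> BESSet:
    """Load a BES FASTA, uppercasing sequences and applying the length floor.

    Records shorter than ``min_len`` are excluded and counted in
    ``BESSet.n_filtered``; set totals reflect retained records only.

    Raises
    ------
    BESError
        on a duplicate read name, an empty sequence, or characters outside
        the IUPAC DNA alphabet.
    """
    beset = BESSet()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise BESError(f"duplicate read name: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise BESError(f"empty sequence for read {rec.id!r}")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise BESError(
                f"read {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if len(seq) < min_len:
            beset.n_filtered += 1
            logger.info("filtered %s (%d nt < %d nt floor)", rec.id, len(seq), min_len)
            continue
        clone, end = parse_read_name(rec.id, end_pattern)
        beset.records.append(BESRecord(rec.id, clone, end, seq))
    return beset


def write_fasta(beset: BESSet, path: str | Path) -> None:
    """Write a BES set as FASTA wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in beset.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def redundancy(beset: BESSet) -> float:
    """Exact-duplicate fraction: 1 − distinct sequences / total records.

    The underlying study reports set redundancy without defining it; this
    implementation counts byte-identical (uppercased) sequences only, so it
    is a lower bound on any clustering-based figure.
    """
    if not beset.records:
        raise BESError("redundancy is undefined for an empty set")
    distinct = len(set(beset.sequences()))
    return 1.0 - distinct / beset.total_reads


def screen_organellar(
    beset: BESSet,
    hits_path: str | Path,
    evalue_max: float = 1e-6,
    organelle_tags: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, str]:
    """Label every read nuclear/chloroplast/mitochondrial from a BLAST hit table.

    A read is organellar iff it has at least one hit with e-value strictly
    below ``evalue_max`` to a subject whose name carries that organelle's tag.
    Chloroplast takes precedence over mitochondrial on conflict (logged).
    Hits for reads absent from the set are ignored with a warning.
    """
    from .genecontent import read_blast_tab

    tags = organelle_tags or DEFAULT_ORGANELLE_TAGS
    known = {r.name for r in beset.records}
    labels = {name: "nuclear" for name in known}
    flagged: dict[str, set[str]] = {}
    for hit in read_blast_tab(hits_path):
        if hit.query not in known:
            logger.warning("organellar hit for unknown read %r ignored", hit.query)
            continue
        if hit.evalue >= evalue_max:
            continue
        subject = hit.subject.lower()
        for organelle, substrings in tags.items():
            if any(s in subject for s in substrings):
                flagged.setdefault(hit.query, set()).add(organelle)
    for name, organelles in flagged.items():
        if len(organelles) > 1:
            logger.warning(
                "read %s hits multiple organelles %s; chloroplast takes precedence",
                name,
                sorted(organelles),
            )
        if "chloroplast" in organelles:
            labels[name] = "chloroplast"
        elif "mitochondrial" in organelles:
            labels[name] = "mitochondrial"
    return labels


def qc_summary(beset: BESSet) -> dict[str, float | int]:
    """Set-level QC statistics as a flat key/value mapping."""
    n = beset.total_reads
    lengths = [r.length for r in beset.records]
    pairing = beset.pairing
    paired = sum(1 for ends in pairing.values() if len(ends) == 2)
    summary: dict[str, float | int] = {
        "n_reads": n,
        "n_filtered_short": beset.n_filtered,
        "total_nt": beset.total_nt,
        "n_clones": len(pairing),
        "n_paired_clones": paired,
        "n_single_end_clones": len(pairing) - paired,
    }
    if n:
        summary["mean_length"] = beset.total_nt / n
        summary["min_length"] = min(lengths)
        summary["max_length"] = max(lengths)
        summary["redundancy"] = redundancy(beset)
    return summary
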