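"""Synthetic genome, clone library, end reads and rearranged reference with
complete truth labels, so every downstream stage is testable at desk scale."""

from __future__ import annotations

from pathlib import Path

from ..besio import BESSet, write_fasta
from .genome import generate_genome
from .library import simulate_library
from .reference import ReferenceMap, derive_reference, write_sam
from .spec import (
    CapacityError,
    ConfigError,
    Rearrangement,
    RepeatFamily,
    SurveySpec,
    default_repeat_families,
    stream,
)
from .truth import TruthTable

__all__ = [
    "SurveySpec",
    "RepeatFamily",
    "Rearrangement",
    "TruthTable",
    "ConfigError",
    "CapacityError",
    "default_repeat_families",
    "generate_genome",
    "simulate_library",
    "derive_reference",
    "ReferenceMap",
    "write_sam",
    "write_repeat_library",
    "run_simulation",
    "stream",
]


def write_repeat_library(spec: SurveySpec, genome: str, truth: TruthTable, path) -> None:
    """Write one representative consensus per family as a search library.

    The first planted copy of each family is used verbatim (at mutation rate
    zero it equals the consensus).
    """
    seen = set()
    with open(path, "w") as fh:
        for rep in truth.repeats:
            if rep.family in seen:
                continue
            seen.add(rep.family)
            seq = genome[rep.start : rep.end]
            fh.write(f">{rep.family} {rep.class_path}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_organellar_hits(beset: BESSet, truth: TruthTable, path) -> None:
    """Stand-in BLAST tabular hit file flagging organellar reads."""
    provenance = {r.name: r.provenance for r in truth.reads}
    with open(path, "w") as fh:
        for rec in beset.records:
            prov = provenance.get(rec.name, "nuclear")
            if prov == "nuclear":
                continue
            subject = f"{prov}_genome"
            fh.write(
                f"{rec.name}\t{subject}\t98.00\t{rec.length}\t0\t0\t1\t{rec.length}"
                f"\t1\t{rec.length}\t1e-50\t500.0\n"
            )


def run_simulation(
    spec: SurveySpec,
    outdir,
    organellar: list[tuple[str, str]] | None = None,
) -> tuple[BESSet, TruthTable]:
    """Full simulation run: genome, library, reference, SAM and truth files.

    Writes genome.fasta, reads.fasta, reference.fasta, alignments.sam,
    repeat_library.fasta, organellar_hits.tsv (when organellar clones exist)
    and the truth_*.tsv tables under ``outdir``.  Identical (spec, seed)
    yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(spec)
    beset, truth = simulate_library(genome, spec, truth, organellar=organellar)
    refmap, truth = derive_reference(genome, spec, truth)

    _write_single_fasta(outdir / "genome.fasta", "genome", genome)
    write_fasta(beset, outdir / "reads.fasta")
    with open(outdir / "reference.fasta", "w") as fh:
        for name, seq in refmap.chromosome_sequences():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_sam(outdir / "alignments.sam", refmap, beset, truth)
    write_repeat_library(spec, genome, truth, outdir / "repeat_library.fasta")
    if any(r.provenance != "nuclear" for r in truth.reads):
        _write_organellar_hits(beset, truth, outdir / "organellar_hits.tsv")
    truth.write(outdir)
    return beset, truth


def _write_single_fasta(path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
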