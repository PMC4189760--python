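"""Truth-label records emitted alongside every synthetic artifact.

All coordinates are 0-based half-open in source-genome space unless stated
otherwise.  Truth tables are written as plain tab-separated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SSRTruth:
    start: int
    end: int
    unit: str
    canonical: str

    @property
    def unit_len(self) -> int:
        return len(self.unit)


@dataclass(frozen=True)
class RepeatTruth:
    start: int
    end: int
    family: str
    class_path: str
    n_mutations: int = 0


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    start: int | None  # None for organellar clones
    insert_len: int
    provenance: str  # nuclear | chloroplast | mitochondrial
    organelle_name: str | None = None
    organelle_start: int | None = None
    duplicate_of: str | None = None


@dataclass(frozen=True)
class ReadTruth:
    name: str
    clone_id: str
    end: str
    length: int
    provenance: str


@dataclass(frozen=True)
class PairTruth:
    clone_id: str
    category: str
    references: tuple[str, ...] = ()
    span_bp: int | None = None


@dataclass
class TruthTable:
    genome_length: int = 0
    ssrs: list[SSRTruth] = field(default_factory=list)
    repeats: list[RepeatTruth] = field(default_factory=list)
    clones: list[CloneTruth] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)
    n_discarded_reads: int = 0

    def repeat_nt(self) -> int:
        return sum(r.end - r.start for r in self.repeats)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        with open(outdir / "truth_ssrs.tsv", "w") as fh:
            fh.write("start\tend\tunit\tcanonical\n")
            for s in self.ssrs:
                fh.write(f"{s.start}\t{s.end}\t{s.unit}\t{s.canonical}\n")
        with open(outdir / "truth_repeats.tsv", "w") as fh:
            fh.write("start\tend\tfamily\tclass_path\tn_mutations\n")
            for r in self.repeats:
                fh.write(f"{r.start}\t{r.end}\t{r.family}\t{r.class_path}\t{r.n_mutations}\n")
        with open(outdir / "truth_clones.tsv", "w") as fh:
            fh.write(
                "clone_id\tstart\tinsert_len\tprovenance\torganelle_name"
                "\torganelle_start\tduplicate_of\n"
            )
            for c in self.clones:
                fh.write(
                    f"{c.clone_id}\t{'' if c.start is None else c.start}\t{c.insert_len}"
                    f"\t{c.provenance}\t{c.organelle_name or ''}"
                    f"\t{'' if c.organelle_start is None else c.organelle_start}"
                    f"\t{c.duplicate_of or ''}\n"
                )
        with open(outdir / "truth_reads.tsv", "w") as fh:
            fh.write("name\tclone_id\tend\tlength\tprovenance\n")
            for r in self.reads:
                fh.write(f"{r.name}\t{r.clone_id}\t{r.end}\t{r.length}\t{r.provenance}\n")
        with open(outdir / "truth_pairs.tsv", "w") as fh:
            fh.write("clone_id\tcategory\treferences\tspan_bp\n")
            for p in self.pairs:
                span = "" if p.span_bp is None else str(p.span_bp)
                fh.write(
                    f"{p.clone_id}\t{p.category}\t{','.join(p.references)}\t{span}\n"
                )
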