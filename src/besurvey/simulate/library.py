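"""Simulate a clone library and its end reads from a source genome.

Clone starts are uniform; insert lengths follow a truncated normal; the F
read is the first L nt of the insert on the forward strand and the R read
the reverse complement of the last L nt.  Optional knobs: a fraction of
clones sequenced at one end only, exact duplicate clones (a stand-in for set
redundancy), and organellar clones drawn from supplied organellar sequences.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .._dna import revcomp
from ..besio import BESRecord, BESSet
from .spec import ConfigError, SurveySpec, stream
from .truth import CloneTruth, ReadTruth, TruthTable

logger = logging.getLogger(__name__)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_library(
    genome: str,
    spec: SurveySpec,
    truth: TruthTable | None = None,
    organellar: list[tuple[str, str]] | None = None,
) -> tuple[BESSet, TruthTable]:
    """Draw clones and emit their end reads; truth records are appended.

    ``organellar`` supplies (name, sequence) organellar genomes; required
    whenever ``spec.organellar_rate > 0``.  Reads shorter than
    ``spec.read_min`` after truncation at insert edges are discarded and
    counted in ``truth.n_discarded_reads``.
    """
    if spec.organellar_rate > 0 and not organellar:
        raise ConfigError("organellar_rate > 0 but no organellar sequences supplied")
    insert_max_nt = int(spec.insert_max * 1000)
    if len(genome) <= insert_max_nt:
        raise ConfigError(
            f"genome ({len(genome)} nt) must be longer than insert_max "
            f"({insert_max_nt} nt)"
        )
    truth = truth if truth is not None else TruthTable(genome_length=len(genome))

    rng_clone = stream(spec.seed, "clones")
    rng_insert = stream(spec.seed, "inserts")
    rng_len = stream(spec.seed, "readlen")
    rng_org = stream(spec.seed, "organellar")
    rng_unpaired = stream(spec.seed, "unpaired")

    n = spec.n_clones
    n_dup = int(round(spec.duplicate_rate * n))
    n_base = n - n_dup
    if n_base <= 0:
        raise ConfigError("duplicate_rate leaves no original clones")

    inserts = np.rint(
        _truncated_normal(
            rng_insert,
            spec.insert_mean * 1000,
            spec.insert_sd * 1000,
            spec.insert_min * 1000,
            spec.insert_max * 1000,
            n_base,
        )
    ).astype(int)
    starts = rng_clone.integers(0, len(genome) - inserts + 1)
    is_org = rng_org.random(n_base) < spec.organellar_rate
    read_lens = np.rint(
        _truncated_normal(
            rng_len, spec.read_length_mean, spec.read_length_sd,
            spec.read_min, spec.read_max, 2 * n_base,
        )
    ).astype(int)
    drop_end = rng_unpaired.random(n_base) < spec.unpaired_fraction
    which_end = rng_unpaired.integers(0, 2, n_base)  # 0 -> drop F, 1 -> drop R

    beset = BESSet()
    base_records: dict[str, list[BESRecord]] = {}

    for i in range(n_base):
        clone_id = f"bac{i:05d}"
        ins = int(inserts[i])
        l_f = min(int(read_lens[2 * i]), ins)
        l_r = min(int(read_lens[2 * i + 1]), ins)
        if is_org[i]:
            org_idx = int(rng_org.integers(0, len(organellar)))
            org_name, org_seq = organellar[org_idx]
            ins = min(ins, len(org_seq))
            org_start = int(rng_org.integers(0, len(org_seq) - ins + 1))
            source, src_start, provenance = org_seq, org_start, _provenance(org_name)
            truth.clones.append(
                CloneTruth(clone_id, None, ins, provenance, org_name, org_start)
            )
        else:
            source, src_start, provenance = genome, int(starts[i]), "nuclear"
            truth.clones.append(CloneTruth(clone_id, src_start, ins, provenance))
        l_f, l_r = min(l_f, ins), min(l_r, ins)
        emit = {"F", "R"}
        if drop_end[i]:
            emit.discard("F" if which_end[i] == 0 else "R")
        records = []
        for end, l in (("F", l_f), ("R", l_r)):
            if end not in emit:
                continue
            if l < spec.read_min:
                truth.n_discarded_reads += 1
                logger.info("discarding %s%s: %d nt below floor", clone_id, end, l)
                continue
            if end == "F":
                seq = source[src_start : src_start + l]
            else:
                seq = revcomp(source[src_start + ins - l : src_start + ins])
            rec = BESRecord(f"{clone_id}{end}", clone_id, end, seq)
            records.append(rec)
            truth.reads.append(ReadTruth(rec.name, clone_id, end, l, provenance))
        base_records[clone_id] = records
        beset.records.extend(records)

    # exact duplicate clones: copies of earlier clones under fresh ids
    for j in range(n_dup):
        src = truth.clones[j % n_base]
        clone_id = f"bac{n_base + j:05d}"
        truth.clones.append(
            CloneTruth(
                clone_id, src.start, src.insert_len, src.provenance,
                src.organelle_name, src.organelle_start, duplicate_of=src.clone_id,
            )
        )
        for rec in base_records[src.clone_id]:
            dup = BESRecord(f"{clone_id}{rec.end}", clone_id, rec.end, rec.sequence)
            beset.records.append(dup)
            truth.reads.append(
                ReadTruth(dup.name, clone_id, rec.end, dup.length,
                          next(r for r in truth.reads if r.name == rec.name).provenance)
            )
    return beset, truth


def _provenance(organelle_name: str) -> str:
    low = organelle_name.lower()
    if "chloro" in low or "cp" in low or "plastid" in low:
        return "chloroplast"
    if "mito" in low or "mt" in low:
        return "mitochondrial"
    return "organellar"
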