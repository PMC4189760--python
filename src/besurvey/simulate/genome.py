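"""Synthetic source-genome generation with planted, truth-labelled features.

Background sequence is i.i.d. with P(G)+P(C) = gc_fraction split evenly.
Planted features (repeat-family copies and SSR loci) never overlap.  So that
exact-recovery tests are meaningful, the background and the repeat consensi
are scrubbed of incidental SSRs: after planting, the genome is rescanned and
any locus not in the truth table is re-randomized (touching only unplanted
positions) until the detected and planted SSR sets coincide.
"""

from __future__ import annotations

import bisect
import logging

import numpy as np

from .. import ssrmine
from ..ssrmine import canonical_motif, is_primitive, scan_sequence
from .spec import CapacityError, SurveySpec, stream
from .truth import RepeatTruth, SSRTruth, TruthTable

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_base_probs(gc))


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _scrub_sequence(arr: np.ndarray, rng: np.random.Generator, gc: float,
                    max_iter: int = 50) -> np.ndarray:
    """Re-randomize until a sequence contains no detectable SSR at all."""
    for _ in range(max_iter):
        loci = scan_sequence(_decode(arr))
        if not loci:
            return arr
        for locus in loci:
            arr[locus.start : locus.end] = _random_bases(
                rng, locus.end - locus.start, gc
            )
    raise RuntimeError("SSR scrub of a synthetic sequence did not converge")


def _random_primitive_unit(rng: np.random.Generator, k: int, gc: float) -> str:
    while True:
        unit = _decode(_random_bases(rng, k, gc))
        if is_primitive(unit):
            return unit


def _apportion(total: int, proportions) -> list[int]:
    """Largest-remainder apportionment of ``total`` across proportions."""
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


class _Placer:
    """Rejection-samples non-overlapping intervals with a 1 nt flank gap."""

    def __init__(self, genome_length: int, rng: np.random.Generator):
        self.length = genome_length
        self.rng = rng
        self.starts: list[int] = []
        self.ends: list[int] = []

    def place(self, flen: int, max_tries: int = 10_000) -> int:
        if flen + 2 > self.length:
            raise CapacityError(f"feature of {flen} nt cannot fit in the genome")
        for _ in range(max_tries):
            pos = int(self.rng.integers(1, self.length - flen - 1))
            lo, hi = pos - 1, pos + flen + 1  # flank gap for run-breaking bases
            i = bisect.bisect_left(self.starts, hi)
            if i > 0 and self.ends[i - 1] > lo:
                continue
            self.starts.insert(i, lo)
            self.ends.insert(i, hi)
            return pos
        raise CapacityError(
            "could not place planted features; requested content exceeds capacity"
        )


def _plan_ssrs(spec: SurveySpec, rng: np.random.Generator) -> list[tuple[str, int]]:
    """(unit, n_units) for every locus to plant; mono n_units is in nt."""
    n_loci = round(spec.ssr_density * spec.genome_length / 100_000)
    per_class = _apportion(n_loci, spec.ssr_class_mix)
    plan: list[tuple[str, int]] = list(spec.explicit_ssrs)
    for cls_idx, count in enumerate(per_class):
        k = cls_idx + 1
        for _ in range(count):
            unit = _random_primitive_unit(rng, k, spec.gc_fraction)
            if k == 1:
                n_units = ssrmine.MIN_MONO_NT + int(rng.geometric(0.35)) - 1
            else:
                n_units = ssrmine.MIN_UNITS[k] + int(rng.geometric(0.5)) - 1
            plan.append((unit, n_units))
    return plan


def _breaking_base(rng: np.random.Generator, forbidden: str) -> int:
    choices = [b for b in b"ACGT" if chr(b) != forbidden]
    return int(rng.choice(choices))


def generate_genome(spec: SurveySpec) -> tuple[str, TruthTable]:
    """Generate the source genome and its truth table.

    Deterministic for a given spec (including its seed).  Raises
    :class:`CapacityError` when the requested planted content exceeds what
    the genome can hold.
    """
    rng_bg = stream(spec.seed, "background")
    rng_cons = stream(spec.seed, "consensi")
    rng_place = stream(spec.seed, "placement")
    rng_ssr = stream(spec.seed, "ssr")
    rng_mut = stream(spec.seed, "mutation")
    rng_scrub = stream(spec.seed, "scrub")

    length = spec.genome_length
    truth = TruthTable(genome_length=length)

    # repeat consensi, scrubbed so copies carry no incidental SSRs
    consensi: dict[str, np.ndarray] = {}
    for fam in spec.repeat_families:
        cons = _random_bases(rng_cons, fam.consensus_len, spec.gc_fraction)
        consensi[fam.name] = _scrub_sequence(cons, rng_cons, spec.gc_fraction)

    ssr_plan = _plan_ssrs(spec, rng_ssr)
    planted_repeat_nt = sum(f.consensus_len * f.copies for f in spec.repeat_families)
    planted_ssr_nt = sum(len(u) * n if len(u) > 1 else n for u, n in ssr_plan)
    n_features = sum(f.copies for f in spec.repeat_families) + len(ssr_plan)
    if planted_repeat_nt + planted_ssr_nt + 2 * n_features > 0.8 * length:
        raise CapacityError(
            f"planted content ({planted_repeat_nt + planted_ssr_nt} nt in "
            f"{n_features} features) exceeds capacity of a {length} nt genome"
        )

    genome = _random_bases(rng_bg, length, spec.gc_fraction)
    placer = _Placer(length, rng_place)

    # plant repeat copies (larger features first packs better)
    for fam in sorted(spec.repeat_families, key=lambda f: -f.consensus_len):
        for _ in range(fam.copies):
            pos = placer.place(fam.consensus_len)
            copy = consensi[fam.name].copy()
            n_mut = 0
            if spec.repeat_mutation_rate > 0:
                mask = rng_mut.random(fam.consensus_len) < spec.repeat_mutation_rate
                for i in np.flatnonzero(mask):
                    copy[i] = _breaking_base(rng_mut, chr(copy[i]))
                n_mut = int(mask.sum())
            genome[pos : pos + fam.consensus_len] = copy
            truth.repeats.append(
                RepeatTruth(pos, pos + fam.consensus_len, fam.name, fam.class_path, n_mut)
            )

    # plant SSR loci with run-breaking flanks
    for unit, n_units in ssr_plan:
        k = len(unit)
        total = n_units if k == 1 else k * n_units
        pos = placer.place(total)
        tile = (unit * (total // k + 1))[:total]
        genome[pos : pos + total] = np.frombuffer(tile.encode(), dtype=np.uint8)
        genome[pos - 1] = _breaking_base(rng_ssr, unit[-1])
        genome[pos + total] = _breaking_base(rng_ssr, unit[0])
        truth.ssrs.append(
            SSRTruth(pos, pos + total, unit, canonical_motif(unit))
        )
    truth.ssrs.sort(key=lambda s: s.start)
    truth.repeats.sort(key=lambda r: r.start)

    if spec.scrub_background_ssrs:
        _scrub_genome(genome, truth, spec, rng_scrub)

    return _decode(genome), truth


def _scrub_genome(
    genome: np.ndarray, truth: TruthTable, spec: SurveySpec, rng: np.random.Generator
) -> None:
    """Iteratively remove SSRs that arise by chance in unplanted sequence.

    Only positions outside planted intervals are modified, so planted repeat
    copies stay byte-exact.  Converges when the detected SSR set equals the
    planted one (loci falling entirely inside mutated repeat copies are
    tolerated, since mutation can legitimately create repeats there).
    """
    planted = np.zeros(spec.genome_length, dtype=bool)
    for r in truth.repeats:
        planted[r.start : r.end] = True
    for s in truth.ssrs:
        planted[s.start : s.end] = True
    truth_set = {(s.start, s.end, s.unit) for s in truth.ssrs}

    for iteration in range(60):
        detected = {
            (l.start, l.end, l.unit) for l in scan_sequence(_decode(genome))
        }
        spurious = detected - truth_set
        missing = truth_set - detected
        actionable = []
        for s, e, unit in spurious:
            free = np.flatnonzero(~planted[s:e]) + s
            if free.size:
                actionable.append((s, e, free))
            elif spec.repeat_mutation_rate == 0:
                raise RuntimeError(
                    f"incidental SSR [{s},{e}) lies entirely inside planted content"
                )
        if not actionable and not missing:
            return
        for s, e, free in actionable:
            genome[free] = _random_bases(rng, free.size, spec.gc_fraction)
        for s, e, unit in missing:
            k = len(unit)
            tile = (unit * ((e - s) // k + 1))[: e - s]
            genome[s:e] = np.frombuffer(tile.encode(), dtype=np.uint8)
            if s > 0 and not planted[s - 1]:
                genome[s - 1] = _breaking_base(rng, unit[-1])
            if e < spec.genome_length and not planted[e]:
                genome[e] = _breaking_base(rng, unit[0])
        logger.debug(
            "scrub iteration %d: %d spurious, %d missing",
            iteration, len(spurious), len(missing),
        )
    raise RuntimeError("background SSR scrub did not converge")
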