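"""Parameters of the synthetic genome/library generator.

Defaults mirror the survey statistics this toolkit is meant to reproduce at
desk scale: ~42% GC, ~10.8 SSR loci per 100 kb with the published class mix,
inserts of 50–196 kb averaging 108 kb, reads of 100–1,255 nt averaging
~587 nt, and a Class-I-dominated repeat complement with Copia:Gypsy near 1:1.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass

import numpy as np
import yaml

SSR_CLASS_ORDER = ("mono", "di", "tri", "tetra", "penta", "hexa")

#: published SSR class proportions (mono..hexa)
DEFAULT_SSR_CLASS_MIX = (0.157, 0.177, 0.125, 0.298, 0.159, 0.084)

#: target genome fraction per repeat class used by :func:`default_repeat_families`
DEFAULT_REPEAT_FRACTIONS = (
    ("copia", "ClassI/LTR/Copia", 5000, 0.0787),
    ("gypsy", "ClassI/LTR/Gypsy", 5000, 0.1018),
    ("line1", "ClassI/LINE_SINE", 3000, 0.0034),
    ("dnatransposon", "ClassII/DNA", 1500, 0.0005),
)


class ConfigError(ValueError):
    """Invalid simulator configuration."""


class CapacityError(ValueError):
    """Requested planted content does not fit in the genome."""


@dataclass(frozen=True)
class RepeatFamily:
    name: str
    class_path: str
    consensus_len: int
    copies: int


@dataclass(frozen=True)
class Rearrangement:
    """One reference edit, coordinates in source-genome space."""

    kind: str  # inversion | translocation | insertion | deletion
    position: int
    length: int
    dest: int | None = None  # translocation destination

    def __post_init__(self):
        if self.kind not in ("inversion", "translocation", "insertion", "deletion"):
            raise ConfigError(f"unknown rearrangement kind {self.kind!r}")
        if self.position < 0 or self.length <= 0:
            raise ConfigError("rearrangement position/length must be valid")
        if self.kind == "translocation" and self.dest is None:
            raise ConfigError("translocation requires a destination position")


def default_repeat_families(genome_length: int) -> tuple[RepeatFamily, ...]:
    """Copy numbers hitting the default per-class genome fractions."""
    return tuple(
        RepeatFamily(
            name=name,
            class_path=class_path,
            consensus_len=consensus_len,
            copies=max(0, round(fraction * genome_length / consensus_len)),
        )
        for name, class_path, consensus_len, fraction in DEFAULT_REPEAT_FRACTIONS
    )


@dataclass
class SurveySpec:
    genome_length: int = 1_000_000
    gc_fraction: float = 0.42
    repeat_families: tuple[RepeatFamily, ...] | None = None  # None -> defaults
    repeat_mutation_rate: float = 0.0
    ssr_density: float = 10.8  # loci per 100 kb
    ssr_class_mix: tuple[float, ...] = DEFAULT_SSR_CLASS_MIX
    explicit_ssrs: tuple[tuple[str, int], ...] = ()  # (unit, n_units) planted verbatim
    n_clones: int = 200
    insert_mean: float = 108.0  # kb
    insert_sd: float = 25.0
    insert_min: float = 50.0
    insert_max: float = 196.0
    read_length_mean: float = 587.0
    read_length_sd: float = 180.0
    read_min: int = 100
    read_max: int = 1255
    organellar_rate: float = 0.0
    unpaired_fraction: float = 0.0
    duplicate_rate: float = 0.0
    rearrangements: tuple[Rearrangement, ...] = ()
    reference_breaks: tuple[int, ...] = ()  # reference split points -> chromosomes
    scrub_background_ssrs: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0,1]")
        self.ssr_class_mix = tuple(self.ssr_class_mix)
        if len(self.ssr_class_mix) != 6:
            raise ConfigError("ssr_class_mix needs six proportions (mono..hexa)")
        if abs(sum(self.ssr_class_mix) - 1.0) > 1e-9:
            raise ConfigError("ssr_class_mix must sum to 1")
        if not self.insert_min <= self.insert_mean <= self.insert_max:
            raise ConfigError("insert sizes must satisfy min <= mean <= max")
        if min(self.insert_min, self.insert_mean) <= 0:
            raise ConfigError("insert sizes must be positive")
        if self.read_min <= 0 or self.read_max < self.read_min:
            raise ConfigError("read length bounds invalid")
        if not 0 <= self.organellar_rate <= 1:
            raise ConfigError("organellar_rate must be in [0,1]")
        if self.repeat_families is None:
            self.repeat_families = default_repeat_families(self.genome_length)
        else:
            self.repeat_families = tuple(
                RepeatFamily(**f) if isinstance(f, dict) else f
                for f in self.repeat_families
            )
        self.rearrangements = tuple(
            Rearrangement(**r) if isinstance(r, dict) else r
            for r in self.rearrangements
        )
        self.explicit_ssrs = tuple((u, int(n)) for u, n in self.explicit_ssrs)
        self.reference_breaks = tuple(sorted(self.reference_breaks))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SurveySpec":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SurveySpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def stream(seed: int, name: str) -> np.random.Generator:
    """A named, seed-derived random stream.

    Each simulator sub-step draws from its own stream so adding steps never
    perturbs earlier draws.
    """
    return np.random.default_rng([seed, zlib.crc32(name.encode("ascii"))])
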