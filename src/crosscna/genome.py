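"""Genome descriptions and chromosome ordering.

A :class:`GenomeSpec` is a minimal stand-in for a reference assembly: an
ordered list of named chromosomes with lengths in base pairs. Two presets
approximate the mouse (19 autosomes + X) and human (22 autosomes + X)
genomes at BAC-array resolution; exact assembly coordinates are irrelevant
for kernel smoothing at multi-megabase scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def chrom_sort_key(name: str) -> tuple[int, float, str]:
    """Natural chromosome ordering: 1, 2, ..., 10, ..., then X, Y, others.

    Accepts names with or without a ``chr`` prefix.
    """
    core = name[3:] if name.lower().startswith("chr") else name
    if core.isdigit():
        return (0, int(core), "")
    special = {"X": 0, "Y": 1, "M": 2, "MT": 2}
    if core.upper() in special:
        return (1, special[core.upper()], "")
    return (2, 0, core)


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes of one species.

    Parameters
    ----------
    species : str
        Free-text species label (e.g. ``"mouse"``).
    chromosomes : list of (name, length) tuples
        Chromosome lengths in base pairs, in the order plots and tables
        should use.
    """

    species: str
    chromosomes: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


# Approximate chromosome lengths (Mb), adequate for megabase-scale smoothing.
_MOUSE_MB = [197, 181, 159, 155, 152, 149, 145, 132, 124, 130,
             122, 120, 120, 125, 103, 98, 95, 90, 61]
_HUMAN_MB = [247, 243, 199, 191, 181, 171, 159, 146, 140, 135, 134, 132,
             114, 106, 100, 89, 79, 76, 64, 62, 47, 50]


def mouse_like_genome() -> GenomeSpec:
    """19 autosomes + X, ~2.6 Gb, mirroring the mouse assembly layout."""
    chroms = [(str(i + 1), mb * 1_000_000) for i, mb in enumerate(_MOUSE_MB)]
    chroms.append(("X", 165_000_000))
    return GenomeSpec("mouse", tuple(chroms))


def human_like_genome() -> GenomeSpec:
    """22 autosomes + X, ~3.1 Gb, mirroring the human assembly layout."""
    chroms = [(str(i + 1), mb * 1_000_000) for i, mb in enumerate(_HUMAN_MB)]
    chroms.append(("X", 155_000_000))
    return GenomeSpec("human", tuple(chroms))


def uniform_genome(n_chromosomes: int, chrom_length: int, species: str = "synthetic") -> GenomeSpec:
    """Equal-length chromosomes; convenient for calibration simulations."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return GenomeSpec(
        species,
        tuple((str(i + 1), int(chrom_length)) for i in range(n_chromosomes)),
    )
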