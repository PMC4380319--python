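"""Standard genetic code and single-nucleotide-mutation reachability.

Two amino acids are *reachable* from each other if some sense codon of one
differs from some sense codon of the other at exactly one nucleotide
position.  Under the standard code 150 of the 380 ordered amino-acid pairs
are reachable; the remaining substitutions require more than one mutation
in the codon and are excluded from the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard one-letter amino acids, alphabetical."""

STOP = "*"

_BASES = "TCAG"
# Standard genetic code laid out in TCAG order: codon = b1 + b2 + b3.
_STANDARD_AA = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)


class ConfigurationError(ValueError):
    """Raised when a codon table or scale set is incomplete."""


@dataclass(frozen=True)
class CodonTable:
    """Mapping from the 64 DNA triplets to amino acids (or ``*`` for stop)."""

    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ConfigurationError(
                f"codon table must have 64 entries, got {len(self.codon_to_aa)}"
            )
        coded = set(self.codon_to_aa.values()) - {STOP}
        missing = set(AMINO_ACIDS) - coded
        if missing:
            raise ConfigurationError(f"codon table lacks codons for {sorted(missing)}")

    def codons_of(self, aa: str) -> list[str]:
        """All sense codons encoding ``aa``."""
        return [c for c, a in self.codon_to_aa.items() if a == aa]

    @classmethod
    def standard(cls) -> "CodonTable":
        mapping = {}
        i = 0
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    mapping[b1 + b2 + b3] = _STANDARD_AA[i]
                    i += 1
        return cls(mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "CodonTable":
        """Read a tab-separated codon<TAB>amino-acid table (testing hook).

        U is accepted and normalised to T.
        """
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split("\t")
            mapping[codon.upper().replace("U", "T")] = aa.upper()
        return cls(mapping)


@dataclass(frozen=True)
class ReachabilityMatrix:
    """20x20 boolean matrix over ``AMINO_ACIDS`` order; diagonal stored False."""

    reachable: np.ndarray = field(repr=False)

    def __getitem__(self, pair: tuple[str, str]) -> bool:
        ref, mut = pair
        return bool(self.reachable[_aa_index(ref), _aa_index(mut)])

    @property
    def n_reachable_ordered(self) -> int:
        return int(self.reachable.sum())


def _aa_index(aa: str) -> int:
    i = AMINO_ACIDS.find(aa)
    if i < 0:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    return i


def build_reachability(table: CodonTable | None = None) -> ReachabilityMatrix:
    """Compute amino-acid reachability under single codon point mutations.

    Stop codons are excluded on both sides: a path through a stop is never
    counted.  The result is symmetric with a False diagonal.
    """
    table = table or CodonTable.standard()
    mat = np.zeros((20, 20), dtype=bool)
    sense = [(c, a) for c, a in table.codon_to_aa.items() if a != STOP]
    for c1, a1 in sense:
        for c2, a2 in sense:
            if a1 == a2:
                continue
            if sum(x != y for x, y in zip(c1, c2)) == 1:
                mat[_aa_index(a1), _aa_index(a2)] = True
    return ReachabilityMatrix(mat)


_STANDARD_REACHABILITY: ReachabilityMatrix | None = None


def standard_reachability() -> ReachabilityMatrix:
    """Cached reachability matrix for the standard code."""
    global _STANDARD_REACHABILITY
    if _STANDARD_REACHABILITY is None:
        _STANDARD_REACHABILITY = build_reachability()
    return _STANDARD_REACHABILITY


def unreachable_mutants(ref_aa: str, reach: ReachabilityMatrix | None = None) -> set[str]:
    """Amino acids that cannot be reached from ``ref_aa`` by one codon mutation.

    E.g. from serine no single point mutation yields D, E, H, K, M, Q or V.
    """
    reach = reach or standard_reachability()
    i = _aa_index(ref_aa)
    return {aa for j, aa in enumerate(AMINO_ACIDS) if j != i and not reach.reachable[i, j]}


def reachable_mutants(ref_aa: str, reach: ReachabilityMatrix | None = None) -> set[str]:
    """Amino acids reachable from ``ref_aa`` by a single codon mutation."""
    reach = reach or standard_reachability()
    i = _aa_index(ref_aa)
    return {aa for j, aa in enumerate(AMINO_ACIDS) if reach.reachable[i, j]}
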