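"""Registry of genetic codes and their fourfold-degenerate codon groups.

The registry holds the 24 NCBI translation tables whose fourfold-degenerate
(4FD) groups for Ala, Gly, Pro, Thr and Val coincide with the standard code's
(the standard code plus 23 alternatives). It is shipped as a tab-separated
data file (one row per ``code_id, codon, meaning``) so that further codes can
be added without touching logic. Tables in which NCBI marks a codon as both
sense and stop (tables 27, 28 and 31, whose TAA/TAG/TGA read through in some
contexts) are registered with the sense meaning; as a consequence those three
codes have no stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Mapping

from .codons import AA_INDEX, CODONS, NUCLEOTIDES, STOP, STOP_INDEX

__all__ = [
    "GeneticCode",
    "FourfoldGroup",
    "UnknownCodeError",
    "RegistryIntegrityError",
    "get_code",
    "registered_ids",
    "fourfold_groups",
    "FOURFOLD_PREFIXES",
]

#: 4FD group definitions shared by every registered code: amino acid -> first
#: two codon positions. Order is fixed (alphabetical by amino acid) and is the
#: documented order of :func:`fourfold_groups`.
FOURFOLD_PREFIXES: Mapping[str, str] = MappingProxyType(
    {"Ala": "GC", "Gly": "GG", "Pro": "CC", "Thr": "AC", "Val": "GT"}
)


class UnknownCodeError(KeyError):
    """Requested translation-table id is not in the registry."""


class RegistryIntegrityError(ValueError):
    """A registry record violates a structural invariant."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon assignment to 20 amino acids or stop.

    Attributes
    ----------
    id : int
        NCBI translation-table number.
    name : str
        NCBI table name.
    assignment : mapping of codon -> meaning
        Meaning is a 3-letter amino-acid code or ``"Stop"``; exactly 64 codons.
    """

    id: int
    name: str
    assignment: Mapping[str, str]
    aa_codes: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.assignment) != set(CODONS):
            raise RegistryIntegrityError(
                f"code {self.id}: assignment must cover exactly the 64 codons"
            )
        codes = []
        for c in CODONS:
            m = self.assignment[c]
            if m == STOP:
                codes.append(STOP_INDEX)
            elif m in AA_INDEX:
                codes.append(AA_INDEX[m])
            else:
                raise RegistryIntegrityError(
                    f"code {self.id}: unknown meaning {m!r} for codon {c}"
                )
        object.__setattr__(self, "aa_codes", tuple(codes))
        object.__setattr__(self, "assignment", MappingProxyType(dict(self.assignment)))
        for aa, prefix in FOURFOLD_PREFIXES.items():
            meanings = {self.assignment[prefix + n] for n in NUCLEOTIDES}
            if meanings != {aa}:
                raise RegistryIntegrityError(
                    f"code {self.id}: {prefix}N is not a single-{aa} group "
                    f"(got {sorted(meanings)})"
                )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.assignment[c] == STOP)

    @property
    def stop_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(CODONS) if self.assignment[c] == STOP)

    @property
    def sense_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(CODONS) if self.assignment[c] != STOP)

    def translate(self, codon: str) -> str:
        return self.assignment[codon.upper().replace("U", "T")]


@dataclass(frozen=True)
class FourfoldGroup:
    """One 4FD codon group: four codons sharing a prefix and an amino acid."""

    amino_acid: str
    prefix: str
    members: Mapping[str, str]  # third-position nucleotide -> codon

    def __post_init__(self) -> None:
        if set(self.members) != set(NUCLEOTIDES):
            raise RegistryIntegrityError(
                f"group {self.amino_acid}: need one member per nucleotide"
            )
        for n, codon in self.members.items():
            if codon != self.prefix + n:
                raise RegistryIntegrityError(
                    f"group {self.amino_acid}: member {codon} does not match "
                    f"prefix {self.prefix} + {n}"
                )
        object.__setattr__(self, "members", MappingProxyType(dict(self.members)))

    @property
    def codons(self) -> tuple[str, ...]:
        """Members in fixed A, C, G, T third-position order."""
        return tuple(self.members[n] for n in NUCLEOTIDES)


def _load_registry() -> dict[int, GeneticCode]:
    data = resources.files("fourfold.data")
    names: dict[int, str] = {}
    with (data / "code_names.tsv").open() as fh:
        next(fh)
        for line in fh:
            cid, name = line.rstrip("\n").split("\t")
            names[int(cid)] = name
    table: dict[int, dict[str, str]] = {}
    with (data / "genetic_codes.tsv").open() as fh:
        next(fh)
        for line in fh:
            cid, codon, meaning = line.rstrip("\n").split("\t")
            table.setdefault(int(cid), {})[codon] = meaning
    return {
        cid: GeneticCode(id=cid, name=names.get(cid, f"table {cid}"), assignment=assign)
        for cid, assign in table.items()
    }


_REGISTRY: dict[int, GeneticCode] | None = None


def _registry() -> dict[int, GeneticCode]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def registered_ids() -> tuple[int, ...]:
    """Translation-table ids in the registry, ascending."""
    return tuple(sorted(_registry()))


def get_code(code_id: int) -> GeneticCode:
    """Return the registered genetic code for an NCBI translation-table id.

    Raises
    ------
    UnknownCodeError
        If the id is not one of the 24 registered tables.
    """
    try:
        return _registry()[code_id]
    except KeyError:
        raise UnknownCodeError(
            f"translation table {code_id} is not registered "
            f"(known ids: {', '.join(map(str, registered_ids()))})"
        ) from None


def fourfold_groups(code: GeneticCode) -> list[FourfoldGroup]:
    """The five 4FD groups (Ala, Gly, Pro, Thr, Val) under ``code``.

    The groups are identical for every registered code; the integrity of the
    single-amino-acid property is still checked so that hand-edited registries
    fail loudly.
    """
    groups = []
    for aa, prefix in FOURFOLD_PREFIXES.items():
        members = {n: prefix + n for n in NUCLEOTIDES}
        for n, codon in members.items():
            if code.assignment[codon] != aa:
                raise RegistryIntegrityError(
                    f"code {code.id}: codon {codon} encodes "
                    f"{code.assignment[codon]}, expected {aa}"
                )
        groups.append(FourfoldGroup(amino_acid=aa, prefix=prefix, members=members))
    return groups
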