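"""Star-allele diplotype notation.

A diplotype is two haplotype slots. Each slot is one or more gene copies:
a single allele with a multiplicity (``*10X2`` = a *10 duplication) or a
tandem chain of different alleles on one chromosome (``*10-*36``). When both
slots carry the same multi-allele tandem, the whole diplotype is written as
the duplicated group, ``(*10/*36)X2``. A multiplicity beyond three, i.e. an
unresolved high copy count, is written with the literal ``XN``.

The grammar covers the full vocabulary used in clinical CYP2D6 reporting:
``*a/*b``, ``*aX2/*b``, ``*aX2/*bX3``, ``*aX2/*bXN``, ``(*a/*b)X2`` and
falls back to ``*a-*b`` chains for tandems that are not a symmetric
duplication. ``parse_diplotype(render_diplotype(d)) == d`` for every
well-formed diplotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterator

__all__ = [
    "HaplotypeCall",
    "Diplotype",
    "parse_diplotype",
    "render_diplotype",
    "allele_sort_key",
    "DiplotypeError",
]


class DiplotypeError(ValueError):
    """Raised for malformed diplotype notation."""


# star-allele names are digits plus an optional letter suffix (*2A); the
# letter must be optional-single so the X of a multiplicity suffix parses
_ALLELE = r"\*\d+[A-W]?"
_ALLELE_RE = re.compile(r"^\*(\d+)([A-W]?)$")
_SLOT_RE = re.compile(rf"^({_ALLELE}(?:-{_ALLELE})*)(?:X(\d+|N))?$")
_GROUP_RE = re.compile(rf"^\(({_ALLELE}(?:/{_ALLELE})+)\)X(\d+|N)$")


def allele_sort_key(name: str) -> tuple[int, str]:
    """Numeric-then-suffix ordering: *1 < *2 < *2A < *10 < *36 < *41."""
    m = _ALLELE_RE.match(name)
    if not m:
        raise DiplotypeError(f"malformed star-allele name: {name!r}")
    return int(m.group(1)), m.group(2)


def _mult_suffix(mult: int | None) -> str:
    if mult is None:
        return "XN"
    if mult == 1:
        return ""
    return f"X{mult}"


@total_ordering
@dataclass(frozen=True)
class HaplotypeCall:
    """One haplotype slot: a chain of alleles sharing one multiplicity.

    ``multiplicity`` is a positive integer, or ``None`` for the symbolic
    "N" of an unresolved high copy count.
    """

    alleles: tuple[str, ...]
    multiplicity: int | None = 1

    def __post_init__(self) -> None:
        if not self.alleles:
            raise DiplotypeError("haplotype slot needs at least one allele")
        if self.multiplicity is not None and self.multiplicity < 1:
            raise DiplotypeError("multiplicity must be >= 1")
        for a in self.alleles:
            allele_sort_key(a)  # validates

    @property
    def sort_key(self) -> tuple:
        mult = self.multiplicity if self.multiplicity is not None else 10**6
        return tuple(allele_sort_key(a) for a in self.alleles), mult

    def __lt__(self, other: "HaplotypeCall") -> bool:
        return self.sort_key < other.sort_key

    def copies(self, n_for_unresolved: int = 4) -> list[str]:
        mult = self.multiplicity if self.multiplicity is not None else n_for_unresolved
        return list(self.alleles) * mult

    def render(self) -> str:
        return "-".join(self.alleles) + _mult_suffix(self.multiplicity)


@dataclass(frozen=True)
class Diplotype:
    """Two haplotype slots; slots are stored in canonical (sorted) order."""

    gene: str
    slots: tuple[HaplotypeCall, HaplotypeCall]

    def __post_init__(self) -> None:
        a, b = self.slots
        if b < a:
            object.__setattr__(self, "slots", (b, a))

    @classmethod
    def of(cls, gene: str, a: HaplotypeCall | str, b: HaplotypeCall | str) -> "Diplotype":
        def coerce(s):
            return HaplotypeCall((s,)) if isinstance(s, str) else s

        return cls(gene, (coerce(a), coerce(b)))

    def copies(self, n_for_unresolved: int = 4) -> list[str]:
        """All gene copies carried, in slot order."""
        return [
            c for slot in self.slots for c in slot.copies(n_for_unresolved)
        ]

    def alleles(self) -> set[str]:
        return {a for slot in self.slots for a in slot.alleles}

    def render(self) -> str:
        return render_diplotype(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def render_diplotype(d: Diplotype) -> str:
    a, b = d.slots
    if a == b and len(a.alleles) > 1 and a.multiplicity == 1:
        return "(" + "/".join(a.alleles) + ")X2"
    return a.render() + "/" + b.render()


def _parse_mult(text: str | None) -> int | None:
    if text is None:
        return 1
    if text == "N":
        return None
    mult = int(text)
    if mult < 1:
        raise DiplotypeError(f"multiplicity must be >= 1, got {mult}")
    return mult


def _parse_slot(text: str) -> HaplotypeCall:
    m = _SLOT_RE.match(text)
    if not m:
        raise DiplotypeError(f"malformed haplotype slot: {text!r}")
    return HaplotypeCall(tuple(m.group(1).split("-")), _parse_mult(m.group(2)))


def parse_diplotype(text: str, gene: str = "CYP2D6") -> Diplotype:
    """Parse diplotype notation; inverse of :func:`render_diplotype`."""
    text = text.strip()
    g = _GROUP_RE.match(text)
    if g:
        mult = _parse_mult(g.group(2))
        if mult != 2:
            raise DiplotypeError(
                f"tandem-group notation supports X2 only: {text!r}"
            )
        slot = HaplotypeCall(tuple(g.group(1).split("/")), 1)
        return Diplotype(gene, (slot, slot))
    if text.count("/") != 1:
        raise DiplotypeError(f"malformed diplotype: {text!r}")
    left, right = text.split("/")
    return Diplotype(gene, (_parse_slot(left), _parse_slot(right)))


def iter_vocabulary_diplotypes(
    alleles: list[str], max_mult: int = 3
) -> Iterator[Diplotype]:  # pragma: no cover - test helper
    """Enumerate single-allele-slot diplotypes over an allele set."""
    from itertools import combinations_with_replacement, product

    for (a, b), (ma, mb) in product(
        combinations_with_replacement(sorted(alleles, key=allele_sort_key), 2),
        product(range(1, max_mult + 1), repeat=2),
    ):
        yield Diplotype(
            "CYP2D6", (HaplotypeCall((a,), ma), HaplotypeCall((b,), mb))
        )
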