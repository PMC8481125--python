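"""Parsing and structural annotation of EGFR protein-level mutations.

Mutations are given in the compact protein notation used in the NSCLC
literature (``L858R``, ``E746_A750del``, ``A763insFQEA``,
``L747_K754delinsATSPE``), with residue numbers in UniProt P00533
coordinates.  Compound alleles join tokens with ``+``, ``/`` or ``;``.

The kinase domain spans residues 688-875 (exons 18-21).  A
:class:`RegionMap` carries the structural intervals used by the
classifier: the P-loop (L718-V726), the alphaC-helix and the loop at its
C-terminal end (A767-G779), the exon-20 insertion span (A767-V774) with
its near/far subdivision, the hinge, and the hydrophobic core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VariantKind",
    "ProteinVariant",
    "Allele",
    "RegionMap",
    "MutationParseError",
    "ReferenceMismatchError",
    "parse_mutation",
    "parse_allele",
    "format_variant",
    "exon_of",
    "annotate_regions",
    "KINASE_DOMAIN",
    "KNOWN_RESIDUES",
]

#: Inclusive residue span of the EGFR tyrosine-kinase domain.
KINASE_DOMAIN = (688, 875)

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
#: ``X`` is accepted as an alternate residue wildcard (e.g. "G719X").
ALT_LETTERS = AA_LETTERS | {"X"}

#: Partial canonical-residue table (P00533 positions named in the EGFR
#: TKI-resistance literature).  Used only when reference validation is
#: requested; a full sequence mapping may be supplied instead.
KNOWN_RESIDUES: Mapping[int, str] = {
    709: "E", 718: "L", 719: "G", 724: "G", 726: "V", 746: "E", 747: "L",
    750: "A", 751: "T", 752: "S", 753: "P", 754: "K", 755: "A", 758: "D",
    761: "D", 762: "E", 763: "A", 764: "Y", 765: "V", 766: "M", 767: "A",
    768: "S", 769: "V", 770: "D", 771: "N", 772: "P", 773: "H", 774: "V",
    775: "C", 779: "G", 790: "T", 792: "L", 793: "M", 796: "G", 797: "C",
    823: "D", 854: "T", 858: "L", 861: "L",
}


class MutationParseError(ValueError):
    """Raised when a mutation token cannot be parsed."""

    def __init__(self, token: str, reason: str = "malformed mutation token"):
        self.token = token
        super().__init__(f"{reason}: {token!r}")


class ReferenceMismatchError(ValueError):
    """Raised when a stated reference residue conflicts with the canonical sequence."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"


@dataclass(frozen=True)
class ProteinVariant:
    """A single protein-level change.

    ``start``/``end`` are 1-based inclusive residue positions; for an
    insertion the variant is anchored to the residue it follows
    (``start == end``).  ``ref_aa`` holds the stated flanking residues
    ("L" for L858R, "EA" for E746_A750del); ``alt_seq`` the inserted or
    substituted residues (empty for a pure deletion).
    """

    kind: VariantKind
    start: int
    end: int
    ref_aa: str
    alt_seq: str
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MutationParseError(self.raw or repr(self), "start > end")
        if self.kind is VariantKind.SUBSTITUTION:
            if len(self.alt_seq) != 1:
                raise MutationParseError(self.raw, "substitution needs one alternate residue")
            if self.alt_seq == self.ref_aa:
                raise MutationParseError(self.raw, "synonymous substitution")
        if self.kind in (VariantKind.INSERTION, VariantKind.DUPLICATION) and not self.alt_seq:
            raise MutationParseError(self.raw, "insertion/duplication needs an inserted sequence")

    @property
    def in_kinase_domain(self) -> bool:
        lo, hi = KINASE_DOMAIN
        return lo <= self.start and self.end <= hi

    @property
    def anchor(self) -> int:
        """Residue an insertion-like change hangs off (end residue for a dup)."""
        if self.kind is VariantKind.DUPLICATION:
            return self.end
        return self.start

    def as_insertion(self) -> "ProteinVariant":
        """Insertion equivalent of a duplication (A767_V769dupASV == V769insASV)."""
        if self.kind is not VariantKind.DUPLICATION:
            return self
        return ProteinVariant(
            kind=VariantKind.INSERTION,
            start=self.end,
            end=self.end,
            ref_aa=self.ref_aa[-1],
            alt_seq=self.alt_seq,
            raw=self.raw,
        )

    def __str__(self) -> str:
        return format_variant(self)


@dataclass(frozen=True)
class Allele:
    """An ordered, de-duplicated set of co-occurring variants.

    Co-occurring order is arbitrary and preserved as given.
    """

    variants: tuple[ProteinVariant, ...]
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.variants:
            raise MutationParseError(self.raw, "empty allele")

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __str__(self) -> str:
        return "+".join(format_variant(v) for v in self.variants)


# ---------------------------------------------------------------------------
# Parsing

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RE = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DEL$")
_DELINS_RE = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DELINS([A-Z]+)$")
_INS_RE = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?INS([A-Z]+)$")
_DUP_RE = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DUP([A-Z]*)$")


def _normalize(text: str) -> str:
    token = text.strip()
    if token.lower().startswith("p."):
        token = token[2:]
    # "del-ins" (paper style) -> "delins"; then "-" doubles as a range separator
    token = re.sub(r"del\s*-\s*ins", "delins", token, flags=re.IGNORECASE)
    token = token.replace("-", "_").replace(" ", "")
    return token.upper()


def _check_aa(letter: str, token: str, alt: bool = False) -> None:
    ok = ALT_LETTERS if alt else AA_LETTERS
    if letter not in ok:
        raise MutationParseError(token, f"invalid amino-acid letter {letter!r}")


def _check_ref(pos: int, aa: str, reference: Optional[Mapping[int, str]], token: str) -> None:
    if reference is None:
        return
    expected = reference.get(pos)
    if expected is not None and expected != aa:
        raise ReferenceMismatchError(
            f"{token!r}: residue {pos} is {expected} in the canonical sequence, not {aa}"
        )


def parse_mutation(
    text: str,
    *,
    validate_reference: bool = False,
    reference: Optional[Mapping[int, str]] = None,
) -> ProteinVariant:
    """Parse one protein-mutation token into a :class:`ProteinVariant`.

    Keywords (del/ins/dup/delins) are case-insensitive; ``-`` and ``_``
    are both accepted as range separators; an optional ``p.`` prefix is
    stripped.  With ``validate_reference=True`` stated reference
    residues are checked against ``reference`` (default: the partial
    :data:`KNOWN_RESIDUES` table).

    Raises
    ------
    MutationParseError
        for a malformed token (names the offending substring).
    ReferenceMismatchError
        when validation is on and a stated residue conflicts.
    """
    if not text or not text.strip():
        raise MutationParseError(text, "empty mutation token")
    token = _normalize(text)
    ref_table = (reference or KNOWN_RESIDUES) if validate_reference else None

    m = _DELINS_RE.match(token)
    if m:
        a1, p1, a2, p2, alt = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        ref = a1 + (a2 or "")
        for ch in ref:
            _check_aa(ch, text)
        for ch in alt:
            _check_aa(ch, text, alt=True)
        _check_ref(start, a1, ref_table, text)
        if a2:
            _check_ref(end, a2, ref_table, text)
        return ProteinVariant(VariantKind.DELINS, start, end, ref, alt, raw=text)

    m = _DEL_RE.match(token)
    if m:
        a1, p1, a2, p2 = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        ref = a1 + (a2 or "")
        for ch in ref:
            _check_aa(ch, text)
        _check_ref(start, a1, ref_table, text)
        if a2:
            _check_ref(end, a2, ref_table, text)
        return ProteinVariant(VariantKind.DELETION, start, end, ref, "", raw=text)

    m = _INS_RE.match(token)
    if m:
        a1, p1, a2, p2, alt = m.groups()
        # HGVS-flavoured two-residue anchors (A767_S768insASV) are accepted;
        # the insertion is anchored to the first residue.
        start = int(p1)
        for ch in a1 + (a2 or ""):
            _check_aa(ch, text)
        for ch in alt:
            _check_aa(ch, text, alt=True)
        _check_ref(start, a1, ref_table, text)
        return ProteinVariant(VariantKind.INSERTION, start, start, a1, alt, raw=text)

    m = _DUP_RE.match(token)
    if m:
        a1, p1, a2, p2, alt = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        ref = a1 + (a2 or "")
        for ch in ref:
            _check_aa(ch, text)
        _check_ref(start, a1, ref_table, text)
        if a2:
            _check_ref(end, a2, ref_table, text)
        if not alt:
            if start == end:
                alt = a1
            else:
                raise MutationParseError(
                    text, "multi-residue duplication needs its duplicated sequence spelled out"
                )
        for ch in alt:
            _check_aa(ch, text, alt=True)
        return ProteinVariant(VariantKind.DUPLICATION, start, end, ref, alt, raw=text)

    m = _SUB_RE.match(token)
    if m:
        a1, p1, a2 = m.groups()
        _check_aa(a1, text)
        _check_aa(a2, text, alt=True)
        pos = int(p1)
        _check_ref(pos, a1, ref_table, text)
        return ProteinVariant(VariantKind.SUBSTITUTION, pos, pos, a1, a2, raw=text)

    raise MutationParseError(text)


_ALLELE_SPLIT_RE = re.compile(r"[+/;]")


def parse_allele(text: str, **kwargs) -> Allele:
    """Parse a compound allele string; tokens separated by ``+``, ``/`` or ``;``.

    Duplicate variants are removed; given order is preserved.  A parse
    failure on any token is re-raised naming the token index.
    """
    if not text or not text.strip():
        raise MutationParseError(text, "empty allele string")
    tokens = [t for t in _ALLELE_SPLIT_RE.split(text) if t.strip()]
    if not tokens:
        raise MutationParseError(text, "empty allele string")
    variants: list[ProteinVariant] = []
    for i, tok in enumerate(tokens):
        try:
            v = parse_mutation(tok, **kwargs)
        except MutationParseError as exc:
            raise MutationParseError(tok, f"token {i} of allele {text!r} failed") from exc
        if v not in variants:
            variants.append(v)
    return Allele(tuple(variants), raw=text)


def format_variant(v: ProteinVariant) -> str:
    """Canonical compact string for a variant (inverse of :func:`parse_mutation`)."""
    r1 = v.ref_aa[0]
    r2 = v.ref_aa[-1]
    if v.kind is VariantKind.SUBSTITUTION:
        return f"{r1}{v.start}{v.alt_seq}"
    if v.kind is VariantKind.INSERTION:
        return f"{r1}{v.start}ins{v.alt_seq}"
    span = f"{r1}{v.start}" if v.start == v.end else f"{r1}{v.start}_{r2}{v.end}"
    if v.kind is VariantKind.DELETION:
        return f"{span}del"
    if v.kind is VariantKind.DELINS:
        return f"{span}delins{v.alt_seq}"
    if v.kind is VariantKind.DUPLICATION:
        return f"{span}dup{v.alt_seq}"
    raise ValueError(f"unknown kind {v.kind}")


# ---------------------------------------------------------------------------
# Regions

Interval = tuple[int, int]


@dataclass(frozen=True)
class RegionMap:
    """Named residue intervals of the kinase domain (1-based, inclusive).

    The exon boundaries follow the canonical EGFR transcript convention;
    the P-loop and alphaC C-terminal loop intervals are the published
    hotspot spans.  ``near_loop``/``far_loop`` split the exon-20
    insertion span at D770/N771.  Everything is overridable.
    """

    exon18: Interval = (688, 728)
    exon19: Interval = (729, 761)
    exon20: Interval = (762, 823)
    exon21: Interval = (824, 875)
    p_loop: Interval = (718, 726)
    alpha_c_helix: Interval = (756, 766)
    alpha_c_loop: Interval = (767, 779)
    ex20_loop_span: Interval = (767, 774)
    near_loop: Interval = (767, 770)
    far_loop: Interval = (771, 774)
    hinge: Interval = (792, 797)
    hydrophobic_core: frozenset[int] = frozenset({790})

    def __post_init__(self) -> None:
        n0, n1 = self.near_loop
        f0, f1 = self.far_loop
        s0, s1 = self.ex20_loop_span
        if not (n0 == s0 and f1 == s1 and f0 == n1 + 1):
            raise ValueError("near_loop and far_loop must tile ex20_loop_span disjointly")

    @property
    def exons(self) -> dict[int, Interval]:
        return {18: self.exon18, 19: self.exon19, 20: self.exon20, 21: self.exon21}

    def to_dict(self) -> dict:
        d = {
            name: list(getattr(self, name))
            for name in (
                "exon18", "exon19", "exon20", "exon21", "p_loop", "alpha_c_helix",
                "alpha_c_loop", "ex20_loop_span", "near_loop", "far_loop", "hinge",
            )
        }
        d["hydrophobic_core"] = sorted(self.hydrophobic_core)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionMap":
        kwargs: dict = {}
        for key, value in d.items():
            if key == "hydrophobic_core":
                kwargs[key] = frozenset(int(x) for x in value)
            else:
                lo, hi = value
                kwargs[key] = (int(lo), int(hi))
        return cls(**kwargs)

    def replace(self, **kwargs) -> "RegionMap":
        return replace(self, **kwargs)


DEFAULT_REGION_MAP = RegionMap()


def exon_of(position: int, region_map: RegionMap = DEFAULT_REGION_MAP) -> Optional[int]:
    """Exon (18-21) containing a residue, or ``None`` outside the kinase domain."""
    if position <= 0:
        raise ValueError("residue positions are positive integers")
    for exon, (lo, hi) in region_map.exons.items():
        if lo <= position <= hi:
            return exon
    return None


def _overlaps(lo: int, hi: int, interval: Interval) -> bool:
    return lo <= interval[1] and hi >= interval[0]


def annotate_regions(
    v: ProteinVariant, region_map: RegionMap = DEFAULT_REGION_MAP
) -> frozenset[str]:
    """Region tags whose interval intersects the variant.

    Substitutions/deletions/delins use their full span; insertions and
    duplications use the single anchor residue (the residue the inserted
    sequence follows).  Near/far-loop tags apply to insertion-like
    variants only, so at most one of the two can fire.
    """
    if v.kind in (VariantKind.INSERTION, VariantKind.DUPLICATION):
        lo = hi = v.as_insertion().anchor
        insertion_like = True
    else:
        lo, hi = v.start, v.end
        insertion_like = False

    tags: set[str] = set()
    for exon, interval in region_map.exons.items():
        if _overlaps(lo, hi, interval):
            tags.add(f"exon{exon}")
    for name in ("p_loop", "alpha_c_helix", "alpha_c_loop", "ex20_loop_span", "hinge"):
        if _overlaps(lo, hi, getattr(region_map, name)):
            tags.add(name)
    if insertion_like:
        if _overlaps(lo, hi, region_map.near_loop):
            tags.add("near_loop")
        elif _overlaps(lo, hi, region_map.far_loop):
            tags.add("far_loop")
    if any(lo <= pos <= hi for pos in region_map.hydrophobic_core):
        tags.add("hydrophobic_core")
    return frozenset(tags)


def variant_exons(v: ProteinVariant, region_map: RegionMap = DEFAULT_REGION_MAP) -> tuple[int, ...]:
    """Exons a variant touches (an indel spanning a boundary may touch two)."""
    tags = annotate_regions(v, region_map)
    return tuple(sorted(int(t[4:]) for t in tags if t.startswith("exon")))
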