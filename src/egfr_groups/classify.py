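"""Structure-function classification of EGFR kinase-domain mutations.

Variants and alleles are assigned to one of four structure-function
groups of atypical mutations -- classical-like (distant from the
ATP-binding pocket), T790M-like (hydrophobic core), Ex20ins-L
(insertions in the loop C-terminal to the alphaC-helix) and PACC
(P-loop/alphaC-helix compressing) -- alongside the classical
L858R/Ex19del/T790M category.  T790M-like alleles split into
third-generation-TKI-sensitive (3S) and -resistant (3R, carrying
C797X/L718X/L792X) subgroups; Ex20ins-L into near-loop (NL) and
far-loop (FL) insertions.

The rule engine is an ordered first-match-wins table: curated
name-level exceptions first, then positional rules over the
:class:`~egfr_groups.variants.RegionMap`.  Every assignment carries a
``rule_trace`` naming the rules that fired, so no variant is ever
labelled silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .variants import (
    Allele,
    ProteinVariant,
    RegionMap,
    VariantKind,
    DEFAULT_REGION_MAP,
    annotate_regions,
    exon_of,
    format_variant,
    variant_exons,
)

__all__ = [
    "Group",
    "Subgroup",
    "Bucket",
    "RuleTable",
    "VariantAssignment",
    "GroupAssignment",
    "default_rule_table",
    "is_classical_variant",
    "is_classical",
    "classify_variant",
    "classify_allele",
    "bucket_patient",
    "tabulate_cohort",
    "CohortTabulation",
]


class Group:
    CLASSICAL = "classical"
    CLASSICAL_LIKE = "classical-like"
    T790M_LIKE = "T790M-like"
    EX20INS_L = "Ex20ins-L"
    PACC = "PACC"
    UNCLASSIFIED = "unclassified"

    ATYPICAL = (CLASSICAL_LIKE, T790M_LIKE, EX20INS_L, PACC)
    ALL = (CLASSICAL,) + ATYPICAL + (UNCLASSIFIED,)


class Subgroup:
    S3 = "3S"
    R3 = "3R"
    NL = "NL"
    FL = "FL"


class Bucket:
    CLASSICAL = "classical"
    EX20INS = "Ex20ins"
    ATYPICAL = "atypical"
    COMPLEX_ATYPICAL = "complex-with-atypical"
    CLASSICAL_T790M_ATYPICAL = "classical+T790M+atypical"

    ALL = (CLASSICAL, EX20INS, ATYPICAL, COMPLEX_ATYPICAL, CLASSICAL_T790M_ATYPICAL)


# --------------------------------------------------------------------------
# Rule table


@dataclass(frozen=True)
class NameRule:
    """Positional name pattern: reference residue + position, optionally a
    specific alternate residue, restricted to one variant kind."""

    rule_id: str
    ref_aa: str
    position: int
    group: str
    alt: Optional[str] = None
    kind: VariantKind = VariantKind.SUBSTITUTION
    subgroup: Optional[str] = None

    def matches(self, v: ProteinVariant) -> bool:
        if v.kind is not self.kind:
            return False
        if not (v.start == self.position == v.end):
            return False
        if v.ref_aa != self.ref_aa:
            return False
        if self.alt is not None and v.alt_seq != self.alt:
            return False
        return True


@dataclass(frozen=True)
class RuleTable:
    """Ordered classification rules; first match wins.

    ``curated_exceptions`` map a normalised mutation name straight to a
    (group, subgroup) pair and are checked before everything else.
    ``name_rules`` are curated residue-level patterns (e.g. any G719
    substitution is PACC); positional region rules run last.
    """

    curated_exceptions: tuple[tuple[str, str, Optional[str]], ...] = ()
    name_rules: tuple[NameRule, ...] = ()

    def lookup_exception(self, v: ProteinVariant) -> Optional[tuple[str, str, Optional[str]]]:
        key = format_variant(v).upper()
        for name, group, sub in self.curated_exceptions:
            if name.upper() == key:
                return name, group, sub
        return None

    def lookup_name_rule(self, v: ProteinVariant) -> Optional[NameRule]:
        for rule in self.name_rules:
            if rule.matches(v):
                return rule
        return None


def default_rule_table() -> RuleTable:
    """Rule table seeded from the worked examples in the source study."""
    pacc_any = [  # any substitution at these residues
        ("E", 709), ("L", 718), ("G", 719), ("L", 747), ("L", 792),
    ]
    pacc_exact = [  # specific named substitutions
        ("V", 765, "L"), ("S", 768, "I"), ("G", 796, "S"), ("C", 797, "S"),
        ("T", 854, "I"),
    ]
    name_rules = [
        NameRule(f"curated:{r}{p}X->PACC", r, p, Group.PACC) for r, p in pacc_any
    ] + [
        NameRule(f"curated:{r}{p}{a}->PACC", r, p, Group.PACC, alt=a)
        for r, p, a in pacc_exact
    ]
    return RuleTable(
        curated_exceptions=(
            ("L747_K754delinsATSPE", Group.T790M_LIKE, None),
        ),
        name_rules=tuple(name_rules),
    )


DEFAULT_RULE_TABLE = default_rule_table()


# --------------------------------------------------------------------------
# Classical definition


def is_classical_variant(v: ProteinVariant) -> bool:
    """L858R, T790M, or an exon-19 deletion/delins starting at E746/L747
    and ending at or before A755."""
    if v.kind is VariantKind.SUBSTITUTION:
        if v.start == 858 and v.ref_aa == "L" and v.alt_seq == "R":
            return True
        if v.start == 790 and v.ref_aa == "T" and v.alt_seq == "M":
            return True
        return False
    if v.kind in (VariantKind.DELETION, VariantKind.DELINS):
        return v.start in (746, 747) and v.end <= 755
    return False


def is_classical(allele: Allele) -> bool:
    """True iff every variant in the allele is classical."""
    return all(is_classical_variant(v) for v in allele)


# --------------------------------------------------------------------------
# Variant-level classification


@dataclass(frozen=True)
class VariantAssignment:
    variant: ProteinVariant
    group: str
    subgroup: Optional[str]
    rule_trace: tuple[str, ...]
    regions: frozenset[str] = frozenset()

    @property
    def is_classical(self) -> bool:
        return self.group == Group.CLASSICAL


def classify_variant(
    v: ProteinVariant,
    rule_table: RuleTable = DEFAULT_RULE_TABLE,
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> VariantAssignment:
    """Assign a single variant to its structure-function group.

    Order of evaluation: curated whole-name exceptions, the classical
    definition, curated residue patterns, then positional rules
    (hydrophobic core -> T790M-like; alphaC-helix insertions ->
    classical-like; exon-20 loop-span insertions -> Ex20ins-L with NL/FL
    subgroup; P-loop/hinge/alphaC-loop point changes -> PACC; other
    kinase-domain changes -> classical-like by the distant-from-pocket
    rule).  Anything outside the kinase domain is ``unclassified``.
    """
    tags = annotate_regions(v, region_map)

    exc = rule_table.lookup_exception(v)
    if exc is not None:
        name, group, sub = exc
        return VariantAssignment(v, group, sub, (f"curated-exception:{name}",), tags)

    if is_classical_variant(v):
        which = "T790M" if v.start == 790 else ("L858R" if v.start == 858 else "Ex19del")
        trace = (f"classical:{which}",)
        if v.start == 790:
            # T790M on its own carries the hydrophobic-core label; the
            # allele-level precedence makes classical compounds classical.
            return VariantAssignment(v, Group.T790M_LIKE, None, trace + ("positional:hydrophobic-core",), tags)
        return VariantAssignment(v, Group.CLASSICAL, None, trace, tags)

    rule = rule_table.lookup_name_rule(v)
    if rule is not None:
        return VariantAssignment(v, rule.group, rule.subgroup, (rule.rule_id,), tags)

    if not v.in_kinase_domain:
        return VariantAssignment(v, Group.UNCLASSIFIED, None, ("positional:outside-kinase-domain",), tags)

    if v.kind is VariantKind.SUBSTITUTION and "hydrophobic_core" in tags:
        return VariantAssignment(v, Group.T790M_LIKE, None, ("positional:hydrophobic-core",), tags)

    if v.kind in (VariantKind.INSERTION, VariantKind.DUPLICATION):
        anchor = v.as_insertion().anchor
        if "alpha_c_helix" in tags:
            return VariantAssignment(
                v, Group.CLASSICAL_LIKE, None, ("positional:alpha-c-helix-insertion",), tags
            )
        if "ex20_loop_span" in tags:
            sub = Subgroup.NL if "near_loop" in tags else Subgroup.FL
            return VariantAssignment(
                v, Group.EX20INS_L, sub,
                (f"positional:ex20-loop-insertion@{anchor}",), tags,
            )

    if v.kind in (VariantKind.SUBSTITUTION, VariantKind.DELETION, VariantKind.DELINS):
        for region in ("p_loop", "hinge", "alpha_c_loop"):
            if region in tags:
                return VariantAssignment(v, Group.PACC, None, (f"positional:{region}",), tags)

    return VariantAssignment(
        v, Group.CLASSICAL_LIKE, None, ("positional:distant-from-pocket",), tags
    )


# --------------------------------------------------------------------------
# Allele-level classification

_RESISTANCE_PARTNERS = (("C", 797), ("L", 718), ("L", 792))


def _has_resistance_partner(allele: Allele) -> bool:
    for v in allele:
        if v.kind is VariantKind.SUBSTITUTION and (v.ref_aa, v.start) in _RESISTANCE_PARTNERS:
            return True
    return False


def _has_t790m(allele: Allele) -> bool:
    return any(
        v.kind is VariantKind.SUBSTITUTION and v.start == 790 and v.alt_seq == "M"
        for v in allele
    )


@dataclass(frozen=True)
class GroupAssignment:
    """Structure-function assignment for an allele.

    ``allele_group`` is the composite label under the precedence
    T790M-like > Ex20ins-L > PACC > classical-like; ``variant_assignments``
    keeps the per-variant labels so composite alleles (e.g. classical +
    acquired PACC) can be re-grouped as "PACC-containing" downstream.
    """

    allele: Allele
    variant_assignments: tuple[VariantAssignment, ...]
    allele_group: str
    subgroup: Optional[str]
    exon_group: Optional[int]
    bucket: str
    rule_trace: tuple[str, ...]

    @property
    def variant_groups(self) -> tuple[str, ...]:
        return tuple(va.group for va in self.variant_assignments)

    @property
    def is_pacc_containing(self) -> bool:
        return Group.PACC in self.variant_groups or self.allele_group == Group.PACC

    @property
    def label(self) -> str:
        if self.subgroup:
            return f"{self.allele_group}-{self.subgroup}"
        return self.allele_group


def _defining_exon(
    allele: Allele, assignments: Sequence[VariantAssignment], allele_group: str,
    region_map: RegionMap,
) -> Optional[int]:
    for va in assignments:
        if va.group == allele_group:
            return exon_of(va.variant.anchor, region_map)
    return exon_of(allele.variants[0].anchor, region_map)


def classify_allele(
    allele: Allele,
    rule_table: RuleTable = DEFAULT_RULE_TABLE,
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> GroupAssignment:
    """Composite structure-function label for a (possibly compound) allele.

    Precedence: fully classical alleles are classical; any T790M (or a
    curated T790M-like variant) makes the allele T790M-like, subgroup 3R
    iff a C797X/L718X/L792X resistance partner co-occurs, else 3S; then
    Ex20ins-L; then PACC; then classical-like; otherwise unclassified.
    """
    vas = tuple(classify_variant(v, rule_table, region_map) for v in allele)
    trace: list[str] = [t for va in vas for t in va.rule_trace]
    # curated name-level exceptions outrank the positional classical rule
    # (e.g. L747_K754delinsATSPE would otherwise satisfy the exon-19
    # deletion definition)
    has_curated_exception = any(
        t.startswith("curated-exception:") for va in vas for t in va.rule_trace
    )

    if is_classical(allele) and not has_curated_exception:
        group, sub = Group.CLASSICAL, None
        trace.append("allele:all-classical")
    elif _has_t790m(allele) or any(va.group == Group.T790M_LIKE for va in vas):
        group = Group.T790M_LIKE
        if _has_resistance_partner(allele):
            sub = Subgroup.R3
            trace.append("allele:T790M-like+resistance-partner->3R")
        else:
            sub = Subgroup.S3
            trace.append("allele:T790M-like->3S")
    elif any(va.group == Group.EX20INS_L for va in vas):
        group = Group.EX20INS_L
        sub = next(va.subgroup for va in vas if va.group == Group.EX20INS_L)
        trace.append("allele:contains-Ex20ins-L")
    elif any(va.group == Group.PACC for va in vas):
        group, sub = Group.PACC, None
        trace.append("allele:contains-PACC")
    elif all(va.group in (Group.CLASSICAL_LIKE, Group.CLASSICAL) for va in vas):
        group, sub = Group.CLASSICAL_LIKE, None
        trace.append("allele:all-classical-like")
    else:
        group, sub = Group.UNCLASSIFIED, None
        trace.append("allele:unclassified")

    bucket = _bucket(allele, vas)
    exon = _defining_exon(allele, vas, group, region_map)
    return GroupAssignment(allele, vas, group, sub, exon, bucket, tuple(trace))


def _bucket(allele: Allele, vas: Sequence[VariantAssignment]) -> str:
    classical_flags = [
        is_classical_variant(v)
        and not any(t.startswith("curated-exception:") for t in va.rule_trace)
        for v, va in zip(allele, vas)
    ]
    has_atypical = not all(classical_flags)
    if not has_atypical:
        return Bucket.CLASSICAL
    if len(allele) == 1:
        if vas[0].group == Group.EX20INS_L:
            return Bucket.EX20INS
        return Bucket.ATYPICAL
    has_classical_driver = any(
        f and v.start != 790 for f, v in zip(classical_flags, allele)
    )
    if has_classical_driver and _has_t790m(allele):
        return Bucket.CLASSICAL_T790M_ATYPICAL
    return Bucket.COMPLEX_ATYPICAL


def bucket_patient(
    allele: Allele,
    rule_table: RuleTable = DEFAULT_RULE_TABLE,
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> str:
    """Cohort bucket for one patient's allele (classical / Ex20ins /
    atypical / complex-with-atypical / classical+T790M+atypical)."""
    vas = tuple(classify_variant(v, rule_table, region_map) for v in allele)
    return _bucket(allele, vas)


# --------------------------------------------------------------------------
# Cohort tabulation


@dataclass
class CohortTabulation:
    """Bucket, exon and hotspot-region frequencies for a cohort of alleles."""

    n_alleles: int
    bucket_counts: pd.Series
    bucket_pct: pd.Series
    n_atypical_variants: int
    atypical_exon_counts: pd.Series
    atypical_exon_pct: pd.Series
    region_fractions: pd.Series  # % of atypical variants in p-loop / alphaC loop

    def summary(self) -> str:
        lines = [f"Cohort of {self.n_alleles} alleles"]
        for bucket, pct in self.bucket_pct.items():
            lines.append(f"  {bucket:<28s} {self.bucket_counts[bucket]:>5d}  {pct:5.1f}%")
        lines.append(f"Atypical variants: {self.n_atypical_variants}")
        for exon, pct in self.atypical_exon_pct.items():
            lines.append(f"  exon {exon}: {pct:5.1f}%")
        for region, pct in self.region_fractions.items():
            lines.append(f"  {region}: {pct:5.1f}%")
        return "\n".join(lines)


def tabulate_cohort(
    alleles: Iterable[Allele],
    rule_table: RuleTable = DEFAULT_RULE_TABLE,
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> CohortTabulation:
    """Frequency report over a cohort: patient buckets, exon distribution
    of atypical variants, and the fraction of atypical variants in the
    P-loop and alphaC C-terminal loop hotspots."""
    alleles = list(alleles)
    if not alleles:
        raise ValueError("empty cohort")

    buckets = pd.Series(
        [bucket_patient(a, rule_table, region_map) for a in alleles], dtype="object"
    )
    bucket_counts = buckets.value_counts().reindex(Bucket.ALL, fill_value=0)
    bucket_pct = 100.0 * bucket_counts / len(alleles)

    atypical: list[ProteinVariant] = [
        v for a in alleles for v in a if not is_classical_variant(v)
    ]
    exon_counts: dict[int, int] = {18: 0, 19: 0, 20: 0, 21: 0}
    in_p_loop = 0
    in_ac_loop = 0
    n_with_exon = 0
    for v in atypical:
        exon = exon_of(v.anchor, region_map)
        if exon is not None:
            exon_counts[exon] += 1
            n_with_exon += 1
        tags = annotate_regions(v, region_map)
        if "p_loop" in tags:
            in_p_loop += 1
        if "alpha_c_loop" in tags:
            in_ac_loop += 1

    exon_series = pd.Series(exon_counts)
    exon_pct = 100.0 * exon_series / max(n_with_exon, 1)
    n_atypical = len(atypical)
    region_fractions = pd.Series(
        {
            "p_loop": 100.0 * in_p_loop / max(n_atypical, 1),
            "alpha_c_loop": 100.0 * in_ac_loop / max(n_atypical, 1),
        }
    )
    return CohortTabulation(
        n_alleles=len(alleles),
        bucket_counts=bucket_counts,
        bucket_pct=bucket_pct,
        n_atypical_variants=n_atypical,
        atypical_exon_counts=exon_series,
        atypical_exon_pct=exon_pct,
        region_fractions=region_fractions,
    )
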