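"""Distinct-haplotype discovery and allele / SNP classification.

A *distinct haplotype* is a set of accessions separated from the rest of the
sample by at least ``min_fixed`` (default 5) perfectly co-segregating fixed
substitutions: at each supporting column every called member carries one
allele and every called non-member the other.  Groups are labelled by
frequency — a *rare allele* (type II) below 10 % of called accessions, an
*intermediate allele* from 10 % to below 50 %, and the *major allele* as the
complement of all discovered groups.

SNP taxonomy follows from the groups: supporting (fixed) substitutions are
gSNPs; remaining polymorphic sites at a locus that carries distinct
haplotypes are nfSNPs; all polymorphic sites at a single-haplotype locus are
dSNPs.  Low-frequency (<10 %) nfSNPs and dSNPs are the type I rare
substitutions.  nfSNPs and dSNPs together are the dispersed rSNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignments_io import CALLED, LocusAlignment, SiteRecord, site_table

logger = logging.getLogger(__name__)

RARE_CUTOFF = 0.10
INTERMEDIATE_CUTOFF = 0.50
MIN_FIXED = 5


class DegenerateLocusError(ValueError):
    """No accession left to form the major allele."""


class InvariantViolationError(ValueError):
    """Haplotype set breaks a structural invariant (e.g. no unique major)."""


@dataclass(frozen=True)
class HaplotypeGroup:
    """A frequency-labelled set of accessions at one locus.

    ``supporting_sites`` are the columns of the fixed substitutions that
    define a non-major group (empty for the major allele).  ``freq`` is
    ``len(members) / n`` over the called accessions of the locus.
    """

    members: frozenset[str]
    supporting_sites: tuple[int, ...]
    freq: float
    klass: str  # 'rare_typeII' | 'intermediate' | 'major'

    @property
    def n_supporting(self) -> int:
        return len(self.supporting_sites)


@dataclass(frozen=True)
class LocusClassification:
    locus_id: str
    locus_type: str  # 'gSNP_locus' | 'dSNP_locus' | 'complex'
    haplotypes: tuple[HaplotypeGroup, ...]

    @property
    def major(self) -> HaplotypeGroup:
        return next(h for h in self.haplotypes if h.klass == "major")

    @property
    def non_major(self) -> tuple[HaplotypeGroup, ...]:
        return tuple(h for h in self.haplotypes if h.klass != "major")

    @property
    def n_rare(self) -> int:
        return sum(h.klass == "rare_typeII" for h in self.haplotypes)

    @property
    def n_intermediate(self) -> int:
        return sum(h.klass == "intermediate" for h in self.haplotypes)


@dataclass
class SnpRecord:
    """One biallelic polymorphic site with its category and polarization."""

    locus_id: str
    column: int
    category: str  # 'gSNP' | 'nfSNP' | 'dSNP'
    minor_count: int
    n_called: int
    focus_allele: str
    other_allele: str
    focus_count: int = -1  # count of focus_allele; defaults to minor_count
    outgroup_state: str = "N"
    polarization: str = "excluded"  # 'derived_in_focus' | 'ancient' | 'excluded'
    derived_state: Optional[str] = None
    ancestral_state: Optional[str] = None
    codon_effect: Optional[str] = None  # 'synonymous' | 'nonsynonymous'
    codon_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.focus_count < 0:
            self.focus_count = self.minor_count

    @property
    def freq(self) -> float:
        """Focus-allele frequency (minor allele, or the haplotype's allele)."""
        return self.focus_count / self.n_called

    @property
    def freq_class(self) -> str:
        return "lt10" if self.freq < RARE_CUTOFF else "ge10"

    @property
    def is_type_I_rare(self) -> bool:
        return self.category in ("nfSNP", "dSNP") and self.freq < RARE_CUTOFF

    @property
    def derived_freq(self) -> Optional[float]:
        """Derived-allele frequency among called accessions, when polarized."""
        if self.polarization == "derived_in_focus":
            return self.focus_count / self.n_called
        if self.polarization == "ancient":
            return 1.0 - self.focus_count / self.n_called
        return None


def carrier_partitions(
    sites: Sequence[SiteRecord],
    min_called: Optional[int] = None,
    n_accessions: Optional[int] = None,
) -> dict[frozenset[str], list[int]]:
    """Group biallelic columns by the accession set carrying the minor allele.

    Only biallelic columns with at least ``min_called`` called accessions are
    considered (default: 80 % of the sample, so the fixed-substitution
    criterion stays meaningful under missing data).  When the two alleles
    tie in count, the alphabetically smallest is taken as the minor allele,
    which keeps the carrier set deterministic.
    """
    if n_accessions is None:
        n_accessions = len(sites[0].states) if sites else 0
    if min_called is None:
        min_called = math.ceil(0.8 * n_accessions)
    partitions: dict[frozenset[str], list[int]] = {}
    for site in sites:
        if len(site.alleles) > 2:
            logger.debug("column %d: >2 alleles, skipped", site.column)
            continue
        if not site.is_biallelic or site.n_called < min_called:
            continue
        (a1, c1), (a2, c2) = sorted(site.alleles.items())
        minor = a1 if c1 <= c2 else a2  # tie -> alphabetically smallest
        carriers = frozenset(
            aid for aid, st in site.states.items() if st == minor
        )
        partitions.setdefault(carriers, []).append(site.column)
    return partitions


def _resolve_overlaps(
    candidates: list[tuple[frozenset[str], list[int]]],
) -> list[tuple[frozenset[str], list[int]]]:
    """Drop truly overlapping candidates (neither disjoint nor nested).

    Preference order: more supporting sites, then fewer members, then the
    lexicographically smallest member tuple.  Nested pairs are both kept.
    """
    ranked = sorted(
        candidates,
        key=lambda kv: (-len(kv[1]), len(kv[0]), tuple(sorted(kv[0]))),
    )
    accepted: list[tuple[frozenset[str], list[int]]] = []
    for members, cols in ranked:
        ok = True
        for kept_members, _ in accepted:
            inter = members & kept_members
            if inter and not (members <= kept_members or kept_members <= members):
                ok = False
                break
        if ok:
            accepted.append((members, cols))
    return accepted


def _label(freq: float) -> str:
    if freq < RARE_CUTOFF:
        return "rare_typeII"
    if freq < INTERMEDIATE_CUTOFF:
        return "intermediate"
    return "major"


def identify_haplotypes(
    locus: LocusAlignment,
    min_fixed: int = MIN_FIXED,
    min_called: Optional[int] = None,
) -> list[HaplotypeGroup]:
    """Discover distinct haplotype groups at a locus.

    Every carrier partition supported by at least ``min_fixed`` fixed
    substitutions becomes a distinct group; the complement of all groups is
    the major allele.  A candidate covering at least half the called sample
    is re-interpreted from its complement's side (the fixed substitutions
    separate both sides equally, and the major allele is by definition the
    larger one).  Nested candidates are all kept; reported member sets are
    made disjoint by assigning each accession to its smallest containing
    candidate, so the groups partition the called accessions.
    """
    sites = site_table(locus)
    called_ids = frozenset(
        aid for aid, seq in locus.accessions if any(c in CALLED for c in seq)
    )
    n = len(called_ids)
    if n == 0:
        raise DegenerateLocusError(f"{locus.locus_id}: no called accessions")
    parts = carrier_partitions(sites, min_called=min_called,
                               n_accessions=locus.n_accessions)

    candidates: list[tuple[frozenset[str], list[int]]] = []
    for carriers, cols in parts.items():
        if len(cols) < min_fixed or not carriers:
            continue
        members = carriers
        if len(members) / n >= INTERMEDIATE_CUTOFF:
            # fixed sites separate both sides; the minority side is the group
            members = called_ids - members
            if not members or len(members) / n >= INTERMEDIATE_CUTOFF:
                continue
        candidates.append((members, sorted(cols)))
    candidates = _resolve_overlaps(candidates)

    if candidates:
        covered = frozenset().union(*(m for m, _ in candidates))
        if covered == called_ids:
            raise DegenerateLocusError(
                f"{locus.locus_id}: no accession left for the major allele"
            )
    groups: list[HaplotypeGroup] = []
    for members, cols in candidates:
        inner = [m for m, _ in candidates if m < members]
        exclusive = members - frozenset().union(*inner) if inner else members
        if not exclusive:
            continue
        groups.append(
            HaplotypeGroup(
                members=frozenset(exclusive),
                supporting_sites=tuple(cols),
                freq=len(exclusive) / n,
                klass=_label(len(exclusive) / n),
            )
        )
    taken = frozenset().union(*(g.members for g in groups)) if groups else frozenset()
    major_members = called_ids - taken
    groups.append(
        HaplotypeGroup(
            members=frozenset(major_members),
            supporting_sites=(),
            freq=len(major_members) / n,
            klass="major",
        )
    )
    groups.sort(key=lambda g: (g.klass != "major", -len(g.members),
                               tuple(sorted(g.members))))
    return groups


def classify_locus(
    locus_id: str, haps: Sequence[HaplotypeGroup]
) -> LocusClassification:
    """Label a locus by its haplotype content.

    dSNP locus: only the major allele; gSNP locus: exactly one distinct
    non-major group; complex: two or more.
    """
    majors = [h for h in haps if h.klass == "major"]
    if len(majors) != 1:
        raise InvariantViolationError(
            f"{locus_id}: expected exactly one major group, got {len(majors)}"
        )
    n_non_major = len(haps) - 1
    if n_non_major == 0:
        locus_type = "dSNP_locus"
    elif n_non_major == 1:
        locus_type = "gSNP_locus"
    else:
        locus_type = "complex"
    return LocusClassification(
        locus_id=locus_id, locus_type=locus_type, haplotypes=tuple(haps)
    )


def classify_snps(
    locus: LocusAlignment,
    classification: LocusClassification,
    min_called: Optional[int] = None,
) -> list[SnpRecord]:
    """Assign each biallelic polymorphic site a SNP category.

    Supporting sites of non-major groups are gSNPs (the focus allele is the
    haplotype's allele, whatever its frequency); the other polymorphic sites
    are nfSNPs at gSNP/complex loci and dSNPs at dSNP loci (focus = minor
    allele).  Polarization itself is filled in by :mod:`rarehap.polarize`.
    """
    sites = site_table(locus)
    supporting: dict[int, HaplotypeGroup] = {}
    for hap in classification.non_major:
        for col in hap.supporting_sites:
            supporting[col] = hap
    at_hap_locus = classification.locus_type in ("gSNP_locus", "complex")
    records: list[SnpRecord] = []
    for site in sites:
        if not site.is_biallelic:
            continue
        (a1, c1), (a2, c2) = sorted(site.alleles.items())
        if c1 < c2 or (c1 == c2 and a1 < a2):
            minor, minor_n, major_allele = a1, c1, a2
        else:
            minor, minor_n, major_allele = a2, c2, a1
        if site.column in supporting:
            hap = supporting[site.column]
            # focus allele = the allele carried by the haplotype's members
            member_states = {
                site.states[aid] for aid in hap.members
                if site.states.get(aid) in CALLED
            }
            focus = member_states.pop() if len(member_states) == 1 else minor
            other = a2 if focus == a1 else a1
            category = "gSNP"
        else:
            focus, other = minor, major_allele
            category = "nfSNP" if at_hap_locus else "dSNP"
        records.append(
            SnpRecord(
                locus_id=locus.locus_id,
                column=site.column,
                category=category,
                minor_count=minor_n,
                n_called=site.n_called,
                focus_allele=focus,
                other_allele=other,
                focus_count=site.alleles[focus],
                outgroup_state=site.outgroup_state,
            )
        )
    return records


_TABLE_ROWS = [
    "gSNP", "rare_typeII", "intermediate",
    "nfSNP", "rare_typeI_nf", "intermediate_nf",
    "dSNP", "rare_typeI_d", "intermediate_d",
    "total",
]


def tabulate(
    classifications: Sequence[LocusClassification],
    snps: Sequence[SnpRecord],
) -> pd.DataFrame:
    """Summary table of mutation classes in the style of a per-category ledger.

    Rows: gSNPs (with rare type II / intermediate sub-rows by the haplotype
    the fixed substitution supports), nfSNPs and dSNPs (with type I rare and
    intermediate-frequency sub-rows), and a grand total.  Columns: loci,
    haplotypes, total sites, derived, ancient and the derived/ancient ratio.
    """
    from .polarize import relative_rate  # local import to avoid cycle

    counts = {
        row: {"loci": 0, "haplotypes": 0, "total": 0, "derived": 0,
              "ancient": 0, "excluded": 0}
        for row in _TABLE_ROWS
    }
    hap_by_locus_col: dict[tuple[str, int], str] = {}
    for cl in classifications:
        non_major = cl.non_major
        if cl.locus_type in ("gSNP_locus", "complex"):
            counts["gSNP"]["loci"] += 1
            counts["nfSNP"]["loci"] += 1
            counts["gSNP"]["haplotypes"] += len(non_major)
            if any(h.klass == "rare_typeII" for h in non_major):
                counts["rare_typeII"]["loci"] += 1
            if any(h.klass == "intermediate" for h in non_major):
                counts["intermediate"]["loci"] += 1
            counts["rare_typeII"]["haplotypes"] += sum(
                h.klass == "rare_typeII" for h in non_major)
            counts["intermediate"]["haplotypes"] += sum(
                h.klass == "intermediate" for h in non_major)
        else:
            counts["dSNP"]["loci"] += 1
        for hap in non_major:
            for col in hap.supporting_sites:
                hap_by_locus_col[(cl.locus_id, col)] = hap.klass

    for snp in snps:
        rows: list[str] = [snp.category]
        if snp.category == "gSNP":
            klass = hap_by_locus_col.get((snp.locus_id, snp.column))
            if klass == "rare_typeII":
                rows.append("rare_typeII")
            elif klass == "intermediate":
                rows.append("intermediate")
        elif snp.category == "nfSNP":
            if snp.freq < RARE_CUTOFF:
                rows.append("rare_typeI_nf")
            elif snp.freq < INTERMEDIATE_CUTOFF:
                rows.append("intermediate_nf")
        elif snp.category == "dSNP":
            if snp.freq < RARE_CUTOFF:
                rows.append("rare_typeI_d")
            elif snp.freq < INTERMEDIATE_CUTOFF:
                rows.append("intermediate_d")
        rows.append("total")
        for row in rows:
            counts[row]["total"] += 1
            if snp.polarization == "derived_in_focus":
                counts[row]["derived"] += 1
            elif snp.polarization == "ancient":
                counts[row]["ancient"] += 1
            else:
                counts[row]["excluded"] += 1

    counts["total"]["loci"] = len(classifications)
    counts["total"]["haplotypes"] = counts["gSNP"]["haplotypes"]
    table = pd.DataFrame.from_dict(counts, orient="index")
    table.index.name = "category"
    table["ratio"] = [
        relative_rate_or_nan(r["derived"], r["ancient"])
        for _, r in table.iterrows()
    ]
    return table


def relative_rate_or_nan(derived: int, ancient: int) -> float:
    from .polarize import PolarizedCounts, relative_rate

    if ancient == 0:
        return float("nan")
    return relative_rate(PolarizedCounts("", derived, ancient, 0))
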