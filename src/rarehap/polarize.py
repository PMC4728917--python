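"""Outgroup polarization of substitutions and indels, and relative rates.

Each biallelic site carries a *focus* allele (the minor allele for dispersed
SNPs, the distinct haplotype's allele for fixed substitutions) and an
*other* allele.  The outgroup decides the mutation's direction: when the
outgroup matches the other allele the focus allele is the new (*derived*)
mutation; when it matches the focus allele the mutation happened on the
other lineage (*ancient*); when it is gapped, missing or a third state the
site is excluded — the direction cannot be defined.

The *relative rate* of a site class is derived/ancient; a value above 1
means the focal allele accumulated new mutations faster than its
counterpart.  Ratios are reported to two decimals, round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignments_io import CALLED, GAP, LocusAlignment
from .haplotypes import HaplotypeGroup, LocusClassification, SnpRecord

DERIVED = "derived_in_focus"
ANCIENT = "ancient"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PolarizedCounts:
    """Derived / ancient / excluded tallies for one site class."""

    label: str
    derived: int
    ancient: int
    excluded: int = 0

    @property
    def total(self) -> int:
        return self.derived + self.ancient + self.excluded

    @property
    def ratio(self) -> Optional[float]:
        if self.ancient == 0:
            return None
        return self.derived / self.ancient


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run shared by a set of accessions.

    ``polarization`` is relative to the indel-differing haplotype pair:
    'derived' when the non-major group carries the new state, 'ancient' when
    the major does, 'excluded' when the outgroup cannot orient it or the two
    haplotypes carry unequal spans at the same place.
    """

    locus_id: str
    start: int
    end: int
    present_in: frozenset[str]
    polarization: str = EXCLUDED

    @property
    def length(self) -> int:
        return self.end - self.start


def polarize_site(
    focus_allele: str, other_allele: str, outgroup_state: str
) -> str:
    """Orient one biallelic substitution with the outgroup.

    Returns 'derived_in_focus', 'ancient' or 'excluded'.
    """
    if focus_allele == other_allele:
        raise ValueError("focus and other allele must differ")
    if outgroup_state == other_allele:
        return DERIVED
    if outgroup_state == focus_allele:
        return ANCIENT
    return EXCLUDED


def polarize_snps(snps: Iterable[SnpRecord]) -> list[SnpRecord]:
    """Fill polarization and derived/ancestral states on SNP records."""
    out: list[SnpRecord] = []
    for snp in snps:
        pol = polarize_site(snp.focus_allele, snp.other_allele,
                            snp.outgroup_state)
        snp.polarization = pol
        if pol == DERIVED:
            snp.derived_state = snp.focus_allele
            snp.ancestral_state = snp.other_allele
        elif pol == ANCIENT:
            snp.derived_state = snp.other_allele
            snp.ancestral_state = snp.focus_allele
        else:
            snp.derived_state = snp.ancestral_state = None
        out.append(snp)
    return out


def count_polarized(label: str, snps: Iterable[SnpRecord]) -> PolarizedCounts:
    d = a = e = 0
    for snp in snps:
        if snp.polarization == DERIVED:
            d += 1
        elif snp.polarization == ANCIENT:
            a += 1
        else:
            e += 1
    return PolarizedCounts(label, d, a, e)


def relative_rate(counts: PolarizedCounts, decimals: int = 2) -> Optional[float]:
    """Derived/ancient ratio rounded half-up; ``None`` when ancient is 0."""
    if counts.ancient == 0:
        return None
    q = Decimal(int(counts.derived)) / Decimal(int(counts.ancient))
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for j, c in enumerate(seq):
        if c == GAP:
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def detect_indels(
    locus: LocusAlignment,
    classification: Optional[LocusClassification] = None,
) -> list[IndelEvent]:
    """Find maximal gap runs and polarize those fixed between haplotypes.

    Runs with an identical span are merged into one event carried by the
    union of gapped accessions.  When a classification is given, an event is
    polarized only if it is *fixed* between a non-major group and the major
    allele (every member of one side gapped over the span, no member of the
    other side gapped there).  Events whose spans overlap between haplotype
    groups but differ in extent are excluded, as are events the outgroup
    cannot orient.
    """
    by_span: dict[tuple[int, int], set[str]] = {}
    for aid, seq in locus.accessions:
        for span in _gap_runs(seq):
            by_span.setdefault(span, set()).add(aid)

    events: list[IndelEvent] = []
    spans = sorted(by_span)
    for span in spans:
        carriers = frozenset(by_span[span])
        pol = EXCLUDED
        overlapping_other = any(
            s != span and s[0] < span[1] and span[0] < s[1] for s in spans
        )
        if classification is not None and not overlapping_other:
            pol = _polarize_indel(locus, classification, span, carriers)
        events.append(
            IndelEvent(
                locus_id=locus.locus_id,
                start=span[0],
                end=span[1],
                present_in=carriers,
                polarization=pol,
            )
        )
    return events


def _polarize_indel(
    locus: LocusAlignment,
    classification: LocusClassification,
    span: tuple[int, int],
    carriers: frozenset[str],
) -> str:
    major = classification.major.members
    for hap in classification.non_major:
        side = None
        if hap.members <= carriers and not (major & carriers):
            side = "non_major_gapped"
        elif major <= carriers and not (hap.members & carriers):
            side = "major_gapped"
        if side is None:
            continue
        out = locus.outgroup
        if out is None:
            return EXCLUDED
        out_span = out[span[0]:span[1]]
        out_gapped = all(c == GAP for c in out_span)
        out_called = all(c in CALLED for c in out_span)
        if not (out_gapped or out_called):
            return EXCLUDED
        # outgroup matches the ungapped state -> the gap is the new mutation
        gap_is_new = out_called
        if side == "non_major_gapped":
            return DERIVED if gap_is_new else ANCIENT
        return ANCIENT if gap_is_new else DERIVED
    return EXCLUDED


def indel_relative_rate(
    events: Iterable[IndelEvent], decimals: int = 2
) -> Optional[float]:
    d = sum(e.polarization == DERIVED for e in events)
    a = sum(e.polarization == ANCIENT for e in events)
    return relative_rate(PolarizedCounts("indel", d, a), decimals)


def rate_by_frequency(
    snps: Sequence[SnpRecord], n_bins: int = 10
) -> list[tuple[tuple[float, float], PolarizedCounts]]:
    """Per-frequency-bin polarized counts and relative rates.

    Sites are binned by their focus-allele frequency (minor allele, or the
    distinct haplotype's frequency for fixed substitutions) into ``n_bins``
    half-open bins on (0, 1); excluded sites are tallied but do not enter
    the ratio.  Bins where no ancient site fell have an undefined ratio.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    tallies = [[0, 0, 0] for _ in range(n_bins)]
    for snp in snps:
        f = snp.freq
        b = min(int(f * n_bins), n_bins - 1)
        if snp.polarization == DERIVED:
            tallies[b][0] += 1
        elif snp.polarization == ANCIENT:
            tallies[b][1] += 1
        else:
            tallies[b][2] += 1
    out = []
    for b in range(n_bins):
        label = f"[{edges[b]:.1f},{edges[b + 1]:.1f})"
        d, a, e = tallies[b]
        out.append(((float(edges[b]), float(edges[b + 1])),
                    PolarizedCounts(label, d, a, e)))
    return out


def indel_vs_nonindel_rate(
    loci_snps: Sequence[tuple[LocusAlignment, Sequence[SnpRecord],
                              Sequence[IndelEvent]]],
    window_bp: Optional[int] = None,
) -> Optional[float]:
    """Ratio of per-bp substitution rates at indel vs non-indel loci.

    An *indel locus* contains at least one indel event.  The rate at each
    class is (number of polymorphic biallelic sites) / (total aligned bp).
    With ``window_bp`` the indel-locus numerator and denominator are
    restricted to columns within that distance of an indel event.
    ``None`` when either class is empty or the non-indel rate is zero.
    """
    indel_sites = indel_bp = 0
    plain_sites = plain_bp = 0
    for locus, snps, events in loci_snps:
        if events:
            if window_bp is None:
                indel_sites += len(snps)
                indel_bp += locus.length
            else:
                cols = set()
                for ev in events:
                    lo = max(0, ev.start - window_bp)
                    hi = min(locus.length, ev.end + window_bp)
                    cols.update(range(lo, hi))
                indel_sites += sum(snp.column in cols for snp in snps)
                indel_bp += len(cols)
        else:
            plain_sites += len(snps)
            plain_bp += locus.length
    if indel_bp == 0 or plain_bp == 0 or plain_sites == 0:
        return None
    return (indel_sites / indel_bp) / (plain_sites / plain_bp)


def rate_chi2(a: PolarizedCounts, b: PolarizedCounts) -> tuple[float, float]:
    """2x2 chi-square comparing two classes' derived/ancient counts."""
    from scipy.stats import chi2_contingency

    table = np.array([[a.derived, a.ancient], [b.derived, b.ancient]])
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
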