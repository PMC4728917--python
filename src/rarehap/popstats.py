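"""Population-genetic statistics over classified loci.

Covers: the random-occurrence model for counts of rare-allele types per
locus, the per-accession occurrence distribution, Tajima's D, the unfolded
site-frequency spectrum with its neutral constant-size expectation
(1/i)/a_n, frequency excess, quadratic extrapolation of SNP-count
distributions to fixation, fixation-probability ratios, between-species
divergence Dxy, codon effects, transition/transversion ratios and the
chromosomal extent of a rare-allele pattern.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from Bio.Seq import Seq

from .alignments_io import CALLED, GAP, Frame, LocusAlignment
from .haplotypes import HaplotypeGroup, LocusClassification, SnpRecord

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


# ---------------------------------------------------------------------------
# Random occurrence of rare-allele types across loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomOccurrenceModel:
    """Null model for the number of distinct rare-allele types per locus.

    If a single rare-allele type arises at a locus with probability F1,
    independent occurrences predict E[F_i] = F1**i for i of them.
    """

    f1: float
    expectations: Mapping[int, float]  # i -> expected fraction of loci
    observed: Mapping[int, float]
    chi2: float
    dof: int
    p_value: float
    pooling: str


def random_occurrence(
    observed_loci_by_type_count: Mapping[int, int],
    n_loci: int,
    max_types: int = 5,
) -> RandomOccurrenceModel:
    """Fit the independent-occurrence null for rare-allele type counts.

    ``observed_loci_by_type_count`` maps i (number of distinct rare-allele
    types at a locus) to the count of such loci.  F1 is the observed
    fraction with exactly one type; expected fractions are F1**i.  The
    chi-square compares observed and expected *counts* over i = 1..max_types
    with cells of expected count < 5 pooled into the previous cell
    (degrees of freedom = cells − 1).
    """
    if n_loci <= 0 or sum(observed_loci_by_type_count.values()) > n_loci:
        raise ValueError("invalid locus counts")
    f1 = observed_loci_by_type_count.get(1, 0) / n_loci
    if f1 == 0:
        raise ValueError("model undefined: no locus with exactly one type")
    expectations = {i: f1 ** i for i in range(2, max_types + 1)}
    observed = {
        i: observed_loci_by_type_count.get(i, 0) / n_loci
        for i in range(1, max_types + 1)
    }

    obs_counts = [observed_loci_by_type_count.get(i, 0)
                  for i in range(1, max_types + 1)]
    exp_counts = [n_loci * f1 ** i for i in range(1, max_types + 1)]
    pooled_obs: list[float] = []
    pooled_exp: list[float] = []
    for o, e in zip(obs_counts, exp_counts):
        if pooled_exp and e < 5:
            pooled_obs[-1] += o
            pooled_exp[-1] += e
        else:
            pooled_obs.append(o)
            pooled_exp.append(e)
    # a leading under-5 cell can only pool forward
    while len(pooled_exp) > 1 and pooled_exp[0] < 5:
        pooled_obs[0] += pooled_obs.pop(1)
        pooled_exp[0] += pooled_exp.pop(1)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(pooled_obs, pooled_exp))
    dof = max(len(pooled_exp) - 1, 1)
    p = float(sps.chi2.sf(chi2, dof))
    pooling = f"{len(pooled_exp)} cells after pooling expected<5"
    return RandomOccurrenceModel(
        f1=f1, expectations=expectations, observed=observed,
        chi2=float(chi2), dof=dof, p_value=p, pooling=pooling,
    )


def accession_occurrence(
    classifications: Sequence[LocusClassification],
    accession_ids: Sequence[str],
    tail_prob: float = 0.01,
) -> dict:
    """Observed vs expected distribution of rare-allele memberships.

    Counts, per accession, in how many rare (type II) haplotypes it sits
    across all loci; under random occurrence each accession carries a rare
    allele at each locus independently with probability p̂ = total
    memberships / (n_loci × n_accessions), so the number of memberships per
    accession is Binomial(n_loci, p̂).  Accessions in the two-sided
    ``tail_prob`` tail are flagged as outliers.
    """
    n_loci = len(classifications)
    member_counts = {aid: 0 for aid in accession_ids}
    total = 0
    for cl in classifications:
        for hap in cl.non_major:
            if hap.klass != "rare_typeII":
                continue
            for aid in hap.members:
                if aid in member_counts:
                    member_counts[aid] += 1
                    total += 1
    n_acc = len(accession_ids)
    p_hat = total / (n_loci * n_acc) if n_loci and n_acc else 0.0
    histogram: dict[int, int] = {}
    for aid, k in member_counts.items():
        histogram[k] = histogram.get(k, 0) + 1
    dist = sps.binom(n_loci, p_hat) if n_loci else None
    expected = {
        k: n_acc * float(dist.pmf(k)) for k in histogram
    } if dist is not None else {}
    outliers = []
    if dist is not None and p_hat > 0:
        for aid, k in member_counts.items():
            p_two = 2 * min(dist.cdf(k), dist.sf(k - 1))
            if p_two < tail_prob:
                outliers.append(aid)
    return {
        "p_hat": p_hat,
        "per_accession": member_counts,
        "histogram": histogram,
        "expected": expected,
        "outliers": sorted(outliers),
    }


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaResult:
    n: int
    S: int
    pi: float
    D: Optional[float]


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(locus: LocusAlignment) -> TajimaResult:
    """Tajima's D over complete-case columns of a locus.

    Columns containing any gap or missing base are dropped; S is the number
    of remaining polymorphic columns and pi the mean number of pairwise
    differences.  D is None when S = 0 or fewer than 4 sequences.
    """
    seqs = [seq for _, seq in locus.accessions]
    n = len(seqs)
    cols = [
        j for j in range(locus.length)
        if all(seq[j] in CALLED for seq in seqs)
    ]
    S = 0
    pairwise_total = 0
    n_pairs = n * (n - 1) // 2
    for j in cols:
        counts: dict[str, int] = {}
        for seq in seqs:
            counts[seq[j]] = counts.get(seq[j], 0) + 1
        if len(counts) > 1:
            S += 1
            same = sum(c * (c - 1) // 2 for c in counts.values())
            pairwise_total += n_pairs - same
    pi = pairwise_total / n_pairs if n_pairs else 0.0
    if S == 0 or n < 4:
        return TajimaResult(n=n, S=S, pi=pi, D=None)
    k = _tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi - S / k["a1"]) / math.sqrt(var)
    return TajimaResult(n=n, S=S, pi=pi, D=float(D))


# ---------------------------------------------------------------------------
# Unfolded SFS and neutral expectation
# ---------------------------------------------------------------------------

def expected_neutral_sfs(n: int, n_bins: int = 10) -> np.ndarray:
    """Neutral constant-size expectation of the unfolded SFS, binned.

    For a sample of n sequences the probability that a segregating site has
    i derived copies is (1/i)/a_n with a_n = sum_{j<n} 1/j.  Counts are
    aggregated into ``n_bins`` half-open frequency bins [k/b, (k+1)/b) by
    i/n.  The returned proportions sum to 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    a_n = sum(1.0 / j for j in range(1, n))
    out = np.zeros(n_bins)
    for i in range(1, n):
        b = min(int((i / n) * n_bins), n_bins - 1)
        out[b] += (1.0 / i) / a_n
    return out


@dataclass(frozen=True)
class SfsTable:
    """Observed unfolded SFS per category with neutral expectation."""

    n_bins: int
    edges: tuple[float, ...]
    observed: Mapping[str, tuple[int, ...]]  # category -> per-bin counts
    expected: tuple[float, ...]  # neutral proportions per bin

    def observed_proportions(self, category: str) -> np.ndarray:
        counts = np.asarray(self.observed[category], dtype=float)
        total = counts.sum()
        return counts / total if total else counts

    def excess(self, category: str) -> np.ndarray:
        obs = self.observed_proportions(category)
        exp = np.asarray(self.expected)
        with np.errstate(divide="ignore", invalid="ignore"):
            return obs / exp - 1.0


def unfolded_sfs(
    snps: Sequence[SnpRecord], n: int, n_bins: int = 10
) -> SfsTable:
    """Bin polarized SNPs by derived-allele frequency.

    Unpolarizable sites are excluded from the spectrum entirely; sites at
    derived frequency exactly 1 would be fixed differences and cannot occur
    among polymorphic sites, so every site falls in [0, 1).
    """
    edges = tuple(np.linspace(0.0, 1.0, n_bins + 1))
    observed: dict[str, list[int]] = {}
    for snp in snps:
        f = snp.derived_freq
        if f is None:
            continue
        b = min(int(f * n_bins), n_bins - 1)
        for cat in (snp.category, "all",
                    "rSNP" if snp.category in ("nfSNP", "dSNP") else None):
            if cat is None:
                continue
            observed.setdefault(cat, [0] * n_bins)[b] += 1
    expected = tuple(expected_neutral_sfs(n, n_bins))
    return SfsTable(
        n_bins=n_bins,
        edges=edges,
        observed={k: tuple(v) for k, v in observed.items()},
        expected=expected,
    )


def frequency_excess(observed_prop: float, expected_prop: float) -> float:
    """Observed/expected bin proportion minus one."""
    if expected_prop <= 0:
        raise ValueError("expected proportion must be positive")
    return observed_prop / expected_prop - 1.0


# ---------------------------------------------------------------------------
# Quadratic extrapolation to fixation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticFit:
    """y = c0 + c1*x + c2*x**2 with Pearson r of observed vs fitted."""

    c0: float
    c1: float
    c2: float
    r: float

    @property
    def y_at_1(self) -> float:
        return self.c0 + self.c1 + self.c2

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c0 + self.c1 * x + self.c2 * x ** 2


def quadratic_fit(
    bin_midpoints: Sequence[float], counts: Sequence[float]
) -> QuadraticFit:
    """Ordinary least-squares degree-2 polynomial through binned counts."""
    x = np.asarray(bin_midpoints, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 bins for a quadratic fit")
    c2, c1, c0 = np.polyfit(x, y, 2)
    fit = QuadraticFit(c0=float(c0), c1=float(c1), c2=float(c2), r=0.0)
    fitted = fit.predict(x)
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r = float(np.corrcoef(y, fitted)[0, 1])
    return QuadraticFit(c0=float(c0), c1=float(c1), c2=float(c2), r=r)


def fixation_probability(
    high_count: int, low_count: int, decimals: int = 1
) -> float:
    """High- over low-frequency SNP count as a percentage (round-half-up)."""
    if low_count <= 0:
        raise ValueError("low-frequency count must be positive")
    q = Decimal(high_count) / Decimal(low_count) * 100
    return float(q.quantize(Decimal(1).scaleb(-decimals),
                            rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Dxy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DxyResult:
    scope: str
    dxy: Optional[float]
    n_sites: int


def dxy(
    members: Iterable[str], locus: LocusAlignment, scope: str = ""
) -> DxyResult:
    """Mean per-site divergence between member accessions and the outgroup.

    For each member, differences are counted over columns where both the
    member and the outgroup carry a called base; the per-member fractions
    are averaged.  ``dxy`` is None when nothing is comparable.
    """
    if locus.outgroup is None:
        return DxyResult(scope=scope, dxy=None, n_sites=0)
    out = locus.outgroup
    fractions = []
    total_sites = 0
    for aid in sorted(members):
        seq = locus.sequence(aid)
        diff = comp = 0
        for a, o in zip(seq, out):
            if a in CALLED and o in CALLED:
                comp += 1
                diff += a != o
        if comp:
            fractions.append(diff / comp)
            total_sites += comp
    if not fractions:
        return DxyResult(scope=scope, dxy=None, n_sites=0)
    return DxyResult(scope=scope, dxy=float(np.mean(fractions)),
                     n_sites=total_sites)


def dxy_permutation_test(
    group_a: Sequence[float], group_b: Sequence[float],
    n_perm: int = 10_000, seed: int = 0,
) -> float:
    """Two-sample permutation p-value for a difference in mean per-locus Dxy."""
    rng = np.random.default_rng(seed)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = abs(pooled[: a.size].mean() - pooled[a.size:].mean())
        hits += d >= obs
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Codon effects and Ts/Tv
# ---------------------------------------------------------------------------

def codon_effect(
    snp: SnpRecord,
    locus: LocusAlignment,
    reference: Optional[str] = None,
) -> Optional[tuple[str, int]]:
    """Synonymous/nonsynonymous call and codon position for a coding SNP.

    The reference codon is read from ``reference`` (default: the locus
    majority consensus, standing in for the major allele) and the SNP's
    derived — or, if unpolarized, focus — allele is substituted.  Returns
    ``None`` when the site lies outside every annotated frame or the
    reference codon is not fully called.
    """
    from .alignments_io import consensus_sequence

    if reference is None:
        reference = consensus_sequence(locus)
    for frame in locus.frames:
        if not frame.start <= snp.column < frame.end:
            continue
        if frame.strand == "+":
            offset = snp.column - frame.start - frame.frame_offset
        else:
            offset = (frame.end - 1 - snp.column) - frame.frame_offset
        if offset < 0:
            return None
        codon_pos = offset % 3  # 0-based within codon
        if frame.strand == "+":
            c_start = snp.column - codon_pos
            codon = reference[c_start:c_start + 3]
            idx = codon_pos
        else:
            c_end = snp.column + codon_pos + 1
            codon = reference[c_end - 3:c_end]
            codon = str(Seq(codon).reverse_complement())
            idx = codon_pos
        if len(codon) != 3 or any(c not in CALLED for c in codon):
            return None
        alt_base = snp.derived_state or snp.focus_allele
        if frame.strand == "-":
            alt_base = str(Seq(alt_base).complement())
        alt = codon[:idx] + alt_base + codon[idx + 1:]
        if alt == codon:
            alt_base_other = snp.ancestral_state or snp.other_allele
            if frame.strand == "-":
                alt_base_other = str(Seq(alt_base_other).complement())
            alt = codon[:idx] + alt_base_other + codon[idx + 1:]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt).translate())
        effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return effect, idx + 1
    return None


def annotate_codon_effects(
    snps: Iterable[SnpRecord], locus: LocusAlignment
) -> None:
    """Fill codon_effect / codon_position in place for coding SNPs."""
    from .alignments_io import consensus_sequence

    if not locus.frames:
        return
    ref = consensus_sequence(locus)
    for snp in snps:
        res = codon_effect(snp, locus, reference=ref)
        if res is not None:
            snp.codon_effect, snp.codon_position = res


def ts_tv(snps: Iterable[SnpRecord], decimals: int = 3) -> Optional[float]:
    """Transition/transversion ratio over biallelic SNPs (round-half-up)."""
    ts = tv = 0
    for snp in snps:
        pair = frozenset((snp.focus_allele, snp.other_allele))
        if pair in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    q = Decimal(ts) / Decimal(tv)
    return float(q.quantize(Decimal(1).scaleb(-decimals),
                            rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Rare-allele extent
# ---------------------------------------------------------------------------

def rare_allele_extent(
    extended_locus: LocusAlignment,
    hap: HaplotypeGroup,
    core: tuple[int, int],
    window_bp: int = 500,
    min_fixed_per_window: int = 1,
) -> dict:
    """Chromosomal extent of a rare-allele pattern around its core locus.

    Walks outward from the ``core`` span (0-based half-open columns of the
    original locus within ``extended_locus``) in steps of ``window_bp``.
    The pattern ends at the start of the first window containing fewer than
    ``min_fixed_per_window`` substitutions fixed between the haplotype's
    members and the other accessions.  Returns left/right/total extent in bp
    and a flag when a flank is shorter than one window (truncated).
    """
    members = hap.members
    others = [
        aid for aid in extended_locus.accession_ids if aid not in members
    ]
    member_seqs = [extended_locus.sequence(a) for a in sorted(members)]
    other_seqs = [extended_locus.sequence(a) for a in others]

    def fixed_at(j: int) -> bool:
        m_states = {s[j] for s in member_seqs if s[j] in CALLED}
        o_states = {s[j] for s in other_seqs if s[j] in CALLED}
        return (len(m_states) == 1 and len(o_states) == 1
                and m_states != o_states)

    core_start, core_end = core
    L = extended_locus.length

    def walk(direction: int) -> tuple[int, bool]:
        extent = 0
        pos = core_start if direction < 0 else core_end
        truncated = False
        while True:
            if direction < 0:
                lo, hi = pos - window_bp, pos
                if lo < 0:
                    truncated = hi > 0 and pos > 0
                    lo = 0
            else:
                lo, hi = pos, pos + window_bp
                if hi > L:
                    truncated = lo < L
                    hi = L
            if hi <= lo:
                break
            n_fixed = sum(fixed_at(j) for j in range(lo, hi))
            if n_fixed < min_fixed_per_window or hi - lo < window_bp:
                if n_fixed >= min_fixed_per_window and hi - lo < window_bp:
                    extent += hi - lo  # pattern runs into the truncated edge
                break
            extent += hi - lo
            pos = lo if direction < 0 else hi
        return extent, truncated

    left, trunc_l = walk(-1)
    right, trunc_r = walk(+1)
    core_len = core_end - core_start
    return {
        "left_bp": left,
        "right_bp": right,
        "total_bp": core_len + left + right,
        "truncated": trunc_l or trunc_r,
    }
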