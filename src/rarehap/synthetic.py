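"""Seeded synthetic data: neutral coalescent loci with known ground truth.

The generator emulates a resequencing panel of ~96 accessions of a selfing
annual with ~500 bp loci, mean pairwise diversity around 0.44 %, and an
outgroup species diverged ~5 % per site.  Backgrounds are standard neutral
coalescent samples (Kingman genealogy, mutations Poisson on branches,
infinite sites placed uniformly on the locus); structured loci additionally
carry implanted distinct haplotypes — a chosen carrier set given private
substitutions at fresh columns — and, optionally, an indel whose flanking
region receives extra carrier-lineage substitutions at a configurable
multiple of the background rate.

The outgroup is generated from the sample's common ancestor, so the
derived/ancient status of every mutation is known exactly and recorded in a
truth ledger.  One root seed drives everything; per-locus streams are keyed
by locus index so each locus is reproducible independently of ``n_loci``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignments_io import Frame, LocusAlignment

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IndelSpec:
    """Per-locus indel implant: occurrence probability, length range (bp),
    flank window (bp) and the substitution-rate multiplier applied to the
    indel-carrying lineage inside the window (1.0 = no elevation)."""

    probability: float = 0.0
    min_length: int = 2
    max_length: int = 10
    flank_window: int = 1000
    flank_multiplier: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic panel.

    ``theta_per_site`` is the scaled mutation rate in the units where the
    expected pairwise diversity equals theta (0.0044 matches the focal
    panel's 0.44 % mean diversity).  ``rare_spec`` / ``intermediate_spec``
    describe the haplotype implants placed on a structured locus:
    (n_carriers, n_fixed_sites) with n_fixed_sites >= 5.
    """

    n_accessions: int = 96
    n_loci: int = 100
    locus_length: int = 500
    theta_per_site: float = 0.0044
    outgroup_divergence: float = 0.05
    rare_spec: tuple[tuple[int, int], ...] = ((5, 10),)
    intermediate_spec: tuple[tuple[int, int], ...] = ()
    rare_locus_fraction: float = 0.234
    intermediate_locus_fraction: float = 0.0
    indel_spec: IndelSpec = field(default_factory=IndelSpec)
    coding_fraction: float = 0.0
    outgroup_misassignment: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.theta_per_site, self.outgroup_divergence,
                     self.rare_locus_fraction,
                     self.intermediate_locus_fraction, self.coding_fraction,
                     self.outgroup_misassignment, self.indel_spec.probability):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        for spec in (*self.rare_spec, *self.intermediate_spec):
            k, m = spec
            if not 1 <= k < self.n_accessions / 2:
                raise ValueError(f"implant carriers {k} not in [1, n/2)")
            if m < 1:
                raise ValueError("implant needs >=1 fixed site")


@dataclass
class MutationRecord:
    locus_id: str
    column: int
    ancestral: str
    derived: str
    carriers: frozenset[str]
    origin: str  # 'background' | 'implant' | 'flank'


@dataclass
class HaplotypeRecord:
    locus_id: str
    kind: str  # 'rare' | 'intermediate'
    members: frozenset[str]
    supporting_sites: tuple[int, ...]


@dataclass
class IndelRecord:
    locus_id: str
    start: int
    end: int
    carriers: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthLedger:
    """Ground truth of every planted event, one-to-one with the emitted data."""

    mutations: list[MutationRecord] = field(default_factory=list)
    haplotypes: list[HaplotypeRecord] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)
    outgroup_mutated_columns: dict[str, tuple[int, ...]] = field(
        default_factory=dict)

    def merge(self, other: "TruthLedger") -> None:
        self.mutations.extend(other.mutations)
        self.haplotypes.extend(other.haplotypes)
        self.indels.extend(other.indels)
        self.outgroup_mutated_columns.update(other.outgroup_mutated_columns)


def accession_names(n: int) -> list[str]:
    return [f"acc{i + 1:03d}" for i in range(n)]


def locus_rng(seed: int, locus_index: int) -> np.random.Generator:
    """Per-locus stream: independent of how many loci are simulated."""
    return np.random.default_rng([seed, locus_index])


def _kingman_branches(
    n: int, rng: np.random.Generator
) -> list[tuple[float, frozenset[int]]]:
    """Sample a Kingman genealogy; return (branch_length, leaf_set) per branch.

    Time is in coalescent units (pairwise coalescence has mean 1), so a
    mutation rate of theta/2 per site per unit time gives E[pi] = theta.
    """
    lineages: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    branches: list[tuple[float, frozenset[int]]] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        (set_j, born_j) = lineages.pop(j)
        (set_i, born_i) = lineages.pop(i)
        branches.append((t - born_i, set_i))
        branches.append((t - born_j, set_j))
        lineages.append((set_i | set_j, t))
        k -= 1
    return branches


def simulate_neutral_locus(
    config: SimConfig,
    locus_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LocusAlignment, TruthLedger]:
    """One neutral coalescent locus plus its outgroup and truth ledger."""
    if rng is None:
        rng = locus_rng(config.seed, locus_index)
    n, L = config.n_accessions, config.locus_length
    names = accession_names(n)
    locus_id = f"locus{locus_index:05d}"

    ancestral = rng.choice(4, size=L)
    branches = _kingman_branches(n, rng)
    free_cols = list(rng.permutation(L))
    ledger = TruthLedger()
    seqs = np.tile(ancestral, (n, 1))
    mu_per_branch = 0.5 * config.theta_per_site * L
    for length, leaves in branches:
        n_mut = rng.poisson(length * mu_per_branch)
        for _ in range(n_mut):
            if not free_cols:
                break  # infinite-sites budget exhausted; drop the mutation
            col = int(free_cols.pop())
            anc = int(ancestral[col])
            derived = int((anc + rng.integers(1, 4)) % 4)
            rows = sorted(leaves)
            seqs[rows, col] = derived
            ledger.mutations.append(
                MutationRecord(
                    locus_id=locus_id, column=col,
                    ancestral=str(BASES[anc]), derived=str(BASES[derived]),
                    carriers=frozenset(names[r] for r in rows),
                    origin="background",
                )
            )

    outgroup = ancestral.copy()
    flips = rng.random(L) < config.outgroup_divergence
    if config.outgroup_misassignment > 0:
        flips |= rng.random(L) < config.outgroup_misassignment
    mutated_cols = []
    for col in np.flatnonzero(flips):
        outgroup[col] = (outgroup[col] + rng.integers(1, 4)) % 4
        mutated_cols.append(int(col))
    ledger.outgroup_mutated_columns[locus_id] = tuple(mutated_cols)

    accessions = tuple(
        (names[i], "".join(BASES[seqs[i]])) for i in range(n)
    )
    locus = LocusAlignment(
        locus_id=locus_id, chrom="chrS", position=1 + locus_index * 100_000,
        accessions=accessions,
        outgroup="".join(BASES[outgroup]), outgroup_id="outgroup",
    )
    return locus, ledger


def _implant_haplotype(
    seqs: np.ndarray,
    ancestral: np.ndarray,
    free_cols: list[int],
    carriers_idx: Sequence[int],
    n_fixed: int,
    names: Sequence[str],
    locus_id: str,
    kind: str,
    rng: np.random.Generator,
    ledger: TruthLedger,
) -> None:
    if len(free_cols) < n_fixed:
        raise ValueError(
            f"{locus_id}: {n_fixed} fixed sites requested but only "
            f"{len(free_cols)} untouched columns remain"
        )
    cols = [int(free_cols.pop()) for _ in range(n_fixed)]
    rows = sorted(carriers_idx)
    for col in cols:
        anc = int(ancestral[col])
        derived = int((anc + rng.integers(1, 4)) % 4)
        seqs[rows, col] = derived
        ledger.mutations.append(
            MutationRecord(
                locus_id=locus_id, column=col,
                ancestral=str(BASES[anc]), derived=str(BASES[derived]),
                carriers=frozenset(names[r] for r in rows),
                origin="implant",
            )
        )
    ledger.haplotypes.append(
        HaplotypeRecord(
            locus_id=locus_id, kind=kind,
            members=frozenset(names[r] for r in rows),
            supporting_sites=tuple(sorted(cols)),
        )
    )


def simulate_structured_locus(
    config: SimConfig,
    locus_index: int = 0,
    rare: bool = True,
    intermediate: bool = False,
    with_indel: Optional[bool] = None,
) -> tuple[LocusAlignment, TruthLedger]:
    """Neutral background plus implanted haplotype(s) and optional indel.

    Implanted carrier sets are disjoint from each other.  The indel (when
    drawn) is placed on the first implanted group — or a fresh small group
    on a purely neutral locus — and its flank receives extra group-private
    substitutions with per-bp mean (multiplier − 1) × theta/2, emulating
    indel-associated local mutation-rate elevation.
    """
    rng = locus_rng(config.seed, locus_index)
    locus, ledger = simulate_neutral_locus(config, locus_index, rng=rng)
    n, L = config.n_accessions, config.locus_length
    names = list(locus.accession_ids)
    locus_id = locus.locus_id

    seqs = np.empty((n, L), dtype=int)
    base_to_int = {b: i for i, b in enumerate(BASES)}
    for i, (_, s) in enumerate(locus.accessions):
        seqs[i] = [base_to_int[c] for c in s]
    # recover the true ancestral states from the ledger (row 0 may carry
    # derived alleles wherever it is a mutation carrier)
    touched = {m.column for m in ledger.mutations}
    ancestral = seqs[0].copy()
    for m in ledger.mutations:
        ancestral[m.column] = base_to_int[m.ancestral]

    free_cols = [j for j in rng.permutation(L) if j not in touched]
    used_rows: set[int] = set()
    implanted_groups: list[list[int]] = []

    specs: list[tuple[str, tuple[int, int]]] = []
    if rare:
        specs += [("rare", s) for s in config.rare_spec]
    if intermediate:
        specs += [("intermediate", s) for s in config.intermediate_spec]
    for kind, (k, m) in specs:
        available = [i for i in range(n) if i not in used_rows]
        carriers = sorted(rng.choice(available, size=k, replace=False))
        used_rows.update(carriers)
        implanted_groups.append(carriers)
        _implant_haplotype(seqs, ancestral, free_cols, carriers, m,
                           names, locus_id, kind, rng, ledger)

    draw_indel = (rng.random() < config.indel_spec.probability
                  if with_indel is None else with_indel)
    if draw_indel:
        spec = config.indel_spec
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        start = int(rng.integers(0, max(L - length, 1)))
        if implanted_groups:
            carriers = implanted_groups[0]
        else:
            k = int(rng.integers(1, max(2, n // 10)))
            carriers = sorted(rng.choice(n, size=k, replace=False))
        gap_cols = list(range(start, start + length))
        ledger.indels.append(
            IndelRecord(locus_id=locus_id, start=start, end=start + length,
                        carriers=frozenset(names[r] for r in carriers))
        )
        flank_lo = max(0, start - spec.flank_window)
        flank_hi = min(L, start + length + spec.flank_window)
        flank_cols = [
            j for j in free_cols
            if flank_lo <= j < flank_hi and j not in gap_cols
        ]
        extra_mean = max(spec.flank_multiplier - 1.0, 0.0) \
            * 0.5 * config.theta_per_site * len(flank_cols)
        n_extra = rng.poisson(extra_mean)
        for _ in range(min(n_extra, len(flank_cols))):
            col = int(flank_cols.pop(rng.integers(len(flank_cols))))
            free_cols.remove(col)
            anc = int(ancestral[col])
            derived = int((anc + rng.integers(1, 4)) % 4)
            seqs[carriers, col] = derived
            ledger.mutations.append(
                MutationRecord(
                    locus_id=locus_id, column=col,
                    ancestral=str(BASES[anc]), derived=str(BASES[derived]),
                    carriers=frozenset(names[r] for r in carriers),
                    origin="flank",
                )
            )

    rows = ["".join(BASES[seqs[i]]) for i in range(n)]
    if draw_indel:
        span = next(iv for iv in ledger.indels if iv.locus_id == locus_id)
        gapped = set(span.carriers)
        rows = [
            (s[:span.start] + "-" * span.length + s[span.end:])
            if names[i] in gapped else s
            for i, s in enumerate(rows)
        ]
    accessions = tuple(zip(names, rows))
    frames = ()
    if rng.random() < config.coding_fraction:
        frames = (Frame(start=0, end=L - (L % 3), frame_offset=0, strand="+"),)
    locus = LocusAlignment(
        locus_id=locus_id, chrom=locus.chrom, position=locus.position,
        accessions=accessions, outgroup=locus.outgroup,
        outgroup_id=locus.outgroup_id, frames=frames,
    )
    return locus, ledger


def simulate_dataset(
    config: SimConfig,
    outdir: str | Path,
    overwrite: bool = False,
) -> tuple[Path, TruthLedger]:
    """Write a full synthetic panel: manifest, per-locus FASTA, truth ledger.

    Each locus independently receives a rare implant with probability
    ``rare_locus_fraction`` and an intermediate implant with
    ``intermediate_locus_fraction``; the remainder are purely neutral.
    Returns the manifest path and the merged ledger.
    """
    from .alignments_io import write_locus_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.tsv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")

    ledger = TruthLedger()
    rows = ["locus_id\tchrom\tposition\tpath\toutgroup_id"]
    frame_rows = ["locus_id\tstart\tend\tframe_offset\tstrand"]
    root = np.random.default_rng([config.seed, 2**20])  # locus-role stream
    for i in range(config.n_loci):
        want_rare = root.random() < config.rare_locus_fraction
        want_int = root.random() < config.intermediate_locus_fraction
        if want_rare or want_int:
            locus, led = simulate_structured_locus(
                config, i, rare=want_rare, intermediate=want_int)
        else:
            locus, led = simulate_structured_locus(
                config, i, rare=False, intermediate=False)
        ledger.merge(led)
        fasta = outdir / f"{locus.locus_id}.fasta"
        write_locus_alignment(locus, fasta)
        rows.append(
            f"{locus.locus_id}\t{locus.chrom}\t{locus.position}"
            f"\t{fasta}\t{locus.outgroup_id}"
        )
        for fr in locus.frames:
            frame_rows.append(
                f"{locus.locus_id}\t{fr.start}\t{fr.end}"
                f"\t{fr.frame_offset}\t{fr.strand}"
            )
    manifest_path.write_text("\n".join(rows) + "\n")
    if len(frame_rows) > 1:
        (outdir / "frames.tsv").write_text("\n".join(frame_rows) + "\n")
    _write_ledger(ledger, outdir / "truth")
    return manifest_path, ledger


def _write_ledger(ledger: TruthLedger, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "mutations.tsv", "w") as fh:
        fh.write("locus_id\tcolumn\tancestral\tderived\torigin\tcarriers\n")
        for m in ledger.mutations:
            fh.write(
                f"{m.locus_id}\t{m.column}\t{m.ancestral}\t{m.derived}"
                f"\t{m.origin}\t{','.join(sorted(m.carriers))}\n"
            )
    with open(outdir / "haplotypes.tsv", "w") as fh:
        fh.write("locus_id\tkind\tsupporting_sites\tmembers\n")
        for h in ledger.haplotypes:
            fh.write(
                f"{h.locus_id}\t{h.kind}"
                f"\t{','.join(map(str, h.supporting_sites))}"
                f"\t{','.join(sorted(h.members))}\n"
            )
    with open(outdir / "indels.tsv", "w") as fh:
        fh.write("locus_id\tstart\tend\tcarriers\n")
        for iv in ledger.indels:
            fh.write(
                f"{iv.locus_id}\t{iv.start}\t{iv.end}"
                f"\t{','.join(sorted(iv.carriers))}\n"
            )


def null_haplotype_rate(
    config: SimConfig,
    n_reps: int = 1000,
    min_fixed: int = 5,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo rate of neutral loci that yield a distinct haplotype.

    Simulates ``n_reps`` purely neutral loci under ``config`` and reports
    the fraction on which haplotype discovery (at ``min_fixed``) finds at
    least one non-major group, with an exact binomial confidence interval.
    """
    from scipy.stats import binomtest

    from .haplotypes import DegenerateLocusError, identify_haplotypes

    hits = 0
    for i in range(n_reps):
        locus, _ = simulate_neutral_locus(config, locus_index=i)
        try:
            groups = identify_haplotypes(locus, min_fixed=min_fixed)
        except DegenerateLocusError:
            hits += 1  # every accession fell in some distinct group
            continue
        if any(g.klass != "major" for g in groups):
            hits += 1
    ci = binomtest(hits, n_reps).proportion_ci(confidence_level=1 - alpha)
    return {
        "rate": hits / n_reps,
        "hits": hits,
        "n_reps": n_reps,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }
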