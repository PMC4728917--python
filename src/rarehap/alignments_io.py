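"""Reading, validation and filtering of per-locus multi-accession alignments.

A *locus* is one aligned FASTA file holding the sequences of many accessions
of the focal species plus (optionally) an aligned outgroup sequence from a
sister species.  A tab-separated manifest names each locus, its genomic
anchor, the alignment file and the FASTA record id of the outgroup.

Coordinates are 0-based half-open internally; reports use 1-based positions.
A gap character ``-`` inside an accession row is treated as missing data for
substitution-level analysis (gap runs are promoted to indel events by
:mod:`rarehap.polarize`).  Ambiguity codes other than ``N`` are mapped to
``N`` with a warning.
"""

from __future__ import annotations

import csv
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
CALLED = frozenset("ACGT")
MISSING = "N"
GAP = "-"


class AlignmentError(ValueError):
    """Base class for malformed locus input."""


class MalformedAlignmentError(AlignmentError):
    """Rows of unequal length, or otherwise not a rectangular alignment."""


class DuplicateIdError(AlignmentError):
    """Two FASTA records share an id."""


class EmptyInputError(AlignmentError):
    """No records in the alignment file."""


@dataclass(frozen=True)
class Frame:
    """A coding frame on the locus, 0-based half-open, strand '+' or '-'."""

    start: int
    end: int
    frame_offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad frame span [{self.start}, {self.end})")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame offset must be 0..2, got {self.frame_offset}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class LocusAlignment:
    """One locus: aligned accession sequences plus an optional outgroup.

    Parameters
    ----------
    locus_id, chrom:
        Identifiers from the manifest.
    position:
        1-based genomic anchor of the locus (report convention).
    accessions:
        Ordered ``(accession_id, aligned_sequence)`` pairs; sequences are
        uppercase strings over ``{A, C, G, T, N, -}`` of identical length.
    outgroup:
        Aligned outgroup sequence of the same length, or ``None``.
    frames:
        Optional coding-frame annotation in locus coordinates.
    """

    locus_id: str
    chrom: str
    position: int
    accessions: tuple[tuple[str, str], ...]
    outgroup: Optional[str] = None
    outgroup_id: Optional[str] = None
    frames: tuple[Frame, ...] = ()

    def __post_init__(self) -> None:
        if not self.accessions:
            raise EmptyInputError(f"{self.locus_id}: no accession sequences")
        lengths = {len(seq) for _, seq in self.accessions}
        if self.outgroup is not None:
            lengths.add(len(self.outgroup))
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise MalformedAlignmentError(f"{self.locus_id}: zero-length alignment")
        ids = [aid for aid, _ in self.accessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if ids.count(a) > 1})
            raise DuplicateIdError(f"{self.locus_id}: duplicate accession ids {dupes}")
        for aid, seq in self.accessions:
            bad = set(seq) - VALID_CHARS
            if bad:
                raise MalformedAlignmentError(
                    f"{self.locus_id}/{aid}: invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.accessions[0][1])

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(aid for aid, _ in self.accessions)

    def sequence(self, accession_id: str) -> str:
        for aid, seq in self.accessions:
            if aid == accession_id:
                return seq
        raise KeyError(accession_id)

    def with_frames(self, frames: Iterable[Frame]) -> "LocusAlignment":
        return replace(self, frames=tuple(frames))


@dataclass(frozen=True)
class SiteRecord:
    """One alignment column, decomposed for SNP-level analysis.

    ``states`` maps accession id to its character at the column; gaps and
    ambiguity codes count as missing.  ``alleles`` holds the distinct called
    nucleotides with their counts (sums to ``n_called``).
    """

    column: int
    states: Mapping[str, str]
    outgroup_state: str  # nucleotide, '-' or 'N'
    n_called: int
    alleles: Mapping[str, int]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2

    @property
    def is_polymorphic(self) -> bool:
        return len(self.alleles) >= 2


def _sanitize(seq: str, label: str) -> str:
    """Uppercase and map non-N ambiguity codes to N."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_CHARS
    if bad:
        warnings.warn(
            f"{label}: ambiguity codes {sorted(bad)} mapped to N", stacklevel=3
        )
        s = "".join(c if c in VALID_CHARS else MISSING for c in s)
    return s


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read the tab-separated locus manifest.

    Expected header: ``locus_id  chrom  position  path  outgroup_id``.
    An empty ``outgroup_id`` field means the locus has no outgroup record.
    """
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"locus_id", "chrom", "position", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise AlignmentError(
                f"manifest {path}: header must contain {sorted(required)}"
            )
        for row in reader:
            rows.append({k: (v or "").strip() for k, v in row.items()})
    return rows


def read_frames(path: str | Path) -> dict[str, list[Frame]]:
    """Read a frames file: ``locus_id  start  end  frame_offset  strand``."""
    out: dict[str, list[Frame]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["locus_id"], []).append(
                Frame(
                    start=int(row["start"]),
                    end=int(row["end"]),
                    frame_offset=int(row["frame_offset"]),
                    strand=row["strand"],
                )
            )
    return out


def read_locus_alignment(
    manifest_row: Mapping[str, str],
    alignment_path: str | Path | None = None,
    frames: Sequence[Frame] = (),
) -> LocusAlignment:
    """Parse one aligned FASTA into a :class:`LocusAlignment`.

    The record whose id equals the manifest's ``outgroup_id`` is detached
    from the accession list and attached as the outgroup sequence.
    """
    path = Path(alignment_path if alignment_path is not None else manifest_row["path"])
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: empty alignment file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdError(f"{path}: duplicate record ids {dupes}")

    outgroup_id = manifest_row.get("outgroup_id") or None
    outgroup = None
    accessions = []
    for rec in records:
        seq = _sanitize(str(rec.seq), f"{manifest_row['locus_id']}/{rec.id}")
        if outgroup_id is not None and rec.id == outgroup_id:
            outgroup = seq
        else:
            accessions.append((rec.id, seq))
    if outgroup_id is not None and outgroup is None:
        logger.warning(
            "locus %s: outgroup record %r not found in %s",
            manifest_row["locus_id"], outgroup_id, path,
        )
    return LocusAlignment(
        locus_id=manifest_row["locus_id"],
        chrom=manifest_row["chrom"],
        position=int(manifest_row["position"]),
        accessions=tuple(accessions),
        outgroup=outgroup,
        outgroup_id=outgroup_id if outgroup is not None else None,
        frames=tuple(frames),
    )


def write_locus_alignment(locus: LocusAlignment, path: str | Path) -> None:
    """Write a locus back to aligned FASTA (outgroup record last)."""
    records = [
        SeqRecord(Seq(seq), id=aid, description="") for aid, seq in locus.accessions
    ]
    if locus.outgroup is not None:
        records.append(
            SeqRecord(Seq(locus.outgroup), id=locus.outgroup_id or "outgroup",
                      description="")
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def consensus_sequence(locus: LocusAlignment) -> str:
    """Majority-rule consensus over called bases; N where no base is called.

    Ties broken toward the alphabetically smallest base, which keeps the
    consensus deterministic.
    """
    cols = []
    for j in range(locus.length):
        counts = Counter(
            seq[j] for _, seq in locus.accessions if seq[j] in CALLED
        )
        if not counts:
            cols.append(MISSING)
        else:
            best = max(sorted(counts), key=counts.get)  # type: ignore[arg-type]
            cols.append(best)
    return "".join(cols)


def outgroup_identity(locus: LocusAlignment) -> Optional[float]:
    """Identity between the outgroup and the accession consensus.

    Computed over columns where both the consensus and the outgroup carry a
    called base (gaps and N excluded).  ``None`` when the locus has no
    outgroup or no comparable column.
    """
    if locus.outgroup is None:
        return None
    cons = consensus_sequence(locus)
    same = total = 0
    for c, o in zip(cons, locus.outgroup):
        if c in CALLED and o in CALLED:
            total += 1
            same += c == o
    if total == 0:
        return None
    return same / total


def filter_loci(
    loci: Iterable[LocusAlignment],
    min_accessions: int = 60,
    min_length: int = 400,
    min_outgroup_identity: Optional[float] = 0.85,
) -> tuple[list[LocusAlignment], dict[str, str]]:
    """Apply the locus-level quality filters.

    A locus is dropped when it has fewer than ``min_accessions`` accessions,
    is shorter than ``min_length`` aligned columns, or (when an identity
    threshold is requested) its outgroup identity is *below*
    ``min_outgroup_identity`` — a locus exactly at the threshold is kept.
    The report maps each dropped locus id to the first failed rule.
    """
    if min_accessions <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    kept: list[LocusAlignment] = []
    report: dict[str, str] = {}
    for locus in loci:
        if locus.n_accessions < min_accessions:
            report[locus.locus_id] = "too-few-accessions"
            continue
        if locus.length < min_length:
            report[locus.locus_id] = "too-short"
            continue
        if min_outgroup_identity is not None:
            ident = outgroup_identity(locus)
            if ident is None:
                report[locus.locus_id] = "no-outgroup"
                continue
            if ident < min_outgroup_identity:
                report[locus.locus_id] = "low-outgroup-identity"
                continue
        kept.append(locus)
    return kept, report


def site_table(locus: LocusAlignment) -> list[SiteRecord]:
    """Decompose a locus into one :class:`SiteRecord` per column.

    Gaps and N in accession rows are missing data here; the outgroup state
    is kept verbatim (nucleotide, gap or N) so downstream polarization can
    distinguish an outgroup gap from an uncalled base.
    """
    records: list[SiteRecord] = []
    ids = locus.accession_ids
    seqs = [seq for _, seq in locus.accessions]
    out = locus.outgroup
    for j in range(locus.length):
        states = {aid: seq[j] for aid, seq in zip(ids, seqs)}
        alleles = Counter(c for c in states.values() if c in CALLED)
        records.append(
            SiteRecord(
                column=j,
                states=states,
                outgroup_state=out[j] if out is not None else MISSING,
                n_called=sum(alleles.values()),
                alleles=dict(alleles),
            )
        )
    return records
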