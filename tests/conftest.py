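"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rarehap import LocusAlignment


def make_locus(
    seqs: dict[str, str],
    outgroup: str | None = None,
    locus_id: str = "L1",
    frames=(),
) -> LocusAlignment:
    """Build a LocusAlignment from a mapping of accession id -> sequence."""
    return LocusAlignment(
        locus_id=locus_id,
        chrom="chr1",
        position=1,
        accessions=tuple(sorted(seqs.items())),
        outgroup=outgroup,
        outgroup_id="outgroup" if outgroup is not None else None,
        frames=tuple(frames),
    )


def random_small_locus(
    rng: np.random.Generator,
    n: int | None = None,
    length: int | None = None,
    with_outgroup: bool = True,
    snp_prob: float = 0.25,
) -> LocusAlignment:
    """A random small alignment: shared backbone plus sprinkled variants."""
    n = n if n is not None else int(rng.integers(4, 11))
    length = length if length is not None else int(rng.integers(10, 31))
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=length)
    rows = np.tile(backbone, (n, 1))
    for j in range(length):
        if rng.random() < snp_prob:
            alt = (backbone[j] + rng.integers(1, 4)) % 4
            carriers = rng.random(n) < rng.uniform(0.1, 0.6)
            rows[carriers, j] = alt
    seqs = {
        f"a{i:02d}": "".join(bases[rows[i]]) for i in range(n)
    }
    out = "".join(bases[backbone]) if with_outgroup else None
    return make_locus(seqs, outgroup=out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
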