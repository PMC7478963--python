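"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from subclonekit.tumor_io import CNASegment, CNAState, SNVRecord


def make_snv(alt, total, chrom="1", pos=100, male=False, snv_id=None):
    return SNVRecord(
        id=snv_id or f"{chrom}:{pos}",
        chromosome=chrom,
        position=pos,
        alt_count=alt,
        total_count=total,
        on_male_sex_chromosome=male,
    )


def make_segment(*states, chrom="1", start=0, end=1_000_000):
    return CNASegment(
        chromosome=chrom,
        start=start,
        end=end,
        states=tuple(CNAState(n_major=a, n_minor=b) for a, b in states),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_clone_reads(rng):
    """Read counts from two prevalence clusters (0.8 and 0.3), diploid, no CNA."""
    snvs = []
    for k, rho in enumerate([0.8] * 300 + [0.3] * 300):
        depth = max(1, int(rng.poisson(120)))
        alt = int(rng.binomial(depth, rho / 2))
        snvs.append(make_snv(alt, depth, pos=k + 1, snv_id=f"s{k}"))
    return snvs
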