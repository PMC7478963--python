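"""Forward model and scenario inversion, checked against independent oracles.

The forward model is validated against a discrete-population count (build an
explicit population of cells with allele copies and count mutated alleles).
The inversion is validated against a numeric root-finder applied to the
forward model, which knows nothing about the closed-form inverses.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from subclonekit.prevalence import (
    Scenario,
    Timing,
    candidate_rhos,
    forward_beta,
    invert_beta,
)

from conftest import make_segment, make_snv


def population_beta(rho, multiplicity, n_major, n_minor, male, timing, n_cells=1000):
    """Oracle: count mutated and total alleles in an explicit cell population.

    ``rho * n_cells`` cells carry the SNV (and, in CNA scenarios, the
    copy-number event); the remaining cells are normal diploid (haploid for
    male sex chromosomes).
    """
    carriers = round(rho * n_cells)
    others = n_cells - carriers
    normal_copies = 1 if male else 2
    if timing == Timing.NO_CNA:
        mutated = carriers * 1
        total = n_cells * normal_copies
    else:
        copies = n_major if male else n_major + n_minor
        mutated = carriers * multiplicity
        total = carriers * copies + others * normal_copies
    return mutated / total


FORWARD_CASES = [
    # (rho, mult, n_major, n_minor, male, timing, expected or None->oracle only)
    (0.6, 1, None, None, False, Timing.NO_CNA, 0.3),
    (0.5, 2, 2, 1, False, Timing.WITH_CNA_MAJOR, 0.4),
    (1.0, 1, 2, 0, True, Timing.WITH_CNA_MAJOR, 0.5),
    (0.4, 1, 3, 2, False, Timing.WITH_CNA_MINOR, None),
    (0.25, 1, 2, 1, False, Timing.AFTER_CNA, None),
    (0.8, 1, None, None, True, Timing.NO_CNA, 0.8),
    (0.5, 3, 3, 0, True, Timing.WITH_CNA_MAJOR, None),
]


@pytest.mark.parametrize("rho,mult,nmaj,nmin,male,timing,expected", FORWARD_CASES)
def test_forward_beta_matches_population_count(rho, mult, nmaj, nmin, male, timing, expected):
    beta = forward_beta(rho, mult, nmaj, nmin, male_sex=male, timing=timing)
    oracle = population_beta(rho, mult, nmaj, nmin, male, timing)
    assert beta == pytest.approx(oracle, abs=1e-12)
    if expected is not None:
        assert beta == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(rho=1.2, multiplicity=1),
        dict(rho=0.5, multiplicity=0),
        dict(rho=0.5, multiplicity=2),  # NO_CNA demands multiplicity 1
        dict(rho=0.5, multiplicity=3, n_major=2, n_minor=1, timing=Timing.WITH_CNA_MAJOR),
        dict(rho=0.5, multiplicity=1, n_major=2, n_minor=0, timing=Timing.WITH_CNA_MINOR),
        dict(rho=0.5, multiplicity=2, n_major=2, n_minor=1, timing=Timing.AFTER_CNA),
    ],
)
def test_forward_beta_rejects_illegal_arguments(kwargs):
    with pytest.raises(ValueError):
        forward_beta(**kwargs)


def oracle_invert(beta, states, male):
    """Oracle: numerically solve forward_beta(rho) = beta per scenario."""
    solutions = []

    def scan(fun):
        f = lambda r: fun(r) - beta
        # forward curves are monotone in rho; bracket on [tiny, 1]
        lo, hi = 1e-12, 1.0
        if f(lo) * f(hi) <= 0:
            solutions.append(brentq(f, lo, hi, xtol=1e-13))

    if not states:
        if male:
            scan(lambda r: forward_beta(r, 1, male_sex=True))
        else:
            scan(lambda r: forward_beta(r, 1))
        return solutions
    for n_major, n_minor in states:
        if n_major < 1:
            continue
        if male:
            for m in range(1, n_major + 1):
                scan(lambda r, m=m, a=n_major: forward_beta(
                    r, m, a, 0, male_sex=True, timing=Timing.WITH_CNA_MAJOR))
            scan(lambda r, a=n_major: forward_beta(
                r, 1, a, 0, male_sex=True, timing=Timing.AFTER_CNA))
        else:
            for m in range(1, n_major + 1):
                scan(lambda r, m=m, a=n_major, b=n_minor: forward_beta(
                    r, m, a, b, timing=Timing.WITH_CNA_MAJOR))
            for m in range(1, n_minor + 1):
                scan(lambda r, m=m, a=n_major, b=n_minor: forward_beta(
                    r, m, a, b, timing=Timing.WITH_CNA_MINOR))
            scan(lambda r, a=n_major, b=n_minor: forward_beta(
                r, 1, a, b, timing=Timing.AFTER_CNA))
    # deduplicate like the implementation does
    unique = []
    for s in sorted(solutions):
        if not unique or abs(s - unique[-1]) > 1e-9:
            unique.append(s)
    return unique


INVERSION_CASES = [
    # beta, states (list of (major, minor)), male, frozen expected candidate set
    (0.4, [(2, 1)], False, {0.5}),
    (0.25, [(3, 1)], False, {1.0, 1.0 / 3.0, 0.2}),
    (0.5, [(2, 0)], True, {1.0, 1.0 / 3.0}),
    (0.2, [], False, {0.4}),
    (0.3, [], True, {0.3}),
    (0.35, [(2, 0)], False, None),  # deletion: minor scenarios absent
    (0.15, [(2, 1), (3, 0)], False, None),  # multistate pools both states
]


@pytest.mark.parametrize("beta,states,male,expected", INVERSION_CASES)
def test_inversion_matches_numeric_root_finding(beta, states, male, expected):
    segment = make_segment(*states) if states else None
    candidates = invert_beta(beta, segment, male_sex=male)
    got = sorted(c.rho for c in candidates)
    oracle = oracle_invert(beta, states, male)
    assert got == pytest.approx(oracle, abs=1e-9)
    if expected is not None:
        assert got == pytest.approx(sorted(expected), abs=1e-12)


def test_impossible_scenarios_are_discarded():
    # beta=0.4 with (2,1): single-copy scenarios invert to 4/3 > 1
    candidates = invert_beta(0.4, make_segment((2, 1)))
    assert [c.rho for c in candidates] == pytest.approx([0.5])
    assert candidates[0].multiplicity == 2
    assert candidates[0].scenario == Scenario.MAJOR_WITH_CNA


def test_zero_beta_gives_single_zero_candidate():
    for segment in (None, make_segment((3, 1))):
        candidates = invert_beta(0.0, segment)
        assert len(candidates) == 1
        assert candidates[0].rho == 0.0


def test_multistate_flag_set_only_for_multistate_segments():
    single = invert_beta(0.2, make_segment((2, 1)))
    multi = invert_beta(0.2, make_segment((2, 1), (3, 0)))
    assert not any(c.from_multistate_segment for c in single)
    assert all(c.from_multistate_segment for c in multi)


def test_homozygous_deletion_state_yields_no_scenarios():
    assert invert_beta(0.3, make_segment((0, 0))) == []


def test_round_trip_recovers_true_prevalence():
    """forward then invert must contain the generating prevalence (1e-9)."""
    rhos = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    for male in (False, True):
        for n_major in range(1, 5):
            for n_minor in ([0] if male else range(0, n_major + 1)):
                segment = make_segment((n_major, n_minor))
                cases = [(Timing.WITH_CNA_MAJOR, m) for m in range(1, n_major + 1)]
                cases += [(Timing.WITH_CNA_MINOR, m) for m in range(1, n_minor + 1)]
                cases += [(Timing.AFTER_CNA, 1)]
                for timing, mult in cases:
                    for rho in rhos:
                        beta = forward_beta(
                            rho, mult, n_major, n_minor, male_sex=male, timing=timing
                        )
                        got = invert_beta(beta, segment, male_sex=male)
                        assert any(abs(c.rho - rho) < 1e-9 for c in got), (
                            rho, mult, n_major, n_minor, male, timing
                        )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    rho=st.floats(0.001, 1.0, allow_nan=False),
    n_major=st.integers(1, 4),
    n_minor=st.integers(0, 4),
    male=st.booleans(),
    data=st.data(),
)
def test_round_trip_property(rho, n_major, n_minor, male, data):
    """Any legal (prevalence, state, timing, multiplicity) combination must
    survive a forward/inverse round trip."""
    n_minor = min(n_minor, n_major)
    if male:
        n_minor = 0
    cases = [(Timing.WITH_CNA_MAJOR, m) for m in range(1, n_major + 1)]
    cases += [(Timing.WITH_CNA_MINOR, m) for m in range(1, n_minor + 1)]
    cases += [(Timing.AFTER_CNA, 1)]
    timing, mult = data.draw(st.sampled_from(cases))
    beta = forward_beta(rho, mult, n_major, n_minor, male_sex=male, timing=timing)
    got = invert_beta(beta, make_segment((n_major, n_minor)), male_sex=male)
    assert any(abs(c.rho - rho) < 1e-9 for c in got)


def test_candidate_rho_is_monotone_in_beta():
    betas = np.linspace(0.01, 0.32, 50)
    prev = -1.0
    for beta in betas:
        (cand,) = [
            c
            for c in invert_beta(float(beta), make_segment((2, 1)))
            if c.scenario == Scenario.MAJOR_WITH_CNA and c.multiplicity == 2
        ]
        assert cand.rho > prev
        prev = cand.rho


def test_candidates_stay_inside_unit_interval(rng):
    for _ in range(200):
        beta = float(rng.uniform(0, 1))
        n_major = int(rng.integers(1, 5))
        n_minor = int(rng.integers(0, n_major + 1))
        for male in (False, True):
            for c in invert_beta(beta, make_segment((n_major, n_minor)), male_sex=male):
                assert 0.0 <= c.rho <= 1.0


def test_candidate_rhos_uses_snv_fields():
    snv = make_snv(40, 100, male=False)
    assert [c.rho for c in candidate_rhos(snv)] == pytest.approx([0.8])
    snv_male = make_snv(40, 100, chrom="X", male=True)
    assert [c.rho for c in candidate_rhos(snv_male)] == pytest.approx([0.4])
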