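"""Cellular-prevalence inversion from observed allele frequencies.

For each SNV the fraction of cells carrying it (rho) is recovered from its
variant allele frequency (beta) given the copy-number context.  Because the
order of the SNV and any copy-number events at the locus is unknown, every
possible timing scenario is enumerated:

* no copy-number event: ``beta = rho/2`` on diploid loci, ``beta = rho`` on
  male sex chromosomes;
* SNV before/during the event on the amplified (major) haplotype, carried by
  ``m`` in ``1..N_major`` copies:
  ``beta = m*rho / ((N_major+N_minor)*rho + 2*(1-rho))``;
* SNV on the minor haplotype, ``m`` in ``1..N_minor`` (skipped entirely when
  the minor allele is deleted);
* SNV after the event, necessarily on a single copy (``m = 1``);
* male sex chromosomes use the haploid denominator
  ``N_major*rho + (1-rho)``.

Scenarios whose inverted prevalence exceeds 1 are impossible and discarded;
a prevalence of exactly 1 (a clonal mutation) is kept.  Scenarios that give
analytically identical prevalences (e.g. single-copy major vs minor) are
collapsed to one candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .tumor_io import CNASegment, SNVRecord

__all__ = [
    "Timing",
    "Scenario",
    "ScenarioCandidate",
    "forward_beta",
    "candidate_rhos",
    "invert_beta",
    "RHO_DUPLICATE_TOL",
]

#: candidates closer than this are considered the same scenario outcome
RHO_DUPLICATE_TOL = 1e-12

#: numerical guard for the "discard rho > 1" rule: analytic rho == 1 must
#: survive a forward/inverse float round trip
_RHO_ONE_SLACK = 1e-9


class Timing(str, Enum):
    """When the SNV occurred relative to the copy-number event at its locus."""

    NO_CNA = "no_cna"
    WITH_CNA_MAJOR = "with_cna_major"
    WITH_CNA_MINOR = "with_cna_minor"
    AFTER_CNA = "after_cna"


class Scenario(str, Enum):
    NO_CNA = "no_cna"
    MAJOR_WITH_CNA = "major_with_cna"
    MINOR_WITH_CNA = "minor_with_cna"
    AFTER_CNA = "after_cna"
    MALE_NO_CNA = "male_no_cna"
    MALE_WITH_CNA = "male_with_cna"
    MALE_AFTER_CNA = "male_after_cna"


@dataclass(frozen=True, slots=True)
class ScenarioCandidate:
    """One (SNV, timing scenario, multiplicity) -> inferred prevalence."""

    snv_id: str
    scenario: Scenario
    multiplicity: int
    rho: float
    from_multistate_segment: bool = False


def forward_beta(
    rho: float,
    multiplicity: int,
    n_major: int | None = None,
    n_minor: int | None = None,
    *,
    male_sex: bool = False,
    timing: Timing = Timing.NO_CNA,
) -> float:
    """Expected allele frequency of an SNV carried by ``multiplicity`` copies
    in a fraction ``rho`` of cells.

    This is the shared forward model of the simulator and of the
    inversion/assignment machinery.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho {rho} outside [0, 1]")
    if multiplicity < 1:
        raise ValueError("multiplicity must be a positive integer")

    if timing == Timing.NO_CNA:
        if multiplicity != 1:
            raise ValueError("multiplicity must be 1 without a copy-number event")
        return rho if male_sex else rho / 2.0

    if n_major is None or n_major < 1:
        raise ValueError("a copy-number scenario requires n_major >= 1")
    n_minor = 0 if male_sex else int(n_minor or 0)

    if timing == Timing.WITH_CNA_MAJOR:
        if multiplicity > n_major:
            raise ValueError(f"multiplicity {multiplicity} > n_major {n_major}")
    elif timing == Timing.WITH_CNA_MINOR:
        if male_sex:
            raise ValueError("male sex chromosomes carry no minor haplotype")
        if n_minor < 1 or multiplicity > n_minor:
            raise ValueError(f"multiplicity {multiplicity} > n_minor {n_minor}")
    elif timing == Timing.AFTER_CNA:
        if multiplicity != 1:
            raise ValueError("an SNV arising after the event sits on one copy")
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown timing {timing}")

    if male_sex:
        denominator = n_major * rho + (1.0 - rho)
    else:
        denominator = (n_major + n_minor) * rho + 2.0 * (1.0 - rho)
    if denominator <= 0.0:
        raise ValueError("degenerate locus: no allele copies present")
    return multiplicity * rho / denominator


def _append_candidate(
    out: list[ScenarioCandidate],
    snv_id: str,
    scenario: Scenario,
    multiplicity: int,
    numerator: float,
    denominator: float,
    multistate: bool,
) -> None:
    # denominator <= 0 means the scenario demands a negative prevalence
    if denominator <= RHO_DUPLICATE_TOL:
        return
    rho = numerator / denominator
    if rho > 1.0 + _RHO_ONE_SLACK:
        return  # impossible scenario: discard
    rho = min(rho, 1.0)
    for existing in out:
        if abs(existing.rho - rho) <= RHO_DUPLICATE_TOL:
            return
    out.append(
        ScenarioCandidate(
            snv_id=snv_id,
            scenario=scenario,
            multiplicity=multiplicity,
            rho=rho,
            from_multistate_segment=multistate,
        )
    )


def candidate_rhos(
    snv: SNVRecord, segment: CNASegment | None = None
) -> list[ScenarioCandidate]:
    """Invert the SNV's allele frequency under every possible scenario.

    Returns the deduplicated candidate prevalences; an empty list means every
    scenario was impossible (all inverted values exceeded 1).
    """
    return invert_beta(
        snv.beta,
        segment,
        male_sex=snv.on_male_sex_chromosome,
        snv_id=snv.id,
    )


def invert_beta(
    beta: float,
    segment: CNASegment | None = None,
    *,
    male_sex: bool = False,
    snv_id: str = "",
) -> list[ScenarioCandidate]:
    """Scenario inversion on a bare allele frequency (see candidate_rhos)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0, 1]")
    male = male_sex
    multistate = segment is not None and segment.multistate

    if beta == 0.0:
        scenario = Scenario.MALE_NO_CNA if male else Scenario.NO_CNA
        return [
            ScenarioCandidate(
                snv_id=snv_id,
                scenario=scenario,
                multiplicity=1,
                rho=0.0,
                from_multistate_segment=multistate,
            )
        ]

    candidates: list[ScenarioCandidate] = []
    if segment is None:
        if male:
            _append_candidate(candidates, snv_id, Scenario.MALE_NO_CNA, 1, beta, 1.0, False)
        else:
            _append_candidate(candidates, snv_id, Scenario.NO_CNA, 1, 2.0 * beta, 1.0, False)
        return candidates

    for state in segment.states:
        n_major, n_minor = state.n_major, state.n_minor
        if n_major < 1:
            continue  # homozygous deletion: no allele left to carry an SNV
        if male:
            for m in range(1, n_major + 1):
                denom = m + beta - beta * n_major
                _append_candidate(
                    candidates, snv_id, Scenario.MALE_WITH_CNA, m, beta, denom, multistate
                )
            denom = 1.0 + beta - beta * n_major
            _append_candidate(
                candidates, snv_id, Scenario.MALE_AFTER_CNA, 1, beta, denom, multistate
            )
        else:
            total = n_major + n_minor
            for m in range(1, n_major + 1):
                denom = m + 2.0 * beta - beta * total
                _append_candidate(
                    candidates, snv_id, Scenario.MAJOR_WITH_CNA, m, 2.0 * beta, denom, multistate
                )
            for m in range(1, n_minor + 1):
                denom = m + 2.0 * beta - beta * total
                _append_candidate(
                    candidates, snv_id, Scenario.MINOR_WITH_CNA, m, 2.0 * beta, denom, multistate
                )
            denom = 1.0 + 2.0 * beta - beta * total
            _append_candidate(
                candidates, snv_id, Scenario.AFTER_CNA, 1, 2.0 * beta, denom, multistate
            )
    return candidates
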