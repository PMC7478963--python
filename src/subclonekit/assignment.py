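"""Binomial-likelihood assignment of SNVs to subclones and mixture weights.

Each subclone j with prevalence rho_j predicts a small set of expected allele
frequencies beta_hat for an SNV, one per admissible timing/multiplicity
scenario at the SNV's copy-number context.  The likelihood that SNV k belongs
to subclone j is the binomial probability of its read counts under the best
of those expected frequencies,

    L_jk = max_scenarios Binom(m_k; r_k, beta_hat).

Subclone mixture weights w_j are fitted by expectation-maximization on the
total mixture log-likelihood sum_k ln sum_j w_j L_jk (the components L are
fixed; only the weights move, so EM monotonically increases the objective).
The association score of SNV k with subclone j is w_j * L_jk; normalized
per SNV it forms the posterior matrix P, and each SNV is hard-assigned to
its highest-scoring subclone.  SNVs on multistate segments pool the expected
frequencies of every state before the maximum, so they are assignable even
though their prevalence could not be inverted for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import binom

from .clustering import SubcloneModel
from .prevalence import RHO_DUPLICATE_TOL, Scenario
from .tumor_io import CNASegment, SegmentIndex, SNVRecord

__all__ = [
    "AssignmentResult",
    "BetaCandidate",
    "expected_beta_candidates",
    "binomial_likelihood",
    "best_likelihood",
    "fit_weights",
    "assign_all",
]


class BetaCandidate(NamedTuple):
    beta_hat: float
    scenario: Scenario
    multiplicity: int


@dataclass
class AssignmentResult:
    """Posterior SNV-to-subclone assignment.

    ``posterior`` is n x C and row-stochastic; ``hard_label`` is the row
    argmax (ties resolve to the lower index, i.e. the larger prevalence);
    ``chosen_beta_hat`` records, per (SNV, subclone), the expected allele
    frequency that maximized the binomial likelihood.
    """

    posterior: np.ndarray
    hard_label: np.ndarray
    chosen_beta_hat: np.ndarray
    weights: np.ndarray
    log_likelihood: float


def expected_beta_candidates(
    rho_j: float,
    segment: CNASegment | None = None,
    male_sex: bool = False,
) -> list[BetaCandidate]:
    """Expected allele frequencies of an SNV if it belongs to a subclone of
    prevalence ``rho_j``, one candidate per admissible scenario.

    Without a copy-number event there is a single candidate (rho/2 diploid,
    rho haploid).  With an event, per state: major-copy scenarios with
    multiplicity 2..N_major, minor-copy scenarios with multiplicity
    1..N_minor (none when the minor allele is deleted), and the single-copy
    after-event scenario.  Multistate segments pool all states' candidates.
    Duplicates are collapsed keeping the smallest multiplicity.
    """
    if not 0.0 < rho_j <= 1.0:
        raise ValueError(f"rho_j {rho_j} outside (0, 1]")

    raw: list[BetaCandidate] = []
    if segment is None:
        beta = rho_j if male_sex else rho_j / 2.0
        raw.append(BetaCandidate(beta, Scenario.MALE_NO_CNA if male_sex else Scenario.NO_CNA, 1))
    else:
        for state in segment.states:
            n_major, n_minor = state.n_major, state.n_minor
            if n_major < 1:
                continue  # homozygous deletion carries no SNV
            if male_sex:
                denom = n_major * rho_j + (1.0 - rho_j)
                raw.append(BetaCandidate(rho_j / denom, Scenario.MALE_AFTER_CNA, 1))
                for m in range(1, n_major + 1):
                    raw.append(
                        BetaCandidate(m * rho_j / denom, Scenario.MALE_WITH_CNA, m)
                    )
            else:
                denom = (n_major + n_minor) * rho_j + 2.0 * (1.0 - rho_j)
                raw.append(BetaCandidate(rho_j / denom, Scenario.AFTER_CNA, 1))
                for m in range(2, n_major + 1):
                    raw.append(
                        BetaCandidate(m * rho_j / denom, Scenario.MAJOR_WITH_CNA, m)
                    )
                for m in range(1, n_minor + 1):
                    raw.append(
                        BetaCandidate(m * rho_j / denom, Scenario.MINOR_WITH_CNA, m)
                    )

    raw.sort(key=lambda c: c.multiplicity)
    candidates: list[BetaCandidate] = []
    for cand in raw:
        beta = float(np.clip(cand.beta_hat, 0.0, 1.0))
        if any(abs(beta - kept.beta_hat) <= RHO_DUPLICATE_TOL for kept in candidates):
            continue
        candidates.append(BetaCandidate(beta, cand.scenario, cand.multiplicity))
    return candidates


def binomial_likelihood(m: int, r: int, beta_hat: float) -> float:
    """Binomial pmf C(r,m) beta^m (1-beta)^(r-m), with 0^0 = 1."""
    if not 0 <= m <= r:
        raise ValueError(f"alt count {m} outside [0, {r}]")
    if not 0.0 <= beta_hat <= 1.0:
        raise ValueError(f"expected frequency {beta_hat} outside [0, 1]")
    return float(binom.pmf(m, r, beta_hat))


def best_likelihood(
    snv: SNVRecord,
    rho_j: float,
    segment: CNASegment | None = None,
    male_sex: bool | None = None,
) -> tuple[float, float]:
    """Likelihood of the SNV under the best scenario of subclone ``rho_j``.

    Returns ``(L_jk, chosen beta_hat)``; ties prefer the smaller multiplicity.
    """
    if male_sex is None:
        male_sex = snv.on_male_sex_chromosome
    candidates = expected_beta_candidates(rho_j, segment, male_sex)
    best_l, best_beta = -1.0, 0.0
    for cand in candidates:  # ordered by increasing multiplicity
        likelihood = float(binom.pmf(snv.alt_count, snv.total_count, cand.beta_hat))
        if likelihood > best_l:
            best_l, best_beta = likelihood, cand.beta_hat
    return best_l, best_beta


def fit_weights(
    L: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Maximize ``sum_k ln sum_j w_j L_jk`` over the weight simplex by EM.

    Components are fixed, so each EM step is the closed-form responsibility
    average and the objective is monotonically non-decreasing.  SNVs whose
    likelihood row is entirely zero carry no information and are dropped
    with a warning.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2:
        raise ValueError("likelihood matrix must be 2-dimensional")
    if np.any(L < 0):
        raise ValueError("likelihoods must be non-negative")
    usable = L.sum(axis=1) > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} SNVs with zero likelihood under every subclone "
            "were dropped from the weight fit",
            stacklevel=2,
        )
    L = L[usable]
    if L.shape[0] == 0:
        raise ValueError("no SNV has positive likelihood under any subclone")

    n, C = L.shape
    weights = np.full(C, 1.0 / C)
    log_likelihood = -np.inf
    for _ in range(max_iter):
        mixture = np.maximum(L @ weights, 1e-300)
        new_ll = float(np.log(mixture).sum())
        if new_ll - log_likelihood < tol and np.isfinite(log_likelihood):
            log_likelihood = new_ll
            break
        log_likelihood = new_ll
        responsibilities = L * weights / mixture[:, None]
        weights = responsibilities.mean(axis=0)
    return weights, log_likelihood


def _group_key(segment: CNASegment | None, male: bool):
    if segment is None:
        return (None, male)
    return ((segment.chromosome, segment.start, segment.end), male)


def assign_all(
    snvs: Sequence[SNVRecord],
    subclone_model: SubcloneModel,
    segments: Sequence[CNASegment],
    *,
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
) -> AssignmentResult:
    """Assign every SNV to a subclone by weighted binomial likelihood.

    Also writes ``weights`` and per-subclone ``snv_support`` counts back into
    the subclone model.
    """
    index = SegmentIndex(segments)
    n = len(snvs)
    C = subclone_model.n_subclones
    if n == 0:
        raise ValueError("no SNVs to assign")

    alt = np.array([s.alt_count for s in snvs], dtype=float)
    total = np.array([s.total_count for s in snvs], dtype=float)

    # SNVs sharing a copy-number context share candidate expected frequencies,
    # so likelihoods are computed per (segment, sex) group, vectorized over
    # the group's members.
    groups: dict = {}
    group_segment: dict = {}
    for k, snv in enumerate(snvs):
        seg = index.lookup(snv)
        key = _group_key(seg, snv.on_male_sex_chromosome)
        groups.setdefault(key, []).append(k)
        group_segment[key] = seg

    L = np.zeros((n, C))
    chosen_beta = np.zeros((n, C))
    for key, members in groups.items():
        seg = group_segment[key]
        male = key[1]
        rows = np.asarray(members, dtype=int)
        for j, rho_j in enumerate(subclone_model.peaks):
            candidates = expected_beta_candidates(float(rho_j), seg, male)
            betas = np.array([c.beta_hat for c in candidates])
            pmf = binom.pmf(alt[rows][None, :], total[rows][None, :], betas[:, None])
            best = np.argmax(pmf, axis=0)  # first max: smallest multiplicity wins
            L[rows, j] = pmf[best, np.arange(rows.size)]
            chosen_beta[rows, j] = betas[best]

    weights, log_likelihood = fit_weights(L, tol=em_tol, max_iter=em_max_iter)

    scores = L * weights
    row_sums = scores.sum(axis=1)
    # fall back to unweighted likelihoods (then to uniform) for rows that a
    # zero weight or zero likelihood would otherwise leave unnormalizable
    dead = row_sums <= 0
    if np.any(dead):
        scores[dead] = L[dead]
        row_sums = scores.sum(axis=1)
        still_dead = row_sums <= 0
        scores[still_dead] = 1.0
        row_sums = scores.sum(axis=1)
    posterior = scores / row_sums[:, None]
    hard_label = np.argmax(posterior, axis=1)

    support = np.bincount(hard_label, minlength=C)
    subclone_model.weights = weights
    subclone_model.snv_support = support

    return AssignmentResult(
        posterior=posterior,
        hard_label=hard_label,
        chosen_beta_hat=chosen_beta,
        weights=weights,
        log_likelihood=log_likelihood,
    )
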