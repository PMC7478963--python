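"""Reproducible recovery experiments over batches of simulated tumors.

These drive the package's own validation: clone-count error rates as a
function of SNV count (the robustness experiment) and end-to-end parameter
recovery (purity, clone count, assignment accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import InferenceConfig, run_inference_records
from .simulator import SimulationConfig, simulate_tumor

__all__ = [
    "RecoverySummary",
    "clone_count_error_rate",
    "parameter_recovery",
]


@dataclass(frozen=True)
class RecoverySummary:
    n_replicates: int
    median_purity_error: float
    clone_count_accuracy: float
    median_assignment_accuracy: float


def _assignment_accuracy(tumor, result) -> float:
    """Hard-assignment accuracy against truth for SNVs off multistate
    segments, mapping each true clone to the nearest inferred peak."""
    truth = tumor.truth
    peaks = np.asarray(result.model.peaks)
    mapped = np.argmin(
        np.abs(peaks[None, :] - truth.clone_prevalence[:, None]), axis=1
    )
    keep = ~truth.snv_on_multistate
    return float(
        np.mean(mapped[truth.snv_clone[keep]] == result.assignment.hard_label[keep])
    )


def clone_count_error_rate(
    *,
    n_snvs: int,
    n_replicates: int = 100,
    n_subclones: int = 4,
    seed: int = 0,
    min_prevalence_gap: float = 0.1,
    purity_range: tuple[float, float] = (0.6, 0.95),
    mean_depth: float = 100.0,
    min_clone_snvs: int = 20,
) -> float:
    """Fraction of simulated tumors whose inferred clone count is wrong.

    Each replicate draws its purity uniformly from ``purity_range``, splits
    ``n_snvs`` among the clones by a Dirichlet draw (each clone at least
    ``min_clone_snvs``), samples depth-``mean_depth`` binomial read counts
    without copy-number events, and runs the full inference.
    """
    rng = np.random.default_rng(seed)
    config = InferenceConfig()
    wrong = 0
    for _ in range(n_replicates):
        sim = SimulationConfig(
            n_subclones=n_subclones,
            purity=float(rng.uniform(*purity_range)),
            n_snvs=n_snvs,
            mean_depth=mean_depth,
            min_prevalence_gap=min_prevalence_gap,
            cna_fraction=0.0,
            min_clone_snvs=min_clone_snvs,
            seed=int(rng.integers(2**31)),
        )
        tumor = simulate_tumor(sim)
        result = run_inference_records(tumor.snvs, tumor.segments, config)
        if result.model.n_subclones != n_subclones:
            wrong += 1
    return wrong / n_replicates


def parameter_recovery(
    *,
    n_replicates: int = 50,
    subclone_choices: tuple[int, ...] = (1, 2, 3),
    n_snvs: int = 2000,
    mean_depth: float = 100.0,
    min_prevalence_gap: float = 0.15,
    purity: float = 0.75,
    cna_fraction: float = 0.2,
    seed: int = 0,
) -> RecoverySummary:
    """End-to-end recovery of purity, clone count and assignments."""
    rng = np.random.default_rng(seed)
    config = InferenceConfig()
    purity_errors, correct, accuracies = [], 0, []
    for _ in range(n_replicates):
        C = int(rng.choice(subclone_choices))
        sim = SimulationConfig(
            n_subclones=C,
            purity=purity,
            n_snvs=n_snvs,
            mean_depth=mean_depth,
            min_prevalence_gap=min_prevalence_gap,
            cna_fraction=cna_fraction,
            seed=int(rng.integers(2**31)),
        )
        tumor = simulate_tumor(sim)
        result = run_inference_records(tumor.snvs, tumor.segments, config)
        purity_errors.append(abs(result.model.purity - purity))
        correct += result.model.n_subclones == C
        accuracies.append(_assignment_accuracy(tumor, result))
    return RecoverySummary(
        n_replicates=n_replicates,
        median_purity_error=float(np.median(purity_errors)),
        clone_count_accuracy=correct / n_replicates,
        median_assignment_accuracy=float(np.median(accuracies)),
    )
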