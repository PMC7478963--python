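"""End-to-end single-sample inference: read counts in, subclone calls out.

Stages: read inputs -> per-SNV prevalence candidates -> candidate selection
-> KDE clustering (clone count, peak prevalences, purity) -> binomial
assignment with EM-fitted mixture weights -> phylogeny enumeration and
ranking -> optional SMC-Het-style output files.  Inference is fully
deterministic; all randomness lives in the simulator.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import clustering, metrics, phylogeny, tumor_io
from .assignment import AssignmentResult, assign_all
from .clustering import SubcloneModel
from .phylogeny import PhylogenyTree, ancestor_matrix
from .prevalence import candidate_rhos
from .tumor_io import CNASegment, SegmentIndex, SNVRecord

__all__ = ["InferenceConfig", "InferenceResult", "run_inference", "run_inference_records"]

logger = logging.getLogger("subclonekit")


@dataclass
class InferenceConfig:
    """Tunable knobs of the inference pipeline (all deterministic)."""

    sex: str = "female"
    grid_resolution: float = 0.001
    merge_tolerance: float = 0.01
    prune_fraction: float = 0.01
    nocna_snv_threshold: int = 100  # strictly-greater-than rule
    em_tolerance: float = 1e-8
    em_max_iterations: int = 500
    max_tree_subclones: int = phylogeny.MAX_SUBCLONES

    def __post_init__(self) -> None:
        if not 0.0 < self.grid_resolution <= 0.1:
            raise ValueError("grid resolution must lie in (0, 0.1]")
        if self.nocna_snv_threshold < 0:
            raise ValueError("SNV threshold must be non-negative")


@dataclass
class InferenceResult:
    """Everything the pipeline inferred about one tumor sample."""

    model: SubcloneModel
    assignment: AssignmentResult
    trees: list[PhylogenyTree] = field(repr=False)
    snv_ids: list[str] = field(repr=False)

    @property
    def best_tree(self) -> PhylogenyTree:
        return self.trees[0]

    def to_prediction(self) -> metrics.Prediction:
        """Re-encode for scoring against a truth record."""
        peaks = np.asarray(self.model.peaks, dtype=float)
        return metrics.Prediction(
            purity=self.model.purity,
            clone_prevalence=peaks,
            P=self.assignment.posterior,
            ancestry=ancestor_matrix(self.best_tree),
            snv_prevalence=peaks[self.assignment.hard_label],
        )


def run_inference_records(
    snvs: Sequence[SNVRecord],
    segments: Sequence[CNASegment],
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Run the full inference on in-memory records."""
    config = config or InferenceConfig()
    if not snvs:
        raise ValueError("no usable SNVs")

    t0 = time.perf_counter()
    index = SegmentIndex(segments)
    candidates = []
    for snv in snvs:
        candidates.extend(candidate_rhos(snv, index.lookup(snv)))
    logger.info(
        "prevalence: %d candidates from %d SNVs (%.2fs)",
        len(candidates), len(snvs), time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    values = clustering.select_clustering_input(
        candidates, nocna_threshold=config.nocna_snv_threshold
    )
    model = clustering.detect_subclones(
        values,
        resolution=config.grid_resolution,
        merge_tolerance=config.merge_tolerance,
        prune_fraction=config.prune_fraction,
    )
    logger.info(
        "clustering: %d subclones, purity %.4f from %d values (%.2fs)",
        model.n_subclones, model.purity, values.size, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    assignment = assign_all(
        snvs,
        model,
        segments,
        em_tol=config.em_tolerance,
        em_max_iter=config.em_max_iterations,
    )
    logger.info(
        "assignment: log-likelihood %.2f, weights %s (%.2fs)",
        assignment.log_likelihood,
        np.array2string(assignment.weights, precision=3),
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    if model.n_subclones > config.max_tree_subclones:
        # enumeration is factorial; beyond the cap report the always-valid chain
        logger.warning(
            "%d subclones exceed the enumeration cap (%d); reporting the chain",
            model.n_subclones, config.max_tree_subclones,
        )
        trees = [phylogeny.chain_tree(model.peaks)]
    else:
        trees = phylogeny.enumerate_trees(model.peaks)
        trees = phylogeny.rank_trees(trees, model.snv_support)
    logger.info(
        "phylogeny: %d candidate trees (%.2fs)", len(trees), time.perf_counter() - t0
    )

    return InferenceResult(
        model=model,
        assignment=assignment,
        trees=trees,
        snv_ids=[s.id for s in snvs],
    )


def run_inference(
    snv_path,
    cna_path=None,
    config: InferenceConfig | None = None,
    out_dir=None,
) -> InferenceResult:
    """Run inference from input files, optionally writing output files."""
    config = config or InferenceConfig()
    snvs = tumor_io.read_snv_table(snv_path, sex=config.sex)
    segments = tumor_io.read_cna_segments(cna_path) if cna_path is not None else []
    result = run_inference_records(snvs, segments, config)
    if out_dir is not None:
        tumor_io.write_smchet_outputs(result, out_dir)
    return result
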