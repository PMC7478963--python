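"""Forward simulation of bulk-sequenced tumors with known subclone truth.

The generator builds a random subclone tree (root prevalence = purity,
children's prevalences summing to at most their parent's, pairwise peak gaps
enforced), distributes SNVs among clones by a Dirichlet draw, scatters them
over a synthetic genome, overlays allele-specific copy-number segments in
three timing regimes (SNV on the amplified haplotype, on the minor
haplotype, or after the event), computes each SNV's expected allele
frequency through the shared forward model, and samples read counts:
total depth Poisson around the configured mean (floored at 1), alternate
reads binomial at the expected frequency.

The synthetic genome is 22 autosomes plus X, 100 Mb each, tiled into 10 Mb
copy-number units.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import metrics, tumor_io
from .phylogeny import PhylogenyTree, ancestor_matrix
from .prevalence import Timing, forward_beta
from .tumor_io import CNASegment, CNAState, SNVRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedTumor",
    "simulate_tumor",
    "truth_to_prediction",
    "write_tumor",
]

_CHROMOSOME_LENGTH = 100_000_000
_TILE_LENGTH = 10_000_000
_AUTOSOMES = tuple(str(i) for i in range(1, 23))
_CHROMOSOMES = _AUTOSOMES + ("X",)

#: allele-specific copy-number states a segment may adopt (no homozygous
#: deletions: those carry no SNVs by construction)
_CNA_STATES = ((2, 1), (3, 1), (2, 0), (2, 2), (3, 2), (4, 1))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic tumor."""

    n_subclones: int = 2
    purity: float = 0.75
    n_snvs: int = 2000
    mean_depth: float = 100.0
    min_prevalence_gap: float = 0.1
    cna_fraction: float = 0.2
    multistate_fraction: float = 0.1
    sex: str = "female"
    seed: int = 0
    min_clone_snvs: int = 1
    min_child_prevalence: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subclones < 1:
            raise ValueError("need at least one subclone")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        for name in ("cna_fraction", "multistate_fraction", "min_prevalence_gap"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_snvs < self.n_subclones * self.min_clone_snvs:
            raise ValueError("not enough SNVs to give every clone its minimum")
        # pigeonhole feasibility of the prevalence-gap constraint
        needed = self.min_child_prevalence + self.min_prevalence_gap * (self.n_subclones - 1)
        if needed > self.purity + 1e-9:
            raise ValueError(
                f"infeasible configuration: {self.n_subclones} clones with pairwise "
                f"gap {self.min_prevalence_gap} cannot fit below purity {self.purity}"
            )


@dataclass
class TruthRecord:
    """Gold standard emitted alongside the simulated read counts."""

    tree: PhylogenyTree
    clone_prevalence: np.ndarray
    purity: float
    snv_clone: np.ndarray
    snv_segment: np.ndarray  # index into the segment list, -1 for none
    snv_multiplicity: np.ndarray
    snv_scenario: list[str]
    snv_prevalence: np.ndarray
    snv_on_multistate: np.ndarray


@dataclass
class SimulatedTumor:
    snvs: list[SNVRecord]
    segments: list[CNASegment]
    truth: TruthRecord
    config: SimulationConfig = field(repr=False, default=None)


def _sample_clone_tree(
    rng: np.random.Generator, config: SimulationConfig, max_attempts: int = 5000
) -> tuple[list[int], list[float]]:
    """Random valid tree: parents and prevalences honoring sum and gap rules.

    Clone prevalences are placed by stratified spread: the founder sits at the
    purity and each descendant draws uniformly within its own band of the
    remaining prevalence range, with rejection until all pairwise gaps hold.
    This emulates designed subclonal compositions (distinct, well-spread
    populations) rather than piling clones near the gap floor.  The topology
    is then drawn uniformly among all trees that are valid for those
    prevalences; the descending chain guarantees at least one exists.
    """
    from .phylogeny import enumerate_trees

    C = config.n_subclones
    if C == 1:
        return [-1], [config.purity]
    lo = config.min_child_prevalence
    hi = config.purity - config.min_prevalence_gap
    edges = np.linspace(lo, hi, C)
    for _ in range(max_attempts):
        children = [
            float(rng.uniform(edges[i], edges[i + 1])) for i in range(C - 1)
        ]
        rho = [config.purity] + sorted(children, reverse=True)
        gaps_ok = all(
            rho[i] - rho[i + 1] >= config.min_prevalence_gap for i in range(C - 1)
        )
        if not gaps_ok:
            continue
        trees = enumerate_trees(rho)
        tree = trees[int(rng.integers(0, len(trees)))]
        return list(tree.parent), rho
    raise RuntimeError(
        "failed to sample a clone tree satisfying the gap constraint; "
        "loosen min_prevalence_gap or reduce n_subclones"
    )


def _partition_snvs(
    rng: np.random.Generator, config: SimulationConfig, max_attempts: int = 1000
) -> np.ndarray:
    """Per-clone SNV counts: proportional to a Dirichlet draw, each clone at
    least ``min_clone_snvs``."""
    C, n = config.n_subclones, config.n_snvs
    for _ in range(max_attempts):
        proportions = rng.dirichlet(np.ones(C))
        counts = np.floor(proportions * n).astype(int)
        remainder = n - counts.sum()
        for j in np.argsort(-(proportions * n - counts))[:remainder]:
            counts[j] += 1
        if counts.min() >= config.min_clone_snvs:
            return counts
    raise RuntimeError("could not honor the per-clone SNV minimum; too many clones")


def _sample_segments(
    rng: np.random.Generator, config: SimulationConfig
) -> list[CNASegment]:
    tiles = [
        (chrom, start)
        for chrom in _CHROMOSOMES
        for start in range(0, _CHROMOSOME_LENGTH, _TILE_LENGTH)
    ]
    n_cna = int(round(config.cna_fraction * len(tiles)))
    if n_cna == 0:
        return []
    chosen = rng.choice(len(tiles), size=n_cna, replace=False)
    segments = []
    for tile_index in sorted(chosen):
        chrom, start = tiles[tile_index]
        states = [_CNA_STATES[rng.integers(0, len(_CNA_STATES))]]
        if rng.random() < config.multistate_fraction:
            alternatives = [s for s in _CNA_STATES if s != states[0]]
            states.append(alternatives[rng.integers(0, len(alternatives))])
        fractions = (0.5, 0.5) if len(states) > 1 else (None,)
        segments.append(
            CNASegment(
                chromosome=chrom,
                start=start,
                end=start + _TILE_LENGTH,
                states=tuple(
                    CNAState(n_major=a, n_minor=b, fraction=f)
                    for (a, b), f in zip(states, fractions)
                ),
            )
        )
    return segments


def _legal_timings(state: CNAState, male: bool) -> list[tuple[Timing, int]]:
    options: list[tuple[Timing, int]] = []
    if state.n_major >= 1:
        for m in range(1, state.n_major + 1):
            options.append((Timing.WITH_CNA_MAJOR, m))
        if not male:
            for m in range(1, state.n_minor + 1):
                options.append((Timing.WITH_CNA_MINOR, m))
        options.append((Timing.AFTER_CNA, 1))
    return options


def simulate_tumor(config: SimulationConfig) -> SimulatedTumor:
    """Generate one synthetic tumor with full truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    male = str(config.sex).lower() == "male"

    parents, rho = _sample_clone_tree(rng, config)
    counts = _partition_snvs(rng, config)
    segments = _sample_segments(rng, config)
    segment_index = tumor_io.SegmentIndex(segments)
    segment_rank = {
        (seg.chromosome, seg.start): i for i, seg in enumerate(segments)
    }

    clone_of_snv = np.repeat(np.arange(config.n_subclones), counts)

    # unique genomic positions so SNV ids (chrom:pos) are unambiguous
    n = config.n_snvs
    positions: set[tuple[int, int]] = set()
    while len(positions) < n:
        chrom_idx = rng.integers(0, len(_CHROMOSOMES), size=n - len(positions))
        pos = rng.integers(1, _CHROMOSOME_LENGTH + 1, size=n - len(positions))
        positions.update(zip(chrom_idx.tolist(), pos.tolist()))
    loci = sorted(positions)
    loci_order = rng.permutation(n)

    snvs: list[SNVRecord] = []
    seg_ids = np.full(n, -1, dtype=int)
    multiplicities = np.ones(n, dtype=int)
    scenarios: list[str] = []
    on_multistate = np.zeros(n, dtype=bool)
    prevalences = np.empty(n, dtype=float)

    for k in range(n):
        chrom_idx, position = loci[loci_order[k]]
        chrom = _CHROMOSOMES[chrom_idx]
        clone = int(clone_of_snv[k])
        clone_rho = rho[clone]
        snv_male = male and tumor_io.is_sex_chromosome(chrom)

        probe = SNVRecord(
            id=f"{chrom}:{position}",
            chromosome=chrom,
            position=int(position),
            alt_count=0,
            total_count=1,
            on_male_sex_chromosome=snv_male,
        )
        segment = segment_index.lookup(probe)

        if segment is None:
            timing, multiplicity = Timing.NO_CNA, 1
            beta = forward_beta(clone_rho, 1, male_sex=snv_male, timing=timing)
        else:
            state_idx = int(rng.integers(0, len(segment.states)))
            state = segment.states[state_idx]
            options = _legal_timings(state, snv_male)
            timing, multiplicity = options[rng.integers(0, len(options))]
            beta = forward_beta(
                clone_rho,
                multiplicity,
                state.n_major,
                state.n_minor,
                male_sex=snv_male,
                timing=timing,
            )
            seg_ids[k] = segment_rank[(segment.chromosome, segment.start)]
            on_multistate[k] = segment.multistate

        depth = max(1, int(rng.poisson(config.mean_depth)))
        alt = int(rng.binomial(depth, beta))
        snvs.append(
            SNVRecord(
                id=f"{chrom}:{position}",
                chromosome=chrom,
                position=int(position),
                alt_count=alt,
                total_count=depth,
                on_male_sex_chromosome=snv_male,
            )
        )
        multiplicities[k] = multiplicity
        scenarios.append(timing.value)
        prevalences[k] = clone_rho

    child_sum = np.zeros(config.n_subclones)
    for j, p in enumerate(parents):
        if p >= 0:
            child_sum[p] += rho[j]
    tree = PhylogenyTree(
        parent=tuple(parents),
        rho=tuple(rho),
        phi=tuple(max(r - s, 0.0) for r, s in zip(rho, child_sum)),
    )
    truth = TruthRecord(
        tree=tree,
        clone_prevalence=np.asarray(rho, dtype=float),
        purity=config.purity,
        snv_clone=clone_of_snv,
        snv_segment=seg_ids,
        snv_multiplicity=multiplicities,
        snv_scenario=scenarios,
        snv_prevalence=prevalences,
        snv_on_multistate=on_multistate,
    )
    return SimulatedTumor(snvs=snvs, segments=segments, truth=truth, config=config)


def truth_to_prediction(truth: TruthRecord) -> metrics.Prediction:
    """Re-encode a truth record in the prediction schema (one-hot P)."""
    n = truth.snv_clone.size
    C = truth.clone_prevalence.size
    P = np.zeros((n, C))
    P[np.arange(n), truth.snv_clone] = 1.0
    return metrics.Prediction(
        purity=truth.purity,
        clone_prevalence=np.asarray(truth.clone_prevalence, dtype=float),
        P=P,
        ancestry=ancestor_matrix(truth.tree),
        snv_prevalence=np.asarray(truth.snv_prevalence, dtype=float),
    )


def write_tumor(tumor: SimulatedTumor, out_dir) -> None:
    """Write the input tables plus truth files (JSON and challenge layout)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tumor_io.write_snv_table(tumor.snvs, out / "snv.tsv")
    tumor_io.write_cna_table(tumor.segments, out / "cna.tsv")

    truth = tumor.truth
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    payload = {
        "purity": truth.purity,
        "clone_prevalence": [float(r) for r in truth.clone_prevalence],
        "tree_parents": list(truth.tree.parent),
        "snv_clone": truth.snv_clone.tolist(),
        "snv_prevalence": truth.snv_prevalence.tolist(),
        "snv_multiplicity": truth.snv_multiplicity.tolist(),
        "snv_scenario": truth.snv_scenario,
        "snv_on_multistate": truth.snv_on_multistate.astype(int).tolist(),
    }
    (truth_dir / "truth.json").write_text(
        json.dumps(payload, indent=1), encoding="utf-8"
    )

    support = np.bincount(truth.snv_clone, minlength=truth.clone_prevalence.size)

    class _TruthView:
        model = type(
            "M",
            (),
            {
                "peaks": truth.clone_prevalence,
                "purity": truth.purity,
                "n_subclones": int(truth.clone_prevalence.size),
                "snv_support": support,
            },
        )()
        assignment = type("A", (), {"hard_label": truth.snv_clone})()
        best_tree = truth.tree

    tumor_io.write_smchet_outputs(_TruthView(), truth_dir)
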