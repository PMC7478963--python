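"""Readers and writers for bulk-tumor inputs and challenge-style outputs.

The canonical input interface is two tab-separated tables:

* an SNV table with columns ``chrom``, ``pos``, ``ref_count``, ``alt_count``
  (positions are 1-based, VCF convention);
* an allele-specific copy-number segment table with columns ``chrom``,
  ``start``, ``end``, ``major``, ``minor`` and an optional ``frac`` column
  (intervals are 0-based half-open, BED convention).  Rows that share an
  identical ``(chrom, start, end)`` interval are merged into one *multistate*
  segment: independent copy-number events that hit the same region in
  different subclones.

Inference results are written in the SMC-Het sub-challenge layout
(``1A.txt`` purity, ``1B.txt`` clone count, ``1C.txt`` per-cluster size and
cellular prevalence, ``2A.txt`` per-SNV cluster assignment, ``3A.txt``
cluster parent list with ``0`` denoting the normal root).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SNVRecord",
    "CNAState",
    "CNASegment",
    "SegmentIndex",
    "read_snv_table",
    "read_cna_segments",
    "read_vcf_snvs",
    "lookup_cna",
    "write_snv_table",
    "write_cna_table",
    "write_smchet_outputs",
    "read_smchet_outputs",
    "is_sex_chromosome",
]


class FormatError(ValueError):
    """A required column or file structure is missing."""


class ValidationError(ValueError):
    """A value in the file violates the input contract."""


_SEX_CHROMOSOMES = {"X", "Y"}


def is_sex_chromosome(chromosome: str) -> bool:
    """True for X/Y in any case, with or without a ``chr`` prefix."""
    name = str(chromosome).strip().upper()
    if name.startswith("CHR"):
        name = name[3:]
    return name in _SEX_CHROMOSOMES


@dataclass(frozen=True, slots=True)
class SNVRecord:
    """One somatic variant with its read support.

    ``beta`` is the observed variant allele frequency, alt_count/total_count.
    ``on_male_sex_chromosome`` is set when the variant lies on X or Y *and*
    the sample is male, in which case the locus carries a single allele copy
    in normal cells and the haploid prevalence equations apply.
    """

    id: str
    chromosome: str
    position: int
    alt_count: int
    total_count: int
    on_male_sex_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValidationError(f"SNV {self.id}: total read count must be positive")
        if self.alt_count < 0 or self.alt_count > self.total_count:
            raise ValidationError(
                f"SNV {self.id}: alt count {self.alt_count} outside [0, {self.total_count}]"
            )
        if self.position < 1:
            raise ValidationError(f"SNV {self.id}: position must be 1-based positive")

    @property
    def beta(self) -> float:
        """Observed variant allele frequency m_k / r_k."""
        return self.alt_count / self.total_count


@dataclass(frozen=True, slots=True)
class CNAState:
    """One (major, minor) allele copy-number configuration of a segment."""

    n_major: int
    n_minor: int
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValidationError(
                f"copy-number state requires major >= minor >= 0, got "
                f"({self.n_major}, {self.n_minor})"
            )
        if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
            raise ValidationError(f"state fraction {self.fraction} outside (0, 1]")

    @property
    def is_homozygous_deletion(self) -> bool:
        return self.n_major == 0 and self.n_minor == 0


@dataclass(frozen=True, slots=True)
class CNASegment:
    """A genomic interval carrying one or more copy-number states.

    Multiple states on one interval encode copy-number events that occurred
    independently in different subclones ("2-state" / "multistate" regions).
    """

    chromosome: str
    start: int
    end: int
    states: tuple[CNAState, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end}: start must be < end"
            )
        if not self.states:
            raise ValidationError("segment must carry at least one state")
        total = sum(s.fraction for s in self.states if s.fraction is not None)
        if total > 1.0 + 1e-9:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                f"state fractions sum to {total:.4f} > 1"
            )

    @property
    def multistate(self) -> bool:
        return len(self.states) > 1

    def contains(self, position0: int) -> bool:
        """Membership test on a 0-based coordinate."""
        return self.start <= position0 < self.end


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for column in required:
        if column not in df.columns:
            raise FormatError(f"{path}: missing required column {column!r}")


def read_snv_table(path, sex: str = "female") -> list[SNVRecord]:
    """Read the tab-separated SNV table.

    ``sex`` controls whether X/Y variants are treated as haploid ("male")
    or diploid ("female", the default).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("chrom", "pos", "ref_count", "alt_count"), path)
    male = str(sex).lower() == "male"
    records: list[SNVRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        chrom = str(getattr(row, "chrom"))
        pos = int(getattr(row, "pos"))
        ref = int(getattr(row, "ref_count"))
        alt = int(getattr(row, "alt_count"))
        if ref < 0 or alt < 0:
            raise ValidationError(f"{path}: line {i}: negative read count")
        total = ref + alt
        if total == 0:
            raise ValidationError(f"{path}: line {i}: zero total depth")
        records.append(
            SNVRecord(
                id=f"{chrom}:{pos}",
                chromosome=chrom,
                position=pos,
                alt_count=alt,
                total_count=total,
                on_male_sex_chromosome=male and is_sex_chromosome(chrom),
            )
        )
    return records


def read_vcf_snvs(path, sex: str = "female") -> list[SNVRecord]:
    """Optional convenience reader for MuTect-style VCFs (needs cyvcf2).

    Allele depths are taken from the first sample's ``AD`` field; multiallelic
    records use the first alternate allele.  The TSV table remains the
    canonical interface.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF reading requires the optional cyvcf2 dependency") from exc
    male = str(sex).lower() == "male"
    records: list[SNVRecord] = []
    for variant in VCF(str(path)):
        ad = variant.format("AD")
        if ad is None:
            continue
        ref_depth = int(ad[0][0])
        alt_depth = int(ad[0][1])
        if ref_depth < 0 or alt_depth < 0 or ref_depth + alt_depth == 0:
            continue
        chrom = str(variant.CHROM)
        records.append(
            SNVRecord(
                id=f"{chrom}:{variant.POS}",
                chromosome=chrom,
                position=int(variant.POS),
                alt_count=alt_depth,
                total_count=ref_depth + alt_depth,
                on_male_sex_chromosome=male and is_sex_chromosome(chrom),
            )
        )
    return records


def read_cna_segments(path) -> list[CNASegment]:
    """Read the copy-number segment table, merging multistate rows.

    Rows with identical ``(chrom, start, end)`` become one segment with
    several states.  Distinct intervals on a chromosome must not overlap.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("chrom", "start", "end", "major", "minor"), path)
    has_frac = "frac" in df.columns

    grouped: dict[tuple[str, int, int], list[CNAState]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        chrom = str(getattr(row, "chrom"))
        start = int(getattr(row, "start"))
        end = int(getattr(row, "end"))
        major = int(getattr(row, "major"))
        minor = int(getattr(row, "minor"))
        if major < minor:
            raise ValidationError(f"{path}: line {i}: major copy number < minor")
        fraction = None
        if has_frac:
            raw = getattr(row, "frac")
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                fraction = float(raw)
        key = (chrom, start, end)
        try:
            state = CNAState(n_major=major, n_minor=minor, fraction=fraction)
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        grouped.setdefault(key, []).append(state)

    segments = [
        CNASegment(chromosome=c, start=s, end=e, states=tuple(states))
        for (c, s, e), states in grouped.items()
    ]
    segments.sort(key=lambda seg: (seg.chromosome, seg.start, seg.end))
    previous: dict[str, CNASegment] = {}
    for seg in segments:
        last = previous.get(seg.chromosome)
        if last is not None and seg.start < last.end:
            raise ValidationError(
                f"{path}: overlapping segments on {seg.chromosome}: "
                f"[{last.start}, {last.end}) and [{seg.start}, {seg.end})"
            )
        previous[seg.chromosome] = seg
    return segments


class SegmentIndex:
    """Per-chromosome binary-search index over validated, sorted segments."""

    def __init__(self, segments: Iterable[CNASegment]):
        by_chrom: dict[str, list[CNASegment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        self._starts: dict[str, list[int]] = {}
        self._segments: dict[str, list[CNASegment]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            self._starts[chrom] = [s.start for s in segs]
            self._segments[chrom] = segs

    def lookup(self, snv: SNVRecord) -> CNASegment | None:
        """Segment containing the SNV, or None when no copy-number event covers it."""
        starts = self._starts.get(snv.chromosome)
        if starts is None:
            return None
        position0 = snv.position - 1  # 1-based SNV to 0-based interval space
        i = bisect_right(starts, position0) - 1
        if i < 0:
            return None
        seg = self._segments[snv.chromosome][i]
        return seg if seg.contains(position0) else None


def lookup_cna(snv: SNVRecord, segments: Sequence[CNASegment]) -> CNASegment | None:
    """Find the unique segment covering the SNV (None means no CNA event)."""
    return SegmentIndex(segments).lookup(snv)


def write_snv_table(snvs: Sequence[SNVRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("chrom\tpos\tref_count\talt_count\n")
        for snv in snvs:
            ref = snv.total_count - snv.alt_count
            handle.write(f"{snv.chromosome}\t{snv.position}\t{ref}\t{snv.alt_count}\n")


def write_cna_table(segments: Sequence[CNASegment], path) -> None:
    any_frac = any(s.fraction is not None for seg in segments for s in seg.states)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        header = "chrom\tstart\tend\tmajor\tminor"
        handle.write(header + ("\tfrac\n" if any_frac else "\n"))
        for seg in segments:
            for state in seg.states:
                row = f"{seg.chromosome}\t{seg.start}\t{seg.end}\t{state.n_major}\t{state.n_minor}"
                if any_frac:
                    frac = "" if state.fraction is None else _fmt(state.fraction)
                    row += f"\t{frac}"
                handle.write(row + "\n")


def _fmt(value: float) -> str:
    return format(float(value), ".6g")


def write_smchet_outputs(result, out_dir) -> dict[str, Path]:
    """Write the five SMC-Het sub-challenge files from an inference result.

    ``result`` must expose ``model`` (peaks, purity, snv_support),
    ``assignment`` (hard labels) and ``best_tree`` (parent array); the
    pipeline's InferenceResult does.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = result.model
    labels = result.assignment.hard_label
    support = model.snv_support
    if support is None:
        support = np.bincount(labels, minlength=model.n_subclones)
    tree = result.best_tree

    paths = {}
    paths["1A"] = out / "1A.txt"
    paths["1A"].write_text(_fmt(model.purity) + "\n", encoding="utf-8")
    paths["1B"] = out / "1B.txt"
    paths["1B"].write_text(f"{model.n_subclones}\n", encoding="utf-8")
    paths["1C"] = out / "1C.txt"
    lines = [
        f"{j + 1}\t{int(support[j])}\t{_fmt(model.peaks[j])}"
        for j in range(model.n_subclones)
    ]
    paths["1C"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["2A"] = out / "2A.txt"
    paths["2A"].write_text("".join(f"{int(j) + 1}\n" for j in labels), encoding="utf-8")
    paths["3A"] = out / "3A.txt"
    parents = ["0" if p < 0 else str(p + 1) for p in tree.parent]
    paths["3A"].write_text("\n".join(parents) + "\n", encoding="utf-8")
    return paths


@dataclass(frozen=True)
class SmchetFiles:
    """Parsed contents of an SMC-Het-style output directory."""

    purity: float
    n_clones: int
    cluster_sizes: np.ndarray
    cluster_prevalence: np.ndarray
    assignments: np.ndarray  # 0-based cluster index per SNV
    parents: np.ndarray  # 0-based parent per cluster, -1 for the root


def read_smchet_outputs(directory) -> SmchetFiles:
    d = Path(directory)
    purity = float(d.joinpath("1A.txt").read_text().strip())
    n_clones = int(d.joinpath("1B.txt").read_text().strip())
    sizes, prevalence = [], []
    for line in d.joinpath("1C.txt").read_text().strip().splitlines():
        _, size, rho = line.split("\t")
        sizes.append(int(size))
        prevalence.append(float(rho))
    assignments = np.array(
        [int(x) - 1 for x in d.joinpath("2A.txt").read_text().split()], dtype=int
    )
    parents = np.array(
        [int(x) - 1 for x in d.joinpath("3A.txt").read_text().split()], dtype=int
    )
    if len(sizes) != n_clones or len(parents) != n_clones:
        raise FormatError(f"{d}: inconsistent cluster counts across 1B/1C/3A")
    return SmchetFiles(
        purity=purity,
        n_clones=n_clones,
        cluster_sizes=np.array(sizes, dtype=int),
        cluster_prevalence=np.array(prevalence, dtype=float),
        assignments=assignments,
        parents=parents,
    )
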