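"""Allele-specific copy-number profiles and whole-genome-doubling (WGD) calls.

A tumor genome is represented as a set of non-overlapping segments, each
carrying an integer major and minor allele copy number (MCN, mcn >= minor).
Two decision rules classify a sample as genome-doubled:

* **MCN rule** — WGD+ when more than 50% of the covered genome has a major
  allele copy number of two or more (a duplication of at least one allele).
* **LOH rule** — WGD+ when cancer-cell ploidy exceeds ``2.5 - 1.25 * FracLOH``,
  where FracLOH is the length fraction of the genome with minor copy number
  zero (loss of heterozygosity).

Both thresholds are strict: a sample sitting exactly on the boundary is WGD-.
All length-weighted statistics are computed over the covered genome only (the
sum of segment lengths), because exome-derived profiles have gaps between
segments.  Sex chromosomes are excluded by default: hemizygous X/Y would
inflate FracLOH in males.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CNSegment",
    "CNProfile",
    "WGDCall",
    "EmptyProfileError",
    "fraction_mcn_ge2",
    "tumor_ploidy",
    "frac_loh",
    "call_wgd_mcn",
    "call_wgd_loh",
]

#: chromosome labels treated as sex chromosomes (case-insensitive, with or
#: without a "chr" prefix; 23/24 are the numeric aliases some callers emit).
SEX_CHROMOSOMES = frozenset({"x", "y", "23", "24"})

MCN_FRACTION_THRESHOLD = 0.5  # strict ">": exactly half the genome is WGD-


class EmptyProfileError(ValueError):
    """Raised when a statistic is requested on a profile with no usable segments."""


def _is_sex_chromosome(label: str) -> bool:
    name = str(label).lower()
    if name.startswith("chr"):
        name = name[3:]
    return name in SEX_CHROMOSOMES


@dataclass(frozen=True)
class CNSegment:
    """One genomic segment with allele-specific integer copy numbers.

    Coordinates are 0-based half-open, so ``end - start`` is the segment
    length in bases.
    """

    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        for attr in ("start", "end", "major_cn", "minor_cn"):
            value = getattr(self, attr)
            if not float(value).is_integer():
                raise ValueError(f"{attr} must be an integer, got {value!r}")
            object.__setattr__(self, attr, int(value))
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start, got [{self.start}, {self.end})"
            )
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValueError(
                "copy numbers must satisfy major_cn >= minor_cn >= 0, got "
                f"major={self.major_cn} minor={self.minor_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


@dataclass
class CNProfile:
    """Segmented allele-specific copy-number profile for one tumor sample.

    ``purity`` is the tumor-cell fraction of the biopsy the profile was fit
    from; it is carried as metadata (copy numbers are already cancer-cell
    states) and not used by the WGD statistics.
    """

    sample_id: str
    segments: Sequence[CNSegment] = field(default_factory=list)
    purity: float = 1.0

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        self._check_non_overlapping()

    def _check_non_overlapping(self) -> None:
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"sample {self.sample_id!r}: overlapping segments on "
                        f"{chrom}: [{prev.start}, {prev.end}) and "
                        f"[{cur.start}, {cur.end})"
                    )

    def included_segments(self, include_sex_chromosomes: bool = False) -> tuple[CNSegment, ...]:
        if include_sex_chromosomes:
            return tuple(self.segments)
        return tuple(s for s in self.segments if not _is_sex_chromosome(s.chromosome))


@dataclass(frozen=True)
class WGDCall:
    """A per-sample WGD decision together with the statistics behind it."""

    sample_id: str
    method: str  # "MCN" or "LOH"
    is_wgd: bool
    mcn_fraction: float
    ploidy: float
    frac_loh: float
    threshold_used: float


def _segment_arrays(
    profile: CNProfile, include_sex_chromosomes: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    segs = profile.included_segments(include_sex_chromosomes)
    if not segs:
        raise EmptyProfileError(
            f"sample {profile.sample_id!r} has no copy-number segments "
            "(after sex-chromosome exclusion)" if profile.segments else
            f"sample {profile.sample_id!r} has no copy-number segments"
        )
    lengths = np.array([s.length for s in segs], dtype=float)
    major = np.array([s.major_cn for s in segs], dtype=float)
    minor = np.array([s.minor_cn for s in segs], dtype=float)
    return lengths, major, minor


def fraction_mcn_ge2(profile: CNProfile, include_sex_chromosomes: bool = False) -> float:
    """Length fraction of the covered genome with major allele copy number >= 2.

    An MCN of two can only arise from a duplication of at least one allele,
    so a large value indicates a genome-scale duplication event.
    """
    lengths, major, _ = _segment_arrays(profile, include_sex_chromosomes)
    return float(lengths[major >= 2].sum() / lengths.sum())


def tumor_ploidy(profile: CNProfile, include_sex_chromosomes: bool = False) -> float:
    """Length-weighted mean total copy number (copies per cancer cell)."""
    lengths, major, minor = _segment_arrays(profile, include_sex_chromosomes)
    return float(np.average(major + minor, weights=lengths))


def frac_loh(profile: CNProfile, include_sex_chromosomes: bool = False) -> float:
    """Length fraction of the covered genome with loss of heterozygosity (minor CN 0)."""
    lengths, _, minor = _segment_arrays(profile, include_sex_chromosomes)
    return float(lengths[minor == 0].sum() / lengths.sum())


def _stats(profile: CNProfile, include_sex: bool) -> tuple[float, float, float]:
    return (
        fraction_mcn_ge2(profile, include_sex),
        tumor_ploidy(profile, include_sex),
        frac_loh(profile, include_sex),
    )


def call_wgd_mcn(profile: CNProfile, include_sex_chromosomes: bool = False) -> WGDCall:
    """Classify WGD by the major-copy-number rule: WGD+ iff mcn_fraction > 0.5."""
    mcn_frac, ploidy, floh = _stats(profile, include_sex_chromosomes)
    return WGDCall(
        sample_id=profile.sample_id,
        method="MCN",
        is_wgd=mcn_frac > MCN_FRACTION_THRESHOLD,
        mcn_fraction=mcn_frac,
        ploidy=ploidy,
        frac_loh=floh,
        threshold_used=MCN_FRACTION_THRESHOLD,
    )


def call_wgd_loh(profile: CNProfile, include_sex_chromosomes: bool = False) -> WGDCall:
    """Classify WGD by the orthogonal LOH rule: WGD+ iff ploidy > 2.5 - 1.25*FracLOH."""
    mcn_frac, ploidy, floh = _stats(profile, include_sex_chromosomes)
    threshold = 2.5 - 1.25 * floh
    return WGDCall(
        sample_id=profile.sample_id,
        method="LOH",
        is_wgd=ploidy > threshold,
        mcn_fraction=mcn_frac,
        ploidy=ploidy,
        frac_loh=floh,
        threshold_used=threshold,
    )
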