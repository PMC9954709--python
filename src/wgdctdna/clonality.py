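"""Cancer-cell-fraction (CCF) estimation, clonality filtering and assay routing.

The variant allele frequency (VAF) observed in a tumor biopsy is diluted by
normal-cell admixture and modulated by the local copy number.  The standard
purity/copy-number correction recovers the fraction of tumor cells carrying
the variant:

    CCF = VAF * (purity * CN_t + 2 * (1 - purity)) / (purity * m)

where ``CN_t`` is the tumor total copy number at the locus and ``m`` the
number of mutant-allele copies per tumor cell (multiplicity).  Mutations with
CCF below 0.9 are considered subclonal and are not used as plasma tracking
targets; the cutoff is strict, so CCF exactly 0.9 counts as clonal.

Patients whose clonal mutation list overlaps a ddPCR assay panel are routed
to ddPCR, everyone else to deep targeted sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

__all__ = [
    "MutationObservation",
    "compute_ccf",
    "estimate_multiplicity",
    "classify_clonality",
    "route_assay",
    "CLONAL_CCF_THRESHOLD",
]

CLONAL_CCF_THRESHOLD = 0.9


@dataclass(frozen=True)
class MutationObservation:
    """A somatic mutation observed in a tumor biopsy, with its CCF annotation."""

    mutation_id: str
    vaf: float
    purity: float
    total_cn: int
    multiplicity: int
    ccf: float

    @classmethod
    def from_vaf(
        cls,
        mutation_id: str,
        vaf: float,
        purity: float,
        total_cn: int,
        major_cn: int,
    ) -> "MutationObservation":
        """Annotate a raw VAF: estimate multiplicity, then compute the CCF."""
        m = estimate_multiplicity(vaf, purity, total_cn, major_cn)
        return cls(
            mutation_id=mutation_id,
            vaf=vaf,
            purity=purity,
            total_cn=total_cn,
            multiplicity=m,
            ccf=compute_ccf(vaf, purity, total_cn, m),
        )

    @property
    def is_clonal(self) -> bool:
        return classify_clonality(self.ccf) == "clonal"


def _validate(vaf: float, purity: float, total_cn: int, multiplicity: int) -> None:
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if purity <= 0.0:
        raise ValueError("purity must be positive: CCF is undefined at purity 0")
    if purity > 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if total_cn < 1:
        raise ValueError(f"total_cn must be >= 1, got {total_cn}")
    if not 1 <= multiplicity <= total_cn:
        raise ValueError(
            f"multiplicity must be in [1, total_cn], got {multiplicity} with total_cn {total_cn}"
        )


def compute_ccf(
    vaf: float, purity: float, total_cn: int, multiplicity: int, clamp: bool = True
) -> float:
    """Fraction of tumor cells carrying the variant.

    Sampling noise can push the raw estimate slightly above 1; by default it
    is clamped to [0, 1].
    """
    _validate(vaf, purity, total_cn, multiplicity)
    raw = vaf * (purity * total_cn + 2.0 * (1.0 - purity)) / (purity * multiplicity)
    if clamp:
        return min(1.0, max(0.0, raw))
    return raw


def estimate_multiplicity(vaf: float, purity: float, total_cn: int, major_cn: int) -> int:
    """Nearest-integer mutant-allele copies per tumor cell, clamped to [1, major_cn].

    Ties (x.5) round half-up.
    """
    if major_cn < 1:
        raise ValueError(f"major_cn must be >= 1, got {major_cn}")
    _validate(vaf, purity, total_cn, 1)
    raw = vaf * (purity * total_cn + 2.0 * (1.0 - purity)) / purity
    m = int(raw + 0.5)  # round half-up on a non-negative value
    return max(1, min(major_cn, m))


def classify_clonality(ccf: float) -> str:
    """Return ``"subclonal"`` when CCF < 0.9 (strict), else ``"clonal"``."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"ccf must be in [0, 1], got {ccf}")
    return "subclonal" if ccf < CLONAL_CCF_THRESHOLD else "clonal"


def route_assay(
    clonal_mutations: AbstractSet[str] | Iterable[str],
    ddpcr_panel: AbstractSet[str] | Iterable[str],
) -> str:
    """Route a patient to ``"ddPCR"`` when a clonal mutation is on the assay
    panel, otherwise to ``"sequencing"``."""
    clonal = set(clonal_mutations)
    if not clonal:
        raise ValueError("no clonal mutations: nothing to track in plasma")
    return "ddPCR" if clonal & set(ddpcr_panel) else "sequencing"
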