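"""Synthetic cohort generator: shedding x genome-copies x limit-of-detection.

Generates everything the downstream stages consume — clinicopathological
covariates, allele-specific copy-number profiles classifiable by both WGD
rules, and strand-resolved plasma read counts — under an explicit mechanism:

1. each tumor sheds DNA into plasma at a rate that grows with tumor size,
   UICC stage and depth of invasion (pT4), with heavy-tailed inter-patient
   variability (plasma tumor fractions span orders of magnitude at fixed
   stage, so the noise is Student-t on the log scale);
2. a genome-doubled (WGD+) tumor cell releases more DNA per cell — the
   released amount scales with ploidy/2 when ``ploidy_effect`` is on;
3. the assay sees the resulting plasma tumor fraction only through finite
   sequencing depth against a background error model, i.e. through a limit
   of detection.

The WGD effect on detection therefore lives entirely in step 2 and can be
ablated (``ploidy_effect=False``), and it saturates: once shedding pushes the
tumor fraction far above the limit of detection, doubling the per-cell DNA
no longer changes the outcome — which is why the WGD odds ratio shrinks from
stage I to stage III in the default configuration.

Default covariate marginals emulate a surgical colorectal cancer cohort:
stage I/II/III at 20/48/32%, WGD prevalence 54%, median tumor diameter
40 mm, positivity around 63%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cn_profile import CNProfile, CNSegment, call_wgd_mcn, tumor_ploidy
from .ctdna_caller import BackgroundModel, SampleCall, SiteCounts, call_sample, fit_background

__all__ = [
    "SheddingConfig",
    "SimConfig",
    "PatientRecord",
    "SimulatedCohort",
    "simulate_patient",
    "simulate_cn_profile",
    "shedding_tumor_fraction",
    "simulate_site_counts",
    "simulate_cohort",
]

STAGES = ("I", "II", "III")

#: approximate autosome lengths, Mb (used as the simulated genome)
AUTOSOME_MB = {
    "1": 248, "2": 242, "3": 198, "4": 190, "5": 182, "6": 171, "7": 159,
    "8": 145, "9": 138, "10": 134, "11": 135, "12": 133, "13": 114,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51,
}
_MB = 1_000_000


@dataclass(frozen=True)
class SheddingConfig:
    """Plasma tumor fraction model.

    tumor_fraction = base_rate * size_mm**size_exponent * stage_multiplier
                     * (pt4_multiplier if pT4) * (ploidy/2 if ploidy_effect)
                     * exp(noise_sigma * T), T ~ Student-t(noise_df),
    clamped to [0, 0.5].

    A ``low_shedder_fraction`` of tumors additionally shed at a small
    multiple (``low_shedder_attenuation``) of the rate their covariates
    predict — the biologically sequestered minority whose plasma signal sits
    so far below the limit of detection that doubling the per-cell DNA
    cannot rescue it.  Both the heavy-tailed noise and this mixture reflect
    the orders-of-magnitude spread of plasma tumor fractions observed at
    fixed stage and size.
    """

    base_rate: float = 4.6e-5          # tumor fraction per mm of diameter, stage I
    size_exponent: float = 1.0
    stage_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"I": 1.0, "II": 1.5, "III": 3.6}
    )
    pt4_multiplier: float = 2.5
    noise_sigma: float = 0.75           # log-scale scale of inter-patient variability
    noise_df: float = 3.0              # Student-t df; heavy tails are intentional
    low_shedder_fraction: float = 0.22
    low_shedder_attenuation: float = 0.003


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 701
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.20, "II": 0.48, "III": 0.32}
    )
    wgd_prevalence: float = 0.54
    #: per-stage (log-median mm, log-sd) of tumor diameter
    size_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (np.log(25.0), 0.40),
            "II": (np.log(45.0), 0.45),
            "III": (np.log(42.0), 0.45),
        }
    )
    shedding: SheddingConfig = field(default_factory=SheddingConfig)
    ploidy_effect: bool = True
    cfdna_genomes_sampled: int = 4000   # genome equivalents recovered from plasma
    depth_per_site: int = 15000         # raw depth; effective depth is capped by input genomes
    n_tracked_sites: int = 12
    background_error: float = 1.0e-4    # per-strand error rate after consensus correction
    n_normals: int = 46
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = [self.stage_probs.get(s, 0.0) for s in STAGES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"stage_probs must be non-negative and sum to 1, got {self.stage_probs}")
        if not 0.0 <= self.wgd_prevalence <= 1.0:
            raise ValueError("wgd_prevalence must be in [0, 1]")
        if not 1 <= self.n_tracked_sites <= 12:
            raise ValueError("n_tracked_sites must be in [1, 12]")
        if not 0.0 <= self.background_error < 1.0:
            raise ValueError("background_error must be in [0, 1)")

    @property
    def effective_depth(self) -> int:
        """Per-site depth after capping by the number of cfDNA genome
        equivalents actually sampled from plasma."""
        return min(self.depth_per_site, self.cfdna_genomes_sampled)


@dataclass
class PatientRecord:
    """One synthetic patient: covariates, ground-truth shedding, and outcome."""

    patient_id: str
    age: int
    sex: str
    uicc_stage: str
    pt_stage: str
    location: str
    size_mm: float
    histology: str
    venous_invasion: bool
    mmr: str
    wgd: bool
    ploidy: float = float("nan")
    true_tumor_fraction: float = float("nan")
    ctdna_detected: bool | None = None


@dataclass
class SimulatedCohort:
    config: SimConfig
    cohort: pd.DataFrame
    profiles: list[CNProfile]
    backgrounds: dict[str, BackgroundModel]
    counts: dict[str, list[SiteCounts]]
    calls: dict[str, SampleCall]


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

_LOCATION_PROBS = {"right colon": 0.45, "left colon": 0.32, "rectum": 0.23}
_ADENOCARCINOMA_PROB = 0.93
_MALE_PROB = 0.55
# venous invasion and MMR deficiency rates rise/fall with stage
_VENOUS_BY_STAGE = {"I": 0.12, "II": 0.22, "III": 0.52}
_MMR_DEFICIENT_BY_STAGE = {"I": 0.18, "II": 0.22, "III": 0.10}
# pT composition: stage I is pT1/pT2; stage II is mostly pT3 with a small pT4
# tail; stage III spans pT2-pT4
_PT_BY_STAGE = {
    "I": (("pT1", 0.45), ("pT2", 0.55)),
    "II": (("pT3", 0.93), ("pT4", 0.07)),
    "III": (("pT2", 0.10), ("pT3", 0.70), ("pT4", 0.20)),
}


def _choice(rng: np.random.Generator, options: Sequence[tuple[str, float]]) -> str:
    labels = [o for o, _ in options]
    probs = np.array([p for _, p in options], dtype=float)
    return str(rng.choice(labels, p=probs / probs.sum()))


def simulate_patient(config: SimConfig, rng: np.random.Generator, patient_id: str = "P0") -> PatientRecord:
    """Draw the clinicopathological covariates (and WGD status) of one patient."""
    stage = _choice(rng, [(s, config.stage_probs.get(s, 0.0)) for s in STAGES])
    log_mu, log_sd = config.size_lognormal_params[stage]
    size = float(np.round(np.exp(rng.normal(log_mu, log_sd)), 0))
    size = max(size, 3.0)
    return PatientRecord(
        patient_id=patient_id,
        age=int(np.clip(round(rng.normal(70.0, 11.0)), 26, 95)),
        sex="male" if rng.random() < _MALE_PROB else "female",
        uicc_stage=stage,
        pt_stage=_choice(rng, _PT_BY_STAGE[stage]),
        location=_choice(rng, list(_LOCATION_PROBS.items())),
        size_mm=size,
        histology="adenocarcinoma" if rng.random() < _ADENOCARCINOMA_PROB else "other",
        venous_invasion=bool(rng.random() < _VENOUS_BY_STAGE[stage]),
        mmr="deficient" if rng.random() < _MMR_DEFICIENT_BY_STAGE[stage] else "proficient",
        wgd=bool(rng.random() < config.wgd_prevalence),
    )


# ---------------------------------------------------------------------------
# copy-number profiles
# ---------------------------------------------------------------------------

# (major, minor) event states and mean genome fractions; the remainder of the
# genome stays at the baseline state.
_WGD_POS_BASELINE = (2, 2)
_WGD_POS_EVENTS = (
    ((2, 1), 0.20),   # single-copy loss after doubling
    ((2, 0), 0.10),   # LOH after doubling
    ((1, 1), 0.05),   # deep loss back to diploid
    ((3, 2), 0.08),   # further gain
)
_WGD_NEG_BASELINE = (1, 1)
_WGD_NEG_EVENTS = (
    ((2, 1), 0.18),   # single-allele gain
    ((1, 0), 0.10),   # copy-neutral-ish LOH (deletion)
    ((2, 0), 0.05),   # LOH with duplication of the remaining allele
    ((3, 1), 0.03),   # higher gain
)


def _generate_profile_once(wgd: bool, rng: np.random.Generator, sample_id: str) -> CNProfile:
    baseline = _WGD_POS_BASELINE if wgd else _WGD_NEG_BASELINE
    events = _WGD_POS_EVENTS if wgd else _WGD_NEG_EVENTS
    # per-profile event intensity scatter, so FracLOH / ploidy vary sample to sample
    scale = rng.uniform(0.4, 1.6)
    states = [baseline] + [s for s, _ in events]
    probs = np.array([f for _, f in events]) * scale
    probs = np.concatenate([[max(1.0 - probs.sum(), 0.05)], probs])
    probs /= probs.sum()
    segments: list[CNSegment] = []
    for chrom, mb in AUTOSOME_MB.items():
        n_pieces = 1 + rng.poisson(2.0)
        cuts = np.sort(rng.uniform(0, mb * _MB, size=n_pieces - 1)).astype(int)
        bounds = np.concatenate([[0], cuts, [mb * _MB]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            major, minor = states[int(rng.choice(len(states), p=probs))]
            segments.append(CNSegment(chrom, int(lo), int(hi), major, minor))
    purity = float(np.clip(rng.normal(0.55, 0.15), 0.15, 0.95))
    return CNProfile(sample_id=sample_id, segments=segments, purity=purity)


def simulate_cn_profile(
    wgd: bool, rng: np.random.Generator, sample_id: str = "sim", max_tries: int = 50
) -> CNProfile:
    """Generate an allele-specific profile whose MCN-rule call matches ``wgd``.

    Profiles are resampled (rarely needed) until the realised major-copy
    fraction lands on the requested side of the 50% boundary.
    """
    for _ in range(max_tries):
        profile = _generate_profile_once(wgd, rng, sample_id)
        if call_wgd_mcn(profile).is_wgd == wgd:
            return profile
    raise RuntimeError("could not generate a profile with the requested WGD state")


# ---------------------------------------------------------------------------
# shedding and plasma counts
# ---------------------------------------------------------------------------

def shedding_tumor_fraction(
    patient: PatientRecord,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Plasma tumor fraction shed by one tumor; deterministic when ``rng`` is
    None (no noise term), clamped to [0, 0.5]."""
    sh = config.shedding
    tf = (
        sh.base_rate
        * patient.size_mm ** sh.size_exponent
        * sh.stage_multipliers[patient.uicc_stage]
        * (sh.pt4_multiplier if patient.pt_stage == "pT4" else 1.0)
    )
    if config.ploidy_effect:
        ploidy = patient.ploidy if np.isfinite(patient.ploidy) else (4.0 if patient.wgd else 2.0)
        tf *= ploidy / 2.0
    if rng is not None:
        tf *= float(np.exp(sh.noise_sigma * rng.standard_t(sh.noise_df)))
        if rng.random() < sh.low_shedder_fraction:
            tf *= sh.low_shedder_attenuation
    return float(np.clip(tf, 0.0, 0.5))


def simulate_site_counts(
    tumor_fraction: float,
    n_sites: int,
    depth: int,
    background: float,
    rng: np.random.Generator,
    prefix: str = "mut",
) -> list[SiteCounts]:
    """Strand-resolved counts at the tracked sites.

    Tracked mutations are assumed heterozygous in the tumor, so the expected
    mutant allele fraction is tumor_fraction/2 plus the background error;
    each strand sees half the depth.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    maf = min(tumor_fraction / 2.0 + background, 1.0)
    per_strand = depth // 2
    counts = []
    for i in range(n_sites):
        fwd_alt = int(rng.binomial(per_strand, maf)) if per_strand > 0 else 0
        rev_alt = int(rng.binomial(per_strand, maf)) if per_strand > 0 else 0
        counts.append(
            SiteCounts(f"{prefix}{i + 1}", fwd_alt, per_strand, rev_alt, per_strand)
        )
    return counts


def simulate_normal_panel(
    config: SimConfig, rng: np.random.Generator, prefix: str = "mut"
) -> dict[str, BackgroundModel]:
    """Simulate the healthy-donor cfDNA panel and fit per-site backgrounds."""
    backgrounds = {}
    depth = config.effective_depth
    for i in range(config.n_tracked_sites):
        site_id = f"{prefix}{i + 1}"
        panel = [
            simulate_site_counts(0.0, 1, depth, config.background_error, rng, prefix="")[0]
            for _ in range(config.n_normals)
        ]
        panel = [dataclasses.replace(c, mutation_id=site_id) for c in panel]
        backgrounds[site_id] = fit_background(panel)
    return backgrounds


# ---------------------------------------------------------------------------
# end-to-end cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort: covariates, copy-number profiles,
    panel-of-normals backgrounds, plasma counts, and ctDNA calls."""
    rng = np.random.default_rng(config.seed)
    backgrounds = simulate_normal_panel(config, rng)
    records: list[PatientRecord] = []
    profiles: list[CNProfile] = []
    counts: dict[str, list[SiteCounts]] = {}
    calls: dict[str, SampleCall] = {}
    depth = config.effective_depth
    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        patient = simulate_patient(config, rng, patient_id=pid)
        profile = simulate_cn_profile(patient.wgd, rng, sample_id=pid)
        patient.ploidy = tumor_ploidy(profile)
        patient.true_tumor_fraction = shedding_tumor_fraction(patient, config, rng)
        sites = simulate_site_counts(
            patient.true_tumor_fraction, config.n_tracked_sites, depth,
            config.background_error, rng,
        )
        call = call_sample(sites, backgrounds, alpha=config.alpha, sample_id=pid)
        patient.ctdna_detected = call.is_positive
        records.append(patient)
        profiles.append(profile)
        counts[pid] = sites
        calls[pid] = call
    cohort = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return SimulatedCohort(
        config=config, cohort=cohort, profiles=profiles,
        backgrounds=backgrounds, counts=counts, calls=calls,
    )
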