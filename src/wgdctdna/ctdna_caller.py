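"""Tumor-informed plasma ctDNA calling against a panel-of-normals background.

Sequencing error at each tracked mutation site is modelled per strand with a
beta-binomial distribution whose mean and overdispersion are fitted by the
method of moments from a panel of healthy-donor cfDNA samples.  An observed
plasma sample is tested one site and one strand at a time with an exact
upper-tail probability P(X >= alt_obs); the per-site statistic is the maximum
of the two strand tails, so a site is significant only when *both* strands
are (the strand-AND rule that guards against strand-specific artifacts).
A plasma sample is called ctDNA positive when at least one tracked site has a
combined statistic strictly below alpha (default 0.05).

This is a frequentist tail-probability caller, not a Bayesian posterior; the
decision rule (any site below the 0.05 cutoff, strand-AND combination) is the
clinically relevant contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SiteCounts",
    "StrandModel",
    "BackgroundModel",
    "SiteTest",
    "SampleCall",
    "fit_background",
    "site_tail_probability",
    "call_sample",
]

PSEUDOCOUNT_ALT = 0.5  # added per normal so zero-error sites keep mean_error > 0
_DISPERSION_EPS = 1e-12


@dataclass(frozen=True)
class SiteCounts:
    """Strand-resolved mutant/total read counts at one site in one sample."""

    mutation_id: str
    fwd_alt: int
    fwd_total: int
    rev_alt: int
    rev_total: int

    def __post_init__(self) -> None:
        for alt, total, strand in (
            (self.fwd_alt, self.fwd_total, "forward"),
            (self.rev_alt, self.rev_total, "reverse"),
        ):
            if alt < 0 or total < 0:
                raise ValueError(f"negative counts on {strand} strand")
            if alt > total:
                raise ValueError(
                    f"{strand} strand alt reads ({alt}) exceed total ({total}) "
                    f"at {self.mutation_id}"
                )


@dataclass(frozen=True)
class StrandModel:
    """Beta-binomial error model for one strand: mean error rate and
    overdispersion rho in [0, 1) (rho = 0 degenerates to binomial)."""

    mean_error: float
    dispersion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_error < 1.0:
            raise ValueError(f"mean_error must be in [0, 1), got {self.mean_error}")
        if self.dispersion < 0.0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass(frozen=True)
class BackgroundModel:
    """Per-site background error model fitted from a panel of normals."""

    mutation_id: str
    fwd: StrandModel
    rev: StrandModel
    n_normals: int


@dataclass(frozen=True)
class SiteTest:
    """Tail probabilities for one site: per strand and strand-AND combined."""

    mutation_id: str
    p_fwd: float
    p_rev: float
    p_combined: float
    uninformative: bool = False


@dataclass(frozen=True)
class SampleCall:
    """ctDNA decision for one plasma sample across its tracked sites."""

    sample_id: str
    site_tests: Mapping[str, SiteTest]
    is_positive: bool
    alpha: float

    @property
    def min_combined(self) -> float:
        return min(t.p_combined for t in self.site_tests.values())


def _fit_strand(alts: np.ndarray, totals: np.ndarray) -> StrandModel:
    """Method-of-moments beta-binomial fit on per-normal error proportions.

    A pseudocount of 0.5 alt reads per normal keeps the mean positive at
    error-free sites.  Overdispersion is the excess of the observed variance
    of proportions over the binomial sampling variance, on the standard
    rho-parameterisation Var(p_i) = mu(1-mu)[1/n_i + rho (n_i - 1)/n_i].
    """
    props = (alts + PSEUDOCOUNT_ALT) / (totals + PSEUDOCOUNT_ALT)
    mu = float(np.mean(props))
    mu = min(mu, 1.0 - 1e-9)
    if len(props) < 2:
        return StrandModel(mean_error=mu, dispersion=0.0)
    s2 = float(np.var(props, ddof=1))
    v_binom = mu * (1.0 - mu) * float(np.mean(1.0 / totals))
    denom = mu * (1.0 - mu) * float(np.mean((totals - 1.0) / totals))
    rho = 0.0 if denom <= 0 else max(0.0, (s2 - v_binom) / denom)
    return StrandModel(mean_error=mu, dispersion=min(rho, 1.0 - 1e-6))


def fit_background(panel_counts: Sequence[SiteCounts]) -> BackgroundModel:
    """Fit the per-strand background error model for one site from >= 2 normals.

    ``panel_counts`` holds one :class:`SiteCounts` per normal sample, all at
    the same tracked mutation.
    """
    counts = [c for c in panel_counts if c.fwd_total > 0 or c.rev_total > 0]
    if not counts:
        raise ValueError("panel of normals has no coverage at this site")
    ids = {c.mutation_id for c in counts}
    if len(ids) != 1:
        raise ValueError(f"panel rows mix multiple sites: {sorted(ids)}")
    if len(counts) < 2:
        raise ValueError(
            "at least 2 normal samples with coverage are required to fit a background"
        )
    fwd = _fit_strand(
        np.array([c.fwd_alt for c in counts], dtype=float),
        np.array([max(c.fwd_total, 1) for c in counts], dtype=float),
    )
    rev = _fit_strand(
        np.array([c.rev_alt for c in counts], dtype=float),
        np.array([max(c.rev_total, 1) for c in counts], dtype=float),
    )
    return BackgroundModel(mutation_id=ids.pop(), fwd=fwd, rev=rev, n_normals=len(counts))


def _strand_tail(alt: int, total: int, model: StrandModel) -> float:
    """Exact upper tail P(X >= alt) under the strand's beta-binomial null."""
    if total <= 0:
        return 1.0
    if alt <= 0:
        return 1.0
    mu, rho = model.mean_error, model.dispersion
    if rho <= _DISPERSION_EPS:
        return float(stats.binom.sf(alt - 1, total, mu))
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float(stats.betabinom.sf(alt - 1, total, a, b))


def site_tail_probability(obs: SiteCounts, bg: BackgroundModel) -> SiteTest:
    """Per-strand and strand-AND-combined tail probabilities for one site.

    A strand with zero total depth is uninformative; the combined statistic
    is then 1 and the site is flagged.
    """
    uninformative = obs.fwd_total == 0 or obs.rev_total == 0
    p_fwd = _strand_tail(obs.fwd_alt, obs.fwd_total, bg.fwd)
    p_rev = _strand_tail(obs.rev_alt, obs.rev_total, bg.rev)
    p_combined = 1.0 if uninformative else max(p_fwd, p_rev)
    return SiteTest(
        mutation_id=obs.mutation_id,
        p_fwd=p_fwd,
        p_rev=p_rev,
        p_combined=p_combined,
        uninformative=uninformative,
    )


def call_sample(
    sites: Sequence[SiteCounts],
    backgrounds: Mapping[str, BackgroundModel],
    alpha: float = 0.05,
    sample_id: str = "sample",
    bonferroni: bool = False,
) -> SampleCall:
    """Call a plasma sample ctDNA positive when at least one tracked site has
    a combined statistic strictly below ``alpha``.

    No multiple-testing correction is applied by default (the any-site rule);
    ``bonferroni=True`` divides alpha by the number of tracked sites.
    """
    if not sites:
        raise ValueError(f"sample {sample_id!r} has no tracked sites")
    missing = [s.mutation_id for s in sites if s.mutation_id not in backgrounds]
    if missing:
        raise KeyError(f"no background model for sites: {missing}")
    tests = {s.mutation_id: site_tail_probability(s, backgrounds[s.mutation_id]) for s in sites}
    threshold = alpha / len(sites) if bonferroni else alpha
    positive = any(t.p_combined < threshold for t in tests.values())
    return SampleCall(sample_id=sample_id, site_tests=tests, is_positive=positive, alpha=alpha)
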