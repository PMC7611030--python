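"""Poisson partition statistics for droplet digital PCR (ddPCR).

A ddPCR reaction is partitioned into thousands of nanoliter droplets; each
droplet is scored positive or negative for a target. If molecules of a target
present at concentration ``lam`` (copies/µL of reaction) are distributed at
random over droplets of volume ``v`` µL, the probability a droplet contains at
least one copy is ``p = 1 - exp(-lam * v)``, so

    lam = -ln(1 - k/n) / v

for ``k`` positive droplets out of ``n`` accepted.  Everything in this module
is arithmetic on that map: merging replicate wells, concentration estimates
with 95% confidence intervals, fractional abundance of two alleles in a
duplexed assay, and the no-template-control contamination check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from statsmodels.stats.proportion import proportion_confint

#: Nominal droplet volume of a Bio-Rad QX200 droplet, in µL of reaction.
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4


class ChannelRole(str, Enum):
    """What the fluorescence channel of a well measures."""

    REF_ALLELE = "REF_ALLELE"
    VAR_ALLELE = "VAR_ALLELE"
    MATERNAL_ALLELE = "MATERNAL_ALLELE"
    PATERNAL_ALLELE = "PATERNAL_ALLELE"
    CNV_TARGET = "CNV_TARGET"
    CNV_REFERENCE_LOCUS = "CNV_REFERENCE_LOCUS"


class SaturationError(ValueError):
    """All droplets positive: the concentration is unbounded above."""


@dataclass(frozen=True)
class WellCount:
    """Called droplet counts for one well x channel."""

    well_id: str
    sample_id: str
    assay_id: str
    channel_role: ChannelRole
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"well {self.well_id}: total droplets must be > 0")
        if not 0 <= self.positive <= self.total:
            raise ValueError(
                f"well {self.well_id}: need 0 <= positive <= total, "
                f"got {self.positive}/{self.total}"
            )


@dataclass(frozen=True)
class ChannelCounts:
    """Droplet counts for one channel, pooled over replicate wells."""

    k: int
    n: int
    n_wells: int = 1

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("pooled total droplets must be > 0")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got {self.k}/{self.n}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Concentration in copies/µL of reaction with a 95% CI."""

    lam: float
    ci_low: float
    ci_high: float
    droplet_volume: float


@dataclass(frozen=True)
class FractionEstimate:
    """Fractional abundance of the first channel with a 95% CI."""

    frac: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class NTCResult:
    """Outcome of the no-template-control contamination check."""

    passed: bool
    failed_wells: tuple[WellCount, ...] = ()
    warning: str | None = None


def merge_wells(wells: list[WellCount]) -> ChannelCounts:
    """Pool replicate wells of one sample/assay/channel by summing counts.

    Raises ``ValueError`` for an empty list or wells that do not share
    ``sample_id``, ``assay_id`` and ``channel_role``.
    """
    if not wells:
        raise ValueError("cannot merge an empty list of wells")
    first = wells[0]
    for w in wells[1:]:
        if (w.sample_id, w.assay_id, w.channel_role) != (
            first.sample_id,
            first.assay_id,
            first.channel_role,
        ):
            raise ValueError(
                "wells to merge must share sample_id, assay_id and channel_role; "
                f"got {first.sample_id}/{first.assay_id}/{first.channel_role.value} "
                f"vs {w.sample_id}/{w.assay_id}/{w.channel_role.value}"
            )
    return ChannelCounts(
        k=sum(w.positive for w in wells),
        n=sum(w.total for w in wells),
        n_wells=len(wells),
    )


def _lam_from_p(p: float, droplet_volume: float) -> float:
    return -math.log1p(-p) / droplet_volume


def estimate_concentration(
    c: ChannelCounts, droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
) -> ConcentrationEstimate:
    """Poisson-corrected concentration with a 95% CI.

    The point estimate is ``-ln(1 - k/n) / v``.  The CI is a Wilson 95%
    binomial interval on the positive fraction pushed through the same
    monotone map (see package docs for why Wilson rather than the
    instrument vendor's undocumented interval).
    """
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be > 0")
    if c.k == c.n:
        raise SaturationError(
            f"all {c.n} droplets positive: concentration is not quantifiable"
        )
    p_lo, p_hi = proportion_confint(c.k, c.n, alpha=0.05, method="wilson")
    # Wilson bounds are strictly inside (0, 1) except at k=0 / k=n.
    lam = _lam_from_p(c.k / c.n, droplet_volume)
    ci_low = _lam_from_p(max(p_lo, 0.0), droplet_volume)
    ci_high = _lam_from_p(min(p_hi, 1.0 - 1e-15), droplet_volume)
    return ConcentrationEstimate(
        lam=lam, ci_low=min(ci_low, lam), ci_high=max(ci_high, lam),
        droplet_volume=droplet_volume,
    )


def fractional_abundance(
    a: ChannelCounts,
    b: ChannelCounts,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
) -> FractionEstimate:
    """Fraction of channel ``a`` out of ``a + b``, on the concentration scale.

    ``frac = lam_a / (lam_a + lam_b)``.  The CI evaluates the fraction at the
    paired per-channel CI extremes (low-a with high-b, and vice versa) — a
    conservative interval that inherits the monotonicity of the map.
    Raises ``ValueError`` when both channels have zero positives (the
    fraction is undefined) and :class:`SaturationError` for a saturated
    channel.
    """
    ea = estimate_concentration(a, droplet_volume)
    eb = estimate_concentration(b, droplet_volume)
    if ea.lam + eb.lam == 0:
        raise ValueError("both channels have zero positives: fraction undefined")
    frac = ea.lam / (ea.lam + eb.lam)
    lo_num, lo_den = ea.ci_low, ea.ci_low + eb.ci_high
    hi_num, hi_den = ea.ci_high, ea.ci_high + eb.ci_low
    ci_low = lo_num / lo_den if lo_den > 0 else 0.0
    ci_high = hi_num / hi_den if hi_den > 0 else 1.0
    return FractionEstimate(
        frac=frac, ci_low=min(ci_low, frac), ci_high=max(ci_high, frac)
    )


def check_ntc(ntc_wells: list[WellCount], max_positive: int = 0) -> NTCResult:
    """Flag contamination in no-template-control wells.

    Fails when any NTC well exceeds ``max_positive`` positive droplets
    (default 0: any positive droplet in a template-free well flags
    contamination).  An empty list passes with a warning.
    """
    if not ntc_wells:
        return NTCResult(passed=True, warning="no NTC wells provided")
    bad = tuple(w for w in ntc_wells if w.positive > max_positive)
    return NTCResult(passed=not bad, failed_wells=bad)
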