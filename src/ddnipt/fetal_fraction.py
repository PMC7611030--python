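"""Fetal fraction estimation and per-sample QC gates.

The fetal fraction ``f`` is the proportion of cell-free DNA in maternal
plasma that originates from the fetus/placenta.  It is measured with a
duplexed ddPCR assay against an allele the fetus carries but the mother does
not: either the Y-linked ZFY gene (male fetus, against the X-linked ZFX
homolog) or a SNP at which the parents are opposite homozygotes.

Per genome equivalent the mother contributes two copies of the
maternal-channel target and none of the paternal-channel target; the fetus
contributes one of each.  The paternal channel therefore carries a share
``f/2`` of the total assay concentration, giving

    f = 2 * lam_pat / (lam_pat + lam_mat)

identically in both assay modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .droplet_stats import (
    DEFAULT_DROPLET_VOLUME_UL,
    ChannelCounts,
    FractionEstimate,
    NTCResult,
    estimate_concentration,
    fractional_abundance,
)


class FFMode(str, Enum):
    OPPOSITE_HOMOZYGOTE_SNP = "OPPOSITE_HOMOZYGOTE_SNP"
    ZFX_ZFY = "ZFX_ZFY"


class QCReason(str, Enum):
    LOW_FETAL_FRACTION = "LOW_FETAL_FRACTION"
    LOW_PATERNAL_DROPLETS = "LOW_PATERNAL_DROPLETS"
    NTC_FAIL = "NTC_FAIL"


@dataclass(frozen=True)
class FFAssayObservation:
    """Merged counts of a fetal-fraction assay.

    ``maternal_channel`` counts the allele shared with the mother (or ZFX);
    ``paternal_channel`` the paternal-only allele (or ZFY).  ``fetal_sex``
    must be ``"male"`` to use ZFX/ZFY mode — for a female or unknown-sex
    fetus ZFY carries no fetal signal and the mode is refused.
    """

    maternal_channel: ChannelCounts
    paternal_channel: ChannelCounts
    mode: FFMode = FFMode.OPPOSITE_HOMOZYGOTE_SNP
    fetal_sex: str | None = None


@dataclass(frozen=True)
class FFEstimate:
    f_hat: float
    paternal_positive_droplets: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class SampleQC:
    """Pre-model exclusion verdict for one plasma sample.

    A sample is excluded from genotype calling when the point-estimate fetal
    fraction is below ``min_ff`` (default 2%), when the fetal-fraction assay
    yielded fewer than ``min_paternal_droplets`` positive paternal droplets
    (default 10), or when a no-template control failed.
    """

    passed: bool
    reasons: tuple[QCReason, ...]
    min_ff: float = 0.02
    min_paternal_droplets: int = 10

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")


def estimate_fetal_fraction(
    obs: FFAssayObservation,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
) -> FFEstimate:
    """Point estimate and 95% CI of the fetal fraction.

    ``f_hat = 2 * lam_pat / (lam_pat + lam_mat)`` on Poisson-corrected
    concentrations.  The CI doubles the propagated fractional-abundance CI
    of the paternal channel, clipped to [0, 1].
    """
    if obs.mode is FFMode.ZFX_ZFY and obs.fetal_sex != "male":
        raise ValueError(
            "ZFX/ZFY fetal-fraction mode requires a fetus annotated male; "
            "use an opposite-homozygote SNP assay otherwise"
        )
    lam_mat = estimate_concentration(obs.maternal_channel, droplet_volume).lam
    lam_pat = estimate_concentration(obs.paternal_channel, droplet_volume).lam
    if lam_mat + lam_pat == 0:
        raise ValueError("no positive droplets in either channel: f undefined")
    f_hat = min(2.0 * lam_pat / (lam_pat + lam_mat), 1.0)
    if obs.paternal_channel.k == 0:
        ci = FractionEstimate(frac=0.0, ci_low=0.0, ci_high=0.0)
        ci_high = min(
            2.0
            * fractional_abundance(
                ChannelCounts(k=0, n=obs.paternal_channel.n),
                obs.maternal_channel,
                droplet_volume,
            ).ci_high,
            1.0,
        )
        return FFEstimate(0.0, 0, 0.0, ci_high)
    frac = fractional_abundance(
        obs.paternal_channel, obs.maternal_channel, droplet_volume
    )
    return FFEstimate(
        f_hat=f_hat,
        paternal_positive_droplets=obs.paternal_channel.k,
        ci_low=max(min(2.0 * frac.ci_low, f_hat), 0.0),
        ci_high=max(min(2.0 * frac.ci_high, 1.0), f_hat),
    )


def qc_sample(
    ff: FFEstimate,
    ntc: NTCResult | None = None,
    min_ff: float = 0.02,
    min_paternal_droplets: int = 10,
) -> SampleQC:
    """Apply the pre-model exclusion gates to one sample."""
    reasons: list[QCReason] = []
    if ff.f_hat < min_ff:
        reasons.append(QCReason.LOW_FETAL_FRACTION)
    if ff.paternal_positive_droplets < min_paternal_droplets:
        reasons.append(QCReason.LOW_PATERNAL_DROPLETS)
    if ntc is not None and not ntc.passed:
        reasons.append(QCReason.NTC_FAIL)
    return SampleQC(
        passed=not reasons,
        reasons=tuple(reasons),
        min_ff=min_ff,
        min_paternal_droplets=min_paternal_droplets,
    )


def filter_candidate_paternal_snvs(
    rows: pd.DataFrame, low: float = 0.01, high: float = 0.15
) -> pd.DataFrame:
    """Select SNVs whose cfDNA minor-allele abundance looks paternally inherited.

    Used when no paternal gDNA is available: candidate informative SNVs are
    taken from sequencing of the cfDNA itself, keeping sites with minor
    allele fraction in [1%, 15%] (inclusive) — the range expected for an
    allele contributed only by the fetus.

    ``rows`` needs columns ``snv_id`` and ``minor_allele_fraction``.
    """
    required = {"snv_id", "minor_allele_fraction"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    maf = rows["minor_allele_fraction"]
    if len(rows) and ((maf < 0) | (maf > 1)).any():
        raise ValueError("minor_allele_fraction values must lie in [0, 1]")
    return rows[(maf >= low) & (maf <= high)].copy()
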