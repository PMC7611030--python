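"""Synthetic ddPCR droplet counts from the model's data-generating process.

Generates per-well droplet counts for the variant and fetal-fraction assays
of a plasma sample with known (recorded) ground truth, for testing,
calibration studies and power analysis.  Droplet occupancy is simulated
directly at the ``Binomial(n, 1 - exp(-lam*v))`` level — distributionally
identical to seeding molecules over droplets, without per-droplet copy
numbers.

Defaults state a realistic world: 50 copies/µL total per assay (a typical
cfDNA load, a few hundred positives in a 15 000-droplet well), 8 replicate
wells per assay (sample volume permitting, up to 16), and cohort fetal
fractions drawn uniformly from the observed clinical range 2.5%–26.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .droplet_stats import (
    DEFAULT_DROPLET_VOLUME_UL,
    ChannelCounts,
    ChannelRole,
    WellCount,
    merge_wells,
)
from .fetal_fraction import FFAssayObservation, FFMode
from .genotype_model import (
    AssayMode,
    FetalGenotype,
    SampleObservation,
    expected_cnv_ratio,
    expected_ref_fraction,
)

#: Observed clinical range of fetal fractions (min 2.5%, max 26.1%).
COHORT_F_RANGE = (0.025, 0.261)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and assay geometry for one simulated plasma sample."""

    true_genotype: FetalGenotype = FetalGenotype.HOM_REF
    true_f: float = 0.10
    conc_var_total: float = 50.0
    conc_ff_total: float = 50.0
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    droplets_per_well: int = 15000
    wells_per_assay: int = 8
    bias: float = 1.0
    assay_mode: AssayMode = AssayMode.ALLELIC
    ff_mode: FFMode = FFMode.OPPOSITE_HOMOZYGOTE_SNP
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_f <= 1.0:
            raise ValueError("true_f must lie in [0, 1]")
        if not 1 <= self.wells_per_assay <= 16:
            raise ValueError("wells_per_assay must lie in [1, 16]")
        for name in ("conc_var_total", "conc_ff_total", "droplet_volume", "bias"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.droplets_per_well < 1:
            raise ValueError("droplets_per_well must be >= 1")


@dataclass(frozen=True)
class SimulatedSample:
    """A sample observation together with the truth that generated it."""

    obs: SampleObservation
    wells: tuple[WellCount, ...]
    true_genotype: FetalGenotype
    true_f: float
    true_lambdas: dict


def simulate_well(
    lam_by_channel: dict[ChannelRole, float],
    n_droplets: int,
    droplet_volume: float,
    rng: np.random.Generator,
    well_id: str = "well",
    sample_id: str = "sample",
    assay_id: str = "assay",
) -> list[WellCount]:
    """Draw positive-droplet counts for one well, independently per channel."""
    out = []
    for role, lam in lam_by_channel.items():
        if lam < 0:
            raise ValueError("channel concentration must be >= 0")
        p = -np.expm1(-lam * droplet_volume)
        k = int(rng.binomial(n_droplets, p))
        out.append(
            WellCount(
                well_id=well_id,
                sample_id=sample_id,
                assay_id=assay_id,
                channel_role=role,
                positive=k,
                total=n_droplets,
            )
        )
    return out


def channel_lambdas(spec: SimulationSpec) -> dict[ChannelRole, float]:
    """True per-channel concentrations implied by a spec, exactly as the
    likelihood parameterises them."""
    g, f = spec.true_genotype, spec.true_f
    if spec.assay_mode is AssayMode.ALLELIC:
        theta = expected_ref_fraction(g, f, spec.bias)
        var_pair = {
            ChannelRole.REF_ALLELE: spec.conc_var_total * theta,
            ChannelRole.VAR_ALLELE: spec.conc_var_total * (1.0 - theta),
        }
    else:
        # conc_var_total is the reference-locus concentration in CNV mode
        r = expected_cnv_ratio(g, f)
        var_pair = {
            ChannelRole.CNV_TARGET: spec.conc_var_total * r,
            ChannelRole.CNV_REFERENCE_LOCUS: spec.conc_var_total,
        }
    return {
        **var_pair,
        ChannelRole.PATERNAL_ALLELE: spec.conc_ff_total * f / 2.0,
        ChannelRole.MATERNAL_ALLELE: spec.conc_ff_total * (1.0 - f / 2.0),
    }


def simulate_sample(
    spec: SimulationSpec,
    sample_id: str = "sim",
    pregnancy_id: str = "",
    gestation_weeks: float | None = None,
) -> SimulatedSample:
    """Simulate all wells of one plasma sample and merge them.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lams = channel_lambdas(spec)
    if spec.assay_mode is AssayMode.ALLELIC:
        var_roles = (ChannelRole.REF_ALLELE, ChannelRole.VAR_ALLELE)
    else:
        var_roles = (ChannelRole.CNV_TARGET, ChannelRole.CNV_REFERENCE_LOCUS)
    ff_roles = (ChannelRole.MATERNAL_ALLELE, ChannelRole.PATERNAL_ALLELE)

    wells: list[WellCount] = []
    for assay_id, roles in (("variant", var_roles), ("ff", ff_roles)):
        for w in range(spec.wells_per_assay):
            wells.extend(
                simulate_well(
                    {r: lams[r] for r in roles},
                    spec.droplets_per_well,
                    spec.droplet_volume,
                    rng,
                    well_id=f"{assay_id}-{w + 1:02d}",
                    sample_id=sample_id,
                    assay_id=assay_id,
                )
            )

    def merged(role: ChannelRole) -> ChannelCounts:
        return merge_wells([w for w in wells if w.channel_role is role])

    obs = SampleObservation(
        sample_id=sample_id,
        pregnancy_id=pregnancy_id or sample_id,
        gestation_weeks=gestation_weeks,
        variant_a=merged(var_roles[0]),
        variant_b=merged(var_roles[1]),
        ff_assay=FFAssayObservation(
            maternal_channel=merged(ChannelRole.MATERNAL_ALLELE),
            paternal_channel=merged(ChannelRole.PATERNAL_ALLELE),
            mode=spec.ff_mode,
            fetal_sex="male" if spec.ff_mode is FFMode.ZFX_ZFY else None,
        ),
        droplet_volume=spec.droplet_volume,
        assay_mode=spec.assay_mode,
        assay_id="variant",
    )
    return SimulatedSample(
        obs=obs,
        wells=tuple(wells),
        true_genotype=spec.true_genotype,
        true_f=spec.true_f,
        true_lambdas={r.value: v for r, v in lams.items()},
    )


def simulate_cohort(
    n_pregnancies: int,
    f_range: tuple[float, float] = COHORT_F_RANGE,
    genotype_prior: float = 0.5,
    base_spec: SimulationSpec | None = None,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Simulate independent single-sample pregnancies.

    Fetal fractions are drawn Uniform(*f_range*) and genotypes
    Bernoulli(``genotype_prior`` for homozygous reference).
    """
    if n_pregnancies < 1:
        raise ValueError("need at least one pregnancy")
    base = base_spec or SimulationSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for i in range(n_pregnancies):
        f = float(rng.uniform(*f_range))
        g = (
            FetalGenotype.HOM_REF
            if rng.random() < genotype_prior
            else FetalGenotype.HET
        )
        spec = replace(
            base,
            true_f=f,
            true_genotype=g,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(
            simulate_sample(
                spec,
                sample_id=f"preg{i + 1:03d}-s1",
                pregnancy_id=f"preg{i + 1:03d}",
                gestation_weeks=float(rng.uniform(9, 36)),
            )
        )
    return out
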