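"""Well-table CSV parsing, run configuration, and the end-to-end pipeline.

The input is one normalised long-format CSV (one row per well x channel)
rather than an instrument's native export; a row carries::

    well_id, sample_id, pregnancy_id, assay_id, assay_role, channel_role,
    positive, total [, gestation_weeks]

where ``assay_role`` is one of VARIANT, FETAL_FRACTION, NTC, GDNA_CONTROL.
The run configuration is a flat YAML key-value document; unknown keys are
rejected so a typo in a threshold cannot pass silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .droplet_stats import (
    DEFAULT_DROPLET_VOLUME_UL,
    ChannelRole,
    NTCResult,
    WellCount,
    check_ntc,
    merge_wells,
)
from .fetal_fraction import (
    FFAssayObservation,
    FFMode,
    estimate_fetal_fraction,
    qc_sample,
)
from .genotype_model import (
    AssayMode,
    MCMCConfig,
    ModelConfig,
    PosteriorSummary,
    SampleObservation,
    calibrate_bias,
    quadrature_posterior,
    run_mcmc,
)
from .simulator import SimulatedSample
from .workflow import (
    CallThresholds,
    DiscordantCallsError,
    GenotypeCall,
    PregnancyResult,
    call_genotype,
    evaluate_pregnancy,
)

logger = logging.getLogger("ddnipt")

ASSAY_ROLES = {"VARIANT", "FETAL_FRACTION", "NTC", "GDNA_CONTROL"}
_REQUIRED_COLUMNS = [
    "well_id",
    "sample_id",
    "assay_id",
    "assay_role",
    "channel_role",
    "positive",
    "total",
]
_VARIANT_CHANNELS = {
    ChannelRole.REF_ALLELE,
    ChannelRole.VAR_ALLELE,
    ChannelRole.CNV_TARGET,
    ChannelRole.CNV_REFERENCE_LOCUS,
}
_FF_CHANNELS = {ChannelRole.MATERNAL_ALLELE, ChannelRole.PATERNAL_ALLELE}


class WellTableError(ValueError):
    """A well-table row violated the format contract."""


def read_well_table(path) -> pd.DataFrame:
    """Read and validate a well-table CSV; errors name the offending row."""
    df = pd.read_csv(path, dtype={"sample_id": str, "pregnancy_id": str,
                                  "assay_id": str, "well_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise WellTableError(f"{path}: missing required columns {missing}")
    if "pregnancy_id" not in df.columns:
        df["pregnancy_id"] = df["sample_id"]
    if "gestation_weeks" not in df.columns:
        df["gestation_weeks"] = np.nan
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.assay_role not in ASSAY_ROLES:
            raise WellTableError(
                f"{path} line {i}: unknown assay_role {row.assay_role!r}"
            )
        try:
            ChannelRole(row.channel_role)
        except ValueError:
            raise WellTableError(
                f"{path} line {i}: unknown channel_role {row.channel_role!r}"
            ) from None
        for col in ("positive", "total"):
            val = getattr(row, col)
            if not float(val).is_integer():
                raise WellTableError(
                    f"{path} line {i}: {col} must be an integer droplet count, "
                    f"got {val!r} (merge wells inside the tool, not upstream)"
                )
        if row.total <= 0 or row.positive < 0 or row.positive > row.total:
            raise WellTableError(
                f"{path} line {i}: need 0 <= positive <= total and total > 0, "
                f"got {row.positive}/{row.total}"
            )
    df["positive"] = df["positive"].astype(int)
    df["total"] = df["total"].astype(int)
    return df


def simulated_to_frame(samples: list[SimulatedSample]) -> pd.DataFrame:
    """Flatten simulated samples into the well-table layout."""
    rows = []
    for s in samples:
        role_of = {"variant": "VARIANT", "ff": "FETAL_FRACTION"}
        for w in s.wells:
            rows.append(
                {
                    "well_id": w.well_id,
                    "sample_id": w.sample_id,
                    "pregnancy_id": s.obs.pregnancy_id,
                    "assay_id": w.assay_id,
                    "assay_role": role_of[w.assay_id],
                    "channel_role": w.channel_role.value,
                    "positive": w.positive,
                    "total": w.total,
                    "gestation_weeks": s.obs.gestation_weeks,
                }
            )
    return pd.DataFrame(rows)


def truth_frame(samples: list[SimulatedSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pregnancy_id": [s.obs.pregnancy_id for s in samples],
            "true_genotype": [s.true_genotype.value for s in samples],
            "true_f": [s.true_f for s in samples],
        }
    ).drop_duplicates("pregnancy_id")


@dataclass(frozen=True)
class RunConfig:
    """Everything the pipeline needs besides the well table."""

    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    min_ff: float = 0.02
    min_paternal_droplets: int = 10
    ntc_max_positive: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    engine: str = "MCMC"
    assay_mode: AssayMode = AssayMode.ALLELIC

    def __post_init__(self) -> None:
        if self.engine not in {"MCMC", "QUADRATURE"}:
            raise ValueError("engine must be MCMC or QUADRATURE")


_CONFIG_KEYS = {
    "droplet_volume": float,
    "p_hom_call": float,
    "p_het_call": float,
    "min_ff": float,
    "min_paternal_droplets": int,
    "ntc_max_positive": int,
    "f_low": float,
    "f_high": float,
    "genotype_prior": float,
    "conc_max_mult": float,
    "bias": float,
    "chains": int,
    "adapt_iters": int,
    "burn_in": int,
    "sampling_iters": int,
    "seed": int,
    "engine": str,
    "assay_mode": str,
}


def read_config(path) -> RunConfig:
    """Load a flat YAML config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    vals = {k: _CONFIG_KEYS[k](v) for k, v in raw.items()}
    return RunConfig(
        droplet_volume=vals.get("droplet_volume", DEFAULT_DROPLET_VOLUME_UL),
        thresholds=CallThresholds(
            p_hom_call=vals.get("p_hom_call", 0.95),
            p_het_call=vals.get("p_het_call", 0.05),
        ),
        min_ff=vals.get("min_ff", 0.02),
        min_paternal_droplets=vals.get("min_paternal_droplets", 10),
        ntc_max_positive=vals.get("ntc_max_positive", 0),
        model=ModelConfig(
            f_low=vals.get("f_low", 0.0),
            f_high=vals.get("f_high", 0.5),
            genotype_prior=vals.get("genotype_prior", 0.5),
            conc_max_mult=vals.get("conc_max_mult", 5.0),
            bias=vals.get("bias", 1.0),
        ),
        mcmc=MCMCConfig(
            chains=vals.get("chains", 4),
            adapt_iters=vals.get("adapt_iters", 1000),
            burn_in=vals.get("burn_in", 10000),
            sampling_iters=vals.get("sampling_iters", 50000),
            seed=vals.get("seed", 0),
        ),
        engine=vals.get("engine", "MCMC"),
        assay_mode=AssayMode(vals.get("assay_mode", "ALLELIC")),
    )


def _wells_from_rows(rows: pd.DataFrame) -> list[WellCount]:
    return [
        WellCount(
            well_id=str(r.well_id),
            sample_id=str(r.sample_id),
            assay_id=str(r.assay_id),
            channel_role=ChannelRole(r.channel_role),
            positive=int(r.positive),
            total=int(r.total),
        )
        for r in rows.itertuples(index=False)
    ]


def run_pipeline(
    well_table: pd.DataFrame, config: RunConfig | None = None, seed: int | None = None
) -> dict:
    """Run the full pipeline on a parsed well table.

    Stages: NTC contamination check per assay -> gDNA-control bias
    calibration -> per-sample well merging -> fetal-fraction estimation and
    QC -> genotype posterior (configured engine) -> per-sample calls ->
    per-pregnancy follow-up resolution.  Samples missing one of the two
    assays are reported with a reason, never dropped silently.

    Returns a dict with ``sample_calls`` and ``pregnancy_results``
    DataFrames plus the underlying result objects.
    """
    config = config or RunConfig()
    if seed is None:
        seed = config.mcmc.seed

    # NTC check per assay
    ntc_by_assay: dict[str, NTCResult] = {}
    for assay_id, grp in well_table[well_table.assay_role == "NTC"].groupby("assay_id"):
        res = check_ntc(_wells_from_rows(grp), config.ntc_max_positive)
        ntc_by_assay[assay_id] = res
        logger.info(
            "NTC check assay %s: %s", assay_id, "pass" if res.passed else "FAIL"
        )

    # gDNA heterozygous controls -> per-assay reference bias
    bias_by_assay: dict[str, float] = {}
    gdna = well_table[well_table.assay_role == "GDNA_CONTROL"]
    for assay_id, grp in gdna.groupby("assay_id"):
        wells = _wells_from_rows(grp)
        ref = [w for w in wells if w.channel_role is ChannelRole.REF_ALLELE]
        var = [w for w in wells if w.channel_role is ChannelRole.VAR_ALLELE]
        if ref and var:
            try:
                bias_by_assay[assay_id] = calibrate_bias(
                    merge_wells(ref), merge_wells(var), config.droplet_volume
                )
                logger.info(
                    "bias calibration assay %s: %.4f", assay_id, bias_by_assay[assay_id]
                )
            except ValueError as e:
                logger.warning("bias calibration assay %s skipped: %s", assay_id, e)

    sample_rows = well_table[well_table.assay_role.isin({"VARIANT", "FETAL_FRACTION"})]
    records: list[dict] = []
    calls_by_pregnancy: dict[str, list[GenotypeCall]] = {}
    summaries: dict[str, PosteriorSummary] = {}
    ss = np.random.SeedSequence(seed)

    for sample_id, grp in sample_rows.groupby("sample_id", sort=True):
        pregnancy_id = str(grp["pregnancy_id"].iloc[0])
        gest = grp["gestation_weeks"].iloc[0]
        gest = None if pd.isna(gest) else float(gest)
        wells = _wells_from_rows(grp)
        by_role: dict[ChannelRole, list[WellCount]] = {}
        for w in wells:
            by_role.setdefault(w.channel_role, []).append(w)

        var_roles = sorted(
            (r for r in by_role if r in _VARIANT_CHANNELS), key=lambda r: r.value
        )
        ff_ok = all(r in by_role for r in _FF_CHANNELS)
        record = {
            "pregnancy_id": pregnancy_id,
            "sample_id": sample_id,
            "gestation_weeks": gest,
        }
        if len(var_roles) != 2 or not ff_ok:
            reason = "MISSING_VARIANT_ASSAY" if len(var_roles) != 2 else "MISSING_FF_ASSAY"
            logger.warning("sample %s skipped: %s", sample_id, reason)
            records.append({**record, "call": "SKIPPED", "reasons": reason})
            continue

        cnv = ChannelRole.CNV_TARGET in by_role
        if cnv:
            a_role, b_role = ChannelRole.CNV_TARGET, ChannelRole.CNV_REFERENCE_LOCUS
            mode = AssayMode.CNV_DELETION
        else:
            a_role, b_role = ChannelRole.REF_ALLELE, ChannelRole.VAR_ALLELE
            mode = AssayMode.ALLELIC
        variant_assay_id = by_role[a_role][0].assay_id
        ff_assay_id = by_role[ChannelRole.PATERNAL_ALLELE][0].assay_id

        obs = SampleObservation(
            sample_id=str(sample_id),
            pregnancy_id=pregnancy_id,
            gestation_weeks=gest,
            variant_a=merge_wells(by_role[a_role]),
            variant_b=merge_wells(by_role[b_role]),
            ff_assay=FFAssayObservation(
                maternal_channel=merge_wells(by_role[ChannelRole.MATERNAL_ALLELE]),
                paternal_channel=merge_wells(by_role[ChannelRole.PATERNAL_ALLELE]),
                mode=FFMode.OPPOSITE_HOMOZYGOTE_SNP,
            ),
            droplet_volume=config.droplet_volume,
            assay_mode=mode,
            assay_id=variant_assay_id,
        )

        ff = estimate_fetal_fraction(obs.ff_assay, config.droplet_volume)
        ntc_flags = [
            ntc_by_assay[a]
            for a in (variant_assay_id, ff_assay_id)
            if a in ntc_by_assay
        ]
        ntc = None
        if ntc_flags:
            failed = [n for n in ntc_flags if not n.passed]
            ntc = failed[0] if failed else ntc_flags[0]
        qc = qc_sample(ff, ntc, config.min_ff, config.min_paternal_droplets)

        post = None
        if qc.passed:
            model_cfg = ModelConfig(
                f_low=config.model.f_low,
                f_high=config.model.f_high,
                genotype_prior=config.model.genotype_prior,
                conc_max_mult=config.model.conc_max_mult,
                bias=bias_by_assay.get(variant_assay_id, config.model.bias),
            )
            if config.engine == "QUADRATURE":
                post = quadrature_posterior(obs, model_cfg)
            else:
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                post = run_mcmc(
                    obs,
                    model_cfg,
                    MCMCConfig(
                        chains=config.mcmc.chains,
                        adapt_iters=config.mcmc.adapt_iters,
                        burn_in=config.mcmc.burn_in,
                        sampling_iters=config.mcmc.sampling_iters,
                        seed=child_seed,
                    ),
                )
            summaries[str(sample_id)] = post

        call = call_genotype(
            post,
            qc,
            config.thresholds,
            sample_id=str(sample_id),
            f_hat=ff.f_hat,
            gestation_weeks=gest,
        )
        calls_by_pregnancy.setdefault(pregnancy_id, []).append(call)
        records.append(
            {
                **record,
                "f_hat": round(ff.f_hat, 6),
                "paternal_droplets": ff.paternal_positive_droplets,
                "p_hom": None if post is None else round(post.p_hom, 6),
                "f_post_median": None if post is None else round(post.f_post["median"], 6),
                "call": call.call.value,
                "reasons": ";".join(call.reasons),
            }
        )
        logger.info("sample %s: %s (p_hom=%s)", sample_id, call.call.value, call.p_hom)

    preg_records = []
    preg_results: list[PregnancyResult] = []
    for pregnancy_id in sorted(calls_by_pregnancy):
        try:
            res = evaluate_pregnancy(pregnancy_id, calls_by_pregnancy[pregnancy_id])
        except DiscordantCallsError as e:
            logger.error("%s", e)
            preg_records.append(
                {
                    "pregnancy_id": pregnancy_id,
                    "final_call": "DISCORDANT_ERROR",
                    "n_samples_used": len(calls_by_pregnancy[pregnancy_id]),
                }
            )
            continue
        preg_results.append(res)
        preg_records.append(
            {
                "pregnancy_id": pregnancy_id,
                "final_call": res.final_call.value,
                "n_samples_used": res.n_samples_used,
            }
        )

    return {
        "sample_calls": pd.DataFrame(records),
        "pregnancy_results": pd.DataFrame(preg_records),
        "pregnancies": preg_results,
        "posteriors": summaries,
        "ntc": ntc_by_assay,
        "bias": bias_by_assay,
    }


def export_draws_csv(summary: PosteriorSummary, path) -> None:
    """Write posterior draws as a flat (chain, iteration, parameter, value)
    CSV for external trace plotting."""
    if summary.draws is None:
        raise ValueError("posterior was computed without return_draws=True")
    frames = []
    for name, arr in summary.draws.items():
        nch, nit = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(nch), nit),
                    "iteration": np.tile(np.arange(nit), nch),
                    "parameter": name,
                    "value": np.asarray(arr, dtype=float).ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
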