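"""End-to-end pipeline driver: VAT modelling → atlas overlap → fibre
connectivity → discriminative-fibre screen → leave-one-out validation,
with the behavioural (antisaccade) path run first when trial tables are
supplied.

Two entry modes mirror the fact that the imaging analysis only needs
per-subject change scores: either trial-level saccade tables are
provided (summarised and differenced here), or a ready-made change-score
table is consumed directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import Parcellation, overlap_report
from .crossval import loo_predict
from .leads import (
    DEFAULT_FIELD_CONSTANT,
    DEFAULT_VAT_THRESHOLD,
    LeadModel,
    StimSettings,
    efield,
    vat_from_efield,
)
from .oculomotor import ANTICIPATORY_CUTOFF_MS, change_scores, summarize_trials
from .screening import (
    ALPHA,
    DEFAULT_MIN_GROUP,
    DEFAULT_RETAIN_FRACTION,
    RMap,
    mass_t,
    rmap,
    retain_top,
    roi_correlations,
)
from .tracts import (
    DEFAULT_RESAMPLE_STEP,
    Tractogram,
    fiber_count_to_roi,
    streamlines_touching,
    voxel_fiber_density,
)
from .volumes import VAT, EmptyVATError

log = logging.getLogger("stimconn")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_inputs",
           "Issue", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and constants of one analysis run.

    In-memory objects may be supplied directly (the synthetic cohort
    path) or loaded from the referenced files. Analysis constants
    default to the reference values: 0.2 V/mm activation threshold,
    90 ms anticipatory cutoff, 20% fibre retention, minimum group size
    2, alpha 0.05, 0.5 mm streamline resampling.
    """

    # inputs: either in-memory objects ...
    parcellation: Parcellation | None = None
    tractogram: Tractogram | None = None
    leads: dict | None = None  # subject -> hemi -> LeadModel
    settings: dict | None = None  # subject -> hemi -> StimSettings
    trials: pd.DataFrame | None = None
    change_table: pd.DataFrame | None = None
    # ... or paths (loaded on run)
    input_dir: str | Path | None = None

    # parameters
    field_constant: float = DEFAULT_FIELD_CONSTANT
    vat_threshold: float = DEFAULT_VAT_THRESHOLD
    anticipatory_ms: float = ANTICIPATORY_CUTOFF_MS
    retain_fraction: float = DEFAULT_RETAIN_FRACTION
    min_group: int = DEFAULT_MIN_GROUP
    alpha: float = ALPHA
    resample_step: float = DEFAULT_RESAMPLE_STEP
    rng_seed: int = 0
    loocv_permutations: int = 199
    compute_rmaps: bool = True

    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for name in ("field_constant", "vat_threshold", "retain_fraction",
                     "resample_step", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def param_dict(self) -> dict:
        return {
            "field_constant": self.field_constant,
            "vat_threshold": self.vat_threshold,
            "anticipatory_ms": self.anticipatory_ms,
            "retain_fraction": self.retain_fraction,
            "min_group": self.min_group,
            "alpha": self.alpha,
            "resample_step": self.resample_step,
            "rng_seed": self.rng_seed,
            "loocv_permutations": self.loocv_permutations,
        }


@dataclass
class Issue:
    level: str  # "warning" | "fatal"
    stage: str
    message: str


@dataclass
class PipelineResult:
    vats: dict
    overlaps: pd.DataFrame
    connected_sets: dict
    roi_counts: pd.DataFrame
    change_table: pd.DataFrame
    behavior_summary: pd.DataFrame | None
    vat_correlations: pd.DataFrame  # change scores vs STN overlaps
    roi_correlation_table: pd.DataFrame
    fiber_profiles: dict  # outcome -> FiberProfile DataFrame
    rmaps: dict  # outcome -> RMap
    loocv: dict  # outcome -> LoocvResult
    provenance: dict


def _resolve_inputs(config: PipelineConfig) -> PipelineConfig:
    if config.input_dir is not None:
        from .synthetic import load_cohort_inputs

        loaded = load_cohort_inputs(config.input_dir)
        config = dataclasses.replace(config)
        for key in ("parcellation", "tractogram", "leads", "settings"):
            if getattr(config, key) is None:
                setattr(config, key, loaded.get(key))
        if config.trials is None:
            config.trials = loaded.get("trials")
        if config.change_table is None:
            config.change_table = loaded.get("change_table")
    return config


def validate_inputs(config: PipelineConfig) -> list[Issue]:
    """Consistency report on the configured inputs (no computation)."""
    config = _resolve_inputs(config)
    issues: list[Issue] = []
    say = lambda lvl, st, msg: issues.append(Issue(lvl, st, msg))  # noqa: E731
    if config.parcellation is None:
        say("fatal", "inputs", "no parcellation provided")
    if config.tractogram is None:
        say("fatal", "inputs", "no tractogram provided")
    if config.leads is None or config.settings is None:
        say("fatal", "inputs", "no lead models / stimulation settings provided")
    if config.trials is None and config.change_table is None:
        say("fatal", "inputs", "neither trial tables nor change scores provided")
    elif config.trials is None:
        say("warning", "inputs",
            "no trial tables: behavioural stage will be skipped, change scores used directly")
    if config.trials is not None:
        required = {"subject", "condition", "target_side", "first_saccade_direction",
                    "latency_ms"}
        missing = required - set(config.trials.columns)
        if missing:
            say("fatal", "behavior", f"trial table missing columns: {sorted(missing)}")
    if config.leads is not None and config.settings is not None:
        if set(config.leads) != set(config.settings):
            say("fatal", "vat", "lead and settings subject sets differ")
    if config.parcellation is not None and config.tractogram is not None:
        # streamlines should largely lie within the grid
        grid = config.parcellation.grid
        sample = config.tractogram.streamlines[:5]
        for s in sample:
            ijk = grid.world_to_index(s)
            if not grid.inside(ijk).any():
                say("warning", "tracts",
                    "a streamline lies entirely outside the parcellation grid")
                break
    return issues


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis sequence on the configured inputs.

    Stages: behaviour (optional) → VAT modelling → STN overlap →
    connectivity → screening (+R-maps) → leave-one-out validation.
    Failures abort with a stage-tagged error.
    """
    config = _resolve_inputs(config)
    fatal = [i for i in validate_inputs(config) if i.level == "fatal"]
    if fatal:
        raise StageError(fatal[0].stage, fatal[0].message)

    parc = config.parcellation
    grid = parc.grid

    # -- behaviour -------------------------------------------------------
    behavior_summary = None
    change_table = config.change_table
    if config.trials is not None:
        log.info("behavior: summarising %d trials", len(config.trials))
        behavior_summary = summarize_trials(config.trials, config.anticipatory_ms)
        change_table = change_scores(behavior_summary)
    change_table = change_table.sort_index()
    subjects = [s for s in config.leads if s in change_table.index]
    if len(subjects) < 4:
        raise StageError("inputs", f"only {len(subjects)} subjects with both "
                         "imaging and behavioural data")

    # -- VAT -------------------------------------------------------------
    vats: dict = {}
    for subject in subjects:
        vats[subject] = {}
        for hemi, lead in config.leads[subject].items():
            f = efield(config.settings[subject][hemi], lead, grid,
                       k=config.field_constant)
            vat = vat_from_efield(f, config.vat_threshold, hemisphere=hemi)
            if vat.is_empty:
                raise StageError(
                    "anatomy",
                    f"empty VAT for {subject}/{hemi} (amplitude too low for the "
                    f"{config.vat_threshold} V/mm threshold); overlap fractions undefined",
                )
            vats[subject][hemi] = vat
    log.info("vat: %d subjects x %d hemispheres", len(vats), 2)

    # -- overlap ---------------------------------------------------------
    try:
        overlaps = overlap_report(vats, parc)
    except EmptyVATError as e:  # pragma: no cover - guarded above
        raise StageError("anatomy", str(e)) from e

    outcome_cols = list(change_table.columns)
    vat_rows = []
    from .screening import spearman, DegenerateInputError

    for outcome in outcome_cols:
        for region in ("motor", "nonmotor"):
            x = overlaps.loc[subjects, region].to_numpy(dtype=float)
            y = change_table.loc[subjects, outcome].to_numpy(dtype=float)
            try:
                res = spearman(x, y)
                vat_rows.append({"region": region, "outcome": outcome,
                                 "rho": res.rho, "p": res.p, "n": res.n,
                                 "defined": True})
            except DegenerateInputError:
                vat_rows.append({"region": region, "outcome": outcome,
                                 "rho": np.nan, "p": np.nan, "n": len(subjects),
                                 "defined": False})
    vat_correlations = pd.DataFrame(vat_rows)

    # -- connectivity ----------------------------------------------------
    tracto = config.tractogram
    connected_sets: dict = {}
    density = {}
    for subject in subjects:
        seed = vats[subject]["left"].union(vats[subject]["right"])
        connected_sets[subject] = streamlines_touching(
            seed, tracto, config.resample_step
        )
        if config.compute_rmaps:
            density[subject] = voxel_fiber_density(
                seed, tracto, grid, config.resample_step
            )
    roi_counts = pd.DataFrame(
        {
            roi: {
                subject: fiber_count_to_roi(
                    vats[subject]["left"].union(vats[subject]["right"]),
                    mask, tracto, config.resample_step)
                for subject in subjects
            }
            for roi, mask in sorted(parc.roi_masks.items())
        }
    )
    roi_counts.index.name = "subject"
    log.info("connect: mean connected fibres %.1f",
             np.mean([len(v) for v in connected_sets.values()]))

    # -- screening -------------------------------------------------------
    roi_corr = roi_correlations(change_table.loc[subjects], roi_counts)
    fiber_profiles = {}
    rmaps: dict = {}
    for outcome in outcome_cols:
        profile = mass_t(change_table.loc[subjects, outcome], connected_sets,
                         tracto.ids, min_group=config.min_group)
        fiber_profiles[outcome] = retain_top(profile, config.retain_fraction)
        if config.compute_rmaps:
            stack = np.stack([density[s] for s in subjects])
            rmaps[outcome] = rmap(change_table.loc[subjects, outcome], stack)

    # -- crossval --------------------------------------------------------
    loocv = {}
    for i, outcome in enumerate(outcome_cols):
        loocv[outcome] = loo_predict(
            change_table.loc[subjects, outcome],
            connected_sets,
            tracto.ids,
            fraction=config.retain_fraction,
            min_group=config.min_group,
            n_permutations=config.loocv_permutations,
            rng=np.random.default_rng(
                np.random.SeedSequence([config.rng_seed, i]).generate_state(1)[0]
            ),
        )

    provenance = _provenance(config)
    result = PipelineResult(
        vats=vats,
        overlaps=overlaps,
        connected_sets=connected_sets,
        roi_counts=roi_counts,
        change_table=change_table.loc[subjects],
        behavior_summary=behavior_summary,
        vat_correlations=vat_correlations,
        roi_correlation_table=roi_corr,
        fiber_profiles=fiber_profiles,
        rmaps=rmaps,
        loocv=loocv,
        provenance=provenance,
    )
    if config.output_dir is not None:
        write_results(result, config)
    return result


def _provenance(config: PipelineConfig) -> dict:
    params = config.param_dict()
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {"package": "stimconn", "version": __version__,
            "config_hash": digest, **params}


def _header(provenance: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in sorted(provenance.items()))


def write_results(result: PipelineResult, config: PipelineConfig) -> dict[str, Path]:
    """Write the result bundle; every text output carries a provenance
    header (config hash, seed, version)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(result.provenance)
    paths = {}

    def _tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            fh.write(head)
            df.to_csv(fh, sep="\t", **kw)
        paths[name] = p

    _tsv("overlaps.tsv", result.overlaps)
    _tsv("roi_counts.tsv", result.roi_counts)
    _tsv("change_scores.tsv", result.change_table)
    _tsv("vat_correlations.tsv", result.vat_correlations, index=False)
    _tsv("roi_correlations.tsv", result.roi_correlation_table, index=False)
    if result.behavior_summary is not None:
        _tsv("behavior_summary.tsv", result.behavior_summary)
    for outcome, profile in result.fiber_profiles.items():
        _tsv(f"fiber_profile_{outcome}.tsv", profile)
    for outcome, rm in result.rmaps.items():
        import nibabel as nib

        p = outdir / f"rmap_{outcome}.nii.gz"
        grid = config.parcellation.grid
        nib.save(grid.to_nifti(rm.data.astype(np.float32),
                               descrip=result.provenance["config_hash"]), p)
        paths[p.name] = p
    loocv_summary = {
        outcome: res.summary() for outcome, res in result.loocv.items()
    }
    p = outdir / "loocv.json"
    with open(p, "w") as fh:
        json.dump({"_provenance": result.provenance, **loocv_summary}, fh, indent=1)
    paths[p.name] = p
    for outcome, res in result.loocv.items():
        _tsv(f"loocv_{outcome}.tsv", res.per_subject)
    return paths
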