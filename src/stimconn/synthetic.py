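"""Self-contained synthetic study generator with known ground truth.

Emulates the full data substrate of a bilateral STN-DBS antisaccade
study in one synthetic 1 mm standard space: directional leads and
stimulation programs for each subject, an ellipsoidal STN per hemisphere
partitioned into a dorsolateral motor and a ventromedial non-motor
(associative + limbic) territory, cortical oculomotor ROIs (FEF, SEF,
DLPFC, ACC bilaterally), streamline bundles with distinct STN
entry/bypass geometry, and behavioural outcomes with *planted* monotone
dependence on the imaging features:

* Δ error rate  = effect_error_rate x (bilateral non-motor overlap) + noise
* Δ latency     = effect_latency   x (bypass-bundle connectivity)   + noise

Trial-level antisaccade tables are then sampled so that they aggregate
back to the planted per-subject rates and latencies. Every artifact is
reproducible bit-for-bit from the config seed: all randomness flows from
one seed sequence with deterministic per-artifact children.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import leads as leads_mod
from .anatomy import NONMOTOR_PARTS, Parcellation, overlap_report
from .leads import LeadModel, StimSettings, efield, vat_from_efield
from .tracts import Tractogram, streamlines_touching
from .volumes import VAT, Grid

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticCohort",
           "generate_cohort", "generate_trials", "write_cohort", "load_cohort"]

ENTRY_REGIONS = ("ventromedial_STN", "dorsolateral_STN", "lateral_bypass")
ROI_NAMES = ("fef", "sef", "dlpfc", "acc")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated study design: 14 subjects, three blocks
    of 50 antisaccades per condition, targets at 10 degrees, a 0.2 V/mm
    activation threshold on a 1 mm isotropic grid.
    """

    n_subjects: int = 14
    rng_seed: int = 0

    # -- space & anatomy -------------------------------------------------
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    stn_centers: dict = field(
        default_factory=lambda: {"right": (22.0, 32.0, 26.0), "left": (42.0, 32.0, 26.0)}
    )
    stn_axes: tuple[float, float, float] = (4.5, 3.5, 3.0)
    nonmotor_fraction: float = 0.35
    # of the non-motor territory, the (ventral) share labelled limbic
    limbic_share: float = 0.3
    roi_radius: float = 3.0

    # -- tractogram ------------------------------------------------------
    n_fibers_per_bundle: int = 30  # per hemisphere
    bundle_specs: tuple = (
        ("ventromedial_STN", "acc"),
        ("dorsolateral_STN", "fef"),
        ("lateral_bypass", "sef"),
    )
    fiber_jitter_mm: float = 0.8
    target_jitter_mm: float = 1.5

    # -- leads & stimulation --------------------------------------------
    amplitude_range_ma: tuple[float, float] = (1.5, 3.5)
    depth_offset_range: tuple[float, float] = (-3.5, 2.0)  # along dorsolateral axis
    lateral_offset_range: tuple[float, float] = (0.0, 4.0)
    hemi_jitter_mm: float = 0.4
    field_constant: float = leads_mod.DEFAULT_FIELD_CONSTANT
    vat_threshold: float = leads_mod.DEFAULT_VAT_THRESHOLD

    # -- planted behavioural effects ------------------------------------
    effect_error_rate: float = 0.5  # Δ error rate per unit non-motor overlap
    effect_latency: float = -60.0  # ms per unit bypass connectivity fraction
    # None -> 0.25 x range of the noiseless planted Δ (the study's
    # signal-to-noise condition); a float fixes an absolute sd.
    noise_sd_error: float | None = None
    noise_sd_latency: float | None = None

    # -- behavioural baseline & trials ----------------------------------
    base_error_rate: float = 0.45
    subject_error_sd: float = 0.18
    base_latency_ms: float = 355.0
    subject_latency_sd: float = 45.0
    latency_sigma: float = 0.25  # lognormal shape of trial latencies
    error_latency_factor: float = 0.9  # errors are slightly faster
    anticipatory_fraction: float = 0.03
    trials_per_block: int = 50
    n_blocks: int = 3
    target_eccentricity_deg: float = 10.0
    target_side_mode: str = "balanced"  # or "alternate"

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for frac in (self.nonmotor_fraction, self.limbic_share):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if not 0 <= self.anticipatory_fraction < 1:
            raise ValueError("anticipatory_fraction must lie in [0, 1)")
        if any(a <= 0 for a in self.stn_axes):
            raise ValueError("STN ellipsoid axes must be positive")
        if self.target_side_mode not in ("balanced", "alternate"):
            raise ValueError("target_side_mode must be 'balanced' or 'alternate'")

    @property
    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_block * self.n_blocks


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    overlaps: pd.DataFrame  # per subject: motor/nonmotor/outside (bilateral)
    bypass_fraction: pd.Series  # per subject
    noiseless: pd.DataFrame  # per subject: delta_error_rate, delta_latency_ms
    culprit_fibers: dict  # outcome -> sorted fibre ids carrying the effect
    bundle_table: pd.DataFrame  # fiber_id -> bundle, hemisphere, target
    noise_sd: dict  # realized noise scales


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    grid: Grid
    parcellation: Parcellation
    leads: dict  # subject -> hemi -> LeadModel
    settings: dict  # subject -> hemi -> StimSettings
    tractogram: Tractogram
    change_table: pd.DataFrame
    trial_tables: pd.DataFrame  # all subjects/conditions, long format
    ground_truth: GroundTruth
    vats: dict  # subject -> hemi -> VAT (derived, for convenience)


# ---------------------------------------------------------------------------
# anatomy


def _hemi_units(hemi: str) -> tuple[np.ndarray, np.ndarray]:
    """(dorsolateral, lateral) unit vectors for one hemisphere."""
    lat = np.array([-1.0, 0.0, 0.0]) if hemi == "right" else np.array([1.0, 0.0, 0.0])
    u = lat + np.array([0.0, 0.0, 1.0])
    return u / np.linalg.norm(u), lat


def _roi_centers(config: SyntheticConfig) -> dict[str, np.ndarray]:
    base = {
        "fef": np.array([17.0, 26.0, 52.0]),
        "sef": np.array([27.0, 38.0, 54.0]),
        "dlpfc": np.array([14.0, 44.0, 48.0]),
        "acc": np.array([29.0, 48.0, 50.0]),
    }
    midline = (config.grid_shape[0] - 1) / 2.0
    out = {}
    for name, c in base.items():
        out[f"{name}_right"] = c
        mirrored = c.copy()
        mirrored[0] = 2 * midline - c[0]
        out[f"{name}_left"] = mirrored
    return out


def build_parcellation(config: SyntheticConfig) -> Parcellation:
    """Ellipsoidal STN per hemisphere split along the dorsolateral axis
    into motor / associative / limbic, plus spherical cortical ROIs.

    The motor/non-motor boundary is placed at the exact quantile of the
    dorsolateral coordinate so the non-motor territory holds the
    configured fraction of STN voxels.
    """
    grid = Grid(shape=config.grid_shape)
    data = np.zeros(config.grid_shape, dtype=np.int16)
    labels: dict[str, int] = {}
    code = 1
    centers = grid.voxel_centers()
    axes = np.asarray(config.stn_axes, dtype=float)
    for hemi in ("left", "right"):
        c = np.asarray(config.stn_centers[hemi], dtype=float)
        u, _ = _hemi_units(hemi)
        rel = (centers - c) / axes
        inside = (rel**2).sum(axis=1) <= 1.0
        dots = (centers - c) @ u
        stn_dots = dots[inside]
        tau = np.quantile(stn_dots, config.nonmotor_fraction)
        tau_limbic = np.quantile(stn_dots, config.nonmotor_fraction * config.limbic_share)
        part = np.full(len(centers), "", dtype=object)
        part[inside & (dots >= tau)] = "motor"
        part[inside & (dots < tau) & (dots >= tau_limbic)] = "associative"
        part[inside & (dots < tau_limbic)] = "limbic"
        for name in ("motor", *NONMOTOR_PARTS):
            label = f"stn_{name}_{hemi}"
            labels[label] = code
            data.flat[np.flatnonzero(part == name)] = code
            code += 1
    roi_masks = {}
    for name, center in _roi_centers(config).items():
        d = np.linalg.norm(centers - center, axis=1)
        roi_masks[name] = (d <= config.roi_radius).reshape(config.grid_shape)
    return Parcellation(data=data, grid=grid, labels=labels, roi_masks=roi_masks)


# ---------------------------------------------------------------------------
# tractogram


def _bundle_waypoints(
    entry: str,
    hemi: str,
    config: SyntheticConfig,
    roi_centers: dict,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Waypoints for ONE fibre of a bundle (per-fibre variation included).

    The three bundle families have deliberately distinct STN geometry:

    * ``ventromedial_STN`` fibres *terminate* in the non-motor territory,
      with terminal depths spread topographically along the
      dorsolateral-ventromedial axis, and leave medially toward cortex;
    * ``dorsolateral_STN`` fibres traverse the nucleus dorsoventrally and
      exit over the dorsolateral edge — any stimulation volume reaching
      the STN touches them, so they are shared by most of the cohort;
    * ``lateral_bypass`` fibres run past the lateral STN border without
      entering the nucleus (corticofugal-like course).
    """
    c = np.asarray(config.stn_centers[hemi], dtype=float)
    u, lat = _hemi_units(hemi)
    up = np.array([0.0, 0.0, 1.0])
    jit = lambda sd: rng.normal(0.0, sd, size=3)  # noqa: E731
    target = roi_centers[f"{_target_for(entry, config)}_{hemi}"]
    if entry == "ventromedial_STN":
        depth = rng.uniform(1.8, 3.4)
        return [
            c - depth * u + jit(0.5),
            c - 4.5 * u + 6.0 * up - 1.5 * lat + jit(config.fiber_jitter_mm),
            target + jit(config.target_jitter_mm),
        ]
    if entry == "dorsolateral_STN":
        return [
            c - 4.5 * u - 5.0 * up + jit(config.fiber_jitter_mm),
            c + jit(config.fiber_jitter_mm),
            c + 4.5 * u + 4.0 * up + jit(config.fiber_jitter_mm),
            target + jit(config.target_jitter_mm),
        ]
    if entry == "lateral_bypass":
        return [
            c + 6.2 * lat - 8.0 * up + jit(config.fiber_jitter_mm),
            c + 6.2 * lat + jit(config.fiber_jitter_mm),
            c + 6.0 * lat + 8.0 * up + jit(config.fiber_jitter_mm),
            target + jit(config.target_jitter_mm),
        ]
    raise ValueError(f"unknown entry region {entry!r}")


def _target_for(entry: str, config: SyntheticConfig) -> str:
    for e, t in config.bundle_specs:
        if e == entry:
            return t
    raise ValueError(f"no bundle spec for {entry!r}")


def build_tractogram(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[Tractogram, pd.DataFrame]:
    """Noisy-spline bundles through declared waypoints.

    Each fibre jitters the shared waypoints (target end more strongly)
    and is interpolated with a centripetal-ish cubic spline sampled at
    ~1 mm. Returns the tractogram and a fibre table (bundle, hemisphere,
    target ROI per fibre id).
    """
    roi_centers = _roi_centers(config)
    streamlines, rows = [], []
    fid = 0
    for entry, target in config.bundle_specs:
        for hemi in ("left", "right"):
            for _ in range(config.n_fibers_per_bundle):
                pts = np.asarray(
                    _bundle_waypoints(entry, hemi, config, roi_centers, rng)
                )
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                t = np.concatenate([[0.0], np.cumsum(seg)])
                spline = CubicSpline(t, pts, axis=0)
                n_samples = max(int(t[-1]), 8)
                streamlines.append(spline(np.linspace(0.0, t[-1], n_samples)))
                rows.append(
                    {"fiber_id": fid, "bundle": entry, "hemisphere": hemi, "target": target}
                )
                fid += 1
    table = pd.DataFrame(rows).set_index("fiber_id")
    return Tractogram(streamlines=streamlines, ids=table.index.to_numpy()), table


# ---------------------------------------------------------------------------
# leads


def build_leads(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Per-subject bilateral leads and stimulation programs.

    Lead placement varies along the dorsolateral-ventromedial axis and
    laterally (shared between hemispheres up to a small jitter), which is
    what spreads the cohort over distinct non-motor overlaps and
    bypass-bundle exposures.
    """
    leads: dict = {}
    settings: dict = {}
    lo_d, hi_d = config.depth_offset_range
    lo_l, hi_l = config.lateral_offset_range
    lo_a, hi_a = config.amplitude_range_ma
    for subject in config.subjects:
        depth = rng.uniform(lo_d, hi_d)
        lateral = rng.uniform(lo_l, hi_l)
        amplitude = rng.uniform(lo_a, hi_a)
        leads[subject], settings[subject] = {}, {}
        for hemi in ("left", "right"):
            c = np.asarray(config.stn_centers[hemi], dtype=float)
            u, lat = _hemi_units(hemi)
            center = (
                c
                + depth * u
                + lateral * lat
                + rng.normal(0.0, config.hemi_jitter_mm, size=3)
            )
            axis = np.array([0.15, 0.1, 1.0]) * (np.array([-1, 1, 1]) if hemi == "right" else 1)
            lead = LeadModel(tip=center, axis=axis, rotation_deg=float(rng.uniform(0, 360)))
            # place the distal ring contact at the intended VAT centre
            lead.tip = center - lead.tip_offset * lead.axis
            leads[subject][hemi] = lead
            settings[subject][hemi] = StimSettings(
                amplitude_ma=float(amplitude), shares={1: 1.0}, hemisphere=hemi
            )
    return leads, settings


# ---------------------------------------------------------------------------
# trials


def generate_trials(
    subject_effects: dict,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trial table for one subject from planted per-condition outcomes.

    ``subject_effects`` holds ``subject``, ``error_rate`` and
    ``mean_latency_ms`` per condition. Latencies of non-anticipatory
    trials are lognormal with the planted mean; a configured fraction of
    trials is anticipatory (< 90 ms, uniform in [40, 90)). Errors are
    Bernoulli draws among non-anticipatory trials only, so the table
    aggregates back to the planted error rate up to binomial noise.
    """
    n = config.trials_per_condition
    rows = []
    for condition in ("off", "on"):
        p_err = float(subject_effects["error_rate"][condition])
        mean_lat = float(subject_effects["mean_latency_ms"][condition])
        sides = _target_sides(config, rng)
        anticipatory = rng.random(n) < config.anticipatory_fraction
        errors = rng.random(n) < p_err
        sigma = config.latency_sigma
        for k in range(n):
            side = sides[k]
            if anticipatory[k]:
                latency = float(rng.uniform(40.0, 89.999))
                direction = side if rng.random() < 0.5 else _opposite(side)
            elif errors[k]:
                mu = np.log(mean_lat * config.error_latency_factor) - sigma**2 / 2
                latency = float(rng.lognormal(mu, sigma))
                direction = side
            else:
                mu = np.log(mean_lat) - sigma**2 / 2
                latency = float(rng.lognormal(mu, sigma))
                direction = _opposite(side)
            latency = max(latency, 90.0) if not anticipatory[k] else latency
            rows.append(
                {
                    "subject": subject_effects["subject"],
                    "condition": condition,
                    "block": k // config.trials_per_block + 1,
                    "target_side": side,
                    "first_saccade_direction": direction,
                    "latency_ms": round(latency, 1),
                    "target_eccentricity_deg": config.target_eccentricity_deg,
                }
            )
    return pd.DataFrame(rows)


def _opposite(side: str) -> str:
    return "left" if side == "right" else "right"


def _target_sides(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    n = config.trials_per_condition
    if config.target_side_mode == "alternate":
        return ["left" if k % 2 == 0 else "right" for k in range(n)]
    sides = []
    for _ in range(config.n_blocks):
        block = ["left", "right"] * (config.trials_per_block // 2)
        block += ["left"] * (config.trials_per_block % 2)
        rng.shuffle(block)
        sides.extend(block)
    return sides


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Build the full synthetic study with known ground truth.

    All sub-generators draw from deterministic children of one seed
    sequence, so a given config reproduces every artifact exactly.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    keys = ("tracts", "leads", "noise", "baseline", "trials")
    child = dict(zip(keys, ss.spawn(len(keys))))

    parcellation = build_parcellation(config)
    grid = parcellation.grid
    tractogram, bundle_table = build_tractogram(config, np.random.default_rng(child["tracts"]))
    leads, settings = build_leads(config, np.random.default_rng(child["leads"]))

    # derive VATs and imaging features (deterministic given leads)
    vats: dict = {}
    for subject in config.subjects:
        vats[subject] = {}
        for hemi in ("left", "right"):
            f = efield(settings[subject][hemi], leads[subject][hemi], grid,
                       k=config.field_constant)
            vats[subject][hemi] = vat_from_efield(f, config.vat_threshold, hemisphere=hemi)

    overlaps = overlap_report(vats, parcellation)

    bypass_ids = set(bundle_table.index[bundle_table["bundle"] == "lateral_bypass"])
    vm_ids = set(bundle_table.index[bundle_table["bundle"] == "ventromedial_STN"])
    n_bypass = max(len(bypass_ids), 1)
    bypass_fraction = {}
    for subject in config.subjects:
        seed_vat = vats[subject]["left"].union(vats[subject]["right"])
        touched = streamlines_touching(seed_vat, tractogram)
        bypass_fraction[subject] = len(touched & bypass_ids) / n_bypass
    bypass_fraction = pd.Series(bypass_fraction, name="bypass_fraction")

    noiseless = pd.DataFrame(
        {
            "delta_error_rate": config.effect_error_rate * overlaps["nonmotor"],
            "delta_latency_ms": config.effect_latency * bypass_fraction,
        }
    )
    sd_err = (
        config.noise_sd_error
        if config.noise_sd_error is not None
        else 0.25 * float(np.ptp(noiseless["delta_error_rate"]))
    )
    sd_lat = (
        config.noise_sd_latency
        if config.noise_sd_latency is not None
        else 0.25 * float(np.ptp(noiseless["delta_latency_ms"]))
    )
    rng_noise = np.random.default_rng(child["noise"])
    change_table = pd.DataFrame(
        {
            "delta_error_rate": noiseless["delta_error_rate"]
            + rng_noise.normal(0.0, sd_err, config.n_subjects),
            "delta_latency_ms": noiseless["delta_latency_ms"]
            + rng_noise.normal(0.0, sd_lat, config.n_subjects),
        }
    )
    change_table.index.name = "subject"

    # behavioural baselines and trial tables consistent with the deltas
    rng_base = np.random.default_rng(child["baseline"])
    p_off = np.clip(
        config.base_error_rate
        + rng_base.normal(0.0, config.subject_error_sd, config.n_subjects),
        0.15,
        0.60,
    )
    lat_off = np.clip(
        config.base_latency_ms
        + rng_base.normal(0.0, config.subject_latency_sd, config.n_subjects),
        220.0,
        520.0,
    )
    trial_rngs = np.random.default_rng(child["trials"]).spawn(config.n_subjects)
    tables = []
    for i, subject in enumerate(config.subjects):
        effects = {
            "subject": subject,
            "error_rate": {
                "off": float(p_off[i]),
                "on": float(
                    np.clip(p_off[i] + change_table["delta_error_rate"].iloc[i], 0.02, 0.98)
                ),
            },
            "mean_latency_ms": {
                "off": float(lat_off[i]),
                "on": float(
                    max(lat_off[i] + change_table["delta_latency_ms"].iloc[i], 150.0)
                ),
            },
        }
        tables.append(generate_trials(effects, config, trial_rngs[i]))
    trial_tables = pd.concat(tables, ignore_index=True)

    ground_truth = GroundTruth(
        overlaps=overlaps,
        bypass_fraction=bypass_fraction,
        noiseless=noiseless,
        culprit_fibers={
            "delta_error_rate": sorted(vm_ids),
            "delta_latency_ms": sorted(bypass_ids),
        },
        bundle_table=bundle_table,
        noise_sd={"delta_error_rate": sd_err, "delta_latency_ms": sd_lat},
    )
    return SyntheticCohort(
        config=config,
        grid=grid,
        parcellation=parcellation,
        leads=leads,
        settings=settings,
        tractogram=tractogram,
        change_table=change_table,
        trial_tables=trial_tables,
        ground_truth=ground_truth,
        vats=vats,
    )


# ---------------------------------------------------------------------------
# on-disk form


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all artifacts: NIfTI atlas/ROIs, TRK tractogram, TSV tables,
    JSON ground truth and lead/settings config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["parcellation"] = outdir / "parcellation.nii.gz"
    cohort.parcellation.save(paths["parcellation"])

    paths["tractogram"] = outdir / "tractogram.trk"
    cohort.tractogram.save_trk(paths["tractogram"], cohort.grid)

    paths["trials"] = outdir / "trials.tsv"
    cohort.trial_tables.to_csv(paths["trials"], sep="\t", index=False)
    paths["change_scores"] = outdir / "change_scores.tsv"
    cohort.change_table.to_csv(paths["change_scores"], sep="\t")

    lead_cfg = {}
    for subject in cohort.config.subjects:
        lead_cfg[subject] = {}
        for hemi in ("left", "right"):
            lead = cohort.leads[subject][hemi]
            st = cohort.settings[subject][hemi]
            lead_cfg[subject][hemi] = {
                "tip": [round(v, 6) for v in lead.tip],
                "axis": [round(v, 6) for v in lead.axis],
                "rotation_deg": round(lead.rotation_deg, 6),
                "amplitude_ma": st.amplitude_ma,
                "shares": {str(k): v for k, v in st.shares.items()},
            }
    paths["leads"] = outdir / "leads.json"
    with open(paths["leads"], "w") as fh:
        json.dump(lead_cfg, fh, indent=1, sort_keys=True)

    gt = cohort.ground_truth
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "overlaps": gt.overlaps.round(9).to_dict(orient="index"),
                "bypass_fraction": gt.bypass_fraction.round(9).to_dict(),
                "noiseless": gt.noiseless.round(9).to_dict(orient="index"),
                "culprit_fibers": {k: [int(i) for i in v] for k, v in gt.culprit_fibers.items()},
                "noise_sd": gt.noise_sd,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["bundles"] = outdir / "bundles.tsv"
    gt.bundle_table.to_csv(paths["bundles"], sep="\t")
    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        cfg = asdict(cohort.config)
        json.dump(cfg, fh, indent=1, sort_keys=True, default=list)
    return paths


def load_cohort_inputs(indir: str | Path) -> dict:
    """Load the on-disk artifacts back as pipeline inputs."""
    indir = Path(indir)
    parcellation = Parcellation.load(indir / "parcellation.nii.gz")
    tractogram = Tractogram.load(indir / "tractogram.trk")
    with open(indir / "leads.json") as fh:
        lead_cfg = json.load(fh)
    leads, settings = {}, {}
    for subject, per_hemi in lead_cfg.items():
        leads[subject], settings[subject] = {}, {}
        for hemi, spec in per_hemi.items():
            leads[subject][hemi] = LeadModel(
                tip=np.asarray(spec["tip"]),
                axis=np.asarray(spec["axis"]),
                rotation_deg=spec["rotation_deg"],
            )
            settings[subject][hemi] = StimSettings(
                amplitude_ma=spec["amplitude_ma"],
                shares={int(k): v for k, v in spec["shares"].items()},
                hemisphere=hemi,
            )
    out = {
        "parcellation": parcellation,
        "tractogram": tractogram,
        "leads": leads,
        "settings": settings,
    }
    trials = indir / "trials.tsv"
    if trials.exists():
        out["trials"] = pd.read_csv(trials, sep="\t", comment="#")
    changes = indir / "change_scores.tsv"
    if changes.exists():
        out["change_table"] = pd.read_csv(changes, sep="\t", comment="#", index_col="subject")
    return out


load_cohort = load_cohort_inputs
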