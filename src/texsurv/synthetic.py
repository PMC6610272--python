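"""Synthetic tumour phantoms and linked survival cohorts.

No patient data ship with this package; this module generates inputs with
the statistical structure the analysis assumes, so the whole pipeline runs
end to end:

* **Phantoms** — ellipsoidal tumour masks of a prescribed volume on a
  regular voxel grid, filled with a smoothed Gaussian intensity field whose
  standard deviation (the *heterogeneity* parameter, as a fraction of the
  base intensity) controls textural homogeneity.  Intensities are rounded
  to integer grey values, as MR magnitude images are stored; this is what
  lets heterogeneity drive histogram uniformity (min-max quantization is
  otherwise invariant to pure intensity scaling): near-zero noise occupies
  one or two grey levels (uniformity -> 1), larger noise spreads the
  histogram.  Two sequences ("T2WI", "CE-T1WI") share the mask but carry
  independently drawn intensity fields.
* **Cohorts** — clinical tables with the stage mix, sex ratio, age
  distribution, ~33% event fraction and 4-47-month PFS range of a
  79-patient nasopharyngeal-carcinoma cohort; progression times follow an
  exponential proportional-hazards model whose linear predictor acts
  through tumour volume and CE-T1WI uniformity only, and administrative
  censoring guarantees >= 24 months of follow-up for every non-progressor.

All randomness flows from explicit seeds; no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .texture import TextureConfig, extract_features, feature_row
from .voi import TumourVOI, VoxelVolume, make_voi

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "draw_phantom_specs",
    "patient_phantom",
    "generate_feature_table",
    "simulate_cohort",
    "generate_cohort",
    "cohort_filter",
    "make_screening_table",
    "STAGE_PROBS",
    "T_STAGE_PROBS",
    "N_STAGE_PROBS",
]

# Cohort composition defaults: overall stage I-IV, T 1-4, N 0-3 frequencies
# and the 52/79 male fraction of the emulated 79-patient cohort.
STAGE_PROBS = (0.038, 0.278, 0.380, 0.304)
T_STAGE_PROBS = (0.443, 0.241, 0.190, 0.127)
N_STAGE_PROBS = (0.051, 0.405, 0.342, 0.203)
MALE_FRACTION = 52 / 79
EXCLUSION_FLAGS = (
    "other_malignancy",
    "distant_metastasis_at_dx",
    "no_mass_formation",
    "incomplete_followup",
)


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic tumour: geometry, intensity model and seed.

    The intensity model is a bright "rim" compartment at ``base_intensity``
    and an optional darker central "core" (emulating necrosis / poorly
    enhancing tissue), each carrying its own smoothed noise field:

        I = base * (1 - core_contrast * core
                      + heterogeneity * n_rim
                      + core_noise * core * n_core)

    ``heterogeneity`` is the rim noise SD as a fraction of base_intensity
    (0 with the default zero-contrast core gives an exactly constant VOI);
    ``core_fraction`` is the core's share of the tumour volume,
    ``core_contrast`` its signal deficit as a fraction of base, and
    ``core_noise`` the extra noise SD inside the core.  ``subregions``
    adds multifocal signal patches — each (contrast, threshold) pair
    carves a random smooth subregion (a smoothed Gaussian field exceeding
    the threshold) and offsets it by ``contrast`` of base; this emulates
    patchy, multifocal enhancement and keeps the across-patient histogram
    variation genuinely high-dimensional.  ``smoothing`` is the Gaussian
    scale (voxels) giving the noise fields their spatial grain.
    Intensities are rounded to integer grey values.
    """

    target_volume_cm3: float = 11.7
    base_intensity: float = 100.0
    heterogeneity: float = 0.0025
    smoothing: float = 1.0
    core_fraction: float = 0.0
    core_contrast: float = 0.0
    core_noise: float = 0.0
    subregions: tuple[tuple[float, float], ...] = ()
    spacing: tuple[float, float, float] = (0.75, 0.75, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_volume_cm3 <= 0:
            raise ValueError("target_volume_cm3 must be positive")
        for name in ("heterogeneity", "core_contrast", "core_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in [0, 1)")


def make_phantom(
    spec: PhantomSpec, sequence_role: str = "CE-T1WI"
) -> tuple[VoxelVolume, TumourVOI]:
    """Build one phantom volume + VOI for one MR sequence role.

    The mask is the set of voxel centres inside an ellipsoid with semi-axis
    ratios 1.25 : 1 : 0.8 (equal enclosed volume to a sphere) sized to the
    target volume; its voxelized volume is within ~5% of the target for
    tumours of more than a few dozen voxels.  The core, when requested, is
    the concentric inner ellipsoid holding ``core_fraction`` of the
    volume.  Deterministic per (seed, sequence_role).
    """
    dx, dy, dz = spec.spacing
    voxel_mm3 = dx * dy * dz
    target_mm3 = spec.target_volume_cm3 * 1000.0
    if target_mm3 < voxel_mm3:
        raise ValueError("target volume is smaller than one voxel")
    r = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi = np.array([1.25 * r, 1.0 * r, 0.8 * r])
    half = np.ceil(semi / (dx, dy, dz)).astype(int) + 1
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, (dx, dy, dz))]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rho2 = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2
    mask = rho2 <= 1.0
    if not mask.any():  # pragma: no cover - excluded by the voxel-size check
        raise ValueError("target volume too small to voxelize")
    # concentric similar ellipsoid: volume scales with the cube of the
    # radial scale, so rho2 <= fraction^(2/3) holds core_fraction of it
    core = (rho2 <= spec.core_fraction ** (2.0 / 3.0)) if spec.core_fraction > 0 else None

    # sequence-specific stream: same mask, independent intensity fields
    stream = np.random.default_rng([spec.seed, _role_tag(sequence_role)])
    rel = -spec.core_contrast * core if core is not None else 0.0
    rel = rel + spec.heterogeneity * _smooth_unit_field(stream, mask, spec.smoothing)
    if core is not None and spec.core_noise > 0:
        rel = rel + spec.core_noise * core * _smooth_unit_field(
            stream, mask, spec.smoothing
        )
    for contrast, threshold in spec.subregions:
        grain = stream.uniform(1.0, 2.5)
        patch = _smooth_unit_field(stream, mask, grain) > threshold
        rel = rel + contrast * patch
    grid = np.zeros(mask.shape)
    grid[mask] = spec.base_intensity * (1.0 + np.broadcast_to(rel, mask.shape)[mask])
    grid = np.rint(grid)  # integer grey values, as stored MR magnitudes
    volume = VoxelVolume(grid=grid, spacing=spec.spacing, sequence_role=sequence_role)
    return volume, make_voi(volume, mask)


def _smooth_unit_field(stream, mask, smoothing: float) -> np.ndarray:
    """Smoothed Gaussian field normalized to zero mean / unit SD in-mask."""
    noise = stream.standard_normal(mask.shape)
    if smoothing > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothing)
    inside = noise[mask]
    sd = inside.std()
    if sd > 0:
        noise = (noise - inside.mean()) / sd
    return noise


def _role_tag(sequence_role: str) -> int:
    tags = {"T2WI": 2, "CE-T1WI": 1}
    try:
        return tags[sequence_role]
    except KeyError:
        raise ValueError(f"unknown sequence role {sequence_role!r}") from None


# ----------------------------------------------------------------- cohort


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, composition and hazard structure.

    log_hr_volume is the log hazard ratio per cm^3 of tumour volume
    (default log 1.054); log_hr_uniformity per unit of CE-T1WI uniformity
    (strongly negative: higher uniformity, lower hazard — on the raw 0-1
    scale even a modest protective effect has a large |log HR|).
    baseline_hazard is the event rate per month at the cohort-mean linear
    predictor; its default puts the event fraction near 26/79 under the
    default follow-up window of 24-47 months, which also enforces the
    >= 24-month follow-up guarantee for non-progressors.
    """

    n_patients: int = 79
    stage_probs: tuple[float, float, float, float] = STAGE_PROBS
    t_stage_probs: tuple[float, float, float, float] = T_STAGE_PROBS
    n_stage_probs: tuple[float, float, float, float] = N_STAGE_PROBS
    male_fraction: float = MALE_FRACTION
    age_mean: float = 46.6
    age_sd: float = 11.5
    log_hr_volume: float = float(np.log(1.054))
    log_hr_uniformity: float = -12.0
    baseline_hazard: float = 0.0055
    followup_window_months: tuple[float, float] = (24.0, 47.0)
    # phantom population: log-normal tumour volumes; per-sequence
    # independent rim noise, smoothing grain and core structure
    volume_log_mean: float = float(np.log(9.0))
    volume_log_sd: float = 0.85
    heterogeneity_log_mean: float = float(np.log(0.002))
    heterogeneity_log_sd: float = 0.5
    smoothing_range: tuple[float, float] = (0.5, 1.8)
    core_fraction_range: tuple[float, float] = (0.0, 0.3)
    core_contrast_range: tuple[float, float] = (0.0, 0.15)
    core_noise_log_mean: float = float(np.log(0.015))
    core_noise_log_sd: float = 0.7
    subregion_rate: float = 1.2
    subregion_contrast_range: tuple[float, float] = (-0.08, 0.03)
    subregion_threshold_range: tuple[float, float] = (0.8, 1.8)
    spacing: tuple[float, float, float] = (0.75, 0.75, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        # printed frequency tables round to 0.1%, so allow tiny slack and
        # renormalize exactly at draw time
        for name in ("stage_probs", "t_stage_probs", "n_stage_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 5e-3 or min(probs) < 0:
                raise ValueError("stage probabilities must be a distribution")
            norm = tuple(p / sum(probs) for p in probs)
            object.__setattr__(self, name, norm)
        if self.followup_window_months[0] < 24.0:
            raise ValueError("follow-up window must guarantee >= 24 months")


def draw_phantom_specs(spec: CohortSpec) -> pd.DataFrame:
    """Per-patient phantom parameters for one cohort draw.

    One row per patient: target volume (log-normal), CE-T1WI and
    (independent) T2WI heterogeneity, per-sequence smoothing scales and a
    per-patient phantom seed.  Deterministic per cohort seed.
    """
    rng = np.random.default_rng([spec.seed, 101])
    n = spec.n_patients
    cols: dict[str, np.ndarray] = {
        "target_volume_cm3": rng.lognormal(spec.volume_log_mean, spec.volume_log_sd, n)
    }
    for tag in ("cet1wi", "t2wi"):  # sequence contrasts differ: independent draws
        cols[f"het_{tag}"] = rng.lognormal(
            spec.heterogeneity_log_mean, spec.heterogeneity_log_sd, n
        )
        cols[f"smooth_{tag}"] = rng.uniform(*spec.smoothing_range, n)
        cols[f"corefrac_{tag}"] = rng.uniform(*spec.core_fraction_range, n)
        cols[f"corecontrast_{tag}"] = rng.uniform(*spec.core_contrast_range, n)
        cols[f"corenoise_{tag}"] = rng.lognormal(
            spec.core_noise_log_mean, spec.core_noise_log_sd, n
        )
        counts = rng.poisson(spec.subregion_rate, n)
        cols[f"subregions_{tag}"] = [
            tuple(
                (
                    float(rng.uniform(*spec.subregion_contrast_range)),
                    float(rng.uniform(*spec.subregion_threshold_range)),
                )
                for _ in range(k)
            )
            for k in counts
        ]
    cols["phantom_seed"] = rng.integers(0, 2**31 - 1, n)
    return pd.DataFrame(
        cols, index=pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    )


def patient_phantom(
    params: pd.Series, role: str, spacing: tuple[float, float, float]
) -> tuple[VoxelVolume, TumourVOI]:
    """Materialize one sequence's phantom from a `draw_phantom_specs` row."""
    tag = "".join(c for c in role.lower() if c.isalnum())
    pspec = PhantomSpec(
        target_volume_cm3=float(params["target_volume_cm3"]),
        heterogeneity=float(params[f"het_{tag}"]),
        smoothing=float(params[f"smooth_{tag}"]),
        core_fraction=float(params[f"corefrac_{tag}"]),
        core_contrast=float(params[f"corecontrast_{tag}"]),
        core_noise=float(params[f"corenoise_{tag}"]),
        subregions=tuple(params[f"subregions_{tag}"]),
        spacing=spacing,
        seed=int(params["phantom_seed"]),
    )
    return make_phantom(pspec, role)


def generate_feature_table(
    spec: CohortSpec,
    texture_config: TextureConfig | None = None,
) -> pd.DataFrame:
    """Draw per-patient phantoms and extract their feature rows.

    Both sequences share each patient's tumour mask but carry independent
    intensity fields.  Returns one tidy row per patient (columns
    ``<sequence>_<feature>`` + ``volume_cm3``), indexed by patient_id.
    Tumour volume is measured on the T2WI mask (identical to the CE-T1WI
    mask here by construction).
    """
    cfg = texture_config or TextureConfig()
    params = draw_phantom_specs(spec)
    rows = []
    for pid, p in params.iterrows():
        per_seq = {}
        vol_cm3 = np.nan
        for role in ("CE-T1WI", "T2WI"):
            volume, voi = patient_phantom(p, role, spec.spacing)
            feats = extract_features(volume, voi, cfg)
            if role == "T2WI":
                vol_cm3 = feats["volume_cm3"]
            per_seq[role] = feats
        row = feature_row(per_seq, vol_cm3)
        row["patient_id"] = pid
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def simulate_cohort(spec: CohortSpec, feature_rows: pd.DataFrame) -> pd.DataFrame:
    """Attach clinical covariates and simulated PFS to a feature table.

    Progression times are exponential with hazard
    ``baseline_hazard * exp(b_vol (vol - mean vol) + b_unif (unif - mean unif))``
    (covariates centred at the realized cohort means so baseline_hazard is
    the typical-patient rate).  Follow-up (administrative censoring) is
    uniform over ``followup_window_months``, so every non-progressor has
    >= 24 months of follow-up.  Stage, sex and age are drawn independently
    of the hazard.
    """
    required = {"volume_cm3", "cet1wi_uniformity"}
    missing = required - set(feature_rows.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    n = len(feature_rows)
    rng = np.random.default_rng([spec.seed, 202])
    vol = feature_rows["volume_cm3"].to_numpy(dtype=float)
    unif = feature_rows["cet1wi_uniformity"].to_numpy(dtype=float)
    lp = spec.log_hr_volume * (vol - vol.mean()) + spec.log_hr_uniformity * (
        unif - unif.mean()
    )
    hazard = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(*spec.followup_window_months, size=n)
    event = (t_event <= t_censor).astype(int)
    pfs = np.minimum(t_event, t_censor)

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 15, 73)
    sex = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    overall = rng.choice([1, 2, 3, 4], size=n, p=spec.stage_probs)
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=spec.t_stage_probs)
    n_stage = rng.choice([0, 1, 2, 3], size=n, p=spec.n_stage_probs)
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": sex,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "overall_stage": overall,
            "pfs_months": np.round(pfs, 2),
            "event": event,
        },
        index=feature_rows.index,
    )


def generate_cohort(
    spec: CohortSpec,
    texture_config: TextureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(feature table, clinical table) for one synthetic cohort."""
    feats = generate_feature_table(spec, texture_config)
    clinical = simulate_cohort(spec, feats)
    return feats, clinical


# ----------------------------------------------------------- cohort entry


def cohort_filter(patient_table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility exclusions and tally them.

    Rows carrying any true exclusion flag (other malignancy, distant
    metastasis at diagnosis, no mass formation, incomplete follow-up) are
    removed.  Returns (included rows, per-reason counts + 'eligible' /
    'included' totals).  A row with several flags counts once per flag but
    is removed once.
    """
    tally = {"eligible": int(len(patient_table))}
    present = [f for f in EXCLUSION_FLAGS if f in patient_table.columns]
    excluded = pd.Series(False, index=patient_table.index)
    for flag in EXCLUSION_FLAGS:
        if flag in present:
            col = patient_table[flag].astype(bool)
            tally[flag] = int(col.sum())
            excluded |= col
        else:
            tally[flag] = 0
    included = patient_table.loc[~excluded].drop(columns=present)
    tally["included"] = int(len(included))
    return included, tally


def make_screening_table(
    n_eligible: int = 116,
    exclusions: Mapping[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic eligibility table with disjoint exclusion flags.

    Defaults reproduce the emulated study's screening flow: 116 eligible
    patients, of whom 3 had another malignancy, 1 distant metastasis at
    diagnosis, 17 no mass formation and 16 incomplete follow-up, leaving
    79 included.
    """
    counts = dict(
        exclusions
        or {
            "other_malignancy": 3,
            "distant_metastasis_at_dx": 1,
            "no_mass_formation": 17,
            "incomplete_followup": 16,
        }
    )
    if sum(counts.values()) > n_eligible:
        raise ValueError("more exclusions than eligible patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_eligible)
    table = pd.DataFrame(
        {flag: np.zeros(n_eligible, dtype=bool) for flag in EXCLUSION_FLAGS},
        index=pd.Index([f"S{i:04d}" for i in range(n_eligible)], name="patient_id"),
    )
    pos = 0
    for flag in EXCLUSION_FLAGS:
        k = counts.get(flag, 0)
        table.iloc[order[pos : pos + k], table.columns.get_loc(flag)] = True
        pos += k
    return table
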