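"""Synthetic FDG-PET phantom cohorts with organ-level irAE inflammation.

The study's clinical images are not public, so every downstream stage is
exercised on phantoms that reproduce the *statistical* structure the
analysis assumes:

* a fixed anatomy — thyroid (two small ellipsoidal lobes plus an isthmus
  bridge), lungs (two large ellipsoids), bowel (a folded tube) — voxelised
  on an axis-aligned grid;
* log-normal baseline organ uptake with a persistent per-patient random
  effect, Gaussian background, Gaussian point-spread smoothing and
  additive measurement noise;
* inflammation events that are either *diffuse* (whole-organ multiplicative
  shift, thyroiditis-like) or *focal* (a connected sub-region covering a
  small fraction of the organ, colitis/pneumonitis-like), ramping in over
  ~30 days and preceding the clinical detection date by a configurable lag;
* a scan schedule with one pre-treatment baseline and follow-ups roughly
  every three months.

Baseline parameters are calibrated so that across irAE-free patients the
mean and SD of the organ's optimal SUV percentile match published normal
ranges; :func:`default_uptake_model` ships the calibrated values for the
default phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CalibrationError, PhantomSpecError
from .imaging import ORGAN_LABELS, ORGANS, ImageGrid, OrganMask, ScanMeta, SUVVolume, save_mask, save_volume
from .quant import DEFAULT_PERCENTILE_GRID, organ_percentiles

# ---------------------------------------------------------------------------
# Phantom geometry


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric anatomy on a stated grid (defaults: 64x64x96 voxels at 4 mm,
    i.e. a 256x256x384 mm field of view; geometry is in world mm, so changing
    the resolution leaves the organs' physical size unchanged)."""

    dims: tuple[int, int, int] = (64, 64, 96)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # lungs: two ellipsoids, (centre, semi-axes) in mm
    lung_centers: tuple = ((88.0, 128.0, 255.0), (168.0, 128.0, 255.0))
    lung_semiaxes: tuple[float, float, float] = (34.0, 40.0, 55.0)

    # thyroid: two small ellipsoidal lobes plus a cylindrical isthmus
    thyroid_centers: tuple = ((112.0, 120.0, 332.0), (144.0, 120.0, 332.0))
    thyroid_semiaxes: tuple[float, float, float] = (9.0, 9.0, 18.0)
    isthmus_radius: float = 5.0

    # bowel: tube of given radius following a serpentine polyline
    bowel_radius: float = 14.0
    bowel_path: tuple = (
        (80.0, 80.0, 95.0), (176.0, 80.0, 105.0),
        (176.0, 112.0, 115.0), (80.0, 112.0, 125.0),
        (80.0, 144.0, 135.0), (176.0, 144.0, 145.0),
        (176.0, 176.0, 150.0), (80.0, 176.0, 155.0),
    )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(dims=self.dims, spacing=self.spacing, origin=self.origin)


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    a, b, c = semiaxes
    return ((x - center[0]) / a) ** 2 + ((y - center[1]) / b) ** 2 + ((z - center[2]) / c) ** 2 <= 1.0


def _tube(coords, path, radius) -> np.ndarray:
    """Voxels within ``radius`` mm of a polyline (capsule union)."""
    x, y, z = np.broadcast_arrays(*coords)
    p = np.stack([x, y, z], axis=-1)
    inside = np.zeros(x.shape, dtype=bool)
    for a, b in zip(path[:-1], path[1:]):
        a = np.asarray(a, dtype=float)
        d = np.asarray(b, dtype=float) - a
        L2 = float(d @ d)
        t = np.clip(((p - a) @ d) / L2, 0.0, 1.0) if L2 > 0 else 0.0
        nearest = a + t[..., None] * d
        inside |= np.sum((p - nearest) ** 2, axis=-1) <= radius**2
    return inside


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> OrganMask:
    """Deterministic labelled organ mask for a phantom specification.

    Raises :class:`PhantomSpecError` for degenerate geometry (nonpositive
    radii), organs extending beyond the grid, or overlapping organs.
    """
    if min(spec.thyroid_semiaxes) <= 0 or min(spec.lung_semiaxes) <= 0 or spec.bowel_radius <= 0:
        raise PhantomSpecError("organ radii/semi-axes must be positive")
    grid = spec.grid
    axes = [grid.axis_coords(a) for a in range(3)]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)

    lung = np.zeros(grid.dims, dtype=bool)
    for c in spec.lung_centers:
        lung |= _ellipsoid(coords, c, spec.lung_semiaxes)
    thyroid = np.zeros(grid.dims, dtype=bool)
    for c in spec.thyroid_centers:
        thyroid |= _ellipsoid(coords, c, spec.thyroid_semiaxes)
    (x0, y0, z0), (x1, _, _) = spec.thyroid_centers
    xs, ys, zs = coords
    thyroid |= (
        (xs >= min(x0, x1)) & (xs <= max(x0, x1))
        & ((ys - y0) ** 2 + (zs - z0) ** 2 <= spec.isthmus_radius**2)
    )
    bowel = _tube(coords, spec.bowel_path, spec.bowel_radius)

    organs = {"bowel": bowel, "lung": lung, "thyroid": thyroid}
    # world-extent check: organ must not touch the outermost voxel layer
    for name, m in organs.items():
        if not m.any():
            raise PhantomSpecError(f"{name} produced no voxels on this grid")
        idx = np.argwhere(m)
        if (idx.min(axis=0) == 0).any() or (idx.max(axis=0) >= np.array(grid.dims) - 1).any():
            raise PhantomSpecError(f"{name} exceeds the grid extent")
    if (bowel & lung).any() or (bowel & thyroid).any() or (lung & thyroid).any():
        raise PhantomSpecError("organ geometries overlap")

    labels = np.zeros(grid.dims, dtype=np.int16)
    for name, m in organs.items():
        labels[m] = ORGAN_LABELS[name]
    return OrganMask(grid=grid, labels=labels)


# ---------------------------------------------------------------------------
# Uptake model


@dataclass(frozen=True)
class OrganUptakeParams:
    """Log-normal baseline uptake for one organ.

    ``location``/``scale`` are the log-space mean and within-organ SD of
    voxel values (g/mL); ``patient_sd`` is a log-space between-patient
    random effect that persists across a patient's scans and carries the
    cohort-level variability of the percentile biomarker.
    """

    location: float
    scale: float
    patient_sd: float

    def __post_init__(self):
        if self.scale < 0 or self.patient_sd < 0:
            raise ValueError("scale and patient_sd must be >= 0")


@dataclass(frozen=True)
class UptakeModel:
    organs: dict = field(default_factory=dict)  # organ name -> OrganUptakeParams
    background_mean: float = 0.7   # soft-tissue SUV, g/mL
    background_sd: float = 0.15
    psf_fwhm_mm: float = 6.0       # scanner point-spread FWHM
    noise_sd: float = 0.05         # additive post-smoothing noise, g/mL

    def __post_init__(self):
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("FWHM, noise sd and background sd must be >= 0")


#: Published cohort composition the simulator's defaults reproduce:
#: 58 melanoma patients; per-organ irAE counts; 18 patients with at least
#: one target-organ irAE; 15 irAE-free patients forming the normative
#: subcohort; 25 with irAE only in non-target organs.
STUDY_COHORT_COUNTS = {
    "n_patients": 58,
    "bowel": 6,
    "lung": 5,
    "thyroid": 9,
    "any_target_organ": 18,
    "irae_free": 15,
    "other_organ_only": 25,
}


def cohort_percentages(counts: dict | None = None) -> dict:
    """Percentage of the cohort in each count category (0-100 scale)."""
    counts = dict(counts or STUDY_COHORT_COUNTS)
    n = counts.pop("n_patients")
    return {key: 100.0 * value / n for key, value in counts.items()}


#: Published normal ranges (95% CI of baseline SUV_OPT%, g/mL) and the
#: organ's optimal percentile; these are the calibration targets.
PUBLISHED_NORMAL_RANGES = {
    "bowel": {"percentile": 95, "lo": 1.74, "hi": 2.86},
    "lung": {"percentile": 95, "lo": 0.73, "hi": 1.46},
    "thyroid": {"percentile": 75, "lo": 0.86, "hi": 1.99},
}


def invert_ci(lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a mu +/- 1.96 sigma band from its endpoints."""
    return (lo + hi) / 2.0, (hi - lo) / 3.92


def calibration_targets() -> dict:
    """Per-organ (percentile, mu, sigma) targets from the published bands."""
    out = {}
    for organ, band in PUBLISHED_NORMAL_RANGES.items():
        mu, sigma = invert_ci(band["lo"], band["hi"])
        out[organ] = {"percentile": band["percentile"], "mu": mu, "sigma": sigma}
    return out


def default_uptake_model() -> UptakeModel:
    """Uptake model calibrated (via :func:`calibrate_baseline`) on the default
    phantom so irAE-free baseline SUV_OPT% statistics match the published
    normal ranges."""
    return UptakeModel(
        organs={
            "bowel": OrganUptakeParams(location=0.6571, scale=0.30, patient_sd=0.1260),
            "lung": OrganUptakeParams(location=-0.0960, scale=0.25, patient_sd=0.1820),
            "thyroid": OrganUptakeParams(location=0.3843, scale=0.20, patient_sd=0.2246),
        }
    )


def sample_uptake(
    mask: OrganMask,
    model: UptakeModel,
    seed,
    *,
    patient_effects: dict | None = None,
    meta: ScanMeta | None = None,
) -> SUVVolume:
    """One noisy SUV volume: log-normal organs over Gaussian background,
    PSF-smoothed, plus additive noise; reproducible under a fixed seed.

    ``patient_effects`` maps organ -> log-space offset added to the organ's
    location (the persistent patient random effect); ``seed`` may be an int
    or a numpy Generator.
    """
    rng = np.random.default_rng(seed)
    vox = rng.normal(model.background_mean, model.background_sd, size=mask.grid.dims)
    np.clip(vox, 0.0, None, out=vox)
    effects = patient_effects or {}
    for organ, params in model.organs.items():
        sel = mask.organ_voxels(organ)
        n = int(sel.sum())
        if n == 0:
            continue
        loc = params.location + float(effects.get(organ, 0.0))
        vox[sel] = rng.lognormal(mean=loc, sigma=params.scale, size=n)
    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm / 2.3548 / np.asarray(mask.grid.spacing)
        vox = ndimage.gaussian_filter(vox, sigma=sigma_vox)
    if model.noise_sd > 0:
        vox = vox + rng.normal(0.0, model.noise_sd, size=vox.shape)
        np.clip(vox, 0.0, None, out=vox)
    if meta is None:
        meta = ScanMeta(patient_id="phantom", scan_day=0, suv_precomputed=True)
    return SUVVolume(grid=mask.grid, voxels=vox, meta=meta)


# ---------------------------------------------------------------------------
# Inflammation events


@dataclass(frozen=True)
class IraeEvent:
    """One organ inflammation event.

    The uptake multiplier ramps from 1 at ``onset_day`` to ``k`` at
    ``onset_day + ramp_days`` along a smoothstep sigmoid, and (when a
    ``resolution_day`` is set) decays back over ``recovery_days``.
    ``clinical_lag`` places clinical detection after imaging-visible onset.
    """

    organ: str
    pattern: str  # "diffuse" | "focal"
    onset_day: int
    k: float
    focal_fraction: float = 1.0
    clinical_lag: int = 30
    resolution_day: int | None = None
    ramp_days: int = 30
    recovery_days: int = 60
    region_seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("diffuse", "focal"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not self.k > 1:
            raise ValueError("peak multiplier k must exceed 1")
        if not (0 < self.focal_fraction <= 1):
            raise PhantomSpecError("focal_fraction must lie in (0, 1]")
        if self.clinical_lag < 0:
            raise ValueError("clinical_lag must be >= 0")

    @property
    def clinical_day(self) -> int:
        return self.onset_day + self.clinical_lag

    def multiplier(self, scan_day: int) -> float:
        """Time-varying uptake multiplier m(t); 1 before onset, k at plateau."""
        if scan_day < self.onset_day:
            return 1.0
        rise = _smoothstep((scan_day - self.onset_day) / max(self.ramp_days, 1))
        fall = 0.0
        if self.resolution_day is not None and scan_day >= self.resolution_day:
            fall = _smoothstep((scan_day - self.resolution_day) / max(self.recovery_days, 1))
        return 1.0 + (self.k - 1.0) * rise * (1.0 - fall)


def _smoothstep(u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def focal_region(mask: OrganMask, organ: str, fraction: float, seed: int = 0) -> np.ndarray:
    """A connected sub-region covering ``fraction`` of the organ's voxels.

    Deterministic for a given seed: a random organ voxel seeds a
    face-connected dilation-growth restricted to the organ until the
    target count is reached.
    """
    sel = mask.organ_voxels(organ)
    n = int(sel.sum())
    target = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    start = tuple(np.argwhere(sel)[rng.integers(n)])
    region = np.zeros_like(sel)
    region[start] = True
    while int(region.sum()) < target:
        grown = ndimage.binary_dilation(region, structure=_FACE_STRUCT, mask=sel)
        added = np.argwhere(grown & ~region)
        if added.size == 0:  # disconnected remainder: organ smaller than target
            break
        need = target - int(region.sum())
        if len(added) > need:
            added = added[rng.permutation(len(added))[:need]]
        region[tuple(added.T)] = True
    return region


def apply_irae(suv: SUVVolume, mask: OrganMask, event: IraeEvent, scan_day: int) -> SUVVolume:
    """Multiply the event organ (diffuse) or a connected sub-region of
    ``focal_fraction`` of its volume (focal) by the event's multiplier at
    ``scan_day``. Scans before onset are returned unchanged."""
    m = event.multiplier(scan_day)
    if m == 1.0:
        return suv
    vox = suv.voxels.copy()
    if event.pattern == "diffuse":
        sel = mask.organ_voxels(event.organ)
    else:
        sel = focal_region(mask, event.organ, event.focal_fraction, seed=event.region_seed)
    vox[sel] *= m
    return SUVVolume(grid=suv.grid, voxels=vox, meta=suv.meta)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition defaults: 58 patients; per-organ irAE prevalences
    matching the published cohort counts (bowel 6/58, lung 5/58, thyroid
    9/58); baseline ~36 days pre-treatment; follow-ups ~every 90 days with
    jitter; 2 + Poisson(2) scans per patient (median 4)."""

    n_patients: int = 58
    prevalence: dict = field(default_factory=lambda: {"bowel": 6 / 58, "lung": 5 / 58, "thyroid": 9 / 58})
    baseline_day: int = -36
    baseline_jitter: int = 15
    followup_interval: int = 90
    interval_jitter: int = 20
    extra_scans_mean: float = 2.0  # scans per patient = 2 + Poisson(mean)
    onset_range: tuple[int, int] = (20, 200)
    k_range: tuple[float, float] = (1.8, 3.0)
    clinical_lag_range: tuple[int, int] = (14, 60)
    focal_fraction: float = 0.1
    patterns: dict = field(default_factory=lambda: {"bowel": "focal", "lung": "focal", "thyroid": "diffuse"})
    seed: int = 0

    def __post_init__(self):
        for organ, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {organ} outside [0, 1]")


@dataclass
class PatientScan:
    meta: ScanMeta
    suv: SUVVolume


@dataclass
class PatientRecord:
    patient_id: str
    events: list
    scan_days: list
    scans: list  # PatientScan; empty when volumes were not kept


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    phantom: PhantomSpec
    mask: OrganMask
    patients: list

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for e in p.events:
                rows.append({
                    "patient_id": p.patient_id, "organ": e.organ, "pattern": e.pattern,
                    "onset_day": e.onset_day, "clinical_day": e.clinical_day,
                    "k": e.k, "f": e.focal_fraction,
                })
        return pd.DataFrame(rows, columns=["patient_id", "organ", "pattern", "onset_day",
                                           "clinical_day", "k", "f"])

    def labels_table(self) -> pd.DataFrame:
        """One row per patient x organ: irAE label and clinical day."""
        truth = self.truth_table().set_index(["patient_id", "organ"]) if self.patients else None
        rows = []
        for p in self.patients:
            by_organ = {e.organ: e for e in p.events}
            for organ in ORGANS:
                e = by_organ.get(organ)
                rows.append({
                    "patient_id": p.patient_id, "organ": organ,
                    "label": int(e is not None),
                    "clinical_day": np.nan if e is None else e.clinical_day,
                })
        return pd.DataFrame(rows)


def _patient_events(rng, spec: CohortSpec, patient_index: int) -> list:
    events = []
    for organ in ORGANS:
        if rng.random() < spec.prevalence.get(organ, 0.0):
            pattern = spec.patterns.get(organ, "diffuse")
            events.append(IraeEvent(
                organ=organ,
                pattern=pattern,
                onset_day=int(rng.integers(spec.onset_range[0], spec.onset_range[1] + 1)),
                k=float(rng.uniform(*spec.k_range)),
                focal_fraction=spec.focal_fraction if pattern == "focal" else 1.0,
                clinical_lag=int(rng.integers(spec.clinical_lag_range[0], spec.clinical_lag_range[1] + 1)),
                region_seed=int(rng.integers(2**31)),
            ))
    return events


def _patient_schedule(rng, spec: CohortSpec) -> list:
    n_scans = 2 + int(rng.poisson(spec.extra_scans_mean))
    days = [spec.baseline_day + int(rng.integers(-spec.baseline_jitter, spec.baseline_jitter + 1))]
    day = 0
    for _ in range(n_scans - 1):
        day += spec.followup_interval + int(rng.integers(-spec.interval_jitter, spec.interval_jitter + 1))
        days.append(day)
    return days


def iter_cohort_scans(
    spec: CohortSpec,
    phantom: PhantomSpec = PhantomSpec(),
    model: UptakeModel | None = None,
    mask: OrganMask | None = None,
):
    """Yield (patient_id, events, scan_day, suv_volume) for every scan.

    Per-patient RNG streams are spawned deterministically from the master
    seed, so each patient's data is reproducible independently of cohort
    iteration order.
    """
    if model is None:
        model = default_uptake_model()
    if mask is None:
        mask = build_phantom(phantom)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i:03d}"
        events = _patient_events(rng, spec, i)
        days = _patient_schedule(rng, spec)
        effects = {
            organ: float(rng.normal(0.0, params.patient_sd))
            for organ, params in model.organs.items()
        }
        for day in days:
            meta = ScanMeta(patient_id=pid, scan_day=day, suv_precomputed=True)
            suv = sample_uptake(mask, model, rng, patient_effects=effects, meta=meta)
            for event in events:
                suv = apply_irae(suv, mask, event, day)
            yield pid, events, day, suv


def simulate_truth_only(spec: CohortSpec, model: UptakeModel | None = None) -> SyntheticCohort:
    """Cohort truth structure (events, schedules, labels) without generating
    any image volume; consumes the per-patient RNG streams in the same order
    as :func:`iter_cohort_scans`, so the truth table matches a full run."""
    if model is None:
        model = default_uptake_model()
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    patients = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i:03d}"
        events = _patient_events(rng, spec, i)
        days = _patient_schedule(rng, spec)
        patients.append(PatientRecord(pid, events, days, []))
    return SyntheticCohort(spec=spec, phantom=PhantomSpec(), mask=None, patients=patients)


def simulate_cohort(
    spec: CohortSpec,
    phantom: PhantomSpec = PhantomSpec(),
    model: UptakeModel | None = None,
    *,
    keep_volumes: bool = True,
) -> SyntheticCohort:
    """Materialise a cohort; with ``keep_volumes=False`` only the truth
    structure and schedule are retained (use :func:`simulate_profile_table`
    for a streaming percentile extraction)."""
    mask = build_phantom(phantom)
    patients: dict[str, PatientRecord] = {}
    for pid, events, day, suv in iter_cohort_scans(spec, phantom, model, mask=mask):
        rec = patients.setdefault(pid, PatientRecord(pid, events, [], []))
        rec.scan_days.append(day)
        if keep_volumes:
            rec.scans.append(PatientScan(meta=suv.meta, suv=suv))
    return SyntheticCohort(spec=spec, phantom=phantom, mask=mask, patients=list(patients.values()))


def simulate_profile_table(
    spec: CohortSpec,
    phantom: PhantomSpec = PhantomSpec(),
    model: UptakeModel | None = None,
    grid=DEFAULT_PERCENTILE_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return (profiles, labels, truth) tables without
    retaining any volume in memory.

    ``profiles`` is the long-format table consumed by the biomarker model:
    (patient_id, organ, scan_day, percentile, suv_gml, n_voxels).
    """
    mask = build_phantom(phantom)
    organ_sel = {organ: mask.organ_voxels(organ) for organ in ORGANS if mask.organ_voxels(organ).any()}
    rows = []
    events_by_pid: dict[str, list] = {}
    for pid, events, day, suv in iter_cohort_scans(spec, phantom, model, mask=mask):
        events_by_pid[pid] = events
        for organ, sel in organ_sel.items():
            prof = organ_percentiles(suv.voxels[sel], grid, patient_id=pid, organ=organ, scan_day=day)
            for x, v in zip(prof.percentiles, prof.suv):
                rows.append((pid, organ, day, float(x), float(v), prof.n_voxels))
    profiles = pd.DataFrame(rows, columns=["patient_id", "organ", "scan_day", "percentile",
                                           "suv_gml", "n_voxels"])
    cohort = SyntheticCohort(spec=spec, phantom=phantom, mask=mask, patients=[
        PatientRecord(pid, evs, sorted(profiles[profiles.patient_id == pid].scan_day.unique()), [])
        for pid, evs in events_by_pid.items()
    ])
    return profiles, cohort.labels_table(), cohort.truth_table()


# ---------------------------------------------------------------------------
# Calibration


def calibrate_baseline(
    model: UptakeModel,
    targets: dict | None = None,
    phantom: PhantomSpec = PhantomSpec(),
    *,
    n_patients: int = 300,
    max_iter: int = 15,
    rel_tol: float = 0.05,
    damping: float = 0.6,
    seed: int = 12345,
) -> UptakeModel:
    """Adjust per-organ location and patient_sd so that simulated irAE-free
    baseline SUV_OPT% statistics match the targets.

    ``targets`` maps organ -> {"percentile", "mu", "sigma"} (default: the
    published normal ranges inverted via mu=(lo+hi)/2, sigma=(hi-lo)/3.92).
    Each iteration simulates ``n_patients`` baseline scans, then applies a
    damped multiplicative log-space correction to the location and a damped
    ratio correction to patient_sd (damping keeps the fixed-point iteration
    from oscillating on Monte-Carlo noise; the SD of an SD estimate at
    n=300 is ~4%, which is why ``rel_tol`` below ~0.05 cannot converge
    reliably). Raises :class:`CalibrationError` with per-organ diagnostics
    if any organ is outside ``rel_tol`` after ``max_iter`` iterations.
    """
    if targets is None:
        targets = calibration_targets()
    mask = build_phantom(phantom)
    current = model
    history = []
    for it in range(max_iter):
        stats = _baseline_statistics(mask, current, targets, n_patients, seed + it)
        history.append(stats)
        ok = all(
            abs(s["mu"] - targets[o]["mu"]) <= rel_tol * targets[o]["mu"]
            and abs(s["sigma"] - targets[o]["sigma"]) <= rel_tol * targets[o]["sigma"]
            for o, s in stats.items()
        )
        if ok:
            return current
        organs = dict(current.organs)
        for organ, s in stats.items():
            p = organs[organ]
            organs[organ] = replace(
                p,
                location=p.location + damping * float(np.log(targets[organ]["mu"] / s["mu"])),
                patient_sd=float(np.clip(
                    p.patient_sd * (targets[organ]["sigma"] / max(s["sigma"], 1e-9)) ** damping,
                    1e-4, 2.0)),
            )
        current = replace(current, organs=organs)
    raise CalibrationError(
        f"calibration did not converge within {max_iter} iterations",
        diagnostics={"targets": targets, "history": history},
    )


def _baseline_statistics(mask, model, targets, n_patients, seed) -> dict:
    """Mean/SD of SUV_OPT% across simulated irAE-free baseline patients."""
    rng = np.random.default_rng(seed)
    values = {organ: [] for organ in targets}
    for _ in range(n_patients):
        effects = {o: float(rng.normal(0.0, p.patient_sd)) for o, p in model.organs.items()}
        suv = sample_uptake(mask, model, rng, patient_effects=effects)
        for organ, t in targets.items():
            vals = suv.voxels[mask.organ_voxels(organ)]
            values[organ].append(float(np.percentile(vals, t["percentile"])))
    return {
        organ: {"mu": float(np.mean(v)), "sigma": float(np.std(v, ddof=1))}
        for organ, v in values.items()
    }


def simulate_baseline_opt_values(
    model: UptakeModel,
    n_patients: int,
    phantom: PhantomSpec = PhantomSpec(),
    *,
    seed: int = 0,
    targets: dict | None = None,
) -> pd.DataFrame:
    """Baseline SUV_OPT% draws for irAE-free patients (one scan each);
    long-format (patient index, organ, value). Used for coverage checks
    and for building normative bands from the simulator."""
    if targets is None:
        targets = calibration_targets()
    mask = build_phantom(phantom)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        effects = {o: float(rng.normal(0.0, p.patient_sd)) for o, p in model.organs.items()}
        suv = sample_uptake(mask, model, rng, patient_effects=effects)
        for organ, t in targets.items():
            vals = suv.voxels[mask.organ_voxels(organ)]
            rows.append((i, organ, float(np.percentile(vals, t["percentile"]))))
    return pd.DataFrame(rows, columns=["patient", "organ", "value"])


# ---------------------------------------------------------------------------
# On-disk cohort export


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes + mask, scan-metadata CSV, truth and label CSVs,
    and a JSON spec echo; returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(cohort.mask, out / "organ_mask.nii.gz")
    meta_rows = []
    for p in cohort.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        for scan in p.scans:
            name = f"scan_d{scan.meta.scan_day:+04d}.nii.gz"
            save_volume(scan.suv, pdir / name)
            meta_rows.append({
                "patient_id": p.patient_id, "scan_day": scan.meta.scan_day,
                "weight_g": scan.meta.weight_g, "dose_Bq": scan.meta.dose_bq,
                "suv_precomputed": int(scan.meta.suv_precomputed), "file": f"{p.patient_id}/{name}",
            })
    pd.DataFrame(meta_rows).to_csv(out / "scans.csv", index=False)
    cohort.truth_table().to_csv(out / "truth.csv", index=False)
    cohort.labels_table().to_csv(out / "labels.csv", index=False)
    spec_echo = {
        "cohort": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in vars(cohort.spec).items()},
        "phantom": {"dims": cohort.phantom.dims, "spacing": cohort.phantom.spacing},
    }
    (out / "spec.json").write_text(json.dumps(spec_echo, indent=2, default=str))
    return out
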