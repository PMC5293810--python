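"""Synthetic multi-site resting-state BOLD cohorts with planted connectivity.

The generator emulates the structure of a pooled multi-site resting-state
study of the dopaminergic midbrain: per-site scan lengths and repetition
times, two small disjoint midbrain seed masks (VTA- and SNc-like), target
voxels whose connectivity to a seed carries additive age and sex effects,
low-frequency (< 0.08 Hz) neural signal, global/white-matter/ventricular
nuisance components, a non-steady-state transient over the first frames,
and sporadic motion spikes that exceed the scrubbing thresholds.

Effects are planted on the **correlation scale**: subject i's target
voxels correlate with the seed's latent time course at

    rho_i = base_rho + beta_age * (age_i - age_ref) + beta_sex * [male_i]

Group inference operates on Fisher-z maps; for the small effects used
here the z-scale slope is beta_age / (1 - rho^2) by the delta method.

Randomness: one master seed; each subject's stream is derived by stable
(SHA-256) hashing of the subject id, so any subject can be regenerated
independently of cohort order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from midfc.denoise import bandpass_timeseries, DEFAULT_BAND_HZ
from midfc.volume import Bold4D, GridGeometry, default_grid

#: per-site scan length and repetition time for the emulated multi-site cohort
SITE_TABLE: dict[str, dict[str, float]] = {
    "Beijing_Zang": {"n_timepoints": 225, "tr": 2.0},
    "Leiden_2180": {"n_timepoints": 215, "tr": 2.18},
    "Leiden_2200": {"n_timepoints": 215, "tr": 2.2},
    "Newark": {"n_timepoints": 135, "tr": 2.0},
    "Yale": {"n_timepoints": 295, "tr": 2.0},
}

DEFAULT_AGE_RANGE = (18.0, 49.0)

# intensity model constants (arbitrary scanner units; baseline 1000 so that
# 1 unit = 0.1% BOLD once rescaled to a grand mean of 100)
BASELINE = 1000.0
SIGNAL_AMP = 2.0            # sd of band-limited neural fluctuations
WHITE_NOISE_SD = 0.5        # thermal noise sd
SEED_NOISE_FRAC = 0.15      # voxel-level jitter inside the seeds
TRANSIENT_AMP = 15.0        # non-steady-state offset at frame 0
TRANSIENT_TAU = 1.5         # frames
SPIKE_INTENSITY_PER_MM = 5.0  # global intensity step per mm of motion step
NOISE_SMOOTH_FWHM_MM = 8.0  # spatial correlation length of the noise field


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member's identity, demographics and scan parameters."""

    subject_id: str
    age: float
    sex: str                    # "male" | "female"
    site: str
    tr: float
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not DEFAULT_AGE_RANGE[0] <= self.age <= DEFAULT_AGE_RANGE[1]:
            raise ValueError(
                f"age {self.age} outside the studied range {DEFAULT_AGE_RANGE}"
            )
        if not self.tr > 0:
            raise ValueError("TR must be positive")
        if not self.n_timepoints > 5:
            raise ValueError("n_timepoints must exceed the 5-frame discard window")

    @property
    def is_male(self) -> bool:
        return self.sex == "male"


@dataclass
class ConnectivityDesign:
    """Planted connectivity structure for a synthetic cohort.

    Attributes
    ----------
    base_rho : float
        Seed-target correlation for a reference-age female.
    beta_age : float
        Correlation change per year of age (applied to both sexes unless a
        sex-specific slope is given).
    beta_sex : float
        Additive correlation offset for males.
    beta_age_male, beta_age_female : float or None
        Sex-specific age slopes overriding ``beta_age`` when set (used to
        plant male-only ageing effects).
    age_ref : float
        Age at which the planted correlation equals ``base_rho`` (+ sex
        offset); defaults to the midpoint of the studied range.
    seed : str
        Which seed ("VTA" or "SNc") the target region couples to.
    seed_coupling : float
        Correlation between the two seeds' latent time courses.
    target_region, null_regions : boolean masks
        Voxels carrying the planted effect / guaranteed-null voxels.
    nuisance_amplitudes : dict
        Scales (in units of the neural signal sd) of the global,
        white-matter and ventricular components.
    spike_frames : dict subject_id -> tuple of frame indices
        Frames at which that subject's motion trace jumps beyond the
        scrubbing threshold.
    clip : bool
        Clip infeasible per-subject correlations into (-1, 1) with a
        warning instead of raising.
    """

    base_rho: float = 0.3
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_age_male: float | None = None
    beta_age_female: float | None = None
    age_ref: float = 33.5
    seed: str = "VTA"
    seed_coupling: float = 0.5
    target_region: np.ndarray | None = None
    null_regions: dict[str, np.ndarray] = field(default_factory=dict)
    nuisance_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "global": 1.0, "white_matter": 1.0, "ventricle": 1.0,
    })
    spike_frames: dict[str, tuple[int, ...]] = field(default_factory=dict)
    clip: bool = False

    _RHO_LIMIT = 1.0 - 1e-6

    def age_slope(self, record: SubjectRecord) -> float:
        if record.is_male and self.beta_age_male is not None:
            return self.beta_age_male
        if not record.is_male and self.beta_age_female is not None:
            return self.beta_age_female
        return self.beta_age

    def rho_for(self, record: SubjectRecord) -> float:
        """Planted seed-target correlation for one subject.

        Raises (or clips, if ``clip``) when the design puts the
        correlation outside (-1, 1).
        """
        rho = (self.base_rho
               + self.age_slope(record) * (record.age - self.age_ref)
               + (self.beta_sex if record.is_male else 0.0))
        if abs(rho) >= 1.0:
            if self.clip:
                clipped = float(np.clip(rho, -self._RHO_LIMIT, self._RHO_LIMIT))
                warnings.warn(
                    f"planted correlation {rho:.3f} for {record.subject_id} "
                    f"clipped to {clipped:.6f}", stacklevel=2)
                return clipped
            raise ValueError(
                f"infeasible planted correlation {rho:.3f} for subject "
                f"{record.subject_id} (age {record.age:.1f}, {record.sex}); "
                "reduce the effect sizes or enable clipping"
            )
        return float(rho)


@dataclass
class SeedMaskPair:
    """The two midbrain seed masks on a common grid."""

    vta: np.ndarray
    snc: np.ndarray
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.vta = np.asarray(self.vta, dtype=bool)
        self.snc = np.asarray(self.snc, dtype=bool)
        if self.vta.shape != self.grid.shape or self.snc.shape != self.grid.shape:
            raise ValueError("seed masks must match the grid shape")
        if not self.vta.any() or not self.snc.any():
            raise ValueError("seed masks must be non-empty")
        if (self.vta & self.snc).any():
            raise ValueError("seed masks must be disjoint")

    def mask(self, seed: str) -> np.ndarray:
        key = seed.upper()
        if key == "VTA":
            return self.vta
        if key == "SNC":
            return self.snc
        raise KeyError(f"unknown seed {seed!r}; expected 'VTA' or 'SNc'")


@dataclass
class TissueMasks:
    """Generator-emitted tissue labels standing in for segmentation."""

    whole_brain: np.ndarray
    white_matter: np.ndarray
    ventricle: np.ndarray

    def __post_init__(self) -> None:
        for name in ("whole_brain", "white_matter", "ventricle"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if not m.any():
                raise ValueError(f"tissue mask {name!r} is empty")
            setattr(self, name, m)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"whole_brain": self.whole_brain,
                "white_matter": self.white_matter,
                "ventricle": self.ventricle}


def _ball(shape: tuple[int, int, int], centre: np.ndarray, radius: float) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius ** 2


def _ellipsoid(shape: tuple[int, int, int], centre: np.ndarray,
               semi: np.ndarray) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return d2 <= 1.0


MIN_SEED_GRID = 10


def make_seed_masks(grid: GridGeometry, seed: int = 0) -> SeedMaskPair:
    """Two disjoint compact seed blobs in the inferior-medial region.

    A VTA-like blob sits near the midline and an SNc-like blob slightly
    lateral and inferior, both low in the grid, with a small deterministic
    jitter drawn from ``seed``.
    """
    shape = grid.shape
    if min(shape) < MIN_SEED_GRID:
        raise ValueError(
            f"grid {shape} too small to place disjoint seed blobs; "
            f"need at least {MIN_SEED_GRID} voxels per axis"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5eed]))
    nx, ny, nz = shape
    base_vta = np.array([nx / 2.0, ny * 0.42, nz * 0.30])
    base_snc = base_vta + np.array([3.4, -0.8, -0.9])
    radius = 1.6
    for _ in range(50):
        jitter = rng.uniform(-0.5, 0.5, size=3)
        vta = _ball(shape, base_vta + jitter, radius)
        snc = _ball(shape, base_snc + jitter, radius)
        if vta.any() and snc.any() and not (vta & snc).any():
            return SeedMaskPair(vta=vta, snc=snc, grid=grid)
    raise ValueError(f"could not place disjoint seed blobs on grid {shape}")


def make_tissue_masks(grid: GridGeometry) -> TissueMasks:
    """Deterministic brain / white-matter / ventricle labels.

    Brain: an ellipsoid filling most of the box.  Ventricle: a small
    central ellipsoid.  White matter: a mid-radius shell excluding the
    ventricle.
    """
    shape = np.array(grid.shape, dtype=float)
    centre = (shape - 1) / 2.0
    brain = _ellipsoid(grid.shape, centre, shape * 0.45)
    inner = _ellipsoid(grid.shape, centre, shape * 0.30)
    core = _ellipsoid(grid.shape, centre, shape * 0.18)
    ventricle = _ellipsoid(grid.shape, centre, shape * 0.07)
    white = inner & ~core
    return TissueMasks(whole_brain=brain, white_matter=white & ~ventricle,
                       ventricle=ventricle)


def make_effect_regions(grid: GridGeometry, brain_mask: np.ndarray,
                        seeds: SeedMaskPair | None = None,
                        radius: float = 3.0) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """A compact cortical-like target blob plus a contralateral null blob.

    Both lie inside the brain mask and away from the seed masks.
    Deterministic (no randomness): placed at fixed fractional positions.
    """
    nx, ny, nz = grid.shape
    target = _ball(grid.shape, np.array([nx * 0.68, ny * 0.62, nz * 0.62]), radius)
    null = _ball(grid.shape, np.array([nx * 0.30, ny * 0.40, nz * 0.66]), radius)
    target &= brain_mask
    null &= brain_mask
    if seeds is not None:
        keep_out = seeds.vta | seeds.snc
        target &= ~keep_out
        null &= ~keep_out
    if not target.any() or not null.any():
        raise ValueError("effect regions fell outside the brain mask")
    return target, {"null": null}


def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject random stream derived by stable hashing of the id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), sub]))


_FILTER_PAD = 40   # frames trimmed from each end after band-limiting


#: the slow band used for the global nuisance component; the global BOLD
#: signal is dominated by respiration and scanner drift, so its
#: frame-to-frame excursions stay well below the DVARS scrubbing limit
GLOBAL_BAND_HZ = (0.009, 0.03)


def _band_limited(rng: np.random.Generator, shape: tuple[int, ...],
                  tr: float, band: tuple[float, float] = DEFAULT_BAND_HZ
                  ) -> np.ndarray:
    """Unit-variance noise filtered into ``band`` (time on the last axis).

    The white noise is generated with ``_FILTER_PAD`` extra frames on
    both ends and the filtered edges discarded, so the kept segment is
    stationary (zero-phase filtering otherwise leaves edge transients).
    """
    low, high = band
    n = shape[-1]
    x = rng.standard_normal((*shape[:-1], n + 2 * _FILTER_PAD))
    y = bandpass_timeseries(x, low, high, tr)[..., _FILTER_PAD:_FILTER_PAD + n]
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def simulate_subject(record: SubjectRecord,
                     design: ConnectivityDesign,
                     masks: SeedMaskPair,
                     tissues: TissueMasks | None = None,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[Bold4D, np.ndarray]:
    """Simulate one subject's 4D BOLD series and motion-parameter trace.

    The seed voxels share a band-limited latent time course s(t); each
    target-region voxel follows rho*s + sqrt(1-rho^2)*e with independent
    band-limited noise e and rho set by the design and the subject's age
    and sex.  Global, white-matter and ventricular nuisance components,
    thermal noise, a decaying non-steady-state transient over the first
    frames, and motion spikes (step displacement plus a proportional
    global intensity step) complete the model.

    Parameters
    ----------
    record, design, masks
        Subject, planted-effect design, and seed masks (grid geometry is
        taken from ``masks.grid``).
    tissues : TissueMasks, optional
        Brain/white-matter/ventricle labels; built from the grid if absent.
    seed : int, optional
        Master seed; the subject stream is derived by hashing
        ``record.subject_id``.  Alternatively pass an explicit ``rng``.

    Returns
    -------
    (Bold4D, ndarray)
        The BOLD series and the (T, 6) motion trace (mm, mm, mm, rad,
        rad, rad).
    """
    if rng is None:
        rng = subject_rng(0 if seed is None else seed, record.subject_id)
    grid = masks.grid
    if tissues is None:
        tissues = make_tissue_masks(grid)
    rho = design.rho_for(record)
    T = record.n_timepoints
    tr = record.tr
    brain = tissues.whole_brain
    V = int(brain.sum())

    # latent seed time courses, mutually coupled
    s_a = _band_limited(rng, (T,), tr)
    e_b = _band_limited(rng, (T,), tr)
    c = design.seed_coupling
    s_b = c * s_a + np.sqrt(max(0.0, 1.0 - c * c)) * e_b
    latents = {"VTA": s_a, "SNC": s_b}
    s_drive = latents[design.seed.upper()]

    # voxelwise band-limited fluctuations with realistic spatial
    # correlation: temporally band-limited white noise, spatially smoothed,
    # then renormalised to unit temporal variance per voxel.  Without the
    # spatial correlation, analysis smoothing would average independent
    # noise down while the shared latent adds coherently, inflating the
    # recovered correlations well above their planted values.
    field = rng.standard_normal((*grid.shape, T + 2 * _FILTER_PAD))
    field = bandpass_timeseries(field, *DEFAULT_BAND_HZ, tr)
    field = field[..., _FILTER_PAD:_FILTER_PAD + T]
    sigma_vox = (NOISE_SMOOTH_FWHM_MM / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                 / grid.voxel_sizes)
    field = ndimage.gaussian_filter(field, sigma=(*sigma_vox, 0.0),
                                    mode="nearest")
    sd = field.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    field /= sd
    flat = field[brain]

    # index bookkeeping within the brain-voxel axis
    brain_idx = np.zeros(grid.shape, dtype=int)
    brain_idx[brain] = np.arange(V)

    def rows(mask: np.ndarray) -> np.ndarray:
        return brain_idx[mask & brain]

    # seed voxels: shared latent plus small voxel jitter
    for name in ("VTA", "SNC"):
        r = rows(masks.mask(name))
        flat[r] = latents[name] + SEED_NOISE_FRAC * flat[r]
    # target voxels: planted correlation with the driving seed
    if design.target_region is not None:
        r = rows(design.target_region)
        flat[r] = rho * s_drive + np.sqrt(1.0 - rho * rho) * flat[r]
    # null regions keep their independent fluctuations untouched

    data = np.zeros((*grid.shape, T))
    data[brain] = SIGNAL_AMP * flat

    # nuisance components; the global component lives in its own slow band
    amp = design.nuisance_amplitudes
    g = _band_limited(rng, (T,), tr, band=GLOBAL_BAND_HZ)
    wm = _band_limited(rng, (T,), tr)
    csf = _band_limited(rng, (T,), tr)
    data[brain] += SIGNAL_AMP * amp.get("global", 0.0) * g
    data[tissues.white_matter] += SIGNAL_AMP * amp.get("white_matter", 0.0) * wm
    data[tissues.ventricle] += SIGNAL_AMP * amp.get("ventricle", 0.0) * csf

    # thermal noise, baseline, initial transient
    data[brain] += WHITE_NOISE_SD * rng.standard_normal((V, T))
    t_axis = np.arange(T)
    transient = TRANSIENT_AMP * np.exp(-t_axis / TRANSIENT_TAU)
    data[brain] += BASELINE + transient

    # motion: slow random walk plus step spikes
    deltas = np.column_stack([
        rng.normal(0.0, 0.005, size=(T, 3)),      # mm
        rng.normal(0.0, 5e-5, size=(T, 3)),       # rad
    ])
    deltas[0] = 0.0
    motion = np.cumsum(deltas, axis=0)
    spikes = design.spike_frames.get(record.subject_id, ())
    for k in spikes:
        if not 0 < k < T:
            raise ValueError(f"spike frame {k} outside series of length {T}")
        mag = float(rng.uniform(0.7, 1.8))        # mm; always beyond 0.5 mm FD
        axis = int(rng.integers(0, 3))
        motion[k:, axis] += mag
        # proportional global intensity step: large spikes also trip DVARS
        data[brain, k:] += SPIKE_INTENSITY_PER_MM * mag

    return Bold4D(data=data, affine=grid.affine.copy(), tr=tr), motion


@dataclass
class Cohort:
    """A simulated cohort: records + metadata, masks, and lazy subject data.

    Subject BOLD series are generated on demand from per-subject random
    streams, so a cohort of any size is cheap to hold and any subject is
    reproducible in isolation.
    """

    records: list[SubjectRecord]
    metadata: pd.DataFrame
    design: ConnectivityDesign
    seeds: SeedMaskPair
    tissues: TissueMasks
    master_seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> GridGeometry:
        return self.seeds.grid

    def subject_data(self, record: SubjectRecord) -> tuple[Bold4D, np.ndarray]:
        return simulate_subject(record, self.design, self.seeds,
                                tissues=self.tissues, seed=self.master_seed)

    def iter_subjects(self):
        for record in self.records:
            yield record, *self.subject_data(record)


def _allocate_sites(n_per_site, site_table) -> list[tuple[str, int]]:
    if isinstance(n_per_site, int):
        if n_per_site <= 0:
            raise ValueError("cohort size must be positive")
        sites = list(site_table)
        counts = {s: 0 for s in sites}
        for i in range(n_per_site):
            counts[sites[i % len(sites)]] += 1
        return [(s, c) for s, c in counts.items() if c > 0]
    items = [(s, int(c)) for s, c in dict(n_per_site).items() if int(c) > 0]
    if not items:
        raise ValueError("cohort is empty")
    for s, _ in items:
        if s not in site_table:
            raise KeyError(f"unknown site {s!r}; known sites: {list(site_table)}")
    return items


def simulate_cohort(n_per_site,
                    design: ConnectivityDesign,
                    seed: int,
                    site_table: dict[str, dict[str, float]] = SITE_TABLE,
                    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
                    male_fraction: float = 0.5,
                    grid: GridGeometry | None = None,
                    spikes_per_subject: int = 0) -> Cohort:
    """Draw a multi-site cohort with per-site scan parameters.

    Parameters
    ----------
    n_per_site : int or dict site -> count
        Either a total (distributed round-robin over the site table) or
        explicit per-site counts.
    design : ConnectivityDesign
        Planted-effect design.  If its ``target_region`` is unset, a
        default target/null region pair is placed on the grid.
    seed : int
        Master seed; drives demographics and all per-subject streams.
    site_table : dict
        Per-site ``n_timepoints`` and ``tr``; defaults to the emulated
        study's five acquisition sites.
    age_range, male_fraction
        Uniform age range and Bernoulli male probability.
    spikes_per_subject : int
        Number of motion-spike frames planted per subject (placed away
        from the initial-discard window).
    """
    grid = default_grid() if grid is None else grid
    allocation = _allocate_sites(n_per_site, site_table)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xc040]))
    seeds = make_seed_masks(grid, seed=seed)
    tissues = make_tissue_masks(grid)
    design = replace(design)
    if design.target_region is None:
        target, nulls = make_effect_regions(grid, tissues.whole_brain, seeds)
        design.target_region = target
        design.null_regions = nulls

    records: list[SubjectRecord] = []
    spike_map: dict[str, tuple[int, ...]] = dict(design.spike_frames)
    idx = 0
    for site, count in allocation:
        info = site_table[site]
        for _ in range(count):
            sid = f"sub{idx:04d}_{site}"
            age = float(rng.uniform(*age_range))
            sex = "male" if rng.random() < male_fraction else "female"
            rec = SubjectRecord(subject_id=sid, age=age, sex=sex, site=site,
                                tr=float(info["tr"]),
                                n_timepoints=int(info["n_timepoints"]))
            records.append(rec)
            if spikes_per_subject > 0:
                lo, hi = 10, rec.n_timepoints - 2
                frames = rng.choice(np.arange(lo, hi), size=spikes_per_subject,
                                    replace=False)
                spike_map[sid] = tuple(int(f) for f in np.sort(frames))
            idx += 1
    design.spike_frames = spike_map
    # verify feasibility up front (raises or warns per design.clip)
    for rec in records:
        design.rho_for(rec)
    metadata = pd.DataFrame(
        [{"subject_id": r.subject_id, "age": r.age, "sex": r.sex,
          "site": r.site, "tr": r.tr, "n_timepoints": r.n_timepoints}
         for r in records]
    )
    return Cohort(records=records, metadata=metadata, design=design,
                  seeds=seeds, tissues=tissues, master_seed=int(seed))


def simulate_zmap_cohort(cohort_or_records,
                         design: ConnectivityDesign,
                         shape: tuple[int, int, int],
                         seed: int,
                         noise_sd: float = 0.1,
                         noise_fwhm_vox: float = 2.7) -> np.ndarray:
    """Subject-level Fisher-z maps generated directly at the map level.

    Each subject's map is the planted mean (Fisher z of that subject's
    design correlation over the target region, zero elsewhere) plus a
    stationary smooth Gaussian noise field: white noise convolved with a
    Gaussian kernel of ``noise_fwhm_vox`` voxels FWHM under periodic
    boundary conditions, rescaled to standard deviation ``noise_sd``.
    ``noise_sd`` bundles per-subject sampling error of z (about
    1/sqrt(T-3)) with between-subject variability; the default smoothness
    of 2.7 voxels (8 mm at 3 mm voxels) matches the smoothness measured
    on z maps produced by the full BOLD subject pipeline.

    This is the right level at which to exercise and calibrate the group
    inference machinery; fidelity of the full BOLD subject pipeline is
    tested separately.

    Returns
    -------
    ndarray, shape (n_subjects, nx, ny, nz)
    """
    records = (cohort_or_records.records
               if isinstance(cohort_or_records, Cohort) else list(cohort_or_records))
    sigma = noise_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    maps = np.empty((len(records), *shape))
    for i, rec in enumerate(records):
        rng = subject_rng(int(seed), rec.subject_id)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma,
                                        mode="wrap")
        noise *= noise_sd / noise.std()
        mean = np.zeros(shape)
        if design.target_region is not None:
            mean[design.target_region] = np.arctanh(design.rho_for(rec))
        maps[i] = mean + noise
    return maps


def write_cohort(cohort: Cohort, directory: str | Path,
                 overwrite: bool = False) -> dict:
    """Write a cohort to disk: NIfTI volumes, motion text files, masks,
    metadata CSV and a JSON manifest.

    Returns the manifest (relative paths), also written as
    ``manifest.json``.  Refuses to clobber existing subject files unless
    ``overwrite`` is set.
    """
    from midfc import io as mio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bold_paths, motion_paths = [], []
    for record in cohort.records:
        bpath = directory / f"{record.subject_id}_bold.nii.gz"
        mpath = directory / f"{record.subject_id}_motion.txt"
        if not overwrite and (bpath.exists() or mpath.exists()):
            raise FileExistsError(
                f"output for {record.subject_id} already exists in {directory}; "
                "pass overwrite=True to replace it")
        bold, motion = cohort.subject_data(record)
        mio.save_bold(bpath, bold)
        mio.save_motion(mpath, motion)
        bold_paths.append(bpath.name)
        motion_paths.append(mpath.name)
    mask_paths = {}
    grid = cohort.grid
    for name, mask in {
        "vta": cohort.seeds.vta, "snc": cohort.seeds.snc,
        "brain": cohort.tissues.whole_brain,
        "white_matter": cohort.tissues.white_matter,
        "ventricle": cohort.tissues.ventricle,
    }.items():
        p = directory / f"mask_{name}.nii.gz"
        mio.save_mask(p, mask, grid.affine)
        mask_paths[name] = p.name
    if cohort.design.target_region is not None:
        p = directory / "mask_target.nii.gz"
        mio.save_mask(p, cohort.design.target_region, grid.affine)
        mask_paths["target"] = p.name
    meta_path = directory / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    manifest = {
        "bold": bold_paths,
        "motion": motion_paths,
        "masks": mask_paths,
        "metadata": meta_path.name,
        "master_seed": cohort.master_seed,
        "n_subjects": len(cohort),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
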