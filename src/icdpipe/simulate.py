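"""Synthetic resting-state cohorts with planted exposure-connectivity effects.

The generator produces everything the analysis chain consumes — 4D BOLD
series, tissue masks, a 7-label reference parcellation, motion traces
and a covariate table — with the statistical structure the downstream
inference assumes:

* Gray matter contains two coupled voxel communities, a
  "somatomotor-like" block and a "DMN-like" block, plus weakly coupled
  background gray matter.  Time series within a community follow a
  single-factor (equicorrelation) multivariate-normal model, so the
  within-community correlation is controlled exactly.
* The somatomotor-like coupling changes linearly with the subject's
  traumatic-event (TE) count for everyone (main effect); the DMN-like
  coupling changes with TE at sex-specific slopes of opposite sign.
* White-matter and ventricle voxels carry structured nuisance signals
  that are linearly mixed into gray matter, so tissue-based regression
  has something real to remove; a slow out-of-band drift exercises the
  band-limit regression.
* Motion traces are a small random walk with occasional displacement
  spikes large enough to trip the 0.3 mm censoring rule; a configurable
  fraction of subjects moves enough to fail QC outright.

Latent signals (community factors, voxel idiosyncratic components,
nuisance sources) are band-limited to the analysis band so the series
look BOLD-like; observation noise is white.  Everything is a
deterministic function of ``SimDesign.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .images import Mask3D, Parcellation3D, Volume4D, make_affine
from .qc import N_TRAUMA_ITEMS, SubjectRecord

logger = logging.getLogger(__name__)

# community codes in the community map
BACKGROUND = 0
SOMATOMOTOR = 1
DMN = 2
BACKGROUND_GM = 3

# reference-parcellation labels carried by the planted communities
# (numbering follows the common 7-network convention: 2 = somatomotor,
# 7 = default mode)
SOMATOMOTOR_LABEL = 2
DMN_LABEL = 7

#: default tetrachoric correlation between trauma items (adverse events
#: co-occur; a positively dependent item set also produces the heavier
#: multi-event tail that motivates pooling counts of three or more)
DEFAULT_ITEM_CORRELATION = 0.4


def _p_none(p_item: float, correlation: float) -> float:
    """P(no item endorsed) under a one-factor Gaussian copula with equal
    marginals ``p_item`` and pairwise latent correlation ``correlation``."""
    if correlation <= 0:
        return (1.0 - p_item) ** N_TRAUMA_ITEMS
    lam = np.sqrt(correlation)
    z = stats.norm.ppf(p_item)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    cond = stats.norm.cdf((z - lam * nodes) / np.sqrt(1.0 - correlation))
    vals = (1.0 - cond) ** N_TRAUMA_ITEMS
    return float(np.sum(weights * vals) / np.sqrt(2.0 * np.pi))


def default_item_rates(p_any: float = 0.478,
                       correlation: float = DEFAULT_ITEM_CORRELATION) -> tuple[float, ...]:
    """Equal per-item marginal rates such that P(at least one event) =
    ``p_any`` under the item-dependence model."""
    if not 0.0 <= p_any < 1.0:
        raise ValueError(f"p_any must be in [0, 1), got {p_any}")
    if p_any == 0.0:
        return (0.0,) * N_TRAUMA_ITEMS
    from scipy.optimize import brentq

    p = brentq(lambda q: 1.0 - _p_none(q, correlation) - p_any, 1e-9, 1 - 1e-9,
               xtol=1e-12)
    return (float(p),) * N_TRAUMA_ITEMS


@dataclass
class SimDesign:
    """Full description of a synthetic cohort; the seed determines every bit."""

    n_subjects: int = 60
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 3.0
    tr_seconds: float = 3.0
    n_trs: int = 124  # ~6.2 min at TR 3 s; first 4 frames are discarded downstream
    n_discard: int = 4

    # coupling structure (within-community Pearson correlation of the signal).
    # The main-effect slope spans most of the usable coupling range because a
    # ~6 min scan leaves subject-level alpha noise of ~0.4 (finite-scan
    # correlation sampling, shared across a community) while alpha responds
    # to coupling at only about -2 per unit correlation, and the sex x TE
    # column inflates the TE coefficient's standard error ~1.6x.
    coupling_somatomotor: float = 0.68
    coupling_dmn: float = 0.55
    coupling_background: float = 0.15
    te_slope_main: float = -0.21  # somatomotor coupling change per TE unit
    te_slope_male: float = 0.06  # DMN coupling change per TE unit, males
    te_slope_female: float = -0.06  # DMN coupling change per TE unit, females
    coupling_clip: tuple[float, float] = (0.0, 0.95)

    # signal / nuisance amplitudes (latent signals are unit variance)
    noise_sd: float = 0.3  # white observation noise
    nuisance_mix: float = 0.3  # WM/ventricle signal mixed into gray matter
    drift_amp: float = 0.5  # slow out-of-band drift amplitude
    band_hz: tuple[float, float] = (0.01, 0.08)
    baseline_intensity: float = 100.0
    equilibration_frames: int = 4  # initial frames get a decaying offset

    # motion model
    motion_step_mm: float = 0.02  # random-walk step SD per axis
    spike_prob: float = 0.04  # per-frame probability of a displacement spike
    spike_min_mm: float = 0.35
    spike_scale_mm: float = 0.2
    rotation_step: float = 0.001  # radians
    high_motion_frac: float = 0.15  # subjects with inflated motion (QC fodder)
    high_motion_factor: float = 8.0

    # covariate marginals
    female_frac: float = 0.578
    age_range: tuple[float, float] = (8.0, 21.0)
    age_mean: float = 14.6
    age_sd: float = 3.3
    item_rates: tuple[float, ...] = field(default_factory=default_item_rates)
    item_correlation: float = DEFAULT_ITEM_CORRELATION  # tetrachoric; items co-occur
    medu_mean_years: float = 14.0
    medu_sd_years: float = 2.0
    medu_te_slope: float = -0.8  # years of maternal education per raw TE count
    medu_range: tuple[float, float] = (6.0, 20.0)
    brain_injury_rate: float = 0.12
    missing_items_rate: float = 0.005
    missing_medu_rate: float = 0.005

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        probs = {
            "female_frac": self.female_frac,
            "brain_injury_rate": self.brain_injury_rate,
            "missing_items_rate": self.missing_items_rate,
            "missing_medu_rate": self.missing_medu_rate,
            "spike_prob": self.spike_prob,
            "high_motion_frac": self.high_motion_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if len(self.item_rates) != N_TRAUMA_ITEMS:
            raise ValueError(f"item_rates must have {N_TRAUMA_ITEMS} entries")
        for p in self.item_rates:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"item rates must be probabilities, got {p}")
        if not 0.0 <= self.item_correlation < 1.0:
            raise ValueError(
                f"item_correlation must be in [0, 1), got {self.item_correlation}"
            )
        lo, hi = self.coupling_clip
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError(f"coupling_clip must satisfy 0 <= lo < hi < 1, got {self.coupling_clip}")
        for name in ("coupling_somatomotor", "coupling_dmn", "coupling_background"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_trs <= self.n_discard + 10:
            raise ValueError("n_trs too small for truncation")

    @property
    def affine(self) -> np.ndarray:
        return make_affine(self.voxel_size_mm)


@dataclass
class CohortGeometry:
    """Masks, community map and reference parcellation on the design grid."""

    gm: Mask3D
    wm: Mask3D
    ventricles: Mask3D
    community_map: np.ndarray  # int codes, same shape as grid
    parcellation: Parcellation3D

    def community_mask(self, code: int) -> np.ndarray:
        return self.community_map == code


def _frac_slice(n: int, lo: float, hi: float) -> slice:
    return slice(int(round(lo * n)), int(round(hi * n)))


def default_geometry(design: SimDesign) -> CohortGeometry:
    """Desk-scale tissue layout: two gray-matter communities, background
    gray matter, a white-matter slab and a small ventricle block.

    The parcellation assigns the somatomotor-like community label 2 and
    the DMN-like community label 7; background gray matter is striped
    with the remaining five labels so all seven appear.
    """
    nx, ny, nz = design.grid_shape
    aff = design.affine
    z_mid = _frac_slice(nz, 1 / 3, 2 / 3)
    regions = {
        SOMATOMOTOR: (_frac_slice(nx, 0.10, 0.35), _frac_slice(ny, 0.10, 0.35), z_mid),
        DMN: (_frac_slice(nx, 0.65, 0.90), _frac_slice(ny, 0.10, 0.35), z_mid),
        BACKGROUND_GM: (_frac_slice(nx, 0.35, 0.60), _frac_slice(ny, 0.60, 0.85), z_mid),
    }
    community = np.zeros(design.grid_shape, dtype=np.int8)
    for code, (sx, sy, sz) in regions.items():
        community[sx, sy, sz] = code

    gm = community > 0
    wm = np.zeros(design.grid_shape, dtype=bool)
    wm[_frac_slice(nx, 0.10, 0.35), _frac_slice(ny, 0.60, 0.85), z_mid] = True
    vent = np.zeros(design.grid_shape, dtype=bool)
    vent[_frac_slice(nx, 0.65, 0.90), _frac_slice(ny, 0.60, 0.85), _frac_slice(nz, 1 / 6, 1 / 2)] = True

    parc = np.zeros(design.grid_shape, dtype=np.int32)
    parc[community == SOMATOMOTOR] = SOMATOMOTOR_LABEL
    parc[community == DMN] = DMN_LABEL
    other_labels = [1, 3, 4, 5, 6]
    bg_idx = np.argwhere(community == BACKGROUND_GM)
    if len(bg_idx):
        xs = np.unique(bg_idx[:, 0])
        for k, x in enumerate(xs):
            sel = bg_idx[bg_idx[:, 0] == x]
            parc[sel[:, 0], sel[:, 1], sel[:, 2]] = other_labels[k % len(other_labels)]

    return CohortGeometry(
        gm=Mask3D(gm, aff),
        wm=Mask3D(wm, aff),
        ventricles=Mask3D(vent, aff),
        community_map=community,
        parcellation=Parcellation3D(parc, aff),
    )


@dataclass
class SubjectTruth:
    """Generating couplings realized for one subject."""

    subject_id: str
    coupling_somatomotor: float
    coupling_dmn: float
    clipped: bool


@dataclass
class CohortTruth:
    """Exact per-voxel generating slopes; recoverable from the design alone."""

    slope_main: np.ndarray  # coupling change per TE unit (somatomotor community)
    slope_male: np.ndarray
    slope_female: np.ndarray
    per_subject: list[SubjectTruth]


@dataclass
class SyntheticCohort:
    design: SimDesign
    geometry: CohortGeometry
    subjects: list[SubjectRecord]
    images: list[Volume4D]
    motion: list[np.ndarray]  # (n_trs, 6): 3 translations mm, 3 rotations rad
    truth: CohortTruth


# ---------------------------------------------------------------------------
# covariates


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_covariates(design: SimDesign) -> list[SubjectRecord]:
    """Draw the covariate table: sex, age, trauma items, maternal
    education (negatively tied to exposure), injury and missingness flags."""
    design.validate()
    # one sub-stream per variable so each marginal depends only on the seed
    lo, hi = design.age_range
    a, b = (lo - design.age_mean) / design.age_sd, (hi - design.age_mean) / design.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=design.age_mean, scale=design.age_sd, size=design.n_subjects,
        random_state=_rng(design.seed, 0, 0),
    )
    females = _rng(design.seed, 0, 1).random(design.n_subjects) < design.female_frac
    # one-factor Gaussian copula: items co-occur through a latent adversity score
    item_rng = _rng(design.seed, 0, 2)
    lam = np.sqrt(design.item_correlation)
    latent = item_rng.standard_normal(design.n_subjects)
    eps = item_rng.standard_normal((design.n_subjects, N_TRAUMA_ITEMS))
    z_scores = lam * latent[:, None] + np.sqrt(1.0 - design.item_correlation) * eps
    thresholds = stats.norm.ppf(np.asarray(design.item_rates))
    items = (z_scores < thresholds).astype(int)
    medu_noise = _rng(design.seed, 0, 3).normal(0.0, design.medu_sd_years, design.n_subjects)
    injury = _rng(design.seed, 0, 4).random(design.n_subjects) < design.brain_injury_rate
    miss_items = _rng(design.seed, 0, 5).random(design.n_subjects) < design.missing_items_rate
    miss_medu = _rng(design.seed, 0, 6).random(design.n_subjects) < design.missing_medu_rate

    out: list[SubjectRecord] = []
    for i in range(design.n_subjects):
        raw = int(items[i].sum())
        medu = float(
            np.clip(
                design.medu_mean_years + design.medu_te_slope * raw + medu_noise[i],
                *design.medu_range,
            )
        )
        out.append(
            SubjectRecord(
                subject_id=f"sub-{i:04d}",
                sex="female" if females[i] else "male",
                age=float(ages[i]),
                maternal_education=None if miss_medu[i] else medu,
                trauma_items=None if miss_items[i] else tuple(int(v) for v in items[i]),
                brain_injury=bool(injury[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# images


def _band_limited(rng: np.random.Generator, n_series: int, n_t: int, tr: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Unit-variance rows containing only Fourier components inside ``band``."""
    white = rng.standard_normal((n_series, n_t))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("band contains no resolvable frequencies")
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_t, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def check_equicorrelation_psd(rho: float, m: int) -> None:
    """An m x m equicorrelation matrix is PSD iff rho >= -1/(m-1)."""
    if m > 1 and rho < -1.0 / (m - 1) - 1e-12:
        raise ValueError(f"equicorrelation rho={rho} is not PSD for block size {m}")


def realized_couplings(design: SimDesign, subject: SubjectRecord) -> SubjectTruth:
    """Generating couplings for one subject (linear in coded TE, clipped)."""
    te = subject.te_coded if subject.te_coded is not None else 0
    lo, hi = design.coupling_clip
    rho_sm = design.coupling_somatomotor + design.te_slope_main * te
    slope_sex = design.te_slope_male if subject.sex == "male" else design.te_slope_female
    rho_dmn = design.coupling_dmn + slope_sex * te
    clipped = not (lo <= rho_sm <= hi and lo <= rho_dmn <= hi)
    if clipped:
        logger.warning(
            "coupling clipped for %s: somatomotor %.3f, dmn %.3f -> [%g, %g]",
            subject.subject_id, rho_sm, rho_dmn, lo, hi,
        )
    return SubjectTruth(
        subject_id=subject.subject_id,
        coupling_somatomotor=float(np.clip(rho_sm, lo, hi)),
        coupling_dmn=float(np.clip(rho_dmn, lo, hi)),
        clipped=clipped,
    )


def _community_series(rng, rho: float, m: int, n_t: int, tr: float, band, subject_id: str) -> np.ndarray:
    """m series with exact pairwise signal correlation rho (single-factor model)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"coupling {rho} for subject {subject_id} is outside [0, 1)")
    check_equicorrelation_psd(rho, m)
    factor = _band_limited(rng, 1, n_t, tr, band)
    idio = _band_limited(rng, m, n_t, tr, band)
    return np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * idio


def simulate_subject_image(
    design: SimDesign,
    geometry: CohortGeometry,
    subject: SubjectRecord,
    subject_index: int,
) -> tuple[Volume4D, np.ndarray, SubjectTruth]:
    """One subject's 4D volume and motion trace.

    The per-subject random stream is keyed by subject index, so any
    subject can be regenerated independently and the cohort is
    bit-reproducible regardless of generation order.
    """
    rng = _rng(design.seed, 1, subject_index)
    n_t, tr, band = design.n_trs, design.tr_seconds, design.band_hz
    truth = realized_couplings(design, subject)

    data = np.zeros(design.grid_shape + (n_t,), dtype=np.float64)
    cm = geometry.community_map

    for code, rho in (
        (SOMATOMOTOR, truth.coupling_somatomotor),
        (DMN, truth.coupling_dmn),
        (BACKGROUND_GM, design.coupling_background),
    ):
        vox = cm == code
        m = int(vox.sum())
        if m:
            data[vox, :] = _community_series(rng, rho, m, n_t, tr, band, subject.subject_id)

    # white-matter slab: one shared source + idiosyncratic components
    wm_vox = geometry.wm.data
    wm_source = _band_limited(rng, 1, n_t, tr, band)[0]
    data[wm_vox, :] = np.sqrt(0.6) * wm_source + np.sqrt(0.4) * _band_limited(
        rng, int(wm_vox.sum()), n_t, tr, band
    )

    # ventricles: three latent components with random loadings
    vent_vox = geometry.ventricles.data
    n_vent = int(vent_vox.sum())
    vent_sources = _band_limited(rng, 3, n_t, tr, band)
    loadings = rng.normal(0.0, 1.0, (n_vent, 3))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    data[vent_vox, :] = loadings @ vent_sources + 0.3 * _band_limited(rng, n_vent, n_t, tr, band)

    # mix nuisance sources into gray matter (what tissue regression must undo)
    gm_vox = geometry.gm.data
    n_gm = int(gm_vox.sum())
    if design.nuisance_mix > 0:
        w_gain = rng.normal(1.0, 0.3, n_gm)
        v_gain = rng.normal(0.0, 1.0, (n_gm, 3)) / np.sqrt(3.0)
        data[gm_vox, :] += design.nuisance_mix * (
            w_gain[:, None] * wm_source + v_gain @ vent_sources
        )

    # slow drift, outside the analysis band
    if design.drift_amp > 0:
        t = np.arange(n_t) * tr
        drift = np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
        gains = rng.uniform(0.5, 1.5, int(np.prod(design.grid_shape)))
        data += design.drift_amp * gains.reshape(design.grid_shape)[..., None] * drift

    # observation noise everywhere, baseline intensity, initial transient
    if design.noise_sd > 0:
        data += design.noise_sd * rng.standard_normal(data.shape)
    data += design.baseline_intensity
    k = min(design.equilibration_frames, n_t)
    if k:
        data[..., :k] += 5.0 * np.exp(-np.arange(k, dtype=float))

    motion = _simulate_motion(design, rng)
    vol = Volume4D(data, design.affine, tr_seconds=tr)
    return vol, motion, truth


def _simulate_motion(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Six rigid-body parameters per frame; spikes create censorable jumps."""
    n_t = design.n_trs
    high = rng.random() < design.high_motion_frac
    step = design.motion_step_mm * (3.0 if high else 1.0)
    spike_p = design.spike_prob * (design.high_motion_factor if high else 1.0)

    trans = np.cumsum(rng.normal(0.0, step, (n_t, 3)), axis=0)
    spikes = rng.random(n_t) < spike_p
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        direction = rng.normal(0.0, 1.0, 3)
        direction /= np.linalg.norm(direction)
        mag = design.spike_min_mm + rng.exponential(design.spike_scale_mm)
        trans[i] += mag * direction  # single-frame excursion: i-1->i and i->i+1 both jump
    rots = np.cumsum(rng.normal(0.0, design.rotation_step, (n_t, 3)), axis=0)
    return np.hstack([trans, rots])


def simulate_images(design: SimDesign, subjects: Sequence[SubjectRecord],
                    geometry: Optional[CohortGeometry] = None) -> SyntheticCohort:
    """Simulate the full cohort (images, motion, masks, truth) for given covariates."""
    design.validate()
    if geometry is None:
        geometry = default_geometry(design)
    images, motion, per_subject = [], [], []
    for i, subj in enumerate(subjects):
        vol, mot, truth = simulate_subject_image(design, geometry, subj, i)
        images.append(vol)
        motion.append(mot)
        per_subject.append(truth)

    cm = geometry.community_map
    slope_main = np.where(cm == SOMATOMOTOR, design.te_slope_main, 0.0)
    slope_male = np.where(cm == DMN, design.te_slope_male, 0.0)
    slope_female = np.where(cm == DMN, design.te_slope_female, 0.0)
    return SyntheticCohort(
        design=design,
        geometry=geometry,
        subjects=list(subjects),
        images=images,
        motion=motion,
        truth=CohortTruth(slope_main, slope_male, slope_female, per_subject),
    )


def simulate_cohort(design: SimDesign) -> SyntheticCohort:
    """Covariates + images in one call."""
    return simulate_images(design, simulate_covariates(design))
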