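"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one input class of the alpha-synuclein assay suite
(step-plateau pHluorin traces with NH4Cl dequench, point-flash TIRF movies,
perinuclear-vs-dispersed vesicle images, locally perturbed mutant shift
tables, sigmoidal lipid/free intensity-ratio profiles, linear blot
calibration lanes with lane-loading variation, and exponential-to-plateau
FITC quench curves) and returns the data alongside a :class:`GroundTruth`
record.  Recovery tests compare estimator output against those recorded
fields only.

Design rules:

* one ``numpy.random.default_rng(cfg.seed)`` per call, no global state —
  identical :class:`GenConfig` gives bit-identical output;
* ``noise_sd = 0`` gives exactly the noiseless model;
* puncta are symmetric Gaussians rendered by analytic integration of the
  Gaussian over each pixel (erf differences), so sub-pixel intensity ground
  truth is exact rather than point-sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .errors import InvalidAnnotationError, PlacementError
from .types import (
    DensitometryTable,
    MaskedImagePair,
    ResidueTable,
    TimeSeriesTrace,
    TirfMovie,
)

__all__ = [
    "GenConfig",
    "GroundTruth",
    "gen_exo_trace",
    "gen_tirf_movie",
    "gen_cell_image",
    "gen_coloc_pair",
    "gen_shift_tables",
    "gen_binding_profile",
    "gen_blot",
    "gen_quench_curve",
    "render_gaussian_spots",
]

# Default blot standard concentrations (ug/ml) of purified recombinant
# protein used to build the calibration curve.
STANDARD_CONCS = (2.0, 3.5, 5.0, 6.5, 8.0)


@dataclass(frozen=True)
class GenConfig:
    """Shared generator configuration.

    seed drives the single per-call RNG; noise_sd is additive Gaussian
    noise in the units of the generated quantity.  Size parameters: trace
    sampling (dt_s over duration_s; 2 s over 600 s matches a course
    monitored ~20 s before stimulation with NH4Cl added 6-8 min later),
    image geometry (image_shape px at pixel_size_nm; 100 nm/px makes an
    800 nm shell 8 px), movie length (n_frames), and table sizes
    (n_residues, n_lanes).
    """

    seed: int = 0
    noise_sd: float = 0.0
    n_frames: int = 80
    image_shape: tuple = (128, 128)
    pixel_size_nm: float = 100.0
    n_residues: int = 140
    n_lanes: int = 8
    dt_s: float = 2.0
    duration_s: float = 600.0
    frame_interval_s: float = 1.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """True values recorded by a generator for recovery testing."""

    true_pct_exocytosis: Optional[float] = None
    events: Optional[pd.DataFrame] = None  # columns t, frame, row, col
    true_shell_fraction: Optional[float] = None
    achieved_shell_fraction: Optional[float] = None
    moc: Optional[float] = None
    n_puncta: Optional[int] = None
    n_colabeled: Optional[int] = None
    perturb_site: Optional[int] = None
    perturb_width: Optional[float] = None
    perturb_magnitude: Optional[float] = None
    carbon_offset: Optional[float] = None
    true_boundary_residue: Optional[int] = None
    bound_free_fraction: Optional[float] = None
    unbound_free_fraction: Optional[float] = None
    true_lane_concentrations: Optional[dict] = None  # lane id -> ug/ml
    slope: Optional[float] = None
    loading_factors: Optional[dict] = None
    true_quench_fraction: Optional[float] = None
    quench_rate: Optional[float] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pHluorin exocytosis traces
# ---------------------------------------------------------------------------

def gen_exo_trace(
    basal_level: float = 100.0,
    stim_rise_fraction: float = 0.25,
    nh4cl_level: float = 400.0,
    t_stim: float = 20.0,
    t_nh4cl: float = 420.0,
    cfg: GenConfig = GenConfig(),
    rise_time_s: float = 60.0,
    reacidification_rate: float = 0.0,
    bafilomycin: bool = False,
) -> tuple:
    """Piecewise pHluorin trace: flat basal, saturating stimulated rise to
    ``basal + f*(nh4cl - basal)``, then a step to the NH4Cl plateau.

    The stimulated rise is a linear ramp over ``rise_time_s`` that clamps
    exactly at its plateau, so the noiseless stimulated window equals the
    plateau value and percent-exocytosis closure is exact.  The kinetics of
    the rise are free parameters of the generator, not measured constants.

    ``reacidification_rate`` (1/s) models endocytic re-uptake quenching the
    stimulated component exponentially; ``bafilomycin`` (proton-pump
    inhibition applied just before stimulation) suppresses that term and
    annotates the trace with ``t_baf``, so paired traces differ in percent
    exocytosis only when the rate is nonzero.
    """
    if not 0.0 <= stim_rise_fraction <= 1.0:
        raise ValueError("stim_rise_fraction must lie in [0, 1]")
    if basal_level >= nh4cl_level:
        raise ValueError("basal_level must be below nh4cl_level")
    times = np.arange(0.0, cfg.duration_s + cfg.dt_s / 2, cfg.dt_s)
    if not (0 <= t_stim < t_nh4cl < times[-1]):
        raise InvalidAnnotationError("need 0 <= t_stim < t_nh4cl < trace end")
    plateau_rise = stim_rise_fraction * (nh4cl_level - basal_level)
    values = np.full_like(times, basal_level)
    stim = (times >= t_stim) & (times < t_nh4cl)
    frac = np.minimum(1.0, (times[stim] - t_stim) / max(rise_time_s, cfg.dt_s))
    if reacidification_rate > 0 and not bafilomycin:
        frac = frac * np.exp(-reacidification_rate * (times[stim] - t_stim))
    values[stim] = basal_level + plateau_rise * frac
    values[times >= t_nh4cl] = nh4cl_level
    if cfg.noise_sd > 0:
        values = values + cfg.rng().normal(0.0, cfg.noise_sd, size=values.shape)
    trace = TimeSeriesTrace(times, values, t_stim=t_stim, t_nh4cl=t_nh4cl,
                            t_baf=t_stim - 5.0 if bafilomycin else None,
                            identifier=f"exo-seed{cfg.seed}")
    return trace, GroundTruth(true_pct_exocytosis=100.0 * stim_rise_fraction,
                              extras={"reacidification_rate": reacidification_rate,
                                      "bafilomycin": bafilomycin})


# ---------------------------------------------------------------------------
# TIRF flash movies
# ---------------------------------------------------------------------------

def gen_tirf_movie(
    n_events: int = 12,
    flash_amplitude: float = 50.0,
    flash_sigma_px: float = 2.0,
    flash_decay_frames: float = 3.0,
    cfg: GenConfig = GenConfig(),
    background: float = 100.0,
    min_dt_frames: int = 10,
    min_dist_px: float = 12.0,
    edge_margin_frames: int = 12,
) -> tuple:
    """Movie of exocytic flashes: each event is a 2-D Gaussian appearing at
    its onset frame and decaying exponentially over ``flash_decay_frames``.

    Events are placed >= 2 sigma (+2 px) from image borders and are
    rejected unless separated by more than ``min_dt_frames`` frames or
    ``min_dist_px`` pixels, so the zero-noise fixture never contains
    overlapping flashes; impossible placements raise :class:`PlacementError`
    rather than silently overlapping.
    """
    rng = cfg.rng()
    n_frames = cfg.n_frames
    h, w = cfg.image_shape
    margin = 2.0 * flash_sigma_px + 2.0
    t_lo, t_hi = edge_margin_frames, n_frames - int(np.ceil(5 * flash_decay_frames)) - 1
    if n_events > 0 and t_hi <= t_lo:
        raise PlacementError("movie too short for the requested events")
    placed: list = []
    tries = 0
    while len(placed) < n_events:
        tries += 1
        if tries > 5000:
            raise PlacementError(
                f"could not place {n_events} events with the stated separation")
        t0 = int(rng.integers(t_lo, t_hi + 1))
        r0 = rng.uniform(margin, h - 1 - margin)
        c0 = rng.uniform(margin, w - 1 - margin)
        ok = True
        for (t1, r1, c1) in placed:
            if abs(t1 - t0) <= min_dt_frames and np.hypot(r1 - r0, c1 - c0) <= min_dist_px:
                ok = False
                break
        if ok:
            placed.append((t0, r0, c0))

    frames = np.full((n_frames, h, w), background, dtype=float)
    span = int(np.ceil(5 * flash_decay_frames))
    for (t0, r0, c0) in placed:
        for dt in range(span + 1):
            amp = flash_amplitude * np.exp(-dt / flash_decay_frames)
            render_gaussian_spots(frames[t0 + dt], [(r0, c0)], flash_sigma_px, amp,
                                  normalize_peak=True)
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, size=frames.shape)
    movie = TirfMovie(frames, frame_interval=cfg.frame_interval_s,
                      pixel_size=cfg.pixel_size_nm)
    events = pd.DataFrame(
        [(t0 * cfg.frame_interval_s, t0, r0, c0) for (t0, r0, c0) in placed],
        columns=["t", "frame", "row", "col"],
    )
    return movie, GroundTruth(events=events)


# ---------------------------------------------------------------------------
# Gaussian spot rendering (shared)
# ---------------------------------------------------------------------------

def render_gaussian_spots(
    image: np.ndarray,
    centers: Sequence,
    sigma_px: float,
    amplitude: float,
    normalize_peak: bool = False,
    window_sigmas: float = 4.0,
) -> np.ndarray:
    """Add symmetric 2-D Gaussian spots to ``image`` in place.

    Each spot's pixel value is the analytic integral of the Gaussian over
    the unit pixel (difference of erf terms), giving exact sub-pixel mass
    ground truth.  Rendering is truncated at ``window_sigmas`` so spots
    placed farther apart than twice that radius have exactly disjoint
    supports.  With ``normalize_peak`` the central pixel integral is scaled
    to ``amplitude``; otherwise ``amplitude`` is the total spot mass.
    """
    h, w = image.shape
    s = sigma_px * np.sqrt(2.0)
    rad = int(np.ceil(window_sigmas * sigma_px))

    def axis_integral(coords, c0):
        return 0.5 * (erf((coords + 0.5 - c0) / s) - erf((coords - 0.5 - c0) / s))

    peak_unit = (erf(0.5 / s) - erf(-0.5 / s)) ** 2 / 4.0
    for (r0, c0) in centers:
        ri = int(round(r0))
        ci = int(round(c0))
        rows = np.arange(max(0, ri - rad), min(h, ri + rad + 1))
        cols = np.arange(max(0, ci - rad), min(w, ci + rad + 1))
        spot = np.outer(axis_integral(rows, r0), axis_integral(cols, c0))
        scale = amplitude / peak_unit if normalize_peak else amplitude
        image[np.ix_(rows, cols)] += scale * spot
    return image


def _ellipse_mask(shape, center=None, semi_axes=None) -> np.ndarray:
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if semi_axes is None:
        semi_axes = (0.72 * h / 2.0, 0.56 * w / 2.0)
    rr, cc = np.mgrid[0:h, 0:w]
    a, b = semi_axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Cell images: membrane-proximal vesicle fraction
# ---------------------------------------------------------------------------

def gen_cell_image(
    true_shell_fraction: float = 0.40,
    n_vesicles: int = 60,
    shell_width_nm: float = 800.0,
    cfg: GenConfig = GenConfig(),
    puncta_sigma_px: float = 1.2,
    amplitude: float = 200.0,
) -> tuple:
    """Elliptical cell with Gaussian vesicle puncta split between a
    membrane-proximal shell and the interior.

    ``round(true_shell_fraction * n_vesicles)`` puncta are centered inside
    the shell (the outer ``shell_width_nm`` band of the mask) and the rest
    well inside the interior, so the noiseless shell-integrated intensity
    fraction matches ``true_shell_fraction`` up to placement/tail leakage;
    the fraction realized by the rendered noiseless image is recorded as
    ``achieved_shell_fraction``.  The default 0.40 mirrors a strongly
    dispersed (high-expression) vesicle distribution.
    """
    if not 0.0 <= true_shell_fraction <= 1.0:
        raise ValueError("true_shell_fraction must lie in [0, 1]")
    shell_px = shell_width_nm / cfg.pixel_size_nm
    if shell_px < 1.0:
        raise ValueError("shell thinner than one pixel at this pixel size")
    shell_px = int(round(shell_px))
    rng = cfg.rng()
    mask = _ellipse_mask(cfg.image_shape)
    dist = ndimage.distance_transform_edt(mask)
    pad = 2.0  # keep centers off the very edge of their band
    shell_zone = mask & (dist >= pad) & (dist <= shell_px - 1)
    interior_zone = dist >= shell_px + 3.0 * puncta_sigma_px
    if not shell_zone.any() or not interior_zone.any():
        raise PlacementError("cell too small for the requested shell geometry")

    n_shell = int(round(true_shell_fraction * n_vesicles))
    centers = []
    for zone, n in ((shell_zone, n_shell), (interior_zone, n_vesicles - n_shell)):
        coords = np.argwhere(zone)
        idx = rng.integers(0, len(coords), size=n)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
        centers.append(coords[idx] + jitter)
    image = np.zeros(cfg.image_shape, dtype=float)
    for pts in centers:
        render_gaussian_spots(image, pts, puncta_sigma_px, amplitude)

    shell_mask = mask & (dist <= shell_px)
    total = image[mask].sum()
    achieved = float(image[shell_mask].sum() / total) if total > 0 else np.nan
    if cfg.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, cfg.noise_sd, size=image.shape), 0, None)
    pair = MaskedImagePair(channel_r=image, channel_g=np.zeros_like(image),
                           cell_mask=mask, pixel_size=cfg.pixel_size_nm)
    gt = GroundTruth(true_shell_fraction=true_shell_fraction,
                     achieved_shell_fraction=achieved,
                     extras={"n_vesicles": n_vesicles, "shell_width_nm": shell_width_nm})
    return pair, gt


# ---------------------------------------------------------------------------
# Two-channel colocalization pairs
# ---------------------------------------------------------------------------

def gen_coloc_pair(
    overlap_mode: str = "partial",
    cfg: GenConfig = GenConfig(),
    n_puncta: int = 10,
    n_shared: int = 7,
    puncta_sigma_px: float = 1.5,
    amplitude: float = 150.0,
    min_dist_px: float = 16.0,
) -> tuple:
    """Two channels of puncta with controlled overlap.

    identical: same spots in both channels (MOC = 1); disjoint: spot
    supports strictly separated (MOC = 0; rendering windows are finite so
    disjointness is exact); partial: ``n_shared`` of ``n_puncta`` red spots
    are co-labeled in green.  The recorded ``moc`` is the overlap formula
    evaluated directly on the noiseless images.
    """
    if overlap_mode not in {"identical", "disjoint", "partial"}:
        raise ValueError("overlap_mode must be identical, disjoint, or partial")
    if not 0 <= n_shared <= n_puncta:
        raise ValueError("need 0 <= n_shared <= n_puncta")
    rng = cfg.rng()
    h, w = cfg.image_shape
    mask = _ellipse_mask(cfg.image_shape)
    dist = ndimage.distance_transform_edt(mask)
    zone = np.argwhere(dist >= 4.0 * puncta_sigma_px + 1)
    def place(n: int, pool: np.ndarray, existing: list, spacing: float) -> list:
        pts: list = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > 20000:
                raise PlacementError("could not place non-overlapping puncta")
            r0, c0 = pool[rng.integers(0, len(pool))] + rng.uniform(-0.5, 0.5, size=2)
            if all(np.hypot(r0 - r1, c0 - c1) > spacing
                   for (r1, c1) in existing + pts):
                pts.append((r0, c0))
        return pts

    if overlap_mode == "disjoint":
        # rendering windows are truncated at 4 sigma, so the half-image gap
        # (> 8 sigma + 2 px wide) guarantees exactly disjoint supports
        gap = 4.0 * puncta_sigma_px + 2.0
        mid = cfg.image_shape[1] / 2.0
        left = zone[zone[:, 1] < mid - gap]
        right = zone[zone[:, 1] > mid + gap]
        if not len(left) or not len(right):
            raise PlacementError("cell too small to split into disjoint halves")
        centers = place(n_puncta, left, [], 8.0) + place(n_puncta, right, [], 8.0)
    else:
        centers = place(n_puncta, zone, [], min_dist_px)

    red = np.zeros(cfg.image_shape, dtype=float)
    green = np.zeros(cfg.image_shape, dtype=float)
    if overlap_mode == "identical":
        render_gaussian_spots(red, centers, puncta_sigma_px, amplitude)
        render_gaussian_spots(green, centers, puncta_sigma_px, amplitude)
        n_colab = n_puncta
    elif overlap_mode == "disjoint":
        render_gaussian_spots(red, centers[:n_puncta], puncta_sigma_px, amplitude)
        render_gaussian_spots(green, centers[n_puncta:], puncta_sigma_px, amplitude)
        n_colab = 0
    else:
        render_gaussian_spots(red, centers, puncta_sigma_px, amplitude)
        render_gaussian_spots(green, centers[:n_shared], puncta_sigma_px, amplitude)
        n_colab = n_shared

    num = float((red * green).sum())
    den = float(np.sqrt((red ** 2).sum() * (green ** 2).sum()))
    moc = num / den if den > 0 else np.nan
    if cfg.noise_sd > 0:
        red = np.clip(red + rng.normal(0.0, cfg.noise_sd, size=red.shape), 0, None)
        green = np.clip(green + rng.normal(0.0, cfg.noise_sd, size=green.shape), 0, None)
    pair = MaskedImagePair(channel_r=red, channel_g=green, cell_mask=mask,
                           pixel_size=cfg.pixel_size_nm)
    gt = GroundTruth(moc=moc, n_puncta=n_puncta, n_colabeled=n_colab,
                     extras={"centers": centers, "puncta_sigma_px": puncta_sigma_px})
    return pair, gt


# ---------------------------------------------------------------------------
# NMR residue tables
# ---------------------------------------------------------------------------

def _default_sequence(n_residues: int, rng: np.random.Generator) -> str:
    from .abs_quant import ASYN_HUMAN
    if n_residues == len(ASYN_HUMAN):
        return ASYN_HUMAN.sequence
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # no proline in random fill
    return "".join(rng.choice(alphabet, size=n_residues))


def _base_shift_table(sequence: str, rng: np.random.Generator) -> pd.DataFrame:
    from .nmr_membrane import load_random_coil_table
    rc = load_random_coil_table()
    n = len(sequence)
    residues = np.arange(1, n + 1)
    data = pd.DataFrame({"residue": residues, "aa": list(sequence)})
    data["H"] = rng.uniform(7.8, 8.6, size=n)
    data["N"] = rng.uniform(113.0, 126.0, size=n)
    data["CA"] = [rc.shift(aa, "CA") + rng.uniform(-0.3, 0.3) for aa in sequence]
    data["CB"] = [
        rc.shift(aa, "CB") + rng.uniform(-0.3, 0.3) if aa != "G" else np.nan
        for aa in sequence
    ]
    is_pro = data["aa"] == "P"
    data.loc[is_pro, ["H", "N"]] = np.nan
    return data


def gen_shift_tables(
    n_residues: int = 140,
    perturb_site: int = 70,
    perturb_width: float = 5.0,
    perturb_magnitude: float = 0.10,
    carbon_offset: float = 0.0,
    cfg: GenConfig = GenConfig(),
) -> tuple:
    """Wild-type and mutant amide/carbon shift tables.

    The mutant's amide shifts carry a Gaussian-bump perturbation centered
    at ``perturb_site`` (proton bump = ``perturb_magnitude`` ppm at the
    peak, nitrogen bump 5x that, matching the 1/25 down-weighting of the
    averaged-deviation formula), and its carbon shifts are additionally
    offset by ``carbon_offset`` ppm everywhere, emulating a mis-referenced
    carbon dimension.
    """
    rng = cfg.rng()
    sequence = _default_sequence(n_residues, rng)
    if not 1 <= perturb_site <= n_residues:
        raise ValueError("perturb_site outside sequence")
    wt = _base_shift_table(sequence, rng)
    mut = wt.copy()
    i = np.arange(1, n_residues + 1)
    bump = perturb_magnitude * np.exp(-((i - perturb_site) ** 2) / (2 * perturb_width ** 2))
    mut["H"] = mut["H"] + bump
    mut["N"] = mut["N"] + 5.0 * bump
    mut["CA"] = mut["CA"] + carbon_offset
    mut["CB"] = mut["CB"] + carbon_offset
    if cfg.noise_sd > 0:
        for col, scale in (("H", 1.0), ("N", 5.0), ("CA", 1.0), ("CB", 1.0)):
            mut[col] = mut[col] + rng.normal(0.0, scale * cfg.noise_sd, size=n_residues)
    gt = GroundTruth(perturb_site=perturb_site, perturb_width=perturb_width,
                     perturb_magnitude=perturb_magnitude, carbon_offset=carbon_offset)
    return ResidueTable(wt), ResidueTable(mut, check_ranges=False), gt


def gen_binding_profile(
    boundary_residue: int = 70,
    bound_free_fraction: float = 0.10,
    unbound_free_fraction: float = 0.90,
    cfg: GenConfig = GenConfig(),
    transition_width: float = 1.5,
    base_intensity: float = 1000.0,
) -> tuple:
    """Lipid-containing and lipid-free peak-intensity tables with a
    logistic binding boundary.

    Residues N-terminal to ``boundary_residue`` show an intensity ratio
    near ``bound_free_fraction`` (mostly membrane-bound, hence attenuated),
    residues C-terminal to it near ``unbound_free_fraction`` — the shape of
    a helix-2-breaking mutant that releases everything downstream of the
    mutation site from the vesicle surface.
    """
    rng = cfg.rng()
    n = cfg.n_residues
    if not 1 <= boundary_residue <= n:
        raise ValueError("boundary_residue outside sequence")
    sequence = _default_sequence(n, rng)
    residues = np.arange(1, n + 1)
    free_int = base_intensity * rng.uniform(0.9, 1.1, size=n)
    ratio = bound_free_fraction + (unbound_free_fraction - bound_free_fraction) / (
        1.0 + np.exp(-(residues - boundary_residue) / transition_width))
    lipid_int = free_int * ratio
    if cfg.noise_sd > 0:
        lipid_int = np.clip(lipid_int + rng.normal(0.0, cfg.noise_sd, size=n), 0, None)
    is_pro = np.array([aa == "P" for aa in sequence])
    free_int = np.where(is_pro, np.nan, free_int)
    lipid_int = np.where(is_pro, np.nan, lipid_int)
    base = pd.DataFrame({"residue": residues, "aa": list(sequence)})
    free = base.assign(intensity=free_int)
    lipid = base.assign(intensity=lipid_int)
    gt = GroundTruth(true_boundary_residue=boundary_residue,
                     bound_free_fraction=bound_free_fraction,
                     unbound_free_fraction=unbound_free_fraction)
    return ResidueTable(lipid), ResidueTable(free), gt


# ---------------------------------------------------------------------------
# Densitometry blots
# ---------------------------------------------------------------------------

def gen_blot(
    standard_concs: Sequence[float] = STANDARD_CONCS,
    unknown_concs: Sequence[float] = (3.0, 6.0),
    slope: float = 120.0,
    loading_cv: float = 0.0,
    cfg: GenConfig = GenConfig(),
    background: float = 0.0,
    cell_equivalents: float = 1.875e5,
    loaded_volume_ml: float = 0.025,
    loading_bases: Sequence[float] = (500.0, 800.0, 1100.0),
) -> tuple:
    """Synthetic blot lanes: standards plus unknown cell-lysate lanes.

    Band density = background + slope * conc * L, where L is the per-lane
    loading factor (CV ``loading_cv`` around 1); the three nonspecific-band
    densities in each lane scale with the same L and encode it for the
    loading-control correction.  Unknown lanes carry the cell-equivalent
    count and loaded volume needed by the per-cell amount chain (defaults:
    25 ul/lane of lysate at 7.5e6 cell equivalents/ml).
    """
    rng = cfg.rng()
    rows = []
    factors = {}
    truths = {}

    def make_lane(lane_id, role, conc):
        L = max(0.5, 1.0 + loading_cv * rng.standard_normal())
        factors[lane_id] = L
        band = background + slope * conc * L
        loads = [b * L for b in loading_bases]
        if cfg.noise_sd > 0:
            band += cfg.noise_sd * rng.standard_normal()
            loads = [b + cfg.noise_sd * rng.standard_normal() for b in loads]
        row = {
            "lane": lane_id, "role": role,
            "band_density": max(0.0, band),
            "loading_1": max(0.0, loads[0]),
            "loading_2": max(0.0, loads[1]),
            "loading_3": max(0.0, loads[2]),
            "known_conc": conc if role == "standard" else np.nan,
            "cell_equivalents": cell_equivalents if role == "unknown" else np.nan,
            "loaded_volume_ml": loaded_volume_ml if role == "unknown" else np.nan,
        }
        rows.append(row)

    for k, conc in enumerate(standard_concs):
        make_lane(f"std{k + 1}", "standard", float(conc))
    for k, conc in enumerate(unknown_concs):
        lane = f"unk{k + 1}"
        make_lane(lane, "unknown", float(conc))
        truths[lane] = float(conc)
    table = DensitometryTable(pd.DataFrame(rows))
    gt = GroundTruth(true_lane_concentrations=truths, slope=slope,
                     loading_factors=factors)
    return table, gt


# ---------------------------------------------------------------------------
# FITC quench curves
# ---------------------------------------------------------------------------

def gen_quench_curve(
    quench_fraction: float = 0.5,
    rate: float = 0.005,
    cfg: GenConfig = GenConfig(),
    t_pre_s: float = 100.0,
    t_post_s: float = 1500.0,
    dt_s: float = 10.0,
) -> tuple:
    """Receptor-internalization quench curve normalized to 1 before
    stimulation: F(t) = 1 - q * (1 - exp(-rate * t)) for t >= 0.

    ~1500 s of post-stimulation sampling matches the duration of a typical
    flow-cytometry quench course.
    """
    if not 0.0 <= quench_fraction <= 1.0:
        raise ValueError("quench_fraction must lie in [0, 1]")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    times = np.arange(-t_pre_s, t_post_s + dt_s / 2, dt_s)
    values = np.ones_like(times)
    post = times >= 0
    values[post] = 1.0 - quench_fraction * (1.0 - np.exp(-rate * times[post]))
    if cfg.noise_sd > 0:
        values = values + cfg.rng().normal(0.0, cfg.noise_sd, size=values.shape)
    trace = TimeSeriesTrace(times, values, t_stim=0.0,
                            identifier=f"quench-seed{cfg.seed}")
    gt = GroundTruth(true_quench_fraction=quench_fraction, quench_rate=rate)
    return trace, gt
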