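"""Synthetic en-face angiograms and cohorts with known ground truth.

No public OCTA dataset accompanies the analysis this package implements, so
every downstream stage is exercised on synthetic scans: bright vessels drawn
by a biased branching random walk over a dark multiplicative-speckle
background, an avascular foveal zone carved at the center of macula scans
(ringed by a perivascular capillary margin so it is a bounded avascular
component, as in real maculas), and a bright avascular disc at the center of
ONH scans.  Per-region multiplicative density factors plant regional
deficits of known size, and the generator records the true vessel mask,
per-region true densities, and the planted FAZ polygon.

The walk model is deliberately simple — direction-persistent random walks
with binary branching and a 1-3 px disc brush — which is visually and
statistically adequate for testing thresholding, thinning and sector
statistics; it is not a physiological angiogenesis model, and the speckle is
a stand-in rather than a calibrated emulation of OCTA decorrelation noise.

Random-number coupling: every stochastic draw a walk makes (turns, branch
decisions, acceptance tests) is pre-drawn per walk from trajectories that do
not depend on the regional multipliers.  Two generations differing only in a
region's multiplier therefore share identical walk trajectories, and the
lower-multiplier run draws a strict subset of the vessel pixels — regional
true density is monotone in the multiplier at fixed seed by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ImageSpec, UndersaturatedError
from .etdrs import build_region_masks, center_grid, region_labels

#: converts a density-response (record-scale) target into the drawing's
#: mask-pixel-fraction target, which is referenced to the never-modified
#: territory outside the ETDRS sectors (the sectors themselves run denser)
MASK_SCALE = 0.5

_VESSEL_LEVEL = 0.85
_BACKGROUND_LEVEL = 0.05
_DISC_LEVEL = 0.90
_DISC_DIAMETER_MM = 1.0  # sits inside the ETDRS central circle, outside all regions
_BRUSH_RADII = (0.5, 1.0, 1.5)  # vessel widths 1-3 px


@dataclass(frozen=True)
class VesselSimConfig:
    """Knobs of the single-image vascular simulation.

    ``regional_multipliers`` maps an ETDRS region to a multiplicative factor
    on the probability that a walk step inside that region deposits vessel
    pixels (1.0 = unmodified); keys are either a quadrant name (applies to
    both rings) or a ``(quadrant, ring)`` tuple.  ``base_density`` is the
    target fraction of vessel pixels in unmodified territory.
    """

    n_seeds: int = 400
    branch_prob: float = 0.08
    step_px: float = 2.0
    base_density: float = 0.06
    regional_multipliers: dict = field(default_factory=dict)
    faz_area_mm2: float = 0.30
    faz_irregularity: float = 0.3
    noise_sd: float = 0.15
    width_probs: tuple = (0.55, 0.35, 0.10)  # root-vessel brush radii 0.5/1.0/1.5 px
    exact_seeds: bool = False  # grow exactly n_seeds trees, ignoring base_density
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError("base_density must lie in [0, 1]")
        if any(m < 0 for m in self.regional_multipliers.values()):
            raise ValueError("regional multipliers must be >= 0")
        if self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    vessel_mask: np.ndarray
    region_true_density: dict
    faz_polygon: np.ndarray | None = None


def _multiplier_image(spec: ImageSpec, cfg: VesselSimConfig) -> np.ndarray:
    mult = np.ones(spec.shape, dtype=np.float64)
    if not cfg.regional_multipliers:
        return mult
    masks = build_region_masks(spec, center_grid(spec))
    for key, m in cfg.regional_multipliers.items():
        if isinstance(key, str):
            targets = [lab for lab in masks if lab[0] == key]
            if not targets:
                raise KeyError(f"unknown quadrant {key!r}")
        else:
            if tuple(key) not in masks:
                raise KeyError(f"unknown region {key!r}")
            targets = [tuple(key)]
        for lab in targets:
            mult[masks[lab]] = m
    return mult


def _faz_polygon(spec: ImageSpec, cfg: VesselSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Closed star-shaped polygon of the planted FAZ, in pixel coordinates.

    Radius is modulated by low-order cosine harmonics scaled by
    ``faz_irregularity`` and then rescaled so the shoelace area matches
    ``faz_area_mm2`` exactly; irregularity changes shape, not size.
    """
    n_vert = 90
    theta = np.linspace(0.0, 2.0 * math.pi, n_vert, endpoint=False)
    modulation = np.zeros(n_vert)
    for h in (2, 3, 4, 5):
        amp = rng.normal(0.0, 0.12 / math.sqrt(h))
        phase = rng.uniform(0.0, 2.0 * math.pi)
        modulation += amp * np.cos(h * theta + phase)
    radius = 1.0 + cfg.faz_irregularity * modulation
    radius = np.maximum(radius, 0.15)
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    scale_mm = math.sqrt(cfg.faz_area_mm2 / area)
    scale_px = scale_mm / spec.mm_per_px
    cx, cy = spec.width_px / 2.0, spec.height_px / 2.0
    return np.column_stack([cx + scale_px * x, cy + scale_px * y])


def _polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon2mask

    # polygon2mask expects (row, col) vertices
    return polygon2mask(shape, np.column_stack([polygon[:, 1], polygon[:, 0]]))


def _brush_offsets() -> dict[float, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for r in _BRUSH_RADII:
        n = int(math.ceil(r))
        di, dj = np.mgrid[-n : n + 1, -n : n + 1]
        keep = di * di + dj * dj <= r * r + 1e-9
        out[r] = (di[keep], dj[keep])
    return out


_OFFSETS = _brush_offsets()


def _stamp_path(canvas: np.ndarray, pts_ij: np.ndarray, radius: float) -> None:
    """Stamp a disc brush of given radius at each (i, j) point, clipped."""
    h, w = canvas.shape
    di, dj = _OFFSETS[radius]
    ii = (pts_ij[:, 0][:, None] + di[None, :]).ravel()
    jj = (pts_ij[:, 1][:, None] + dj[None, :]).ravel()
    keep = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
    canvas[ii[keep], jj[keep]] = True


def _grow_tree(
    canvas: np.ndarray,
    mult: np.ndarray,
    spec: ImageSpec,
    cfg: VesselSimConfig,
    rng: np.random.Generator,
    root_xy: tuple[float, float],
    root_angle: float,
) -> None:
    """Grow one vessel tree (root walk plus branches) onto the canvas.

    All randomness is pre-drawn per walk so random-number consumption depends
    only on trajectories, never on the multiplier field.
    """
    h, w = spec.shape
    max_steps = int(2.5 * spec.width_px / cfg.step_px)
    max_depth = 6
    max_walks = 32  # caps tree size; branching is supercritical otherwise
    root_radius = rng.choice(_BRUSH_RADII, p=cfg.width_probs)
    queue = [(root_xy[0], root_xy[1], root_angle, float(root_radius), 0)]
    walks = 0
    while queue and walks < max_walks:
        walks += 1
        x, y, ang, radius, depth = queue.pop(0)
        turns = rng.normal(0.0, 0.35, max_steps)
        branch_u = rng.random(max_steps)
        branch_sides = rng.choice((-1.0, 1.0), max_steps)
        # acceptance is drawn per ~16-step segment, not per step: a rejected
        # segment removes a whole capillary stretch (rarefaction) instead of
        # dotting the vessel, so planted deficits survive skeletonization
        seg_len = 16
        accept_u = rng.random(max_steps // seg_len + 1)
        pts = []
        accepted = []
        for t in range(max_steps):
            px, py = x, y
            ang += turns[t]
            x += cfg.step_px * math.cos(ang)
            y += cfg.step_px * math.sin(ang)
            i, j = int(y), int(x)
            if not (0 <= i < h and 0 <= j < w):
                break
            ok = accept_u[t // seg_len] < min(1.0, mult[i, j])
            # stamp the mid-point too so steps longer than 1 px stay connected
            mi, mj = int((py + y) / 2.0), int((px + x) / 2.0)
            if 0 <= mi < h and 0 <= mj < w:
                pts.append((mi, mj))
                accepted.append(ok)
            pts.append((i, j))
            accepted.append(ok)
            if depth < max_depth and branch_u[t] < cfg.branch_prob:
                child_radius = _BRUSH_RADII[max(0, _BRUSH_RADII.index(radius) - 1)]
                queue.append((x, y, ang + branch_sides[t] * rng.uniform(0.5, 1.2),
                              child_radius, depth + 1))
        if pts:
            pts_arr = np.asarray(pts, dtype=np.intp)
            acc = np.asarray(accepted, dtype=bool)
            if acc.any():
                _stamp_path(canvas, pts_arr[acc], radius)


def generate_angiogram(spec: ImageSpec, cfg: VesselSimConfig):
    """Draw one synthetic en-face angiogram.

    Returns
    -------
    (image, ground_truth)
        ``image`` is an 8-bit grayscale array; ``ground_truth`` records the
        true vessel mask, the per-region vessel-pixel fractions, and, for
        macula scans, the planted FAZ outline polygon.

    Raises
    ------
    UndersaturatedError
        If the configured ``n_seeds`` root vessels cannot reach
        ``base_density`` in unmodified territory.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = spec.shape
    mult = _multiplier_image(spec, cfg)
    grid = center_grid(spec)
    cx, cy = grid.center_px

    faz_polygon = None
    forbidden = np.zeros(spec.shape, dtype=bool)
    if spec.center_type == "macula" and cfg.faz_area_mm2 > 0:
        faz_polygon = _faz_polygon(spec, cfg, rng)
        from scipy.ndimage import binary_dilation

        forbidden = binary_dilation(_polygon_mask(faz_polygon, spec.shape),
                                    structure=np.ones((3, 3), dtype=bool))
    elif spec.center_type == "onh":
        dx, dy = spec.pixel_centers_mm(grid.center_px)
        forbidden = np.hypot(dx, dy) <= _DISC_DIAMETER_MM / 2.0

    canvas = np.zeros(spec.shape, dtype=bool)
    # Density target is tracked over territory no regional multiplier can
    # touch (outside the ETDRS sectors), so the number of trees grown is
    # identical across multiplier settings and stays coupled at fixed seed.
    region_masks = build_region_masks(spec, grid)
    in_regions = np.zeros(spec.shape, dtype=bool)
    for m in region_masks.values():
        in_regions |= m
    unmod = ~in_regions & ~forbidden
    n_unmod = max(1, int(unmod.sum()))

    disc_margin_px = (_DISC_DIAMETER_MM / 2.0) / spec.mm_per_px + 2.0
    trees = 0
    while trees < cfg.n_seeds:
        if not cfg.exact_seeds and \
                np.count_nonzero(canvas & unmod) / n_unmod >= cfg.base_density:
            break
        if spec.center_type == "onh":
            a = rng.uniform(0.0, 2.0 * math.pi)
            root = (cx + disc_margin_px * math.cos(a), cy + disc_margin_px * math.sin(a))
            heading = a  # radially outward
        else:
            side = rng.integers(4)
            u = rng.uniform(0.0, 1.0)
            root, heading = {
                0: ((u * w, 0.0), math.pi / 2.0),   # top edge, growing down
                1: ((u * w, float(h)), -math.pi / 2.0),
                2: ((0.0, u * h), 0.0),              # left edge, growing right
                3: ((float(w), u * h), math.pi),
            }[int(side)]
            heading += rng.normal(0.0, 0.3)
        _grow_tree(canvas, mult, spec, cfg, rng, root, heading)
        trees += 1

    reached = np.count_nonzero(canvas & unmod) / n_unmod
    if (not cfg.exact_seeds and reached < cfg.base_density - 1e-12
            and trees >= cfg.n_seeds and cfg.base_density > 0):
        raise UndersaturatedError(
            f"undersaturated: reached density {reached:.3f} < {cfg.base_density} "
            f"with n_seeds={cfg.n_seeds}")

    canvas[forbidden] = False
    if faz_polygon is not None:
        # Perivascular capillary ring enclosing the zone, stamped on a path
        # pushed ~1.5 px radially outward so the margin survives the interior
        # carve and the avascular component stays bounded.
        center = np.array([cx, cy])
        v = faz_polygon - center
        ring_path = faz_polygon + 1.5 * v / np.linalg.norm(v, axis=1, keepdims=True)
        edges = np.vstack([ring_path, ring_path[:1]])
        seg = np.diff(edges, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        pts = []
        for k in range(len(seg)):
            n_sub = max(2, int(seg_len[k] / 0.5))
            frac = np.linspace(0.0, 1.0, n_sub, endpoint=False)
            pts.append(edges[k] + frac[:, None] * seg[k])
        ring_xy = np.vstack(pts)
        ring_ij = np.column_stack([ring_xy[:, 1], ring_xy[:, 0]]).astype(np.intp)
        inb = ((ring_ij[:, 0] >= 0) & (ring_ij[:, 0] < h)
               & (ring_ij[:, 1] >= 0) & (ring_ij[:, 1] < w))
        _stamp_path(canvas, ring_ij[inb], 1.0)
        # no vessel pixel may sit strictly inside the planted outline
        canvas[_polygon_mask(faz_polygon, spec.shape)] = False

    region_true_density = {lab: float(canvas[m].mean()) for lab, m in region_masks.items()}

    base = np.where(canvas, _VESSEL_LEVEL, _BACKGROUND_LEVEL)
    if spec.center_type == "onh":
        # bright disc with a linear taper at its rim: a hard edge would leave
        # a ring of spurious above-local-mean pixels under local thresholding
        dx, dy = spec.pixel_centers_mm(grid.center_px)
        r = np.hypot(dx, dy)
        r_disc = _DISC_DIAMETER_MM / 2.0
        taper_start = 0.5 * r_disc
        ramp = np.clip((r_disc - r) / (r_disc - taper_start), 0.0, 1.0)
        base = np.maximum(base, _DISC_LEVEL * ramp)
    if cfg.noise_sd > 0:
        log_noise = rng.normal(0.0, cfg.noise_sd, spec.shape)
        base = np.exp(np.log(np.maximum(base, 1e-6)) + log_noise)
    img = np.clip(np.round(np.clip(base, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    return img, GroundTruth(vessel_mask=canvas, region_true_density=region_true_density,
                            faz_polygon=faz_polygon)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """A two-group cohort with a planted temporal density deficit.

    ``temporal_deficit`` is the fractional reduction delta applied to the SSD
    group's temporal density (0.3 means SSD temporal density is 70% of the
    control value in expectation).  ``age_deficit_interaction``, if given as
    ``{"young": d1, "old": d2}``, replaces delta by an age-group-dependent
    value (young = age <= 30).  Group sizes, age distribution and the sex
    imbalance default to the cohort composition this pipeline is meant to
    emulate (39 controls vs 51 cases, ages ~N(35.7, 12.5) truncated to
    [18, 70], male fractions 17/39 vs 39/51).
    """

    n_control: int = 39
    n_ssd: int = 51
    temporal_deficit: float = 0.0
    base_density: float = 0.12
    age_mean: float = 35.7
    age_sd: float = 12.5
    age_range: tuple[float, float] = (18.0, 70.0)
    age_slope: float = -0.0004  # density decline per year, planted in controls & cases
    age_deficit_interaction: dict | None = None
    male_frac_control: float = 17 / 39
    male_frac_ssd: float = 39 / 51
    subject_sd: float = 0.02
    eye_sd: float = 0.01
    residual_sd: float = 0.02
    faz_area_sd: float = 0.08  # between-eye spread of planted FAZ area (mm^2)
    faz_area_ssd_scale: float = 1.0  # multiplies the SSD group's mean FAZ area
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temporal_deficit <= 1.0:
            raise ValueError("temporal_deficit must lie in [0, 1]")
        if min(self.subject_sd, self.eye_sd, self.residual_sd) < 0:
            raise ValueError("variance components must be >= 0")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _deficit_for_age(cfg: CohortSimConfig, age: float) -> float:
    if cfg.age_deficit_interaction is not None:
        return cfg.age_deficit_interaction["young" if age <= 30 else "old"]
    return cfg.temporal_deficit


def simulate_subjects(cfg: CohortSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level covariates: diagnosis, age, sex, random subject offset."""
    rows = []
    for grp, n, male_frac in (("control", cfg.n_control, cfg.male_frac_control),
                              ("ssd", cfg.n_ssd, cfg.male_frac_ssd)):
        ages = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, n)
        for i in range(n):
            rows.append({
                "subject": f"{grp[:1].upper()}{i + 1:03d}",
                "diagnosis": grp,
                "age": float(ages[i]),
                "sex": "M" if rng.random() < male_frac else "F",
                "subject_offset": float(rng.normal(0.0, cfg.subject_sd)),
            })
    return pd.DataFrame(rows)


def simulate_density_records(
    cfg: CohortSimConfig,
    site: str = "onh",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate long-format regional density records directly on the density scale.

    This bypasses image rendering: per-region densities are drawn from the
    planted linear model (group mean + age trend + subject and eye random
    intercepts + residual) with the SSD temporal deficit applied.  It is the
    workhorse for statistical calibration experiments, where thousands of
    model fits would make rendering angiograms prohibitive.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects = simulate_subjects(cfg, rng)
    labels = region_labels(site)
    clipped = 0
    rows = []
    for _, subj in subjects.iterrows():
        delta = _deficit_for_age(cfg, subj["age"])
        for eye in ("OD", "OS"):
            eye_off = rng.normal(0.0, cfg.eye_sd)
            for quadrant, ring in labels:
                mu = (cfg.base_density
                      + cfg.age_slope * (subj["age"] - cfg.age_mean)
                      + subj["subject_offset"] + eye_off)
                if subj["diagnosis"] == "ssd" and quadrant == "temporal":
                    mu -= delta * cfg.base_density
                d = mu + rng.normal(0.0, cfg.residual_sd)
                if d < 0.0 or d > 1.0:
                    clipped += 1
                    d = min(1.0, max(0.0, d))
                rows.append({"subject": subj["subject"], "eye": eye,
                             "diagnosis": subj["diagnosis"], "age": subj["age"],
                             "sex": subj["sex"], "site": site,
                             "quadrant": quadrant, "ring": ring, "density": d})
    if clipped:
        warnings.warn(f"{clipped} simulated densities fell outside [0, 1] and were clipped")
    return pd.DataFrame(rows)


def add_rnfl_column(
    records: pd.DataFrame,
    intercept: float = 90.0,
    slope: float = 200.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a synthetic per-quadrant RNFL thickness (microns), affine in density."""
    rng = np.random.default_rng(seed)
    out = records.copy()
    out["rnfl_thickness"] = (intercept + slope * out["density"].to_numpy()
                             + rng.normal(0.0, noise_sd, len(out)))
    return out


def generate_cohort(
    spec_macula: ImageSpec,
    spec_onh: ImageSpec,
    cfg: CohortSimConfig,
    vessel_cfg: VesselSimConfig | None = None,
):
    """Render per-eye macula + ONH angiogram pairs for a whole cohort.

    Returns ``(scans, cohort_table)`` where ``scans`` is a list of dicts
    (subject, eye, site, spec, image, ground_truth) and ``cohort_table`` has
    one row per eye per subject.  SSD eyes receive a temporal regional
    multiplier of ``1 - delta``; subject and eye random offsets perturb the
    drawing's base density (offsets are applied on the mask-density scale via
    the brush-width factor).  Densities pushed outside [0, 1] are clipped and
    flagged with a warning.
    """
    if cfg.n_control < 1 or cfg.n_ssd < 1:
        raise ValueError("need at least one subject per group")
    base_vcfg = vessel_cfg or VesselSimConfig()
    rng = np.random.default_rng(cfg.seed)
    subjects = simulate_subjects(cfg, rng)
    scans = []
    cohort_rows = []
    clipped = 0
    for _, subj in subjects.iterrows():
        delta = _deficit_for_age(cfg, subj["age"])
        for eye in ("OD", "OS"):
            eye_off = rng.normal(0.0, cfg.eye_sd)
            mask_density = MASK_SCALE * (cfg.base_density
                                         + cfg.age_slope * (subj["age"] - cfg.age_mean)
                                         + subj["subject_offset"] + eye_off)
            if mask_density < 0.0 or mask_density > 1.0:
                clipped += 1
                mask_density = min(1.0, max(0.0, mask_density))
            # the planted deficit is peripapillary only: macula scans of SSD
            # eyes are left unmodified, as in the condition being emulated
            onh_multipliers = dict(base_vcfg.regional_multipliers)
            if subj["diagnosis"] == "ssd":
                onh_multipliers["temporal"] = (
                    onh_multipliers.get("temporal", 1.0) * (1.0 - delta))
            faz_mean = base_vcfg.faz_area_mm2 * (
                cfg.faz_area_ssd_scale if subj["diagnosis"] == "ssd" else 1.0)
            eye_faz = max(0.05, float(rng.normal(faz_mean, cfg.faz_area_sd)))
            for site, spec in (("macula", spec_macula), ("onh", spec_onh)):
                eye_spec = replace(spec, laterality=eye)
                vcfg = replace(base_vcfg, base_density=mask_density,
                               regional_multipliers=(onh_multipliers if site == "onh"
                                                     else base_vcfg.regional_multipliers),
                               faz_area_mm2=eye_faz,
                               seed=int(rng.integers(2**31)))
                img, truth = generate_angiogram(eye_spec, vcfg)
                scans.append({"subject": subj["subject"], "eye": eye, "site": site,
                              "spec": eye_spec, "image": img, "ground_truth": truth})
            cohort_rows.append({"subject": subj["subject"], "eye": eye,
                                "diagnosis": subj["diagnosis"], "age": subj["age"],
                                "sex": subj["sex"]})
    if clipped:
        warnings.warn(f"{clipped} eye-level base densities fell outside [0, 1] and were clipped")
    return scans, pd.DataFrame(cohort_rows)
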