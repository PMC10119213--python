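"""Synthetic 3D spheroid-invasion image stacks with exported ground truth.

The generator emulates the specimen phenomenology of an invasive tumor
spheroid after several days of 3D collagen culture: a cell-dense residual
core, a compact concentric rim at the former spheroid–matrix interface,
and individually invading cells whose number density decays with radial
distance out to a configurable maximum. On top of the specimen it applies
a simple optics model — single-exponential depth attenuation
(Beer–Lambert, parameterised by an optical mean free path so that a small
``attenuation_length`` stands for an uncleared sample and a large one for
an optically cleared sample), an in-plane Gaussian PSF, a constant
background, Poisson shot noise and additive Gaussian read noise.

Every cell is recorded in a :class:`GroundTruth` table (position, zone,
state, apoptotic fragment layout), which makes the downstream segmentation
and event-detection stages testable by parameter recovery.

Reproducibility contract
------------------------
One RNG stream (``numpy.random.default_rng(seed)``) drives specimen
sampling, in this documented draw order:

1. one uniform per cell (cell order: core block, rim block, invading
   block) deciding the state — apoptotic if ``u < apoptotic_fraction``
   of the cell's zone, else mitotic if ``u < apoptotic + mitotic_fraction``,
   else normal;
2. core positions (per cell: 3 standard normals for the direction, one
   uniform for the radius);
3. rim positions (same pattern);
4. invading positions (one uniform for the truncated-exponential radius,
   3 normals for the direction);
5. nucleus diameters (one normal per cell);
6. per apoptotic cell: fragment count, fragment diameters, scatter
   positions and z-jitter.

Optics noise uses a derived seed ``seed + NOISE_SEED_OFFSET``; treatment
edits (cell kill, apoptotic conversion) use ``seed + TREATMENT_SEED_OFFSET``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import ImageStack, PixelCalibration

NOISE_SEED_OFFSET = 7919
TREATMENT_SEED_OFFSET = 104729

ZONES = ("core", "rim", "invasion")


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Scene + optics parameters of one simulated spheroid.

    Lengths are µm, intensities arbitrary units. Defaults describe a
    cleared day-7-like specimen imaged in central-slice mode; see
    :func:`preset` for the named variants.
    """

    core_radius: float = 100.0
    rim_thickness: float = 30.0
    max_invasion_distance: float = 400.0
    n_core: int = 400
    n_rim: int = 900
    n_invading: int = 300
    nucleus_diameter_mean: float = 12.0
    nucleus_diameter_sd: float = 1.5
    invasion_density_decay: float = 100.0
    apoptotic_fraction: dict = field(
        default_factory=lambda: {"core": 0.01, "rim": 0.01, "invasion": 0.01}
    )
    fragments_per_event_min: int = 4
    fragments_per_event_max: int = 7
    fragment_diameter_range: tuple = (2.2, 3.6)
    fragment_scatter_radius: float = 18.0
    fragment_min_spacing: float = 10.0
    mitotic_fraction: float = 0.02
    mitotic_intensity_gain: float = 2.5
    attenuation_length: float = 500.0
    background_level: float = 10.0
    gaussian_noise_sd: float = 2.0
    psf_sigma: float = 1.0
    nucleus_peak_intensity: float = 150.0
    fragment_intensity_factor: float = 0.95
    fragment_z_envelope_factor: float = 1.2
    shot_noise: bool = True
    image_shape: tuple = (3, 860, 860)
    slice_mode: str = "central"  # 'central' (slices about spheroid center) or 'full'
    calibration: PixelCalibration = field(
        default_factory=lambda: PixelCalibration(xy_size=1.0, z_step=10.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_radius", "rim_thickness", "max_invasion_distance",
                     "invasion_density_decay", "nucleus_diameter_mean",
                     "fragment_scatter_radius", "attenuation_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("n_core", "n_rim", "n_invading"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for zone in ZONES:
            f = self.apoptotic_fraction.get(zone, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"apoptotic_fraction[{zone}] outside [0,1]")
        if not 0.0 <= self.mitotic_fraction <= 1.0:
            raise ParameterError("mitotic_fraction outside [0,1]")
        if self.fragment_scatter_radius > 20.0:
            raise ParameterError("fragment_scatter_radius must be <= 20 µm "
                                 "(detector linking radius)")
        if not (2 <= self.fragments_per_event_min <= self.fragments_per_event_max):
            raise ParameterError("need 2 <= fragments_per_event_min <= max")
        if self.core_radius + self.rim_thickness >= self.max_invasion_distance:
            raise ParameterError(
                "core_radius + rim_thickness must be < max_invasion_distance")
        half_extent = min(self.image_shape[1], self.image_shape[2]) / 2 \
            * self.calibration.xy_size
        if self.max_invasion_distance > half_extent + 1e-9:
            raise ParameterError(
                f"max_invasion_distance {self.max_invasion_distance} µm exceeds "
                f"image half-extent {half_extent:.1f} µm")
        if self.slice_mode not in ("central", "full"):
            raise ParameterError("slice_mode must be 'central' or 'full'")

    # -- derived geometry ---------------------------------------------------

    @property
    def rim_outer_radius(self) -> float:
        return self.core_radius + self.rim_thickness

    @property
    def centroid_px(self) -> tuple[float, float]:
        _, h, w = self.image_shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    def slice_z_positions(self) -> np.ndarray:
        """z of each slice plane, µm, relative to the spheroid center."""
        n = self.image_shape[0]
        z_top = -self.rim_outer_radius
        if self.slice_mode == "central":
            return (np.arange(n) - (n - 1) / 2.0) * self.calibration.z_step
        return z_top + np.arange(n) * self.calibration.z_step

    @property
    def depth_offset(self) -> float:
        """Imaging depth of slice 0 below the upper spheroid border, µm."""
        z_top = -self.rim_outer_radius
        return float(self.slice_z_positions()[0] - z_top)

    def zone_of_radius(self, r: np.ndarray) -> np.ndarray:
        zone = np.where(r <= self.core_radius, "core",
                        np.where(r <= self.rim_outer_radius, "rim", "invasion"))
        return zone.astype(object)


@dataclass
class GroundTruth:
    """Per-cell and per-fragment truth of one simulated scene.

    ``cells`` columns: id, z_um/y_um/x_um (relative to the spheroid
    center), radius_um (3D), inplane_radius_um, row_px/col_px, zone,
    state, diameter_um, nearest_slice.
    ``fragments`` columns: event_id (= apoptotic cell id), frag_id,
    z_um/y_um/x_um, diameter_um, area_um2.
    """

    cells: pd.DataFrame
    fragments: pd.DataFrame
    attenuation_length: float
    seed: int

    def counts_by_zone(self) -> dict:
        return {z: int((self.cells["zone"] == z).sum()) for z in ZONES}

    def visible_cells(self, params: SimParams, max_dz_um: float) -> pd.DataFrame:
        """Cells whose center lies within ``max_dz_um`` of a slice plane."""
        z_planes = params.slice_z_positions()
        dz = np.abs(self.cells["z_um"].to_numpy()[:, None] - z_planes[None, :])
        return self.cells[dz.min(axis=1) <= max_dz_um]


# ---------------------------------------------------------------------------
# specimen sampling
# ---------------------------------------------------------------------------

def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def sample_truth(params: SimParams) -> GroundTruth:
    """Sample the specimen (no rendering) following the documented RNG order."""
    rng = np.random.default_rng(params.seed)
    n_total = params.n_core + params.n_rim + params.n_invading
    zones = np.array(["core"] * params.n_core + ["rim"] * params.n_rim
                     + ["invasion"] * params.n_invading, dtype=object)

    _check_packing(params)

    # 1. state uniforms
    u_state = rng.random(n_total)
    a = np.array([params.apoptotic_fraction.get(z, 0.0) for z in zones])
    state = np.where(u_state < a, "apoptotic",
                     np.where(u_state < a + params.mitotic_fraction,
                              "mitotic", "normal")).astype(object)

    # 2-4. positions
    pos = np.zeros((n_total, 3))  # (z, y, x) µm about spheroid center
    i0 = 0
    if params.n_core:
        d = _uniform_directions(rng, params.n_core)
        r = params.core_radius * rng.random(params.n_core) ** (1 / 3)
        pos[i0:i0 + params.n_core] = d * r[:, None]
        i0 += params.n_core
    if params.n_rim:
        d = _uniform_directions(rng, params.n_rim)
        r0, r1 = params.core_radius, params.rim_outer_radius
        u = rng.random(params.n_rim)
        r = (u * (r1**3 - r0**3) + r0**3) ** (1 / 3)
        pos[i0:i0 + params.n_rim] = d * r[:, None]
        i0 += params.n_rim
    if params.n_invading:
        u = rng.random(params.n_invading)
        r = _truncated_exp_radius(u, params)
        d = _uniform_directions(rng, params.n_invading)
        pos[i0:i0 + params.n_invading] = d * r[:, None]

    # 5. diameters
    diam = rng.normal(params.nucleus_diameter_mean, params.nucleus_diameter_sd,
                      n_total).clip(min=4.0)

    radius = np.linalg.norm(pos, axis=1)
    inplane = np.linalg.norm(pos[:, 1:], axis=1)
    cr, cc = params.centroid_px
    xy = params.calibration.xy_size
    z_planes = params.slice_z_positions()
    nearest = np.abs(pos[:, 0:1] - z_planes[None, :]).argmin(axis=1)

    cells = pd.DataFrame({
        "id": np.arange(n_total),
        "z_um": pos[:, 0], "y_um": pos[:, 1], "x_um": pos[:, 2],
        "radius_um": radius, "inplane_radius_um": inplane,
        "row_px": cr + pos[:, 1] / xy, "col_px": cc + pos[:, 2] / xy,
        "zone": zones, "state": state, "diameter_um": diam,
        "nearest_slice": nearest,
    })

    # 6. apoptotic fragment layouts
    fragments = _sample_fragments(rng, cells[cells["state"] == "apoptotic"], params)
    return GroundTruth(cells=cells, fragments=fragments,
                       attenuation_length=params.attenuation_length,
                       seed=params.seed)


def _truncated_exp_radius(u: np.ndarray, params: SimParams) -> np.ndarray:
    """Inverse-CDF sample of the invading-cell radial distance.

    The radius beyond the rim is exponential with scale
    ``invasion_density_decay``, truncated at ``max_invasion_distance``,
    so the histogram of radii follows exp(-d/decay).
    """
    r0, rmax = params.rim_outer_radius, params.max_invasion_distance
    tau = params.invasion_density_decay
    cmax = 1.0 - math.exp(-(rmax - r0) / tau)
    return r0 - tau * np.log1p(-u * cmax)


def _sample_fragments(rng: np.random.Generator, apoptotic: pd.DataFrame,
                      params: SimParams) -> pd.DataFrame:
    rows = []
    dmin, dmax = params.fragment_diameter_range
    for cell in apoptotic.itertuples():
        k = int(rng.integers(params.fragments_per_event_min,
                             params.fragments_per_event_max + 1))
        dia = rng.uniform(dmin, dmax, k)
        # uniform in a disc of the scatter radius, in-plane about the cell,
        # with a minimum spacing so fragments stay optically resolvable;
        # in z the fragment cloud keeps the envelope of the parent cell
        # (apoptotic bodies stay distributed through the rounded cell's
        # depth), so events and intact nuclei present comparable
        # z-visibility windows to the slice-wise detector
        placed: list[tuple[float, float]] = []
        for j in range(k):
            dy = dx = 0.0
            for _ in range(100):
                ang = rng.uniform(0, 2 * np.pi)
                rad = params.fragment_scatter_radius * math.sqrt(rng.random())
                dy, dx = rad * math.sin(ang), rad * math.cos(ang)
                if all(math.hypot(dy - py, dx - px) >= params.fragment_min_spacing
                       for py, px in placed):
                    break
            placed.append((dy, dx))
            rows.append({
                "event_id": cell.id, "frag_id": j,
                "z_um": cell.z_um,
                "y_um": cell.y_um + dy,
                "x_um": cell.x_um + dx,
                "diameter_um": dia[j],
                "area_um2": np.pi * (dia[j] / 2.0) ** 2,
                "z_envelope_um": cell.diameter_um * params.fragment_z_envelope_factor,
            })
    cols = ["event_id", "frag_id", "z_um", "y_um", "x_um",
            "diameter_um", "area_um2", "z_envelope_um"]
    return pd.DataFrame(rows, columns=cols)


def _check_packing(params: SimParams) -> None:
    vol_nucleus = (4 / 3) * np.pi * (params.nucleus_diameter_mean / 2) ** 3
    r0, r1, rmax = (params.core_radius, params.rim_outer_radius,
                    params.max_invasion_distance)
    zone_vol = {
        "core": (4 / 3) * np.pi * r0**3,
        "rim": (4 / 3) * np.pi * (r1**3 - r0**3),
        "invasion": (4 / 3) * np.pi * (rmax**3 - r1**3),
    }
    counts = {"core": params.n_core, "rim": params.n_rim,
              "invasion": params.n_invading}
    for zone in ZONES:
        if counts[zone] == 0:
            continue
        if zone_vol[zone] <= 0:
            raise ParameterError(f"cells requested in zone '{zone}' "
                                 "but zero volume available")
        packing = counts[zone] * vol_nucleus / zone_vol[zone]
        if packing > 0.9:
            raise ParameterError(
                f"packing fraction {packing:.2f} > 0.9 in zone '{zone}'")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# A nucleus of stated diameter d is a Gaussian blob whose half-maximum
# contour has diameter d: sigma = d / (2*sqrt(2 ln 2)).
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def render_clean(truth: GroundTruth, params: SimParams) -> ImageStack:
    """Render the noise-free specimen volume (no attenuation, no noise)."""
    n, h, w = params.image_shape
    vol = np.zeros((n, h, w), dtype=np.float64)
    z_planes = params.slice_z_positions()
    xy = params.calibration.xy_size

    for cell in truth.cells.itertuples():
        if cell.state == "apoptotic":
            continue  # rendered from its fragments below
        amp = params.nucleus_peak_intensity
        dia = cell.diameter_um
        elong = 1.0
        if cell.state == "mitotic":
            amp *= params.mitotic_intensity_gain
            dia *= 0.75  # condensed chromatin
        if cell.zone == "invasion":
            elong = 1.4  # radial polarization of migrating cells
        theta = math.atan2(cell.y_um, cell.x_um)
        _add_blob(vol, z_planes, xy, cell.z_um, cell.row_px, cell.col_px,
                  dia, amp, elong, theta)

    cr, cc = params.centroid_px
    for frag in truth.fragments.itertuples():
        _add_blob(vol, z_planes, xy, frag.z_um,
                  cr + frag.y_um / xy, cc + frag.x_um / xy,
                  frag.diameter_um,
                  params.nucleus_peak_intensity * params.fragment_intensity_factor,
                  1.0, 0.0, sigma_z_um=frag.z_envelope_um / _FWHM)

    return ImageStack(voxels=vol, calibration=params.calibration,
                      depth_offset=params.depth_offset)


def _add_blob(vol: np.ndarray, z_planes: np.ndarray, xy: float,
              z_um: float, row_px: float, col_px: float,
              diameter_um: float, amplitude: float,
              elongation: float, theta: float,
              sigma_z_um: float | None = None) -> None:
    n, h, w = vol.shape
    sigma_um = diameter_um / _FWHM
    sig_z = sigma_um if sigma_z_um is None else sigma_z_um
    sig_long = sigma_um * elongation / xy
    sig_short = sigma_um / max(elongation, 1.0) ** 0.5 / xy
    pr = int(math.ceil(3.0 * max(sig_long, sig_short))) + 1
    r0 = max(int(math.floor(row_px)) - pr, 0)
    r1 = min(int(math.ceil(row_px)) + pr + 1, h)
    c0 = max(int(math.floor(col_px)) - pr, 0)
    c1 = min(int(math.ceil(col_px)) + pr + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None] - row_px
    cols = np.arange(c0, c1)[None, :] - col_px
    ct, st = math.cos(theta), math.sin(theta)
    # in (row, col): y ~ rows, x ~ cols; long axis along (sin θ, cos θ)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    patch = np.exp(-0.5 * ((u / sig_long) ** 2 + (v / sig_short) ** 2))
    for i in range(n):
        wz = math.exp(-0.5 * ((z_planes[i] - z_um) / sig_z) ** 2)
        if wz < 0.01:
            continue
        vol[i, r0:r1, c0:c1] += amplitude * wz * patch


def apply_optics(clean_stack: ImageStack, attenuation_length: float,
                 background_level: float, gaussian_noise_sd: float,
                 psf_sigma: float, seed: int, *,
                 shot_noise: bool = True) -> ImageStack:
    """Apply the optics model to a noise-free stack.

    Per-slice attenuation ``exp(-depth/attenuation_length)`` with
    ``depth = depth_offset + index * z_step``, then in-plane Gaussian PSF
    blur, then background plus Poisson shot noise (on signal + background)
    plus additive Gaussian read noise. ``attenuation_length = inf`` and
    zero noise reduce to ``input + background``. Pure function of inputs
    and seed.
    """
    from scipy.ndimage import gaussian_filter

    if not attenuation_length > 0:
        raise ParameterError("attenuation_length must be > 0 (use inf to disable)")
    rng = np.random.default_rng(seed)
    cal = clean_stack.calibration
    out = clean_stack.voxels.astype(np.float64).copy()
    for i in range(clean_stack.n_slices):
        depth = clean_stack.slice_depth(i)
        if np.isfinite(attenuation_length):
            out[i] *= math.exp(-depth / attenuation_length)
        if psf_sigma > 0:
            out[i] = gaussian_filter(out[i], psf_sigma / cal.xy_size,
                                     mode="reflect")
    out += background_level
    if shot_noise:
        out = rng.poisson(np.maximum(out, 0)).astype(np.float64)
    if gaussian_noise_sd > 0:
        out += rng.normal(0.0, gaussian_noise_sd, out.shape)
    np.maximum(out, 0, out=out)
    return ImageStack(voxels=out, calibration=cal,
                      depth_offset=clean_stack.depth_offset)


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------

def simulate_spheroid(params: SimParams) -> tuple[ImageStack, GroundTruth]:
    """Sample a specimen and image it through the optics model."""
    truth = sample_truth(params)
    clean = render_clean(truth, params)
    stack = apply_optics(clean, params.attenuation_length,
                         params.background_level, params.gaussian_noise_sd,
                         params.psf_sigma, params.seed + NOISE_SEED_OFFSET,
                         shot_noise=params.shot_noise)
    return stack, truth


def simulate_treatment_pair(params: SimParams, invasion_kill_fraction: float,
                            invasion_distance_reduction: float,
                            extra_apoptotic_fraction: float,
                            ) -> tuple[tuple[ImageStack, GroundTruth],
                                       tuple[ImageStack, GroundTruth]]:
    """Simulate a sham-treated control and a treated sibling scene.

    The treated scene starts from the identical specimen, then (with RNG
    ``default_rng(seed + TREATMENT_SEED_OFFSET)``, draws in this order)
    (1) removes each invading cell independently with probability
    ``invasion_kill_fraction``, (2) removes invading cells beyond
    ``max_invasion_distance - invasion_distance_reduction``, and
    (3) converts each surviving normal invading cell to apoptotic with
    probability ``extra_apoptotic_fraction``. Core and rim populations are
    untouched, matching the observation that the treatment affects only
    the invasion zone.
    """
    for name, f in (("invasion_kill_fraction", invasion_kill_fraction),
                    ("extra_apoptotic_fraction", extra_apoptotic_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{name} outside [0,1]")
    if not 0.0 <= invasion_distance_reduction < params.max_invasion_distance:
        raise ParameterError("invasion_distance_reduction outside geometric bounds")

    control_truth = sample_truth(params)
    control_clean = render_clean(control_truth, params)
    control_stack = apply_optics(
        control_clean, params.attenuation_length, params.background_level,
        params.gaussian_noise_sd, params.psf_sigma,
        params.seed + NOISE_SEED_OFFSET, shot_noise=params.shot_noise)

    rng = np.random.default_rng(params.seed + TREATMENT_SEED_OFFSET)
    cells = control_truth.cells.copy()
    inv_mask = (cells["zone"] == "invasion").to_numpy()

    u_kill = rng.random(int(inv_mask.sum()))
    survive = np.ones(len(cells), dtype=bool)
    survive[inv_mask] = u_kill >= invasion_kill_fraction

    max_r = params.max_invasion_distance - invasion_distance_reduction
    survive &= ~(inv_mask & (cells["radius_um"].to_numpy() > max_r))

    cells = cells[survive].reset_index(drop=True)
    conv_candidates = ((cells["zone"] == "invasion")
                       & (cells["state"] == "normal")).to_numpy()
    u_conv = rng.random(int(conv_candidates.sum()))
    converted = np.zeros(len(cells), dtype=bool)
    converted[conv_candidates] = u_conv < extra_apoptotic_fraction
    cells.loc[converted, "state"] = "apoptotic"

    frags = control_truth.fragments
    frags = frags[frags["event_id"].isin(cells.loc[cells["state"] == "apoptotic", "id"])]
    new_frags = _sample_fragments(rng, cells[converted], params)
    nonempty = [f for f in (frags, new_frags) if len(f)]
    if nonempty:
        frags = pd.concat(nonempty, ignore_index=True)

    treated_truth = GroundTruth(cells=cells, fragments=frags,
                                attenuation_length=params.attenuation_length,
                                seed=params.seed)
    treated_clean = render_clean(treated_truth, params)
    treated_stack = apply_optics(
        treated_clean, params.attenuation_length, params.background_level,
        params.gaussian_noise_sd, params.psf_sigma,
        params.seed + TREATMENT_SEED_OFFSET + NOISE_SEED_OFFSET,
        shot_noise=params.shot_noise)
    return (control_stack, control_truth), (treated_stack, treated_truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

TREATMENT_DEFAULTS = {
    "invasion_kill_fraction": 0.5,
    "invasion_distance_reduction": 100.0,
    "extra_apoptotic_fraction": 0.07,
}


def preset(name: str, seed: int = 0) -> SimParams:
    """Named study conditions.

    - ``control``: cleared central-slice scene (3 slices, 10 µm apart).
    - ``irradiated``: same scene; pair it with
      :func:`simulate_treatment_pair` and :data:`TREATMENT_DEFAULTS`.
    - ``uncleared`` / ``cleared``: full-stack scenes (6 µm steps from the
      upper spheroid border) differing only in attenuation length
      (25 µm vs 500 µm) for SNR-depth profiling.
    """
    base = SimParams(seed=seed)
    snr = replace(
        base,
        core_radius=90.0, rim_thickness=25.0, max_invasion_distance=125.0,
        n_core=300, n_rim=650, n_invading=0,
        image_shape=(40, 256, 256), slice_mode="full",
        calibration=PixelCalibration(xy_size=1.0, z_step=6.0),
        seed=seed,
    )
    table = {
        "control": base,
        "irradiated": base,
        "uncleared": replace(snr, attenuation_length=25.0),
        "cleared": replace(snr, attenuation_length=500.0),
    }
    if name not in table:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(table)}")
    return table[name]
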