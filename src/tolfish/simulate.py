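"""Synthetic multi-channel micrograph generator with full ground truth.

Emulates the imaging conditions of single-cell FISH on *P. putida*:
rod-shaped (spherocylindrical) cells on a dark field; a DAPI channel whose
nucleoid is a smoothed, optionally two-lobed density occupying ~60% of the
cell length (plus a faint contribution at plasmid positions, since DAPI
binds plasmid DNA too); a red mRNA channel with 1–2 diffraction-limited
foci per induced cell, placed by a three-zone mixture over the nucleoid
(dense / peripheral / nucleoid-free); and a green plasmid channel with 1–2
foci per cell.  Red foci can be colocalized with, adjacent to, or
independent of a plasmid focus.  Rifampin-treated conditions render the
red signal as a dispersed low-spatial-frequency field instead of foci.

Which signals appear in which condition is decided by
:func:`tolfish.logic.expressed_transcripts`; every focus carries its true
subpixel position, zone label (validated against the same contour
classifier the analysis uses, on the noiseless DAPI density) and pairing
label, so the whole pipeline is testable without real micrographs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc, segment
from .logic import Condition, ExpressionState, Genotype, Level, expressed_transcripts

log = logging.getLogger(__name__)

CHANNELS = ("phase", "dapi", "red", "green")
ZONES = ("DENSE", "PERIPHERAL", "FREE")
PAIRINGS = ("COLOCALIZED", "ADJACENT", "INDEPENDENT")


@dataclass
class SimParams:
    """Everything the generator needs; defaults emulate the study conditions.

    Lengths are in µm where flagged, otherwise pixels.  Amplitudes and
    backgrounds are 16-bit camera counts.
    """

    field_shape: tuple = (512, 512)
    pixel_size_um: float = 0.065
    n_cells: int = 25
    cell_length_um: tuple = (2.0, 4.0)
    cell_width_um: tuple = (0.8, 1.0)

    # nucleoid model
    nucleoid_length_frac: float = 0.6     # fraction of cell length occupied
    two_lobe_prob: float = 0.5
    l_dense: float = 0.5                  # truth thresholds on per-cell
    l_diffuse: float = 0.2                # normalized noiseless density

    # mRNA (red) foci
    target: str = "xylUW"                 # transcript the red probe set reads
    zone_weights: tuple = (0.01, 0.15, 0.84)   # dense, peripheral, free
    mean_mrna_foci: float = 1.4           # per induced cell (HIGH)
    t7_mean_mrna_foci: float = 3.0        # T7-driven HIGH condition
    paw140_foci_multiplier: float = 1.3   # chromosomal-strain boost
    low_level_factor: float = 0.5         # LOW: halves count mean and amplitude
    min_focus_separation: float = 5.0     # px, same-channel foci within a cell

    # plasmid (green) foci
    plasmid_tagged: bool = True
    plasmid_count_probs: tuple = (0.7, 0.3)     # P(1 focus), P(2 foci)
    plasmid_placement: tuple = (0.6, 0.4)       # nucleoid-associated, peripheral
    pairing_mix: tuple = (0.3, 0.5, 0.2)        # colocalized, adjacent, independent
    adjacency_offset_px: float = 5.0
    independent_min_dist_px: float = 9.0        # independent mRNA keeps clear of plasmids

    # optics / camera
    psf_sigma: float = 1.3                # px
    mrna_amplitude: float = 600.0
    plasmid_amplitude: float = 500.0
    dapi_peak: float = 4000.0     # nucleoid staining is the brightest channel
    dapi_plasmid_frac: float = 0.05
    background: float = 200.0             # fluorescence channels
    phase_background: float = 1000.0
    phase_cell_depth: float = 400.0
    photon_scale: float = 1.0
    read_sigma: float = 10.0
    depth_max: int = 65535

    # dispersion (rifampin) mode
    dispersed_heterogeneity: float = 0.5
    dispersed_intensity_cv: float = 0.5   # cell-to-cell lognormal variability

    max_place_retries: int = 1000

    def __post_init__(self):
        w = np.asarray(self.zone_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("zone weights must be nonnegative and sum to 1")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if abs(sum(self.pairing_mix) - 1.0) > 1e-9:
            raise ValueError("pairing mix must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class ImageStack:
    """Registered multi-channel raster with pixel metadata."""

    channels: dict                 # name -> 2-D uint16/float array, same shape
    pixel_size_um: float = 0.065

    def __post_init__(self):
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for name, arr in self.channels.items():
            if np.asarray(arr).min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass
class CellTruth:
    cell_id: int
    center: tuple                  # (x, y) px
    orientation: float             # radians
    length_px: float
    width_px: float


@dataclass
class FocusTruth:
    cell_id: int
    channel: str                   # "red" or "green"
    x: float
    y: float
    zone: str                      # DENSE / PERIPHERAL / FREE
    pair_label: str                # COLOCALIZED / ADJACENT / INDEPENDENT / NA
    amplitude: float


@dataclass
class FieldTruth:
    """Ground truth for one generated field."""

    cells: list = field(default_factory=list)      # list[CellTruth]
    foci: list = field(default_factory=list)       # list[FocusTruth]
    labels: np.ndarray | None = None               # labeled cell mask
    condition: Condition | None = None
    state: ExpressionState | None = None
    seed: int | None = None

    def foci_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": f.cell_id,
                    "channel": f.channel,
                    "x": f.x,
                    "y": f.y,
                    "zone": f.zone,
                    "pair_label": f.pair_label,
                    "amplitude": f.amplitude,
                }
                for f in self.foci
            ],
            columns=["cell_id", "channel", "x", "y", "zone", "pair_label", "amplitude"],
        )

    def cells_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "x": c.center[0],
                    "y": c.center[1],
                    "orientation": c.orientation,
                    "length_px": c.length_px,
                    "width_px": c.width_px,
                }
                for c in self.cells
            ],
            columns=["cell_id", "x", "y", "orientation", "length_px", "width_px"],
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _capsule_mask(shape, center, theta, length, width):
    """Boolean mask of a 2-D spherocylinder (capsule), vectorized."""
    h, w = shape
    half = max(length / 2 + width, 8)
    cx, cy = center
    x0, x1 = max(int(cx - half), 0), min(int(cx + half) + 1, w)
    y0, y1 = max(int(cy - half), 0), min(int(cy + half) + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    ux, uy = np.cos(theta), np.sin(theta)
    # distance to the axis segment of half-length (length - width)/2
    s = dx * ux + dy * uy
    s = np.clip(s, -(length - width) / 2, (length - width) / 2)
    d2 = (dx - s * ux) ** 2 + (dy - s * uy) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = d2 <= (width / 2) ** 2
    return mask


def _segments_clear(poses, cand, margin=2.0):
    """True if the candidate capsule overlaps none of the placed ones."""
    from shapely.geometry import LineString, Point

    def axis(p):
        cx, cy, th, L, W = p
        hx, hy = np.cos(th) * (L - W) / 2, np.sin(th) * (L - W) / 2
        if (L - W) / 2 < 0.5:
            return Point(cx, cy), W
        return LineString([(cx - hx, cy - hy), (cx + hx, cy + hy)]), W

    ac, wc = axis(cand)
    for p in poses:
        ap, wp = axis(p)
        if ac.distance(ap) < (wc + wp) / 2 + margin:
            return False
    return True


class _CellGeom:
    """Per-cell noiseless geometry: masks, normalized density, zone machinery."""

    def __init__(self, cell_id, pose, shape, params, rng):
        self.cell_id = cell_id
        cx, cy, theta, L, W = pose
        self.pose = pose
        self.mask = _capsule_mask(shape, (cx, cy), theta, L, W)
        self.region = segment.CellRegion.from_labeled(
            self.mask.astype(int) * cell_id, cell_id
        )
        self.density = self._nucleoid_density(shape, params, rng)
        # per-cell min-max normalized noiseless density
        vals = self.density[self.mask]
        lo, hi = vals.min(), vals.max()
        self.norm_density = np.zeros(shape)
        if hi > lo:
            self.norm_density[self.mask] = (vals - lo) / (hi - lo)
        self.zones = segment.nucleoid_zones(
            np.where(self.mask, self.norm_density, np.nan),
            self.region,
            params.l_dense,
            params.l_diffuse,
        )
        norm = self.norm_density
        # foci are placed >= 2 px inside the membrane: a spot centered on the
        # boundary would bleed its PSF tail into neighboring cells
        from scipy import ndimage as ndi

        interior = ndi.binary_erosion(self.mask, iterations=2)
        if not interior.any():
            interior = self.mask
        self.zone_pixels = {
            "DENSE": np.argwhere(interior & (norm >= params.l_dense)),
            "PERIPHERAL": np.argwhere(
                interior & (norm >= params.l_diffuse) & (norm < params.l_dense)
            ),
            "FREE": np.argwhere(interior & (norm < params.l_diffuse)),
        }
        self.interior = interior

    def _nucleoid_density(self, shape, params, rng):
        cx, cy, theta, L, W = self.pose
        ux, uy = np.cos(theta), np.sin(theta)
        nuc_len = params.nucleoid_length_frac * L
        two_lobes = rng.random() < params.two_lobe_prob
        if two_lobes:
            offsets = (-nuc_len / 4, nuc_len / 4)
            sig_long = nuc_len / 6
        else:
            offsets = (0.0,)
            sig_long = nuc_len / 4
        sig_short = W / 4.5
        h, w = shape
        half = L / 2 + W
        x0, x1 = max(int(cx - half), 0), min(int(cx + half) + 1, w)
        y0, y1 = max(int(cy - half), 0), min(int(cy + half) + 1, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx, dy = xs - cx, ys - cy
        s = dx * ux + dy * uy       # along-axis coordinate
        t = -dx * uy + dy * ux      # across-axis coordinate
        dens = np.zeros((y1 - y0, x1 - x0))
        for off in offsets:
            dens += np.exp(-((s - off) ** 2) / (2 * sig_long**2) - t**2 / (2 * sig_short**2))
        out = np.zeros(shape)
        out[y0:y1, x0:x1] = dens
        out[~self.mask] = 0.0
        return out

    def classify(self, x, y):
        return coloc.classify_focus_zone(_Pt(x, y), self.zones).value.replace(
            "NUCLEOID_OVERLAP", "DENSE"
        ).replace("NUCLEOID_FREE", "FREE")


class _Pt:
    def __init__(self, x, y):
        self.x, self.y = x, y


# ---------------------------------------------------------------------------
# primitive renderers


def render_spot(raster, position, amplitude, psf_sigma):
    """Add an isotropic Gaussian focus to ``raster`` in place (and return it).

    The discrete sum of added intensity equals amplitude * 2*pi*sigma^2 to
    well within 1% for sigma >= 1 px (window truncated at 6 sigma).
    """
    if amplitude == 0:
        return raster
    x, y = position
    h, w = raster.shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"spot position {position} outside raster")
    r = int(np.ceil(6 * psf_sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    raster[y0:y1, x0:x1] += amplitude * np.exp(
        -((xs - x) ** 2 + (ys - y) ** 2) / (2 * psf_sigma**2)
    )
    return raster


def render_dispersed(raster, cell_mask, total_intensity, heterogeneity, rng):
    """Spread ``total_intensity`` over a cell as a smooth random field.

    ``heterogeneity`` in [0, 1] mixes a uniform fill (0) with a positive
    low-spatial-frequency random field (1).  The in-cell sum is exactly
    ``total_intensity`` (before noise).
    """
    from scipy import ndimage as ndi

    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must lie in [0, 1]")
    npx = int(cell_mask.sum())
    if npx == 0:
        return raster
    rows, cols = np.nonzero(cell_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = cell_mask[r0:r1, c0:c1]
    if heterogeneity > 0:
        noise = rng.standard_normal(sub.shape)
        smooth = ndi.gaussian_filter(noise, sigma=3.0)
        smooth -= smooth[sub].min()
        mean = smooth[sub].mean()
        g = smooth / mean if mean > 0 else np.ones_like(smooth)
        weights = (1.0 - heterogeneity) + heterogeneity * g
    else:
        weights = np.ones(sub.shape)
    weights = np.where(sub, weights, 0.0)
    weights *= total_intensity / weights.sum()
    raster[r0:r1, c0:c1] += weights
    return raster


def apply_noise(stack: ImageStack, photon_scale, read_sigma, rng, depth_max=65535):
    """Shot noise (Poisson at mean pixel*photon_scale, rescaled) plus Gaussian
    read noise, clipped to [0, depth_max]; returns a new uint16 stack."""
    out = {}
    for name, img in stack.channels.items():
        arr = np.asarray(img, dtype=float)
        if np.isfinite(photon_scale):
            shot = rng.poisson(np.clip(arr, 0, None) * photon_scale) / photon_scale
        else:
            shot = arr
        noisy = shot + (rng.normal(0.0, read_sigma, arr.shape) if read_sigma > 0 else 0.0)
        out[name] = np.clip(np.round(noisy), 0, depth_max).astype(np.uint16)
    return ImageStack(channels=out, pixel_size_um=stack.pixel_size_um)


# ---------------------------------------------------------------------------
# focus placement


def sample_focus_position(geom: _CellGeom, w, rng, max_tries: int = 100, exclude=None):
    """Draw a focus position by the three-zone mixture.

    The zone is chosen categorically by ``w`` = (dense, peripheral, free);
    the position is a uniformly chosen pixel of that zone plus sub-pixel
    jitter, accepted only when the contour classifier run on the noiseless
    density agrees with the requested zone (so truth labels are exact).
    An empty requested zone triggers a warning and a resample among the
    nonempty zones.

    ``exclude`` is an optional predicate on (x, y) that rejects a candidate
    position.  Crucially, the zone is drawn once and only the position is
    resampled on rejection: redrawing the zone after a placement-constraint
    failure would re-weight the mixture toward zones with more room (the
    small nucleoid-free polar caps lose draws to the peripheral shell),
    biasing the realized zone fractions away from ``w``.  Returns
    ``(None, None)`` if no position in the zone satisfies ``exclude``
    within the retry budget.
    """
    w = np.asarray(w, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("zone weights must sum to 1")
    zone = ZONES[rng.choice(3, p=w)]
    if len(geom.zone_pixels[zone]) == 0:
        warnings.warn(f"cell {geom.cell_id}: zone {zone} empty, resampling another zone")
        avail = [z for z in ZONES if len(geom.zone_pixels[z]) > 0]
        probs = np.array([w[ZONES.index(z)] for z in avail])
        probs = probs / probs.sum() if probs.sum() > 0 else np.full(len(avail), 1 / len(avail))
        zone = avail[rng.choice(len(avail), p=probs)]
    px = geom.zone_pixels[zone]
    fallback = None
    for _ in range(max_tries):
        r, c = px[rng.integers(len(px))]
        x = c + rng.uniform(-0.5, 0.5)
        y = r + rng.uniform(-0.5, 0.5)
        if exclude is not None and exclude((x, y)):
            continue
        if geom.classify(x, y) == zone:
            return (x, y), zone
        if fallback is None:
            fallback = ((x, y), geom.classify(x, y))
    if fallback is not None:
        # boundary pixel that never verifies: fall back to the classified label
        return fallback
    return None, None


def _poisson_count(rng, mean):
    return int(rng.poisson(mean))


# ---------------------------------------------------------------------------
# field generation


def generate_field(params: SimParams, cond: Condition, seed: int):
    """Generate one synthetic field: (ImageStack, FieldTruth).

    Deterministic for fixed (params, cond, seed).  Channel content follows
    the regulatory logic for the condition: the red channel carries the
    transcript named by ``params.target`` at its condition level (foci, or
    a dispersed field under rifampin), green carries plasmid foci when the
    plasmid is tetO-tagged, and DAPI carries the nucleoid plus a faint
    plasmid contribution.
    """
    rng = np.random.default_rng(seed)
    state = expressed_transcripts(cond)
    shape = tuple(params.field_shape)
    px = params.pixel_size_um

    # --- place cells -------------------------------------------------------
    poses = []
    margin = params.cell_length_um[1] / px / 2 + 4
    for i in range(params.n_cells):
        ok = False
        for _ in range(params.max_place_retries):
            L = rng.uniform(*params.cell_length_um) / px
            W = rng.uniform(*params.cell_width_um) / px
            cx = rng.uniform(margin, shape[1] - margin)
            cy = rng.uniform(margin, shape[0] - margin)
            theta = rng.uniform(0, np.pi)
            cand = (cx, cy, theta, L, W)
            if _segments_clear(poses, cand):
                poses.append(cand)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cell {i + 1}/{params.n_cells} within the "
                f"retry budget of {params.max_place_retries}; enlarge the field "
                "or reduce n_cells"
            )

    geoms = [
        _CellGeom(i + 1, pose, shape, params, rng) for i, pose in enumerate(poses)
    ]

    truth = FieldTruth(condition=cond, state=state, seed=seed)
    labels = np.zeros(shape, dtype=np.int32)
    for g in geoms:
        labels[g.mask] = g.cell_id
        cx, cy, theta, L, W = g.pose
        truth.cells.append(
            CellTruth(g.cell_id, (cx, cy), theta, L, W)
        )
    truth.labels = labels

    # --- channel scaffolds -------------------------------------------------
    dapi = np.full(shape, params.background)
    red = np.full(shape, params.background)
    green = np.full(shape, params.background)
    from scipy import ndimage as ndi

    allmask = labels > 0
    phase = params.phase_background - params.phase_cell_depth * ndi.gaussian_filter(
        allmask.astype(float), 1.0
    )

    # --- per-cell signal content ------------------------------------------
    red_level = state.levels.get(params.target, Level.OFF)
    mean_foci = params.mean_mrna_foci
    if cond.genotype == Genotype.PUXT7_IN_T7_HOST and cond.iptg and params.target == "xylUW":
        mean_foci = params.t7_mean_mrna_foci
    if cond.genotype == Genotype.PAW140_CHROMOSOMAL:
        mean_foci *= params.paw140_foci_multiplier
    amp = params.mrna_amplitude
    if red_level == Level.LOW:
        mean_foci *= params.low_level_factor
        amp *= params.low_level_factor

    for g in geoms:
        dapi[g.mask] += params.dapi_peak * g.norm_density[g.mask]

        # plasmid foci (green)
        green_pos = []
        if params.plasmid_tagged:
            n_pl = 1 + int(rng.random() < params.plasmid_count_probs[1])
            for _ in range(n_pl):
                assoc = rng.random() < params.plasmid_placement[0]
                wts = (0.2, 0.8, 0.0) if assoc else (0.0, 0.0, 1.0)
                pos, zone = sample_focus_position(
                    g,
                    wts,
                    rng,
                    exclude=lambda q: _too_close(q, green_pos, params.min_focus_separation),
                )
                if pos is None:  # cramped cell: keep the zone draw honest anyway
                    pos, zone = sample_focus_position(g, wts, rng)
                green_pos.append(pos)
                render_spot(green, pos, params.plasmid_amplitude * rng.uniform(0.7, 1.3), params.psf_sigma)
                # DAPI stains plasmid DNA faintly
                render_spot(dapi, pos, params.dapi_plasmid_frac * params.dapi_peak, params.psf_sigma)
                truth.foci.append(
                    FocusTruth(g.cell_id, "green", pos[0], pos[1], zone, "NA", params.plasmid_amplitude)
                )

        # mRNA signal (red)
        if red_level == Level.OFF:
            continue
        if not state.focal:
            # rifampin: dispersed field, intensity ~ the focal photon budget
            budget = mean_foci * amp * 2 * np.pi * params.psf_sigma**2
            cv = params.dispersed_intensity_cv
            factor = rng.lognormal(-0.5 * np.log(1 + cv**2), np.sqrt(np.log(1 + cv**2)))
            render_dispersed(red, g.mask, budget * factor, params.dispersed_heterogeneity, rng)
            continue
        n_red = _poisson_count(rng, mean_foci)
        red_pos = []
        free_greens = list(range(len(green_pos)))
        for _ in range(n_red):
            pair = PAIRINGS[rng.choice(3, p=np.asarray(params.pairing_mix))] if free_greens else "INDEPENDENT"
            pos, zone, pair, used = _place_red(g, pair, green_pos, free_greens, red_pos, params, rng)
            if pos is None:
                continue
            if used is not None:
                free_greens.remove(used)
            red_pos.append(pos)
            render_spot(red, pos, amp * rng.uniform(0.7, 1.3), params.psf_sigma)
            truth.foci.append(FocusTruth(g.cell_id, "red", pos[0], pos[1], zone, pair, amp))

    stack = ImageStack(
        channels={"phase": phase, "dapi": dapi, "red": red, "green": green},
        pixel_size_um=px,
    )
    stack = apply_noise(stack, params.photon_scale, params.read_sigma, rng, params.depth_max)
    return stack, truth


def _too_close(pos, others, sep):
    return any(np.hypot(pos[0] - o[0], pos[1] - o[1]) < sep for o in others)



def _place_red(geom, pair, green_pos, free_greens, red_pos, params, rng):
    """Position one red focus according to its pairing category.

    Each plasmid focus anchors at most one paired (colocalized or adjacent)
    transcript, so the pairing ground truth is recoverable by one-to-one
    matching; when no free plasmid focus remains, or a cramped cell defeats
    the geometric constraints, the focus falls back to independent
    placement and is labeled accordingly.  Returns
    (position, zone, realized pairing, green index consumed or None).
    """
    sep = params.min_focus_separation
    if pair == "COLOCALIZED" and free_greens:
        for gi in rng.permutation(free_greens):
            base = green_pos[gi]
            for _ in range(50):
                pos = (base[0] + rng.normal(0, 0.4), base[1] + rng.normal(0, 0.4))
                if (
                    _inside(geom, pos)
                    and np.hypot(pos[0] - base[0], pos[1] - base[1]) < 1.5
                    and not _too_close(pos, red_pos, sep)
                ):
                    return pos, geom.classify(*pos), "COLOCALIZED", int(gi)
        pair = "ADJACENT"
    if pair == "ADJACENT" and free_greens:
        gi = int(rng.choice(free_greens))
        base = green_pos[gi]
        # the migrated transcript keeps the adjacency distance but prefers
        # the zone drawn from the zone weights (transcripts accumulate in
        # DNA-poor regions even when still near their template)
        target = ZONES[rng.choice(3, p=np.asarray(params.zone_weights))]
        fallback = None
        for _ in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            d = params.adjacency_offset_px + rng.normal(0, 0.5)
            d = float(np.clip(d, 2.5, 7.5))
            pos = (base[0] + d * np.cos(ang), base[1] + d * np.sin(ang))
            if _inside(geom, pos) and not _too_close(pos, red_pos, sep):
                zone = geom.classify(*pos)
                if zone == target:
                    return pos, zone, "ADJACENT", gi
                if fallback is None:
                    fallback = (pos, zone)
        if fallback is not None:
            return fallback[0], fallback[1], "ADJACENT", gi
        # cell too cramped: fall through to independent placement
    pos, zone = sample_focus_position(
        geom,
        params.zone_weights,
        rng,
        exclude=lambda q: _too_close(q, red_pos, sep)
        or _too_close(q, green_pos, params.independent_min_dist_px),
    )
    if pos is None:
        # cramped cell: relax the plasmid-distance preference, keep resolvability
        pos, zone = sample_focus_position(
            geom, params.zone_weights, rng, exclude=lambda q: _too_close(q, red_pos, sep)
        )
    if pos is None:
        return None, None, None, None
    return pos, zone, "INDEPENDENT", None


def _inside(geom, pos):
    ix, iy = int(round(pos[0])), int(round(pos[1]))
    h, w = geom.mask.shape
    return 0 <= iy < h and 0 <= ix < w and geom.interior[iy, ix]


def generate_fields(params: SimParams, cond: Condition, seed: int, n_fields: int):
    """Generate several independent fields with child seeds spawned from ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_fields)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        out.append(generate_field(params, cond, sub_seed))
    return out


# ---------------------------------------------------------------------------
# I/O


def write_field(outdir, name, stack: ImageStack, truth: FieldTruth, params: SimParams):
    """Write a field as multi-page TIFF + truth CSVs + a JSON manifest."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pages = [stack.channels[c] for c in CHANNELS]
    tifffile.imwrite(
        outdir / f"{name}.tif",
        np.stack(pages),
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(CHANNELS)},
        description=json.dumps({"channels": list(CHANNELS), "pixel_size_um": stack.pixel_size_um}),
    )
    tifffile.imwrite(outdir / f"{name}_labels.tif", truth.labels.astype(np.int32))
    truth.foci_df().to_csv(outdir / f"{name}_truth_foci.csv", index=False)
    truth.cells_df().to_csv(outdir / f"{name}_truth_cells.csv", index=False)
    manifest = {
        "name": name,
        "seed": truth.seed,
        "condition": truth.condition.to_dict() if truth.condition else None,
        "params": params.to_dict(),
    }
    with open(outdir / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_field(path):
    """Read a multi-page TIFF written by :func:`write_field` into an ImageStack."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    names = list(CHANNELS)
    pixel_size = 0.065
    try:
        meta = json.loads(desc)
        names = meta.get("channels", names)
        pixel_size = meta.get("pixel_size_um", pixel_size)
    except (json.JSONDecodeError, TypeError):
        pass
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(
        channels={n: arr[i] for i, n in enumerate(names[: arr.shape[0]])},
        pixel_size_um=pixel_size,
    )
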