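"""Synthetic steady-state populations and rendered microscopy scenes.

The generator emulates the statistical structure the downstream analysis
assumes for an exponentially growing rod-shaped population imaged in 2D:

* cell-cycle ages drawn from the steady-state density p(a) = 2 ln2 · 2^(−a),
  a ∈ [0, 1] (each division replaces one old cell with two newborns, so
  young cells are over-represented);
* exponential single-cell growth L(a) = L0 · 2^a, with multiplicative
  length noise for between-cell variability;
* mid-cell constriction past a configurable onset age, visible in the
  phase channel as a shallower intensity depression at mid-cell;
* fluorescence localization classes: cytoplasmic (uniform), membrane /
  contour (ring), periplasmic (ring; the leakage reporter), and septal
  (mid-cell Gaussian band appearing past an onset age, with an
  age-dependent amplitude so the population has a well-defined moment of
  peak localization);
* injected envelope defects: leaky cells whose ring signal is attenuated,
  and bright Gaussian puncta (outer-membrane blebs / vesicles) placed
  just outside the contour of their parent cell.

Everything a test needs back is recorded in :class:`GroundTruth`; no
ground-truth quantity requires re-reading the rendered images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._geom import segment_distance
from .errors import PlacementError
from .profile import AxialProfile

#: Camera pixel size, µm (the imaging configuration the defaults emulate).
DEFAULT_PIXEL_SIZE_UM = 0.064

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# parameter models


@dataclass(frozen=True)
class GrowthModel:
    """Steady-state growth law and rod geometry.

    Length doubles over the cycle, L(a) = birth_length_um · 2^a; width is
    constant; past `constriction_onset_age` the mid-cell radius is
    pinched by a Gaussian notch whose depth ramps linearly to
    `constriction_depth` (fraction of the radius) at division.
    `length_noise_cv` is the between-cell multiplicative length noise
    (lognormal coefficient of variation).
    """

    birth_length_um: float = 2.0
    width_um: float = 1.0
    constriction_onset_age: float = 0.6
    constriction_depth: float = 0.5
    constriction_sigma_um: float = 0.25
    length_noise_cv: float = 0.05

    def __post_init__(self):
        if self.birth_length_um <= 0 or self.width_um <= 0:
            raise ValueError("birth_length_um and width_um must be positive")
        if not 0.0 <= self.constriction_onset_age <= 1.0:
            raise ValueError("constriction_onset_age must be in [0, 1]")
        if not 0.0 <= self.constriction_depth < 1.0:
            raise ValueError("constriction_depth must be in [0, 1)")

    def length_at_age(self, age):
        return self.birth_length_um * np.exp2(np.asarray(age, dtype=float))

    def constriction_fraction(self, age) -> float:
        """Depth of the mid-cell radial notch, 0 before onset."""
        if age < self.constriction_onset_age:
            return 0.0
        span = max(1.0 - self.constriction_onset_age, 1e-9)
        return self.constriction_depth * (age - self.constriction_onset_age) / span

    def local_radius(self, age: float, s_um) -> np.ndarray:
        """Cell radius at signed axial position `s_um` from mid-cell, µm."""
        r0 = self.width_um / 2.0
        depth = self.constriction_fraction(age)
        s = np.asarray(s_um, dtype=float)
        notch = np.exp(-(s**2) / (2.0 * self.constriction_sigma_um**2))
        return r0 * (1.0 - depth * notch)


@dataclass(frozen=True)
class ChannelModel:
    """One fluorescence channel: localization class and imaging parameters.

    kind:
      'cytoplasmic'  uniform per-pixel amplitude over the cell body
      'contour'      ring of signal along the envelope (membrane stain)
      'periplasmic'  same ring geometry (periplasm-confined reporter;
                     attenuated in leaky cells, like 'contour')
      'septal'       uniform base plus a transverse Gaussian band at
                     mid-cell for cells past `septal_onset_age`

    The septal band amplitude depends on age: zero before onset, rising
    linearly to the full `amplitude` at `septal_peak_age`, then declining
    to `amplitude · septal_end_fraction` at division, so a population
    carries both an initiation and a moment of peak localization.
    `cell_cv` is lognormal between-cell expression variability applied to
    every cell's amplitude.
    """

    name: str = "fluor"
    kind: str = "cytoplasmic"
    amplitude: float = 100.0
    base_amplitude: float = 20.0
    septal_onset_age: float = 0.4
    septal_sigma_um: float = 0.15
    septal_peak_age: float = 0.65
    septal_end_fraction: float = 0.3
    ring_halfwidth_um: float = 0.08
    noise_sd: float = 2.0
    background: float = 10.0
    cell_cv: float = 0.1

    def __post_init__(self):
        if self.kind not in {"cytoplasmic", "contour", "periplasmic", "septal"}:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")
        if not 0.0 <= self.septal_onset_age <= 1.0:
            raise ValueError("septal_onset_age must be in [0, 1]")

    def amplitude_at_age(self, age: float) -> float:
        """Per-cell septal band amplitude as a function of cycle age."""
        if self.kind != "septal":
            return self.amplitude
        if age < self.septal_onset_age:
            return 0.0
        peak = max(self.septal_peak_age, self.septal_onset_age + 1e-9)
        if age <= peak:
            return self.amplitude * (age - self.septal_onset_age) / (
                peak - self.septal_onset_age
            )
        tail = max(1.0 - peak, 1e-9)
        frac = (age - peak) / tail
        return self.amplitude * (1.0 - (1.0 - self.septal_end_fraction) * frac)


@dataclass(frozen=True)
class DefectModel:
    """Envelope-defect injection parameters."""

    leak_fraction: float = 0.0
    leak_attenuation: float = 0.2
    bleb_rate: float = 0.0
    bleb_amplitude: float = 500.0
    bleb_radius_um: float = 0.15
    bleb_max_offset_um: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ValueError("leak_fraction must be in [0, 1]")
        for name in ("leak_attenuation", "bleb_rate", "bleb_amplitude",
                     "bleb_radius_um", "bleb_max_offset_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """Per-cell and per-bleb truth for a synthetic population/scene."""

    cells: pd.DataFrame
    blebs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["bleb_id", "cell_id", "row_px", "col_px", "x_um", "y_um",
                     "radius_um", "amplitude", "rendered_total"]
        )
    )
    labels: np.ndarray | None = None


@dataclass
class Scene:
    """A rendered multi-channel field with its ground truth."""

    images: dict[str, np.ndarray]
    pixel_size: float
    truth: GroundTruth
    channels: list[ChannelModel]
    phase_background: float
    phase_depth: float


# ---------------------------------------------------------------------------
# population sampling


def steady_state_age_pdf(age):
    """p(a) = 2 ln2 · 2^(−a) on [0, 1]."""
    a = np.asarray(age, dtype=float)
    return 2.0 * LN2 * np.exp2(-a)


def steady_state_age_cdf(age):
    """F(a) = 2 (1 − 2^(−a)) on [0, 1]."""
    a = np.asarray(age, dtype=float)
    return 2.0 * (1.0 - np.exp2(-a))


def sample_population(
    n: int, growth: GrowthModel | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a steady-state population of `n` cells.

    Ages come from p(a) = 2 ln2 · 2^(−a) by inverse-CDF sampling; lengths
    follow L0 · 2^a with lognormal noise of CV `growth.length_noise_cv`.
    Returns the population table (cell_id, length_um) and the matching
    GroundTruth.  Identical (seed, parameters) give identical output.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    growth = growth or GrowthModel()
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    ages = -np.log2(1.0 - u / 2.0)
    lengths = growth.length_at_age(ages)
    if growth.length_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + growth.length_noise_cv**2))
        lengths = lengths * rng.lognormal(-0.5 * sigma**2, sigma, n)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=int),
            "true_age": ages,
            "true_length_um": lengths,
            "is_leaky": np.zeros(n, dtype=bool),
            "septal_present": np.zeros(n, dtype=bool),
        }
    )
    pop = cells[["cell_id"]].copy()
    pop["length_um"] = lengths
    return pop, GroundTruth(cells=cells)


# ---------------------------------------------------------------------------
# analytic axial profiles (no rendering)


def analytic_profiles(
    truth: GroundTruth,
    channel: ChannelModel,
    n_bins: int = 50,
    seed: int = 0,
) -> list[AxialProfile]:
    """Exact per-cell axial profiles for a channel, bypassing rendering.

    Bin values are exact integrals of the channel's axial intensity model
    over each of `n_bins` equal bins: a uniform component of linear
    density amplitude·(L/n_bins per bin) plus, for septal channels past
    onset, a mid-cell Gaussian band of integrated mass amplitude_at_age(a)
    and width septal_sigma_um.  Per-bin Gaussian noise of SD `noise_sd`
    is added when nonzero.  Useful for testing the demograph statistics
    at population sizes where rendering whole fields is unnecessary.
    """
    rng = np.random.default_rng(seed)
    cells = truth.cells
    sigma_cv = (
        math.sqrt(math.log(1.0 + channel.cell_cv**2)) if channel.cell_cv > 0 else 0.0
    )
    factors = (
        rng.lognormal(-0.5 * sigma_cv**2, sigma_cv, len(cells))
        if sigma_cv > 0
        else np.ones(len(cells))
    )
    profiles = []
    for (idx, cell), factor in zip(cells.iterrows(), factors):
        L = float(cell.true_length_um)
        age = float(cell.true_age)
        edges = np.linspace(0.0, L, n_bins + 1)
        if channel.kind == "septal":
            uniform = channel.base_amplitude
        else:
            uniform = channel.amplitude
        values = factor * uniform * np.diff(edges)
        if channel.kind == "septal":
            mass = factor * channel.amplitude_at_age(age)
            if mass > 0:
                cdf = norm.cdf(edges, loc=L / 2.0, scale=channel.septal_sigma_um)
                values = values + mass * np.diff(cdf)
        if channel.noise_sd > 0:
            values = values + rng.normal(0.0, channel.noise_sd, n_bins)
        profiles.append(
            AxialProfile(int(cell.cell_id), channel.name, values, L)
        )
    return profiles


# ---------------------------------------------------------------------------
# scene rendering


def _auto_field_shape(lengths, width, pixel_size, margin_px, fill=0.12):
    footprint = np.sum((lengths + width + 0.6) * (2.0 * width + 0.6))
    side_um = math.sqrt(max(footprint, 1.0) / fill)
    side_px = int(math.ceil(side_um / pixel_size)) + 2 * margin_px
    return (side_px, side_px)


def _place_cells(lengths_um, growth, shape, pixel_size, min_separation_px, rng,
                 max_tries=300):
    """Rejection-sample non-overlapping capsule placements (px coords)."""
    sep_um = min_separation_px * pixel_size
    r0 = growth.width_um / 2.0
    margin = (np.asarray(lengths_um) / 2.0 + r0 + sep_um) / pixel_size
    order = np.argsort(lengths_um)[::-1]  # long cells first packs better
    centers = np.full((len(lengths_um), 2), np.nan)
    thetas = np.zeros(len(lengths_um))
    spines = []  # (p1, p2, half_len+r) per placed cell, µm coords

    placed_idx = []
    for k, i in enumerate(order):
        L = lengths_um[i]
        h = max(L / 2.0 - r0, 0.0)
        if 2.0 * margin[i] >= min(shape):
            raise PlacementError(len(placed_idx), len(lengths_um))
        ok = False
        for _ in range(max_tries):
            row = rng.uniform(margin[i], shape[0] - margin[i])
            col = rng.uniform(margin[i], shape[1] - margin[i])
            theta = rng.uniform(0.0, math.pi)
            c_um = np.array([row, col]) * pixel_size
            u = np.array([math.sin(theta), math.cos(theta)])
            p1, p2 = c_um - h * u, c_um + h * u
            ok = True
            for q1, q2, reach in spines:
                mid_q = (q1 + q2) / 2.0
                coarse = np.hypot(*(c_um - mid_q))
                if coarse > h + r0 + sep_um + reach:
                    continue
                if segment_distance(p1, p2, q1, q2) < 2.0 * r0 + sep_um:
                    ok = False
                    break
            if ok:
                centers[i] = (row, col)
                thetas[i] = theta
                spines.append((p1, p2, h + r0 + sep_um))
                placed_idx.append(i)
                break
        if not ok:
            raise PlacementError(len(placed_idx), len(lengths_um))
    return centers, thetas


def render_scene(
    population: pd.DataFrame,
    truth: GroundTruth,
    channels: list[ChannelModel],
    growth: GrowthModel | None = None,
    defects: DefectModel | None = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    field_shape: tuple[int, int] | None = None,
    min_separation_px: int = 5,
    margin_px: int = 12,
    phase_background: float = 200.0,
    phase_depth: float = 100.0,
    phase_noise_sd: float = 2.0,
    blur_sigma_px: float = 0.0,
) -> Scene:
    """Render a population into a multi-channel field.

    Produces a phase-like channel (dark rods on a bright background, with
    the depression depth proportional to the local cell radius so
    constriction reads as mid-cell brightening of the raw image /
    shallowing of the depression), plus one image per fluorescence
    channel.  Leak flags and blebs from `defects` are drawn here and
    recorded in the returned ground truth, together with an integer label
    image of the true masks and per-cell noiseless rendered totals per
    channel.  Deterministic under a fixed seed.
    """
    from scipy import ndimage

    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    growth = growth or GrowthModel()
    defects = defects or DefectModel()
    rng = np.random.default_rng(seed)

    cells = truth.cells.copy().reset_index(drop=True)
    lengths = cells["true_length_um"].to_numpy(dtype=float)
    ages = cells["true_age"].to_numpy(dtype=float)
    n = len(cells)
    if field_shape is None:
        field_shape = _auto_field_shape(
            lengths, growth.width_um, pixel_size, margin_px
        )

    centers, thetas = _place_cells(
        lengths, growth, field_shape, pixel_size, min_separation_px, rng
    )
    cells["row_px"] = centers[:, 0]
    cells["col_px"] = centers[:, 1]
    cells["theta"] = thetas
    cells["is_leaky"] = rng.random(n) < defects.leak_fraction
    septal_onsets = [c.septal_onset_age for c in channels if c.kind == "septal"]
    onset = septal_onsets[0] if septal_onsets else np.inf
    cells["septal_present"] = ages >= onset

    sigma_by_channel = {
        c.name: math.sqrt(math.log(1.0 + c.cell_cv**2)) if c.cell_cv > 0 else 0.0
        for c in channels
    }
    cell_factors = {
        c.name: (
            rng.lognormal(-0.5 * sigma_by_channel[c.name] ** 2,
                          sigma_by_channel[c.name], n)
            if sigma_by_channel[c.name] > 0
            else np.ones(n)
        )
        for c in channels
    }

    labels = np.zeros(field_shape, dtype=np.int32)
    phase = np.zeros(field_shape, dtype=np.float64)
    images = {c.name: np.zeros(field_shape, dtype=np.float64) for c in channels}
    totals = {c.name: np.zeros(n) for c in channels}

    r0 = growth.width_um / 2.0
    for i in range(n):
        L, age = lengths[i], ages[i]
        h = max(L / 2.0 - r0, 0.0)
        half_px = int(math.ceil((L / 2.0 + r0 + 2.0) / pixel_size))
        rc, cc = centers[i]
        rlo = max(int(rc) - half_px, 0)
        rhi = min(int(rc) + half_px + 1, field_shape[0])
        clo = max(int(cc) - half_px, 0)
        chi = min(int(cc) + half_px + 1, field_shape[1])
        rows, cols = np.mgrid[rlo:rhi, clo:chi]
        dy = (rows - rc) * pixel_size
        dx = (cols - cc) * pixel_size
        u = np.array([math.sin(thetas[i]), math.cos(thetas[i])])
        s = dy * u[0] + dx * u[1]                     # axial µm, from mid-cell
        t = -dy * u[1] + dx * u[0]                    # transverse µm
        s_body = np.clip(s, -h, h)
        d = np.hypot(np.abs(s) - np.abs(s_body), t)   # distance to spine
        r_loc = growth.local_radius(age, s_body)
        inside = d <= r_loc

        labels[rlo:rhi, clo:chi][inside] = int(cells.at[i, "cell_id"])
        # phase depression proportional to local radius (thicker = darker)
        phase[rlo:rhi, clo:chi][inside] -= (
            phase_depth * (r_loc[inside] / r0)
        )

        for ch in channels:
            factor = cell_factors[ch.name][i]
            if ch.kind in ("contour", "periplasmic") and cells.at[i, "is_leaky"]:
                factor *= defects.leak_attenuation
            canvas = images[ch.name][rlo:rhi, clo:chi]
            if ch.kind == "cytoplasmic":
                add = np.where(inside, ch.amplitude * factor, 0.0)
            elif ch.kind in ("contour", "periplasmic"):
                # envelope band just inside the cell outline, so the ring
                # lies wholly within the mask (d <= r_loc)
                ring = (d <= r_loc) & (d >= r_loc - 2.0 * ch.ring_halfwidth_um)
                add = np.where(ring, ch.amplitude * factor, 0.0)
            else:  # septal
                add = np.where(inside, ch.base_amplitude * factor, 0.0)
                amp = ch.amplitude_at_age(age) * factor
                if amp > 0:
                    band = amp * np.exp(-(s**2) / (2.0 * ch.septal_sigma_um**2))
                    add = add + np.where(inside, band, 0.0)
            canvas += add
            totals[ch.name][i] = float(add.sum())

    for ch in channels:
        cells[f"total_{ch.name}"] = totals[ch.name]

    bleb_rows = _render_blebs(
        cells, lengths, ages, centers, thetas, growth, defects, channels,
        images, field_shape, pixel_size, rng,
    )

    if blur_sigma_px > 0:
        phase = ndimage.gaussian_filter(phase, blur_sigma_px)
        for name in images:
            images[name] = ndimage.gaussian_filter(images[name], blur_sigma_px)

    phase = phase + phase_background
    if phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, phase_noise_sd, field_shape)
    out_images = {"phase": phase.astype(np.float32)}
    for ch in channels:
        img = images[ch.name] + ch.background
        if ch.noise_sd > 0:
            img = img + rng.normal(0.0, ch.noise_sd, field_shape)
        out_images[ch.name] = img.astype(np.float32)

    blebs = pd.DataFrame(
        bleb_rows,
        columns=["bleb_id", "cell_id", "row_px", "col_px", "x_um", "y_um",
                 "radius_um", "amplitude", "rendered_total"],
    )
    new_truth = GroundTruth(cells=cells, blebs=blebs, labels=labels)
    return Scene(
        images=out_images,
        pixel_size=pixel_size,
        truth=new_truth,
        channels=list(channels),
        phase_background=phase_background,
        phase_depth=phase_depth,
    )


def _render_blebs(cells, lengths, ages, centers, thetas, growth, defects,
                  channels, images, field_shape, pixel_size, rng):
    """Draw Gaussian puncta just outside their parent contours."""
    bleb_rows = []
    if defects.bleb_rate <= 0:
        return bleb_rows
    ring_channels = [c for c in channels if c.kind in ("contour", "periplasmic")]
    r0 = growth.width_um / 2.0
    sigma = defects.bleb_radius_um
    bleb_id = 0
    counts = rng.poisson(defects.bleb_rate, len(cells))
    for i, count in enumerate(counts):
        L = lengths[i]
        h = max(L / 2.0 - r0, 0.0)
        u = np.array([math.sin(thetas[i]), math.cos(thetas[i])])
        v = np.array([-u[1], u[0]])
        c_px = centers[i]
        for _ in range(count):
            for _try in range(50):
                s_b = rng.uniform(-h, h) if h > 0 else 0.0
                side = rng.choice([-1.0, 1.0])
                offset = rng.uniform(0.25, 1.0) * defects.bleb_max_offset_um
                r_here = float(growth.local_radius(ages[i], s_b))
                pos_px = (
                    c_px
                    + (s_b * u + side * (r_here + offset) * v) / pixel_size
                )
                if (
                    sigma / pixel_size
                    <= pos_px[0]
                    < field_shape[0] - sigma / pixel_size
                ) and (
                    sigma / pixel_size
                    <= pos_px[1]
                    < field_shape[1] - sigma / pixel_size
                ):
                    break
            else:
                continue
            half = int(math.ceil(4.0 * sigma / pixel_size)) + 1
            rlo = max(int(pos_px[0]) - half, 0)
            rhi = min(int(pos_px[0]) + half + 1, field_shape[0])
            clo = max(int(pos_px[1]) - half, 0)
            chi = min(int(pos_px[1]) + half + 1, field_shape[1])
            rows, cols = np.mgrid[rlo:rhi, clo:chi]
            d2 = ((rows - pos_px[0]) ** 2 + (cols - pos_px[1]) ** 2) * pixel_size**2
            blob = defects.bleb_amplitude * np.exp(-d2 / (2.0 * sigma**2))
            blob[d2 > (4.0 * sigma) ** 2] = 0.0
            for ch in ring_channels:
                images[ch.name][rlo:rhi, clo:chi] += blob
            bleb_id += 1
            bleb_rows.append(
                (
                    bleb_id,
                    int(cells.at[i, "cell_id"]),
                    float(pos_px[0]),
                    float(pos_px[1]),
                    float(pos_px[1]) * pixel_size,
                    float(pos_px[0]) * pixel_size,
                    sigma,
                    defects.bleb_amplitude,
                    float(blob.sum()) * len(ring_channels),
                )
            )
    return bleb_rows


def make_scene(
    n: int,
    channels: list[ChannelModel],
    growth: GrowthModel | None = None,
    defects: DefectModel | None = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    **render_kwargs,
) -> Scene:
    """Convenience: sample a population and render it in one call.

    The population and the scene use seeds derived from `seed` so the
    whole artefact is reproducible from a single integer.
    """
    growth = growth or GrowthModel()
    pop, truth = sample_population(n, growth, seed=seed)
    return render_scene(
        pop, truth, channels, growth=growth, defects=defects,
        pixel_size=pixel_size, seed=seed + 1, **render_kwargs,
    )
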