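"""Synthetic panicle-image generator with exact ground truth.

Renders scanner-like images of detached rice panicles: bright elliptical
grains strung along gently curved branch rachides, a thin stem (attached
for Shape B, detached segments lying in frame for Shape C), speckle
noise from the light-absorbing fabric, and a near-black background. Every
render carries pixel-exact ground-truth masks and the true grain count,
so the whole measurement pipeline is testable without real image data.

Geometry defaults describe full-resolution scanner frames (2480×3507 px,
grains 30–50 px wide, stems 5–10 px wide, speckles < 100 px); use
:meth:`SyntheticSpec.at_scale` to shrink every length coherently for
faster experiments.

Layout model: branches are packed left-to-right into horizontal rows whose
pitch guarantees rows cannot touch; along a branch, consecutive grains are
placed by exact x-extent bookkeeping so that with ``overlap_prob = 0`` all
grains are pairwise disjoint (component count equals the true count after
stem removal), while each overlap event is verified pixel-wise to actually
touch (``overlap_prob = 1`` yields one connected blob per branch).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line

from .preprocess import disk_element

#: default grain aspect (length/width) per subspecies; Indica grains are
#: long and slender, Japonica shorter and plumper.
SUBSPECIES_ASPECT = {"indica": 3.5, "japonica": 2.2}


class PlacementOverflowError(RuntimeError):
    """Grains cannot be placed in the frame under the overlap constraints."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions for one rendered panicle."""

    image_size: tuple[int, int] = (2480, 3507)  # (H, W)
    n_grains: int = 140
    grain_width_px: tuple[float, float] = (30.0, 50.0)
    grain_aspect: float | None = None  # None -> subspecies default
    aspect_jitter: float = 0.10        # relative, uniform +/-
    n_branches: int | None = None      # None -> derived from grains_per_branch
    grains_per_branch: float = 14.0
    stem_width_px: tuple[float, float] = (5.0, 10.0)
    overlap_prob: float = 0.5
    n_speckles: int = 40
    speckle_area_px: tuple[float, float] = (4.0, 95.0)
    background_level: float = 12.0
    background_noise: float = 3.0
    foreground_level: tuple[float, float] = (140.0, 230.0)
    tilt_deg: tuple[float, float] = (20.0, 50.0)  # grain tilt off the rachis
    shape: str = "C"
    subspecies: str = "indica"
    stem_debris: tuple[int, int] = (1, 3)  # detached stem pieces (Shape C)
    draw_rachis: bool = True
    awns: bool = False
    hard: bool = False  # low-contrast photometry
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must be in [0, 1]")
        if self.n_grains < 0:
            raise ValueError("n_grains must be >= 0")
        for lo, hi in (self.grain_width_px, self.stem_width_px,
                       self.speckle_area_px, self.foreground_level):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive with lo <= hi")
        if self.shape not in ("B", "C"):
            raise ValueError("shape must be 'B' or 'C'")
        if self.subspecies not in SUBSPECIES_ASPECT:
            raise ValueError(f"subspecies must be one of {sorted(SUBSPECIES_ASPECT)}")

    @property
    def aspect_resolved(self) -> float:
        return self.grain_aspect if self.grain_aspect is not None \
            else SUBSPECIES_ASPECT[self.subspecies]

    def at_scale(self, s: float) -> "SyntheticSpec":
        """Shrink/grow every pixel quantity by a linear factor ``s``.

        Lengths scale with ``s``, areas with ``s**2``; e.g. the default
        frame at ``s=0.25`` is 620×877 px with 7.5–12.5 px grains.
        """
        if s <= 0:
            raise ValueError("scale factor must be positive")
        H, W = self.image_size
        return dataclasses.replace(
            self,
            image_size=(max(1, round(H * s)), max(1, round(W * s))),
            grain_width_px=(self.grain_width_px[0] * s, self.grain_width_px[1] * s),
            stem_width_px=(self.stem_width_px[0] * s, self.stem_width_px[1] * s),
            speckle_area_px=(
                max(1.0, self.speckle_area_px[0] * s * s),
                max(1.0, self.speckle_area_px[1] * s * s),
            ),
            scale=self.scale * s,
        )


@dataclass
class SyntheticPanicle:
    """A rendered panicle with pixel-exact ground truth."""

    image: np.ndarray        # (H, W, 3) uint8
    grain_mask: np.ndarray   # grains only
    stem_mask: np.ndarray    # visible stem pixels (main stem/tail/debris)
    rachis_mask: np.ndarray  # visible branch-axis pixels (part of the branch)
    true_count: int
    per_grain: list[tuple[tuple[float, float], tuple[float, float], float]]
    n_branches: int
    spec: SyntheticSpec = field(repr=False)

    def __post_init__(self) -> None:
        assert self.true_count == len(self.per_grain)


def _x_extent(half_len: float, half_wid: float, angle: float) -> float:
    """Full x-extent of an ellipse with the given rotation (radians)."""
    return 2.0 * math.hypot(half_len * math.cos(angle), half_wid * math.sin(angle))


def _axis_chord(half_len: float, half_wid: float, angle: float) -> float:
    """Half-length of the ellipse's chord along a horizontal through its centre."""
    return 1.0 / math.hypot(math.cos(angle) / half_len, math.sin(angle) / half_wid)


def _grain_color(level: float) -> np.ndarray:
    return np.array([level, 0.92 * level, 0.55 * level])


def _stem_color(level: float) -> np.ndarray:
    return np.array([0.75 * level, level, 0.45 * level])


def render_panicle(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SyntheticPanicle:
    """Render one panicle; identical spec (and seed) gives identical output."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    H, W = spec.image_size
    wlo, whi = spec.grain_width_px
    aspect = spec.aspect_resolved
    tilt_lo, tilt_hi = (math.radians(t) for t in spec.tilt_deg)

    lmax = whi * aspect * (1.0 + spec.aspect_jitter)
    amp = 0.25 * whi                      # rachis waviness amplitude
    wavelength = 18.0 * whi
    slope_max = math.atan(amp * 2.0 * math.pi / wavelength)
    half_perp = lmax / 2.0 * math.sin(min(math.pi / 2, tilt_hi + slope_max)) + whi / 2.0 + 2.0
    row_pitch = 2.0 * (half_perp + amp) + 6.0
    margin_x = int(lmax / 2.0) + 6
    margin_y = half_perp + amp + 4.0
    x_left, x_right = margin_x, W - margin_x
    y_rows = np.arange(margin_y, H - margin_y + 1e-9, row_pitch)
    if len(y_rows) < 1 or x_right - x_left < 2 * whi:
        raise PlacementOverflowError("placement overflow: frame too small for grain geometry")

    # branch sizes
    n_branches = spec.n_branches or max(1, round(spec.n_grains / spec.grains_per_branch))
    if spec.shape == "B":
        n_branches = min(n_branches, len(y_rows))
    n_branches = min(n_branches, max(1, spec.n_grains)) if spec.n_grains else 0
    nb_list: list[int] = []
    if spec.n_grains:
        base, rem = divmod(spec.n_grains, n_branches)
        nb_list = [base + (1 if i < rem else 0) for i in range(n_branches)]
        rng.shuffle(nb_list)

    grain_mask = np.zeros((H, W), dtype=bool)
    stem_center = np.zeros((H, W), dtype=bool)    # main stem / tail / debris
    rachis_center = np.zeros((H, W), dtype=bool)  # branch axes
    per_grain: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    grain_draws: list[tuple[float, float, float, float, float, float]] = []
    stem_w = rng.uniform(*spec.stem_width_px)
    stem_radius = max(0, round((round(stem_w) - 1) / 2))

    def rachis_curve(base_x: float, amp_b: float, phase: float):
        k = 2.0 * math.pi / wavelength

        def y_of(x: float, y0: float) -> float:
            return y0 + amp_b * math.sin(k * (x - base_x) + phase)

        def slope_of(x: float) -> float:
            return amp_b * k * math.cos(k * (x - base_x) + phase)

        return y_of, slope_of

    def draw_centerline_curve(canvas: np.ndarray, base_x: float, y0: float,
                              x0: float, x1: float, y_of) -> None:
        xs = np.arange(int(round(x0)), int(round(x1)) + 1)
        ys = np.rint([y_of(float(x), y0) for x in xs]).astype(int)
        ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
        canvas[ys[ok], xs[ok]] = True

    row_idx = 0
    cur_x = x_left + rng.uniform(0.0, whi)
    branch_bases: list[tuple[int, float]] = []  # (row index, base x) for Shape B stems
    rachis_starts: list[tuple[int, int]] = []   # (y, x) pixel where each rachis begins
    last_used_row = 0

    for b, nb in enumerate(nb_list):
        # per-grain geometry
        widths = rng.uniform(wlo, whi, nb)
        aspects = aspect * (1.0 + rng.uniform(-spec.aspect_jitter, spec.aspect_jitter, nb))
        lengths = widths * aspects
        sign0 = 1 if rng.random() < 0.5 else -1
        tilts = np.array([sign0 * (-1) ** i for i in range(nb)]) * rng.uniform(tilt_lo, tilt_hi, nb)
        levels = rng.uniform(*spec.foreground_level, nb)
        amp_b = rng.uniform(0.3, 1.0) * amp
        phase = rng.uniform(0.0, 2.0 * math.pi)
        phi_max = math.atan(amp_b * 2.0 * math.pi / wavelength)

        # conservative x-footprints: widest at the smallest possible |angle|
        fx = np.array([
            _x_extent(lengths[i] / 2, widths[i] / 2, max(0.0, abs(tilts[i]) - phi_max))
            for i in range(nb)
        ])
        chord = np.array([
            _axis_chord(lengths[i] / 2, widths[i] / 2, abs(tilts[i])) for i in range(nb)
        ])
        is_overlap = rng.random(nb) < spec.overlap_prob
        is_overlap[0] = False
        dx = np.empty(nb)
        dx[0] = fx[0] / 2 + 3.0
        for i in range(1, nb):
            if is_overlap[i]:
                dx[i] = rng.uniform(0.55, 0.80) * (chord[i - 1] + chord[i])
            else:
                dx[i] = (fx[i - 1] + fx[i]) / 2 + 3.0 + rng.uniform(0.0, 0.15 * whi)
        blen = float(dx.sum() + fx[-1] / 2 + 3.0)

        if spec.shape == "B":
            if b > 0:
                row_idx += 1
                cur_x = x_left
            if row_idx >= len(y_rows) or x_left + blen > x_right:
                raise PlacementOverflowError("placement overflow")
        elif cur_x + blen > x_right:
            row_idx += 1
            cur_x = x_left + rng.uniform(0.0, whi)
            if row_idx >= len(y_rows) or cur_x + blen > x_right:
                raise PlacementOverflowError("placement overflow")

        base_x = cur_x
        y0 = float(y_rows[row_idx])
        last_used_row = max(last_used_row, row_idx)
        branch_bases.append((row_idx, base_x))
        y_of, slope_of = rachis_curve(base_x, amp_b, phase)
        rachis_starts.append(
            (int(round(y_of(base_x - 3, y0))), int(round(base_x - 3)))
        )
        if spec.draw_rachis:
            draw_centerline_curve(rachis_center, base_x, y0,
                                  base_x - 3, base_x + blen - 3, y_of)

        x_prev = None
        for i in range(nb):
            step = float(dx[i])
            attempts = 0
            while True:
                x_c = (base_x + step) if x_prev is None else (x_prev + step)
                y_c = y_of(x_c, y0)
                angle = float(tilts[i] + math.atan(slope_of(x_c)))
                rr, cc = _draw_ellipse(
                    y_c, x_c, widths[i] / 2, lengths[i] / 2, rotation=angle, shape=(H, W)
                )
                if not is_overlap[i] or grain_mask[rr, cc].any() or step <= 2.0 or attempts >= 8:
                    break
                step *= 0.7  # pull towards the previous grain until they touch
                attempts += 1
            grain_mask[rr, cc] = True
            grain_draws.append((y_c, x_c, widths[i] / 2, lengths[i] / 2, angle, levels[i]))
            per_grain.append(((y_c, x_c), (lengths[i] / 2, widths[i] / 2), angle))
            x_prev = x_c

        cur_x = base_x + blen + rng.uniform(0.4, 1.0) * whi + 4.0

    # stems: attached main stem + peduncle tail (Shape B) or detached debris (Shape C)
    if spec.shape == "B" and branch_bases:
        x_sv = max(4, int(0.4 * margin_x))
        y_top = int(round(y_rows[branch_bases[0][0]]))
        tail = rng.uniform(0.2, 0.7) * H
        y_bot = int(min(H - 5, y_rows[last_used_row] + tail))
        rr, cc = _draw_line(y_top, x_sv, y_bot, x_sv)
        stem_center[rr, cc] = True
        # connectors run from the stem to each rachis's true start point
        for (row, bx), start in zip(branch_bases, rachis_starts):
            sy, sx = start
            rr, cc = _draw_line(int(round(y_rows[row])), x_sv, sy, sx)
            stem_center[rr, cc] = True
    elif spec.shape == "C" and spec.stem_debris[1] > 0:
        n_debris = int(rng.integers(spec.stem_debris[0], spec.stem_debris[1] + 1))
        free_rows = [r for r in range(len(y_rows)) if r > last_used_row]
        for r in free_rows[:n_debris]:
            usable = x_right - x_left
            seg_len = rng.uniform(0.25, 0.55) * usable
            x0 = rng.uniform(x_left, x_right - seg_len)
            slope = rng.uniform(-0.05, 0.05)
            xs = np.arange(int(x0), int(x0 + seg_len))
            ys = np.rint(y_rows[r] + slope * (xs - x0)).astype(int)
            ok = (ys >= 0) & (ys < H)
            stem_center[ys[ok], xs[ok]] = True

    if stem_radius > 0:
        el = disk_element(2 * stem_radius + 1)
        stem_draw = ndi.binary_dilation(stem_center, structure=el)
        rachis_draw = ndi.binary_dilation(rachis_center, structure=el)
    else:
        stem_draw, rachis_draw = stem_center, rachis_center

    # compose the image
    if spec.hard:
        bg_level, noise_sd = max(30.0, spec.background_level), max(8.0, spec.background_noise)
        fg_shift = -80.0
    else:
        bg_level, noise_sd, fg_shift = spec.background_level, spec.background_noise, 0.0
    img = np.empty((H, W, 3), dtype=np.float64)
    img[...] = (bg_level, bg_level, bg_level + 2.0)
    stem_level = rng.uniform(120.0, 180.0) + fg_shift
    img[stem_draw | rachis_draw] = _stem_color(stem_level)
    for y_c, x_c, rw, rl, angle, level in grain_draws:
        rr, cc = _draw_ellipse(y_c, x_c, rw, rl, rotation=angle, shape=(H, W))
        img[rr, cc] = _grain_color(level + fg_shift)
        if spec.awns and rng.random() < 0.4:
            ax = x_c + rl * math.cos(angle)
            ay = y_c + rl * math.sin(angle)
            alen = rng.uniform(0.5, 1.2) * 2 * rl
            rr2, cc2 = _draw_line(
                int(round(ay)), int(round(ax)),
                int(np.clip(round(ay + alen * math.sin(angle)), 0, H - 1)),
                int(np.clip(round(ax + alen * math.cos(angle)), 0, W - 1)),
            )
            img[rr2, cc2] = _grain_color(level + fg_shift) * 0.8

    # fabric speckles: bright specks clear of the panicle
    area_cap = max(2.0, spec.speckle_area_px[1])
    forbidden = ndi.binary_dilation(grain_mask | stem_draw | rachis_draw,
                                    structure=disk_element(5))
    for _ in range(spec.n_speckles):
        for _attempt in range(20):
            area = rng.uniform(*spec.speckle_area_px)
            a = math.sqrt(area / math.pi)
            r1 = max(0.6, a * rng.uniform(0.6, 1.4))
            r2 = max(0.6, area / (math.pi * r1))
            y_c = rng.uniform(3, H - 4)
            x_c = rng.uniform(3, W - 4)
            rr, cc = _draw_ellipse(y_c, x_c, r1, r2, rotation=rng.uniform(0, math.pi),
                                   shape=(H, W))
            while len(rr) >= area_cap and r1 > 0.6:
                r1, r2 = r1 * 0.8, r2 * 0.8
                rr, cc = _draw_ellipse(y_c, x_c, r1, r2, shape=(H, W))
            if len(rr) == 0 or len(rr) >= area_cap:
                continue
            if not forbidden[rr, cc].any():
                level = rng.uniform(90.0, 200.0) + fg_shift
                img[rr, cc] = (level, level, 0.9 * level)
                forbidden[rr, cc] = True
                break

    img += rng.normal(0.0, noise_sd, (H, W))[..., None]
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticPanicle(
        image=image,
        grain_mask=grain_mask,
        stem_mask=stem_draw & ~grain_mask,
        rachis_mask=rachis_draw & ~grain_mask & ~stem_draw,
        true_count=spec.n_grains,
        per_grain=per_grain,
        n_branches=len(nb_list),
        spec=spec,
    )


def generate_dataset(
    n_images: int,
    seed: int,
    base_spec: SyntheticSpec | None = None,
    count_range: tuple[int, int] = (60, 220),
) -> tuple[list[SyntheticPanicle], pd.DataFrame]:
    """Render a deterministic batch of panicles with a counts table.

    Each image gets its own grain count (uniform over ``count_range``) and
    a sub-seed derived from ``seed`` and the image counter, so the batch is
    reproducible image-by-image.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = base_spec or SyntheticSpec()
    master = np.random.default_rng(seed)
    panicles: list[SyntheticPanicle] = []
    rows = []
    for i in range(n_images):
        n = int(master.integers(count_range[0], count_range[1] + 1))
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec_i = dataclasses.replace(base, n_grains=n, seed=sub_seed)
        pan = render_panicle(spec_i)
        panicles.append(pan)
        rows.append({
            "image_id": f"syn_{i:04d}",
            "true_count": pan.true_count,
            "n_branches": pan.n_branches,
            "shape": spec_i.shape,
            "subspecies": spec_i.subspecies,
            "seed": sub_seed,
        })
    return panicles, pd.DataFrame(rows)
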