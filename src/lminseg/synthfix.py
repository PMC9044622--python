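"""Seeded generator of synthetic single-cell blood-smear images.

Real inputs are micrographs of one stained white blood cell: a dark,
often multi-lobed nucleus inside a mid-intensity cytoplasm, surrounded by
pale annular red blood cells (RBCs) on a bright background.  The
generator emulates exactly that geometry with exact tri-level ground
truth, in two regimes:

* ``separated`` — every RBC keeps a clear gap to the white cell (the
  regime the averaged-threshold strategy assumes);
* ``touching`` — at least one RBC overlaps the cytoplasm rim by a few
  pixels (the regime that needs the SLIC/watershed fallbacks).

Default class means are (nucleus 0.20, cytoplasm 0.55, RBC 0.70,
background 0.90): the dark nucleus and bright background bracket an
initial value near 1/3 inside the nucleus–cytoplasm histogram valley,
matching the intensity regime of stained smears.  Gaussian noise
(default sigma 0.03, well under half the smallest inter-class gap) is
added and clipped to [0, 1].

A matching RGB rendering (purple nucleus, pink cytoplasm, red RBCs) is
produced for the superpixel path; each class color is scaled so its
BT.601 luminance equals the class gray mean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage import draw, morphology

from .errors import ParameterError
from .imgio import BT601_WEIGHTS, write_mask

__all__ = ["FixtureSpec", "generate_cell_image", "generate_suite"]

#: chromatic templates per class; scaled so BT.601 luminance hits the
#: class gray mean
_COLOR_TEMPLATES = {
    "nucleus": np.array([0.50, 0.10, 0.90]),
    "cytoplasm": np.array([0.90, 0.55, 0.80]),
    "rbc": np.array([1.00, 0.60, 0.60]),
    "rbc_pale": np.array([1.00, 0.80, 0.80]),
    "background": np.array([0.95, 0.92, 0.95]),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cell image."""

    image_size: tuple[int, int] = (120, 120)
    nucleus_lobes: int = 2
    nucleus_mean: float = 0.20
    cytoplasm_mean: float = 0.55
    rbc_mean: float = 0.70
    background_mean: float = 0.90
    noise_sigma: float = 0.03
    rbc_count: int = 3
    touching: bool = False
    random_seed: int = 0

    def __post_init__(self):
        means = (
            self.nucleus_mean,
            self.cytoplasm_mean,
            self.rbc_mean,
            self.background_mean,
        )
        if not (means[0] < means[1] < means[2] <= means[3]):
            raise ParameterError(
                "class means must satisfy nucleus < cytoplasm < rbc <= background"
            )
        if not all(0.0 < m < 1.0 for m in means):
            raise ParameterError("class means must lie in (0, 1)")
        gaps = (means[1] - means[0], means[2] - means[1], means[3] - means[2])
        positive_gaps = [g for g in gaps if g > 0]
        if self.noise_sigma >= min(positive_gaps) / 2:
            raise ParameterError(
                "noise_sigma must be below half the smallest inter-class gap"
            )
        if self.nucleus_lobes < 1:
            raise ParameterError("nucleus_lobes must be >= 1")


def _color_for(klass: str, luminance: float) -> np.ndarray:
    template = _COLOR_TEMPLATES[klass]
    return np.clip(template * (luminance / float(template @ BT601_WEIGHTS)), 0, 1)


def _nucleus_mask(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.image_size
    m = min(rows, cols)
    center = np.array([rows / 2, cols / 2]) + rng.uniform(-0.03 * m, 0.03 * m, 2)
    r_lobe = 0.10 * m
    mask = np.zeros(spec.image_size, dtype=bool)
    for _ in range(spec.nucleus_lobes):
        offset = rng.uniform(-0.8 * r_lobe, 0.8 * r_lobe, 2)
        axes = rng.uniform(0.7 * r_lobe, 1.1 * r_lobe, 2)
        rr, cc = draw.ellipse(
            center[0] + offset[0], center[1] + offset[1],
            axes[0], axes[1], shape=spec.image_size,
            rotation=rng.uniform(0, np.pi),
        )
        mask[rr, cc] = True
    return mask


def _place_rbcs(
    spec: FixtureSpec, wbc_blob: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """RBC centers and radii honoring the regime's contact constraints."""
    rows, cols = spec.image_size
    m = min(rows, cols)
    r_rbc = 0.08 * m
    margin = 3.0
    wr, wc = np.nonzero(wbc_blob)
    centroid = np.array([wr.mean(), wc.mean()])
    placed: list[tuple[float, float, float]] = []

    def overlaps_placed(c, r):
        return any(
            np.hypot(c[0] - pr, c[1] - pc) < r + prr + 2 for pr, pc, prr in placed
        )

    def blob_clearance(c):
        return np.hypot(wr - c[0], wc - c[1]).min()

    n_touch = 1 if spec.touching and spec.rbc_count >= 1 else 0
    for i in range(spec.rbc_count):
        ok = False
        for _ in range(300):
            if i < n_touch:
                theta = rng.uniform(0, 2 * np.pi)
                u = np.array([np.cos(theta), np.sin(theta)])
                # march out from the centroid to the blob boundary
                d = 1.0
                while True:
                    p = centroid + d * u
                    ri, ci = int(round(p[0])), int(round(p[1]))
                    if (
                        not (0 <= ri < rows and 0 <= ci < cols)
                        or not wbc_blob[ri, ci]
                    ):
                        break
                    d += 1.0
                c = centroid + (d + r_rbc - 2.0) * u
            else:
                c = rng.uniform([r_rbc + 1, r_rbc + 1], [rows - r_rbc - 1, cols - r_rbc - 1])
            in_canvas = (
                r_rbc <= c[0] < rows - r_rbc and r_rbc <= c[1] < cols - r_rbc
            )
            if not in_canvas or overlaps_placed(c, r_rbc):
                continue
            clearance = blob_clearance(c)
            if i < n_touch:
                if clearance < r_rbc:  # genuinely overlapping the rim
                    ok = True
            else:
                if clearance > r_rbc + margin:
                    ok = True
            if ok:
                placed.append((float(c[0]), float(c[1]), float(r_rbc)))
                break
        if not ok:
            raise ParameterError(
                f"could not place RBC {i + 1}/{spec.rbc_count} on a "
                f"{rows}x{cols} canvas; reduce rbc_count"
            )
    return placed


def generate_cell_image(
    spec: FixtureSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one synthetic cell.

    Returns ``(gray, trilevel_mask, color)``: the noisy [0, 1] gray image,
    the exact tri-level ground truth (nucleus 255, cytoplasm 128,
    background — including RBCs — 0), and the matching RGB rendering in
    [0, 1].  Identical specs (including the seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.random_seed)
    rows, cols = spec.image_size
    m = min(rows, cols)

    nucleus = _nucleus_mask(spec, rng)
    hull = morphology.convex_hull_image(nucleus)
    cyto_radius = max(int(round(0.11 * m)), 4)
    blob = morphology.dilation(hull, morphology.disk(cyto_radius))
    cytoplasm = blob & ~nucleus

    rbcs = _place_rbcs(spec, blob, rng)

    pale = (spec.rbc_mean + spec.background_mean) / 2.0
    gray = np.full(spec.image_size, spec.background_mean)
    color = np.empty((rows, cols, 3))
    color[:] = _color_for("background", spec.background_mean)
    for cr, cc_, r in rbcs:
        rr, cc2 = draw.disk((cr, cc_), r, shape=spec.image_size)
        gray[rr, cc2] = spec.rbc_mean
        color[rr, cc2] = _color_for("rbc", spec.rbc_mean)
        rr, cc2 = draw.disk((cr, cc_), 0.55 * r, shape=spec.image_size)
        gray[rr, cc2] = pale  # the pale annulus center of a real RBC
        color[rr, cc2] = _color_for("rbc_pale", pale)
    gray[cytoplasm] = spec.cytoplasm_mean
    color[cytoplasm] = _color_for("cytoplasm", spec.cytoplasm_mean)
    gray[nucleus] = spec.nucleus_mean
    color[nucleus] = _color_for("nucleus", spec.nucleus_mean)

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, spec.image_size)
        gray = gray + noise
        color = color + noise[..., None]
    gray = np.clip(gray, 0.0, 1.0)
    color = np.clip(color, 0.0, 1.0)

    trilevel = np.zeros(spec.image_size, dtype=np.uint8)
    trilevel[cytoplasm] = 128
    trilevel[nucleus] = 255
    return gray, trilevel, color


def _suite_specs(
    n_images: int, regime: str, seed: int
) -> list[FixtureSpec]:
    if regime not in ("separated", "touching"):
        raise ParameterError(f"regime must be 'separated' or 'touching', got {regime!r}")
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_images):
        specs.append(
            FixtureSpec(
                nucleus_lobes=int(rng.integers(1, 4)),
                rbc_count=int(rng.integers(2, 5)),
                touching=(regime == "touching"),
                random_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_suite(
    n_images: int, regime: str = "separated", seed: int = 42, outdir=None
) -> list[tuple[FixtureSpec, np.ndarray, np.ndarray, np.ndarray]]:
    """Generate a reproducible suite of cell images.

    Per-image lobe counts, RBC counts and geometry seeds are drawn from
    ``seed``; class means and noise stay at the defaults, which define
    the study conditions.  When ``outdir`` is given, gray and color
    images, tri-level masks and a JSON manifest of the specs are written
    there (all PNG; the manifest is byte-stable for a fixed seed).

    Returns the list of ``(spec, gray, trilevel, color)`` tuples.
    """
    specs = _suite_specs(n_images, regime, seed)
    out = []
    for i, spec in enumerate(specs):
        gray, trilevel, color = generate_cell_image(spec)
        out.append((spec, gray, trilevel, color))
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            import imageio.v3 as iio

            iio.imwrite(
                outdir / f"img_{i:03d}_gray.png",
                np.round(gray * 255).astype(np.uint8),
            )
            iio.imwrite(
                outdir / f"img_{i:03d}_color.png",
                np.round(color * 255).astype(np.uint8),
            )
            write_mask(trilevel, outdir / f"img_{i:03d}_mask.png")
    if outdir is not None:
        manifest = {
            "regime": regime,
            "seed": seed,
            "n_images": n_images,
            "specs": [asdict(s) for s in specs],
        }
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return out
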