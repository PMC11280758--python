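"""Synthetic tongue-image generator.

Real tongue photographs for coating segmentation are clinical data and not
generally shareable, so this module fabricates image/mask pairs with the
structure that makes the task hard: an elliptical tongue body on a dark
background, a coating region whose colour is close to the body colour, fuzzy
colour boundaries, and the irregular phenomena segmentation models struggle
with — cracks cutting through the coating, scalloped tooth-marked body
edges, and peeled patches where coating is missing.

Labels are intentionally *hard* (binary) while the image is blurred: the
ambiguity lives in the pixels, not in the annotation, mirroring how clinical
masks are drawn.

Every sample is generated from ``(spec, seed, index)`` alone, so datasets
are bit-reproducible and any single sample can be regenerated without the
rest.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage


class SpecValidationError(ValueError):
    """A synthetic-spec field is outside its allowed range."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic tongue generator.

    ``coating_coverage`` is the target fraction of the tongue-body area
    covered by coating, hit to within about +/-0.1 (before peel patches and
    cracks remove pixels).  Colours are RGB with per-channel jitter.
    """

    image_size: int = 224
    body_axes: Tuple[float, float] = (0.30, 0.40)  # (x, y) semi-axes / size
    body_color: Tuple[int, int, int] = (176, 106, 110)
    coating_color: Tuple[int, int, int] = (198, 186, 168)
    color_jitter_std: float = 10.0
    coating_coverage: float = 0.6
    n_cracks: int = 2
    crack_width: int = 2
    tooth_mark_amplitude: float = 4.0
    n_peel_patches: int = 1
    boundary_blur_sigma: float = 2.0
    noise_std: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 16:
            raise SpecValidationError("image_size must be >= 16")
        if not (0.05 < self.body_axes[0] < 0.5 and 0.05 < self.body_axes[1] < 0.5):
            raise SpecValidationError("body_axes must lie in (0.05, 0.5)")
        if not (0.0 <= self.coating_coverage <= 0.95):
            raise SpecValidationError("coating_coverage must lie in [0, 0.95]")
        if self.n_cracks < 0:
            raise SpecValidationError("n_cracks must be >= 0")
        if self.crack_width < 1:
            raise SpecValidationError("crack_width must be >= 1")
        if self.tooth_mark_amplitude < 0:
            raise SpecValidationError("tooth_mark_amplitude must be >= 0")
        if self.n_peel_patches < 0:
            raise SpecValidationError("n_peel_patches must be >= 0")
        if self.boundary_blur_sigma < 0:
            raise SpecValidationError("boundary_blur_sigma must be >= 0")
        if self.noise_std < 0:
            raise SpecValidationError("noise_std must be >= 0")


@dataclass
class LabeledImage:
    """An RGB tongue image with its aligned binary coating mask."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray   # H x W uint8 in {0, 1}
    id: str

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial dimensions differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must contain only 0 and 1")


def _sample_rng(spec: SyntheticSpec, index: int) -> np.random.Generator:
    # per-sample stream: order-independent, partially regenerable
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index)]))


def _body_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2.0
    ax = spec.body_axes[0] * s
    ay = spec.body_axes[1] * s
    dx = (xx - cx) / ax
    dy = (yy - cy) / ay
    r = np.sqrt(dx * dx + dy * dy)
    boundary = np.ones_like(r)
    if spec.tooth_mark_amplitude > 0:
        # inward scallops on the left/right flanks: tooth marks
        theta = np.arctan2(dy, dx)
        n_scallops = int(rng.integers(6, 11))
        phase = rng.uniform(0, 2 * np.pi)
        scallop = np.abs(np.sin(n_scallops * theta / 2.0 + phase))
        flank = np.abs(np.cos(theta))  # strongest at left/right edges
        depth = spec.tooth_mark_amplitude / max(ax, 1.0)
        boundary = 1.0 - depth * scallop * flank
    return (r <= boundary).astype(np.uint8)


def _coating_mask(
    spec: SyntheticSpec, body: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Thresholded low-frequency noise blob inside the (eroded) body."""
    if spec.coating_coverage <= 0.0:
        return np.zeros_like(body)
    s = spec.image_size
    margin = max(2, s // 64)
    inner = ndimage.binary_erosion(body, iterations=margin)
    if not inner.any():
        return np.zeros_like(body)
    f = ndimage.gaussian_filter(rng.normal(size=(s, s)), sigma=s / 10.0)
    body_area = int(body.sum())
    want = spec.coating_coverage * body_area
    vals = np.sort(f[inner.astype(bool)])[::-1]
    n_take = int(min(len(vals), max(1, round(want))))
    thr = vals[n_take - 1]
    return ((f >= thr) & inner.astype(bool)).astype(np.uint8)


def _draw_cracks(
    mask: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Cut thin, wandering background-class curves through the coating."""
    if spec.n_cracks == 0 or not mask.any():
        return mask
    s = spec.image_size
    ys, xs = np.nonzero(mask)
    out = mask.copy()
    for _ in range(spec.n_cracks):
        crack = np.zeros_like(mask, dtype=bool)
        j = rng.integers(len(ys))
        y, x = float(ys[j]), float(xs[j])
        angle = rng.uniform(0, 2 * np.pi)
        # walk in both directions from the seed point so cracks span the blob
        for direction in (angle, angle + np.pi):
            py, px, a = y, x, direction
            for _ in range(2 * s):
                iy, ix = int(round(py)), int(round(px))
                if not (0 <= iy < s and 0 <= ix < s):
                    break
                crack[iy, ix] = True
                a += rng.normal(0.0, 0.25)
                py += np.sin(a)
                px += np.cos(a)
        if spec.crack_width > 1:
            crack = ndimage.binary_dilation(
                crack, iterations=spec.crack_width - 1
            )
        out[crack] = 0
    return out


def _peel_patches(
    mask: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.n_peel_patches == 0 or not mask.any():
        return mask
    s = spec.image_size
    ys, xs = np.nonzero(mask)
    out = mask.copy()
    yy, xx = np.mgrid[0:s, 0:s]
    for _ in range(spec.n_peel_patches):
        j = rng.integers(len(ys))
        cy, cx = ys[j], xs[j]
        ry = rng.uniform(0.03, 0.08) * s
        rx = rng.uniform(0.03, 0.08) * s
        patch = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        out[patch] = 0
    return out


def generate_sample(spec: SyntheticSpec, index: int = 0) -> LabeledImage:
    """Generate one image/mask pair, deterministically from (spec, seed, index)."""
    spec.validate()
    rng = _sample_rng(spec, index)
    s = spec.image_size

    body = _body_mask(spec, rng)
    coating = _coating_mask(spec, body, rng)
    coating = _draw_cracks(coating, spec, rng)
    coating = _peel_patches(coating, spec, rng)

    bg = np.array([32.0, 26.0, 30.0])
    body_c = np.asarray(spec.body_color, float) + rng.normal(
        0, spec.color_jitter_std, 3
    )
    coat_c = np.asarray(spec.coating_color, float) + rng.normal(
        0, spec.color_jitter_std, 3
    )
    img = np.empty((s, s, 3))
    img[:] = bg
    img[body.astype(bool)] = body_c
    img[coating.astype(bool)] = coat_c
    # slowly varying colour texture inside the tongue
    texture = ndimage.gaussian_filter(rng.normal(0, 14.0, size=(s, s)), sigma=s / 28.0)
    img += texture[..., None] * body[..., None]
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(spec.boundary_blur_sigma, spec.boundary_blur_sigma, 0)
        )
    if spec.noise_std > 0:
        img += rng.normal(0, spec.noise_std, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(image=image, mask=coating.astype(np.uint8), id=f"s{index:05d}")


# --------------------------------------------------------------------- I/O
def save_labeled_image(sample: LabeledImage, image_path: Path, mask_path: Path) -> None:
    Image.fromarray(sample.image, mode="RGB").save(image_path)
    Image.fromarray((sample.mask * 255).astype(np.uint8), mode="L").save(mask_path)


def load_labeled_image(image_path: Path, mask_path: Path, id: str = "") -> LabeledImage:
    image = np.asarray(Image.open(image_path).convert("RGB"))
    raw = np.asarray(Image.open(mask_path).convert("L"))
    mask = (raw > 127).astype(np.uint8)
    return LabeledImage(image=image, mask=mask, id=id or Path(image_path).stem)


def generate_dataset(
    spec: SyntheticSpec, n: int, out_dir: Path
) -> List[dict]:
    """Write ``n`` samples as PNGs plus a CSV manifest and the spec as YAML.

    Returns the manifest rows (id, image_path, mask_path).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for i in range(n):
        sample = generate_sample(spec, i)
        img_p = out_dir / "images" / f"{sample.id}.png"
        msk_p = out_dir / "masks" / f"{sample.id}.png"
        save_labeled_image(sample, img_p, msk_p)
        rows.append(
            {"id": sample.id, "image_path": str(img_p), "mask_path": str(msk_p)}
        )
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "image_path", "mask_path"])
        writer.writeheader()
        writer.writerows(rows)
    with open(out_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(spec), fh)
    return rows


def read_manifest(path: Path) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_dataset(manifest_path: Path) -> List[LabeledImage]:
    return [
        load_labeled_image(r["image_path"], r["mask_path"], r["id"])
        for r in read_manifest(manifest_path)
    ]
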