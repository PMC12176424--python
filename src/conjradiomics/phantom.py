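"""Synthetic conjunctiva-phantom cohort generator.

Produces a cohort of participants (age, sex, hemoglobin, WHO anemia label)
and grayscale conjunctiva-like photographs with aligned elliptical ROI
masks. The phantom encodes the class signal the downstream analysis is
meant to recover: anemic participants have sparser and lower-contrast dark
curvilinear "vessel" strokes inside the ROI, mimicking conjunctival pallor
as a loss of visible microvascular texture. Device profiles add blur,
resolution loss, tone-curve and noise differences between the three
emulated smartphone models.

Everything is deterministic under a fixed seed (bit-identical images and
metadata).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from conjradiomics.stats import who_anemia_label

__all__ = [
    "DeviceProfile",
    "PhantomParams",
    "Participant",
    "PhotoRecord",
    "DEFAULT_DEVICES",
    "generate_participants",
    "generate_cohort",
    "render_conjunctiva_photo",
    "write_cohort",
]


@dataclass(frozen=True)
class DeviceProfile:
    """Optical/electronic signature of one smartphone camera.

    ``blur_sigma`` is the Gaussian PSF width in pixels, ``noise_sigma`` the
    additive read-noise SD in 8-bit intensity units, ``scale`` a relative
    resolution factor (1 = native; 0.75 = image resampled through a 25%
    coarser grid), and ``gamma`` a tone-curve exponent.
    """

    name: str
    blur_sigma: float = 1.0
    noise_sigma: float = 2.0
    scale: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0 or self.scale <= 0:
            raise ValueError("invalid device profile parameters")


#: Three profiles loosely emulating the study's high-end / budget / mid-range
#: handsets (which resolved ~172 / 110 / 137 um at the conjunctiva).
DEFAULT_DEVICES = (
    DeviceProfile("galaxy_s22", blur_sigma=1.2, noise_sigma=1.5, scale=0.80, gamma=1.05),
    DeviceProfile("galaxy_a52", blur_sigma=0.8, noise_sigma=3.0, scale=1.00, gamma=0.95),
    DeviceProfile("pixel_6", blur_sigma=1.0, noise_sigma=2.0, scale=0.90, gamma=1.00),
)


@dataclass
class PhantomParams:
    """Generator configuration; defaults emulate the study cohort structure.

    565 children aged 5-15, ~56% anemia prevalence, hemoglobin from
    class-conditional normals (anemic 9.1 +/- 1.1, nonanemic 11.8 +/- 1.0
    g/dL, giving an overall mean near 10.3 +/- 1.7), 53% male, and 2 eyes x
    3 devices x 4 photos = 24 photos per participant (~22 in the study).
    Vessel density is in strokes per 1000 ROI pixels; contrast is the
    fractional intensity drop of a stroke against the background. The
    ``*_sd`` values are the between-participant SDs of the latent class
    parameters; the class gaps of the defaults are several SDs wide
    (a strong, recoverable effect).
    """

    n_participants: int = 565
    photos_per_eye_per_device: int = 4
    prevalence: float = 0.56
    hgb_mean_by_class: tuple[float, float] = (9.1, 11.8)  # (anemic, nonanemic)
    hgb_sd_by_class: tuple[float, float] = (1.1, 1.0)
    vessel_density_by_class: tuple[float, float] = (6.0, 14.0)
    vessel_density_sd: float = 1.5
    vessel_contrast_by_class: tuple[float, float] = (0.22, 0.42)
    vessel_contrast_sd: float = 0.04
    male_fraction: float = 0.53
    roi_kind: str = "palpebral"
    image_size: tuple[int, int] = (96, 96)
    devices: tuple[DeviceProfile, ...] = DEFAULT_DEVICES
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.photos_per_eye_per_device <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if min(self.vessel_density_by_class) < 0 or min(self.vessel_contrast_by_class) < 0:
            raise ValueError("densities and contrasts must be non-negative")
        for v in (*self.hgb_mean_by_class,):
            if not 3 < v < 20:
                raise ValueError("hemoglobin means must lie in (3, 20) g/dL")
        if self.roi_kind not in ("palpebral", "bulbar"):
            raise ValueError("roi_kind must be 'palpebral' or 'bulbar'")


@dataclass
class Participant:
    """One child: identifier, demographics, hemoglobin and anemia status.

    The latent vessel density/contrast are the participant-level texture
    parameters the renderer draws photos around (ground truth for the
    class effect)."""

    id: str
    age_years: int
    sex: str
    hgb: float
    anemia: bool
    vessel_density: float = 0.0
    vessel_contrast: float = 0.0


@dataclass
class PhotoRecord:
    """One grayscale photograph with its aligned binary ROI mask."""

    participant_id: str
    eye: str  # "left" | "right"
    device: str
    image: np.ndarray  # uint8, HxW
    mask: np.ndarray  # bool, HxW
    region: str  # "palpebral" | "bulbar"

    def __post_init__(self):
        if self.mask.shape != self.image.shape:
            raise ValueError("mask shape must equal image shape")


def _draw_hgb(rng: np.random.Generator, anemic: bool, age: int, sex: str,
              params: PhantomParams) -> float:
    """Class-conditional normal draw, resampled until the WHO label agrees."""
    mean = params.hgb_mean_by_class[0 if anemic else 1]
    sd = params.hgb_sd_by_class[0 if anemic else 1]
    for _ in range(1000):
        hgb = float(rng.normal(mean, sd))
        if 3.0 < hgb < 20.0 and who_anemia_label(age, sex, hgb) == anemic:
            return round(hgb, 2)
    raise RuntimeError("could not draw a consistent hemoglobin value")


def generate_participants(params: PhantomParams) -> list[Participant]:
    """Generate the participant table (no photos) for the configured cohort."""
    rng = np.random.default_rng(params.seed)
    participants = []
    for k in range(params.n_participants):
        anemic = bool(rng.random() < params.prevalence)
        sex = "male" if rng.random() < params.male_fraction else "female"
        age = int(rng.integers(5, 16))
        hgb = _draw_hgb(rng, anemic, age, sex, params)
        ci = 0 if anemic else 1
        density = max(0.0, float(rng.normal(
            params.vessel_density_by_class[ci], params.vessel_density_sd)))
        contrast = float(np.clip(rng.normal(
            params.vessel_contrast_by_class[ci], params.vessel_contrast_sd),
            0.0, 0.95))
        participants.append(Participant(
            id=f"P{k:04d}", age_years=age, sex=sex, hgb=hgb, anemia=anemic,
            vessel_density=density, vessel_contrast=contrast,
        ))
    return participants


def _roi_mask(shape, kind: str, rng: np.random.Generator) -> np.ndarray:
    """Elliptical lid-shaped (palpebral) or scleral (bulbar) ROI mask."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "palpebral":
        # wide, flat ellipse in the lower half (everted lower lid)
        cy = h * (0.62 + 0.06 * rng.random())
        cx = w * (0.5 + 0.06 * (rng.random() - 0.5))
        ry = h * (0.14 + 0.04 * rng.random())
        rx = w * (0.34 + 0.06 * rng.random())
    else:
        # rounder, larger region in the upper half (exposed sclera)
        cy = h * (0.40 + 0.06 * rng.random())
        cx = w * (0.5 + 0.06 * (rng.random() - 0.5))
        ry = h * (0.22 + 0.05 * rng.random())
        rx = w * (0.28 + 0.05 * rng.random())
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_vessels(shape, mask, n_vessels: int, contrast: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Additive dark-stroke field from random-walk vessel centerlines.

    Each vessel is a smooth random walk started inside the ROI; its
    centerline impulses are spread by a Gaussian cross-profile of width
    drawn from 1-4 px. Returns a non-negative field to subtract from the
    background, scaled so stroke depth ~ contrast * background.
    """
    h, w = shape
    field = np.zeros(shape, dtype=float)
    ys, xs = np.nonzero(mask)
    if ys.size == 0 or n_vessels == 0:
        return field
    widths = 1.0 + 3.0 * rng.random(n_vessels)
    for v in range(n_vessels):
        j = int(rng.integers(0, ys.size))
        y, x = float(ys[j]), float(xs[j])
        theta = rng.uniform(0, 2 * np.pi)
        length = int(rng.integers(10, max(11, (h + w) // 3)))
        canvas = np.zeros(shape, dtype=float)
        for _ in range(length):
            theta += rng.normal(0.0, 0.25)  # smooth direction drift
            y += np.sin(theta)
            x += np.cos(theta)
            if not (0 <= y < h and 0 <= x < w):
                break
            canvas[int(y), int(x)] = 1.0
        sigma = widths[v] / 2.355  # width as FWHM of the cross-profile
        blurred = ndimage.gaussian_filter(canvas, sigma, mode="constant")
        if blurred.max() > 0:
            field += blurred / blurred.max() * contrast
    return field


def _apply_device(image: np.ndarray, device: DeviceProfile,
                  rng: np.random.Generator) -> np.ndarray:
    """Device degradation: PSF blur, resolution loss, gamma, read noise."""
    out = image.astype(float)
    if device.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, device.blur_sigma, mode="mirror")
    if device.scale < 1.0:
        small = ndimage.zoom(out, device.scale, order=1, mode="mirror")
        out = ndimage.zoom(small, np.array(image.shape) / np.array(small.shape),
                           order=1, mode="mirror")
        out = out[: image.shape[0], : image.shape[1]]
        if out.shape != image.shape:  # zoom rounding
            pad = np.array(image.shape) - np.array(out.shape)
            out = np.pad(out, ((0, pad[0]), (0, pad[1])), mode="edge")
    if device.gamma != 1.0:
        out = 255.0 * np.clip(out / 255.0, 0, 1) ** device.gamma
    if device.noise_sigma > 0:
        out = out + rng.normal(0.0, device.noise_sigma, out.shape)
    return np.clip(out, 0, 255)


def render_conjunctiva_photo(
    participant: Participant,
    device: DeviceProfile,
    eye: str,
    params: PhantomParams,
    rng: np.random.Generator | None = None,
    n_vessels: int | None = None,
    contrast: float | None = None,
) -> PhotoRecord:
    """Render one grayscale conjunctiva phantom photo for a participant.

    The ROI is an elliptical lid- or sclera-shaped mask; inside it, dark
    curvilinear vessel strokes (count ~ Poisson around the participant's
    latent density, contrast around the latent contrast) are drawn over a
    brighter background with a smooth illumination gradient, then the
    device profile's blur, resolution loss, gamma and noise are applied to
    the whole frame. A degenerate mask (<100 px) is regenerated with new
    geometry up to 10 times.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape = params.image_size
    mask = _roi_mask(shape, params.roi_kind, rng)
    for _ in range(10):
        if mask.sum() >= 100:
            break
        mask = _roi_mask(shape, params.roi_kind, rng)
    else:
        raise RuntimeError("could not generate a non-degenerate ROI mask")

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    base = 150.0 + 40.0 * rng.random()
    gx, gy = rng.normal(0, 0.15, 2)  # smooth illumination gradient
    background = base * (1.0 + gx * (xx / w - 0.5) + gy * (yy / h - 0.5))

    area = float(mask.sum())
    if n_vessels is None:
        lam = max(participant.vessel_density, 0.0) * area / 1000.0
        n_vessels = int(rng.poisson(lam))
    if contrast is None:
        contrast = float(np.clip(
            rng.normal(participant.vessel_contrast, 0.03), 0.0, 0.95))
    vessel_field = _render_vessels(shape, mask, n_vessels, contrast, rng)
    clean = background * np.clip(1.0 - vessel_field, 0.0, 1.0)
    degraded = _apply_device(clean, device, rng)
    image = np.clip(np.rint(degraded), 0, 255).astype(np.uint8)
    return PhotoRecord(
        participant_id=participant.id, eye=eye, device=device.name,
        image=image, mask=mask, region=params.roi_kind,
    )


def generate_cohort(
    params: PhantomParams,
) -> tuple[list[Participant], list[PhotoRecord]]:
    """Generate the full synthetic cohort: participants and their photos.

    Each participant receives ``2 eyes x len(devices) x
    photos_per_eye_per_device`` photos of the configured region. The same
    seed reproduces bit-identical metadata and pixel data.
    """
    participants = generate_participants(params)
    photo_seed = np.random.SeedSequence([params.seed, 1])
    rng = np.random.default_rng(photo_seed)
    photos: list[PhotoRecord] = []
    for part in participants:
        for eye in ("left", "right"):
            for device in params.devices:
                for _ in range(params.photos_per_eye_per_device):
                    photos.append(render_conjunctiva_photo(
                        part, device, eye, params, rng=rng))
    return participants, photos


def write_cohort(participants, photos, out_dir) -> Path:
    """Write images/masks as 8-bit PNGs and a metadata CSV; returns the CSV path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    by_id = {p.id: p for p in participants}
    rows = []
    for k, ph in enumerate(photos):
        img_path = out / "images" / f"photo_{k:06d}.png"
        msk_path = out / "masks" / f"mask_{k:06d}.png"
        iio.imwrite(img_path, ph.image)
        iio.imwrite(msk_path, (ph.mask.astype(np.uint8) * 255))
        p = by_id[ph.participant_id]
        rows.append({
            "participant_id": ph.participant_id, "eye": ph.eye,
            "device": ph.device, "region": ph.region,
            "age_years": p.age_years, "sex": p.sex, "hgb_g_dl": p.hgb,
            "anemia": int(p.anemia),
            "image_path": str(img_path.relative_to(out)),
            "mask_path": str(msk_path.relative_to(out)),
        })
    csv_path = out / "metadata.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return csv_path
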