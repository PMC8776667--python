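"""Synthetic CT-like phantom slices of pancreatic cystic lesions.

Real cohorts of serous (SCN) and mucinous (MCN) cystic neoplasm CT slices
are not publicly deposited, so this module generates seeded 2-D phantoms
carrying the radiological signal the classifier must exploit: an elliptical
cystic lesion with hypodense fluid, denser septa and wall, and surrounding
parenchyma.  SCN-like lesions are microcystic ("honeycomb": many small
locules, hence many internal septa); MCN-like lesions are uni/oligo-locular
(one or a few large smooth locules).

Each synthetic patient owns one lesion geometry; its slices differ only in
the additive-noise realization, reproducing the intra-patient correlation
that makes image-level versus patient-level splitting a meaningful choice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SCN",
    "MCN",
    "LABELS",
    "PNG_HU_OFFSET",
    "PhantomParams",
    "PhantomSample",
    "InvalidLabelError",
    "generate_phantom",
    "generate_cohort",
    "generate_dataset",
    "read_manifest",
    "load_image_png",
    "load_mask_png",
]

SCN = "SCN"
MCN = "MCN"
LABELS = (SCN, MCN)

#: 16-bit PNGs store ``HU + PNG_HU_OFFSET`` so that air (-1000 HU) stays positive.
PNG_HU_OFFSET = 1024


class InvalidLabelError(ValueError):
    """Raised when a lesion class label is not one of SCN / MCN."""


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings; defaults are the package's declared study conditions.

    Intensities are mean values in Hounsfield units.  Fluid must be
    hypodense relative to septa, which must be hypodense relative to
    parenchyma — cyst content on CT is near water, soft tissue is denser.
    """

    image_size: int = 128
    fluid_hu: float = 10.0
    septum_hu: float = 60.0
    parenchyma_hu: float = 90.0
    noise_sigma: float = 10.0
    scn_locule_count_range: tuple[int, int] = (6, 12)
    mcn_locule_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (15.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if not (self.fluid_hu < self.septum_hu < self.parenchyma_hu):
            raise ValueError(
                "expected fluid_hu < septum_hu < parenchyma_hu "
                f"(got {self.fluid_hu}, {self.septum_hu}, {self.parenchyma_hu})"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("scn_locule_count_range", "mcn_locule_count_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty interval with lo >= 1")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must be a nonempty positive interval")
        if 2 * hi >= self.image_size:
            raise ValueError("lesion diameter cannot exceed the image")

    def locule_count_range(self, label: str) -> tuple[int, int]:
        if label == SCN:
            return self.scn_locule_count_range
        if label == MCN:
            return self.mcn_locule_count_range
        raise InvalidLabelError(f"label must be one of {LABELS}, got {label!r}")


@dataclass
class PhantomSample:
    """One synthetic slice: HU image, lesion support mask, and metadata."""

    image: np.ndarray
    mask: np.ndarray
    label: str
    patient_id: str
    slice_index: int = 0
    clean_image: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share a shape")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")


def _lesion_geometry(
    label: str, params: PhantomParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free slice and mask for one lesion.

    The lesion is an axis-rotated ellipse.  Its interior is partitioned into
    locules by a Voronoi tessellation of random internal seed points; septa
    are the ~2 px boundaries between Voronoi cells plus a ~2 px wall at the
    lesion rim.  Within the mask every noise-free pixel is therefore either
    fluid_hu or septum_hu (the mask-fidelity invariant).
    """
    n = params.image_size
    r_lo, r_hi = params.lesion_radius_range

    center = n / 2 + rng.uniform(-0.05 * n, 0.05 * n, size=2)
    semi_axes = rng.uniform(r_lo, r_hi, size=2)
    theta = rng.uniform(0.0, np.pi)

    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    mask = (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0

    lo, hi = params.locule_count_range(label)
    n_locules = int(rng.integers(lo, hi + 1))

    interior = mask & ndimage.binary_erosion(mask, iterations=3)
    cand_r, cand_c = np.nonzero(interior if interior.any() else mask)
    pick = rng.choice(len(cand_r), size=min(n_locules, len(cand_r)), replace=False)
    seeds = np.column_stack([cand_r[pick], cand_c[pick]]).astype(float)

    mr, mc = np.nonzero(mask)
    d2 = (mr[:, None] - seeds[:, 0]) ** 2 + (mc[:, None] - seeds[:, 1]) ** 2
    cell = np.full((n, n), -1, dtype=int)
    cell[mr, mc] = np.argmin(d2, axis=1)

    # septa: pixels whose 4-neighbourhood (within the lesion) holds another cell
    septum = np.zeros((n, n), dtype=bool)
    for shift_r, shift_c in ((1, 0), (0, 1)):
        a = cell[: n - shift_r or n, : n - shift_c or n]
        b = cell[shift_r:, shift_c:]
        diff = (a != b) & (a >= 0) & (b >= 0)
        septum[: n - shift_r or n, : n - shift_c or n] |= diff
        septum[shift_r:, shift_c:] |= diff
    wall = mask & ~ndimage.binary_erosion(mask, iterations=2)
    septum = (septum | wall) & mask

    image = np.full((n, n), params.parenchyma_hu, dtype=float)
    image[mask] = params.fluid_hu
    image[septum] = params.septum_hu
    return image, mask


def generate_phantom(
    label: str,
    params: PhantomParams | None = None,
    rng: np.random.Generator | int | None = None,
    patient_id: str = "synthetic-0",
    slice_index: int = 0,
) -> PhantomSample:
    """Generate one phantom slice of the requested lesion class.

    Parameters
    ----------
    label
        ``"SCN"`` (microcystic, many locules) or ``"MCN"`` (few locules).
    params
        Generator settings; defaults to :class:`PhantomParams`.
    rng
        ``numpy`` Generator, integer seed, or None (uses ``params.seed``).

    Deterministic for a given RNG state.
    """
    if label not in LABELS:
        raise InvalidLabelError(f"label must be one of {LABELS}, got {label!r}")
    params = params or PhantomParams()
    if rng is None:
        rng = params.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clean, mask = _lesion_geometry(label, params, rng)
    image = clean + rng.normal(0.0, params.noise_sigma, size=clean.shape) \
        if params.noise_sigma > 0 else clean.copy()
    return PhantomSample(
        image=image,
        mask=mask,
        label=label,
        patient_id=patient_id,
        slice_index=slice_index,
        clean_image=clean,
    )


def generate_cohort(
    n_per_class: int,
    slices_per_patient: int = 1,
    params: PhantomParams | None = None,
) -> list[PhantomSample]:
    """Generate ``n_per_class`` synthetic patients per class, in memory.

    Each patient owns one lesion geometry; the patient's slices share it and
    differ only in the noise realization.  Fully determined by
    ``params.seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    params = params or PhantomParams()
    root = np.random.default_rng(params.seed)
    samples: list[PhantomSample] = []
    for label in LABELS:
        for p in range(n_per_class):
            patient_rng = np.random.default_rng(root.integers(0, 2**31))
            patient_id = f"{label}-{p:04d}"
            clean, mask = _lesion_geometry(label, params, patient_rng)
            for s in range(slices_per_patient):
                noise = (
                    patient_rng.normal(0.0, params.noise_sigma, size=clean.shape)
                    if params.noise_sigma > 0
                    else 0.0
                )
                samples.append(
                    PhantomSample(
                        image=clean + noise,
                        mask=mask.copy(),
                        label=label,
                        patient_id=patient_id,
                        slice_index=s,
                        clean_image=clean,
                    )
                )
    return samples


def _write_image_png(path: Path, image_hu: np.ndarray) -> None:
    coded = np.clip(np.rint(image_hu) + PNG_HU_OFFSET, 0, 65535).astype(np.uint16)
    Image.fromarray(coded).save(path)  # uint16 -> 16-bit grayscale PNG


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def load_image_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit phantom PNG back to HU scale (undoes the +1024 offset)."""
    coded = np.asarray(Image.open(path), dtype=float)
    return coded - PNG_HU_OFFSET


def load_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


MANIFEST_COLUMNS = ("path", "mask_path", "label", "patient_id", "slice_index")


def generate_dataset(
    out_dir: str | Path,
    n_per_class: int,
    slices_per_patient: int = 1,
    params: PhantomParams | None = None,
) -> Path:
    """Write a phantom dataset (16-bit PNG images, 8-bit masks, CSV manifest).

    Returns the manifest path.  Re-running with identical parameters and seed
    produces byte-identical files.
    """
    params = params or PhantomParams()
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    samples = generate_cohort(n_per_class, slices_per_patient, params)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        fh.write(f"# pixel value = HU + {PNG_HU_OFFSET} (uint16); masks 0/255\n")
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for s in samples:
            img_rel = f"images/{s.patient_id}_{s.slice_index:02d}.png"
            msk_rel = f"masks/{s.patient_id}_{s.slice_index:02d}.png"
            _write_image_png(out_dir / img_rel, s.image)
            _write_mask_png(out_dir / msk_rel, s.mask)
            writer.writerow([img_rel, msk_rel, s.label, s.patient_id, s.slice_index])
    return manifest_path


def read_manifest(manifest_path: str | Path):
    """Load a dataset manifest CSV (comment lines allowed) as a DataFrame."""
    import pandas as pd

    df = pd.read_csv(manifest_path, comment="#")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
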