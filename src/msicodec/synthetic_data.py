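"""Synthetic MS images with known tissue classes.

Each synthetic "tissue class" emits a characteristic set of Gaussian-shaped
peaks at class-specific m/z positions, on top of background peaks shared by
all classes.  Pixel-to-pixel variation is modeled by independent log-normal
multiplicative factors on each peak plus an additive Gaussian noise floor,
clipped at zero.  Because the class signatures are disjoint by construction,
the planted segmentation is recoverable by clustering, which makes these
images a ground-truthed stand-in for real tissue data in every pipeline test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import UNLABELED, BinnedImage, LabelMap

__all__ = [
    "SignatureSet",
    "generate_label_map",
    "generate_signatures",
    "render_image",
    "default_fixture",
]


@dataclass
class SignatureSet:
    """Peak signatures of the synthetic classes plus the noise model.

    ``class_peaks[c]`` lists ``(m/z, mean intensity)`` pairs specific to class
    c; ``background_peaks`` are shared by every class.  ``sigma_peak`` is the
    Gaussian peak width in Da.  ``sigma_mult`` is the log-normal sigma of the
    per-pixel multiplicative peak variation; ``sigma_add`` the standard
    deviation of the additive noise floor (absolute intensity units).
    """

    class_peaks: list[list[tuple[float, float]]]
    background_peaks: list[tuple[float, float]] = field(default_factory=list)
    sigma_peak: float = 0.15
    sigma_mult: float = 0.2
    sigma_add: float = 1.0

    def __post_init__(self) -> None:
        if not self.class_peaks:
            raise ValueError("at least one class signature is required")
        all_peaks = [p for peaks in self.class_peaks for p in peaks] + list(
            self.background_peaks
        )
        if any(intensity <= 0 for _, intensity in all_peaks):
            raise ValueError("peak intensities must be positive")
        keyed = [tuple(sorted(mz for mz, _ in peaks)) for peaks in self.class_peaks]
        if len(set(keyed)) != len(keyed):
            raise ValueError("class signatures must be pairwise distinct")

    @property
    def n_classes(self) -> int:
        return len(self.class_peaks)


def generate_label_map(
    width: int,
    height: int,
    n_classes: int,
    geometry: str = "nested_rings",
    seed: int | None = 0,
    border: int = 0,
) -> LabelMap:
    """Partition a pixel grid into ``n_classes`` contiguous regions.

    Geometries: ``stripes`` (equal vertical bands), ``nested_rings``
    (concentric bands by distance from the image center) and ``voronoi``
    (nearest of ``n_classes`` random sites).  ``border`` pixels around the
    edge are left unlabeled (-1), emulating off-tissue background.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be at least 1")
    if width * height < n_classes:
        raise ValueError("grid too small for the requested class count")
    inner_w, inner_h = width - 2 * border, height - 2 * border
    if inner_w < 1 or inner_h < 1 or inner_w * inner_h < n_classes:
        raise ValueError("border leaves no room for the classes")
    xs, ys = np.meshgrid(np.arange(inner_w), np.arange(inner_h))
    if geometry == "stripes":
        if inner_w < n_classes:
            raise ValueError(f"stripes need width >= {n_classes}")
        inner = (xs * n_classes) // inner_w
    elif geometry == "nested_rings":
        cx, cy = (inner_w - 1) / 2.0, (inner_h - 1) / 2.0
        r = np.hypot(xs - cx, ys - cy)
        edges = np.quantile(r, np.linspace(0, 1, n_classes + 1)[1:-1])
        inner = np.searchsorted(edges, r, side="right")
    elif geometry == "voronoi":
        rng = np.random.default_rng(seed)
        sites = np.column_stack(
            [rng.uniform(0, inner_w, n_classes), rng.uniform(0, inner_h, n_classes)]
        )
        d = np.hypot(xs[..., None] - sites[:, 0], ys[..., None] - sites[:, 1])
        inner = np.argmin(d, axis=-1)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    present = np.unique(inner)
    if len(present) < n_classes:
        raise ValueError(
            f"geometry {geometry!r} realized only {len(present)} of {n_classes} classes"
        )
    labels = np.full((height, width), UNLABELED, dtype=np.int64)
    labels[border: border + inner_h, border: border + inner_w] = inner
    return LabelMap(labels=labels, provenance="baseline")


def generate_signatures(
    n_classes: int,
    n_bins: int,
    peaks_per_class: int = 5,
    seed: int | None = 0,
    n_background: int = 10,
    mz_start: float = 100.0,
    grid_step: float = 0.1,
    sigma_peak: float = 0.15,
    sigma_mult: float = 0.2,
    sigma_add_fraction: float = 0.01,
    min_separation_bins: int = 8,
) -> SignatureSet:
    """Draw disjoint class-specific and shared background peak positions.

    Peaks are placed on distinct bins at least ``min_separation_bins`` apart
    so neighboring Gaussian profiles do not merge.  Mean intensities are
    uniform in [50, 100]; the additive noise sigma is ``sigma_add_fraction``
    of the largest mean peak intensity.
    """
    if peaks_per_class < 1:
        raise ValueError("peaks_per_class must be at least 1")
    total = n_classes * peaks_per_class + n_background
    margin = max(4, min_separation_bins)
    candidates = np.arange(margin, n_bins - margin, min_separation_bins)
    if len(candidates) < total:
        raise ValueError(
            f"axis of {n_bins} bins cannot host {total} peaks "
            f"{min_separation_bins} bins apart"
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(candidates, size=total, replace=False)
    amplitudes = rng.uniform(50.0, 100.0, size=total)
    mz = mz_start + positions * grid_step

    def take(n: int, offset: int) -> list[tuple[float, float]]:
        return [(float(mz[offset + j]), float(amplitudes[offset + j])) for j in range(n)]

    class_peaks = [take(peaks_per_class, c * peaks_per_class) for c in range(n_classes)]
    background = take(n_background, n_classes * peaks_per_class)
    return SignatureSet(
        class_peaks=class_peaks,
        background_peaks=background,
        sigma_peak=sigma_peak,
        sigma_mult=sigma_mult,
        sigma_add=sigma_add_fraction * float(amplitudes.max()),
    )


def render_image(
    label_map: LabelMap,
    signatures: SignatureSet,
    mz_start: float = 100.0,
    grid_step: float = 0.1,
    n_bins: int = 3000,
    seed: int | None = 0,
) -> BinnedImage:
    """Render every labeled pixel's profile-mode spectrum.

    A pixel of class c receives the sum of class-c and background peak
    profiles, each scaled by an independent per-pixel log-normal factor
    (sigma ``sigma_mult``), plus additive Gaussian noise (sigma
    ``sigma_add``) clipped at zero.  Unlabeled pixels are absent from the
    output image, not zero.
    """
    if label_map.labels.max() >= signatures.n_classes:
        raise ValueError("label map references a class without a signature")
    rng = np.random.default_rng(seed)
    mz_axis = mz_start + np.arange(n_bins) * grid_step
    coords = label_map.occupied_coords()
    classes = label_map.values_at(coords)

    def profile(peaks: list[tuple[float, float]]) -> np.ndarray:
        out = np.zeros((len(peaks), n_bins))
        for j, (mz, amp) in enumerate(peaks):
            out[j] = amp * np.exp(-0.5 * ((mz_axis - mz) / signatures.sigma_peak) ** 2)
        return out

    intensities = np.zeros((len(coords), n_bins))
    for c in range(signatures.n_classes):
        rows = np.nonzero(classes == c)[0]
        if rows.size == 0:
            continue
        profiles = profile(signatures.class_peaks[c] + list(signatures.background_peaks))
        if signatures.sigma_mult > 0:
            factors = rng.lognormal(0.0, signatures.sigma_mult,
                                    size=(rows.size, len(profiles)))
        else:
            factors = np.ones((rows.size, len(profiles)))
        intensities[rows] = factors @ profiles
    if signatures.sigma_add > 0:
        intensities += rng.normal(0.0, signatures.sigma_add, size=intensities.shape)
    np.clip(intensities, 0.0, None, out=intensities)
    return BinnedImage(
        width=label_map.width,
        height=label_map.height,
        pixel_coords=coords,
        mz_axis=mz_axis,
        intensities=intensities,
    )


def default_fixture(
    seed: int = 0,
    width: int = 32,
    height: int = 32,
    n_classes: int = 4,
    n_bins: int = 3000,
    geometry: str = "nested_rings",
) -> tuple[BinnedImage, LabelMap, SignatureSet]:
    """The standard test image: 32 x 32 pixels, four nested-ring classes,
    3000 bins from m/z 100.0, five peaks per class plus ten background peaks."""
    rng = np.random.default_rng(seed)
    label_map = generate_label_map(
        width, height, n_classes, geometry=geometry, seed=int(rng.integers(2**31))
    )
    signatures = generate_signatures(
        n_classes, n_bins, peaks_per_class=5, seed=int(rng.integers(2**31)),
        n_background=10,
    )
    image = render_image(
        label_map, signatures, n_bins=n_bins, seed=int(rng.integers(2**31))
    )
    return image, label_map, signatures
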