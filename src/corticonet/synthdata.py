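"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates toy voxel connectomes on a spherical shell, trial-structured
response tensors with controlled split-half reliability, and grating /
natural-like image batches.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .flatmap import VoxelConnectome


@dataclass(frozen=True)
class PatchSpec:
    """Angular patch on the generator sphere: center (azimuth, elevation) and
    half-extent, all in radians.  Patches sit near the projection equator so
    the flat map is faithful."""

    azimuth: float
    elevation: float
    half_extent: float


@dataclass(frozen=True)
class ConnectomeGenSpec:
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_um: float = 20000.0
    patches: Mapping[str, PatchSpec] = field(default_factory=dict)
    pitch_um: float = 100.0
    sigma_true_um: float = 200.0
    peak_weight: float = 1.0
    background_weight: float = 0.0
    edges: Sequence[tuple[str, str]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_true_um <= 0:
            raise InvalidInputError("sigma_true must be positive")
        names = list(self.patches)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                pa, pb = self.patches[names[a]], self.patches[names[b]]
                if (
                    abs(pa.azimuth - pb.azimuth) < pa.half_extent + pb.half_extent
                    and abs(pa.elevation - pb.elevation)
                    < pa.half_extent + pb.half_extent
                ):
                    raise InvalidInputError(
                        f"patches {names[a]!r} and {names[b]!r} overlap"
                    )


def _patch_grid(patch: PatchSpec, radius: float, pitch: float):
    """Angular grid covering the patch at roughly `pitch` um spacing."""
    step = pitch / radius
    n = max(1, int(np.floor(patch.half_extent / step)))
    offsets = np.arange(-n, n + 1) * step
    az, el = np.meshgrid(
        patch.azimuth + offsets, patch.elevation + offsets, indexing="ij"
    )
    return az.ravel(), el.ravel()


def _sphere_points(az, el, center, radius):
    # +x2 is the equatorial reference direction of the flat map
    d = np.column_stack(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)]
    )
    return np.asarray(center) + radius * d


def gen_voxel_connectome(spec: ConnectomeGenSpec) -> VoxelConnectome:
    """Voxel connectome on a spherical shell with Gaussian connection profiles.

    For each requested edge (i, j), every target voxel k receives weight from
    source voxel l equal to ``peak * exp(-g(l, m(k))^2 / sigma_true^2) +
    background``, where g is the geodesic distance and m maps the target patch
    linearly onto the source patch.  ``sigma_true`` is the root-mean-square
    radial spread of the profile, the exact quantity the width estimator
    reports for an isotropic Gaussian.
    """
    if not spec.patches:
        raise InvalidInputError("spec must define at least one patch")
    positions = []
    labels = []
    angulars: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, patch in spec.patches.items():
        az, el = _patch_grid(patch, spec.radius_um, spec.pitch_um)
        angulars[name] = (az, el)
        positions.append(_sphere_points(az, el, spec.center, spec.radius_um))
        labels.extend([name] * len(az))
    positions = np.vstack(positions)
    labels = np.asarray(labels)
    n = len(positions)
    weights = np.zeros((n, n))

    unit = (positions - np.asarray(spec.center)) / spec.radius_um
    index_of = {name: np.flatnonzero(labels == name) for name in spec.patches}
    for src, tgt in spec.edges:
        if src not in spec.patches or tgt not in spec.patches:
            raise InvalidInputError(f"edge ({src}, {tgt}) references unknown patch")
        si, ti = index_of[src], index_of[tgt]
        # mirror each target voxel to the same angular offset in the source
        # patch; a source patch larger than the target leaves a Gaussian-tail
        # margin so boundary truncation does not bias the width estimate
        ps, pt = spec.patches[src], spec.patches[tgt]
        az_t, el_t = angulars[tgt]
        az_m = ps.azimuth + (az_t - pt.azimuth)
        el_m = ps.elevation + (el_t - pt.elevation)
        mirror = _sphere_points(az_m, el_m, spec.center, spec.radius_um)
        mirror_unit = (mirror - np.asarray(spec.center)) / spec.radius_um
        cosang = np.clip(unit[si] @ mirror_unit.T, -1.0, 1.0)
        geo = spec.radius_um * np.arccos(cosang)  # (n_src, n_tgt)
        weights[np.ix_(si, ti)] = (
            spec.peak_weight * np.exp(-(geo**2) / spec.sigma_true_um**2)
            + spec.background_weight
        )
    return VoxelConnectome(
        positions=positions,
        labels=labels,
        weights=weights,
        meta={"sigma_true_um": spec.sigma_true_um, "seed": spec.seed},
    )


@dataclass(frozen=True)
class ResponseGenSpec:
    n_images: int = 118
    n_neurons: int = 50
    n_trials: int = 50
    signal_var: float = 1.0
    noise_var: float = 1.0
    rectify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_var < 0 or self.noise_var < 0:
            raise InvalidInputError("variances must be nonnegative")

    @property
    def expected_reliability(self) -> float:
        """Closed-form split-half reliability of trial-half averages."""
        half = self.n_trials // 2
        denom = self.signal_var + self.noise_var / half
        return self.signal_var / denom if denom > 0 else 0.0


def gen_responses(spec: ResponseGenSpec) -> np.ndarray:
    """images x neurons x trials tensor: per-(image, neuron) signal plus
    i.i.d. trial noise, optionally rectified for calcium-like nonnegativity."""
    rng = np.random.default_rng(spec.seed)
    signal = rng.normal(
        0.0, np.sqrt(spec.signal_var), (spec.n_images, spec.n_neurons)
    )
    noise = rng.normal(
        0.0,
        np.sqrt(spec.noise_var),
        (spec.n_images, spec.n_neurons, spec.n_trials),
    )
    T = signal[:, :, None] + noise
    if spec.rectify:
        T = np.maximum(T, 0.0)
    return T


@dataclass(frozen=True)
class StimulusGenSpec:
    directions_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    spatial_freqs: tuple[float, ...] = (0.08,)
    phases: tuple[float, ...] = (0.0,)
    size: int = 64
    n_natural: int = 118
    natural_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        dirs = [d % 180.0 for d in self.directions_deg]
        if len(set(dirs)) != len(dirs):
            raise InvalidInputError("grating directions must be distinct mod 180")


def gen_gratings(spec: StimulusGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal gratings (n, size, size) plus per-image direction labels
    [degrees]."""
    x = np.arange(spec.size)
    xx, yy = np.meshgrid(x, x, indexing="xy")
    images, labels = [], []
    for theta_deg in spec.directions_deg:
        theta = np.deg2rad(theta_deg)
        for f in spec.spatial_freqs:
            for phase in spec.phases:
                img = np.sin(
                    2 * np.pi * f * (xx * np.cos(theta) + yy * np.sin(theta))
                    + phase
                )
                images.append(img)
                labels.append(theta_deg)
    return np.stack(images), np.asarray(labels)


def gen_natural_like(spec: StimulusGenSpec) -> np.ndarray:
    """1/f-filtered noise images (n, size, size), a stand-in for the natural
    image probe set (which is not redistributable)."""
    rng = np.random.default_rng(spec.seed)
    fy = np.fft.fftfreq(spec.size)[:, None]
    fx = np.fft.fftfreq(spec.size)[None, :]
    f = np.hypot(fx, fy)
    f[0, 0] = 1.0
    filt = 1.0 / f**spec.natural_exponent
    filt[0, 0] = 0.0
    out = []
    for _ in range(spec.n_natural):
        white = rng.normal(size=(spec.size, spec.size))
        img = np.fft.ifft2(np.fft.fft2(white) * filt).real
        img = (img - img.mean()) / (img.std() + 1e-12)
        out.append(img)
    return np.stack(out)


def to_rgb_batch(images: np.ndarray) -> np.ndarray:
    """(n, h, w) grayscale stack -> (n, 3, h, w) network input batch."""
    return np.repeat(images[:, None, :, :], 3, axis=1)
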