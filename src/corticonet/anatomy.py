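"""Laminar neuron censuses and interlaminar connection statistics.

Turns structured anatomical tables (excitatory densities, 10-um voxel counts,
cross-species Gaussian connection widths, offset connection probabilities)
into per-region neuron counts and interlaminar Gaussian parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError, InvalidInputError

LAYERS = ("L4", "L2/3", "L5")

#: Volume of a single (10 um)^3 voxel, in mm^3.
VOXEL_VOLUME_MM3 = 1e-6

#: Feedforward interlaminar projections used inside each area.
FEEDFORWARD_LAMINAR = (("L4", "L2/3"), ("L2/3", "L5"))


def average_density(densities: Sequence[float]) -> float:
    """Arithmetic mean density over a set of areas for one layer.

    Parameters
    ----------
    densities:
        Per-area excitatory densities [neurons/mm^3]; must be nonempty and
        strictly positive.
    """
    if len(densities) == 0:
        raise InvalidInputError("cannot average an empty density list")
    if any(d <= 0 for d in densities):
        raise InvalidInputError("densities must be positive")
    return float(sum(densities)) / len(densities)


def neuron_count(density: float, voxels: float) -> int:
    """Estimated excitatory neuron count from density and 10-um voxel count.

    ``density * voxels * 1e-6 mm^3``, rounded half-away-from-zero to the
    nearest integer.  Rounding (not flooring) is the convention validated
    against the printed census.
    """
    if density < 0 or voxels < 0:
        raise InvalidInputError("density and voxel count must be nonnegative")
    return int(math.floor(density * voxels * VOXEL_VOLUME_MM3 + 0.5))


def scale_interlaminar_width(
    cat_width: float, mouse_ref: float = 114.0, cat_ref: float = 180.0
) -> float:
    """Scale a cat-cortex Gaussian width [um] to mouse cortex.

    Anchored on the L4->L4 pair: 114 um in mouse, 180 um in cat.
    """
    if cat_width <= 0:
        raise InvalidInputError("cat width must be positive")
    if mouse_ref <= 0 or cat_ref <= 0:
        raise InvalidInputError("reference widths must be positive")
    return cat_width * mouse_ref / cat_ref


def peak_from_offset(d75: float, dw: float, offset: float = 75.0) -> float:
    """Recover the Gaussian peak probability from the offset probability.

    ``d_p = d75 / exp(-offset^2 / (2 dw^2))``.  The result may exceed 1;
    capping happens when the binary mask is generated, not here.
    """
    if dw <= 0:
        raise InvalidInputError("Gaussian width must be positive")
    if not 0 <= d75 <= 1:
        raise InvalidInputError("d75 must be a probability")
    return d75 / math.exp(-(offset**2) / (2.0 * dw**2))


@dataclass(frozen=True)
class LaminarDensityTable:
    """Excitatory densities [neurons/mm^3] per (area, layer), plus the
    per-layer average used for areas without direct measurements."""

    densities: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for area, row in self.densities.items():
            for layer, d in row.items():
                if d <= 0:
                    raise InvalidInputError(
                        f"density for {area} {layer} must be positive"
                    )

    def layer_average(self, layer: str) -> float:
        return average_density([row[layer] for row in self.densities.values()])

    def density(self, area: str, layer: str) -> float:
        if area in self.densities:
            return self.densities[area][layer]
        return self.layer_average(layer)


@dataclass(frozen=True)
class VoxelCountTable:
    """Number of 10-um voxels per (area, layer)."""

    counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for area, row in self.counts.items():
            for layer, c in row.items():
                if c <= 0:
                    raise InvalidInputError(
                        f"voxel count for {area} {layer} must be positive"
                    )

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(self.counts)


@dataclass(frozen=True)
class RegionCensus:
    """Estimated excitatory neuron count per region, plus the dLGN count."""

    counts: Mapping[str, Mapping[str, int]]
    dlgn: int

    def count(self, area: str, layer: str) -> int:
        return self.counts[area][layer]


@dataclass(frozen=True)
class InterlaminarStats:
    """Gaussian parameters for source-layer -> target-layer connections.

    ``widths_cat`` are the measured cat-V1 widths [um]; ``widths_mouse`` are
    the mouse-scaled widths d_w [um]; ``d75`` the offset-75-um connection
    probabilities and ``d_peak`` the recovered Gaussian peaks d_p.
    """

    widths_cat: Mapping[str, Mapping[str, float]]
    widths_mouse: Mapping[str, Mapping[str, float]]
    d75: Mapping[str, Mapping[str, float]]
    d_peak: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for src in self.widths_mouse:
            for tgt, w in self.widths_mouse[src].items():
                if w <= 0:
                    raise InvalidInputError("widths must be positive")
                if self.d_peak[src][tgt] < self.d75[src][tgt]:
                    raise InvalidInputError(
                        f"peak probability below offset probability for "
                        f"{src}->{tgt}"
                    )

    def width(self, src_layer: str, tgt_layer: str) -> float:
        return self.widths_mouse[src_layer][tgt_layer]

    def peak(self, src_layer: str, tgt_layer: str) -> float:
        return self.d_peak[src_layer][tgt_layer]


@dataclass(frozen=True)
class AnatomyConfig:
    """Parsed anatomy config: all tables plus derived census and stats."""

    densities: LaminarDensityTable
    voxels: VoxelCountTable
    census: RegionCensus
    interlaminar: InterlaminarStats
    surface_areas: Mapping[str, Mapping[str, float]]
    in_degree: float
    dlgn_rf_degrees: float
    acuity: float
    dlgn_to_visp_kernel: int
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def areas(self) -> tuple[str, ...]:
        return self.voxels.areas


def build_census(
    densities: LaminarDensityTable, voxels: VoxelCountTable, dlgn: int
) -> RegionCensus:
    """Compute the per-region neuron census from densities and voxel counts.

    Areas absent from the density table use the per-layer average density.
    """
    counts: dict[str, dict[str, int]] = {}
    for area in voxels.areas:
        counts[area] = {
            layer: neuron_count(densities.density(area, layer), v)
            for layer, v in voxels.counts[area].items()
        }
    return RegionCensus(counts=counts, dlgn=dlgn)


def build_interlaminar_stats(
    widths_cat: Mapping[str, Mapping[str, float]],
    d75: Mapping[str, Mapping[str, float]],
    mouse_ref: float = 114.0,
    cat_ref: float = 180.0,
    offset: float = 75.0,
) -> InterlaminarStats:
    widths_mouse = {
        src: {
            tgt: scale_interlaminar_width(w, mouse_ref, cat_ref)
            for tgt, w in row.items()
        }
        for src, row in widths_cat.items()
    }
    d_peak = {
        src: {
            tgt: peak_from_offset(p, widths_mouse[src][tgt], offset)
            for tgt, p in row.items()
        }
        for src, row in d75.items()
    }
    return InterlaminarStats(
        widths_cat=widths_cat, widths_mouse=widths_mouse, d75=d75, d_peak=d_peak
    )


_REQUIRED_SECTIONS = (
    "densities",
    "voxel_counts",
    "interlaminar_widths_cat",
    "interlaminar_d75",
    "dlgn_count",
)


def load_anatomy(path: str | Path | None = None) -> AnatomyConfig:
    """Load an anatomy YAML config; ``None`` loads the shipped tables."""
    if path is None:
        text = (
            resources.files("corticonet").joinpath("data/anatomy.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    for section in _REQUIRED_SECTIONS:
        if section not in raw:
            raise ConfigurationError(f"anatomy config missing section {section!r}")

    densities = LaminarDensityTable(raw["densities"])
    voxels = VoxelCountTable(raw["voxel_counts"])
    census = build_census(densities, voxels, int(raw["dlgn_count"]))
    scaling = raw.get("width_scaling", {})
    stats = build_interlaminar_stats(
        raw["interlaminar_widths_cat"],
        raw["interlaminar_d75"],
        mouse_ref=float(scaling.get("mouse_um", 114.0)),
        cat_ref=float(scaling.get("cat_um", 180.0)),
        offset=float(raw.get("d75_offset_um", 75.0)),
    )
    return AnatomyConfig(
        densities=densities,
        voxels=voxels,
        census=census,
        interlaminar=stats,
        surface_areas=raw.get("surface_areas", {}),
        in_degree=float(raw.get("in_degree", 1000)),
        dlgn_rf_degrees=float(raw.get("dlgn_rf_degrees", 9.0)),
        acuity=float(raw.get("acuity_pixels_per_degree", 1.0)),
        dlgn_to_visp_kernel=int(raw.get("dlgn_to_visp_kernel", 3)),
        raw=raw,
    )
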