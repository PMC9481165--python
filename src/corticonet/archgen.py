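"""Compiles anatomy into a fully specified sparse convolutional architecture.

Determines channel counts from neuron censuses, kernel sizes and paddings
from Gaussian connection widths, Gaussian mask probability grids from peak
probabilities, and the 22-region feedforward DAG with its classifier head.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .anatomy import AnatomyConfig
from .errors import ConfigurationError, InvalidInputError
from .flatmap import InterarealProfile, estimate_interareal_peak

#: Lateral (intermediate-hierarchy) visual areas, in presentation order.
LATERAL_AREAS = ("VISal", "VISl", "VISli", "VISpl", "VISrl")

AREAS = ("VISp",) + LATERAL_AREAS + ("VISpor",)

_LAYER_SUFFIX = {"L4": "4", "L2/3": "2/3", "L5": "5"}


def region_name(area: str, layer: str) -> str:
    return area + _LAYER_SUFFIX[layer]


def channel_count(n: int, lx: int, ly: int) -> int:
    """Channels in a region: floor(neurons / grid size).

    Flooring (not rounding) is the convention validated against the printed
    channel table (e.g. 29.86 -> 29).
    """
    if lx <= 0 or ly <= 0:
        raise InvalidInputError("grid dimensions must be positive")
    if n < 0:
        raise InvalidInputError("neuron count must be nonnegative")
    return n // (lx * ly)


def pixel_scale(lx: int, ly: int, area_um2: float) -> float:
    """sigma_i = sqrt(lx*ly / a_i) [pixels/um], with a_i in um^2."""
    if area_um2 <= 0:
        raise InvalidInputError("surface area must be positive")
    return math.sqrt(lx * ly / area_um2)


def kernel_and_padding(
    d_w_um: float, sigma: float, stride: int
) -> tuple[int, int, float]:
    """Kernel size, padding and pixel-space width for one edge.

    ``dw_px = sigma * d_w``; ``k = 2 * floor(dw_px) + 1``; padding is
    ``ceil((k - s) / 2)``, which keeps the output grid exactly input/stride
    for every odd kernel at strides 1 and 2.
    """
    if d_w_um < 0:
        raise InvalidInputError("Gaussian width must be nonnegative")
    if sigma <= 0:
        raise InvalidInputError("pixel scale must be positive")
    if stride not in (1, 2):
        raise InvalidInputError("stride must be 1 or 2")
    dw_px = sigma * d_w_um
    k = 2 * math.floor(dw_px) + 1
    p = math.ceil((k - stride) / 2)
    return k, p, dw_px


def padding_for(k: int, stride: int) -> int:
    return math.ceil((k - stride) / 2)


def mask_probability_grid(k: int, d_p: float, dw_px: float) -> np.ndarray:
    """k x k grid of connection probabilities, Gaussian about the center.

    Entry at integer offset (u, v) is ``min(1, d_p * exp(-(u^2+v^2) /
    (2 dw_px^2)))``; peaks above 1 are capped here, at mask time.
    """
    if k % 2 == 0 or k < 1:
        raise InvalidInputError("kernel size must be odd and positive")
    if dw_px <= 0:
        raise InvalidInputError("pixel-space width must be positive")
    half = k // 2
    u = np.arange(-half, half + 1)
    r2 = u[:, None] ** 2 + u[None, :] ** 2
    return np.minimum(1.0, d_p * np.exp(-r2 / (2.0 * dw_px**2)))


def sample_mask(
    prob_grid: np.ndarray, cout: int, cin: int, seed: int
) -> np.ndarray:
    """Binary (cout, cin, k, k) mask with independent Bernoulli draws.

    The spatial probability profile is shared across channel pairs; draws are
    independent across all elements and reproducible given the seed.
    """
    grid = np.asarray(prob_grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random((cout, cin) + grid.shape)
    return (u < grid).astype(np.uint8)


@dataclass(frozen=True)
class RegionNode:
    """One cortical layer of one area (or dLGN / the input plane)."""

    name: str
    area: str
    layer: str | None
    neurons: int
    grid: tuple[int, int]
    channels: int
    area_mm2: float | None = None

    @property
    def sigma(self) -> float:
        """Pixel scale sigma_i [pixels/um]; requires a surface area."""
        if self.area_mm2 is None:
            raise InvalidInputError(f"region {self.name} has no surface area")
        return pixel_scale(self.grid[0], self.grid[1], self.area_mm2 * 1e6)


@dataclass(frozen=True)
class EdgeSpec:
    """One inter-region projection compiled to conv meta-parameters."""

    source: str
    target: str
    kernel: int
    stride: int
    padding: int
    dw_px: float | None = None
    d_p: float | None = None
    d_w_um: float | None = None
    masked: bool = True
    kernel_formula: int | None = None  # formula value when it deviates
    provenance: str = "generated"

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"

    def probability_grid(self) -> np.ndarray:
        if not self.masked:
            return np.ones((self.kernel, self.kernel))
        if self.dw_px is None or self.d_p is None:
            raise ConfigurationError(f"edge {self.name} lacks mask parameters")
        return mask_probability_grid(self.kernel, self.d_p, self.dw_px)


@dataclass
class ClassifierSpec:
    pool: tuple[int, int] = (4, 4)
    n_classes: int = 1000
    source_regions: tuple[str, ...] = ()

    def feature_width(self, channels: Mapping[str, int]) -> int:
        return self.pool[0] * self.pool[1] * sum(
            channels[r] for r in self.source_regions
        )


@dataclass
class ArchitectureGraph:
    """Feedforward DAG of regions and conv edges plus the classifier head."""

    regions: dict[str, RegionNode]
    edges: list[EdgeSpec]
    classifier: ClassifierSpec
    input_channels: int = 3
    input_grid: tuple[int, int] = (64, 64)
    mask_seed: int = 0
    meta: dict = field(default_factory=dict)

    def inbound(self, region: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.target == region]

    def outbound(self, region: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.source == region]

    def edge(self, source: str, target: str) -> EdgeSpec:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target}")

    def topological_order(self) -> list[str]:
        indeg = {r: 0 for r in self.regions}
        for e in self.edges:
            if e.source in self.regions:
                indeg[e.target] += 1
        ready = sorted(r for r, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            r = ready.pop(0)
            order.append(r)
            for e in self.outbound(r):
                indeg[e.target] -= 1
                if indeg[e.target] == 0:
                    ready.append(e.target)
        if len(order) != len(self.regions):
            raise ConfigurationError("architecture graph has a cycle")
        return order

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_channels": self.input_channels,
            "input_grid": list(self.input_grid),
            "mask_seed": self.mask_seed,
            "regions": [
                {
                    "name": r.name, "area": r.area, "layer": r.layer,
                    "neurons": r.neurons, "grid": list(r.grid),
                    "channels": r.channels, "area_mm2": r.area_mm2,
                }
                for r in self.regions.values()
            ],
            "edges": [
                {
                    "source": e.source, "target": e.target, "kernel": e.kernel,
                    "stride": e.stride, "padding": e.padding,
                    "dw_px": e.dw_px, "d_p": e.d_p, "d_w_um": e.d_w_um,
                    "masked": e.masked, "kernel_formula": e.kernel_formula,
                    "provenance": e.provenance,
                }
                for e in self.edges
            ],
            "classifier": {
                "pool": list(self.classifier.pool),
                "n_classes": self.classifier.n_classes,
                "source_regions": list(self.classifier.source_regions),
            },
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureGraph":
        regions = {
            r["name"]: RegionNode(
                name=r["name"], area=r["area"], layer=r["layer"],
                neurons=r["neurons"], grid=tuple(r["grid"]),
                channels=r["channels"], area_mm2=r["area_mm2"],
            )
            for r in d["regions"]
        }
        edges = [EdgeSpec(**e) for e in d["edges"]]
        cls_spec = ClassifierSpec(
            pool=tuple(d["classifier"]["pool"]),
            n_classes=d["classifier"]["n_classes"],
            source_regions=tuple(d["classifier"]["source_regions"]),
        )
        return cls(
            regions=regions, edges=edges, classifier=cls_spec,
            input_channels=d["input_channels"],
            input_grid=tuple(d["input_grid"]),
            mask_seed=d.get("mask_seed", 0), meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ArchitectureGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def channel_map(self) -> dict[str, int]:
        m = {r.name: r.channels for r in self.regions.values()}
        m["input"] = self.input_channels
        return m


def load_published_kernels(path: str | Path | None = None) -> dict[str, int]:
    if path is None:
        text = (
            resources.files("corticonet")
            .joinpath("data/published_kernels.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return {str(k): int(v) for k, v in yaml.safe_load(text).items()}


def _edge_list() -> list[tuple[str, str]]:
    """The published feedforward wiring (excluding the two subcortical edges)."""
    edges: list[tuple[str, str]] = []
    for area in AREAS:
        edges.append((region_name(area, "L4"), region_name(area, "L2/3")))
        edges.append((region_name(area, "L2/3"), region_name(area, "L5")))
    for layer in ("L4", "L2/3", "L5"):
        src = region_name("VISp", layer)
        for lat in LATERAL_AREAS:
            edges.append((src, region_name(lat, "L4")))
        edges.append((src, "VISpor4"))
    for lat in LATERAL_AREAS:
        for layer in ("L4", "L2/3", "L5"):
            edges.append((region_name(lat, layer), "VISpor4"))
    return edges


def build_graph(
    anatomy: AnatomyConfig,
    profiles: Mapping[tuple[str, str], InterarealProfile] | None = None,
    interlaminar_kernels: str = "formula",
    published_kernels: Mapping[str, int] | None = None,
    n_classes: int = 1000,
    mask_seed: int = 0,
    interareal_fractions: Mapping[str, Mapping[str, float]] | None = None,
) -> ArchitectureGraph:
    """Compile anatomy (and optional interareal profiles) into the full graph.

    Interlaminar kernels come from the width-to-pixels formula
    (``interlaminar_kernels="formula"``) or verbatim from the published table
    (``"published"``); either way, cells where the two disagree are flagged in
    ``meta["kernel_discrepancies"]`` rather than silently reconciled.

    Interareal mask parameters come from ``profiles`` (flat-map estimates)
    when given; otherwise the pixel-space width is inverted from the
    published kernel (``dw_px = k / 2``) and the peak probability from the
    in-degree relation, using ``interareal_fractions`` (target -> source ->
    weight fraction) or uniform fractions over each target's inbound edges.
    """
    if interlaminar_kernels not in ("formula", "published"):
        raise ConfigurationError(
            "interlaminar_kernels must be 'formula' or 'published'"
        )
    pub = dict(published_kernels or load_published_kernels())

    regions: dict[str, RegionNode] = {
        "dLGN": RegionNode(
            name="dLGN", area="dLGN", layer=None,
            neurons=anatomy.census.dlgn, grid=(64, 64),
            channels=channel_count(anatomy.census.dlgn, 64, 64),
        )
    }
    for area in AREAS:
        for layer in ("L4", "L2/3", "L5"):
            grid = (64, 64) if area == "VISp" else (32, 32)
            n = anatomy.census.count(area, layer)
            try:
                a_mm2 = anatomy.surface_areas[area][layer]
            except KeyError as exc:
                raise ConfigurationError(
                    f"missing surface area for {area} {layer}"
                ) from exc
            regions[region_name(area, layer)] = RegionNode(
                name=region_name(area, layer), area=area, layer=layer,
                neurons=n, grid=grid,
                channels=channel_count(n, *grid), area_mm2=a_mm2,
            )

    k_dlgn = 2 * int(anatomy.dlgn_rf_degrees * anatomy.acuity // 2) + 1
    edges: list[EdgeSpec] = [
        EdgeSpec(
            source="input", target="dLGN", kernel=k_dlgn, stride=1,
            padding=padding_for(k_dlgn, 1), masked=False,
            provenance="receptive-field",
        ),
        EdgeSpec(
            source="dLGN", target="VISp4",
            kernel=anatomy.dlgn_to_visp_kernel, stride=1,
            padding=padding_for(anatomy.dlgn_to_visp_kernel, 1), masked=False,
            provenance="receptive-field",
        ),
    ]

    discrepancies: dict[str, dict[str, int]] = {}
    interareal: list[tuple[str, str]] = []
    for src, tgt in _edge_list():
        s_node, t_node = regions[src], regions[tgt]
        stride = 2 if s_node.area == "VISp" and t_node.area != "VISp" else 1
        if s_node.area == t_node.area:  # interlaminar
            d_w = anatomy.interlaminar.width(s_node.layer, t_node.layer)
            d_p = anatomy.interlaminar.peak(s_node.layer, t_node.layer)
            k_formula, p, dw_px = kernel_and_padding(d_w, s_node.sigma, stride)
            k_pub = pub.get(f"{src}->{tgt}")
            if k_pub is not None and k_pub != k_formula:
                discrepancies[f"{src}->{tgt}"] = {
                    "formula": k_formula, "published": k_pub,
                }
            if interlaminar_kernels == "published" and k_pub is not None:
                k = k_pub
            else:
                k = k_formula
            edges.append(
                EdgeSpec(
                    source=src, target=tgt, kernel=k, stride=stride,
                    padding=padding_for(k, stride), dw_px=dw_px, d_p=d_p,
                    d_w_um=d_w,
                    kernel_formula=k_formula if k != k_formula else None,
                    provenance="interlaminar-statistics",
                )
            )
        else:
            interareal.append((src, tgt))

    # interareal edges: widths/peaks from flat-map profiles or published table
    inbound_count: dict[str, int] = {}
    for _, tgt in interareal:
        inbound_count[tgt] = inbound_count.get(tgt, 0) + 1
    for src, tgt in interareal:
        s_node = regions[src]
        t_node = regions[tgt]
        stride = 2 if s_node.area == "VISp" else 1
        if profiles is not None:
            key = (src, tgt)
            if key not in profiles:
                raise ConfigurationError(f"missing interareal profile for {src}->{tgt}")
            prof = profiles[key]
            k, p, dw_px = kernel_and_padding(prof.d_w, s_node.sigma, stride)
            d_p = prof.d_p
            d_w_um = prof.d_w
            provenance = "flatmap"
        else:
            name = f"{src}->{tgt}"
            if name not in pub:
                raise ConfigurationError(f"missing published kernel for {name}")
            k = pub[name]
            dw_px = k / 2.0
            if interareal_fractions is not None:
                frac = interareal_fractions[tgt][src]
            else:
                frac = 1.0 / inbound_count[tgt]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d_p = estimate_interareal_peak(
                    frac, 1.0, anatomy.in_degree, dw_px, s_node.channels
                )
            d_w_um = dw_px / s_node.sigma
            provenance = "published-kernel"
        edges.append(
            EdgeSpec(
                source=src, target=tgt, kernel=k, stride=stride,
                padding=padding_for(k, stride), dw_px=dw_px, d_p=d_p,
                d_w_um=d_w_um, provenance=provenance,
            )
        )

    classifier = ClassifierSpec(
        pool=(4, 4), n_classes=n_classes,
        source_regions=tuple(region_name(a, "L5") for a in AREAS),
    )
    graph = ArchitectureGraph(
        regions=regions, edges=edges, classifier=classifier,
        mask_seed=mask_seed,
        meta={
            "kernel_discrepancies": discrepancies,
            "interlaminar_kernels": interlaminar_kernels,
            "interareal_source": "flatmap" if profiles is not None
            else "published-kernel",
        },
    )
    _check_spatial_bookkeeping(graph)
    return graph


def _check_spatial_bookkeeping(graph: ArchitectureGraph) -> None:
    """Every edge must map its input grid exactly onto the target grid."""
    grids = {r.name: r.grid for r in graph.regions.values()}
    grids["input"] = graph.input_grid
    for e in graph.edges:
        lin = grids[e.source][0]
        lout = grids[e.target][0]
        produced = (lin + 2 * e.padding - e.kernel) // e.stride + 1
        if produced != lout:
            raise ConfigurationError(
                f"edge {e.name}: produces {produced}, target grid is {lout}"
            )


def count_parameters(
    graph: ArchitectureGraph, mode: str = "dense", seed: int | None = None
) -> int:
    """Parameter accounting for the compiled architecture.

    ``dense``: sum of c_in*c_out*k^2 over all conv edges.
    ``masked-expected``: dense weighted by each edge's mean mask probability
    (unmasked edges count fully).
    ``masked-sampled``: nonzeros of Bernoulli-sampled masks (uses ``seed`` or
    the graph's mask seed).
    ``classifier``: linear head weights plus biases.
    """
    channels = graph.channel_map()
    if mode == "classifier":
        c = graph.classifier
        return c.feature_width(channels) * c.n_classes + c.n_classes
    if mode not in ("dense", "masked-expected", "masked-sampled"):
        raise InvalidInputError(f"unknown counting mode {mode!r}")
    total: float = 0
    base = graph.mask_seed if seed is None else seed
    for i, e in enumerate(graph.edges):
        cin, cout = channels[e.source], channels[e.target]
        if mode == "dense" or not e.masked:
            total += cin * cout * e.kernel**2
        elif mode == "masked-expected":
            total += cin * cout * float(e.probability_grid().sum())
        else:
            mask = sample_mask(e.probability_grid(), cout, cin, base + i)
            total += int(mask.sum())
    return int(round(total))


def summarize(graph: ArchitectureGraph) -> str:
    """Printed channel/kernel summary, one row per conv edge."""
    channels = graph.channel_map()
    lines = [f"{'source':<14}{'target':<14}{'k':>4}{'s':>3}{'p':>3}{'ch_out':>8}"]
    for e in graph.edges:
        lines.append(
            f"{e.source + f'({channels[e.source]})':<14}{e.target:<14}"
            f"{e.kernel:>4}{e.stride:>3}{e.padding:>3}{channels[e.target]:>8}"
        )
    disc = graph.meta.get("kernel_discrepancies", {})
    for name, d in disc.items():
        lines.append(
            f"# {name}: published kernel {d['published']} vs formula {d['formula']}"
        )
    return "\n".join(lines)
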