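"""Executes a compiled architecture as a masked convolutional network.

A small NumPy runtime: masked convolutions (im2col), per-region batch
normalization + ReLU with multi-input summation, the concatenating classifier
head, and a momentum-SGD training harness that preserves mask sparsity after
every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .archgen import ArchitectureGraph, sample_mask
from .errors import InvalidInputError, TrainingError, WiringError


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if s == 1:
        phases = {(0, 0): xp}
    else:
        # contiguous per-phase subsampled copies keep the k^2 gather fast
        phases = {
            (a, b): np.ascontiguousarray(xp[:, :, a::s, b::s])
            for a in range(s)
            for b in range(s)
        }
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            ph = phases[(i % s, j % s)]
            cols[:, :, i, j] = ph[:, :, i // s : i // s + ho, j // s : j // s + wo]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(
    gcols: np.ndarray, xshape: tuple, k: int, s: int, p: int, ho: int, wo: int
) -> np.ndarray:
    n, c, h, w = xshape
    g = gcols.reshape(n, c, k, k, ho, wo)
    gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + s * ho : s, j : j + s * wo : s] += g[:, :, i, j]
    return gx[:, :, p : p + h, p : p + w] if p else gx


class MaskedConv2d:
    """Conv layer whose weights are elementwise multiplied by a binary mask.

    The invariant ``weight * (1 - mask) == 0`` is maintained by ``apply_mask``
    which the optimizer calls after every update step.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int,
        padding: int,
        mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        # He/variance-scaled init on the dense kernel, applied before masking
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)
        ).astype(np.float32)
        self.mask = None if mask is None else np.asarray(mask, dtype=np.float32)
        self.stride, self.padding, self.k = stride, padding, k
        self.grad = np.zeros_like(self.weight)
        self._cache: tuple | None = None
        self.apply_mask()

    def apply_mask(self) -> None:
        if self.mask is not None:
            self.weight *= self.mask

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.padding)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = np.matmul(wmat, cols)  # (n, cout, ho*wo) via broadcasting
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xshape, cols, ho, wo = self._cache
        g = gout.reshape(gout.shape[0], gout.shape[1], -1)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        gw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        gw = gw.reshape(self.weight.shape)
        if self.mask is not None:
            gw *= self.mask
        self.grad += gw
        gcols = np.matmul(wmat.T, g)
        return _col2im(gcols, xshape, self.k, self.stride, self.padding, ho, wo)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv) if training else None
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.ggamma += (gout * xhat).sum(axis=(0, 2, 3))
        self.gbeta += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma[None, :, None, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return gx


class Linear:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.weight = rng.normal(0.0, np.sqrt(1.0 / fin), (fout, fin)).astype(
            np.float32
        )
        self.bias = np.zeros(fout, dtype=np.float32)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gweight += gout.T @ self._x
        self.gbias += gout.sum(axis=0)
        return gout @ self.weight


def _avgpool(x: np.ndarray, out: int) -> np.ndarray:
    n, c, h, w = x.shape
    f = h // out
    return x.reshape(n, c, out, f, out, f).mean(axis=(3, 5))


def _avgpool_back(g: np.ndarray, h: int) -> np.ndarray:
    n, c, out, _ = g.shape
    f = h // out
    return np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)


@dataclass
class RegionState:
    bn: BatchNorm2d
    activation: np.ndarray | None = None
    preact: np.ndarray | None = None
    grad: np.ndarray | None = None


class Network:
    """Masked convolutional network executing an :class:`ArchitectureGraph`.

    Regions are evaluated in topological order; each region applies a single
    batch normalization and ReLU to the *sum* of its inbound conv outputs.
    The classifier average-pools the designated output regions to a fixed
    size, concatenates, and applies one linear map.
    """

    def __init__(self, graph: ArchitectureGraph, seed: int = 0, bias: bool = False):
        if bias:
            raise NotImplementedError("conv bias is disabled; BN follows every conv")
        self.graph = graph
        self.rng = np.random.default_rng(seed)
        channels = graph.channel_map()
        self.order = graph.topological_order()
        self.convs: dict[str, MaskedConv2d] = {}
        for i, e in enumerate(graph.edges):
            mask = None
            if e.masked:
                mask = sample_mask(
                    e.probability_grid(), channels[e.target], channels[e.source],
                    graph.mask_seed + i,
                )
            self.convs[e.name] = MaskedConv2d(
                channels[e.source], channels[e.target], e.kernel, e.stride,
                e.padding, mask=mask, rng=self.rng,
            )
        self.regions = {
            r: RegionState(bn=BatchNorm2d(channels[r])) for r in self.order
        }
        feat = graph.classifier.feature_width(channels)
        self.classifier = Linear(feat, graph.classifier.n_classes, self.rng)
        self._grids = {r.name: r.grid for r in graph.regions.values()}
        self._grids["input"] = graph.input_grid

    # -- forward -----------------------------------------------------------

    def forward(
        self, images: np.ndarray, training: bool = False
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Run the network; returns per-region activations and class logits."""
        x = np.asarray(images, dtype=np.float32)
        expected = (self.graph.input_channels,) + tuple(self.graph.input_grid)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise InvalidInputError(
                f"input must be (batch, {expected[0]}, {expected[1]}, "
                f"{expected[2]}), got {x.shape}"
            )
        acts: dict[str, np.ndarray] = {"input": x}
        for r in self.order:
            inbound = self.graph.inbound(r)
            total = None
            for e in inbound:
                src = acts[e.source]
                out = self.convs[e.name].forward(src)
                if out.shape[2] != self._grids[r][0]:
                    raise WiringError(
                        f"edge {e.name} produced spatial size {out.shape[2]}, "
                        f"region grid is {self._grids[r][0]}"
                    )
                total = out if total is None else total + out
            state = self.regions[r]
            state.preact = total
            state.activation = np.maximum(
                state.bn.forward(total, training=training), 0.0
            )
            acts[r] = state.activation
        feats = [
            _avgpool(acts[r], self.graph.classifier.pool[0]).reshape(len(x), -1)
            for r in self.graph.classifier.source_regions
        ]
        logits = self.classifier.forward(np.concatenate(feats, axis=1))
        return {r: acts[r] for r in self.order}, logits

    # -- backward / training ----------------------------------------------

    def zero_grad(self) -> None:
        for conv in self.convs.values():
            conv.grad[:] = 0
        for state in self.regions.values():
            state.bn.ggamma[:] = 0
            state.bn.gbeta[:] = 0
            state.grad = None
        self.classifier.gweight[:] = 0
        self.classifier.gbias[:] = 0

    def backward(self, glogits: np.ndarray) -> None:
        gfeat = self.classifier.backward(glogits)
        pool = self.graph.classifier.pool[0]
        channels = self.graph.channel_map()
        offset = 0
        for r in self.graph.classifier.source_regions:
            c = channels[r]
            width = c * pool * pool
            g = gfeat[:, offset : offset + width].reshape(-1, c, pool, pool)
            h = self._grids[r][0]
            gact = _avgpool_back(g, h)
            st = self.regions[r]
            st.grad = gact if st.grad is None else st.grad + gact
            offset += width
        for r in reversed(self.order):
            st = self.regions[r]
            if st.grad is None:
                continue
            grelu = st.grad * (st.activation > 0)
            gpre = st.bn.backward(grelu)
            for e in self.graph.inbound(r):
                gsrc = self.convs[e.name].backward(gpre)
                if e.source == "input":
                    continue
                src_state = self.regions[e.source]
                src_state.grad = (
                    gsrc if src_state.grad is None else src_state.grad + gsrc
                )

    def parameters(self):
        for name in sorted(self.convs):
            conv = self.convs[name]
            yield conv.weight, conv.grad, conv
        for r in self.order:
            bn = self.regions[r].bn
            yield bn.gamma, bn.ggamma, None
            yield bn.beta, bn.gbeta, None
        yield self.classifier.weight, self.classifier.gweight, None
        yield self.classifier.bias, self.classifier.gbias, None

    def apply_masks(self) -> None:
        for conv in self.convs.values():
            conv.apply_mask()

    def mask_violation(self) -> float:
        """Max |weight| on masked-out positions; exactly 0 when the invariant
        holds."""
        worst = 0.0
        for conv in self.convs.values():
            if conv.mask is not None:
                worst = max(worst, float(np.abs(conv.weight * (1 - conv.mask)).max()))
        return worst

    def calibrate_bn(self, images: np.ndarray, batch: int = 32) -> None:
        """One statistics-calibration pass for untrained-network analyses."""
        for i in range(0, len(images), batch):
            self.forward(images[i : i + batch], training=True)

    def extract_layer_activations(
        self, images: np.ndarray, region: str, batch: int = 16
    ) -> np.ndarray:
        """images x (c*h*w) matrix of flattened eval-mode activations."""
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}")
        rows = []
        for i in range(0, len(images), batch):
            acts, _ = self.forward(images[i : i + batch], training=False)
            rows.append(acts[region].reshape(acts[region].shape[0], -1))
        return np.concatenate(rows, axis=0)

    # -- weights I/O -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, conv in self.convs.items():
            out[f"conv/{name}/weight"] = conv.weight
            if conv.mask is not None:
                out[f"conv/{name}/mask"] = conv.mask
        for r, st in self.regions.items():
            out[f"bn/{r}/gamma"] = st.bn.gamma
            out[f"bn/{r}/beta"] = st.bn.beta
            out[f"bn/{r}/running_mean"] = st.bn.running_mean
            out[f"bn/{r}/running_var"] = st.bn.running_var
        out["classifier/weight"] = self.classifier.weight
        out["classifier/bias"] = self.classifier.bias
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, conv in self.convs.items():
            conv.weight[:] = d[f"conv/{name}/weight"]
            if conv.mask is not None and f"conv/{name}/mask" in d:
                conv.mask = np.asarray(d[f"conv/{name}/mask"], dtype=float)
        for r, st in self.regions.items():
            st.bn.gamma[:] = d[f"bn/{r}/gamma"]
            st.bn.beta[:] = d[f"bn/{r}/beta"]
            st.bn.running_mean[:] = d[f"bn/{r}/running_mean"]
            st.bn.running_var[:] = d[f"bn/{r}/running_var"]
        self.classifier.weight[:] = d["classifier/weight"]
        self.classifier.bias[:] = d["classifier/bias"]


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(labels)
    loss = -logp[np.arange(n), labels].mean()
    g = np.exp(logp)
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n


class SGD:
    """Momentum SGD that re-applies conv masks after every step."""

    def __init__(self, network: Network, lr: float = 0.01, momentum: float = 0.9):
        self.network = network
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p) for p, _, _ in network.parameters()]

    def step(self) -> None:
        for v, (p, g, layer) in zip(self.velocity, self.network.parameters()):
            v *= self.momentum
            v += g
            p -= self.lr * v
        self.network.apply_masks()


def train_step(
    network: Network, optimizer: SGD, images: np.ndarray, labels: np.ndarray
) -> float:
    """One SGD step; returns the batch loss.  Masked weights stay zero."""
    network.zero_grad()
    _, logits = network.forward(images, training=True)
    loss, glogits = softmax_cross_entropy(logits, np.asarray(labels))
    if not np.isfinite(loss):
        raise TrainingError(f"non-finite loss {loss}")
    network.backward(glogits)
    optimizer.step()
    return loss
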