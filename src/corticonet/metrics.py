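"""Functional-comparison statistics for model and neural representations.

Similarity matrices and their Spearman comparison (SSM), split-half
reliability and thresholded noise ceilings, lifetime sparseness, circular
selectivity, Jensen-Shannon distances, and the MDS layout / diversity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon
from sklearn.manifold import MDS

from .errors import EstimationError, InvalidInputError


@dataclass
class SimilarityResult:
    """Pearson similarity matrix with bookkeeping of excluded rows."""

    matrix: np.ndarray
    excluded: tuple[int, ...] = ()


def similarity_matrix(R: np.ndarray) -> SimilarityResult:
    """n x n Pearson correlations between the image rows of a representation.

    Rows with zero variance cannot be correlated; their entries are NaN and
    the row indices are reported in ``excluded`` rather than propagated
    silently.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise InvalidInputError("representation must be (n>=2) x units")
    sd = R.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R)
    C[constant, :] = np.nan
    C[:, constant] = np.nan
    np.fill_diagonal(C, 1.0)
    return SimilarityResult(matrix=C, excluded=tuple(constant.tolist()))


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def ssm(A: np.ndarray | SimilarityResult, B: np.ndarray | SimilarityResult) -> float:
    """Spearman rank correlation of two similarity matrices.

    Flattens the upper triangles (excluding the constant diagonal, which
    would otherwise bias the rank correlation); NaN pairs are dropped.
    """
    Am = A.matrix if isinstance(A, SimilarityResult) else np.asarray(A, dtype=float)
    Bm = B.matrix if isinstance(B, SimilarityResult) else np.asarray(B, dtype=float)
    if Am.shape != Bm.shape:
        raise InvalidInputError("similarity matrices must have the same shape")
    a, b = _upper(Am), _upper(Bm)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise EstimationError("not enough finite similarity pairs")
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)


def _half_splits(t: int, n_splits: int, rng: np.random.Generator):
    half = t // 2
    for _ in range(n_splits):
        perm = rng.permutation(t)
        yield perm[:half], perm[half : 2 * half]


def split_half_reliability(
    T: np.ndarray, n_splits: int = 10, seed: int = 0
) -> np.ndarray:
    """Per-neuron split-half reliability of an images x neurons x trials tensor.

    For each of ``n_splits`` random disjoint half-splits of the trials, the
    Pearson correlation across images between the two half-averaged responses
    is computed; the reliability is the mean over splits.  Neurons constant
    across images get NaN (recorded as missing, not an error).
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 3:
        raise InvalidInputError("response tensor must be images x neurons x trials")
    n, m, t = T.shape
    if t < 2:
        raise InvalidInputError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    acc = np.zeros(m)
    count = np.zeros(m)
    for ia, ib in _half_splits(t, n_splits, rng):
        a = T[:, :, ia].mean(axis=2)
        b = T[:, :, ib].mean(axis=2)
        sa, sb = a.std(axis=0), b.std(axis=0)
        # tolerance absorbs float jitter in means of truly constant neurons
        tol_a = 1e-10 * (np.abs(a).max(axis=0) + 1.0)
        tol_b = 1e-10 * (np.abs(b).max(axis=0) + 1.0)
        ok = (sa > tol_a) & (sb > tol_b)
        az = (a - a.mean(axis=0)) / np.where(sa == 0, 1, sa)
        bz = (b - b.mean(axis=0)) / np.where(sb == 0, 1, sb)
        r = (az * bz).mean(axis=0)
        acc[ok] += r[ok]
        count[ok] += 1
    out = np.full(m, np.nan)
    good = count > 0
    out[good] = acc[good] / count[good]
    return out


def noise_ceiling(
    T: np.ndarray,
    threshold: float = -np.inf,
    n_splits: int = 10,
    seed: int = 0,
    reliability: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and sd over splits of the self-SSM across disjoint trial halves.

    Restricted to neurons whose split-half reliability exceeds ``threshold``.
    """
    T = np.asarray(T, dtype=float)
    if reliability is None:
        reliability = split_half_reliability(T, n_splits=n_splits, seed=seed)
    keep = np.flatnonzero(np.nan_to_num(reliability, nan=-np.inf) > threshold)
    if len(keep) < 2:
        raise EstimationError(
            f"fewer than 2 neurons pass reliability threshold {threshold}"
        )
    sub = T[:, keep, :]
    rng = np.random.default_rng(seed + 1)
    vals = []
    for ia, ib in _half_splits(sub.shape[2], n_splits, rng):
        A = similarity_matrix(sub[:, :, ia].mean(axis=2))
        B = similarity_matrix(sub[:, :, ib].mean(axis=2))
        vals.append(ssm(A, B))
    return float(np.mean(vals)), float(np.std(vals))


def best_noise_ceiling(
    T: np.ndarray,
    thresholds: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """(threshold, ceiling) maximizing the noise ceiling over a grid.

    Ties break toward the lowest threshold (more neurons retained).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise InvalidInputError("threshold grid must be nonempty")
    reliability = split_half_reliability(T, n_splits=n_splits, seed=seed)
    best: tuple[float, float] | None = None
    for th in np.sort(thresholds):
        try:
            mean, _ = noise_ceiling(
                T, threshold=th, n_splits=n_splits, seed=seed,
                reliability=reliability,
            )
        except EstimationError:
            continue
        if best is None or mean > best[1] + 1e-12:
            best = (float(th), mean)
    if best is None:
        raise EstimationError("no threshold leaves >= 2 neurons")
    return best


def lifetime_sparseness(r: np.ndarray) -> float:
    """Normalized selectivity of per-condition mean responses, in [0, 1].

    ``(1 - (sum r)^2 / (N sum r^2)) / (1 - 1/N)``: 1 for a one-hot response
    profile, 0 for a uniform one.  All-zero responses are undefined (NaN).
    """
    r = np.asarray(r, dtype=float)
    N = r.size
    if N < 2:
        raise InvalidInputError("need at least 2 stimulus conditions")
    s2 = float((r**2).sum())
    if s2 == 0:
        return float("nan")
    return (1.0 - (float(r.sum()) ** 2 / s2) / N) / (1.0 - 1.0 / N)


def circular_selectivity(r: np.ndarray, theta: np.ndarray) -> float:
    """Magnitude of the doubled-angle resultant: ``|sum r e^{2i theta}| / sum r``.

    One minus the circular variance over orientations; angles in radians.
    Zero total response is undefined (NaN).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if r.shape != theta.shape:
        raise InvalidInputError("responses and angles must align")
    total = float(r.sum())
    if total == 0:
        return float("nan")
    resultant = np.abs(np.sum(r * np.exp(2j * theta)))
    return float(resultant / total)


def js_distance(
    sample1: np.ndarray,
    sample2: np.ndarray,
    bins: int = 50,
    range_: tuple[float, float] | None = None,
) -> float:
    """Jensen-Shannon distance (base-2) between two samples' histograms.

    Histograms share ``bins`` equal-width bins spanning the pooled sample
    range unless an explicit range is given; the result lies in [0, 1].
    """
    s1 = np.asarray(sample1, dtype=float).ravel()
    s2 = np.asarray(sample2, dtype=float).ravel()
    if s1.size == 0 or s2.size == 0:
        raise InvalidInputError("samples must be nonempty")
    if range_ is None:
        lo = min(s1.min(), s2.min())
        hi = max(s1.max(), s2.max())
        if hi == lo:
            hi = lo + 1.0
        range_ = (lo, hi)
    h1, edges = np.histogram(s1, bins=bins, range=range_)
    h2, _ = np.histogram(s2, bins=edges)
    return float(jensenshannon(h1, h2, base=2))


def mds_layout_and_diversity(
    ssm_matrix: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Metric MDS layout of layers (distance = 1 - SSM) and diversity index.

    The diversity index is the product of the singular values of the centered
    2D coordinate set; identical layers (pairwise SSM 1) give 0.
    """
    S = np.asarray(ssm_matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidInputError("SSM matrix must be square")
    if S.shape[0] < 3:
        raise EstimationError("need at least 3 layers for an MDS layout")
    if not np.allclose(S, S.T):
        raise InvalidInputError("SSM matrix must be symmetric")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    mds = MDS(
        n_components=2, metric="precomputed", init="classical_mds",
        random_state=seed, normalized_stress=False,
    )
    coords = mds.fit_transform(D)
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return coords, float(np.prod(sv[:2]))
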