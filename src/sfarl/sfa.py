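"""Slow feature analysis primitives and the trainable hierarchy node.

Slow feature analysis (SFA) finds instantaneous input-output functions
``g_j`` whose outputs ``y_j(t) = g_j(x(t))`` vary as slowly as possible
over time, measured by the delta value

    Delta(y_j) = < (dy_j/dt)^2 >_t

subject to zero mean, unit variance, and mutual decorrelation of the
outputs.  For a linear (or linearly expanded) function space the optimum
is the solution of a generalized symmetric eigenproblem on the pair
(difference covariance, signal covariance): the eigenvectors with the
smallest eigenvalues are the slowest directions and the eigenvalues are
their delta values.

A hierarchy node composes: additive Gaussian noise (a numerical
safeguard against singular covariances, applied only while accumulating
training statistics) -> linear SFA -> quadratic expansion -> linear SFA
-> clipping.  Linear SFA on the quadratically expanded signal is
equivalent to SFA over the space of polynomials of degree up to two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


class InvalidInputError(ValueError):
    """Raised when an input violates an operation's preconditions."""


def _as_timeseries(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InvalidInputError(f"expected a (T, d) time-series matrix, got shape {x.shape}")
    return x


def delta_value(y) -> np.ndarray:
    """Per-channel slowness measure: mean squared forward difference.

    The temporal derivative is approximated by the forward difference
    ``y(t+1) - y(t)`` (T-1 derivative samples), so a constant channel
    has delta 0 and an uncorrelated unit-variance channel has delta 2.
    """
    y = _as_timeseries(y)
    if y.shape[0] < 2:
        raise InvalidInputError("delta_value needs at least 2 samples")
    d = np.diff(y, axis=0)
    return np.mean(d * d, axis=0)


class SfaStats:
    """Accumulates the first/second moments and the difference covariance.

    Time series may be fed in several chunks (e.g. one receptive-field
    location at a time under weight sharing); temporal differences are
    taken only within each chunk, never across chunk boundaries.
    """

    def __init__(self, dim: int):
        self.dim = int(dim)
        self._n = 0
        self._sum = np.zeros(dim)
        self._outer = np.zeros((dim, dim))
        self._dn = 0
        self._douter = np.zeros((dim, dim))

    def update(self, x) -> None:
        x = _as_timeseries(x)
        if x.shape[1] != self.dim:
            raise InvalidInputError(f"expected {self.dim} channels, got {x.shape[1]}")
        self._n += x.shape[0]
        self._sum += x.sum(axis=0)
        self._outer += x.T @ x
        if x.shape[0] >= 2:
            dx = np.diff(x, axis=0)
            self._dn += dx.shape[0]
            self._douter += dx.T @ dx

    @property
    def n_samples(self) -> int:
        return self._n

    def moments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._n < 2 or self._dn < 1:
            raise InvalidInputError("need at least 2 samples to form SFA statistics")
        mean = self._sum / self._n
        cov = self._outer / self._n - np.outer(mean, mean)
        dcov = self._douter / self._dn
        return mean, cov, dcov


@dataclass
class LinearSFAModel:
    """A fitted linear stage: ``y = (x - input_mean) @ projection``.

    For the slowness criterion ``delta_values`` holds the per-component
    delta values in ascending order and the outputs are zero-mean,
    unit-variance, decorrelated on the training data.  For the variance
    criterion (PCA baseline node) ``delta_values`` holds the explained
    variances in descending order and the projection is orthonormal
    (components are not whitened).
    """

    input_mean: np.ndarray
    projection: np.ndarray
    delta_values: np.ndarray
    criterion: str = "slowness"

    @property
    def input_dim(self) -> int:
        return self.projection.shape[0]

    @property
    def output_dim(self) -> int:
        return self.projection.shape[1]

    def apply(self, x) -> np.ndarray:
        return apply_linear_sfa(self, x)


def apply_linear_sfa(model: LinearSFAModel, x) -> np.ndarray:
    """Instantaneous application; accepts any number of samples (T >= 1)."""
    x = _as_timeseries(x)
    if x.shape[1] != model.input_dim:
        raise InvalidInputError(
            f"model expects {model.input_dim} channels, got {x.shape[1]}"
        )
    return (x - model.input_mean) @ model.projection


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # Sign convention: the loading of largest magnitude is positive.
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


_COV_REG = 1e-10  # relative ridge on the covariance before eigendecomposition


def _solve_from_moments(
    mean: np.ndarray,
    cov: np.ndarray,
    dcov: np.ndarray,
    out_dim: int,
    criterion: str,
) -> LinearSFAModel:
    d = cov.shape[0]
    if not (1 <= out_dim <= d):
        raise InvalidInputError(f"out_dim {out_dim} not in [1, {d}]")
    if criterion == "slowness":
        trace = np.trace(cov)
        eps = _COV_REG * (trace / d if trace > 0 else 1.0)
        eigvals, eigvecs = scipy.linalg.eigh(
            dcov, cov + eps * np.eye(d), subset_by_index=(0, out_dim - 1)
        )
        # eigh normalizes v^T C v = 1 -> unit output variance on training data
        proj = np.ascontiguousarray(_fix_signs(eigvecs))
        return LinearSFAModel(mean, proj, eigvals, criterion="slowness")
    if criterion == "variance":
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1][:out_dim]
        proj = np.ascontiguousarray(_fix_signs(eigvecs[:, order]))
        return LinearSFAModel(mean, proj, eigvals[order], criterion="variance")
    raise InvalidInputError(f"unknown criterion {criterion!r}")


def fit_linear_sfa_from_stats(
    stats: SfaStats, out_dim: int, criterion: str = "slowness"
) -> LinearSFAModel:
    mean, cov, dcov = stats.moments()
    return _solve_from_moments(mean, cov, dcov, out_dim, criterion)


def fit_linear_sfa(x, out_dim: int, criterion: str = "slowness") -> LinearSFAModel:
    """Fit one linear SFA (or PCA) stage on a single time series."""
    x = _as_timeseries(x)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("input contains non-finite values")
    stats = SfaStats(x.shape[1])
    stats.update(x)
    return fit_linear_sfa_from_stats(stats, out_dim, criterion)


def expanded_dim(d: int) -> int:
    """Dimensionality after quadratic expansion: d + d(d+1)/2."""
    return d + d * (d + 1) // 2


def quadratic_expand(x) -> np.ndarray:
    """Append all degree-2 monomials ``x_i * x_j`` (i <= j).

    Output order: the d original channels first, then the products in
    row-major upper-triangular order (0,0), (0,1), ..., (0,d-1), (1,1),
    (1,2), ..., (d-1,d-1).  This order is part of the serialization
    contract for fitted nodes.
    """
    x = _as_timeseries(x)
    T, d = x.shape
    out = np.empty((T, expanded_dim(d)), dtype=np.float64)
    out[:, :d] = x
    off = d
    for i in range(d):  # row-major upper triangle, one stripe at a time
        n = d - i
        np.multiply(x[:, i : i + 1], x[:, i:], out=out[:, off : off + n])
        off += n
    return out


def add_gaussian_noise(x, variance: float, rng: np.random.Generator) -> np.ndarray:
    """Elementwise i.i.d. zero-mean Gaussian noise; variance 0 is the identity."""
    x = _as_timeseries(x)
    if variance < 0:
        raise InvalidInputError("noise variance must be >= 0")
    if variance == 0:
        return x.copy()
    return x + rng.normal(0.0, np.sqrt(variance), size=x.shape)


def clip_signal(x, bound: float) -> np.ndarray:
    """Clamp all entries to [-bound, +bound]; removes extreme test-set values."""
    if bound <= 0:
        raise InvalidInputError("clip bound must be > 0")
    return np.clip(_as_timeseries(x), -bound, bound)


@dataclass(frozen=True)
class NodeSpec:
    """Per-node configuration.

    noise_variance : variance of the training-time Gaussian safeguard
    sfa1_dim       : outputs kept by the first linear stage
    sfa2_dim       : outputs kept after the quadratic expansion
    clip_bound     : symmetric output clamp (None disables)
    criterion      : "slowness" (SFA node) or "variance" (PCA node)
    """

    sfa1_dim: int
    sfa2_dim: int
    noise_variance: float = 1e-4
    clip_bound: float | None = 4.0
    criterion: str = "slowness"

    def __post_init__(self):
        if self.sfa1_dim < 1 or self.sfa2_dim < 1:
            raise InvalidInputError("sfa1_dim and sfa2_dim must be positive")
        if self.noise_variance < 0:
            raise InvalidInputError("noise_variance must be >= 0")
        if self.clip_bound is not None and self.clip_bound <= 0:
            raise InvalidInputError("clip_bound must be > 0 or None")
        if self.sfa2_dim > expanded_dim(self.sfa1_dim):
            raise InvalidInputError(
                f"sfa2_dim {self.sfa2_dim} exceeds expanded dimensionality "
                f"{expanded_dim(self.sfa1_dim)}"
            )


@dataclass
class SFANode:
    """One trained hierarchy node: sfa1 -> quadratic expansion -> sfa2 -> clip.

    Application is deterministic; the training-time noise is never
    re-applied at apply time so the closed control loop is reproducible.
    """

    spec: NodeSpec
    sfa1: LinearSFAModel
    sfa2: LinearSFAModel

    @property
    def input_dim(self) -> int:
        return self.sfa1.input_dim

    @property
    def output_dim(self) -> int:
        return self.sfa2.output_dim

    def apply(self, x) -> np.ndarray:
        y1 = self.sfa1.apply(x)
        y2 = self.sfa2.apply(quadratic_expand(y1))
        if self.spec.clip_bound is not None:
            y2 = clip_signal(y2, self.spec.clip_bound)
        return y2


def apply_sfa_node(node: SFANode, x) -> np.ndarray:
    return node.apply(x)


def _noise_rng(seed_root: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed_root), int(index)]))


def fit_sfa_node_streamed(series_factory, input_dim: int, spec: NodeSpec, seed: int) -> SFANode:
    """Fit a node from an iterable of time-series chunks.

    ``series_factory()`` must return a fresh iterable of (T_i, input_dim)
    arrays each time it is called (one chunk per receptive-field location
    under weight sharing).  Two passes are made: one to fit the first
    linear stage and one to fit the second stage on the expanded outputs.
    The Gaussian safeguard noise is derived per chunk index from ``seed``
    so both passes see identical noisy data.
    """
    stats1 = SfaStats(input_dim)
    for i, x in enumerate(series_factory()):
        stats1.update(add_gaussian_noise(x, spec.noise_variance, _noise_rng(seed, i)))
    if spec.sfa1_dim > input_dim:
        raise InvalidInputError(
            f"sfa1_dim {spec.sfa1_dim} exceeds input dimensionality {input_dim}"
        )
    sfa1 = fit_linear_sfa_from_stats(stats1, spec.sfa1_dim, spec.criterion)

    stats2 = SfaStats(expanded_dim(spec.sfa1_dim))
    for i, x in enumerate(series_factory()):
        xn = add_gaussian_noise(x, spec.noise_variance, _noise_rng(seed, i))
        stats2.update(quadratic_expand(sfa1.apply(xn)))
    sfa2 = fit_linear_sfa_from_stats(stats2, spec.sfa2_dim, spec.criterion)
    return SFANode(spec=spec, sfa1=sfa1, sfa2=sfa2)


def fit_sfa_node(x, spec: NodeSpec, rng: np.random.Generator | int | None = None) -> SFANode:
    """Fit a node on a single time series."""
    x = _as_timeseries(x)
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    elif rng is None:
        seed = 0
    else:
        seed = int(rng)
    return fit_sfa_node_streamed(lambda: [x], x.shape[1], spec, seed)
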