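"""Pooled 1-D Gaussian-mixture discretization and spatial patterns.

The core idea: pool the windowed RMS amplitudes of *all* channels into
one 1-D sample, fit a K-component Gaussian mixture to it by
expectation-maximization, and replace every channel's continuous
amplitude by the index of its maximum-posterior component. Components
are relabeled in ascending-mean order after fitting, so index 0 always
means "quietest". Arranging one window's per-channel indices on the
electrode grid yields a simplified 2-D spatial activation pattern — a
compact, discrete description of which muscle regions are how active,
usable both for motion classification and for channel selection.

The EM fit here is written out explicitly (it is the method under
study); scikit-learn's ``GaussianMixture`` serves as an independent
cross-check in the test-suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.metrics import mutual_info_score

from .features import FeatureSeries
from .layout import ElectrodeLayout

UNOCCUPIED = -1  # sentinel for grid cells with no electrode

VARIANCE_FLOOR_FRACTION = 1e-6  # floor = fraction * pooled variance


@dataclass
class GmmModel:
    """A fitted 1-D Gaussian mixture, amplitude-ordered.

    ``weights``, ``means`` (μV) and ``variances`` (μV²) each have
    length ``K`` with means strictly ascending. ``log_likelihood`` is
    the total training log-likelihood at convergence.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_training: int
    converged: bool
    iterations: int
    variance_floor: float
    floor_hit: bool = False
    degenerate: bool = False
    ll_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("weights, means, variances must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("means must be ascending (amplitude-ordered)")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "variances": [float(v) for v in self.variances],
            "log_likelihood": float(self.log_likelihood),
            "n_training": int(self.n_training),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "variance_floor": float(self.variance_floor),
            "floor_hit": bool(self.floor_hit),
            "degenerate": bool(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GmmModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            n_training=int(d["n_training"]),
            converged=bool(d["converged"]),
            iterations=int(d["iterations"]),
            variance_floor=float(d["variance_floor"]),
            floor_hit=bool(d.get("floor_hit", False)),
            degenerate=bool(d.get("degenerate", False)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GmmModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SpatialPattern:
    """One window's grid of per-channel cluster indices.

    ``grid`` is ``rows x cols`` of integers in ``[0, K-1]``, with
    ``UNOCCUPIED`` (−1) in cells that hold no electrode.
    """

    grid: np.ndarray
    K: int
    layout: ElectrodeLayout
    window_time: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        occupied = self.grid != UNOCCUPIED
        if np.any((self.grid[occupied] < 0) | (self.grid[occupied] >= self.K)):
            raise ValueError(f"cluster indices must lie in [0, {self.K - 1}]")

    def flatten(self) -> np.ndarray:
        """Recover the per-channel index row through the layout."""
        pos = self.layout.positions()
        return self.grid[pos[:, 0], pos[:, 1]]


# -- EM fit --------------------------------------------------------------


def _log_pdf_matrix(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
                    variances: np.ndarray) -> np.ndarray:
    """log(w_k * N(x_i; mu_k, var_k)) as an (n, K) matrix."""
    diff = x[:, None] - means[None, :]
    return (np.log(weights) - 0.5 * np.log(2 * np.pi * variances))[None, :] \
        - diff**2 / (2 * variances)[None, :]


def _em_run(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
            variances: np.ndarray, max_iter: int, tol: float, floor: float):
    """One EM run from a given start; returns params, ll history, convergence."""
    n = len(x)
    K = len(means)
    ll_history = []
    prev_ll = -np.inf
    converged = False
    it = 0
    floor_hit = False
    xc = x[:, None]
    x2 = x * x
    log_joint = np.empty((n, K))
    resp = np.empty((n, K))
    for it in range(1, max_iter + 1):
        # E-step: log_joint[i,k] = log w_k + log N(x_i; mu_k, var_k)
        np.subtract(xc, means[None, :], out=log_joint)
        np.square(log_joint, out=log_joint)
        log_joint *= -0.5 / variances[None, :]
        log_joint += np.log(weights) - 0.5 * np.log(2 * np.pi * variances)
        row_max = log_joint.max(axis=1)
        np.subtract(log_joint, row_max[:, None], out=resp)
        np.exp(resp, out=resp)
        row_sum = resp.sum(axis=1)
        ll = float(np.log(row_sum).sum() + row_max.sum())
        resp /= row_sum[:, None]
        ll_history.append(ll)
        if prev_ll > -np.inf:
            denom = max(abs(prev_ll), 1.0)
            if (ll - prev_ll) / denom < tol:
                converged = True
                break
        prev_ll = ll
        # M-step via sufficient statistics: var_k = E_k[x^2] - mu_k^2
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        weights = nk / n
        means = x @ resp / nk
        variances = x2 @ resp / nk - means**2
        if np.any(variances < floor):
            floor_hit = True
        variances = np.maximum(variances, floor)
    return weights, means, variances, np.array(ll_history), converged, it, floor_hit


def quantile_init(x: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic start: means at the (2i+1)/(2K) quantiles, pooled
    variance for every component, uniform weights."""
    qs = (2 * np.arange(K) + 1) / (2 * K)
    means = np.quantile(x, qs)
    pooled_var = float(np.var(x))
    variances = np.full(K, max(pooled_var, 1e-12))
    weights = np.full(K, 1.0 / K)
    return weights, means, variances


def fit_gmm(features: FeatureSeries | np.ndarray, K: int, max_iter: int = 500,
            tol: float = 1e-8, seed: int = 0, n_restarts: int = 5,
            init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None) -> GmmModel:
    """Fit a 1-D Gaussian mixture to the pooled per-channel RMS sample.

    The first start is the deterministic quantile initialization; the
    remaining ``n_restarts - 1`` starts perturb it with seeded noise,
    and the run with the best final log-likelihood wins. An explicit
    ``init`` (weights, means, variances) suppresses restarts — used for
    like-for-like comparison against reference implementations.
    Components are relabeled by ascending mean after fitting.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    x = features.values.ravel() if isinstance(features, FeatureSeries) else \
        np.asarray(features, dtype=float).ravel()
    n = len(x)
    if n < 10 * K:
        raise ValueError(f"need >= {10 * K} pooled samples for K={K}, got {n}")

    n_distinct = len(np.unique(x))
    degenerate = False
    if n_distinct < K:
        if n_distinct == 1:
            degenerate = True
            K = 1
        else:
            raise ValueError(
                f"K={K} exceeds the number of distinct amplitudes ({n_distinct})"
            )

    pooled_var = float(np.var(x))
    floor = max(VARIANCE_FLOOR_FRACTION * pooled_var, 1e-30)

    if degenerate:
        model = GmmModel(
            weights=np.ones(1), means=np.array([float(x[0])]),
            variances=np.array([floor]),
            log_likelihood=float(
                _log_pdf_matrix(x, np.ones(1), np.array([x[0]]),
                                np.array([floor])).sum()
            ),
            n_training=n, converged=True, iterations=0,
            variance_floor=floor, floor_hit=True, degenerate=True,
        )
        return model

    starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    if init is not None:
        w0, m0, v0 = (np.asarray(a, dtype=float).copy() for a in init)
        starts = [(w0, m0, np.maximum(v0, floor))]
    else:
        rng = np.random.default_rng(seed)
        w0, m0, v0 = quantile_init(x, K)
        starts = [(w0, m0, v0)]
        spread = float(np.std(x)) or 1.0
        for _ in range(max(n_restarts - 1, 0)):
            mj = np.sort(m0 + rng.normal(0, 0.25 * spread, K))
            starts.append((w0.copy(), mj, v0.copy()))

    best = None
    for w0, m0, v0 in starts:
        w, m, v, ll_hist, conv, iters, hit = _em_run(
            x, w0, m0, v0, max_iter, tol, floor
        )
        final_ll = ll_hist[-1] if len(ll_hist) else -np.inf
        if best is None or final_ll > best[3][-1]:
            best = (w, m, v, ll_hist, conv, iters, hit)

    w, m, v, ll_hist, conv, iters, hit = best
    order = np.argsort(m, kind="stable")
    return GmmModel(
        weights=w[order], means=m[order], variances=v[order],
        log_likelihood=float(ll_hist[-1]), n_training=n,
        converged=conv, iterations=iters, variance_floor=floor,
        floor_hit=hit, ll_history=ll_hist,
    )


# -- discretization and patterns -----------------------------------------


def discretize(features: FeatureSeries | np.ndarray, model: GmmModel) -> np.ndarray:
    """Map every amplitude to its maximum-posterior component index.

    Ties break toward the lower index; indices refer to the
    amplitude-ordered components (0 = quietest cluster). The result has
    the shape of the input values.
    """
    values = features.values if isinstance(features, FeatureSeries) else \
        np.asarray(features, dtype=float)
    flat = values.ravel()
    log_joint = _log_pdf_matrix(flat, model.weights, model.means, model.variances)
    idx = np.argmax(log_joint, axis=1)  # argmax takes the first (lowest) maximum
    return idx.reshape(values.shape)


def to_spatial_pattern(index_row: np.ndarray, layout: ElectrodeLayout, K: int,
                       window_time: float | None = None) -> SpatialPattern:
    """Place one window's per-channel cluster indices on the electrode grid."""
    index_row = np.asarray(index_row, dtype=int)
    if index_row.shape != (layout.n_channels,):
        raise ValueError(
            f"index row of length {index_row.size} for layout with "
            f"{layout.n_channels} channels"
        )
    if np.any((index_row < 0) | (index_row >= K)):
        raise ValueError(f"cluster indices must lie in [0, {K - 1}]")
    grid = np.full((layout.rows, layout.cols), UNOCCUPIED, dtype=int)
    pos = layout.positions()
    grid[pos[:, 0], pos[:, 1]] = index_row
    return SpatialPattern(grid, K, layout, window_time)


def modal_pattern(index_rows: np.ndarray, layout: ElectrodeLayout, K: int
                  ) -> SpatialPattern:
    """Per-channel modal (most frequent) index across windows, as a pattern."""
    index_rows = np.atleast_2d(np.asarray(index_rows, dtype=int))
    modal = np.empty(index_rows.shape[1], dtype=int)
    for c in range(index_rows.shape[1]):
        counts = np.bincount(index_rows[:, c], minlength=K)
        modal[c] = int(np.argmax(counts))
    return to_spatial_pattern(modal, layout, K)


# -- channel selection ----------------------------------------------------


def select_channels(index_rows: np.ndarray, labels: np.ndarray
                    ) -> list[tuple[int, float]]:
    """Rank channels by how informative their cluster index is about motion.

    The score is the mutual information, in bits, between a channel's
    per-window cluster index and the motion label, estimated from the
    empirical joint frequencies. Returns ``(channel_index, bits)``
    sorted by descending score (ties by channel index), deterministic.
    """
    index_rows = np.atleast_2d(np.asarray(index_rows, dtype=int))
    labels = np.asarray(labels)
    if index_rows.shape[0] != labels.shape[0]:
        raise ValueError("index_rows and labels must have equal length")
    classes = np.unique(labels.astype(str))
    if len(classes) < 2:
        raise ValueError("channel selection requires at least 2 classes")
    scores = []
    for c in range(index_rows.shape[1]):
        mi_nats = mutual_info_score(labels.astype(str), index_rows[:, c])
        scores.append((c, float(mi_nats / np.log(2))))
    return sorted(scores, key=lambda s: (-s[1], s[0]))


def bic_scan(features: FeatureSeries | np.ndarray, k_values, seed: int = 0
             ) -> list[tuple[int, float]]:
    """Report (K, BIC) over candidate mixture counts; lower BIC is better.

    Report-only: automatic K selection is deliberately not the default.
    """
    x = features.values.ravel() if isinstance(features, FeatureSeries) else \
        np.asarray(features, dtype=float).ravel()
    out = []
    for k in k_values:
        model = fit_gmm(x, k, seed=seed)
        n_params = 3 * model.K - 1
        bic = n_params * np.log(len(x)) - 2 * model.log_likelihood
        out.append((k, float(bic)))
    return out


def render_pattern(pattern: SpatialPattern, path, title: str | None = None) -> None:
    """Save a figure of the spatial pattern (grid of cluster indices)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    masked = np.ma.masked_equal(pattern.grid, UNOCCUPIED)
    im = ax.imshow(masked, cmap="viridis", vmin=0, vmax=pattern.K - 1)
    for (r, c), val in np.ndenumerate(pattern.grid):
        if val != UNOCCUPIED:
            ax.text(c, r, str(val), ha="center", va="center", color="w")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="cluster index")
    fig.savefig(path, dpi=100)
    plt.close(fig)
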