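"""Clustering local-interaction maps into shared spatial communication patterns.

Each eligible ligand-receptor pair contributes one signal over the M
locations (binary locally-significant indicators or the continuous
``1 - p_local`` strengths). Pairs are modeled as a mixture of Gaussian-
process pattern surfaces: pattern c has a latent mean surface
``mu_c ~ N(0, K)`` with squared-exponential kernel
``K(d) = exp(-d^2 / (2 l^2)) + noise_floor*I``, and a pair assigned to c is
observed as ``x ~ N(mu_c, sigma^2 I)``. Fitting is MAP expectation-
maximization: responsibilities in the E-step, exact posterior-mean surface,
mixing weights and noise updates in the M-step, so the penalized
log-likelihood is non-decreasing.

The block-sparse variant approximates K block-diagonally over spatially
contiguous groups of about ``group_size`` locations (seeded k-means on the
coordinates), dropping the per-iteration cost from O(M^3) to
O(M * group_size^2); a single block recovers the full model exactly.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans


def build_pattern_input(result, mode: str = "binary") -> tuple[np.ndarray, np.ndarray]:
    """Matrix [eligible pairs x M] for pattern clustering.

    ``binary`` rows are the locally-significant indicators; ``continuous``
    rows are ``1 - p_local``. Returns ``(X, eligible_pair_positions)``.
    """
    if "eligible" not in result.pairs.columns:
        raise ValueError("run select_pairs before building pattern input")
    eligible = np.flatnonzero(result.pairs["eligible"].to_numpy())
    if eligible.size == 0:
        raise ValueError("no eligible pairs for pattern analysis")
    if mode == "binary":
        X = result.x_bin[:, eligible].T.astype(float)
    elif mode == "continuous":
        X = result.x_con[:, eligible].T
    else:
        raise ValueError("mode must be 'binary' or 'continuous'")
    return X, eligible


def _blocks(coords: np.ndarray, group_size: int, seed: int) -> list[np.ndarray]:
    """Spatially contiguous location blocks of about ``group_size``."""
    M = coords.shape[0]
    n_blocks = max(1, int(round(M / group_size)))
    if n_blocks == 1:
        return [np.arange(M)]
    km = KMeans(n_clusters=n_blocks, n_init=4, random_state=seed)
    labels = km.fit_predict(coords)
    return [np.flatnonzero(labels == b) for b in range(n_blocks)]


class SpatialPatternMixture:
    """Scikit-learn style estimator for spatial pattern clustering.

    Parameters
    ----------
    n_patterns : number of pattern surfaces (user-set; no model selection).
    lengthscale : squared-exponential kernel lengthscale in coordinate units.
    group_size : covariance block size; ``None`` or >= M fits the full
        dense-covariance model (guarded at M <= 5000).
    noise_floor : jitter added to the kernel diagonal.
    low_rank_dim : per-block eigenvalue cap carried as an opaque passthrough
        (kept for config compatibility; ``None`` disables truncation).

    Fitted attributes: ``labels_``, ``responsibilities_``,
    ``pattern_means_`` ([M x n_patterns]), ``loglik_trace_``, ``sigma2_``.
    """

    _FULL_GUARD = 5000

    def __init__(
        self,
        n_patterns: int = 3,
        lengthscale: float | str = "auto",
        group_size: int | None = None,
        noise_floor: float = 1e-5,
        low_rank_dim: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-5,
        seed: int = 0,
    ):
        self.n_patterns = n_patterns
        self.lengthscale = lengthscale
        self.group_size = group_size
        self.noise_floor = noise_floor
        self.low_rank_dim = low_rank_dim
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_patterns", "lengthscale", "group_size", "noise_floor",
                "low_rank_dim", "max_iter", "tol", "seed",
            )
        }

    def set_params(self, **params) -> "SpatialPatternMixture":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, coords: np.ndarray) -> "SpatialPatternMixture":
        """Fit the mixture to ``X`` ([pairs x M]) on location ``coords``."""
        X = np.asarray(X, dtype=float)
        coords = np.asarray(coords, dtype=float)
        G, M = X.shape
        if coords.shape[0] != M:
            raise ValueError("coords must have one row per location")
        C = self.n_patterns
        if self.group_size is not None:
            if self.group_size > M:
                raise ValueError("group_size cannot exceed the location count")
            blocks = _blocks(coords, self.group_size, self.seed)
        else:
            if M > self._FULL_GUARD:
                raise ValueError(
                    f"M={M} exceeds the dense-covariance guard "
                    f"({self._FULL_GUARD}); use the block-sparse variant "
                    "(set group_size)"
                )
            blocks = [np.arange(M)]

        ls = self._resolve_lengthscale(coords)
        # eigendecompose the kernel once per block; every EM iteration then
        # costs O(block_size^2) per block and component
        eigs, vecs, logdets = [], [], []
        for b in blocks:
            d2 = (
                (coords[b, None, :] - coords[None, b, :]) ** 2
            ).sum(axis=2)
            Kb = np.exp(-d2 / (2.0 * ls**2)) + self.noise_floor * np.eye(len(b))
            lam, Q = np.linalg.eigh(Kb)
            if self.low_rank_dim is not None and self.low_rank_dim < len(b):
                # cap the spectrum: keep the top-d eigenvalues, clamp the rest
                lam = lam.copy()
                lam[: len(b) - self.low_rank_dim] = self.noise_floor
            lam = np.maximum(lam, 1e-12)
            eigs.append(lam)
            vecs.append(Q)
            logdets.append(float(np.log(lam).sum()))

        rng = np.random.default_rng(self.seed)
        km = KMeans(n_clusters=min(C, G), n_init=4,
                    random_state=int(rng.integers(2**31 - 1)))
        init_labels = km.fit_predict(X) if G >= C else np.arange(G) % C
        resp = np.full((G, C), 1e-3)
        resp[np.arange(G), init_labels % C] = 1.0
        resp /= resp.sum(axis=1, keepdims=True)

        pi = np.full(C, 1.0 / C)
        sigma2 = max(float(X.var()), 1e-4)
        mu = np.zeros((M, C))
        trace = []
        prev = -np.inf
        for _ in range(self.max_iter):
            # M-step: posterior-mean surfaces given responsibilities,
            # mu = K (Nc K + s2 I)^-1 s  in the kernel eigenbasis
            Nc = resp.sum(axis=0)  # [C]
            S = X.T @ resp  # [M, C] weighted sums
            for c in range(C):
                for b, lam, Q in zip(blocks, eigs, vecs):
                    proj = Q.T @ S[b, c]
                    mu[b, c] = Q @ (lam / (Nc[c] * lam + sigma2) * proj)
            pi = np.maximum(Nc / G, 1e-12)
            pi /= pi.sum()
            # noise update with the new surfaces
            resid = 0.0
            for c in range(C):
                diff = X - mu[:, c][None, :]
                resid += (resp[:, c][:, None] * diff**2).sum()
            sigma2 = max(resid / (G * M), 1e-8)

            # E-step + penalized log-likelihood
            log_lik = np.empty((G, C))
            for c in range(C):
                diff = X - mu[:, c][None, :]
                log_lik[:, c] = (
                    -0.5 * (diff**2).sum(axis=1) / sigma2
                    - 0.5 * M * np.log(2 * np.pi * sigma2)
                    + np.log(pi[c])
                )
            mmax = log_lik.max(axis=1, keepdims=True)
            lse = mmax.ravel() + np.log(
                np.exp(log_lik - mmax).sum(axis=1)
            )
            prior = 0.0
            for c in range(C):
                for b, lam, Q, ld in zip(blocks, eigs, vecs, logdets):
                    proj = Q.T @ mu[b, c]
                    prior += (
                        -0.5 * float((proj**2 / lam).sum())
                        - 0.5 * ld
                        - 0.5 * len(b) * np.log(2 * np.pi)
                    )
            objective = float(lse.sum() + prior)
            resp = np.exp(log_lik - lse[:, None])
            trace.append(objective)
            if objective - prev < self.tol and len(trace) > 1:
                break
            prev = objective

        self.responsibilities_ = resp
        self.labels_ = np.argmax(resp, axis=1)  # ties -> lowest index
        self.pattern_means_ = mu
        self.loglik_trace_ = np.asarray(trace)
        self.sigma2_ = sigma2
        self.mixing_ = pi
        self.blocks_ = blocks
        return self

    def _resolve_lengthscale(self, coords: np.ndarray) -> float:
        if self.lengthscale != "auto":
            return float(self.lengthscale)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(coords).query(coords, k=2)
        med = float(np.median(d[:, 1]))
        if med <= 0:
            raise ValueError("cannot infer lengthscale from duplicate coords")
        return 2.0 * med


def fit_aeh_full(
    X: np.ndarray, coords: np.ndarray, n_patterns: int,
    lengthscale: float | str = "auto", seed: int = 0, **kw,
) -> SpatialPatternMixture:
    """Dense-covariance fit (exact model; guarded to M <= 5000)."""
    return SpatialPatternMixture(
        n_patterns=n_patterns, lengthscale=lengthscale, group_size=None,
        seed=seed, **kw,
    ).fit(X, coords)


def fit_aeh_sparse(
    X: np.ndarray, coords: np.ndarray, n_patterns: int,
    group_size: int = 16, lengthscale: float | str = "auto", seed: int = 0,
    **kw,
) -> SpatialPatternMixture:
    """Block-sparse covariance fit for large location counts."""
    return SpatialPatternMixture(
        n_patterns=n_patterns, lengthscale=lengthscale, group_size=group_size,
        seed=seed, **kw,
    ).fit(X, coords)


def match_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relabel ``b`` by the best bipartite match against ``a``."""
    from scipy.optimize import linear_sum_assignment

    ka, kb = a.max() + 1, b.max() + 1
    k = max(ka, kb)
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -np.sum((a == i) & (b == j))
    rows, cols = linear_sum_assignment(cost)
    mapping = {c: r for r, c in zip(rows, cols)}
    return np.array([mapping[x] for x in b])
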