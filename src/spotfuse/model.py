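"""Autoencoder-embedded contrastive model fusing tile features and expression.

Four trainable maps are learned jointly: an image-feature autoencoder
(encoder ``g1: R^C -> R^h``, decoder ``f1``), an expression autoencoder
(encoder ``g2: R^p -> R^h``, decoder ``f2`` ending in softplus so predicted
expression is non-negative), an InfoNCE contrastive alignment between
spot-level projections of the two latent spaces, and a trans-modality loss
that decodes image latents into expression, sums a spot's tiles, and
compares against the measured spot profile. Total objective::

    L = w1*L_image + w2*L_expr + w3*L_infonce + w4*L_cross

The reconstruction and cross losses are row-plus-column cosine dissimilarity
means; the InfoNCE denominator excludes the positive pair (the form this
model family defines), with the standard denominator available as a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Parameter, Tensor

logger = logging.getLogger(__name__)

_EPS = 1e-30


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``batch_pairs`` is K: each step samples K/2 spots forming K/2 positive
    image-expression pairs (all cross pairs negative). Defaults follow the
    published settings: K=64 for Visium (640 for VisiumHD), temperature
    tau=0.03, all loss weights 1.
    """

    K: int = 64
    tau: float = 0.03
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0
    epochs: int = 500
    lr: float = 1e-3
    seed: int = 0
    train_fraction: float = 0.8
    hidden_dim: int = 128
    expr_loss: str = "cosine"  # or "mse"
    standard_infonce: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.K % 2:
            raise ValueError("K must be even")
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass
class LossBreakdown:
    loss_image: float
    loss_expr: float
    loss_infonce: float
    loss_cross: float
    loss_total: float


# ---------------------------------------------------------------------------
# losses (autodiff graph builders; accept Tensor or ndarray)
# ---------------------------------------------------------------------------


def _cos_terms(A: Tensor, B: Tensor, axis: int) -> Tensor:
    """Mean of (1 - cosine) along one axis; zero-norm vectors count cos=0."""
    dot = (A * B).sum(axis=axis)
    na = (A * A).sum(axis=axis).sqrt()
    nb = (B * B).sum(axis=axis).sqrt()
    cos = dot / (na * nb).maximum(_EPS)
    return (1.0 - cos).mean()


def cosine_row_col_loss(A, B) -> Tensor:
    """Row-wise plus column-wise mean cosine dissimilarity of two matrices.

    ``(1/nr) sum_i (1-cos(A_i., B_i.)) + (1/nc) sum_j (1-cos(A_.j, B_.j))``;
    rows or columns with zero norm contribute 1 (cosine defined as 0).
    """
    A, B = Tensor.as_tensor(A), Tensor.as_tensor(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    return _cos_terms(A, B, axis=1) + _cos_terms(A, B, axis=0)


def mse_loss(A, B) -> Tensor:
    A, B = Tensor.as_tensor(A), Tensor.as_tensor(B)
    diff = A - B
    return (diff * diff).mean()


def l2_normalize_rows(H: Tensor) -> Tensor:
    norm = (H * H).sum(axis=1, keepdims=True).sqrt().maximum(_EPS)
    return H / norm


def infonce_loss(H_img, H_expr, tau: float, standard: bool = False) -> Tensor:
    """Temperature-scaled contrastive loss on matched projection rows.

    Projections are L2-normalized; row k of each matrix is the positive
    pair. By default the denominator sums only the mismatched pairs
    (``l != k``), so the value can be negative; ``standard=True`` includes
    the positive term as in the common InfoNCE form.
    """
    H_img, H_expr = Tensor.as_tensor(H_img), Tensor.as_tensor(H_expr)
    K = H_img.shape[0]
    if K < 2:
        raise ValueError("InfoNCE needs at least 2 pairs")
    Hi = l2_normalize_rows(H_img)
    He = l2_normalize_rows(H_expr)
    S = (Hi @ He.T) * (1.0 / tau)  # [K, K]
    eye = np.eye(K)
    pos = (S * eye).sum(axis=1)  # diagonal
    # stabilized log-sum-exp over the masked denominator
    rowmax = S.data.max(axis=1, keepdims=True)  # constant shift
    expS = (S - rowmax).exp()
    mask = np.ones((K, K)) if standard else (1.0 - eye)
    denom = ((expS * mask).sum(axis=1)).log() + Tensor(rowmax.ravel())
    return -(pos - denom).sum()


def cross_modal_loss(Y, tile_features_pred: Tensor, l: int) -> Tensor:
    """Trans-modality loss: per-spot sum of decoded tiles vs measured spots.

    ``tile_features_pred`` is the decoded expression of all tiles, grouped
    as ``l`` consecutive rows per spot; the prediction for spot k is the sum
    of its ``l`` tile rows, compared to ``Y`` with the row+column cosine
    loss.
    """
    Y = Tensor.as_tensor(Y)
    n, p = Y.shape
    if tile_features_pred.shape[0] != n * l:
        raise ValueError(
            f"ragged tile groups: {tile_features_pred.shape[0]} tile rows "
            f"for {n} spots with l={l}"
        )
    per_spot = tile_features_pred.reshape(n, l, p).sum(axis=1)
    return cosine_row_col_loss(Y, per_spot)


# ---------------------------------------------------------------------------
# MLP blocks
# ---------------------------------------------------------------------------


class _MLP:
    """Two-layer perceptron ``in -> hidden (tanh) -> out`` with optional softplus."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng, softplus_out=False):
        s1 = np.sqrt(2.0 / (n_in + n_hidden))
        s2 = np.sqrt(2.0 / (n_hidden + n_out))
        self.W1 = Parameter(rng.standard_normal((n_in, n_hidden)) * s1)
        self.b1 = Parameter(np.zeros(n_hidden))
        self.W2 = Parameter(rng.standard_normal((n_hidden, n_out)) * s2)
        self.b2 = Parameter(np.zeros(n_out))
        self.softplus_out = softplus_out

    def __call__(self, X: Tensor) -> Tensor:
        X = Tensor.as_tensor(X)
        H = (X @ self.W1 + self.b1).tanh()
        out = H @ self.W2 + self.b2
        return out.softplus() if self.softplus_out else out

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def state(self):
        return [p.data.copy() for p in self.params]

    def load(self, state):
        for p, s in zip(self.params, state):
            p.data = s.copy()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class ContrastiveImputation:
    """Scikit-learn style estimator for image-to-expression translation.

    Parameters mirror :class:`TrainConfig`; after :meth:`fit` the trained
    maps live in ``g1_``, ``f1_``, ``g2_``, ``f2_`` and the per-epoch loss
    log in ``log_`` (a DataFrame). :meth:`predict` decodes tile features to
    non-negative tile-level expression via ``f2(g1(x))``.
    """

    def __init__(
        self,
        hidden_dim: int = 128,
        K: int = 64,
        tau: float = 0.03,
        w1: float = 1.0,
        w2: float = 1.0,
        w3: float = 1.0,
        w4: float = 1.0,
        epochs: int = 500,
        lr: float = 1e-3,
        seed: int = 0,
        train_fraction: float = 0.8,
        expr_loss: str = "cosine",
        standard_infonce: bool = False,
    ):
        self.hidden_dim = hidden_dim
        self.K = K
        self.tau = tau
        self.w1 = w1
        self.w2 = w2
        self.w3 = w3
        self.w4 = w4
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.train_fraction = train_fraction
        self.expr_loss = expr_loss
        self.standard_infonce = standard_infonce

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "hidden_dim",
                "K",
                "tau",
                "w1",
                "w2",
                "w3",
                "w4",
                "epochs",
                "lr",
                "seed",
                "train_fraction",
                "expr_loss",
                "standard_infonce",
            )
        }

    def set_params(self, **params) -> "ContrastiveImputation":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- training ----------------------------------------------------------
    def _losses(self, feats, Y, l, spot_idx):
        """Build the four-loss graph for the given spot subset.

        ``feats`` and ``Y`` are expected on the model's internal scale
        (columns divided by their training RMS, which keeps the tanh
        encoders in their active range; cosine objectives are unaffected
        by the per-row geometry this preserves).
        """
        X = Tensor(feats[_tile_rows(spot_idx, l)])
        Yb = Tensor(Y[spot_idx])
        Z = self.g1_(X)
        X_rec = self.f1_(Z)
        T = self.g2_(Yb)
        Y_rec = self.f2_(T)
        loss_image = cosine_row_col_loss(X, X_rec)
        if self.expr_loss == "mse":
            loss_expr = mse_loss(Yb, Y_rec)
        else:
            loss_expr = cosine_row_col_loss(Yb, Y_rec)
        # projections: image = normalized sum of a spot's tile latents,
        # expression = normalized spot latent
        h = self.hidden_dim
        H_img = Z.reshape(len(spot_idx), l, h).sum(axis=1)
        loss_nce = infonce_loss(H_img, T, self.tau, self.standard_infonce)
        pred_tiles = self.f2_(Z)
        loss_cross = cross_modal_loss(Yb, pred_tiles, l)
        total = (
            self.w1 * loss_image
            + self.w2 * loss_expr
            + self.w3 * loss_nce
            + self.w4 * loss_cross
        )
        return loss_image, loss_expr, loss_nce, loss_cross, total

    def fit(self, features: np.ndarray, Y: np.ndarray, l: int | None = None):
        """Train on within-spot tiles.

        ``features`` is ``[n_spots * l, C]`` with each spot's ``l`` tile
        rows consecutive; ``Y`` is the measured ``[n_spots, p]`` expression
        on the model's gene panel.
        """
        feats = np.asarray(features, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = Y.shape
        # per-column RMS scaling keeps the tanh encoders out of saturation
        self.feat_scale_ = np.maximum(np.sqrt((feats**2).mean(axis=0)), 1e-8)
        self.expr_scale_ = np.maximum(np.sqrt((Y**2).mean(axis=0)), 1e-8)
        feats = feats / self.feat_scale_
        Y = Y / self.expr_scale_
        if l is None:
            if feats.shape[0] % n:
                raise ValueError("feature rows not a multiple of spot count")
            l = feats.shape[0] // n
        if feats.shape[0] != n * l:
            raise ValueError("ragged tile groups: rows != n_spots * l")
        C = feats.shape[1]
        h = self.hidden_dim
        rng = np.random.default_rng(self.seed)
        self.g1_ = _MLP(C, 2 * h, h, rng)
        self.f1_ = _MLP(h, 2 * h, C, rng)
        self.g2_ = _MLP(p, 2 * h, h, rng)
        self.f2_ = _MLP(h, 2 * h, p, rng, softplus_out=True)
        self.l_ = l
        self.n_features_in_ = C

        order = rng.permutation(n)
        n_train = max(2, int(round(self.train_fraction * n)))
        train_idx, test_idx = order[:n_train], order[n_train:]

        half = self.K // 2
        if len(train_idx) < half:
            warnings.warn(
                f"batch size K/2={half} clipped to {len(train_idx)} training spots"
            )
            half = len(train_idx)
        if half < 2:
            raise ValueError("need at least 2 training spots")

        params = (
            self.g1_.params + self.f1_.params + self.g2_.params + self.f2_.params
        )
        opt = Adam(params, lr=self.lr)
        steps = max(1, len(train_idx) // half)
        log = []
        best = (np.inf, None)
        for epoch in range(self.epochs):
            perm = rng.permutation(train_idx)
            ep = np.zeros(5)
            for s in range(steps):
                batch = perm[s * half : (s + 1) * half]
                if len(batch) < 2:
                    continue
                li, le, ln, lc, lt = self._losses(feats, Y, l, batch)
                opt.zero_grad()
                lt.backward()
                opt.step()
                ep += [li.item(), le.item(), ln.item(), lc.item(), lt.item()]
            ep /= steps
            if len(test_idx) >= 2:
                *_, lc_h, _ = self._losses(feats, Y, l, test_idx)
                held = lc_h.item()
            else:
                held = ep[3]
            log.append(
                dict(
                    epoch=epoch,
                    loss_image=ep[0],
                    loss_expr=ep[1],
                    loss_infonce=ep[2],
                    loss_cross=ep[3],
                    loss_total=ep[4],
                    heldout_loss_cross=held,
                )
            )
            if held < best[0]:
                best = (
                    held,
                    [m.state() for m in (self.g1_, self.f1_, self.g2_, self.f2_)],
                )
        if best[1] is not None:
            for m, s in zip((self.g1_, self.f1_, self.g2_, self.f2_), best[1]):
                m.load(s)
        import pandas as pd

        self.log_ = pd.DataFrame(log)
        self.train_idx_ = train_idx
        self.test_idx_ = test_idx
        self.best_heldout_cross_ = best[0]
        return self

    # -- inference ---------------------------------------------------------
    def predict(self, features: np.ndarray) -> np.ndarray:
        """Tile-level non-negative expression ``f2(g1(x))`` per feature row."""
        self._check_fitted()
        feats = np.asarray(features, dtype=float)
        if feats.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {feats.shape[1]} != model C={self.n_features_in_}"
            )
        out = self.f2_(self.g1_(Tensor(feats / self.feat_scale_))).data
        return out * self.expr_scale_

    def project(self, features=None, Y=None, l: int | None = None):
        """L2-normalized spot-level projections of either modality."""
        self._check_fitted()
        out = []
        if features is not None:
            l = l or self.l_
            scaled = np.asarray(features, dtype=float) / self.feat_scale_
            Z = self.g1_(Tensor(scaled))
            n = Z.shape[0] // l
            H = Z.reshape(n, l, self.hidden_dim).sum(axis=1)
            out.append(l2_normalize_rows(H).data)
        if Y is not None:
            T = self.g2_(Tensor(np.asarray(Y, dtype=float) / self.expr_scale_))
            out.append(l2_normalize_rows(T).data)
        return out[0] if len(out) == 1 else tuple(out)

    def loss_breakdown(self, features, Y, l: int | None = None) -> LossBreakdown:
        self._check_fitted()
        l = l or self.l_
        n = np.asarray(Y).shape[0]
        li, le, ln, lc, lt = self._losses(
            np.asarray(features, float) / self.feat_scale_,
            np.asarray(Y, float) / self.expr_scale_,
            l,
            np.arange(n),
        )
        return LossBreakdown(li.item(), le.item(), ln.item(), lc.item(), lt.item())

    def _check_fitted(self) -> None:
        if not hasattr(self, "g1_"):
            raise RuntimeError("model is not fitted")


def _tile_rows(spot_idx: np.ndarray, l: int) -> np.ndarray:
    """Row indices of the tiles belonging to the given spots."""
    return (np.asarray(spot_idx)[:, None] * l + np.arange(l)[None, :]).ravel()


def train_fusion_model(features, Y, config: TrainConfig) -> ContrastiveImputation:
    """Functional wrapper: train a :class:`ContrastiveImputation` model."""
    est = ContrastiveImputation(
        hidden_dim=config.hidden_dim,
        K=config.K,
        tau=config.tau,
        w1=config.w1,
        w2=config.w2,
        w3=config.w3,
        w4=config.w4,
        epochs=config.epochs,
        lr=config.lr,
        seed=config.seed,
        train_fraction=config.train_fraction,
        expr_loss=config.expr_loss,
        standard_infonce=config.standard_infonce,
    )
    return est.fit(np.asarray(features, float), np.asarray(Y, float))
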