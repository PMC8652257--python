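"""Capsule model core: per-source encoders and dynamic-routing classification.

Forward pass, per sample:

1. each source block ``x_i`` (length ``r_i``) is standardized into a primary
   capsule ``u_i = tanh(Wp_i x_i)`` of length ``n``;
2. prediction vectors ``u_hat[j|i] = W_ij u_i`` (length ``m``);
3. dynamic routing: logits ``b_ij`` start at zero; each iteration computes
   couplings ``c_i = softmax(b_i)`` over the type axis, weighted sums
   ``s_j = sum_i c_ij u_hat[j|i]``, and on non-final iterations overwrites
   ``b_ij`` with ``u_hat[j|i] . normalize(s_j)``;
4. type capsules ``v_j = squash(s_j)``; class score = ``||v_j||``.

Everything is plain dense NumPy (float64). Gradients are hand-derived and
verified against central differences in the test suite; no autodiff
framework is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .sources import ModularDataset, SourceSpec

CHECKPOINT_FORMAT_VERSION = 1
_EPS = 1e-12


@dataclass
class CapsuleConfig:
    """Hyperparameters of the capsule model.

    ``normalize_every_iter`` applies the L2 normalization of the weighted sum
    on the final routing iteration too (the literal pseudocode reading);
    the default normalizes on non-final iterations only, so capsule lengths
    stay informative. ``accumulate_logits`` adds each iteration's agreement
    to the previous logits instead of overwriting them.
    """

    n: int = 8              # primary capsule length
    m: int = 16             # type capsule length
    r: int = 3              # routing iterations
    squash_const: float = 0.5
    normalize_every_iter: bool = False
    accumulate_logits: bool = False

    def validate(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("capsule lengths n and m must be >= 1")
        if self.r < 1:
            raise ValueError(f"routing iterations r must be >= 1, got {self.r}")
        if self.squash_const <= 0:
            raise ValueError("squash constant must be positive")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, const: float = 0.5, axis: int = -1) -> np.ndarray:
    """Nonlinearity mapping s to a parallel vector of norm ||s||^2/(const+||s||^2).

    The zero vector maps to the zero vector.
    """
    s = np.asarray(s, dtype=np.float64)
    sq = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq)
    scale = np.where(norm > 0, sq / (const + sq) / np.maximum(norm, _EPS), 0.0)
    return scale * s


def coupling_from_logits(b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax of routing logits over the type-capsule axis (subtract-max stable)."""
    b = np.asarray(b, dtype=np.float64)
    z = b - np.max(b, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _l2_normalize(s: np.ndarray, axis: int = -1) -> np.ndarray:
    norm = np.linalg.norm(s, axis=axis, keepdims=True)
    return np.where(norm > 0, s / np.maximum(norm, _EPS), 0.0)


def routing(
    u_hat: np.ndarray,
    r: int,
    squash_const: float = 0.5,
    normalize_every_iter: bool = False,
    accumulate_logits: bool = False,
    return_cache: bool = False,
):
    """Dynamic routing between primary and type capsules.

    Parameters
    ----------
    u_hat
        Prediction vectors, shape ``(..., l, k, m)``.
    r
        Number of routing iterations (>= 1).

    Returns
    -------
    (v, c)
        Type capsules ``(..., k, m)`` and the final couplings ``(..., l, k)``.
        With ``return_cache=True`` a third element holds the per-iteration
        intermediates needed for backpropagation.
    """
    if r < 1:
        raise ValueError(f"routing iterations r must be >= 1, got {r}")
    u_hat = np.asarray(u_hat, dtype=np.float64)
    b = np.zeros(u_hat.shape[:-1], dtype=np.float64)  # (..., l, k)
    cs, ss, s_hats = [], [], []
    c = s = None
    for t in range(r):
        c = coupling_from_logits(b, axis=-1)
        s = np.einsum("...lk,...lkm->...km", c, u_hat)
        cs.append(c)
        ss.append(s)
        if t < r - 1:
            s_hat = _l2_normalize(s, axis=-1)
            s_hats.append(s_hat)
            agree = np.einsum("...lkm,...km->...lk", u_hat, s_hat)
            b = b + agree if accumulate_logits else agree
    s_final = _l2_normalize(s, axis=-1) if normalize_every_iter else s
    v = squash(s_final, const=squash_const, axis=-1)
    if return_cache:
        cache = {"cs": cs, "ss": ss, "s_hats": s_hats, "s_final": s_final, "v": v}
        return v, c, cache
    return v, c


# ---------------------------------------------------------------------------
# Parameter container and forward/backward
# ---------------------------------------------------------------------------

@dataclass
class CapsuleModel:
    """Trainable multi-source capsule classifier.

    Parameters are the per-source encoder matrices ``Wp[i]`` of shape
    ``(n, r_i)`` and the routing tensor ``W`` of shape ``(l, k, m, n)``.
    """

    sources: list[SourceSpec]
    class_names: list[str]
    config: CapsuleConfig = field(default_factory=CapsuleConfig)
    Wp: list[np.ndarray] = field(default_factory=list)
    W: np.ndarray | None = None

    @classmethod
    def initialize(
        cls,
        sources: Sequence[SourceSpec],
        class_names: Sequence[str],
        config: CapsuleConfig | None = None,
        seed: int | np.random.Generator = 0,
    ) -> "CapsuleModel":
        config = config or CapsuleConfig()
        config.validate()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        l, k = len(sources), len(class_names)
        # Glorot-style scaling keeps tanh pre-activations in its linear range.
        Wp = [
            rng.normal(0.0, np.sqrt(2.0 / (config.n + s.length)), size=(config.n, s.length))
            for s in sources
        ]
        W = rng.normal(0.0, np.sqrt(2.0 / (config.m + config.n)), size=(l, k, config.m, config.n))
        return cls(sources=list(sources), class_names=list(class_names),
                   config=config, Wp=Wp, W=W)

    # -- shape plumbing ------------------------------------------------------

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def _check_blocks(self, blocks: Sequence[np.ndarray]) -> list[np.ndarray]:
        if len(blocks) != self.n_sources:
            raise ValueError(
                f"model expects {self.n_sources} source blocks, got {len(blocks)}"
            )
        out = []
        for spec, block, w in zip(self.sources, blocks, self.Wp):
            block = np.asarray(block, dtype=np.float64)
            if block.ndim != 2 or block.shape[1] != w.shape[1]:
                raise ValueError(
                    f"source {spec.name!r}: block has shape {block.shape}, "
                    f"encoder expects (*, {w.shape[1]})"
                )
            out.append(block)
        return out

    # -- forward -------------------------------------------------------------

    def encode(self, blocks: Sequence[np.ndarray]) -> np.ndarray:
        """Primary capsules u, shape (batch, l, n)."""
        blocks = self._check_blocks(blocks)
        u = np.stack([np.tanh(x @ w.T) for x, w in zip(blocks, self.Wp)], axis=1)
        return u

    def predict_vectors(self, u: np.ndarray) -> np.ndarray:
        """Prediction vectors u_hat, shape (batch, l, k, m)."""
        return np.einsum("lkmn,bln->blkm", self.W, u)

    def forward(self, blocks: Sequence[np.ndarray], return_cache: bool = False):
        """Full forward pass.

        Returns ``(scores, c)`` — class scores ``||v_j||`` of shape
        ``(batch, k)`` and final couplings of shape ``(batch, l, k)`` — plus
        a cache of intermediates when ``return_cache`` is set.
        """
        blocks = self._check_blocks(blocks)
        u = self.encode(blocks)
        u_hat = self.predict_vectors(u)
        cfg = self.config
        v, c, rcache = routing(
            u_hat, cfg.r, squash_const=cfg.squash_const,
            normalize_every_iter=cfg.normalize_every_iter,
            accumulate_logits=cfg.accumulate_logits, return_cache=True,
        )
        scores = np.linalg.norm(v, axis=-1)
        if return_cache:
            cache = {"x": blocks, "u": u, "u_hat": u_hat, "v": v,
                     "scores": scores, **rcache}
            return scores, c, cache
        return scores, c

    def predict_scores(self, dataset_or_blocks) -> np.ndarray:
        blocks = getattr(dataset_or_blocks, "blocks", dataset_or_blocks)
        scores, _ = self.forward(blocks)
        return scores

    def predict(self, dataset_or_blocks) -> np.ndarray:
        """Argmax class per sample; ties resolve to the lowest class index."""
        return np.argmax(self.predict_scores(dataset_or_blocks), axis=1)

    def couplings(self, dataset_or_blocks) -> np.ndarray:
        """Final-iteration couplings, shape (batch, l, k)."""
        blocks = getattr(dataset_or_blocks, "blocks", dataset_or_blocks)
        _, c = self.forward(blocks)
        return c

    # -- backward ------------------------------------------------------------

    def backward(self, cache: dict, dscores: np.ndarray):
        """Gradients of a scalar loss wrt all parameters, given d loss/d scores.

        Backpropagates through the squash, the unrolled routing iterations
        (including the softmax and the L2 normalizations), the prediction
        map and the tanh encoders. Returns ``(dWp, dW)``.
        """
        cfg = self.config
        u, u_hat = cache["u"], cache["u_hat"]
        cs, ss, s_hats = cache["cs"], cache["ss"], cache["s_hats"]
        v, s_final = cache["v"], cache["s_final"]

        # scores = ||v||  ->  dv
        norm_v = np.linalg.norm(v, axis=-1, keepdims=True)
        dv = np.where(norm_v > 0, dscores[..., None] * v / np.maximum(norm_v, _EPS), 0.0)

        # v = squash(s_final): v = g(rho) * s with g = rho/(a+rho^2)
        a = cfg.squash_const
        rho = np.linalg.norm(s_final, axis=-1, keepdims=True)
        g = rho / (a + rho * rho)
        gp = (a - rho * rho) / (a + rho * rho) ** 2          # dg/drho
        sdot = np.sum(s_final * dv, axis=-1, keepdims=True)
        ds_final = np.where(
            rho > 0, g * dv + gp / np.maximum(rho, _EPS) * sdot * s_final, 0.0
        )

        ds = ds_final
        if cfg.normalize_every_iter:
            ds = self._normalize_backward(ss[-1], ds)

        du_hat = np.zeros_like(u_hat)
        db_carry = None  # gradient reaching b_t from later iterations (accumulate mode)
        for t in range(cfg.r - 1, -1, -1):
            c_t = cs[t]
            # s_t = sum_i c_ij u_hat
            dc = np.einsum("bkm,blkm->blk", ds, u_hat)
            du_hat += c_t[..., None] * ds[:, None, :, :]
            if t == 0:
                # b_0 = 0 is a constant: the softmax input carries no gradient.
                break
            # c_t = softmax(b_t); b_t = (b_{t-1} +) u_hat . s_hat_{t-1}
            db = c_t * (dc - np.sum(c_t * dc, axis=-1, keepdims=True))
            if db_carry is not None:
                db = db + db_carry
            du_hat += db[..., None] * s_hats[t - 1][:, None, :, :]
            ds_hat = np.einsum("blk,blkm->bkm", db, u_hat)
            ds = self._normalize_backward(ss[t - 1], ds_hat)
            db_carry = db if cfg.accumulate_logits else None

        dW = np.einsum("blkm,bln->lkmn", du_hat, u)
        du = np.einsum("lkmn,blkm->bln", self.W, du_hat)
        dz = du * (1.0 - u * u)  # tanh'
        dWp = [dz[:, i, :].T @ x for i, x in enumerate(cache["x"])]
        return dWp, dW

    @staticmethod
    def _normalize_backward(s: np.ndarray, ds_hat: np.ndarray) -> np.ndarray:
        """Backprop through s_hat = s/||s|| (zero gradient at s = 0)."""
        norm = np.linalg.norm(s, axis=-1, keepdims=True)
        s_hat = np.where(norm > 0, s / np.maximum(norm, _EPS), 0.0)
        proj = np.sum(s_hat * ds_hat, axis=-1, keepdims=True)
        return np.where(norm > 0, (ds_hat - proj * s_hat) / np.maximum(norm, _EPS), 0.0)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (npz with a JSON metadata entry)."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "class_names": self.class_names,
            "config": asdict(self.config),
            "sources": [
                {"name": s.name, "kind": s.kind, "features": list(s.features)}
                for s in self.sources
            ],
        }
        arrays = {f"Wp_{i}": w for i, w in enumerate(self.Wp)}
        arrays["W"] = self.W
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CapsuleModel":
        with np.load(Path(path)) as npz:
            meta = json.loads(bytes(npz["meta_json"].tobytes()).decode("utf-8"))
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format version {meta.get('format_version')}"
                )
            sources = [
                SourceSpec(name=s["name"], kind=s["kind"], features=tuple(s["features"]))
                for s in meta["sources"]
            ]
            Wp = [np.array(npz[f"Wp_{i}"]) for i in range(len(sources))]
            W = np.array(npz["W"])
        return cls(
            sources=sources,
            class_names=list(meta["class_names"]),
            config=CapsuleConfig(**meta["config"]),
            Wp=Wp,
            W=W,
        )

    def check_dataset(self, dataset: ModularDataset) -> None:
        """Raise if a dataset's schema does not match this model."""
        if dataset.n_sources != self.n_sources:
            raise ValueError(
                f"dataset has {dataset.n_sources} sources, model expects {self.n_sources}"
            )
        for ds_spec, m_spec in zip(dataset.sources, self.sources):
            if ds_spec.name != m_spec.name or ds_spec.length != m_spec.length:
                raise ValueError(
                    f"source mismatch: dataset has {ds_spec.name!r} "
                    f"(r={ds_spec.length}), model expects {m_spec.name!r} "
                    f"(r={m_spec.length})"
                )
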