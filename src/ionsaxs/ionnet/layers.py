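"""Graph attention and graph convolution layers with manual backprop.

All layers act on a packed :class:`~ionsaxs.ionnet.graphs.GraphBatch`.
Forward passes return an activation cache; backward passes consume it and
return the gradient with respect to the layer input plus per-parameter
gradients.  Gradient correctness is checked against numeric differentiation
in the test suite.
"""

from __future__ import annotations

import numpy as np

from .graphs import GraphBatch

__all__ = ["gat_init", "gat_forward", "gat_backward",
           "gcn_init", "gcn_forward", "gcn_backward",
           "head_init", "head_forward", "head_backward"]

_LEAKY = 0.2


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


# ---------------------------------------------------------------------------
# Graph attention (single head, edge-distance-aware logits)

def gat_init(rng: np.random.Generator, fan_in: int, fan_out: int, name: str) -> dict:
    return {
        f"{name}.W": _glorot(rng, (fan_in, fan_out)),
        f"{name}.a_src": _glorot(rng, (fan_out,)),
        f"{name}.a_dst": _glorot(rng, (fan_out,)),
        f"{name}.a_edge": np.zeros(1),
        f"{name}.b": np.zeros(fan_out),
    }


def gat_forward(params: dict, name: str, X: np.ndarray, batch: GraphBatch):
    import scipy.sparse as sp
    src, dst = batch.src, batch.dst
    N = batch.n_nodes
    W = params[f"{name}.W"]
    H = X @ W
    z = (H @ params[f"{name}.a_src"])[src] + (H @ params[f"{name}.a_dst"])[dst] \
        + params[f"{name}.a_edge"][0] * batch.dist
    e = np.where(z > 0, z, _LEAKY * z)
    # segment softmax over edges sharing a destination node
    m = np.full(N, -np.inf)
    np.maximum.at(m, dst, e)
    ex = np.exp(e - m[dst])
    denom = np.bincount(dst, weights=ex, minlength=N)
    alpha = ex / denom[dst]
    P = sp.csr_matrix((alpha, (dst, src)), shape=(N, N))
    pre = P @ H + params[f"{name}.b"]
    out = _elu(pre)
    cache = {"X": X, "H": H, "z": z, "alpha": alpha, "P": P, "pre": pre}
    return out, cache


def gat_backward(params: dict, name: str, grad_out: np.ndarray, cache: dict,
                 batch: GraphBatch):
    src, dst = batch.src, batch.dst
    N = batch.n_nodes
    X, H, z, alpha, P, pre = (cache["X"], cache["H"], cache["z"],
                              cache["alpha"], cache["P"], cache["pre"])
    gp = grad_out * _elu_grad(pre)
    grads = {f"{name}.b": gp.sum(axis=0)}
    dH = P.T @ gp
    dalpha = np.einsum("eh,eh->e", gp[dst], H[src])
    seg = np.bincount(dst, weights=alpha * dalpha, minlength=N)
    de = alpha * (dalpha - seg[dst])
    dz = de * np.where(z > 0, 1.0, _LEAKY)
    ds_src = np.bincount(src, weights=dz, minlength=N)
    ds_dst = np.bincount(dst, weights=dz, minlength=N)
    grads[f"{name}.a_edge"] = np.array([np.dot(dz, batch.dist)])
    grads[f"{name}.a_src"] = H.T @ ds_src
    grads[f"{name}.a_dst"] = H.T @ ds_dst
    dH = dH + np.outer(ds_src, params[f"{name}.a_src"]) \
            + np.outer(ds_dst, params[f"{name}.a_dst"])
    grads[f"{name}.W"] = X.T @ dH
    dX = dH @ params[f"{name}.W"].T
    return dX, grads


# ---------------------------------------------------------------------------
# Graph convolution (symmetric normalization, self-loops)

def gcn_init(rng: np.random.Generator, fan_in: int, fan_out: int, name: str) -> dict:
    return {f"{name}.W": _glorot(rng, (fan_in, fan_out)),
            f"{name}.b": np.zeros(fan_out)}


def gcn_forward(params: dict, name: str, X: np.ndarray, batch: GraphBatch):
    HW = X @ params[f"{name}.W"]
    pre = batch.A_hat @ HW + params[f"{name}.b"]
    out = np.maximum(pre, 0.0)
    return out, {"X": X, "pre": pre}


def gcn_backward(params: dict, name: str, grad_out: np.ndarray, cache: dict,
                 batch: GraphBatch):
    gp = grad_out * (cache["pre"] > 0)
    dHW = batch.A_hat.T @ gp
    grads = {f"{name}.W": cache["X"].T @ dHW, f"{name}.b": gp.sum(axis=0)}
    dX = dHW @ params[f"{name}.W"].T
    return dX, grads


# ---------------------------------------------------------------------------
# Mean-pool read-out + linear probability head

def head_init(rng: np.random.Generator, fan_in: int, name: str = "head") -> dict:
    return {f"{name}.w": _glorot(rng, (fan_in,)), f"{name}.b": np.zeros(1)}


def head_forward(params: dict, X: np.ndarray, batch: GraphBatch,
                 name: str = "head"):
    pooled = batch.pool @ X
    logits = pooled @ params[f"{name}.w"] + params[f"{name}.b"][0]
    return logits, {"pooled": pooled}


def head_backward(params: dict, grad_logits: np.ndarray, cache: dict,
                  batch: GraphBatch, name: str = "head"):
    pooled = cache["pooled"]
    grads = {f"{name}.w": pooled.T @ grad_logits,
             f"{name}.b": np.array([grad_logits.sum()])}
    dpooled = np.outer(grad_logits, params[f"{name}.w"])
    dX = batch.pool.T @ dpooled
    return dX, grads
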