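"""AdamW over nested parameter dicts, with a step learning-rate drop.

Two parameter groups (backbone vs transformer/heads) are handled by
instantiating one optimizer per group, mirroring the detection-transformer
convention of a lower backbone learning rate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_map", "tree_flatten", "flatten_params", "unflatten_params",
           "AdamW", "clip_grad_norm"]


def tree_map(fn, *trees):
    """Apply ``fn`` leaf-wise across identically-structured nested dicts."""
    first = trees[0]
    if isinstance(first, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in first}
    if isinstance(first, (list, tuple)):
        return type(first)(tree_map(fn, *parts) for parts in zip(*trees))
    return fn(*trees)


def tree_flatten(tree, prefix=""):
    """Yield (dotted_name, leaf) pairs in deterministic key order."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_flatten(tree[k], f"{prefix}{k}.")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from tree_flatten(v, f"{prefix}{i}.")
    else:
        yield prefix[:-1], tree


def flatten_params(tree):
    """Pack a parameter tree into one float32 vector plus a layout.

    Differentiating with respect to the packed vector keeps autograd's
    gradient accumulation sparse (per-slice) instead of per-leaf over the
    whole container, which matters enormously for large models.
    """
    leaves = list(tree_flatten(tree))
    layout = []
    offset = 0
    chunks = []
    for name, leaf in leaves:
        size = int(np.prod(leaf.shape)) if leaf.shape else 1
        layout.append((name, offset, leaf.shape))
        chunks.append(np.ravel(leaf).astype(np.float32))
        offset += size
    vec = np.concatenate(chunks) if chunks else np.zeros(0, np.float32)
    return vec, layout


def _assign(tree, dotted, value):
    keys = dotted.split(".")
    node = tree
    for i, k in enumerate(keys[:-1]):
        idx = int(k) if k.isdigit() else k
        nxt = keys[i + 1]
        if isinstance(node, list):
            while len(node) <= idx:
                node.append([] if nxt.isdigit() else {})
            node = node[idx]
        else:
            if idx not in node:
                node[idx] = [] if nxt.isdigit() else {}
            node = node[idx]
    last = keys[-1]
    if isinstance(node, list):
        while len(node) <= int(last):
            node.append(None)
        node[int(last)] = value
    else:
        node[last] = value


def unflatten_params(vec, layout):
    """Rebuild the nested dict from a (possibly autograd-traced) vector."""
    import autograd.numpy as anp

    tree: dict = {}
    for name, offset, shape in layout:
        size = int(np.prod(shape)) if shape else 1
        leaf = anp.reshape(vec[offset : offset + size], shape)
        _assign(tree, name, leaf)
    return tree


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        lr, eps, wd = self.lr, self.eps, self.weight_decay

        def upd(p, g, m, v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            step = lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
            return (p - step - lr * wd * p).astype(p.dtype)

        return tree_map(upd, params, grads, self.m, self.v)

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = state["m"]
        self.v = state["v"]
        self.lr = state["lr"]


def clip_grad_norm(grads, max_norm: float):
    """Global-norm gradient clipping; returns (clipped, norm)."""
    total = 0.0
    for _, g in tree_flatten(grads):
        total += float(np.sum(np.asarray(g, dtype=np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        grads = tree_map(lambda g: g * scale, grads)
    return grads, norm
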