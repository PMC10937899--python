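"""The particle-detection network.

A residual convolutional backbone produces a 1/32-resolution activation
map (2048 channels for bottleneck depths 50/101/152, 512 for basic-block
depths 18/34).  A 1x1 convolution projects the channels down to the
transformer width ``d``, the spatial grid is flattened into tokens, and
an encoder-decoder transformer with ``N`` learnable particle queries
turns them into a fixed-size set of predictions: per query a softmax
over {particle, no-particle} and a sigmoid-bounded box (cx, cy, w, h)
normalized to the un-padded image extent.

Everything is written against ``autograd.numpy`` so the training loss can
be differentiated end-to-end.  Batches of unequal image sizes are
zero-padded to the largest extent; per-image valid sizes are tracked
through every stage, features outside the valid region are zeroed, the
normalization statistics are computed over valid pixels only, and
attention masks exclude padded tokens — so a prediction computed inside a
padded batch matches the unbatched prediction to float precision.

Normalization in the backbone is (mask-aware) group normalization: it is
deterministic, independent of batch composition, and keeps the
padded-batch equivalence exact, which running-statistics batch
normalization would not.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from cryopick.io import Micrograph
from cryopick.nn.init import xavier_uniform
from cryopick.nn.ops import conv2d, conv_out_size, max_pool2d_3x3s2
from cryopick.nn.optim import tree_flatten

__all__ = [
    "ModelConfig",
    "ParticleTransformer",
    "init_params",
    "model_forward",
    "backbone_forward",
    "pad_batch",
    "sine_positional_encoding",
    "save_checkpoint",
    "load_checkpoint",
]

_BLOCKS = {
    18: ("basic", [2, 2, 2, 2]),
    34: ("basic", [3, 4, 6, 3]),
    50: ("bottleneck", [3, 4, 6, 3]),
    101: ("bottleneck", [3, 4, 23, 3]),
    152: ("bottleneck", [3, 8, 36, 3]),
}


@dataclass
class ModelConfig:
    backbone_depth: int = 152
    hidden_dim: int = 256
    num_queries: int = 600
    encoder_layers: int = 6
    decoder_layers: int = 6
    attention_heads: int = 8
    ffn_dim: int | None = None  # defaults to 4 * hidden_dim
    dropout: float = 0.1
    learnable_pos: bool = False
    norm_groups: int = 8

    def __post_init__(self):
        if self.backbone_depth not in _BLOCKS:
            raise ValueError(f"backbone_depth must be one of {sorted(_BLOCKS)}")
        if self.hidden_dim % self.attention_heads:
            raise ValueError("hidden_dim must be divisible by attention_heads")
        if self.hidden_dim % 4:
            raise ValueError("hidden_dim must be divisible by 4 (2-D sine encoding)")
        if self.num_queries < 1:
            raise ValueError("num_queries must be >= 1")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.hidden_dim

    @property
    def backbone_channels(self) -> int:
        kind, _ = _BLOCKS[self.backbone_depth]
        return 2048 if kind == "bottleneck" else 512


# =================================================================== init

def _conv_p(rng, co, ci, k):
    return {"w": xavier_uniform(rng, (co, ci, k, k))}


def _norm_p(c):
    return {"g": np.ones(c, np.float32), "b": np.zeros(c, np.float32)}


def _linear_p(rng, d_out, d_in):
    return {"w": xavier_uniform(rng, (d_out, d_in)),
            "b": np.zeros(d_out, np.float32)}


def _block_p(rng, kind, c_in, width, stride):
    if kind == "basic":
        p = {
            "conv1": _conv_p(rng, width, c_in, 3), "norm1": _norm_p(width),
            "conv2": _conv_p(rng, width, width, 3), "norm2": _norm_p(width),
        }
        c_out = width
    else:
        c_out = width * 4
        p = {
            "conv1": _conv_p(rng, width, c_in, 1), "norm1": _norm_p(width),
            "conv2": _conv_p(rng, width, width, 3), "norm2": _norm_p(width),
            "conv3": _conv_p(rng, c_out, width, 1), "norm3": _norm_p(c_out),
        }
    if stride != 1 or c_in != c_out:
        p["down_conv"] = _conv_p(rng, c_out, c_in, 1)
        p["down_norm"] = _norm_p(c_out)
    return p, c_out


def _backbone_p(rng, depth):
    kind, counts = _BLOCKS[depth]
    p = {"stem": {"conv": _conv_p(rng, 64, 3, 7), "norm": _norm_p(64)}}
    c = 64
    for li, (width, n_blocks) in enumerate(zip([64, 128, 256, 512], counts)):
        blocks = []
        for bi in range(n_blocks):
            stride = 2 if (li > 0 and bi == 0) else 1
            bp, c = _block_p(rng, kind, c, width, stride)
            blocks.append(bp)
        p[f"layer{li + 1}"] = blocks
    return p


def _mha_p(rng, d):
    return {
        "wq": _linear_p(rng, d, d), "wk": _linear_p(rng, d, d),
        "wv": _linear_p(rng, d, d), "wo": _linear_p(rng, d, d),
    }


def _enc_layer_p(rng, cfg):
    d, f = cfg.hidden_dim, cfg.ffn_dim
    return {
        "attn": _mha_p(rng, d), "ln1": _norm_p(d),
        "ffn1": _linear_p(rng, f, d), "ffn2": _linear_p(rng, d, f),
        "ln2": _norm_p(d),
    }


def _dec_layer_p(rng, cfg):
    d, f = cfg.hidden_dim, cfg.ffn_dim
    return {
        "self_attn": _mha_p(rng, d), "ln1": _norm_p(d),
        "cross_attn": _mha_p(rng, d), "ln2": _norm_p(d),
        "ffn1": _linear_p(rng, f, d), "ffn2": _linear_p(rng, d, f),
        "ln3": _norm_p(d),
    }


def init_params(config: ModelConfig, seed: int = 0) -> dict:
    """Xavier-initialized parameter tree (same seed => identical weights)."""
    rng = np.random.default_rng(seed)
    d = config.hidden_dim
    p = {
        "backbone": _backbone_p(rng, config.backbone_depth),
        "proj": _conv_p(rng, d, config.backbone_channels, 1),
        "encoder": [_enc_layer_p(rng, config) for _ in range(config.encoder_layers)],
        "decoder": [_dec_layer_p(rng, config) for _ in range(config.decoder_layers)],
        "dec_norm": _norm_p(d),
        # particle queries: learnable embeddings, random at start
        "query_embed": rng.standard_normal((config.num_queries, d)).astype(np.float32),
        "class_head": _linear_p(rng, 2, d),
        "bbox_head": [_linear_p(rng, d, d), _linear_p(rng, d, d),
                      _linear_p(rng, 4, d)],
    }
    if config.learnable_pos:
        p["pos_embed"] = 0.1 * rng.standard_normal((2500, d)).astype(np.float32)
    return p


# =================================================================== pieces

def _linear(p, x):
    return anp.dot(x, p["w"].T) + p["b"]


def _layer_norm(p, x, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return p["g"] * (x - mu) / anp.sqrt(var + eps) + p["b"]


def _group_norm(p, x, mask, groups, eps=1e-5):
    """Mask-aware group normalization over (C/G, valid H*W)."""
    b, c, h, w = x.shape
    g = groups if c % groups == 0 else 1
    xg = anp.reshape(x, (b, g, c // g, h, w))
    if mask is None:
        mu = anp.mean(xg, axis=(2, 3, 4), keepdims=True)
        var = anp.mean((xg - mu) ** 2, axis=(2, 3, 4), keepdims=True)
    else:
        m = anp.reshape(mask, (b, 1, 1, h, w))
        cnt = anp.sum(m, axis=(2, 3, 4), keepdims=True) * (c // g)
        mu = anp.sum(xg * m, axis=(2, 3, 4), keepdims=True) / cnt
        var = anp.sum(((xg - mu) * m) ** 2, axis=(2, 3, 4), keepdims=True) / cnt
    xn = (xg - mu) / anp.sqrt(var + eps)
    xn = anp.reshape(xn, (b, c, h, w))
    out = p["g"][None, :, None, None] * xn + p["b"][None, :, None, None]
    if mask is not None:
        out = out * mask
    return out


def _relu(x):
    return anp.maximum(x, 0.0)


def _softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def _dropout(x, rate, rng):
    if rng is None or rate <= 0:
        return x
    keep = (rng.uniform(size=np.shape(x)) >= rate).astype(np.float32)
    return x * keep / (1.0 - rate)


def _mask_from_sizes(sizes, h, w):
    m = np.zeros((len(sizes), 1, h, w), dtype=np.float32)
    for i, (vh, vw) in enumerate(sizes):
        m[i, 0, :vh, :vw] = 1.0
    return m


def _shrink(sizes, k, s, p):
    return [(conv_out_size(vh, k, s, p), conv_out_size(vw, k, s, p))
            for vh, vw in sizes]


# =================================================================== backbone

def _apply_block(bp, x, mask_in, mask_out, stride, groups):
    bottleneck = "conv3" in bp
    if bottleneck:
        h = conv2d(x, bp["conv1"]["w"], 1, 0)
        h = _relu(_group_norm(bp["norm1"], h, mask_in, groups))
        h = conv2d(h, bp["conv2"]["w"], stride, 1)
        h = _relu(_group_norm(bp["norm2"], h, mask_out, groups))
        h = conv2d(h, bp["conv3"]["w"], 1, 0)
        h = _group_norm(bp["norm3"], h, mask_out, groups)
    else:
        h = conv2d(x, bp["conv1"]["w"], stride, 1)
        h = _relu(_group_norm(bp["norm1"], h, mask_out, groups))
        h = conv2d(h, bp["conv2"]["w"], 1, 1)
        h = _group_norm(bp["norm2"], h, mask_out, groups)
    if "down_conv" in bp:
        sc = conv2d(x, bp["down_conv"]["w"], stride, 0)
        sc = _group_norm(bp["down_norm"], sc, mask_out, groups)
    else:
        sc = x
    return _relu(h + sc)


def backbone_forward(params, images, sizes=None, config: ModelConfig | None = None):
    """Residual backbone: (B, 3, H0, W0) -> (B, C, H0//32, W0//32).

    ``sizes`` lists each image's valid (height, width); padding beyond it
    is kept at zero through every stage.  Returns (features, sizes).
    """
    cfg = config or ModelConfig()
    b, _, h0, w0 = images.shape
    if h0 < 32 or w0 < 32:
        raise ValueError(f"input {h0}x{w0} is below the 32-pixel minimum")
    if sizes is None:
        sizes = [(h0, w0)] * b
    groups = cfg.norm_groups
    full = all((vh, vw) == (h0, w0) for vh, vw in sizes)

    def mk_mask(sz, hh, ww):
        if full:
            return None
        return _mask_from_sizes(sz, hh, ww)

    bp = params["backbone"]
    x = conv2d(images, bp["stem"]["conv"]["w"], 2, 3)
    sizes = _shrink(sizes, 7, 2, 3)
    mask = mk_mask(sizes, x.shape[2], x.shape[3])
    x = _relu(_group_norm(bp["stem"]["norm"], x, mask, groups))
    x = max_pool2d_3x3s2(x)
    sizes = _shrink(sizes, 3, 2, 1)
    mask = mk_mask(sizes, x.shape[2], x.shape[3])
    if mask is not None:
        x = x * mask

    for li in range(1, 5):
        blocks = bp[f"layer{li}"]
        for bi, blk in enumerate(blocks):
            stride = 2 if (li > 1 and bi == 0) else 1
            mask_in = mask
            if stride == 2:
                # downsampling conv is 3x3/s2/p1 in both block kinds; the
                # 1x1/s2 shortcut yields the same output extent
                sizes = _shrink(sizes, 3, 2, 1)
            new_h = conv_out_size(x.shape[2], 3, stride, 1)
            new_w = conv_out_size(x.shape[3], 3, stride, 1)
            mask_out = mk_mask(sizes, new_h, new_w)
            x = _apply_block(blk, x, mask_in, mask_out, stride, groups)
            mask = mask_out
    return x, sizes


# =================================================================== encoding

def sine_positional_encoding(mask: np.ndarray, d: int,
                             temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2-D sine/cosine positional features, (B, H, W, d).

    ``mask`` is (B, H, W) with 1 on valid cells.  Positions are
    normalized to (0, 2*pi] over each image's own valid extent, so the
    encoding of a valid cell does not depend on how much padding the
    batch carries.  Channels come in (sin, cos) pairs of the same
    argument; the first d/2 channels encode y, the rest x.
    """
    mask = np.asarray(mask, dtype=np.float64)
    y_embed = mask.cumsum(axis=1)
    x_embed = mask.cumsum(axis=2)
    eps = 1e-6
    y_embed = y_embed / (y_embed.max(axis=(1, 2), keepdims=True) + eps) * 2 * np.pi
    x_embed = x_embed / (x_embed.max(axis=(1, 2), keepdims=True) + eps) * 2 * np.pi
    half = d // 2
    n_pair = half // 2
    freqs = temperature ** (np.arange(n_pair) / max(n_pair, 1))
    ang_y = y_embed[..., None] / freqs  # (B, H, W, n_pair)
    ang_x = x_embed[..., None] / freqs
    pos_y = np.stack([np.sin(ang_y), np.cos(ang_y)], axis=-1).reshape(
        *mask.shape, half)
    pos_x = np.stack([np.sin(ang_x), np.cos(ang_x)], axis=-1).reshape(
        *mask.shape, half)
    return np.concatenate([pos_y, pos_x], axis=-1).astype(np.float32)


# =================================================================== attention

def _mha(p, q_in, k_in, v_in, heads, key_mask=None):
    b, lq, d = q_in.shape[0], q_in.shape[1], q_in.shape[2]
    lk = k_in.shape[1]
    dh = d // heads

    def split(x, L):
        return anp.transpose(anp.reshape(x, (b, L, heads, dh)), (0, 2, 1, 3))

    q = split(_linear(p["wq"], q_in), lq)
    k = split(_linear(p["wk"], k_in), lk)
    v = split(_linear(p["wv"], v_in), lk)
    logits = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / float(np.sqrt(dh))
    if key_mask is not None:
        bias = (1.0 - key_mask)[:, None, None, :] * -1e9
        logits = logits + bias
    attn = _softmax(logits, axis=-1)
    out = anp.matmul(attn, v)  # (B, h, Lq, dh)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (b, lq, d))
    return _linear(p["wo"], out)


def _encoder_layer(p, src, pos, heads, key_mask, rate, rng):
    q = src + pos
    a = _mha(p["attn"], q, q, src, heads, key_mask)
    src = _layer_norm(p["ln1"], src + _dropout(a, rate, rng))
    f = _linear(p["ffn2"], _dropout(_relu(_linear(p["ffn1"], src)), rate, rng))
    return _layer_norm(p["ln2"], src + _dropout(f, rate, rng))


def _decoder_layer(p, tgt, memory, pos, query_pos, heads, key_mask, rate, rng):
    q = tgt + query_pos
    a = _mha(p["self_attn"], q, q, tgt, heads)
    tgt = _layer_norm(p["ln1"], tgt + _dropout(a, rate, rng))
    a2 = _mha(p["cross_attn"], tgt + query_pos, memory + pos, memory, heads,
              key_mask)
    tgt = _layer_norm(p["ln2"], tgt + _dropout(a2, rate, rng))
    f = _linear(p["ffn2"], _dropout(_relu(_linear(p["ffn1"], tgt)), rate, rng))
    return _layer_norm(p["ln3"], tgt + _dropout(f, rate, rng))


# =================================================================== forward

_POS_CACHE: dict = {}


def project_and_flatten(params, features):
    """1x1-conv channel reduction C -> d, then flatten space into tokens."""
    z0 = conv2d(features, params["proj"]["w"], 1, 0)
    b, d, h, w = z0.shape
    return anp.transpose(anp.reshape(z0, (b, d, h * w)), (0, 2, 1))


def model_forward(params, config: ModelConfig, images, sizes=None,
                  train: bool = False, dropout_rng=None,
                  return_aux: bool = False):
    """Full forward pass: images -> N predictions per image.

    Returns a dict with ``class_logits`` (B, N, 2), ``class_probs``
    (softmax rows), and ``boxes`` (B, N, 4) as normalized (cx, cy, w, h).
    """
    feats, fsizes = backbone_forward(params, images, sizes, config)
    return head_forward(params, config, feats, fsizes, train, dropout_rng,
                        return_aux)


def head_forward(params, config: ModelConfig, feats, fsizes,
                 train: bool = False, dropout_rng=None,
                 return_aux: bool = False):
    """Transformer + prediction heads on (possibly precomputed) features.

    With ``return_aux`` the heads are also applied to every intermediate
    decoder layer's (normalized) output, for auxiliary supervision.
    """
    rate = config.dropout if train else 0.0
    rng = dropout_rng if train else None
    b, _, fh, fw = feats.shape
    tokens = project_and_flatten(params, feats)  # (B, HW, d)

    fmask = _mask_from_sizes(fsizes, fh, fw)[:, 0]  # (B, fh, fw)
    if config.learnable_pos:
        idx = np.arange(fh * fw) % params["pos_embed"].shape[0]
        pos = anp.reshape(params["pos_embed"][idx], (1, fh * fw, config.hidden_dim))
        pos = anp.repeat(pos, b, axis=0)
    else:
        key = (tuple(map(tuple, fsizes)), fh, fw, config.hidden_dim)
        pos = _POS_CACHE.get(key)
        if pos is None:
            pos = sine_positional_encoding(fmask, config.hidden_dim)
            pos = pos.reshape(b, fh * fw, config.hidden_dim)
            if len(_POS_CACHE) < 64:
                _POS_CACHE[key] = pos
    key_mask = fmask.reshape(b, fh * fw).astype(np.float32)
    if key_mask.all():
        key_mask_arg = None
    else:
        key_mask_arg = key_mask

    src = tokens
    for lp in params["encoder"]:
        src = _encoder_layer(lp, src, pos, config.attention_heads,
                             key_mask_arg, rate, rng)
    memory = src

    n = config.num_queries
    query_pos = anp.repeat(params["query_embed"][None], b, axis=0)
    tgt = anp.zeros((b, n, config.hidden_dim), dtype=np.float32)
    intermediates = []
    for lp in params["decoder"]:
        tgt = _decoder_layer(lp, tgt, memory, pos, query_pos,
                             config.attention_heads, key_mask_arg, rate, rng)
        if return_aux:
            intermediates.append(tgt)
    tgt = _layer_norm(params["dec_norm"], tgt)

    def heads(h):
        logits = _linear(params["class_head"], h)  # (B, N, 2)
        hb = h
        for i, lp in enumerate(params["bbox_head"]):
            hb = _linear(lp, hb)
            if i < len(params["bbox_head"]) - 1:
                hb = _relu(hb)
        return logits, _sigmoid(hb)

    logits, boxes = heads(tgt)
    out = {
        "class_logits": logits,
        "class_probs": _softmax(logits, axis=-1),
        "boxes": boxes,
    }
    if return_aux:
        aux = []
        for h in intermediates[:-1]:
            al, ab = heads(_layer_norm(params["dec_norm"], h))
            aux.append({"class_logits": al, "boxes": ab})
        out["aux"] = aux
    return out


def pad_batch(pixel_arrays: list[np.ndarray]):
    """Zero-pad single-channel images to a common extent.

    Returns (batch, sizes, mask): batch is (B, 3, Hmax, Wmax) with the
    grayscale image replicated onto three channels, sizes the per-image
    valid (h, w), mask a boolean (B, Hmax, Wmax) validity map.
    """
    sizes = [a.shape for a in pixel_arrays]
    hmax = max(h for h, _ in sizes)
    wmax = max(w for _, w in sizes)
    batch = np.zeros((len(pixel_arrays), 3, hmax, wmax), dtype=np.float32)
    mask = np.zeros((len(pixel_arrays), hmax, wmax), dtype=bool)
    for i, a in enumerate(pixel_arrays):
        h, w = a.shape
        batch[i, :, :h, :w] = a[None]
        mask[i, :h, :w] = True
    return batch, sizes, mask


# =================================================================== wrapper

class ParticleTransformer:
    """Config + parameter bundle with convenience inference methods."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 params: dict | None = None):
        self.config = config or ModelConfig()
        self.params = params if params is not None else init_params(self.config, seed)

    def forward(self, images, sizes=None, train=False, dropout_rng=None,
                params=None):
        return model_forward(params if params is not None else self.params,
                             self.config, images, sizes, train, dropout_rng)

    def detect(self, micrograph: Micrograph) -> dict:
        """Evaluation-mode forward on a single micrograph."""
        batch, sizes, _ = pad_batch([micrograph.pixels.astype(np.float32)])
        out = self.forward(batch, sizes)
        return {
            "boxes": np.asarray(out["boxes"][0]),
            "class_probs": np.asarray(out["class_probs"][0]),
            "micrograph": micrograph.name,
        }


def save_checkpoint(path, model: ParticleTransformer, extra: dict | None = None):
    """Serialize config + weights (+ optional training state) to .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param:{k}": v for k, v in tree_flatten(model.params)}
    meta = {"config": asdict(model.config)}
    if extra:
        meta["extra"] = extra
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _tree_set(tree, dotted, value):
    keys = dotted.split(".")
    node = tree
    for k in keys[:-1]:
        k2 = int(k) if k.isdigit() else k
        node = node[k2]
    last = keys[-1]
    node[int(last) if last.isdigit() else last] = value


def load_checkpoint(path) -> tuple[ParticleTransformer, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = ModelConfig(**meta["config"])
        model = ParticleTransformer(config=config)
        for key in data.files:
            if key.startswith("param:"):
                _tree_set(model.params, key[len("param:"):], data[key])
    return model, meta.get("extra", {})
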