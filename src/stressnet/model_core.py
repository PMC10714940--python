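"""StressNet forward computation.

The classifier has two halves.  A convolutional feature extractor (AlexNet-
or VGG-16-shaped, or a compact desk-scale variant) whose final convolution
is deformable: every kernel tap samples the input at its regular grid
position plus a learned fractional offset, evaluated by bilinear
interpolation, so the receptive field can follow canopy shrinkage and leaf
deformation as stress progresses.  The per-date feature vectors are then
fused over time by two stacked LSTM layers — the first runs forward over
the sequence, the second consumes the first layer's hidden states in
reverse order — followed by a softmax attention pool over the hidden-state
matrix H:

    M = tanh(H),  alpha = softmax(w^T M),  R_att = H alpha^T

and a two-layer classifier head over the fused feature R_att.

Ablation variants: standard (non-deformable) final convolution and/or
last-hidden-state pooling instead of attention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Tensor, adaptive_avgpool2d, conv2d, deform_conv2d,
                        maxpool2d, softmax, stack)

CANONICAL_CHANNELS = ("blue", "green", "red", "rededge", "nir")

VARIANTS = ("case1_std_bilstm", "case2_std_bilstm_attn",
            "case3_deform_bilstm", "full_deform_bilstm_attn")

_VARIANT_ALIASES = {"case1": "case1_std_bilstm", "case2": "case2_std_bilstm_attn",
                    "case3": "case3_deform_bilstm", "full": "full_deform_bilstm_attn"}


def resolve_variant(name: str) -> str:
    name = _VARIANT_ALIASES.get(name, name)
    if name not in VARIANTS:
        raise ValueError(f"unknown model variant {name!r}")
    return name


def variant_uses_deform(variant: str) -> bool:
    return resolve_variant(variant) in ("case3_deform_bilstm", "full_deform_bilstm_attn")


def variant_uses_attention(variant: str) -> bool:
    return resolve_variant(variant) in ("case2_std_bilstm_attn", "full_deform_bilstm_attn")


# ---------------------------------------------------------------------------
# bilinear sampling (reference scalar form)
# ---------------------------------------------------------------------------

def bilinear_sample(feature_map: np.ndarray, location) -> float:
    """Bilinearly interpolate a 2-D map at a fractional (row, col) location.

    Locations outside the map contribute zero (zero padding), matching the
    padding semantics of standard convolution so that zero-offset deformable
    convolution is exactly standard convolution.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim != 2:
        raise ValueError("feature_map must be 2-D")
    py, px = float(location[0]), float(location[1])
    if not (np.isfinite(py) and np.isfinite(px)):
        raise ValueError("location must be finite")
    H, W = fm.shape
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    fy, fx = py - y0, px - x0
    total = 0.0
    for dy, dx, cf in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                       (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = y0 + dy, x0 + dx
        if 0 <= yy < H and 0 <= xx < W and cf != 0.0:
            total += cf * fm[yy, xx]
    return total


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _he_array(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


@dataclass
class ConvLayer:
    """A convolution layer, optionally deformable.

    When deformable, a standard convolution (the offset predictor) maps the
    layer input to 2·kh·kw offset channels; its weights start at zero so
    training begins exactly as standard convolution.
    """
    w: Tensor
    b: Tensor
    stride: int
    padding: int
    deformable: bool = False
    off_w: Tensor | None = None
    off_b: Tensor | None = None

    @classmethod
    def create(cls, rng, in_ch, out_ch, k, padding, stride, deformable=False):
        fan_in = in_ch * k * k
        w = Tensor(_he_array(rng, (out_ch, in_ch, k, k), fan_in), requires_grad=True)
        b = Tensor(np.zeros(out_ch), requires_grad=True)
        layer = cls(w, b, stride, padding, deformable)
        if deformable:
            layer.off_w = Tensor(np.zeros((2 * k * k, in_ch, k, k)), requires_grad=True)
            layer.off_b = Tensor(np.zeros(2 * k * k), requires_grad=True)
        return layer

    def forward(self, x: Tensor) -> Tensor:
        if self.deformable:
            off = conv2d(x, self.off_w, self.off_b, self.stride, self.padding)
            return deform_conv2d(x, self.w, self.b, off, self.stride, self.padding)
        return conv2d(x, self.w, self.b, self.stride, self.padding)

    def parameters(self):
        ps = [self.w, self.b]
        if self.deformable:
            ps += [self.off_w, self.off_b]
        return ps


def predict_offsets(x, off_w, off_b, stride=1, padding=0) -> np.ndarray:
    """Run the offset-predictor convolution, returning the offset field.

    A zero-initialized predictor yields an all-zero field, so a freshly
    created deformable layer behaves as standard convolution.
    """
    xt = Tensor(np.asarray(x, dtype=np.float64)[None] if np.asarray(x).ndim == 3
                else np.asarray(x, dtype=np.float64))
    out = conv2d(xt, Tensor(off_w), Tensor(off_b), stride, padding)
    return out.data[0] if np.asarray(x).ndim == 3 else out.data


def deformable_conv(x, weights, bias, offsets, stride=1, padding=0) -> np.ndarray:
    """Deformable convolution on plain arrays (NCHW or CHW)."""
    xa = np.asarray(x, dtype=np.float64)
    single = xa.ndim == 3
    if single:
        xa = xa[None]
        offsets = np.asarray(offsets)[None]
    out = deform_conv2d(Tensor(xa), Tensor(weights),
                        None if bias is None else Tensor(bias),
                        Tensor(np.asarray(offsets, dtype=np.float64)),
                        stride, padding)
    return out.data[0] if single else out.data


# ---------------------------------------------------------------------------
# backbone configurations
# ---------------------------------------------------------------------------

@dataclass
class BackboneConfig:
    """Layer plan of a feature extractor.

    `specs` is a list of ("conv", in, out, k, pad, stride) / ("pool", k, s) /
    ("adapt", h, w) / ("final", in, out, k, pad, stride) entries; the final
    entry is the layer replaced by a deformable convolution in the deformable
    variants.  The spatial output is forced to `adaptive` (4×4) by average
    pooling immediately before the final layer.
    """
    name: str
    input_channels: int
    specs: list = field(default_factory=list)
    deform_out_channels: int = 0

    @property
    def feature_length(self) -> int:
        return 4 * 4 * self.deform_out_channels


def backbone_config(name: str, input_channels: int = 5) -> BackboneConfig:
    """Standard extractor plans.

    ``alexnet`` and ``vgg16`` follow the classical layer shapes (channel
    progression, kernel sizes, paddings and strides) with max pooling at the
    canonical block boundaries, ending in a 3×3 deformable layer at 4×4
    spatial size (384→256 and 512→512 channels respectively).  ``compact`` is
    a two-block desk-scale extractor for small frames.
    """
    c = input_channels
    if name == "alexnet":
        specs = [("conv", c, 96, 11, 0, 4), ("pool", 3, 2),
                 ("conv", 96, 256, 5, 2, 1), ("pool", 3, 2),
                 ("conv", 256, 384, 3, 1, 1), ("conv", 384, 384, 3, 1, 1),
                 ("adapt", 4, 4), ("final", 384, 256, 3, 1, 1)]
        out_ch = 256
    elif name == "vgg16":
        specs = [("conv", c, 64, 3, 1, 1), ("conv", 64, 64, 3, 1, 1), ("pool", 2, 2),
                 ("conv", 64, 128, 3, 1, 1), ("conv", 128, 128, 3, 1, 1), ("pool", 2, 2),
                 ("conv", 128, 256, 3, 1, 1), ("conv", 256, 256, 3, 1, 1),
                 ("conv", 256, 256, 3, 1, 1), ("pool", 2, 2),
                 ("conv", 256, 512, 3, 1, 1), ("conv", 512, 512, 3, 1, 1),
                 ("conv", 512, 512, 3, 1, 1), ("pool", 2, 2),
                 ("conv", 512, 512, 3, 1, 1), ("conv", 512, 512, 3, 1, 1),
                 ("adapt", 4, 4), ("final", 512, 512, 3, 1, 1)]
        out_ch = 512
    elif name == "compact":
        specs = [("conv", c, 16, 3, 1, 1), ("pool", 2, 2),
                 ("conv", 16, 32, 3, 1, 1), ("pool", 2, 2),
                 ("adapt", 4, 4), ("final", 32, 32, 3, 1, 1)]
        out_ch = 32
    else:
        raise ValueError(f"unknown backbone {name!r}")
    return BackboneConfig(name, input_channels, specs, out_ch)


class Backbone:
    """Feature extractor: convolutions + rectifiers + pooling, flattened."""

    def __init__(self, config: BackboneConfig, deformable_final: bool,
                 rng: np.random.Generator):
        self.config = config
        self.layers = []
        for spec in config.specs:
            kind = spec[0]
            if kind in ("conv", "final"):
                _, ci, co, k, p, s = spec
                self.layers.append(("conv", ConvLayer.create(
                    rng, ci, co, k, p, s,
                    deformable=deformable_final and kind == "final")))
            elif kind == "pool":
                self.layers.append(("pool", spec[1], spec[2]))
            elif kind == "adapt":
                self.layers.append(("adapt", (spec[1], spec[2])))

    def forward(self, x: Tensor) -> Tensor:
        for entry in self.layers:
            if entry[0] == "conv":
                x = entry[1].forward(x).relu()
            elif entry[0] == "pool":
                x = maxpool2d(x, entry[1], entry[2])
            else:
                x = adaptive_avgpool2d(x, entry[1])
        n = x.shape[0]
        return x.reshape(n, int(np.prod(x.shape[1:])))

    def parameters(self):
        ps = []
        for entry in self.layers:
            if entry[0] == "conv":
                ps += entry[1].parameters()
        return ps


def build_backbone(config: BackboneConfig, deformable_final: bool = True,
                   seed: int = 0) -> Backbone:
    """Construct a feature extractor from a layer plan (He-initialized)."""
    return Backbone(config, deformable_final, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Gate weights for one LSTM layer.

    Input-side matrices are stored (input_dim × hidden) and hidden-side
    (hidden × hidden) so a batch row-vector x_t maps through ``x_t @ W``.
    """
    W_ix: Tensor; W_ih: Tensor; b_i: Tensor
    W_fx: Tensor; W_fh: Tensor; b_f: Tensor
    W_cx: Tensor; W_ch: Tensor; b_c: Tensor
    W_ox: Tensor; W_oh: Tensor; b_o: Tensor

    @property
    def hidden_size(self) -> int:
        return self.W_ih.shape[0]

    @classmethod
    def create(cls, rng, input_dim: int, hidden: int):
        def wx():
            return Tensor(_he_array(rng, (input_dim, hidden), input_dim),
                          requires_grad=True)

        def wh():
            return Tensor(_he_array(rng, (hidden, hidden), hidden),
                          requires_grad=True)

        def bb():
            return Tensor(np.zeros(hidden), requires_grad=True)
        return cls(wx(), wh(), bb(), wx(), wh(), bb(), wx(), wh(), bb(),
                   wx(), wh(), bb())

    def parameters(self):
        return [self.W_ix, self.W_ih, self.b_i, self.W_fx, self.W_fh, self.b_f,
                self.W_cx, self.W_ch, self.b_c, self.W_ox, self.W_oh, self.b_o]


@dataclass
class LSTMState:
    h: Tensor
    c: Tensor


def lstm_step(x_t, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM cell update.

    i_t = σ(x_t W_ix + h_{t-1} W_ih + b_i)      (input gate)
    f_t = σ(x_t W_fx + h_{t-1} W_fh + b_f)      (forget gate)
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ tanh(x_t W_cx + h_{t-1} W_ch + b_c)
    o_t = σ(x_t W_ox + h_{t-1} W_oh + b_o)      (output gate)
    h_t = o_t ⊙ tanh(c_t)
    """
    x = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
    h, c = state.h, state.c
    if x.shape[-1] != params.W_ix.shape[0]:
        raise ValueError(f"input dim {x.shape[-1]} != {params.W_ix.shape[0]}")
    i = (x @ params.W_ix + h @ params.W_ih + params.b_i).sigmoid()
    f = (x @ params.W_fx + h @ params.W_fh + params.b_f).sigmoid()
    g = (x @ params.W_cx + h @ params.W_ch + params.b_c).tanh()
    c_new = f * c + i * g
    o = (x @ params.W_ox + h @ params.W_oh + params.b_o).sigmoid()
    return LSTMState(o * c_new.tanh(), c_new)


def _zero_state(batch: int, hidden: int) -> LSTMState:
    return LSTMState(Tensor(np.zeros((batch, hidden))),
                     Tensor(np.zeros((batch, hidden))))


def _run_lstm(xs: list, params: LSTMParams) -> list:
    batch = xs[0].shape[0]
    state = _zero_state(batch, params.hidden_size)
    hs = []
    for x in xs:
        state = lstm_step(x, state, params)
        hs.append(state.h)
    return hs


def bilstm_forward(features, layer1: LSTMParams, layer2: LSTMParams,
                   mode: str = "stacked_reverse") -> Tensor:
    """Two-layer recurrent fusion over a feature sequence.

    ``stacked_reverse`` (default): layer 1 runs forward over the T feature
    vectors; layer 2 consumes layer 1's hidden sequence in reverse time
    order; the output matrix H holds layer-2 states re-ordered back to
    original time order, shape (batch, hidden, T).

    ``concat``: conventional bidirectional wiring — layer 1 forward and
    layer 2 backward both read the features, and H concatenates the two
    hidden states per time step (batch, 2·hidden, T).
    """
    if isinstance(features, Tensor):
        xs = [features[:, t] if features.data.ndim == 3 else features[t]
              for t in range(features.shape[-2] if features.data.ndim == 3 else features.shape[0])]
    else:
        arr = np.asarray(features, dtype=np.float64)
        if arr.ndim == 2:   # (T, D) -> batch of 1
            arr = arr[None]
        xs = [Tensor(arr[:, t]) for t in range(arr.shape[1])]
    if not xs:
        raise ValueError("empty sequence")
    if mode == "stacked_reverse":
        h1 = _run_lstm(xs, layer1)
        h2_rev = _run_lstm(h1[::-1], layer2)
        cols = h2_rev[::-1]
    elif mode == "concat":
        h1 = _run_lstm(xs, layer1)
        h2 = _run_lstm(xs[::-1], layer2)[::-1]
        cols = [stack([a, b], axis=1).reshape(a.shape[0], 2 * a.shape[1])
                for a, b in zip(h1, h2)]
    else:
        raise ValueError(f"unknown BiLSTM mode {mode!r}")
    return stack(cols, axis=2)   # (batch, hidden_dim, T)


# ---------------------------------------------------------------------------
# attention and head
# ---------------------------------------------------------------------------

def attention_pool(H, w):
    """Softmax attention over time: M = tanh(H), alpha = softmax(w^T M),
    R_att = H alpha^T.  H is (hidden, T) or (batch, hidden, T)."""
    as_tensor = isinstance(H, Tensor)
    Ht = H if as_tensor else Tensor(np.asarray(H, dtype=np.float64))
    wt = w if isinstance(w, Tensor) else Tensor(np.asarray(w, dtype=np.float64))
    squeeze = Ht.data.ndim == 2
    if squeeze:
        Ht = Ht.reshape(1, *Ht.shape)
    B, D, T = Ht.shape
    M = Ht.tanh()
    z = (wt.reshape(1, D, 1) * M).sum(axis=1)        # (B, T)
    alpha = softmax(z, axis=-1)
    R = (Ht * alpha.reshape(B, 1, T)).sum(axis=2)    # (B, D)
    if squeeze:
        R, alpha = R.reshape(D), alpha.reshape(T)
    return (R, alpha) if as_tensor else (R.data, alpha.data)


def classify(R, fc1_w, fc1_b, fc2_w, fc2_b) -> Tensor:
    """Two affine layers with a rectifier between, then softmax."""
    x = R if isinstance(R, Tensor) else Tensor(np.asarray(R, dtype=np.float64))
    single = x.data.ndim == 1
    if single:
        x = x.reshape(1, x.shape[0])
    z = (x @ fc1_w + fc1_b).relu() @ fc2_w + fc2_b
    p = softmax(z, axis=-1)
    return p.reshape(p.shape[-1]) if single else p


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class StressNet:
    """Feature extractor + stacked BiLSTM + (optional) attention + head.

    The extractor weights are shared across time steps.  Variants:

    - ``case1_std_bilstm``        standard final conv, last-state pooling
    - ``case2_std_bilstm_attn``   standard final conv, attention pooling
    - ``case3_deform_bilstm``     deformable final conv, last-state pooling
    - ``full_deform_bilstm_attn`` deformable final conv, attention pooling
    """

    def __init__(self, backbone: str = "compact", input_channels: int = 5,
                 hidden_size: int = 128, head_hidden: int = 64,
                 n_classes: int = 3, variant: str = "full",
                 bilstm_mode: str = "stacked_reverse", seed: int = 0):
        variant = resolve_variant(variant)
        self.config = dict(backbone=backbone, input_channels=input_channels,
                           hidden_size=hidden_size, head_hidden=head_hidden,
                           n_classes=n_classes, variant=variant,
                           bilstm_mode=bilstm_mode, seed=seed)
        rng = np.random.default_rng(seed)
        bc = backbone_config(backbone, input_channels)
        self.backbone = Backbone(bc, variant_uses_deform(variant), rng)
        feat = bc.feature_length
        self.lstm1 = LSTMParams.create(rng, feat, hidden_size)
        self.lstm2 = LSTMParams.create(rng, hidden_size, hidden_size)
        hdim = hidden_size if bilstm_mode == "stacked_reverse" else 2 * hidden_size
        self.att_w = (Tensor(_he_array(rng, (hdim,), hdim), requires_grad=True)
                      if variant_uses_attention(variant) else None)
        self.fc1_w = Tensor(_he_array(rng, (hdim, head_hidden), hdim), requires_grad=True)
        self.fc1_b = Tensor(np.zeros(head_hidden), requires_grad=True)
        self.fc2_w = Tensor(_he_array(rng, (head_hidden, n_classes), head_hidden),
                            requires_grad=True)
        self.fc2_b = Tensor(np.zeros(n_classes), requires_grad=True)

    # -- forward ----------------------------------------------------------
    def forward(self, seqs) -> Tensor:
        """Class probabilities for a batch of sequences (B,T,C,H,W)."""
        arr = seqs if isinstance(seqs, Tensor) else Tensor(np.asarray(seqs, dtype=np.float64))
        if arr.data.ndim == 4:
            arr = arr.reshape(1, *arr.shape)
        B, T, C, H, W = arr.shape
        if C != self.config["input_channels"]:
            raise ValueError(f"expected {self.config['input_channels']} channels, got {C}")
        flat = arr.reshape(B * T, C, H, W)
        feats = self.backbone.forward(flat)          # (B*T, F)
        feats = feats.reshape(B, T, feats.shape[1])
        Hmat = bilstm_forward(feats, self.lstm1, self.lstm2,
                              self.config["bilstm_mode"])
        if self.att_w is not None:
            R, _ = attention_pool(Hmat, self.att_w)
        else:
            R = Hmat[:, :, -1]                       # h_T in original time order
        return classify(R, self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b)

    def predict_proba(self, seqs) -> np.ndarray:
        return self.forward(seqs).data

    def predict(self, seqs) -> np.ndarray:
        return self.predict_proba(seqs).argmax(axis=-1)

    # -- parameters / persistence -----------------------------------------
    def parameters(self):
        ps = self.backbone.parameters()
        ps += self.lstm1.parameters() + self.lstm2.parameters()
        if self.att_w is not None:
            ps.append(self.att_w)
        ps += [self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b]
        return ps

    def get_state(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = np.array(a, dtype=np.float64)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path, __config__=json.dumps(self.config),
                 __hash__=self.config_hash(), **arrays)

    @classmethod
    def load(cls, path) -> "StressNet":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            model = cls(**cfg)
            if str(z["__hash__"]) != model.config_hash():
                raise ValueError("checkpoint config hash mismatch")
            model.set_state([z[f"p{i}"] for i in range(len(model.parameters()))])
        return model


def stressnet_forward(seq, model: StressNet) -> np.ndarray:
    """Class-probability vector for a single image sequence (T,C,H,W)."""
    return model.predict_proba(np.asarray(seq))[0]
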