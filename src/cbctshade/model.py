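"""Declarative U-Net construction, parameter counting and fine-tune scoping.

The network is a symmetric encoder/decoder for single-channel axial slices.
Each processing block is conv3x3 + ReLU + BN, dropout, conv3x3 + ReLU + BN.
Every contracting block is followed by 2x2 max pooling; every expanding block
is followed by a channel-preserving kernel-2/stride-2 transpose convolution,
after which the matching-resolution contracting feature map is concatenated.
A final single-feature convolution with sigmoid activation produces the
output in [0, 1].

For the reference configuration (4 blocks, 16 first-level filters) the level
widths read 16-32-64-128 mirrored as 128-64-32-16, and the total trainable
parameter count of this construction is 919,777 (convolution and transpose-
convolution weights and biases plus batch-norm scale/shift).

Fine-tune scopes are symmetric: pair ``d`` (counted from the deepest level)
couples contracting block ``n_blocks - d`` with expanding block ``d - 1`` and
its transpose convolution, so a scope of 1 on the 4-block network retrains
exactly the 128/128 pair and a scope of 2 the 64/128/128/64 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative U-Net description from which counts and scopes derive."""

    n_blocks: int = 4
    first_filters: int = 16
    transpose_kernel: int = 2
    final_kernel: int = 1
    dropout_rate: float = 0.10
    # trainable flags for symmetric block pairs, index 0 = deepest pair
    pair_trainable: tuple[bool, ...] = ()
    final_trainable: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.first_filters < 1:
            raise ValueError("n_blocks and first_filters must be >= 1")
        if not self.pair_trainable:
            object.__setattr__(self, "pair_trainable", (True,) * self.n_blocks)
        if len(self.pair_trainable) != self.n_blocks:
            raise ValueError("pair_trainable must have one flag per block pair")

    @property
    def encoder_widths(self) -> list[int]:
        return [self.first_filters * 2**i for i in range(self.n_blocks)]

    @property
    def decoder_widths(self) -> list[int]:
        return self.encoder_widths[::-1]

    def width_signature(self) -> str:
        """E.g. '16-32-64-128-128-64-32-16' for the reference configuration."""
        return "-".join(str(w) for w in self.encoder_widths + self.decoder_widths)

    def decoder_input_channels(self) -> list[int]:
        """Input channels of each expanding block (after skip concatenation)."""
        enc = self.encoder_widths
        ins = [enc[-1]]  # pooled bottom features
        for i in range(1, self.n_blocks):
            # previous transpose output + matching skip
            ins.append(self.decoder_widths[i - 1] + enc[self.n_blocks - i])
        return ins

    @property
    def final_input_channels(self) -> int:
        return self.decoder_widths[-1] + self.encoder_widths[0]


def build_unet(n_blocks: int = 4, first_filters: int = 16, **options) -> NetworkSpec:
    """Build a NetworkSpec; structural options are keyword arguments."""
    return NetworkSpec(n_blocks=n_blocks, first_filters=first_filters, **options)


def _block_params(c_in: int, c_out: int) -> int:
    conv1 = c_in * c_out * 9 + c_out
    conv2 = c_out * c_out * 9 + c_out
    return conv1 + conv2 + 2 * 2 * c_out  # + two BN (gamma, beta) layers


def count_trainable_parameters(spec: NetworkSpec, scoped: bool = True) -> int:
    """Trainable parameter count of the network described by ``spec``.

    Counts conv / transpose-conv weights and biases and batch-norm
    scale/shift pairs.  When ``scoped`` and a fine-tune scope is active, only
    blocks flagged trainable contribute (full count when every flag is set).
    """
    enc = spec.encoder_widths
    dec = spec.decoder_widths
    dec_in = spec.decoder_input_channels()
    total = 0
    c_in = 1
    for i, f in enumerate(enc):
        pair_depth_idx = spec.n_blocks - 1 - i  # 0 = deepest
        if not scoped or spec.pair_trainable[pair_depth_idx]:
            total += _block_params(c_in, f)
        c_in = f
    for i, f in enumerate(dec):
        if not scoped or spec.pair_trainable[i]:
            total += _block_params(dec_in[i], f)
            total += f * f * spec.transpose_kernel**2 + f  # transpose conv
    if not scoped or spec.final_trainable:
        total += spec.final_input_channels * spec.final_kernel**2 + 1
    return total


def set_finetune_scope(spec: NetworkSpec, x: int) -> NetworkSpec:
    """Mark the ``x`` deepest symmetric block pairs trainable, freeze the rest.

    ``x = 0`` freezes every block (the final conv stays governed by
    ``final_trainable``); ``x = n_blocks`` restores full end-to-end training.
    """
    if not (0 <= x <= spec.n_blocks):
        raise ValueError(f"fine-tune scope {x} out of range [0, {spec.n_blocks}]")
    flags = tuple(i < x for i in range(spec.n_blocks))
    return replace(spec, pair_trainable=flags)


# ---------------------------------------------------------------------------
# runnable network


class _Block:
    """conv -> ReLU -> BN -> dropout -> conv -> ReLU -> BN."""

    def __init__(self, c_in: int, c_out: int, dropout: float, rng: np.random.Generator):
        s = lambda: int(rng.integers(0, 2**31 - 1))
        self.conv1 = nn.Conv2D(c_in, c_out, 3, seed=s())
        self.relu1 = nn.ReLU()
        self.bn1 = nn.BatchNorm2D(c_out)
        self.drop = nn.Dropout(dropout)
        self.conv2 = nn.Conv2D(c_out, c_out, 3, seed=s())
        self.relu2 = nn.ReLU()
        self.bn2 = nn.BatchNorm2D(c_out)

    @property
    def layers(self):
        return [self.conv1, self.relu1, self.bn1, self.drop, self.conv2, self.relu2, self.bn2]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def set_trainable(self, flag: bool):
        for layer in self.layers:
            layer.trainable = flag


class UNet:
    """Runnable U-Net instantiated from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc_w = spec.encoder_widths
        dec_w = spec.decoder_widths
        dec_in = spec.decoder_input_channels()
        self.enc: list[_Block] = []
        self.pools: list[nn.MaxPool2D] = []
        c_in = 1
        for f in enc_w:
            self.enc.append(_Block(c_in, f, spec.dropout_rate, rng))
            self.pools.append(nn.MaxPool2D())
            c_in = f
        self.dec: list[_Block] = []
        self.trans: list[nn.ConvTranspose2D] = []
        for i, f in enumerate(dec_w):
            self.dec.append(_Block(dec_in[i], f, spec.dropout_rate, rng))
            self.trans.append(
                nn.ConvTranspose2D(f, f, spec.transpose_kernel, seed=int(rng.integers(0, 2**31 - 1)))
            )
        if spec.final_kernel != 1:
            raise NotImplementedError("runnable network supports final_kernel=1")
        self.final = nn.Conv2D(spec.final_input_channels, 1, 1, seed=int(rng.integers(0, 2**31 - 1)))
        self.sigmoid = nn.Sigmoid()
        self.apply_scope()

    # -- structure ----------------------------------------------------------

    @property
    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.layers)
        out.extend(self.pools)
        for blk, tc in zip(self.dec, self.trans):
            out.extend(blk.layers)
            out.append(tc)
        out.extend([self.final, self.sigmoid])
        return out

    def apply_scope(self) -> None:
        """Propagate the spec's trainable flags onto the layers."""
        n = self.spec.n_blocks
        for d in range(n):  # d = 0 is the deepest pair
            flag = bool(self.spec.pair_trainable[d])
            self.enc[n - 1 - d].set_trainable(flag)
            self.dec[d].set_trainable(flag)
            self.trans[d].trainable = flag
        self.final.trainable = bool(self.spec.final_trainable)

    def set_finetune_scope(self, x: int) -> None:
        self.spec = set_finetune_scope(self.spec, x)
        self.apply_scope()

    def count_parameters(self, only_trainable: bool = False) -> int:
        return int(
            sum(l.n_params for l in self.layers if (l.trainable or not only_trainable))
        )

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        h = np.ascontiguousarray(x, dtype=np.float32)
        side = h.shape[-1]
        if side % 2**self.spec.n_blocks:
            raise ValueError(
                f"input side {side} not divisible by 2^{self.spec.n_blocks}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        self._concat_ch = []
        n = self.spec.n_blocks
        for i, (blk, tc) in enumerate(zip(self.dec, self.trans)):
            h = blk.forward(h, training)
            h = tc.forward(h, training)
            skip = skips[n - 1 - i]
            self._concat_ch.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
        return self.sigmoid.forward(self.final.forward(h, training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = self.spec.n_blocks
        dh = self.final.backward(self.sigmoid.backward(dy))
        dskips: list[np.ndarray | None] = [None] * n
        for i in reversed(range(n)):
            ch = self._concat_ch[i]
            d_up, d_skip = dh[:, :ch], dh[:, ch:]
            dskips[n - 1 - i] = d_skip
            dh = self.dec[i].backward(self.trans[i].backward(np.ascontiguousarray(d_up)))
        for i in reversed(range(n)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)
        return dh

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on one 2D slice or a (B, H, W) stack; returns same shape."""
        squeeze = x.ndim == 2
        y = self.forward(x, training=False)[:, 0]
        return y[0] if squeeze else y

    # -- state --------------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                state[f"{i}:{k}"] = p.copy()
            if isinstance(layer, nn.BatchNorm2D):
                state[f"{i}:running_mean"] = layer.running_mean.copy()
                state[f"{i}:running_var"] = layer.running_var.copy()
        return state

    def save(self, path) -> None:
        """Serialize weights, batch-norm statistics and the spec to .npz."""
        import json

        meta = dict(self.spec.__dict__)
        meta["pair_trainable"] = list(meta["pair_trainable"])
        np.savez(path, __spec__=json.dumps(meta), **self.get_state())

    @classmethod
    def load(cls, path) -> "UNet":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__spec__"]))
            meta["pair_trainable"] = tuple(meta["pair_trainable"])
            spec = NetworkSpec(**meta)
            net = cls(spec)
            net.set_state({k: data[k] for k in data.files if k != "__spec__"})
        return net

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{i}:{k}"]
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean[...] = state[f"{i}:running_mean"]
                layer.running_var[...] = state[f"{i}:running_var"]
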