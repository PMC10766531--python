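"""The lightweight spatiotemporal transformer.

Layout: a temporal encoder module (two encoders, each compressing the frame
axis by a factor ``r`` with 3x3 spatial convolutions and *no* spatial
downsampling) -> one spatiotemporal transformer block (STB) -> a temporal
decoder module (two decoders restoring the original frame count).

Inside the STB the feature volume is cut into ``p x p`` spatial patches for
every compressed frame; each patch is channel-reduced, flattened and linearly
embedded into a token.  Learned spatial and temporal position embeddings are
added and two cascaded multi-head self-attention blocks let every token
interact with every other token — the receptive field is global in both
space and time after a single STB.  A windowed (Swin-style) spatial block
with one cyclically shifted sub-block then refines local structure.

Frame counts are padded by mirror reflection to a multiple of r^2 and spatial
extents to a multiple of p; all padding is cropped on exit, so output shape
always equals input shape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, TransformerBlock, gelu, trunc_normal

__all__ = [
    "ModelConfig",
    "FeatureVolume",
    "SRDTransNet",
    "Checkpoint",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = "srdtrans-ckpt-1"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    r: temporal compression factor of each encoder (two encoders -> T/r^2).
    p: attention patch / window edge in pixels.
    heads: attention heads; embed_channels: feature channels after encoding.
    window_shift: whether the second spatial sub-block uses shifted windows.
    max_patch_grid / max_time_tokens bound the learned position-embedding
    tables (and hence the largest patch grid a single forward pass accepts).
    """

    r: int = 4
    n_encoders: int = 2
    p: int = 7
    heads: int = 8
    embed_channels: int = 128
    window_shift: bool = True
    max_patch_grid: int = 12
    max_time_tokens: int = 16
    init_seed: int = 0

    def __post_init__(self):
        if self.r < 2:
            raise ValueError("temporal compression factor r must be >= 2")
        if self.p < 2:
            raise ValueError("attention patch edge p must be >= 2")
        if (self.embed_channels // 2) % self.heads:
            raise ValueError("embed_channels/2 must be divisible by heads")

    @property
    def t_factor(self) -> int:
        """Total temporal compression T -> T / t_factor."""
        return self.r**self.n_encoders

    @property
    def min_frames(self) -> int:
        """Smallest T the mirror-padding policy can stretch to t_factor."""
        return int(np.ceil(self.t_factor / 2))

    @property
    def mid_channels(self) -> int:
        return max(self.embed_channels // 8, 8)

    @property
    def reduce_channels(self) -> int:
        return max(self.embed_channels // 32, 4)


@dataclass
class FeatureVolume:
    """Intermediate activation: (rows, cols, compressed-frames, channels)."""

    data: np.ndarray
    provenance: str  # encoded | attended | decoded
    pad_spatial: tuple[int, int] = (0, 0)
    pad_temporal: int = 0
    original_shape: tuple[int, int, int] | None = None  # (H, W, T) before padding


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    """Index vector realizing mirror padding of ``pad`` elements at the end."""
    return np.pad(np.arange(n), (0, pad), mode="symmetric")


class SRDTransNet(Module):
    """Temporal encoders -> spatiotemporal transformer block -> temporal decoders."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), dtype=np.float32):
        if cfg.n_encoders != 2:
            raise ValueError("this architecture uses exactly two temporal encoders")
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.init_seed)
        r, c1, C, cr, p = cfg.r, cfg.mid_channels, cfg.embed_channels, cfg.reduce_channels, cfg.p
        d_inner = C // 2
        self.enc1 = Conv2d(r, c1, 3, rng, dtype)
        self.enc2 = Conv2d(r * c1, C, 3, rng, dtype)
        self.patch_reduce = Linear(C, cr, rng, dtype)
        self.patch_embed = Linear(p * p * cr, C, rng, dtype)
        self.pos_spatial = Tensor(
            trunc_normal(rng, (cfg.max_patch_grid, cfg.max_patch_grid, C), dtype=dtype), requires_grad=True
        )
        self.pos_temporal = Tensor(trunc_normal(rng, (cfg.max_time_tokens, C), dtype=dtype), requires_grad=True)
        self.t_blocks = [TransformerBlock(C, cfg.heads, d_inner, C, rng, dtype) for _ in range(2)]
        self.patch_unembed = Linear(C, p * p * cr, rng, dtype)
        self.patch_expand = Linear(cr, C, rng, dtype)
        self.s_blocks = [TransformerBlock(C, cfg.heads, d_inner, C, rng, dtype) for _ in range(2)]
        self.dec2 = Conv2d(C, r * c1, 3, rng, dtype)
        self.dec1 = Conv2d(c1, r, 3, rng, dtype)
        # final output projection bias starts at zero (Conv2d already zero-inits biases)
        self.last_feature_shapes: list[tuple[str, tuple[int, ...]]] = []

    # ----- padding policy ---------------------------------------------------
    def _pad_temporal(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        """Mirror-pad (B, H, W, T) to a multiple of r^2 frames."""
        T = x.shape[3]
        tf = self.cfg.t_factor
        pad_t = (-T) % tf
        if pad_t > T:
            raise ValueError(
                f"input too short along time: T={T}; this configuration needs at least "
                f"{self.cfg.min_frames} frames"
            )
        if pad_t:
            x = x[..., _reflect_indices(T, pad_t)]
        return x, pad_t

    # ----- stages -----------------------------------------------------------
    def _encode(self, xt: Tensor, B: int) -> Tensor:
        """(B, T, H, W) -> (B*T2, C, H, W) feature tensor."""
        _, T, H, W = xt.shape
        r, c1 = self.cfg.r, self.cfg.mid_channels
        f = xt.reshape(B * (T // r), r, H, W)
        f = gelu(self.enc1(f))
        self._trace("encoder-1", f.shape)
        T1 = T // r
        f = f.reshape(B * (T1 // r), r * c1, H, W)
        f = gelu(self.enc2(f))
        self._trace("encoder-2", f.shape)
        return f

    def _stb(self, f: Tensor, B: int) -> Tensor:
        cfg = self.cfg
        p, C, cr = cfg.p, cfg.embed_channels, cfg.reduce_channels
        BT2, _, H0, W0 = f.shape
        T2 = BT2 // B
        # mirror-pad the spatial extent to a multiple of p (cropped on exit)
        pad_h, pad_w = (-H0) % p, (-W0) % p
        if pad_h:
            f = f[:, :, _reflect_indices(H0, pad_h), :]
        if pad_w:
            f = f[:, :, :, _reflect_indices(W0, pad_w)]
        H, W = H0 + pad_h, W0 + pad_w
        gh, gw = H // p, W // p
        if gh > cfg.max_patch_grid or gw > cfg.max_patch_grid:
            raise ValueError(
                f"patch grid {gh}x{gw} exceeds max_patch_grid={cfg.max_patch_grid}; use smaller tiles"
            )
        if T2 > cfg.max_time_tokens:
            raise ValueError(f"{T2} compressed frames exceed max_time_tokens={cfg.max_time_tokens}")

        # --- global spatiotemporal attention over patch tokens -------------
        g = f.transpose(0, 2, 3, 1)  # (B*T2, H, W, C)
        tok = self.patch_reduce(g)  # (B*T2, H, W, cr)
        tok = tok.reshape(B, T2, gh, p, gw, p, cr).transpose(0, 1, 2, 4, 3, 5, 6)
        tok = tok.reshape(B, T2, gh * gw, p * p * cr)
        tok = self.patch_embed(tok)  # (B, T2, gh*gw, C)
        pos_s = self.pos_spatial[:gh, :gw].reshape(gh * gw, C)
        pos_t = self.pos_temporal[:T2].reshape(T2, 1, C)
        tok = tok + pos_s + pos_t
        tok = tok.reshape(B, T2 * gh * gw, C)
        for blk in self.t_blocks:
            tok = blk(tok)
        tok = self.patch_unembed(tok.reshape(B, T2, gh * gw, C))
        tok = tok.reshape(B, T2, gh, gw, p, p, cr).transpose(0, 1, 2, 4, 3, 5, 6)
        tok = tok.reshape(BT2, H, W, cr)
        f = f + self.patch_expand(tok).transpose(0, 3, 1, 2)
        self._trace("stb-temporal", f.shape)

        # --- windowed spatial attention (regular + shifted sub-block) ------
        shift = p // 2 if cfg.window_shift else 0
        g = f.transpose(0, 2, 3, 1)  # (B*T2, H, W, C)
        g = self._windowed(g, self.s_blocks[0], gh, gw, 0)
        g = self._windowed(g, self.s_blocks[1], gh, gw, shift)
        f = g.transpose(0, 3, 1, 2)
        f = f[:, :, :H0, :W0]  # crop the spatial mirror padding
        self._trace("stb-spatial", f.shape)
        return f

    def _windowed(self, g: Tensor, block: TransformerBlock, gh: int, gw: int, shift: int) -> Tensor:
        p, C = self.cfg.p, self.cfg.embed_channels
        BT2, H, W, _ = g.shape
        if shift:
            g = g.roll((-shift, -shift), axis=(1, 2))
        g = g.reshape(BT2, gh, p, gw, p, C).transpose(0, 1, 3, 2, 4, 5).reshape(BT2 * gh * gw, p * p, C)
        g = block(g)
        g = g.reshape(BT2, gh, gw, p, p, C).transpose(0, 1, 3, 2, 4, 5).reshape(BT2, H, W, C)
        if shift:
            g = g.roll((shift, shift), axis=(1, 2))
        return g

    def _decode(self, f: Tensor, B: int) -> Tensor:
        """(B*T2, C, H, W) -> (B, T, H, W)."""
        r, c1 = self.cfg.r, self.cfg.mid_channels
        BT2, _, H, W = f.shape
        f = gelu(self.dec2(f))  # (B*T2, r*c1, H, W)
        self._trace("decoder-2", f.shape)
        f = f.reshape(BT2 * r, c1, H, W)
        f = self.dec1(f)  # (B*T2*r, r, H, W) -> T frames
        self._trace("decoder-1", f.shape)
        return f.reshape(B, BT2 // B * r * r, H, W)

    def _trace(self, stage: str, shape) -> None:
        self.last_feature_shapes.append((stage, tuple(shape)))

    # ----- public surface ----------------------------------------------------
    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Full forward pass on (B, H, W, T) or (H, W, T); returns same shape."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(x)
        squeeze = arr.ndim == 3
        if squeeze:
            arr = arr[None]
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in model input")
        B, H, W, T = arr.shape
        padded, pt = self._pad_temporal(arr.astype(self.dtype))
        self.last_feature_shapes = []
        self._trace("input-padded", padded.shape)
        xt = Tensor(np.moveaxis(padded, -1, 1))  # (B, T', H, W)
        f = self._encode(xt, B)
        f = self._stb(f, B)
        out = self._decode(f, B)  # (B, T', H, W)
        out = out.transpose(0, 2, 3, 1)  # (B, H, W, T')
        if pt:
            out = out[:, :, :, :T]
        self._trace("output", out.shape)
        return out.reshape(H, W, T) if squeeze else out

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass without building gradient tape."""
        params = self.parameters()
        flags = {k: p.requires_grad for k, p in params.items()}
        for p in params.values():
            p.requires_grad = False
        try:
            out = self.forward(x)
        finally:
            for k, p in params.items():
                p.requires_grad = flags[k]
        return out.data

    def temporal_encode(self, x: np.ndarray) -> FeatureVolume:
        """(H, W, T) -> encoded feature volume (H', W', T/r^2, C)."""
        arr = np.asarray(x, dtype=self.dtype)
        if arr.ndim != 3:
            raise ValueError("expected (row, col, frame) input")
        H, W, T = arr.shape
        padded, pt = self._pad_temporal(arr[None])
        f = self._encode(Tensor(np.moveaxis(padded, -1, 1)), 1)
        data = np.moveaxis(f.data, 1, -1)  # (T2, H, W, C)
        data = np.moveaxis(data, 0, 2)  # (H, W, T2, C)
        return FeatureVolume(data, "encoded", (0, 0), pt, (H, W, T))

    def stb_forward(self, fv: FeatureVolume) -> FeatureVolume:
        data = np.moveaxis(np.moveaxis(fv.data, 2, 0), -1, 1)  # (T2, C, H', W')
        if data.shape[1] != self.cfg.embed_channels:
            raise ValueError(
                f"feature volume has {data.shape[1]} channels; model expects {self.cfg.embed_channels}"
            )
        out = self._stb(Tensor(data.astype(self.dtype)), 1).data
        out = np.moveaxis(np.moveaxis(out, 1, -1), 0, 2)
        return FeatureVolume(out, "attended", fv.pad_spatial, fv.pad_temporal, fv.original_shape)

    def temporal_decode(self, fv: FeatureVolume, original_T: int) -> np.ndarray:
        """Feature volume -> (H, W, original_T) intensity stack (padding cropped)."""
        T2 = fv.data.shape[2]
        T_padded = T2 * self.cfg.t_factor
        if fv.original_shape is not None and fv.original_shape[2] != original_T:
            raise ValueError(
                f"original_T={original_T} inconsistent with recorded pad metadata ({fv.original_shape[2]})"
            )
        if not (T_padded - fv.pad_temporal == original_T):
            raise ValueError(
                f"original_T={original_T} incompatible with {T2} compressed frames and pad {fv.pad_temporal}"
            )
        data = np.moveaxis(np.moveaxis(fv.data, 2, 0), -1, 1)
        out = self._decode(Tensor(data.astype(self.dtype)), 1).data[0]  # (T', H, W)
        out = np.moveaxis(out, 0, -1)
        return out[:, :, :original_T]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters().values()))


# ----- checkpoints -----------------------------------------------------------


@dataclass
class Checkpoint:
    """Trained weights plus the normalization statistics needed at inference."""

    config: ModelConfig
    state: dict[str, np.ndarray]
    norm_mean: float = 0.0
    norm_std: float = 1.0
    format_version: str = CHECKPOINT_FORMAT_VERSION
    epoch: int | None = None

    def build_model(self) -> SRDTransNet:
        model = SRDTransNet(self.config)
        model.load_state(self.state)
        return model


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    meta = {
        "format_version": ckpt.format_version,
        "config": asdict(ckpt.config),
        "norm_mean": float(ckpt.norm_mean),
        "norm_std": float(ckpt.norm_std),
        "epoch": ckpt.epoch,
    }
    arrays = {f"param/{k}": v for k, v in ckpt.state.items()}
    with open(path, "wb") as fh:  # keep the exact filename (np.savez appends .npz)
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        if "__meta__" not in z:
            raise ValueError(f"not a srdtrans checkpoint (missing metadata): {path}")
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format {meta.get('format_version')!r} unsupported "
                f"(expected {CHECKPOINT_FORMAT_VERSION!r})"
            )
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return Checkpoint(
        config=ModelConfig(**meta["config"]),
        state=state,
        norm_mean=meta["norm_mean"],
        norm_std=meta["norm_std"],
        epoch=meta["epoch"],
    )
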