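"""End-to-end multi-task model: fusion -> hybrid encoder -> {segmentation
decoder, marker head}, with YAML-configurable sizes and versioned
checkpoint serialization."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cmaf import CMAF, CmafConfig
from .data import NUM_CLASSES
from .decoder import DecoderConfig, SegDecoder, SegmentationOutput
from .encoder import EncoderConfig, HybridEncoder
from .markers import MarkerHead, MarkerHeadConfig
from .nn import Module, Tensor, no_grad

CHECKPOINT_SCHEMA = 1

__all__ = ["ModelConfig", "GliomaNet", "tiny_config", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    cmaf: CmafConfig = field(default_factory=CmafConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    markers: MarkerHeadConfig = field(default_factory=MarkerHeadConfig)
    seed: int = 0

    def __post_init__(self):
        # keep cross-module channel contracts consistent
        self.encoder.in_channels = self.cmaf.channels
        self.decoder.latent_channels = self.encoder.out_channels
        w = self.encoder.cnn_widths
        self.decoder.skip_channels = (w[0], w[0], w[1])
        self.markers.latent_channels = self.encoder.out_channels

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            cmaf=CmafConfig(**d.get("cmaf", {})),
            encoder=EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in d.get("encoder", {}).items()}),
            decoder=DecoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in d.get("decoder", {}).items()}),
            markers=MarkerHeadConfig(**d.get("markers", {})),
            seed=d.get("seed", 0),
        )

    def to_dict(self) -> dict:
        return {
            "cmaf": asdict(self.cmaf),
            "encoder": asdict(self.encoder),
            "decoder": asdict(self.decoder),
            "markers": asdict(self.markers),
            "seed": self.seed,
        }


def tiny_config(seed: int = 0) -> ModelConfig:
    """Desk-scale configuration for CPU experiments on small phantoms."""
    return ModelConfig(
        cmaf=CmafConfig(channels=8),
        encoder=EncoderConfig(
            in_channels=8,
            cnn_widths=(8, 16, 16),
            branch_channels=16,
            out_channels=16,
            window=4,
            swin_dim=8,
            swin_depths=(1,),
            swin_heads=(2,),
        ),
        decoder=DecoderConfig(
            latent_channels=16, skip_channels=(8, 8, 16), widths=(16, 16, 16), se_ratio=4
        ),
        markers=MarkerHeadConfig(latent_channels=16, attn_hidden=16, head_hidden=16),
        seed=seed,
    )


class GliomaNet(Module):
    def __init__(self, cfg: ModelConfig, build_shape: tuple[int, int, int] = (16, 16, 16)):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.cmaf = CMAF(cfg.cmaf, rng)
        self.encoder = HybridEncoder(cfg.encoder, rng)
        self.decoder = SegDecoder(cfg.decoder, rng)
        self.marker_head = MarkerHead(cfg.markers, rng)
        # materialize lazily-built attention blocks with a dry forward
        self.eval()
        with no_grad():
            self.forward(np.zeros((1, 4) + tuple(build_shape)))
        self.train()

    def forward(self, x) -> tuple[SegmentationOutput, dict[str, Tensor], dict]:
        """x: (N, 4, H, W, D) preprocessed modalities.

        Returns (segmentation output, marker probability tensors, extras)
        where extras carries the CMAF attention field and the latent volume.
        """
        fused, attn = self.cmaf(x)
        latent, skips = self.encoder(fused)
        seg = self.decoder(latent, skips)
        markers = self.marker_head(latent, seg.probabilities)
        return seg, markers, {"cmaf_attention": attn, "latent": latent}


def save_checkpoint(path, model: GliomaNet, extra: dict | None = None):
    """Serialize parameters + config to an .npz with a JSON config sidecar field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path, build_shape=(16, 16, 16)) -> tuple[GliomaNet, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    model = GliomaNet(cfg, build_shape=build_shape)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
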