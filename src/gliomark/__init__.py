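"""gliomark: multi-modal MRI glioma subregion segmentation and molecular
marker prediction.

The package implements a multi-task volumetric network — voxel-wise
cross-modality attention fusion of the four standard MRI sequences (T1,
T1ce, T2, FLAIR), a hybrid CNN / shifted-window-transformer encoder, a
hierarchical segmentation decoder for the four post-treatment tumor
subregions (ET, NETC, SNFH, RC), and a segmentation-gated attention-pooled
head predicting IDH, 1p/19q and TERT status — together with a synthetic
phantom generator, the preprocessing pipeline, training utilities,
Gaussian-weighted sliding-window inference and a full evaluation stack.
"""

__version__ = "0.1.0"

MODALITIES = ("t1", "t1ce", "t2", "flair")
CLASS_NAMES = ("background", "ET", "NETC", "SNFH", "RC")
MARKERS = ("idh", "1p19q", "tert")


def __getattr__(name):
    # lazy top-level access to the main entry points
    if name in ("GliomaNet", "ModelConfig", "tiny_config"):
        from . import model

        return getattr(model, name)
    if name == "sliding_window_predict":
        from .inference import sliding_window_predict

        return sliding_window_predict
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
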