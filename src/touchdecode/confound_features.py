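"""Image-derived visual confound features.

Two features are computed directly from stimulus frames: Shannon entropy
of the 256-level grayscale intensity histogram (bits; complexity of the
first frame) and mean luminance (average brightness over all pixels and
color components of the first frame).  The third confound — the leading
principal component of deep convolutional-network activations on the
middle frame — is consumed as an externally provided per-stimulus vector;
the network itself is deliberately not part of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "frame_entropy",
    "frame_mean_luminance",
    "to_grayscale",
    "load_frame",
    "assemble_confounds",
]


def load_frame(path) -> np.ndarray:
    """Read a PNG/JPEG frame into an array (uint8, HxW or HxWxC)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Average color channels into one grayscale plane."""
    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def frame_entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale intensity histogram.

    Float images in [0, 1] are scaled to 8-bit levels first.  Permutation-
    invariant over pixels and bounded by 8 bits.
    """
    img = to_grayscale(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() <= 1.0 and np.issubdtype(np.asarray(image).dtype, np.floating):
        img = img * 255.0
    levels = np.clip(np.round(img), 0, 255).astype(int)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def frame_mean_luminance(image: np.ndarray) -> float:
    """Mean per-pixel brightness (grand mean over pixels and color channels)."""
    img = np.asarray(image, float)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.mean())


def assemble_confounds(
    design: pd.DataFrame,
    entropy,
    luminance,
    deep_pc1=None,
) -> pd.DataFrame:
    """Assemble the per-stimulus confound matrix in design order.

    ``entropy`` and ``luminance`` must have one value per stimulus; the
    deep-network component is optional and, when absent, the returned frame
    has no ``deep_pc1`` column and carries ``attrs["deep_pc1"] = "absent"``.
    """
    n = len(design)
    entropy = np.asarray(entropy, float)
    luminance = np.asarray(luminance, float)
    if len(entropy) != n or len(luminance) != n:
        raise ValueError(
            f"confound values misaligned: design has {n} stimuli, got "
            f"{len(entropy)} entropy / {len(luminance)} luminance values"
        )
    out = pd.DataFrame(
        {
            "stimulus_id": design["stimulus_id"].to_numpy(),
            "entropy": entropy,
            "mean_luminance": luminance,
        }
    )
    if deep_pc1 is not None:
        deep_pc1 = np.asarray(deep_pc1, float)
        if len(deep_pc1) != n:
            raise ValueError("deep_pc1 misaligned with the design")
        out["deep_pc1"] = deep_pc1
        out.attrs["deep_pc1"] = "provided"
    else:
        out.attrs["deep_pc1"] = "absent"
    return out
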