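"""Image export and convolutional feature extraction.

Raw DICOM pixel data (12-16 bit) is converted to clean 8-bit 128x128 images
in five steps: modality rescale (slope/intercept), linear VOI windowing to
8 bits, a value policy rejecting single-valued images, a shape policy
rejecting non-2-D arrays, and an aspect-preserving bilinear resize with
centred zero padding. Feature extraction is a mirrored convolutional
autoencoder whose flattened final encoder feature map is the embedding,
optionally reduced with PCA.

The windowing follows the standard linear VOI LUT closed form

    y = clip(((x - (c - 0.5)) / (w - 1) + 0.5) * 255, 0, 255)

rounded half-up. MONOCHROME1 data is inverted before windowing so that
polarity does not split otherwise-identical images across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.decomposition import PCA

from ._nn import ConvAutoencoder

logger = logging.getLogger(__name__)

__all__ = [
    "ExportedImage",
    "CAEConfig",
    "rescale_pixels",
    "window_to_8bit",
    "value_policy",
    "shape_policy",
    "resize_pad",
    "export_record",
    "is_eligible",
    "fit_cae",
    "reduce_pca",
    "read_dicom_record",
]

WINDOW_TAGS = ("RescaleSlope", "RescaleIntercept", "WindowCenter", "WindowWidth")


@dataclass
class ExportedImage:
    """A clean 8-bit side x side image with provenance and padding box."""

    pixels: np.ndarray
    provenance: str
    pad_box: tuple[int, int, int, int]  # rows top, rows bottom, cols left, cols right

    def __post_init__(self):
        if self.pixels.dtype != np.uint8:
            raise ValueError("exported pixels must be 8-bit")


@dataclass(frozen=True)
class CAEConfig:
    """Convolutional autoencoder hyperparameters. Defaults follow the
    winning configuration: encoder filters 64/128/256/512 with a final
    1,024-filter layer, Adam at learning rate 1e-6."""

    encoder_filters: tuple[int, ...] = (64, 128, 256, 512)
    final_filters: int = 1024
    learning_rate: float = 1e-6
    max_epochs: int = 40
    patience: int = 5
    batch_size: int = 32
    seed: int = 0


# ---------------------------------------------------------------------------
# export steps
# ---------------------------------------------------------------------------


def is_eligible(tags: dict) -> bool:
    """True when all four rescale/window tags are present (records missing
    any of them are excluded at dataset assembly)."""
    return all(tags.get(name) is not None for name in WINDOW_TAGS)


def _first_value(v):
    if isinstance(v, (list, tuple, np.ndarray)):
        if len(v) == 0:
            return None
        return float(v[0])
    return float(v)


def rescale_pixels(raw: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Modality LUT: ``raw * slope + intercept`` elementwise."""
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("rescale slope/intercept must be finite")
    return np.asarray(raw, dtype=np.float64) * slope + intercept


def window_to_8bit(rescaled: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear VOI windowing into 8-bit, rounded half-up."""
    if width <= 1:
        raise ValueError("window width must be > 1")
    x = np.asarray(rescaled, dtype=np.float64)
    y = ((x - (center - 0.5)) / (width - 1.0) + 0.5) * 255.0
    y = np.clip(y, 0.0, 255.0)
    return np.floor(y + 0.5).astype(np.uint8)  # round half-up


def value_policy(img: np.ndarray) -> bool:
    """Pass iff the image is not single-valued (rejects all-black/all-white)."""
    img = np.asarray(img)
    return img.size > 0 and bool(img.max() != img.min())


def shape_policy(raw: np.ndarray) -> bool:
    """Pass iff the array is 2-D with nonzero dimensions."""
    raw = np.asarray(raw)
    return raw.ndim == 2 and all(d > 0 for d in raw.shape)


def resize_pad(img: np.ndarray, side: int = 128) -> ExportedImage:
    """Aspect-preserving bilinear resize of an 8-bit image to side x side.

    The longest side is scaled to ``side``; the other side is scaled by the
    same factor and centred with zero padding (odd remainders put the extra
    row/column at the bottom/right).
    """
    img = np.asarray(img, dtype=np.uint8)
    h, w = img.shape
    scale = side / max(h, w)
    new_h = side if h >= w else max(1, round(h * scale))
    new_w = side if w >= h else max(1, round(w * scale))
    resized = np.asarray(
        Image.fromarray(img).resize((new_w, new_h), Image.BILINEAR))
    pad_top = (side - new_h) // 2
    pad_bottom = side - new_h - pad_top
    pad_left = (side - new_w) // 2
    pad_right = side - new_w - pad_left
    out = np.pad(resized, ((pad_top, pad_bottom), (pad_left, pad_right)))
    return ExportedImage(out, provenance="",
                         pad_box=(pad_top, pad_bottom, pad_left, pad_right))


def export_record(raw: np.ndarray, tags: dict, record_id: str = "",
                  side: int = 128):
    """Run the full export chain on one record.

    Returns ``(ExportedImage, None)`` on success or ``(None, reason)`` when
    the record is rejected (missing tags, bad width, shape or value policy).
    """
    if not is_eligible(tags):
        return None, "missing rescale/window tags"
    raw = np.asarray(raw)
    if not shape_policy(raw):
        return None, "shape policy"
    slope = _first_value(tags["RescaleSlope"])
    intercept = _first_value(tags["RescaleIntercept"])
    center = _first_value(tags["WindowCenter"])
    width = _first_value(tags["WindowWidth"])
    if width is None or width <= 1:
        return None, "window width <= 1"
    rescaled = rescale_pixels(raw, slope, intercept)
    if str(tags.get("PhotometricInterpretation", "")).upper() == "MONOCHROME1":
        # invert polarity before windowing
        rescaled = rescaled.min() + rescaled.max() - rescaled
    img8 = window_to_8bit(rescaled, center, width)
    if not value_policy(img8):
        return None, "value policy"
    exported = resize_pad(img8, side=side)
    exported.provenance = record_id
    return exported, None


def read_dicom_record(path):
    """Read one DICOM file back into ``(pixel array, tags dict)``."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    tags = {}
    for name in ("Modality", "BodyPartExamined", "StudyDescription",
                 "SOPInstanceUID", "PatientID", "BitsStored",
                 "PhotometricInterpretation", "KVP", "ExposureTime",
                 "ProtocolName", "PatientPosition", "ContrastBolusAgent"):
        tags[name] = getattr(ds, name, None)
    for name in WINDOW_TAGS + ("PixelSpacing",):
        value = getattr(ds, name, None)
        if value is not None and isinstance(value, (list, pydicom.multival.MultiValue)):
            value = [float(v) for v in value]
        elif value is not None:
            value = float(value)
        tags[name] = value
    return arr, tags


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _to_nchw(images):
    X = np.asarray(images, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None, :, :]
    if X.max() > 1.5:  # 8-bit input: scale to [0, 1]
        X = X / 255.0
    return X


def fit_cae(images, validation, cfg: CAEConfig = CAEConfig()) -> ConvAutoencoder:
    """Train the convolutional autoencoder on exported images.

    ``images``/``validation`` are arrays of 8-bit (or [0, 1] float) images.
    Validation loss is checked twice per epoch; training stops after
    ``cfg.patience`` checks without improvement or ``cfg.max_epochs`` epochs.
    """
    X = _to_nchw(images)
    X_val = _to_nchw(validation)
    cae = ConvAutoencoder(filters=cfg.encoder_filters,
                          final_filters=cfg.final_filters, seed=cfg.seed)
    cae.fit(X, X_val, lr=cfg.learning_rate, batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed)
    return cae


def embed_images(cae: ConvAutoencoder, images, batch_size: int = 32):
    """Flattened final-feature-map embeddings for a batch of images."""
    return cae.transform(_to_nchw(images), batch_size=batch_size)


def reduce_pca(embeddings, n_components: int = 500, solver: str = "randomised",
               seed: int = 0) -> PCA:
    """Fit a PCA reduction of image embeddings (default 500 components,
    randomised solver)."""
    from .tags import _PCA_SOLVERS

    embeddings = np.asarray(embeddings, dtype=np.float64)
    if n_components > min(embeddings.shape):
        raise ValueError("n_components exceeds sample count or dimension")
    pca = PCA(n_components=n_components, svd_solver=_PCA_SOLVERS[solver],
              random_state=seed)
    pca.fit(embeddings)
    return pca
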