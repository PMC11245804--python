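"""Synthetic multimodal radiology fixtures.

Real clinical archives pair three data sources per record: a high-bit-depth
pixel array, a DICOM tag header, and a free-text diagnosis shared by all
files of one examination. This module generates datasets with that structure
and with the statistical properties the annotation pipeline assumes:

* exams hold 1..15 records; modalities (CR, CT, MR, XA, RF) can be balanced;
* pixel arrays are 12-16 bit procedural patterns parameterised by the
  (modality, body part) group — a base intensity + oriented gradient per
  modality and a geometric primitive per body part, plus Gaussian noise —
  so that records of one group are visually closer to each other than to
  records of other groups;
* the tag table carries real-world pathologies: array-valued tags, unique
  identifiers, constant tags, a free-text tag, structured missingness at a
  configurable rate, and a BodyPartExamined tag blanked at a configurable
  rate with a recoverable hint left in StudyDescription;
* diagnoses are drawn from a body-part-specific stem vocabulary plus shared
  stems with Zipf weights and optional typo corruption.

Ground truth (modality, body part) is retained on every record so that
clustering quality is measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FixtureConfig",
    "Record",
    "generate_dataset",
    "write_dicom_fixtures",
    "BODYPART_HINTS",
    "DEFAULT_BPE_RULES",
]

DEFAULT_MODALITIES = ("CR", "CT", "MR", "XA", "RF")
DEFAULT_BODY_PARTS = ("HEAD", "CHEST", "ABDOMEN", "HAND", "FOOT")

# Study-description hint written when BodyPartExamined is blanked; the keyword
# is recoverable through DEFAULT_BPE_RULES.
BODYPART_HINTS = {
    "HEAD": "skull lat neuro",
    "CHEST": "thorax pa insp",
    "ABDOMEN": "abdomen native scan",
    "HAND": "wrist dp oblique",
    "FOOT": "ankle ap lat",
}

# Ordered (regex pattern, source tag, body-part value); first match wins.
DEFAULT_BPE_RULES = [
    (r"(?i)skull|cranium|head|neuro", "StudyDescription", "HEAD"),
    (r"(?i)thorax|chest|lung", "StudyDescription", "CHEST"),
    (r"(?i)abdomen|liver|pelvis", "StudyDescription", "ABDOMEN"),
    (r"(?i)wrist|hand|finger", "StudyDescription", "HAND"),
    (r"(?i)ankle|foot|toe|calcaneus", "StudyDescription", "FOOT"),
]

_SHARED_STEMS = [
    "nalaz", "bez", "uredan", "vidljiv", "promjena", "lijevo", "desno",
    "status", "post", "kontrola", "preporuka", "klinick", "obostran",
    "znak", "manji", "veci", "rubno", "jasno", "stanje", "usporedba",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Generation parameters for one synthetic dataset."""

    n_exams: int = 100
    files_per_exam_range: tuple[int, int] = (1, 15)
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    body_parts: tuple[str, ...] = DEFAULT_BODY_PARTS
    bit_depth: int = 12
    tag_missing_rate: float = 0.1
    bpe_blank_rate: float = 0.4
    vocab_size_per_bodypart: int = 30
    n_shared_stems: int = 20
    typo_rate: float = 0.02
    words_per_diagnosis: tuple[int, int] = (8, 20)
    balanced_modalities: bool = True
    #: restrict each modality to one body part (and vice versa), planting
    #: exactly ``len(modalities)`` well-separated groups
    paired_groups: bool = False
    noise_scale: float = 0.04
    seed: int = 0

    def validate(self):
        lo, hi = self.files_per_exam_range
        if not (1 <= lo <= hi):
            raise ValueError("files_per_exam_range must satisfy 1 <= lo <= hi")
        if not 12 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in [12, 16]")
        for name in ("tag_missing_rate", "typo_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.bpe_blank_rate <= 1.0:
            raise ValueError("bpe_blank_rate must be in [0, 1]")
        if self.n_exams < 1:
            raise ValueError("n_exams must be positive")
        if self.paired_groups and len(self.modalities) != len(self.body_parts):
            raise ValueError("paired_groups needs equally many modalities and body parts")


@dataclass
class Record:
    """One data point: pixel array + tag mapping + exam-level diagnosis."""

    record_id: str
    exam_id: str
    raw_pixels: np.ndarray
    tags: dict
    diagnosis: str
    truth_modality: str
    truth_bodypart: str


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

_SHAPES = ("disk", "square", "cross", "ring", "stripes")
# modality-characteristic detector formats (two options each, keeping the
# aspect-preserving resize + padding path exercised)
_SIZES_BY_MODALITY = (
    ((192, 96), (176, 88)),    # e.g. long-bone computed radiography plates
    ((160, 160), (144, 144)),  # square CT-style matrices
    ((128, 128), (120, 120)),  # square MR-style matrices
    ((144, 112), (128, 96)),   # angiography detectors
    ((96, 192), (88, 176)),    # fluoroscopy strips
)


def _pattern(rng, modality_idx, bodypart_idx, n_groups, shape, noise_scale):
    """Procedural [0, 1] image for one (modality, body part) group."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn, xn = yy / (h - 1), xx / (w - 1)
    # golden-ratio spacing keeps the base intensities of distinct groups far
    # apart for any combination of modality and body-part indices
    group = modality_idx * n_groups + bodypart_idx
    base = 0.12 + 0.72 * ((group * 0.618034) % 1.0)
    angle = modality_idx * np.pi / 5.0
    grad = 0.25 * (np.cos(angle) * xn + np.sin(angle) * yn)
    img = base + grad
    prim = _SHAPES[bodypart_idx % len(_SHAPES)]
    cy = 0.35 + 0.3 * ((bodypart_idx * 0.61) % 1.0) + rng.uniform(-0.05, 0.05)
    cx = 0.35 + 0.3 * ((bodypart_idx * 0.29) % 1.0) + rng.uniform(-0.05, 0.05)
    r = 0.18 + 0.04 * rng.uniform(-1, 1)
    d2 = (yn - cy) ** 2 + (xn - cx) ** 2
    if prim == "disk":
        mask = d2 < r * r
    elif prim == "square":
        mask = (np.abs(yn - cy) < r) & (np.abs(xn - cx) < r)
    elif prim == "cross":
        mask = (np.abs(yn - cy) < r / 3) | (np.abs(xn - cx) < r / 3)
    elif prim == "ring":
        mask = (d2 < r * r) & (d2 > (0.55 * r) ** 2)
    else:  # stripes
        mask = (np.floor((yn + xn) / (r / 1.5)) % 2) == 0
    img = img + 0.35 * np.where(mask, 1.0, -0.3)
    img = img + rng.normal(0.0, noise_scale, size=shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# text synthesis
# ---------------------------------------------------------------------------


def _bodypart_vocab(body_part, size, rng):
    """Deterministic pseudo-Croatian stem list for one body part."""
    consonants = "bcdgjklmnprstvz"
    vowels = "aeiou"
    local = np.random.default_rng(abs(hash(body_part)) % (2**31))
    stems = set()
    while len(stems) < size:
        n_syll = int(local.integers(2, 4))
        word = "".join(
            consonants[local.integers(len(consonants))] + vowels[local.integers(len(vowels))]
            for _ in range(n_syll)
        )
        stems.add(word)
    return sorted(stems)


def _make_diagnosis(rng, vocab, shared, n_words, typo_rate):
    pool = list(vocab) + list(shared)
    ranks = np.arange(1, len(pool) + 1, dtype=float)
    weights = 1.0 / ranks  # Zipf
    weights /= weights.sum()
    words = list(rng.choice(pool, size=n_words, p=weights))
    # join with punctuation sprinkled in
    text = ""
    for i, word in enumerate(words):
        if rng.random() < typo_rate and len(word) > 3:
            pos = int(rng.integers(1, len(word) - 1))
            word = word[:pos] + "x" + word[pos + 1:]
        text += word
        if i < n_words - 1:
            text += "," if (i % 6 == 5) else ""
            text += " "
    return text + "."


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_dataset(config: FixtureConfig) -> list[Record]:
    """Generate a deterministic synthetic dataset of :class:`Record`.

    Records of one exam share exam id, modality, body part and diagnosis.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mods = list(config.modalities)
    parts = list(config.body_parts)
    vocabs = {bp: _bodypart_vocab(bp, config.vocab_size_per_bodypart, rng)
              for bp in parts}
    shared = _SHARED_STEMS[: config.n_shared_stems]

    # balanced exam-level modality assignment (within +/-1)
    if config.balanced_modalities:
        exam_mods = [mods[i % len(mods)] for i in range(config.n_exams)]
        rng.shuffle(exam_mods)
    else:
        exam_mods = [mods[int(rng.integers(len(mods)))] for _ in range(config.n_exams)]

    max_val = 2 ** config.bit_depth - 1
    records: list[Record] = []
    lo, hi = config.files_per_exam_range
    for e in range(config.n_exams):
        exam_id = f"EX{e:06d}"
        modality = exam_mods[e]
        m_idx = mods.index(modality)
        if config.paired_groups:
            bp = parts[m_idx]
        else:
            bp = parts[int(rng.integers(len(parts)))]
        b_idx = parts.index(bp)
        n_words = int(rng.integers(config.words_per_diagnosis[0],
                                   config.words_per_diagnosis[1] + 1))
        diagnosis = _make_diagnosis(rng, vocabs[bp], shared, n_words,
                                    config.typo_rate)
        n_files = int(rng.integers(lo, hi + 1))
        for f in range(n_files):
            options = _SIZES_BY_MODALITY[m_idx % len(_SIZES_BY_MODALITY)]
            shape = options[int(rng.integers(len(options)))]
            img01 = _pattern(rng, m_idx, b_idx, len(mods), shape,
                             config.noise_scale)
            raw = np.round(img01 * max_val).astype(np.uint16)
            record_id = f"{exam_id}.{f:03d}"
            blank_bpe = rng.random() < config.bpe_blank_rate
            tags = _make_tags(rng, record_id, modality, bp, blank_bpe,
                              m_idx, b_idx, max_val, config)
            records.append(Record(
                record_id=record_id,
                exam_id=exam_id,
                raw_pixels=raw,
                tags=tags,
                diagnosis=diagnosis,
                truth_modality=modality,
                truth_bodypart=bp,
            ))
    return records


#: tags subject to tag_missing_rate masking
MASKABLE_TAGS = ("ExposureTime", "KVP", "ProtocolName", "PatientPosition")


def _make_tags(rng, record_id, modality, bp, blank_bpe, m_idx, b_idx,
               max_val, config):
    def maybe(value):
        return None if rng.random() < config.tag_missing_rate else value

    tags = {
        "Modality": modality,
        "BodyPartExamined": "" if blank_bpe else bp,
        "StudyDescription": BODYPART_HINTS.get(bp, bp.lower()),
        "SOPInstanceUID": (f"1.2.840.99999.{abs(hash(record_id)) % 10**8 + 1}."
                           f"{int(record_id[2:].replace('.', '')) + 1}"),
        "SpecificCharacterSet": "ISO_IR 100",
        "RescaleSlope": 1.0,
        "RescaleIntercept": float(-(m_idx == 1) * 1024),  # CT-style offset
        "WindowCenter": [max_val / 2 - (m_idx == 1) * 1024,
                         max_val / 4 - (m_idx == 1) * 1024],
        "WindowWidth": [float(max_val), float(max_val) / 2],
        "PixelSpacing": [round(0.1 + 0.05 * m_idx + rng.uniform(0, 0.02), 4),
                         round(0.1 + 0.05 * m_idx + rng.uniform(0, 0.02), 4)],
        "ExposureTime": maybe(int(round(100.0 * (m_idx + 1) + rng.normal(0, 10.0)))),
        "KVP": maybe(round(60.0 + 15.0 * m_idx + rng.normal(0, 2.0), 1)),
        "ProtocolName": maybe(f"PROT_{bp}_{int(rng.integers(2))}"),
        "PatientPosition": maybe(("HFS", "FFS", "HFP")[int(rng.integers(3))]),
        # rarely filled: exercises the 35% fill-rate filter
        "ContrastBolusAgent": "IOMERON" if rng.random() < 0.15 else None,
    }
    return tags


# ---------------------------------------------------------------------------
# DICOM round-trip
# ---------------------------------------------------------------------------


def write_dicom_fixtures(dataset: list[Record], directory) -> list[Path]:
    """Write one standards-conformant DICOM file per record plus a JSON
    sidecar with ground-truth labels and diagnoses. Returns written paths."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if not dataset:
        raise ValueError("dataset is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    paths = []
    truth = {}
    for rec in dataset:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = rec.tags.get("SOPInstanceUID") or meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = generate_uid(entropy_srcs=[rec.exam_id])
        ds.PatientID = rec.exam_id
        ds.Modality = rec.tags.get("Modality", "")
        ds.BodyPartExamined = rec.tags.get("BodyPartExamined", "")
        ds.StudyDescription = rec.tags.get("StudyDescription", "")
        for name in ("RescaleSlope", "RescaleIntercept", "WindowCenter",
                     "WindowWidth", "PixelSpacing", "KVP", "ExposureTime",
                     "ProtocolName", "PatientPosition", "ContrastBolusAgent"):
            value = rec.tags.get(name)
            if value is not None:
                setattr(ds, name, value)
        arr = np.ascontiguousarray(rec.raw_pixels.astype(np.uint16))
        bits_stored = max(12, min(16, int(arr.max()).bit_length()))
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = bits_stored
        ds.HighBit = bits_stored - 1
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()
        path = directory / f"{rec.record_id}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
        truth[rec.record_id] = {
            "exam_id": rec.exam_id,
            "modality": rec.truth_modality,
            "body_part": rec.truth_bodypart,
            "diagnosis": rec.diagnosis,
        }
    with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, ensure_ascii=False, indent=1)
    return paths
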