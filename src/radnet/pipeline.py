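"""End-to-end unsupervised labelling.

The orchestrator ties the per-source stages together: exam-level dataset
splitting, tag preprocessing + embedding, image export + embedding, text
preprocessing + embedding, late fusion, final clustering, evaluation and
cluster post-filtering. All randomness funnels through one master seed,
expanded deterministically per stage, so a run manifest suffices to
reproduce a run bit-identically. Previously unseen records are assignable
through the persisted per-source transforms and nearest-centre assignment in
the fused space.

Defaults follow the winning per-source configuration (tag autoencoder
512 -> 200 -> 125 -> 32 at lr 1e-2; convolutional image autoencoder at
lr 1e-6 with a 500-component PCA; PV-DBOW with 1,000-dim vectors, window 7,
50 epochs, minimum word frequency 50; plain embedding concatenation;
k-means, Euclidean, kappa = 50). ``PipelineConfig.small()`` gives a reduced
desk-scale configuration for experimentation and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import clustering, evaluation, fusion, images, tags, text
from .fixtures import DEFAULT_BPE_RULES

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SourceClusterConfig",
    "split_dataset",
    "LabellingPipeline",
    "label_dataset",
]


@dataclass(frozen=True)
class SourceClusterConfig:
    """Per-source clustering used by the cluster-space fusion methods
    (defaults: the winning per-source algorithm/metric/kappa)."""

    algorithm: str
    metric: str
    kappa: int


@dataclass(frozen=True)
class PipelineConfig:
    split_ratios: tuple[float, float, float] = (0.80, 0.10, 0.10)
    tag_ae: tags.TagAEConfig = field(default_factory=tags.TagAEConfig)
    cae: images.CAEConfig = field(default_factory=images.CAEConfig)
    image_pca_components: int = 500
    doc2vec: text.Doc2VecConfig = field(default_factory=text.Doc2VecConfig)
    fusion_method: str = "embeddings"  # embeddings | clusterdists | clusterprobs
    final_algorithm: str = "k-means"
    final_metric: str = "euclidean"
    final_kappa: int = 50
    #: per-source clustering for clusterdists/clusterprobs fusion
    source_clusters: dict = field(default_factory=lambda: {
        "diagnosis": SourceClusterConfig("k-means", "euclidean", 20),
        "tags": SourceClusterConfig("k-medoids", "cosine", 25),
        "image": SourceClusterConfig("k-means", "euclidean", 40),
    })
    bpe_rules: tuple = tuple(DEFAULT_BPE_RULES)
    fill_threshold: float = 0.35
    impute_trees: int = 100
    impute_max_iter: int = 10
    min_cluster_size: int = 100
    entropy_cutoff: float = 0.9
    stemmer: str = "suffix"  # identity | suffix
    seed: int = 0

    def validate(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.final_kappa < 2:
            raise ValueError("final kappa must be >= 2")
        if self.fusion_method not in ("embeddings", "clusterdists", "clusterprobs"):
            raise ValueError(f"unknown fusion method {self.fusion_method!r}")

    @classmethod
    def small(cls, seed: int = 0, final_kappa: int = 5,
              fusion_method: str = "embeddings"):
        """Reduced desk-scale configuration: smaller networks and embedding
        widths, fewer epochs/trees; preprocessing identical to the default."""
        return cls(
            tag_ae=tags.TagAEConfig(layer_sizes=(64, 48, 32), bottleneck=16,
                                    max_epochs=40, seed=seed),
            cae=images.CAEConfig(encoder_filters=(8, 8, 16, 16),
                                 final_filters=32, learning_rate=1e-3,
                                 max_epochs=2, patience=4, seed=seed),
            image_pca_components=64,
            doc2vec=text.Doc2VecConfig(embedding_size=128, window=7,
                                       epochs=30, min_word_frequency=5,
                                       seed=seed),
            fusion_method=fusion_method,
            final_kappa=final_kappa,
            source_clusters={
                "diagnosis": SourceClusterConfig("k-means", "euclidean", 8),
                "tags": SourceClusterConfig("k-medoids", "cosine", 8),
                "image": SourceClusterConfig("k-means", "euclidean", 8),
            },
            impute_trees=25,
            impute_max_iter=3,
            seed=seed,
        )


def _stage_seeds(master_seed: int, n: int = 10):
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def split_dataset(records, ratios=(0.80, 0.10, 0.10), seed: int = 0):
    """Random exam-level split into train/validation/test.

    All records of one exam land in one subset; exam counts match the
    requested ratios exactly up to integer rounding (largest remainder), so
    record-level fractions deviate when exams have variable file counts.
    Returns a per-record array of ``"train" | "val" | "test"``.
    """
    exam_ids = sorted({r.exam_id for r in records})
    if len(exam_ids) < 3:
        raise ValueError("need at least as many exams as subsets")
    rng = np.random.default_rng(seed)
    rng.shuffle(exam_ids)
    n = len(exam_ids)
    raw = [r * n for r in ratios]
    counts = [int(np.floor(v)) for v in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - v for c, v in zip(counts, raw)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    subset_of_exam = {}
    start = 0
    for name, count in zip(("train", "val", "test"), counts):
        for exam in exam_ids[start:start + count]:
            subset_of_exam[exam] = name
        start += count
    return np.array([subset_of_exam[r.exam_id] for r in records])


class LabellingPipeline:
    """Fits every stage on the training subset and labels all records.

    After :meth:`fit`, per-record labels are in ``labels_``, reports in
    ``metrics_`` / ``dissimilarity_``, the filtered labels in
    ``filtered_labels_``, and the run manifest in ``manifest_``. New records
    are labelled with :meth:`transform_records` (nearest final centre in the
    fused space).
    """

    def __init__(self, config: PipelineConfig = PipelineConfig()):
        config.validate()
        self.config = config

    # -- per-source embedding -------------------------------------------------
    def _embed_tags(self, records, train_mask, seeds):
        cfg = self.config
        table = tags.TagTable.from_records(records)
        table, n_bpe = tags.reconstruct_bpe(table, list(cfg.bpe_rules))
        table = tags.split_array_tags(table)
        train_index = table.frame.index[train_mask]
        table = tags.filter_tags(table, cfg.fill_threshold,
                                 train_index=train_index)
        table = tags.impute_missing(table, n_trees=cfg.impute_trees,
                                    max_iter=cfg.impute_max_iter, seed=seeds[0])
        self.tag_encoder_ = tags.TagEncoder().fit(table, train_index)
        matrix = self.tag_encoder_.transform(table)
        ae_cfg = replace(cfg.tag_ae, seed=seeds[1])
        self.tag_ae_ = tags.fit_tag_autoencoder(
            matrix[train_mask], ae_cfg,
            validation=matrix[~train_mask] if (~train_mask).any() else None)
        self._tag_prep_stats = {"bpe_reconstructed": n_bpe,
                                "kept_tag_columns": list(table.frame.columns)}
        self._tag_columns = list(table.frame.columns)
        return self.tag_ae_.transform(matrix)

    def _tag_matrix_for(self, records):
        table = tags.TagTable.from_records(records)
        table, _ = tags.reconstruct_bpe(table, list(self.config.bpe_rules))
        table = tags.split_array_tags(table)
        frame = table.frame
        for col in self._tag_columns:  # align to the fitted column set
            if col not in frame.columns:
                frame[col] = np.nan
        table = tags.TagTable(frame[self._tag_columns],
                              {c: self.tag_encoder_.kinds_[c]
                               for c in self._tag_columns})
        table = tags.impute_missing(table, n_trees=self.config.impute_trees,
                                    max_iter=self.config.impute_max_iter,
                                    seed=self._seeds[0])
        return self.tag_encoder_.transform(table)

    def _export_images(self, records):
        exported, rejected = [], {}
        for rec in records:
            img, reason = images.export_record(rec.raw_pixels, rec.tags,
                                               rec.record_id)
            if img is None:
                rejected[rec.record_id] = reason
            exported.append(img)
        return exported, rejected

    def _embed_images(self, exported, train_mask, val_mask, seeds):
        cfg = self.config
        stack = np.stack([e.pixels for e in exported]).astype(np.float32) / 255.0
        val = stack[val_mask] if val_mask.any() else stack[train_mask][:32]
        cae_cfg = replace(cfg.cae, seed=seeds[2])
        self.cae_ = images.fit_cae(stack[train_mask], val, cae_cfg)
        raw_emb = images.embed_images(self.cae_, stack)
        n_comp = min(cfg.image_pca_components, int(train_mask.sum()),
                     raw_emb.shape[1])
        self.image_pca_ = images.reduce_pca(raw_emb[train_mask], n_comp,
                                            seed=seeds[3])
        return self.image_pca_.transform(raw_emb)

    def _embed_text(self, records, train_mask, seeds):
        cfg = self.config
        stemmer = (text.suffix_stemmer if cfg.stemmer == "suffix"
                   else text.identity_stemmer)
        self._stemmer = stemmer
        docs = [text.preprocess_text(r.diagnosis, stemmer) for r in records]
        d2v_cfg = replace(cfg.doc2vec, seed=seeds[4])
        train_docs = [d for d, m in zip(docs, train_mask) if m]
        self.doc2vec_ = text.fit_doc2vec(train_docs, d2v_cfg)
        return self.doc2vec_.infer(docs)

    # -- fusion + clustering --------------------------------------------------
    def _fuse(self, parts, train_mask, fit: bool):
        cfg = self.config
        if cfg.fusion_method == "embeddings":
            return fusion.fuse_embeddings(parts)
        if fit:
            self.source_models_ = {}
            for name, sc in cfg.source_clusters.items():
                self.source_models_[name] = clustering.fit_cluster(
                    parts[name][train_mask], sc.algorithm, sc.metric,
                    sc.kappa, seed=self._seeds[5])
            self.fuser_ = fusion.ClusterSpaceFuser(
                self.source_models_, cfg.fusion_method)
            self.fuser_.fit({k: v[train_mask] for k, v in parts.items()})
        return self.fuser_.transform(parts)

    # -- API ------------------------------------------------------------------
    def fit(self, records):
        cfg = self.config
        self._seeds = seeds = _stage_seeds(cfg.seed)
        subsets = split_dataset(records, cfg.split_ratios, seed=seeds[6])

        exported, rejected = self._export_images(records)
        keep = np.array([e is not None for e in exported])
        if rejected:
            logger.warning("excluded %d records at image export", len(rejected))
        records = [r for r, k in zip(records, keep) if k]
        exported = [e for e in exported if e is not None]
        subsets = subsets[keep]
        self.subsets_ = subsets
        self.record_ids_ = [r.record_id for r in records]
        self.rejected_ = rejected
        train = subsets == "train"
        val = subsets == "val"

        logger.info("embedding DICOM tags")
        tag_emb = self._embed_tags(records, train, seeds)
        logger.info("embedding images")
        img_emb = self._embed_images(exported, train, val, seeds)
        logger.info("embedding diagnoses")
        txt_emb = self._embed_text(records, train, seeds)
        parts = {"diagnosis": txt_emb, "tags": tag_emb, "image": img_emb}
        self.embeddings_ = parts

        logger.info("fusing (%s) and clustering", cfg.fusion_method)
        fused = self._fuse(parts, train, fit=True)
        self.fused_ = fused
        self.final_model_ = clustering.fit_cluster(
            fused.vectors[train], cfg.final_algorithm, cfg.final_metric,
            min(cfg.final_kappa, int(train.sum()) - 1), seed=seeds[7])
        assignment = clustering.assign(self.final_model_, fused.vectors)
        self.labels_ = assignment.labels

        truth = evaluation.LabelVector(
            y_m=np.array([r.truth_modality for r in records]),
            y_b=np.array([r.truth_bodypart for r in records]))
        self.truth_ = truth
        self.metrics_ = evaluation.metrics_report(truth, self.labels_)
        self.dissimilarity_ = {
            "image": evaluation.cluster_dissimilarity(
                img_emb, self.labels_, seed=seeds[8]),
            "diagnosis": evaluation.cluster_dissimilarity(
                txt_emb, self.labels_, seed=seeds[8]),
        }
        d_i = self.dissimilarity_["image"].mean
        d_d = self.dissimilarity_["diagnosis"].mean
        self.d_score_ = evaluation.d_score(d_i, d_d)
        self.filtered_labels_, self.removal_log_ = evaluation.filter_clusters(
            self.labels_, truth, cfg.min_cluster_size, cfg.entropy_cutoff)
        self.oversample_plan_ = evaluation.oversample_plan(self.filtered_labels_)
        self.manifest_ = {
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "n_records": len(records),
            "n_rejected": len(rejected),
            "subset_counts": {name: int((subsets == name).sum())
                              for name in ("train", "val", "test")},
            "fusion_method": cfg.fusion_method,
            "fused_length": fused.length,
            "component_spans": {k: list(v) for k, v
                                in fused.component_spans.items()},
            "final": {"algorithm": cfg.final_algorithm,
                      "metric": cfg.final_metric,
                      "kappa": int(self.final_model_.kappa)},
            "tag_prep": self._tag_prep_stats,
        }
        return self

    def transform_records(self, records):
        """Label previously unseen records: per-source transforms, fusion
        with the fitted constants, nearest final centre."""
        exported, rejected = self._export_images(records)
        keep = [e is not None for e in exported]
        if not all(keep):
            raise ValueError(f"records rejected at export: {rejected}")
        stack = np.stack([e.pixels for e in exported]).astype(np.float32) / 255.0
        img_emb = self.image_pca_.transform(images.embed_images(self.cae_, stack))
        tag_emb = self.tag_ae_.transform(self._tag_matrix_for(records))
        docs = [text.preprocess_text(r.diagnosis, self._stemmer)
                for r in records]
        txt_emb = self.doc2vec_.infer(docs)
        parts = {"diagnosis": txt_emb, "tags": tag_emb, "image": img_emb}
        fused = self._fuse(parts, None, fit=False)
        return clustering.assign(self.final_model_, fused.vectors).labels


def label_dataset(records, config: PipelineConfig = PipelineConfig()
                  ) -> LabellingPipeline:
    """Run the full labelling pipeline; returns the fitted pipeline with
    labels, reports and manifest attached."""
    return LabellingPipeline(config).fit(records)
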