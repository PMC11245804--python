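"""Narrative-diagnosis preprocessing and embeddings.

Diagnoses are tokenised (lowercased, punctuation stripped, whitespace split),
stemmed by an injectable stemmer, and counted into a corpus built from the
training subset only: a stem enters the vocabulary when its training
occurrence count reaches ``min_word_frequency``. Embeddings come from four
extractors: bag-of-words counts, TF-IDF with smoothed idf
``ln((1 + N) / (1 + df)) + 1`` (raw term frequency, natural log), and the two
paragraph-vector models — PV-DM (doc vector + window context predicts the
centre word) and PV-DBOW (doc vector alone predicts the doc's words) —
trained with negative sampling on a shallow network.

Two reference stemmers ship with the module: the identity, and a minimal
suffix stripper for inflected languages; a full morphological stemmer can be
injected as any ``word -> stem`` function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Corpus",
    "Doc2VecConfig",
    "Doc2Vec",
    "preprocess_text",
    "build_corpus",
    "bow_embed",
    "tfidf_embed",
    "fit_doc2vec",
    "identity_stemmer",
    "suffix_stemmer",
]

_PUNCT = re.compile(r"[,;:.()\[\]/\\\-!?\"'«»*+=<>|{}~`]")

#: common inflection suffixes, longest first (minimal reference stemmer)
_SUFFIXES = ("ijima", "ijega", "ijemu", "ijim", "ijih", "ijoj", "ijeg", "ijem",
             "ima", "ama", "oga", "ome", "omu", "ega", "emu", "ovi", "evi",
             "om", "eg", "em", "im", "ih", "oj", "a", "e", "i", "o", "u")


def identity_stemmer(word: str) -> str:
    return word


def suffix_stemmer(word: str) -> str:
    """Strip the longest matching inflection suffix, keeping stems >= 3 chars."""
    for suffix in _SUFFIXES:
        if word.endswith(suffix) and len(word) - len(suffix) >= 3:
            return word[: -len(suffix)]
    return word


def preprocess_text(diagnosis: str, stemmer=identity_stemmer) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace, stem; empty tokens
    are dropped. Digits are kept."""
    text = _PUNCT.sub(" ", diagnosis.lower())
    tokens = [stemmer(tok) for tok in text.split()]
    return [t for t in tokens if t]


@dataclass
class Corpus:
    """Training-subset vocabulary with occurrence and document counts."""

    vocabulary: list[str]
    min_word_frequency: int
    doc_count: int
    stem_counts: dict = field(default_factory=dict)
    doc_freq: dict = field(default_factory=dict)
    index: dict = field(init=False)

    def __post_init__(self):
        self.index = {stem: i for i, stem in enumerate(self.vocabulary)}

    def __len__(self):
        return len(self.vocabulary)


def build_corpus(training_docs, min_word_frequency: int = 1) -> Corpus:
    """Build the corpus from tokenised (stem-sequence) training documents.

    The vocabulary holds every stem whose total training occurrence count is
    at least ``min_word_frequency``, in lexicographic order.
    """
    if min_word_frequency < 1:
        raise ValueError("min_word_frequency must be >= 1")
    counts: dict[str, int] = {}
    doc_freq: dict[str, int] = {}
    n_docs = 0
    for doc in training_docs:
        n_docs += 1
        for stem in doc:
            counts[stem] = counts.get(stem, 0) + 1
        for stem in set(doc):
            doc_freq[stem] = doc_freq.get(stem, 0) + 1
    vocab = sorted(s for s, c in counts.items() if c >= min_word_frequency)
    if not vocab:
        raise ValueError("empty vocabulary: threshold excludes every stem")
    return Corpus(vocabulary=vocab, min_word_frequency=min_word_frequency,
                  doc_count=n_docs,
                  stem_counts={s: counts[s] for s in vocab},
                  doc_freq={s: doc_freq[s] for s in vocab})


def bow_embed(doc_stems, corpus: Corpus) -> np.ndarray:
    """Integer stem counts over the vocabulary order; out-of-vocabulary stems
    are ignored."""
    vec = np.zeros(len(corpus), dtype=np.int64)
    for stem in doc_stems:
        i = corpus.index.get(stem)
        if i is not None:
            vec[i] += 1
    return vec


def idf(corpus: Corpus) -> np.ndarray:
    """Smoothed inverse document frequency: ln((1 + N) / (1 + df)) + 1."""
    df = np.array([corpus.doc_freq[s] for s in corpus.vocabulary], dtype=float)
    return np.log((1.0 + corpus.doc_count) / (1.0 + df)) + 1.0


def tfidf_embed(doc_stems, corpus: Corpus) -> np.ndarray:
    """Raw term frequency times smoothed idf."""
    return bow_embed(doc_stems, corpus).astype(np.float64) * idf(corpus)


# ---------------------------------------------------------------------------
# doc2vec (paragraph vectors with negative sampling)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Doc2VecConfig:
    """Paragraph-vector hyperparameters (defaults: the winning PV-DBOW
    configuration — 1,000-dim embeddings, window 7, 50 epochs, minimum word
    frequency 50)."""

    mode: str = "pv-dbow"  # "pv-dm" | "pv-dbow"
    embedding_size: int = 1000
    window: int = 7
    epochs: int = 50
    min_word_frequency: int = 50
    negative: int = 5
    alpha: float = 0.05
    min_alpha: float = 1e-4
    seed: int = 0

    def validate(self):
        if self.mode not in ("pv-dm", "pv-dbow"):
            raise ValueError("mode must be 'pv-dm' or 'pv-dbow'")
        if self.embedding_size < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("embedding_size, window and epochs must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class Doc2Vec:
    """Shallow paragraph-vector model (PV-DM / PV-DBOW), numpy SGD with
    negative sampling. Training and inference are deterministic for a fixed
    seed (single worker, fixed document order)."""

    def __init__(self, cfg: Doc2VecConfig = Doc2VecConfig()):
        cfg.validate()
        self.cfg = cfg

    # -- internal ------------------------------------------------------------
    def _noise_table(self):
        counts = np.array([self.corpus_.stem_counts[s]
                           for s in self.corpus_.vocabulary], dtype=float)
        probs = counts ** 0.75
        return probs / probs.sum()

    def _doc_ids(self, doc):
        return np.array([self.corpus_.index[s] for s in doc
                         if s in self.corpus_.index], dtype=np.int64)

    def _train_doc_dbow(self, dvec, ids, rng, lr, update_words=True):
        if len(ids) == 0:
            return
        k = self.cfg.negative
        neg = rng.choice(len(self.corpus_), size=(len(ids), k), p=self._noise)
        idx = np.concatenate([ids[:, None], neg], axis=1)  # (T, 1+k)
        labels = np.zeros((len(ids), 1 + k))
        labels[:, 0] = 1.0
        W = self.W_out[idx]                       # (T, 1+k, d)
        scores = _sigmoid(W @ dvec)               # (T, 1+k)
        g = (labels - scores) * lr
        d_doc = np.einsum("tk,tkd->d", g, W)
        if update_words:
            np.add.at(self.W_out, idx, g[:, :, None] * dvec)
        dvec += d_doc

    def _train_doc_dm(self, dvec, ids, rng, lr, update_words=True):
        if len(ids) == 0:
            return
        k = self.cfg.negative
        win = self.cfg.window
        for pos in range(len(ids)):
            lo = max(0, pos - win)
            ctx = np.concatenate([ids[lo:pos], ids[pos + 1:pos + 1 + win]])
            if len(ctx):
                h = (dvec + self.W_in[ctx].sum(axis=0)) / (1 + len(ctx))
            else:
                h = dvec
            targets = np.concatenate([
                ids[pos:pos + 1],
                rng.choice(len(self.corpus_), size=k, p=self._noise)])
            W = self.W_out[targets]               # (1+k, d)
            scores = _sigmoid(W @ h)
            labels = np.zeros(1 + k)
            labels[0] = 1.0
            g = (labels - scores) * lr            # (1+k,)
            gh = g @ W                            # (d,)
            if update_words:
                np.add.at(self.W_out, targets, g[:, None] * h)
                if len(ctx):
                    np.add.at(self.W_in, ctx, gh / (1 + len(ctx)))
            dvec += gh / (1 + (len(ctx) if len(ctx) else 0))

    def _run_epochs(self, vectors, docs_ids, epochs, seed, update_words):
        rng = np.random.default_rng(seed)
        cfg = self.cfg
        n_steps = max(1, epochs * len(docs_ids))
        step = 0
        train = self._train_doc_dm if cfg.mode == "pv-dm" else self._train_doc_dbow
        for _epoch in range(epochs):
            for d, ids in enumerate(docs_ids):
                lr = cfg.alpha + (cfg.min_alpha - cfg.alpha) * step / n_steps
                train(vectors[d], ids, rng, lr, update_words=update_words)
                step += 1
        return vectors

    # -- API -----------------------------------------------------------------
    def fit(self, training_docs):
        """Train on tokenised training documents (lists of stems)."""
        cfg = self.cfg
        docs = [list(d) for d in training_docs]
        self.corpus_ = build_corpus(docs, cfg.min_word_frequency)
        self._noise = self._noise_table()
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embedding_size
        v = len(self.corpus_)
        self.W_out = np.zeros((v, d))
        self.W_in = (rng.random((v, d)) - 0.5) / d
        self.D_ = (rng.random((len(docs), d)) - 0.5) / d
        docs_ids = [self._doc_ids(doc) for doc in docs]
        self._run_epochs(self.D_, docs_ids, cfg.epochs, cfg.seed + 1,
                         update_words=True)
        return self

    def infer(self, docs, epochs=None, seed=None):
        """Infer paragraph vectors for tokenised documents with frozen word
        weights; deterministic for a fixed seed."""
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        seed = (cfg.seed + 2) if seed is None else seed
        docs_ids = [self._doc_ids(list(doc)) for doc in docs]
        rng = np.random.default_rng(seed)
        vectors = (rng.random((len(docs_ids), cfg.embedding_size)) - 0.5) \
            / cfg.embedding_size
        self._run_epochs(vectors, docs_ids, epochs, seed, update_words=False)
        return vectors

    def transform(self, docs):
        return self.infer(docs)


def fit_doc2vec(training_docs, cfg: Doc2VecConfig = Doc2VecConfig()) -> Doc2Vec:
    """Fit a paragraph-vector extractor on tokenised training documents."""
    return Doc2Vec(cfg).fit(training_docs)
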