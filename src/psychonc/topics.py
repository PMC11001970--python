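"""Topic summarization of attribution-selected sentences.

Desk-scale topic backend: sentences are embedded as TF-IDF term vectors,
clustered agglomeratively under cosine distance with a distance
threshold (so duplicate-heavy collections collapse naturally), merged
down to at most the requested number of topics, and small clusters are
routed to an outlier class.  Each topic is represented by its top terms
under class-based TF-IDF (term frequency within the topic, rescaled by
log(1 + average topic size / corpus term count)) — the standard
class-based weighting for topic keyword lists.

The backend is pluggable: anything callable as
``backend(sentences, n_topics, top_k) -> TopicSummary`` can replace it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

__all__ = ["Topic", "TopicSummary", "topic_summarize"]


@dataclass(frozen=True)
class Topic:
    topic_id: int
    count: int
    terms: tuple[str, ...]


@dataclass
class TopicSummary:
    """Clustered topic table over a sentence collection."""

    topics: list[Topic]
    outlier_count: int
    n_sentences: int
    requested: int

    @property
    def coverage(self) -> float:
        if self.n_sentences == 0:
            return 0.0
        return sum(t.count for t in self.topics) / self.n_sentences

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"topic": t.topic_id, "count": t.count,
             "terms": ", ".join(t.terms)} for t in self.topics])


def _ctfidf_terms(counts, labels, cluster_ids, vocab, top_k):
    """Top terms per cluster by class-based TF-IDF.

    weight(term, class) = tf_{t,c} / words_c * log(1 + A / tf_t), with
    tf_{t,c} the term count inside the class, words_c the class word
    total, tf_t the corpus-wide term count and A the average class word
    count.
    """
    total_tf = np.asarray(counts.sum(axis=0)).ravel()
    A = total_tf.sum() / max(1, len(cluster_ids))
    out = {}
    for cid in cluster_ids:
        rows = np.flatnonzero(labels == cid)
        tf = np.asarray(counts[rows].sum(axis=0)).ravel()
        weight = (tf / max(1.0, tf.sum())) * np.log1p(
            A / np.maximum(total_tf, 1.0))
        order = np.argsort(-weight)
        terms = tuple(vocab[j] for j in order[:top_k] if tf[j] > 0)
        out[cid] = terms if terms else tuple(vocab[j] for j in order[:1])
    return out


def topic_summarize(sentences, n_topics: int = 20, top_k: int = 10,
                    min_topic_size: int = 5,
                    distance_threshold: float = 0.7) -> TopicSummary:
    """Cluster a sentence collection into at most ``n_topics`` topics.

    Accepts a :class:`~psychonc.interpret.SalientSentenceSet` or a plain
    list of strings.  Clusters smaller than ``min_topic_size`` are
    counted as outliers.  If fewer sentences than topics are supplied,
    fewer topics are returned with a warning.
    """
    texts = sentences.texts() if hasattr(sentences, "texts") else list(sentences)
    n = len(texts)
    if n == 0:
        return TopicSummary(topics=[], outlier_count=0, n_sentences=0,
                            requested=n_topics)
    if n < n_topics:
        warnings.warn(
            f"only {n} sentences for {n_topics} requested topics; "
            "returning fewer topics", stacklevel=2)
    vectorizer = CountVectorizer(token_pattern=r"(?u)\b\w+\b")
    counts = vectorizer.fit_transform(texts)
    vocab = vectorizer.get_feature_names_out()
    tfidf = TfidfTransformer().fit_transform(counts)
    dense = np.asarray(tfidf.todense())

    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        # natural clusters under a cosine-distance threshold
        clus = AgglomerativeClustering(
            n_clusters=None, distance_threshold=distance_threshold,
            metric="cosine", linkage="average")
        labels = clus.fit_predict(dense)

    # merge down to at most n_topics by clustering the cluster centroids
    uniq = np.unique(labels)
    if uniq.size > n_topics:
        centroids = np.vstack([
            dense[labels == c].mean(axis=0) for c in uniq])
        merger = AgglomerativeClustering(
            n_clusters=n_topics, metric="cosine", linkage="average")
        merged = merger.fit_predict(centroids)
        mapping = {c: m for c, m in zip(uniq, merged)}
        labels = np.array([mapping[c] for c in labels])
        uniq = np.unique(labels)

    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    keep = [c for c in uniq if sizes[c] >= min_topic_size]
    if not keep:  # degenerate tiny collections: keep the largest cluster
        keep = [max(uniq, key=lambda c: sizes[c])]
    outliers = int(n - sum(sizes[c] for c in keep))
    keep.sort(key=lambda c: -sizes[c])
    term_map = _ctfidf_terms(counts, labels, keep, vocab, top_k)
    topics = [Topic(topic_id=i, count=sizes[c], terms=term_map[c])
              for i, c in enumerate(keep)]
    return TopicSummary(topics=topics, outlier_count=outliers,
                        n_sentences=n, requested=n_topics)
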