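"""Typicality and coherence metrics for free narratives.

Two families of measures on preprocessed (lowercased, stopword-stripped,
lemmatized) narrative documents:

* **Narrative typicality** — mean TF-IDF cosine similarity between a
  participant's document and every other document written to the same
  prompt.  IDF downweights words common to all narratives.
* **Windowed coherence** — semantic similarity between consecutive
  non-overlapping groups of N content words, averaged over all N starting
  offsets, using either the cosine of aggregated (mean) word vectors or the
  negated relaxed word mover's distance.  Higher is more coherent.

Composite per-participant scores standardize each measure within prompt and
sum across prompts; a first-half/second-half typicality split probes drift
away from the common topic over the course of a narrative.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.feature_extraction.text import TfidfVectorizer

from .norms import SuffixLemmatizer

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z']+|\d+")


def preprocess_narrative(
    raw_text: str,
    stopwords: set[str] | list[str],
    lexicon: set[str] | list[str],
    extra_common: set[str] | list[str] = (),
    lemmatizer=None,
) -> list[str]:
    """Tokenize and clean one narrative; returns ordered content lemmas.

    Removes nonwords/misspellings (absent from the lexicon), digits,
    stopwords, single letters and configured common words, then lemmatizes
    the survivors preserving order.  An empty result means the document is
    unscoreable.
    """
    lexicon = set(w.lower() for w in lexicon)
    stopwords = set(w.lower() for w in stopwords)
    extra_common = set(w.lower() for w in extra_common)
    if lemmatizer is None:
        lemmatizer = SuffixLemmatizer(lexicon=lexicon)
    lemmas = []
    for tok in _WORD_RE.findall(raw_text.lower()):
        if tok.isdigit() or len(tok) == 1:
            continue
        if tok in stopwords or tok in extra_common:
            continue
        if tok not in lexicon:
            continue
        lemmas.append(lemmatizer(tok))
    return lemmas


def narrative_typicality(docs: list[list[str]], focal: int) -> float:
    """Mean TF-IDF cosine similarity of document ``focal`` to all others.

    ``docs`` are same-prompt documents as lemma lists.  Uses smoothed IDF
    ``ln((1+N)/(1+df)) + 1`` with L2-normalized vectors, so identical
    documents score 1 and documents sharing no lemma score 0.  Returns NaN
    for an unscoreable (empty) focal document.
    """
    if len(docs) < 2:
        raise ValueError("typicality needs at least 2 documents for the prompt")
    if not docs[focal]:
        return float("nan")
    vec = TfidfVectorizer(analyzer=lambda d: d, smooth_idf=True, norm="l2")
    X = vec.fit_transform(docs)
    sims = (X[focal] @ X.T).toarray().ravel()
    others = [sims[i] for i in range(len(docs)) if i != focal and docs[i]]
    if not others:
        return float("nan")
    return float(np.mean(others))


def typicality_scores(docs: list[list[str]]) -> np.ndarray:
    """Narrative typicality for every document of one prompt's corpus."""
    return np.array([narrative_typicality(docs, i) for i in range(len(docs))])


# ---------------------------------------------------------------------------
# Coherence


def _embed(group: list[str], embeddings: dict[str, np.ndarray]) -> np.ndarray:
    vecs = [embeddings[w] for w in group if w in embeddings]
    dropped = len(group) - len(vecs)
    if dropped:
        logger.debug("dropped %d lemmas without embeddings", dropped)
    return np.array(vecs) if vecs else np.empty((0, 0))


def relaxed_wmd(
    group1: list[str],
    group2: list[str],
    embeddings: dict[str, np.ndarray],
    full_transport: bool = False,
) -> float:
    """Symmetrized nearest-neighbor word mover's distance between word groups.

    Mean over words in group1 of the Euclidean distance to their nearest
    word in group2, averaged with the mirror direction.  Zero iff the two
    groups cover the same set of vectors.  ``full_transport=True`` solves
    the full optimal-transport problem (uniform weights) instead of the
    nearest-neighbor relaxation.
    """
    V1, V2 = _embed(group1, embeddings), _embed(group2, embeddings)
    if V1.size == 0 or V2.size == 0:
        return float("nan")
    D = cdist(V1, V2)
    if not full_transport:
        return 0.5 * (D.min(axis=1).mean() + D.min(axis=0).mean())
    return _emd_uniform(D)


def _emd_uniform(D: np.ndarray) -> float:
    """Earth mover's distance with uniform weights via linear programming."""
    n, m = D.shape
    # variables: flow matrix flattened; constraints: row sums 1/n, col sums 1/m
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / n)
    for jcol in range(m):
        col = np.zeros(n * m)
        col[jcol::m] = 1.0
        A_eq.append(col)
        b_eq.append(1.0 / m)
    res = linprog(D.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def windowed_coherence(
    lemmas: list[str],
    embeddings: dict[str, np.ndarray],
    window: int,
    metric: str = "wmd",
) -> float:
    """Coherence of a document at one window size; higher = more coherent.

    For each starting offset 0..window-1, consecutive non-overlapping
    windows of ``window`` lemmas are compared pairwise -- by cosine of mean
    vectors (``agg_cosine``) or negated relaxed word mover's distance
    (``wmd``) -- then scores are averaged over pairs and offsets.  Documents
    shorter than ``2 * window`` are unscoreable (NaN).
    """
    if metric not in ("wmd", "agg_cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(lemmas) < 2 * window:
        return float("nan")
    offset_scores = []
    for offset in range(window):
        chunks = [
            lemmas[i : i + window]
            for i in range(offset, len(lemmas) - window + 1, window)
        ]
        pair_scores = []
        for g1, g2 in zip(chunks[:-1], chunks[1:]):
            if metric == "wmd":
                d = relaxed_wmd(g1, g2, embeddings)
                score = -d if np.isfinite(d) else np.nan
            else:
                v1, v2 = _embed(g1, embeddings), _embed(g2, embeddings)
                if v1.size == 0 or v2.size == 0:
                    score = np.nan
                else:
                    m1, m2 = v1.mean(axis=0), v2.mean(axis=0)
                    denom = np.linalg.norm(m1) * np.linalg.norm(m2)
                    score = float(m1 @ m2 / denom) if denom > 0 else np.nan
            if np.isfinite(score):
                pair_scores.append(score)
        if pair_scores:
            offset_scores.append(np.mean(pair_scores))
    return float(np.mean(offset_scores)) if offset_scores else float("nan")


def coherence_profile(
    lemmas: list[str],
    embeddings: dict[str, np.ndarray],
    window_sizes: list[int] = (1, 2, 3, 4, 5),
    metric: str = "wmd",
) -> dict[int, float]:
    """Windowed coherence at several window sizes (NaN where too short)."""
    return {w: windowed_coherence(lemmas, embeddings, w, metric) for w in window_sizes}


# ---------------------------------------------------------------------------
# Composite per-participant scores


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("standardization needs at least 2 scoreable documents")
    m, s = np.nanmean(x[finite]), np.nanstd(x[finite])
    if s == 0:
        return np.where(finite, 0.0, np.nan)
    return (x - m) / s


def composite_scores(
    doc_table: pd.DataFrame,
    embeddings: dict[str, np.ndarray],
    window_sizes: list[int] = (1, 2, 3, 4, 5),
    metric: str = "wmd",
) -> pd.DataFrame:
    """Per-participant composites of typicality and coherence across prompts.

    ``doc_table`` has columns participant_id, prompt_id, lemmas (list).  Each
    measure is z-scored within prompt across participants and summed across
    prompts.  Also emits first-half and second-half typicality (documents
    split at the midpoint, halves scored against same-half corpora).
    """
    measures: dict[str, dict[tuple, float]] = {}

    for prompt, grp in doc_table.groupby("prompt_id"):
        pids = grp["participant_id"].tolist()
        docs = grp["lemmas"].tolist()
        if len(docs) < 2:
            raise ValueError(f"prompt {prompt} has fewer than 2 documents")
        typ = typicality_scores(docs)
        halves1 = [d[: len(d) // 2] for d in docs]
        halves2 = [d[len(d) // 2 :] for d in docs]
        typ_h1 = typicality_scores(halves1)
        typ_h2 = typicality_scores(halves2)
        coh = {
            w: np.array([windowed_coherence(d, embeddings, w, metric) for d in docs])
            for w in window_sizes
        }
        cols = {"typicality": typ, "typicality_half1": typ_h1, "typicality_half2": typ_h2}
        cols.update({f"coherence_w{w}": coh[w] for w in window_sizes})
        for name, vals in cols.items():
            z = _zscore(vals)
            for pid, v in zip(pids, z):
                measures.setdefault(name, {}).setdefault(pid, []).append(v)

    rows = []
    for pid in sorted({p for m in measures.values() for p in m}):
        row = {"participant_id": pid}
        for name, per_pid in measures.items():
            vals = [v for v in per_pid.get(pid, []) if np.isfinite(v)]
            row[name] = float(np.sum(vals)) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
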