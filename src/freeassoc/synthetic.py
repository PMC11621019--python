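"""Synthetic inputs for the association-modelling pipeline.

Generates every input the analysis needs with the statistical structure it
assumes: power-law per-cue typicality norms, cohorts with known SMP
parameters drawn from group priors, forward-simulated association trials
(RT = generation times + uniform non-decision time), clustered synthetic
embedding spaces, and two-prompt narrative corpora with controllable topic
drift.  Ground truth (true parameters, latent rejection counts) is kept in
sidecar structures, never in the primary trial table.

Defaults emulate the main-study conditions: a 148-cue pool with each
participant responding to a random subset of 20 cues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norms import CueNorms
from .params import GroupPrior, SMPParameters, default_group_prior
from .smp import simulate_trial

#: Cue-pool size of the main-study emulation.
DEFAULT_CUE_POOL = 148
#: Cues presented per participant ("a random subset of 20").
DEFAULT_TRIALS_PER_PARTICIPANT = 20

# Child-seed offsets: one global seed expands into per-component streams.
_SEED_NORMS = 11
_SEED_COHORT = 23
_SEED_TRIALS = 37
_SEED_NARRATIVE = 53


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic association study."""

    n_cues: int = DEFAULT_CUE_POOL
    cue_pool_size: int | None = None  # defaults to n_cues
    trials_per_participant: int = DEFAULT_TRIALS_PER_PARTICIPANT
    n_assoc_per_cue: int = 25
    skew_exponent: float = 1.0
    group_prior: GroupPrior = field(default_factory=default_group_prior)
    seed: int = 0

    def __post_init__(self):
        if self.cue_pool_size is None:
            self.cue_pool_size = self.n_cues
        for name in ("n_cues", "cue_pool_size", "trials_per_participant", "n_assoc_per_cue"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.skew_exponent < 0:
            raise ValueError("skew_exponent must be nonnegative")
        if self.trials_per_participant > self.cue_pool_size:
            raise ValueError("trials_per_participant cannot exceed cue_pool_size")
        if self.cue_pool_size > self.n_cues:
            raise ValueError("cue_pool_size cannot exceed n_cues")


@dataclass
class NarrativeGenConfig:
    """Configuration of the synthetic narrative corpus."""

    n_topics: int = 8
    words_per_topic: int = 40
    embedding_dim: int = 16
    drift_probability: float = 0.1
    min_words: int = 100  # participants "write at least 100 words"
    n_prompts: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.drift_probability <= 1.0):
            raise ValueError("drift_probability must lie in [0, 1]")
        if self.min_words < 1:
            raise ValueError("min_words must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        for name in ("n_topics", "words_per_topic", "n_prompts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------


def generate_cue_norms(cfg: SyntheticConfig) -> dict[str, CueNorms]:
    """Power-law typicality norms: rank r gets weight r**(-skew_exponent),
    normalized to sum to exactly 1 per cue.  Deterministic given the seed
    (the seed only orders which lemma labels attach to which rank)."""
    rng = np.random.default_rng(cfg.seed + _SEED_NORMS)
    ranks = np.arange(1, cfg.n_assoc_per_cue + 1, dtype=float)
    weights = ranks ** (-cfg.skew_exponent)
    typ = weights / weights.sum()
    # emulate integer endorsement counts from a virtual respondent pool
    n_resp = max(4 * cfg.n_assoc_per_cue, 100)
    counts = np.maximum(np.round(typ * n_resp).astype(int), 1)
    norms = {}
    for c in range(cfg.n_cues):
        cue_id = f"cue{c:03d}"
        labels = [f"{cue_id}_assoc{r:03d}" for r in range(cfg.n_assoc_per_cue)]
        rng.integers(0, 1)  # advance the stream per cue for future variants
        norms[cue_id] = CueNorms(
            cue_id=cue_id,
            lemmas=labels,
            counts=counts,
            typicalities=typ.copy(),
            n_respondents=n_resp,
        )
    return norms


def generate_cohort(
    n_participants: int,
    group_prior: GroupPrior,
    seed: int = 0,
) -> dict[str, SMPParameters]:
    """Draw each participant's seven parameters independently from the group
    priors; this is the recorded ground truth for recovery studies."""
    rng = np.random.default_rng(seed + _SEED_COHORT)
    draws = group_prior.sample_settings(n_participants, rng)
    cohort = {}
    for i in range(n_participants):
        pid = f"p{i:04d}"
        cohort[pid] = SMPParameters(
            beta=float(draws["beta"][i]),
            alpha_I=float(draws.get("alpha_I", np.zeros(n_participants))[i]),
            alpha_sign=int(draws.get("alpha_sign", np.ones(n_participants))[i]),
            s_mu=float(draws["s_mu"][i]),
            lam=float(draws["lam"][i]),
            tau0=float(draws["tau0"][i]),
            tau_r=float(draws["tau_r"][i]),
        )
    return cohort


def simulate_dataset(
    cohort: dict[str, SMPParameters],
    norms: dict[str, CueNorms],
    cfg: SyntheticConfig,
    no_rejection: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate the association task for a whole cohort.

    Each participant answers ``trials_per_participant`` cues drawn without
    replacement from the cue pool.  Returns the primary trial table
    (participant_id, cue_id, response, rt_ms, valid) and a latent sidecar
    table (rejection counts) for testing only.
    """
    pool = sorted(norms)[: cfg.cue_pool_size]
    missing = [c for c in pool if c not in norms]
    if missing:
        raise KeyError(f"cues missing from norms: {missing[:5]}")
    rng = np.random.default_rng(cfg.seed + _SEED_TRIALS)
    rows, latent = [], []
    for pid in sorted(cohort):
        params = cohort[pid]
        cues = rng.choice(pool, size=cfg.trials_per_participant, replace=False)
        for cue in cues:
            lemma, rt_s, n_rej = simulate_trial(
                norms[str(cue)], params, rng, no_rejection=no_rejection
            )
            rows.append((pid, str(cue), lemma, lemma, rt_s * 1000.0, True, "none"))
            latent.append((pid, str(cue), n_rej))
    trials = pd.DataFrame(
        rows,
        columns=["participant_id", "cue_id", "response_raw", "response_lemma",
                 "rt_ms", "valid", "exclusion_reason"],
    )
    sidecar = pd.DataFrame(latent, columns=["participant_id", "cue_id", "n_rejected"])
    return trials, sidecar


def write_ground_truth_json(cohort: dict[str, SMPParameters], path) -> None:
    with open(path, "w") as fh:
        json.dump({pid: p.to_dict() for pid, p in cohort.items()}, fh, indent=1)


def read_ground_truth_json(path) -> dict[str, SMPParameters]:
    with open(path) as fh:
        return {pid: SMPParameters.from_dict(d) for pid, d in json.load(fh).items()}


# ---------------------------------------------------------------------------
# Narrative corpora


def _topic_embedding_space(cfg: NarrativeGenConfig, rng) -> tuple[dict[str, np.ndarray], list[list[str]]]:
    """Clustered unit-vector vocabulary: cluster centers uniform on the
    sphere, members = center + small isotropic noise, renormalized."""
    vocab_by_topic = []
    emb = {}
    for k in range(cfg.n_topics):
        center = rng.normal(size=cfg.embedding_dim)
        center /= np.linalg.norm(center)
        words = []
        for w in range(cfg.words_per_topic):
            token = f"topic{k}_word{w}"
            v = center + 0.15 * rng.normal(size=cfg.embedding_dim)
            emb[token] = v / np.linalg.norm(v)
            words.append(token)
        vocab_by_topic.append(words)
    return emb, vocab_by_topic


def generate_narrative_corpus(
    cfg: NarrativeGenConfig, n_participants: int = 50
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Topical random-walk documents over a clustered embedding space.

    Each document starts in a random topic; at each word, with probability
    ``1 - drift_probability`` the next word stays in the current topic,
    otherwise the topic is redrawn uniformly (possibly landing back in the
    same one).  Returns a document table (participant_id, prompt_id, lemmas
    space-joined) and the token -> vector embedding map.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_NARRATIVE)
    emb, vocab = _topic_embedding_space(cfg, rng)
    rows = []
    for i in range(n_participants):
        pid = f"p{i:04d}"
        for prompt in range(cfg.n_prompts):
            topic = int(rng.integers(cfg.n_topics))
            words = []
            for _ in range(cfg.min_words):
                if rng.random() < cfg.drift_probability:
                    topic = int(rng.integers(cfg.n_topics))
                words.append(vocab[topic][int(rng.integers(cfg.words_per_topic))])
            rows.append((pid, f"prompt{prompt}", " ".join(words)))
    docs = pd.DataFrame(rows, columns=["participant_id", "prompt_id", "text"])
    return docs, emb


# ---------------------------------------------------------------------------
# Embedding IO: word2vec text format ("N dim" header, then token + values)


def write_word2vec_text(embeddings: dict[str, np.ndarray], path) -> None:
    tokens = sorted(embeddings)
    dim = len(next(iter(embeddings.values())))
    with open(path, "w") as fh:
        fh.write(f"{len(tokens)} {dim}\n")
        for tok in tokens:
            vec = " ".join(f"{x:.6f}" for x in embeddings[tok])
            fh.write(f"{tok} {vec}\n")


def read_word2vec_text(path) -> dict[str, np.ndarray]:
    emb = {}
    with open(path) as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            emb[parts[0]] = np.array([float(x) for x in parts[1 : dim + 1]])
    if len(emb) != n:
        raise ValueError(f"embedding file declares {n} tokens but has {len(emb)}")
    return emb
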