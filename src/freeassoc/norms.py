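"""Free-association response cleaning and per-cue typicality norms.

Raw association trials (participant, cue, free-text response, RT) are
cleaned -- lowercasing, nonword/color-name/single-letter exclusion,
lemmatization -- and aggregated into per-cue norms where an association's
*typicality* (pTP) is the proportion of responding participants who endorsed
it, and an association endorsed by exactly one participant is flagged
*idiosyncratic*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant_id",
    "cue_id",
    "response_raw",
    "response_lemma",
    "rt_ms",
    "valid",
    "exclusion_reason",
]

EXCLUSION_REASONS = ("none", "nonword", "color_name", "single_letter", "skipped")

#: Default participant-validity threshold: participants with fewer valid
#: trials than this are excluded from modelling ("less than" is strict).
DEFAULT_MIN_VALID = 10


# ---------------------------------------------------------------------------
# Lemmatization: a pluggable contract (callable text -> dictionary form).


class SuffixLemmatizer:
    """Basic rule lemmatizer: strips common English inflectional suffixes.

    Handles regular plurals ("chores" -> "chore", "bodies" -> "body") and
    -ing/-ed forms ("going" -> "go", "walked" -> "walk").  An explicit
    exception dictionary takes precedence over the rules.  When a lexicon is
    supplied, a rule only fires if its output is in the lexicon, which keeps
    irregular words ("glass", "sing") intact.
    """

    def __init__(self, exceptions: dict[str, str] | None = None,
                 lexicon: set[str] | None = None):
        self.exceptions = dict(exceptions or {})
        self.lexicon = set(lexicon) if lexicon is not None else None

    def _ok(self, candidate: str) -> bool:
        return self.lexicon is None or candidate in self.lexicon

    def __call__(self, word: str) -> str:
        w = word.lower()
        if w in self.exceptions:
            return self.exceptions[w]
        if w.endswith("ies") and len(w) > 4:
            c = w[:-3] + "y"
            if self._ok(c):
                return c
        if w.endswith("sses") or w.endswith("shes") or w.endswith("ches"):
            c = w[:-2]
            if self._ok(c):
                return c
        if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
            c = w[:-1]
            if self._ok(c):
                return c
        if w.endswith("ing") and len(w) > 4:
            for c in (w[:-3], w[:-3] + "e"):
                if self._ok(c):
                    return c
        if w.endswith("ed") and len(w) > 3:
            for c in (w[:-2], w[:-1]):
                if self._ok(c):
                    return c
        return w


@dataclass
class CueNorms:
    """Per-cue association norms.

    ``typicalities[i]`` is the proportion of responding participants who
    endorsed ``lemmas[i]``; ``idiosyncratic[i]`` marks count == 1.
    """

    cue_id: str
    lemmas: list[str]
    counts: np.ndarray
    typicalities: np.ndarray
    n_respondents: int
    idiosyncratic: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.typicalities = np.asarray(self.typicalities, dtype=float)
        if self.idiosyncratic is None:
            self.idiosyncratic = self.counts == 1
        self.idiosyncratic = np.asarray(self.idiosyncratic, dtype=bool)
        if len(self.lemmas) != len(set(self.lemmas)):
            raise ValueError(f"duplicate lemmas in norms for cue {self.cue_id}")
        if not (len(self.lemmas) == len(self.counts) == len(self.typicalities)):
            raise ValueError("ragged norm entry lists")
        if np.any(self.typicalities <= 0) or np.any(self.typicalities > 1):
            raise ValueError("typicalities must lie in (0, 1]")
        self._index = {lem: i for i, lem in enumerate(self.lemmas)}

    def __len__(self) -> int:
        return len(self.lemmas)

    def index_of(self, lemma: str) -> int | None:
        return self._index.get(lemma)

    def with_smoothed(self, lemma: str) -> tuple["CueNorms", int]:
        """Candidate set including ``lemma``.

        If the lemma is unseen (held-out data), it is appended with the
        smoothed typicality 1/(n_respondents + 1) so that no trial has zero
        probability.  Returns (norms, index of lemma).
        """
        i = self.index_of(lemma)
        if i is not None:
            return self, i
        smoothed = 1.0 / (self.n_respondents + 1)
        return (
            CueNorms(
                cue_id=self.cue_id,
                lemmas=self.lemmas + [lemma],
                counts=np.append(self.counts, 1),
                typicalities=np.append(self.typicalities, smoothed),
                n_respondents=self.n_respondents,
            ),
            len(self.lemmas),
        )


# ---------------------------------------------------------------------------
# Response normalization


_TOKEN_RE = re.compile(r"[a-z']+")


def normalize_responses(
    trials: pd.DataFrame,
    lexicon: set[str] | list[str],
    color_names: set[str] | list[str],
    lemmatizer=None,
) -> pd.DataFrame:
    """Clean raw association responses into validated, lemmatized trials.

    Lowercases responses, then marks invalid: empty/skipped responses,
    nonwords and misspellings (tokens absent from ``lexicon``), color
    names, and single-letter responses.  Survivors are lemmatized with the
    supplied lemmatizer (any callable text -> dictionary form; default a
    :class:`SuffixLemmatizer` restricted to the lexicon).

    Parameters
    ----------
    trials : DataFrame with columns participant_id, cue_id, response_raw, rt_ms.
    """
    lexicon = set(w.lower() for w in lexicon)
    if not lexicon:
        raise ValueError("lexicon must be nonempty")
    color_names = set(w.lower() for w in color_names)
    if lemmatizer is None:
        lemmatizer = SuffixLemmatizer(lexicon=lexicon)

    out = trials.copy()
    lemmas, valids, reasons = [], [], []
    for raw in out["response_raw"].astype(str):
        token = raw.strip().lower()
        m = _TOKEN_RE.fullmatch(token)
        if token == "" or token == "nan":
            reason = "skipped"
        elif len(token) == 1:
            reason = "single_letter"
        elif token in color_names:
            reason = "color_name"
        elif m is None or token not in lexicon:
            reason = "nonword"
        else:
            reason = "none"
        if reason == "none":
            lemmas.append(lemmatizer(token))
            valids.append(True)
        else:
            lemmas.append("")
            valids.append(False)
        reasons.append(reason)
    out["response_lemma"] = lemmas
    out["valid"] = valids
    out["exclusion_reason"] = reasons
    return out[TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]]


def build_typicality_norms(trials: pd.DataFrame) -> dict[str, CueNorms]:
    """Aggregate valid trials into per-cue typicality norms.

    For every cue, each participant is counted at most once per lemma;
    typicality = endorsement count / number of participants with at least
    one valid response to that cue.  Cues with zero valid trials are
    excluded with a warning.
    """
    norms: dict[str, CueNorms] = {}
    valid = trials[trials["valid"].astype(bool) & (trials["response_lemma"] != "")]
    for cue_id, grp in valid.groupby("cue_id", sort=True):
        endorsements = grp[["participant_id", "response_lemma"]].drop_duplicates()
        counts = endorsements.groupby("response_lemma").size().sort_index()
        n_resp = endorsements["participant_id"].nunique()
        # order entries by descending count, lemma as tie-break, for stable IO
        order = sorted(counts.index, key=lambda lem: (-counts[lem], lem))
        cvec = np.array([counts[lem] for lem in order], dtype=int)
        norms[str(cue_id)] = CueNorms(
            cue_id=str(cue_id),
            lemmas=[str(lem) for lem in order],
            counts=cvec,
            typicalities=cvec / n_resp,
            n_respondents=int(n_resp),
        )
    dropped = set(trials["cue_id"].astype(str)) - set(norms)
    for cue in sorted(dropped):
        logger.warning("cue %s has no valid trials; excluded from norms", cue)
    return norms


def filter_participants(
    trials: pd.DataFrame, min_valid: int = DEFAULT_MIN_VALID
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants with fewer than ``min_valid`` valid trials.

    Returns the retained trial table and an exclusion report (one row per
    dropped participant with their valid-trial count).  The threshold is
    strict: a participant with exactly ``min_valid`` valid trials is kept.
    """
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    counts = (
        trials.assign(_v=trials["valid"].astype(bool))
        .groupby("participant_id")["_v"]
        .sum()
    )
    dropped = counts[counts < min_valid]
    report = pd.DataFrame(
        {"participant_id": dropped.index, "n_valid": dropped.values.astype(int)}
    ).reset_index(drop=True)
    retained = trials[~trials["participant_id"].isin(dropped.index)].reset_index(drop=True)
    return retained, report


# ---------------------------------------------------------------------------
# IO


def write_norms_tsv(norms: dict[str, CueNorms], path) -> None:
    rows = []
    for cue_id in sorted(norms):
        cn = norms[cue_id]
        for lem, cnt, typ, idio in zip(cn.lemmas, cn.counts, cn.typicalities, cn.idiosyncratic):
            rows.append((cue_id, lem, int(cnt), float(typ), int(idio), cn.n_respondents))
    pd.DataFrame(
        rows,
        columns=["cue_id", "lemma", "count", "typicality", "idiosyncratic", "n_respondents"],
    ).to_csv(path, sep="\t", index=False)


def read_norms_tsv(path) -> dict[str, CueNorms]:
    df = pd.read_csv(path, sep="\t", dtype={"cue_id": str, "lemma": str})
    norms = {}
    for cue_id, grp in df.groupby("cue_id", sort=True):
        norms[str(cue_id)] = CueNorms(
            cue_id=str(cue_id),
            lemmas=grp["lemma"].tolist(),
            counts=grp["count"].to_numpy(),
            typicalities=grp["typicality"].to_numpy(),
            n_respondents=int(grp["n_respondents"].iloc[0]),
            idiosyncratic=grp["idiosyncratic"].to_numpy(dtype=bool),
        )
    return norms


def read_wordlist(path) -> set[str]:
    """Plain-text word list, one token per line."""
    with open(path) as fh:
        return {line.strip().lower() for line in fh if line.strip()}
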