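"""End-to-end pipeline stages and the parameter-recovery experiment.

Each stage reads/writes the documented plain-text formats (TSV, JSON,
word2vec text), embeds the config hash and seed in its outputs, and streams
logs to standard error.  ``run_recovery_experiment`` ties all stages
together: generate norms and a cohort with known parameters, simulate
trials, fit hierarchically, and measure truth-estimate agreement.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .fitting import estimates_to_frame
from .model import SemiMarkovAssociationModel
from .narrative import composite_scores, preprocess_narrative
from .norms import (
    DEFAULT_MIN_VALID,
    build_typicality_norms,
    filter_participants,
    read_norms_tsv,
    write_norms_tsv,
)
from .params import PARAM_NAMES, GroupPrior, PriorSpec, default_group_prior
from .synthetic import NarrativeGenConfig, SyntheticConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build-norms", "fit", "estimate", "narrative-metrics", "recover")

#: Reduced desk-scale recovery configuration: enough trials and settings for
#: informative recovery at minutes-scale runtime.
RECOVERY_DEFAULTS = {
    "n_participants": 60,
    "n_cues": 60,
    "trials_per_participant": 30,
    "n_assoc_per_cue": 8,
    "skew_exponent": 1.0,
    "n_settings": 300,
    "max_iter": 6,
    "n_final_settings": 1500,
}

#: Group prior used to *generate* recovery cohorts: realistic heterogeneity
#: with RTs of a few seconds and a mix of regulation directions.
def recovery_generating_prior() -> GroupPrior:
    return GroupPrior({
        "beta": PriorSpec("normal", (-0.5, 0.6)),
        "alpha_I": PriorSpec("beta", (2.0, 2.0)),
        "alpha_sign": PriorSpec("bernoulli_pm1", (0.6,)),
        "s_mu": PriorSpec("normal", (0.0, 0.4)),
        "lam": PriorSpec("lognormal", (np.log(0.5), 0.25)),
        "tau0": PriorSpec("lognormal", (np.log(0.4), 0.25)),
        "tau_r": PriorSpec("lognormal", (np.log(0.5), 0.3)),
    })


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stamp(cfg: dict, seed: int) -> dict:
    return {"config_hash": config_hash(cfg), "seed": seed}


def _write_tsv_with_header(df: pd.DataFrame, path, stamp: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv_with_header(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _synthetic_config(cfg: dict, seed: int) -> SyntheticConfig:
    keys = ("n_cues", "cue_pool_size", "trials_per_participant",
            "n_assoc_per_cue", "skew_exponent")
    kwargs = {k: cfg[k] for k in keys if k in cfg}
    return SyntheticConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Generate norms + cohort, simulate the association task, write all
    artifacts (trials TSV, norms TSV, ground-truth JSON sidecars)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    scfg = _synthetic_config(cfg, seed)
    gen_prior = (GroupPrior.from_dict(cfg["generating_prior"])
                 if "generating_prior" in cfg else recovery_generating_prior())
    norms = synthetic.generate_cue_norms(scfg)
    cohort = synthetic.generate_cohort(cfg.get("n_participants", 30), gen_prior, seed)
    trials, sidecar = synthetic.simulate_dataset(
        cohort, norms, scfg, no_rejection=cfg.get("no_rejection", False)
    )
    stamp = _stamp(cfg, seed)
    _write_tsv_with_header(
        trials[["participant_id", "cue_id", "response_raw", "rt_ms", "valid"]]
        .rename(columns={"response_raw": "response"}),
        out_dir / "trials.tsv", stamp)
    write_norms_tsv(norms, out_dir / "norms.tsv")
    synthetic.write_ground_truth_json(cohort, out_dir / "ground_truth_params.json")
    _write_tsv_with_header(sidecar, out_dir / "latent_rejections.tsv", stamp)
    logger.info("simulate: %d trials, %d cues", len(trials), len(norms))
    return {"trials": str(out_dir / "trials.tsv"), "norms": str(out_dir / "norms.tsv"), **stamp}


def stage_build_norms(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Rebuild typicality norms from a trial table (validity-filtered)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = read_tsv_with_header(cfg["trials"])
    if "response_lemma" not in trials.columns:
        trials = trials.rename(columns={"response": "response_lemma"})
        trials["valid"] = trials.get("valid", True)
    retained, report = filter_participants(trials, cfg.get("min_valid", DEFAULT_MIN_VALID))
    norms = build_typicality_norms(retained)
    write_norms_tsv(norms, out_dir / "norms_rebuilt.tsv")
    stamp = _stamp(cfg, seed)
    _write_tsv_with_header(report, out_dir / "excluded_participants.tsv", stamp)
    return {"norms": str(out_dir / "norms_rebuilt.tsv"), "n_excluded": len(report), **stamp}


def _model_from_cfg(cfg: dict):
    trials = read_tsv_with_header(cfg["trials"])
    if "response_lemma" not in trials.columns:
        trials = trials.rename(columns={"response": "response_lemma"})
    norms = read_norms_tsv(cfg["norms"])
    return SemiMarkovAssociationModel(trials, norms, variant=cfg.get("variant", "full"))


def stage_fit(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Hierarchical EM fit; writes the FitReport as JSON and estimates TSV."""
    out_dir.mkdir(parents=True, exist_ok=True)
    model = _model_from_cfg(cfg)
    res = model.fit(
        n_settings=cfg.get("n_settings", 1000),
        max_iter=cfg.get("max_iter", 15),
        n_final_settings=cfg.get("n_final_settings", 10_000),
        seed=seed,
    )
    stamp = _stamp(cfg, seed)
    report = res.report.to_dict()
    report.update(stamp)
    with open(out_dir / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    _write_tsv_with_header(res.params, out_dir / "estimates.tsv", stamp)
    return {"fit_report": str(out_dir / "fit_report.json"),
            "ibic": res.ibic, **stamp}


def stage_estimate(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Shared-sample participant estimation under priors from a fit report."""
    from .fitting import estimate_participants

    out_dir.mkdir(parents=True, exist_ok=True)
    model = _model_from_cfg(cfg)
    with open(cfg["fit_report"]) as fh:
        prior = GroupPrior.from_dict(json.load(fh)["final_prior"])
    rng = np.random.default_rng(seed)
    est = estimate_participants(
        model.trials, model.norms, prior,
        n_settings=cfg.get("n_final_settings", 10_000), rng=rng,
        variant=model.variant,
    )
    stamp = _stamp(cfg, seed)
    _write_tsv_with_header(estimates_to_frame(est), out_dir / "estimates.tsv", stamp)
    return {"estimates": str(out_dir / "estimates.tsv"), "n": len(est), **stamp}


def stage_narrative_metrics(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Typicality/coherence composites for a narrative corpus.

    Without an input corpus, generates a synthetic drifting corpus first.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    if "documents" in cfg:
        docs = read_tsv_with_header(cfg["documents"])
        emb = synthetic.read_word2vec_text(cfg["embeddings"])
        lexicon = set(emb)
        stop = set(cfg.get("stopwords", []))
        docs["lemmas"] = [
            preprocess_narrative(t, stop, lexicon) for t in docs["text"].astype(str)
        ]
    else:
        ncfg = NarrativeGenConfig(
            seed=seed, drift_probability=cfg.get("drift_probability", 0.1)
        )
        docs, emb = synthetic.generate_narrative_corpus(
            ncfg, n_participants=cfg.get("n_participants", 30)
        )
        docs["lemmas"] = [t.split() for t in docs["text"]]
        synthetic.write_word2vec_text(emb, out_dir / "embeddings.w2v.txt")
    scores = composite_scores(
        docs, emb,
        window_sizes=tuple(cfg.get("window_sizes", (1, 2, 3))),
        metric=cfg.get("metric", "wmd"),
    )
    stamp = _stamp(cfg, seed)
    _write_tsv_with_header(scores, out_dir / "narrative_scores.tsv", stamp)
    return {"scores": str(out_dir / "narrative_scores.tsv"), "n": len(scores), **stamp}


def run_stage(stage: str, cfg: dict, seed: int, out_dir) -> dict:
    out_dir = Path(out_dir)
    dispatch = {
        "simulate": stage_simulate,
        "build-norms": stage_build_norms,
        "fit": stage_fit,
        "estimate": stage_estimate,
        "narrative-metrics": stage_narrative_metrics,
        "recover": run_recovery_experiment_cfg,
    }
    if stage not in dispatch:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    try:
        return dispatch[stage](cfg, seed, out_dir)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"[{stage}] missing input: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"[{stage}] failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Recovery experiment


def run_recovery_experiment(
    seed: int = 0,
    out_dir=None,
    **overrides,
) -> dict:
    """Simulate a cohort with known parameters, fit, and score recovery.

    Returns (and optionally writes) a report with per-parameter Pearson r
    between true and estimated values, alpha_sign accuracy overall and among
    strongly regulating participants (true alpha_I >= 0.6), and the iBIC
    trace of the fit.
    """
    cfg = {**RECOVERY_DEFAULTS, **overrides}
    scfg = SyntheticConfig(
        n_cues=cfg["n_cues"],
        trials_per_participant=cfg["trials_per_participant"],
        n_assoc_per_cue=cfg["n_assoc_per_cue"],
        skew_exponent=cfg["skew_exponent"],
        seed=seed,
    )
    gen_prior = cfg.get("generating_prior") or recovery_generating_prior()
    norms = synthetic.generate_cue_norms(scfg)
    cohort = synthetic.generate_cohort(cfg["n_participants"], gen_prior, seed)
    trials, _ = synthetic.simulate_dataset(cohort, norms, scfg)

    model = SemiMarkovAssociationModel(trials, norms)
    res = model.fit(
        n_settings=cfg["n_settings"],
        max_iter=cfg["max_iter"],
        n_final_settings=cfg["n_final_settings"],
        seed=seed,
    )

    est = res.params.set_index("participant_id")
    true = pd.DataFrame({pid: p.to_dict() for pid, p in cohort.items()}).T
    true.index.name = "participant_id"

    report = {"seed": seed, "config": {k: v for k, v in cfg.items()
                                       if not isinstance(v, GroupPrior)},
              "ibic_trace": res.ibic_trace, "converged": res.converged,
              "recovery_r": {}, "alpha_sign": {}}
    for name in PARAM_NAMES:
        if name == "alpha_sign":
            continue
        t = true[name].astype(float).loc[est.index]
        e = est[name].astype(float)
        r = float(np.corrcoef(t, e)[0, 1]) if t.std() > 0 and e.std() > 0 else float("nan")
        report["recovery_r"][name] = r
    sign_true = true["alpha_sign"].astype(float).loc[est.index]
    sign_est = est["alpha_sign"].astype(float)
    strong = true["alpha_I"].astype(float).loc[est.index] >= 0.6
    report["alpha_sign"]["accuracy"] = float(np.mean(sign_true == sign_est))
    report["alpha_sign"]["accuracy_strong_regulators"] = (
        float(np.mean((sign_true == sign_est)[strong])) if strong.any() else float("nan")
    )
    report["alpha_sign"]["n_strong_regulators"] = int(strong.sum())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = _stamp(report["config"], seed)
        report.update(stamp)
        with open(out_dir / "recovery_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        _write_tsv_with_header(res.params, out_dir / "estimates.tsv", stamp)
        _write_tsv_with_header(
            true.reset_index(), out_dir / "true_params.tsv", stamp)
    return report


def run_recovery_experiment_cfg(cfg: dict, seed: int, out_dir: Path) -> dict:
    return run_recovery_experiment(seed=seed, out_dir=out_dir, **cfg)


# ---------------------------------------------------------------------------
# Model-variant comparison


#: Desk-scale model-comparison conditions: rejection-heavy regulation
#: (alpha_I concentrated at 0.8, alpha_sign = +1) over the same cue
#: structure as the recovery experiment.
MODEL_COMPARISON_DEFAULTS = {
    "n_participants": 100,
    "n_cues": 40,
    "trials_per_participant": 20,
    "n_assoc_per_cue": 8,
    "skew_exponent": 1.0,
    "n_settings": 300,
    "max_iter": 12,
    "n_settings_final_ibic": 1000,
}


def rejection_heavy_prior() -> GroupPrior:
    """Generating prior for the model-comparison cohort: heavy rejection of
    atypical candidates (alpha_I ~ Beta(16,4), mean 0.8; alpha_sign = +1)."""
    prior = recovery_generating_prior()
    prior.specs["alpha_I"] = PriorSpec("beta", (16.0, 4.0))
    prior.specs["alpha_sign"] = PriorSpec("bernoulli_pm1", (1.0,))
    return prior


def run_model_comparison(seed: int = 0, **overrides) -> dict:
    """Fit the full and no-rejection variants to rejection-heavy synthetic
    data and compare their iBIC.  Data generated by the full process should
    yield a lower (better) iBIC for the full variant.

    Each variant is fitted by hierarchical EM; the compared iBIC is then
    evaluated for each variant's best prior with a common, larger
    evidence-sample size, so that the two variants' marginal likelihoods
    are estimated with equal precision regardless of their dimensionality.
    """
    from .fitting import em_iteration

    cfg = {**MODEL_COMPARISON_DEFAULTS, **overrides}
    scfg = SyntheticConfig(
        n_cues=cfg["n_cues"],
        trials_per_participant=cfg["trials_per_participant"],
        n_assoc_per_cue=cfg["n_assoc_per_cue"],
        skew_exponent=cfg["skew_exponent"],
        seed=seed,
    )
    norms = synthetic.generate_cue_norms(scfg)
    cohort = synthetic.generate_cohort(cfg["n_participants"], rejection_heavy_prior(), seed)
    trials, sidecar = synthetic.simulate_dataset(cohort, norms, scfg)
    by_pid = {str(pid): grp for pid, grp in trials.groupby("participant_id")}
    result = {"seed": seed, "mean_rejections": float(sidecar["n_rejected"].mean())}
    for variant in ("full", "no_rejection"):
        res = SemiMarkovAssociationModel(trials, norms, variant=variant).fit(
            n_settings=cfg["n_settings"], max_iter=cfg["max_iter"],
            n_final_settings=50, seed=seed,
        )
        rng = np.random.default_rng(seed + 101)
        _, ibic_final = em_iteration(
            by_pid, norms, res.group_prior,
            cfg["n_settings_final_ibic"], rng, variant,
        )
        result[variant] = {"ibic": float(ibic_final),
                           "ibic_trace": res.ibic_trace}
    result["full_preferred"] = result["full"]["ibic"] < result["no_rejection"]["ibic"]
    return result
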