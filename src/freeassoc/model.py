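"""Model/results interface for fitting the SMP to association data.

:class:`SemiMarkovAssociationModel` bundles a trial table and cue norms;
``fit()`` runs the hierarchical importance-sampling EM and returns an
:class:`SMPFitResults` carrying per-participant estimates, group-level
priors, the iBIC trace and a printable summary.  Forward simulation hangs
off the model for posterior-predictive checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import (
    DEFAULT_MAX_ITER,
    DEFAULT_N_FINAL_SETTINGS,
    DEFAULT_N_SETTINGS,
    FitReport,
    estimate_participants,
    estimates_to_frame,
    fit_hierarchical,
    participant_loglik,
)
from .norms import CueNorms
from .params import PARAM_NAMES, GroupPrior, SMPParameters, default_group_prior
from .smp import simulate_trial


class SemiMarkovAssociationModel:
    """Hierarchical SMP model of free-association choices and RTs.

    Parameters
    ----------
    trials : DataFrame
        Columns participant_id, cue_id, response_lemma, rt_ms (valid trials).
    norms : dict cue_id -> CueNorms
        Typicality norms defining each cue's candidate set.
    variant : {"full", "no_rejection", "fixed_sign"}
        ``no_rejection`` removes the acceptance stage (every candidate is
        reported); ``fixed_sign`` clamps alpha_sign to +1.
    """

    def __init__(self, trials: pd.DataFrame, norms: dict[str, CueNorms],
                 variant: str = "full"):
        required = {"participant_id", "cue_id", "response_lemma", "rt_ms"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        if "valid" in trials.columns:
            trials = trials[trials["valid"].astype(bool)]
        self.trials = trials.reset_index(drop=True)
        self.norms = norms
        self.variant = variant

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, norms: dict[str, CueNorms],
                       variant: str = "full") -> "SemiMarkovAssociationModel":
        return cls(trials, norms, variant=variant)

    @property
    def n_participants(self) -> int:
        return self.trials["participant_id"].nunique()

    def loglike(self, params: SMPParameters, participant_id: str) -> float:
        """Joint log-likelihood of one participant's trials at one setting."""
        ptrials = self.trials[self.trials["participant_id"] == participant_id]
        return float(participant_loglik(ptrials, self.norms, [params], self.variant)[0])

    def default_init_prior(self) -> GroupPrior:
        """Broad initial priors, with the tau0 prior anchored below the
        cohort's minimum RT (non-decision time cannot exceed any observed
        RT, and participants vary widely in their minimum)."""
        prior = default_group_prior(self.variant)
        min_rt_s = float(self.trials["rt_ms"].min()) / 1000.0
        from .params import PriorSpec

        prior.specs["tau0"] = PriorSpec(
            "lognormal", (np.log(max(0.5 * min_rt_s, 1e-3)), 0.6)
        )
        return prior

    def fit(
        self,
        init_prior: GroupPrior | None = None,
        n_settings: int = DEFAULT_N_SETTINGS,
        max_iter: int = DEFAULT_MAX_ITER,
        n_final_settings: int = DEFAULT_N_FINAL_SETTINGS,
        seed: int | None = None,
    ) -> "SMPFitResults":
        """Hierarchical EM fit followed by shared-sample participant estimation."""
        if init_prior is None:
            init_prior = self.default_init_prior()
        report = fit_hierarchical(
            self.trials, self.norms, init_prior,
            n_settings=n_settings, max_iter=max_iter, seed=seed,
            variant=self.variant,
        )
        report.n_settings_final = n_final_settings
        rng = np.random.default_rng(None if seed is None else seed + 1)
        report.final_estimates = estimate_participants(
            self.trials, self.norms, report.final_prior,
            n_settings=n_final_settings, rng=rng, variant=self.variant,
        )
        report.estimate_table = estimates_to_frame(report.final_estimates)
        return SMPFitResults(self, report)

    def simulate(self, cohort: dict[str, SMPParameters], seed: int | None = None,
                 trials_per_participant: int | None = None) -> pd.DataFrame:
        """Posterior-predictive simulation: replay each participant's cues
        (or a random subset) under the given parameters."""
        rng = np.random.default_rng(seed)
        rows = []
        for pid, params in cohort.items():
            cues = self.trials.loc[
                self.trials["participant_id"] == pid, "cue_id"
            ].unique()
            if trials_per_participant is not None:
                cues = rng.choice(cues, size=min(trials_per_participant, len(cues)),
                                  replace=False)
            for cue in cues:
                lemma, rt_s, n_rej = simulate_trial(self.norms[str(cue)], params, rng)
                rows.append((pid, str(cue), lemma, rt_s * 1000.0, n_rej))
        return pd.DataFrame(
            rows, columns=["participant_id", "cue_id", "response_lemma", "rt_ms",
                           "n_rejected"]
        )


class SMPFitResults:
    """Results of a hierarchical SMP fit."""

    def __init__(self, model: SemiMarkovAssociationModel, report: FitReport):
        self.model = model
        self.report = report

    @property
    def params(self) -> pd.DataFrame:
        """Per-participant posterior-weighted parameter estimates."""
        return self.report.estimate_table

    @property
    def group_prior(self) -> GroupPrior:
        return self.report.final_prior

    @property
    def ibic_trace(self) -> list[float]:
        return self.report.ibic_trace

    @property
    def ibic(self) -> float:
        return self.report.best_ibic

    @property
    def converged(self) -> bool:
        return self.report.converged

    def params_for(self, participant_id: str) -> SMPParameters:
        return self.report.final_estimates[str(participant_id)]

    def summary(self) -> str:
        """Printable summary: fit configuration, iBIC trace, group priors and
        the dispersion of participant estimates."""
        lines = [
            "Semi-Markov association model".center(72),
            "=" * 72,
            f"variant: {self.report.variant:<18} participants: {self.model.n_participants}",
            f"trials: {len(self.model.trials):<20} settings/iter: {self.report.n_settings_per_iteration}",
            f"final settings: {self.report.n_settings_final:<12} converged: {self.report.converged}",
            f"iBIC trace: " + " -> ".join(f"{x:.1f}" for x in self.ibic_trace),
            "-" * 72,
            f"{'parameter':<12}{'prior family':<16}{'hyperparameters':<24}{'est. mean':>10}{'est. sd':>10}",
        ]
        est = self.params
        for name in PARAM_NAMES:
            if name in self.group_prior.specs:
                spec = self.group_prior[name]
                hyper = ", ".join(f"{h:.3f}" for h in spec.hyper)
                col = est[name].astype(float)
                lines.append(
                    f"{name:<12}{spec.family:<16}{hyper:<24}{col.mean():>10.3f}{col.std():>10.3f}"
                )
        lines.append("=" * 72)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<SMPFitResults variant={self.report.variant!r} "
                f"n={self.model.n_participants} iBIC={self.ibic:.1f}>")
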