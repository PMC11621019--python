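"""Participant-level parameters and group-level priors for the SMP model.

The semi-Markov process (SMP) model of free association has exactly seven
free parameters per participant:

``beta``
    Tempering of the typicality-based generation distribution.  Association
    probabilities are proportional to ``pTP ** exp(beta)``; more negative
    values flatten the distribution (less-constrained associative maps).
``alpha_I``
    Regulation threshold in [0, 1]: the (min-max transformed) typicality at
    which the acceptance probability crosses 0.5.  Higher values mean more
    candidates are rejected before one is reported.
``alpha_sign``
    Direction of regulation, +1 or -1.  With +1 atypical associations are
    preferentially rejected; with -1 typical ones are (deliberate
    atypicality).
``s_mu``
    Log-slope linking an association's surprisal, ``-log P(A_i)``, to its
    mean generation time in seconds: ``mu_i = exp(s_mu) * surprisal_i``.
``lam``
    Coefficient of variation of the gamma generation-time distribution:
    ``sigma_i = lam * mu_i``.
``tau0``
    Minimum non-decision time in seconds (encoding, motor onset).
``tau_r``
    Range of the uniform non-decision time: ndt ~ Uniform(tau0, tau0+tau_r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields

import numpy as np

PARAM_NAMES = ("beta", "alpha_I", "alpha_sign", "s_mu", "lam", "tau0", "tau_r")


@dataclass(frozen=True)
class SMPParameters:
    """One participant's seven free SMP parameters."""

    beta: float
    alpha_I: float
    alpha_sign: int
    s_mu: float
    lam: float
    tau0: float
    tau_r: float

    def __post_init__(self) -> None:
        if self.alpha_sign not in (-1, 1):
            raise ValueError(f"alpha_sign must be -1 or +1, got {self.alpha_sign}")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.tau0 < 0:
            raise ValueError("tau0 must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "SMPParameters":
        return cls(**{f.name: d[f.name] for f in fields(cls)})

    @classmethod
    def from_json(cls, s: str) -> "SMPParameters":
        return cls.from_dict(json.loads(s))


N_FREE_PARAMETERS = len(fields(SMPParameters))

# Distribution families usable as group-level priors.  Each has a fixed
# number of hyperparameters, which is what the iBIC complexity term counts.
_FAMILY_NHYPER = {"normal": 2, "lognormal": 2, "beta": 2, "bernoulli_pm1": 1}


@dataclass
class PriorSpec:
    """Group-level prior for a single parameter: a family plus hyperparameters.

    Hyperparameter conventions:
      normal        -- (mean, sd)
      lognormal     -- (mean of log, sd of log)
      beta          -- (a, b), support [0, 1]
      bernoulli_pm1 -- (p,) = P(+1), support {-1, +1}
    """

    family: str
    hyper: tuple

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_NHYPER:
            raise ValueError(f"unknown prior family {self.family!r}")
        self.hyper = tuple(float(h) for h in self.hyper)
        if len(self.hyper) != _FAMILY_NHYPER[self.family]:
            raise ValueError(
                f"{self.family} takes {_FAMILY_NHYPER[self.family]} "
                f"hyperparameters, got {len(self.hyper)}"
            )
        if self.family in ("normal", "lognormal") and self.hyper[1] < 0:
            raise ValueError("sd hyperparameter must be nonnegative")
        if self.family == "beta" and (self.hyper[0] <= 0 or self.hyper[1] <= 0):
            raise ValueError("beta hyperparameters must be positive")
        if self.family == "bernoulli_pm1" and not (0.0 <= self.hyper[0] <= 1.0):
            raise ValueError("bernoulli_pm1 probability must lie in [0, 1]")

    @property
    def n_hyper(self) -> int:
        return _FAMILY_NHYPER[self.family]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.hyper[0], self.hyper[1], size=n)
        if self.family == "lognormal":
            return rng.lognormal(self.hyper[0], self.hyper[1], size=n)
        if self.family == "beta":
            return rng.beta(self.hyper[0], self.hyper[1], size=n)
        # bernoulli_pm1
        return np.where(rng.random(n) < self.hyper[0], 1.0, -1.0)

    def mean(self) -> float:
        if self.family == "normal":
            return self.hyper[0]
        if self.family == "lognormal":
            return float(np.exp(self.hyper[0] + 0.5 * self.hyper[1] ** 2))
        if self.family == "beta":
            a, b = self.hyper
            return a / (a + b)
        return 2.0 * self.hyper[0] - 1.0


class GroupPrior:
    """Group-level prior over the seven SMP parameters.

    A mapping parameter name -> :class:`PriorSpec`.  Model variants drop
    parameters: the ``no_rejection`` variant has no acceptance stage, so
    ``alpha_I`` and ``alpha_sign`` are absent; ``fixed_sign`` drops only
    ``alpha_sign`` (clamped externally).
    """

    def __init__(self, specs: dict[str, PriorSpec]):
        unknown = set(specs) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        self.specs = dict(specs)

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __getitem__(self, name: str) -> PriorSpec:
        return self.specs[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupPrior) and self.specs == other.specs

    @property
    def n_hyperparameters(self) -> int:
        """Total hyperparameter count; the iBIC complexity ``H``."""
        return sum(s.n_hyper for s in self.specs.values())

    def sample_settings(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Draw ``n`` parameter settings; returns name -> array of length n."""
        return {name: spec.sample(n, rng) for name, spec in self.specs.items()}

    def to_dict(self) -> dict:
        return {k: {"family": v.family, "hyper": list(v.hyper)} for k, v in self.specs.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupPrior":
        return cls({k: PriorSpec(v["family"], tuple(v["hyper"])) for k, v in d.items()})


def default_group_prior(variant: str = "full") -> GroupPrior:
    """Broad, weakly informative group priors respecting each parameter's support.

    Families: beta, s_mu ~ normal; lam, tau0, tau_r ~ lognormal; alpha_I ~
    beta distribution on [0, 1]; alpha_sign ~ Bernoulli on {-1, +1}.
    """
    specs = {
        "beta": PriorSpec("normal", (0.0, 1.0)),
        "s_mu": PriorSpec("normal", (0.0, 0.7)),
        "lam": PriorSpec("lognormal", (np.log(0.5), 0.5)),
        "tau0": PriorSpec("lognormal", (np.log(0.3), 0.6)),
        "tau_r": PriorSpec("lognormal", (np.log(0.5), 0.6)),
    }
    if variant == "full":
        specs["alpha_I"] = PriorSpec("beta", (1.2, 1.2))
        specs["alpha_sign"] = PriorSpec("bernoulli_pm1", (0.5,))
    elif variant == "fixed_sign":
        specs["alpha_I"] = PriorSpec("beta", (1.2, 1.2))
    elif variant != "no_rejection":
        raise ValueError(f"unknown model variant {variant!r}")
    return GroupPrior(specs)
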