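"""Synthetic agent cohorts with controllable metacognition.

A minimal signal-detection-flavoured generative model produces trial tables
with the structure the downstream analyses assume: a guess floor per
answering condition, confidence that tracks trial discriminability on correct
answers and falls with it on errors (the folded X-pattern), and agent groups
whose confidence is either graded (human-like) or compressed near the ceiling
and weakly coupled to accuracy (LLM-like).

Per trial (agent ``i``, item ``j``, condition with guess rate ``g``):

1. ability ``a_i ~ N(ability_mean, ability_sd)``; item difficulty
   ``b_j ~ N(0, difficulty_sd)`` (items shared by all agents);
2. effective discriminability ``d_ij = max(0, a_i - b_j + e1)``,
   ``e1 ~ N(0, trial_noise)``;
3. ``P(correct) = g + (1 - g) * (1 - exp(-accuracy_rate * d_ij))``;
   ``correct ~ Bernoulli``;
4. metacognitive readout ``r_ij = d_ij + e2`` when correct, else
   ``r_ij = error_offset - error_slope * d_ij + e2``,
   ``e2 ~ N(0, meta_noise)``;
5. ``confidence = clip(conf_bias + conf_scale * r_ij, 0, 100)``, optionally
   rounded to integers (default, matching 0-100 ratings).

Step 4 builds the folded-X structure by construction: correct-trial
confidence rises and incorrect-trial confidence falls with ``d``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .trials import DEFAULT_CHANCE_MAP, TrialTable


class ParameterError(ValueError):
    """A generative parameter violates its admissible range."""


@dataclass(frozen=True)
class AgentProfile:
    """Generative parameters of one agent group.

    ``conf_bias`` (B) and ``conf_scale`` (S) map the metacognitive readout to
    the 0-100 rating scale; ``meta_noise`` blurs the readout; ``error_slope``
    (gamma) and ``error_offset`` (d0) shape the incorrect branch of the folded
    X. ``independent_confidence`` severs confidence from the readout entirely
    (uniform ratings), giving a zero-information control group.
    """

    ability_mean: float = 1.0
    ability_sd: float = 0.5
    conf_bias: float = 40.0
    conf_scale: float = 30.0
    meta_noise: float = 0.3
    error_slope: float = 0.5
    error_offset: float = 0.5
    round_to_integers: bool = True
    independent_confidence: bool = False

    def __post_init__(self) -> None:
        for name in ("ability_sd", "conf_scale", "meta_noise"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    def replace(self, **kw) -> "AgentProfile":
        return dataclasses.replace(self, **kw)


#: Named parameter sets covering the qualitative regimes the analyses probe.
#: * ``human_like``  - graded, difficulty-tracking confidence: moderate bias,
#:   large scale, small metacognitive noise.
#: * ``llm_like``    - compressed ceiling confidence, weakly coupled to
#:   accuracy: bias near 90, small scale, large metacognitive noise, higher
#:   ability (the LLM-like group outperforms while over-claiming).
#: * ``oracle``      - zero metacognitive noise and non-overlapping branches
#:   (every incorrect rating sits below every correct one).
#: * ``independent`` - confidence drawn ignoring the readout.
_PRESETS: dict[str, AgentProfile] = {
    "human_like": AgentProfile(
        ability_mean=1.0, ability_sd=0.5, conf_bias=40.0, conf_scale=30.0,
        meta_noise=0.3, error_slope=0.5, error_offset=0.5,
    ),
    "llm_like": AgentProfile(
        ability_mean=2.2, ability_sd=0.3, conf_bias=92.0, conf_scale=4.0,
        meta_noise=1.2, error_slope=0.1, error_offset=0.5,
    ),
    "oracle": AgentProfile(
        ability_mean=1.0, ability_sd=0.5, conf_bias=50.0, conf_scale=25.0,
        meta_noise=0.0, error_slope=0.0, error_offset=-1.0,
    ),
    "independent": AgentProfile(independent_confidence=True),
}


def make_profile(name: str) -> AgentProfile:
    """Return a documented preset :class:`AgentProfile` by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown profile preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass
class SimConfig:
    """Cohort-level generative configuration.

    Defaults mirror the study layout this generator emulates: two agent
    groups of 87 agents, 60 items split evenly over the three answering
    conditions (guess rates 0.5, 0.25, 0).
    """

    n_agents_per_group: int = 87
    n_items_per_condition: int = 20
    chance_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHANCE_MAP))
    difficulty_sd: float = 1.0
    trial_noise: float = 0.5
    accuracy_rate: float = 1.0
    profiles: dict[str, AgentProfile] = field(
        default_factory=lambda: {"human": make_profile("human_like"), "llm": make_profile("llm_like")}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents_per_group < 1 or self.n_items_per_condition < 1:
            raise ParameterError("agent and item counts must be >= 1")
        if self.difficulty_sd < 0 or self.trial_noise < 0:
            raise ParameterError("noise scales must be >= 0")
        if self.accuracy_rate <= 0:
            raise ParameterError("accuracy_rate must be > 0")
        for cond, g in self.chance_map.items():
            if not 0.0 <= g < 1.0:
                raise ParameterError(f"chance level for {cond!r} must lie in [0, 1): {g}")
        if not self.profiles:
            raise ParameterError("at least one agent-group profile is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "profiles" in d:
            profs = {}
            for grp, p in d["profiles"].items():
                if isinstance(p, str):
                    profs[grp] = make_profile(p)
                elif isinstance(p, AgentProfile):
                    profs[grp] = p
                else:
                    profs[grp] = AgentProfile(**p)
            d["profiles"] = profs
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def generate_cohort(config: SimConfig, seed: int | None = None) -> TrialTable:
    """Simulate a full cohort; deterministic given config and seed.

    One root seed sequence is spawned into per-agent streams, so regenerating
    the same config reproduces every agent's trials byte for byte.
    """
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    item_rng = np.random.default_rng(ss.spawn(1)[0])

    conditions = sorted(config.chance_map)
    # Item difficulties are drawn once and shared by every agent in every
    # group, mirroring a fixed question set answered by all participants.
    items: list[tuple[str, str, float]] = []  # (condition, item_id, difficulty)
    for cond in conditions:
        diffs = item_rng.normal(0.0, config.difficulty_sd, size=config.n_items_per_condition)
        for j, b in enumerate(diffs):
            items.append((cond, f"{cond}_{j + 1:03d}", float(b)))

    n_agents_total = config.n_agents_per_group * len(config.profiles)
    agent_seeds = ss.spawn(n_agents_total)

    records: list[tuple] = []
    k = 0
    for group in sorted(config.profiles):
        prof = config.profiles[group]
        for i in range(config.n_agents_per_group):
            rng = np.random.default_rng(agent_seeds[k])
            k += 1
            agent_id = f"{group}_{i + 1:03d}"
            ability = rng.normal(prof.ability_mean, prof.ability_sd)
            for cond, item_id, b in items:
                g = config.chance_map[cond]
                e1 = rng.normal(0.0, config.trial_noise)
                d = max(0.0, ability - b + e1)
                p_correct = g + (1.0 - g) * (1.0 - np.exp(-config.accuracy_rate * d))
                correct = int(rng.random() < p_correct)
                if prof.independent_confidence:
                    conf = rng.uniform(0.0, 100.0)
                else:
                    e2 = rng.normal(0.0, prof.meta_noise)
                    r = d + e2 if correct else prof.error_offset - prof.error_slope * d + e2
                    conf = prof.conf_bias + prof.conf_scale * r
                conf = min(100.0, max(0.0, conf))
                if prof.round_to_integers:
                    conf = float(round(conf))
                records.append((agent_id, group, cond, item_id, correct, conf))

    df = pd.DataFrame.from_records(
        records,
        columns=["agent_id", "agent_group", "condition", "item_id", "correct", "confidence"],
    )
    return TrialTable(df, dict(config.chance_map))
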