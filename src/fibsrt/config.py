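"""Structured YAML configuration for grammars, experiment, learners and RT.

A config file has up to four optional sections; missing keys fall back to
the package defaults (which reproduce the experimental design):

.. code-block:: yaml

    grammar:            # extra grammar definitions, by name
      thue_morse: {alphabet: "01", rules: {"0": "10", "1": "01"}}
    experiment:
      fib_generation: 12
      skip_generation: 4
      block_sizes: [89, 89, 55, 97]
      incongruent_period: 6
      response_deadline: 1000
    learner:
      kind: structural
      learning_rate: 0.02
      anticipation_gain: 70
      k_gain: 40
      first_law_threshold: 0.8
      confidence_threshold: 0.8
    rt:
      base_mean: 505
      subject_sd: 85
      congruency_penalty: 195
      practice_decay: 0.0
      noise_sd: 0.18
      deadline: 1000
      accuracy: {congruent: 0.96, incongruent: 0.70}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .grammar import LSystemGrammar, BUILTIN_GRAMMARS, load_grammar
from .trials import ExperimentConfig
from .cohort import LearnerSpec, RTParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    rt: RTParams = field(default_factory=RTParams)
    grammars: dict[str, LSystemGrammar] = field(
        default_factory=lambda: dict(BUILTIN_GRAMMARS)
    )


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a config file (or defaults) with optional flat overrides.

    ``overrides`` maps ``section.key`` strings to values, mirroring CLI
    flags, and wins over file values.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for dotted, value in (overrides or {}).items():
        section, key = dotted.split(".", 1)
        data.setdefault(section, {})[key] = value

    grammars = dict(BUILTIN_GRAMMARS)
    for name, spec in (data.get("grammar") or {}).items():
        spec = dict(spec)
        spec.setdefault("name", name)
        grammars[name] = load_grammar(spec)

    exp_kwargs = dict(data.get("experiment") or {})
    if "block_sizes" in exp_kwargs:
        exp_kwargs["block_sizes"] = tuple(exp_kwargs["block_sizes"])
    return RunConfig(
        experiment=ExperimentConfig(**exp_kwargs),
        learner=LearnerSpec(**(data.get("learner") or {})),
        rt=RTParams(**(data.get("rt") or {})),
        grammars=grammars,
    )
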