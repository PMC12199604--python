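"""Study configuration: YAML/JSON (de)serialization of CohortConfig.

A config file holds the card sets (per-card P(sun)), trial counts, the
chance-test alpha, randomizer settings, learner parameters, per-group
effects, and the injected-pathology counts. Every field has the default
study value, so an empty config reproduces the default design.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Mapping

import yaml

from . import randomizer as rnd
from .cohort import CohortConfig, GroupEffect, LearnerParams
from .task import CardSet, card_set_from_probs, default_card_set


def config_to_dict(cfg: CohortConfig) -> dict:
    return {
        "n_total": cfg.n_total,
        "group_labels": list(cfg.group_labels),
        "group_effects": {
            g: {
                "delta_mean": e.delta_mean,
                "delta_sd": e.delta_sd,
                "mode": e.mode,
                "decay": e.decay,
                "jitter": e.jitter,
            }
            for g, e in cfg.group_effects.items()
        },
        "learner": asdict(cfg.learner),
        "n_training": cfg.n_training,
        "n_blocks": cfg.n_blocks,
        "n_test": cfg.n_test,
        "alpha": cfg.alpha,
        "card_set_1": list(cfg.card_set_1.p_suns()),
        "card_set_2": list(cfg.card_set_2.p_suns()),
        "n_noncompliant": cfg.n_noncompliant,
        "n_nonlearner": cfg.n_nonlearner,
        "n_reverser": cfg.n_reverser,
        "include_protocol_phases": cfg.include_protocol_phases,
        "randomizer_objective": cfg.randomizer_objective,
        "size_slack": cfg.size_slack,
        "schedule": dict(cfg.schedule),
    }


def config_from_dict(d: Mapping) -> CohortConfig:
    base = CohortConfig()
    labels = tuple(d.get("group_labels", base.group_labels))
    effects = {}
    eff_in = d.get("group_effects")
    if eff_in is None:
        defaults = base.group_effects
        effects = {
            g: defaults.get(g, GroupEffect(g)) for g in labels
        }
    else:
        for g in labels:
            e = eff_in.get(g, {})
            effects[g] = GroupEffect(
                group_label=g,
                delta_mean=float(e.get("delta_mean", 0.0)),
                delta_sd=float(e.get("delta_sd", 0.0)),
                mode=str(e.get("mode", "DIRECT")),
                decay=float(e.get("decay", 1.0)),
                jitter=float(e.get("jitter", 0.0)),
            )
    learner = LearnerParams(**d.get("learner", {}))

    def card_set(key: str, set_id: int) -> CardSet:
        if key in d:
            return card_set_from_probs(d[key], set_id=set_id)
        return default_card_set(set_id)

    return CohortConfig(
        n_total=int(d.get("n_total", base.n_total)),
        group_labels=labels,
        group_effects=effects,
        learner=learner,
        n_training=int(d.get("n_training", base.n_training)),
        n_blocks=int(d.get("n_blocks", base.n_blocks)),
        n_test=int(d.get("n_test", base.n_test)),
        alpha=float(d.get("alpha", base.alpha)),
        card_set_1=card_set("card_set_1", 1),
        card_set_2=card_set("card_set_2", 2),
        n_noncompliant=int(d.get("n_noncompliant", 0)),
        n_nonlearner=int(d.get("n_nonlearner", 0)),
        n_reverser=int(d.get("n_reverser", 0)),
        include_protocol_phases=bool(d.get("include_protocol_phases", True)),
        randomizer_objective=str(d.get("randomizer_objective", rnd.OBJECTIVE_VARIANCE)),
        size_slack=int(d.get("size_slack", 0)),
        schedule=dict(d.get("schedule", base.schedule)),
    )


def load_config(path) -> CohortConfig:
    """Load a YAML (or JSON: YAML is a superset) study config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def save_config(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
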