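"""Canonical network and task-epoch vocabularies.

These name lists are the single source of truth for column ordering
throughout the package.  The 12 functional networks follow the
Cole-Anticevic cortical partition; the 17 task epochs are the first-level
contrasts of the seven HCP-style task paradigms (emotion, gambling,
language, motor, relational, social cognition, working memory).
"""

from __future__ import annotations

#: The 12 canonical functional networks, in fixed display order.
NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMM", "CON", "DAN", "LAN",
    "FPN", "AUD", "DMN", "PMM", "VMM", "ORA",
)

#: The 9 "major" networks used as predictors in the PLS models.
#: ORA, VMM and PMM are excluded for their small size and diffuse,
#: less task-specific activation.
MAJOR_NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMM", "CON", "DAN", "LAN", "FPN", "AUD", "DMN",
)

#: The 17 task epochs (first-level contrasts), in fixed order.
EPOCHS: tuple[str, ...] = (
    "faces", "shapes",            # emotion
    "reward", "punish",           # gambling
    "story", "math",              # language
    "lh", "rh", "lf", "rf", "tongue",   # motor (left/right hand, foot, tongue)
    "rel", "match",               # relational
    "social", "random",           # social cognition
    "0bk", "2bk",                 # working memory
)

#: The 5 motor epochs.  The motor paradigm has no accuracy metric.
MOTOR_EPOCHS: tuple[str, ...] = ("lh", "rh", "lf", "rf", "tongue")

#: The 12 non-motor epochs for which behavioural accuracy exists.
ACCURACY_EPOCHS: tuple[str, ...] = tuple(
    e for e in EPOCHS if e not in MOTOR_EPOCHS
)

#: Epoch roles for the univariate accuracy analyses: "control" conditions
#: versus their matched "task" conditions.
CONTROL_EPOCHS: tuple[str, ...] = ("shapes", "punish", "math", "match", "random", "0bk")
TASK_EPOCHS: tuple[str, ...] = ("faces", "reward", "story", "rel", "social", "2bk")

#: Vertices per hemisphere on the full-resolution symmetric mesh (fs_LR 32k).
FULL_MESH_VERTICES: int = 32492


def validate_epochs(epochs) -> list[str]:
    """Return ``epochs`` as a list, raising if any name is unknown."""
    epochs = list(epochs)
    unknown = [e for e in epochs if e not in EPOCHS]
    if unknown:
        raise ValueError(f"unknown epoch name(s): {unknown}; valid epochs are {list(EPOCHS)}")
    return epochs


def validate_networks(networks) -> list[str]:
    """Return ``networks`` as a list, raising if any label is unknown."""
    networks = list(networks)
    unknown = [k for k in networks if k not in NETWORKS]
    if unknown:
        raise ValueError(
            f"unknown network label(s): {unknown}; valid networks are {list(NETWORKS)}"
        )
    return networks
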