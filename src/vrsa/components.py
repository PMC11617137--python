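"""Hypothesis components for the pattern component model.

Six components describe how condition-to-condition pattern covariance could
arise in the 2x2x2 reach task: three *distance* components (near vs far
hand-target HT, gaze-target ET, and hand-gaze HE separation) and three
*direction* components (left vs right target T, hand H, and gaze E position).
Each is a +/-1 contrast over the 8 conditions; its model second-moment matrix
is the trace-normalized outer product of that contrast.  The six contrasts are
the main effects and two-way interactions of the factorial, so the model
matrices are mutually trace-orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_design import TrialType, enumerate_trial_types

__all__ = [
    "COMPONENT_NAMES",
    "ComponentModel",
    "contrast_vector",
    "model_matrix",
    "component_matrices",
    "build_components",
]

COMPONENT_NAMES = ("HT_dist", "ET_dist", "HE_dist", "T_dir", "H_dir", "E_dir")

_DIRECTION_CODE = {
    "T_dir": lambda t: t.target_side,
    "H_dir": lambda t: t.hand_side,
    "E_dir": lambda t: t.gaze_side,
}
_DISTANCE_CODE = {
    # +1 = near (the two elements share a side), -1 = far.
    "HT_dist": lambda t: t.hand_side * t.target_side,
    "ET_dist": lambda t: t.gaze_side * t.target_side,
    "HE_dist": lambda t: t.hand_side * t.gaze_side,
}


def contrast_vector(name: str, trial_types: list[TrialType] | None = None) -> np.ndarray:
    """Length-8 +/-1 contrast for one component over the canonical conditions.

    Direction components take the side code (left = -1, right = +1) of the
    named element; distance components take the elementwise product of the two
    relevant side codes, so +1 marks near (same side) and -1 far.
    """
    if trial_types is None:
        trial_types = enumerate_trial_types()
    code = _DIRECTION_CODE.get(name) or _DISTANCE_CODE.get(name)
    if code is None:
        raise KeyError(f"unknown component {name!r}; expected one of {COMPONENT_NAMES}")
    return np.array([code(t) for t in trial_types], dtype=float)


@dataclass(frozen=True)
class ComponentModel:
    name: str
    contrast: np.ndarray
    G: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.contrast, dtype=float)
        G = np.outer(c, c)
        object.__setattr__(self, "G", G / np.trace(G))


def model_matrix(component: ComponentModel | str) -> np.ndarray:
    """8x8 model second-moment matrix: rank-1, PSD, trace 1, equal diagonal."""
    if isinstance(component, str):
        component = ComponentModel(component, contrast_vector(component))
    return component.G


def build_components(names=COMPONENT_NAMES) -> list[ComponentModel]:
    return [ComponentModel(n, contrast_vector(n)) for n in names]


def component_matrices(names=COMPONENT_NAMES) -> dict[str, np.ndarray]:
    return {c.name: c.G for c in build_components(names)}
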