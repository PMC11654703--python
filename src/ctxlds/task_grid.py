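"""Task grid: signed coherence levels and the condition table.

The task crosses motion and color evidence: each modality has a set of
signed coherence levels (three strengths in two directions in the original
design, giving 6 levels per modality and K = 36 conditions) and each
condition is one (motion level, color level) pair.  Context 0 is the
attend-motion context, context 1 the attend-color context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGridError

CONTEXT_NAMES = ("motion", "color")


@dataclass(frozen=True)
class TaskGrid:
    """Signed coherence levels per modality and the full condition table."""

    motion_levels: tuple[float, ...]
    color_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        for nm, lv in (("motion", self.motion_levels), ("color", self.color_levels)):
            arr = np.asarray(lv, dtype=float)
            if arr.size == 0 or arr.size % 2:
                raise InvalidGridError(f"{nm} levels must come in +/- pairs")
            if np.any(arr == 0) or len(set(arr.tolist())) != arr.size:
                raise InvalidGridError(f"{nm} levels must be nonzero and distinct")
            s = np.sort(arr)
            if not np.allclose(s, -s[::-1]):
                raise InvalidGridError(f"{nm} levels must be mirrored about 0")

    @property
    def n_levels(self) -> int:
        return len(self.motion_levels)

    @property
    def K(self) -> int:
        return len(self.motion_levels) * len(self.color_levels)

    @property
    def conditions(self) -> list[tuple[int, int]]:
        """All (motion level index, color level index) pairs, motion-major."""
        nc = len(self.color_levels)
        return [(im, ic) for im in range(len(self.motion_levels)) for ic in range(nc)]

    @property
    def motion_index(self) -> np.ndarray:
        """Motion level index of each condition, shape (K,)."""
        return np.repeat(np.arange(len(self.motion_levels)), len(self.color_levels))

    @property
    def color_index(self) -> np.ndarray:
        """Color level index of each condition, shape (K,)."""
        return np.tile(np.arange(len(self.color_levels)), len(self.motion_levels))

    @property
    def contexts(self) -> tuple[str, str]:
        return CONTEXT_NAMES

    def condition_id(self, motion_index: int, color_index: int) -> int:
        return motion_index * len(self.color_levels) + color_index

    def mirror_permutation(self) -> np.ndarray:
        """Condition permutation induced by negating every coherence sign.

        Levels are mirrored about 0, so negation maps level index j to
        n_levels-1-j in the ascending ordering; the permutation maps each
        condition to its sign-flipped counterpart.
        """
        nm, nc = len(self.motion_levels), len(self.color_levels)
        perm = np.empty(self.K, dtype=int)
        for k, (im, ic) in enumerate(self.conditions):
            perm[k] = self.condition_id(nm - 1 - im, nc - 1 - ic)
        return perm

    def to_json(self) -> str:
        return json.dumps(
            {"motion_levels": list(self.motion_levels), "color_levels": list(self.color_levels)}
        )

    @classmethod
    def from_json(cls, text: str) -> "TaskGrid":
        obj = json.loads(text)
        return cls(tuple(obj["motion_levels"]), tuple(obj["color_levels"]))


DEFAULT_STRENGTHS = (0.05, 0.15, 0.5)


def make_task_grid(
    n_strengths: int = 3, strength_values: tuple[float, ...] | None = None
) -> TaskGrid:
    """Build the mirrored coherence grid.

    ``strength_values`` are the positive-direction coherence strengths (one
    per strength level); the grid contains each strength with both signs, so
    a modality has 2*n_strengths levels and the grid K = (2*n_strengths)^2
    conditions.  Defaults to the roughly geometric strength ladder
    (0.05, 0.15, 0.5) used in random-dots tasks of this family.
    """
    if n_strengths < 1:
        raise InvalidGridError("n_strengths must be >= 1")
    if strength_values is None:
        if n_strengths <= len(DEFAULT_STRENGTHS):
            strength_values = DEFAULT_STRENGTHS[-n_strengths:]
        else:
            strength_values = tuple(0.5 * 0.33 ** i for i in range(n_strengths))[::-1]
    strengths = np.asarray(strength_values, dtype=float)
    if strengths.size != n_strengths:
        raise InvalidGridError("strength_values length must equal n_strengths")
    if np.any(strengths <= 0):
        raise InvalidGridError("strength values must be positive (direction is implied)")
    if len(set(strengths.tolist())) != strengths.size:
        raise InvalidGridError("duplicate strength values")
    pos = np.sort(strengths)
    levels = tuple(np.concatenate([-pos[::-1], pos]).tolist())
    return TaskGrid(motion_levels=levels, color_levels=levels)
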