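"""Diffusion-model parameter vector.

The model has condition-specific drift rates and relative starting points
(word vs. nonword stimuli) while boundary separation, nondecision time and
the three across-trial variability parameters are shared across conditions.
The within-trial diffusion coefficient ``s`` is the scaling parameter of the
model and is fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np

from ._exceptions import ParameterError

#: Canonical ordering of the free parameters (used by the fitter and the
#: parametric bootstrap; ``s`` is fixed and therefore not listed).
PARAM_NAMES = (
    "v_word",
    "v_nonword",
    "a",
    "zr_word",
    "zr_nonword",
    "t0",
    "s_v",
    "s_zr",
    "s_t0",
)

CONDITIONS = ("word", "nonword")


@dataclass(frozen=True)
class DiffusionParams:
    """Full parameter vector of the two-condition diffusion model.

    Parameters
    ----------
    v_word, v_nonword
        Mean drift rates (evidence units per second, ``s = 1`` scale).
        The word boundary is the upper boundary, so ``v_word`` is normally
        positive and ``v_nonword`` negative.
    a
        Boundary separation (> 0).
    zr_word, zr_nonword
        Relative starting points in (0, 1); 0.5 means no response bias.
    t0
        Nondecision time in seconds (encoding plus motor execution).
    s_v
        Across-trial drift SD (normal variation).
    s_zr
        Across-trial relative-starting-point range (full width of a
        uniform distribution).
    s_t0
        Across-trial nondecision range in seconds (uniform full width).
    s
        Within-trial diffusion coefficient; fixed at 1.
    """

    v_word: float
    v_nonword: float
    a: float
    zr_word: float
    zr_nonword: float
    t0: float
    s_v: float = 0.0
    s_zr: float = 0.0
    s_t0: float = 0.0
    s: float = 1.0

    def validate(self) -> "DiffusionParams":
        """Raise :class:`ParameterError` unless all invariants hold."""
        if self.s != 1.0:
            raise ParameterError("within-trial diffusion coefficient s must be 1")
        if not self.a > 0:
            raise ParameterError(f"boundary separation must be positive, got {self.a}")
        if not (self.s_v >= 0 and self.s_zr >= 0 and self.s_t0 >= 0):
            raise ParameterError("variability parameters must be non-negative")
        for cond in CONDITIONS:
            zr = self.zr(cond)
            if not (0.0 < zr - self.s_zr / 2 and zr + self.s_zr / 2 < 1.0):
                raise ParameterError(
                    f"starting-point range zr_{cond} ± s_zr/2 must lie inside (0, 1)"
                )
        if self.t0 - self.s_t0 / 2 < 0:
            raise ParameterError("nondecision range t0 ± s_t0/2 must be non-negative")
        return self

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ParameterError:
            return False
        return True

    def v(self, condition: str) -> float:
        """Mean drift rate for a condition."""
        return self.v_word if condition == "word" else self.v_nonword

    def zr(self, condition: str) -> float:
        """Relative starting point for a condition."""
        return self.zr_word if condition == "word" else self.zr_nonword

    def to_array(self) -> np.ndarray:
        """Free parameters in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "DiffusionParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def replace(self, **kwargs) -> "DiffusionParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
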