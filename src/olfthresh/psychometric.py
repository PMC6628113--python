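"""Weibull psychometric model on the Sniffin' Sticks pen scale.

The 16-pen threshold set is a geometric dilution series of 2-phenylethanol:
pen 1 holds the strongest concentration (4% v/v) and each subsequent pen is
diluted by a factor of 2, so pen 16 holds about 1.22e-4%.  Throughout the
package the *pen number* is the stimulus axis: larger pen number means weaker
odor, and a larger threshold (in pen units, often called "T units") means a
more sensitive nose.

The probability of a correct response in the 3-alternative forced-choice
triplet task is modelled by a Weibull-family sigmoid

    psi(x) = lambda*gamma + (1 - lambda) * [1 - (1 - gamma) * exp(-10**(beta*(x + T)))]

with ``x = -pen`` so that psi increases with concentration: ``gamma`` is the
guess rate (1/3 for the triplet task), ``lambda`` the lapse rate, ``beta`` the
slope in inverse pen units and ``T`` the threshold location.  The function
ranges over the open interval (gamma, lambda*gamma + 1 - lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "PenScale",
    "WeibullParams",
    "PEN_SCALE",
    "pen_concentration",
    "p_correct",
    "level_at_p",
    "threshold_offset",
]

# exponent clip: 10**2.8 ~ 631, exp(-631) underflows cleanly to 0.0
_EXP_HI = 2.8
_EXP_LO = -300.0


@dataclass(frozen=True)
class PenScale:
    """The discrete dilution series: pen numbers 1..n_pens.

    ``top_dilution`` is the percent v/v concentration of pen 1 and ``ratio``
    the dilution factor between adjacent pens.
    """

    n_pens: int = 16
    top_dilution: float = 4.0
    ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.n_pens < 1:
            raise DomainError("n_pens must be a positive integer")
        if self.top_dilution <= 0 or self.ratio <= 1:
            raise DomainError("top_dilution must be > 0 and ratio > 1")


PEN_SCALE = PenScale()


def pen_concentration(pen: int, scale: PenScale = PEN_SCALE) -> float:
    """Concentration (percent v/v) of a pen in the dilution series.

    Pen 1 is the strongest; concentration falls geometrically with pen number.
    """
    if not float(pen).is_integer() or not 1 <= int(pen) <= scale.n_pens:
        raise DomainError(
            f"pen must be an integer in [1, {scale.n_pens}], got {pen!r}"
        )
    return scale.top_dilution * scale.ratio ** -(int(pen) - 1)


@dataclass(frozen=True)
class WeibullParams:
    """Parameter bundle for the Weibull psychometric function.

    Parameters
    ----------
    threshold
        Location of the function on the pen axis, in pen units.  If
        ``anchor_p`` is None this is the level at which the exponent term of
        the model equals -1 (about 75% correct for the default shape).  If
        ``anchor_p`` is given, ``threshold`` is instead the level at which the
        function equals ``anchor_p`` — e.g. with ``anchor_p=0.8`` the
        threshold is literally the 80%-correct level, which is the convention
        the adaptive QUEST run uses internally.
    beta
        Slope in inverse pen units.
    guess
        Lower asymptote, the chance level gamma (1/3 for the triplet task).
    lapse
        Lapse rate lambda, capping the upper asymptote at
        ``lapse*guess + 1 - lapse``.
    """

    threshold: float
    beta: float = 3.5
    guess: float = 1.0 / 3.0
    lapse: float = 0.01
    anchor_p: float | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")
        if not 0 <= self.guess < 1:
            raise DomainError(f"guess rate must be in [0, 1), got {self.guess}")
        if not 0 <= self.lapse < 0.5:
            raise DomainError(f"lapse rate must be in [0, 0.5), got {self.lapse}")
        if not math.isfinite(self.threshold):
            raise DomainError("threshold must be finite")
        if self.anchor_p is not None:
            lo, hi = self.p_range
            if not lo < self.anchor_p < hi:
                raise DomainError(
                    f"anchor_p must lie strictly inside ({lo:.6g}, {hi:.6g})"
                )

    @property
    def p_range(self) -> tuple[float, float]:
        """Open interval of attainable response probabilities."""
        return self.guess, self.lapse * self.guess + (1.0 - self.lapse)

    @property
    def location(self) -> float:
        """The pen level where the exponent term equals -1 (psi "midpoint")."""
        if self.anchor_p is None:
            return self.threshold
        return self.threshold + threshold_offset(
            self.anchor_p, self.beta, self.guess, self.lapse
        )


def threshold_offset(p: float, beta: float, guess: float, lapse: float) -> float:
    """Signed pen-unit offset from the psi-midpoint to the level with value ``p``.

    Solves ``10**(beta*d) = -ln[(1 - (p - lapse*guess)/(1 - lapse))/(1 - guess)]``
    for ``d``; positive ``d`` means ``p`` is reached at a *stronger* stimulus
    than the midpoint.
    """
    lo = guess
    hi = lapse * guess + (1.0 - lapse)
    if not lo < p < hi:
        raise DomainError(
            f"target probability must lie strictly inside ({lo:.6g}, {hi:.6g}),"
            f" got {p}"
        )
    inner = (1.0 - (p - lapse * guess) / (1.0 - lapse)) / (1.0 - guess)
    return math.log10(-math.log(inner)) / beta


def _psi(pen, location, beta, guess, lapse):
    """Vectorised Weibull evaluated at pen number(s) for midpoint ``location``."""
    a = np.clip(beta * (np.asarray(location) - np.asarray(pen, dtype=float)),
                _EXP_LO, _EXP_HI)
    with np.errstate(under="ignore"):
        return lapse * guess + (1.0 - lapse) * (
            1.0 - (1.0 - guess) * np.exp(-(10.0 ** a))
        )


def p_correct(pen, params: WeibullParams):
    """Probability of a correct 3-AFC response at a (real-valued) pen level.

    Strictly decreasing in pen number: stronger stimuli (lower pens) are easier.
    Accepts scalars or arrays of pen levels.
    """
    out = _psi(pen, params.location, params.beta, params.guess, params.lapse)
    if np.isscalar(pen) or np.ndim(pen) == 0:
        return float(out)
    return out


def level_at_p(p: float, params: WeibullParams) -> float:
    """Pen level at which ``p_correct`` equals ``p`` (closed-form inverse).

    Raises :class:`DomainError` if ``p`` lies outside the attainable open
    range of the function.
    """
    d = threshold_offset(p, params.beta, params.guess, params.lapse)
    return params.location - d
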