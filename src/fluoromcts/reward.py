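"""Four-component photophysical reward for fluorophore search.

A candidate is scored on its vertical S0→S1 absorption (wavelength ``a_w``,
oscillator strength ``a_i``) and its S1-minimum fluorescence (``f_w``,
``f_i``).  Each wavelength contributes a Gaussian band centred on its target
(width sigma); each oscillator strength contributes a tanh term on the log10
scale relative to its threshold.  The total is the weighted sum

    R = W_aw R_aw + W_ai R_ai + W_fw R_fw + W_fi R_fi,   weights summing to 1,

so R is bounded in [0, 1].  The defaults target near-infrared bioimaging
dyes: absorption at 700 nm, fluorescence at 1200 nm, oscillator-strength
thresholds of 0.01, weights 0.4/0.1/0.4/0.1, sigma 150 nm, floor 1e-8.

Two oscillator-strength variants exist because the squared form rewards
intensities far *below* threshold as much as far above.  ``literal_squared``
(default) applies tanh to the squared log-distance; ``signed_monotone``
clamps tanh of the signed log-distance at zero, making the term
non-decreasing in intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError, InputError

STATUS_OK = "ok"
STATUS_FAILED = "evaluation_failed"

OS_LITERAL_SQUARED = "literal_squared"
OS_SIGNED_MONOTONE = "signed_monotone"


@dataclass(frozen=True)
class PhotophysicalProfile:
    """The quadruple (a_w, a_i, f_w, f_i) plus evaluation status.

    Wavelengths in nm; oscillator strengths dimensionless.  A profile with
    ``status == "evaluation_failed"`` carries no physical values and always
    scores zero.
    """

    a_w: float
    a_i: float
    f_w: float
    f_i: float
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if not (self.a_w > 0 and self.f_w > 0):
                raise InputError("wavelengths must be positive for an ok profile")
            if self.a_i < 0 or self.f_i < 0:
                raise InputError("oscillator strengths must be nonnegative")

    @classmethod
    def failed(cls) -> "PhotophysicalProfile":
        return cls(a_w=float("nan"), a_i=float("nan"), f_w=float("nan"),
                   f_i=float("nan"), status=STATUS_FAILED)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def stokes_shift(self) -> float:
        """Fluorescence minus absorption wavelength, nm."""
        return self.f_w - self.a_w


@dataclass(frozen=True)
class RewardParams:
    """All reward constants; defaults are the near-infrared design targets."""

    t_aw: float = 700.0     # target absorption wavelength, nm
    t_fw: float = 1200.0    # target fluorescence wavelength, nm
    t_ai: float = 0.01      # absorption OS threshold
    t_fi: float = 0.01      # fluorescence OS threshold
    w_aw: float = 0.4
    w_ai: float = 0.1
    w_fw: float = 0.4
    w_fi: float = 0.1
    sigma_a: float = 150.0  # absorption band width, nm
    sigma_f: float = 150.0  # fluorescence band width, nm
    epsilon: float = 1e-8   # log floor for zero oscillator strengths
    os_variant: str = OS_LITERAL_SQUARED

    def __post_init__(self) -> None:
        weights = (self.w_aw, self.w_ai, self.w_fw, self.w_fi)
        if any(w < 0 for w in weights):
            raise ConfigError("reward weights must be nonnegative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigError(f"reward weights must sum to 1, got {sum(weights)}")
        if self.sigma_a <= 0 or self.sigma_f <= 0:
            raise ConfigError("sigmas must be positive")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.os_variant not in (OS_LITERAL_SQUARED, OS_SIGNED_MONOTONE):
            raise ConfigError(f"unknown os_variant {self.os_variant!r}")


def wavelength_reward(x: float, target: float, sigma: float) -> float:
    """Gaussian band reward exp(-(x - target)^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise InputError("sigma must be positive")
    return math.exp(-((x - target) ** 2) / (2.0 * sigma * sigma))


def os_reward(x: float, target: float, epsilon: float,
              variant: str = OS_LITERAL_SQUARED) -> float:
    """Oscillator-strength reward on the log10 scale, bounded in [0, 1)."""
    if x < 0:
        raise InputError("oscillator strength must be nonnegative")
    d = math.log10(x + epsilon) - math.log10(target)
    if variant == OS_LITERAL_SQUARED:
        return math.tanh(d * d)
    if variant == OS_SIGNED_MONOTONE:
        return max(0.0, math.tanh(d))
    raise InputError(f"unknown os_variant {variant!r}")


def total_reward(profile: PhotophysicalProfile, params: RewardParams) -> float:
    """Weighted four-component reward in [0, 1]; failed evaluations score 0."""
    if not profile.ok:
        return 0.0
    return (
        params.w_aw * wavelength_reward(profile.a_w, params.t_aw, params.sigma_a)
        + params.w_ai * os_reward(profile.a_i, params.t_ai, params.epsilon,
                                  params.os_variant)
        + params.w_fw * wavelength_reward(profile.f_w, params.t_fw, params.sigma_f)
        + params.w_fi * os_reward(profile.f_i, params.t_fi, params.epsilon,
                                  params.os_variant)
    )
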