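"""Parameter container for the three-accumulator antisaccade race model.

The model decomposes antisaccade behavior into three single-boundary Wald
(diffusion-to-bound) accumulators: a prepotent process that drives the
reflexive look-toward response, an inhibitory process that can suppress it,
and an executive process that drives the instructed look-away response after
a fixed onset delay.  Prosaccade trials engage only the prepotent process.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the model's constraints."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the antisaccade race model.

    Attributes
    ----------
    v_pre : float
        Drift rate of the prepotent accumulator (evidence units/s, > 0).
    v_inhib : float
        Drift rate of the inhibitory accumulator (> 0).
    v_exec : float
        Drift rate of the executive-control accumulator (> 0).
    a_mean : float
        Mean decision threshold across conditions (evidence units, > 0).
    a_diff : float
        Threshold difference between anti and pro conditions; the effective
        thresholds are ``a_pro = a_mean - a_diff/2`` and
        ``a_anti = a_mean + a_diff/2``.  Zero collapses the two-threshold
        variant onto a single shared threshold.
    t : float
        Non-decision time in seconds (sensory + motor latency, >= 0).
    t_exec : float
        Fixed onset delay of the executive accumulator in seconds (>= 0),
        capturing rule retrieval and saccade-vector inversion.
    """

    v_pre: float
    v_inhib: float
    v_exec: float
    a_mean: float
    a_diff: float = 0.0
    t: float = 0.2
    t_exec: float = 0.1

    def __post_init__(self) -> None:
        for name in ("v_pre", "v_inhib", "v_exec"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not self.a_pro > 0 or not self.a_anti > 0:
            raise InvalidParameterError(
                "effective thresholds a_pro and a_anti must be strictly positive "
                f"(a_mean={self.a_mean}, a_diff={self.a_diff})"
            )
        if self.t < 0:
            raise InvalidParameterError("non-decision time t must be >= 0")
        if self.t_exec < 0:
            raise InvalidParameterError("executive delay t_exec must be >= 0")

    @property
    def a_pro(self) -> float:
        """Effective decision threshold on prosaccade trials."""
        return self.a_mean - self.a_diff / 2.0

    @property
    def a_anti(self) -> float:
        """Effective decision threshold on antisaccade trials."""
        return self.a_mean + self.a_diff / 2.0

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return ModelParams(**kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PARAM_NAMES = tuple(f.name for f in fields(ModelParams))

#: Reference parameter set used throughout the documentation and tests.
REFERENCE_PARAMS = ModelParams(
    v_pre=8.0, v_inhib=4.0, v_exec=6.0, a_mean=1.5, a_diff=0.0, t=0.2, t_exec=0.1
)
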