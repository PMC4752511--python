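"""Generative cohorts for parameter-recovery studies.

Recovery asks whether the fitting machinery can re-identify known
parameters from simulated sessions; subjects are drawn from wide plausible
uniform ranges (spanning the staged cohort's means with margin) rather than
from any particular stage structure, so recovery quality is not an artifact
of a narrow prior.
"""

from __future__ import annotations

import numpy as np

from .data import SubjectData
from .params import ModelParams
from .simulate import simulate_anti, simulate_pro

#: Wide plausible per-parameter ranges for recovery draws.
RECOVERY_RANGES = {
    "v_pre": (3.5, 8.0),
    "v_inhib": (2.5, 9.0),
    "v_exec": (4.5, 10.0),
    "a_mean": (0.7, 1.6),
    "t": (0.10, 0.22),
    "t_exec": (0.02, 0.12),
}


def recovery_cohort(
    n_subjects: int,
    n_pro: int,
    n_anti: int,
    seed: int = 0,
    ranges: dict | None = None,
):
    """Draw ``n_subjects`` parameter sets uniformly and simulate sessions.

    Returns a list of ``(true ModelParams, SubjectData)`` pairs suitable for
    :func:`antirace.fitting.recover_parameters`.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    ranges = {**RECOVERY_RANGES, **(ranges or {})}
    pairs = []
    for i in range(n_subjects):
        kwargs = {p: float(rng.uniform(lo, hi)) for p, (lo, hi) in ranges.items()}
        params = ModelParams(a_diff=0.0, **kwargs)
        pro = simulate_pro(params, n_pro, rng)
        anti_rt, anti_ok = simulate_anti(params, n_anti, rng)
        pairs.append(
            (
                params,
                SubjectData(
                    subject_id=f"rec{i:03d}",
                    pro_rts=pro,
                    anti_rts=anti_rt,
                    anti_correct=anti_ok,
                ),
            )
        )
    return pairs
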