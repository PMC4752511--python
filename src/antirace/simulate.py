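"""Trial simulation for the antisaccade race model.

Race logic on an antisaccade trial: three finishing times are drawn,

    T_pre   = FPT(v_pre, a_anti)
    T_inhib = FPT(v_inhib, a_anti)
    T_exec  = t_exec + FPT(v_exec, a_anti)

An error (reflexive prosaccade toward the target) is committed only when the
prepotent racer beats BOTH the inhibitory and the executive racer; its RT is
``t + T_pre``.  Otherwise the inhibitory process has stopped the prepotent
one (or the executive response simply finished first) and the trial resolves
as a correct antisaccade at ``rt = t + T_exec``.  Requiring the prepotent
racer to beat the executive racer as well prevents arbitrarily slow
inhibition from producing errors later than the already-executed correct
response.  Ties (measure zero for continuous draws) resolve in favor of
inhibition, i.e. a correct response.

Prosaccade trials engage only the prepotent accumulator and are always
correct; prosaccade errors are rare in practice (on the order of 1% of
trials) and the model does not represent them.

Every antisaccade trial consumes exactly six uniforms (two per racer) and
every prosaccade trial exactly two, so simulations at different parameter
settings can be coupled trial-for-trial through common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams
from .wald import UNIFORMS_PER_DRAW, wald_fpt_from_uniforms

UNIFORMS_PER_ANTI_TRIAL = 3 * UNIFORMS_PER_DRAW


@dataclass(frozen=True)
class SimulatedTrial:
    condition: str  # "pro" | "anti"
    outcome: str  # "correct" | "error"
    rt: float  # seconds


def anti_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw the ``(n, 6)`` uniform block underlying n antisaccade trials."""
    return rng.uniform(size=(n, UNIFORMS_PER_ANTI_TRIAL))


def simulate_anti_from_uniforms(params: ModelParams, u: np.ndarray):
    """Resolve antisaccade trials from a fixed uniform block.

    Parameters
    ----------
    u : ndarray of shape (n, 6)
        Columns 0-1 feed the prepotent racer, 2-3 the inhibitory racer,
        4-5 the executive racer.

    Returns
    -------
    rt : ndarray
        Observed RT per trial (seconds, includes non-decision time).
    correct : ndarray of bool
        Trial outcome.
    """
    a = params.a_anti
    t_pre = wald_fpt_from_uniforms(u[:, 0:2], params.v_pre, a)
    t_inhib = wald_fpt_from_uniforms(u[:, 2:4], params.v_inhib, a)
    t_exec = params.t_exec + wald_fpt_from_uniforms(u[:, 4:6], params.v_exec, a)
    error = (t_pre < t_inhib) & (t_pre < t_exec)
    rt = params.t + np.where(error, t_pre, t_exec)
    return rt, ~error


def simulate_anti(params: ModelParams, n: int, rng: np.random.Generator):
    """Simulate ``n`` antisaccade trials; returns ``(rt, correct)`` arrays."""
    if n == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    return simulate_anti_from_uniforms(params, anti_uniforms(rng, n))


def simulate_pro(params: ModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n`` prosaccade RTs (always correct)."""
    if n == 0:
        return np.empty(0)
    u = rng.uniform(size=(n, UNIFORMS_PER_DRAW))
    return params.t + wald_fpt_from_uniforms(u, params.v_pre, params.a_pro)


def simulate_trial(params: ModelParams, condition: str, rng: np.random.Generator) -> SimulatedTrial:
    """Draw one trial of the given condition ("pro" or "anti")."""
    if condition == "pro":
        rt = simulate_pro(params, 1, rng)[0]
        return SimulatedTrial("pro", "correct", float(rt))
    if condition == "anti":
        rt, correct = simulate_anti(params, 1, rng)
        return SimulatedTrial("anti", "correct" if correct[0] else "error", float(rt[0]))
    raise ValueError(f"condition must be 'pro' or 'anti', got {condition!r}")


def simulate_dataset(params: ModelParams, n_pro: int, n_anti: int, seed) -> pd.DataFrame:
    """Simulate a randomly interleaved session of pro- and antisaccade trials.

    Returns a DataFrame with columns ``trial_type`` ("pro"/"anti"),
    ``response`` ("correct"/"error") and ``rt`` (seconds), deterministic for
    a fixed seed.
    """
    if n_pro < 0 or n_anti < 0:
        raise ValueError("trial counts must be >= 0")
    rng = np.random.default_rng(seed)
    pro_rt = simulate_pro(params, n_pro, rng)
    anti_rt, anti_ok = simulate_anti(params, n_anti, rng)
    df = pd.DataFrame(
        {
            "trial_type": ["pro"] * n_pro + ["anti"] * n_anti,
            "response": ["correct"] * n_pro
            + ["correct" if ok else "error" for ok in anti_ok],
            "rt": np.concatenate([pro_rt, anti_rt]),
        }
    )
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)
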