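"""Per-subject maximum-likelihood estimation of the race-model parameters.

The PDA objective is rough at small simulation counts, so local Powell
searches are wrapped in basin-hopping restarts; with the simulation seed
held fixed the objective is deterministic and the whole fit is reproducible.

:class:`RaceModelMLE` is a scikit-learn style estimator (``fit`` on a trial
table or :class:`~antirace.data.SubjectData`, fitted attributes with a
trailing underscore) so fits compose with sklearn tooling; the module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import basinhopping
from sklearn.base import BaseEstimator

from .data import SubjectData
from .likelihood import DEFAULT_N_SIMS, total_loglik
from .params import ModelParams

#: Box bounds for the free parameters.  Drifts and thresholds cover the
#: physiological saccade-RT range with margin; non-decision time spans
#: plausible sensorimotor latencies.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "v_pre": (0.1, 40.0),
    "v_inhib": (0.1, 40.0),
    "v_exec": (0.1, 40.0),
    "a_mean": (0.3, 5.0),
    "a_diff": (-2.5, 2.5),
    "t": (0.05, 0.6),
    "t_exec": (0.0, 0.6),
}

_PENALTY = 1e10
MIN_TRIALS = 20  # per condition; below this the fit proceeds but is flagged


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    params_hat: ModelParams
    loglik: float
    n_sims: int
    seed: int
    n_hops: int
    n_evals: int
    converged: bool
    low_data: bool = False
    subject_id: str | None = None


class RaceModelMLE(BaseEstimator):
    """Maximum-likelihood race-model fit for a single subject.

    Parameters
    ----------
    n_sims : int
        Antisaccade simulations per objective evaluation (the PDA sample).
    n_hops : int
        Basin-hopping restarts around the Powell local searches.
    seed : int
        Seeds both the fixed PDA simulation stream and the hop proposals.
    fit_a_diff : bool
        Free the anti-vs-pro threshold difference (otherwise fixed at 0,
        the single-threshold variant).
    fit_t_exec : bool
        Free the executive onset delay (otherwise fixed at 0).
    bounds : dict or None
        Override entries of :data:`DEFAULT_BOUNDS`.
    step_frac : float
        Hop proposal scale as a fraction of each bound range.
    xtol, ftol : float
        Powell convergence tolerances; loose values suit the KDE-rough
        objective surface.
    """

    def __init__(
        self,
        n_sims: int = DEFAULT_N_SIMS,
        n_hops: int = 5,
        seed: int = 0,
        fit_a_diff: bool = False,
        fit_t_exec: bool = True,
        bounds: dict | None = None,
        step_frac: float = 0.25,
        xtol: float = 1e-3,
        ftol: float = 1e-3,
    ):
        self.n_sims = n_sims
        self.n_hops = n_hops
        self.seed = seed
        self.fit_a_diff = fit_a_diff
        self.fit_t_exec = fit_t_exec
        self.bounds = bounds
        self.step_frac = step_frac
        self.xtol = xtol
        self.ftol = ftol

    # -- parameter vector <-> ModelParams ---------------------------------
    @property
    def free_names_(self) -> list[str]:
        names = ["v_pre", "v_inhib", "v_exec", "a_mean", "t"]
        if self.fit_t_exec:
            names.append("t_exec")
        if self.fit_a_diff:
            names.append("a_diff")
        return names

    def _bounds(self) -> dict[str, tuple[float, float]]:
        b = dict(DEFAULT_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        return b

    def _to_params(self, x: np.ndarray) -> ModelParams | None:
        kwargs = dict(zip(self.free_names_, x))
        kwargs.setdefault("t_exec", 0.0)
        kwargs.setdefault("a_diff", 0.0)
        if abs(kwargs["a_diff"]) > kwargs["a_mean"] / 2.0:
            return None
        try:
            return ModelParams(**kwargs)
        except ValueError:
            return None

    # -- fitting -----------------------------------------------------------
    def _initial_point(self, subject: SubjectData, bounds) -> np.ndarray:
        """Moment-matching start from the prosaccade marginal.

        mean decision time d = a/v and variance s^2 = a/v^3 give
        v = sqrt(d/s^2), a = v*d.
        """
        if len(subject.pro_rts) >= 2:
            t0 = 0.9 * float(np.min(subject.pro_rts))
            d = max(float(np.mean(subject.pro_rts)) - t0, 1e-3)
            s2 = max(float(np.var(subject.pro_rts, ddof=1)), 1e-6)
            v0 = float(np.sqrt(d / s2))
            a0 = v0 * d
        else:
            t0, v0, a0 = 0.2, 8.0, 1.5
        start = {
            "v_pre": v0,
            "v_inhib": v0,
            "v_exec": v0,
            "a_mean": a0,
            "t": t0,
            "t_exec": 0.05,
            "a_diff": 0.0,
        }
        x0 = []
        for name in self.free_names_:
            lo, hi = bounds[name]
            margin = 0.01 * (hi - lo)
            x0.append(float(np.clip(start[name], lo + margin, hi - margin)))
        return np.asarray(x0)

    def fit(self, X, y=None) -> "RaceModelMLE":
        """Fit to a trial table (trial_type/response/rt) or SubjectData."""
        subject = X if isinstance(X, SubjectData) else SubjectData.from_trials(X)
        low_data = len(subject.pro_rts) < MIN_TRIALS or len(subject.anti_rts) < MIN_TRIALS
        if low_data:
            warnings.warn(
                f"subject {subject.subject_id}: fewer than {MIN_TRIALS} trials in a "
                "condition; estimates will be noisy",
                stacklevel=2,
            )
        bounds = self._bounds()
        names = self.free_names_
        box = [bounds[n] for n in names]
        n_evals = 0

        best_valid = {"f": np.inf, "x": None}

        def objective(x: np.ndarray) -> float:
            nonlocal n_evals
            n_evals += 1
            params = self._to_params(x)
            if params is None:
                return _PENALTY
            f = -total_loglik(params, subject, n_sims=self.n_sims, seed=self.seed)
            if f < best_valid["f"]:
                best_valid["f"] = f
                best_valid["x"] = np.array(x, dtype=float)
            return f

        x0 = self._initial_point(subject, bounds)
        if objective(x0) >= _PENALTY:
            raise RuntimeError("no valid starting point within bounds")

        rng = np.random.default_rng(self.seed)
        ranges = np.array([hi - lo for lo, hi in box])
        lows = np.array([lo for lo, _ in box])
        highs = np.array([hi for _, hi in box])

        def take_step(x):
            step = rng.uniform(-1.0, 1.0, size=len(x)) * self.step_frac * ranges
            return np.clip(x + step, lows, highs)

        result = basinhopping(
            objective,
            x0,
            niter=self.n_hops,
            take_step=take_step,
            minimizer_kwargs={
                "method": "Powell",
                "bounds": box,
                "options": {"xtol": self.xtol, "ftol": self.ftol},
            },
            seed=int(rng.integers(2**31 - 1)),
        )
        # the best *valid* evaluation is authoritative: hop proposals can
        # stray into the relative a_diff constraint where the objective is
        # a penalty plateau
        best = np.clip(best_valid["x"], lows, highs)
        params_hat = self._to_params(best)
        if params_hat is None:  # pragma: no cover - best_valid was evaluated
            raise RuntimeError("optimizer returned an invalid point")
        self.params_ = params_hat
        self.loglik_ = -float(best_valid["f"])
        self.n_evals_ = n_evals
        self.converged_ = bool(result.lowest_optimization_result.success)
        self.result_ = FitResult(
            params_hat=params_hat,
            loglik=self.loglik_,
            n_sims=self.n_sims,
            seed=self.seed,
            n_hops=self.n_hops,
            n_evals=n_evals,
            converged=self.converged_,
            low_data=low_data,
            subject_id=subject.subject_id,
        )
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of a trial table under the fitted parameters."""
        subject = X if isinstance(X, SubjectData) else SubjectData.from_trials(X)
        return total_loglik(self.params_, subject, n_sims=self.n_sims, seed=self.seed)


def fit_subject(subject: SubjectData, config: RaceModelMLE | dict | None = None) -> FitResult:
    """Fit one subject and return the :class:`FitResult`."""
    if isinstance(config, RaceModelMLE):
        est = config
    else:
        est = RaceModelMLE(**(config or {}))
    return est.fit(subject).result_


# -- model comparison ------------------------------------------------------

def aic(k: int, loglik: float) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    return 2.0 * k - 2.0 * loglik


def compare_models(subject: SubjectData, configs) -> pd.DataFrame:
    """Fit each model variant and tabulate AIC, sorted ascending.

    ``configs`` is an iterable of ``(name, RaceModelMLE-or-kwargs)``; the
    number of free parameters of each variant sets k.
    """
    rows = []
    for name, cfg in configs:
        est = cfg if isinstance(cfg, RaceModelMLE) else RaceModelMLE(**cfg)
        res = est.fit(subject).result_
        k = len(est.free_names_)
        rows.append({"variant": name, "k": k, "loglik": res.loglik, "aic": aic(k, res.loglik)})
    return pd.DataFrame(rows).sort_values("aic", ignore_index=True)


# -- parameter recovery ----------------------------------------------------

@dataclass
class RecoveryReport:
    """True-vs-estimated comparison over a simulated cohort."""

    table: pd.DataFrame  # one row per subject; true_<p> and est_<p> columns
    correlations: dict = field(default_factory=dict)  # param -> r or None
    bias: dict = field(default_factory=dict)  # param -> mean(est - true)
    n_subjects: int = 0
    trials_per_subject: tuple[int, int] = (0, 0)


def recover_parameters(cohort, config: RaceModelMLE | dict | None = None) -> RecoveryReport:
    """Simulate -> fit -> tabulate parameter recovery.

    ``cohort`` is either a :class:`~antirace.cohort.SyntheticCohort` or an
    iterable of ``(ModelParams, SubjectData)`` pairs.  Per-subject fit
    failures are recorded (NaN estimates) without aborting the batch.
    A parameter with zero between-subject variance has an undefined
    correlation, reported as None.
    """
    pairs = cohort.truth_pairs() if hasattr(cohort, "truth_pairs") else list(cohort)
    if len(pairs) < 1:
        raise ValueError("need at least one subject to run recovery")
    base = config if isinstance(config, RaceModelMLE) else RaceModelMLE(**(config or {}))
    param_names = list(base.free_names_)
    rows = []
    n_pro = n_anti = 0
    for i, (true_params, subject) in enumerate(pairs):
        n_pro, n_anti = len(subject.pro_rts), len(subject.anti_rts)
        row = {"subject_id": subject.subject_id or f"s{i}"}
        for p in param_names:
            row[f"true_{p}"] = getattr(true_params, p)
        est = RaceModelMLE(**base.get_params())
        try:
            res = est.fit(subject).result_
            for p in param_names:
                row[f"est_{p}"] = getattr(res.params_hat, p)
            row["loglik"] = res.loglik
            row["converged"] = res.converged
        except Exception as exc:  # keep the batch alive
            warnings.warn(f"fit failed for subject {row['subject_id']}: {exc}", stacklevel=2)
            for p in param_names:
                row[f"est_{p}"] = np.nan
            row["loglik"] = np.nan
            row["converged"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    correlations: dict = {}
    bias: dict = {}
    for p in param_names:
        truth = table[f"true_{p}"].to_numpy()
        est_v = table[f"est_{p}"].to_numpy()
        ok = np.isfinite(est_v)
        bias[p] = float(np.mean(est_v[ok] - truth[ok])) if ok.any() else None
        if ok.sum() >= 2 and np.ptp(truth[ok]) > 0 and np.ptp(est_v[ok]) > 0:
            correlations[p] = float(np.corrcoef(truth[ok], est_v[ok])[0, 1])
        else:
            correlations[p] = None
    return RecoveryReport(
        table=table,
        correlations=correlations,
        bias=bias,
        n_subjects=len(pairs),
        trials_per_subject=(n_pro, n_anti),
    )
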