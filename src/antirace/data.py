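"""In-memory containers for per-subject behavioral observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_TYPES = ("pro", "anti")
RESPONSES = ("correct", "error")


@dataclass
class SubjectData:
    """Observed trials for one subject.

    RTs are in seconds.  ``anti_correct`` flags each antisaccade trial's
    outcome, aligned with ``anti_rts``.
    """

    subject_id: str
    pro_rts: np.ndarray
    anti_rts: np.ndarray
    anti_correct: np.ndarray
    stage: int | None = None
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pro_rts = np.asarray(self.pro_rts, dtype=float)
        self.anti_rts = np.asarray(self.anti_rts, dtype=float)
        self.anti_correct = np.asarray(self.anti_correct, dtype=bool)
        if len(self.anti_rts) != len(self.anti_correct):
            raise ValueError("anti_rts and anti_correct must be aligned")
        if np.any(self.pro_rts <= 0) or np.any(self.anti_rts <= 0):
            raise ValueError("all RTs must be strictly positive")

    @property
    def n_trials(self) -> int:
        return len(self.pro_rts) + len(self.anti_rts)

    @property
    def anti_correct_rts(self) -> np.ndarray:
        return self.anti_rts[self.anti_correct]

    @property
    def anti_error_rts(self) -> np.ndarray:
        return self.anti_rts[~self.anti_correct]

    @classmethod
    def from_trials(
        cls,
        df: pd.DataFrame,
        subject_id: str = "s0",
        stage: int | None = None,
        clinical: dict | None = None,
    ) -> "SubjectData":
        """Build from a trial table with columns trial_type/response/rt."""
        pro = df[df["trial_type"] == "pro"]
        anti = df[df["trial_type"] == "anti"]
        return cls(
            subject_id=subject_id,
            pro_rts=pro["rt"].to_numpy(),
            anti_rts=anti["rt"].to_numpy(),
            anti_correct=(anti["response"] == "correct").to_numpy(),
            stage=stage,
            clinical=dict(clinical or {}),
        )

    def to_trials(self) -> pd.DataFrame:
        """Flatten back to a trial table (pro trials first, then anti)."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial_type": ["pro"] * len(self.pro_rts) + ["anti"] * len(self.anti_rts),
                "response": ["correct"] * len(self.pro_rts)
                + ["correct" if ok else "error" for ok in self.anti_correct],
                "rt": np.concatenate([self.pro_rts, self.anti_rts]),
            }
        )
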