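"""Delimited-text file formats and run configuration.

Trial tables are UTF-8 comma-separated files with a required header:
``subject_id, stage_label, trial_type, response, rt_seconds`` (RTs in
seconds as decimals).  Lines starting with ``#`` are provenance comments:
every artifact written by the pipeline embeds the run seed and a hash of
the configuration so any number in any report can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RESPONSES, TRIAL_TYPES, SubjectData

TRIAL_COLUMNS = ("subject_id", "trial_type", "response", "rt_seconds")


class TrialFormatError(ValueError):
    """Malformed trial table (missing columns or invalid rows)."""


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed, config: dict | None = None) -> str:
    h = config_hash(config or {})
    return f"# antirace seed={seed} config_hash={h}\n"


def write_table(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write a CSV with a provenance comment line when a seed is given."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(provenance_header(seed, config))
        df.to_csv(fh, index=False)


def write_trials(subjects, path, seed=None, config: dict | None = None) -> None:
    """Write SubjectData records (or a prepared trial table) to CSV."""
    if isinstance(subjects, pd.DataFrame):
        df = subjects
    else:
        frames = []
        for s in subjects:
            t = s.to_trials().rename(columns={"rt": "rt_seconds"})
            t.insert(1, "stage_label", s.stage)
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
    write_table(df, path, seed=seed, config=config)


def _data_line_numbers(path: Path) -> np.ndarray:
    """1-based file line number of each data row (skipping comments+header)."""
    numbers = []
    seen_header = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.lstrip().startswith("#") or not line.strip():
                continue
            if not seen_header:
                seen_header = True
                continue
            numbers.append(lineno)
    return np.asarray(numbers)


def read_trials(path) -> list[SubjectData]:
    """Read and validate a trial table; returns one SubjectData per subject.

    Validation failures cite the 1-based line number of the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required column(s) {missing}")
    lines = _data_line_numbers(path)
    bad_type = ~df["trial_type"].isin(TRIAL_TYPES)
    if bad_type.any():
        ln = lines[int(np.flatnonzero(bad_type)[0])]
        raise TrialFormatError(f"{path}: line {ln}: trial_type must be one of {TRIAL_TYPES}")
    bad_resp = ~df["response"].isin(RESPONSES)
    if bad_resp.any():
        ln = lines[int(np.flatnonzero(bad_resp)[0])]
        raise TrialFormatError(f"{path}: line {ln}: response must be one of {RESPONSES}")
    rt = pd.to_numeric(df["rt_seconds"], errors="coerce")
    bad_rt = ~(rt > 0)
    if bad_rt.any():
        ln = lines[int(np.flatnonzero(bad_rt)[0])]
        raise TrialFormatError(f"{path}: line {ln}: rt_seconds must be a positive number")
    df["rt_seconds"] = rt
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        stage = None
        if "stage_label" in grp.columns and grp["stage_label"].notna().all():
            stage = int(grp["stage_label"].iloc[0])
        pro = grp[grp["trial_type"] == "pro"]
        anti = grp[grp["trial_type"] == "anti"]
        subjects.append(
            SubjectData(
                subject_id=str(sid),
                pro_rts=pro["rt_seconds"].to_numpy(),
                anti_rts=anti["rt_seconds"].to_numpy(),
                anti_correct=(anti["response"] == "correct").to_numpy(),
                stage=stage,
            )
        )
    return subjects


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path) -> dict:
    """Load the YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
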