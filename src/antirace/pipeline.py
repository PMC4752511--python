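"""Glue between the pipeline stages: batch fitting, feature assembly and
label construction for the group contrasts of interest."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .behavior import summary_stats
from .classify import FeatureSet
from .fitting import RaceModelMLE
from .params import PARAM_NAMES

log = logging.getLogger("antirace")

SUMMARY_FEATURES = (
    "pro_rt_mean",
    "pro_rt_sd",
    "anti_correct_rt_mean",
    "anti_correct_rt_sd",
    "anti_accuracy",
)


def fit_cohort(subjects, config: RaceModelMLE | dict | None = None) -> pd.DataFrame:
    """Fit every subject; one row per subject with fitted parameters.

    Also tabulates the behavioral summary statistics and any clinical
    scores carried on the subjects, so the result is directly usable as a
    feature table.
    """
    base = config if isinstance(config, RaceModelMLE) else RaceModelMLE(**(config or {}))
    rows = []
    for i, s in enumerate(subjects):
        est = RaceModelMLE(**base.get_params())
        res = est.fit(s).result_
        row = {"subject_id": s.subject_id, "stage": s.stage, "loglik": res.loglik}
        for p in PARAM_NAMES:
            row[p] = getattr(res.params_hat, p)
        ss = summary_stats(s)
        for f in SUMMARY_FEATURES:
            row[f] = getattr(ss, f)
        row.update(s.clinical)
        rows.append(row)
        log.debug("fit %s (%d/%d): loglik=%.1f", s.subject_id, i + 1, len(subjects), res.loglik)
    return pd.DataFrame(rows)


def contrast_labels(table: pd.DataFrame, contrast: str) -> pd.Series:
    """Binary labels for a named group contrast on the ``stage`` column.

    Contrasts: ``control_vs_prehd`` (0 vs 1+2), ``control_vs_prehd_a``
    (0 vs 1), ``control_vs_prehd_b`` (0 vs 2), ``prehd_a_vs_b`` (1 vs 2),
    ``control_vs_hd`` (0 vs 3+4).  Rows outside the contrast get NaN.
    """
    mapping = {
        "control_vs_prehd": ({0: 0, 1: 1, 2: 1}),
        "control_vs_prehd_a": ({0: 0, 1: 1}),
        "control_vs_prehd_b": ({0: 0, 2: 1}),
        "prehd_a_vs_b": ({1: 0, 2: 1}),
        "control_vs_hd": ({0: 0, 3: 1, 4: 1}),
    }
    if contrast not in mapping:
        raise ValueError(f"unknown contrast {contrast!r}")
    return table["stage"].map(mapping[contrast])


def build_feature_sets(table: pd.DataFrame, contrast: str) -> dict[str, FeatureSet]:
    """Assemble the standard feature sets for a binary contrast.

    ``summary`` = behavioral summary statistics; ``all_params`` = the fitted
    model parameters; ``v_exec`` = the executive drift alone; ``uhdrs`` =
    TMS + TFC; ``v_exec+uhdrs`` = their combination.  Sets that need
    clinical scores are skipped when the table lacks them.
    """
    labels = contrast_labels(table, contrast)
    keep = labels.notna()
    sub = table.loc[keep].reset_index(drop=True)
    y = labels.loc[keep].astype(int).to_numpy()
    ids = sub["subject_id"].to_numpy()
    free_params = [p for p in PARAM_NAMES if p != "a_diff" or sub["a_diff"].nunique() > 1]
    sets = {
        "summary": FeatureSet("summary", sub[list(SUMMARY_FEATURES)], y, ids),
        "all_params": FeatureSet("all_params", sub[free_params], y, ids),
        "v_exec": FeatureSet("v_exec", sub[["v_exec"]], y, ids),
    }
    if {"tms", "tfc"}.issubset(sub.columns):
        sets["uhdrs"] = FeatureSet("uhdrs", sub[["tms", "tfc"]], y, ids)
        sets["v_exec+uhdrs"] = FeatureSet("v_exec+uhdrs", sub[["v_exec", "tms", "tfc"]], y, ids)
    return sets


def multiclass_features(table: pd.DataFrame, grouping: str = "coarse"):
    """Feature set for multiclass staging from the fitted parameters.

    ``grouping='coarse'`` folds the five stages into control / pre-manifest
    / manifest (the three-class problem); ``'fine'`` keeps all five stages.
    """
    if grouping == "coarse":
        y = table["stage"].map({0: 0, 1: 1, 2: 1, 3: 2, 4: 2}).to_numpy()
    elif grouping == "fine":
        y = table["stage"].to_numpy()
    else:
        raise ValueError("grouping must be 'coarse' or 'fine'")
    free_params = [p for p in PARAM_NAMES if p != "a_diff" or table["a_diff"].nunique() > 1]
    return FeatureSet("all_params", table[free_params].reset_index(drop=True), y,
                      table["subject_id"].to_numpy())
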