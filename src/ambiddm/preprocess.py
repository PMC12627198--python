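"""Exclusion cascade and eligibility reporting.

Three criteria, applied per participant:

* two or more catch-trial errors -> excluded from everything;
* 10% or more RT-outlier trials (RT < 300 ms or > 10 s) -> excluded from the
  DDM analyses;
* 100 or more preference switches over the task -> excluded from the DDM
  analyses.

Boundary conventions follow the wording literally: the RT cuts are strict
("shorter than" / "longer than"), the count/fraction cuts are inclusive
("or more").  Outlier trials are additionally dropped from all likelihoods
for participants who remain included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RT_LOW = 0.3
RT_HIGH = 10.0
MAX_CATCH_ERRORS = 2       # >= 2 excludes
MAX_OUTLIER_FRAC = 0.10    # >= 10% excludes from DDM
MAX_SWITCHES = 100         # >= 100 excludes from DDM

REPORT_COLUMNS = ["participant", "n_catch_errors", "pct_outlier_trials",
                  "n_switches_total", "included_glmm", "included_ddm"]


def flag_outlier_trials(behavior: pd.DataFrame) -> pd.DataFrame:
    """(Re)set the is_rt_outlier flag from the recorded RTs."""
    if (behavior["rt"] <= 0).any():
        raise ValueError("all RTs must be positive")
    out = behavior.copy()
    out["is_rt_outlier"] = (out["rt"] < RT_LOW) | (out["rt"] > RT_HIGH)
    return out


def apply_exclusions(behavior: pd.DataFrame,
                     include_catch_in_outlier_frac: bool = True) -> pd.DataFrame:
    """Per-participant eligibility report.

    The outlier fraction is computed over all trials including catch trials
    by default (configurable).  A participant without catch trials makes the
    attention criterion unevaluable and raises.
    """
    behavior = flag_outlier_trials(behavior)
    rows = []
    for pid, g in behavior.groupby("participant", sort=True):
        catch = g[g["kind"] == "catch"]
        if len(catch) == 0:
            raise ValueError(f"participant {pid} has no catch trials; "
                             "attention criterion unevaluable")
        n_catch_err = int((catch["choice"] == "variable").sum())
        denom = g if include_catch_in_outlier_frac else g[g["kind"] != "catch"]
        pct_out = float(denom["is_rt_outlier"].mean())
        n_sw = int(g["n_switches"].sum())
        inc_glmm = n_catch_err < MAX_CATCH_ERRORS
        inc_ddm = (inc_glmm and pct_out < MAX_OUTLIER_FRAC
                   and n_sw < MAX_SWITCHES)
        rows.append(dict(participant=pid, n_catch_errors=n_catch_err,
                         pct_outlier_trials=pct_out, n_switches_total=n_sw,
                         included_glmm=inc_glmm, included_ddm=inc_ddm))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def filter_for_ddm(behavior: pd.DataFrame,
                   report: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trials entering the DDM likelihoods: DDM-eligible participants only,
    catch trials and outlier-flagged trials dropped."""
    if report is None:
        report = apply_exclusions(behavior)
    behavior = flag_outlier_trials(behavior)
    keep = set(report.loc[report["included_ddm"], "participant"])
    mask = (behavior["participant"].isin(keep)
            & (behavior["kind"] != "catch")
            & ~behavior["is_rt_outlier"])
    return behavior[mask].reset_index(drop=True)


def exclusion_summary(report: pd.DataFrame) -> dict:
    """Per-criterion counts for the summary JSON."""
    n = len(report)
    return {
        "n_participants": int(n),
        "n_failed_catch": int((report["n_catch_errors"] >= MAX_CATCH_ERRORS).sum()),
        "n_failed_outliers": int((report["pct_outlier_trials"] >= MAX_OUTLIER_FRAC).sum()),
        "n_failed_switches": int((report["n_switches_total"] >= MAX_SWITCHES).sum()),
        "n_included_glmm": int(report["included_glmm"].sum()),
        "n_included_ddm": int(report["included_ddm"].sum()),
    }
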