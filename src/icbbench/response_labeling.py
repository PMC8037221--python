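"""Responder / non-responder classification from RECIST categories.

Four strategies are supported, differing only in how stable disease (SD)
is handled:

* ``PD``  — CR/PR/SD are responders; PD is the non-responder class.
* ``OR``  — objective response: CR/PR responders; SD/PD non-responders.
* ``OS``  — CR/PR responders; SD responders iff overall survival exceeds
  one year; PD non-responders.
* ``DCB`` — durable clinical benefit: CR/PR responders; SD responders iff
  progression-free survival exceeds six months; PD non-responders.

Thresholds are strict (>): SD at exactly one year of OS, or exactly six
months of PFS, is a non-responder.  Samples without a RECIST category are
unevaluable everywhere; SD samples missing the required survival time
under OS/DCB are unevaluable too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRATEGIES = ("PD", "OR", "OS", "DCB")

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNEVALUABLE = "unevaluable"

#: default calendar conversions, in days
DAYS_PER_YEAR = 365.25
DAYS_PER_6MO = 182.625


class DataError(ValueError):
    pass


def assign_labels(
    clinical: pd.DataFrame,
    strategy: str,
    time_units_per_year: float = DAYS_PER_YEAR,
    time_units_per_6mo: float = DAYS_PER_6MO,
) -> pd.Series:
    """Label every sample responder / non_responder / unevaluable."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    labels = {}
    for sample_id, row in clinical.iterrows():
        recist = row["recist"]
        if recist == "missing":
            labels[sample_id] = UNEVALUABLE
            continue
        if recist not in ("CR", "PR", "SD", "PD"):
            raise DataError(f"unknown RECIST token {recist!r} for sample {sample_id!r}")
        if recist in ("CR", "PR"):
            labels[sample_id] = RESPONDER
        elif recist == "PD":
            labels[sample_id] = NON_RESPONDER
        else:  # SD
            if strategy == "PD":
                labels[sample_id] = RESPONDER
            elif strategy == "OR":
                labels[sample_id] = NON_RESPONDER
            elif strategy == "OS":
                labels[sample_id] = _gate(row["os_time"], time_units_per_year)
            else:  # DCB
                labels[sample_id] = _gate(row["pfs_time"], time_units_per_6mo)
    return pd.Series(labels, name=f"label_{strategy}")


def _gate(time, threshold) -> str:
    if time is None or (isinstance(time, float) and np.isnan(time)):
        return UNEVALUABLE
    return RESPONDER if time > threshold else NON_RESPONDER


def objective_response_rate(clinical: pd.DataFrame) -> float:
    """ORR = (CR + PR) / evaluable patients; missing RECIST excluded."""
    recist = clinical["recist"]
    evaluable = recist.isin(["CR", "PR", "SD", "PD"])
    n = int(evaluable.sum())
    if n == 0:
        raise DataError("no sample has a RECIST category; ORR undefined")
    return float(recist.isin(["CR", "PR"]).sum()) / n


def labels_to_binary(labels: pd.Series) -> pd.Series:
    """Evaluable labels as 1 (responder) / 0 (non-responder); drops the rest."""
    keep = labels.isin([RESPONDER, NON_RESPONDER])
    return (labels[keep] == RESPONDER).astype(int)


def write_labels(labels: pd.Series, strategy: str, path) -> None:
    out = pd.DataFrame({
        "sample_id": labels.index,
        "strategy": strategy,
        "label": labels.values,
    })
    out.to_csv(path, sep="\t", index=False)
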