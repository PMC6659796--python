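"""LC50 estimation from viability curves and between-cluster comparison.

LC50 is obtained by linear interpolation between the two adjacent
concentrations bracketing the 50% viability crossing:

    LC50 = (V_above - 50) / (V_above - V_below) * (c_below - c_above) + c_above

where V_above > 50 is the viability at the lower concentration c_above and
V_below < 50 at the next concentration c_below.  Curves that never cross
50% are censored at the grid boundary.  Cluster comparison uses the median
fold and a two-sided Mann-Whitney U test on the LC50 distributions.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DoseResponseRecord,
    DoseResponseSet,
    LC50Result,
    TestResult,
    ValidationError,
    as_group_series,
)
from .outcomes import mann_whitney_u

log = logging.getLogger(__name__)


def compute_lc50(record: DoseResponseRecord) -> LC50Result:
    """LC50 of one viability curve by bracketing linear interpolation.

    Scanning in ascending concentration: a viability of exactly 50% at a
    grid point returns that concentration (``exact_50``); otherwise the
    first adjacent pair crossing from above to below 50% is interpolated.
    A curve starting below 50% is ``censored_below_min``; one never dipping
    below 50% is ``censored_above_max`` (LC50 beyond the highest tested
    concentration).
    """
    conc = record.concentrations
    viab = record.viability_pct
    if len(conc) < 2:
        raise ValidationError(
            f"need at least 2 concentrations for {record.sample}/{record.drug}"
        )
    common = dict(sample=record.sample, drug=record.drug,
                  conc_min=float(conc[0]), conc_max=float(conc[-1]))
    if viab[0] < 50.0:
        return LC50Result(lc50=float(conc[0]), status="censored_below_min", **common)
    for i in range(len(conc)):
        if viab[i] == 50.0:
            return LC50Result(lc50=float(conc[i]), status="exact_50", **common)
        if i + 1 < len(conc) and viab[i] > 50.0 and viab[i + 1] < 50.0:
            v_above, v_below = viab[i], viab[i + 1]
            c_above, c_below = conc[i], conc[i + 1]
            lc50 = (v_above - 50.0) / (v_above - v_below) * (c_below - c_above) + c_above
            return LC50Result(
                lc50=float(lc50), status="interpolated",
                bracket=(float(c_above), float(c_below)), **common,
            )
    return LC50Result(lc50=float(conc[-1]), status="censored_above_max", **common)


def compute_all_lc50(drset: DoseResponseSet) -> list[LC50Result]:
    return [compute_lc50(rec) for rec in drset.records]


def lc50_table(results: Sequence[LC50Result]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "drug": [r.drug for r in results],
            "lc50": [r.lc50 for r in results],
            "status": [r.status for r in results],
        }
    )


def compare_lc50(
    results: Sequence[LC50Result],
    labels: Mapping[str, int] | pd.Series,
    include_censored_in_test: bool = True,
    include_censored_in_median: bool = False,
) -> dict[str, dict]:
    """Per-drug cluster comparison of LC50 distributions.

    Fold = median(cluster-2) / median(cluster-1).  By default censored
    curves enter the Mann-Whitney test at their boundary concentration
    (ties at the grid edge) but are excluded from the medians; both
    behaviors are switchable.
    """
    labels = as_group_series(labels)
    by_drug: dict[str, list[LC50Result]] = {}
    for r in results:
        by_drug.setdefault(r.drug, []).append(r)

    out: dict[str, dict] = {}
    for drug, recs in by_drug.items():
        values: dict[int, list[float]] = {1: [], 2: []}
        median_vals: dict[int, list[float]] = {1: [], 2: []}
        n_censored = 0
        for r in recs:
            if r.sample not in labels.index:
                continue
            c = int(labels[r.sample])
            censored = r.status.startswith("censored")
            if censored:
                n_censored += 1
            if not censored or include_censored_in_test:
                values[c].append(r.lc50)
            if not censored or include_censored_in_median:
                median_vals[c].append(r.lc50)
        for c in (1, 2):
            if len(median_vals[c]) == 0:
                raise ValidationError(f"no evaluable LC50 in cluster {c} for {drug}")
        med1 = float(np.median(median_vals[1]))
        med2 = float(np.median(median_vals[2]))
        test = mann_whitney_u(values[1], values[2])
        out[drug] = {
            "median_cluster1": med1,
            "median_cluster2": med2,
            "fold": med2 / med1,
            "n_cluster1": len(values[1]),
            "n_cluster2": len(values[2]),
            "n_censored": n_censored,
            "test": test,
        }
        log.info("%s: median LC50 fold %.2f (MW p = %.3g)", drug, med2 / med1, test.p_value)
    return out
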