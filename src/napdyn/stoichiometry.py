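"""Per-nucleus ARF1:ARF2 ratio dynamics in double-knockin-style data.

In a line carrying both tagged ARFs, each nucleus yields a two-channel
intensity pair, and the channel ratio tracks the activator:repressor
stoichiometry through germination.  Statistics run on log2 ratios so the two
channels enter symmetrically and paired per-nucleus differences are
approximately normal.  A ratio is censored (NaN, never infinite) wherever
the denominator channel is below its detection floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["compute_ratios", "paired_test", "paired_tests_vs_t0", "ratio_trend",
           "PairedTestResult"]


def compute_ratios(table: pd.DataFrame, numerator: str, denominator: str,
                   pairing: dict[int, int | None] | None = None,
                   floor: float = 0.0) -> pd.DataFrame:
    """Per-nucleus channel ratios over time from a quantification table.

    ``table`` is a long-format quantification table (gemma_id, time_h,
    nucleus_id, channel, intensity[, censored]).  By default nucleus_ids are
    assumed stable over time within a gemma (re-identified nuclei); a
    tracking ``pairing`` from :func:`napdyn.image_quant.track_nuclei` can be
    given to remap later time points onto t = 0 identities, in which case
    unpaired nuclei are dropped with a log entry.

    Censoring: a time point is censored when the denominator intensity is
    below ``floor`` or either channel carries a censored flag; ratio and
    log2_ratio are NaN there (never infinite or negative).
    """
    df = table.copy()
    if pairing is not None:
        back = {v: k for k, v in pairing.items() if v is not None}
        t0 = df["time_h"].min()
        later = df["time_h"] > t0
        mapped = df.loc[later, "nucleus_id"].map(back)
        dropped = int(mapped.isna().sum())
        if dropped:
            logger.info("compute_ratios: dropping %d unpaired nucleus rows", dropped)
        df = pd.concat([df[~later], df[later].assign(nucleus_id=mapped).dropna(subset=["nucleus_id"])])
        df["nucleus_id"] = df["nucleus_id"].astype(int)

    wide = df.pivot_table(index=["gemma_id", "nucleus_id", "time_h"],
                          columns="channel", values="intensity").reset_index()
    for ch in (numerator, denominator):
        if ch not in wide.columns:
            raise ValueError(f"channel {ch!r} missing from table")
    if "censored" in df.columns:
        cens = df.pivot_table(index=["gemma_id", "nucleus_id", "time_h"],
                              columns="channel", values="censored", aggfunc="any").reset_index()
        flagged = cens[numerator].astype(bool) | cens[denominator].astype(bool)
    else:
        flagged = pd.Series(False, index=wide.index)
    censored = flagged | (wide[denominator] <= floor) | (wide[denominator] <= 0)

    ratio = np.where(censored, np.nan, wide[numerator] / wide[denominator].where(~censored))
    out = wide[["gemma_id", "nucleus_id", "time_h"]].copy()
    out["ratio"] = ratio
    out["log2_ratio"] = np.log2(out["ratio"])
    out["censored"] = censored.to_numpy()
    return out.sort_values(["gemma_id", "nucleus_id", "time_h"]).reset_index(drop=True)


@dataclass(frozen=True)
class PairedTestResult:
    t0: float
    t: float
    n: int
    mean_diff: float        # mean per-nucleus log2-ratio difference (t minus t0)
    t_stat: float
    p_value: float
    degenerate: bool = False  # zero-variance differences: statistic is 0 or +/-inf


def paired_test(series: pd.DataFrame, t0: float, t: float) -> PairedTestResult:
    """Paired Student's t test on per-nucleus log2 ratios between two times.

    Only nuclei with uncensored values at both times contribute.  Identical
    values give p = 1; a constant nonzero shift with zero variance is
    reported as an infinite statistic with ``degenerate=True`` rather than
    an error.
    """
    wide = (series[~series["censored"]]
            .pivot_table(index=["gemma_id", "nucleus_id"], columns="time_h",
                         values="log2_ratio"))
    if t0 not in wide.columns or t not in wide.columns:
        raise ValueError(f"time points {t0} and {t} not both present")
    pairs = wide[[t0, t]].dropna()
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 nuclei with uncensored values at both times")
    d = (pairs[t] - pairs[t0]).to_numpy()
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTestResult(t0, t, n, 0.0, 0.0, 1.0, degenerate=True)
        return PairedTestResult(t0, t, n, float(d.mean()),
                                float(np.sign(d.mean()) * np.inf), 0.0, degenerate=True)
    res = stats.ttest_rel(pairs[t], pairs[t0])
    return PairedTestResult(t0, t, n, float(d.mean()),
                            float(res.statistic), float(res.pvalue))


def paired_tests_vs_t0(series: pd.DataFrame, t0: float = 0.0,
                       holm: bool = False) -> pd.DataFrame:
    """Paired tests of every later time point against t0.

    Per-time-point tests are reported unadjusted by default, matching
    common per-time-point reporting; ``holm=True`` adds a Holm-adjusted
    column across the tested time points.
    """
    times = sorted(x for x in series["time_h"].unique() if x != t0)
    rows = [paired_test(series, t0, t).__dict__ for t in times]
    out = pd.DataFrame(rows)
    if holm and len(out):
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


def ratio_trend(series: pd.DataFrame) -> pd.DataFrame:
    """Least-squares slope of median log2 ratio versus time, per gemma.

    A positive slope means the stoichiometry shifts toward the numerator
    channel (ARF1) during germination.
    """
    rows = []
    for gemma, grp in series[~series["censored"]].groupby("gemma_id"):
        med = grp.groupby("time_h")["log2_ratio"].median()
        if len(med) < 2:
            raise ValueError(f"gemma {gemma!r} has fewer than 2 time points")
        slope = float(np.polyfit(med.index.to_numpy(float), med.to_numpy(), 1)[0])
        rows.append({"gemma_id": gemma, "slope_log2_per_h": slope,
                     "n_times": len(med)})
    return pd.DataFrame(rows)
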