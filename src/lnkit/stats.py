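"""Before/after and across-treatment statistics.

Response-feature changes are summarized per unit with the bounded modulation
index MI = (after - before) / (after + before); paired changes are tested
with the Wilcoxon signed-rank test (Bonferroni-corrected across features),
and treatment groups are compared against the saline control with a
Kruskal-Wallis omnibus test followed by a Dunn-style post-hoc comparison of
average group ranks (Holm-adjusted).  The gain-vs-kinetics analysis pools
per-unit (gain MI, latency or frequency MI) pairs across treatments and
reports their Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sstats


@dataclass
class ModulationRecord:
    """One unit's before/after values for one response feature."""

    unit_id: str
    feature: str  # peak_latency, peak_frequency, mean_rate, gain, rf_size, ds, os
    a_before: float
    a_after: float

    @property
    def modulation_index(self) -> float:
        return modulation_index(self.a_before, self.a_after)


def modulation_index(a_before, a_after):
    """Bounded change measure (after - before) / (after + before).

    For nonnegative inputs the result lies in [-1, 1]; it is antisymmetric
    under swapping the arguments and invariant to common rescaling.  A 0/0
    pair is undefined (NaN).  Accepts scalars or arrays.
    """
    a_before = np.asarray(a_before, dtype=np.float64)
    a_after = np.asarray(a_after, dtype=np.float64)
    denom = a_before + a_after
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a_after - a_before) / denom, np.nan)
    return float(out) if out.ndim == 0 else out


class PairedResult(NamedTuple):
    statistic: float
    p_value: float
    p_adjusted: float
    n: int


def paired_compare(before, after, n_comparisons: int = 1) -> PairedResult:
    """Wilcoxon signed-rank test on paired values with Bonferroni correction.

    The two-sided p-value is multiplied by ``n_comparisons`` and capped at 1.
    All-zero differences are a degenerate case reported as p = 1.
    """
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if before.size != after.size or before.size < 5:
        raise ValueError("need equal-length paired samples of size >= 5")
    diffs = after - before
    if np.all(diffs == 0):
        return PairedResult(0.0, 1.0, 1.0, before.size)
    stat, p = sstats.wilcoxon(before, after)
    return PairedResult(float(stat), float(p), min(float(p) * n_comparisons, 1.0),
                        before.size)


def _dunn_vs_control(groups: dict, control: str) -> dict:
    """Dunn's z-tests of average group ranks against the control group,
    with a tie correction, Holm-adjusted over the non-control groups."""
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], float) for g in names])
    ranks = sstats.rankdata(all_vals)
    n_total = all_vals.size
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start: start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw = {}
    for g in names:
        if g == control:
            continue
        se = np.sqrt(var_base * (1.0 / len(groups[g]) + 1.0 / len(groups[control])))
        z = (mean_ranks[g] - mean_ranks[control]) / se if se > 0 else np.nan
        raw[g] = (z, 2.0 * sstats.norm.sf(abs(z)) if np.isfinite(z) else np.nan)
    # Holm step-down
    order = sorted(raw, key=lambda g: raw[g][1])
    m = len(order)
    adj = {}
    running_max = 0.0
    for rank, g in enumerate(order):
        p = min(raw[g][1] * (m - rank), 1.0)
        running_max = max(running_max, p)
        adj[g] = running_max
    return {g: {"z": raw[g][0], "p_raw": raw[g][1], "p_adjusted": adj[g]}
            for g in raw}


def treatment_vs_control(
    mi_by_group: dict, control: str = "saline"
) -> dict:
    """Kruskal-Wallis omnibus plus post-hoc comparisons against the control.

    ``mi_by_group`` maps treatment name to a list of per-unit modulation
    indices and must include the control group.  Identical constant groups
    make the omnibus undefined (NaN, flagged).
    """
    if control not in mi_by_group:
        raise ValueError(f"control group {control!r} missing")
    if len(mi_by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in mi_by_group.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    arrays = [np.asarray(v, float) for v in mi_by_group.values()]
    try:
        with np.errstate(invalid="ignore"):
            h, p = sstats.kruskal(*arrays)
    except ValueError:  # all values identical
        h, p = float("nan"), float("nan")
    if not np.isfinite(h):  # scipy reports NaN when every value ties
        return {"omnibus_h": float("nan"), "omnibus_p": float("nan"),
                "degenerate": True, "posthoc": {}}
    return {
        "omnibus_h": float(h),
        "omnibus_p": float(p),
        "degenerate": False,
        "posthoc": _dunn_vs_control(mi_by_group, control),
    }


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def gain_kinetics_correlation(gain_mi, kinetics_mi) -> CorrelationResult:
    """Pearson correlation between gain modulation and a kinetics modulation.

    Pairs with a missing value on either side are dropped; fewer than 3
    complete pairs, or zero variance in either variable, is undefined.
    """
    x = np.asarray(gain_mi, dtype=np.float64)
    y = np.asarray(kinetics_mi, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("inputs must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), int(x.size))
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))
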