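"""Region-, clone- and position-level comparison of NS vs S LONR samples.

The selection test is an unpaired, unequal-variance (Welch) t-test between
the LONR values of non-synonymous and synonymous mutations pooled over a
scope (a region within one clone, or over many clones).  Positive mean
NS - S difference indicates positive selection in that region.  Degenerate
inputs (fewer than two events per class, zero pooled variance) are flagged
explicitly rather than silently coerced to zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lonr.events import classify_mutation, events_to_frame

_VALID = set("ACGT")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    valid: bool
    reason: str = ""


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean a - mean b) / sqrt(s2a/na + s2b/nb), with Welch-Satterthwaite
    degrees of freedom.  Returns a flagged (NaN) result when either group
    has fewer than two values or the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return WelchResult(math.nan, math.nan, math.nan, False, "group too small")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        if a.mean() == b.mean():
            return WelchResult(math.nan, math.nan, math.nan, False, "zero variance")
        return WelchResult(math.inf, math.nan, 0.0, False, "zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue), True)


def _as_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    return events_to_frame(events)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def significant_clones(events, p_threshold: float = 0.01) -> list[str]:
    """Clone ids whose pooled NS-vs-S Welch test is significant at ``p_threshold``."""
    df = _as_frame(events)
    keep = []
    for clone_id, sub in df.groupby("clone_id", sort=False):
        res = welch_t_test(
            sub.loc[sub.mutation_class == "NS", "lonr"],
            sub.loc[sub.mutation_class == "S", "lonr"],
        )
        if res.valid and res.p < p_threshold:
            keep.append(clone_id)
    return keep


def region_report(
    events,
    scope: Mapping[str, str] | None = None,
    significant_tree_p: float | None = None,
) -> pd.DataFrame:
    """Per-region NS-vs-S selection report.

    For every region label present in the events, pools all NS and all S
    LONR values over the scope's clones and reports counts, means, the
    pooled mean NS - S difference, a per-clone-mean variant of the same
    difference, and the Welch test.  With ``significant_tree_p`` set, the
    report is restricted to clones whose own pooled test is significant at
    that level (the "significant trees only" view).  A Benjamini-Hochberg
    column is appended for convenience; the headline p-values are raw.
    """
    df = _as_frame(events)
    if significant_tree_p is not None:
        df = df[df.clone_id.isin(significant_clones(df, significant_tree_p))]
    rows = []
    for region, sub in df.groupby("region", sort=False):
        ns = sub.loc[sub.mutation_class == "NS", "lonr"].to_numpy()
        s = sub.loc[sub.mutation_class == "S", "lonr"].to_numpy()
        res = welch_t_test(ns, s)
        per_clone = []
        for _, csub in sub.groupby("clone_id", sort=False):
            cns = csub.loc[csub.mutation_class == "NS", "lonr"]
            cs = csub.loc[csub.mutation_class == "S", "lonr"]
            if len(cns) and len(cs):
                per_clone.append(cns.mean() - cs.mean())
        row = {
            "region": region,
            "n_ns": int(ns.size),
            "n_s": int(s.size),
            "mean_lonr_ns": float(ns.mean()) if ns.size else math.nan,
            "mean_lonr_s": float(s.mean()) if s.size else math.nan,
            "mean_difference": (
                float(ns.mean() - s.mean()) if ns.size and s.size else math.nan
            ),
            "per_clone_mean_difference": (
                float(np.mean(per_clone)) if per_clone else math.nan
            ),
            "t_statistic": res.t,
            "degrees_freedom": res.df,
            "p_value": res.p,
            "test_valid": res.valid,
            "flag": res.reason,
        }
        rows.append(row)
        if scope:
            row.update(scope)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = _bh_adjust(out["p_value"].to_numpy())
    return out


def position_profile(events, sequence_length: int, frame_offset: int = 0) -> pd.DataFrame:
    """Per-codon mean LONR trace (combined, NS-only, S-only).

    Averages the LONR of all events falling on a codon's three nucleotide
    positions; codons with no events carry NaN, never zero.  Each event
    counts once -- this is the per-nucleotide (unweighted by mutation
    multiplicity) view, which can differ from region-pooled means when
    events are unevenly spread across positions.
    """
    df = _as_frame(events)
    n_codons = (sequence_length - frame_offset) // 3
    idx = pd.RangeIndex(n_codons, name="codon")
    out = pd.DataFrame(
        {
            "mean_lonr": np.nan,
            "mean_lonr_ns": np.nan,
            "mean_lonr_s": np.nan,
            "n_events": 0,
        },
        index=idx,
    )
    if not len(df):
        return out
    codon = (df.position - frame_offset) // 3
    df = df.assign(codon=codon)
    df = df[(df.codon >= 0) & (df.codon < n_codons)]
    grouped = df.groupby("codon")
    out.loc[grouped.size().index, "n_events"] = grouped.size()
    out["mean_lonr"] = grouped["lonr"].mean()
    out["mean_lonr_ns"] = df[df.mutation_class == "NS"].groupby("codon")["lonr"].mean()
    out["mean_lonr_s"] = df[df.mutation_class == "S"].groupby("codon")["lonr"].mean()
    return out


@dataclass(frozen=True)
class NsFractionResult:
    value: float
    mean_ns: float
    mean_s: float
    valid: bool


def ns_fraction(leaf_sequences: Iterable[str], ancestor: str) -> NsFractionResult:
    """NS/(NS + S) mutation load of a clone's leaves against its ancestor.

    Counts NS and S substitutions per leaf relative to the ancestral
    sequence (each differing position classified on the ancestral codon,
    substituted singly), averages both counts over leaves, and returns
    mean-NS/(mean-NS + mean-S).  Flagged undefined when no mutations at all.
    """
    ancestor = ancestor.upper()
    leaf_list = [s.upper() for s in leaf_sequences]
    if not leaf_list:
        raise ValueError("no leaves")
    ns_counts, s_counts = [], []
    for leaf in leaf_list:
        if len(leaf) != len(ancestor):
            raise ValueError("leaf/ancestor length mismatch")
        ns = s = 0
        for pos, (a, b) in enumerate(zip(ancestor, leaf)):
            if a == b or a not in _VALID or b not in _VALID:
                continue
            start = 3 * (pos // 3)
            if start + 3 > len(ancestor):
                continue
            codon = ancestor[start : start + 3]
            if not set(codon) <= _VALID:
                continue
            k = pos - start
            to_codon = codon[:k] + b + codon[k + 1 :]
            if classify_mutation(codon, to_codon) == "S":
                s += 1
            else:
                ns += 1
        ns_counts.append(ns)
        s_counts.append(s)
    mean_ns = float(np.mean(ns_counts))
    mean_s = float(np.mean(s_counts))
    denom = mean_ns + mean_s
    if denom == 0:
        return NsFractionResult(math.nan, mean_ns, mean_s, False)
    return NsFractionResult(mean_ns / denom, mean_ns, mean_s, True)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(sps.spearmanr(x, y).statistic)
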