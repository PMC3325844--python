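"""Differential-expression reduction for two-channel arrays and 2-D gels.

Transcriptome: two-channel (test vs reference) probe intensities are
background-corrected with a half-minimum floor, converted to per-array
log2 ratios, median-centered, tested per locus with a one-sample t-test
across replicate arrays, and FDR-adjusted with the Benjamini-Hochberg
step-up.  Calls use the conventional thresholds: BH-adjusted p < 0.05
and fold change strictly above 2 in either direction; a stricter raw-p
filter (fold > 3.5, p < 0.03) is available for focused comparisons.

Proteome: 2-D-gel spot volumes are compared between conditions (Welch
t-test on log2 volumes across replicate gels) with the twofold-or-more /
half-or-less rule at p < 0.05; spots detected in only one condition pass
through as presence/absence calls.

Fold changes are displayed with the signed convention used in microarray
tables: -6.7 means 6.7-fold down, and |signed fold| >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArraySet",
    "normalize_and_logratio",
    "bh_adjust",
    "signed_fold",
    "transcript_de_table",
    "call_transcript_de",
    "strict_cutoff_filter",
    "call_protein_de",
    "overlap_and_concordance",
    "DESummary",
]


@dataclass(frozen=True)
class ArraySet:
    """A replicate set of two-channel arrays over a common probe list.

    All intensity matrices are (n_probes, n_arrays): test/reference
    channel foregrounds and backgrounds, aligned to ``locus_tags``.
    """

    locus_tags: Sequence[str]
    test_fg: np.ndarray
    test_bg: np.ndarray
    ref_fg: np.ndarray
    ref_bg: np.ndarray
    array_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        shape = np.shape(self.test_fg)
        for name in ("test_fg", "test_bg", "ref_fg", "ref_bg"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != shape:
                raise ValueError("intensity matrices must share one shape")
            if np.any(m < 0):
                raise ValueError(f"{name} intensities must be >= 0")
            object.__setattr__(self, name, m)
        if len(self.locus_tags) != shape[0]:
            raise ValueError("locus_tags must match the probe dimension")
        if self.array_ids is not None and len(self.array_ids) != shape[1]:
            raise ValueError("array_ids must match the array dimension")

    @property
    def n_arrays(self) -> int:
        return self.test_fg.shape[1]


def _floor_corrected(fg: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Background-subtract with a half-minimum-positive floor, per array."""
    corrected = fg - bg
    out = np.empty_like(corrected)
    for j in range(corrected.shape[1]):
        col = corrected[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(
                f"array column {j} has no positive background-corrected "
                "intensity"
            )
        floor = positive.min() / 2.0
        out[:, j] = np.maximum(col, floor)
    return out


def normalize_and_logratio(arrays: ArraySet) -> pd.DataFrame:
    """Per-probe, per-array median-centered log2(test/reference) ratios.

    Background correction floors at half the smallest positive corrected
    intensity of each array/channel, so ratios stay finite even when the
    background exceeds the foreground.
    """
    test = _floor_corrected(arrays.test_fg, arrays.test_bg)
    ref = _floor_corrected(arrays.ref_fg, arrays.ref_bg)
    ratios = np.log2(test / ref)
    ratios = ratios - np.median(ratios, axis=0, keepdims=True)
    cols = (
        list(arrays.array_ids)
        if arrays.array_ids is not None
        else [f"array_{j + 1}" for j in range(arrays.n_arrays)]
    )
    return pd.DataFrame(ratios, index=list(arrays.locus_tags), columns=cols)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, ``q_i = p_i * m / i``, monotonised from the largest
    rank down, capped at 1, and returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(q, 1.0)
    return adjusted


def signed_fold(log2_fold_change: float | np.ndarray) -> float | np.ndarray:
    """Signed fold change with magnitude >= 1 (-6.7 means 6.7-fold down)."""
    x = np.asarray(log2_fold_change, dtype=float)
    out = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    if np.isscalar(log2_fold_change) or out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DESummary:
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def transcript_de_table(log_ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-locus statistics from replicate log2 ratios.

    One-sample t-test of the replicate log ratios against zero, plus BH
    adjustment across all loci.  Loci with zero variance across
    replicates get p = 0 when the mean is nonzero and p = 1 otherwise
    (the t statistic is degenerate there).
    """
    values = log_ratios.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("p-values need >= 2 replicate arrays")
    mean = values.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_1samp(values, 0.0, axis=1)
        p = np.asarray(t_res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = np.where(mean[degenerate] != 0.0, 0.0, 1.0)
    return pd.DataFrame(
        {
            "locus_tag": log_ratios.index,
            "log2_fold_change": mean,
            "fold_change_signed": signed_fold(mean),
            "p_value": p,
            "adj_p_value": bh_adjust(p),
        }
    ).set_index("locus_tag")


def call_transcript_de(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, DESummary]:
    """Call transcripts up/down/ns at the standard thresholds.

    Up when the fold change strictly exceeds ``fc_threshold`` and the
    BH-adjusted p-value is below ``alpha``; down symmetric; otherwise
    not significant.
    """
    fold = results["fold_change_signed"].to_numpy()
    adj = results["adj_p_value"].to_numpy()
    call = np.where(
        (fold > fc_threshold) & (adj < alpha),
        "up",
        np.where((fold < -fc_threshold) & (adj < alpha), "down", "ns"),
    )
    out = results.copy()
    out["call"] = call
    return out, DESummary(
        n_up=int((call == "up").sum()), n_down=int((call == "down").sum())
    )


def strict_cutoff_filter(
    results: pd.DataFrame,
    fc_threshold: float = 3.5,
    p_threshold: float = 0.03,
) -> pd.DataFrame:
    """Subset of loci passing a strict raw-p filter (fold > 3.5, p < 0.03).

    Uses the unadjusted p-value, matching the focused secondary screen
    convention; both comparisons are strict.
    """
    fold = results["fold_change_signed"].abs()
    keep = (fold > fc_threshold) & (results["p_value"] < p_threshold)
    return results.loc[keep]


def call_protein_de(
    spots: pd.DataFrame,
    ratio_hi: float = 2.0,
    ratio_lo: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-spot protein calls from replicate 2-D-gel volumes.

    ``spots`` is long-form with columns ``spot_id``, ``locus_tag``,
    ``condition`` ('test' or 'ref') and ``volume`` (one row per gel).
    For spots present in both conditions the expression ratio is the
    mean test volume over the mean reference volume; the p-value is a
    Welch t-test on log2 volumes.  Up needs ratio >= 2 (inclusive, per
    the twofold-or-higher rule) and p < alpha; down needs ratio <= 0.5.
    Spots with volumes in only one condition become ``only_in_test`` /
    ``only_in_ref`` calls with no ratio.
    """
    required = {"spot_id", "condition", "volume"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table is missing columns: {sorted(missing)}")
    rows = []
    for spot_id, grp in spots.groupby("spot_id", sort=False):
        locus = (
            grp["locus_tag"].dropna().iloc[0]
            if "locus_tag" in grp and grp["locus_tag"].notna().any()
            else None
        )
        test = grp.loc[grp["condition"] == "test", "volume"].to_numpy(float)
        ref = grp.loc[grp["condition"] == "ref", "volume"].to_numpy(float)
        test = test[test > 0]
        ref = ref[ref > 0]
        if test.size and not ref.size:
            rows.append((spot_id, locus, np.nan, np.nan, "only_in_test"))
            continue
        if ref.size and not test.size:
            rows.append((spot_id, locus, np.nan, np.nan, "only_in_ref"))
            continue
        if not test.size and not ref.size:
            rows.append((spot_id, locus, np.nan, np.nan, "ns"))
            continue
        ratio = test.mean() / ref.mean()
        if test.size >= 2 and ref.size >= 2:
            p = float(
                stats.ttest_ind(
                    np.log2(test), np.log2(ref), equal_var=False
                ).pvalue
            )
            if not np.isfinite(p):  # zero variance in both groups
                p = 0.0 if not np.isclose(ratio, 1.0) else 1.0
        else:
            p = np.nan
        if ratio >= ratio_hi and p < alpha:
            call = "up"
        elif ratio <= ratio_lo and p < alpha:
            call = "down"
        else:
            call = "ns"
        rows.append((spot_id, locus, ratio, p, call))
    return pd.DataFrame(
        rows, columns=["spot_id", "locus_tag", "ratio", "p_value", "call"]
    ).set_index("spot_id")


_DIRECTIONAL = {"up", "down", "only_in_test", "only_in_ref"}


def _de_loci(calls: pd.DataFrame) -> set[str]:
    mask = calls["call"] != "ns"
    if "locus_tag" in calls.columns:
        loci = calls.loc[mask, "locus_tag"].dropna()
    else:
        loci = calls.index[mask]
    return set(loci)


def overlap_and_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    protein_calls: pd.DataFrame | None = None,
) -> dict:
    """Shared DE loci between two comparisons, and transcript-protein
    concordance.

    ``de_a``/``de_b`` are called transcript tables (index locus_tag,
    column ``call``); ``protein_calls`` the spot-call table.  A protein
    is concordant when its call direction matches the transcript call of
    the same locus in ``de_a`` (presence-only protein calls count as up/
    down for the direction comparison: only_in_test = up).
    """
    shared = _de_loci(de_a) & _de_loci(de_b)
    result: dict = {"shared_loci": sorted(shared), "n_shared": len(shared)}
    if protein_calls is not None:
        direction = {"only_in_test": "up", "only_in_ref": "down"}
        records = []
        n_concordant = 0
        for _, row in protein_calls.iterrows():
            locus = row.get("locus_tag")
            if locus is None or (isinstance(locus, float) and np.isnan(locus)):
                continue
            pcall = direction.get(row["call"], row["call"])
            tcall = (
                de_a.loc[locus, "call"] if locus in de_a.index else "absent"
            )
            concordant = pcall != "ns" and pcall == tcall
            n_concordant += bool(concordant)
            records.append(
                {
                    "locus_tag": locus,
                    "protein_call": pcall,
                    "transcript_call": tcall,
                    "concordant": bool(concordant),
                }
            )
        result["concordance"] = pd.DataFrame(records)
        result["n_concordant"] = n_concordant
    return result
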