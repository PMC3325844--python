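"""GC-MS metabolite annotation, normalization and level-change calls.

Retention times are converted to Kovats retention indices against an
n-alkane ladder (C10..C36); peaks are annotated against a spectral
library by RI window plus a cosine match factor on square-root-scaled
intensities (acceptance at >= 0.75).  Quantification is relative: peak
area over internal-standard (ribitol) area over cell dry weight.  QC
reports per-group relative standard deviations (technical vs biological
replicates) and Pearson correlation between condition mean profiles;
metabolites whose biological RSD exceeds a ceiling are excluded from
level-change calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlkaneLadder",
    "MetabolitePeak",
    "LibraryEntry",
    "Annotation",
    "retention_index",
    "inverse_retention_index",
    "match_factor",
    "annotate",
    "normalize_abundance",
    "qc_metrics",
    "level_change_calls",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane retention-index marker: (carbon number, retention time).

    Both sequences must be strictly increasing; alkane n anchors
    RI = 100 n.
    """

    carbon_numbers: Sequence[int]
    retention_times: Sequence[float]

    def __post_init__(self) -> None:
        n = np.asarray(self.carbon_numbers, dtype=float)
        t = np.asarray(self.retention_times, dtype=float)
        if n.size != t.size or n.size < 2:
            raise ValueError("ladder needs >= 2 matched (n, rt) pairs")
        if np.any(np.diff(n) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("ladder must be strictly increasing in n and rt")
        object.__setattr__(self, "carbon_numbers", n)
        object.__setattr__(self, "retention_times", t)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.retention_times[0]), float(self.retention_times[-1])


def retention_index(
    rt: float, ladder: AlkaneLadder, extrapolate: bool = False
) -> float:
    """Kovats retention index (linear, temperature-programmed form).

    Between bracketing alkanes n and n+1:
    ``RI = 100 (n + (rt - t_n) / (t_{n+1} - t_n))``; piecewise linear on
    irregular ladders.  Outside the ladder span a range error is raised
    unless ``extrapolate`` is set, in which case the terminal segment is
    extended linearly.
    """
    lo, hi = ladder.span
    t = ladder.retention_times
    ri_anchor = 100.0 * ladder.carbon_numbers
    if rt < lo or rt > hi:
        if not extrapolate:
            raise ValueError(
                f"retention time {rt:g} min outside ladder span "
                f"[{lo:g}, {hi:g}] min (pass extrapolate=True to extend)"
            )
        if rt < lo:
            slope = (ri_anchor[1] - ri_anchor[0]) / (t[1] - t[0])
            return float(ri_anchor[0] + slope * (rt - t[0]))
        slope = (ri_anchor[-1] - ri_anchor[-2]) / (t[-1] - t[-2])
        return float(ri_anchor[-1] + slope * (rt - t[-1]))
    return float(np.interp(rt, t, ri_anchor))


def inverse_retention_index(ri: float, ladder: AlkaneLadder) -> float:
    """Retention time whose Kovats index equals ``ri`` (within the span)."""
    ri_anchor = 100.0 * ladder.carbon_numbers
    if ri < ri_anchor[0] or ri > ri_anchor[-1]:
        raise ValueError(
            f"retention index {ri:g} outside ladder range "
            f"[{ri_anchor[0]:g}, {ri_anchor[-1]:g}]"
        )
    return float(np.interp(ri, ri_anchor, ladder.retention_times))


@dataclass(frozen=True)
class MetabolitePeak:
    """A deconvolved GC-MS peak: retention time, area and sparse spectrum.

    The spectrum maps integer m/z (nominally 40-460) to non-negative
    intensities.  ``retention_index`` is filled by the caller once a
    ladder is available.
    """

    retention_time: float
    area: float
    spectrum: Mapping[int, float]
    retention_index: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be >= 0")
        if any(v < 0 for v in self.spectrum.values()):
            raise ValueError("spectrum intensities must be >= 0")


@dataclass(frozen=True)
class LibraryEntry:
    """Reference compound: name, retention index and reference spectrum."""

    name: str
    retention_index: float
    spectrum: Mapping[int, float]
    quantifier_mz: tuple[int, ...] = ()


@dataclass(frozen=True)
class Annotation:
    name: str
    match: float
    ri_distance: float


def match_factor(
    spec_a: Mapping[int, float], spec_b: Mapping[int, float]
) -> float:
    """Cosine similarity of sqrt-scaled intensities over the m/z union.

    Symmetric, scale-invariant and bounded in [0, 1]; raises on an
    all-zero spectrum.
    """
    mz = sorted(set(spec_a) | set(spec_b))
    a = np.sqrt([max(spec_a.get(m, 0.0), 0.0) for m in mz])
    b = np.sqrt([max(spec_b.get(m, 0.0), 0.0) for m in mz])
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot match an all-zero spectrum")
    return float(np.dot(a, b) / (na * nb))


def annotate(
    peak: MetabolitePeak,
    library: Sequence[LibraryEntry],
    ri_window: float = 5.0,
    min_match: float = 0.75,
) -> Annotation | None:
    """Best library hit for a peak, or None.

    Candidates must lie within ``ri_window`` RI units; the hit is the
    candidate with the highest match factor, provided it reaches
    ``min_match`` (inclusive).  Ties break toward the smaller RI
    distance, then library order.
    """
    if peak.retention_index is None:
        raise ValueError("peak needs a retention index before annotation")
    best: Annotation | None = None
    for entry in library:
        ri_dist = abs(peak.retention_index - entry.retention_index)
        if ri_dist > ri_window:
            continue
        score = match_factor(peak.spectrum, entry.spectrum)
        if score < min_match:
            continue
        if (
            best is None
            or score > best.match
            or (score == best.match and ri_dist < best.ri_distance)
        ):
            best = Annotation(name=entry.name, match=score, ri_distance=ri_dist)
    return best


def normalize_abundance(
    area: float, internal_standard_area: float, cdw_g: float
) -> float:
    """Relative abundance: area per IS (ribitol) area per g cell dry
    weight."""
    if internal_standard_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if cdw_g <= 0:
        raise ValueError("cell dry weight must be > 0")
    if area < 0:
        raise ValueError("peak area must be >= 0")
    return area / internal_standard_area / cdw_g


def _rsd(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero-mean group")
    return 100.0 * values.std(ddof=1) / mean


def qc_metrics(
    abundances: pd.DataFrame,
    rsd_ceiling: float = 60.0,
) -> dict:
    """Replicate QC on a long-form abundance table.

    ``abundances`` has columns ``metabolite``, ``condition``,
    ``replicate_class`` ('technical' or 'biological'), ``replicate`` and
    ``value``.  Returns per-group RSDs, mean technical/biological RSDs,
    the Pearson correlation of log10 condition mean profiles for every
    condition pair, and the set of metabolites excluded because their
    biological RSD exceeds ``rsd_ceiling`` (percent) in some condition.
    """
    required = {"metabolite", "condition", "replicate_class", "value"}
    missing = required - set(abundances.columns)
    if missing:
        raise ValueError(f"abundance table missing columns {sorted(missing)}")
    groups = []
    for (met, cond, cls), grp in abundances.groupby(
        ["metabolite", "condition", "replicate_class"], sort=False
    ):
        v = grp["value"].to_numpy(float)
        if v.size < 2:
            continue
        groups.append(
            {
                "metabolite": met,
                "condition": cond,
                "replicate_class": cls,
                "n": v.size,
                "rsd_percent": _rsd(v),
            }
        )
    rsd_table = pd.DataFrame(
        groups,
        columns=["metabolite", "condition", "replicate_class", "n", "rsd_percent"],
    )
    mean_rsd = (
        rsd_table.groupby("replicate_class")["rsd_percent"].mean().to_dict()
    )
    bio = rsd_table[rsd_table["replicate_class"] == "biological"]
    excluded = set(bio.loc[bio["rsd_percent"] > rsd_ceiling, "metabolite"])

    profile = (
        abundances.groupby(["metabolite", "condition"])["value"]
        .mean()
        .unstack("condition")
    )
    pearson = {}
    conditions = list(profile.columns)
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            pair = profile[[a, b]].dropna()
            pair = pair[(pair > 0).all(axis=1)]
            if len(pair) >= 2:
                r, _ = stats.pearsonr(
                    np.log10(pair[a]), np.log10(pair[b])
                )
                pearson[(a, b)] = float(r)
    return {
        "rsd_table": rsd_table,
        "mean_rsd_percent": mean_rsd,
        "pearson_log10": pearson,
        "excluded_metabolites": excluded,
    }


def level_change_calls(
    abundances: pd.DataFrame,
    reference_condition: str,
    min_fold: float = 1.5,
    excluded: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-metabolite up/down/n.d. calls relative to a reference condition.

    A metabolite is ``up`` in a comparison when its condition mean
    exceeds ``min_fold`` times the reference mean, ``down`` when below
    1/``min_fold``, otherwise unchanged (``-``).  Metabolites absent in
    either condition or listed in ``excluded`` (QC failures) report
    ``n.d.``.
    """
    profile = (
        abundances.groupby(["metabolite", "condition"])["value"]
        .mean()
        .unstack("condition")
    )
    if reference_condition not in profile.columns:
        raise ValueError(
            f"reference condition {reference_condition!r} not present"
        )
    excluded = set(excluded)
    comparisons = [
        c for c in profile.columns if c != reference_condition
    ]
    rows = {}
    for met, row in profile.iterrows():
        ref = row[reference_condition]
        calls = {}
        for cond in comparisons:
            val = row[cond]
            if (
                met in excluded
                or not np.isfinite(ref)
                or not np.isfinite(val)
                or ref <= 0
            ):
                calls[cond] = "n.d."
                continue
            ratio = val / ref
            if ratio > min_fold:
                calls[cond] = "up"
            elif ratio < 1.0 / min_fold:
                calls[cond] = "down"
            else:
                calls[cond] = "-"
        rows[met] = calls
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metabolite"
    return out[comparisons] if comparisons else out
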