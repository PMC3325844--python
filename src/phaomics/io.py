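"""Readers/writers for the pipeline's TSV schemas, config and reports.

All interchange is plain UTF-8 TSV with a header row and decimal
points.  Residual-nutrient values below the assay detection limit are
written as the literal ``ND`` and parsed back as zero consumption with
the below-detection flag set (the nitrogen assay's limit, 1.9 mg N/l,
is recorded on the record).  Every writer's output re-parses under its
own reader.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import physiology
from .metabolomics import AlkaneLadder, LibraryEntry, MetabolitePeak
from .omics_de import ArraySet
from .pha_gc import GcRun
from .physiology import (
    ChemostatTrace,
    FeedMedium,
    SteadyStateRecord,
    StudyConfig,
)

__all__ = [
    "SchemaError",
    "read_feed",
    "write_feed",
    "read_steady_states",
    "write_steady_states",
    "read_trace",
    "write_trace",
    "read_gc_runs",
    "write_gc_runs",
    "read_arrays",
    "write_arrays",
    "read_spots",
    "write_spots",
    "read_ladder",
    "write_ladder",
    "read_library",
    "write_library",
    "read_peaks",
    "write_peaks",
    "parse_spectrum",
    "format_spectrum",
    "RunConfig",
    "load_config",
    "physiology_report",
]

ND = "ND"


class SchemaError(ValueError):
    """A table violates its schema; the message names file and column."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: cannot parse as TSV ({exc})") from exc


def _to_float(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        try:
            out[col] = out[col].astype(float)
        except ValueError as exc:
            raise SchemaError(
                f"{path}: column {col!r} is not numeric ({exc})"
            ) from exc
    return out


# -- feed --------------------------------------------------------------

FEED_COLUMNS = ["condition", "decanoate_g_per_l", "nh4cl_g_per_l"]


def read_feed(path) -> dict[str, FeedMedium]:
    df = _read_tsv(path)
    _require_columns(df, FEED_COLUMNS, path)
    df = _to_float(df, FEED_COLUMNS[1:], path)
    return {
        row["condition"]: physiology.elemental_content(
            row["decanoate_g_per_l"],
            row["nh4cl_g_per_l"],
            condition=row["condition"],
        )
        for _, row in df.iterrows()
    }


def write_feed(feeds: Mapping[str, FeedMedium], path) -> None:
    pd.DataFrame(
        [
            {
                "condition": cond,
                "decanoate_g_per_l": feed.decanoate_conc,
                "nh4cl_g_per_l": feed.nh4cl_conc,
            }
            for cond, feed in feeds.items()
        ]
    ).to_csv(path, sep="\t", index=False)


# -- steady states -----------------------------------------------------

STATE_COLUMNS = [
    "condition", "D_per_h", "cdw_g_per_l", "cdw_sd", "pha_pct_cdw",
    "pha_sd", "resid_C_g_per_l", "resid_N_g_per_l",
    "molpct_C6", "molpct_C8", "molpct_C10",
]


def read_steady_states(path) -> dict[str, SteadyStateRecord]:
    df = _read_tsv(path)
    _require_columns(df, STATE_COLUMNS, path)
    records = {}
    for i, row in df.iterrows():
        def residual(col):
            raw = row[col]
            if isinstance(raw, str) and raw.strip().upper() == ND:
                return 0.0, True
            try:
                return float(raw), False
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: line {i + 2}, column {col!r}: "
                    f"expected number or {ND!r}, got {raw!r}"
                ) from exc

        resid_c, c_nd = residual("resid_C_g_per_l")
        resid_n, n_nd = residual("resid_N_g_per_l")
        num = _to_float(
            row.to_frame().T,
            ["D_per_h", "cdw_g_per_l", "cdw_sd", "pha_pct_cdw", "pha_sd",
             "molpct_C6", "molpct_C8", "molpct_C10"],
            path,
        ).iloc[0]
        records[row["condition"]] = SteadyStateRecord(
            condition=row["condition"],
            dilution_rate=num["D_per_h"],
            cdw=num["cdw_g_per_l"],
            cdw_sd=num["cdw_sd"],
            pha_fraction=num["pha_pct_cdw"] / 100.0,
            pha_sd=num["pha_sd"] / 100.0,
            residual_carbon=resid_c,
            residual_nitrogen=resid_n,
            residual_carbon_below_detection=c_nd,
            residual_nitrogen_below_detection=n_nd,
            monomer_molpercent={
                "C6": num["molpct_C6"],
                "C8": num["molpct_C8"],
                "C10": num["molpct_C10"],
            },
        )
    return records


def write_steady_states(
    records: Mapping[str, SteadyStateRecord], path
) -> None:
    rows = []
    for cond, rec in records.items():
        mol = rec.monomer_molpercent or {}
        rows.append(
            {
                "condition": cond,
                "D_per_h": rec.dilution_rate,
                "cdw_g_per_l": rec.cdw,
                "cdw_sd": rec.cdw_sd,
                "pha_pct_cdw": 100.0 * rec.pha_fraction,
                "pha_sd": 100.0 * rec.pha_sd,
                "resid_C_g_per_l": (
                    ND if rec.residual_carbon_below_detection
                    else rec.residual_carbon
                ),
                "resid_N_g_per_l": (
                    ND if rec.residual_nitrogen_below_detection
                    else rec.residual_nitrogen
                ),
                "molpct_C6": mol.get("C6", np.nan),
                "molpct_C8": mol.get("C8", np.nan),
                "molpct_C10": mol.get("C10", np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- traces ------------------------------------------------------------

TRACE_COLUMNS = ["time_h", "od600", "dO2_pct", "co2_frac", "o2_frac"]


def read_trace(
    path, gas_flow: float = 1.0, culture_volume: float = 0.8
) -> ChemostatTrace:
    df = _read_tsv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    df = _to_float(df, TRACE_COLUMNS, path)
    return ChemostatTrace(
        time=df["time_h"].to_numpy(),
        od600=df["od600"].to_numpy(),
        dissolved_o2=df["dO2_pct"].to_numpy(),
        offgas_co2_fraction=df["co2_frac"].to_numpy(),
        offgas_o2_fraction=df["o2_frac"].to_numpy(),
        gas_flow=gas_flow,
        culture_volume=culture_volume,
    )


def write_trace(trace: ChemostatTrace, path) -> None:
    pd.DataFrame(
        {
            "time_h": trace.time,
            "od600": trace.od600,
            "dO2_pct": trace.dissolved_o2,
            "co2_frac": trace.offgas_co2_fraction,
            "o2_frac": trace.offgas_o2_fraction,
        }
    ).to_csv(path, sep="\t", index=False)


# -- GC runs -----------------------------------------------------------


def read_gc_runs(peaks_path, meta_path) -> dict[str, GcRun]:
    peaks = _read_tsv(peaks_path)
    _require_columns(peaks, ["run_id", "monomer", "area"], peaks_path)
    peaks = _to_float(peaks, ["area"], peaks_path)
    meta = _read_tsv(meta_path)
    _require_columns(meta, ["run_id", "is_mass_mg", "sample_mg"], meta_path)
    meta = _to_float(meta, ["is_mass_mg", "sample_mg"], meta_path).set_index(
        "run_id"
    )
    runs = {}
    for run_id, grp in peaks.groupby("run_id", sort=False):
        if run_id not in meta.index:
            raise SchemaError(
                f"{meta_path}: no metadata row for run {run_id!r}"
            )
        runs[run_id] = GcRun(
            areas=dict(zip(grp["monomer"], grp["area"])),
            internal_standard_mass=float(meta.loc[run_id, "is_mass_mg"]),
            sample_dry_mass=float(meta.loc[run_id, "sample_mg"]),
        )
    return runs


def write_gc_runs(runs: Mapping[str, GcRun], peaks_path, meta_path) -> None:
    peak_rows, meta_rows = [], []
    for run_id, run in runs.items():
        for monomer, area in run.areas.items():
            peak_rows.append(
                {"run_id": run_id, "monomer": monomer, "area": area}
            )
        meta_rows.append(
            {
                "run_id": run_id,
                "is_mass_mg": run.internal_standard_mass,
                "sample_mg": run.sample_dry_mass,
            }
        )
    pd.DataFrame(peak_rows).to_csv(peaks_path, sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


# -- arrays ------------------------------------------------------------

ARRAY_COLUMNS = ["probe", "locus_tag", "array_id", "channel", "fg", "bg", "role"]


def read_arrays(path) -> ArraySet:
    df = _read_tsv(path)
    _require_columns(df, ARRAY_COLUMNS, path)
    df = _to_float(df, ["fg", "bg"], path)
    bad_roles = set(df["role"]) - {"test", "ref"}
    if bad_roles:
        raise SchemaError(
            f"{path}: role must be 'test' or 'ref', got {sorted(bad_roles)}"
        )
    probes = list(dict.fromkeys(df["probe"]))
    tags = dict(zip(df["probe"], df["locus_tag"]))
    array_ids = list(dict.fromkeys(df["array_id"]))
    shape = (len(probes), len(array_ids))
    mats = {
        (role, field): np.full(shape, np.nan)
        for role in ("test", "ref")
        for field in ("fg", "bg")
    }
    p_idx = {p: i for i, p in enumerate(probes)}
    a_idx = {a: j for j, a in enumerate(array_ids)}
    for _, row in df.iterrows():
        i, j = p_idx[row["probe"]], a_idx[row["array_id"]]
        mats[(row["role"], "fg")][i, j] = row["fg"]
        mats[(row["role"], "bg")][i, j] = row["bg"]
    for key, m in mats.items():
        if np.isnan(m).any():
            raise SchemaError(
                f"{path}: incomplete design — every probe needs "
                f"{key[0]}/{key[1]} on every array"
            )
    return ArraySet(
        locus_tags=[tags[p] for p in probes],
        test_fg=mats[("test", "fg")],
        test_bg=mats[("test", "bg")],
        ref_fg=mats[("ref", "fg")],
        ref_bg=mats[("ref", "bg")],
        array_ids=array_ids,
    )


def write_arrays(arrays: ArraySet, path) -> None:
    ids = arrays.array_ids or [
        f"array_{j + 1}" for j in range(arrays.n_arrays)
    ]
    rows = []
    for i, tag in enumerate(arrays.locus_tags):
        for j, array_id in enumerate(ids):
            for role, fg, bg, channel in (
                ("test", arrays.test_fg, arrays.test_bg, "Cy5"),
                ("ref", arrays.ref_fg, arrays.ref_bg, "Cy3"),
            ):
                rows.append(
                    {
                        "probe": tag,
                        "locus_tag": tag,
                        "array_id": array_id,
                        "channel": channel,
                        "fg": fg[i, j],
                        "bg": bg[i, j],
                        "role": role,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- spots -------------------------------------------------------------

SPOT_COLUMNS = ["spot_id", "locus_tag", "gel_id", "condition", "volume"]


def read_spots(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, SPOT_COLUMNS, path)
    df = _to_float(df, ["volume"], path)
    if (df["volume"] < 0).any():
        raise SchemaError(f"{path}: spot volumes must be >= 0")
    return df


def write_spots(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


# -- metabolomics ------------------------------------------------------


def parse_spectrum(text: str, where: str = "spectrum") -> dict[int, float]:
    """Parse ``mz:intensity;mz:intensity`` into a sparse spectrum."""
    spectrum: dict[int, float] = {}
    for k, token in enumerate(str(text).split(";")):
        token = token.strip()
        if not token:
            continue
        try:
            mz_text, intensity_text = token.split(":")
            spectrum[int(mz_text)] = float(intensity_text)
        except ValueError as exc:
            raise SchemaError(
                f"{where}: malformed spectrum token {token!r} "
                f"(position {k + 1}); expected 'mz:intensity'"
            ) from exc
    return spectrum


def format_spectrum(spectrum: Mapping[int, float]) -> str:
    return ";".join(
        f"{mz}:{intensity:.12g}" for mz, intensity in sorted(spectrum.items())
    )


def read_ladder(path) -> AlkaneLadder:
    df = _read_tsv(path)
    _require_columns(df, ["n", "rt_min"], path)
    df = _to_float(df, ["n", "rt_min"], path)
    return AlkaneLadder(
        carbon_numbers=df["n"].to_numpy(),
        retention_times=df["rt_min"].to_numpy(),
    )


def write_ladder(ladder: AlkaneLadder, path) -> None:
    pd.DataFrame(
        {"n": ladder.carbon_numbers.astype(int), "rt_min": ladder.retention_times}
    ).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[LibraryEntry]:
    df = _read_tsv(path)
    _require_columns(df, ["name", "ri", "spectrum"], path)
    df = _to_float(df, ["ri"], path)
    entries = []
    for i, row in df.iterrows():
        quantifier = ()
        if "quantifier_mz" in df.columns and isinstance(
            row.get("quantifier_mz"), str
        ):
            quantifier = tuple(
                int(tok) for tok in row["quantifier_mz"].split(",") if tok
            )
        entries.append(
            LibraryEntry(
                name=row["name"],
                retention_index=row["ri"],
                spectrum=parse_spectrum(
                    row["spectrum"], where=f"{path}: line {i + 2}"
                ),
                quantifier_mz=quantifier,
            )
        )
    return entries


def write_library(library: Sequence[LibraryEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "name": e.name,
                "ri": e.retention_index,
                "spectrum": format_spectrum(e.spectrum),
                "quantifier_mz": ",".join(str(m) for m in e.quantifier_mz),
            }
            for e in library
        ]
    ).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> dict[str, list[MetabolitePeak]]:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "rt_min", "area", "spectrum"], path)
    df = _to_float(df, ["rt_min", "area"], path)
    samples: dict[str, list[MetabolitePeak]] = {}
    for i, row in df.iterrows():
        samples.setdefault(row["sample_id"], []).append(
            MetabolitePeak(
                retention_time=row["rt_min"],
                area=row["area"],
                spectrum=parse_spectrum(
                    row["spectrum"], where=f"{path}: line {i + 2}"
                ),
                sample_id=row["sample_id"],
            )
        )
    return samples


def write_peaks(samples: Mapping[str, Sequence[MetabolitePeak]], path) -> None:
    rows = []
    for sample_id, peaks in samples.items():
        for peak in peaks:
            rows.append(
                {
                    "sample_id": sample_id,
                    "rt_min": peak.retention_time,
                    "area": peak.area,
                    "spectrum": format_spectrum(peak.spectrum),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- config ------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Structured run configuration loaded from YAML.

    ``paths`` maps logical input names (feed, steadystate, ...) to
    files; thresholds override the documented defaults.
    """

    paths: Mapping[str, Path]
    study: StudyConfig = StudyConfig()
    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_match: float = 0.75
    ri_window: float = 5.0
    rsd_ceiling: float = 60.0
    level_change_fold: float = 1.5
    output_dir: Path = Path("out")
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key!r}: {p} not found")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.min_match <= 1:
            raise ValueError("min_match must be in (0, 1]")
        if self.fc_threshold < 1 or self.level_change_fold < 1:
            raise ValueError("fold thresholds must be >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    study = StudyConfig(**raw.get("study", {}))
    base = Path(path).parent
    paths = {
        key: (base / p if not Path(p).is_absolute() else Path(p))
        for key, p in raw.get("paths", {}).items()
    }
    kwargs = {
        key: raw[key]
        for key in (
            "fc_threshold", "alpha", "min_match", "ri_window",
            "rsd_ceiling", "level_change_fold", "seed",
        )
        if key in raw
    }
    out = raw.get("output_dir", "out")
    return RunConfig(paths=paths, study=study, output_dir=Path(out), **kwargs)


# -- report ------------------------------------------------------------


def physiology_report(
    feeds: Mapping[str, FeedMedium],
    states: Mapping[str, SteadyStateRecord],
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """One-row-per-condition physiology summary with regime labels.

    Yields and specific rates are recomputed per condition; the
    dual-limitation borders come from the most carbon-limited (lowest
    feed ratio) and most nitrogen-limited (highest ratio) conditions,
    and every feed ratio is classified against them.
    """
    shared = sorted(set(feeds) & set(states), key=lambda c: feeds[c].c0_n0_ratio)
    if not shared:
        raise ValueError("no condition appears in both feed and state tables")
    for cond in shared:
        if states[cond].dilution_rate >= config.mu_max:
            raise physiology.PhysiologyError(
                f"{cond}: dilution rate {states[cond].dilution_rate} "
                f"exceeds mu_max {config.mu_max}"
            )
    yields = {
        cond: physiology.yield_coefficients(feeds[cond], states[cond])
        for cond in shared
    }
    borders = None
    if len(shared) >= 2:
        borders = physiology.regime_boundaries(
            yields[shared[0]], yields[shared[-1]]
        )
    rows = []
    for cond in shared:
        feed, state = feeds[cond], states[cond]
        rates = physiology.specific_rates(state, feed)
        mol = state.monomer_molpercent or {}
        row = {
            "condition": cond,
            "c0_n0": feed.c0_n0_ratio,
            "y_xc": yields[cond].y_xc,
            "y_xn": yields[cond].y_xn,
            "border_lower": borders.lower_border if borders else np.nan,
            "border_upper": borders.upper_border if borders else np.nan,
            "regime": (
                physiology.classify_regime(feed.c0_n0_ratio, borders)
                if borders
                else ""
            ),
            "cdw_g_per_l": state.cdw,
            "pha_pct_cdw": 100.0 * state.pha_fraction,
            "q_c": rates.q_carbon,
            "q_pha": rates.q_pha,
            "molpct_C6": mol.get("C6", np.nan),
            "molpct_C8": mol.get("C8", np.nan),
            "molpct_C10": mol.get("C10", np.nan),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")
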