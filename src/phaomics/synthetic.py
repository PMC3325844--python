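"""Synthetic chemostat study generator with planted ground truth.

Emulates the full study layout — three nutrient-limitation conditions
(carbon, dual, nitrogen) at D = 0.1 h^-1 with three biological
replicates — so that every pipeline stage can be exercised offline
against known truth:

* steady-state measurements constructed to close the carbon balance
  exactly before noise, then perturbed with multiplicative lognormal
  measurement noise (offline assays carry ~22 % technical RSD);
* wash-in chemostat traces x(t) = x_ss (1 - e^(-D t)) with small
  multiplicative sensor jitter on the on-line channels;
* two-channel arrays with planted symmetric log2 effects on a chosen
  fraction of features;
* GC-MS metabolite peaks laid down at retention times back-interpolated
  from library retention indices, with a ribitol internal-standard peak
  per sample.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metabolomics, pha_gc, physiology, reference
from .metabolomics import AlkaneLadder, LibraryEntry, MetabolitePeak
from .omics_de import ArraySet
from .physiology import (
    ChemostatTrace,
    FeedMedium,
    SteadyStateRecord,
    StudyConfig,
)

__all__ = [
    "ConditionSpec",
    "GroundTruth",
    "StudyData",
    "default_conditions",
    "simulate_study",
    "simulate_trace",
    "simulate_arrays",
    "default_ladder",
    "default_library",
    "simulate_metabolite_abundances",
    "simulate_metabolite_peaks",
]


def _lognormal_factor(rng: np.random.Generator, rsd: float, size=None):
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if rsd == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(rsd**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


@dataclass(frozen=True)
class ConditionSpec:
    """Planted truth for one chemostat condition."""

    name: str
    feed: FeedMedium
    cdw: float
    pha_fraction: float
    monomer_molpercent: Mapping[str, float]
    residual_carbon: float = 0.0
    residual_nitrogen: float = 0.0
    dilution_rate: float = 0.1

    def noise_free_record(self) -> SteadyStateRecord:
        return SteadyStateRecord(
            condition=self.name,
            dilution_rate=self.dilution_rate,
            cdw=self.cdw,
            pha_fraction=self.pha_fraction,
            residual_carbon=self.residual_carbon,
            residual_nitrogen=self.residual_nitrogen,
            monomer_molpercent=dict(self.monomer_molpercent),
        )


def default_conditions() -> list[ConditionSpec]:
    """Three conditions seeded from the published steady-state table."""
    specs = []
    media = reference.feed_media()
    for name, record in reference.steady_state_records().items():
        specs.append(
            ConditionSpec(
                name=name,
                feed=media[name],
                cdw=record.cdw,
                pha_fraction=record.pha_fraction,
                monomer_molpercent=dict(record.monomer_molpercent),
                residual_carbon=record.residual_carbon,
                residual_nitrogen=record.residual_nitrogen,
                dilution_rate=record.dilution_rate,
            )
        )
    return specs


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-condition truth of a simulated study."""

    seed: int
    yields: Mapping[str, physiology.YieldSet]
    borders: physiology.RegimeBoundaries
    regimes: Mapping[str, str]
    q_pha: Mapping[str, float]
    cer: Mapping[str, float]  # C-mol/(l h), chosen to close the balance
    co2_share: Mapping[str, float]  # percent of consumed carbon


@dataclass(frozen=True)
class StudyData:
    """All synthetic measurements of one simulated study."""

    conditions: Sequence[ConditionSpec]
    replicates: pd.DataFrame  # per-replicate noisy measurements
    steady_states: Mapping[str, SteadyStateRecord]  # replicate means
    gc_runs: Mapping[tuple[str, int], pha_gc.GcRun]
    traces: Mapping[str, ChemostatTrace]
    truth: GroundTruth


def _planted_cer(spec: ConditionSpec) -> tuple[float, float, float]:
    """CER (C-mol/(l h)) closing the planted balance, plus consumed and
    CO2 C-mol/l."""
    record = spec.noise_free_record()
    consumed = (
        spec.feed.carbon_elemental - spec.residual_carbon
    ) / physiology.DEFAULT_CONSTANTS.molar_mass_c
    to_biomass = (
        physiology.residual_biomass(record)
        / physiology.DEFAULT_CONSTANTS.biomass_gram_per_cmol
    )
    comp = pha_gc.composition_from_molpercent(spec.monomer_molpercent)
    to_pha = pha_gc.pha_carbon(comp, spec.cdw * spec.pha_fraction)
    to_co2 = consumed - to_biomass - to_pha
    if to_co2 < 0:
        raise ValueError(
            f"condition {spec.name!r} cannot close its carbon balance: "
            "biomass + PHA carbon exceeds the consumed carbon"
        )
    return to_co2 * spec.dilution_rate, consumed, to_co2


def simulate_study(
    conditions: Sequence[ConditionSpec] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    measurement_rsd: float = 0.22,
    sensor_noise: float = 0.01,
    sample_dry_mass_mg: float = 10.0,
    is_mass_mg: float = 1.0,
) -> StudyData:
    """Simulate the physiology/GC side of a complete study.

    Offline measurements (CDW, PHA fraction, residuals, GC areas) get
    multiplicative lognormal noise at ``measurement_rsd``; the on-line
    trace channels use the much smaller ``sensor_noise``.  The planted
    CER of each condition is chosen so its noise-free carbon balance
    closes at exactly 1.
    """
    if conditions is None:
        conditions = default_conditions()
    rng = np.random.default_rng(seed)

    yields, regimes, q_pha, cer, co2_share = {}, {}, {}, {}, {}
    for spec in conditions:
        record = spec.noise_free_record()
        yields[spec.name] = physiology.yield_coefficients(spec.feed, record)
        q_pha[spec.name] = physiology.specific_rates(record, spec.feed).q_pha
        c, consumed, to_co2 = _planted_cer(spec)
        cer[spec.name] = c
        co2_share[spec.name] = 100.0 * to_co2 / consumed
    by_name = {s.name: s for s in conditions}
    if "carbon" in by_name and "nitrogen" in by_name:
        borders = physiology.regime_boundaries(
            yields["carbon"], yields["nitrogen"]
        )
        for spec in conditions:
            regimes[spec.name] = physiology.classify_regime(
                spec.feed.c0_n0_ratio, borders
            )
        if len({regimes[s.name] for s in conditions}) == 1:
            import warnings

            warnings.warn(
                "all simulated conditions fall into one regime",
                stacklevel=2,
            )
    else:
        borders = physiology.RegimeBoundaries(10.0, 20.0)

    rows = []
    gc_runs: dict[tuple[str, int], pha_gc.GcRun] = {}
    traces: dict[str, ChemostatTrace] = {}
    for spec in conditions:
        for rep in range(1, n_replicates + 1):
            cdw = spec.cdw * _lognormal_factor(rng, measurement_rsd)
            f = min(
                spec.pha_fraction * _lognormal_factor(rng, measurement_rsd),
                0.99,
            )
            resid_c = spec.residual_carbon * _lognormal_factor(
                rng, measurement_rsd
            )
            resid_n = spec.residual_nitrogen * _lognormal_factor(
                rng, measurement_rsd
            )
            rows.append(
                {
                    "condition": spec.name,
                    "replicate": rep,
                    "cdw_g_per_l": cdw,
                    "pha_fraction": f,
                    "resid_C_g_per_l": resid_c,
                    "resid_N_g_per_l": resid_n,
                }
            )
            gc_runs[(spec.name, rep)] = _gc_run(
                spec, f, rng, measurement_rsd, sample_dry_mass_mg, is_mass_mg
            )
        traces[spec.name] = simulate_trace(
            od_ss=2.5 * spec.cdw,
            dilution_rate=spec.dilution_rate,
            noise=sensor_noise,
            seed=int(rng.integers(2**31)),
            co2_fraction_ss=(
                cer[spec.name]
                * physiology.MOLAR_VOLUME_25C
                * 0.8
                / 60.0
                + physiology.AMBIENT_CO2_FRACTION
            ),
        )

    replicates = pd.DataFrame(rows)
    steady_states = {}
    for spec in conditions:
        grp = replicates[replicates["condition"] == spec.name]
        steady_states[spec.name] = SteadyStateRecord(
            condition=spec.name,
            dilution_rate=spec.dilution_rate,
            cdw=float(grp["cdw_g_per_l"].mean()),
            cdw_sd=float(grp["cdw_g_per_l"].std(ddof=1)) if len(grp) > 1 else 0.0,
            pha_fraction=float(grp["pha_fraction"].mean()),
            pha_sd=float(grp["pha_fraction"].std(ddof=1)) if len(grp) > 1 else 0.0,
            residual_carbon=float(grp["resid_C_g_per_l"].mean()),
            residual_nitrogen=float(grp["resid_N_g_per_l"].mean()),
            monomer_molpercent=dict(spec.monomer_molpercent),
        )

    truth = GroundTruth(
        seed=seed,
        yields=yields,
        borders=borders,
        regimes=regimes,
        q_pha=q_pha,
        cer=cer,
        co2_share=co2_share,
    )
    return StudyData(
        conditions=list(conditions),
        replicates=replicates,
        steady_states=steady_states,
        gc_runs=gc_runs,
        traces=traces,
        truth=truth,
    )


def _gc_run(
    spec: ConditionSpec,
    pha_fraction: float,
    rng: np.random.Generator,
    rsd: float,
    sample_dry_mass_mg: float,
    is_mass_mg: float,
) -> pha_gc.GcRun:
    """GC peak areas for one methanolysed sample of planted composition."""
    comp = pha_gc.composition_from_molpercent(spec.monomer_molpercent)
    pha_mass = sample_dry_mass_mg * pha_fraction
    mol_frac = comp.mol_fraction
    mass_frac = {
        m: frac * pha_gc.REPEAT_UNIT_MASS[m] / comp.mean_repeat_mass
        for m, frac in mol_frac.items()
    }
    is_area = 1.0e5
    areas = {pha_gc.INTERNAL_STANDARD: is_area}
    for monomer, frac in mass_frac.items():
        mass = pha_mass * frac
        areas[monomer] = (
            mass / is_mass_mg * is_area * _lognormal_factor(rng, rsd)
        )
    return pha_gc.GcRun(
        areas=areas,
        internal_standard_mass=is_mass_mg,
        sample_dry_mass=sample_dry_mass_mg,
    )


def simulate_trace(
    od_ss: float,
    dilution_rate: float = 0.1,
    duration: float | None = None,
    noise: float = 0.01,
    seed: int = 0,
    dt: float = 0.25,
    do2_ss: float = 35.0,
    co2_fraction_ss: float = 0.004,
    o2_fraction_ss: float = 0.195,
    gas_flow: float = 1.0,
    culture_volume: float = 0.8,
) -> ChemostatTrace:
    """First-order wash-in trace approaching steady state.

    Every channel follows ``x(t) = x_0 + (x_ss - x_0)(1 - e^(-D t))``
    with multiplicative lognormal jitter of CV ``noise``; the default
    duration is eight residence times, by which the deterministic part
    is within the 5 % steady-state tolerance.
    """
    if duration is None:
        duration = 8.0 / dilution_rate
    if duration < 8.0 / dilution_rate:
        raise ValueError("trace must span at least eight residence times")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    approach = 1.0 - np.exp(-dilution_rate * t)

    def channel(x0: float, xss: float) -> np.ndarray:
        x = x0 + (xss - x0) * approach
        return x * _lognormal_factor(rng, noise, size=t.size)

    inlet = physiology.AMBIENT_CO2_FRACTION
    return ChemostatTrace(
        time=t,
        od600=channel(0.0, od_ss),
        dissolved_o2=channel(100.0, do2_ss),
        offgas_co2_fraction=np.clip(channel(inlet, co2_fraction_ss), 0, 1),
        offgas_o2_fraction=np.clip(channel(0.2095, o2_fraction_ss), 0, 1),
        gas_flow=gas_flow,
        culture_volume=culture_volume,
    )


def simulate_arrays(
    n_features: int = 10000,
    frac_de: float = 0.05,
    effect_log2: float | tuple[float, float] = (1.0, 5.0),
    n_reps: int = 3,
    seed: int = 0,
    noise_sd: float = 0.10,
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 1.5,
    bg_level: float = 100.0,
) -> tuple[ArraySet, pd.DataFrame]:
    """Two-channel arrays with planted symmetric up/down effects.

    A fraction ``frac_de`` of features get a nonzero log2 effect, half
    up and half down, with magnitudes drawn uniformly from
    ``effect_log2`` when it is a (lo, hi) range or fixed at its value
    when scalar.  Replicate log2 ratios scatter around the effect with
    sd ``noise_sd``.  Returns the array set and a truth table with
    columns ``locus_tag``, ``effect_log2`` and ``is_de``.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tags = [f"PP{i:05d}" for i in range(1, n_features + 1)]
    n_de = int(round(n_features * frac_de))
    effects = np.zeros(n_features)
    if n_de:
        if np.isscalar(effect_log2):
            magnitude = np.full(n_de, float(effect_log2))
        else:
            lo, hi = effect_log2
            magnitude = rng.uniform(lo, hi, n_de)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        rng.shuffle(signs)
        de_idx = rng.choice(n_features, n_de, replace=False)
        effects[de_idx] = magnitude * signs

    baseline = np.exp2(
        rng.normal(baseline_log2_mean, baseline_log2_sd, n_features)
    )
    ref_signal = baseline[:, None] * _lognormal_factor(
        rng, 0.1, size=(n_features, n_reps)
    )
    test_signal = ref_signal * np.exp2(
        effects[:, None] + rng.normal(0.0, noise_sd, (n_features, n_reps))
    )
    bg = np.full((n_features, n_reps), bg_level)
    arrays = ArraySet(
        locus_tags=tags,
        test_fg=test_signal + bg,
        test_bg=bg.copy(),
        ref_fg=ref_signal + bg,
        ref_bg=bg.copy(),
        array_ids=[f"array_{j + 1}" for j in range(n_reps)],
    )
    truth = pd.DataFrame(
        {
            "locus_tag": tags,
            "effect_log2": effects,
            "is_de": effects != 0.0,
        }
    ).set_index("locus_tag")
    return arrays, truth


def simulate_spots(
    array_truth: pd.DataFrame,
    n_spots: int = 74,
    n_gels: int = 3,
    noise_sd: float = 0.2,
    frac_only_in: float = 0.15,
    seed: int = 0,
    base_volume: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D-gel spot volumes for a subset of array loci.

    Samples ``n_spots`` loci from the array truth table and lays down
    triplicate gel volumes per condition whose ratio follows the
    transcript-level effect (so transcript and protein calls agree on
    these loci up to noise); a fraction of spots instead appear in only
    one condition.  Returns the long-form spot table (columns spot_id,
    locus_tag, gel_id, condition, volume) and per-spot truth with the
    expected call.
    """
    rng = np.random.default_rng(seed)
    de_loci = array_truth.index[array_truth["is_de"]].to_numpy()
    null_loci = array_truth.index[~array_truth["is_de"]].to_numpy()
    n_de = min(len(de_loci), int(round(n_spots * 0.6)))
    chosen = list(rng.choice(de_loci, n_de, replace=False)) + list(
        rng.choice(null_loci, n_spots - n_de, replace=False)
    )
    rows, truth_rows = [], []
    for spot_id, locus in enumerate(chosen, start=1):
        effect = float(array_truth.loc[locus, "effect_log2"])
        only_in = rng.random() < frac_only_in
        if only_in and effect != 0.0:
            present = "test" if effect > 0 else "ref"
            for gel in range(1, n_gels + 1):
                rows.append(
                    {
                        "spot_id": spot_id,
                        "locus_tag": locus,
                        "gel_id": f"{present}_gel{gel}",
                        "condition": present,
                        "volume": base_volume
                        * _lognormal_factor(rng, noise_sd),
                    }
                )
            truth_rows.append(
                {"spot_id": spot_id, "locus_tag": locus,
                 "expected_call": f"only_in_{present}"}
            )
            continue
        for condition, log2_level in (("ref", 0.0), ("test", effect)):
            for gel in range(1, n_gels + 1):
                volume = (
                    base_volume
                    * np.exp2(log2_level + rng.normal(0.0, noise_sd))
                )
                rows.append(
                    {
                        "spot_id": spot_id,
                        "locus_tag": locus,
                        "gel_id": f"{condition}_gel{gel}",
                        "condition": condition,
                        "volume": volume,
                    }
                )
        expected = "up" if effect >= 1 else "down" if effect <= -1 else "ns"
        truth_rows.append(
            {"spot_id": spot_id, "locus_tag": locus, "expected_call": expected}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows).set_index("spot_id")


def default_ladder() -> AlkaneLadder:
    """C10..C36 n-alkane ladder with a mildly nonlinear elution profile."""
    n = np.arange(10, 37)
    rt = 4.0 + 1.0 * (n - 10) - 0.005 * (n - 10) ** 2
    return AlkaneLadder(carbon_numbers=n, retention_times=rt)


_LIBRARY_RI = {
    "alanine": 1100.0,
    "pyruvate": 1170.0,
    "succinate": 1310.0,
    "fumarate": 1350.0,
    "malate": 1480.0,
    "aspartate": 1520.0,
    "alpha-ketoglutarate": 1580.0,
    "glutamate": 1620.0,
    "ribitol": 1730.0,
    "citrate": 1820.0,
    "glucose-6-phosphate": 2300.0,
    "6-phosphogluconate": 2480.0,
    "trehalose": 2730.0,
}

#: Internal-standard compound injected into every simulated sample.
INTERNAL_STANDARD_NAME = "ribitol"


def _pseudo_spectrum(name: str, n_fragments: int = 15) -> dict[int, float]:
    """Deterministic synthetic EI spectrum for a compound name.

    Not a measured spectrum: fragments are drawn reproducibly from a
    name-keyed generator within m/z 40-460, with the silyl marker ion at
    m/z 73 common to all derivatized compounds.
    """
    digest = hashlib.sha256(name.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    mz = rng.choice(np.arange(40, 461), size=n_fragments, replace=False)
    intensity = rng.uniform(5.0, 100.0, n_fragments)
    spectrum = {int(m): float(i) for m, i in zip(mz, intensity)}
    spectrum[73] = 100.0
    return spectrum


def default_library() -> list[LibraryEntry]:
    """Synthetic in-house library of central-metabolism compounds.

    Retention indices are typical for TMS-derivatized metabolites;
    spectra are reproducible pseudo-spectra (see
    :func:`_pseudo_spectrum`), not measured references.
    """
    return [
        LibraryEntry(
            name=name,
            retention_index=ri,
            spectrum=_pseudo_spectrum(name),
        )
        for name, ri in _LIBRARY_RI.items()
    ]


#: Planted level changes vs the carbon-limited reference (fold per
#: comparison), mirroring the qualitative published trend (citrate up in
#: both, sugar phosphates down under nitrogen limitation).
DEFAULT_PLANTED_FOLDS: dict[str, dict[str, float]] = {
    "citrate": {"dual": 2.5, "nitrogen": 3.0},
    "succinate": {"dual": 1.0, "nitrogen": 2.0},
    "fumarate": {"dual": 1.0, "nitrogen": 1.0},
    "malate": {"dual": 1.0, "nitrogen": 2.2},
    "glutamate": {"dual": 0.4, "nitrogen": 0.3},
    "aspartate": {"dual": 0.5, "nitrogen": 0.4},
    "alanine": {"dual": 1.0, "nitrogen": 0.5},
    "glucose-6-phosphate": {"dual": 1.0, "nitrogen": 0.4},
    "6-phosphogluconate": {"dual": 0.45, "nitrogen": 0.45},
    "alpha-ketoglutarate": {"dual": 1.0, "nitrogen": 1.0},
    "pyruvate": {"dual": 1.0, "nitrogen": 1.0},
    "trehalose": {"dual": 2.0, "nitrogen": 2.0},
}


def _base_level(name: str) -> float:
    """Per-metabolite base abundance, reproducible from the name.

    Levels span roughly two orders of magnitude, as metabolite pools
    do, so condition profiles share most of their variance and their
    cross-condition correlation is dominated by the planted changes.
    """
    digest = hashlib.sha256(("level:" + name).encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return float(10.0 ** rng.normal(0.0, 1.0))


def simulate_metabolite_abundances(
    planted_folds: Mapping[str, Mapping[str, float]] | None = None,
    reference_condition: str = "carbon",
    base_level: float | None = None,
    n_technical: int = 3,
    n_biological: int = 2,
    technical_rsd: float = 0.22,
    biological_rsd: Mapping[str, float] | float = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-form normalized metabolite abundances with planted folds.

    Per condition, ``n_biological`` independent cultivations each yield
    ``n_technical`` technical replicates; biological noise defaults to
    the per-condition RSDs reported for the study (32/28/49 % for
    carbon/dual/nitrogen) and technical noise to 22 %.  Returns the
    abundance table (columns metabolite, condition, replicate_class,
    replicate, value) and the planted truth of expected level-change
    calls.
    """
    if planted_folds is None:
        planted_folds = DEFAULT_PLANTED_FOLDS
    if biological_rsd is None:
        biological_rsd = {"carbon": 0.32, "dual": 0.28, "nitrogen": 0.49}
    rng = np.random.default_rng(seed)
    conditions = [reference_condition] + sorted(
        {c for folds in planted_folds.values() for c in folds}
    )
    rows = []
    for met, folds in planted_folds.items():
        met_base = base_level if base_level is not None else _base_level(met)
        for cond in conditions:
            fold = 1.0 if cond == reference_condition else folds.get(cond, 1.0)
            level = met_base * fold
            bio_rsd = (
                biological_rsd.get(cond, 0.3)
                if isinstance(biological_rsd, Mapping)
                else float(biological_rsd)
            )
            for bio in range(1, n_biological + 1):
                bio_level = level * _lognormal_factor(rng, bio_rsd)
                for tech in range(1, n_technical + 1):
                    rows.append(
                        {
                            "metabolite": met,
                            "condition": cond,
                            "replicate_class": "technical",
                            "replicate": f"bio{bio}_tech{tech}",
                            "value": bio_level
                            * _lognormal_factor(rng, technical_rsd),
                        }
                    )
                rows.append(
                    {
                        "metabolite": met,
                        "condition": cond,
                        "replicate_class": "biological",
                        "replicate": f"bio{bio}",
                        "value": bio_level,
                    }
                )
    table = pd.DataFrame(rows)
    truth_rows = {}
    for met, folds in planted_folds.items():
        calls = {}
        for cond in conditions:
            if cond == reference_condition:
                continue
            fold = folds.get(cond, 1.0)
            calls[cond] = "up" if fold > 1.5 else "down" if fold < 1 / 1.5 else "-"
        truth_rows[met] = calls
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "metabolite"
    return table, truth


def simulate_metabolite_peaks(
    abundances: pd.DataFrame,
    library: Sequence[LibraryEntry] | None = None,
    ladder: AlkaneLadder | None = None,
    noise: float = 0.0,
    seed: int = 0,
    is_area: float = 1.0e6,
    cdw_g: float = 0.01,
) -> dict[str, list[MetabolitePeak]]:
    """Per-sample GC-MS peak lists from planted abundances.

    ``abundances`` is long-form with columns ``metabolite``,
    ``condition``, ``replicate`` and ``value`` (normalized abundance
    units, area / IS area / g CDW).  Each sample gets one peak per
    planted metabolite — retention time back-interpolated from the
    library retention index, spectrum proportional to the library
    spectrum with multiplicative noise per fragment — plus the ribitol
    internal-standard peak of area ``is_area``.
    """
    if library is None:
        library = default_library()
    if ladder is None:
        ladder = default_ladder()
    by_name = {entry.name: entry for entry in library}
    if INTERNAL_STANDARD_NAME not in by_name:
        raise ValueError("library must contain the internal standard")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[MetabolitePeak]] = {}
    for (cond, rep), grp in abundances.groupby(
        ["condition", "replicate"], sort=False
    ):
        sample_id = f"{cond}_{rep}"
        peaks: list[MetabolitePeak] = []
        for _, row in grp.iterrows():
            entry = by_name[row["metabolite"]]
            area = float(row["value"]) * is_area * cdw_g
            if area <= 0:
                continue
            peaks.append(_peak_from_entry(entry, ladder, area, rng, noise, sample_id))
        is_entry = by_name[INTERNAL_STANDARD_NAME]
        peaks.append(
            _peak_from_entry(is_entry, ladder, is_area, rng, noise, sample_id)
        )
        samples[sample_id] = peaks
    return samples


def _peak_from_entry(
    entry: LibraryEntry,
    ladder: AlkaneLadder,
    area: float,
    rng: np.random.Generator,
    noise: float,
    sample_id: str,
) -> MetabolitePeak:
    rt = metabolomics.inverse_retention_index(entry.retention_index, ladder)
    total = sum(entry.spectrum.values())
    spectrum = {
        mz: intensity / total * area * float(_lognormal_factor(rng, noise))
        for mz, intensity in entry.spectrum.items()
    }
    return MetabolitePeak(
        retention_time=rt, area=area, spectrum=spectrum, sample_id=sample_id
    )
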