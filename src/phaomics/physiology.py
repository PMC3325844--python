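"""Steady-state chemostat physiology for a PHA-accumulating culture.

This module does the elemental nutrient accounting for a chemostat fed
decanoate (carbon source) and NH4Cl (nitrogen source): yield coefficients
on elemental carbon and nitrogen, specific consumption/production rates,
the dual-nutrient-limitation regime boundaries of the Egli model, a
C-mol carbon mass balance over biomass, stored polyester (PHA) and
off-gas CO2, and steady-state detection on on-line fermentation traces.

Conventions
-----------
* Carbon and nitrogen are tracked as **elemental grams** (g C, g N), not
  substrate grams.  Feed decanoate mass is interpreted as decanoic-acid
  equivalents (MW 172.26 g/mol, 10 C atoms); NH4Cl carries one N.
* Cell dry weight (CDW) *includes* stored PHA.  The PHA-free residual
  biomass ``X = CDW * (1 - f)`` is the denominator of specific rates.
* The regime-boundary equation uses the integer molar masses 14 and 12
  (as conventional for the Egli criterion); all other elemental
  conversions use 14.007 and 12.011.  The difference is below 0.1 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import pha_gc

__all__ = [
    "PhysiologyError",
    "UndefinedRatioError",
    "ElementalConstants",
    "DEFAULT_CONSTANTS",
    "FeedMedium",
    "SteadyStateRecord",
    "YieldSet",
    "RegimeBoundaries",
    "CarbonBalance",
    "ChemostatTrace",
    "StudyConfig",
    "elemental_content",
    "yield_coefficients",
    "specific_rates",
    "residual_biomass",
    "regime_boundary",
    "regime_boundaries",
    "classify_regime",
    "co2_evolution",
    "carbon_balance",
    "detect_steady_state",
    "first_steady_window",
]

#: Detection limit of the ammonium assay, in g N per liter (1.9 mg N/l).
NITROGEN_DETECTION_LIMIT = 1.9e-3


class PhysiologyError(ValueError):
    """Invalid physiological input (negative concentration, f = 1, ...)."""


class UndefinedRatioError(PhysiologyError):
    """C0/N0 requested for a medium without nitrogen."""


@dataclass(frozen=True)
class ElementalConstants:
    """Molar masses and fixed stoichiometric constants.

    ``molar_mass_c_boundary``/``molar_mass_n_boundary`` (12, 14) are used
    only in the regime-boundary equation; everything else uses the exact
    atomic masses.
    """

    molar_mass_c: float = 12.011
    molar_mass_n: float = 14.007
    molar_mass_c_boundary: float = 12.0
    molar_mass_n_boundary: float = 14.0
    molar_mass_nh4cl: float = 53.49
    molar_mass_decanoic_acid: float = 172.26
    carbon_atoms_per_decanoate: int = 10
    biomass_gram_per_cmol: float = 27.0

    def __post_init__(self) -> None:
        for name in (
            "molar_mass_c",
            "molar_mass_n",
            "molar_mass_c_boundary",
            "molar_mass_n_boundary",
            "molar_mass_nh4cl",
            "molar_mass_decanoic_acid",
            "carbon_atoms_per_decanoate",
            "biomass_gram_per_cmol",
        ):
            if getattr(self, name) <= 0:
                raise PhysiologyError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = ElementalConstants()


@dataclass(frozen=True)
class FeedMedium:
    """Feed composition with derived elemental content.

    ``decanoate_conc`` is the decanoic-acid-equivalent mass concentration
    of the carbon source; ``nh4cl_conc`` the NH4Cl mass concentration.
    Derived fields are elemental g C/l and g N/l.  Construct via
    :func:`elemental_content`.
    """

    decanoate_conc: float
    nh4cl_conc: float
    carbon_elemental: float
    nitrogen_elemental: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.decanoate_conc < 0 or self.nh4cl_conc < 0:
            raise PhysiologyError("feed concentrations must be >= 0")

    @property
    def c0_n0_ratio(self) -> float:
        """Molar feed carbon-to-nitrogen ratio (mol C / mol N).

        Zero carbon gives 0; zero nitrogen raises
        :class:`UndefinedRatioError`.
        """
        mol_c = self.carbon_elemental / DEFAULT_CONSTANTS.molar_mass_c
        mol_n = self.nitrogen_elemental / DEFAULT_CONSTANTS.molar_mass_n
        if mol_n == 0:
            if mol_c == 0:
                return 0.0
            raise UndefinedRatioError(
                "C0/N0 undefined: medium contains no nitrogen"
            )
        return mol_c / mol_n


def elemental_content(
    decanoate_g_per_l: float,
    nh4cl_g_per_l: float,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
    condition: str = "",
) -> FeedMedium:
    """Convert a feed recipe to elemental carbon/nitrogen content.

    Parameters
    ----------
    decanoate_g_per_l
        Carbon-source concentration in decanoic-acid equivalents, g/l.
    nh4cl_g_per_l
        NH4Cl concentration, g/l.

    Returns
    -------
    FeedMedium
        With ``carbon_elemental`` = g C/l and ``nitrogen_elemental`` =
        g N/l.
    """
    if decanoate_g_per_l < 0 or nh4cl_g_per_l < 0:
        raise PhysiologyError("feed concentrations must be >= 0")
    carbon = decanoate_g_per_l * (
        constants.carbon_atoms_per_decanoate
        * constants.molar_mass_c
        / constants.molar_mass_decanoic_acid
    )
    nitrogen = nh4cl_g_per_l * (
        constants.molar_mass_n / constants.molar_mass_nh4cl
    )
    return FeedMedium(
        decanoate_conc=decanoate_g_per_l,
        nh4cl_conc=nh4cl_g_per_l,
        carbon_elemental=carbon,
        nitrogen_elemental=nitrogen,
        condition=condition,
    )


def feed_for_ratio(
    c0_n0: float,
    nh4cl_g_per_l: float = 1.0,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
    condition: str = "",
) -> FeedMedium:
    """Back-calculate the decanoate feed giving a molar C0/N0 ratio.

    Inverse of :attr:`FeedMedium.c0_n0_ratio` at fixed NH4Cl; useful
    because published chemostat media are often stated as ratios.
    """
    if c0_n0 < 0:
        raise PhysiologyError("c0_n0 must be >= 0")
    mol_n = nh4cl_g_per_l / constants.molar_mass_nh4cl
    mol_c = c0_n0 * mol_n
    decanoate = mol_c * constants.molar_mass_decanoic_acid / (
        constants.carbon_atoms_per_decanoate
    )
    return elemental_content(decanoate, nh4cl_g_per_l, constants, condition)


@dataclass(frozen=True)
class SteadyStateRecord:
    """Measured state of one chemostat condition at steady state.

    ``pha_fraction`` is the PHA mass fraction of CDW (dimensionless in
    [0, 1)).  Residual nutrient concentrations are elemental g/l in the
    culture supernatant; values below detection are stored as 0 with the
    corresponding ``*_below_detection`` flag set.
    """

    condition: str
    dilution_rate: float
    cdw: float
    pha_fraction: float
    residual_carbon: float = 0.0
    residual_nitrogen: float = 0.0
    cdw_sd: float = 0.0
    pha_sd: float = 0.0
    monomer_molpercent: Mapping[str, float] | None = None
    residual_carbon_below_detection: bool = False
    residual_nitrogen_below_detection: bool = False

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise PhysiologyError("dilution rate must be > 0")
        if not 0.0 <= self.pha_fraction < 1.0:
            raise PhysiologyError("PHA fraction must be in [0, 1)")
        if self.cdw < 0:
            raise PhysiologyError("CDW must be >= 0")
        if self.residual_carbon < 0 or self.residual_nitrogen < 0:
            raise PhysiologyError("residual concentrations must be >= 0")
        if self.monomer_molpercent is not None:
            total = float(sum(self.monomer_molpercent.values()))
            if abs(total - 100.0) > 0.5:
                raise PhysiologyError(
                    f"monomer mol% must sum to 100 +- 0.5, got {total:.2f}"
                )


@dataclass(frozen=True)
class YieldSet:
    """Yield coefficients on elemental carbon and nitrogen.

    ``y_xc = delta_x / delta_c`` (g biomass per g C consumed) and
    ``y_xn = delta_x / delta_n`` (g biomass per g N consumed), where
    ``delta_x`` is total CDW (PHA included).
    """

    y_xc: float
    y_xn: float
    delta_x: float = float("nan")
    delta_c: float = float("nan")
    delta_n: float = float("nan")

    def __post_init__(self) -> None:
        if self.y_xc < 0 or self.y_xn < 0:
            raise PhysiologyError("yields must be >= 0")
        for y, dx, d in (
            (self.y_xc, self.delta_x, self.delta_c),
            (self.y_xn, self.delta_x, self.delta_n),
        ):
            if np.isfinite(dx) and np.isfinite(d) and d > 0:
                if abs(y - dx / d) > 1e-9 * max(1.0, abs(y)):
                    raise PhysiologyError(
                        "yield inconsistent with delta_x / delta"
                    )


@dataclass(frozen=True)
class RegimeBoundaries:
    """Dual-limitation window [lower, upper] in mol C / mol N."""

    lower_border: float
    upper_border: float

    def __post_init__(self) -> None:
        if not 0 < self.lower_border < self.upper_border:
            raise PhysiologyError(
                "need 0 < lower_border < upper_border, got "
                f"({self.lower_border}, {self.upper_border})"
            )


@dataclass(frozen=True)
class CarbonBalance:
    """C-mol/l carbon balance over one steady state.

    ``closure`` is (biomass + PHA + CO2) / consumed; the three ``share_*``
    fields are the same components as percent of consumed carbon.
    """

    consumed: float
    to_biomass: float
    to_pha: float
    to_co2: float
    closure: float
    share_biomass: float
    share_pha: float
    share_co2: float
    over_closure: bool = False


@dataclass(frozen=True)
class ChemostatTrace:
    """On-line fermentation trace: OD, dissolved O2 and off-gas fractions."""

    time: np.ndarray
    od600: np.ndarray
    dissolved_o2: np.ndarray
    offgas_co2_fraction: np.ndarray
    offgas_o2_fraction: np.ndarray
    gas_flow: float = 1.0
    culture_volume: float = 0.8

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", t)
        for name in ("od600", "dissolved_o2", "offgas_co2_fraction", "offgas_o2_fraction"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != t.shape:
                raise PhysiologyError(f"{name} must match time in length")
            object.__setattr__(self, name, v)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise PhysiologyError("time must be strictly increasing")
        for name in ("offgas_co2_fraction", "offgas_o2_fraction"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise PhysiologyError(f"{name} must lie in [0, 1]")
        if self.gas_flow <= 0 or self.culture_volume <= 0:
            raise PhysiologyError("gas flow and culture volume must be > 0")


@dataclass(frozen=True)
class StudyConfig:
    """Study-level parameters.

    mu_max (h^-1) caps admissible dilution rates; the steady-state
    criterion requires every monitored channel to stay within
    ``steady_state_tolerance`` relative deviation of its window mean over
    ``steady_state_window`` residence times.
    """

    mu_max: float = 0.53
    steady_state_tolerance: float = 0.05
    steady_state_window: float = 4.0

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise PhysiologyError("mu_max must be > 0")
        if not 0 < self.steady_state_tolerance < 0.5:
            raise PhysiologyError("tolerance must be in (0, 0.5)")
        if self.steady_state_window < 1:
            raise PhysiologyError("window must be >= 1 residence time")


def yield_coefficients(
    feed: FeedMedium,
    state: SteadyStateRecord,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
) -> YieldSet:
    """Biomass yields on consumed elemental carbon and nitrogen.

    Consumption is feed minus residual (elemental g/l); below-detection
    residuals enter as 0.  Raises if either consumption is non-positive,
    naming the nutrient.
    """
    delta_c = feed.carbon_elemental - state.residual_carbon
    delta_n = feed.nitrogen_elemental - state.residual_nitrogen
    if delta_c <= 0:
        raise PhysiologyError(
            f"non-positive carbon consumption ({delta_c:.4g} g C/l): "
            "residual carbon exceeds the feed"
        )
    if delta_n <= 0:
        raise PhysiologyError(
            f"non-positive nitrogen consumption ({delta_n:.4g} g N/l): "
            "residual nitrogen exceeds the feed"
        )
    return YieldSet(
        y_xc=state.cdw / delta_c,
        y_xn=state.cdw / delta_n,
        delta_x=state.cdw,
        delta_c=delta_c,
        delta_n=delta_n,
    )


def residual_biomass(state: SteadyStateRecord) -> float:
    """PHA-free biomass concentration, ``CDW * (1 - f)`` in g/l."""
    return state.cdw * (1.0 - state.pha_fraction)


@dataclass(frozen=True)
class SpecificRates:
    """Biomass-specific rates, per gram of PHA-free biomass."""

    q_carbon: float  # g C consumed per g residual biomass per h
    q_pha: float  # g PHA formed per g residual biomass per h


def specific_rates(
    state: SteadyStateRecord,
    feed: FeedMedium,
) -> SpecificRates:
    """Specific carbon-consumption and PHA-production rates.

    At steady state the volumetric rates are D times the concentrations,
    so ``q_PHA = PHA * D / X_PHA-free`` and ``q_C = deltaC * D /
    X_PHA-free``.
    """
    x_free = residual_biomass(state)
    if x_free <= 0:
        raise PhysiologyError(
            "residual (PHA-free) biomass is zero: PHA fraction of 1 leaves "
            "no catalytic biomass to normalise rates by"
        )
    pha = state.cdw * state.pha_fraction
    delta_c = feed.carbon_elemental - state.residual_carbon
    d = state.dilution_rate
    return SpecificRates(
        q_carbon=delta_c * d / x_free,
        q_pha=pha * d / x_free,
    )


def regime_boundary(
    yields: YieldSet,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Critical feed C0/N0 ratio for a culture with the given yields.

    Egli boundary criterion: ``C0/N0 = (Y_X/N * 14) / (Y_X/C * 12)`` in
    mol/mol, with the integer masses 14 and 12.  Feeds leaner in carbon
    than the boundary of a carbon-limited culture are carbon-limited;
    feeds richer than the boundary of a nitrogen-limited culture are
    nitrogen-limited.
    """
    if yields.y_xc <= 0:
        raise PhysiologyError("y_xc must be > 0 to compute a boundary")
    if yields.y_xn <= 0:
        raise PhysiologyError("y_xn must be > 0 to compute a boundary")
    return (yields.y_xn * constants.molar_mass_n_boundary) / (
        yields.y_xc * constants.molar_mass_c_boundary
    )


def regime_boundaries(
    carbon_limited: YieldSet,
    nitrogen_limited: YieldSet,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
) -> RegimeBoundaries:
    """Both edges of the dual-limitation window.

    The lower (carbon-side) border comes from the carbon-limited
    culture's yields, the upper (nitrogen-side) border from the
    nitrogen-limited culture's.
    """
    return RegimeBoundaries(
        lower_border=regime_boundary(carbon_limited, constants),
        upper_border=regime_boundary(nitrogen_limited, constants),
    )


def classify_regime(c0_n0: float, borders: RegimeBoundaries) -> str:
    """Classify a feed ratio as ``carbon``, ``dual`` or ``nitrogen``.

    Boundary values belong to the dual-limitation window (closed
    interval).
    """
    if c0_n0 < 0:
        raise PhysiologyError("c0_n0 must be >= 0")
    if c0_n0 < borders.lower_border:
        return "carbon"
    if c0_n0 > borders.upper_border:
        return "nitrogen"
    return "dual"


#: Molar volume of an ideal gas at 1 atm, 25 degC (l/mol).
MOLAR_VOLUME_25C = 24.45

#: CO2 mole fraction of ambient air used as the inlet default.
AMBIENT_CO2_FRACTION = 4.0e-4


def co2_evolution(
    trace: ChemostatTrace,
    dilution_rate: float | None = None,
    config: StudyConfig = StudyConfig(),
    inlet_co2_fraction: float = AMBIENT_CO2_FRACTION,
) -> float:
    """Carbon-dioxide evolution rate (CER) from off-gas data, C-mol/(l h).

    ``CER = F * 60 * (y_out - y_in) / Vm / V`` with gas flow F in l/min,
    molar volume Vm at 25 degC/1 atm, and culture volume V in l.  When a
    dilution rate is supplied the off-gas fraction is averaged over the
    trailing steady-state window, otherwise over the whole trace.
    Negative differences warn and clip to zero.
    """
    y = trace.offgas_co2_fraction
    if dilution_rate is not None:
        window = config.steady_state_window / dilution_rate
        mask = trace.time >= trace.time[-1] - window
        y = y[mask]
    dy = float(np.mean(y)) - inlet_co2_fraction
    if dy < 0:
        if dy < -1e-6:
            warnings.warn(
                "off-gas CO2 below inlet level; CER clipped to 0",
                stacklevel=2,
            )
        dy = 0.0
    return (
        trace.gas_flow * 60.0 * dy / MOLAR_VOLUME_25C / trace.culture_volume
    )


def carbon_balance(
    feed: FeedMedium,
    state: SteadyStateRecord,
    cer: float,
    constants: ElementalConstants = DEFAULT_CONSTANTS,
) -> CarbonBalance:
    """C-mol balance: consumed carbon vs biomass + PHA + CO2.

    Consumed carbon is (feed - residual)/12.011 C-mol/l; PHA-free
    biomass converts at 27 g per C-mol; PHA carbon follows the monomer
    composition; CO2 is ``CER / D`` (the steady-state concentration
    equivalent of the evolution rate).  A closure above 1.05 sets the
    ``over_closure`` flag and warns rather than raising.
    """
    delta_c = feed.carbon_elemental - state.residual_carbon
    if delta_c <= 0:
        raise PhysiologyError("non-positive carbon consumption")
    consumed = delta_c / constants.molar_mass_c
    to_biomass = residual_biomass(state) / constants.biomass_gram_per_cmol
    pha_mass = state.cdw * state.pha_fraction
    if pha_mass > 0:
        if state.monomer_molpercent is None:
            raise PhysiologyError(
                "monomer composition required to balance PHA carbon"
            )
        comp = pha_gc.composition_from_molpercent(state.monomer_molpercent)
        to_pha = pha_gc.pha_carbon(comp, pha_mass)
    else:
        to_pha = 0.0
    to_co2 = cer / state.dilution_rate
    closure = (to_biomass + to_pha + to_co2) / consumed
    over = closure > 1.05
    if over:
        warnings.warn(
            f"carbon balance over-closure: {closure:.3f} > 1.05",
            stacklevel=2,
        )
    return CarbonBalance(
        consumed=consumed,
        to_biomass=to_biomass,
        to_pha=to_pha,
        to_co2=to_co2,
        closure=closure,
        share_biomass=100.0 * to_biomass / consumed,
        share_pha=100.0 * to_pha / consumed,
        share_co2=100.0 * to_co2 / consumed,
        over_closure=over,
    )


_STEADY_CHANNELS = ("od600", "dissolved_o2", "offgas_co2_fraction")


def _window_ok(
    trace: ChemostatTrace, idx: slice, tolerance: float
) -> bool:
    for name in _STEADY_CHANNELS:
        x = getattr(trace, name)[idx]
        mean = x.mean()
        if mean == 0:
            if np.any(x != 0):
                return False
            continue
        if np.max(np.abs(x - mean)) / abs(mean) > tolerance:
            return False
    return True


def detect_steady_state(
    trace: ChemostatTrace,
    dilution_rate: float,
    config: StudyConfig = StudyConfig(),
) -> tuple[bool, tuple[float, float]]:
    """Is the trailing window of the trace at steady state?

    The window spans ``steady_state_window`` residence times (e.g. 40 h
    for 4 residence times at D = 0.1 h^-1).  Steady means every
    monitored channel (OD, dissolved O2, off-gas CO2) stays within the
    configured relative deviation of its window mean.  Returns the flag
    and the (t_start, t_end) of the window examined.
    """
    window = config.steady_state_window / dilution_rate
    span = trace.time[-1] - trace.time[0]
    if span < window:
        raise PhysiologyError(
            f"trace spans {span:.1f} h but steady-state detection needs "
            f">= {window:.1f} h ({config.steady_state_window:g} residence "
            f"times at D = {dilution_rate:g} h^-1)"
        )
    start = int(np.searchsorted(trace.time, trace.time[-1] - window))
    idx = slice(start, trace.time.size)
    ok = _window_ok(trace, idx, config.steady_state_tolerance)
    return ok, (float(trace.time[start]), float(trace.time[-1]))


def first_steady_window(
    trace: ChemostatTrace,
    dilution_rate: float,
    config: StudyConfig = StudyConfig(),
) -> tuple[float, float] | None:
    """Earliest window of one steady-state length that passes the criterion.

    Scans candidate start points in order and returns the (t_start,
    t_end) of the first window of ``steady_state_window`` residence
    times over which all monitored channels hold within tolerance, or
    None if no window qualifies.
    """
    window = config.steady_state_window / dilution_rate
    t = trace.time
    n = t.size
    ends = np.searchsorted(t, t + window)
    for i in range(n):
        j = ends[i]
        if j >= n:
            break
        if _window_ok(trace, slice(i, j + 1), config.steady_state_tolerance):
            return float(t[i]), float(t[j])
    return None
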