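"""Diagnostic quantities: penetration, mean error, stoichiometric checks.

The *critical point* of a species is the deepest location (measured from
the injection face) at which its concentration still reaches a small
threshold epsilon; the *penetration ratio* is that depth as a
percentage of the column height.  "Zero concentration" is numerically
unattainable, so epsilon defaults to 1e-3 times the injected
concentration (1e-3 times the profile maximum for species that are not
injected, such as precipitated calcite).

The *mean error* delta quantifies the influence of the scale-dependent
dispersivity:  delta = 100 (C_scale - C_original) / C_original  applied
to column-averaged (or cumulative) quantities of the paired runs.

Stoichiometry: hydrolysing 1 mol of urea removes 1 mol of Ca2+ and
releases 2 mol of NH4+, so the theoretical ammonium production at 100%
conversion is twice the urea consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedMetricError

DEFAULT_EPSILON_REL = 1e-3


@dataclass
class Profile:
    """Axial profile of one species at one instant.

    ``positions`` are strictly increasing distances (m) from the
    injection face; ``length`` is the total column height (defaults to
    the last position).
    """

    positions: np.ndarray
    values: np.ndarray
    species: str = ""
    time: float = 0.0
    length: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size == 0:
            raise DomainError("empty profile")
        if self.positions.size != self.values.size:
            raise DomainError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0.0):
            raise DomainError("profile positions must be strictly increasing")
        if np.any(self.values < 0.0):
            raise DomainError("profile values must be >= 0")

    @property
    def total_length(self) -> float:
        return float(self.length if self.length is not None else self.positions[-1])


def critical_point(profile: Profile, epsilon: float) -> tuple[float, float]:
    """Deepest location with value >= epsilon, and its penetration ratio (%).

    The crossing is linearly interpolated between cell centres; a
    profile that stays at or above epsilon everywhere penetrates the
    full height (ratio 100); an everywhere-below-epsilon profile
    returns (0, 0).
    """
    if epsilon <= 0.0:
        raise DomainError("epsilon must be positive")
    v = profile.values
    x = profile.positions
    total = profile.total_length
    above = np.nonzero(v >= epsilon)[0]
    if above.size == 0:
        return 0.0, 0.0
    last = int(above[-1])
    if last == v.size - 1:
        return total, 100.0
    x1, x2 = x[last], x[last + 1]
    v1, v2 = v[last], v[last + 1]
    loc = x1 + (v1 - epsilon) / (v1 - v2) * (x2 - x1)
    return float(loc), float(100.0 * loc / total)


def mean_error(scale_value: float, original_value: float) -> float:
    """delta (%) between a scale-effect and an original-mode quantity."""
    if original_value == 0.0:
        raise UndefinedMetricError("mean error undefined for zero reference value")
    return 100.0 * (scale_value - original_value) / original_value


def mean_error_series(scale_values, original_values) -> np.ndarray:
    """Elementwise delta (%) over paired series; NaN where the reference is 0."""
    s = np.asarray(scale_values, dtype=float)
    o = np.asarray(original_values, dtype=float)
    out = np.full_like(s, np.nan)
    np.divide(s - o, o, out=out, where=o != 0.0)
    return 100.0 * out


def theoretical_ammonium(urea_consumed: float) -> float:
    """Ammonium (mol) produced by full conversion of the given urea moles."""
    if urea_consumed < 0.0:
        raise DomainError("urea consumption must be >= 0")
    return 2.0 * urea_consumed


def profile_summaries(profile: Profile) -> tuple[float, float, float]:
    """(volume-weighted mean, max, location of max) of a profile."""
    x = profile.positions
    v = profile.values
    if x.size == 1:
        return float(v[0]), float(v[0]), float(x[0])
    mids = 0.5 * (x[:-1] + x[1:])
    lo = min(0.0, x[0])
    hi = profile.total_length if profile.length is not None else x[-1] + (x[-1] - mids[-1])
    edges = np.concatenate(([lo], mids, [max(hi, x[-1])]))
    weights = np.diff(edges)
    mean = float(np.average(v, weights=weights))
    imax = int(np.argmax(v))
    return mean, float(v[imax]), float(x[imax])


def column_average_conductivity(k: np.ndarray) -> float:
    """Series (length-weighted harmonic mean) conductivity of the column.

    This is the effective conductivity a constant-head test on the whole
    column measures: axial flow passes the cells in series.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0.0):
        raise DomainError("conductivities must be positive")
    return float(k.size / np.sum(1.0 / k))


def depth_profile(frame: pd.DataFrame, column: str, source_end: str,
                  length: float, species: str = "", time: float = 0.0) -> Profile:
    """Extract a profile with positions measured from the injection face."""
    x = frame["x_m"].to_numpy()
    v = frame[column].to_numpy()
    if source_end == "top":
        depth = length - x[::-1]
        v = v[::-1]
    else:
        depth = x
    return Profile(positions=depth, values=np.maximum(v, 0.0),
                   species=species, time=time, length=length)


def _phase_sources(scenario) -> dict:
    src = {}
    for phase in scenario.phases:
        if phase.kind in ("B", "C") and phase.kind not in src:
            src[phase.kind] = phase.source_end
    return src


def _injected_concentration(scenario, species: str) -> float | None:
    for phase in scenario.phases:
        if species in phase.injected:
            return float(phase.injected[species])
    return None


def penetration_ratio(result, species: str, label: str,
                      epsilon_rel: float = DEFAULT_EPSILON_REL,
                      epsilon: float | None = None) -> float:
    """Penetration ratio (%) of a species at a phase-end snapshot.

    Depth is measured from the bacterial injection face for bacteria and
    calcite (calcite forms where the bacteria settled), from the
    cementation face for the dissolved reactants.  ``epsilon`` overrides
    the relative threshold when given.
    """
    scn = result.scenario
    snap = result.phase_end(label.replace("_end", "")) if label.endswith("_end") \
        else result.phase_end(label)
    sources = _phase_sources(scn)
    source = sources.get("B", "top") if species in ("bacl", "bacs", "caco3") \
        else sources.get("C", "bottom")
    length = scn.geometry.length
    column = result.species_column(species)
    prof = depth_profile(snap.frame, column, source, length,
                        species=species, time=snap.time)
    if epsilon is None:
        base = {"bacs": "bacl"}.get(species, species)
        ref = _injected_concentration(scn, base)
        if ref is None or ref == 0.0:
            ref = float(np.max(prof.values))
            if ref == 0.0:
                return 0.0
        epsilon = epsilon_rel * ref
    return critical_point(prof, epsilon)[1]


def metrics_table(result, epsilon_rel: float = DEFAULT_EPSILON_REL) -> pd.DataFrame:
    """Tidy metric rows (scenario, species, phase, metric, value)."""
    scn = result.scenario
    name = getattr(scn, "name", "scenario")
    sources = _phase_sources(scn)
    length = scn.geometry.length
    rows = []

    def add(species, phase, metric, value):
        rows.append({"scenario": name, "species": species, "phase": phase,
                     "metric": metric, "value": value})

    kinds_present = {p.kind for p in scn.phases}
    for kind in ("B", "R", "C"):
        if kind not in kinds_present:
            continue
        try:
            snap = result.phase_end(kind)
        except KeyError:
            continue
        for species in ("bacl", "bacs", "urea", "ca", "nh4", "caco3"):
            column = result.species_column(species)
            if column not in snap.frame.columns:
                continue
            source = sources.get("B", "top") if species in ("bacl", "bacs", "caco3") \
                else sources.get("C", "bottom")
            prof = depth_profile(snap.frame, column, source or "top", length,
                                 species=species, time=snap.time)
            if np.max(prof.values) <= 0.0:
                continue
            try:
                ratio = penetration_ratio(result, species, f"{kind}_end",
                                          epsilon_rel=epsilon_rel)
            except KeyError:
                continue
            add(species, f"{kind}_end", "penetration_ratio_pct", ratio)
            mean, vmax, argmax = profile_summaries(prof)
            add(species, f"{kind}_end", "mean", mean)
            add(species, f"{kind}_end", "max", vmax)
            add(species, f"{kind}_end", "argmax_depth_m", argmax)

    if result.final_state is not None:
        add("-", "final", "column_avg_conductivity_m_s",
            column_average_conductivity(result.final_state.k_cond))
        add("caco3", "final", "total_mass_kg", result.final_state.total_caco3_mass())
    if len(result.series):
        last = result.series.iloc[-1]
        add("urea", "final", "converted_mol", float(last["cum_urea_converted_mol"]))
        add("nh4", "final", "produced_mol", float(last["cum_nh4_produced_mol"]))
    return pd.DataFrame(rows, columns=["scenario", "species", "phase",
                                       "metric", "value"])
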