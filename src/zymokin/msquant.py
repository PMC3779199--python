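"""Quenched-flow ESI-MS quantification of activation time courses.

A continuous-flow reaction mixture, quenched on-line and electrosprayed,
yields a series of time-stamped centroided spectra in which every protein
species appears as a small set of multiply-protonated charge states.  The
quantification chain implemented here is:

1. **XIC extraction** — per declared (species, charge) target m/z, sum
   centroid intensities within a tolerance window in every scan.
2. **Internal-standard normalization** — divide each charge-state trace,
   scan by scan, by the intensity of a constant-concentration internal
   standard (a small peptide spiked into the reaction), cancelling
   ionization/transmission drift:  I_t = I_obs / I_std.
3. **Charge-state summation and concentration reconstruction** — the
   normalized intensities of a species' charge states are summed and
   scaled to concentration against the zymogen pool at time zero:
   C_t = C_0 * SumI(t) / I_0, where I_0 is the initial summed normalized
   intensity of all zymogen-pool species (intact + truncated forms, for
   preparations that start as mixtures) and C_0 the known loading
   concentration.
4. **Kinetic fitting** — the reconstructed zymogen decay is fitted with
   the integrated Michaelis-Menten depletion model.

Equal ionization response across species is assumed by step 3; the
synthetic-data generator exposes per-species response factors so the bias
of that assumption can be studied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activation
from .proteoforms import Proteoform, mz_of

log = logging.getLogger(__name__)

__all__ = [
    "SpectrumSeries",
    "SpeciesAssignment",
    "NormalizedTrace",
    "SpeciesTimeCourse",
    "extract_xic",
    "normalize_to_standard",
    "species_concentration",
    "build_time_courses",
    "estimate_activation_kinetics",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_assignments_json",
    "write_assignments_json",
    "courses_to_frame",
]


@dataclass
class SpectrumSeries:
    """Time-stamped centroided spectra: scan times (s, strictly
    increasing) and per-scan centroid arrays (m/z, intensity)."""

    scan_times_s: np.ndarray
    scans: list  # list of (mz_array, intensity_array)

    def __post_init__(self) -> None:
        self.scan_times_s = np.asarray(self.scan_times_s, dtype=float)
        if len(self.scans) != self.scan_times_s.size:
            raise ValueError("scan count and time count differ")
        if self.scan_times_s.size and not np.all(np.diff(self.scan_times_s) > 0):
            raise ValueError("scan times must be strictly increasing")
        clean = []
        for mz, inten in self.scans:
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if np.any(inten < 0):
                raise ValueError("intensities must be non-negative")
            order = np.argsort(mz)
            clean.append((mz[order], inten[order]))
        self.scans = clean

    @property
    def n_scans(self) -> int:
        return self.scan_times_s.size


@dataclass(frozen=True)
class SpeciesAssignment:
    """Which m/z windows quantify one proteoform: one target per declared
    charge state, each matched within ``tolerance_Th``."""

    proteoform: Proteoform
    tolerance_Th: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance_Th <= 0:
            raise ValueError("tolerance must be positive")
        if not self.proteoform.charge_states:
            raise ValueError(
                f"{self.proteoform.id}: assignment needs declared charge states")

    @property
    def targets(self) -> dict[int, float]:
        return {z: mz_of(self.proteoform.neutral_mass, z)
                for z in sorted(self.proteoform.charge_states)}


@dataclass
class NormalizedTrace:
    """Internal-standard-normalized intensity trace of one charge state
    (dimensionless; NaN where the standard was absent)."""

    species: str
    charge: int
    time_s: np.ndarray
    values: np.ndarray
    ambiguous: bool = False


@dataclass
class SpeciesTimeCourse:
    """Reconstructed concentration (µM) versus time for one species, with
    the charge states that were summed."""

    species: str
    role: str
    time_s: np.ndarray
    concentration_uM: np.ndarray
    charges: tuple[int, ...] = ()
    ambiguous: bool = False


def extract_xic(series: SpectrumSeries, target_mz: float,
                tol_Th: float) -> np.ndarray:
    """Extracted ion current: per scan, the summed intensity of centroids
    within [target - tol, target + tol]; zero when none fall inside."""
    if tol_Th <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = target_mz - tol_Th, target_mz + tol_Th
    out = np.zeros(series.n_scans)
    for j, (mz, inten) in enumerate(series.scans):
        a, b = np.searchsorted(mz, (lo, hi))
        if b > a:
            out[j] = inten[a:b].sum()
    return out


def normalize_to_standard(raw: np.ndarray, standard: np.ndarray,
                          *, time_s=None, species: str = "",
                          charge: int = 0) -> NormalizedTrace:
    """Pointwise ratio of a raw charge-state trace to the internal
    standard's trace on the same scan grid.  Scans where the standard is
    zero are marked missing (NaN), never zero."""
    raw = np.asarray(raw, float)
    standard = np.asarray(standard, float)
    if raw.shape != standard.shape:
        raise ValueError("trace grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(standard > 0, raw / standard, np.nan)
    n_missing = int(np.sum(standard <= 0))
    if n_missing:
        log.info("internal standard absent in %d scans; points marked missing",
                 n_missing)
    t = np.arange(raw.size, dtype=float) if time_s is None else np.asarray(time_s, float)
    return NormalizedTrace(species, charge, t, vals)


def species_concentration(summed_normalized: np.ndarray, c0_uM: float,
                          i0: float, *, time_s=None, species: str = "",
                          role: str = "zymogen",
                          charges=()) -> SpeciesTimeCourse:
    """Scale a species' summed normalized intensity to concentration:
    C_t = C_0 * SumI(t) / I_0."""
    if i0 <= 0:
        raise ValueError("initial normalized zymogen intensity I_0 must be > 0")
    vals = np.asarray(summed_normalized, float)
    conc = c0_uM * vals / i0
    t = np.arange(vals.size, dtype=float) if time_s is None else np.asarray(time_s, float)
    return SpeciesTimeCourse(species, role, t, conc, tuple(charges))


_ZYMOGEN_ROLES = {"zymogen", "truncated_zymogen"}


def build_time_courses(series: SpectrumSeries,
                       assignments: list[SpeciesAssignment],
                       c0_uM: float = 16.0) -> dict[str, SpeciesTimeCourse]:
    """Full quantification chain for one spectrum series.

    Requires exactly one assignment with role ``internal_standard``.
    Scans lacking the standard are dropped from every course (with a
    logged count).  I_0 is taken from the first retained scan as the
    summed normalized intensity of all zymogen-pool species (roles
    ``zymogen`` and ``truncated_zymogen``), so preparations that start as
    truncation mixtures are scaled against their combined pool.
    Overlapping m/z targets from different assignments (within the sum of
    their tolerances) flag both courses as ambiguous.
    """
    if series.n_scans == 0:
        warnings.warn("empty scan series; no courses built")
        return {}
    std = [a for a in assignments if a.proteoform.role == "internal_standard"]
    if len(std) != 1:
        raise ValueError("exactly one internal-standard assignment is required")
    std_assign = std[0]
    others = [a for a in assignments if a is not std_assign]

    # ambiguity scan over all protein targets
    flat = []
    for a in others:
        for z, mz in a.targets.items():
            flat.append((a.proteoform.id, mz, a.tolerance_Th))
    ambiguous: set[str] = set()
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            si, mi, ti = flat[i]
            sj, mj, tj = flat[j]
            if si != sj and abs(mi - mj) < ti + tj:
                ambiguous |= {si, sj}
                log.warning("targets %s (%.2f) and %s (%.2f) overlap within "
                            "tolerance", si, mi, sj, mj)

    std_trace = np.zeros(series.n_scans)
    for z, mz in std_assign.targets.items():
        std_trace += extract_xic(series, mz, std_assign.tolerance_Th)
    keep = std_trace > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        log.info("dropping %d scans without internal standard", n_dropped)
    if not np.any(keep):
        raise ValueError("internal standard never observed")
    t = series.scan_times_s[keep]

    summed: dict[str, np.ndarray] = {}
    for a in others:
        total = np.zeros(series.n_scans)
        for z, mz in a.targets.items():
            total += extract_xic(series, mz, a.tolerance_Th)
        summed[a.proteoform.id] = (total / std_trace)[keep]

    i0 = sum(summed[a.proteoform.id][0] for a in others
             if a.proteoform.role in _ZYMOGEN_ROLES)
    if i0 <= 0:
        raise ValueError("no zymogen-pool signal in the first retained scan; "
                         "cannot anchor I_0")

    courses: dict[str, SpeciesTimeCourse] = {}
    for a in others:
        pid = a.proteoform.id
        course = species_concentration(
            summed[pid], c0_uM, i0, time_s=t, species=pid,
            role=a.proteoform.role, charges=sorted(a.proteoform.charge_states))
        course.ambiguous = pid in ambiguous
        courses[pid] = course
    return courses


def zymogen_pool_course(courses: dict[str, SpeciesTimeCourse]) -> SpeciesTimeCourse:
    """Summed concentration course of all zymogen-pool species."""
    pool = [c for c in courses.values() if c.role in _ZYMOGEN_ROLES]
    if not pool:
        raise ValueError("no zymogen-pool course present")
    total = np.sum([c.concentration_uM for c in pool], axis=0)
    return SpeciesTimeCourse("zymogen_pool", "zymogen", pool[0].time_s, total)


def estimate_activation_kinetics(courses: dict[str, SpeciesTimeCourse],
                                 activator_uM: float,
                                 z0_uM: float) -> activation.MMFitResult:
    """Fit the Michaelis-Menten depletion model to the reconstructed
    zymogen-pool decay; K_m is flagged unidentifiable for flat or purely
    exponential decays (the ratio k_cat/K_m is still reported)."""
    pool = zymogen_pool_course(courses)
    return activation.fit_mm_depletion(pool.time_s, pool.concentration_uM,
                                       activator_uM, z0_uM)


# ---------------------------------------------------------------------------
# I/O — long-format CSV for spectra, JSON for assignments


def read_spectra_csv(path) -> SpectrumSeries:
    """Read a spectrum series from long-format CSV with columns
    scan_time_s, mz, intensity."""
    df = pd.read_csv(path, comment="#")
    need = {"scan_time_s", "mz", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"spectra CSV needs columns {sorted(need)}")
    times = np.sort(df["scan_time_s"].unique())
    scans = []
    for t in times:
        g = df[df["scan_time_s"] == t]
        scans.append((g["mz"].to_numpy(float), g["intensity"].to_numpy(float)))
    return SpectrumSeries(times, scans)


def write_spectra_csv(series: SpectrumSeries, path) -> None:
    rows = []
    for t, (mz, inten) in zip(series.scan_times_s, series.scans):
        for m, i in zip(mz, inten):
            rows.append((t, m, i))
    pd.DataFrame(rows, columns=["scan_time_s", "mz", "intensity"]).to_csv(
        path, index=False)


def read_assignments_json(path) -> list[SpeciesAssignment]:
    """Read species assignments from JSON: a list of objects with keys
    species, mass (Da), role, charges, and optional tolerance (Th)."""
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for row in data:
        pf = Proteoform(id=row["species"], neutral_mass=float(row["mass"]),
                        role=row.get("role", "zymogen"),
                        charge_states=frozenset(int(z) for z in row["charges"]))
        out.append(SpeciesAssignment(pf, float(row.get("tolerance", 0.5))))
    return out


def write_assignments_json(assignments: list[SpeciesAssignment], path) -> None:
    data = [{"species": a.proteoform.id,
             "mass": a.proteoform.neutral_mass,
             "role": a.proteoform.role,
             "charges": sorted(a.proteoform.charge_states),
             "tolerance": a.tolerance_Th} for a in assignments]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def courses_to_frame(courses: dict[str, SpeciesTimeCourse]) -> pd.DataFrame:
    """Long-format table (species, role, time_s, concentration_uM)."""
    rows = []
    for c in courses.values():
        for t, conc in zip(c.time_s, c.concentration_uM):
            rows.append((c.species, c.role, t, conc))
    return pd.DataFrame(rows, columns=["species", "role", "time_s",
                                       "concentration_uM"])
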