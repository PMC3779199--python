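"""Synthetic-data generation for every stage of the pipeline.

The generators stand in for the wet-lab instruments: a scanning
fluorimeter (thermal melts), a fluorimeter running a coupled continuous
activation assay (progress curves), and a quenched-flow electrospray mass
spectrometer (time-stamped centroid spectra).  Each generator is a pure
function of ground-truth parameters and a seed, and returns (or can
return) the exact truth it used, so parameter-recovery tests and bias
studies close the loop through the analysis code.

Default study conditions mirror the experiment being emulated:

* melts: 20-70 °C scanned at 0.5 °C/min, read every 30 s (0.25 °C
  spacing, 201 points), 0.5% relative signal noise;
* activation assays: 30-min continuous reads of a 10 µM fluorogenic
  substrate, 12.5 nM zymogen, nM-range activator;
* quenched-flow MS: 16 µM zymogen pool + 0.16 µM activator + 1.8 µM
  internal standard (a 556 Da peptide), spectra every 3 s (20 per
  minute), centroid (stick) spectra with relative intensity noise, a
  small m/z jitter, and optional global ionization drift.

The construct catalogs of the nine expression constructs (wild type,
single- and triple-proline-to-alanine mutants, and the four N-terminal
deletions) observed after purification at 4 °C are transcribed here as
named fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import activation as _act
from . import melt as _melt
from .activation import MMActivationParams, SpeciesNetwork
from .msquant import SpectrumSeries
from .proteoforms import (CatalogEntry, ConstructCatalog, Proteoform,
                          average_mass, mz_of)

__all__ = [
    "ZYMOGEN_MASS_DA",
    "MATURE_MASS_DA",
    "PROPEPTIDE_MASS_DA",
    "INTERNAL_STANDARD_SEQUENCE",
    "QfmsScenario",
    "simulate_melting_curve",
    "simulate_progress_curve",
    "simulate_qfms_series",
    "wild_type_scenario",
    "construct_catalog",
    "construct_names",
]


# ---------------------------------------------------------------------------
# Instrument-independent fixtures

#: Average neutral masses (Da) of the wild-type species as observed by ESI-MS.
ZYMOGEN_MASS_DA = 26354.0
MATURE_MASS_DA = 24987.0
PROPEPTIDE_MASS_DA = 1385.0

#: Leucine enkephalin, the 556 Da internal standard.
INTERNAL_STANDARD_SEQUENCE = "YGGFL"

#: Default ESI charge-state envelopes.
ZYMOGEN_CHARGES = (10, 11, 12)
MATURE_CHARGES = (9, 10, 11, 12)
PROPEPTIDE_CHARGES = (1, 2)

_MATURE_PREFIX = "IVGGEKALAG"

# N-terminal-form catalogs observed after purification at 4 C:
# (sequence or None when unidentified, approximate percent).
_CATALOGS: dict[str, list[tuple[str | None, float]]] = {
    "proDer p 3": [("EFNPILPASPQAT" + _MATURE_PREFIX, 100)],
    "P2A": [("EFNAILPASPQAT" + _MATURE_PREFIX, 100)],
    "P5A": [("EFNPILAASPQAT" + _MATURE_PREFIX, 100)],
    "P8A": [("EFNPILPASAQAT" + _MATURE_PREFIX, 100)],
    "P-A": [
        ("EFNAILAASAQAT" + _MATURE_PREFIX, 8),
        ("ILAASAQAT" + _MATURE_PREFIX, 5),
        ("ASAQAT" + _MATURE_PREFIX, 9),
        ("SAQAT" + _MATURE_PREFIX, 42),
        ("AQAT" + _MATURE_PREFIX, 16),
        ("AT" + _MATURE_PREFIX, 14),
        ("ALAGE", 6),
    ],
    "D1-2": [
        ("EFILPASPQAT" + _MATURE_PREFIX, 88),
        ("SPQAT" + _MATURE_PREFIX, 3),
        (None, 9),
    ],
    "D1-5": [
        ("EFASPQAT" + _MATURE_PREFIX, 88),
        ("AT" + _MATURE_PREFIX, 8),
        (None, 4),
    ],
    "D1-8": [
        ("EFQAT" + _MATURE_PREFIX, 24),
        ("EAEFQAT" + _MATURE_PREFIX, 74),
        (None, 2),
    ],
    "D1-11": [
        ("EAEF" + _MATURE_PREFIX, 94),
        ("EAEAEF" + _MATURE_PREFIX, 6),
    ],
}

_ALIASES = {"wt": "proDer p 3", "wild-type": "proDer p 3",
            "wild_type": "proDer p 3", "proder p 3": "proDer p 3",
            "p2a": "P2A", "p5a": "P5A", "p8a": "P8A", "p-a": "P-A"}


def construct_names() -> list[str]:
    return list(_CATALOGS)


def construct_catalog(name: str) -> ConstructCatalog:
    """Catalog of the N-terminal forms observed for one construct after
    purification at 4 °C.  Deletion constructs may be named 'D1-2' ...
    'D1-11' (unicode delta and en-dash variants accepted)."""
    key = name.strip()
    norm = key.lower().replace("Δ", "d").replace("δ", "d").replace("–", "-")
    norm = re.sub(r"\s*proder p 3$", "", norm) or "proder p 3"
    canonical = _ALIASES.get(norm, norm.upper() if norm.upper() in _CATALOGS
                             else None)
    if canonical is None and key in _CATALOGS:
        canonical = key
    if canonical is None or canonical not in _CATALOGS:
        raise ValueError(
            f"unknown construct {name!r}; valid names: {sorted(_CATALOGS)}")
    entries = tuple(CatalogEntry(seq, pct) for seq, pct in _CATALOGS[canonical])
    intact = _CATALOGS[canonical][0][0]
    if canonical == "D1-11":
        intact = "EF" + _MATURE_PREFIX  # expected form carries only EF
    return ConstructCatalog(construct=canonical, entries=entries,
                            mature_start="IVGG", intact_sequence=intact)


# ---------------------------------------------------------------------------
# Melting curves


def simulate_melting_curve(truth: _melt.TwoStateFit,
                           start_C: float = 20.0, stop_C: float = 70.0,
                           step_C: float = 0.25,
                           noise_rel: float = 0.005,
                           seed: int | None = 0) -> _melt.MeltingCurve:
    """Forward-simulate a thermal scan read on a regular temperature grid
    (default 20-70 °C every 0.25 °C, i.e. a 0.5 °C/min ramp read every
    30 s) with relative Gaussian noise.  Deterministic for a fixed seed."""
    if noise_rel < 0:
        raise ValueError("noise must be non-negative")
    n = int(round((stop_C - start_C) / step_C)) + 1
    temp_C = start_C + step_C * np.arange(n)
    signal = _melt.two_state_signal(temp_C + _melt.CELSIUS_OFFSET, truth)
    if noise_rel:
        rng = np.random.default_rng(seed)
        signal = signal * (1.0 + rng.normal(0.0, noise_rel, n))
    return _melt.MeltingCurve.from_celsius(
        temp_C, signal,
        metadata={"scan_rate_C_min": 0.5, "read_interval_s": 30.0,
                  "noise_rel": noise_rel, "seed": seed})


# ---------------------------------------------------------------------------
# Progress curves


def simulate_progress_curve(truth: _act.ProgressFit,
                            duration_s: float = 1800.0,
                            sampling_s: float = 5.0,
                            noise_rel: float = 0.01,
                            seed: int | None = 0,
                            activator_nM: float = float("nan"),
                            ) -> _act.ProgressCurve:
    """Forward-simulate a continuous activation assay: the lag/burst
    product curve sampled on a regular grid with relative Gaussian
    noise.  Deterministic for a fixed seed."""
    if noise_rel < 0:
        raise ValueError("noise must be non-negative")
    n = int(round(duration_s / sampling_s)) + 1
    t = sampling_s * np.arange(n)
    p = _act.progress_value(t, truth.v_i, truth.v_s, truth.k_obs)
    if noise_rel:
        rng = np.random.default_rng(seed)
        p = p * (1.0 + rng.normal(0.0, noise_rel, n))
    return _act.ProgressCurve(t, p, activator_nM=activator_nM)


# ---------------------------------------------------------------------------
# Quenched-flow ESI-MS series


@dataclass
class QfmsScenario:
    """Ground truth for one quenched-flow MS run.

    Either ``mm`` alone (a single intact zymogen processed with
    Michaelis-Menten kinetics — the wild-type experiment) or ``network``
    (a mixture of forms processed in parallel first order — the mutant
    experiments) drives the concentration courses.  ``species`` maps a
    name to its observable :class:`Proteoform`; it must contain 'mature'
    and 'propeptide' entries plus one per zymogen form ('zymogen' in MM
    mode, the network species names otherwise).

    ``envelope_weights`` (per species, per charge; defaults uniform over
    the declared charges) split a species' ion current between charge
    states; ``response`` (default 1) scales species ionization
    efficiency, so the equal-response assumption of the reconstruction
    can be violated deliberately.  ``drift_amplitude`` applies a global
    linear ionization drift reaching the given relative change at the end
    of the run, affecting every centroid in a scan equally (what the
    internal standard is there to cancel).
    """

    mm: MMActivationParams
    network: SpeciesNetwork | None = None
    species: dict[str, Proteoform] = field(default_factory=dict)
    envelope_weights: dict[str, dict[int, float]] = field(default_factory=dict)
    response: dict[str, float] = field(default_factory=dict)
    standard_uM: float = 1.8
    scan_interval_s: float = 3.0
    duration_s: float = 2400.0
    noise_rel: float = 0.02
    mz_jitter_Th: float = 0.05
    drift_amplitude: float = 0.0
    counts_per_uM: float = 1000.0

    def weights_for(self, name: str) -> dict[int, float]:
        pf = self.species[name]
        if name in self.envelope_weights:
            w = self.envelope_weights[name]
            if set(w) != set(pf.charge_states):
                raise ValueError(f"{name}: envelope weights do not cover the "
                                 "declared charge states")
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: envelope weights sum to {total}")
            return dict(w)
        zs = sorted(pf.charge_states)
        return {z: 1.0 / len(zs) for z in zs}


def _default_species() -> dict[str, Proteoform]:
    return {
        "zymogen": Proteoform(id="zymogen", neutral_mass=ZYMOGEN_MASS_DA,
                              role="zymogen",
                              charge_states=frozenset(ZYMOGEN_CHARGES)),
        "mature": Proteoform(id="mature", neutral_mass=MATURE_MASS_DA,
                             role="mature",
                             charge_states=frozenset(MATURE_CHARGES)),
        "propeptide": Proteoform(id="propeptide",
                                 neutral_mass=PROPEPTIDE_MASS_DA,
                                 role="propeptide",
                                 charge_states=frozenset(PROPEPTIDE_CHARGES)),
    }


def internal_standard_proteoform() -> Proteoform:
    return Proteoform.from_sequence(
        "internal_standard", INTERNAL_STANDARD_SEQUENCE,
        role="internal_standard", charge_states=(1,))


def wild_type_scenario(km_uM: float = 4.5, kcat_per_s: float = 0.095,
                       z0_uM: float = 16.0, activator_uM: float = 0.16,
                       **kwargs) -> QfmsScenario:
    """The reference run: a single intact zymogen pool at 16 µM activated
    by 0.16 µM protease with Michaelis-Menten kinetics (K_m in the low-µM
    range, k_cat such that depletion is essentially complete within the
    40-min observation window)."""
    mm = MMActivationParams(km_uM=km_uM, kcat_per_s=kcat_per_s,
                            activator_uM=activator_uM, z0_uM=z0_uM)
    return QfmsScenario(mm=mm, species=_default_species(), **kwargs)


def _truth_courses(scenario: QfmsScenario, t: np.ndarray) -> dict[str, np.ndarray]:
    if scenario.network is None:
        tc = _act.mm_depletion(scenario.mm, t, method="ode")
        return {"zymogen": tc.zymogen, "mature": tc.mature,
                "propeptide": tc.propeptide}
    net = _act.simulate_species_network(scenario.network,
                                        scenario.mm.activator_uM, t)
    out = {s.name: net[s.name] for s in scenario.network.species}
    out["mature"] = net["mature"]
    out["propeptide"] = net["mature"] + net["degraded"]
    return out


def simulate_qfms_series(scenario: QfmsScenario, seed: int | None = 0,
                         ) -> tuple[SpectrumSeries, dict[str, np.ndarray]]:
    """Emit a centroided spectrum series for a scenario, together with the
    exact concentration courses used.

    Per scan, each (species, charge) contributes one centroid at its
    theoretical m/z (plus a small Gaussian jitter) with intensity
    concentration x response x envelope weight x counts-per-µM, perturbed
    by relative Gaussian noise truncated at zero; the internal standard
    contributes a constant-concentration centroid.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(scenario.duration_s / scenario.scan_interval_s)) + 1
    t = scenario.scan_interval_s * np.arange(n)
    truth = _truth_courses(scenario, t)
    truth = {**truth, "time_s": t}

    std_pf = internal_standard_proteoform()
    std_mz = mz_of(std_pf.neutral_mass, 1)
    std_resp = scenario.response.get("internal_standard", 1.0)

    drift = np.ones(n)
    if scenario.drift_amplitude:
        drift += scenario.drift_amplitude * t / t[-1]

    scans = []
    for j in range(n):
        mzs: list[float] = []
        intens: list[float] = []
        for name, pf in scenario.species.items():
            conc = truth[name][j]
            if conc <= 0:
                continue
            resp = scenario.response.get(name, 1.0)
            for z, w in scenario.weights_for(name).items():
                base = conc * resp * w * scenario.counts_per_uM * drift[j]
                inten = base * (1.0 + rng.normal(0.0, scenario.noise_rel))
                if inten <= 0:
                    continue
                mzs.append(mz_of(pf.neutral_mass, z)
                           + rng.normal(0.0, scenario.mz_jitter_Th))
                intens.append(inten)
        base = (scenario.standard_uM * std_resp * scenario.counts_per_uM
                * drift[j])
        inten = max(base * (1.0 + rng.normal(0.0, scenario.noise_rel)), 0.0)
        mzs.append(std_mz + rng.normal(0.0, scenario.mz_jitter_Th))
        intens.append(inten)
        scans.append((np.array(mzs), np.array(intens)))
    return SpectrumSeries(t, scans), truth
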