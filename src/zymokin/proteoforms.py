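"""Proteoform bookkeeping for zymogen-activation studies.

A zymogen (inactive protease precursor) carries an N-terminal propeptide
that is removed on maturation; recombinant preparations additionally
contain N-terminally truncated forms produced by non-specific proteolysis
during expression and purification.  This module tracks every such species
as a :class:`Proteoform` — sequence and/or average neutral mass, biological
role, and the ESI charge states under which it is observed — and provides
the mass arithmetic the downstream MS quantification relies on:

* average (isotope-abundance-weighted) peptide masses,
* m/z values of protonated ions,
* cleavage with exact mass balance (one water per peptide bond hydrolysed),
* classification of N-terminal truncation catalogs into activatable and
  non-activatable forms, and
* detection of proline-rich PxxP-periodic motifs (prolines spaced three
  residues apart, the polyproline-II-prone arrangement).

Average rather than monoisotopic masses are used throughout: the proteins
of interest are ~25 kDa species measured on a quadrupole/ToF instrument at
unit-ish resolution, where the isotope envelope centroid (the average
mass) is what a charge-state deconvolution reports.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PROTON_MASS",
    "Proteoform",
    "ConstructCatalog",
    "CatalogEntry",
    "TruncationForm",
    "MotifHit",
    "average_mass",
    "mz_of",
    "cleave",
    "enumerate_truncations",
    "activatable_fraction",
    "find_proline_rich_motif",
    "read_fasta",
    "proteoforms_to_json",
]

#: Average masses (Da) of the 20 standard amino-acid residues (i.e. the
#: monomer minus one water), IUPAC 2021 atomic weights.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Average mass of water (Da), added once per linear peptide.
WATER_MASS: float = 18.01528

#: Mass of the proton (Da) carried per positive charge in ESI.
PROTON_MASS: float = 1.00728

#: Allowed roles for a proteoform in an activation experiment.
ROLES = frozenset({
    "zymogen", "truncated_zymogen", "mature", "propeptide",
    "internal_fragment", "internal_standard",
})


def average_mass(sequence: str) -> float:
    """Average neutral mass (Da) of a linear peptide.

    Sum of residue average masses plus one water; the empty sequence
    returns the mass of water.  Raises ``ValueError`` naming the first
    unknown residue code and its 1-based position.
    """
    total = WATER_MASS
    for i, aa in enumerate(sequence):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i + 1}"
            ) from None
    return total


def mz_of(neutral_mass: float, z: int) -> float:
    """m/z (Th) of the z-fold protonated ion of a species of the given
    neutral mass: (M + z * m_proton) / z."""
    if not isinstance(z, (int,)) or isinstance(z, bool):
        raise TypeError(f"charge must be an integer, got {z!r}")
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class Proteoform:
    """One protein/peptide species with sequence and/or neutral mass.

    ``neutral_mass`` may be given without a sequence (MS-only species); if
    both are present they must agree to 0.01 Da.  ``charge_states`` lists
    the ESI charges under which the species is quantified.
    """

    id: str
    neutral_mass: float
    construct: str = ""
    sequence: str | None = None
    role: str = "zymogen"
    charge_states: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; valid: {sorted(ROLES)}")
        if self.sequence is not None:
            seq_mass = average_mass(self.sequence)
            if abs(seq_mass - self.neutral_mass) > 0.01:
                raise ValueError(
                    f"{self.id}: declared mass {self.neutral_mass:.3f} Da "
                    f"disagrees with sequence mass {seq_mass:.3f} Da"
                )
        else:
            log.warning(
                "proteoform %s has no sequence; mass-balance checks skipped",
                self.id,
            )
        if any(z < 1 for z in self.charge_states):
            raise ValueError("charge states must be positive integers")

    @classmethod
    def from_sequence(cls, id: str, sequence: str, *, construct: str = "",
                      role: str = "zymogen",
                      charge_states: Iterable[int] = ()) -> "Proteoform":
        return cls(id=id, neutral_mass=average_mass(sequence),
                   construct=construct, sequence=sequence, role=role,
                   charge_states=frozenset(charge_states))

    @property
    def mz_targets(self) -> dict[int, float]:
        """Target m/z per declared charge state."""
        return {z: mz_of(self.neutral_mass, z) for z in sorted(self.charge_states)}


def cleave(zymogen: Proteoform, site_index: int,
           *, propeptide_role: str = "propeptide",
           mature_role: str = "mature") -> tuple[Proteoform, Proteoform]:
    """Hydrolyse one peptide bond: split after residue ``site_index``
    (1-based index of the last residue of the N-terminal product).

    The two product sequences concatenate back to the input, and their
    masses sum to the input mass plus one water (the hydrolysis water).
    """
    if zymogen.sequence is None:
        raise ValueError(f"{zymogen.id}: cannot cleave a sequence-less proteoform")
    n = len(zymogen.sequence)
    if not 0 < site_index < n:
        raise ValueError(
            f"cleavage site {site_index} outside sequence of length {n}"
        )
    left = zymogen.sequence[:site_index]
    right = zymogen.sequence[site_index:]
    pro = Proteoform.from_sequence(
        f"{zymogen.id}/propeptide", left, construct=zymogen.construct,
        role=propeptide_role)
    mat = Proteoform.from_sequence(
        f"{zymogen.id}/mature", right, construct=zymogen.construct,
        role=mature_role)
    return pro, mat


# ---------------------------------------------------------------------------
# Truncation catalogs


@dataclass(frozen=True)
class CatalogEntry:
    """One observed N-terminal form: sequence (None when the band could not
    be identified) and its approximate abundance in percent."""

    sequence: str | None
    percent: float


@dataclass(frozen=True)
class ConstructCatalog:
    """Catalog of the N-terminal forms observed for one expression
    construct, with the sequence marker at which the mature protease
    domain begins (the IVGG... junction of trypsin-like proteases)."""

    construct: str
    entries: tuple[CatalogEntry, ...]
    mature_start: str = "IVGG"
    #: full known N-terminal sequence of the intact construct (cloning
    #: extension + propeptide + visible start of the mature domain)
    intact_sequence: str = ""

    def __post_init__(self) -> None:
        for e in self.entries:
            if not 0 <= e.percent <= 100:
                raise ValueError(f"percentage {e.percent} outside [0, 100]")
        total = sum(e.percent for e in self.entries)
        if abs(total - 100.0) > 1.0:
            raise ValueError(
                f"{self.construct}: form percentages sum to {total}, not 100 ± 1"
            )


@dataclass(frozen=True)
class TruncationForm:
    """A truncation proteoform with its abundance fraction and activation
    classification: 'activatable' (N-terminus at or before the mature
    domain start, so propeptide removal can still yield the native
    enzyme), 'non_activatable' (N-terminus inside the mature domain), or
    'unknown' (form not sequenced)."""

    proteoform: Proteoform | None
    fraction: float
    classification: str


# N-terminal extensions left by incomplete processing of the yeast
# secretion signal, observed in front of the cloning EF dipeptide.
_SIGNAL_REMNANTS = ("", "EA", "EAEA")


def _is_suffix_compatible(form: str, intact: str) -> bool:
    """True when ``form`` can be aligned as an N-terminal truncation of the
    known intact sequence: after an optional EA/EAEA signal-peptide
    remnant, the form must match a suffix of ``intact`` over their
    overlap (the form may extend past the known region at the C side,
    since only the start of the mature domain is recorded)."""
    for ext in _SIGNAL_REMNANTS:
        if not form.startswith(ext):
            continue
        core = form[len(ext):]
        offsets = [0] if ext else range(len(intact))
        for off in offsets:
            tail = intact[off:]
            overlap = min(len(core), len(tail))
            if overlap >= 2 and core[:overlap] == tail[:overlap]:
                return True
    return False


def enumerate_truncations(catalog: ConstructCatalog,
                          charge_states: Iterable[int] = ()) -> list[TruncationForm]:
    """Expand a construct catalog into classified truncation proteoforms.

    Each sequenced entry becomes a :class:`Proteoform` (role ``zymogen``
    for the intact form, ``truncated_zymogen`` otherwise — unless its
    N-terminus already lies inside the mature domain, in which case it is
    an ``internal_fragment`` and non-activatable).  Unsequenced entries
    yield classification ``'unknown'``.  Fractions are percent / 100.
    """
    if not catalog.intact_sequence:
        raise ValueError(f"{catalog.construct}: catalog lacks an intact sequence")
    forms: list[TruncationForm] = []
    zs = frozenset(charge_states)
    for i, entry in enumerate(catalog.entries):
        frac = entry.percent / 100.0
        if entry.sequence is None:
            forms.append(TruncationForm(None, frac, "unknown"))
            continue
        seq = entry.sequence
        if not _is_suffix_compatible(seq, catalog.intact_sequence):
            raise ValueError(
                f"{catalog.construct}: form {seq!r} is not a suffix-compatible "
                f"fragment of {catalog.intact_sequence!r}"
            )
        if catalog.mature_start in seq:
            # N-terminus at or before the mature-domain junction
            classification = "activatable"
            intact = seq == catalog.intact_sequence
            role = "zymogen" if intact else "truncated_zymogen"
        else:
            classification = "non_activatable"
            role = "internal_fragment"
        pf = Proteoform.from_sequence(
            f"{catalog.construct}/form{i}", seq, construct=catalog.construct,
            role=role, charge_states=zs)
        forms.append(TruncationForm(pf, frac, classification))
    return forms


def activatable_fraction(catalog: ConstructCatalog) -> float:
    """Percent of the preparation whose N-terminus still allows maturation
    into the native enzyme (unsequenced forms are not counted)."""
    forms = enumerate_truncations(catalog)
    return 100.0 * sum(f.fraction for f in forms
                       if f.classification == "activatable")


# ---------------------------------------------------------------------------
# Proline-rich motifs


@dataclass(frozen=True)
class MotifHit:
    """A maximal run of prolines spaced three residues apart.

    ``positions`` are 1-based within the scanned sequence; ``motif`` is the
    schematic string ('PxxP', 'PxxPxxP', ...); ``span`` is the (start, end)
    1-based inclusive range from the first to the last proline.
    """

    positions: tuple[int, ...]
    motif: str
    span: tuple[int, int]


def find_proline_rich_motif(sequence: str, min_prolines: int = 2) -> list[MotifHit]:
    """Find maximal PxxP-periodic proline runs (spacing exactly 3).

    Prolines at positions p, p+3, p+6, ... form one run; only runs of at
    least ``min_prolines`` prolines are reported.  Adjacent prolines
    (spacing 1 or 2) do not satisfy the period and are ignored.
    """
    pros = [i + 1 for i, aa in enumerate(sequence) if aa == "P"]
    pro_set = set(pros)
    hits: list[MotifHit] = []
    for p in pros:
        if p - 3 in pro_set:
            continue  # not the start of a maximal run
        run = [p]
        while run[-1] + 3 in pro_set:
            run.append(run[-1] + 3)
        if len(run) >= min_prolines:
            motif = "P" + "xxP" * (len(run) - 1)
            hits.append(MotifHit(tuple(run), motif, (run[0], run[-1])))
    return hits


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    """Read amino-acid sequences from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def proteoforms_to_json(forms: Sequence[TruncationForm]) -> str:
    """Serialize classified truncation forms (id, sequence, mass, role,
    charges, fraction, classification) to a JSON string."""
    rows = []
    for f in forms:
        pf = f.proteoform
        rows.append({
            "id": pf.id if pf else None,
            "sequence": pf.sequence if pf else None,
            "neutral_mass_da": round(pf.neutral_mass, 3) if pf else None,
            "role": pf.role if pf else None,
            "charge_states": sorted(pf.charge_states) if pf else [],
            "fraction": f.fraction,
            "classification": f.classification,
        })
    return json.dumps(rows, indent=2)
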