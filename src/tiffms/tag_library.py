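"""The 3D-tag spectral library: (peptide, charge, CV) entries with accurate
monoisotopic mass and a reference retention time.

Each entry is one "3D tag": the (retention time, accurate mass, FAIMS CV)
triple that uniquely characterizes a peptide species observed in high-input
library runs acquired one CV at a time.  The library also carries species
provenance (e.g. a target and an entrapment species) so that false-transfer
rates can be estimated downstream.

Masses are neutral monoisotopic masses; the matcher converts a feature's
(mono m/z, z) to neutral mass via m*z - z*1.007276, which keeps the ppm
tolerance charge-consistent.
"""

from __future__ import annotations

import json
import logging
import re
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pymass

from .mzml_io import round_cv

logger = logging.getLogger("tiffms")

#: Proton mass used for m/z <-> neutral-mass conversion (Da).
PROTON_MASS = 1.007276

#: Monoisotopic mass of water (Da), added once per peptide chain.
WATER_MASS = 18.0105646863

#: Fixed carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.02146
#: Variable oxidation of methionine, Da.
OXIDATION = 15.99491
#: Variable N-terminal acetylation, Da.
ACETYL = 42.01057

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = dict(_pymass.std_aa_mass)

_MOD_RE = re.compile(r"\(([a-z]+)\)")


def peptide_mono_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of a modified peptide sequence.

    The grammar is MaxQuant-like: an optional leading ``(ac)`` marks
    N-terminal acetylation, ``M(ox)`` marks oxidized methionine, and every
    cysteine implicitly carries the fixed carbamidomethyl modification.

    >>> round(peptide_mono_mass("PEPTIDE"), 4)
    799.3599
    """
    seq = peptide.strip()
    mass = WATER_MASS
    if seq.startswith("(ac)"):
        mass += ACETYL
        seq = seq[4:]
    i = 0
    while i < len(seq):
        aa = seq[i]
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} in peptide {peptide!r}")
        mass += RESIDUE_MASS[aa]
        if aa == "C":
            mass += CARBAMIDOMETHYL
        i += 1
        if i < len(seq) and seq[i] == "(":
            m = _MOD_RE.match(seq, i)
            if m is None:
                raise ValueError(f"malformed modification token in {peptide!r}")
            mod = m.group(1)
            if mod == "ox":
                if aa != "M":
                    raise ValueError(f"oxidation on non-methionine residue {aa!r} in {peptide!r}")
                mass += OXIDATION
            else:
                raise ValueError(f"unknown modification token ({mod}) in {peptide!r}")
            i = m.end()
    return mass


def neutral_mass(mono_mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from monoisotopic m/z and charge."""
    return mono_mz * charge - charge * PROTON_MASS


def mz_from_mass(mono_mass: float, charge: int) -> float:
    """Monoisotopic m/z of a neutral mass at the given charge."""
    return (mono_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class LibraryEntry:
    """One 3D tag: a peptide ion with its reference RT and FAIMS CV."""

    peptide: str
    charge: int                    # 2..7 (precursor selection window)
    mono_mass: float               # Da, neutral
    ref_rt: float                  # minutes
    cv: float | None               # volts
    proteins: tuple[str, ...]
    species: str
    lib_intensity: float | None = None
    n_obs: int = 1

    @property
    def key(self) -> tuple[str, int, float | None]:
        return (self.peptide, self.charge, self.cv)


class SpectralLibrary:
    """Mass-indexed container of :class:`LibraryEntry` objects.

    Entries are unique on (peptide, charge, cv).  A per-CV mass-sorted index
    supports binary-search mass-window queries; a pooled index serves
    CV-agnostic (2D) queries.
    """

    def __init__(self, entries: list[LibraryEntry]):
        seen = set()
        for e in entries:
            if e.key in seen:
                raise ValueError(f"duplicate library entry {e.key}")
            seen.add(e.key)
        self.entries = sorted(
            entries, key=lambda e: (e.cv is not None, e.cv or 0.0, e.mono_mass,
                                    e.peptide, e.charge))
        self._by_key = {e.key: e for e in self.entries}
        self.cv_index: dict[float | None, np.ndarray] = {}
        self._cv_masses: dict[float | None, np.ndarray] = {}
        by_cv: dict[float | None, list[int]] = {}
        for i, e in enumerate(self.entries):
            by_cv.setdefault(e.cv, []).append(i)
        for cv, idx in by_cv.items():
            idx = sorted(idx, key=lambda i: self.entries[i].mono_mass)
            self.cv_index[cv] = np.asarray(idx, dtype=int)
            self._cv_masses[cv] = np.asarray([self.entries[i].mono_mass for i in idx])
        self._all_order = np.argsort([e.mono_mass for e in self.entries], kind="stable")
        self._all_masses = np.asarray([self.entries[i].mono_mass for i in self._all_order])

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key) -> LibraryEntry:
        return self._by_key[key]

    @property
    def gradient_span(self) -> tuple[float, float]:
        rts = [e.ref_rt for e in self.entries]
        return (min(rts), max(rts)) if rts else (0.0, 0.0)

    @property
    def species_counts(self) -> dict[str, int]:
        return dict(Counter(e.species for e in self.entries))

    def species_peptide_counts(self) -> dict[str, int]:
        """Distinct peptide sequences per species (entrapment bookkeeping)."""
        out: dict[str, set] = {}
        for e in self.entries:
            out.setdefault(e.species, set()).add(e.peptide)
        return {sp: len(peps) for sp, peps in out.items()}

    def query_mass_window(self, cv: float | None, mass_lo: float, mass_hi: float,
                          any_cv: bool = False) -> list[LibraryEntry]:
        """Entries with the given CV and mono_mass in [mass_lo, mass_hi] (closed).

        With ``any_cv=True`` the CV is ignored and the pooled index is used.
        """
        if any_cv:
            masses, order = self._all_masses, self._all_order
        else:
            cv = round_cv(cv)
            if cv not in self.cv_index:
                return []
            masses, order = self._cv_masses[cv], self.cv_index[cv]
        lo = bisect_left(masses, mass_lo)
        hi = bisect_right(masses, mass_hi)
        return [self.entries[i] for i in order[lo:hi]]


def build_library(id_tables: dict[str, pd.DataFrame | str],
                  run_cv_map: dict[str, float | None]) -> SpectralLibrary:
    """Build a spectral library from per-run identification tables.

    Each table (DataFrame or TSV path) must carry columns ``peptide``,
    ``charge``, ``rt``, ``proteins`` (semicolon-separated accessions) and
    ``species``; an optional ``intensity`` column feeds lib_intensity.
    Duplicate (peptide, charge, cv) observations across runs are merged:
    ref_rt and lib_intensity become medians, n_obs accumulates.  Rows with
    charge outside 2..7 are skipped with a warning (precursor selection only
    sampled +2..+7); peptide sequences shared between species are dropped to
    keep entrapment accounting unambiguous.
    """
    obs: dict[tuple, dict] = {}
    for run_id in sorted(id_tables):
        if run_id not in run_cv_map:
            raise ValueError(f"identification table for run {run_id!r} has no known CV")
        cv = round_cv(run_cv_map[run_id])
        table = id_tables[run_id]
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", comment="#")
        for row in table.itertuples(index=False):
            charge = int(row.charge)
            if not 2 <= charge <= 7:
                logger.warning("run %s: peptide %s charge %d outside 2..7, row skipped",
                               run_id, row.peptide, charge)
                continue
            key = (str(row.peptide), charge, cv)
            rec = obs.setdefault(key, {"rts": [], "ints": [], "proteins": set(),
                                       "species": set()})
            rec["rts"].append(float(row.rt))
            if hasattr(row, "intensity") and not pd.isna(row.intensity):
                rec["ints"].append(float(row.intensity))
            rec["proteins"].update(str(row.proteins).split(";"))
            rec["species"].add(str(row.species))

    shared = {key[0] for key, rec in obs.items() if len(rec["species"]) > 1}
    by_pep_species: dict[str, set] = {}
    for (pep, _, _), rec in obs.items():
        by_pep_species.setdefault(pep, set()).update(rec["species"])
    shared |= {pep for pep, sps in by_pep_species.items() if len(sps) > 1}
    if shared:
        logger.warning("%d peptide sequences shared between species dropped from library",
                       len(shared))

    entries = []
    for (pep, charge, cv), rec in obs.items():
        if pep in shared:
            continue
        entries.append(LibraryEntry(
            peptide=pep, charge=charge, cv=cv,
            mono_mass=peptide_mono_mass(pep),
            ref_rt=float(np.median(rec["rts"])),
            proteins=tuple(sorted(rec["proteins"])),
            species=next(iter(rec["species"])),
            lib_intensity=float(np.median(rec["ints"])) if rec["ints"] else None,
            n_obs=len(rec["rts"]),
        ))
    return SpectralLibrary(entries)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ["peptide", "charge", "cv", "mono_mass", "ref_rt", "proteins",
                "species", "lib_intensity", "n_obs"]


def library_to_frame(library: SpectralLibrary) -> pd.DataFrame:
    rows = [{
        "peptide": e.peptide, "charge": e.charge, "cv": e.cv,
        "mono_mass": e.mono_mass, "ref_rt": e.ref_rt,
        "proteins": ";".join(e.proteins), "species": e.species,
        "lib_intensity": e.lib_intensity, "n_obs": e.n_obs,
    } for e in library.entries]
    return pd.DataFrame(rows, columns=_LIB_COLUMNS)


def write_library(library: SpectralLibrary, path, sidecar_path=None,
                  header_lines: list[str] | None = None) -> None:
    """Write the library as TSV plus a small JSON metadata sidecar."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        library_to_frame(library).to_csv(fh, sep="\t", index=False, na_rep="NA",
                                         lineterminator="\n")
    if sidecar_path is not None:
        meta = {"n_entries": len(library),
                "gradient_span": list(library.gradient_span),
                "species_counts": library.species_counts,
                "species_peptide_counts": library.species_peptide_counts()}
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_library(path) -> SpectralLibrary:
    frame = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for row in frame.itertuples(index=False):
        entries.append(LibraryEntry(
            peptide=str(row.peptide), charge=int(row.charge),
            cv=None if pd.isna(row.cv) else float(row.cv),
            mono_mass=float(row.mono_mass), ref_rt=float(row.ref_rt),
            proteins=tuple(str(row.proteins).split(";")),
            species=str(row.species),
            lib_intensity=None if pd.isna(row.lib_intensity) else float(row.lib_intensity),
            n_obs=int(row.n_obs)))
    return SpectralLibrary(entries)


__all__ = [
    "PROTON_MASS", "WATER_MASS", "CARBAMIDOMETHYL", "OXIDATION", "ACETYL",
    "RESIDUE_MASS", "peptide_mono_mass", "neutral_mass", "mz_from_mass",
    "LibraryEntry", "SpectralLibrary", "build_library",
    "library_to_frame", "write_library", "read_library",
]
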