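"""Entrapment-based false-transfer estimation.

The library mixes a target species (present in the sample) with an
entrapment species known to be absent (e.g. a bacterial digest spiked into
a human library).  Every accepted match to an entrapment peptide is a
demonstrable false transfer, so the entrapment fraction of accepted
identifications estimates the false-match rate (FMR).

Because an entrapment hit only samples the decoy fraction of the
confusable search space, the report also carries a composition-corrected
estimate ``fmr_corrected = fmr * (1 + target/entrapment library size)``,
capped at 1.  Both numbers plus the raw counts are reported so either
convention can be recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

from .feature_finder import Ms1Feature
from .matcher import MatchParams, MatchResult, transfer_ids
from .rt_alignment import AlignmentModel
from .tag_library import SpectralLibrary


@dataclass
class EntrapmentReport:
    """Peptide- and protein-level entrapment false-match estimates."""

    n_total_accepted: int
    n_entrap_accepted: int
    fmr: float
    fmr_corrected: float
    library_target_size: int
    library_entrap_size: int
    protein_n_total: int | None = None
    protein_n_entrap: int | None = None
    protein_fdr: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _species_of(library: SpectralLibrary, key: tuple) -> str:
    return library[key].species


def _check_mixed(library: SpectralLibrary, entrap_species: str) -> tuple[int, int]:
    counts = library.species_peptide_counts()
    if len(counts) < 2:
        raise ValueError("entrapment requires a mixed-species library")
    if entrap_species not in counts:
        raise ValueError(f"entrapment species {entrap_species!r} not in library "
                         f"(has {sorted(counts)})")
    entrap = counts[entrap_species]
    target = sum(n for sp, n in counts.items() if sp != entrap_species)
    return target, entrap


def peptide_fmr(matches: list[MatchResult], library: SpectralLibrary,
                entrap_species: str, charge_resolved: bool = False,
                ) -> EntrapmentReport:
    """Peptide-level false-match rate from accepted matches.

    Distinct peptides are counted per species — by sequence alone by default,
    or by (sequence, charge) with ``charge_resolved=True``.
    """
    target_size, entrap_size = _check_mixed(library, entrap_species)
    seen: set = set()
    entrap: set = set()
    for r in matches:
        if not r.accepted:
            continue
        entry = library[r.entry_key]
        pep = (entry.peptide, entry.charge) if charge_resolved else entry.peptide
        seen.add(pep)
        if entry.species == entrap_species:
            entrap.add(pep)
    n_total, n_entrap = len(seen), len(entrap)
    fmr = n_entrap / n_total if n_total else 0.0
    corrected = min(1.0, fmr * (1.0 + target_size / entrap_size)) if entrap_size else fmr
    return EntrapmentReport(
        n_total_accepted=n_total, n_entrap_accepted=n_entrap,
        fmr=fmr, fmr_corrected=corrected,
        library_target_size=target_size, library_entrap_size=entrap_size)


def protein_fdr(matches: list[MatchResult], library: SpectralLibrary,
                entrap_species: str, protein_map: dict[str, tuple] | None = None,
                ) -> EntrapmentReport:
    """Protein-level entrapment FDR.

    A protein counts as entrapment iff *all* of its accepted peptides belong
    to the entrapment species.  ``protein_map`` (peptide -> protein
    accessions) defaults to the library's own annotations.
    """
    report = peptide_fmr(matches, library, entrap_species)
    proteins: dict[str, set] = {}
    for r in matches:
        if not r.accepted:
            continue
        entry = library[r.entry_key]
        accs = protein_map.get(entry.peptide, entry.proteins) if protein_map else entry.proteins
        for acc in accs:
            proteins.setdefault(acc, set()).add(entry.species)
    n_total = len(proteins)
    n_entrap = sum(1 for sps in proteins.values() if sps == {entrap_species})
    return replace(report,
                   protein_n_total=n_total, protein_n_entrap=n_entrap,
                   protein_fdr=n_entrap / n_total if n_total else 0.0)


def compare_modes(features: list[Ms1Feature], library: SpectralLibrary,
                  model: AlignmentModel, params: MatchParams,
                  entrap_species: str) -> dict[str, EntrapmentReport]:
    """Run identity transfer in 2D (CV disabled) and 3D (CV enabled) modes.

    Both modes see identical features, library and alignment model; only the
    CV-matching switch differs, mirroring how the FAIMS matching function is
    toggled in the underlying search engine.
    """
    out = {}
    for label, use_cv in (("2d", False), ("3d", True)):
        mode_params = replace(params, use_cv=use_cv)
        results = transfer_ids(features, library, model, mode_params)
        out[label] = protein_fdr(results, library, entrap_species)
    return out


def write_report(reports: dict[str, EntrapmentReport], path,
                 extra: dict | None = None) -> None:
    payload = {label: rep.to_dict() for label, rep in reports.items()}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
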