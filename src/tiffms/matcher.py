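"""Identity transfer: match run features to library 3D tags.

A feature is matched to library entries of the same charge whose neutral
mass agrees within a ppm tolerance (6 ppm default, computed on neutral
monoisotopic mass) and whose reference RT lies within a tight window
(0.4 min default) of the feature's *aligned* RT.  In 3D mode the FAIMS CV
must additionally agree — the third matching coordinate that distinguishes
this method from conventional 2D (mass, RT) match-between-runs.

Conflicts are resolved on a normalized distance
``sqrt((ppm/ppm_tol)^2 + (dRT/rt_window)^2)``: the best candidate is
accepted only when clearly ahead of the runner-up, and a library entry may
be claimed by at most one feature per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .feature_finder import Ms1Feature
from .mzml_io import round_cv
from .rt_alignment import AlignmentModel
from .tag_library import LibraryEntry, SpectralLibrary, neutral_mass


@dataclass(frozen=True)
class MatchParams:
    """Acceptance region and conflict-resolution tunables."""

    ppm_tol: float = 6.0          # ppm, on neutral mass, closed interval
    rt_window: float = 0.4        # minutes, on aligned RT, closed interval
    use_cv: bool = True           # 3D (True) vs 2D (False) matching
    cv_tol: float = 0.0           # volts, after 0.1-V rounding
    min_charge: int = 2           # singly charged features never matched
    ambiguity_ratio: float = 0.8  # best must beat runner-up by this factor
    unique_entries: bool = True   # an entry matches at most one feature per run

    def __post_init__(self):
        if self.ppm_tol <= 0 or self.rt_window <= 0 or self.cv_tol < 0:
            raise ValueError("ppm_tol and rt_window must be > 0, cv_tol >= 0")


@dataclass
class MatchResult:
    """One feature <-> entry pairing, accepted or rejected."""

    feature_id: str
    entry_key: tuple               # (peptide, charge, cv)
    ppm_error: float               # signed, feature vs entry neutral mass
    delta_rt: float                # signed minutes, aligned RT - ref RT
    distance: float
    accepted: bool
    n_candidates: int
    run_id: str = ""
    cv: float | None = None


def _distance(ppm_error: float, delta_rt: float, params: MatchParams) -> float:
    return math.sqrt((ppm_error / params.ppm_tol) ** 2
                     + (delta_rt / params.rt_window) ** 2)


def _cv_compatible(feature_cv: float | None, entry_cv: float | None,
                   params: MatchParams) -> bool:
    if not params.use_cv:
        return True
    if feature_cv is None or entry_cv is None:
        return False
    return abs(feature_cv - entry_cv) <= params.cv_tol + 1e-9


def find_candidates(feature: Ms1Feature, library: SpectralLibrary,
                    model: AlignmentModel, params: MatchParams | None = None,
                    ) -> list[tuple[LibraryEntry, float, float]]:
    """Library entries compatible with a feature, with signed errors.

    Returns (entry, ppm_error, delta_rt) triples for entries of matching
    charge within the closed ppm and RT windows (and same CV in 3D mode).
    """
    params = params or MatchParams()
    if feature.charge < params.min_charge:
        return []
    cv = round_cv(feature.cv)
    if params.use_cv and cv is None:
        return []
    rt_aligned = (feature.rt_aligned if feature.rt_aligned is not None
                  else float(model.predict(feature.rt_apex)))
    mass = neutral_mass(feature.mono_mz, feature.charge)
    tol = mass * params.ppm_tol * 1e-6
    if params.use_cv and params.cv_tol == 0:
        pool = library.query_mass_window(cv, mass - tol, mass + tol)
    else:
        pool = library.query_mass_window(None, mass - tol, mass + tol, any_cv=True)
    out = []
    for entry in pool:
        if entry.charge != feature.charge:
            continue
        if not _cv_compatible(cv, entry.cv, params):
            continue
        ppm_error = (mass - entry.mono_mass) / entry.mono_mass * 1e6
        if abs(ppm_error) > params.ppm_tol:
            continue
        delta_rt = rt_aligned - entry.ref_rt
        if abs(delta_rt) > params.rt_window:
            continue
        out.append((entry, ppm_error, delta_rt))
    out.sort(key=lambda c: (_distance(c[1], c[2], params),
                            -(c[0].lib_intensity or 0.0), c[0].peptide))
    return out


def resolve(feature: Ms1Feature, candidates: list, params: MatchParams | None = None,
            ) -> MatchResult | None:
    """Pick the winning candidate, or reject the match as ambiguous.

    A single candidate is accepted outright.  With several, the minimum-
    distance candidate is accepted only if its distance is strictly below
    ``ambiguity_ratio`` times the runner-up's; otherwise the result is kept
    but marked rejected.  Candidate order ties are broken by higher library
    intensity, then lexicographic peptide.
    """
    params = params or MatchParams()
    if not candidates:
        return None
    entry, ppm_error, delta_rt = candidates[0]
    dist = _distance(ppm_error, delta_rt, params)
    if len(candidates) == 1:
        accepted = True
    else:
        runner_up = _distance(candidates[1][1], candidates[1][2], params)
        accepted = dist < params.ambiguity_ratio * runner_up
    return MatchResult(
        feature_id=feature.feature_id, entry_key=entry.key,
        ppm_error=ppm_error, delta_rt=delta_rt, distance=dist,
        accepted=accepted, n_candidates=len(candidates),
        run_id=feature.run_id, cv=round_cv(feature.cv))


def transfer_ids(features: list[Ms1Feature], library: SpectralLibrary,
                 model: AlignmentModel, params: MatchParams | None = None,
                 ) -> list[MatchResult]:
    """Match every candidate-bearing feature of a run against the library.

    Returns one :class:`MatchResult` per feature with at least one candidate.
    Accepted matches are one-to-one: when several features claim the same
    entry, the smallest-distance claim survives and the others are demoted to
    rejected (ambiguous) status.
    """
    params = params or MatchParams()
    results: list[MatchResult] = []
    for f in sorted(features, key=lambda f: f.feature_id):
        res = resolve(f, find_candidates(f, library, model, params), params)
        if res is not None:
            results.append(res)

    if params.unique_entries:
        claims: dict[tuple, list[int]] = {}
        for i, r in enumerate(results):
            if r.accepted:
                claims.setdefault(r.entry_key, []).append(i)
        for key, idxs in claims.items():
            if len(idxs) > 1:
                idxs.sort(key=lambda i: (results[i].distance, results[i].feature_id))
                for i in idxs[1:]:
                    results[i] = replace(results[i], accepted=False)
    return results


def accepted(results: list[MatchResult]) -> list[MatchResult]:
    """Convenience filter for accepted matches."""
    return [r for r in results if r.accepted]


# ---------------------------------------------------------------------------
# Match table I/O
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = ["run_id", "cv", "feature_id", "peptide", "charge", "entry_cv",
                  "ppm_error", "delta_rt", "distance", "accepted", "n_candidates",
                  "species"]


def matches_to_frame(results: list[MatchResult], library: SpectralLibrary):
    import pandas as pd

    rows = []
    for r in results:
        entry = library[r.entry_key]
        rows.append({
            "run_id": r.run_id, "cv": r.cv, "feature_id": r.feature_id,
            "peptide": entry.peptide, "charge": entry.charge, "entry_cv": entry.cv,
            "ppm_error": r.ppm_error, "delta_rt": r.delta_rt,
            "distance": r.distance, "accepted": r.accepted,
            "n_candidates": r.n_candidates, "species": entry.species,
        })
    return pd.DataFrame(rows, columns=_MATCH_COLUMNS)


def write_matches(results: list[MatchResult], library: SpectralLibrary, path,
                  header_lines: list[str] | None = None) -> None:
    frame = matches_to_frame(results, library)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")
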