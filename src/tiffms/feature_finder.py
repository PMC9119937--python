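"""MS1 feature detection: XIC tracing and isotope-envelope assembly.

An MS1 feature is a peptide-like ion signal traced over retention time and
resolved into an isotope envelope: a set of co-eluting chromatographic
traces spaced by 1.003355/z Da (the 13C-12C mass difference divided by the
charge).  Features carry monoisotopic m/z, charge, RT span/apex, summed
intensity and a signal-to-noise ratio — the objects that are matched
against the 3D-tag library downstream.

The assembler is deliberately transparent: greedy, seeded at the most
intense unassigned trace, testing charges high to low and accepting the
first charge that explains at least two traces.  On small inputs it is
checked against an exhaustive search (see tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mzml_io import Run

#: 13C - 12C monoisotopic mass difference (Da).
ISOTOPE_SPACING = 1.003355


@dataclass
class FinderParams:
    """Tunables for tracing and envelope assembly."""

    trace_ppm: float = 10.0        # m/z agreement within an XIC trace
    min_scans: int = 3             # minimum consecutive scans per trace
    isotope_spacing: float = ISOTOPE_SPACING  # Da
    spacing_tol: float = 0.01      # Da, tolerance on isotope spacing
    max_charge: int = 7            # highest charge tested (+2..+7 precursor selection)

    def __post_init__(self) -> None:
        if min(self.trace_ppm, self.spacing_tol, self.isotope_spacing) <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_charge < 1 or self.min_scans < 1:
            raise ValueError("max_charge and min_scans must be >= 1")


@dataclass
class Xic:
    """One extracted-ion chromatogram trace."""

    mz: float                       # intensity-weighted mean m/z
    rts: np.ndarray                 # minutes, one per scan
    intensities: np.ndarray
    peak_refs: list[tuple[int, int]]  # (scan index in run, peak index in scan)

    @property
    def rt_start(self) -> float:
        return float(self.rts[0])

    @property
    def rt_end(self) -> float:
        return float(self.rts[-1])

    @property
    def rt_apex(self) -> float:
        return float(self.rts[int(np.argmax(self.intensities))])

    @property
    def apex_intensity(self) -> float:
        return float(np.max(self.intensities))

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.intensities))

    def overlaps(self, other: "Xic") -> bool:
        return self.rt_start <= other.rt_end and other.rt_start <= self.rt_end


@dataclass
class Ms1Feature:
    """A detected LC-MS feature (isotope envelope traced over RT)."""

    feature_id: str
    mono_mz: float                 # Th
    charge: int
    rt_apex: float                 # minutes
    rt_start: float
    rt_end: float
    intensity: float               # summed over member traces and scans
    snr: float = 0.0
    cv: float | None = None        # volts
    n_isotopes: int = 1
    run_id: str = ""
    low_confidence: bool = False   # single-trace feature, charge defaulted to 1
    rt_aligned: float | None = None
    extrapolated: bool = False
    trace_indices: tuple[int, ...] = field(default_factory=tuple, repr=False)

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValueError(f"{self.feature_id}: rt_apex outside [rt_start, rt_end]")
        if self.charge < 1 or self.n_isotopes < 1:
            raise ValueError(f"{self.feature_id}: charge and n_isotopes must be >= 1")


# ---------------------------------------------------------------------------
# XIC tracing
# ---------------------------------------------------------------------------

def trace_xics(run: Run, params: FinderParams | None = None) -> list[Xic]:
    """Group centroid peaks into XIC traces.

    Peaks agree within ``trace_ppm`` of the trace's running intensity-weighted
    mean m/z and must appear in consecutive scans; traces shorter than
    ``min_scans`` are discarded.  Every input peak joins at most one trace.
    """
    params = params or FinderParams()
    open_traces: list[dict] = []   # {'mz_sum','w_sum','mz','rts','ints','refs','last'}
    closed: list[dict] = []

    for si, spec in enumerate(run.spectra):
        mzs, ints = spec.mz, spec.intensity
        taken = np.zeros(mzs.size, dtype=bool)
        still_open = []
        for tr in open_traces:
            if tr["last"] != si - 1:
                closed.append(tr)
                continue
            tol = tr["mz"] * params.trace_ppm * 1e-6
            j = int(np.searchsorted(mzs, tr["mz"]))
            best, best_d = -1, tol
            for k in (j - 1, j):
                if 0 <= k < mzs.size and not taken[k]:
                    d = abs(mzs[k] - tr["mz"])
                    if d <= best_d:
                        best, best_d = k, d
            if best >= 0:
                taken[best] = True
                w = max(ints[best], 1e-12)
                tr["mz_sum"] += mzs[best] * w
                tr["w_sum"] += w
                tr["mz"] = tr["mz_sum"] / tr["w_sum"]
                tr["rts"].append(spec.rt)
                tr["ints"].append(ints[best])
                tr["refs"].append((si, best))
                tr["last"] = si
                still_open.append(tr)
            else:
                closed.append(tr)
        open_traces = still_open
        for k in np.flatnonzero(~taken):
            w = max(ints[k], 1e-12)
            open_traces.append({
                "mz_sum": mzs[k] * w, "w_sum": w, "mz": mzs[k],
                "rts": [spec.rt], "ints": [ints[k]],
                "refs": [(si, int(k))], "last": si,
            })
    closed.extend(open_traces)

    traces = [
        Xic(mz=tr["mz"], rts=np.asarray(tr["rts"]), intensities=np.asarray(tr["ints"]),
            peak_refs=tr["refs"])
        for tr in closed if len(tr["rts"]) >= params.min_scans
    ]
    traces.sort(key=lambda t: (t.mz, t.rt_start))
    return traces


# ---------------------------------------------------------------------------
# Envelope assembly
# ---------------------------------------------------------------------------

def _extend_chain(seed_idx: int, traces: list[Xic], assigned: np.ndarray,
                  charge: int, params: FinderParams) -> list[int]:
    """Maximal isotope chain through the seed at the given charge.

    Walks down and up in m/z in steps of isotope_spacing/charge, picking the
    nearest unassigned, co-eluting trace within spacing_tol at each step.
    """
    step = params.isotope_spacing / charge
    seed = traces[seed_idx]
    chain = [seed_idx]
    for direction in (-1, +1):
        k = direction
        while True:
            target = seed.mz + k * step
            best, best_d = -1, params.spacing_tol
            for j, tr in enumerate(traces):
                if assigned[j] or j in chain:
                    continue
                d = abs(tr.mz - target)
                if d <= best_d and tr.overlaps(seed):
                    best, best_d = j, d
            if best < 0:
                break
            chain.append(best)
            k += direction
    return sorted(chain, key=lambda j: traces[j].mz)


def assemble_envelopes(traces: list[Xic], params: FinderParams | None = None,
                       cv: float | None = None, run_id: str = "") -> list[Ms1Feature]:
    """Greedy isotope-envelope assembly.

    Seeds at the most intense unassigned trace; charges are tested from
    ``max_charge`` down to 1 and the first charge explaining >= 2 traces is
    accepted.  A lone trace becomes a singly charged, low-confidence feature.
    The monoisotopic m/z is the lowest-m/z member; intensity sums members.
    """
    params = params or FinderParams()
    assigned = np.zeros(len(traces), dtype=bool)
    order = sorted(range(len(traces)),
                   key=lambda j: (-traces[j].total_intensity, traces[j].mz))
    features: list[Ms1Feature] = []
    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        chosen_chain, chosen_z = [seed_idx], 1
        for z in range(params.max_charge, 0, -1):
            chain = _extend_chain(seed_idx, traces, assigned, z, params)
            if len(chain) >= 2:
                chosen_chain, chosen_z = chain, z
                break
        members = [traces[j] for j in chosen_chain]
        for j in chosen_chain:
            assigned[j] = True
        apex_trace = max(members, key=lambda t: t.apex_intensity)
        features.append(Ms1Feature(
            feature_id=f"F{len(features):05d}",
            mono_mz=members[0].mz,
            charge=chosen_z,
            rt_apex=apex_trace.rt_apex,
            rt_start=min(t.rt_start for t in members),
            rt_end=max(t.rt_end for t in members),
            intensity=sum(t.total_intensity for t in members),
            cv=cv,
            n_isotopes=len(members),
            run_id=run_id,
            low_confidence=len(members) == 1,
            trace_indices=tuple(chosen_chain),
        ))
    features.sort(key=lambda f: (f.mono_mz, f.rt_apex))
    for i, f in enumerate(features):
        f.feature_id = f"F{i:05d}"
    return features


# ---------------------------------------------------------------------------
# Signal-to-noise
# ---------------------------------------------------------------------------

def compute_snr(feature: Ms1Feature, run: Run, traces: list[Xic],
                all_features: list[Ms1Feature] | None = None) -> float:
    """S/N = apex peak intensity / median intensity of unassigned peaks.

    "Unassigned" means centroid peaks in the feature's apex spectrum that do
    not belong to any envelope (of ``all_features`` when given, else of the
    feature alone).  The noise floor is 1 count.
    """
    member = [traces[j] for j in feature.trace_indices]
    apex_trace = max(member, key=lambda t: t.apex_intensity)
    apex_scan = apex_trace.peak_refs[int(np.argmax(apex_trace.intensities))][0]
    apex_intensity = apex_trace.apex_intensity

    assigned_in_scan: set[int] = set()
    pool = all_features if all_features is not None else [feature]
    for f in pool:
        for j in f.trace_indices:
            for si, pi in traces[j].peak_refs:
                if si == apex_scan:
                    assigned_in_scan.add(pi)
    spec = run.spectra[apex_scan]
    noise_peaks = [spec.intensity[i] for i in range(spec.mz.size)
                   if i not in assigned_in_scan]
    noise = max(float(np.median(noise_peaks)) if noise_peaks else 0.0, 1.0)
    return apex_intensity / noise


def detect_features(run: Run, params: FinderParams | None = None) -> list[Ms1Feature]:
    """Full detection pipeline for a single-CV (or CV-less) run."""
    params = params or FinderParams()
    cvs = run.cv_set
    if len(cvs) > 1:
        raise ValueError(
            f"run {run.run_id} carries {len(cvs)} CVs; demultiplex with "
            "split_by_cv before feature detection")
    cv = next(iter(cvs)) if cvs else None
    traces = trace_xics(run, params)
    features = assemble_envelopes(traces, params, cv=cv, run_id=run.run_id)
    for f in features:
        f.snr = compute_snr(f, run, traces, all_features=features)
    return features


def filter_multiply_charged(features: list[Ms1Feature]) -> list[Ms1Feature]:
    """Keep features with charge >= 2, preserving order."""
    return [f for f in features if f.charge >= 2]


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["feature_id", "run_id", "cv", "mono_mz", "charge", "rt_apex",
                    "rt_start", "rt_end", "intensity", "snr", "n_isotopes"]


def features_to_frame(features: list[Ms1Feature]):
    import pandas as pd

    return pd.DataFrame(
        [{c: getattr(f, c) for c in _FEATURE_COLUMNS} for f in features],
        columns=_FEATURE_COLUMNS,
    )


def write_features(features: list[Ms1Feature], path, header_lines: list[str] | None = None) -> None:
    frame = features_to_frame(features)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_features(path) -> list[Ms1Feature]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in frame.itertuples(index=False):
        cv = None if pd.isna(row.cv) else float(row.cv)
        out.append(Ms1Feature(
            feature_id=str(row.feature_id), run_id=str(row.run_id), cv=cv,
            mono_mz=float(row.mono_mz), charge=int(row.charge),
            rt_apex=float(row.rt_apex), rt_start=float(row.rt_start),
            rt_end=float(row.rt_end), intensity=float(row.intensity),
            snr=float(row.snr), n_isotopes=int(row.n_isotopes)))
    return out
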