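"""Ground-truth simulator for FAIMS multi-CV LC-MS identity transfer.

Generates a mixed-species 3D-tag library and low-input runs with the
statistical structure the matching method assumes:

* tryptic-like peptide sequences (length 7-30, C-terminal K/R) with exact
  monoisotopic masses and m/z confined to the instrument scan range;
* a per-peptide preferred FAIMS CV that correlates with mass and charge
  (heavier, lower-charge ions transmit at more negative CV) plus noise —
  informative but imperfect, as FAIMS selectivity is in practice;
* a smooth monotone RT drift between the library axis and each run,
  ppm-scale mass error, log-normal intensities and peptide dropout;
* an entrapment species present in the library but never in a sample; and
* a large population of "unknown" features — real signals (contaminants,
  peptides outside the library) with no correct match in the library.
  These are the raw material of false transfers: low-input runs routinely
  contain far more MS1 features than the library can explain.

Every simulated feature links back to a truth peptide or is labeled
unknown, so matching, FDR estimation and quantification can all be tested
closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_finder import Ms1Feature
from .mzml_io import Ms1Spectrum, Run
from .tag_library import (CARBAMIDOMETHYL, RESIDUE_MASS, WATER_MASS,
                          LibraryEntry, SpectralLibrary, mz_from_mass)

# residues eligible inside simulated tryptic peptides: no internal K/R, and
# no leading P (cleavage before proline is suppressed), so that concatenating
# a protein's peptides digests back into exactly those peptides
_BODY = np.array(list("ACDEFGHILMNQSTVWY"))
_FIRST = np.array(list("ACDEFGHILMNQSTVWY"))  # no P first
_TAIL = np.array(list("KR"))

_MASS_OF = {aa: RESIDUE_MASS[aa] + (CARBAMIDOMETHYL if aa == "C" else 0.0)
            for aa in RESIDUE_MASS}


@dataclass(frozen=True)
class DriftParams:
    """Monotone RT drift family: rt_lib = a*rt_run + b + c*sin(rt_run/period)."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    period: float = 15.0

    def __post_init__(self):
        if self.a - abs(self.c) / self.period <= 0:
            raise ValueError("drift not monotone: need a > |c|/period")

    def warp(self, rt_run):
        rt_run = np.asarray(rt_run, dtype=float)
        return self.a * rt_run + self.b + self.c * np.sin(rt_run / self.period)

    def inverse(self, rt_lib):
        """Invert the warp on a dense grid (the family is strictly monotone)."""
        rt_lib = np.asarray(rt_lib, dtype=float)
        if rt_lib.size == 0:
            return rt_lib
        lo = (np.min(rt_lib) - abs(self.b)) / max(self.a, 1e-6) - 10.0
        hi = (np.max(rt_lib) + abs(self.b)) / max(self.a, 1e-6) + 10.0
        grid = np.linspace(lo, hi, 20001)
        return np.interp(rt_lib, self.warp(grid), grid)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the acquisition the method models: a 4-CV cycle
    (-45, -55, -65, -75 V), a 60-min gradient with peptides eluting from
    8 min, scan range 350-1500 m/z, ~2 ppm calibrated mass error, ~0.1 min
    residual RT jitter, 30% dropout at single-cell input, and a library
    whose entrapment share (2,280 / 7,280 ~ 31%) matches the mixed-species
    design the entrapment FDR procedure assumes.  ``n_unknown_features``
    sets how many library-less features each run carries (see module
    docstring); ``cv_noise`` scales how imperfectly CV tracks mass/charge.
    """

    n_target_peptides: int = 5000
    n_entrap_peptides: int = 2280
    cv_levels: tuple[float, ...] = (-45.0, -55.0, -65.0, -75.0)
    gradient: tuple[float, float] = (8.0, 60.0)        # minutes
    mz_range: tuple[float, float] = (350.0, 1500.0)    # Th
    ppm_sd: float = 2.0
    rt_noise_sd: float = 0.1                           # minutes
    drift: DriftParams = field(default_factory=lambda: DriftParams(a=1.02, b=-0.8,
                                                                   c=0.5, period=12.0))
    dropout: float = 0.3
    n_unknown_features: int = 20000
    intensity_mu: float = 6.0      # log10 counts
    intensity_sigma: float = 0.6   # log10 counts
    ionization_sigma: float = 0.3  # log10, per-peptide efficiency spread
    charge_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # charges 2, 3, 4
    cv_noise: float = 1.0          # in units of CV steps
    peptides_per_protein: int = 5
    target_species: str = "TARGET"
    entrap_species: str = "ENTRAP"
    noise_peaks_per_spectrum: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if len(set(self.cv_levels)) != len(self.cv_levels):
            raise ValueError("cv_levels must be distinct")
        if self.gradient[0] >= self.gradient[1]:
            raise ValueError("gradient span must be increasing")
        if not np.isclose(sum(self.charge_probs), 1.0):
            raise ValueError("charge_probs must sum to 1")


@dataclass
class GroundTruth:
    """Everything the simulator knows: per-peptide truth plus the CV model."""

    peptides: pd.DataFrame     # sequence, species, charge, mono_mass, rt_lib, cv, ...
    config: SimConfig
    mass_mean: float
    mass_sd: float
    charge_mean: float
    charge_sd: float
    cv_thresholds: np.ndarray  # score quantile cuts between CV bins

    def warp(self, rt_run):
        return self.config.drift.warp(rt_run)

    def inverse_warp(self, rt_lib):
        return self.config.drift.inverse(rt_lib)


# ---------------------------------------------------------------------------
# Sequence and mass generation
# ---------------------------------------------------------------------------

def _random_peptides(rng: np.random.Generator, n: int, config: SimConfig,
                     exclude: set[str] | None = None) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tryptic-like sequences with charge and mass, m/z inside the scan range."""
    exclude = set(exclude or ())
    charges = np.arange(2, 2 + len(config.charge_probs))
    seqs: list[str] = []
    out_charge: list[int] = []
    out_mass: list[float] = []
    mz_lo, mz_hi = config.mz_range
    guard = 0
    while len(seqs) < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("infeasible simulator ranges: cannot place peptides "
                               "inside the m/z scan range")
        batch = max(256, int((n - len(seqs)) * 1.8))
        lengths = rng.integers(7, 31, size=batch)
        z = rng.choice(charges, size=batch, p=config.charge_probs)
        for length, charge in zip(lengths, z):
            body = rng.choice(_BODY, size=length - 1)
            body[0] = rng.choice(_FIRST)
            seq = "".join(body) + str(rng.choice(_TAIL))
            if seq in exclude or seq in seqs[-64:]:
                continue
            mass = WATER_MASS + sum(_MASS_OF[aa] for aa in seq)
            mz = mz_from_mass(mass, int(charge))
            if not (mz_lo <= mz <= mz_hi):
                continue
            if seq in exclude:
                continue
            exclude.add(seq)
            seqs.append(seq)
            out_charge.append(int(charge))
            out_mass.append(mass)
            if len(seqs) == n:
                break
    return seqs, np.asarray(out_charge), np.asarray(out_mass)


def _cv_scores(mass: np.ndarray, charge: np.ndarray, truth_stats: tuple,
               cv_noise: float, rng: np.random.Generator) -> np.ndarray:
    mass_mean, mass_sd, charge_mean, charge_sd = truth_stats
    z_mass = (mass - mass_mean) / mass_sd
    z_charge = (charge - charge_mean) / max(charge_sd, 1e-9)
    return z_mass - z_charge + rng.normal(0.0, cv_noise, size=mass.size)


def _assign_cv(scores: np.ndarray, thresholds: np.ndarray,
               cv_levels: tuple[float, ...]) -> np.ndarray:
    idx = np.searchsorted(thresholds, scores)
    return np.asarray(cv_levels, dtype=float)[idx]


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(config: SimConfig) -> tuple[SpectralLibrary, GroundTruth]:
    """Generate a mixed-species library and the ground truth behind it.

    Peptides are grouped into proteins (``peptides_per_protein`` each) with a
    log-normal molar abundance per protein and a log-normal ionization
    efficiency per peptide; the entrapment species appears in the library
    only.  The preferred CV is a quantile binning of a mass/charge score plus
    Gaussian noise, making CV informative but imperfect.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_total = config.n_target_peptides + config.n_entrap_peptides
    seqs, charge, mass = _random_peptides(rng, n_total, config)
    species = np.array([config.target_species] * config.n_target_peptides
                       + [config.entrap_species] * config.n_entrap_peptides)

    stats = (float(mass.mean()), float(mass.std()), float(charge.mean()),
             float(charge.std()))
    scores = _cv_scores(mass, charge, stats, config.cv_noise, rng)
    k = len(config.cv_levels)
    thresholds = np.quantile(scores, np.arange(1, k) / k)
    cvs = _assign_cv(scores, thresholds, config.cv_levels)

    rt_lib = rng.uniform(config.gradient[0], config.gradient[1], size=n_total)

    prot_ids = []
    per = max(config.peptides_per_protein, 1)
    for sp, count in ((config.target_species, config.n_target_peptides),
                      (config.entrap_species, config.n_entrap_peptides)):
        tag = sp[:1]
        prot_ids.extend(f"{tag}P{i // per:05d}" for i in range(count))
    prot_ids = np.array(prot_ids)

    n_proteins = len(set(prot_ids))
    abun_by_prot = {p: a for p, a in zip(
        sorted(set(prot_ids)),
        10.0 ** rng.normal(config.intensity_mu, config.intensity_sigma, size=n_proteins))}
    abundance = np.array([abun_by_prot[p] for p in prot_ids])
    # per-peptide ionization efficiency, log-normal with unit median
    efficiency = 10.0 ** rng.normal(0.0, config.ionization_sigma, size=n_total)

    peptides = pd.DataFrame({
        "peptide": seqs, "species": species, "charge": charge,
        "mono_mass": mass, "rt_lib": rt_lib, "cv": cvs,
        "protein": prot_ids, "abundance": abundance, "efficiency": efficiency,
    })
    truth = GroundTruth(peptides=peptides, config=config,
                        mass_mean=stats[0], mass_sd=stats[1],
                        charge_mean=stats[2], charge_sd=stats[3],
                        cv_thresholds=thresholds)

    entries = [
        LibraryEntry(
            peptide=row.peptide, charge=int(row.charge),
            mono_mass=float(row.mono_mass), ref_rt=float(row.rt_lib),
            cv=float(row.cv), proteins=(row.protein,), species=row.species,
            lib_intensity=float(row.abundance * row.efficiency), n_obs=1)
        for row in peptides.itertuples(index=False)
    ]
    return SpectralLibrary(entries), truth


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------

def simulate_run(truth: GroundTruth, run_seed: int = 0,
                 config: SimConfig | None = None,
                 ) -> tuple[list[Ms1Feature], pd.DataFrame]:
    """Realize one low-input run from the truth.

    Target-species peptides each survive with probability 1 - dropout and
    appear with ppm-scale mass error, warped + jittered RT and log-normal
    intensity; entrapment peptides never appear.  ``n_unknown_features``
    additional features are drawn from the same physical model but from
    peptides outside the library.  Returns the feature list and a links
    table mapping feature_id to its truth peptide (or flagging it unknown).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 977, run_seed])
    pep = truth.peptides
    target = pep[pep["species"] == config.target_species]

    keep = rng.random(len(target)) >= config.dropout
    obs = target[keep]
    n_obs = len(obs)

    mass_obs = obs["mono_mass"].to_numpy() * (
        1.0 + rng.normal(0.0, config.ppm_sd * 1e-6, size=n_obs))
    rt_run = truth.inverse_warp(obs["rt_lib"].to_numpy()) \
        + rng.normal(0.0, config.rt_noise_sd, size=n_obs)
    rt_run = np.maximum(rt_run, 0.0)
    intensity = (obs["abundance"].to_numpy() * obs["efficiency"].to_numpy()
                 * 10.0 ** rng.normal(0.0, 0.1, size=n_obs))

    # unknown features: real signals with no library counterpart
    n_unk = config.n_unknown_features
    known = set(pep["peptide"])
    unk_seqs, unk_charge, unk_mass = _random_peptides(rng, n_unk, config, exclude=known)
    stats = (truth.mass_mean, truth.mass_sd, truth.charge_mean, truth.charge_sd)
    unk_scores = _cv_scores(unk_mass, unk_charge, stats, config.cv_noise, rng)
    unk_cv = _assign_cv(unk_scores, truth.cv_thresholds, config.cv_levels)
    run_span = truth.inverse_warp(np.asarray(config.gradient))
    unk_rt = rng.uniform(run_span[0], run_span[1], size=n_unk)
    unk_mass_obs = unk_mass * (1.0 + rng.normal(0.0, config.ppm_sd * 1e-6, size=n_unk))
    unk_intensity = 10.0 ** rng.normal(config.intensity_mu, config.intensity_sigma,
                                       size=n_unk)

    run_id = f"sim_run{run_seed}"
    features: list[Ms1Feature] = []
    links: list[dict] = []

    def add(mono_mass, charge, rt, cv, inten, peptide, species, is_unknown):
        fid = f"{run_id}_F{len(features):06d}"
        features.append(Ms1Feature(
            feature_id=fid, mono_mz=mz_from_mass(mono_mass, charge), charge=charge,
            rt_apex=float(rt), rt_start=float(rt) - 0.15, rt_end=float(rt) + 0.15,
            intensity=float(inten), snr=10.0, cv=float(cv), n_isotopes=3,
            run_id=run_id))
        links.append({"feature_id": fid, "peptide": peptide, "species": species,
                      "is_unknown": is_unknown})

    for i, row in enumerate(obs.itertuples(index=False)):
        add(mass_obs[i], int(row.charge), rt_run[i], row.cv, intensity[i],
            row.peptide, row.species, False)
    for i in range(n_unk):
        add(unk_mass_obs[i], int(unk_charge[i]), unk_rt[i], unk_cv[i],
            unk_intensity[i], unk_seqs[i], "unknown", True)

    return features, pd.DataFrame(links, columns=["feature_id", "peptide",
                                                  "species", "is_unknown"])


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------

def simulate_spectra(features: list[Ms1Feature], config: SimConfig,
                     run_id: str = "sim", scan_period: float = 0.02,
                     n_isotopes: int = 3, scans_per_side: int = 3,
                     run_seed: int = 0) -> Run:
    """Render features as centroided MS1 spectra interleaved across CVs.

    Each feature becomes an isotope envelope (geometrically decaying
    intensities, spacing 1.003355/z) with a Gaussian elution profile over
    ``2 * scans_per_side + 1`` scans of its own CV.  ``scan_period`` is the
    per-CV sampling interval in minutes (the CV cycle is phase-shifted so
    spectra interleave in time).  Optional uniform noise peaks are added per
    spectrum.
    """
    rng = np.random.default_rng([config.seed, 7919, run_seed])
    cv_levels = [float(cv) for cv in config.cv_levels]
    phase = {cv: i * scan_period / max(len(cv_levels), 1)
             for i, cv in enumerate(cv_levels)}
    # collect required scan times per CV
    scan_peaks: dict[tuple[float, float], dict[float, float]] = {}

    def scan_time(cv: float, k: int) -> float:
        return k * scan_period + phase.get(cv, 0.0)

    for f in features:
        cv = f.cv if f.cv is not None else cv_levels[0]
        k0 = round((f.rt_apex - phase.get(cv, 0.0)) / scan_period)
        for dk in range(-scans_per_side, scans_per_side + 1):
            t = scan_time(cv, k0 + dk)
            if t < 0:
                continue
            profile = np.exp(-0.5 * (dk / (scans_per_side / 2.0)) ** 2)
            for iso in range(n_isotopes):
                mz = f.mono_mz + iso * 1.003355 / f.charge
                inten = f.intensity * profile * (0.5 ** iso)
                key = (cv, round(t, 9))
                scan_peaks.setdefault(key, {})
                scan_peaks[key][mz] = scan_peaks[key].get(mz, 0.0) + inten

    spectra = []
    items = sorted(scan_peaks.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    for i, ((cv, t), peaks) in enumerate(items):
        mzs = np.array(sorted(peaks))
        ints = np.array([peaks[m] for m in mzs])
        if config.noise_peaks_per_spectrum:
            nmz = rng.uniform(*config.mz_range, size=config.noise_peaks_per_spectrum)
            nint = 10.0 ** rng.normal(config.intensity_mu - 3.0, 0.5,
                                      size=config.noise_peaks_per_spectrum)
            mzs = np.concatenate([mzs, nmz])
            ints = np.concatenate([ints, nint])
            order = np.argsort(mzs)
            mzs, ints = mzs[order], ints[order]
            dup = np.concatenate([[False], np.diff(mzs) <= 1e-9])
            mzs, ints = mzs[~dup], ints[~dup]
        spectra.append(Ms1Spectrum(scan_id=f"scan={i}", rt=float(t),
                                   mz=mzs, intensity=ints, cv=cv))
    return Run(run_id=run_id, spectra=spectra)


# ---------------------------------------------------------------------------
# Truth / FASTA export
# ---------------------------------------------------------------------------

def truth_fasta(truth: GroundTruth) -> dict[str, str]:
    """Synthetic protein sequences: each protein is the concatenation of its
    peptides, which digests back into exactly those peptides."""
    seqs: dict[str, list[str]] = {}
    for row in truth.peptides.itertuples(index=False):
        seqs.setdefault(row.protein, []).append(row.peptide)
    return {prot: "".join(peps) for prot, peps in seqs.items()}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(seqs):
            fh.write(f">{acc} synthetic\n")
            seq = seqs[acc]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_truth(truth: GroundTruth, path) -> None:
    truth.peptides.to_csv(path, sep="\t", index=False, lineterminator="\n")


def cv_information(truth: GroundTruth, n_mass_bins: int = 4) -> float:
    """Mutual information (nats) between CV and (mass-quartile, charge) bins."""
    pep = truth.peptides
    mass_bin = pd.qcut(pep["mono_mass"], n_mass_bins, labels=False)
    joint = pd.crosstab([mass_bin, pep["charge"]], pep["cv"]).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return float(terms.sum())
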