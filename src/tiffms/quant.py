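"""Protein-level iBAQ quantification and matrix post-processing.

iBAQ (intensity-based absolute quantification) divides a protein's summed
feature intensity by its number of theoretically observable tryptic
peptides, giving values proportional to molar amount.  The module also
provides the standard single-cell post-processing chain on the resulting
proteins x runs matrix: missingness filtering, "at least 2 valid values per
group" quantifiability, downshifted-normal imputation (width 0.3,
downshift 1.8 on log2 values), width normalization to equal interquartile
ranges, and reproducibility statistics (per-protein CV%, pairwise run
correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import parser as _pyparser

from .feature_finder import Ms1Feature
from .matcher import MatchResult
from .tag_library import SpectralLibrary

logger = logging.getLogger("tiffms")

#: Cleave C-terminal to K or R, except before proline.
TRYPSIN_RULE = r"(?<=[KR])(?!P)"


@dataclass(frozen=True)
class DigestParams:
    """In-silico tryptic digestion settings for the iBAQ denominator."""

    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def count_theoretical_peptides(protein_seq: str, params: DigestParams | None = None) -> int:
    """Number of distinct fully tryptic peptides with length in [min_len, max_len]."""
    params = params or DigestParams()
    seq = protein_seq.strip().upper()
    if not seq:
        return 0
    peptides = _pyparser.cleave(seq, TRYPSIN_RULE,
                                missed_cleavages=params.missed_cleavages)
    return sum(1 for p in set(peptides) if params.min_len <= len(p) <= params.max_len)


def ibaq(protein_summed_intensity: float, n_theoretical: int) -> float | None:
    """Summed intensity / theoretical peptide count; None when unquantifiable."""
    if n_theoretical < 1:
        return None
    return protein_summed_intensity / n_theoretical


# ---------------------------------------------------------------------------
# Protein roll-up
# ---------------------------------------------------------------------------

def protein_rollup(matches: list[MatchResult], features: list[Ms1Feature],
                   library: SpectralLibrary) -> dict[str, float]:
    """Summed accepted-feature intensity per protein for one run.

    Peptides unique to one protein go to it directly; shared peptides are
    assigned razor-style to the protein with more distinct accepted peptides,
    with ties dropped.
    """
    by_fid = {f.feature_id: f for f in features}
    pep_intensity: dict[str, float] = {}
    pep_proteins: dict[str, tuple] = {}
    for r in matches:
        if not r.accepted:
            continue
        entry = library[r.entry_key]
        feat = by_fid.get(r.feature_id)
        if feat is None:
            continue
        pep_intensity[entry.peptide] = pep_intensity.get(entry.peptide, 0.0) + feat.intensity
        pep_proteins[entry.peptide] = entry.proteins

    distinct: dict[str, set] = {}
    for pep, accs in pep_proteins.items():
        for acc in accs:
            distinct.setdefault(acc, set()).add(pep)

    totals: dict[str, float] = {}
    for pep, accs in pep_proteins.items():
        if len(accs) == 1:
            owner = accs[0]
        else:
            counts = sorted(((len(distinct[a]), a) for a in accs), reverse=True)
            if len(counts) > 1 and counts[0][0] == counts[1][0]:
                continue  # razor tie: peptide dropped
            owner = counts[0][1]
        totals[owner] = totals.get(owner, 0.0) + pep_intensity[pep]
    return totals


@dataclass
class QuantMatrix:
    """Proteins x runs table with explicit missingness and group labels."""

    values: pd.DataFrame                 # NaN = missing
    group_of: dict[str, str] = field(default_factory=dict)
    is_log2: bool = False

    def __post_init__(self):
        for run in self.values.columns:
            self.group_of.setdefault(run, "all")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), dict(self.group_of), self.is_log2)

    def log2(self) -> "QuantMatrix":
        if self.is_log2:
            return self.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(self.values.where(self.values > 0))
        return QuantMatrix(vals, dict(self.group_of), is_log2=True)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for run, grp in self.group_of.items():
            if run in self.values.columns:
                out.setdefault(grp, []).append(run)
        return out


def build_quant_matrix(per_run_totals: dict[str, dict[str, float]],
                       n_theoretical: dict[str, int],
                       group_of: dict[str, str] | None = None) -> QuantMatrix:
    """Assemble linear-scale iBAQ values into a :class:`QuantMatrix`.

    Proteins without a theoretical-peptide count (or with zero) are flagged
    unquantifiable: their cells stay missing.
    """
    runs = sorted(per_run_totals)
    proteins = sorted({p for totals in per_run_totals.values() for p in totals})
    data = np.full((len(proteins), len(runs)), np.nan)
    unquantifiable = set()
    for j, run in enumerate(runs):
        for i, prot in enumerate(proteins):
            total = per_run_totals[run].get(prot)
            if total is None:
                continue
            val = ibaq(total, n_theoretical.get(prot, 0))
            if val is None:
                unquantifiable.add(prot)
            else:
                data[i, j] = val
    if unquantifiable:
        logger.warning("%d proteins lack theoretical peptides; left missing",
                       len(unquantifiable))
    frame = pd.DataFrame(data, index=proteins, columns=runs)
    return QuantMatrix(frame, dict(group_of or {}), is_log2=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def missingness_filter(matrix: QuantMatrix, max_frac: float = 0.5) -> QuantMatrix:
    """Keep proteins with missing fraction <= max_frac in >= 1 condition."""
    keep = []
    groups = matrix.groups()
    for prot in matrix.values.index:
        row = matrix.values.loc[prot]
        for runs in groups.values():
            if row[runs].isna().mean() <= max_frac:
                keep.append(prot)
                break
    out = matrix.copy()
    out.values = out.values.loc[keep]
    return out


def quantifiable_filter(matrix: QuantMatrix, min_valid: int = 2) -> QuantMatrix:
    """Keep proteins with >= min_valid observed values in >= 1 group."""
    keep = []
    groups = matrix.groups()
    for prot in matrix.values.index:
        row = matrix.values.loc[prot]
        for runs in groups.values():
            if row[runs].notna().sum() >= min_valid:
                keep.append(prot)
                break
    out = matrix.copy()
    out.values = out.values.loc[keep]
    return out


# ---------------------------------------------------------------------------
# Imputation and normalization
# ---------------------------------------------------------------------------

def impute_missing(matrix: QuantMatrix, width: float = 0.3, downshift: float = 1.8,
                   seed: int = 0) -> QuantMatrix:
    """Downshifted-normal imputation of missing log2 values.

    Each missing cell of a column is drawn from Normal(m - downshift*s,
    (width*s)^2) where m, s are the mean and sd of the column's observed
    values — emulating signals just below the detection limit.  Columns with
    fewer than two observed values fall back to the global mean/sd with a
    warning.  Observed cells are untouched; a fixed seed fixes the output.
    """
    if not matrix.is_log2:
        raise ValueError("imputation operates on log2-scale matrices")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values
    observed = vals.to_numpy()[~np.isnan(vals.to_numpy())]
    g_mean = float(np.mean(observed)) if observed.size else 0.0
    g_sd = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
    for col in vals.columns:
        column = vals[col]
        obs = column.dropna()
        if len(obs) < 2:
            logger.warning("column %s has %d observed values; imputing from "
                           "global statistics", col, len(obs))
            m, s = g_mean, g_sd
        else:
            m, s = float(obs.mean()), float(obs.std(ddof=1))
        missing = column.isna()
        n_miss = int(missing.sum())
        if n_miss:
            draws = rng.normal(m - downshift * s, width * s, size=n_miss)
            vals.loc[missing, col] = draws
    return out


def width_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Per-column: subtract the median, scale to unit interquartile range.

    Quartiles use linear interpolation (numpy default, the "type 7"
    convention).  Zero-IQR columns are flagged and left median-centered.
    """
    if not matrix.is_log2:
        raise ValueError("width normalization operates on log2-scale matrices")
    out = matrix.copy()
    vals = out.values
    for col in vals.columns:
        x = vals[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size == 0:
            continue
        med = float(np.median(obs))
        q1, q3 = np.percentile(obs, [25, 75])
        iqr = float(q3 - q1)
        if iqr == 0:
            logger.warning("column %s has zero IQR; median-centered only", col)
            vals[col] = x - med
        else:
            vals[col] = (x - med) / iqr
    return out


# ---------------------------------------------------------------------------
# Reproducibility statistics
# ---------------------------------------------------------------------------

def reproducibility_stats(matrix: QuantMatrix) -> dict:
    """Per-protein CV% per group, pairwise run correlations, missingness.

    CV% is computed on linear-scale observed values (>= 2 required, else
    NaN); Pearson correlations on log2 values over pairwise-complete rows.
    """
    linear = matrix if not matrix.is_log2 else QuantMatrix(
        2.0 ** matrix.values, dict(matrix.group_of), is_log2=False)
    groups = matrix.groups()
    cv_rows = {}
    for grp, runs in sorted(groups.items()):
        sub = linear.values[runs]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[n < 2] = np.nan
        cv_rows[grp] = cv
    cv_frame = pd.DataFrame(cv_rows)

    log2m = matrix.log2()
    corr = log2m.values.corr(method="pearson", min_periods=3)

    missing = matrix.missing_mask.mean(axis=1)
    medians = {grp: float(np.nanmedian(col)) if col.notna().any() else float("nan")
               for grp, col in cv_frame.items()}
    return {
        "cv_percent": cv_frame,
        "cv_percent_median": medians,
        "run_correlations": corr,
        "missing_fraction": missing,
    }


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: QuantMatrix, path, meta_path=None,
                 header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep="\t", na_rep="NA", index_label="protein",
                             lineterminator="\n")
    if meta_path is not None:
        meta = pd.DataFrame({"run": list(matrix.values.columns),
                             "condition": [matrix.group_of.get(r, "all")
                                           for r in matrix.values.columns]})
        meta.to_csv(meta_path, sep="\t", index=False, lineterminator="\n")


def read_matrix(path, meta_path=None, is_log2: bool = False) -> QuantMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="protein")
    group_of = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
        group_of = dict(zip(meta["run"].astype(str), meta["condition"].astype(str)))
    return QuantMatrix(frame, group_of, is_log2=is_log2)
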