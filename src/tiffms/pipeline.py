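"""End-to-end workflow: split -> detect -> align -> match -> fdr -> quant.

The pipeline is file-based and deterministic: every stage consumes files
(or the simulator's in-memory products written to files), every output
carries the hash of the resolved configuration, and all randomness derives
from the configured seed, so identical configs yield byte-identical output
directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import entrapment, feature_finder, matcher, mzml_io, quant, rt_alignment
from . import simulate as sim
from . import tag_library

logger = logging.getLogger("tiffms")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


_TOP_KEYS = {"seed", "out_dir", "simulate", "runs", "finder", "align", "match",
             "quant", "write_mzml", "library", "mzml_runs"}
_ALIGN_KEYS = {"span", "coarse_rt_window", "ppm_tol"}
_QUANT_KEYS = {"min_len", "max_len", "missed_cleavages", "max_missing_frac",
               "min_valid", "impute", "width", "downshift", "normalize"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(path_or_dict)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    _check_keys(config, _TOP_KEYS, "pipeline config")
    if "simulate" in config:
        sim_keys = {f for f in sim.SimConfig.__dataclass_fields__} | {"drift"}
        _check_keys(config["simulate"], sim_keys, "simulate block")
    for block, allowed in (("finder", set(feature_finder.FinderParams.__dataclass_fields__)),
                           ("match", set(matcher.MatchParams.__dataclass_fields__)),
                           ("align", _ALIGN_KEYS), ("quant", _QUANT_KEYS)):
        if block in config:
            _check_keys(config[block], allowed, f"{block} block")
    for key in ("library",):
        if key in config and not Path(config[key]).exists():
            raise ConfigError(f"configured path does not exist: {config[key]}")
    for path in config.get("mzml_runs", []) or []:
        p = path["path"] if isinstance(path, dict) else path
        if not Path(p).exists():
            raise ConfigError(f"configured path does not exist: {p}")
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _sim_config(config: dict) -> sim.SimConfig:
    block = dict(config.get("simulate", {}))
    drift = block.pop("drift", None)
    if drift is not None:
        block["drift"] = sim.DriftParams(**drift)
    block.setdefault("seed", config.get("seed", 0))
    for key in ("cv_levels", "gradient", "mz_range", "charge_probs"):
        if key in block:
            block[key] = tuple(block[key])
    return sim.SimConfig(**block)


def _align_run(features_by_cv: dict, library, align_cfg: dict, log: list[str]):
    """Fit one alignment model per CV, pooling anchors as fallback."""
    span = align_cfg.get("span", 0.3)
    window = align_cfg.get("coarse_rt_window", 10.0)
    ppm = align_cfg.get("ppm_tol", 6.0)
    anchors_by_cv = {}
    for cv, feats in features_by_cv.items():
        try:
            anchors_by_cv[cv] = rt_alignment.select_anchors(
                feats, library, coarse_rt_window=window, ppm_tol=ppm)
        except rt_alignment.AlignmentError:
            anchors_by_cv[cv] = []
    pooled = [a for anchors in anchors_by_cv.values() for a in anchors]
    for cv, feats in sorted(features_by_cv.items(), key=lambda kv: str(kv[0])):
        anchors = anchors_by_cv[cv]
        if len(anchors) < rt_alignment.MIN_ANCHORS:
            anchors = pooled
            log.append(f"align cv={cv}: pooled anchors fallback ({len(anchors)})")
        if len(anchors) < rt_alignment.MIN_ANCHORS:
            model = rt_alignment.AlignmentModel.identity()
            log.append(f"align cv={cv}: identity fallback")
        else:
            model = rt_alignment.fit_alignment(anchors, span=span)
            log.append(f"align cv={cv}: n_anchors={model.n_anchors} "
                       f"residual_sd={model.residual_sd:.4f}")
        rt_alignment.apply_alignment(model, feats)
    return anchors_by_cv


def run_pipeline(config, out_dir) -> Path:
    """Execute the full workflow into ``out_dir``; returns the path.

    With a ``simulate`` block, the library, truth and per-run mzML files are
    generated first; otherwise ``library`` and ``mzml_runs`` paths are read.
    Outputs: per-run feature and match tables, a paired 2D/3D entrapment
    report, quantification matrices, and a deterministic log.
    """
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = [f"config_hash={chash}"]
    log: list[str] = [f"config_hash={chash}"]
    stage = "setup"
    try:
        seed = int(config.get("seed", 0))
        match_cfg = dict(config.get("match", {}))
        match_cfg.pop("use_cv", None)
        params = matcher.MatchParams(use_cv=True, **match_cfg)
        finder_params = feature_finder.FinderParams(**config.get("finder", {}))

        # ------------------------------------------------------------------
        stage = "simulate"
        if "simulate" in config:
            scfg = _sim_config(config)
            library, truth = sim.simulate_library(scfg)
            tag_library.write_library(library, out / "library.tsv",
                                      out / "library.meta.json", header_lines=header)
            sim.write_truth(truth, out / "truth.tsv")
            sim.write_fasta(sim.truth_fasta(truth), out / "proteins.fasta")
            entrap_species = scfg.entrap_species
            runs_cfg = config.get("runs", [{"run_seed": 1, "group": "all"}])
            run_inputs = []
            for rc in runs_cfg:
                run_seed = int(rc.get("run_seed", 1))
                features, links = sim.simulate_run(truth, run_seed=run_seed)
                run_id = f"sim_run{run_seed}"
                links.to_csv(out / f"{run_id}.links.tsv", sep="\t", index=False,
                             lineterminator="\n")
                if config.get("write_mzml", False):
                    rendered = sim.simulate_spectra(features, scfg, run_id=run_id,
                                                    run_seed=run_seed)
                    mzml_path = out / f"{run_id}.mzML"
                    mzml_io.write_run(rendered, mzml_path)
                    run_inputs.append((run_id, rc.get("group", "all"), mzml_path, None))
                else:
                    run_inputs.append((run_id, rc.get("group", "all"), None, features))
        else:
            if "library" not in config or not config.get("mzml_runs"):
                raise ConfigError("need either a simulate block or library + mzml_runs")
            library = tag_library.read_library(config["library"])
            entrap_species = None
            run_inputs = []
            for rc in config["mzml_runs"]:
                rc = rc if isinstance(rc, dict) else {"path": rc}
                path = Path(rc["path"])
                run_inputs.append((rc.get("run_id", path.stem),
                                   rc.get("group", "all"), path, None))

        # ------------------------------------------------------------------
        group_of: dict[str, str] = {}
        per_run_matches: dict[str, list] = {}
        per_run_features: dict[str, list] = {}
        all_reports = {}
        for run_id, group, mzml_path, pre_features in run_inputs:
            group_of[run_id] = group
            if pre_features is None:
                stage = "split"
                run = mzml_io.read_run(mzml_path, run_id=run_id)
                sub_runs = mzml_io.split_by_cv(run)
                log.append(f"{run_id}: {len(run)} spectra in {len(sub_runs)} CV groups")
                stage = "detect"
                features = []
                for cv in sorted(sub_runs, key=lambda c: (c is None, c)):
                    sub_features = feature_finder.detect_features(sub_runs[cv],
                                                                  finder_params)
                    features.extend(sub_features)
                for i, f in enumerate(sorted(features, key=lambda f: (f.mono_mz,
                                                                      f.rt_apex))):
                    f.feature_id = f"{run_id}_F{i:06d}"
                    f.run_id = run_id
            else:
                features = pre_features
            log.append(f"{run_id}: {len(features)} features")

            stage = "align"
            by_cv: dict = {}
            for f in features:
                by_cv.setdefault(f.cv, []).append(f)
            _align_run(by_cv, library, config.get("align", {}), log)
            feature_finder.write_features(features, out / f"{run_id}.features.tsv",
                                          header_lines=header)

            stage = "match"
            results = matcher.transfer_ids(features, library,
                                           rt_alignment.AlignmentModel.identity(),
                                           params)
            matcher.write_matches(results, library, out / f"{run_id}.matches.tsv",
                                  header_lines=header)
            n_acc = len(matcher.accepted(results))
            log.append(f"{run_id}: {len(results)} matches, {n_acc} accepted (3D)")
            per_run_matches[run_id] = results
            per_run_features[run_id] = features

            stage = "fdr"
            if entrap_species is not None:
                reports = entrapment.compare_modes(
                    features, library, rt_alignment.AlignmentModel.identity(),
                    params, entrap_species)
                all_reports[run_id] = reports
                log.append(f"{run_id}: fmr 2d={reports['2d'].fmr:.4f} "
                           f"3d={reports['3d'].fmr:.4f}")
        if all_reports:
            payload = {run_id: {label: rep.to_dict() for label, rep in reports.items()}
                       for run_id, reports in all_reports.items()}
            payload["config_hash"] = chash
            with open(out / "fdr_report.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")

        # ------------------------------------------------------------------
        stage = "quant"
        qcfg = dict(config.get("quant", {}))
        digest = quant.DigestParams(
            min_len=qcfg.get("min_len", 7), max_len=qcfg.get("max_len", 30),
            missed_cleavages=qcfg.get("missed_cleavages", 0))
        fasta_path = out / "proteins.fasta"
        n_theoretical: dict[str, int] = {}
        if fasta_path.exists():
            for acc, seq in _read_fasta(fasta_path).items():
                n_theoretical[acc] = quant.count_theoretical_peptides(seq, digest)
        totals = {run_id: quant.protein_rollup(per_run_matches[run_id],
                                               per_run_features[run_id], library)
                  for run_id in per_run_matches}
        matrix = quant.build_quant_matrix(totals, n_theoretical, group_of)
        quant.write_matrix(matrix, out / "ibaq_raw.tsv", out / "runs.meta.tsv",
                           header_lines=header)
        processed = matrix.log2()
        processed = quant.missingness_filter(processed,
                                             qcfg.get("max_missing_frac", 0.5))
        processed = quant.quantifiable_filter(processed, qcfg.get("min_valid", 2))
        if qcfg.get("impute", True):
            processed = quant.impute_missing(processed, qcfg.get("width", 0.3),
                                             qcfg.get("downshift", 1.8), seed=seed)
        if qcfg.get("normalize", True):
            processed = quant.width_normalize(processed)
        quant.write_matrix(processed, out / "ibaq_processed.tsv",
                           header_lines=header)
        log.append(f"quant: {matrix.values.shape[0]} proteins raw, "
                   f"{processed.values.shape[0]} after filters")
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return out


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    acc = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                acc = line[1:].split()[0]
                seqs[acc] = []
            elif acc is not None and line:
                seqs[acc].append(line)
    return {acc: "".join(parts) for acc, parts in seqs.items()}
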