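"""XIC tracing, isotope-envelope assembly, S/N and charge filtering."""

import itertools

import numpy as np
import pytest

from tiffms.feature_finder import (ISOTOPE_SPACING, FinderParams, Xic,
                                   assemble_envelopes, compute_snr,
                                   detect_features, filter_multiply_charged,
                                   trace_xics)
from tiffms.mzml_io import Ms1Spectrum, Run, split_by_cv
from tiffms.simulate import simulate_run, simulate_spectra


def make_run(peaks_per_scan, rt_step=0.01, run_id="r"):
    """peaks_per_scan: list per scan of [(mz, intensity), ...]."""
    spectra = []
    for i, peaks in enumerate(peaks_per_scan):
        peaks = sorted(peaks)
        spectra.append(Ms1Spectrum(
            scan_id=f"s{i:03d}", rt=rt_step * i,
            mz=np.array([p[0] for p in peaks]),
            intensity=np.array([p[1] for p in peaks])))
    return Run(run_id=run_id, spectra=spectra)


def make_trace(mz, rts, intensity=100.0):
    rts = np.asarray(rts, dtype=float)
    return Xic(mz=mz, rts=rts, intensities=np.full(rts.size, intensity),
               peak_refs=[(i, 0) for i in range(rts.size)])


class TestTraceXics:
    def test_persistent_peak_gives_one_trace(self):
        run = make_run([[(500.0, 100.0)]] * 5)
        traces = trace_xics(run)
        assert len(traces) == 1
        assert traces[0].rts.size == 5

    def test_short_trace_dropped_below_min_scans(self):
        run = make_run([[(500.0, 100.0)]] * 2 + [[]])
        assert trace_xics(run, FinderParams(min_scans=3)) == []

    def test_coeluting_species_stay_separate(self):
        run = make_run([[(500.0, 100.0), (500.3, 80.0)]] * 4)
        traces = trace_xics(run)
        assert len(traces) == 2
        assert [round(t.mz, 1) for t in traces] == [500.0, 500.3]

    def test_lower_min_scans_never_decreases_trace_count(self, small_library,
                                                         small_config):
        _, truth = small_library
        features, _ = simulate_run(truth, run_seed=5)
        run = simulate_spectra(features[:15], small_config, run_seed=5)
        sub = next(iter(split_by_cv(run).values()))
        counts = [len(trace_xics(sub, FinderParams(min_scans=m)))
                  for m in (5, 4, 3, 2, 1)]
        assert counts == sorted(counts)

    def test_peak_partition(self):
        """Every centroid peak belongs to at most one trace."""
        run = make_run([[(500.0, 100.0), (500.5017, 60.0), (610.0, 10.0)]] * 6)
        traces = trace_xics(run)
        refs = [ref for t in traces for ref in t.peak_refs]
        assert len(refs) == len(set(refs))


class TestAssembleEnvelopes:
    def test_charge2_envelope(self):
        spacing = ISOTOPE_SPACING / 2
        traces = [make_trace(500.0, [0, 0.01, 0.02], 100),
                  make_trace(500.0 + spacing, [0, 0.01, 0.02], 60),
                  make_trace(500.0 + 2 * spacing, [0, 0.01, 0.02], 30)]
        feats = assemble_envelopes(traces)
        assert len(feats) == 1
        assert feats[0].charge == 2
        assert feats[0].mono_mz == pytest.approx(500.0, abs=1e-6)
        assert feats[0].n_isotopes == 3
        assert feats[0].intensity == pytest.approx(sum(t.total_intensity
                                                       for t in traces))

    def test_charge1_envelope(self):
        traces = [make_trace(600.0, [0, 0.01, 0.02], 100),
                  make_trace(600.0 + ISOTOPE_SPACING, [0, 0.01, 0.02], 40)]
        feats = assemble_envelopes(traces)
        assert len(feats) == 1 and feats[0].charge == 1

    def test_lone_trace_low_confidence(self):
        feats = assemble_envelopes([make_trace(700.0, [0, 0.01, 0.02])])
        assert len(feats) == 1
        f = feats[0]
        assert f.charge == 1 and f.n_isotopes == 1 and f.low_confidence

    def test_greedy_matches_exhaustive_on_small_runs(self, small_library,
                                                     small_config):
        """Greedy assembly agrees with exhaustive max-intensity grouping."""
        _, truth = small_library
        features, _ = simulate_run(truth, run_seed=9)
        params = FinderParams()
        for start in range(0, 9, 3):
            run = simulate_spectra(features[start:start + 3], small_config,
                                   run_seed=9)
            sub = next(iter(split_by_cv(run).values())) if run.spectra else run
            for cv, piece in split_by_cv(run).items():
                traces = trace_xics(piece, params)
                assert sum(len(s.mz) for s in piece.spectra) <= 200
                greedy = assemble_envelopes(traces, params)
                best = _exhaustive_assembly(traces, params)
                got = sorted((round(f.mono_mz, 4), f.charge, f.n_isotopes)
                             for f in greedy if f.n_isotopes > 1)
                assert got == best

    def test_noise_free_recovery(self, small_library, small_config):
        """All planted features recovered with correct charge and mono m/z."""
        _, truth = small_library
        features, _ = simulate_run(truth, run_seed=2)
        planted = features[:12]
        run = simulate_spectra(planted, small_config, run_seed=2)
        detected = []
        for cv, sub in split_by_cv(run).items():
            detected.extend(detect_features(sub))
        got = sorted((round(f.mono_mz, 4), f.charge) for f in detected)
        want = sorted((round(f.mono_mz, 4), f.charge) for f in planted)
        assert got == want


def _group_consistent(traces, group, params):
    """Charges under which a trace subset forms one isotope envelope."""
    if len(group) == 1:
        return [1]
    members = sorted(group, key=lambda j: traces[j].mz)
    charges = []
    for z in range(params.max_charge, 0, -1):
        step = params.isotope_spacing / z
        base = traces[members[0]].mz
        ok = all(abs(traces[j].mz - (base + k * step)) <= params.spacing_tol
                 for k, j in enumerate(members))
        ok = ok and all(traces[a].overlaps(traces[b])
                        for a, b in itertools.combinations(members, 2))
        if ok:
            charges.append(z)
    return charges


def _exhaustive_assembly(traces, params):
    """Best partition of traces into consistent envelopes, maximizing the
    summed intensity explained by multi-trace envelopes."""
    n = len(traces)
    best = {"score": -1.0, "feats": []}

    def recurse(remaining, groups):
        if not remaining:
            feats = []
            score = 0.0
            for group in groups:
                charges = _group_consistent(traces, group, params)
                members = sorted(group, key=lambda j: traces[j].mz)
                z = max(charges)
                if len(group) > 1:
                    score += sum(traces[j].total_intensity for j in group)
                feats.append((round(traces[members[0]].mz, 4), z, len(group)))
            if score > best["score"]:
                best["score"] = score
                best["feats"] = sorted(f for f in feats if f[2] > 1)
            return
        first = remaining[0]
        rest = remaining[1:]
        for size in range(0, len(rest) + 1):
            for combo in itertools.combinations(rest, size):
                group = (first,) + combo
                if _group_consistent(traces, group, params):
                    recurse([j for j in rest if j not in combo], groups + [group])

    recurse(list(range(n)), [])
    return best["feats"]


class TestSnr:
    def _run_with_noise(self, apex=1000.0, noise=(100.0, 90.0, 110.0)):
        scans = []
        for i in range(3):
            peaks = [(500.0, apex if i == 1 else apex / 2)]
            peaks += [(520.0 + 3 * j, v) for j, v in enumerate(noise)]
            scans.append(peaks)
        return make_run(scans)

    def test_snr_is_apex_over_unassigned_median(self):
        run = self._run_with_noise()
        params = FinderParams(min_scans=3)
        traces = trace_xics(run, params)
        feats = assemble_envelopes(traces, params)
        target = next(f for f in feats if abs(f.mono_mz - 500.0) < 0.01)
        others = [f for f in feats if f is not target]
        # noise = median of peaks not assigned to any envelope; with the noise
        # traces assembled too, exclude them from the pool explicitly
        snr = compute_snr(target, run, traces, all_features=feats)
        assert snr == pytest.approx(1000.0 / 1.0)  # all peaks assigned -> floor
        snr_alone = compute_snr(target, run, traces, all_features=[target])
        assert snr_alone == pytest.approx(1000.0 / 100.0)

    def test_noise_floor_of_one(self):
        run = make_run([[(500.0, 500.0)]] * 3)
        traces = trace_xics(run)
        feats = assemble_envelopes(traces)
        assert compute_snr(feats[0], run, traces, feats) == pytest.approx(500.0)

    def test_scale_invariance(self):
        run1 = self._run_with_noise()
        run10 = self._run_with_noise(apex=10000.0, noise=(1000.0, 900.0, 1100.0))
        def snr_of(run):
            traces = trace_xics(run)
            feats = assemble_envelopes(traces)
            target = next(f for f in feats if abs(f.mono_mz - 500.0) < 0.01)
            return compute_snr(target, run, traces, all_features=[target])
        assert snr_of(run1) == pytest.approx(snr_of(run10))


class TestChargeFilter:
    def test_keeps_multiply_charged_in_order(self):
        feats = assemble_envelopes([make_trace(700.0, [0, 0.01, 0.02])])
        feats[0].charge = 1
        z2 = assemble_envelopes([make_trace(400.0, [0, 0.01, 0.02]),
                                 make_trace(400.0 + ISOTOPE_SPACING / 2,
                                            [0, 0.01, 0.02])])
        mixed = feats + z2
        kept = filter_multiply_charged(mixed)
        assert [f.charge for f in kept] == [2]

    def test_all_singly_charged_empty(self):
        feats = assemble_envelopes([make_trace(700.0, [0, 0.01, 0.02])])
        assert filter_multiply_charged(feats) == []

    def test_simulator_truth_count(self, small_library, small_config):
        _, truth = small_library
        features, _ = simulate_run(truth, run_seed=4)
        planted = features[:10]
        run = simulate_spectra(planted, small_config, run_seed=4)
        detected = []
        for sub in split_by_cv(run).values():
            detected.extend(detect_features(sub))
        truth_multi = sum(1 for f in planted if f.charge >= 2)
        assert len(filter_multiply_charged(detected)) == truth_multi
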