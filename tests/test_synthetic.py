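"""Synthetic polysomnography generator: architecture, EEG spectra, cohorts."""

import numpy as np
import pytest

from somnostage import (ArchitectureParams, GroupEffect, Hypnogram,
                        SpectralTemplate, simulate_cohort, simulate_hypnogram,
                        sleep_metrics, synthesize_eeg, stationary_occupancy)
from somnostage.exceptions import ConfigurationError, DataError
from somnostage.types import STAGE_TO_CODE

from ._naive import band_power

BAND_EDGES = {"delta": (1.5, 4), "theta": (4, 8), "alpha": (8, 13),
              "beta": (13, 25), "gamma": (25, 40)}


class TestHypnogram:
    def test_degenerate_sol_realised_exactly(self):
        params = ArchitectureParams(sol_mean_min=26.0, sol_sd_min=0.0)
        h = simulate_hypnogram(params, seed=0)
        first_n2 = np.flatnonzero(h.stages == STAGE_TO_CODE["N2"])[0]
        assert first_n2 == 52
        assert sleep_metrics(h, 9).sol_min == 26.0

    def test_determinism(self):
        params = ArchitectureParams()
        a = simulate_hypnogram(params, seed=7)
        b = simulate_hypnogram(params, seed=7)
        assert np.array_equal(a.stages, b.stages)

    def test_length_and_alphabet(self):
        for tsc in (1.0, 3.0, 9.0):
            h = simulate_hypnogram(ArchitectureParams(tsc_hours=tsc), seed=1)
            assert len(h) == int(tsc * 120)
            assert set(h.stages) <= set(range(5))

    def test_complete_cycle_present(self):
        h = simulate_hypnogram(ArchitectureParams(tsc_hours=3.0), seed=3)
        firsts = [np.flatnonzero(h.stages == STAGE_TO_CODE[s])[0]
                  for s in ("N1", "N2", "N3", "REM")]
        assert firsts == sorted(firsts)

    def test_bad_transition_row_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureParams(transition={"N1": {"N2": 0.0}})
        with pytest.raises(ConfigurationError):
            ArchitectureParams(transition={"N1": {"N2": -1.0}})

    def test_occupancy_calibration_to_target(self):
        """Monte-Carlo: dwell means re-solved for an N3% target are realised
        within +/-2 points on average over 200 nights."""
        params = ArchitectureParams().with_stage_targets(
            {"N1": 6.0, "N2": 46.5, "N3": 25.0, "REM": 22.5})
        assert stationary_occupancy(params)["N3"] == pytest.approx(25.0, abs=0.01)
        n3 = [sleep_metrics(simulate_hypnogram(params, seed=s), 9).n3_pct
              for s in range(200)]
        assert np.mean(n3) == pytest.approx(25.0, abs=2.0)


class TestEEGSynthesis:
    def _uniform(self, stage, n_epochs=10):
        return Hypnogram(np.full(n_epochs, STAGE_TO_CODE[stage], dtype=np.int8))

    @pytest.mark.parametrize("stage,dom", [("N3", "delta"), ("N0", "alpha")])
    def test_dominant_band_per_epoch(self, stage, dom):
        rec = synthesize_eeg(self._uniform(stage), seed=0)
        x = rec.channel("Pz-Oz")
        for e in range(10):
            seg = x[e * 3000:(e + 1) * 3000]
            powers = {b: band_power(seg, 100.0, *edges)
                      for b, edges in BAND_EDGES.items()}
            assert max(powers, key=powers.get) == dom

    def test_bit_identical_under_seed(self):
        h = self._uniform("N2", 4)
        a = synthesize_eeg(h, seed=9)
        b = synthesize_eeg(h, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_continuity_across_epoch_boundaries(self):
        h = Hypnogram(np.array([0, 3, 0, 3, 0, 3], dtype=np.int8))  # N0/N3 flips
        x = synthesize_eeg(h, seed=1).channel("Pz-Oz")
        jumps = [abs(x[k * 3000] - x[k * 3000 - 1]) for k in range(1, 6)]
        typical = np.percentile(np.abs(np.diff(x)), 99.9)
        assert max(jumps) < 3 * typical

    def test_unknown_stage_template_rejected(self):
        weights = {s: dict(SpectralTemplate().band_weights[s])
                   for s in ("N0", "N1", "N2", "N3")}  # no REM entry
        with pytest.raises(DataError):
            synthesize_eeg(self._uniform("REM", 2),
                           SpectralTemplate(band_weights=weights), seed=0)

    def test_duplicate_dominant_bands_rejected(self):
        w = {s: dict(SpectralTemplate().band_weights[s])
             for s in SpectralTemplate().band_weights}
        w["N1"] = dict(w["N0"])  # two alpha-dominant stages
        with pytest.raises(ConfigurationError):
            SpectralTemplate(band_weights=w)


class TestCohort:
    def test_default_sizes(self):
        cohort = simulate_cohort(seed=0, base=ArchitectureParams(tsc_hours=1.0))
        assert len(cohort) == 41
        assert sum(r.group == "exposed" for r in cohort) == 21
        assert sum(r.group == "sham" for r in cohort) == 20

    def test_null_effect_leaves_parameters_identical(self):
        base = ArchitectureParams()
        assert GroupEffect().apply(base) == base

    def test_reproducible_under_master_seed(self):
        kw = dict(n_exposed=2, n_sham=2, seed=5,
                  base=ArchitectureParams(tsc_hours=1.0))
        a = simulate_cohort(**kw)
        b = simulate_cohort(**kw)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.hypnograms[0].stages,
                                  rb.hypnograms[0].stages)

    def test_n3_dwell_shift_raises_ground_truth_n3(self):
        base = ArchitectureParams()
        effect = GroupEffect(d_n3_dwell=2.0)
        cohort = simulate_cohort(n_exposed=25, n_sham=25, base=base,
                                 effect=effect, seed=11)
        n3 = {"exposed": [], "sham": []}
        for rec in cohort:
            n3[rec.group].append(sleep_metrics(rec.hypnograms[0], 9).n3_pct)
        assert np.mean(n3["exposed"]) > np.mean(n3["sham"])

    def test_too_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(n_exposed=1, n_sham=5)
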