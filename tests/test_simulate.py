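"""Synthetic dyad generator: coupling, turn-taking, rendering."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from dyadsync.core import GeometryError, ParameterError, RegionSpec, UniformSeries
from dyadsync.motion import frame_difference_series
from dyadsync.simulate import (ConditionCell, ConditionEffects,
                               MovementSimParams, SpeechSimParams,
                               generate_movement_pair, generate_speech_pair,
                               render_frames)


class TestMovementPair:
    def test_full_coupling_zero_lag_duplicates_naive(self):
        p = MovementSimParams(duration_s=60, coupling_gain=1.0,
                              coupling_lag_s=0.0, seed=1)
        naive, da = generate_movement_pair(p)
        np.testing.assert_array_equal(naive.values, da.values)

    def test_seeded_determinism_is_bitwise(self):
        p = MovementSimParams(duration_s=90, coupling_gain=0.5, seed=42)
        n1, d1 = generate_movement_pair(p)
        n2, d2 = generate_movement_pair(p)
        assert n1.values.tobytes() == n2.values.tobytes()
        assert d1.values.tobytes() == d2.values.tobytes()

    def test_uncoupled_pair_correlation_within_monte_carlo_null(self):
        """g=0 series correlate no more than AR-matched independent pairs."""
        null_rs = []
        for s in range(300):
            p = MovementSimParams(duration_s=300, coupling_gain=0.0, seed=7000 + s)
            naive, da = generate_movement_pair(p)
            null_rs.append(pearsonr(naive.values, da.values).statistic)
        band = np.percentile(np.abs(null_rs), 95)
        p = MovementSimParams(duration_s=300, coupling_gain=0.0, seed=123456)
        naive, da = generate_movement_pair(p)
        assert abs(pearsonr(naive.values, da.values).statistic) <= band

    def test_nonnegative_after_softplus_and_abs(self):
        for kind in ("softplus", "abs"):
            p = MovementSimParams(duration_s=30, nonneg_transform=kind, seed=3)
            naive, da = generate_movement_pair(p)
            assert (naive.values >= 0).all() and (da.values >= 0).all()

    @pytest.mark.parametrize("bad", [
        dict(coupling_gain=1.5), dict(coupling_gain=-0.1),
        dict(coupling_lag_s=-1.0), dict(duration_s=0.1),
        dict(ou_theta=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            MovementSimParams(**bad)


class TestSpeechPair:
    def test_turns_alternate_and_never_overlap(self):
        sp = generate_speech_pair(SpeechSimParams(duration_s=300, seed=11))
        speakers = [t[0] for t in sp.turns]
        assert all(a != b for a, b in zip(speakers, speakers[1:]))
        bounds = [(t[1], t[2]) for t in sp.turns]
        assert all(b0 >= a1 for (_, a1), (b0, _) in zip(bounds, bounds[1:]))
        # no time belongs to both speakers' utterances
        grid = np.linspace(0, 300, 6001)
        both = sp.tier_a.contains(grid) & sp.tier_b.contains(grid)
        assert not both.any()

    def test_full_matching_copies_previous_realized_rate(self):
        sp = generate_speech_pair(SpeechSimParams(
            duration_s=240, matching_c=1.0, rate_noise_sd=0.0, seed=5))
        for prev, cur in zip(sp.turns, sp.turns[1:]):
            assert cur[3] == pytest.approx(prev[4])  # gen rate = prev realized

    def test_onsets_fall_inside_own_utterances(self):
        sp = generate_speech_pair(SpeechSimParams(duration_s=200, seed=9))
        for events, tier in ((sp.events_a, sp.tier_a), (sp.events_b, sp.tier_b)):
            assert tier.contains(events.onsets_s).all()

    def test_total_onset_count_matches_poisson_oracle(self):
        """With fixed rate 4/s the onset count over the realized speaking
        time is Poisson(4*T): check a 3-sigma band."""
        sp = generate_speech_pair(SpeechSimParams(
            duration_s=300, base_rate_a=4.0, base_rate_b=4.0,
            matching_c=0.0, rate_noise_sd=0.0, seed=21))
        t_total = sp.tier_a.total_speaking_s + sp.tier_b.total_speaking_s
        count = len(sp.events_a) + len(sp.events_b)
        lam = 4.0 * t_total
        assert abs(count - lam) <= 3.0 * np.sqrt(lam)

    def test_seeded_determinism(self):
        p = SpeechSimParams(duration_s=120, seed=33)
        s1, s2 = generate_speech_pair(p), generate_speech_pair(p)
        np.testing.assert_array_equal(s1.events_a.onsets_s, s2.events_a.onsets_s)
        assert s1.turns == s2.turns


class TestRenderFrames:
    rois = (RegionSpec("naive", 4, 4, 44, 28), RegionSpec("da", 52, 30, 92, 54))

    def test_zero_motion_renders_identical_frames(self):
        z = UniformSeries(np.zeros(24), 6.0)
        stack = render_frames(z, z, self.rois)
        assert (stack.frames == stack.frames[0]).all()

    def test_motion_is_confined_to_its_roi(self):
        naive, _ = generate_movement_pair(
            MovementSimParams(duration_s=5, seed=2))
        z = UniformSeries(np.zeros(len(naive)), 6.0)
        stack = render_frames(naive, z, self.rois)  # only ROI A moves
        diff = np.abs(stack.frames[1:].astype(int) - stack.frames[:-1].astype(int))
        mask = np.ones(stack.shape, dtype=bool)
        ys, xs = self.rois[0].slices()
        mask[ys, xs] = False
        assert diff.max(axis=(0, 3))[mask].max() == 0

    def test_motion_energy_rank_tracks_the_series(self):
        p = MovementSimParams(duration_s=60, coupling_gain=0.4, seed=7)
        naive, da = generate_movement_pair(p)
        stack = render_frames(naive, da, self.rois)
        for roi, series in zip(self.rois, (naive, da)):
            me = frame_difference_series(stack, roi)
            n = min(len(me), len(series))
            rho = spearmanr(me.values[:n], series.values[:n]).statistic
            assert rho > 0.8

    def test_roi_outside_frame_raises(self):
        z = UniformSeries(np.zeros(12), 6.0)
        bad = (RegionSpec("naive", 4, 4, 200, 28), self.rois[1])
        with pytest.raises(GeometryError):
            render_frames(z, z, bad)


class TestConditionEffects:
    def test_all_four_cells_required(self):
        with pytest.raises(ParameterError):
            ConditionEffects(cells={("deception", "disagree"):
                                    ConditionCell(0.5, 0.5, 0.5)})

    def test_default_encodes_highest_coupling_for_deceptive_disagreement(self):
        eff = ConditionEffects()
        target = eff[("deception", "disagree")]
        others = [c for k, c in eff.cells.items()
                  if k != ("deception", "disagree")]
        assert all(target.coupling_gain > o.coupling_gain for o in others)
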