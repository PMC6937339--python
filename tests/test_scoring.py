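"""Standardized-error scoring: reference fitting, the two outcomes,
aggregation, missing-channel policy, and age normalization."""
from __future__ import annotations

import numpy as np
import pytest

import svmckit as sk
from svmckit.scoring import DEFAULT_SD_FLOOR


RATE = 29.0
N = 726  # 25 s analysis window


def _grid():
    return np.arange(N) / RATE


def _path(p=None):
    t = _grid()
    p_star = np.full(N, 50.0) if p is None else np.asarray(p, float)
    return sk.TargetPath(t_grid=t, p_star=p_star, star_times=np.array([0.0]))


def _session(dev=None, derivs=None, meta=None):
    """Build a ProcessedSession directly from deviation + derivative traces."""
    path = _path()
    dev = np.zeros(N) if dev is None else np.asarray(dev, float)
    avatar = sk.AvatarTrace(t_grid=path.t_grid, p=path.p_star + dev)
    meta = meta or sk.SessionMeta(group="NIA", target_joint="ankle_L", extremity="LE")
    return sk.ProcessedSession(meta=meta, path=path, avatar=avatar, derivs=dict(derivs or {}))


def _reference(sessions, **kw):
    return sk.NormativeReference.fit(sessions, **kw)


class TestNormativeReferenceFit:
    def test_on_path_adults_floor_the_sd(self):
        ref = _reference([_session(), _session(), _session()])
        np.testing.assert_array_equal(ref.sigma_path, DEFAULT_SD_FLOOR)

    def test_two_adult_sd_is_sqrt2_times_deviation(self):
        d = 3.0 + 2.0 * np.sin(2 * np.pi * 0.2 * _grid())
        ref = _reference([_session(dev=d), _session(dev=-d)])
        np.testing.assert_allclose(ref.sigma_path, np.abs(d) * np.sqrt(2), rtol=1e-12)

    def test_gaussian_cohort_sd_in_sampling_band(self):
        rng = np.random.default_rng(17)
        sessions = [_session(dev=rng.normal(0, 4.0, N)) for _ in range(30)]
        ref = _reference(sessions)
        frac = np.mean((ref.sigma_path >= 3.0) & (ref.sigma_path <= 5.0))
        assert frac >= 0.95

    def test_channel_statistics_mean_and_sd(self):
        d = np.sin(_grid())
        sessions = [
            _session(derivs={"knee_R": d + 1.0}),
            _session(derivs={"knee_R": d - 1.0}),
        ]
        ref = _reference(sessions)
        np.testing.assert_allclose(ref.mu["knee_R"], d, atol=1e-12)
        np.testing.assert_allclose(ref.sigma["knee_R"], np.sqrt(2), rtol=1e-12)

    def test_fit_rejects_mismatched_paths(self):
        a = _session()
        b = _session()
        b.path.p_star = b.path.p_star + 1.0
        with pytest.raises(sk.InvalidInputError):
            _reference([a, b])

    def test_fit_needs_two_sessions(self):
        with pytest.raises(sk.InvalidInputError):
            _reference([_session()])


class TestAccuracyScore:
    def _ref(self, sigma):
        s = _session()
        ref = _reference([s, s])
        ref.sigma_path = np.full(N, float(sigma))
        return ref

    def test_perfect_tracking_scores_zero(self):
        assert sk.accuracy_score(_session().avatar, _path(), self._ref(3.0)) == 0.0

    def test_constant_deviation_ratio(self):
        s = _session(dev=np.full(N, 6.0))
        assert sk.accuracy_score(s.avatar, s.path, self._ref(3.0)) == pytest.approx(2.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(23)
        dev = rng.normal(0, 5, N)
        sigma = rng.uniform(0.5, 6, N)
        s = _session(dev=dev)
        ref = self._ref(1.0)
        ref.sigma_path = sigma
        expected = sum(abs(dev[i]) / sigma[i] for i in range(N)) / N
        assert sk.accuracy_score(s.avatar, s.path, ref) == pytest.approx(expected, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(29)
        dev = rng.normal(0, 4, N)
        ref = self._ref(2.5)
        base = sk.accuracy_score(_session(dev=dev).avatar, _path(), ref)
        scaled = sk.accuracy_score(_session(dev=3.0 * dev).avatar, _path(), ref)
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        ref = self._ref(1.0)
        short = sk.AvatarTrace(t_grid=_grid()[:-1], p=np.zeros(N - 1))
        with pytest.raises(sk.InvalidInputError):
            sk.accuracy_score(short, _path(), ref)


class TestInvoluntaryChannelError:
    def test_physiological_co_movement_scores_zero(self):
        mu = np.sin(_grid()) * 5
        assert sk.involuntary_channel_error(mu, mu, np.ones(N)) == 0.0

    def test_one_sd_offset_scores_one(self):
        mu = np.cos(_grid())
        sigma = np.full(N, 2.0)
        assert sk.involuntary_channel_error(mu + sigma, mu, sigma) == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(31)
        d, mu = rng.normal(size=(2, N))
        sigma = rng.uniform(0.5, 3, N)
        expected = sum(abs(d[i] - mu[i]) / sigma[i] for i in range(N)) / N
        assert sk.involuntary_channel_error(d, mu, sigma) == pytest.approx(expected, abs=1e-10)


class TestAggregation:
    def test_ankle_target_hand_example(self, le_table):
        per_channel = {
            "trunk_lateral": 1.0, "trunk_ventral": 3.0,
            "hip_flexion_L": 2.0, "hip_rotation_L": 2.0,
            "hip_flexion_R": 0.0, "hip_rotation_R": 4.0,
            "knee_L": 5.0, "knee_R": 1.0, "ankle_R": 6.0,
        }
        score, per_unit = sk.aggregate_involuntary(per_channel, "ankle_L", le_table)
        assert per_unit == {
            "trunk": 2.0, "hip_L": 2.0, "hip_R": 2.0,
            "knee_L": 5.0, "knee_R": 1.0, "ankle_R": 6.0,
        }
        assert score == pytest.approx(3.0)

    def test_constant_errors_survive_averaging(self, le_table):
        per_channel = {c: 1.7 for c in le_table.monitored_channels("ankle_L")}
        score, _ = sk.aggregate_involuntary(per_channel, "ankle_L", le_table)
        assert score == pytest.approx(1.7)

    def test_target_channel_always_excluded(self, le_table):
        per_channel = {c: 2.0 for c in le_table.monitored_channels("ankle_L")}
        base, _ = sk.aggregate_involuntary(per_channel, "ankle_L", le_table)
        per_channel["ankle_L"] = 1e6
        spiked, _ = sk.aggregate_involuntary(per_channel, "ankle_L", le_table)
        assert spiked == base

    def test_score_is_mean_of_units(self, le_table):
        rng = np.random.default_rng(37)
        per_channel = {c: float(rng.uniform(0, 5)) for c in le_table.monitored_channels("ankle_L")}
        score, per_unit = sk.aggregate_involuntary(per_channel, "ankle_L", le_table)
        assert score == pytest.approx(np.mean(list(per_unit.values())), abs=1e-12)

    def test_unit_counts_per_target(self, le_table, ue_table):
        assert len(le_table.aggregation_units("ankle_L")) == 6
        assert len(le_table.aggregation_units("hip_flexion_L")) == 7  # hip unit keeps rotation
        assert len(ue_table.aggregation_units("elbow_R")) == 10


class TestMissingChannels:
    def test_no_missing_is_identity(self):
        errs = {"a": 1.0, "b": 2.0}
        assert sk.handle_missing_channels(errs) == errs

    def test_drop_leaves_partial_unit(self, le_table):
        per_channel = {c: 2.0 for c in le_table.monitored_channels("ankle_L")}
        per_channel["trunk_ventral"] = None
        per_channel["trunk_lateral"] = 4.0
        kept = sk.handle_missing_channels(per_channel, "drop")
        _, per_unit = sk.aggregate_involuntary(kept, "ankle_L", le_table)
        assert per_unit["trunk"] == pytest.approx(4.0)  # lateral alone

    def test_fail_strategy_raises(self):
        with pytest.raises(sk.InvalidInputError):
            sk.handle_missing_channels({"a": 1.0, "b": None}, "fail")

    def test_all_missing_raises(self):
        with pytest.raises(sk.InvalidInputError):
            sk.handle_missing_channels({"a": None}, "drop")


class TestAgeNormalize:
    def _cohort(self):
        rng = np.random.default_rng(41)
        cohort = []
        for age in [5.5, 6.2, 6.8, 7.1, 7.9, 8.4, 8.9, 9.3, 10.5]:
            cohort.append((age, "NIC", float(rng.uniform(0.5, 2.5))))
        cohort += [(30.0, "NIA", 0.8), (35.0, "NIA", 1.0), (40.0, "NIA", 1.2)]
        return cohort

    def test_peer_mean_scores_zero(self):
        cohort = self._cohort()
        peers = [s for a, g, s in cohort if g == "NIC" and 6 <= int(a) <= 8]
        res = sk.age_normalize(float(np.mean(peers)), 7.2, "P", cohort)
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_worse_scores_plus_one(self):
        cohort = self._cohort()
        peers = [s for a, g, s in cohort if g == "NIC" and 6 <= int(a) <= 8]
        res = sk.age_normalize(float(np.mean(peers) + np.std(peers, ddof=1)), 7.2, "P", cohort)
        assert res.z == pytest.approx(1.0, abs=1e-12)  # positive = worse

    def test_age_7_2_peers_are_integer_ages_6_to_8(self):
        res = sk.age_normalize(1.0, 7.2, "P", self._cohort())
        # cohort holds 6 NIC children with integer age in {6, 7, 8}
        assert res.n_peers == 6

    def test_adults_use_whole_adult_group(self):
        res = sk.age_normalize(1.0, 33.0, "NIA", self._cohort())
        assert res.n_peers == 3 and res.z == pytest.approx(0.0)

    def test_small_peer_group_yields_no_z(self):
        res = sk.age_normalize(1.0, 16.0, "P", self._cohort())
        assert res.z is None and "peer group" in res.reason

    def test_zero_sd_yields_no_z(self):
        cohort = [(7.0, "NIC", 1.0)] * 4
        res = sk.age_normalize(1.0, 7.0, "P", cohort)
        assert res.z is None and "zero SD" in res.reason

    def test_shared_age_group_z_scores_standardized(self):
        rng = np.random.default_rng(43)
        cohort = [(7.3, "NIC", float(rng.uniform(0, 3))) for _ in range(12)]
        zs = [sk.age_normalize(s, a, "NIC", cohort).z for a, _, s in cohort]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-12)
        assert np.std(zs, ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestEndToEndScoring:
    def test_reference_score_invariants(self, nia_reference, nia_sessions):
        ps = sk.process_sim_session(nia_sessions[0])
        scores = nia_reference.score(ps)
        assert scores.accuracy >= 0 and scores.involuntary >= 0
        assert scores.involuntary == pytest.approx(
            np.mean(list(scores.per_joint_unit.values())), abs=1e-12
        )
        assert not scores.missing_channels
        assert "accuracy" in scores.summary()

    def test_score_rejects_other_target(self, nia_reference):
        s = _session(meta=sk.SessionMeta(group="P", age=10, target_joint="knee_L"))
        with pytest.raises(sk.InvalidInputError):
            nia_reference.score(s)

    def test_score_cohort_attaches_z(self, nia_reference, nia_sessions):
        processed = [sk.process_sim_session(s) for s in nia_sessions[:5]]
        scored = sk.score_cohort(processed, nia_reference)
        assert all(s.z_accuracy is not None for s in scored)
        zs = [s.z_involuntary for s in scored]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)
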