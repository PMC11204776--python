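import warnings

import numpy as np
import pytest

from pivotshift.errors import DegenerateSignalError
from pivotshift.features import characteristic_table
from pivotshift.model import StudySession, SubjectRecord
from pivotshift.reliability import (
    ICC_FORMS,
    RatingsMatrix,
    icc,
    interobserver_analysis,
    intraobserver_analysis,
    landis_koch_label,
)
from pivotshift.simulate import SimParams, simulate_recording


def brute_force_icc(x, form):
    """Independent ANOVA oracle: explicit double loops, no vectorization."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum(
        (x[i][j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_total - ss_rows - ss_cols, 0.0) / ((n - 1) * (k - 1))
    msw = max(ss_total - ss_rows, 0.0) / (n * (k - 1))
    if form == "ICC(1)":
        return (msr - msw) / (msr + (k - 1) * msw)
    if form == "ICC(2,1)":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_identical_raters_give_one_for_every_form(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        for form in ICC_FORMS:
            assert icc(RatingsMatrix(x), form).estimate == pytest.approx(1.0)

    def test_additive_shift_consistency_vs_agreement(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc(RatingsMatrix(x), "ICC(3,1)").estimate == pytest.approx(1.0)
        # absolute agreement penalizes the systematic shift: exactly 8/9
        r21 = icc(RatingsMatrix(x), "ICC(2,1)")
        assert r21.estimate == pytest.approx(8.0 / 9.0, rel=1e-12)
        assert r21.estimate < 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(2, 21))
            k = int(rng.integers(2, 7))
            x = rng.normal(scale=rng.uniform(0.5, 10.0), size=(n, k))
            for form in ICC_FORMS:
                got = icc(RatingsMatrix(x), form).estimate_raw
                assert got == pytest.approx(brute_force_icc(x, form), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="target", raters="rater", ratings="score"
        )["ICC"]
        # rows 0..2 are the single-rating forms: one-way random, two-way
        # random absolute agreement, two-way mixed consistency
        assert icc(RatingsMatrix(x), "ICC(1)").estimate_raw == pytest.approx(
            ref.iloc[0], abs=1e-9
        )
        assert icc(RatingsMatrix(x), "ICC(2,1)").estimate_raw == pytest.approx(
            ref.iloc[1], abs=1e-9
        )
        assert icc(RatingsMatrix(x), "ICC(3,1)").estimate_raw == pytest.approx(
            ref.iloc[2], abs=1e-9
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 4))
        perm = rng.permutation(10)
        for form in ICC_FORMS:
            assert icc(RatingsMatrix(x), form).estimate_raw == pytest.approx(
                icc(RatingsMatrix(x[perm]), form).estimate_raw, abs=1e-12
            )

    def test_monotone_degradation_with_rater_noise(self):
        """More rater noise never increases the average ICC."""
        rng = np.random.default_rng(0)
        means = []
        for sd in (0.5, 2.0, 5.0, 10.0):
            vals = []
            for _ in range(40):
                truth = rng.normal(scale=5.0, size=(12, 1))
                x = truth + rng.normal(scale=sd, size=(12, 4))
                vals.append(icc(RatingsMatrix(x), "ICC(2,1)").estimate)
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            icc(RatingsMatrix(np.full((3, 2), 7.0)))

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            RatingsMatrix(np.array([[1.0, 2.0]]))

    def test_mean_squares_reproduce_estimate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 3))
        r = icc(RatingsMatrix(x), "ICC(3,1)")
        k = r.k_raters
        recomputed = (r.ms_between_targets - r.ms_error) / (
            r.ms_between_targets + (k - 1) * r.ms_error
        )
        assert recomputed == pytest.approx(r.estimate_raw, abs=1e-12)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.95, "almost perfect"),
            (0.71, "substantial"),
            (0.0, "poor"),
            (0.3, "fair"),
            (0.5, "moderate"),
        ],
    )
    def test_bands(self, value, label):
        assert landis_koch_label(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            landis_koch_label(1.2)


def _session_from(recs, subject_ids, evaluators):
    return StudySession(
        subjects=[SubjectRecord(subject_id=s) for s in subject_ids],
        recordings=recs,
        evaluators=evaluators,
    )


def _make_recording(times, amps, sid, eid, rep):
    return simulate_recording(
        SimParams(peak_times_cs=times, peak_amplitudes=amps, noise_sd=0.0),
        sid, eid, rep,
    )


def _cv(session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return characteristic_table(session)


class TestIntraObserver:
    def _copy_repeat_session(self):
        rng = np.random.default_rng(1)
        recs, sids = [], []
        for i in range(5):
            sid = f"S{i}"
            sids.append(sid)
            start = rng.uniform(60, 95)
            times = [start, start + rng.uniform(130, 150)]
            times.append(times[1] + rng.uniform(130, 150))
            amps = rng.uniform(100, 200, 3)
            for rep in (1, 2):
                recs.append(_make_recording(list(times), list(amps), sid, "E1", rep))
        return _session_from(recs, sids, ["E1"])

    def test_exact_copies_give_unit_icc(self):
        res = intraobserver_analysis(_cv(self._copy_repeat_session()))
        assert res.global_average["time"] == pytest.approx(1.0)
        assert res.global_average["amplitude"] == pytest.approx(1.0)

    def test_amplitude_gain_jitter_degrades_amplitude_only(self):
        """Repeats that differ by a pure gain keep timing reliable."""
        worse = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            recs, sids = [], []
            for i in range(5):
                sid = f"S{i}"
                sids.append(sid)
                start = rng.uniform(60, 95)
                times = [start, start + rng.uniform(130, 150)]
                times.append(times[1] + rng.uniform(130, 150))
                amps = rng.uniform(100, 220, 3)
                for rep in (1, 2, 3):
                    gain = rng.normal(1.0, 0.15)
                    gain = max(gain, 0.3)
                    recs.append(
                        _make_recording(times, list(amps * gain), sid, "E1", rep)
                    )
            res = intraobserver_analysis(_cv(_session_from(recs, sids, ["E1"])))
            e1 = res.per_evaluator["E1"]
            assert e1["time"].estimate == pytest.approx(1.0, abs=1e-6)
            if e1["amplitude"].estimate < e1["time"].estimate:
                worse += 1
        assert worse >= 48  # amplitude reliability below timing almost always

    def test_single_repeat_evaluator_excluded_with_warning(self):
        session = self._copy_repeat_session()
        lone = _make_recording([70, 210, 350], [120, 130, 140], "S0", "E2", 1)
        session = _session_from(
            session.recordings + [lone],
            [s.subject_id for s in session.subjects],
            ["E1", "E2"],
        )
        with pytest.warns(UserWarning, match="E2"):
            res = intraobserver_analysis(_cv(session))
        assert "E2" in res.excluded
        assert list(res.per_evaluator) == ["E1"]


class TestInterObserver:
    def _two_rater_session(self, gain=1.0):
        rng = np.random.default_rng(3)
        recs, sids = [], []
        for i in range(6):
            sid = f"S{i}"
            sids.append(sid)
            start = rng.uniform(60, 95)
            times = [start, start + rng.uniform(130, 150)]
            times.append(times[1] + rng.uniform(130, 150))
            amps = rng.uniform(100, 220, 3)
            recs.append(_make_recording(times, list(amps), sid, "E1", 1))
            recs.append(_make_recording(times, list(amps * gain), sid, "E2", 1))
        return _session_from(recs, sids, ["E1", "E2"])

    def test_identical_raters_give_one(self):
        res = interobserver_analysis(_cv(self._two_rater_session(gain=1.0)))
        assert res.per_measure["time"].estimate == pytest.approx(1.0)
        assert res.per_measure["amplitude"].estimate == pytest.approx(1.0)

    def test_gain_difference_hits_amplitude_not_time(self):
        res = interobserver_analysis(_cv(self._two_rater_session(gain=1.4)))
        assert res.per_measure["amplitude"].estimate < res.per_measure["time"].estimate
        assert res.per_measure["time"].estimate == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_coverage_rejected(self):
        rng = np.random.default_rng(4)
        recs, sids = [], []
        for i in range(4):
            sid = f"S{i}"
            sids.append(sid)
            start = rng.uniform(60, 95)
            times = [start, start + 140, start + 280]
            amps = list(rng.uniform(100, 200, 3))
            eid = "E1" if i < 2 else "E2"
            recs.append(_make_recording(times, amps, sid, eid, 1))
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            interobserver_analysis(_cv(_session_from(recs, sids, ["E1", "E2"])))
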