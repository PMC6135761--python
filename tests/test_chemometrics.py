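"""PCR calibration: recovery, interference rejection, and score-space geometry."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from fscvkit import (
    CalibrationSet,
    DegenerateCalibrationError,
    EvokedConfig,
    PCRCalibration,
    cluster_separation,
    cv_correlation,
    extract_cv,
    make_calibration_standards,
    make_da_template,
    make_ph_template,
    simulate_evoked_session,
    subtract_background,
    transient_metrics,
)


def test_single_species_calibration_recovers_labels_exactly(waveform, template_spec):
    concs = (250.0, 500.0, 1000.0)
    cvs = [make_da_template(template_spec, c / 1000.0, waveform) for c in concs]
    labels = [("DA", c) for c in concs]
    res = PCRCalibration(CalibrationSet(cvs, labels, waveform)).fit()
    assert res.k == 1  # exact multiples of one template span one component
    pred = res.predict(cvs[1])
    assert pred[0, 0] == pytest.approx(500.0, abs=1e-6)


def test_da_and_ph_standards_form_disjoint_clusters(waveform, template_spec):
    cvs, labels = make_calibration_standards(
        template_spec, waveform, drift_amplitudes_nA=(), current_noise_rms=0.05,
        seed=2,
    )
    res = PCRCalibration(CalibrationSet(cvs, labels, waveform)).fit()
    assert res.k >= 2
    space = res.score_space(cvs, [t for t, _ in labels])
    groups = np.array(space.groups)
    sil = silhouette_score(space.scores, groups)
    assert sil > 0.5


def test_full_variance_threshold_retains_pca_rank(waveform, template_spec):
    cvs, labels = make_calibration_standards(
        template_spec, waveform, da_concs_nM=(200.0, 600.0),
        ph_values=(-0.1, 0.1), drift_amplitudes_nA=(), replicates=1,
        current_noise_rms=0.01, seed=3,
    )
    res = PCRCalibration(CalibrationSet(cvs, labels, waveform), 1.0).fit()
    assert res.k == min(len(cvs) - 1, waveform.samples_per_scan)


def test_identical_standards_raise_degenerate_error(waveform, template_spec):
    cv = make_da_template(template_spec, 0.5, waveform)
    cvs = [cv.copy(), cv.copy(), cv.copy()]
    labels = [("DA", 250.0), ("DA", 500.0), ("DA", 1000.0)]
    with pytest.raises(DegenerateCalibrationError):
        PCRCalibration(CalibrationSet(cvs, labels, waveform)).fit()


def test_projection_recovers_standards_exactly(noiseless_calibration):
    cal = noiseless_calibration.model.calibration
    pred = noiseless_calibration.predict(np.vstack(cal.cvs))
    truth = cal.label_matrix()
    np.testing.assert_allclose(pred, truth, atol=1e-6)


def test_evoked_peak_recovered_within_ten_percent(
    waveform, template_spec, noiseless_calibration
):
    session, truth = simulate_evoked_session(
        EvokedConfig(true_peak_conc=200.0, current_noise_rms=0.04, seed=7),
        template_spec, waveform,
    )
    plot = subtract_background(session, (0, 20))
    trace = noiseless_calibration.project(plot)
    tm = transient_metrics(trace)
    assert tm.peak_dDA_nM == pytest.approx(200.0, rel=0.10)


def test_pure_ph_session_projects_below_lod(
    waveform, template_spec, noiseless_calibration
):
    """A pH transient with no dopamine must not masquerade as dopamine."""
    # noiseless leakage: the pH + drift directions are nulled by calibration
    clean, _ = simulate_evoked_session(
        EvokedConfig(true_peak_conc=0.0, ph_transient_amplitude=0.1,
                     current_noise_rms=0.0, seed=0),
        template_spec, waveform,
    )
    leak = noiseless_calibration.project(subtract_background(clean, (0, 20)))
    assert np.max(np.abs(leak.dda_nM)) < 0.5  # nM, far below any LOD

    # at the chronic noise level the whole trace stays under the LOD
    session, _ = simulate_evoked_session(
        EvokedConfig(true_peak_conc=0.0, ph_transient_amplitude=0.1,
                     current_noise_rms=0.04, seed=3),
        template_spec, waveform,
    )
    trace = noiseless_calibration.project(subtract_background(session, (0, 20)))
    assert np.max(np.abs(trace.dda_nM)) < trace.lod_nM


def test_concentration_estimate_linear_in_cv_scale(
    waveform, template_spec, noiseless_calibration
):
    cv = make_da_template(template_spec, 0.4, waveform)  # 400 nM
    base = noiseless_calibration.predict(cv)[0, 0]
    for alpha in (0.5, 2.0, 10.0):
        scaled = noiseless_calibration.predict(alpha * cv)[0, 0]
        assert scaled == pytest.approx(alpha * base, rel=1e-9)


def test_pcr_equals_direct_least_squares_on_tiny_instance():
    """With k = n-1, PCR prediction must match the min-norm regression of
    labels on centered CVs (oracle identity on a 3 x 8 instance)."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(3, 8))
    labels = [("DA", 100.0), ("DA", 300.0), ("pH", 0.1)]
    cal = CalibrationSet([x for x in X], labels)
    res = PCRCalibration(cal, variance_threshold=1.0).fit()
    assert res.k == 2
    Xc = X - X.mean(axis=0)
    Y = cal.label_matrix()
    B = np.linalg.pinv(Xc) @ (Y - Y.mean(axis=0))
    probe = rng.normal(size=(5, 8))
    direct = Y.mean(axis=0) + (probe - X.mean(axis=0)) @ B
    np.testing.assert_allclose(res.predict(probe), direct, atol=1e-8)


class TestCvCorrelation:
    def test_self_and_anti_correlation(self, waveform, template_spec):
        cv = make_da_template(template_spec, 1.0, waveform)
        assert cv_correlation(cv, cv) == pytest.approx(1.0)
        assert cv_correlation(-cv, cv) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self, waveform):
        flat = np.zeros(waveform.samples_per_scan)
        with pytest.raises(ValueError):
            cv_correlation(flat, flat)

    def test_chronic_cv_correlates_with_standard(self, waveform, template_spec):
        session, truth = simulate_evoked_session(
            EvokedConfig(true_peak_conc=300.0, current_noise_rms=0.04, seed=12),
            template_spec, waveform,
        )
        plot = subtract_background(session, (0, 20))
        cv = extract_cv(plot, truth["peak_scan"])
        template = make_da_template(template_spec, 0.5, waveform)
        assert cv_correlation(cv, template) > 0.75


class TestScoreSpace:
    def test_mean_cv_projects_to_origin(self, noiseless_calibration):
        scores = noiseless_calibration.transform(noiseless_calibration.mean_cv)
        np.testing.assert_allclose(scores, 0.0, atol=1e-9)

    def test_da_dilution_series_is_collinear(self, waveform, template_spec,
                                             noiseless_calibration):
        concs = np.linspace(100, 900, 9)
        cvs = [make_da_template(template_spec, c / 1000.0, waveform) for c in concs]
        space = noiseless_calibration.score_space(cvs, ["DA"] * len(cvs))
        pc1, pc2 = space.scores[:, 0], space.scores[:, 1]
        fit = np.polyfit(pc1, pc2, 1)
        resid = pc2 - np.polyval(fit, pc1)
        ss_tot = np.sum((pc2 - pc2.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        assert r2 > 0.99

    def test_evoked_cvs_nearer_da_than_ph_centroid(self, waveform, template_spec,
                                                   noiseless_calibration):
        da_cvs = [make_da_template(template_spec, c, waveform)
                  for c in (0.25, 0.5, 1.0)]
        ph_cvs = [make_ph_template(d, waveform) for d in (-0.2, -0.15, -0.1, -0.05)]
        vivo = []
        for seed in range(1, 6):
            session, truth = simulate_evoked_session(
                EvokedConfig(true_peak_conc=150.0 + 100.0 * seed, seed=seed),
                template_spec, waveform,
            )
            plot = subtract_background(session, (0, 20))
            vivo.append(extract_cv(plot, truth["peak_scan"]))
        cvs = da_cvs + ph_cvs + vivo
        groups = ["DA"] * 3 + ["pH"] * 4 + ["invivo"] * len(vivo)
        space = noiseless_calibration.score_space(cvs, groups)
        da_c = space.group_scores("DA").mean(axis=0)
        ph_c = space.group_scores("pH").mean(axis=0)
        for point in space.group_scores("invivo"):
            assert np.linalg.norm(point - da_c) < np.linalg.norm(point - ph_c)


class TestClusterSeparation:
    def test_identical_groups_score_zero(self, rng):
        pts = rng.normal(size=(20, 2))
        from fscvkit.chemometrics import ScoreSpace

        space = ScoreSpace(np.vstack([pts, pts]), ["a"] * 20 + ["b"] * 20)
        assert cluster_separation(space, "a", "b") == pytest.approx(0.0)

    def test_matches_closed_form_for_gaussian_clusters(self, rng):
        from fscvkit.chemometrics import ScoreSpace

        d, s, n = 5.0, 1.0, 4000
        # isotropic 2-D clusters at (+-d, 0) with per-axis sigma s/sqrt(2),
        # so the RMS distance from each centroid is s
        a = rng.normal([d, 0.0], s / np.sqrt(2), size=(n, 2))
        b = rng.normal([-d, 0.0], s / np.sqrt(2), size=(n, 2))
        space = ScoreSpace(np.vstack([a, b]), ["a"] * n + ["b"] * n)
        expected = 2 * d / (s * np.sqrt(2))
        assert cluster_separation(space, "a", "b") == pytest.approx(expected, rel=0.1)

    def test_da_and_ph_standards_are_separated(self, waveform, template_spec):
        cvs, labels = make_calibration_standards(
            template_spec, waveform, drift_amplitudes_nA=(),
            current_noise_rms=0.05, seed=6,
        )
        res = PCRCalibration(CalibrationSet(cvs, labels, waveform)).fit()
        space = res.score_space(cvs, [t for t, _ in labels])
        assert cluster_separation(space, "DA", "pH") > 2.0

    def test_single_member_group_rejected(self):
        from fscvkit.chemometrics import ScoreSpace

        space = ScoreSpace(np.array([[0.0, 0], [1, 1], [2, 2]]), ["a", "a", "b"])
        with pytest.raises(ValueError):
            cluster_separation(space, "a", "b")
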