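"""Synthetic-cohort generator: calibration closed form, cohort structure,
grade encoding, and phantom construction."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from elshydro.cohort import (
    PUBLISHED_DISTRIBUTIONS,
    CohortConfig,
    GradeCutpoints,
    GroupDistribution,
    InvalidDistributionError,
    calibrate_lognormal,
    generate_cohort,
    generate_phantom,
    grade_from_ratio,
)
from elshydro.volumetry import measure

Z75 = norm.ppf(0.75)


class TestCalibration:
    def test_closed_form_control_cochlea(self):
        d = GroupDistribution("cochlea", "control", 8.15, 4.93, 14.45)
        mu, sigma = calibrate_lognormal(d)
        assert mu == pytest.approx(math.log(8.15))
        assert sigma == pytest.approx(math.log(14.45 / 4.93) / (2 * Z75))

    @pytest.mark.parametrize("dist", PUBLISHED_DISTRIBUTIONS, ids=lambda d: f"{d.compartment}-{d.group}")
    def test_quantiles_reproduced_exactly(self, dist):
        """The calibrated log-normal hits the target median and IQR ratio."""
        mu, sigma = calibrate_lognormal(dist)
        q1, med, q3 = (math.exp(mu + sigma * norm.ppf(q)) for q in (0.25, 0.5, 0.75))
        assert med == pytest.approx(dist.median_pct, rel=1e-12)
        assert q3 / q1 == pytest.approx(dist.q3_pct / dist.q1_pct, rel=1e-12)

    def test_median_depends_only_on_mu(self):
        for k in (1.5, 3.0, 9.0):
            d = GroupDistribution("cochlea", "control", 10.0, 10.0 / k, min(10.0 * k, 100.0))
            mu, _ = calibrate_lognormal(d)
            assert mu == pytest.approx(math.log(10.0))

    def test_degenerate_quantiles_rejected(self):
        with pytest.raises(InvalidDistributionError):
            GroupDistribution("cochlea", "control", 10.0, 10.0, 10.0)
        with pytest.raises(InvalidDistributionError):
            GroupDistribution("cochlea", "control", 10.0, -1.0, 20.0)
        with pytest.raises(InvalidDistributionError):
            GroupDistribution("cochlea", "control", 10.0, 12.0, 20.0)


class TestGrading:
    def test_extremes(self):
        assert grade_from_ratio(0.0, "vestibule") == 0.0
        assert grade_from_ratio(1.0, "vestibule") == 1.0

    def test_boundary_takes_higher_grade(self):
        cp = GradeCutpoints(cochlea=(0.2, 0.4), vestibule=(0.3, 0.5))
        assert grade_from_ratio(0.2, "cochlea", cp) == 0.5
        assert grade_from_ratio(0.4, "cochlea", cp) == 1.0
        assert grade_from_ratio(0.3 - 1e-12, "vestibule", cp) == 0.0

    def test_unknown_compartment(self):
        with pytest.raises(ValueError):
            grade_from_ratio(0.5, "scc")


class TestGenerateCohort:
    def test_row_counts_match_study_design(self, cohort):
        """47 controls contribute both ears; 86 patients one ear each."""
        assert (cohort["group"] == "control").sum() == 94
        assert (cohort["group"] == "uMD").sum() == 86
        ctrl = cohort[cohort["group"] == "control"]
        assert (ctrl.groupby("subject_id").size() == 2).all()
        pat = cohort[cohort["group"] == "uMD"]
        assert (pat.groupby("subject_id").size() == 1).all()

    def test_determinism(self):
        cfg = CohortConfig(n_controls=5, n_patients=5, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.equals(b)

    def test_volume_ordering_and_truncation(self, cohort):
        for els, tot in (("Vh", "Vv"), ("Ch", "Cv"), ("Sh", "Sv")):
            ratio = cohort[els] / cohort[tot]
            assert (cohort[els] >= 0).all()
            assert (ratio > 0).all() and (ratio <= 1).all()

    def test_grades_consistent_with_ratios(self, cohort):
        cp = GradeCutpoints()
        expect = cohort.apply(
            lambda r: grade_from_ratio(r["Ch"] / r["Cv"], "cochlea", cp), axis=1
        )
        assert (cohort["EHC"] == expect).all()

    def test_sex_age_marginals(self):
        """Subject-level sex and age marginals match the configured design
        within sampling error."""
        cfg = CohortConfig(n_controls=500, n_patients=500, seed=11)
        df = generate_cohort(cfg)
        subj = df.drop_duplicates("subject_id")
        ctrl = subj[subj["group"] == "control"]
        pat = subj[subj["group"] == "uMD"]
        for grp, p, mean, sd in (
            (ctrl, cfg.p_male_control, cfg.age_mean_control, cfg.age_sd_control),
            (pat, cfg.p_male_patient, cfg.age_mean_patient, cfg.age_sd_patient),
        ):
            n = len(grp)
            p_hat = (grp["sex"] == "male").mean()
            assert abs(p_hat - p) < 3 * math.sqrt(p * (1 - p) / n)
            assert abs(grp["age"].mean() - mean) < 3 * sd / math.sqrt(n)

    def test_onset_interval_patients_only(self, cohort):
        pat = cohort[cohort["group"] == "uMD"]
        ctrl = cohort[cohort["group"] == "control"]
        assert pat["onset_interval_days"].notna().all()
        assert ctrl["onset_interval_days"].isna().all()
        assert pat["onset_interval_days"].between(0, 3650).all()

    def test_ratio_correlation_option(self):
        """A positive copula correlation induces positive empirical
        correlation between compartment ratios."""
        cfg = CohortConfig(n_controls=400, n_patients=2, seed=5, ratio_correlation=0.8)
        df = generate_cohort(cfg)
        ctrl = df[df["group"] == "control"]
        r = np.corrcoef(
            np.log(ctrl["Ch"] / ctrl["Cv"]), np.log(ctrl["Vh"] / ctrl["Vv"])
        )[0, 1]
        assert r > 0.5

    def test_contralateral_option(self):
        cfg = CohortConfig(n_controls=3, n_patients=4, seed=1, include_contralateral=True)
        df = generate_cohort(cfg)
        pat = df[df["group"] == "uMD"]
        assert len(pat) == 8
        assert pat["affected"].sum() == 4

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CohortConfig(n_controls=0)
        with pytest.raises(ValueError):
            CohortConfig(p_male_control=1.5)


class TestPhantom:
    def test_constructed_counts(self):
        rec = {"Cv": 75.0, "Vv": 60.0, "Sv": 60.0, "Ch": 15.0, "Vh": 30.0, "Sh": 6.0}
        res = generate_phantom(rec, voxel_size=(0.5, 0.5, 0.5))
        vx = 0.125
        assert res.counts["vestibule"] == (round(60 / vx), round(30 / vx))
        m = measure(res.volume)
        assert m.compartments["vestibule"].total_volume == pytest.approx(60.0, abs=vx)
        assert m.compartments["vestibule"].els_volume == pytest.approx(30.0, abs=vx)

    def test_zero_els_gives_no_negative_voxels(self):
        rec = {"Cv": 20.0, "Vv": 20.0, "Sv": 20.0, "Ch": 0.0, "Vh": 0.0, "Sh": 0.0}
        res = generate_phantom(rec, voxel_size=(1.0, 1.0, 1.0), grid_shape=(9, 8, 8))
        assert (res.volume.signal < 0).sum() == 0

    def test_roundtrip_ratio_within_one_voxel(self, cohort):
        """Volumetry on a phantom recovers each ELS ratio to within the
        relative contribution of a single voxel."""
        for _, rec in cohort.head(10).iterrows():
            res = generate_phantom(rec)
            m = measure(res.volume)
            for comp, (n_tot, n_els) in res.counts.items():
                true_ratio = {"cochlea": rec["Ch"] / rec["Cv"],
                              "vestibule": rec["Vh"] / rec["Vv"],
                              "scc": rec["Sh"] / rec["Sv"]}[comp]
                assert m.compartments[comp].els_ratio == pytest.approx(
                    true_ratio, abs=1.0 / n_tot
                )

    def test_capacity_error(self):
        rec = {"Cv": 75.0, "Vv": 60.0, "Sv": 60.0, "Ch": 15.0, "Vh": 30.0, "Sh": 6.0}
        with pytest.raises(ValueError, match="slab holds"):
            generate_phantom(rec, voxel_size=(0.1, 0.1, 0.1), grid_shape=(9, 8, 8))
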