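"""Tests for operon burden prediction, calibration and decomposition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ribocap import (
    AssayConfig,
    BurdenPipeline,
    CapacityCalibrator,
    CalibrationFit,
    CalibrationRegistry,
    Cistron,
    ConstructSpec,
    OperonDesign,
    decompose_burden,
    fit_calibration,
    mrna_concentration,
    operon_to_species,
    predict_in_vitro,
    predict_in_vivo,
)


class TestMrnaConcentration:
    @pytest.mark.parametrize(
        "promoter, plasmid, expected",
        [("strong", 30.0, 900.0), ("strong", 20.0, 600.0), ("medium", 20.0, 200.0),
         ("weak", 20.0, 60.0)],
    )
    def test_per_dna_yields(self, promoter, plasmid, expected):
        assert mrna_concentration(promoter, plasmid) == expected

    def test_unknown_promoter_rejected(self):
        with pytest.raises(ValueError, match="unknown promoter"):
            mrna_concentration("ultra", 20.0)

    def test_non_positive_plasmid_rejected(self):
        with pytest.raises(ValueError):
            mrna_concentration("strong", 0.0)


class TestOperonToSpecies:
    def test_single_cistron_equals_single_gene(self):
        op = OperonDesign("op", "strong", 20.0, (Cistron("g", 2.6, 900, 0.8),))
        (sp,) = operon_to_species(op)
        assert sp == ConstructSpec("g", 2.6, 600.0, 900, 0.8)

    def test_cistrons_share_transcript_concentration(self):
        op = OperonDesign(
            "op", "strong", 20.0,
            (Cistron("a", 2.6, 900, 1.0), Cistron("b", 1.0, 600, 0.5)),
        )
        species = operon_to_species(op)
        assert [s.mrna_conc for s in species] == [600.0, 600.0]

    def test_missing_gamma_names_the_cistron(self):
        op = OperonDesign("op", "strong", 20.0, (Cistron("luxA", 2.6, 900),))
        with pytest.raises(ValueError, match="luxA"):
            operon_to_species(op)

    def test_empty_operon_rejected(self):
        with pytest.raises(ValueError):
            OperonDesign("op", "strong", 20.0, ())


class TestPredictInVitro:
    def test_single_cistron_matches_construct_path(self, assay):
        op = OperonDesign("op", "strong", 20.0, (Cistron("g", 2.6, 900, 0.8),))
        c = ConstructSpec("g", 2.6, 600.0, 900, 0.8)
        assert predict_in_vitro(op, assay) == predict_in_vitro(c, assay)

    def test_weaker_rbs_gives_higher_capacity(self, assay):
        bcd2 = ConstructSpec("g", 2.6, 600.0, 1500, 0.5)
        bcd21 = ConstructSpec("g", 2.1, 600.0, 1500, 0.5)
        assert predict_in_vitro(bcd21, assay) > predict_in_vitro(bcd2, assay)

    def test_added_cistron_never_increases_capacity(self, assay):
        cistrons = [
            Cistron("crtE", 2.0, 900, 0.9),
            Cistron("crtB", 1.5, 930, 0.7),
            Cistron("crtI", 2.2, 1480, 0.5),
            Cistron("crtY", 1.2, 1150, 0.8),
        ]
        caps = []
        for k in range(1, 5):
            op = OperonDesign("op", "strong", 20.0, tuple(cistrons[:k]))
            caps.append(predict_in_vitro(op, assay))
        assert np.all(np.diff(caps) <= 1e-9)
        # full operon is at most the capacity of any single cistron alone
        singles = [
            predict_in_vitro(OperonDesign("s", "strong", 20.0, (c,)), assay)
            for c in cistrons
        ]
        assert caps[-1] <= min(singles) + 1e-9

    def test_mrna_sweep_regimes_differ(self, assay):
        """Cheap strong-RBS construct responds near-linearly to dosage,
        expensive one super-linearly (the published sweep contrast)."""
        sweeps = {}
        for name, (gamma, rbs) in {"cheap": (1.4, 2.6), "costly": (0.6, 2.4)}.items():
            concs = np.linspace(0.0, 900.0, 6)
            caps = []
            for m in concs:
                if m == 0:
                    caps.append(1.0)
                else:
                    c = ConstructSpec("t", rbs, float(m), 3000, gamma)
                    caps.append(predict_in_vitro(c, assay))
            fit = np.polyfit(concs, caps, 1)
            resid = caps - np.polyval(fit, concs)
            ss = 1 - resid @ resid / np.var(caps) / len(caps)
            sweeps[name] = ss
        assert sweeps["cheap"] > sweeps["costly"]


class TestCalibration:
    def test_exact_fit_on_printed_relation(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        fit = fit_calibration(list(zip(x, 0.7 * x + 0.19)), condition="reference")
        assert fit.slope == pytest.approx(0.7, abs=1e-12)
        assert fit.intercept == pytest.approx(0.19, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 5

    def test_identity_fit(self):
        x = np.array([0.1, 0.5, 0.9])
        fit = fit_calibration(list(zip(x, x)))
        assert fit.slope == pytest.approx(1.0) and fit.intercept == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.5, 0.2), (0.5, 0.6)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.5, 0.2)])

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.2, 1.0, size=10)
        y = (0.7 * x + 0.19) * rng.lognormal(0, 0.05, size=10)
        fit = fit_calibration(list(zip(x, y)))
        assert fit.slope == pytest.approx(0.7, rel=0.10)


class TestPredictInVivo:
    def test_printed_relation_at_unity(self):
        fit = CalibrationFit(0.7, 0.19, 1.0, "reference", 10)
        assert predict_in_vivo(1.0, fit) == pytest.approx(0.89)
        assert predict_in_vivo(0.0, fit) == pytest.approx(0.19)

    def test_identity_fit_passthrough(self):
        fit = CalibrationFit(1.0, 0.0, 1.0, "id", 2)
        assert predict_in_vivo(0.37, fit) == pytest.approx(0.37)

    def test_clipping_warns(self):
        fit = CalibrationFit(1.5, 0.0, 1.0, "c", 2)
        with pytest.warns(UserWarning, match="clipped"):
            assert predict_in_vivo(0.9, fit) == 1.0


class TestCalibrationRegistry:
    def test_explicit_condition_required(self):
        reg = CalibrationRegistry()
        reg.add(CalibrationFit(0.7, 0.19, 1.0, "reference", 5))
        assert reg.get("reference").slope == 0.7
        with pytest.raises(KeyError, match="no calibration"):
            reg.get("LB")

    def test_unlabelled_fit_rejected(self):
        with pytest.raises(ValueError):
            CalibrationRegistry().add(CalibrationFit(0.7, 0.19, 1.0, "", 5))


class TestDecomposition:
    def test_component_identities(self):
        d = decompose_burden(0.8, 0.6)
        assert d.metabolic_component == 0.8 - 0.6
        assert d.expression_component == 1.0 - 0.8
        assert not d.over_predicted

    def test_equal_prediction_zero_metabolic(self):
        assert decompose_burden(0.55, 0.55).metabolic_component == 0.0

    def test_over_prediction_flagged(self):
        with pytest.warns(UserWarning):
            d = decompose_burden(0.4, 0.6)
        assert d.over_predicted and d.metabolic_component == pytest.approx(-0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decompose_burden(1.2, 0.5)


class TestCapacityCalibrator:
    def test_sklearn_contract_and_fit(self):
        est = CapacityCalibrator(condition="reference")
        assert clone(est).get_params()["condition"] == "reference"
        x = np.array([0.2, 0.5, 0.8, 1.0])
        est.fit(x.reshape(-1, 1), 0.7 * x + 0.19)
        assert est.slope_ == pytest.approx(0.7)
        assert est.intercept_ == pytest.approx(0.19)
        np.testing.assert_allclose(est.predict([[1.0]]), [0.89])
        fit = est.to_fit()
        assert isinstance(fit, CalibrationFit) and fit.condition == "reference"

    def test_clipping_toggle(self):
        x = np.array([0.0, 1.0])
        est = CapacityCalibrator(clip=False).fit(x, 1.5 * x)
        assert est.predict([2.0])[0] == pytest.approx(3.0)
        est = CapacityCalibrator(clip=True).fit(x, 1.5 * x)
        assert est.predict([2.0])[0] == 1.0


class TestBurdenPipeline:
    def test_fit_calibrate_predict_flow(self, assay):
        # characterise two genes from model-simulated capacities
        genes = pd.DataFrame(
            {"sample": ["lucC", "lucE"], "rbs_strength": [2.6, 2.6],
             "length_bp": [1650, 1200]}
        )
        true_gamma = [0.45, 0.9]
        caps = [
            predict_in_vitro(
                ConstructSpec(n, 2.6, 600.0, L, g), assay
            )
            for n, L, g in zip(genes["sample"], genes["length_bp"], true_gamma)
        ]
        pipe = BurdenPipeline(assay=assay).fit(genes, caps)
        np.testing.assert_allclose(pipe.gamma_table_["gamma"], true_gamma, rtol=0.01)

        pipe.calibrate([(0.2, 0.33), (0.6, 0.61), (1.0, 0.89)], condition="reference")
        design = OperonDesign(
            "operon1", "strong", 20.0,
            (Cistron("lucC", 1.8, 1650), Cistron("lucE", 1.2, 1200)),
        )
        out = pipe.predict([design], condition="reference")
        assert 0 < out.loc[0, "predicted_in_vitro"] < 1
        assert 0 <= out.loc[0, "predicted_in_vivo"] <= 1

    def test_unknown_gene_named_in_error(self, assay):
        genes = pd.DataFrame(
            {"sample": ["a"], "rbs_strength": [2.6], "length_bp": [900]}
        )
        cap = predict_in_vitro(ConstructSpec("a", 2.6, 600.0, 900, 1.0), assay)
        pipe = BurdenPipeline(assay=assay).fit(genes, [cap])
        design = OperonDesign("op", "strong", 20.0, (Cistron("mystery", 2.0, 600),))
        with pytest.raises(ValueError, match="mystery"):
            pipe.predict([design])

    def test_missing_condition_rejected(self, assay):
        genes = pd.DataFrame({"sample": ["a"], "rbs_strength": [2.6], "length_bp": [900]})
        cap = predict_in_vitro(ConstructSpec("a", 2.6, 600.0, 900, 1.0), assay)
        pipe = BurdenPipeline(assay=assay).fit(genes, [cap])
        design = OperonDesign("op", "strong", 20.0, (Cistron("a", 2.0, 600),))
        with pytest.raises(KeyError):
            pipe.predict([design], condition="reference")
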