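import json
import warnings

import numpy as np
import pytest

from iltox import (
    CollinearityError,
    DescriptorTable,
    IonDescriptors,
    PooledModelFit,
    ToxicityRecord,
    backward_eliminate,
    build_design,
    fit_mlr,
    fit_pooled_model,
    intrinsic_value,
    predict_eq4,
    published_model,
    published_table,
)


def _single_system_records(ions, responses):
    cations = [i for i in ions if i.role == "cation"]
    anions = [i for i in ions if i.role == "anion"]
    records = []
    for i, y in enumerate(responses):
        records.append(
            ToxicityRecord(
                cations[i % len(cations)].ion_id,
                anions[i % len(anions)].ion_id,
                "sys1",
                "EC50",
                float(y),
            )
        )
    return records


class TestFitMlr:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        ions = []
        for i in range(12):
            ions.append(IonDescriptors(f"C{i}", "cation", *rng.uniform(0, 2, 6)))
            ions.append(IonDescriptors(f"A{i}", "anion", *rng.uniform(0, 2, 6)))
        table = DescriptorTable(ions)
        records = []
        for i in range(12):
            cat = table.get(f"C{i}", "cation")
            records.append(
                ToxicityRecord(f"C{i}", f"A{i}", "sys1", "EC50", 1.5 * cat.V - 0.7)
            )
        design = build_design(records, table, "sys1")
        result = fit_mlr(design, terms=["V_c"])
        assert result.coefficients["V_c"] == pytest.approx(1.5, abs=1e-10)
        assert result.intercept == pytest.approx(-0.7, abs=1e-10)
        assert result.r_squared == pytest.approx(1.0, abs=1e-10)
        assert result.se == pytest.approx(0.0, abs=1e-8)

    def test_three_point_bivariate_toy(self):
        # V_c takes 0, 1, 2 and y equals V_c: slope 1, intercept 0
        ions = [
            IonDescriptors(f"C{v}", "cation", 0, 0, 0, 0, float(v), 0)
            for v in range(3)
        ] + [IonDescriptors("A0", "anion", 0, 0, 0, 0, 0, 0)]
        table = DescriptorTable(ions)
        records = [
            ToxicityRecord(f"C{v}", "A0", "sys1", "EC50", float(v)) for v in range(3)
        ]
        design = build_design(records, table, "sys1")
        result = fit_mlr(design, terms=["V_c"])
        assert result.coefficients["V_c"] == pytest.approx(1.0, abs=1e-10)
        assert result.intercept == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_pvalues_mostly_insignificant(self, make_panel):
        """Under a null surface the descriptor t-tests keep their size."""
        retained = 0
        total = 0
        for seed in range(12):
            ions, true, records = make_panel(
                seed=100 + seed,
                coefficients={},  # all-zero surface: y is z + noise only
                n_systems=4,
                n_per_system=120,
            )
            design = build_design(records, ions, true.reference_system)
            result = fit_mlr(design)
            pvals = [result.p_values[t] for t in result.terms]
            retained += sum(p > 0.05 for p in pvals)
            total += len(pvals)
        # each test exceeds 0.05 with probability ~0.95 under the null
        assert 0.88 <= retained / total <= 0.99

    def test_insufficient_rows_rejected(self, small_ions):
        records = _single_system_records(list(small_ions), [0.0, 1.0, 2.0])
        design = build_design(records, small_ions, "sys1")
        with pytest.raises(ValueError, match="insufficient data"):
            fit_mlr(design)  # 12 descriptor columns, 3 rows

    def test_collinear_columns_named(self):
        # E == S for every ion makes E_c/S_c (and E_a/S_a) collinear
        rng = np.random.default_rng(1)
        ions = []
        for i in range(20):
            e = float(rng.uniform(0, 2))
            ions.append(
                IonDescriptors(f"C{i}", "cation", e, e, *rng.uniform(0, 2, 4))
            )
            ions.append(
                IonDescriptors(f"A{i}", "anion", *rng.uniform(0, 2, 6))
            )
        table = DescriptorTable(ions)
        records = _single_system_records(list(table), np.arange(40.0))
        design = build_design(records, table, "sys1")
        with pytest.raises(CollinearityError, match="S_c"):
            fit_mlr(design)

    def test_constant_column_dropped_with_warning(self):
        # single anion: every anion descriptor column is constant
        rng = np.random.default_rng(2)
        cations = [
            IonDescriptors(f"C{i}", "cation", *rng.uniform(0, 2, 6))
            for i in range(15)
        ]
        ions = DescriptorTable(
            cations + [IonDescriptors("A1", "anion", -0.2, 0.8, 0.1, 0.6, 0.7, -0.4)]
        )
        records = [
            ToxicityRecord(
                f"C{rng.integers(15)}", "A1", "sys1", "EC50",
                float(rng.standard_normal()),
            )
            for _ in range(40)
        ]
        design = build_design(records, ions, "sys1")
        with pytest.warns(UserWarning, match="constant descriptor"):
            result = fit_mlr(design)
        assert not set(result.terms) & {"E_a", "S_a", "A_a", "B_a", "V_a", "J_minus"}


class TestBackwardElimination:
    def test_threshold_one_keeps_full_model(self, make_panel):
        ions, true, records = make_panel(seed=30, n_systems=5, n_per_system=80)
        design = build_design(records, ions, true.reference_system)
        full = fit_mlr(design)
        kept = backward_eliminate(design, p_threshold=1.0)
        assert set(kept.retained_terms) == set(full.terms)
        for t in full.terms:
            assert kept.coefficients[t] == pytest.approx(full.coefficients[t])

    def test_noiseless_full_truth_nothing_eliminated(self, make_panel):
        all_nonzero = {
            "E_c": 2.254, "S_c": -2.545, "A_c": 0.646, "B_c": -1.471,
            "V_c": 1.650, "J_plus": 2.917, "E_a": -0.201, "S_a": 0.35,
            "A_a": 0.2, "B_a": -0.4, "V_a": 0.418, "J_minus": 0.131,
        }
        ions, true, records = make_panel(
            seed=31, noise_sd=0.0, n_systems=5, n_per_system=60,
            coefficients=all_nonzero,
        )
        design = build_design(records, ions, true.reference_system)
        fit = backward_eliminate(design)
        assert fit.elimination_history == ()
        assert len(fit.retained_terms) == 12

    def test_null_anion_terms_usually_eliminated(self, make_panel):
        """S_a, A_a, B_a carry no signal and should typically be dropped.

        Each null term survives a 5 % significance screen with probability
        about 0.05, so the exact three-term set is recovered in roughly
        0.95^3 ~ 86 % of panels; assert the modal outcome and a rate
        consistent with that.
        """
        want = {"S_a", "A_a", "B_a"}
        hits = 0
        for seed in range(15):
            ions, true, records = make_panel(
                seed=300 + seed, n_cations=120, n_anions=50,
                n_systems=8, n_per_system=180,
            )
            fit = fit_pooled_model(records, ions, true.reference_system)
            hits += set(t for t, _ in fit.elimination_history) == want
        assert hits >= 9

    def test_all_terms_eliminated_warns(self, make_panel):
        ions, true, records = make_panel(
            seed=33, coefficients={}, n_systems=3, n_per_system=100
        )
        design = build_design(records, ions, true.reference_system)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = backward_eliminate(design, p_threshold=1e-12)
        assert fit.retained_terms == ()
        assert any("dummies-only" in str(w.message) for w in caught)
        assert set(fit.z) == set(true.z_true)


class TestPublishedModel:
    def test_coefficients(self, published):
        assert published.coefficients["E_c"] == 2.254
        assert published.coefficients["J_plus"] == 2.917
        assert published.coefficients["V_a"] == 0.418
        assert published.intercept == -0.709
        assert len(published.retained_terms) == 9

    def test_reference_system_sensitivity_zero(self, published):
        assert published.z["Leukemia rat cell (A)"] == 0.0
        assert published.reference_system == "Leukemia rat cell (A)"

    def test_catalogue_diagnostics(self, published):
        assert published.n_obs == 1633
        assert published.r_squared == pytest.approx(0.880)
        assert published.se == pytest.approx(0.465)

    def test_table_covers_all_systems(self):
        table = published_table()
        assert len(table) == 58
        assert set(table.columns) == {"NO", "system", "R2", "SE", "z", "alpha", "beta", "N"}

    def test_fresh_copy_each_call(self):
        a = published_model()
        b = published_model()
        a.z["Leukemia rat cell (A)"] = 99.0
        assert b.z["Leukemia rat cell (A)"] == 0.0


class TestIntrinsicAndPredict:
    def test_intercept_at_origin(self, published, zero_ions):
        assert intrinsic_value(*zero_ions, published) == pytest.approx(-0.709)

    def test_unit_E_c(self, published, zero_ions):
        cat = IonDescriptors("c", "cation", 1, 0, 0, 0, 0, 0)
        assert intrinsic_value(cat, zero_ions[1], published) == pytest.approx(1.545)

    def test_all_zero_model(self, zero_ions):
        model = PooledModelFit(
            retained_terms=(), coefficients={}, intercept=0.0,
            z={"s": 0.0}, reference_system="s", n_obs=0,
            r_squared=float("nan"), se=float("nan"),
        )
        assert intrinsic_value(*zero_ions, model) == 0.0

    def test_role_mismatch_rejected(self, published, zero_ions):
        with pytest.raises(ValueError, match="expected a cation"):
            intrinsic_value(zero_ions[1], zero_ions[1], published)

    def test_reference_prediction_is_intrinsic(self, published, zero_ions):
        eq4 = predict_eq4(*zero_ions, "Leukemia rat cell (A)", published)
        assert eq4 == intrinsic_value(*zero_ions, published)

    def test_daphnia_offset(self, published, zero_ions):
        eq4 = predict_eq4(*zero_ions, "D. magna (B & C)", published)
        assert eq4 == pytest.approx(intrinsic_value(*zero_ions, published) + 1.63)

    def test_system_difference_is_z_difference(self, published, small_ions):
        cat, an = small_ions.get("C1", "cation"), small_ions.get("A1", "anion")
        d = predict_eq4(cat, an, "S. vacuolatus (A)", published) - predict_eq4(
            cat, an, "V. fischeri (A)", published
        )
        assert d == pytest.approx(1.45 - 0.23)

    def test_unknown_system_rejected(self, published, zero_ions):
        with pytest.raises(KeyError, match="onboard"):
            predict_eq4(*zero_ions, "no such assay", published)


class TestModelInvariants:
    def test_ols_matches_normal_equations(self):
        """Brute-force normal-equations solution agrees with the fit."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, k = 40, 4
            ions = []
            for i in range(n):
                ions.append(IonDescriptors(f"C{i}", "cation", *rng.uniform(0, 2, 6)))
                ions.append(IonDescriptors(f"A{i}", "anion", *rng.uniform(0, 2, 6)))
            table = DescriptorTable(ions)
            records = [
                ToxicityRecord(f"C{i}", f"A{i}", "sys1", "EC50",
                               float(rng.standard_normal()))
                for i in range(n)
            ]
            design = build_design(records, table, "sys1")
            terms = ["E_c", "V_c", "J_plus", "V_a"][: k]
            result = fit_mlr(design, terms=terms)
            idx = [design.descriptor_names.index(t) for t in terms]
            A = np.column_stack([np.ones(n), design.X[:, idx]])
            beta = np.linalg.solve(A.T @ A, A.T @ design.y)
            assert result.intercept == pytest.approx(beta[0], abs=1e-8)
            for j, t in enumerate(terms):
                assert result.coefficients[t] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_z_equals_mean_residual_in_sample(self, make_panel, published):
        """Dummy coding makes z the exact in-sample mean offset per system."""
        ions, true, records = make_panel(seed=40, n_systems=6, n_per_system=80)
        fit = fit_pooled_model(records, ions, true.reference_system)
        by_system = {}
        for r in records:
            cat = ions.get(r.cation_id, "cation")
            an = ions.get(r.anion_id, "anion")
            by_system.setdefault(r.system_id, []).append(
                r.response - intrinsic_value(cat, an, fit)
            )
        for system, offsets in by_system.items():
            assert np.mean(offsets) == pytest.approx(fit.z[system], abs=1e-8)

    def test_json_roundtrip(self, make_panel, tmp_path):
        ions, true, records = make_panel(seed=41, n_systems=4, n_per_system=60)
        fit = fit_pooled_model(records, ions, true.reference_system)
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = PooledModelFit.from_json(path)
        assert back == fit
        # and the payload is plain JSON
        json.loads(path.read_text())
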