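"""Signature construction, scoring, serialization, and the cutoff scan."""

import numpy as np
import pandas as pd
import pytest

from dntp.signature import (PUBLISHED_SIGNATURE, SignatureError,
                            SignatureModel, assign_group, build_signature,
                            compute_score, scan_cutoff, score_samples)
from dntp.simulate import SyntheticConfig, generate_split_cohort

# the ten interaction z-scores as published, keyed by gene
PUBLISHED_Z = {"GNAS": 3.74, "COX15": -3.65, "NMRK1": -3.693,
               "CLYBL": -4.332, "PNCK": -3.629, "MMS19": -3.75,
               "COL4A5": -3.514, "ZNF774": -3.569, "HBA1": -3.654,
               "DBNDD2": -3.496}


class TestPackagedSignature:
    def test_weights_equal_published_z_scores(self):
        assert PUBLISHED_SIGNATURE.weights == PUBLISHED_Z

    def test_cutoff(self):
        assert PUBLISHED_SIGNATURE.cutoff == -95.798

    def test_single_positive_weight_is_gnas(self):
        pos = [g for g, w in PUBLISHED_SIGNATURE.weights.items() if w > 0]
        assert pos == ["GNAS"]


class TestScore:
    def test_zero_vector_scores_zero(self):
        vec = {g: 0.0 for g in PUBLISHED_Z}
        assert compute_score(vec, PUBLISHED_SIGNATURE) == 0.0

    def test_unit_gnas_returns_leading_coefficient(self):
        vec = {g: (1.0 if g == "GNAS" else 0.0) for g in PUBLISHED_Z}
        assert compute_score(vec, PUBLISHED_SIGNATURE) == pytest.approx(3.74)

    def test_all_ones_sums_weights(self):
        vec = {g: 1.0 for g in PUBLISHED_Z}
        assert compute_score(vec, PUBLISHED_SIGNATURE) == pytest.approx(-29.547)

    def test_missing_gene_raises(self):
        vec = {g: 1.0 for g in list(PUBLISHED_Z)[:-1]}
        with pytest.raises(SignatureError, match="DBNDD2"):
            compute_score(vec, PUBLISHED_SIGNATURE)

    def test_invariant_to_extra_genes_and_order(self):
        rng = np.random.default_rng(0)
        vec = {g: float(v) for g, v in zip(PUBLISHED_Z, rng.random(10))}
        s1 = compute_score(vec, PUBLISHED_SIGNATURE)
        shuffled = dict(reversed(list(vec.items())))
        shuffled["OTHER"] = 99.0
        assert compute_score(shuffled, PUBLISHED_SIGNATURE) == pytest.approx(s1)

    def test_score_samples_matrix_matches_per_vector(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.random((10, 4)), index=list(PUBLISHED_Z),
                            columns=list("abcd"))
        scores = score_samples(expr, PUBLISHED_SIGNATURE)
        for s in expr.columns:
            assert scores[s] == pytest.approx(
                compute_score(expr[s], PUBLISHED_SIGNATURE))

    def test_doubling_weights_doubles_scores(self):
        rng = np.random.default_rng(2)
        vec = {g: float(v) for g, v in zip(PUBLISHED_Z, rng.random(10))}
        doubled = SignatureModel({g: 2 * w for g, w in PUBLISHED_Z.items()})
        assert compute_score(vec, doubled) == pytest.approx(
            2 * compute_score(vec, PUBLISHED_SIGNATURE))


class TestBuild:
    def test_from_screen_rows(self):
        table = pd.DataFrame({"gene": ["A", "B", "C"],
                              "z": [2.5, -3.0, 1.0],
                              "p": [0.01, 0.001, 0.2],
                              "converged": [True, True, True]})
        sig = build_signature(type("R", (), {"table": table})(), alpha=0.05)
        assert sig.weights == {"A": 2.5, "B": -3.0}
        assert sig.cutoff is None

    def test_empty_selection_raises(self):
        table = pd.DataFrame({"gene": ["A"], "z": [0.5], "p": [0.9],
                              "converged": [True]})
        with pytest.raises(SignatureError):
            build_signature(type("R", (), {"table": table})())

    def test_nonconverged_excluded(self):
        table = pd.DataFrame({"gene": ["A", "B"], "z": [9.0, 2.6],
                              "p": [1e-9, 0.01], "converged": [False, True]})
        sig = build_signature(type("R", (), {"table": table})())
        assert sig.weights == {"B": 2.6}


class TestSerialization:
    def test_json_roundtrip_exact(self, tmp_path):
        path = tmp_path / "sig.json"
        PUBLISHED_SIGNATURE.to_json(path)
        back = SignatureModel.from_json(path)
        assert back.weights == PUBLISHED_SIGNATURE.weights
        assert back.cutoff == PUBLISHED_SIGNATURE.cutoff


class TestAssignGroup:
    def test_cutoff_boundary_is_high(self):
        assert assign_group(-95.798, -95.798) == "high"

    def test_below_cutoff_is_low(self):
        assert assign_group(-95.799, -95.798) == "low"

    def test_zero_is_high(self):
        assert assign_group(0.0, -95.798) == "high"


@pytest.fixture(scope="module")
def crossover_cohort():
    sig = SignatureModel({"G0001": 2.0, "G0002": -1.5})
    cfg = SyntheticConfig(n_patients=400, n_genes=4, seed=314)
    true_cutoff = 2.0 * 3.0 - 1.5 * 3.0  # both genes centred at 3
    cohort = generate_split_cohort(cfg, sig, true_cutoff, benefit_hr=3.0)
    return sig, cohort, true_cutoff


class TestScanCutoff:
    def test_recovers_designed_crossover(self, crossover_cohort):
        sig, cohort, true_cutoff = crossover_cohort
        scores = score_samples(cohort.expression, sig)
        scan = scan_cutoff(scores, cohort.clinical)
        agree = np.mean((scores >= scan.cutoff) == (scores >= true_cutoff))
        assert agree >= 0.9

    def test_translation_equivariance(self, crossover_cohort):
        sig, cohort, _ = crossover_cohort
        scores = score_samples(cohort.expression, sig)
        scan1 = scan_cutoff(scores, cohort.clinical)
        scan2 = scan_cutoff(scores + 17.5, cohort.clinical)
        assert scan2.cutoff == pytest.approx(scan1.cutoff + 17.5, abs=1e-9)

    def test_constant_scores_rejected(self, default_cohort):
        co = default_cohort
        scores = pd.Series(1.0, index=co.clinical["sample_id"])
        with pytest.raises(SignatureError, match="constant"):
            scan_cutoff(scores, co.clinical)

    def test_group_fraction_respected(self, crossover_cohort):
        sig, cohort, _ = crossover_cohort
        scores = score_samples(cohort.expression, sig)
        scan = scan_cutoff(scores, cohort.clinical, min_group_fraction=0.3)
        n = len(scores)
        assert scan.diagnostics["n_high"].min() >= 0.3 * n
        assert scan.diagnostics["n_low"].min() >= 0.3 * n

    def test_diagnostics_expose_within_group_logrank(self, crossover_cohort):
        sig, cohort, _ = crossover_cohort
        scores = score_samples(cohort.expression, sig)
        diag = scan_cutoff(scores, cohort.clinical).diagnostics
        assert {"logrank_p_high", "logrank_p_low",
                "interaction_p"}.issubset(diag.columns)

    def test_null_cohort_rarely_significant(self):
        """Without a true crossover the best candidate interaction p is
        usually unremarkable after min-group filtering."""
        sig = SignatureModel({"G0001": 1.0})
        hits = 0
        n_reps = 20
        for s in range(n_reps):
            cfg = SyntheticConfig(n_patients=100, n_genes=2, seed=7000 + s)
            cohort = generate_split_cohort(cfg, sig, true_cutoff=3.0,
                                           benefit_hr=1.0)  # no effect
            scores = score_samples(cohort.expression, sig)
            scan = scan_cutoff(scores, cohort.clinical)
            best = scan.diagnostics["interaction_p"].min()
            if best < 0.05:
                hits += 1
        # selection-optimised p is inflated, but clear nulls dominate
        assert hits <= n_reps // 2
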