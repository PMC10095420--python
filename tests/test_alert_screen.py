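"""Alert matching and the two-cohort proportion-difference screen."""

import numpy as np
import pytest

from qtalert import (
    AlertDefinition,
    CohortSpec,
    apply_retention_filter,
    cohort_from_smiles,
    generate_cohorts,
    match_alert,
    mol_from_smiles,
    screen_alerts,
    tabulate_by_category,
)
from qtalert.alerts import AlertConfigError, AlertScreenRow, load_reference_counts, screen_from_counts


class TestMatchAlert:
    @pytest.mark.parametrize(
        "smiles,alert_name,expected",
        [
            ("CCN(CC)CC", "tertiary aliphatic amines", True),
            ("C", "tertiary aliphatic amines", False),
            ("C", "aryl halide", False),
            ("C", "halogens", False),
            ("Clc1ccccc1", "aryl halide", True),
            ("Clc1ccccc1", "tertiary aliphatic amines", False),
            ("COc1ccccc1", "alkylarylethers", True),
            ("CCOCC", "alkylarylethers", False),
            ("CCOCC", "ethers", True),
            ("CCl", "halogens", True),
            ("CCl", "aryl halide", False),
            ("c1ccccc1", "arenes", True),
            ("CN(C)C(C)=O", "tertiary aliphatic amines", False),  # amide N excluded
        ],
    )
    def test_definitional_matches(self, alerts_by_name, smiles, alert_name, expected):
        mol = mol_from_smiles(smiles)
        assert match_alert(mol, alerts_by_name[alert_name]) is expected

    def test_invalid_smarts_is_config_error(self):
        with pytest.raises(AlertConfigError, match="broken"):
            AlertDefinition(99, "broken", "others", "[[[")

    def test_match_is_presence_not_occurrence(self, alerts_by_name, dictionary):
        # five tertiary amines still count as one matching molecule
        penta = mol_from_smiles("CN(C)CCN(C)CCN(C)CCN(C)CCN(C)C")
        single = mol_from_smiles("CCN(CC)CC")
        alert = alerts_by_name["tertiary aliphatic amines"]
        pos = cohort_from_smiles(
            [("m1", "CN(C)CCN(C)CCN(C)CCN(C)CCN(C)C"), ("m2", "CCN(CC)CC")],
            label="positive",
        )
        neg = cohort_from_smiles([("n1", "CC")], label="negative")
        report = screen_alerts(pos, neg, [alert])
        assert report.rows[0].n_pos == 2


class TestScreen:
    def test_printed_count_arithmetic(self, alerts_by_name):
        row = AlertScreenRow(
            alert_id=1, name="tertiary amines", class_group="amines",
            n_pos=88, total_pos=144, n_neg=12, total_neg=95,
        )
        assert round(row.p_pos, 4) == 0.6111
        assert round(row.p_neg, 4) == 0.1263
        assert round(row.difference, 4) == 0.4848

    def test_identical_cohorts_all_zero(self, synthetic_dictionary, small_pos_cohort):
        report = screen_alerts(small_pos_cohort, small_pos_cohort, synthetic_dictionary)
        assert all(r.difference == 0 for r in report.rows)
        assert report.retained == []

    def test_empty_cohort_rejected(self, synthetic_dictionary, small_pos_cohort):
        from qtalert import CompoundCohort

        with pytest.raises(ValueError):
            screen_alerts(small_pos_cohort, CompoundCohort([], "negative"), synthetic_dictionary)

    def test_order_invariance(self, synthetic_dictionary, small_pos_cohort, small_neg_cohort):
        from qtalert import CompoundCohort

        fwd = screen_alerts(small_pos_cohort, small_neg_cohort, synthetic_dictionary)
        rev = screen_alerts(
            CompoundCohort(list(reversed(small_pos_cohort.records)), "positive"),
            CompoundCohort(list(reversed(small_neg_cohort.records)), "negative"),
            synthetic_dictionary,
        )
        for a, b in zip(fwd.rows, rev.rows):
            assert (a.n_pos, a.n_neg) == (b.n_pos, b.n_neg)

    def test_hand_enumerated_truth_table(self, alerts_by_name):
        """Per-molecule match results equal a hand-built truth table."""
        mols = {
            "NEt3": "CCN(CC)CC",
            "PhCl": "Clc1ccccc1",
            "anisole": "COc1ccccc1",
            "butane": "CCCC",
            "CCl4": "ClC(Cl)(Cl)Cl",
        }
        alerts = ["tertiary aliphatic amines", "aryl halide", "alkylarylethers", "halogens"]
        # rows: molecule, columns: alert, hand-enumerated
        truth = {
            "NEt3": (True, False, False, False),
            "PhCl": (False, True, False, True),
            "anisole": (False, False, True, False),
            "butane": (False, False, False, False),
            "CCl4": (False, False, False, True),
        }
        for mname, smi in mols.items():
            mol = mol_from_smiles(smi)
            got = tuple(match_alert(mol, alerts_by_name[a]) for a in alerts)
            assert got == truth[mname], mname


class TestRetention:
    def test_strict_threshold_semantics(self):
        rows = [
            AlertScreenRow(i, f"a{i}", "others", n, 100, 0, 100)
            for i, n in [(1, 19), (2, 20), (3, 21)]
        ]
        kept = apply_retention_filter(rows, 0.20)
        assert [r.alert_id for r in kept] == [3]

    def test_all_24_reference_rows_retained(self):
        counts = load_reference_counts()
        report = screen_from_counts(counts, total_pos=144, total_neg=95, threshold=0.20)
        assert len(report.rows) == 24
        assert len(report.retained) == 24
        # sorted descending by difference
        diffs = [r.difference for r in report.retained]
        assert diffs == sorted(diffs, reverse=True)

    def test_empty_input(self):
        assert apply_retention_filter([], 0.2) == []


class TestAtcTabulation:
    def test_counts_once_per_level1_letter(self, alerts_by_name):
        cohort = cohort_from_smiles(
            [("d1", "CCN(CC)CC"), ("d2", "CN(C)CC")],
            label="positive",
            atc=[["N05"], ["J01"]],
        )
        out = tabulate_by_category(cohort, alerts_by_name["tertiary aliphatic amines"])
        assert out == {"J": 1, "N": 1}

    def test_multi_atc_drug_counts_in_each_class(self, alerts_by_name):
        cohort = cohort_from_smiles(
            [("d1", "CCN(CC)CC")], label="positive", atc=[["M05", "A11"]]
        )
        out = tabulate_by_category(cohort, alerts_by_name["tertiary aliphatic amines"])
        assert out == {"A": 1, "M": 1}

    def test_no_matches_empty(self, alerts_by_name):
        cohort = cohort_from_smiles([("d1", "CCCC")], label="positive", atc=[["N05"]])
        assert tabulate_by_category(cohort, alerts_by_name["tertiary aliphatic amines"]) == {}


class TestPlantedPrevalence:
    def test_planted_difference_recovered_within_binomial_error(self, synthetic_dictionary):
        """Screen differences on generated cohorts track the planted
        Bernoulli prevalences within 3 binomial standard errors."""
        n = 400
        failures = 0
        n_seeds = 6
        for seed in range(n_seeds):
            spec = CohortSpec(n_pos=n, n_neg=n, seed=seed)
            synth = generate_cohorts(spec, synthetic_dictionary)
            report = screen_alerts(synth.pos, synth.neg, synthetic_dictionary)
            for row in report.rows:
                name = row.name
                p_pos, p_neg = spec.prevalences[name]
                se = np.sqrt(p_pos * (1 - p_pos) / n + p_neg * (1 - p_neg) / n)
                if abs(row.difference - (p_pos - p_neg)) > 3 * se:
                    failures += 1
        assert failures == 0

    def test_screen_counts_equal_generator_truth(self, synthetic_dictionary):
        spec = CohortSpec(n_pos=60, n_neg=40, seed=5)
        synth = generate_cohorts(spec, synthetic_dictionary)
        report = screen_alerts(synth.pos, synth.neg, synthetic_dictionary)
        for row in report.rows:
            assert row.n_pos == synth.realized.loc[row.name, "n_pos"]
            assert row.n_neg == synth.realized.loc[row.name, "n_neg"]
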