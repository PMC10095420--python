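"""Contingency aggregation, ROR computation, ranking and matching."""

import numpy as np
import pandas as pd
import pytest

from qtalert import (
    ContingencyTable,
    DrugRorSpec,
    ReportTableSpec,
    RorResult,
    build_contingency,
    build_matched_test_set,
    cohort_from_smiles,
    compute_ror,
    generate_report_table,
    rank_by_ror,
    report_table_from_cells,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["case_id", "drug_id", "event_id"])


class TestBuildContingency:
    def test_four_case_quadrants(self):
        rec = _records(
            [
                ("c1", "D", "E"),
                ("c2", "D", "other"),
                ("c3", "x", "E"),
                ("c4", "x", "other"),
            ]
        )
        assert build_contingency(rec, "D", "E").as_tuple() == (1, 1, 1, 1)

    def test_case_level_dedup(self):
        rec = _records(
            [
                ("c1", "D", "E"),
                ("c1", "D", "E"),  # repeat mention, same case
                ("c1", "D", "other"),
                ("c2", "x", "other"),
            ]
        )
        t = build_contingency(rec, "D", "E")
        assert t.a == 1 and t.total == 2

    def test_absent_drug_gives_zero_row_not_error(self):
        rec = _records([("c1", "x", "E")])
        t = build_contingency(rec, "missing", "E")
        assert (t.a, t.b) == (0, 0)

    def test_generator_cells_recovered_exactly(self):
        rec = report_table_from_cells("drugA", 20, 10, 5, 40)
        assert build_contingency(rec, "drugA", "QT_prolongation").as_tuple() == (20, 10, 5, 40)


class TestComputeRor:
    def test_symmetric_table_is_one(self):
        assert compute_ror(ContingencyTable(10, 10, 10, 10)).ror == 1.0

    def test_forced_arithmetic(self):
        assert compute_ror(ContingencyTable(20, 10, 5, 40)).ror == 16.0

    def test_haldane_anscombe_correction(self):
        res = compute_ror(ContingencyTable(5, 0, 3, 10), correction=True)
        assert res.corrected
        assert res.ror == pytest.approx((5.5 * 10.5) / (0.5 * 3.5))  # 33.0

    def test_zero_cell_without_correction_errors(self):
        with pytest.raises(ZeroDivisionError):
            compute_ror(ContingencyTable(5, 0, 3, 10), correction=False)

    def test_row_scaling_invariance(self):
        base = compute_ror(ContingencyTable(12, 7, 9, 31)).ror
        for k in (2, 5):
            for m in (3, 7):
                scaled = compute_ror(ContingencyTable(12 * k, 7 * k, 9 * m, 31 * m)).ror
                assert scaled == pytest.approx(base)

    def test_against_statsmodels_oracle(self):
        """Point estimate and 95% CI match the independent 2x2 table
        implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, size=4)
            t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            res = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert res.ror == pytest.approx(t22.oddsratio)
            low, high = t22.oddsratio_confint(0.05)
            assert res.ci95 == pytest.approx((low, high), rel=1e-9)


class TestRanking:
    def _res(self, drug, ror):
        return RorResult(drug, ror, 0.1, (ror * 0.5, ror * 2), False, ContingencyTable(1, 1, 1, 1))

    def test_reference_order(self):
        ranked = rank_by_ror(
            [self._res("Cisapride", 272.797), self._res("Doxapram", 398.298),
             self._res("Ibutilide", 223.102)]
        )
        assert ranked.ids() == ["Doxapram", "Cisapride", "Ibutilide"]

    def test_tie_break_lexicographic(self):
        ranked = rank_by_ror([self._res("b", 5.0), self._res("a", 5.0)])
        assert ranked.ids() == ["a", "b"]

    def test_top_n_truncates(self):
        ranked = rank_by_ror([self._res(f"d{i}", i) for i in range(30)])
        assert len(ranked.top_n(50)) == 30

    def test_prefix_nesting(self):
        ranked = rank_by_ror([self._res(f"d{i:03d}", 500.0 - i) for i in range(120)])
        small = {r.drug_id for r in ranked.top_n(50)}
        large = {r.drug_id for r in ranked.top_n(100)}
        assert small <= large


class TestGeneratorRor:
    def test_multi_drug_planted_cells_recovered(self):
        spec = ReportTableSpec(
            drugs=[DrugRorSpec("hi", 100.0, 100), DrugRorSpec("mid", 10.0, 100),
                   DrugRorSpec("lo", 1.0, 100)],
            total_cases=5000, background_rate=0.05, seed=0,
        )
        records, truth = generate_report_table(spec)
        assert records["case_id"].nunique() == 5000
        for drug, table in truth.tables.items():
            got = build_contingency(records, drug, spec.event_id)
            assert got.as_tuple() == table.as_tuple()

    def test_rank_order_preserved(self):
        spec = ReportTableSpec(
            drugs=[DrugRorSpec("hi", 100.0, 150), DrugRorSpec("mid", 10.0, 150),
                   DrugRorSpec("lo", 1.0, 150)],
            total_cases=6000, seed=1,
        )
        records, _ = generate_report_table(spec)
        from qtalert import ror_from_records

        ranked = ror_from_records(records, spec.event_id)
        assert ranked.ids() == ["hi", "mid", "lo"]

    def test_ci_coverage_near_nominal(self):
        """Sampling-mode tables: the Wald 95% CI covers the planted ROR
        at roughly the nominal rate."""
        covered = total = 0
        for ror in (0.5, 2.0, 10.0, 100.0):
            for seed in range(125):
                spec = ReportTableSpec(
                    drugs=[DrugRorSpec("D", ror, 400)],
                    total_cases=2500, background_rate=0.05,
                    seed=seed, sample=True,
                )
                _, truth = generate_report_table(spec)
                res = compute_ror(truth.tables["D"])
                covered += res.ci95[0] <= ror <= res.ci95[1]
                total += 1
        assert covered / total == pytest.approx(0.95, abs=0.03)


class TestMatchedTestSet:
    def _ranked(self, n):
        return rank_by_ror(
            [
                RorResult(f"p{i:02d}", float(n - i), 0.1, (0.1, 1e6), False,
                          ContingencyTable(1, 1, 1, 1))
                for i in range(n)
            ]
        )

    def test_mirrored_pool_gives_zero_distance(self):
        ranked = self._ranked(4)
        atc = {"p00": ["N05"], "p01": ["N06"], "p02": ["J01"], "p03": ["C01"]}
        pool = cohort_from_smiles(
            [(f"n{i}", "CCO") for i in range(4)],
            label="negative",
            atc=[["N01"], ["N02"], ["J05"], ["C09"]],
        )
        pos_ids, neg_ids, l1 = build_matched_test_set(ranked, atc, pool, k=4, seed=0)
        assert len(pos_ids) == len(neg_ids) == 4
        assert l1 == 0

    def test_missing_letter_reallocated(self):
        ranked = self._ranked(3)
        atc = {"p00": ["J01"], "p01": ["J02"], "p02": ["N05"]}
        pool = cohort_from_smiles(
            [("n0", "CCO"), ("n1", "CCN"), ("n2", "CCC")],
            label="negative",
            atc=[["N01"], ["N02"], ["N03"]],  # no J available
        )
        pos_ids, neg_ids, l1 = build_matched_test_set(ranked, atc, pool, k=3, seed=0)
        assert len(neg_ids) == 3
        assert l1 == 4  # two J deficits moved to N surplus

    def test_k_exceeding_pool_errors(self):
        ranked = self._ranked(2)
        pool = cohort_from_smiles([("n0", "CCO")], label="negative")
        with pytest.raises(ValueError):
            build_matched_test_set(ranked, {}, pool, k=2, seed=0)
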