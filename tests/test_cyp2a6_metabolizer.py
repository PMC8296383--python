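import itertools

import numpy as np
import pytest

from pgx_smoke.cyp2a6_metabolizer import (
    DEFAULT_MINOR_COUNT_SNPS,
    EXCLUDED_MINOR_COUNT_SNP,
    call_star_alleles,
    classify_by_function,
    classify_by_minor_count,
    classify_matrix_by_function,
    phenotype_vs_smoking,
)
from pgx_smoke.panel_io import PanelError, StarAlleleDef

from conftest import make_subject, matrix_from_doses


@pytest.fixture(scope="module")
def five_snps(panel=None):
    from pgx_smoke.panel_io import load_default_panel

    panel = load_default_panel()
    by_rsid = {s.rsid: s for s in panel}
    return [by_rsid[r] for r in DEFAULT_MINOR_COUNT_SNPS]


def classify_doses(five_snps, dose_rows):
    m = matrix_from_doses(five_snps, dose_rows)
    return classify_by_minor_count(m)


class TestMinorCountRule:
    def test_default_set_excludes_nonspecific_marker(self):
        assert EXCLUDED_MINOR_COUNT_SNP not in DEFAULT_MINOR_COUNT_SNPS
        assert len(DEFAULT_MINOR_COUNT_SNPS) == 5

    @pytest.mark.parametrize("doses,expected", [
        ([0, 0, 0, 0, 0], "normal"),
        ([1, 0, 0, 0, 0], "intermediate"),
        ([2, 0, 0, 0, 0], "slow"),        # homozygous minor at one SNP
        ([1, 1, 0, 0, 0], "slow"),        # two hets across SNPs
        ([2, 2, 1, 0, 0], "slow"),
    ])
    def test_dose_rule(self, five_snps, doses, expected):
        calls = classify_doses(five_snps, [doses])
        assert calls[0].phenotype == expected

    def test_missing_that_could_change_class_unclassifies(self, five_snps):
        calls = classify_doses(five_snps, [[0, None, 0, 0, 0]])
        assert calls[0].phenotype == "unclassified"

    def test_missing_that_cannot_change_class_is_ignored(self, five_snps):
        # already slow on observed dose; missing SNP cannot demote the class
        calls = classify_doses(five_snps, [[2, None, 0, 0, 0]])
        assert calls[0].phenotype == "slow"

    def test_monotone_in_added_minor_alleles(self, five_snps):
        # adding a minor allele never moves the class toward normal
        order = {"normal": 0, "intermediate": 1, "slow": 2}
        for doses in itertools.product((0, 1, 2), repeat=3):
            base = list(doses) + [0, 0]
            before = classify_doses(five_snps, [base])[0].phenotype
            for j in range(5):
                if base[j] < 2:
                    bumped = list(base)
                    bumped[j] += 1
                    after = classify_doses(five_snps, [bumped])[0].phenotype
                    assert order[after] >= order[before]

    def test_non_panel_rsid_rejected(self, five_snps):
        m = matrix_from_doses(five_snps, [[0, 0, 0, 0, 0]])
        with pytest.raises(PanelError):
            classify_by_minor_count(m, snp_set=["rs424242"])


class TestStarAlleleCalling:
    def test_het_at_single_defining_snp(self, panel, allele_defs):
        nine = next(d for d in allele_defs if d.name == "*9")
        rsid, req = next(iter(nine.defining_snps.items()))
        snp = next(s for s in panel if s.rsid == rsid)
        m = matrix_from_doses([snp], [[1]])
        res = call_star_alleles(m, allele_defs)
        assert res["S000"]["pair"] == ("*1", "*9")

    def test_no_minor_alleles_is_reference_homozygote(self, panel, allele_defs):
        cyp = [s for s in panel if s.gene == "CYP2A6"]
        m = matrix_from_doses(cyp, [[0] * len(cyp)])
        res = call_star_alleles(m, allele_defs)
        assert res["S000"]["pair"] == ("*1", "*1")

    def test_dose_conservation_over_small_genotypes(self, panel, allele_defs):
        # copies consumed equal observed minor dose for every <=2-SNP genotype
        cyp = [s for s in panel if s.gene == "CYP2A6"]
        snp_a = next(s for s in cyp if s.rsid == "rs28399433")
        snp_b = next(s for s in cyp if s.rsid == "rs1801272")
        for da, db in itertools.product((0, 1, 2), repeat=2):
            m = matrix_from_doses([snp_a, snp_b], [[da, db]])
            res = call_star_alleles(m, allele_defs)["S000"]
            total = da + db
            if total > 2:
                assert res["status"] == "unclassified"
            else:
                consumed = sum(1 for a in res["pair"] if a != "*1")
                assert consumed == total

    def test_homozygous_minor_gives_allele_homozygote(self, panel, allele_defs):
        snp = next(s for s in panel if s.rsid == "rs1801272")
        m = matrix_from_doses([snp], [[2]])
        assert call_star_alleles(m, allele_defs)["S000"]["pair"] == ("*2", "*2")

    def test_trans_assignment_of_two_hets(self, panel, allele_defs):
        by_rsid = {s.rsid: s for s in panel}
        snps = [by_rsid["rs28399433"], by_rsid["rs1801272"]]
        m = matrix_from_doses(snps, [[1, 1]])
        assert call_star_alleles(m, allele_defs)["S000"]["pair"] == ("*2", "*9")
        strict = call_star_alleles(m, allele_defs, trans_on_ambiguity=False)
        assert strict["S000"]["status"] == "unclassified"

    def test_conflicting_definitions_rejected(self, panel):
        snp = next(s for s in panel if s.rsid == "rs28399433")
        defs = [
            StarAlleleDef("*1", {}, "normal"),
            StarAlleleDef("*9", {"rs28399433": "C"}, "decreased"),
            StarAlleleDef("*14", {"rs28399433": "C"}, "decreased"),
        ]
        m = matrix_from_doses([snp], [[0]])
        with pytest.raises(ValueError, match="claimed"):
            call_star_alleles(m, defs)


class TestFunctionRule:
    PAIRS = [
        (("*1", "*1"), "normal"),            # normal x normal
        (("*1", "*9"), "intermediate"),      # normal x decreased
        (("*1", "*2"), "slow"),              # normal x loss
        (("*9", "*2"), "slow"),              # decreased x loss
        (("*9", "*9"), "slow"),              # decreased x decreased
        (("*2", "*2"), "slow"),              # loss x loss
    ]

    @pytest.mark.parametrize("pair,expected", PAIRS)
    def test_published_combination_table(self, allele_defs, pair, expected):
        assert classify_by_function(pair, allele_defs).phenotype == expected

    @pytest.mark.parametrize("pair,expected", PAIRS)
    def test_order_invariance(self, allele_defs, pair, expected):
        assert (classify_by_function(pair, allele_defs).phenotype
                == classify_by_function(pair[::-1], allele_defs).phenotype)

    def test_unknown_function_unclassifies(self, allele_defs):
        res = classify_by_function(("*1", "*18"), allele_defs)
        assert res.phenotype == "unclassified"

    def test_matrix_phenotype_counts_conserve_n(self, matrix, allele_defs):
        calls = classify_matrix_by_function(matrix, allele_defs)
        counts = {}
        for c in calls:
            counts[c.phenotype] = counts.get(c.phenotype, 0) + 1
        classified = sum(v for k, v in counts.items() if k != "unclassified")
        assert classified + counts.get("unclassified", 0) == len(matrix.subjects)


class TestPhenotypeVsSmoking:
    @staticmethod
    def _cohort(rng, effect=2.0, n=40):
        """Subjects with a cigarettes/day shift for slow metabolizers."""
        from pgx_smoke.cyp2a6_metabolizer import MetabolizerCall
        from pgx_smoke.panel_io import SubjectRecord

        subjects, calls = [], []
        for i, phen in enumerate(
                ["normal"] * n + ["intermediate"] * n + ["slow"] * n):
            shift = effect if phen == "slow" else 0.0
            cpd = max(1.0, rng.normal(10 + shift, 3.0))
            subjects.append(SubjectRecord(
                subject_id=f"P{i:03d}", cohort="e-Dec", age=35, gender="male",
                cigarettes_per_day=cpd, years_smoking=10, onset_age=18,
                tobacco_index=cpd * 10 / 20))
            calls.append(MetabolizerCall(f"P{i:03d}", "minor_allele_count", phen))
        return calls, subjects

    def test_detects_cigarette_shift_in_slow_group(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(200):
            calls, subjects = self._cohort(rng, effect=2.0, n=40)
            res = phenotype_vs_smoking(calls, subjects)
            if res["p_value"] < 0.05:
                rejections += 1
        assert rejections / 200 > 0.5

    def test_type_i_rate_near_nominal_under_null(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            calls, subjects = self._cohort(rng, effect=0.0, n=30)
            ps.append(phenotype_vs_smoking(calls, subjects)["p_value"])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= rate <= 0.10  # 3-SE band around 5% over 200 sims

    def test_single_group_errors(self):
        rng = np.random.default_rng(13)
        calls, subjects = self._cohort(rng, n=5)
        only_normal = [c for c in calls if c.phenotype == "normal"]
        with pytest.raises(ValueError):
            phenotype_vs_smoking(only_normal, subjects)

    def test_group_medians_reported(self):
        rng = np.random.default_rng(14)
        calls, subjects = self._cohort(rng, effect=3.0, n=50)
        res = phenotype_vs_smoking(calls, subjects)
        assert set(res["groups"]) == {"normal", "intermediate", "slow"}
        assert res["groups"]["slow"]["median"] > res["groups"]["normal"]["median"]
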