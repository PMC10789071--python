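"""Fisher enrichment framework: exact primitives and counting rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from diffabc import enrichment as en


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by explicit summation over the hypergeometric support."""
    M, n, N = a + b + c + d, a + b, a + c
    lo, hi = max(0, n + N - M), min(n, N)
    total = comb(M, N, exact=True)
    return sum(
        comb(n, x, exact=True) * comb(M - n, N - x, exact=True)
        for x in range(a, hi + 1)
    ) / total


class TestFisherOneSided:
    def test_perfect_association(self):
        r = en.fisher_one_sided(10, 0, 0, 10)
        assert r.odds_ratio == np.inf
        assert r.p == pytest.approx(1 / comb(20, 10, exact=True))

    def test_balanced_table(self):
        r = en.fisher_one_sided(5, 5, 5, 5)
        assert r.odds_ratio == 1.0
        assert r.p == pytest.approx(hypergeom_tail_oracle(5, 5, 5, 5))
        assert r.p == pytest.approx(0.6719, abs=2e-4)

    def test_depleted_table(self):
        assert en.fisher_one_sided(0, 10, 10, 0).p == pytest.approx(1.0)

    def test_matches_enumeration_for_small_tables(self):
        """OR and one-sided P agree with brute-force enumeration, totals <= 40."""
        rng = np.random.default_rng(5)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or min(a + b, c + d, a + c, b + d) == 0:
                continue
            r = en.fisher_one_sided(a, b, c, d)
            assert r.p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), rel=1e-10)
            if b * c > 0:
                assert r.odds_ratio == pytest.approx(a * d / (b * c))

    def test_ci_lower_satisfies_defining_equation(self):
        """The exact bound L solves P_L(X >= a) = 0.05 in Fisher's model."""
        for table in [(8, 2, 3, 9), (15, 5, 6, 14), (4, 1, 2, 13)]:
            a, b, c, d = table
            r = en.fisher_one_sided(a, b, c, d)
            M, n, N = a + b + c + d, a + b, a + c
            tail = stats.nchypergeom_fisher.sf(a - 1, M, n, N, r.ci_lower)
            assert tail == pytest.approx(0.05, abs=1e-6)
            assert r.ci_lower < r.odds_ratio

    def test_zero_margin_flagged(self):
        r = en.fisher_one_sided(0, 0, 5, 5)
        assert r.p == 1.0 and r.note == "zero margin"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            en.fisher_one_sided(-1, 2, 3, 4)


class TestSignTest:
    def test_central_case(self):
        assert en.sign_test(5, 10, 0.5) == pytest.approx(1.0)

    def test_one_sided_extreme(self):
        assert en.sign_test(10, 10, 0.5) == pytest.approx(2 * 0.5**10)

    def test_mode_has_largest_p(self):
        p_mode = en.sign_test(7, 10, 0.7)
        assert all(en.sign_test(k, 10, 0.7) <= p_mode + 1e-12 for k in range(11))

    def test_empty_is_nan(self):
        assert np.isnan(en.sign_test(0, 0, 0.5))


def _top_frame(rows):
    """Helper: build a per-gene top diff-CRE frame from compact tuples."""
    return pd.DataFrame(rows, columns=[
        "gene_id", "cre_id", "p", "direction", "diff_flag", "nondiff_flag",
        "element_class", "is_promoter_pair"])


class TestDeOverlap:
    def test_cre_counted_once_despite_many_de_targets(self):
        top = _top_frame([
            ("g1", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g2", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g3", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g4", "c2", 0.8, "EUR", False, True, "enhancer", False),
        ])
        de = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "sign": "AFR",
                           "lfsr": 0.001})
        r = en.de_overlap_test(top, de)
        assert r.table == (1, 0, 0, 1)  # c1 once, not three times

    def test_intermediate_p_excluded(self):
        top = _top_frame([
            ("g1", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g2", "c2", 0.2, "AFR", False, False, "enhancer", False),
            ("g3", "c3", 0.7, "EUR", False, True, "enhancer", False),
        ])
        de = pd.DataFrame({"gene_id": ["g1"], "sign": ["AFR"], "lfsr": [0.01]})
        r = en.de_overlap_test(top, de)
        assert sum(r.table) == 2  # c2 (0.05 <= p < 0.5) is in neither group

    def test_enhancer_filter_excludes_promoter_for_de_target(self):
        # c1 is a promoter for its DE target -> not an enhancer-test hit
        top = _top_frame([
            ("g1", "c1", 0.01, "AFR", True, False, "promoter", True),
            ("g2", "c2", 0.01, "AFR", True, False, "promoter", False),
        ])
        de = pd.DataFrame({"gene_id": ["g1", "g2"], "sign": "AFR", "lfsr": 0.001})
        r = en.de_overlap_test(top, de, class_filter="enhancer")
        # c2 is a distal promoter (not promoter for g2) -> counts as enhancer hit
        assert r.table[0] == 1 and r.table[1] == 1


class TestDirectionMatch:
    def test_opposite_sign_targets_excluded(self):
        top = _top_frame([
            ("g1", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g2", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g3", "c2", 0.01, "EUR", True, False, "enhancer", False),
        ])
        de = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                           "sign": ["AFR", "EUR", "EUR"], "lfsr": 0.001})
        r = en.direction_match_test(top, de)
        assert sum(r.table) == 1  # c1 excluded (targets disagree), c2 kept

    def test_all_matching_gives_infinite_or(self):
        top = _top_frame([
            ("g1", "c1", 0.01, "AFR", True, False, "enhancer", False),
            ("g2", "c2", 0.01, "EUR", True, False, "enhancer", False),
        ])
        de = pd.DataFrame({"gene_id": ["g1", "g2"], "sign": ["AFR", "EUR"],
                           "lfsr": 0.001})
        r = en.direction_match_test(top, de)
        assert r.table == (1, 0, 0, 1)


def _cre_diff_frame(rows):
    return pd.DataFrame(rows, columns=[
        "cre_id", "pair_id", "p", "log2fc", "direction", "diff_flag",
        "nondiff_flag", "element_class", "bin_key"])


class TestQtlTests:
    QTL = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"],
        "cre_id": ["c1", "c1", "c1", "c2"],
        "qtl_type": ["PU1", "PU1", "PU1", "PU1"],
        "qtl_p": [1e-8, 1e-4, 0.01, 1e-3],
        "af_AFR": [0.9, 0.8, 0.7, 0.2],
        "af_EUR": [0.1, 0.2, 0.3, 0.8],
        "fst": [0.9, 0.5, 0.1, 0.4],
    })

    def test_lowest_p_qtl_represents_cre(self):
        best = en.best_qtl_per_cre(self.QTL, "PU1")
        assert best.set_index("cre_id").loc["c1", "variant_id"] == "v1"
        assert best.set_index("cre_id").loc["c1", "all_agree"]

    def test_overlap_table(self):
        cre = _cre_diff_frame([
            ("c1", "c1|g1", 0.01, 1.0, "EUR", True, False, "enhancer", "b1"),
            ("c2", "c2|g2", 0.01, -1.0, "AFR", True, False, "enhancer", "b2"),
            ("c3", "c3|g3", 0.9, 0.1, "EUR", False, True, "enhancer", "b3"),
        ])
        r = en.qtl_overlap_test(cre, self.QTL, "PU1")
        assert r.table == (2, 0, 0, 1)

    def test_direction_match_and_fst_restriction(self):
        cre = _cre_diff_frame([
            ("c1", "c1|g1", 0.01, -1.0, "AFR", True, False, "enhancer", "b1"),
            ("c2", "c2|g2", 0.01, 1.0, "EUR", True, False, "enhancer", "b2"),
        ])
        r = en.qtl_direction_match_test(cre, self.QTL, "PU1")
        # c1 AFR-CRE with AFR-direction QTL, c2 EUR-CRE with EUR-direction QTL
        assert r.table == (1, 0, 0, 1)
        # raising the F_ST floor drops c2 (its best QTL has fst 0.4)
        r2 = en.qtl_direction_match_test(cre, self.QTL, "PU1", fst_threshold=0.6)
        assert sum(r2.table) == 1

    def test_unknown_class_filter_rejected(self):
        cre = _cre_diff_frame([
            ("c1", "c1|g1", 0.01, -1.0, "AFR", True, False, "enhancer", "b1")])
        with pytest.raises(ValueError):
            en.qtl_overlap_test(cre, self.QTL, "PU1", class_filter="bogus")


class TestCalibration:
    def test_null_rejection_rate_bounded(self):
        """With random diff status and random DE genes the one-sided Fisher
        tests reject at no more than the nominal 5% (discreteness makes the
        exact test conservative)."""
        rng = np.random.default_rng(12)
        rejections_overlap, rejections_dir, n_seeds = 0, 0, 220
        for _ in range(n_seeds):
            genes = [f"g{i}" for i in range(60)]
            p = np.where(rng.uniform(size=60) < 0.5,
                         rng.uniform(0, 0.05, 60), rng.uniform(0.5, 1.0, 60))
            top = pd.DataFrame({
                "gene_id": genes, "cre_id": [f"c{i}" for i in range(60)],
                "p": p, "direction": rng.choice(["AFR", "EUR"], 60),
                "diff_flag": p < 0.05, "nondiff_flag": p >= 0.5,
                "element_class": "enhancer", "is_promoter_pair": False,
            })
            de = pd.DataFrame({
                "gene_id": genes, "sign": rng.choice(["AFR", "EUR"], 60),
                "lfsr": np.where(rng.uniform(size=60) < 0.4, 0.01, 0.5),
            })
            if en.de_overlap_test(top, de).p < 0.05:
                rejections_overlap += 1
            if en.direction_match_test(top, de).p < 0.05:
                rejections_dir += 1
        assert rejections_overlap / n_seeds <= 0.08
        assert rejections_dir / n_seeds <= 0.08


def test_bonferroni_stars():
    assert en.bonferroni_stars(0.04, 1) == "*"
    assert en.bonferroni_stars(0.01, 10) == ""
    assert en.bonferroni_stars(1e-7, 22) == "****"
    assert en.bonferroni_stars(2e-4, 10) == "**"
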