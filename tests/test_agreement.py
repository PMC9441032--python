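"""Agreement tables, Cohen's kappa, specific agreement, pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optimise_smi.agreement import (AgreementTable, DecisionMatrix,
                                    UndefinedKappaError,
                                    build_agreement_table, cohen_kappa,
                                    interpret_kappa, pooled_kappa,
                                    proportion_agreement, read_decisions_csv)

cells = st.tuples(st.integers(0, 200), st.integers(0, 200),
                  st.integers(0, 200), st.integers(0, 200))


def grid(bools, rater_id="r"):
    frame = pd.DataFrame(np.asarray(bools, dtype=bool))
    return DecisionMatrix(rater_id=rater_id, decisions=frame)


class TestAgreementTable:
    def test_perfect_agreement_counts(self):
        g = [[1, 0, 0], [0, 1, 1], [0, 1, 0]]
        table = build_agreement_table(grid(g, "std"), grid(g, "r1"))
        assert (table.a, table.b, table.c, table.d) == (4, 0, 0, 5)

    def test_complement_rater_empties_the_diagonal(self):
        g = np.array([[1, 0], [0, 1]], dtype=bool)
        table = build_agreement_table(grid(g, "std"), grid(~g, "r1"))
        assert table.a == 0 and table.d == 0
        assert table.b == 2 and table.c == 2

    def test_counts_match_double_loop_tally_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = rng.random((20, 65)) < 0.15
            r = np.where(rng.random((20, 65)) < 0.1, ~s, s)
            table = build_agreement_table(grid(s, "std"), grid(r, "r"))
            a = b = c = d = 0
            for i in range(20):
                for j in range(65):
                    if s[i, j] and r[i, j]:
                        a += 1
                    elif not s[i, j] and r[i, j]:
                        b += 1
                    elif s[i, j] and not r[i, j]:
                        c += 1
                    else:
                        d += 1
            assert (table.a, table.b, table.c, table.d) == (a, b, c, d)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grids differ"):
            build_agreement_table(grid([[1, 0]]), grid([[1], [0]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AgreementTable(-1, 0, 0, 1)


class TestCohenKappa:
    def test_perfect_agreement_is_one(self):
        result = cohen_kappa(AgreementTable(10, 0, 0, 30))
        assert result.kappa == pytest.approx(1.0)

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, size=4)
            result = cohen_kappa(AgreementTable(int(a), int(b), int(c), int(d)))
            assert result.kappa <= result.po + 1e-12

    @given(cells)
    @settings(deadline=None)
    def test_label_swap_symmetry(self, abcd):
        a, b, c, d = abcd
        table, swapped = AgreementTable(a, b, c, d), AgreementTable(d, c, b, a)
        try:
            k1 = cohen_kappa(table).kappa
        except (ValueError, UndefinedKappaError):
            return
        assert k1 == pytest.approx(cohen_kappa(swapped).kappa)

    @given(cells, st.integers(2, 7))
    @settings(deadline=None)
    def test_scale_invariance(self, abcd, factor):
        a, b, c, d = abcd
        try:
            base = cohen_kappa(AgreementTable(a, b, c, d))
        except (ValueError, UndefinedKappaError):
            return
        scaled_table = AgreementTable(a * factor, b * factor, c * factor, d * factor)
        scaled = cohen_kappa(scaled_table)
        assert scaled.kappa == pytest.approx(base.kappa)
        props, scaled_props = (proportion_agreement(AgreementTable(a, b, c, d)),
                               proportion_agreement(scaled_table))
        if props.ppos is not None:
            assert scaled_props.ppos == pytest.approx(props.ppos)
        if props.pneg is not None:
            assert scaled_props.pneg == pytest.approx(props.pneg)

    def test_matches_statsmodels_on_random_tables(self):
        import statsmodels.stats.inter_rater as ir
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
            mine = cohen_kappa(AgreementTable(a, b, c, d))
            theirs = ir.cohens_kappa(np.array([[a, c], [b, d]]))
            assert mine.kappa == pytest.approx(theirs.kappa)
            assert mine.se == pytest.approx(theirs.std_kappa)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(AgreementTable(0, 0, 0, 0))

    def test_both_raters_constant_is_undefined(self):
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(AgreementTable(12, 0, 0, 0))

    def test_one_rater_constant_flags_se_only(self):
        result = cohen_kappa(AgreementTable(5, 0, 3, 0))
        assert result.se is None and result.ci95 is None


class TestPipelineEquivalence:
    def test_kappa_from_decisions_equals_kappa_from_table(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            s = rng.random((20, 65)) < 0.2
            r = np.where(rng.random((20, 65)) < 0.15, ~s, s)
            std, rat = grid(s, "std"), grid(r, "r")
            table = build_agreement_table(std, rat)
            # oracle route: confusion matrix from flattened decisions
            import statsmodels.stats.inter_rater as ir
            flat_s = s.ravel().astype(int)
            flat_r = r.ravel().astype(int)
            confusion = np.zeros((2, 2))
            for i, j in zip(flat_s, flat_r):
                confusion[1 - i, 1 - j] += 1
            assert cohen_kappa(table).kappa == pytest.approx(
                ir.cohens_kappa(confusion).kappa)


class TestProportions:
    @pytest.mark.parametrize("abcd,ppos,pneg", [
        ((155, 42, 91, 1012), 0.70, 0.94),
        ((229, 33, 28, 1010), 0.88, 0.97),
    ])
    def test_specific_agreement(self, abcd, ppos, pneg):
        props = proportion_agreement(AgreementTable(*abcd))
        assert round(props.ppos, 2) == ppos
        assert round(props.pneg, 2) == pneg

    def test_no_disagreement_gives_unity(self):
        props = proportion_agreement(AgreementTable(4, 0, 0, 9))
        assert props.ppos == 1.0 and props.pneg == 1.0

    def test_zero_denominator_flagged_as_undefined(self):
        props = proportion_agreement(AgreementTable(0, 0, 0, 10))
        assert props.ppos is None and props.pneg == 1.0


class TestInterpretation:
    @pytest.mark.parametrize("kappa,band", [
        (0.75, "substantial"),
        (0.20, "poor"),
        (0.21, "fair"),
        (0.40, "fair"),
        (0.41, "moderate"),
        (0.60, "moderate"),
        (0.61, "substantial"),
        (0.80, "substantial"),
        (0.81, "good"),
        (0.865, "good"),
        (1.0, "good"),
        (-0.3, "poor"),
    ])
    def test_bands(self, kappa, band):
        assert interpret_kappa(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)


class TestPooling:
    def test_single_table_identity(self):
        table = AgreementTable(155, 42, 91, 1012)
        assert pooled_kappa([table]).kappa == pytest.approx(
            cohen_kappa(table).kappa)

    def test_concatenating_identical_tables_preserves_kappa(self):
        table = AgreementTable(155, 42, 91, 1012)
        pooled = pooled_kappa([table, table], method="concatenate")
        assert pooled.kappa == pytest.approx(cohen_kappa(table).kappa)
        assert pooled.n == 2 * table.n

    def test_methods_are_labelled_and_generally_differ(self):
        tables = [AgreementTable(155, 42, 91, 1012),
                  AgreementTable(226, 35, 20, 1019)]
        concat = pooled_kappa(tables, method="concatenate")
        weighted = pooled_kappa(tables, method="weighted_mean")
        assert concat.method == "pooled_concatenate"
        assert weighted.method == "pooled_weighted_mean"
        assert concat.kappa != pytest.approx(weighted.kappa, abs=1e-6)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_kappa([])


class TestDecisionsIO:
    def test_long_format_roundtrip(self, tmp_path):
        rows = []
        for rater in ("std", "r1"):
            for ds in ("d1", "d2"):
                for item in ("i1", "i2", "i3"):
                    rows.append({"rater_id": rater, "dataset_id": ds,
                                 "indicator_id": item,
                                 "applied": int((rater + ds + item).count("1") % 2)})
        path = tmp_path / "decisions.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        matrices = read_decisions_csv(path)
        assert [m.rater_id for m in matrices] == ["r1", "std"]
        assert all(m.shape == (2, 3) for m in matrices)
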