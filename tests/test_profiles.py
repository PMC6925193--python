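"""Compound classification, densities, descriptors and set operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riverdom.chem import MolecularFormula
from riverdom.profiles import (CompoundClass, SampleEnsemble,
                               class_densities, classify, common_formulae,
                               number_averaged, stoichiometry_shares,
                               unique_formulae, vk_table)


def _f(c, h, n=0, o=0, s=0):
    return MolecularFormula(c=c, h=h, n=n, o=o, s=s)


class TestClassify:
    @pytest.mark.parametrize("formula, expected", [
        (_f(10, 20, o=2), CompoundClass.ALIPHATICS),        # O/C .2, H/C 2
        (_f(10, 12, o=7), CompoundClass.LIGNIN_OX),         # .7, 1.2
        (_f(12, 22, n=1, o=5), CompoundClass.N_SATURATED),  # .417, 1.83
        (_f(10, 12, o=3), CompoundClass.LIGNIN_LOW_OX),     # .3, 1.2
        (_f(20, 10, o=6), CompoundClass.TANNIN_CONDENSED),  # .3, .5
        (_f(20, 10, o=14), CompoundClass.TANNIN_HYDROLYSABLE),
        (_f(20, 34, o=14), CompoundClass.CARBOHYDRATES),    # .7, 1.7
        (_f(10, 2, o=10), CompoundClass.UNCLASSIFIED),      # H/C .2
    ])
    def test_region_membership(self, formula, expected):
        assert classify(formula) is expected

    def test_nitrogen_precedence_over_aliphatic(self):
        # O/C and H/C land in both the aliphatic and the N-saturated
        # region; nitrogen presence decides
        f = _f(10, 18, n=1, o=2)  # O/C .2, H/C 1.8
        assert classify(f) is CompoundClass.N_SATURATED
        assert classify(_f(10, 18, o=2)) is CompoundClass.ALIPHATICS

    @pytest.mark.parametrize("oc, hc, inside_class", [
        # boundary values: left-closed / right-open exactly as printed
        (0.5, 1.2, CompoundClass.LIGNIN_OX),       # O/C 0.5 joins oxidized
        (0.499, 1.2, CompoundClass.LIGNIN_LOW_OX),
        (0.3, 0.7, CompoundClass.LIGNIN_LOW_OX),   # H/C 0.7 joins lignin
        (0.3, 0.699, CompoundClass.TANNIN_CONDENSED),
        (0.3, 1.6, CompoundClass.ALIPHATICS),      # H/C 1.6 joins aliphatics
        (0.3, 1.599, CompoundClass.LIGNIN_LOW_OX),
        # the printed oxidized-lignin and carbohydrate regions overlap
        # for O/C in [0.65, 1), H/C in [1.3, 1.6); printed order wins
        (0.65, 1.4, CompoundClass.LIGNIN_OX),
        (0.649, 1.4, CompoundClass.LIGNIN_OX),
        (0.65, 1.65, CompoundClass.CARBOHYDRATES),  # O/C 0.65 joins sugars
        (0.649, 1.65, CompoundClass.ALIPHATICS),
    ])
    def test_printed_boundaries(self, oc, hc, inside_class):
        c = 1000  # large c so integer atom counts hit the ratio exactly
        f = _f(c, round(hc * c), o=round(oc * c))
        assert f.oc_ratio == pytest.approx(oc, abs=1e-9)
        assert classify(f) is inside_class


def _ensemble(members, sid="t"):
    return SampleEnsemble(sample_id=sid, members=dict(members))


class TestClassDensities:
    def test_single_class_density_one(self):
        e = _ensemble([(_f(10, 12, o=3), 0.3), (_f(12, 14, o=4), 0.7)])
        d = class_densities(e)
        assert d["lignin_low_ox"] == pytest.approx(1.0)
        assert d.drop("lignin_low_ox").sum() == pytest.approx(0.0)

    def test_two_class_split(self):
        e = _ensemble([(_f(10, 12, o=3), 0.25), (_f(10, 12, o=7), 0.75)])
        d = class_densities(e)
        assert d["lignin_low_ox"] == pytest.approx(0.25)
        assert d["lignin_ox"] == pytest.approx(0.75)

    def test_scale_invariance(self):
        raw = [(_f(10, 12, o=3), 3.0), (_f(10, 12, o=7), 9.0),
               (_f(20, 10, o=14), 1.0)]
        d1 = class_densities(_ensemble(raw))
        d2 = class_densities(_ensemble([(f, 1000.0 * i) for f, i in raw]))
        pd.testing.assert_series_equal(d1, d2)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(5, 40), st.integers(1, 80),
                  st.integers(0, 2), st.integers(0, 40), st.integers(0, 1),
                  st.floats(1e-6, 1.0)),
        min_size=1, max_size=25, unique_by=lambda t: t[:5]))
    def test_partition_sums_to_one(self, rows):
        members = {}
        for c, h, n, o, s, i in rows:
            members[MolecularFormula(c=c, h=h, n=n, o=o, s=s)] = i
        d = class_densities(_ensemble(members))
        assert d.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((d >= 0) & (d <= 1)).all()

    def test_transect_tannin_ordering(self, default_transect):
        """Southern archetype carries less hydrolysable tannin than the
        northern archetype, as designed."""
        ens, truth = default_transect
        south = class_densities(ens[0])["tannin_hydrolysable"]
        north = class_densities(ens[-1])["tannin_hydrolysable"]
        assert south < north


class TestDescriptors:
    def test_shares_all_cho(self):
        e = _ensemble([(_f(10, 12, o=3), 1.0)])
        s = stoichiometry_shares(e)
        assert s.tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_shares_counting(self):
        members = [(_f(10 + k, 12, o=3), 1.0) for k in range(8)]
        members += [(_f(10, 13, n=1, o=3), 1.0), (_f(10, 12, o=3, s=1), 1.0)]
        s = stoichiometry_shares(_ensemble(members))
        assert s["pct_cho"] == pytest.approx(80.0)
        assert s["pct_chon"] == pytest.approx(10.0)
        assert s["pct_chos"] == pytest.approx(10.0)

    def test_number_averaged_single(self):
        f = _f(10, 12, o=7)
        row = number_averaged(_ensemble([(f, 1.0)]))
        assert row["m_n"] == pytest.approx(f.monoisotopic_mass)
        assert row["oc_n"] == pytest.approx(0.7)
        assert row["hc_n"] == pytest.approx(1.2)
        assert row["n_formulae"] == 1

    def test_number_averaged_unweighted_mean(self):
        f1, f2 = _f(16, 18, o=9), _f(20, 18, o=8)  # DBE 8 and 12
        row = number_averaged(_ensemble([(f1, 0.9), (f2, 0.1)]))
        assert row["dbe_n"] == pytest.approx(10.0)  # intensity ignored
        weighted = number_averaged(_ensemble([(f1, 0.9), (f2, 0.1)]),
                                   intensity_weighted=True)
        assert weighted["dbe_n"] == pytest.approx(8.4)

    def test_default_ensemble_cho_dominates(self, default_transect):
        ens, _ = default_transect
        for e in ens[:3]:
            assert stoichiometry_shares(e)["pct_cho"] > 80.0


class TestSetOperations:
    def test_duplicated_sample_full_intersection(self):
        e = _ensemble([(_f(10, 12, o=3), 0.4), (_f(10, 12, o=7), 0.6)])
        e2 = _ensemble(dict(e.members), sid="u")
        assert common_formulae([e, e2]) == e.formulae()

    def test_disjoint_samples_empty_intersection(self):
        e1 = _ensemble([(_f(10, 12, o=3), 1.0)])
        e2 = _ensemble([(_f(10, 12, o=7), 1.0)], sid="u")
        assert common_formulae([e1, e2]) == set()

    def test_designed_core_recovered_exactly(self, default_transect):
        ens, truth = default_transect
        assert common_formulae(ens) == truth.shared_core
        assert len(truth.shared_core) == 1600

    def test_unique_occurrence_rules(self):
        shared = _f(10, 12, o=3)
        only1 = _f(11, 12, o=3)
        in3 = _f(12, 14, o=4)
        e1 = _ensemble([(shared, .5), (only1, .3), (in3, .2)], "a")
        e2 = _ensemble([(shared, .5), (in3, .5)], "b")
        e3 = _ensemble([(shared, .3), (in3, .7)], "c")
        uniq = unique_formulae([e1, e2, e3])
        assert uniq["a"] == {only1}       # occurrence 1
        assert uniq["b"] == set()         # in3 occurs 3 times
        assert in3 not in uniq["c"]

    def test_planted_singletons_recovered(self, default_transect):
        ens, truth = default_transect
        uniq = unique_formulae(ens)
        for sid, planted in truth.unique_sets.items():
            assert planted <= uniq[sid]

    def test_unique_disjoint_from_common(self, default_transect):
        ens, truth = default_transect
        uniq = unique_formulae(ens)
        common = common_formulae(ens)
        for s in uniq.values():
            assert not (s & common)


class TestVkTable:
    def test_empty_ensemble(self):
        df = vk_table(SampleEnsemble(sample_id="e", members={}))
        assert len(df) == 0

    def test_rows_and_class_consistency(self, default_transect):
        ens, _ = default_transect
        df = vk_table(ens[0])
        assert len(df) == len(ens[0])
        for _, row in df.sample(40, random_state=0).iterrows():
            f = MolecularFormula.from_string(row["formula"])
            assert classify(f).value == row["compound_class"]
        assert (df["oc"].diff().dropna() >= 0).all()
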