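"""Generator determinism and ground-truth consistency."""

import numpy as np
import pytest

from riverdom.peaks import determine_charge, filter_peaks
from riverdom.profiles import CompoundClass, classify, common_formulae
from riverdom.synth import (TransectDesign, generate_ensembles,
                            generate_hydro, generate_peaklist,
                            generate_transect)


class TestDesign:
    def test_gradient_strictly_increasing(self):
        g = TransectDesign().gradient()
        assert np.all(np.diff(g) > 0)
        assert g[0] == 0.0 and g[-1] == 1.0

    def test_station_weights_normalized(self):
        W = TransectDesign().station_weights()
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_invalid_confluence_rejected(self):
        with pytest.raises(ValueError):
            TransectDesign(n_stations=10, confluence_index=10)


class TestGenerateEnsembles:
    def test_deterministic_under_seed(self, small_design):
        e1, t1 = generate_ensembles(small_design)
        e2, t2 = generate_ensembles(small_design)
        for a, b in zip(e1, e2):
            assert a.members == b.members
        assert t1.shared_core == t2.shared_core

    def test_single_class_design(self):
        design = TransectDesign(
            n_stations=4, confluence_index=2, shared_core_size=80,
            unique_per_south_station=0,
            south_weights={CompoundClass.LIGNIN_OX: 1.0},
            north_weights={CompoundClass.LIGNIN_OX: 1.0}, seed=1)
        ens, truth = generate_ensembles(design)
        for f in truth.shared_core:
            assert classify(f) is CompoundClass.LIGNIN_OX

    def test_tannin_density_strictly_increasing(self, default_transect):
        _, truth = default_transect
        d = truth.class_density["tannin_hydrolysable"].to_numpy()
        assert np.all(np.diff(d) > 0)

    def test_core_is_common_and_sized(self, small_design):
        ens, truth = generate_ensembles(small_design)
        assert common_formulae(ens) == truth.shared_core
        assert len(truth.shared_core) == small_design.shared_core_size

    def test_unique_counts_planted(self, small_design):
        ens, truth = generate_ensembles(small_design)
        for i, sid in enumerate(small_design.station_ids()):
            expected = (small_design.unique_per_south_station
                        if i < small_design.confluence_index else 0)
            assert len(truth.unique_sets[sid]) == expected


class TestGeneratePeaklist:
    def test_zero_noise_full_recovery(self, small_design):
        from riverdom.assign import assign_formulae
        ens, truth = generate_ensembles(small_design)
        pl, _ = generate_peaklist(ens[0], noise_ppm=0.0, offset_ppm=0.0,
                                  n_noise_peaks=0, seed=0)
        pl = determine_charge(filter_peaks(pl))
        res = assign_formulae(pl, require_calibrated=False)
        got = {a.formula for a in res}
        cho = {f for f in ens[0].members if f.family == "CHO"}
        assert got >= cho  # every CHO formula returns exactly

    def test_noise_peaks_removed_by_snr_filter(self, small_design):
        ens, _ = generate_ensembles(small_design)
        pl, truth = generate_peaklist(ens[0], n_noise_peaks=500, seed=2)
        kept = filter_peaks(pl)
        kept_mz = set(kept.mz_array())
        noise_mz = {m for m, k in zip(truth.true_mz, truth.kind)
                    if k == "noise"}
        assert not (kept_mz & noise_mz)
        assert len(pl) - len(kept) >= 500

    def test_deterministic_under_seed(self, small_design):
        ens, _ = generate_ensembles(small_design)
        pl1, _ = generate_peaklist(ens[0], seed=9)
        pl2, _ = generate_peaklist(ens[0], seed=9)
        assert np.array_equal(pl1.mz_array(), pl2.mz_array())
        assert np.array_equal(pl1.intensity_array(), pl2.intensity_array())


class TestGenerateHydro:
    def test_zero_noise_perfect_rank_correlation(self, default_transect):
        from scipy.stats import spearmanr
        _, truth = default_transect
        hydro = generate_hydro(TransectDesign(seed=0), truth, seed=0,
                               noise_frac=0.0)
        c_org = [h.c_org for h in hydro]
        tannin = truth.class_density["tannin_hydrolysable"]
        assert spearmanr(c_org, tannin).statistic == pytest.approx(1.0)

    def test_c_org_selected_on_generator_ensembles(self, default_transect):
        """The designed molecular gradient produces > 200 significant
        correlations for organic carbon."""
        from riverdom.correlate import select_parameters, spearman_map
        ens, truth = default_transect
        hydro = generate_hydro(TransectDesign(seed=0), truth, seed=0)
        cmap = spearman_map(ens, hydro, truth.shared_core)
        selected = select_parameters(cmap, 200)
        assert "c_org" in selected

    def test_shuffled_stations_select_nothing(self, default_transect):
        from riverdom.correlate import select_parameters, spearman_map
        from riverdom.profiles import SampleEnsemble
        ens, truth = default_transect
        hydro = generate_hydro(TransectDesign(seed=0), truth, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ens))
        shuffled = [SampleEnsemble(sample_id=ens[j].sample_id,
                                   members=ens[int(i)].members)
                    for j, i in enumerate(perm)]
        cmap = spearman_map(shuffled, hydro, truth.shared_core)
        assert select_parameters(cmap, 200) == []


class TestGenerateTransect:
    def test_all_input_kinds_produced(self, small_design):
        data = generate_transect(small_design)
        n = small_design.n_stations
        assert len(data.peaklists) == n
        assert len(data.absorption) == n
        assert len(data.eems) == n
        assert len(data.hydro) == n

    def test_deterministic_under_seed(self, small_design):
        d1 = generate_transect(small_design)
        d2 = generate_transect(small_design)
        assert np.array_equal(d1.peaklists[0].mz_array(),
                              d2.peaklists[0].mz_array())
        assert np.array_equal(d1.eems[0].intensity, d2.eems[0].intensity)
        assert d1.hydro[3] == d2.hydro[3]
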