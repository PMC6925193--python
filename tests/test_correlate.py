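"""Spearman mapping, parameter selection, overlays, hydro matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverdom.chem import MolecularFormula
from riverdom.correlate import (HydroRecord, hydro_matrix,
                                select_parameters, spearman_map,
                                vk_overlay)
from riverdom.profiles import SampleEnsemble


def _formulae(m):
    out = []
    c = 10
    while len(out) < m:
        for o in range(1, 9):
            out.append(MolecularFormula(c=c, h=12, o=o))
            if len(out) == m:
                break
        c += 1
    return out


def _hydro(station, **over):
    base = dict(temperature=10.0, salinity=0.1, ph=7.5, alkalinity=1500.0,
                hco3=1400.0, co2=100.0, si=50.0, c_org=0.5, a254=20.0)
    base.update(over)
    return HydroRecord(station_id=station, **base)


def _stations(values_by_formula, c_orgs, jitter=None):
    """Build matched ensembles + hydro with designed intensity series."""
    n = len(c_orgs)
    samples, hydro = [], []
    for i in range(n):
        members = {f: max(series[i], 1e-9)
                   for f, series in values_by_formula.items()}
        samples.append(SampleEnsemble(sample_id=f"s{i}", members=members))
        hydro.append(_hydro(f"s{i}", c_org=float(c_orgs[i])))
    return samples, hydro


class TestSpearmanMap:
    def test_perfect_monotone_correlation(self):
        f1, f2 = _formulae(2)
        n = 8
        series = {f1: np.arange(1.0, n + 1),          # rises with c_org
                  f2: np.arange(n, 0.0, -1)}          # falls
        samples, hydro = _stations(series, np.arange(1.0, n + 1) / 10)
        cmap = spearman_map(samples, hydro, {f1, f2})
        assert cmap.r.at["c_org", str(f1)] == pytest.approx(1.0)
        assert cmap.r.at["c_org", str(f2)] == pytest.approx(-1.0)
        assert cmap.p.at["c_org", str(f1)] < 0.05

    def test_antisymmetry_under_sign_flip(self, rng):
        fs = _formulae(5)
        n = 12
        series = {f: rng.uniform(0.1, 1.0, n) for f in fs}
        c = rng.uniform(0.2, 1.2, n)
        samples, hydro1 = _stations(series, c)
        _, hydro2 = _stations(series, -c + 2.0)  # strictly decreasing map
        m1 = spearman_map(samples, hydro1, set(fs))
        m2 = spearman_map(samples, hydro2, set(fs))
        assert np.allclose(m1.r.loc["c_org"], -m2.r.loc["c_org"])

    def test_monotone_transform_invariance(self, rng):
        fs = _formulae(4)
        n = 10
        series = {f: rng.uniform(0.1, 1.0, n) for f in fs}
        c = rng.uniform(0.2, 1.2, n)
        samples, hydro1 = _stations(series, c)
        _, hydro2 = _stations(series, np.exp(c))
        m1 = spearman_map(samples, hydro1, set(fs))
        m2 = spearman_map(samples, hydro2, set(fs))
        assert np.allclose(m1.r.loc["c_org"], m2.r.loc["c_org"])

    def test_station_mismatch_rejected(self):
        fs = _formulae(2)
        series = {f: np.arange(1.0, 7.0) for f in fs}
        samples, hydro = _stations(series, np.arange(1.0, 7.0))
        hydro[0] = _hydro("elsewhere")
        with pytest.raises(ValueError):
            spearman_map(samples, hydro, set(fs))

    def test_constant_vector_excluded(self):
        # both formulae keep fixed proportions, so their sum-normalized
        # intensities are constant across stations
        f1, f2 = _formulae(2)
        n = 8
        series = {f1: np.full(n, 1.0), f2: np.full(n, 2.0)}
        samples, hydro = _stations(series, np.arange(1.0, n + 1) / 10)
        cmap = spearman_map(samples, hydro, {f1, f2})
        assert np.isnan(cmap.r.at["c_org", str(f1)])
        assert cmap.n_constant_excluded >= 1

    def test_exact_small_n_p_matches_scipy_no_ties(self):
        """For small n without ties the permutation p equals scipy's
        exact Spearman p-value."""
        f, g = _formulae(2)
        x = np.array([0.3, 0.9, 0.1, 0.7, 0.5, 0.8])
        y = np.array([0.2, 0.8, 0.3, 0.9, 0.4, 0.7])
        # pair each series with its complement so sum-normalization
        # leaves the intended intensities intact
        samples, hydro = _stations({f: y, g: 1.0 - y}, x)
        cmap = spearman_map(samples, hydro, {f, g})
        ref = stats.spearmanr(x, y)
        assert cmap.r.at["c_org", str(f)] == pytest.approx(ref.statistic)
        # independent exact null: enumerate all pairings with scipy's rho
        from itertools import permutations
        obs = abs(ref.statistic)
        null = [abs(stats.spearmanr(x, np.array(p)).statistic)
                for p in permutations(y)]
        exact_p = np.mean(np.array(null) >= obs - 1e-12)
        assert cmap.p.at["c_org", str(f)] == pytest.approx(exact_p,
                                                           abs=1e-9)

    def test_null_rejection_rate_calibrated(self, rng):
        """Independent inputs reject at ~alpha (small-scale version of
        the acceptance-suite calibration)."""
        fs = _formulae(400)
        n = 18
        series = {f: rng.uniform(0.1, 1.0, n) for f in fs}
        samples, hydro = _stations(series, rng.uniform(0.2, 1.2, n))
        cmap = spearman_map(samples, hydro, set(fs))
        frac = float(cmap.significant.loc["c_org"].mean())
        assert 0.02 < frac < 0.09


class TestSelectionAndOverlay:
    def _map(self, rng, n_sig=300, n_null=300):
        fs = _formulae(n_sig + n_null)
        n = 18
        trend = np.linspace(0.1, 1.0, n)
        series = {}
        for i, f in enumerate(fs):
            if i < n_sig:
                series[f] = trend * rng.uniform(0.5, 1.5) \
                    + rng.normal(0, 0.03, n)
            else:
                series[f] = rng.uniform(0.1, 1.0, n)
        samples, hydro = _stations(series, trend + rng.normal(0, 0.02, n))
        return spearman_map(samples, hydro, set(fs))

    def test_parameter_selection_threshold_strict(self, rng):
        cmap = self._map(rng)
        selected = select_parameters(cmap, min_significant=200)
        assert "c_org" in selected
        total_sig = int(cmap.significant.loc["temperature"].sum())
        assert ("temperature" in
                select_parameters(cmap, min_significant=total_sig - 1))
        assert ("temperature" not in
                select_parameters(cmap, min_significant=total_sig))

    def test_overlay_thresholds_strict(self, rng):
        cmap = self._map(rng, n_sig=40, n_null=40)
        # force exact boundary values to verify strictness
        cmap.r.loc["c_org", :] = 0.0
        cols = cmap.r.columns
        cmap.r.at["c_org", cols[0]] = 0.70
        cmap.r.at["c_org", cols[1]] = 0.700001
        cmap.r.at["c_org", cols[2]] = -0.9
        overlay = vk_overlay(cmap, "c_org")
        by = overlay.set_index("formula")["highlight"]
        assert by[cols[0]] == "weak"          # 0.70 is not > 0.70
        assert by[cols[1]] == "strong_pos"
        assert by[cols[2]] == "strong_neg"

    def test_overlay_has_vk_coordinates(self, rng):
        cmap = self._map(rng, n_sig=30, n_null=30)
        overlay = vk_overlay(cmap, "c_org")
        assert {"oc", "hc", "r", "p", "highlight"} <= set(overlay.columns)
        assert len(overlay) == len(cmap.formulae)


class TestHydroMatrix:
    def test_duplicated_parameter_perfect_correlation(self):
        hydro = [_hydro(f"s{i}", alkalinity=1000.0 + 50 * i,
                        hco3=950.0 + 47.5 * i) for i in range(8)]
        m = hydro_matrix(hydro)
        assert m.at["alkalinity", "hco3"] == pytest.approx(1.0)
        assert np.allclose(np.diag(m), 1.0)
        # constant parameters leave NaN cells; the matrix is still symmetric
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_independent_columns_mostly_insignificant(self, rng):
        n = 40
        hydro = [_hydro(f"s{i}",
                        temperature=float(rng.uniform(0, 20)),
                        si=float(rng.uniform(10, 90)),
                        c_org=float(rng.uniform(0.2, 1.2)))
                 for i in range(n)]
        m = hydro_matrix(hydro, ["temperature", "si", "c_org"])
        crit = stats.t.ppf(0.975, n - 2) / np.sqrt(n - 2)  # approx cutoff
        off = m.values[np.triu_indices(3, 1)]
        assert (np.abs(off) < crit + 0.15).all()

    def test_transect_c_org_a254_strongly_linked(self, default_transect):
        from riverdom.synth import TransectDesign, generate_hydro
        ens, truth = default_transect
        hydro = generate_hydro(TransectDesign(seed=0), truth, seed=4)
        m = hydro_matrix(hydro)
        assert m.at["c_org", "a254"] > 0.7


class TestBhCorrection:
    def test_bh_stricter_than_raw(self, rng):
        from riverdom.correlate import spearman_map
        fs = _formulae(200)
        n = 18
        series = {f: rng.uniform(0.1, 1.0, n) for f in fs}
        c = rng.uniform(0.2, 1.2, n)
        samples, hydro = _stations(series, c)
        raw = spearman_map(samples, hydro, set(fs))
        bh = spearman_map(samples, hydro, set(fs), bh_correction=True)
        n_raw = int(raw.significant.loc["c_org"].sum())
        n_bh = int(bh.significant.loc["c_org"].sum())
        assert n_bh <= n_raw  # step-up rule can only be stricter
        # under the null, BH keeps (almost) nothing
        assert n_bh <= max(2, n_raw // 2)
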