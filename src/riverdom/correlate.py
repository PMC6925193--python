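"""Spearman rank-correlation mapping of molecular abundances onto
hydrochemistry.

For every hydrochemistry parameter and every formula common to all
stations, the Spearman rho between the parameter and the formula's
sum-normalized intensity across stations is computed with average-rank
tie handling and a two-sided p-value.  Parameters with more than a
threshold count of significant correlations (raw p < 0.05; no
multiple-testing correction, a Benjamini-Hochberg screen is available
off by default) are selected for Van Krevelen overlays in which
|rho| > 0.7 marks the strong direct/inverse correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import MolecularFormula
from .profiles import SampleEnsemble, classify

__all__ = [
    "HydroRecord",
    "CorrelationMap",
    "spearman_map",
    "select_parameters",
    "vk_overlay",
    "hydro_matrix",
    "HYDRO_PARAMETERS",
]

#: Hydrochemistry parameter columns, in reporting order.
HYDRO_PARAMETERS = ["temperature", "salinity", "ph", "alkalinity",
                    "hco3", "co2", "si", "c_org", "a254"]

EXACT_P_MAX_N = 9  # exact permutation null below this many stations


@dataclass(frozen=True)
class HydroRecord:
    """One station's hydrochemistry vector."""

    station_id: str
    temperature: float      # degC
    salinity: float         # g/kg
    ph: float               # NBS scale
    alkalinity: float       # umol/kg
    hco3: float             # umol/kg
    co2: float              # umol/kg
    si: float               # uM
    c_org: float            # mM
    a254: float             # 1/m

    def __post_init__(self) -> None:
        if not 0 < self.ph < 14:
            raise ValueError("pH must lie in (0, 14)")
        for name in ("salinity", "alkalinity", "hco3", "co2", "si",
                     "c_org", "a254"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series({p: getattr(self, p) for p in HYDRO_PARAMETERS},
                         name=self.station_id)


@dataclass
class CorrelationMap:
    """Spearman rho / p per (parameter, common formula)."""

    r: pd.DataFrame            # parameters x formulae
    p: pd.DataFrame
    alpha: float
    n_stations: int
    n_constant_excluded: int
    formulae: list[MolecularFormula]
    bh_correction: bool = False

    @property
    def significant(self) -> pd.DataFrame:
        """p < alpha, raw by default; with ``bh_correction`` the
        Benjamini-Hochberg step-up rule is applied per parameter."""
        if not self.bh_correction:
            return self.p < self.alpha
        out = pd.DataFrame(False, index=self.p.index,
                           columns=self.p.columns)
        for param in self.p.index:
            pv = self.p.loc[param].to_numpy()
            ok = ~np.isnan(pv)
            m = int(ok.sum())
            if not m:
                continue
            order = np.argsort(pv[ok])
            ranked = pv[ok][order]
            passed = ranked <= self.alpha * (np.arange(1, m + 1) / m)
            k = np.nonzero(passed)[0]
            thresh = ranked[k[-1]] if k.size else -1.0
            out.loc[param, ok] = pv[ok] <= thresh
        return out


def _spearman_rho(x_rank: np.ndarray, Y_rank: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank vectors: x (n,) against Y (n, m)."""
    xc = x_rank - x_rank.mean()
    Yc = Y_rank - Y_rank.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.sum(Yc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ Yc) / denom


def _p_t_approx(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return p


def _p_exact(x_rank: np.ndarray, Y_rank: np.ndarray,
             rho_obs: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Exact permutation two-sided p, respecting observed tie structures."""
    n = len(x_rank)
    perms = np.array(list(itertools.permutations(range(n))))
    Xp = x_rank[perms]                      # (n!, n)
    xc = Xp - Xp.mean(axis=1, keepdims=True)
    xnorm = np.sqrt(np.sum(xc ** 2, axis=1))
    p = np.empty(Y_rank.shape[1])
    for j0 in range(0, Y_rank.shape[1], chunk):
        Yc = Y_rank[:, j0:j0 + chunk]
        Yc = Yc - Yc.mean(axis=0)
        ynorm = np.sqrt(np.sum(Yc ** 2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            null = (xc @ Yc) / (xnorm[:, None] * ynorm[None, :])
        obs = np.abs(rho_obs[j0:j0 + chunk])
        p[j0:j0 + chunk] = np.mean(np.abs(null) >= obs[None, :] - 1e-12,
                                   axis=0)
    return p


def spearman_map(samples: list[SampleEnsemble],
                 hydro: list[HydroRecord],
                 common: set[MolecularFormula],
                 alpha: float = 0.05,
                 parameters: list[str] | None = None,
                 bh_correction: bool = False) -> CorrelationMap:
    """Correlate each parameter with each common formula across stations.

    Samples and hydrochemistry records are matched 1:1 by id; a mismatch
    is an error.  Constant vectors (parameter or intensity) leave rho
    undefined; those cells are NaN and counted.  p-values use the
    t-approximation for n >= 10 stations and the exact permutation null
    for smaller sets.
    """
    if len(samples) < 5:
        raise ValueError("need at least five stations")
    if not common:
        raise ValueError("the common formula set is empty")
    ids_s = {s.sample_id for s in samples}
    ids_h = {h.station_id for h in hydro}
    if ids_s != ids_h:
        raise ValueError(f"station mismatch: {sorted(ids_s ^ ids_h)}")
    by_id = {h.station_id: h for h in hydro}
    hydro = [by_id[s.sample_id] for s in samples]

    parameters = parameters or HYDRO_PARAMETERS
    formulae = sorted(common)
    n = len(samples)
    Y = np.array([[s.members.get(f, 0.0) for f in formulae]
                  for s in samples])                    # (n, m)
    Y_rank = stats.rankdata(Y, axis=0)
    const_y = np.all(Y == Y[0], axis=0)

    r_rows, p_rows = [], []
    n_const = int(const_y.sum())
    for param in parameters:
        x = np.array([getattr(h, param) for h in hydro], dtype=float)
        x_rank = stats.rankdata(x)
        rho = _spearman_rho(x_rank, Y_rank)
        if np.all(x == x[0]):
            rho = np.full(len(formulae), np.nan)
            n_const += len(formulae)
        rho[const_y] = np.nan
        if n <= EXACT_P_MAX_N:
            p = _p_exact(x_rank, Y_rank, rho)
        else:
            p = _p_t_approx(rho, n)
        p[np.isnan(rho)] = np.nan
        r_rows.append(rho)
        p_rows.append(p)

    cols = [str(f) for f in formulae]
    return CorrelationMap(
        r=pd.DataFrame(r_rows, index=parameters, columns=cols),
        p=pd.DataFrame(p_rows, index=parameters, columns=cols),
        alpha=alpha, n_stations=n, n_constant_excluded=n_const,
        formulae=formulae, bh_correction=bh_correction)


def select_parameters(cmap: CorrelationMap,
                      min_significant: int = 200) -> list[str]:
    """Parameters with strictly more than ``min_significant`` significant
    correlations (raw p < alpha)."""
    counts = cmap.significant.sum(axis=1)
    return [p for p in cmap.r.index if counts[p] > min_significant]


def vk_overlay(cmap: CorrelationMap, parameter: str,
               r_threshold: float = 0.7) -> pd.DataFrame:
    """Van Krevelen overlay of a parameter's correlation map.

    One row per common formula with its O/C, H/C, rho, p and a highlight
    label: ``strong_pos`` for rho strictly above the threshold,
    ``strong_neg`` strictly below its negative, else ``weak``.
    """
    if parameter not in cmap.r.index:
        raise KeyError(f"unknown parameter {parameter!r}")
    rows = []
    for f in cmap.formulae:
        r = cmap.r.at[parameter, str(f)]
        p = cmap.p.at[parameter, str(f)]
        if np.isnan(r):
            label = "undefined"
        elif r > r_threshold:
            label = "strong_pos"
        elif r < -r_threshold:
            label = "strong_neg"
        else:
            label = "weak"
        rows.append({"formula": str(f), "oc": f.oc_ratio, "hc": f.hc_ratio,
                     "compound_class": classify(f).value, "r": r, "p": p,
                     "highlight": label})
    return pd.DataFrame(rows)


def hydro_matrix(hydro: list[HydroRecord],
                 parameters: list[str] | None = None) -> pd.DataFrame:
    """Symmetric Spearman matrix of the hydrochemistry parameters."""
    if len(hydro) < 5:
        raise ValueError("need at least five stations")
    parameters = parameters or HYDRO_PARAMETERS
    df = pd.DataFrame([[getattr(h, p) for p in parameters] for h in hydro],
                      columns=parameters)
    rho = df.corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    return rho
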