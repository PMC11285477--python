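"""Robust heteroscedastic group comparisons: Welch–Yuen, Dunnett-T3-type
pairwise tests on trimmed means, and Cliff's rank-based method.

The battery follows the robust-statistics convention of symmetric per-tail
trimming (default γ = 0.15) inside the Yuen/Welch machinery: trimmed means
with winsorized variances and Welch-type degrees of freedom.  Cliff's method
is rank-based and uses the untrimmed data.  With γ = 0 the Welch–Yuen test
reduces to the ordinary Welch heteroscedastic test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import DesignError, SampleSizeError
from .registry import ALL_PARAMS
from .surface_io import MeasurementTable


@dataclass
class StatsConfig:
    """Configuration of the three-test battery.

    gamma: fraction trimmed per tail (0.15 default, 0 disables trimming).
    alpha: significance level used for flagging and Cliff's CI (two-sided).
    tests: subset of {"welch_yuen", "t3", "cliff"} to run.
    adjust: "none" or "holm" (Holm step-down across the 30 parameters).
    """

    gamma: float = 0.15
    alpha: float = 0.05
    tests: tuple = ("welch_yuen", "t3", "cliff")
    adjust: str = "none"

    def __post_init__(self):
        if not (0.0 <= self.gamma < 0.5):
            raise ValueError("gamma must lie in [0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.adjust not in ("none", "holm"):
            raise ValueError("adjust must be 'none' or 'holm'")


# ---------------------------------------------------------------------------
# trimmed / winsorized moments
# ---------------------------------------------------------------------------


def trimmed_moments(x, gamma: float) -> dict:
    """Trimmed mean, winsorized variance and effective sample size.

    g = floor(γ·n) observations are removed from each tail for the trimmed
    mean; the winsorized variance replaces each tail with its innermost
    retained order statistic (sample variance, n−1 denominator).  The
    effective size is h = n − 2g.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    g = int(np.floor(gamma * n))
    h = n - 2 * g
    if h < 2:
        raise SampleSizeError(f"h = {h} after trimming {g} per tail from n = {n}")
    tmean = float(x[g : n - g].mean())
    w = x.copy()
    w[:g] = x[g]
    w[n - g :] = x[n - g - 1]
    wvar = float(w.var(ddof=1))
    return {"mean": tmean, "winvar": wvar, "h": h, "n": n, "g": g}


def _group_weights(samples, gamma, labels=None):
    moms = []
    for i, x in enumerate(samples):
        try:
            moms.append(trimmed_moments(x, gamma))
        except SampleSizeError as exc:
            name = labels[i] if labels is not None else f"group {i}"
            raise SampleSizeError(f"{name}: {exc}") from None
    d = np.array([(m["n"] - 1) * m["winvar"] / (m["h"] * (m["h"] - 1)) for m in moms])
    # constant groups carry no sampling variance; keep the algebra finite
    d = np.where(d == 0.0, 1e-300, d)
    return moms, d


# ---------------------------------------------------------------------------
# Welch–Yuen heteroscedastic omnibus test
# ---------------------------------------------------------------------------


def welch_yuen(samples, config: StatsConfig | None = None) -> dict:
    """Heteroscedastic omnibus F test on trimmed means (Welch–Yuen).

    For two groups this equals Yuen's trimmed t with Ft = t², nu1 = 1 and the
    Welch–Satterthwaite nu2; with γ = 0 it is the ordinary Welch test.
    Returns {"Ft", "nu1", "nu2", "p"}.
    """
    config = config or StatsConfig()
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise DesignError("welch_yuen needs at least two groups")
    moms, d = _group_weights(samples, config.gamma)
    J = len(samples)
    w = 1.0 / d
    U = w.sum()
    means = np.array([m["mean"] for m in moms])
    h = np.array([m["h"] for m in moms])
    xt = (w * means).sum() / U
    A = (w * (means - xt) ** 2).sum() / (J - 1)
    term = ((1.0 - w / U) ** 2 / (h - 1)).sum()
    B = 2.0 * (J - 2) / (J**2 - 1.0) * term
    Ft = A / (1.0 + B)
    nu1 = J - 1
    nu2 = 1.0 / (3.0 / (J**2 - 1.0) * term)
    if A == 0.0:
        return {"Ft": 0.0, "nu1": nu1, "nu2": float(nu2), "p": 1.0}
    p = float(stats.f.sf(Ft, nu1, nu2))
    return {"Ft": float(Ft), "nu1": nu1, "nu2": float(nu2), "p": p}


# ---------------------------------------------------------------------------
# pairwise Dunnett-T3-type comparisons (studentized maximum modulus)
# ---------------------------------------------------------------------------


def smm_cdf(q: float, n_comparisons: int, df: float) -> float:
    """CDF of the studentized maximum modulus with C comparisons and df ν.

    P(max_i |T_i| <= q) for C independent standard normals studentized by a
    common chi(ν)/sqrt(ν); evaluated by fixed-tolerance numerical quadrature.
    For C = 1 this is the two-sided t CDF.
    """
    if q <= 0:
        return 0.0

    def integrand(u):
        return (2.0 * stats.norm.cdf(q * u) - 1.0) ** n_comparisons * stats.chi.pdf(
            u * np.sqrt(df), df
        ) * np.sqrt(df)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(min(max(val, 0.0), 1.0))


def pairwise_t3(samples, config: StatsConfig | None = None, labels=None) -> list[dict]:
    """Trimmed-mean pairwise comparisons with SMM family-wise p values.

    Each pair gets a Yuen-type statistic with Welch df; the family-wise p is
    1 − F_SMM(|t|; C, df) with C = number of pairs.  For two groups this
    reduces to Yuen's test.
    """
    config = config or StatsConfig()
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise DesignError("pairwise_t3 needs at least two groups")
    labels = labels if labels is not None else list(range(len(samples)))
    moms, d = _group_weights(samples, config.gamma)
    pairs = list(itertools.combinations(range(len(samples)), 2))
    C = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(d[i] + d[j])
        diff = moms[i]["mean"] - moms[j]["mean"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (d[i] + d[j]) ** 2 / (
                d[i] ** 2 / (moms[i]["h"] - 1) + d[j] ** 2 / (moms[j]["h"] - 1)
            )
        if not np.isfinite(df) or df <= 0:
            df = moms[i]["h"] + moms[j]["h"] - 2.0
        if se == 0.0:
            t = 0.0 if diff == 0 else np.inf
        else:
            t = diff / se
        p = 1.0 - smm_cdf(abs(t), C, df) if np.isfinite(t) else 0.0
        out.append({"pair": (labels[i], labels[j]), "stat": float(t), "Df": float(df), "p": float(p)})
    return out


# ---------------------------------------------------------------------------
# Cliff's rank-based method
# ---------------------------------------------------------------------------


def cliff(x, y, alpha: float = 0.05) -> dict:
    """Cliff's ordinal dominance test of two samples.

    ph = P(x > y) + 0.5·P(x = y) estimated over all pairs; delta = 2·ph − 1
    with Cliff's consistent variance estimate; the asymmetric CI for delta is
    back-transformed to (pl, pu) on the ph scale; two-sided p from the normal
    deviate of delta.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise DesignError("cliff requires two nonempty samples")
    dmat = np.sign(x[:, None] - y[None, :])
    delta = float(dmat.mean())
    ph = (delta + 1.0) / 2.0
    di = dmat.mean(axis=1)
    dj = dmat.mean(axis=0)
    if m > 1 and n > 1:
        s_di = ((di - delta) ** 2).sum() / (m - 1)
        s_dj = ((dj - delta) ** 2).sum() / (n - 1)
        s_dij = ((dmat - delta) ** 2).sum() / (m * n - 1)
        var = ((m - 1) * s_di + (n - 1) * s_dj + s_dij) / (m * n)
    else:
        var = ((dmat - delta) ** 2).sum() / (m * n - 1) / (m * n) if m * n > 1 else 0.0
    sd = float(np.sqrt(var))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    if sd == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
        lo = hi = delta
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / sd))
        # Cliff's asymmetric CI for delta
        den = 1.0 - delta**2 + zq**2 * var
        root = zq * sd * np.sqrt((1.0 - delta**2) ** 2 + zq**2 * var)
        lo = (delta - delta**3 - root) / den
        hi = (delta - delta**3 + root) / den
    pl = float(np.clip((lo + 1.0) / 2.0, 0.0, 1.0))
    pu = float(np.clip((hi + 1.0) / 2.0, 0.0, 1.0))
    pl, pu = min(pl, ph), max(pu, ph)
    return {"ph": float(ph), "pl": pl, "pu": pu, "p": min(p, 1.0), "delta": delta}


# ---------------------------------------------------------------------------
# full battery over a measurement table
# ---------------------------------------------------------------------------


@dataclass
class ComparisonRow:
    group: str
    parameter: str
    Ft: float = np.nan
    p_welch: float = np.nan
    nu1: float = np.nan
    nu2: float = np.nan
    t3_stat: float = np.nan
    t3_df: float = np.nan
    p_t3: float = np.nan
    ph: float = np.nan
    pl: float = np.nan
    pu: float = np.nan
    p_cliff: float = np.nan
    significant: bool = False
    stars: str = ""


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_parameters(
    table: MeasurementTable,
    factor: str,
    config: StatsConfig | None = None,
    parameters=ALL_PARAMS,
    label: str | None = None,
) -> pd.DataFrame:
    """Run the three-test battery on every parameter, grouped by ``factor``.

    Scans are the analysis units (replicate rows are not averaged per
    specimen).  For factors with more than two levels the omnibus columns are
    shared across rows and one row per parameter and level pair is emitted;
    Cliff's test is computed per pair.  Rows with p ≤ alpha in any requested
    test are flagged ``significant``.
    """
    config = config or StatsConfig()
    df = table.data
    levels = [lv for lv in pd.unique(df[factor]) if pd.notna(lv)]
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has fewer than two levels present")
    label = label or f"{factor}: " + " vs. ".join(str(lv) for lv in levels)

    rows = []
    for param in parameters:
        samples = [df.loc[df[factor] == lv, param].to_numpy(dtype=float) for lv in levels]
        res = ComparisonRow(group=label, parameter=param)
        if "welch_yuen" in config.tests:
            wy = welch_yuen(samples, config)
            res.Ft, res.p_welch, res.nu1, res.nu2 = wy["Ft"], wy["p"], wy["nu1"], wy["nu2"]
        pair_rows = [res]
        if "t3" in config.tests:
            t3 = pairwise_t3(samples, config, labels=levels)
            if len(t3) == 1:
                res.t3_stat, res.t3_df, res.p_t3 = t3[0]["stat"], t3[0]["Df"], t3[0]["p"]
            else:
                pair_rows = []
                for entry in t3:
                    r = ComparisonRow(
                        group=f"{label} [{entry['pair'][0]} vs. {entry['pair'][1]}]",
                        parameter=param,
                        Ft=res.Ft, p_welch=res.p_welch, nu1=res.nu1, nu2=res.nu2,
                        t3_stat=entry["stat"], t3_df=entry["Df"], p_t3=entry["p"],
                    )
                    pair_rows.append(r)
        if "cliff" in config.tests:
            for r in pair_rows:
                if len(levels) == 2:
                    xi, yi = 0, 1
                else:
                    la = r.group[r.group.rfind("[") + 1 : -1].split(" vs. ")
                    xi = [str(l) for l in levels].index(la[0])
                    yi = [str(l) for l in levels].index(la[1])
                cl = cliff(samples[xi], samples[yi], config.alpha)
                r.ph, r.pl, r.pu, r.p_cliff = cl["ph"], cl["pl"], cl["pu"], cl["p"]
        rows.extend(pair_rows)

    out = pd.DataFrame([vars(r) for r in rows])
    pcols = [c for c in ("p_welch", "p_t3", "p_cliff") if out[c].notna().any()]
    if config.adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        for c in pcols:
            mask = out[c].notna()
            out.loc[mask, c] = multipletests(out.loc[mask, c], method="holm")[1]
    out["significant"] = out[pcols].le(config.alpha).any(axis=1)
    out["stars"] = out[pcols].min(axis=1).map(_stars)
    return out
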