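"""Phage phenotype statistics.

Covers the four phenotype analyses of a temperate-phage characterisation:

* **RBG** (reduction in bacterial growth), a virulence statistic:
  ``1 - (OD+ gain) / (OD- gain)`` over a fixed interval, per replicate
  pair of phage-treated and phage-free cultures;
* **host-range grading** of spot assays into none/weak/strong/
  lysogenization;
* **one-step growth-curve estimation** of latent period and burst size
  from a PFU time series (plateau means plus the max-slope tangent);
* **fixed-effects ANOVA with pairwise contrasts** in the design used for
  such assays (phage x host, type-I sums of squares).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from rhizophage.io import AssayTable


# ---------------------------------------------------------------------------
# RBG


@dataclass
class RBGResult:
    phage_id: str
    host_id: str
    replicate: int
    t0: float
    tx: float
    rbg: float
    flag: str | None = None


def _reading_at(series: pd.DataFrame, t: float, tol: float) -> float:
    times = series["time"].to_numpy()
    idx = int(np.argmin(np.abs(times - t)))
    if abs(times[idx] - t) > tol:
        raise ValueError(f"no reading within {tol:g} min of t={t:g}")
    return float(series["value"].to_numpy()[idx])


def compute_rbg(
    assay: AssayTable, t0: float | None = None, tx: float = 2400.0
) -> list[RBGResult]:
    """Reduction in bacterial growth per replicate pair.

    ``rbg = 1 - (OD+(tx) - OD+(t0)) / (OD-(tx) - OD-(t0))`` where the
    control series shares (host, replicate) with the treated series.
    ``t0`` defaults to the first reading.  Readings are taken at the
    nearest time within half a sampling interval.  A non-positive control
    gain leaves RBG undefined (NaN) with a flag rather than dividing by
    it.
    """
    df = assay.df
    results = []
    plus = df[df["treatment"] == "phage+"]
    minus = df[df["treatment"] == "phage-"]
    for sid in dict.fromkeys(plus["series_id"]):
        sp = plus[plus["series_id"] == sid].sort_values("time")
        phage_id = sp["phage_id"].iloc[0]
        host_id = sp["host_id"].iloc[0]
        rep = sp["replicate"].iloc[0]
        ctrl = minus[(minus["host_id"] == host_id) & (minus["replicate"] == rep)]
        same_phage = ctrl[ctrl["phage_id"] == phage_id]
        if not same_phage.empty:
            ctrl = same_phage
        if ctrl.empty:
            raise ValueError(
                f"series {sid!r}: no phage- control for host {host_id!r}, "
                f"replicate {rep!r}"
            )
        ctrl_sid = ctrl["series_id"].iloc[0]
        sc = ctrl[ctrl["series_id"] == ctrl_sid].sort_values("time")
        step = float(np.median(np.diff(sp["time"].to_numpy())))
        tol = step / 2
        t_start = float(sp["time"].iloc[0]) if t0 is None else t0
        if not t_start < tx:
            raise ValueError("tx must exceed t0")
        d_plus = _reading_at(sp, tx, tol) - _reading_at(sp, t_start, tol)
        d_minus = _reading_at(sc, tx, tol) - _reading_at(sc, t_start, tol)
        if d_minus <= 0:
            results.append(
                RBGResult(phage_id, host_id, rep, t_start, tx, float("nan"),
                          flag="control-gain-nonpositive")
            )
            continue
        results.append(
            RBGResult(phage_id, host_id, rep, t_start, tx,
                      1.0 - d_plus / d_minus)
        )
    return results


# ---------------------------------------------------------------------------
# Host-range grading


@dataclass
class HostRangeCall:
    phage_id: str
    host_id: str
    grade: str  # none | weak | strong | lysogenization
    flag: str | None = None


def grade_host_range(
    phage_id: str,
    host_id: str,
    day1_clearing: str,
    plaques_at_dilution: bool = False,
    regrowth_in_spot: bool = False,
    lysogen_pcr_positive: bool | None = None,
) -> HostRangeCall:
    """Grade one spot-assay observation.

    No clearing -> ``none``; turbid clearing at high titre -> ``weak``;
    clear zone with individual plaques at dilution -> ``strong``; a strong
    spot that regrows and whose colonies test PCR-positive for the
    prophage -> ``lysogenization``.  Regrowth without a PCR result keeps
    the grade ``strong`` with a ``lysogeny-untested`` flag.  Clear zones
    without plaques are graded ``weak`` (lysis-from-without cannot be
    excluded).
    """
    if day1_clearing not in ("none", "turbid", "clear"):
        raise ValueError(f"unknown clearing state {day1_clearing!r}")
    if day1_clearing == "none":
        return HostRangeCall(phage_id, host_id, "none")
    if day1_clearing == "turbid" or not plaques_at_dilution:
        return HostRangeCall(phage_id, host_id, "weak")
    if regrowth_in_spot:
        if lysogen_pcr_positive is None:
            return HostRangeCall(phage_id, host_id, "strong",
                                 flag="lysogeny-untested")
        if lysogen_pcr_positive:
            return HostRangeCall(phage_id, host_id, "lysogenization")
    return HostRangeCall(phage_id, host_id, "strong")


# ---------------------------------------------------------------------------
# One-step growth fit


@dataclass
class GrowthFit:
    phage_id: str
    replicate: int
    latent_min: float | None
    burst_size: float
    baseline_pfu: float
    plateau_pfu: float
    rss: float
    flag: str | None = None


def _fit_single(times: np.ndarray, values: np.ndarray,
                phage_id: str, rep: int) -> GrowthFit:
    if len(times) < 6:
        raise ValueError("one-step fit needs at least 6 time points")
    if (values <= 0).any():
        raise ValueError("PFU values must be positive")
    y = np.log10(values)
    lo, hi = y.min(), y.max()
    rng_y = hi - lo
    slopes = np.diff(y) / np.diff(times)
    m = int(np.argmax(slopes))
    base_idx = [i for i in range(m + 1) if y[i] <= lo + 0.25 * rng_y]
    if not base_idx:
        base_idx = [0]
    plat_idx = [i for i in range(m + 1, len(y)) if y[i] >= lo + 0.75 * rng_y]
    if not plat_idx:
        plat_idx = [len(y) - 1]
    # medians: a partially-risen sample that sneaks past the range
    # threshold cannot drag the plateau estimate
    base = float(np.median(y[base_idx]))
    plat = float(np.median(y[plat_idx]))
    burst = 10.0 ** (plat - base)
    flag = None
    latent: float | None
    if burst < 2.0:
        latent, flag = None, "no-rise"
    else:
        t_mid = 0.5 * (times[m] + times[m + 1])
        y_mid = 0.5 * (y[m] + y[m + 1])
        latent = float(t_mid - (y_mid - base) / slopes[m])
        latent = float(np.clip(latent, times[0], times[-1]))
    # piecewise reconstruction for a residual diagnostic
    if latent is None:
        model = np.full_like(y, base)
    else:
        t_plat = latent + (plat - base) / slopes[m]
        model = np.where(
            times <= latent, base,
            np.where(times >= t_plat, plat, base + slopes[m] * (times - latent)),
        )
    rss = float(((y - model) ** 2).sum())
    return GrowthFit(
        phage_id=phage_id, replicate=rep, latent_min=latent,
        burst_size=float(burst), baseline_pfu=float(10.0 ** base),
        plateau_pfu=float(10.0 ** plat), rss=rss, flag=flag,
    )


def fit_one_step(series: AssayTable, i0: float | None = None) -> list[GrowthFit]:
    """Estimate latent period and burst size from one-step PFU series.

    Baseline and final plateaus are medians (in log10) of the pre- and
    post-rise points; the rise is located by the maximum slope of
    log10(PFU); the latent period is where the max-slope tangent meets
    the baseline; burst size is plateau / baseline.  One fit per series
    in the table.
    """
    if i0 is not None and i0 <= 0:
        raise ValueError("i0 must be positive")
    fits = []
    for sid in series.series_ids():
        sub = series.series(sid)
        fits.append(
            _fit_single(
                sub["time"].to_numpy(dtype=float),
                sub["value"].to_numpy(dtype=float),
                sub["phage_id"].iloc[0],
                sub["replicate"].iloc[0],
            )
        )
    return fits


# ---------------------------------------------------------------------------
# ANOVA with contrasts


@dataclass
class AnovaReport:
    factor_table: pd.DataFrame    # term, df, sum_sq, F, p
    contrast_table: pd.DataFrame  # pair, estimate, t, p
    residual_df: int
    mse: float


def anova_with_contrasts(
    values,
    factor_a,
    factor_b=None,
    tukey: bool = False,
) -> AnovaReport:
    """Fixed-effects ANOVA (type-I sums of squares, order A then B then
    A x B) with pairwise contrasts on the first factor's level means.

    Contrast t statistics use the pooled residual error from the full
    model; p-values are two-sided and unadjusted by default (``tukey=True``
    switches to Tukey HSD adjusted p-values).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "A": list(factor_a)})
    if len(set(df["A"])) < 2:
        raise ValueError("factor A needs at least 2 levels")
    if factor_b is not None:
        df["B"] = list(factor_b)
        counts = df.groupby(["A", "B"], sort=True).size()
        for a_lv, b_lv in itertools.product(
            sorted(set(df["A"])), sorted(set(df["B"]))
        ):
            if (a_lv, b_lv) not in counts.index:
                raise ValueError(f"empty design cell ({a_lv!r}, {b_lv!r})")
        formula = "value ~ C(A) + C(B) + C(A):C(B)"
    else:
        formula = "value ~ C(A)"
    if np.ptp(df["value"].to_numpy()) == 0:
        # constant response: every effect is exactly zero
        n = len(df)
        levels = sorted(set(df["A"]))
        terms = [("C(A)", len(levels) - 1)]
        if factor_b is not None:
            nb = len(set(df["B"]))
            terms += [("C(B)", nb - 1), ("C(A):C(B)", (len(levels) - 1) * (nb - 1))]
        resid_df = n - 1 - sum(d for _, d in terms)
        factor_table = pd.DataFrame(
            [{"term": t, "df": d, "sum_sq": 0.0, "F": 0.0, "p": 1.0}
             for t, d in terms]
            + [{"term": "Residual", "df": resid_df, "sum_sq": 0.0,
                "F": np.nan, "p": np.nan}]
        )
        contrast_table = pd.DataFrame(
            [{"pair": f"{l2}-{l1}", "estimate": 0.0, "t": 0.0, "p": 1.0}
             for l1, l2 in itertools.combinations(levels, 2)]
        )
        return AnovaReport(factor_table, contrast_table, resid_df, 0.0)
    fit = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    resid_df = int(table.loc["Residual", "df"])
    factor_rows = []
    for term in table.index:
        factor_rows.append(
            {
                "term": term,
                "df": int(table.loc[term, "df"]),
                "sum_sq": float(table.loc[term, "sum_sq"]),
                "F": float(table.loc[term, "F"]) if term != "Residual" else np.nan,
                "p": float(table.loc[term, "PR(>F)"]) if term != "Residual" else np.nan,
            }
        )
    factor_table = pd.DataFrame(factor_rows)
    if mse == 0:  # degenerate data: no residual variation
        zero_var = factor_table["term"] != "Residual"
        factor_table.loc[zero_var & (factor_table["sum_sq"] < 1e-12), "F"] = 0.0
        factor_table.loc[zero_var & (factor_table["sum_sq"] < 1e-12), "p"] = 1.0

    levels = sorted(set(df["A"]))
    if mse == 0:
        contrast_rows = [
            {"pair": f"{l1}-{l2}", "estimate": 0.0, "t": 0.0, "p": 1.0}
            for l1, l2 in itertools.combinations(levels, 2)
        ]
        contrast_table = pd.DataFrame(contrast_rows)
        return AnovaReport(factor_table, contrast_table, resid_df, mse)
    contrast_rows = []
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df["value"], df["A"])
        for (l1, l2), diff, p_adj in zip(
            itertools.combinations(res.groupsunique, 2),
            res.meandiffs, res.pvalues,
        ):
            n1 = (df["A"] == l1).sum()
            n2 = (df["A"] == l2).sum()
            se = np.sqrt(mse * (1 / n1 + 1 / n2))
            contrast_rows.append(
                {"pair": f"{l2}-{l1}", "estimate": float(diff),
                 "t": float(diff / se), "p": float(p_adj)}
            )
    else:
        for l1, l2 in itertools.combinations(levels, 2):
            v1 = df.loc[df["A"] == l1, "value"]
            v2 = df.loc[df["A"] == l2, "value"]
            est = float(v2.mean() - v1.mean())
            se = np.sqrt(mse * (1 / len(v1) + 1 / len(v2)))
            t = est / se
            p = 2 * stats.t.sf(abs(t), resid_df)
            contrast_rows.append(
                {"pair": f"{l2}-{l1}", "estimate": est,
                 "t": float(t), "p": float(p)}
            )
    contrast_table = pd.DataFrame(contrast_rows)
    return AnovaReport(factor_table, contrast_table, resid_df, mse)
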