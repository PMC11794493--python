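"""Within-subject statistics: outlier screening, paired t-tests, 3 x 2
repeated-measures ANOVA with Greenhouse-Geisser correction, and simple
effects.

The RM-ANOVA partitions sums of squares subject-wise: each within-subject
effect is tested against its own subject x effect interaction term. The
Greenhouse-Geisser epsilon deflates the degrees of freedom of effects with
more than one numerator df to correct for sphericity violations; effect
sizes are partial eta-squared, eta2p = SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One test: statistic, df (possibly fractional after GG), p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or math.isnan(self.p)):
            raise ValueError(f"p={self.p} outside [0, 1]")

    def as_row(self) -> dict:
        row = {"effect": self.name, "statistic": self.statistic,
               "p": self.p}
        for i, d in enumerate(self.df, 1):
            row[f"df{i}"] = d
        if self.effect_size is not None:
            row[self.effect_size_name or "effect_size"] = self.effect_size
        row.update(self.extra)
        return row


def exclude_outliers(values, k: float = 3.0):
    """Single-pass +/- k SD screen.

    Mean and SD come from the full sample; values with |v - mean| > k * SD
    are removed in one pass (no re-iteration on the reduced sample). Returns
    ``(kept_values, exclusion_log)``.
    """
    values = np.asarray(values, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(values) < 3:
        raise ValueError("need at least 3 values for an SD-based screen")
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0 or not np.isfinite(k):
        keep = np.ones(len(values), dtype=bool)
    else:
        keep = np.abs(values - mean) <= k * sd
    log = {"mean": float(mean), "sd": float(sd), "k": k,
           "removed_indices": np.where(~keep)[0].tolist(),
           "removed_values": values[~keep].tolist()}
    return values[keep], log


def paired_t(x, y, names: tuple[str, str] = ("x", "y")) -> StatResult:
    """Two-sided paired t-test with Cohen's d_z.

    t = mean(d) / (sd(d) / sqrt(n)) on d = x - y, df = n - 1. A zero-variance
    nonzero difference yields an infinite t reported with p = 0 and a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D (paired by subject)")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    means = {names[0]: float(x.mean()), names[1]: float(y.mean())}
    sds = {names[0]: float(x.std(ddof=1)), names[1]: float(y.std(ddof=1))}
    if sd == 0:
        if d.mean() == 0:
            return StatResult("paired_t", 0.0, (n - 1,), 1.0, 0.0, "cohen_dz",
                              means, sds)
        t = math.inf if d.mean() > 0 else -math.inf
        return StatResult("paired_t", t, (n - 1,), 0.0, t, "cohen_dz",
                          means, sds, extra={"degenerate": "sd(d)=0"})
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return StatResult("paired_t", float(t), (n - 1,), float(p),
                      float(d.mean() / sd), "cohen_dz", means, sds)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-condition covariance.

    Computed from the eigenvalues lambda of the double-centered covariance
    (equivalently of C S C' for any orthonormal contrast basis C):
    eps = (sum lambda)^2 / ((k - 1) * sum lambda^2), bounded in
    [1/(k-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k) or k < 2:
        raise ValueError("covariance must be k x k with k >= 2")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    H = np.eye(k) - 1.0 / k
    S = H @ cov @ H
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0, None)
    denom = (k - 1) * (lam ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate (zero) covariance: epsilon undefined")
    return float(lam.sum() ** 2 / denom)


def _contrast_epsilon(cells: np.ndarray, C: np.ndarray) -> float:
    """Epsilon for an effect given subject x cell scores and contrast rows C."""
    if C.shape[0] == 1:
        return 1.0
    Y = cells @ C.T                       # subjects x df
    S = np.cov(Y, rowvar=False)
    S = np.atleast_2d(S)
    lam = np.clip(np.linalg.eigvalsh(S), 0, None)
    denom = C.shape[0] * (lam ** 2).sum()
    if denom == 0:
        return 1.0  # no contrast variance at all: sphericity is vacuous
    return float(lam.sum() ** 2 / denom)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to the mean."""
    H = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(H)
    return u[:, :k - 1].T


@dataclass
class RMAnovaResult:
    """Results container for the two-way within-subject ANOVA."""

    effects: dict[str, StatResult]
    dv: str
    factors: tuple[str, str]
    levels: tuple[tuple[str, ...], tuple[str, ...]]
    n_subjects: int
    cell_means: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for res in self.effects.values():
            rows.append({
                "effect": res.name, "SS": res.extra["SS"],
                "df": res.df[0], "df_error": res.df[1],
                "df_GG": res.extra["df_GG"], "df_error_GG": res.extra["df_error_GG"],
                "F": res.statistic, "p": res.extra["p_uncorrected"],
                "p_GG": res.p, "epsilon": res.extra["epsilon"],
                "eta2p": res.effect_size,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA on {self.dv!r} "
                 f"({self.n_subjects} subjects, "
                 f"{self.factors[0]} x {self.factors[1]} = "
                 f"{len(self.levels[0])} x {len(self.levels[1])})", ""]
        t = self.table()
        lines.append(t.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def rm_anova_3x2(table: pd.DataFrame, dv: str = "value",
                 factors: tuple[str, str] = ("channel_type", "music_type"),
                 subject: str = "subject") -> RMAnovaResult:
    """Two-way fully within-subject ANOVA (any a x b layout, named for the
    study's 3 x 2 design).

    ``table`` is tidy with one row per subject x cell (trial-averaged).
    Each effect uses its own subject x effect error term; Greenhouse-Geisser
    epsilon is computed per effect from the orthonormal-contrast covariance
    and applied to the corrected p-value (trivially 1 for single-df effects).
    """
    fa, fb = factors
    need = {subject, fa, fb, dv}
    if not need <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    a_levels = tuple(sorted(table[fa].unique()))
    b_levels = tuple(sorted(table[fb].unique()))
    a, b = len(a_levels), len(b_levels)
    piv = table.pivot_table(index=subject, columns=[fa, fb], values=dv,
                            aggfunc="mean")
    expected = [(x, y) for x in a_levels for y in b_levels]
    missing = [c for c in expected if c not in piv.columns]
    incomplete = piv.index[piv.isna().any(axis=1)].tolist()
    if missing or incomplete:
        raise ValueError(
            f"incomplete design: missing cells {missing}, "
            f"subjects with missing data {incomplete}")
    piv = piv[expected]
    Y = piv.to_numpy()                       # n x (a*b), cells in a-major order
    n = Y.shape[0]
    cube = Y.reshape(n, a, b)

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))             # per subject
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)                 # a x b
    m_sa = cube.mean(axis=2)                 # n x a
    m_sb = cube.mean(axis=1)                 # n x b

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = (resid ** 2).sum()

    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    eps = {
        fa: _contrast_epsilon(m_sa, Ca),
        fb: _contrast_epsilon(m_sb, Cb),
        f"{fa}:{fb}": _contrast_epsilon(Y, np.kron(Ca, Cb)),
    }
    spec = {
        fa: (ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        fb: (ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        f"{fa}:{fb}": (ss_ab, (a - 1) * (b - 1), ss_sab,
                       (a - 1) * (b - 1) * (n - 1)),
    }
    # numerically-zero sums of squares (pure subject effects) must yield
    # F = 0, not a 0/0 ratio of rounding residue
    tol = 1e-12 * max(float(((cube - grand) ** 2).sum()), 1e-300)
    effects = {}
    for name, (ss_eff, df1, ss_err, df2) in spec.items():
        if ss_eff < tol:
            ss_eff = 0.0
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
        e = eps[name]
        p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        p_gg = float(sps.f.sf(F, e * df1, e * df2)) if np.isfinite(F) else 0.0
        eta2p = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = StatResult(
            name, float(F), (float(df1), float(df2)),
            p_gg, float(eta2p), "eta2p",
            extra={"SS": float(ss_eff), "SS_error": float(ss_err),
                   "epsilon": e, "df_GG": e * df1, "df_error_GG": e * df2,
                   "p_uncorrected": p_unc})
    cell_means = table.pivot_table(index=fa, columns=fb, values=dv,
                                   aggfunc="mean")
    return RMAnovaResult(effects, dv, factors, (a_levels, b_levels), n,
                         cell_means=cell_means)


def simple_effects(table: pd.DataFrame, within: str, at_factor: str,
                   at_level: str, dv: str = "value", subject: str = "subject",
                   adjust: str | None = None) -> list[StatResult]:
    """Pairwise paired t-tests of ``within`` at one level of the other factor.

    ``adjust`` may be ``"holm"`` or ``"fdr"``; default reports per-comparison
    (uncorrected) p-values, with the adjusted values added to ``extra`` when
    requested.
    """
    sub = table[table[at_factor] == at_level]
    if sub.empty:
        raise ValueError(f"no rows with {at_factor} == {at_level!r}")
    piv = sub.pivot_table(index=subject, columns=within, values=dv,
                          aggfunc="mean").dropna()
    levels = list(piv.columns)
    if len(levels) < 2:
        raise ValueError(f"factor {within!r} has fewer than 2 levels at "
                         f"{at_factor}={at_level!r}")
    results = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            li, lj = levels[i], levels[j]
            res = paired_t(piv[li].to_numpy(), piv[lj].to_numpy(),
                           names=(str(li), str(lj)))
            res.name = f"{within}: {li} vs {lj} | {at_factor}={at_level}"
            results.append(res)
    if adjust:
        ps = np.array([r.p for r in results])
        if adjust == "holm":
            order = np.argsort(ps)
            adj = np.empty_like(ps)
            prev = 0.0
            for rank, idx in enumerate(order):
                val = min(1.0, (len(ps) - rank) * ps[idx])
                prev = max(prev, val)
                adj[idx] = prev
        elif adjust == "fdr":
            order = np.argsort(ps)[::-1]
            adj = np.empty_like(ps)
            prev = 1.0
            for rank, idx in enumerate(order):
                val = min(1.0, ps[idx] * len(ps) / (len(ps) - rank))
                prev = min(prev, val)
                adj[idx] = prev
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for r, pa in zip(results, adj):
            r.extra[f"p_{adjust}"] = float(pa)
    return results


def band_metric_ttests(metrics: pd.DataFrame, dv_cols: list[str],
                       band_col: str = "band", cond_col: str = "music_type",
                       subject_col: str = "subject",
                       cond_pair: tuple[str, str] = ("nostalgic", "non-nostalgic"),
                       adjust: str | None = None) -> pd.DataFrame:
    """Paired t-tests of each network metric between two conditions per band.

    Mirrors the band-wise neural comparison: for every band and metric
    column, subjects' values under the two conditions are compared with a
    paired t-test. Uncorrected p-values by default (a multiplicity warning
    column flags the number of tests); optional Holm/FDR adjustment.
    """
    rows = []
    n_tests = metrics[band_col].nunique() * len(dv_cols)
    for band in sorted(metrics[band_col].unique()):
        sub = metrics[metrics[band_col] == band]
        piv_all = sub.pivot_table(index=subject_col, columns=cond_col,
                                  values=dv_cols, aggfunc="mean").dropna()
        for dv in dv_cols:
            x = piv_all[(dv, cond_pair[0])].to_numpy()
            y = piv_all[(dv, cond_pair[1])].to_numpy()
            res = paired_t(x, y, names=cond_pair)
            rows.append({
                "band": band, "metric": dv, "t": res.statistic,
                "df": res.df[0], "p": res.p, "cohen_dz": res.effect_size,
                f"mean_{cond_pair[0]}": res.means[cond_pair[0]],
                f"mean_{cond_pair[1]}": res.means[cond_pair[1]],
                f"sd_{cond_pair[0]}": res.sds[cond_pair[0]],
                f"sd_{cond_pair[1]}": res.sds[cond_pair[1]],
                "n_tests_family": n_tests,
            })
    out = pd.DataFrame(rows)
    if adjust == "fdr":
        from scipy.stats import false_discovery_control
        out["p_fdr"] = false_discovery_control(out["p"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
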