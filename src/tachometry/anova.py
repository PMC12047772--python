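"""Binned accuracy analysis: two-factor repeated-measures ANOVA and post-hocs.

The rPT axis is divided into 100-ms half-open bins [a, a+100) labeled by
their centers (50, 150, ...). Per participant and congruency condition the
mean accuracy is computed per bin, and only *complete* bins — those with a
value for every participant x congruency cell — are retained. On that
balanced table a two-factor within-subject ANOVA (congruency x bin) is
computed with Mauchly's sphericity test per multi-level effect,
Greenhouse-Geisser correction applied when sphericity is rejected, and
generalized eta-squared effect sizes. Post-hoc paired t tests use
Bonferroni adjustment and the paired Cohen's d = t / sqrt(n).

All sums of squares are computed from the balanced cell-mean array, so the
within-subject decomposition is exact (checked to 1e-10 in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .trials import CONGRUENCIES, TrialTable


@dataclass
class BinnedAccuracyTable:
    """Participant x congruency x bin mean accuracies (complete bins only)."""

    cells: pd.DataFrame  # MultiIndex columns (congruency, bin_center), index participant
    bin_width: int
    lo: int
    hi: int
    complete_bins: list[int]
    n_dropped_bins: int = 0

    @property
    def participants(self) -> list:
        return list(self.cells.index)

    def condition_matrix(self, congruency: str) -> pd.DataFrame:
        """Participant x bin matrix for one congruency condition."""
        return self.cells[congruency]

    def array(self) -> np.ndarray:
        """(n_participants, 2, n_bins) array ordered like CONGRUENCIES."""
        return np.stack(
            [self.cells[c].to_numpy(float) for c in CONGRUENCIES], axis=1
        )


@dataclass
class SphericityResult:
    W: float
    chi2: float
    df: int
    p: float


@dataclass
class EffectResult:
    """One ANOVA effect: F test, sphericity handling, effect size."""

    F: float
    df1: int
    df2: int
    p: float
    gg_epsilon: float
    p_gg: float
    eta2_g: float
    sphericity: SphericityResult | None = None
    p_reported: float = np.nan  # GG-corrected iff Mauchly rejects

    def __post_init__(self) -> None:
        if np.isnan(self.p_reported):
            use_gg = (
                self.sphericity is not None
                and self.df1 > 1
                and self.sphericity.p < 0.05
            )
            self.p_reported = self.p_gg if use_gg else self.p


@dataclass
class RmAnovaResult:
    congruency: EffectResult
    bin: EffectResult
    interaction: EffectResult
    ss: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("congruency", "bin", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append({
                "effect": name, "F": e.F, "df1": e.df1, "df2": e.df2,
                "p": e.p, "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg,
                "p_reported": e.p_reported, "eta2_g": e.eta2_g,
                "mauchly_W": e.sphericity.W if e.sphericity else np.nan,
                "mauchly_p": e.sphericity.p if e.sphericity else np.nan,
            })
        return pd.DataFrame(rows)


def bin_accuracy_100ms(
    table: TrialTable, lo: int = 0, hi: int = 1000, bin_width: int = 100
) -> BinnedAccuracyTable:
    """Mean accuracy per participant x congruency x 100-ms rPT bin.

    Bins are half-open ``[lo + k*w, lo + (k+1)*w)`` labeled by center
    ``lo + k*w + w//2``; trials outside ``[lo, hi)`` are ignored. Bins
    missing any participant x congruency value are dropped entirely.
    """
    if len(table) == 0:
        raise ValueError("cannot bin an empty trial table")
    df = table.data
    rpt = df["rpt_ms"].to_numpy("int64")
    inside = (rpt >= lo) & (rpt < hi)
    sub = df.loc[inside, ["participant_id", "congruency", "correct"]].copy()
    if len(sub) == 0:
        raise ValueError(f"no trials with rPT in [{lo}, {hi})")
    sub["bin_center"] = (rpt[inside] - lo) // bin_width * bin_width + lo + bin_width // 2
    wide = (
        sub.groupby(["participant_id", "congruency", "bin_center"], sort=True)
        ["correct"].mean().unstack(["congruency", "bin_center"])
    )
    all_bins = sorted({b for (_, b) in wide.columns})
    complete = [
        b for b in all_bins
        if all((c, b) in wide.columns and wide[(c, b)].notna().all()
               for c in CONGRUENCIES)
    ]
    if not complete:
        raise ValueError("no bin is complete for every participant and condition")
    cols = pd.MultiIndex.from_tuples(
        [(c, b) for c in CONGRUENCIES for b in complete],
        names=["congruency", "bin_center"],
    )
    cells = wide.reindex(columns=cols)
    return BinnedAccuracyTable(
        cells=cells, bin_width=bin_width, lo=lo, hi=hi,
        complete_bins=list(complete),
        n_dropped_bins=len(all_bins) - len(complete),
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) matrix with orthonormal columns orthogonal to the mean."""
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    u, s, _ = np.linalg.svd(h)
    return u[:, : k - 1]


def mauchly_test(data: np.ndarray | pd.DataFrame) -> SphericityResult:
    """Mauchly's sphericity test on a participant x level matrix.

    Uses the covariance of orthonormal within-factor contrasts with the
    chi-square approximation. For k = 2 levels sphericity holds trivially
    (W = 1, p = 1).
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 within-factor levels")
    if n <= k:
        raise ValueError("need more participants than levels")
    if k == 2:
        return SphericityResult(W=1.0, chi2=0.0, df=0, p=1.0)
    C = _orthonormal_contrasts(k)
    S = np.cov(x, rowvar=False, ddof=1)
    M = C.T @ S @ C
    eig = np.linalg.eigvalsh(M)
    if np.any(eig <= 0):
        raise ValueError("singular contrast covariance; Mauchly W undefined")
    W, chi2, df, p = _mauchly_from_eigs(eig, n, k)
    return SphericityResult(W=W, chi2=chi2, df=df, p=p)


def _mauchly_from_eigs(eig: np.ndarray, n: int, k: int):
    """W, chi-square, df and p from the contrast-covariance eigenvalues.

    Uses the chi-square approximation with the second-order correction term
    (as in R's ezANOVA), so p values match the R convention.
    """
    d = k - 1
    W = float(np.prod(eig) / (eig.mean() ** d))
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -f * (n - 1) * np.log(W)
    df = d * (d + 1) // 2 - 1
    if df <= 0:
        return W, float(chi2), df, 1.0
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return W, float(chi2), df, p


def gg_epsilon(data: np.ndarray | pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the levels.

    Bounded in [1/(k-1), 1]; equals 1 exactly for k = 2.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 within-factor levels")
    if k == 2:
        return 1.0
    C = _orthonormal_contrasts(k)
    S = np.cov(x, rowvar=False, ddof=1)
    M = C.T @ S @ C
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 == 0:
        raise ValueError("degenerate covariance")
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _effect_epsilon_mauchly(y_flat: np.ndarray, C: np.ndarray):
    """Epsilon and Mauchly's test for an effect given its contrast matrix."""
    n = y_flat.shape[0]
    m = C.shape[1]
    proj = y_flat @ C
    if m == 1:
        return 1.0, SphericityResult(W=1.0, chi2=0.0, df=0, p=1.0)
    S = np.cov(proj, rowvar=False, ddof=1)
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    eps = float(np.clip(tr**2 / (m * tr2), 1.0 / m, 1.0))
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0) or n - 1 <= m:
        sph = SphericityResult(W=np.nan, chi2=np.nan, df=m * (m + 1) // 2 - 1,
                               p=np.nan)
        return eps, sph
    W, chi2, df, p = _mauchly_from_eigs(eig, n, m + 1)
    return eps, SphericityResult(W=W, chi2=chi2, df=df, p=p)


def rm_anova_2way(bt: BinnedAccuracyTable) -> RmAnovaResult:
    """Two-factor (congruency x bin) within-subject ANOVA.

    Computes the classical balanced decomposition from the participant x
    condition x bin cell means, Greenhouse-Geisser epsilon per multi-level
    effect, Mauchly's test, and generalized eta-squared with all error
    strata (including subject variance) in the denominator.
    """
    y = bt.array()  # (n, a, b)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if b < 2:
        raise ValueError("need at least 2 complete bins")
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_s = a * b * np.sum((m_s - g) ** 2)
    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_tot = np.sum((y - g) ** 2)
    ss_abs = ss_tot - (ss_s + ss_a + ss_b + ss_as + ss_bs + ss_ab)

    err_all = ss_s + ss_as + ss_bs + ss_abs

    def make_effect(ss_eff, df1, ss_err, df2, y_matrix, C):
        F = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2))
        eps, sph = _effect_epsilon_mauchly(y_matrix, C)
        p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
        eta = ss_eff / (ss_eff + err_all)
        return EffectResult(F=float(F), df1=df1, df2=df2, p=p,
                            gg_epsilon=eps, p_gg=p_gg, eta2_g=float(eta),
                            sphericity=sph)

    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    y_flat = y.reshape(n, a * b)
    eff_a = make_effect(ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                        y_flat, np.kron(Ca, np.full((b, 1), 1 / np.sqrt(b))))
    eff_b = make_effect(ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                        y_flat, np.kron(np.full((a, 1), 1 / np.sqrt(a)), Cb))
    eff_ab = make_effect(ss_ab, (a - 1) * (b - 1), ss_abs,
                         (a - 1) * (b - 1) * (n - 1),
                         y_flat, np.kron(Ca, Cb))
    return RmAnovaResult(
        congruency=eff_a, bin=eff_b, interaction=eff_ab,
        ss={"subject": float(ss_s), "congruency": float(ss_a),
            "bin": float(ss_b), "congruency_x_subject": float(ss_as),
            "bin_x_subject": float(ss_bs), "interaction": float(ss_ab),
            "interaction_x_subject": float(ss_abs), "total": float(ss_tot)},
    )


def congruency_effect(bt: BinnedAccuracyTable) -> pd.DataFrame:
    """Per participant and bin: accuracy_congruent - accuracy_incongruent."""
    return bt.condition_matrix("congruent") - bt.condition_matrix("incongruent")


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, m * p). Rounding only at display."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def cohens_d_paired(t: float, n: int) -> float:
    """Paired-samples Cohen's d from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    return t / np.sqrt(n)


def _stars(p: float) -> str:
    if np.isnan(p):
        return "undefined"
    for thresh, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return s
    return "ns"


def posthoc_paired_t(
    data: pd.DataFrame, family_size: int | None = None
) -> pd.DataFrame:
    """All pairwise paired t tests over the columns of a subject x level table.

    Returns rows (level_a, level_b, t, df, p, p_adj, significance, d) with
    Bonferroni-adjusted p values (family size defaults to the number of
    pairs) and d = t / sqrt(n). A pair with a constant difference vector has
    no t statistic and is flagged ``undefined``.
    """
    data = pd.DataFrame(data)
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 participants")
    levels = list(data.columns)
    pairs = list(combinations(levels, 2))
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for la, lb in pairs:
        diff = data[la].to_numpy(float) - data[lb].to_numpy(float)
        if np.allclose(diff.std(ddof=1), 0):
            if np.allclose(diff, 0):
                t, p, d = 0.0, 1.0, 0.0
                sig = "ns"
            else:
                t = p = d = np.nan
                sig = "undefined"
        else:
            t, p = stats.ttest_rel(data[la], data[lb])
            d = cohens_d_paired(float(t), n)
        p_adj = bonferroni_adjust(float(p), m) if not np.isnan(p) else np.nan
        rows.append({
            "level_a": la, "level_b": lb, "t": float(t), "df": n - 1,
            "p": float(p), "p_adj": p_adj,
            "significance": _stars(p_adj) if not np.isnan(p) else "undefined",
            "d": float(d),
        })
    return pd.DataFrame(rows)


def format_posthoc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display formatting used by the CSV export: 2-decimal t, adj-p and d."""
    out = table.copy()
    for c in ("t", "p_adj", "d"):
        out[c] = out[c].round(2)
    out["p"] = out["p"].round(3)
    return out
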