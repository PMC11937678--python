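"""Inferential statistics for pre/post x verum/sham designs.

Implements, from first principles, the test family used on the study
endpoints: a 2 (group, between) x 2 (time or condition, within) mixed
repeated-measures ANOVA and its aligned-rank-transform variant, the
t-test family with Bonferroni correction and Cohen's d, Pearson
correlation, the default JZS (Cauchy-prior) Bayes factor for t-tests,
and mass-univariate time-frequency testing with cluster-level FDR
correction via a permutation null.

The mixed ANOVA exploits the two-level within structure: with subject
sums ``s_i = y_i1 + y_i2`` and differences ``d_i = y_i2 - y_i1`` the
split-plot decomposition separates exactly into a between-subject part
(a one-way ANOVA on subject means) and a within part (mean and group
contrast of the differences), each tested on (1, N-2) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import ndimage
from scipy import stats as sstats

EFFECTS = ("group", "within", "interaction")


# ---------------------------------------------------------------------------
# mixed 2x2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _pivot_mixed(data: pd.DataFrame, subject: str, group: str,
                 within: str, value: str):
    """Validate a long-format table and pivot to one row per subject."""
    for col in (subject, group, within, value):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    levels = sorted(data[within].unique())
    groups = sorted(data[group].unique())
    if len(levels) != 2 or len(groups) != 2:
        raise ValueError("mixed_anova_2x2 requires exactly 2 within levels "
                         "and 2 groups")
    wide = data.pivot_table(index=[subject, group], columns=within,
                            values=value, aggfunc="mean")
    if wide.isna().any().any() or len(wide) != data[subject].nunique():
        raise ValueError("every subject needs exactly one value per "
                         "within level (no imputation)")
    grp = wide.index.get_level_values(group).to_numpy()
    y = wide.to_numpy()                      # subjects x 2 within levels
    if min((grp == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 subjects per group")
    return y, grp, groups, levels


def mixed_anova_2x2(
    data: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    within: str = "within",
    value: str = "value",
) -> pd.DataFrame:
    """2x2 mixed (split-plot) ANOVA.

    Returns a table indexed by effect (``group``, ``within``,
    ``interaction``) with columns ``F``, ``df1``, ``df2``, ``p``,
    ``eta_sq`` (classical, SS_effect / SS_total) and ``eta_sq_partial``.
    All effects are tested on (1, N-2) degrees of freedom. Unequal group
    sizes are handled by the weighted (observation-level) decomposition.
    """
    y, grp, groups, _ = _pivot_mixed(data, subject, group, within, value)
    n_subj = y.shape[0]
    df2 = n_subj - 2

    m = y.mean(axis=1)                   # subject means (between part)
    d = y[:, 1] - y[:, 0]                # within differences
    grand = y.mean()

    in_g = [grp == g for g in groups]
    n_g = np.array([mask.sum() for mask in in_g])

    ss_group = 2.0 * np.sum(n_g * (np.array([m[mask].mean() for mask in in_g])
                                   - grand) ** 2)
    ss_err_between = 2.0 * sum(
        np.sum((m[mask] - m[mask].mean()) ** 2) for mask in in_g
    )

    d_bar = d.mean()
    d_bar_g = np.array([d[mask].mean() for mask in in_g])
    ss_within = n_subj * d_bar**2 / 2.0
    ss_inter = np.sum(n_g * (d_bar_g - d_bar) ** 2) / 2.0
    ss_err_within = sum(
        np.sum((d[mask] - d[mask].mean()) ** 2) for mask in in_g
    ) / 2.0

    ss_total = np.sum((y - grand) ** 2)

    rows = {}
    for effect, ss_eff, ss_err in (
        ("group", ss_group, ss_err_between),
        ("within", ss_within, ss_err_within),
        ("interaction", ss_inter, ss_err_within),
    ):
        ms_err = ss_err / df2
        f = ss_eff / ms_err if ms_err > 0 else 0.0
        p = float(sstats.f.sf(f, 1, df2)) if ms_err > 0 else 1.0
        rows[effect] = {
            "F": float(f),
            "df1": 1,
            "df2": df2,
            "p": p,
            "eta_sq": float(ss_eff / ss_total) if ss_total > 0 else 0.0,
            "eta_sq_partial": (
                float(ss_eff / (ss_eff + ss_err))
                if (ss_eff + ss_err) > 0
                else 0.0
            ),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "effect"
    return out


def art_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    within: str = "within",
    value: str = "value",
) -> pd.DataFrame:
    """Aligned-rank-transform variant of the 2x2 mixed ANOVA.

    For each effect the responses are aligned (cell-mean residual plus
    that effect's own cell-mean estimate), rank-transformed with
    mid-ranks for ties, and fed to the same parametric ANOVA; each
    effect's row comes from its own alignment.
    """
    df = data[[subject, group, within, value]].copy()
    cell = df.groupby([group, within])[value].transform("mean")
    resid = df[value] - cell
    cell_means = df.groupby([group, within])[value].mean()
    # unweighted estimates from cell means (standard ART alignment)
    grand = cell_means.mean()
    g_mean = cell_means.groupby(level=0).mean()
    w_mean = cell_means.groupby(level=1).mean()

    g_of = df[group].map(g_mean)
    w_of = df[within].map(w_mean)
    aligned = {
        "group": resid + (g_of - grand),
        "within": resid + (w_of - grand),
        "interaction": resid + (cell - g_of - w_of + grand),
    }
    rows = []
    for effect, values in aligned.items():
        ranked = df.copy()
        ranked[value] = sstats.rankdata(values.to_numpy())
        res = mixed_anova_2x2(ranked, subject, group, within, value)
        rows.append(res.loc[effect])
    out = pd.DataFrame(rows, index=list(aligned))
    out.index.name = "effect"
    return out


# ---------------------------------------------------------------------------
# t-test family
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float


def ttest(
    sample_a,
    sample_b=None,
    paired: bool = False,
    mu: float = 0.0,
) -> TTestResult:
    """One-sample, paired or two-sample (pooled-variance) t-test.

    Cohen's d conventions: two-sample uses the pooled SD; paired and
    one-sample use the SD of the (difference) scores (d_z for paired
    contrasts).
    """
    a = np.asarray(sample_a, dtype=float)
    if sample_b is None or paired:
        x = a - np.asarray(sample_b, dtype=float) if paired else a - mu
        if x.size < 2:
            raise ValueError("need n >= 2")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance")
        n = x.size
        t = x.mean() / (sd / np.sqrt(n))
        df = n - 1
        d = x.mean() / sd
    else:
        b = np.asarray(sample_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per sample")
        na, nb = a.size, b.size
        var_pooled = (
            (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
        ) / (na + nb - 2)
        if var_pooled == 0:
            raise ValueError("zero variance")
        t = (a.mean() - b.mean()) / np.sqrt(var_pooled * (1 / na + 1 / nb))
        df = na + nb - 2
        d = (a.mean() - b.mean()) / np.sqrt(var_pooled)
    p = 2.0 * float(sstats.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), p, float(d))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values: ``min(1, m * p)`` elementwise."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("zero variance")
    r = float(np.sum(xc * yc) / denom)
    df = x.size - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return r, 2.0 * float(sstats.t.sf(abs(t), df))


def jzs_bayes_factor_t(
    sample_a,
    sample_b=None,
    paired: bool = False,
    r_scale: float = 1.0 / np.sqrt(2.0),
) -> float:
    """Default JZS Bayes factor for a t-test, on the log scale.

    Uses the Jeffreys-Zellner-Siow prior (Cauchy on standardized effect
    size, scale ``r_scale``) and evaluates the marginal likelihood ratio
    by numerical integration over the prior's mixing parameter g.
    Positive values favor the alternative (logBF10 > 0).
    """
    res = ttest(sample_a, sample_b, paired=paired)
    t, nu = res.t, res.df
    if sample_b is None or paired:
        n_eff = np.asarray(sample_a).size
    else:
        na = np.asarray(sample_a).size
        nb = np.asarray(sample_b).size
        n_eff = na * nb / (na + nb)

    def integrand(g: float) -> float:
        w = 1.0 + n_eff * g * r_scale**2
        return (
            w**-0.5
            * (1.0 + t**2 / (w * nu)) ** (-(nu + 1.0) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * max(num, 1e-12):
        raise RuntimeError("JZS integral did not converge")
    den = (1.0 + t**2 / nu) ** (-(nu + 1.0) / 2.0)
    return float(np.log(num) - np.log(den))


# ---------------------------------------------------------------------------
# mass-univariate time-frequency testing with cluster-level FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float        # sum of |t| over the cluster
    sign: int
    p: float
    q: float = np.nan


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    threshold_p: float
    clusters: list[Cluster] = field(default_factory=list)
    significant_mask: np.ndarray | None = None


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return m / (sd / np.sqrt(n))


def _t_two_sample(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    var_pooled = (
        (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
    ) / (na + nb - 2)
    var_pooled[var_pooled == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
        var_pooled * (1 / na + 1 / nb)
    )


def _clusters_from_tmap(t_map: np.ndarray, t_crit: float) -> list[tuple]:
    """(mask, mass, sign) of 4-connected suprathreshold components."""
    out = []
    for sign in (1, -1):
        supra = (sign * t_map) > t_crit
        labels, n_lab = ndimage.label(supra)   # default structure = 4-conn
        for lab in range(1, n_lab + 1):
            mask = labels == lab
            out.append((mask, float(np.abs(t_map[mask]).sum()), sign))
    return out


def _max_cluster_mass(t_map: np.ndarray, t_crit: float) -> float:
    masses = [m for _, m, _ in _clusters_from_tmap(t_map, t_crit)]
    return max(masses, default=0.0)


def cluster_fdr_map(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None = None,
    threshold_p: float = 1e-4,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """Pixelwise t-map with cluster-level FDR correction.

    ``maps_a`` (and optionally ``maps_b``) are stacks of per-subject
    frequency x time maps. One-sample (vs zero) t-tests apply when
    ``maps_b`` is None, two-sample otherwise. Suprathreshold pixels
    (two-sided p < ``threshold_p``) are grouped into 4-connected
    clusters; the cluster statistic is the mass (sum of |t|); its null
    distribution comes from sign-flip (one-sample) or group-label
    permutations of the maximum cluster mass; cluster p-values are then
    Benjamini-Hochberg corrected and clusters with q <= ``alpha`` form
    the significant mask. No suprathreshold pixel simply yields an empty
    cluster set.
    """
    a = np.asarray(maps_a, dtype=float)
    if a.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_freq, n_time)")
    rng = np.random.default_rng(seed)

    if maps_b is None:
        if a.shape[0] < 2:
            raise ValueError("one-sample test needs >= 2 maps")
        df = a.shape[0] - 1
        t_map = _t_one_sample(a)
    else:
        b = np.asarray(maps_b, dtype=float)
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("two-sample test needs >= 2 maps per group")
        if a.shape[1:] != b.shape[1:]:
            raise ValueError("maps must share the frequency x time grid")
        df = a.shape[0] + b.shape[0] - 2
        t_map = _t_two_sample(a, b)

    t_crit = float(sstats.t.isf(threshold_p / 2.0, df))
    observed = _clusters_from_tmap(t_map, t_crit)
    result = ClusterTestResult(
        t_map=t_map, threshold_p=threshold_p,
        significant_mask=np.zeros(t_map.shape, dtype=bool),
    )
    if not observed:
        return result

    null_max = np.empty(n_permutations)
    if maps_b is None:
        for i in range(n_permutations):
            signs = rng.choice((-1.0, 1.0), size=a.shape[0])
            null_max[i] = _max_cluster_mass(
                _t_one_sample(signs[:, None, None] * a), t_crit
            )
    else:
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        for i in range(n_permutations):
            perm = rng.permutation(pooled.shape[0])
            null_max[i] = _max_cluster_mass(
                _t_two_sample(pooled[perm[:na]], pooled[perm[na:]]), t_crit
            )

    p_clusters = np.array([
        (1.0 + np.sum(null_max >= mass)) / (n_permutations + 1.0)
        for _, mass, _ in observed
    ])
    q_clusters = bh_fdr(p_clusters)
    for (mask, mass, sign), p, q in zip(observed, p_clusters, q_clusters):
        result.clusters.append(Cluster(mask=mask, mass=mass, sign=sign,
                                       p=float(p), q=float(q)))
        if q <= alpha:
            result.significant_mask |= mask
    return result
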