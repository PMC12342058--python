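"""Statistical toolkit: mixed RM-ANOVA, Holm–Šídák, Mann–Whitney U,
Shapiro–Wilk gate, t-tests and the power-based sample-size calculation.

The mixed (split-plot) ANOVA supports zero, one or two between-subject
factors crossed with one within-subject (repeated) factor. Unbalanced
between-cells are handled by the unweighted-means solution (cell means
weighted equally, scaled by the harmonic mean cell size), which reduces
to the classical partition for balanced designs. No sphericity
correction is applied (flagged in the output); all tests are two-sided
at alpha = 0.05 by default.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


def _factorial_effects(grid: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Equal-weight factorial effect arrays for every non-empty axis subset.

    effect(S) = sum over T subset of S of (-1)^|S-T| * (grid averaged over
    all axes not in T), the standard Möbius decomposition of a full
    factorial table of means.
    """
    ndim = grid.ndim
    axes = tuple(range(ndim))
    avg_cache: dict[tuple[int, ...], np.ndarray] = {}

    def avg_keep(keep: tuple[int, ...]) -> np.ndarray:
        if keep not in avg_cache:
            drop = tuple(a for a in axes if a not in keep)
            avg_cache[keep] = grid.mean(axis=drop, keepdims=True) if drop else grid
        return avg_cache[keep]

    effects = {}
    for r in range(1, ndim + 1):
        for S in combinations(axes, r):
            acc = np.zeros([grid.shape[a] if a in S else 1 for a in axes])
            for k in range(len(S) + 1):
                for T in combinations(S, k):
                    sign = (-1) ** (len(S) - len(T))
                    acc = acc + sign * avg_keep(T)
            effects[S] = acc
    return effects


def mixed_anova(data: pd.DataFrame, dv: str = "value",
                subject: str = "subject_id", within: str = "time_bin",
                between: tuple[str, ...] | list[str] | str = ()) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA (unweighted means, no sphericity
    correction).

    Parameters
    ----------
    data : long-format DataFrame
        One row per (subject, within level); between-factor columns are
        constant within subject.
    between : between-subject factor column names (0, 1 or 2 of them).

    Returns
    -------
    DataFrame with one row per effect: ``effect``, ``SS``, ``df_num``,
    ``df_den``, ``MS``, ``F``, ``p``, ``stratum``. The attribute
    ``attrs['sphericity_correction']`` is ``'none'``.
    """
    if isinstance(between, str):
        between = (between,)
    between = tuple(between)
    if len(between) > 2:
        raise ValueError("at most two between-subject factors are supported")

    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete within-subject series for {missing}")
    times = list(wide.columns)
    T = len(times)
    if T < 2:
        raise ValueError("need at least 2 within-factor levels")

    meta = data.drop_duplicates(subject).set_index(subject)
    for b in between:
        per_subject = data.groupby(subject)[b].nunique()
        if (per_subject > 1).any():
            raise ValueError(f"between factor {b!r} varies within a subject")
    levels = [sorted(meta[b].unique()) for b in between]
    shape_b = [len(lv) for lv in levels]

    # map subjects to between-cells
    subj_cell = {}
    for sid in wide.index:
        subj_cell[sid] = tuple(levels[i].index(meta.loc[sid, between[i]])
                               for i in range(len(between)))
    cells = {}
    for sid, c in subj_cell.items():
        cells.setdefault(c, []).append(sid)
    expected = int(np.prod(shape_b)) if between else 1
    if len(cells) != expected:
        raise ValueError("empty between-factor cells")
    n_g = {c: len(sids) for c, sids in cells.items()}
    if any(n < 2 for n in n_g.values()):
        raise ValueError("every between-cell needs at least 2 subjects")
    G = len(cells)
    N = len(wide)
    n_h = G / sum(1.0 / n for n in n_g.values())

    # cell x time mean grid, axes = (*between, time)
    grid = np.zeros(shape_b + [T])
    for c, sids in cells.items():
        grid[c + (slice(None),)] = wide.loc[sids].to_numpy().mean(axis=0)

    effects = _factorial_effects(grid)
    time_axis = len(between)

    # error strata
    ss_err_between = 0.0
    ss_err_within = 0.0
    for c, sids in cells.items():
        rows = wide.loc[sids].to_numpy()
        m_subj = rows.mean(axis=1)
        cell_profile = grid[c + (slice(None),)]
        cell_mean = cell_profile.mean()
        ss_err_between += T * float(np.sum((m_subj - m_subj.mean()) ** 2))
        ss_err_within += float(np.sum(
            (rows - m_subj[:, None] - cell_profile[None, :] + cell_mean) ** 2))
    df_err_between = N - G
    df_err_within = (N - G) * (T - 1)
    ms_err_between = ss_err_between / df_err_between if df_err_between else np.nan
    ms_err_within = ss_err_within / df_err_within if df_err_within else np.nan

    def effect_name(S):
        parts = [between[a] if a < time_axis else within for a in S]
        return " * ".join(parts)

    rows = []
    full_shape = shape_b + [T]
    for S, eff in effects.items():
        ss = n_h * float(np.prod([full_shape[a] for a in range(len(full_shape))
                                  if a not in S])) * float(np.sum(eff ** 2))
        df_num = int(np.prod([full_shape[a] - 1 for a in S]))
        is_within = time_axis in S
        ms_err = ms_err_within if is_within else ms_err_between
        df_den = df_err_within if is_within else df_err_between
        ms = ss / df_num
        if ms_err and np.isfinite(ms_err) and ms_err > 0:
            F = ms / ms_err
            p = float(sps.f.sf(F, df_num, df_den))
        else:
            F = 0.0 if ss <= 1e-12 else np.inf
            p = 1.0 if F == 0.0 else 0.0
        rows.append({"effect": effect_name(S), "SS": ss, "df_num": df_num,
                     "df_den": df_den, "MS": ms, "F": F, "p": p,
                     "stratum": "within" if is_within else "between"})
    rows.append({"effect": "error (subjects)", "SS": ss_err_between,
                 "df_num": df_err_between, "df_den": np.nan,
                 "MS": ms_err_between, "F": np.nan, "p": np.nan,
                 "stratum": "between"})
    rows.append({"effect": f"error ({within} * subjects)", "SS": ss_err_within,
                 "df_num": df_err_within, "df_den": np.nan,
                 "MS": ms_err_within, "F": np.nan, "p": np.nan,
                 "stratum": "within"})
    out = pd.DataFrame(rows)
    out.attrs["sphericity_correction"] = "none"
    out.attrs["solution"] = "unweighted-means"
    out.attrs["harmonic_cell_n"] = n_h
    return out


# ---------------------------------------------------------------------------
# multiple comparisons


def holm_sidak(pvals, alpha: float = 0.05) -> pd.DataFrame:
    """Holm–Šídák step-down procedure at family-wise error rate ``alpha``.

    The i-th smallest of k p-values is compared against
    ``1 - (1 - alpha)**(1/(k - i + 1))``; rejection stops at the first
    failure. Decisions are returned in input order with the per-step
    adjusted alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    thresholds = 1.0 - (1.0 - alpha) ** (1.0 / (k - np.arange(k)))
    reject_sorted = np.zeros(k, dtype=bool)
    for i in range(k):
        if p[order[i]] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(k, dtype=bool)
    reject[order] = reject_sorted
    adj_alpha = np.empty(k)
    adj_alpha[order] = thresholds
    return pd.DataFrame({"p": p, "adjusted_alpha": adj_alpha, "reject": reject})


# ---------------------------------------------------------------------------
# Mann–Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U_x with midrank tie handling: #(x > y) + 0.5 #(x == y)."""
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_x = float(np.sum(ranks[:nx]))
    return r_x - nx * (nx + 1) / 2.0


def mann_whitney_u(x, y, exact_max_n: int = 8) -> dict:
    """Two-sided Mann–Whitney U test.

    The p-value is exact (full enumeration of group assignments) when the
    combined sample size is at most ``exact_max_n``, otherwise a normal
    approximation with tie correction and continuity correction is used;
    the method applied is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)
    mu = nx * ny / 2.0
    if nx + ny <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(nx + ny)
        obs_dev = abs(u - mu)
        count = 0
        total = 0
        for comb in combinations(idx, nx):
            sel = np.zeros(nx + ny, dtype=bool)
            sel[list(comb)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        n = nx + ny
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
        method = "normal"
    return {"U": u, "p": p, "method": method, "n_x": nx, "n_y": ny}


# ---------------------------------------------------------------------------
# power / sample size


def sample_size(sd: float, diff: float, alpha: float = 0.05,
                power: float = 0.8, method: str = "normal") -> int:
    """Per-group n for a two-sample, two-sided comparison of means.

    ``method='normal'`` uses the normal-approximation formula
    n = ceil((z_{1-alpha/2} + z_{1-beta})^2 * 2 sd^2 / diff^2) with a
    floor of 2. ``method='exact-t'`` iterates the noncentral-t power
    function instead, which is slightly more conservative (it returns 7
    rather than 6 for sd = 14.6, diff = 25).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if diff == 0:
        raise ValueError("diff must be nonzero")
    if method == "normal":
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        n = int(np.ceil(z**2 * 2 * sd**2 / diff**2))
        return max(n, 2)
    if method == "exact-t":
        for n in range(2, 10_000):
            df = 2 * (n - 1)
            nc = abs(diff) / (sd * np.sqrt(2.0 / n))
            crit = sps.t.ppf(1 - alpha / 2, df)
            achieved = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
            if achieved >= power:
                return n
        raise RuntimeError("no n found below 10000")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# normality gate and t-tests


def shapiro_wilk_gate(values, alpha: float = 0.05) -> dict:
    """Shapiro–Wilk normality check; ``normal`` is True when p > alpha.

    A constant sample cannot be tested and gates False with NaN p.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(v) == 0:
        return {"normal": False, "p": float("nan")}
    res = sps.shapiro(v)
    return {"normal": bool(res.pvalue > alpha), "p": float(res.pvalue)}


def paired_t(x, y) -> dict:
    """Two-sided paired Student's t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] != 0:
            raise ValueError("constant nonzero differences: t undefined")
        return {"t": 0.0, "df": len(d) - 1, "p": 1.0}
    res = sps.ttest_rel(x, y)
    return {"t": float(res.statistic), "df": int(len(d) - 1),
            "p": float(res.pvalue)}


def two_sample_t(x, y, equal_var: bool = True) -> dict:
    """Two-sided two-sample Student's t-test (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return {"t": 0.0, "df": len(x) + len(y) - 2, "p": 1.0}
        raise ValueError("zero variance in both samples: t undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = len(x) + len(y) - 2 if equal_var else float(res.df)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}
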