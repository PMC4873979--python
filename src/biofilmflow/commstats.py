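"""Statistics on subpopulation tables: group comparisons and redundancy analysis.

Redundancy analysis (RDA) is a constrained ordination: the Hellinger-
transformed subpopulation table is regressed on (log-transformed, except
pH) physico-chemical variables and the fitted values are eigen-decomposed;
the constrained eigenvalue share is the fraction of community variance the
environment explains. Model selection combines forward, backward and
marginal permutation-based selection (a variable must be chosen by at
least two procedures) followed by variance-inflation-factor screening.
Significance is assessed by free row permutation of the response.

Group differences in subpopulation fractions are tested per subpopulation
with one-way ANOVA followed by Tukey HSD, Holm-corrected across each
subpopulation's pairwise family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hellinger_transform", "env_transform", "rda_fit", "select_model",
    "permutation_tests", "vector_fit", "anova_tukey_holm", "holm_adjust",
    "variance_inflation_factors", "RDAResult",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def hellinger_transform(table) -> pd.DataFrame:
    """Row-wise Hellinger transform: ``sqrt(value / row sum)``.

    Rows of the result have unit sum of squares, making the community table
    suitable for Euclidean-based ordination; counts and fractions give
    identical output. Accepts a DataFrame or anything with a ``counts``
    DataFrame attribute.
    """
    df = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("table must be nonnegative")
    row_sums = values.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(f"all-zero row(s): {list(df.index[zero])}")
    out = np.sqrt(values / row_sums[:, None])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def env_transform(env: pd.DataFrame, ph_columns: Sequence[str] = ("pH",)
                  ) -> pd.DataFrame:
    """Natural log of every environmental variable except pH (pass-through).

    pH is already a log-scale quantity. Constrained-ordination results are
    invariant to the log base (an affine per-column rescaling).
    """
    out = env.copy().astype(float)
    for col in out.columns:
        if col in ph_columns:
            continue
        if (out[col] <= 0).any():
            raise ValueError(f"variable {col!r} has nonpositive values; "
                             "cannot log-transform")
        out[col] = np.log(out[col])
    return out


# ---------------------------------------------------------------------------
# RDA core
# ---------------------------------------------------------------------------

def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _orthobasis(X: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space of (centered) X."""
    if X.size == 0 or X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > rtol * s[0]).sum()) if s.size and s[0] > 0 else 0
    return u[:, :rank]


@dataclass
class RDAResult:
    """Constrained-ordination result."""

    eigenvalues: np.ndarray            # constrained axes
    unconstrained_eigenvalues: np.ndarray
    proportion_constrained: float
    site_scores: pd.DataFrame          # n x n_axes, axes RDA1, RDA2, ...
    response_scores: pd.DataFrame      # subpopulations x n_axes
    biplot_scores: pd.DataFrame        # constraints x n_axes (correlations)
    variables: list
    p_model: float | None = None
    p_axes: np.ndarray | None = None
    p_terms: pd.Series | None = None

    @property
    def proportions(self) -> np.ndarray:
        total = self.eigenvalues.sum() + self.unconstrained_eigenvalues.sum()
        return self.eigenvalues / total


def rda_fit(Y, X) -> RDAResult:
    """Redundancy analysis of response table Y constrained by X.

    Y and X are centered; each response column is regressed on X, the
    fitted values are eigen-decomposed into constrained axes and the
    residuals into unconstrained axes. ``proportion_constrained`` is the
    constrained eigenvalue sum over total variance.
    """
    Ydf = pd.DataFrame(Y)
    Xdf = pd.DataFrame(X)
    if Ydf.shape[0] != Xdf.shape[0]:
        raise ValueError("Y and X must have aligned rows")
    n, q = Xdf.shape
    if n <= q + 1:
        raise ValueError(f"need n_sites > n_constraints + 1 (n={n}, q={q})")
    Yc = _center(Ydf.to_numpy(float))
    Xc = _center(Xdf.to_numpy(float))
    if np.linalg.matrix_rank(Xc) < q:
        raise ValueError("constraint matrix is rank deficient; screen "
                         "collinear variables (VIF) before fitting")
    Q = _orthobasis(Xc)
    Yhat = Q @ (Q.T @ Yc)
    resid = Yc - Yhat

    denom = n - 1
    u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / denom
    keep = eig > 1e-12 * max(eig.max(), 1e-300)
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep]
    ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
    eig_res = sr**2 / denom
    eig_res = eig_res[eig_res > 1e-12 * max(eig_res.max(), 1e-300)] \
        if eig_res.size else eig_res

    total = (Yc**2).sum() / denom
    prop = float(eig.sum() / total) if total > 0 else 0.0

    axes = [f"RDA{i + 1}" for i in range(eig.size)]
    site_scores = pd.DataFrame(u * s, index=Ydf.index, columns=axes)
    response_scores = pd.DataFrame(vt.T, index=Ydf.columns, columns=axes)
    # biplot arrows: correlation of each constraint with the site scores
    bip = np.zeros((q, eig.size))
    ss = site_scores.to_numpy()
    for j in range(q):
        xj = Xc[:, j]
        for a in range(eig.size):
            sd = xj.std() * ss[:, a].std()
            bip[j, a] = float(np.dot(xj - xj.mean(), ss[:, a] - ss[:, a].mean())
                              / (n * sd)) if sd > 0 else 0.0
    biplot_scores = pd.DataFrame(bip, index=Xdf.columns, columns=axes)
    return RDAResult(eig, eig_res, prop, site_scores, response_scores,
                     biplot_scores, list(Xdf.columns))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _ss(Q: np.ndarray, Yc: np.ndarray) -> float:
    """Sum of squares of Yc explained by the orthonormal basis Q."""
    if Q.shape[1] == 0:
        return 0.0
    return float(((Q.T @ Yc)**2).sum())


def _partial_permutation_p(Yc: np.ndarray, Q_base: np.ndarray,
                           Q_add: np.ndarray, n_perm: int,
                           rng: np.random.Generator) -> tuple[float, float]:
    """Permutation p for the added constraint subspace given a base subspace.

    Statistic: partial pseudo-F for the added axes; the rows of the
    (centered) response are freely permuted.
    """
    n = Yc.shape[0]
    df_add = Q_add.shape[1]
    df_base = Q_base.shape[1]
    df_res = n - 1 - df_base - df_add
    if df_add == 0 or df_res <= 0:
        return 0.0, 1.0

    def pseudo_f(Y):
        total = (Y**2).sum()
        ss_base = _ss(Q_base, Y)
        ss_add = _ss(Q_add, Y)
        ss_res = max(total - ss_base - ss_add, 1e-300)
        return (ss_add / df_add) / (ss_res / df_res)

    f_obs = pseudo_f(Yc)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Yc[perm]) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (n_perm + 1)


def permutation_tests(rda: RDAResult, Y, X, n_perm: int = 999,
                      seed: int = 0) -> RDAResult:
    """Permutation p-values for the whole model, each axis and each term.

    p = (1 + #{permuted statistic >= observed}) / (n_perm + 1); the minimum
    attainable p with 999 permutations is therefore 1/1000. Axis tests
    compare each constrained eigenvalue against its null distribution under
    whole-row permutation; term tests are marginal (each variable given all
    others).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Ydf, Xdf = pd.DataFrame(Y), pd.DataFrame(X)
    Yc = _center(Ydf.to_numpy(float))
    Xc = _center(Xdf.to_numpy(float))
    n, q = Xc.shape
    rng = np.random.default_rng(seed)
    Q = _orthobasis(Xc)

    # whole model
    _, p_model = _partial_permutation_p(Yc, np.empty((n, 0)), Q, n_perm, rng)

    # axes: null distribution of each eigenvalue under row permutation
    k = rda.eigenvalues.size
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_perm):
        Yp = Yc[rng.permutation(n)]
        s = np.linalg.svd(Q @ (Q.T @ Yp), compute_uv=False)
        eig_p = np.zeros(k)
        eig_p[:min(k, s.size)] = (s[:k]**2) / (n - 1)
        exceed += eig_p >= rda.eigenvalues - 1e-15
    p_axes = (1 + exceed) / (n_perm + 1)

    # marginal term tests
    p_terms = {}
    for j, name in enumerate(Xdf.columns):
        others = np.delete(Xc, j, axis=1)
        Q_base = _orthobasis(others)
        zj = Xc[:, [j]] - Q_base @ (Q_base.T @ Xc[:, [j]])
        Q_add = _orthobasis(zj)
        _, p = _partial_permutation_p(Yc, Q_base, Q_add, n_perm, rng)
        p_terms[name] = p

    rda.p_model = p_model
    rda.p_axes = p_axes
    rda.p_terms = pd.Series(p_terms)
    return rda


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def variance_inflation_factors(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2) of regressing variable j on the others."""
    Xc = _center(pd.DataFrame(X).to_numpy(float))
    out = {}
    for j, name in enumerate(pd.DataFrame(X).columns):
        others = np.delete(Xc, j, axis=1)
        xj = Xc[:, j]
        tot = (xj**2).sum()
        if tot == 0:
            out[name] = np.inf
            continue
        Qo = _orthobasis(others)
        res = xj - Qo @ (Qo.T @ xj)
        r2 = 1 - (res**2).sum() / tot
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _forward_select(Yc, Xdf, alpha, n_perm, rng) -> list:
    selected: list = []
    candidates = list(Xdf.columns)
    Xc = _center(Xdf.to_numpy(float))
    col = {name: Xc[:, [i]] for i, name in enumerate(Xdf.columns)}
    while candidates:
        Q_base = _orthobasis(np.hstack([col[s] for s in selected])
                             if selected else np.empty((Yc.shape[0], 0)))
        best, best_f = None, -np.inf
        for name in candidates:
            z = col[name] - Q_base @ (Q_base.T @ col[name])
            Q_add = _orthobasis(z)
            if Q_add.shape[1] == 0:
                continue
            df_res = Yc.shape[0] - 1 - Q_base.shape[1] - 1
            if df_res <= 0:
                continue
            ss_add = _ss(Q_add, Yc)
            ss_res = (Yc**2).sum() - _ss(Q_base, Yc) - ss_add
            f = ss_add / max(ss_res / df_res, 1e-300)
            if f > best_f:
                best, best_f = name, f
        if best is None:
            break
        z = col[best] - Q_base @ (Q_base.T @ col[best])
        _, p = _partial_permutation_p(Yc, Q_base, _orthobasis(z), n_perm, rng)
        if p <= alpha:
            selected.append(best)
            candidates.remove(best)
        else:
            break
    return selected


def _backward_select(Yc, Xdf, alpha, n_perm, rng) -> list:
    remaining = list(Xdf.columns)
    Xc = _center(Xdf.to_numpy(float))
    col = {name: Xc[:, [i]] for i, name in enumerate(Xdf.columns)}
    while len(remaining) > 0:
        worst, worst_p = None, -1.0
        for name in remaining:
            others = [col[s] for s in remaining if s != name]
            Q_base = _orthobasis(np.hstack(others)
                                 if others else np.empty((Yc.shape[0], 0)))
            z = col[name] - Q_base @ (Q_base.T @ col[name])
            _, p = _partial_permutation_p(Yc, Q_base, _orthobasis(z), n_perm, rng)
            if p > worst_p:
                worst, worst_p = name, p
        if worst_p > alpha:
            remaining.remove(worst)
        else:
            break
    return remaining


def _marginal_select(Yc, Xdf, alpha, n_perm, rng) -> list:
    """Single-term screening: each variable alone against the response."""
    Xc = _center(Xdf.to_numpy(float))
    out = []
    empty = np.empty((Yc.shape[0], 0))
    for i, name in enumerate(Xdf.columns):
        Q_add = _orthobasis(Xc[:, [i]])
        _, p = _partial_permutation_p(Yc, empty, Q_add, n_perm, rng)
        if p <= alpha:
            out.append(name)
    return out


def select_model(Y, X_candidates: pd.DataFrame, alpha: float = 0.05,
                 n_perm: int = 199, vif_cutoff: float = 10.0,
                 seed: int = 0) -> tuple[list, pd.DataFrame]:
    """Three-way constrained-model selection with a two-vote rule.

    Forward, backward and marginal permutation selection (inclusion at
    permutation p <= ``alpha``, ``n_perm`` permutations per step) are run
    independently; variables chosen by at least two procedures are kept,
    then the highest-VIF variable is dropped iteratively while any VIF
    exceeds ``vif_cutoff``. Returns the final variable list and an audit
    table of the per-procedure votes.
    """
    Xdf = pd.DataFrame(X_candidates)
    if Xdf.shape[1] < 2:
        raise ValueError("need at least two candidate variables")
    Yc = _center(pd.DataFrame(Y).to_numpy(float))
    rng = np.random.default_rng(seed)
    votes = {
        "forward": _forward_select(Yc, Xdf, alpha, n_perm, rng),
        "backward": _backward_select(Yc, Xdf, alpha, n_perm, rng),
        "marginal": _marginal_select(Yc, Xdf, alpha, n_perm, rng),
    }
    audit = pd.DataFrame(
        {proc: [v in chosen for v in Xdf.columns]
         for proc, chosen in votes.items()},
        index=Xdf.columns)
    audit["votes"] = audit.sum(axis=1)
    selected = [v for v in Xdf.columns if audit.loc[v, "votes"] >= 2]
    # VIF screening of the surviving set
    while len(selected) >= 2:
        vif = variance_inflation_factors(Xdf[selected])
        if (vif <= vif_cutoff).all():
            break
        selected.remove(vif.idxmax())
    if not selected:
        warnings.warn("model selection returned an empty variable set")
    audit["selected"] = [v in selected for v in Xdf.columns]
    return selected, audit


# ---------------------------------------------------------------------------
# Vector fitting
# ---------------------------------------------------------------------------

def vector_fit(site_scores, env: pd.DataFrame, n_perm: int = 999,
               seed: int = 0) -> pd.DataFrame:
    """Fit raw environmental vectors onto the first two ordination axes.

    For each variable the least-squares direction in the 2-D score plane
    maximizing the correlation with the variable is found; reported are the
    unit direction, the r-squared of the projection and a permutation p
    (variable values permuted across sites). Raw (untransformed) values are
    the conventional input.
    """
    scores = np.asarray(pd.DataFrame(site_scores).iloc[:, :2], float)
    Sc = _center(scores)
    rng = np.random.default_rng(seed)
    Qs = _orthobasis(Sc)
    rows = []
    for name in env.columns:
        v = env[name].to_numpy(float)
        vc = v - v.mean()
        tot = (vc**2).sum()
        if tot == 0:
            warnings.warn(f"variable {name!r} is constant; r2 set to 0")
            rows.append({"variable": name, "dx": 0.0, "dy": 0.0,
                         "r2": 0.0, "p": 1.0})
            continue
        b, *_ = np.linalg.lstsq(Sc, vc, rcond=None)
        fitted = Sc @ b
        r2 = float((fitted**2).sum() / tot)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        count = 0
        for _ in range(n_perm):
            vp = vc[rng.permutation(vc.size)]
            r2p = ((Qs.T @ vp)**2).sum() / tot
            if r2p >= r2 - 1e-15:
                count += 1
        rows.append({"variable": name, "dx": float(direction[0]),
                     "dy": float(direction[1]), "r2": r2,
                     "p": (1 + count) / (n_perm + 1)})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# ANOVA + Tukey + Holm
# ---------------------------------------------------------------------------

def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment: ``p_(i) -> max cummax((m - i + 1) p_(i))``."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, ix in enumerate(order):
        running = max(running, (m - rank) * p[ix])
        adj[ix] = min(running, 1.0)
    return adj


def anova_tukey_holm(table, grouping: Sequence) -> dict[str, pd.DataFrame]:
    """Per-subpopulation one-way ANOVA with Tukey HSD and Holm correction.

    ``table`` is a samples x subpopulations fraction table (or an object
    with a ``fractions`` attribute); ``grouping`` assigns each sample row
    to a group. Returns ``{"anova": ..., "pairwise": ...}``: the ANOVA
    table (F, p per subpopulation) and the pairwise table with Tukey p and
    Holm-adjusted p within each subpopulation's family.
    """
    df = table.fractions if hasattr(table, "fractions") else pd.DataFrame(table)
    groups = np.asarray(grouping, dtype=object)
    if groups.shape[0] != df.shape[0]:
        raise ValueError("grouping length != number of samples")
    levels = pd.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    anova_rows, pair_frames = [], []
    for sub in df.columns:
        y = df[sub].to_numpy(float)
        blocks = [y[groups == g] for g in levels]
        grand = y.mean()
        ssb = sum(len(b) * (b.mean() - grand)**2 for b in blocks)
        ssw = sum(((b - b.mean())**2).sum() for b in blocks)
        df_b, df_w = levels.size - 1, y.size - levels.size
        if ssb <= 1e-300:           # identical group means (incl. all-equal data)
            f_stat, p = 0.0, 1.0
        elif ssw <= 1e-300:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (ssb / df_b) / (ssw / df_w)
            p = float(stats.f.sf(f_stat, df_b, df_w))
        anova_rows.append({"subpopulation": sub, "F": f_stat, "p": p})

        pairs = list(combinations(levels, 2))
        if ssw <= 1e-300 and ssb <= 1e-300:
            raw = np.ones(len(pairs))
        else:
            res = pairwise_tukeyhsd(y, groups)
            uniq = [str(u) for u in res.groupsunique]
            raw = np.empty(len(pairs))
            for i, (a, b) in enumerate(pairs):
                ia, ib = uniq.index(str(a)), uniq.index(str(b))
                raw[i] = res.pvalues[_pair_index(ia, ib, len(uniq))]
        adj = holm_adjust(raw)
        pair_frames.append(pd.DataFrame({
            "subpopulation": sub,
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_tukey": raw,
            "p_holm": adj,
        }))
    return {"anova": pd.DataFrame(anova_rows).set_index("subpopulation"),
            "pairwise": pd.concat(pair_frames, ignore_index=True)}


def _pair_index(i: int, j: int, k: int) -> int:
    """Index of pair (i, j), i < j, in itertools.combinations(range(k), 2)."""
    i, j = min(i, j), max(i, j)
    return i * (2 * k - i - 1) // 2 + (j - i - 1)
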