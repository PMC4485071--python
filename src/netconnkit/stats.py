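"""Group-level inference on network measures.

Parametric tests (one/two-sample t, paired t, one-way and repeated-measures
ANOVA) on global or nodal measures with optional covariate adjustment,
multiple-comparison control (Benjamini-Hochberg FDR, Bonferroni), the
network-based statistic (NBS) for edge-wise inference with component-level
permutation control, and network-behavior (partial) correlation.

All p-values are two-sided. Covariates of no interest are residualized out
against [1 | covariates] before group tests; the one-sample test with
covariates instead tests the intercept of an OLS fit (residualizing would
zero the tested mean by construction). Permutation p-values use the
(1 + exceedances) / (1 + n_perm) convention and are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidDesignError

__all__ = [
    "GroupDesign",
    "StatResult",
    "EdgeComponentResult",
    "glm_metric_test",
    "fdr_correct",
    "bonferroni_correct",
    "nbs",
    "behavior_correlation",
]


@dataclass(frozen=True)
class GroupDesign:
    """Subject-level design: group labels, optional pairing, covariates, behavior."""

    subject_ids: tuple[str, ...]
    groups: np.ndarray | None = None
    pair_ids: np.ndarray | None = None  # pairing/subject factor for paired & RM designs
    covariates: np.ndarray | None = None
    behavior: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("groups", "pair_ids", "covariates", "behavior"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            if arr.shape[0] != n:
                raise InvalidDesignError(f"{name} has {arr.shape[0]} rows for {n} subjects")
            object.__setattr__(self, name, arr)
        if self.covariates is not None and not np.all(np.isfinite(self.covariates.astype(float))):
            raise InvalidDesignError("covariates must be numeric and finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroupDesign":
        """Build from a tidy table with columns id, [group], [pair], [behavior],
        treating every remaining numeric column as a covariate."""
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols:
            raise InvalidDesignError("design table needs an 'id' column")
        used = {cols["id"]}
        groups = pair = behavior = None
        if "group" in cols:
            groups = df[cols["group"]].to_numpy()
            used.add(cols["group"])
        if "pair" in cols:
            pair = df[cols["pair"]].to_numpy()
            used.add(cols["pair"])
        if "behavior" in cols:
            behavior = df[cols["behavior"]].to_numpy(dtype=float)
            used.add(cols["behavior"])
        rest = [c for c in df.columns if c not in used]
        cov = df[rest].to_numpy(dtype=float) if rest else None
        return cls(
            tuple(str(v) for v in df[cols["id"]]),
            groups=groups,
            pair_ids=pair,
            covariates=cov,
            behavior=behavior,
        )


@dataclass(frozen=True)
class StatResult:
    """Test output: statistic(s), degrees of freedom, p-value(s), method tag."""

    statistic: np.ndarray
    df: tuple[float, ...]
    p: np.ndarray
    method: str
    p_corrected: np.ndarray | None = None
    reject: np.ndarray | None = None


@dataclass(frozen=True)
class EdgeComponentResult:
    """NBS output: suprathreshold components and their permutation p-values."""

    edge_stats: np.ndarray  # N x N statistic matrix
    suprathreshold: np.ndarray  # N x N boolean mask
    components: tuple[tuple[tuple[int, int], ...], ...]  # edge sets, (i, j) i<j
    component_sizes: tuple[int, ...]  # edge counts (extent)
    component_values: tuple[float, ...]  # extent or intensity, per component_stat
    component_p: tuple[float, ...]
    null_max_sizes: np.ndarray  # null distribution of the max component value
    n_perm: int
    seed: int
    component_stat: str = "extent"


def _residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return values
    # constant covariate columns duplicate the intercept: drop them so a
    # constant covariate behaves exactly like no covariate at all
    keep = covariates.std(axis=0) > 1e-12 * (np.abs(covariates.mean(axis=0)) + 1.0)
    covariates = covariates[:, keep]
    if covariates.shape[1] == 0:
        return values
    X = np.column_stack([np.ones(values.shape[0]), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidDesignError("singular covariate design")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def glm_metric_test(
    values: np.ndarray,
    design: GroupDesign,
    model: str,
    popmean: float = 0.0,
) -> StatResult:
    """Parametric test on each measure column of a subjects x measures array.

    Models: one_sample (mean vs ``popmean``), two_sample, paired (two
    conditions matched by ``pair_ids``), anova1 (one-way across G groups),
    rm_anova (two-level additive condition x subject model, F on condition).
    Covariates present in the design are residualized out first, except for
    one_sample (see module docstring).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and design.n_subjects != 1:
        values = values.T
    if values.shape[0] != design.n_subjects:
        raise InvalidDesignError(
            f"{values.shape[0]} value rows for {design.n_subjects} subjects"
        )
    n, m = values.shape

    if model == "one_sample":
        if design.covariates is not None:
            X = np.column_stack([np.ones(n), design.covariates])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise InvalidDesignError("singular covariate design")
            beta, *_ = np.linalg.lstsq(X, values - popmean, rcond=None)
            resid = (values - popmean) - X @ beta
            dof = n - X.shape[1]
            mse = (resid**2).sum(axis=0) / dof
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(mse * xtx_inv[0, 0])
            _check_variance(se)
            t = beta[0] / se
        else:
            dof = n - 1
            sd = values.std(axis=0, ddof=1)
            _check_variance(sd)
            t = (values.mean(axis=0) - popmean) / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), dof)
        return StatResult(np.asarray(t), (float(dof),), np.asarray(p), "one_sample_t")

    vals = _residualize(values, design.covariates)

    if model == "two_sample":
        g1, g2 = _two_groups(design)
        a, b = vals[g1], vals[g2]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise InvalidDesignError("each group needs at least 2 subjects")
        t, p = sps.ttest_ind(a, b, axis=0)
        dof = a.shape[0] + b.shape[0] - 2
        return StatResult(np.asarray(t), (float(dof),), np.asarray(p), "two_sample_t")

    if model == "paired":
        diffs = _paired_differences(vals, design)
        sd = diffs.std(axis=0, ddof=1)
        _check_variance(sd)
        t, p = sps.ttest_1samp(diffs, 0.0, axis=0)
        return StatResult(
            np.asarray(t), (float(diffs.shape[0] - 1),), np.asarray(p), "paired_t"
        )

    if model == "anova1":
        if design.groups is None:
            raise InvalidDesignError("anova1 needs group labels")
        levels = np.unique(design.groups)
        if levels.size < 2:
            raise InvalidDesignError("anova1 needs >= 2 groups")
        samples = [vals[design.groups == lev] for lev in levels]
        if any(s.shape[0] < 2 for s in samples):
            raise InvalidDesignError("each group needs at least 2 subjects")
        f, p = sps.f_oneway(*samples, axis=0)
        df1 = levels.size - 1
        df2 = n - levels.size
        return StatResult(np.asarray(f), (float(df1), float(df2)), np.asarray(p), "anova1")

    if model == "rm_anova":
        return _rm_anova(vals, design)

    raise ValueError(f"unknown model {model!r}")


def _check_variance(scale: np.ndarray | float) -> None:
    if np.any(np.asarray(scale) == 0):
        raise InvalidDesignError("zero variance: test statistic undefined")


def _two_groups(design: GroupDesign) -> tuple[np.ndarray, np.ndarray]:
    if design.groups is None:
        raise InvalidDesignError("two-group model needs group labels")
    levels = np.unique(design.groups)
    if levels.size != 2:
        raise InvalidDesignError(f"expected 2 groups, found {levels.size}")
    return design.groups == levels[0], design.groups == levels[1]


def _paired_differences(vals: np.ndarray, design: GroupDesign) -> np.ndarray:
    g1, g2 = _two_groups(design)
    if design.pair_ids is None:
        raise InvalidDesignError("paired model needs pair_ids")
    first = {p: k for k, p in zip(np.flatnonzero(g1), design.pair_ids[g1])}
    second = {p: k for k, p in zip(np.flatnonzero(g2), design.pair_ids[g2])}
    if set(first) != set(second):
        raise InvalidDesignError("pair_ids do not match across the two conditions")
    pairs = sorted(first)
    if len(pairs) < 2:
        raise InvalidDesignError("need at least 2 pairs")
    i1 = [first[p] for p in pairs]
    i2 = [second[p] for p in pairs]
    return vals[i1] - vals[i2]


def _rm_anova(vals: np.ndarray, design: GroupDesign) -> StatResult:
    """Two-level additive (condition + subject) repeated-measures ANOVA."""
    if design.groups is None or design.pair_ids is None:
        raise InvalidDesignError("rm_anova needs condition labels and pair_ids")
    conds = np.unique(design.groups)
    subjects = np.unique(design.pair_ids)
    c, s = conds.size, subjects.size
    if c < 2 or s < 2:
        raise InvalidDesignError("rm_anova needs >= 2 conditions and >= 2 subjects")
    m = vals.shape[1]
    cell = np.full((c, s, m), np.nan)
    for ci, cond in enumerate(conds):
        for si, subj in enumerate(subjects):
            rows = (design.groups == cond) & (design.pair_ids == subj)
            if rows.sum() != 1:
                raise InvalidDesignError(
                    "rm_anova needs exactly one observation per condition x subject"
                )
            cell[ci, si] = vals[rows][0]
    grand = cell.mean(axis=(0, 1))
    cond_means = cell.mean(axis=1)
    subj_means = cell.mean(axis=0)
    ss_cond = s * ((cond_means - grand) ** 2).sum(axis=0)
    resid = cell - cond_means[:, None, :] - subj_means[None, :, :] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1 = c - 1
    df2 = (c - 1) * (s - 1)
    _check_variance(ss_err)
    f = (ss_cond / df1) / (ss_err / df2)
    p = sps.f.sf(f, df1, df2)
    return StatResult(np.asarray(f), (float(df1), float(df2)), np.asarray(p), "rm_anova")


def fdr_correct(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, reject mask) at level q."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def bonferroni_correct(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni: p multiplied by the family size, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="bonferroni")
    return p_adj, reject


def _edge_tstats_two_sample(X: np.ndarray, g1_masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for many labelings at once.

    X is subjects x edges; g1_masks is labelings x subjects (boolean, group
    1 membership). Returns labelings x edges t-statistics.
    """
    n = X.shape[0]
    g1 = g1_masks.astype(float)
    n1 = g1.sum(axis=1, keepdims=True)
    n2 = n - n1
    s1 = g1 @ X
    s2 = X.sum(axis=0)[None, :] - s1
    q1 = g1 @ (X**2)
    q2 = (X**2).sum(axis=0)[None, :] - q1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = q1 - n1 * m1**2
    ss2 = q2 - n2 * m2**2
    pooled = (ss1 + ss2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    return np.where(np.isfinite(t), t, 0.0)


def _components_from_mask(mask_edges: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                          n_nodes: int) -> list[list[int]]:
    """Connected components (as lists of edge indices) of a suprathreshold
    edge set, via union-find over the touched nodes."""
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active = np.flatnonzero(mask_edges)
    for e in active:
        ri, rj = find(int(iu[e])), find(int(ju[e]))
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for e in active:
        comps.setdefault(find(int(iu[e])), []).append(int(e))
    return list(comps.values())


def nbs(
    edge_values: np.ndarray,
    design: GroupDesign,
    edge_threshold: float,
    n_perm: int = 1000,
    seed: int = 0,
    model: str = "two_sample",
    component_stat: str = "extent",
) -> EdgeComponentResult:
    """Network-based statistic: component-level permutation inference on edges.

    An edgewise test statistic (two-sample t on group labels, or one-sample
    t against zero with sign-flipping permutations) is computed over the
    upper triangle of the subjects x N x N stack; edges with |stat| above
    ``edge_threshold`` form a graph whose connected components are measured
    by ``component_stat``: "extent" (edge count, the default) or "intensity"
    (sum of |stat| - threshold over the component's edges; continuous, so
    the permutation distribution has no ties and the test is closer to
    exact). Group labels (or signs) are permuted ``n_perm`` times rebuilding
    the maximal component statistic, and each observed component receives
    p = (1 + #{null max >= observed}) / (1 + n_perm).
    """
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.ndim != 3 or edge_values.shape[1] != edge_values.shape[2]:
        raise ValueError("edge_values must be subjects x N x N")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n_sub, n_nodes, _ = edge_values.shape
    iu, ju = np.triu_indices(n_nodes, k=1)
    X = edge_values[:, iu, ju]  # subjects x edges
    rng = np.random.default_rng(seed)

    if model == "two_sample":
        g1_obs, _ = _two_groups(design)
        n1 = int(g1_obs.sum())
        masks = np.empty((n_perm + 1, n_sub), dtype=bool)
        masks[0] = g1_obs
        for k in range(1, n_perm + 1):
            perm = rng.permutation(n_sub)
            row = np.zeros(n_sub, dtype=bool)
            row[perm[:n1]] = True
            masks[k] = row
        tstats = _edge_tstats_two_sample(X, masks)
    elif model == "one_sample":
        signs = np.empty((n_perm + 1, n_sub))
        signs[0] = 1.0
        signs[1:] = rng.choice((-1.0, 1.0), size=(n_perm, n_sub))
        tstats = np.empty((n_perm + 1, X.shape[1]))
        for k in range(n_perm + 1):
            flipped = X * signs[k][:, None]
            sd = flipped.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = flipped.mean(axis=0) / (sd / np.sqrt(n_sub))
            tstats[k] = np.where(np.isfinite(t), t, 0.0)
    else:
        raise ValueError(f"unknown NBS model {model!r}")

    if component_stat not in ("extent", "intensity"):
        raise ValueError(f"unknown component_stat {component_stat!r}")

    def comp_value(comp: list[int], stats_row: np.ndarray) -> float:
        if component_stat == "extent":
            return float(len(comp))
        return float((np.abs(stats_row[comp]) - edge_threshold).sum())

    supra = np.abs(tstats) > edge_threshold
    obs_comps = _components_from_mask(supra[0], iu, ju, n_nodes)
    obs_sizes = [len(c) for c in obs_comps]
    obs_values = [comp_value(c, tstats[0]) for c in obs_comps]
    null_max = np.zeros(n_perm)
    for k in range(1, n_perm + 1):
        if supra[k].any():
            comps = _components_from_mask(supra[k], iu, ju, n_nodes)
            null_max[k - 1] = max(comp_value(c, tstats[k]) for c in comps)
    pvals = tuple(
        float((1 + (null_max >= val).sum()) / (1 + n_perm)) for val in obs_values
    )
    stat_mat = np.zeros((n_nodes, n_nodes))
    stat_mat[iu, ju] = tstats[0]
    stat_mat += stat_mat.T
    supra_mat = np.zeros((n_nodes, n_nodes), dtype=bool)
    supra_mat[iu, ju] = supra[0]
    supra_mat |= supra_mat.T
    comps_edges = tuple(
        tuple((int(iu[e]), int(ju[e])) for e in comp) for comp in obs_comps
    )
    return EdgeComponentResult(
        edge_stats=stat_mat,
        suprathreshold=supra_mat,
        components=comps_edges,
        component_sizes=tuple(obs_sizes),
        component_values=tuple(obs_values),
        component_p=pvals,
        null_max_sizes=null_max,
        n_perm=n_perm,
        seed=seed,
        component_stat=component_stat,
    )


def behavior_correlation(
    metric: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
) -> StatResult:
    """(Partial) Pearson correlation between a network measure and behavior.

    With covariates, both vectors are residualized against [1 | covariates]
    and the correlation of the residuals is tested on n - 2 - k degrees of
    freedom.
    """
    x = np.asarray(metric, dtype=float).ravel()
    y = np.asarray(behavior, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("metric and behavior must have the same length")
    k = 0 if covariates is None else np.atleast_2d(covariates).reshape(x.size, -1).shape[1]
    if x.size < 4 + k:
        raise InvalidDesignError(f"need at least {4 + k} subjects, got {x.size}")
    scale = max(x.std(), y.std(), 1.0)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(x.size, -1)
        x = _residualize(x[:, None], cov).ravel()
        y = _residualize(y[:, None], cov).ravel()
    if x.std() <= 1e-10 * scale or y.std() <= 1e-10 * scale:
        raise InvalidDesignError("zero variance in metric or behavior")
    r = float(np.corrcoef(x, y)[0, 1])
    dof = x.size - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(
        np.asarray([r]), (float(dof),), np.asarray([p]),
        "partial_pearson" if k else "pearson",
    )
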