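"""Spatiotemporal cluster-based permutation testing and condition effects.

The cluster test controls the family-wise error of a dependent-samples
comparison over channels x time: sample-wise paired t-values are
thresholded at the two-tailed parametric critical value, suprathreshold
samples of the same sign are clustered by spatial adjacency (electrodes
within a distance threshold) and temporal adjacency (consecutive samples),
each cluster is scored by its summed t, and the observed cluster scores
are referred to a Monte-Carlo null distribution of maximal scores obtained
by randomly sign-flipping the per-subject difference maps (equivalent to
swapping condition labels within subjects). When the subject count is
small enough that every sign assignment can be enumerated, the exact
permutation distribution is used instead.

Condition effects on ROI amplitudes and behavioral endpoints are estimated
with linear mixed models (subject random intercepts), delegating the fit
to statsmodels MixedLM; the contract here is parameter recovery, not a new
estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "paired_t_map",
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "EffectEstimate",
    "fit_condition_effect",
]

T_SENTINEL = 1e6  # stands in for an infinite t when differences have zero variance


@dataclass
class AdjacencyGraph:
    labels: list[str]
    coords_cm: np.ndarray
    edges: np.ndarray  # m x 2 channel-index pairs, i < j
    threshold_cm: float

    def neighbors(self, label: str) -> list[str]:
        i = self.labels.index(label)
        out = set()
        for a, b in self.edges:
            if a == i:
                out.add(self.labels[b])
            elif b == i:
                out.add(self.labels[a])
        return sorted(out)


def build_adjacency(montage: pd.DataFrame, threshold_cm: float = 5.0) -> AdjacencyGraph:
    """Electrodes within ``threshold_cm`` (Euclidean) are neighbours."""
    required = {"label", "x_cm", "y_cm", "z_cm"}
    if not required.issubset(montage.columns):
        raise ValueError("montage must provide label and x/y/z_cm columns")
    if montage[["x_cm", "y_cm", "z_cm"]].isna().any().any():
        raise ValueError("missing electrode coordinate")
    xyz = montage[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    i, j = np.where((d <= threshold_cm) & (d > 0))
    keep = i < j
    edges = np.column_stack([i[keep], j[keep]])
    return AdjacencyGraph(list(montage["label"]), xyz, edges, threshold_cm)


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Dependent-samples t at every (channel, sample).

    Inputs are subject-matched arrays (subjects x channels x samples).
    Zero-variance differences yield an infinite t; these are replaced by a
    signed large-magnitude sentinel and logged.
    """
    a, b = np.asarray(cond_a, dtype=float), np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("need matched subjects x channels x samples arrays, n >= 2")
    d = a - b
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var & (m != 0)):
        warnings.warn("zero-variance differences: t capped at sentinel magnitude")
    t = np.where(zero_var, np.sign(m) * T_SENTINEL, t)
    return t


def _st_edges(adjacency: AdjacencyGraph, n_channels: int, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (channel*n_samples + sample) edge arrays for the combined
    spatial (same sample) + temporal (same channel, consecutive samples)
    neighbourhood."""
    if len(adjacency.labels) != n_channels:
        raise ValueError("adjacency does not match data channel count")
    s = np.arange(n_samples)
    us, vs = [], []
    for a, b in adjacency.edges:
        us.append(a * n_samples + s)
        vs.append(b * n_samples + s)
    c = np.arange(n_channels)
    us.append((c[:, None] * n_samples + s[:-1][None, :]).ravel())
    vs.append((c[:, None] * n_samples + s[1:][None, :]).ravel())
    return np.concatenate(us), np.concatenate(vs)


def _cluster_sums(
    t_flat: np.ndarray, mask: np.ndarray, eu: np.ndarray, ev: np.ndarray, members: bool = False
):
    """Connected same-sign suprathreshold clusters via union-find over the
    masked edge set. Returns (sums, list-of-member-arrays or None)."""
    nodes = np.flatnonzero(mask)
    if len(nodes) == 0:
        return np.empty(0), [] if members else None
    keep = mask[eu] & mask[ev]
    parent: dict[int, int] = {int(v): int(v) for v in nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in zip(eu[keep], ev[keep]):
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[ru] = rv
    roots: dict[int, int] = {}
    sums: list[float] = []
    mem: list[list[int]] = []
    for v in nodes:
        r = find(int(v))
        if r not in roots:
            roots[r] = len(sums)
            sums.append(0.0)
            mem.append([])
        k = roots[r]
        sums[k] += t_flat[v]
        if members:
            mem[k].append(int(v))
    return np.asarray(sums), ([np.asarray(m) for m in mem] if members else None)


def _max_cluster_stat(t_flat: np.ndarray, tcrit: float, eu: np.ndarray, ev: np.ndarray) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        sums, _ = _cluster_sums(t_flat, sign * t_flat > tcrit, eu, ev)
        if len(sums):
            best = max(best, float(np.max(np.abs(sums))))
    return best


@dataclass
class Cluster:
    members: np.ndarray  # k x 2 array of (channel, sample) indices
    summed_t: float
    p_value: float
    sign: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= 0.05)

    def channels(self, labels: list[str]) -> list[str]:
        return sorted({labels[c] for c in self.members[:, 0]})

    def time_span_samples(self) -> tuple[int, int]:
        s = self.members[:, 1]
        return int(s.min()), int(s.max())


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    null_max: np.ndarray
    alpha: float
    cluster_alpha: float
    n_permutations: int
    exhaustive: bool
    tcrit: float

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha]


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: AdjacencyGraph,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Spatiotemporal cluster-based permutation test for a paired design.

    ``cluster_alpha`` sets the cluster-forming threshold: the two-tailed
    parametric critical t for n-1 degrees of freedom. Cluster-level
    significance is assessed at ``alpha`` against the permutation
    distribution of the maximal |summed t|. If ``2**n_subjects`` does not
    exceed ``n_permutations`` the full sign-flip distribution is
    enumerated and p-values are exact; otherwise Monte-Carlo p-values use
    the (count + 1) / (n + 1) convention.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b = np.asarray(cond_a, dtype=float), np.asarray(cond_b, dtype=float)
    n, n_ch, n_samp = a.shape
    d = (a - b).reshape(n, n_ch * n_samp)
    tcrit = float(spstats.t.ppf(1 - cluster_alpha / 2.0, n - 1))
    eu, ev = _st_edges(adjacency, n_ch, n_samp)

    t_obs_flat = paired_t_map(a, b).ravel()
    clusters: list[Cluster] = []
    for sign in (1, -1):
        sums, mems = _cluster_sums(t_obs_flat, sign * t_obs_flat > tcrit, eu, ev, members=True)
        for s, m in zip(sums, mems):
            clusters.append(
                Cluster(
                    members=np.column_stack([m // n_samp, m % n_samp]),
                    summed_t=float(s),
                    p_value=np.nan,
                    sign=sign,
                )
            )

    exhaustive = 2**n <= n_permutations
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    # All permutation t-maps at once: the second moment of the differences
    # is sign-invariant, so only the flipped means vary.
    ss = np.sum(d * d, axis=0)
    m_perm = signs @ d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss[None, :] - n * m_perm**2) / (n - 1)
        t_perm = m_perm / np.sqrt(var / n)
    zero = var <= 0
    t_perm = np.where(zero, np.sign(m_perm) * T_SENTINEL, t_perm)

    null_max = np.empty(len(signs))
    for k in range(len(signs)):
        null_max[k] = _max_cluster_stat(t_perm[k], tcrit, eu, ev)

    for c in clusters:
        ge = int(np.sum(null_max >= abs(c.summed_t) - 1e-12))
        if exhaustive:
            c.p_value = ge / len(signs)
        else:
            c.p_value = (ge + 1) / (len(signs) + 1)

    clusters.sort(key=lambda c: abs(c.summed_t), reverse=True)
    return ClusterResult(
        clusters=clusters,
        t_obs=t_obs_flat.reshape(n_ch, n_samp),
        null_max=null_max,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        n_permutations=len(signs),
        exhaustive=exhaustive,
        tcrit=tcrit,
    )


# ---------------------------------------------------------------------------
# Condition-effect estimation


@dataclass
class EffectEstimate:
    params: pd.DataFrame  # index: term; columns: estimate, se, p
    random_intercept_var: float
    aic: float
    aic_interaction: Optional[float] = None
    fallback: bool = False
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])


def _paired_fallback(
    df: pd.DataFrame, outcome: str, condition: str, subject: str, reference: str
) -> EffectEstimate:
    """Within-subject paired contrasts vs the reference level (used when
    the mixed model cannot be fit)."""
    cell = df.groupby([subject, condition])[outcome].mean().unstack(condition)
    rows = {}
    for lev in cell.columns:
        if lev == reference:
            continue
        diff = (cell[lev] - cell[reference]).dropna()
        t, p = spstats.ttest_1samp(diff, 0.0) if len(diff) > 1 else (np.nan, np.nan)
        se = diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1 else np.nan
        rows[f"{condition}[{lev}-{reference}]"] = (float(diff.mean()), float(se), float(p))
    params = pd.DataFrame.from_dict(rows, orient="index", columns=["estimate", "se", "p"])
    return EffectEstimate(
        params=params,
        random_intercept_var=float("nan"),
        aic=float("nan"),
        fallback=True,
        notes=["mixed model failed; paired within-subject contrasts reported"],
    )


def fit_condition_effect(
    data: pd.DataFrame,
    outcome: str = "value",
    condition: str = "condition",
    subject: str = "subject",
    reference: str = "none",
    covariates: list[str] | None = None,
    interaction_with: str | None = None,
) -> EffectEstimate:
    """Linear mixed model with subject random intercepts.

    Fixed effects: condition (treatment-coded against ``reference``) plus
    optional continuous covariates (e.g. an ERP amplitude). When
    ``interaction_with`` names a covariate, a second candidate model adds
    the condition x covariate interaction; both models' AICs are reported
    (no selection is performed) and the interaction model's parameters are
    returned.

    With zero between-subject variance and balanced data the fixed effects
    coincide with the condition cell means/differences.
    """
    import statsmodels.formula.api as smf

    need = {outcome, condition, subject} | set(covariates or [])
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    levels = sorted(data[condition].unique())
    if len(levels) < 2 or data[subject].nunique() < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    if reference not in levels:
        reference = levels[0]

    cond_term = f"C({condition}, Treatment(reference='{reference}'))"
    rhs = [cond_term] + list(covariates or [])
    formula_main = f"{outcome} ~ " + " + ".join(rhs)
    formulas = [formula_main]
    if interaction_with is not None:
        if interaction_with not in data.columns:
            raise ValueError(f"unknown interaction covariate {interaction_with!r}")
        formulas.append(formula_main + f" + {cond_term}:{interaction_with}")

    def _fit(formula, reml):
        last = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = smf.mixedlm(formula, data, groups=data[subject])
                    return md.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as e:
                last = e
        raise last

    # REML for the reported estimates/SEs; ML refits for comparable AICs.
    try:
        fits = [_fit(f, reml=True) for f in formulas]
        aics = [float(_fit(f, reml=False).aic) for f in formulas]
    except (np.linalg.LinAlgError, ValueError):
        return _paired_fallback(data, outcome, condition, subject, reference)

    res = fits[-1]
    rows = {}
    for name in res.fe_params.index:
        pretty = name.replace(cond_term, condition)
        rows[pretty] = (
            float(res.fe_params[name]),
            float(res.bse_fe[name]),
            float(res.pvalues[name]),
        )
    params = pd.DataFrame.from_dict(rows, orient="index", columns=["estimate", "se", "p"])
    if (params["se"] <= 0).any() or params["se"].isna().all():
        return _paired_fallback(data, outcome, condition, subject, reference)
    return EffectEstimate(
        params=params,
        random_intercept_var=float(np.asarray(res.cov_re).ravel()[0]),
        aic=aics[0],
        aic_interaction=aics[1] if len(aics) > 1 else None,
        fallback=False,
    )
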