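"""Group statistics for band power, graph metrics and edgewise connectivity.

Three inference layers mirror the analysis design:

* non-parametric permutation tests (label shuffling, or sign flips for
  the paired within-subject contrast) for band-power comparisons,
  1,000 randomizations by default;
* parametric t-tests with Benjamini-Hochberg FDR across the sparsity
  grid and metrics for the global graph measures;
* the network-based statistic (NBS) for edgewise connectivity: edgewise
  t-tests, a primary one-sided threshold at edge p = 0.05, connected
  supra-threshold components scored by extent (edge count), and a
  max-component permutation null (5,000 permutations, component
  p = 0.01), run separately for each contrast direction.

Permutation p-values use the add-one convention
p = (1 + #{|T*| >= |T|}) / (1 + n_perm), so the attainable minimum is
1/(n_perm + 1) and p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StatSpec",
    "NBSResult",
    "permutation_test",
    "t_statistic",
    "fdr_bh",
    "nbs",
    "edge_count_summary",
    "updrs_improvement",
    "graph_metric_group_tests",
]


@dataclass(frozen=True)
class StatSpec:
    """Statistical-testing parameters."""

    n_perm_psd: int = 1000
    n_perm_nbs: int = 5000
    edge_alpha: float = 0.05
    component_alpha: float = 0.01
    fdr_q: float = 0.05
    paired: bool = False
    seed: int = 0
    component_statistic: str = "extent"  # or "intensity"

    def __post_init__(self) -> None:
        if self.n_perm_psd < 100 or self.n_perm_nbs < 100:
            raise ValueError("permutation counts must be >= 100")
        for a in (self.edge_alpha, self.component_alpha, self.fdr_q):
            if not (0 < a < 1):
                raise ValueError("alphas must lie in (0, 1)")
        if self.component_statistic not in ("extent", "intensity"):
            raise ValueError("component_statistic must be 'extent' or 'intensity'")


@dataclass
class NBSResult:
    """Supra-threshold components for one contrast direction.

    ``components`` lists each component's edges as (i, j) index pairs;
    ``extents`` the edge counts; ``p_values`` the max-component
    permutation p per component.  ``direction`` is "increase" when the
    first group exceeds the second on the component's edges.
    """

    direction: str
    components: list[list[tuple[int, int]]]
    extents: list[int]
    p_values: list[float]
    observed_t: np.ndarray
    threshold: float
    component_alpha: float = 0.01
    statistic_values: list[float] = field(default_factory=list)

    @property
    def significant(self) -> list[int]:
        """Indices of components with p below the component alpha."""
        return [k for k, p in enumerate(self.p_values) if p < self.component_alpha]

    def significant_edges(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for k in self.significant:
            out.update(self.components[k])
        return out

    def significant_nodes(self) -> set[int]:
        return {v for e in self.significant_edges() for v in e}


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def permutation_test(a: np.ndarray, b: np.ndarray, paired: bool = False,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided non-parametric permutation test on a difference of means.

    Independent design: the group labels of the pooled sample are
    shuffled.  Paired design: the signs of the within-pair differences
    are flipped at random.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    rng = np.random.default_rng(seed)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        observed = d.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = (signs * d).mean(axis=1)
    else:
        pooled = np.concatenate([a, b])
        observed = a.mean() - b.mean()
        n_a = a.size
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        shuffled = pooled[idx]
        null = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_perm))


def t_statistic(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Student t: pooled-variance two-sample, or one-sample on differences."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError("zero variance of paired differences")
        return float(d.mean() / (sd / np.sqrt(d.size)))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ZeroDivisionError("zero variance in both groups")
    n_a, n_b = a.size, b.size
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n_a + 1 / n_b)))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask.

    Rejects all p <= p_(k*), k* = max{k : p_(k) <= k q / m}.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool)
    k_star = np.max(np.flatnonzero(below))
    return p <= ranked[k_star]


# ---------------------------------------------------------------------------
# network-based statistic
# ---------------------------------------------------------------------------

def _edge_stacks(group: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subjects, n_edges) upper-triangle edge values from matrix stacks."""
    group = np.asarray(group, dtype=float)
    if group.ndim != 3 or group.shape[1] != group.shape[2]:
        raise ValueError("expected a stack of square matrices (n_subj, n, n)")
    n = group.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return group[:, iu, ju], iu, ju


def _paired_t_rows(d_signed: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t over columns of (n_rows, n_pairs, n_edges)."""
    n = d_signed.shape[1]
    mean = d_signed.mean(axis=1)
    var = d_signed.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _indep_t_rows(x: np.ndarray, member_a: np.ndarray) -> np.ndarray:
    """Pooled-variance t for many label assignments at once.

    x : (n_subjects, n_edges); member_a : (n_rows, n_subjects) boolean.
    """
    n_a = member_a[0].sum()
    n_b = member_a.shape[1] - n_a
    fa = member_a.astype(float)
    fb = 1.0 - fa
    sum_a, sum_b = fa @ x, fb @ x
    sq_a, sq_b = fa @ (x * x), fb @ (x * x)
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = sq_a - n_a * mean_a ** 2
    ss_b = sq_b - n_b * mean_b ** 2
    sp2 = (ss_a + ss_b) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_component_stat(t_row: np.ndarray, thresh: float, iu: np.ndarray,
                        ju: np.ndarray, n_nodes: int, intensity: bool) -> float:
    """Largest supra-threshold component statistic for one t map."""
    mask = t_row > thresh
    if not mask.any():
        return 0.0
    ii, jj = iu[mask], ju[mask]
    adj = csr_array((np.ones(ii.size), (ii, jj)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[ii]
    if intensity:
        sums = np.zeros(labels.max() + 1)
        np.add.at(sums, comp_of_edge, t_row[mask] - thresh)
        return float(sums.max())
    return float(np.bincount(comp_of_edge).max())


def _observed_components(t_row: np.ndarray, thresh: float, iu: np.ndarray,
                         ju: np.ndarray, n_nodes: int, intensity: bool,
                         ) -> tuple[list[list[tuple[int, int]]], list[int], list[float]]:
    mask = t_row > thresh
    if not mask.any():
        return [], [], []
    ii, jj = iu[mask], ju[mask]
    adj = csr_array((np.ones(ii.size), (ii, jj)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[ii]
    comps, extents, stat_vals = [], [], []
    for lbl in np.unique(comp_of_edge):
        sel = comp_of_edge == lbl
        edges = list(zip(ii[sel].tolist(), jj[sel].tolist()))
        comps.append(edges)
        extents.append(int(sel.sum()))
        stat_vals.append(float((t_row[mask][sel] - thresh).sum()) if intensity
                         else float(sel.sum()))
    # largest components first
    order = np.argsort(stat_vals)[::-1]
    return ([comps[k] for k in order], [extents[k] for k in order],
            [stat_vals[k] for k in order])


def nbs(group_a: np.ndarray, group_b: np.ndarray,
        spec: StatSpec | None = None) -> tuple[NBSResult, NBSResult]:
    """Network-based statistic for both contrast directions.

    Parameters
    ----------
    group_a, group_b : stacks of symmetric connectivity matrices,
        shape (n_subjects, n_nodes, n_nodes).  For a paired design
        (``spec.paired``) the stacks must be subject-aligned.

    Returns
    -------
    (increase, decrease) : NBSResult per direction; "increase" collects
        components where group_a exceeds group_b.
    """
    spec = spec or StatSpec()
    xa, iu, ju = _edge_stacks(group_a)
    xb, _, _ = _edge_stacks(group_b)
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("node-count mismatch between the two groups")
    n_nodes = group_a.shape[1]
    rng = np.random.default_rng(spec.seed)
    intensity = spec.component_statistic == "intensity"

    if spec.paired:
        if xa.shape[0] != xb.shape[0]:
            raise ValueError("paired design requires aligned stacks")
        d = xa - xb
        n_sub = d.shape[0]
        df = n_sub - 1
        t_obs = _paired_t_rows(d[None])[0]
    else:
        x = np.concatenate([xa, xb], axis=0)
        n_tot = x.shape[0]
        df = n_tot - 2
        member_obs = np.zeros((1, n_tot), dtype=bool)
        member_obs[0, : xa.shape[0]] = True
        t_obs = _indep_t_rows(x, member_obs)[0]
    thresh = float(stats.t.ppf(1.0 - spec.edge_alpha, df))

    # permutation null of the max component statistic, per direction
    null_inc = np.empty(spec.n_perm_nbs)
    null_dec = np.empty(spec.n_perm_nbs)
    block = 500
    done = 0
    while done < spec.n_perm_nbs:
        nb = min(block, spec.n_perm_nbs - done)
        if spec.paired:
            signs = rng.choice([-1.0, 1.0], size=(nb, n_sub))
            t_perm = _paired_t_rows(signs[:, :, None] * d[None])
        else:
            member = np.zeros((nb, n_tot), dtype=bool)
            for r in range(nb):
                member[r, rng.permutation(n_tot)[: xa.shape[0]]] = True
            t_perm = _indep_t_rows(x, member)
        for r in range(nb):
            null_inc[done + r] = _max_component_stat(
                t_perm[r], thresh, iu, ju, n_nodes, intensity)
            null_dec[done + r] = _max_component_stat(
                -t_perm[r], thresh, iu, ju, n_nodes, intensity)
        done += nb

    results = []
    for direction, t_dir, null in (("increase", t_obs, null_inc),
                                   ("decrease", -t_obs, null_dec)):
        comps, extents, stat_vals = _observed_components(
            t_dir, thresh, iu, ju, n_nodes, intensity)
        pvals = [float((1 + np.sum(null >= sv)) / (1 + spec.n_perm_nbs))
                 for sv in stat_vals]
        results.append(NBSResult(
            direction=direction, components=comps, extents=extents,
            p_values=pvals, observed_t=_square_from_edges(t_obs, iu, ju, n_nodes),
            threshold=thresh, component_alpha=spec.component_alpha,
            statistic_values=stat_vals))
    return results[0], results[1]


def _square_from_edges(vals: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                       n: int) -> np.ndarray:
    m = np.zeros((n, n))
    m[iu, ju] = vals
    return m + m.T


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _direction_count(entry) -> tuple[int, int]:
    """(edges, nodes) from an NBSResult or a bare edge count."""
    if isinstance(entry, NBSResult):
        return len(entry.significant_edges()), len(entry.significant_nodes())
    return int(entry), 0


def edge_count_summary(nbs_by_band: dict) -> dict:
    """Across-band summary of significant increased vs decreased edges.

    Parameters
    ----------
    nbs_by_band : band name -> (increase, decrease), where each entry
        is either an :class:`NBSResult` or a bare significant-edge
        count.

    Returns a dict with per-band counts, across-band means and sample
    standard deviations (n-1 denominator) per direction, and a
    two-sided Welch t-test comparing the two per-band count vectors.
    """
    if len(nbs_by_band) < 2:
        raise ValueError("need at least 2 bands to summarize across bands")
    per_band = {}
    inc_counts, dec_counts = [], []
    for band, (inc, dec) in nbs_by_band.items():
        e_inc, n_inc = _direction_count(inc)
        e_dec, n_dec = _direction_count(dec)
        per_band[band] = {"increase_edges": e_inc, "increase_nodes": n_inc,
                          "decrease_edges": e_dec, "decrease_nodes": n_dec}
        inc_counts.append(e_inc)
        dec_counts.append(e_dec)
    inc = np.asarray(inc_counts, dtype=float)
    dec = np.asarray(dec_counts, dtype=float)
    welch = stats.ttest_ind(inc, dec, equal_var=False)
    return {
        "per_band": per_band,
        "increase_mean": float(inc.mean()),
        "increase_sd": float(inc.std(ddof=1)),
        "decrease_mean": float(dec.mean()),
        "decrease_sd": float(dec.std(ddof=1)),
        "welch_t": float(welch.statistic),
        "welch_p": float(welch.pvalue),
    }


def updrs_improvement(mean_off: float, mean_on: float) -> float:
    """Fractional motor-score improvement (off - on) / off."""
    if mean_off <= 0:
        raise ValueError("baseline (stimulation-off) score must be positive")
    return (mean_off - mean_on) / mean_off


def graph_metric_group_tests(df_a: pd.DataFrame, df_b: pd.DataFrame,
                             paired: bool = False, q: float = 0.05,
                             ) -> pd.DataFrame:
    """t-tests with BH-FDR for global graph metrics, per band.

    Inputs are long-format tables from :func:`graphmetrics.metrics_sweep`
    (columns subject, band, sparsity, metric, value).  Within each band
    the FDR correction spans all (sparsity, metric) cells.
    """
    rows = []
    for band in sorted(df_a["band"].unique()):
        cells = []
        sub_a = df_a[df_a["band"] == band]
        sub_b = df_b[df_b["band"] == band]
        for (sparsity, metric), grp_a in sub_a.groupby(["sparsity", "metric"]):
            grp_b = sub_b[(sub_b["sparsity"] == sparsity)
                          & (sub_b["metric"] == metric)]
            va = grp_a.sort_values("subject")["value"].to_numpy()
            vb = grp_b.sort_values("subject")["value"].to_numpy()
            if np.isnan(va).any() or np.isnan(vb).any() or len(vb) == 0:
                continue
            try:
                t = t_statistic(va, vb, paired=paired)
            except ZeroDivisionError:
                continue
            dfree = va.size - 1 if paired else va.size + vb.size - 2
            p = 2 * stats.t.sf(abs(t), dfree)
            cells.append({"band": band, "sparsity": sparsity, "metric": metric,
                          "t": t, "p": p})
        if not cells:
            continue
        pvals = np.array([c["p"] for c in cells])
        reject = fdr_bh(pvals, q)
        for c, r in zip(cells, reject):
            c["significant_fdr"] = bool(r)
            rows.append(c)
    return pd.DataFrame(rows)
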