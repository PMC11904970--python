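"""Within-subject statistics: RM-ANOVA, multiplicity control, and
spatiotemporal cluster-based permutation tests.

The analysis plan combines:

* repeated-measures ANOVA (one or two within-subject factors) with
  Greenhouse-Geisser sphericity correction and partial eta squared,
* Holm step-down correction for planned comparisons,
* Benjamini-Hochberg step-up FDR within declared families of tests,
* mass-univariate one-sample / paired t maps over channels x time, and
* cluster-based permutation inference: suprathreshold points are clustered
  by spatiotemporal adjacency, cluster mass is the summed statistic, and the
  null is the permutation distribution of the maximal cluster mass
  (sign flips for one-sample designs, within-participant label exchange for
  factorial designs).

ANOVA effects are computed through orthonormal contrasts: for an effect with
contrast matrix ``C`` the per-participant scores ``z_i = C y_i`` give
``SS_effect = n * ||z_bar||^2`` and ``SS_error = sum_i ||z_i - z_bar||^2``,
and the Greenhouse-Geisser epsilon is ``tr(E)^2 / (df * tr(E^2))`` with
``E`` the covariance of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse
from scipy import stats as sstats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    gg_epsilon: float
    df1_gg: float
    df2_gg: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float
    family_id: str | None = None
    p_fdr: float | None = None
    n_participants: int = 0


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows, each orthogonal to ones."""
    if k < 2:
        raise ValueError("factor needs >= 2 levels")
    return sla.helmert(k, full=False)


def _complete_cases(
    table: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list[tuple[int, ...]], list[str], list[list]]:
    """Pivot long data to subjects x cells, dropping incomplete participants.

    Returns (Y, cell index tuples, retained subjects, factor levels).
    """
    levels = [sorted(table[f].unique().tolist()) for f in within]
    cells = [tuple(idx) for idx in np.ndindex(*[len(l) for l in levels])]
    piv = table.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    expected = len(cells)
    complete = piv.dropna(axis=0)
    if complete.shape[1] != expected or len(complete) < 2:
        raise ValueError(
            f"incomplete within-subject design: {expected} cells expected, "
            f"{piv.shape[1]} present; {len(complete)} complete participants"
        )
    dropped = sorted(set(piv.index) - set(complete.index))
    if dropped:
        # listwise deletion, mirrored in the result's n_participants
        pass
    # order columns canonically
    if len(within) == 1:
        cols = [l for l in levels[0]]
    else:
        cols = [tuple(levels[f][i] for f, i in enumerate(cell)) for cell in cells]
    Y = complete[cols].to_numpy(dtype=float)
    return Y, cells, list(complete.index), levels


def _effect_contrast(levels_n: Sequence[int], which: Sequence[bool]) -> np.ndarray:
    """Kronecker contrast over cells: centring contrasts for factors in the
    effect, normalised averaging vectors for the rest."""
    mats = []
    for k, involved in zip(levels_n, which):
        mats.append(_orthonormal_contrasts(k) if involved else np.ones((1, k)) / np.sqrt(k))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return C


def _gg_epsilon_from_scores(Z: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast scores (n x df)."""
    df = Z.shape[1]
    if df < 2:
        return 1.0
    E = np.cov(Z, rowvar=False)
    tr = np.trace(E)
    tr2 = np.trace(E @ E)
    if tr2 <= 0 or tr <= 0:
        return 1.0  # degenerate (constant) data
    return float(min(tr**2 / (df * tr2), 1.0))


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: Sequence[str] = ("block",),
    subject: str = "participant",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA for one or two within-subject factors.

    Participants with missing cells are dropped listwise. Every effect is
    reported with uncorrected and Greenhouse-Geisser-corrected degrees of
    freedom and p-values, plus partial eta squared.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within factors")
    Y, _, subjects, levels = _complete_cases(table, dv, within, subject)
    n = len(subjects)
    levels_n = [len(l) for l in levels]

    effects: list[tuple[str, Sequence[bool]]] = []
    if len(within) == 1:
        effects.append((within[0], (True,)))
    else:
        effects.append((within[0], (True, False)))
        effects.append((within[1], (False, True)))
        effects.append((f"{within[0]}:{within[1]}", (True, True)))

    # rounding floor: contrasts of data constant within participant leave
    # ~1e-16 dust whose ratio would masquerade as a real F
    ss_floor = 1e-20 * max(1.0, float((Y * Y).sum()))
    results = []
    for name, which in effects:
        C = _effect_contrast(levels_n, which)
        Z = Y @ C.T
        zbar = Z.mean(axis=0)
        ss_eff = n * float(zbar @ zbar)
        dev = Z - zbar
        ss_err = float((dev * dev).sum())
        if ss_eff < ss_floor:
            ss_eff = 0.0
        if ss_err < ss_floor:
            ss_err = 0.0
        df1 = C.shape[0]
        df2 = df1 * (n - 1)
        if ss_err <= 0:
            F = 0.0 if ss_eff <= 0 else np.inf
        else:
            F = (ss_eff / df1) / (ss_err / df2)
        eps = _gg_epsilon_from_scores(Z)
        lower = 1.0 / df1 if df1 >= 1 else 1.0
        eps = max(eps, lower)
        p = float(sstats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        p_gg = float(sstats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        results.append(
            AnovaResult(
                effect=name,
                F=float(F),
                df1=df1,
                df2=df2,
                gg_epsilon=eps,
                df1_gg=df1 * eps,
                df2_gg=df2 * eps,
                p_uncorrected=p,
                p_gg=p_gg,
                partial_eta_sq=float(peta),
                n_participants=n,
            )
        )
    return results


def gg_epsilon(table: pd.DataFrame, factor: str, dv: str = "value", subject: str = "participant") -> float:
    """Greenhouse-Geisser epsilon for a single within factor (k = 2 -> 1)."""
    Y, _, _, levels = _complete_cases(table, dv, [factor], subject)
    C = _orthonormal_contrasts(len(levels[0]))
    return max(_gg_epsilon_from_scores(Y @ C.T), 1.0 / C.shape[0])


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "block",
    between: str = "session_order",
    subject: str = "participant",
) -> list[AnovaResult]:
    """Split-plot ANOVA: one within factor, one between blocking factor.

    Used to re-run within-subject analyses with session order as a
    between-participant covariate; the within-by-between interaction term is
    the one consulted before adjusted statistics are reported.
    """
    wlev = sorted(table[within].unique().tolist())
    piv = table.pivot_table(index=[subject, between], columns=within, values=dv).dropna()
    k = len(wlev)
    Y = piv[wlev].to_numpy(dtype=float)
    groups = piv.index.get_level_values(1).to_numpy()
    glabels = sorted(pd.unique(groups).tolist())
    g = len(glabels)
    n = Y.shape[0]
    if n < g + 1:
        raise ValueError("not enough participants for a between factor")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    cell_gw = np.vstack([Y[groups == gl].mean(axis=0) for gl in glabels])  # g x k
    group_means = cell_gw.mean(axis=1)
    level_means = Y.mean(axis=0)
    ng = np.array([(groups == gl).sum() for gl in glabels])

    ss_between = float((ng * (group_means - grand) ** 2).sum() * k)
    ss_subj_within = float(k * ((subj_means - group_means[np.searchsorted(glabels, groups)]) ** 2).sum())
    ss_w = float(n * ((level_means - grand) ** 2).sum())
    ss_inter = float(
        (ng[:, None] * (cell_gw - group_means[:, None] - level_means[None, :] + grand) ** 2).sum()
    )
    resid = Y - cell_gw[np.searchsorted(glabels, groups)] - subj_means[:, None] + group_means[np.searchsorted(glabels, groups)][:, None]
    ss_err_w = float((resid**2).sum())

    df_b, df_sw = g - 1, n - g
    df_w = k - 1
    df_i = (g - 1) * (k - 1)
    df_ew = (n - g) * (k - 1)

    out = []
    for name, ss, df1, ss_e, df2 in (
        (between, ss_between, df_b, ss_subj_within, df_sw),
        (within, ss_w, df_w, ss_err_w, df_ew),
        (f"{within}:{between}", ss_inter, df_i, ss_err_w, df_ew),
    ):
        F = (ss / df1) / (ss_e / df2) if ss_e > 0 else np.inf
        p = float(sstats.f.sf(F, df1, df2))
        out.append(
            AnovaResult(
                effect=name, F=float(F), df1=df1, df2=df2,
                gg_epsilon=1.0, df1_gg=df1, df2_gg=df2,
                p_uncorrected=p, p_gg=p,
                partial_eta_sq=ss / (ss + ss_e) if ss + ss_e > 0 else 0.0,
                n_participants=n,
            )
        )
    return out


# --------------------------------------------------------------------------
# multiplicity control
# --------------------------------------------------------------------------


def holm(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejection flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adj, reject


def bh_fdr(
    p_values: Sequence[float], family_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, applied within each family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_ids is None:
        family_ids = ["all"] * p.size
    fam = np.asarray(list(family_ids))
    adj = np.empty_like(p)
    for f in pd.unique(fam):
        sel = fam == f
        _, a, _, _ = multipletests(p[sel], method="fdr_bh")
        adj[sel] = a
    return adj


# --------------------------------------------------------------------------
# mass-univariate t maps
# --------------------------------------------------------------------------


def one_sample_t(maps: np.ndarray) -> np.ndarray:
    """t map against 0 over the first (participant) axis; zero-variance
    points are NaN, never +/-inf."""
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def paired_t(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Paired t map on per-participant differences."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired maps must share a shape")
    return one_sample_t(a - b)


# --------------------------------------------------------------------------
# adjacency and clustering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected channel adjacency from a sensor-distance threshold."""

    n_channels: int
    edges: tuple[tuple[int, int], ...]  # i < j, no self-edges

    def neighbor_pairs(self) -> np.ndarray:
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.asarray(self.edges, dtype=int)


def build_adjacency(positions: np.ndarray, threshold: float) -> AdjacencyGraph:
    """Edge iff Euclidean sensor distance < threshold (strict)."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2:
        raise ValueError("positions must be (n_channels, n_dims)")
    if not np.all(np.isfinite(pos)):
        raise ValueError("missing (non-finite) channel position")
    n = pos.shape[0]
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    edges = tuple(
        (i, j) for i in range(n) for j in range(i + 1, n) if d[i, j] < threshold
    )
    return AdjacencyGraph(n_channels=n, edges=edges)


def grid_adjacency(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """4-neighbour adjacency for sensors on a regular grid (row-major)."""
    pos = np.array([(r, c) for r in range(n_rows) for c in range(n_cols)], dtype=float)
    return build_adjacency(pos, threshold=1.5)


def _cluster_masses(
    stat: np.ndarray, mask: np.ndarray, adj_pairs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a suprathreshold (channels x time) mask.

    Connectivity joins same-channel temporal neighbours and same-time
    spatially adjacent channels. Returns (per-node cluster labels for nodes
    in the mask order of np.flatnonzero, cluster masses).
    """
    n_ch, n_t = stat.shape
    flat_mask = mask.ravel()
    n_nodes = int(flat_mask.sum())
    if n_nodes == 0:
        return np.array([], dtype=int), np.array([])
    node_id = -np.ones(n_ch * n_t, dtype=np.int64)
    node_id[flat_mask] = np.arange(n_nodes)
    nid = node_id.reshape(n_ch, n_t)

    rows, cols = [], []
    temporal = mask[:, :-1] & mask[:, 1:]
    if temporal.any():
        a = nid[:, :-1][temporal]
        b = nid[:, 1:][temporal]
        rows.append(a)
        cols.append(b)
    for i, j in adj_pairs:
        both = mask[i] & mask[j]
        if both.any():
            rows.append(nid[i][both])
            cols.append(nid[j][both])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = sparse.coo_matrix(
            (np.ones(r.size, dtype=np.int8), (r, c)), shape=(n_nodes, n_nodes)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n_nodes)
    masses = np.bincount(labels, weights=stat.ravel()[flat_mask])
    return labels, masses


@dataclass
class Cluster:
    channels: np.ndarray  # node channel indices
    times: np.ndarray  # node time indices
    mass: float
    p_value: float = np.nan
    sign: int = 1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    seed: int
    threshold: float
    max_mass_null: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=np.nan)


def _find_signed_clusters(
    t_map: np.ndarray, threshold: float, adj_pairs: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """Positive and negative suprathreshold clusters of a signed map."""
    out = []
    finite = np.nan_to_num(t_map, nan=0.0)
    for sign in (1, -1):
        mask = (sign * finite) > threshold
        labels, masses = _cluster_masses(sign * finite, mask, adj_pairs)
        if masses.size:
            ch_idx, t_idx = np.nonzero(mask)
            for k in range(masses.size):
                sel = labels == k
                out.append((ch_idx[sel], t_idx[sel], float(masses[k]), sign))
    return out


def _max_signed_mass(t_map: np.ndarray, threshold: float, adj_pairs: np.ndarray) -> float:
    best = 0.0
    finite = np.nan_to_num(t_map, nan=0.0)
    for sign in (1, -1):
        mask = (sign * finite) > threshold
        _, masses = _cluster_masses(sign * finite, mask, adj_pairs)
        if masses.size:
            best = max(best, float(masses.max()))
    return best


def _sign_flip_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for many sign-flip patterns at once.

    diffs: (n, P) flattened maps; signs: (R, n). Uses the sign-flip
    invariance of the per-point sum of squares.
    """
    n = diffs.shape[0]
    ss = (diffs**2).sum(axis=0)  # (P,)
    means = signs @ diffs / n  # (R, P)
    var = (ss[None, :] / n - means**2) * n / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation(
    data,
    design: Literal["one_sample_t", "paired_t", "one_way_F"],
    adjacency: AdjacencyGraph,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test over channels x time.

    Parameters
    ----------
    data
        ``one_sample_t``: array (n_subjects, n_channels, n_times).
        ``paired_t``: tuple (a, b) of such arrays; the test runs on a - b.
        ``one_way_F``: array (n_subjects, k_conditions, n_channels, n_times).
    design
        Statistic and permutation scheme. One-sample and paired designs use
        participant sign flips; the factorial design permutes condition
        labels within participants.
    adjacency
        Channel adjacency; temporal adjacency is implicit.
    cluster_alpha
        Parametric quantile for the cluster-forming threshold (two-sided for
        t statistics).
    n_permutations
        Monte-Carlo permutations; if the exact relabelling group is smaller,
        it is enumerated exhaustively instead.

    Cluster p-values use the max-mass null:
    ``p = (1 + #{perm max mass >= observed}) / (n_used + 1)``.
    """
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse p-value floor")
    rng = np.random.default_rng(seed)
    adj_pairs = adjacency.neighbor_pairs()

    if design == "paired_t":
        a, b = data
        X = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        design = "one_sample_t"
    elif design == "one_sample_t":
        X = np.asarray(data, dtype=float)
    if design == "one_sample_t":
        n, n_ch, n_t = X.shape
        if n_ch != adjacency.n_channels:
            raise ValueError("adjacency does not match channel count")
        threshold = float(sstats.t.ppf(1 - cluster_alpha / 2, df=n - 1))
        t_obs = one_sample_t(X)
        found = _find_signed_clusters(t_obs, threshold, adj_pairs)

        flat = X.reshape(n, -1)
        if 2**n <= n_permutations:
            signs = np.array(
                [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)],
                dtype=float,
            )
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        null = np.empty(signs.shape[0])
        chunk = 200  # bound the (R, P) scratch array
        t_shape = (n_ch, n_t)
        pos = 0
        for lo in range(0, signs.shape[0], chunk):
            t_perm = _sign_flip_t(flat, signs[lo : lo + chunk])
            for r in range(t_perm.shape[0]):
                null[pos] = _max_signed_mass(t_perm[r].reshape(t_shape), threshold, adj_pairs)
                pos += 1
        n_used = signs.shape[0]
    elif design == "one_way_F":
        X = np.asarray(data, dtype=float)
        n, k, n_ch, n_t = X.shape
        if n_ch != adjacency.n_channels:
            raise ValueError("adjacency does not match channel count")
        df1, df2 = k - 1, (k - 1) * (n - 1)
        threshold = float(sstats.f.ppf(1 - cluster_alpha, df1, df2))

        def f_map(Y: np.ndarray) -> np.ndarray:
            cell = Y.mean(axis=0)  # (k, P)
            grand = cell.mean(axis=0)
            subj = Y.mean(axis=1)  # (n, P)
            ss_a = n * ((cell - grand) ** 2).sum(axis=0)
            resid = Y - cell[None] - subj[:, None, :] + grand[None, None, :]
            ss_err = (resid**2).sum(axis=(0, 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ss_a / df1) / (ss_err / df2)
            return np.nan_to_num(F, nan=0.0, posinf=0.0, neginf=0.0)

        flat = X.reshape(n, k, -1)
        F_obs = f_map(flat).reshape(n_ch, n_t)
        mask = F_obs > threshold
        found = []
        labels, masses = _cluster_masses(F_obs, mask, adj_pairs)
        if masses.size:
            ch_idx, t_idx = np.nonzero(mask)
            for kk in range(masses.size):
                sel = labels == kk
                found.append((ch_idx[sel], t_idx[sel], float(masses[kk]), 1))

        null = np.empty(n_permutations)
        for r in range(n_permutations):
            perm = np.empty_like(flat)
            for i in range(n):
                perm[i] = flat[i, rng.permutation(k)]
            F_p = f_map(perm).reshape(n_ch, n_t)
            m = F_p > threshold
            _, ms = _cluster_masses(F_p, m, adj_pairs)
            null[r] = float(ms.max()) if ms.size else 0.0
        n_used = n_permutations
    else:
        raise ValueError(f"unknown design {design!r}")

    clusters = []
    for ch_idx, t_idx, mass, sign in found:
        p = (1.0 + float((null >= mass).sum())) / (n_used + 1.0)
        clusters.append(Cluster(channels=ch_idx, times=t_idx, mass=mass, p_value=p, sign=sign))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_used,
        seed=seed,
        threshold=threshold,
        max_mass_null=null,
    )


# --------------------------------------------------------------------------
# null calibration of the cluster test
# --------------------------------------------------------------------------


def _pink_noise_stack(rng: np.random.Generator, shape: tuple[int, ...], n_times: int, exponent: float = 1.0) -> np.ndarray:
    """Independent 1/f noise series along the last axis."""
    white = rng.standard_normal(shape + (n_times,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n_times, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def cluster_fwer_null(
    seed: int,
    n_datasets: int = 200,
    n_subjects: int = 15,
    n_channels: int = 16,
    n_times: int = 100,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error of the paired cluster test under a pure-noise null.

    Simulates paired two-condition datasets of pink noise with no injected
    effect and counts how often any cluster reaches p < alpha. Returns the
    empirical FWER together with the binomial context.
    """
    adj = grid_adjacency(4, n_channels // 4)
    rng = np.random.default_rng(seed)
    false_positives = 0
    for d in range(n_datasets):
        a = _pink_noise_stack(rng, (n_subjects, n_channels), n_times)
        b = _pink_noise_stack(rng, (n_subjects, n_channels), n_times)
        res = cluster_permutation(
            (a, b),
            design="paired_t",
            adjacency=adj,
            n_permutations=n_permutations,
            cluster_alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        if res.clusters and res.min_p < alpha:
            false_positives += 1
    fwer = false_positives / n_datasets
    return {
        "fwer": fwer,
        "n_datasets": n_datasets,
        "false_positives": false_positives,
        "alpha": alpha,
        "binom_upper95": float(sstats.binom.ppf(0.975, n_datasets, alpha) / n_datasets),
    }


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------


def report_tables(
    results: Sequence[AnovaResult], family_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """One row per effect: F, dfs (raw and GG), p, p_gg, p_fdr, eta_p^2.

    ``family_map`` assigns effects to FDR families; BH adjustment is applied
    within each family.
    """
    rows = []
    for r in results:
        fam = r.family_id
        if family_map and r.effect in family_map:
            fam = family_map[r.effect]
        rows.append(
            {
                "effect": r.effect,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "gg_epsilon": r.gg_epsilon,
                "df1_gg": r.df1_gg,
                "df2_gg": r.df2_gg,
                "p": r.p_uncorrected,
                "p_gg": r.p_gg,
                "partial_eta_sq": r.partial_eta_sq,
                "family_id": fam if fam is not None else "all",
                "n_participants": r.n_participants,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "effect", "F", "df1", "df2", "gg_epsilon", "df1_gg", "df2_gg",
            "p", "p_gg", "partial_eta_sq", "family_id", "n_participants",
        ],
    )
    if len(df):
        df["p_fdr"] = bh_fdr(df["p_gg"].to_numpy(), df["family_id"].to_numpy())
    else:
        df["p_fdr"] = pd.Series(dtype=float)
    return df
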