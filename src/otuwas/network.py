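"""Compositional correlation (SparCC), co-abundance groups and PERMANOVA.

SparCC infers correlations between the unobserved basis abundances from the
variances of pairwise log-ratios, t_ij = Var(log x_i / x_j). Under sparsity
the basis variances omega solve the linear system obtained by summing t_ij
over included partners; strongly correlated pairs are excluded from the sums
iteratively and the system re-solved. Each repetition perturbs the observed
counts to fractions with a Dirichlet draw (pseudocount 1) and the final
correlation matrix is the elementwise median over repetitions.

Significance is assessed with a bootstrap that shuffles each OTU's counts
independently across samples, destroying correlation while preserving
marginals; edges are kept at p < 0.05 and |r| > 0.4, clustered into
co-abundance groups with Ward linkage on d = (1 - r)/2, and the partition is
validated by PERMANOVA on the same distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import OtuCountTable, PhenotypeFrame, RelAbundanceTable

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.4
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_N_BOOT = 100
DEFAULT_PERMANOVA_PERM = 999


@dataclass
class CorrelationNetwork:
    otu_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    edges: list[tuple[str, str, float, float]]
    cag_labels: dict[str, int]
    permanova: tuple[float, float, int] | None = None


@dataclass
class CagAssociation:
    cag_id: int
    abundance: np.ndarray = field(repr=False)
    spearman_rho: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")


def _solve_basis(T: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Basis variances from the log-ratio variance system restricted to the
    included pair set. Non-positive solutions are clipped with a warning."""
    deg = include.sum(axis=1).astype(float)
    A = include.astype(float)
    A[np.diag_indices_from(A)] = deg
    t_vec = (T * include).sum(axis=1)
    omega, *_ = np.linalg.lstsq(A, t_vec, rcond=None)
    if (omega <= 0).any():
        logger.warning("clipping %d non-positive basis variances", int((omega <= 0).sum()))
        floor = max(np.median(omega[omega > 0]) if (omega > 0).any() else 1.0, 1e-12) * 1e-6
        omega = np.maximum(omega, floor)
    return omega


def _corr_from_basis(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2 * np.sqrt(np.outer(omega, omega))
    r = (omega[:, None] + omega[None, :] - T) / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _sparcc_once(
    fractions: np.ndarray, n_exclude_iter: int, exclude_threshold: float
) -> np.ndarray:
    """One SparCC estimate from a fraction matrix (samples x OTUs)."""
    m = fractions.shape[1]
    L = np.log(fractions)
    V = np.cov(L, rowvar=False)
    d = np.diag(V)
    T = d[:, None] + d[None, :] - 2 * V
    include = ~np.eye(m, dtype=bool)
    omega = _solve_basis(T, include)
    r = _corr_from_basis(T, omega)
    for _ in range(n_exclude_iter):
        cand = np.abs(np.where(include, r, 0.0))
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclude_threshold:
            break
        include[i, j] = include[j, i] = False
        if (include.sum(axis=1) < 2).any():
            include[i, j] = include[j, i] = True
            break
        omega = _solve_basis(T, include)
        r = _corr_from_basis(T, omega)
    return r


def sparcc(
    counts: OtuCountTable,
    n_inner: int = 20,
    n_exclude_iter: int = 20,
    exclude_threshold: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """SparCC correlation matrix for the given OTU panel.

    Deterministic given ``seed``; the returned matrix is symmetric with unit
    diagonal, clipped to [-1, 1].
    """
    m = len(counts.otu_ids)
    if m < 4:
        raise ValueError(f"SparCC needs >= 4 OTUs, got {m}")
    rng = np.random.default_rng(seed)
    reps = np.empty((n_inner, m, m))
    alpha = counts.counts + 1.0
    for it in range(n_inner):
        fractions = np.vstack([rng.dirichlet(alpha[i]) for i in range(alpha.shape[0])])
        reps[it] = _sparcc_once(fractions, n_exclude_iter, exclude_threshold)
    r = np.median(reps, axis=0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def sparcc_bootstrap_p(
    counts: OtuCountTable,
    r_obs: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    n_inner: int = 20,
    n_exclude_iter: int = 20,
    exclude_threshold: float = 0.1,
) -> np.ndarray:
    """Two-sided bootstrap pseudo-p-values for SparCC correlations.

    Each bootstrap dataset shuffles every OTU's counts independently across
    samples; p = (1 + #{|r_boot| >= |r_obs|}) / (1 + n_boot), so the smallest
    attainable value is 1/(1 + n_boot).
    """
    if n_boot < 50:
        raise ValueError(f"n_boot must be >= 50, got {n_boot}")
    rng = np.random.default_rng(seed)
    n, m = counts.counts.shape
    exceed = np.zeros((m, m))
    abs_obs = np.abs(r_obs)
    for b in range(n_boot):
        shuffled = np.empty_like(counts.counts)
        for j in range(m):
            shuffled[:, j] = counts.counts[rng.permutation(n), j]
        boot_tbl = OtuCountTable(list(counts.sample_ids), list(counts.otu_ids), shuffled)
        r_b = sparcc(
            boot_tbl,
            n_inner=n_inner,
            n_exclude_iter=n_exclude_iter,
            exclude_threshold=exclude_threshold,
            seed=int(rng.integers(2**31 - 1)),
        )
        exceed += np.abs(r_b) >= abs_obs
    p = (1 + exceed) / (1 + n_boot)
    np.fill_diagonal(p, 1.0)
    return p


def build_network(
    r: np.ndarray,
    p: np.ndarray,
    otu_ids: list[str],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[tuple[str, str, float, float]]:
    """Edges (a, b, r, p) with p < p_threshold and |r| > r_threshold (strict)."""
    if r.shape != p.shape or r.shape[0] != len(otu_ids):
        raise ValueError("correlation and p matrices misaligned with OTU ids")
    edges = []
    m = len(otu_ids)
    for i in range(m):
        for j in range(i + 1, m):
            if p[i, j] < p_threshold and abs(r[i, j]) > r_threshold:
                edges.append((otu_ids[i], otu_ids[j], float(r[i, j]), float(p[i, j])))
    return edges


def cluster_cags(r: np.ndarray, otu_ids: list[str], k: int = 2) -> dict[str, int]:
    """Ward clustering of OTUs on d = (1 - r)/2, cut into k co-abundance groups.

    Labels are renumbered so CAG 1 contains the lexicographically smallest
    OTU id, CAG 2 the smallest id outside CAG 1, and so on.
    """
    m = len(otu_ids)
    if k > m:
        raise ValueError(f"k={k} exceeds number of OTUs ({m})")
    d = (1.0 - r) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # stable renumbering by each cluster's smallest member id
    order = sorted(set(raw), key=lambda c: min(otu_ids[i] for i in np.flatnonzero(raw == c)))
    remap = {c: rank + 1 for rank, c in enumerate(order)}
    return {otu: remap[c] for otu, c in zip(otu_ids, raw)}


def _permanova_f(d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    k = len(uniq)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: np.ndarray,
    labels,
    n_perm: int = DEFAULT_PERMANOVA_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """Pseudo-F and permutation p-value for a grouping on a distance matrix.

    SS terms use squared distances; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    groups = np.asarray(labels)
    if len(groups) != n:
        raise ValueError("labels length does not match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("singleton group not allowed in PERMANOVA")
    d2 = d**2
    if d2[np.triu_indices(n, 1)].sum() == 0:
        raise ValueError("all points identical: pseudo-F undefined")
    f_obs = _permanova_f(d2, groups, uniq)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = groups[rng.permutation(n)]
        f_p = _permanova_f(d2, perm, uniq)
        if np.isnan(f_p):
            continue
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def cag_phenotype_assoc(
    rel: RelAbundanceTable,
    cag_labels: dict[str, int],
    pheno: PhenotypeFrame,
) -> list[CagAssociation]:
    """Spearman association of per-sample CAG abundance with the phenotype.

    CAG abundance is the sum of member OTU relative abundances (the mean is a
    monotone rescaling, so the choice does not affect rho). q-values are
    Benjamini-Hochberg across CAGs.
    """
    missing = [o for o in cag_labels if o not in rel.otu_ids]
    if missing:
        raise ValueError(f"CAG members missing from abundance table: {missing[:5]}")
    y = pheno.phenotype_adj(list(rel.sample_ids))
    col = {o: i for i, o in enumerate(rel.otu_ids)}
    out = []
    for cag in sorted(set(cag_labels.values())):
        members = [col[o] for o, c in cag_labels.items() if c == cag]
        ab = rel.abundances[:, members].sum(axis=1)
        rho, p = stats.spearmanr(ab, y)
        out.append(CagAssociation(cag_id=cag, abundance=ab, spearman_rho=float(rho), p=float(p)))
    pvals = np.array([c.p for c in out])
    qvals = stats.false_discovery_control(pvals, method="bh")
    for c, q in zip(out, qvals):
        c.q = float(q)
    return out


def write_edges_tsv(edges: list[tuple[str, str, float, float]], path) -> None:
    import pandas as pd

    pd.DataFrame(edges, columns=["source", "target", "r", "p"]).to_csv(path, sep="\t", index=False)


def write_graphml(edges, cag_labels: dict[str, int], path) -> None:
    import networkx as nx

    g = nx.Graph()
    for otu, cag in sorted(cag_labels.items()):
        g.add_node(otu, cag=int(cag))
    for a, b, r, p in edges:
        g.add_edge(a, b, r=float(r), p=float(p))
    nx.write_graphml(g, path)
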