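"""Two-part association of OTU abundances with a continuous phenotype.

Per OTU the model has two components fitted on the covariate-adjusted
phenotype:

* binary — OLS of the phenotype on the presence/absence indicator, which is
  algebraically a pooled-variance two-sample t-test;
* quantitative — OLS of the phenotype on the log relative abundance
  (standardized to mean 0, sd 1) among the samples where the OTU is present.

The two z-scores (signed by effect direction) are combined with the
unweighted-Z method, z_meta = (z1 + z2)/sqrt(2), and the final per-OTU
p-value is the minimum of the defined component p-values. Because min-P is
anticonservative, the false discovery rate is estimated by permuting the
adjusted phenotype across samples and re-running the full scan.

Internals are vectorized over OTUs and over phenotype permutations: the
binary and quantitative OLS statistics for every OTU reduce to a handful of
matrix products against the (possibly permuted) phenotype matrix, which is
what makes 1000-permutation FDR estimation cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import PhenotypeFrame, RelAbundanceTable

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # numerical floor; keeps log/z transforms finite
DEFAULT_MIN_GROUP = 5  # smallest present/absent group for the binary fit
DEFAULT_MIN_PRESENT = 10  # smallest detected subset for the quantitative fit


@dataclass
class TwoPartResult:
    """Per-OTU two-part statistics; undefined components are None/NaN."""

    otu_id: str
    n_present: int
    presence_fraction: float
    beta1: float | None = None
    se1: float | None = None
    z1: float | None = None
    p_binary: float | None = None
    beta2: float | None = None
    se2: float | None = None
    z2: float | None = None
    p_quant: float | None = None
    z_meta: float | None = None
    p_meta: float | None = None
    p_final: float = 1.0
    q_value: float = float("nan")
    direction: int = 0
    # log-abundance moments among present samples, frozen at fit time; the
    # additive prediction model reuses them to transform new samples.
    q_mu: float = float("nan")
    q_sd: float = float("nan")


def _z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed z with |z| = Phi^-1(1 - p/2)."""
    return np.where(sign < 0, -1.0, 1.0) * stats.norm.isf(np.maximum(p, P_FLOOR) / 2)


def _p_two_sided_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(t), df)
    return np.clip(p, P_FLOOR, 1.0)


def transform_quant(
    abundances: np.ndarray, presence: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized log abundance among present samples, per OTU.

    Returns (X, mu, sd): X is zero where the OTU is absent and the
    (log a - mu)/sd score where present; mu/sd (ddof=1) are the frozen
    transform parameters. OTUs with < 2 present samples or zero spread get
    sd = 0 and an all-zero column.
    """
    n, m = abundances.shape
    with np.errstate(divide="ignore"):
        la = np.where(presence, np.log(abundances, where=presence, out=np.zeros_like(abundances, dtype=float)), 0.0)
    n_present = presence.sum(axis=0)
    safe_np = np.maximum(n_present, 1)
    mu = la.sum(axis=0) / safe_np
    centered = np.where(presence, la - mu, 0.0)
    ss = (centered**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(ss / np.maximum(n_present - 1, 1))
    sd = np.where(n_present < 2, 0.0, sd)
    X = np.where((presence) & (sd > 0), centered / np.where(sd > 0, sd, 1.0), 0.0)
    return X, mu, sd


def _scan_stats(
    presence: np.ndarray,
    Xq: np.ndarray,
    Y: np.ndarray,
    min_group: int = DEFAULT_MIN_GROUP,
    min_present: int = DEFAULT_MIN_PRESENT,
) -> dict[str, np.ndarray]:
    """Vectorized two-part statistics.

    presence: (n, m) boolean; Xq: (n, m) standardized log abundance, zero
    where absent (zero column marks an undefined quantitative fit);
    Y: (n, K) phenotype columns. Returns arrays of shape (m, K); undefined
    entries are NaN except p_final which falls back to 1.
    """
    n, m = presence.shape
    B = presence.astype(float)
    n1 = B.sum(axis=0)  # present
    n0 = n - n1
    Y2 = Y**2
    S1 = B.T @ Y  # (m, K) sum of y among present
    Q1 = B.T @ Y2
    tot = Y.sum(axis=0)  # (K,)
    qtot = Y2.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = S1 / n1[:, None]
        mean0 = (tot[None, :] - S1) / n0[:, None]
        ss1 = Q1 - S1**2 / n1[:, None]
        ss0 = (qtot[None, :] - Q1) - (tot[None, :] - S1) ** 2 / n0[:, None]
        sp2 = (ss1 + ss0) / (n - 2)
        se1 = np.sqrt(sp2 * (1 / n1 + 1 / n0)[:, None])
        beta1 = mean1 - mean0
        t1 = beta1 / se1
    df1 = np.full(m, n - 2.0)
    p_binary = _p_two_sided_t(t1, df1[:, None])
    # se = 0 with a nonzero effect is a perfect separation: t = +-inf gives
    # the floor p; only 0/0 (constant phenotype within groups) is undefined
    bin_ok = (np.minimum(n1, n0) >= min_group) & (n >= 3)
    bin_ok = bin_ok[:, None] & ~np.isnan(t1)

    sxx = (Xq**2).sum(axis=0)  # = n_present - 1 after standardization
    sxy = Xq.T @ Y  # (m, K); sum x = 0 among present
    with np.errstate(divide="ignore", invalid="ignore"):
        syy = Q1 - S1**2 / n1[:, None]
        beta2 = sxy / sxx[:, None]
        sse = syy - sxy**2 / sxx[:, None]
        df2 = n1 - 2.0
        se2 = np.sqrt(np.maximum(sse, 0.0) / df2[:, None] / sxx[:, None])
        t2 = beta2 / se2
    p_quant = _p_two_sided_t(t2, df2[:, None])
    quant_ok = (n1 >= min_present) & (sxx > 0)
    quant_ok = quant_ok[:, None] & ~np.isnan(t2)

    z1 = _z_from_p(p_binary, np.sign(beta1))
    z2 = _z_from_p(p_quant, np.sign(beta2))
    z_meta = (z1 + z2) / np.sqrt(2.0)
    p_meta = np.clip(2 * stats.norm.sf(np.abs(z_meta)), P_FLOOR, 1.0)
    meta_ok = bin_ok & quant_ok

    p_final = np.where(bin_ok, p_binary, np.inf)
    p_final = np.minimum(p_final, np.where(quant_ok, p_quant, np.inf))
    p_final = np.minimum(p_final, np.where(meta_ok, p_meta, np.inf))
    p_final = np.where(np.isfinite(p_final), p_final, 1.0)

    nan = np.nan
    return {
        "n_present": n1.astype(int),
        "beta1": np.where(bin_ok, beta1, nan),
        "se1": np.where(bin_ok, se1, nan),
        "z1": np.where(bin_ok, z1, nan),
        "p_binary": np.where(bin_ok, p_binary, nan),
        "beta2": np.where(quant_ok, beta2, nan),
        "se2": np.where(quant_ok, se2, nan),
        "z2": np.where(quant_ok, z2, nan),
        "p_quant": np.where(quant_ok, p_quant, nan),
        "z_meta": np.where(meta_ok, z_meta, nan),
        "p_meta": np.where(meta_ok, p_meta, nan),
        "p_final": p_final,
    }


def binary_component(
    presence: np.ndarray, pheno_adj: np.ndarray, min_group: int = DEFAULT_MIN_GROUP
) -> tuple[float, float, float, float] | None:
    """(beta1, se1, z1, p) for phenotype ~ presence, or None if undefined."""
    presence = np.asarray(presence, dtype=bool).reshape(-1, 1)
    y = np.asarray(pheno_adj, dtype=float).reshape(-1, 1)
    if np.ptp(y) == 0:
        logger.info("binary component undefined: constant phenotype")
        return None
    s = _scan_stats(presence, np.zeros_like(presence, dtype=float), y, min_group=min_group)
    if np.isnan(s["p_binary"][0, 0]):
        return None
    return tuple(float(s[k][0, 0]) for k in ("beta1", "se1", "z1", "p_binary"))


def quant_component(
    abundance: np.ndarray,
    pheno_adj: np.ndarray,
    min_present: int = DEFAULT_MIN_PRESENT,
    transform: str = "log",
) -> tuple[float, float, float, float] | None:
    """(beta2, se2, z2, p) for phenotype ~ transformed abundance among
    detected samples, or None if undefined."""
    abundance = np.asarray(abundance, dtype=float).reshape(-1, 1)
    y = np.asarray(pheno_adj, dtype=float).reshape(-1, 1)
    presence = abundance > 0
    Xq, _, sd = _build_quant_design(abundance, presence, transform)
    if sd[0] == 0:
        logger.info("quantitative component undefined: zero abundance spread")
        return None
    s = _scan_stats(presence, Xq, y, min_present=min_present)
    if np.isnan(s["p_quant"][0, 0]):
        return None
    return tuple(float(s[k][0, 0]) for k in ("beta2", "se2", "z2", "p_quant"))


def meta_component(z1: float | None, z2: float | None) -> tuple[float, float] | None:
    """Unweighted-Z combination of the two component z-scores."""
    if z1 is None or z2 is None:
        return None
    z = (z1 + z2) / np.sqrt(2.0)
    p = float(np.clip(2 * stats.norm.sf(abs(z)), P_FLOOR, 1.0))
    return float(z), p


def _rank_invnorm(la: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal scores among present samples, per OTU."""
    X = np.zeros_like(la)
    for j in range(la.shape[1]):
        idx = np.flatnonzero(presence[:, j])
        if idx.size < 2:
            continue
        r = stats.rankdata(la[idx, j])
        X[idx, j] = stats.norm.ppf((r - 0.375) / (idx.size + 0.25))
    return X


def _build_quant_design(
    abundances: np.ndarray, presence: np.ndarray, transform: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if transform == "log":
        return transform_quant(abundances, presence)
    if transform == "rank_invnorm":
        with np.errstate(divide="ignore"):
            la = np.where(presence, np.log(np.where(presence, abundances, 1.0)), 0.0)
        X = _rank_invnorm(la, presence)
        sd = np.where((X**2).sum(axis=0) > 0, 1.0, 0.0)
        return X, np.zeros(abundances.shape[1]), sd
    raise ValueError(f"unknown transform {transform!r}")


def _direction(row: dict) -> int:
    pf = row["p_final"]
    for p_key, eff_key in (("p_binary", "beta1"), ("p_quant", "beta2"), ("p_meta", "z_meta")):
        p = row[p_key]
        if p is not None and not np.isnan(p) and p == pf:
            eff = row[eff_key]
            return int(np.sign(eff)) if eff is not None and not np.isnan(eff) else 0
    return 0


def two_part_scan(
    rel: RelAbundanceTable,
    pheno: PhenotypeFrame,
    min_group: int = DEFAULT_MIN_GROUP,
    min_present: int = DEFAULT_MIN_PRESENT,
    transform: str = "log",
) -> list[TwoPartResult]:
    """Run the two-part model for every OTU against the adjusted phenotype."""
    if list(rel.sample_ids) != list(pheno.sample_ids):
        if set(rel.sample_ids) != set(pheno.sample_ids):
            raise ValueError("sample sets of abundance table and phenotype differ")
        pheno = pheno.select_samples(list(rel.sample_ids))
    y = pheno.phenotype_adj(list(rel.sample_ids)).reshape(-1, 1)
    presence = rel.abundances > 0
    Xq, mu, sd = _build_quant_design(rel.abundances, presence, transform)
    s = _scan_stats(presence, Xq, y, min_group=min_group, min_present=min_present)

    n = len(rel.sample_ids)
    results = []
    for j, otu in enumerate(rel.otu_ids):
        row = {k: (None if np.isnan(v[j, 0]) else float(v[j, 0])) for k, v in s.items() if k != "n_present"}
        row["p_final"] = float(s["p_final"][j, 0])
        res = TwoPartResult(
            otu_id=otu,
            n_present=int(s["n_present"][j]),
            presence_fraction=float(s["n_present"][j] / n),
            p_final=row["p_final"],
            q_mu=float(mu[j]),
            q_sd=float(sd[j]),
            **{k: row[k] for k in (
                "beta1", "se1", "z1", "p_binary",
                "beta2", "se2", "z2", "p_quant", "z_meta", "p_meta",
            )},
        )
        res.direction = _direction(row)
        results.append(res)
    return results


def _null_p_final(
    rel: RelAbundanceTable,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_group: int,
    min_present: int,
    transform: str,
    chunk: int = 250,
) -> np.ndarray:
    """p_final matrix (n_perm, m) under phenotype permutation."""
    presence = rel.abundances > 0
    Xq, _, _ = _build_quant_design(rel.abundances, presence, transform)
    n = len(y)
    out = np.empty((n_perm, len(rel.otu_ids)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        Y = np.empty((n, k))
        for c in range(k):
            Y[:, c] = y[rng.permutation(n)]
        s = _scan_stats(presence, Xq, Y, min_group=min_group, min_present=min_present)
        out[done : done + k] = s["p_final"].T
        done += k
    return out


def permutation_fdr(
    scan: list[TwoPartResult],
    rel: RelAbundanceTable,
    pheno: PhenotypeFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_group: int = DEFAULT_MIN_GROUP,
    min_present: int = DEFAULT_MIN_PRESENT,
    transform: str = "log",
) -> np.ndarray:
    """Permutation-based q-values for the min-P statistic.

    The adjusted phenotype is permuted across samples ``n_perm`` times
    (preserving the inter-OTU correlation structure) and the full two-part
    scan re-run. For each observed p_final threshold t,
    FDR(t) = mean null count of {p <= t} / max(1, observed count), and the
    q-value is the step-up monotonization min over t' >= t, capped at 1.
    The q-values are also written back onto the scan results.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    y = pheno.phenotype_adj(list(rel.sample_ids))
    null_p = _null_p_final(rel, y, n_perm, rng, min_group, min_present, transform)
    pool = np.sort(null_p.ravel())

    obs = np.array([r.p_final for r in scan])
    order = np.argsort(obs, kind="stable")
    sorted_p = obs[order]
    # observed count of p <= t must use the rightmost index among ties
    r_obs = np.searchsorted(sorted_p, sorted_p, side="right")
    e_null = np.searchsorted(pool, sorted_p, side="right") / n_perm
    fdr = e_null / np.maximum(r_obs, 1)
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    for r, qv in zip(scan, q):
        r.q_value = float(qv)
    return q


def results_to_frame(scan: list[TwoPartResult]):
    """Flatten scan results to a DataFrame (one row per OTU)."""
    import pandas as pd

    cols = [
        "otu_id", "n_present", "presence_fraction",
        "beta1", "se1", "z1", "p_binary",
        "beta2", "se2", "z2", "p_quant",
        "z_meta", "p_meta", "p_final", "q_value", "direction",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in scan])
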