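"""Spearman + FDR screening of per-sample feature tables against the phenotype.

Applies to any samples-by-features relative-abundance table — in practice
predicted KEGG Orthology (KO) or pathway profiles — and reports, per feature,
the Spearman correlation with the covariate-adjusted phenotype, its two-sided
p-value, and a Benjamini-Hochberg q-value across the table. The significant
set uses the joint rule q < 0.05 and |rho| > 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeFrame

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.3
DEFAULT_Q_THRESHOLD = 0.05


@dataclass
class FeatureAssociation:
    feature_id: str
    rho: float
    p: float
    q: float = float("nan")

    @property
    def direction(self) -> int:
        return int(np.sign(self.rho))


def spearman_scan(
    features: pd.DataFrame,
    pheno: PhenotypeFrame,
    r_threshold: float = DEFAULT_RHO_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> tuple[list[FeatureAssociation], list[FeatureAssociation]]:
    """Rank-correlate every feature column with the adjusted phenotype.

    Ties get average ranks; p-values come from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)). Constant features are excluded with a
    logged reason. Returns (all associations, significant sublist).
    """
    sample_ids = [str(s) for s in features.index]
    y = pheno.phenotype_adj(sample_ids)
    X = features.to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for a Spearman scan")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        logger.info(
            "excluding %d constant features: %s",
            int(const.sum()),
            list(features.columns[const][:5]),
        )
    keep = np.flatnonzero(~const)
    rx = stats.rankdata(X[:, keep], axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    rho = np.clip((rx * ry[:, None]).sum(axis=0) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = np.clip(2 * stats.t.sf(np.abs(t), n - 2), 1e-300, 1.0)
    q = stats.false_discovery_control(p, method="bh")
    all_assoc = [
        FeatureAssociation(str(features.columns[j]), float(r_), float(p_), float(q_))
        for j, r_, p_, q_ in zip(keep, rho, p, q)
    ]
    significant = [a for a in all_assoc if a.q < q_threshold and abs(a.rho) > r_threshold]
    return all_assoc, significant


def associations_to_frame(assoc: list[FeatureAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_id": a.feature_id, "rho": a.rho, "p": a.p, "q": a.q, "direction": a.direction}
            for a in assoc
        ]
    )
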