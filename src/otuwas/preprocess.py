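"""Rarefaction, OTU filtering, relative abundance and phenotype residualization.

The processing order follows the study design: rarefy counts to a common
library size, convert to proportions, then drop OTUs that are too rare in
mean abundance (< 0.05% by default) or prevalence (< 5% of analyzed samples).
Abundances are intentionally NOT renormalized after filtering, so the
per-OTU fractions keep their original meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import OtuCountTable, PhenotypeFrame, RelAbundanceTable

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 40_000
DEFAULT_MIN_MEAN_ABUNDANCE = 0.0005  # 0.05 %
DEFAULT_MIN_PREVALENCE = 0.05  # 5 % of analyzed samples


@dataclass
class FilterReport:
    """Accounting of the abundance/prevalence filter.

    An OTU failing both rules is attributed to the abundance rule only, so
    the two removal counts partition ``removed_ids``.
    """

    n_input_otus: int
    n_removed_abundance: int
    n_removed_prevalence: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_otus": self.n_input_otus,
            "n_removed_abundance": self.n_removed_abundance,
            "n_removed_prevalence": self.n_removed_prevalence,
            "n_retained": self.n_retained,
            "removed_ids": list(self.removed_ids),
        }


def rarefy(table: OtuCountTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0) -> OtuCountTable:
    """Subsample every sample to ``depth`` tags without replacement.

    Samples whose library is smaller than ``depth`` are dropped with a logged
    warning. Sampling is multivariate hypergeometric per sample, so a sample
    whose library size equals ``depth`` is returned unchanged. Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=1)
    keep = sums >= depth
    if not keep.all():
        dropped = [table.sample_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((len(sample_ids), len(table.otu_ids)), dtype=np.int64)
    for r, i in enumerate(np.flatnonzero(keep)):
        row = table.counts[i]
        if sums[i] == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
    return OtuCountTable(sample_ids, list(table.otu_ids), out)


def to_relative(table: OtuCountTable) -> RelAbundanceTable:
    """Convert counts to per-sample fractions (rows sum to 1)."""
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"all-zero sample rows: {bad}")
    ab = table.counts / sums[:, None]
    return RelAbundanceTable(list(table.sample_ids), list(table.otu_ids), ab)


def filter_otus(
    rel: RelAbundanceTable,
    min_mean_abundance: float = DEFAULT_MIN_MEAN_ABUNDANCE,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    abundance_stat: str = "mean",
) -> tuple[RelAbundanceTable, FilterReport]:
    """Drop OTUs below the abundance or prevalence threshold (both inclusive
    on the keep side: an OTU is retained iff its abundance statistic is
    >= ``min_mean_abundance`` AND its prevalence is >= ``min_prevalence``).

    ``abundance_stat`` selects the per-OTU summary compared with the
    abundance threshold: ``mean`` (default) or ``max`` across samples.
    The surviving abundances are not renormalized.
    """
    for t in (min_mean_abundance, min_prevalence):
        if not 0 <= t <= 1:
            raise ValueError(f"thresholds must lie in [0, 1], got {t}")
    if abundance_stat not in ("mean", "max"):
        raise ValueError(f"unknown abundance_stat {abundance_stat!r}")
    stat = rel.abundances.mean(axis=0) if abundance_stat == "mean" else rel.abundances.max(axis=0)
    prevalence = (rel.abundances > 0).mean(axis=0)
    fail_abund = stat < min_mean_abundance
    fail_prev = prevalence < min_prevalence
    keep = ~(fail_abund | fail_prev)
    removed_ids = [o for o, k in zip(rel.otu_ids, keep) if not k]
    report = FilterReport(
        n_input_otus=len(rel.otu_ids),
        n_removed_abundance=int(fail_abund.sum()),
        n_removed_prevalence=int((fail_prev & ~fail_abund).sum()),
        n_retained=int(keep.sum()),
        removed_ids=removed_ids,
    )
    kept_ids = [o for o, k in zip(rel.otu_ids, keep) if k]
    filtered = RelAbundanceTable(
        list(rel.sample_ids), kept_ids, rel.abundances[:, keep], normalized=False
    )
    return filtered, report


def adjust_phenotype(pheno: PhenotypeFrame) -> PhenotypeFrame:
    """Residualize the raw weight on sex and cage (fixed effects, OLS).

    The design is an intercept, one sex indicator, and cage indicators with
    one reference level. Residuals have zero mean and are orthogonal to every
    design column; they are invariant to the categorical reference chosen.
    Rank-deficient designs (e.g. a sex perfectly nested in cages) are handled
    by the pseudoinverse fit with a logged warning.
    """
    df = pheno.data
    y = df["phenotype_raw"].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    if df["sex"].nunique() > 1:
        cols.append((df["sex"] == "male").to_numpy(dtype=float))
    if df["cage"].nunique() > 1:
        dummies = pd.get_dummies(df["cage"], drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("collinear sex/cage design; redundant columns absorbed by pinv fit")
    fit = sm.OLS(y, X).fit()
    out = df.copy()
    out["phenotype_adj"] = fit.resid
    return PhenotypeFrame(out)
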