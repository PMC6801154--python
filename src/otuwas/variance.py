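"""Cross-validated estimate of phenotypic variance explained by the microbiome.

The cohort is split repeatedly into an 80% discovery set and a 20% validation
set. On each discovery set the two-part scan estimates, per OTU, a binary
effect beta1 and a quantitative effect beta2 together with the log-abundance
standardization moments. OTUs passing a nominal p_final threshold form an
additive predictor evaluated on the held-out samples,

    r_m = sum_j (beta1_j * b_j + beta2_j * q_j),

where b_j is the presence indicator and q_j the discovery-standardized log
abundance when present (0 when absent). The explained variance at a threshold
is the squared Pearson correlation between r_m and the adjusted phenotype
over validation samples, averaged over repeats. Everything the predictor
needs — selection, effect sizes, transform moments — comes from discovery
samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PhenotypeFrame, RelAbundanceTable
from .twopart import TwoPartResult, two_part_scan

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1)
DEFAULT_N_REPEATS = 100


@dataclass
class AdditivePrediction:
    sample_id: str
    r_m: float


@dataclass
class VarianceCurve:
    thresholds: list[float]
    mean_r2: list[float]
    sd_r2: list[float]
    mean_n_otus: list[float]
    n_repeats: int
    seed: int
    per_repeat_r2: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_r2": self.mean_r2,
                "sd_r2": self.sd_r2,
                "mean_n_otus": self.mean_n_otus,
            }
        )


def cv_split(
    sample_ids: list[str], fraction_discovery: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive discovery/validation split; deterministic per seed."""
    if not 0 < fraction_discovery < 1:
        raise ValueError(f"fraction_discovery must lie in (0, 1), got {fraction_discovery}")
    n = len(sample_ids)
    if n < 10:
        raise ValueError(f"need >= 10 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_disc = int(round(fraction_discovery * n))
    disc = [sample_ids[i] for i in sorted(perm[:n_disc])]
    val = [sample_ids[i] for i in sorted(perm[n_disc:])]
    return disc, val


def additive_predict(
    rel_val: RelAbundanceTable,
    selected: list[TwoPartResult],
    formula: str = "product",
) -> list[AdditivePrediction]:
    """Additive microbiome prediction for each validation sample.

    Effect sizes and the log-abundance transform moments must come from the
    discovery-set scan (they are carried on the TwoPartResult records).
    Undefined components contribute 0. ``formula="literal"`` switches to the
    verbatim printed form sum_j (beta1 + b_j + beta2*q_j), kept for audit.
    """
    if formula not in ("product", "literal"):
        raise ValueError(f"unknown formula {formula!r}")
    col = {o: i for i, o in enumerate(rel_val.otu_ids)}
    missing = [r.otu_id for r in selected if r.otu_id not in col]
    if missing:
        raise ValueError(f"selected OTUs absent from validation table: {missing[:5]}")
    n = len(rel_val.sample_ids)
    r_m = np.zeros(n)
    for res in selected:
        a = rel_val.abundances[:, col[res.otu_id]]
        b = (a > 0).astype(float)
        if res.q_sd > 0:
            with np.errstate(divide="ignore"):
                q = np.where(a > 0, (np.log(np.where(a > 0, a, 1.0)) - res.q_mu) / res.q_sd, 0.0)
        else:
            q = np.zeros(n)
        beta1 = res.beta1 if res.beta1 is not None else 0.0
        beta2 = res.beta2 if res.beta2 is not None else 0.0
        if formula == "product":
            r_m += beta1 * b + beta2 * q
        else:
            r_m += beta1 + b + beta2 * q
    return [AdditivePrediction(s, float(v)) for s, v in zip(rel_val.sample_ids, r_m)]


def _r2(pred: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def explained_variance(
    rel: RelAbundanceTable,
    pheno: PhenotypeFrame,
    thresholds=DEFAULT_THRESHOLDS,
    n_repeats: int = DEFAULT_N_REPEATS,
    fraction_discovery: float = 0.8,
    seed: int = 0,
    min_group: int = 5,
    min_present: int = 10,
) -> VarianceCurve:
    """Repeated-CV variance-explained curve over nominal p_final thresholds.

    Per repeat: split, two-part scan on discovery only, select OTUs with
    p_final <= threshold, predict r_m on validation, and record the squared
    Pearson correlation with the adjusted phenotype (0 when r_m is constant).
    """
    thresholds = sorted(float(t) for t in thresholds)
    samples = list(rel.sample_ids)
    n_val = len(samples) - int(round(fraction_discovery * len(samples)))
    if n_val < 5:
        raise ValueError(f"validation set would have {n_val} (< 5) samples")
    rng = np.random.default_rng(seed)
    r2 = np.zeros((n_repeats, len(thresholds)))
    n_sel = np.zeros((n_repeats, len(thresholds)))
    for rep in range(n_repeats):
        disc_ids, val_ids = cv_split(samples, fraction_discovery, seed=int(rng.integers(2**31 - 1)))
        rel_d = rel.select_samples(disc_ids)
        rel_v = rel.select_samples(val_ids)
        scan = two_part_scan(
            rel_d, pheno.select_samples(disc_ids), min_group=min_group, min_present=min_present
        )
        y_val = pheno.phenotype_adj(val_ids)
        p_final = np.array([r.p_final for r in scan])
        for ti, t in enumerate(thresholds):
            sel = [r for r, p in zip(scan, p_final) if p <= t]
            n_sel[rep, ti] = len(sel)
            if not sel:
                r2[rep, ti] = 0.0
                continue
            preds = additive_predict(rel_v, sel)
            r2[rep, ti] = _r2(np.array([p.r_m for p in preds]), y_val)
    return VarianceCurve(
        thresholds=list(thresholds),
        mean_r2=list(r2.mean(axis=0)),
        sd_r2=list(r2.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(len(thresholds))),
        mean_n_otus=list(n_sel.mean(axis=0)),
        n_repeats=n_repeats,
        seed=seed,
        per_repeat_r2=r2,
    )
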