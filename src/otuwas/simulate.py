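"""Synthetic rarefied 16S count tables and phenotypes with known ground truth.

The generator mimics the structure every downstream stage assumes: each
sample's OTU profile comes from a multivariate log-normal basis with a
configurable correlation matrix, per-OTU structural zeros (Bernoulli presence
masks, so presence/absence is meaningful ground truth for the binary model),
compositional renormalization, and multinomial sequencing at a fixed library
depth — i.e. every simulated library is already rarefied.

The phenotype (weaning weight, grams) is a grand mean plus a sex effect, a
cage random intercept, planted per-OTU binary and quantitative effects, and
Gaussian noise. Defaults follow the study design scale: 135 animals in 90
cages (one or two sampled per cage), ~800 OTUs, 40 000 tags per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuCountTable, PhenotypeFrame

logger = logging.getLogger(__name__)


def block_correlation(n_otus: int, blocks: list[tuple[int, int, float]]) -> np.ndarray:
    """Correlation matrix with equicorrelated blocks.

    ``blocks`` is a list of (start, size, rho) in OTU-index space; everything
    outside the blocks is uncorrelated.
    """
    C = np.eye(n_otus)
    for start, size, rho in blocks:
        idx = np.arange(start, start + size)
        C[np.ix_(idx, idx)] = rho
        C[idx, idx] = 1.0
    return C


@dataclass
class SimulationConfig:
    n_samples: int = 135
    n_otus: int = 800
    library_depth: int = 40_000
    basis_correlation: np.ndarray | None = None  # identity when None
    log_mean: np.ndarray | float | None = None  # drawn N(0, 1.5^2) per OTU when None
    log_sd: np.ndarray | float = 1.0
    zero_inflation: np.ndarray | float | None = None  # per-OTU presence prob; U(0.2, 1) when None
    n_cages: int = 90
    grand_mean: float = 500.0  # grams, weaning weight scale
    sex_effect: float = 20.0  # grams added for males
    cage_sd: float = 30.0  # sd of cage random intercepts, grams
    noise_sd: float = 50.0  # residual sd, grams
    effects: list[tuple[int, float, float]] = field(default_factory=list)  # (otu, beta1 g, beta2 g/SD)
    seed: int = 0

    def validate(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.n_samples < 2 or self.n_otus < 1:
            raise ValueError("need at least 2 samples and 1 OTU")
        if self.basis_correlation is not None:
            C = np.asarray(self.basis_correlation)
            if C.shape != (self.n_otus, self.n_otus):
                raise ValueError("basis_correlation shape mismatch")
            ev = np.linalg.eigvalsh((C + C.T) / 2)
            if ev.min() <= -1e-10:
                raise ValueError("basis_correlation is not positive definite")
        if self.zero_inflation is not None:
            z = np.atleast_1d(np.asarray(self.zero_inflation, dtype=float))
            if (z <= 0).any() or (z > 1).any():
                raise ValueError("presence probabilities must lie in (0, 1]")


def simulate(config: SimulationConfig) -> tuple[OtuCountTable, PhenotypeFrame, dict]:
    """Draw one cohort: counts, metadata, and the planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_otus

    log_mean = config.log_mean
    if log_mean is None:
        log_mean = rng.normal(0.0, 1.5, size=m)
    log_mean = np.broadcast_to(np.asarray(log_mean, dtype=float), (m,)).copy()
    log_sd = np.broadcast_to(np.asarray(config.log_sd, dtype=float), (m,)).copy()
    presence_prob = config.zero_inflation
    if presence_prob is None:
        presence_prob = rng.uniform(0.2, 1.0, size=m)
    presence_prob = np.broadcast_to(np.asarray(presence_prob, dtype=float), (m,)).copy()

    Z = rng.standard_normal((n, m))
    if config.basis_correlation is not None:
        chol = np.linalg.cholesky(
            np.asarray(config.basis_correlation) + 1e-12 * np.eye(m)
        )
        Z = Z @ chol.T
    L = log_mean + log_sd * Z  # log basis abundance
    present = rng.random((n, m)) < presence_prob
    # guard: a sample with no present OTU keeps its most abundant one
    empty = ~present.any(axis=1)
    if empty.any():
        present[np.flatnonzero(empty), np.argmax(L[empty], axis=1)] = True
    basis = np.where(present, np.exp(L), 0.0)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(config.library_depth, fractions[i]) for i in range(n)]
    )
    # planted quantitative effects act on the realized composition (log
    # fraction), the scale every downstream analysis observes
    log_frac = np.where(present, np.log(np.where(present, fractions, 1.0)), 0.0)

    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    otu_ids = [f"OTU_{j+1:05d}" for j in range(m)]
    table = OtuCountTable(sample_ids, otu_ids, counts)

    n_male = int(round(n / 2))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex)
    cage_of = np.sort(np.arange(n) % config.n_cages)
    rng.shuffle(cage_of)
    cage_effects = rng.normal(0.0, config.cage_sd, size=config.n_cages)

    micro = np.zeros(n)
    effect_truth = []
    for otu_idx, beta1, beta2 in config.effects:
        b = present[:, otu_idx].astype(float)
        q = np.zeros(n)
        idx = np.flatnonzero(present[:, otu_idx])
        if idx.size >= 2:
            lx = log_frac[idx, otu_idx]
            sd = lx.std(ddof=1)
            if sd > 0:
                q[idx] = (lx - lx.mean()) / sd
        micro += beta1 * b + beta2 * q
        effect_truth.append({"otu_id": otu_ids[otu_idx], "beta1": beta1, "beta2": beta2})

    pheno = (
        config.grand_mean
        + config.sex_effect * (sex == "male")
        + cage_effects[cage_of]
        + micro
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    frame = PhenotypeFrame(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "sex": sex,
                "cage": [f"C{c+1:03d}" for c in cage_of],
                "phenotype_raw": pheno,
            }
        )
    )
    truth = {
        "effects": effect_truth,
        "presence_prob": presence_prob,
        "presence_mask": present,
        "log_basis": L,
        "microbiome_contribution": micro,
        "cage_effects": cage_effects,
        "sex_effect": config.sex_effect,
        "noise_sd": config.noise_sd,
    }
    return table, frame, truth


def simulate_features(
    pheno: PhenotypeFrame,
    n_features: int,
    effects: list[tuple[int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with chosen Spearman correlations to the phenotype.

    Correlated features are built through a Gaussian copula on the phenotype
    ranks; the Pearson latent correlation 2*sin(pi*rho_s/6) targets the
    requested Spearman rho_s. Null features are independent Gaussians.
    """
    effects = effects or []
    for _, rho in effects:
        if not abs(rho) < 1:
            raise ValueError("target Spearman correlations must satisfy |rho| < 1")
    rng = np.random.default_rng(seed)
    y = (
        pheno.phenotype_adj()
        if pheno.adjusted
        else pheno.data["phenotype_raw"].to_numpy(dtype=float)
    )
    n = len(y)
    from scipy import stats

    zy = stats.norm.ppf((stats.rankdata(y) - 0.375) / (n + 0.25))
    X = rng.standard_normal((n, n_features))
    for j, rho_s in effects:
        rho_p = 2 * np.sin(np.pi * rho_s / 6)
        X[:, j] = rho_p * zy + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    cols = [f"K{j+1:05d}" for j in range(n_features)]
    return pd.DataFrame(X, index=pheno.sample_ids, columns=cols)
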