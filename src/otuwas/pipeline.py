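"""End-to-end run: preprocess -> association -> network -> features -> variance.

All stage parameters live on :class:`RunConfig` (serializable to/from YAML);
every source of randomness derives from the master seed through stable
per-stage substreams, so a rerun with the same config is bit-identical and
adding a stage never perturbs earlier stages' streams.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import features as feat
from . import io as oio
from . import network as net
from . import preprocess as pre
from . import twopart as tp
from . import variance as var

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31)."""
    return (int(master_seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    otu_table: str = ""
    metadata: str = ""
    taxonomy: str | None = None
    feature_tables: dict[str, str] = field(default_factory=dict)  # name -> path
    out_dir: str = "otuwas_run"
    # preprocessing
    rarefaction_depth: int = pre.DEFAULT_RAREFACTION_DEPTH
    min_mean_abundance: float = pre.DEFAULT_MIN_MEAN_ABUNDANCE
    min_prevalence: float = pre.DEFAULT_MIN_PREVALENCE
    abundance_stat: str = "mean"
    # two-part association
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    min_group: int = tp.DEFAULT_MIN_GROUP
    min_present: int = tp.DEFAULT_MIN_PRESENT
    transform: str = "log"
    # SparCC network / CAGs
    sparcc_n_inner: int = 20
    sparcc_n_exclude_iter: int = 20
    sparcc_exclude_threshold: float = 0.1
    n_boot: int = net.DEFAULT_N_BOOT
    r_threshold: float = net.DEFAULT_R_THRESHOLD
    p_threshold: float = net.DEFAULT_P_THRESHOLD
    n_cags: int = 2
    permanova_n_perm: int = net.DEFAULT_PERMANOVA_PERM
    # feature screens
    feature_rho_threshold: float = feat.DEFAULT_RHO_THRESHOLD
    feature_q_threshold: float = feat.DEFAULT_Q_THRESHOLD
    # variance explained
    cv_thresholds: list[float] = field(default_factory=lambda: list(var.DEFAULT_THRESHOLDS))
    cv_repeats: int = var.DEFAULT_N_REPEATS
    cv_fraction_discovery: float = 0.8
    # master seed
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_all(config: RunConfig) -> Path:
    """Execute every stage, writing result tables and a manifest JSON.

    Returns the run directory. A failing stage raises with the stage name;
    outputs already written are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        logger.info("stage %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        st = _stage("preprocess")
        table = oio.read_otu_table(config.otu_table)
        pheno = oio.read_metadata(config.metadata)
        table, pheno = oio.align_samples(table, pheno)
        st["n_samples_shared"] = len(table.sample_ids)
        table = pre.rarefy(table, config.rarefaction_depth, seed=stage_seed(config.seed, "rarefy"))
        pheno = pheno.select_samples(list(table.sample_ids))
        rel_full = pre.to_relative(table)
        rel, report = pre.filter_otus(
            rel_full, config.min_mean_abundance, config.min_prevalence, config.abundance_stat
        )
        pheno = pre.adjust_phenotype(pheno)
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        oio.write_metadata(pheno, out / "phenotype_adjusted.tsv")
        st.update(
            n_samples=len(rel.sample_ids),
            n_otus_input=report.n_input_otus,
            n_otus_retained=report.n_retained,
        )
    except Exception as e:
        raise RuntimeError(f"stage preprocess failed: {e}") from e

    try:
        st = _stage("twopart_assoc")
        scan = tp.two_part_scan(
            rel, pheno, min_group=config.min_group,
            min_present=config.min_present, transform=config.transform,
        )
        tp.permutation_fdr(
            scan, rel, pheno, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "permutation_fdr"),
            min_group=config.min_group, min_present=config.min_present,
            transform=config.transform,
        )
        res = tp.results_to_frame(scan)
        res.to_csv(out / "twopart_results.tsv", sep="\t", index=False, float_format="%.10g")
        sig = res[res["q_value"] < config.fdr_threshold].copy()
        if config.taxonomy:
            taxmap = oio.read_taxonomy(config.taxonomy)
            sig["lineage"] = sig["otu_id"].map(taxmap)
        sig.to_csv(out / "twopart_significant.tsv", sep="\t", index=False, float_format="%.10g")
        sig_ids = list(sig["otu_id"])
        st.update(
            n_significant=len(sig_ids),
            n_positive=int((sig["direction"] > 0).sum()),
            n_negative=int((sig["direction"] < 0).sum()),
        )
    except Exception as e:
        raise RuntimeError(f"stage twopart_assoc failed: {e}") from e

    try:
        st = _stage("sparcc_cag")
        if len(sig_ids) >= 4:
            counts_sig = table.select_otus(sig_ids)
            r = net.sparcc(
                counts_sig, n_inner=config.sparcc_n_inner,
                n_exclude_iter=config.sparcc_n_exclude_iter,
                exclude_threshold=config.sparcc_exclude_threshold,
                seed=stage_seed(config.seed, "sparcc"),
            )
            p = net.sparcc_bootstrap_p(
                counts_sig, r, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "sparcc_bootstrap"),
                n_inner=config.sparcc_n_inner,
                n_exclude_iter=config.sparcc_n_exclude_iter,
                exclude_threshold=config.sparcc_exclude_threshold,
            )
            edges = net.build_network(r, p, sig_ids, config.r_threshold, config.p_threshold)
            labels = net.cluster_cags(r, sig_ids, k=config.n_cags)
            import numpy as np

            d = (1.0 - r) / 2.0
            np.fill_diagonal(d, 0.0)
            lab_vec = [labels[o] for o in sig_ids]
            try:
                f_stat, p_perm = net.permanova(
                    d, lab_vec, n_perm=config.permanova_n_perm,
                    seed=stage_seed(config.seed, "permanova"),
                )
            except ValueError as e:
                f_stat, p_perm = float("nan"), float("nan")
                logger.warning("PERMANOVA skipped: %s", e)
            cag_assoc = net.cag_phenotype_assoc(rel.select_otus(sig_ids), labels, pheno)
            net.write_edges_tsv(edges, out / "network_edges.tsv")
            net.write_graphml(edges, labels, out / "network.graphml")
            import pandas as pd

            pd.DataFrame(
                {"otu_id": sig_ids, "cag": [labels[o] for o in sig_ids]}
            ).to_csv(out / "cag_membership.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {"cag_id": c.cag_id, "spearman_rho": c.spearman_rho, "p": c.p, "q": c.q}
                    for c in cag_assoc
                ]
            ).to_csv(out / "cag_association.tsv", sep="\t", index=False, float_format="%.10g")
            st.update(
                n_edges=len(edges),
                n_cags=len(set(labels.values())),
                permanova_pseudo_f=f_stat,
                permanova_p=p_perm,
            )
        else:
            st["skipped"] = f"only {len(sig_ids)} significant OTUs (< 4)"
    except Exception as e:
        raise RuntimeError(f"stage sparcc_cag failed: {e}") from e

    try:
        st = _stage("feature_assoc")
        for name, path in config.feature_tables.items():
            ftab = oio.read_relabundance_table(path)
            ftab = ftab.loc[[s for s in ftab.index if s in set(rel.sample_ids)]]
            ftab = ftab.reindex(rel.sample_ids)
            allf, sigf = feat.spearman_scan(
                ftab, pheno, config.feature_rho_threshold, config.feature_q_threshold
            )
            feat.associations_to_frame(allf).to_csv(
                out / f"features_{name}_all.tsv", sep="\t", index=False, float_format="%.10g"
            )
            feat.associations_to_frame(sigf).to_csv(
                out / f"features_{name}_significant.tsv", sep="\t", index=False, float_format="%.10g"
            )
            st[name] = {"n_features": len(allf), "n_significant": len(sigf)}
    except Exception as e:
        raise RuntimeError(f"stage feature_assoc failed: {e}") from e

    try:
        st = _stage("variance_explained")
        curve = var.explained_variance(
            rel, pheno,
            thresholds=config.cv_thresholds,
            n_repeats=config.cv_repeats,
            fraction_discovery=config.cv_fraction_discovery,
            seed=stage_seed(config.seed, "variance"),
            min_group=config.min_group, min_present=config.min_present,
        )
        curve.to_frame().to_csv(
            out / "variance_curve.tsv", sep="\t", index=False, float_format="%.10g"
        )
        import pandas as pd

        long = pd.DataFrame(curve.per_repeat_r2, columns=[f"{t:g}" for t in curve.thresholds])
        long.insert(0, "repeat", range(1, curve.n_repeats + 1))
        long.melt(id_vars="repeat", var_name="threshold", value_name="r2").to_csv(
            out / "variance_per_repeat.tsv", sep="\t", index=False, float_format="%.10g"
        )
        st.update(
            thresholds=[float(t) for t in curve.thresholds],
            mean_r2=[float(x) for x in curve.mean_r2],
            mean_n_otus=[float(x) for x in curve.mean_n_otus],
        )
    except Exception as e:
        raise RuntimeError(f"stage variance_explained failed: {e}") from e

    from importlib.metadata import version

    try:
        manifest["version"] = version("otuwas")
    except Exception:
        manifest["version"] = "unknown"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
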