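"""Config-driven orchestration of the full analysis battery.

``run_pipeline`` takes a declarative YAML config naming an OTU table, an
environment table, a groups file and optional FASTQ files, and produces in
order: QC table, rarefied table, phylum-level relative abundances (+ stacked
bars), per-sample diversity with group comparisons, DCA scores (+ plot),
the ANOSIM/Adonis/MRPP dissimilarity-test table, per-group RMT networks
(stats, module roles, edge list, GraphML, Zi-Pi plot, threshold scan), CCA
(+ triplot and percent-explained table), and per-group connectivity-GS
tables.  Every artifact is listed with its SHA-256 checksum in
``manifest.json``; a fixed global seed makes numeric tables byte-identical
across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from menanet import community_tests, diversity, ordination, otu_io, rmt_network, seq_qc
from menanet import synthetic_data

log = logging.getLogger("menanet.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]

# deterministic SVG output
matplotlib.rcParams["svg.hashsalt"] = "menanet"
_SVG_META = {"Date": None}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    otu_table: str
    env_table: str | None = None
    groups: str | None = None
    fastq: list[str] = field(default_factory=list)
    out_dir: str = "menanet_out"
    seed: int = 0
    rarefaction_depth: int = 1500
    simpson_kind: str = "gini"
    group_test: str = "welch_t"
    distance_metric: str = "bray_curtis"
    n_permutations: int = 999
    dca_segments: int = 26
    dca_rescale: bool = False
    network: dict = field(default_factory=dict)
    # network block keys: min_prevalence_fraction, zero_fill, threshold
    # ("auto" or a number), s_min, s_max, step, alpha

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        base = Path(path).parent
        # resolve paths relative to the config file
        cfg.otu_table = str((base / cfg.otu_table).resolve())
        if cfg.env_table:
            cfg.env_table = str((base / cfg.env_table).resolve())
        if cfg.groups:
            cfg.groups = str((base / cfg.groups).resolve())
        cfg.fastq = [str((base / f).resolve()) for f in cfg.fastq]
        if not Path(cfg.out_dir).is_absolute():
            cfg.out_dir = str((base / cfg.out_dir).resolve())
        for p in [cfg.otu_table, cfg.env_table, cfg.groups, *cfg.fastq]:
            if p and not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the artifact manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict[str, list[dict]] = {"artifacts": []}

    def record(stage: str, path: Path) -> None:
        manifest["artifacts"].append(
            {"stage": stage, "path": path.name, "sha256": _sha256(path)}
        )

    stage = "load"
    try:
        table = otu_io.read_otu_table(config.otu_table)
        groups = otu_io.read_groups(config.groups) if config.groups else {}
        env = otu_io.read_env_table(config.env_table) if config.env_table else None
        log.info("loaded %d samples x %d OTUs (seed=%d)",
                 table.n_samples, table.n_otus, config.seed)

        if config.fastq:
            stage = "qc"
            rows = []
            for fq in config.fastq:
                st = seq_qc.fastq_stats(fq)
                rows.append({"file": Path(fq).name, "reads": st.n_reads,
                             "AvgLen (bp)": st.avg_len, "GC (%)": st.gc_pct,
                             "Q20 (%)": st.q20_pct, "Q30 (%)": st.q30_pct})
            p = out / "qc_stats.tsv"
            _save_tsv(pd.DataFrame(rows), p, index=False)
            record(stage, p)

        stage = "rarefy"
        table = otu_io.rarefy(table, config.rarefaction_depth, config.seed)
        p = out / "rarefied_otu_table.tsv"
        otu_io.write_otu_table(table, p)
        record(stage, p)
        labels = [groups.get(s, "all") for s in table.sample_ids]

        stage = "phylum_abundance"
        if table.taxonomy is not None:
            phy = otu_io.aggregate_by_taxonomy(table, "phylum")
            ra = pd.DataFrame(otu_io.relative_abundance(phy),
                              index=phy.sample_ids, columns=phy.otu_ids)
            p = out / "phylum_relative_abundance.tsv"
            _save_tsv(ra, p, index_label="sample_id")
            record(stage, p)
            fig, ax = plt.subplots(figsize=(9, 4))
            ra.plot(kind="bar", stacked=True, ax=ax, width=1.0, legend=False)
            ax.set_ylabel("relative abundance")
            ax.set_xticks([])
            fig.savefig(out / "phylum_bars.svg", metadata=_SVG_META)
            plt.close(fig)
            record(stage, out / "phylum_bars.svg")

        stage = "diversity"
        div = diversity.diversity_table(table, simpson_kind=config.simpson_kind)
        p = out / "diversity.tsv"
        _save_tsv(div, p)
        record(stage, p)
        if len(set(labels)) == 2:
            rows = []
            lab = np.array(labels)
            for col in ("richness", "shannon", "simpson"):
                res = diversity.compare_groups(div[col].to_numpy(), lab,
                                               method=config.group_test)
                for g in dict.fromkeys(labels):
                    sub = div[col].to_numpy()[lab == g]
                    rows.append({"index": col, "group": g, "mean": sub.mean(),
                                 "sd": sub.std(ddof=1), "P": res.p_value})
            p = out / "diversity_group_comparison.tsv"
            _save_tsv(pd.DataFrame(rows), p, index=False)
            record(stage, p)

        stage = "dca"
        dca_res = ordination.dca(table, n_segments=config.dca_segments,
                                 rescale=config.dca_rescale)
        scores = pd.DataFrame(
            dca_res.site_scores,
            index=dca_res.sample_ids,
            columns=[f"DCA{i + 1}" for i in range(dca_res.site_scores.shape[1])],
        )
        p = out / "dca_site_scores.tsv"
        _save_tsv(scores, p, index_label="sample_id")
        record(stage, p)
        fig, ax = plt.subplots(figsize=(5, 5))
        for g in dict.fromkeys(labels):
            m = np.array(labels) == g
            ax.scatter(scores.to_numpy()[m, 0], scores.to_numpy()[m, 1], label=g, s=18)
        ax.set_xlabel("DCA1")
        ax.set_ylabel("DCA2")
        ax.legend()
        fig.savefig(out / "dca_plot.svg", metadata=_SVG_META)
        plt.close(fig)
        record(stage, out / "dca_plot.svg")

        if len(set(labels)) >= 2:
            stage = "dissimilarity_tests"
            dm = community_tests.distance_matrix(table, config.distance_metric)
            rows = []
            for name, fn in (("Anosim", community_tests.anosim),
                             ("Adonis", community_tests.adonis),
                             ("MRPP", community_tests.mrpp)):
                res = fn(dm, labels, n_perm=config.n_permutations, seed=config.seed)
                row = {"test": name, "statistic_name": res.statistic_name,
                       "statistic": res.statistic, "P": res.p_value}
                row.update(res.extra or {})
                rows.append(row)
            p = out / "dissimilarity_tests.tsv"
            _save_tsv(pd.DataFrame(rows), p, index=False)
            record(stage, p)

        stage = "network"
        netcfg = dict(config.network)
        stats_by_group: dict[str, rmt_network.NetworkStats] = {}
        nets: dict[str, rmt_network.EcologicalNetwork] = {}
        logmats: dict[str, rmt_network.LogAbundanceMatrix] = {}
        for g in dict.fromkeys(labels):
            sub_ids = [s for s, lg in zip(table.sample_ids, labels) if lg == g]
            sub = table.select_samples(sub_ids)
            lm = rmt_network.prepare_log_matrix(
                sub,
                netcfg.get("min_prevalence_fraction", 0.5),
                netcfg.get("zero_fill", 0.01),
            )
            sim = rmt_network.similarity_matrix(lm)
            thr = netcfg.get("threshold", "auto")
            if thr == "auto":
                scan = rmt_network.rmt_threshold_scan(
                    sim,
                    s_min=netcfg.get("s_min", 0.30),
                    s_max=netcfg.get("s_max", 0.99),
                    step=netcfg.get("step", 0.01),
                    alpha=netcfg.get("alpha", 0.05),
                )
                thr = scan.chosen_threshold
                p = out / f"network_{g}_threshold_scan.tsv"
                rmt_network.write_threshold_scan(scan, p)
                record(stage, p)
            net = rmt_network.build_network(sim, float(thr))
            modules, q = rmt_network.detect_modules(net)
            stats = rmt_network.topology(net)
            roles = rmt_network.node_roles(net)
            nets[g], logmats[g], stats_by_group[g] = net, lm, stats
            p = out / f"network_{g}_edges.tsv"
            rmt_network.write_edge_list(net, p)
            record(stage, p)
            rmt_network.write_graphml(net, out / f"network_{g}.graphml")
            record(stage, out / f"network_{g}.graphml")
            p = out / f"network_{g}_node_roles.tsv"
            rmt_network.write_node_roles(roles, p)
            record(stage, p)
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter([r.pi for r in roles], [r.zi for r in roles], s=14)
            ax.axhline(2.5, color="grey", ls="--", lw=0.8)
            ax.axvline(0.62, color="grey", ls="--", lw=0.8)
            ax.set_xlabel("participation coefficient (Pi)")
            ax.set_ylabel("within-module degree (Zi)")
            ax.set_title(f"{g} (threshold {net.threshold:.2f})")
            fig.savefig(out / f"network_{g}_zipi.svg", metadata=_SVG_META)
            plt.close(fig)
            record(stage, out / f"network_{g}_zipi.svg")
        p = out / "network_stats.tsv"
        rmt_network.write_network_stats(stats_by_group, p)
        record(stage, p)

        if env is not None:
            stage = "cca"
            env_al = env.select_samples(list(table.sample_ids))
            cca_res = ordination.cca(table, env_al)
            naxes = cca_res.site_scores.shape[1]
            eig_tab = pd.DataFrame(
                {
                    "axis": [f"CCA{i + 1}" for i in range(naxes)],
                    "eigenvalue": cca_res.constrained_eigenvalues[:naxes],
                    "pct_explained": cca_res.pct_explained_axis,
                    "cumulative_pct": cca_res.cumulative_pct,
                }
            )
            eig_tab.attrs["constrained_pct"] = cca_res.constrained_pct
            p = out / "cca_percent_explained.tsv"
            _save_tsv(eig_tab, p, index=False)
            record(stage, p)
            sc = pd.DataFrame(cca_res.site_scores, index=cca_res.sample_ids,
                              columns=[f"CCA{i + 1}" for i in range(naxes)])
            p = out / "cca_site_scores.tsv"
            _save_tsv(sc, p, index_label="sample_id")
            record(stage, p)
            fig, ax = plt.subplots(figsize=(5.5, 5))
            for g in dict.fromkeys(labels):
                m = np.array(labels) == g
                ax.scatter(sc.to_numpy()[m, 0], sc.to_numpy()[m, 1], label=g, s=18)
            span = np.abs(sc.to_numpy()[:, :2]).max()
            for j, var in enumerate(cca_res.variables):
                bx, by = cca_res.biplot_scores[j, :2] * span
                ax.annotate("", xy=(bx, by), xytext=(0, 0),
                            arrowprops=dict(arrowstyle="->", color="tab:red", lw=0.9))
                ax.text(bx * 1.05, by * 1.05, var, fontsize=8, color="tab:red")
            ax.set_xlabel("CCA1")
            ax.set_ylabel("CCA2")
            ax.legend(fontsize=8)
            fig.savefig(out / "cca_triplot.svg", metadata=_SVG_META)
            plt.close(fig)
            record(stage, out / "cca_triplot.svg")

            stage = "connectivity_gs"
            for g, net in nets.items():
                lm = logmats[g]
                env_g = env.select_samples(list(lm.sample_ids))
                gs = rmt_network.gene_significance(lm, env_g)
                tab6 = rmt_network.connectivity_gs_table(
                    net, gs, n_perm=config.n_permutations, seed=config.seed
                )
                p = out / f"connectivity_gs_{g}.tsv"
                _save_tsv(tab6, p)
                record(stage, p)
    except Exception as exc:
        partial = out / "manifest.json"
        partial.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d artifacts to %s", len(manifest["artifacts"]), out)
    return manifest


def make_demo(out_dir, seed: int = 0) -> Path:
    """Write a self-contained demo dataset + config; returns the config path.

    The demo mirrors the default study conditions: 2 groups x 9 sites x 3
    subplots (54 samples) at depth 1500, four dominant phyla at ~80% of the
    community, planted correlated OTU blocks for the network stage, and
    environment variables linked to driver OTUs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = synthetic_data.BlockSpec(
        blocks=[(12, 0.9), (10, 0.85), (8, 0.9)], n_noise_otus=0,
        n_samples=54, seed=seed,
    )
    spec = synthetic_data.CommunitySpec(
        n_otus=260, depth=3000, group_effect=1.0, seed=seed,
        block_spec=blocks, block_sigma=0.8,
    )
    link = synthetic_data.EnvLinkSpec(
        driver_map={
            "pH": ([0, 1, 2], 0.5),
            "SM": ([5, 6], 0.45),
            "SOC": ([12], 0.5),
        },
        seed=seed + 1,
    )
    table, env = synthetic_data.simulate_env_linked(spec, link)
    labels = [s.split(".")[0] for s in table.sample_ids]  # ids encode the group
    otu_io.write_otu_table(table, out / "otu_table.tsv")
    otu_io.write_env_table(env, out / "env_table.tsv")
    otu_io.write_groups(dict(zip(table.sample_ids, labels)), out / "groups.tsv")
    synthetic_data.simulate_fastq(
        200, 250, 0.56,
        {20: 0.03, 28: 0.07, 32: 0.20, 36: 0.40, 38: 0.30},
        seed, out / "demo_reads.fastq",
    )
    cfg = {
        "otu_table": "otu_table.tsv",
        "env_table": "env_table.tsv",
        "groups": "groups.tsv",
        "fastq": ["demo_reads.fastq"],
        "out_dir": "results",
        "seed": seed,
        "rarefaction_depth": 1500,
        "network": {"min_prevalence_fraction": 0.5, "threshold": "auto"},
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
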