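"""End-to-end orchestration: simulate -> preprocess -> associate -> cluster
-> network -> enrich, under one config and one master seed.

Every stage draws its randomness from a stream derived from the master seed
by a stable stage label, so disabling one stage never perturbs another's
output, and re-running a config reproduces every output bit-identically.
A manifest records every resolved parameter and stage log.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clustering, enrichment, network, preprocess, synthdata
from .containers import CrossomixError, OmicsMatrix


def stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master) * 1000003 + zlib.crc32(label.encode())) % (2**31 - 1)


@dataclasses.dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    # simulation
    simulate: bool = True
    input_dir: str | None = None
    n_participants: int = 50
    n_features: int = 500
    n_mrna: int = 40
    edge_density: float = 0.02
    mrna_edge_density: float = 0.1
    n_affected: int = 25
    n_affected_mrna: int = 8
    beta: float = 0.02
    pollutant: str = "NO2"
    batch_sd: float = 0.3
    censor_fraction: float = 0.1
    participant_sd: float = 0.5
    effect_entry: str = "post"  # generator convention: effects on post-walk occasions
    # preprocessing
    max_missing_frac: float = 0.40
    tune_sigma: float = 1.0
    outlier_components: int = 3
    outlier_mad_multiplier: float = 5.0
    technical_factors: tuple = ("plate", "box")
    # association
    effect_mode: str = "main"
    include_bmi: bool = True
    fwer: float = 0.05
    ent_var_threshold: float = 0.99
    # clustering / networks
    run_clustering: bool = True
    run_networks: bool = True
    cluster_subsamples: int = 500
    network_K: int = 500
    network_frac: float = 0.8
    network_n_lambda: int = 25
    multiblock: bool = True
    multiblock_n_lambda: int = 5
    min_network_features: int = 5
    # enrichment
    run_enrichment: bool = True
    tol_ppm: float = 8.0
    pollutant_thresholds: dict = dataclasses.field(
        default_factory=lambda: dict(enrichment.DEFAULT_POLLUTANT_THRESHOLDS)
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CrossomixError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["technical_factors"] = list(d["technical_factors"])
        return d


class StageFailure(CrossomixError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run all configured stages; returns the output directory.

    On stage failure the run aborts with the stage name; outputs of earlier
    stages are preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("associate", _stage_associate),
        ("cluster", _stage_cluster),
        ("network", _stage_network),
        ("enrich", _stage_enrich),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        try:
            log = fn(cfg, state, out)
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise StageFailure(name, exc) from exc
        manifest["stages"][name] = log or {}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> dict:
    if not cfg.simulate:
        src = Path(cfg.input_dir)
        state["design"] = pd.read_csv(src / "samples.tsv", sep="\t", index_col=0)
        state["exposures"] = pd.read_csv(src / "exposures.tsv", sep="\t").set_index(
            ["participant", "visit"]
        )
        state["metabolites"] = OmicsMatrix.from_tsv(
            src / "features.tsv", src / "feature_meta.tsv", scale="raw"
        )
        state["mrna"] = None
        return {"source": str(src)}

    seed = stage_seed(cfg.seed, "simulate")
    design = synthdata.generate_design(
        synthdata.DesignConfig(n_participants=cfg.n_participants, seed=seed)
    )
    expo = synthdata.generate_exposures(
        design, synthdata.ExposureModel(), seed=stage_seed(cfg.seed, "exposures")
    )
    rng = np.random.default_rng(stage_seed(cfg.seed, "effects"))

    theta_m, edges_m = synthdata.generate_precision_matrix(
        synthdata.PrecisionSpec(p=cfg.n_features, density=cfg.edge_density),
        seed=stage_seed(cfg.seed, "precision_metabolites"),
    )
    affected = np.sort(rng.choice(cfg.n_features, size=cfg.n_affected, replace=False))
    effects = synthdata.EffectSpec(
        affected=affected, beta=cfg.beta, pollutant=cfg.pollutant
    )
    metab, truth_m = synthdata.generate_omics(
        design,
        expo,
        theta_m,
        effects,
        batch_sd=cfg.batch_sd,
        censor_fraction=cfg.censor_fraction,
        participant_sd=cfg.participant_sd,
        effect_mode=cfg.effect_entry,
        seed=stage_seed(cfg.seed, "omics_metabolites"),
        kind="metabolite",
    )
    truth_m["edges"] = edges_m

    theta_t, edges_t = synthdata.generate_precision_matrix(
        synthdata.PrecisionSpec(p=cfg.n_mrna, density=cfg.mrna_edge_density),
        seed=stage_seed(cfg.seed, "precision_mrna"),
    )
    affected_t = np.sort(rng.choice(cfg.n_mrna, size=cfg.n_affected_mrna, replace=False))
    effects_t = synthdata.EffectSpec(
        affected=affected_t, beta=cfg.beta, pollutant=cfg.pollutant
    )
    mrna, truth_t = synthdata.generate_omics(
        design,
        expo,
        theta_t,
        effects_t,
        batch_sd=cfg.batch_sd,
        censor_fraction=0.0,  # arrays report complete intensities
        participant_sd=cfg.participant_sd,
        effect_mode=cfg.effect_entry,
        seed=stage_seed(cfg.seed, "omics_mrna"),
        kind="mrna",
    )
    reference, pathways, feat2cpd = synthdata.generate_reference(
        metab.feature_meta, seed=stage_seed(cfg.seed, "reference")
    )

    synthdata.write_study(out / "simulated", design, expo, metab, truth_m)
    mrna.to_tsv(out / "simulated" / "mrna.tsv", out / "simulated" / "mrna_meta.tsv")
    reference.to_csv(out / "simulated" / "reference_masses.tsv", sep="\t")
    enrichment.PathwayMap(pathways, set(reference.index)).to_gmt(
        out / "simulated" / "pathways.gmt"
    )

    state.update(
        design=design,
        exposures=expo,
        metabolites=metab,
        mrna=mrna,
        truth={"metabolites": truth_m, "mrna": truth_t},
        reference=reference,
        pathways=pathways,
        feat2cpd=feat2cpd,
    )
    return {
        "n_profiles": int(len(design)),
        "n_features": int(metab.n_features),
        "n_mrna": int(mrna.n_features),
        "n_affected": int(len(affected)),
    }


def _preprocess_block(cfg: RunConfig, m: OmicsMatrix, design: pd.DataFrame, label: str):
    log: dict = {}
    m, flog = preprocess.filter_missingness(
        m, cfg.max_missing_frac, sample_meta=design
    )
    log["filter"] = {k: v for k, v in flog.items() if k != "missing_fraction"}
    m = preprocess.log2_transform(m)
    m, qparams = preprocess.impute_qrilc(
        m, tune_sigma=cfg.tune_sigma, seed=stage_seed(cfg.seed, f"impute_{label}")
    )
    log["impute"] = {"n_samples_imputed": len(qparams)}
    flags = preprocess.flag_pca_outliers(
        m, n_components=cfg.outlier_components, mad_multiplier=cfg.outlier_mad_multiplier
    )
    keep = flags.index[~flags]
    m = m.select_samples(keep)
    log["outliers"] = {"flagged": list(flags.index[flags])}
    factors = [f for f in cfg.technical_factors if f in design.columns]
    m, dlog = preprocess.denoise_technical(m, design.loc[keep, factors])
    log["denoise"] = {"factors": dlog["factors"], "dropped": dlog["dropped"],
                      "n_fallback": len(dlog["fallback_features"])}
    return m, log


def _stage_preprocess(cfg: RunConfig, state: dict, out: Path) -> dict:
    design = state["design"]
    log = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        m, log["metabolites"] = _preprocess_block(cfg, state["metabolites"], design, "metab")
        state["metabolites_clean"] = m
        m.to_tsv(out / "metabolites_preprocessed.tsv")
        if state.get("mrna") is not None:
            t, log["mrna"] = _preprocess_block(cfg, state["mrna"], design, "mrna")
            state["mrna_clean"] = t
            t.to_tsv(out / "mrna_preprocessed.tsv")
    return log


def _stage_associate(cfg: RunConfig, state: dict, out: Path) -> dict:
    log = {}
    for label in ("metabolites", "mrna"):
        m = state.get(f"{label}_clean")
        if m is None:
            continue
        design = state["design"].loc[m.values.columns]
        ent = association.effective_number_tests(m, cfg.ent_var_threshold)
        results = association.association_scan(
            m,
            design,
            state["exposures"],
            effect_mode=cfg.effect_mode,
            include_bmi=cfg.include_bmi,
        )
        results = association.apply_corrections(results, ent, m.n_features, cfg.fwer)
        results.to_csv(out / f"association_{label}.tsv", sep="\t", index=False)
        summary = association.association_summary(results)
        state[f"results_{label}"] = results
        state[f"ent_{label}"] = ent
        state[f"summary_{label}"] = summary
        log[label] = {
            "ent": int(ent),
            "n_features": int(m.n_features),
            "n_unique_significant": int(summary["n_unique"]),
            "per_exposure": summary["per_exposure"],
        }
        if label == "metabolites" and m.feature_meta is not None and "rt" in m.feature_meta:
            manhattan = results.merge(
                m.feature_meta[["mz", "rt"]], left_on="feature", right_index=True
            ).sort_values(["exposure", "rt"])
            manhattan.to_csv(out / "association_by_rt.tsv", sep="\t", index=False)
    return log


def _significant_features(state: dict, label: str, fallback_top: int) -> list:
    results = state[f"results_{label}"]
    sig = results.loc[results["significant_ent"], "feature"].unique()
    if len(sig) >= 3:
        return list(sig)
    best = (
        results.groupby("feature")["p"].min().sort_values().head(fallback_top).index
    )
    return list(best)


def _stage_cluster(cfg: RunConfig, state: dict, out: Path) -> dict:
    if not cfg.run_clustering:
        return {"skipped": True}
    m = state["metabolites_clean"]
    feats = _significant_features(state, "metabolites", fallback_top=20)
    sub = m.select_features(feats)
    assignment = clustering.ConsensusClustering(sub.values).fit(
        n_subsamples=cfg.cluster_subsamples,
        seed=stage_seed(cfg.seed, "cluster"),
    )
    assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
    assignment.comembership.to_csv(out / "comembership.tsv", sep="\t")
    state["clusters"] = assignment
    return {
        "n_features": len(feats),
        "G": int(assignment.G),
        "pi": float(assignment.pi),
        "n_clusters": int(assignment.n_clusters),
        "medoids": {int(k): v for k, v in assignment.medoids.items()},
    }


def _network_data(state: dict, cfg: RunConfig, time_point: str):
    """Medoid (+ mRNA) variables restricted to one time point, standardized."""
    m = state["metabolites_clean"]
    design = state["design"].loc[m.values.columns]
    if state.get("clusters") is not None:
        nodes = state["clusters"].medoid_features()
    else:
        nodes = _significant_features(state, "metabolites", fallback_top=15)
    cols = design.index[design["time_point"] == time_point]
    frames = [m.values.loc[nodes, cols]]
    blocks = ["metabolite"] * len(nodes)
    if cfg.multiblock and state.get("mrna_clean") is not None:
        t = state["mrna_clean"]
        tnodes = _significant_features(state, "mrna", fallback_top=10)
        tcols = [c for c in cols if c in t.values.columns]
        frames = [m.values.loc[nodes, tcols], t.values.loc[tnodes, tcols]]
        blocks += ["mrna"] * len(tnodes)
    X = pd.concat(frames).T  # samples x variables
    X = X.dropna(axis=0)
    Xs = (X - X.mean()) / X.std(ddof=1).replace(0.0, 1.0)
    parts = state["design"].loc[Xs.index, "participant"].to_numpy()
    return Xs, blocks, parts


def _stage_network(cfg: RunConfig, state: dict, out: Path) -> dict:
    if not cfg.run_networks:
        return {"skipped": True}
    design = state["design"]
    time_points = list(dict.fromkeys(design["time_point"]))
    nets = {}
    log = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for tp in time_points:
            X, blocks, parts = _network_data(state, cfg, tp)
            if X.shape[1] < cfg.min_network_features:
                log[tp] = {"skipped": "too few variables"}
                continue
            if cfg.multiblock and len(set(blocks)) == 2:
                net = network.multiblock_stability_network(
                    X,
                    blocks,
                    K=cfg.network_K,
                    frac=cfg.network_frac,
                    seed=stage_seed(cfg.seed, f"network_{tp}"),
                    participants=parts,
                    node_names=list(X.columns),
                    n_lambda=cfg.multiblock_n_lambda,
                )
            else:
                net = network.stability_select_network(
                    X,
                    lam_grid=network.default_lambda_grid(
                        np.corrcoef(X.to_numpy(), rowvar=False),
                        n_lambda=cfg.network_n_lambda,
                    ),
                    K=cfg.network_K,
                    frac=cfg.network_frac,
                    seed=stage_seed(cfg.seed, f"network_{tp}"),
                    participants=parts,
                    node_names=list(X.columns),
                )
            nets[tp] = net
            net.edge_table().to_csv(out / f"network_{tp}.tsv", sep="\t", index=False)
            try:
                import networkx as nx

                nx.write_graphml(net.to_graph(), out / f"network_{tp}.graphml")
            except Exception:
                pass
            log[tp] = {
                "n_nodes": len(net.nodes),
                "n_edges": len(net.edges),
                "lam_star": net.lam_star,
                "pi_star": net.pi_star,
                "n_cross_edges": len(net.cross_edges()),
            }
    state["networks"] = nets
    if len(nets) == 3:
        rewiring = network.compare_networks(*[nets[tp] for tp in time_points])
        log["rewiring"] = rewiring["counts"]
        pd.DataFrame(
            [
                {"class": c, "node1": u, "node2": v}
                for c, edges in rewiring["edges"].items()
                for u, v in edges
            ]
        ).to_csv(out / "network_rewiring.tsv", sep="\t", index=False)
        state["rewiring"] = rewiring
    return log


def _stage_enrich(cfg: RunConfig, state: dict, out: Path) -> dict:
    if not cfg.run_enrichment or state.get("reference") is None:
        return {"skipped": True}
    results = state["results_metabolites"]
    meta = state["metabolites_clean"].feature_meta
    selected_sets = enrichment.select_significant(results, cfg.pollutant_thresholds)
    pmap = enrichment.PathwayMap(state["pathways"], set(state["reference"].index))
    log = {}
    tables = []
    for pol, feats in selected_sets.items():
        sub_meta = meta.loc[[f for f in feats if f in meta.index]]
        ann = enrichment.annotate_features(
            sub_meta, state["reference"], tol_ppm=cfg.tol_ppm
        )
        compounds = set(ann["compound"])
        if not compounds:
            log[pol] = {"n_selected": len(feats), "n_compounds": 0}
            continue
        ora = enrichment.ora_fisher(compounds, pmap)
        ora.insert(0, "exposure", pol)
        tables.append(ora)
        log[pol] = {
            "n_selected": len(feats),
            "n_compounds": len(compounds),
            "top_pathway": ora.iloc[0]["pathway"] if len(ora) else None,
        }
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
    return log


def _stage_report(cfg: RunConfig, state: dict, out: Path) -> dict:
    lines = ["# Pipeline report", ""]
    if "summary_metabolites" in state:
        s = state["summary_metabolites"]
        lines += [
            "## Association (metabolites)",
            f"- effective number of tests: {state['ent_metabolites']}",
            f"- unique significant features (ENT-Bonferroni): {s['n_unique']}",
            f"- per exposure: {s['per_exposure']}",
            "",
        ]
    if "summary_mrna" in state:
        s = state["summary_mrna"]
        lines += [
            "## Association (mRNA)",
            f"- effective number of tests: {state['ent_mrna']}",
            f"- unique significant transcripts: {s['n_unique']}",
            "",
        ]
    if state.get("clusters") is not None:
        lines += ["## Clustering", state["clusters"].summary(), ""]
    if state.get("rewiring") is not None:
        lines += ["## Network rewiring", str(state["rewiring"]["counts"]), ""]
    (out / "report.md").write_text("\n".join(lines))
    return {"report": "report.md"}
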