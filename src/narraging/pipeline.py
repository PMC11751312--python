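"""End-to-end pipeline orchestration with reproducible seeding.

Stages (a DAG, validated before execution):

    simulate -> cpm (macro, micro) -> hubs -> enrichment
                                   -> aging -> decoding
                                            -> structural
    behaviour (independent of imaging stages)

Every stage draws its RNG from the global seed via stable per-stage
sub-streams; an identical seed yields an identical output bundle.  The
serialized configuration is written into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aging import AgingTrendAnalysis
from .behavior import SUR, estimate_turning_point, fit_domain_regressions, shapley_r2
from .cohort import COGNITIVE_DOMAINS, Cohort, load_cohort, save_cohort
from .cpm import CPMConfig, ConnectomePredictiveModel
from .decoding import decode_regions
from .enrichment import community_enrichment, edge_enrichment
from .simulate import GroundTruth, SimulationConfig, simulate_cohort
from .structural import SCNAnalysis, wm_predicts_fc_aging
from .topology import authority_ranking, build_graph, dice_overlap, louvain_communities

log = logging.getLogger(__name__)

STAGES = ("simulate", "cpm", "hubs", "enrich", "aging", "decode",
          "structure", "behavior")

#: stage -> stages it needs
_DAG = {
    "simulate": (),
    "cpm": ("simulate",),
    "hubs": ("cpm",),
    "enrich": ("hubs",),
    "aging": ("hubs",),
    "decode": ("aging",),
    "structure": ("aging",),
    "behavior": ("simulate",),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort_dir: str | None = None          # load instead of simulating
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cpm: CPMConfig = field(default_factory=CPMConfig)
    window_size: int = 30
    window_mode: str = "sliding"
    window_step: int = 1
    n_perm_aging: int = 300
    n_perm_enrich: int = 1000
    n_perm_decode: int = 500
    top_k_hubs: int = 50
    top_k_enrich: int = 10
    n_communities: int = 4
    louvain_runs: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cpm = CPMConfig(**raw.pop("cpm", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "age_range" in dataclasses.asdict(sim):
            sim.age_range = tuple(sim.age_range)
        return cls(simulation=sim, cpm=cpm, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"]["age_range"] = list(self.simulation.age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate_dag(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        enabled = set(self.stages)
        if self.cohort_dir is not None:
            enabled.add("simulate")  # loading satisfies the cohort dependency
        for s in self.stages:
            missing = [d for d in _DAG[s] if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage {s!r} requires {missing} which are not enabled")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages; returns the report dict (also on disk)."""
    cfg.validate_dag()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}

    # --- cohort -----------------------------------------------------------
    truth: GroundTruth | None = None
    if cfg.cohort_dir is not None:
        cohort = load_cohort(directory=cfg.cohort_dir)
    else:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        cohort, truth = simulate_cohort(sim_cfg)
        if "simulate" in cfg.stages:
            save_cohort(cohort, out / "cohort", matrix_format="npz")
            truth.to_json(out / "cohort" / "ground_truth.json")
    report["n_subjects"] = cohort.n_subjects
    report["n_nodes"] = cohort.n_nodes

    cpm_results: dict = {}
    hubs: dict = {}
    aging_results: dict = {}

    def stage_enabled(s: str) -> bool:
        return s in cfg.stages

    try:
        if stage_enabled("cpm"):
            for score in ("macro_score", "micro_score"):
                cpm_cfg = dataclasses.replace(cfg.cpm, seed=cfg.seed)
                res = ConnectomePredictiveModel(cohort, score, cpm_cfg).fit()
                cpm_results[score] = res
                (out / f"cpm_{score}.json").write_text(
                    json.dumps(res.to_dict(), default=_jsonable, indent=1))
            report["cpm"] = {s: {"n_edges": r.n_edges_selected,
                                 "test_r": r.test_r, "p_perm": r.p_perm}
                             for s, r in cpm_results.items()}

        if stage_enabled("hubs"):
            hub_frames = []
            comm = {}
            for score, res in cpm_results.items():
                if res.n_edges_selected == 0:
                    log.warning("no contributing edges for %s; hub stage skipped", score)
                    continue
                g = build_graph(res.selected_edges, np.abs(res.edge_r), cohort.n_nodes)
                ranking = authority_ranking(g)
                hubs[score] = ranking
                hf = ranking.to_frame()
                hf.insert(0, "score", score)
                hub_frames.append(hf)
                comm[score] = louvain_communities(
                    g, n_runs=cfg.louvain_runs, seed=cfg.seed,
                    n_communities=cfg.n_communities)
            if hub_frames:
                pd.concat(hub_frames).to_csv(out / "hubs.tsv", sep="\t", index=False)
                pd.concat([c.to_frame().assign(score=s) for s, c in comm.items()]
                          ).to_csv(out / "communities.tsv", sep="\t", index=False)
            if len(hubs) == 2:
                a = hubs["macro_score"].top(cfg.top_k_hubs)
                b = hubs["micro_score"].top(cfg.top_k_hubs)
                dice, p = dice_overlap(a, b, cohort.n_nodes, seed=cfg.seed)
                report["hub_overlap"] = {"dice": dice, "p": p}
                (out / "overlap.json").write_text(json.dumps(report["hub_overlap"]))
            report["communities"] = {s: {"n": c.n_communities, "Q": c.modularity}
                                     for s, c in comm.items()}

        if stage_enabled("enrich"):
            frames = []
            for score, res in cpm_results.items():
                if score not in hubs:
                    continue
                top = hubs[score].top(cfg.top_k_enrich)
                ee = edge_enrichment(top, res.selected_edges, cohort.parcellation,
                                     n_perm=cfg.n_perm_enrich, seed=cfg.seed)
                ee.insert(0, "unit", f"{score}_hub_edges")
                frames.append(ee)
                if score in (c := report.get("communities", {})):
                    pass
            for score in cpm_results:
                if score not in hubs:
                    continue
                g = build_graph(cpm_results[score].selected_edges,
                                np.abs(cpm_results[score].edge_r), cohort.n_nodes)
                assign = louvain_communities(g, n_runs=cfg.louvain_runs,
                                             seed=cfg.seed,
                                             n_communities=cfg.n_communities)
                ce = community_enrichment(assign.main_community(),
                                          cohort.parcellation,
                                          n_perm=cfg.n_perm_enrich, seed=cfg.seed)
                ce.insert(0, "unit", f"{score}_main_community")
                frames.append(ce)
            if frames:
                enr = pd.concat(frames)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                report["enrichment"] = enr.to_dict(orient="records")

        if stage_enabled("aging"):
            for score in cpm_results:
                if score not in hubs:
                    continue
                seeds = hubs[score].top(cfg.top_k_enrich)
                ana = AgingTrendAnalysis(
                    cohort, score, seeds, window_size=cfg.window_size,
                    mode=cfg.window_mode, step=cfg.window_step,
                    n_perm=cfg.n_perm_aging, seed=cfg.seed)
                aging_results[score] = ana.fit()
            if aging_results:
                pd.concat([r.edge_table().assign(score=s)
                           for s, r in aging_results.items()]
                          ).to_csv(out / "aging_trends.tsv", sep="\t", index=False)
                pd.concat([r.region_table().assign(score=s)
                           for s, r in aging_results.items()]
                          ).to_csv(out / "regions.tsv", sep="\t", index=False)
                report["aging"] = {
                    s: {"n_sig": int((r.q < 0.05).sum()),
                        "n_pos": int(((r.q < 0.05) & (r.trend > 0)).sum())}
                    for s, r in aging_results.items()}

        if stage_enabled("decode") and "macro_score" in aging_results:
            res = aging_results["macro_score"]
            seeds = hubs["macro_score"].top(cfg.top_k_enrich)
            decoding = {}
            for polarity, label in (("positive", "compensatory"),
                                    ("negative", "declining")):
                regions = res.region_nodes(label)
                if regions.size == 0:
                    continue
                rep = decode_regions(
                    cohort, seeds, regions,
                    test_n=max(10, cohort.n_subjects // 10),
                    cpm_config=dataclasses.replace(cfg.cpm, seed=cfg.seed),
                    n_perm=cfg.n_perm_decode, seed=cfg.seed)
                decoding[polarity] = rep.to_dict()
            (out / "decoding_report.json").write_text(
                json.dumps(decoding, default=_jsonable, indent=1))
            report["decoding"] = {k: v["best_domain"] for k, v in decoding.items()}

        if stage_enabled("structure") and "macro_score" in aging_results:
            res = aging_results["macro_score"]
            seeds = np.asarray(hubs["macro_score"].top(cfg.top_k_enrich))
            comp = res.region_nodes("compensatory")
            decl = res.region_nodes("declining")
            if comp.size and decl.size and cohort.gmv is not None:
                labels = {int(v): "compensatory" for v in comp}
                labels.update({int(v): "declining" for v in decl})
                scn = SCNAnalysis(cohort, seeds, labels,
                                  window_size=cfg.window_size,
                                  mode=cfg.window_mode, step=cfg.window_step,
                                  n_perm=min(cfg.n_perm_aging, 300),
                                  seed=cfg.seed).fit()
                scn.pair_table().to_csv(out / "scn_trends.tsv", sep="\t", index=False)
                report["scn"] = {"ms": scn.ms, "p": scn.p_ms}
            if cohort.wm is not None:
                targets = np.concatenate([comp, decl]) if comp.size or decl.size \
                    else np.empty(0, int)
                if targets.size:
                    wm = wm_predicts_fc_aging(
                        cohort, seeds, targets, res.edge_table(), seed=cfg.seed)
                    (out / "wm_regression.json").write_text(
                        json.dumps(wm.to_dict(), indent=1))
                    report["wm"] = wm.to_dict()

        if stage_enabled("behavior"):
            behav: dict = {}
            doms = [d for d in COGNITIVE_DOMAINS if d != "mmse"]
            for score in ("macro_score", "micro_score"):
                behav[f"regression_{score}"] = fit_domain_regressions(
                    cohort, score, doms).to_dict(orient="index")
            sur = SUR(cohort.phenotype[["macro_score", "micro_score"]],
                      cohort.phenotype[doms]).fit()
            behav["sur_wald"] = sur.wald_table().to_dict(orient="records")
            shap = shapley_r2(cohort.score("macro_score"),
                              cohort.phenotype[doms].astype(float))
            behav["shapley_macro"] = {"shares": shap.shares.to_dict(),
                                      "full_r2": shap.full_r2}
            tp = estimate_turning_point(cohort.ages, cohort.score("macro_score"),
                                        seed=cfg.seed)
            behav["turning_point"] = {"found": tp.found, "age": tp.age,
                                      "p": tp.p_value, "ci": tp.ci}
            (out / "behavior_report.json").write_text(
                json.dumps(behav, default=_jsonable, indent=1))
            report["behavior"] = {"turning_point": behav["turning_point"]}
    except Exception as e:
        (out / "FAILED.json").write_text(json.dumps({"error": str(e)}))
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    (out / "report.json").write_text(json.dumps(report, default=_jsonable,
                                                indent=1, sort_keys=True))
    _write_summary(report, out / "summary.md")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["# Pipeline summary", ""]
    for key in sorted(report):
        lines.append(f"- **{key}**: `{json.dumps(report[key], default=_jsonable)}`")
    path.write_text("\n".join(lines) + "\n")
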