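"""End-to-end orchestration: cohort -> connectivity -> topology -> stats -> LDA.

``analyze_cohort`` runs the full in-memory analysis chain on a list of
subjects and returns a result bundle; ``run_pipeline`` wraps it with file
I/O (manifest reading or on-the-fly synthesis, artifact writing, a run
log).  All intermediate artifacts are plain CSV/JSON so each stage can be
inspected or re-run independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    ClassificationReport,
    FeatureTable,
    StepwiseResult,
    loocv_evaluate,
    stepwise_lda_select,
)
from .cohort import (
    CohortSpec,
    SyntheticSubject,
    generate_cohort,
    read_cohort_manifest,
)
from .connectivity import (
    ConnectivityMatrix,
    global_average_pli,
    regional_pli,
    subject_connectivity,
)
from .graph import BrainGraph, normalized_small_world
from .montage import BAND_MAP, DEFAULT_ROI_MAP, BandDefinition, RoiMap
from .mst import SpanningTree, extract_mst, tree_dissimilarity, tree_metrics
from .recording import read_recording, reject_artifacts
from .stats import (
    GateReport,
    permutation_test,
    run_connectivity_battery,
    run_topology_battery,
)

__all__ = ["PipelineConfig", "PipelineResult", "analyze_cohort", "run_pipeline"]

TREE_MEASURES = (
    "k_star_max", "e_star_avr", "bc_star_max", "kappa", "d_star", "l_star", "t_h",
)
TRADITIONAL_MEASURES = ("Cw_hat", "Lw_hat", "S")


@dataclass
class PipelineConfig:
    """Thresholds, seeds and I/O locations of one pipeline run."""

    manifest: str | None = None  # read cohort from disk; else synthesize
    cohort_spec: CohortSpec | None = None
    bands: tuple[str, ...] = ("delta", "theta", "lower_alpha", "upper_alpha", "beta")
    roi_map: RoiMap = field(default_factory=lambda: DEFAULT_ROI_MAP)
    artifact_threshold: float = 100.0
    n_perm: int = 10000
    alpha_global: float = 0.05
    alpha_local: float = 0.01
    alpha: float = 0.05
    q: float = 0.05
    f_in: float = 3.84
    f_out: float = 2.71
    n_null_graphs: int = 50
    seed: int = 0
    output_dir: str | None = None

    def band_defs(self) -> tuple[BandDefinition, ...]:
        return tuple(BAND_MAP[name] for name in self.bands)

    def to_jsonable(self) -> dict:
        d = dict(
            manifest=self.manifest,
            bands=list(self.bands),
            roi_map={r: list(l) for r, l in self.roi_map.regions.items()},
            artifact_threshold=self.artifact_threshold,
            n_perm=self.n_perm,
            alpha_global=self.alpha_global,
            alpha_local=self.alpha_local,
            alpha=self.alpha,
            q=self.q,
            f_in=self.f_in,
            f_out=self.f_out,
            n_null_graphs=self.n_null_graphs,
            seed=self.seed,
        )
        if self.cohort_spec is not None:
            d["cohort_seed"] = self.cohort_spec.seed
            d["cohort_size"] = [
                self.cohort_spec.n_controls, self.cohort_spec.n_patients,
            ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    global_pli: pd.DataFrame  # subjects x bands
    within_pli: pd.DataFrame  # subjects x (band, region)
    between_pli: pd.DataFrame  # subjects x (band, "A|B")
    traditional: pd.DataFrame  # subjects x (band, measure)
    tree: pd.DataFrame  # subjects x (band, measure)
    dissimilarity: pd.DataFrame  # subjects x bands
    cognitive: pd.DataFrame  # subjects x tests
    labels: pd.Series
    connectivity_report: GateReport
    topology_report: GateReport
    cognitive_significant: list[str]
    models: dict[str, tuple[StepwiseResult, ClassificationReport]]
    log: list[str] = field(default_factory=list)
    n_epochs_dropped: dict[str, int] = field(default_factory=dict)


def _majority_report(labels: pd.Series) -> ClassificationReport:
    """Majority-class predictions for a model with no usable features."""
    ids = labels.index
    majority = labels.value_counts().idxmax()
    preds = pd.Series([majority] * len(ids), index=ids, name="loocv_prediction")
    pos = labels == "patient"
    tp = int(((preds == "patient") & pos).sum())
    fn = int(((preds != "patient") & pos).sum())
    tn = int(((preds != "patient") & ~pos).sum())
    fp = int(((preds == "patient") & ~pos).sum())
    return ClassificationReport(
        accuracy=(tp + tn) / len(ids),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        predictions=preds,
        selected=[],
        counts=dict(tp=tp, fn=fn, tn=tn, fp=fp),
    )


def _subject_matrices(
    subject: SyntheticSubject,
    config: PipelineConfig,
    log: list[str],
) -> tuple[dict[str, ConnectivityMatrix], int]:
    rec, dropped = reject_artifacts(
        subject.recording, config.artifact_threshold, subject.subject_id
    )
    if dropped:
        log.append(
            f"{subject.subject_id}: dropped {dropped} artifact epochs "
            f"(threshold {config.artifact_threshold})"
        )
    return {
        band.name: subject_connectivity(rec, band)
        for band in config.band_defs()
    }, dropped


def analyze_cohort(
    subjects: Sequence[SyntheticSubject],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full analysis chain on in-memory subjects."""
    roi = config.roi_map
    bands = config.bands
    log: list[str] = []
    rng = np.random.default_rng(config.seed)

    ids = [s.subject_id for s in subjects]
    labels = pd.Series([s.group for s in subjects], index=ids, name="group")
    region_names = roi.region_names
    region_pairs = roi.region_pairs()

    glob_rows, within_rows, between_rows = [], [], []
    trad_rows, tree_rows = [], []
    dropped_counts: dict[str, int] = {}
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {}
    trees: dict[str, dict[str, SpanningTree]] = {}

    for s in subjects:
        mats, dropped = _subject_matrices(s, config, log)
        dropped_counts[s.subject_id] = dropped
        matrices[s.subject_id] = mats
        trees[s.subject_id] = {}
        g_row, w_row, b_row, tr_row, te_row = {}, {}, {}, {}, {}
        for band in bands:
            cm = mats[band]
            g_row[band] = global_average_pli(cm)
            for region in region_names:
                w_row[(band, region)] = regional_pli(cm, roi, region)
            for ra, rb in region_pairs:
                b_row[(band, f"{ra}|{rb}")] = regional_pli(cm, roi, ra, rb)
            graph = BrainGraph.from_connectivity(cm)
            tm = normalized_small_world(
                graph, config.n_null_graphs, seed=int(rng.integers(2**31))
            )
            tr_row[(band, "Cw_hat")] = tm.Cw_hat
            tr_row[(band, "Lw_hat")] = tm.Lw_hat
            tr_row[(band, "S")] = tm.S
            tree = extract_mst(graph)
            trees[s.subject_id][band] = tree
            for name, value in tree_metrics(tree).as_dict().items():
                te_row[(band, name)] = value
        glob_rows.append(g_row)
        within_rows.append(w_row)
        between_rows.append(b_row)
        trad_rows.append(tr_row)
        tree_rows.append(te_row)

    global_df = pd.DataFrame(glob_rows, index=ids)
    within_df = pd.DataFrame(within_rows, index=ids)
    within_df.columns = pd.MultiIndex.from_tuples(within_df.columns)
    between_df = pd.DataFrame(between_rows, index=ids)
    between_df.columns = pd.MultiIndex.from_tuples(between_df.columns)
    trad_df = pd.DataFrame(trad_rows, index=ids)
    trad_df.columns = pd.MultiIndex.from_tuples(trad_df.columns)
    tree_df = pd.DataFrame(tree_rows, index=ids)
    tree_df.columns = pd.MultiIndex.from_tuples(tree_df.columns)

    # tree dissimilarity against the control-average reference tree per band
    control_ids = [i for i in ids if labels[i] == "control"]
    dissim = {}
    for band in bands:
        mean_mat = np.mean(
            [matrices[i][band].values for i in control_ids], axis=0
        )
        ref_tree = extract_mst(
            BrainGraph(0.5 * (mean_mat + mean_mat.T),
                       matrices[control_ids[0]][band].channel_labels)
        )
        dissim[band] = [
            tree_dissimilarity(trees[i][band], ref_tree, i, "control-mean").value
            for i in ids
        ]
    dissim_df = pd.DataFrame(dissim, index=ids)

    cog_df = pd.DataFrame(
        [s.cognitive_scores for s in subjects], index=ids
    ).sort_index(axis=1)

    # statistics
    conn_report = run_connectivity_battery(
        global_df, within_df, between_df, labels.to_numpy(),
        config.alpha_global, config.alpha_local, config.n_perm,
        seed=int(rng.integers(2**31)),
    )
    topo_report = run_topology_battery(
        trad_df, dissim_df, tree_df, labels.to_numpy(),
        config.alpha, config.q, config.n_perm,
        seed=int(rng.integers(2**31)),
    )
    log.append(f"connectivity gate passed bands: {list(conn_report.passed_bands)}")
    log.append(f"topology gate passed bands: {list(topo_report.passed_bands)}")

    cog_sig = []
    for test in cog_df.columns:
        res = permutation_test(
            cog_df[test].to_numpy(), labels.to_numpy(), config.n_perm,
            seed=int(rng.integers(2**31)),
        )
        if res.p_value < config.alpha:
            cog_sig.append(test)
    log.append(f"significant cognitive subtests: {cog_sig}")

    # feature assembly
    eeg_features: dict[str, pd.Series] = {}
    s2 = conn_report.stage2
    if len(s2):
        for _, row in s2[s2.significant].iterrows():
            band, kind, name = row["band"], row["kind"], row["name"]
            col = (band, name)
            src = within_df if kind == "within" else between_df
            eeg_features[f"{band}:{name}"] = src[col]
    s1 = topo_report.stage1
    if len(s1):
        for _, row in s1[(s1.kind == "traditional") & s1.significant].iterrows():
            eeg_features[f"{row['band']}:{row['name']}"] = trad_df[
                (row["band"], row["name"])
            ]
    s2t = topo_report.stage2
    if len(s2t):
        for _, row in s2t[s2t.significant].iterrows():
            eeg_features[f"{row['band']}:{row['name']}"] = tree_df[
                (row["band"], row["name"])
            ]
    eeg_df = pd.DataFrame(eeg_features, index=ids)
    cog_feat_df = cog_df[cog_sig]

    models: dict[str, tuple[StepwiseResult, ClassificationReport]] = {}
    model_tables = {
        "cognitive": cog_feat_df,
        "eeg": eeg_df,
        "combined": pd.concat([cog_feat_df, eeg_df], axis=1),
    }
    for model_name, feats in model_tables.items():
        if feats.shape[1] == 0:
            log.append(f"model {model_name!r}: no candidate features (null model)")
            models[model_name] = (
                StepwiseResult([], 1.0, 0.0, 0, 1.0),
                _majority_report(labels),
            )
            continue
        table = FeatureTable(feats.astype(float), labels)
        sel = stepwise_lda_select(table, config.f_in, config.f_out)
        if sel.selected:
            report = loocv_evaluate(table, sel)
        else:
            log.append(f"model {model_name!r}: stepwise selected nothing (null model)")
            report = _majority_report(labels)
        log.append(
            f"model {model_name!r}: selected {sel.selected}, "
            f"lambda={sel.wilks_lambda:.3f}, accuracy={report.accuracy:.3f}"
        )
        models[model_name] = (sel, report)

    return PipelineResult(
        global_pli=global_df,
        within_pli=within_df,
        between_pli=between_df,
        traditional=trad_df,
        tree=tree_df,
        dissimilarity=dissim_df,
        cognitive=cog_df,
        labels=labels,
        connectivity_report=conn_report,
        topology_report=topo_report,
        cognitive_significant=cog_sig,
        models=models,
        log=log,
        n_epochs_dropped=dropped_counts,
    )


def _load_subjects(config: PipelineConfig) -> list[SyntheticSubject]:
    if config.manifest is not None:
        rows = read_cohort_manifest(config.manifest)
        cog_path = Path(config.manifest).parent / "cognitive_scores.csv"
        cog = (
            pd.read_csv(cog_path, index_col=0)
            if cog_path.exists()
            else pd.DataFrame()
        )
        subjects = []
        for row in rows:
            rec = read_recording(row["path"])
            scores = {}
            if len(cog) and row["subject_id"] in cog.index:
                scores = {
                    k: float(v)
                    for k, v in cog.loc[row["subject_id"]].items()
                    if k != "group"
                }
            subjects.append(
                SyntheticSubject(row["subject_id"], row["group"], rec, scores)
            )
        return subjects
    if config.cohort_spec is None:
        raise ValueError("config needs either a manifest or a cohort_spec")
    return generate_cohort(config.cohort_spec)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load or synthesize the cohort, analyze it, and write artifacts."""
    subjects = _load_subjects(config)
    result = analyze_cohort(subjects, config)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = config.config_hash()
        result.global_pli.to_csv(out / "global_pli.csv")
        result.within_pli.to_csv(out / "within_pli.csv")
        result.between_pli.to_csv(out / "between_pli.csv")
        result.traditional.to_csv(out / "traditional_metrics.csv")
        result.tree.to_csv(out / "tree_metrics.csv")
        result.dissimilarity.to_csv(out / "dissimilarity.csv")
        result.cognitive.to_csv(out / "cognitive_scores.csv")
        result.connectivity_report.stage1.to_csv(
            out / "connectivity_stage1.csv", index=False
        )
        result.connectivity_report.stage2.to_csv(
            out / "connectivity_stage2.csv", index=False
        )
        result.topology_report.stage1.to_csv(
            out / "topology_stage1.csv", index=False
        )
        result.topology_report.stage2.to_csv(
            out / "topology_stage2.csv", index=False
        )
        summary = {
            "config": config.to_jsonable(),
            "config_hash": tag,
            "seed": config.seed,
            "epochs_dropped": result.n_epochs_dropped,
            "models": {
                name: {
                    "selected": sel.selected,
                    "wilks_lambda": sel.wilks_lambda,
                    "chi_square": sel.chi_square,
                    "df": sel.df,
                    "p_value": sel.p_value,
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
                for name, (sel, rep) in result.models.items()
            },
        }
        for name, (_sel, rep) in result.models.items():
            if rep.scores is not None:
                rep.scores.to_csv(out / f"discriminant_scores_{name}.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "run.log").write_text("\n".join(result.log) + "\n")
    return result
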