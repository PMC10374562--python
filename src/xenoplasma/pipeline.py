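"""End-to-end orchestration of the analysis stages.

Stages (``simulate → normalize → screen → train-volume → classify →
mdtv → enrich``) communicate through tab-delimited artifacts in a run
directory, so any stage can be re-run or inspected in isolation.  Every
stochastic step draws its seed deterministically from the config seed and
the stage name, and a run manifest records the seed, config hash and
stage order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adat, enrichment, mdtv as mdtv_mod, models, normalize, screen, \
    synthetic

STAGES = ["simulate", "normalize", "screen", "train-volume", "classify",
          "mdtv", "enrich"]


class MissingArtifactError(FileNotFoundError):
    def __init__(self, artifact: str, stage: str):
        super().__init__(
            f"missing artifact {artifact!r}: run the {stage!r} stage first"
        )


@dataclass
class ThresholdConfig:
    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    min_abs_r: float = 0.25
    q_enrich: float = 0.25
    edge_threshold: float = 0.375


@dataclass
class ModelConfig:
    mixing_points: int = 7
    lambda_points: int = 50
    folds: int = 5
    holdout_fraction: float = 0.27
    rule: str = models.MAX_SPEC_AT_FULL_SENS


@dataclass
class MdtvConfig:
    z: float = 1.96
    mouse_ml: float = 0.025 * 58.5
    human_ml: float = 4900.0


@dataclass
class SyntheticConfig:
    design: str = "nsclc"  # "nsclc" or "multi-line"
    n_animals: int = 6
    n_analytes: int = 300
    n_shared: int = 15
    n_line_specific: int = 10
    sigma_log: float = 0.05


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    gene_sets: str | None = None  # GMT path; toy collection when absent
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    mdtv: MdtvConfig = field(default_factory=MdtvConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in [("thresholds", ThresholdConfig),
                         ("model", ModelConfig), ("mdtv", MdtvConfig),
                         ("synthetic", SyntheticConfig)]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        # deterministic, stage-specific, below 2^31
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _out(config: PipelineConfig) -> Path:
    path = Path(config.out_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(path.name, stage)
    return path


def _truth_path(out: Path) -> Path:
    return out / "truth_analytes.tsv"


def run_simulate(config: PipelineConfig) -> dict:
    out = _out(config)
    seed = config.stage_seed("simulate")
    sc = config.synthetic
    if sc.design == "nsclc":
        design = synthetic.nsclc_design(seed=seed, n_animals=sc.n_animals)
    elif sc.design == "multi-line":
        design = synthetic.multi_line_design(seed=seed)
    else:
        raise ValueError(f"unknown design {sc.design!r}")
    samples, trajectories = synthetic.generate_cohort(design)
    truth = synthetic.make_truth(
        design.cell_lines, n_analytes=sc.n_analytes, n_shared=sc.n_shared,
        n_line_specific=sc.n_line_specific, sigma_log=sc.sigma_log, seed=seed,
    )
    dataset = synthetic.generate_rfu(truth, samples, seed=seed)
    adat.write_adat(dataset, out / "raw.adat")
    adat.write_reference(truth.hyb_reference, out / "hyb_reference.tsv")
    adat.write_reference(truth.calibrator_reference,
                         out / "calibrator_reference.tsv")
    trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    truth_rows = pd.DataFrame(
        [dataclasses.asdict(t) for t in truth.analytes.values()]
    ).set_index("analyte_id")
    truth_rows.to_csv(_truth_path(out), sep="\t")
    groups = {g.name: g.cell_line for g in design.groups}
    (out / "groups.json").write_text(json.dumps(groups, indent=1))
    return {"samples": len(samples), "analytes": len(dataset.values.columns)}


def _load_truth(out: Path) -> synthetic.TruthLedger:
    frame = pd.read_csv(_require(_truth_path(out), "simulate"),
                        sep="\t", index_col="analyte_id",
                        keep_default_na=False)
    analytes = {}
    for aid, row in frame.iterrows():
        analytes[aid] = synthetic.AnalyteTruth(
            analyte_id=aid, analyte_class=row["analyte_class"],
            line=str(row["line"]) or None, baseline=row["baseline"],
            amplitude=row["amplitude"], rate=row["rate"],
            sigma_log=row["sigma_log"], dilution_bin=row["dilution_bin"],
        )
    hyb = adat.read_reference(out / "hyb_reference.tsv")
    cal = adat.read_reference(out / "calibrator_reference.tsv")
    return synthetic.TruthLedger(analytes, hyb, cal)


def run_normalize(config: PipelineConfig) -> dict:
    out = _out(config)
    dataset = adat.read_adat(_require(out / "raw.adat", "simulate"))
    hyb_ref = adat.read_reference(_require(out / "hyb_reference.tsv",
                                           "simulate"))
    cal_ref = adat.read_reference(_require(out / "calibrator_reference.tsv",
                                           "simulate"))
    normalized, factors = normalize.normalize_pipeline(dataset, hyb_ref,
                                                       cal_ref)
    adat.write_adat(normalized, out / "normalized.adat")
    factors.hybridization.to_csv(out / "scale_hyb.tsv", sep="\t")
    factors.calibration.to_csv(out / "scale_plate.tsv", sep="\t")
    factors.median.to_csv(out / "scale_median.tsv", sep="\t")
    return {"stages": factors.stages_applied}


def _load_groups(out: Path) -> dict[str, str]:
    return json.loads(_require(out / "groups.json", "simulate").read_text())


def run_screen(config: PipelineConfig) -> dict:
    out = _out(config)
    dataset = adat.read_adat(_require(out / "normalized.adat", "normalize"))
    groups = _load_groups(out)
    tumor_groups = {g: line for g, line in groups.items()
                    if line != synthetic.CONTROL_LINE and g != "calibrator"}
    control_groups = [g for g, line in groups.items()
                      if line == synthetic.CONTROL_LINE and g != "calibrator"]
    thresholds = screen.ScreenThresholds(
        config.thresholds.q_max, config.thresholds.min_abs_log2fc,
        config.thresholds.min_abs_r)
    control_screen = None
    if control_groups:
        control_screen = screen.screen_group(dataset, control_groups[0])
        control_screen.to_csv(out / "screen_control.tsv", sep="\t")
    marker_sets = {}
    for group in tumor_groups:
        result = screen.screen_group(dataset, group)
        result.to_csv(out / f"screen_{group}.tsv", sep="\t")
        mset = screen.select_markers(result, control_screen, group, thresholds)
        marker_sets[group] = set(mset.analytes)
        (out / f"markers_{group}.txt").write_text(
            "\n".join(sorted(mset.analytes)) + "\n")
    if len(marker_sets) >= 2:
        venn = screen.venn_sets(marker_sets)
        (out / "markers_intersection.txt").write_text(
            "\n".join(sorted(venn.intersection)) + "\n")
        for group, unique in venn.unique.items():
            (out / f"markers_unique_{group}.txt").write_text(
                "\n".join(sorted(unique)) + "\n")
    return {g: len(s) for g, s in marker_sets.items()}


def _read_markers(path: Path, stage: str = "screen") -> list[str]:
    text = _require(path, stage).read_text().strip()
    return text.split("\n") if text else []


def _volume_dataset(config: PipelineConfig):
    out = _out(config)
    dataset = adat.read_adat(_require(out / "normalized.adat", "normalize"))
    study = dataset.subset_samples(dataset.study_ids).drop_hyb_controls()
    markers = _read_markers(out / "markers_intersection.txt")
    if not markers:
        raise ValueError("no shared markers selected; cannot train")
    return out, study, markers


def run_train_volume(config: PipelineConfig) -> dict:
    out, study, markers = _volume_dataset(config)
    mc = config.model
    seed = config.stage_seed("train-volume")
    train_ids, test_ids = models.split_holdout(
        study.samples, mc.holdout_fraction, seed)
    x_train, transform = models.make_design(study.values.loc[train_ids],
                                            markers)
    x_test, _ = models.make_design(study.values.loc[test_ids], markers,
                                   transform)
    vols = pd.to_numeric(study.samples["TumorVolume_mm3"])
    predictor = models.train_elastic_net(
        x_train, vols[train_ids], study.samples.loc[train_ids, "AnimalId"],
        mixing_grid=np.round(np.linspace(0.1, 1.0, mc.mixing_points), 3),
        n_lambda=mc.lambda_points, folds=mc.folds, seed=seed)
    predictor.transform = transform
    pred_train = models.predict_volume(predictor, x_train)
    pred_test = models.predict_volume(predictor, x_test)
    r2_train = models.evaluate_r2(vols[train_ids], pred_train)
    r2_test = models.evaluate_r2(vols[test_ids], pred_test)
    points, selected = models.scan_operating_point(
        pred_test, vols[test_ids] > 0, mc.rule)
    pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
        out / "operating_points.tsv", sep="\t", index=False)
    preds = pd.DataFrame({
        "actual_mm3": vols[test_ids], "predicted_mm3": pred_test,
    }, index=test_ids)
    preds.to_csv(out / "volume_predictions.tsv", sep="\t")
    _write_predictor(out / "volume_model.txt", predictor)
    metrics = {
        "r2_train": r2_train, "r2_test": r2_test,
        "panel_size": len(predictor.panel),
        "threshold_mm3": selected.threshold,
        "sensitivity": selected.sensitivity,
        "specificity": selected.specificity,
        "n_train": len(train_ids), "n_test": len(test_ids),
    }
    (out / "volume_metrics.json").write_text(json.dumps(metrics, indent=1))
    return metrics


def _write_predictor(path: Path, predictor: models.VolumePredictor) -> None:
    lines = [
        f"!Mixing\t{predictor.mixing}",
        f"!Lambda\t{predictor.strength}",
        f"!Intercept\t{predictor.intercept!r}",
        "SeqId\tCoefficient\tMean_log10\tSD_log10",
    ]
    for aid in predictor.coef.index:
        lines.append("\t".join([
            aid, repr(float(predictor.coef[aid])),
            repr(float(predictor.transform.mean[aid])),
            repr(float(predictor.transform.sd[aid])),
        ]))
    path.write_text("\n".join(lines) + "\n")


def run_classify(config: PipelineConfig) -> dict:
    out = _out(config)
    dataset = adat.read_adat(_require(out / "normalized.adat", "normalize"))
    study = dataset.subset_samples(dataset.study_ids).drop_hyb_controls()
    groups = _load_groups(out)
    tumor_groups = [g for g, line in groups.items()
                    if line != synthetic.CONTROL_LINE]
    feats: set[str] = set()
    for group in tumor_groups:
        feats |= set(_read_markers(out / f"markers_unique_{group}.txt"))
    if not feats:
        raise ValueError("no differentiating markers; cannot classify")
    vols = pd.to_numeric(study.samples["TumorVolume_mm3"])
    labels = np.where(vols > 0, study.samples["Group"], "control")
    seed = config.stage_seed("classify")
    train_ids, test_ids = models.split_holdout(
        study.samples, config.model.holdout_fraction, seed)
    x_train, transform = models.make_design(study.values.loc[train_ids],
                                            sorted(feats))
    x_test, _ = models.make_design(study.values.loc[test_ids], sorted(feats),
                                   transform)
    lab = pd.Series(labels, index=study.samples.index)
    clf = models.train_type_classifier(
        x_train, lab[train_ids], study.samples.loc[train_ids, "AnimalId"],
        seed=seed)
    clf.transform = transform
    models.evaluate_classifier(clf, x_test, lab[test_ids])
    for cls, (fpr, tpr, roc_auc) in clf.roc.items():
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            out / f"roc_{cls}.tsv", sep="\t", index=False)
    metrics = {
        "accuracy": clf.accuracy,
        "classes": clf.classes,
        "auc": {cls: roc[2] for cls, roc in clf.roc.items()},
        "n_features": len(feats),
    }
    (out / "classifier_metrics.json").write_text(json.dumps(metrics, indent=1))
    return metrics


def run_mdtv(config: PipelineConfig) -> dict:
    out = _out(config)
    dataset = adat.read_adat(_require(out / "normalized.adat", "normalize"))
    groups = _load_groups(out)
    scaling = mdtv_mod.BloodScaling(config.mdtv.mouse_ml, config.mdtv.human_ml)
    control_groups = [g for g, line in groups.items()
                      if line == synthetic.CONTROL_LINE and g != "calibrator"]
    all_rows = []
    for group, line in groups.items():
        if line == synthetic.CONTROL_LINE or group == "calibrator":
            continue
        markers = _read_markers(out / f"markers_{group}.txt")
        if not markers:
            continue
        mask = dataset.samples["Group"].isin([group] + control_groups) \
            & (dataset.samples["SampleType"] == "study")
        sub = dataset.subset_samples(dataset.samples.index[mask])
        vols = pd.to_numeric(sub.samples["TumorVolume_mm3"]).to_numpy()
        fits = {}
        for aid in markers:
            try:
                fits[aid] = mdtv_mod.fit_saturation(
                    vols, sub.values[aid].to_numpy())
            except (mdtv_mod.FitError, ValueError):
                continue
        rows = mdtv_mod.mdtv_table(fits, z=config.mdtv.z, scaling=scaling)
        for row in rows:
            row["group"] = group
        all_rows.extend(rows)
    table = pd.DataFrame(all_rows)
    table.to_csv(out / "mdtv_table.tsv", sep="\t", index=False)
    detectable = table[table["flag"] == ""] if len(table) else table
    return {"n_fits": len(table), "n_detectable": int(len(detectable))}


def _toy_gene_sets(truth: synthetic.TruthLedger, seed: int,
                   n_random: int = 10) -> list[enrichment.GeneSet]:
    """Synthetic gene-set collection over the simulated analyte menu.

    Built from the truth ledger: one set per planted responder class plus
    random null sets, so enrichment has signal to find.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(truth.analytes)
    sets = [enrichment.GeneSet("PLANTED_SHARED_RESPONSE",
                               frozenset(truth.shared_responders()),
                               "synthetic")]
    lines = sorted({t.line for t in truth.analytes.values() if t.line})
    for line in lines:
        members = {a for a, t in truth.analytes.items()
                   if t.analyte_class == synthetic.LINE_SPECIFIC
                   and t.line == line}
        if members:
            sets.append(enrichment.GeneSet(f"PLANTED_{line}_RESPONSE",
                                           frozenset(members), "synthetic"))
    for i in range(n_random):
        size = int(rng.integers(10, 40))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(enrichment.GeneSet(f"RANDOM_{i + 1:02d}",
                                       frozenset(members), "synthetic"))
    return sets


def run_enrich(config: PipelineConfig) -> dict:
    out = _out(config)
    groups = _load_groups(out)
    if config.gene_sets:
        gene_sets = enrichment.read_gmt(config.gene_sets)
    else:
        truth = _load_truth(out)
        gene_sets = _toy_gene_sets(truth, config.stage_seed("enrich"))
        enrichment.write_gmt(gene_sets, out / "toy_gene_sets.gmt")
    universe: set[str] | None = None
    truth_path = _truth_path(out)
    if truth_path.exists():
        universe = set(_load_truth(out).analytes)
    by_name = {gs.name: gs for gs in gene_sets}
    supporting: dict[str, set[str]] = {}
    enriched_sets: dict[str, enrichment.GeneSet] = {}
    n_tested = 0
    for group, line in groups.items():
        if line == synthetic.CONTROL_LINE or group == "calibrator":
            continue
        markers = set(_read_markers(out / f"markers_{group}.txt"))
        if not markers:
            continue
        result = enrichment.ora(markers, gene_sets, universe=universe)
        result.to_csv(out / f"ora_{group}.tsv", sep="\t")
        n_tested += 1
        kept = enrichment.filter_enriched(result, config.thresholds.q_enrich)
        for name in kept.index:
            enriched_sets[name] = by_name[name]
            supporting.setdefault(name, set()).add(group)
    emap = enrichment.build_map(enriched_sets, supporting,
                                config.thresholds.edge_threshold)
    nodes = pd.DataFrame(
        [{"set": n, "size": emap.graph.nodes[n]["size"],
          "models": ",".join(sorted(emap.graph.nodes[n]["models"]))}
         for n in emap.graph.nodes])
    edges = pd.DataFrame(
        [{"set1": a, "set2": b, **attrs}
         for a, b, attrs in emap.graph.edges(data=True)])
    nodes.to_csv(out / "map_nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "map_edges.tsv", sep="\t", index=False)
    (out / "map_clusters.txt").write_text(
        "\n".join(" ".join(sorted(c)) for c in emap.clusters) + "\n")
    return {"models_tested": n_tested, "enriched": len(enriched_sets),
            "clusters": len(emap.clusters),
            "removed_singletons": emap.removed_singletons}


_RUNNERS = {
    "simulate": run_simulate,
    "normalize": run_normalize,
    "screen": run_screen,
    "train-volume": run_train_volume,
    "classify": run_classify,
    "mdtv": run_mdtv,
    "enrich": run_enrich,
}


def run(stage: str, config: PipelineConfig) -> dict:
    """Run one stage, or every stage in order with ``stage='all'``."""
    out = _out(config)
    if stage == "all":
        summary = {}
        for name in STAGES:
            summary[name] = _RUNNERS[name](config)
        _write_manifest(out, config, STAGES)
        return summary
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ['all']}")
    result = _RUNNERS[stage](config)
    _write_manifest(out, config, [stage])
    return result


def _write_manifest(out: Path, config: PipelineConfig, stages: list[str]):
    from . import __version__

    manifest_path = out / "manifest.json"
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(), "stages": []}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest["stages"] = manifest.get("stages", []) + stages
    manifest_path.write_text(json.dumps(manifest, indent=1))
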