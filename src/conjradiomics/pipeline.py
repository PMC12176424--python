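"""End-to-end orchestration: simulate -> extract -> select -> train -> evaluate.

The pipeline runs the palpebral and bulbar regions over a shared cohort and
a shared participant-level split (so the two regions' test scores are
paired photo-for-photo, as the DeLong comparison requires), but keeps
everything downstream of the cohort — feature tables, selection, models —
separate per region.

A master seed fans out to per-stage seeds through a fixed counter scheme so
any stage can be rerun in isolation and reproduce its part bit-for-bit. An
access log records which participant ids each fitting stage touched; test
participants appear only in the evaluate stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from conjradiomics.classifier import (
    NetworkSpec,
    predict_scores,
    train_classifier,
    tune_hyperparameters,
)
from conjradiomics.features import (
    build_feature_table,
    feature_columns,
    impute_knn,
    minmax_scale,
    split_cohort,
    stability_select_features,
    zscore_standardize,
)
from conjradiomics.phantom import PhantomParams, generate_participants, generate_cohort
from conjradiomics.stats import auc_mann_whitney, delong_test, subgroup_rocs
from conjradiomics.texture import ExtractionConfig

__all__ = ["PipelineConfig", "PipelineResult", "extract_region_tables", "run_downstream", "run_pipeline"]

# Stage offsets of the counter-based seed fan-out.
_STAGE_SEEDS = {"cohort": 0, "split": 1, "select": 2, "tune": 3, "train": 4,
                "eval": 5}


@dataclass
class SelectionConfig:
    n_select: int = 20
    n_seeds: int = 20
    top_k: int = 30
    threshold: float = 0.8
    n_estimators: int = 100


@dataclass
class PipelineConfig:
    """Declarative configuration of one end-to-end run."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    regions: tuple[str, ...] = ("palpebral", "bulbar")
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train_fraction: float = 0.7
    tune: bool = False
    knn_impute_k: int = 5
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        # counter scheme: distinct, reproducible, and < 2**31
        return (self.master_seed * 16 + _STAGE_SEEDS[stage]) % (2**31)

    def config_hash(self) -> str:
        blob = json.dumps(_serialize(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _serialize(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serialize(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    return obj


@dataclass
class PipelineResult:
    """Per-region artifacts plus cross-region comparisons and the manifest."""

    participants: list
    tables: dict  # region -> (train, test) preprocessed tables
    selections: dict  # region -> SelectionResult
    models: dict  # region -> TrainedModel
    scores: dict  # region -> (test_scores, test_labels, test_meta)
    metrics: dict
    access_log: dict
    manifest: dict


def _split_participant_ids(participants, train_fraction, seed):
    df = pd.DataFrame(
        {"participant_id": [p.id for p in participants],
         "anemia": [int(p.anemia) for p in participants]}
    )
    tr, te = split_cohort(df, train_fraction=train_fraction, seed=seed)
    return set(tr["participant_id"]), set(te["participant_id"])


def extract_region_tables(config: PipelineConfig):
    """Simulate the cohort and extract per-region feature tables.

    The expensive stage: renders every photo for every region and runs the
    full radiomic extraction. Returns ``(participants, {region: table})``.
    """
    participants = generate_participants(
        replace(config.phantom, seed=config.stage_seed("cohort")))
    tables = {}
    for region in config.regions:
        params = replace(config.phantom, roi_kind=region,
                         seed=config.stage_seed("cohort"))
        _, photos = generate_cohort(params)
        tables[region] = build_feature_table(
            photos, participants, config.extraction)
    return participants, tables


def run_downstream(participants, region_tables, config: PipelineConfig,
                   label_permutation_seed: int | None = None,
                   out_dir=None) -> PipelineResult:
    """Split, preprocess, select, train and evaluate pre-extracted tables.

    ``label_permutation_seed``, when given, permutes the anemia labels at
    participant level before splitting (the null pipeline used for
    calibration checks).
    """
    t0 = time.time()
    access_log: dict[str, list[str]] = {}
    participants = [replace(p) for p in participants]

    if label_permutation_seed is not None:
        rng = np.random.default_rng(label_permutation_seed)
        labels = np.array([p.anemia for p in participants])
        perm = rng.permutation(len(labels))
        for p, lab in zip(participants, labels[perm]):
            p.anemia = bool(lab)
        label_map = {p.id: int(p.anemia) for p in participants}
        region_tables = {
            region: table.assign(
                anemia=table["participant_id"].map(label_map))
            for region, table in region_tables.items()
        }

    train_ids, test_ids = _split_participant_ids(
        participants, config.train_fraction, config.stage_seed("split"))
    access_log["split"] = sorted(train_ids)

    tables, selections, models, scores = {}, {}, {}, {}
    metrics: dict = {"regions": {}}
    stage_checksums: dict[str, str] = {}
    for region in config.regions:
        table = region_tables[region]
        stage_checksums[f"features_{region}"] = _df_checksum(table)

        train = table[table["participant_id"].isin(train_ids)].reset_index(drop=True)
        test = table[table["participant_id"].isin(test_ids)].reset_index(drop=True)
        train, test, _ = zscore_standardize(train, test)
        train, test = impute_knn(train, test, k=config.knn_impute_k)
        train, test, _ = minmax_scale(train, test)
        access_log[f"preprocess_{region}"] = sorted(
            train["participant_id"].unique())

        sel = stability_select_features(
            train,
            n_select=config.selection.n_select,
            n_seeds=config.selection.n_seeds,
            top_k=config.selection.top_k,
            threshold=config.selection.threshold,
            n_estimators=config.selection.n_estimators,
            base_seed=config.stage_seed("select"),
        )
        access_log[f"select_{region}"] = sorted(train["participant_id"].unique())

        spec = replace(config.network, seed=config.stage_seed("train"))
        if config.tune:
            spec = tune_hyperparameters(
                train, sel.selected, seed=config.stage_seed("tune"))
            spec = replace(spec, seed=config.stage_seed("train"))
        model = train_classifier(train, sel.selected, spec)
        access_log[f"train_{region}"] = sorted(train["participant_id"].unique())

        s = predict_scores(model, test)
        y = test["anemia"].to_numpy(dtype=int)
        auc = auc_mann_whitney(s, y)
        # participant-level aggregation: mean score over a participant's
        # photos; removes within-participant clustering from the ROC unit
        agg = (pd.DataFrame({"participant_id": test["participant_id"],
                             "score": s, "label": y})
               .groupby("participant_id", sort=True)
               .agg(score=("score", "mean"), label=("label", "first")))
        auc_part = auc_mann_whitney(agg["score"].to_numpy(),
                                    agg["label"].to_numpy())
        meta = test[["participant_id", "eye", "device", "sex"]]
        metrics["regions"][region] = {
            "auc": auc.as_dict(),
            "auc_participant": auc_part.as_dict(),
            "n_selected": len(sel.selected),
            "selected": sel.selected,
            "subgroups": subgroup_rocs(
                s, y, meta, seed=config.stage_seed("eval")),
        }
        tables[region] = (train, test)
        selections[region] = sel
        models[region] = model
        scores[region] = (s, y, meta)
        access_log[f"evaluate_{region}"] = sorted(test["participant_id"].unique())

    if len(config.regions) == 2:
        r0, r1 = config.regions
        s0, y0, _ = scores[r0]
        s1, y1, _ = scores[r1]
        # photos are rendered in identical participant/eye/device order per
        # region, so rows pair one-to-one
        if s0.size == s1.size and np.array_equal(y0, y1):
            d = delong_test(s0, s1, y0)
            metrics["region_comparison"] = {
                "test": "delong_paired", "regions": [r0, r1],
                "auc_a": d.auc_a, "auc_b": d.auc_b, "z": d.z, "p": d.p,
            }
            # participant-aggregated variant (independent ROC cases)
            m0, m1 = scores[r0][2], scores[r1][2]
            a0 = (pd.DataFrame({"pid": m0["participant_id"], "s": s0, "y": y0})
                  .groupby("pid", sort=True).agg(s=("s", "mean"), y=("y", "first")))
            a1 = (pd.DataFrame({"pid": m1["participant_id"], "s": s1, "y": y1})
                  .groupby("pid", sort=True).agg(s=("s", "mean"), y=("y", "first")))
            if a0.index.equals(a1.index):
                dp = delong_test(a0["s"].to_numpy(), a1["s"].to_numpy(),
                                 a0["y"].to_numpy().astype(bool))
                metrics["region_comparison_participant"] = {
                    "test": "delong_paired", "regions": [r0, r1],
                    "auc_a": dp.auc_a, "auc_b": dp.auc_b, "z": dp.z, "p": dp.p,
                }

    manifest = {
        "config_hash": config.config_hash(),
        "config": _serialize(config),
        "stage_checksums": stage_checksums,
        "n_train_participants": len(train_ids),
        "n_test_participants": len(test_ids),
        "runtime_s": round(time.time() - t0, 2),
    }
    metrics["n_train_participants"] = len(train_ids)
    metrics["n_test_participants"] = len(test_ids)

    result = PipelineResult(
        participants=participants, tables=tables, selections=selections,
        models=models, scores=scores, metrics=metrics,
        access_log=access_log, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def run_pipeline(config: PipelineConfig, out_dir=None,
                 label_permutation_seed: int | None = None) -> PipelineResult:
    """Execute the full analysis end-to-end for each configured region.

    Equivalent to :func:`extract_region_tables` followed by
    :func:`run_downstream`. When ``out_dir`` is given the feature tables,
    selection results, scores, metrics and a manifest with the config hash
    and stage checksums are written there.
    """
    participants, region_tables = extract_region_tables(config)
    return run_downstream(participants, region_tables, config,
                          label_permutation_seed=label_permutation_seed,
                          out_dir=out_dir)


def _df_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.round(10), index=False).values.tobytes()
    ).hexdigest()[:16]


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for region, (train, test) in result.tables.items():
        train.to_csv(out / f"features_{region}_train.csv", index=False)
        test.to_csv(out / f"features_{region}_test.csv", index=False)
        sidecar = {
            "region": region,
            "config_hash": config.config_hash(),
            "extraction": _serialize(config.extraction),
            "inventory_size": len(feature_columns(train)),
            "n_train_rows": len(train),
            "n_test_rows": len(test),
        }
        with open(out / f"features_{region}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        result.selections[region].to_json(out / f"selection_{region}.json")
        s, y, meta = result.scores[region]
        pd.DataFrame({
            "participant_id": meta["participant_id"],
            "eye": meta["eye"], "device": meta["device"],
            "score": s, "label": y,
        }).to_csv(out / f"scores_{region}.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump({**result.manifest, "access_log": result.access_log},
                  fh, indent=2, default=str)
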