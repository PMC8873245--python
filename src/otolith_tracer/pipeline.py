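"""End-to-end pipeline: ingest -> core detection -> segmentation ->
element selection -> per-river location models -> movement reconstruction
-> habitat statistics, with deterministic per-stage seeding and a
machine-readable run report."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import core_detection, element_selection, habitat_stats, location_model
from . import movement_reconstruction as mr
from . import segmentation, transect_io

logger = logging.getLogger("otolith_tracer")

__all__ = ["RunConfig", "PipelineError", "stage_seed", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and offending ids."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed from the global seed; adding a stage never
    shifts another stage's random stream."""
    digest = hashlib.blake2b(
        f"{global_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big")


@dataclass
class RunConfig:
    transects_path: str = ""
    sites_path: str = ""
    out_dir: str = "tracer_out"
    seed: int = 0
    dl_threshold: float = 0.25
    edge_window: tuple[float, float] = (2.0, 7.0)
    core_smooth_window: int = 5
    core_min_prominence: float = 3.0
    core_edge_exclusion: float = 0.1
    limb_rule: str = "longer"
    min_seg_len: int = 5
    max_partitions: int = 6
    penalty: float = 0.05
    importance_threshold_pct: float = 5.0
    importance_repeats: int = 10
    importance_trees: int = 500
    model_runs: int = 100
    model_trees: int = 500
    estuary_threshold: float = 0.5
    n_permutations: int = 9999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.edge_window = tuple(cfg.edge_window)  # yaml lists -> tuple
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["edge_window"] = list(self.edge_window)
        return d


@dataclass
class PipelineResult:
    report: dict[str, Any]
    histories: list[mr.MovementHistory] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, default=_jsonable)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(
    config: RunConfig,
    transects: list[transect_io.ElementalTransect] | None = None,
    sites: dict[str, transect_io.SamplingSite] | None = None,
) -> PipelineResult:
    """Execute the full inference chain.

    ``transects``/``sites`` may be passed in-memory (e.g. straight from
    the synthetic generator); otherwise they are read from the configured
    paths.
    """
    params_used: dict[str, Any] = config.to_dict()

    # ---- ingest -----------------------------------------------------
    stage = "ingest"
    try:
        if transects is None:
            if not config.transects_path:
                raise PipelineError(stage, "no transect table configured")
            transects, rejected = transect_io.read_transects(config.transects_path)
            if len(rejected):
                logger.warning("%d rows rejected at ingest", len(rejected))
        if sites is None:
            if not config.sites_path:
                raise PipelineError(stage, f"no site table at {config.sites_path!r}")
            sites = transect_io.read_sites(config.sites_path)
        retained, dl_report = transect_io.filter_elements(
            transects, config.dl_threshold
        )
        transects = [t.restrict_elements(retained) for t in transects]
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- core detection & orientation -------------------------------
    stage = "core_detection"
    try:
        calls = [
            core_detection.detect_core(
                t,
                smooth_window=config.core_smooth_window,
                min_prominence=config.core_min_prominence,
                edge_exclusion_fraction=config.core_edge_exclusion,
            )
            for t in transects
        ]
        cored, coreless, core_table = core_detection.split_cohort_by_core(
            transects, calls, sites
        )
        calls_by_fish = {c.fish_id: c for c in calls}
        oriented = [
            core_detection.orient_core_to_edge(
                t, calls_by_fish[t.fish_id], limb_rule=config.limb_rule
            )
            for t in cored
        ]
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- edge signatures --------------------------------------------
    stage = "edge_signatures"
    try:
        edge_sigs = {
            t.fish_id: transect_io.extract_edge_signature(t, config.edge_window)
            for t in oriented + coreless
        }
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    rivers = sorted({s.river_system for s in sites.values()})
    by_river_sites = {
        r: [s.site_id for s in sites.values() if s.river_system == r] for r in rivers
    }

    # ---- element selection ------------------------------------------
    stage = "element_selection"
    try:
        tables = {}
        for r in rivers:
            sigs = [
                edge_sigs[t.fish_id]
                for t in oriented + coreless
                if sites[t.capture_site_id].river_system == r
            ]
            tables[r] = element_selection.rank_element_importance(
                sigs,
                r,
                n_repeats=config.importance_repeats,
                n_trees=config.importance_trees,
                seed=stage_seed(config.seed, f"importance:{r}"),
            )
        selected = element_selection.select_elements(
            tables, config.importance_threshold_pct
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    importance_table = pd.concat(
        [t.scores.assign(river_system=r) for r, t in tables.items()]
    ).reset_index()

    # ---- segmentation -----------------------------------------------
    stage = "segmentation"
    try:
        psets = {
            t.fish_id: segmentation.segment_transect(
                t,
                min_seg_len=config.min_seg_len,
                max_partitions=config.max_partitions,
                penalty=config.penalty,
                elements=selected,
            )
            for t in oriented
        }
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- per-river location models & partition prediction -----------
    stage = "location_model"
    oriented_by_fish = {t.fish_id: t for t in oriented}
    oob_models = []
    predictions: dict[str, list[location_model.PartitionPrediction]] = {}
    try:
        for r in rivers:
            r_cored = [
                t for t in oriented if sites[t.capture_site_id].river_system == r
            ]
            r_coreless = [
                t for t in coreless if sites[t.capture_site_id].river_system == r
            ]
            if not r_cored:
                continue
            cored_rows = [
                location_model.last_partition_row(
                    psets[t.fish_id], t, selected
                )
                for t in r_cored
            ]
            coreless_rows = [
                location_model.coreless_edge_row(edge_sigs[t.fish_id], selected)
                for t in r_coreless
            ]
            full = location_model.build_training_set(r, cored_rows, coreless_rows)
            model = location_model.train_location_model(
                full,
                n_runs=config.model_runs,
                n_trees=config.model_trees,
                seed=stage_seed(config.seed, f"oob:{r}"),
            )
            oob_models.append(model)
            # leave-one-fish-out prediction keeps training and evaluation
            # rows independent
            for t in r_cored:
                held = location_model.build_training_set(
                    r, cored_rows, coreless_rows, holdout_fish=[t.fish_id]
                )
                held.audit_independence([t.fish_id])
                fit = location_model.train_location_model(
                    held,
                    n_runs=1,
                    n_trees=config.model_trees,
                    seed=stage_seed(config.seed, f"predict:{r}:{t.fish_id}"),
                )
                preds = []
                for rank, part in enumerate(psets[t.fish_id].partitions):
                    fp = part.fingerprint[
                        [t.element_index(e) for e in selected]
                    ]
                    preds.append(
                        location_model.predict_partition_location(
                            fit, fp, selected, fish_id=t.fish_id, partition_rank=rank
                        )
                    )
                predictions[t.fish_id] = preds
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    oob_summary = (
        location_model.summarize_oob(oob_models) if len(oob_models) >= 2 else None
    )

    # ---- estuarine-signature model ----------------------------------
    stage = "estuary_model"
    estuary_model = None
    try:
        est_rows, fresh_rows = [], []
        for t in oriented + coreless:
            site = sites[t.capture_site_id]
            sig = edge_sigs[t.fish_id]
            idx = [list(sig.elements).index(e) for e in selected]
            row = location_model.TrainingRow(
                fish_id=t.fish_id,
                site_id="estuary" if site.habitat == "estuary" else "freshwater",
                fingerprint=sig.fingerprint[idx],
                elements=tuple(selected),
                source="coreless_edge",
            )
            # estuarine signal: fish captured in estuaries; freshwater
            # signal: fish captured anywhere else (all freshwater habitats,
            # so mid-river signatures are represented in training)
            if site.habitat == "estuary":
                est_rows.append(row)
            else:
                fresh_rows.append(row)
        if est_rows and fresh_rows:
            est_training = location_model.TrainingSet(
                river_system="pooled", rows=est_rows + fresh_rows
            )
            estuary_model = location_model.train_location_model(
                est_training,
                n_runs=1,
                n_trees=config.model_trees,
                seed=stage_seed(config.seed, "estuary"),
            )
        else:
            warnings.warn("no estuary/upper contrast available; estuarine "
                          "flags default to False", stacklevel=2)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- movement reconstruction ------------------------------------
    stage = "movement_reconstruction"
    histories = []
    movement_rows = []
    try:
        for fish_id, preds in predictions.items():
            t = oriented_by_fish[fish_id]
            history = mr.reconstruct_movement(preds, sites)
            if estuary_model is not None:
                fps = np.vstack(
                    [
                        p.fingerprint[[t.element_index(e) for e in selected]]
                        for p in psets[fish_id].partitions
                    ]
                )
                flags, _ = mr.detect_estuarine_signature(
                    fps,
                    selected,
                    estuary_model,
                    estuarine_class="estuary",
                    threshold=config.estuary_threshold,
                    fish_id=fish_id,
                )
            else:
                flags = [False] * len(preds)
            history.estuarine_flags = flags
            mr.classify_life_history(
                history, sites[t.capture_site_id].habitat
            )
            histories.append(history)
            for rank, (site_pred, flag) in enumerate(
                zip(history.predicted_sites, flags)
            ):
                movement_rows.append(
                    {
                        "fish_id": fish_id,
                        "partition_rank": rank,
                        "predicted_site": site_pred,
                        "estuarine_flag": flag,
                        "vote_max": max(history.vote_proportions[rank].values()),
                    }
                )
        recruitment = (
            mr.summarize_recruitment(histories) if histories else pd.DataFrame()
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- habitat statistics -----------------------------------------
    stage = "habitat_stats"
    try:
        all_sigs = [edge_sigs[t.fish_id] for t in oriented + coreless]
        fps = np.vstack(
            [
                s.fingerprint[[list(s.elements).index(e) for e in selected]]
                for s in all_sigs
            ]
        )
        habitats = np.array([sites[s.site_id].habitat for s in all_sigs])
        seasons = np.array(
            [t.season for t in oriented + coreless], dtype=object
        )
        locations = np.array([s.site_id for s in all_sigs])
        perm_seed = stage_seed(config.seed, "permanova")
        overall = habitat_stats.permanova(
            fps, habitats, n_permutations=config.n_permutations, seed=perm_seed
        )
        pairwise = habitat_stats.pairwise_permanova(
            fps, habitats, n_permutations=config.n_permutations, seed=perm_seed
        )
        per_element = habitat_stats.per_element_tests(fps, habitats, selected)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            season_results = habitat_stats.season_effect_test(
                fps, locations, seasons, n_permutations=999, seed=perm_seed
            )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    report = {
        "parameters": params_used,
        "n_fish": len(transects),
        "n_core_identified": len(oriented),
        "n_core_not_identified": len(coreless),
        "retained_elements_dl": retained,
        "selected_elements": selected,
        "oob_by_river": {
            m.river_system: {
                "mean_accuracy": m.oob_mean,
                "sd_accuracy": m.oob_sd,
                "mean_error": 1 - m.oob_mean,
            }
            for m in oob_models
        },
        "life_history_summary": recruitment.to_dict(orient="records")
        if len(recruitment)
        else [],
        "permanova": {
            "pseudo_F": overall.pseudo_f,
            "p": overall.p_value,
            "n_permutations": overall.n_permutations,
            "group_sizes": overall.group_sizes,
        },
        "season_effect": {
            loc: {"pseudo_F": r.pseudo_f, "p": r.p_value}
            for loc, r in season_results.items()
        },
        "rivers": {r: by_river_sites[r] for r in rivers},
    }
    tables = {
        "core_table": core_table,
        "dl_report": dl_report,
        "importance": importance_table,
        "movement": pd.DataFrame(movement_rows),
        "pairwise_permanova": pairwise,
        "per_element_tests": per_element,
        "life_history": recruitment,
    }
    if oob_summary is not None:
        tables["oob_summary"] = oob_summary
    return PipelineResult(report=report, histories=histories, tables=tables)
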