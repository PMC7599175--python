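"""End-to-end orchestration: simulate -> select -> zones -> train -> predict
-> evaluate, under one config and one global seed.

The global seed fans out to per-stage seeds through a splittable seed
sequence, so any stage can be re-run in isolation with its own seed.

Two zone-fitting protocols are supported. ``fit_zones="per-fold"`` (the
default, leakage-free) assigns the stratified folds on the full analysis
set and rebuilds the zones inside each 3-fold training split; a subject is
screened with the zones of its own held-out fold, so a delayed subject
unlike the training delayed cluster can fall outside — the mechanism by
which step 1 produces false negatives on unseen data. ``fit_zones="once"``
fits a single zone set on all delayed subjects before folding, the
resubstitution-style alternative.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddcrz import INCOMPLETE, MEMBER, RelaxedZoneSet, build_ddcrz, zone_membership
from .evaluation import IN_ZONE, WHOLE_DATASET, score
from .fnn_ensemble import (DELAYED, EXCLUDED, NORMAL, EnsemblePredictor,
                           FnnSpec, _feature_matrix, _train_type,
                           ensemble_to_dict, predict, stratified_folds,
                           tally_votes, train_ensemble)
from .ld_selection import SelectionResult, select_characteristics
from .synthetic_cohort import (CharacteristicDescriptor, ClassDistribution,
                               CohortSpec, CohortTable, generate_cohort,
                               read_cohort, write_cohort)

log = logging.getLogger("neoprog")

_DEFAULT_PREVALENCE = {"motor": 0.126, "cognitive": 7 / 115}
_DEFAULT_INNER_SIZE = {"motor": 5, "cognitive": 4}


@dataclass(frozen=True)
class RunConfig:
    """Every stage parameter of one reproducible run.

    Defaults mirror the study conditions: a 103-subject motor cohort at
    12.6% prevalence, LD cut 0.375 with an inner subset of 5 (motor) or 4
    (cognitive), 10%-of-range zone relaxation with full (AND) membership,
    and a 4-fold x 100-network ensemble with a 2-of-4 final vote.
    """

    outcome: str = "motor"
    n_subjects: int = 103
    prevalence: float | None = None  # None -> outcome default
    dropout_rate: float = 0.0
    severe_injury_rate: float = 0.0
    ld_threshold: float = 0.375
    inner_size: int | None = None  # None -> outcome default
    min_delayed: int = 3
    relaxation: float = 0.10
    membership_fraction: float = 1.0
    fit_zones: str = "per-fold"  # or "once"
    folds: int = 4
    nets_per_type: int = 100
    vote_threshold_final: int = 2
    n_hidden: int | None = None
    max_epochs: int = 200
    learning_rate: float = 0.5
    exclude_severe: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in ("motor", "cognitive"):
            raise ValueError("outcome must be 'motor' or 'cognitive'")
        if self.fit_zones not in ("per-fold", "once"):
            raise ValueError("fit_zones must be 'per-fold' or 'once'")

    @property
    def effective_prevalence(self) -> float:
        return (self.prevalence if self.prevalence is not None
                else _DEFAULT_PREVALENCE[self.outcome])

    @property
    def effective_inner_size(self) -> int:
        return (self.inner_size if self.inner_size is not None
                else _DEFAULT_INNER_SIZE[self.outcome])

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fan one global seed out into per-stage 31-bit seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass
class PipelineResult:
    cohort: CohortTable
    selection: SelectionResult
    predictions: pd.DataFrame  # subject_id, label, membership, counts, final
    in_zone: "MetricReport"
    whole: "MetricReport"
    zones: RelaxedZoneSet | list[RelaxedZoneSet]
    ensemble: EnsemblePredictor | None


def _fit_predict_per_fold(table: CohortTable, selection: SelectionResult,
                          config: RunConfig, fnn_spec: FnnSpec,
                          seed: int) -> tuple[pd.DataFrame, list[RelaxedZoneSet]]:
    """Leakage-free protocol: per-training-split zones, held-out screening."""
    labels = table.labels
    ss = np.random.SeedSequence(seed)
    fold_seed, *type_seeds = ss.spawn(1 + config.folds)
    folds = stratified_folds(labels, config.folds,
                             np.random.default_rng(fold_seed))
    zone_sets: list[RelaxedZoneSet] = []
    type_models = []
    member_rows: dict[int, list[int]] = {}
    for k in range(config.folds):
        train_table = table.restrict(folds != k)
        zones_k = build_ddcrz(train_table, selection, config.relaxation,
                              config.membership_fraction)
        zone_sets.append(zones_k)
        # training members of type k: training-split subjects inside zones_k
        tr_idx = np.flatnonzero(folds != k)
        statuses = [zone_membership(table.subject_values(i), zones_k)
                    for i in tr_idx]
        m_idx = np.array([i for i, s in zip(tr_idx, statuses) if s == MEMBER])
        if len(m_idx) == 0 or labels[m_idx].sum() == 0:
            raise ValueError(f"type {k}: no delayed training members; use "
                             "fewer folds or more data")
        member_rows[k] = list(m_idx)
        X = _feature_matrix(table.restrict(np.isin(np.arange(len(table)), m_idx)),
                            selection.inner_subset)
        y = labels[m_idx]
        type_models.append(_train_type(
            X, y, np.arange(len(m_idx)), np.array([], dtype=int),
            fnn_spec, config.nets_per_type,
            np.random.default_rng(type_seeds[k])))

    rows = []
    for i in range(len(table)):
        k = int(folds[i])
        sv = table.subject_values(i)
        status = zone_membership(sv, zone_sets[k])
        counts: list[int | None]
        if status == MEMBER:
            try:
                x = np.array([[sv[c] for c in selection.inner_subset]])
            except KeyError:
                status = INCOMPLETE
        if status == MEMBER:
            counts = [int((m.probabilities(x)[:, 0, 1] >= 0.5).sum())
                      for m in type_models]
            record = tally_votes(counts, config.nets_per_type,
                                 config.vote_threshold_final)
            final = DELAYED if record.final_delayed else NORMAL
        else:
            counts = [None] * config.folds
            final = EXCLUDED if status == INCOMPLETE else NORMAL
        rows.append({
            "subject_id": table.df["subject_id"].iloc[i],
            "label": int(labels[i]),
            "step1": status,
            **{f"type{j}_count": counts[j] for j in range(config.folds)},
            "final": final,
        })
    return pd.DataFrame(rows), zone_sets


def _fit_predict_once(table: CohortTable, selection: SelectionResult,
                      config: RunConfig, fnn_spec: FnnSpec, seed: int,
                      ) -> tuple[pd.DataFrame, RelaxedZoneSet, EnsemblePredictor]:
    """Fit-once protocol: one zone set, ensemble folded over its members."""
    zones = build_ddcrz(table, selection, config.relaxation,
                        config.membership_fraction)
    statuses = [zone_membership(table.subject_values(i), zones)
                for i in range(len(table))]
    members = table.restrict([s == MEMBER for s in statuses])
    ensemble = train_ensemble(members, selection, fnn_spec, seed=seed,
                              n_folds=config.folds,
                              nets_per_type=config.nets_per_type,
                              vote_threshold_final=config.vote_threshold_final)
    rows = []
    for i, status in enumerate(statuses):
        sv = table.subject_values(i)
        if status == MEMBER:
            record = predict(sv, ensemble)
            counts = list(record.counts)
            final = DELAYED if record.final_delayed else NORMAL
        else:
            counts = [None] * config.folds
            final = EXCLUDED if status == INCOMPLETE else NORMAL
        rows.append({
            "subject_id": table.df["subject_id"].iloc[i],
            "label": int(table.labels[i]),
            "step1": status,
            **{f"type{j}_count": counts[j] for j in range(config.folds)},
            "final": final,
        })
    return pd.DataFrame(rows), zones, ensemble


def _score_predictions(pred: pd.DataFrame, excluded_severe: bool):
    in_scope = pred[pred["step1"] == MEMBER]
    in_zone = score(in_scope["final"], in_scope["label"], scope=IN_ZONE,
                    excluded_severe=excluded_severe)
    whole = score(pred["final"], pred["label"], scope=WHOLE_DATASET,
                  excluded_severe=excluded_severe)
    return in_zone, whole


def run_pipeline(config: RunConfig, out_dir=None, cohort_path=None,
                 dist: ClassDistribution | None = None) -> PipelineResult:
    """Run the full two-step analysis; optionally write the run directory.

    With ``cohort_path`` the cohort is read from CSV; otherwise one is
    simulated from the packaged class-conditional defaults for
    ``config.outcome``. Re-running with an identical config reproduces
    metrics.json byte for byte.
    """
    sim_seed, select_seed, train_seed, _ = stage_seeds(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig()

    def _stage(name):
        log.info("stage %s", name)

    try:
        if cohort_path is not None:
            table = read_cohort(cohort_path)
        else:
            spec = CohortSpec(n_subjects=config.n_subjects,
                              prevalence=config.effective_prevalence,
                              dropout_rate=config.dropout_rate,
                              severe_injury_rate=config.severe_injury_rate,
                              seed=sim_seed)
            table = generate_cohort(spec, dist, outcome=config.outcome)
            if out is not None:
                write_cohort(table, out / "cohort.csv")
    except Exception as e:
        raise RuntimeError(f"stage simulate: {e}") from e

    if config.exclude_severe:
        table = table.restrict(table.df["severe_injury"].to_numpy() == 0)

    # subjects missing any selected characteristic are excluded from steps
    # 1-2; selection itself uses per-characteristic pairwise deletion
    try:
        selection = select_characteristics(
            table, ld_threshold=config.ld_threshold,
            inner_size=config.effective_inner_size,
            min_delayed=config.min_delayed)
        if not selection.selected:
            raise ValueError("no characteristic passed the LD threshold")
    except Exception as e:
        raise RuntimeError(f"stage select: {e}") from e

    fnn_spec = FnnSpec(n_hidden=config.n_hidden, max_epochs=config.max_epochs,
                       learning_rate=config.learning_rate)
    ensemble = None
    try:
        if config.fit_zones == "per-fold":
            pred, zones = _fit_predict_per_fold(table, selection, config,
                                                fnn_spec, train_seed)
        else:
            pred, zones, ensemble = _fit_predict_once(table, selection, config,
                                                      fnn_spec, train_seed)
    except Exception as e:
        raise RuntimeError(f"stage train: {e}") from e

    try:
        in_zone, whole = _score_predictions(pred, config.exclude_severe)
    except Exception as e:
        raise RuntimeError(f"stage evaluate: {e}") from e

    if out is not None:
        _write_artifacts(out, config, table, selection, zones, ensemble,
                         pred, in_zone, whole)
    return PipelineResult(cohort=table, selection=selection, predictions=pred,
                          in_zone=in_zone, whole=whole, zones=zones,
                          ensemble=ensemble)


def selection_to_dict(selection: SelectionResult) -> dict:
    return {
        "ld_threshold": selection.ld_threshold,
        "selected": [c.column for c in selection.selected],
        "inner_subset": [c.column for c in selection.inner_subset],
        "profiles": [
            {"characteristic": p.characteristic.column, "ld": p.ld,
             "occupied_octiles": p.occupied_octiles,
             "range_low": p.range_low, "range_high": p.range_high,
             "n_delayed_used": p.n_delayed_used}
            for p in selection.all_profiles
        ],
    }


def zones_to_dict(zones) -> dict:
    def one(z: RelaxedZoneSet) -> dict:
        return {"relaxation": z.relaxation,
                "membership_fraction": z.membership_fraction,
                "n_train": z.n_train,
                "zones": {c.column: list(z.zones[c])
                          for c in z.characteristics}}
    if isinstance(zones, list):
        return {"mode": "per-fold", "per_type": [one(z) for z in zones]}
    return {"mode": "once", **one(zones)}


def zones_from_dict(d: dict) -> RelaxedZoneSet:
    if d.get("mode") == "per-fold":
        raise ValueError("per-fold zone files hold one zone set per type; "
                         "load them individually")
    return RelaxedZoneSet(
        zones={CharacteristicDescriptor.from_column(c): tuple(v)
               for c, v in d["zones"].items()},
        relaxation=d["relaxation"],
        membership_fraction=d["membership_fraction"],
        n_train=d["n_train"])


def _metrics_payload(config, in_zone, whole) -> dict:
    def block(rep):
        c = rep.counts
        return {"counts": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
                "metrics": rep.summary()}
    return {"outcome": config.outcome, "exclude_severe": config.exclude_severe,
            "in_zone": block(in_zone), "whole_dataset": block(whole)}


def _write_artifacts(out: Path, config, table, selection, zones, ensemble,
                     pred, in_zone, whole) -> None:
    with open(out / "selection.json", "w") as f:
        json.dump(selection_to_dict(selection), f, indent=2)
    with open(out / "zones.json", "w") as f:
        json.dump(zones_to_dict(zones), f, indent=2)
    if ensemble is not None:
        with open(out / "model.json", "w") as f:
            json.dump(ensemble_to_dict(ensemble), f)
    pred.to_csv(out / "predictions.csv", index=False)
    with open(out / "metrics.json", "w") as f:
        json.dump(_metrics_payload(config, in_zone, whole), f, indent=2,
                  sort_keys=True)
    with open(out / "run.log", "w") as f:
        f.write(f"neoprog {__version__}\n")
        f.write(f"config_hash {config.digest()}\n")
        for k, v in asdict(config).items():
            f.write(f"{k} = {v}\n")
        f.write(f"effective_prevalence = {config.effective_prevalence}\n")
        f.write(f"effective_inner_size = {config.effective_inner_size}\n")
        f.write(f"n_subjects_analysed = {len(table)}\n")
        f.write(f"selected = {[str(c) for c in selection.selected]}\n")
        f.write(f"inner_subset = {[str(c) for c in selection.inner_subset]}\n")
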