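"""End-to-end pipeline: curate -> split -> (distort) -> fit-dict -> encode
-> train -> evaluate.

The feature dictionary is fitted on training molecules only by default so
no test-set geometry leaks into the bin boundaries; ``dict_on_all``
restores the literal fit-on-everything behaviour.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import Molecule, read_structure, perceive_bonds, read_targets, attach_targets
from .curation import FilterConfig, apply_filters, dedupe_free_energy, split_by_stoichiometry
from .featurizer import FeaturizerConfig, build_dictionary, encode_matrix
from .augment import DistortionConfig, augment_training_set
from .models import ModelConfig, train, predict, evaluate_mae, save_model

__all__ = ["RunConfig", "RunResult", "PipelineError", "run_pipeline", "load_structures"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    structures_dir: str | None = None
    targets_csv: str | None = None
    output_dir: str | None = None
    target_kind: str = "electronic"        # electronic | free
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    split_seed: int = 0
    test_fraction: float = 0.33
    distortion: DistortionConfig | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    dict_on_all: bool = False
    dedupe_free_energies: bool = False
    bond_scale: float = 1.15

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: conv(getattr(v, k)) for k in v.__dataclass_fields__}
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            return v
        return {k: conv(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass
class RunResult:
    dictionary: object
    model: object
    predictions: pd.DataFrame
    train_mae: float
    test_mae: float
    filter_report: object
    split: object
    manifest: dict


def load_structures(directory: str | Path, bond_scale: float = 1.15) -> list[Molecule]:
    """Read every .xyz/.sdf file in a directory, perceiving bonds where absent."""
    mols = []
    for p in sorted(Path(directory).iterdir()):
        if p.suffix.lower() not in (".xyz", ".sdf", ".mol"):
            continue
        m = read_structure(p)
        if not m.bonds:
            m = perceive_bonds(m, scale=bond_scale)
        mols.append(m)
    return mols


def _target_of(m: Molecule, kind: str) -> float:
    v = m.electronic_energy if kind == "electronic" else m.free_energy
    if v is None:
        raise PipelineError(f"train: molecule {m.id} is missing its {kind} energy target")
    return v


def run_pipeline(config: RunConfig,
                 molecules: list[Molecule] | None = None) -> RunResult:
    """Run the full pipeline on loaded molecules (or load them from config
    paths), returning all artifacts; writes them out when an output dir is
    configured."""
    cfg = config
    if molecules is None:
        if cfg.structures_dir is None:
            raise PipelineError("load: no molecules given and no structures_dir configured")
        molecules = load_structures(cfg.structures_dir, cfg.bond_scale)
        if cfg.targets_csv:
            molecules = attach_targets(molecules, read_targets(cfg.targets_csv))
    molecules = [m if m.bonds else perceive_bonds(m, cfg.bond_scale) for m in molecules]

    # -- curation ----------------------------------------------------------
    report = apply_filters(molecules, cfg.filters)
    kept = report.kept_molecules(molecules)
    if cfg.dedupe_free_energies:
        dd = dedupe_free_energy(kept)
        report.removed.update(dd.removed)
        report.kept = dd.kept
        kept = dd.kept_molecules(kept)
    if not kept:
        raise PipelineError("curate: no molecules survive the filters")

    # -- split -------------------------------------------------------------
    split = split_by_stoichiometry(kept, cfg.test_fraction, cfg.split_seed)
    train_mols = [m for m in kept if m.id in split.train]
    test_mols = [m for m in kept if m.id in split.test]
    if not train_mols or not test_mols:
        raise PipelineError("split: empty train or test set")

    # -- distortion augmentation (training side only) ------------------------
    if cfg.distortion is not None:
        train_mols = augment_training_set(train_mols, cfg.distortion)

    # -- dictionary (train only unless told otherwise) -----------------------
    dict_mols = (kept if cfg.dict_on_all else train_mols)
    test_ids = {m.id for m in test_mols}
    if not cfg.dict_on_all and any(m.id in test_ids for m in dict_mols):
        raise PipelineError("fit-dict: test molecules passed to dictionary fitting")
    dictionary = build_dictionary(dict_mols, cfg.featurizer)

    # -- encode + train ------------------------------------------------------
    Xtr, ids_tr, _ = encode_matrix(train_mols, dictionary)
    Xte, ids_te, dropped = encode_matrix(test_mols, dictionary)
    ytr = np.array([_target_of(m, cfg.target_kind) for m in train_mols])
    yte = np.array([_target_of(m, cfg.target_kind) for m in test_mols])
    model = train(Xtr, ytr, cfg.model,
                  dictionary_fingerprint=dictionary.fingerprint(),
                  target_kind=cfg.target_kind)
    pred_tr = predict(model, Xtr)
    pred_te = predict(model, Xte)
    train_mae = evaluate_mae(pred_tr, ytr)
    test_mae = evaluate_mae(pred_te, yte)
    preds = pd.DataFrame({
        "id": ids_tr + ids_te,
        "set": ["train"] * len(ids_tr) + ["test"] * len(ids_te),
        "truth": np.concatenate([ytr, yte]),
        "prediction": np.concatenate([pred_tr, pred_te]),
    })

    manifest = {
        "config": cfg.to_dict(),
        "n_input": len(molecules), "n_kept": len(report.kept),
        "n_train": len(train_mols), "n_test": len(test_mols),
        "n_unassigned": len(split.unassigned),
        "dictionary_fingerprint": dictionary.fingerprint(),
        "dictionary_length": dictionary.total_length,
        "dropped_test_observations": dropped,
        "train_mae": train_mae, "test_mae": test_mae,
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "dictionary.json").write_text(dictionary.to_json())
        (out / "filter_report.json").write_text(report.to_json())
        (out / "split.json").write_text(split.to_json())
        preds.to_csv(out / "predictions.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        save_model(model, out / "model.joblib")

    return RunResult(dictionary, model, preds, train_mae, test_mae, report, split, manifest)
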