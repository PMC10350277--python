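"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` executes the canonical stage order — simulate (or load)
-> preprocess -> extract -> stability -> select -> train -> evaluate —
on declared training/testing patient lists, normalizes the test cohort
with the training statistics (carried inside the fitted signature), and
writes a JSON manifest (config, seeds, stage summaries) so a run can be
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import RadiomicSignature
from .preprocess import PreprocessConfig, preprocess_patient
from .radiomics import ExtractionConfig, extract_all
from .selection import SelectionConfig
from .stability import perturb_mask, stability_screen
from .survival_eval import SurvivalData
from .synthetic import PhantomCohort, PhantomSpec, generate_phantom_cohort
from .volume import load_nifti_mask, load_nifti_volume

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Training vs testing cohorts are declared by patient-id lists, never
    inferred; when both are None the cohort is split in half by order.
    All randomness derives from ``seed`` via named substreams.
    """

    out_dir: str = "radpipe_run"
    seed: int = 0
    # simulation (used when input_dir is None)
    n_patients: int = 40
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    survival_beta: float = 1.0
    # or: load NIfTI + survival.csv from here
    input_dir: str | None = None
    train_ids: list[str] | None = None
    test_ids: list[str] | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    icc_threshold: float = 0.75
    perturb_fraction: float = 0.10
    run_stability: bool = True
    n_boot_eval: int = 100


def _load_cohort(input_dir: str) -> PhantomCohort:
    from .synthetic import PhantomPatient

    d = Path(input_dir)
    df = pd.read_csv(d / "survival.csv")
    surv = SurvivalData.from_frame(df)
    patients = []
    for pid in surv.patient_id:
        t1 = load_nifti_volume(str(d / f"{pid}_T1w.nii.gz"), "T1w")
        t2 = load_nifti_volume(str(d / f"{pid}_T2w.nii.gz"), "T2w")
        mask = load_nifti_mask(str(d / f"{pid}_mask.nii.gz"))
        patients.append(PhantomPatient(pid, t1, t2, mask, np.nan))
    stages = df[[c for c in ("patient_id", "cTNM", "pTNM") if c in df]]
    return PhantomCohort(patients, surv, stages, np.full(len(surv), np.nan))


def _extract_cohort(patients, cfg: RunConfig,
                    perturbed: bool = False) -> list[pd.DataFrame]:
    """Preprocess + extract every patient; with ``perturbed`` also under
    the 4 translated-mask conditions (stability analysis input)."""
    tables: list[dict[str, pd.Series]] = []
    n_cond = 1
    for p in patients:
        t1, t2, mask = preprocess_patient(p.t1, p.t2, p.mask, cfg.preprocess)
        conds = [mask]
        if perturbed:
            pset = perturb_mask(mask, cfg.perturb_fraction)
            conds = pset.conditions
            n_cond = len(conds)
        tables.append({p.patient_id: [
            extract_all(t1, t2, m, cfg.extraction) for m in conds]})
    out = []
    for c in range(n_cond):
        rows = {pid: vecs[c] for tab in tables for pid, vecs in tab.items()}
        out.append(pd.DataFrame(rows).T)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the pipeline and return the run manifest (also written to
    ``out_dir/manifest.json`` along with stage outputs)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: simulate or load ------------------------------------------------
    if cfg.input_dir is None:
        cohort = generate_phantom_cohort(cfg.n_patients, cfg.phantom,
                                         survival_beta=cfg.survival_beta,
                                         seed=cfg.seed)
        logger.info("simulated %d phantom patients", cfg.n_patients)
    else:
        cohort = _load_cohort(cfg.input_dir)
        logger.info("loaded %d patients from %s", len(cohort.survival),
                    cfg.input_dir)

    ids = list(cohort.survival.patient_id)
    if cfg.train_ids is None:
        half = len(ids) // 2
        train_ids = ids[:half]
        test_ids = ids[half:] if cfg.test_ids is None else cfg.test_ids
    else:
        train_ids = list(cfg.train_ids)
        test_ids = list(cfg.test_ids) if cfg.test_ids is not None else \
            [i for i in ids if i not in train_ids]
    id_pos = {pid: k for k, pid in enumerate(ids)}
    tr_idx = [id_pos[i] for i in train_ids]
    te_idx = [id_pos[i] for i in test_ids]

    # stage: preprocess + extract (+ perturbed conditions on training) ------
    train_pats = [cohort.patients[i] for i in tr_idx]
    test_pats = [cohort.patients[i] for i in te_idx]
    train_tabs = _extract_cohort(train_pats, cfg, perturbed=cfg.run_stability)
    test_tabs = _extract_cohort(test_pats, cfg, perturbed=False)
    train_features = train_tabs[0]
    test_features = test_tabs[0]
    train_features.to_csv(out / "features_train.csv")
    test_features.to_csv(out / "features_test.csv")
    with open(out / "extraction_config.json", "w") as fh:
        json.dump(cfg.extraction.to_dict(), fh, indent=1)

    # stage: stability -------------------------------------------------------
    if cfg.run_stability:
        report = stability_screen(train_tabs, cfg.icc_threshold)
        stable = report.stable_features
        report.table.to_csv(out / "icc_report.csv", index=False)
    else:
        stable = list(train_features.columns)
    # drop features that are constant on the training cohort (un-normalizable)
    sd = train_features[stable].std(axis=0)
    stable = [f for f in stable if sd[f] > 0]
    logger.info("%d stable features retained", len(stable))

    # stage: select + train --------------------------------------------------
    train_surv = cohort.survival.subset(tr_idx)
    test_surv = cohort.survival.subset(te_idx)
    model = RadiomicSignature(train_features[stable], train_surv,
                              selection=cfg.selection)
    results = model.fit(seed=cfg.seed)
    results.signature.to_json(str(out / "signature.json"))
    (out / "summary.txt").write_text(results.summary() + "\n")

    # stage: evaluate ---------------------------------------------------------
    eval_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 777)))
    report_train = results.evaluate(n_boot=cfg.n_boot_eval, rng=eval_rng)
    report_test = results.evaluate(test_features, test_surv,
                                   n_boot=cfg.n_boot_eval, rng=eval_rng)

    cfg_json = json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True)
    manifest = {
        "radpipe_version": __version__,
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "selection_seeds": cfg.selection.resolved_seeds(cfg.seed),
        "train_ids": train_ids,
        "test_ids": test_ids,
        "n_stable_features": len(stable),
        "selected_features": results.signature.features,
        "threshold": results.threshold,
        "evaluation": {"train": report_train.to_dict(),
                       "test": report_test.to_dict()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def validate_inputs(input_dir: str) -> list[str]:
    """Schema/sanity checks on an input directory; returns the list of
    violations (empty when clean)."""
    problems: list[str] = []
    d = Path(input_dir)
    surv_path = d / "survival.csv"
    if not surv_path.exists():
        return [f"missing {surv_path}"]
    df = pd.read_csv(surv_path)
    for col in ("patient_id", "time_months", "event"):
        if col not in df.columns:
            problems.append(f"survival.csv lacks column {col!r}")
    if problems:
        return problems
    bad_t = df["time_months"] <= 0
    if bad_t.any():
        problems.append(f"non-positive follow-up time for "
                        f"{df.loc[bad_t, 'patient_id'].tolist()}")
    bad_e = ~df["event"].isin((0, 1))
    if bad_e.any():
        problems.append(f"event indicator not 0/1 for "
                        f"{df.loc[bad_e, 'patient_id'].tolist()}")

    import nibabel as nib
    for pid in df["patient_id"]:
        shapes = {}
        for kind in ("T1w", "T2w", "mask"):
            path = d / f"{pid}_{kind}.nii.gz"
            if not path.exists():
                problems.append(f"missing {path.name}")
                continue
            img = nib.load(str(path))
            shapes[kind] = img.shape
            if kind == "mask":
                vals = np.unique(np.asanyarray(img.dataobj))
                if not np.all(np.isin(vals, (0, 1))):
                    problems.append(f"{path.name}: mask not binary")
        if len(set(shapes.values())) > 1:
            problems.append(f"{pid}: grids disagree {shapes}")
    return problems
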