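"""End-to-end orchestration: per-patient integrated dossiers.

Combines the phenotype table, trio variant prioritization (with optional
microsatellite phase resolution) and misrouting statistics (from supplied
epoch containers or a seeded simulation) into one
:class:`PatientDossier` per patient plus cohort-level summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import datasets, io as ocio
from .misrouting import (
    GroupMisroutingStats,
    MisroutingResult,
    evaluate_waveform_pair,
    group_chiasm_ttest,
)
from .phenotype import KruijtAssessment, assess_kruijt, summarize_cohort
from .preprocess import preprocess_epochs
from .simulate import VepSimConfig, simulate_vep_cohort
from .strs import haplo_identity, resolve_polymorphism_phase
from .variants import (
    DIAGNOSTIC_CLASSES,
    HYPOMORPHIC_PAIR,
    phase_trio,
    prioritize_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class PatientDossier:
    """Integrated per-patient result.

    The with-molecular Kruijt verdict uses ``has_molecular_dx = True``
    exactly when the genotype classification is diagnostic (biallelic
    pathogenic, or pathogenic in trans with the hypomorphic haplotype).
    """

    patient_id: str
    phenotype: object | None = None
    misrouting: MisroutingResult | None = None
    misrouting_assessed: bool = False
    classification: str | None = None
    phase_status: str | None = None
    kruijt_clinical: KruijtAssessment | None = None
    kruijt_with_molecular: KruijtAssessment | None = None
    error: str | None = None


def default_config() -> dict:
    """Configuration pointing at the packaged cohort fixtures."""
    return {
        "phenotype_table": str(datasets.table1_phenotypes_path()),
        "vcf": str(datasets.trio_vcf_path()),
        "ped": str(datasets.trio_ped_path()),
        "annotations": str(datasets.annotations_path()),
        "panel": str(datasets.gene_panel_path()),
        "montage": str(datasets.montage_path()),
        "str_table": str(datasets.str_table_path()),
        "str_family": {
            "sib1": "P4",
            "sib2": "P5",
            "father": "F45_F",
            "mother": "F45_M",
            "apply_to": ["P4", "P5"],
        },
        "resolve_phase": True,
        "vep": None,  # None | {"simulate": {...VepSimConfig kwargs...}}
        "seed": 0,
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _str_phase_resolutions(config, families, pathogenic) -> dict:
    """Microsatellite haplo-identity -> cis-phase resolution for the sibs."""
    spec = config.get("str_family") or {}
    table = config.get("str_table")
    if not table or not spec:
        return {}
    genotypes = ocio.read_str_table(table)
    sib1, sib2 = spec["sib1"], spec["sib2"]
    haplo = haplo_identity(
        genotypes, sib1, sib2, father=spec["father"], mother=spec["mother"]
    )
    fam1 = next((f for f in families if f.proband_id == sib1), None)
    fam2 = next((f for f in families if f.proband_id == sib2), None)
    if fam1 is None or haplo.verdict != "identical":
        return {}
    gt = lambda fam: {t.variant: t.proband for t in fam.trios}
    match = fam2 is not None and gt(fam1) == gt(fam2)
    phased = phase_trio(fam1.trios)
    resolution = resolve_polymorphism_phase(
        haplo, phased, pathogenic, HYPOMORPHIC_PAIR, genotypes_match=match
    )
    if not resolution:
        return {}
    return {pid: resolution for pid in spec.get("apply_to", [sib1, sib2])}


def _misrouting_results(config, patient_ids) -> tuple[dict, GroupMisroutingStats | None]:
    vep_cfg = config.get("vep")
    if not vep_cfg:
        return {}, None
    montage = ocio.read_montage(config["montage"])
    results: dict[str, MisroutingResult] = {}
    if "simulate" in vep_cfg:
        kwargs = dict(vep_cfg["simulate"] or {})
        kwargs.setdefault("seed", config.get("seed", 0))
        kwargs.setdefault("n_subjects", len(patient_ids))
        cfg = VepSimConfig(**kwargs)
        subjects = simulate_vep_cohort(cfg)
        for pid, subj in zip(patient_ids, subjects):
            veps = {
                eye: preprocess_epochs(rec) for eye, rec in subj.recordings.items()
            }
            res = evaluate_waveform_pair(veps["OS"], veps["OD"], montage)
            res.subject_id = pid
            results[pid] = res
    elif "epoch_dir" in vep_cfg:
        root = Path(vep_cfg["epoch_dir"])
        for pid in patient_ids:
            try:
                recs = {
                    eye: ocio.load_epochs(root / f"{pid}_{eye}")
                    for eye in ("OS", "OD")
                }
            except FileNotFoundError:
                log.warning("no VEP epochs for %s; misrouting not assessed", pid)
                continue
            veps = {eye: preprocess_epochs(r) for eye, r in recs.items()}
            results[pid] = evaluate_waveform_pair(veps["OS"], veps["OD"], montage)
    group = None
    if len(results) >= 2:
        group = group_chiasm_ttest(
            np.array([r.mean_D_OS for r in results.values()]),
            np.array([r.mean_D_OD for r in results.values()]),
        )
    return results, group


def run_pipeline(config: dict | None = None):
    """Run phenotype + genotype (+ optional VEP) stages over one cohort.

    Deterministic given the config and its seed.  Per-patient failures are
    isolated: the corresponding dossier carries an ``error`` and the rest
    of the cohort is still produced.  Returns (dossiers, summary dict).
    """
    config = {**default_config(), **(config or {})}
    records = ocio.read_phenotype_table(config["phenotype_table"])
    by_id = {r.patient_id: r for r in records}
    patient_ids = [r.patient_id for r in records]

    families, retained, audit, pathogenic = datasets.load_table2_cohort(
        vcf_path=config["vcf"],
        ped_path=config["ped"],
        annotation_path=config["annotations"],
        panel_path=config["panel"],
    )
    resolutions = (
        _str_phase_resolutions(config, families, pathogenic)
        if config.get("resolve_phase")
        else {}
    )
    reports, class_counts = prioritize_cohort(
        families, pathogenic, resolutions=resolutions
    )
    report_by_id = {r.proband_id: r for r in reports}

    mis_results, group_stats = _misrouting_results(config, patient_ids)

    dossiers = []
    for pid in patient_ids:
        d = PatientDossier(patient_id=pid, phenotype=by_id[pid])
        rep = report_by_id.get(pid)
        if rep is not None:
            if rep.error:
                d.error = rep.error
            elif rep.classification is not None:
                d.classification = rep.classification.classification
                d.phase_status = rep.phased.phase_status if rep.phased else None
        mis = mis_results.get(pid)
        if mis is not None:
            d.misrouting = mis
            d.misrouting_assessed = True
        try:
            has_dx = d.classification in DIAGNOSTIC_CLASSES
            d.kruijt_clinical = assess_kruijt(by_id[pid], has_molecular_dx=False)
            d.kruijt_with_molecular = assess_kruijt(by_id[pid], has_molecular_dx=has_dx)
        except ValueError as exc:
            d.error = (d.error + "; " if d.error else "") + str(exc)
        dossiers.append(d)

    summary = {
        "n_patients": len(dossiers),
        "classification_counts": class_counts,
        "phenotype": summarize_cohort(records),
        "group_misrouting": group_stats,
        "kruijt_diagnostic_with_molecular": sum(
            1
            for d in dossiers
            if d.kruijt_with_molecular and d.kruijt_with_molecular.diagnostic_with_molecular
        ),
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.get("seed"),
            "inputs": {
                k: config.get(k)
                for k in ("phenotype_table", "vcf", "ped", "annotations", "panel")
            },
        },
    }
    return dossiers, summary


def evaluate_simulated_cohort(cfg: VepSimConfig, montage=None):
    """Simulate one VEP cohort and run the full misrouting analysis on it.

    Returns (per-subject MisroutingResult list, GroupMisroutingStats).
    Convenience wrapper used for power/false-positive evaluation of the
    misrouting indexes under known routing ground truth.
    """
    from .misrouting import default_montage

    montage = montage or default_montage(cfg.n_channels_per_side)
    results = []
    for subj in simulate_vep_cohort(cfg):
        veps = {eye: preprocess_epochs(rec) for eye, rec in subj.recordings.items()}
        results.append(evaluate_waveform_pair(veps["OS"], veps["OD"], montage))
    group = group_chiasm_ttest(
        np.array([r.mean_D_OS for r in results]),
        np.array([r.mean_D_OD for r in results]),
    )
    return results, group


def per_average_snr(cfg: VepSimConfig) -> float:
    """Signal-to-noise ratio of the trial-averaged differential activity.

    Signal: the peak noise-free differential amplitude a*A.  Noise: the
    standard deviation of the averaged D(t) with n = n_trials_mean trials
    and k electrodes per side, sd * sqrt(2/k) / sqrt(n).
    """
    sd_avg = cfg.noise_sd * np.sqrt(
        2.0 / (cfg.n_channels_per_side * cfg.n_trials_mean)
    )
    return cfg.asymmetry * cfg.evoked_amplitude / sd_avg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj, key=str)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(dossiers, summary, path) -> None:
    """Serialise dossiers + summary as JSON (NaN -> null)."""
    payload = {
        "dossiers": [_jsonable(d) for d in dossiers],
        "summary": _jsonable(summary),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
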