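"""Readers and writers for the pipeline's file formats.

Text formats throughout: TSV tables (phenotypes, STR genotypes, variant
annotations, events), VCF v4.2 + 6-column PED for trio genotypes (pysam),
YAML for the electrode montage, and JSON sidecars.  Epoch stacks are
exchanged as ``.npz`` arrays with a JSON sidecar carrying the metadata;
continuous EEG can be read from EDF through mne (optional dependency).
Every writer round-trips through the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import EpochedRecording, VEPWaveform
from .misrouting import Montage
from .phenotype import PhenotypeRecord
from .variants import AnnotatedVariant, GenePanelEntry, MAF_SOURCES, PREDICTOR_TOOLS

_BOOL = {"Y": True, "N": False, "TRUE": True, "FALSE": False, "1": True, "0": False}


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    try:
        return _BOOL[str(x).strip().upper()]
    except KeyError:
        raise ValueError(f"cannot parse boolean {x!r}") from None


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype_table(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                patient_id=row["patient_id"],
                sex=row["sex"],
                age_years=float(row["age_years"]),
                fh_grade=int(row["fh_grade"]),
                bcva_logmar_re=float(row["bcva_logmar_re"]),
                bcva_logmar_le=float(row["bcva_logmar_le"]),
                iris_transillumination=_parse_bool(row["iris_transillumination"]),
                nystagmus=_parse_bool(row["nystagmus"]),
                misrouting=_parse_bool(row["misrouting"]),
                strabismus=_parse_bool(row["strabismus"]),
                fundus_pigmentation_grade=int(row["fundus_pigmentation_grade"]),
                skin_hair_hypopigmentation=_parse_bool(
                    row["skin_hair_hypopigmentation"]
                ),
            )
        )
    return records


def write_phenotype_table(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "fh_grade": r.fh_grade,
                "bcva_logmar_re": r.bcva_logmar_re,
                "bcva_logmar_le": r.bcva_logmar_le,
                "iris_transillumination": "Y" if r.iris_transillumination else "N",
                "nystagmus": "Y" if r.nystagmus else "N",
                "misrouting": "Y" if r.misrouting else "N",
                "strabismus": "Y" if r.strabismus else "N",
                "fundus_pigmentation_grade": r.fundus_pigmentation_grade,
                "skin_hair_hypopigmentation": "Y"
                if r.skin_hair_hypopigmentation
                else "N",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant annotations
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> list[AnnotatedVariant]:
    """Annotation sidecar TSV -> AnnotatedVariant list.

    Expected columns: name, gene, chrom, pos, ref, alt, hgvs_p,
    consequence, maf_<source> for 1000g/evs/dbsnp/in_house,
    gnomad_hom_or_hemi, predictor_<tool> for the six tools,
    clinvar_or_hgmd_pathogenic, splice_predicted_damaging, acmg_class.
    Empty MAF cells mean "absent from the database".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    src_cols = {"1000G": "maf_1000g", "EVS": "maf_evs",
                "dbSNP": "maf_dbsnp", "in_house": "maf_in_house"}
    out = []
    for _, row in df.iterrows():
        maf = {}
        for source, col in src_cols.items():
            val = row.get(col)
            maf[source] = None if pd.isna(val) or val == "" else float(val)
        preds = {
            tool: str(row[f"predictor_{tool}"]) for tool in PREDICTOR_TOOLS
        }
        out.append(
            AnnotatedVariant(
                name=row["name"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                hgvs_p=row.get("hgvs_p", ""),
                consequence=row["consequence"],
                maf=maf,
                gnomad_hom_or_hemi_count=int(row["gnomad_hom_or_hemi"]),
                predictor_calls=preds,
                in_clinvar_or_hgmd_pathogenic=_parse_bool(
                    row["clinvar_or_hgmd_pathogenic"]
                ),
                splice_predicted_damaging=_parse_bool(
                    row["splice_predicted_damaging"]
                ),
                acmg_class=row["acmg_class"],
            )
        )
    return out


def read_gene_panel(path) -> tuple[GenePanelEntry, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return tuple(
        GenePanelEntry(row["gene"], row["inheritance"]) for _, row in df.iterrows()
    )


# ---------------------------------------------------------------------------
# VCF + PED trio genotypes
# ---------------------------------------------------------------------------

_GT_TO_STATE = {(0, 0): "WT", (0, 1): "Het", (1, 0): "Het", (1, 1): "Hom"}
_STATE_TO_GT = {"WT": (0, 0), "Het": (0, 1), "Hom": (1, 1)}


def write_trio_vcf(variants, genotypes: dict, path, contig: str = "chr11",
                   contig_length: int = 135086622) -> None:
    """Write a multi-sample VCF v4.2 with GT calls.

    ``variants``: AnnotatedVariant list (defines sites, sorted by
    position); ``genotypes``: {sample -> {variant name -> WT|Het|Hom}};
    samples missing a call get ./. .
    """
    samples = list(genotypes)
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=PNAME,Number=1,Type=String,Description="Protein-level variant name">')
    for s in samples:
        header.add_sample(s)
    path = str(path)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: x.pos):
            rec = vcf.new_record(
                contig=contig, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.name
            )
            rec.info["GENE"] = v.gene
            rec.info["PNAME"] = v.name
            for s in samples:
                state = genotypes[s].get(v.name)
                if state is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = _STATE_TO_GT[state]
            vcf.write(rec)


def read_trio_vcf(path) -> tuple[list[dict], dict]:
    """Read a GT-only VCF -> (site list, {sample -> {name -> state}}).

    Site dicts carry name/chrom/pos/ref/alt/gene so callers can join with
    an annotation table via either the name or the coordinate key.
    """
    sites = []
    genotypes: dict[str, dict[str, str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            genotypes[s] = {}
        for rec in vcf:
            name = rec.info.get("PNAME", rec.id) or f"{rec.chrom}:{rec.pos}"
            sites.append(
                {
                    "name": name,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else None,
                    "gene": rec.info.get("GENE"),
                }
            )
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt:
                    continue
                genotypes[s][name] = _GT_TO_STATE[tuple(gt)]
    return sites, genotypes


def write_ped(rows, path) -> None:
    """6-column PED: family, individual, father, mother, sex(1/2), phenotype(1/2)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_ped(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family", "individual", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    df["sex"] = df["sex"].astype(int)
    df["phenotype"] = df["phenotype"].astype(int)
    return df


# ---------------------------------------------------------------------------
# STR genotype table
# ---------------------------------------------------------------------------

def write_str_table(genotypes: dict, path) -> None:
    """{individual -> {marker -> (a1, a2)}} as a long TSV."""
    rows = [
        {"individual": ind, "marker": m, "allele1": a1, "allele2": a2}
        for ind, per_marker in genotypes.items()
        for m, (a1, a2) in per_marker.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_str_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "marker": str})
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["individual"], {})[row["marker"]] = (
            int(row["allele1"]),
            int(row["allele2"]),
        )
    return out


# ---------------------------------------------------------------------------
# Montage, events, epoch containers, waveform TSV
# ---------------------------------------------------------------------------

def read_montage(path) -> Montage:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return Montage(left=tuple(spec["left"]), right=tuple(spec["right"]))


def write_montage(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"left": list(montage.left), "right": list(montage.right)}, fh
        )


def write_events(onsets, eyes, path) -> None:
    pd.DataFrame({"onset_s": onsets, "eye": eyes}).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_epochs(rec: EpochedRecording, basepath) -> None:
    """Write ``<base>.npz`` (trial data) + ``<base>.json`` (metadata)."""
    base = Path(basepath)
    np.savez_compressed(base.with_suffix(".npz"), data=rec.data)
    meta = {
        "subject_id": rec.subject_id,
        "eye": rec.eye,
        "sample_rate": rec.sample_rate,
        "window": list(rec.window),
        "channel_labels": list(rec.channel_labels),
        "trials_per_row": rec.trials_per_row,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(basepath) -> EpochedRecording:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    with np.load(base.with_suffix(".npz")) as npz:
        data = npz["data"]
    return EpochedRecording(
        subject_id=meta["subject_id"],
        eye=meta["eye"],
        sample_rate=meta["sample_rate"],
        window=tuple(meta["window"]),
        data=data,
        channel_labels=tuple(meta["channel_labels"]),
        trials_per_row=meta.get("trials_per_row", 1),
    )


def write_vep_tsv(vep: VEPWaveform, path) -> None:
    """Averaged waveform as TSV: time column + one column per channel."""
    df = pd.DataFrame(vep.data.T, columns=list(vep.channel_labels))
    df.insert(0, "time_s", vep.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vep_tsv(path, subject_id: str = "", eye: str = "OS") -> VEPWaveform:
    df = pd.read_csv(path, sep="\t")
    times = df["time_s"].to_numpy()
    labels = [c for c in df.columns if c != "time_s"]
    dt = float(np.median(np.diff(times)))
    fs = 1.0 / dt
    window = (float(times[0]), float(times[0] + len(times) * dt))
    return VEPWaveform(
        subject_id=subject_id,
        eye=eye,
        sample_rate=fs,
        window=window,
        data=df[labels].to_numpy().T,
        channel_labels=tuple(labels),
    )


def read_raw_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Continuous EEG from an EDF file -> (channels x samples in uV, fs, labels).

    Delegates to mne (install the ``edf`` extra); mne returns volts, which
    are converted to microvolts here.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF reading requires mne; install ocadx[edf]"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
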