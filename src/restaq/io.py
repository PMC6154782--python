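"""Readers and writers for the pipeline's plain-text artifact formats.

Activity traces travel as long-format CSV (participant_id,
epoch_start_iso8601, activity, missing_flag); genotypes as a dosage TSV
(variant metadata columns then one column per sample) or as VCF v4.2 with
a ``DS`` FORMAT field; tables as TSV; provenance as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ActivitySeries, GenotypeMatrix

__all__ = [
    "write_activity_csv",
    "read_activity_csv",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_json",
    "read_json",
]

_FLAG_COLS = ("calibration_poor", "size_unreliable", "dst_overlap")


def write_activity_csv(cohort: list[ActivitySeries], path) -> None:
    frames = []
    for s in cohort:
        ts = s.start + (np.arange(s.n_epochs) * s.epoch_s).astype("timedelta64[s]")
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "epoch_start_iso8601": ts.astype("datetime64[s]"),
                    "activity": np.round(s.values, 6),
                    "missing_flag": s.missing.astype(int),
                    **{c: int(s.flags.get(c, False)) for c in _FLAG_COLS},
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_activity_csv(path) -> list[ActivitySeries]:
    df = pd.read_csv(path, parse_dates=["epoch_start_iso8601"])
    cohort = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("epoch_start_iso8601")
        ts = grp["epoch_start_iso8601"].to_numpy()
        if len(ts) > 1:
            epoch_s = int((ts[1] - ts[0]) / np.timedelta64(1, "s"))
        else:
            epoch_s = 5
        flags = {c: bool(grp[c].iloc[0]) for c in _FLAG_COLS if c in grp}
        cohort.append(
            ActivitySeries(
                participant_id=str(pid),
                start=ts[0].astype("datetime64[s]"),
                epoch_s=epoch_s,
                values=grp["activity"].to_numpy(float),
                missing=grp["missing_flag"].to_numpy().astype(bool),
                flags=flags,
            )
        )
    return cohort


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    meta = g.variants[["snp", "chrom", "pos", "ref", "alt", "info"]].copy()
    dosage_df = pd.DataFrame(
        np.round(g.dosages.T, 4), columns=list(g.sample_ids)
    )
    pd.concat([meta.reset_index(drop=True), dosage_df], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp", "chrom", "pos", "ref", "alt", "info"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        np.array(sample_cols, dtype=object),
        df[meta_cols],
        df[sample_cols].to_numpy(float).T,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with per-sample DS (dosage) and GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in g.variants.reset_index(drop=True).iterrows():
            d = g.dosages[:, j]
            hard = np.rint(d).astype(int)
            fields = [
                f"{gt_codes.get(int(h), './.')}:{x:.3f}" for h, x in zip(hard, d)
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['snp']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\tINFO={v['info']:.4f}\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF with DS dosages via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows, dosage_cols = [], []
    for var in vcf:
        info = var.INFO.get("INFO", np.nan)
        rows.append(
            {
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": int(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "info": float(info) if info is not None else np.nan,
            }
        )
        ds = var.format("DS")
        if ds is not None:
            dosage_cols.append(np.asarray(ds, dtype=float).ravel())
        else:  # fall back to hard genotypes
            dosage_cols.append(np.asarray(var.gt_types, dtype=float))
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, pd.DataFrame(rows), dosages)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
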