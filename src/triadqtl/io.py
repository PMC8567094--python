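"""File formats: PLINK PED/MAP, expression/trait TSV, transcript BED, truth JSON.

Genotypes travel as classic whitespace-delimited PED/MAP with 1/2 allele
coding ('0 0' = missing call). Expression and trait tables are TSV with
samples in rows. Transcript coordinates are BED6 (0-based half-open) with
a seventh column carrying the gene symbol; in memory the pipeline uses
1-based inclusive coordinates, converted at this boundary. The planted
truth of a simulation round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, TraitTable
from .simulate import CisEffect, PlantedTruth, TraitSpec, TransEffect

_ALLELES = {0.0: ("1", "1"), 1.0: ("1", "2"), 2.0: ("2", "2")}


def write_ped_map(genotypes: GenotypeMatrix, out_dir, basename: str = "cross") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snp_map = genotypes.snp_map
    with open(out / f"{basename}.map", "w") as fh:
        for _, row in snp_map.iterrows():
            cm = row["pos"] / 1e6
            fh.write(f"{row['chrom']}\t{row['snp']}\t{cm:.6f}\t{row['pos']}\n")
    ped = genotypes.pedigree
    sex = genotypes.sex
    with open(out / f"{basename}.ped", "w") as fh:
        for sample in genotypes.samples:
            sire = ped.loc[sample, "sire"] if sample in ped.index else "0"
            dam = ped.loc[sample, "dam"] if sample in ped.index else "0"
            sx = int(sex.get(sample, 0))
            row = genotypes.dosages.loc[sample].to_numpy()
            alleles = " ".join(
                "0 0" if np.isnan(d) else " ".join(_ALLELES[d]) for d in row
            )
            fh.write(f"POP {sample} {sire} {dam} {sx} -9 {alleles}\n")


def read_ped_map(ped_path, map_path, samples_path=None) -> GenotypeMatrix:
    snp_map = pd.read_csv(
        map_path, sep="\t", header=None, names=["chrom", "snp", "cm", "pos"]
    )[["snp", "chrom", "pos"]]
    sample_ids, sires, dams, sexes, rows = [], [], [], [], []
    n_snps = len(snp_map)
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            _, iid, sire, dam, sx = fields[:5]
            alleles = fields[6:]
            if len(alleles) != 2 * n_snps:
                raise ValueError(f"sample {iid}: expected {2 * n_snps} alleles, got {len(alleles)}")
            a = np.array(alleles).reshape(-1, 2)
            missing = (a == "0").any(axis=1)
            dosage = (a == "2").sum(axis=1).astype(float)
            dosage[missing] = np.nan
            sample_ids.append(iid)
            sires.append(sire)
            dams.append(dam)
            sexes.append(int(sx))
            rows.append(dosage)
    idx = pd.Index(sample_ids, name="sample")
    ped = pd.DataFrame({"sire": sires, "dam": dams}, index=idx)
    known = set(sample_ids)
    gen = []
    for s, d in zip(sires, dams):
        if s == "0" and d == "0":
            gen.append(0)
        else:
            gen.append(None)
    ped["generation"] = gen
    # resolve generations: parent generation + 1
    gen_map = {iid: g for iid, g in zip(sample_ids, gen) if g is not None}
    changed = True
    while changed:
        changed = False
        for iid, s, d in zip(sample_ids, sires, dams):
            if iid in gen_map:
                continue
            gp = [gen_map.get(p) for p in (s, d) if p in known]
            if gp and all(g is not None for g in gp):
                gen_map[iid] = max(gp) + 1
                changed = True
    ped["generation"] = [gen_map.get(iid, 0) for iid in sample_ids]

    batch = pd.Series(0, index=idx, dtype=int)
    if samples_path is not None:
        meta = pd.read_csv(samples_path, sep="\t").set_index("sample")
        batch = meta["batch"].reindex(idx).fillna(0).astype(int)
    return GenotypeMatrix(
        dosages=pd.DataFrame(np.vstack(rows), index=idx, columns=snp_map["snp"]),
        snp_map=snp_map,
        pedigree=ped,
        sex=pd.Series(sexes, index=idx, name="sex"),
        batch=batch,
    )


def write_samples_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "sample": genotypes.samples,
            "sex": genotypes.sex.reindex(genotypes.samples).to_numpy(),
            "batch": genotypes.batch.reindex(genotypes.samples).to_numpy(),
            "generation": genotypes.pedigree["generation"].reindex(genotypes.samples).to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "sample") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """Transcript coordinates as BED6 + gene symbol (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in annotation.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\t{row['transcript']}\t0\t{row['strand']}\t{row['gene']}\n"
            )


def read_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end", "transcript", "score", "strand", "gene"],
    )
    out = pd.DataFrame(
        {
            "transcript": df["transcript"],
            "gene": df["gene"],
            "chrom": df["chrom"],
            "start": df["start0"] + 1,
            "end": df["end"],
            "strand": df["strand"],
        }
    )
    return out


def write_truth_json(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path) -> PlantedTruth:
    with open(path) as fh:
        d = json.load(fh)
    return PlantedTruth(
        cis_eqtls=[CisEffect(**e) for e in d["cis_eqtls"]],
        trans_eqtls=[TransEffect(**e) for e in d["trans_eqtls"]],
        module_labels=d["module_labels"],
        trait_specs=[
            TraitSpec(
                name=t["name"],
                mediators=[tuple(m) for m in t["mediators"]],
                direct_qtl=tuple(t["direct_qtl"]) if t["direct_qtl"] else None,
                h2=t["h2"],
                sex_share=t["sex_share"],
                batch_share=t["batch_share"],
            )
            for t in d["trait_specs"]
        ],
        variance_decomposition=d["variance_decomposition"],
        module_factors={int(k): np.asarray(v) for k, v in d.get("module_factors", {}).items()},
    )


def write_dataset(genotypes, expr, traits, truth, out_dir) -> dict:
    """Emit the full simulated dataset; returns the paths written.

    Files: cross.ped/cross.map + samples.tsv (genotypes & metadata),
    expression.tsv (TPM, samples x transcripts), transcripts.bed,
    traits.tsv, truth.json. A round-trip read reproduces every matrix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped_map(genotypes, out)
    write_samples_tsv(genotypes, out / "samples.tsv")
    write_matrix_tsv(expr.values, out / "expression.tsv")
    write_annotation_bed(expr.annotation, out / "transcripts.bed")
    write_matrix_tsv(traits.values, out / "traits.tsv")
    write_truth_json(truth, out / "truth.json")
    return {
        "ped": out / "cross.ped",
        "map": out / "cross.map",
        "samples": out / "samples.tsv",
        "expression": out / "expression.tsv",
        "bed": out / "transcripts.bed",
        "traits": out / "traits.tsv",
        "truth": out / "truth.json",
    }


def read_dataset(out_dir):
    """Inverse of :func:`write_dataset`."""
    out = Path(out_dir)
    genotypes = read_ped_map(out / "cross.ped", out / "cross.map", out / "samples.tsv")
    expr = ExpressionMatrix(
        values=read_matrix_tsv(out / "expression.tsv"),
        annotation=read_annotation_bed(out / "transcripts.bed"),
    )
    traits = TraitTable(values=read_matrix_tsv(out / "traits.tsv"))
    truth = read_truth_json(out / "truth.json")
    return genotypes, expr, traits, truth
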