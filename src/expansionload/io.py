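"""Readers and writers: VCF cohorts, population maps, tidy TSVs, YAML configs.

The VCF dialect is minimal but standard: positions are 1-based, the
ancestral allele lives in INFO/AA and the effect class in INFO/EC, genotypes
are unphased GT fields.  REF/ALT are placeholder nucleotides (the model has
no nucleotide identity); the derived allele is whichever allele differs from
AA, and sites where AA matches neither allele are dropped on reading.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MutationModelConfig
from .popgen import AnnotatedVariantTable
from .simulate import SimulationConfig

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_popmap",
    "read_popmap",
    "write_table_tsv",
    "read_table_tsv",
    "write_tidy_tsv",
    "load_sim_config",
    "dump_sim_config",
    "config_hash",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: AnnotatedVariantTable, path) -> Path:
    """Write a cohort (with per-sample genotypes) as an uncompressed VCF."""
    if table.genotypes is None:
        raise ValueError("per-sample genotypes are required to write a VCF")
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=expansionload"]
    for c in dict.fromkeys(table.chrom):
        length = int(table.pos[table.chrom == c].max()) + 1
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##INFO=<ID=EC,Number=1,Type=String,Description="Effect class">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples))
    for i in range(table.n_sites):
        gts = "\t".join(_GT[int(g)] for g in table.genotypes[i])
        lines.append(
            f"{table.chrom[i]}\t{int(table.pos[i])}\t.\tA\tT\t.\tPASS\t"
            f"AA=A;EC={table.effect_class[i]}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path, popmap: dict, aa_field: str = "AA", class_field: str = "EC") -> AnnotatedVariantTable:
    """Read an annotated VCF into an AnnotatedVariantTable.

    ``popmap`` maps sample name to population.  Only biallelic sites with a
    resolvable ancestral allele are kept; the derived allele is the one
    differing from INFO/<aa_field>.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in popmap]
    if missing_samples:
        raise KeyError(f"samples absent from population map: {missing_samples}")
    sample_pop = np.array([popmap[s] for s in samples], dtype=object)
    chrom, pos, eclass, rows = [], [], [], []
    n_unpolarized = 0
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        aa = v.INFO.get(aa_field)
        ec = v.INFO.get(class_field)
        if aa is None or ec is None:
            n_unpolarized += 1
            continue
        if aa == v.REF:
            derived_allele = 1
        elif aa == v.ALT[0]:
            derived_allele = 0
        else:
            n_unpolarized += 1
            continue
        row = np.empty(len(samples), np.int8)
        for j, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row[j] = -1
            else:
                row[j] = (a == derived_allele) + (b == derived_allele)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        eclass.append(ec)
        rows.append(row)
    table = AnnotatedVariantTable.from_genotypes(
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(eclass, dtype=object),
        np.vstack(rows) if rows else np.empty((0, len(samples)), np.int8),
        samples,
        sample_pop,
    )
    return table


def write_popmap(sample_pop: dict, path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{s}\t{p}\n" for s, p in sample_pop.items()))
    return path


def read_popmap(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sample, pop = line.split("\t")[:2]
        out[sample] = pop
    return out


def write_table_tsv(table: AnnotatedVariantTable, path) -> Path:
    """Pre-digested per-site counts TSV (one row per site, per-population
    derived/called/hom/het columns)."""
    data = {"chrom": table.chrom, "pos": table.pos, "effect_class": table.effect_class}
    for j, p in enumerate(table.populations):
        data[f"derived_{p}"] = table.derived[:, j]
        data[f"called_{p}"] = table.called[:, j]
        data[f"hom_{p}"] = table.hom[:, j]
        data[f"het_{p}"] = table.het[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_table_tsv(path) -> AnnotatedVariantTable:
    df = pd.read_csv(path, sep="\t")
    pops = [c[len("derived_") :] for c in df.columns if c.startswith("derived_")]
    table = AnnotatedVariantTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        effect_class=df["effect_class"].to_numpy(dtype=object),
        populations=pops,
        derived=df[[f"derived_{p}" for p in pops]].to_numpy(dtype=np.int64),
        called=df[[f"called_{p}" for p in pops]].to_numpy(dtype=np.int64),
        hom=df[[f"hom_{p}" for p in pops]].to_numpy(dtype=np.int64),
        het=df[[f"het_{p}" for p in pops]].to_numpy(dtype=np.int64),
    )
    table.validate()
    return table


def write_tidy_tsv(df: pd.DataFrame, path, header_comment: str = "") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# simulation configuration files


def dump_sim_config(cfg: SimulationConfig, path) -> Path:
    d = dataclasses.asdict(cfg)
    d["mutation_model"]["class_proportions"] = list(d["mutation_model"]["class_proportions"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
    return Path(path)


def load_sim_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    mm = d.pop("mutation_model", {})
    if "class_proportions" in mm:
        mm["class_proportions"] = tuple(mm["class_proportions"])
    cfg = SimulationConfig(mutation_model=MutationModelConfig(**mm), **d)
    cfg.validate()
    return cfg


def config_hash(cfg) -> str:
    d = dataclasses.asdict(cfg) if dataclasses.is_dataclass(cfg) else dict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
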