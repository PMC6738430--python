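"""Delimited-text readers/writers for every pipeline table.

All files are tab-separated with a header row and a leading schema-version
comment line; readers skip ``#`` comment lines.  The beta matrix is probes
x samples with the probe id as the first column; probe annotation is
BED-like 0-based half-open (a CpG dinucleotide spans [pos, pos + 2)).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMA_COMMENT = "# telemeth table schema v1"

PHENO_COLUMNS = [
    "sample_id", "ltl", "age", "sex", "ethnicity", "cohort", "batch",
    "family_id", "smoking", "stratum_id",
]
ANNOT_COLUMNS = ["chrom", "start", "end", "cpg_id", "gene", "island_relation"]


def _write(df: pd.DataFrame, path, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def write_beta(beta: pd.DataFrame, path) -> None:
    out = beta.copy()
    out.index.name = "cpg_id"
    _write(out, path, index=True)


def read_beta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="cpg_id")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    _write(pheno[PHENO_COLUMNS], path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"family_id": "object"}, keep_default_na=True,
    )


def write_annotation(annot: pd.DataFrame, path) -> None:
    """Annotation written BED-like: chrom, start, end, cpg_id, gene, island."""
    bed = pd.DataFrame(
        {
            "chrom": annot["chrom"],
            "start": annot["pos"].astype(int),
            "end": annot["pos"].astype(int) + 2,
            "cpg_id": annot["cpg_id"],
            "gene": annot["gene"].fillna("."),
            "island_relation": annot["island_relation"].fillna("."),
        }
    )
    _write(bed, path, index=False)


def read_annotation(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ANNOT_COLUMNS) - set(bed.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    return pd.DataFrame(
        {
            "cpg_id": bed["cpg_id"],
            "chrom": bed["chrom"],
            "pos": bed["start"].astype(int),
            "gene": bed["gene"].replace(".", None),
            "island_relation": bed["island_relation"].replace(".", None),
        }
    )


def write_reference(reference: pd.DataFrame, path) -> None:
    out = reference.copy()
    out.index.name = "cpg_id"
    _write(out, path, index=True)


def read_reference(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="cpg_id")


def write_truth(truth, path) -> None:
    """Ground-truth record as a key-value text file (one fact per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        fh.write(f"negative_fraction\t{truth.negative_fraction:.10g}\n")
        fh.write(f"clipped_fraction\t{truth.clipped_fraction:.10g}\n")
        fh.write(
            "celltype_effects\t"
            + ",".join(f"{v:.10g}" for v in truth.celltype_effects) + "\n"
        )
        for cpg, eff in sorted(truth.causal_cpg_effects.items()):
            fh.write(f"causal\t{cpg}\t{eff:.10g}\n")
        for members, label in truth.planted_module_blocks:
            fh.write(f"module_block\t{label}\t{','.join(sorted(members))}\n")
        for cpg, (bzx, bxy) in sorted(truth.smr_truth.items()):
            fh.write(f"smr\t{cpg}\t{bzx:.10g}\t{bxy:.10g}\n")


def write_table(df: pd.DataFrame, path) -> None:
    _write(df, path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_proportions(props: pd.DataFrame, path) -> None:
    out = props.copy()
    out.index.name = "sample_id"
    _write(out, path, index=True)


def read_proportions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
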