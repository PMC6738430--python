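"""End-to-end orchestration of the stratified LTL EWAS.

Stage order: cell-type deconvolution -> partial and full LTL adjustment ->
per-stratum EWAS under both adjustments -> group-specific and global
meta-analyses -> significance calls -> positional / cis-mQTL enrichment ->
SMR (when summary pairs are provided) -> consensus co-methylation network
(when at least two network cohorts are present).  Both the partial- and
full-adjustment EWAS are emitted so associations can be compared before
and after removing blood-cell composition.

Every run writes a manifest (config hash, seed, per-stage counts,
software version, timestamps) that is created at start and finalized at
the end; a failed stage leaves a FAILED marker in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .adjust import AdjustmentSpec, adjust_ltl
from .celltypes import estimate_cell_proportions
from .comethyl import (
    NetworkConfig, cohort_eigengenes, consensus_tom, detect_modules,
    module_trait_meta,
)
from .ewas import ProbeFilter, stratum_ewas
from .meta import GENOME_WIDE_P, group_concordance, run_meta, significance_calls
from .position_enrich import (
    classify_subtelomeric, hypergeom_overlap, load_genome_table,
    positive_proportion_test,
)
from .smr import smr_batch
from .synthdata import CONSENSUS_COHORTS

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    beta: str
    phenotypes: str
    annotation: str
    reference: str
    outdir: str
    seed: int = 0
    mqtl_catalogue: str | None = None     # newline-delimited CpG ids
    smr_pairs: str | None = None          # pre-harmonized pair table
    genome_table: str | None = None
    subtelomere_fraction: float = 0.05
    significance_threshold: float = GENOME_WIDE_P
    autosomes_only: bool = True
    exclude_snp_probes: str | None = None
    exclude_multimap_probes: str | None = None
    use_family_random_effect: bool = True
    network: NetworkConfig = field(default_factory=NetworkConfig)
    network_cohorts: tuple[str, ...] = CONSENSUS_COHORTS
    run_network: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net = raw.pop("network", {})
        cfg = cls(**raw)
        cfg.network = NetworkConfig(**{**net, "seed": net.get("seed", cfg.seed)})
        return cfg

    def validate(self) -> None:
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance threshold must be in (0, 1)")
        for name in ("beta", "phenotypes", "annotation", "reference"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _group_of(row) -> str:
    return f"{row['ethnicity']}{str(row['sex']).capitalize()}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the finalized run manifest (also written
    to ``<outdir>/manifest.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "status": "RUNNING",
    }
    _write_manifest(manifest, outdir)

    try:
        beta = io.read_beta(config.beta)
        pheno = io.read_phenotypes(config.phenotypes)
        annot = io.read_annotation(config.annotation)
        reference = io.read_reference(config.reference)
        manifest["stages"]["load"] = {
            "probes": int(beta.shape[0]), "samples": int(beta.shape[1]),
        }

        # --- cell-type deconvolution -------------------------------------
        props = _stage(
            "celltypes", lambda: estimate_cell_proportions(beta, reference)
        )
        io.write_proportions(props, outdir / "cell_proportions.tsv")
        manifest["stages"]["celltypes"] = {"samples": int(len(props))}

        # --- trait adjustment --------------------------------------------
        cell_cols = tuple(props.columns)
        partial = AdjustmentSpec(
            mode="partial", covariates=("age",),
            use_family_random_effect=config.use_family_random_effect,
        )
        # proportions sum to 1, so one cell column is redundant with the
        # intercept and is left out of the design
        full = AdjustmentSpec(
            mode="full", covariates=("age", *cell_cols[:-1]),
            use_family_random_effect=config.use_family_random_effect,
        )
        adjusted = {}
        for name, spec in (("partial", partial), ("full", full)):
            adjusted[name] = _stage(
                f"adjust_{name}", lambda s=spec: adjust_ltl(pheno, props, s)
            )
            io.write_table(adjusted[name], outdir / f"adjusted_ltl_{name}.tsv")
            manifest["stages"][f"adjust_{name}"] = {
                "samples": int(len(adjusted[name]))
            }

        # --- per-stratum EWAS ---------------------------------------------
        probe_filter = ProbeFilter(
            autosomes_only=config.autosomes_only,
            exclude_snp_probes=_read_id_set(config.exclude_snp_probes),
            exclude_multimap_probes=_read_id_set(config.exclude_multimap_probes),
        )
        grouping = {
            sid: _group_of(sub.iloc[0])
            for sid, sub in pheno.groupby("stratum_id")
        }
        meta_by_adjustment = {}
        for name in ("partial", "full"):
            results = []
            for sid, sub in adjusted[name].groupby("stratum_id", sort=False):
                res = _stage(
                    f"ewas_{name}",
                    lambda s=sub: stratum_ewas(beta, s, probe_filter, annot),
                )
                io.write_table(res, outdir / f"ewas_{name}_{sid}.tsv")
                results.append(res)
            manifest["stages"][f"ewas_{name}"] = {
                "strata": len(results),
                "probes": int(len(results[0])) if results else 0,
            }
            metas = _stage(f"meta_{name}", lambda r=results: run_meta(r, grouping))
            for gname, m in metas.items():
                io.write_table(m, outdir / f"meta_{name}_{gname}.tsv")
            meta_by_adjustment[name] = metas

        # pairwise agreement between group meta-Z vectors (full adjustment)
        groups = [g for g in meta_by_adjustment["full"] if g != "Global"]
        concordance = {
            f"{a}~{b}": group_concordance(
                meta_by_adjustment["full"][a], meta_by_adjustment["full"][b]
            )
            for i, a in enumerate(groups)
            for b in groups[i + 1 :]
        }
        with open(outdir / "group_concordance.json", "w") as fh:
            json.dump(concordance, fh, indent=2)

        calls = significance_calls(
            meta_by_adjustment["full"]["Global"], config.significance_threshold
        )
        io.write_table(calls, outdir / "significant_cpgs_full.tsv")
        n_sig = int(calls["significant"].sum())
        manifest["stages"]["significance"] = {"significant_cpgs": n_sig}

        # --- positional & mQTL enrichment ----------------------------------
        genome = load_genome_table(
            config.genome_table, config.subtelomere_fraction
        )
        sig_cpgs = set(calls.loc[calls["significant"], "cpg"])
        enrich_out = {}
        analyzed = meta_by_adjustment["full"]["Global"]
        if sig_cpgs:
            sub_annot = annot[annot["cpg_id"].isin(sig_cpgs)].reset_index(drop=True)
            flags = classify_subtelomeric(sub_annot, genome)
            signs = (
                analyzed.set_index("cpg")
                .loc[sub_annot["cpg_id"], "direction"]
                .to_numpy()
            )
            if flags.any() and not flags.all():
                r = positive_proportion_test(flags, signs)
                enrich_out["subtelomeric"] = r._asdict()
        if config.mqtl_catalogue:
            catalogue = _read_id_set(config.mqtl_catalogue) or frozenset()
            background = set(analyzed["cpg"])
            ov = hypergeom_overlap(sig_cpgs, catalogue, background)
            enrich_out["mqtl_overlap"] = ov._asdict()
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(enrich_out, fh, indent=2)
        manifest["stages"]["position_enrich"] = {
            k: True for k in enrich_out
        } or {"skipped": True}

        # --- SMR ------------------------------------------------------------
        if config.smr_pairs:
            pairs = io.read_table(config.smr_pairs)
            smr_res = _stage(
                "smr", lambda: smr_batch(pairs, sig_cpgs or None)
            )
            io.write_table(smr_res, outdir / "smr_results.tsv")
            manifest["stages"]["smr"] = {"pairs": int(len(smr_res))}

        # --- consensus co-methylation network -------------------------------
        cohorts_present = [
            c for c in config.network_cohorts if (pheno["cohort"] == c).any()
        ]
        if config.run_network and len(cohorts_present) >= 2:
            beta_by_cohort = {
                c: beta[pheno.loc[pheno["cohort"] == c, "sample_id"]]
                for c in cohorts_present
            }
            tom, probes = _stage(
                "network",
                lambda: consensus_tom(list(beta_by_cohort.values()),
                                      config.network),
            )
            all_beta = pd.concat(beta_by_cohort.values(), axis=1)
            assignment = detect_modules(
                tom, config.network, beta=all_beta, probe_ids=probes
            )
            io.write_table(
                assignment.rename_axis("cpg").reset_index(),
                outdir / "modules.tsv",
            )
            traits = _network_traits(pheno, props, adjusted)
            beta_by_stratum = {
                sid: beta[sub["sample_id"]]
                for sid, sub in pheno.groupby("stratum_id")
                if sub["cohort"].iloc[0] in cohorts_present
            }
            if set(assignment) - {"grey"}:
                mt = module_trait_meta(assignment, beta_by_stratum, traits)
                mt.to_csv(outdir / "module_trait_meta.tsv", sep="\t")
                eigs = cohort_eigengenes(assignment, beta_by_cohort)
                for c, eg in eigs.items():
                    io.write_proportions(eg, outdir / f"eigengenes_{c}.tsv")
            manifest["stages"]["network"] = {
                "probes": int(len(probes)),
                "modules": int(len(set(assignment) - {"grey"})),
            }

        manifest["status"] = "OK"
    except StageError as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = exc.stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest(manifest, outdir)
    return manifest


def _network_traits(pheno, props, adjusted) -> dict[str, pd.DataFrame]:
    """Per-stratum trait table: raw/partially/fully adjusted LTL, age,
    cell proportions (the module-trait heat-map columns)."""
    merged = pheno.set_index("sample_id").join(props)
    out = {}
    for sid, sub in merged.groupby("stratum_id"):
        t = sub[["ltl", "age", *props.columns]].copy()
        for name in ("partial", "full"):
            adj = adjusted[name].set_index("sample_id")["residual_ltl"]
            t[f"ltl_adj_{name}"] = adj.reindex(t.index)
        out[sid] = t
    return out


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise StageError(name, str(exc)) from exc


def _read_id_set(path) -> frozenset | None:
    if not path:
        return None
    ids = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(ids)


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def simulate_command(profile: str, seed: int, outdir, **overrides) -> dict:
    """Generate a synthetic dataset on disk (profiles: "mini", "table2").

    "table2" reproduces the full 16-stratum study sizes (5,713 samples);
    "mini" is the same structure at 50 samples per stratum and 2,000 probes.
    """
    from . import synthdata

    profiles = {"mini", "table2"}
    if profile not in profiles:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(profiles)}")
    if profile == "table2":
        specs = synthdata.study_specs()
        params = dict(n_probes=20_000, n_causal=20)
    else:
        specs = synthdata.mini_specs()
        params = dict(n_probes=2_000, n_causal=20)
    params.update(overrides)
    beta, pheno, annot, truth = synthdata.generate_cohorts(
        specs, seed=seed, **params
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_beta(beta, outdir / "beta.tsv")
    io.write_phenotypes(pheno, outdir / "phenotypes.tsv")
    io.write_annotation(annot, outdir / "annotation.bed.tsv")
    io.write_reference(truth.reference, outdir / "reference_signatures.tsv")
    io.write_truth(truth, outdir / "truth.txt")
    return {
        "profile": profile, "seed": seed,
        "samples": int(beta.shape[1]), "probes": int(beta.shape[0]),
    }
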