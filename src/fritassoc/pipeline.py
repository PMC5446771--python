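"""End-to-end orchestration: qc -> pca -> assoc -> envdiff -> fst -> cluster.

A single YAML configuration names the inputs, thresholds, permutation counts
and one global seed; per-stage seeds are derived from it deterministically,
every masking/skip decision is logged, and identical config + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import SCHEMES, association_scan
from .cluster import cluster_samples, encode_counts
from .data import (
    DataError,
    GenotypeMatrix,
    check_alignment,
    read_samples,
    read_traits,
)
from .envdiff import results_frame, scan_loci
from .fst import fst_frame, fst_matrix
from .qc import apply_qc, qc_report_frame
from .simulate import default_battery_config
from .traits import reduce_batteries, scores_frame, summary_frame

log = logging.getLogger("fritassoc")


@dataclass
class RunConfig:
    genotypes: str
    samples: str
    traits: str
    out_dir: str
    hwe_alpha: float = 0.05
    maf_min: float = 0.05
    schemes: tuple = SCHEMES
    batteries: dict = field(default_factory=default_battery_config)
    n_perm_envdiff: int = 1_000_000
    n_perm_fst: int = 10_000
    bonferroni_alpha: float = 0.01
    seed: int = 1
    envdiff_groups: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("genotypes", "samples", "traits"):
            p = Path(getattr(cfg, key))
            if not p.exists():
                raise DataError(f"config input {key} does not exist: {p}")
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> str:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return _checksum(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_env, seed_fst = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"envdiff": seed_env, "fst": seed_fst},
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for key in ("genotypes", "samples", "traits"):
        report["inputs"][key] = _checksum(Path(getattr(config, key)))

    stage = "read"
    try:
        geno = GenotypeMatrix.from_tsv(config.genotypes)
        meta = read_samples(config.samples)
        traits = read_traits(config.traits)
        check_alignment(geno, meta)

        stage = "qc"
        log.info("qc: %d loci, %d samples", len(geno.loci), len(geno.samples))
        filtered, records = apply_qc(geno, meta, hwe_alpha=config.hwe_alpha,
                                     maf_min=config.maf_min)
        qc_frame = qc_report_frame(records)
        report["stages"]["qc"] = {
            "loci_in": len(geno.loci),
            "loci_retained": len(filtered.loci),
            "dropped": [r.locus for r in records if r.verdict == "drop"],
            "masked": {r.locus: r.masked_populations
                       for r in records if r.verdict == "mask"},
        }
        report["outputs"]["qc_report"] = _write(qc_frame, out / "qc_report.tsv")
        filtered.to_tsv(out / "genotypes_qc.tsv")
        report["outputs"]["genotypes_qc"] = _checksum(out / "genotypes_qc.tsv")

        stage = "pca"
        pca = reduce_batteries(traits, config.batteries)
        scores = scores_frame(pca)
        report["stages"]["pca"] = {
            name: {"retained": res.retained_components,
                   "n_complete": len(res.scores)}
            for name, res in pca.items()
        }
        report["outputs"]["pcs"] = _write(scores, out / "pcs.tsv", index=False)
        report["outputs"]["pca_summary"] = _write(
            summary_frame(pca), out / "pca_summary.tsv", index=False)

        stage = "assoc"
        table, assoc_log = association_scan(scores, filtered, meta,
                                            schemes=config.schemes)
        report["stages"]["assoc"] = {
            "tests_fitted": assoc_log["tests_fitted"],
            "tests_skipped": assoc_log["tests_skipped"],
            "fdr_family_size": assoc_log["fdr_family_size"],
            "skips": assoc_log["skips"],
        }
        report["outputs"]["assoc"] = _write(table, out / "assoc.tsv", index=False)

        stage = "envdiff"
        env_results = scan_loci(filtered, meta, n_perm=config.n_perm_envdiff,
                                seed=seed_env, groups=config.envdiff_groups,
                                family_alpha=config.bonferroni_alpha)
        env_frame = results_frame(env_results)
        report["stages"]["envdiff"] = {
            "n_loci": len(env_results),
            "consistent": int(env_frame["consistent"].sum()),
            "significant": list(env_frame.index[env_frame["bonferroni_significant"]]),
        }
        report["outputs"]["envdiff"] = _write(env_frame, out / "envdiff.tsv")

        stage = "fst"
        pairs = fst_matrix(filtered, meta, n_perm=config.n_perm_fst, seed=seed_fst)
        report["stages"]["fst"] = {"n_pairs": len(pairs)}
        report["outputs"]["fst"] = _write(fst_frame(pairs), out / "fst.tsv",
                                          index=False)

        stage = "cluster"
        counts = encode_counts(filtered)
        clust = cluster_samples(counts)
        leaf = pd.DataFrame({"sample_id": clust.leaf_order})
        merges = pd.DataFrame(clust.merges,
                              columns=["left", "right", "distance", "size"])
        report["stages"]["cluster"] = {"excluded": clust.excluded}
        report["outputs"]["leaf_order"] = _write(leaf, out / "leaf_order.tsv",
                                                 index=False)
        report["outputs"]["merges"] = _write(merges, out / "merges.tsv", index=False)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
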