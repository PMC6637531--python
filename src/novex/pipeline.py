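"""End-to-end pipeline orchestration from a single config mapping.

Stages run in dependency order (detect → features → SED → enrichment);
every output directory carries a summary JSON stamped with a hash of
the resolved config, and all randomness flows from the config seed so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml
from pyfaidx import Fasta

from . import annotation_io, exonization, features as features_mod, sed as sed_mod, stats

log = logging.getLogger("novex")

DEFAULT_THRESHOLDS = dict(
    min_reads=5, min_psi=0.05, overlap_fraction=0.2, min_sj_coverage=5
)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    cfg = dict(cfg)
    for key in ("annotation", "samples"):
        if key not in cfg:
            raise ConfigError(f"config missing required key {key!r}")
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = thresholds
    cfg.setdefault("seed", 0)
    for key in (
        "annotation", "genome", "repeats", "expression", "timecourse",
        "gene_sets", "m6a_sam", "m6a_loci",
    ):
        p = cfg.get(key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{key} path does not exist: {p}")
    for sample_id, spec in cfg["samples"].items():
        if spec.get("condition") not in ("control", "perturbed"):
            raise ConfigError(f"sample {sample_id}: condition must be control|perturbed")
        if not Path(spec["path"]).exists():
            raise ConfigError(f"sample {sample_id}: missing junction table {spec['path']}")
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute all configured stages; returns (and writes) the summary."""
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config_hash": config_hash(cfg)}
    th = cfg["thresholds"]

    # ---- detect
    try:
        annotation = annotation_io.parse_gtf(cfg["annotation"], cfg.get("genome"))
        by_condition: dict[str, dict] = {"control": {}, "perturbed": {}}
        for sample_id in sorted(cfg["samples"]):
            spec = cfg["samples"][sample_id]
            records = annotation_io.read_junction_table(
                spec["path"], sample_id, annotation
            )
            by_condition[spec["condition"]][sample_id] = records
        repeats = (
            annotation_io.read_repeats(cfg["repeats"]) if cfg.get("repeats") else []
        )
        accepted, everything = exonization.call_events(
            by_condition["perturbed"],
            by_condition["control"],
            annotation,
            repeats,
            min_reads=th["min_reads"],
            min_psi=th["min_psi"],
            overlap_fraction=th["overlap_fraction"],
        )
        annotation_io.write_events(
            accepted, outdir / "events.bed", outdir / "events.tsv"
        )
        annotation_io.write_events(
            everything, outdir / "candidates.bed", outdir / "candidates.tsv"
        )
        rejections: dict[str, int] = {}
        for ev in everything:
            if not ev.accepted:
                for c, v in ev.verdicts.items():
                    if not v.passed:
                        rejections[c] = rejections.get(c, 0) + 1
        summary["events"] = dict(
            candidates=len(everything),
            accepted=len(accepted),
            alu=sum(
                1
                for ev in accepted
                if ev.repeat_overlap and ev.repeat_overlap.repeat_class == "Alu"
            ),
            rejection_tallies=dict(sorted(rejections.items())),
            per_sample_junctions={
                s: len(by_condition[cfg["samples"][s]["condition"]][s])
                for s in sorted(cfg["samples"])
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", exc) from exc

    # ---- features + logistic model
    if cfg.get("genome") and cfg.get("expression"):
        try:
            genome = Fasta(cfg["genome"])
            expression = annotation_io.read_expression_table(cfg["expression"])
            table, metadata = features_mod.extract_features(
                annotation, genome, accepted, expression, repeats
            )
            table.to_csv(outdir / "features.tsv", sep="\t", index=False)
            with open(outdir / "features.meta.json", "w") as fh:
                json.dump(metadata, fh, indent=1, sort_keys=True)
            if table["label"].nunique() == 2 and (table["label"] == "exonized").sum() >= 5:
                fit = features_mod.fit_logistic(table, split_seed=cfg["seed"])
                summary["model"] = _round_floats(
                    dict(
                        auc=fit.auc,
                        n_train=fit.n_train,
                        n_test=fit.n_test,
                        separation_flag=fit.separation_flag,
                        coefficients=fit.coefficients,
                    )
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("features", exc) from exc

    # ---- splicing-efficiency dynamics
    if cfg.get("timecourse"):
        try:
            records = sed_mod.read_timecourse(cfg["timecourse"])
            records = sed_mod.cluster_speed(records, k=5, seed=cfg["seed"])
            sed_mod.records_to_frame(records).to_csv(
                outdir / "sed.tsv", sep="\t", index=False
            )
            counts: dict[str, int] = {}
            for r in records:
                lab = r.speed_class or "unassigned"
                counts[lab] = counts.get(lab, 0) + 1
            summary["sed"] = dict(class_counts=dict(sorted(counts.items())))
        except Exception as exc:  # noqa: BLE001
            raise StageError("sed", exc) from exc

    # ---- m6a coverage over repeat loci
    if cfg.get("m6a_sam") and cfg.get("m6a_loci") and cfg.get("expression"):
        try:
            from . import m6a as m6a_mod

            expression = annotation_io.read_expression_table(cfg["expression"])
            loci_bed = annotation_io.read_repeats(cfg["m6a_loci"])
            loci = [(f"{iv.chrom}:{iv.start}-{iv.end}", iv) for iv, _g in loci_bed]
            gene_of = {f"{iv.chrom}:{iv.start}-{iv.end}": g for iv, g in loci_bed}
            host_tpm = {lid: expression.get(gene_of[lid], 0.0) for lid, _ in loci}
            reads = m6a_mod.load_multireads(cfg["m6a_sam"], loci)
            em = m6a_mod.em_assign(reads, host_tpm)
            cov = m6a_mod.normalized_coverage(
                reads, em.assignments, loci, float(len(reads))
            )
            with open(outdir / "m6a_coverage.tsv", "w") as fh:
                fh.write("locus_id\thost_gene\tread_mass\tcoverage_rpm_per_nt\n")
                for lid, _iv in loci:
                    fh.write(
                        f"{lid}\t{gene_of[lid]}\t{em.locus_mass.get(lid, 0.0):.4f}\t"
                        f"{cov.get(lid, 0.0):.6g}\n"
                    )
            summary["m6a"] = dict(
                n_reads=len(reads), n_loci=len(loci), converged=em.converged
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("m6a", exc) from exc

    # ---- enrichment
    if cfg.get("gene_sets") and cfg.get("expression"):
        try:
            expression = annotation_io.read_expression_table(cfg["expression"])
            background = {g for g, t in expression.items() if t > 1.0}
            query = {ev.gene_id for ev in accepted} & background
            gene_sets = stats.read_gmt(cfg["gene_sets"])
            results = stats.hypergeom_enrichment(query, background, gene_sets)
            stats.enrichment_frame(results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
            summary["enrichment"] = dict(
                terms_tested=len(results),
                significant_q_lt_0p05=sum(1 for r in results if r.q < 0.05),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
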