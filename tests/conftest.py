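"""Shared fixtures: a session-scoped synthetic bundle with ground truth."""

from __future__ import annotations


import pytest
from pyfaidx import Fasta

from novex.annotation_io import (
    parse_gtf,
    read_expression_table,
    read_junction_table,
    read_repeats,
)
from novex.exonization import call_events
from novex.simulate import (
    SimConfig,
    generate_bundle,
    simulate_multimap_reads,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default 20-gene / 10-plant exact-mode bundle plus time-course and
    multimapped-read fixtures."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimConfig(seed=7)
    manifest = generate_bundle(config, outdir)
    tc_path, tc_truth = simulate_timecourse(manifest, config, outdir)
    em_truth = simulate_multimap_reads(manifest, config, outdir)
    return dict(
        dir=outdir,
        config=config,
        manifest=manifest,
        timecourse=tc_path,
        timecourse_truth=tc_truth,
        em_truth=em_truth,
    )


@pytest.fixture(scope="session")
def annotation(bundle):
    return parse_gtf(bundle["dir"] / "annotation.gtf", bundle["dir"] / "genome.fa")


@pytest.fixture(scope="session")
def genome(bundle):
    return Fasta(str(bundle["dir"] / "genome.fa"))


@pytest.fixture(scope="session")
def junctions(bundle, annotation):
    pert, ctrl = {}, {}
    for sample_id, spec in bundle["manifest"]["samples"].items():
        records = read_junction_table(spec["path"], sample_id, annotation)
        (pert if spec["condition"] == "perturbed" else ctrl)[sample_id] = records
    return dict(perturbed=pert, control=ctrl)


@pytest.fixture(scope="session")
def repeats(bundle):
    return read_repeats(bundle["dir"] / "repeats.bed")


@pytest.fixture(scope="session")
def expression(bundle):
    return read_expression_table(bundle["dir"] / "expression.tsv")


@pytest.fixture(scope="session")
def called(bundle, annotation, junctions, repeats):
    accepted, everything = call_events(
        junctions["perturbed"], junctions["control"], annotation, repeats
    )
    return dict(accepted=accepted, everything=everything)


@pytest.fixture(scope="session")
def big_bundle(tmp_path_factory):
    """50-plant bundle used for recovery/saturation checks."""
    outdir = tmp_path_factory.mktemp("big_bundle")
    config = SimConfig(seed=11, n_genes=20, n_plants=50)
    manifest = generate_bundle(config, outdir)
    annotation = parse_gtf(outdir / "annotation.gtf")
    pert, ctrl = {}, {}
    for sample_id, spec in manifest["samples"].items():
        records = read_junction_table(spec["path"], sample_id, annotation)
        (pert if spec["condition"] == "perturbed" else ctrl)[sample_id] = records
    return dict(
        dir=outdir,
        config=config,
        manifest=manifest,
        annotation=annotation,
        perturbed=pert,
        control=ctrl,
        repeats=read_repeats(outdir / "repeats.bed"),
    )
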