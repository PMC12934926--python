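"""Shared fixtures: tiny annotations and a small simulated population."""

from __future__ import annotations

import numpy as np
import pytest

import ddpheno as dp


def make_gtf(tmp_path, genes, name="toy.gtf"):
    """Write a GTF from (gene_id, chrom, strand, start1, end1, biotype,
    [(exon_start1, exon_end1), ...]) tuples (1-based inclusive coords)."""
    lines = []
    for gid, chrom, strand, start, end, biotype, exons in genes:
        attrs = f'gene_id "{gid}"; gene_type "{biotype}";'
        lines.append(f"{chrom}\tt\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
        tattrs = attrs + f' transcript_id "{gid}.t1";'
        for es, ee in exons:
            lines.append(f"{chrom}\tt\texon\t{es}\t{ee}\t.\t{strand}\t.\t{tattrs}")
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def gtf_factory(tmp_path):
    return lambda genes, name="toy.gtf": make_gtf(tmp_path, genes, name)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """6-gene, 60-sample simulated population with bins and raw coverage.

    Session-scoped: the pipeline is deterministic, and most tests only
    read from it.
    """
    cfg = dp.SimConfig(n_genes=6, n_samples=60, seed=7,
                       min_span=5_000, max_span=15_000)
    source, truth = dp.simulate_coverage(cfg)
    gtf_text, _ = dp.simulate_annotation(cfg)
    gtf = tmp_path_factory.mktemp("sim") / "annotation.gtf"
    gtf.write_text(gtf_text)
    regions = dp.parse_gene_regions(gtf, 1000)
    run_cfg = dp.RunConfig(target_mean_bins=64, n_calibration_genes=6,
                           n_binning_samples=60, seed=7)
    schemes, calib = dp.define_bins(regions, source, run_cfg)
    raw = dp.bin_dataset(regions, schemes, source)
    return {
        "config": cfg, "source": source, "truth": truth, "gtf": gtf,
        "regions": regions, "run_cfg": run_cfg, "schemes": schemes,
        "calibration": calib, "raw": raw,
    }


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    store = dp.fit_models(sim_small["raw"], sim_small["schemes"],
                          sim_small["run_cfg"])
    table = dp.apply_models(store, sim_small["raw"], sim_small["run_cfg"])
    return {"store": store, "table": table, **sim_small}


def random_log2_coverage(gene_id, n_samples, n_bins, rng,
                         stage="log2") -> dp.BinnedCoverage:
    """Gaussian stand-in for normalized binned coverage."""
    return dp.BinnedCoverage(
        gene_id,
        [f"{gene_id}:{i}" for i in range(n_bins)],
        [f"S{i:03d}" for i in range(n_samples)],
        rng.normal(size=(n_samples, n_bins)),
        stage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
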