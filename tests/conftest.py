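"""Shared fixtures: one small simulated cohort and one full pipeline run.

The cohort is the 24-sample error-free design (one fly per
site-season-sex cell, six host species, two Wolbachia strains, planted
blank-shared contaminants); the pipeline run over it is reused by the
end-to-end tests.
"""

from __future__ import annotations

import warnings

import pytest

import darkamp.synthetic_data as sd
from darkamp.pipeline import PipelineConfig, run_all

COHORT_SEED = 101


@pytest.fixture(scope="session")
def small_cohort():
    cfg, rs = sd.preset_small()
    rs = type(rs)(**{**rs.__dict__, "seed": COHORT_SEED})
    truth = sd.simulate_truth(cfg, seed=COHORT_SEED)
    sim = sd.simulate_reads(truth, rs)
    return truth, sim


@pytest.fixture(scope="session")
def pipeline_run(small_cohort, tmp_path_factory):
    truth, sim = small_cohort
    tmp = tmp_path_factory.mktemp("cohort")
    sim.write_fastq(tmp / "reads", gzipped=False)
    refs = tmp / "refs"
    refs.mkdir()
    (refs / "taxonomy_16s.fasta").write_text(sd.taxonomy_fasta_16s(truth))
    (refs / "taxonomy_coi.fasta").write_text(sd.taxonomy_fasta_coi(truth))
    (refs / "named_barcodes.fasta").write_text(sd.named_barcode_fasta(truth))
    (refs / "spikein.fasta").write_text(
        f">Ec5502 extraction spike-in\n{truth.spikein_seq}\n"
        f">Ec5001 pcr spike-in (unused)\n{truth.pcr_spike_seq}\n")
    truth.sample_sheet.to_csv(tmp / "sample_sheet.tsv", sep="\t", index=False)
    cfg = PipelineConfig(
        input_dir=str(tmp / "reads"), output_dir=str(tmp / "out"),
        sample_sheet=str(tmp / "sample_sheet.tsv"),
        taxonomy_16s=str(refs / "taxonomy_16s.fasta"),
        taxonomy_coi=str(refs / "taxonomy_coi.fasta"),
        spikein_fasta=str(refs / "spikein.fasta"),
        named_barcodes=str(refs / "named_barcodes.fasta"),
        seed=COHORT_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_all(cfg)
    return {"truth": truth, "sim": sim, "config": cfg,
            "out": tmp / "out", "manifest": manifest}
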