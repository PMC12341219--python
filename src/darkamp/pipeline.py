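"""End-to-end orchestration: split -> merge/QC -> denoise -> barcode/
decontamination -> quantify -> Wolbachia -> model, with a run manifest.

The pipeline is driven by a :class:`PipelineConfig` naming the input
FASTQ directory, the sample sheet, and the reference files.  Every
stage writes TSV outputs under the output directory and registers
per-stage counts plus file digests in the manifest, so that reruns
with identical inputs and config reproduce identical digests for the
deterministic stages.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import warnings
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import decontam as dc
from . import denoise as dn
from . import hostbarcode as hb
from . import quantify as qt
from . import symbiont_coi as sc
from .readprep import (DEFAULT_SCHEMES, LENGTH_WINDOWS, MergedContig, ReadPair,
                       match_primer, merge_pair, qc_filter)

__all__ = ["PipelineConfig", "RunManifest", "run_all", "read_fastq_pairs"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds for one pipeline run.

    Threshold defaults follow the study protocol: 300 dominant-OTU
    reads and a 95% arthropod read ratio for barcode QC, 418-nt
    barcodes, 97% OTU identity, 80% taxonomy confidence, a 5x blank
    ratio for contamination, 100-copy richness threshold, and 2
    Wolbachia COI reads for presence.
    """

    input_dir: str
    output_dir: str
    sample_sheet: str
    taxonomy_16s: str
    taxonomy_coi: str
    spikein_fasta: str
    named_barcodes: Optional[str] = None
    min_overlap: int = 20
    max_mismatch_frac: float = 0.25
    primer_mismatches: int = 1
    max_spacer: int = 7
    unoise_alpha: float = 2.0
    unoise_minsize: int = 2
    otu_identity: float = 0.97
    sintax_cutoff: float = 0.80
    min_dominant_reads: int = 300
    min_arthropod_ratio: float = 0.95
    barcode_length: int = 418
    species_cut: float = 0.03
    name_identity: float = 0.97
    quack_factor: float = 5.0
    min_copies: float = 100.0
    wolbachia_min_reads: int = 2
    run_model: bool = False
    model_min_species_n: int = 5
    model_n_taxa: int = 50
    model_thin: int = 1
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_fastq_pairs(r1: Path, r2: Path) -> list[ReadPair]:
    """Load one library's mates into ReadPair objects."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    def _open(p: Path):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    pairs = []
    with _open(r1) as f1, _open(r2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(FastqGeneralIterator(f1),
                                              FastqGeneralIterator(f2)):
            pairs.append(ReadPair(
                t1.split()[0], s1.upper(), s2.upper(),
                [ord(c) - 33 for c in q1], [ord(c) - 33 for c in q2]))
    return pairs


def _find_fastqs(input_dir: Path, sample_ids: list[str]) -> dict[str, tuple[Path, Path]]:
    found = {}
    for sid in sample_ids:
        for suffix in (".fastq.gz", ".fastq"):
            r1 = input_dir / f"{sid}_R1{suffix}"
            r2 = input_dir / f"{sid}_R2{suffix}"
            if r1.exists() and r2.exists():
                found[sid] = (r1, r2)
                break
    return found


def _process_library(pairs: list[ReadPair], cfg: PipelineConfig
                     ) -> tuple[dict[str, Counter], dict]:
    """Split, merge, and QC one library; contig counts per target.

    Identical raw pairs are collapsed first so each unique pair is
    split/merged once — all downstream operations are deterministic per
    read, so this changes nothing but runtime.
    """
    schemes = [type(s)(s.target_id, s.fwd_primer, s.rev_primer,
                       cfg.max_spacer, cfg.primer_mismatches)
               for s in DEFAULT_SCHEMES]
    uniq = Counter((p.fwd_seq, p.rev_seq, bytes(p.fwd_qual), bytes(p.rev_qual))
                   for p in pairs)
    counts = {"input_pairs": len(pairs), "unassigned": 0,
              "merge_rejected": 0, "qc_length": 0, "qc_quality": 0}
    contigs: dict[str, Counter] = {s.target_id: Counter() for s in schemes}
    for t in contigs:
        counts[f"assigned_{t}"] = 0
    from .readprep import split_reads

    for (fs, rs, fq, rq), n in uniq.items():
        pair = ReadPair("u", fs, rs, list(fq), list(rq))
        res = split_reads([pair], schemes)
        target = next((t for t, b in res.bins.items() if b), None)
        if target is None:
            counts["unassigned"] += n
            continue
        counts[f"assigned_{target}"] += n
        trimmed = res.bins[target][0]
        contig = merge_pair(trimmed, cfg.min_overlap, cfg.max_mismatch_frac,
                            target_id=target)
        if contig is None:
            counts["merge_rejected"] += n
            continue
        keep, reason = qc_filter(contig, target)
        if not keep:
            counts[f"qc_{reason}"] += n
            continue
        contigs[target][contig.seq] += n
    return contigs, counts


def _denoise_target(per_sample: dict[str, Counter], cfg: PipelineConfig
                    ) -> list[dn.Zotu]:
    per_sample_zotus = {}
    for sid, counter in per_sample.items():
        uniques = [dn.UniqueSeq(s, c, sid) for s, c in counter.items()
                   if c >= cfg.unoise_minsize]
        uniques.sort(key=lambda u: (-u.count, u.seq))
        if not uniques:
            continue
        zotus, _ = dn.unoise_denoise(uniques, cfg.unoise_alpha, cfg.unoise_minsize)
        per_sample_zotus[sid] = zotus
    return dn.build_zotu_table(per_sample_zotus)


def _zotu_frame(zotus: list[dn.Zotu], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame({s: [z.counts.get(s, 0) for z in zotus] for s in samples},
                        index=[z.zotu_id for z in zotus])


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage in order and write outputs plus the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.config_hash(), cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))

    # ---- pre-flight
    sheet_path = Path(cfg.sample_sheet)
    for label, p in [("sample_sheet", sheet_path),
                     ("taxonomy_16s", Path(cfg.taxonomy_16s)),
                     ("taxonomy_coi", Path(cfg.taxonomy_coi)),
                     ("spikein_fasta", Path(cfg.spikein_fasta))]:
        if not p.exists():
            raise FileNotFoundError(f"missing input {label}: {p}")
        manifest.inputs[label] = _digest(p)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "control_type", "spikein_copies"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet missing columns {required - set(sheet.columns)}")
    fastqs = _find_fastqs(Path(cfg.input_dir), sheet.sample_id.tolist())
    missing = [s for s in sheet.sample_id if s not in fastqs]
    if missing:
        raise FileNotFoundError(f"no FASTQ pair for sample(s) {missing[:5]}")
    for sid, (r1, r2) in fastqs.items():
        try:
            opener = gzip.open if str(r1).endswith(".gz") else open
            with opener(r1, "rt") as fh:
                head = fh.readline()
            if head and not head.startswith("@"):
                raise ValueError
        except (OSError, ValueError):
            raise ValueError(f"corrupt FASTQ: {r1}")
    manifest.add_stage("preflight", samples=len(fastqs))

    # ---- split / merge / QC
    coi_contigs: dict[str, Counter] = {}
    s16_contigs: dict[str, Counter] = {}
    split_rows = []
    for sid, (r1, r2) in fastqs.items():
        pairs = read_fastq_pairs(r1, r2)
        contigs, counts = _process_library(pairs, cfg)
        coi_contigs[sid] = contigs.get("COI", Counter())
        s16_contigs[sid] = contigs.get("16S-V4", Counter())
        split_rows.append({"sample_id": sid, **counts})
    split_df = pd.DataFrame(split_rows)
    split_df.to_csv(out / "read_counts.tsv", sep="\t", index=False)
    manifest.add_stage("split_merge_qc",
                       pairs=int(split_df.input_pairs.sum()),
                       unassigned=int(split_df.unassigned.sum()))

    # ---- denoise both targets
    coi_zotus = _denoise_target(coi_contigs, cfg)
    s16_zotus = _denoise_target(s16_contigs, cfg)
    dn.flag_chimeras(coi_zotus)
    dn.flag_chimeras(s16_zotus)
    samples_all = sheet.sample_id.tolist()
    manifest.add_stage("denoise", coi_zotus=len(coi_zotus), s16_zotus=len(s16_zotus))

    ref16 = dn.TaxonomyReference.from_fasta(cfg.taxonomy_16s)
    refcoi = dn.TaxonomyReference.from_fasta(cfg.taxonomy_coi)
    tax16: dict[str, dict[str, str]] = {}
    taxcoi: dict[str, dict[str, str]] = {}
    for z in s16_zotus:
        lin, conf = dn.classify_taxonomy(z.centroid_seq, ref16,
                                         cutoff=cfg.sintax_cutoff, rng=rng)
        z.taxonomy, z.confidences = lin, conf
        tax16[z.zotu_id] = lin
    for z in coi_zotus:
        lin, conf = dn.classify_taxonomy(z.centroid_seq, refcoi,
                                         cutoff=cfg.sintax_cutoff, rng=rng)
        z.taxonomy, z.confidences = lin, conf
        taxcoi[z.zotu_id] = lin

    # ---- host barcodes
    experimental = sheet.loc[sheet.control_type == "sample", "sample_id"].tolist()
    coi_clean = [z for z in coi_zotus
                 if not z.chimera_flag and len(z.centroid_seq) == cfg.barcode_length]
    is_arth = {z.zotu_id: taxcoi.get(z.zotu_id, {}).get("phylum") == "Arthropoda"
               for z in coi_clean}
    coi_otumap = dn.cluster_otus(coi_clean, cfg.otu_identity)
    barcode_records = [
        hb.select_barcode(sid, coi_clean, coi_otumap, is_arth,
                          cfg.min_dominant_reads, cfg.min_arthropod_ratio,
                          cfg.barcode_length)
        for sid in experimental]
    genotypes = hb.dereplicate_genotypes(barcode_records)
    genotype_seqs = {}
    for rec in barcode_records:
        if rec.passed:
            for gid, sids in genotypes.items():
                if rec.sample_id in sids:
                    genotype_seqs[gid] = rec.barcode_seq
    named_refs: dict[str, str] = {}
    ref_species: dict[str, str] = {}
    if cfg.named_barcodes:
        from Bio import SeqIO

        for rec in SeqIO.parse(cfg.named_barcodes, "fasta"):
            named_refs[rec.id] = str(rec.seq).upper()
            m = [f for f in rec.description.split() if f.startswith("species=")]
            ref_species[rec.id] = m[0].split("=", 1)[1] if m else rec.id
    clusters = hb.propose_species_clusters(genotype_seqs, named_refs, ref_species,
                                           cfg.species_cut)
    assignment_rows = []
    for gid, (cl, amb) in clusters.items():
        name, level, ident = hb.assign_name(
            genotype_seqs[gid], named_refs, ref_species,
            classifier_lineage=None, min_identity=cfg.name_identity)
        assignment_rows.append({
            "genotype_id": gid, "species_cluster": cl, "ambiguous": amb,
            "name": name, "name_level": level, "name_identity": round(ident, 4),
            "n_individuals": len(genotypes[gid])})
    qc_df = pd.DataFrame([{
        "sample_id": r.sample_id, "passed": r.passed,
        "dominant_otu_reads": r.dominant_otu_reads,
        "arthropod_ratio": round(r.arthropod_ratio, 4),
        "reject_reason": r.reject_reason} for r in barcode_records])
    qc_df.to_csv(out / "barcode_qc.tsv", sep="\t", index=False)
    pd.DataFrame(assignment_rows).to_csv(out / "species_assignments.tsv",
                                         sep="\t", index=False)
    meta = sheet.set_index("sample_id")
    geno_rows = []
    for gid, sids in genotypes.items():
        for s in sids:
            geno_rows.append({"genotype_id": gid, "sample_id": s,
                              "site": meta.loc[s].get("site", ""),
                              "season": meta.loc[s].get("season", ""),
                              "sex": meta.loc[s].get("sex", "")})
    geno_df = pd.DataFrame(geno_rows)
    if not geno_df.empty:
        (geno_df.groupby(["genotype_id", "site", "season", "sex"])
         .size().rename("n").reset_index()
         .to_csv(out / "genotype_table.tsv", sep="\t", index=False))
    with open(out / "barcodes.fasta", "w") as fh:
        for gid, seq in genotype_seqs.items():
            fh.write(f">{gid}\n{seq}\n")
    manifest.add_stage("barcode", passed=int(qc_df.passed.sum()),
                       genotypes=len(genotypes),
                       species_clusters=len({c for c, _ in clusters.values()}))

    # ---- Wolbachia COI bycatch
    wolb = sc.extract_wolbachia(coi_zotus, taxcoi, cfg.barcode_length,
                                cfg.otu_identity)
    wolb_table = wolb.table.reindex(columns=experimental, fill_value=0) \
        if not wolb.table.empty else pd.DataFrame(columns=experimental)
    coi_presence = sc.call_presence(wolb_table, cfg.wolbachia_min_reads) \
        if not wolb_table.empty else pd.Series(False, index=experimental)
    coi_presence = coi_presence.reindex(experimental, fill_value=False)
    wolb_table.to_csv(out / "wolbachia_coi_zotus.tsv", sep="\t")
    manifest.add_stage("wolbachia_coi", strains=len(wolb.zotus),
                       present=int(coi_presence.sum()))

    # ---- 16S decontamination
    s16_table = _zotu_frame(s16_zotus, samples_all)
    zotu_seqs = {z.zotu_id: z.centroid_seq for z in s16_zotus}
    chim = {z.zotu_id: z.chimera_flag for z in s16_zotus}
    blanks = sheet.loc[sheet.control_type.str.endswith("blank", na=False),
                      "sample_id"].tolist()
    from Bio import SeqIO

    spikes = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(cfg.spikein_fasta, "fasta")}
    extraction = {k: v for k, v in spikes.items() if not k.startswith("Ec5001")}
    pcr_spike = {k: v for k, v in spikes.items() if k.startswith("Ec5001")}
    # spike-ins are identified on the raw table (they sit in blanks by
    # design, so the blank-ratio rule must not see them)
    table0 = s16_table
    pcr_ids: list[str] = []
    if pcr_spike:  # detected and dropped; not used for quantification
        table0, _, pcr_ids = dc.split_spikein(table0, zotu_seqs, pcr_spike)
    table0, spike_reads, spike_ids = dc.split_spikein(table0, zotu_seqs, extraction)
    # percentages are computed on the raw decontamination input table
    pct = dc.to_percentages(s16_table)
    decisions = dc.quack_filter(pct.drop(index=spike_ids + pcr_ids, errors="ignore"),
                                experimental, blanks, cfg.quack_factor)
    keep_ids = [d.zotu_id for d in decisions if d.keep]
    table1 = table0.loc[[z for z in table0.index if z in keep_ids]]
    table3, nt_decisions = dc.remove_nontarget(table1, tax16, chim)
    decisions_df = pd.DataFrame([asdict(d) for d in decisions + nt_decisions])
    decisions_df.to_csv(out / "contaminant_decisions.tsv", sep="\t", index=False)
    table3.to_csv(out / "zotu_table_decontaminated.tsv", sep="\t")
    kept_16s = set(table3.index.astype(str))
    with open(out / "zotus_16s.fasta", "w") as fh:
        for z in s16_zotus:
            fh.write(f">{z.zotu_id} kept={z.zotu_id in kept_16s}\n"
                     f"{z.centroid_seq}\n")
    with open(out / "zotus_coi.fasta", "w") as fh:
        for z in coi_zotus:
            fh.write(f">{z.zotu_id} chimera={z.chimera_flag}\n{z.centroid_seq}\n")
    spike_reads.rename("spike_reads").to_csv(out / "spikein_reads.tsv", sep="\t")
    manifest.add_stage("decontam",
                       removed_ratio=sum(not d.keep for d in decisions),
                       removed_nontarget=len(nt_decisions),
                       spike_zotus=len(spike_ids))

    # ---- quantification
    exp_table = table3[experimental]
    spike_exp = spike_reads.reindex(experimental, fill_value=0)
    spike_copies = sheet.set_index("sample_id").spikein_copies
    hom = sheet.set_index("sample_id").get(
        "homogenate_factor", pd.Series(5.0, index=sheet.sample_id))
    no_spike = [s for s in experimental if spike_exp[s] <= 0]
    if no_spike:
        warnings.warn(f"discarding {len(no_spike)} sample(s) without "
                      f"extraction spike-in reads: {no_spike[:5]}")
    abundance = exp_table.copy().astype(float)
    kept_samples = [s for s in experimental if spike_exp[s] > 0]
    abundance = abundance[kept_samples]
    for s in kept_samples:
        abundance[s] = exp_table[s] / spike_exp[s] * spike_copies[s] * \
            float(hom[s] if s in hom.index else 5.0)
    s16_otumap = dn.cluster_otus([z for z in s16_zotus
                                  if z.zotu_id in abundance.index], cfg.otu_identity)
    otu_abundance = qt.aggregate_otus(abundance, s16_otumap.zotu_to_otu)
    summary = pd.DataFrame({
        "total_copies": qt.sample_total(abundance),
        "zotu_richness": qt.richness_at_threshold(abundance, cfg.min_copies),
        "otu_richness": qt.richness_at_threshold(otu_abundance, cfg.min_copies),
    })
    abundance.to_csv(out / "abundance_zotu.tsv", sep="\t")
    otu_abundance.to_csv(out / "abundance_otu.tsv", sep="\t")
    summary.to_csv(out / "sample_summary.tsv", sep="\t")
    manifest.add_stage("quantify", samples=len(kept_samples),
                       discarded_no_spike=len(no_spike))

    # ---- cross-marker Wolbachia agreement
    wolb16_ids = [z for z in abundance.index
                  if tax16.get(str(z), {}).get("genus") == "Wolbachia"]
    s16_reads_wolb = table3.loc[wolb16_ids, kept_samples].sum(axis=0) \
        if wolb16_ids else pd.Series(0, index=kept_samples)
    s16_presence = s16_reads_wolb >= 400
    agreement = None
    if len(kept_samples) > 0:
        coi_p = (wolb_table[kept_samples].sum(axis=0) >= 3) \
            if not wolb_table.empty else pd.Series(False, index=kept_samples)
        agreement, ct, kappa = sc.cross_marker_agreement(coi_p, s16_presence)
        ct.to_csv(out / "wolbachia_concordance.tsv", sep="\t")
        manifest.add_stage("cross_marker", agreement=round(agreement, 4),
                           kappa=round(kappa, 4))

    # ---- community model (optional)
    if cfg.run_model:
        _run_model_stage(cfg, manifest, abundance, sheet, genotypes, clusters, out)

    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")):
        manifest.outputs[p.name] = _digest(p)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_model_stage(cfg: PipelineConfig, manifest: RunManifest,
                     abundance: pd.DataFrame, sheet: pd.DataFrame,
                     genotypes: dict[str, list[str]],
                     clusters: dict[str, tuple[int, bool]], out: Path) -> None:
    from . import community_model as cm

    meta = sheet.set_index("sample_id")
    geno_of = {s: gid for gid, sids in genotypes.items() for s in sids}
    species_of = {s: clusters[geno_of[s]][0] for s in abundance.columns
                  if s in geno_of and geno_of[s] in clusters}
    counts = Counter(species_of.values())
    keep = [s for s in abundance.columns
            if species_of.get(s) is not None
            and counts[species_of[s]] >= cfg.model_min_species_n]
    if len(keep) < 10 or abundance.shape[0] < 2:
        manifest.add_stage("model", skipped="insufficient data")
        return
    sub = abundance[keep]
    top = sub.sum(axis=1).sort_values(ascending=False).index[:cfg.model_n_taxa]
    sub = sub.loc[top]
    P, A = cm.hurdle_split(sub)

    def codes(values):
        uniq = {v: i for i, v in enumerate(dict.fromkeys(values))}
        return np.array([uniq[v] for v in values])

    X = np.column_stack([
        np.ones(len(keep)),
        (meta.loc[keep, "season"] == "summer").astype(float),
        (meta.loc[keep, "sex"] == "M").astype(float)])
    levels = {"site": codes(meta.loc[keep, "site"]),
              "species": codes([species_of[s] for s in keep]),
              "genotype": codes([geno_of[s] for s in keep]),
              "unit": np.arange(len(keep))}
    inp = cm.ModelInput(P.T.values.astype(float), X,
                        ["intercept", "season", "sex"], levels,
                        taxa=[str(t) for t in P.index], samples=keep)
    post = cm.fit_with_convergence(inp, "presence", thin_schedule=(cfg.model_thin,),
                                   seed=cfg.seed)
    ok, psrfs = cm.psrf_check(post)
    vp = cm.variance_partition(post, X)
    support = cm.fixed_effect_support(post)
    vp.to_csv(out / "variance_partition_presence.tsv", sep="\t")
    support.to_csv(out / "fixed_effect_support_presence.tsv", sep="\t", index=False)
    psrfs.rename("psrf").to_csv(out / "psrf_presence.tsv", sep="\t")
    manifest.add_stage("model", component="presence", taxa=int(P.shape[0]),
                       samples=len(keep), converged=bool(ok),
                       psrf_q3=round(float(psrfs.quantile(0.75)), 4))
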