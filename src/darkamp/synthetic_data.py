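"""Synthetic wild-insect communities and raw amplicon reads.

The generator emulates the structure of a Malaise-trap cohort of
scuttle flies: a skewed (log-series) host species abundance
distribution, several COI genotypes per species, species/genotype/sex-
structured facultative endosymbiont infections with high loads,
broadly distributed generalist bacteria, extraction spike-ins at known
input copies, and contaminant ZOTUs shared with blank libraries.
Every pipeline stage can thus be tested against known truth without
any downloads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .readprep import IUPAC, ReadPair, revcomp

__all__ = [
    "CommunitySimConfig",
    "ReadSimConfig",
    "CommunityTruth",
    "SimulatedReads",
    "simulate_truth",
    "simulate_reads",
    "allocate_reads",
    "write_fixtures",
    "preset_small",
    "preset_paper_shaped",
]

_BASES = np.array(list("ACGT"))

GENERALIST_GENERA = ["Serratia", "Providencia", "Carnobacterium", "Pseudomonas",
                     "Lactobacillus", "Acinetobacter", "Enterobacter", "Gilliamella"]
ENDOSYMBIONT_GENERA = ["Wolbachia", "Rickettsia", "Spiroplasma"]

_LINEAGE_BASE = {
    "Wolbachia": {"domain": "Bacteria", "phylum": "Proteobacteria",
                  "class": "Alphaproteobacteria", "order": "Rickettsiales",
                  "family": "Anaplasmataceae", "genus": "Wolbachia"},
    "Rickettsia": {"domain": "Bacteria", "phylum": "Proteobacteria",
                   "class": "Alphaproteobacteria", "order": "Rickettsiales",
                   "family": "Rickettsiaceae", "genus": "Rickettsia"},
    "Spiroplasma": {"domain": "Bacteria", "phylum": "Tenericutes",
                    "class": "Mollicutes", "order": "Entomoplasmatales",
                    "family": "Spiroplasmataceae", "genus": "Spiroplasma"},
    "Serratia": {"domain": "Bacteria", "phylum": "Proteobacteria",
                 "class": "Gammaproteobacteria", "order": "Enterobacterales",
                 "family": "Yersiniaceae", "genus": "Serratia"},
    "Providencia": {"domain": "Bacteria", "phylum": "Proteobacteria",
                    "class": "Gammaproteobacteria", "order": "Enterobacterales",
                    "family": "Morganellaceae", "genus": "Providencia"},
    "Carnobacterium": {"domain": "Bacteria", "phylum": "Firmicutes",
                       "class": "Bacilli", "order": "Lactobacillales",
                       "family": "Carnobacteriaceae", "genus": "Carnobacterium"},
    "Pseudomonas": {"domain": "Bacteria", "phylum": "Proteobacteria",
                    "class": "Gammaproteobacteria", "order": "Pseudomonadales",
                    "family": "Pseudomonadaceae", "genus": "Pseudomonas"},
    "Lactobacillus": {"domain": "Bacteria", "phylum": "Firmicutes",
                      "class": "Bacilli", "order": "Lactobacillales",
                      "family": "Lactobacillaceae", "genus": "Lactobacillus"},
    "Acinetobacter": {"domain": "Bacteria", "phylum": "Proteobacteria",
                      "class": "Gammaproteobacteria", "order": "Pseudomonadales",
                      "family": "Moraxellaceae", "genus": "Acinetobacter"},
    "Enterobacter": {"domain": "Bacteria", "phylum": "Proteobacteria",
                     "class": "Gammaproteobacteria", "order": "Enterobacterales",
                     "family": "Enterobacteriaceae", "genus": "Enterobacter"},
    "Gilliamella": {"domain": "Bacteria", "phylum": "Proteobacteria",
                    "class": "Gammaproteobacteria", "order": "Orbales",
                    "family": "Orbaceae", "genus": "Gilliamella"},
    "Sphingomonas": {"domain": "Bacteria", "phylum": "Proteobacteria",
                     "class": "Alphaproteobacteria", "order": "Sphingomonadales",
                     "family": "Sphingomonadaceae", "genus": "Sphingomonas"},
    "Cutibacterium": {"domain": "Bacteria", "phylum": "Actinobacteriota",
                      "class": "Actinobacteria", "order": "Propionibacteriales",
                      "family": "Propionibacteriaceae", "genus": "Cutibacterium"},
    "Ralstonia": {"domain": "Bacteria", "phylum": "Proteobacteria",
                  "class": "Betaproteobacteria", "order": "Burkholderiales",
                  "family": "Burkholderiaceae", "genus": "Ralstonia"},
    "Chloroplast": {"domain": "Bacteria", "phylum": "Cyanobacteria",
                    "class": "Cyanobacteriia", "order": "Chloroplast",
                    "family": "Chloroplast", "genus": "Chloroplast"},
}

CONTAMINANT_GENERA = ["Sphingomonas", "Cutibacterium", "Ralstonia", "Chloroplast"]


@dataclass(frozen=True)
class CommunitySimConfig:
    """Study-design and community parameters of the simulated cohort.

    Defaults mirror the sampled study design: 88 males and 88 females per
    site-season combination at six sites across two seasons, extraction
    spike-ins of 10,000 or 20,000 copies alternating by 88-sample batch,
    and six negative plus two positive controls per batch.
    """

    species_pool: int = 186
    max_genotypes_per_species: int = 10
    logseries_p: float = 0.98
    n_sites: int = 6
    seasons: tuple[str, ...] = ("spring", "summer")
    sexes: tuple[str, ...] = ("F", "M")
    per_cell: int = 88
    n_wolbachia_strains: int = 6
    n_other_endosymbionts: int = 4
    n_generalists: int = 8
    n_contaminants: int = 4
    endo_median_load: float = 1.0e6
    endo_sigma: float = 1.0
    endo_female_odds: float = 3.0
    gen_median_load: float = 2.0e4
    gen_sigma: float = 1.5
    gen_presence_prob: float = 0.6
    contam_sample_load: float = 200.0
    contam_blank_weight: float = 2000.0
    spike_choices: tuple[int, ...] = (10000, 20000)
    batch_size: int = 88
    blanks_per_batch: int = 6
    positives_per_batch: int = 2
    barcode_length: int = 418
    s16_length: int = 253
    homogenate_factor: float = 5.0


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing parameters for read simulation.

    Depth defaults follow the study's per-library averages (about 27K
    COI and 30K 16S-V4 reads); the error model is uniform per-base
    substitution with a flat quality profile.
    """

    depth_coi: float = 27000.0
    depth_16s: float = 30000.0
    error_rate: float = 0.001
    chimera_rate: float = 0.002
    bycatch_frac: float = 0.01
    max_spacer: int = 7
    read_length: int = 250
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "chimera_rate", "bycatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_coi <= 0 or self.depth_16s <= 0:
            raise ValueError("read depths must be positive")


def preset_small() -> tuple[CommunitySimConfig, ReadSimConfig]:
    """A 24-sample cohort (one fly per site-season-sex cell) for tests."""
    community = CommunitySimConfig(
        species_pool=6, max_genotypes_per_species=2, logseries_p=0.7,
        per_cell=1, n_wolbachia_strains=2, n_other_endosymbionts=0,
        n_generalists=4, n_contaminants=2, batch_size=24,
        blanks_per_batch=2, positives_per_batch=1,
    )
    reads = ReadSimConfig(depth_coi=3000, depth_16s=4000,
                          error_rate=0.0, chimera_rate=0.0, bycatch_frac=0.05)
    return community, reads


def preset_paper_shaped() -> tuple[CommunitySimConfig, ReadSimConfig]:
    """The full study-shaped design (about 2100 libraries)."""
    return CommunitySimConfig(), ReadSimConfig()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
    return "".join(s)


@dataclass
class CommunityTruth:
    """Fully specified ground truth for one simulated cohort."""

    config: CommunitySimConfig
    sample_sheet: pd.DataFrame  # sample_id, site, season, sex, control_type, spikein_copies
    genotype_seqs: dict[str, str]
    genotype_species: dict[str, int]  # genotype -> species rank (1-based)
    sample_genotype: dict[str, str]  # experimental sample -> genotype id
    strains: pd.DataFrame  # strain_id, category, genus
    strain_seq16: dict[str, str]
    strain_coi: dict[str, str]  # endosymbiont strains with a COI template
    lineages: dict[str, dict[str, str]]
    loads: pd.DataFrame  # 16S strains x all samples, true rRNA copies
    spikein_seq: str = ""
    pcr_spike_seq: str = ""

    @property
    def experimental_ids(self) -> list[str]:
        sheet = self.sample_sheet
        return sheet.loc[sheet.control_type == "sample", "sample_id"].tolist()

    @property
    def blank_ids(self) -> list[str]:
        sheet = self.sample_sheet
        return sheet.loc[sheet.control_type.isin(
            ["extraction_blank", "pcr_blank", "index_blank"]), "sample_id"].tolist()


def simulate_truth(config: CommunitySimConfig | None = None,
                   seed: int = 0) -> CommunityTruth:
    """Draw a complete community truth under the configured design.

    Host species identities follow a log-series rank-abundance curve;
    endosymbiont infections are structured by host species, genotype and
    sex with lognormal loads of high median; generalists are broadly
    distributed; contaminants are shared between blanks and (at low
    level) experimental samples.
    """
    cfg = config or CommunitySimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))

    # host species and genotypes
    n_geno = rng.integers(1, cfg.max_genotypes_per_species + 1, cfg.species_pool)
    genotype_seqs: dict[str, str] = {}
    genotype_species: dict[str, int] = {}
    species_genotypes: dict[int, list[str]] = {}
    for sp in range(1, cfg.species_pool + 1):
        ancestor = _random_seq(rng, cfg.barcode_length)
        gids = []
        for g in range(n_geno[sp - 1]):
            gid = f"sp{sp}_g{g + 1}"
            seq = ancestor if g == 0 else _mutate(ancestor, int(rng.integers(1, 4)), rng)
            genotype_seqs[gid] = seq
            genotype_species[gid] = sp
            gids.append(gid)
        species_genotypes[sp] = gids

    # log-series species weights, geometric genotype weights within species
    ranks = np.arange(1, cfg.species_pool + 1)
    sp_weights = cfg.logseries_p ** ranks / ranks
    sp_weights /= sp_weights.sum()

    # design grid
    rows = []
    sample_genotype: dict[str, str] = {}
    i = 0
    for site in range(1, cfg.n_sites + 1):
        for season in cfg.seasons:
            for sex in cfg.sexes:
                for _ in range(cfg.per_cell):
                    i += 1
                    sid = f"S{i:04d}"
                    rows.append((sid, f"site{site}", season, sex, "sample"))
                    sp = int(rng.choice(ranks, p=sp_weights))
                    gids = species_genotypes[sp]
                    gw = 0.5 ** np.arange(len(gids))
                    sample_genotype[sid] = str(rng.choice(gids, p=gw / gw.sum()))
    n_samples = i
    n_batches = max(1, int(np.ceil(n_samples / cfg.batch_size)))
    for b in range(n_batches):
        for k in range(cfg.blanks_per_batch):
            kind = ["extraction_blank", "pcr_blank", "index_blank"][k % 3]
            rows.append((f"BLK{b + 1:02d}_{k + 1}", "", "", "", kind))
        for k in range(cfg.positives_per_batch):
            rows.append((f"POS{b + 1:02d}_{k + 1}", "", "", "", "positive"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "site", "season", "sex",
                                        "control_type"])
    # spike-in copies alternate by batch; controls get the batch's amount
    batch_of = {}
    for j, sid in enumerate(sheet.loc[sheet.control_type == "sample", "sample_id"]):
        batch_of[sid] = j // cfg.batch_size
    for sid in sheet.loc[sheet.control_type != "sample", "sample_id"]:
        batch_of[sid] = int(sid[3:5]) - 1
    sheet["spikein_copies"] = [cfg.spike_choices[batch_of[s] % len(cfg.spike_choices)]
                               for s in sheet.sample_id]
    sheet["homogenate_factor"] = cfg.homogenate_factor

    # bacterial strains
    strain_rows = []
    strain_seq16: dict[str, str] = {}
    strain_coi: dict[str, str] = {}
    lineages: dict[str, dict[str, str]] = {}
    endo_host: dict[str, dict[str, float]] = {}  # strain -> genotype -> prevalence

    def add_strain(sid: str, category: str, genus: str, coi: bool = False) -> None:
        strain_rows.append((sid, category, genus))
        strain_seq16[sid] = _random_seq(rng, cfg.s16_length)
        lineages[sid] = dict(_LINEAGE_BASE[genus], species=f"{genus}_{sid}")
        if coi:
            strain_coi[sid] = _random_seq(rng, cfg.barcode_length)

    top_species = ranks[:max(3, cfg.species_pool // 3)]
    n_endo = cfg.n_wolbachia_strains + cfg.n_other_endosymbionts
    for k in range(n_endo):
        genus = "Wolbachia" if k < cfg.n_wolbachia_strains else \
            ENDOSYMBIONT_GENERA[1 + k % 2]
        sid = f"{genus[:3].lower()}{k + 1}"
        add_strain(sid, "endosymbiont", genus, coi=genus in ("Wolbachia", "Rickettsia"))
        hosts = rng.choice(top_species, size=min(len(top_species),
                                                 int(rng.integers(1, 4))),
                           replace=False)
        prev = {}
        for sp in hosts:
            for gid in species_genotypes[int(sp)]:
                if rng.uniform() < 0.7:
                    prev[gid] = float(rng.beta(2.5, 1.5))
        endo_host[sid] = prev
    for k in range(cfg.n_generalists):
        genus = GENERALIST_GENERA[k % len(GENERALIST_GENERA)]
        add_strain(f"gen{k + 1}", "generalist", genus)
    for k in range(cfg.n_contaminants):
        genus = CONTAMINANT_GENERA[k % len(CONTAMINANT_GENERA)]
        add_strain(f"con{k + 1}", "contaminant", genus)
    strains = pd.DataFrame(strain_rows, columns=["strain_id", "category", "genus"])

    # true loads (16S rRNA copies) per strain x sample
    loads = pd.DataFrame(0.0, index=strains.strain_id, columns=sheet.sample_id)
    sex_of = dict(zip(sheet.sample_id, sheet.sex))
    for sid in sheet.loc[sheet.control_type == "sample", "sample_id"]:
        gid = sample_genotype[sid]
        for strain in endo_host:
            base = endo_host[strain].get(gid, 0.0)
            if base == 0.0:
                continue
            odds = base / (1 - base + 1e-9)
            if sex_of[sid] == "F":
                odds *= cfg.endo_female_odds
            p = odds / (1 + odds)
            if rng.uniform() < p:
                loads.loc[strain, sid] = cfg.endo_median_load * \
                    float(rng.lognormal(0.0, cfg.endo_sigma))
        for strain in strains.loc[strains.category == "generalist", "strain_id"]:
            if rng.uniform() < cfg.gen_presence_prob:
                loads.loc[strain, sid] = cfg.gen_median_load * \
                    float(rng.lognormal(0.0, cfg.gen_sigma))
        for strain in strains.loc[strains.category == "contaminant", "strain_id"]:
            loads.loc[strain, sid] = cfg.contam_sample_load * \
                float(rng.lognormal(0.0, 0.5))
    blank_ids = sheet.loc[sheet.control_type.str.endswith("blank"), "sample_id"]
    for sid in blank_ids:
        for strain in strains.loc[strains.category == "contaminant", "strain_id"]:
            loads.loc[strain, sid] = cfg.contam_blank_weight * \
                float(rng.lognormal(0.0, 0.3))
    pos_ids = sheet.loc[sheet.control_type == "positive", "sample_id"]
    mock = strains.loc[strains.category == "generalist", "strain_id"].tolist()[:2]
    for sid in pos_ids:
        for strain in mock:
            loads.loc[strain, sid] = 5.0e5

    return CommunityTruth(
        config=cfg, sample_sheet=sheet, genotype_seqs=genotype_seqs,
        genotype_species=genotype_species, sample_genotype=sample_genotype,
        strains=strains, strain_seq16=strain_seq16, strain_coi=strain_coi,
        lineages=lineages, loads=loads,
        spikein_seq=_random_seq(np.random.default_rng(12345), cfg.s16_length),
        pcr_spike_seq=_random_seq(np.random.default_rng(54321), cfg.s16_length),
    )


def allocate_reads(copies: dict[str, float], spike_copies: float, depth: int,
                   homogenate_factor: float, rng: np.random.Generator
                   ) -> dict[str, int]:
    """Multinomial read allocation over templates plus the spike-in.

    The spike-in is added to the full extract while only 1/f of the
    homogenate is used, so template weights are copies/f against the
    spike-in's full copy number.  Returns template -> reads with the
    spike under key ``"spike"``.
    """
    names = list(copies)
    w = np.array([copies[n] / homogenate_factor for n in names] + [spike_copies])
    if w.sum() <= 0 or depth <= 0:
        return {n: 0 for n in names} | {"spike": 0}
    counts = rng.multinomial(depth, w / w.sum())
    out = dict(zip(names, (int(c) for c in counts[:-1])))
    out["spike"] = int(counts[-1])
    return out


@dataclass
class SimulatedReads:
    """Raw paired reads per library plus read-allocation truth tables."""

    reads: dict[str, list[ReadPair]]
    coi_counts: pd.DataFrame  # COI template x sample reads (host + bycatch)
    s16_counts: pd.DataFrame  # 16S template x sample reads (incl. spike rows)
    coi_templates: dict[str, str]
    s16_templates: dict[str, str]

    def write_fastq(self, out_dir: str | Path, gzipped: bool = True) -> list[Path]:
        """One pair of FASTQ files per library."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sid, pairs in self.reads.items():
            for mate in (1, 2):
                suffix = ".fastq.gz" if gzipped else ".fastq"
                path = out_dir / f"{sid}_R{mate}{suffix}"
                opener = gzip.open if gzipped else open
                with opener(path, "wt") as fh:
                    for p in pairs:
                        seq = p.fwd_seq if mate == 1 else p.rev_seq
                        qual = p.fwd_qual if mate == 1 else p.rev_qual
                        fh.write(f"@{p.read_id}\n{seq}\n+\n")
                        fh.write("".join(chr(q + 33) for q in qual) + "\n")
                paths.append(path)
        return paths


def _concrete(primer: str) -> str:
    return "".join(sorted(IUPAC[c])[0] for c in primer)


def simulate_reads(truth: CommunityTruth, rs: ReadSimConfig | None = None
                   ) -> SimulatedReads:
    """Generate paired reads for every library, controls included.

    Per sample, reads are allocated multinomially over templates (16S:
    bacterial strains plus the spike-in at its known copies; COI: host
    mitochondrial barcode plus endosymbiont bycatch proportional to
    strain loads).  Heterogeneity spacers of random length are prepended
    before the primer, and substitution errors applied per base.  Blanks
    carry only contaminant and spike-in templates.
    """
    rs = rs or ReadSimConfig()
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([rs.seed, 7002]))
    from .readprep import DEFAULT_SCHEMES

    schemes = {s.target_id: s for s in DEFAULT_SCHEMES}
    primers = {t: (_concrete(s.fwd_primer), _concrete(s.rev_primer))
               for t, s in schemes.items()}

    s16_templates = {f"16S_{k}": v for k, v in truth.strain_seq16.items()}
    s16_templates["16S_spike"] = truth.spikein_seq
    s16_templates["16S_pcr_spike"] = truth.pcr_spike_seq
    coi_templates = {f"COI_{g}": s for g, s in truth.genotype_seqs.items()}
    coi_templates.update({f"COI_{k}": v for k, v in truth.strain_coi.items()})

    sheet = truth.sample_sheet
    all_ids = sheet.sample_id.tolist()
    coi_counts = pd.DataFrame(0, index=list(coi_templates), columns=all_ids)
    s16_counts = pd.DataFrame(0, index=list(s16_templates), columns=all_ids)
    reads: dict[str, list[ReadPair]] = {}

    err = rs.error_rate
    qual = [rs.base_quality] * rs.read_length
    # heterogeneity spacers are a fixed ladder of defined sequences
    spacers = ["ACGTACG"[:k] for k in range(rs.max_spacer + 1)]
    memo: dict[tuple, tuple[str, str]] = {}

    def make_pair(read_id: str, target: str, insert: str) -> ReadPair:
        l1 = int(rng.integers(0, rs.max_spacer + 1))
        l2 = int(rng.integers(0, rs.max_spacer + 1))
        key = (target, insert, l1, l2)
        if key in memo:
            r1, r2 = memo[key]
        else:
            fp, rp = primers[target]
            r1 = (spacers[l1] + fp + insert)[:rs.read_length]
            r2 = (spacers[l2] + rp + revcomp(insert))[:rs.read_length]
            memo[key] = (r1, r2)
        if err > 0:
            r1 = _add_errors(r1, err, rng)
            r2 = _add_errors(r2, err, rng)
        return ReadPair(read_id, r1, r2, qual[:len(r1)], qual[:len(r2)])

    for _, row in sheet.iterrows():
        sid = row.sample_id
        is_sample = row.control_type == "sample"
        pairs: list[ReadPair] = []

        # --- 16S library
        copies = {f"16S_{k}": float(v) for k, v in truth.loads[sid].items() if v > 0}
        # the unused PCR spike-in rides along at a small constant weight
        alloc = allocate_reads(copies, float(row.spikein_copies),
                               int(rng.poisson(rs.depth_16s)),
                               cfg.homogenate_factor, rng)
        alloc["16S_spike"] = alloc.pop("spike")
        pcr_reads = int(rng.poisson(0.002 * rs.depth_16s))
        alloc["16S_pcr_spike"] = pcr_reads
        n_chim = 0
        chim_sources = [k for k in alloc if alloc[k] > 0 and k != "16S_pcr_spike"]
        for tmpl, n in alloc.items():
            s16_counts.loc[tmpl, sid] = n
            seq = s16_templates[tmpl]
            for r in range(n):
                if rs.chimera_rate > 0 and len(chim_sources) > 1 \
                        and rng.uniform() < rs.chimera_rate:
                    other = s16_templates[str(rng.choice(chim_sources))]
                    k = int(rng.integers(60, len(seq) - 60))
                    insert = seq[:k] + other[k:]
                    n_chim += 1
                else:
                    insert = seq
                pairs.append(make_pair(f"{sid}_16S_{tmpl}_{r}", "16S-V4", insert))

        # --- COI library
        if is_sample:
            gid = truth.sample_genotype[sid]
            coi_weights = {f"COI_{gid}": 1.0 - rs.bycatch_frac}
            endo = {k: truth.loads.loc[k, sid] for k in truth.strain_coi
                    if truth.loads.loc[k, sid] > 0}
            tot = sum(endo.values())
            if tot > 0:
                for k, v in endo.items():
                    coi_weights[f"COI_{k}"] = rs.bycatch_frac * v / tot
            else:
                coi_weights[f"COI_{gid}"] = 1.0
            depth = int(rng.poisson(rs.depth_coi))
            names = list(coi_weights)
            w = np.array([coi_weights[n] for n in names])
            counts = rng.multinomial(depth, w / w.sum())
            for tmpl, n in zip(names, counts):
                coi_counts.loc[tmpl, sid] = int(n)
                seq = coi_templates[tmpl]
                for r in range(int(n)):
                    pairs.append(make_pair(f"{sid}_COI_{tmpl}_{r}", "COI", seq))

        order = rng.permutation(len(pairs))
        reads[sid] = [pairs[k] for k in order]

    return SimulatedReads(reads, coi_counts, s16_counts, coi_templates,
                          s16_templates)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
    return "".join(s)


# ----------------------------------------------------------------------
# reference fixtures


def taxonomy_fasta_16s(truth: CommunityTruth) -> str:
    """16S reference FASTA text with rank-annotated headers."""
    lines = []
    for sid, seq in truth.strain_seq16.items():
        lin = truth.lineages[sid]
        tax = ",".join(f"{r[0]}:{lin[r]}" for r in
                       ("domain", "phylum", "class", "order", "family",
                        "genus", "species") if r in lin)
        lines.append(f">{sid};tax={tax};\n{seq}")
    return "\n".join(lines) + "\n"


def taxonomy_fasta_coi(truth: CommunityTruth) -> str:
    """COI reference FASTA: one arthropod entry per species plus
    alphaproteobacterial (Wolbachia/Rickettsia) COI templates."""
    lines = []
    seen_species = set()
    for gid, seq in truth.genotype_seqs.items():
        sp = truth.genotype_species[gid]
        if sp in seen_species:
            continue
        seen_species.add(sp)
        tax = (f"d:Eukaryota,p:Arthropoda,c:Insecta,o:Diptera,"
               f"f:Phoridae,g:Megaselia,s:Megaselia_sp{sp}")
        lines.append(f">coi_sp{sp};tax={tax};\n{seq}")
    for sid, seq in truth.strain_coi.items():
        lin = truth.lineages[sid]
        tax = ",".join(f"{r[0]}:{lin[r]}" for r in
                       ("domain", "phylum", "class", "order", "family",
                        "genus", "species") if r in lin)
        lines.append(f">coi_{sid};tax={tax};\n{seq}")
    return "\n".join(lines) + "\n"


def named_barcode_fasta(truth: CommunityTruth, n_named: int | None = None) -> str:
    """Named-species barcode references (first genotype per species)."""
    lines = []
    seen = set()
    for gid, seq in truth.genotype_seqs.items():
        sp = truth.genotype_species[gid]
        if sp in seen:
            continue
        seen.add(sp)
        if n_named is not None and len(seen) > n_named:
            break
        lines.append(f">ref_sp{sp} species=Megaselia_sp{sp}\n{seq}")
    return "\n".join(lines) + "\n"


def write_fixtures(out_dir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a small, self-consistent reference fixture set.

    Taxonomy FASTA (16S and COI), named barcode FASTA, spike-in FASTA,
    and a sample sheet, all generated from a fixed-seed small community
    (deterministic bytes for a given seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, _ = preset_small()
    truth = simulate_truth(cfg, seed=seed)
    paths = {}
    files = {
        "taxonomy_16s.fasta": taxonomy_fasta_16s(truth),
        "taxonomy_coi.fasta": taxonomy_fasta_coi(truth),
        "named_barcodes.fasta": named_barcode_fasta(truth),
        "spikein.fasta": (f">Ec5502 extraction spike-in\n{truth.spikein_seq}\n"
                          f">Ec5001 pcr spike-in (unused)\n{truth.pcr_spike_seq}\n"),
    }
    for name, text in files.items():
        path = out / name
        path.write_text(text)
        paths[name] = path
    sheet_path = out / "sample_sheet.tsv"
    truth.sample_sheet.to_csv(sheet_path, sep="\t", index=False)
    paths["sample_sheet.tsv"] = sheet_path
    return paths
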