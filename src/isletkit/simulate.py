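"""Synthetic paired-species fixtures with planted ground truth.

The generator emulates the study design the pipeline targets: two
FACS-purified islet populations (beta and alpha cells) sequenced in
replicate in the mouse, a human beta/non-beta counterpart, an ortholog
table covering most genes 1:1, pooled read-coverage tracks hiding novel
lncRNA loci among decoys that each violate exactly one discovery rule,
TF ChIP peaks planted at transcript ends with species-biased read
counts, and a sequence carrying a dense motif cluster.

Counts are negative binomial with Var = mu + alpha * mu^2. Population
and species enrichment is planted one-sided (the enriched population's
mean is multiplied by the fold), since the genes the comparison
highlights are the abundantly, selectively expressed ones. Species-
unique genes get mean zero in the other species: at desk-scale depth a
single stray count already yields RPKM above the uniqueness gate,
whereas a deeply sequenced real library resolves RPKM far below 1.

Everything is deterministic given ``SimConfig.seed``; each stage draws
from its own spawned generator so the stages can be regenerated
independently and reproduce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ikio
from .models import Block, BlockMap, GeneModel, GenomeAnnotation, OrthologMap, PeakSet
from .regulatory import PWM
from .intervals import overlap_length

log = logging.getLogger(__name__)

DECOY_RULES = ("exon_overlap", "short", "low_rpkm", "rrna", "conserved")
ETS_CONSENSUS = "ACCGGAAGT"
_RC = str.maketrans("ACGT", "TGCA")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for fixture generation.

    Defaults mirror the target study where it states them (two replicate
    groups per population; 145 novel lncRNAs as 18 intronic + 127
    intergenic; 20-fold planted enrichment; a 13-site motif cluster in a
    300 bp window; 4-/5-fold species peak ratios) and fall back to
    typical bulk RNA-seq values elsewhere (NB dispersion 0.05, library
    size factors log-uniform in [0.5, 2]).
    """

    n_genes: int = 2000
    n_lnc_intronic: int = 18
    n_lnc_intergenic: int = 127
    n_decoys_per_rule: int = 20
    replicates_per_population: int = 2
    nb_dispersion: float = 0.05
    planted_beta_enriched: int = 50
    planted_alpha_enriched: int = 50
    planted_species_unique: int = 40     # per species
    planted_species_enriched: int = 20   # per species
    planted_glucose_up: int = 30
    planted_glucose_down: int = 30
    planted_glucose_lnc: int = 10        # of the up-set, planted on lncRNAs
    enrichment_fold: float = 20.0
    glucose_fold: float = 10.0
    coreg_rho: float = 0.6               # target Spearman for lnc/neighbor ratios
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 12_000_000
    ortholog_coverage: float = 0.9
    read_length: int = 50
    coverage_total_reads: float = 2_000_000.0
    n_peaks: int = 200
    peak_end_fraction: float = 0.6
    peak_window: int = 1000
    n_species_specific_peaks: int = 20   # per species
    peak_species_ratio: float = 5.0
    n_rrna_loci: int = 5                 # standalone rRNA loci
    motif_cluster_sites: int = 13
    motif_cluster_window: int = 300
    n_scattered_sites: int = 8
    cluster_seq_length: int = 20_000

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.replicates_per_population < 2:
            raise ConfigError("need at least 2 replicates per population")
        if not (-1.0 <= self.coreg_rho <= 1.0):
            raise ConfigError("coreg_rho must lie in [-1, 1]")
        special = (
            self.n_lnc_intergenic + self.n_lnc_intronic + self.n_decoys_per_rule
        )
        planted = (
            self.planted_beta_enriched + self.planted_alpha_enriched
            + 2 * self.planted_species_unique + 2 * self.planted_species_enriched
        )
        if special + planted > self.n_genes:
            raise ConfigError(
                f"planted categories ({planted}) plus lncRNA-hosting genes "
                f"({special}) exceed n_genes ({self.n_genes})"
            )

    @property
    def n_lnc(self) -> int:
        return self.n_lnc_intronic + self.n_lnc_intergenic


SMALL_PRESET = dict(
    n_genes=300,
    n_lnc_intronic=4,
    n_lnc_intergenic=12,
    n_decoys_per_rule=3,
    planted_beta_enriched=15,
    planted_alpha_enriched=15,
    planted_species_unique=10,
    planted_species_enriched=5,
    planted_glucose_up=8,
    planted_glucose_down=8,
    planted_glucose_lnc=3,
    n_chroms=2,
    chrom_length=3_000_000,
    n_peaks=80,
    n_species_specific_peaks=8,
    n_rrna_loci=3,
    n_scattered_sites=5,
)


def preset_config(name: str, seed: int = 0) -> SimConfig:
    if name == "paper-scale":
        return SimConfig(seed=seed)
    if name == "small":
        return SimConfig(seed=seed, **SMALL_PRESET)
    raise ConfigError(f"unknown preset {name!r} (choose small or paper-scale)")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass
class _LncSlot:
    kind: str          # true_intergenic / true_intronic / decoy:<rule>
    chrom: str
    start: int
    end: int
    neighbor_gene: str | None = None
    rrna: tuple[int, int] | None = None


@dataclass
class _Layout:
    ann: GenomeAnnotation
    slots: list[_LncSlot]
    rrna: list[tuple[str, int, int]]
    roles: dict[str, str]  # gene_id -> plain/neighbor/host/decoy_host


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        r = 1.0 / dispersion
        out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def _make_gene(gid: str, chrom: str, pos: int, rng: np.random.Generator) -> GeneModel:
    n_ex = int(rng.integers(2, 5))
    exons = []
    p = pos
    for k in range(n_ex):
        elen = int(rng.integers(200, 1200))
        exons.append((p, p + elen - 1))
        if k < n_ex - 1:
            p += elen + int(rng.integers(500, 2500))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                     exons=tuple(exons), biotype="protein_coding")


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> _Layout:
    units: list[tuple[str, int]] = []
    units += [("neighbor", i) for i in range(cfg.n_lnc_intergenic)]
    units += [("host", i) for i in range(cfg.n_lnc_intronic)]
    for rule in DECOY_RULES:
        units += [(f"decoy_{rule}", i) for i in range(cfg.n_decoys_per_rule)]
    units += [("rrna_plain", i) for i in range(cfg.n_rrna_loci)]
    n_gene_units = cfg.n_lnc_intergenic + cfg.n_lnc_intronic + cfg.n_decoys_per_rule
    n_plain = cfg.n_genes - n_gene_units
    units += [("plain", i) for i in range(n_plain)]
    rng.shuffle(units)

    genes: list[GeneModel] = []
    slots: list[_LncSlot] = []
    rrna: list[tuple[str, int, int]] = []
    roles: dict[str, str] = {}
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    chrom_idx, pos = 0, 50_000
    margin = 60_000
    gid_counter = 0

    def next_gid() -> str:
        nonlocal gid_counter
        gid = f"mg{gid_counter:05d}"
        gid_counter += 1
        return gid

    for kind, _i in units:
        chrom = f"chr{chrom_idx + 1}"
        if kind == "plain":
            g = _make_gene(next_gid(), chrom, pos, rng)
            genes.append(g)
            roles[g.gene_id] = "plain"
            pos = g.span[1] + int(rng.integers(2000, 5000))
        elif kind == "neighbor":
            g = _make_gene(next_gid(), chrom, pos, rng)
            genes.append(g)
            roles[g.gene_id] = "neighbor"
            d1 = int(rng.integers(3000, 8000))
            lnc_len = int(rng.integers(3200, 6000))
            s = g.span[1] + d1
            slots.append(_LncSlot("true_intergenic", chrom, s, s + lnc_len - 1,
                                  neighbor_gene=g.gene_id))
            pos = s + lnc_len + 20_000
        elif kind == "host":
            lnc_len = int(rng.integers(3200, 5000))
            exon1 = (pos, pos + 399)
            lnc_s = exon1[1] + 1000
            lnc_e = lnc_s + lnc_len - 1
            exon2 = (lnc_e + 1000, lnc_e + 1399)
            gid = next_gid()
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                                   exons=(exon1, exon2), biotype="protein_coding"))
            roles[gid] = "host"
            slots.append(_LncSlot("true_intronic", chrom, lnc_s, lnc_e,
                                  neighbor_gene=gid))
            pos = exon2[1] + 3000
        elif kind == "decoy_exon_overlap":
            g = _make_gene(next_gid(), chrom, pos, rng)
            genes.append(g)
            roles[g.gene_id] = "decoy_host"
            last_end = g.span[1]
            s = last_end - 200
            slots.append(_LncSlot("decoy:exon_overlap", chrom, s, s + 3499))
            pos = s + 3500 + 20_000
        elif kind == "decoy_short":
            slots.append(_LncSlot("decoy:short", chrom, pos, pos + 2499))
            pos += 2500 + 3000
        elif kind == "decoy_low_rpkm":
            slots.append(_LncSlot("decoy:low_rpkm", chrom, pos, pos + 3999))
            pos += 4000 + 3000
        elif kind == "decoy_rrna":
            r = (pos + 2000, pos + 2499)
            rrna.append((chrom, r[0], r[1]))
            slots.append(_LncSlot("decoy:rrna", chrom, pos, pos + 3999, rrna=r))
            pos += 4000 + 3000
        elif kind == "decoy_conserved":
            slots.append(_LncSlot("decoy:conserved", chrom, pos, pos + 3999))
            pos += 4000 + 3000
        elif kind == "rrna_plain":
            rrna.append((chrom, pos, pos + 499))
            pos += 500 + 3000
        if pos > cfg.chrom_length - margin:
            chrom_idx += 1
            pos = 50_000
            if chrom_idx >= cfg.n_chroms:
                raise ConfigError(
                    "insufficient genomic space for the requested layout; "
                    "increase chrom_length or n_chroms"
                )
    ann = GenomeAnnotation(genes=genes, genome_id="mouse", chrom_sizes=chrom_sizes)
    return _Layout(ann=ann, slots=slots, rrna=rrna, roles=roles)


def _build_human_annotation(cfg: SimConfig, rng: np.random.Generator) -> GenomeAnnotation:
    chrom_sizes = {f"hchr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    genes = []
    chrom_idx, pos = 0, 50_000
    for i in range(cfg.n_genes):
        chrom = f"hchr{chrom_idx + 1}"
        g = _make_gene(f"hg{i:05d}", chrom, pos, rng)
        genes.append(g)
        pos = g.span[1] + int(rng.integers(2000, 5000))
        if pos > cfg.chrom_length - 60_000:
            chrom_idx += 1
            pos = 50_000
            if chrom_idx >= cfg.n_chroms:
                raise ConfigError("insufficient human genomic space; increase chrom_length")
    return GenomeAnnotation(genes=genes, genome_id="human", chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CountsSim:
    counts_mouse: pd.DataFrame
    counts_human: pd.DataFrame
    ann_mouse: GenomeAnnotation
    ann_human: GenomeAnnotation
    orthologs: OrthologMap
    gene_truth: pd.DataFrame  # index mouse gene_id
    sample_groups: dict[str, list[str]]


@dataclass
class LncSim:
    coverage: dict[str, pd.DataFrame]       # population -> track
    conservation: pd.DataFrame
    rrna: pd.DataFrame
    lnc_truth: pd.DataFrame
    mapped_totals: dict[str, float]
    read_length: int


@dataclass
class RegSim:
    peaks_mouse: PeakSet
    peaks_human: PeakSet
    blockmap_m2h: BlockMap
    sequences: dict[str, str]
    pwm: PWM
    transcripts: pd.DataFrame
    peak_truth: pd.DataFrame
    cluster_truth: dict


@dataclass
class GlucoseSim:
    counts_control: pd.DataFrame
    counts_glucose: pd.DataFrame
    truth: pd.DataFrame
    lnc_ids: list[str]


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class Simulation:
    """Deterministic fixture generator; all stages share one layout."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        seeds = np.random.SeedSequence(cfg.seed).spawn(6)
        self._rng_layout = np.random.default_rng(seeds[0])
        self._rng_human = np.random.default_rng(seeds[1])
        self._rng_counts = np.random.default_rng(seeds[2])
        self._rng_lnc = np.random.default_rng(seeds[3])
        self._rng_reg = np.random.default_rng(seeds[4])
        self._rng_glucose = np.random.default_rng(seeds[5])
        self.layout = _build_layout(cfg, self._rng_layout)
        self.ann_human = _build_human_annotation(cfg, self._rng_human)
        self._counts: CountsSim | None = None
        self._lnc: LncSim | None = None
        self._reg: RegSim | None = None
        self._glucose: GlucoseSim | None = None

    # -- counts -------------------------------------------------------------

    def counts(self) -> CountsSim:
        if self._counts is not None:
            return self._counts
        cfg = self.cfg
        rng = self._rng_counts
        ann = self.layout.ann
        gene_ids = [g.gene_id for g in ann.genes]
        n = len(gene_ids)
        idx = pd.Index(gene_ids)

        base = 10 ** rng.uniform(0.5, 3.0, n)
        beta_mean = base.copy()
        alpha_mean = base.copy()

        # coreg neighbors/hosts get a continuous beta/alpha skew
        roles = self.layout.roles
        coreg_genes = [g for g in gene_ids if roles[g] in ("neighbor", "host")]
        coreg_pos = idx.get_indexer(coreg_genes)
        coreg_l = rng.normal(0.0, 1.2, len(coreg_genes))
        if len(coreg_genes):
            coreg_base = 10 ** rng.uniform(1.3, 2.5, len(coreg_genes))
            base[coreg_pos] = coreg_base
            beta_mean[coreg_pos] = coreg_base * 2 ** (coreg_l / 2)
            alpha_mean[coreg_pos] = coreg_base * 2 ** (-coreg_l / 2)

        plain = [g for g in gene_ids if roles[g] == "plain"]
        picks = rng.choice(len(plain), size=(
            cfg.planted_beta_enriched + cfg.planted_alpha_enriched
            + 2 * cfg.planted_species_unique + 2 * cfg.planted_species_enriched
        ), replace=False)
        cursor = 0

        def take(k: int) -> list[str]:
            nonlocal cursor
            sel = [plain[j] for j in picks[cursor:cursor + k]]
            cursor += k
            return sel

        beta_set = take(cfg.planted_beta_enriched)
        alpha_set = take(cfg.planted_alpha_enriched)
        m_unique = take(cfg.planted_species_unique)
        h_unique = take(cfg.planted_species_unique)
        m_enr = take(cfg.planted_species_enriched)
        h_enr = take(cfg.planted_species_enriched)

        beta_mean[idx.get_indexer(beta_set)] *= cfg.enrichment_fold
        alpha_mean[idx.get_indexer(alpha_set)] *= cfg.enrichment_fold

        # human beta mirrors mouse beta unless a species category overrides
        hbeta_mean = beta_mean.copy()
        hnonbeta_mean = alpha_mean.copy()

        pos_mu = idx.get_indexer(m_unique)
        beta_mean[pos_mu] = 10 ** rng.uniform(1.7, 3.0, len(m_unique))
        hbeta_mean[pos_mu] = 0.0
        pos_hu = idx.get_indexer(h_unique)
        hbeta_mean[pos_hu] = 10 ** rng.uniform(1.7, 3.0, len(h_unique))
        beta_mean[pos_hu] = 0.0
        pos_me = idx.get_indexer(m_enr)
        beta_mean[pos_me] = 10 ** rng.uniform(2.3, 3.0, len(m_enr))
        hbeta_mean[pos_me] = beta_mean[pos_me] / cfg.enrichment_fold
        pos_he = idx.get_indexer(h_enr)
        hbeta_mean[pos_he] = 10 ** rng.uniform(2.3, 3.0, len(h_enr))
        beta_mean[pos_he] = hbeta_mean[pos_he] / cfg.enrichment_fold

        R = cfg.replicates_per_population
        log2 = np.log(2.0)

        def sample_block(means: np.ndarray, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
            factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n_samples))
            cols = np.stack(
                [_nb_draw(rng, means * f, cfg.nb_dispersion) for f in factors], axis=1
            )
            return cols, factors

        mb, _ = sample_block(beta_mean, R)
        ma, _ = sample_block(alpha_mean, R)
        counts_mouse = pd.DataFrame(
            np.hstack([mb, ma]), index=idx,
            columns=[f"beta_{i + 1}" for i in range(R)] + [f"alpha_{i + 1}" for i in range(R)],
        )
        # ensure species-unique genes are truly absent in the other species
        hb, _ = sample_block(hbeta_mean, R)
        hn, _ = sample_block(hnonbeta_mean, R)
        human_ids = [f"hg{i:05d}" for i in range(n)]
        counts_human = pd.DataFrame(
            np.hstack([hb, hn]), index=pd.Index(human_ids),
            columns=[f"beta_{i + 1}" for i in range(R)] + [f"nonbeta_{i + 1}" for i in range(R)],
        )

        n_pair = int(round(cfg.ortholog_coverage * n))
        planted_set = set(beta_set + alpha_set + m_unique + h_unique + m_enr + h_enr)
        droppable = [i for i, g in enumerate(gene_ids)
                     if g not in planted_set and roles[g] == "plain"]
        n_drop = n - n_pair
        drop = set(rng.choice(droppable, size=min(n_drop, len(droppable)), replace=False).tolist())
        pairs = [(gene_ids[i], human_ids[i]) for i in range(n) if i not in drop]
        omap = OrthologMap(pairs, species1="mouse", species2="human")

        # expected RPKM for truth labels, from planted means and lengths
        def expected_rpkm(means: np.ndarray, annotation: GenomeAnnotation,
                          ids: list[str]) -> np.ndarray:
            lengths = np.array([annotation.by_id[g].merged_exon_length for g in ids]) / 1000.0
            total = means.sum() / 1e6
            with np.errstate(divide="ignore", invalid="ignore"):
                return means / (lengths * total)

        rpkm_m = expected_rpkm(beta_mean, ann, gene_ids)
        rpkm_h = expected_rpkm(hbeta_mean, self.ann_human, human_ids)

        pop_label = pd.Series("neutral", index=idx, dtype=object)
        pop_label[beta_set] = "beta_enriched"
        pop_label[alpha_set] = "alpha_enriched"
        sp_label = pd.Series("", index=idx, dtype=object)
        paired = {a for a, _ in pairs}
        for g, r_m, r_h in zip(gene_ids, rpkm_m, rpkm_h):
            if g not in paired:
                continue
            sp_label[g] = "common" if (r_m > 1 and r_h > 1) else "absent"
        sp_label[m_unique] = "mouse_unique"
        sp_label[h_unique] = "human_unique"
        sp_label[m_enr] = "mouse_enriched"
        sp_label[h_enr] = "human_enriched"

        truth = pd.DataFrame(
            {
                "population_label": pop_label,
                "species_label": sp_label,
                "human_id": [human_ids[i] if i not in drop else "" for i in range(n)],
                "role": [roles[g] for g in gene_ids],
                "beta_mean": beta_mean,
                "alpha_mean": alpha_mean,
                "human_beta_mean": hbeta_mean,
                "coreg_log_ratio": np.nan,
            }
        )
        truth.loc[coreg_genes, "coreg_log_ratio"] = coreg_l
        _ = log2  # (kept for clarity of units above)

        self._counts = CountsSim(
            counts_mouse=counts_mouse,
            counts_human=counts_human,
            ann_mouse=ann,
            ann_human=self.ann_human,
            orthologs=omap,
            gene_truth=truth,
            sample_groups={
                "mouse_beta": [f"beta_{i + 1}" for i in range(R)],
                "mouse_alpha": [f"alpha_{i + 1}" for i in range(R)],
                "human_beta": [f"beta_{i + 1}" for i in range(R)],
                "human_nonbeta": [f"nonbeta_{i + 1}" for i in range(R)],
            },
        )
        return self._counts

    # -- lncRNA loci --------------------------------------------------------

    def lnc_loci(self) -> LncSim:
        if self._lnc is not None:
            return self._lnc
        cfg = self.cfg
        rng = self._rng_lnc
        counts = self.counts()
        truth_genes = counts.gene_truth
        T = cfg.coverage_total_reads
        rl = float(cfg.read_length)

        # latent coreg: lnc ratio correlated with the neighbor gene's ratio.
        # Gaussian-copula Pearson r chosen so the *Spearman* target is coreg_rho.
        r_latent = 2 * np.sin(np.pi * cfg.coreg_rho / 6)

        cov_rows: dict[str, list] = {"alpha": [], "beta": []}
        cons_rows: list = []
        truth_rows: list = []
        lnc_counter = 0

        def emit_coverage(slot: _LncSlot, rpkm: dict[str, float]) -> None:
            length = slot.end - slot.start + 1
            # occasionally split the locus into two chunks with a small gap
            if rng.random() < 0.5 and length > 2000:
                gap = int(rng.integers(100, 800))
                cut = slot.start + length // 2
                chunks = [(slot.start, cut - 1), (cut + gap, slot.end)]
                chunks = [(s, min(e, slot.end)) for s, e in chunks if s < e]
            else:
                chunks = [(slot.start, slot.end)]
            covered = sum(e - s + 1 for s, e in chunks)
            for pop in ("alpha", "beta"):
                count = rpkm[pop] * (length / 1000.0) * (T / 1e6)
                depth = count * rl / covered
                if depth <= 0:
                    continue
                for s, e in chunks:
                    cov_rows[pop].append((slot.chrom, s, e, depth))

        for slot in self.layout.slots:
            conservation = float(rng.uniform(0.05, 0.30))
            if slot.kind in ("true_intergenic", "true_intronic"):
                lnc_id = f"lnc{lnc_counter:04d}"
                lnc_counter += 1
                gene_l = float(truth_genes.loc[slot.neighbor_gene, "coreg_log_ratio"])
                z_gene = gene_l / 1.2
                lam = 1.2 * (r_latent * z_gene + np.sqrt(1 - r_latent**2) * rng.normal())
                geo = float(rng.uniform(1.5, 4.0))
                rpkm = {"beta": geo * 2 ** (lam / 2), "alpha": geo * 2 ** (-lam / 2)}
                label, cls = "true_lnc", slot.kind.replace("true_", "")
            else:
                rule = slot.kind.split(":", 1)[1]
                lnc_id = f"decoy_{rule}_{lnc_counter:04d}"
                lnc_counter += 1
                rpkm = {"beta": 2.0, "alpha": 2.0}
                if rule == "low_rpkm":
                    rpkm = {"beta": 0.3, "alpha": 0.3}
                if rule == "conserved":
                    conservation = 0.8
                label, cls = slot.kind, ""
            emit_coverage(slot, rpkm)
            cons_rows.append((slot.chrom, slot.start - 500, slot.end + 500, conservation))
            truth_rows.append(
                {
                    "lnc_id": lnc_id,
                    "label": label,
                    "chrom": slot.chrom,
                    "start": slot.start,
                    "end": slot.end,
                    "class": cls,
                    "neighbor_gene": slot.neighbor_gene or "",
                    "beta_rpkm": rpkm["beta"],
                    "alpha_rpkm": rpkm["alpha"],
                    "conservation": conservation,
                }
            )

        coverage = {
            pop: pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
            .sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            for pop, rows in cov_rows.items()
        }
        conservation_df = pd.DataFrame(
            cons_rows, columns=["chrom", "start", "end", "score"]
        ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        rrna_df = pd.DataFrame(self.layout.rrna, columns=["chrom", "start", "end"])
        self._lnc = LncSim(
            coverage=coverage,
            conservation=conservation_df,
            rrna=rrna_df,
            lnc_truth=pd.DataFrame(truth_rows),
            mapped_totals={"alpha": T, "beta": T},
            read_length=cfg.read_length,
        )
        return self._lnc

    # -- regulatory ---------------------------------------------------------

    def _block_map(self) -> BlockMap:
        """Whole-genome colinear map chrN -> hchrN, middle third inverted."""
        cfg = self.cfg
        blocks = []
        L = cfg.chrom_length
        third = L // 3
        for i in range(cfg.n_chroms):
            src, dst = f"chr{i + 1}", f"hchr{i + 1}"
            blocks.append(Block(src, 1, third, dst, 1, third, "+"))
            blocks.append(Block(src, third + 1, 2 * third, dst, third + 1, 2 * third, "-"))
            blocks.append(Block(src, 2 * third + 1, L, dst, 2 * third + 1, L, "+"))
        return BlockMap(blocks, src_genome="mouse", dst_genome="human")

    def regulatory(self) -> RegSim:
        if self._reg is not None:
            return self._reg
        cfg = self.cfg
        rng = self._rng_reg
        lnc = self.lnc_loci()
        truth = lnc.lnc_truth
        transcripts = truth[truth["label"] == "true_lnc"][
            ["lnc_id", "chrom", "start", "end"]
        ].reset_index(drop=True)
        bmap = self._block_map()
        chrom_sizes = self.layout.ann.chrom_sizes
        chroms = sorted(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)

        n_end = int(round(cfg.peak_end_fraction * cfg.n_peaks))
        rows = []
        placed: dict[str, list[tuple[int, int]]] = {}

        def clashes(chrom: str, s: int, e: int) -> bool:
            return any(s <= pe + 1000 and ps - 1000 <= e for ps, pe in placed.get(chrom, []))

        for i in range(cfg.n_peaks):
            width = int(rng.integers(200, 600))
            if i < n_end and len(transcripts):
                t = transcripts.iloc[int(rng.integers(0, len(transcripts)))]
                anchor = int(t["start"] if rng.random() < 0.5 else t["end"])
                center = anchor + int(rng.integers(-cfg.peak_window, cfg.peak_window + 1))
                chrom = str(t["chrom"])
                s = max(1, center - width // 2)
                e = min(chrom_sizes[chrom], s + width - 1)
            else:
                # background peaks keep clear of every placed peak so that
                # planted species read ratios survive region merging
                for _attempt in range(200):
                    ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
                    chrom = chroms[ci]
                    center = int(rng.integers(1, chrom_sizes[chrom]))
                    s = max(1, center - width // 2)
                    e = min(chrom_sizes[chrom], s + width - 1)
                    if not clashes(chrom, s, e):
                        break
                else:
                    raise ConfigError("could not place background peaks without overlap")
            placed.setdefault(chrom, []).append((s, e))
            reads = int(rng.integers(50, 500))
            rows.append((chrom, s, e, f"mpk{i:04d}", reads, i < n_end))

        n_sp = cfg.n_species_specific_peaks
        bg_indices = [i for i in range(cfg.n_peaks) if not rows[i][5]]
        if len(bg_indices) < 2 * n_sp:
            raise ConfigError("not enough background peaks for species-specific planting")
        sp_pick = rng.choice(bg_indices, size=2 * n_sp, replace=False)
        mouse_specific = set(sp_pick[:n_sp].tolist())
        human_specific = set(sp_pick[n_sp:].tolist())

        m_rows, h_rows, truth_rows = [], [], []
        for i, (chrom, s, e, name, reads, end_prox) in enumerate(rows):
            if i in mouse_specific:
                reads_m, reads_h = reads, max(1, int(round(reads / cfg.peak_species_ratio)))
                sp = "mouse_specific"
            elif i in human_specific:
                reads_m, reads_h = max(1, int(round(reads / cfg.peak_species_ratio))), reads
                sp = "human_specific"
            else:
                reads_m = reads
                reads_h = int(round(reads * rng.uniform(0.85, 1.18)))
                sp = "shared"
            m_rows.append((chrom, s, e, name, reads_m))
            mapped = ikio.convert_interval((chrom, s, e), bmap)
            h_rows.append((mapped.chrom, mapped.start, mapped.end,
                           name.replace("mpk", "hpk"), reads_h))
            truth_rows.append({"name": name, "end_proximal": bool(end_prox),
                               "species_label": sp})

        peaks_m = PeakSet(
            pd.DataFrame(m_rows, columns=ikio.PEAK_COLUMNS), tf_name="PDX1",
            genome_id="mouse",
        )
        peaks_h = PeakSet(
            pd.DataFrame(h_rows, columns=ikio.PEAK_COLUMNS), tf_name="PDX1",
            genome_id="human",
        )

        pwm = PWM.from_counts(
            "ETS1",
            np.array([
                [0.85 if b == c else 0.05 for c in ETS_CONSENSUS]
                for b in "ACGT"
            ]) * 100,
            pseudocount=0.0,
        )
        pwm.score_threshold = 0.8 * pwm.max_score
        seq, cluster_truth = self._cluster_sequence(rng)
        self._reg = RegSim(
            peaks_mouse=peaks_m,
            peaks_human=peaks_h,
            blockmap_m2h=bmap,
            sequences={"cluster_locus": seq},
            pwm=pwm,
            transcripts=transcripts,
            peak_truth=pd.DataFrame(truth_rows),
            cluster_truth=cluster_truth,
        )
        return self._reg

    def _cluster_sequence(self, rng: np.random.Generator) -> tuple[str, dict]:
        cfg = self.cfg
        n = cfg.cluster_seq_length
        seq = list("".join(rng.choice(list("ACGT"), size=n)))
        motif = ETS_CONSENSUS
        rc = motif.translate(_RC)[::-1]
        # scrub chance occurrences of the consensus on either strand
        text = "".join(seq)
        for pat in (motif, rc):
            start = 0
            while True:
                at = text.find(pat, start)
                if at < 0:
                    break
                mid = at + len(pat) // 2
                cur = text[mid]
                repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
                text = text[:mid] + repl + text[mid + 1:]
                start = at + 1
        seq = list(text)

        k = cfg.motif_cluster_sites
        win = cfg.motif_cluster_window
        ws = n // 2
        step = (win - len(motif)) // max(k - 1, 1)
        positions = [ws + j * step for j in range(k)]
        for j, p in enumerate(positions):
            site = motif if j % 2 == 0 else rc
            seq[p:p + len(motif)] = list(site)
        scattered = []
        p = 1000
        for _ in range(cfg.n_scattered_sites):
            if p + 600 >= ws - 1500:
                break
            seq[p:p + len(motif)] = list(motif)
            scattered.append(p)
            p += int(rng.integers(600, 1200))
        return "".join(seq), {
            "seq_name": "cluster_locus",
            "window_start": ws,
            "n_sites": k,
            "site_positions": positions,
            "scattered_positions": scattered,
        }

    # -- glucose response ---------------------------------------------------

    def glucose(self) -> GlucoseSim:
        if self._glucose is not None:
            return self._glucose
        cfg = self.cfg
        rng = self._rng_glucose
        counts = self.counts()
        lnc = self.lnc_loci()
        lnc_ids = lnc.lnc_truth.loc[lnc.lnc_truth["label"] == "true_lnc", "lnc_id"].tolist()
        gene_ids = list(counts.counts_mouse.index)
        universe = gene_ids + lnc_ids

        base = np.concatenate([
            counts.gene_truth["beta_mean"].to_numpy(),
            10 ** rng.uniform(0.7, 2.0, len(lnc_ids)),
        ])
        base = np.maximum(base, 0.5)
        up_lnc = min(cfg.planted_glucose_lnc, len(lnc_ids), cfg.planted_glucose_up)
        picked_lnc = rng.choice(lnc_ids, size=up_lnc, replace=False).tolist() if up_lnc else []
        eligible = [g for g in gene_ids
                    if counts.gene_truth.loc[g, "role"] == "plain"]
        picked_up_genes = rng.choice(
            eligible, size=cfg.planted_glucose_up - up_lnc, replace=False
        ).tolist()
        picked_down = rng.choice(
            [g for g in eligible if g not in picked_up_genes],
            size=cfg.planted_glucose_down, replace=False,
        ).tolist()
        up_set = set(picked_up_genes) | set(picked_lnc)
        down_set = set(picked_down)

        idx = pd.Index(universe)
        mean_low = base.copy()
        mean_high = base.copy()
        up_pos = idx.get_indexer(sorted(up_set))
        mean_high[up_pos] = np.maximum(mean_high[up_pos], 20.0) * cfg.glucose_fold
        mean_low[up_pos] = np.maximum(mean_low[up_pos], 20.0)
        down_pos = idx.get_indexer(sorted(down_set))
        mean_low[down_pos] = np.maximum(mean_low[down_pos], 20.0) * cfg.glucose_fold
        mean_high[down_pos] = np.maximum(mean_high[down_pos], 20.0)

        R = cfg.replicates_per_population
        def block(means):
            factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), R))
            return np.stack([_nb_draw(rng, means * f, cfg.nb_dispersion) for f in factors], axis=1)

        counts_low = pd.DataFrame(block(mean_low), index=idx,
                                  columns=[f"ctrl_{i + 1}" for i in range(R)])
        counts_high = pd.DataFrame(block(mean_high), index=idx,
                                   columns=[f"glc_{i + 1}" for i in range(R)])
        label = pd.Series("neutral", index=idx, dtype=object)
        label[sorted(up_set)] = "up"
        label[sorted(down_set)] = "down"
        truth = pd.DataFrame({"label": label, "is_lnc": idx.isin(lnc_ids)})
        self._glucose = GlucoseSim(
            counts_control=counts_low,
            counts_glucose=counts_high,
            truth=truth,
            lnc_ids=lnc_ids,
        )
        return self._glucose

    # -- fixture on disk ----------------------------------------------------

    def write_fixture(self, outdir) -> Path:
        """Write every input the pipeline reads, plus ground truth and manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.cfg
        counts = self.counts()
        lnc = self.lnc_loci()
        reg = self.regulatory()
        glc = self.glucose()

        ikio.write_annotation(counts.ann_mouse, out / "mouse.gtf")
        ikio.write_annotation(counts.ann_human, out / "human.gtf")
        ikio.write_chrom_sizes(counts.ann_mouse.chrom_sizes, out / "mouse.chrom.sizes")
        ikio.write_chrom_sizes(counts.ann_human.chrom_sizes, out / "human.chrom.sizes")
        ikio.write_counts(counts.counts_mouse, out / "counts_mouse.tsv")
        ikio.write_counts(counts.counts_human, out / "counts_human.tsv")
        ikio.write_orthologs(counts.orthologs, out / "orthologs.tsv")
        for pop, track in lnc.coverage.items():
            ikio.write_bedgraph(track, out / f"coverage_{pop}.bedgraph")
        ikio.write_bedgraph(lnc.conservation, out / "conservation.tsv")
        rrna = lnc.rrna.copy()
        rrna["name"] = [f"rRNA{i}" for i in range(len(rrna))]
        ikio.write_bed(rrna, out / "rrna.bed")
        ikio.write_peaks(reg.peaks_mouse, out / "peaks_mouse.tsv")
        ikio.write_peaks(reg.peaks_human, out / "peaks_human.tsv")
        ikio.write_block_map(reg.blockmap_m2h, out / "blockmap_mouse_to_human.tsv")
        ikio.write_fasta(reg.sequences, out / "cluster_locus.fa")
        from .regulatory import write_jaspar
        write_jaspar([reg.pwm], out / "motifs.jaspar")
        ikio.write_counts(glc.counts_control, out / "counts_glucose_low.tsv")
        ikio.write_counts(glc.counts_glucose, out / "counts_glucose_high.tsv")

        counts.gene_truth.sort_index().to_csv(out / "truth_genes.tsv", sep="\t",
                                              index_label="gene_id", float_format="%.6g")
        lnc.lnc_truth.to_csv(out / "truth_lnc.tsv", sep="\t", index=False,
                             float_format="%.6g")
        reg.peak_truth.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
        glc.truth.sort_index().to_csv(out / "truth_glucose.tsv", sep="\t",
                                      index_label="transcript_id")
        manifest = {
            "config": asdict(cfg),
            "sample_groups": counts.sample_groups,
            "coverage_mapped_totals": lnc.mapped_totals,
            "read_length": cfg.read_length,
            "cluster_truth": reg.cluster_truth,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return out


# ---------------------------------------------------------------------------
# convenience entry points
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimConfig) -> CountsSim:
    return Simulation(cfg).counts()


def simulate_lnc_loci(cfg: SimConfig) -> LncSim:
    return Simulation(cfg).lnc_loci()


def simulate_regulatory(cfg: SimConfig) -> RegSim:
    return Simulation(cfg).regulatory()


def simulate_fixture(cfg: SimConfig, outdir) -> Path:
    return Simulation(cfg).write_fixture(outdir)


def verify_ground_truth(sim: Simulation) -> list[str]:
    """Re-derive planted labels from the emitted data; list inconsistencies.

    Structural plantings are checked exactly (decoy geometry, rRNA and
    exon overlaps, conservation, peak read ratios, cluster positions,
    absence of the species-unique genes in the other species); mean-level
    plantings are checked against the stored generating means.
    """
    problems: list[str] = []
    cfg = sim.cfg
    counts = sim.counts()
    truth = counts.gene_truth

    for g, row in truth.iterrows():
        if row["species_label"] == "mouse_unique":
            hid = row["human_id"]
            if hid and counts.counts_human.loc[hid, counts.sample_groups["human_beta"]].sum() != 0:
                problems.append(f"{g}: mouse_unique but human beta counts nonzero")
        if row["population_label"] == "beta_enriched":
            if not row["beta_mean"] >= cfg.enrichment_fold * row["alpha_mean"] - 1e-9:
                problems.append(f"{g}: beta_enriched mean ratio below fold")
        if row["population_label"] == "alpha_enriched":
            if not row["alpha_mean"] >= cfg.enrichment_fold * row["beta_mean"] - 1e-9:
                problems.append(f"{g}: alpha_enriched mean ratio below fold")

    lnc = sim.lnc_loci()
    ann = sim.layout.ann
    exon_idx = ann.exon_index()
    rrna_idx = [(c, int(s), int(e))
                for c, s, e in lnc.rrna[["chrom", "start", "end"]].itertuples(index=False)]
    for row in lnc.lnc_truth.itertuples(index=False):
        length = row.end - row.start + 1
        label = row.label
        exonic = exon_idx.overlaps_any(row.chrom, row.start, row.end)
        rrna_hit = any(c == row.chrom and overlap_length((row.start, row.end), (s, e)) > 0
                       for c, s, e in rrna_idx)
        checks = {
            "exon_overlap": exonic,
            "short": length <= 3000,
            "low_rpkm": max(row.beta_rpkm, row.alpha_rpkm) <= 1.0,
            "rrna": rrna_hit,
            "conserved": row.conservation > 0.4,
        }
        if label == "true_lnc":
            if any(checks.values()):
                bad = [k for k, v in checks.items() if v]
                problems.append(f"{row.lnc_id}: true lncRNA violates {bad}")
        else:
            rule = label.split(":", 1)[1]
            expected = {k: (k == rule) for k in checks}
            if checks != expected:
                problems.append(f"{row.lnc_id}: decoy violates {sorted(k for k, v in checks.items() if v)}, wanted [{rule}]")

    reg = sim.regulatory()
    tm = reg.peaks_mouse.total_reads
    th = reg.peaks_human.total_reads
    m = reg.peaks_mouse.peaks.set_index("name")["reads"]
    h = reg.peaks_human.peaks.set_index("name")["reads"]
    for row in reg.peak_truth.itertuples(index=False):
        rm = m[row.name] / tm * 1e6
        rh = h[row.name.replace("mpk", "hpk")] / th * 1e6
        ratio = (rm + 1) / (rh + 1)
        if row.species_label == "mouse_specific" and ratio < 4:
            problems.append(f"{row.name}: planted mouse-specific ratio {ratio:.2f} < 4")
        if row.species_label == "human_specific" and 1 / ratio < 4:
            problems.append(f"{row.name}: planted human-specific ratio {1/ratio:.2f} < 4")

    ct = reg.cluster_truth
    span = max(ct["site_positions"]) + len(ETS_CONSENSUS) - min(ct["site_positions"])
    if span > cfg.motif_cluster_window:
        problems.append(f"cluster span {span} exceeds window {cfg.motif_cluster_window}")
    seq = reg.sequences[ct["seq_name"]]
    rc = ETS_CONSENSUS.translate(_RC)[::-1]
    for p in ct["site_positions"]:
        if seq[p:p + len(ETS_CONSENSUS)] not in (ETS_CONSENSUS, rc):
            problems.append(f"cluster site at {p} not a consensus occurrence")
    return problems
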