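"""Seeded synthetic bloom datasets with planted colonizer/generalist structure.

The generator emulates the derived tables a spring-bloom time series study
produces upstream of this pipeline: diatom cell counts with rotating
dominant species, MAG read-recruitment counts, per-MAG gene content and
GFF3 annotations (including contiguous tad loci), and a metaproteome
evidence chain (spectral counts, pairwise hits, KO annotations).  Every
output is a deterministic function of the :class:`SimConfig` seed, and the
planted ground truth (niche labels, host couplings, discriminating
features, protein origins) is returned alongside so recovery can be scored.

Model sketch
------------
* Diatom blooms are Gaussian curves in time on the count scale; each year
  one or two species dominate, and dominance rotates across years.
* Generalist MAGs have a persistent lognormal abundance baseline;
  colonizer MAGs follow an affine function of their host diatom's counts.
  Per-sample read counts are multinomial over MAGs (probability ∝ latent
  abundance × genome length) at a fixed per-sample depth.  At
  ``noise_sd = 0`` the generator returns exact expectations (the zero-noise
  limit is fully deterministic).
* Tad loci are planted as contiguous 14-gene blocks (single contig,
  inter-gene gaps < 2 kb) in a configured fraction of each niche group;
  quorum-sensing, chemotaxis, motility and ~200 background features carry
  group-specific Bernoulli presence rates.
* Protein spectral counts are Poisson with rates proportional to the source
  MAG's relative abundance; transport emission is weighted so that the
  expected generalist share of transport %NSAF equals the configured value.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from .abundance import RecruitmentTable
from .enrichment import GeneContentMatrix
from .io import (BLAST6_COLUMNS, write_gff3, write_hits, write_tsv)
from .niche import DiatomCountTable, flag_dominants
from .proteome import SpectralCounts, load_ko_flags
from .tadlocus import CANONICAL_GENES, SYNONYMS, GeneAnnotationTable

logger = logging.getLogger(__name__)

_DIATOM_NAMES = [
    "Thalassiosira_nordenskioeldii", "Mediopyxis_helysia",
    "Chaetoceros_debilis", "Skeletonema_costatum",
    "Thalassionema_nitzschioides", "Rhizosolenia_setigera",
    "Ditylum_brightwellii", "Guinardia_delicatula",
]

_BRITE_CATEGORIES = {
    "transport": "Transporters",
    "ribosome": "Ribosome",
    "glycolysis": "Glycolysis / Gluconeogenesis",
    "tca": "Citrate cycle (TCA cycle)",
    "rnap": "RNA polymerase",
    "chaperone": "Chaperones and folding catalysts",
    "oxphos": "Oxidative phosphorylation",
    "amino": "Amino acid related enzymes",
    "twocomp": "Two-component system",
    "porphyrin": "Porphyrin and chlorophyll metabolism",
    "flagellar": "Bacterial motility proteins",
}

#: (category key, proteins per MAG)
_PROTEINS_PER_MAG = [
    ("transport", 5), ("ribosome", 4), ("glycolysis", 3), ("tca", 3),
    ("rnap", 2), ("chaperone", 2), ("oxphos", 2), ("amino", 2),
    ("twocomp", 1), ("porphyrin", 1),
]


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic bloom dataset.

    Defaults mirror the real study's scale: 38 samples over three spring
    blooms, 8 diatom species, 19 generalist + 14 colonizer MAGs, a tad
    locus in 12/14 colonizers and 2/19 generalists, luxI in 71.4% of
    colonizers vs 31.6% of generalists, and ~85% of transport protein
    expression from generalists.
    """

    seed: int
    n_years: int = 3
    samples_per_year: int = 13
    total_samples: int | None = 38       # 38 → 13+13+12 over three years
    n_diatoms: int = 8
    n_generalists: int = 19
    n_colonizers: int = 14
    depth_mean: int = 2_000_000
    noise_sd: float = 0.3
    tad_prevalence_colonizers: float = 0.857
    tad_prevalence_generalists: float = 0.105
    luxI_prevalence_colonizers: float = 0.714
    luxI_prevalence_generalists: float = 0.316
    generalist_transport_share: float = 0.85
    decoy_rate: float = 0.15             # low-identity extra hits
    ambiguous_rate: float = 0.03         # second passing hit → planted ambiguity

    def __post_init__(self) -> None:
        for name in ("tad_prevalence_colonizers", "tad_prevalence_generalists",
                     "luxI_prevalence_colonizers",
                     "luxI_prevalence_generalists",
                     "generalist_transport_share", "decoy_rate",
                     "ambiguous_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_years", "samples_per_year", "n_diatoms",
                     "n_generalists", "n_colonizers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def years(self) -> list[int]:
        return [2010 + i for i in range(self.n_years)]

    @property
    def samples_by_year(self) -> dict[int, int]:
        total = self.total_samples
        if total is None:
            total = self.n_years * self.samples_per_year
        base, rem = divmod(total, self.n_years)
        return {y: base + (1 if i < rem else 0)
                for i, y in enumerate(self.years)}


def _rng(cfg: SimConfig, label: str) -> np.random.Generator:
    """Per-operation child stream: reproducible regardless of call order."""
    return np.random.default_rng([cfg.seed, zlib.crc32(label.encode())])


@dataclass
class GroundTruth:
    """Planted structure: labels, host couplings, features, protein origins."""

    labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    hosts: dict[str, list[str]] = field(default_factory=dict)
    planted_gene_set: set[str] = field(default_factory=set)
    protein_mag: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"colonizer", "generalist"}
        if len(self.labels) and bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def colonizers(self) -> list[str]:
        return self.labels.index[self.labels == "colonizer"].tolist()

    @property
    def generalists(self) -> list[str]:
        return self.labels.index[self.labels == "generalist"].tolist()


# ---------------------------------------------------------------------------
# diatoms


def simulate_diatoms(cfg: SimConfig) -> DiatomCountTable:
    """Species × sample diatom cell counts with rotating yearly dominance."""
    rng = _rng(cfg, "diatoms")
    species = list(_DIATOM_NAMES[:cfg.n_diatoms])
    for i in range(len(species), cfg.n_diatoms):
        species.append(f"Diatom_sp_{i + 1}")

    sample_ids, sample_year = [], []
    for year, n_w in cfg.samples_by_year.items():
        for w in range(1, n_w + 1):
            sample_ids.append(f"{year}-{w:02d}")
            sample_year.append(year)
    sample_year = pd.Series(sample_year, index=pd.Index(sample_ids),
                            name="year")

    counts = np.zeros((cfg.n_diatoms, len(sample_ids)))
    ptr = 0
    col_offset = 0
    for year, n_w in cfg.samples_by_year.items():
        weeks = np.arange(1, n_w + 1)
        n_dom = int(rng.integers(1, 3)) if cfg.n_diatoms > 1 else 1
        dom_idx = [(ptr + i) % cfg.n_diatoms for i in range(n_dom)]
        ptr += n_dom
        peak0 = int(rng.integers(max(n_w // 3, 1), max(2 * n_w // 3, 2)))
        for s in range(cfg.n_diatoms):
            if s in dom_idx:
                amp = 10 ** rng.normal(5.7, 0.15)
                mu = peak0 if s == dom_idx[0] else \
                    min(n_w - 1, peak0 + int(rng.integers(2, 5)))
            else:
                amp = 10 ** rng.normal(4.0, 0.3)
                mu = float(rng.uniform(1, n_w))
            sigma = float(rng.uniform(1.5, 3.0))
            curve = amp * np.exp(-0.5 * ((weeks - mu) / sigma) ** 2)
            noise = (np.exp(rng.normal(0.0, cfg.noise_sd, size=n_w))
                     if cfg.noise_sd > 0 else 1.0)
            counts[s, col_offset:col_offset + n_w] = curve * noise
        col_offset += n_w

    df = pd.DataFrame(counts, index=pd.Index(species, name="species_id"),
                      columns=sample_ids)
    dom = flag_dominants(df, sample_year)
    return DiatomCountTable(counts=df, sample_year=sample_year, dominants=dom)


# ---------------------------------------------------------------------------
# recruitment


def _bloom_phases(chl: pd.Series, sample_year: pd.Series) -> pd.Series:
    """pre/mid/post per sample from a chlorophyll-like bloom proxy."""
    phases = pd.Series("mid", index=chl.index, name="bloom_phase")
    for year in sorted(sample_year.unique()):
        cols = sample_year.index[sample_year == year]
        sub = chl[cols]
        cutoff = 0.5 * sub.max()
        high = np.flatnonzero(sub.to_numpy() >= cutoff)
        first, last = int(high[0]), int(high[-1])
        for i, sid in enumerate(cols):
            phases[sid] = "pre" if i < first else \
                ("post" if i > last else "mid")
    return phases


def simulate_recruitment(cfg: SimConfig, diatoms: DiatomCountTable
                         ) -> tuple[RecruitmentTable, GroundTruth]:
    """Multinomial read recruitment over planted generalists and colonizers."""
    rng = _rng(cfg, "recruitment")
    n_mags = cfg.n_generalists + cfg.n_colonizers
    mags = [f"MAG_{i + 1:03d}" for i in range(n_mags)]
    label_arr = np.array(["generalist"] * cfg.n_generalists
                         + ["colonizer"] * cfg.n_colonizers)
    rng.shuffle(label_arr)
    labels = pd.Series(label_arr, index=pd.Index(mags, name="mag_id"),
                       name="true_label")
    lengths = pd.Series(rng.integers(2_000_000, 5_000_001, size=n_mags),
                        index=mags, name="length_bp")

    # host assignment: colonizers round-robin over dominant species
    dominant_pool: list[str] = []
    for year in sorted(diatoms.dominants):
        for sp in diatoms.dominants[year]:
            if sp not in dominant_pool:
                dominant_pool.append(sp)
    if not dominant_pool:
        dominant_pool = list(diatoms.species[:1])
    colonizers = labels.index[labels == "colonizer"].tolist()
    hosts = {mag: [dominant_pool[i % len(dominant_pool)]]
             for i, mag in enumerate(colonizers)}

    samples = diatoms.counts.columns
    n_s = len(samples)
    latent = np.zeros((n_mags, n_s))
    host_norm = diatoms.counts.div(diatoms.counts.max(axis=1), axis=0)
    for i, mag in enumerate(mags):
        noise = (np.exp(rng.normal(0.0, cfg.noise_sd, size=n_s))
                 if cfg.noise_sd > 0 else 1.0)
        if labels[mag] == "generalist":
            base = float(np.exp(rng.normal(np.log(2.0), 0.35)))
            latent[i] = base * noise
        else:
            gain = float(np.exp(rng.normal(0.0, 0.3)))
            h = host_norm.loc[hosts[mag][0]].to_numpy()
            latent[i] = (0.02 + gain * h) * noise

    weights = latent * lengths.to_numpy()[:, None]
    probs = weights / weights.sum(axis=0, keepdims=True)
    if cfg.depth_mean == 0:
        logger.warning("depth_mean=0: all recruitment counts are zero")
        counts = np.zeros((n_mags, n_s))
    elif cfg.noise_sd == 0:
        # zero-noise limit: exact expected reads, fully deterministic
        counts = probs * cfg.depth_mean
    else:
        counts = np.zeros((n_mags, n_s), dtype=np.int64)
        for j in range(n_s):
            counts[:, j] = rng.multinomial(cfg.depth_mean, probs[:, j])

    count_df = pd.DataFrame(counts, index=pd.Index(mags, name="mag_id"),
                            columns=samples)
    totals = count_df.sum(axis=0)
    totals[totals == 0] = max(cfg.depth_mean, 1)  # degenerate depth-0 case

    chl = diatoms.counts.sum(axis=0) / 2e5  # µg/L-scale bloom proxy
    meta = pd.DataFrame({
        "date": [f"{s.split('-')[0]}-03-01" for s in samples],
        "year": diatoms.sample_year[samples].to_numpy(),
        "bloom_phase": _bloom_phases(chl, diatoms.sample_year),
        "chlorophyll_a": chl,
    }, index=pd.Index(samples, name="sample_id"))
    # weekly dates within each year
    dates = []
    for s in samples:
        year, week = s.split("-")
        day = pd.Timestamp(f"{year}-03-01") + pd.Timedelta(days=7 * (int(week) - 1))
        dates.append(day.date().isoformat())
    meta["date"] = dates

    recr = RecruitmentTable(counts=count_df, lengths=lengths, totals=totals,
                            samples=meta)
    truth = GroundTruth(labels=labels, hosts=hosts)
    return recr, truth


# ---------------------------------------------------------------------------
# gene content + annotations


def _exact_carriers(rng: np.random.Generator, members: list[str],
                    prevalence: float) -> list[str]:
    """Pick round(prevalence × n) members uniformly without replacement."""
    k = int(round(prevalence * len(members)))
    k = min(k, len(members))
    idx = rng.choice(len(members), size=k, replace=False)
    return [members[i] for i in sorted(idx)]


_CHE_GENES = ["cheA", "cheB", "cheR", "cheW", "cheY"]
_MOT_GENES = ["flaA", "flgB", "flgK", "fliC", "fliM", "motA", "motB"]


def simulate_gene_content(cfg: SimConfig, truth: GroundTruth,
                          near_complete: dict[str, str] | None = None
                          ) -> tuple[GeneContentMatrix, GeneAnnotationTable]:
    """Plant tad blocks, QS/chemotaxis/motility genes and background COGs.

    ``near_complete`` maps MAG → one canonical tad gene to delete from that
    MAG's planted block (the "missing one gene" open-circle case).
    """
    rng = _rng(cfg, "gene_content")
    near_complete = near_complete or {}
    mags = truth.labels.index.tolist()
    col = truth.colonizers
    gen = truth.generalists

    tad_carriers = set(_exact_carriers(rng, col, cfg.tad_prevalence_colonizers)) \
        | set(_exact_carriers(rng, gen, cfg.tad_prevalence_generalists))
    luxI_carriers = set(_exact_carriers(rng, col, cfg.luxI_prevalence_colonizers)) \
        | set(_exact_carriers(rng, gen, cfg.luxI_prevalence_generalists))

    tad_features = [f"COG_{g}" for g in CANONICAL_GENES]
    core_features = [f"COG{i:04d}" for i in range(1, 236)]
    bg_features = [f"COG{i:04d}" for i in range(1001, 1201)]
    che_features = [f"COG_{g}" for g in _CHE_GENES]
    mot_features = [f"COG_{g}" for g in _MOT_GENES]
    features = (tad_features + ["COG_luxI", "COG_luxR"] + che_features
                + mot_features + core_features + bg_features)
    counts = pd.DataFrame(0, index=pd.Index(mags, name="mag_id"),
                          columns=pd.Index(features, name="feature_id"))

    counts[core_features] = 1
    bg_rates = rng.uniform(0.15, 0.85, size=len(bg_features))
    for f, rate in zip(bg_features, bg_rates):
        counts[f] = (rng.random(len(mags)) < rate).astype(int)

    che_rate = {"colonizer": 0.85, "generalist": 0.55}
    mot_rate = {"colonizer": 0.95, "generalist": 0.95}
    luxR_rate = 0.8

    anno_tables: dict[str, pd.DataFrame] = {}
    lengths_proxy = {}
    for mag in mags:
        lab = truth.labels[mag]
        rows = []
        # tad block: contiguous, single contig, gaps < 2 kb
        tad_genes_here: list[str] = []
        if mag in tad_carriers:
            tad_genes_here = [g for g in CANONICAL_GENES
                              if g != near_complete.get(mag)]
            use_cpa = bool(rng.random() < 0.5)
            pos = 10_000
            for g in tad_genes_here:
                glen = int(rng.integers(300, 2500))
                gap = int(rng.integers(50, 1900))
                symbol = g
                if use_cpa:
                    for syn, canon in SYNONYMS.items():
                        if canon == g:
                            symbol = syn
                            break
                product = f"Flp pilus assembly protein {g[0].upper()}{g[1:]}"
                rows.append(("ctg001", pos, pos + glen - 1, "+",
                             f"{mag}_tad_{g}", symbol, product))
                pos += glen + gap
        for f, g in zip(tad_features, CANONICAL_GENES):
            counts.loc[mag, f] = int(g in tad_genes_here)

        pos = 5_000
        if mag in luxI_carriers:
            counts.loc[mag, "COG_luxI"] = 1
            rows.append(("ctg002", pos, pos + 600, "+", f"{mag}_luxI",
                         "luxI", "Acyl-homoserine-lactone synthase LuxI"))
            pos += 2_000
        if rng.random() < luxR_rate:
            n_luxr = 1 + int(rng.poisson(1.2))
            counts.loc[mag, "COG_luxR"] = n_luxr
            for i in range(n_luxr):
                rows.append(("ctg002", pos, pos + 700, "-",
                             f"{mag}_luxR_{i + 1}", "luxR",
                             "Transcriptional regulator LuxR"))
                pos += 1_500
        for g, f in zip(_CHE_GENES, che_features):
            if rng.random() < che_rate[lab]:
                counts.loc[mag, f] = 1
                rows.append(("ctg003", pos, pos + 900, "+", f"{mag}_{g}", g,
                             f"Chemotaxis protein {g[0].upper()}{g[1:]}"))
                pos += 1_200
        for g, f in zip(_MOT_GENES, mot_features):
            if rng.random() < mot_rate[lab]:
                counts.loc[mag, f] = 1
                rows.append(("ctg004", pos, pos + 1_000, "+", f"{mag}_{g}", g,
                             f"Flagellar protein {g[0].upper()}{g[1:]}"))
                pos += 1_400
        # anonymous background annotations
        for i in range(int(rng.integers(20, 40))):
            start = 5_000 + 1_500 * i
            rows.append(("ctg005", start, start + 1_000,
                         "+" if rng.random() < 0.5 else "-",
                         f"{mag}_hyp_{i + 1}", "", "hypothetical protein"))
        anno_tables[mag] = pd.DataFrame(
            rows, columns=["contig_id", "start", "end", "strand", "gene_id",
                           "gene_symbol", "product"])
        lengths_proxy[mag] = None

    cds = pd.Series({mag: int(rng.integers(1_800, 4_500)) for mag in mags},
                    name="cds_count")
    truth.planted_gene_set = set(tad_features)
    gcm = GeneContentMatrix(counts, kind="COG", groups=truth.labels)
    anno = GeneAnnotationTable(tables=anno_tables, cds_counts=cds)
    return gcm, anno


# ---------------------------------------------------------------------------
# proteome


def _pick_proteome_samples(recr: RecruitmentTable, n_target: int = 10
                           ) -> list[str]:
    """Roughly one sample per (year, phase), topped up to ``n_target``."""
    meta = recr.samples
    chosen: list[str] = []
    for (year, phase), grp in meta.groupby(["year", "bloom_phase"],
                                           sort=True):
        ids = grp.index.tolist()
        chosen.append(ids[len(ids) // 2])
    extras = [s for s in meta.index if s not in chosen]
    for s in extras:
        if len(chosen) >= n_target:
            break
        chosen.append(s)
    chosen = chosen[:n_target]
    return [s for s in meta.index if s in chosen]


def simulate_proteome(cfg: SimConfig, truth: GroundTruth,
                      recr: RecruitmentTable
                      ) -> tuple[SpectralCounts, pd.DataFrame, pd.DataFrame]:
    """Spectral counts, pairwise hit table and KO annotations per protein."""
    rng = _rng(cfg, "proteome")
    mags = truth.labels.index.tolist()
    psamples = _pick_proteome_samples(recr)
    rel = ab.relative_abundance(ab.compute_rpkm(recr)).values[psamples]

    ko_flags = load_ko_flags()
    transport_kos = sorted(k for k, v in ko_flags.items() if "transport" in v)
    cobalamin_kos = sorted(k for k, v in ko_flags.items()
                           if "cobalamin_biosynthesis" in v)
    generic_ko_pool = [f"K{30_000 + i:05d}" for i in range(200)]

    w = rel.mean(axis=1)
    G = float(w[truth.generalists].sum())
    C = float(w[truth.colonizers].sum())
    alpha = cfg.generalist_transport_share
    if C > 0 and G > 0 and 0 < alpha < 1:
        kappa = (G * (1 - alpha)) / (alpha * C)
    else:
        kappa = 1.0

    proteins, rate_rows, anno_rows, true_mag = [], [], [], []
    pid = 0

    def add_protein(mag: str, ko: str | None, brite: str,
                    cat_weight: float) -> None:
        nonlocal pid
        pid += 1
        name = f"P{pid:05d}"
        base = float(np.exp(rng.normal(0.0, 0.6)))
        proteins.append(name)
        rate_rows.append(base * cat_weight
                         * rel.loc[mag].to_numpy(dtype=float))
        anno_rows.append((name, ko, brite))
        true_mag.append(mag)

    cobalamin_mags = list(rng.choice(mags, size=min(4, len(mags)),
                                     replace=False))
    flagellar_mags = [m for m in truth.generalists if rng.random() < 0.2]

    for mag in mags:
        is_col = truth.labels[mag] == "colonizer"
        for cat, n in _PROTEINS_PER_MAG:
            for _ in range(n):
                if cat == "transport":
                    ko = transport_kos[int(rng.integers(len(transport_kos)))]
                    weight = 3.0 * (kappa if is_col else 1.0)
                else:
                    ko = generic_ko_pool[int(rng.integers(len(generic_ko_pool)))]
                    weight = 1.0
                add_protein(mag, ko, _BRITE_CATEGORIES[cat], weight)
    for mag in cobalamin_mags:
        ko = cobalamin_kos[int(rng.integers(len(cobalamin_kos)))]
        add_protein(mag, ko, _BRITE_CATEGORIES["porphyrin"], 0.5)
    for mag in flagellar_mags:
        add_protein(mag, "K02406", _BRITE_CATEGORIES["flagellar"], 0.3)

    rates = np.vstack(rate_rows)
    scale = 3_000.0 * len(psamples) / max(rates.sum(), 1e-12)
    lam = rates * scale
    spc = rng.poisson(lam).astype(np.int64)
    lengths = pd.Series(rng.integers(100, 801, size=len(proteins)),
                        index=pd.Index(proteins, name="protein_id"),
                        name="length_aa")
    sc = SpectralCounts(
        counts=pd.DataFrame(spc, index=pd.Index(proteins, name="protein_id"),
                            columns=psamples),
        lengths=lengths)

    # KO dropout (~10%), never for the scarce cobalamin markers
    anno_df = pd.DataFrame(anno_rows,
                           columns=["protein_id", "ko_id", "brite"]
                           ).set_index("protein_id")
    protected = anno_df["ko_id"].isin(cobalamin_kos)
    drop = (rng.random(len(anno_df)) < 0.10) & ~protected.to_numpy()
    anno_df.loc[drop, ["ko_id", "brite"]] = [np.nan, ""]

    hit_rows = []
    other = {m: [x for x in mags if x != m] for m in mags}
    for name, mag, length in zip(proteins, true_mag, lengths.to_numpy()):
        aln = int(length)
        evalue = 10.0 ** -float(rng.uniform(31, 50))
        hit_rows.append((name, f"{mag}|ctg001",
                         round(float(rng.uniform(99.2, 100.0)), 2), aln,
                         int(rng.integers(0, 3)), 0, 1, aln, 1, aln,
                         evalue, round(2.0 * aln, 1)))
        r = rng.random()
        if r < cfg.ambiguous_rate and other[mag]:
            decoy = other[mag][int(rng.integers(len(other[mag])))]
            hit_rows.append((name, f"{decoy}|ctg001",
                             round(float(rng.uniform(99.1, 99.9)), 2), aln,
                             int(rng.integers(0, 3)), 0, 1, aln, 1, aln,
                             1e-20, round(1.9 * aln, 1)))
        elif r < cfg.ambiguous_rate + cfg.decoy_rate and other[mag]:
            decoy = other[mag][int(rng.integers(len(other[mag])))]
            hit_rows.append((name, f"{decoy}|ctg002",
                             round(float(rng.uniform(85.0, 98.0)), 2), aln,
                             int(rng.integers(3, 30)), 1, 1, aln, 1, aln,
                             10.0 ** -float(rng.uniform(11, 25)),
                             round(1.5 * aln, 1)))
    hits = pd.DataFrame(hit_rows, columns=BLAST6_COLUMNS)

    truth.protein_mag = pd.Series(true_mag,
                                  index=pd.Index(proteins,
                                                 name="protein_id"),
                                  name="true_mag_id")
    return sc, hits, anno_df


# ---------------------------------------------------------------------------
# dataset assembly and writing


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    diatoms: DiatomCountTable
    recruitment: RecruitmentTable
    truth: GroundTruth
    gene_content: GeneContentMatrix
    annotations: GeneAnnotationTable
    spectral_counts: SpectralCounts
    hits: pd.DataFrame
    protein_anno: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = [f"seed={self.cfg.seed}"]
        write_tsv(self.diatoms.counts, outdir / "diatoms.tsv", comments=tag)
        write_tsv(self.recruitment.counts, outdir / "recruitment.tsv",
                  comments=tag)
        completeness = pd.Series(
            {m: (88.0 if self.truth.labels[m] == "colonizer" else 91.0)
             for m in self.truth.labels.index}, name="completeness")
        meta = pd.DataFrame({
            "length_bp": self.recruitment.lengths,
            "cds_count": self.annotations.cds_counts,
            "completeness": completeness,
            "taxon": "Rhodobacterales",
        })
        meta.index.name = "mag_id"
        write_tsv(meta, outdir / "mag_meta.tsv", comments=tag)
        write_tsv(self.recruitment.samples, outdir / "samples.tsv",
                  comments=tag)
        write_tsv(self.gene_content.counts, outdir / "gene_content.tsv",
                  comments=tag)
        for mag, table in self.annotations.tables.items():
            write_gff3(table, outdir / "annotations" / f"{mag}.gff3",
                       comments=tag)
        spc = self.spectral_counts.counts.copy()
        spc.insert(0, "length_aa", self.spectral_counts.lengths)
        write_tsv(spc, outdir / "spectral_counts.tsv", comments=tag)
        write_hits(self.hits, outdir / "hits.tsv", comments=tag)
        write_tsv(self.protein_anno, outdir / "protein_anno.tsv",
                  comments=tag)
        truth_df = pd.DataFrame({
            "true_label": self.truth.labels,
            "host_diatoms": pd.Series(
                {m: ",".join(v) for m, v in self.truth.hosts.items()}
            ).reindex(self.truth.labels.index, fill_value=""),
        })
        truth_df.index.name = "mag_id"
        write_tsv(truth_df, outdir / "truth.tsv",
                  comments=tag + ["planted_gene_set="
                                  + ",".join(sorted(self.truth.planted_gene_set))])
        write_tsv(self.truth.protein_mag.to_frame(),
                  outdir / "truth_proteins.tsv", comments=tag)


def generate_dataset(cfg: SimConfig,
                     near_complete: dict[str, str] | None = None
                     ) -> SimulatedDataset:
    """Run every simulator in order and bundle the outputs."""
    diatoms = simulate_diatoms(cfg)
    recr, truth = simulate_recruitment(cfg, diatoms)
    gcm, anno = simulate_gene_content(cfg, truth, near_complete=near_complete)
    sc, hits, panno = simulate_proteome(cfg, truth, recr)
    return SimulatedDataset(cfg=cfg, diatoms=diatoms, recruitment=recr,
                            truth=truth, gene_content=gcm, annotations=anno,
                            spectral_counts=sc, hits=hits, protein_anno=panno)
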