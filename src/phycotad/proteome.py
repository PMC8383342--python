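"""Metaproteome evidence: protein→MAG assignment, %NSAF, category summaries.

Proteins identified in the metaproteome are tied back to MAGs through a
pairwise hit table (12-column tabular format).  Hits are filtered at
percent identity > 99 and e-value < 1e-10 (both strict), and any protein
whose passing hits touch two or more distinct MAGs is excluded outright so
that no protein inflates the abundance of a MAG it may not belong to.

Semiquantitative abundance uses the percent normalized spectral abundance
factor: per sample, ``%NSAF_i = 100 · (SpC_i/L_i) / Σ_j (SpC_j/L_j)`` where
``SpC`` is the spectral count and ``L`` the protein length in amino acids.

Functional context comes from KO annotations binned into BRITE-style
categories, with a shipped (editable) KO→flag map marking transport,
cobalamin-transport, cobalamin-biosynthesis, flagellar and Flp-pilus
proteins.  Only the last enzymes of the cobalamin pathway (adenosyl-
transferase MMAB/pduO, CobW) count as biosynthesis markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import read_hits, read_tsv, write_tsv
from .niche import NicheLabels

logger = logging.getLogger(__name__)

FLAG_NAMES = ("transport", "cobalamin_transport", "cobalamin_biosynthesis",
              "flagellar", "flp_pilus")


def load_ko_flags(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the KO → functional-flag map (shipped TSV, user-overridable)."""
    if path is None:
        ref = resources.files("phycotad.resources") / "ko_flags.tsv"
        with resources.as_file(ref) as p:
            df = read_tsv(p, index_col=None)
    else:
        df = read_tsv(path, index_col=None)
    out: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        flags = frozenset(f.strip() for f in str(row.flags).split(",")
                          if f.strip())
        unknown = flags - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)} for {row.ko_id}")
        out[row.ko_id] = flags
    return out


@dataclass
class SpectralCounts:
    """Protein × sample spectral counts with protein lengths (aa)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        lens = self.lengths.reindex(self.counts.index)
        if lens.isna().any():
            raise KeyError(
                f"missing length for {lens[lens.isna()].index.tolist()}")
        if (lens <= 0).any():
            raise ValueError("non-positive protein length")


@dataclass
class NSAFTable:
    """Per-sample %NSAF values plus the protein→MAG assignment."""

    values: pd.DataFrame              # protein × sample, percent
    assigned_mag: pd.Series           # protein -> mag (may be partial)
    flagged_samples: list = field(default_factory=list)


@dataclass
class ProteinAnnotationTable:
    """protein → KO id (optional) and BRITE categories.

    Functional flags are derived from the KO→flag map, never stored.
    """

    table: pd.DataFrame               # columns: ko_id, brite
    ko_flags: dict[str, frozenset[str]] = field(default_factory=load_ko_flags)

    def categories(self, protein: str) -> set[str]:
        val = self.table.loc[protein, "brite"]
        if pd.isna(val) or not str(val):
            return set()
        return {c.strip() for c in str(val).split(";") if c.strip()}

    def flags(self, protein: str) -> frozenset[str]:
        ko = self.table.loc[protein, "ko_id"]
        if pd.isna(ko):
            return frozenset()
        return self.ko_flags.get(str(ko), frozenset())

    def proteins_with_flag(self, flag: str) -> list[str]:
        if flag not in FLAG_NAMES:
            raise ValueError(f"unknown flag {flag!r}")
        flagged_kos = {k for k, v in self.ko_flags.items() if flag in v}
        mask = self.table["ko_id"].isin(flagged_kos)
        return self.table.index[mask].tolist()


class HitAssignment(NamedTuple):
    assignments: pd.Series            # protein -> mag, unambiguous only
    ambiguous: list[str]              # passing hits to >=2 distinct MAGs
    unassigned: list[str]             # no passing hit at all


def _subject_mag(sseqid: str) -> str:
    """MAG id of a subject; contig-qualified subjects use 'mag|contig'."""
    return str(sseqid).split("|", 1)[0]


def filter_hits(hits: pd.DataFrame, identity_min: float = 99.0,
                evalue_max: float = 1e-10) -> HitAssignment:
    """One-to-one-or-none protein→MAG assignment from a pairwise hit table.

    Keeps rows with identity strictly above ``identity_min`` and e-value
    strictly below ``evalue_max``; proteins whose surviving hits touch two
    or more distinct MAGs are excluded and logged.  Hits to multiple
    contigs of the same MAG are fine.
    """
    if (hits["pident"] < 0).any() or (hits["pident"] > 100).any():
        raise ValueError("percent identity outside [0, 100]")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-value")
    passing = hits[(hits["pident"] > identity_min)
                   & (hits["evalue"] < evalue_max)]
    mags = passing["sseqid"].map(_subject_mag)
    per_protein = mags.groupby(passing["qseqid"]).agg(set)
    assignments = {}
    ambiguous = []
    for protein, magset in per_protein.items():
        if len(magset) == 1:
            assignments[protein] = next(iter(magset))
        else:
            ambiguous.append(protein)
    if ambiguous:
        logger.info("excluded %d proteins with passing hits to multiple "
                    "MAGs: %s", len(ambiguous), sorted(ambiguous)[:10])
    all_proteins = set(hits["qseqid"])
    unassigned = sorted(all_proteins - set(assignments) - set(ambiguous))
    return HitAssignment(
        pd.Series(assignments, name="mag_id", dtype=object).sort_index(),
        sorted(ambiguous), unassigned)


def compute_nsaf(sc: SpectralCounts,
                 assigned_mag: pd.Series | None = None) -> NSAFTable:
    """Percent normalized spectral abundance factors per sample.

    Samples with no detected protein at all are flagged and set missing.
    """
    lens = sc.lengths.reindex(sc.counts.index).to_numpy(dtype=float)
    saf = sc.counts.to_numpy(dtype=float) / lens[:, None]
    colsum = saf.sum(axis=0)
    empty = colsum == 0
    flagged = sc.counts.columns[empty].tolist()
    if flagged:
        logger.warning("samples with zero spectral counts flagged: %s",
                       flagged)
    colsum[empty] = np.nan
    vals = 100.0 * saf / colsum[None, :]
    if assigned_mag is None:
        assigned_mag = pd.Series(dtype=object, name="mag_id")
    return NSAFTable(
        pd.DataFrame(vals, index=sc.counts.index, columns=sc.counts.columns),
        assigned_mag, flagged)


def top_categories(nsaf: NSAFTable, anno: ProteinAnnotationTable,
                   k: int = 10, samples: pd.DataFrame | None = None,
                   mag_taxon: pd.Series | None = None
                   ) -> tuple[list[str], pd.DataFrame]:
    """Top-k BRITE categories by unique-protein count, with cell summaries.

    Returns the ranked category list (ties broken by lexicographic category
    name) and a long table of log10 summed %NSAF per
    (category, year, bloom_phase, order); without sample metadata the
    summary is a single pooled cell per category.
    """
    cat_proteins: dict[str, set[str]] = {}
    for protein in nsaf.values.index:
        if protein not in anno.table.index:
            continue
        for cat in anno.categories(protein):
            cat_proteins.setdefault(cat, set()).add(protein)
    ranked = sorted(cat_proteins, key=lambda c: (-len(cat_proteins[c]), c))
    top = ranked[:k]

    if samples is not None:
        groups = samples[["year", "bloom_phase"]].copy()
    else:
        groups = pd.DataFrame({"year": "all", "bloom_phase": "all"},
                              index=nsaf.values.columns)
    taxon = (nsaf.assigned_mag.map(mag_taxon)
             if mag_taxon is not None else None)

    rows = []
    for cat in top:
        members = sorted(cat_proteins[cat] & set(nsaf.values.index))
        sub = nsaf.values.loc[members]
        if taxon is not None:
            orders = taxon.reindex(members)
        else:
            orders = pd.Series("all", index=pd.Index(members))
        for order in sorted(orders.dropna().unique()):
            order_prot = orders.index[orders == order]
            for (year, phase), cols in groups.groupby(
                    ["year", "bloom_phase"], sort=True):
                cell_cols = nsaf.values.columns.intersection(cols.index)
                total = float(np.nansum(
                    sub.loc[order_prot, cell_cols].to_numpy()))
                rows.append({
                    "category": cat, "order": order, "year": year,
                    "bloom_phase": phase,
                    "summed_pct_nsaf": total,
                    "log10_summed_pct_nsaf":
                        float(np.log10(total)) if total > 0 else np.nan,
                    "n_unique_proteins": len(cat_proteins[cat]),
                })
    return top, pd.DataFrame(rows)


def cobalamin_summary(nsaf: NSAFTable, anno: ProteinAnnotationTable,
                      group_map: pd.Series) -> pd.DataFrame:
    """Summed %NSAF of cobalamin transport vs biosynthesis per group.

    ``group_map`` maps MAG → group (taxonomic order or niche label).  Every
    declared group appears in the output; groups without qualifying
    proteins are reported with ``detected = False`` rather than dropped.
    Biosynthesis counts only terminal-pathway enzymes (the shipped flag map
    carries adenosyltransferase and CobW identifiers).
    """
    groups = sorted(pd.Series(group_map).dropna().unique())
    rows = []
    for cat, flag in (("transport", "cobalamin_transport"),
                      ("biosynthesis", "cobalamin_biosynthesis")):
        flagged = set(anno.proteins_with_flag(flag))
        for group in groups:
            mags = set(group_map.index[group_map == group])
            members = [p for p in nsaf.values.index
                       if p in flagged
                       and nsaf.assigned_mag.get(p) in mags]
            total = float(np.nansum(nsaf.values.loc[members].to_numpy())) \
                if members else 0.0
            rows.append({
                "group": group, "category": cat,
                "summed_pct_nsaf": total if members else np.nan,
                "n_proteins": len(members),
                "detected": bool(members),
            })
    return pd.DataFrame(rows)


class TransportShare(NamedTuple):
    share: float
    numerator: float      # summed transport %NSAF from generalist MAGs
    denominator: float    # summed transport %NSAF from all labelled MAGs


def transport_share(nsaf: NSAFTable, anno: ProteinAnnotationTable,
                    niche: NicheLabels,
                    mag_taxon: pd.Series | None = None,
                    taxon: str = "Rhodobacterales") -> TransportShare:
    """Fraction of (Rhodobacterales) transport %NSAF from generalists."""
    transporters = set(anno.proteins_with_flag("transport"))
    labelled = set(niche.labels.index)
    if mag_taxon is not None:
        labelled &= set(mag_taxon.index[mag_taxon == taxon])
    num = den = 0.0
    for protein in nsaf.values.index:
        if protein not in transporters:
            continue
        mag = nsaf.assigned_mag.get(protein)
        if mag not in labelled:
            continue
        total = float(np.nansum(nsaf.values.loc[protein].to_numpy()))
        den += total
        if niche.labels[mag] == "generalist":
            num += total
    share = num / den if den > 0 else np.nan
    return TransportShare(share, num, den)


# ---------------------------------------------------------------------------
# file-level pipeline


def load_spectral_counts(path: str | Path) -> SpectralCounts:
    df = read_tsv(path)
    lengths = df["length_aa"]
    counts = df.drop(columns=["length_aa"])
    return SpectralCounts(counts=counts, lengths=lengths)


def run(indir: str | Path, outdir: str | Path,
        niche_labels: NicheLabels | None = None) -> dict:
    """File-level entry point: hits + spectra + annotations → summaries."""
    indir, outdir = Path(indir), Path(outdir)
    hits = read_hits(indir / "hits.tsv")
    sc = load_spectral_counts(indir / "spectral_counts.tsv")
    anno = ProteinAnnotationTable(read_tsv(indir / "protein_anno.tsv"))
    assignment = filter_hits(hits)
    nsaf = compute_nsaf(sc, assignment.assignments)

    samples = None
    if (indir / "samples.tsv").exists():
        samples = read_tsv(indir / "samples.tsv")
        samples = samples.loc[samples.index.intersection(nsaf.values.columns)]
    mag_taxon = None
    if (indir / "mag_meta.tsv").exists():
        mag_taxon = read_tsv(indir / "mag_meta.tsv")["taxon"]

    top, cells = top_categories(nsaf, anno, samples=samples,
                                mag_taxon=mag_taxon)
    group_map = mag_taxon if mag_taxon is not None else pd.Series(dtype=object)
    cobalamin = cobalamin_summary(nsaf, anno, group_map)

    write_tsv(nsaf.values, outdir / "nsaf.tsv",
              comments=[f"excluded_ambiguous={assignment.ambiguous}"])
    write_tsv(cells, outdir / "category_summary.tsv", index=False,
              comments=["ranking=unique protein count",
                        "cell=log10 of summed %NSAF (sum-then-log)"])
    write_tsv(cobalamin, outdir / "cobalamin_summary.tsv", index=False)
    out = {"assignment": assignment, "nsaf": nsaf, "top_categories": top,
           "category_cells": cells, "cobalamin": cobalamin}
    if niche_labels is not None:
        out["transport_share"] = transport_share(
            nsaf, anno, niche_labels, mag_taxon=mag_taxon)
    return out
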