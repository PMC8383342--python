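"""Tad (tight adherence) locus detection, completeness and group contrasts.

The tad locus — also called the Widespread Colonization Island — is the
14-gene cluster ``flp1-flp2-tadV-rcpC-rcpA-rcpB-tadZ-tadA-tadB-tadC-tadD-
tadE-tadF-tadG`` encoding a type IVc secretion system that assembles
adhesive Flp pili.  Twelve of the fourteen genes are essential for fibril
secretion (all except *flp2* and *rcpB*).  Several genes go by *cpa*
synonyms in Caulobacter-style annotations (cpaA=tadV, cpaB=rcpC, cpaC=rcpA,
cpaE=tadZ, cpaF=tadA).

Detection is annotation-based: gene symbols and product strings from the
per-MAG annotation tables are matched (case-insensitively) against the
canonical names, the synonym map and a shipped, user-extensible product
regular-expression resource.  An external hit table can be injected for
users who run their own sequence searches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_gff3, read_tsv, write_tsv
from .niche import NicheLabels

CANONICAL_GENES = ("flp1", "flp2", "tadV", "rcpC", "rcpA", "rcpB", "tadZ",
                   "tadA", "tadB", "tadC", "tadD", "tadE", "tadF", "tadG")
NONESSENTIAL = ("flp2", "rcpB")
SYNONYMS = {"cpaA": "tadV", "cpaB": "rcpC", "cpaC": "rcpA", "cpaE": "tadZ",
            "cpaF": "tadA"}

#: annotation categories tallied for Fig-7-style gene maps
FEATURE_PATTERNS = {
    "flp_pilus": re.compile(
        r"\b(?:flp[12]?|tad[VZABCDEFG]|rcp[ABC]|cpa[ABCEF])\b|flp pilus",
        re.IGNORECASE),
    "chemotaxis": re.compile(
        r"\bche[ABRWYZ]\b|\bmcp\w*\b|methyl-accepting chemotaxis",
        re.IGNORECASE),
    "motility": re.compile(
        r"\b(?:fla[A-Z]|flg[A-Z]|fli[A-Z]|mot[AB])\b|flagell",
        re.IGNORECASE),
    "luxI": re.compile(r"\bluxI\b|acyl-?homoserine-?lactone synthase",
                       re.IGNORECASE),
    "luxR": re.compile(
        r"\bluxR\b|transcriptional (?:activator|regulator) LuxR",
        re.IGNORECASE),
}


@dataclass(frozen=True)
class TadReference:
    """Canonical tad gene set, essentiality and synonym map."""

    genes: tuple[str, ...] = CANONICAL_GENES
    nonessential: tuple[str, ...] = NONESSENTIAL
    synonyms: Mapping[str, str] = field(default_factory=lambda: dict(SYNONYMS))

    @property
    def essential(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if g not in self.nonessential)

    def canonical_name(self, symbol: str) -> str | None:
        """Resolve a gene symbol to a canonical tad gene name, if any."""
        sym = symbol.strip()
        lowered = {g.lower(): g for g in self.genes}
        if sym.lower() in lowered:
            return lowered[sym.lower()]
        syn = {k.lower(): v for k, v in self.synonyms.items()}
        return syn.get(sym.lower())


def load_product_patterns(path: str | Path | None = None
                          ) -> dict[str, re.Pattern]:
    """Load product-string regexes mapping annotations to canonical genes."""
    if path is None:
        ref = resources.files("phycotad.resources") / "tad_products.tsv"
        with resources.as_file(ref) as p:
            df = read_tsv(p, index_col=None)
    else:
        df = read_tsv(path, index_col=None)
    return {row.canonical: re.compile(row.pattern, re.IGNORECASE)
            for row in df.itertuples(index=False)}


@dataclass
class GeneAnnotationTable:
    """Positional gene annotations per MAG (1-based inclusive coordinates)."""

    tables: dict[str, pd.DataFrame]   # mag -> annotation DataFrame
    cds_counts: pd.Series             # mag -> number of coding sequences

    def __post_init__(self) -> None:
        for mag, df in self.tables.items():
            if (df["start"] > df["end"]).any():
                raise ValueError(f"{mag}: start > end in annotation")
            bad = ~df["strand"].isin(["+", "-"])
            if bad.any():
                raise ValueError(f"{mag}: invalid strand values")

    @property
    def mags(self) -> list[str]:
        return list(self.tables)


@dataclass
class LocusReport:
    mag_id: str
    found: set[str]
    missing: set[str]
    n_found: int
    contiguous_block_size: int
    status: str                        # complete|near_complete|partial|absent

    def as_row(self) -> dict:
        return {
            "mag_id": self.mag_id, "n_found": self.n_found,
            "contiguous_block_size": self.contiguous_block_size,
            "status": self.status,
            "found": ",".join(g for g in CANONICAL_GENES if g in self.found),
            "missing": ",".join(g for g in CANONICAL_GENES
                                if g in self.missing),
        }


def map_homologs(anno: GeneAnnotationTable, ref: TadReference | None = None,
                 product_patterns: Mapping[str, re.Pattern] | None = None,
                 external_hits: pd.DataFrame | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Locate canonical tad genes in each MAG's annotations.

    Matches gene symbols against canonical names + synonyms first, then
    product strings against the regex resource.  Duplicates collapse to one
    canonical hit per locus position (copy number kept in the ``copies``
    column).  ``external_hits`` (columns mag_id, canonical, contig_id,
    start, end, strand) is merged in verbatim for users running their own
    homology searches.
    """
    ref = ref or TadReference()
    product_patterns = product_patterns or load_product_patterns()
    out: dict[str, pd.DataFrame] = {}
    for mag, df in anno.tables.items():
        rows = []
        for rec in df.itertuples(index=False):
            name = ref.canonical_name(str(rec.gene_symbol))
            if name is None:
                for canon, pat in product_patterns.items():
                    if pat.search(str(rec.product)) or \
                            pat.search(str(rec.gene_symbol)):
                        name = canon
                        break
            if name is not None:
                rows.append({"canonical": name, "contig_id": rec.contig_id,
                             "start": int(rec.start), "end": int(rec.end),
                             "strand": rec.strand})
        hits = pd.DataFrame(
            rows, columns=["canonical", "contig_id", "start", "end",
                           "strand"])
        if external_hits is not None:
            extra = external_hits[external_hits["mag_id"] == mag]
            if len(extra):
                hits = pd.concat(
                    [hits, extra[["canonical", "contig_id", "start", "end",
                                  "strand"]]], ignore_index=True)
        copies = hits.groupby("canonical").size().rename("copies")
        hits = (hits.sort_values(["contig_id", "start"])
                    .drop_duplicates(subset=["canonical", "contig_id",
                                             "start"])
                    .reset_index(drop=True))
        hits = hits.merge(copies, left_on="canonical", right_index=True)
        out[mag] = hits
    return out


def score_completeness(hits: Mapping[str, pd.DataFrame],
                       ref: TadReference | None = None,
                       near_gap: int = 2,
                       anno: GeneAnnotationTable | None = None,
                       max_gap_bp: int = 10_000) -> dict[str, LocusReport]:
    """Score tad locus completeness per MAG.

    Status thresholds: ``complete`` = all 14 genes; ``near_complete`` =
    at most ``near_gap`` genes missing (default 2, configurable); ``partial``
    = anything else with at least one gene; ``absent`` = none.
    """
    ref = ref or TadReference()
    n_total = len(ref.genes)
    reports = {}
    for mag, df in hits.items():
        found = set(df["canonical"]) & set(ref.genes)
        n_found = len(found)
        missing = set(ref.genes) - found
        if n_found == n_total:
            status = "complete"
        elif n_found == 0:
            status = "absent"
        elif n_total - n_found <= near_gap:
            status = "near_complete"
        else:
            status = "partial"
        block = contiguity_single(df, max_gap_bp=max_gap_bp)
        reports[mag] = LocusReport(
            mag_id=mag, found=found, missing=missing, n_found=n_found,
            contiguous_block_size=block, status=status)
    return reports


def contiguity_single(hits: pd.DataFrame, max_gap_bp: int = 10_000) -> int:
    """Largest run of canonical hits on one contig with gaps <= max_gap_bp."""
    if hits.empty:
        return 0
    best = 0
    for _, sub in hits.groupby("contig_id"):
        sub = sub.sort_values("start")
        run_genes: set[str] = set()
        best_here = 0
        prev_end = None
        for rec in sub.itertuples(index=False):
            if prev_end is not None and rec.start - prev_end > max_gap_bp:
                best_here = max(best_here, len(run_genes))
                run_genes = set()
            run_genes.add(rec.canonical)
            prev_end = max(prev_end or rec.end, rec.end)
        best_here = max(best_here, len(run_genes))
        best = max(best, best_here)
    return best


def contiguity(anno: GeneAnnotationTable, hits: Mapping[str, pd.DataFrame],
               max_gap_bp: int = 10_000) -> pd.Series:
    """Contiguous canonical-gene block size per MAG."""
    return pd.Series({mag: contiguity_single(df, max_gap_bp)
                      for mag, df in hits.items()}, name="block_size")


def tally_features(anno: GeneAnnotationTable,
                   categories: Iterable[str] = tuple(FEATURE_PATTERNS)
                   ) -> pd.DataFrame:
    """Per-MAG gene counts and per-CDS rates for colonization-related
    categories (flp_pilus, chemotaxis, motility, luxI, luxR).

    luxI and luxR are counted separately and luxR multiplicity is reported
    as-is (several luxR copies per MAG are common).
    """
    categories = list(categories)
    unknown = set(categories) - set(FEATURE_PATTERNS)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    rows = []
    for mag, df in anno.tables.items():
        cds = anno.cds_counts.get(mag)
        if cds is None or cds <= 0 or pd.isna(cds):
            raise ValueError(f"invalid CDS count for MAG {mag!r}")
        text = (df["gene_symbol"].astype(str) + " "
                + df["product"].astype(str))
        row: dict = {"mag_id": mag, "cds_count": int(cds)}
        for cat in categories:
            pat = FEATURE_PATTERNS[cat]
            n = int(text.str.contains(pat).sum())
            row[f"{cat}_count"] = n
            row[f"{cat}_per_cds"] = n / cds
        rows.append(row)
    return pd.DataFrame(rows).set_index("mag_id")


def group_prevalence(reports: Mapping[str, LocusReport],
                     tallies: pd.DataFrame, niche: NicheLabels,
                     welch: bool = False) -> pd.DataFrame:
    """Per-niche-group feature prevalence with two-sample t-tests.

    Prevalence compares presence (rate > 0, or tad locus at least
    near-complete); the t statistic is computed on per-CDS rates with a
    pooled-variance Student's t by default (``welch=True`` switches to
    Welch's correction).
    """
    col = [m for m in niche.colonizers if m in tallies.index]
    gen = [m for m in niche.generalists if m in tallies.index]
    if len(col) < 2 or len(gen) < 2:
        raise ValueError("need >=2 MAGs per niche group")
    rows = []
    tad_ok = {m: r.status in ("complete", "near_complete")
              for m, r in reports.items()}
    tad_series = pd.Series({m: float(tad_ok.get(m, False))
                            for m in tallies.index})
    candidates = {"tad_locus": tad_series}
    for cat in FEATURE_PATTERNS:
        rate_col = f"{cat}_per_cds"
        if rate_col in tallies.columns:
            candidates[cat] = tallies[rate_col]
    for name, series in candidates.items():
        xa = series.loc[col].to_numpy(dtype=float)
        xb = series.loc[gen].to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
        rows.append({
            "feature": name,
            "prevalence_colonizers": float((xa > 0).mean()),
            "prevalence_generalists": float((xb > 0).mean()),
            "mean_rate_colonizers": float(xa.mean()),
            "mean_rate_generalists": float(xb.mean()),
            "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows).set_index("feature")


def genome_size_test(sizes: pd.Series, groups: pd.Series,
                     welch: bool = False) -> pd.DataFrame:
    """Pairwise Student's t-tests of genome size between groups."""
    out = []
    uniq = sorted(groups.dropna().unique())
    for i, ga in enumerate(uniq):
        for gb in uniq[i + 1:]:
            xa = sizes[groups.index[groups == ga]].dropna()
            xb = sizes[groups.index[groups == gb]].dropna()
            if np.ptp(np.concatenate([xa, xb])) == 0:
                t, p = 0.0, 1.0    # degenerate: all values identical
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
            out.append({"group_a": ga, "group_b": gb,
                        "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                        "t": float(t), "p": float(p)})
    return pd.DataFrame(out)


def bgc_table(counts: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Summarize externally supplied secondary-metabolite cluster counts.

    ``counts``: MAG × BGC-class counts (e.g. from an antiSMASH-style run,
    out of scope here).  Returns per-group totals and prevalence per class.
    """
    if counts.empty:
        return pd.DataFrame(
            columns=["group", "bgc_class", "total", "n_mags", "prevalence"])
    rows = []
    for group in sorted(groups.dropna().unique()):
        mags = [m for m in groups.index[groups == group]
                if m in counts.index]
        sub = counts.loc[mags]
        for cls in counts.columns:
            rows.append({
                "group": group, "bgc_class": cls,
                "total": int(sub[cls].sum()), "n_mags": len(mags),
                "prevalence": float((sub[cls] > 0).mean()) if mags else 0.0,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-level pipeline


def load_annotations(indir: str | Path,
                     cds_counts: pd.Series) -> GeneAnnotationTable:
    indir = Path(indir)
    tables = {}
    for gff in sorted(indir.glob("*.gff3")):
        mag = gff.stem
        tables[mag] = read_gff3(gff)
    return GeneAnnotationTable(tables=tables, cds_counts=cds_counts)


def locus_diagram(hits: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per canonical gene occurrence — enough to redraw gene maps."""
    rows = []
    for mag, df in hits.items():
        for rec in df.itertuples(index=False):
            rows.append({"mag_id": mag, "contig_id": rec.contig_id,
                         "start": rec.start, "end": rec.end,
                         "strand": rec.strand, "canonical": rec.canonical})
    return pd.DataFrame(rows, columns=["mag_id", "contig_id", "start", "end",
                                       "strand", "canonical"])


def run(indir: str | Path, outdir: str | Path, near_gap: int = 2,
        max_gap_bp: int = 10_000) -> dict:
    """File-level entry point: annotations + niche labels → tad reports."""
    indir, outdir = Path(indir), Path(outdir)
    meta = read_tsv(indir / "mag_meta.tsv")
    anno = load_annotations(indir / "annotations", meta["cds_count"])
    ref = TadReference()
    hits = map_homologs(anno, ref)
    reports = score_completeness(hits, ref, near_gap=near_gap,
                                 max_gap_bp=max_gap_bp)
    tallies = tally_features(anno)
    write_tsv(pd.DataFrame([r.as_row() for r in reports.values()]),
              outdir / "tad_report.tsv", index=False,
              comments=[f"near_gap={near_gap}", f"max_gap_bp={max_gap_bp}"])
    write_tsv(tallies, outdir / "feature_rates.tsv")
    write_tsv(locus_diagram(hits), outdir / "locus_diagram.tsv", index=False)
    out = {"hits": hits, "reports": reports, "tallies": tallies}

    labels_path = indir / "niche_labels.tsv"
    if labels_path.exists():
        ldf = read_tsv(labels_path)
        niche = NicheLabels(ldf["label"], ldf.get("rationale",
                                                  ldf["label"]))
        stats_df = group_prevalence(reports, tallies, niche)
        write_tsv(stats_df, outdir / "group_stats.tsv")
        out["group_stats"] = stats_df
    bgc_path = indir / "bgc_counts.tsv"
    if bgc_path.exists() and labels_path.exists():
        bgc = bgc_table(read_tsv(bgc_path), ldf["label"])
        write_tsv(bgc, outdir / "bgc_summary.tsv", index=False)
        out["bgc"] = bgc
    return out
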