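"""Read-recruitment normalization and abundance-pattern clustering.

Recruitment counts (reads mapped per MAG per sample) are turned into RPKM
(reads per kilobase of genome per million mapped reads), then into per-sample
relative abundances, and finally into centered log-ratio (CLR) coordinates
for linear statistics on compositional data.  MAG abundance profiles are
clustered hierarchically (Canberra distance, Ward.D2 linkage, as in the R
``hclust`` convention) into a *persistent* group — consistently high relative
abundance — and a *fluctuating* group whose abundance rises and falls with
individual blooms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace

from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)

Unit = Literal["counts", "rpkm", "relabund", "clr"]


@dataclass
class RecruitmentTable:
    """Raw mapped-read counts per MAG per sample.

    Parameters
    ----------
    counts : DataFrame
        MAG (rows) × sample (columns) mapped-read counts.
    lengths : Series
        MAG → genome length in bp.
    totals : Series
        sample → total mapped reads in that metagenome.
    samples : DataFrame, optional
        Per-sample metadata indexed by sample id, with columns
        ``date``, ``year``, ``bloom_phase`` and optionally
        ``chlorophyll_a`` (µg/L).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            bad = self.lengths[self.lengths <= 0].index.tolist()
            raise ValueError(f"non-positive MAG length for {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def mags(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class AbundanceMatrix:
    """MAG × sample abundance values in one declared unit."""

    values: pd.DataFrame
    unit: Unit
    flagged_samples: list = field(default_factory=list)

    @property
    def mags(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PatternClusters:
    """Two-way partition of MAG abundance patterns.

    ``assignments`` maps each MAG to ``"persistent"`` (consistently high
    relative abundance) or ``"fluctuating"``.
    """

    assignments: pd.Series
    linkage: np.ndarray | None
    metric: str = "canberra"

    def __getitem__(self, mag: str) -> str:
        return self.assignments[mag]


def compute_rpkm(recr: RecruitmentTable) -> AbundanceMatrix:
    """RPKM = reads / ((MAG length in kb) × (total mapped reads / 1e6))."""
    lengths = recr.lengths.reindex(recr.counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise KeyError(f"missing MAG length for {missing}")
    totals = recr.totals.reindex(recr.counts.columns)
    if totals.isna().any():
        missing = totals[totals.isna()].index.tolist()
        raise KeyError(f"missing total mapped reads for sample {missing}")
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive total mapped reads for sample {bad}")
    kb = lengths.to_numpy()[:, None] / 1000.0
    per_million = totals.to_numpy()[None, :] / 1e6
    vals = recr.counts.to_numpy(dtype=float) / (kb * per_million)
    return AbundanceMatrix(
        pd.DataFrame(vals, index=recr.counts.index,
                     columns=recr.counts.columns),
        unit="rpkm")


def relative_abundance(rpkm: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample share of summed RPKM over the MAGs in the table.

    All-zero samples are set to missing and flagged rather than divided 0/0.
    """
    if rpkm.unit != "rpkm":
        raise ValueError(f"expected unit 'rpkm', got {rpkm.unit!r}")
    colsum = rpkm.values.sum(axis=0)
    flagged = colsum.index[colsum == 0].tolist()
    if flagged:
        logger.warning("samples with zero summed RPKM set to missing: %s",
                       flagged)
    safe = colsum.replace(0, np.nan)
    vals = rpkm.values.div(safe, axis=1)
    return AbundanceMatrix(vals, unit="relabund", flagged_samples=flagged)


def _replace_zeros(comp: np.ndarray, strategy: str, delta: float | None
                   ) -> np.ndarray:
    """Zero replacement on a samples×parts composition array (rows sum 1)."""
    if not (comp > 0).any():
        raise ValueError("composition is entirely zero")
    if delta is None:
        delta = 0.5 * comp[comp > 0].min()
    if (comp == 0).any():
        if strategy == "multiplicative":
            comp = multi_replace(comp, delta=delta)
        elif strategy == "pseudocount":
            comp = comp + delta
            comp = comp / comp.sum(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown zero-replacement strategy {strategy!r}")
    return comp


def clr_transform(rel: AbundanceMatrix, pseudo: str = "multiplicative",
                  delta: float | None = None) -> AbundanceMatrix:
    """Centered log-ratio transform of per-sample MAG compositions.

    Zeros are replaced first (default: multiplicative replacement with
    δ = half the smallest nonzero relative abundance in the matrix); each
    sample's CLR coordinates then sum to zero.
    """
    if rel.unit != "relabund":
        raise ValueError(f"expected unit 'relabund', got {rel.unit!r}")
    vals = rel.values.to_numpy(dtype=float).T  # samples × MAGs
    if np.nanmin(vals) < 0:
        raise ValueError("negative relative abundance")
    keep = ~np.isnan(vals).any(axis=1)
    comp = _replace_zeros(vals[keep], pseudo, delta)
    out = np.full_like(vals, np.nan)
    out[keep] = _skbio_clr(comp)
    return AbundanceMatrix(
        pd.DataFrame(out.T, index=rel.values.index,
                     columns=rel.values.columns),
        unit="clr", flagged_samples=list(rel.flagged_samples))


def cluster_patterns(rel: AbundanceMatrix, delta: float | None = None
                     ) -> PatternClusters:
    """Split MAGs into persistent vs fluctuating abundance patterns.

    Profiles are log10 relative abundances (zeros replaced as for CLR);
    pairwise Canberra distances are clustered with Ward.D2 linkage and the
    tree cut at two clusters.  The cluster whose members have the higher
    mean relative abundance is labelled ``persistent``; a tie is broken
    toward the cluster containing the single highest relative-abundance
    value.
    """
    if rel.unit != "relabund":
        raise ValueError(f"expected unit 'relabund', got {rel.unit!r}")
    mags = rel.values.index
    if len(mags) < 2:
        warnings.warn("fewer than 2 MAGs: returning a single trivial cluster")
        return PatternClusters(
            pd.Series("persistent", index=mags, name="cluster"), None)
    vals = rel.values.to_numpy(dtype=float).T
    keep = ~np.isnan(vals).any(axis=1)
    comp = _replace_zeros(vals[keep], "multiplicative", delta)
    profiles = np.log10(comp).T  # MAGs × samples
    dist = pdist(profiles, metric="canberra")
    # scipy's 'ward' on a precomputed distance corresponds to R's ward.D2
    Z = linkage(dist, method="ward")
    flat = fcluster(Z, t=2, criterion="maxclust")
    means = rel.values.mean(axis=1)
    m1 = means[flat == 1].mean()
    m2 = means[flat == 2].mean()
    if np.isclose(m1, m2):
        top = int(flat[np.argmax(means.to_numpy())])
        persistent_id = top
    else:
        persistent_id = 1 if m1 > m2 else 2
    labels = np.where(flat == persistent_id, "persistent", "fluctuating")
    return PatternClusters(pd.Series(labels, index=mags, name="cluster"), Z)


# ---------------------------------------------------------------------------
# file-level pipeline


def load_recruitment(indir: str | Path) -> RecruitmentTable:
    indir = Path(indir)
    counts = read_tsv(indir / "recruitment.tsv")
    meta = read_tsv(indir / "mag_meta.tsv")
    totals = counts.sum(axis=0)
    samples = None
    if (indir / "samples.tsv").exists():
        samples = read_tsv(indir / "samples.tsv")
    return RecruitmentTable(counts=counts, lengths=meta["length_bp"],
                            totals=totals, samples=samples)


def run(indir: str | Path, outdir: str | Path,
        pseudo: str = "multiplicative") -> dict:
    """File-level entry point: recruitment.tsv → abundance tables + clusters."""
    outdir = Path(outdir)
    recr = load_recruitment(indir)
    rpkm = compute_rpkm(recr)
    rel = relative_abundance(rpkm)
    clrm = clr_transform(rel, pseudo=pseudo)
    clusters = cluster_patterns(rel)
    write_tsv(rpkm.values, outdir / "abundance_rpkm.tsv")
    write_tsv(rel.values, outdir / "abundance_relabund.tsv",
              comments=[f"flagged_samples={rel.flagged_samples}"])
    write_tsv(clrm.values, outdir / "abundance_clr.tsv",
              comments=[f"zero_replacement={pseudo}"])
    write_tsv(clusters.assignments.to_frame(), outdir / "clusters.tsv",
              comments=["distance=canberra", "linkage=ward.D2",
                        "profiles=log10 relative abundance"])
    return {"rpkm": rpkm, "relabund": rel, "clr": clrm, "clusters": clusters}
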