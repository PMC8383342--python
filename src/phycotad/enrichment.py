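"""Gene-content (KO/COG) enrichment between MAG groups.

Two complementary tests per feature: Fisher's exact test on the 2×2
presence/absence table (two-sided, minimum-likelihood convention) and a
Mann-Whitney U test on per-MAG feature counts for overrepresentation.
Raw p-values are corrected (Benjamini-Hochberg by default) and a feature
only *passes* if its corrected p < 0.05 AND it is present in more than half
of the MAGs of the enriched group.

Two further rule-based selections sidestep p-values entirely:

* core functions — features present in every analyzed MAG;
* the occurrence criterion — features present in more than ``hi`` (default
  70%) of colonizers and fewer than ``lo`` (default 20%) of generalists,
  both strict.  With small groups nothing may reach corrected significance
  while a handful of features still meet this criterion; that is exactly
  the situation the rule exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import read_tsv, write_tsv


@dataclass
class GeneContentMatrix:
    """MAG × feature copy-number counts; presence means count > 0."""

    counts: pd.DataFrame                 # mag × feature, nonneg ints
    kind: str = "COG"                    # KO | COG
    groups: pd.Series | None = None      # mag -> group label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative feature counts")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def mags(self) -> pd.Index:
        return self.counts.index

    @property
    def features(self) -> pd.Index:
        return self.counts.columns

    def prevalence(self, mags: Sequence[str]) -> pd.Series:
        """Fraction of the given MAGs carrying each feature."""
        return self.presence.loc[list(mags)].mean(axis=0)


def _check_groups(gcm: GeneContentMatrix, group_a, group_b,
                  min_size: int = 1):
    a = list(group_a)
    b = list(group_b)
    if len(a) < min_size or len(b) < min_size:
        raise ValueError(
            f"both groups need >= {min_size} members (got {len(a)}, {len(b)})")
    missing = (set(a) | set(b)) - set(gcm.mags)
    if missing:
        raise KeyError(f"MAGs not in matrix: {sorted(missing)}")
    return a, b


def fisher_presence(gcm: GeneContentMatrix, group_a: Sequence[str],
                    group_b: Sequence[str]) -> pd.DataFrame:
    """Two-sided Fisher's exact test on presence/absence per feature.

    Returns one row per feature with the raw p, per-group prevalences,
    the prevalence difference as the effect direction, and an
    ``uninformative`` flag for features absent (or fixed) everywhere.
    """
    a, b = _check_groups(gcm, group_a, group_b)
    pres = gcm.presence
    ka = pres.loc[a].sum(axis=0).to_numpy()
    kb = pres.loc[b].sum(axis=0).to_numpy()
    na, nb = len(a), len(b)
    rows = []
    for feat, xa, xb in zip(gcm.features, ka, kb):
        uninformative = (xa + xb == 0) or (xa == na and xb == nb)
        if uninformative:
            p = 1.0
            odds = np.nan
        else:
            odds, p = stats.fisher_exact([[xa, na - xa], [xb, nb - xb]],
                                         alternative="two-sided")
        prev_a, prev_b = xa / na, xb / nb
        rows.append({
            "feature_id": feat, "test": "fisher", "statistic": odds,
            "p_raw": float(p), "prevalence_a": prev_a, "prevalence_b": prev_b,
            "direction": "a" if prev_a > prev_b
                         else ("b" if prev_b > prev_a else "none"),
            "uninformative": uninformative,
        })
    return pd.DataFrame(rows).set_index("feature_id")


def mannwhitney_counts(gcm: GeneContentMatrix, group_a: Sequence[str],
                       group_b: Sequence[str],
                       exact_max_n: int = 12) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test on per-MAG feature counts.

    Exact null distribution when the pooled size is <= ``exact_max_n`` and
    there are no ties; normal approximation with tie correction otherwise.
    """
    a, b = _check_groups(gcm, group_a, group_b, min_size=2)
    rows = []
    for feat in gcm.features:
        xa = gcm.counts.loc[a, feat].to_numpy(dtype=float)
        xb = gcm.counts.loc[b, feat].to_numpy(dtype=float)
        pooled = np.concatenate([xa, xb])
        uninformative = np.ptp(pooled) == 0
        if uninformative:
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            ties = len(np.unique(pooled)) < len(pooled)
            method = ("exact" if (len(pooled) <= exact_max_n and not ties)
                      else "asymptotic")
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                      method=method)
        ma, mb = xa.mean(), xb.mean()
        rows.append({
            "feature_id": feat, "test": "mannwhitney", "statistic": float(u),
            "p_raw": float(p),
            "prevalence_a": float((xa > 0).mean()),
            "prevalence_b": float((xb > 0).mean()),
            "direction": "a" if ma > mb else ("b" if mb > ma else "none"),
            "uninformative": bool(uninformative),
        })
    return pd.DataFrame(rows).set_index("feature_id")


def adjust_p(results: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Attach multiplicity-corrected p-values (BH default, Bonferroni, none)."""
    out = results.copy()
    p = out["p_raw"].to_numpy()
    if method in ("bh", "fdr_bh"):
        out["p_adjusted"] = multipletests(p, method="fdr_bh")[1]
    elif method == "bonferroni":
        out["p_adjusted"] = multipletests(p, method="bonferroni")[1]
    elif method == "none":
        out["p_adjusted"] = p
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return out


def prevalence_filter(results: pd.DataFrame, alpha: float = 0.05,
                      threshold: float = 0.5) -> pd.DataFrame:
    """Mark features passing: adjusted p < alpha AND prevalence in the
    enriched group strictly above ``threshold``."""
    out = results.copy()
    enriched_prev = np.where(out["direction"] == "a",
                             out["prevalence_a"],
                             np.where(out["direction"] == "b",
                                      out["prevalence_b"], 0.0))
    out["passes"] = ((out["p_adjusted"] < alpha)
                     & (enriched_prev > threshold)
                     & ~out["uninformative"])
    return out


def core_functions(gcm: GeneContentMatrix) -> list[str]:
    """Features present in 100% of the MAGs in the matrix."""
    if gcm.counts.empty:
        return []
    pres = gcm.presence
    return pres.columns[pres.all(axis=0)].tolist()


def occurrence_criterion(gcm: GeneContentMatrix, colonizers: Sequence[str],
                         generalists: Sequence[str], hi: float = 0.7,
                         lo: float = 0.2) -> list[str]:
    """Features present in > ``hi`` of colonizers and < ``lo`` of generalists.

    Both inequalities are strict.  This deliberately bypasses p-value
    gating (see module docstring).
    """
    col, gen = _check_groups(gcm, colonizers, generalists)
    prev_c = gcm.prevalence(col)
    prev_g = gcm.prevalence(gen)
    mask = (prev_c > hi) & (prev_g < lo)
    return gcm.features[mask].tolist()


# ---------------------------------------------------------------------------
# file-level pipeline


def load_gene_content(path: str | Path,
                      groups: pd.Series | None = None) -> GeneContentMatrix:
    return GeneContentMatrix(read_tsv(path), groups=groups)


def run(indir: str | Path, outdir: str | Path, group_by: str = "niche",
        method: str = "bh") -> dict:
    """File-level entry point: gene content + group labels → enrichment."""
    indir, outdir = Path(indir), Path(outdir)
    if group_by == "niche":
        labels = read_tsv(indir / "niche_labels.tsv")["label"]
        group_a = labels.index[labels == "colonizer"].tolist()
        group_b = labels.index[labels == "generalist"].tolist()
    else:
        meta = read_tsv(indir / "mag_meta.tsv")
        taxa = meta["taxon"]
        uniq = sorted(taxa.unique())
        if len(uniq) != 2:
            raise ValueError(
                f"order-level comparison needs exactly 2 orders, got {uniq}")
        group_a = taxa.index[taxa == uniq[0]].tolist()
        group_b = taxa.index[taxa == uniq[1]].tolist()
    gcm = load_gene_content(indir / "gene_content.tsv")
    gcm = GeneContentMatrix(gcm.counts.loc[group_a + group_b], gcm.kind)

    fisher = prevalence_filter(adjust_p(
        fisher_presence(gcm, group_a, group_b), method))
    mw = prevalence_filter(adjust_p(
        mannwhitney_counts(gcm, group_a, group_b), method))
    core = core_functions(gcm)
    hits = occurrence_criterion(gcm, group_a, group_b) \
        if group_by == "niche" else []

    write_tsv(pd.concat([fisher, mw]), outdir / "enrichment.tsv",
              comments=[f"groups={group_by}", f"correction={method}",
                        "group_a=colonizers" if group_by == "niche" else ""])
    write_tsv(pd.DataFrame({"feature_id": core}), outdir / "core.tsv",
              index=False)
    write_tsv(pd.DataFrame({"feature_id": hits}),
              outdir / "criterion_hits.tsv", index=False,
              comments=["criterion=present in >70% colonizers and <20% "
                        "generalists"])
    return {"fisher": fisher, "mannwhitney": mw, "core": core,
            "criterion_hits": hits}
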