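"""Colonizer vs generalist classification from abundance–diatom coupling.

The central question: which MAGs track specific diatom species closely
enough to be plausible phycosphere colonizers?  The evidence chain is

1. redundancy analysis (RDA) of CLR-transformed MAG abundances on
   Hellinger-transformed diatom cell counts, with an ANOVA-like Monte Carlo
   permutation test of the model pseudo-F — establishes that diatom
   composition explains MAG community variation at all;
2. Spearman rank correlations between each MAG's relative abundance and
   each diatom's cell counts — identifies the specific couplings;
3. a rule set: a MAG is a putative colonizer iff it has at least one
   significant positive diatom correlation AND its abundance pattern is
   fluctuating (not persistently high).  Everything else is a putative
   generalist, with a machine-readable rationale code.

RDA here is multivariate least squares of the (column-centred) response on
the (column-centred) predictors: R² is the fraction of total response sum of
squares captured by the fitted values, the pseudo-F is
``(SS_fit/p) / (SS_res/(n-p-1))``, and canonical axis variances are the
eigenvalues of the fitted-value covariance.  Significance is assessed by
permuting response rows and recomputing F, with the add-one rule
``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix, PatternClusters
from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class DiatomCountTable:
    """Diatom species × sample cell counts (cells/L) with dominance flags.

    ``dominants`` maps year → species that had the highest cell count at
    that year's bloom peak (near-ties allowed, as blooms can be bimodal or
    co-dominated).
    """

    counts: pd.DataFrame
    sample_year: pd.Series
    dominants: dict[int, list[str]] = field(default_factory=dict)

    @property
    def species(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def flag_dominants(counts: pd.DataFrame, sample_year: pd.Series,
                   tie_fraction: float = 0.9) -> dict[int, list[str]]:
    """Flag the species with maximal count at each year's bloom peak.

    The bloom peak is the sample with the highest total diatom count;
    species within ``tie_fraction`` of the maximum there are co-dominant.
    """
    dominants: dict[int, list[str]] = {}
    for year in sorted(sample_year.unique()):
        cols = sample_year.index[sample_year == year]
        sub = counts[cols]
        peak = sub.sum(axis=0).idxmax()
        at_peak = sub[peak]
        cutoff = tie_fraction * at_peak.max()
        dominants[int(year)] = at_peak.index[at_peak >= cutoff].tolist()
    return dominants


@dataclass
class RDAResult:
    r2: float
    adj_r2: float | None
    F: float
    perm_p: float | None
    n_perm: int
    axis_variances: np.ndarray
    n_samples: int
    n_predictors: int
    dropped_predictors: list = field(default_factory=list)


@dataclass
class CorrelationResult:
    """Spearman rho / p per (MAG, diatom species) pair."""

    rho: pd.DataFrame          # MAG × species
    p: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha

    @property
    def positive(self) -> pd.DataFrame:
        return self.rho > 0


#: rationale codes for niche labels
POS_CORR = "POS_CORR"      # colonizer: significant positive diatom coupling
PERSISTENT = "PERSISTENT"  # generalist: consistently high abundance
NEG_ONLY = "NEG_ONLY"      # generalist: only negative significant couplings
NO_SIG = "NO_SIG"          # generalist: no significant coupling at all


@dataclass
class NicheLabels:
    labels: pd.Series      # mag -> colonizer | generalist
    rationale: pd.Series   # mag -> POS_CORR | PERSISTENT | NEG_ONLY | NO_SIG

    def __getitem__(self, mag: str) -> str:
        return self.labels[mag]

    @property
    def colonizers(self) -> list[str]:
        return self.labels.index[self.labels == "colonizer"].tolist()

    @property
    def generalists(self) -> list[str]:
        return self.labels.index[self.labels == "generalist"].tolist()


# ---------------------------------------------------------------------------
# transforms and ordination


def hellinger(diatoms: DiatomCountTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of each sample's species proportions.

    Returns a samples × species matrix whose rows have unit sum of squares.
    All-zero samples are left as NaN and logged.
    """
    counts = diatoms.counts if isinstance(diatoms, DiatomCountTable) else diatoms
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative diatom counts")
    mat = counts.to_numpy(dtype=float).T  # samples × species
    totals = mat.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("all-zero diatom samples flagged: %s",
                       counts.columns[empty].tolist())
    out = np.full_like(mat, np.nan)
    out[~empty] = np.sqrt(mat[~empty] / totals[~empty, None])
    return pd.DataFrame(out, index=counts.columns, columns=counts.index)


def _drop_collinear(X: np.ndarray, cols: list, tol: float = 1e-10):
    """QR with column pivoting: keep an independent column subset."""
    from scipy.linalg import qr as _qr
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0:
        return X[:, :0], [], list(cols)
    rank = int((diag > tol * diag[0]).sum()) if diag[0] > 0 else 0
    keep = sorted(piv[:rank])
    dropped = [cols[i] for i in sorted(piv[rank:])]
    return X[:, keep], [cols[i] for i in keep], dropped


def rda(Y: pd.DataFrame | AbundanceMatrix, X: pd.DataFrame,
        n_perm: int = 0, seed: int | None = None) -> RDAResult:
    """Redundancy analysis of responses ``Y`` on predictors ``X``.

    ``Y``: samples × responses (e.g. CLR MAG abundances transposed), or an
    :class:`AbundanceMatrix` (MAG × sample; transposed internally).
    ``X``: samples × predictors (e.g. Hellinger diatom counts).
    With ``n_perm > 0`` a Monte Carlo permutation test of the pseudo-F is
    run (rows of Y permuted).
    """
    if isinstance(Y, AbundanceMatrix):
        Y = Y.values.T
    common = Y.index.intersection(X.index)
    if len(common) < len(Y.index) or len(common) < len(X.index):
        Y, X = Y.loc[common], X.loc[common]
    if not Y.index.equals(X.index):
        X = X.loc[Y.index]
    Ym = Y.to_numpy(dtype=float)
    Xm = X.to_numpy(dtype=float)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    Xc = Xm - Xm.mean(axis=0)
    Xc, kept, dropped = _drop_collinear(Xc, list(X.columns))
    if dropped:
        warnings.warn(f"dropping collinear predictors: {dropped}")
    p = Xc.shape[1]
    if p == 0:
        raise ValueError("no independent predictors remain")
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yfit = Xc @ beta
    ss_tot = float((Yc ** 2).sum())
    ss_fit = float((Yfit ** 2).sum())
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot if ss_tot > 0 else np.nan
    if n - p - 1 > 0:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        F = (ss_fit / p) / (ss_res / (n - p - 1)) if ss_res > 0 else np.inf
    else:
        adj_r2 = None
        F = np.nan
    # canonical axis variances: eigenvalues of the fitted-value covariance
    sv = np.linalg.svd(Yfit, compute_uv=False)
    axis_var = (sv ** 2) / max(n - 1, 1)
    axis_var = axis_var[axis_var > 1e-12 * max(axis_var[0], 1.0)] \
        if axis_var.size else axis_var

    perm_p = None
    if n_perm > 0:
        perm_p = _permute_f(Yc, Xc, ss_fit, ss_tot, n_perm, seed)
    return RDAResult(r2=r2, adj_r2=adj_r2, F=float(F), perm_p=perm_p,
                     n_perm=n_perm, axis_variances=axis_var, n_samples=n,
                     n_predictors=p, dropped_predictors=dropped)


def _permute_f(Yc: np.ndarray, Xc: np.ndarray, ss_fit_obs: float,
               ss_tot: float, n_perm: int, seed: int | None) -> float:
    """Add-one permutation p-value for the RDA pseudo-F.

    SS_tot is invariant under row permutation, so F_perm >= F_obs iff
    SS_fit_perm >= SS_fit_obs; only the fitted sum of squares is recomputed.
    """
    rng = np.random.default_rng(seed)
    n = Yc.shape[0]
    # hat-matrix via QR once; fitted SS = ||Q^T Yp||^2
    Q, _ = np.linalg.qr(Xc)
    exceed = 0
    for _ in range(n_perm):
        Yp = Yc[rng.permutation(n)]
        Yp = Yp - Yp.mean(axis=0)
        ss_fit = float(((Q.T @ Yp) ** 2).sum())
        if ss_fit >= ss_fit_obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def permutation_test(Y: pd.DataFrame | AbundanceMatrix, X: pd.DataFrame,
                     n_perm: int = 999, seed: int | None = None) -> RDAResult:
    """RDA with an ANOVA-like Monte Carlo permutation test (rows of Y)."""
    return rda(Y, X, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# correlation screen


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n, no ties)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                       # n! × n
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman_pair(x: np.ndarray, y: np.ndarray,
                  exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair of series.

    Exact permutation p when n <= ``exact_max_n`` and neither series has
    ties; otherwise the t-approximation on ranked data.  Constant series
    give (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not has_ties:
        return rho, _spearman_exact_p(x, y, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_matrix(rel: AbundanceMatrix, diatoms: DiatomCountTable,
                    alpha: float = 0.05) -> CorrelationResult:
    """Spearman rho/p for every (MAG, diatom species) pair over shared samples.

    No multiplicity correction is applied to this screen (the significance
    threshold is a raw p < alpha); see the methods note.
    """
    common = rel.values.columns.intersection(diatoms.counts.columns)
    if len(common) < 3:
        raise ValueError("need >=3 paired samples for correlation")
    A = rel.values[common]
    D = diatoms.counts[common]
    rho = pd.DataFrame(np.nan, index=A.index, columns=D.index)
    pmat = pd.DataFrame(np.nan, index=A.index, columns=D.index)
    for mag in A.index:
        xa = A.loc[mag].to_numpy(dtype=float)
        for sp in D.index:
            r, p = spearman_pair(xa, D.loc[sp].to_numpy(dtype=float))
            rho.loc[mag, sp] = r
            pmat.loc[mag, sp] = p
    n_undef = int(rho.isna().sum().sum())
    if n_undef:
        logger.warning("%d undefined correlations (constant series) flagged",
                       n_undef)
    return CorrelationResult(rho=rho, p=pmat, alpha=alpha)


# ---------------------------------------------------------------------------
# classification


def classify(corr: CorrelationResult, clusters: PatternClusters,
             min_rho: float | None = None) -> NicheLabels:
    """Label MAGs as putative colonizers or generalists.

    colonizer ⇔ at least one diatom with a significant positive correlation
    (optionally rho > ``min_rho``) AND a fluctuating abundance pattern.
    Generalists carry the first matching rationale in the order
    PERSISTENT → NEG_ONLY → NO_SIG.
    """
    mags = corr.rho.index
    missing = mags.difference(clusters.assignments.index)
    if len(missing):
        raise KeyError(f"MAGs without cluster assignment: {list(missing)}")
    labels, rationale = {}, {}
    sig = corr.significant
    pos = corr.positive
    for mag in mags:
        s = sig.loc[mag].fillna(False)
        p = pos.loc[mag].fillna(False)
        strong = p if min_rho is None else (corr.rho.loc[mag] > min_rho)
        has_pos = bool((s & p & strong.fillna(False)).any())
        persistent = clusters[mag] == "persistent"
        if has_pos and not persistent:
            labels[mag], rationale[mag] = "colonizer", POS_CORR
        elif persistent:
            labels[mag], rationale[mag] = "generalist", PERSISTENT
        elif bool(s.any()):
            labels[mag], rationale[mag] = "generalist", NEG_ONLY
        else:
            labels[mag], rationale[mag] = "generalist", NO_SIG
    return NicheLabels(pd.Series(labels, name="label"),
                       pd.Series(rationale, name="rationale"))


def rda_per_year(clr: AbundanceMatrix, diatoms: DiatomCountTable,
                 n_perm: int = 999, seed: int | None = None
                 ) -> dict[int, RDAResult]:
    """Run RDA separately within each bloom year."""
    results = {}
    for i, year in enumerate(sorted(diatoms.sample_year.unique())):
        cols = diatoms.sample_year.index[diatoms.sample_year == year]
        cols = clr.values.columns.intersection(cols)
        Y = clr.values[cols].T
        H = hellinger(diatoms.counts[cols])
        sub_seed = None if seed is None else seed + i
        results[int(year)] = rda(Y, H, n_perm=n_perm, seed=sub_seed)
    return results


def significant_species(clr: AbundanceMatrix, diatoms: DiatomCountTable,
                        per_year: dict[int, RDAResult],
                        loading_quantile: float = 0.25,
                        alpha: float = 0.05) -> set[str]:
    """Diatom species with non-trivial RDA loading in any significant year.

    A species qualifies if, in a year whose permutation p < alpha, the norm
    of its fitted-regression coefficient row is above the
    ``loading_quantile`` quantile across species for that year.
    """
    out: set[str] = set()
    for year, res in per_year.items():
        if res.perm_p is None or res.perm_p >= alpha:
            continue
        cols = diatoms.sample_year.index[diatoms.sample_year == year]
        cols = clr.values.columns.intersection(cols)
        H = hellinger(diatoms.counts[cols])
        Yc = clr.values[cols].T.to_numpy(dtype=float)
        Yc = Yc - Yc.mean(axis=0)
        Xc = H.to_numpy(dtype=float)
        Xc = Xc - Xc.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        norms = np.linalg.norm(beta, axis=1)
        cutoff = np.quantile(norms, loading_quantile)
        out |= {sp for sp, nv in zip(H.columns, norms) if nv >= cutoff}
    return out


def export_network(corr: CorrelationResult, labels: NicheLabels,
                   diatoms: DiatomCountTable,
                   species_filter: set[str] | None = None) -> pd.DataFrame:
    """Edge table of significant positive MAG–diatom correlations.

    Columns: mag_id, species_id, rho, dominance_years, significant.
    ``species_filter`` (e.g. RDA-significant species) restricts the diatom
    side when given.
    """
    year_of: dict[str, list[int]] = {}
    for year, specs in diatoms.dominants.items():
        for sp in specs:
            year_of.setdefault(sp, []).append(int(year))
    rows = []
    mask = corr.significant & corr.positive
    for mag in corr.rho.index:
        for sp in corr.rho.columns:
            if not bool(mask.loc[mag, sp]):
                continue
            if species_filter is not None and sp not in species_filter:
                continue
            rows.append({
                "mag_id": mag, "species_id": sp,
                "rho": float(corr.rho.loc[mag, sp]),
                "mag_label": labels[mag],
                "dominance_years": ",".join(
                    str(y) for y in sorted(year_of.get(sp, []))),
                "significant": True,
            })
    return pd.DataFrame(
        rows, columns=["mag_id", "species_id", "rho", "mag_label",
                       "dominance_years", "significant"])


# ---------------------------------------------------------------------------
# file-level pipeline


def load_diatoms(path: str | Path,
                 sample_year: pd.Series | None = None) -> DiatomCountTable:
    counts = read_tsv(path)
    if sample_year is None:
        # sample ids of the form <year>-<week>
        sample_year = pd.Series(
            [int(str(c).split("-")[0]) for c in counts.columns],
            index=counts.columns)
    dom = flag_dominants(counts, sample_year)
    return DiatomCountTable(counts=counts, sample_year=sample_year,
                            dominants=dom)


def run(indir: str | Path, outdir: str | Path, n_perm: int = 999,
        seed: int | None = None) -> dict:
    """File-level entry point: abundance tables + diatoms → niche labels."""
    indir, outdir = Path(indir), Path(outdir)
    rel = AbundanceMatrix(read_tsv(indir / "abundance_relabund.tsv"),
                          unit="relabund")
    clrm = AbundanceMatrix(read_tsv(indir / "abundance_clr.tsv"), unit="clr")
    clusters_df = read_tsv(indir / "clusters.tsv")
    clusters = PatternClusters(clusters_df["cluster"], None)
    diatoms = load_diatoms(indir / "diatoms.tsv")

    per_year = rda_per_year(clrm, diatoms, n_perm=n_perm, seed=seed)
    corr = spearman_matrix(rel, diatoms)
    labels = classify(corr, clusters)
    spec_sig = significant_species(clrm, diatoms, per_year)
    edges = export_network(corr, labels, diatoms, species_filter=spec_sig)

    rda_rows = [{"year": y, "r2": r.r2, "adj_r2": r.adj_r2, "F": r.F,
                 "perm_p": r.perm_p, "n_perm": r.n_perm,
                 "n_samples": r.n_samples, "n_predictors": r.n_predictors}
                for y, r in per_year.items()]
    write_tsv(pd.DataFrame(rda_rows), outdir / "rda_per_year.tsv",
              index=False, comments=[f"seed={seed}"])
    write_tsv(corr.rho, outdir / "correlations.tsv",
              comments=["value=spearman_rho"])
    write_tsv(corr.p, outdir / "correlation_p.tsv")
    out = pd.concat([labels.labels, labels.rationale], axis=1)
    write_tsv(out, outdir / "niche_labels.tsv")
    write_tsv(edges, outdir / "network_edges.tsv", index=False)
    return {"rda": per_year, "corr": corr, "labels": labels, "edges": edges}
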