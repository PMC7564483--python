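"""Cohort-level inferential statistics.

Nonparametric two-group comparison (Mann-Whitney U, exact by enumeration
for small tie-free samples), Spearman rank correlation, the pooled
two-proportion z-test used to compare signature coverages, PCA-based
grouping of panel miRNAs into co-regulated sets, and KRAS-stratified
per-miRNA testing. Raw p-values are reported throughout with the number of
tests performed alongside — no multiple-testing correction is applied, so
readers can apply their own.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .calling import CallTable, coverage
from .errors import ConfigurationError, DegenerateDataError, GroupingError
from .screen import CASE

EXACT_MW_MAX_N = 12  # total sample size up to which the exact U null is used
EXACT_SPEARMAN_MAX_N = 8  # full permutation enumeration up to this n


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # "U", "rho", or "Z"
    statistic: float
    p_value: float
    n1: int
    n2: int
    method_note: str


@dataclass(frozen=True)
class SignatureComparison:
    """Pooled two-proportion z comparison of two panels' >=k coverage."""

    panel_a: tuple[str, ...]
    panel_b: tuple[str, ...]
    k: int
    x_a: int
    x_b: int
    n: int
    fraction_a: float
    fraction_b: float
    z: float
    p_value: float


@dataclass
class MirnaSetGrouping:
    sets: dict[int, list[str]]
    loadings: pd.DataFrame  # miRNAs x retained PCs
    variance_fraction: np.ndarray
    within_set_correlations: pd.DataFrame  # mirna_a, mirna_b, set, rho, p
    dropped: list[str]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution of U is used when n1 + n2 <=
    ``EXACT_MW_MAX_N`` and the pooled data are tie-free; otherwise the
    normal approximation with tie correction. Identical pooled values carry
    no ordering information: U is its null mean and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise GroupingError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups", stacklevel=2)
        return TestResult("U", len(a) * len(b) / 2, 1.0, len(a), len(b), "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        note = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        note = "normal-approximation"
    return TestResult(
        "U", float(res.statistic), float(min(res.pvalue, 1.0)), len(a), len(b), note
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for |rho| by full enumeration of pairings."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    hits = total = 0
    ry_c0 = ry - ry.mean()
    norm_y = np.sqrt((ry_c0**2).sum())
    tol = 1e-12
    for perm in itertools.permutations(range(len(y))):
        ry_p = ry_c0[list(perm)]
        rho = float(rx_c @ ry_p) / (denom * norm_y)
        total += 1
        if abs(rho) >= abs(rho_obs) - tol:
            hits += 1
    return hits / total


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation on mid-ranks.

    p by full permutation enumeration when n <= ``EXACT_SPEARMAN_MAX_N``,
    else the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigurationError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise ConfigurationError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant vector: rho undefined")
    rho, p_t = sps.spearmanr(x, y)
    if len(x) <= EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(x, y, float(rho))
        note = "exact-permutation"
    else:
        p, note = float(p_t), "t-approximation"
    return TestResult("rho", float(rho), min(float(p), 1.0), len(x), len(y), note)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test, no continuity correction.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    p = (x1+x2)/(n1+n2); two-sided p from the standard normal.
    """
    for x, n, tag in ((x1, n1, "first"), (x2, n2, "second")):
        if n <= 0:
            raise ConfigurationError(f"{tag} sample size must be positive")
        if not 0 <= x <= n:
            raise ConfigurationError(f"{tag} count must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateDataError("pooled proportion is 0 or 1: z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * sps.norm.sf(abs(z))
    return TestResult("Z", float(z), float(min(p, 1.0)), n1, n2, "pooled-normal")


def _subset_table(table: CallTable, panel: Sequence[str]) -> CallTable:
    mask = table.calls["mirna_id"].isin(panel)
    return CallTable(calls=table.calls[mask].reset_index(drop=True), panel=list(panel))


def compare_signatures(
    table_full: CallTable,
    panel_a: Sequence[str],
    panel_b: Sequence[str],
    k: int = 2,
) -> SignatureComparison:
    """Compare two panels' >=k dysregulation coverage on the same patients.

    Each panel's flagged-patient count is computed from the full call
    table restricted to that panel, then the two proportions (same
    denominator) are compared with the pooled z-test.
    """
    shared = set(panel_a) & set(panel_b)
    if shared:
        warnings.warn(
            f"panels overlap ({sorted(shared)}): shared miRNAs count in both",
            stacklevel=2,
        )
    missing = (set(panel_a) | set(panel_b)) - set(table_full.panel)
    if missing:
        raise ConfigurationError(f"panel miRNAs not in call table: {sorted(missing)}")
    cov_a = coverage(_subset_table(table_full, panel_a), k)
    cov_b = coverage(_subset_table(table_full, panel_b), k)
    if cov_a.n_patients != cov_b.n_patients:
        raise ConfigurationError("panels must be measured on the same patients")
    res = two_proportion_z(cov_a.n_flagged, cov_a.n_patients, cov_b.n_flagged, cov_b.n_patients)
    return SignatureComparison(
        panel_a=tuple(panel_a),
        panel_b=tuple(panel_b),
        k=k,
        x_a=cov_a.n_flagged,
        x_b=cov_b.n_flagged,
        n=cov_a.n_patients,
        fraction_a=cov_a.fraction,
        fraction_b=cov_b.fraction,
        z=res.statistic,
        p_value=res.p_value,
    )


def group_mirna_sets(
    levels: pd.DataFrame,
    n_sets: int = 3,
    n_components: int = 3,
    pseudocount: float = 0.5,
    random_state: int = 0,
) -> MirnaSetGrouping:
    """Partition panel miRNAs into co-regulated sets from PCA loadings.

    ``levels`` is a patients x miRNAs matrix of copies/µL. Each miRNA
    column is log-transformed and standardized, a PCA across patients is
    taken, and miRNAs are clustered (k-means) on their loadings over the
    first ``n_components`` retained components. Within-set pairwise
    Spearman correlations are reported so co-regulation claims can be read
    off directly.
    """
    if levels.shape[0] < 3:
        raise ConfigurationError("need at least 3 patients")
    if n_sets > levels.shape[1]:
        raise ConfigurationError("n_sets must not exceed the panel size")
    X = np.log(levels.to_numpy(dtype=float) + pseudocount)
    stds = X.std(axis=0, ddof=0)
    tol = 1e-10 * max(1.0, float(np.abs(X).max()))  # constant up to float noise
    dropped = list(levels.columns[stds <= tol])
    keep = stds > tol
    if dropped:
        warnings.warn(f"constant miRNA column(s) dropped: {dropped}", stacklevel=2)
    X = X[:, keep]
    cols = list(levels.columns[keep])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    pca.fit(X)
    # biplot-style loadings: component weights scaled by the component's
    # standard deviation, so low-variance trailing PCs cannot dominate the
    # clustering geometry
    scaled = pca.components_.T * np.sqrt(pca.explained_variance_)
    loadings = pd.DataFrame(
        scaled, index=cols, columns=[f"PC{i + 1}" for i in range(k)]
    )
    km = KMeans(n_clusters=n_sets, n_init=10, random_state=random_state)
    labels = km.fit_predict(loadings.to_numpy())
    sets: dict[int, list[str]] = {
        s: [c for c, l in zip(cols, labels) if l == s] for s in range(n_sets)
    }
    rows = []
    raw = levels[cols]
    for s, members in sets.items():
        for a, b in itertools.combinations(members, 2):
            res = spearman(raw[a].to_numpy(), raw[b].to_numpy())
            rows.append(
                {"mirna_a": a, "mirna_b": b, "set": s, "rho": res.statistic,
                 "p_value": res.p_value}
            )
    within = pd.DataFrame(rows, columns=["mirna_a", "mirna_b", "set", "rho", "p_value"])
    return MirnaSetGrouping(
        sets=sets,
        loadings=loadings,
        variance_fraction=pca.explained_variance_ratio_,
        within_set_correlations=within,
        dropped=dropped,
    )


def kras_stratified_tests(
    ddpcr: pd.DataFrame,
    meta: pd.DataFrame,
    panel: Sequence[str],
) -> pd.DataFrame:
    """Per-miRNA Mann-Whitney comparison of KRAS-mutant vs wild-type patients.

    Only CASE samples enter; each panel miRNA's copies/µL are compared
    between the MUT and WT strata. Returns a tidy frame with the U
    statistic, raw two-sided p, stratum sizes, and the total number of
    tests performed (no correction applied).
    """
    cases = meta.index[meta["group"] == CASE]
    mut = [s for s in cases if meta.loc[s, "kras_status"] == "MUT"]
    wt = [s for s in cases if meta.loc[s, "kras_status"] == "WT"]
    if not mut:
        raise GroupingError("KRAS MUT stratum is empty")
    if not wt:
        raise GroupingError("KRAS WT stratum is empty")
    wide = ddpcr.pivot(index="sample_id", columns="mirna_id", values="copies_per_ul")
    rows = []
    for mirna in panel:
        vals_mut = wide.loc[wide.index.isin(mut), mirna].dropna()
        vals_wt = wide.loc[wide.index.isin(wt), mirna].dropna()
        res = mann_whitney(vals_mut.to_numpy(), vals_wt.to_numpy())
        rows.append(
            {
                "mirna_id": mirna,
                "U": res.statistic,
                "p_value": res.p_value,
                "n_mut": res.n1,
                "n_wt": res.n2,
                "method": res.method_note,
            }
        )
    out = pd.DataFrame(rows)
    out["n_tests"] = len(panel)
    return out
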