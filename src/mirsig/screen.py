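"""NGS training-set screen: normalization, fold changes, candidate filters.

The screening stage of the pipeline mirrors a small-cohort plasma miRNome
experiment: a handful of case and control sequencing libraries are
depth-normalized with median-of-ratios size factors, per-miRNA case/control
fold changes are computed on the normalized group means, and candidates are
retained by a conjunction of filters — fold-change magnitude, control-group
variability, minimum absolute abundance in an orthogonal ddPCR assay, and
assay availability. Exploratory structure (PCA, hierarchical clustering on
correlation distance) is exposed alongside.

The screen is deliberately a fold-change ranking, not a per-miRNA hypothesis
test: with 3-vs-5 libraries a dispersion-based test has essentially no power
and the downstream ddPCR validation is the real arbiter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    GroupingError,
    NormalizationError,
)

CONTROL = "CONTROL"
CASE = "CASE"


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


class FilterTag(str, Enum):
    """First failing filter, in the fixed order FC, VARIABILITY, ABUNDANCE, ASSAY."""

    FC = "FC"
    VARIABILITY = "VARIABILITY"
    ABUNDANCE = "ABUNDANCE"
    ASSAY = "ASSAY"
    MISSING = "MISSING"


@dataclass
class CountMatrix:
    """Raw miRNA read counts, miRNAs x samples, with per-sample group labels.

    ``counts`` is a DataFrame indexed by miRNA id with sample-id columns;
    ``group`` maps each sample id to CONTROL or CASE.
    """

    counts: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.counts.columns)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise ConfigurationError(f"samples without group label: {missing}")
        bad = set(self.group.unique()) - {CONTROL, CASE}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ConfigurationError("duplicate miRNA ids in count matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])


@dataclass(frozen=True)
class FoldChangeRecord:
    """Case-vs-control fold change of one miRNA on normalized means.

    ``fc`` is the magnitude convention of bench practice: always >= 1, with
    the sign carried separately as ``direction`` (UP when the case mean is
    the larger one).
    """

    mirna_id: str
    case_mean: float
    control_mean: float
    fc: float
    direction: Direction


@dataclass
class ScreenConfig:
    """Thresholds of the candidate filters.

    fc_threshold
        Strict lower bound on fold-change magnitude (default 2.0; the
        looser discovery pass of the original workflow used 1.5).
    variability_cv_threshold
        Maximum control-group coefficient of variation (sample SD / mean);
        candidates more variable than this across controls are dropped.
    min_ddpcr_copies
        Minimum absolute control-level abundance in copies/µL; analytes
        below 0.2 copies/µL are too dilute to call reliably by ddPCR.
    pseudocount
        Added to group means before ratio formation so all-zero rows give a
        finite fold change.
    assay_available
        Optional per-miRNA mask; miRNAs without a commercial ddPCR assay
        cannot be validated and are excluded.
    """

    fc_threshold: float = 2.0
    variability_cv_threshold: float = 2.5
    min_ddpcr_copies: float = 0.2
    pseudocount: float = 0.5
    assay_available: Mapping[str, bool] | None = None

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "variability_cv_threshold", "min_ddpcr_copies"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")


@dataclass
class ScreenResult:
    candidates: list[FoldChangeRecord]
    excluded: dict[str, FilterTag]
    size_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def candidate_ids(self) -> list[str]:
        return [r.mirna_id for r in self.candidates]


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios sequencing-depth size factors.

    For each sample, the factor is the median over miRNAs (restricted to
    rows positive in every sample) of the ratio count / geometric-mean of
    that row across samples, rescaled so the factors multiply to 1.
    Dividing each sample's counts by its factor puts the libraries on a
    common depth scale; with the unit-product convention, multiplying one
    sample's counts by c multiplies exactly its factor by c.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no miRNA has positive counts in every sample; add a pseudocount "
            "or filter samples before normalizing"
        )
    ref = values[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    log_factors = np.median(ratios, axis=0)
    factors = np.exp(log_factors - log_factors.mean())  # geometric mean 1
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalize(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(counts)
    return counts.counts / factors.reindex(counts.counts.columns)


def fold_changes(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> list[FoldChangeRecord]:
    """Per-miRNA case-vs-control fold change of normalized group means."""
    cases = counts.samples_in(CASE)
    controls = counts.samples_in(CONTROL)
    if not cases or not controls:
        raise GroupingError("both CASE and CONTROL groups must be non-empty")
    norm = normalize(counts, factors)
    case_means = norm[cases].mean(axis=1) + pseudocount
    control_means = norm[controls].mean(axis=1) + pseudocount
    records = []
    for mirna in counts.mirna_ids:
        cm, tm = float(case_means[mirna]), float(control_means[mirna])
        if cm > tm:
            fc, direction = cm / tm, Direction.UP
        elif cm < tm:
            fc, direction = tm / cm, Direction.DOWN
        else:
            fc, direction = 1.0, Direction.NONE
        records.append(FoldChangeRecord(mirna, cm, tm, fc, direction))
    return records


def control_cv(values: Sequence[float]) -> float:
    """Sample-SD coefficient of variation (ddof=1) of control-group values."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise DegenerateDataError("CV needs at least two control values")
    mean = arr.mean()
    if mean == 0:
        return np.inf
    return float(arr.std(ddof=1) / mean)


def apply_filters(
    fcs: Sequence[FoldChangeRecord],
    control_values: Mapping[str, Sequence[float]],
    ddpcr_control: Mapping[str, float],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Candidate selection as a conjunction of filters.

    A miRNA survives iff its fold-change magnitude strictly exceeds
    ``fc_threshold`` AND its control CV is <= ``variability_cv_threshold``
    AND its ddPCR control level is >= ``min_ddpcr_copies`` AND an assay is
    available. Excluded miRNAs are tagged with the *first* failing filter in
    the order FC, VARIABILITY, ABUNDANCE, ASSAY (the surviving set does not
    depend on this order). A candidate that passed the FC cut but has no
    ddPCR measurement is tagged MISSING and excluded: absence of an absolute
    quantification is not evidence of abundance.
    """
    config = config or ScreenConfig()
    candidates: list[FoldChangeRecord] = []
    excluded: dict[str, FilterTag] = {}
    for rec in fcs:
        if not rec.fc > config.fc_threshold:
            excluded[rec.mirna_id] = FilterTag.FC
            continue
        cv = control_cv(control_values[rec.mirna_id])
        if cv > config.variability_cv_threshold:
            excluded[rec.mirna_id] = FilterTag.VARIABILITY
            continue
        level = ddpcr_control.get(rec.mirna_id)
        if level is None or (isinstance(level, float) and np.isnan(level)):
            excluded[rec.mirna_id] = FilterTag.MISSING
            continue
        if level < config.min_ddpcr_copies:
            excluded[rec.mirna_id] = FilterTag.ABUNDANCE
            continue
        if config.assay_available is not None and not config.assay_available.get(
            rec.mirna_id, False
        ):
            excluded[rec.mirna_id] = FilterTag.ASSAY
            continue
        candidates.append(rec)
    return ScreenResult(candidates=candidates, excluded=excluded)


def run_screen(
    counts: CountMatrix,
    ddpcr_control: Mapping[str, float],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Normalize, compute fold changes, and filter — the full training screen.

    ``ddpcr_control`` maps miRNA id to its mean control-group copies/µL;
    miRNAs absent from it that pass the FC cut are tagged MISSING.
    """
    config = config or ScreenConfig()
    factors = size_factors(counts)
    fcs = fold_changes(counts, factors, config.pseudocount)
    norm = normalize(counts, factors)
    controls = counts.samples_in(CONTROL)
    control_vals = {m: norm.loc[m, controls].to_numpy() for m in counts.mirna_ids}
    result = apply_filters(fcs, control_vals, ddpcr_control, config)
    result.size_factors = factors
    return result


@dataclass
class PcaResult:
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    variance_fraction: np.ndarray
    scores: pd.DataFrame  # samples x components


def pca_embed(
    matrix: pd.DataFrame,
    log_transform: bool = True,
    pseudocount: float = 0.5,
    n_components: int | None = None,
) -> PcaResult:
    """Centered PCA of a samples-x-features abundance matrix.

    With ``log_transform`` the matrix is first mapped through
    ``log(x + pseudocount)``, the conventional variance-stabilization for
    count-like abundances spanning orders of magnitude.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DegenerateDataError("PCA needs at least 2 samples and 2 features")
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        X = np.log(X + pseudocount)
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateDataError("constant matrix: no variance to decompose")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        components=pca.components_,
        variance_fraction=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
    )


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    dropped: list[str]


def hierarchical_order(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage agglomeration of rows on correlation distance.

    Distance between two rows is 1 - Pearson r. Zero-variance rows have no
    defined correlation and are dropped (reported in ``dropped``).
    """
    variances = matrix.var(axis=1, ddof=0)
    dropped = list(matrix.index[variances == 0])
    kept = matrix.drop(index=dropped)
    if kept.shape[0] < 2:
        raise DegenerateDataError("need at least 2 rows with variance to cluster")
    corr = np.corrcoef(kept.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [kept.index[i] for i in leaves_list(Z)]
    return ClusterResult(linkage_matrix=Z, leaf_order=order, dropped=dropped)
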