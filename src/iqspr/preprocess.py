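"""Descriptor pre-selection, autoscaling, Kennard-Stone splitting and the
isocratic lipophilicity fit.

Pre-selection applies three filters in a fixed order — relative standard
deviation (near-constant descriptors), pairwise correlation (redundant
descriptors, keeping the member better correlated with the responses), and
zero-value removal for continuous descriptors — mirroring standard
chemometric practice for reducing a Dragon-scale descriptor block before
variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import DescriptorTable, PropertyTable, RetentionSeries, ValidationError


@dataclass
class FilterReport:
    """Fate of every descriptor through the pre-selection chain."""

    removed_by_rsd: list[str] = field(default_factory=list)
    removed_by_correlation: list[str] = field(default_factory=list)
    removed_by_zero: list[str] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    def all_names(self) -> list[str]:
        return (
            self.removed_by_rsd
            + self.removed_by_correlation
            + self.removed_by_zero
            + self.surviving
        )


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class LipophilicityFit:
    """log k = log k_w + S*phi — intercept is the extrapolated lipophilicity."""

    logkw: float
    S: float
    residual_sse: float


# ---------------------------------------------------------------------------
# Filters


def rsd_filter(desc: DescriptorTable, threshold_pct: float = 5.0,
               remove_high: bool = False) -> list[str]:
    """Names of descriptors removed by the relative-standard-deviation rule.

    RSD = 100 * sample sd / |mean|. Descriptors with RSD below
    ``threshold_pct`` (near-constant) are removed; all-zero columns (sd = 0,
    mean = 0) are removed; mean 0 with positive sd leaves RSD undefined and
    the descriptor is kept. ``remove_high`` inverts the rule.
    """
    if desc.n_compounds < 2:
        raise ValidationError("RSD filter needs at least 2 compounds")
    sd = desc.values.std(axis=0, ddof=1)
    mean = desc.values.mean(axis=0)
    removed = []
    for j, name in enumerate(desc.descriptor_names):
        if sd[j] == 0.0 and mean[j] == 0.0:
            removed.append(name)
            continue
        if mean[j] == 0.0:
            continue  # RSD undefined -> keep
        rsd = 100.0 * sd[j] / abs(mean[j])
        if (rsd > threshold_pct) if remove_high else (rsd < threshold_pct):
            removed.append(name)
    return removed


def correlation_filter(desc: DescriptorTable, props: PropertyTable,
                       threshold: float = 0.8) -> list[str]:
    """Names removed by the pairwise-correlation rule.

    For every descriptor pair with |Pearson r| > threshold, the member whose
    best |r| against the two responses is lower is removed. Pairs are
    processed in descending |r|; pairs with an already-removed member are
    skipped. Zero-variance descriptors are treated as correlation 0 (they are
    the RSD filter's job). Ties in response correlation keep the descriptor
    earlier in column order.
    """
    X = desc.values
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
        C = np.where(np.isfinite(C), C, 0.0)
        ry = np.zeros(p)
        Y = props.Y
        for j in range(p):
            if sd[j] == 0:
                continue
            r1 = _pearson(X[:, j], Y[:, 0])
            r2 = _pearson(X[:, j], Y[:, 1])
            ry[j] = max(abs(r1), abs(r2))
    iu, ju = np.triu_indices(p, k=1)
    absr = np.abs(C[iu, ju])
    mask = absr > threshold
    order = np.argsort(-absr[mask], kind="stable")
    pairs = list(zip(iu[mask][order], ju[mask][order]))
    removed: set[int] = set()
    for a, b in pairs:
        if a in removed or b in removed:
            continue
        # keep the one better correlated with Y; tie -> keep earlier column
        loser = b if ry[a] >= ry[b] else a
        removed.add(loser)
    return [desc.descriptor_names[j] for j in sorted(removed)]


def zero_filter(desc: DescriptorTable) -> list[str]:
    """Continuous descriptors containing any exact zero; binary/integer exempt."""
    removed = []
    for j, (name, kind) in enumerate(zip(desc.descriptor_names, desc.kinds)):
        if kind == "continuous" and np.any(desc.values[:, j] == 0.0):
            removed.append(name)
    return removed


def apply_filters(desc: DescriptorTable, props: PropertyTable,
                  rsd_threshold_pct: float = 5.0,
                  corr_threshold: float = 0.8) -> tuple[DescriptorTable, FilterReport]:
    """Full pre-selection chain: RSD -> correlation -> zero."""
    report = FilterReport()
    report.removed_by_rsd = rsd_filter(desc, rsd_threshold_pct)
    keep = [n for n in desc.descriptor_names if n not in set(report.removed_by_rsd)]
    desc = desc.subset(keep)
    report.removed_by_correlation = correlation_filter(desc, props, corr_threshold)
    keep = [n for n in desc.descriptor_names
            if n not in set(report.removed_by_correlation)]
    desc = desc.subset(keep)
    report.removed_by_zero = zero_filter(desc)
    report.surviving = [n for n in desc.descriptor_names
                        if n not in set(report.removed_by_zero)]
    if not report.surviving:
        raise ValidationError("no descriptors survive pre-selection")
    return desc.subset(report.surviving), report


# ---------------------------------------------------------------------------
# Autoscaling


class Autoscaler(TransformerMixin, BaseEstimator):
    """Column-wise centring and unit-variance scaling with the sample (n-1) sd.

    The chemometric convention (sample sd) differs from
    ``sklearn.preprocessing.StandardScaler`` (population sd); leverage,
    Hotelling T2 and DModX limits all presuppose the former, so the package
    uses this transformer throughout.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValidationError("autoscaling needs >= 2 training rows")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = np.nonzero(self.scale_ == 0.0)[0]
        if zero.size:
            raise ValidationError(f"zero-variance column(s) at index {zero.tolist()}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float, ensure_2d=True)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def autoscale(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Functional wrapper: returns (scaled train, scaled apply_to, scaler)."""
    scaler = Autoscaler().fit(train)
    train_s = scaler.transform(train)
    other = scaler.transform(apply_to) if apply_to is not None else None
    return train_s, other, scaler


# ---------------------------------------------------------------------------
# Kennard-Stone


def kennard_stone_indices(X: np.ndarray, n_train: int) -> list[int]:
    """Classic max-min Kennard-Stone selection on a (scaled) matrix.

    Seeds with the pair at maximum Euclidean distance, then repeatedly adds
    the sample whose minimum distance to the selected set is largest. Ties
    break on the lowest row index. Deterministic.
    """
    n = X.shape[0]
    if not 1 < n_train <= n:
        raise ValidationError(f"n_train={n_train} out of range for n={n}")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    i, j = np.unravel_index(np.argmax(D), D.shape)  # argmax: first (lowest) index
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    mind = D[:, selected].min(axis=1)
    while len(selected) < n_train:
        best = max(remaining, key=lambda k: (mind[k], -k))
        selected.append(best)
        remaining.remove(best)
        mind = np.minimum(mind, D[:, best])
    return selected


def kennard_stone_split(desc: DescriptorTable, n_train: int) -> SplitResult:
    """Split compounds into a representative training set and a test set.

    Distances are computed on autoscaled descriptors so that every descriptor
    contributes on the same footing.
    """
    if desc.n_compounds == n_train:
        return SplitResult(list(desc.compound_ids), [])
    X = desc.values
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0  # constant columns carry no distance information
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    sel = kennard_stone_indices(Xs, n_train)
    selset = set(sel)
    train_ids = [desc.compound_ids[k] for k in sel]
    test_ids = [c for k, c in enumerate(desc.compound_ids) if k not in selset]
    return SplitResult(train_ids, test_ids)


# ---------------------------------------------------------------------------
# Lipophilicity fit


def fit_logkw(series: RetentionSeries) -> LipophilicityFit:
    """Ordinary least-squares line of log k on phi.

    The intercept at phi = 0 is the extrapolated chromatographic
    lipophilicity log k_w; the slope S is the solvent-strength parameter.
    """
    res = stats.linregress(series.phi, series.logk)
    pred = res.intercept + res.slope * series.phi
    sse = float(((series.logk - pred) ** 2).sum())
    return LipophilicityFit(logkw=float(res.intercept), S=float(res.slope),
                            residual_sse=sse)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
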