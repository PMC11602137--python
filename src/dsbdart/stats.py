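"""Metagene aggregation, windowed fold changes, rank-sum testing, replicate PCA, 2^-DDCt.

These are the numerical summaries behind the figures: per-bin metagene means
with standard errors, per-site coverage sums in a window around the DSB,
log2 fold changes between condition and control, the two-sample Wilcoxon
(Mann-Whitney) test used on fold-change distributions, and a PCA over
per-site coverage to check replicate agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import FlankMatrix
from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Per-bin mean CPM (and SEM) across a group of DSB sites."""

    mean: np.ndarray
    sem: np.ndarray
    label: str
    n_sites: int
    flank: int
    bin_size: int

    @property
    def offsets(self) -> np.ndarray:
        """Signed bp offset of each bin start relative to the anchor."""
        return np.arange(-self.flank, self.flank, self.bin_size)


def metagene_profile(
    matrix: FlankMatrix, site_subset: Sequence[str] | None = None, label: str = ""
) -> MetageneProfile:
    """Column-wise mean over the selected rows; SEM = sample SD / sqrt(n) (0 when n = 1)."""
    if site_subset is not None:
        if len(site_subset) == 0:
            raise ValidationError("empty site subset")
        matrix = matrix.subset(list(site_subset))
    if matrix.values.shape[0] == 0:
        raise ValidationError("metagene over an empty matrix")
    n = matrix.values.shape[0]
    mean = matrix.values.mean(axis=0)
    sem = (
        matrix.values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    )
    return MetageneProfile(
        mean=mean,
        sem=sem,
        label=label or matrix.orientation,
        n_sites=n,
        flank=matrix.flank,
        bin_size=matrix.bin_size,
    )


def window_coverage(
    matrix: FlankMatrix, center_offset: int = 0, width: int = 500
) -> pd.Series:
    """Per-site sum of bin values over a ``width``-bp window centered ``center_offset``
    bp from the anchor (signed; positive = rightwards in genomic coordinates).

    With the defaults this is the DSB-centered 500-bp box-plot quantity; offsets
    of 1000/2000/3000 give the distance-resolved variant.
    """
    lo_bp = center_offset - width // 2
    hi_bp = lo_bp + width
    if lo_bp < -matrix.flank or hi_bp > matrix.flank:
        raise ValidationError(
            f"window [{lo_bp}, {hi_bp}) bp exceeds flank +/-{matrix.flank}"
        )
    lo_bin = (lo_bp + matrix.flank) // matrix.bin_size
    hi_bin = -((-(hi_bp + matrix.flank)) // matrix.bin_size)
    sums = matrix.values[:, lo_bin:hi_bin].sum(axis=1)
    return pd.Series(sums, index=pd.Index(matrix.site_ids, name="site_id"), name="coverage")


def log2_fold_change(
    cond: FlankMatrix,
    ctrl: FlankMatrix,
    center_offset: int = 0,
    width: int = 500,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-site log2 fold change of windowed coverage, condition over control.

    Returns a DataFrame with columns ``coverage_cond``, ``coverage_ctrl``,
    ``log2fc`` and ``excluded`` (True where both windowed coverages are 0;
    such sites are flagged for exclusion from downstream tests). The window
    and pseudocount are recorded in ``DataFrame.attrs``.
    """
    if not cond.same_shape_as(ctrl):
        raise ValidationError("condition and control matrices differ in sites or shape")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    w_cond = window_coverage(cond, center_offset, width)
    w_ctrl = window_coverage(ctrl, center_offset, width)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((w_cond + pseudocount) / (w_ctrl + pseudocount))
    out = pd.DataFrame(
        {
            "coverage_cond": w_cond,
            "coverage_ctrl": w_ctrl,
            "log2fc": lfc,
            "excluded": (w_cond == 0) & (w_ctrl == 0),
        }
    )
    out.attrs.update(center_offset=center_offset, width=width, pseudocount=pseudocount)
    n_excl = int(out["excluded"].sum())
    if n_excl:
        logger.info("log2_fold_change: %d sites with zero coverage in both conditions", n_excl)
    return out


@dataclass
class RankSumResult:
    """Mann-Whitney U with the branch actually used (exact vs normal approximation)."""

    statistic: float
    pvalue: float
    method: str
    n: int
    m: int


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> RankSumResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test via midranks.

    The exact null distribution (full enumeration over rank assignments) is
    used when ``n + m <= 12`` and the pooled sample is tie-free; otherwise the
    normal approximation with tie-corrected variance and continuity correction.
    ``statistic`` is the U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and tie_free:
        method = "exact"
    else:
        method = "normal-approximation"
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=method,
        n=int(x.size),
        m=int(y.size),
    )


@dataclass
class PcaResult:
    """Per-sample principal-component coordinates and explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]


def pca_samples(per_site_coverage: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of samples over per-site coverage features (sites as rows, samples as columns).

    Used to compare replicates by their coverage over DSB flanks (e.g. the 5 kb
    window around each efficiently-cut site). Features are centered but not
    scaled — coverage features share CPM units. Constant features are dropped
    with a warning. The sign of each component is fixed by making its
    largest-magnitude loading positive.
    """
    from sklearn.decomposition import PCA

    if per_site_coverage.shape[1] < 2 or per_site_coverage.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 sites")
    X = per_site_coverage.T  # samples x features
    variances = X.var(axis=0, ddof=0)
    dropped = [str(f) for f in X.columns[variances == 0]]
    if dropped:
        logger.warning("pca_samples: dropping %d constant features", len(dropped))
        X = X.loc[:, variances > 0]
    if X.shape[1] == 0:
        raise ValidationError("all features constant across samples")
    if n_components is None:
        n_components = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X.to_numpy())
    # Deterministic sign: largest-|loading| entry of each component made positive.
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=X.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_features=dropped,
    )


def fold_enrichment_ddct(
    ct_target_ip: float, ct_target_input: float, ct_ref_ip: float, ct_ref_input: float
) -> float:
    """qPCR fold enrichment by the 2^-DDCt method.

    DDCt = (Ct_target_IP - Ct_target_input) - (Ct_ref_IP - Ct_ref_input);
    the returned enrichment is 2^(-DDCt).
    """
    for v in (ct_target_ip, ct_target_input, ct_ref_ip, ct_ref_input):
        if not np.isfinite(v):
            raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_ip - ct_target_input) - (ct_ref_ip - ct_ref_input)
    return float(2.0 ** (-ddct))
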