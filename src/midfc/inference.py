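"""Group-level voxelwise inference on Fisher-z connectivity maps.

One-sample, paired and two-sample t tests, voxelwise age regressions,
probability-matched t-to-Z conversion, GRF-corrected voxel and cluster
thresholds, and the comparison of men's vs women's age-regression slopes
within a region (two-separate-lines formulation, Bonferroni-corrected
across the battery of regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from midfc.connectivity import SubjectZMap
from midfc.grf import (
    SmoothnessEstimate,
    cluster_p_corrected,
    estimate_smoothness,
)

Z_CAP = 40.0   # finite stand-in for numerically infinite Z values
DEFAULT_FORMING_P = 0.001
DEFAULT_CLUSTER_ALPHA = 0.05
DEFAULT_N_SLOPE_TESTS = 12


@dataclass
class GroupStatMap:
    """A 3D group statistic map with its sampling metadata."""

    stat: np.ndarray            # 3D; NaN outside the analysis mask
    stat_type: str              # "t" | "Z"
    df: float
    contrast: str
    n: int
    mask: np.ndarray            # analysis mask (finite voxels)
    residuals: np.ndarray | None = None   # (n, nx, ny, nz), for smoothness

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stat.shape != self.mask.shape:
            raise ValueError("stat map and mask shapes differ")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not np.all(np.isfinite(self.stat[self.mask])):
            raise ValueError("stat map must be finite within the mask")


@dataclass
class SlopeTestResult:
    """Comparison of men's vs women's age-regression slopes in one region."""

    region_id: str
    slope_men: float            # z units per year
    slope_women: float
    se_diff: float
    t: float
    df: int
    p: float
    alpha_corrected: float
    significant: bool


def _stack(zmaps) -> np.ndarray:
    """Accept a list of SubjectZMap or an (n, nx, ny, nz) array."""
    if isinstance(zmaps, np.ndarray):
        arr = np.asarray(zmaps, dtype=float)
    else:
        zmaps = list(zmaps)
        if zmaps and isinstance(zmaps[0], SubjectZMap):
            arr = np.stack([m.z for m in zmaps])
        else:
            arr = np.stack([np.asarray(m, dtype=float) for m in zmaps])
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3D maps")
    return arr


def _finite_mask(arr: np.ndarray) -> np.ndarray:
    return np.isfinite(arr).all(axis=0)


def _zero_var_warning(count: int) -> None:
    if count:
        warnings.warn(f"{count} zero-variance voxels set to t = 0", stacklevel=3)


def one_sample_t(zmaps, contrast: str = "one-sample") -> GroupStatMap:
    """Per-voxel one-sample t test of the stack's mean against zero.

    t = mean / (sd / sqrt(n)), df = n - 1, with the sample sd using the
    n-1 denominator.  Zero-variance voxels get t = 0 (counted in a
    warning) so group maps stay finite.
    """
    arr = _stack(zmaps)
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"one-sample t test needs n >= 3, got {n}")
    mask = _finite_mask(arr)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero = mask & (sd == 0)
    _zero_var_warning(int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = 0.0
    t[~mask] = np.nan
    residuals = np.where(mask, arr - mean, np.nan)
    return GroupStatMap(stat=t, stat_type="t", df=n - 1, contrast=contrast,
                        n=n, mask=mask, residuals=residuals)


def paired_t(zmaps_a, zmaps_b, contrast: str = "paired") -> GroupStatMap:
    """Paired t test: one-sample t on the per-subject differences A - B.

    When both inputs are SubjectZMap lists, subject ids must match
    pairwise (same subjects, same order).
    """
    la, lb = list(zmaps_a), list(zmaps_b)
    if (la and lb and isinstance(la[0], SubjectZMap)
            and isinstance(lb[0], SubjectZMap)):
        mism = [(a.subject_id, b.subject_id) for a, b in zip(la, lb)
                if a.subject_id != b.subject_id]
        if len(la) != len(lb) or mism:
            raise ValueError(f"paired test subject mismatch: {mism or 'lengths differ'}")
    a = _stack(la)
    b = _stack(lb)
    if a.shape != b.shape:
        raise ValueError("paired stacks must have identical shape")
    return one_sample_t(a - b, contrast=contrast)


def two_sample_t(group1, group2, contrast: str = "two-sample") -> GroupStatMap:
    """Pooled-variance two-sample t test (group1 minus group2).

    df = n1 + n2 - 2; equal variances are assumed, matching the
    convention of classical SPM group analyses.
    """
    a = _stack(group1)
    b = _stack(group2)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need n >= 2, got {n1} and {n2}")
    if n1 + n2 < 5:
        raise ValueError("two-sample t test needs n1 + n2 >= 5")
    mask = _finite_mask(a) & _finite_mask(b)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss1 = ((a - m1) ** 2).sum(axis=0)
    ss2 = ((b - m2) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero = mask & (se == 0)
    _zero_var_warning(int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t[zero] = 0.0
    t[~mask] = np.nan
    resid = np.concatenate([a - m1, b - m2])
    resid[:, ~mask] = np.nan
    return GroupStatMap(stat=t, stat_type="t", df=df, contrast=contrast,
                        n=n1 + n2, mask=mask, residuals=resid)


def regress_age(zmaps, ages, select=None,
                contrast: str = "age regression") -> GroupStatMap:
    """Per-voxel simple linear regression z ~ intercept + age.

    The map holds the t statistic of the age slope, df = n - 2.
    ``select`` optionally restricts to a subgroup (boolean or index array
    over subjects) — used for the men-only / women-only regressions.
    """
    arr = _stack(zmaps)
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != arr.shape[0]:
        raise ValueError("ages length does not match the number of maps")
    if select is not None:
        arr = arr[select]
        ages = ages[select]
    n = arr.shape[0]
    if n < 4:
        raise ValueError(f"age regression needs n >= 4, got {n}")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; slope undefined")
    mask = _finite_mask(arr)
    ac = ages - ages.mean()
    sxx = (ac ** 2).sum()
    y_mean = arr.mean(axis=0)
    slope = np.tensordot(ac, arr, axes=(0, 0)) / sxx
    fitted = y_mean + slope * ac[:, None, None, None]
    resid = arr - fitted
    rss = (resid ** 2).sum(axis=0)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    zero = mask & (se == 0)
    _zero_var_warning(int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    t[zero] = 0.0
    t[~mask] = np.nan
    resid[:, ~mask] = np.nan
    return GroupStatMap(stat=t, stat_type="t", df=df, contrast=contrast,
                        n=n, mask=mask, residuals=resid)


def t_to_z(statmap: GroupStatMap) -> GroupStatMap:
    """Probability-matching conversion of a t map to a Z map.

    Z = Phi^-1(F_t(t; df)) applied symmetrically: the upper-tail p of |t|
    under the t distribution is mapped to the equally extreme normal
    quantile with the original sign.  Values beyond Z = 40 (where the
    tail probability underflows) are capped.
    """
    if statmap.stat_type != "t":
        raise ValueError(f"expected a t map, got {statmap.stat_type!r}")
    if statmap.df is None or statmap.df <= 0:
        raise ValueError("t map lacks degrees of freedom")
    t = statmap.stat
    z = np.full_like(t, np.nan)
    finite = np.isfinite(t)
    tt = np.abs(t[finite])
    p = stats.t.sf(tt, statmap.df)
    with np.errstate(divide="ignore"):
        zz = stats.norm.isf(p)
    zz = np.where(np.isfinite(zz), zz, Z_CAP)
    z[finite] = np.sign(t[finite]) * np.minimum(zz, Z_CAP)
    return GroupStatMap(stat=z, stat_type="Z", df=statmap.df,
                        contrast=statmap.contrast, n=statmap.n,
                        mask=statmap.mask, residuals=statmap.residuals)


def cluster_fwe(statmap: GroupStatMap,
                forming_p: float = DEFAULT_FORMING_P,
                alpha: float = DEFAULT_CLUSTER_ALPHA,
                smoothness: SmoothnessEstimate | None = None,
                connectivity: int = 18,
                two_sided: bool = True) -> list[dict]:
    """Cluster-extent FWE inference on a Z map.

    The map is thresholded at the voxel p < ``forming_p`` (uncorrected)
    quantile of its own distribution — the t quantile for a t map (its
    df then also selects t-field EC densities for the expected cluster
    count), the normal quantile for a Z map.  Suprathreshold voxels are
    grouped into connected components and each cluster receives a
    GRF-corrected cluster-level p; clusters with p < ``alpha`` survive.
    The negative tail is handled by running the same procedure on the
    negated map.

    Returns a list of dicts (sign, n_voxels, p_fwe, peak_z, peak_ijk,
    mask), largest clusters first.  An empty list means nothing survived.
    """
    from midfc.reporting import label_clusters

    if not 0 < forming_p < 1 or not 0 < alpha < 1:
        raise ValueError("forming_p and alpha must lie in (0, 1)")
    if smoothness is None:
        if statmap.residuals is None:
            raise ValueError("no smoothness estimate and no residuals to "
                             "estimate it from")
        smoothness = estimate_smoothness(statmap.residuals, statmap.mask)
    if statmap.stat_type == "t":
        df = statmap.df
        u = float(stats.t.isf(forming_p, df))
        zmap = t_to_z(statmap)
        data = np.where(statmap.mask, statmap.stat, 0.0)
    else:
        df = None
        u = float(stats.norm.isf(forming_p))
        zmap = statmap
        data = np.where(statmap.mask, statmap.stat, 0.0)
    zdata = np.where(zmap.mask, zmap.stat, 0.0)
    out: list[dict] = []
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        sup = (sign * data) > u
        labels, n_clusters = label_clusters(sup, connectivity=connectivity)
        for lab in range(1, n_clusters + 1):
            cmask = labels == lab
            size = int(cmask.sum())
            p = cluster_p_corrected(size, u, smoothness, df=df)
            if p < alpha:
                signed = zdata * cmask * sign
                peak_flat = int(np.argmax(signed))
                peak_ijk = np.unravel_index(peak_flat, data.shape)
                out.append({
                    "sign": sign,
                    "n_voxels": size,
                    "p_fwe": p,
                    "peak_z": float(zdata[peak_ijk]),
                    "peak_ijk": tuple(int(i) for i in peak_ijk),
                    "mask": cmask,
                })
    out.sort(key=lambda c: (-c["n_voxels"], c["peak_ijk"]))
    return out


def slope_difference_test(roi_z: np.ndarray,
                          ages: np.ndarray,
                          sex_labels,
                          n_tests: int = DEFAULT_N_SLOPE_TESTS,
                          family_alpha: float = 0.05,
                          region_id: str = "") -> SlopeTestResult:
    """Test whether men's and women's age-regression slopes differ.

    Fits z ~ age separately within each sex and compares the two slopes
    with the classical two-separate-lines statistic: pooled residual
    variance s2 = (RSS_m + RSS_w) / (n_m + n_w - 4),
    SE = sqrt(s2 * (1/Sxx_m + 1/Sxx_w)), t = (b_m - b_w) / SE on
    n_m + n_w - 4 degrees of freedom.  Significance is declared at the
    Bonferroni-corrected level ``family_alpha / n_tests`` (0.05/12 =
    0.004 for the default battery of 12 regions).
    """
    roi_z = np.asarray(roi_z, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sex = np.asarray(sex_labels)
    male = (sex == "male") | (sex == "M")
    female = (sex == "female") | (sex == "F")
    if not np.all(male | female):
        raise ValueError("sex labels must be 'male'/'female' (or 'M'/'F')")

    def fit(idx: np.ndarray) -> tuple[float, float, float, int]:
        n = int(idx.sum())
        if n < 3:
            raise ValueError(f"need at least 3 subjects per sex, got {n}")
        a = ages[idx]
        y = roi_z[idx]
        ac = a - a.mean()
        sxx = float((ac ** 2).sum())
        if sxx == 0:
            raise ValueError("zero age variance within one sex group")
        b = float((ac * y).sum() / sxx)
        rss = float(((y - y.mean() - b * ac) ** 2).sum())
        return b, sxx, rss, n

    b_m, sxx_m, rss_m, n_m = fit(male)
    b_w, sxx_w, rss_w, n_w = fit(female)
    df = n_m + n_w - 4
    s2 = (rss_m + rss_w) / df
    se = float(np.sqrt(s2 * (1.0 / sxx_m + 1.0 / sxx_w)))
    if se == 0:
        t = np.inf if b_m != b_w else 0.0
        p = 0.0 if b_m != b_w else 1.0
    else:
        t = (b_m - b_w) / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    alpha_c = family_alpha / n_tests
    return SlopeTestResult(region_id=region_id, slope_men=b_m, slope_women=b_w,
                           se_diff=se, t=float(t), df=df, p=p,
                           alpha_corrected=alpha_c,
                           significant=bool(p < alpha_c))
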