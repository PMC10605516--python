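"""Case-level risk scoring from patch confidence-score distributions.

A weakly supervised slide classifier emits one confidence score per tissue
patch.  A case (patient / whole-slide image) therefore carries a whole
*distribution* of patch scores rather than a single number.  This module
turns that distribution into a scalar risk score and a binary risk group:

1.  Each case's scores are histogrammed into 10 equal-width bins spanning
    the case's own score range ``[s_min, s_max]`` with bin width
    ``(s_max - s_min) / 10``.
2.  Bin counts are max-normalized (divided by the largest bin count) so
    every bin frequency lies in [0, 1].
3.  The unadjusted score is the difference between two designated bins,
    ``S_u = D_m - D_r``, where *r* is a reference bin dominated by
    negative (non-lethal) patches and *m* is the median bin.  By default
    r = 2 and m = 5.
4.  Because an external cohort may have a shifted score distribution, a
    cohort-level adjustment recenters the scores without ground truth:
    with mu = mean(S_u) and mu_half = median(S_u - mu),
    ``S_CSD = -mu + mu_half + S_u``.
5.  A threshold ``T = mu0 + 1.05 * sigma0 + alpha`` splits cases into
    low/high risk, where mu0 and sigma0 are the mean and standard
    deviation of S_u on the development cohort and ``alpha = mu0 - mu_c``
    corrects for the shift of the target cohort mean mu_c.

A midrange quality check guards the implicit assumption that per-case
equal-width bins line up across cohorts: the cohort median of the bin-r
and bin-m score midpoints should be stable (reference medians 0.17 and
0.41 with IQRs 0.16-0.18 and 0.37-0.42 on the development data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseScoreProfile",
    "DecileSelection",
    "CohortAdjustment",
    "ThresholdModel",
    "MidrangeQC",
    "case_histogram",
    "select_deciles",
    "unadjusted_score",
    "cohort_adjust",
    "compute_threshold",
    "categorize",
    "midrange_qc",
    "score_cohort",
]

N_BINS = 10
#: multiplier of sigma0 in the risk threshold; a fixed model constant
THRESHOLD_SIGMA_FACTOR = 1.05
#: reference cohort medians of the bin-r / bin-m score midranges
MIDRANGE_REF_R = 0.17
MIDRANGE_REF_M = 0.41
MIDRANGE_IQR_R = (0.16, 0.18)
MIDRANGE_IQR_M = (0.37, 0.42)


@dataclass(frozen=True)
class CaseScoreProfile:
    """Equal-width 10-bin histogram of one case's patch scores.

    ``counts`` sums to the number of patches; ``norm_freq`` is counts
    divided by the maximum count (so ``max(norm_freq) == 1`` whenever the
    case has at least one patch); ``bin_midrange[k]`` is the score
    midpoint ``s_min + (k + 0.5) * bin_width`` of bin ``k`` (0-based).
    """

    case_id: str
    s_min: float
    s_max: float
    bin_width: float
    counts: np.ndarray
    norm_freq: np.ndarray
    bin_midrange: np.ndarray

    @property
    def n_patches(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DecileSelection:
    """Reference (r) and middle (m) bin indices, 1-based.

    ``negative_fraction`` holds the fraction of label-0 patches per
    pooled-score decile when patch labels were available for selection.
    """

    r: int = 2
    m: int = 5
    negative_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.r < self.m <= N_BINS):
            raise ValueError(
                f"decile indices must satisfy 1 <= r < m <= {N_BINS}, "
                f"got r={self.r}, m={self.m}"
            )


@dataclass(frozen=True)
class CohortAdjustment:
    """Cohort statistics used to adjust S_u into S_CSD."""

    mu: float
    mu_half: float

    @property
    def shift(self) -> float:
        """The cohort-constant added to every S_u: ``-mu + mu_half``."""
        return -self.mu + self.mu_half


@dataclass(frozen=True)
class ThresholdModel:
    """Development-set statistics plus the cohort-corrected threshold."""

    mu0: float
    sigma0: float
    mu_c: float
    alpha: float
    threshold: float
    sigma_factor: float = THRESHOLD_SIGMA_FACTOR


@dataclass(frozen=True)
class MidrangeQC:
    """Cohort medians/IQRs of the bin-r and bin-m score midranges."""

    median_mr_r: float
    iqr_r: tuple[float, float]
    median_mr_m: float
    iqr_m: tuple[float, float]
    tolerance: float
    passed: bool
    reference_mr_r: float = MIDRANGE_REF_R
    reference_mr_m: float = MIDRANGE_REF_M


def case_histogram(
    scores: Sequence[float] | np.ndarray, case_id: str = ""
) -> CaseScoreProfile:
    """Histogram one case's patch scores into 10 equal-width bins.

    Bins span ``[s_min, s_max]`` (the case's own range), are right-open
    except the last, which is closed so that ``s_max`` is counted.  When
    every score is identical (``s_max == s_min``) the bin width is zero
    and all mass is assigned to the first bin; such a case carries no
    dominance signal and later yields ``S_u == 0``.

    Raises
    ------
    ValueError
        If ``scores`` is empty or contains non-finite values.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError(f"case {case_id!r}: empty score list")
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"case {case_id!r}: scores contain non-finite values")
    s_min = float(scores.min())
    s_max = float(scores.max())
    if s_max == s_min:
        counts = np.zeros(N_BINS, dtype=np.int64)
        counts[0] = scores.size
        bin_width = 0.0
    else:
        counts, _ = np.histogram(scores, bins=N_BINS, range=(s_min, s_max))
        counts = counts.astype(np.int64)
        bin_width = (s_max - s_min) / N_BINS
    norm_freq = counts / counts.max()
    midrange = s_min + (np.arange(N_BINS) + 0.5) * bin_width
    return CaseScoreProfile(
        case_id=case_id,
        s_min=s_min,
        s_max=s_max,
        bin_width=bin_width,
        counts=counts,
        norm_freq=norm_freq,
        bin_midrange=midrange,
    )


def select_deciles(
    pooled_scores: Sequence[float] | np.ndarray,
    patch_labels: Sequence[int] | np.ndarray | None = None,
    m: int | None = None,
    negative_cutoff: float = 0.5,
) -> DecileSelection:
    """Choose the reference and middle deciles from pooled patch scores.

    The pooled scores (all patches, all cases) are split into ten deciles
    by their empirical quantiles.  The reference decile *r* is the lowest
    decile whose fraction of negative (label 0) patches exceeds
    ``negative_cutoff``; the middle decile *m* defaults to 5, the median
    decile of the nine non-reference deciles.  Without labels the
    defaults (2, 5) are returned unchanged.

    Raises
    ------
    ValueError
        If fewer than 10 distinct pooled scores are given, labels are not
        binary, or no decile is negative-dominated (manual selection is
        then required).
    """
    if patch_labels is None:
        return DecileSelection(r=2, m=5 if m is None else m)

    pooled_scores = np.asarray(pooled_scores, dtype=float)
    labels = np.asarray(patch_labels)
    if pooled_scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if np.unique(pooled_scores).size < N_BINS:
        raise ValueError("need at least 10 distinct pooled scores")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("patch labels must be binary 0/1")

    edges = np.quantile(pooled_scores, np.linspace(0, 1, N_BINS + 1))
    # right-open decile intervals, last closed; 0-based decile index
    idx = np.clip(np.searchsorted(edges[1:-1], pooled_scores, side="right"), 0, N_BINS - 1)
    neg_frac = np.full(N_BINS, np.nan)
    for k in range(N_BINS):
        in_k = idx == k
        if in_k.any():
            neg_frac[k] = float((labels[in_k] == 0).mean())
    dominated = np.flatnonzero(neg_frac > negative_cutoff)
    if dominated.size == 0:
        raise ValueError(
            "no decile has a negative-patch fraction above "
            f"{negative_cutoff}; select the reference decile manually"
        )
    r = int(dominated[0]) + 1
    m = 5 if m is None else m
    return DecileSelection(r=r, m=m, negative_fraction=neg_frac)


def unadjusted_score(
    profile: CaseScoreProfile, sel: DecileSelection = DecileSelection()
) -> float:
    """Unadjusted case score ``S_u = D_m - D_r``; always within [-1, 1]."""
    return float(profile.norm_freq[sel.m - 1] - profile.norm_freq[sel.r - 1])


def cohort_adjust(
    s_u: Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, CohortAdjustment]:
    """Adjust unadjusted scores for the cohort's own score distribution.

    With ``mu = mean(S_u)`` and ``mu_half = median(S_u - mu)``, each score
    becomes ``S_CSD = -mu + mu_half + S_u``.  The adjustment is a single
    cohort-wide shift ``median(S_u) - 2 * mean(S_u)``; a single-case
    cohort collapses to ``S_CSD = 0``.
    """
    s_u = np.asarray(s_u, dtype=float)
    if s_u.size == 0:
        raise ValueError("empty cohort: need at least one S_u value")
    mu = float(s_u.mean())
    mu_half = float(np.median(s_u - mu))
    return s_u - mu + mu_half, CohortAdjustment(mu=mu, mu_half=mu_half)


def compute_threshold(
    dev_s_u: Sequence[float] | np.ndarray,
    cohort_s_u: Sequence[float] | np.ndarray,
    sigma_factor: float = THRESHOLD_SIGMA_FACTOR,
) -> ThresholdModel:
    """Cohort-corrected risk threshold ``T = mu0 + 1.05*sigma0 + alpha``.

    ``mu0`` and ``sigma0`` (sample standard deviation, n-1 denominator)
    come from the development cohort's unadjusted scores; ``alpha = mu0 -
    mu_c`` offsets the mean shift of the target cohort.  When the target
    cohort equals the development cohort, ``alpha == 0`` and ``T == mu0 +
    1.05 * sigma0`` exactly.
    """
    dev = np.asarray(dev_s_u, dtype=float)
    cohort = np.asarray(cohort_s_u, dtype=float)
    if dev.size < 2:
        raise ValueError("need >= 2 development cases to estimate sigma0")
    if cohort.size == 0:
        raise ValueError("empty target cohort")
    mu0 = float(dev.mean())
    sigma0 = float(dev.std(ddof=1))
    mu_c = float(cohort.mean())
    alpha = mu0 - mu_c
    threshold = mu0 + sigma_factor * sigma0 + alpha
    return ThresholdModel(
        mu0=mu0,
        sigma0=sigma0,
        mu_c=mu_c,
        alpha=alpha,
        threshold=threshold,
        sigma_factor=sigma_factor,
    )


def categorize(s_csd, threshold: float):
    """Binary risk group: ``"high"`` iff ``S_CSD >= T``, else ``"low"``.

    Accepts a scalar or an array; returns the same shape.  The boundary
    case ``S_CSD == T`` is assigned to the high-risk group (ties are
    measure-zero for continuous scores).
    """
    s_csd = np.asarray(s_csd, dtype=float)
    out = np.where(s_csd >= threshold, "high", "low")
    if out.ndim == 0:
        return str(out)
    return out


def midrange_qc(
    profiles: Sequence[CaseScoreProfile],
    sel: DecileSelection = DecileSelection(),
    tolerance: float = 0.05,
) -> MidrangeQC:
    """Check that per-case bin midranges align with the reference cohort.

    Computes the cohort median and IQR of each case's bin-r and bin-m
    score midpoints (``s_min + (k - 0.5) * bin_width`` for 1-based bin
    ``k``) and passes iff both medians lie within ``tolerance`` of the
    reference medians 0.17 (bin r) and 0.41 (bin m).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one case profile")
    mr_r = np.array([p.bin_midrange[sel.r - 1] for p in profiles])
    mr_m = np.array([p.bin_midrange[sel.m - 1] for p in profiles])
    med_r = float(np.median(mr_r))
    med_m = float(np.median(mr_m))
    iqr_r = tuple(float(q) for q in np.quantile(mr_r, [0.25, 0.75]))
    iqr_m = tuple(float(q) for q in np.quantile(mr_m, [0.25, 0.75]))
    passed = (
        abs(med_r - MIDRANGE_REF_R) <= tolerance
        and abs(med_m - MIDRANGE_REF_M) <= tolerance
    )
    return MidrangeQC(
        median_mr_r=med_r,
        iqr_r=iqr_r,
        median_mr_m=med_m,
        iqr_m=iqr_m,
        tolerance=tolerance,
        passed=passed,
    )


def score_cohort(
    patch_scores: pd.DataFrame,
    sel: DecileSelection = DecileSelection(),
    dev_s_u: Sequence[float] | np.ndarray | None = None,
    sigma_factor: float = THRESHOLD_SIGMA_FACTOR,
    qc_tolerance: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Score every case of a cohort and assign risk groups.

    Parameters
    ----------
    patch_scores:
        Long table with columns ``case_id``, ``score`` (one row per
        patch; extra columns ignored).
    sel:
        Reference/middle bin selection (defaults r=2, m=5).
    dev_s_u:
        Unadjusted scores of the development cohort used for the
        threshold statistics mu0/sigma0.  When ``None`` the cohort is
        treated as its own development set (alpha = 0).
    sigma_factor:
        Multiplier of sigma0 in the threshold.

    Returns
    -------
    (cases, meta):
        ``cases`` has one row per case (``case_id``, ``s_min``,
        ``s_max``, ``d_r``, ``d_m``, ``s_u``, ``s_csd``, ``risk_group``);
        ``meta`` holds the :class:`CohortAdjustment`,
        :class:`ThresholdModel` and :class:`MidrangeQC`.
    """
    if not {"case_id", "score"}.issubset(patch_scores.columns):
        raise ValueError("patch_scores must have columns 'case_id' and 'score'")
    profiles = [
        case_histogram(g["score"].to_numpy(), case_id=str(cid))
        for cid, g in patch_scores.groupby("case_id", sort=True)
    ]
    if not profiles:
        raise ValueError("no cases in patch_scores")
    s_u = np.array([unadjusted_score(p, sel) for p in profiles])
    s_csd, adjustment = cohort_adjust(s_u)
    if dev_s_u is None:
        dev_s_u = s_u
        if len(s_u) < 2:
            warnings.warn(
                "single-case cohort with no development statistics; "
                "threshold is degenerate"
            )
            dev_s_u = np.concatenate([s_u, s_u])
    model = compute_threshold(dev_s_u, s_u, sigma_factor=sigma_factor)
    groups = categorize(s_csd, model.threshold)
    qc = midrange_qc(profiles, sel, tolerance=qc_tolerance)
    cases = pd.DataFrame(
        {
            "case_id": [p.case_id for p in profiles],
            "n_patches": [p.n_patches for p in profiles],
            "s_min": [p.s_min for p in profiles],
            "s_max": [p.s_max for p in profiles],
            "d_r": [p.norm_freq[sel.r - 1] for p in profiles],
            "d_m": [p.norm_freq[sel.m - 1] for p in profiles],
            "s_u": s_u,
            "s_csd": s_csd,
            "risk_group": groups,
        }
    )
    meta = {"adjustment": adjustment, "threshold_model": model, "midrange_qc": qc,
            "selection": sel}
    return cases, meta
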