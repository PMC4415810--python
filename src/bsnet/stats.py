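"""Surrogate-based source significance and burst/suppression contrasts.

Source significance uses within-subject Monte-Carlo surrogates: one-second
epochs are re-ordered independently per channel, which preserves every
channel's spectrum while destroying cross-channel alignment; each
permutation rebuilds the band CSD and the maximum beamformer coherence with
the reference outside its exclusion sphere.  The 99th percentile of these
null maxima is the per-subject significance threshold (family-wise, since
the null statistic is the map maximum).  Phase contrasts (source power,
mean source coherence) are compared across subjects with a Friedman
two-way rank analysis of variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from . import dics
from .headmodel import LeadField
from .phases import PhaseSegments
from .spectra import DEFAULT_EPOCH_S, DEFAULT_K, DEFAULT_NW

__all__ = [
    "SurrogateDistribution",
    "PhaseContrast",
    "surrogate_source_threshold",
    "friedman_test",
    "compare_phases",
]

log = logging.getLogger(__name__)


@dataclass
class SurrogateDistribution:
    statistic: str
    n_permutations: int
    null_samples: np.ndarray  # (n_perm,) null map maxima off the reference
    threshold: float  # stated quantile of the null map maxima
    quantile: float
    observed: float
    p_value: float  # (1 + #{null >= obs}) / (1 + n_perm)
    voxel_thresholds: np.ndarray | None = None  # (n_points,) per-voxel null quantiles
    reference: int | None = None


@dataclass
class PhaseContrast:
    subjects: list[str]
    power: dict[str, np.ndarray]  # phase -> per-subject mean source power
    coherence: dict[str, np.ndarray]  # phase -> per-subject mean source coherence
    power_statistic: float
    power_p: float
    coherence_statistic: float
    coherence_p: float
    direction: str  # e.g. 'burst > suppression'


def surrogate_source_threshold(
    segments: PhaseSegments,
    leadfield: LeadField,
    lam: float = dics.DEFAULT_LAMBDA,
    n_perm: int = 100,
    quantile: float = 0.99,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = (1.0, 4.0),
    exclusion_radius: float = dics.DEFAULT_EXCLUSION_MM,
    epoch: float = DEFAULT_EPOCH_S,
    time_bandwidth: float = DEFAULT_NW,
    k_tapers: int = DEFAULT_K,
) -> SurrogateDistribution:
    """Monte-Carlo null of the maximum off-reference map coherence.

    Each permutation reorders the one-second epochs independently per
    channel — destroying all cross-channel alignment while preserving
    every channel's spectrum — and rebuilds the band CSD; the spatial
    filters and the reference stay those of the observed data.  For
    recordings whose channels really are independent this shuffling is
    law-invariant, so the null is exact.  The threshold is the
    ``quantile`` (linearly interpolated) of the null map maxima outside
    the reference's exclusion sphere; per-voxel quantiles are returned
    alongside.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 makes the upper quantile unreliable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = dics._band_select(segments, band, epoch, time_bandwidth, k_tapers)
    n_ep, n_tap, n_ch, n_f = x.shape
    if n_ep < 10:
        raise ValueError(f"need >= 10 epochs for surrogates, got {n_ep}")
    pts = leadfield.grid.points

    csd_obs = dics._band_csd_of(x)
    pmap = dics.source_power_map(csd_obs, leadfield, lam, band)
    ref = dics.select_reference(pmap)
    filters = dics._filters_all(leadfield.gain, csd_obs, lam)
    outside = np.linalg.norm(pts - pts[ref], axis=1) > exclusion_radius
    cmap_obs = dics.source_coherence_map(csd_obs, leadfield, ref, lam, filters=filters)
    observed = float(np.max(cmap_obs.coherence[outside]))

    null_maps = np.empty((n_perm, pts.shape[0]))
    ix_t = np.arange(n_tap)[None, :, None, None]
    ix_c = np.arange(n_ch)[None, None, :, None]
    ix_f = np.arange(n_f)[None, None, None, :]
    for b in range(n_perm):
        perm = np.stack([rng.permutation(n_ep) for _ in range(n_ch)], axis=1)
        xs = x[perm[:, None, :, None], ix_t, ix_c, ix_f]
        null_maps[b] = dics.source_coherence_map(
            dics._band_csd_of(xs), leadfield, ref, lam, filters=filters).coherence
    null_max = null_maps[:, outside].max(axis=1)
    threshold = float(np.quantile(null_max, quantile))  # linear interpolation
    voxel_thr = np.quantile(null_maps, quantile, axis=0)
    p = float((1 + np.sum(null_max >= observed)) / (1 + n_perm))
    return SurrogateDistribution(
        statistic="max_off_reference_coherence", n_permutations=n_perm,
        null_samples=null_max, threshold=threshold, quantile=quantile,
        observed=observed, p_value=p, voxel_thresholds=voxel_thr, reference=int(ref))


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman two-way rank ANOVA over subjects x conditions.

    Mid-ranks within each subject row; the statistic uses the standard tie
    correction and is referred to chi-square with k-1 degrees of freedom.
    Works for k >= 2 conditions (at k = 2 it is the two-sided sign test in
    rank form).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    n, k = m.shape
    ranks = spstats.rankdata(m, axis=1)  # mid-ranks for ties
    col_sums = ranks.sum(axis=0)
    q_num = 12.0 * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = n * k * (k + 1) * (1.0 - tie_sum / (n * k * (k * k - 1)))
    if denom <= 0:  # every row constant
        return 0.0, 1.0
    q = q_num / denom
    p = float(spstats.chi2.sf(q, df=k - 1))
    return float(q), p


def compare_phases(
    subjects: list[str],
    power_by_phase: dict[str, list[float]],
    coherence_by_phase: dict[str, list[float]],
    phases: tuple[str, str] = ("burst", "suppression"),
) -> PhaseContrast:
    """Friedman contrast of per-subject source power and mean coherence.

    Subjects missing either phase (NaN entries) are excluded with a log
    entry; the reported direction compares the first phase to the second.
    """
    a, b = phases
    pw = np.column_stack([power_by_phase[a], power_by_phase[b]]).astype(float)
    co = np.column_stack([coherence_by_phase[a], coherence_by_phase[b]]).astype(float)
    ok = np.all(np.isfinite(pw), axis=1) & np.all(np.isfinite(co), axis=1)
    if not np.all(ok):
        dropped = [s for s, o in zip(subjects, ok) if not o]
        log.warning("compare_phases: excluding subjects with a missing phase: %s", dropped)
    pw, co = pw[ok], co[ok]
    kept = [s for s, o in zip(subjects, ok) if o]
    if pw.shape[0] < 2:
        raise ValueError("need >= 2 complete subjects for a phase contrast")
    q_p, p_p = friedman_test(pw)
    q_c, p_c = friedman_test(co)
    direction = f"{a} > {b}" if np.median(pw[:, 0] - pw[:, 1]) > 0 else f"{b} > {a}"
    return PhaseContrast(
        subjects=kept,
        power={a: pw[:, 0], b: pw[:, 1]},
        coherence={a: co[:, 0], b: co[:, 1]},
        power_statistic=q_p, power_p=p_p,
        coherence_statistic=q_c, coherence_p=p_c,
        direction=direction)
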