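"""Dynamic imaging of coherent sources (DICS) on the sphere-model grid.

A frequency-domain beamformer: for every grid point a unit-gain spatial
filter ``A(r) = (L^H C_reg^-1 L)^-1 L^H C_reg^-1`` is built from the
band-averaged sensor cross-spectral density ``C`` (Tikhonov-regularized by
``lambda * trace(C)/N``).  Source band power is the dominant eigenvalue of
``Re(A C A^H)``; its noise-normalized maximum (neural activity index)
defines the reference region, and maps of source-to-reference coherence
are scanned iteratively for further coherent sources.

The iteration nulls each accepted source: subsequent scan filters carry
zero-gain constraints at the found sources' scalp topographies, so a
found source can neither re-appear through its leakage skirt nor distort
new candidates through minimum-variance cancellation residues.  At every
step the map is compared against a
Monte-Carlo null built by shuffling the one-second epochs of the reference
signal against the sensor epochs, which destroys the reference-to-voxel
alignment while preserving all spectra and the fixed analysis operator;
the scan stops when no grid point exceeds its null quantile.  Extraction
for the directionality stage uses multi-constraint (nulled) filters with
unit gain at the own source and zero gain at the other identified sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .headmodel import LeadField
from .phases import PhaseSegments
from . import spectra as _spectra

__all__ = [
    "SpatialFilter",
    "PowerMap",
    "CoherenceMap",
    "CoherentSourceSet",
    "dics_spatial_filter",
    "source_power_map",
    "select_reference",
    "source_coherence_map",
    "iterate_coherent_sources",
    "extract_source_signals",
    "bandpass_sensor_data",
]

log = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.05
DEFAULT_EXCLUSION_MM = 20.0
DEFAULT_MAX_SOURCES = 8


@dataclass
class SpatialFilter:
    """Unit-gain beamformer filter at one grid point."""

    grid_index: int
    location: np.ndarray  # (3,) mm
    weights: np.ndarray  # (3, n_channels), complex
    orientation: np.ndarray  # (3,) unit vector, dominant power orientation
    lam: float

    def scalar_weights(self) -> np.ndarray:
        """Real scalar filter row u^T Re(A), sign-canonicalized."""
        w = np.real(self.orientation @ self.weights)
        nz = np.flatnonzero(np.abs(w) > 1e-12 * np.max(np.abs(w), initial=1.0))
        if nz.size and w[nz[0]] < 0:
            w = -w
        return w


@dataclass
class PowerMap:
    band: tuple[float, float]
    power: np.ndarray  # (n_points,), >= 0
    orientations: np.ndarray  # (n_points, 3)
    nai: np.ndarray | None = None  # noise-normalized power (neural activity index)
    projected: np.ndarray | None = None  # scalp-projected power, P * ||L u||^2


@dataclass
class CoherenceMap:
    reference_index: int
    coherence: np.ndarray  # (n_points,), in [0, 1]


@dataclass
class CoherentSourceSet:
    """Reference plus coherent sources, in decreasing coherence order."""

    locations: np.ndarray  # (n_sources, 3) mm
    grid_indices: list[int]
    statistics: list[float]  # reference power, then coherence values
    roles: list[str]  # 'reference', 'coherent'
    filters: list[SpatialFilter]
    signals: np.ndarray | None = None  # (n_sources, n_samples) once extracted
    labels: list[str] = field(default_factory=list)
    scalar_filters: np.ndarray | None = None  # (n_sources, n_channels) nulled rows

    @property
    def n_sources(self) -> int:
        return len(self.grid_indices)


def _regularize(csd: np.ndarray, lam: float) -> np.ndarray:
    n = csd.shape[0]
    return csd + lam * (np.real(np.trace(csd)) / n) * np.eye(n)


def _filters_all(gain: np.ndarray, csd: np.ndarray, lam: float) -> np.ndarray:
    """Batched DICS filters for all grid points: (G, 3, E) complex."""
    c_reg = _regularize(csd.astype(complex), lam)
    c_inv = np.linalg.inv(c_reg)
    l = gain.transpose(1, 0, 2)  # (G, E, 3)
    cil = np.einsum("ef,gfo->geo", c_inv, l)  # C^-1 L
    gram = np.einsum("geo,gep->gop", np.conj(l), cil)  # L^H C^-1 L, (G, 3, 3)
    # pinv: deflated or rank-deficient lead fields keep a usable filter in
    # the surviving orientation subspace
    gram_inv = np.linalg.pinv(gram, rcond=1e-10, hermitian=True)
    return np.einsum("gop,gep->goe", gram_inv, np.conj(cil))  # (G, 3, E)


def dics_spatial_filter(
    csd: np.ndarray, leadfield: LeadField, grid_index: int, lam: float = DEFAULT_LAMBDA
) -> SpatialFilter:
    """Unit-gain spatial filter for one grid point."""
    gain = leadfield.gain[:, [grid_index], :]
    a = _filters_all(gain, csd, lam)[0]
    resid = np.max(np.abs(a @ leadfield.gain[:, grid_index, :] - np.eye(3)))
    if resid > 1e-6:
        raise np.linalg.LinAlgError(
            f"unit-gain constraint violated at grid point {grid_index} (resid {resid:.2e})")
    p = a @ csd @ np.conj(a.T)
    ori = _dominant_orientation(np.real(p))
    return SpatialFilter(grid_index=grid_index,
                         location=leadfield.grid.points[grid_index].copy(),
                         weights=a, orientation=ori, lam=lam)


def _dominant_orientation(p3: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (p3 + p3.T))
    ori = v[:, -1]
    nz = np.flatnonzero(np.abs(ori) > 1e-12)
    if nz.size and ori[nz[0]] < 0:
        ori = -ori
    return ori


def source_power_map(
    csd: np.ndarray, leadfield: LeadField, lam: float = DEFAULT_LAMBDA,
    band: tuple[float, float] = (1.0, 4.0),
) -> PowerMap:
    """Band power (dominant-orientation) at every grid point.

    ``power`` is the raw beamformer output power; ``nai`` divides it by the
    filter's projected sensor-noise power along the same orientation (the
    neural activity index), which removes the strong center-of-head noise
    amplification bias of the raw map.
    """
    a = _filters_all(leadfield.gain, csd, lam)  # (G, 3, E)
    p = np.einsum("goe,ef,gpf->gop", a, csd.astype(complex), np.conj(a))
    p = 0.5 * np.real(p + np.conj(np.transpose(p, (0, 2, 1))))
    w, v = np.linalg.eigh(p)
    power = np.maximum(w[:, -1], 0.0)
    ori = v[:, :, -1]
    first = np.argmax(np.abs(ori) > 1e-12, axis=1)
    flip = np.sign(ori[np.arange(len(first)), first])
    flip[flip == 0] = 1.0
    ori = ori * flip[:, None]
    noise = np.real(np.einsum("go,goe,gpe,gp->g", ori, a, np.conj(a), ori))
    with np.errstate(divide="ignore", invalid="ignore"):
        nai = np.where(noise > 0, power / noise, 0.0)
    lnorm = np.einsum("go,ego,egp,gp->g", ori, leadfield.gain, leadfield.gain, ori)
    return PowerMap(band=band, power=power, orientations=ori, nai=nai,
                    projected=power * lnorm)


def select_reference(power_map: PowerMap) -> int:
    """Grid index of the scalp-projected power maximum (ties -> lowest).

    Raw minimum-variance power grows toward the head center where lead
    fields are weak (noise amplification); multiplying each point's source
    power by the squared norm of its oriented lead field gives the scalp
    variance that source explains, a geometric depth correction that does
    not depend on the data-adaptive filter norm.
    """
    if power_map.power.size == 0:
        raise ValueError("empty power map")
    stat = power_map.projected if power_map.projected is not None else power_map.power
    return int(np.argmax(stat))


def source_coherence_map(
    csd: np.ndarray,
    leadfield: LeadField,
    reference: int,
    lam: float = DEFAULT_LAMBDA,
    filters: np.ndarray | None = None,
) -> CoherenceMap:
    """Magnitude-squared coherence of every grid point with the reference.

    The vector-to-scalar reduction follows the source cross-spectrum
    C_s(ref, r) = A(ref) C A(r)^H: its dominant singular pair (u, v) fixes
    the source orientations, and coh(r) = sigma_1^2 / (P_u(ref) P_v(r))
    with the auto powers projected onto those same orientations.  Values
    are clamped to [0, 1].
    """
    if filters is None:
        filters = _filters_all(leadfield.gain, csd, lam)
    c = csd.astype(complex)
    a_ref = filters[reference]
    # cross[g] = A_ref C A_g^H
    cross = np.einsum("oe,gpe->gop", a_ref @ c, np.conj(filters))
    uu, sv_all, vh = np.linalg.svd(cross)
    sv = sv_all[:, 0]
    u = uu[:, :, 0]  # (G, 3) complex: reference-side orientation per point
    v = np.conj(vh[:, 0, :])  # (G, 3): target-side orientation
    p3 = np.einsum("goe,ef,gpf->gop", filters, c, np.conj(filters))
    p_ref3 = p3[reference]
    p_u = np.real(np.einsum("go,op,gp->g", np.conj(u), p_ref3, u))
    p_v = np.real(np.einsum("go,gop,gp->g", np.conj(v), p3, v))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = sv**2 / (p_u * p_v)
    zero = ~np.isfinite(coh)
    if np.any(zero):
        log.info("coherence set to 0 at %d zero-power grid points", int(zero.sum()))
        coh[zero] = 0.0
    n_clamped = int(np.sum(coh > 1.0))
    if n_clamped:
        log.debug("clamped %d coherence values > 1", n_clamped)
    coh = np.clip(coh, 0.0, 1.0)
    coh[reference] = 1.0
    return CoherenceMap(reference_index=reference, coherence=coh)


def _band_select(segments: PhaseSegments, band, epoch, time_bandwidth, k_tapers):
    freqs, x = _spectra.epoch_taper_fft(segments, epoch, time_bandwidth, k_tapers)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not np.any(sel):
        raise ValueError(f"band {band} outside the spectral support")
    return x[..., sel]  # (E, K, C, Fb)


def _band_csd_of(x: np.ndarray) -> np.ndarray:
    n_ep, n_tap, _, n_f = x.shape
    s = np.einsum("ekcf,ekdf->cd", x, np.conj(x)) / (n_ep * n_tap * n_f)
    return 0.5 * (s + np.conj(s.T))


def _voxel_scalar_weights(gain: np.ndarray, csd: np.ndarray, lam: float,
                          null_topos: np.ndarray | None = None):
    """Per-voxel filters, dominant orientations, and scalar weight rows.

    With ``null_topos`` (E x m scalp patterns) each voxel filter carries
    additional zero-gain constraints at those patterns, so the output at a
    candidate location contains neither leakage from, nor cancellation
    residue against, the already-identified sources.
    """
    c_reg = _regularize(csd.astype(complex), lam)
    c_inv = np.linalg.inv(c_reg)
    l = gain.transpose(1, 0, 2)  # (G, E, 3)
    cil = np.einsum("ef,gfo->geo", c_inv, l)
    if null_topos is None or null_topos.size == 0:
        gram = np.einsum("geo,gep->gop", np.conj(l), cil)
        gram_inv = np.linalg.pinv(gram, rcond=1e-10, hermitian=True)
        filters = np.einsum("gop,gep->goe", gram_inv, np.conj(cil))
    else:
        gmat = np.asarray(null_topos, dtype=float)  # (E, m)
        m = gmat.shape[1]
        cig = c_inv @ gmat  # (E, m)
        b11 = np.einsum("geo,gep->gop", np.conj(l), cil)  # (G, 3, 3)
        b12 = np.einsum("geo,em->gom", np.conj(l), cig)  # (G, 3, m)
        b21 = np.einsum("em,geo->gmo", np.conj(gmat), cil)  # (G, m, 3)
        b22 = np.conj(gmat).T @ cig  # (m, m)
        n_g = l.shape[0]
        big = np.empty((n_g, 3 + m, 3 + m), dtype=complex)
        big[:, :3, :3] = b11
        big[:, :3, 3:] = b12
        big[:, 3:, :3] = b21
        big[:, 3:, 3:] = b22
        big_inv = np.linalg.pinv(big, rcond=1e-10, hermitian=True)
        # rows of G^H C^-1: voxel lead field rows then nulled topographies
        rhs = np.concatenate(
            [np.conj(cil).transpose(0, 2, 1),
             np.broadcast_to(np.conj(cig).T, (n_g, m, l.shape[1]))], axis=1)
        filters = np.einsum("gop,gpe->goe", big_inv, rhs)[:, :3, :]
    p3 = np.einsum("goe,ef,gpf->gop", filters, csd.astype(complex), np.conj(filters))
    p3 = 0.5 * np.real(p3 + np.transpose(p3, (0, 2, 1)))
    w, v = np.linalg.eigh(p3)
    ori = v[:, :, -1]
    scal = np.einsum("go,goe->ge", ori, filters)  # (G, E) complex
    return filters, ori, np.maximum(w[:, -1], 0.0), scal


def _coherence_with_reference(r: np.ndarray, y: np.ndarray):
    """Band coherence of every voxel output with the reference signal.

    ``r``: (E, K, F) reference epoch spectra; ``y``: (G, E, K, F) voxel
    epoch spectra.  Returns (coherence (G,), s_rr, s_yy (G,)).
    """
    n = r.size
    s_rr = float(np.sum(np.abs(r) ** 2).real) / n
    s_yy = np.einsum("gekf,gekf->g", y, np.conj(y)).real / n
    s_ry = np.einsum("ekf,gekf->g", np.conj(r), y) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s_ry) ** 2 / (s_rr * s_yy)
    coh[~np.isfinite(coh)] = 0.0
    return np.clip(coh, 0.0, 1.0), s_rr, s_yy


def _null_coherence(r, y, s_rr, s_yy, n_perm, quantile, rng):
    """Per-voxel null quantile of coherence under reference epoch shuffling."""
    n_ep = r.shape[0]
    n = r.size
    null = np.empty((n_perm, y.shape[0]))
    for b in range(n_perm):
        rp = np.conj(r[rng.permutation(n_ep)])
        s_ry = np.einsum("ekf,gekf->g", rp, y) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(s_ry) ** 2 / (s_rr * s_yy)
        c[~np.isfinite(c)] = 0.0
        null[b] = c
    return np.quantile(null, quantile, axis=0), null


def iterate_coherent_sources(
    segments: PhaseSegments,
    leadfield: LeadField,
    lam: float = DEFAULT_LAMBDA,
    n_perm: int = 100,
    quantile: float = 0.99,
    exclusion_radius: float = DEFAULT_EXCLUSION_MM,
    max_sources: int = DEFAULT_MAX_SOURCES,
    band: tuple[float, float] = (1.0, 4.0),
    seed: int | np.random.Generator = 0,
    epoch: float = 1.0,
    time_bandwidth: float = _spectra.DEFAULT_NW,
    k_tapers: int = _spectra.DEFAULT_K,
) -> CoherentSourceSet:
    """Automated reference + coherent-source identification with deflation.

    The reference is the neural-activity-index maximum of the band power
    map.  Each subsequent source is the maximum of the coherence map with
    the reference signal, restricted to grid points whose coherence
    exceeds the ``quantile`` of its Monte-Carlo null (reference epochs
    shuffled against sensor epochs, ``n_perm`` permutations) and lying
    outside ``exclusion_radius`` spheres around already-found sources.
    The scan filters carry zero-gain constraints at every already-found
    source topography, so neither leakage from, nor minimum-variance
    cancellation against, the found sources can masquerade as (or mask) a
    new one; the loop stops when no significant grid point remains or at
    ``max_sources``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _band_select(segments, band, epoch, time_bandwidth, k_tapers)
    gain = leadfield.gain
    pts = leadfield.grid.points

    csd0 = _band_csd_of(x)
    pmap = source_power_map(csd0, leadfield, lam, band)
    ref = select_reference(pmap)
    filters0 = _filters_all(gain, csd0, lam)
    u_ref = pmap.orientations[ref]
    w_ref = u_ref @ filters0[ref]  # (E,) complex scalar filter
    r = np.einsum("c,ekcf->ekf", w_ref, x)

    found = [ref]
    stats = [float(pmap.power[ref])]
    roles = ["reference"]
    orientations = [u_ref]
    topographies = [gain[:, ref, :] @ u_ref]  # model scalp patterns of found sources
    excluded = np.linalg.norm(pts - pts[ref], axis=1) <= exclusion_radius

    while len(found) < max_sources:
        nulls = np.column_stack(topographies)
        _, ori_n, _, scal_n = _voxel_scalar_weights(gain, csd0, lam, null_topos=nulls)
        y = np.einsum("gc,ekcf->gekf", scal_n, x)
        coh, s_rr, s_yy = _coherence_with_reference(r, y)
        thr, _ = _null_coherence(r, y, s_rr, s_yy, n_perm, quantile, rng)
        cand = np.where((coh > thr) & ~excluded, coh, -np.inf)
        idx = int(np.argmax(cand))
        if not np.isfinite(cand[idx]):
            break
        found.append(idx)
        stats.append(float(coh[idx]))
        roles.append("coherent")
        orientations.append(ori_n[idx])
        topographies.append(gain[:, idx, :] @ ori_n[idx])
        excluded |= np.linalg.norm(pts - pts[idx], axis=1) <= exclusion_radius

    filters = []
    for idx, u in zip(found, orientations):
        filters.append(SpatialFilter(
            grid_index=idx, location=pts[idx].copy(), weights=filters0[idx],
            orientation=u, lam=lam))
    srcset = CoherentSourceSet(
        locations=pts[found].copy(), grid_indices=found, statistics=stats,
        roles=roles, filters=filters)
    srcset.scalar_filters = _nulled_extraction_filters(
        np.column_stack(topographies), np.real(csd0), lam)
    return srcset


def _nulled_extraction_filters(topos: np.ndarray, cov: np.ndarray, lam: float) -> np.ndarray:
    """Multi-constraint LCMV rows: unit gain at own source, zero at others.

    ``topos``: (E, m) scalp topographies of the identified sources;
    ``cov``: real sensor covariance proxy (real part of the band CSD).
    """
    n = cov.shape[0]
    c_reg = cov + lam * (np.trace(cov) / n) * np.eye(n)
    ci_g = np.linalg.solve(c_reg, topos)  # (E, m)
    gram = topos.T @ ci_g  # (m, m)
    w = np.linalg.solve(gram, ci_g.T)  # (m, E)
    for i in range(w.shape[0]):
        nz = np.flatnonzero(np.abs(w[i]) > 1e-12 * np.max(np.abs(w[i]), initial=1.0))
        if nz.size and w[i, nz[0]] < 0:
            w[i] = -w[i]
    return w


def bandpass_sensor_data(
    data: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 4.0)
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of channels x time."""
    sos = signal.butter(2, np.asarray(band) / (fs / 2), "bandpass", output="sos")
    return signal.sosfiltfilt(sos, data, axis=1)


def extract_source_signals(
    band_data: np.ndarray, sources: CoherentSourceSet
) -> np.ndarray:
    """Scalar source waveforms for the identified source set.

    Uses the multi-constraint (nulled) extraction rows when present — unit
    gain at the own source, zero gain at the other identified sources, so
    the extracted signals carry no mutual zero-lag leakage — and falls
    back to the per-source scalar beamformer rows otherwise.
    """
    if not sources.filters:
        raise ValueError("source set carries no filters")
    n_ch = sources.filters[0].weights.shape[1]
    if band_data.shape[0] != n_ch:
        raise ValueError(f"{band_data.shape[0]} channels vs filters for {n_ch}")
    w = getattr(sources, "scalar_filters", None)
    if w is not None:
        out = w @ band_data
    else:
        out = np.stack([f.scalar_weights() @ band_data for f in sources.filters])
    sources.signals = out
    return out
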