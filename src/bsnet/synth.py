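"""Ground-truth burst-suppression EEG generator.

Simulates a directed delta-band (1-4 Hz) source network — brainstem,
thalamus, and bilateral cortical nodes — as a stable VAR process at a low
model rate, upsamples the node signals to the sensor rate, projects them
through the five-sphere forward model, and adds white sensor noise.  Burst
phases carry the full directed network (brainstem -> thalamus -> cortex,
posterior -> anterior); suppression phases contain only weak, symmetrically
coupled cortical activity with silent subcortical nodes.

Scalp amplitudes are calibrated so that bursts reach 150-350 uV peak-to-peak
and the burst/suppression delta-band power ratio lies in the 35.85-39.09 dB
range reported for clinical burst-suppression recordings; suppression then
stays far below the 25 uV clinical ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .headmodel import (
    SphereModel,
    ElectrodeMontage,
    apply_average_reference,
    build_sphere_model,
    standard_montage_1020,
    _potentials,
)

__all__ = [
    "SourceNodeSpec",
    "NetworkSpec",
    "GroundTruth",
    "Recording",
    "default_network",
    "simulate_network_dynamics",
    "project_sources",
    "assemble_burst_suppression",
    "simulate_cohort",
]

#: rate at which the node VAR dynamics are simulated (Hz); one VAR lag is
#: 31.25 ms, so lags 1-2 give coupling delays of ~31-62 ms
MODEL_FS = 32.0
DELTA_BAND = (1.0, 4.0)

BURST_P2P_RANGE = (150.0, 350.0)
SUPPRESSION_P2P_MAX = 25.0
#: calibration target for the burst/suppression delta-band power ratio (dB),
#: the midpoint of the clinically reported 35.85-39.09 dB range
TARGET_SNR_DB = 37.5


@dataclass(frozen=True)
class SourceNodeSpec:
    name: str
    location: tuple[float, float, float]  # mm
    orientation: tuple[float, float, float]  # unit vector
    burst_amplitude: float  # relative source strength during bursts
    suppression_amplitude: float  # relative strength during suppression (0 = silent)

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"orientation of {self.name} must be unit-norm (got |o|={n})")


@dataclass(frozen=True)
class NetworkSpec:
    """Directed lagged network over the source nodes.

    ``burst_coupling`` / ``suppression_coupling`` are (p, K, K) lag
    coefficient stacks; entry ``[k, i, j]`` couples node j into node i at
    lag k+1 of the 32 Hz model process.
    """

    nodes: tuple[SourceNodeSpec, ...]
    burst_coupling: np.ndarray
    suppression_coupling: np.ndarray
    band: tuple[float, float] = DELTA_BAND

    def __post_init__(self) -> None:
        for name, coupling in (("burst", self.burst_coupling),
                               ("suppression", self.suppression_coupling)):
            a = np.asarray(coupling, dtype=float)
            if a.ndim != 3 or a.shape[1] != a.shape[2] or a.shape[1] != len(self.nodes):
                raise ValueError(f"{name} coupling must be (p, K, K) with K = n nodes")
            if _companion_spectral_radius(a) >= 1.0:
                raise ValueError(f"{name} VAR is unstable "
                                 f"(spectral radius {_companion_spectral_radius(a):.3f})")
        # silent nodes must have no coupling in or out during suppression
        amp = self.amplitudes("suppression")
        silent = np.where(amp == 0)[0]
        sc = np.asarray(self.suppression_coupling)
        if np.any(sc[:, silent, :] != 0) or np.any(sc[:, :, silent] != 0):
            raise ValueError("suppression coupling into/out of silent nodes must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def amplitudes(self, phase: str) -> np.ndarray:
        if phase == "burst":
            return np.array([n.burst_amplitude for n in self.nodes])
        if phase == "suppression":
            return np.array([n.suppression_amplitude for n in self.nodes])
        raise ValueError(f"unknown phase {phase!r}")

    def coupling(self, phase: str) -> np.ndarray:
        return np.asarray(
            self.burst_coupling if phase == "burst" else self.suppression_coupling,
            dtype=float,
        )

    def active_nodes(self, phase: str) -> list[str]:
        amp = self.amplitudes(phase)
        return [n.name for n, a in zip(self.nodes, amp) if a > 0]

    def true_edges(self, phase: str) -> list[tuple[str, str]]:
        """Directed role-level edges (source_role -> target_role) of a phase.

        An edge is listed when any lag couples a node of one role into a
        node of another and the reverse coupling is everywhere weaker
        (suppression-phase symmetric couplings therefore yield no edges).
        """
        coup = self.coupling(phase)
        roles = [_role(n.name) for n in self.nodes]
        strength: dict[tuple[str, str], float] = {}
        for i in range(self.n_nodes):
            for j in range(self.n_nodes):
                if roles[i] == roles[j]:
                    continue
                s = float(np.abs(coup[:, i, j]).sum())
                key = (roles[j], roles[i])  # j -> i
                strength[key] = strength.get(key, 0.0) + s
        edges = []
        for (a, b), s in strength.items():
            if s > 0 and s > strength.get((b, a), 0.0) + 1e-12:
                edges.append((a, b))
        return sorted(edges)


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score a simulated recording."""

    active_nodes: dict[str, list[str]]  # phase -> node names
    true_edges: dict[str, list[tuple[str, str]]]  # phase -> role-level edges
    node_locations: dict[str, tuple[float, float, float]]
    node_projections: dict[str, list[float]]  # name -> per-channel gain (uV / unit signal)
    seed: int
    source_scales: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "active_nodes": self.active_nodes,
            "true_edges": {k: [list(e) for e in v] for k, v in self.true_edges.items()},
            "node_locations": {k: list(v) for k, v in self.node_locations.items()},
            "node_projections": self.node_projections,
            "seed": self.seed,
            "source_scales": self.source_scales,
        }
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class Recording:
    """Multichannel scalp EEG with phase annotations."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    labels: tuple[str, ...]
    annotations: list[tuple[float, float, str]]  # (onset s, duration s, label)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.data.shape[1] / self.fs
        last = 0.0
        for onset, length, _ in sorted(self.annotations):
            if onset < last - 1e-9 or onset + length > dur + 1e-9:
                raise ValueError("annotations overlap or exceed the record bounds")
            last = onset + length

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def _role(name: str) -> str:
    """Strip the hemisphere suffix: 'precuneus_L' -> 'precuneus'."""
    return name.rsplit("_", 1)[0] if name.endswith(("_L", "_R")) else name


def _companion_spectral_radius(coeffs: np.ndarray) -> float:
    p, k, _ = coeffs.shape
    if p == 0 or np.all(coeffs == 0):
        return 0.0
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = coeffs.transpose(1, 0, 2).reshape(k, p * k)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _unit(v) -> tuple[float, float, float]:
    v = np.asarray(v, dtype=float)
    return tuple(v / np.linalg.norm(v))


def default_network() -> NetworkSpec:
    """The default ten-node burst-suppression network.

    Deep nodes follow the anatomy reported for burst-phase generators
    (mid-brain tegmentum and thalamus); cortical nodes sit at 50 mm radius
    along the anatomical directions of the precuneus, somatosensory,
    prefrontal and occipital regions, bilaterally.  Burst coupling carries
    the upward arousal pathway brainstem -> thalamus -> precuneus (plus the
    direct diffuse brainstem -> precuneus projection of the ascending
    arousal system) and the posterior-to-anterior cortical chain precuneus
    -> somatosensory / prefrontal, somatosensory -> prefrontal; suppression
    couples cortical neighbours weakly and symmetrically, with silent deep
    nodes.  Deep nodes carry larger dipole moments than cortical ones:
    subcortical sources must be several-fold stronger to remain visible on
    the scalp, which the clinical detectability of deep burst generators
    implies.  Coupling strengths are moderate so that inter-source
    correlations stay below the regime where a minimum-variance beamformer
    cancels correlated sources.
    """

    def cort(direction, r=50.0):
        d = np.asarray(direction, dtype=float)
        return tuple(d / np.linalg.norm(d) * r)

    nodes = (
        SourceNodeSpec("brainstem", (0.0, -25.0, -15.0), _unit((0.2, 0.3, 1.0)), 2.2, 0.0),
        SourceNodeSpec("thalamus", (0.0, -15.0, 10.0), _unit((0.3, 1.0, 0.4)), 2.4, 0.0),
        SourceNodeSpec("precuneus_L", cort((-20, -55, 45)), _unit((-0.85, 0.35, 0.4)), 2.6, 2.2),
        SourceNodeSpec("precuneus_R", cort((20, -55, 45)), _unit((0.85, 0.35, 0.4)), 2.6, 2.2),
        SourceNodeSpec("somatosensory_L", cort((-35, -25, 50)), _unit((-0.75, 0.2, 0.65)), 0.75, 0.70),
        SourceNodeSpec("somatosensory_R", cort((35, -25, 50)), _unit((0.75, 0.2, 0.65)), 0.75, 0.70),
        SourceNodeSpec("prefrontal_L", cort((-25, 40, 30)), _unit((-0.4, 0.8, 0.5)), 0.60, 0.55),
        SourceNodeSpec("prefrontal_R", cort((25, 40, 30)), _unit((0.4, 0.8, 0.5)), 0.60, 0.55),
        SourceNodeSpec("occipital_L", cort((-15, -65, 10)), _unit((-0.3, -0.9, 0.3)), 0.0, 0.80),
        SourceNodeSpec("occipital_R", cort((15, -65, 10)), _unit((0.3, -0.9, 0.3)), 0.0, 0.80),
    )
    names = [n.name for n in nodes]
    ix = {n: i for i, n in enumerate(names)}
    k = len(nodes)

    burst = np.zeros((3, k, k))
    for i, n in enumerate(nodes):
        if n.burst_amplitude > 0:
            burst[0, i, i] = 0.30  # light self-damping keeps spectra smooth
    # directed influences; lags of 1-2 model steps = 31-62 ms
    burst[0, ix["thalamus"], ix["brainstem"]] = 0.80
    burst[0, ix["precuneus_L"], ix["thalamus"]] = 0.45
    burst[0, ix["precuneus_R"], ix["thalamus"]] = 0.45
    burst[1, ix["precuneus_L"], ix["brainstem"]] = 0.30
    burst[1, ix["precuneus_R"], ix["brainstem"]] = 0.30
    burst[0, ix["somatosensory_L"], ix["precuneus_L"]] = 0.35
    burst[0, ix["somatosensory_R"], ix["precuneus_R"]] = 0.35
    burst[1, ix["prefrontal_L"], ix["precuneus_L"]] = 0.30
    burst[1, ix["prefrontal_R"], ix["precuneus_R"]] = 0.30
    burst[0, ix["prefrontal_L"], ix["somatosensory_L"]] = 0.30
    burst[0, ix["prefrontal_R"], ix["somatosensory_R"]] = 0.30

    supp = np.zeros((3, k, k))
    for i, n in enumerate(nodes):
        if n.suppression_amplitude > 0:
            supp[0, i, i] = 0.30
    pairs = [
        ("precuneus_L", "precuneus_R", 0.32),
        ("precuneus_L", "occipital_L", 0.22), ("precuneus_R", "occipital_R", 0.22),
        ("precuneus_L", "somatosensory_L", 0.22), ("precuneus_R", "somatosensory_R", 0.22),
        ("somatosensory_L", "prefrontal_L", 0.22), ("somatosensory_R", "prefrontal_R", 0.22),
        ("precuneus_L", "prefrontal_L", 0.18), ("precuneus_R", "prefrontal_R", 0.18),
    ]
    for a, b, c in pairs:
        supp[0, ix[a], ix[b]] = c
        supp[0, ix[b], ix[a]] = c
    return NetworkSpec(nodes=nodes, burst_coupling=burst, suppression_coupling=supp)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def simulate_network_dynamics(
    spec: NetworkSpec,
    phase: str,
    duration: float,
    fs: float,
    seed: int | np.random.Generator,
    warmup: float = 5.0,
) -> np.ndarray:
    """Node time series (K x samples) for one phase at sensor rate ``fs``.

    The VAR runs at 32 Hz on innovations band-passed to the delta band
    (zero-phase 4th-order Butterworth); the result is polyphase-upsampled
    to ``fs`` and scaled by the per-node phase amplitudes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = spec.coupling(phase)  # validated stable at construction
    if _companion_spectral_radius(coeffs) >= 1.0:
        raise ValueError("unstable VAR")
    amps = spec.amplitudes(phase)
    k = spec.n_nodes
    p = coeffs.shape[0]

    n_model = int(np.ceil((duration + warmup) * MODEL_FS))
    innov = rng.standard_normal((k, n_model))
    sos = signal.butter(2, np.asarray(spec.band) / (MODEL_FS / 2), "bandpass", output="sos")
    innov = signal.sosfiltfilt(sos, innov, axis=1)

    x = np.zeros((k, n_model))
    for t in range(n_model):
        acc = innov[:, t].copy()
        for lag in range(1, min(p, t) + 1):
            acc += coeffs[lag - 1] @ x[:, t - lag]
        x[:, t] = acc
    x = x[:, int(warmup * MODEL_FS):]
    x *= amps[:, None]

    up = int(round(fs / MODEL_FS))
    if not np.isclose(fs, MODEL_FS * up):
        raise ValueError(f"sensor rate {fs} must be an integer multiple of {MODEL_FS}")
    y = signal.resample_poly(x, up, 1, axis=1) if up > 1 else x
    n_out = int(round(duration * fs))
    return y[:, :n_out]


def project_sources(
    node_signals: np.ndarray,
    node_specs: tuple[SourceNodeSpec, ...] | list[SourceNodeSpec],
    model: SphereModel,
    montage: ElectrodeMontage,
    noise_sigma: float,
    seed: int | np.random.Generator,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Scalp data (uV): sum of forward-projected node signals plus noise."""
    node_signals = np.asarray(node_signals, dtype=float)
    if node_signals.shape[0] != len(node_specs):
        raise ValueError(
            f"{node_signals.shape[0]} signal rows for {len(node_specs)} node specs")
    if gains is None:
        gains = node_gains(node_specs, model, montage)
    data = gains.T @ node_signals  # (E, T)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return apply_average_reference(data)


def node_gains(
    node_specs, model: SphereModel, montage: ElectrodeMontage
) -> np.ndarray:
    """Forward gain column per node (K x E): uV per unit source signal."""
    locs = np.array([n.location for n in node_specs])
    moms = np.array([n.orientation for n in node_specs])
    return _potentials(model, montage, locs, moms)


# ---------------------------------------------------------------------------
# full recordings
# ---------------------------------------------------------------------------

def _phase_band_power(data: np.ndarray, fs: float, band=DELTA_BAND) -> float:
    """Total delta-band power summed over channels (Welch)."""
    f, p = signal.welch(data, fs=fs, nperseg=int(2 * fs), axis=1)
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[:, sel].sum())


def assemble_burst_suppression(
    spec: NetworkSpec | None = None,
    n_bursts: int = 28,
    burst_duration: tuple[float, float] = (2.0, 4.0),
    suppression_duration: tuple[float, float] = (2.0, 4.0),
    fs: float = 512.0,
    seed: int = 0,
    model: SphereModel | None = None,
    montage: ElectrodeMontage | None = None,
    noise_sigma: float = 0.2,
    burst_p2p_target: float = 250.0,
    snr_target_db: float = TARGET_SNR_DB,
    max_retune: int = 10,
    n_background: int = 80,
    background_fraction: float = 0.10,
) -> tuple[Recording, GroundTruth]:
    """Simulate one annotated burst-suppression recording with ground truth.

    Source moments are calibrated so the maximum burst peak-to-peak scalp
    amplitude hits ``burst_p2p_target`` (within 150-350 uV) and the
    burst/suppression delta-band power ratio hits ``snr_target_db``.

    Besides the network nodes, ``n_background`` random dipoles spread
    through the brain carry independent delta-band activity whose scalp
    band power is ``background_fraction`` of each phase's network power:
    spatially-distributed brain noise scales with the global activity
    level and bounds the adaptivity of sensor-covariance-based methods,
    as it does in real EEG.
    """
    spec = spec or default_network()
    model = model or build_sphere_model()
    montage = montage or standard_montage_1020(19)
    rng = np.random.default_rng(seed)
    gains = node_gains(spec.nodes, model, montage)

    # background dipole population (fixed per recording)
    if n_background > 0:
        bg_dirs = rng.standard_normal((n_background, 3))
        bg_dirs /= np.linalg.norm(bg_dirs, axis=1, keepdims=True)
        bg_radii = (model.inner_radius - 6.0) * rng.uniform(0, 1, n_background) ** (1 / 3)
        bg_locs = bg_dirs * bg_radii[:, None]
        bg_oris = rng.standard_normal((n_background, 3))
        bg_oris /= np.linalg.norm(bg_oris, axis=1, keepdims=True)
        bg_gains = _potentials(model, montage, bg_locs, bg_oris)  # (N, E)
        sos_bg = signal.butter(2, np.asarray(spec.band) / (MODEL_FS / 2),
                               "bandpass", output="sos")
    else:
        bg_gains = None

    durations: list[tuple[str, float]] = []
    for _ in range(n_bursts):
        durations.append(("burst", float(rng.uniform(*burst_duration))))
        durations.append(("suppression", float(rng.uniform(*suppression_duration))))

    # simulate source signals per segment (sample counts exact per segment)
    segs = [(lab, simulate_network_dynamics(spec, lab, dur, fs, rng))
            for lab, dur in durations]

    def noiseless_scalp(sig_seg: np.ndarray) -> np.ndarray:
        v = gains.T @ sig_seg
        return v - v.mean(axis=0, keepdims=True)

    # Per-burst amplitude calibration: every burst's peak-to-peak scalp
    # amplitude is set inside the clinical 150-350 uV band (each burst of a
    # real recording satisfies the band individually, not just the record
    # maximum).  Linear scaling of all nodes in a segment preserves the
    # directed lag structure.
    lo = burst_p2p_target - 40.0
    hi = burst_p2p_target + 40.0
    if not (BURST_P2P_RANGE[0] < lo and hi < BURST_P2P_RANGE[1]):
        raise ValueError(f"burst_p2p_target {burst_p2p_target} leaves no margin "
                         f"inside {BURST_P2P_RANGE}")
    seg_scales: list[float] = []
    for lab, sig_seg in segs:
        if lab != "burst":
            seg_scales.append(1.0)
            continue
        v = noiseless_scalp(sig_seg)
        p2p = float(np.max(v.max(axis=1) - v.min(axis=1)))
        if p2p <= 0:
            seg_scales.append(0.0)
            continue
        seg_scales.append(float(rng.uniform(lo, hi)) / p2p)

    def scalp(phase: str) -> np.ndarray:
        xs = [s * sc for (lab, s), sc in zip(segs, seg_scales) if lab == phase]
        return noiseless_scalp(np.concatenate(xs, axis=1))

    scale_b = float(np.median([sc for (lab, _), sc in zip(segs, seg_scales)
                               if lab == "burst"]))
    scale_s = 1.0
    pb = _phase_band_power(scalp("burst"), fs)
    if np.any(spec.amplitudes("suppression") > 0) and pb > 0:
        # suppression strength calibrated to the clinical burst/suppression
        # delta-band power ratio
        for attempt in range(max_retune):
            vs = scalp("suppression") * scale_s
            ps = _phase_band_power(vs, fs)
            snr = 10 * np.log10(pb / ps)
            scale_s *= 10 ** ((snr - snr_target_db) / 20.0)
            if abs(snr - snr_target_db) < 0.05:
                break
        else:
            raise RuntimeError("suppression SNR calibration did not converge")
        vs = scalp("suppression") * scale_s
        p2p_s = float(np.max(vs.max(axis=1) - vs.min(axis=1)))
        if p2p_s >= SUPPRESSION_P2P_MAX:
            raise RuntimeError(
                f"calibrated suppression peak-to-peak {p2p_s:.1f} uV exceeds "
                f"{SUPPRESSION_P2P_MAX} uV")

    chunks = []
    annotations = []
    t = 0.0
    for (lab, sig_seg), sc in zip(segs, seg_scales):
        scale = sc if lab == "burst" else sc * scale_s
        chunks.append(gains.T @ (sig_seg * scale))
        n = sig_seg.shape[1]
        annotations.append((t, n / fs, lab))
        t += n / fs
    data = np.concatenate(chunks, axis=1)

    if bg_gains is not None and background_fraction > 0:
        n_total = data.shape[1]
        up = int(round(fs / MODEL_FS))
        n_model = n_total // up + 8
        bg_sig = signal.sosfiltfilt(
            sos_bg, rng.standard_normal((n_background, n_model)), axis=1)
        bg_sig = signal.resample_poly(bg_sig, up, 1, axis=1)[:, :n_total]
        bg_scalp = bg_gains.T @ bg_sig  # (E, T)
        # per-phase scaling: background power follows the global activity level
        pos = 0
        for (lab, sig_seg), sc in zip(segs, seg_scales):
            n = sig_seg.shape[1]
            sl = slice(pos, pos + n)
            p_net = _phase_band_power(data[:, sl], fs)
            p_bg = _phase_band_power(bg_scalp[:, sl], fs)
            if p_bg > 0 and p_net > 0:
                data[:, sl] += bg_scalp[:, sl] * np.sqrt(
                    background_fraction * p_net / p_bg)
            pos += n

    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    data = apply_average_reference(data)

    rec = Recording(data=data, fs=fs, labels=montage.labels, annotations=annotations)
    gt = GroundTruth(
        active_nodes={ph: spec.active_nodes(ph) for ph in ("burst", "suppression")},
        true_edges={ph: spec.true_edges(ph) for ph in ("burst", "suppression")},
        node_locations={n.name: tuple(n.location) for n in spec.nodes},
        node_projections={n.name: list(gains[i]) for i, n in enumerate(spec.nodes)},
        seed=int(seed) if np.isscalar(seed) else -1,
        source_scales={"burst": scale_b, "suppression": scale_s},
    )
    return rec, gt


def simulate_cohort(
    n_subjects: int = 13,
    base_spec: NetworkSpec | None = None,
    location_jitter: float = 5.0,
    amplitude_jitter: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> list[tuple[Recording, GroundTruth]]:
    """Cohort of independently jittered subjects from one master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_spec = base_spec or default_network()
    model = kwargs.get("model") or build_sphere_model()
    kwargs.setdefault("model", model)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        spec = _jitter_spec(base_spec, rng, location_jitter, amplitude_jitter, model)
        out.append(assemble_burst_suppression(spec, seed=sub_seed, **kwargs))
    return out


def _jitter_spec(
    spec: NetworkSpec,
    rng: np.random.Generator,
    location_jitter: float,
    amplitude_jitter: float,
    model: SphereModel,
) -> NetworkSpec:
    if location_jitter == 0 and amplitude_jitter == 0:
        return spec
    nodes = []
    margin = 1.0
    for n in spec.nodes:
        loc = np.asarray(n.location, dtype=float)
        if location_jitter > 0:
            # uniform in the ball of radius <= location_jitter
            d = rng.standard_normal(3)
            d *= rng.uniform(0, location_jitter) / np.linalg.norm(d)
            loc = loc + d
            r = np.linalg.norm(loc)
            rmax = model.inner_radius - margin
            if r > rmax:
                loc *= rmax / r
        fac = 1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter)
        nodes.append(SourceNodeSpec(
            n.name, tuple(loc), n.orientation,
            n.burst_amplitude * fac, n.suppression_amplitude * fac,
        ))
    return NetworkSpec(
        nodes=tuple(nodes),
        burst_coupling=spec.burst_coupling,
        suppression_coupling=spec.suppression_coupling,
        band=spec.band,
    )
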