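"""Synthetic multi-subject resting-state BOLD data with known ground truth.

The generator emulates the statistical structure that low-frequency
fluctuation analysis assumes, on a small voxel grid with three labelled
tissue compartments (grey matter, white matter, cerebrospinal fluid):

* band-limited grey-matter fluctuations in a configurable band
  (default 0.01–0.1 Hz) with a per-subject spatial amplitude map;
* subject-specific constant/linear/quadratic scanner drifts, stable
  across a subject's sessions up to a small session-level jitter;
* a non-polynomial scanner wander band-limited below the analysis band
  (real drift is smooth but not an exact polynomial, so polynomial
  detrending removes it only approximately);
* shared physiological components (aliased cardiac/respiratory
  sinusoids) coupled into each tissue with tissue-specific weights and
  session-specific amplitude and phase;
* motion-coupled signal derived linearly from simulated realignment
  parameters (slow random walks with occasional spikes);
* white thermal noise and a smooth multiplicative bias field.

Every voxel time course is

``bold = bias * (baseline + gm_signal + drift + physio + motion + noise)``

and the generating components are returned alongside the data so that
parameter-recovery and variance-decomposition tests can check the
analysis pipeline against ground truth.  All randomness descends from a
single integer seed through ``numpy.random.SeedSequence`` spawn keys, so
a subject's stable characteristics are reproduced identically for every
one of their sessions and the whole group is bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .regression import normalised_time_axis

__all__ = [
    "SimulationConfig",
    "SubjectDataset",
    "GroundTruth",
    "TISSUES",
    "TISSUE_BASELINES",
    "make_tissue_masks",
    "generate_drift",
    "generate_band_limited_signal",
    "generate_bias_field",
    "generate_realignment_params",
    "generate_subject",
    "generate_group",
]

TISSUES = ("gm", "wm", "csf")

#: Mean signal intensity per tissue compartment (arbitrary scanner units).
TISSUE_BASELINES = {"gm": 100.0, "wm": 80.0, "csf": 120.0}

#: Session-level drift jitter, as a fraction of ``drift_coeff_sd``.
SESSION_DRIFT_JITTER = 0.1

#: Relative spread of the constant/linear/quadratic drift coefficients.
DRIFT_COEFF_WEIGHTS = np.array([1.0, 1.0, 1.0])

#: Log-scale spread of the per-subject CSF pulsatility factor.  CSF
#: physiological amplitude varies strongly between subjects independently
#: of the global fluctuation scale (cardiac-driven pulsatile flow).
CSF_PULSATILITY_SD = 0.5

#: Session-to-session jitter (Hz) of each physiological frequency;
#: cardiac and respiratory rates differ between runs.
PHYSIO_FREQ_JITTER_HZ = 0.01

#: Amplitude (a.u.) of the shared broadband aperiodic fluctuation carried
#: by each non-grey tissue (slow flow and respiratory volume effects);
#: this is the shared tissue noise that component-based nuisance
#: regression is designed to capture.
TISSUE_NOISE_SD = 0.4


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic resting-state acquisition.

    Defaults emulate a standard 2-s TR EPI protocol with 128 volumes per
    run, two runs per subject and a 20-subject group.  Noise magnitudes
    are in the same arbitrary units as the tissue baselines (~100 a.u.);
    see the package methods note for the rationale behind each value.

    ``lff_band`` is the nominal analysis band.  The grey-matter
    fluctuation process itself has a 1/f-shaped spectrum
    (``gm_spectral_exponent``) reaching from ``gm_process_low_hz`` (0 =
    the lowest resolvable bin) up to the band's upper edge: real
    low-frequency fluctuations are not brick-walled at the lower analysis
    edge, and their sub-band tail is what the fALFF denominator absorbs.
    ``subject_amp_sd`` is the log-scale spread of a per-subject global
    fluctuation-amplitude factor (biological heterogeneity).
    """

    n_subjects: int = 20
    n_sessions: int = 2
    n_timepoints: int = 128
    tr_seconds: float = 2.0
    grid_dims: tuple[int, int, int] = (18, 16, 10)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    lff_band: tuple[float, float] = (0.01, 0.1)
    gm_lff_sd: float = 1.0
    subject_amp_sd: float = 0.4
    gm_spectral_exponent: float = 1.3
    gm_process_low_hz: float = 0.0
    drift_coeff_sd: float = 0.5
    slow_drift_sd: float = 0.25
    physio_freqs: tuple[float, ...] = (0.05, 0.16, 0.2)
    physio_coupling: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"gm": 0.5, "wm": 1.0, "csf": 1.5}
    )
    motion_coupling: float = 0.7
    thermal_noise_sd: float = 0.5
    bias_field_range: tuple[float, float] = (0.8, 1.25)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.lff_band
        if not (0.0 < low < high < nyquist):
            raise ValueError(
                f"lff_band {self.lff_band} must lie strictly inside "
                f"(0, Nyquist={nyquist} Hz)"
            )
        if self.gm_process_low_hz < 0 or self.gm_process_low_hz >= self.lff_band[1]:
            raise ValueError("gm_process_low_hz must lie in [0, band high)")
        for name in (
            "gm_lff_sd",
            "subject_amp_sd",
            "drift_coeff_sd",
            "slow_drift_sd",
            "motion_coupling",
            "thermal_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.bias_field_range
        if not (0.0 < lo <= hi):
            raise ValueError("bias_field_range must be strictly positive, min <= max")
        if set(self.physio_coupling) - set(TISSUES):
            raise ValueError(f"physio_coupling keys must be among {TISSUES}")
        for f in self.physio_freqs:
            if not (0.0 < f <= nyquist):
                raise ValueError(f"physio frequency {f} outside (0, Nyquist]")
        if any(d < 1 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ValueError("grid_dims must be three positive voxel counts")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclasses.dataclass
class GroundTruth:
    """Generating components of one synthetic session."""

    drift: np.ndarray  # (N,) polynomial drift time course added to brain voxels
    drift_coeffs: np.ndarray  # (3,) session-level polynomial coefficients
    subject_drift_coeffs: np.ndarray  # (3,) subject-level coefficients
    slow_drift: np.ndarray  # (N,) non-polynomial sub-band scanner wander
    physio: np.ndarray  # (N, n_freqs) unit-coupling physiological series
    motion_signal: np.ndarray  # (N,) motion-coupled component
    amplitude_map: np.ndarray  # 3-D, band-limited signal SD per GM voxel


@dataclasses.dataclass
class SubjectDataset:
    """One synthetic subject/session: data, masks, and ground truth."""

    bold: np.ndarray  # (x, y, z, N)
    masks: dict[str, np.ndarray]  # disjoint boolean volumes per tissue
    realignment_params: np.ndarray  # (N, 6)
    bias_field: np.ndarray  # 3-D positive gain
    ground_truth: GroundTruth
    subject_index: int
    session_index: int
    tr_seconds: float

    def __post_init__(self) -> None:
        n = self.bold.shape[-1]
        if self.realignment_params.shape != (n, 6):
            raise ValueError("realignment_params must have one row per time point")
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("bold contains non-finite values")
        if np.any(self.bias_field <= 0):
            raise ValueError("bias field must be strictly positive")
        pairs = [("gm", "wm"), ("gm", "csf"), ("wm", "csf")]
        for a, b in pairs:
            if np.any(self.masks[a] & self.masks[b]):
                raise ValueError(f"masks {a!r} and {b!r} overlap")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.masks["gm"] | self.masks["wm"] | self.masks["csf"]

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[-1]


def make_tissue_masks(grid_dims: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Three disjoint box-shaped tissue compartments on a small grid.

    The compartments are adjacent boxes along x, separated by one-voxel
    gaps and surrounded by a one-voxel out-of-brain border, so that each
    survives a one-voxel morphological erosion.  Grey matter takes the
    largest share (roughly 55/25/20 GM/WM/CSF), mirroring the tissue
    composition of an in-brain mask.  Group statistics only need labelled
    compartments, not anatomical shapes.
    """
    nx, ny, nz = grid_dims
    usable = nx - 4  # 1-voxel outer borders and two 1-voxel gaps
    gm_w = max(3, round(usable * 0.55))
    csf_w = max(3, round(usable * 0.20))
    wm_w = usable - gm_w - csf_w
    if wm_w < 3 or ny < 5 or nz < 5:
        raise ValueError(
            f"grid {grid_dims} too small to host three disjoint tissue "
            "compartments (need at least 17 x 5 x 5 voxels)"
        )
    masks = {}
    x0 = 1
    for tissue, width in zip(TISSUES, (gm_w, wm_w, csf_w)):
        m = np.zeros(grid_dims, dtype=bool)
        m[x0 : x0 + width, 1 : ny - 1, 1 : nz - 1] = True
        masks[tissue] = m
        x0 += width + 1
    return masks


def generate_drift(n_timepoints: int, coeffs) -> np.ndarray:
    """Polynomial drift ``c0 + c1*t + c2*t**2`` on a [-1, 1] time axis."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (3,):
        raise ValueError("coeffs must be three scalars (constant, linear, quadratic)")
    if not np.all(np.isfinite(c)):
        raise ValueError("drift coefficients must be finite")
    t = normalised_time_axis(n_timepoints)
    return c[0] + c[1] * t + c[2] * t**2


def _band_limited(
    n_timepoints: int,
    tr_seconds: float,
    band: tuple[float, float],
    sd,
    rng: np.random.Generator,
    n_series: int = 1,
    spectral_exponent: float = 0.0,
) -> np.ndarray:
    """Vectorised band-limited series, shape (n_series, N), exact sample SD.

    ``spectral_exponent`` > 0 weights the in-band magnitudes by
    ``f ** -exponent`` (1/f-type colouring); 0 gives a flat spectrum.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError(
            f"no DFT bin falls inside band {band} Hz "
            f"(bin spacing {freqs[1]:.6g} Hz, N={n_timepoints})"
        )
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    k = int(in_band.sum())
    weights = freqs[in_band] ** -spectral_exponent if spectral_exponent else 1.0
    spec[:, in_band] = weights * (
        rng.normal(size=(n_series, k)) + 1j * rng.normal(size=(n_series, k))
    )
    x = np.fft.irfft(spec, n=n_timepoints, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * np.reshape(np.broadcast_to(sd, (n_series,)), (n_series, 1))


def generate_band_limited_signal(
    n_timepoints: int,
    tr_seconds: float,
    band: tuple[float, float],
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean series whose spectral content lies inside ``band``.

    Constructed directly in the Fourier domain: independent complex
    Gaussian coefficients at the in-band bins, zeros elsewhere, inverse
    transformed and rescaled so the sample standard deviation equals
    ``sd`` exactly.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return _band_limited(n_timepoints, tr_seconds, band, sd, rng, n_series=1)[0]


def generate_bias_field(
    grid_dims: tuple[int, int, int],
    gain_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth positive multiplicative gain field with values in ``gain_range``.

    White noise is low-pass filtered with a broad Gaussian kernel (a
    quarter of the grid extent) and min-max rescaled into the requested
    range, mimicking slowly varying receive-coil sensitivity.
    """
    lo, hi = gain_range
    if lo <= 0:
        raise ValueError("bias field minimum must be strictly positive")
    if hi < lo:
        raise ValueError("bias field range must satisfy min <= max")
    if lo == hi:
        return np.full(grid_dims, lo)
    raw = rng.normal(size=grid_dims)
    sigma = [max(d / 4.0, 1.0) for d in grid_dims]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    smin, smax = smooth.min(), smooth.max()
    if smax == smin:  # pathological but possible on a 1-voxel grid
        return np.full(grid_dims, 0.5 * (lo + hi))
    return lo + (smooth - smin) / (smax - smin) * (hi - lo)


def generate_realignment_params(
    n_timepoints: int,
    rng: np.random.Generator,
    translation_step_mm: float = 0.02,
    rotation_step_rad: float = 5e-4,
    spike_probability: float = 0.02,
) -> np.ndarray:
    """Six rigid-body motion parameters: slow random walks plus spikes.

    Columns are three translations (mm) and three rotations (rad).  Each
    is an integrated Gaussian random walk; occasional step spikes of ten
    times the usual magnitude emulate abrupt head movements.
    """
    steps = np.empty((n_timepoints, 6))
    steps[:, :3] = rng.normal(0.0, translation_step_mm, size=(n_timepoints, 3))
    steps[:, 3:] = rng.normal(0.0, rotation_step_rad, size=(n_timepoints, 3))
    spikes = rng.random((n_timepoints, 6)) < spike_probability
    steps[spikes] *= 10.0
    rp = np.cumsum(steps, axis=0)
    rp[0] = 0.0  # realignment is relative to the first volume
    return rp


def _motion_signal(rp: np.ndarray, coupling: float) -> np.ndarray:
    """Low-order combination of realignment parameters: mean of z-scored RPs."""
    sd = rp.std(axis=0)
    ok = sd > 0
    if not ok.any() or coupling == 0.0:
        return np.zeros(rp.shape[0])
    z = (rp[:, ok] - rp[:, ok].mean(axis=0)) / sd[ok]
    return coupling * z.mean(axis=1)


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(subject_index,))
    return np.random.default_rng(ss)


def _session_rng(
    config: SimulationConfig, subject_index: int, session_index: int
) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.rng_seed, spawn_key=(subject_index, session_index + 1)
    )
    return np.random.default_rng(ss)


def _subject_params(config: SimulationConfig, subject_index: int, masks):
    """Stable per-subject characteristics, identical for all sessions."""
    rng = _subject_rng(config, subject_index)
    drift_coeffs = rng.normal(0.0, config.drift_coeff_sd * DRIFT_COEFF_WEIGHTS)
    slow_drift_scale = config.slow_drift_sd * np.exp(rng.normal(0.0, 0.4))
    gm = masks["gm"]
    brain = masks["gm"] | masks["wm"] | masks["csf"]
    subject_amp = np.exp(rng.normal(0.0, config.subject_amp_sd))
    amp_map = np.zeros(config.grid_dims)
    amp_map[gm] = (
        config.gm_lff_sd * subject_amp * rng.uniform(0.8, 1.2, size=int(gm.sum()))
    )
    # Motion and scanner-drift artefacts are spatially heterogeneous (edge
    # and interface effects); per-voxel coupling weights, stable within a
    # subject, model that heterogeneity.
    n_brain = int(brain.sum())
    motion_weights = np.zeros(config.grid_dims)
    motion_weights[brain] = rng.uniform(0.0, 2.0, size=n_brain)
    drift_gain = np.zeros(config.grid_dims)
    drift_gain[brain] = rng.uniform(0.5, 1.5, size=n_brain)
    csf_pulsatility = np.exp(rng.normal(0.0, CSF_PULSATILITY_SD))
    bias = generate_bias_field(config.grid_dims, config.bias_field_range, rng)
    return (
        drift_coeffs,
        slow_drift_scale,
        amp_map,
        motion_weights,
        drift_gain,
        bias,
        subject_amp,
        csf_pulsatility,
    )


def _slow_drift(
    config: SimulationConfig, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Non-polynomial scanner wander band-limited below the analysis band.

    Real scanner drift is smooth but not an exact polynomial; its content
    below the low-frequency band edge is what polynomial detrending can
    remove only approximately.  Band-limited to (0, 0.95 * band_low] Hz;
    for runs too short to resolve any sub-band bin this returns zeros.
    """
    n = config.n_timepoints
    upper = 0.95 * config.lff_band[0]
    freqs = np.fft.rfftfreq(n, d=config.tr_seconds)
    if scale <= 0 or not np.any((freqs > 0) & (freqs <= upper)):
        return np.zeros(n)
    return generate_band_limited_signal(
        n, config.tr_seconds, (freqs[1] / 2.0, upper), scale, rng
    )


def generate_subject(
    config: SimulationConfig, subject_index: int = 0, session_index: int = 0
) -> SubjectDataset:
    """Generate one synthetic session for one subject.

    Subject-stable characteristics (drift coefficients, grey-matter
    amplitude map, bias field) are derived from a per-subject seed stream
    and therefore identical across that subject's sessions; everything
    else (component realisations, motion, physiological phase/amplitude,
    noise, session drift jitter) is drawn from a per-session stream.
    """
    n = config.n_timepoints
    masks = make_tissue_masks(config.grid_dims)
    (
        subj_coeffs,
        slow_scale,
        amp_map,
        motion_weights,
        drift_gain,
        bias,
        subject_amp,
        csf_pulsatility,
    ) = _subject_params(config, subject_index, masks)
    rng = _session_rng(config, subject_index, session_index)

    sess_coeffs = subj_coeffs + rng.normal(
        0.0, SESSION_DRIFT_JITTER * config.drift_coeff_sd * DRIFT_COEFF_WEIGHTS
    )
    drift = generate_drift(n, sess_coeffs)
    slow_drift = _slow_drift(config, slow_scale, rng)

    # physiological components are sinusoids whose exact frequency varies
    # from session to session around the nominal value (cardiac and
    # respiratory rates differ between runs and never sit exactly on a
    # DFT bin), with session-varying amplitude and phase
    t = np.arange(n) * config.tr_seconds
    physio = np.zeros((n, len(config.physio_freqs)))
    for j, f in enumerate(config.physio_freqs):
        amplitude = np.exp(rng.normal(0.0, 0.35))  # session-varying strength
        f_sess = f + rng.uniform(-PHYSIO_FREQ_JITTER_HZ, PHYSIO_FREQ_JITTER_HZ)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        physio[:, j] = amplitude * np.sin(2.0 * np.pi * f_sess * t + phase)

    rp = generate_realignment_params(n, rng)
    motion = _motion_signal(rp, config.motion_coupling)

    bold = np.zeros(config.grid_dims + (n,))
    for tissue in TISSUES:
        m = masks[tissue]
        # CSF carries the subject's pulsatility factor: cardiac-driven
        # pulsatile flow varies strongly between subjects
        coupling = config.physio_coupling.get(tissue, 0.0)
        if tissue == "csf":
            coupling *= csf_pulsatility
        base = TISSUE_BASELINES[tissue] + coupling * physio.sum(axis=1)
        if tissue in ("wm", "csf"):
            # shared broadband aperiodic tissue fluctuation, 1/f-shaped,
            # with subject-varying amplitude (CSF scaled by pulsatility)
            scale = TISSUE_NOISE_SD * (csf_pulsatility if tissue == "csf" else 1.0)
            nyq = config.nyquist_hz
            freqs_all = np.fft.rfftfreq(n, d=config.tr_seconds)
            base = base + _band_limited(
                n,
                config.tr_seconds,
                (freqs_all[1] / 2.0, nyq),
                scale,
                rng,
                spectral_exponent=1.0,
            )[0]
        bold[m] = (
            base
            + drift_gain[m, None] * (drift + slow_drift)
            + motion_weights[m, None] * motion
        )

    gm = masks["gm"]
    n_gm = int(gm.sum())
    if config.gm_lff_sd > 0:
        freqs = np.fft.rfftfreq(n, d=config.tr_seconds)
        process_low = config.gm_process_low_hz if config.gm_process_low_hz > 0 else freqs[1] / 2.0
        signals = _band_limited(
            n,
            config.tr_seconds,
            (process_low, config.lff_band[1]),
            amp_map[gm],
            rng,
            n_series=n_gm,
            spectral_exponent=config.gm_spectral_exponent,
        )
        bold[gm] += signals

    if config.thermal_noise_sd > 0:
        brain = masks["gm"] | masks["wm"] | masks["csf"]
        bold[brain] += rng.normal(
            0.0, config.thermal_noise_sd, size=(int(brain.sum()), n)
        )

    bold *= bias[..., None]

    truth = GroundTruth(
        drift=drift,
        drift_coeffs=sess_coeffs,
        subject_drift_coeffs=subj_coeffs,
        slow_drift=slow_drift,
        physio=physio,
        motion_signal=motion,
        amplitude_map=amp_map,
    )
    return SubjectDataset(
        bold=bold,
        masks=masks,
        realignment_params=rp,
        bias_field=bias,
        ground_truth=truth,
        subject_index=subject_index,
        session_index=session_index,
        tr_seconds=config.tr_seconds,
    )


def generate_group(config: SimulationConfig) -> dict[int, dict[int, SubjectDataset]]:
    """Generate all subjects and sessions of a synthetic group.

    Returns ``{subject_index: {session_index: SubjectDataset}}``.  With a
    fixed ``config.rng_seed`` the output is bit-reproducible, and each
    subject's stable characteristics are shared across their sessions.
    """
    if config.n_subjects < 2:
        raise ValueError("a group needs at least 2 subjects")
    return {
        s: {
            r: generate_subject(config, subject_index=s, session_index=r)
            for r in range(config.n_sessions)
        }
        for s in range(config.n_subjects)
    }
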