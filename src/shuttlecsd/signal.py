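"""Laminar LFP preprocessing and current source density transforms.

The one-dimensional CSD is estimated as the negated second spatial
difference of the laminar field potential along the electrode axis,

    CSD(z, t) = -[Phi(z + n*dz) - 2*Phi(z) + Phi(z - n*dz)] / (n*dz)**2,

with sinks (net inward current) negative.  Because the second difference
annihilates any depth-constant or depth-linear component, the transform is
reference-free and insensitive to far-field potentials.  The AVREC trace is
the per-timepoint mean of the rectified CSD over channels and summarizes the
overall columnar current flow.

Channel 0 is the most superficial contact; depth grows with channel index.
Spacing is carried in micrometres; internally the CSD divides by the spacing
in millimetres, so with potentials in millivolts the CSD is in mV/mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hamming

LAYERS = ("I/II", "III/IV", "Va", "Vb", "VI")


class LayerAssignmentError(RuntimeError):
    """Raised when sink clusters cannot be identified automatically."""


@dataclass
class LaminarRecording:
    """Channels x samples laminar field potential for one trial.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Field potential; channel 0 most superficial.
    fs : float
        Sampling rate in Hz.
    spacing_um : float
        Inter-channel spacing in micrometres.
    t0 : float
        Time of the first sample relative to trial onset (s); negative values
        are pre-trial baseline.
    """

    data: np.ndarray
    fs: float
    spacing_um: float = 50.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] < 3:
            raise ValueError("laminar recording needs at least 3 channels")
        if self.fs <= 0 or self.spacing_um <= 0:
            raise ValueError("fs and spacing_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class CSDParams:
    """Parameters of the CSD estimator.

    n : differential grid multiplier (spatial step = n * spacing).
    smoothing_channels : odd length of the spatial Hamming kernel applied to
        the LFP before differentiation (9 channels at 50 um ~ a 400 um filter).
    boundary : "replicate" computes all channels with edge-replication and
        marks the outer n channels in the validity mask; "drop" sets them NaN.
    """

    n: int = 1
    smoothing_channels: int = 9
    boundary: str = "replicate"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("differential grid n must be >= 1")
        if self.smoothing_channels % 2 == 0:
            raise ValueError("smoothing window length must be odd")
        if self.boundary not in ("replicate", "drop"):
            raise ValueError("boundary must be 'replicate' or 'drop'")


@dataclass
class CSDProfile:
    """Channels x samples CSD with sink-negative sign convention."""

    values: np.ndarray
    fs: float
    spacing_um: float = 50.0
    t0: float = 0.0
    #: True for channels whose value relied on boundary padding (or was dropped)
    boundary_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.boundary_mask is None:
            self.boundary_mask = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.boundary_mask = np.asarray(self.boundary_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.shape[1]) / self.fs


@dataclass
class AVRECTrace:
    """Average rectified CSD: per-sample mean of |CSD| over channels."""

    values: np.ndarray
    fs: float
    n_channels: int
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.shape[0]) / self.fs


@dataclass
class LayerMap:
    """Inclusive channel ranges for the five laminar bands.

    ``bands`` maps each of "I/II", "III/IV", "Va", "Vb", "VI" to a
    ``(first, last)`` pair of 0-based channel indices.
    """

    bands: dict

    def __post_init__(self) -> None:
        missing = [l for l in LAYERS if l not in self.bands]
        if missing:
            raise ValueError(f"layer map missing bands: {missing}")
        prev_last = -1
        for layer in LAYERS:
            lo, hi = self.bands[layer]
            if lo > hi:
                raise ValueError(f"band {layer} has first > last")
            if lo != prev_last + 1:
                raise ValueError(
                    f"bands must be contiguous and depth-ordered; {layer} "
                    f"starts at {lo}, expected {prev_last + 1}"
                )
            prev_last = hi
        self.n_channels_covered = prev_last + 1

    def validate_against(self, n_channels: int) -> None:
        if self.bands["VI"][1] >= n_channels:
            raise ValueError("layer map extends beyond channel count")

    def channels(self, layer: str) -> np.ndarray:
        lo, hi = self.bands[layer]
        return np.arange(lo, hi + 1)


def interpolate_bad_channels(rec: LaminarRecording, bad: set) -> LaminarRecording:
    """Replace bad channels by linear interpolation between good neighbours.

    Bad channels beyond the outermost good channel copy the nearest good one.
    """
    bad = set(int(b) for b in bad)
    n = rec.n_channels
    if not bad:
        return replace(rec, data=rec.data.copy())
    if not all(0 <= b < n for b in bad):
        raise ValueError("bad channel index out of range")
    good = np.array(sorted(set(range(n)) - bad))
    if good.size == 0:
        raise ValueError("all channels marked bad; nothing to interpolate from")
    out = rec.data.copy()
    for b in sorted(bad):
        below = good[good < b]
        above = good[good > b]
        if below.size and above.size:
            lo, hi = below[-1], above[0]
            w = (b - lo) / (hi - lo)
            out[b] = (1.0 - w) * rec.data[lo] + w * rec.data[hi]
        elif above.size:  # bad channel at the superficial edge
            out[b] = rec.data[above[0]]
        else:  # bad channel at the deep edge
            out[b] = rec.data[below[-1]]
    return replace(rec, data=out)


def smooth_channels(rec: LaminarRecording, window: int = 9) -> LaminarRecording:
    """Spatially smooth the LFP across channels with a normalized Hamming window.

    Edges are handled by replicate padding, so depth-constant profiles pass
    through unchanged.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window length must be odd")
    if window > rec.n_channels:
        raise ValueError("smoothing window longer than channel count")
    if window == 1:
        return replace(rec, data=rec.data.copy())
    w = hamming(window, sym=True)
    w = w / w.sum()
    half = window // 2
    padded = np.pad(rec.data, ((half, half), (0, 0)), mode="edge")
    # correlate along the channel axis
    out = np.zeros_like(rec.data)
    for k in range(window):
        out += w[k] * padded[k : k + rec.n_channels]
    return replace(rec, data=out)


def hamming_weights(window: int = 9) -> np.ndarray:
    """Normalized spatial smoothing weights (exposed for inspection/tests)."""
    w = hamming(window, sym=True)
    return w / w.sum()


@dataclass
class ArtifactReport:
    rejected: bool
    reason: str | None
    n_masked_samples: int


def reject_artifacts(
    rec: LaminarRecording,
    amplitude_sd_threshold: float = 10.0,
    us_onset: float | None = None,
) -> tuple[LaminarRecording, ArtifactReport]:
    """Mask shock-clipped samples and flag extreme-amplitude trials.

    Samples at/after ``us_onset`` (trial-relative seconds) are removed, since
    the foot shock clips the amplifier.  The trial is flagged rejected when
    any channel exceeds ``amplitude_sd_threshold`` robust standard deviations
    (1.4826 * median absolute deviation, per channel) of the retained signal.
    """
    if amplitude_sd_threshold <= 0:
        raise ValueError("amplitude_sd_threshold must be positive")
    data = rec.data
    n_masked = 0
    if us_onset is not None:
        keep = rec.times < us_onset
        n_masked = int(np.sum(~keep))
        data = data[:, keep]
        if data.shape[1] == 0:
            raise ValueError("US onset precedes the whole recording")
    centered = data - np.median(data, axis=1, keepdims=True)
    mad = np.median(np.abs(centered), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    # guard silent channels
    floor = np.median(robust_sd[robust_sd > 0]) if np.any(robust_sd > 0) else 1.0
    robust_sd = np.maximum(robust_sd, 1e-12 * floor)
    exceed = np.abs(centered) > amplitude_sd_threshold * robust_sd
    rejected = bool(exceed.any())
    reason = None
    if rejected:
        ch = int(np.argwhere(exceed.any(axis=1))[0][0])
        reason = f"amplitude beyond {amplitude_sd_threshold} robust SD on channel {ch}"
    cleaned = replace(rec, data=data.copy())
    return cleaned, ArtifactReport(rejected, reason, n_masked)


def compute_csd(rec: LaminarRecording, params: CSDParams | None = None) -> CSDProfile:
    """Estimate the CSD as the negated second spatial difference of the LFP.

    The caller is expected to have interpolated bad channels and applied the
    spatial smoothing already (pipeline order: interpolate -> smooth -> CSD).
    """
    params = params or CSDParams()
    n = params.n
    if rec.n_channels < 2 * n + 1:
        raise ValueError(f"need at least {2 * n + 1} channels for grid n={n}")
    dz_mm = rec.spacing_um / 1000.0
    phi = np.pad(rec.data, ((n, n), (0, 0)), mode="edge")
    c = rec.n_channels
    second_diff = phi[2 * n : 2 * n + c] - 2.0 * phi[n : n + c] + phi[0:c]
    csd = -second_diff / (n * dz_mm) ** 2
    mask = np.zeros(c, dtype=bool)
    mask[:n] = True
    mask[-n:] = True
    if params.boundary == "drop":
        csd[mask] = np.nan
    return CSDProfile(csd, fs=rec.fs, spacing_um=rec.spacing_um, t0=rec.t0,
                      boundary_mask=mask)


def avrec(csd: CSDProfile, include_boundary: bool = True) -> AVRECTrace:
    """Average rectified CSD over channels (mean of |CSD| per sample)."""
    if include_boundary:
        keep = ~np.isnan(csd.values).any(axis=1)
    else:
        keep = ~csd.boundary_mask
        keep &= ~np.isnan(csd.values).any(axis=1)
    if not keep.any():
        raise ValueError("no channels available for AVREC")
    vals = np.abs(csd.values[keep]).mean(axis=0)
    return AVRECTrace(vals, fs=csd.fs, n_channels=int(keep.sum()), t0=csd.t0)


def assign_layers(
    avg_csd: CSDProfile,
    onset_window: tuple[float, float] = (0.0, 0.08),
    threshold_sd: float = 5.0,
    early_tol_s: float = 0.005,
    min_cluster_channels: int = 2,
    manual: LayerMap | None = None,
) -> LayerMap:
    """Assign the five laminar bands from trial-averaged evoked CSD.

    The two earliest sink clusters (contiguous runs of at least
    ``min_cluster_channels`` channels whose -CSD crosses ``threshold_sd``
    pre-stimulus SDs within ``onset_window``) identify the thalamorecipient
    bands: the deeper cluster becomes Vb, the shallower III/IV.  I/II, Va
    and VI fill the remaining depth ranges.  A ``manual`` map, when given,
    is validated and returned verbatim.
    """
    if manual is not None:
        manual.validate_against(avg_csd.n_channels)
        return manual
    t = avg_csd.times
    base = t < 0.0
    if base.sum() < 2:
        raise LayerAssignmentError("no pre-stimulus baseline available")
    sd = avg_csd.values[:, base].std(axis=1, ddof=1)
    sd = np.maximum(sd, 1e-12 * max(sd.max(), 1e-30))
    win = (t >= onset_window[0]) & (t < onset_window[1])
    neg = -avg_csd.values[:, win]  # sink-positive for detection
    crossed = neg > (threshold_sd * sd)[:, None]
    onset_idx = np.where(crossed.any(axis=1), crossed.argmax(axis=1), -1)
    active = onset_idx >= 0

    clusters = []  # (first_ch, last_ch, earliest onset sample)
    ch = 0
    n = avg_csd.n_channels
    while ch < n:
        if active[ch]:
            start = ch
            while ch < n and active[ch]:
                ch += 1
            seg = onset_idx[start:ch]
            if ch - start >= min_cluster_channels:
                clusters.append((start, ch - 1, int(seg.min())))
        else:
            ch += 1
    if len(clusters) < 2:
        raise LayerAssignmentError(
            "fewer than two early sink clusters detected; supply a manual map"
        )
    fs = avg_csd.fs
    t_min = min(c[2] for c in clusters)
    early = [c for c in clusters if (c[2] - t_min) / fs <= early_tol_s]
    if len(early) < 2:
        early = sorted(clusters, key=lambda c: c[2])[:2]
    early = sorted(early, key=lambda c: c[0])
    shallow, deep = early[0], early[-1]
    if shallow[0] == deep[0]:
        raise LayerAssignmentError("early sink clusters overlap; supply a manual map")
    g_lo, g_hi = shallow[0], shallow[1]       # III/IV
    vb_lo, vb_hi = deep[0], deep[1]           # Vb
    if g_lo < 1 or vb_hi >= n - 1 or g_hi >= vb_lo:
        raise LayerAssignmentError(
            "sink clusters leave no room for I/II, Va or VI; supply a manual map"
        )
    bands = {
        "I/II": (0, g_lo - 1),
        "III/IV": (g_lo, g_hi),
        "Va": (g_hi + 1, vb_lo - 1),
        "Vb": (vb_lo, vb_hi),
        "VI": (vb_hi + 1, n - 1),
    }
    if bands["Va"][0] > bands["Va"][1]:
        raise LayerAssignmentError("no channels between granular and Vb sinks")
    return LayerMap(bands)


def default_layer_map(n_channels: int = 32) -> LayerMap:
    """Canonical band boundaries for a 32-channel, 50 um array.

    Proportions follow the usual supragranular/granular/infragranular split
    for rodent auditory cortex; used as the generator's ground truth and as a
    manual-override fallback.
    """
    if n_channels < 10:
        raise ValueError("need at least 10 channels for a five-band map")
    edges = np.round(np.array([0.0, 0.22, 0.44, 0.59, 0.81, 1.0]) * n_channels)
    edges = edges.astype(int)
    bands = {}
    for layer, lo, hi in zip(LAYERS, edges[:-1], edges[1:] - 1):
        bands[layer] = (int(lo), int(hi))
    return LayerMap(bands)
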